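"""Seeded experiment suites: rivalry ensembles and parameter sweeps.

Every sweep draws per-run seeds deterministically from a master seed, so a
SweepResult can be reproduced bit-identically from its spec.  Each network
realization plays the role of a different experimental participant; sweep
observables are averaged over realizations with standard errors.

Stimulus-strength manipulations (Levelt's laws) rescale the mean
feedforward drive into a pool — a pool-specific ``m0`` — leaving the image
structure fixed.  Runs in which fewer than two dominance segments are
observed cannot contribute duration statistics; they are flagged censored
and counted, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import (
    alternation_rate,
    dominant_ei_summary,
    dominant_pool_series,
    dominant_threshold_summary,
    extract_dominance_durations,
    predominance,
)
from .network import ModelParameters, build_network, perturb_feedforward_gaussian
from .recovery import reconstruct_windows
from .simulator import SimulatorSettings, run_simulation
from .stimuli import StimulusSet, fusion_gratings, rivalry_gratings

__all__ = [
    "SweepSpec",
    "SweepResult",
    "simulate_realization",
    "rivalry_ensemble",
    "run_levelt_sweep",
    "run_amblyopia_sweep",
    "run_autism_sweep",
    "run_homogeneity_sweep",
    "run_window_size_sweep",
]


@dataclass(frozen=True)
class SweepSpec:
    """One experiment sweep: values, replication, duration, base parameters."""

    values: tuple
    realizations: int = 10
    duration: float = 40.0
    master_seed: int = 0
    params: ModelParameters = field(default_factory=ModelParameters)
    label_bin: float = 0.1
    smooth: int = 3

    def __post_init__(self):
        if len(self.values) < 1:
            raise ValueError("need at least one swept value")
        if self.realizations < 1 or self.duration <= 0:
            raise ValueError("realizations >= 1 and duration > 0 required")

    def run_seed(self, value_index: int, realization: int) -> np.random.SeedSequence:
        return np.random.SeedSequence([self.master_seed, value_index, realization])


@dataclass
class SweepResult:
    """Per-value summaries plus the raw per-run records behind them."""

    spec: SweepSpec
    summary: pd.DataFrame
    raw: list[dict]

    def censored_counts(self) -> pd.Series:
        df = pd.DataFrame(self.raw)
        return df.groupby("value")["censored"].sum()


def simulate_realization(
    params: ModelParameters,
    stimulus_set: StimulusSet,
    duration: float,
    seed,
    drive_scale=None,
    feedforward: str = "localized",
    connection_prob: float | None = None,
    gauss_std: float | None = None,
    record_voltage: bool = False,
    record_currents: bool = True,
):
    """Build one network realization and simulate it; returns (realization, result).

    ``gauss_std`` perturbs a fully homogeneous feedforward drive
    (Bernoulli p=1 construction) with i.i.d. zero-mean Gaussian offsets of
    the given standard deviation, stated in units of ``g_L (theta_E - V_Re)``
    per unit time like ``sqrt(K) f_k m0`` itself.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_net, s_sim, s_pert = ss.spawn(3)
    realization = build_network(
        params, stimulus_set, s_net,
        feedforward=feedforward, connection_prob=connection_prob,
    )
    drive_override = None
    if gauss_std is not None:
        base = realization.feedforward_drive(stimulus_set)
        drive_override, _ = perturb_feedforward_gaussian(
            base, gauss_std * params.g_L, np.random.default_rng(s_pert)
        )
    settings = SimulatorSettings(
        duration=duration,
        seed=s_sim,
        record_voltage=record_voltage,
        record_currents=record_currents,
    )
    result = run_simulation(
        realization, stimulus_set, settings,
        drive_scale=drive_scale, drive_override=drive_override,
    )
    return realization, result


def _duration_record(result, label_bin=0.1, smooth=3):
    """Dominance record with transient and censored-tail exclusion."""
    labels = dominant_pool_series(result, label_bin, smooth)
    return extract_dominance_durations(
        labels, label_bin, exclude_transient=True, exclude_censored_tail=True
    ), labels


def rivalry_ensemble(
    params: ModelParameters,
    stimulus_set: StimulusSet,
    n_realizations: int,
    duration: float,
    master_seed: int,
    record_currents: bool = False,
) -> tuple[list[float], list[dict]]:
    """Pooled dominance durations over seeded realizations.

    Follows the reference protocol: per run, the first dominance period is
    excluded as transient and the right-censored final segment is dropped;
    the remaining durations from all runs are pooled.
    """
    durations: list[float] = []
    records = []
    for r in range(n_realizations):
        seed = np.random.SeedSequence([master_seed, r])
        _, result = simulate_realization(
            params, stimulus_set, duration, seed, record_currents=record_currents,
        )
        rec, labels = _duration_record(result)
        d = rec.all_durations().tolist()
        durations.extend(d)
        records.append({
            "realization": r, "n_durations": len(d),
            "mean_duration": float(np.mean(d)) if d else np.nan,
            "censored": len(d) == 0,
            "result": result, "record": rec, "labels": labels,
        })
    return durations, records


def _sweep_frame(rows):
    df = pd.DataFrame(rows)
    agg = {}
    for col in df.columns:
        if col in ("value", "realization", "censored"):
            continue
        agg[col] = ["mean", "sem"]
    out = df.groupby("value").agg(agg)
    out.columns = ["_".join(c) for c in out.columns]
    out["n_censored"] = df.groupby("value")["censored"].sum()
    return out.reset_index()


def run_levelt_sweep(kind: int, spec: SweepSpec, stimulus_set: StimulusSet | None = None) -> SweepResult:
    """Sweep monocular stimulus strength and measure Levelt-law observables.

    Laws 1-3 vary pool 1's drive strength with pool 2 held at the base
    ``m0``; law 4 varies both strengths together.  Observables recorded per
    run: pool-1 predominance (law 1), per-pool mean durations (law 2), and
    the consecutive-pair alternation rate (laws 3 and 4).
    """
    if kind not in (1, 2, 3, 4):
        raise ValueError("kind must be 1..4")
    p = spec.params
    if stimulus_set is None:
        stimulus_set = rivalry_gratings()
    rows = []
    for vi, m0_1 in enumerate(spec.values):
        for r in range(spec.realizations):
            scale = m0_1 / p.m0
            drive_scale = np.array([scale, scale]) if kind == 4 else np.array([scale, 1.0])
            _, result = simulate_realization(
                p, stimulus_set, spec.duration, spec.run_seed(vi, r),
                drive_scale=drive_scale, record_currents=False,
            )
            rec, labels = _duration_record(result, spec.label_bin, spec.smooth)
            row = {"value": m0_1, "realization": r}
            n_dur = len(rec.all_durations())
            row["censored"] = n_dur < 2
            # predominance is a time fraction: keep the right-censored tail
            # (dominance time is real even if the final period is truncated)
            rec_time = extract_dominance_durations(
                labels, spec.label_bin, exclude_transient=True,
                exclude_censored_tail=False,
            )
            pre = predominance(rec_time)
            row["predominance_1"] = pre[0] if len(pre) > 0 else np.nan
            if n_dur >= 1:
                d1 = rec.durations.get(0, [])
                d2 = rec.durations.get(1, [])
                row["mean_duration_1"] = float(np.mean(d1)) if d1 else np.nan
                row["mean_duration_2"] = float(np.mean(d2)) if d2 else np.nan
            if n_dur >= 2:
                row["alternation_rate"] = alternation_rate(rec)
            rows.append(row)
    return SweepResult(spec, _sweep_frame(rows), rows)


def run_amblyopia_sweep(spec: SweepSpec, stimulus_set: StimulusSet | None = None) -> SweepResult:
    """Scale the pool-1 -> pool-2 long-range connections by S_C and measure durations.

    Strengthening one direction of interocular competition models the
    fellow eye's advantage in amblyopia: pool 1 suppresses pool 2 more
    effectively, so pool-1 dominance lengthens and pool-2 (the amblyopic
    eye) dominance shortens.
    """
    if stimulus_set is None:
        stimulus_set = rivalry_gratings()
    rows = []
    for vi, s_c in enumerate(spec.values):
        params = spec.params.with_(S_C={(0, 1): float(s_c)})
        for r in range(spec.realizations):
            _, result = simulate_realization(
                params, stimulus_set, spec.duration, spec.run_seed(vi, r),
                record_currents=False,
            )
            rec, _ = _duration_record(result, spec.label_bin, spec.smooth)
            d1 = rec.durations.get(0, [])
            d2 = rec.durations.get(1, [])
            rows.append({
                "value": s_c, "realization": r,
                "censored": len(rec.all_durations()) < 2,
                "mean_duration_1": float(np.mean(d1)) if d1 else np.nan,
                "mean_duration_2": float(np.mean(d2)) if d2 else np.nan,
            })
    return SweepResult(spec, _sweep_frame(rows), rows)


def run_autism_sweep(
    which: str, spec: SweepSpec, stimulus_set: StimulusSet | None = None,
    diagnostics: bool = True,
) -> SweepResult:
    """Scale recurrent inhibition (S_I) or excitation (S_E) and measure durations.

    Both manipulations raise the magnitude of the E/I input ratio — the
    imbalance hypothesized in autism — while leaving the balance-condition
    ratios untouched.  Diagnostics per run: the dominance-period-averaged
    dominant-excitatory threshold and E/I input ratio.
    """
    if which not in ("S_I", "S_E"):
        raise ValueError("which must be 'S_I' or 'S_E'")
    if stimulus_set is None:
        stimulus_set = rivalry_gratings()
    rows = []
    for vi, s in enumerate(spec.values):
        if s <= 0:
            raise ValueError("scaling values must be > 0")
        params = spec.params.with_(**{which: float(s)})
        for r in range(spec.realizations):
            _, result = simulate_realization(
                params, stimulus_set, spec.duration, spec.run_seed(vi, r),
                record_currents=diagnostics,
            )
            rec, labels = _duration_record(result, spec.label_bin, spec.smooth)
            d = rec.all_durations()
            row = {
                "value": s, "realization": r, "censored": len(d) < 2,
                "mean_duration": float(np.mean(d)) if len(d) else np.nan,
            }
            if diagnostics:
                dom_ei, _ = dominant_ei_summary(result, labels, spec.label_bin)
                row["dominant_ei"] = dom_ei
                row["dominant_threshold"] = dominant_threshold_summary(
                    result, labels, spec.label_bin
                )
            rows.append(row)
    return SweepResult(spec, _sweep_frame(rows), rows)


def run_homogeneity_sweep(
    kind: str, spec: SweepSpec, stimulus_set: StimulusSet | None = None
) -> SweepResult:
    """Vary feedforward-drive homogeneity at fixed expected drive.

    ``bernoulli_p`` sweeps the i.i.d. feedforward connection probability
    (denser sampling -> more homogeneous total drive); ``gauss_std`` sweeps
    the standard deviation of Gaussian perturbations to a fully homogeneous
    drive.  More homogeneous drive means rarer switch-triggering input
    fluctuations, hence longer dominance durations.
    """
    if kind not in ("bernoulli_p", "gauss_std"):
        raise ValueError("kind must be 'bernoulli_p' or 'gauss_std'")
    if stimulus_set is None:
        stimulus_set = rivalry_gratings()
    rows = []
    for vi, v in enumerate(spec.values):
        for r in range(spec.realizations):
            kw = dict(record_currents=False)
            if kind == "bernoulli_p":
                kw.update(feedforward="bernoulli", connection_prob=float(v))
            else:
                kw.update(feedforward="bernoulli", connection_prob=1.0,
                          gauss_std=float(v))
            _, result = simulate_realization(
                spec.params, stimulus_set, spec.duration, spec.run_seed(vi, r), **kw
            )
            rec, _ = _duration_record(result, spec.label_bin, spec.smooth)
            d = rec.all_durations()
            rows.append({
                "value": v, "realization": r, "censored": len(d) < 2,
                "mean_duration": float(np.mean(d)) if len(d) else np.nan,
            })
    return SweepResult(spec, _sweep_frame(rows), rows)


def run_window_size_sweep(
    spec: SweepSpec,
    max_windows: int | None = None,
    max_atoms: int | None = None,
) -> dict[str, SweepResult]:
    """Mean percept reconstruction error vs. window size, rivalry and fusion.

    For each realization one simulation is recorded with per-neuron voltage
    and threshold statistics, then reconstructed at every requested window
    size (``spec.values``, seconds).  ``max_windows`` caps the number of
    windows reconstructed per run (evenly subsampled) to bound cost.
    """
    out = {}
    for name, stim in [("rivalry", rivalry_gratings()), ("fusion", fusion_gratings())]:
        rows = []
        for r in range(spec.realizations):
            realization, result = simulate_realization(
                spec.params, stim, spec.duration,
                np.random.SeedSequence([spec.master_seed, r]),
                record_voltage=True, record_currents=False,
            )
            for vi, w in enumerate(spec.values):
                n_win = int(np.floor(spec.duration / w))
                idx = None
                if max_windows is not None and n_win - 1 > max_windows:
                    idx = set(np.unique(np.linspace(1, n_win - 1, max_windows).astype(int)).tolist())
                recons = reconstruct_windows(
                    realization, result, stim, window=float(w),
                    max_atoms=max_atoms, window_indices=idx,
                )
                errs = [rc.percept_error for rc in recons]
                rows.append({
                    "value": w, "realization": r, "censored": len(errs) == 0,
                    "mean_error": float(np.mean(errs)) if errs else np.nan,
                })
        out[name] = SweepResult(spec, _sweep_frame(rows), rows)
    return out
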