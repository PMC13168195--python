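"""Behavioral observables: dominance, durations, predominance, E/I ratios.

A pool is "dominant" in a bin when its excitatory population fires fastest;
a dominance period is a maximal run of bins with the same dominant pool.
The labeling bin (default 100 ms) is majority-smoothed over a small window
(default 3 bins) to suppress single-bin chatter around switches; it is a
detection granularity, independent of the 600 ms reconstruction window and
of the 60 ms current bin used for E/I input ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .simulator import SimulationResult

__all__ = [
    "DominanceRecord",
    "EIRatioSeries",
    "dominant_pool_series",
    "extract_dominance_durations",
    "predominance",
    "alternation_rate",
    "ei_ratio_series",
    "duration_statistics",
    "dominant_ei_summary",
    "dominant_threshold_summary",
]


@dataclass
class DominanceRecord:
    """Run-length encoded dominance segments and the durations per pool."""

    segments: list[tuple[float, float, int]]   # (start s, end s, pool)
    durations: dict[int, list[float]]
    transient_excluded: bool
    censored_tail_excluded: bool = False
    run_id: object = None

    def all_durations(self) -> np.ndarray:
        return np.array([end - start for start, end, _ in self.segments])

    def ordered_durations(self) -> np.ndarray:
        """Durations in temporal order (for consecutive-pair statistics)."""
        return self.all_durations()


@dataclass
class EIRatioSeries:
    """Population-mean E/I input ratios per 60 ms bin; zero-I neurons excluded."""

    bin_width: float
    ratios: np.ndarray          # (n_bins, q, 2) population means, NaN where empty
    excluded_counts: np.ndarray # (n_bins, q, 2) neurons dropped for zero I input


def dominant_pool_series(
    result: SimulationResult, bin_width: float = 0.1, smooth: int = 3
) -> np.ndarray:
    """Per-bin dominant-pool labels: argmax excitatory rate, majority-smoothed.

    Bins with no excitatory spikes anywhere carry the previous label
    forward.  ``smooth`` is the (odd) width of the centered majority filter.
    """
    counts = result.excitatory_counts(bin_width)
    n_bins, q = counts.shape
    labels = np.argmax(counts, axis=1)
    empty = counts.sum(axis=1) == 0
    for i in range(n_bins):
        if empty[i] and i > 0:
            labels[i] = labels[i - 1]
    if smooth > 1:
        half = smooth // 2
        sm = labels.copy()
        for i in range(n_bins):
            lo, hi = max(0, i - half), min(n_bins, i + half + 1)
            window = labels[lo:hi]
            votes = np.bincount(window, minlength=q)
            best = votes.max()
            # ties keep the current label to avoid spurious switches
            if votes[labels[i]] < best:
                sm[i] = int(np.argmax(votes))
        labels = sm
    return labels


def extract_dominance_durations(
    labels: np.ndarray,
    bin_width: float = 0.1,
    exclude_transient: bool = True,
    exclude_censored_tail: bool = False,
) -> DominanceRecord:
    """Run-length encode labels into dominance segments.

    ``exclude_transient`` drops the first segment (the initial transient,
    during which thresholds are low and alternations are atypically fast).
    ``exclude_censored_tail`` additionally drops the final segment, which is
    right-censored by the end of the run and is not a completed dominance
    duration; ensemble statistics set this flag.
    """
    labels = np.asarray(labels)
    n = len(labels)
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [n]])
    segments = [
        (s * bin_width, e * bin_width, int(labels[s])) for s, e in zip(starts, ends)
    ]
    if exclude_transient and len(segments) > 1:
        segments = segments[1:]
    if exclude_censored_tail and len(segments) > 1:
        segments = segments[:-1]
    durations: dict[int, list[float]] = {}
    for s, e, pool in segments:
        durations.setdefault(pool, []).append(e - s)
    return DominanceRecord(
        segments=segments,
        durations=durations,
        transient_excluded=exclude_transient,
        censored_tail_excluded=exclude_censored_tail,
    )


def predominance(record: DominanceRecord) -> np.ndarray:
    """Fraction of (retained) time each pool is dominant; sums to 1."""
    if not record.segments:
        raise ValueError("empty dominance record")
    q = max(pool for _, _, pool in record.segments) + 1
    totals = np.zeros(q)
    for s, e, pool in record.segments:
        totals[pool] += e - s
    return totals / totals.sum()


def alternation_rate(record: DominanceRecord) -> float:
    """Mean over consecutive duration pairs of 1 / (d_i + d_{i+1}), in 1/s.

    The pairwise-sum reciprocal weights each pool's duration fairly even
    when the two monocular stimuli differ in strength.
    """
    d = record.ordered_durations()
    if len(d) < 2:
        raise ValueError("need at least two consecutive dominance durations")
    return float(np.mean(1.0 / (d[:-1] + d[1:])))


def ei_ratio_series(result: SimulationResult) -> EIRatioSeries:
    """Population-mean per-neuron E/I input ratios in the recorded current bins.

    The per-neuron ratio (excitatory total / inhibitory total) is negative
    by sign convention: -1 indicates balance, values in (-1, 0) excess
    inhibition, below -1 excess excitation.  Neurons with zero inhibitory
    input in a bin are excluded from that bin's average (counts recorded).
    """
    if result.exc_input is None:
        raise ValueError("run was not recorded with record_currents=True")
    p = result.params
    n_bins = result.exc_input.shape[0]
    ratios = np.full((n_bins, p.q, 2), np.nan)
    excluded = np.zeros((n_bins, p.q, 2), dtype=int)
    for x in range(p.q):
        for k, sl in enumerate([
            slice(x * p.N, x * p.N + p.N_E),
            slice(x * p.N + p.N_E, (x + 1) * p.N),
        ]):
            E = result.exc_input[:, sl]
            I = result.inh_input[:, sl]
            defined = I < 0
            excluded[:, x, k] = (~defined).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(defined, E / I, np.nan)
            any_def = defined.any(axis=1)
            ratios[any_def, x, k] = np.nanmean(r[any_def], axis=1)
    return EIRatioSeries(result.settings.current_bin, ratios, excluded)


def duration_statistics(record: DominanceRecord, gamma_fit: bool = False) -> dict:
    """Sample moments (mean, CV, skewness), histogram, optional gamma ML fit."""
    d = record.all_durations()
    out: dict = {"n": len(d)}
    counts, edges = np.histogram(d, bins="auto") if len(d) else (np.array([]), np.array([]))
    out["histogram"] = (counts, edges)
    if len(d) >= 5:
        out["mean"] = float(np.mean(d))
        out["cv"] = float(np.std(d, ddof=1) / np.mean(d))
        out["skewness"] = float(scipy.stats.skew(d))
    if gamma_fit:
        if len(d) < 5:
            raise ValueError("need >= 5 durations for a gamma fit")
        shape, loc, scale = scipy.stats.gamma.fit(d, floc=0.0)
        out["gamma_shape"] = float(shape)
        out["gamma_scale"] = float(scale)
    return out


def _dominance_bins(result, labels, label_bin):
    """Map each current bin to the concurrent dominance label."""
    cb = result.settings.current_bin
    n_cbins = result.exc_input.shape[0]
    centers = (np.arange(n_cbins) + 0.5) * cb
    idx = np.minimum((centers / label_bin).astype(int), len(labels) - 1)
    return labels[idx], centers


def dominant_ei_summary(
    result: SimulationResult,
    labels: np.ndarray | None = None,
    label_bin: float = 0.1,
    exclude_before: float | None = None,
) -> tuple[float, float]:
    """Mean E/I ratio of the dominant vs. suppressed excitatory populations.

    Averages each current bin's population-mean excitatory E/I ratio over
    bins where the pool is (respectively is not) dominant, then over bins.
    ``exclude_before`` drops bins before that time; by default the first
    dominance segment is excluded per the transient policy.
    """
    if labels is None:
        labels = dominant_pool_series(result, label_bin)
    series = ei_ratio_series(result)
    lbl, centers = _dominance_bins(result, labels, label_bin)
    if exclude_before is None:
        rec = extract_dominance_durations(labels, label_bin, exclude_transient=False)
        exclude_before = rec.segments[0][1] if len(rec.segments) > 1 else 0.0
    keep = centers >= exclude_before
    p = result.params
    dom_vals, sup_vals = [], []
    for b in np.flatnonzero(keep):
        d = lbl[b]
        dom_vals.append(series.ratios[b, d, 0])
        for x in range(p.q):
            if x != d:
                sup_vals.append(series.ratios[b, x, 0])
    return float(np.nanmean(dom_vals)), float(np.nanmean(sup_vals))


def dominant_threshold_summary(
    result: SimulationResult,
    labels: np.ndarray | None = None,
    label_bin: float = 0.1,
    exclude_before: float | None = None,
) -> float:
    """Dominance-period-averaged excitatory threshold of the dominant pool."""
    if labels is None:
        labels = dominant_pool_series(result, label_bin)
    cb = result.settings.current_bin
    n_cbins = result.pop_threshold_traces.shape[0]
    centers = (np.arange(n_cbins) + 0.5) * cb
    idx = np.minimum((centers / label_bin).astype(int), len(labels) - 1)
    lbl = labels[idx]
    if exclude_before is None:
        rec = extract_dominance_durations(labels, label_bin, exclude_transient=False)
        exclude_before = rec.segments[0][1] if len(rec.segments) > 1 else 0.0
    keep = centers >= exclude_before
    vals = [result.pop_threshold_traces[b, lbl[b], 0] for b in np.flatnonzero(keep)]
    return float(np.mean(vals))
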