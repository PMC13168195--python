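"""Percept recovery from short-time windows of network statistics.

For each time window (default 600 ms, comparable to human reaction time) we
measure per-neuron firing rates, mean voltages and mean thresholds, invert
the linear input-output map restricted to the excitatory rows,

    F_x p_x = g_L (vbar_x - V_Re) - R_x m_x - sum_y C_xy m_y + m_x (thbar_x - V_Re),

and solve the underdetermined system (N_E equations, n = 10 N_E unknowns)
by orthogonal matching pursuit in an orthonormal 2-D DCT basis, where
gratings and natural scenes are sparse.  Per-pool reconstructions are then
combined into a single percept, weighted by each pool's relative excitatory
population rate — the current evidence in favor of each percept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.sparse as sp

from .network import NetworkRealization
from .simulator import SimulationResult
from .stimuli import StimulusSet

__all__ = [
    "WindowStatistics",
    "ReconstructionResult",
    "compute_window_statistics",
    "assemble_inverse_problem",
    "sparse_reconstruct",
    "combine_percepts",
    "relative_error",
    "dominance_metric",
    "reconstruct_windows",
]


@dataclass
class WindowStatistics:
    """Per-window measurements feeding the inverse problem."""

    index: int
    t_start: float
    t_end: float
    rates: np.ndarray            # (qN,) spikes/s
    mean_voltage: np.ndarray     # (qN,)
    mean_threshold: np.ndarray   # (qN,)
    pool_exc_rates: np.ndarray   # (q,) population-mean excitatory rate, spikes/s
    weights: np.ndarray          # (q,) relative excitatory rates; sum to 1
    weights_defined: bool


@dataclass
class ReconstructionResult:
    """Per-pool reconstructions and the combined, rate-weighted percept."""

    window: WindowStatistics
    pool_reconstructions: np.ndarray   # (q, n), clipped at 0
    percept: np.ndarray                # (n,)
    weights: np.ndarray                # (q,)
    relative_errors: np.ndarray        # (q,) per-pool error vs. own stimulus
    percept_error: float               # combined percept vs. dominant stimulus
    dominant_pool: int
    atoms: list = field(default_factory=list)
    residual_norms: list = field(default_factory=list)


def compute_window_statistics(
    result: SimulationResult, window: float
) -> list[WindowStatistics]:
    """Tile [0, duration] into ``floor(duration/window)`` windows of statistics.

    Rates are spike counts divided by the window length; voltage/threshold
    means average the simulator's per-neuron stat bins falling in the
    window (the window must be a multiple of the stat bin, and the run must
    have been recorded with ``record_voltage=True``).
    """
    s = result.settings
    if window > s.duration:
        raise ValueError("window exceeds run duration")
    if result.neuron_voltage_bins is None:
        raise ValueError("run was not recorded with record_voltage=True")
    ratio = window / s.stat_bin
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("window must be a multiple of stat_bin")
    bins_per = int(round(ratio))
    p = result.params
    n_windows = int(np.floor(s.duration / window))
    is_exc = np.zeros(p.q * p.N, dtype=bool)
    for x in range(p.q):
        is_exc[x * p.N : x * p.N + p.N_E] = True
    out = []
    for w in range(n_windows):
        t0, t1 = w * window, (w + 1) * window
        rates = result.spike_counts_per_neuron(t0, t1) / window
        vbar = result.neuron_voltage_bins[w * bins_per : (w + 1) * bins_per].mean(axis=0)
        thbar = result.neuron_threshold_bins[w * bins_per : (w + 1) * bins_per].mean(axis=0)
        pool_rates = np.array([
            rates[x * p.N : x * p.N + p.N_E].mean() for x in range(p.q)
        ])
        total = pool_rates.sum()
        if total > 0:
            weights = pool_rates / total
            defined = True
        else:
            weights = np.full(p.q, np.nan)
            defined = False
        out.append(WindowStatistics(
            index=w, t_start=t0, t_end=t1, rates=rates,
            mean_voltage=vbar, mean_threshold=thbar,
            pool_exc_rates=pool_rates, weights=weights, weights_defined=defined,
        ))
    return out


def assemble_inverse_problem(
    realization: NetworkRealization,
    stats: WindowStatistics,
    pool: int,
) -> tuple[sp.csr_array, np.ndarray]:
    """Excitatory-row restriction of the pool's linear inverse problem.

    Returns the (N_E, n) feedforward matrix and the right-hand side computed
    from the window's rates, voltages and thresholds.  Only the excitatory
    rows are used because inhibitory neurons keep firing when their pool is
    suppressed, so their statistics carry cross-pool rather than stimulus
    information.
    """
    p = realization.params
    m = stats.rates
    sl = slice(pool * p.N, pool * p.N + p.N_E)
    pool_sl = slice(pool * p.N, (pool + 1) * p.N)
    recurrent_in = (realization.recurrent[pool] @ m[pool_sl])[: p.N_E]
    cross_in = np.zeros(p.N_E)
    for (src, tgt), C in realization.long_range.items():
        if tgt == pool:
            cross_in += (C @ m[src * p.N : (src + 1) * p.N])[: p.N_E]
    rhs = (
        p.g_L * (stats.mean_voltage[sl] - p.V_Re)
        - recurrent_in
        - cross_in
        + m[sl] * (stats.mean_threshold[sl] - p.V_Re)
    )
    F_exc = realization.feedforward[pool][: p.N_E]
    return F_exc, rhs


class IdentityBasis:
    """Trivial basis: the signal is assumed sparse in the pixel domain."""

    def analyze(self, signal: np.ndarray) -> np.ndarray:
        return np.asarray(signal, dtype=float).ravel()

    def synthesize(self, coeffs: np.ndarray) -> np.ndarray:
        return np.asarray(coeffs, dtype=float).ravel()

    def transform_measurement(self, A) -> np.ndarray:
        return np.asarray(A.todense()) if sp.issparse(A) else np.asarray(A, dtype=float)


class DCTBasis:
    """Orthonormal 2-D DCT sparsifying basis for square images."""

    def __init__(self, shape: tuple[int, int]):
        self.shape = shape

    def analyze(self, signal: np.ndarray) -> np.ndarray:
        """Image-domain vector -> DCT coefficients."""
        return scipy.fft.dctn(signal.reshape(self.shape), norm="ortho").ravel()

    def synthesize(self, coeffs: np.ndarray) -> np.ndarray:
        """DCT coefficients -> image-domain vector."""
        return scipy.fft.idctn(coeffs.reshape(self.shape), norm="ortho").ravel()

    def transform_measurement(self, A) -> np.ndarray:
        """Rows of A re-expressed in the coefficient domain: M = A B^{-1}.

        For an orthonormal basis B, M's rows are the forward transform of
        A's rows.
        """
        A = np.asarray(A.todense()) if sp.issparse(A) else np.asarray(A)
        out = np.empty_like(A)
        for i in range(A.shape[0]):
            out[i] = self.analyze(A[i])
        return out


def _omp(M: np.ndarray, rhs: np.ndarray, max_atoms: int, residual_tol: float):
    """Orthogonal matching pursuit with incremental Gram solves.

    Picks the max-|correlation| atom each iteration, re-fits all active
    coefficients by least squares, stops when ``max_atoms`` are selected or
    the residual norm drops below ``residual_tol``.  Deterministic;
    rank-degenerate picks are dropped with a warning flag.
    """
    m, n = M.shape
    norms = np.linalg.norm(M, axis=0)
    norms[norms == 0] = 1.0
    residual = rhs.astype(float).copy()
    active: list[int] = []
    banned: set[int] = set()
    coeffs = np.zeros(0)
    res_norms = [float(np.linalg.norm(residual))]
    G = np.zeros((max_atoms, max_atoms))
    Mty = np.zeros(max_atoms)
    while len(active) < max_atoms and res_norms[-1] > residual_tol:
        corr = np.abs(M.T @ residual) / norms
        if active or banned:
            corr[list(set(active) | banned)] = -1.0
        j = int(np.argmax(corr))
        if corr[j] <= 0:
            break
        k = len(active)
        col = M[:, j]
        G[k, :k] = G[:k, k] = M[:, active].T @ col if k else 0.0
        G[k, k] = col @ col
        Mty[k] = col @ rhs
        try:
            c = np.linalg.solve(G[: k + 1, : k + 1], Mty[: k + 1])
        except np.linalg.LinAlgError:
            banned.add(j)
            continue
        if not np.all(np.isfinite(c)):
            banned.add(j)
            continue
        active.append(j)
        coeffs = c
        residual = rhs - M[:, active] @ coeffs
        res_norms.append(float(np.linalg.norm(residual)))
    return np.array(active, dtype=int), coeffs, res_norms


def sparse_reconstruct(
    A,
    rhs: np.ndarray,
    basis: DCTBasis,
    max_atoms: int | None = None,
    residual_tol: float | None = None,
    transformed: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Greedy sparse recovery of a nonnegative image from A p = rhs.

    Solves for coefficients sparse in ``basis`` via OMP, synthesizes the
    image, and clips negative pixels to zero (images are nonnegative; the
    number of clipped pixels is recorded in the diagnostics).  Stopping:
    ``max_atoms`` (default 10% of the number of equations) or a residual
    below ``residual_tol`` (default 1e-3 of the rhs norm), whichever first.
    """
    rhs = np.asarray(rhs, dtype=float)
    if not np.all(np.isfinite(rhs)):
        raise ValueError("non-finite right-hand side")
    m = A.shape[0]
    if max_atoms is None:
        max_atoms = max(1, m // 10)
    if residual_tol is None:
        residual_tol = 1e-3 * float(np.linalg.norm(rhs))
    if not np.any(rhs):
        n = A.shape[1]
        return np.zeros(n), {"atoms": [], "residual_norms": [0.0], "clipped": 0}
    M = basis.transform_measurement(A) if transformed is None else transformed
    active, coeffs, res_norms = _omp(M, rhs, max_atoms, residual_tol)
    c_full = np.zeros(A.shape[1])
    c_full[active] = coeffs
    recon = basis.synthesize(c_full)
    clipped = int(np.sum(recon < 0))
    recon = np.clip(recon, 0.0, None)
    return recon, {
        "atoms": active.tolist(),
        "residual_norms": res_norms,
        "clipped": clipped,
    }


def combine_percepts(recons: np.ndarray, weights: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Convex combination of per-pool reconstructions with rate weights."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if abs(weights.sum() - 1.0) > tol:
        raise ValueError("weights must sum to 1")
    return np.tensordot(weights, np.asarray(recons), axes=1)


def relative_error(truth: np.ndarray, recon: np.ndarray) -> float:
    """Euclidean relative reconstruction error ||p - p_recon|| / ||p||."""
    truth = np.asarray(truth, dtype=float).ravel()
    nt = np.linalg.norm(truth)
    if nt == 0:
        raise ValueError("truth image has zero norm")
    return float(np.linalg.norm(truth - np.asarray(recon).ravel()) / nt)


def dominance_metric(pool_exc_rates: np.ndarray) -> np.ndarray:
    """Two-pool dominance metric M = (m1E - m2E) / (m1E + m2E), in [-1, 1].

    Positive values indicate pool-1 dominance.  Windows where both rates are
    zero are emitted as NaN gaps.
    """
    r = np.asarray(pool_exc_rates, dtype=float)
    if r.ndim == 1:
        r = r[None, :]
    if r.shape[1] != 2:
        raise ValueError("dominance metric is defined for q = 2 only")
    denom = r[:, 0] + r[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(denom > 0, (r[:, 0] - r[:, 1]) / denom, np.nan)
    return M


def reconstruct_windows(
    realization: NetworkRealization,
    result: SimulationResult,
    stimulus_set: StimulusSet,
    window: float = 0.6,
    max_atoms: int | None = None,
    residual_tol: float | None = None,
    skip_first: bool = True,
    window_indices=None,
) -> list[ReconstructionResult]:
    """Run the full recovery pipeline over a simulation's time windows.

    The first window is skipped by default (initial transient, during which
    thresholds are still low and reconstructions degrade).  The per-window
    truth for the combined-percept error is the stimulus of the pool with
    the highest excitatory population rate in that window.
    ``window_indices`` restricts recovery to a subset of windows.
    """
    stats = compute_window_statistics(result, window)
    basis = DCTBasis(stimulus_set.shape)
    truths = stimulus_set.vectors()
    p = realization.params
    # the measurement matrix is fixed per realization; transform it once
    transformed = [
        basis.transform_measurement(realization.feedforward[x][: p.N_E])
        for x in range(stimulus_set.q)
    ]
    out = []
    for st in stats:
        if skip_first and st.index == 0:
            continue
        if window_indices is not None and st.index not in window_indices:
            continue
        if not st.weights_defined:
            continue
        recons = np.zeros((stimulus_set.q, stimulus_set.n))
        atoms, res_norms = [], []
        for pool in range(stimulus_set.q):
            A, rhs = assemble_inverse_problem(realization, st, pool)
            recons[pool], diag = sparse_reconstruct(
                A, rhs, basis, max_atoms=max_atoms, residual_tol=residual_tol,
                transformed=transformed[pool],
            )
            atoms.append(diag["atoms"])
            res_norms.append(diag["residual_norms"][-1])
        percept = combine_percepts(recons, st.weights)
        dom = int(np.argmax(st.pool_exc_rates))
        out.append(ReconstructionResult(
            window=st,
            pool_reconstructions=recons,
            percept=percept,
            weights=st.weights,
            relative_errors=np.array([
                relative_error(truths[x], recons[x]) for x in range(stimulus_set.q)
            ]),
            percept_error=relative_error(truths[dom], percept),
            dominant_pool=dom,
            atoms=atoms,
            residual_norms=res_norms,
        ))
    return out
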