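"""Model parameters and sampled connectivity for one network realization.

Conventions
-----------
* Voltages are nondimensional: reset ``V_Re = 0`` and excitatory threshold
  ``theta_E = 1``; time is in seconds with leak rate ``g_L = 50 /s``.
* Balanced-network scaling: an individual synaptic weight is
  ``R_kl / sqrt(K)`` and the population-expected feedforward drive into a
  population-``k`` neuron is ``sqrt(K) * f_k * m0`` threshold units per
  membrane time constant, i.e. a drive of ``g_L * sqrt(K) * f_k * m0`` per
  second.  With this scaling the mean recurrent and feedforward inputs are
  each ``O(sqrt(K))`` and cancel to ``O(1)``, leaving fluctuation-driven
  irregular firing — the regime the whole framework relies on.
* Within each pool's ``N x N`` matrices, excitatory neurons occupy the first
  ``N_E`` indices and inhibitory the next ``N_I``.  Globally, pool ``x``
  occupies indices ``[x*N, (x+1)*N)``.
* Adaptation rate ``lambda_adapt`` and increment ``phi`` are read in the
  same nondimensional units (per membrane leak time), so the physical decay
  rate is ``lambda_adapt * g_L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .stimuli import StimulusSet

__all__ = [
    "ModelParameters",
    "NetworkRealization",
    "build_recurrent",
    "build_long_range",
    "build_feedforward_localized",
    "build_feedforward_bernoulli",
    "perturb_feedforward_gaussian",
    "build_network",
]


@dataclass(frozen=True)
class ModelParameters:
    """All scalar model parameters; the single source of truth.

    Defaults reproduce the reference two-pool rivalry configuration:
    balanced recurrent strengths, 1000+1000 neurons per pool, mean in-degree
    40, and the rivalry adaptation constants.
    """

    R_EE: float = 1.0
    R_IE: float = 1.0
    R_EI: float = -2.0
    R_II: float = -1.8
    N_E: int = 1000
    N_I: int = 1000
    K: int = 40
    q: int = 2
    f_E: float = 1.0
    f_I: float = 0.8
    m0: float = 0.4
    lambda_adapt: float = 0.00625
    phi: float = 0.005
    theta_E: float = 1.0
    theta_I: float = 0.8
    g_L: float = 50.0
    V_Re: float = 0.0
    rho: float = 0.96
    sigma_rf: float = 1.75
    S_C: dict = field(default_factory=dict)   # (source_pool, target_pool) -> scale
    S_I: float = 1.0
    S_E: float = 1.0

    def __post_init__(self):
        if not (self.R_EE > 0 and self.R_IE > 0):
            raise ValueError("excitatory strengths R_EE, R_IE must be > 0")
        if not (self.R_EI < 0 and self.R_II < 0):
            raise ValueError("inhibitory strengths R_EI, R_II must be < 0")
        if not (1 <= self.K <= min(self.N_E, self.N_I)):
            raise ValueError("need 1 <= K <= min(N_E, N_I)")
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.phi < 0 or self.lambda_adapt < 0:
            raise ValueError("phi and lambda_adapt must be >= 0")
        if self.theta_E <= self.V_Re or self.theta_I <= self.V_Re:
            raise ValueError("thresholds must exceed the reset potential")
        if not (0 < self.rho <= 1):
            raise ValueError("rho must lie in (0, 1]")
        if self.sigma_rf <= 0:
            raise ValueError("sigma_rf must be > 0")

    @property
    def N(self) -> int:
        return self.N_E + self.N_I

    @property
    def sqrtK(self) -> float:
        return float(np.sqrt(self.K))

    @property
    def lambda_phys(self) -> float:
        """Threshold decay rate in 1/s."""
        return self.lambda_adapt * self.g_L

    def long_range_scale(self, source: int, target: int) -> float:
        return float(self.S_C.get((source, target), 1.0))

    def with_(self, **kw) -> "ModelParameters":
        return replace(self, **kw)

    def theta_base(self) -> np.ndarray:
        """Per-neuron non-adapted thresholds for one pool (E block then I block)."""
        return np.concatenate([
            np.full(self.N_E, self.theta_E),
            np.full(self.N_I, self.theta_I),
        ])


def _dense_bernoulli(rng, n_post, n_pre, prob, value):
    """Bernoulli(prob) mask times a constant, as a CSR sparse matrix.

    Sampling draws the full uniform block so that a block's pattern depends
    only on the rng stream position and its shape — never on the connection
    value.  That makes S_E / S_I scaling exactly equivariant: scaling after
    construction equals constructing with scaled strengths under the same
    seed.
    """
    mask = rng.random((n_post, n_pre)) < prob
    return sp.csr_array(mask * value)


def build_recurrent(params: ModelParameters, rng) -> list[sp.csr_array]:
    """Sample the per-pool N x N recurrent matrices.

    Entry (post i in population k, pre j in population l) equals
    ``S * R_kl / sqrt(K)`` with probability ``K / N_l`` and 0 otherwise,
    where ``S`` is ``S_E`` for excitatory sources and ``S_I`` for inhibitory
    sources.  The diagonal is forced to zero (no self-coupling).
    """
    rng = np.random.default_rng(rng)
    p = params
    sK = p.sqrtK
    mats = []
    for _ in range(p.q):
        # S * (R / sqrt(K)): scaling the base weight keeps post-construction
        # S-scaling exactly (bitwise) equivalent to scaled construction
        ee = _dense_bernoulli(rng, p.N_E, p.N_E, p.K / p.N_E, p.S_E * (p.R_EE / sK))
        ei = _dense_bernoulli(rng, p.N_E, p.N_I, p.K / p.N_I, p.S_I * (p.R_EI / sK))
        ie = _dense_bernoulli(rng, p.N_I, p.N_E, p.K / p.N_E, p.S_E * (p.R_IE / sK))
        ii = _dense_bernoulli(rng, p.N_I, p.N_I, p.K / p.N_I, p.S_I * (p.R_II / sK))
        R = sp.block_array([[ee, ei], [ie, ii]], format="csr")
        R.setdiag(0.0)
        R.eliminate_zeros()
        mats.append(R)
    return mats


def build_long_range(params: ModelParameters, rng) -> dict[tuple[int, int], sp.csr_array]:
    """Sample long-range matrices for each ordered pool pair (source, target).

    Long-range connections exist only from excitatory neurons of the source
    pool onto inhibitory neurons of the target pool, with strength
    ``S_C(source, target) * R_IE / sqrt(K)`` and probability ``K / N_E`` —
    the same statistics as within-pool E-to-I coupling, which is why both
    pools' inhibitory populations stay equally driven whichever pool wins.
    """
    rng = np.random.default_rng(rng)
    p = params
    out: dict[tuple[int, int], sp.csr_array] = {}
    if p.q < 2:
        return out
    for src in range(p.q):
        for tgt in range(p.q):
            if src == tgt:
                continue
            val = p.long_range_scale(src, tgt) * (p.R_IE / p.sqrtK)
            ie = _dense_bernoulli(rng, p.N_I, p.N_E, p.K / p.N_E, val)
            zero_ee = sp.csr_array((p.N_E, p.N_E))
            zero_ei = sp.csr_array((p.N_E, p.N_I))
            zero_ii = sp.csr_array((p.N_I, p.N_I))
            out[(src, tgt)] = sp.block_array(
                [[zero_ee, zero_ei], [ie, zero_ii]], format="csr"
            )
    return out


def _normalize_rows(masks, stimulus_vec, params, weights_out):
    """Common positive weight per population making the population-mean drive
    equal g_L * sqrt(K) * f_k * m0 (in 1/s) for this stimulus."""
    p = params
    F = []
    for f_k, sl in [(p.f_E, slice(0, p.N_E)), (p.f_I, slice(p.N_E, p.N))]:
        mask = masks[sl]
        raw = mask @ stimulus_vec
        mean_raw = raw.mean()
        if mean_raw <= 0:
            raise ValueError("stimulus yields zero expected feedforward drive")
        w = p.g_L * p.sqrtK * f_k * p.m0 / mean_raw
        F.append(mask * w)
        weights_out.append(w)
    return sp.vstack(F, format="csr")


def build_feedforward_localized(
    params: ModelParameters, stimulus_set: StimulusSet, rng,
    centers_out: list | None = None,
) -> list[sp.csr_array]:
    """Sample localized-receptive-field feedforward matrices, one per pool.

    Each downstream neuron is given a uniformly random center on the pixel
    grid and samples pixel ``j`` independently with probability
    ``rho * exp(-[(xi-xj)^2 + (yi-yj)^2] / (2 sigma^2))``.  Sampled entries
    share a common positive weight per population, fixed so the
    population-mean total drive for the pool's (normalized) stimulus equals
    ``g_L * sqrt(K) * f_k * m0`` per second.  The Gaussian profile is
    truncated beyond 4 sigma from the center, where the sampling probability
    is below ``rho * 3.4e-4``.  ``centers_out``, if given, collects the
    per-pool (row, col) receptive-field centers (1-based).
    """
    rng = np.random.default_rng(rng)
    p = params
    rows_px, cols_px = stimulus_set.shape
    n = stimulus_set.n
    halfw = int(np.ceil(4 * p.sigma_rf))
    mats = []
    for x in range(p.q):
        vec = stimulus_set.images[x].vector
        centers_r = rng.integers(1, rows_px + 1, p.N)
        centers_c = rng.integers(1, cols_px + 1, p.N)
        if centers_out is not None:
            centers_out.append((centers_r.copy(), centers_c.copy()))
        rows_idx, cols_idx = [], []
        for i in range(p.N):
            r0, c0 = centers_r[i], centers_c[i]
            rr = np.arange(max(1, r0 - halfw), min(rows_px, r0 + halfw) + 1)
            cc = np.arange(max(1, c0 - halfw), min(cols_px, c0 + halfw) + 1)
            RR, CC = np.meshgrid(rr, cc, indexing="ij")
            prob = p.rho * np.exp(
                -((RR - r0) ** 2 + (CC - c0) ** 2) / (2 * p.sigma_rf**2)
            )
            hit = rng.random(prob.shape) < prob
            j = (RR[hit] - 1) * cols_px + (CC[hit] - 1)
            rows_idx.append(np.full(j.size, i))
            cols_idx.append(j)
        mask = sp.csr_array(
            (
                np.ones(sum(len(a) for a in rows_idx)),
                (np.concatenate(rows_idx), np.concatenate(cols_idx)),
            ),
            shape=(p.N, n),
        )
        weights: list[float] = []
        mats.append(_normalize_rows(mask, vec, p, weights))
    return mats


def build_feedforward_bernoulli(
    params: ModelParameters,
    connection_prob: float,
    stimulus_set: StimulusSet,
    rng,
) -> list[sp.csr_array]:
    """Feedforward matrices with i.i.d. Bernoulli(connection_prob) structure.

    The common weight is rescaled so the expected total drive stays at
    ``g_L * sqrt(K) * f_k * m0`` regardless of ``connection_prob``: sparser
    sampling means stronger individual connections and hence more
    heterogeneous total drive across neurons.
    """
    if not (0 < connection_prob <= 1):
        raise ValueError("connection_prob must lie in (0, 1]")
    rng = np.random.default_rng(rng)
    p = params
    n = stimulus_set.n
    mats = []
    for x in range(p.q):
        vec = stimulus_set.images[x].vector
        if connection_prob == 1.0:
            mask = sp.csr_array(np.ones((p.N, n)))
        else:
            mask = sp.csr_array(rng.random((p.N, n)) < connection_prob)
        weights: list[float] = []
        mats.append(_normalize_rows(mask.astype(float), vec, p, weights))
    return mats


def perturb_feedforward_gaussian(drive: np.ndarray, std: float, rng) -> tuple[np.ndarray, int]:
    """Add i.i.d. N(0, std^2) offsets to per-neuron feedforward drives.

    Negative totals are clipped at zero; returns the perturbed drive and the
    number of clipped entries.  ``std`` is in the same units as the drive.
    """
    if std < 0:
        raise ValueError("std must be >= 0")
    rng = np.random.default_rng(rng)
    out = np.asarray(drive, dtype=float) + (
        rng.standard_normal(len(drive)) * std if std > 0 else 0.0
    )
    clipped = int(np.sum(out < 0))
    return np.clip(out, 0.0, None), clipped


@dataclass
class NetworkRealization:
    """Sampled connectivity for one 'individual': recurrent, long-range, feedforward."""

    params: ModelParameters
    recurrent: list[sp.csr_array]
    long_range: dict[tuple[int, int], sp.csr_array]
    feedforward: list[sp.csr_array]
    seed: object = None

    def coupling_matrix(self) -> sp.csc_array:
        """Global (qN x qN) impulse matrix, columns presynaptic.

        Diagonal blocks are the recurrent matrices; block (target, source)
        holds the long-range matrix for that ordered pair.  CSC layout so a
        presynaptic spike delivers one column.
        """
        p = self.params
        blocks = [[None] * p.q for _ in range(p.q)]
        for x in range(p.q):
            blocks[x][x] = self.recurrent[x]
        for (src, tgt), C in self.long_range.items():
            blocks[tgt][src] = C
        return sp.block_array(blocks, format="csc")

    def feedforward_drive(self, stimulus_set: StimulusSet) -> np.ndarray:
        """Per-neuron constant drive (1/s), concatenated over pools."""
        if stimulus_set.q != self.params.q:
            raise ValueError("stimulus count must equal the number of pools")
        return np.concatenate(
            [F @ im.vector for F, im in zip(self.feedforward, stimulus_set.images)]
        )

    def presynaptic_is_excitatory(self) -> np.ndarray:
        """Boolean mask over global indices: True for excitatory neurons."""
        p = self.params
        m = np.zeros(p.q * p.N, dtype=bool)
        for x in range(p.q):
            m[x * p.N : x * p.N + p.N_E] = True
        return m


def build_network(
    params: ModelParameters,
    stimulus_set: StimulusSet,
    seed,
    feedforward: str = "localized",
    connection_prob: float | None = None,
) -> NetworkRealization:
    """Sample a full network realization from one seed.

    ``feedforward`` selects the localized receptive-field builder (default)
    or the i.i.d. Bernoulli variant (``"bernoulli"``, requires
    ``connection_prob``).  Sub-seeds for the recurrent, long-range and
    feedforward samplers are spawned independently so the three structures
    are uncorrelated but individually reproducible.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_rec, s_lr, s_ff = ss.spawn(3)
    rec = build_recurrent(params, np.random.default_rng(s_rec))
    lr = build_long_range(params, np.random.default_rng(s_lr))
    if feedforward == "localized":
        ff = build_feedforward_localized(params, stimulus_set, np.random.default_rng(s_ff))
    elif feedforward == "bernoulli":
        if connection_prob is None:
            raise ValueError("bernoulli feedforward requires connection_prob")
        ff = build_feedforward_bernoulli(
            params, connection_prob, stimulus_set, np.random.default_rng(s_ff)
        )
    else:
        raise ValueError(f"unknown feedforward kind: {feedforward!r}")
    return NetworkRealization(params, rec, lr, ff, seed=seed)
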