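"""Fixed-step integration of the coupled voltage/threshold dynamics.

Between synaptic events each voltage relaxes exponentially toward its
feedforward fixed point (the leak equation has a closed-form solution), so a
fixed-step exponential-Euler update is exact for the subthreshold flow; the
only discretization error is in spike timing, which is resolved to one step
(default dt = 0.1 ms, well below the membrane time constant of 20 ms).

Spikes detected in a step are processed in a single synchronous round: every
crossing neuron resets to ``V_Re``, its threshold jumps by ``phi``, and its
delta-pulse impulses are applied to all postsynaptic voltages at the end of
the step.  This makes the update order-free and bit-reproducible.

Per-neuron excitatory and inhibitory input totals are accumulated online in
``current_bin``-sized bins (default 60 ms): the excitatory total is the
integrated feedforward drive plus all positive impulse weights received; the
inhibitory total is the (negative) sum of inhibitory impulse weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkRealization
from .stimuli import StimulusSet

__all__ = [
    "SimulatorSettings",
    "SimulationResult",
    "run_simulation",
    "threshold_decay",
    "bin_input_currents",
]


@dataclass(frozen=True)
class SimulatorSettings:
    """Integration and recording settings for one run."""

    duration: float = 40.0
    dt: float = 1e-4
    current_bin: float = 0.06
    stat_bin: float = 0.02
    record_voltage: bool = False
    record_currents: bool = True
    transient_policy: str = "exclude_first_dominance"
    seed: object = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.current_bin < self.dt:
            raise ValueError("current_bin must be >= dt")
        if self.duration < self.current_bin:
            raise ValueError("duration must be >= current_bin")
        if self.transient_policy not in (
            "exclude_first_dominance", "exclude_first_window", "none"
        ):
            raise ValueError("unknown transient_policy")


@dataclass
class SimulationResult:
    """Spikes, binned input currents, and population traces from one run."""

    params: object
    settings: SimulatorSettings
    spike_times: np.ndarray          # seconds, nondecreasing
    spike_neurons: np.ndarray        # global neuron indices
    pop_voltage_traces: np.ndarray   # (n_current_bins, q, 2) population means
    pop_threshold_traces: np.ndarray # (n_current_bins, q, 2)
    exc_input: np.ndarray | None     # (n_current_bins, qN) E totals, >= 0
    inh_input: np.ndarray | None     # (n_current_bins, qN) I totals, <= 0
    neuron_voltage_bins: np.ndarray | None    # (n_stat_bins, qN) mean v per stat bin
    neuron_threshold_bins: np.ndarray | None  # (n_stat_bins, qN)
    drive: np.ndarray = None         # per-neuron feedforward drive (1/s)
    seed: object = None

    @property
    def duration(self) -> float:
        return self.settings.duration

    @property
    def q(self) -> int:
        return self.params.q

    def pool_population(self, neuron: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map global neuron indices to (pool, population) with 0=E, 1=I."""
        N = self.params.N
        pool = neuron // N
        pop = (neuron % N >= self.params.N_E).astype(int)
        return pool, pop

    def excitatory_counts(self, bin_width: float) -> np.ndarray:
        """(n_bins, q) spike counts of each pool's excitatory population."""
        p = self.params
        n_bins = int(round(self.duration / bin_width))
        pool, pop = self.pool_population(self.spike_neurons)
        keep = pop == 0
        b = np.minimum((self.spike_times[keep] / bin_width).astype(int), n_bins - 1)
        out = np.zeros((n_bins, p.q))
        np.add.at(out, (b, pool[keep]), 1.0)
        return out

    def spike_counts_per_neuron(self, t0: float, t1: float) -> np.ndarray:
        """Per-neuron spike counts in the half-open interval (t0, t1]."""
        i0, i1 = np.searchsorted(self.spike_times, [t0, t1], side="right")
        counts = np.zeros(self.params.q * self.params.N)
        np.add.at(counts, self.spike_neurons[i0:i1], 1.0)
        return counts


def threshold_decay(theta0, theta_base, lambda_phys: float, t) -> np.ndarray:
    """Closed-form threshold relaxation toward the non-adapted value."""
    if lambda_phys < 0:
        raise ValueError("lambda_phys must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return theta_base + (np.asarray(theta0) - theta_base) * np.exp(-lambda_phys * t)


def run_simulation(
    realization: NetworkRealization,
    stimulus_set: StimulusSet,
    settings: SimulatorSettings,
    drive_scale: np.ndarray | None = None,
    drive_override: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the network and record spikes, currents, and traces.

    ``drive_scale`` (length q) multiplies each pool's feedforward drive —
    the handle used by stimulus-strength sweeps, equivalent to a pool-specific
    ``m0``.  ``drive_override`` replaces the per-neuron drive vector entirely
    (used by the homogeneity experiments).  Fully deterministic given the
    settings seed: randomness enters only through initial voltages.
    """
    p = realization.params
    s = settings
    if stimulus_set.q != p.q:
        raise ValueError("stimulus count must equal the number of pools")

    if drive_override is not None:
        drive = np.asarray(drive_override, dtype=float).copy()
        if drive.shape != (p.q * p.N,):
            raise ValueError("drive_override has wrong shape")
    else:
        drive = realization.feedforward_drive(stimulus_set)
    if drive_scale is not None:
        drive_scale = np.asarray(drive_scale, dtype=float)
        if drive_scale.shape != (p.q,):
            raise ValueError("drive_scale must have length q")
        drive = drive * np.repeat(drive_scale, p.N)

    W = realization.coupling_matrix()
    indptr, indices, data = W.indptr, W.indices, W.data
    is_exc = realization.presynaptic_is_excitatory()

    n_total = p.q * p.N
    theta_base = np.tile(p.theta_base(), p.q)
    dt = s.dt
    decay = np.exp(-p.g_L * dt)
    v_step = drive / p.g_L * (1.0 - decay) + p.V_Re * (1.0 - decay)
    th_decay = np.exp(-p.lambda_phys * dt)

    rng = np.random.default_rng(s.seed)
    v = rng.uniform(p.V_Re, theta_base)
    th = theta_base.copy()

    n_steps = int(round(s.duration / dt))
    cb_steps = int(round(s.current_bin / dt))
    n_cbins = int(np.ceil(n_steps / cb_steps))
    sb_steps = int(round(s.stat_bin / dt))
    n_sbins = int(np.ceil(n_steps / sb_steps))

    # population-mean traces accumulated per current bin
    pop_slices = [
        slice(x * p.N + (0 if k == 0 else p.N_E), x * p.N + (p.N_E if k == 0 else p.N))
        for x in range(p.q) for k in range(2)
    ]
    pop_bounds = np.array([sl.start for sl in pop_slices] + [n_total])
    pop_sizes = np.array([sl.stop - sl.start for sl in pop_slices], dtype=float)
    pop_v = np.zeros((n_cbins, p.q * 2))
    pop_th = np.zeros((n_cbins, p.q * 2))

    if s.record_currents:
        exc = np.zeros((n_cbins, n_total))
        inh = np.zeros((n_cbins, n_total))
        # feedforward integral per bin (last bin may be shorter)
        for b in range(n_cbins):
            steps_in = min(cb_steps, n_steps - b * cb_steps)
            exc[b] = drive * (steps_in * dt)
    else:
        exc = inh = None

    if s.record_voltage:
        nv = np.zeros((n_sbins, n_total))
        nth = np.zeros((n_sbins, n_total))
        sb_counts = np.zeros(n_sbins)
    else:
        nv = nth = None

    spike_t: list[np.ndarray] = []
    spike_i: list[np.ndarray] = []

    for step in range(n_steps):
        v *= decay
        v += v_step
        th -= theta_base
        th *= th_decay
        th += theta_base

        cb = step // cb_steps
        pop_v[cb] += np.add.reduceat(v, pop_bounds[:-1])
        pop_th[cb] += np.add.reduceat(th, pop_bounds[:-1])
        if nv is not None:
            sb = step // sb_steps
            nv[sb] += v
            nth[sb] += th
            sb_counts[sb] += 1

        fired = v >= th
        if fired.any():
            idx = np.nonzero(fired)[0]
            v[idx] = p.V_Re
            th[idx] += p.phi
            t_spike = (step + 1) * dt
            spike_t.append(np.full(idx.size, t_spike))
            spike_i.append(idx)
            for j in idx:
                sl = slice(indptr[j], indptr[j + 1])
                tgt = indices[sl]
                w = data[sl]
                v[tgt] += w
                # within one presynaptic column the target indices are unique,
                # so fancy-index accumulation is exact
                if exc is not None:
                    if is_exc[j]:
                        exc[cb, tgt] += w
                    else:
                        inh[cb, tgt] += w
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(
                f"non-finite voltage at t={step * dt:.4f} s"
            )

    steps_per_cbin = np.minimum(cb_steps, n_steps - np.arange(n_cbins) * cb_steps)
    pop_v = (pop_v / pop_sizes[None, :] / steps_per_cbin[:, None]).reshape(n_cbins, p.q, 2)
    pop_th = (pop_th / pop_sizes[None, :] / steps_per_cbin[:, None]).reshape(n_cbins, p.q, 2)
    if nv is not None:
        nv /= sb_counts[:, None]
        nth /= sb_counts[:, None]

    if spike_t:
        times = np.concatenate(spike_t)
        neurons = np.concatenate(spike_i)
    else:
        times = np.empty(0)
        neurons = np.empty(0, dtype=int)

    return SimulationResult(
        params=p,
        settings=s,
        spike_times=times,
        spike_neurons=neurons,
        pop_voltage_traces=pop_v,
        pop_threshold_traces=pop_th,
        exc_input=exc,
        inh_input=inh,
        neuron_voltage_bins=nv,
        neuron_threshold_bins=nth,
        drive=drive,
        seed=s.seed,
    )


def bin_input_currents(
    spike_times: np.ndarray,
    spike_neurons: np.ndarray,
    coupling,
    drive: np.ndarray,
    duration: float,
    bin_width: float,
    dt: float,
    is_excitatory_presyn: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Recompute binned E/I input totals from a spike log.

    Independent of the simulator's online accumulation (which it must match
    exactly): each delivered impulse is assigned to the bin containing its
    emission step, and the constant feedforward drive is integrated over each
    bin.  Spike times are assumed to lie on the step grid (t = (step+1)*dt).
    """
    n_steps = int(round(duration / dt))
    bin_steps = int(round(bin_width / dt))
    n_bins = int(np.ceil(n_steps / bin_steps))
    n_total = len(drive)
    W = coupling.tocsc()
    exc = np.zeros((n_bins, n_total))
    inh = np.zeros((n_bins, n_total))
    for b in range(n_bins):
        steps_in = min(bin_steps, n_steps - b * bin_steps)
        exc[b] = drive * (steps_in * dt)
    steps = np.rint(spike_times / dt).astype(int) - 1
    bins = steps // bin_steps
    for t_bin, j in zip(bins, spike_neurons):
        sl = slice(W.indptr[j], W.indptr[j + 1])
        tgt = W.indices[sl]
        w = W.data[sl]
        if is_excitatory_presyn[j]:
            exc[t_bin, tgt] += w
        else:
            inh[t_bin, tgt] += w
    return exc, inh
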