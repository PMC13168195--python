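"""Coarse-grained theory: balance conditions, population rates, voltage map.

In the balanced regime the O(sqrt(K)) mean excitatory and inhibitory inputs
into a neuron must cancel to O(1) as K grows, which pins the population
rates to the solution of a 2x2 linear system:

    m_E = (|R_II| f_E - |R_EI| f_I) / (R_IE |R_EI| - R_EE |R_II|) * m0
    m_I = (R_IE  f_E - R_EE  f_I) / (R_IE |R_EI| - R_EE |R_II|) * m0

(rates in units of g_L; multiply by g_L for spikes/s).  Nonnegative finite
rates require the strict ordering

    f_E / f_I  >  |R_EI| / |R_II|  >  R_EE / R_IE.

Both the ratios and the rates are exactly invariant under joint scaling of
the inhibitory strengths (S_I) or the excitatory strengths (S_E), since the
scale factors cancel inside each ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ModelParameters, NetworkRealization
from .stimuli import StimulusSet

__all__ = [
    "BalanceReport",
    "balance_inequality",
    "theoretical_rates",
    "gain_curve",
    "expected_voltage_map",
]


@dataclass(frozen=True)
class BalanceReport:
    """Balance-condition ratios, their ordering, and the implied rates."""

    ratios: tuple[float, float, float]   # (f_E/f_I, |R_EI|/|R_II|, R_EE/R_IE)
    satisfied: bool
    rates: tuple[float, float]           # (m_E, m_I) in units of g_L
    drive_offsets: tuple[float, float]   # residual d_k at the theoretical rates


def theoretical_rates(params: ModelParameters) -> tuple[float, float]:
    """Population-averaged rates of a dominant (or isolated) pool, in g_L units."""
    p = params
    # S_E / S_I scale both numerator and denominator identically and cancel.
    denom = p.R_IE * abs(p.R_EI) - p.R_EE * abs(p.R_II)
    if denom == 0:
        raise ZeroDivisionError("singular balance system: R_IE|R_EI| == R_EE|R_II|")
    m_E = (abs(p.R_II) * p.f_E - abs(p.R_EI) * p.f_I) / denom * p.m0
    m_I = (p.R_IE * p.f_E - p.R_EE * p.f_I) / denom * p.m0
    return m_E, m_I


def balance_inequality(params: ModelParameters) -> BalanceReport:
    """Evaluate the balance ordering f_E/f_I > |R_EI|/|R_II| > R_EE/R_IE."""
    p = params
    if p.f_I == 0 or p.R_II == 0 or p.R_IE == 0:
        raise ZeroDivisionError("f_I, R_II and R_IE must be nonzero")
    ratios = (p.f_E / p.f_I, abs(p.R_EI) / abs(p.R_II), p.R_EE / p.R_IE)
    satisfied = ratios[0] > ratios[1] > ratios[2]
    try:
        m_E, m_I = theoretical_rates(p)
    except ZeroDivisionError:
        m_E = m_I = float("nan")
    # expected voltage offset from reset (threshold units): sqrt(K) times the
    # net mean input per population, which vanishes at the theoretical rates
    d_E = p.sqrtK * (p.f_E * p.m0 + p.R_EE * m_E + p.R_EI * m_I)
    d_I = p.sqrtK * (p.f_I * p.m0 + p.R_IE * m_E + p.R_II * m_I)
    return BalanceReport(ratios, bool(satisfied), (m_E, m_I), (d_E, d_I))


def gain_curve(params: ModelParameters, m0_values) -> np.ndarray:
    """Tabulate theoretical (m0, m_E, m_I) over a drive-strength sweep.

    Rates are linear in m0 and pass through the origin; the returned array
    has columns (m0, m_E, m_I) in g_L units.
    """
    m0_values = np.asarray(m0_values, dtype=float)
    if np.any(m0_values < 0):
        raise ValueError("m0 values must be >= 0")
    rows = []
    for m0 in m0_values:
        m_E, m_I = theoretical_rates(params.with_(m0=float(m0)))
        rows.append((m0, m_E, m_I))
    return np.array(rows)


def expected_voltage_map(
    realization: NetworkRealization,
    rates: np.ndarray,
    mean_thresholds: np.ndarray,
    stimulus_set: StimulusSet,
    drive: np.ndarray | None = None,
) -> np.ndarray:
    """Long-time expected voltage of every neuron given rates and thresholds.

    Implements, per pool,

        v_bar = V_Re + (1/g_L) (F p + R m + sum_y C_xy m_y - m (theta_bar - V_Re))

    with per-neuron rates ``m`` (spikes/s) and time-averaged thresholds,
    using the realized connectivity (not its expectation).  ``drive`` may
    supply the feedforward term directly when the simulated run used a
    scaled or overridden drive.
    """
    p = realization.params
    n_total = p.q * p.N
    rates = np.asarray(rates, dtype=float)
    mean_thresholds = np.asarray(mean_thresholds, dtype=float)
    if rates.shape != (n_total,) or mean_thresholds.shape != (n_total,):
        raise ValueError("rates and mean_thresholds must have shape (q*N,)")
    if drive is None:
        drive = realization.feedforward_drive(stimulus_set)
    recurrent_in = np.concatenate([
        realization.recurrent[x] @ rates[x * p.N : (x + 1) * p.N]
        for x in range(p.q)
    ])
    cross_in = np.zeros(n_total)
    for (src, tgt), C in realization.long_range.items():
        cross_in[tgt * p.N : (tgt + 1) * p.N] += C @ rates[src * p.N : (src + 1) * p.N]
    net = drive + recurrent_in + cross_in - rates * (mean_thresholds - p.V_Re)
    return p.V_Re + net / p.g_L
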