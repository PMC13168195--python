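# rivalnet

An image-driven spiking-network model of visual perceptual multistability —
binocular rivalry, binocular fusion, and interocular grouping — with a
compressive-sensing pipeline that reconstructs the currently perceived image
from short windows of neuronal activity.

## The model

`q` pools of pulse-coupled integrate-and-fire neurons compete to represent
`q` candidate percepts, each percept a gray-scale image **p**<sub>x</sub>
(100×100 pixels by default).  Each pool holds `N_E` excitatory and `N_I`
inhibitory neurons whose voltage and firing threshold obey

    dv/dt = -g_L (v - V_Re) + Σ_j W_ij Σ_h δ(t - τ_jh) + Σ_j F_ij p_j
    dθ/dt = -λ (θ - θ_k),        θ → θ + φ at each spike of the neuron

with reset to `V_Re` on threshold crossing.  Three kinds of connectivity are
sampled per realization ("individual"):

* **Recurrent** — Bernoulli-sparse within a pool, weight `R_kl / √K` with
  probability `K / N_l`; `R_EE, R_IE > 0`, `R_EI, R_II < 0` in the classical
  balanced-network regime, so large excitatory and inhibitory inputs cancel
  on average and spikes are fluctuation-driven.
* **Long-range** — from excitatory neurons of one pool onto inhibitory
  neurons of every other pool, same statistics as within-pool E→I coupling.
  A high-firing pool therefore silences its competitors' excitatory
  populations (winner-take-all), while the adapting threshold slowly
  fatigues the winner and lets a suppressed pool escape: irregular
  perceptual alternations.
* **Feedforward** — each neuron has a Gaussian spatial receptive field on
  the pixel grid (sampling probability `ρ exp(-d²/2σ²)`), and the common
  weight is normalized so the population-mean drive is `√K f_k m0` threshold
  units per membrane time constant.

Balance pins the population rates of the dominant pool to

    m_E = (|R_II| f_E - |R_EI| f_I) / (R_IE |R_EI| - R_EE |R_II|) · m0,

(`m_I` analogous), valid under the ordering
`f_E/f_I > |R_EI|/|R_II| > R_EE/R_IE` — at the defaults, `m_E = m_I = 0.4`
in units of `g_L`, i.e. 20 spikes/s.

**Percept recovery.**  Over a short window (600 ms, about a reaction time)
the per-neuron rates m, mean voltages v̄ and mean thresholds θ̄ satisfy an
approximately linear map, which is inverted for the unknown image:

    F_x p_x = g_L (v̄_x - V_Re) - R_x m_x - Σ_y C_xy m_y + m_x (θ̄_x - V_Re).

The system is underdetermined (1000 excitatory equations, 10000 pixels), so
the image is recovered by orthogonal matching pursuit in an orthonormal 2-D
DCT basis, where gratings and natural-like scenes are sparse.  Per-pool
reconstructions are combined with weights `w_x = m_xE / Σ_y m_yE` — the
relative excitatory population rates, i.e. the evidence for each percept.

The same machinery drives the disorder studies: scaling one direction of
long-range competition (`S_C`) models amblyopia; scaling recurrent
inhibition down (`S_I`) or recurrent excitation up (`S_E`) raises the
excitation/inhibition ratio as hypothesized in autism, and lengthens
dominance durations.

## Worked example

```python
import numpy as np
import rivalnet as rn
from rivalnet.experiments import simulate_realization
from rivalnet.analysis import (dominant_pool_series, extract_dominance_durations,
                               dominant_ei_summary)

params = rn.ModelParameters()          # two-pool rivalry defaults
stim = rn.rivalry_gratings()           # orthogonal gratings, equal mean
realization, result = simulate_realization(
    params, stim, duration=12.0, seed=42, record_voltage=True,
)

labels = dominant_pool_series(result)
record = extract_dominance_durations(labels, exclude_transient=True,
                                     exclude_censored_tail=True)
durations = record.all_durations()
print(f"dominance durations (s): {np.round(durations, 2)}")
print(f"mean duration: {durations.mean():.2f} s")

dom, sup = dominant_ei_summary(result)
print(f"E/I input ratio, dominant excitatory pool:   {dom:.2f}")
print(f"E/I input ratio, suppressed excitatory pool: {sup:.2f}")

recons = rn.reconstruct_windows(realization, result, stim, window=0.6,
                                max_atoms=100, window_indices={3, 4, 5})
for rc in recons:
    print(f"window {rc.window.index}: weights {np.round(rc.weights, 3)}, "
          f"percept error {rc.percept_error:.3f}")
```

prints

```
dominance durations (s): [1.9 1.7 2.3 1.8 2.5]
mean duration: 2.04 s
E/I input ratio, dominant excitatory pool:   -1.06
E/I input ratio, suppressed excitatory pool: -0.53
window 3: weights [0.04 0.96], percept error 0.071
window 4: weights [0.418 0.582], percept error 0.282
window 5: weights [0.989 0.011], percept error 0.078
```

The percept alternates irregularly with ~2 s dominance periods.  The
dominant pool's excitatory neurons sit at an E/I input ratio near −1
(balance); the suppressed pool's sit near −0.5 (excess inhibition).
Windows lying inside one dominance period put almost all weight on one
pool and reconstruct its grating accurately (relative error ≈ 0.07);
window 4 straddles a perceptual switch, so the recovered percept is a
weighted mixture of both gratings — a mixed percept — with higher error.

A command-line interface wraps the same library:

```
rivalnet simulate --duration 40 --seed 1 --out run/
rivalnet sweep levelt4 --values 0.15,0.2,0.3,0.45 --realizations 2 --out sweep.csv
rivalnet reconstruct --stimulus rivalry --duration 12 --out recon/
rivalnet fixtures --out fixtures/
rivalnet gain-curve
```

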