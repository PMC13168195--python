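# Methods

## Model and units

Voltages are nondimensionalized so the reset potential is `V_Re = 0` and
the non-adapted excitatory threshold is `θ_E = 1` (`θ_I = 0.8`).  Time is
in seconds with leak rate `g_L = 50 s⁻¹` (membrane time constant 20 ms).
Rate-like nondimensional parameters are converted to physical units by one
rule: multiply by `g_L`.  The adaptation decay `λ = 0.00625` therefore
corresponds to `λ_phys = 0.3125 s⁻¹` (timescale ≈ 3.2 s, commensurate with
1–2.5 s dominance durations; the alternative readings — per millisecond or
per second — give 0.16 s or 160 s adaptation timescales, both incompatible
with the phenomenon).  The threshold increment `φ = 0.005` is a direct
nondimensional jump.  Adaptation applies to both populations; the rivalry
values `λ = 0.00625, φ = 0.005` are used for all multistability runs.

Synaptic weights follow the classical balanced-network scaling: an
individual weight is `R_kl/√K` and the population-expected feedforward
drive is `√K f_k m0` threshold units per membrane time constant.  We
verified the alternative literal scaling (`R_kl/K` with drive `K f_k m0`)
produces runaway excitatory rates (~280 spikes/s) with no rivalry, whereas
the `√K` convention reproduces the theoretical rate line, E/I ratios near
−1, and irregular alternations; only the `√K` reading is consistent with a
balance limit in which net input vanishes as `K → ∞`.

Population rates from the balance equations are reported in units of `g_L`
(0.4 ≡ 20 spikes/s at the defaults).

## Default parameters

| symbol | value | meaning |
|---|---|---|
| `R_EE, R_IE` | 1 | recurrent excitatory strengths |
| `R_EI, R_II` | −2, −1.8 | recurrent inhibitory strengths |
| `N_E, N_I` | 1000, 1000 | neurons per population per pool |
| `K` | 40 | mean in-degree per source population |
| `f_E, f_I` | 1, 0.8 | population drive scalings |
| `m0` | 0.4 | overall drive strength |
| `θ_E, θ_I` | 1, 0.8 | non-adapted thresholds |
| `λ, φ` | 0.00625, 0.005 | threshold decay / increment |
| `ρ, σ` | 0.96, 1.75 px | receptive-field peak probability / width |
| `q` | 2 (4 for grouping) | competing pools |

`S_C` (per ordered pool pair), `S_I`, `S_E` (recurrent inhibitory /
excitatory scalings) default to 1 and implement the amblyopia and autism
manipulations.  The balance ratios `f_E/f_I > |R_EI|/|R_II| > R_EE/R_IE`
(1.25 > 1.11 > 1.0 at the defaults) are exactly invariant under `S_I` and
`S_E`, so those manipulations change dynamics without breaking the balance
conditions.

## Numerical integration

Between synaptic events the leak equation is solved exactly, so the
simulator uses a fixed-step exponential-Euler update (`dt = 0.1 ms`) with
end-of-step threshold tests.  All neurons crossing threshold in a step are
processed in one synchronous round: reset, threshold jump `φ`, and
delta-pulse delivery to postsynaptic voltages at the end of the step.
This makes the update independent of any within-step ordering and
bit-reproducible; spike timing carries an `O(dt)` discretization error,
negligible against the 20 ms membrane and multi-second adaptation
timescales (the closed-form LIF period is reproduced to <0.1% at reduced
`dt` in the tests).  Initial voltages are i.i.d. uniform on `[V_Re, θ_k)`;
thresholds start at `θ_k`.  Every run is fully determined by its seed:
randomness enters only through connectivity sampling and initial voltages.

Per-neuron excitatory input totals (integrated feedforward drive plus
positive impulse weights) and inhibitory totals (negative impulse weights)
are accumulated in 60 ms bins during integration; an offline re-binning
from the spike log reproduces them exactly (conservation is tested).

## Stimulus fixtures

* **Rivalry gratings** — horizontal vs. vertical square-wave gratings,
  period 20 px, gray levels 0.25/0.75 (50% Michelson contrast about
  mid-gray), equal-mean normalized.  Rivalry experiments use moderate-
  contrast gratings; in this framework a pixel value of 0 means literally
  zero feedforward drive to neurons sampling it, an extreme
  drive-heterogeneity condition that the homogeneity experiments probe
  separately.  Drive heterogeneity is the main determinant of the
  dominance-duration scale (see limitations).
* **Fusion** — identical horizontal gratings in both pools.
* **Interocular grouping** — two synthetic `1/f²`-spectrum scenes
  (min-max scaled to [0, 1]) plus their complementary rearrangement
  (checkerboard block swap, 50 px quadrant blocks by default; applying the
  rearrangement twice restores the originals).  The `1/f²` spectrum mimics
  the second-order statistics of natural scenes, which is what makes them
  sparse in the DCT basis; the synthetic scenes stand in for natural
  photographs so that no external data is needed.

Equal-mean normalization rescales every image multiplicatively to the
first image's mean, making the expected feedforward drive per pool
comparable.

## Dominance detection and observables

Dominance is labeled per 100 ms bin as the pool with the highest
excitatory population rate, then majority-smoothed over 3 bins to remove
single-bin chatter around switches.  (The labeling granularity is a
detection choice, independent of the 600 ms reconstruction window and the
60 ms current bins.)  Durations are run lengths of constant labels; the
first dominance period of each run is excluded as the initial transient
(thresholds are still low and alternations atypically fast), and ensemble
duration statistics also drop the final, right-censored segment.  The
operational bin/smoothing choices are exposed as arguments.  Predominance
(time fractions) keeps the censored tail, since truncated dominance time
is still dominance time; runs with fewer than two completed durations are
flagged censored and counted, never dropped.

E/I input ratios are computed per neuron per 60 ms bin as (excitatory
total)/(inhibitory total) — negative by convention, −1 at balance — then
averaged over a population, excluding neurons with zero inhibitory input
in that bin (exclusion counts are recorded).

## Percept recovery choices

The sparsifying basis is the orthonormal 2-D DCT (pluggable); gratings
and `1/f` scenes are strongly sparse there.  OMP stops at
`max_atoms = N_E/10` (100 at the defaults) or when the residual falls
below `10⁻³‖rhs‖`, whichever is first; degenerate atom picks are dropped.
Only the excitatory rows of the map are used (inhibitory neurons keep
firing when their pool is suppressed, so their statistics carry cross-pool
rather than stimulus information).  Negative reconstructed pixels are
clipped to zero before error computation (images are nonnegative; counts
recorded).  Window statistics use the window's own time-averaged
thresholds as `θ̄`, approximating the long-time averages the map assumes,
which is accurate once adaptation has saturated.  The relative error is
Euclidean, against the stimulus of the pool with the highest excitatory
population rate in that window.

## Experiment suites and problem sizes

Sweeps average over seeded realizations (each realization = one sampled
connectivity, analogous to one participant) and report means with
standard errors; all seeds derive deterministically from a master seed,
so any sweep is bit-reproducible from its spec.  Stimulus-strength
manipulations (Levelt's laws) rescale a pool's feedforward drive — a
pool-specific `m0` — leaving image structure fixed.  The feedforward
homogeneity experiments replace the localized receptive fields with
i.i.d. Bernoulli sampling (sweeping density at fixed expected drive) or
with a fully homogeneous drive perturbed by i.i.d. Gaussian offsets
(negative drives clipped at zero, counts recorded; the perturbation
standard deviation is stated in the same `g_L`-units as `√K f_k m0`).

The bundled test-suite and acceptance-script ensembles are scaled down to
run on one core in minutes: 3–5 realizations × 40 s for the two-pool
duration ensemble, 1–2 × 60–80 s for the four-pool configuration, one
12 s run for the E/I ratio structure, 1–3 realizations per swept value for
trend checks.  At these sizes, means and trend signs are stable, but
distribution-shape statistics (e.g. skewness of the pooled duration
histogram, whose standard error is ≈ 0.3 at ~90 durations) are not
resolvable and are reported rather than asserted.

## What the synthetic conditions do and do not show

The generator's gratings and `1/f²` scenes reproduce the two properties
the framework actually exploits — controlled mean drive and DCT sparsity —
but not higher-order structure of natural photographs (edges, objects,
phase alignment).  Passing tests therefore demonstrate the mechanism
(balanced competition, adaptation-driven alternation, CS recovery), not
performance on any particular natural-image corpus.  Dominance-duration
scale is sensitive to feedforward drive heterogeneity, which in turn
depends on stimulus contrast and receptive-field size: with the default
moderate-contrast gratings the two-pool ensemble mean is ≈ 2 s, with
full-contrast (0/1) gratings it drops to ≈ 1.2 s.  Quantities tied to the
balance structure (population rates, E/I ratios near −1 / −0.5, the
effects of `S_I`, `S_E`) are robust to this choice.

## Known limitations

* Dominance-duration variability within a realization is modest
  (CV ≈ 0.15–0.2), so scaled-down pooled histograms are narrower and less
  right-skewed than classic experimental gamma-like distributions; the
  across-individual (across-realization) spread that widens such
  histograms only appears at much larger ensemble sizes.
* Under simultaneous common-drive scaling, the alternation rate falls
  clearly as the common strength rises toward `m0 ≈ 0.3` (the low-strength
  branch of the fourth law), but the rising branch above the minimum is
  flat within noise under the default fixture, so the reversal position is
  not resolved at 0.2.
* Strengthening one direction of long-range competition lengthens the
  favored pool's dominance strongly, but the disfavored pool's periods
  become rarer rather than shorter; their mean length is roughly flat in
  `S_C` here.
* Scaling recurrent excitation (`S_E`) up lengthens durations and raises
  adapted thresholds, but leaves the dominant-pool E/I ratio essentially
  flat over `S_E ∈ [1, 1.4]` (the corresponding inhibitory manipulation
  `S_I` moves it clearly, −1.04 → −1.30 for `S_I: 1 → 0.6`).
* No orientation-selective receptive fields, opponency/dichoptic
  differencing, top-down feedback, synaptic delays, or plasticity; images
  are treated as flat 2-D patches (no depth cues); percept selection is
  agnostic about eye-based vs. stimulus-based rivalry.
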