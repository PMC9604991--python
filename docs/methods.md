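# Methods

## Model

`oanet` simulates whole-brain resting-state dynamics with one neural
ensemble per cortical region. Each ensemble is an infinite population of
Kuramoto phase oscillators whose natural frequencies follow a Lorentzian
(Cauchy) law with center Ω and half-width Δ. Under the Ott–Antonsen
ansatz the population collapses exactly onto its complex Kuramoto order
parameter z_n = r_n e^{iψ_n}, giving one delayed ODE pair per region:

    ṙ_n  = −Δ r_n + (L_n/2)(1 − r_n²) r_n
           + (G/2E)(1 − r_n²) Σ_{p≠n} A_np r_p(t−τ_np) cos(ψ_p(t−τ_np) − ψ_n)
    ψ̇_n = Ω + (G/2E)(r_n + 1/r_n) Σ_{p≠n} A_np r_p(t−τ_np) sin(ψ_p(t−τ_np) − ψ_n)

r_n ∈ [0, 1] is the within-region synchrony (0 incoherent, 1 fully
synchronized), ψ_n the mean phase. A is the fiber-density matrix, τ_np =
D_np / v the interaction delay from the Euclidean distance D (mm) and a
constant spike-propagation velocity v (m/s). An isolated region (G = 0)
is the mean-field of a plain Kuramoto model: it synchronizes iff its
local coupling exceeds the critical value L^c = 2Δ, settling at
r_eq = √(1 − 2Δ/L). The (r + 1/r) factor makes desynchronized regions
highly phase-susceptible to their neighbors — the mechanism by which
delayed global interactions create fluctuations of local synchrony.

The finite-N counterpart (`oanet.micro`) integrates the explicit
network-of-networks of phase oscillators whose N → ∞ limit is the model
above: within-region coupling L_n/N instantaneous and all-to-all,
between-region coupling (G/E) A_np delayed, acting through the source
region's mean field. It serves as an independent oracle: on small
instances the reduced and microscopic trajectories must agree.

## Parameters and defaults

| parameter | meaning | default | notes |
|---|---|---|---|
| Ω | center natural frequency | 10.5 Hz | alpha band; converted to rad/s internally |
| Δ | frequency half-width | 1 s⁻¹ | sets L^c = 2 |
| L_n | local coupling | free | per region, or one shared value |
| G | global coupling | free | scaled by 1/(2E) in the equations |
| v | spike-propagation velocity | free (m/s) | `inf` disables delays |
| dt | Euler step | 1 ms | delays rounded to the step grid |
| t_total / t_transient | duration / discard | 66 s / 19 s | 321 s for time-resolved FC |
| r_floor | lower clamp on r | 1e−3 | see below |

Rates (Δ, L, G) are taken in s⁻¹ as printed and Ω in Hz: this is the only
unit reading that places the spectral peak at 10.5 Hz while keeping the
critical coupling at L = 2.

## Numerical scheme

Time-delayed first-order Euler with dt = 1 ms. Delayed states are read
from a dense complex history z[t, n]; delays are rounded to the nearest
integer step (no interpolation — consistent with first-order accuracy).
Initialization: phases at t = −τ_max are uniform on [−π, π), r starts at
the floored isolated equilibrium, and every region is advanced
*decoupled* (G = 0) from −τ_max to 0 to fill the buffer. After each step
r is clamped to [r_floor, 1] and ψ wrapped to [−π, π); phase differences
enter only through complex arithmetic, so wrapping has no dynamical
effect.

The phase equation contains 1/r_n and is singular at r = 0. We clamp at
r_floor = 1e−3 (configurable): small enough to preserve the strong
phase-susceptibility of desynchronized regions, large enough to bound
ψ̇. The clamp also fixes the behavior of threshold searches: a region
whose r has decayed to the floor is classed as non-synchronizing.

Bisection for the critical coupling uses a 1000 s horizon. Near L^c the
linear decay/growth rate |L/2 − Δ| vanishes (critical slowing), so short
horizons systematically underestimate the threshold: the closed-form
solution of ṙ = a r − (L/2) r³ shows the decay discriminator at a 50 s
horizon crosses near L ≈ 1.77, whereas at 1000 s the bisection lands at
1.99, within 0.5% of the exact value 2.

## Microscopic oracle choices

Lorentzian draws are truncated at ±300 half-widths (0.2% tail mass) and
resampled. Truncation redistributes drifting tail oscillators into the
locked core and therefore biases the ensemble toward synchrony: at ±20
half-widths the steady synchrony of a near-critical ensemble is inflated
by ~0.04–0.06, which would dominate the reduced-vs-micro comparison; at
±300 the bias is below 0.01 while the largest per-step Euler phase
increment stays near 0.3 rad. Initial oscillator phases are drawn from a
wrapped-Cauchy distribution — the stationary density of the mean-field
manifold — with concentration calibrated by bisection so the empirical
order parameter matches the reduced model's initial (r₀, ψ₀). Matched
comparisons start at r₀ = 0.3: starting at the floor would put the micro
system below its finite-N noise floor (~N^{−1/2}), making the comparison
meaningless.

## Functional-connectivity pipeline

Simulated activity is the imaginary part of the order parameter,
r sin ψ, at the native 1000 Hz. The envelope pipeline is: zero-phase
4th-order Butterworth band-pass 8–13 Hz → Hilbert-transform magnitude →
zero-phase 4th-order Butterworth low-pass 0.5 Hz → decimation to 5 Hz →
1 s trimmed from each end (filter edges). Static FC is the Pearson
correlation of region envelopes; with the 66 s fitness runs this leaves
45 s of usable envelope, and 300 s for the 321 s time-resolved runs.
Time-resolved FC uses 15 s windows with 12 s overlap (3 s step; 96
windows over 300 s); recurrence is the Pearson correlation between the
upper-triangle FC vectors of every window pair (4560 values), and
recurrence distributions are compared with the two-sample
Kolmogorov–Smirnov statistic computed on the raw samples (ECDFs), not on
binned histograms, which removes the bin-width choice. Simulated signals
are never orthogonalized — there is no source leakage to correct.
Filters have no prescribed design in the source data conventions;
zero-phase Butterworth is the standard choice for MEG envelope FC.

## Constrained fitness

One evaluation runs a batch of simulations differing only in their
initial phases (seeds fixed per optimization, reused every iteration),
takes the element-wise median sFC, and correlates its upper triangle
with the target FC. Four plausibility gates apply to batch medians, all
strict: 0.25 < ⟨R⟩_t < 0.8, SD(R)_t > 0.05, 0.25 < ⟨⟨r_n⟩⟩ < 0.8,
⟨SD(r_n)⟩ > 0.05. Infeasible sets score −2 − (number of violations):
strictly below any correlation, and graded so optimizers are pulled back
toward feasibility. The penalty form is a package choice; only "heavily
penalized" is prescribed by the constraint scheme it implements.

## Optimizers

PSO uses the standard constriction-style constants (inertia 0.7298,
cognitive = social = 1.49618), velocity clamped at half the box range,
positions clipped. The self-adaptive DE is jDE: DE/rand/1/bin with
per-individual F ∈ [0.1, 1] and CR ∈ [0, 1] regenerated with probability
0.1 and inherited on success. This is a deliberate simplification of the
multi-variant adaptive DE used in large pagmo runs; both optimizers are
expected to reach equivalent optima on this problem class, and the test
suite checks exactly that. Scenario 1 searches (G, L_shared, v) in
[0, 10] × [−5, 6] × [1, 40]; scenario 2 searches E/2 homotopically tied
local couplings in [−5, 8] with (G, v) fixed.

## Synthetic connectome

`synthesize_connectome` stands in for tractography-derived anatomy:
E/2 barycenters uniform in one half of a 140 × 180 × 120 mm box,
mirrored across the midsagittal plane (exact homotopic pairs and
inter-hemispheric distance symmetry); weights exp(−D/40 mm) with
multiplicative lognormal jitter (σ = 0.5), symmetrized; weakest 20% of
edges removed; rescaled so the mean nonzero edge weight is 1 (the
default normalization; mean row-sum normalization is available behind
`mode="mean_degree"`). The 40 mm length scale is the widely reported
exponential falloff of cortico-cortical connection strength; σ = 0.5
gives the weight distribution a realistic spread without destroying the
distance ordering. What it does not emulate: the heavy-tailed weight
distribution of streamline counts, true fiber (non-Euclidean) lengths,
hemispheric asymmetries, and community structure beyond distance decay.
Tests passing on this generator therefore validate the machinery and the
dynamical regimes, not any claim about a specific empirical connectome.

## Study conditions used by the test harness

Problem sizes are chosen so every stage runs end-to-end on one CPU:
oracle comparisons use 2 regions × 5000 oscillators over 10 s;
whole-network checks use 68 regions × 66 s; the recovery harness uses a
16-region connectome, truth (G, L, v) = (7, 1, 3.5), a 20-run-median
target, 10-run evaluation batches sharing the target's first ten seeds,
and a pop-10 × 15-generation budget for each optimizer. The truth point
sits inside the metastable feasible regime of the 16-region synthetic
connectome (grid mapping: feasibility at v = 3.5 for G ≈ 5–10 with
L ≈ 0.5–1.5 — the same below-critical-L, strong-G balance the full-scale
model exhibits). On this connectome the feasible band begins at larger G
than on 68 regions because the effective drive (G/2E) Σ A_np depends on
the row sums of the normalized weights.

## Known limitations

- First-order Euler: errors are O(dt); halving dt changes trajectories
  by < 1e−3 in the reference configurations, but stiff parameter corners
  (|L| large, G large) may need smaller steps.
- No noise terms: all variability comes from initial conditions, so
  run-to-run FC spread is narrower than in stochastic models.
- Homogeneous Ω and Δ across regions: the fields exist per-ensemble in
  the equations, but heterogeneous sweeps are untested.
- The Kolmogorov–Smirnov comparison is sensitive to tie-breaking at
  machine precision; recurrence vectors are therefore written at full
  precision.
- Scenario-2 optimization at realistic budgets (pop 110, 250
  generations, E = 68) is computationally heavy; the package exposes it,
  but the test suite validates the machinery at reduced scale only.
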