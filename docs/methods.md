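# Methods

## The kinetic model

Hole transport between a donor guanine (D = G-3') and an acceptor stack
(A = 5'-GGG) is modeled as a continuous-time Markov chain on six states
{D, D*, A*, A, PD, PA}. D and A are the equilibrium charge-localized states;
D* and A* are the ensembles of configurations in which solvent and counterion
motion has brought the two hole site energies into vibronic resonance; PD and
PA are absorbing damage products formed by deprotonation of the radical
cation. The eight transitions are

| transition | rate | meaning |
|---|---|---|
| D → D* | `k_act0·exp(−max(0,ΔE_DA)/k_BT)` | activated resonance seeking |
| D* → D | `k_rel_D` | solvent relaxation |
| D* ↔ A* | `k_HT` (both directions) | resonant tunneling |
| A* → A | `k_rel_A` | solvent relaxation |
| A → A* | `k_act0·exp(−max(0,ΔE_AD)/k_BT)` | reverse activation out of the trap |
| D → PD | `k_dam_D` | deprotonation of G·⁺ |
| A → PA | `k_dam_A` | deprotonation of GG·⁺/GGG·⁺ |

Defaults: `k_rel = 1e13 s⁻¹` (solvent response of a few tens of fs),
`k_dam_D = 1e7 s⁻¹`, `k_dam_A = 3e6 s⁻¹` (measured deprotonation rates),
T = 300 K, `k_B = 8.617333262e−5 eV/K`.

Model assumptions worth making explicit:

* **Uphill-only Arrhenius barriers.** A literal exponential with a negative
  ΔE would make activation faster than the solvent-limited prefactor, which
  is unphysical for a resonance-seeking step; downhill barriers are clamped
  to zero and the two directions carry separate energies (`ΔE_DA`, `ΔE_AD`).
* **Two-site reduction.** The (T)n bridge is not resolved into explicit
  states; bridge length enters only through `k_HT`, which is calibrated per
  n. Nothing in the printed data constrains per-bridge-state parameters.
* **Reverse activation.** The equilibrium G/GGG trap depth is not published;
  the default `ΔE_AD = 0.3 eV` makes the reverse step negligible at 300 K
  (factor ~1e−5), and the calibration/prediction workflow uses exactly zero
  reverse activation so the closed form below is exact. Both are
  configurable.
* **τ ↔ rate conversion.** When an activation time is given, `k_act = 1/τ`
  with no separately resolved prefactor/barrier split (the trace analysis
  measures the composite timescale, not the barrier).

### Solvers

*Absorption (default).* With the generator partitioned into transient block
M and absorption flows R, expected occupation times are `τ = (−M)⁻¹ p₀` and
terminal yields `p_abs = R τ`. Exact to linear-solver precision; a residual
check (‖−Mτ − p₀‖ ≤ 1e−8) converts near-singular transient blocks (a
populated state with no outflow, or no reachable product) into a structural
error. Unreachable products give an exact 0 yield; ratios 0 and +inf are
returned flagged, not thrown.

*ODE.* The rates span seven orders of magnitude, so instead of a stiff
integrator the solver evaluates one short-time propagator `P = expm(Q t₀)`
with `t₀ = 0.1/max rate` and squares it (`P(2t) = P(t)²`), walking a
log-spaced time grid. After each squaring the matrix is projected back onto
the column-stochastic nonnegative cone (clip, renormalize columns), which
keeps total probability conserved to ~1e−15 per step instead of compounding
roundoff. Integration stops when the transient mass drops below 1e−12; three
further doublings then drive it toward underflow so that even ~1e−9 yields
are not limited by leftover transient mass. Failure to reach the threshold
raises a convergence error carrying the residual.

*Monte Carlo.* Terminal yields of a CTMC depend only on its embedded jump
chain, so the stochastic solver simulates walkers in aggregate: per step,
the count in each transient state is redistributed multinomially among its
successors with probabilities `q_ij / Σq_ij`. This is exact in distribution
for the absorbed counts, reproducible per seed, and fast enough for 1e5
walkers; one global step advances every live walker by exactly one jump, so
the `max_jumps` guard is per-walker faithful, and walkers still in transit
at the cap are reported as unabsorbed rather than dropped. Holding times are
not tracked — they do not affect yields.

### Closed form and calibration

For equal relaxation rates and zero reverse activation, first-step analysis
gives the exact ratio

    p_PA / p_PD = (k_act / k_dam_D) · k_HT / (2 k_HT + k_rel),

linear in `k_act` and strictly increasing in `k_HT` with supremum
`(k_act/k_dam_D)/2`. The calibration inverts this monotone response by
Brent's method on log₁₀(k_HT) over [1e6, 1e14] s⁻¹ (deterministic; targets
beyond the bracket's attainable range raise a typed error reporting the
supremum). The yield-table workflow calibrates `k_HT` per bridge length at
one activation time and re-solves at another; by the linearity above, the
reverse-free predictions are exactly the calibration inputs scaled by
`τ_calibrate/τ_predict`.

## Trajectory statistics

Traces are uniformly sampled (grid uniformity enforced to 1e−9 relative);
degenerate inputs (constant series, zero variance) raise typed errors rather
than returning NaNs.

* **ACF.** N-normalized (biased) estimator with the record mean as the
  equilibrium value: `ACF(ℓ) = Σ δE(t)δE(t+ℓ) / Σ δE(t)²`, so ACF(0) = 1
  exactly and the estimate is invariant under affine transforms of the
  input. Default maximum lag is half the record; the lag grid advances by
  one sampling interval (no sub-interval behavior is modeled — at 0.5 ps
  sampling the initial fs-scale decay is invisible by construction).
* **Half period.** The ACF of the slow solvent mode behaves like a low-
  frequency cosine; `cos(π·lag/T_half)` first changes sign at `T_half/2`, so
  the estimator reports twice the (interpolated) lag of the first sign
  reversal of the smoothed ACF (centered moving average, default 25 ps). An
  ACF that never changes sign in range is flagged not-found. The reversal
  was deliberately read as the zero crossing rather than the first local
  minimum: only that reading is consistent both with the cosine identity
  above and with reading the extremum lag itself as the half period.
* **Equalization time.** First zero crossing of the 50 ps centered moving
  average of ΔE(t), linearly interpolated between samples; alternatively the
  zero intercept of a straight-line fit to the pre-crossing segment. The
  50 ps default suppresses the ±0.1–0.2 eV fluctuation scale while resolving
  a ~800 ps drift. No-crossing traces are flagged not-found with the final
  smoothed value attached.
* **Spectra.** Mean (or linear-trend) removal, Hann taper (any scipy window
  name accepted), one-sided rfft magnitude against wavenumbers via
  1 THz = 33.35641 cm⁻¹ (c fixed at 2.99792458e10 cm/s). The raw |X_k|
  convention makes Parseval's identity checkable directly from the stored
  amplitudes. Resolving the 100–3000 cm⁻¹ vibrational band requires
  fs-sampled input (0.5 ps sampling caps the axis near 33 cm⁻¹).

## Electrostatic probe

The potential at a nucleobase site is the bare Coulomb sum
`V = k_e Σ q_i/r_i` (`k_e = 14.399645 V·Å/e`; charges in e, distances in Å)
evaluated at the unweighted centroid of the site's atoms — "mean point" is
read as a mass-free average because no weighting is published. The probed
site's own atoms are excluded (self-potential is unphysical for this probe);
there are no periodic images and no reaction field, the probe being a
diagnostic rather than an energy model; a spherical cutoff is available but
off by default. Sources within 1e−6 Å of the probe raise a singularity error
naming the atom.

## Synthetic data

The generators are pure functions of (config, seed); replicate i uses seed
base+i.

* **Gap traces.** The acceptor channel fluctuates about a fixed HOMO-like
  level (−5 eV); the donor channel carries the deterministic gap: a linear
  ramp from −2.0 eV at +2.5e−3 eV/ps (zero crossing at 800 ps), clamped at
  zero afterwards so the levels stay degenerate once equalized. A clamped
  ramp plus stationary noise is the simplest testable reading of an "almost
  linear" approach to degeneracy; a relaxing stochastic mean would add
  parameters nothing constrains. Noise is stationary Ornstein–Uhlenbeck by
  exact discretization (`x' = ax + σ√(1−a²)ξ`, `a = e^{−dt/τc}`), σ/√2 per
  channel and independent between channels so the gap fluctuates at the
  configured σ = 0.15 eV with τc = 10 ps — chosen to match the visual
  scatter of published HOMO traces, for which no SD is printed. An optional
  common-mode OU term (cancelling in the gap) models correlated solvent
  drift; off by default.
* **Potential signals.** Mean level + cosines at configured wavenumbers with
  per-seed random phases + OU noise, Nyquist-checked; a 740 cm⁻¹ harmonic
  closes its first oscillation in ~45 fs.
* **Charge snapshots.** Fixed solute clusters (a +1 e donor site, a neutral
  acceptor stack, and two −1 e counterions that make both site potentials
  negative, i.e. hole-stabilizing) plus water-like dipoles — two opposite
  fractional charges at 1 Å separation whose orientations random-walk on the
  unit sphere — at a deliberately toy scale (50 dipoles in a 20 Å box).

What the synthetic data does *not* emulate: real force-field energetics,
base-step geometry, polarization, the coupling between solvent configuration
and site energies, or replicate-to-replicate variability of the equalization
time (unreported in the source data). Passing tests therefore demonstrate
that the estimators recover known planted structure under realistic noise,
not that any particular molecular system behaves this way.

## Numerical choices and known limitations

* The equalization estimator applied to the default 3-replicate scenario has
  a sampling spread of roughly ±50 ps (SD) with a right tail: once the
  clamped ramp sits at zero, the smoothed gap is a zero-mean correlated
  process and its first upcrossing can arrive late. Tests therefore average
  the recovered time over five independent scenario draws; single draws
  occasionally land outside ±80 ps of the configured crossing.
* The calibration bracket [1e6, 1e14] s⁻¹ bounds recoverable `k_HT`; targets
  needing rates outside it raise rather than extrapolate.
* Problem sizes used in tests and the acceptance script — 2 ns / 0.5 ps / 3
  replicates for gap scenarios, 1e5 walkers for Monte-Carlo cross-checks,
  16k-sample fs-sampled spectra — are the package's standard desk-scale
  conditions; the Monte-Carlo agreement tests skip randomly drawn schemes
  whose expected jump count exceeds ~2e3, since walkers in such schemes
  bounce millions of times between activation and relaxation before
  absorbing.
* PQR is written with 1e−4 Å / 1e−4 e precision and parsed by taking the
  last five whitespace-separated fields of each atom record, so optional
  chain identifiers do not break parsing.
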