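# Methods

This note documents the models, estimators, numerical choices and known
limitations of `aquadyn`. Units throughout: lengths in Å, times in ps,
frequencies in GHz externally (SI internally for the dielectric algebra),
rotational diffusion coefficients in rad²/ps.

## Geometry and topology

Only orthorhombic periodic cells are supported; triclinic lattices are
rejected at parse time. All distances use the minimum-image convention with
each displacement component mapped into (−L/2, L/2]; coordinates are stored
unwrapped as read and never rewrapped. Water topology (O with its two H) is
assigned once, from a reference frame, by giving each hydrogen to its
nearest oxygen within 1.2 Å (the same cutoff as the covalent O–H criterion
of the hydrogen-bond definition) and is held fixed: no O–H dissociation is
expected, consistent with the empty W_11B/W_21B/W_B1B subpopulations. An
oxygen that ends up with other than two hydrogens is a hard error naming the
offending indices.

## Structural analyses

**RDF.** g(r) is the frame-averaged pair histogram normalized by the
ideal-gas shell count at the B-species density, with the (N−1)/V
self-exclusion for like pairs. Raw integer pair counts are retained on the
profile so the histogram can be compared exactly against independent
counting. The coordination number integrates 4πρ_B g r² by trapezoid from
an implicit g(0)=0 anchor through the bin centers, with g interpolated at
the cutoff itself (omitting the final sliver biases an ideal-gas
coordination number low by ~2% at typical bin widths).

**Shell boundaries.** First/second shell edges are the first local minimum
after the first peak and the first minimum after the second peak of g(r)
smoothed by a centered moving average (default 5 bins — short-trajectory
RDFs are noisy). When no second peak is detectable the configured fallback
boundaries are used; with no fallback, an error. Shell intervals are
half-open: [0, r_min1), [r_min1, r_min2), [r_min2, ∞).

**Hydrogen bonds.** Geometric criterion: |O_i−O_j| < 3.5 Å, donor O_j–H_k
< 1.2 Å (covalent), H_k···O_i < 2.5 Å, and the angle at the donor oxygen
between O_j→O_i and O_j→H_k at most 30°. The angle vertex is configurable
("donor"/"acceptor") because the caption-style subscript ordering of the
criterion is ambiguous in parts of the literature; the body-text "O–O–H"
donor-vertex convention is the default. Per-molecule n_HB counts donated
plus accepted bonds.

**Water exchanges (direct method).** A crossing of the shell boundary
counts as an exchange only if the new side persists for at least t* = 0.5
ps continuously (the standard persistence threshold of the method). The
side sequence is coarse-grained to persistent runs first, so a sub-t*
flicker neither counts itself nor lets the return trip count.

**Ion-pair speciation.** Per frame, each cation is paired with its nearest
anion: CIP below r_min1 of the cation–anion RDF, SSHIP in [r_min1, r_min2),
SSIP out to a configurable 8 Å horizon; farther pairs are not counted.

## Time-correlation engine

One engine serves S_HB, C1 and the VACF: multiple time origins (default
stride derived from the trajectory length to target 1024 origins) over a
fixed window, averaged over entities and origins with a single global
normalization Σ num / Σ weight. In the fixed-origin protocol every lag
shares one origin set, which gives the whole curve a common statistical
basis but leaves most of the run unused at short lags when the window is
nearly as long as the trajectory; a `per_lag_origins` mode instead averages
each lag over every origin that fits it (computed by FFT autocorrelation
when no selection is active), the minimum-variance choice when the curve
feeds a fit. The `survival` kernel enforces the
continuous-bond definition via a cumulative product from the origin (a bond
must hold at every intermediate frame). Selections are evaluated at the
time origin only: a water contributes to the subpopulation it occupies at
the origin and is then tracked across the whole window even if it migrates
(a continuous-membership mode is not the default because designed synthetic
shells do not exchange; the generator has an exchange-enabled stress mode).

Default windows: 11 ps for S_HB(t), 16 ps for C1(t).

**HB lifetime.** τ_HB = ∫S_HB dt by trapezoid over the window, optionally
plus a single-exponential tail extrapolation fitted in log space to the
last 20% of the window (both numbers are available; the tail-corrected one
is the default since truncation biases slow rates low). At the scale of
2000 bonded pairs each pair contributes exactly one lifetime, so the
estimator carries an irreducible ~1/√2000 ≈ 2.2% standard error.

**Bi-exponential fit.** C1(t) is fit by a·e^(−t/τ₁) + b·e^(−t/τ₂) for
t ≥ fit_start (default 0.2 ps, excluding the librational transient) with
multi-start nonlinear least squares, positive bounds, and τ capped at 5×
the window end (slower components are not identifiable). Two numerical
safeguards matter in practice:

* residuals are weighted by the lag-dependent uncertainty of a normalized
  TCF estimate, σ(t) ∝ √(1 − C²): the early decay is orders of magnitude
  more precise than the tail, whose noise is strongly correlated across
  lags;
* the fit range is truncated where C(t) first falls below a noise floor
  (default 5% of its initial value): beyond that point a finite-sample TCF
  is correlated statistical noise that otherwise biases the fit;
* identifiability of the second mode is enforced: a fitted τ₂ slower than
  ~0.7× the fitted range never shows its decay inside the data, so its
  amplitude/time split — and with it the amplitude-weighted
  τ_reor = (aτ₁ + bτ₂)/(a + b) — is unconstrained; such fits, along with
  amplitude-degenerate ones and those where the nested single-exponential
  model comes within a factor of 10 of the two-mode weighted SSR, fall back
  to the single-exponential τ. Correlated tail noise otherwise masquerades
  as a spurious slow mode and can shift τ_reor by tens of percent; genuinely
  two-mode decays with both times inside the window are unaffected.

With these safeguards the τ_reor estimator is unbiased on rotational
Brownian benchmarks, with a residual seed-to-seed spread of ~4% at 500
dipoles over 20 ps — essentially the information limit of that sample
size, so recoveries quoted at the 5% level there are ~1σ statements.

**VDOS.** Per-species (O, H) velocity autocorrelations are normalized at
zero lag, tapered by a one-sided half-Hann window (1 at t=0 so the
zero-lag delta of uncorrelated motion survives; 0 at the window end), and
transformed; intensity is the magnitude of the one-sided DFT on a
wavenumber grid (cm⁻¹). No mass weighting. Frequency resolution is set by
the window length; pure tones land within one grid bin.

## Cooperative hydration model

Labels W_abc use unordered hydrogen states under the order 1 < 2 < B
(3 × 6 = 18 labels, 15 admissible). Per-subpopulation τ_reor comes from the
origin-membership C1 fit above. The bulk reference time is the
population-weighted mean τ over the *seed* bulk set — the labels expected
bulk-like a priori, i.e. oxygen not in the cation first shell and no
hydrogen in the anion first shell. Using a set rather than W_BBB alone
matters at high concentration, where W_BBB can be empty.

**Empirical-Rule classification.** Starting from the seed set, the
population-weighted mean and σ of f over the current bulk set are computed
and every populated label is reclassified bulk-like iff |f − mean| ≤ 3σ,
iterated to a fixed point. σ combines (in quadrature, configurable) the
weighted spread of f across the bulk set with the weighted rms of the
per-label block errors — the spread alone degenerates when a single label
dominates the bulk, the block errors alone ignore genuine label-to-label
scatter. On 10⁶ null draws from the bulk distribution the iterated 3σ band
retains ≈99.7% (the trimming fixed point sits near 2.95σ, coverage
~99.68%). Known limitation: the iteration assumes the seed is predominantly
bulk-like; a slow population *inside* the seed with weight comparable to
the bulk inflates σ and is not shed. Physically slow subpopulations are
small and/or excluded from the seed by construction, which is why the seed
rule exists.

**Hydration number.** h = Σ slow populations / salt units, decomposed into
the cation first shell (a = 1) and beyond. Uncertainties: populations use
four non-overlapping 5 ps frame blocks; τ uses the time origins split into
four consecutive groups and refit, because a 16 ps window cannot be fit
inside a 5 ps block. Sparsely populated labels (≲ 0.5 waters) whose C1
cannot be fit are reported "empty" and excluded from h; on designed
fixtures this produces sub-water undercounts, within the ±1-water recovery
tolerance.

## Dielectric relaxation chain

Spectra store the dielectric loss ε″ as positive; the Ohmic term σ/(ωε₀)
is removed before fitting (add/remove are exact inverses). The double-Debye
fit is a joint least-squares on real and loss parts with equal absolute
weights, S ≥ 0, τ > 0, τ₁ initialized at the ~20 GHz mode (7.96 ps) and τ₂
at the ~1 THz mode (0.159 ps) with a few spread-out restarts; modes are
swapped post-fit so τ₁ > τ₂ always names the slow mode. ε_∞ is fixed at
3.52 for solutions (overridable). On noise-free model spectra the recovery
is exact to ~1e-15 relative.

Depolarization uses the positive-magnitude convention ΔS_total =
S(0) − S(c) ≥ 0. The kinetic term is the perfect-slip form, entirely in SI:
ΔS_kin = ⅔ σ(c) τ₁(0)/ε₀ · (ε_s(0) − ε_∞(c))/ε_s(0); printed forms of this
expression elsewhere mix ps/GHz units and an explicit 10³ factor, which
cancels identically in SI. The permittivity difference in the numerator is
switchable to ε_s(c) − ε_∞(c) for sensitivity analysis. The hydration
number is

    N_hyd = [c_H2O(c) − (S(0) − ΔS_static)/S(0) · c_H2O(0)] / c

(S(0) − ΔS_static is the bulk-like strength remaining after removing the
kinetic contribution, so pure dilution gives N_hyd = 0 identically — the
algebraic form with a plus sign seen with signed-Δ conventions is the same
expression). S(0) means S₁+S₂ of pure water by default (S₁-only
switchable). Negative N_hyd is reported and flagged, never clipped.

## Synthetic data

The generators emulate the statistical structure the estimators assume, not
liquid physics: no forces, no translational diffusion (optional jiggle), no
shell exchange by default.

* **Rotational Brownian dipoles.** Each rigid water (r_OH = 0.9572 Å,
  ∠HOH = 104.52°) is rotated each step about a uniformly random axis by an
  angle ~ Normal(0, √(6 D dt)). A small rotation by angle α displaces a
  body-fixed unit vector by ⟨|δu|²⟩ = ⅔α², and diffusion on the sphere
  requires ⟨|δu|²⟩ = 4 D dt, hence the √(6 D dt) calibration; it reproduces
  C1(t) = e^(−2Dt) to within sampling error. Validity requires D·dt ≪ 1
  (enforced: D·dt < 0.01).
* **Designed solutions.** Ions sit on a fixed well-separated grid (≥ 9 Å
  pairwise at the default 26 Å box); shell waters are placed on spheres
  (octahedral axes up to 6, Fibonacci beyond) at 2.1 Å from cations (first
  shell) and 3.0 Å from anions (hydrogens then fall in the anion first or
  second shell as the molecule rotates — the label wobbles among slow
  labels but never reaches W_BBB); bulk waters are rejection-sampled ≥ 6.5
  Å from every ion and ≥ 2.5 Å from every other water oxygen. Default
  rates: D = 0.1 rad²/ps for bulk (τ ≈ 5 ps), 0.02 for designed-slow
  (retardation f ≈ 5, inside the 2–6 range characteristic of ion-retarded
  water). Ground truth (class and D per water, designed h and its
  first-shell/beyond split) is returned and written as a JSON sidecar.
* **Poisson HB events.** Pairs start bonded and break with per-step
  probability 1 − e^(−k dt), never reforming, so the continuous survival is
  exactly e^(−kt) and τ_HB = 1/k.
* **Debye spectra.** The two-mode model on a log-spaced 0.01–110 GHz grid
  (matching the measurement window convention), plus Ohmic loss and
  multiplicative Gaussian noise, all seeded.

What passing tests on these fixtures does **not** show: correctness on real
liquid water (librational transients, genuinely multi-modal C1, shell
exchange, collective dipole cross-correlations — the last is explicitly out
of scope), nor force-field or electronic-structure accuracy.

## Problem sizes

Defaults used by the test suite and acceptance script: 500 dipoles / 20 ps
(dt 4 fs) for rotational recovery; 500-water boxes, 1000 frames at 20 fs
for hydration-number recovery with a 16 ps C1 window; 2000 pairs for HB
kinetics; 10⁶ draws for the classifier null; 200-point spectra. These sizes
put every statistical check at a comfortable multiple of its tolerance
while keeping the whole suite around a minute of CPU.
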