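# Methods

## Model and schemes

The macroscopic model is the conservative advection–diffusion equation

    ∂u/∂t + ∇·(A u) − ∇·(D ∇u) = 0,     x ∈ Ω ⊂ R²,

with space-dependent advection A(x) ∈ R² and symmetric positive-
semidefinite diffusion D(x) ∈ R²ˣ².  For a unit-mass cell cluster, the
first moment ν₁ = ∫x u dx and central second moment N = ν₂ − ν₁ν₁ᵀ obey,
in the point-mass limit u = δ(x − x_t),

    dν₁/dt = A(x_t) + ∇·D(x_t),        dN/dt = 2 D(x_t),

where ∇·D is the column-wise divergence (component i is ∇·(column i); for
the symmetric D used here the row/column distinction is immaterial, but
the column convention is fixed throughout).  These two identities fix the
Euler–Maruyama scheme consistent with the PDE:

    x ← x + (A + ∇·D) Δt + √(2Δt) V ξ,      V Vᵀ = D,

an Itô-type scheme.  It is *not* the Stratonovich transcription of the
naive scheme (drift A only); no Stratonovich mode is provided.  The factor
√(2Δt) reflects the convention that D (not 2D) multiplies ∇u in the flux.

`diffusion_factor` returns the symmetric spectral square root (diagonal
shortcut for diagonal D).  Any factor with V Vᵀ = D induces the same law;
tests only rely on the factorisation identity.  Eigenvalues in
(−10⁻¹², 0) are clamped to zero — roundoff protection at diffusivity
zeros such as the v = 1 contours of the environment field — and anything
more negative is rejected.

## Built-in coefficient families

* **power_law** (a, b): A = (a x₁⁷, a x₂⁷), D = diag(b x₁⁷, b x₂⁷),
  ∇·D = (7b x₁⁶, 7b x₂⁶).  Defaults a = 0.01, b = 0.001 with start (1,1),
  horizon T = 1 in N = 1000 steps and ensemble sizes 10² (paired), 10⁵
  (binning sweep) and 10⁶ (distance statistic) — the reference study
  conditions.  D is negative for xᵢ < 0, where the scheme's square root
  is undefined; since the defaults keep trajectories in the positive
  quadrant (reaching x = 0 from (1,1) is a ≳20σ event), the simulator
  clamps the offending diffusion entry to zero for that step and counts
  the event in a guard counter rather than aborting.  Experiment runs
  report the counter; it is 0 under the default conditions.
* **environment** (v): A = −∇v, D = (v − 1)·I for a fixed scalar
  environment v ≥ 1; the built-in v = 1 + 0.5(sin²x₁ + cos²x₂).  Because
  ∇·((v−1)I) = ∇v, the corrected drift vanishes identically and the
  consistent single-cell scheme is pure (state-dependent) noise, while
  the naive scheme keeps the drift −∇v that herds cells into the valleys
  of v.  Evaluation rejects v < 1 − 10⁻¹² (negative diffusivity).

User families can be registered by name; callables must be vectorised
over an (n, d) batch of positions.

## Ensemble simulation

Ensembles are advanced chunk-wise (32 768 realisations per chunk, a fixed
constant so results are independent of memory configuration).  Each chunk
draws its Gaussian increments from its own substream,
`SeedSequence(entropy=seed, spawn_key=(stream, chunk))` feeding an SFC64
generator.  Consequences:

* runs are bitwise reproducible given (seed, K, N);
* shared-noise pairing is exact: the paired simulator steps both schemes
  through the same increment array, so after one step from a common start
  the position difference is ∇·D(x₀)Δt to machine precision;
* for a field with spatially constant D the two schemes are bitwise
  identical under shared noise (the analytic ∇·D is exactly zero).

Per-realisation substreams were considered and rejected: constructing one
generator per realisation costs two orders of magnitude more than the
draws themselves at K = 10⁶, for no statistical benefit.

Non-finite states freeze the affected realisation at its last finite
position and are counted (`guard.aborted`); under all default conditions
the count is zero.  An optional axis-aligned box applies specular
reflection after each step.  The environment experiment uses [−12, 12]²
to mirror the PDE's no-flux boundary; from the origin with diffusivity
≤ 1 and T = 10 the wall is essentially never reached, so the choice is
inert but principled.  The step count for that experiment is not a
published quantity; the default N = 1000 mirrors the power-law
experiments, and the distance statistic moves by < 4 % between N = 100
and N = 5000 (the acceptance suite checks N ∈ {500, 1000, 2000}).

## Finite-volume PDE solver

Cell-centred conservative finite volume on a uniform square grid.
Advective face fluxes are first-order upwind with coefficients evaluated
at face centres; diffusive fluxes are central, with face-centred D.
Off-diagonal D entries (unused by the built-in families but supported)
contribute through face-averaged tangential gradients.  Boundary faces
carry zero flux, so total mass is conserved to roundoff by construction
(observed relative drift ~10⁻¹⁶ over the full environment run).  Time
integration is explicit Euler with

    Δt = 0.4 · min( h²/(4 max D), h / max |A| ),

checked before every step.  Coefficients are time-independent, so face
data are precomputed once per solve.  The default environment run uses
M = 240 cells per axis (h = 0.1) on [−12, 12]², initial condition
u(0,x) = 3×10⁵ e^(−20|x|²), T = 10 (10⁴ steps, ≈20 s on one core); the
test suite includes a self-convergence check (M = 120 vs 240 on a reduced
domain and horizon, chosen to keep the default test run fast) and the
classical limits (heat-kernel variance growth, pure-advection centroid
translation).  First-order upwinding is diffusive; it keeps the solution
positive and the comparison statistics are ensemble-level, for which the
scheme is converged at the default resolution (the second moment moves
< 2 % under grid halving).  A minmod-limited second-order variant was
considered and left out as unnecessary for these statistics.

## Moment recovery

`moment_recovery_test` estimates dν₁/dt and dN/dt over a short horizon
(default 50 steps of Δt = 10⁻⁴) by least-squares slopes of the moment
time series — lower Monte-Carlo noise than a forward difference and
unbiased to leading order.  Both slope estimators are means of
per-realisation quantities, so standard errors are computed directly as
std/√K; agreement is declared within 3 SE.  A precondition flag records
whether the predicted rates vary by more than 5 % between the start and
the mean final position (they do not, under the default horizons).  For
constant coefficients the scheme's law is exactly Gaussian and the test
passes at any horizon.

## Comparison statistics

* **Average net distance** d = (1/K) Σ |x_T − x_0| per scheme, and the
  signed relative difference E = (d₂ − d₁)/d₁ (corrected vs naive).
* **J2 criterion.**  Final positions are partitioned into x₁-bins of
  width r (left-closed, anchored at the minimum x₁; when two schemes are
  compared the anchor is the pooled minimum so both use identical edges;
  empty bins are dropped).  With classes = bins and samples = the x₂
  values per bin, occupancy weights P_i = n_i/K, bin means μ_i and
  overall mean μ₀ = Σ P_i μ_i:

      S_i = mean over bin i of (x₂ − μ₀)²,   S_w = Σ P_i S_i,
      S_b = Σ P_i (μ_i − μ₀)²,               J2 = |S_w + S_b| / S_w.

  This follows the printed scatter formulas verbatim, including S_i
  taken about the overall mean μ₀; the classical within-class variant
  about μ_i is available via `scatter_about="bin_mean"`.  The printed
  formulas admit several readings (scalar vs matrix scatters, μ₀ vs μ_i
  in S_i); a systematic evaluation of the alternatives — including 2-D
  scatter matrices with determinant or trace reduction, unnormalised
  scatter sums, and binned-coordinate samples — found none that
  reproduces both published sweep averages from ensembles whose distance
  statistics match the published values closely, so the verbatim scalar
  reading is kept as the default and the sweep averages should be read
  as ordering (sign) information rather than calibrated magnitudes.
  The bin sums U_i are computed and reported in `BinSummary` for
  completeness although no downstream statistic consumes them.
* **Sweep**: ℰʳ = (J2_corrected − J2_naive)/J2_naive over
  r = 0.01 + k·0.001, with the mean over k reported.
* **Density mismatch**: L1 distance between the mass-normalised PDE field
  and the normalised final-position histogram on the PDE grid, in [0, 2];
  ensemble mass outside the grid counts as mismatch.  This quantifies the
  Fokker–Planck consistency gate: the corrected scheme's histogram is
  strictly closer to the PDE solution than the naive scheme's.

## Numerical / degenerate-input policy

Diffusion matrices must be symmetric to 10⁻¹² (relative) and PSD up to
the −10⁻¹² eigenvalue floor.  J2 raises on fewer than two occupied bins
or zero within-scatter rather than returning a sentinel.  Convex hulls
fall back to the extreme points along the principal direction for
degenerate (collinear or tiny) clouds; vertices are returned
counter-clockwise.  Bin indices carry a 10⁻⁹ offset so points sitting on
a bin edge up to roundoff land where exact arithmetic would put them.

## What the experiments do and do not show

The three experiment runners use pure simulation; there is no external
data.  They demonstrate the internal consistency of the two schemes with
the moment laws and with the PDE under the two built-in coefficient
families — smooth, separable or periodic fields with known analytic
derivatives.  They do not probe rough or data-estimated coefficient
fields, dimensions above 2, boundary-dominated regimes (particles
essentially never reach the wall under the defaults), or biological
calibration of a, b, v; conclusions about real tissue would need all of
these.

## Known limitations

* The corrected scheme is first-order weak, like any Euler–Maruyama
  variant; no Milstein or adaptive stepping.
* The PDE solver is explicit; stiff (fine-grid) runs pay the parabolic
  CFL price.
* Subset reproducibility of ensembles is at chunk, not single-realisation,
  granularity.
* The J2 sweep magnitudes depend strongly on the criterion reading (see
  above); only their sign structure is robust across readings.
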