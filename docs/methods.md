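# Methods

This note documents the models implemented by `paintkinetics`, the
assumptions behind them, the synthetic-data generator and its defaults, the
numerical choices in the fitting stages, and known limitations.

## Binding model

A docking site is modelled as a memoryless two-state process. With imager
concentration ⟨A⟩ (molar), association rate constant k_a (M⁻¹s⁻¹) and
dissociation rate constant k_d (s⁻¹):

- dark dwell ~ Exp(k_a⟨A⟩); bright dwell ~ Exp(k_d + k_bleach);
- relaxation (SI-FCS decay) time τ_c = 1/(k_a⟨A⟩ + k_d);
- occupation probability ρ = k_a⟨A⟩/(k_a⟨A⟩ + k_d), identically equal to
  τ̄_B/(τ̄_B + τ̄_D) when the dwell means take their theoretical values.

The solution reservoir is assumed infinite and well mixed (⟨A⟩ constant in
time), binding sites are independent (no competition for imager), and
rebinding after unbinding or dye bleaching is immediate — a bleached dye
leaves the docking site intact and free.

Units: all rates are SI internally; nanomolar values are converted at the
interface (`units.nM`). Affinities are displayed at two significant
figures but carried at full precision.

## Depletion model

Photo-induced damage is assumed to occur only while a site is hybridized
(the excited dye generates the damaging species locally). The simulator
implements this as an exponential damage clock that runs only during bright
intervals: the total *occupied* time a site survives is Exp(δ)-distributed,
where δ (s⁻¹) is the per-occupied-site depletion rate constant. Drawing
that occupied-time budget once per site is mathematically identical to a
competing exponential channel of rate δ during every bright interval, and
it makes the per-site history fully vectorizable. The terminal binding
event ends at the damage instant and the site emits no further events.

In the ensemble this yields a site-survival law S(t) = exp(−δρt) and an
effective intensity decay rate κ = δ·ρ, the quantity extracted by the
monoexponential trend fit I(t) = I₀exp(−κt) + I∞. The quantification is
accurate in the regime τ_c ≪ 1/κ, which holds by several orders of
magnitude at all defaults used here.

## Synthetic-data generator

The generator emulates TIRF acquisitions of surface-immobilized DNA
origami, each carrying 12 docking sites on a 3×4 grid with 20 nm pitch
(130 nm pixels). Defaults follow the study conditions the package targets:

| parameter | default | note |
|---|---|---|
| k_a | 1.5·10⁶ M⁻¹s⁻¹ | conventional 9-nt imager |
| k_d | 0.3 s⁻¹ | bright time ≈ 3.3 s |
| ⟨A⟩ | 10 nM | titrations use 10–600 nM |
| δ | 0 (simulations opt in) | conventional-imager value 470·10⁻⁶ s⁻¹ |
| exposure | 0.2 s (PAINT), 0.01 s (SI-FCS) | camera discretization |
| segment | 5100 frames = 17 min | PAINT subset length |
| sites/origami | 12 | incorporation probability configurable, default 1.0 |

`copasi_reference_preset()` returns the mass-action reference parameter set
(10 nM, 0.2 s interval, 17-min segment, no depletion or bleaching) used
for bright/dark-time validation. The nominal imaging concentration printed
as 10 µM in one protocol source is inconsistent with the nanomolar-scale
kinetics; the preset deliberately uses 10 nM, the value the kinetic
simulations state.

Randomness: one master seed; each site draws from a counter-based
substream (`SeedSequence(entropy=seed, spawn_key=(site_index,))`), so
realizations are bit-identical regardless of evaluation order.

Renderers: ROI traces integrate the exact fractional frame occupancy of
all member sites (computed from the piecewise-linear integrated indicator,
so occupied time is conserved to machine precision); the localization
table emits a row for every frame whose occupied fraction reaches a
threshold (default 0.5 — there is no photon-detection model, so the rule
is a configurable geometric criterion); the movie renderer deposits each
origami's intensity as a Gaussian kernel and quantizes to uint16.

What the generator does **not** emulate: localization error and spot
fitting, drift, EMCCD gain and excess noise, PSF overlap between
neighbouring origami, unspecific binding, triplet photophysics, and 3D
geometry. Passing recovery tests therefore demonstrates correctness of
the analysis chain under the stated stochastic binding model, not
robustness to every artifact of real TIRF data.

## Multiple-τ correlator

`multi_tau_acf` estimates G(τ) = ⟨I(t)I(t+τ)⟩/(⟨I(t)⟩⟨I(t+τ)⟩) − 1 with
symmetric normalization (the two means are taken over the same overlap
window as the product), which suppresses bias from residual slow trends.
The lag grid holds m = 16 points per octave: lags 1..m at base resolution,
then blocks of m lags whose spacing doubles after each block, the trace
being block-averaged by the matching factor. Block starts are aligned to
the doubled bin width so every lag is an integer number of binned samples;
at base resolution the estimator coincides exactly with the direct
estimator on the unbinned trace. Lags are capped at a quarter of the
trace length.

## Fitting stages

All fits are unweighted or 1/σ² weighted least squares
(`scipy.optimize.curve_fit`); confidence bounds are Student-t at the
residual degrees of freedom, and covariances are scaled by the reduced
χ² (relative weights), which makes per-point SDs act as weights without
requiring them to be absolute error bars.

- **Detrend (trend model):** start values are deterministic — offset from
  the trace tail, amplitude from head minus tail, rate from a log-linear
  envelope fit. A constant trace returns κ = 0 with the mean as offset;
  non-convergence falls back to κ = 0 with a warning flag, and flagged
  ROIs are excluded (and counted) in pipeline aggregation.
- **ACF decay:** single exponential with offset by default; a second,
  slower exponential is added for nominal concentrations above 100 nM,
  where the depletion component contaminates the curve — the faster
  component is reported as the binding decay. Components are re-ordered
  if the optimizer returns them swapped; alternative start points are
  tried before flagging non-convergence.
- **Titration:** weighted fit of τ_c(⟨A⟩) = 1/(k_a⟨A⟩ + k_d), start
  values from the linearization 1/τ_c = k_a⟨A⟩ + k_d, weights from the
  per-concentration ROI scatter. The affinity CI uses relative-error
  propagation (adequate at the small relative errors encountered; exact
  profile bounds are out of scope).
- **Depletion:** weighted regression of κ on ρ **through the origin** —
  the model has no intercept because an unoccupied population is not
  damaged. An intercept mode exists for diagnostics only.
- **Confocal diffusion:** G(τ) = N⁻¹(1+τ/τ_D)⁻¹(1+τ/(S²τ_D))⁻¹ᐟ²; the
  structure parameter may be fitted or fixed; D = w²ₓᵧ/(4τ_D) and
  c = N(π^{3/2}w³ₓᵧS)⁻¹ (1 nM = 0.60221 µm⁻³).

Temperature scaling of diffusion uses D ~ T/η(T) with the
Vogel–Fulcher–Tammann water-viscosity correlation
η(T) = 0.02939 mPa·s · exp(507.88 K/(T − 149.3 K)), accurate to better
than 1% over 273–373 K; inputs outside that range are rejected.

## Localization-trace analytics

Frames are 0-based; subsets are half-open ranges of 5000 frames by
default. Isolated single-frame dark gaps are merged into the surrounding
bright event before dwell extraction (one missed localization should not
split an event); the operation is idempotent. Merging is applied to whole
traces before subset splitting for whole-trace statistics, and within
subsets for subset analytics. The alternative reading — discarding
one-frame dark times from the statistics instead of merging — is available
by disabling the merge and filtering, but merging is the default because
it addresses the missed-localization artifact directly.

Censoring: leading/trailing dark runs (and dark runs abutting subset
borders) have unknown true length and are excluded from dark-time
statistics; bright runs truncated at borders are kept (small downward
bias, noted here). Active-site counting uses a strict "> threshold"
rule (default 3, i.e. ≥ 4 localizations per subset); the threshold shifts
absolute counts but not the shape of the decay, and it is exposed as a
parameter. Box statistics use linear-interpolation quartiles and
1.5·IQR whiskers clipped to the data.

Frame discretization of dwell times: with the 0.5-overlap emission rule
and uniform event phase, the frame count K of an exponential dwell
observed at all satisfies K−1 ~ Geometric(e^{−k·Δt}). The estimator
k = −ln(1 − 1/K̄)/Δt (`rate_from_frame_counts`) therefore corrects both
the discretization and the loss of sub-half-frame events; its SE follows
from the delta method. The naive inverse mean frame count is biased and
is used only as a comparison in tests.

Two naming collisions inherited from the field are resolved explicitly:
τ_D denotes the *dark time* in trace analytics (`dark`) and the
*diffusion time* in the confocal model (`tau_diff`); the equilibrium
affinity K_d (`kd_affinity`) is distinct from the dissociation rate
constant k_d (`kd`).

## Problem sizes used by the reproduction script

`scripts/acceptance.py` uses: 500 origami × 12 sites × 5100 frames for
the bright-time dissociation-rate recovery; five concentrations
(10, 30, 100, 300, 600 nM) × 64 ROIs × 8 origami × 12 sites × 2·10⁵
frames at 10 ms for the titration (with the conventional imager's
depletion rate 470·10⁻⁶ s⁻¹ active, matching the condition it analyzes);
five concentrations × 2000 sites in 8 groups over 18 000 s for the
depletion regression; 200 noiseless log-spaced lags for the confocal
round trips. The reduced-size equivalents in the test suite use the same
code paths with smaller ensembles and correspondingly wider statistical
tolerances.

## Known limitations

- The detrend fit of a slow decay (κT ≲ 0.5) is ill-conditioned —
  amplitude, rate and offset trade off; the pipeline handles this by
  weighting regression points with the observed group scatter rather
  than by constraining the fit.
- The bi-exponential ACF fit can be degenerate when no slow component is
  present; the concentration-based trigger assumes depletion is active in
  the data being analyzed.
- ROI traces assign whole origami to ROIs; there is no PSF bleed between
  ROIs, so ROI statistics are slightly cleaner than in real binned stacks.
- Dwell statistics assume at most one imager per site; simultaneous
  binding on a *structure* is represented only through origami-level
  binarization.
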