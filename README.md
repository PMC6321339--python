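# paintkinetics

Analysis of DNA-PAINT hybridization kinetics and photo-induced depletion of
docking sites, for single-molecule microscopists who quantify transient
imager binding either from localization time traces (DNA-PAINT/qPAINT) or
from camera-based fluorescence correlation spectroscopy (SI-FCS).

## The science

In DNA-PAINT, a dye-labelled *imager* strand at solution concentration ⟨A⟩
binds reversibly to a surface-attached *docking* strand. A single docking
site is a two-state telegraph process with association rate constant *k*ₐ
and dissociation rate constant *k*_d:

- bright (bound) dwell times: τ_B ~ Exp(*k*_d), dark dwell times:
  τ_D ~ Exp(*k*ₐ⟨A⟩);
- the SI-FCS autocorrelation of an ROI-integrated intensity trace decays as
  G(τ) ∝ exp(−τ/τ_c) with **τ_c = 1/(*k*ₐ⟨A⟩ + *k*_d)**, so a titration of
  ⟨A⟩ yields both rate constants and the affinity K_d = *k*_d/*k*ₐ;
- the equilibrium occupation probability is
  **ρ = 1/(1 + *k*_d(*k*ₐ⟨A⟩)⁻¹) = τ̄_B/(τ̄_B + τ̄_D)**.

Under illumination, reactive oxygen species generated by the excited dye on
a *hybridized* duplex irreversibly damage the docking strand. Because
damage only accrues while a site is occupied, the ensemble fluorescence
decays as I(t) = I₀·exp(−κt) + I∞ with an effective rate
**κ = δ·ρ(⟨A⟩)** where δ is the per-occupied-site depletion rate constant.
Regressing κ (from the trend fit) on ρ (from the titration rates) through
the origin recovers δ.

The package provides:

- `kinetics` — the closed forms above, plus the 3D-diffusion confocal FCS
  model (amplitude 1/N, c = N(π^{3/2}w_xy³S)⁻¹) and water-viscosity
  temperature scaling of diffusion coefficients;
- `simulate` — a seeded stochastic per-site simulator with an
  occupied-gated damage clock, plus renderers to ROI traces, localization
  tables and TIFF stacks;
- `correlate` — software binning and the multiple-τ autocorrelator
  (m points per octave, bin width doubled after each block);
- `models` — statsmodels-style Model/Results pairs for every inference
  stage (trend detrending, ACF decay, titration, depletion regression,
  confocal diffusion), each with 95% confidence bounds and `summary()`;
- `traces` — bright/dark-time extraction with single-frame gap merging,
  5000-frame subset analytics and active-docking-site counting;
- `io`/`cli` — picked-localization HDF5/CSV schema, YAML run configs and a
  `paintkinetics` command with `simulate`, `correlate`, `fit-acf`,
  `titrate`, `deplete` and `traces` subcommands.

## Worked example

Recover the conventional-imager rate constants from a synthetic SI-FCS
titration (10–600 nM, 16 ROIs, 50 000 frames at 10 ms — a reduced-size run
of the full pipeline):

```python
import paintkinetics as pk

rates = pk.BindingRates(ka=1.49e6, kd=0.303)       # ground truth, 1/(M s), 1/s
res, points = pk.run_titration(
    rates, n_rois=16, origami_per_roi=4, n_frames=50_000,
    seed=11, delta=470e-6,                          # occupied-gated depletion
)
print(res.summary())
```

```
Titration fit  tau_c = 1/(ka <A> + kd)
======================================
parameter           estimate     std err        [0.025        0.975]
ka                1.4938e+06    3.72e+04   1.37546e+06   1.61215e+06
kd                  0.299478     0.00689      0.277544      0.321412
df_resid = 3, converged = True
Kd = kd/ka = 200.5 nM (95% CI 179 – 222 nM)
```

The fitted association rate (1.49·10⁶ (Ms)⁻¹), dissociation rate
(0.299 s⁻¹) and affinity (200 nM) recover the generative values within
their confidence bounds. The same objects expose the per-concentration
decay times (`points`), and `pk.run_depletion` performs the analogous
κ-versus-ρ experiment for the depletion rate constant δ.

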