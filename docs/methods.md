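# Methods

`amorphquant` implements a chemometric workflow for quantifying the amorphous
fraction of a drug inside a polymer matrix from near-infrared (NIR)
reflectance and Raman spectra, aimed at laser-sintered (SLS 3D-printed)
formulations where the printing process itself converts crystalline drug to
the amorphous form. The reference system is itraconazole (a BCS class II
drug) at a constant 20% w/w load in hydroxypropyl cellulose (HPC) with 3%
w/w of a colourant/laser absorber. This note records the models, the
defaults and why, what the synthetic data generator does and does not
emulate, and the numerical choices.

## Calibration model

The response is amorphous drug content y (% w/w, 0–20). Spectra are
preprocessed (below), assembled into a matrix X (samples x retained
wavenumbers), and regressed by single-response partial least squares
(PLS1) computed with NIPALS. For each latent variable (LV) on the centred
data:

    w_k = X'y / ||X'y||,   t_k = X w_k,
    p_k = X't_k / t_k't_k,  q_k = y't_k / t_k't_k,
    X <- X - t_k p_k',      y <- y - q_k t_k.

The regression vector is b = W (P'W)^-1 q and predictions are
ŷ = (x − x̄)·b + ȳ. Score columns are mutually orthogonal by construction;
the per-LV share of X variance is 100·‖t_k p_k'‖²_F / ‖X_c‖²_F, and the
first share (LV1 %) is reported as the model's *specificity* for solid-state
change.

The LV count is chosen by leave-one-out cross-validation with a parsimony
rule: the smallest k whose RMSECV is within 2% (relative) of the minimum.
Each fold refits from scratch, including re-centering, so the held-out
sample never touches the fold's statistics; NIPALS components are nested in
k, so one fit per fold serves every candidate k (verified in the tests
against a naive per-k refit loop).

Validation follows the ICH Q2(R1) triad: specificity = LV1 % X-variance,
linearity = R² (defined as 1 − SSE/SST, i.e. the coefficient of
determination, which penalises bias — a deliberate choice over squared
Pearson correlation), accuracy = RMSEP on a held-out internal validation
set (4 of the 18 design samples, drawn without replacement, seeded). RMSEC,
RMSECV and RMSEP are reported separately rather than conflated.

Score-space admissibility uses the Hotelling T² ellipse over (LV1, LV2):
T² = Σ t_k²/var(t_k) with variances from the calibration scores (n−1
denominator throughout the package) and the small-sample limit
2(n−1)/(n−2)·F(1−α; 2, n−2), α = 0.05. For large n this limit tends to the
χ²₂ quantile; the tests verify ~95% empirical coverage at n = 10,000. When
the selected model has a single LV, an auxiliary 2-LV fit supplies the
(LV1, LV2) scores for the ellipse, since the diagnostic is inherently
two-dimensional.

## Preprocessing chains

Two fixed reference chains, with all operators also usable à la carte:

* **NIR**: select 4000–6200 cm⁻¹ with 4800–5200 cm⁻¹ (moisture band)
  excluded → 2nd-derivative Savitzky–Golay (21-point window, 2nd-order
  polynomial) → standard normal variate (SNV) → mean-center.
* **Raman**: select 1000–1700 cm⁻¹ → Whittaker asymmetric-least-squares
  baseline (λ = 100,000, p = 0.001) → normalisation to the 1614 cm⁻¹ peak
  area → mean-center.

Numerical choices:

* The SG window is 21 *points* (the chemometrics convention), not 21 cm⁻¹ —
  on an 8 cm⁻¹ grid a 21 cm⁻¹ window could not support a 2nd-order fit.
  The derivative is taken per grid step (index units); this differs from a
  per-cm⁻¹ derivative by the constant step^2, which SNV/mean-centering
  removes. Edges are trimmed, (window−1)/2 points per side, rather than
  padded — no fabricated derivative values; region selection makes the lost
  edge points immaterial. Because the water-band exclusion leaves a
  piecewise-uniform axis, the filter operates on maximal contiguous
  uniform-step runs (each must span at least one window); a truly irregular
  axis raises an error instructing explicit resampling.
* SNV standardises each spectrum with the n−1 standard deviation; a
  constant spectrum is a degenerate-input error. SNV removes per-spectrum
  positive scale and offset exactly; peak-area normalisation removes
  positive scale exactly (both verified against the simulator's
  multiplicative-scatter term).
* The Whittaker baseline minimises Σ wᵢ(xᵢ−zᵢ)² + λ Σ(Δ²z)² with weights
  iteratively reset to p above the baseline and 1−p below, starting from
  all ones, stopping when the weight vector stabilises (relative change
  < 1e-6) or after 10 solves. The pentadiagonal normal equations are solved
  in symmetric banded form (equal to a dense solve to < 1e-8 in the tests).
* Peak-area normalisation integrates trapezoidally over the closed window
  1614 ± 15 cm⁻¹ (the half-width spans the rendered ν(C=C) band; the window
  centre is configurable — 1614 vs 1618 cm⁻¹ both appear in the
  literature for this band and no reconciliation is attempted).
* Interval selection is closed on both keep and exclude bounds, and
  exclusion wins; the grid anchoring decides borderline points (on the
  8 cm⁻¹ grid anchored at 3600, the NIR chain retains 4000–4792 and
  5208–6200 cm⁻¹).
* The only *fitted* chain statistic is the column-mean vector, frozen on
  the calibration set and reapplied verbatim to validation/prediction
  spectra (leakage is tested by perturbing validation spectra and asserting
  a bit-identical model).

## Synthetic data generator

No measured spectra ship with the package; a seeded generator emulates the
study conditions so every stage is testable:

* **Design**: six composition levels, crystalline:amorphous =
  20:0, 16:4, 12:8, 8:12, 4:16, 0:20 (% w/w) at 77% polymer + 3% colourant;
  3 independent preparations per level; 3 scan positions per sample,
  averaged; 4 of the 18 samples held out (seeded, without replacement) for
  internal validation. Sintered-disc test sets default to 3 discs per HPC
  grade with amorphous conversion fractions 0.90/0.85/0.65 of the 20% w/w
  load for HPC-L/-SL/-SSL (invented defaults echoing the reported
  qualitative ordering; the truth is retained for recovery tests).
* **Signatures**: pseudo-Voigt bands (FWHM-parameterised Gaussian/Lorentzian
  blend). Band positions are literature-anchored — the crystalline C–H
  first-overtone doublet at 5800/5900 cm⁻¹, the amorphous single broad band
  at 5775 cm⁻¹, the ~5000 cm⁻¹ moisture band, and the ν(C=C) Raman band at
  1618 cm⁻¹ — while every height/width/amplitude is an invented fixture
  constant collected in `signature_defaults.py`. Raman amorphous bands share
  the crystalline centres at 2.0x the width and 0.50x the height (area
  conserved, so the 1614 cm⁻¹ normalisation denominator stays stable across
  the design — the regime in which a linear calibration is the right
  model); a fluorescence background A·exp(−shift/600 cm⁻¹) scales with the
  amorphous (coloured) fraction. The NIR moisture band is a Gaussian at
  5000 cm⁻¹ (FWHM 200, support hard-limited to 4600–5400 cm⁻¹) fed by the
  hygroscopic amorphous form *and* by the cellulose polymer.
* **Mixing and noise**: noiseless spectra are exactly linear in mass
  fractions (equal scattering/absorption efficiency per component — the
  assumption under which PLS calibration against content is well-posed).
  Noise adds, per spectrum: a lognormal multiplicative scatter factor
  (log-sd 0.05; doubled for disc presentation, standing for the rougher
  sintered surface), a random linear baseline (offset sd 0.01, slope sd
  0.005), i.i.d. additive noise (sd 0.002), and a lognormal jitter
  (log-sd 0.7) on the moisture band only — sample-to-sample ambient
  humidity. That jitter is what makes the documented 4800–5200 cm⁻¹
  exclusion *beneficial*: a moisture band deterministically tied to
  composition would help a model rather than justify exclusion.
* **Grids**: NIR 3600–12496 cm⁻¹ at 8 cm⁻¹ (the instrument's stated
  resolution read as the grid step; 12500 is off-lattice), Raman 100–2000
  cm⁻¹ at 1 cm⁻¹ (a typical dispersive scale; configurable).

What the generator does **not** emulate: radiative transfer in sintered
surfaces, instrument line-shape functions, detector nonlinearity,
wavelength drift, cosmic-ray spikes, or any quantitative match to measured
itraconazole/HPC band intensities. Passing recovery tests therefore
demonstrate that the *pipeline* is correct and well-conditioned under
linear-mixing conditions with realistic artefact classes — not that the
specific published model statistics are reproduced. The published model
metrics (R² = 0.998, RMSEP ≈ 1%, LV1 ≈ 86–90%) depend on undeposited raw
spectra and serve only as qualitative benchmarks; the package's own design
thresholds are calibration r² ≥ 0.99 and held-out RMSEP ≤ 1.5% w/w over
seeds 1–10, which both modalities meet with margin.

## Powder flow

Bulk density ρ_b = M/V and tapped density ρ_t = M/V_f feed the
compressibility (Carr) index CI = 100(ρ_t − ρ_b)/ρ_t and Hausner ratio
HR = ρ_t/ρ_b, tied by CI = 100(1 − 1/HR). Note an erratum in the source
literature for this system: the compressibility-index equation is printed
with ρ_b in the denominator, but every tabulated value there (e.g. pure
drug: ρ_b 0.26, ρ_t 0.52 → CI 50%) is consistent only with the standard
ρ_t divisor, which is what this package implements. Classification uses
half-open CI bands [0,11) excellent, [11,16) good, [16,21) fair, [21,26)
passable, [26,32) poor, [32,∞) very poor, with the companion Hausner ranges
reported informationally (no arbitration rule between the two is invented).
Replicates are summarised by computing indices per replicate first and then
averaging (mean of ratios) — that is how replicate standard deviations of
the indices arise — and the class is assigned from the mean CI.

## Problem sizes and determinism

Default problem sizes are the study's own: 18 samples x 3 positions per
modality, 1113-point NIR and 1901-point Raman grids, 9 discs; a full
two-modality calibration plus disc prediction runs in well under a second,
and the whole acceptance sweep (10 seeds x 2 modalities plus a 10,000-point
ellipse coverage simulation) in a few seconds. All randomness flows through
`numpy.random.default_rng` seeds carried in the configuration objects;
identical configuration and seed reproduce bit-identical spectra, models
and serialized reports (hash-verified in the tests). Model JSON uses
shortest-repr doubles, so serialization round-trips exactly.

## Known limitations

* The linear-mixing assumption ignores nonlinear scattering/absorption
  coupling (no Kubelka–Munk treatment); real reflectance data may need MSC
  or more LVs than the synthetic defaults suggest.
* SNV and peak-area normalisation are ratio transforms and mildly nonlinear
  in composition; with the default signatures the effect is negligible, but
  strongly composition-dependent normalisation denominators would curve the
  response.
* The JCAMP-DX reader covers plain AFFN `XYDATA`/`XYPOINTS` tables only;
  compressed dialects (SQZ/DIF/DUP/PAC) and vendor binaries are declared
  unsupported.
* Axis equality across a set is exact by design; no silent interpolation or
  spectral warping is performed, so mismatched grids must be resampled
  explicitly upstream.
* Whether calibration samples were presented as loose powder or compressed
  squares is recorded per spectrum but the defaults assume powder; the
  presentation field only becomes load-bearing through the disc scatter
  term.
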