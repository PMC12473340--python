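# Methods

`qmtkit` implements five magnetization-transfer-contrast (MTC) estimation
methods for skeletal muscle on one shared physical foundation, together
with the relaxometry they depend on, a synthetic acquisition simulator,
and the statistics used to compare young and senior cohorts. This note
describes the models, the numerical choices, what the simulator does and
does not emulate, and the known limitations.

## The two-pool signal model

Muscle water protons (free pool A, T2 ~ tens of ms) exchange longitudinal
magnetization with protons bound to macromolecules (pool B, T2 ~ microseconds).
An off-resonance pulse saturates pool B through its absorption lineshape;
exchange transfers the saturation to the observable water signal. With the
signal normalized to an MT-free acquisition, the steady-state saturated
signal is

    Sn = (RB·X + RB + R_RFB + R·M0A)
         / (X·(RB + R_RFB) + D·(R_RFB + RB + R·M0A)),

where `X = R·M0A·F/RA`, `D = 1 + (ω1_eq / 2πΔf)² / (RA·T2A)` is the direct
(free-pool) saturation factor, and `R_RFB = π·ω1_eq²·G(Δf; T2B)` is the
bound-pool saturation rate. `F = M0B/M0A` is the pool-size ratio and
`f = F/(1+F)` the macromolecular fraction, the primary tissue index.
`Sn ∈ (0, 1]` for every physical parameter set (the denominator exceeds
the numerator by `X·R_RFB + (D−1)·(R_RFB+RB+R·M0A) ≥ 0`).

The bound-pool lineshape `G` is the super-Lorentzian — the orientational
average of dipolar-broadened semi-solids, standard for tissue qMT. Its
integrand has a sharp (finite) feature where `3cos²θ − 1` vanishes, so a
single Gauss–Legendre panel over `[0, π/2]` converges poorly (~3×10⁻⁵
relative at 512 points). We therefore split the interval at the magic
angle `arccos(1/√3)` and apply a fixed 512-point rule per panel, which is
converged to ~10⁻¹³ and bit-stable across runs (nodes cached at import).
The lineshape is singular on resonance; evaluation below a 100 Hz floor
is refused rather than extrapolated (the protocols never go below 1 kHz).

### Pulsed irradiation as continuous-wave equivalents

The MT preparation is a Gaussian pulse (spectral FWHM 200 Hz, duration
10.24 ms, TR 50 ms for the qMT protocols; 375 Hz / 9.984 ms for the
MT_sat protocol). The temporal envelope follows from the Fourier pair
`σ_f = FWHM/(2√(2 ln 2))`, `σ_t = 1/(2π σ_f)`, truncated to the stated
duration and calibrated so the truncated envelope integrates to the
nominal flip angle. Envelope integrals use exact erf closed forms
(verified against high-resolution quadrature in the tests). Two
continuous-wave equivalents are supported:

* `ω1_CWPE² = (1/TR) ∫ ω1²(t) dt` — power averaged over TR (the
  convention of the "Ramani" model);
* `ω1_rms² = (1/t_mt) ∫ ω1²(t) dt` — power averaged over the pulse (the
  "Yarnykh" convention).

They satisfy `ω1_CWPE²·TR = ω1_rms²·t_mt` identically; since `t_mt < TR`,
the RMS convention always implies more saturation power, so the
Ramani-mode signal is pointwise ≥ the Yarnykh-mode signal. Signals are
modeled as exact steady state: the protocols apply ~100 preparation
pulses over 5 s before readout, which justifies neglecting the transient.

## Estimation methods

**Multi-offset qMT** (`fit_multioffset`): nonlinear least squares of
(F, R·M0A, T2A, T2B) over 14 points (MT flips 350° and 500° × offsets 1,
2, 5, 10, 20, 50, 100 kHz), normalized to the MT-free volume. RB is fixed
at 1 s⁻¹ (it barely influences the other parameters) and RA is fixed to
the VFA-measured R1 with no observed-to-free-pool correction. The fit
runs in log-parameter space with physiologic bounds (F ∈ [10⁻⁴, 0.5],
R·M0A ∈ [1, 200] s⁻¹, T2A ∈ [5, 200] ms, T2B ∈ [1, 30] µs), initial values
F = 0.07, R·M0A = 48 s⁻¹, T2A = 0.025/RA, T2B = 6 µs, and three
deterministic restarts (nominal, ×1.5, ×0.5) with best-residual selection.
Voxel B1 scales the MT flip angle (the CW-equivalent amplitude is linear
in flip, so B1 enters multiplicatively); voxel B0 shifts the offsets as
`Δf_eff = Δf_nominal − B0` (positive B0 = resonating above nominal).

**Single-offset qMT** (`solve_single_offset`): the accelerated
two-parameter route fixes T2B = 6 µs, RA·T2A = 0.025 and R·M0A = 48 s⁻¹
(muscle literature constants), uses the 100 kHz image as the MT-free
reference (far off-resonance saturates neither pool appreciably), and
inverts the signal equation in closed form at the 650°/1 kHz point:

    F/RA = (R_RFB + RB + R·M0A)(1 − Sn·D) / (R·M0A·(Sn·(R_RFB+RB) − RB)).

By construction this is the exact algebraic inverse of the forward model
when the constants match — the consistency oracle in the tests verifies
the identity to ≤10⁻⁶ relative on F.

**MT_sat** (`estimate_A_R1`, `mtsat_delta`): the fractional saturation δ
of the free pool by one MT pulse per TR, from the small-angle rational
spoiled-GRE model `S = A·α·R1·TR/(α²/2 + δ + R1·TR)`. A and R1 come from
the PDw (4°) and T1w (20°) volumes via the rational estimators (exact
inverses of that model); δ is then solved from the MTw (10°) volume. All
flip angles are B1-scaled first; afterwards the semi-empirical correction
`δ_corr = δ·(1−0.4)/(1−0.4·B1_rel)` is applied, in that order. δ is
reported in percent units (p.u., δ×100) at every interface. Note the
correction factor increases with B1 — it was calibrated against the
empirically *decreasing* apparent MT_sat of in-vivo protocols.

**MTR / MTR_corr** (`compute_mtr`, `fit_k`, `apply_mtr_correction`):
`MTR = 1 − S_MT/S_ref`, stored as a fraction. The B1 correction assumes a
linear MTR-vs-B1-error relation, fits `MTR = intercept + k_specific·b1_error`
per subject on voxels of a reference tissue (tibialis posterior by
default; `b1_error = b1_rel − 1`), derives the tissue-independent
`k = k_specific/intercept`, and corrects `MTR_corr = MTR/(k·b1_error + 1)`.

**Relaxometry**: VFA T1 from the linearized spoiled-GRE fit
`S/sin α = E1·(S/tan α) + M0(1−E1)` at 5/15/25°, TR 25 ms, with B1-scaled
angles; B0 from the dual-echo phase difference
`Δf = wrap(φ2−φ1)/(2π·ΔTE)` at TE 4.92/7.38 ms (unaliased to ±203.25 Hz).
Only temporal (per-voxel) wrapping is handled — muscle B0 offsets at 3 T
stay well inside the aliasing range, so no spatial unwrapping is needed.

**Analysis convention**: indices are computed from ROI-averaged signals
(the ROI-mean-then-index path), matching the study design; a voxelwise
map-then-average mode exists for comparison, and the two agree on
homogeneous tissue.

## The synthetic data generator

The generator defines the study conditions under which the pipeline is
validated; none of its parameters are fitted to outputs.

* **Geometry**: a schematic calf cross-section — five disjoint elliptical
  muscles (SOL, MG, LG, TA, TP) on a 64×64×4 grid (agarose cylinders on
  48×48×2). The geometry is schematic, not anatomical; volumes are
  generated pre-aligned, so registration is unnecessary by construction.
  Grid sizes are the package's own choice: labels and fields are
  z-invariant and smooth, so larger matrices add voxels but no
  information.
* **Tissue truths**: per-muscle two-pool parameters with young
  macromolecular-fraction medians TA 0.075, TP 0.074, SOL 0.072, MG 0.071,
  LG 0.070 (tibialis above plantarflexors), R·M0A = 48 s⁻¹, T2B = 6 µs,
  RA = 1/T1, T2A = 0.025·T1. Young T1 is 1.40 s. The senior group's f is
  shifted down by 0.006 and T1 up by 0.07 s. Age contrasts are induced
  only through tissue parameters, never painted onto index maps, so all
  five methods see one consistent ground truth.
* **Biological spread**: subject-level effects (f SD 0.003, T1 SD 0.03 s)
  and muscle-level effects (f SD 0.001, T1 SD 0.02 s). Subject f and T1
  share one latent factor with correlation −0.5, modeling the
  inflammation/composition coupling that makes MT indices co-vary
  negatively with T1 within groups.
* **Fields**: B1 and B0 are low-order random polynomials; a
  coil-geometry component shared by all subjects of a study plus a 30%
  subject-specific perturbation, with total ranges ±15% (B1) and ±40 Hz
  (B0). Agarose vials share one session field with per-vial mean B1
  within ±3% (phantom at isocenter) and an ±8% internal gradient.
* **Signals**: MT-weighted volumes are the spoiled-GRE steady state times
  the two-pool attenuation at the voxel's B1-scaled flip and B0-shifted
  offset; the MT_sat triplet uses the rational small-angle family (the
  model the estimators invert), with the per-TR saturation δ derived from
  the two-pool attenuation of the MT_sat pulse; VFA volumes use the full
  spoiled-GRE model. Magnitude noise is Rician, with SNR defined on the
  mean tissue signal of the reference volume (cohort default 100, agarose
  200). All draws are deterministic given the seeds.
* **Generative RF convention**: MT attenuation is simulated under the CW
  power-equivalent convention by default; `mode="yarnykh"` switches to
  the RMS convention. Each multi-offset model is validated against data
  from its own convention: a cross-convention fit is misspecified by
  construction (the T2B bound blocks the compensating solution) and not a
  meaningful test of the estimator.

What the simulator does **not** emulate: fat infiltration and fascicles
(acquisitions are fat-suppressed by design), motion and registration
error, coil sensitivity profiles, anatomical muscle shapes, the empirical
in-vivo B1 dependence of apparent MT_sat that the 0.4-factor correction
was calibrated against (on synthetic data the apparent MT_sat *rises*
with B1, so that correction does not cancel the dependence here), and the
real-data discrepancy between Ramani- and Yarnykh-fitted f values.
Passing tests therefore demonstrate internal consistency and correct
implementation of each estimator, not in-vivo accuracy.

## Statistics

Following the study design, all tests are two-sided at α = 0.05.
T1 goes to the parametric branch when Shapiro–Wilk accepts normality —
evaluated on cell-centered residuals, since a genuine age effect makes
the pooled distribution bimodal by construction — and is then analyzed
with a two-way (age × region) type-II ANOVA plus a Levene homogeneity
diagnostic and Bonferroni-adjusted pairwise t-tests on a significant
region effect. The MT indices use Mann–Whitney U (age, muscles pooled)
and Kruskal–Wallis (region, groups pooled) with Bonferroni-adjusted
post-hoc U-tests. Effect sizes: the Hodges–Lehmann estimator (median of
all young−senior pairwise differences) with an exact rank-based 95% CI
(exact Mann–Whitney null distribution for n1·n2 ≤ 400, normal
approximation above; deterministic), and the rank-biserial correlation
`r = 1 − 2U/(n1·n2)` with magnitude labels |r| < 0.3 small, ≤ 0.5 medium,
else large. Pearson regression of each index against T1 pools all
(subject, muscle) ROI points. Pooling conventions (age across muscles,
region across groups) follow the reporting layout of the study.

## Known limitations

* ROI-mean analysis applies scalar (ROI-mean) B1/B0 corrections to
  ROI-mean signals; with strong intra-ROI field gradients this aggregation
  is second-order biased relative to voxelwise correction.
* MTR is intrinsically concave in f (noiseless straight-line R² ≈ 0.97
  over f ∈ [0.02, 0.12] against ≈ 1.0 for f(so) and MT_sat), so MTR ranks
  last in phantom linearity — consistent with its standing as the least
  reliable surrogate marker.
* The ANOVA treats the five per-subject muscle values as independent
  observations (as in the study design); with subject-level clustering
  this is anti-conservative. A mixed-effects model is out of scope.
* Group comparisons at n = 15/9 with pooled muscles have limited power
  for the noisier multi-offset estimates; the synthetic experiments
  default to the same sizes.
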