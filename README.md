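# qmtkit

Magnetization-transfer contrast (MTC) estimation for skeletal muscle MRI.

Aging muscle loses myofibrillar protein and gains collagen; both change the
macromolecular proton fraction that magnetization transfer (MT) imaging
probes. `qmtkit` implements the five MTC estimation methods commonly
compared for this purpose — multi-offset quantitative MT (qMT) under the
Ramani (CW-power-equivalent) and Yarnykh (RMS) RF approximations,
single-offset qMT, MT_sat, MTR, and B1-corrected MTR — on one shared
two-pool physical model, together with the supporting relaxometry (VFA T1,
dual-echo B0, B1 application), a synthetic calf/agarose acquisition
simulator, and the cohort statistics (Mann–Whitney with Hodges–Lehmann and
rank-biserial effect sizes, Kruskal–Wallis, two-way ANOVA for T1, Pearson
regression against T1) needed to run a complete young-vs-senior comparison
end to end. It is aimed at muscle qMT researchers who want a reference
implementation whose every stage is testable against known ground truth.

## The model

The saturated signal, normalized to an MT-free acquisition, follows the
binary spin-bath steady state

    Sn = (R_B·X + R_B + R_RFB + R·M0A) / (X·(R_B + R_RFB) + D·(R_RFB + R_B + R·M0A))

with `X = R·M0A·F/R_A`, direct-saturation factor
`D = 1 + (ω₁ᵉᑫ/2πΔf)²/(R_A T2A)`, and bound-pool saturation rate
`R_RFB = π·ω₁ᵉᑫ²·G(Δf; T2B)` under the super-Lorentzian lineshape G.
`F = M0B/M0A` is the pool-size ratio; the reported index is the
macromolecular fraction `f = F/(1+F)`. The multi-offset fit estimates
(F, R·M0A, T2A, T2B) from 14 (flip, offset) points with R_B = 1 s⁻¹ and
R_A from VFA T1; the single-offset method fixes T2B = 6 µs,
R_A·T2A = 0.025, R·M0A = 48 s⁻¹ and solves the same equation for F in
closed form from one 650°/1 kHz measurement. MT_sat inverts
`S = A·α·R₁·TR/(α²/2 + δ + R₁·TR)` for the per-TR saturation δ (percent
units); MTR = 1 − S_MT/S_ref, with an optional reference-tissue k-factor
correction `MTR_corr = MTR/(k·ΔB1 + 1)`. See `docs/methods.md` for the
full account.

## Worked example

Simulate one synthetic subject and compute every index per muscle ROI:

```python
from qmtkit.pipeline import subject_indices
from qmtkit.synthetic import CohortConfig, simulate_subject

config = CohortConfig(seed=1)           # study defaults: 15 young / 9 senior
sub = simulate_subject(config, 0, "young")
table = subject_indices(
    sub.stacks, sub.phantom.labels, sub.phantom.label_names,
    methods=("multioffset_ramani", "singleoffset", "mtsat",
             "mtr", "mtr_corr", "t1_vfa", "b0"),
)
print(table.pivot(index="muscle", columns="index", values="value").round(4))
```

```
index       B0      B1     MTR  MTR_corr  MT_sat      T1   f_ram    f_so
muscle
LG      1.5099  1.0071  0.5553    0.5539  6.1688  1.3765  0.0696  0.0694
MG      5.8681  1.0019  0.5594    0.5590  6.2811  1.3617  0.0720  0.0725
SOL     1.8593  0.9997  0.5584    0.5585  6.2338  1.3672  0.0727  0.0725
TA      1.2072  0.9989  0.5655    0.5657  6.3846  1.3774  0.0752  0.0753
TP     -0.9116  0.9939  0.5602    0.5615  6.2446  1.3608  0.0742  0.0749
```

Each row is one calf muscle. `f_so`/`f_ram` are macromolecular fractions
(dimensionless; this subject's ground truths lie at 0.069–0.075 per
muscle and both estimates recover them at the simulated SNR of 100),
`MT_sat` is in percent units, `MTR`/`MTR_corr` are fractions, `T1` in
seconds, `B0` in Hz, `B1` relative to nominal. A full two-cohort study —
simulation, index computation and statistics — is one call each:

```python
from qmtkit.pipeline import analyze_cohort, cohort_statistics

table = analyze_cohort(CohortConfig(seed=1))
stats = cohort_statistics(table)
print(stats["age_comparisons"][["index_name", "p_two_sided", "hl_estimate",
                                "rank_biserial_r", "magnitude"]])
```

```
  index_name   p_two_sided  hl_estimate  rank_biserial_r magnitude
0       f_so  3.683830e-09     0.006565         0.645037     large
1     MT_sat  6.128943e-07     0.392371         0.545481     large
2        MTR  3.612744e-04     0.008287         0.390222    medium
3   MTR_corr  1.848808e-05     0.009013         0.468444    medium
```

The Hodges–Lehmann column is the young-minus-senior shift in the index's
own units (the f(so) shift of ~0.0066 reflects the generator's configured
age contrast of 0.006); p-values are two-sided Mann–Whitney tests pooled
over the five muscles.

The same stages are scriptable from the shell (`qmtkit simulate-cohort`,
`qmtkit roi-extract`, `qmtkit stats`, `qmtkit run-all`, ...); see
`qmtkit --help`.

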