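# isotroph

Trophic-niche inference for detritivores from compound-specific stable
isotopes. The package implements the quantitative chain used to ask how
soil animals such as earthworms feed: **where they sit in the food web**
(trophic position from amino-acid δ¹⁵N), **which basal energy channel
feeds them** (plant, bacterial or fungal carbon, from amino-acid δ¹³C
fingerprints), and **what the surrounding microbial community looks
like** (PLFA biomarkers). A built-in synthetic-study generator with
known ground truth makes the whole chain testable end to end without
any external data.

## The methods

**Trophic position.** Glutamic acid is strongly ¹⁵N-enriched at every
trophic transfer while phenylalanine is nearly conserved, so

TP = (δ¹⁵N_Glu − δ¹⁵N_Phe − β) / TDF + 1

where β is the Glu–Phe offset of the basal producer (presets: rape
−7.5 ± 1.6‰, legume −8.2 ± 1.4‰, generic C3 plants −8.4 ± 1.6‰) and
TDF = 7.6 ± 1.2‰ is the per-level discrimination factor. The
uncertainties of β and TDF are propagated by Monte Carlo into TP
credible intervals, and planned contrasts compare litter treatments
against a reference within each species.

**δ¹³C fingerprinting.** Metazoans cannot synthesize essential amino
acids (eAAs), so a consumer's eAA δ¹³C pattern is inherited from the
basal resource that produced them. After per-sample mean-centering
(which removes baseline offsets, leaving only the multivariate
pattern), consumers are classified against a plant/bacteria/fungi
endmember library with a from-first-principles linear discriminant
analysis, validated by leave-one-out cross-validation.

**Bayesian mixing.** Mean-centered values of the three informative
tracers (Leu, Phe, Val) are modelled as convex mixtures of the source
fingerprints, y_ij ~ N(Σₖ pₖ μ_jk, √(Σₖ pₖ² σ_jk² + σ²_res,j)), with an
independent proportion vector on the simplex per species × litter cell,
a Dirichlet(1,1,1) prior, and random-walk Metropolis sampling in
isometric log-ratio coordinates. Convergence is accepted only when
every split Gelman–Rubin R̂ < 1.05.

**PLFA.** Marker fatty acids (18:2ω6,9 fungal; i15:0, a15:0, i16:0,
i17:0 Gram⁺; cy17:0, cy19:0, 16:1ω7, 18:1ω7 Gram⁻) are summed per
sample after a strict 0.2 mol% filter; total abundance is reported
over all detected acids, plus the fungal:bacterial ratio.

## Worked example

Simulate a full-factorial study (4 litter treatments × 5 earthworm
species × 5 replicates), estimate trophic positions, then apportion
basal resources:

```sh
isotroph simulate --out demo --seed 42
isotroph tp  --input demo/consumers_d15n.csv --out tp.csv --draws 10000 --seed 1
isotroph mix --sources demo/sources_d13c.csv --consumers demo/consumers_d13c.csv \
             --out mix --seed 1 --fast
```

Mean TP per litter treatment (from `tp.csv`):

```
                  tp_point  tp_mc_sd
horse_manure          2.41      0.33
legume                2.16      0.28
rape                  1.90      0.27
wheat_straw           2.63      0.36
```

TP ≈ 2 means a primary decomposer (feeding directly on plant detritus);
TP ≈ 3 a secondary decomposer (feeding on microbially reworked
material). The generator's truth decreases from 2.6 (wheat straw) to
2.0 (rape), and the estimates recover that gradient; `tp_mc_sd`
reflects the literature uncertainty in β and TDF.

Posterior mean diet proportions per litter (from `mix.summary.csv`,
averaged over species; the sampler reports acceptance ≈ 0.30 and
max R̂ = 1.006, inside the <1.05 acceptance rule):

```
                  bacteria  fungi  plant
wheat_straw           0.62   0.17   0.20
horse_manure          0.57   0.11   0.31
legume                0.39   0.11   0.50
rape                  0.32   0.08   0.60
```

The plant energy channel strengthens with litter quality (configured
truth rises from 0.15 to 0.60) while the bacterial channel weakens —
the directional pattern the estimators are built to detect.

The same stages are available as library functions
(`isotroph.tp_with_uncertainty`, `isotroph.fit_lda`,
`isotroph.fit_mixing_model`, `isotroph.plfa_summary`, ...) and as one
orchestrated run with a YAML config (`isotroph run --config run.yaml`),
which writes stage CSVs plus a manifest sufficient to reproduce the run
bit-identically.

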