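# pbomics

Integrated metabolomic–transcriptomic analysis of a dose–response toxicology
study, packaged as a tested, reusable pipeline.

## The problem

Non-genotoxic carcinogens such as phenobarbital leave no DNA-damage
signature, so their early effects must be read from molecular profiles
instead. The classic study design doses rats at 0/50/500/1000 ppm, samples
liver and plasma at days 1, 3, 7 and 14 (five animals per cell), and
profiles each animal twice: ¹H-NMR spectra of tissue extracts (metabolome)
and microarray expression (transcriptome). `pbomics` implements the complete
analysis chain for such a study:

* **Spectral processing** — integration of spectra into fixed-width
  chemical-shift buckets (0.01 ppm over 0.20–9.95 ppm for liver extracts,
  water region excluded), constant-sum normalization of every spectrum to a
  total integral of 10 000, and renormalization with dominant glucose and
  glycogen resonances removed.
* **Chemometrics** — PCA and NIPALS partial least squares with Pareto or
  unit-variance scaling. Model quality is the cross-validated predictive
  ability **Q² = 1 − PRESS/SS**, computed by excluding every 7th sample; a
  model is trusted only if its Q² exceeds every Q² obtained after randomly
  permuting the response, and leave-out dose prediction is provided as a
  second check.
* **Expression cascade** — per-array normalization to mean 500, flooring and
  per-gene median normalization, the detection filter (≥ 3 Present flags and
  ≥ 3 samples at intensity ≥ 90), the 1.5-fold change filter against
  time-matched controls, two-way ANOVA (dose × day) with Benjamini–Hochberg
  FDR < 0.05, control-normalized expression ratios, and hierarchical
  clustering on 1 − Pearson correlation.
* **Integration** — (i) pathway overlay: flag pathways where both a
  transcript and a metabolite changed; (ii) data fusion: for each metabolite,
  a PLS1 model with the transcriptome as the X-block and the metabolite as
  the response, accepted when Q² > 0.40 **and** the real Q² beats 30
  Y-permutation refits; the first component's weights, ranked by magnitude,
  name the most strongly co-varying transcripts.
* **Endpoint statistics** — one-way ANOVA with two-sided Dunnett many-to-one
  comparisons (computable directly from printed mean ± SD summaries), percent
  changes, and the per-fatty-acid / per-headgroup tally of changed lipid
  species.
* **Synthetic data** — a generator that emulates the full study with planted
  ground truth (dose-dependent glycogen/glucose decreases, succinate
  increase, Table-style expression fold changes, gene–metabolite links with
  exact target correlations), so every stage is testable without any
  download.

## Worked example

```python
import pbomics as pb

design = pb.make_design(n_rep=5, seed=1)          # 80 samples, 4 doses x 4 days
truth = pb.default_ground_truth(seed=1)
spectra = pb.simulate_spectra(design, truth)

table = pb.normalize_total(
    pb.bucket_spectra(spectra, pb.SCHEME_PRESETS["liver_extract"])
)
frame = design.to_frame()
ids = frame.index[frame["day"] == 14]
q2, _ = pb.q2_cv(
    table.data.loc[ids].to_numpy(),
    frame.loc[ids, "dose_ppm"].to_numpy(float),
    n_components=1,
    x_scaling=pb.ScalingSpec(center=True, mode="pareto"),
)
print(f"day-14 dose model Q2 = {q2[0]:.2f}")

conc = pb.metabolite_concentrations(design, truth)
expr, flags = pb.simulate_expression(design, truth, n_null_genes=500,
                                     metabolite_table=conc)
res = pb.fuse_metabolite(expr.T, conc["succinate"], pb.FusionConfig(seed=1))
print(f"succinate fusion: Q2 = {res.q2:.2f}, passed = {res.passed}")
print("top correlates:", res.top_transcripts(3))
```

prints

```
day-14 dose model Q2 = 0.64
succinate fusion: Q2 = 0.60, passed = True
top correlates: ['Alas1_aminolevulinate_synthase', 'Cyp2b2',
 'Ephx1_epoxide_hydrolase']
```

The dose model's Q² of 0.64 sits in the range typical of a strong
metabolomic dose response; the fusion model passes both acceptance hurdles
and correctly places the planted aminolevulinate-synthase probeset — the
heme-synthesis enzyme whose induction tracks hepatic succinate — at the top
of the loading ranking.

A command-line interface mirrors the library
(`pbomics simulate|bucket|pls|filter-genes|fuse|enrich|overlay|`
`report-endpoints|tally-lipids|run`); `pbomics run --seed 1 --out run_dir`
executes every stage and writes a reproducible, config-hashed run directory.

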