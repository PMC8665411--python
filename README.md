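# lfqdiff

Label-free quantitative differential abundance for proteomes and
ubiquitylomes, starting from peptide extracted-ion-chromatogram (XIC)
tables.

`lfqdiff` is aimed at proteomics analysts running E3-ligase substrate
screens (and similar two-condition label-free comparisons): given a
long-format peptide quantification table exported downstream of the search
engine, it sums fraction XICs, merges technical replicates, normalizes,
removes outlier peptides, tests every protein or ubiquitylation site with
a peptide-adjusted linear model, selects substrate candidates, and
integrates candidate lists across experiments — a whole proteome, a
diGly-remnant site-level ubiquitylome, and a pan-ubiquitin protein-level
ubiquitylome. A synthetic-data generator with known ground truth makes
every stage testable end to end.

## The model

For one feature (a protein, or a ubiquitylation site `PROT_K<pos>`), with
peptides *p*, conditions *c* ∈ {a, b} (a = reference, e.g. parental cells;
b = perturbed, e.g. ligase knock-out) and biological replicates *r*, the
log2 intensities are modeled by fixed-effects least squares:

```
log2 x_{p,c,r} = μ + β_p + δ·1[c = b] + ε,   ε ~ N(0, σ²)
```

The peptide effects β_p absorb ionization-efficiency differences between
peptides; biological replicates enter as independent observations. δ is
the log2 fold change (b over a); its two-sided p-value comes from the t
distribution with the residual degrees of freedom, and p-values are
adjusted across features with the Benjamini–Hochberg step-up procedure.
For a single-peptide feature the model reduces exactly to a two-sample
equal-variance t test.

Before fitting, log2 intensities are median-and-scale normalized per
biological replicate over the total signal, and outlier peptides are
removed within each (feature, condition) cell by Tukey's fences
(`[Q1 − k·IQR, Q3 + k·IQR]`, k = 1.5) applied to peptide-centered
residuals. Features observed in only one condition skip the model and are
carried as condition-specific candidates.

Candidates satisfy, with the default thresholds: fold change ≥ 2 in the
expected direction (increase of protein abundance, decrease of
ubiquitylation, when the ligase is inactive), BH-adjusted p ≤ 0.05, and at
least one peptide identified in ≥ 3 biological replicates of either
condition. Site-level candidate sets are collapsed to proteins before
cross-experiment intersections.

## Worked example

```python
from lfqdiff import (RunConfig, make_builtin_designs, run_differential,
                     select_candidates, simulate_experiment)
from lfqdiff.simulate import TruthParams

design = make_builtin_designs()["panub"]          # 4 vs 8 replicates, protein level
params = TruthParams(n_features=300, frac_changed=0.03,
                     log2fc_changed=-2.0, seed=42)
table, truth = simulate_experiment(design, params)
results = run_differential(table, RunConfig())
print(results.loc[results["adj_p"] < 0.05,
                  ["feature_id", "log2_fc", "adj_p", "n_peptides_used"]]
      .head(5).to_string(index=False))

cset = select_candidates(results, RunConfig(direction="decrease"), "panub")
print(f"{len(cset)} candidates of {len(results)} quantified proteins")
print("condition-specific among them:", cset.specific_member_ids)
```

prints

```
feature_id   log2_fc        adj_p  n_peptides_used
    P00045 -1.829946 2.377056e-08                3
    P00051 -1.908412 6.263174e-19                7
    P00076 -1.992269 2.218576e-20                7
    P00102 -1.915983 7.641237e-05                2
    P00153 -2.204383 1.521761e-10                3
11 candidates of 300 quantified proteins
condition-specific among them: ['P00015', 'P00140']
```

`log2_fc` is the estimated log2 ratio of the knock-out over the reference
condition (−2 means a 4-fold loss of ubiquitylation), `adj_p` the
BH-adjusted significance of that change, and the candidate set contains
the proteins passing all three criteria — here including two proteins
quantified only in the reference condition, which carry no p-value and
enter on the detection filter alone.

The same flows are available from the shell:

```
lfqdiff simulate --design digly --seed 1 --out digly.tsv --truth truth.tsv
lfqdiff quantify --in digly.tsv --design digly --out digly_results.tsv
lfqdiff run --design panub --simulate --seed 1 --direction decrease --out run/
lfqdiff integrate --results prot.tsv --results digly_results.tsv \
    --labels proteome --labels digly \
    --directions increase --directions decrease --out report/
```

Input tables are TSV with columns `protein_id gene_symbol peptide_key
is_proteotypic gg_positions condition bio_rep tech_rep fraction xic`
(`gg_positions` semicolon-joined 1-based residue positions, blank or `NA`
for a missing intensity).

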