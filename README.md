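# redoxquant

Dual-label redox proteomics analysis: quantifying cysteine oxidation
against protein abundance from isobaric reporter-ion intensities.

## The problem

Reversible oxidation of cysteine thiols (disulfides, sulfenic acids,
S-nitrosylation, glutathionylation) is a core regulatory mechanism in plant
stress signalling. A thiol-reactive isobaric tag (iodoTMT, reporters m/z
126–131) quantifies the oxidized-cysteine pool of each peptide across a
6-plex control/treatment time course — but a change in that signal confounds
two causes: a genuine shift in thiol redox state, and a change in the amount
of the parent protein. Labeling the same samples with an amine-reactive tag
(iTRAQ, reporters m/z 113–118) measures total protein abundance in the same
runs, so the two causes can be separated statistically.

`redoxquant` implements that separation as a tested, reusable pipeline for
peptide-spectrum-match (PSM) tables: normalization of reporter intensities,
treated/control fold changes per biological replicate, per-timepoint t-tests,
a redox-vs-abundance classification for every labeled cysteine peptide, and
hierarchical clustering of the resulting log2 fold-change profiles. A
synthetic-data generator with planted effects provides ground truth for
validating the whole chain, and a small chemistry helper computes the
HCO3−/CO2 speciation of a bicarbonate treatment medium.

## Model and statistics

For each labeled cysteine peptide and timepoint t ∈ {5, 30, 120} min, let
R_pep(t, r) be the iodoTMT treated/control ratio in replicate r and
R_prot(t, r) the parent protein's iTRAQ ratio. After per-replicate
normalization (channel-median equalization for iodoTMT, 113-anchored total
scaling for iTRAQ, protein rollup by median of PSM-summed peptides, and a
second normalization of every ratio slice to median 1):

* **peptide test** — one-sample two-tailed t-test of log2 R_pep(t, ·)
  against 0;
* **protein test** — the same on log2 R_prot(t, ·);
* **comparison test** — two-sample t-test between log2 R_pep(t, ·) and
  log2 R_prot(t, ·).

A peptide is **redox_responsive** if some significant peptide timepoint
(p < α, observed in ≥ 2 replicates) is *not* explained by a significant,
same-direction protein change with a non-significant comparison test;
**abundance_driven** if every significant timepoint is so explained; and
**unchanged** otherwise. Zero-variance samples conservatively receive p = 1.

Fold-change profiles are clustered agglomeratively with distance
1 − uncentered correlation and average linkage (centered Pearson, Euclidean,
complete and single linkage available), with deterministic tie-breaking and
export to Newick and Cluster-3.0-style CDT/GTR files.

## Worked example

```python
from redoxquant import (
    RedoxQuantModel, generate_psm_dataset, scenario_presets,
)

psmset, truth = generate_psm_dataset(scenario_presets()["mixed"])
results = RedoxQuantModel(psmset).fit(alpha=0.05, min_reps=2)
print(results.summary())
```

```
Dual-label redox discovery summary
==========================================
PSMs read                     1059
distinct peptides              178
unique (single-protein)        178
proteins                        60
Cys-containing peptides         86
iodoTMT-labeled peptides        86  (100%)
tested (quantified)             86
------------------------------------------
alpha = 0.05, min replicates = 2
redox_responsive                19
abundance_driven                11
unchanged                       56
```

The `mixed` scenario plants ten pure-redox peptides (2-fold oxidation at
30 min) and five pure-abundance proteins (0.5-fold across the course) among
nulls, with log2-scale reporter noise of 0.1. All ten planted redox peptides
appear among the `redox_responsive` calls and every labeled peptide of the
abundance-only proteins is called `abundance_driven` (the remaining
`redox_responsive` calls reflect the nominal per-test error rate of raw
p < 0.05 testing over three timepoints — pass `bh=True` to `fit` for
Benjamini–Hochberg control).

Clustering the packaged 47-peptide reference fold-change table:

```python
from redoxquant import (
    cluster_sizes, cut_tree, hierarchical_cluster,
    load_table1_fixture, log2_profile_matrix,
)

matrix = log2_profile_matrix(load_table1_fixture())          # 47 x 3
tree = hierarchical_cluster(matrix)                          # uncentered/average
print(cluster_sizes(cut_tree(tree, 2)))                      # [42, 5]
```

The treatment-medium chemistry:

```python
from redoxquant import CarbonateConditions, carbonate_speciation
hco3, co2 = carbonate_speciation(CarbonateConditions(3.0, pH=5.8))
# [HCO3-] = 0.66 mM, [CO2] = 2.34 mM   (pH below pK1 = 6.352)
```

A command-line interface wraps the same functionality:

```sh
redoxquant simulate --preset mixed --seed 7
redoxquant discover --psm psms.tsv --alpha 0.05 --min-reps 2
redoxquant cluster --input fold_changes.tsv --k 2
redoxquant run --preset mixed --seed 7 --outdir out/
```

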