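# Methods

## Study design the package assumes

One experiment is a 6-plex control/treatment time course measured twice in
the same MS runs: a thiol-reactive isobaric label (iodoTMT) reports the
*oxidized*-cysteine pool of each peptide, and an amine-reactive label
(iTRAQ) reports total peptide/protein abundance. Controls at 5/30/120 min
carry iodoTMT reporters 126/128/130 and iTRAQ 113/115/117; treated samples
carry 127/129/131 and 114/116/118. Three biological replicates are three
independent 6-plex runs sharing the same underlying fold changes; reporter
intensity scales are not comparable across replicates, so every
normalization is computed within one replicate.

The chemistry is a reverse-labeling scheme: free thiols are blocked during
extraction (NEM), reversibly oxidized thiols are then reduced (TCEP) and
labeled. An *increase* in a treated iodoTMT channel therefore means more
oxidation; a decrease means net reduction. Because the label sits on the
protein before digestion, the iodoTMT signal scales with protein amount as
well as oxidation state — the confound the dual labeling resolves.

## Quantification

1. **Unique peptides only.** Peptides mapping to more than one protein
   accession are kept in the data model but excluded from quantification.
2. **PSM summation.** Repeated PSMs of the same modified peptide are summed
   per channel within a replicate before anything else.
3. **iodoTMT normalization.** Within a replicate, each of the six channels
   is scaled so its median over unique labeled cysteine peptides equals the
   grand median of the six channel medians. Channel medians (not per-row
   scaling) preserve treated/control ratio structure; a channel with no
   observations is left unscaled and flagged.
4. **iTRAQ normalization.** Within a replicate, each channel's total over
   unique peptides observed in channel 113 is scaled to the 113 total.
5. **Protein rollup.** Per protein and channel, the median over its
   peptides' summed intensities; a single-peptide protein keeps that
   peptide's value.
6. **Ratios.** Treated/control per timepoint and replicate from the channel
   design; missing wherever either side is missing, flagged when a control
   intensity is non-positive.
7. **Second normalization.** Every (timepoint, replicate) slice of fold
   changes is divided by its median, for both label spaces (a constructor
   flag disables either). This recentres each slice at median 1 and is what
   restores exact calibration after the total-sum iTRAQ scaling, which
   otherwise spreads a genuine abundance change across all channels.

Medians of even-sized sets are the mean of the two central values. Missing
observations never enter a median or total; zero and blank intensity cells
are both treated as missing because reporter interference makes true zeros
unobservable. No imputation, no isotopic-impurity or co-isolation
correction is applied (ratio compression is a known attenuation of isobaric
ratios; the pipeline relies on statistical testing rather than fixed
fold-change cut-offs, and the simulator exposes an optional linear
compression factor for sensitivity checks).

## Testing and classification

Replicate-level fold changes are the test units. Per peptide and timepoint:
a one-sample two-tailed t-test of the log2 fold changes against 0; the same
per protein on iTRAQ ratios; and a pooled-variance two-sample t-test
between peptide and protein log2 fold changes (Welch form behind a flag —
with strongly unequal variances and n = 3 per side the pooled test is
mildly anticonservative, which slightly inflates comparison-test rejections).

Conventions chosen for small-n robustness:

* p is undefined with fewer than two replicates; undefined p counts as
  non-significant and is flagged.
* A sample whose log2 spread is below 1e-9 is treated as zero-variance and
  receives p = 1 (flagged `degenerate-variance`), never p = 0: duplicated
  or saturated values and ulp-level normalization jitter must not create
  certainty. The two-sample analogue returns p = 1 whether or not the two
  degenerate means coincide.
* Significance requires p < α *and* the ratio observed in at least
  `min_reps` (default 2) replicates, applied per timepoint.
* No multiple-testing correction by default; Benjamini–Hochberg is
  available via `fit(bh=True)` and is applied separately to the peptide and
  protein p-value families.

Classification: a significant peptide timepoint is *explained by abundance*
when the protein change at that timepoint is significant, has the same sign
of mean log2 fold change, and the comparison test is not significant. A
peptide with at least one unexplained significant timepoint is
`redox_responsive`; with all significant timepoints explained,
`abundance_driven`; with none, `unchanged`. An opposite-direction protein
change cannot explain a peptide change and therefore counts as redox
evidence. The `protein-level-change-detected` flag is set whenever any
protein timepoint is significant. The comparison test is per-timepoint (not
pooled across the course), matching the per-timepoint decoy narrative it
implements.

## Clustering

Profiles are log2 fold changes over three timepoints, so shape matters more
than magnitude. The default distance is 1 − uncentered correlation with
average linkage: the uncentered form is the classic default of the
Cluster 3.0 tool this output format targets, and with only three columns
the centered Pearson correlation discards one of two remaining degrees of
freedom. On the packaged 47-peptide reference table this default
reproduces the published two-cluster structure (42 + 5); centered Pearson
yields 44 + 3 instead, which is why uncentered is the default rather than
the more common centered form. Centered Pearson and Euclidean distance,
and complete/single linkage, are exposed as options.

Agglomeration is an explicit O(n³) Lance–Williams loop with a fully
specified tie-break (smallest node indices merge first), so trees are
deterministic and row-order invariant; the test suite cross-checks heights
and all flat cuts against an independent implementation. A zero-variance
row has no centered correlation; pairs involving one fall back to the
uncentered form and the tree is flagged. Cutting at k removes the k − 1
highest merges; cluster ids are ordered by descending size, then by first
appearance in leaf order. Exports: Newick, and CDT/GTR files whose GTR
similarity column is 1 − merge height.

## Synthetic data

The generator emulates the statistical structure the analysis assumes — it
is the ground-truth instrument for the test suite, not a spectrum
simulator. Per replicate and PSM, a base abundance is drawn log-normally
(log2 sd 1.0 around a 1e5 baseline); a control channel reads
base × 2^N(0, σ); a treated channel additionally multiplies in the planted
linear fold changes for its timepoint — oxidation × abundance for iodoTMT,
abundance alone for iTRAQ. Channel noise is independent multiplicative
log-normal (no co-isolation model; an optional linear compression factor
attenuates observed fold changes toward 1). Channels drop out independently
with a configurable probability, except that a PSM always retains at least
one iTRAQ reporter. Sequences are random tryptic-like peptides (8–16
residues, C/K/M excluded from the first position so lowercase-marked
annotations round-trip); with the defaults half the peptides contain a
cysteine and 29% of those carry the iodoTMT label, the labeling rate the
reverse-labeling chemistry typically achieves. Everything is driven by one
seeded generator: identical seeds give byte-identical PSM tables.

Named scenarios (`scenario_presets()`): `null` (σ = 0, no effects),
`null_noisy` (σ = 0.2, ~2000 labeled peptides, for false-positive-rate
calibration), `glp_like` (a protein whose abundance falls 0.76/0.75/0.95
across the course with no oxidation — the abundance-driven decoy; σ = 0.05
and 3–5 peptides per protein so the protein-level drop is reliably
detectable), `nr_like` (exactly one peptide oxidized 1.51-fold at 30 min),
and `mixed` (ten 2-fold oxidations at 30 min plus five 0.5-fold abundance
proteins, σ = 0.1). Scenario sizes (40–60 proteins, 500 for the noisy null)
are chosen so the full suite exercises every code path in seconds.

What passing these tests shows — and does not. Recovery and error rates on
this generator validate the arithmetic and the decision logic under the
model's own assumptions (log-normal noise, independent channels, planted
truth). Real data additionally contain co-isolation ratio compression,
correlated channel noise, charge-state and missed-cleavage redundancy, and
search-engine identification error, none of which are simulated; absolute
power figures on synthetic data therefore do not transfer to instruments.

## Treatment chemistry

The bicarbonate/CO2 partition of the treatment medium follows
pH = pK1 + log10([HCO3−]/[CO2]) with pK1 = 6.352 (first dissociation of
carbonic acid). At 3 mM total carbonate and pH 5.8 this gives
[CO2] = 2.34 mM and [HCO3−] = 0.66 mM — below pK1 the majority species is
dissolved CO2. Published descriptions of this medium sometimes attach the
two numbers to the opposite species; the implementation follows the
equation, and the numeric pair is unchanged either way.

## Known limitations

* Cysteine sites are reported peptide-relative; mapping to protein
  coordinates needs the protein database and is out of scope.
* The iodoTMT chemistry cannot distinguish which reversible oxidation
  produced a labeled thiol.
* Protein inference is unique-peptide assignment only; shared peptides are
  parsed but never quantified.
* The PSM table dialect is this package's documented TSV; vendor binary
  exports must be converted upstream.
* With n = 3 replicates the variance estimates behind every test are
  themselves noisy; borderline p-values near α flip easily between seeds,
  and classification inherits the nominal error rates of raw p < 0.05
  testing unless `bh=True` is used.
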