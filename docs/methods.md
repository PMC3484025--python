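# Methods

This note documents the statistical model behind `eqtlenrich`, the
parameter defaults and why they are what they are, what the synthetic-data
generator does and does not emulate, and the numerical and design choices
made where conventions differ.

## The enrichment test

**Data.** Three inputs, all delimited text: a SNP universe (the array
manifest: rsid, chromosome, 1-based position, minor allele frequency), one
or more GWAS hit lists (rsid, association P; filtered at the inclusion
threshold at read time), and one raw eQTL association table per tissue
(rsid, target gene, probe chromosome/position, association P).

**eQTL determination.** Each SNP-probe association is classified *cis*
when the SNP lies on the probe's (normalized) chromosome within the cis
window, *trans* otherwise — cross-chromosome pairs are always trans.  The
window is inclusive (distance ≤ 4,000,000 bp): "within 4 Mb" is read at
face value, and the boundary case is vanishingly rare in practice.
Significance is strict: cis at *p* < `cis_alpha`, trans at
*p* < `trans_alpha_numerator / n_probes`, the Bonferroni correction over
the expression panel.  The probe coordinate is taken as given; whether it
marks the probe start or midpoint is the data provider's convention and
shifts the window by at most a probe length, which is negligible against
4 Mb.

**The statistic.** The observed count is the number of *distinct* hit SNPs
with at least one significant eQTL in the tissue.  Counting distinct SNPs
(not SNP-gene pairs) is the only convention under which a multi-gene
regulator contributes once, which is how such counts are conventionally
reported; the identical rule scores every null set.

**The null.** Null sets are drawn from the universe, not from the eQTL
table, and are matched on MAF: SNPs are binned at 5% intervals
(left-closed bins `[0,0.05), …, [0.45,0.5]`, top bin closed so MAF = 0.5
is representable), and each null set reproduces the hit list's per-bin
tallies exactly — this is asserted structurally on every fit.  Sampling is
without replacement *within* a set; the same SNP may recur across sets,
and observed hits are not excluded from the frame (excluding them would
bias the null slightly anticonservative and is not part of the matched
design).  Hits absent from the manifest are excluded from the observed
count, since they can never appear in a null set; they are logged.

**The P-value.** The proportion of null sets whose count matches or
exceeds the observed count.  No pseudo-count is added; a zero-exceedance
result is stored as 0.0 and displayed as `<1/N`.  The estimator is the
plain Monte-Carlo tail proportion, so its resolution is 1/N and its
standard error √(p(1−p)/N).

Each analysis × tissue combination is tested independently with its own
null; no cross-tissue multiplicity correction is applied, mirroring how
these analyses are reported.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `n_null_sets` | 1000 | sets | resolution 10⁻³, the customary reporting scale |
| `bin_width`, `n_bins` | 0.05, 10 | MAF fraction | 5% intervals tiling (0, 0.5] |
| `cis_window_bp` | 4,000,000 | bp | the cis definition used by the eQTL panels consumed here |
| `cis_alpha` | 10⁻⁴ | – | the panels' corrected cis threshold |
| `trans_alpha_numerator`, `n_probes` | 0.05, 25,834 | – | Bonferroni over the expression panel |
| `gwas_p_threshold` | 10⁻³ | – | the sub-significant-tail inclusion rule |

All are overridable through `EnrichmentConfig` (YAML-serialisable); the
thresholds travel with the eQTL panel and should be changed together with
it.

The Fisher gene-overlap tests need a gene universe the paper-style reports
rarely state.  The default is the number of distinct genes appearing in
the raw eQTL tables (the testable panel); pass `gene_universe_size`
explicitly when the platform's gene count is known — the P-values depend
on it directly.  The two-sided P is the sum of probabilities of all tables
no more likely than the observed one (the `scipy` convention), stated
here because two-sided conventions for Fisher's test differ.

## The synthetic generator

`simulate_study` emulates the data-generating assumptions the test relies
on, not a real genome:

* **Universe** — 22 autosomes of 250 Mb, positions uniform, MAF uniform on
  [0.01, 0.5] by default (a beta option exists).  The uniform default
  exercises all ten MAF bins roughly equally, which is the property the
  matched null cares about; real array MAF spectra are skewed but the test
  conditions on the bins, so the spectrum's shape does not change the
  null's validity.  The default universe is 50,000 SNPs — the scale at
  which the statistical validation suite runs; real arrays are one to two
  orders larger, and nothing in the code depends on the scale.
* **eQTL maps** — each SNP is independently a significant eQTL per tissue
  at base rate `eqtl_base_rate` (default 0.05, scalar or per-MAF-bin).
  Significant rows get a cis (probability `cis_fraction` = 0.58, matching
  the observed single-target cis share) or trans placement with
  probe coordinates consistent with the class, and a P-value log-uniform
  between 10⁻¹² and the class threshold; with probability
  `multi_gene_rate` = 0.16 a second target is added.  Unflagged SNPs get
  decoy rows with P log-uniform between the class threshold and 1, so the
  significance boundary is exercised from both sides; the exact P
  distributions are irrelevant to the binary statistic.  Gene labels are
  2 Mb locus blocks, so clustered cis signals implicate the same gene —
  giving the multiply-implicated-gene pattern real studies show.
* **Hit lists** — sequential weighted sampling without replacement
  (exponential-keys construction), weight θ = `enrichment_multiplier` for
  SNPs that are eQTLs in the designated tissues (default: the non-LCL
  tissues) and 1 otherwise.  θ = 1 reduces exactly to simple random
  sampling; for small lists the expected hit-list eQTL fraction is
  θq/(θq+1−q).  Planting enrichment through the sampling weights keeps the
  eQTL annotation fixed, as in the real workflow where the eQTL map
  pre-exists the GWAS.  All four analysis lists are drawn from the same
  weighted frame, so they overlap the way non-independent GWAS strata do.

**What the generator does not emulate** — and therefore what passing
validation does not establish about real data: linkage disequilibrium
(real top-SNP lists are LD-clustered, so their effective sample size is
smaller and a SNP-level null is anticonservative in a way only an LD-aware
null would capture); eQTL sharing across tissues (tissue flags are
independent here); any dependence of eQTL status on annotation other than
MAF (e.g. distance to genes); genotype or expression noise (eQTL status is
generated as a clean binary).  The validation shows the machinery is
correct and calibrated under its own assumptions, not that those
assumptions hold for a given dataset.

## Validation

The test suite validates the pipeline at three levels (sizes chosen to
keep the full suite within a few minutes on one CPU):

* **Exactness** — on a 20-SNP universe with a 4-SNP hit list, the
  Monte-Carlo empirical P at N = 2000 is compared against exact
  enumeration of all bin-respecting subsets; Fisher's test is compared
  against direct hypergeometric-support enumeration for every 2×2 table
  with universe ≤ 40 plus a seeded sample up to 60.
* **Calibration** — across 200 replicate null datasets (θ = 1, 50,000-SNP
  universe, 500-SNP lists, 500 null sets) the rejection rate at α = 0.05
  must fall inside the exact binomial 99% band, and the null P-values must
  pass a Kolmogorov–Smirnov uniformity check at the 1% level.
* **Power** — at θ = 4 the same design rejects essentially always
  (the closed-form hit-list eQTL fraction 4q/(4q+1−q) ≈ 0.174 against a
  null mean of q = 0.05 gives a ~9-sigma separation).  Note that at these
  design points the median empirical P saturates the 1/N Monte-Carlo
  floor already at θ = 2, so medians separate the null from enrichment
  but cannot rank strong enrichments against each other; the rejection
  rate can.

## Numerical and degenerate-input choices

* MAF bin assignment adds 10⁻⁹ before flooring so exact multiples of the
  bin width (0.05, 0.30, …) land in their left-closed bin despite binary
  rounding of the quotient.
* Null sampling within a bin uses rejection sampling of k-tuples when
  k² ≤ bin size (redrawing rows containing duplicates) and the
  random-keys order-statistics construction otherwise; both draw uniform
  k-subsets, the switch is purely a cost trade-off.  One master
  `numpy` generator seeded per fit drives all sets; sets are independent
  and runs are bit-reproducible given the seed.
* P-values of exactly 0 in input files are rejected, not clamped — they
  signal an upstream problem that clamping would hide.
* An empty eQTL table is valid: observed count 0, all null counts 0,
  empirical P 1.  An empty hit list yields an all-zero bin profile and
  empty null sets.  An infeasible bin (universe too small to match the
  profile) raises an error naming the bin and the deficit.
* Gene rankings break ties lexicographically; percentages are reported
  rounded to the nearest integer alongside the exact fractions.
* "Unique eQTL SNPs" are distinct rsids pooled across tissues and
  analyses; distinct (rsid, gene) pairs are tallied separately and
  labelled as such.

## Known limitations

* No LD-aware null, no proxy/tagging lookup, and no matching on
  covariates other than MAF (distance-to-gene matching is sometimes used
  as a post-hoc check; it is out of scope here).
* eQTL discovery itself (association of genotype dosages with expression,
  batch correction, imputation) is upstream of this package: the eQTL
  tables are consumed as given.
* Pathway over-representation and haplotype analyses are out of scope.
* The gene universe for overlap tests is a user responsibility; the
  default (genes in the supplied tables) is defensible but not canonical.
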