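# Methods

`lncfun` implements the guilt-by-association analysis chain used to
characterise long noncoding RNAs (lncRNAs) on small two-group expression
designs — typically a handful of case and control tissue arrays. This note
documents the statistical models, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the
numerical conventions.

## Differential expression

Input is a linear-scale intensity matrix (features × samples) with a
two-group design. After log2 transformation, each feature is tested with a
two-sided two-sample *t*-test on the log2 values — pooled-variance
(classic Student) by default, since small array studies conventionally
report "Student's t-test"; Welch's correction is available via
`equal_var=False` for unequal-variance designs.

The fold change is the ratio of the **anti-logged group means**
(`2^(mean log2 a − mean log2 b)`), folded to FC\_abs = max(ratio, 1/ratio),
not the mean of per-sample ratios. A feature is called differentially
expressed when **FC\_abs > 2.0 and p < 0.05, both strict inequalities**
(a feature at exactly 2.0-fold is not called). No multiple-testing
correction is applied to the calls — the convention this pipeline mirrors
thresholds raw p — but a Benjamini–Hochberg q-value column is emitted for
information.

Zero-pooled-variance features are degenerate: the statistic is undefined,
so they are reported with p = 1 and a `degenerate` flag, regardless of the
fold change.

Hierarchical clustering of features or samples uses distance
1 − Pearson correlation on standardized values with average linkage, the
common microarray default (neither metric nor linkage is canonical; both
are configurable at the scipy layer). Constant rows get distance 1 to
everything, with a warning.

## Co-expression

Every differentially expressed lncRNA is correlated with every
differentially expressed mRNA across **all** samples, both groups pooled
(within-group correlation at n = 3 per group is hopeless; pooling is also
what gives the screen its power, at the price of group-shift-driven
correlation — see the generator caveats below). The p-value of Pearson's r
uses the exact null transformation t = r·√(n−2)/√(1−r²) on n−2 degrees of
freedom.

An edge is retained when **|r| > 0.8 and p < 0.05, both strict**. At n = 6
samples the p filter binds: |r| = 0.8 gives p ≈ 0.056, so retention
effectively requires |r| > 0.811. Both filters are always applied
independently rather than collapsing to the binding one, so the behaviour
is correct at any sample count. Edge sign is the sign of r.

## Function prediction (guilt by association)

For each lncRNA, its co-expressed mRNAs form a query set, tested for
over-representation against GO/KEGG gene sets (GMT files) with the
hypergeometric upper tail P(X ≥ k) — the enrichment direction of the
cumulative distribution function. The universe is the set of measurable
mRNAs (those in the expression matrix), not the whole genome; this
restricts the null to genes the query could have contained. Sets are
intersected with the universe before testing.

Significance requires **p < 0.05 and BH FDR < 0.01**. BH adjustment runs
within one gene-set category at a time (GO\_BP / GO\_CC / GO\_MF / KEGG /
TF are separate families). Significant terms are assigned to the lncRNA as
its predicted functions, and a pooled "hit count" table ranks annotations
by how many lncRNAs received them.

## Cis and trans regulatory screens

**Cis**: a co-expression edge is a candidate cis regulation when the two
loci share a chromosome and are within 100 kbp. Distance is the gap
between nearest interval edges on 0-based half-open (BED) coordinates;
overlapping intervals have distance 0; the boundary is **inclusive**
(exactly 100,000 bp qualifies). Strand is ignored — the window covers both
sides of the lncRNA. A TSS-to-TSS mode exists behind `mode="tss"` for
users who prefer promoter distance; the interval-gap default is the more
permissive and more common reading.

**Trans**: for each lncRNA, its co-expressed mRNAs are tested against
transcription-factor regulons (TF target gene sets) with the same
hypergeometric machinery and the same p < 0.05 / FDR < 0.01 gate. Links
are ranked by "prediction reliability", operationalised as enrichment
p-value ascending with ties broken by overlap size descending, then names
(no canonical reliability score exists; the p-value is the natural
choice). The top 100 links form the lncRNA–TF network; the top 10 are
expanded with the co-expressed mRNAs inside each TF's regulon to form the
core lncRNA–TF–mRNA network. Networks are exported as SIF or edge-list
TSV with interaction types `coexp+`, `coexp-`, `cis`, `trans`, rows sorted
for byte-reproducible files.

## qPCR relative quantification

The 2^−ΔΔCt method: technical replicates are averaged per (sample, gene);
ΔCt = Ct(gene) − Ct(reference, e.g. GAPDH) within each sample; ΔΔCt is the
difference of group-mean ΔCt (case − control); fold change = 2^−ΔΔCt and
log2 fold change = −ΔΔCt exactly (positive = up in cases). The group
comparison p-value is a Student's t-test on per-sample ΔCt values —
averaging technical replicates first avoids pseudo-replication. Shifting
all of a sample's Ct values by a constant leaves every ΔΔCt unchanged
(normalisation invariance), which the suite asserts. Amplification-
efficiency correction (Pfaffl) is out of scope.

## The synthetic-data generator

The generator emulates the statistical structure of a 3-vs-3 lncRNA/mRNA
microarray comparison at desk scale (default 150 lncRNAs + 350 mRNAs), so
every downstream stage has a recoverable planted answer:

* **Intensities**: features live on the log2 scale, baseline ~ U[6, 14],
  Gaussian residual SD 0.25 (a typical post-normalisation array residual);
  the emitted matrix is the exponentiated linear scale. Gaussian-on-log2
  is a modelling choice, not a claim about any particular platform's noise.
* **Differential expression**: a fraction (default 0.1) of features gets a
  ±2 log2 shift between groups (the group-mean difference before noise is
  exactly the effect), direction random.
* **Co-expression modules**: blocks of DE lncRNAs and DE mRNAs share a
  per-sample latent factor with loading √module_r, giving expected
  pairwise correlation ±module_r (default 0.95). A member's loading sign
  equals its DE direction, so the latent-factor and group-shift
  contributions to the pooled-sample correlation never fight: the planted
  pair sign (product of member directions) is what the screen should
  recover. Members are drawn from the DE features because only DE features
  enter the co-expression stage.
* **Loci**: one chromosome per module. Per module, a subset of
  a lncRNAs × b mRNAs is packed into a span short enough that every cross
  pair's gap is ≤ 100 kbp ("cis cluster"); (a, b) is chosen so clustered
  pairs ≈ cis_fraction (default 0.5) of the module's planted pairs.
  Everything else is spaced ≥ 500 kbp apart, far beyond the window, so the
  planted geometry is exactly recoverable.
* **Gene sets**: one functional set per module (its mRNA members), one TF
  regulon per module (module mRNAs plus random fillers up to regulon_size,
  default 20), plus random decoy sets and decoy regulons.
* **qPCR**: target Ct values in the case group are shifted by −planted
  log2 FC (one doubling of template = one cycle), with per-sample loading
  offsets that cancel in ΔCt and per-replicate Gaussian noise. In the
  zero-noise limit the recovered fold change is bit-exact.

All randomness flows from one master seed through `SeedSequence` child
streams (structure / expression / loci / gene sets), so identical
(seed, config) gives byte-identical written files.

**What a green test does not establish.** The generator omits, among other
things: probe-level effects and normalisation artefacts, batch and
covariate structure, heavy-tailed or intensity-dependent noise,
correlation between non-module features beyond what the group shift
induces, and realistic genome geometry (gene density, strand bias). In
particular, with a 4-fold planted effect and 3 samples per group, *any*
two DE features correlate strongly across the pooled samples, so the
recovered edge set is much larger than the planted one; recovery tests
therefore assert recall and sign agreement on the planted pairs, not edge
precision — matching how such screens behave on real small-n data, where
co-expression edges number in the thousands.

## Numerical and policy choices

* All thresholds use the comparison stated next to them (strict for FC, r
  and the p/FDR gates; inclusive for the 100 kbp window).
* Ranking tie-breaks are total and documented (|r| desc, p asc, names;
  enrichment p asc, overlap desc, names), so outputs are reproducible.
* The hypergeometric tail is computed by `scipy.stats.hypergeom.sf`
  (log-space internally); the test suite verifies it against exhaustive
  enumeration of every draw for all N ≤ 12 to 1e−12.
* BH q-values come from `statsmodels` and are checked against hand-worked
  step-up examples. BH is *not* idempotent in general (e.g. p = (0.1, 0.8)
  gives q = (0.2, 0.8) but BH(q) = (0.4, 0.8)); the suite asserts the true
  invariants (q ≥ p, q ≤ 1, monotone in p-rank) instead.
* The packaged cis-regulation table (35 lncRNAs, 41 pairs, |r| > 0.8,
  5 negative) ships as a hand-transcribed TSV; the printed source table
  contains typesetting run-ons, and one duplicated fragment was resolved
  as an artifact (documented in the file header and flagged for review).

## Known limitations

* The DE stage assumes one row per feature; probe-to-gene collapsing and
  RMA-style normalisation are upstream of this package.
* Correlation across 6 pooled samples has enormous sampling variance; the
  |r| > 0.8 screen is a heuristic, not an inference procedure, and the
  pipeline faithfully reproduces that heuristic rather than improving it.
* Moderated (empirical-Bayes) tests, partial correlation, WGCNA-style
  soft thresholds, GO DAG propagation, and efficiency-corrected qPCR are
  deliberately out of scope.
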