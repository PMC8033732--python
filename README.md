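# lncfun

**Function prediction for long noncoding RNAs from small two-group
expression profiles.**

Long noncoding RNAs (lncRNAs) are transcripts longer than 200 nt with no
protein product. Most have no direct functional annotation, so the standard
way to characterise them on an expression study — for example a microarray
comparison of diseased vs healthy tissue with 3 samples per group — is
*guilt by association*: find the protein-coding mRNAs whose expression
tracks each lncRNA, and borrow their annotations. `lncfun` packages that
whole analysis chain as tested, reproducible library code plus a CLI:

1. **Differential expression** — per-feature Student's *t*-test on log2
   intensities; called when FC\_abs > 2.0 **and** p < 0.05 (strict), where
   FC\_abs = max(ratio, 1/ratio) of anti-logged group means. Unsupervised
   hierarchical clustering (1 − Pearson, average linkage) of the calls.
2. **Co-expression** — Pearson's r between every DE lncRNA and DE mRNA
   across all samples; edges kept when |r| > 0.8 **and** p < 0.05, with
   p from t = r·√(n−2)/√(1−r²) on n−2 df.
3. **Function prediction** — for each lncRNA, its co-expressed mRNAs are
   tested against GO/KEGG gene sets (GMT) with the hypergeometric upper
   tail P(X ≥ k); terms with p < 0.05 and BH FDR < 0.01 become the
   lncRNA's predicted functions.
4. **Cis regulation** — co-expressed pairs whose loci (BED) lie within
   100 kbp on the same chromosome (nearest-edge gap, boundary inclusive).
5. **Trans regulation** — lncRNAs whose co-expressed mRNAs overlap a
   transcription factor's regulon (same hypergeometric gate); the top
   links form lncRNA–TF and core lncRNA–TF–mRNA networks (SIF export).
6. **qPCR validation** — 2^−ΔΔCt relative quantification normalised to a
   reference gene (e.g. GAPDH), with direction concordance against the
   array calls.

A synthetic-data generator produces expression matrices, gene loci, gene
sets, TF regulons and qPCR Ct tables with *known planted ground truth*
(effects, correlated modules, cis geometry, regulons), so every stage is
validated by parameter recovery. See `docs/methods.md` for the models,
defaults and caveats.

## Worked example

Run the whole pipeline on simulated data (no inputs needed):

```sh
$ lncfun run --simulate --outdir demo --seed 7
annotated_lncrnas: 18
cis_n_lncrnas: 12
cis_n_mrnas: 26
cis_n_negative: 31
cis_n_pairs: 58
cis_n_positive: 27
cis_pairs: 58
coexpression_edges: 576
de_lncrnas: 18
de_mrnas: 32
qpcr_concordant: 6
qpcr_genes: 6
trans_links: 90
outputs in demo
```

Reading: of 500 simulated features (3 cases vs 3 controls), 18 lncRNAs and
32 mRNAs pass the FC > 2 / p < 0.05 screen; 576 lncRNA–mRNA pairs pass the
|r| > 0.8 / p < 0.05 co-expression screen; 58 of those pairs sit within
100 kbp on a shared chromosome (27 positively, 31 negatively correlated,
involving 12 distinct lncRNAs and 26 distinct mRNAs); 90 lncRNA–TF links
pass the trans screen; and all 6 simulated qPCR genes
agree in direction with the array calls. `demo/` contains per-stage TSVs
(`de.tsv`, `edges.tsv`, `cis.tsv`, `trans.tsv`, `annotations.tsv`,
`relquant.tsv`), SIF network files, and `manifest.json` with the config
hash and seed — rerunning with the same seed is byte-identical.

The first cis pairs found (`demo/cis.tsv`):

```
lncrna_id    mrna_id   chromosome  genomic_distance  r              p_value          sign
lnc-SIM0013  GENE0040  chr1        9267              -0.9940333529  5.329510709e-05  -
lnc-SIM0013  GENE0045  chr1        7408              -0.9987164896  2.470041328e-06  -
```

The same machinery as a library, for qPCR quantification:

```python
>>> from lncfun import generate_qpcr_cts, delta_delta_ct
>>> cts = generate_qpcr_cts(7, ["CXCL12", "GAPDH"], "GAPDH",
...                         {"CXCL12": 1.5}, ct_noise_sd=0.1)
>>> delta_delta_ct(cts, "GAPDH", "AR", "nonAR").round(3)
         delta_ct_AR  delta_ct_nonAR  delta_delta_ct  fold_change  log2_fold_change direction  p_value
gene_id
CXCL12         7.486           9.025          -1.538        2.904             1.538        up      0.0
```

A planted 1.5 log2 fold change is recovered as ΔΔCt = −1.538, i.e. a
2.9-fold increase in the case group.

Each stage also has its own subcommand (`lncfun simulate / de / coexpress /
enrich / regnet / qpcr`); run any of them with `--help`.

## Packaged reference table

`lncfun.load_cis_table_fixture()` returns the published cis-regulation
table (41 lncRNA–mRNA pairs over 35 lncRNAs, |r| > 0.8) from the
allergic-rhinitis nasal-mucosa microarray study the pipeline's thresholds
mirror (GEO accession GSE159415), useful as a realistic summary-level test
input for `summarize_network`.

## Acceptance script

`scripts/acceptance.py` re-runs the package's full computation from
scratch: it simulates a dataset from the given seed, executes every
pipeline stage, prints the per-stage counts, and writes the result JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
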