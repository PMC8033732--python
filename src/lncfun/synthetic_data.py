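"""Synthetic two-group expression data with known, recoverable ground truth.

The generator emulates the statistical structure of a small two-group lncRNA
microarray experiment (3 cases vs 3 controls) at desk scale:

* log-normal-style intensities — features are simulated on the log2 scale
  with baselines ~ U[6, 14] and Gaussian residuals, then exponentiated to a
  linear-scale matrix (the analysis scale after log2 transform is where the
  model lives);
* planted differential expression — a fraction of features receives a
  between-group log2 shift of ±``log2_effect`` (difference of group means
  before noise is exactly the effect);
* planted co-expression modules — blocks of differentially expressed
  lncRNAs and mRNAs share a per-sample latent factor with loading
  sqrt(module_r), giving expected pairwise Pearson correlation
  ±``module_r``; a member's loading sign equals its DE direction, so the
  latent-factor and group-shift contributions to the pooled-sample
  correlation never fight each other and the planted pair sign
  (product of member signs) is recoverable;
* planted cis geometry — a fraction of planted pairs is placed on a shared
  chromosome with an interval gap drawn uniformly from [0, 100000] bp; all
  other loci are spaced far beyond the 100 kbp window;
* TF regulons — one planted transcription-factor target set per module
  (module mRNAs plus random fillers) plus decoy regulons, so
  trans-regulation screening has known positives.

All randomness flows from one master seed through per-component
``numpy.random.SeedSequence`` child streams, so identical (seed, config)
yields byte-identical written files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import (
    ExpressionMatrix,
    GeneLociCatalog,
    GeneSetCollection,
    write_design,
    write_expression_matrix,
    write_gene_loci,
    write_gene_sets,
)

__all__ = ["SimConfig", "GroundTruth", "generate_dataset", "generate_qpcr_cts", "write_dataset"]

CIS_WINDOW = 100_000  # bp; the cis-regulation screening window
FEATURE_LEN = 1_000  # bp; simulated feature interval length
FAR_SPACING = 500_000  # bp; spacing that guarantees non-cis placement


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated microarray experiment.

    Defaults mirror the emulated study design: 3 samples per group, planted
    |log2 fold change| of 2 (i.e. 4-fold), log2-scale residual SD 0.25, and
    tight co-expression modules (r = 0.95).
    """

    seed: int = 0
    n_per_group: int = 3
    n_lncrna: int = 150
    n_mrna: int = 350
    de_fraction: float = 0.1
    log2_effect: float = 2.0
    noise_sd: float = 0.25
    n_modules: int = 5
    module_r: float = 0.95
    cis_fraction: float = 0.5
    n_tfs: int = 10
    regulon_size: int = 20
    group_labels: tuple[str, str] = ("AR", "nonAR")

    def __post_init__(self) -> None:
        for name in ("n_per_group", "n_lncrna", "n_mrna", "n_modules", "n_tfs", "regulon_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.de_fraction < 1.0:
            raise ValueError("de_fraction must be in [0, 1)")
        if not 0.0 <= self.module_r <= 1.0:
            raise ValueError("module_r must be in [0, 1]")
        if not 0.0 <= self.cis_fraction <= 1.0:
            raise ValueError("cis_fraction must be in [0, 1]")
        if self.log2_effect < 0:
            raise ValueError("log2_effect must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if len(set(self.group_labels)) != 2:
            raise ValueError("exactly two distinct group labels required")


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks.

    ``cis_pairs`` is always a subset of the (lncRNA, mRNA) projections of
    ``coexpressed_pairs``; every ID exists in the generated matrix.
    """

    de_features: dict[str, int]  # feature -> planted direction (+1 up in case group)
    coexpressed_pairs: set[tuple[str, str, int]]  # (lncrna, mrna, sign)
    cis_pairs: set[tuple[str, str]]
    tf_links: dict[str, frozenset[str]]  # planted TF -> regulon members
    trans_links: set[tuple[str, str]]  # expected (lncrna, tf) links
    modules: list[tuple[list[str], list[str]]] = field(default_factory=list)

    def pair_set(self) -> set[tuple[str, str]]:
        return {(l, m) for l, m, _ in self.coexpressed_pairs}


def _split_chunks(items: list[str], n_chunks: int) -> list[list[str]]:
    if not items:
        return [[] for _ in range(n_chunks)]
    idx = np.array_split(np.arange(len(items)), n_chunks)
    return [[items[i] for i in part] for part in idx]


def generate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, GeneLociCatalog, dict[str, GeneSetCollection], GroundTruth]:
    """Simulate one experiment.

    Returns the linear-scale expression matrix, the gene loci, a dict of
    gene-set collections keyed by category (``"GO_BP"`` functional sets and
    ``"TF"`` regulons), and the ground truth.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_expr, rng_loci, rng_sets = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    lnc_ids = [f"lnc-SIM{i + 1:04d}" for i in range(config.n_lncrna)]
    mrna_ids = [f"GENE{i + 1:04d}" for i in range(config.n_mrna)]
    features = lnc_ids + mrna_ids
    n_features = len(features)
    case, control = config.group_labels
    samples = [f"{case}_{j + 1}" for j in range(config.n_per_group)] + [
        f"{control}_{j + 1}" for j in range(config.n_per_group)
    ]
    design = {s: (case if s.startswith(f"{case}_") else control) for s in samples}
    is_case = np.array([design[s] == case for s in samples])

    # --- plant differential expression -------------------------------------
    n_de = int(round(config.de_fraction * n_features))
    de_idx = rng_struct.choice(n_features, size=n_de, replace=False) if n_de else np.array([], int)
    directions = rng_struct.choice([-1, 1], size=n_de)
    de_features = {features[i]: int(d) for i, d in zip(de_idx, directions)}

    # --- plant co-expression modules among the DE features -----------------
    de_lnc = [f for f in lnc_ids if f in de_features]
    de_mrna = [f for f in mrna_ids if f in de_features]
    modules: list[tuple[list[str], list[str]]] = []
    if config.module_r > 0 and de_lnc and de_mrna:
        lnc_chunks = _split_chunks(de_lnc, config.n_modules)
        mrna_chunks = _split_chunks(de_mrna, config.n_modules)
        modules = [(l, m) for l, m in zip(lnc_chunks, mrna_chunks) if l and m]

    coexpressed_pairs: set[tuple[str, str, int]] = set()
    for lncs, mrnas in modules:
        for l in lncs:
            for m in mrnas:
                coexpressed_pairs.add((l, m, de_features[l] * de_features[m]))

    # --- expression values on the log2 scale --------------------------------
    baseline = rng_expr.uniform(6.0, 14.0, size=n_features)
    log2 = np.tile(baseline[:, None], (1, len(samples)))
    for i, d in zip(de_idx, directions):
        shift = d * config.log2_effect / 2.0
        log2[i, is_case] += shift
        log2[i, ~is_case] -= shift

    loading = np.sqrt(config.module_r)
    residual = np.sqrt(1.0 - config.module_r)
    eps = rng_expr.normal(0.0, 1.0, size=(n_features, len(samples)))
    feat_pos = {f: i for i, f in enumerate(features)}
    in_module = np.zeros(n_features, dtype=bool)
    for lncs, mrnas in modules:
        z = rng_expr.normal(0.0, 1.0, size=len(samples))  # shared latent factor
        for f in lncs + mrnas:
            i = feat_pos[f]
            in_module[i] = True
            sign = de_features[f]
            log2[i] += config.noise_sd * (sign * loading * z + residual * eps[i])
    log2[~in_module] += config.noise_sd * eps[~in_module]

    matrix = ExpressionMatrix(
        values=pd.DataFrame(np.exp2(log2), index=features, columns=samples),
        feature_class=pd.Series(
            ["lncRNA"] * config.n_lncrna + ["mRNA"] * config.n_mrna, index=features
        ),
        scale="linear",
        design=design,
    )

    # --- loci: one chromosome per module; a "cis cluster" per module ---------
    # Per module, a subset of a lncRNAs x b mRNAs is packed into a span short
    # enough that every cross pair is within the 100 kbp window; (a, b) is
    # chosen so the total clustered pair count approximates cis_fraction of
    # the planted pairs. Everything else is spaced far beyond the window.
    cis_pairs: set[tuple[str, str]] = set()
    cursors: dict[str, int] = {}
    rows: list[tuple[str, str, int, int, str]] = []
    placed: set[str] = set()

    def _place(feature: str, chrom: str, start: int) -> int:
        strand = "+" if rng_loci.random() < 0.5 else "-"
        rows.append((feature, chrom, start, start + FEATURE_LEN, strand))
        placed.add(feature)
        return start + FEATURE_LEN

    def _cluster_size(n_l: int, n_m: int, wanted: int) -> tuple[int, int]:
        best, best_err = (0, 0), wanted  # (0,0) = no cluster
        for a in range(n_l + 1):
            for b in range(n_m + 1):
                pairs = a * b if (a and b) else 0
                err = abs(pairs - wanted)
                if err < best_err:
                    best, best_err = (a, b), err
        return best

    for mod_i, (lncs, mrnas) in enumerate(modules):
        chrom = f"chr{(mod_i % 22) + 1}"
        cur = cursors.get(chrom, 1_000_000)
        wanted = int(round(config.cis_fraction * len(lncs) * len(mrnas)))
        a, b = _cluster_size(len(lncs), len(mrnas), wanted)
        cluster = list(lncs[:a]) + list(mrnas[:b])
        if cluster:
            cis_pairs.update((l, m) for l in lncs[:a] for m in mrnas[:b])
            order = [cluster[i] for i in rng_loci.permutation(len(cluster))]
            k = len(order)
            # worst-case gap (first to last) = (k-2)*len + sum(gaps) <= window
            gap_budget = CIS_WINDOW - max(k - 2, 0) * FEATURE_LEN
            gap_max = gap_budget // max(k - 1, 1) if k > 1 else 0
            end = _place(order[0], chrom, cur)
            for f in order[1:]:
                gap = int(rng_loci.integers(0, max(gap_max, 1)))
                end = _place(f, chrom, end + gap)
            cur = end + FAR_SPACING
        for f in lncs + mrnas:
            if f not in placed:
                cur = _place(f, chrom, cur) + FAR_SPACING
        cursors[chrom] = cur
    for i, f in enumerate(features):
        if f not in placed:
            chrom = f"chr{(i % 22) + 1}"
            cur = cursors.get(chrom, 1_000_000)
            cursors[chrom] = _place(f, chrom, cur) + FAR_SPACING
    loci = GeneLociCatalog(
        pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "strand"])
        .set_index("name")
        .loc[features]
    )

    # --- gene sets: functional sets for modules, TF regulons, decoys --------
    func_sets: dict[str, frozenset[str]] = {}
    func_desc: dict[str, str] = {}
    for mod_i, (_, mrnas) in enumerate(modules):
        name = f"FUNC_MODULE{mod_i + 1}"
        func_sets[name] = frozenset(mrnas)
        func_desc[name] = f"planted functional annotation of module {mod_i + 1}"
    for j in range(max(5, config.n_modules)):
        name = f"FUNC_DECOY{j + 1}"
        members = rng_sets.choice(mrna_ids, size=min(config.regulon_size, len(mrna_ids)), replace=False)
        func_sets[name] = frozenset(members)
        func_desc[name] = "random decoy annotation"

    tf_sets: dict[str, frozenset[str]] = {}
    tf_desc: dict[str, str] = {}
    tf_links: dict[str, frozenset[str]] = {}
    trans_links: set[tuple[str, str]] = set()
    for mod_i, (lncs, mrnas) in enumerate(modules[: config.n_tfs]):
        tf = f"TF{mod_i + 1}"
        fillers = [m for m in mrna_ids if m not in mrnas]
        n_fill = max(0, config.regulon_size - len(mrnas))
        extra = list(rng_sets.choice(fillers, size=min(n_fill, len(fillers)), replace=False))
        regulon = frozenset(list(mrnas) + extra)
        tf_sets[tf] = regulon
        tf_desc[tf] = f"planted regulon covering module {mod_i + 1}"
        tf_links[tf] = regulon
        trans_links.update((l, tf) for l in lncs)
    for j in range(len(tf_links), config.n_tfs):
        tf = f"TF{j + 1}"
        members = rng_sets.choice(mrna_ids, size=min(config.regulon_size, len(mrna_ids)), replace=False)
        tf_sets[tf] = frozenset(members)
        tf_desc[tf] = "random decoy regulon"

    collections = {
        "GO_BP": GeneSetCollection(sets=func_sets, descriptions=func_desc, category="GO_BP"),
        "TF": GeneSetCollection(sets=tf_sets, descriptions=tf_desc, category="TF"),
    }
    truth = GroundTruth(
        de_features=de_features,
        coexpressed_pairs=coexpressed_pairs,
        cis_pairs=cis_pairs,
        tf_links=tf_links,
        trans_links=trans_links,
        modules=modules,
    )
    return matrix, loci, collections, truth


def generate_qpcr_cts(
    seed: int,
    genes: Sequence[str],
    reference_gene: str,
    planted_log2fc: Mapping[str, float],
    *,
    group_labels: tuple[str, str] = ("AR", "nonAR"),
    ct_noise_sd: float = 0.1,
    n_samples_per_group: int = 3,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate a qPCR Ct table with planted relative expression.

    The case group's target-gene Ct values are shifted by ``-planted_log2fc``
    (one extra doubling of template removes one cycle), so the expected
    ddCt of each gene is exactly ``-planted_log2fc[gene]`` and the expected
    recovered log2 fold change equals the planted one. Per-sample global Ct
    offsets (pipetting/input variation) are added to every gene including
    the reference; they cancel in dCt.

    Returns a tidy table with columns sample_id, group, gene_id, replicate, ct.
    """
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} not in gene list")
    if reference_gene in planted_log2fc:
        raise ValueError("the reference gene cannot carry a planted effect")
    unknown = set(planted_log2fc) - set(genes)
    if unknown:
        raise ValueError(f"planted effects for genes not in list: {sorted(unknown)}")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    case, control = group_labels
    base_ct = {g: (18.0 if g == reference_gene else float(rng.uniform(22.0, 30.0))) for g in genes}
    rows = []
    for group in (case, control):
        for j in range(n_samples_per_group):
            sample = f"{group}_{j + 1}"
            # sample-wide loading offset; cancels in dCt, suppressed in the
            # zero-noise limit so the recovered fold change is bit-exact
            offset = float(rng.normal(0.0, 0.3)) if ct_noise_sd > 0 else 0.0
            for gene in genes:
                ct0 = base_ct[gene] + offset
                if group == case:
                    ct0 -= float(planted_log2fc.get(gene, 0.0))
                for rep in range(1, n_replicates + 1):
                    ct = ct0 + (float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd else 0.0)
                    rows.append((sample, group, gene, rep, ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene_id", "replicate", "ct"])


def write_dataset(
    config: SimConfig,
    outdir: str | Path,
) -> tuple[ExpressionMatrix, GeneLociCatalog, dict[str, GeneSetCollection], GroundTruth]:
    """Generate a dataset and write every component under *outdir*.

    Files: matrix.tsv, design.tsv, loci.bed, functional_sets.gmt,
    tf_regulons.gmt, and truth_*.tsv tables. Deterministic for a fixed
    (seed, config): reruns are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, loci, collections, truth = generate_dataset(config)
    write_expression_matrix(matrix, outdir / "matrix.tsv")
    write_design(matrix.design, outdir / "design.tsv")
    write_gene_loci(loci, outdir / "loci.bed")
    write_gene_sets(collections["GO_BP"], outdir / "functional_sets.gmt")
    write_gene_sets(collections["TF"], outdir / "tf_regulons.gmt")

    pd.DataFrame(
        sorted(truth.de_features.items()), columns=["feature_id", "direction"]
    ).to_csv(outdir / "truth_de_features.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.coexpressed_pairs), columns=["lncrna_id", "mrna_id", "sign"]
    ).to_csv(outdir / "truth_coexpressed_pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.cis_pairs), columns=["lncrna_id", "mrna_id"]
    ).to_csv(outdir / "truth_cis_pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(tf, m) for tf in sorted(truth.tf_links) for m in sorted(truth.tf_links[tf])],
        columns=["tf", "target"],
    ).to_csv(outdir / "truth_tf_links.tsv", sep="\t", index=False)
    return matrix, loci, collections, truth
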