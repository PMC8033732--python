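"""Readers and writers for the tabular formats the pipeline touches.

The pipeline exchanges five plain-text formats:

* expression matrix — TSV, one row per feature, one column per sample, with
  ``# scale=`` metadata comment and an optional ``feature_class`` column;
* sample design — two-column TSV mapping sample IDs to group labels;
* gene loci — BED4/BED6 (0-based half-open, per BED convention);
* gene sets — GMT (set name, description, member IDs);
* networks — SIF or a typed edge-list TSV.

All readers reject malformed input rather than coercing it; every
writer/reader pair is an exact round trip (asserted in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneLociCatalog",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "write_design",
    "read_gene_loci",
    "write_gene_loci",
    "read_gene_sets",
    "write_gene_sets",
    "write_network",
    "read_network",
    "load_cis_table_fixture",
]

GENE_SET_CATEGORIES = ("GO_BP", "GO_CC", "GO_MF", "KEGG", "TF")

#: SIF interaction vocabulary used by :func:`write_network`.
EDGE_TYPES = ("coexp+", "coexp-", "cis", "trans")


@dataclass
class ExpressionMatrix:
    """Feature x sample intensity table with its two-group design.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID with sample IDs as columns.
    feature_class
        Per-feature label, ``"lncRNA"`` or ``"mRNA"``, aligned to ``values``.
    scale
        ``"linear"`` (raw intensities, strictly positive) or ``"log2"``.
    design
        Mapping of every sample ID to its group label.
    """

    values: pd.DataFrame
    feature_class: pd.Series
    scale: str
    design: dict[str, str]

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature IDs: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and (vals <= 0).any():
            raise ValueError("linear-scale expression values must be > 0")
        self.feature_class = self.feature_class.reindex(self.values.index)
        if self.feature_class.isna().any():
            missing = self.feature_class.index[self.feature_class.isna()].tolist()
            raise ValueError(f"features without a class label: {missing}")
        bad = set(self.feature_class.unique()) - {"lncRNA", "mRNA"}
        if bad:
            raise ValueError(f"unknown feature classes: {sorted(bad)}")
        missing = set(self.design) - set(self.values.columns)
        if missing:
            raise ValueError(f"design samples missing from matrix: {sorted(missing)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def features_of_class(self, cls: str) -> list[str]:
        return list(self.feature_class.index[self.feature_class == cls])

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.design.get(s) == group]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            if s in self.design:
                seen.setdefault(self.design[s], None)
        return list(seen)


@dataclass
class GeneLociCatalog:
    """One genomic interval per feature (0-based half-open coordinates)."""

    table: pd.DataFrame  # index = feature ID; columns chrom, start, end, strand

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "strand"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"loci table needs columns {sorted(required)}")
        if self.table.index.duplicated().any():
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"multiple loci for feature(s): {dupes}")
        bad = self.table[self.table["start"] >= self.table["end"]]
        if len(bad):
            raise ValueError(f"start >= end for feature(s): {bad.index.tolist()}")

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.table.index

    def locus(self, feature_id: str) -> pd.Series:
        return self.table.loc[feature_id]


@dataclass
class GeneSetCollection:
    """Named, categorised gene sets (GO terms, KEGG pathways or TF regulons)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    category: str = "GO_BP"

    def __post_init__(self) -> None:
        if self.category not in GENE_SET_CATEGORIES:
            raise ValueError(
                f"category must be one of {GENE_SET_CATEGORIES}, got {self.category!r}"
            )
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with *universe*, dropping sets that empty out."""
        uni = frozenset(universe)
        kept = {
            name: members & uni
            for name, members in self.sets.items()
            if members & uni
        }
        return GeneSetCollection(
            sets=kept,
            descriptions={n: self.descriptions.get(n, "") for n in kept},
            category=self.category,
        )


# ---------------------------------------------------------------------------
# expression matrix TSV


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        out = matrix.values.copy()
        out.insert(0, "feature_class", matrix.feature_class)
        out.index.name = "feature_id"
        out.to_csv(fh, sep="\t", lineterminator="\n", float_format="%.10g")


def write_design(design: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in design.items():
            fh.write(f"{sample}\t{group}\n")


def read_design(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["sample_id", "group"]:
        raise ValueError(f"design file must have columns sample_id, group: {path}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in design file")
    return dict(zip(df["sample_id"], df["group"]))


def read_expression_matrix(
    path: str | Path,
    design_path: str | Path | None = None,
    *,
    scale: str | None = None,
    design: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column = feature ID).

    The scale is taken from a ``# scale=...`` comment header; if absent it
    must be passed explicitly — it is never guessed from the values, because
    silently misreading log2 as linear corrupts every fold change downstream.
    """
    path = Path(path)
    header_scale = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# scale="):
                header_scale = line.strip().split("=", 1)[1]
    if scale is None:
        scale = header_scale
    if scale is None:
        raise ValueError(
            f"{path}: no '# scale=' header and no explicit scale given; "
            "declare 'linear' or 'log2'"
        )
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ID(s): {dupes}")
    if "feature_class" in df.columns:
        feature_class = df.pop("feature_class").astype(str)
    else:
        feature_class = pd.Series("mRNA", index=df.index)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression values: {exc}") from exc
    if design is None:
        if design_path is None:
            raise ValueError("either design_path or design must be provided")
        design = read_design(design_path)
    return ExpressionMatrix(
        values=values,
        feature_class=feature_class,
        scale=scale,
        design=dict(design),
    )


# ---------------------------------------------------------------------------
# BED loci


def read_gene_loci(path: str | Path, *, first_wins: bool = False) -> GeneLociCatalog:
    """Read a BED4/BED6 file into a :class:`GeneLociCatalog`.

    Multi-locus features are an error unless ``first_wins`` is set, in which
    case the first locus is kept with a warning.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs >= 4 columns")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end for {name!r}")
            strand = fields[5] if len(fields) >= 6 else "unknown"
            if strand not in ("+", "-", "unknown", "."):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            rows.append((name, chrom, start, end, "unknown" if strand == "." else strand))
    df = pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "strand"])
    if df["name"].duplicated().any():
        dupes = df["name"][df["name"].duplicated()].unique().tolist()
        if not first_wins:
            raise ValueError(f"{path}: multiple loci for feature(s) {dupes}")
        warnings.warn(f"multiple loci for {dupes}; keeping first occurrence")
        df = df.drop_duplicates("name", keep="first")
    return GeneLociCatalog(df.set_index("name"))


def write_gene_loci(catalog: GeneLociCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in catalog.table.iterrows():
            strand = row["strand"] if row["strand"] in ("+", "-") else "."
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{name}\t0\t{strand}\n"
            )


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(path: str | Path, category: str) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member...)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT needs name, description, members")
            name, description, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if len(members) != len(set(members)):
                warnings.warn(f"{path}:{lineno}: duplicate members in {name!r} deduplicated")
            sets[name] = frozenset(members)
            descriptions[name] = description
    return GeneSetCollection(sets=sets, descriptions=descriptions, category=category)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.descriptions.get(name, '')}\t{members}\n")


# ---------------------------------------------------------------------------
# networks


def write_network(
    network: nx.DiGraph,
    path: str | Path,
    fmt: str = "sif",
    *,
    allow_empty: bool = False,
) -> None:
    """Write a typed regulatory network as SIF or an edge-list TSV.

    Edges must carry an ``interaction`` attribute from :data:`EDGE_TYPES`.
    Rows are sorted (source, interaction, target) so identical networks
    always produce byte-identical files.
    """
    if network.number_of_edges() == 0 and not allow_empty:
        raise ValueError("refusing to write an empty network (pass allow_empty=True)")
    rows = []
    for u, v, data in network.edges(data=True):
        interaction = data.get("interaction")
        if interaction not in EDGE_TYPES:
            raise ValueError(f"edge ({u}, {v}) has invalid interaction {interaction!r}")
        rows.append((str(u), interaction, str(v)))
    rows.sort()
    with open(path, "w") as fh:
        if fmt == "sif":
            for u, interaction, v in rows:
                fh.write(f"{u}\t{interaction}\t{v}\n")
        elif fmt == "tsv":
            fh.write("source\tinteraction\ttarget\n")
            for u, interaction, v in rows:
                fh.write(f"{u}\t{interaction}\t{v}\n")
        else:
            raise ValueError(f"format must be 'sif' or 'tsv', got {fmt!r}")


def read_network(path: str | Path, fmt: str = "sif") -> nx.DiGraph:
    graph = nx.DiGraph()
    with open(path) as fh:
        lines = fh.read().splitlines()
    if fmt == "tsv" and lines:
        lines = lines[1:]
    for lineno, line in enumerate(lines, start=1):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        u, interaction, v = fields
        if interaction not in EDGE_TYPES:
            raise ValueError(f"{path}:{lineno}: invalid interaction {interaction!r}")
        graph.add_edge(u, v, interaction=interaction)
    return graph


# ---------------------------------------------------------------------------
# packaged fixture


def load_cis_table_fixture() -> pd.DataFrame:
    """The published cis-regulation table shipped with the package.

    41 lncRNA–mRNA pairs (35 distinct lncRNAs) transcribed from the printed
    cis-regulation table of the allergic-rhinitis nasal-mucosa microarray
    study (GEO GSE159415). Columns: chromosome (as printed; ``-`` where the
    table prints none), correlation (Pearson r across the six arrays),
    lncrna_id, mrna_id.
    """
    ref = resources.files("lncfun.data").joinpath("cis_regulation_table.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype={"chromosome": str})
    df["correlation"] = df["correlation"].astype(float)
    if not ((df["correlation"].abs() > 0.8) & (df["correlation"].abs() <= 1)).all():
        raise AssertionError("fixture violates |r| in (0.8, 1]")
    return df
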