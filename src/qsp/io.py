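"""Readers and writers for the pipeline's interchange formats.

All tabular formats are TSV; gene sets use GMT. Identifiers are opaque
strings and are never normalized. Readers are strict: duplicate ids,
short lines and non-numeric cells raise :class:`DataError` with enough
context to locate the offending record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger("qsp")

__all__ = [
    "DataError",
    "GeneSetCollection",
    "PerturbationDB",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_edgelist",
    "write_edgelist",
    "read_perturbations",
    "write_perturbations",
    "read_metadata",
    "read_categories",
    "write_categories",
    "read_drug_targets",
    "write_drug_targets",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (GMT semantics).

    ``sets`` maps set name -> member gene list; ``descriptions`` carries the
    GMT description field. Order of insertion is preserved.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.descriptions == other.descriptions

    def add(self, name: str, genes: list[str], description: str = "") -> None:
        if name in self.sets:
            raise DataError(f"duplicate gene-set name {name!r}")
        if not genes:
            raise DataError(f"gene set {name!r} has no members")
        self.sets[name] = list(genes)
        self.descriptions[name] = description

    def names(self) -> list[str]:
        return list(self.sets)

    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out


@dataclass
class PerturbationDB:
    """Perturbation-instance collection.

    ``meta`` is one row per instance (index = instance_id) with columns
    compound_id, cell_type, time, dose. ``profiles`` is a genes x instances
    frame of signed differential scores covering a single shared gene
    universe. Rankings (gene order by descending score) are derived lazily
    and cached.
    """

    meta: pd.DataFrame
    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meta.index.is_unique:
            dup = self.meta.index[self.meta.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate instance ids: {dup}")
        missing = set(self.meta.index) ^ set(self.profiles.columns)
        if missing:
            raise DataError(f"instance ids inconsistent between meta and profiles: {sorted(missing)}")
        if not self.profiles.index.is_unique:
            raise DataError("duplicate gene ids in perturbation profiles")
        self.profiles = self.profiles[self.meta.index]
        self._rank_cache: dict[str, pd.Series] = {}

    @property
    def instances(self) -> list[str]:
        return list(self.meta.index)

    @property
    def genes(self) -> list[str]:
        return list(self.profiles.index)

    def n_instances(self) -> int:
        return len(self.meta)

    def ranking(self, instance_id: str) -> list[str]:
        """Genes ordered by descending score for one instance (ties by gene id)."""
        return list(self.rank_positions(instance_id).index)

    def rank_positions(self, instance_id: str) -> pd.Series:
        """1-based rank per gene (1 = highest score) for one instance."""
        if instance_id not in self._rank_cache:
            col = self.profiles[instance_id]
            order = col.sort_values(ascending=False, kind="mergesort").index
            self._rank_cache[instance_id] = pd.Series(
                range(1, len(order) + 1), index=order
            )
        return self._rank_cache[instance_id]


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path) -> GeneSetCollection:
    coll = GeneSetCollection()
    seen: dict[str, int] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise DataError(f"{path}: empty file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise DataError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if name in seen:
            raise DataError(
                f"{path}: duplicate gene-set name {name!r} (lines {seen[name]} and {lineno})"
            )
        seen[name] = lineno
        coll.add(name, genes, desc)
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll:
            for token in [name, *genes]:
                if "\t" in token or "\n" in token:
                    raise DataError(f"identifier {token!r} contains a tab or newline")
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices and plain tables

def _read_tsv(path, **kw) -> pd.DataFrame:
    import os

    if os.path.getsize(path) == 0:
        raise DataError(f"{path}: empty file")
    return pd.read_csv(path, sep="\t", **kw)


def read_expression(path) -> pd.DataFrame:
    """Genes x samples numeric matrix; first column = gene id, header = sample ids."""
    df = _read_tsv(path, index_col=0)
    if df.empty:
        raise DataError(f"{path}: no data rows")
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicated gene rows: {dup}")
    if not df.columns.is_unique:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicated sample columns: {dup}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.argmax()]
            raise DataError(f"{path}: non-numeric value at gene {gene!r}, sample {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        raise DataError(f"{path}: missing values present")
    return df


def write_expression(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata; first column = sample id."""
    df = _read_tsv(path, index_col=0)
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicated sample ids: {dup}")
    return df


def read_categories(path) -> dict[str, list[str]]:
    """Pathway -> category list. Columns: pathway, categories (comma separated)."""
    df = _read_tsv(path)
    if not {"pathway", "categories"} <= set(df.columns):
        raise DataError(f"{path}: need columns 'pathway' and 'categories'")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        p = str(row["pathway"])
        if p in out:
            raise DataError(f"{path}: duplicated pathway {p!r}")
        cats = [c.strip() for c in str(row["categories"]).split(",") if c.strip()]
        if not cats:
            raise DataError(f"{path}: pathway {p!r} has no categories")
        out[p] = cats
    return out


def write_categories(cat: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway\tcategories\n")
        for p, cats in cat.items():
            fh.write(f"{p}\t{','.join(cats)}\n")


# ---------------------------------------------------------------------------
# Networks and drug targets

def read_edgelist(path) -> nx.Graph:
    """Two-column TSV edge list; undirected, simple (duplicates/reverses collapse)."""
    g = nx.Graph()
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise DataError(f"{path}: empty file")
    start = 0
    first = lines[0].split("\t")
    if [f.lower() for f in first[:2]] in (["source", "target"], ["node1", "node2"]):
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.replace(" ", "\t").split("\t")
        fields = [f for f in fields if f]
        if len(fields) < 2:
            raise DataError(f"{path}:{lineno}: edge line needs two node ids")
        a, b = fields[0], fields[1]
        if a == b:
            continue  # self-loops dropped: network treated as simple
        g.add_edge(a, b)
    if g.number_of_nodes() == 0:
        raise DataError(f"{path}: no edges parsed")
    return g


def write_edgelist(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")


def read_drug_targets(path) -> dict[str, set[str]]:
    """Columns: drug, target. One row per (drug, target) pair."""
    df = _read_tsv(path)
    if not {"drug", "target"} <= set(df.columns):
        raise DataError(f"{path}: need columns 'drug' and 'target'")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["drug"]), set()).add(str(row["target"]))
    return out


def write_drug_targets(dt: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("drug\ttarget\n")
        for drug in sorted(dt):
            for t in sorted(dt[drug]):
                fh.write(f"{drug}\t{t}\n")


# ---------------------------------------------------------------------------
# Perturbation database (long format)

_PERT_COLS = ["instance_id", "compound_id", "cell_type", "time", "dose", "gene", "score"]


def read_perturbations(path) -> PerturbationDB:
    df = _read_tsv(path)
    missing = set(_PERT_COLS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        row = int(scores.isna().argmax())
        raise DataError(f"{path}: non-numeric score at data row {row}")
    df["score"] = scores
    profiles = df.pivot(index="gene", columns="instance_id", values="score")
    if profiles.isna().any().any():
        raise DataError(f"{path}: instances do not share a complete gene universe")
    meta = (
        df[["instance_id", "compound_id", "cell_type", "time", "dose"]]
        .drop_duplicates()
        .set_index("instance_id")
    )
    if not meta.index.is_unique:
        dup = meta.index[meta.index.duplicated()].unique().tolist()
        raise DataError(f"{path}: instances with inconsistent metadata: {dup}")
    return PerturbationDB(meta=meta, profiles=profiles)


def write_perturbations(db: PerturbationDB, path) -> None:
    long = db.profiles.stack().rename("score").reset_index()
    long.columns = ["gene", "instance_id", "score"]
    long = long.merge(db.meta.reset_index(), on="instance_id")
    long[_PERT_COLS].to_csv(path, sep="\t", index=False)
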