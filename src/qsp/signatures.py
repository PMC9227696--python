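"""Category-stratified disease gene signatures.

For each pairwise group comparison and each core disease-process category
(C1 insulin resistance/oxidative stress, C2 cell stress/apoptosis/
lipotoxicity, C3 inflammation, C4 fibrosis), the signature collects the
differentially expressed genes (gene-level q below a threshold) that are
members of at least one differentially enriched pathway (pathway-level q
below the same threshold) annotated with that category, split into up- and
down-regulated sets by the sign of the gene-level change. Three
comparisons x four categories = twelve signatures, indexed s1-s12 in
row-major (comparison, category) order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .io import DataError, GeneSetCollection, read_gmt, write_gmt

logger = logging.getLogger("qsp")

CORE_CATEGORIES = ["C1", "C2", "C3", "C4"]

CATEGORY_NAMES = {
    "C1": "insulin resistance and oxidative stress",
    "C2": "cell stress, apoptosis, and lipotoxicity",
    "C3": "inflammation",
    "C4": "fibrosis",
}

__all__ = [
    "GeneSignature",
    "build_signatures",
    "export_signatures",
    "import_signatures",
    "CORE_CATEGORIES",
    "CATEGORY_NAMES",
]


@dataclass
class GeneSignature:
    """Disjoint up/down gene sets for one (comparison, category) pair."""

    index: str  # s1..s12
    comparison: str
    category: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"{self.index}: genes in both up and down: {sorted(overlap)}")

    def is_empty(self) -> bool:
        return not self.up and not self.down

    def size(self) -> int:
        return len(self.up) + len(self.down)


def build_signatures(
    deg: dict,
    pathway_de: dict,
    cat: dict[str, list[str]],
    membership: GeneSetCollection,
    alpha: float = 0.001,
    categories: list[str] | None = None,
) -> list[GeneSignature]:
    """Build one signature per (comparison, category).

    Parameters
    ----------
    deg, pathway_de : dict of comparison name -> DE table
        Moderated-t result tables (indexed by feature, with ``q`` and
        ``direction``) for genes and for pathway enrichment scores.
    cat : pathway -> category list
    membership : pathway -> member genes
    alpha : FDR threshold applied to both gene- and pathway-level q.

    Signatures are emitted even when empty (with a warning) so the
    s1-s12 indexing stays stable across datasets. A gene belonging to
    several qualifying pathways appears once; a pathway annotated with
    several categories contributes to each.
    """
    if categories is None:
        categories = CORE_CATEGORIES
    comparisons = list(deg)
    missing = set(comparisons) ^ set(pathway_de)
    if missing:
        raise ValueError(f"comparisons not present in both inputs: {sorted(missing)}")
    uncovered = [p for p in set().union(*(list(t.index) for t in pathway_de.values())) if p not in membership]
    if uncovered:
        raise ValueError(f"pathways missing from membership collection: {sorted(uncovered)[:5]}")

    out: list[GeneSignature] = []
    i = 0
    for comp in comparisons:
        genes_tab = deg[comp]
        path_tab = pathway_de[comp]
        sig_paths = set(path_tab.index[path_tab["q"] < alpha])
        deg_up = set(genes_tab.index[(genes_tab["q"] < alpha) & (genes_tab["direction"] == "up")])
        deg_down = set(genes_tab.index[(genes_tab["q"] < alpha) & (genes_tab["direction"] == "down")])
        for category in categories:
            i += 1
            qualifying = {p for p in sig_paths if category in cat.get(p, [])}
            members: set[str] = set()
            for p in qualifying:
                members.update(membership[p])
            sig = GeneSignature(
                index=f"s{i}",
                comparison=comp,
                category=category,
                up=members & deg_up,
                down=members & deg_down,
            )
            if sig.is_empty():
                warnings.warn(f"signature {sig.index} ({comp}, {category}) is empty")
            out.append(sig)
    return out


def export_signatures(signatures: list[GeneSignature], path) -> None:
    """Write signatures as paired up/down GMT records (``<index>_up``, ``<index>_down``).

    Empty signatures are skipped with a warning; the description field
    encodes comparison and category so the file round-trips losslessly.
    """
    coll = GeneSetCollection()
    for sig in signatures:
        if sig.is_empty():
            warnings.warn(f"signature {sig.index} empty on both sides; record skipped")
            continue
        desc = f"{sig.comparison}|{sig.category}"
        for side, genes in (("up", sig.up), ("down", sig.down)):
            if genes:
                coll.add(f"{sig.index}_{side}", sorted(genes), desc)
    write_gmt(coll, path)


def import_signatures(path) -> list[GeneSignature]:
    """Read back a signature GMT written by :func:`export_signatures`."""
    coll = read_gmt(path)
    sigs: dict[str, GeneSignature] = {}
    for name, genes in coll:
        if "_" not in name:
            raise DataError(f"{path}: set name {name!r} lacks an _up/_down suffix")
        index, side = name.rsplit("_", 1)
        if side not in ("up", "down"):
            raise DataError(f"{path}: set name {name!r} lacks an _up/_down suffix")
        desc = coll.descriptions.get(name, "|")
        comp, _, category = desc.partition("|")
        sig = sigs.setdefault(
            index, GeneSignature(index=index, comparison=comp, category=category)
        )
        getattr(sig, side).update(genes)
    out = sorted(sigs.values(), key=lambda s: (len(s.index), s.index))
    for sig in out:
        if sig.up & sig.down:
            raise DataError(f"{path}: {sig.index} has overlapping up/down sets")
    return out
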