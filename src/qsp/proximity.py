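"""Network proximity of drug targets to a disease subnetwork.

A disease module S is the induced subgraph of differentially expressed
genes lying on disease-associated pathways within a tissue interactome.
For a drug with target set T, proximity is the average over targets of the
hop distance to the closest module node,

    d(S, T) = (1/|T|) * sum_{t in T} min_{s in S} sp(s, t).

The observed d is standardized against a null of degree-matched random
node sets (logarithmic degree bins, both S and T redrawn per iteration by
default): z = (d - mu) / delta. Negative z means the drug's targets sit
closer to the disease module than degree-matched chance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("qsp")

__all__ = [
    "SubnetworkSpec",
    "ProximityResult",
    "build_subnetwork",
    "proximity_distance",
    "proximity_zscore",
    "rank_drugs",
    "hub_ranking",
    "degree_bins",
]


@dataclass
class SubnetworkSpec:
    """Pathway gene lists plus the DEG union that filters them."""

    pathway_genes: dict[str, list[str]]
    deg_union: set[str]


@dataclass
class ProximityResult:
    drug: str
    d: float
    mu: float
    delta: float
    z: float | None
    n_targets_used: int
    n_targets_excluded: int = 0


def build_subnetwork(background: nx.Graph, spec: SubnetworkSpec) -> nx.Graph:
    """Induced subgraph of pathway genes restricted to the DEG union.

    Pathway genes absent from the background are silently excluded but
    counted in the returned graph's ``coverage`` attribute.
    """
    pathway_union: set[str] = set()
    for genes in spec.pathway_genes.values():
        pathway_union.update(genes)
    in_background = pathway_union & set(background.nodes)
    nodes = in_background & spec.deg_union
    if not nodes:
        raise ValueError("subnetwork is empty after pathway/DEG intersection")
    sub = background.subgraph(nodes).copy()
    sub.graph["coverage"] = {
        "pathway_genes": len(pathway_union),
        "in_background": len(in_background),
        "after_deg_filter": len(nodes),
    }
    return sub


def _min_distances_to_set(net: nx.Graph, sources: set) -> dict:
    """Hop distance from every reachable node to the nearest source (multi-source BFS)."""
    sources = {s for s in sources if s in net}
    dist = {s: 0 for s in sources}
    frontier = list(sources)
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in net[u]:
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def proximity_distance(
    net: nx.Graph, S: set, T: set, unreachable: str = "exclude"
) -> tuple[float, int]:
    """Average minimum shortest-path distance from targets T to module S.

    Targets absent from the network or with no path to any module node are
    excluded from the average (and counted) by default; with
    ``unreachable="diameter"`` they contribute diameter + 1 instead.

    Returns ``(d, n_excluded)``.
    """
    S_in = {s for s in S if s in net}
    T_in = {t for t in T if t in net}
    if not S_in:
        raise ValueError("no module node present in the network")
    if not T_in:
        raise ValueError("no target present in the network")
    dist = _min_distances_to_set(net, S_in)
    vals, excluded = [], len(T) - len(T_in)
    penalty = None
    for t in T_in:
        if t in dist:
            vals.append(dist[t])
        elif unreachable == "diameter":
            if penalty is None:
                comp = max(nx.connected_components(net), key=len)
                penalty = nx.diameter(net.subgraph(comp)) + 1
            vals.append(penalty)
        else:
            excluded += 1
    if not vals:
        raise ValueError("all targets unreachable from the disease module")
    if excluded:
        logger.warning("proximity: %d target(s) excluded (absent or unreachable)", excluded)
    return float(np.mean(vals)), excluded


def degree_bins(net: nx.Graph, min_size: int = 1) -> dict:
    """Node -> bin assignment with logarithmic (doubling) degree bin edges.

    Bins are [1,2), [2,4), [4,8), ... on degree (degree-0 nodes get their
    own bin); bins smaller than ``min_size`` are merged upward.
    """
    by_bin: dict[int, list] = {}
    for node, deg in net.degree():
        b = -1 if deg == 0 else int(np.floor(np.log2(deg)))
        by_bin.setdefault(b, []).append(node)
    merged: dict[int, list] = {}
    keys = sorted(by_bin)
    pending: list = []
    pending_key = None
    for k in keys:
        members = pending + by_bin[k]
        if pending_key is None:
            pending_key = k
        if len(members) >= min_size:
            merged[pending_key] = members
            pending, pending_key = [], None
        else:
            pending = members
    if pending:
        if merged:
            last = max(merged)
            merged[last] = merged[last] + pending
        else:
            merged[pending_key] = pending
    node_bin = {}
    for b, members in merged.items():
        for node in members:
            node_bin[node] = b
    return {"node_bin": node_bin, "bins": {b: sorted(m) for b, m in merged.items()}}


def _degree_matched_sample(
    nodes: set, bins: dict, rng: np.random.Generator
) -> set:
    """Random node set matching the per-bin degree counts of ``nodes`` exactly."""
    node_bin = bins["node_bin"]
    counts: dict[int, int] = {}
    # sorted iteration: set order is hash-dependent and would leak into
    # the RNG consumption order, breaking cross-process reproducibility
    for node in sorted(nodes):
        counts[node_bin[node]] = counts.get(node_bin[node], 0) + 1
    out: set = set()
    for b in sorted(counts):
        pool = bins["bins"][b]
        idx = rng.choice(len(pool), size=counts[b], replace=False)
        out.update(pool[i] for i in idx)
    return out


def proximity_zscore(
    net: nx.Graph,
    S: set,
    T: set,
    n_rand: int = 1000,
    seed: int | None = None,
    randomize: str = "both",
    unreachable: str = "exclude",
) -> ProximityResult:
    """Proximity z-score of targets T against a degree-matched null.

    Each null draw resamples degree-matched stand-ins for both S and T
    (``randomize="targets"`` keeps S fixed). When the null distance
    distribution is degenerate (delta = 0) the z-score is reported as
    missing.
    """
    S_in = {s for s in S if s in net}
    T_in = {t for t in T if t in net}
    d, unreach = proximity_distance(net, S_in, T_in, unreachable=unreachable)
    rng = np.random.default_rng(seed)
    bins = degree_bins(net)
    null = np.empty(n_rand)
    for i in range(n_rand):
        s_rand = _degree_matched_sample(S_in, bins, rng) if randomize == "both" else S_in
        t_rand = _degree_matched_sample(T_in, bins, rng)
        null[i], _ = proximity_distance(net, s_rand, t_rand, unreachable=unreachable)
    mu = float(null.mean())
    delta = float(null.std(ddof=0))
    if delta == 0:
        warnings.warn("degenerate null distance distribution (delta = 0); z undefined")
        z = None
    else:
        z = float((d - mu) / delta)
    return ProximityResult(
        drug="", d=d, mu=mu, delta=delta, z=z,
        n_targets_used=len(T_in) - unreach,
        n_targets_excluded=unreach + (len(T) - len(T_in)),
    )


def rank_drugs(
    net: nx.Graph,
    S: set,
    drugmap: dict[str, set[str]],
    n_rand: int = 1000,
    seed: int | None = None,
    randomize: str = "both",
) -> tuple[pd.DataFrame, list[str]]:
    """Proximity z-score per drug, sorted ascending (closest first).

    Drugs with no usable target in the network are excluded and listed in
    the returned skipped-drugs report. Identical target sets share one
    null (cached), so they get identical d and z.
    """
    if not drugmap:
        raise ValueError("empty drug-target map")
    rng = np.random.default_rng(seed)
    cache: dict[frozenset, ProximityResult] = {}
    rows, skipped = [], []
    for drug in sorted(drugmap):
        targets = drugmap[drug]
        usable = {t for t in targets if t in net}
        if not usable:
            skipped.append(drug)
            continue
        key = frozenset(usable)
        if key not in cache:
            sub_seed = int(rng.integers(2**31))
            try:
                cache[key] = proximity_zscore(
                    net, S, usable, n_rand=n_rand, seed=sub_seed, randomize=randomize
                )
            except ValueError:
                cache[key] = None  # type: ignore[assignment]
        res = cache[key]
        if res is None:
            skipped.append(drug)
            continue
        rows.append(
            {
                "drug": drug,
                "d": res.d,
                "mu": res.mu,
                "delta": res.delta,
                "z": res.z,
                "n_targets_used": res.n_targets_used,
            }
        )
    table = pd.DataFrame(rows, columns=["drug", "d", "mu", "delta", "z", "n_targets_used"])
    if not table.empty:
        table = table.sort_values(
            ["z", "d", "drug"], na_position="last"
        ).reset_index(drop=True)
    if skipped:
        logger.warning("rank_drugs: %d drug(s) skipped (no usable targets)", len(skipped))
    return table, skipped


def hub_ranking(net: nx.Graph, k: int = 20) -> pd.DataFrame:
    """Top-k nodes by degree (descending), ties broken by node id."""
    degs = sorted(net.degree(), key=lambda x: (-x[1], str(x[0])))
    if k > len(degs):
        warnings.warn(f"k = {k} exceeds node count {len(degs)}; returning all nodes")
        k = len(degs)
    return pd.DataFrame(degs[:k], columns=["node", "degree"])
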