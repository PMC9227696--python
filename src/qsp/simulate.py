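"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators emulate the study's data sources at desk scale, with
ground-truth labels for every planted effect:

* a bulk RNA-seq cohort: negative-binomial counts over four disease
  classes (normal, steatosis, lobular inflammation, fibrosis) with
  log-normal library sizes, disjoint pathway blocks shifted up or down in
  each disease class, category annotations C1-C4, and an optional
  multiplicative batch artifact;
* a perturbation database: signed per-gene differential scores per
  instance (compound x cell type x time x dose), with planted reverter
  compounds whose profiles push a signature's up-genes toward the bottom
  of the ranking and its down-genes toward the top;
* a degree-heterogeneous (preferential-attachment) interaction network
  with planted proximal drugs whose targets sit inside or adjacent to the
  disease node set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneSetCollection, PerturbationDB

logger = logging.getLogger("qsp")

CLASSES = ["normal", "steatosis", "lobular", "fibrosis"]

#: canonical pairwise comparisons, mirroring the progression contrasts
COMPARISONS = [
    ("lobular_vs_early", "lobular", ["normal", "steatosis"]),
    ("fibrosis_vs_early", "fibrosis", ["normal", "steatosis"]),
    ("fibrosis_vs_lobular", "fibrosis", ["lobular"]),
]

__all__ = [
    "CohortConfig",
    "PerturbConfig",
    "NetConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_perturbation_db",
    "generate_network",
    "CLASSES",
    "COMPARISONS",
]


class ConfigError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Cohort generator settings.

    Default class sizes follow the study cohort (36 normal, 46 steatosis,
    50 lobular inflammation, 50 fibrosis); gene/pathway counts are desk
    scale. ``shift_magnitude`` is the planted log2 fold change applied to
    every gene of a shifted pathway in the affected class.
    """

    n_genes: int = 2000
    n_samples_per_class: dict = field(
        default_factory=lambda: {"normal": 36, "steatosis": 46, "lobular": 50, "fibrosis": 50}
    )
    n_pathways: int = 48
    genes_per_pathway: int = 25
    shift_magnitude: float = 2.0
    dispersion: float = 0.1
    batch_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in [
            ("n_genes", self.n_genes),
            ("n_pathways", self.n_pathways),
            ("genes_per_pathway", self.genes_per_pathway),
        ]:
            if v < 1:
                raise ConfigError(f"{name} must be >= 1")
        if any(v < 1 for v in self.n_samples_per_class.values()):
            raise ConfigError("all class sizes must be >= 1")
        if set(self.n_samples_per_class) != set(CLASSES):
            raise ConfigError(f"classes must be exactly {CLASSES}")
        if self.shift_magnitude < 0:
            raise ConfigError("shift_magnitude must be >= 0")
        if not 0.0 <= self.batch_fraction <= 1.0:
            raise ConfigError("batch_fraction must lie in [0, 1]")
        if self.genes_per_pathway * self.n_pathways > self.n_genes:
            raise ConfigError(
                f"{self.n_pathways} pathways x {self.genes_per_pathway} genes "
                f"exceed the {self.n_genes}-gene universe"
            )


@dataclass
class PerturbConfig:
    n_compounds: int = 50
    n_instances_per_compound: int = 3
    n_cell_types: int = 2
    n_reverters: int = 5
    reversal_strength: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reverters > self.n_compounds:
            raise ConfigError("n_reverters cannot exceed n_compounds")
        for name, v in [
            ("n_compounds", self.n_compounds),
            ("n_instances_per_compound", self.n_instances_per_compound),
            ("n_cell_types", self.n_cell_types),
        ]:
            if v < 1:
                raise ConfigError(f"{name} must be >= 1")


@dataclass
class NetConfig:
    n_nodes: int = 500
    attachment_parameter: int = 3
    n_disease_nodes: int = 40
    n_drugs: int = 20
    targets_per_drug: int = 4
    proximal_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_disease_nodes >= self.n_nodes:
            raise ConfigError("n_disease_nodes must be < n_nodes")
        if self.targets_per_drug > self.n_nodes:
            raise ConfigError("targets_per_drug cannot exceed n_nodes")
        if not 0.0 <= self.proximal_fraction <= 1.0:
            raise ConfigError("proximal_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted-effect labels for generated data."""

    sample_class: dict = field(default_factory=dict)
    pathway_shifts: dict = field(default_factory=dict)  # pathway -> (class, direction)
    compound_reverter: dict = field(default_factory=dict)  # compound -> signature index or None
    drug_proximal: dict = field(default_factory=dict)  # drug -> bool
    batch_samples: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_class": self.sample_class,
            "pathway_shifts": {p: list(v) for p, v in self.pathway_shifts.items()},
            "compound_reverter": self.compound_reverter,
            "drug_proximal": self.drug_proximal,
            "batch_samples": self.batch_samples,
        }


def generate_cohort(config: CohortConfig):
    """Simulate the cohort.

    Returns ``(counts, metadata, pathways, category_map, truth)`` where
    counts is genes x samples NB counts, metadata carries diagnosis / T2D /
    sex / BMI / age per sample, pathways is a GeneSetCollection of disjoint
    gene blocks, and category_map assigns each pathway one of C1-C4.

    Half of the pathways are left unshifted; the rest are planted in
    up/down pairs per (disease class, category) across steatosis, lobular
    and fibrosis samples (see inline note), so downstream signatures carry
    genes on both sides.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    samples, classes = [], []
    for cls in CLASSES:
        for i in range(config.n_samples_per_class[cls]):
            samples.append(f"{cls}_{i:03d}")
            classes.append(cls)
    meta = pd.DataFrame(
        {
            "diagnosis": classes,
            "t2d": rng.random(len(samples)) < np.where(
                np.isin(classes, ["fibrosis"]), 0.55, 0.32
            ),
            "sex": rng.choice(["F", "M"], size=len(samples)),
            "bmi": np.round(rng.normal(45, 7, size=len(samples)), 1),
            "age": rng.integers(25, 65, size=len(samples)),
        },
        index=pd.Index(samples, name="sample"),
    )

    pathways = GeneSetCollection()
    for p in range(config.n_pathways):
        block = genes[p * config.genes_per_pathway : (p + 1) * config.genes_per_pathway]
        pathways.add(f"pw{p:03d}", block, "synthetic pathway")

    # Plant shifts on the last half of pathways. Shifted pathways come in
    # pairs sharing a (disease class, category) but with opposite
    # directions, so each downstream (comparison, category) signature has
    # both up- and down-regulated genes; pairs cycle through classes and
    # categories with coprime periods, covering all 12 combinations once
    # >= 24 pathways are shifted. Unshifted pathways cycle C1-C4 by index.
    truth = GroundTruth(sample_class=dict(zip(samples, classes)))
    shifted = pathways.names()[config.n_pathways // 2 :]
    null_paths = pathways.names()[: config.n_pathways // 2]
    categories = {name: [f"C{(i % 4) + 1}"] for i, name in enumerate(null_paths)}
    disease_classes = [c for c in CLASSES if c != "normal"]
    log2fc = np.zeros((config.n_genes, len(samples)))
    gene_index = {g: i for i, g in enumerate(genes)}
    class_arr = np.array(classes)
    for j, pw in enumerate(shifted):
        pair = j // 2
        cls = disease_classes[pair % len(disease_classes)]
        categories[pw] = [f"C{(pair % 4) + 1}"]
        direction = "up" if j % 2 == 0 else "down"
        truth.pathway_shifts[pw] = (cls, direction)
        sign = 1.0 if direction == "up" else -1.0
        rows = [gene_index[g] for g in pathways[pw]]
        cols = np.flatnonzero(class_arr == cls)
        log2fc[np.ix_(rows, cols)] = sign * config.shift_magnitude
    categories = {name: categories[name] for name in pathways.names()}

    base_mean = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=config.n_genes)
    lib = rng.lognormal(mean=0.0, sigma=np.sqrt(np.log(1.04)), size=len(samples))
    mu = base_mean[:, None] * lib[None, :] * 2.0**log2fc

    if config.batch_fraction > 0:
        n_batch = int(round(config.batch_fraction * len(samples)))
        batch_idx = rng.choice(len(samples), size=n_batch, replace=False)
        factors = rng.lognormal(mean=0.0, sigma=0.4, size=config.n_genes)
        mu[:, batch_idx] *= factors[:, None]
        truth.batch_samples = [samples[i] for i in sorted(batch_idx)]

    disp = max(config.dispersion, 1e-8)
    lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
    counts = pd.DataFrame(
        rng.poisson(lam), index=pd.Index(genes, name="gene"), columns=samples
    )
    return counts, meta, pathways, categories, truth


def comparison_groups(meta: pd.DataFrame):
    """Sample groups for the three canonical progression comparisons."""
    from .differential import ComparisonSpec

    specs = []
    for name, cls_a, cls_b in COMPARISONS:
        a = list(meta.index[meta["diagnosis"] == cls_a])
        b = list(meta.index[meta["diagnosis"].isin(cls_b)])
        specs.append(ComparisonSpec(name=name, group_a=a, group_b=b))
    return specs


def generate_perturbation_db(
    config: PerturbConfig, signatures: list, universe: list[str] | None = None
):
    """Simulate a perturbation database against a list of signatures.

    Non-reverter compounds get exchangeable standard-normal noise
    profiles. Each reverter compound is assigned one signature (cycling
    through the non-empty ones): every instance's profile subtracts
    ``reversal_strength`` from the signature's up-genes and adds it to the
    down-genes, so up-genes sink toward the ranking bottom and down-genes
    rise toward the top.
    """
    if not signatures:
        raise ValueError("empty signature list")
    usable = [s for s in signatures if not s.is_empty()]
    if config.n_reverters > 0 and not usable:
        raise ValueError("no non-empty signature to plant reverters against")
    if universe is None:
        universe_set: set[str] = set()
        for s in signatures:
            universe_set |= set(s.up) | set(s.down)
        universe = sorted(universe_set)
    gene_index = {g: i for i, g in enumerate(universe)}
    for s in usable:
        missing = (set(s.up) | set(s.down)) - set(gene_index)
        if missing:
            raise ValueError(f"signature {s.index} genes outside universe: {sorted(missing)[:5]}")

    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    meta_rows, profiles = [], []
    for c in range(config.n_compounds):
        compound = f"cpd{c:03d}"
        is_reverter = c < config.n_reverters
        sig = usable[c % len(usable)] if is_reverter else None
        truth.compound_reverter[compound] = sig.index if sig else None
        for k in range(config.n_instances_per_compound):
            inst = f"{compound}_i{k}"
            profile = rng.normal(0.0, 1.0, size=len(universe))
            if sig is not None:
                profile[[gene_index[g] for g in sig.up]] -= config.reversal_strength
                profile[[gene_index[g] for g in sig.down]] += config.reversal_strength
            meta_rows.append(
                {
                    "instance_id": inst,
                    "compound_id": compound,
                    "cell_type": f"cell{rng.integers(config.n_cell_types)}",
                    "time": float(rng.choice([6.0, 24.0])),
                    "dose": float(rng.choice([0.1, 1.0, 10.0])),
                }
            )
            profiles.append(profile)
    meta = pd.DataFrame(meta_rows).set_index("instance_id")
    prof = pd.DataFrame(
        np.column_stack(profiles), index=pd.Index(universe, name="gene"), columns=meta.index
    )
    return PerturbationDB(meta=meta, profiles=prof), truth


def generate_network(config: NetConfig):
    """Simulate a background network with planted proximal/distal drugs.

    The graph is a preferential-attachment (Barabasi-Albert) graph, so
    degrees are heavy-tailed and the degree-matched null is non-trivial.
    Proximal drugs draw targets from the disease nodes and their first
    neighbors; distal drugs draw uniformly outside that halo.
    """
    rng = np.random.default_rng(config.seed)
    g_int = nx.barabasi_albert_graph(
        config.n_nodes, config.attachment_parameter, seed=int(rng.integers(2**31))
    )
    mapping = {i: f"n{i:04d}" for i in g_int.nodes}
    net = nx.relabel_nodes(g_int, mapping)

    nodes = sorted(net.nodes)
    disease = set(
        nodes[i] for i in rng.choice(len(nodes), size=config.n_disease_nodes, replace=False)
    )
    halo = set(disease)
    for s in disease:
        halo.update(net[s])
    outside = sorted(set(nodes) - halo)

    truth = GroundTruth()
    drugmap: dict[str, set[str]] = {}
    n_proximal = int(round(config.proximal_fraction * config.n_drugs))
    halo_sorted = sorted(halo)
    for d in range(config.n_drugs):
        drug = f"drug{d:03d}"
        proximal = d < n_proximal
        pool = halo_sorted if proximal else outside
        if len(pool) < config.targets_per_drug:
            pool = sorted(net.nodes)
        idx = rng.choice(len(pool), size=config.targets_per_drug, replace=False)
        drugmap[drug] = {pool[i] for i in idx}
        truth.drug_proximal[drug] = proximal
    truth.sample_class = {}
    net.graph["disease_nodes"] = sorted(disease)
    return net, drugmap, truth
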