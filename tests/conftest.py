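import numpy as np
import pandas as pd
import pytest

from qsp import differential, simulate
from qsp.signatures import GeneSignature


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with strong planted pathway shifts (all stages resolvable)."""
    cfg = simulate.CohortConfig(
        n_genes=600,
        n_samples_per_class={"normal": 10, "steatosis": 10, "lobular": 10, "fibrosis": 10},
        n_pathways=48,
        genes_per_pathway=10,
        shift_magnitude=2.0,
        seed=11,
    )
    return simulate.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_de(small_cohort):
    counts, meta, pathways, categories, truth = small_cohort
    logcpm = differential.log2_cpm(counts)
    specs = simulate.comparison_groups(meta)
    deg = {s.name: differential.moderated_t(logcpm, s) for s in specs}
    pde = {}
    from qsp import enrichment

    es = enrichment.single_sample_enrichment(logcpm, pathways, kernel="gaussian")
    for s in specs:
        pde[s.name] = differential.moderated_t(es, s)
    return logcpm, es, deg, pde


@pytest.fixture
def toy_signature():
    return GeneSignature(
        index="s1",
        comparison="test",
        category="C1",
        up={"g1", "g2", "g3"},
        down={"g7", "g8"},
    )


@pytest.fixture
def small_db(toy_signature):
    """Ten-compound perturbation DB with two planted reverters of toy_signature."""
    universe = [f"g{i}" for i in range(1, 41)]
    cfg = simulate.PerturbConfig(
        n_compounds=10, n_instances_per_compound=3, n_cell_types=2,
        n_reverters=2, reversal_strength=8.0, seed=7,
    )
    db, truth = simulate.generate_perturbation_db(cfg, [toy_signature], universe=universe)
    return db, truth


def brute_force_es(ranking, gene_set):
    """Independent running-sum oracle for the two-sided KS enrichment score.

    Walks the ranked list step by step: +1/t on hits, -1/n on every
    position; ES is the larger-magnitude extreme of (a) max of the hit
    fraction minus position fraction and (b) its mirror, exactly as the
    position-wise definition states.
    """
    genes = list(ranking)
    gset = set(gene_set)
    n = len(genes)
    t = len(gset)
    a = -np.inf
    b = -np.inf
    j = 0
    for i, g in enumerate(genes, start=1):
        if g in gset:
            j += 1
            a = max(a, j / t - i / n)
            b = max(b, i / n - (j - 1) / t)
    return a if a > b else -b
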