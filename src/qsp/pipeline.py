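"""End-to-end pipeline: simulate -> enrich -> cluster -> differential ->
signatures -> connectivity mapping -> network proximity -> classifier eval.

A run is driven by a validated :class:`PipelineConfig` (unknown keys are
rejected before any stage executes) and writes every stage output plus a
manifest recording parameters, the seed, and SHA-256 checksums of all
written files. Per-stage random substreams are derived from the top-level
seed through ``numpy.random.SeedSequence(seed).spawn``, so stages are
independently rerunnable and the whole run is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, cmap, differential, enrichment, proximity, signatures, simulate
from .io import (
    write_categories,
    write_drug_targets,
    write_edgelist,
    write_expression,
    write_perturbations,
)

logger = logging.getLogger("qsp")

_STAGES = ["simulate", "enrich", "cluster", "de", "signatures", "cmap", "proximity", "evaluate"]

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


@dataclass
class PipelineConfig:
    """Validated parameters for a full pipeline run."""

    out_dir: str = "qsp_run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)
    perturb: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    cut_level: int = 3
    stability_boot: int = 20
    de_alpha: float = 0.001
    cmap_method: str = "most_negative"
    cmap_n_perm: int = 2000
    cmap_top_n: int = 20
    cmap_fdr_alpha: float = 0.05
    proximity_n_rand: int = 200
    run_evaluate: bool = False
    classifier_alpha: float = 0.95
    eval_n_sets: int = 10
    train_frac: float = 0.7
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31)."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    A stage failure aborts the run with the failing stage named; outputs
    of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        # --- simulate -----------------------------------------------------
        stage = "simulate"
        cohort_cfg = simulate.CohortConfig(
            **{"seed": stage_seed(config.seed, "simulate"), **config.cohort}
        )
        counts, meta, pathways, categories, truth = simulate.generate_cohort(cohort_cfg)
        write_expression(counts, out / "expression.tsv")
        meta.to_csv(out / "metadata.tsv", sep="\t")
        from .io import write_gmt

        write_gmt(pathways, out / "pathways.gmt")
        write_categories(categories, out / "categories.tsv")
        written += [out / "expression.tsv", out / "metadata.tsv", out / "pathways.gmt", out / "categories.tsv"]

        # --- enrich -------------------------------------------------------
        stage = "enrich"
        logcpm = differential.log2_cpm(counts)
        es = enrichment.single_sample_enrichment(logcpm, pathways, kernel="gaussian")
        write_expression(es, out / "enrichment.tsv", index_label="pathway")
        written.append(out / "enrichment.tsv")

        # --- cluster ------------------------------------------------------
        stage = "cluster"
        assign = enrichment.cluster_samples(es, cut_level=config.cut_level)
        stability = enrichment.cluster_stability(
            es, assign, n_boot=config.stability_boot, seed=stage_seed(config.seed, "cluster")
        )
        chi2, chi2_p = enrichment.association_test(assign, meta["diagnosis"])
        assign.labels.to_frame().to_csv(out / "clusters.tsv", sep="\t")
        (out / "cluster_summary.json").write_text(
            json.dumps(
                {
                    "n_clusters": assign.n_clusters,
                    "jaccard": {str(k): v for k, v in stability.items()},
                    "chi2": chi2,
                    "chi2_p": chi2_p,
                },
                indent=2,
            )
        )
        written += [out / "clusters.tsv", out / "cluster_summary.json"]

        # --- differential -------------------------------------------------
        stage = "de"
        specs = simulate.comparison_groups(meta)
        deg, pathway_de = {}, {}
        for spec in specs:
            deg[spec.name] = differential.moderated_t(logcpm, spec)
            pathway_de[spec.name] = differential.moderated_t(es, spec)
            deg[spec.name].to_csv(out / f"de_genes_{spec.name}.tsv", sep="\t")
            pathway_de[spec.name].to_csv(out / f"de_pathways_{spec.name}.tsv", sep="\t")
            written += [out / f"de_genes_{spec.name}.tsv", out / f"de_pathways_{spec.name}.tsv"]

        # --- signatures ---------------------------------------------------
        stage = "signatures"
        sigs = signatures.build_signatures(
            deg, pathway_de, categories, pathways, alpha=config.de_alpha
        )
        signatures.export_signatures(sigs, out / "signatures.gmt")
        manifest_sigs = {
            s.index: {
                "comparison": s.comparison,
                "category": s.category,
                "n_up": len(s.up),
                "n_down": len(s.down),
            }
            for s in sigs
        }
        (out / "signatures.json").write_text(json.dumps(manifest_sigs, indent=2))
        written += [out / "signatures.gmt", out / "signatures.json"]

        # --- connectivity mapping ------------------------------------------
        stage = "cmap"
        perturb_cfg = simulate.PerturbConfig(
            **{"seed": stage_seed(config.seed, "cmap"), **config.perturb}
        )
        db, pert_truth = simulate.generate_perturbation_db(
            perturb_cfg, sigs, universe=list(counts.index)
        )
        write_perturbations(db, out / "perturbations.tsv")
        written.append(out / "perturbations.tsv")
        summaries = []
        cmap_rng = np.random.default_rng(stage_seed(config.seed, "cmap") + 1)
        for sig in sigs:
            if sig.is_empty():
                logger.warning("skipping empty signature %s in connectivity query", sig.index)
                continue
            res = cmap.score_query(db, sig)
            res = cmap.permutation_pvalues(
                db, sig, res, n_perm=config.cmap_n_perm, seed=int(cmap_rng.integers(2**31))
            )
            res.to_csv(out / f"cmap_{sig.index}.tsv", sep="\t", index=False)
            written.append(out / f"cmap_{sig.index}.tsv")
            if config.cmap_method == "max_quantile":
                summaries.append(cmap.summarize_max_quantile(res, query_id=sig.index))
            else:
                summaries.append(cmap.summarize_most_negative(res, query_id=sig.index))
        priority = cmap.prioritize(
            summaries, top_n=config.cmap_top_n, fdr_alpha=config.cmap_fdr_alpha
        )
        priority.table.to_csv(out / "priority.tsv", sep="\t", index=False)
        written.append(out / "priority.tsv")

        # --- network proximity ---------------------------------------------
        stage = "proximity"
        net_cfg = simulate.NetConfig(
            **{"seed": stage_seed(config.seed, "proximity"), **config.network}
        )
        net, drugmap, net_truth = simulate.generate_network(net_cfg)
        write_edgelist(net, out / "network.tsv")
        write_drug_targets(drugmap, out / "drug_targets.tsv")
        S = set(net.graph["disease_nodes"])
        prox_table, skipped = proximity.rank_drugs(
            net, S, drugmap, n_rand=config.proximity_n_rand,
            seed=stage_seed(config.seed, "proximity") + 1,
        )
        prox_table.to_csv(out / "proximity.tsv", sep="\t", index=False)
        pd.Series(skipped, name="drug").to_csv(out / "proximity_skipped.tsv", sep="\t", index=False)
        written += [out / "network.tsv", out / "drug_targets.tsv", out / "proximity.tsv", out / "proximity_skipped.tsv"]

        # --- classifier evaluation (optional) -------------------------------
        if config.run_evaluate:
            stage = "evaluate"
            spec = classify.ClassifierSpec(alpha=config.classifier_alpha)
            Xp, _ = classify.prepare_features(logcpm, logcpm, top_n=500)
            result = classify.bootstrap_evaluate(
                Xp,
                meta["diagnosis"],
                spec,
                n_sets=config.eval_n_sets,
                train_frac=config.train_frac,
                seed=stage_seed(config.seed, "evaluate"),
            )
            result.summary.to_csv(out / "eval_summary.tsv", sep="\t", index=False)
            result.per_set.to_csv(out / "eval_per_set.tsv", sep="\t", index=False)
            written += [out / "eval_summary.tsv", out / "eval_per_set.tsv"]

        # --- manifest -------------------------------------------------------
        manifest = {
            "seed": config.seed,
            "parameters": config.to_dict(),
            "ground_truth": truth.to_dict() | {
                "compound_reverter": pert_truth.compound_reverter,
                "drug_proximal": net_truth.drug_proximal,
            },
            "checksums": {p.name: _sha256(p) for p in written},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
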