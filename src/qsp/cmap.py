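"""Connectivity mapping: score disease gene signatures against a
perturbation database and prioritize signature-reverting compounds.

The connectivity score (CS) of a signature against one perturbation
instance combines two Kolmogorov-Smirnov enrichment statistics: ES_up for
the signature's up-regulated genes and ES_down for the down-regulated
genes, both computed on the instance's gene ranking (descending
differential score). When the two enrichment scores agree in sign the
compound neither mimics nor reverts the signature coherently and CS = 0;
otherwise CS = (ES_up - ES_down) / 2. A compound that pushes the up-genes
to the bottom of its ranking and the down-genes to the top gets CS near
-1: a predicted signature reverter.

Significance is calibrated by drawing random (instance, gene-set) pairs
matched to the query's up/down set sizes; per-compound summaries use
either the most negative CS or the max-quantile statistic (33rd/67th
percentile, larger magnitude wins).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import bh_fdr
from .io import PerturbationDB

logger = logging.getLogger("qsp")

__all__ = [
    "ks_enrichment",
    "connectivity_score",
    "score_query",
    "permutation_pvalues",
    "summarize_most_negative",
    "summarize_max_quantile",
    "prioritize",
]


def _es_from_positions(positions: np.ndarray, n: int) -> float:
    """Two-sided KS enrichment from 1-based hit positions in a ranking of n genes."""
    v = np.sort(np.asarray(positions, dtype=float))
    t = v.size
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - v / n)
    b = np.max(v / n - (j - 1) / t)
    return float(a) if a > b else float(-b)


def _weighted_es(ranked_scores: np.ndarray, hit_mask: np.ndarray) -> float:
    """Weighted (exponent 1) running-sum ES over a descending ranking."""
    w = np.abs(ranked_scores) * hit_mask
    tot = w.sum()
    if tot == 0:  # all hits have zero score: fall back to equal weights
        w = hit_mask.astype(float)
        tot = w.sum()
    n = ranked_scores.size
    nh = int(hit_mask.sum())
    step_hit = w / tot
    step_miss = np.where(hit_mask, 0.0, 1.0 / (n - nh))
    walk = np.cumsum(step_hit - step_miss)
    pos = walk.max()
    neg = walk.min()
    return float(pos) if pos > -neg else float(neg)


def ks_enrichment(profile_ranking, gene_set, weights=None) -> float:
    """KS enrichment score of ``gene_set`` within an ordered gene list.

    Parameters
    ----------
    profile_ranking : sequence of str
        Genes ordered by descending differential score.
    gene_set : iterable of str
        Query genes; must be a non-empty subset of the ranking.
    weights : array-like, optional
        Per-position scores aligned with ``profile_ranking``. When given,
        the weighted (exponent 1) running-sum variant is used instead of
        the classic unweighted two-sided KS statistic.
    """
    genes = list(profile_ranking)
    gset = set(gene_set)
    if not gset:
        raise ValueError("gene set is empty")
    missing = gset - set(genes)
    if missing:
        raise ValueError(f"gene set members absent from the ranking: {sorted(missing)}")
    if weights is not None:
        mask = np.fromiter((g in gset for g in genes), dtype=bool, count=len(genes))
        return _weighted_es(np.asarray(weights, dtype=float), mask)
    pos = np.fromiter(
        (i + 1 for i, g in enumerate(genes) if g in gset), dtype=float, count=len(gset)
    )
    return _es_from_positions(pos, len(genes))


def connectivity_score(es_up: float, es_down: float) -> float:
    """Combine up/down enrichment into the connectivity score.

    Sign-agreeing pairs give 0; an ES of exactly 0 is treated as agreeing
    with any sign (conservative). Otherwise CS = (ES_up - ES_down) / 2.
    """
    for name, v in (("es_up", es_up), ("es_down", es_down)):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} outside [-1, 1]")
    if es_up == 0.0 or es_down == 0.0:
        return 0.0
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    return (es_up - es_down) / 2.0


def _positions_of(rank_pos: pd.Series, genes) -> np.ndarray:
    return rank_pos.loc[list(genes)].to_numpy(dtype=float)


def score_query(db: PerturbationDB, sig) -> pd.DataFrame:
    """Score one signature against every instance of the database.

    Returns one row per instance with ES_up, ES_down and CS. ``sig`` needs
    ``up`` and ``down`` gene-set attributes (either may be empty, not
    both). A one-sided signature is scored by its single enrichment
    statistic: CS = ES_up when the down side is empty, CS = -ES_down when
    the up side is empty (so negative CS always means signature reversal).
    """
    up, down = set(sig.up), set(sig.down)
    if not up and not down:
        raise ValueError(f"signature {getattr(sig, 'index', '?')} is empty on both sides")
    universe = set(db.genes)
    missing = (up | down) - universe
    if missing:
        raise ValueError(f"signature genes absent from profiles: {sorted(missing)[:5]}")
    n = len(db.genes)
    rows = []
    for inst in db.instances:
        rank_pos = db.rank_positions(inst)
        es_up = _es_from_positions(_positions_of(rank_pos, up), n) if up else 0.0
        es_down = _es_from_positions(_positions_of(rank_pos, down), n) if down else 0.0
        if not down:
            cs = es_up
        elif not up:
            cs = -es_down
        else:
            cs = connectivity_score(es_up, es_down)
        rows.append((inst, es_up, es_down, cs))
    out = pd.DataFrame(rows, columns=["instance_id", "ES_up", "ES_down", "CS"])
    out = out.merge(
        db.meta[["compound_id", "cell_type"]], left_on="instance_id", right_index=True
    )
    return out


def null_cs_distribution(
    db: PerturbationDB, n_up: int, n_down: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null CS draws: random instance x random disjoint up/down gene sets."""
    n = len(db.genes)
    instances = db.instances
    out = np.empty(n_perm)
    k = n_up + n_down
    for i in range(n_perm):
        inst = instances[rng.integers(len(instances))]
        rank_pos = db.rank_positions(inst).to_numpy()
        idx = rng.choice(n, size=k, replace=False)
        pos = rank_pos[idx]
        es_up = _es_from_positions(pos[:n_up], n) if n_up else 0.0
        es_down = _es_from_positions(pos[n_up:], n) if n_down else 0.0
        if n_down == 0:
            out[i] = es_up
        elif n_up == 0:
            out[i] = -es_down
        else:
            out[i] = connectivity_score(es_up, es_down)
    return out


def permutation_pvalues(
    db: PerturbationDB,
    sig,
    results: pd.DataFrame,
    n_perm: int = 50_000,
    seed: int | None = None,
    smooth: bool = False,
) -> pd.DataFrame:
    """Attach permutation p-values and BH q-values to a score_query table.

    The null draws random (instance, gene-set) pairs with the query's
    up/down sizes; p is two-sided on |CS| with the add-one estimator.

    The null CS carries an atom at 0 (sign-agreeing enrichment pairs), so
    the default conservative estimator is uniform only below the nonzero
    mass, with the remainder at p = 1. ``smooth=True`` switches to the
    randomized p-value for discrete statistics, p = (#{|null| > |cs|} +
    U * (1 + #{|null| = |cs|})) / (n_perm + 1) with U ~ U(0,1), which is
    exactly uniform under the null; use it for calibration studies.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} gives an unstable permutation tail")
    rng = np.random.default_rng(seed)
    null = np.abs(
        null_cs_distribution(db, len(set(sig.up)), len(set(sig.down)), n_perm, rng)
    )
    null.sort()
    cs = np.abs(results["CS"].to_numpy())
    gt = n_perm - np.searchsorted(null, cs, side="right")
    ge = n_perm - np.searchsorted(null, cs, side="left")
    out = results.copy()
    if smooth:
        u = rng.random(cs.size)
        out["p"] = (gt + u * (1.0 + ge - gt)) / (n_perm + 1.0)
    else:
        out["p"] = (1.0 + ge) / (n_perm + 1.0)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def _normalize_by_cell_type(results: pd.DataFrame) -> pd.Series:
    """Divide each CS by the mean |CS| of same-signed scores in its cell type."""
    cs = results["CS"].copy().astype(float)
    for ct, grp in results.groupby("cell_type"):
        for sign in (-1, 1):
            mask = (grp["CS"] * sign) > 0
            if not mask.any():
                continue
            scale = grp.loc[mask, "CS"].abs().mean()
            if scale == 0:
                logger.warning("cell type %r: zero-variance scores, normalization skipped", ct)
                continue
            cs.loc[grp.index[mask]] = grp.loc[mask, "CS"] / scale
    return cs


def summarize_most_negative(results: pd.DataFrame, query_id: str = "") -> pd.DataFrame:
    """Per-compound summary: the minimum CS over the compound's instances."""
    rows = []
    for compound, grp in results.groupby("compound_id"):
        if len(grp) == 0:
            continue
        s = float(grp["CS"].min())
        rows.append(
            {
                "compound_id": compound,
                "query_id": query_id,
                "summary": s,
                "method": "most_negative",
                "Q_lo": s,
                "Q_hi": s,
                "n_instances": len(grp),
                "q": float(grp["q"].min()) if "q" in grp else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_max_quantile(
    results: pd.DataFrame, query_id: str = "", normalize: bool = True
) -> pd.DataFrame:
    """Per-compound max-quantile summary.

    CS values are normalized within cell type (optional), then Q_lo = 33rd
    and Q_hi = 67th linear-interpolation percentile per compound; the one
    larger in magnitude is the summary (ties go to Q_lo, favoring
    reverters).
    """
    work = results.copy()
    work["CS_norm"] = _normalize_by_cell_type(work) if normalize else work["CS"]
    rows = []
    for compound, grp in work.groupby("compound_id"):
        vals = grp["CS_norm"].to_numpy(dtype=float)
        q_lo = float(np.percentile(vals, 33))
        q_hi = float(np.percentile(vals, 67))
        summary = q_lo if abs(q_lo) >= abs(q_hi) else q_hi
        rows.append(
            {
                "compound_id": compound,
                "query_id": query_id,
                "summary": summary,
                "method": "max_quantile",
                "Q_lo": q_lo,
                "Q_hi": q_hi,
                "n_instances": len(grp),
                "q": float(grp["q"].min()) if "q" in grp else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PriorityTable:
    """Compound prioritization across signature queries."""

    table: pd.DataFrame  # compound_id, frequency, best_rank, queries_hit

    def top(self, k: int) -> pd.DataFrame:
        return self.table.head(k)


def prioritize(
    summaries: list[pd.DataFrame], top_n: int = 20, fdr_alpha: float = 0.05
) -> PriorityTable:
    """Rank compounds by frequency of appearance across query top lists.

    Per query, compounds are ranked ascending by summary score (most
    negative first); the top ``top_n`` passing q < ``fdr_alpha`` (q from
    the compound's best instance) are retained. Compounds are then ordered
    by frequency (desc), best within-query rank (asc), compound id.
    """
    if not summaries:
        raise ValueError("no query summaries supplied")
    hits: dict[str, list[tuple[str, int]]] = {}
    for summ in summaries:
        if summ.empty:
            continue
        ranked = summ.sort_values(["summary", "compound_id"]).reset_index(drop=True)
        ranked["rank"] = np.arange(1, len(ranked) + 1)
        kept = ranked.head(top_n)
        if "q" in kept and kept["q"].notna().any():
            kept = kept[kept["q"] < fdr_alpha]
        for _, row in kept.iterrows():
            hits.setdefault(row["compound_id"], []).append(
                (str(row["query_id"]), int(row["rank"]))
            )
    rows = []
    for compound, qh in hits.items():
        rows.append(
            {
                "compound_id": compound,
                "frequency": len(qh),
                "best_rank": min(r for _, r in qh),
                "queries_hit": ";".join(f"{q}:{r}" for q, r in sorted(qh, key=lambda x: x[1])),
            }
        )
    table = pd.DataFrame(rows, columns=["compound_id", "frequency", "best_rank", "queries_hit"])
    if not table.empty:
        table = table.sort_values(
            ["frequency", "best_rank", "compound_id"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return PriorityTable(table=table)
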