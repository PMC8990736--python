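"""Per-cluster KEGG-ortholog enrichment and cohort-level habitat tests.

For each KO retained in the abundance matrix, a Kruskal-Wallis test compares
per-strain copy numbers across clusters; the resulting p-values are
Bonferroni-corrected over all KOs tested (q = min(1, m*p)). Direction is a
separate axis: for each (KO, cluster), fold = cluster mean / overall mean,
with status "over"/"under" when q < alpha and fold is above/below 1, and a
"strong" flag for fold >= 2 or <= 0.5 — the conventional two-fold highlight.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pool import PprPool
from .profiles import AbundanceMatrix, ClusterAssignment

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["ko", "cluster", "cluster_mean", "overall_mean",
                      "fold", "p_value", "q_value", "status", "strong"]


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment q = min(1, m*p), with m >= len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H on mid-ranks with tie correction.

    Returns ``(H, p)`` with p from the chi-square upper tail on
    ``len(groups) - 1`` degrees of freedom. When every observation is
    identical the statistic degenerates to H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs >= 1 observation")
    if sum(len(a) for a in arrays) < 3:
        raise ValueError("need >= 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        logger.debug("kruskal_wallis: all observations identical; H=0")
        return 0.0, 1.0
    H, p = stats.kruskal(*arrays)
    return float(H), float(p)


def ko_enrichment(
    matrix: AbundanceMatrix,
    assignment: ClusterAssignment,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cluster over/under-representation of each KO.

    One global Kruskal-Wallis p-value per KO (copy numbers across clusters),
    Bonferroni-corrected over all KOs tested; per-cluster fold changes set
    the direction. Records are sorted by (cluster, descending fold).
    """
    counts = matrix.counts
    clusters = assignment.cluster_of.reindex(counts.index)
    if clusters.isna().any():
        missing = counts.index[clusters.isna()][0]
        raise ValueError(f"strain {missing} has no cluster assignment")
    labels = sorted(clusters.unique())
    kos, pvals, folds = [], [], {}
    for ko in counts.columns:
        col = counts[ko]
        overall = float(col.mean())
        if overall == 0.0:
            logger.info("ko_enrichment: %s absent everywhere; skipped", ko)
            continue
        groups = [col[clusters == lab].to_numpy() for lab in labels]
        _, p = kruskal_wallis(groups)
        kos.append(ko)
        pvals.append(p)
        folds[ko] = {lab: float(col[clusters == lab].mean()) / overall
                     for lab in labels}, overall
    q = bonferroni(pvals, m=len(kos))
    rows = []
    for ko, p, qv in zip(kos, pvals, q):
        per_cluster, overall = folds[ko]
        for lab in labels:
            fold = per_cluster[lab]
            if qv < alpha and fold > 1.0:
                status = "over"
            elif qv < alpha and fold < 1.0:
                status = "under"
            else:
                status = "ns"
            rows.append({
                "ko": ko, "cluster": int(lab),
                "cluster_mean": fold * overall, "overall_mean": overall,
                "fold": fold, "p_value": p, "q_value": float(qv),
                "status": status, "strong": bool(fold >= 2.0 or fold <= 0.5),
            })
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    if len(out):
        out = out.sort_values(["cluster", "fold"], ascending=[True, False],
                              kind="mergesort").reset_index(drop=True)
    return out


def enrichment_summary(records: pd.DataFrame) -> dict:
    """Per-cluster tallies of significant over/under-represented KOs."""
    out: dict[str, dict[str, int]] = {}
    for lab, sub in records.groupby("cluster"):
        out[str(lab)] = {
            "over": int((sub["status"] == "over").sum()),
            "under": int((sub["status"] == "under").sum()),
            "ns": int((sub["status"] == "ns").sum()),
        }
    return out


def habitat_metric_test(
    strains: pd.DataFrame,
    metric: str,
    pool: PprPool | None = None,
) -> tuple[float, float]:
    """Kruskal-Wallis of a per-strain metric grouped by habitat.

    ``metric`` is ``"genome_length"`` (genome_length_bp from the strain
    table) or ``"ppr_count"`` (per-strain pool sizes, requiring ``pool``).
    """
    if metric == "genome_length":
        values = strains.set_index("strain_id")["genome_length_bp"].astype(float)
    elif metric == "ppr_count":
        if pool is None:
            raise ValueError("metric='ppr_count' requires a PprPool")
        values = pool.per_strain_count.reindex(
            strains["strain_id"], fill_value=0).astype(float)
        values.index = strains["strain_id"]
    else:
        raise ValueError("metric must be 'genome_length' or 'ppr_count'")
    hab = strains.set_index("strain_id")["habitat"]
    groups = [values[hab == h].to_numpy() for h in sorted(hab.unique())]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need >= 2 habitats")
    return kruskal_wallis(groups)


__all__ = ["bonferroni", "kruskal_wallis", "ko_enrichment",
           "enrichment_summary", "habitat_metric_test", "ENRICHMENT_COLUMNS"]
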