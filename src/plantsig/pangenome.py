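"""Pan-genome construction: identity-cutoff derivation, gene-family
clustering from pairwise protein homology, and core/accessory classification.

The protein-clustering identity cutoff is derived from per-marker identity
matrices of a fixed set of universal bacterial core genes: for each marker the
off-diagonal minimum and maximum percent identity are taken, averaged over
markers, and the mean minimum is rounded down to the nearest multiple of 5 to
give an operative cutoff (70% for a typical congeneric cohort).

Gene families are single-linkage connected components over homology hits that
pass the identity cutoff and a query-coverage floor. This is a deliberately
simple surrogate for a full pan-genome pipeline: it preserves the property
actually used downstream — which families are present in every strain (core)
and which are accessory — without paralog splitting or synteny.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .io import gene_key, query_coverage


@dataclass
class CutoffReport:
    """Summary of the marker-based identity-cutoff derivation."""

    per_marker_min: dict[str, float]
    per_marker_max: dict[str, float]
    mean_min: float
    mean_max: float
    chosen_cutoff: float

    def to_dict(self) -> dict:
        return {
            "per_marker_min": self.per_marker_min,
            "per_marker_max": self.per_marker_max,
            "mean_min": self.mean_min,
            "mean_max": self.mean_max,
            "chosen_cutoff": self.chosen_cutoff,
        }


@dataclass
class FamilyAssignment:
    """A total partition of the gene universe into families.

    ``frame`` has one row per gene with columns strain_id, gene_id,
    family_id, is_core. A family id is the lexicographically smallest
    ``strain|gene`` key among its members, which makes assignments
    independent of input order.
    """

    frame: pd.DataFrame
    core_families: set[str] = field(default_factory=set)

    @property
    def family_of(self) -> pd.Series:
        keyed = self.frame.set_index(["strain_id", "gene_id"])
        return keyed["family_id"]

    def members(self, family_id: str) -> set[tuple[str, str]]:
        sub = self.frame[self.frame["family_id"] == family_id]
        return set(zip(sub["strain_id"], sub["gene_id"]))

    def n_families(self) -> int:
        return self.frame["family_id"].nunique()


def derive_identity_cutoff(matrices: dict[str, pd.DataFrame]) -> CutoffReport:
    """Derive the protein-clustering identity cutoff from marker matrices.

    Parameters
    ----------
    matrices
        Mapping of marker id to a square symmetric percent-identity matrix
        (strain ids on both axes, 100 on the diagonal).

    The chosen cutoff is ``mean_min`` rounded down to the nearest multiple
    of 5, so a cohort whose weakest marker identities average in [70, 75)
    yields the operative 70% threshold.
    """
    if not matrices:
        raise ValueError("need at least one marker identity matrix")
    per_min: dict[str, float] = {}
    per_max: dict[str, float] = {}
    for marker, df in matrices.items():
        m = np.asarray(df, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] < 2:
            raise ValueError(f"marker {marker}: matrix must be square with >=2 strains")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError(f"marker {marker}: identity matrix is not symmetric")
        if not np.allclose(np.diag(m), 100.0, atol=1e-9):
            raise ValueError(f"marker {marker}: diagonal must be 100")
        off = m[~np.eye(m.shape[0], dtype=bool)]
        per_min[marker] = float(off.min())
        per_max[marker] = float(off.max())
    mean_min = float(np.mean(list(per_min.values())))
    mean_max = float(np.mean(list(per_max.values())))
    chosen = 5.0 * math.floor(mean_min / 5.0)
    return CutoffReport(per_min, per_max, mean_min, mean_max, chosen)


def _sort_codes(arr: np.ndarray) -> np.ndarray:
    """Integer codes ranking ``arr`` values in lexicographic order."""
    codes, uniques = pd.factorize(arr)
    rank = np.empty(len(uniques), dtype=np.int64)
    rank[np.argsort(uniques)] = np.arange(len(uniques))
    return rank[codes]


def cluster_gene_families(
    hits: pd.DataFrame,
    cutoff_pct: float,
    min_coverage_pct: float,
    genes: pd.DataFrame,
) -> FamilyAssignment:
    """Partition genes into families by single-linkage over qualifying hits.

    An undirected edge joins two genes when any hit between them has
    ``pident >= cutoff_pct`` and query coverage ``>= min_coverage_pct``
    (both inclusive); families are the connected components, and genes with
    no qualifying edge form singleton families.

    Parameters
    ----------
    hits
        Bacteria-vs-bacteria hits with ``strain|gene`` keys in qseqid/sseqid.
    genes
        The gene universe (gene table with strain_id/gene_id); every hit
        endpoint must resolve to a listed gene.
    """
    strain_arr0 = genes["strain_id"].astype(str).to_numpy()
    gene_arr0 = genes["gene_id"].astype(str).to_numpy()
    keys = np.array([f"{s}|{g}" for s, g in zip(strain_arr0, gene_arr0)],
                    dtype=object)
    index = pd.Index(keys)
    if index.has_duplicates:
        raise ValueError("duplicate gene keys in gene universe")
    n = len(index)
    if len(hits):
        qi = index.get_indexer(hits["qseqid"])
        si = index.get_indexer(hits["sseqid"])
        unknown = hits.loc[(qi < 0) | (si < 0)]
        if len(unknown):
            row = unknown.iloc[0]
            raise ValueError(
                f"hit references unknown gene: {row['qseqid']} vs {row['sseqid']}")
        ok = (hits["pident"].to_numpy() >= cutoff_pct) & (
            query_coverage(hits).to_numpy() >= min_coverage_pct)
        qi, si = qi[ok], si[ok]
    else:
        qi = si = np.empty(0, dtype=int)
    graph = coo_matrix((np.ones(len(qi)), (qi, si)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    # family id: lexicographically smallest (strain_id, gene_id) member
    # (sort integer rank codes; direct lexsort on object arrays is slow)
    order = np.lexsort((_sort_codes(gene_arr0), _sort_codes(strain_arr0)))
    firsts = pd.Series(keys[order]).groupby(labels[order], sort=False).first()
    family_ids = firsts.reindex(labels).to_numpy()
    frame = pd.DataFrame({
        "strain_id": strain_arr0,
        "gene_id": gene_arr0,
        "family_id": family_ids,
        "is_core": False,
    })
    return FamilyAssignment(frame=frame)


def assignment_from_orthogroups(genes: pd.DataFrame) -> FamilyAssignment:
    """Family assignment taken directly from precomputed orthogroup labels.

    A fast path for cohorts whose annotations already carry orthogroup
    membership (e.g. Orthofinder output): each orthogroup is one family,
    genes without an orthogroup become singletons. Family ids follow the
    same smallest-member rule as :func:`cluster_gene_families`.
    """
    strain_arr = genes["strain_id"].astype(str).to_numpy()
    gene_arr = genes["gene_id"].astype(str).to_numpy()
    keys = np.array([f"{s}|{g}" for s, g in zip(strain_arr, gene_arr)],
                    dtype=object)
    og = genes["orthogroup"].fillna("").astype(str).to_numpy()
    labels_arr = np.where(og == "", keys, og)
    labels, _ = pd.factorize(labels_arr)
    order = np.lexsort((_sort_codes(gene_arr), _sort_codes(strain_arr)))
    firsts = pd.Series(keys[order]).groupby(labels[order], sort=False).first()
    frame = pd.DataFrame({
        "strain_id": strain_arr, "gene_id": gene_arr,
        "family_id": firsts.reindex(labels).to_numpy(), "is_core": False,
    })
    return FamilyAssignment(frame=frame)


def classify_core(
    assignment: FamilyAssignment,
    strains: pd.DataFrame,
    core_fraction: float = 1.0,
) -> set[str]:
    """Flag families present in at least ``core_fraction`` of strains as core.

    A family counts as present in a strain when it has >= 1 member there.
    The default requires presence in every strain; ``core_fraction`` may be
    relaxed toward common pan-genome conventions (e.g. 0.99).
    """
    if not (0.0 < core_fraction <= 1.0):
        raise ValueError("core_fraction must lie in (0, 1]")
    n_strains = strains["strain_id"].nunique()
    present = assignment.frame.groupby("family_id")["strain_id"].nunique()
    core = set(present.index[present >= core_fraction * n_strains - 1e-9])
    assignment.core_families = core
    assignment.frame["is_core"] = assignment.frame["family_id"].isin(core)
    return core


def families_to_frame(assignment: FamilyAssignment) -> pd.DataFrame:
    """families.tsv payload: strain_id, gene_id, family_id, is_core."""
    return assignment.frame.copy()


def gene_key_frame(genes: pd.DataFrame) -> pd.Series:
    """``strain|gene`` keys for a gene table, in row order."""
    return pd.Series(
        [f"{s}|{g}" for s, g in zip(genes["strain_id"].astype(str),
                                    genes["gene_id"].astype(str))],
        index=genes.index)


__all__ = [
    "CutoffReport", "FamilyAssignment", "derive_identity_cutoff",
    "cluster_gene_families", "assignment_from_orthogroups", "classify_core",
    "families_to_frame", "gene_key", "gene_key_frame",
]
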