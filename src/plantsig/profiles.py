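"""Functional profiling of the plant-related gene pool and strain clustering.

Strains are profiled as COG-category or KEGG-ortholog (KO) count matrices
over their pooled plant-related genes, reduced by standardized PCA, and
grouped by Ward agglomeration in component space — the "hierarchical
clustering on principal components" (HCPC) recipe. Habitat association of
the resulting clusters is tested with a Pearson chi-square on the
habitat x cluster contingency table, reported together with adjusted
standardized residuals to localize the association cell by cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .pool import PprPool

logger = logging.getLogger(__name__)


@dataclass
class AbundanceMatrix:
    """Per-strain feature counts over the plant-related pool."""

    counts: pd.DataFrame  # strains x features, nonnegative ints
    feature_kind: str  # "cog_category" or "ko"

    @property
    def strain_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class PcaResult:
    """Standardized PCA with FactoMineR-style variable contributions.

    ``scores @ loadings.T`` reconstructs the centered/scaled input;
    ``contributions_pct`` gives each feature's squared-loading share of a
    component, summing to 100 per component.
    """

    scores: pd.DataFrame  # strains x components
    loadings: pd.DataFrame  # features x components
    variance_pct: pd.Series  # per component, sums to 100
    contributions_pct: pd.DataFrame  # features x components
    dropped_features: list[str]


@dataclass
class ClusterAssignment:
    cluster_of: pd.Series  # strain -> cluster label in 1..k
    k: int
    linkage_record: np.ndarray  # scipy linkage matrix


@dataclass
class ChiSquareReport:
    observed: pd.DataFrame  # habitat x cluster
    expected: pd.DataFrame
    statistic: float
    df: int
    p_value: float
    adj_std_residuals: pd.DataFrame
    low_expected: bool  # any expected cell < 5

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "observed": self.observed.to_dict(),
            "expected": self.expected.to_dict(),
            "adj_std_residuals": self.adj_std_residuals.to_dict(),
            "low_expected": self.low_expected,
        }


def build_abundance_matrix(
    pool: PprPool,
    genes: pd.DataFrame,
    feature_kind: str,
    strains: list[str] | None = None,
) -> AbundanceMatrix:
    """Tally pool genes per strain and feature.

    A gene annotated with several COG letters increments each of them. For
    ``feature_kind="ko"``, KOs present in fewer than two strains are dropped
    (unique-strain features carry no comparative signal).
    """
    if feature_kind not in ("cog_category", "ko"):
        raise ValueError("feature_kind must be 'cog_category' or 'ko'")
    members = pool.frame[["strain_id", "gene_id"]]
    ann = members.merge(genes, on=["strain_id", "gene_id"], how="left")
    if feature_kind == "ko":
        ann = ann[ann["ko"].fillna("").astype(str) != ""]
        pairs = ann[["strain_id", "ko"]].rename(columns={"ko": "feature"})
    else:
        letters = ann["cog_category"].fillna("").astype(str).map(list)
        pairs = pd.DataFrame({
            "strain_id": ann["strain_id"].repeat(letters.map(len)),
            "feature": [c for gene in letters for c in gene],
        })
    table = pd.crosstab(pairs["strain_id"], pairs["feature"])
    if strains is not None:
        table = table.reindex(index=strains, fill_value=0)
    table = table.sort_index().sort_index(axis=1)
    if feature_kind == "ko":
        n_strains_with = (table > 0).sum(axis=0)
        table = table.loc[:, n_strains_with >= 2]
    table.index.name = "strain_id"
    table.columns.name = feature_kind
    return AbundanceMatrix(counts=table.astype(int), feature_kind=feature_kind)


def run_pca(matrix: AbundanceMatrix | pd.DataFrame, scale: bool = True) -> PcaResult:
    """Standardized PCA via SVD of the centered (and scaled) count matrix.

    Zero-variance columns are removed (and logged) before scaling. The sign
    of each component is fixed so that its largest-magnitude loading is
    positive, making output platform-independent.
    """
    counts = matrix.counts if isinstance(matrix, AbundanceMatrix) else matrix
    X = counts.astype(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs >=2 strains and >=2 features")
    sd = X.std(axis=0, ddof=1)
    dropped = list(X.columns[sd == 0.0])
    if dropped:
        logger.info("run_pca: dropping %d zero-variance features", len(dropped))
        X = X.loc[:, sd > 0.0]
        sd = sd[sd > 0.0]
    if X.shape[1] == 0:
        raise ValueError("all features have zero variance")
    Z = X - X.mean(axis=0)
    if scale:
        Z = Z / sd
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    comp = [f"PC{i + 1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=X.index, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=comp)
    var = S**2
    variance_pct = pd.Series(100.0 * var / var.sum(), index=comp)
    contributions = pd.DataFrame(100.0 * Vt.T**2, index=X.columns, columns=comp)
    return PcaResult(scores, loadings, variance_pct, contributions, dropped)


def _n_components(pca: PcaResult, k: int, n_components) -> int:
    avail = pca.scores.shape[1]
    if n_components == "auto":
        # as many components as clusters sought: enough dimensions to
        # separate k groups while shedding the near-isotropic noise bulk
        return max(1, min(k, avail))
    if n_components == "var80":
        cum = pca.variance_pct.cumsum()
        return int(np.searchsorted(cum.to_numpy(), 80.0 - 1e-9) + 1)
    n = int(n_components)
    if not (1 <= n <= avail):
        raise ValueError(f"n_components must lie in [1, {avail}]")
    return n


def hierarchical_clusters(
    pca: PcaResult,
    k: int,
    n_components: int | str = "auto",
) -> ClusterAssignment:
    """Ward agglomeration on the leading PCA scores, cut at ``k`` clusters.

    Clusters are renumbered by decreasing size (ties broken by the smallest
    member strain id) so that cluster 1 is always the largest.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_strains = pca.scores.shape[0]
    if k > n_strains:
        raise ValueError("k cannot exceed the number of strains")
    ncp = _n_components(pca, k, n_components)
    X = pca.scores.iloc[:, :ncp].to_numpy()
    if n_strains == 1 or k == n_strains:
        raw = np.arange(1, n_strains + 1)
        Z = np.empty((0, 4))
    else:
        Z = linkage(X, method="ward")
        raw = fcluster(Z, t=k, criterion="maxclust")
    strains = pd.Series(pca.scores.index.astype(str), index=pca.scores.index)
    sizes = pd.Series(raw).groupby(raw).size()
    smallest_member = {
        lab: strains.to_numpy()[raw == lab].min() for lab in sizes.index}
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], smallest_member[lab]))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    cluster_of = pd.Series([relabel[c] for c in raw], index=pca.scores.index,
                           name="cluster")
    return ClusterAssignment(cluster_of=cluster_of, k=int(cluster_of.max()),
                             linkage_record=Z)


def habitat_association(
    assignment: ClusterAssignment,
    strains: pd.DataFrame,
) -> ChiSquareReport:
    """Pearson chi-square of habitat vs cluster with adjusted residuals.

    Expected counts come from the product of the margins; adjusted
    standardized residuals (O-E)/sqrt(E(1-row/n)(1-col/n)) localize which
    habitat-cluster cells drive the association. A warning is raised when
    any expected cell is below 5 (the asymptotic p-value is then rough).
    """
    hab = strains.set_index("strain_id")["habitat"]
    cl = assignment.cluster_of
    common = cl.index.intersection(hab.index)
    observed = pd.crosstab(hab.loc[common], cl.loc[common])
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError(
            "degenerate contingency table: need >=2 habitats and >=2 clusters")
    res = stats.chi2_contingency(observed.to_numpy(), correction=False)
    expected = pd.DataFrame(res.expected_freq, index=observed.index,
                            columns=observed.columns)
    n = observed.to_numpy().sum()
    row = observed.sum(axis=1).to_numpy()[:, None] / n
    col = observed.sum(axis=0).to_numpy()[None, :] / n
    denom = np.sqrt(expected.to_numpy() * (1 - row) * (1 - col))
    adj = (observed.to_numpy() - expected.to_numpy()) / denom
    adj = pd.DataFrame(adj, index=observed.index, columns=observed.columns)
    low = bool((expected.to_numpy() < 5).any())
    if low:
        warnings.warn("chi-square: some expected cells < 5; p-value is approximate",
                      stacklevel=2)
    return ChiSquareReport(
        observed=observed, expected=expected, statistic=float(res.statistic),
        df=int(res.dof), p_value=float(res.pvalue), adj_std_residuals=adj,
        low_expected=low)


__all__ = [
    "AbundanceMatrix", "PcaResult", "ClusterAssignment", "ChiSquareReport",
    "build_abundance_matrix", "run_pca", "hierarchical_clusters",
    "habitat_association",
]
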