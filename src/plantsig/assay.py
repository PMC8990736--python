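"""Statistics for the plant inoculation assay.

Four growth parameters per plant (root length, rosette diameter, flower and
fruit counts) are Z-score standardized over the whole plant pool, summed into
an accumulated score per treatment (strain or control), compared across
treatments by Kruskal-Wallis per parameter, and related to treatments by a
PCA over the treatment-mean standardized profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .enrichment import bonferroni, kruskal_wallis
from .io import ASSAY_PARAMETERS, validate_assay
from .profiles import PcaResult, run_pca


@dataclass
class AssayZScores:
    """Standardized assay measurements.

    ``z`` holds one row per plant with the four parameters standardized to
    mean 0, sample (n-1) SD 1 over the pooled plants; ``accumulated`` sums
    each treatment's Z-scores over its plants and all four parameters —
    a single growth-promotion score per strain.
    """

    z: pd.DataFrame  # treatment, plant_id, four z-scored parameters
    accumulated: pd.Series  # treatment -> summed z


def zscore_standardize(
    measurements: pd.DataFrame,
    include_control: bool = True,
) -> AssayZScores:
    """Standardize each growth parameter over the pooled plants.

    ``include_control=False`` drops control plants before computing the
    pooling mean/SD (they are then absent from the result entirely).
    """
    df = validate_assay(measurements)
    if not include_control:
        df = df[df["treatment"] != "control"]
    if len(df) < 2:
        raise ValueError("need >= 2 plants to standardize")
    z = df[["treatment", "plant_id"]].copy()
    for param in ASSAY_PARAMETERS:
        x = df[param].astype(float)
        sd = x.std(ddof=1)
        if sd == 0.0:
            raise ValueError(f"parameter {param} has zero variance")
        z[param] = (x - x.mean()) / sd
    accumulated = z.groupby("treatment")[ASSAY_PARAMETERS].sum().sum(axis=1)
    return AssayZScores(z=z, accumulated=accumulated)


def assay_tests(
    z: AssayZScores,
    bonferroni_correct: bool = False,
) -> dict[str, dict[str, float]]:
    """Kruskal-Wallis across treatments, one test per growth parameter.

    Returns ``{parameter: {"H": ..., "p": ...[, "q": ...]}}``; the optional
    Bonferroni correction spans the four parameters.
    """
    treatments = z.z["treatment"]
    if treatments.nunique() < 2:
        raise ValueError("need >= 2 treatments")
    out: dict[str, dict[str, float]] = {}
    for param in ASSAY_PARAMETERS:
        groups = [z.z.loc[treatments == t, param].to_numpy()
                  for t in sorted(treatments.unique())]
        H, p = kruskal_wallis(groups)
        out[param] = {"H": H, "p": p}
    if bonferroni_correct:
        q = bonferroni([out[p]["p"] for p in ASSAY_PARAMETERS])
        for param, qv in zip(ASSAY_PARAMETERS, q):
            out[param]["q"] = float(qv)
    return out


def assay_pca(
    measurements: pd.DataFrame,
    include_control: bool = True,
) -> PcaResult:
    """PCA of treatments against growth parameters.

    Rows are treatment means of the standardized parameters (already on a
    common scale, so column scaling is off). Requires >= 3 treatments.
    """
    z = zscore_standardize(measurements, include_control=include_control)
    means = z.z.groupby("treatment")[ASSAY_PARAMETERS].mean()
    if means.shape[0] < 3:
        raise ValueError("need >= 3 treatments for assay PCA")
    return run_pca(means, scale=False)


def scores_frame(z: AssayZScores) -> pd.DataFrame:
    """assay_scores.tsv payload: treatment, accumulated_z, rank (1 = best)."""
    acc = z.accumulated.sort_values(ascending=False)
    return pd.DataFrame({
        "treatment": acc.index,
        "accumulated_z": acc.to_numpy(),
        "rank": range(1, len(acc) + 1),
    })


__all__ = ["AssayZScores", "zscore_standardize", "assay_tests", "assay_pca",
           "scores_frame"]
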