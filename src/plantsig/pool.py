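"""Assembly of the putative plant-related (PPR) gene pool.

Three ingredients feed the pool:

* **PRB tagging** — a bacterial gene is a "plant-resembling bacterial gene"
  when at least one of its hits against the plant proteome passes all of
  E-value <= 1e-30, query coverage >= 70% and identity >= 30% (inclusive).
* **Catalog screening** — genes whose annotations (KO, Pfam, TIGRFAM,
  orthogroup or COG) match a plant-associated feature from a published
  catalog of bacterial plant-adaptation features, keeping only features
  supported by two or more of the catalog's statistical approaches.
* **Core subtraction** — genes belonging to core families are present in
  every strain, hence not habitat-differential, and are removed last from
  the union of the first two sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import query_coverage
from .pangenome import FamilyAssignment

GeneKey = tuple[str, str]


@dataclass
class PrbThresholds:
    """Plant-proteome homology thresholds for PRB tagging (all inclusive)."""

    max_evalue: float = 1e-30
    min_coverage_pct: float = 70.0
    min_identity_pct: float = 30.0

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        for v in (self.min_coverage_pct, self.min_identity_pct):
            if not (0.0 < v <= 100.0):
                raise ValueError("percentage thresholds must lie in (0, 100]")


@dataclass
class PprPool:
    """The assembled plant-related gene pool.

    ``frame`` has one row per member gene with columns strain_id, gene_id,
    is_prb, is_gfobap; every member has at least one flag set, and no
    member belongs to a core family.
    """

    frame: pd.DataFrame
    per_strain_count: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    @property
    def members(self) -> set[GeneKey]:
        return set(zip(self.frame["strain_id"], self.frame["gene_id"]))

    def __len__(self) -> int:
        return len(self.frame)


def filter_prb(hits: pd.DataFrame, thresholds: PrbThresholds | None = None) -> set[GeneKey]:
    """Tag plant-resembling bacterial genes from bacteria-vs-plant hits.

    A gene passes when *any* of its hits satisfies every threshold; the
    retained set therefore only grows as thresholds are relaxed.
    """
    thresholds = thresholds or PrbThresholds()
    if not len(hits):
        return set()
    ok = (
        (hits["evalue"] <= thresholds.max_evalue)
        & (query_coverage(hits) >= thresholds.min_coverage_pct)
        & (hits["pident"] >= thresholds.min_identity_pct)
    )
    if not ok.any():
        return set()
    passing = hits.loc[ok, "qseqid"].str.partition("|")
    return set(zip(passing[0], passing[2]))


def screen_gfobap(
    genes: pd.DataFrame,
    features: pd.DataFrame,
    min_support: int = 2,
) -> set[GeneKey]:
    """Flag genes whose annotations match a retained plant-associated feature.

    Features are retained when ``plant_associated`` and supported by at least
    ``min_support`` statistical approaches. A gene matches via its KO, any
    Pfam or TIGRFAM id, its orthogroup, or any of its COG category letters.
    """
    kept = features[(features["plant_associated"]) & (features["n_support"] >= min_support)]
    by_type = {t: set(kept.loc[kept["feature_type"] == t, "feature_id"])
               for t in ("ko", "pfam", "tigrfam", "orthogroup", "cog")}
    flagged = pd.Series(False, index=genes.index)
    if by_type["ko"]:
        flagged |= genes["ko"].isin(by_type["ko"])
    if by_type["orthogroup"]:
        flagged |= genes["orthogroup"].isin(by_type["orthogroup"])
    for col, t in (("pfam_ids", "pfam"), ("tigrfam_ids", "tigrfam")):
        retained = by_type[t]
        if retained:
            flagged |= genes[col].str.split(";").map(
                lambda ids: any(i in retained for i in ids if i))
    if by_type["cog"]:
        flagged |= genes["cog_category"].map(
            lambda s: any(c in by_type["cog"] for c in str(s)))
    sub = genes.loc[flagged]
    return set(zip(sub["strain_id"], sub["gene_id"]))


def assemble_ppr(
    prb: set[GeneKey],
    gfobap_flagged: set[GeneKey],
    assignment: FamilyAssignment,
) -> PprPool:
    """Pool PRB and catalog-flagged genes and subtract core-family members."""
    union = sorted(prb | gfobap_flagged)
    if not union:
        return PprPool(frame=pd.DataFrame(
            columns=["strain_id", "gene_id", "is_prb", "is_gfobap"]))
    cand = pd.DataFrame(union, columns=["strain_id", "gene_id"])
    cand["is_prb"] = [p in prb for p in union]
    cand["is_gfobap"] = [p in gfobap_flagged for p in union]
    merged = cand.merge(assignment.frame[["strain_id", "gene_id", "is_core"]],
                        on=["strain_id", "gene_id"], how="left")
    missing = merged["is_core"].isna()
    if missing.any():
        row = merged.loc[missing].iloc[0]
        raise ValueError(
            f"gene missing from family assignment: "
            f"({row['strain_id']}, {row['gene_id']})")
    frame = (merged.loc[~merged["is_core"].astype(bool),
                        ["strain_id", "gene_id", "is_prb", "is_gfobap"]]
             .reset_index(drop=True))
    counts = frame.groupby("strain_id").size()
    return PprPool(frame=frame, per_strain_count=counts)


__all__ = ["PrbThresholds", "PprPool", "filter_prb", "screen_gfobap", "assemble_ppr"]
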