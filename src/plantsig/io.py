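"""Tabular readers and writers for the cohort data model.

All tables are UTF-8, tab-separated pandas DataFrames. Every table except the
homology-hit format carries a mandatory header. Homology hits use the standard
12-column BLAST tabular layout (``outfmt 6``) extended with the query length
as a 13th column, because query coverage cannot be derived from the default
12 columns. Coordinates are 1-based inclusive, per BLAST convention.

Schemas
-------
strains.tsv          strain_id, habitat, genome_length_bp, n_genes
genes.tsv            strain_id, gene_id, cog_category, ko, pfam_ids,
                     tigrfam_ids, orthogroup  (multi-valued fields are
                     ``;``-joined; empty string means absent)
gfobap_features.tsv  feature_id, feature_type, n_support, plant_associated
assay.tsv            treatment, plant_id, root_length, rosette_diameter,
                     n_flowers, n_fruits
hits_*.b6            headerless, 13 columns (see ``B6_COLUMNS``)
identity matrices    square TSV, strain ids as header row and first column
"""

from __future__ import annotations

import pandas as pd

HABITATS = ("plant_associated", "soil_rhizosphere", "marine_mangrove", "other")

#: The 25 single-letter COG functional categories (no "X").
COG_ALPHABET = frozenset("ABCDEFGHIJKLMNOPQRSTUVWYZ")

FEATURE_TYPES = ("pfam", "tigrfam", "ko", "cog", "orthogroup")

#: BLAST tabular columns, standard 12 plus qlen.
B6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen",
]

STRAIN_COLUMNS = ["strain_id", "habitat", "genome_length_bp", "n_genes"]
GENE_COLUMNS = ["strain_id", "gene_id", "cog_category", "ko",
                "pfam_ids", "tigrfam_ids", "orthogroup"]
GFOBAP_COLUMNS = ["feature_id", "feature_type", "n_support", "plant_associated"]
ASSAY_COLUMNS = ["treatment", "plant_id", "root_length", "rosette_diameter",
                 "n_flowers", "n_fruits"]

ASSAY_PARAMETERS = ["root_length", "rosette_diameter", "n_flowers", "n_fruits"]


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing columns {missing}")


def validate_strains(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, STRAIN_COLUMNS, "strain table")
    dup = df["strain_id"][df["strain_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate strain_id: {sorted(dup.unique())}")
    bad = sorted(set(df["habitat"]) - set(HABITATS))
    if bad:
        raise ValueError(
            f"unknown habitat {bad}; allowed values are {list(HABITATS)}")
    if (df["genome_length_bp"] <= 0).any() or (df["n_genes"] <= 0).any():
        raise ValueError("genome_length_bp and n_genes must be positive")
    return df


def read_strains(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"strain_id": str, "habitat": str})
    return validate_strains(df)


def write_strains(df: pd.DataFrame, path) -> None:
    validate_strains(df)
    df.to_csv(path, sep="\t", index=False, columns=STRAIN_COLUMNS)


def validate_genes(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, GENE_COLUMNS, "gene table")
    if df.duplicated(["strain_id", "gene_id"]).any():
        dup = df[df.duplicated(["strain_id", "gene_id"])].iloc[0]
        raise ValueError(
            f"duplicate gene key ({dup['strain_id']}, {dup['gene_id']})")
    letters = set("".join(df["cog_category"].fillna("").astype(str)))
    bad = letters - COG_ALPHABET
    if bad:
        raise ValueError(f"cog_category letters outside COG alphabet: {sorted(bad)}")
    return df


def read_genes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return validate_genes(df)


def write_genes(df: pd.DataFrame, path) -> None:
    validate_genes(df)
    df.to_csv(path, sep="\t", index=False, columns=GENE_COLUMNS)


def read_hits(path) -> pd.DataFrame:
    """Read 13-column BLAST tabular hits (12 standard columns plus qlen)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=B6_COLUMNS,
                         dtype={"qseqid": str, "sseqid": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=B6_COLUMNS)
    return validate_hits(df)


def validate_hits(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, B6_COLUMNS, "hit table")
    bad = df.index[(df["qstart"] > df["qend"]) | (df["qend"] > df["qlen"])
                   | (df["qstart"] < 1)]
    if len(bad):
        raise ValueError(
            f"hit line {bad[0] + 1}: requires 1 <= qstart <= qend <= qlen")
    if (df["pident"] < 0).any() or (df["pident"] > 100).any():
        raise ValueError("pident must lie in [0, 100]")
    if (df["evalue"] < 0).any():
        raise ValueError("evalue must be nonnegative")
    return df


def write_hits(df: pd.DataFrame, path) -> None:
    validate_hits(df)
    df.to_csv(path, sep="\t", index=False, header=False, columns=B6_COLUMNS)


def query_coverage(hits: pd.DataFrame) -> pd.Series:
    """Percent of the query covered by the alignment, in (0, 100]."""
    return 100.0 * (hits["qend"] - hits["qstart"] + 1) / hits["qlen"]


def validate_gfobap(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, GFOBAP_COLUMNS, "feature table")
    if df.duplicated(["feature_id", "feature_type"]).any():
        raise ValueError("duplicate (feature_id, feature_type)")
    bad = sorted(set(df["feature_type"]) - set(FEATURE_TYPES))
    if bad:
        raise ValueError(f"unknown feature_type {bad}")
    if (df["n_support"] < 0).any():
        raise ValueError("n_support must be nonnegative")
    return df


def read_gfobap(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"feature_id": str, "feature_type": str,
                            "n_support": int, "plant_associated": bool})
    return validate_gfobap(df)


def write_gfobap(df: pd.DataFrame, path) -> None:
    validate_gfobap(df)
    df.to_csv(path, sep="\t", index=False, columns=GFOBAP_COLUMNS)


def validate_assay(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ASSAY_COLUMNS, "assay table")
    if df.duplicated(["treatment", "plant_id"]).any():
        raise ValueError("duplicate (treatment, plant_id)")
    if (df[["root_length", "rosette_diameter"]] <= 0).any().any():
        raise ValueError("root_length and rosette_diameter must be positive")
    if (df[["n_flowers", "n_fruits"]] < 0).any().any():
        raise ValueError("n_flowers and n_fruits must be nonnegative")
    return df


def read_assay(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"treatment": str, "plant_id": str})
    return validate_assay(df)


def write_assay(df: pd.DataFrame, path) -> None:
    validate_assay(df)
    df.to_csv(path, sep="\t", index=False, columns=ASSAY_COLUMNS)


def read_identity_matrix(path) -> pd.DataFrame:
    """Read one per-marker square identity matrix (strain ids on both axes)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("identity matrix row and column strain ids differ")
    return df


def write_identity_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def gene_key(strain_id: str, gene_id: str) -> str:
    """Encode a (strain_id, gene_id) pair as the ``strain|gene`` key used in
    homology-hit files."""
    return f"{strain_id}|{gene_id}"


def split_gene_key(key: str) -> tuple[str, str]:
    strain_id, _, g = key.partition("|")
    if not g:
        raise ValueError(f"not a strain|gene key: {key!r}")
    return strain_id, g
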