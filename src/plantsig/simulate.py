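"""Synthetic cohort generator with known planted truth.

Emulates the statistical structure of a ~74-strain actinobacterial cohort
sampled from four habitats: per-strain gene inventories around 6,400 genes,
a core genome of 992 single-copy families shared by every strain, KEGG
orthologs whose copy numbers carry a planted habitat signal, plant-proteome
homology hits whose scores straddle the PRB thresholds so that an expected
307 genes per plant-associated strain pass, marker identity matrices whose
mean off-diagonal minimum sits just above 70%, a plant-adaptation feature
catalog, and a plant growth assay with habitat-ordered effects.

Every quantity the pipeline later recovers (core families, signature KOs,
PRB genes, catalog-flagged genes) is recorded in a :class:`SyntheticTruth`
built from the generator's own bookkeeping, so recovery can be scored
without re-running any pipeline logic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as psio

HABITAT_PREFIX = {
    "plant_associated": "PA",
    "soil_rhizosphere": "SR",
    "marine_mangrove": "MM",
    "other": "OT",
}

#: COG letter weights for synthetic genes; tilted toward the categories that
#: dominate plant-related pools (carbohydrate metabolism G, transcription K,
#: secondary metabolism Q, inorganic ion transport P).
_COG_LETTERS = list("GKQPECFHIJLMNOTUVR")
_COG_WEIGHTS = np.array(
    [0.18, 0.12, 0.08, 0.06, 0.08, 0.06, 0.05, 0.05, 0.04, 0.04,
     0.05, 0.04, 0.04, 0.04, 0.03, 0.02, 0.01, 0.01])
_COG_WEIGHTS = _COG_WEIGHTS / _COG_WEIGHTS.sum()

_ASSAY_BASE = {  # (mean, sd) per growth parameter, control conditions
    "root_length": (50.0, 10.0),
    "rosette_diameter": (30.0, 6.0),
    "n_flowers": (8.0, 3.0),
    "n_fruits": (5.0, 2.0),
}


@dataclass
class CohortSimConfig:
    """Generative conditions for one synthetic cohort.

    Defaults reproduce the study scale: 25/29/14/6 strains across the four
    habitats, ~6,407 genes per genome (SD 300), 992 single-copy core
    families, 92 core markers, 40 habitat-signature KOs at 2.5-fold over a
    base Poisson copy rate of 2.0, and an expected 307 PRB genes per
    plant-associated strain (lower elsewhere).
    """

    n_per_habitat: dict[str, int] = field(default_factory=lambda: {
        "plant_associated": 25, "soil_rhizosphere": 29,
        "marine_mangrove": 14, "other": 6})
    mean_genes: int = 6407
    sd_genes: float = 300.0
    n_core_families: int = 992
    n_accessory_families: int = 4000
    n_markers: int = 92
    n_signature_kos: int = 40
    n_background_kos: int = 260
    signature_fold: float = 2.5
    base_ko_rate: float = 2.0
    prb_target_per_strain: int = 307
    prb_target_other: int = 230
    marker_identity_range: tuple[float, float] = (72.0, 98.0)
    n_pfam_pool: int = 500
    n_plant_pfams: int = 30
    pfam_prob: float = 0.10
    tigrfam_prob: float = 0.02
    n_plant_orthogroups: int = 10
    assay_effects: tuple[float, float, float] = (1.0, 0.4, 0.0)
    n_plants_per_treatment: int = 40
    n_assay_strains_per_habitat: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_per_habitat.values()):
            raise ValueError("habitat counts must be nonnegative")
        if self.signature_fold <= 0:
            raise ValueError("signature_fold must be positive")
        for name in ("n_core_families", "n_markers", "n_signature_kos",
                     "n_background_kos", "prb_target_per_strain",
                     "prb_target_other"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class Cohort:
    """All generated tables for one synthetic cohort."""

    strains: pd.DataFrame
    genes: pd.DataFrame
    hits_self: pd.DataFrame
    hits_plant: pd.DataFrame
    gfobap_features: pd.DataFrame
    marker_matrices: dict[str, pd.DataFrame]
    assay: pd.DataFrame


@dataclass
class SyntheticTruth:
    """Planted ground truth, recorded from the generator's bookkeeping."""

    habitat_of: dict[str, str]
    core_family_ids: set[str]  # canonical smallest-member family ids
    core_genes: set[tuple[str, str]]
    signature_kos: pd.DataFrame  # ko, home_habitat, home_rate, base_rate
    prb_true_genes: set[tuple[str, str]]
    gfobap_true_genes: set[tuple[str, str]]
    inert: bool = False  # True when no signal was planted

    @property
    def signature_ko_ids(self) -> set[str]:
        return set() if self.inert else set(self.signature_kos["ko"])

    @property
    def ppr_true_genes(self) -> set[tuple[str, str]]:
        return (self.prb_true_genes | self.gfobap_true_genes) - self.core_genes


def _strain_ids(config: CohortSimConfig) -> pd.DataFrame:
    rows = []
    for habitat in HABITAT_PREFIX:
        for i in range(config.n_per_habitat.get(habitat, 0)):
            rows.append((f"{HABITAT_PREFIX[habitat]}{i + 1:02d}", habitat))
    return pd.DataFrame(rows, columns=["strain_id", "habitat"])


def _signature_table(config: CohortSimConfig) -> pd.DataFrame:
    """Assign each signature KO a home habitat, smallest habitats first."""
    candidates = [h for h in ("plant_associated", "soil_rhizosphere",
                              "marine_mangrove") if config.n_per_habitat.get(h, 0) > 0]
    candidates.sort(key=lambda h: config.n_per_habitat[h])
    kos = [f"K{i:05d}" for i in range(config.n_signature_kos)]
    homes = [candidates[i % len(candidates)] for i in range(len(kos))] if candidates else []
    return pd.DataFrame({
        "ko": kos,
        "home_habitat": homes or [""] * len(kos),
        "home_rate": config.signature_fold * config.base_ko_rate,
        "base_rate": config.base_ko_rate,
    })


def _gfobap_table(config: CohortSimConfig, rng: np.random.Generator,
                  all_kos: list[str]) -> pd.DataFrame:
    rows = []
    for ko in all_kos:  # every real KO is a supported plant feature
        rows.append((ko, "ko", int(rng.integers(2, 6)), True))
    for i in range(20):  # decoy KOs absent from every genome
        rows.append((f"KD{i:04d}", "ko", int(rng.integers(2, 6)), True))
    for i in range(config.n_plant_pfams):
        rows.append((f"PF{i:05d}", "pfam", int(rng.integers(2, 6)), True))
    for i in range(config.n_plant_pfams, config.n_plant_pfams + 10):
        rows.append((f"PF{i:05d}", "pfam", 1, True))  # under-supported
    for i in range(config.n_plant_pfams + 10, config.n_plant_pfams + 20):
        rows.append((f"PF{i:05d}", "pfam", 3, False))  # not plant-associated
    for i in range(5):
        rows.append((f"TIGR{i:05d}", "tigrfam", int(rng.integers(2, 6)), True))
    for i in range(5, 10):
        rows.append((f"TIGR{i:05d}", "tigrfam", 3, False))
    for i in range(config.n_plant_orthogroups):
        rows.append((f"A{i:05d}", "orthogroup", int(rng.integers(2, 6)), True))
    rows.append(("F00000", "orthogroup", 2, True))  # core family: subtracted later
    rows.append(("F00001", "orthogroup", 3, True))
    rows.append(("G", "cog", 1, True))   # fails the support rule
    rows.append(("K", "cog", 3, False))  # fails the plant-associated rule
    return pd.DataFrame(rows, columns=psio.GFOBAP_COLUMNS)


def simulate_cohort(config: CohortSimConfig | None = None) -> tuple[Cohort, SyntheticTruth]:
    """Generate one cohort with planted truth; reproducible from the seed."""
    config = config or CohortSimConfig()
    rng = np.random.default_rng(config.seed)
    strains = _strain_ids(config)
    n_strains = len(strains)

    sig = _signature_table(config)
    bg_kos = [f"K{i + config.n_signature_kos:05d}"
              for i in range(config.n_background_kos)]
    all_kos = list(sig["ko"]) + bg_kos

    # truncation floor: room for the core, the PRB candidate draw, and the
    # KO copy load (Poisson with the largest possible rate sum)
    max_ko_rate = config.base_ko_rate * (
        config.n_background_kos
        + max(config.signature_fold, 1.0) * config.n_signature_kos)
    min_genes = (config.n_core_families
                 + 8 * max(config.prb_target_per_strain, config.prb_target_other)
                 + int(1.35 * max_ko_rate) + 50)

    gene_cols: dict[str, list[np.ndarray]] = {
        c: [] for c in psio.GENE_COLUMNS}
    key_blocks: list[np.ndarray] = []
    strain_rows: list[tuple] = []
    prb_cols: dict[str, list[np.ndarray]] = {c: [] for c in psio.B6_COLUMNS}
    prb_true: set[tuple[str, str]] = set()
    gfobap_true: set[tuple[str, str]] = set()
    core_genes: set[tuple[str, str]] = set()
    plant_pfams = {f"PF{i:05d}" for i in range(config.n_plant_pfams)}
    plant_tigrs = {f"TIGR{i:05d}" for i in range(5)}
    plant_ogs = ({f"A{i:05d}" for i in range(config.n_plant_orthogroups)}
                 | {"F00000", "F00001"})
    nc = config.n_core_families

    for strain_id, habitat in strains.itertuples(index=False):
        n_genes = int(np.clip(round(rng.normal(config.mean_genes, config.sd_genes)),
                              min_genes, None))
        gene_ids = np.array([f"g{i:05d}" for i in range(n_genes)])
        family = np.empty(n_genes, dtype=object)
        family[:nc] = [f"F{i:05d}" for i in range(nc)]
        n_acc = n_genes - nc
        acc_fams = rng.integers(0, config.n_accessory_families, n_acc)
        family[nc:] = [f"A{i:05d}" for i in acc_fams]
        core_genes.update((strain_id, g) for g in gene_ids[:nc])

        # KEGG orthologs: Poisson copy numbers, signature KOs elevated at home
        rates = np.full(len(all_kos), config.base_ko_rate)
        home = sig["home_habitat"].to_numpy()
        rates[: len(sig)] = np.where(home == habitat,
                                     sig["home_rate"], sig["base_rate"])
        copies = rng.poisson(rates)
        total = int(copies.sum())
        ko = np.full(n_genes, "", dtype=object)
        if total > n_acc:
            raise ValueError("gene inventory too small for the KO copy load")
        ko_slots = nc + rng.choice(n_acc, size=total, replace=False)
        ko[ko_slots] = np.repeat(all_kos, copies)

        # Pfam / TIGRFAM / orthogroup annotations
        pfam = np.full(n_genes, "", dtype=object)
        has_pf = rng.random(n_genes) < config.pfam_prob
        pfam[has_pf] = [f"PF{i:05d}"
                        for i in rng.integers(0, config.n_pfam_pool, int(has_pf.sum()))]
        tigr = np.full(n_genes, "", dtype=object)
        has_tg = rng.random(n_genes) < config.tigrfam_prob
        tigr[has_tg] = [f"TIGR{i:05d}" for i in rng.integers(0, 100, int(has_tg.sum()))]

        # COG letters; ~10% of genes carry a second category
        letters = rng.choice(_COG_LETTERS, size=n_genes, p=_COG_WEIGHTS)
        second = rng.random(n_genes) < 0.10
        extra = rng.choice(_COG_LETTERS, size=int(second.sum()), p=_COG_WEIGHTS)
        cog = letters.astype(object)
        cog[second] = [a + b if a != b else a
                       for a, b in zip(letters[second], extra)]

        keys = np.array([f"{strain_id}|{g}" for g in gene_ids], dtype=object)
        key_blocks.append(keys)
        for col, arr in (("strain_id", np.full(n_genes, strain_id, dtype=object)),
                         ("gene_id", gene_ids.astype(object)),
                         ("cog_category", cog), ("ko", ko),
                         ("pfam_ids", pfam), ("tigrfam_ids", tigr),
                         ("orthogroup", family)):
            gene_cols[col].append(arr)
        strain_rows.append((strain_id, habitat,
                            int(rng.normal(7.1e6, 0.4e6)), n_genes))

        flagged = ((ko != "")
                   | np.isin(pfam, list(plant_pfams))
                   | np.isin(tigr, list(plant_tigrs))
                   | np.isin(family, list(plant_ogs)))
        gfobap_true.update((strain_id, g) for g in gene_ids[flagged])

        # plant-proteome hits straddling every PRB threshold
        target = (config.prb_target_per_strain if habitat == "plant_associated"
                  else config.prb_target_other)
        n_cand = 8 * target
        if n_cand:
            cand = nc + rng.choice(n_acc, size=n_cand, replace=False)
            pident = np.round(rng.uniform(25.0, 35.0, n_cand), 3)
            qend = rng.integers(180, 240, n_cand)  # coverage 60-79.7%, P(>=70%)=1/2
            evalue = 10.0 ** rng.uniform(-40.0, -20.0, n_cand)
            passing = (evalue <= 1e-30) & (qend >= 210) & (pident >= 30.0)
            prb_true.update((strain_id, g) for g in gene_ids[cand[passing]])
            _append_hits(prb_cols, rng, keys[cand], pident, qend, evalue)
        # boundary hits on core genes that always fail the E-value threshold
        n_core_hits = min(20, nc)
        if n_core_hits:
            ci = rng.choice(nc, size=n_core_hits, replace=False)
            _append_hits(prb_cols, rng, keys[ci],
                         np.round(rng.uniform(30.0, 35.0, n_core_hits), 3),
                         rng.integers(210, 240, n_core_hits),
                         10.0 ** rng.uniform(-29.5, -20.0, n_core_hits))

    genes = _concat_columns(gene_cols, psio.GENE_COLUMNS)
    strains_df = pd.DataFrame(strain_rows, columns=psio.STRAIN_COLUMNS)

    all_keys = (np.concatenate(key_blocks) if key_blocks
                else np.empty(0, dtype=object))
    hits_self = _family_chain_hits(all_keys, genes["orthogroup"].to_numpy(), rng)
    hits_plant = _concat_columns(prb_cols, psio.B6_COLUMNS)

    gfobap = _gfobap_table(config, rng, all_kos)
    matrices = _marker_matrices(config, rng, list(strains_df["strain_id"]))
    assay = _assay_table(config, rng, strains_df)

    core_ids = set()
    if n_strains and nc:
        first = strains_df["strain_id"].min()
        core_ids = {f"{first}|g{i:05d}" for i in range(nc)}

    truth = SyntheticTruth(
        habitat_of=dict(zip(strains_df["strain_id"], strains_df["habitat"])),
        core_family_ids=core_ids, core_genes=core_genes,
        signature_kos=sig, prb_true_genes=prb_true,
        gfobap_true_genes=gfobap_true,
        inert=config.signature_fold == 1.0,
    )
    cohort = Cohort(strains=strains_df, genes=genes, hits_self=hits_self,
                    hits_plant=hits_plant, gfobap_features=gfobap,
                    marker_matrices=matrices, assay=assay)
    return cohort, truth


def _append_hits(cols: dict[str, list], rng: np.random.Generator,
                 qseqid: np.ndarray, pident: np.ndarray,
                 qend: np.ndarray, evalue: np.ndarray) -> None:
    """Accumulate 13-column hit rows as raw arrays (one DataFrame is built
    at the end; repeated small concats are expensive)."""
    n = len(qseqid)
    cols["qseqid"].append(qseqid)
    cols["sseqid"].append(np.array(
        [f"PLANT{i:06d}" for i in rng.integers(0, 731325, n)], dtype=object))
    cols["pident"].append(pident)
    cols["length"].append(qend)
    cols["mismatch"].append(rng.integers(0, 40, n))
    cols["gapopen"].append(rng.integers(0, 5, n))
    cols["qstart"].append(np.ones(n, dtype=np.int64))
    cols["qend"].append(qend)
    cols["sstart"].append(np.ones(n, dtype=np.int64))
    cols["send"].append(qend)
    cols["evalue"].append(evalue)
    cols["bitscore"].append(np.round(rng.uniform(80, 300, n), 1))
    cols["qlen"].append(np.full(n, 300, dtype=np.int64))


def _concat_columns(cols: dict[str, list], order: list[str]) -> pd.DataFrame:
    if not next(iter(cols.values())):
        return pd.DataFrame(columns=order)
    return pd.DataFrame({c: np.concatenate(cols[c]) for c in order},
                        columns=order)


def _family_chain_hits(keys: np.ndarray, fam: np.ndarray,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Within-family hits as a spanning chain per family, above the cutoff,
    plus below-cutoff decoy pairs that must never merge families."""
    if not len(keys):
        return pd.DataFrame(columns=psio.B6_COLUMNS)
    codes, _ = pd.factorize(fam)  # any spanning chain works: group by code
    order = np.argsort(codes, kind="stable")
    keys_s, codes_s = keys[order], codes[order]
    link = codes_s[:-1] == codes_s[1:]
    q, s = keys_s[:-1][link], keys_s[1:][link]
    n = len(q)
    n_decoy = min(2000, len(keys))
    qi = rng.integers(0, len(keys), n_decoy)
    si = rng.integers(0, len(keys), n_decoy)
    qend = np.concatenate([rng.integers(270, 291, n),
                           rng.integers(200, 280, n_decoy)])
    m = n + n_decoy
    return pd.DataFrame({
        "qseqid": np.concatenate([q, keys[qi]]),
        "sseqid": np.concatenate([s, keys[si]]),
        "pident": np.round(np.concatenate([rng.uniform(75.0, 95.0, n),
                                           rng.uniform(30.0, 65.0, n_decoy)]), 3),
        "length": qend,
        "mismatch": rng.integers(0, 60, m),
        "gapopen": rng.integers(0, 5, m),
        "qstart": np.ones(m, dtype=np.int64), "qend": qend,
        "sstart": np.ones(m, dtype=np.int64), "send": qend,
        "evalue": 10.0 ** np.concatenate([rng.uniform(-80.0, -50.0, n),
                                          rng.uniform(-25.0, -5.0, n_decoy)]),
        "bitscore": np.round(rng.uniform(50, 500, m), 1),
        "qlen": np.full(m, 300, dtype=np.int64),
    }, columns=psio.B6_COLUMNS)


def _marker_matrices(config: CohortSimConfig, rng: np.random.Generator,
                     strain_ids: list[str]) -> dict[str, pd.DataFrame]:
    lo, hi = config.marker_identity_range
    n = len(strain_ids)
    out: dict[str, pd.DataFrame] = {}
    for m in range(config.n_markers):
        mat = np.full((n, n), 100.0)
        iu = np.triu_indices(n, k=1)
        vals = rng.uniform(lo, hi, len(iu[0]))
        mat[iu] = vals
        mat[(iu[1], iu[0])] = vals
        out[f"marker{m + 1:03d}"] = pd.DataFrame(mat, index=strain_ids,
                                                 columns=strain_ids)
    return out


def _assay_table(config: CohortSimConfig, rng: np.random.Generator,
                 strains: pd.DataFrame) -> pd.DataFrame:
    effect_of = dict(zip(
        ("plant_associated", "soil_rhizosphere", "marine_mangrove"),
        config.assay_effects))
    treatments: list[tuple[str, float]] = [("control", 0.0)]
    for habitat, eff in effect_of.items():
        chosen = strains.loc[strains["habitat"] == habitat, "strain_id"]
        for sid in sorted(chosen)[: config.n_assay_strains_per_habitat]:
            treatments.append((sid, eff))
    rows = []
    for treatment, eff in treatments:
        for p in range(config.n_plants_per_treatment):
            rec = {"treatment": treatment, "plant_id": f"p{p + 1:03d}"}
            for param, (mu, sd) in _ASSAY_BASE.items():
                x = rng.normal(mu + eff * sd, sd)
                if param.startswith("n_"):
                    rec[param] = int(max(0, round(x)))
                else:
                    rec[param] = round(max(1.0, x), 2)
            rows.append(rec)
    return pd.DataFrame(rows, columns=psio.ASSAY_COLUMNS)


def null_cohort(config: CohortSimConfig | None = None) -> tuple[Cohort, SyntheticTruth]:
    """Same generative process with no planted signal: signature fold forced
    to 1 and habitat-independent PRB rates. The truth marks its signature
    KOs inert."""
    config = config or CohortSimConfig()
    null_cfg = dataclasses.replace(
        config, signature_fold=1.0,
        prb_target_other=config.prb_target_per_strain)
    return simulate_cohort(null_cfg)


def write_cohort(cohort: Cohort, truth: SyntheticTruth, outdir) -> None:
    """Serialize a cohort in the pipeline's on-disk formats plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    psio.write_strains(cohort.strains, outdir / "strains.tsv")
    psio.write_genes(cohort.genes, outdir / "genes.tsv")
    psio.write_hits(cohort.hits_self, outdir / "hits_self.b6")
    psio.write_hits(cohort.hits_plant, outdir / "hits_plant.b6")
    psio.write_gfobap(cohort.gfobap_features, outdir / "gfobap_features.tsv")
    psio.write_assay(cohort.assay, outdir / "assay.tsv")
    mdir = outdir / "markers"
    mdir.mkdir(exist_ok=True)
    for marker, df in cohort.marker_matrices.items():
        psio.write_identity_matrix(df, mdir / f"{marker}.tsv")
    payload = {
        "habitat_of": truth.habitat_of,
        "core_family_ids": sorted(truth.core_family_ids),
        "core_genes": sorted(map(list, truth.core_genes)),
        "signature_kos": truth.signature_kos.to_dict(orient="records"),
        "prb_true_genes": sorted(map(list, truth.prb_true_genes)),
        "gfobap_true_genes": sorted(map(list, truth.gfobap_true_genes)),
        "inert": truth.inert,
    }
    (outdir / "truth.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


__all__ = ["CohortSimConfig", "Cohort", "SyntheticTruth", "simulate_cohort",
           "null_cohort", "write_cohort"]
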