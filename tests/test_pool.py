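"""PRB thresholding, catalog screening, and pool assembly."""

import numpy as np
import pandas as pd
import pytest

from plantsig import (PrbThresholds, assemble_ppr, assignment_from_orthogroups,
                      classify_core, filter_prb, screen_gfobap)
from plantsig.io import B6_COLUMNS


def _hit(gene, evalue=1e-40, qend=80, pident=50.0, qlen=100):
    return {"qseqid": gene, "sseqid": "plant1", "pident": pident,
            "length": qend, "mismatch": 0, "gapopen": 0, "qstart": 1,
            "qend": qend, "sstart": 1, "send": qend, "evalue": evalue,
            "bitscore": 100.0, "qlen": qlen}


def _random_hits(rng, n):
    qend = rng.integers(40, 101, n)
    return pd.DataFrame({
        "qseqid": [f"s{rng.integers(20):02d}|g{i:05d}" for i in range(n)],
        "sseqid": "plant1",
        "pident": rng.uniform(10, 60, n), "length": qend,
        "mismatch": 0, "gapopen": 0, "qstart": 1, "qend": qend,
        "sstart": 1, "send": qend,
        "evalue": 10.0 ** rng.uniform(-45, -15, n),
        "bitscore": 100.0, "qlen": 100,
    }, columns=B6_COLUMNS)


class TestFilterPrb:
    def test_all_thresholds_passed(self):
        hits = pd.DataFrame([_hit("s1|a", evalue=1e-31, qend=75, pident=35.0)])
        assert filter_prb(hits) == {("s1", "a")}

    def test_evalue_alone_fails(self):
        hits = pd.DataFrame([_hit("s1|a", evalue=1e-20, qend=90, pident=90.0)])
        assert filter_prb(hits) == set()

    def test_thresholds_inclusive(self):
        hits = pd.DataFrame([_hit("s1|a", evalue=1e-30, qend=70, pident=30.0)])
        assert filter_prb(hits) == {("s1", "a")}

    def test_empty_input(self):
        assert filter_prb(pd.DataFrame(columns=B6_COLUMNS)) == set()

    def test_matches_brute_force_scan(self):
        """10,000 random hits: retained set equals a row-by-row scan."""
        rng = np.random.default_rng(42)
        hits = _random_hits(rng, 10_000)
        got = filter_prb(hits)
        expected = set()
        for row in hits.itertuples(index=False):
            cov = 100.0 * (row.qend - row.qstart + 1) / row.qlen
            if row.evalue <= 1e-30 and cov >= 70.0 and row.pident >= 30.0:
                strain, _, gene = row.qseqid.partition("|")
                expected.add((strain, gene))
        assert got == expected

    def test_relaxing_thresholds_monotone(self):
        rng = np.random.default_rng(1)
        hits = _random_hits(rng, 2_000)
        tight = filter_prb(hits, PrbThresholds(1e-30, 70.0, 30.0))
        for loose in (PrbThresholds(1e-25, 70.0, 30.0),
                      PrbThresholds(1e-30, 60.0, 30.0),
                      PrbThresholds(1e-30, 70.0, 20.0)):
            assert tight <= filter_prb(hits, loose)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            PrbThresholds(max_evalue=0.0)
        with pytest.raises(ValueError):
            PrbThresholds(min_coverage_pct=0.0)


def _gene(strain, gene, ko="", pfam="", tigr="", og="", cog=""):
    return {"strain_id": strain, "gene_id": gene, "cog_category": cog,
            "ko": ko, "pfam_ids": pfam, "tigrfam_ids": tigr, "orthogroup": og}


def _feature(fid, ftype, n_support=2, plant=True):
    return {"feature_id": fid, "feature_type": ftype, "n_support": n_support,
            "plant_associated": plant}


class TestScreenGfobap:
    def test_supported_pfam_flags_gene(self):
        genes = pd.DataFrame([_gene("s1", "a", pfam="PF00001")])
        feats = pd.DataFrame([_feature("PF00001", "pfam", 3)])
        assert screen_gfobap(genes, feats) == {("s1", "a")}

    def test_single_support_not_flagged(self):
        genes = pd.DataFrame([_gene("s1", "a", pfam="PF00001")])
        feats = pd.DataFrame([_feature("PF00001", "pfam", 1)])
        assert screen_gfobap(genes, feats) == set()

    def test_non_plant_feature_not_flagged(self):
        genes = pd.DataFrame([_gene("s1", "a", ko="K00001")])
        feats = pd.DataFrame([_feature("K00001", "ko", 4, plant=False)])
        assert screen_gfobap(genes, feats) == set()

    def test_multivalued_and_cog_matching(self):
        genes = pd.DataFrame([
            _gene("s1", "a", pfam="PF1;PF2"),
            _gene("s1", "b", cog="GK"),
            _gene("s1", "c", og="OG7"),
        ])
        feats = pd.DataFrame([
            _feature("PF2", "pfam"), _feature("G", "cog"),
            _feature("OG7", "orthogroup"),
        ])
        assert screen_gfobap(genes, feats) == {("s1", "a"), ("s1", "b"),
                                               ("s1", "c")}

    def test_matches_brute_force_cross_join(self):
        rng = np.random.default_rng(9)
        genes = pd.DataFrame([
            _gene(f"s{i % 5}", f"g{i}",
                  ko=f"K{rng.integers(5)}",
                  pfam=";".join(f"PF{j}" for j in rng.integers(0, 8, 2)),
                  og=f"OG{rng.integers(6)}")
            for i in range(300)])
        feats = pd.DataFrame([
            _feature(f"K{i}", "ko", int(rng.integers(1, 4)),
                     bool(rng.integers(2))) for i in range(5)
        ] + [
            _feature(f"PF{i}", "pfam", int(rng.integers(1, 4)),
                     bool(rng.integers(2))) for i in range(8)
        ] + [
            _feature(f"OG{i}", "orthogroup", int(rng.integers(1, 4)),
                     bool(rng.integers(2))) for i in range(6)
        ])
        retained = {(r.feature_id, r.feature_type)
                    for r in feats.itertuples()
                    if r.plant_associated and r.n_support >= 2}
        expected = set()
        for g in genes.itertuples(index=False):
            anns = ({(g.ko, "ko"), (g.orthogroup, "orthogroup")}
                    | {(p, "pfam") for p in g.pfam_ids.split(";") if p})
            if anns & retained:
                expected.add((g.strain_id, g.gene_id))
        assert screen_gfobap(genes, feats) == expected


class TestAssemblePpr:
    def _assignment(self):
        genes = pd.DataFrame({
            "strain_id": ["s1", "s2", "s1", "s2"],
            "gene_id": ["core", "core", "acc", "acc"],
            "orthogroup": ["F1", "F1", "", ""],
        })
        asg = assignment_from_orthogroups(genes)
        strains = pd.DataFrame({
            "strain_id": ["s1", "s2"], "habitat": ["other"] * 2,
            "genome_length_bp": [10, 10], "n_genes": [2, 2]})
        classify_core(asg, strains)
        return asg

    def test_core_member_excluded(self):
        asg = self._assignment()
        pool = assemble_ppr({("s1", "core"), ("s1", "acc")}, set(), asg)
        assert pool.members == {("s1", "acc")}

    def test_flags_preserved(self):
        asg = self._assignment()
        pool = assemble_ppr({("s1", "acc")}, {("s2", "acc")}, asg)
        row = pool.frame.set_index(["strain_id", "gene_id"])
        assert bool(row.loc[("s1", "acc"), "is_prb"])
        assert not bool(row.loc[("s1", "acc"), "is_gfobap"])
        assert bool(row.loc[("s2", "acc"), "is_gfobap"])
        assert pool.per_strain_count.to_dict() == {"s1": 1, "s2": 1}

    def test_missing_gene_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            assemble_ppr({("sX", "nope")}, set(), self._assignment())

    def test_size_bound_and_no_core_members(self):
        asg = self._assignment()
        prb = {("s1", "acc"), ("s1", "core")}
        gf = {("s1", "acc"), ("s2", "acc")}
        pool = assemble_ppr(prb, gf, asg)
        assert len(pool) <= len(prb) + len(gf)
        core = {("s1", "core"), ("s2", "core")}
        assert not (pool.members & core)

    def test_matches_truth_set_algebra(self, slim_cohort):
        """Pool equals (PRB union catalog) minus core genes on planted truth."""
        cohort, truth = slim_cohort
        asg = assignment_from_orthogroups(cohort.genes)
        classify_core(asg, cohort.strains)
        prb = filter_prb(cohort.hits_plant)
        gf = screen_gfobap(cohort.genes, cohort.gfobap_features)
        pool = assemble_ppr(prb, gf, asg)
        assert prb == truth.prb_true_genes
        assert gf == truth.gfobap_true_genes
        assert pool.members == truth.ppr_true_genes
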