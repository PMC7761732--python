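"""PED/MAP round trips, pedigree sorting and the QC cascade."""

import numpy as np
import pandas as pd
import pytest

import rohkit as rk
from rohkit.genotype_io import (
    MISSING,
    ParseError,
    StructuralError,
    pedigree_from_records,
    read_ped_map,
    read_pedigree,
    write_ped_map,
    write_pedigree,
)

from conftest import make_genotypes, make_map


PED_3SNP = """\
FAM A1 0 0 0 -9 A A A G 0 0
FAM A2 0 0 0 -9 A G G G C C
"""
MAP_3SNP = """\
1 s1 0 1000
1 s2 0 2000
2 s3 0 500
"""


@pytest.fixture
def tiny_files(tmp_path):
    (tmp_path / "t.ped").write_text(PED_3SNP)
    (tmp_path / "t.map").write_text(MAP_3SNP)
    return tmp_path / "t.ped", tmp_path / "t.map"


class TestReadPedMap:
    def test_missing_pair_becomes_sentinel(self, tiny_files):
        g, m = read_ped_map(*tiny_files)
        assert (g.values == MISSING).sum() == 1
        # the 0 0 pair sits at SNP s3 of animal A1
        col = list(m.table["snp_id"]).index("s3")
        assert g.values[0, col] == MISSING

    def test_counted_allele_is_first_observed(self, tiny_files):
        g, m = read_ped_map(*tiny_files)
        cols = {s: i for i, s in enumerate(m.table["snp_id"])}
        # s1: first allele A -> A1 has AA=2, A2 has AG=1
        assert g.values[0, cols["s1"]] == 2
        assert g.values[1, cols["s1"]] == 1
        # s2: first observed is A (A1 "A G") -> A1=1; A2 GG=0
        assert g.values[0, cols["s2"]] == 1
        assert g.values[1, cols["s2"]] == 0

    def test_map_sorted_by_chrom_and_position(self, tiny_files):
        _, m = read_ped_map(*tiny_files)
        assert list(m.table["snp_id"]) == ["s1", "s2", "s3"]
        assert m.chroms == ["1", "2"]

    def test_ragged_row_names_line(self, tmp_path, tiny_files):
        ped, mp = tiny_files
        (tmp_path / "bad.ped").write_text(
            "FAM A1 0 0 0 -9 A A A G 0 0\nFAM A2 0 0 0 -9 A G G\n")
        with pytest.raises(ParseError, match="line 2"):
            read_ped_map(tmp_path / "bad.ped", mp)

    def test_snp_count_mismatch_is_structural(self, tmp_path, tiny_files):
        _, mp = tiny_files
        (tmp_path / "short.ped").write_text("FAM A1 0 0 0 -9 A A G G\n")
        with pytest.raises(StructuralError):
            read_ped_map(tmp_path / "short.ped", mp)

    def test_three_alleles_rejected(self, tmp_path, tiny_files):
        _, mp = tiny_files
        (tmp_path / "tri.ped").write_text(
            "FAM A1 0 0 0 -9 A C A A A A\nFAM A2 0 0 0 -9 G G A A A A\n")
        with pytest.raises(ParseError, match="two allele"):
            read_ped_map(tmp_path / "tri.ped", mp)


class TestWritePedMap:
    def test_empty_sample_set(self, tmp_path):
        m = make_map(3)
        g = make_genotypes(np.zeros((0, 3), dtype=np.int8), samples=[])
        write_ped_map(g, m, tmp_path / "e.ped", tmp_path / "e.map")
        assert (tmp_path / "e.ped").read_text() == ""
        g2, m2 = read_ped_map(tmp_path / "e.ped", tmp_path / "e.map")
        assert g2.n_samples == 0 and m2.n_snps == 3

    def test_het_written_as_two_symbols(self, tmp_path):
        m = make_map(1)
        g = make_genotypes([[1]])
        write_ped_map(g, m, tmp_path / "h.ped", tmp_path / "h.map")
        line = (tmp_path / "h.ped").read_text().strip().split()
        assert line[-2:] == ["A", "B"]

    def test_dimension_mismatch(self, tmp_path):
        with pytest.raises(StructuralError):
            write_ped_map(make_genotypes([[0, 1]]), make_map(3),
                          tmp_path / "x.ped", tmp_path / "x.map")

    def test_read_write_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(5)
        m = make_map(40, spacing_bp=50_000)
        vals = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        vals[rng.random(vals.shape) < 0.1] = MISSING
        g = make_genotypes(vals)
        write_ped_map(g, m, tmp_path / "a.ped", tmp_path / "a.map")
        g1, m1 = read_ped_map(tmp_path / "a.ped", tmp_path / "a.map")
        # read-write-read is the identity once the coding is canonical
        write_ped_map(g1, m1, tmp_path / "b.ped", tmp_path / "b.map")
        g2, m2 = read_ped_map(tmp_path / "b.ped", tmp_path / "b.map")
        np.testing.assert_array_equal(g1.values, g2.values)
        assert g1.samples == g2.samples
        pd.testing.assert_frame_equal(m1.table, m2.table)

    def test_write_read_write_fixpoint_on_gene_drop(self, tmp_path):
        cfg = rk.SimulationConfig(n_founders=6, n_generations=1, n_chrom=2,
                                  snps_per_chrom=50, chrom_length_mb=10,
                                  seed=1)
        ped = rk.simulate_pedigree(cfg)
        g, m, _ = rk.gene_drop(ped, cfg)
        write_ped_map(g, m, tmp_path / "1.ped", tmp_path / "1.map")
        g1, m1 = read_ped_map(tmp_path / "1.ped", tmp_path / "1.map")
        write_ped_map(g1, m1, tmp_path / "2.ped", tmp_path / "2.map")
        g2, m2 = read_ped_map(tmp_path / "2.ped", tmp_path / "2.map")
        write_ped_map(g2, m2, tmp_path / "3.ped", tmp_path / "3.map")
        assert (tmp_path / "2.ped").read_bytes() == (tmp_path / "3.ped").read_bytes()
        assert (tmp_path / "2.map").read_bytes() == (tmp_path / "3.map").read_bytes()


class TestPedigree:
    def test_single_founder(self, tmp_path):
        (tmp_path / "p.csv").write_text("A,0,0\n")
        ped = read_pedigree(tmp_path / "p.csv")
        assert ped.animals == ["A"]
        assert ped.table["sire"].iloc[0] is None

    def test_cycle_detected(self, tmp_path):
        (tmp_path / "p.csv").write_text("B,A,A\nA,B,0\n")
        with pytest.raises(StructuralError, match="cycle"):
            read_pedigree(tmp_path / "p.csv")

    def test_sort_invariance_under_shuffling(self, tmp_path):
        records = [("F1", None, None), ("F2", None, None),
                   ("C1", "F1", "F2"), ("C2", "F1", "F2"),
                   ("D1", "C1", "C2"), ("D2", "C1", "F2"),
                   ("E1", "D1", "D2"), ("E2", "D1", "C2"),
                   ("E3", "C1", "D2"), ("E4", "D2", "D1")]
        sorted_ped = pedigree_from_records(records)
        rng = np.random.default_rng(3)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        resorted = pedigree_from_records(shuffled)
        # same topological constraint satisfied; same animal set
        assert set(resorted.animals) == set(sorted_ped.animals)
        pos = {a: i for i, a in enumerate(resorted.animals)}
        for a, s, d in records:
            for p in (s, d):
                if p is not None:
                    assert pos[p] < pos[a]

    def test_named_parent_without_record_becomes_founder(self, tmp_path):
        (tmp_path / "p.txt").write_text("KID SIRE DAM\n")
        ped = read_pedigree(tmp_path / "p.txt")
        assert set(ped.animals) == {"KID", "SIRE", "DAM"}
        assert ped.animals[-1] == "KID"

    def test_write_read_round_trip(self, tmp_path):
        ped = pedigree_from_records(
            [("X", None, None), ("Y", None, None), ("Z", "X", "Y")])
        write_pedigree(ped, tmp_path / "out.csv")
        again = read_pedigree(tmp_path / "out.csv")
        assert again.animals == ped.animals


class TestApplyQc:
    def _panel(self):
        # 10 animals x 8 SNPs, fully called
        vals = np.ones((10, 8), dtype=np.int8)
        return make_genotypes(vals), make_map(8)

    def test_snp_below_call_rate_dropped(self):
        g, m = self._panel()
        g.values[0, 2] = MISSING  # call rate 0.9 < 0.95
        out_g, out_m, rep = rk.apply_qc(g, m)
        assert rep.n_snps_low_call_rate == 1
        assert "snp1_2" not in set(out_m.table["snp_id"])

    def test_sample_threshold_is_strict(self):
        # 20 SNPs so 15% and 16% are representable after SNP filtering
        vals = np.ones((10, 100), dtype=np.int8)
        g, m = make_genotypes(vals), make_map(100)
        g.values[0, :16] = MISSING  # 16% missing -> removed
        g.values[1, :15] = MISSING  # exactly 15% -> retained
        out_g, _, rep = rk.apply_qc(g, m, min_snp_call_rate=0.0)
        assert rep.removed_samples == ["S000"]
        assert "S001" in out_g.samples

    def test_planted_failures_counted_in_order(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 3, size=(50, 40)).astype(np.int8)
        g, m = make_genotypes(vals), make_map(40)
        for j in (3, 17, 31):           # 3 bad SNPs: 3/50 missing (0.94)
            g.values[:3, j] = MISSING
        for i in (5, 11):               # 2 bad animals: missing on all even
            g.values[i, ::2] = MISSING  # columns (call rate 48/50 elsewhere)
        out_g, out_m, rep = rk.apply_qc(g, m)
        assert rep.n_snps_low_call_rate == 3
        assert rep.n_samples_high_missing == 2
        assert rep.n_snps_in - rep.n_snps_nonautosomal - \
            rep.n_snps_low_call_rate == rep.n_snps_out
        assert rep.n_samples_in - rep.n_samples_high_missing == rep.n_samples_out

    def test_nonautosomal_dropped_first(self):
        vals = np.ones((4, 6), dtype=np.int8)
        table = make_map(6).table.copy()
        table.loc[5, "chrom"] = "X"
        table.loc[5, "snp_id"] = "sexsnp"
        from rohkit.genotype_io import MarkerMap
        m = MarkerMap(table)
        _, out_m, rep = rk.apply_qc(make_genotypes(vals), m)
        assert rep.n_snps_nonautosomal == 1
        assert "X" not in set(out_m.table["chrom"])

    def test_idempotent(self):
        cfg = rk.SimulationConfig(n_founders=10, n_generations=2, n_chrom=2,
                                  snps_per_chrom=100, chrom_length_mb=20,
                                  missing_rate=0.02, seed=4)
        ped = rk.simulate_pedigree(cfg)
        g, m, _ = rk.gene_drop(ped, cfg)
        g1, m1, _ = rk.apply_qc(g, m)
        g2, m2, rep2 = rk.apply_qc(g1, m1)
        np.testing.assert_array_equal(g1.values, g2.values)
        assert rep2.n_snps_low_call_rate == 0
        assert rep2.n_samples_high_missing == 0

    def test_all_snps_removed_raises(self):
        g, m = self._panel()
        g.values[:] = MISSING
        with pytest.raises(StructuralError, match="every SNP"):
            rk.apply_qc(g, m)
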