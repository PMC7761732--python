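"""Run detectors against hand fixtures, brute-force oracles and the IBD
truth of gene-drop data."""

import numpy as np
import pytest

import rohkit as rk
from rohkit.genotype_io import MISSING
from rohkit.runs_detection import (
    ConsecutiveParams,
    RohParams,
    detect_roh_sliding,
    detect_runs_consecutive,
    verify_counts,
)
from rohkit.synthetic_data import PlantedRun

from conftest import make_genotypes, make_map
from oracles import (
    consecutive_runs_naive,
    runset_index_pairs,
    sliding_runs_naive,
)


class TestSlidingWindow:
    def test_fully_homozygous_chromosome(self, single_chrom_map):
        g = make_genotypes(np.full(60, 2, dtype=np.int8))
        runs = detect_roh_sliding(g, single_chrom_map)
        assert len(runs) == 1
        run = runs.df.iloc[0]
        assert run.n_snps == 60
        assert run.length_bp == 5_900_000
        assert run.n_het == 0 and run.n_missing == 0

    def test_fully_heterozygous_chromosome(self, single_chrom_map):
        g = make_genotypes(np.ones(60, dtype=np.int8))
        assert len(detect_roh_sliding(g, single_chrom_map)) == 0

    def test_chromosome_shorter_than_window_yields_nothing(self):
        g = make_genotypes(np.full(30, 2, dtype=np.int8))
        m = make_map(30, spacing_bp=100_000)
        assert len(detect_roh_sliding(g, m, RohParams(window_snps=50))) == 0

    @pytest.mark.parametrize("max_het,detected", [(1, True), (0, False)])
    def test_blemished_planted_run(self, max_het, detected):
        # 40-SNP / ~3 Mb planted run with one interior het; window of 20
        # SNPs so a run longer than the window is callable
        m = make_map(200, spacing_bp=75_000)
        g = rk.plant_runs(1, m, [PlantedRun(0, "1", 6_000_000, 8_925_000,
                                            "hom", n_opposite=1)])
        params = RohParams(window_snps=20, max_het=max_het)
        runs = detect_roh_sliding(g, m, params)
        intact = [r for r in runs.df.itertuples()
                  if r.start_bp <= 6_100_000 and r.end_bp >= 8_800_000]
        assert bool(intact) is detected
        # exact agreement with the naive enumeration either way
        oracle = sliding_runs_naive(g.values[0], m.positions, params)
        assert runset_index_pairs(runs, m, "S000", "1") == oracle

    def test_matches_naive_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        m = make_map(300, spacing_bp=60_000)
        params = RohParams(window_snps=20, min_snps=25, min_length_mb=1.0)
        for _ in range(30):
            n_runs = rng.integers(1, 3)
            specs, cursor = [], 1
            for _ in range(n_runs):
                start = cursor + int(rng.integers(5, 30))
                width = int(rng.integers(30, 80))
                if start + width > 295:
                    break
                specs.append(PlantedRun(
                    0, "1", int(m.positions[start]),
                    int(m.positions[start + width]), "hom",
                    n_opposite=int(rng.integers(0, 2)),
                    n_missing=int(rng.integers(0, 2))))
                cursor = start + width + 5
            g = rk.plant_runs(1, m, specs)
            runs = detect_roh_sliding(g, m, params)
            oracle = sliding_runs_naive(g.values[0], m.positions, params)
            assert runset_index_pairs(runs, m, "S000", "1") == oracle

    def test_gap_splitting(self):
        # homozygous chromosome with a 2 Mb hole in the map
        pos = np.concatenate([100_000 + 50_000 * np.arange(60),
                              5_000_000 + 50_000 * np.arange(60)])
        import pandas as pd
        from rohkit.genotype_io import MarkerMap
        m = MarkerMap(pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(120)], "chrom": "1",
            "cm": pos / 1e6, "pos_bp": pos}))
        g = make_genotypes(np.full(120, 2, dtype=np.int8))
        runs = detect_roh_sliding(g, m, RohParams(min_length_mb=2.0))
        assert len(runs) == 2


class TestConsecutive:
    def test_twenty_het_snps_is_one_rohet(self):
        m = make_map(60, spacing_bp=20_000)
        vals = np.full(60, 2, dtype=np.int8)
        vals[20:40] = 1  # 20 consecutive hets spanning 380 kb
        runs = detect_runs_consecutive(make_genotypes(vals), m)
        assert len(runs) == 1
        assert runs.df.iloc[0].n_snps == 20
        assert runs.df.iloc[0].kind == "ROHet"

    def test_fourteen_het_snps_is_below_minimum(self):
        m = make_map(60, spacing_bp=20_000)
        vals = np.full(60, 2, dtype=np.int8)
        vals[20:34] = 1
        assert len(detect_runs_consecutive(make_genotypes(vals), m)) == 0

    def test_four_hom_blemishes_split_the_run(self):
        # 40 hets with 4 interspersed homs: max_opposite=3 forces a break;
        # coordinates equal the naive scan
        m = make_map(120, spacing_bp=20_000)
        vals = np.full(120, 2, dtype=np.int8)
        vals[20:80] = 1
        vals[[30, 40, 50, 60]] = 0
        g = make_genotypes(vals)
        params = ConsecutiveParams()
        runs = detect_runs_consecutive(g, m, params)
        oracle = consecutive_runs_naive(vals, m.positions, params)
        assert runset_index_pairs(runs, m, "S000", "1") == oracle
        assert len(oracle) >= 1

    def test_matches_naive_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        m = make_map(250, spacing_bp=20_000)
        params = ConsecutiveParams()
        for _ in range(30):
            specs, cursor = [], 1
            for _ in range(int(rng.integers(1, 4))):
                start = cursor + int(rng.integers(4, 25))
                width = int(rng.integers(16, 50))
                if start + width > 245:
                    break
                specs.append(PlantedRun(
                    0, "1", int(m.positions[start]),
                    int(m.positions[start + width]), "het",
                    n_opposite=int(rng.integers(0, 4)),
                    n_missing=int(rng.integers(0, 3))))
                cursor = start + width + 4
            g = rk.plant_runs(1, m, specs)
            runs = detect_runs_consecutive(g, m, params)
            oracle = consecutive_runs_naive(g.values[0], m.positions, params)
            assert runset_index_pairs(runs, m, "S000", "1") == oracle

    def test_runs_trimmed_to_target_state(self):
        m = make_map(60, spacing_bp=20_000)
        vals = np.full(60, 2, dtype=np.int8)
        vals[20:40] = 1
        vals[19] = MISSING  # absorbed leading missing must be trimmed
        runs = detect_runs_consecutive(make_genotypes(vals), m)
        assert runs.df.iloc[0].start_bp == int(m.positions[20])
        assert runs.df.iloc[0].n_missing == 0


class TestInvariants:
    def _gene_drop(self, seed=3):
        cfg = rk.SimulationConfig(
            n_founders=20, n_generations=3, offspring_per_mating=2,
            mating_design="full_sib_loop", n_chrom=4, snps_per_chrom=1500,
            chrom_length_mb=75, genotyping_error_rate=0.002,
            missing_rate=0.005, seed=seed)
        ped = rk.simulate_pedigree(cfg)
        g, m, t = rk.gene_drop(ped, cfg)
        return g, m, t, ped

    def test_relaxing_het_allowance_is_monotone(self):
        g, m, _, _ = self._gene_drop()
        totals = []
        for max_het in (0, 1, 2):
            runs = detect_roh_sliding(g, m, RohParams(max_het=max_het))
            per_animal = runs.total_length_bp().reindex(g.samples,
                                                        fill_value=0)
            totals.append(per_animal)
        assert (totals[1] >= totals[0]).all()
        assert (totals[2] >= totals[1]).all()

    def test_emitted_runs_revalidate_against_genotypes(self):
        g, m, _, _ = self._gene_drop(seed=9)
        for runs in (detect_roh_sliding(g, m),
                     detect_runs_consecutive(g, m)):
            verify_counts(runs, g, m)  # raises on any mismatch

    def test_truth_segments_are_recovered(self):
        # error-free drop: every autozygous segment >= 1.5 x the minimum
        # length is covered >= 90% by detected ROH
        cfg = rk.SimulationConfig(
            n_founders=20, n_generations=3, offspring_per_mating=2,
            mating_design="full_sib_loop", n_chrom=4, snps_per_chrom=1500,
            chrom_length_mb=75, genotyping_error_rate=0.0, missing_rate=0.0,
            seed=15)
        ped = rk.simulate_pedigree(cfg)
        g, m, t = rk.gene_drop(ped, cfg)
        params = RohParams()
        runs = detect_roh_sliding(g, m, params)
        lengths = t.segments["end_bp"] - t.segments["start_bp"] + 1
        big = t.segments[lengths >= 1.5 * params.min_length_mb * 1e6]
        assert len(big) > 20
        for seg in big.itertuples(index=False):
            mine = runs.df[(runs.df["animal"] == seg.animal)
                           & (runs.df["chrom"] == seg.chrom)]
            covered = 0
            for r in mine.itertuples(index=False):
                covered += max(0, min(r.end_bp, seg.end_bp)
                               - max(r.start_bp, seg.start_bp))
            assert covered >= 0.9 * (seg.end_bp - seg.start_bp)

    def test_degenerate_window_equals_consecutive_hom(self):
        # window of 1 SNP with hit proportion 1 and no blemish allowance
        # reduces the sliding method to plain consecutive homozygous runs
        rng = np.random.default_rng(11)
        m = make_map(300, spacing_bp=40_000)
        vals = rng.choice([0, 1, 2], size=300, p=[0.3, 0.2, 0.5]).astype(np.int8)
        g = make_genotypes(vals)
        slid = detect_roh_sliding(g, m, RohParams(
            window_snps=1, window_hit_proportion=1.0, min_snps=10,
            min_length_mb=0.3, density_kb_per_snp=1e9, max_het=0,
            max_missing=0))
        cons = detect_runs_consecutive(g, m, ConsecutiveParams(
            target="hom", min_snps=10, min_length_kb=300, max_opposite=0,
            max_missing=0))
        cols = ["animal", "chrom", "start_bp", "end_bp", "n_snps"]
        assert slid.df[cols].reset_index(drop=True).equals(
            cons.df[cols].reset_index(drop=True))
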