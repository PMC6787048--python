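"""Bin-map genotyping: filters, windows, segmentation, breakpoints and
population summaries."""

import numpy as np
import pandas as pd
import pytest

import hapfish as hf
from hapfish.binmap import InputFilters


def make_rows(alleles, pos=None, depth=2, qual=60.0, mapq=60):
    n = len(alleles)
    return pd.DataFrame({
        "chrom": "chr1",
        "pos": pos if pos is not None else np.arange(1, n + 1) * 100,
        "allele": list(alleles),
        "depth": depth,
        "qual": qual,
        "mapq": mapq,
    })


class TestFilters:
    def test_empty_table(self):
        out = hf.filter_snp_calls(make_rows([]))
        assert out.empty

    def test_hand_evaluated_boundary_rows(self):
        rows = pd.DataFrame({
            "pos": [100, 200, 300, 400, 500, 600],
            "allele": ["P1"] * 6,
            "depth": [2, 40, 3, 2, 5, 1],
            "qual": [60, 900, 30, 45, 80, 40],
            "mapq": [60, 60, 60, 60, 60, 60],
        })
        # row 2: depth 40 not < 40; row 3: qual/depth == 10 not > 10
        out = hf.filter_snp_calls(rows)
        assert out["pos"].tolist() == [100, 400, 500, 600]

    def test_default_thresholds_are_published_values(self):
        f = InputFilters()
        assert (f.min_mapq, f.min_qual, f.max_depth, f.min_qual_over_depth) == \
            (50, 30, 40, 10)

    def test_missing_columns_named(self):
        with pytest.raises(ValueError, match="qual"):
            hf.filter_snp_calls(pd.DataFrame({"pos": [1]}))

    def test_tightening_thresholds_never_adds_rows(self, rng):
        rows = make_rows(
            ["P1"] * 200,
            depth=rng.integers(1, 60, 200),
            qual=rng.uniform(0, 200, 200),
            mapq=rng.choice([30, 60], 200),
        )
        base = hf.filter_snp_calls(rows)
        for tighter in (
            InputFilters(min_mapq=55), InputFilters(min_qual=40),
            InputFilters(max_depth=30), InputFilters(min_qual_over_depth=15),
        ):
            sub = hf.filter_snp_calls(rows, tighter)
            assert len(sub) <= len(base)
            assert set(sub["pos"]) <= set(base["pos"])


class TestWindowGenotype:
    @pytest.mark.parametrize("frac,call", [
        (1.0, "homP1"), (0.0, "homP2"), (0.81, "homP1"), (0.8, "het"),
        (0.5, "het"), (0.2, "het"), (0.19, "homP2"),
    ])
    def test_threshold_rules(self, frac, call):
        assert hf.window_genotype(frac) == call

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            hf.window_genotype(1.5)


class TestScanWindows:
    def test_exact_tiling_900_snps(self):
        rows = make_rows(["P1"] * 900)
        windows = hf.scan_windows(rows)
        assert len(windows) == 3
        assert all(w.n_snps == 300 and w.call == "homP1" for w in windows)

    def test_trailing_partial_window_rule(self):
        # 1050 SNPs: the trailing 150 >= half a window and is kept
        assert len(hf.scan_windows(make_rows(["P2"] * 1050))) == 4
        # 1049 SNPs: trailing 149 dropped
        assert len(hf.scan_windows(make_rows(["P2"] * 1049))) == 3

    def test_uniform_p2_input(self):
        for w in hf.scan_windows(make_rows(["P2"] * 900)):
            assert w.call == "homP2" and w.frac_p1 == 0.0

    def test_unsorted_positions_rejected(self):
        rows = make_rows(["P1"] * 10, pos=np.arange(10, 0, -1))
        with pytest.raises(ValueError, match="sorted"):
            hf.scan_windows(rows)


class TestSegmentsAndBreakpoints:
    def test_uniform_calls_no_exchange_points(self):
        rows = make_rows(["P1"] * 900)
        windows = hf.scan_windows(rows)
        segments, eps = hf.segment_and_call_breakpoints(windows, rows)
        assert len(segments) == 1 and eps == []

    def test_het_tract_flanked_by_hom_flags_ambiguous_double_co(self, rng):
        alleles = ["P2"] * 300
        alleles += [("P1" if rng.random() < 0.5 else "P2") for _ in range(300)]
        alleles += ["P2"] * 300
        rows = make_rows(alleles)
        windows = hf.scan_windows(rows)
        assert [w.call for w in windows] == ["homP2", "het", "homP2"]
        segments, eps = hf.segment_and_call_breakpoints(windows, rows)
        assert len(eps) == 2
        assert all(e.ambiguous_double_co for e in eps)
        assert eps[0].transition == ("homP2", "het")
        for e in eps:
            assert e.left_bound_bp < e.mid_bp < e.right_bound_bp

    def test_unrefined_bounds_are_window_boundary_snps(self):
        alleles = ["P1"] * 600 + ["P2"] * 600
        rows = make_rows(alleles)
        windows = hf.scan_windows(rows)
        _, eps = hf.segment_and_call_breakpoints(windows, rows=None, refine=False)
        assert len(eps) == 1
        assert eps[0].left_bound_bp == int(rows["pos"][599])
        assert eps[0].right_bound_bp == int(rows["pos"][600])

    def test_refined_interval_contains_sharp_transition(self):
        alleles = ["P1"] * 750 + ["P2"] * 750
        rows = make_rows(alleles)
        result = hf.call_binmap(rows, filters=None)
        assert len(result.exchange_points) == 1
        e = result.exchange_points[0]
        true_bp = (rows["pos"][749] + rows["pos"][750]) / 2
        assert e.left_bound_bp <= true_bp <= e.right_bound_bp
        # noiseless step transition: the support interval is tight
        assert e.right_bound_bp - e.left_bound_bp < 3000

    def test_hidden_subwindow_tract_recovered(self, rng):
        # a 120-SNP homozygous tract inside a heterozygous background never
        # dominates any 300-SNP window but must still be split out
        het = lambda n: [("P1" if rng.random() < 0.5 else "P2") for _ in range(n)]
        alleles = het(450) + ["P1"] * 120 + het(450)
        rows = make_rows(alleles)
        result = hf.call_binmap(rows, filters=None)
        calls = [s.call for s in result.segments]
        assert calls == ["het", "homP1", "het"]
        assert len(result.exchange_points) == 2

    def test_single_plant_simulation_truth_in_bounds(self, pair1mb):
        plant = hf.simulate_f2_plant(pair1mb, {1: 1.0}, seed=77)
        obs = hf.sample_allele_observations(plant, pair1mb, mean_depth=2.41,
                                            error_rate=0.01, seed=78)
        result = hf.call_binmap(obs)
        for copy in plant:
            bp = copy.breakpoints[0] + 1  # 1-based observation coordinates
            assert any(
                e.left_bound_bp <= bp <= e.right_bound_bp
                for e in result.exchange_points
            )

    def test_noiseless_parental_copies_give_zero_exchange_points(self, pair1mb):
        plant = hf.simulate_f2_plant(pair1mb, {0: 1.0}, seed=79)
        obs = hf.sample_allele_observations(plant, pair1mb, error_rate=0.0, seed=80)
        result = hf.call_binmap(obs)
        assert result.exchange_points == []

    def test_windows_partition_retained_snps(self, pair1mb):
        plant = hf.simulate_f2_plant(pair1mb, seed=81)
        obs = hf.sample_allele_observations(plant, pair1mb, seed=82)
        result = hf.call_binmap(obs)
        spans = [(w.first_snp_index, w.first_snp_index + w.n_snps)
                 for w in result.windows]
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert b == c
        assert spans[0][0] == 0


class TestPopulationSummary:
    @staticmethod
    def records():
        # 116 copies: 50 with an exchange, 60 exchange-negative, 6 ambiguous;
        # 13 sequencing-checked copies, 9 of them confirmed non-recombinant
        return (
            [{"status": "recombinant"} for _ in range(50)]
            + [{"status": "non_recombinant", "checked": i < 13,
                "confirmed_non_co": i < 9} for i in range(60)]
            + [{"status": "ambiguous"} for _ in range(6)]
        )

    def test_published_percentages(self):
        out = hf.summarize_population(self.records())
        assert out["n_total"] == 116
        assert out["pct_with_exchange"] == 43
        assert out["pct_confirmed_non_co"] == 69
        assert out["pct_non_co_estimate"] == 36

    def test_distance_to_chromosome_end(self):
        assert hf.distance_to_end(145.73e6, 150.98e6) == pytest.approx(5.25e6)
        out = hf.summarize_population(
            [{"status": "recombinant", "ep_bp": [145.73e6]}], chrom_len_bp=150.98e6
        )
        assert out["ep_distance_to_end_bp"][0] == pytest.approx(5.25e6)

    def test_estimate_without_checked_records_rejected(self):
        with pytest.raises(ValueError, match="checked"):
            hf.summarize_population(
                [{"status": "recombinant", "confirmed_non_co": True}]
            )
        with pytest.raises(ValueError, match="no records"):
            hf.summarize_population([])
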