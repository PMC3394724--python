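import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divscan import window_scan as ws
from divscan.errors import DomainError
from divscan.genotype_io import MISSING

from conftest import make_dataset


class TestLineAlleleFreq:
    @pytest.mark.parametrize(
        "genos, expected",
        [
            ([2, 2, 1, 0], 5 / 8),
            ([2, 2, 2, 2], 1.0),
            ([2, MISSING, 0], 0.5),  # missing excluded from the denominator
        ],
    )
    def test_direct_count(self, genos, expected):
        ds = make_dataset(np.array(genos)[:, None], ["lean"] * len(genos))
        assert ws.line_allele_freq(ds, "lean")[0] == pytest.approx(expected)

    def test_zero_calls_flagged_as_nan(self):
        ds = make_dataset([[MISSING], [MISSING], [2]], ["lean", "lean", "fat"])
        assert np.isnan(ws.line_allele_freq(ds, "lean")[0])

    def test_unknown_line_rejected(self):
        ds = make_dataset([[1]], ["lean"])
        with pytest.raises(DomainError):
            ws.line_allele_freq(ds, "fat")


class TestSnpStats:
    def test_afd_and_heterozygosity_closed_forms(self):
        # lean: p = 0.9 (het 0.18); fat: p = 0.2 (het 0.32); afd 0.7
        lean = [[2]] * 4 + [[1]]  # 9/10
        fat = [[1]] * 2 + [[0]] * 3  # 2/10
        ds = make_dataset(np.array(lean + fat), ["lean"] * 5 + ["fat"] * 5)
        s = ws.snp_stats(ds)
        assert s["afd"][0] == pytest.approx(0.7)
        assert s["het_lean"][0] == pytest.approx(2 * 0.9 * 0.1)
        assert s["het_fat"][0] == pytest.approx(2 * 0.2 * 0.8)

    def test_equal_frequencies_give_zero_afd(self):
        ds = make_dataset([[1], [1]], ["lean", "fat"])
        s = ws.snp_stats(ds)
        assert s["afd"][0] == 0.0
        assert s["het_lean"][0] == pytest.approx(0.5)  # p = 0.5

    def test_fixed_alleles_have_zero_heterozygosity(self):
        ds = make_dataset([[2], [0]], ["lean", "fat"])
        s = ws.snp_stats(ds)
        assert s["het_lean"][0] == 0.0 and s["het_fat"][0] == 0.0


def _markers(positions, chrom="1"):
    return pd.DataFrame(
        {
            "id": [f"m{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos_bp": positions,
            "allele_a": "A",
            "allele_b": "G",
        }
    )


class TestSlidingWindows:
    def test_interval_membership(self):
        m = _markers([100_000, 300_000, 600_000])
        wins = ws.sliding_windows(m, size_bp=500_000, step_bp=500_000, min_snps=1)
        first = next(w for w in wins if w.start_bp == 0)
        assert first.snp_idx.tolist() == [0, 1]

    def test_empty_chromosome_yields_no_windows(self):
        assert ws.sliding_windows(_markers([])) == []

    def test_min_snps_filter_drops_thin_windows(self):
        m = _markers([100_000, 300_000, 600_000])
        wins = ws.sliding_windows(m, size_bp=500_000, step_bp=500_000, min_snps=3)
        assert wins == []

    @given(
        pos=st.lists(
            st.integers(min_value=1, max_value=2_000_000),
            min_size=1, max_size=60, unique=True,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_membership_matches_exhaustive_interval_scan(self, pos):
        size, step = 500_000, 250_000
        m = _markers(sorted(pos))
        wins = ws.sliding_windows(m, size_bp=size, step_bp=step, min_snps=1)
        sorted_pos = np.array(sorted(pos))
        # oracle: exhaustive interval scan over the step-multiple grid anchored
        # at the first marker position rounded down to a step multiple
        expected = {}
        start = (int(sorted_pos.min()) // step) * step
        while start <= sorted_pos.max():
            members = [
                i for i, p in enumerate(sorted_pos) if start <= p < start + size
            ]
            if members:
                expected[start] = members
            start += step
        got = {w.start_bp: w.snp_idx.tolist() for w in wins}
        assert got == expected


class TestWindowSummary:
    def test_unweighted_means(self):
        ds = make_dataset(
            np.array([[2, 2], [1, 0], [1, 2], [0, 0]]),
            ["lean", "lean", "fat", "fat"],
            positions=[100_000, 200_000],
        )
        stats = ws.snp_stats(ds)
        wins = ws.sliding_windows(ds.markers, min_snps=1)
        wdf = ws.window_summary(wins, stats)
        row = wdf[wdf.start_bp == 0].iloc[0]
        assert row.afd_mean == pytest.approx(stats["afd"].mean())
        assert row.het_lean_mean == pytest.approx(stats["het_lean"].mean())

    def test_random_window_matches_direct_resummation(self, small_sim):
        stats = ws.snp_stats(small_sim.dataset)
        wins = ws.sliding_windows(small_sim.dataset.markers)
        wdf = ws.window_summary(wins, stats)
        k = len(wins) // 2
        expected = stats.iloc[wins[k].snp_idx]["afd"].mean()
        assert wdf.iloc[k]["afd_mean"] == pytest.approx(expected)

    def test_increasing_member_afd_never_decreases_mean(self, small_sim):
        stats = ws.snp_stats(small_sim.dataset)
        wins = ws.sliding_windows(small_sim.dataset.markers)
        base = ws.window_summary(wins, stats)["afd_mean"]
        boosted = stats.copy()
        boosted["afd"] = np.minimum(boosted["afd"] + 0.05, 1.0)
        up = ws.window_summary(wins, boosted)["afd_mean"]
        assert (up >= base - 1e-12).all()


class TestStandardize:
    def _wdf(self, values, chrom="1"):
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start_bp": 250_000 * np.arange(len(values)),
                "end_bp": 250_000 * np.arange(len(values)) + 500_000,
                "n_snps": 5,
                "n_snps_used": 5,
                "afd_mean": values,
                "het_lean_mean": values,
                "het_fat_mean": values,
            }
        )

    def test_z_has_mean_zero_and_unit_sample_sd(self):
        out = ws.standardize_by_chrom(self._wdf([0.1, 0.2, 0.5, 0.3, 0.15]))
        assert out["z_afd"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["z_afd"].std(ddof=1) == pytest.approx(1.0)

    def test_hand_computed_values(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = ws.standardize_by_chrom(self._wdf(vals))
        sd = np.std(vals, ddof=1)
        assert out["z_afd"].tolist() == pytest.approx(
            [(v - 3.0) / sd for v in vals]
        )

    def test_constant_chromosome_flagged_non_assessable(self):
        out = ws.standardize_by_chrom(self._wdf([0.2, 0.2, 0.2]))
        assert out["z_afd"].isna().all()
        assert (~out["assessable"]).all()

    def test_shift_invariance(self):
        base = ws.standardize_by_chrom(self._wdf([0.1, 0.2, 0.5, 0.3]))
        shifted = ws.standardize_by_chrom(
            self._wdf([0.1 + 0.2, 0.2 + 0.2, 0.5 + 0.2, 0.3 + 0.2])
        )
        assert np.allclose(base["z_afd"], shifted["z_afd"])


def _wrow(chrom, start, afd, z_afd, z_lean, z_fat):
    return {
        "chrom": chrom, "start_bp": start, "end_bp": start + 500_000,
        "n_snps": 10, "n_snps_used": 10, "afd_mean": afd,
        "het_lean_mean": 0.3, "het_fat_mean": 0.3,
        "z_afd": z_afd, "z_lean": z_lean, "z_fat": z_fat, "assessable": True,
    }


class TestCallSignatures:
    def test_large_afd_and_zafd_flag_both_signals(self):
        wdf = pd.DataFrame([_wrow("Z", 0, 0.75, 4.98, -3.7, -1.13)])
        sig = ws.call_signatures(wdf)
        assert len(sig) == 1
        assert sig.iloc[0]["signals"] == "AFD,Z_AFD"

    def test_heterozygosity_increase_is_a_signal_with_note(self):
        wdf = pd.DataFrame([_wrow("26", 0, 0.50, 4.50, -3.58, 5.02)])
        sig = ws.call_signatures(wdf)
        assert sig.iloc[0]["signals"] == "AFD,Z_AFD,Z_fat_up"
        assert "extreme-initial-frequency" in sig.iloc[0]["note"]

    def test_single_line_het_decrease_flags_and_infers_line(self):
        wdf = pd.DataFrame([_wrow("1", 0, 0.26, 1.42, 0.76, -5.99)])
        sig = ws.call_signatures(wdf)
        assert sig.iloc[0]["signals"] == "Z_fat_down"
        assert sig.iloc[0]["inferred_line"] == "fat"

    def test_subthreshold_windows_are_not_flagged(self):
        wdf = pd.DataFrame([_wrow("5", 0, 0.42, 3.9, -4.05, 0.35)])
        assert len(ws.call_signatures(wdf)) == 0

    def test_overlapping_flagged_windows_merge_and_regions_are_disjoint(self):
        wdf = pd.DataFrame(
            [
                _wrow("1", 0, 0.5, 5.0, 0, 0),
                _wrow("1", 250_000, 0.6, 5.5, 0, 0),
                _wrow("1", 2_000_000, 0.5, 4.4, 0, 0),
                _wrow("2", 0, 0.45, 4.1, 0, 0),
            ]
        )
        sig = ws.call_signatures(wdf)
        assert len(sig) == 3
        first = sig.iloc[0]
        assert (first.start_bp, first.end_bp) == (0, 750_000)
        assert first.peak_afd == pytest.approx(0.6)
        by_chrom = sig.groupby("chrom")
        for _, grp in by_chrom:
            starts = grp["start_bp"].to_numpy()
            ends = grp["end_bp"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()


class TestChromosomeSummary:
    def test_fixed_allele_counts_match_brute_force(self, small_sim):
        stats = ws.snp_stats(small_sim.dataset)
        summary = ws.chromosome_summary(small_sim.dataset, stats)
        for _, row in summary.iterrows():
            grp = stats[stats["chrom"] == row["chrom"]]
            for line in ("lean", "fat"):
                fixed = sum(1 for p in grp[f"p_{line}"] if p in (0.0, 1.0))
                assert row[f"fixed_{line}"] == fixed
                assert row[f"fixed_{line}_pct"] == pytest.approx(
                    100.0 * fixed / len(grp)
                )

    def test_no_fixed_alleles_counts_zero(self):
        ds = make_dataset(
            np.array([[1, 1], [1, 1], [1, 1], [1, 1]]),
            ["lean", "lean", "fat", "fat"],
        )
        summary = ws.chromosome_summary(ds, ws.snp_stats(ds))
        assert summary.iloc[0]["fixed_lean"] == 0

    def test_percentage_arithmetic(self):
        g = np.ones((4, 100), dtype=np.int8)
        g[:, :2] = 2  # two fixed SNPs
        ds = make_dataset(g, ["lean", "lean", "fat", "fat"])
        summary = ws.chromosome_summary(ds, ws.snp_stats(ds))
        assert summary.iloc[0]["fixed_lean"] == 2
        assert summary.iloc[0]["fixed_lean_pct"] == pytest.approx(2.0)
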