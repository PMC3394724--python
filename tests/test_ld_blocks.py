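import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from divscan import ld_blocks as ld

from conftest import make_phased


def oracle_ld(c):
    """Direct from-scratch evaluation of D, D', r2 on haplotype counts."""
    n = c.total
    pa = (c.n11 + c.n12) / n
    pb = (c.n11 + c.n21) / n
    d = c.n11 / n - pa * pb
    dmax = (
        min(pa * (1 - pb), (1 - pa) * pb)
        if d >= 0
        else min(pa * pb, (1 - pa) * (1 - pb))
    )
    return d, abs(d) / dmax, d * d / (pa * (1 - pa) * pb * (1 - pb))


counts_strategy = st.tuples(
    *[st.integers(min_value=0, max_value=60)] * 4
).filter(lambda t: sum(t) >= 2)


class TestLdMeasures:
    def test_complete_ld(self):
        pair = ld.ld_measures(ld.TwoLocusCounts(5, 0, 0, 5))
        assert pair.dprime == pytest.approx(1.0)
        assert pair.r2 == pytest.approx(1.0)

    def test_independence(self):
        pair = ld.ld_measures(ld.TwoLocusCounts(25, 25, 25, 25))
        assert pair.d == pytest.approx(0.0)
        assert pair.r2 == pytest.approx(0.0)

    def test_matches_direct_formula(self):
        c = ld.TwoLocusCounts(40, 10, 10, 40)
        pair = ld.ld_measures(c)
        d, dp, r2 = oracle_ld(c)
        assert r2 == pytest.approx(0.36)
        assert (pair.d, pair.dprime, pair.r2) == pytest.approx((d, dp, r2))

    def test_monomorphic_locus_is_undefined(self):
        assert ld.ld_measures(ld.TwoLocusCounts(10, 10, 0, 0)) is None

    @given(counts=counts_strategy)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_and_formula_agreement(self, counts):
        c = ld.TwoLocusCounts(*counts)
        pair = ld.ld_measures(c)
        if pair is None:
            n = c.total
            pa = (c.n11 + c.n12) / n
            pb = (c.n11 + c.n21) / n
            assert pa in (0.0, 1.0) or pb in (0.0, 1.0)
            return
        assert -1e-9 <= pair.r2 <= 1 + 1e-9
        assert -1e-9 <= pair.dprime <= 1 + 1e-9
        _, dp, r2 = oracle_ld(c)
        assert pair.dprime == pytest.approx(min(dp, 1.0), abs=1e-9)
        assert pair.r2 == pytest.approx(min(r2, 1.0), abs=1e-9)


def oracle_dprime_ci(c, grid_points=10_001, tail=0.05):
    """Fine-grid normalization of the multinomial likelihood over |D'|."""
    n = c.total
    pa = (c.n11 + c.n12) / n
    pb = (c.n11 + c.n21) / n
    d_obs = c.n11 / n - pa * pb
    sign = 1.0 if d_obs >= 0 else -1.0
    dmax = (
        min(pa * (1 - pb), (1 - pa) * pb)
        if d_obs >= 0
        else min(pa * pb, (1 - pa) * (1 - pb))
    )
    grid = np.linspace(0, 1, grid_points)
    weights = np.empty(grid_points)
    counts = [c.n11, c.n12, c.n21, c.n22]
    for k, dp in enumerate(grid):
        d = sign * dp * dmax
        probs = np.clip(
            [
                pa * pb + d,
                pa * (1 - pb) - d,
                (1 - pa) * pb - d,
                (1 - pa) * (1 - pb) + d,
            ],
            1e-12,
            None,
        )
        weights[k] = sps.multinomial.logpmf(counts, n, probs / probs.sum())
    w = np.exp(weights - weights.max())
    w /= w.sum()
    cdf = np.cumsum(w)
    upper = np.cumsum(w[::-1])[::-1]
    low = grid[np.argmax(cdf >= tail)]
    high = grid[len(grid) - 1 - np.argmax((upper >= tail)[::-1])]
    return low, high


class TestDprimeCi:
    def test_large_sample_complete_ld_concentrates_at_one(self):
        low, high = ld.dprime_ci(ld.TwoLocusCounts(500, 0, 0, 500))
        assert low >= 0.98
        assert high == pytest.approx(1.0)
        assert ld.classify_pair((low, high)) == "strong"

    def test_tiny_sample_is_uninformative(self):
        low, high = ld.dprime_ci(ld.TwoLocusCounts(2, 1, 1, 0))
        assert high - low > 0.5
        assert ld.classify_pair((low, high)) == "uninformative"

    def test_endpoints_match_fine_grid_oracle(self):
        c = ld.TwoLocusCounts(30, 5, 5, 30)
        low, high = ld.dprime_ci(c)
        o_low, o_high = oracle_dprime_ci(c)
        assert low == pytest.approx(o_low, abs=0.011)
        assert high == pytest.approx(o_high, abs=0.011)

    @given(counts=counts_strategy)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_ci_brackets_point_estimate(self, counts):
        c = ld.TwoLocusCounts(*counts)
        pair = ld.ld_measures(c)
        ci = ld.dprime_ci(c)
        if pair is None or ci is None:
            return
        low, high = ci
        assert low <= high
        # the point estimate lies inside the CI up to grid resolution
        assert low - 0.011 <= pair.dprime <= high + 0.011

    def test_replication_narrows_the_ci(self):
        widths = []
        for mult in (1, 4, 16):
            low, high = ld.dprime_ci(
                ld.TwoLocusCounts(12 * mult, 3 * mult, 3 * mult, 12 * mult)
            )
            widths.append(high - low)
        assert widths[0] > widths[1] > widths[2]


def oracle_gabriel(ci_by_pair, n, strong_low=0.70, strong_high=0.98,
                   recomb_high=0.90, min_frac=0.95):
    """Exhaustive span enumeration + greedy selection, written independently,
    sharing only the pair classifications."""
    def pair_class(i, j):
        ci = ci_by_pair.get((i, j))
        if ci is None:
            return "uninformative"
        lo, hi = ci
        if lo >= strong_low and hi >= strong_high:
            return "strong"
        if hi < recomb_high:
            return "recomb"
        return "uninformative"

    spans = []
    for i, j in itertools.combinations(range(n), 2):
        classes = [
            pair_class(a, b) for a, b in itertools.combinations(range(i, j + 1), 2)
        ]
        informative = [cl for cl in classes if cl != "uninformative"]
        if informative and (
            sum(cl == "strong" for cl in informative) / len(informative) >= min_frac
        ):
            spans.append((i, j))
    spans.sort(key=lambda s: (-(s[1] - s[0]), s[0]))
    chosen, used = [], set()
    for i, j in spans:
        if not used.intersection(range(i, j + 1)):
            chosen.append((i, j))
            used.update(range(i, j + 1))
    return sorted(chosen)


def _panel_with_blocks(seed=5, n_markers=12, n_per_line=60):
    """Seeded panel: markers 0-4 drawn from 2 pool haplotypes (strong LD),
    5-11 independent (equilibrium)."""
    rng = np.random.default_rng(seed)
    pool = rng.choice(["A", "G"], size=(2, 5))
    while (pool[0] == pool[1]).all():
        pool = rng.choice(["A", "G"], size=(2, 5))
    rows = []
    for _ in range(2 * n_per_line):
        left = pool[rng.integers(0, 2)]
        right = rng.choice(["A", "G"], size=7)
        rows.append("".join(np.concatenate([left, right])))
    return make_phased(rows, ["lean"] * n_per_line + ["fat"] * n_per_line)


class TestGabrielBlocks:
    def test_perfect_ld_panel_gives_one_block(self):
        rows = ["AAAAA", "GGGGG"] * 50
        ph = make_phased(rows, ["lean", "lean", "fat", "fat"] * 25)
        blocks = ld.blocks_for_line(ph, "lean")
        assert len(blocks) == 1
        assert (blocks[0].start_idx, blocks[0].end_idx) == (0, 4)

    def test_linkage_equilibrium_gives_no_blocks(self):
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(["A", "G"], 6)) for _ in range(200)]
        ph = make_phased(rows, ["lean"] * 100 + ["fat"] * 100)
        assert ld.blocks_for_line(ph, "lean") == []

    def test_matches_exhaustive_span_oracle_on_12_marker_panel(self):
        ph = _panel_with_blocks()
        pairs = ld.ld_scan(ph, "lean")
        ci = {k: (v.ci_low, v.ci_high) for k, v in pairs.items()
              if v.ci_low is not None}
        blocks = ld.gabriel_blocks(ci, ph.markers)
        got = sorted((b.start_idx, b.end_idx) for b in blocks)
        assert got == oracle_gabriel(ci, ph.n_markers)
        assert (0, 4) in got

    def test_invariant_to_allele_relabeling(self):
        ph = _panel_with_blocks(seed=8)
        base = [(b.start_idx, b.end_idx) for b in ld.blocks_for_line(ph, "lean")]
        flipped = ph.alleles.copy()
        flipped[:, 2] = np.where(flipped[:, 2] == "A", "G", "A")
        ph2 = make_phased(["".join(r) for r in flipped], ph.samples["line"].tolist())
        relabeled = [(b.start_idx, b.end_idx) for b in ld.blocks_for_line(ph2, "lean")]
        assert relabeled == base


class TestMeanAdjacentR2:
    def test_complete_ld_gives_one(self):
        rows = ["AAAA", "GGGG"] * 30
        ph = make_phased(rows, ["lean", "lean", "fat", "fat"] * 15)
        assert ld.mean_adjacent_r2(ph, "lean") == pytest.approx(1.0)

    def test_independent_markers_give_near_zero(self):
        rng = np.random.default_rng(9)
        n = 2000
        rows = ["".join(rng.choice(["A", "G"], 5)) for _ in range(n)]
        ph = make_phased(rows, ["lean"] * (n // 2) + ["fat"] * (n // 2))
        assert ld.mean_adjacent_r2(ph, "lean") < 5.0 / (n // 2)

    def test_equals_mean_of_individually_recomputed_pairs(self):
        ph = _panel_with_blocks(seed=12, n_markers=6)
        vals = []
        for i in range(ph.n_markers - 1):
            pair = ld.ld_measures(ld.two_locus_counts(ph, i, i + 1, ph.line_rows("fat")))
            if pair is not None:
                vals.append(pair.r2)
        assert ld.mean_adjacent_r2(ph, "fat") == pytest.approx(np.mean(vals))
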