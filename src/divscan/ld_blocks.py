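"""Pairwise linkage disequilibrium from phased haplotypes and haplotype-block
definition by the Gabriel confidence-interval rules.

For two biallelic loci with allele-1 frequencies p_A, p_B and haplotype-11
frequency p_11:

    D  = p_11 - p_A * p_B
    D' = D / D_max, with D_max = min(p_A(1-p_B), (1-p_A)p_B) for D >= 0
                     and D_max = min(p_A p_B, (1-p_A)(1-p_B)) for D < 0
    r2 = D^2 / (p_A(1-p_A) p_B(1-p_B))

A confidence interval on |D'| comes from the multinomial likelihood of the
four observed haplotype counts evaluated over a grid of |D'| values with the
allele frequencies fixed at their observed margins.  Pairs are classified as
strong LD (CI low >= 0.70 and high >= 0.98) or strong recombination
(CI high < 0.90); a marker span is a block when at least 95% of its
informative pairs are in strong LD, and maximal non-overlapping blocks are
kept greedily in descending size order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .genotype_io import MISSING, PhasedHaplotypes

CI_STRONG_LOW = 0.70
CI_STRONG_HIGH = 0.98
CI_RECOMB_HIGH = 0.90
MIN_STRONG_FRACTION = 0.95


@dataclass(frozen=True)
class TwoLocusCounts:
    """Haplotype counts between two markers in one line: n11 counts haplotypes
    carrying allele 1 at both loci, n12 allele 1 at the first only, etc."""

    n11: int
    n12: int
    n21: int
    n22: int

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    def as_array(self) -> np.ndarray:
        return np.array([self.n11, self.n12, self.n21, self.n22], dtype=float)


@dataclass(frozen=True)
class LdPair:
    i: int
    j: int
    d: float
    dprime: float
    r2: float
    ci_low: float | None = None
    ci_high: float | None = None


def _counts_from_codes(codes: np.ndarray, i: int, j: int, rows=None) -> TwoLocusCounts:
    a = codes[rows if rows is not None else slice(None), i]
    b = codes[rows if rows is not None else slice(None), j]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    return TwoLocusCounts(
        n11=int(np.sum((a == 1) & (b == 1))),
        n12=int(np.sum((a == 1) & (b == 0))),
        n21=int(np.sum((a == 0) & (b == 1))),
        n22=int(np.sum((a == 0) & (b == 0))),
    )


def two_locus_counts(ph: PhasedHaplotypes, i: int, j: int, rows=None) -> TwoLocusCounts:
    """Count the four two-locus haplotypes between markers ``i`` and ``j``
    over the given haplotype rows (default: all); rows missing either site are
    dropped."""
    return _counts_from_codes(ph.allele1_codes(), i, j, rows)


def _margins(c: TwoLocusCounts):
    n = c.total
    p_a = (c.n11 + c.n12) / n
    p_b = (c.n11 + c.n21) / n
    return p_a, p_b


def ld_measures(c: TwoLocusCounts, i: int = -1, j: int = -1) -> LdPair | None:
    """D, D' and r2 from two-locus haplotype counts.

    Returns None (undefined LD) when either locus is monomorphic in the
    counted sample; such pairs are excluded from means and block rules.
    """
    n = c.total
    if n == 0:
        return None
    p_a, p_b = _margins(c)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return None
    d = c.n11 / n - p_a * p_b
    if d >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LdPair(i=i, j=j, d=d, dprime=min(dprime, 1.0), r2=min(r2, 1.0))


def dprime_ci(
    c: TwoLocusCounts, grid: int = 101, tail: float = 0.05
) -> tuple[float, float] | None:
    """Likelihood-based confidence interval on |D'|.

    The multinomial likelihood of the four counts is evaluated on a ``grid``
    of |D'| values in [0, 1] (allele frequencies fixed at the observed
    margins, the sign of D fixed at its point estimate), normalized to a unit
    mass.  The lower bound is the smallest grid value whose inclusive
    cumulative mass reaches ``tail``; the upper bound is the largest grid
    value whose inclusive upper-tail mass reaches ``tail``.  The interval is
    widened, when necessary, to include the grid maximum-likelihood value, so
    the reported CI always brackets the point estimate (relevant only for
    near-flat likelihoods with a boundary maximum).

    Returns None when the margins are degenerate (monomorphic locus).
    """
    if c.total < 2:
        return None
    p_a, p_b = _margins(c)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return None
    d_obs = c.n11 / c.total - p_a * p_b
    if d_obs >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
        sign = 1.0
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
        sign = -1.0
    if dmax <= 0:
        return None
    dp = np.linspace(0.0, 1.0, grid)
    d = sign * dp * dmax
    p11 = np.clip(p_a * p_b + d, 1e-12, None)
    p12 = np.clip(p_a * (1 - p_b) - d, 1e-12, None)
    p21 = np.clip((1 - p_a) * p_b - d, 1e-12, None)
    p22 = np.clip((1 - p_a) * (1 - p_b) + d, 1e-12, None)
    counts = c.as_array()
    ll = (
        counts[0] * np.log(p11)
        + counts[1] * np.log(p12)
        + counts[2] * np.log(p21)
        + counts[3] * np.log(p22)
    )
    w = np.exp(ll - ll.max())
    w /= w.sum()
    cdf = np.cumsum(w)
    upper = np.cumsum(w[::-1])[::-1]  # inclusive upper-tail mass
    low = dp[np.argmax(cdf >= tail)]
    high = dp[len(dp) - 1 - np.argmax((upper >= tail)[::-1])]
    mle = dp[np.argmax(w)]
    return float(min(low, mle)), float(max(high, mle))


def classify_pair(
    ci: tuple[float, float] | None,
    strong_low: float = CI_STRONG_LOW,
    strong_high: float = CI_STRONG_HIGH,
    recomb_high: float = CI_RECOMB_HIGH,
) -> str:
    """'strong', 'recomb' or 'uninformative' from a D' confidence interval."""
    if ci is None:
        return "uninformative"
    low, high = ci
    if low >= strong_low and high >= strong_high:
        return "strong"
    if high < recomb_high:
        return "recomb"
    return "uninformative"


@dataclass(frozen=True)
class BlockDefinition:
    chrom: str
    start_idx: int  # marker indices, inclusive
    end_idx: int
    start_bp: int
    end_bp: int
    n_strong: int
    n_informative: int

    @property
    def n_markers(self) -> int:
        return self.end_idx - self.start_idx + 1


def gabriel_blocks(
    ci_by_pair: dict[tuple[int, int], tuple[float, float] | None],
    markers,
    strong_low: float = CI_STRONG_LOW,
    strong_high: float = CI_STRONG_HIGH,
    recomb_high: float = CI_RECOMB_HIGH,
    min_strong_fraction: float = MIN_STRONG_FRACTION,
    two_marker_strong_low: float | None = None,
) -> list[BlockDefinition]:
    """Gabriel-rule haplotype blocks from pairwise D' confidence intervals.

    ``ci_by_pair`` maps marker index pairs (i < j) to CIs (None = undefined).
    A span [i, j] (j > i) qualifies when it has at least one informative pair
    and strong/informative >= ``min_strong_fraction``; qualifying spans are
    accepted greedily, largest marker count first (ties: leftmost), skipping
    spans that overlap an accepted block.

    ``two_marker_strong_low`` optionally raises the strong-LD lower bound for
    two-marker spans (Haploview applies stricter rules to short spans); by
    default short spans use the same thresholds as long ones.
    """
    n = len(markers)
    cls: dict[tuple[int, int], str] = {}
    for (i, j), ci in ci_by_pair.items():
        cls[(i, j)] = classify_pair(ci, strong_low, strong_high, recomb_high)

    candidates = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            strong = informative = 0
            for a in range(i, j):
                for b in range(a + 1, j + 1):
                    kind = cls.get((a, b), "uninformative")
                    if kind == "strong" and j == i + 1 and two_marker_strong_low is not None:
                        ci = ci_by_pair.get((a, b))
                        if ci is None or ci[0] < two_marker_strong_low:
                            kind = "uninformative"
                    if kind == "strong":
                        strong += 1
                        informative += 1
                    elif kind == "recomb":
                        informative += 1
            if informative >= 1 and strong / informative >= min_strong_fraction:
                candidates.append((i, j, strong, informative))

    candidates.sort(key=lambda t: (-(t[1] - t[0]), t[0]))
    taken = np.zeros(n, dtype=bool)
    blocks = []
    pos = markers["pos_bp"].to_numpy()
    chrom = str(markers["chrom"].iloc[0]) if n else ""
    for i, j, strong, informative in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append(
            BlockDefinition(
                chrom=chrom,
                start_idx=i,
                end_idx=j,
                start_bp=int(pos[i]),
                end_bp=int(pos[j]),
                n_strong=strong,
                n_informative=informative,
            )
        )
    blocks.sort(key=lambda b: b.start_idx)
    return blocks


def ld_scan(
    ph: PhasedHaplotypes,
    line: str | None = None,
    max_distance_bp: int = 1_000_000,
    with_ci: bool = True,
) -> dict[tuple[int, int], LdPair]:
    """All pairwise LD measures (optionally with D' CIs) within one line and a
    maximum marker distance."""
    rows = ph.line_rows(line) if line is not None else None
    codes = ph.allele1_codes()
    pos = ph.markers["pos_bp"].to_numpy()
    out: dict[tuple[int, int], LdPair] = {}
    for i in range(ph.n_markers - 1):
        for j in range(i + 1, ph.n_markers):
            if pos[j] - pos[i] > max_distance_bp:
                break
            c = _counts_from_codes(codes, i, j, rows)
            pair = ld_measures(c, i, j)
            if pair is None:
                continue
            if with_ci:
                ci = dprime_ci(c)
                if ci is not None:
                    pair = LdPair(i, j, pair.d, pair.dprime, pair.r2, ci[0], ci[1])
            out[(i, j)] = pair
    return out


def blocks_for_line(
    ph: PhasedHaplotypes,
    line: str,
    max_distance_bp: int = 1_000_000,
    **gabriel_kwargs,
) -> list[BlockDefinition]:
    pairs = ld_scan(ph, line, max_distance_bp, with_ci=True)
    ci = {k: (v.ci_low, v.ci_high) for k, v in pairs.items() if v.ci_low is not None}
    return gabriel_blocks(ci, ph.markers, **gabriel_kwargs)


def mean_adjacent_r2(ph: PhasedHaplotypes, line: str | None = None) -> float:
    """Unweighted mean r2 over adjacent marker pairs with defined LD.

    Raises DomainError when no adjacent pair has defined LD.
    """
    rows = ph.line_rows(line) if line is not None else None
    codes = ph.allele1_codes()
    vals = []
    for i in range(ph.n_markers - 1):
        pair = ld_measures(_counts_from_codes(codes, i, i + 1, rows), i, i + 1)
        if pair is not None:
            vals.append(pair.r2)
    if not vals:
        raise DomainError("no adjacent marker pair with defined LD")
    return float(np.mean(vals))
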