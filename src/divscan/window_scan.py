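"""Sliding-window allele-frequency-difference and heterozygosity scan.

Per SNP the scan computes the frequency of allele 1 in each line, the absolute
between-line allele frequency difference (AFD) and per-line expected
heterozygosity 2p(1-p).  SNP statistics are averaged in 0.5 Mb sliding
windows, window values are standardized per chromosome (AFD against the
chromosome's window AFD distribution; each line's heterozygosity against its
own within-line chromosome distribution) and windows are flagged as selection
signatures by threshold rules:

    afd_mean >= 0.44  OR  Z_AFD >= 4.0  OR  |Z_lean| >= 5.0  OR  |Z_fat| >= 5.0

A heterozygosity *decrease* in exactly one line marks that line as selected; a
heterozygosity *increase* is kept as a signal too, because a large frequency
change from an extreme starting frequency raises heterozygosity, and a "p-q
sweep" (p_t = q_0, q_t = p_0) changes heterozygosity not at all -- AFD is the
only signal that sees it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .genotype_io import MISSING, LINES, GenotypeDataset

WINDOW_SIZE_BP = 500_000
WINDOW_STEP_BP = 250_000
MIN_SNPS_PER_WINDOW = 3

#: signature-calling thresholds
AFD_THRESHOLD = 0.44
Z_AFD_THRESHOLD = 4.0
Z_HET_THRESHOLD = 5.0


def line_allele_freq(ds: GenotypeDataset, line: str) -> np.ndarray:
    """Frequency of allele 1 per SNP within one line.

    p = (allele-1 copies) / (2 * called individuals); NaN where the line has
    zero calls at the SNP (such SNPs are excluded from windows downstream).
    """
    rows = ds.line_mask(line)
    if not rows.any():
        raise DomainError(f"no individuals in line {line!r}")
    g = ds.genotypes[rows]
    called = g != MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(called, g, 0).sum(axis=0) / (2.0 * n)
    return np.where(n > 0, p, np.nan)


def snp_stats(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-SNP line frequencies, AFD and expected heterozygosity.

    Columns: chrom, pos_bp, p_lean, p_fat, afd, het_lean, het_fat,
    n_called_lean, n_called_fat.
    """
    out = ds.markers[["id", "chrom", "pos_bp"]].copy()
    for line in LINES:
        p = line_allele_freq(ds, line)
        out[f"p_{line}"] = p
        out[f"het_{line}"] = 2.0 * p * (1.0 - p)
        rows = ds.line_mask(line)
        out[f"n_called_{line}"] = (ds.genotypes[rows] != MISSING).sum(axis=0)
    out["afd"] = (out["p_lean"] - out["p_fat"]).abs()
    return out


@dataclass(frozen=True)
class Window:
    chrom: str
    start_bp: int
    end_bp: int  # half-open [start_bp, end_bp)
    snp_idx: np.ndarray = field(compare=False)

    @property
    def n_snps(self) -> int:
        return len(self.snp_idx)


def sliding_windows(
    markers: pd.DataFrame,
    size_bp: int = WINDOW_SIZE_BP,
    step_bp: int = WINDOW_STEP_BP,
    min_snps: int = MIN_SNPS_PER_WINDOW,
) -> list[Window]:
    """Tile each chromosome with half-open windows of ``size_bp`` every
    ``step_bp``, anchored at the first marker position rounded down to a step
    multiple.  Windows holding fewer than ``min_snps`` markers are dropped.
    """
    windows: list[Window] = []
    pos_all = markers["pos_bp"].to_numpy()
    for chrom in markers["chrom"].unique():
        idx = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
        pos = pos_all[idx]
        if len(pos) == 0:
            continue
        start0 = (int(pos.min()) // step_bp) * step_bp
        last = int(pos.max())
        start = start0
        while start <= last:
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, start + size_bp, side="left")
            if hi - lo >= min_snps:
                windows.append(Window(chrom, start, start + size_bp, idx[lo:hi]))
            start += step_bp
    return windows


def window_summary(windows: list[Window], stats: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-window means of SNP AFD and line heterozygosity.

    SNPs with an undefined frequency in either line are excluded from the
    window means (and from n_snps_used).
    """
    afd = stats["afd"].to_numpy()
    het = {line: stats[f"het_{line}"].to_numpy() for line in LINES}
    rows = []
    for w in windows:
        idx = w.snp_idx
        ok = np.isfinite(afd[idx])
        for line in LINES:
            ok &= np.isfinite(het[line][idx])
        use = idx[ok]
        rows.append(
            {
                "chrom": w.chrom,
                "start_bp": w.start_bp,
                "end_bp": w.end_bp,
                "n_snps": w.n_snps,
                "n_snps_used": len(use),
                "afd_mean": afd[use].mean() if len(use) else np.nan,
                "het_lean_mean": het["lean"][use].mean() if len(use) else np.nan,
                "het_fat_mean": het["fat"][use].mean() if len(use) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def standardize_by_chrom(wdf: pd.DataFrame) -> pd.DataFrame:
    """Add z_afd, z_lean, z_fat columns (chromosome-wise standardization).

    z = (x - chromosome mean) / chromosome sample (n-1) sd.  Heterozygosity is
    standardized within its own line.  Chromosomes with fewer than two windows
    or zero spread get NaN z values and assessable=False -- never a silent 0.
    """
    out = wdf.copy()
    for src, dst in (
        ("afd_mean", "z_afd"),
        ("het_lean_mean", "z_lean"),
        ("het_fat_mean", "z_fat"),
    ):
        grp = out.groupby("chrom")[src]
        mean = grp.transform("mean")
        sd = grp.transform("std")  # sample (n-1) standard deviation
        # guard against zero spread reported as float noise
        degenerate = sd.isna() | (sd <= (mean.abs() + 1.0) * 1e-12)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (out[src] - mean) / sd
        z[degenerate] = np.nan
        out[dst] = z
    out["assessable"] = out[["z_afd", "z_lean", "z_fat"]].notna().all(axis=1)
    return out


_SIGNALS = ("AFD", "Z_AFD", "Z_lean_down", "Z_lean_up", "Z_fat_down", "Z_fat_up")


def _window_signals(row, afd_min, z_afd_min, z_het_min) -> list[str]:
    sig = []
    if row.afd_mean >= afd_min:
        sig.append("AFD")
    if np.isfinite(row.z_afd) and row.z_afd >= z_afd_min:
        sig.append("Z_AFD")
    for line in LINES:
        z = getattr(row, f"z_{line}")
        if np.isfinite(z):
            if z <= -z_het_min:
                sig.append(f"Z_{line}_down")
            elif z >= z_het_min:
                sig.append(f"Z_{line}_up")
    return sig


def call_signatures(
    wdf: pd.DataFrame,
    afd_min: float = AFD_THRESHOLD,
    z_afd_min: float = Z_AFD_THRESHOLD,
    z_het_min: float = Z_HET_THRESHOLD,
) -> pd.DataFrame:
    """Flag windows by the threshold rules and merge overlapping or touching
    flagged windows into signature regions.

    Returns one row per signature: chrom, start_bp, end_bp, n_windows, peak
    values of each statistic, the union of triggered signals, and the inferred
    selected line (the line whose heterozygosity dropped, when exactly one
    did; a heterozygosity increase is annotated as possible selection from an
    extreme initial frequency).
    """
    flagged = []
    for row in wdf.itertuples(index=False):
        sig = _window_signals(row, afd_min, z_afd_min, z_het_min)
        if sig:
            flagged.append((row, sig))
    regions = []
    for row, sig in flagged:
        if (
            regions
            and regions[-1]["chrom"] == row.chrom
            and row.start_bp <= regions[-1]["end_bp"]
        ):
            regions[-1]["rows"].append(row)
            regions[-1]["signals"].update(sig)
            regions[-1]["end_bp"] = max(regions[-1]["end_bp"], row.end_bp)
        else:
            regions.append(
                {
                    "chrom": row.chrom,
                    "start_bp": row.start_bp,
                    "end_bp": row.end_bp,
                    "rows": [row],
                    "signals": set(sig),
                }
            )
    out = []
    for reg in regions:
        rows = reg["rows"]
        signals = [s for s in _SIGNALS if s in reg["signals"]]
        down = [line for line in LINES if f"Z_{line}_down" in signals]
        inferred = down[0] if len(down) == 1 else ""
        note = (
            "heterozygosity increase: possible extreme-initial-frequency selection"
            if any(s.endswith("_up") for s in signals)
            else ""
        )
        out.append(
            {
                "chrom": reg["chrom"],
                "start_bp": reg["start_bp"],
                "end_bp": reg["end_bp"],
                "n_windows": len(rows),
                "peak_afd": max(r.afd_mean for r in rows),
                "peak_z_afd": max(r.z_afd for r in rows),
                "min_z_lean": min(r.z_lean for r in rows),
                "min_z_fat": min(r.z_fat for r in rows),
                "signals": ",".join(signals),
                "inferred_line": inferred,
                "note": note,
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "chrom",
            "start_bp",
            "end_bp",
            "n_windows",
            "peak_afd",
            "peak_z_afd",
            "min_z_lean",
            "min_z_fat",
            "signals",
            "inferred_line",
            "note",
        ],
    )


def chromosome_summary(ds: GenotypeDataset, stats: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome marker-density and frequency summary.

    Columns: chrom, n_snps, mean_adjacent_bp, snps_per_mb, mean_afd, and per
    line the count and percentage of fixed alleles (p exactly 0 or 1).
    """
    rows = []
    for chrom, grp in stats.groupby("chrom", sort=False):
        pos = np.sort(grp["pos_bp"].to_numpy())
        span_mb = (pos.max() - pos.min()) / 1e6 if len(pos) > 1 else np.nan
        row = {
            "chrom": chrom,
            "n_snps": len(grp),
            "mean_adjacent_bp": np.diff(pos).mean() if len(pos) > 1 else np.nan,
            "snps_per_mb": len(grp) / span_mb if span_mb else np.nan,
            "mean_afd": grp["afd"].mean(),
        }
        for line in LINES:
            p = grp[f"p_{line}"].to_numpy()
            fixed = int(np.sum((p == 0.0) | (p == 1.0)))
            row[f"fixed_{line}"] = fixed
            row[f"fixed_{line}_pct"] = 100.0 * fixed / len(grp)
        rows.append(row)
    return pd.DataFrame(rows)
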