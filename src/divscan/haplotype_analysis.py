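"""Per-line haplotype frequency tables within blocks, recombinant-haplotype
detection across two adjacent blocks, and line-specific haplotype labels.

In a strongly divergently selected region the two lines are expected to carry
nearly opposite main haplotypes, each almost absent from the other line, plus
possibly a shared recombinant assembled from segments of both mains.  The
functions here quantify exactly that pattern from phased data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .genotype_io import MISSING_BASE, LINES, PhasedHaplotypes
from .ld_blocks import BlockDefinition

ABSENT_MAX = 0.02  # "virtually absent" frequency ceiling
MAIN_MIN = 0.40  # minimum frequency for a line's main haplotype


@dataclass(frozen=True)
class HaplotypeTable:
    """Per-line haplotype frequencies within a block.

    table: DataFrame with columns haplotype, count_<line>, freq_<line> for
        each line, sorted by total frequency descending then lexicographic.
    n_dropped: haplotype rows excluded for missing bases inside the block.
    """

    block: BlockDefinition | None
    table: pd.DataFrame
    n_dropped: int = 0

    def freq(self, haplotype: str, line: str) -> float:
        row = self.table[self.table["haplotype"] == haplotype]
        return float(row[f"freq_{line}"].iloc[0]) if len(row) else 0.0

    def main_haplotype(self, line: str) -> str:
        idx = self.table[f"freq_{line}"].idxmax()
        return str(self.table.loc[idx, "haplotype"])


def _hap_strings(ph: PhasedHaplotypes, start_idx: int, end_idx: int, rows):
    sub = ph.alleles[rows, start_idx : end_idx + 1]
    complete = ~(sub == MISSING_BASE).any(axis=1)
    return np.array(["".join(r) for r in sub[complete]]), int((~complete).sum())


def block_haplotype_freqs(
    ph: PhasedHaplotypes, block: BlockDefinition
) -> HaplotypeTable:
    """Count block haplotypes per line; frequency = count / usable rows of the
    line.  Rows with a missing base anywhere in the block are dropped (and
    counted in ``n_dropped``)."""
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    n_dropped = 0
    for line in LINES:
        rows = ph.line_rows(line)
        haps, dropped = _hap_strings(ph, block.start_idx, block.end_idx, rows)
        n_dropped += dropped
        totals[line] = len(haps)
        if len(haps) == 0:
            warnings.warn(f"no usable haplotype rows in line {line!r}", stacklevel=2)
        uniq, cnt = np.unique(haps, return_counts=True)
        counts[line] = dict(zip(uniq.tolist(), cnt.tolist()))
    all_haps = sorted(set().union(*[set(c) for c in counts.values()]))
    rows_out = []
    for h in all_haps:
        row = {"haplotype": h}
        for line in LINES:
            c = counts[line].get(h, 0)
            row[f"count_{line}"] = c
            row[f"freq_{line}"] = c / totals[line] if totals[line] else np.nan
        rows_out.append(row)
    df = pd.DataFrame(rows_out)
    if len(df):
        df["_tot"] = sum(df[f"freq_{line}"].fillna(0.0) for line in LINES)
        df = (
            df.sort_values(["_tot", "haplotype"], ascending=[False, True])
            .drop(columns="_tot")
            .reset_index(drop=True)
        )
    return HaplotypeTable(block=block, table=df, n_dropped=n_dropped)


def hamming(h1: str, h2: str) -> int:
    """Number of positions at which two equal-length haplotype strings differ."""
    if len(h1) != len(h2):
        raise DomainError(f"length mismatch: {len(h1)} vs {len(h2)}")
    return sum(a != b for a, b in zip(h1, h2))


@dataclass(frozen=True)
class RecombinantCall:
    haplotype_block1: str
    haplotype_block2: str
    parent1: str  # donor of the block-1 segment ("H1"/"H2" style labels)
    parent2: str  # donor of the block-2 segment
    freq_lean: float
    freq_fat: float

    @property
    def haplotype(self) -> str:
        return self.haplotype_block1 + self.haplotype_block2


def two_block_table(
    ph: PhasedHaplotypes, block1: BlockDefinition, block2: BlockDefinition
) -> pd.DataFrame:
    """Joint (block1, block2) haplotype frequencies per line.

    Columns: block1, block2, count_<line>, freq_<line>.
    """
    rows_out: dict[tuple[str, str], dict] = {}
    totals = {}
    for line in LINES:
        rows = ph.line_rows(line)
        sub1 = ph.alleles[rows, block1.start_idx : block1.end_idx + 1]
        sub2 = ph.alleles[rows, block2.start_idx : block2.end_idx + 1]
        complete = ~(
            (sub1 == MISSING_BASE).any(axis=1) | (sub2 == MISSING_BASE).any(axis=1)
        )
        pairs = [
            ("".join(a), "".join(b)) for a, b in zip(sub1[complete], sub2[complete])
        ]
        totals[line] = len(pairs)
        for p in pairs:
            rows_out.setdefault(p, {f"count_{ln}": 0 for ln in LINES})
            rows_out[p][f"count_{line}"] += 1
    records = []
    for (h1, h2), cnts in sorted(rows_out.items()):
        rec = {"block1": h1, "block2": h2, **cnts}
        for line in LINES:
            rec[f"freq_{line}"] = (
                cnts[f"count_{line}"] / totals[line] if totals[line] else np.nan
            )
        records.append(rec)
    df = pd.DataFrame(records)
    if len(df):
        df["_tot"] = sum(df[f"freq_{line}"].fillna(0.0) for line in LINES)
        df = (
            df.sort_values(["_tot", "block1", "block2"], ascending=[False, True, True])
            .drop(columns="_tot")
            .reset_index(drop=True)
        )
    return df


def find_recombinants(
    joined: pd.DataFrame,
    parents: tuple[tuple[str, str], tuple[str, str]],
    parent_labels: tuple[str, str] = ("H1", "H2"),
) -> list[RecombinantCall]:
    """Detect crossover products of two parental two-block haplotypes.

    ``joined`` is a two_block_table frame; ``parents`` gives the two parental
    haplotypes as (block1 segment, block2 segment) pairs.  Any observed row
    equal to parentA-block1 + parentB-block2 with A != B is returned.  If a
    parent is absent from the panel an empty list is returned with a warning.
    """
    (p1b1, p1b2), (p2b1, p2b2) = parents
    observed = set(zip(joined["block1"], joined["block2"]))
    for want in ((p1b1, p1b2), (p2b1, p2b2)):
        if want not in observed:
            warnings.warn(f"parent haplotype {want} absent from panel", stacklevel=2)
            return []
    targets = {
        (p1b1, p2b2): (parent_labels[0], parent_labels[1]),
        (p2b1, p1b2): (parent_labels[1], parent_labels[0]),
    }
    # identical parental segments on one block would make the "recombinant"
    # indistinguishable from a parent; skip those combinations
    calls = []
    for row in joined.itertuples(index=False):
        key = (row.block1, row.block2)
        if key in targets and key not in {(p1b1, p1b2), (p2b1, p2b2)}:
            lab1, lab2 = targets[key]
            calls.append(
                RecombinantCall(
                    haplotype_block1=row.block1,
                    haplotype_block2=row.block2,
                    parent1=lab1,
                    parent2=lab2,
                    freq_lean=float(row.freq_lean),
                    freq_fat=float(row.freq_fat),
                )
            )
    return calls


def classify_line_specific(
    table: HaplotypeTable | pd.DataFrame,
    absent_max: float = ABSENT_MAX,
    main_min: float = MAIN_MIN,
) -> pd.Series:
    """Label each haplotype lean-specific / fat-specific / shared / minor.

    A haplotype is X-specific when its frequency is >= ``main_min`` in line X
    and <= ``absent_max`` in the other line; shared when it exceeds
    ``absent_max`` in both lines without being specific; minor otherwise.
    """
    df = table.table if isinstance(table, HaplotypeTable) else table
    labels = []
    for row in df.itertuples(index=False):
        f = {line: getattr(row, f"freq_{line}") for line in LINES}
        if f["lean"] >= main_min and f["fat"] <= absent_max:
            labels.append("lean-specific")
        elif f["fat"] >= main_min and f["lean"] <= absent_max:
            labels.append("fat-specific")
        elif f["lean"] > absent_max and f["fat"] > absent_max:
            labels.append("shared")
        else:
            labels.append("minor")
    return pd.Series(labels, index=df.index, name="label")


def minor_frequency_sum(table: HaplotypeTable | pd.DataFrame, line: str, **kw) -> float:
    """Combined frequency in ``line`` of the haplotypes labelled minor."""
    df = table.table if isinstance(table, HaplotypeTable) else table
    labels = classify_line_specific(df, **kw)
    return float(df.loc[labels == "minor", f"freq_{line}"].sum())
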