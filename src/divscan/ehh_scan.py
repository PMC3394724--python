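"""Extended haplotype homozygosity (EHH) decay around core regions.

EHH at marker x, for the n carriers of a core haplotype, is the probability
that two carriers drawn without replacement are identical over the whole
stretch from the core out to x:

    EHH(x) = sum_h e_h (e_h - 1) / (n (n - 1))

over the distinct extended haplotypes h with carrier counts e_h.  EHH is 1 at
the core boundary and non-increasing outward (haplotype classes only refine),
and decays more slowly around a recently swept allele, whose carriers share a
long ancestral haplotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .genotype_io import MISSING_BASE, PhasedHaplotypes
from .ld_blocks import BlockDefinition

MIN_CARRIERS = 5
STOP_THRESHOLD = 0.05


@dataclass(frozen=True)
class CoreRegion:
    chrom: str
    start_idx: int  # inclusive marker indices
    end_idx: int

    def __post_init__(self):
        if self.end_idx < self.start_idx:
            raise DomainError("core end before start")


@dataclass(frozen=True)
class EHHCurve:
    core: CoreRegion
    core_haplotype: str
    line: str
    direction: str  # "upstream" (toward smaller bp) or "downstream"
    n_carriers: int
    #: DataFrame columns marker_idx, distance_bp, ehh
    points: pd.DataFrame = field(compare=False)

    def area(self) -> float:
        """Trapezoidal area under the curve over physical distance (bp)."""
        pts = self.points.sort_values("distance_bp")
        if len(pts) < 2:
            return 0.0
        return float(np.trapezoid(pts["ehh"], pts["distance_bp"]))


def ehh_at(extended: np.ndarray) -> float:
    """EHH of a set of extended haplotypes (rows of bases, no missing).

    Raises DomainError for fewer than two carriers.
    """
    ext = np.asarray(extended)
    n = len(ext)
    if n < 2:
        raise DomainError("EHH undefined for fewer than two carriers")
    keys = ["".join(r) for r in ext] if ext.ndim == 2 else list(ext)
    _, counts = np.unique(keys, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def select_cores(
    blocks: list[BlockDefinition] | None = None,
    ranges: list[tuple[str, int, int]] | None = None,
) -> list[CoreRegion]:
    """Build cores from Gabriel blocks (default) or explicit marker-index
    ranges (chrom, start_idx, end_idx); overlapping user ranges are an error."""
    if ranges is not None:
        cores = [CoreRegion(c, s, e) for c, s, e in ranges]
        by_chrom: dict[str, list[CoreRegion]] = {}
        for core in cores:
            by_chrom.setdefault(core.chrom, []).append(core)
        for chrom_cores in by_chrom.values():
            chrom_cores.sort(key=lambda c: c.start_idx)
            for a, b in zip(chrom_cores, chrom_cores[1:]):
                if b.start_idx <= a.end_idx:
                    raise DomainError(f"overlapping cores on {a.chrom}")
        return cores
    if blocks is None:
        raise DomainError("either blocks or ranges must be given")
    return [CoreRegion(b.chrom, b.start_idx, b.end_idx) for b in blocks]


def _decay_one_direction(
    alleles: np.ndarray,
    carrier_rows: np.ndarray,
    core: CoreRegion,
    pos: np.ndarray,
    step: int,
    stop_threshold: float,
) -> pd.DataFrame:
    """Walk outward one marker at a time, refining haplotype classes.

    Rows that hit a missing base are dropped from that evaluation point
    onward (per-point complete case).
    """
    if step < 0:
        boundary_idx, limit = core.start_idx, -1
    else:
        boundary_idx, limit = core.end_idx, alleles.shape[1]
    boundary_pos = pos[boundary_idx]

    active = carrier_rows.copy()
    labels = np.zeros(len(active), dtype=np.int64)  # class id per active row
    records = [(boundary_idx, 0, 1.0)]
    ehh = 1.0
    x = boundary_idx + step
    while x != limit and ehh >= stop_threshold:
        col = alleles[active, x]
        ok = col != MISSING_BASE
        active, labels, col = active[ok], labels[ok], col[ok]
        if len(active) < 2:
            break
        # refine classes by the new allele
        _, labels = np.unique(
            np.stack([labels, col.view(np.uint32)]), axis=1, return_inverse=True
        )
        n = len(active)
        _, counts = np.unique(labels, return_counts=True)
        ehh = float((counts * (counts - 1)).sum() / (n * (n - 1)))
        records.append((x, int(abs(pos[x] - boundary_pos)), ehh))
        x += step
    return pd.DataFrame(records, columns=["marker_idx", "distance_bp", "ehh"])


def ehh_decay(
    ph: PhasedHaplotypes,
    core: CoreRegion,
    line: str,
    min_carriers: int = MIN_CARRIERS,
    stop_threshold: float = STOP_THRESHOLD,
) -> list[EHHCurve]:
    """EHH decay curves in both directions for every core haplotype carried by
    at least ``min_carriers`` haplotype rows of ``line``.

    Curves are ordered by core-haplotype count descending (ties: haplotype
    string), with the two directions of a haplotype adjacent.
    """
    rows = ph.line_rows(line)
    sub = ph.alleles[rows, core.start_idx : core.end_idx + 1]
    complete = ~(sub == MISSING_BASE).any(axis=1)
    rows = rows[complete]
    haps = np.array(["".join(r) for r in sub[complete]])
    if len(haps) == 0:
        warnings.warn(f"no usable core haplotypes in line {line!r}", stacklevel=2)
        return []
    uniq, counts = np.unique(haps, return_counts=True)
    order = np.lexsort((uniq, -counts))
    pos = ph.markers["pos_bp"].to_numpy()
    curves = []
    for k in order:
        if counts[k] < min_carriers:
            continue
        carriers = rows[haps == uniq[k]]
        for direction, step in (("upstream", -1), ("downstream", +1)):
            pts = _decay_one_direction(
                ph.alleles, carriers, core, pos, step, stop_threshold
            )
            curves.append(
                EHHCurve(
                    core=core,
                    core_haplotype=str(uniq[k]),
                    line=line,
                    direction=direction,
                    n_carriers=int(counts[k]),
                    points=pts,
                )
            )
    if not curves:
        warnings.warn(
            f"no core haplotype reaches {min_carriers} carriers in line {line!r}",
            stacklevel=2,
        )
    return curves


def relative_ehh(curves: list[EHHCurve]) -> pd.DataFrame:
    """Relative EHH of each curve vs. the pooled other core haplotypes,
    reported at each marker where both are defined (informational only)."""
    rows = []
    for cur in curves:
        others = [
            c
            for c in curves
            if c.direction == cur.direction and c.core_haplotype != cur.core_haplotype
        ]
        if not others:
            continue
        merged = cur.points.rename(columns={"ehh": "ehh_self"})
        pooled = (
            pd.concat([o.points for o in others])
            .groupby("marker_idx", as_index=False)["ehh"]
            .mean()
            .rename(columns={"ehh": "ehh_others"})
        )
        merged = merged.merge(pooled, on="marker_idx")
        with np.errstate(divide="ignore", invalid="ignore"):
            merged["rehh"] = merged["ehh_self"] / merged["ehh_others"]
        merged.insert(0, "core_haplotype", cur.core_haplotype)
        merged.insert(1, "direction", cur.direction)
        rows.append(merged)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def main_haplotype_ehh_area(
    ph: PhasedHaplotypes, core: CoreRegion, line: str, **kw
) -> float:
    """Total area under the main core haplotype's EHH curves (both
    directions); 0.0 when no curve is computable."""
    curves = ehh_decay(ph, core, line, **kw)
    if not curves:
        return 0.0
    main = curves[0].core_haplotype
    return sum(c.area() for c in curves if c.core_haplotype == main)


def pooled_ehh_decay(
    ph: PhasedHaplotypes,
    core: CoreRegion,
    line: str,
    stop_threshold: float = STOP_THRESHOLD,
) -> list[EHHCurve]:
    """Line-level haplotype-homozygosity decay: the probability that two
    random haplotypes of the line are identical from the core out to marker x.

    Unlike the per-core-haplotype curves, this pooled statistic starts at the
    core's haplotype homozygosity (not at 1) and directly reflects how much of
    the line's diversity selection has removed: a swept line starts high and
    decays slowly, an unselected line starts low.  It equals the count-weighted
    combination of the conditional curves and is the quantity compared between
    lines when judging which line was selected.
    """
    rows = ph.line_rows(line)
    sub = ph.alleles[rows, core.start_idx : core.end_idx + 1]
    complete = ~(sub == MISSING_BASE).any(axis=1)
    rows = rows[complete]
    if len(rows) < 2:
        warnings.warn(f"fewer than two usable rows in line {line!r}", stacklevel=2)
        return []
    core_haps = ["".join(r) for r in sub[complete]]
    _, labels0 = np.unique(core_haps, return_inverse=True)
    pos = ph.markers["pos_bp"].to_numpy()
    curves = []
    for direction, step in (("upstream", -1), ("downstream", +1)):
        boundary = core.start_idx if step < 0 else core.end_idx
        limit = -1 if step < 0 else ph.n_markers
        labels = labels0.copy()
        active = rows.copy()
        n = len(active)
        counts = np.bincount(labels)
        h = float((counts * (counts - 1)).sum() / (n * (n - 1)))
        records = [(boundary, 0, h)]
        x = boundary + step
        while x != limit and h >= stop_threshold:
            col = ph.alleles[active, x]
            ok = col != MISSING_BASE
            active, labels, col = active[ok], labels[ok], col[ok]
            if len(active) < 2:
                break
            _, labels = np.unique(
                np.stack([labels, col.view(np.uint32).astype(np.int64)]),
                axis=1,
                return_inverse=True,
            )
            n = len(active)
            counts = np.bincount(labels)
            h = float((counts * (counts - 1)).sum() / (n * (n - 1)))
            records.append((x, int(abs(pos[x] - pos[boundary])), h))
            x += step
        curves.append(
            EHHCurve(
                core=core,
                core_haplotype="*pooled*",
                line=line,
                direction=direction,
                n_carriers=len(rows),
                points=pd.DataFrame(
                    records, columns=["marker_idx", "distance_bp", "ehh"]
                ),
            )
        )
    return curves


def line_ehh_area(
    ph: PhasedHaplotypes, core: CoreRegion, line: str,
    stop_threshold: float = STOP_THRESHOLD,
) -> float:
    """Area under the pooled haplotype-homozygosity decay (both directions);
    the between-line comparison statistic."""
    return sum(
        c.area() for c in pooled_ehh_decay(ph, core, line, stop_threshold)
    )


def curves_to_frame(curves: list[EHHCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        df = c.points.copy()
        df.insert(0, "chrom", c.core.chrom)
        df.insert(1, "core_start_idx", c.core.start_idx)
        df.insert(2, "core_end_idx", c.core.end_idx)
        df.insert(3, "core_haplotype", c.core_haplotype)
        df.insert(4, "line", c.line)
        df.insert(5, "direction", c.direction)
        df.insert(6, "n_carriers", c.n_carriers)
        rows.append(df)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
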