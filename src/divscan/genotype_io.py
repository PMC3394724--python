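"""Genotype, phased-haplotype and phenotype file handling plus marker QC.

Genotypes travel as an individuals x markers dosage matrix counting copies of
"allele 1" -- the alphabetically prior base of each SNP's allele pair (A before
C/G/T, C before G/T, G before T).  Using a fixed, line-independent reference
allele keeps between-line allele-frequency differences sign-stable, which the
downstream window scan relies on.

File dialects
-------------
* genotypes: whitespace-delimited PLINK-style PED/MAP text.
* phased haplotypes: one TSV per chromosome; ``#marker`` comment lines carry
  the marker map, then a header row and one row per haplotype
  (individual_id, hap_index, line, one base per marker).
* phenotypes: TSV with named columns (individual_id, line, family, hatch,
  AFW, AFP, BW7).

All readers and writers round-trip losslessly, including missing codes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, EmptyResultError, FormatError

MISSING = -1  # genotype code for a no-call
MISSING_BASE = "N"  # missing base in a phased haplotype row

_BASES = ("A", "C", "G", "T")

#: canonical line labels of a two-line divergent design
LINES = ("lean", "fat")


def allele1(pair) -> str:
    """Return "allele 1" of a biallelic SNP: the alphabetically prior base.

    A for A/C, A/G, A/T; C for C/G, C/T; G for G/T.
    """
    alleles = sorted(set(pair))
    if len(alleles) != 2:
        raise DomainError(f"allele pair must be two distinct bases, got {pair!r}")
    for a in alleles:
        if a not in _BASES:
            raise DomainError(f"non-ACGT allele {a!r} in pair {pair!r}")
    return alleles[0]


@dataclass(frozen=True)
class GenotypeDataset:
    """Individuals x markers allele-1 dosage matrix with metadata.

    markers: DataFrame with columns id, chrom, pos_bp, allele_a, allele_b;
        allele_a is allele 1; rows sorted by (chrom, pos_bp, id).
    individuals: DataFrame with columns id, line, family, sex, hatch.
    genotypes: int8 array (n_individuals, n_markers); -1 = missing.
    """

    markers: pd.DataFrame
    individuals: pd.DataFrame
    genotypes: np.ndarray
    qc_report: dict | None = field(default=None, compare=False)

    def __post_init__(self):
        n_ind, n_snp = self.genotypes.shape
        if n_ind != len(self.individuals) or n_snp != len(self.markers):
            raise DataError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def line_mask(self, line: str) -> np.ndarray:
        return (self.individuals["line"] == line).to_numpy()

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of called genotypes."""
        return (self.genotypes != MISSING).mean(axis=0)

    def individual_missingness(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)

    def maf(self) -> np.ndarray:
        """Combined-sample (both lines pooled) minor allele frequency."""
        called = self.genotypes != MISSING
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(called, self.genotypes, 0).sum(axis=0) / (2.0 * n_called)
        return np.minimum(p, 1.0 - p)

    def subset(self, ind_idx=None, marker_idx=None) -> "GenotypeDataset":
        ind_idx = np.arange(self.n_individuals) if ind_idx is None else np.asarray(ind_idx)
        marker_idx = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeDataset(
            markers=self.markers.iloc[marker_idx].reset_index(drop=True),
            individuals=self.individuals.iloc[ind_idx].reset_index(drop=True),
            genotypes=self.genotypes[np.ix_(ind_idx, marker_idx)],
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.markers.equals(other.markers)
            and self.individuals.equals(other.individuals)
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass(frozen=True)
class PhasedHaplotypes:
    """Phased haplotypes of one chromosome.

    markers: marker map of the chromosome (same columns as GenotypeDataset).
    samples: DataFrame with columns individual_id, hap_index, line; two rows
        per diploid individual.
    alleles: (n_haplotypes, n_markers) array of single-character bases;
        ``N`` marks a missing base.
    """

    markers: pd.DataFrame
    samples: pd.DataFrame
    alleles: np.ndarray

    def __post_init__(self):
        if self.alleles.shape != (len(self.samples), len(self.markers)):
            raise DataError("haplotype matrix shape does not match samples x markers")

    @property
    def n_haplotypes(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def line_rows(self, line: str) -> np.ndarray:
        return np.flatnonzero((self.samples["line"] == line).to_numpy())

    def allele1_codes(self) -> np.ndarray:
        """0/1 matrix: 1 where the base equals allele 1, -1 where missing."""
        a1 = self.markers["allele_a"].to_numpy()[None, :]
        codes = np.where(self.alleles == a1, 1, 0).astype(np.int8)
        codes[self.alleles == MISSING_BASE] = MISSING
        return codes

    def equals(self, other: "PhasedHaplotypes") -> bool:
        return (
            self.markers.equals(other.markers)
            and self.samples.equals(other.samples)
            and np.array_equal(self.alleles, other.alleles)
        )


def _sort_markers(markers: pd.DataFrame) -> pd.DataFrame:
    return markers.sort_values(
        ["chrom", "pos_bp", "id"], kind="mergesort"
    ).reset_index(drop=True)


def _parse_line_family(fid: str):
    """Split a PED family id of the form ``<line>_<family>``; else the FID is
    both line and family label (single-label files)."""
    if "_" in fid:
        head, tail = fid.split("_", 1)
        if head in LINES:
            return head, tail
    return fid, fid


def read_genotypes(ped_path, map_path, samples_path=None) -> GenotypeDataset:
    """Read a PED/MAP pair into a GenotypeDataset.

    MAP rows: chrom, id, [genetic distance,] pos_bp.  PED rows: FID IID PAT
    MAT SEX PHENO then two allele columns per SNP; "0 0" is a no-call.  Line,
    family and hatch come from an optional sidecar sample TSV (columns
    individual_id, line, family, sex, hatch); otherwise FID is parsed as
    ``line_family``.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, raw in enumerate(fh, 1):
            parts = raw.split()
            if not parts:
                continue
            if len(parts) == 4:
                chrom, mid, _, pos = parts
            elif len(parts) == 3:
                chrom, mid, pos = parts
            else:
                raise FormatError(f"{map_path}: row {ln}: expected 3 or 4 columns")
            map_rows.append((chrom, mid, int(pos)))
    if not map_rows:
        raise EmptyResultError(f"{map_path}: no markers")
    n_snp = len(map_rows)

    ids, fams, sexes, allele_cols = [], [], [], []
    with open(ped_path) as fh:
        for ln, raw in enumerate(fh, 1):
            parts = raw.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snp:
                raise FormatError(
                    f"{ped_path}: row {ln}: expected {6 + 2 * n_snp} columns for "
                    f"{n_snp} MAP SNPs, got {len(parts)}"
                )
            fams.append(parts[0])
            ids.append(parts[1])
            sexes.append(parts[4])
            allele_cols.append(parts[6:])
    if not ids:
        raise EmptyResultError(f"{ped_path}: no individuals")

    alleles = np.array(allele_cols, dtype="U1").reshape(len(ids), n_snp, 2)

    # Establish each marker's observed allele pair and the allele-1 convention.
    marker_rows, geno_cols = [], []
    for j, (chrom, mid, pos) in enumerate(map_rows):
        col = alleles[:, j, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise DataError(f"SNP {mid}: more than two alleles observed: {observed}")
        if len(observed) == 2:
            a1 = allele1(observed)
            a2 = observed[0] if observed[1] == a1 else observed[1]
        elif len(observed) == 1:
            a1, a2 = observed[0], "0"
        else:
            a1, a2 = "0", "0"
        dosage = (col == a1).sum(axis=1).astype(np.int8)
        dosage[(col == "0").any(axis=1)] = MISSING
        marker_rows.append((mid, chrom, pos, a1, a2))
        geno_cols.append(dosage)

    markers = pd.DataFrame(
        marker_rows, columns=["id", "chrom", "pos_bp", "allele_a", "allele_b"]
    )
    order = _sort_markers(markers.assign(_j=range(n_snp)))
    genotypes = np.column_stack(geno_cols)[:, order["_j"].to_numpy()]
    markers = order.drop(columns="_j")

    if samples_path is not None:
        samp = pd.read_csv(samples_path, sep="\t", dtype=str)
        samp = samp.set_index("individual_id")
        missing_ids = [i for i in ids if i not in samp.index]
        if missing_ids:
            raise DataError(f"sample table missing individuals: {missing_ids[:5]}")
        individuals = pd.DataFrame(
            {
                "id": ids,
                "line": samp.loc[ids, "line"].to_numpy(),
                "family": samp.loc[ids, "family"].to_numpy(),
                "sex": samp.loc[ids, "sex"].to_numpy()
                if "sex" in samp.columns
                else sexes,
                "hatch": samp.loc[ids, "hatch"].to_numpy()
                if "hatch" in samp.columns
                else "1",
            }
        )
    else:
        parsed = [_parse_line_family(f) for f in fams]
        individuals = pd.DataFrame(
            {
                "id": ids,
                "line": [p[0] for p in parsed],
                "family": [p[1] for p in parsed],
                "sex": sexes,
                "hatch": "1",
            }
        )
    return GenotypeDataset(markers=markers, individuals=individuals, genotypes=genotypes)


def write_genotypes(ds: GenotypeDataset, ped_path, map_path) -> None:
    with open(map_path, "w") as fh:
        for row in ds.markers.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos_bp}\n")
    a1 = ds.markers["allele_a"].to_numpy()
    a2 = ds.markers["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(ds.individuals.itertuples(index=False)):
            g = ds.genotypes[i]
            pair = np.empty((ds.n_markers, 2), dtype="U1")
            pair[g == 2] = np.column_stack([a1, a1])[g == 2]
            pair[g == 1] = np.column_stack([a1, a2])[g == 1]
            pair[g == 0] = np.column_stack([a2, a2])[g == 0]
            pair[g == MISSING] = "0"
            cols = [f"{ind.line}_{ind.family}", ind.id, "0", "0", str(ind.sex), "-9"]
            cols += pair.ravel().tolist()
            fh.write(" ".join(cols) + "\n")


def write_samples(ds: GenotypeDataset, path) -> None:
    """Sidecar sample table preserving line/family/sex/hatch metadata."""
    out = ds.individuals.rename(columns={"id": "individual_id"})
    out.to_csv(path, sep="\t", index=False)


def apply_qc(
    ds: GenotypeDataset,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
    ind_miss_max: float = 0.05,
) -> GenotypeDataset:
    """Marker and individual quality control.

    Individuals with missingness >= ind_miss_max are removed first, then SNPs
    with combined-sample MAF < maf_min or call rate < call_rate_min.  MAF is
    computed on the pooled sample of both lines.  The returned dataset carries
    a ``qc_report`` dict of per-criterion removal counts.
    """
    if ds.n_individuals == 0 or ds.n_markers == 0:
        raise EmptyResultError("empty dataset")
    keep_ind = ds.individual_missingness() < ind_miss_max
    if not keep_ind.any():
        raise EmptyResultError("QC removed every individual")
    ds2 = ds.subset(ind_idx=np.flatnonzero(keep_ind))

    call = ds2.call_rate()
    maf = ds2.maf()
    ok_call = call >= call_rate_min
    ok_maf = np.nan_to_num(maf, nan=0.0) >= maf_min
    keep_snp = ok_call & ok_maf
    if not keep_snp.any():
        raise EmptyResultError("QC removed every SNP")
    out = ds2.subset(marker_idx=np.flatnonzero(keep_snp))
    report = {
        "n_individuals_in": ds.n_individuals,
        "n_individuals_removed_missingness": int((~keep_ind).sum()),
        "n_snps_in": ds.n_markers,
        "n_snps_removed_call_rate": int((~ok_call).sum()),
        "n_snps_removed_maf": int((ok_call & ~ok_maf).sum()),
        "n_individuals_kept": out.n_individuals,
        "n_snps_kept": out.n_markers,
    }
    object.__setattr__(out, "qc_report", report)
    return out


# ---------------------------------------------------------------------------
# phased haplotypes


def write_phased(ph: PhasedHaplotypes, path) -> None:
    with open(path, "w") as fh:
        for row in ph.markers.itertuples(index=False):
            fh.write(
                f"#marker\t{row.id}\t{row.chrom}\t{row.pos_bp}\t"
                f"{row.allele_a}\t{row.allele_b}\n"
            )
        fh.write(
            "individual_id\thap_index\tline\t"
            + "\t".join(ph.markers["id"]) + "\n"
        )
        for i, s in enumerate(ph.samples.itertuples(index=False)):
            fh.write(
                f"{s.individual_id}\t{s.hap_index}\t{s.line}\t"
                + "\t".join(ph.alleles[i]) + "\n"
            )


def read_phased(path) -> PhasedHaplotypes:
    marker_rows, data_rows = [], []
    header = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            if raw.startswith("#marker\t"):
                _, mid, chrom, pos, a1, a2 = raw.split("\t")
                marker_rows.append((mid, chrom, int(pos), a1, a2))
            elif header is None:
                header = raw.split("\t")
            else:
                data_rows.append(raw.split("\t"))
    if not marker_rows or header is None:
        raise EmptyResultError(f"{path}: no phased data")
    markers = pd.DataFrame(
        marker_rows, columns=["id", "chrom", "pos_bp", "allele_a", "allele_b"]
    )
    if header[3:] != list(markers["id"]):
        raise FormatError(f"{path}: header marker ids do not match #marker lines")
    if not data_rows:
        raise EmptyResultError(f"{path}: no haplotype rows")
    samples = pd.DataFrame(
        [(r[0], int(r[1]), r[2]) for r in data_rows],
        columns=["individual_id", "hap_index", "line"],
    )
    alleles = np.array([r[3:] for r in data_rows], dtype="U1")
    if alleles.shape[1] != len(markers):
        raise FormatError(f"{path}: haplotype row length does not match marker count")
    valid = (
        (alleles == markers["allele_a"].to_numpy()[None, :])
        | (alleles == markers["allele_b"].to_numpy()[None, :])
        | (alleles == MISSING_BASE)
    )
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise DataError(
            f"{path}: haplotype row {i} has base {alleles[i, j]!r} outside the "
            f"allele pair of marker {markers['id'].iloc[j]}"
        )
    counts = samples.groupby("individual_id").size()
    if (counts % 2 != 0).any():
        raise DataError(f"{path}: odd haplotype count for some individual")
    return PhasedHaplotypes(markers=markers, samples=samples, alleles=alleles)


# ---------------------------------------------------------------------------
# phenotypes

PHENO_COLUMNS = ["individual_id", "line", "family", "hatch", "AFW", "AFP", "BW7"]


def read_phenotypes(path, afp_check_tol: float = 0.5) -> pd.DataFrame:
    """Read a phenotype TSV.

    AFW and BW7 in grams, AFP in percent.  When all three are present, AFP is
    checked against 100*AFW/BW7; per-bird disagreement beyond ``afp_check_tol``
    percentage points raises a warning (line means of ratios need not equal
    ratios of means, so this is not an error).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"individual_id": str, "line": str, "family": str, "hatch": str},
    )
    missing = {"individual_id", "AFW", "AFP"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing phenotype columns {sorted(missing)}")
    if df.empty:
        raise EmptyResultError(f"{path}: no phenotype rows")
    if (df["AFP"] < 0).any() or (df["AFW"] < 0).any():
        raise DataError(f"{path}: negative AFW or AFP")
    if "BW7" in df.columns:
        implied = 100.0 * df["AFW"] / df["BW7"]
        bad = (implied - df["AFP"]).abs() > afp_check_tol
        if bad.any():
            warnings.warn(
                f"{path}: {int(bad.sum())} rows where AFP disagrees with "
                f"100*AFW/BW7 by more than {afp_check_tol}",
                stacklevel=2,
            )
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    cols = [c for c in PHENO_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False)


def line_phenotype_summary(pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-line mean/sd/n of each trait, plus the fat/lean ratio of means.

    The returned frame is indexed by trait with columns mean_<line>, sd_<line>,
    n_<line> and fat_lean_ratio (NaN when a lean mean is zero).
    """
    traits = [c for c in ("AFW", "AFP", "BW7") if c in pheno.columns]
    rows = {}
    for trait in traits:
        row = {}
        for line, grp in pheno.groupby("line"):
            row[f"mean_{line}"] = grp[trait].mean()
            row[f"sd_{line}"] = grp[trait].std(ddof=1)
            row[f"n_{line}"] = len(grp)
        if row.get("mean_lean"):
            row["fat_lean_ratio"] = row.get("mean_fat", np.nan) / row["mean_lean"]
        else:
            row["fat_lean_ratio"] = np.nan
        rows[trait] = row
    return pd.DataFrame(rows).T


def write_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Deterministic TSV dump used for all report tables."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
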