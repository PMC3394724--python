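"""End-to-end orchestration: simulate/load -> QC -> window scan -> signature
calls -> LD/blocks -> haplotype tables -> EHH -> association, with TSV outputs
and a Markdown report.

The stage order mirrors how multi-signal selection scans are read: the
window statistics (AFD, Z_AFD, Z_lean, Z_fat) do the first screening; LD
structure, haplotype frequencies and EHH corroborate each flagged region and
say which line was selected; the association scan attaches phenotypic
evidence (most significant SNP near each signature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import ehh_scan, haplotype_analysis, ld_blocks, window_scan
from .errors import ConfigError
from .genotype_io import (
    PhasedHaplotypes,
    apply_qc,
    read_genotypes,
    read_phased,
    read_phenotypes,
    write_table,
)
from .synthetic_data import SimConfig, simulate

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs.

    Provide either ``sim`` (a SimConfig) or the three input paths.  Threshold
    fields default to the scan's standard values and are echoed in the
    report.
    """

    out_dir: str
    sim: SimConfig | None = None
    ped_path: str | None = None
    map_path: str | None = None
    samples_path: str | None = None
    phased_paths: tuple[str, ...] = ()
    pheno_path: str | None = None

    maf_min: float = 0.05
    call_rate_min: float = 0.95
    ind_miss_max: float = 0.05
    window_size_bp: int = window_scan.WINDOW_SIZE_BP
    window_step_bp: int = window_scan.WINDOW_STEP_BP
    min_snps_per_window: int = window_scan.MIN_SNPS_PER_WINDOW
    afd_threshold: float = window_scan.AFD_THRESHOLD
    z_afd_threshold: float = window_scan.Z_AFD_THRESHOLD
    z_het_threshold: float = window_scan.Z_HET_THRESHOLD
    assoc_flank_bp: int = 250_000
    max_ld_distance_bp: int = 1_000_000
    traits: tuple[str, ...] = ("AFW", "AFP")
    covariates: tuple[str, ...] = ("hatch",)
    family_mode: str = "random"
    alpha: float = 0.05

    def __post_init__(self):
        if self.sim is None and (self.ped_path is None or self.map_path is None):
            raise ConfigError("either a SimConfig or ped/map paths are required")


@dataclass
class RunReport:
    qc_report: dict
    chromosome_summary: pd.DataFrame
    windows: pd.DataFrame
    signatures: pd.DataFrame
    association: pd.DataFrame
    bonferroni_p: float
    thresholds: dict

    def to_markdown(self) -> str:
        lines = ["# divscan run report", ""]
        lines.append("## Thresholds")
        for k, v in self.thresholds.items():
            lines.append(f"- {k}: {v}")
        lines.append(f"- bonferroni_p: {self.bonferroni_p:.6g}")
        lines.append("")
        lines.append("## QC")
        for k, v in self.qc_report.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
        lines.append(f"## Signatures ({len(self.signatures)})")
        if len(self.signatures):
            lines.append(self.signatures.to_csv(sep="\t", index=False,
                                                float_format="%.4g").rstrip())
        lines.append("")
        return "\n".join(lines) + "\n"


def _load_inputs(cfg: RunConfig):
    if cfg.sim is not None:
        res = simulate(cfg.sim)
        return res.dataset, res.phased, res.phenotypes
    ds = read_genotypes(cfg.ped_path, cfg.map_path, cfg.samples_path)
    phased = {}
    for p in cfg.phased_paths:
        ph = read_phased(p)
        phased[str(ph.markers["chrom"].iloc[0])] = ph
    pheno = read_phenotypes(cfg.pheno_path) if cfg.pheno_path else None
    return ds, phased, pheno


def _phased_region(ph: PhasedHaplotypes, start_bp: int, end_bp: int):
    pos = ph.markers["pos_bp"].to_numpy()
    idx = np.flatnonzero((pos >= start_bp) & (pos < end_bp))
    if len(idx) < 2:
        return None
    return PhasedHaplotypes(
        markers=ph.markers.iloc[idx].reset_index(drop=True),
        samples=ph.samples,
        alleles=ph.alleles[:, idx],
    )


def _annotate_signature(
    sig_row: dict,
    phased: dict[str, PhasedHaplotypes],
    assoc_df: pd.DataFrame | None,
    markers: pd.DataFrame,
    cfg: RunConfig,
) -> dict:
    """Corroboration columns for one signature region; every column is filled
    or explicitly 'non-assessable'."""
    out = dict(sig_row)
    chrom = sig_row["chrom"]
    region = None
    if chrom in phased:
        region = _phased_region(phased[chrom], sig_row["start_bp"], sig_row["end_bp"])
    if region is None:
        out.update(
            n_blocks_lean="non-assessable",
            n_blocks_fat="non-assessable",
            main_hap_label="non-assessable",
            ehh_area_lean="non-assessable",
            ehh_area_fat="non-assessable",
            ehh_favored_line="non-assessable",
        )
    else:
        areas = {}
        for line in ("lean", "fat"):
            blocks = ld_blocks.blocks_for_line(region, line, cfg.max_ld_distance_bp)
            out[f"n_blocks_{line}"] = len(blocks)
            core = ehh_scan.CoreRegion(chrom, 0, region.n_markers - 1)
            if blocks:
                big = max(blocks, key=lambda b: b.n_markers)
                core = ehh_scan.CoreRegion(chrom, big.start_idx, big.end_idx)
            areas[line] = ehh_scan.line_ehh_area(phased[chrom], _lift_core(region, phased[chrom], core), line)
            out[f"ehh_area_{line}"] = round(areas[line], 1)
        out["ehh_favored_line"] = max(areas, key=areas.get) if any(areas.values()) else ""
        # line-specificity of the main haplotypes over the whole region
        whole = ld_blocks.BlockDefinition(
            chrom, 0, region.n_markers - 1,
            int(region.markers["pos_bp"].iloc[0]),
            int(region.markers["pos_bp"].iloc[-1]), 0, 0,
        )
        table = haplotype_analysis.block_haplotype_freqs(region, whole)
        labels = haplotype_analysis.classify_line_specific(table)
        specific = [l for l in labels if l.endswith("-specific")]
        out["main_hap_label"] = ",".join(sorted(set(specific))) or "none-specific"
        # refine inferred line: lower het z wins; ties broken by EHH area
        if not out.get("inferred_line"):
            z = {"lean": sig_row["min_z_lean"], "fat": sig_row["min_z_fat"]}
            if np.isfinite(list(z.values())).all() and z["lean"] != z["fat"]:
                out["inferred_line"] = min(z, key=z.get)
            elif any(areas.values()):
                out["inferred_line"] = max(areas, key=areas.get)
    if assoc_df is None or assoc_df.empty:
        out["top_snp"] = out["top_snp_p"] = out["top_snp_trait"] = "non-assessable"
    else:
        pos = markers.set_index("id")["pos_bp"]
        sub = assoc_df[assoc_df["marker"].map(markers.set_index("id")["chrom"]) == chrom]
        mpos = sub["marker"].map(pos)
        near = sub[
            (mpos >= sig_row["start_bp"] - cfg.assoc_flank_bp)
            & (mpos < sig_row["end_bp"] + cfg.assoc_flank_bp)
        ].copy()
        near["best_p"] = near[["add_p", "dom_p"]].min(axis=1)
        near = near.dropna(subset=["best_p"])
        if near.empty:
            out["top_snp"] = out["top_snp_p"] = out["top_snp_trait"] = "non-assessable"
        else:
            best = near.loc[near["best_p"].idxmin()]
            out["top_snp"] = best["marker"]
            out["top_snp_p"] = float(best["best_p"])
            out["top_snp_trait"] = best["trait"]
    return out


def _lift_core(region: PhasedHaplotypes, full: PhasedHaplotypes, core: ehh_scan.CoreRegion):
    """Translate a core defined on a region subset into full-chromosome marker
    indices so EHH can extend beyond the region."""
    ids = region.markers["id"].iloc[[core.start_idx, core.end_idx]]
    full_idx = full.markers.reset_index().set_index("id").loc[ids, "index"]
    return ehh_scan.CoreRegion(core.chrom, int(full_idx.iloc[0]), int(full_idx.iloc[1]))


def run(cfg: RunConfig) -> RunReport:
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ds, phased, pheno = _load_inputs(cfg)
    log.info("loaded %d individuals x %d markers", ds.n_individuals, ds.n_markers)
    ds = apply_qc(ds, cfg.maf_min, cfg.call_rate_min, cfg.ind_miss_max)
    log.info("after QC: %d x %d", ds.n_individuals, ds.n_markers)

    stats = window_scan.snp_stats(ds)
    windows = window_scan.sliding_windows(
        ds.markers, cfg.window_size_bp, cfg.window_step_bp, cfg.min_snps_per_window
    )
    wdf = window_scan.standardize_by_chrom(window_scan.window_summary(windows, stats))
    signatures = window_scan.call_signatures(
        wdf, cfg.afd_threshold, cfg.z_afd_threshold, cfg.z_het_threshold
    )
    chrom_summary = window_scan.chromosome_summary(ds, stats)

    bonf = assoc.bonferroni_threshold(
        cfg.alpha, ds.n_markers, n_traits=len(cfg.traits), n_effects=2
    )
    assoc_frames = []
    if pheno is not None:
        pheno_aligned = (
            pheno.set_index("individual_id").loc[ds.individuals["id"]].reset_index()
        )
        for trait in cfg.traits:
            spec = assoc.AssocModelSpec(
                trait=trait, covariates=cfg.covariates, family_mode=cfg.family_mode,
                alpha=cfg.alpha, n_traits=len(cfg.traits),
            )
            assoc_frames.append(
                assoc.run_association(
                    pheno_aligned, ds.genotypes, spec,
                    marker_ids=ds.markers["id"].tolist(),
                )
            )
    assoc_df = (
        pd.concat(assoc_frames, ignore_index=True) if assoc_frames else pd.DataFrame()
    )

    annotated = [
        _annotate_signature(row._asdict(), phased, assoc_df, ds.markers, cfg)
        for row in signatures.itertuples(index=False)
    ]
    signatures_out = pd.DataFrame(annotated) if annotated else signatures

    thresholds = {
        "maf_min": cfg.maf_min,
        "call_rate_min": cfg.call_rate_min,
        "ind_miss_max": cfg.ind_miss_max,
        "window_size_bp": cfg.window_size_bp,
        "window_step_bp": cfg.window_step_bp,
        "min_snps_per_window": cfg.min_snps_per_window,
        "afd_threshold": cfg.afd_threshold,
        "z_afd_threshold": cfg.z_afd_threshold,
        "z_het_threshold": cfg.z_het_threshold,
        "alpha": cfg.alpha,
        "family_mode": cfg.family_mode,
    }
    report = RunReport(
        qc_report=ds.qc_report or {},
        chromosome_summary=chrom_summary,
        windows=wdf,
        signatures=signatures_out,
        association=assoc_df,
        bonferroni_p=bonf,
        thresholds=thresholds,
    )

    write_table(chrom_summary, out_dir / "chromosome_summary.tsv")
    write_table(wdf, out_dir / "windows.tsv")
    write_table(signatures_out, out_dir / "signatures.tsv")
    if not assoc_df.empty:
        write_table(assoc_df, out_dir / "assoc.tsv")
    (out_dir / "report.md").write_text(report.to_markdown())
    return report
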