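"""Forward simulator of two-line divergent truncation selection.

The generator emulates a divergent breeding design: a single base population
is split at random into a lean and a fat line; each line then undergoes 11
generations of truncation selection (downward in the lean line, upward in the
fat line) on an abdominal-fat phenotype controlled by planted QTL plus
environmental noise, with a 1 sire : 4 dams mating structure producing 25
half-sib families per line and generation.  Founder haplotypes are drawn from
a finite haplotype pool, which creates background LD; meiosis recombines
parental haplotypes with per-interval recombination fractions from a uniform
3 cM/Mb map (Haldane, no interference).  The marker map mimics a 60k-chip
panel: evenly spaced markers at 22.5 kb over a configurable number of
chromosomes.

Outputs are the exact containers and file formats the rest of the pipeline
reads (GenotypeDataset, PhasedHaplotypes, phenotype table) plus truth tables
(QTL effects, per-generation allele-frequency trajectories, line phenotype
means) so every stage is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .genotype_io import GenotypeDataset, PhasedHaplotypes, allele1

_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]


@dataclass(frozen=True)
class Qtl:
    chrom: str
    marker_index: int  # index within the chromosome's marker list
    add_effect: float  # allele-substitution effect of allele 1, phenotype units
    dom_effect: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are the study conditions the scan is
    meant to detect: 11 generations, 25 half-sib families of 1 sire x 4 dams
    per line, a 22.5 kb marker grid, and one strong additive QTL (effect one
    phenotypic standard deviation, h2 = 0.5) segregating at frequency 0.5 in
    the founders."""

    seed: int = 0
    n_chromosomes: int = 5
    markers_per_chromosome: int = 400
    marker_spacing_bp: int = 22_500
    founder_pool_size: int = 20
    founder_freq_range: tuple[float, float] = (0.1, 0.9)
    #: founder haplotype pool structure: with n_ancestral_haplotypes = 2 the
    #: pool haplotypes are recombinant mosaics of two ancestral haplotypes
    #: (a single-grandsire-line bottleneck; gives chip-like common-MAF markers
    #: and locally two-class haplotype structure); None = independent draws
    n_ancestral_haplotypes: int | None = 2
    within_class_diversity: float = 0.05  # per-marker flip prob off the ancestor
    mosaic_segment_mb: float = 1.0  # mean ancestry-segment length in the pool
    n_founders_per_line: int = 250
    qtls: tuple[Qtl, ...] = (Qtl(chrom="3", marker_index=200, add_effect=1.0),)
    qtl_founder_freq: float = 0.5
    heritability: float = 0.5
    generations: int = 11
    n_sires: int = 25
    dams_per_sire: int = 4
    offspring_per_family: int = 12
    recomb_rate_cm_per_mb: float = 3.0
    selection: dict = field(
        default_factory=lambda: {"lean": "down", "fat": "up"}
    )  # per line: "up", "down" or "none"
    afp_base: float = 2.9
    afp_scale: float = 0.85
    bw7_mean: float = 2400.0
    bw7_sd: float = 220.0
    hatch_effect_afp: float = 0.0
    track_markers: tuple[tuple[str, int], ...] | None = None  # default: the QTL

    def __post_init__(self):
        if self.founder_pool_size < 2:
            raise ConfigError("founder haplotype pool must hold at least 2 haplotypes")
        if not (0.0 <= self.heritability <= 1.0):
            raise ConfigError("heritability must be in [0, 1]")
        if self.offspring_per_family % self.dams_per_sire != 0:
            raise ConfigError("offspring_per_family must divide evenly over dams")
        n_off_line = self.n_sires * self.offspring_per_family
        if n_off_line // 2 < self.n_sires * self.dams_per_sire:
            raise ConfigError(
                "not enough female offspring per generation to supply "
                f"{self.n_sires * self.dams_per_sire} dams"
            )
        for q in self.qtls:
            if not np.isfinite([q.add_effect, q.dom_effect]).all():
                raise ConfigError("QTL effects must be finite")
            if q.chrom not in self.chrom_names:
                raise ConfigError(
                    f"QTL chromosome {q.chrom!r} outside the simulated map "
                    f"{self.chrom_names}"
                )
            if not (0 <= q.marker_index < self.markers_per_chromosome):
                raise ConfigError("QTL marker_index outside the chromosome")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(str(i + 1) for i in range(self.n_chromosomes))


@dataclass
class Population:
    """In-memory population state: allele-1 indicator haplotypes per
    chromosome (n_individuals, 2, n_markers) plus individual metadata."""

    markers: pd.DataFrame  # full map across chromosomes
    haplotypes: dict[str, np.ndarray]
    individuals: pd.DataFrame  # id, line, family, sex, hatch
    generation: int = 0

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def line_index(self, line: str) -> np.ndarray:
        return np.flatnonzero((self.individuals["line"] == line).to_numpy())

    def dosage(self) -> np.ndarray:
        return np.concatenate(
            [self.haplotypes[c].sum(axis=1) for c in self.markers["chrom"].unique()],
            axis=1,
        ).astype(np.int8)


@dataclass(frozen=True)
class SimTruth:
    qtls: pd.DataFrame  # chrom, marker_index, pos_bp, add_effect, dom_effect
    freq_trajectories: pd.DataFrame  # line, chrom, marker_index, generation, p
    pheno_means: pd.DataFrame  # line, generation, mean_pheno


@dataclass(frozen=True)
class SimResult:
    dataset: GenotypeDataset
    phased: dict[str, PhasedHaplotypes]
    phenotypes: pd.DataFrame
    truth: SimTruth
    population: Population


def _build_markers(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom in cfg.chrom_names:
        pair_idx = rng.integers(0, len(_PAIRS), cfg.markers_per_chromosome)
        for i in range(cfg.markers_per_chromosome):
            pair = _PAIRS[pair_idx[i]]
            a1 = allele1(pair)
            a2 = pair[0] if pair[1] == a1 else pair[1]
            rows.append(
                (
                    f"snp_{chrom}_{i:05d}",
                    chrom,
                    10_000 + i * cfg.marker_spacing_bp,
                    a1,
                    a2,
                )
            )
    return pd.DataFrame(rows, columns=["id", "chrom", "pos_bp", "allele_a", "allele_b"])


def _recomb_fractions(cfg: SimConfig, markers_chrom: pd.DataFrame) -> np.ndarray:
    """Per-interval recombination fraction between adjacent markers (Haldane
    map function on a uniform cM/Mb rate)."""
    pos = markers_chrom["pos_bp"].to_numpy()
    d_morgans = np.diff(pos) * cfg.recomb_rate_cm_per_mb / 1e8
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def meiose(
    haps: np.ndarray,
    parent_idx: np.ndarray,
    rfrac: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per requested parent.

    ``haps``: (n_parents, 2, M) haplotypes; ``parent_idx``: (C,) parent row
    per gamete; ``rfrac``: (M-1,) adjacent-interval recombination fractions.
    Each gamete starts on a random parental haplotype and switches between
    the two with probability rfrac per interval (no interference), so every
    gamete is a contiguous mosaic of its parent's two haplotypes.
    """
    c = len(parent_idx)
    m = haps.shape[2]
    switch = rng.random((c, m - 1)) < rfrac[None, :]
    start = rng.integers(0, 2, size=c)
    state = np.empty((c, m), dtype=np.int64)
    state[:, 0] = start
    state[:, 1:] = (start[:, None] + np.cumsum(switch, axis=1)) % 2
    parent_haps = haps[parent_idx]  # (C, 2, M)
    return np.take_along_axis(parent_haps, state[:, None, :], axis=1)[:, 0, :]


def _genetic_values(pop: Population, cfg: SimConfig) -> np.ndarray:
    g = np.zeros(pop.n_individuals)
    for q in cfg.qtls:
        dos = pop.haplotypes[q.chrom][:, :, q.marker_index].sum(axis=1)
        g += q.add_effect * (dos - 1.0) + q.dom_effect * (dos == 1)
    return g


def simulate_founders(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Base population before selection: founder haplotypes drawn from a
    finite pool, lines assigned by a random split.  Returns (Population, rng)
    so callers can continue the same stream."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    markers = _build_markers(cfg, rng)
    n_total = 2 * cfg.n_founders_per_line

    m = cfg.markers_per_chromosome
    pool: dict[str, np.ndarray] = {}
    ancestry_of: dict[str, np.ndarray | None] = {}
    for chrom in cfg.chrom_names:
        freqs = rng.uniform(*cfg.founder_freq_range, m)
        if cfg.n_ancestral_haplotypes is None:
            pool_c = (
                rng.random((cfg.founder_pool_size, m)) < freqs[None, :]
            ).astype(np.uint8)
            ancestry_of[chrom] = None
        else:
            n_anc = cfg.n_ancestral_haplotypes
            anc = (rng.random((n_anc, m)) < freqs[None, :]).astype(np.uint8)
            switch_prob = cfg.marker_spacing_bp / (cfg.mosaic_segment_mb * 1e6)
            switch = rng.random((cfg.founder_pool_size, m - 1)) < switch_prob
            ancestry = np.empty((cfg.founder_pool_size, m), dtype=np.int64)
            ancestry[:, 0] = rng.integers(0, n_anc, cfg.founder_pool_size)
            jumps = np.cumsum(
                switch * rng.integers(1, n_anc, switch.shape, endpoint=True), axis=1
            )
            ancestry[:, 1:] = (ancestry[:, [0]] + jumps) % n_anc
            pool_c = np.take_along_axis(anc[None, :, :].repeat(
                cfg.founder_pool_size, axis=0), ancestry[:, None, :], axis=1
            )[:, 0, :].astype(np.uint8)
            flips = rng.random(pool_c.shape) < cfg.within_class_diversity
            pool_c ^= flips.astype(np.uint8)
            ancestry_of[chrom] = ancestry
        pool[chrom] = pool_c
    for q in cfg.qtls:
        ancestry = ancestry_of[q.chrom]
        if ancestry is not None:
            # the favored allele rides the first ancestral class(es): the QTL
            # column equals local ancestry, so the sweep drags its haplotype
            n_anc = cfg.n_ancestral_haplotypes
            k_classes = max(1, int(round(cfg.qtl_founder_freq * n_anc)))
            pool[q.chrom][:, q.marker_index] = (
                ancestry[:, q.marker_index] < k_classes
            ).astype(np.uint8)
        else:
            k = int(round(cfg.qtl_founder_freq * cfg.founder_pool_size))
            col = np.zeros(cfg.founder_pool_size, dtype=np.uint8)
            col[rng.permutation(cfg.founder_pool_size)[:k]] = 1
            pool[q.chrom][:, q.marker_index] = col

    draws = rng.integers(0, cfg.founder_pool_size, size=(n_total, 2))
    haplotypes = {c: pool[c][draws] for c in cfg.chrom_names}

    line = np.array(["lean"] * cfg.n_founders_per_line + ["fat"] * cfg.n_founders_per_line)
    line = line[rng.permutation(n_total)]
    sex = np.array((["M", "F"] * n_total)[:n_total])
    sex = sex[rng.permutation(n_total)]
    # balance sexes within each line so selection always has enough parents
    for ln in ("lean", "fat"):
        idx = np.flatnonzero(line == ln)
        half = len(idx) // 2
        sex[idx[:half]] = "M"
        sex[idx[half:]] = "F"
    individuals = pd.DataFrame(
        {
            "id": [f"G0_{i:05d}" for i in range(n_total)],
            "line": line,
            "family": "G0_base",
            "sex": sex,
            "hatch": rng.choice(["1", "2"], n_total),
        }
    )
    pop = Population(markers=markers, haplotypes=haplotypes, individuals=individuals)
    return pop, rng


def _phenotypes(
    pop: Population, cfg: SimConfig, sigma_e: float, rng: np.random.Generator
) -> np.ndarray:
    return _genetic_values(pop, cfg) + rng.normal(0.0, sigma_e, pop.n_individuals)


def _select_parents(order_idx, sexes, cfg: SimConfig):
    males = [i for i in order_idx if sexes[i] == "M"]
    females = [i for i in order_idx if sexes[i] == "F"]
    n_dams = cfg.n_sires * cfg.dams_per_sire
    if len(males) < cfg.n_sires or len(females) < n_dams:
        raise ConfigError(
            f"selection needs {cfg.n_sires} sires and {n_dams} dams; "
            f"only {len(males)} males / {len(females)} females available"
        )
    return np.array(males[: cfg.n_sires]), np.array(females[:n_dams])


def evolve_divergent(pop: Population, cfg: SimConfig, rng: np.random.Generator) -> SimResult:
    """Run the divergent-selection generations and export every artifact."""
    track = cfg.track_markers or tuple((q.chrom, q.marker_index) for q in cfg.qtls)
    rfracs = {
        c: _recomb_fractions(cfg, pop.markers[pop.markers["chrom"] == c])
        for c in cfg.chrom_names
    }
    g0 = _genetic_values(pop, cfg)
    var_g = float(np.var(g0))
    if var_g > 0 and cfg.heritability > 0:
        sigma_e = float(np.sqrt(var_g * (1.0 - cfg.heritability) / cfg.heritability))
    else:
        sigma_e = 1.0
    pheno = _phenotypes(pop, cfg, sigma_e, rng)
    pheno_mu0, pheno_sd0 = float(pheno.mean()), float(pheno.std()) or 1.0

    traj_rows, mean_rows = [], []

    def record(pop, pheno, gen):
        for line in ("lean", "fat"):
            idx = pop.line_index(line)
            for chrom, mi in track:
                p = pop.haplotypes[chrom][idx, :, mi].mean()
                traj_rows.append((line, chrom, mi, gen, float(p)))
            mean_rows.append((line, gen, float(pheno[idx].mean())))

    record(pop, pheno, 0)

    for gen in range(1, cfg.generations + 1):
        new_haps = {c: [] for c in cfg.chrom_names}
        new_rows = []
        for line in ("lean", "fat"):
            idx = pop.line_index(line)
            mode = cfg.selection.get(line, "none")
            score = pheno[idx] + 1e-12 * rng.random(len(idx))  # seeded tie-break
            if mode == "up":
                order = idx[np.argsort(-score, kind="stable")]
            elif mode == "down":
                order = idx[np.argsort(score, kind="stable")]
            else:
                order = idx[rng.permutation(len(idx))]
            sexes = pop.individuals["sex"].to_numpy()
            sires, dams = _select_parents(order, sexes, cfg)
            dams = dams[rng.permutation(len(dams))]
            per_dam = cfg.offspring_per_family // cfg.dams_per_sire
            sire_of_child, dam_of_child, fam_of_child = [], [], []
            for s_rank, sire in enumerate(sires):
                fam = f"G{gen}_{line}_S{s_rank:02d}"
                for dam in dams[s_rank * cfg.dams_per_sire : (s_rank + 1) * cfg.dams_per_sire]:
                    sire_of_child += [sire] * per_dam
                    dam_of_child += [dam] * per_dam
                    fam_of_child += [fam] * per_dam
            sire_of_child = np.array(sire_of_child)
            dam_of_child = np.array(dam_of_child)
            n_children = len(sire_of_child)
            for chrom in cfg.chrom_names:
                pat = meiose(pop.haplotypes[chrom], sire_of_child, rfracs[chrom], rng)
                mat = meiose(pop.haplotypes[chrom], dam_of_child, rfracs[chrom], rng)
                new_haps[chrom].append(np.stack([pat, mat], axis=1))
            # exact half-and-half sexes so the parent supply never collapses
            half = n_children // 2
            child_sex = np.array(["M"] * half + ["F"] * (n_children - half))
            child_sex = child_sex[rng.permutation(n_children)]
            for k in range(n_children):
                new_rows.append(
                    {
                        "id": f"G{gen}_{line}_{k:05d}",
                        "line": line,
                        "family": fam_of_child[k],
                        "sex": child_sex[k],
                        "hatch": "",
                    }
                )
        individuals = pd.DataFrame(new_rows)
        individuals["hatch"] = rng.choice(["1", "2"], len(individuals))
        haplotypes = {c: np.concatenate(new_haps[c], axis=0) for c in cfg.chrom_names}
        pop = Population(
            markers=pop.markers,
            haplotypes=haplotypes,
            individuals=individuals,
            generation=gen,
        )
        pheno = _phenotypes(pop, cfg, sigma_e, rng)
        record(pop, pheno, gen)

    truth = SimTruth(
        qtls=pd.DataFrame(
            [
                {
                    "chrom": q.chrom,
                    "marker_index": q.marker_index,
                    "pos_bp": 10_000 + q.marker_index * cfg.marker_spacing_bp,
                    "add_effect": q.add_effect,
                    "dom_effect": q.dom_effect,
                }
                for q in cfg.qtls
            ]
        ),
        freq_trajectories=pd.DataFrame(
            traj_rows, columns=["line", "chrom", "marker_index", "generation", "p"]
        ),
        pheno_means=pd.DataFrame(
            mean_rows, columns=["line", "generation", "mean_pheno"]
        ),
    )
    phenotypes = _make_phenotype_table(pop, pheno, pheno_mu0, pheno_sd0, cfg, rng)
    return SimResult(
        dataset=to_genotype_dataset(pop),
        phased={c: to_phased(pop, c) for c in cfg.chrom_names},
        phenotypes=phenotypes,
        truth=truth,
        population=pop,
    )


def _make_phenotype_table(pop, pheno, mu0, sd0, cfg, rng) -> pd.DataFrame:
    z = (pheno - mu0) / sd0
    afp = np.clip(cfg.afp_base + cfg.afp_scale * z, 0.05, None)
    afp = afp + cfg.hatch_effect_afp * (pop.individuals["hatch"] == "2").to_numpy()
    bw7 = np.clip(rng.normal(cfg.bw7_mean, cfg.bw7_sd, pop.n_individuals), 500, None)
    return pd.DataFrame(
        {
            "individual_id": pop.individuals["id"],
            "line": pop.individuals["line"],
            "family": pop.individuals["family"],
            "hatch": pop.individuals["hatch"],
            "AFW": np.round(afp * bw7 / 100.0, 2),
            "AFP": np.round(afp, 4),
            "BW7": np.round(bw7, 2),
        }
    )


def simulate(cfg: SimConfig) -> SimResult:
    """Convenience wrapper: founders + divergent evolution under one seed."""
    pop, rng = simulate_founders(cfg)
    return evolve_divergent(pop, cfg, rng)


def to_genotype_dataset(pop: Population) -> GenotypeDataset:
    return GenotypeDataset(
        markers=pop.markers.copy(),
        individuals=pop.individuals.copy().reset_index(drop=True),
        genotypes=pop.dosage(),
    )


def to_phased(pop: Population, chrom: str) -> PhasedHaplotypes:
    sel = pop.markers["chrom"] == chrom
    markers = pop.markers[sel].reset_index(drop=True)
    haps = pop.haplotypes[chrom]
    n = pop.n_individuals
    codes = haps.reshape(n * 2, haps.shape[2])
    a1 = markers["allele_a"].to_numpy()
    a2 = markers["allele_b"].to_numpy()
    alleles = np.where(codes == 1, a1[None, :], a2[None, :]).astype("U1")
    samples = pd.DataFrame(
        {
            "individual_id": np.repeat(pop.individuals["id"].to_numpy(), 2),
            "hap_index": np.tile([0, 1], n),
            "line": np.repeat(pop.individuals["line"].to_numpy(), 2),
        }
    )
    return PhasedHaplotypes(markers=markers, samples=samples, alleles=alleles)


# ---------------------------------------------------------------------------
# p-q sweep scenario


@dataclass(frozen=True)
class PqSweepScenario:
    before: GenotypeDataset
    after: GenotypeDataset
    chrom: str
    target_start_bp: int
    target_end_bp: int
    target_marker_idx: np.ndarray
    p0: float

    @property
    def expected_afd(self) -> float:
        return abs(1.0 - 2.0 * self.p0)


def _exact_freq_column(n_ind: int, p: float) -> np.ndarray:
    copies = 2 * n_ind * p
    if abs(copies - round(copies)) > 1e-9:
        raise DomainError(
            f"frequency {p} is not exactly representable with {n_ind} diploids"
        )
    copies = int(round(copies))
    col = np.zeros(n_ind, dtype=np.int8)
    col[: copies // 2] = 2
    if copies % 2:
        col[copies // 2] = 1
    return col


def pq_sweep_scenario(
    p0: float,
    n_per_line: int = 50,
    n_markers: int = 100,
    spacing_bp: int = 22_500,
    background_freq: float = 0.5,
    target_start_bp: int = 1_000_000,
    target_end_bp: int = 1_500_000,
) -> PqSweepScenario:
    """Construct, exactly, a frequency reversal at a target window.

    Before: both lines at frequency ``p0`` for every marker inside the target
    window.  After: the fat line's frequency flips to 1 - p0 there while the
    lean line stays at p0.  Background markers sit at ``background_freq`` in
    both lines throughout.  Expected heterozygosity 2p(1-p) is identical
    before and after (p and 1-p are symmetric) while the window AFD becomes
    |1 - 2 p0| -- the p-q sweep that a heterozygosity-only scan cannot see.
    """
    if not (0.0 < p0 < 1.0):
        raise DomainError("p0 must be in (0, 1)")
    if p0 == 0.5:
        raise DomainError("p0 = 0.5 is degenerate: the reversal has AFD 0")
    chrom = "1"
    pos = 10_000 + spacing_bp * np.arange(n_markers)
    markers = pd.DataFrame(
        {
            "id": [f"snp_{chrom}_{i:05d}" for i in range(n_markers)],
            "chrom": chrom,
            "pos_bp": pos,
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    in_target = (pos >= target_start_bp) & (pos < target_end_bp)
    individuals = pd.DataFrame(
        {
            "id": [f"{ln}_{i:03d}" for ln in ("lean", "fat") for i in range(n_per_line)],
            "line": ["lean"] * n_per_line + ["fat"] * n_per_line,
            "family": "F0",
            "sex": "M",
            "hatch": "1",
        }
    )

    def build(freq_lean: dict, freq_fat: dict) -> GenotypeDataset:
        cols = []
        for j in range(n_markers):
            key = bool(in_target[j])
            col_lean = _exact_freq_column(n_per_line, freq_lean[key])
            col_fat = _exact_freq_column(n_per_line, freq_fat[key])
            cols.append(np.concatenate([col_lean, col_fat]))
        return GenotypeDataset(
            markers=markers.copy(),
            individuals=individuals.copy(),
            genotypes=np.column_stack(cols),
        )

    bg = background_freq
    before = build({False: bg, True: p0}, {False: bg, True: p0})
    after = build({False: bg, True: p0}, {False: bg, True: 1.0 - p0})
    return PqSweepScenario(
        before=before,
        after=after,
        chrom=chrom,
        target_start_bp=target_start_bp,
        target_end_bp=target_end_bp,
        target_marker_idx=np.flatnonzero(in_target),
        p0=p0,
    )
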