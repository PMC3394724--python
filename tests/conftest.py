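import numpy as np
import pandas as pd
import pytest

from divscan.genotype_io import GenotypeDataset, PhasedHaplotypes
from divscan.synthetic_data import Qtl, SimConfig, simulate


def make_dataset(genotypes, lines, positions=None, chrom="1"):
    """Hand-built GenotypeDataset from a genotype matrix and line labels."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_snp = genotypes.shape
    positions = positions if positions is not None else 10_000 * (1 + np.arange(n_snp))
    markers = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(n_snp)],
            "chrom": chrom,
            "pos_bp": positions,
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    individuals = pd.DataFrame(
        {
            "id": [f"ind{i}" for i in range(n_ind)],
            "line": lines,
            "family": [f"F{i % 3}" for i in range(n_ind)],
            "sex": "M",
            "hatch": "1",
        }
    )
    return GenotypeDataset(markers=markers, individuals=individuals, genotypes=genotypes)


def make_phased(allele_rows, lines, positions=None, chrom="1",
                allele_a="A", allele_b="G"):
    """Hand-built PhasedHaplotypes; allele_rows is a list of strings."""
    alleles = np.array([list(r) for r in allele_rows], dtype="U1")
    n_rows, n_snp = alleles.shape
    positions = positions if positions is not None else 10_000 * (1 + np.arange(n_snp))
    markers = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(n_snp)],
            "chrom": chrom,
            "pos_bp": positions,
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    samples = pd.DataFrame(
        {
            "individual_id": [f"ind{i // 2}" for i in range(n_rows)],
            "hap_index": [i % 2 for i in range(n_rows)],
            "line": lines,
        }
    )
    return PhasedHaplotypes(markers=markers, samples=samples, alleles=alleles)


@pytest.fixture(scope="session")
def small_sim():
    """One small divergent-selection run shared across tests."""
    cfg = SimConfig(
        seed=11,
        n_chromosomes=2,
        markers_per_chromosome=80,
        qtls=(Qtl("1", 40, 1.0),),
        n_founders_per_line=120,
        n_sires=10,
        offspring_per_family=12,
        generations=6,
    )
    return simulate(cfg)
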