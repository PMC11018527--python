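import numpy as np
import pandas as pd
import pytest

from polykit.core import GenotypeMatrix
from polykit.synthdata import SimConfig, gen_syntelog_landscape, generate_all


@pytest.fixture(scope="session")
def small_fixtures():
    """One compact synthetic bundle shared by fast tests."""
    segs = [
        ("acc01", "chr1", 100, 160, "3:1"),
        ("acc02", "chr1", 100, 160, "3:1"),
        ("acc02", "chr2", 50, 120, "4:0"),
    ]
    cfg = SimConfig(seed=1, n_accessions=3, he_segments=segs, bias_fraction=0.1)
    return generate_all(cfg)


@pytest.fixture(scope="session")
def big_run_landscape():
    """Landscape with ~10^4 planted deletion runs per side (p = 0.5)."""
    cfg = SimConfig(
        seed=9,
        n_chroms=1,
        n_genes_per_chrom=120_000,
        deletion_run_p=0.5,
        retention_base=0.8,
        retention_pericentromere=0.8,
        pericentromere_span=0.0,
        plant_origin_bias=False,
    )
    return gen_syntelog_landscape(cfg)


def make_matrix(genotypes, chrom=None, pos=None, ancestral=None, contig_lengths=None):
    """Tiny GenotypeMatrix from a (samples x sites) list/array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_sites = g.shape
    return GenotypeMatrix(
        genotypes=g,
        samples=[f"s{i}" for i in range(n_samples)],
        chrom=np.array(chrom if chrom is not None else ["chr1"] * n_sites, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, n_sites + 1)),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["C"] * n_sites, dtype=object),
        ancestral=ancestral,
        contig_lengths=contig_lengths,
    )


def make_syntelogs(statuses, chrom="chr1", gene_bp=1000, intergenic_bp=500):
    """Syntelog table from a status sequence, synthetic-layout coordinates."""
    n = len(statuses)
    idx = np.arange(n)
    start = intergenic_bp + idx * (gene_bp + intergenic_bp) + 1
    end = start + gene_bp - 1
    return pd.DataFrame(
        {
            "pair_id": [f"{chrom}P{i:05d}" for i in idx],
            "block_id": chrom,
            "chrom": chrom,
            "ancestral_index": idx,
            "gene_cc": [f"{chrom}_CC_{i}" if s != "ee_only" else "" for i, s in enumerate(statuses)],
            "gene_ee": [f"{chrom}_EE_{i}" if s != "cc_only" else "" for i, s in enumerate(statuses)],
            "status": statuses,
            "cc_start": start,
            "cc_end": end,
            "ee_start": start,
            "ee_end": end,
            "ks": np.nan,
            "origin_class": "",
        }
    )
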