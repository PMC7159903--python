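import numpy as np
import pandas as pd
import pytest

import pangevo as pg


def tiny_dataset() -> pg.Dataset:
    """Hand-built 2-bin dataset with every table populated."""
    bins = pd.DataFrame(
        {
            "bin_id": ["binA", "binB"],
            "site": ["Axial", "MCR"],
            "completeness": [0.9, 0.8],
            "redundancy": [0.01, 0.02],
            "length_bp": [5000, 4000],
            "gc": [0.36, 0.40],
        }
    )
    contigs = pd.DataFrame(
        {
            "contig_id": ["cA1", "cB1"],
            "bin_id": ["binA", "binB"],
            "length_bp": [5000, 4000],
            "mean_coverage": [50.0, 60.0],
        }
    )
    gene_calls = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "bin_id": ["binA", "binA", "binB"],
            "contig_id": ["cA1", "cA1", "cB1"],
            "start": [0, 1000, 0],
            "stop": [900, 1900, 900],
            "strand": ["+", "-", "+"],
            "cluster_id": ["GC_1", "GC_2", "GC_1"],
        }
    )
    clusters = pd.DataFrame(
        {
            "cluster_id": ["GC_1", "GC_2"],
            "cog_functions": ["funcA", "funcB"],
            "cog_categories": ["J", "M;P"],
        }
    )
    snvs = pd.DataFrame(
        {
            "contig_id": ["cA1", "cA1", "cB1"],
            "position": [10, 500, 20],
            "ref_base": ["A", "C", "G"],
            "alt_base": ["G", "T", "A"],
        }
    )
    codon_variants = pd.DataFrame(
        {
            "gene_id": ["g1", "g1"],
            "codon_index": [0, 1],
            "ref_codon": ["TTT", "CTA"],
            "alt_codon": ["TTC", "GTA"],
            "full_codon_coverage": [True, True],
        }
    )
    sequences = {"g1": "TTTCTA" * 150, "g2": "ATGGCT" * 150, "g3": "GCTGCA" * 150}
    return pg.Dataset(
        bins=bins,
        contigs=contigs,
        gene_calls=gene_calls,
        clusters=clusters,
        snvs=snvs,
        codon_variants=codon_variants,
        sequences=sequences,
    )


@pytest.fixture
def dataset_tiny():
    return tiny_dataset()


@pytest.fixture(scope="session")
def sim_small():
    """Moderate synthetic dataset reused across read-only tests."""
    cfg = pg.SimulationConfig(
        n_clusters=400,
        seed=11,
        n_biased_clusters=25,
        n_swept_contigs=4,
        variants_per_orf=12,
        snv_density_range=(0.5, 5.0),
    )
    dataset, truth = pg.simulate_dataset(cfg)
    return cfg, dataset, truth


def matrix_from_sets(memberships: dict[str, set[str]], bins: list[str]):
    """Build a PresenceAbsenceMatrix straight from cluster -> bin-set data."""
    occ = pd.DataFrame(
        {b: [b in mem for mem in memberships.values()] for b in bins},
        index=pd.Index(list(memberships), name="cluster_id"),
    )
    return pg.PresenceAbsenceMatrix(occ)
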