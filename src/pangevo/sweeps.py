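"""SNV density and Poisson-deficit detection of gene-specific sweeps.

Within each genome bin the null model spreads the bin's N SNVs uniformly
over its L bp, so a contig of length ``l_c`` expects ``n_c = N * l_c / L``
SNVs. The sweep statistic for the contig is the inclusive lower-tail Poisson
CDF at the observed count; genes inherit the statistic of their contig, and
values below a threshold (default 1e-10) are flagged as sweep candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import DomainError, IntegrityError

SWEEP_P_THRESHOLD = 1e-10


@dataclass(frozen=True)
class ContigSweepResult:
    contig_id: str
    bin_id: str
    length_bp: int
    observed: int
    bin_snvs: int
    bin_length: int
    expected: float  # n_c = N * l_c / L
    p_value: float  # Poisson CDF at the observed count
    snv_free: bool


def _poisson_cdf(x: int, mu: float) -> float:
    if mu == 0.0:
        return 1.0
    return float(stats.poisson.cdf(x, mu))


def contig_sweep_test(
    x: int,
    l_c: int,
    n_total: int,
    l_total: int,
    *,
    contig_id: str = "",
    bin_id: str = "",
) -> ContigSweepResult:
    """Poisson deficit test for one contig.

    ``x`` observed SNVs on a contig of ``l_c`` bp inside a bin with
    ``n_total`` SNVs over ``l_total`` bp. With ``n_total = 0`` the expected
    count is 0 and the P value is 1.
    """
    if l_c > l_total:
        raise DomainError(f"contig length {l_c} exceeds bin length {l_total}")
    if x < 0 or n_total < 0 or l_c <= 0 or l_total <= 0:
        raise DomainError("counts must be non-negative and lengths positive")
    n_c = n_total * l_c / l_total
    return ContigSweepResult(
        contig_id=contig_id,
        bin_id=bin_id,
        length_bp=l_c,
        observed=x,
        bin_snvs=n_total,
        bin_length=l_total,
        expected=n_c,
        p_value=_poisson_cdf(x, n_c),
        snv_free=x == 0,
    )


def _snv_counts_per_contig(snvs: pd.DataFrame, contigs: pd.DataFrame) -> pd.Series:
    known = set(contigs["contig_id"])
    unknown = sorted(set(snvs["contig_id"]) - known)
    if unknown:
        raise IntegrityError(f"SNVs reference unknown contigs: {unknown[:10]}")
    counts = snvs.groupby("contig_id").size()
    return counts.reindex(contigs["contig_id"], fill_value=0)


def snv_density(snvs: pd.DataFrame, contigs: pd.DataFrame) -> pd.DataFrame:
    """Per-bin SNVs per kbp: ``1000 * (total SNVs in bin) / (bin length bp)``.

    Bin length is the sum of its contig lengths (contigs below the upstream
    length floor are assumed already excluded).
    """
    counts = _snv_counts_per_contig(snvs, contigs).to_numpy()
    per_contig = contigs.assign(n_snvs=counts)
    per_bin = per_contig.groupby("bin_id").agg(
        n_snvs=("n_snvs", "sum"), length_bp=("length_bp", "sum")
    )
    if (per_bin["length_bp"] <= 0).any():
        raise DomainError("bin with non-positive total length")
    per_bin["snv_per_kbp"] = 1000.0 * per_bin["n_snvs"] / per_bin["length_bp"]
    return per_bin.reset_index()


def contig_sweep_table(snvs: pd.DataFrame, contigs: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`contig_sweep_test` for every contig.

    Within each bin the expected counts sum exactly to the bin's SNV total.
    """
    counts = _snv_counts_per_contig(snvs, contigs).to_numpy()
    df = contigs[["contig_id", "bin_id", "length_bp"]].copy()
    df["observed"] = counts
    totals = df.groupby("bin_id").agg(
        bin_snvs=("observed", "sum"), bin_length=("length_bp", "sum")
    )
    df = df.merge(totals, on="bin_id")
    df["expected"] = df["bin_snvs"] * df["length_bp"] / df["bin_length"]
    df["p_value"] = np.where(
        df["expected"] == 0.0,
        1.0,
        stats.poisson.cdf(df["observed"], df["expected"]),
    )
    df["snv_free"] = df["observed"] == 0
    return df


def gene_sweep_pvalues(
    contig_results: pd.DataFrame,
    gene_calls: pd.DataFrame,
    *,
    threshold: float = SWEEP_P_THRESHOLD,
) -> pd.DataFrame:
    """Assign each gene the sweep P value of its containing contig and flag
    genes below the threshold."""
    tested = contig_results.set_index("contig_id")
    orphans = sorted(set(gene_calls["contig_id"]) - set(tested.index))
    if orphans:
        raise IntegrityError(f"genes on untested contigs: {orphans[:10]}")
    out = gene_calls[["gene_id", "bin_id", "contig_id", "cluster_id"]].copy()
    out["p_value"] = tested["p_value"].reindex(out["contig_id"]).to_numpy()
    out["snv_free"] = tested["snv_free"].reindex(out["contig_id"]).to_numpy()
    out["flagged"] = out["p_value"] < threshold
    return out


def sweep_summary_by_frequency(
    gene_pvalues: pd.DataFrame, matrix
) -> pd.DataFrame:
    """Per gene-frequency class: fraction of genes flagged and fraction on
    SNV-free contigs."""
    freq = matrix.frequency
    df = gene_pvalues.copy()
    df["frequency"] = freq.reindex(df["cluster_id"]).to_numpy()
    grouped = df.groupby("frequency").agg(
        n_genes=("gene_id", "size"),
        frac_flagged=("flagged", "mean"),
        frac_snv_free=("snv_free", "mean"),
    )
    return grouped.reset_index()


def coverage_by_frequency(
    contigs: pd.DataFrame, gene_calls: pd.DataFrame, matrix
) -> pd.DataFrame:
    """Mean and SD of containing-contig coverage per gene-frequency class
    (diagnostic for coverage-driven artifacts)."""
    cov = contigs.set_index("contig_id")["mean_coverage"]
    df = gene_calls[["gene_id", "contig_id", "cluster_id"]].copy()
    df["coverage"] = cov.reindex(df["contig_id"]).to_numpy()
    df["frequency"] = matrix.frequency.reindex(df["cluster_id"]).to_numpy()
    df = df.dropna(subset=["coverage"])
    grouped = df.groupby("frequency").agg(
        n_genes=("gene_id", "size"),
        mean_coverage=("coverage", "mean"),
        sd_coverage=("coverage", "std"),
    )
    return grouped.reset_index()
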