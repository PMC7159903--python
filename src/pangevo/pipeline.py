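"""Stage orchestration: chain the analysis modules over one dataset and
write every stage output with the configuration echoed.

Stages whose optional inputs are absent (SNVs, codon variants) are skipped;
any stage failure is re-raised as :class:`~pangevo._errors.StageError`
carrying the stage name.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from ._errors import StageError
from . import biogeo as _biogeo
from . import enrichment as _enrichment
from . import pangenome as _pangenome
from . import selection as _selection
from . import sweeps as _sweeps
from .io_core import Dataset, PipelineConfig, load_dataset, write_table

log = logging.getLogger(__name__)


def _stage(name):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, exc) from exc
            log.info("stage %s: done", name)
            return result

        return run

    return wrap


@_stage("pangenome")
def stage_pangenome(dataset: Dataset, config: PipelineConfig, out: Path) -> dict:
    matrix = _pangenome.build_matrix(dataset)
    occ = matrix.occupancy.astype(int)
    occ.insert(0, "cluster_id", occ.index)
    write_table(occ, out / "matrix.tsv")
    spectrum = _pangenome.frequency_spectrum(matrix).rename_axis("frequency").reset_index()
    write_table(spectrum, out / "frequency_spectrum.tsv")
    cont = _pangenome.containment(matrix)
    write_table(cont.rename_axis("bin_id").reset_index(), out / "containment.tsv")
    dendro = _pangenome.cluster_genomes(cont)
    (out / "genome_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    rare = _pangenome.rarefaction(matrix, config.n_rarefaction, config.seed)
    write_table(rare.curve, out / "rarefaction.tsv")
    completeness = dataset.bins["completeness"].to_numpy()
    posterior = _pangenome.core_posterior_curve(
        completeness, n_sims=config.n_montecarlo, seed=config.seed
    )
    write_table(
        pd.DataFrame(
            [
                {
                    "n_obs": cp.n_obs,
                    "probability": cp.probability,
                    "std_error": cp.std_error,
                    "n_qualifying": cp.n_qualifying,
                    "prior": cp.prior,
                }
                for cp in posterior.values()
            ]
        ),
        out / "core_posterior.tsv",
    )
    return {"matrix": matrix, "n_clusters": len(matrix.cluster_ids)}


@_stage("cogfreq")
def stage_cogfreq(dataset, matrix, config, out: Path) -> dict:
    profile = _enrichment.category_profile(matrix, dataset.annotations)
    write_table(profile.table, out / "category_profile.tsv")
    enr = _enrichment.permutation_enrichment(
        profile, config.n_permutations, config.seed
    )
    pv = enr.pvalues.reset_index()
    write_table(pv, out / "enrichment_pvalues.tsv")
    meta = {"n_perm": enr.n_perm, "seed": enr.seed, "scheme": enr.scheme}
    (out / "enrichment_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    if len(enr.pvalues) >= 2:
        dendro = _enrichment.category_cluster_dendrogram(enr)
        (out / "category_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    return {"profile": profile, "n_cells": enr.pvalues.size}


@_stage("biogeo")
def stage_biogeo(dataset, matrix, config, out: Path) -> dict:
    result = _biogeo.score_clusters(
        matrix,
        dataset.site_labels,
        site1=config.site1,
        site2=config.site2,
        p=config.p_site1,
        min_site1=config.min_site1,
        min_site2=config.min_site2,
        cdf_lo=config.cdf_lo,
        cdf_hi=config.cdf_hi,
    )
    scores = result.scores.copy()
    scores["cdf"] = scores["cdf"].map(lambda v: f"{v:.8f}")
    cats = dataset.annotations
    scores["categories"] = scores["cluster_id"].map(lambda c: cats.get(c, "N/A"))
    write_table(scores, out / "biogeo_scores.tsv")
    return {"result": result, "n_scored": len(result.scores), "n_excluded": result.n_excluded}


@_stage("pnps")
def stage_pnps(dataset, matrix, config, out: Path) -> dict:
    table = _selection.pnps_table(dataset.sequences, dataset.codon_variants)
    write_table(table, out / "pnps.tsv")
    finite = table[table["status"] == _selection.STATUS_OK].set_index("gene_id")
    freq = matrix.frequency
    cluster_of = dict(zip(dataset.gene_calls["gene_id"], dataset.gene_calls["cluster_id"]))
    grouping = pd.Series(
        {g: freq.get(cluster_of.get(g), pd.NA) for g in finite.index}, name="frequency"
    )
    stats_df = _selection.pnps_group_stats(finite["ratio"], grouping.loc[finite.index])
    write_table(stats_df, out / "pnps_by_frequency.tsv")
    return {"table": table, "n_finite": len(finite)}


@_stage("sweeps")
def stage_sweeps(dataset, matrix, config, out: Path) -> dict:
    contigs = dataset.contigs[dataset.contigs["length_bp"] >= config.min_contig_length]
    density = _sweeps.snv_density(dataset.snvs, contigs)
    write_table(density, out / "snv_density.tsv")
    contig_results = _sweeps.contig_sweep_table(dataset.snvs, contigs)
    write_table(contig_results, out / "contig_sweeps.tsv")
    calls = dataset.gene_calls[dataset.gene_calls["contig_id"].isin(contigs["contig_id"])]
    gene_p = _sweeps.gene_sweep_pvalues(
        contig_results, calls, threshold=config.sweep_p_threshold
    )
    write_table(gene_p, out / "gene_sweeps.tsv")
    summary = _sweeps.sweep_summary_by_frequency(gene_p, matrix)
    write_table(summary, out / "sweep_summary.tsv")
    coverage = _sweeps.coverage_by_frequency(contigs, calls, matrix)
    write_table(coverage, out / "coverage_by_frequency.tsv")
    return {"contig_results": contig_results, "n_flagged": int(gene_p["flagged"].sum())}


def run_pipeline(config: PipelineConfig, dataset: Dataset | None = None) -> dict:
    """Run every applicable stage; returns a report dict of per-stage facts.

    ``dataset`` may be passed directly (e.g. fresh from the simulator);
    otherwise it is loaded from ``config.input_dir``.
    """
    if dataset is None:
        if config.input_dir is None:
            raise StageError("load", ValueError("no dataset and no input_dir"))
        dataset = load_dataset(config.input_dir, config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {"seed": config.seed, "config_digest": config.digest()}
    pan = stage_pangenome(dataset, config, out)
    matrix = pan["matrix"]
    report["pangenome"] = {"n_clusters": pan["n_clusters"]}
    cog = stage_cogfreq(dataset, matrix, config, out)
    report["cogfreq"] = {"n_cells": cog["n_cells"]}
    bio = stage_biogeo(dataset, matrix, config, out)
    report["biogeo"] = {"n_scored": bio["n_scored"], "n_excluded": bio["n_excluded"]}
    if dataset.sequences is not None and dataset.codon_variants is not None:
        sel = stage_pnps(dataset, matrix, config, out)
        report["pnps"] = {"n_finite": sel["n_finite"]}
    else:
        log.info("stage pnps: skipped (no codon variants / sequences)")
        report["pnps"] = "skipped"
    if dataset.snvs is not None:
        sw = stage_sweeps(dataset, matrix, config, out)
        report["sweeps"] = {"n_flagged": sw["n_flagged"]}
    else:
        log.info("stage sweeps: skipped (no SNV table)")
        report["sweeps"] = "skipped"

    summary = dict(report)
    summary["config"] = {k: str(v) for k, v in vars(config).items()}
    summary["row_counts"] = dataset.counts()
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return report
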