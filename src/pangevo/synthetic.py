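"""Synthetic dataset generator with the statistical structure the pipeline
assumes, plus a truth table for parameter-recovery testing.

The generator draws, per cluster, a true presence set from a U-shaped
frequency spectrum (core mass at frequency M, a singleton spike, and a
truncated-geometric accessory tail), then thins presence through per-bin
completeness (``observed = true AND Bernoulli(completeness)``). Gene calls
are tiled on contigs without overlap, codon variants are drawn so that the
expected pN/pS of each ORF matches its selection-class target under the
selection module's site counting, and SNVs fall as a Poisson process at a
per-bin density (with an optional density multiplier on swept contigs).

All randomness flows from one seed; each stage uses its own deterministic
substream, so the three generator entry points are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._errors import ConfigError, SizingError
from .io_core import Dataset, write_dataset, write_table
from . import selection as _sel

# frequency-band category compositions; weights are renormalized internally.
DEFAULT_HIGH_WEIGHTS = {
    "J": 0.18, "E": 0.14, "H": 0.10, "F": 0.08, "C": 0.10, "O": 0.06,
    "K": 0.06, "L": 0.05, "I": 0.05, "D": 0.03, "N/A": 0.15,
}
DEFAULT_LOW_WEIGHTS = {
    "M": 0.17, "T": 0.11, "P": 0.11, "G": 0.09, "L": 0.08, "V": 0.05,
    "K": 0.05, "S": 0.09, "N/A": 0.25,
}

_STAGE_PANGENOME, _STAGE_VARIANTS, _STAGE_SNVS = 0, 1, 2

# contigs must clear the upstream 1 kbp inclusion floor
MIN_CONTIG_LENGTH = 1000


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults emulate a 22-bin two-site design."""

    n_site1: int = 13  # "Axial"
    n_site2: int = 9  # "MCR"
    site1: str = "Axial"
    site2: str = "MCR"
    n_clusters: int = 10_000
    core_fraction: float = 0.15
    singleton_fraction: float = 0.35
    accessory_decay: float = 0.25  # geometric rate over frequencies 2..M-1
    completeness_range: tuple[float, float] = (0.70, 0.97)
    redundancy_range: tuple[float, float] = (0.0, 0.05)
    # site-biased clusters: present in `biased_site2_presence` site-2 bins and
    # at most `biased_site1_max` site-1 bins before completeness dropout
    n_biased_clusters: int = 0
    biased_site2_presence: int = 9
    biased_site1_max: int = 1
    biased_category: str = "P"
    category_weights_high: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HIGH_WEIGHTS)
    )
    category_weights_low: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOW_WEIGHTS)
    )
    band_split: int = 15
    multi_annotation_fraction: float = 0.05
    # selection classes: per-class target pN/pS and per-ORF variant count
    pnps_targets: Mapping[str, float] = field(
        default_factory=lambda: {"core": 0.15, "accessory": 0.25, "singleton": 0.35}
    )
    variants_per_orf: int = 30
    partial_coverage_fraction: float = 0.03
    # SNVs: per-bin density (per kbp) drawn log-uniformly from this range
    snv_density_range: tuple[float, float] = (0.1, 10.0)
    n_swept_contigs: int = 0
    sweep_density_multiplier: float = 0.0
    # layout
    gene_length: int = 900  # multiple of 3
    gene_spacing: int = 100
    contigs_per_bin: int = 25
    coverage_range: tuple[float, float] = (20.0, 200.0)
    max_bin_length: int | None = None
    with_sequences: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_site1 < 1 or self.n_site2 < 1:
            raise ConfigError("need at least one bin per site")
        for lo, hi, what in [
            (*self.completeness_range, "completeness"),
            (*self.redundancy_range, "redundancy"),
        ]:
            if not 0 <= lo <= hi <= 1:
                raise ConfigError(f"invalid {what} range ({lo}, {hi})")
        if self.completeness_range[0] <= 0:
            raise ConfigError("completeness must be positive")
        fracs = (
            self.core_fraction,
            self.singleton_fraction,
            self.multi_annotation_fraction,
            self.partial_coverage_fraction,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ConfigError("fractions must lie in [0, 1]")
        if self.core_fraction + self.singleton_fraction > 1:
            raise ConfigError("core_fraction + singleton_fraction must be <= 1")
        if not 0 < self.accessory_decay < 1:
            raise ConfigError("accessory_decay must lie in (0, 1)")
        if min(self.snv_density_range) < 0:
            raise ConfigError("SNV densities must be >= 0")
        if self.sweep_density_multiplier < 0:
            raise ConfigError("sweep multiplier must be >= 0")
        if any(t < 0 for t in self.pnps_targets.values()):
            raise ConfigError("pN/pS targets must be >= 0")
        if self.gene_length % 3 or self.gene_length < 3:
            raise ConfigError("gene_length must be a positive multiple of 3")

    @property
    def n_bins(self) -> int:
        return self.n_site1 + self.n_site2


@dataclass
class TruthTable:
    """Ground truth for every generated entity."""

    clusters: pd.DataFrame  # cluster_id, true_frequency, members, site_biased,
    #                         categories, selection_class, pnps_target
    bins: pd.DataFrame  # bin_id, site, completeness, snv_density
    contigs: pd.DataFrame  # contig_id, bin_id, swept
    orfs: pd.DataFrame  # gene_id, cluster_id, selection_class, pnps_target

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        write_table(self.clusters, out_dir / "truth.tsv")
        write_table(self.bins, out_dir / "truth_bins.tsv")
        write_table(self.contigs, out_dir / "truth_contigs.tsv")
        write_table(self.orfs, out_dir / "truth_orfs.tsv")


def _rng_for(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[stage])


def _draw_frequencies(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    m = config.n_bins
    freqs = np.arange(1, m + 1)
    probs = np.zeros(m)
    probs[0] = config.singleton_fraction
    probs[m - 1] = config.core_fraction
    mid = np.arange(2, m)
    if len(mid):
        w = (1.0 - config.accessory_decay) ** (mid - 2)
        w = w / w.sum() * (1.0 - config.core_fraction - config.singleton_fraction)
        probs[1 : m - 1] = w
    probs = probs / probs.sum()
    return rng.choice(freqs, size=config.n_clusters, p=probs)


def _category_for(config, freq: int, rng: np.random.Generator) -> str:
    weights = (
        config.category_weights_high
        if freq >= config.band_split
        else config.category_weights_low
    )
    cats = list(weights)
    p = np.array([weights[c] for c in cats], dtype=float)
    cat = rng.choice(cats, p=p / p.sum())
    if cat != "N/A" and rng.random() < config.multi_annotation_fraction:
        others = [c for c in cats if c not in (cat, "N/A")]
        if others:
            cat = ";".join(sorted([cat, str(rng.choice(others))]))
    return str(cat)


def generate_pangenome(config: SimulationConfig) -> tuple[Dataset, TruthTable]:
    """Generate bins, contigs, gene calls, annotations and (optionally)
    coding sequences; return the observable dataset and the truth table.

    Raises
    ------
    SizingError
        If ``max_bin_length`` is set and the genes of some bin do not fit.
    """
    rng = _rng_for(config, _STAGE_PANGENOME)
    m = config.n_bins
    bin_ids = [f"bin_{i:02d}" for i in range(m)]
    sites = [config.site1] * config.n_site1 + [config.site2] * config.n_site2
    completeness = rng.uniform(*config.completeness_range, size=m)
    redundancy = rng.uniform(*config.redundancy_range, size=m)
    site1_idx = np.arange(config.n_site1)
    site2_idx = np.arange(config.n_site1, m)

    if config.n_biased_clusters > config.n_clusters:
        raise ConfigError("more biased clusters than clusters")
    if config.biased_site2_presence > config.n_site2:
        raise ConfigError("biased_site2_presence exceeds the site-2 bin count")

    freqs = _draw_frequencies(config, rng)
    presence = np.zeros((config.n_clusters, m), dtype=bool)
    biased = np.zeros(config.n_clusters, dtype=bool)
    biased_idx = (
        rng.choice(config.n_clusters, size=config.n_biased_clusters, replace=False)
        if config.n_biased_clusters
        else np.array([], dtype=int)
    )
    biased[biased_idx] = True
    for g in range(config.n_clusters):
        if biased[g]:
            members2 = rng.choice(site2_idx, size=config.biased_site2_presence, replace=False)
            n1 = rng.integers(0, config.biased_site1_max + 1)
            members1 = rng.choice(site1_idx, size=n1, replace=False)
            members = np.concatenate([members2, members1])
            freqs[g] = len(members)
        else:
            members = rng.choice(m, size=freqs[g], replace=False)
        presence[g, members] = True

    observed = presence & (rng.random((config.n_clusters, m)) < completeness[None, :])

    cluster_ids = [f"GC_{g:06d}" for g in range(config.n_clusters)]
    categories = []
    for g in range(config.n_clusters):
        if biased[g] and config.biased_category:
            categories.append(config.biased_category)
        else:
            categories.append(_category_for(config, int(freqs[g]), rng))
    sel_class = np.where(
        freqs == 1, "singleton", np.where(freqs == m, "core", "accessory")
    )
    targets = np.array([config.pnps_targets[c] for c in sel_class])

    # layout: tile each bin's observed genes on contigs, no overlap
    pitch = config.gene_length + config.gene_spacing
    contig_rows, call_rows = [], []
    sequences: dict[str, str] | None = {} if config.with_sequences else None
    codon_pool = _sense_codons()
    for b in range(m):
        cluster_here = np.flatnonzero(observed[:, b])
        n_genes = len(cluster_here)
        if config.max_bin_length is not None and n_genes * pitch > config.max_bin_length:
            raise SizingError(
                f"bin {bin_ids[b]}: {n_genes} genes need {n_genes * pitch} bp, "
                f"budget is {config.max_bin_length}"
            )
        n_contigs = max(1, min(config.contigs_per_bin, n_genes)) if n_genes else 1
        per_contig = np.array_split(rng.permutation(cluster_here), n_contigs)
        for ci, genes in enumerate(per_contig):
            contig_id = f"{bin_ids[b]}_c{ci:03d}"
            slack = int(rng.integers(500, 5000))
            length = max(MIN_CONTIG_LENGTH, len(genes) * pitch + slack)
            contig_rows.append(
                {
                    "contig_id": contig_id,
                    "bin_id": bin_ids[b],
                    "length_bp": length,
                    "mean_coverage": float(
                        np.round(rng.uniform(*config.coverage_range), 2)
                    ),
                }
            )
            for gi, g in enumerate(genes):
                start = gi * pitch + config.gene_spacing // 2
                gene_id = f"{bin_ids[b]}_g{len(call_rows):06d}"
                call_rows.append(
                    {
                        "gene_id": gene_id,
                        "bin_id": bin_ids[b],
                        "contig_id": contig_id,
                        "start": start,
                        "stop": start + config.gene_length,
                        "strand": "+" if rng.random() < 0.5 else "-",
                        "cluster_id": cluster_ids[g],
                    }
                )
                if sequences is not None:
                    n_codons = config.gene_length // 3
                    seq = "".join(rng.choice(codon_pool, size=n_codons))
                    sequences[gene_id] = seq

    contigs = pd.DataFrame(contig_rows)
    calls = pd.DataFrame(
        call_rows,
        columns=["gene_id", "bin_id", "contig_id", "start", "stop", "strand", "cluster_id"],
    )
    bin_lengths = contigs.groupby("bin_id")["length_bp"].sum()
    bins = pd.DataFrame(
        {
            "bin_id": bin_ids,
            "site": sites,
            "completeness": np.round(completeness, 4),
            "redundancy": np.round(redundancy, 4),
            "length_bp": bin_lengths.reindex(bin_ids).fillna(0).astype(int).to_numpy(),
            "gc": np.round(rng.uniform(0.30, 0.50, size=m), 4),
        }
    )
    observed_clusters = sorted(set(calls["cluster_id"])) if len(calls) else []
    clusters = pd.DataFrame(
        {
            "cluster_id": cluster_ids,
            "cog_functions": ["simulated"] * config.n_clusters,
            "cog_categories": categories,
        }
    )
    clusters_observed = clusters[clusters["cluster_id"].isin(observed_clusters)]

    dataset = Dataset(
        bins=bins,
        contigs=contigs,
        gene_calls=calls,
        clusters=clusters_observed.reset_index(drop=True),
        sequences=sequences,
    )
    truth_clusters = pd.DataFrame(
        {
            "cluster_id": cluster_ids,
            "true_frequency": freqs,
            "members": [
                ";".join(bin_ids[i] for i in np.flatnonzero(presence[g]))
                for g in range(config.n_clusters)
            ],
            "site_biased": biased,
            "categories": categories,
            "selection_class": sel_class,
            "pnps_target": targets,
        }
    )
    truth_bins = pd.DataFrame(
        {
            "bin_id": bin_ids,
            "site": sites,
            "completeness": completeness,
            "snv_density": np.nan,  # filled by generate_snvs
        }
    )
    truth_contigs = contigs[["contig_id", "bin_id"]].copy()
    truth_contigs["swept"] = False
    target_of = dict(zip(cluster_ids, targets))
    class_of = dict(zip(cluster_ids, sel_class))
    truth_orfs = calls[["gene_id", "cluster_id"]].copy()
    truth_orfs["selection_class"] = truth_orfs["cluster_id"].map(class_of)
    truth_orfs["pnps_target"] = truth_orfs["cluster_id"].map(target_of)
    truth = TruthTable(
        clusters=truth_clusters, bins=truth_bins, contigs=truth_contigs, orfs=truth_orfs
    )
    return dataset, truth


def _sense_codons() -> np.ndarray:
    table = _sel._aa_table(1)
    return np.array([c for c, aa in table.items() if aa != "*"])


def _mutant_cache() -> dict[str, tuple[list[str], list[str]]]:
    """codon -> (synonymous alt codons, nonsynonymous alt codons), stop
    introductions excluded (they would be dropped downstream)."""
    cache = {}
    for codon in _sense_codons():
        syn, nonsyn = [], []
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1 :]
                kind = _sel.classify_variant(codon, alt)
                if kind == _sel.SYNONYMOUS:
                    syn.append(alt)
                elif kind == _sel.NONSYNONYMOUS:
                    nonsyn.append(alt)
        cache[codon] = (syn, nonsyn)
    return cache


def simulate_orf_variants(
    sequence: str,
    target: float,
    n_variants: int,
    rng: np.random.Generator,
    *,
    _cache: dict | None = None,
) -> list[tuple[int, str, str, str]]:
    """Draw ``n_variants`` distinct single-codon variants for one ORF so the
    expected pN/pS equals ``target``; returns (codon_index, ref, alt, kind).

    The nonsynonymous draw count is ``Binomial(n, p)`` with
    ``p = target * N_pot / (target * N_pot + S_pot)`` so that
    ``E[pN] / E[pS] = target`` under the selection module's site counting.

    Raises
    ------
    SizingError
        If the ORF has too few distinct mutant slots of a required kind.
    """
    cache = _cache if _cache is not None else _mutant_cache()
    codons = [sequence[i : i + 3] for i in range(0, len(sequence), 3)]
    syn_slots, nonsyn_slots = [], []
    s_pot = n_pot = 0.0
    for idx, codon in enumerate(codons):
        syn_alts, nonsyn_alts = cache[codon]
        syn_slots.extend((idx, codon, alt) for alt in syn_alts)
        nonsyn_slots.extend((idx, codon, alt) for alt in nonsyn_alts)
        s, n = _sel.potential_sites(codon)
        s_pot += float(s)
        n_pot += float(n)
    if target == 0.0:
        n_nonsyn = 0
    else:
        p_n = target * n_pot / (target * n_pot + s_pot)
        n_nonsyn = int(rng.binomial(n_variants, p_n))
    n_syn = n_variants - n_nonsyn
    if n_syn > len(syn_slots) or n_nonsyn > len(nonsyn_slots):
        raise SizingError(
            f"ORF too short for {n_syn} synonymous / {n_nonsyn} nonsynonymous "
            f"variants (slots: {len(syn_slots)} / {len(nonsyn_slots)})"
        )
    out = []
    for slots, count, kind in [
        (syn_slots, n_syn, _sel.SYNONYMOUS),
        (nonsyn_slots, n_nonsyn, _sel.NONSYNONYMOUS),
    ]:
        chosen = rng.choice(len(slots), size=count, replace=False)
        out.extend((*slots[i], kind) for i in chosen)
    return out


def generate_codon_variants(
    dataset: Dataset, truth: TruthTable, config: SimulationConfig
) -> pd.DataFrame:
    """Codon variant records for every ORF with a sequence, at the per-class
    pN/pS targets. A small fraction of extra records carries
    ``full_codon_coverage = False`` to exercise the coverage filter."""
    if dataset.sequences is None:
        raise ConfigError("dataset has no coding sequences")
    rng = _rng_for(config, _STAGE_VARIANTS)
    cache = _mutant_cache()
    target_of = dict(zip(truth.orfs["gene_id"], truth.orfs["pnps_target"]))
    rows = []
    for gene_id, seq in dataset.sequences.items():
        target = float(target_of[gene_id])
        for idx, ref, alt, _kind in simulate_orf_variants(
            seq, target, config.variants_per_orf, rng, _cache=cache
        ):
            rows.append(
                {
                    "gene_id": gene_id,
                    "codon_index": idx,
                    "ref_codon": ref,
                    "alt_codon": alt,
                    "full_codon_coverage": True,
                }
            )
        # partial-coverage decoys, ignored downstream
        if rng.random() < config.partial_coverage_fraction:
            codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            idx = int(rng.integers(len(codons)))
            syn_alts, nonsyn_alts = cache[codons[idx]]
            alts = syn_alts + nonsyn_alts
            if alts:
                rows.append(
                    {
                        "gene_id": gene_id,
                        "codon_index": idx,
                        "ref_codon": codons[idx],
                        "alt_codon": alts[int(rng.integers(len(alts)))],
                        "full_codon_coverage": False,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "codon_index", "ref_codon", "alt_codon", "full_codon_coverage"],
    )


def generate_snvs(
    dataset: Dataset, truth: TruthTable, config: SimulationConfig
) -> pd.DataFrame:
    """Poisson SNVs per contig at the bin's density (per kbp); swept contigs
    use the multiplied density. Updates ``truth`` in place with the per-bin
    densities and the swept flags."""
    rng = _rng_for(config, _STAGE_SNVS)
    lo, hi = config.snv_density_range
    if lo == 0.0 and hi == 0.0:
        densities = np.zeros(len(dataset.bins))
    elif lo == hi:
        densities = np.full(len(dataset.bins), lo)
    else:
        if lo <= 0:
            raise ConfigError("log-uniform density range needs a positive lower bound")
        densities = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(dataset.bins)))
    density_of = dict(zip(dataset.bins["bin_id"], densities))
    truth.bins["snv_density"] = truth.bins["bin_id"].map(density_of)

    contigs = dataset.contigs
    swept: set[str] = set()
    if config.n_swept_contigs:
        chosen = rng.choice(
            len(contigs), size=min(config.n_swept_contigs, len(contigs)), replace=False
        )
        swept = set(contigs["contig_id"].iloc[chosen])
    truth.contigs["swept"] = truth.contigs["contig_id"].isin(swept)

    bases = np.array(list("ACGT"))
    rows = []
    for row in contigs.itertuples(index=False):
        density = density_of[row.bin_id]
        if row.contig_id in swept:
            density *= config.sweep_density_multiplier
        mu = density * row.length_bp / 1000.0
        count = int(rng.poisson(mu))
        count = min(count, row.length_bp)
        if count == 0:
            continue
        positions = rng.choice(row.length_bp, size=count, replace=False)
        ref = rng.integers(0, 4, size=count)
        alt = (ref + rng.integers(1, 4, size=count)) % 4
        for pos, r, a in zip(np.sort(positions), ref, alt):
            rows.append(
                {
                    "contig_id": row.contig_id,
                    "position": int(pos),
                    "ref_base": bases[r],
                    "alt_base": bases[a],
                }
            )
    return pd.DataFrame(rows, columns=["contig_id", "position", "ref_base", "alt_base"])


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, TruthTable]:
    """Run all three generator stages and return a complete dataset."""
    dataset, truth = generate_pangenome(config)
    if config.with_sequences:
        dataset.codon_variants = generate_codon_variants(dataset, truth, config)
    dataset.snvs = generate_snvs(dataset, truth, config)
    dataset.validate()
    return dataset, truth


def write_simulation(config: SimulationConfig, out_dir: str | Path) -> tuple[Dataset, TruthTable]:
    dataset, truth = simulate_dataset(config)
    write_dataset(dataset, out_dir)
    truth.write(out_dir)
    return dataset, truth


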