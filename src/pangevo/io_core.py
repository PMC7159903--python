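"""Readers/writers for the tabular and sequence dialects of the pipeline.

All tables are UTF-8 TSV with a header line and "NA" for missing values.
Gene calls use 0-based half-open coordinates; SNV positions are 0-based.

Files and required columns
--------------------------
bins.tsv            bin_id, site, completeness, redundancy, length_bp, gc
contigs.tsv         contig_id, bin_id, length_bp, mean_coverage
gene_calls.tsv      gene_id, bin_id, contig_id, start, stop, strand, cluster_id
clusters.tsv        cluster_id, cog_functions, cog_categories
snvs.tsv            contig_id, position, ref_base, alt_base [, sample_id]
codon_variants.tsv  gene_id, codon_index, ref_codon, alt_codon, full_codon_coverage
cds.fasta           coding sequences keyed by gene_id
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._errors import ConfigError, FormatError, IntegrityError

log = logging.getLogger(__name__)

NA = "NA"

REQUIRED_COLUMNS = {
    "bins": ["bin_id", "site", "completeness", "redundancy", "length_bp", "gc"],
    "contigs": ["contig_id", "bin_id", "length_bp", "mean_coverage"],
    "gene_calls": [
        "gene_id",
        "bin_id",
        "contig_id",
        "start",
        "stop",
        "strand",
        "cluster_id",
    ],
    "clusters": ["cluster_id", "cog_functions", "cog_categories"],
    "snvs": ["contig_id", "position", "ref_base", "alt_base"],
    "codon_variants": [
        "gene_id",
        "codon_index",
        "ref_codon",
        "alt_codon",
        "full_codon_coverage",
    ],
}

TABLE_FILES = {
    "bins": "bins.tsv",
    "contigs": "contigs.tsv",
    "gene_calls": "gene_calls.tsv",
    "clusters": "clusters.tsv",
    "snvs": "snvs.tsv",
    "codon_variants": "codon_variants.tsv",
}
FASTA_FILE = "cds.fasta"


@dataclass
class PipelineConfig:
    """Everything the pipeline stages need beyond the dataset itself."""

    input_dir: Path | None = None
    output_dir: Path = Path("pangevo_out")
    site1: str = "Axial"
    site2: str = "MCR"
    p_site1: float | None = None  # default: n_site1 / (n_site1 + n_site2)
    min_site1: int = 12
    min_site2: int = 7
    cdf_lo: float = 0.05
    cdf_hi: float = 0.95
    sweep_p_threshold: float = 1e-10
    frequency_band_split: int = 15
    min_contig_length: int = 1000
    n_permutations: int = 999
    n_montecarlo: int = 100_000
    n_rarefaction: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.p_site1 is not None and not 0.0 < self.p_site1 < 1.0:
            raise ConfigError(f"p_site1 must lie in (0, 1), got {self.p_site1}")
        if not 0 < self.cdf_lo < self.cdf_hi < 1:
            raise ConfigError("require 0 < cdf_lo < cdf_hi < 1")
        if self.min_site1 < 1 or self.min_site2 < 1:
            raise ConfigError("inclusion thresholds must be >= 1")
        if not 0 < self.sweep_p_threshold < 1:
            raise ConfigError("sweep_p_threshold must lie in (0, 1)")
        if self.n_permutations < 99:
            raise ConfigError("n_permutations must be >= 99")
        if self.n_montecarlo < 1 or self.n_rarefaction < 1:
            raise ConfigError("simulation counts must be >= 1")
        if int(self.seed) != self.seed:
            raise ConfigError("seed must be an integer")
        self.seed = int(self.seed)
        self.input_dir = Path(self.input_dir) if self.input_dir else None
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        # paths are excluded: the digest tracks analytic parameters only
        payload = {
            k: str(v)
            for k, v in asdict(self).items()
            if k not in ("input_dir", "output_dir")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class Dataset:
    """Fully cross-referenced in-memory form of one input bundle."""

    bins: pd.DataFrame
    contigs: pd.DataFrame
    gene_calls: pd.DataFrame
    clusters: pd.DataFrame
    snvs: pd.DataFrame | None = None
    codon_variants: pd.DataFrame | None = None
    sequences: dict[str, str] | None = None

    def __post_init__(self):
        self.validate()

    @property
    def site_labels(self) -> dict[str, str]:
        return dict(zip(self.bins["bin_id"], self.bins["site"]))

    @property
    def annotations(self) -> dict[str, str]:
        return dict(zip(self.clusters["cluster_id"], self.clusters["cog_categories"]))

    def validate(self) -> None:
        bins = set(self.bins["bin_id"])
        if self.bins["bin_id"].duplicated().any():
            raise IntegrityError("duplicated bin ids")
        contig_bins = set(self.contigs["bin_id"]) - bins
        if contig_bins:
            raise IntegrityError(f"contigs reference unknown bins: {sorted(contig_bins)[:10]}")
        contigs = self.contigs.set_index("contig_id")
        if contigs.index.duplicated().any():
            raise IntegrityError("duplicated contig ids")

        calls = self.gene_calls
        bad_bins = sorted(set(calls["bin_id"]) - bins)
        if bad_bins:
            raise IntegrityError(f"gene calls reference unknown bins: {bad_bins[:10]}")
        bad_contigs = sorted(set(calls["contig_id"]) - set(contigs.index))
        if bad_contigs:
            raise IntegrityError(
                f"gene calls reference unknown contigs: {bad_contigs[:10]}"
            )
        if (calls["cluster_id"].astype(str).str.len() == 0).any():
            raise IntegrityError("empty cluster ids in gene calls")
        if len(calls):
            if (calls["start"] >= calls["stop"]).any():
                bad = calls.loc[calls["start"] >= calls["stop"], "gene_id"]
                raise IntegrityError(f"gene spans with start >= stop: {list(bad[:10])}")
            lengths = contigs["length_bp"].reindex(calls["contig_id"]).to_numpy()
            over = calls.loc[calls["stop"].to_numpy() > lengths, "gene_id"]
            if len(over):
                raise IntegrityError(
                    f"gene spans extend beyond contig length: {list(over[:10])}"
                )
        if self.snvs is not None and len(self.snvs):
            bad = sorted(set(self.snvs["contig_id"]) - set(contigs.index))
            if bad:
                raise IntegrityError(f"SNVs reference unknown contigs: {bad[:10]}")
            lengths = contigs["length_bp"].reindex(self.snvs["contig_id"]).to_numpy()
            if (self.snvs["position"].to_numpy() >= lengths).any():
                raise IntegrityError("SNV positions beyond contig length")
        if self.codon_variants is not None and len(self.codon_variants):
            genes = set(calls["gene_id"])
            bad = sorted(set(self.codon_variants["gene_id"]) - genes)
            if bad:
                raise IntegrityError(
                    f"codon variants reference unknown genes: {bad[:10]}"
                )

    def counts(self) -> dict[str, int]:
        return {
            "bins": len(self.bins),
            "contigs": len(self.contigs),
            "gene_calls": len(self.gene_calls),
            "clusters": len(self.clusters),
            "snvs": 0 if self.snvs is None else len(self.snvs),
            "codon_variants": 0
            if self.codon_variants is None
            else len(self.codon_variants),
            "sequences": 0 if self.sequences is None else len(self.sequences),
        }


def _read_table(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"missing input file: {path}")
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    return df


def read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def load_dataset(input_dir: str | Path, config: PipelineConfig | None = None) -> Dataset:
    """Load one input bundle from a directory of the canonical files.

    ``snvs.tsv``, ``codon_variants.tsv`` and ``cds.fasta`` are optional; the
    corresponding pipeline stages are skipped when they are absent. Row
    counts are logged per table.
    """
    input_dir = Path(input_dir)
    tables: dict[str, pd.DataFrame | None] = {}
    for name, fname in TABLE_FILES.items():
        path = input_dir / fname
        optional = name in ("snvs", "codon_variants")
        if optional and not path.exists():
            tables[name] = None
            continue
        tables[name] = _read_table(path, name)
    fasta = input_dir / FASTA_FILE
    sequences = read_fasta(fasta) if fasta.exists() else None
    ds = Dataset(
        bins=tables["bins"],
        contigs=tables["contigs"],
        gene_calls=tables["gene_calls"],
        clusters=tables["clusters"],
        snvs=tables["snvs"],
        codon_variants=tables["codon_variants"],
        sequences=sequences,
    )
    for name, count in ds.counts().items():
        log.info("loaded %s: %d rows", name, count)
    if config is not None:
        sites = set(ds.bins["site"])
        expected = {config.site1, config.site2}
        if not sites <= expected:
            raise ConfigError(
                f"unknown site labels {sorted(sites - expected)}; expected {sorted(expected)}"
            )
    return ds


def write_dataset(dataset: Dataset, out_dir: str | Path) -> None:
    """Write a dataset back to the canonical dialect (inverse of load)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = {
        "bins": dataset.bins,
        "contigs": dataset.contigs,
        "gene_calls": dataset.gene_calls,
        "clusters": dataset.clusters,
        "snvs": dataset.snvs,
        "codon_variants": dataset.codon_variants,
    }
    for name, df in frames.items():
        if df is None:
            continue
        write_table(df, out_dir / TABLE_FILES[name])
    if dataset.sequences is not None:
        write_fasta(dataset.sequences, out_dir / FASTA_FILE)


def write_table(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=NA)
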