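"""Presence/absence structure of a pangenome across genome bins.

Builds the cluster-by-bin occupancy matrix and the statistics derived from
it: the gene-frequency spectrum, asymmetric gene-content containment,
average-linkage genome clustering, rarefaction (pangenome accumulation and
core decay) curves, and a completeness-aware Monte Carlo posterior for a
cluster being truly core given the number of bins it was observed in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

from ._errors import ConfigError, DomainError, IntegrityError


@dataclass(frozen=True)
class GenomeBin:
    """One genome bin (MAG) with its quality metadata."""

    bin_id: str
    site: str
    completeness: float
    redundancy: float
    length_bp: int = 0
    gc: float = float("nan")

    def passes_quality(
        self, *, min_completeness: float = 0.70, max_redundancy: float = 0.10
    ) -> bool:
        """Inclusion rule for downstream analyses (configurable thresholds)."""
        return self.completeness > min_completeness and self.redundancy < max_redundancy


@dataclass
class PresenceAbsenceMatrix:
    """Boolean occupancy of gene clusters (rows) across bins (columns)."""

    occupancy: pd.DataFrame

    def __post_init__(self):
        self.occupancy = self.occupancy.astype(bool)
        self.occupancy = self.occupancy.sort_index(axis=0).sort_index(axis=1)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.occupancy.index)

    @property
    def bin_ids(self) -> list[str]:
        return list(self.occupancy.columns)

    @property
    def n_bins(self) -> int:
        return self.occupancy.shape[1]

    @property
    def frequency(self) -> pd.Series:
        """Number of bins containing each cluster."""
        return self.occupancy.sum(axis=1)


def build_matrix(dataset) -> PresenceAbsenceMatrix:
    """Occupancy[g, m] is true iff bin m holds at least one gene call of
    cluster g; paralogous calls collapse to a single presence.

    Columns cover every bin in the dataset, including bins without gene
    calls; rows cover only clusters observed at least once (an empty
    gene-call table yields an empty matrix).
    """
    bins = list(dataset.bins["bin_id"])
    calls = dataset.gene_calls
    if len(calls) == 0:
        occ = pd.DataFrame(False, index=pd.Index([], name="cluster_id"), columns=bins)
        return PresenceAbsenceMatrix(occ)
    occ = (
        pd.crosstab(calls["cluster_id"], calls["bin_id"]) > 0
    ).reindex(columns=bins, fill_value=False)
    occ.index.name = "cluster_id"
    return PresenceAbsenceMatrix(occ)


def frequency_spectrum(matrix: PresenceAbsenceMatrix) -> pd.Series:
    """Cluster counts per frequency 1..M; sums to the total cluster count."""
    m = matrix.n_bins
    counts = matrix.frequency.value_counts()
    return counts.reindex(range(1, m + 1), fill_value=0).rename("n_clusters")


def containment(matrix: PresenceAbsenceMatrix) -> pd.DataFrame:
    """Asymmetric containment ``C[A, B] = |clusters(A) ∩ clusters(B)| / |clusters(A)|``.

    Raises
    ------
    IntegrityError
        If any bin has zero clusters (its row would be undefined).
    """
    occ = matrix.occupancy.to_numpy()
    sizes = occ.sum(axis=0)
    empty = [b for b, s in zip(matrix.bin_ids, sizes) if s == 0]
    if empty:
        raise IntegrityError(f"bins with zero clusters: {empty}")
    inter = occ.T.astype(np.int64) @ occ.astype(np.int64)
    c = inter / sizes[:, None]
    return pd.DataFrame(c, index=matrix.bin_ids, columns=matrix.bin_ids)


@dataclass
class GenomeDendrogram:
    """Average-linkage tree over bins with its scipy linkage encoding."""

    linkage_matrix: np.ndarray
    ids: list[str]

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.ids)
        return str(tree).strip()


def cluster_genomes(containment_matrix: pd.DataFrame) -> GenomeDendrogram:
    """Average-linkage agglomeration on the symmetrized containment distance
    ``d(A, B) = 1 - (C[A,B] + C[B,A]) / 2``.

    Bin ids are sorted lexicographically before linkage so that ties are
    broken deterministically and the topology does not depend on input order.
    """
    if containment_matrix.shape[0] < 2:
        raise ConfigError("need at least 2 bins to build a dendrogram")
    ids = sorted(containment_matrix.index)
    c = containment_matrix.loc[ids, ids].to_numpy()
    d = 1.0 - (c + c.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    return GenomeDendrogram(linkage_matrix=z, ids=ids)


@dataclass
class RarefactionResult:
    """Accumulation (union) and core (intersection) curves over bin orderings."""

    curve: pd.DataFrame  # n_bins, mean_total, mean_core
    totals: np.ndarray  # (n_perm, M) per-ordering cumulative union sizes
    cores: np.ndarray  # (n_perm, M) per-ordering cumulative intersection sizes


def rarefaction(
    matrix: PresenceAbsenceMatrix, n_perm: int, seed: int
) -> RarefactionResult:
    """Mean total-cluster and core-cluster counts after observing 1..M bins,
    averaged over ``n_perm`` random bin orderings.

    Per ordering the total curve is non-decreasing and the core curve
    non-increasing; the final values are the pangenome size and the count of
    frequency-M clusters regardless of ordering.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    occ = matrix.occupancy.to_numpy()
    m = matrix.n_bins
    rng = np.random.default_rng(seed)
    totals = np.empty((n_perm, m), dtype=np.int64)
    cores = np.empty((n_perm, m), dtype=np.int64)
    for i in range(n_perm):
        order = rng.permutation(m)
        seen = np.logical_or.accumulate(occ[:, order], axis=1)
        core = np.logical_and.accumulate(occ[:, order], axis=1)
        totals[i] = seen.sum(axis=0)
        cores[i] = core.sum(axis=0)
    curve = pd.DataFrame(
        {
            "n_bins": np.arange(1, m + 1),
            "mean_total": totals.mean(axis=0),
            "mean_core": cores.mean(axis=0),
        }
    )
    return RarefactionResult(curve=curve, totals=totals, cores=cores)


@dataclass
class CorePosterior:
    """Monte Carlo posterior that a cluster observed in ``n_obs`` bins is
    present in all M genomes."""

    n_obs: int
    probability: float  # NaN when undefined
    std_error: float
    prior: str
    n_sims: int
    n_qualifying: int

    @property
    def undefined(self) -> bool:
        return self.n_qualifying == 0


def _simulate_observed_counts(
    completeness: np.ndarray, n_sims: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (true presence count t, observed count) pairs under a flat prior
    on t in {1..M}, a uniform random subset of size t, and per-bin Bernoulli
    detection with the bin's completeness."""
    m = len(completeness)
    t = rng.integers(1, m + 1, size=n_sims)
    # uniform random subset of size t: membership = rank of a random shuffle < t
    ranks = np.argsort(rng.random((n_sims, m)), axis=1).argsort(axis=1)
    member = ranks < t[:, None]
    detected = member & (rng.random((n_sims, m)) < completeness[None, :])
    return t, detected.sum(axis=1)


def _simulate_observed_counts_all_core(
    completeness: np.ndarray, n_sims: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Degenerate prior: every cluster is truly present in all M bins, so the
    observed count is a product-Bernoulli (Binomial when completeness is
    equal) draw."""
    m = len(completeness)
    t = np.full(n_sims, m)
    member = np.ones((n_sims, m), dtype=bool)
    detected = member & (rng.random((n_sims, m)) < completeness[None, :])
    return t, detected.sum(axis=1)


def core_posterior(
    n_obs: int,
    completeness: Sequence[float],
    *,
    prior: str = "flat",
    n_sims: int = 100_000,
    seed: int = 0,
) -> CorePosterior:
    """Posterior probability ``P(t = M | observed count = n_obs)`` by Monte
    Carlo, under a flat prior on the true presence count t in {1..M}.

    The standard error is the binomial SE of the posterior estimate given the
    number of qualifying simulations; if no simulation produced ``n_obs``
    observed bins, the result is flagged undefined rather than reported as 0.
    """
    return core_posterior_curve(
        completeness, prior=prior, n_sims=n_sims, seed=seed
    )[n_obs]


def core_posterior_curve(
    completeness: Sequence[float],
    *,
    prior: str = "flat",
    n_sims: int = 100_000,
    seed: int = 0,
) -> dict[int, CorePosterior]:
    """:func:`core_posterior` for every observable count 0..M from a single
    simulation batch (one batch keeps the curve internally consistent)."""
    comp = np.asarray(completeness, dtype=float)
    m = len(comp)
    if m == 0:
        raise ConfigError("completeness vector is empty")
    if np.any((comp <= 0) | (comp > 1)):
        raise ConfigError("completeness values must lie in (0, 1]")
    if prior not in ("flat", "all-core"):
        raise ConfigError(f"unknown prior {prior!r}; use 'flat' or 'all-core'")
    if n_sims < 1:
        raise ConfigError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    simulate = (
        _simulate_observed_counts if prior == "flat" else _simulate_observed_counts_all_core
    )
    t, obs = simulate(comp, n_sims, rng)
    out: dict[int, CorePosterior] = {}
    for n in range(m + 1):
        mask = obs == n
        n_qual = int(mask.sum())
        if n_qual == 0:
            prob, se = float("nan"), float("nan")
        else:
            prob = float((t[mask] == m).mean())
            se = float(np.sqrt(prob * (1.0 - prob) / n_qual))
        out[n] = CorePosterior(
            n_obs=n,
            probability=prob,
            std_error=se,
            prior=prior,
            n_sims=n_sims,
            n_qualifying=n_qual,
        )
    return out
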