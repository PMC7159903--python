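"""COG-category composition across gene frequency with a permutation null.

The null model shuffles the category annotation sets across clusters while
every cluster keeps its own frequency, which is equivalent to permuting the
frequency labels. One-sided empirical P values use the add-one correction
``P = (1 + #{sim >= obs}) / (n_perm + 1)``: small values mean a category is
over-represented at a frequency, large values under-represented.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from ._errors import ConfigError, FormatError
from .pangenome import GenomeDendrogram

# one-letter functional categories of the COG scheme, plus N/A for
# unannotated clusters
COG_LETTERS = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
UNANNOTATED = "N/A"


@dataclass
class CategoryProfile:
    """Counts and proportions per (category, frequency).

    ``per_cluster`` keeps the raw cluster-level rows (frequency + category
    tuple) needed by the permutation null. Clusters with multiple categories
    contribute once to each, so proportions at a frequency may sum above 1.
    """

    per_cluster: pd.DataFrame  # cluster_id, frequency, categories (tuple)
    table: pd.DataFrame  # category, frequency, count, proportion
    categories: list[str]
    n_bins: int


def _parse_categories(raw: str) -> tuple[str, ...]:
    if raw is None or raw == "" or raw == UNANNOTATED:
        return (UNANNOTATED,)
    letters = tuple(part for part in str(raw).split(";") if part)
    bad = [c for c in letters if c != UNANNOTATED and c not in COG_LETTERS]
    if bad:
        raise FormatError(f"unknown COG category letters: {sorted(set(bad))}")
    return letters


def category_profile(matrix, annotations: Mapping[str, str]) -> CategoryProfile:
    """Build the category-by-frequency profile.

    ``annotations`` maps cluster id to a ``;``-separated string of category
    letters (missing/empty means unannotated). Proportions are taken among
    all clusters at the same frequency.
    """
    freq = matrix.frequency
    rows = []
    for cluster_id, f in freq.items():
        cats = _parse_categories(annotations.get(cluster_id, UNANNOTATED))
        rows.append((cluster_id, int(f), cats))
    per_cluster = pd.DataFrame(rows, columns=["cluster_id", "frequency", "categories"])
    exploded = per_cluster.explode("categories")
    counts = (
        exploded.groupby(["categories", "frequency"]).size().rename("count").reset_index()
    )
    counts = counts.rename(columns={"categories": "category"})
    per_freq_total = per_cluster.groupby("frequency").size()
    counts["proportion"] = counts["count"] / counts["frequency"].map(per_freq_total)
    cats = sorted(counts["category"].unique())
    return CategoryProfile(
        per_cluster=per_cluster, table=counts, categories=cats, n_bins=matrix.n_bins
    )


@dataclass
class EnrichmentMatrix:
    """One-sided empirical P per (category, frequency) cell."""

    pvalues: pd.DataFrame  # categories x frequencies
    n_perm: int
    seed: int | None
    method: str  # "sampled" (add-one corrected) or "exhaustive" (exact)
    scheme: str = "label-shuffle-frequency-fixed"


def _cell_counts(
    cat_idx: np.ndarray, freq_idx: np.ndarray, n_cat: int, n_freq: int
) -> np.ndarray:
    return np.bincount(cat_idx * n_freq + freq_idx, minlength=n_cat * n_freq).reshape(
        n_cat, n_freq
    )


def permutation_enrichment(
    profile: CategoryProfile,
    n_perm: int,
    seed: int | None = None,
    *,
    method: str = "sampled",
) -> EnrichmentMatrix:
    """Permutation P values for every (category, frequency) cell.

    ``method="sampled"`` draws ``n_perm`` random permutations and applies the
    add-one correction; ``method="exhaustive"`` enumerates every permutation
    of the cluster labels (only feasible for a handful of clusters) and
    returns the exact permutation P including the identity.
    """
    per_cluster = profile.per_cluster
    freqs = sorted(per_cluster["frequency"].unique())
    freq_pos = {f: i for i, f in enumerate(freqs)}
    cat_pos = {c: i for i, c in enumerate(profile.categories)}
    n_cat, n_freq = len(cat_pos), len(freq_pos)

    # flatten annotations: one row per (cluster, category) pair
    cluster_of = []
    cat_idx = []
    for row_i, cats in enumerate(per_cluster["categories"]):
        for c in cats:
            cluster_of.append(row_i)
            cat_idx.append(cat_pos[c])
    cluster_of = np.asarray(cluster_of)
    cat_idx = np.asarray(cat_idx)
    freq_of_cluster = per_cluster["frequency"].map(freq_pos).to_numpy()

    observed = _cell_counts(cat_idx, freq_of_cluster[cluster_of], n_cat, n_freq)

    n_clusters = len(per_cluster)
    if method == "exhaustive":
        if n_clusters > 8:
            raise ConfigError("exhaustive enumeration limited to <= 8 clusters")
        ge = np.zeros_like(observed)
        total = 0
        for perm in itertools.permutations(range(n_clusters)):
            perm = np.asarray(perm)
            sim = _cell_counts(
                cat_idx, freq_of_cluster[perm][cluster_of], n_cat, n_freq
            )
            ge += sim >= observed
            total += 1
        pvals = ge / total
        n_perm = total
    elif method == "sampled":
        if n_perm < 99:
            raise ConfigError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        ge = np.zeros_like(observed)
        for _ in range(n_perm):
            perm = rng.permutation(n_clusters)
            sim = _cell_counts(
                cat_idx, freq_of_cluster[perm][cluster_of], n_cat, n_freq
            )
            ge += sim >= observed
        pvals = (1 + ge) / (n_perm + 1)
    else:
        raise ConfigError(f"unknown method {method!r}")

    pdf = pd.DataFrame(pvals, index=profile.categories, columns=freqs)
    pdf.index.name = "category"
    pdf.columns.name = "frequency"
    return EnrichmentMatrix(pvalues=pdf, n_perm=n_perm, seed=seed, method=method)


def category_cluster_dendrogram(enrichment: EnrichmentMatrix) -> GenomeDendrogram:
    """Average-linkage tree of categories on Euclidean distance between their
    P-value profiles across frequencies."""
    pv = enrichment.pvalues.sort_index()
    if pv.shape[0] < 2:
        raise ConfigError("need at least 2 categories to build a dendrogram")
    z = linkage(pdist(pv.to_numpy(), metric="euclidean"), method="average")
    return GenomeDendrogram(linkage_matrix=z, ids=list(pv.index))


def frequency_band_test(
    profile: CategoryProfile,
    band_a: Sequence[int],
    band_b: Sequence[int],
    category: str,
) -> tuple[float, float]:
    """Welch two-sided t-test comparing a category's per-frequency proportions
    between two disjoint frequency bands (frequencies in a band with no
    clusters at all are skipped; a frequency with clusters but none in the
    category contributes a 0 proportion)."""
    band_a, band_b = set(band_a), set(band_b)
    if band_a & band_b:
        raise ConfigError("frequency bands must be disjoint")
    present = set(profile.per_cluster["frequency"].unique())
    sub = profile.table[profile.table["category"] == category].set_index("frequency")

    def proportions(band):
        usable = sorted(band & present)
        return np.array(
            [sub["proportion"].get(f, 0.0) for f in usable]
        )

    a, b = proportions(band_a), proportions(band_b)
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("each band needs at least 2 represented frequencies")
    return welch_ttest(a, b)


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch two-sided t-test; degenerate equal-constant samples give (0, 1)."""
    if np.var(a) == 0.0 and np.var(b) == 0.0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
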