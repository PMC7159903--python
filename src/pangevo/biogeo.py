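"""Binomial-CDF biogeographic enrichment of gene clusters between two sites.

For a cluster found in ``N`` genome bins of which ``k`` come from site 1, the
enrichment score is the inclusive lower-tail binomial CDF ``P(X <= k)`` with
``X ~ Binomial(N, p)``, where ``p`` is the expected site-1 proportion (the
fraction of bins from site 1; 13/22 on the two-site design this defaults to).
Scores near 0 mean the cluster is depleted at site 1 (enriched at site 2);
scores near 1 mean the opposite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigError, DomainError

CALL_NONE = "none"
CALL_SITE1 = "site1_enriched"
CALL_SITE2 = "site2_enriched"


def binom_cdf(k: int, n: int, p: float) -> float:
    """Inclusive lower-tail binomial CDF ``P(X <= k)``, ``X ~ Binomial(n, p)``.

    Exact to at least 8 significant digits.

    Raises
    ------
    DomainError
        If ``k`` and ``n`` are not integers with ``0 <= k <= n``.
    ConfigError
        If ``p`` is outside the open interval (0, 1).
    """
    if int(k) != k or int(n) != n:
        raise DomainError(f"k and n must be integers, got k={k!r} n={n!r}")
    k, n = int(k), int(n)
    if n < 0 or k < 0 or k > n:
        raise DomainError(f"require 0 <= k <= n, got k={k} n={n}")
    if not 0.0 < p < 1.0:
        raise ConfigError(f"p must lie in (0, 1), got {p}")
    return float(stats.binom.cdf(k, n, p))


@dataclass
class BiogeoResult:
    """Scored clusters plus the inclusion bookkeeping."""

    scores: pd.DataFrame  # cluster_id, n_total, k_site1, p, cdf, call
    n_excluded: int
    p: float
    cdf_lo: float
    cdf_hi: float
    site1: str
    site2: str


def score_clusters(
    matrix,
    site_labels: Mapping[str, str],
    *,
    site1: str = "Axial",
    site2: str = "MCR",
    p: float | None = None,
    min_site1: int = 12,
    min_site2: int = 7,
    cdf_lo: float = 0.05,
    cdf_hi: float = 0.95,
    add_bh: bool = False,
) -> BiogeoResult:
    """Score every cluster passing the inclusion filter.

    A cluster is included when it is observed in at least ``min_site2`` site-2
    bins or at least ``min_site1`` site-1 bins (a cluster passing both counts
    once). ``p`` defaults to ``n_site1 / (n_site1 + n_site2)`` computed from
    the labels of the matrix's bins.

    Parameters
    ----------
    matrix:
        A :class:`~pangevo.pangenome.PresenceAbsenceMatrix`.
    site_labels:
        Mapping bin id -> site label; must cover every bin with one of the
        two site names.
    add_bh:
        Optionally append a Benjamini–Hochberg-adjusted column for the folded
        two-sided p-value (off by default; raw CDF cutoffs are the primary
        calls).
    """
    occupancy = matrix.occupancy
    bins = list(occupancy.columns)
    labels = {}
    for b in bins:
        if b not in site_labels:
            raise ConfigError(f"bin {b!r} has no site label")
        if site_labels[b] not in (site1, site2):
            raise ConfigError(
                f"bin {b!r} has unknown site label {site_labels[b]!r}; "
                f"expected {site1!r} or {site2!r}"
            )
        labels[b] = site_labels[b]
    site1_bins = [b for b in bins if labels[b] == site1]
    site2_bins = [b for b in bins if labels[b] == site2]
    if not site1_bins or not site2_bins:
        raise ConfigError("both site groups must be present among the bins")
    if p is None:
        p = len(site1_bins) / len(bins)
    if not 0.0 < p < 1.0:
        raise ConfigError(f"p must lie in (0, 1), got {p}")
    if not (0 < cdf_lo < cdf_hi < 1):
        raise ConfigError(f"invalid CDF cutoffs ({cdf_lo}, {cdf_hi})")

    k1 = occupancy[site1_bins].sum(axis=1)
    k2 = occupancy[site2_bins].sum(axis=1)
    included = (k2 >= min_site2) | (k1 >= min_site1)
    n_excluded = int((~included).sum())
    k = k1[included].astype(int)
    n = (k1 + k2)[included].astype(int)
    cdf = stats.binom.cdf(k.to_numpy(), n.to_numpy(), p)
    call = np.where(cdf > cdf_hi, CALL_SITE1, np.where(cdf < cdf_lo, CALL_SITE2, CALL_NONE))
    scores = pd.DataFrame(
        {
            "cluster_id": k.index,
            "n_total": n.to_numpy(),
            "k_site1": k.to_numpy(),
            "p": p,
            "cdf": cdf,
            "call": call,
        }
    ).reset_index(drop=True)
    if add_bh:
        folded = 2.0 * np.minimum(scores["cdf"], 1.0 - scores["cdf"]).clip(upper=0.5)
        scores["bh_q"] = _bh_adjust(folded.to_numpy())
    return BiogeoResult(
        scores=scores,
        n_excluded=n_excluded,
        p=p,
        cdf_lo=cdf_lo,
        cdf_hi=cdf_hi,
        site1=site1,
        site2=site2,
    )


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out


def category_cdf_ttest(
    scores: pd.DataFrame,
    categories: Mapping[str, tuple[str, ...]],
    category: str,
    *,
    mode: str = "two-sample",
    null_value: float = 0.5,
) -> tuple[float, float]:
    """Welch two-sided t-test of CDF scores for one COG category.

    ``mode="two-sample"`` (default) compares clusters carrying the category
    against all other scored clusters; ``mode="one-sample"`` tests the
    category's scores against ``null_value``.

    Raises
    ------
    ConfigError
        If the category is absent from the scored set or a group is too small.
    """
    in_cat = scores["cluster_id"].map(
        lambda c: category in categories.get(c, ())
    )
    inside = scores.loc[in_cat, "cdf"].to_numpy()
    outside = scores.loc[~in_cat, "cdf"].to_numpy()
    if len(inside) < 2:
        raise ConfigError(f"category {category!r}: fewer than 2 scored clusters")
    if mode == "one-sample":
        t, p = stats.ttest_1samp(inside, null_value)
    elif mode == "two-sample":
        if len(outside) < 2:
            raise ConfigError("fewer than 2 scored clusters outside the category")
        from .enrichment import welch_ttest

        return welch_ttest(inside, outside)
    else:
        raise ConfigError(f"unknown mode {mode!r}")
    return float(t), float(p)
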