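"""Independent brute-force oracles used to pin the package's statistics.

Everything here is written from first principles (exact rational arithmetic,
exhaustive enumeration, its own genetic-code table) and deliberately shares
no code path with the package.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

# ---------------------------------------------------------------------------
# standard genetic code, written out independently (TCAG ordering)
_BASES_TCAG = "TCAG"
_AA_STRING = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODE = {
    a + b + c: _AA_STRING[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES_TCAG)
    for j, b in enumerate(_BASES_TCAG)
    for k, c in enumerate(_BASES_TCAG)
}


def binom_cdf_oracle(k: int, n: int, p: Fraction) -> Fraction:
    """Exact inclusive lower-tail binomial CDF by term-wise summation."""
    p = Fraction(p)
    return sum(
        Fraction(math.comb(n, i)) * p**i * (1 - p) ** (n - i) for i in range(k + 1)
    )


def poisson_cdf_oracle(x: int, mu: float) -> float:
    """Inclusive lower-tail Poisson CDF: exact rational partial sum times
    exp(-mu)."""
    if mu == 0.0:
        return 1.0
    mu_frac = Fraction(mu).limit_denominator(10**12)
    partial = sum(mu_frac**i / Fraction(math.factorial(i)) for i in range(x + 1))
    return math.exp(-float(mu_frac)) * float(partial)


# ---------------------------------------------------------------------------
# pN/pS by exhaustive single-nucleotide mutant enumeration


def potential_sites_oracle(codon: str) -> tuple[Fraction, Fraction]:
    aa = CODE[codon]
    assert aa != "*"
    syn = Fraction(0)
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if CODE[mutant] == aa:
                syn += Fraction(1, 3)
    return syn, Fraction(3) - syn


def pnps_oracle(sequence: str, variants) -> dict:
    """Exact-rational pN/pS. ``variants``: (codon_index, ref, alt, full_cov)
    tuples. Conventions: stop-introducing or multi-nucleotide changes are
    excluded; reference stop codons contribute no sites; partial-coverage
    records are dropped."""
    codons = [sequence[i : i + 3] for i in range(0, len(sequence), 3)]
    s_pot = Fraction(0)
    n_pot = Fraction(0)
    for codon in codons:
        if CODE[codon] == "*":
            continue
        s, n = potential_sites_oracle(codon)
        s_pot += s
        n_pot += n
    s_obs = n_obs = excluded = 0
    for idx, ref, alt, full_cov in variants:
        if not full_cov:
            continue
        diff = sum(a != b for a, b in zip(ref, alt))
        if diff > 1 or CODE[alt] == "*":
            excluded += 1
        elif CODE[ref] == CODE[alt]:
            s_obs += 1
        else:
            n_obs += 1
    result = {
        "s_obs": s_obs,
        "n_obs": n_obs,
        "s_pot": s_pot,
        "n_pot": n_pot,
        "excluded": excluded,
    }
    if s_obs + n_obs == 0:
        result["status"] = "nonpolymorphic"
    elif s_obs == 0:
        result["status"] = "undefined_no_syn"
    else:
        result["status"] = "ok"
        result["ratio"] = (Fraction(n_obs) / n_pot) / (Fraction(s_obs) / s_pot)
    return result


# ---------------------------------------------------------------------------
# exact completeness-aware core posterior (enumeration / DP, no sampling)


def core_posterior_oracle(completeness) -> np.ndarray:
    """P(t = M | observed = n) for n = 0..M under a flat prior on t in
    {1..M}, a uniform subset of size t, and Bernoulli detection.

    DP over bins tracking (members chosen, members detected); averaging over
    subsets uses the binomial coefficient normalizer.
    """
    comp = list(map(Fraction, map(lambda c: Fraction(c).limit_denominator(10**9), completeness)))
    m = len(comp)
    # f[j][n] = sum over ways of choosing j members among processed bins of
    # P(n of them detected)
    f = [[Fraction(0)] * (m + 1) for _ in range(m + 1)]
    f[0][0] = Fraction(1)
    for c in comp:
        g = [[Fraction(0)] * (m + 1) for _ in range(m + 1)]
        for j in range(m + 1):
            for n in range(j + 1):
                v = f[j][n]
                if v == 0:
                    continue
                g[j][n] += v  # bin not a member
                if j + 1 <= m:
                    g[j + 1][n] += v * (1 - c)  # member, missed
                    g[j + 1][n + 1] += v * c  # member, detected
        f = g
    # P(obs = n | t) = f[t][n] / C(m, t); joint with flat prior over t
    joint_t_m = [Fraction(0)] * (m + 1)
    joint_all = [Fraction(0)] * (m + 1)
    for t in range(1, m + 1):
        norm = Fraction(math.comb(m, t))
        for n in range(m + 1):
            contrib = f[t][n] / norm / m
            joint_all[n] += contrib
            if t == m:
                joint_t_m[n] += contrib
    out = np.full(m + 1, np.nan)
    for n in range(m + 1):
        if joint_all[n] > 0:
            out[n] = float(joint_t_m[n] / joint_all[n])
    return out


# ---------------------------------------------------------------------------
# brute-force average linkage on a small distance matrix


def average_linkage_oracle(dist: np.ndarray, labels):
    """Naive agglomeration; returns list of (frozenset_a, frozenset_b, height)
    merges. Distances between groups are unweighted averages of the original
    pairwise distances (UPGMA on the full matrix)."""
    clusters = [frozenset([l]) for l in labels]
    pos = {l: i for i, l in enumerate(labels)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = np.mean([dist[pos[x], pos[y]] for x in a for y in b])
            key = (d, tuple(sorted(a)), tuple(sorted(b)))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        merges.append((a, b, d))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges


def welch_oracle(a, b) -> tuple[float, float]:
    """Closed-form Welch t statistic and two-sided P (Satterthwaite df)."""
    from scipy import stats as ss

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * ss.t.sf(abs(t), df)
    return t, p


def exact_ranksum_p(a, b) -> float:
    """Exact two-sided rank-sum P by enumerating all group assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = _rankdata(pooled)
    obs = sum(ranks[: n_a])
    stats_all = []
    for idx in itertools.combinations(range(len(pooled)), n_a):
        stats_all.append(sum(ranks[i] for i in idx))
    stats_all = np.array(stats_all)
    mean = stats_all.mean()
    return float(np.mean(np.abs(stats_all - mean) >= abs(obs - mean) - 1e-12))


def _rankdata(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks
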