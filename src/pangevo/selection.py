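"""Per-ORF pN/pS from single-codon variants.

The statistic is polymorphism-based: observed synonymous and nonsynonymous
variant counts are normalized by the *potential* number of synonymous and
nonsynonymous single-nucleotide changes of the reference coding sequence
(equal-weight, Nei–Gojobori-style site counting).

Conventions (fixed and recorded in output metadata):

* potential sites: each of the 9 single-nucleotide mutants of a sense codon
  is classified by amino-acid identity; mutants that create a stop codon
  count as nonsynonymous, so every sense codon contributes exactly 3 sites;
* observed variants: codon changes touching more than one nucleotide, or
  introducing a stop codon, are excluded from the counts and tallied in a
  diagnostics column;
* reference stop codons are skipped (with a warning) and contribute no sites;
* an ORF with no admitted variant is ``nonpolymorphic``; an ORF with
  nonsynonymous but no synonymous variants has an undefined (not infinite)
  ratio, status ``undefined_no_syn``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy import stats

from ._errors import ConfigError, DomainError, IntegrityError

log = logging.getLogger(__name__)

BASES = "ACGT"

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
EXCLUDED = "excluded"

STATUS_OK = "ok"
STATUS_UNDEFINED = "undefined_no_syn"
STATUS_NONPOLYMORPHIC = "nonpolymorphic"


def _codon_to_aa(code: int) -> Mapping[str, str]:
    table = unambiguous_dna_by_id[code]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@lru_cache(maxsize=None)
def _aa_table(code: int) -> Mapping[str, str]:
    return _codon_to_aa(code)


def translate_codon(codon: str, code: int = 1) -> str:
    """Amino acid (one letter, ``*`` for stop) of a codon under a genetic code."""
    _validate_codon(codon)
    return _aa_table(code)[codon]


def _validate_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise DomainError(f"invalid codon {codon!r}: expected a 3-mer over ACGT")


@lru_cache(maxsize=None)
def potential_sites(codon: str, code: int = 1) -> tuple[Fraction, Fraction]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each codon position contributes ``(# synonymous single-nt mutants)/3``
    synonymous sites; the remainder (including mutational paths to stop
    codons) is nonsynonymous, so the two counts always sum to 3.

    Returns
    -------
    (syn_sites, nonsyn_sites) as exact :class:`~fractions.Fraction` values.

    Raises
    ------
    DomainError
        If the codon is not a 3-mer over ACGT or is a stop codon.
    """
    _validate_codon(codon)
    aa = _aa_table(code)[codon]
    if aa == "*":
        raise DomainError(f"{codon} is a stop codon and has no defined sites")
    syn = Fraction(0)
    for pos in range(3):
        n_syn = sum(
            1
            for base in BASES
            if base != codon[pos]
            and _aa_table(code)[codon[:pos] + base + codon[pos + 1 :]] == aa
        )
        syn += Fraction(n_syn, 3)
    return syn, Fraction(3) - syn


@lru_cache(maxsize=None)
def classify_variant(ref_codon: str, alt_codon: str, code: int = 1) -> str:
    """Classify a codon change as synonymous, nonsynonymous, or excluded.

    Changes touching more than one nucleotide, or introducing a stop codon,
    are excluded (tallied separately downstream). Identical codons violate
    the variant-record invariant and raise.
    """
    _validate_codon(ref_codon)
    _validate_codon(alt_codon)
    if ref_codon == alt_codon:
        raise DomainError(f"variant with identical codons {ref_codon}")
    if sum(a != b for a, b in zip(ref_codon, alt_codon)) > 1:
        return EXCLUDED
    if _aa_table(code)[alt_codon] == "*":
        return EXCLUDED
    if _aa_table(code)[ref_codon] == _aa_table(code)[alt_codon]:
        return SYNONYMOUS
    return NONSYNONYMOUS


@dataclass(frozen=True)
class OrfSequence:
    """An in-frame coding sequence for one ORF."""

    orf_id: str
    sequence: str
    code: int = 1

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 3 or len(seq) % 3:
            raise DomainError(
                f"ORF {self.orf_id}: length {len(seq)} not a positive multiple of 3"
            )
        if any(b not in BASES for b in seq):
            raise DomainError(f"ORF {self.orf_id}: non-ACGT characters in sequence")

    @property
    def codons(self) -> list[str]:
        return [self.sequence[i : i + 3] for i in range(0, len(self.sequence), 3)]

    @property
    def internal_stops(self) -> list[int]:
        """Indices of stop codons before the final codon (flagged, not fatal)."""
        table = _aa_table(self.code)
        return [i for i, c in enumerate(self.codons[:-1]) if table[c] == "*"]


@dataclass(frozen=True)
class CodonVariant:
    """A single-codon variant observed against a reference ORF."""

    orf_id: str
    codon_index: int
    ref_codon: str
    alt_codon: str
    full_codon_coverage: bool = True

    def __post_init__(self):
        _validate_codon(self.ref_codon)
        _validate_codon(self.alt_codon)
        if self.ref_codon == self.alt_codon:
            raise DomainError(
                f"{self.orf_id}[{self.codon_index}]: alternate equals reference codon"
            )


@dataclass
class PnPsResult:
    """Observed/potential counts and the pN/pS ratio (or status) for one ORF."""

    orf_id: str
    n_obs: int
    s_obs: int
    n_pot: float
    s_pot: float
    pn: float
    ps: float
    ratio: float  # NaN unless status == "ok"
    status: str
    n_excluded: int = 0


def pnps(
    orf: OrfSequence,
    variants: Iterable[CodonVariant],
    *,
    require_full_coverage: bool = True,
) -> PnPsResult:
    """Compute pN/pS for one ORF from its single-codon variants.

    Parameters
    ----------
    orf:
        Reference coding sequence.
    variants:
        Codon variant records for this ORF. Records without full codon
        coverage are dropped when ``require_full_coverage`` is set.

    Raises
    ------
    IntegrityError
        If a variant belongs to another ORF or its codon index falls outside
        the reference sequence.
    """
    codons = orf.codons
    table = _aa_table(orf.code)
    s_pot = Fraction(0)
    n_pot = Fraction(0)
    n_stop_ref = 0
    for codon in codons:
        if table[codon] == "*":
            n_stop_ref += 1
            continue
        s, n = potential_sites(codon, orf.code)
        s_pot += s
        n_pot += n
    if n_stop_ref:
        log.warning("ORF %s: %d reference stop codon(s) excluded", orf.orf_id, n_stop_ref)

    n_obs = s_obs = n_excluded = 0
    for var in variants:
        if var.orf_id != orf.orf_id:
            raise IntegrityError(
                f"variant for {var.orf_id} passed to ORF {orf.orf_id}"
            )
        if var.codon_index < 0 or var.codon_index >= len(codons):
            raise IntegrityError(
                f"{orf.orf_id}: codon index {var.codon_index} outside ORF "
                f"({len(codons)} codons)"
            )
        if require_full_coverage and not var.full_codon_coverage:
            continue
        kind = classify_variant(var.ref_codon, var.alt_codon, orf.code)
        if kind == SYNONYMOUS:
            s_obs += 1
        elif kind == NONSYNONYMOUS:
            n_obs += 1
        else:
            n_excluded += 1

    pn = n_obs / float(n_pot) if n_pot else float("nan")
    ps = s_obs / float(s_pot) if s_pot else float("nan")
    if n_obs + s_obs == 0:
        status, ratio = STATUS_NONPOLYMORPHIC, float("nan")
    elif s_obs == 0:
        status, ratio = STATUS_UNDEFINED, float("nan")
    else:
        status, ratio = STATUS_OK, pn / ps
    return PnPsResult(
        orf_id=orf.orf_id,
        n_obs=n_obs,
        s_obs=s_obs,
        n_pot=float(n_pot),
        s_pot=float(s_pot),
        pn=pn,
        ps=ps,
        ratio=ratio,
        status=status,
        n_excluded=n_excluded,
    )


def pnps_table(
    sequences: Mapping[str, str],
    codon_variants: pd.DataFrame,
    *,
    code: int = 1,
    require_full_coverage: bool = True,
) -> pd.DataFrame:
    """Vector form of :func:`pnps` over a whole dataset.

    ``codon_variants`` columns: ``gene_id``, ``codon_index``, ``ref_codon``,
    ``alt_codon``, ``full_codon_coverage``. Every ORF in ``sequences`` is
    reported, including nonpolymorphic ones (status column tells them apart).
    """
    by_gene: dict[str, list[CodonVariant]] = {}
    for row in codon_variants.itertuples(index=False):
        if row.gene_id not in sequences:
            raise IntegrityError(f"codon variant references unknown ORF {row.gene_id}")
        by_gene.setdefault(row.gene_id, []).append(
            CodonVariant(
                orf_id=row.gene_id,
                codon_index=int(row.codon_index),
                ref_codon=row.ref_codon,
                alt_codon=row.alt_codon,
                full_codon_coverage=bool(row.full_codon_coverage),
            )
        )
    rows = []
    for gene_id, seq in sequences.items():
        res = pnps(
            OrfSequence(gene_id, seq, code),
            by_gene.get(gene_id, ()),
            require_full_coverage=require_full_coverage,
        )
        rows.append(vars(res))
    out = pd.DataFrame(rows)
    return out.rename(columns={"orf_id": "gene_id"})


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    # exact null distribution (no tie correction) for small samples, normal
    # approximation otherwise
    method = "exact" if len(a) + len(b) <= 40 else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def pnps_group_stats(
    ratios: pd.Series,
    groups: pd.Series,
    *,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Per-group mean/SD of finite pN/pS ratios plus a two-sided rank-sum test
    of each group against its complement.

    Groups with fewer than ``min_group_size`` finite ratios are skipped with a
    notice. ``ratios`` and ``groups`` must be aligned on the same index.
    """
    if not ratios.index.equals(groups.index):
        raise ConfigError("ratios and groups must share an index")
    finite = ratios[np.isfinite(ratios)]
    groups = groups.loc[finite.index]
    rows = []
    values = finite.to_numpy()
    for name, members in finite.groupby(groups):
        if len(members) < min_group_size:
            log.info("group %r skipped: only %d finite ratios", name, len(members))
            continue
        inside = members.to_numpy()
        mask = np.ones(len(values), dtype=bool)
        indexer = finite.index.get_indexer(members.index)
        mask[indexer] = False
        complement = values[mask]
        p = _ranksum_p(inside, complement) if len(complement) >= min_group_size else float("nan")
        rows.append(
            {
                "group": name,
                "n": len(inside),
                "mean": float(np.mean(inside)),
                "sd": float(np.std(inside, ddof=1)) if len(inside) > 1 else float("nan"),
                "p_vs_rest": p,
            }
        )
    return pd.DataFrame(rows)
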