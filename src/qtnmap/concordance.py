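"""Marker-QTL concordance classification and its exact chance-probability model.

A candidate polymorphism is fully concordant with a QTL when (1) every sire
homozygous for the QTL is homozygous at the marker, (2) every sire
heterozygous for the QTL is heterozygous at the marker, and (3) all doubly
heterozygous sires carry the same marker allele in coupling with the
favorable QTL allele.  Concordance across a panel of patriarchs is evidence
that the marker is the causal nucleotide (or tightly linked to it), provided
the probability of the observed configuration arising by chance — for a
marker segregating independently of the QTL — is small.

Null model.  Let p be the marker allele frequency and q = 1 - p, with
sire genotypes independent and chromosomes drawn at random.  Then a
QTL-homozygous sire is marker-homozygous with probability p^2 + q^2, and a
QTL-heterozygous sire is marker-heterozygous *with a designated linkage
phase* with probability pq (half of 2pq).  The probability of the exact
configuration "all n_hom QTL-homozygous sires marker-homozygous, all n_het
QTL-heterozygous sires marker-heterozygous, exactly k of them carrying the
designated phase" is

    P = (p^2 + q^2)^n_hom * C(n_het, k) * (pq)^n_het.

With p = 0.5, n_hom = n_het = 5, k = 4 this gives 0.5^5 * 5 * 0.25^5
= 1.5259e-4, and over m independently tested markers the expected number
showing the configuration is m * P.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, PhaseAssignment, SirePanel, QtlStatus, UNKNOWN
from .errors import DomainError, ValidationError


@dataclass(frozen=True)
class ConcordanceConfig:
    """Counts describing one marker's concordance configuration.

    ``k_phase_correct`` counts, among the doubly heterozygous sires with
    known phase, those whose linked marker allele equals the majority linked
    allele; ``p`` is the marker allele frequency used by the null model.
    """

    n_hom: int
    n_het: int
    n_hom_match: int
    n_het_match: int
    k_phase_correct: int
    p: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_hom_match <= self.n_hom):
            raise DomainError("need 0 <= n_hom_match <= n_hom")
        if not (0 <= self.k_phase_correct <= self.n_het_match <= self.n_het):
            raise DomainError("need 0 <= k_phase_correct <= n_het_match <= n_het")


class Classification(enum.Enum):
    FULL = "FULL"
    PHASE_PARTIAL = "PHASE_PARTIAL"
    STATE_PARTIAL = "STATE_PARTIAL"
    NONE = "NONE"
    SKIPPED_MISSING = "SKIPPED_MISSING"


_CLASS_RANK = {
    Classification.FULL: 0,
    Classification.PHASE_PARTIAL: 1,
    Classification.STATE_PARTIAL: 2,
    Classification.NONE: 3,
    Classification.SKIPPED_MISSING: 4,
}


@dataclass
class ConcordanceResult:
    snp_id: str
    config: ConcordanceConfig | None
    classification: Classification
    chance_probability: float | None
    position_bp: int = 0
    phase_tie: bool = False

    @property
    def n_concordant_families(self) -> int:
        """Families satisfying their concordance condition: state match for
        QTL-homozygous sires, state match plus majority phase for
        QTL-heterozygous sires."""
        if self.config is None:
            return 0
        c = self.config
        return c.n_hom_match + c.k_phase_correct


def configuration_probability(n_hom: int, n_het: int, n_hom_match: int,
                              n_het_match: int, k_phase_correct: int,
                              p: float) -> float:
    """Null probability of an arbitrary concordance configuration.

    Under marker-QTL independence with marker allele frequency ``p``:
    each QTL-homozygous sire is marker-homozygous w.p. p^2+q^2 (else 2pq);
    each QTL-heterozygous sire is marker-heterozygous with the designated
    phase w.p. pq, with the opposite phase w.p. pq, or marker-homozygous
    w.p. p^2+q^2.  Allows boundary p in [0, 1] for degenerate markers.
    """
    q = 1.0 - p
    hom = p * p + q * q
    return (
        math.comb(n_hom, n_hom_match)
        * hom ** n_hom_match
        * (2 * p * q) ** (n_hom - n_hom_match)
        * math.comb(n_het, n_het_match)
        * hom ** (n_het - n_het_match)
        * math.comb(n_het_match, k_phase_correct)
        * (p * q) ** n_het_match
    )


def concordance_chance_probability(n_hom: int | ConcordanceConfig,
                                   n_het: int | None = None,
                                   k_phase_correct: int | None = None,
                                   p: float | None = None,
                                   *, n_hom_match: int | None = None,
                                   n_het_match: int | None = None) -> float:
    """Exact chance probability of an observed concordance configuration.

    Accepts either a :class:`ConcordanceConfig` or the counts directly; the
    match counts default to the fully state-concordant configuration, giving
    the closed form ``(p^2+q^2)^n_hom * C(n_het, k) * (pq)^n_het``.
    """
    if isinstance(n_hom, ConcordanceConfig):
        cfg = n_hom
    else:
        assert n_het is not None and k_phase_correct is not None and p is not None
        cfg = ConcordanceConfig(
            n_hom=n_hom, n_het=n_het,
            n_hom_match=n_hom if n_hom_match is None else n_hom_match,
            n_het_match=n_het if n_het_match is None else n_het_match,
            k_phase_correct=k_phase_correct, p=p,
        )
    if not (0.0 < cfg.p < 1.0):
        raise DomainError(f"allele frequency p must lie in (0, 1), got {cfg.p}")
    return configuration_probability(cfg.n_hom, cfg.n_het, cfg.n_hom_match,
                                     cfg.n_het_match, cfg.k_phase_correct, cfg.p)


def expected_concordant_count(per_snp_probability: float, n_snps_tested: int) -> float:
    """Expected number of markers reaching a configuration by chance (m * P)."""
    if not (0.0 <= per_snp_probability <= 1.0):
        raise DomainError("probability must lie in [0, 1]")
    if n_snps_tested < 0:
        raise DomainError("n_snps_tested must be >= 0")
    return per_snp_probability * n_snps_tested


def tail_probability(n_hom: int, n_het: int, k_min: int, p: float) -> float:
    """Null probability of full state concordance with designated-phase count
    >= ``k_min`` — the 'this level of concordance or better' tail used by the
    Monte-Carlo calibration check."""
    return sum(
        configuration_probability(n_hom, n_het, n_hom, n_het, k, p)
        for k in range(k_min, n_het + 1)
    )


def classify_snp(panel: SirePanel, snp_id: str,
                 phases: list[PhaseAssignment] | None = None,
                 null_p: float | None = None) -> ConcordanceResult:
    """Classify one marker's concordance with the panel's QTL statuses.

    ``phases`` gives, for doubly heterozygous sires, the marker allele in
    coupling with the favorable QTL allele.  ``k_phase_correct`` is the size
    of the majority phase group (an exact tie takes ceil(n/2) and flags the
    result).  The chance probability of the observed configuration uses
    ``null_p`` when given, else the marker allele frequency estimated from
    the panel's chromosomes.
    """
    j = panel.snp_index(snp_id)
    snp = panel.snps[j]
    g = panel.genotypes[:, j]

    if (g == MISSING).any():
        return ConcordanceResult(snp_id, None, Classification.SKIPPED_MISSING,
                                 None, snp.position_bp)

    het_sires = [s for s, st in zip(panel.sire_ids, panel.qtl_status)
                 if st is QtlStatus.HET]
    n_hom = panel.n_sires - len(het_sires)
    n_het = len(het_sires)
    is_het_marker = {s: int(gi) == 1 for s, gi in zip(panel.sire_ids, g)}
    n_het_match = sum(1 for s in het_sires if is_het_marker[s])
    n_hom_match = sum(1 for s, st in zip(panel.sire_ids, panel.qtl_status)
                      if st is QtlStatus.HOM and not is_het_marker[s])

    phase_tie = False
    k = 0
    if phases:
        linked: list[str] = []
        for ph in phases:
            if ph.sire_id not in panel.sire_ids:
                raise ValidationError(f"phase for unknown sire {ph.sire_id}")
            if ph.linked_allele == UNKNOWN:
                continue
            if ph.linked_allele not in snp.alleles:
                raise ValidationError(
                    f"linked allele {ph.linked_allele!r} not among {snp.alleles}")
            if not is_het_marker[ph.sire_id]:
                raise ValidationError(
                    f"phase assignment for marker-homozygous sire {ph.sire_id}")
            linked.append(ph.linked_allele)
        if linked:
            counts = Counter(linked).most_common()
            if len(counts) == 2 and counts[0][1] == counts[1][1]:
                phase_tie = True
                k = -(-n_het_match // 2)  # ceil
            else:
                k = counts[0][1]

    state_full = n_hom_match == n_hom and n_het_match == n_het
    if state_full and k == n_het_match and not phase_tie:
        cls = Classification.FULL
    elif state_full:
        cls = Classification.PHASE_PARTIAL
    elif n_hom_match == n_hom or n_het_match == n_het:
        cls = Classification.STATE_PARTIAL
    else:
        cls = Classification.NONE

    p = null_p if null_p is not None else panel.allele_frequency(snp_id)
    if null_p is not None and not (0.0 < null_p < 1.0):
        raise DomainError("null_p must lie in (0, 1)")
    cfg = ConcordanceConfig(n_hom, n_het, n_hom_match, n_het_match, k, p)
    prob = configuration_probability(n_hom, n_het, n_hom_match, n_het_match, k, p)
    return ConcordanceResult(snp_id, cfg, cls, prob, snp.position_bp, phase_tie)


def scan_concordance(panel: SirePanel,
                     phases: dict[str, list[PhaseAssignment]] | None = None,
                     region: tuple[int, int] | None = None,
                     null_p: float | None = None) -> list[ConcordanceResult]:
    """Classify every marker (optionally restricted to the half-open
    position interval ``region``) and rank the results.

    Ranking: classification (FULL best), then ascending chance probability,
    then ascending position — fully deterministic.
    """
    if panel.n_sires == 0:
        raise ValidationError("empty panel")
    results = []
    for s in panel.snps:
        if region is not None and not (region[0] <= s.position_bp < region[1]):
            continue
        ph = phases.get(s.snp_id) if phases else None
        results.append(classify_snp(panel, s.snp_id, ph, null_p))
    results.sort(key=lambda r: (
        _CLASS_RANK[r.classification],
        r.chance_probability if r.chance_probability is not None else float("inf"),
        r.position_bp,
    ))
    return results


def results_to_frame(results: list[ConcordanceResult]) -> pd.DataFrame:
    """Ranked results as a DataFrame (the scan's TSV/JSON output schema)."""
    rows = []
    for rank, r in enumerate(results, start=1):
        c = r.config
        rows.append({
            "snp_id": r.snp_id,
            "position_bp": r.position_bp,
            "n_hom_match": c.n_hom_match if c else np.nan,
            "n_het_match": c.n_het_match if c else np.nan,
            "k_phase_correct": c.k_phase_correct if c else np.nan,
            "p_used": c.p if c else np.nan,
            "chance_probability": (r.chance_probability
                                   if r.chance_probability is not None else np.nan),
            "classification": r.classification.value,
            "rank": rank,
        })
    return pd.DataFrame(rows)
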