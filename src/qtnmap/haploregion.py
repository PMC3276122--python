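"""Shared-haplotype detection around an anchor allele, and phase cross-checks.

All chromosomes carrying the favorable allele of a concordant marker are
expected to descend from a common ancestor, and therefore to share an
identical-by-descent segment around the causal site.  The detector collects
every chromosome (haplotype) carrying the anchor allele and extends a region
outward from the anchor SNP, one marker at a time, for as long as *all*
carriers agree on the allele; the maximal unanimous segment is the candidate
region containing the causal nucleotide.  Because the shared alleles may be
common in the population, the same consensus can also appear on non-carrier
chromosomes; :func:`region_exclusivity` counts those.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING_ALLELE, PhasedWindow
from .errors import DomainError, ValidationError


@dataclass
class SharedRegion:
    """Maximal segment on which all anchor-allele carriers are identical.

    Boundaries are reported at SNP positions (inclusive); ``span_bp`` is the
    distance between the outermost shared SNPs, with no extrapolation past
    them.
    """

    anchor_snp_id: str
    anchor_allele: str
    carrier_chromosomes: list[tuple[str, int]]
    left_pos_bp: int
    right_pos_bp: int
    snp_ids_in_region: list[str]
    consensus_alleles: list[str]

    @property
    def span_bp(self) -> int:
        return self.right_pos_bp - self.left_pos_bp

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_chromosomes)


def find_shared_region(window: PhasedWindow, anchor_snp_id: str,
                       anchor_allele: str, *,
                       missing_tolerant: bool = False) -> SharedRegion:
    """Greedy bidirectional unanimity extension from the anchor SNP.

    Carriers are chromosomes, not individuals (a homozygote contributes
    two).  By default a missing allele on any carrier stops extension on
    that side; with ``missing_tolerant`` missing alleles abstain and
    unanimity is judged on the observed alleles (at least one required).
    """
    a = window.snp_index(anchor_snp_id)
    snp = window.snps[a]
    if anchor_allele not in snp.alleles:
        raise DomainError(
            f"anchor allele {anchor_allele!r} is not an allele of {anchor_snp_id} "
            f"{snp.alleles}")

    carriers = [(ind, h) for ind, h, row in window.chromosomes()
                if row[a] == anchor_allele]
    if not carriers:
        raise ValidationError(
            f"no chromosome carries {anchor_allele!r} at {anchor_snp_id}")

    idx = {ind: i for i, ind in enumerate(window.individuals)}
    rows = np.stack([window.haplotypes[idx[ind], h] for ind, h in carriers])

    def unanimous(j: int) -> str | None:
        col = rows[:, j]
        obs = col[col != MISSING_ALLELE]
        if missing_tolerant:
            if obs.size == 0:
                return None
        else:
            if obs.size != col.size:
                return None
        u = np.unique(obs)
        return str(u[0]) if u.size == 1 else None

    left = right = a
    consensus = {a: anchor_allele}
    j = a - 1
    while j >= 0 and (allele := unanimous(j)) is not None:
        consensus[j] = allele
        left = j
        j -= 1
    j = a + 1
    while j < window.n_snps and (allele := unanimous(j)) is not None:
        consensus[j] = allele
        right = j
        j += 1

    span = list(range(left, right + 1))
    return SharedRegion(
        anchor_snp_id=anchor_snp_id,
        anchor_allele=anchor_allele,
        carrier_chromosomes=carriers,
        left_pos_bp=window.snps[left].position_bp,
        right_pos_bp=window.snps[right].position_bp,
        snp_ids_in_region=[window.snps[j].snp_id for j in span],
        consensus_alleles=[consensus[j] for j in span],
    )


def region_exclusivity(window: PhasedWindow, region: SharedRegion
                       ) -> tuple[int, list[tuple[str, int]]]:
    """Non-carrier chromosomes that match the region consensus everywhere
    except at the anchor SNP itself.

    A high count means the shared haplotype is common in the population and
    not exclusive to the anchor allele.  Missing alleles count as
    mismatches.
    """
    try:
        cols = [window.snp_index(s) for s in region.snp_ids_in_region]
    except KeyError as e:
        raise ValidationError(f"region SNP {e.args[0]!r} absent from window") from e
    anchor_col = window.snp_index(region.anchor_snp_id)
    carrier_set = set(region.carrier_chromosomes)

    matches: list[tuple[str, int]] = []
    for ind, h, row in window.chromosomes():
        if (ind, h) in carrier_set:
            continue
        ok = all(row[j] == c for j, c in zip(cols, region.consensus_alleles)
                 if j != anchor_col)
        if ok:
            matches.append((ind, h))
    return len(matches), matches


def phase_conflict_check(a: PhasedWindow, b: PhasedWindow
                         ) -> list[tuple[str, str]]:
    """Compare two independent phasings of the same individuals and SNPs.

    Haplotype pairs are compared up to swap: per individual the pairing of
    a's two haplotypes onto b's that minimizes disagreements is chosen, and
    every SNP still disagreeing under that pairing is reported as a conflict
    (missing alleles agree with anything).  An empty list means the two
    phase sources are consistent.
    """
    if set(a.individuals) != set(b.individuals):
        raise ValidationError("windows cover different individuals")
    ids_a = [(s.snp_id, s.position_bp) for s in a.snps]
    ids_b = [(s.snp_id, s.position_bp) for s in b.snps]
    if ids_a != ids_b:
        raise ValidationError("windows cover different SNPs")

    bidx = {ind: i for i, ind in enumerate(b.individuals)}
    conflicts: list[tuple[str, str]] = []
    for i, ind in enumerate(a.individuals):
        ha = a.haplotypes[i]
        hb = b.haplotypes[bidx[ind]]

        def mismatches(pair_map: tuple[int, int]) -> list[int]:
            out = []
            for j in range(a.n_snps):
                for ka, kb in enumerate(pair_map):
                    x, y = ha[ka, j], hb[kb, j]
                    if MISSING_ALLELE in (x, y):
                        continue
                    if x != y:
                        out.append(j)
                        break
            return out

        direct, swapped = mismatches((0, 1)), mismatches((1, 0))
        best = direct if len(direct) <= len(swapped) else swapped
        conflicts.extend((ind, a.snps[j].snp_id) for j in best)
    return conflicts
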