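"""Bundled worked-example data: the BTA7 fertility fine-mapping panel.

These are the published data of the 10-patriarch Israeli Holstein daughter
design around the intergenic marker NGS-58779 on Bos taurus chromosome 7:
the sires' QTL segregation statuses and NGS-58779 genotypes, their phased
haplotypes over the 20-SNP window flanking the marker (positions printed to
0.01 Mbp and stored as Mbp * 1e6), the marker-QTL linkage phases of the
segregating sires, and the allele-specific amplicon base calls over seven
polymorphic exon-3 sites of the duplicated KIAA1683 gene, from which four
gene variants (V1-V4) are reconstructed.

Everything is constructed programmatically; no external files are read.
"""

from __future__ import annotations

import numpy as np

from .core import PhaseAssignment, PhasedWindow, QtlStatus, SirePanel, SnpInfo
from .variantdecon import SiteCallProfile, VariantSequence

ANCHOR_SNP_ID = "NGS-58779"
FAVORABLE_ALLELE = "A"

# sire -> (NGS-58779 A-dosage, QTL status); "+" = segregating (heterozygous)
_PANEL_ROWS: list[tuple[str, int, str]] = [
    ("3099", 2, "-"),
    ("2357", 2, "-"),
    ("3089", 1, "+"),
    ("3208", 1, "+"),
    ("2278", 1, "+"),
    ("3070", 1, "+"),
    ("3258", 1, "+"),
    ("3241", 0, "-"),
    ("3274", 0, "-"),
    ("2283", 0, "-"),
]


def sire_panel() -> SirePanel:
    """The 10-sire panel at NGS-58779 (4922643 bp, Btau4.0; alleles G/A,
    genotype = A-allele dosage)."""
    snp = SnpInfo(ANCHOR_SNP_ID, "7", 4_922_643, ("G", "A"), assembly="Btau4.0")
    sires = [r[0] for r in _PANEL_ROWS]
    geno = np.array([[r[1]] for r in _PANEL_ROWS], dtype=np.int8)
    statuses = [QtlStatus.parse(r[2]) for r in _PANEL_ROWS]
    return SirePanel(sires, statuses, geno, [snp])


def phase_assignments() -> list[PhaseAssignment]:
    """Marker alleles in coupling with the favorable QTL allele for the five
    segregating sires: "A" for four of them, "G" for sire 3258 (the single
    phase-discordant family)."""
    return [
        PhaseAssignment("2278", "A"),
        PhaseAssignment("3070", "A"),
        PhaseAssignment("3089", "A"),
        PhaseAssignment("3208", "A"),
        PhaseAssignment("3258", "G"),
    ]


#: Number of markers tested for concordance inside the QTL confidence interval.
N_SNPS_TESTED = 704

# Phased haplotypes over the 20-SNP window (Mbp positions, two rows per sire).
_WINDOW_POSITIONS_MBP = [4.43, 4.50, 4.52, 4.59, 4.63, 4.65, 4.67, 4.72, 4.76,
                         4.82, 4.92, 4.96, 5.01, 5.03, 5.06, 5.09, 5.11, 5.14,
                         5.16, 5.20]

_WINDOW_ROWS: list[tuple[str, str, str, str]] = [
    # (sire, status, hap1, hap2)
    ("2278", "+", "GAGGAGAAGGAGGAGGGAAG", "GGCAAGAAGGGGGAGGGAAG"),
    ("3070", "+", "GGGGGGAAGGAAGAAGGAGG", "GGGGGGAAGGGAGAGGGGGG"),
    ("3089", "+", "GGGGGGAAGGAAGGGGCGAG", "GGGGGGAAGAGGGAGGGAAG"),
    ("3208", "+", "GGGGGGAAGGAAGGGGCGAG", "GGGGGGAAGGGGAGAGGAGA"),
    ("3258", "+", "GAGGGGAAGGAGGAGGGGGG", "GGGGGGAAGGGGAGGGGAGG"),
    ("3099", "-", "GGGGGGAAGGAAGGGGCGAG", "GAGGGGAAGGAGGAGGGGGG"),
    ("2357", "-", "GGGGGGAAGGAAGGGGCGAG", "GGGGGGAAGGAGGAGGGGGG"),
    ("2283", "-", "GGGGGGAAGAGGGAGGGAGG", "AGGGGGAAGGGGAGGGCGAG"),
    ("3241", "-", "GGGGGGAAGGGGAGAGGAGG", "AGGGGGAAGGGGAGGGCGGA"),
    ("3274", "-", "GGGGGGAAGGGGAGAGGAGA", "GAGGAGGGGGGGGAGAGAGG"),
]


def phased_window() -> PhasedWindow:
    """Phased haplotypes of the 10 sires over the 20 SNPs flanking NGS-58779.

    SNP IDs are ``bta7_<Mbp>`` except the anchor, which keeps its marker
    name; positions are Mbp * 1e6.
    """
    snps = []
    for j, mbp in enumerate(_WINDOW_POSITIONS_MBP):
        pos = round(mbp * 1_000_000)
        snp_id = ANCHOR_SNP_ID if mbp == 4.92 else f"bta7_{mbp:.2f}"
        col = [row[2][j] for row in _WINDOW_ROWS] + [row[3][j] for row in _WINDOW_ROWS]
        order: list[str] = []
        for x in col:
            if x not in order:
                order.append(x)
        alleles = (order[0], order[1]) if len(order) == 2 else (order[0], "N")
        snps.append(SnpInfo(snp_id, "7", pos, alleles))
    individuals = [row[0] for row in _WINDOW_ROWS]
    hap = np.array([[list(row[2]), list(row[3])] for row in _WINDOW_ROWS],
                   dtype="<U1")
    return PhasedWindow(snps, individuals, hap)


# Allele-specific amplicon base calls over the seven polymorphic exon-3
# sites of the duplicated KIAA1683 gene (positions on the first paralog,
# Btau4.0).  SP1 amplifies the "A" pool at the anchor site, SP2 the "G" pool;
# a two-base cell is a heterogeneous chromatogram peak.
_SITE_POSITIONS = (4856941, 4857096, 4857126, 4857153, 4857165, 4857178, 4857214)

_SP1_MIXED = "A, C/T, C/T, C, C, T/C, G/A"
_SP1_PURE = "A, C, T, C, C, C, A"
_SP2_PURE_V2 = "G, C, C, A, T, C, G"
_CALL_ROWS: list[tuple[str, str, str]] = [
    ("SP1", "2278", _SP1_MIXED),
    ("SP1", "3070", _SP1_MIXED),
    ("SP1", "3089", _SP1_MIXED),
    ("SP1", "3208", _SP1_MIXED),
    ("SP1", "2357", _SP1_MIXED),
    ("SP1", "3099", _SP1_MIXED),
    ("SP1", "3258", _SP1_MIXED),
    ("SP1", "3241", _SP1_PURE),
    ("SP1", "3274", _SP1_PURE),
    ("SP1", "2283", _SP1_PURE),
    ("SP2", "2278", _SP2_PURE_V2),
    ("SP2", "3070", _SP2_PURE_V2),
    ("SP2", "3089", _SP2_PURE_V2),
    ("SP2", "3208", _SP2_PURE_V2),
    ("SP2", "2357", _SP2_PURE_V2),
    ("SP2", "3099", "G, C, C, C/A, T/C, C, G"),
    ("SP2", "3258", "G, C, C, C, C, C, G"),
    ("SP2", "3241", _SP2_PURE_V2),
    ("SP2", "3274", _SP2_PURE_V2),
    ("SP2", "2283", _SP2_PURE_V2),
]


def amplicon_profiles() -> list[SiteCallProfile]:
    """Per-sire base-call profiles of the SP1/SP2 allele-specific amplicons."""
    out = []
    for amp, sire, cells in _CALL_ROWS:
        calls = tuple(frozenset(tok.strip().split("/"))
                      for tok in cells.split(","))
        out.append(SiteCallProfile(amp, sire, _SITE_POSITIONS, calls))
    return out


def known_variants() -> list[VariantSequence]:
    """The four reconstructed KIAA1683 exon-3 variants over the seven sites."""
    return [
        VariantSequence("V1", "ATCCCTG", source="reference"),
        VariantSequence("V2", "GCCATCG", source="reference"),
        VariantSequence("V3", "ACTCCCA", source="reference"),
        VariantSequence("V4", "GCCCCCG", source="deconvolved"),
    ]


def variant_labels() -> dict[str, str]:
    """Base-string -> canonical label map pinning V1..V4 names."""
    return {v.bases: v.label for v in known_variants()}
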