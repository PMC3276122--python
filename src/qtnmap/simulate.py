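"""Synthetic daughter-design and qPCR data with the structure the pipeline assumes.

The generator emulates a half-sib daughter-design study population: a small
pool of founder haplotypes carrying linkage disequilibrium (block-mosaic
copies of a handful of ancestral haplotypes, with mutation), a biallelic
causal site (QTN) embedded in the map, patriarch sires drawn as pairs of
founder haplotypes with their QTL segregation status defined by QTN
heterozygosity, additive breeding values, and qPCR Ct tables generated from
true copy numbers with log-scale noise.  Every draw flows from a single
integer seed, so identical configurations reproduce byte-identical outputs.

Defaults mirror the study design the pipeline targets: 10 patriarchs forced
to a 5 heterozygous / 5 homozygous QTL split, an allele substitution effect
of 0.57 trait units, duplicate qPCR reactions with 0.1-cycle noise, and
~50 kb marker spacing (the density of a 50K bovine SNP chip).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (PhaseAssignment, PhasedWindow, QtlStatus, SirePanel,
                   SnpInfo, BreedingValueTable)
from .cnv_qpcr import QpcrPanel
from .errors import FeasibilityError, ValidationError

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class QpcrConfig:
    """qPCR generator settings: Ct scale, efficiency, noise and replication."""

    base_ct: float = 25.0        # Ct of a single-copy template, cycles
    efficiency: float = 2.0      # fold amplification per cycle
    ct_noise_sd: float = 0.1     # per-replicate Gaussian noise, cycles
    replicates: int = 2
    residual_floor_offset: float = 8.0  # Ct above base for zero-copy samples


@dataclass(frozen=True)
class SimulationConfig:
    n_snps: int = 101
    n_founder_haplotypes: int = 24
    n_ancestral: int = 4
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_length_bp: float = 250_000.0
    snp_spacing_bp: int = 50_000
    start_bp: int = 1_000_000
    chromosome: str = "7"
    mutation_rate: float = 0.01
    qtn_index: int = 50
    qtn_favorable_allele: str = "A"
    allele_substitution_effect: float = 0.57
    polygenic_sd: float = 1.0
    n_sires: int = 10
    status_split: tuple[int, int] | None = (5, 5)  # (n_het, n_hom); None = free
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0 <= self.qtn_index < self.n_snps):
            raise ValidationError("qtn_index out of range")
        if self.status_split is not None and sum(self.status_split) != self.n_sires:
            raise ValidationError("status_split must sum to n_sires")


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated panel, for parameter recovery."""

    founders: np.ndarray              # (n_founders, n_snps) of allele chars
    sire_hap_indices: np.ndarray      # (n_sires, 2) founder indices
    qtl_status: list[QtlStatus]
    snps: list[SnpInfo]
    qtn_index: int
    qtn_favorable_allele: str
    sire_ids: list[str]
    founder_sources: np.ndarray | None = None  # (n_founders, n_snps) ancestor idx
    founder_mutated: np.ndarray | None = None  # (n_founders, n_snps) bool

    def diplotype(self, i: int) -> np.ndarray:
        return self.founders[self.sire_hap_indices[i]]

    def favorable_dosage(self, i: int) -> int:
        d = self.diplotype(i)[:, self.qtn_index]
        return int((d == self.qtn_favorable_allele).sum())

    def linked_allele(self, i: int, snp_index: int) -> str | None:
        """Marker allele on the haplotype carrying the favorable QTN allele
        (QTL-heterozygous sires only)."""
        d = self.diplotype(i)
        fav = d[:, self.qtn_index] == self.qtn_favorable_allele
        if fav.sum() != 1:
            return None
        return str(d[int(np.flatnonzero(fav)[0]), snp_index])

    def shared_ancestral_segment(self, founder_indices: Sequence[int],
                                 around: int) -> tuple[int, int]:
        """Maximal SNP-index run around ``around`` on which the given founder
        haplotypes are identical by descent: copied from the same ancestral
        haplotype with no mutation.  Returns (left_index, right_index),
        inclusive; requires source tracking."""
        if self.founder_sources is None or self.founder_mutated is None:
            raise ValidationError("truth was built without source tracking")
        idx = list(founder_indices)
        src = self.founder_sources[idx]
        mut = self.founder_mutated[idx]

        def shared(j: int) -> bool:
            return bool((src[:, j] == src[0, j]).all() and not mut[:, j].any())

        if not shared(around):
            return around, around - 1  # empty segment
        left = right = around
        while left - 1 >= 0 and shared(left - 1):
            left -= 1
        while right + 1 < src.shape[1] and shared(right + 1):
            right += 1
        return left, right


def _draw_founders(config: SimulationConfig, rng: np.random.Generator
                   ) -> tuple[np.ndarray, list[SnpInfo]]:
    n, m = config.n_founder_haplotypes, config.n_snps
    snps: list[SnpInfo] = []
    pairs = []
    for j in range(m):
        a, b = rng.choice(len(_BASES), size=2, replace=False)
        pair = (_BASES[a], _BASES[b])
        if j == config.qtn_index:
            # favorable allele must be one of the QTN's two alleles
            pair = (config.qtn_favorable_allele,
                    pair[0] if pair[0] != config.qtn_favorable_allele else pair[1])
        pairs.append(pair)
        snps.append(SnpInfo(f"snp{j:04d}" if j != config.qtn_index else "qtn",
                            config.chromosome,
                            config.start_bp + j * config.snp_spacing_bp, pair))

    freqs = rng.uniform(*config.maf_range, size=m)
    ancestral = np.empty((config.n_ancestral, m), dtype="<U1")
    for j in range(m):
        draw = rng.random(config.n_ancestral) < freqs[j]
        ancestral[:, j] = np.where(draw, pairs[j][0], pairs[j][1])

    switch_p = min(1.0, config.snp_spacing_bp / config.ld_block_length_bp)
    founders = np.empty((n, m), dtype="<U1")
    sources = np.empty((n, m), dtype=np.int64)
    mutated = np.zeros((n, m), dtype=bool)
    for i in range(n):
        src = rng.integers(config.n_ancestral)
        for j in range(m):
            if j > 0 and rng.random() < switch_p:
                src = rng.integers(config.n_ancestral)
            allele = ancestral[src, j]
            if rng.random() < config.mutation_rate:
                a, b = pairs[j]
                allele = b if allele == a else a
                mutated[i, j] = True
            founders[i, j] = allele
            sources[i, j] = src
    return founders, snps, sources, mutated


def simulate_panel(config: SimulationConfig
                   ) -> tuple[SirePanel, PhasedWindow,
                              dict[str, list[PhaseAssignment]], SimulationTruth]:
    """Generate a sire panel, its phased window, per-SNP phase assignments
    and the underlying truth.

    Raises :class:`FeasibilityError` if the requested het/hom status split
    cannot be drawn from the founder pool in 10,000 attempts (e.g. the QTN
    became monomorphic among founders).
    """
    rng = np.random.default_rng(config.seed)
    for _ in range(50):
        founders, snps, sources, mutated = _draw_founders(config, rng)
        if len(set(founders[:, config.qtn_index])) == 2:
            break
    else:
        raise FeasibilityError("QTN monomorphic among founders in 50 redraws")

    n = config.n_sires
    want_het = None if config.status_split is None else config.status_split[0]
    for _ in range(10_000):
        hap_idx = rng.integers(config.n_founder_haplotypes, size=(n, 2))
        qtn = founders[hap_idx, config.qtn_index]
        het = qtn[:, 0] != qtn[:, 1]
        if want_het is None or int(het.sum()) == want_het:
            break
    else:
        raise FeasibilityError(
            f"could not draw {want_het} QTL-heterozygous sires in 10,000 attempts")

    sire_ids = [f"sire{i:03d}" for i in range(n)]
    statuses = [QtlStatus.HET if h else QtlStatus.HOM for h in het]
    hap = founders[hap_idx]                     # (n, 2, m)
    counted = np.array([s.alleles[1] for s in snps])
    geno = (hap == counted[None, None, :]).sum(axis=1).astype(np.int8)

    panel = SirePanel(sire_ids, statuses, geno, snps)
    window = PhasedWindow(snps, sire_ids, hap.copy())
    truth = SimulationTruth(founders, hap_idx, statuses, snps,
                            config.qtn_index, config.qtn_favorable_allele,
                            sire_ids, founder_sources=sources,
                            founder_mutated=mutated)

    phases: dict[str, list[PhaseAssignment]] = {}
    for j, s in enumerate(snps):
        lst = []
        for i in range(n):
            if statuses[i] is not QtlStatus.HET or geno[i, j] != 1:
                continue
            la = truth.linked_allele(i, j)
            if la is not None:
                lst.append(PhaseAssignment(sire_ids[i], la))
        phases[s.snp_id] = lst
    return panel, window, phases, truth


def simulate_breeding_values(truth: SimulationTruth, config: SimulationConfig,
                             seed: int | None = None) -> BreedingValueTable:
    """Additive model: bv = effect * favorable-allele dosage + N(0, polygenic_sd)."""
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    out = {}
    for i, sire in enumerate(truth.sire_ids):
        noise = rng.normal(0.0, config.polygenic_sd) if config.polygenic_sd > 0 else 0.0
        out[sire] = (config.allele_substitution_effect * truth.favorable_dosage(i)
                     + noise)
    return BreedingValueTable(out)


def simulate_qpcr(true_copies: dict[str, float], config: SimulationConfig,
                  seed: int | None = None, *, target_probe: str = "target",
                  reference_probe: str = "reference",
                  reference_copies: float = 2.0) -> QpcrPanel:
    """Ct tables from true copy numbers: Ct = base - log_E(copies) + noise.

    The reference probe sees a constant copy number (a non-CNV reference
    gene).  Zero-copy samples produce Ct at a residual floor
    (base_ct + residual_floor_offset), emulating the trace amplification an
    absent variant still yields.
    """
    qc = config.qpcr
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    loge = np.log(qc.efficiency)

    def ct_for(copies: float) -> float:
        if copies < 0:
            raise ValidationError("copy numbers must be >= 0")
        if copies == 0:
            return qc.base_ct + qc.residual_floor_offset
        return qc.base_ct - float(np.log(copies) / loge)

    ct: dict[tuple[str, str], tuple[float, ...]] = {}
    for sample, copies in true_copies.items():
        for probe, c0 in ((target_probe, ct_for(copies)),
                          (reference_probe, ct_for(reference_copies))):
            reps = c0 + rng.normal(0.0, qc.ct_noise_sd, size=qc.replicates) \
                if qc.ct_noise_sd > 0 else np.full(qc.replicates, c0)
            ct[(sample, probe)] = tuple(float(x) for x in reps)
    return QpcrPanel(ct, {target_probe: "target", reference_probe: "reference"},
                     {target_probe: qc.efficiency, reference_probe: qc.efficiency})
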