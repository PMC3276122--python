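"""Shared domain types and tabular I/O for the fine-mapping pipeline.

The pipeline consumes four kinds of input: a panel of patriarch sires with
QTL segregation statuses and biallelic SNP genotypes (the concordance-scan
substrate), phased haplotypes over an ordered SNP window (the
haplotype-sharing substrate), allele-specific amplicon base-call profiles,
and qPCR Ct tables.  This module holds the first two plus breeding values,
and the readers/writers for their on-disk formats.

Genotypes are coded as the number of copies of the SNP's *second* listed
allele (0, 1, 2) with an explicit ``MISSING`` sentinel; the coding is
involution-safe: swapping the allele order maps ``g -> 2 - g`` and leaves
heterozygosity untouched.  Coordinates are 1-based base pairs.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import LookupMissError, ParseError, ValidationError

#: Sentinel for an unobserved genotype (never silently imputed).
MISSING: int = -1

#: Sentinel character for an unobserved haplotype allele.
MISSING_ALLELE: str = "."

#: Sentinel for an unknown linkage phase.
UNKNOWN: str = "?"


class QtlStatus(enum.Enum):
    """QTL segregation status of a patriarch inferred from a daughter design.

    ``HET`` ("+") — the sire segregates for the QTL; ``HOM`` ("−") — it does
    not.
    """

    HET = "+"
    HOM = "-"

    @classmethod
    def parse(cls, token: str) -> "QtlStatus":
        t = token.strip()
        if t in ("+", "HET", "het", "1"):
            return cls.HET
        if t in ("-", "−", "HOM", "hom", "0"):
            return cls.HOM
        raise ValidationError(f"unrecognized QTL status {token!r}")


@dataclass(frozen=True)
class SnpInfo:
    """A biallelic SNP marker with its map position.

    ``alleles`` is an ordered pair; the second entry is the counted allele
    of the genotype coding.  ``assembly`` is a free-text genome-build label.
    """

    snp_id: str
    chromosome: str
    position_bp: int
    alleles: tuple[str, str]
    assembly: str = ""

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValidationError(
                f"SNP {self.snp_id}: position_bp must be >= 1, got {self.position_bp}"
            )
        a, b = self.alleles
        if a == b:
            raise ValidationError(f"SNP {self.snp_id}: alleles must be distinct")
        if len(a) != 1 or len(b) != 1:
            raise ValidationError(f"SNP {self.snp_id}: alleles must be single bases")


@dataclass(frozen=True)
class PhaseAssignment:
    """Marker allele carried on the haplotype bearing the favorable QTL allele.

    Only meaningful for sires heterozygous for both the QTL and the marker;
    ``linked_allele`` may be :data:`UNKNOWN`.
    """

    sire_id: str
    linked_allele: str = UNKNOWN


@dataclass
class SirePanel:
    """Patriarch panel: QTL statuses plus a sire x SNP genotype matrix.

    ``genotypes[i, j]`` counts copies of ``snps[j].alleles[1]`` carried by
    ``sire_ids[i]`` (0/1/2) or is :data:`MISSING`.
    """

    sire_ids: list[str]
    qtl_status: list[QtlStatus]
    genotypes: np.ndarray
    snps: list[SnpInfo]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, m = len(self.sire_ids), len(self.snps)
        if self.genotypes.shape != (n, m):
            raise ValidationError(
                f"genotype matrix shape {self.genotypes.shape} != ({n}, {m})"
            )
        if len(self.qtl_status) != n:
            raise ValidationError("one QTL status required per sire")
        if len(set(self.sire_ids)) != n:
            raise ValidationError("duplicate sire IDs")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != m:
            raise ValidationError("duplicate SNP IDs")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError(f"genotype entries outside {{0,1,2,MISSING}}")

    @property
    def n_sires(self) -> int:
        return len(self.sire_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        for j, s in enumerate(self.snps):
            if s.snp_id == snp_id:
                return j
        raise LookupMissError(snp_id)

    def snp(self, snp_id: str) -> SnpInfo:
        return self.snps[self.snp_index(snp_id)]

    def column(self, snp_id: str) -> np.ndarray:
        return self.genotypes[:, self.snp_index(snp_id)]

    def allele_frequency(self, snp_id: str) -> float:
        """Frequency of the counted (second) allele among non-missing chromosomes."""
        g = self.column(snp_id)
        obs = g[g != MISSING]
        if obs.size == 0:
            raise ValidationError(f"SNP {snp_id}: no observed genotypes")
        return float(obs.sum()) / (2 * obs.size)

    def swap_alleles(self, snp_id: str) -> "SirePanel":
        """Return a panel with the allele order of one SNP reversed (g -> 2-g)."""
        j = self.snp_index(snp_id)
        snps = list(self.snps)
        s = snps[j]
        snps[j] = replace(s, alleles=(s.alleles[1], s.alleles[0]))
        geno = self.genotypes.copy()
        col = geno[:, j]
        flip = col != MISSING
        col[flip] = 2 - col[flip]
        return SirePanel(list(self.sire_ids), list(self.qtl_status), geno, snps)


@dataclass
class PhasedWindow:
    """Phased haplotypes of a set of individuals over an ordered SNP window.

    ``haplotypes`` has shape (n_individuals, 2, n_snps) of single-character
    alleles; the within-individual haplotype order carries no meaning
    (maternal/paternal labels are arbitrary), so all comparisons are made up
    to a swap.
    """

    snps: list[SnpInfo]
    individuals: list[str]
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype="<U1")
        n, m = len(self.individuals), len(self.snps)
        if self.haplotypes.shape != (n, 2, m):
            raise ValidationError(
                f"haplotype array shape {self.haplotypes.shape} != ({n}, 2, {m})"
            )
        if len(set(self.individuals)) != n:
            raise ValidationError("duplicate individual IDs")
        pos = [s.position_bp for s in self.snps]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValidationError("SNP positions must be strictly increasing")
        for j, s in enumerate(self.snps):
            col = self.haplotypes[:, :, j]
            ok = np.isin(col, (*s.alleles, MISSING_ALLELE))
            if not ok.all():
                bad = sorted(set(col[~ok]))
                raise ValidationError(
                    f"SNP {s.snp_id}: alleles {bad} not in {s.alleles}"
                )

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        for j, s in enumerate(self.snps):
            if s.snp_id == snp_id:
                return j
        raise LookupMissError(snp_id)

    def chromosomes(self) -> Iterator[tuple[str, int, np.ndarray]]:
        """Yield (individual, haplotype index in {0,1}, allele row)."""
        for i, ind in enumerate(self.individuals):
            for h in (0, 1):
                yield ind, h, self.haplotypes[i, h]

    def allele(self, individual: str, hap: int, snp_id: str) -> str:
        i = self.individuals.index(individual)
        return str(self.haplotypes[i, hap, self.snp_index(snp_id)])


class BreedingValueTable(dict):
    """Mapping sire_id -> estimated breeding value (trait units)."""

    def __init__(self, values: Mapping[str, float] | None = None):
        super().__init__()
        if values:
            for k, v in values.items():
                self[k] = float(v)
                if not np.isfinite(self[k]):
                    raise ValidationError(f"non-finite breeding value for {k}")


# ---------------------------------------------------------------------------
# Genotype table I/O
#
# Canonical TSV dialect: header  sire_id<TAB>qtl_status<TAB><snp>...
# where a SNP column header is either a bare ID or the annotated form
# ``id:chrom:pos_bp:X/Y`` pinning the map position and allele order.  Cells
# are ``X/Y`` base pairs, ``./.`` for missing.  PLINK ped/map and minimal
# (GT-only) VCF are accepted as conveniences.
# ---------------------------------------------------------------------------


def _parse_snp_header(token: str, ordinal: int) -> SnpInfo | str:
    """Annotated header -> SnpInfo; bare header -> the ID (alleles inferred later)."""
    if ":" not in token:
        return token
    parts = token.split(":")
    if len(parts) not in (4, 5) or "/" not in parts[3]:
        raise ParseError(f"bad SNP column header {token!r}", line=1)
    snp_id, chrom, pos, al = parts[:4]
    a, b = al.split("/")
    assembly = parts[4] if len(parts) == 5 else ""
    return SnpInfo(snp_id, chrom, int(pos), (a, b), assembly=assembly)


def _infer_snp(snp_id: str, ordinal: int, observed: list[str]) -> SnpInfo:
    """Build SnpInfo for a bare-header column from first-appearance allele order."""
    order: list[str] = []
    for a in observed:
        if a not in order and a != MISSING_ALLELE:
            order.append(a)
    if len(order) > 2:
        raise ValidationError(f"SNP {snp_id}: more than two alleles {order}")
    while len(order) < 2:
        order.append("N" if "N" not in order else "M")
    return SnpInfo(snp_id, "NA", ordinal + 1, (order[0], order[1]))


def read_genotype_table(path: str | Path, format_tag: str = "tsv", *,
                        qtl_status: Mapping[str, QtlStatus | str] | None = None
                        ) -> SirePanel:
    """Read a sire genotype panel from TSV, PLINK ped/map, or minimal VCF.

    Parameters
    ----------
    path
        Input file (for ``ped_map``: the ``.ped`` file or the shared prefix;
        the ``.map`` must sit next to it).
    format_tag
        One of ``tsv``, ``ped_map``, ``vcf``.
    qtl_status
        Required for ``vcf`` (VCF carries no status field): mapping
        sire -> status ("+"/"-" or :class:`QtlStatus`).
    """
    path = Path(path)
    if not path.exists() and format_tag != "ped_map":
        raise FileNotFoundError(path)
    if format_tag == "tsv":
        return _read_tsv(path)
    if format_tag == "ped_map":
        return _read_ped_map(path)
    if format_tag == "vcf":
        return _read_vcf(path, qtl_status)
    raise ValidationError(f"unknown format_tag {format_tag!r}")


def _read_tsv(path: Path) -> SirePanel:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ParseError(f"{path}: empty file", line=1)
    header = rows[0]
    if header[:2] != ["sire_id", "qtl_status"]:
        raise ParseError(f"{path}: header must start with sire_id, qtl_status", line=1)
    snp_cols = header[2:]
    sire_ids: list[str] = []
    statuses: list[QtlStatus] = []
    cells: list[list[str]] = []
    for ln, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(header):
            raise ParseError(f"{path}: expected {len(header)} fields, got {len(row)}", line=ln)
        sire_ids.append(row[0])
        statuses.append(QtlStatus.parse(row[1]))
        cells.append(row[2:])
    if len(set(sire_ids)) != len(sire_ids):
        raise ValidationError(f"{path}: duplicate sire ID")

    parsed = [_parse_snp_header(tok, j) for j, tok in enumerate(snp_cols)]
    # split cells into allele pairs
    pairs: list[list[tuple[str, str]]] = []
    for ln, row in enumerate(cells, start=2):
        prow = []
        for tok in row:
            if "/" not in tok:
                raise ParseError(f"{path}: genotype cell {tok!r} is not X/Y", line=ln)
            a, b = tok.split("/", 1)
            prow.append((a, b))
        pairs.append(prow)

    snps: list[SnpInfo] = []
    for j, item in enumerate(parsed):
        if isinstance(item, SnpInfo):
            snps.append(item)
        else:
            observed = [a for row in pairs for a in row[j]]
            snps.append(_infer_snp(item, j, observed))

    geno = np.full((len(sire_ids), len(snps)), MISSING, dtype=np.int8)
    for i, row in enumerate(pairs):
        for j, (a, b) in enumerate(row):
            geno[i, j] = _code_pair(a, b, snps[j], path)
    return SirePanel(sire_ids, statuses, geno, snps)


def _code_pair(a: str, b: str, snp: SnpInfo, path: Path) -> int:
    if MISSING_ALLELE in (a, b) or "0" in (a, b):
        return MISSING
    for x in (a, b):
        if x not in snp.alleles:
            raise ValidationError(f"{path}: allele {x!r} not in {snp.alleles} for {snp.snp_id}")
    return (a == snp.alleles[1]) + (b == snp.alleles[1])


def _read_ped_map(path: Path) -> SirePanel:
    path = Path(path)
    if path.suffix == ".ped":
        ped, mp = path, path.with_suffix(".map")
    else:
        ped, mp = path.with_suffix(".ped"), path.with_suffix(".map")
    if not ped.exists():
        raise FileNotFoundError(ped)
    if not mp.exists():
        raise FileNotFoundError(mp)

    snps_raw: list[tuple[str, str, int]] = []
    with open(mp) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) != 4:
                raise ParseError(f"{mp}: map line needs 4 columns", line=ln)
            chrom, snp_id, _cm, bp = f
            snps_raw.append((snp_id, chrom, int(bp)))

    sire_ids, statuses, allele_rows = [], [], []
    with open(ped) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) != 6 + 2 * len(snps_raw):
                raise ParseError(
                    f"{ped}: expected {6 + 2 * len(snps_raw)} fields, got {len(f)}", line=ln
                )
            sire_ids.append(f[1])
            # phenotype column carries QTL status: 2=segregating(+), 1=not(-)
            statuses.append(QtlStatus.HET if f[5] == "2" else QtlStatus.HOM)
            allele_rows.append(f[6:])
    if len(set(sire_ids)) != len(sire_ids):
        raise ValidationError(f"{ped}: duplicate sire ID")

    snps: list[SnpInfo] = []
    for j, (snp_id, chrom, bp) in enumerate(snps_raw):
        observed = [row[2 * j + k] for row in allele_rows for k in (0, 1)]
        order: list[str] = []
        for a in observed:
            if a not in ("0", MISSING_ALLELE) and a not in order:
                order.append(a)
        if len(order) > 2:
            raise ValidationError(f"SNP {snp_id}: more than two alleles {order}")
        while len(order) < 2:
            order.append("N" if "N" not in order else "M")
        snps.append(SnpInfo(snp_id, chrom, bp, (order[0], order[1])))

    geno = np.full((len(sire_ids), len(snps)), MISSING, dtype=np.int8)
    for i, row in enumerate(allele_rows):
        for j, snp in enumerate(snps):
            a, b = row[2 * j], row[2 * j + 1]
            if "0" in (a, b):
                continue
            geno[i, j] = (a == snp.alleles[1]) + (b == snp.alleles[1])
    return SirePanel(sire_ids, statuses, geno, snps)


def _read_vcf(path: Path, qtl_status: Mapping[str, QtlStatus | str] | None) -> SirePanel:
    if qtl_status is None:
        raise ValidationError("VCF input requires a qtl_status mapping (VCF has no status field)")
    from cyvcf2 import VCF  # deferred: only needed for this format

    vcf = VCF(str(path))
    sire_ids = list(vcf.samples)
    statuses = []
    for s in sire_ids:
        if s not in qtl_status:
            raise ValidationError(f"no QTL status for sample {s}")
        st = qtl_status[s]
        statuses.append(st if isinstance(st, QtlStatus) else QtlStatus.parse(str(st)))
    snps: list[SnpInfo] = []
    cols: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValidationError(f"variant {v.ID or v.POS}: not biallelic")
        snps.append(SnpInfo(v.ID or f"{v.CHROM}_{v.POS}", v.CHROM, v.POS,
                            (v.REF, v.ALT[0])))
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT; ALT is counted
        gt = np.asarray(v.gt_types)
        col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        cols.append(col.astype(np.int8))
    geno = (np.stack(cols, axis=1) if cols
            else np.zeros((len(sire_ids), 0), dtype=np.int8))
    return SirePanel(sire_ids, statuses, geno, snps)


def write_genotype_table(panel: SirePanel, path: str | Path,
                         format_tag: str = "tsv") -> None:
    """Write a panel as annotated TSV or as a PLINK ped/map pair."""
    path = Path(path)
    if format_tag == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["sire_id", "qtl_status"] +
                       [f"{s.snp_id}:{s.chromosome}:{s.position_bp}:"
                        f"{s.alleles[0]}/{s.alleles[1]}"
                        + (f":{s.assembly}" if s.assembly else "")
                        for s in panel.snps])
            for i, sire in enumerate(panel.sire_ids):
                row = [sire, panel.qtl_status[i].value]
                for j, s in enumerate(panel.snps):
                    g = panel.genotypes[i, j]
                    if g == MISSING:
                        row.append("./.")
                    else:
                        row.append("/".join([s.alleles[0]] * (2 - g) + [s.alleles[1]] * g))
                w.writerow(row)
    elif format_tag == "ped_map":
        ped, mp = path.with_suffix(".ped"), path.with_suffix(".map")
        with open(mp, "w") as fh:
            for s in panel.snps:
                fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\n")
        with open(ped, "w") as fh:
            for i, sire in enumerate(panel.sire_ids):
                pheno = "2" if panel.qtl_status[i] is QtlStatus.HET else "1"
                f = ["FAM", sire, "0", "0", "0", pheno]
                for j, s in enumerate(panel.snps):
                    g = panel.genotypes[i, j]
                    if g == MISSING:
                        f += ["0", "0"]
                    else:
                        f += [s.alleles[0]] * (2 - g) + [s.alleles[1]] * g
                fh.write("\t".join(f) + "\n")
    else:
        raise ValidationError(f"unsupported output format {format_tag!r}")


# ---------------------------------------------------------------------------
# Phased window I/O
#
# Dialect: header  individual<TAB>hap<TAB><snp>... with SNP columns either a
# bare position or ``id@pos_bp``; two rows per individual, hap in {1, 2}.
# ---------------------------------------------------------------------------


def read_phased_window(path: str | Path) -> PhasedWindow:
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ParseError(f"{path}: empty file", line=1)
    header = rows[0]
    if header[:2] != ["individual", "hap"]:
        raise ParseError(f"{path}: header must start with individual, hap", line=1)
    snp_meta: list[tuple[str, int]] = []
    for j, tok in enumerate(header[2:]):
        if "@" in tok:
            snp_id, pos = tok.split("@", 1)
            snp_meta.append((snp_id, int(pos)))
        else:
            snp_meta.append((f"snp_{tok}", int(tok)))
    pos = [p for _, p in snp_meta]
    if any(b <= a for a, b in zip(pos, pos[1:])):
        raise ValidationError(f"{path}: SNP positions must be strictly increasing")

    by_ind: dict[str, dict[int, list[str]]] = {}
    order: list[str] = []
    for ln, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(header):
            raise ParseError(f"{path}: expected {len(header)} fields", line=ln)
        ind, hap = row[0], row[1]
        if hap not in ("1", "2"):
            raise ParseError(f"{path}: hap must be 1 or 2, got {hap!r}", line=ln)
        if ind not in by_ind:
            by_ind[ind] = {}
            order.append(ind)
        if int(hap) in by_ind[ind]:
            raise ValidationError(f"{path}: duplicate haplotype row {ind}/{hap}")
        by_ind[ind][int(hap)] = row[2:]
    for ind, haps in by_ind.items():
        if set(haps) != {1, 2}:
            raise ValidationError(f"{path}: individual {ind} needs exactly 2 haplotype rows")

    arr = np.array([[by_ind[i][1], by_ind[i][2]] for i in order], dtype="<U1")
    snps = []
    for j, (snp_id, p) in enumerate(snp_meta):
        observed = list(arr[:, :, j].ravel())
        snps.append(_infer_snp_at(snp_id, p, observed))
    return PhasedWindow(snps, order, arr)


def _infer_snp_at(snp_id: str, pos: int, observed: list[str]) -> SnpInfo:
    order: list[str] = []
    for a in observed:
        if a != MISSING_ALLELE and a not in order:
            order.append(a)
    if len(order) > 2:
        raise ValidationError(f"SNP {snp_id}: more than two alleles {order}")
    while len(order) < 2:
        order.append("N" if "N" not in order else "M")
    return SnpInfo(snp_id, "NA", pos, (order[0], order[1]))


def write_phased_window(window: PhasedWindow, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["individual", "hap"] +
                   [f"{s.snp_id}@{s.position_bp}" for s in window.snps])
        for i, ind in enumerate(window.individuals):
            for h in (0, 1):
                w.writerow([ind, str(h + 1)] + list(window.haplotypes[i, h]))


# ---------------------------------------------------------------------------
# Breeding values
# ---------------------------------------------------------------------------


def read_breeding_values(path: str | Path) -> BreedingValueTable:
    """Read a two-column TSV ``sire_id<TAB>breeding_value`` (header optional)."""
    values: dict[str, float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 2:
                raise ParseError(f"{path}: expected 2 columns", line=ln)
            if ln == 1 and f[1].lower() in ("breeding_value", "ebv", "bv"):
                continue
            if f[0] in values:
                raise ValidationError(f"{path}: duplicate sire {f[0]}")
            try:
                values[f[0]] = float(f[1])
            except ValueError as e:
                raise ParseError(f"{path}: bad value {f[1]!r}", line=ln) from e
    return BreedingValueTable(values)


def write_breeding_values(bv: BreedingValueTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sire_id\tbreeding_value\n")
        for k, v in bv.items():
            fh.write(f"{k}\t{v!r}\n")
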