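"""Deconvolution of gene-variant sequences from allele-specific amplicons.

When a locus exists in several near-identical copies (paralogs/variants),
an allele-specific primer splits the template pool in two, and direct
sequencing of each pool produces, at every polymorphic site, either a single
base (the pool is homogeneous there) or a double peak (two co-amplified
variants differ there).  A pool therefore mixes *at most two* variant
sequences.  Given one known component (a seed obtained from a sire whose
pool was pure), the second component is determined site by site: at a
double-peak site it is the base the seed does not have; at a single-base
site both components share that base.

:func:`collect_variants` iterates this over a whole panel of profiles:
pure profiles are harvested as seeds, mixed profiles are deconvolved against
every consistent seed, newly inferred sequences join the seed pool, and the
distinct sequences are labelled V1, V2, ... in order of first appearance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError, ValidationError


@dataclass(frozen=True)
class SiteCallProfile:
    """Observed base calls of one allele-specific amplicon for one sire.

    ``calls[i]`` is the set of bases seen at ``site_positions[i]`` — one
    base for a clean peak, two for a heterogeneous (double) peak.
    """

    amplicon_id: str
    sire_id: str
    site_positions: tuple[int, ...]
    calls: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.site_positions):
            raise ValidationError("one call set required per site")
        for pos, c in zip(self.site_positions, self.calls):
            if not 1 <= len(c) <= 2:
                raise ValidationError(
                    f"{self.amplicon_id}/{self.sire_id} site {pos}: call set "
                    f"must contain 1 or 2 bases, got {sorted(c)}")

    @property
    def is_pure(self) -> bool:
        return all(len(c) == 1 for c in self.calls)


@dataclass(frozen=True)
class VariantSequence:
    """One reconstructed variant over an amplicon's polymorphic sites."""

    label: str
    bases: str
    source: str = "deconvolved"  # pure_observation | deconvolved | reference

    def base_at(self, i: int) -> str:
        return self.bases[i]


def _pure_sequence(profile: SiteCallProfile, label: str = "") -> VariantSequence:
    return VariantSequence(label, "".join(next(iter(c)) for c in profile.calls),
                           source="pure_observation")


def is_consistent(profile: SiteCallProfile, seq: VariantSequence) -> bool:
    """Could ``seq`` be one of the (<=2) components of this profile?

    At a single-base site both components carry that base, so the candidate
    must match it; at a double-peak site the candidate must carry one of the
    two bases.
    """
    if len(seq.bases) != len(profile.calls):
        return False
    return all(seq.bases[i] in c for i, c in enumerate(profile.calls))


def deconvolve_profile(profile: SiteCallProfile,
                       known: VariantSequence | None = None
                       ) -> list[VariantSequence]:
    """Resolve a profile into its one or two component sequences.

    A pure profile resolves to itself.  A mixed profile needs ``known`` (one
    component); the other is inferred site-wise: the complementary base at
    double-peak sites, the shared base elsewhere.
    """
    if profile.is_pure:
        return [_pure_sequence(profile)]
    if known is None:
        raise DomainError(
            f"{profile.amplicon_id}/{profile.sire_id}: mixed profile needs a "
            "known component sequence")
    if len(known.bases) != len(profile.calls):
        raise ValidationError("known sequence length != profile site count")
    inferred = []
    for i, c in enumerate(profile.calls):
        if known.bases[i] not in c:
            raise ValidationError(
                f"{profile.amplicon_id}/{profile.sire_id} site "
                f"{profile.site_positions[i]}: known base {known.bases[i]!r} "
                f"absent from call set {sorted(c)}")
        if len(c) == 1:
            inferred.append(known.bases[i])
        else:
            inferred.append(next(iter(c - {known.bases[i]})))
    return [known, VariantSequence("", "".join(inferred), source="deconvolved")]


@dataclass
class DeconvolutionReport:
    """Outcome of :func:`collect_variants` over a profile panel."""

    variants: list[VariantSequence]
    #: (amplicon_id, sire_id) -> set of variant labels resolved for that profile
    assignments: dict[tuple[str, str], set[str]]
    #: mixed profiles consistent with no seed
    unresolved: list[SiteCallProfile]

    def label_of(self, bases: str) -> str | None:
        for v in self.variants:
            if v.bases == bases:
                return v.label
        return None


def collect_variants(profiles: Sequence[SiteCallProfile],
                     labels: Mapping[str, str] | None = None
                     ) -> DeconvolutionReport:
    """Reconstruct the distinct variant sequences present in a profile panel.

    Pure profiles seed the pool first (in input order); mixed profiles are
    then deconvolved against every consistent known sequence, repeatedly,
    until no new sequence appears.  Distinct sequences are labelled V1, V2,
    ... by first appearance; ``labels`` (base string -> name) pins chosen
    names instead.
    """
    for p in profiles:
        same = [q for q in profiles if q.amplicon_id == p.amplicon_id]
        if any(len(q.calls) != len(p.calls) for q in same):
            raise ValidationError(
                f"amplicon {p.amplicon_id}: inconsistent site counts")

    known: dict[str, VariantSequence] = {}  # bases -> sequence
    order: list[str] = []

    def register(seq: VariantSequence) -> str:
        if seq.bases not in known:
            known[seq.bases] = seq
            order.append(seq.bases)
        return seq.bases

    assignments: dict[tuple[str, str], set[str]] = {}
    for p in profiles:
        if p.is_pure:
            b = register(_pure_sequence(p))
            assignments.setdefault((p.amplicon_id, p.sire_id), set()).add(b)

    mixed = [p for p in profiles if not p.is_pure]
    unresolved: list[SiteCallProfile] = []
    pending = list(mixed)
    while pending:
        progressed = False
        still = []
        for p in pending:
            seeds = [known[b] for b in order if is_consistent(p, known[b])]
            if not seeds:
                still.append(p)
                continue
            got = assignments.setdefault((p.amplicon_id, p.sire_id), set())
            for seed in seeds:
                pair = deconvolve_profile(p, seed)
                for seq in pair:
                    got.add(register(seq))
            progressed = True
        pending = still
        if not progressed:
            unresolved = pending
            break

    name_of: dict[str, str] = {}
    counter = 0
    for b in order:
        if labels and b in labels:
            name_of[b] = labels[b]
    for b in order:
        if b not in name_of:
            counter += 1
            while f"V{counter}" in name_of.values():
                counter += 1
            name_of[b] = f"V{counter}"

    variants = [VariantSequence(name_of[b], b, known[b].source) for b in order]
    assignments = {k: {name_of[b] for b in v} for k, v in assignments.items()}
    return DeconvolutionReport(variants, assignments, unresolved)


def variant_presence_matrix(report: DeconvolutionReport
                            ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-sire variant presence table plus pattern clusters.

    Union over a sire's amplicons of the variants resolved for it; sires
    appearing only in unresolved profiles are excluded (a warning is issued
    by the caller's logging if desired).  The second return value groups
    sires with identical presence patterns.
    """
    per_sire: dict[str, set[str]] = {}
    for (_amp, sire), labs in report.assignments.items():
        per_sire.setdefault(sire, set()).update(labs)
    cols = [v.label for v in report.variants]
    rows = {s: [lab in labs for lab in cols] for s, labs in per_sire.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "sire_id"

    clusters: dict[str, list[str]] = {}
    for sire, labs in per_sire.items():
        key = "+".join(sorted(labs))
        clusters.setdefault(key, []).append(sire)
    return df, clusters


# ---------------------------------------------------------------------------
# I/O: profile TSV (amplicon, sire, one column per site, cells `C` or `C/T`)
# and FASTA output of reconstructed variants.
# ---------------------------------------------------------------------------


def read_call_profiles(path) -> list[SiteCallProfile]:
    import csv
    from pathlib import Path

    from .errors import ParseError

    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ParseError(f"{path}: empty file", line=1)
    header = rows[0]
    if header[:2] != ["amplicon", "sire"]:
        raise ParseError(f"{path}: header must start with amplicon, sire", line=1)
    positions = tuple(int(t) for t in header[2:])
    out = []
    for ln, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(header):
            raise ParseError(f"{path}: expected {len(header)} fields", line=ln)
        calls = tuple(frozenset(tok.split("/")) for tok in row[2:])
        out.append(SiteCallProfile(row[0], row[1], positions, calls))
    return out


def write_variant_fasta(variants: Iterable[VariantSequence], path) -> None:
    with open(path, "w") as fh:
        for v in variants:
            fh.write(f">{v.label} source={v.source}\n{v.bases}\n")
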