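"""Read-backed cis/trans phasing of two variants on a single transcript.

When a sample carries two heterozygous coding variants, paired-end reads
whose mates together cover both positions reveal whether the alternate
alleles sit on the same molecule (cis) or on opposite molecules (trans) —
for a tumor suppressor, trans means both copies are hit.  This module
extracts per-pair allele calls from alignments to the transcript and applies
a counting decision rule.

Only alt-containing pairs discriminate the configurations: a ref-ref pair is
produced by the non-variant haplotype in cis and by either recombinant-free
haplotype in trans, so it counts toward coverage (informativeness) but is
neutral in the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam

NUCLEOTIDES = ("A", "C", "G", "T")
ALLELE_CATEGORIES = ("ref", "alt", "other", "uncovered")

MIN_BASE_QUALITY_DEFAULT = 20
MIN_INFORMATIVE_DEFAULT = 5
MAX_CONFLICT_DEFAULT = 0.1


class PhasingError(ValueError):
    pass


@dataclass(frozen=True)
class VariantSite:
    """A biallelic substitution at a 1-based transcript coordinate."""

    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise PhasingError(f"position must be >= 1, got {self.position}")
        if self.ref_base not in NUCLEOTIDES or self.alt_base not in NUCLEOTIDES:
            raise PhasingError("ref/alt bases must be A, C, G or T")
        if self.ref_base == self.alt_base:
            raise PhasingError("ref and alt bases must differ")

    @classmethod
    def from_string(cls, spec: str) -> "VariantSite":
        """Parse ``'659:A>G'`` -> VariantSite(659, 'A', 'G')."""
        try:
            pos, change = spec.split(":")
            ref, alt = change.split(">")
            return cls(int(pos), ref.strip().upper(), alt.strip().upper())
        except (ValueError, AttributeError) as exc:
            raise PhasingError(f"cannot parse variant site {spec!r}") from exc

    def classify(self, base: str) -> str:
        if base == self.ref_base:
            return "ref"
        if base == self.alt_base:
            return "alt"
        return "other"


@dataclass(frozen=True)
class ReadPairObservation:
    """Allele call of one read pair at the two sites."""

    pair_id: str
    allele_site1: str
    allele_site2: str
    min_base_quality: int | None = None

    def __post_init__(self) -> None:
        for a in (self.allele_site1, self.allele_site2):
            if a not in ALLELE_CATEGORIES:
                raise PhasingError(f"unknown allele category {a!r}")

    @property
    def informative(self) -> bool:
        return self.allele_site1 in ("ref", "alt") and self.allele_site2 in ("ref", "alt")


@dataclass(frozen=True)
class PhasingCall:
    """Aggregate call with its supporting 2x2 allele count table.

    ``counts[(a1, a2)]`` for a1, a2 in {ref, alt} sums to the number of
    informative pairs; ``conflict_fraction`` is the share of alt-containing
    pairs contradicting the returned call (0 when no call was made).
    """

    call: str  # cis | trans | ambiguous | insufficient
    counts: dict
    n_informative: int
    conflict_fraction: float

    @property
    def n_cis_support(self) -> int:
        return self.counts[("alt", "alt")]

    @property
    def n_trans_support(self) -> int:
        return self.counts[("alt", "ref")] + self.counts[("ref", "alt")]


def _base_at(
    read: pysam.AlignedSegment, position0: int, min_qual: int
) -> tuple[str, int] | None:
    """(base, quality) called by ``read`` at a 0-based reference position.

    None when the read does not align a base there or the base quality is
    below ``min_qual``; missing quality strings count as quality 255.
    """
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == position0:
            qual = 255 if read.query_qualities is None else read.query_qualities[qpos]
            if qual < min_qual:
                return None
            return read.query_sequence[qpos].upper(), qual
    return None


def extract_pair_alleles(
    alignments: str | Iterable[pysam.AlignedSegment],
    sites: Sequence[VariantSite],
    min_qual: int = MIN_BASE_QUALITY_DEFAULT,
) -> list[ReadPairObservation]:
    """Collapse alignments to one allele observation per read pair.

    ``alignments`` is a SAM path or an iterable of mapped
    :class:`pysam.AlignedSegment` on one transcript.  A site is "uncovered"
    for a pair when no mate aligns a base of sufficient quality there;
    mates disagreeing at a site yield "other" (conservative).  Unmapped or
    malformed records are skipped (counted, not fatal).
    """
    if len(sites) != 2 or sites[0].position == sites[1].position:
        raise PhasingError("exactly two distinct variant sites are required")
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
            reads = [r for r in fh if not r.is_unmapped]
    else:
        reads = [r for r in alignments if not r.is_unmapped]

    by_pair: dict[str, list[pysam.AlignedSegment]] = {}
    n_skipped = 0
    for read in reads:
        if read.query_sequence is None or read.query_name is None:
            n_skipped += 1
            continue
        by_pair.setdefault(read.query_name, []).append(read)
    if n_skipped:
        import logging

        logging.getLogger(__name__).warning("skipped %d malformed records", n_skipped)

    observations = []
    for pair_id in by_pair:  # insertion order: deterministic given input order
        mates = by_pair[pair_id]
        alleles = []
        quals = []
        for site in sites:
            pos0 = site.position - 1
            calls = [c for c in (_base_at(m, pos0, min_qual) for m in mates) if c is not None]
            bases = {base for base, _ in calls}
            if not bases:
                alleles.append("uncovered")
                continue
            quals.extend(q for _, q in calls)
            if len(bases) > 1:
                alleles.append("other")  # mates disagree
            else:
                alleles.append(site.classify(bases.pop()))
        observations.append(
            ReadPairObservation(
                pair_id, alleles[0], alleles[1], min(quals) if quals else None
            )
        )
    return observations


def phase(
    observations: Iterable[ReadPairObservation],
    min_informative: int = MIN_INFORMATIVE_DEFAULT,
    max_conflict: float = MAX_CONFLICT_DEFAULT,
) -> PhasingCall:
    """Call cis/trans from pair allele counts.

    Let ``n_aa``, ``n_ar``, ``n_ra`` be the alt-alt, alt-ref and ref-alt
    pair counts and ``d = n_aa + n_ar + n_ra`` (alt-containing pairs).
    With at least ``min_informative`` informative pairs:

    * cis   when ``n_aa / d >= 1 - max_conflict``
    * trans when ``(n_ar + n_ra) / d >= 1 - max_conflict``
    * ambiguous otherwise (including d == 0, e.g. all pairs ref-ref)

    Fewer informative pairs -> "insufficient".  Swapping the two site labels
    exchanges ``n_ar`` and ``n_ra`` and therefore never flips cis vs trans.
    """
    counts = {(a, b): 0 for a in ("ref", "alt") for b in ("ref", "alt")}
    for obs in observations:
        if obs.informative:
            counts[(obs.allele_site1, obs.allele_site2)] += 1
    n_informative = sum(counts.values())
    n_aa = counts[("alt", "alt")]
    n_discordant = counts[("alt", "ref")] + counts[("ref", "alt")]
    d = n_aa + n_discordant

    if n_informative < min_informative:
        call, conflict = "insufficient", 0.0
    elif d == 0:
        call, conflict = "ambiguous", 0.0
    elif n_aa / d >= 1.0 - max_conflict:
        call, conflict = "cis", n_discordant / d
    elif n_discordant / d >= 1.0 - max_conflict:
        call, conflict = "trans", n_aa / d
    else:
        call, conflict = "ambiguous", min(n_aa, n_discordant) / d
    return PhasingCall(call=call, counts=counts, n_informative=n_informative,
                       conflict_fraction=conflict)
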