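"""Extraction of SV signatures from haplotype-tagged long-read alignments.

A *signature* is the footprint a candidate structural variant leaves in a
single read's alignment: a long insertion/deletion run in the CIGAR string
(intra-read evidence) or a breakpoint pattern between the split alignments
of one read (inter-read evidence).  Reads may carry an integer ``HP`` aux
tag (1 or 2, WhatsHap convention) assigning them to a parental haplotype;
untagged reads are labelled haplotype 0 and participate in calling without
haplotype information.

All coordinates are 0-based half-open internally; VCF output converts to
1-based at the writing stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

import pysam

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "INS", "DUP", "INV")

#: CIGAR operation codes that consume the reference.
_REF_OPS = {0, 2, 3, 7, 8}
#: CIGAR operation codes that consume the query.
_QRY_OPS = {0, 1, 4, 7, 8}


@dataclass(frozen=True, slots=True)
class Signature:
    """One piece of SV evidence from one read.

    ``left``/``right`` bound the affected reference interval (for INS both
    equal the anchor point), ``length`` is the SV length in bp, ``haplotype``
    is 0 (untagged), 1 or 2, and ``source`` records whether the evidence came
    from a CIGAR run (``cigar``) or a split-alignment pair (``split``).
    """

    chrom: str
    left: int
    right: int
    length: int
    sv_type: str
    read_id: str
    haplotype: int
    source: str

    def __post_init__(self) -> None:
        if self.right < self.left:
            raise ValueError(f"right < left ({self.right} < {self.left})")
        if self.length < 1:
            raise ValueError(f"non-positive SV length {self.length}")
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.haplotype not in (0, 1, 2):
            raise ValueError(f"haplotype must be 0, 1 or 2, got {self.haplotype}")
        if self.source not in ("cigar", "split"):
            raise ValueError(f"unknown signature source {self.source!r}")
        if self.sv_type == "DEL" and self.right - self.left != self.length:
            raise ValueError("DEL signature must span exactly its length")
        if self.sv_type == "INS" and self.right != self.left:
            raise ValueError("INS signature must be anchored at a point")


@dataclass(frozen=True, slots=True)
class CoverageEstimate:
    """Mean fold read depth of one chromosome."""

    chrom: str
    cov: float

    def __post_init__(self) -> None:
        if self.cov < 0:
            raise ValueError("coverage must be non-negative")


class TaggedAlignment(NamedTuple):
    aln: pysam.AlignedSegment
    haplotype: int


class SegmentLayout(NamedTuple):
    """Placement of one alignment segment in read and reference space.

    ``read_start``/``read_end`` are coordinates on the *original* read strand
    (clips included in the length), so segments of one read can be ordered
    as they occur on the molecule regardless of mapping strand.
    """

    chrom: str
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    strand: str


def read_haplotype(aln: pysam.AlignedSegment) -> int:
    """Return the haplotype label of a read: its integer HP tag, else 0.

    HP values outside {1, 2} are treated as untagged (with a warning), per
    the WhatsHap tagging convention.
    """
    try:
        hp = aln.get_tag("HP")
    except KeyError:
        return 0
    if hp in (1, 2):
        return int(hp)
    logger.warning(
        "read %s carries HP=%r outside {1,2}; treating as untagged",
        aln.query_name, hp,
    )
    return 0


def load_tagged_alignments(
    bam_path: str, region: str | None = None
) -> Iterator[TaggedAlignment]:
    """Stream mapped primary and supplementary alignments with HP labels.

    Unmapped and secondary alignments are skipped.  The BAM must be
    coordinate-sorted and indexed.
    """
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        it = bam.fetch(region) if region is not None else bam.fetch()
        for aln in it:
            if aln.is_unmapped or aln.is_secondary:
                continue
            yield TaggedAlignment(aln, read_haplotype(aln))


def _merge_events(
    events: list[tuple[int, int, int]], merge_gap: int, sv_type: str
) -> list[tuple[int, int, int]]:
    """Merge same-type (left, right, length) events closer than merge_gap.

    Merged length is the sum of event lengths.  The merged DEL interval is
    re-anchored at the first event with right = left + length, keeping the
    DEL span == length invariant that the clustering distances rely on;
    INS keeps the first anchor (point interval).
    """
    merged: list[tuple[int, int, int]] = []
    for left, right, length in events:
        if merged and left - merged[-1][1] < merge_gap:
            pl, pr, pn = merged[-1]
            if sv_type == "INS":
                merged[-1] = (pl, pl, pn + length)
            else:
                merged[-1] = (pl, pl + pn + length, pn + length)
        else:
            merged.append((left, right, length))
    return merged


def extract_cigar_signatures(
    aln: pysam.AlignedSegment,
    min_sv_size: int = 30,
    merge_gap: int = 500,
    haplotype: int | None = None,
) -> list[Signature]:
    """Extract intra-read DEL/INS signatures from one alignment's CIGAR.

    Each D run >= ``min_sv_size`` yields a DEL spanning its reference
    interval; each I run >= ``min_sv_size`` yields an INS anchored at its
    reference position.  Same-type runs separated by fewer than
    ``merge_gap`` reference bp are merged into a single signature (length =
    sum of run lengths).  Note merging can only grow lengths, so no
    signature shorter than ``min_sv_size`` is ever emitted.
    """
    if haplotype is None:
        haplotype = read_haplotype(aln)
    cigar = aln.cigartuples
    if cigar is None:
        logger.warning("read %s has no CIGAR; skipped", aln.query_name)
        return []
    ref = aln.reference_start
    dels: list[tuple[int, int, int]] = []
    inss: list[tuple[int, int, int]] = []
    for op, ln in cigar:
        if op == 2:  # D
            if ln >= min_sv_size:
                dels.append((ref, ref + ln, ln))
            ref += ln
        elif op == 1:  # I
            if ln >= min_sv_size:
                inss.append((ref, ref, ln))
        elif op in _REF_OPS:
            ref += ln
    out = []
    for sv_type, events in (("DEL", dels), ("INS", inss)):
        for left, right, length in _merge_events(events, merge_gap, sv_type):
            out.append(
                Signature(
                    chrom=aln.reference_name,
                    left=left,
                    right=right,
                    length=length,
                    sv_type=sv_type,
                    read_id=aln.query_name,
                    haplotype=haplotype,
                    source="cigar",
                )
            )
    return out


def segment_layout(aln: pysam.AlignedSegment) -> SegmentLayout:
    """Compute the read-space/reference-space placement of one segment."""
    cigar = aln.cigartuples or []
    left_clip = 0
    for op, ln in cigar:
        if op in (4, 5):
            left_clip += ln
        else:
            break
    right_clip = 0
    for op, ln in reversed(cigar):
        if op in (4, 5):
            right_clip += ln
        else:
            break
    qalen = sum(ln for op, ln in cigar if op in (0, 1, 7, 8))
    if aln.is_reverse:
        # stored sequence is the reverse complement; flip to molecule coords
        read_start = right_clip
    else:
        read_start = left_clip
    return SegmentLayout(
        chrom=aln.reference_name,
        read_start=read_start,
        read_end=read_start + qalen,
        ref_start=aln.reference_start,
        ref_end=aln.reference_end,
        strand="-" if aln.is_reverse else "+",
    )


def split_signatures_from_layouts(
    read_id: str,
    layouts: list[SegmentLayout],
    haplotype: int,
    min_sv_size: int = 30,
) -> list[Signature]:
    """Derive inter-read signatures from the split segments of one read.

    Segments are ordered along the molecule.  For two adjacent same-strand,
    same-chromosome segments the difference between the reference jump and
    the unaligned read gap classifies the event: extra reference -> DEL,
    extra read sequence -> INS, a backward reference jump -> DUP.  A strand
    switch marks an inversion spanning the reverse-strand segment.
    """
    if len(layouts) < 2:
        return []
    segs = sorted(layouts, key=lambda s: (s.read_start, s.read_end))
    found: dict[tuple, Signature] = {}

    def _add(sv_type: str, chrom: str, left: int, right: int, length: int) -> None:
        key = (sv_type, chrom, left, right, length)
        if key not in found:
            found[key] = Signature(
                chrom=chrom,
                left=left,
                right=right,
                length=length,
                sv_type=sv_type,
                read_id=read_id,
                haplotype=haplotype,
                source="split",
            )

    for a, b in zip(segs, segs[1:]):
        if a.chrom != b.chrom:
            continue
        if a.strand != b.strand:
            inv = a if a.strand == "-" else b
            length = inv.ref_end - inv.ref_start
            if length >= min_sv_size:
                _add("INV", inv.chrom, inv.ref_start, inv.ref_end, length)
            continue
        read_gap = b.read_start - a.read_end
        if a.strand == "+":
            ref_gap = b.ref_start - a.ref_end
            bp = a.ref_end
        else:
            ref_gap = a.ref_start - b.ref_end
            bp = b.ref_end
        diff = ref_gap - read_gap
        if ref_gap <= -min_sv_size:
            # backward jump: the read traverses part of the reference twice
            length = -ref_gap
            left = bp - length
            _add("DUP", a.chrom, left, bp, length)
        elif diff >= min_sv_size:
            _add("DEL", a.chrom, bp, bp + diff, diff)
        elif -diff >= min_sv_size:
            _add("INS", a.chrom, bp, bp, -diff)
    return list(found.values())


def extract_split_signatures(
    alignments: Iterable[pysam.AlignedSegment], min_sv_size: int = 30
) -> list[Signature]:
    """Extract inter-read signatures from all alignment segments of one read.

    The haplotype label is inherited from the primary alignment's HP tag
    (falling back to any tagged segment).
    """
    alns = [a for a in alignments if not a.is_unmapped and not a.is_secondary]
    if len(alns) < 2:
        return []
    read_id = alns[0].query_name
    haplotype = 0
    for a in alns:
        if not a.is_supplementary:
            haplotype = read_haplotype(a)
            break
    if haplotype == 0:
        for a in alns:
            hp = read_haplotype(a)
            if hp:
                haplotype = hp
                break
    layouts = [segment_layout(a) for a in alns]
    return split_signatures_from_layouts(read_id, layouts, haplotype, min_sv_size)


def chromosome_coverage(
    bam: str | pysam.AlignmentFile, chrom: str
) -> CoverageEstimate:
    """Mean read depth: aligned reference bases of primary reads / length."""
    own = isinstance(bam, str)
    handle = pysam.AlignmentFile(bam, "rb") if own else bam
    try:
        if chrom not in handle.references:
            raise ValueError(f"chromosome {chrom!r} absent from BAM header")
        length = handle.get_reference_length(chrom)
        total = 0
        for aln in handle.fetch(chrom):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            total += aln.reference_length or 0
        return CoverageEstimate(chrom=chrom, cov=total / length if length else 0.0)
    finally:
        if own:
            handle.close()
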