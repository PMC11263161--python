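"""Self-contained synthetic diploid test data.

Generates a random toy genome, plants DEL/INS/DUP/INV variants on one or
both haplotypes, and writes a coordinate-sorted, indexed BAM of constructed
alignments that carry each variant exactly as a long-read aligner would
represent it: deletions as CIGAR ``D`` runs, insertions and tandem
duplications as ``I`` runs, and inversions as a primary plus two
supplementary segments with a strand switch across the inverted interval.
Alignments are written directly (no raw-read simulation or external
aligner), which keeps the generator dependency-free while preserving the
exact signature structure the caller consumes.

Reads are tiled per haplotype with stratified random offsets, so local
depth is close to its expectation everywhere.  Per read and per variant,
breakpoint position and length receive integer-rounded Gaussian jitter.
Each read is HP-tagged with its haplotype of origin with probability
``tag_rate``; a tagged read receives the wrong haplotype with probability
``mistag_rate``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pysam

__all__ = [
    "SimConfig",
    "TruthRecord",
    "random_reference",
    "simulate_truth",
    "simulate_tagged_bam",
    "write_truth_vcf",
    "write_reference_fasta",
    "simulate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: reference-position margin a read must retain on each side of a variant
#: for the variant to be embedded in its alignment
_ANCHOR = 300


@dataclass(frozen=True, slots=True)
class SimConfig:
    """Study conditions of one simulated diploid dataset.

    Defaults describe a 2 Mb single-chromosome genome carrying 10 variants
    of each type (50-500 bp, half heterozygous) sequenced to 20-fold depth
    with 10 kb reads, perfect tagging and no breakpoint jitter.
    """

    genome_length: int = 2_000_000
    n_chroms: int = 1
    n_del: int = 10
    n_ins: int = 10
    n_dup: int = 10
    n_inv: int = 10
    size_range: tuple[int, int] = (50, 500)
    het_fraction: float = 0.5
    depth: float = 20.0
    read_length: int = 10_000
    pos_jitter_sd: float = 0.0
    len_jitter_sd: float = 0.0
    tag_rate: float = 1.0
    mistag_rate: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("het_fraction", "tag_rate", "mistag_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.size_range[0] < 50:
            raise ValueError("minimum SV size is 50 bp")
        if self.pos_jitter_sd < 0 or self.len_jitter_sd < 0:
            raise ValueError("jitter SDs must be >= 0")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "DEL": self.n_del,
            "INS": self.n_ins,
            "DUP": self.n_dup,
            "INV": self.n_inv,
        }


@dataclass(frozen=True, slots=True)
class TruthRecord:
    """A planted SV: 1-based position, type, length, genotype, and the
    carrier haplotype (1 or 2 for heterozygous, 0 for both)."""

    chrom: str
    pos: int
    sv_type: str
    svlen: int
    genotype: str  # "0/1" or "1/1"
    haplotype: int  # 0 = both haplotypes

    def ref_interval(self) -> tuple[int, int]:
        """0-based reference footprint (point interval for INS/DUP)."""
        left = self.pos - 1
        if self.sv_type in ("DEL", "INV"):
            return left, left + self.svlen
        return left, left + 1


def random_reference(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _min_separation(cfg: SimConfig) -> int:
    # keep neighbouring variants out of each other's merge reach
    return int(max(2 * cfg.pos_jitter_sd + 600, 2500))


def simulate_truth(cfg: SimConfig) -> tuple[dict[str, str], list[TruthRecord]]:
    """Random reference plus non-overlapping planted SVs.

    Deterministic for a given seed.  Raises ``ValueError`` when the genome
    cannot hold the requested variants with the spacing constraints.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom_len = cfg.genome_length // cfg.n_chroms
    reference = {
        f"chr{i + 1}": random_reference(chrom_len, rng) for i in range(cfg.n_chroms)
    }
    sv_types: list[str] = []
    for sv_type, count in cfg.counts.items():
        sv_types.extend([sv_type] * count)
    rng.shuffle(sv_types)
    per_chrom: dict[str, list[str]] = {name: [] for name in reference}
    names = list(reference)
    for i, sv_type in enumerate(sv_types):
        per_chrom[names[i % len(names)]].append(sv_type)

    margin = cfg.read_length + 1000
    sep = _min_separation(cfg) + cfg.size_range[1]
    truth: list[TruthRecord] = []
    for chrom, types in per_chrom.items():
        if not types:
            continue
        span = chrom_len - 2 * margin
        if span < len(types) * sep:
            raise ValueError(
                f"genome too small: {len(types)} SVs need {len(types) * sep} bp "
                f"of usable span on {chrom}, only {span} available"
            )
        positions = None
        for _ in range(1000):
            cand = np.sort(rng.integers(margin, chrom_len - margin, size=len(types)))
            if len(cand) < 2 or np.diff(cand).min() >= sep:
                positions = cand
                break
        if positions is None:
            raise ValueError("could not place SVs with the required spacing")
        for sv_type, left in zip(types, positions):
            svlen = int(rng.integers(cfg.size_range[0], cfg.size_range[1] + 1))
            if rng.random() < cfg.het_fraction:
                gt, hap = "0/1", int(rng.integers(1, 3))
            else:
                gt, hap = "1/1", 0
            truth.append(
                TruthRecord(
                    chrom=chrom,
                    pos=int(left) + 1,
                    sv_type=sv_type,
                    svlen=svlen,
                    genotype=gt,
                    haplotype=hap,
                )
            )
    truth.sort(key=lambda t: (t.chrom, t.pos))
    return reference, truth


def _jitter(rng: np.random.Generator, sd: float) -> int:
    return int(round(rng.normal(0.0, sd))) if sd > 0 else 0


def _event_cigar(
    start: int, end: int, events: list[tuple[int, str, int]]
) -> tuple[list[tuple[int, int]], int]:
    """CIGAR tuples and query length for a segment [start, end) carrying
    DEL (D) and INS/DUP (I) events at jittered positions."""
    cig: list[tuple[int, int]] = []
    qlen = 0
    cur = start
    for pos, sv_type, length in sorted(events):
        pos = max(pos, cur + 1)
        m = pos - cur
        cig.append((0, m))
        qlen += m
        if sv_type == "DEL":
            cig.append((2, length))
            cur = pos + length
        else:
            cig.append((1, length))
            qlen += length
            cur = pos
    if end > cur:
        cig.append((0, end - cur))
        qlen += end - cur
    return cig, qlen


def _make_segment(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    pos: int,
    cigar: list[tuple[int, int]],
    is_reverse: bool = False,
    is_supplementary: bool = False,
    hp: int | None = None,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_name = chrom
    a.reference_start = pos
    a.mapping_quality = 60
    a.cigartuples = cigar
    flag = 0
    if is_reverse:
        flag |= 0x10
    if is_supplementary:
        flag |= 0x800
    a.flag = flag
    qlen = sum(ln for op, ln in cigar if op in (0, 1, 4, 7, 8))
    a.query_sequence = "A" * qlen
    if hp is not None:
        a.set_tag("HP", hp, value_type="i")
    return a


def _read_records(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    start: int,
    end: int,
    events: list[tuple[int, str, int]],
    hp: int | None,
) -> list[pysam.AlignedSegment]:
    """Alignment records of one read: a single record for a CIGAR-only read,
    or alternating forward/reverse segments around each inversion."""
    plain = sorted(e for e in events if e[1] != "INV")
    invs = sorted((p, p + ln) for p, t, ln in events if t == "INV")
    if not invs:
        cig, _ = _event_cigar(start, end, plain)
        return [_make_segment(header, name, chrom, start, cig, hp=hp)]
    # fwd | rev(inverted) | fwd | rev(inverted) | ... | fwd
    spans: list[tuple[int, int, str]] = []
    cur = start
    for il, ir in invs:
        spans.append((cur, il, "+"))
        spans.append((il, ir, "-"))
        cur = ir
    spans.append((cur, end, "+"))
    parts: list[tuple[int, int, str, list[tuple[int, int]], int]] = []
    for a, b, strand in spans:
        if b <= a:
            continue
        if strand == "+":
            cig, q = _event_cigar(a, b, [e for e in plain if a <= e[0] < b])
        else:
            cig, q = [(0, b - a)], b - a
        parts.append((a, b, strand, cig, q))
    qtotal = sum(p[4] for p in parts)
    recs: list[pysam.AlignedSegment] = []
    offset = 0
    for k, (a, b, strand, cig, q) in enumerate(parts):
        left, right = offset, qtotal - offset - q
        if strand == "+":
            clips = ([(4, left)] if left else [], [(4, right)] if right else [])
        else:  # stored orientation flips the clips
            clips = ([(4, right)] if right else [], [(4, left)] if left else [])
        recs.append(
            _make_segment(
                header,
                name,
                chrom,
                a,
                clips[0] + cig + clips[1],
                is_reverse=(strand == "-"),
                is_supplementary=(k > 0),
                hp=hp,
            )
        )
        offset += q
    return recs


def simulate_tagged_bam(
    reference: dict[str, str],
    truth: Sequence[TruthRecord],
    cfg: SimConfig,
    out_path: str,
) -> None:
    """Write a coordinate-sorted, indexed BAM of constructed alignments.

    Reads are sampled per haplotype to depth/2 each; a read fully spanning
    a planted SV of its haplotype (with an anchor margin on both sides)
    carries the SV in its alignment, with per-read positional and length
    jitter.  Reads only partially overlapping an SV are trimmed back to
    clean flanking sequence so no truncated signatures arise.
    """
    rng = np.random.default_rng([cfg.seed, 0x5E])
    header = pysam.AlignmentHeader.from_references(
        list(reference), [len(s) for s in reference.values()]
    )
    records: list[pysam.AlignedSegment] = []
    spacing = cfg.read_length / (cfg.depth / 2.0)
    for chrom, seq in reference.items():
        chrom_len = len(seq)
        for hap in (1, 2):
            events_all = [
                t for t in truth if t.chrom == chrom and t.haplotype in (0, hap)
            ]
            n_reads = max(int((chrom_len - cfg.read_length) // spacing) + 1, 1)
            for i in range(n_reads):
                s = int(i * spacing + rng.random() * spacing)
                s = min(s, max(chrom_len - cfg.read_length, 0))
                e = min(s + cfg.read_length, chrom_len)
                # trim the read away from partially overlapped variants;
                # trimming can expose new partial overlaps, so iterate
                changed = True
                while changed and e > s:
                    changed = False
                    for t in events_all:
                        lo, hi = t.ref_interval()
                        if hi <= s or lo >= e:
                            continue
                        if s + _ANCHOR <= lo and hi <= e - _ANCHOR:
                            continue
                        if (lo + hi) / 2 >= (s + e) / 2:
                            e = min(e, lo - 50)
                        else:
                            s = max(s, hi + 50)
                        changed = True
                if e - s < 2 * _ANCHOR + 100:
                    continue
                events: list[tuple[int, str, int]] = []
                for t in events_all:
                    lo, hi = t.ref_interval()
                    if not (s + _ANCHOR <= lo and hi <= e - _ANCHOR):
                        continue
                    pos = lo + _jitter(rng, cfg.pos_jitter_sd)
                    length = max(30, t.svlen + _jitter(rng, cfg.len_jitter_sd))
                    pos = min(max(pos, s + 50), e - 50 - (length if t.sv_type != "INS" else 0))
                    events.append((pos, t.sv_type, length))
                hp: int | None = None
                if rng.random() < cfg.tag_rate:
                    hp = hap
                    if rng.random() < cfg.mistag_rate:
                        hp = 3 - hap
                name = f"r_{chrom}_h{hap}_{i}"
                records.extend(
                    _read_records(header, name, chrom, s, e, events, hp)
                )
    order = {name: i for i, name in enumerate(reference)}
    records.sort(key=lambda r: (order[r.reference_name], r.reference_start, r.query_name))
    with pysam.AlignmentFile(out_path, "wb", header=header) as bam:
        for r in records:
            bam.write(r)
    pysam.index(out_path)


def write_truth_vcf(
    truth: Sequence[TruthRecord], out_path: str, contigs: dict[str, int]
) -> None:
    """Write planted SVs as a VCF 4.2 truth set (GT 0/1 or 1/1)."""
    order = {name: i for i, name in enumerate(contigs)}
    keys = [(order[t.chrom], t.pos) for t in truth]
    if keys != sorted(keys):
        raise ValueError("truth records must be sorted by (chrom, pos)")
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for sv_type in ("DEL", "INS", "DUP", "INV"):
        header.add_line(f'##ALT=<ID={sv_type},Description="{sv_type}">')
    header.add_line(
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">'
    )
    header.add_line(
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length (negative for deletions)">'
    )
    header.add_line(
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample("SAMPLE")
    with pysam.VariantFile(out_path, "w", header=header) as vf:
        for i, t in enumerate(truth):
            end = t.pos + t.svlen if t.sv_type != "INS" else t.pos
            rec = vf.new_record(
                contig=t.chrom,
                start=t.pos - 1,
                stop=end,
                alleles=("N", f"<{t.sv_type}>"),
                id=f"truth.{t.sv_type}.{i}",
            )
            rec.info["SVTYPE"] = t.sv_type
            rec.info["SVLEN"] = -t.svlen if t.sv_type == "DEL" else t.svlen
            rec.samples["SAMPLE"]["GT"] = (0, 1) if t.genotype == "0/1" else (1, 1)
            vf.write(rec)


def write_reference_fasta(reference: dict[str, str], out_path: str) -> None:
    with open(out_path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    pysam.faidx(out_path)


def simulate_dataset(cfg: SimConfig, out_dir: str) -> dict[str, str]:
    """Generate reference FASTA, tagged BAM and truth VCF under ``out_dir``.

    Returns the paths under keys ``reference``, ``bam`` and ``truth``.
    """
    os.makedirs(out_dir, exist_ok=True)
    reference, truth = simulate_truth(cfg)
    paths = {
        "reference": os.path.join(out_dir, "reference.fa"),
        "bam": os.path.join(out_dir, "reads.bam"),
        "truth": os.path.join(out_dir, "truth.vcf"),
    }
    write_reference_fasta(reference, paths["reference"])
    simulate_tagged_bam(reference, truth, cfg, paths["bam"])
    write_truth_vcf(truth, paths["truth"], {n: len(s) for n, s in reference.items()})
    return paths
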