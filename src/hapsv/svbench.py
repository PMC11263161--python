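"""Presence and genotype benchmarking of SV calls against a truth set.

Matching is sequence-free, in the spirit of truvari's ``-p 0.0`` mode: a
call matches a truth record iff the SV types agree, the start positions lie
within ``refdist`` bp, and the size ratio min(len)/max(len) is at least
``pctsize``.  Matches are one-to-one, assigned greedily by best size
similarity and then smallest distance.  Precision, recall and F1 are

    precision = TP_call / (TP_call + FP_call)
    recall    = TP_base / (TP_base + FN_base)
    F1        = 2 P R / (P + R)

computed at *presence* level (any match counts) and at *genotype* level (a
match additionally requires identical GT), overall and stratified by SV
type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pysam

__all__ = [
    "SVRecord",
    "MatchPair",
    "Matching",
    "BenchResult",
    "load_vcf",
    "load_bed",
    "filter_region",
    "match_calls",
    "metrics",
    "summarize",
    "stratify",
    "bench",
]

_TYPES = {"DEL", "INS", "DUP", "INV"}


@dataclass(frozen=True, slots=True)
class SVRecord:
    """A normalized SV from a VCF: 1-based POS, type, |SVLEN|, genotype."""

    chrom: str
    pos: int
    sv_type: str
    svlen: int
    gt: str


@dataclass(frozen=True, slots=True)
class MatchPair:
    call_idx: int
    truth_idx: int
    size_ratio: float
    distance: int
    gt_match: bool


@dataclass(slots=True)
class Matching:
    calls: list[SVRecord]
    truth: list[SVRecord]
    pairs: list[MatchPair]


@dataclass(frozen=True, slots=True)
class BenchResult:
    tp_call: int
    fp_call: int
    tp_base: int
    fn_base: int
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(
        cls, tp_call: int, fp_call: int, tp_base: int, fn_base: int
    ) -> "BenchResult":
        p, r, f1 = metrics(tp_call, fp_call, tp_base, fn_base)
        return cls(tp_call, fp_call, tp_base, fn_base, p, r, f1)

    def as_dict(self) -> dict:
        return {
            "TP_call": self.tp_call,
            "FP_call": self.fp_call,
            "TP_base": self.tp_base,
            "FN_base": self.fn_base,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def _normalize_gt(sample) -> str:
    gt = sample.get("GT")
    if gt is None or any(a is None for a in gt):
        return "./."
    return "/".join(str(a) for a in sorted(gt))


def load_vcf(path: str) -> list[SVRecord]:
    """Load SV records (SVTYPE normalized to DEL/INS/DUP/INV) from a VCF."""
    out: list[SVRecord] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            sv_type = rec.info.get("SVTYPE")
            if sv_type is None and rec.alts:
                alt = rec.alts[0]
                sv_type = alt.strip("<>") if alt.startswith("<") else None
            if sv_type not in _TYPES:
                continue
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            if svlen is None:
                svlen = (rec.stop or rec.pos) - rec.pos
            gt = "./."
            if rec.samples:
                gt = _normalize_gt(rec.samples[0])
            out.append(
                SVRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    sv_type=sv_type,
                    svlen=abs(int(svlen)),
                    gt=gt,
                )
            )
    return out


def load_bed(path: str) -> list[tuple[str, int, int]]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append((chrom, int(start), int(end)))
    return regions


def filter_region(
    records: list[SVRecord], regions: list[tuple[str, int, int]]
) -> list[SVRecord]:
    """Keep records whose POS (0-based) falls inside a half-open region."""
    return [
        r
        for r in records
        if any(c == r.chrom and s <= r.pos - 1 < e for c, s, e in regions)
    ]


def _check_sorted(records: list[SVRecord], label: str) -> None:
    order: dict[str, int] = {}
    for r in records:
        order.setdefault(r.chrom, len(order))
    keys = [(order[r.chrom], r.pos) for r in records]
    if keys != sorted(keys):
        raise ValueError(f"{label} records are not sorted by (chrom, pos)")


def _types_compatible(a: str, b: str, dup_to_ins: bool) -> bool:
    if a == b:
        return True
    return dup_to_ins and {a, b} == {"DUP", "INS"}


def match_calls(
    calls: list[SVRecord],
    truth: list[SVRecord],
    refdist: int = 500,
    pctsize: float = 0.7,
    dup_to_ins: bool = False,
) -> Matching:
    """One-to-one greedy matching of calls to truth records.

    Candidate pairs require the same chromosome, compatible SV type, start
    distance <= refdist and size ratio >= pctsize; candidates are consumed
    in order of descending size ratio, then ascending distance.
    """
    _check_sorted(calls, "call")
    _check_sorted(truth, "truth")
    candidates: list[tuple[float, int, int, int]] = []
    for ci, c in enumerate(calls):
        for ti, t in enumerate(truth):
            if c.chrom != t.chrom:
                continue
            if not _types_compatible(c.sv_type, t.sv_type, dup_to_ins):
                continue
            dist = abs(c.pos - t.pos)
            if dist > refdist:
                continue
            if c.svlen == 0 or t.svlen == 0:
                continue
            ratio = min(c.svlen, t.svlen) / max(c.svlen, t.svlen)
            if ratio < pctsize:
                continue
            candidates.append((ratio, dist, ci, ti))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2], x[3]))
    used_c: set[int] = set()
    used_t: set[int] = set()
    pairs: list[MatchPair] = []
    for ratio, dist, ci, ti in candidates:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        pairs.append(
            MatchPair(
                call_idx=ci,
                truth_idx=ti,
                size_ratio=ratio,
                distance=dist,
                gt_match=(
                    calls[ci].gt == truth[ti].gt and calls[ci].gt != "./."
                ),
            )
        )
    pairs.sort(key=lambda p: (p.truth_idx, p.call_idx))
    return Matching(calls=calls, truth=truth, pairs=pairs)


def metrics(
    tp_call: int, fp_call: int, tp_base: int, fn_base: int
) -> tuple[float, float, float]:
    """Precision, recall and F1; any 0/0 denominator yields 0."""
    precision = tp_call / (tp_call + fp_call) if tp_call + fp_call else 0.0
    recall = tp_base / (tp_base + fn_base) if tp_base + fn_base else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1


def _counts(
    matching: Matching,
    level: str,
    call_subset: set[int] | None = None,
    truth_subset: set[int] | None = None,
) -> BenchResult:
    if level not in ("presence", "gt"):
        raise ValueError("level must be 'presence' or 'gt'")
    n_calls = (
        len(matching.calls) if call_subset is None else len(call_subset)
    )
    n_truth = (
        len(matching.truth) if truth_subset is None else len(truth_subset)
    )
    tp = 0
    for p in matching.pairs:
        if call_subset is not None and p.call_idx not in call_subset:
            continue
        if truth_subset is not None and p.truth_idx not in truth_subset:
            continue
        if level == "presence" or p.gt_match:
            tp += 1
    return BenchResult.from_counts(tp, n_calls - tp, tp, n_truth - tp)


def summarize(matching: Matching, level: str = "presence") -> BenchResult:
    """Overall TP/FP/FN tallies and metrics at one level."""
    return _counts(matching, level)


def stratify(matching: Matching) -> dict[str, dict[str, BenchResult]]:
    """Per-SV-type results; matched pairs count under the truth type so the
    per-type tallies sum to the overall ones."""
    matched_calls = {p.call_idx: p.truth_idx for p in matching.pairs}
    out: dict[str, dict[str, BenchResult]] = {}
    for sv_type in sorted(_TYPES):
        truth_subset = {
            i for i, t in enumerate(matching.truth) if t.sv_type == sv_type
        }
        call_subset = set()
        for i, c in enumerate(matching.calls):
            if i in matched_calls:
                if matching.truth[matched_calls[i]].sv_type == sv_type:
                    call_subset.add(i)
            elif c.sv_type == sv_type:
                call_subset.add(i)
        out[sv_type] = {
            "presence": _counts(matching, "presence", call_subset, truth_subset),
            "gt": _counts(matching, "gt", call_subset, truth_subset),
        }
    return out


def bench(
    calls_path: str,
    truth_path: str,
    bed_path: str | None = None,
    refdist: int = 500,
    pctsize: float = 0.7,
    dup_to_ins: bool = False,
) -> dict:
    """Full benchmark: load, optionally region-filter, match, and report
    overall plus per-type presence/GT metrics as a JSON-ready dict."""
    calls = load_vcf(calls_path)
    truth = load_vcf(truth_path)
    if bed_path:
        regions = load_bed(bed_path)
        calls = filter_region(calls, regions)
        truth = filter_region(truth, regions)
    matching = match_calls(
        calls, truth, refdist=refdist, pctsize=pctsize, dup_to_ins=dup_to_ins
    )
    report = {
        "n_calls": len(calls),
        "n_truth": len(truth),
        "overall": {
            "presence": summarize(matching, "presence").as_dict(),
            "gt": summarize(matching, "gt").as_dict(),
        },
        "by_type": {
            sv_type: {lvl: res.as_dict() for lvl, res in levels.items()}
            for sv_type, levels in stratify(matching).items()
        },
    }
    return report
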