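"""Haplotype-conditioned clustering of SV signatures.

Signatures of one SV type on one chromosome are grouped by single-linkage
clustering: two clusters merge whenever any signature pair across them is
similar enough.  Similarity is either positional,

    max(|L1 - L2|, |R1 - R2|) < F * m,

or relative,

    max(|L1 - L2|, |R1 - R2|, |len1 - len2|) / min(len1, len2) < CR * m,

where the multiplier m is SR (< 1, stricter) when both signatures carry the
same haplotype tag, DR (> 1, looser) when they carry different tags, and 1
when either is untagged.  After clustering, a cluster whose per-haplotype
mean lengths differ significantly (|M1 - M2| > max(SD1, SD2)) is disunited
into one cluster per haplotype, recovering two overlapping heterozygous SVs
that classical position/length clustering would fuse into one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean, pstdev
from typing import Iterable, Mapping, NamedTuple, Sequence

from .sig_extract import Signature

__all__ = [
    "ClusterParams",
    "Cluster",
    "ClusterStats",
    "haplotype_multiplier",
    "pair_mergeable",
    "cluster_signatures",
    "cluster_stats",
    "significantly_different",
    "split_by_haplotype",
]


@dataclass(frozen=True, slots=True)
class ClusterParams:
    """Per-SV-type merge tolerances.

    F: absolute breakpoint tolerance in bp.
    CR: relative tolerance (ratio of the largest coordinate/length difference
        to the smaller length).
    SR: multiplier applied for same-haplotype pairs, in [0, 1].
    DR: multiplier applied for different-haplotype pairs, >= 1.
    """

    F: float = 500.0
    CR: float = 0.3
    SR: float = 0.8
    DR: float = 1.3

    def __post_init__(self) -> None:
        if self.F <= 0:
            raise ValueError("F must be > 0")
        if self.CR <= 0:
            raise ValueError("CR must be > 0")
        if not 0 <= self.SR <= 1:
            raise ValueError("SR must be in [0, 1]")
        if self.DR < 1:
            raise ValueError("DR must be >= 1")


class ClusterStats(NamedTuple):
    """Summary statistics of one cluster.

    n: total signatures; m: signatures from tagged reads; h1/h2: counts per
    haplotype; m1/m2 and sd1/sd2: per-haplotype length mean and population
    standard deviation (0.0 when the haplotype is absent); mean_pos and
    mean_len: means over all signatures.
    """

    n: int
    m: int
    h1: int
    h2: int
    m1: float
    m2: float
    sd1: float
    sd2: float
    mean_pos: float
    mean_len: float


@dataclass(slots=True)
class Cluster:
    """A set of same-type, same-chromosome signatures hypothesised to arise
    from one SV."""

    chrom: str
    sv_type: str
    signatures: tuple[Signature, ...]

    def __post_init__(self) -> None:
        if not self.signatures:
            raise ValueError("cluster must contain at least one signature")
        for s in self.signatures:
            if s.chrom != self.chrom or s.sv_type != self.sv_type:
                raise ValueError("all signatures must share chrom and sv_type")

    @property
    def support(self) -> int:
        """Number of distinct supporting reads."""
        return len({s.read_id for s in self.signatures})


_SIG_ORDER = lambda s: (s.left, s.right, s.length, s.read_id, s.haplotype, s.source)


def haplotype_multiplier(s1: Signature, s2: Signature, params: ClusterParams) -> float:
    """SR for a same-haplotype pair, DR for a cross-haplotype pair, 1 when
    either signature is untagged."""
    if s1.haplotype == 0 or s2.haplotype == 0:
        return 1.0
    return params.SR if s1.haplotype == s2.haplotype else params.DR


def pair_mergeable(s1: Signature, s2: Signature, params: ClusterParams) -> bool:
    """True iff the two signatures satisfy the positional or the relative
    merge condition (strict inequalities, both tolerances scaled by the
    haplotype multiplier)."""
    m = haplotype_multiplier(s1, s2, params)
    dl = abs(s1.left - s2.left)
    dr = abs(s1.right - s2.right)
    if max(dl, dr) < params.F * m:
        return True
    mn = min(s1.length, s2.length)
    if mn <= 0:
        return False
    return max(dl, dr, abs(s1.length - s2.length)) / mn < params.CR * m


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _cluster_group(sigs: list[Signature], params: ClusterParams) -> list[Cluster]:
    """Single-linkage closure over one (chrom, sv_type) group.

    Signatures are scanned in left-coordinate order; a pair (i, j) with
    i < j can only be mergeable if left_j - left_i < DR * max(F, CR * len_j)
    (the multiplier never exceeds DR and min(len_i, len_j) <= len_j), so the
    backward scan stops at that bound without missing any mergeable pair.
    The result therefore equals the brute-force transitive closure.
    """
    sigs = sorted(sigs, key=_SIG_ORDER)
    n = len(sigs)
    uf = _UnionFind(n)
    for j in range(n):
        bound = params.DR * max(params.F, params.CR * sigs[j].length)
        for i in range(j - 1, -1, -1):
            if sigs[j].left - sigs[i].left >= bound:
                break
            if pair_mergeable(sigs[i], sigs[j], params):
                uf.union(i, j)
    groups: dict[int, list[Signature]] = {}
    for i, s in enumerate(sigs):
        groups.setdefault(uf.find(i), []).append(s)
    clusters = [
        Cluster(chrom=g[0].chrom, sv_type=g[0].sv_type, signatures=tuple(g))
        for g in groups.values()
    ]
    clusters.sort(key=lambda c: _SIG_ORDER(c.signatures[0]))
    return clusters


def cluster_signatures(
    signatures: Iterable[Signature],
    params: ClusterParams | Mapping[str, ClusterParams],
) -> list[Cluster]:
    """Partition signatures into clusters, per (chrom, sv_type).

    ``params`` is a single :class:`ClusterParams` or a mapping from SV type
    to one.  The output is independent of input order.
    """
    by_group: dict[tuple[str, str], list[Signature]] = {}
    for s in signatures:
        by_group.setdefault((s.chrom, s.sv_type), []).append(s)
    out: list[Cluster] = []
    for (chrom, sv_type) in sorted(by_group):
        p = params[sv_type] if isinstance(params, Mapping) else params
        out.extend(_cluster_group(by_group[(chrom, sv_type)], p))
    return out


def cluster_stats(cluster: Cluster) -> ClusterStats:
    """Counts, per-haplotype length mean/SD (population SD; singleton SD is
    0), and overall mean position/length of a cluster."""
    lens1 = [s.length for s in cluster.signatures if s.haplotype == 1]
    lens2 = [s.length for s in cluster.signatures if s.haplotype == 2]
    all_lens = [s.length for s in cluster.signatures]
    all_pos = [s.left for s in cluster.signatures]

    def _mean_sd(v: list[int]) -> tuple[float, float]:
        if not v:
            return 0.0, 0.0
        return fmean(v), (pstdev(v) if len(v) > 1 else 0.0)

    m1, sd1 = _mean_sd(lens1)
    m2, sd2 = _mean_sd(lens2)
    return ClusterStats(
        n=len(cluster.signatures),
        m=len(lens1) + len(lens2),
        h1=len(lens1),
        h2=len(lens2),
        m1=m1,
        m2=m2,
        sd1=sd1,
        sd2=sd2,
        mean_pos=fmean(all_pos),
        mean_len=fmean(all_lens),
    )


def significantly_different(m1: float, sd1: float, m2: float, sd2: float) -> bool:
    """Two per-haplotype mean lengths differ significantly when the gap
    exceeds the larger of the two standard deviations."""
    return abs(m1 - m2) > max(sd1, sd2)


def split_by_haplotype(cluster: Cluster) -> list[Cluster]:
    """Disunite a cluster into per-haplotype clusters when warranted.

    If both haplotypes contribute signatures and their mean lengths are
    significantly different, two clusters are returned (haplotype-1 and
    haplotype-2 signatures); each untagged signature joins the side whose
    mean length is nearer to its own (ties go to haplotype 1).  Otherwise
    the cluster is returned unchanged.  The total signature count is
    conserved either way.
    """
    st = cluster_stats(cluster)
    if st.h1 == 0 or st.h2 == 0:
        return [cluster]
    if not significantly_different(st.m1, st.sd1, st.m2, st.sd2):
        return [cluster]
    side1: list[Signature] = []
    side2: list[Signature] = []
    for s in cluster.signatures:
        if s.haplotype == 1:
            side1.append(s)
        elif s.haplotype == 2:
            side2.append(s)
        elif abs(s.length - st.m1) <= abs(s.length - st.m2):
            side1.append(s)
        else:
            side2.append(s)
    return [
        Cluster(chrom=cluster.chrom, sv_type=cluster.sv_type, signatures=tuple(side))
        for side in (side1, side2)
    ]
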