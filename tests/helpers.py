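"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import pysam

from hapsv.hap_cluster import Cluster, ClusterParams, pair_mergeable
from hapsv.sig_extract import Signature


def sig(
    left: int,
    length: int,
    sv_type: str = "DEL",
    hap: int = 0,
    read_id: str | None = None,
    chrom: str = "chr1",
    source: str = "cigar",
    right: int | None = None,
) -> Signature:
    if right is None:
        if sv_type == "DEL":
            right = left + length
        elif sv_type == "INS":
            right = left
        else:
            right = left + length
    return Signature(
        chrom=chrom,
        left=left,
        right=right,
        length=length,
        sv_type=sv_type,
        read_id=read_id if read_id is not None else f"r{left}.{length}.{hap}",
        haplotype=hap,
        source=source,
    )


def cluster_of(*signatures: Signature) -> Cluster:
    return Cluster(
        chrom=signatures[0].chrom,
        sv_type=signatures[0].sv_type,
        signatures=tuple(signatures),
    )


def brute_force_clusters(
    signatures: list[Signature], params: ClusterParams
) -> set[frozenset[Signature]]:
    """Independent O(n^2) transitive closure over pair_mergeable.

    Builds the full similarity graph and returns its connected components
    (depth-first search, no union-find), as a set of frozensets.
    """
    by_group: dict[tuple[str, str], list[Signature]] = {}
    for s in signatures:
        by_group.setdefault((s.chrom, s.sv_type), []).append(s)
    components: set[frozenset[Signature]] = set()
    for group in by_group.values():
        n = len(group)
        adj: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if pair_mergeable(group[i], group[j], params):
                    adj[i].append(j)
                    adj[j].append(i)
        seen = [False] * n
        for start in range(n):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                v = stack.pop()
                comp.append(group[v])
                for w in adj[v]:
                    if not seen[w]:
                        seen[w] = True
                        stack.append(w)
            components.add(frozenset(comp))
    return components


def clusters_as_sets(clusters: list[Cluster]) -> set[frozenset[Signature]]:
    return {frozenset(c.signatures) for c in clusters}


def make_bam(path: str, records: list[dict], contigs: dict[str, int]) -> str:
    """Write a coordinate-sorted indexed BAM from record dicts.

    Each dict: name, chrom, pos, cigar (string), plus optional flags
    (is_reverse, is_supplementary, is_secondary, is_unmapped) and hp.
    """
    header = pysam.AlignmentHeader.from_references(
        list(contigs), list(contigs.values())
    )
    alns = []
    for rec in records:
        a = pysam.AlignedSegment(header)
        a.query_name = rec["name"]
        a.reference_name = rec["chrom"]
        a.reference_start = rec["pos"]
        a.cigarstring = rec["cigar"]
        a.mapping_quality = rec.get("mapq", 60)
        flag = 0
        if rec.get("is_reverse"):
            flag |= 0x10
        if rec.get("is_secondary"):
            flag |= 0x100
        if rec.get("is_supplementary"):
            flag |= 0x800
        a.flag = flag
        qlen = sum(
            ln for op, ln in a.cigartuples or [] if op in (0, 1, 4, 7, 8)
        )
        a.query_sequence = "A" * qlen
        if "hp" in rec:
            a.set_tag("HP", rec["hp"], value_type="i")
        alns.append(a)
    order = {name: i for i, name in enumerate(contigs)}
    alns.sort(key=lambda a: (order[a.reference_name], a.reference_start))
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for a in alns:
            bam.write(a)
    pysam.index(path)
    return path
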