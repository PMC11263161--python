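"""Filtering, genotyping and VCF refinement of signature clusters.

A cluster must clear a minimum-support threshold, FF + FR * Cov, and a
minimum length-homogeneity ("consistent") score FS, where the consistent
score is 1 - SD(lengths) / max(lengths).  Two parameter sets (a permissive
and a strict one) are evaluated; a cluster passes if it satisfies either.

Both thresholds are scaled by a factor SC derived from the cluster's
haplotype-tagging quality: with H = M/N the tagged fraction and
HR = max(H1, H2)/M the majority-haplotype fraction,

    H > H0, HR > HR0:  SC = 1 - (HomoSF + HomoSR * (H - H0))     (relax)
    H > H0, HR <= HR0: SC = 1 - (NonHomoSF + NonHomoSR * (H - H0))
    H <= H0:           SC = 1 + (LowHRF + LowHRR * (H0 - H))     (tighten)

so well-tagged clusters face relaxed thresholds and poorly tagged ones face
stricter thresholds.  Passing clusters are genotyped (haplotype composition
first, read allele fraction as fallback) and refined into VCF records whose
POS and SVLEN are the means of the clustered signature positions and
lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pysam

from .hap_cluster import Cluster, ClusterStats, cluster_stats
from .sig_extract import SV_TYPES

__all__ = [
    "FilterSet",
    "FilterParams",
    "SVCall",
    "consistent_score",
    "haplotype_scale",
    "apply_filter",
    "genotype_call",
    "refine_call",
    "write_vcf",
]

# floor keeping the scale factor positive under extreme parameters
_SC_FLOOR = 1e-6


@dataclass(frozen=True, slots=True)
class FilterSet:
    """One support/score threshold set.

    FF: fixed support floor (reads); FR: support per fold of coverage;
    FS: minimum consistent score in [0, 1].
    """

    FF: float
    FR: float
    FS: float

    def __post_init__(self) -> None:
        if self.FF < 0 or self.FR < 0:
            raise ValueError("FF and FR must be >= 0")
        if not 0 <= self.FS <= 1:
            raise ValueError("FS must be in [0, 1]")


@dataclass(frozen=True, slots=True)
class FilterParams:
    """All filtering tunables for one SV type.

    ``HomoR`` is accepted for config compatibility but enters no formula.
    """

    set_a: FilterSet = FilterSet(FF=2.0, FR=0.2, FS=0.55)
    set_b: FilterSet = FilterSet(FF=1.0, FR=0.1, FS=0.75)
    H0: float = 0.8
    HR0: float = 0.8
    HomoSF: float = 0.05
    HomoSR: float = 0.25
    NonHomoSF: float = 0.0
    NonHomoSR: float = 0.1
    LowHRF: float = 0.05
    LowHRR: float = 0.25
    HomoR: float = 0.0

    def __post_init__(self) -> None:
        for name in ("H0", "HR0", "HomoSF", "HomoSR", "LowHRF", "LowHRR", "HomoR"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("NonHomoSF", "NonHomoSR"):
            v = getattr(self, name)
            if not -1 <= v <= 1:
                raise ValueError(f"{name} must be in [-1, 1], got {v}")

    def is_neutral(self) -> bool:
        """True when all six scale parameters are zero (SC == 1 always)."""
        return (
            self.HomoSF == self.HomoSR == self.NonHomoSF == self.NonHomoSR
            == self.LowHRF == self.LowHRR == 0
        )


@dataclass(slots=True)
class SVCall:
    """A refined, genotyped, filter-annotated VCF-ready SV record."""

    chrom: str
    pos: int  # 1-based
    sv_type: str
    svlen: int  # negative for DEL (VCF convention)
    end: int
    support: int
    consistent_score: float
    hap_fraction: float  # H
    majority_fraction: float  # HR
    scale: float  # SC
    gt: str
    filter_set: str | None = None

    @property
    def passed(self) -> bool:
        return self.filter_set is not None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (VCF coordinate)")
        if self.support < 1:
            raise ValueError("support must be >= 1")
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.gt not in ("0/1", "1/1", "./."):
            raise ValueError(f"unexpected genotype {self.gt!r}")


def consistent_score(cluster: Cluster) -> float:
    """Length-homogeneity score 1 - SD(lengths)/max(lengths).

    Population SD; 1.0 for a singleton or identical lengths.
    """
    lens = [s.length for s in cluster.signatures]
    mx = max(lens)
    if mx == 0 or len(lens) == 1:
        return 1.0
    mean = sum(lens) / len(lens)
    sd = math.sqrt(sum((x - mean) ** 2 for x in lens) / len(lens))
    return 1.0 - sd / mx


def haplotype_scale(stats: ClusterStats, params: FilterParams) -> float:
    """Tagging-quality scale factor SC applied to filter thresholds."""
    h = stats.m / stats.n
    hr = max(stats.h1, stats.h2) / stats.m if stats.m >= 1 else 0.0
    if h > params.H0:
        if hr > params.HR0:
            sc = 1.0 - (params.HomoSF + params.HomoSR * (h - params.H0))
        else:
            sc = 1.0 - (params.NonHomoSF + params.NonHomoSR * (h - params.H0))
    else:
        sc = 1.0 + (params.LowHRF + params.LowHRR * (params.H0 - h))
    return max(sc, _SC_FLOOR)


def apply_filter(
    cluster: Cluster, cov: float, params: FilterParams
) -> tuple[bool, str | None]:
    """Evaluate both threshold sets; return (passed, id of the passing set).

    Within a set the cluster must satisfy both the scaled support threshold,
    support >= SC * (FF + FR * Cov), and the scaled score threshold,
    score >= min(1, SC * FS).
    """
    sc = haplotype_scale(cluster_stats(cluster), params)
    score = consistent_score(cluster)
    support = cluster.support
    for set_id, fs in (("a", params.set_a), ("b", params.set_b)):
        if support >= sc * (fs.FF + fs.FR * cov) and score >= min(1.0, sc * fs.FS):
            return True, set_id
    return False, None


def genotype_call(
    cluster: Cluster,
    cov: float,
    params: FilterParams | None = None,
    use_haplotype: bool = True,
) -> str:
    """Assign 0/1, 1/1 or ./. to a passing cluster.

    When the cluster is well tagged (H > H0) the split of tagged signatures
    between haplotypes is the primary evidence: a minority-haplotype share
    >= 0.3 indicates both haplotypes carry the variant (1/1, confirmed
    against the read allele fraction when coverage is known), a share
    <= 0.1 indicates a single carrier haplotype (0/1), and the band in
    between defers to the allele fraction support/Cov (>= 0.75 -> 1/1,
    >= 0.2 -> 0/1, else ./.).  With ``use_haplotype=False`` only the allele
    fraction is used.
    """
    h0 = params.H0 if params is not None else 0.8
    st = cluster_stats(cluster)
    af = cluster.support / cov if cov > 0 else None
    hap_strong = use_haplotype and st.m > 0 and st.m / st.n > h0
    if hap_strong:
        minority = min(st.h1, st.h2) / st.m
        if minority >= 0.3 and (af is None or af >= 0.6):
            return "1/1"
        if af is not None and af >= 0.75:
            return "1/1"
        if minority <= 0.1:
            return "0/1"
        if af is None:
            return "1/1" if minority >= 0.2 else "0/1"
    if af is None:
        return "./."
    if af >= 0.75:
        return "1/1"
    if af >= 0.2:
        return "0/1"
    return "./."


def _round_half_away(x: float) -> int:
    """Round half away from zero (so a mean of 100.5 refines to 101)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def refine_call(
    cluster: Cluster,
    cov: float = 0.0,
    params: FilterParams | None = None,
    filter_set: str | None = None,
    use_haplotype_gt: bool = True,
) -> SVCall:
    """Refine a (passing) cluster into a VCF-ready call.

    POS is the rounded mean of signature left positions (1-based in the
    record), SVLEN the rounded mean length (negated for DEL), END = POS +
    |SVLEN| for DEL/DUP/INV and POS for INS.
    """
    st = cluster_stats(cluster)
    if params is None:
        params = FilterParams()
    pos = _round_half_away(st.mean_pos) + 1
    length = _round_half_away(st.mean_len)
    svlen = -length if cluster.sv_type == "DEL" else length
    end = pos if cluster.sv_type == "INS" else pos + length
    h = st.m / st.n
    hr = max(st.h1, st.h2) / st.m if st.m >= 1 else 0.0
    return SVCall(
        chrom=cluster.chrom,
        pos=pos,
        sv_type=cluster.sv_type,
        svlen=svlen,
        end=end,
        support=cluster.support,
        consistent_score=consistent_score(cluster),
        hap_fraction=h,
        majority_fraction=hr,
        scale=haplotype_scale(st, params),
        gt=genotype_call(cluster, cov, params, use_haplotype=use_haplotype_gt),
        filter_set=filter_set,
    )


_GT_TUPLES = {"0/1": (0, 1), "1/1": (1, 1), "./.": (None, None)}


def _build_header(contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    header.add_line('##ALT=<ID=INS,Description="Insertion">')
    header.add_line('##ALT=<ID=DUP,Description="Duplication">')
    header.add_line('##ALT=<ID=INV,Description="Inversion">')
    header.add_line(
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">'
    )
    header.add_line(
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length (negative for deletions)">'
    )
    header.add_line(
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">'
    )
    header.add_line(
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Distinct supporting reads">'
    )
    header.add_line(
        '##INFO=<ID=HAPF,Number=1,Type=Float,Description="Fraction of cluster signatures from haplotype-tagged reads (H)">'
    )
    header.add_line(
        '##INFO=<ID=HAPMAJ,Number=1,Type=Float,Description="Majority-haplotype fraction of tagged signatures (HR)">'
    )
    header.add_line(
        '##INFO=<ID=HAPSC,Number=1,Type=Float,Description="Tagging-quality filter scale factor (SC)">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample("SAMPLE")
    return header


def write_vcf(
    calls: list[SVCall],
    out_path: str,
    contigs: dict[str, int],
    reference: str | None = None,
) -> None:
    """Write calls as VCF 4.2 with symbolic ALT alleles.

    ``contigs`` maps contig name to length (defines the sort order).  The
    REF base is read from ``reference`` (FASTA path) when given, else "N".
    Calls must already be sorted by (chrom, pos); unsorted input raises
    before anything is written.
    """
    order = {name: i for i, name in enumerate(contigs)}
    for c in calls:
        if c.chrom not in order:
            raise ValueError(f"call contig {c.chrom!r} not in contig list")
    keys = [(order[c.chrom], c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (chrom, pos) before writing")

    fasta = pysam.FastaFile(reference) if reference else None
    try:
        header = _build_header(contigs)
        with pysam.VariantFile(out_path, "w", header=header) as vf:
            for i, c in enumerate(calls):
                if fasta is not None:
                    ref_base = fasta.fetch(c.chrom, c.pos - 1, c.pos).upper() or "N"
                else:
                    ref_base = "N"
                rec = vf.new_record(
                    contig=c.chrom,
                    start=c.pos - 1,
                    stop=c.end,
                    alleles=(ref_base, f"<{c.sv_type}>"),
                    id=f"hapsv.{c.sv_type}.{i}",
                )
                rec.info["SVTYPE"] = c.sv_type
                rec.info["SVLEN"] = c.svlen
                rec.info["SUPPORT"] = c.support
                rec.info["HAPF"] = round(c.hap_fraction, 4)
                rec.info["HAPMAJ"] = round(c.majority_fraction, 4)
                rec.info["HAPSC"] = round(c.scale, 4)
                rec.samples["SAMPLE"]["GT"] = _GT_TUPLES[c.gt]
                vf.write(rec)
    finally:
        if fasta is not None:
            fasta.close()
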