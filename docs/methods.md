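# Methods

## Signature model

A signature is one read's evidence for one candidate SV, held as a
`(chrom, left, right, length, type, read, haplotype, source)` tuple with
0-based half-open coordinates. Intra-read signatures come from CIGAR runs:
every `D` run ≥ `min_sv_size` (default 30 bp) becomes a DEL spanning its
reference interval, every `I` run ≥ `min_sv_size` an INS anchored at its
reference position. Same-type runs closer than `merge_gap` (default
500 bp) are merged — aligners routinely shatter one biological event into
nearby runs — with the merged length being the *sum* of run lengths. A
merged DEL is re-anchored at the first run with `right = left + length`:
the invariant that a DEL's span equals its length is kept deliberately,
because the right coordinate feeds the positional merge condition and
should track the SV extent implied by the summed length, not the
run-to-run gap structure.

Inter-read signatures come from the split alignments of one read, ordered
along the molecule. For adjacent same-strand segments, the difference
between the reference jump and the unaligned read gap classifies the
event (extra reference → DEL, extra read → INS, backward reference jump →
DUP); a strand switch marks an INV spanning the reverse-strand segment.
The haplotype of a split signature is the primary alignment's HP tag.

`min_sv_size` is set below the 50 bp SV definition on purpose: jittered
evidence for a 50-60 bp SV frequently dips under 50, and discarding it at
extraction time biases cluster means. The 50 bp floor is applied once, to
the refined `SVLEN` (`min_report_size`).

## Clustering

Per (chromosome, SV type), clustering is the transitive closure of the
pairwise merge relation (single linkage): positional similarity
`max(Δleft, Δright) < F·m` or relative similarity
`max(Δleft, Δright, Δlen)/min(len) < CR·m`, strict inequalities as
stated. The haplotype multiplier `m` is `SR` for same-haplotype pairs,
`DR` for cross-haplotype pairs, and exactly 1 when either signature is
untagged — an untagged read gives no evidence either way, so it must not
shift the thresholds.

The implementation scans signatures sorted by left coordinate and joins
pairs with union-find. A pair (i, j), i before j, can only merge if
`left_j − left_i < DR·max(F, CR·len_j)` (the multiplier never exceeds DR
and `min(len_i, len_j) ≤ len_j`), so the backward scan can stop at that
bound without missing any mergeable pair; the result provably equals the
O(n²) closure, and the test suite re-verifies this against an independent
graph-components oracle on 1000 randomized inputs.

Defaults: `F` = 500 bp (DEL/INS/DUP) and 600 bp (INV), `CR` = 0.3,
`SR` = 0.8, `DR` = 1.3 — chosen once near the tolerances common in
long-read callers; all per-type and configurable.

## Disunion of overlapping heterozygous SVs

After clustering, a cluster containing signatures from both haplotypes is
tested with `|M1 − M2| > max(SD1, SD2)` on the per-haplotype length means
and population standard deviations (singleton SD = 0, which keeps the test
well-defined for minimal clusters). On significance the cluster is split
into a haplotype-1 and a haplotype-2 cluster; each untagged signature
joins the side whose mean length is nearer to its own (ties to haplotype
1). The split is applied once per cluster, not recursively — the test
only distinguishes two haplotypes, so one split exhausts the information
it carries.

## Filtering, scaling and genotyping

A cluster passes one threshold set when `support ≥ SC·(FF + FR·Cov)` and
`consistent_score ≥ min(1, SC·FS)`; both conditions are required within a
set, and passing either of the two sets (defaults: a = (2, 0.2, 0.55),
b = (1, 0.1, 0.75)) suffices. `Cov` is the chromosome's mean primary-
alignment depth; `support` counts distinct reads. `SC·FS` is clamped at 1
so the score condition stays satisfiable. The scale factor SC follows the
three tagging-quality branches (see README); `H = H0` exactly falls in the
low-tagging branch, and SC is floored at a small positive value so
degenerate parameter choices cannot flip thresholds negative. Scale
defaults: `H0 = HR0 = 0.8`, `HomoSF = 0.05`, `HomoSR = 0.25`,
`NonHomoSF = 0`, `NonHomoSR = 0.1`, `LowHRF = 0.05`, `LowHRR = 0.25`,
kept within the declared parameter ranges; a `HomoR` key is accepted in
configs but enters no formula. With all six scale parameters at zero,
SC ≡ 1 and the filter reduces exactly to the unscaled two-set filter.

Genotyping combines two signals. When the cluster is well tagged
(`H > H0`), the minority-haplotype share of tagged signatures is primary:
≥ 0.3 (with an allele fraction of at least 0.6 when coverage is known)
means both haplotypes carry the variant → `1/1`; ≤ 0.1 means one carrier
haplotype → `0/1`; the band between defers to the allele fraction
`support/Cov` (≥ 0.75 → `1/1`, ≥ 0.2 → `0/1`, else `./.`), which is also
the complete rule for poorly tagged clusters. The allele fraction is
consulted *before* declaring `0/1` from a near-unanimous tagging pattern
because tagged reads are a binomial sample of the two haplotypes: a
homozygous cluster occasionally draws nearly all its tags from one side,
and the read-count signal is the robust tiebreaker in exactly that case.

Refinement sets `POS` (1-based) and `|SVLEN|` to the rounded means of
signature left positions and lengths, rounding half away from zero;
`SVLEN` is negated for DEL; `END = POS + |SVLEN|` except INS, where
`END = POS`. Calls with `|SVLEN| < 50` bp are dropped. The VCF carries
`SVTYPE`, `SVLEN`, `END`, `SUPPORT`, the cluster's `H`/`HR`/`SC`
(`HAPF`/`HAPMAJ`/`HAPSC`) and a `GT` sample field.

## Vanilla containment

A configuration with `SR = DR = 1` everywhere and all six scale parameters
zero makes haplotype labels formally inert in clustering and filtering.
The pipeline treats that configuration as a declaration that haplotype
information should not be used at all: HP tags are ignored at extraction
time, no disunion is attempted and genotypes come from the allele fraction
alone. A neutral run on a tagged BAM is therefore byte-identical (VCF
body) to the same run on a tag-stripped BAM — the haplotype-aware layer
cleanly contains the vanilla caller, which the test suite asserts. Users
who want Eq-3 disunion with otherwise neutral multipliers can set
`DR = 1 + ε`.

## Synthetic data

The simulator writes alignments directly — no raw-read simulation, no
external aligner — because the caller consumes alignment signatures, and
constructing them exactly controls the experiment. A random reference is
generated; DEL/INS/DUP/INV are planted non-overlapping with at least
`max(2·pos_jitter_sd + 600, 2500)` bp separation plus the maximum SV size
(so neighbouring events never fall within one another's merge reach), a
read-length margin from the chromosome ends, heterozygous events assigned
to a random haplotype. DUP is modelled as a tandem duplication and emitted
as an `I` run at the source locus, so the caller reports it as INS; the
benchmarking engine's `dup_to_ins` flag exists for exactly this
comparison. INV reads are emitted as a primary plus two supplementary
segments with a strand switch over the inverted interval.

Reads of fixed length are tiled per haplotype with one read per
`read_length/(depth/2)` stratum at a uniform random offset. Stratified
tiling makes local depth near-deterministic, which is what "depth 20×"
should mean as a study condition; with independent uniform starts the
per-SV support would be Poisson and a 100 %-recall expectation at 20×
would fail on a nontrivial fraction of seeds for reasons unrelated to the
method. Reads only partially overlapping a variant are trimmed back to
clean flanking sequence (iterated to a fixed point) so no truncated
signatures arise. Breakpoint position and length receive integer-rounded
Gaussian jitter per read and per event; each read is HP-tagged with
probability `tag_rate` and, if tagged, mislabelled with probability
`mistag_rate`. Sequencing substitution errors are not modelled — they
perturb SV calling only through breakpoint/length noise, which the jitter
parameters control directly; read bases are a constant filler since the
caller never inspects them.

What passing tests on this generator do **not** show: robustness to
alignment artefacts in low-complexity or repetitive sequence, reference
bias, chimeric reads, fragmented signatures of very large or nested
events, or realistic ONT error profiles. Results on real data depend on
those factors; the generator isolates the clustering/filtering/genotyping
logic from them by design.

## Benchmarking

Matching is sequence-free (type equality, start distance ≤ `refdist` =
500 bp, size ratio ≥ `pctsize` = 0.7) with greedy one-to-one assignment by
descending size ratio then ascending distance — a documented
simplification of truvari's internal ranking, adequate for synthetic
truth sets with well-separated events. Genotype-level TP additionally
requires identical (unphased, sorted) GT. Per-type stratification assigns
each matched pair to the *truth* record's type, so per-type tallies sum
exactly to the overall ones even under DUP↔INS cross-matching. Any 0/0
metric denominator yields 0. An optional BED restricts both calls and
truth to records whose POS falls in a half-open interval.

## Problem sizes and determinism

The shipped study conditions are a 2 Mb single-chromosome diploid genome,
40 planted SVs (10 per type, 50 % heterozygous, 50-500 bp), 20× depth and
10 kb reads — large enough for ~9 supporting reads per heterozygous event
and stable per-type metrics, small enough that the full suite and the
acceptance script each run in minutes on one CPU. The noisy replicates
use position/length jitter SDs of 30/15 bp, 85 % tagging and 2 %
mistagging. All randomness flows through seeded NumPy generators; a fixed
seed reproduces the truth set, the read set and the VCF byte-for-byte,
and the caller itself is deterministic (sorted scans, explicit
tie-breaks) for any fixed input.

## Known limitations

- Breakend (BND) notation, phased genotypes (`0|1` + PS) and multi-sample
  VCFs are out of scope.
- DUP calling relies on backward-jump split signatures; CIGAR-only tandem
  duplications are reported as INS at the source locus.
- The greedy matcher is not byte-compatible with truvari on adversarial
  many-to-many configurations.
- Coverage estimation counts primary alignments only, slightly
  undercounting depth around inversions represented as split reads (the
  effect lowers support thresholds marginally and is conservative).
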