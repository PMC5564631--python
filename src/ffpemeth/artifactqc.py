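"""Strand-resolved C>T deamination testing and on/off-target analysis.

Deamination vs SNV
------------------
At a candidate C>T position (forward-strand C) only antisense evidence can
separate a true variant from a bisulfite/deamination artifact: reads from
the original-bottom (OB) strand carry the antisense base, which is A for a
real T allele (the SNV hit both strands) and G when the forward strand's T
arose on one strand only (hydrolytic deamination, or ordinary conversion of
an unmethylated C).  In SAM storage (forward convention) the antisense A
appears as T and the antisense G as C; counts are reported on the antisense
basis (count_A, count_G).  The first and last bases of each read are
excluded (default 10 bp each) and only primary, non-duplicate alignments are
used.

The pair test is a two-sided Fisher exact test on the 2x2 table of A/G
counts in the two samples: p is the sum of hypergeometric probabilities of
all tables (fixed margins) no more probable than the observed one.

On/off-target
-------------
A primary, non-duplicate, mapped read is on-target iff its alignment span
overlaps any (merged) target by at least 1 bp.  Off-target alignment spans
are merged (overlapping or book-ended joined, gap 0 by default) into
off-target regions, whose pairwise intersections across samples are
reported in bp.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bsio import AlignedRead, GenomicSite, Region, merge_regions, sort_regions
from .methcall import bisulfite_strand

__all__ = [
    "DeaminationCounts",
    "DeaminationResult",
    "TargetStats",
    "deamination_counts",
    "deamination_test",
    "fisher_exact_two_sided",
    "target_stats",
    "offtarget_overlap",
    "offtarget_preservation_test",
]


# ---------------------------------------------------------------------------
# deamination
# ---------------------------------------------------------------------------

@dataclass
class DeaminationCounts:
    """Antisense A/G tallies at candidate C>T sites for one sample."""

    label: str
    per_site: pd.DataFrame  # chrom, pos, count_A, count_G

    @property
    def count_A(self) -> int:
        return int(self.per_site["count_A"].sum())

    @property
    def count_G(self) -> int:
        return int(self.per_site["count_G"].sum())

    @property
    def snv_fraction(self) -> float:
        """A / (A+G): the fraction of antisense evidence supporting a true SNV."""
        tot = self.count_A + self.count_G
        return self.count_A / tot if tot else float("nan")

    @property
    def artifact_fraction(self) -> float:
        """G / (A+G): antisense evidence pointing at a single-strand origin."""
        tot = self.count_A + self.count_G
        return self.count_G / tot if tot else float("nan")


def deamination_counts(
    reads: Iterable[AlignedRead],
    ct_candidates: Sequence[GenomicSite],
    reference: Mapping[str, str],
    end_clip: int = 10,
    label: str = "",
) -> DeaminationCounts:
    """Tally antisense A/G evidence at candidate C>T sites.

    Only OB-strand (antisense-informative), primary, non-duplicate reads
    contribute; bases within ``end_clip`` of either read end are skipped.
    A candidate outside the reference is an error.
    """
    sites: dict[tuple[str, int], list[int]] = {}
    for s in ct_candidates:
        if s.chrom not in reference or s.pos >= len(reference[s.chrom]):
            raise ValueError(f"candidate {s.chrom}:{s.pos} outside reference")
        sites[(s.chrom, s.pos)] = [0, 0]  # [A, G] on the antisense basis
    for read in reads:
        if read.is_unmapped or not read.is_primary or read.is_duplicate:
            continue
        if bisulfite_strand(read) != "OB":
            continue
        qlen = read.query_length
        for qpos, rpos in read.aligned_pairs():
            key = (read.chrom, rpos)
            if key not in sites:
                continue
            cycle = (qlen - qpos) if read.is_reverse else (qpos + 1)
            if cycle <= end_clip or cycle > qlen - end_clip:
                continue
            base = read.seq[qpos]
            if base == "T":  # stored T = antisense A = true T allele
                sites[key][0] += 1
            elif base == "C":  # stored C = antisense G = reference C
                sites[key][1] += 1
    rows = [(c, p, a, g) for (c, p), (a, g) in sorted(sites.items())]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "count_A", "count_G"])
    return DeaminationCounts(label=label, per_site=df)


@dataclass
class DeaminationResult:
    """2x2 Fisher comparison of antisense A/G counts between two samples."""

    label_a: str
    label_b: str
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: samples; cols: A, G
    p: float
    degenerate: bool
    snv_fraction_a: float
    snv_fraction_b: float

    @property
    def direction(self) -> str | None:
        """Which sample shows the higher artifact (G) fraction, if any."""
        fa = 1.0 - self.snv_fraction_a if not math.isnan(self.snv_fraction_a) else float("nan")
        fb = 1.0 - self.snv_fraction_b if not math.isnan(self.snv_fraction_b) else float("nan")
        if math.isnan(fa) or math.isnan(fb) or fa == fb:
            return None
        return self.label_a if fa > fb else self.label_b


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> tuple[float, bool]:
    """Two-sided Fisher exact p for a 2x2 table.

    The p-value is the sum over the hypergeometric support of probabilities
    <= the observed table's probability.  Small tables (N <= 300) are summed
    in exact rational arithmetic; larger tables in log space with a 1e-12
    relative tolerance for ties.  Returns (p, degenerate) where degenerate
    flags a zero margin (p is 1 by convention).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n1, n2 = a + b, c + d
    k = a + c  # first-column margin
    N = n1 + n2
    if n1 == 0 or n2 == 0 or k == 0 or k == N:
        return 1.0, True
    lo, hi = max(0, k - n2), min(k, n1)
    if N <= 300:
        denom = math.comb(N, k)
        probs = [
            Fraction(math.comb(n1, x) * math.comb(n2, k - x), denom)
            for x in range(lo, hi + 1)
        ]
        obs = probs[a - lo]
        p = float(sum(pr for pr in probs if pr <= obs))
    else:
        xs = np.arange(lo, hi + 1)
        logp = sps.hypergeom.logpmf(xs, N, k, n1)
        obs = logp[a - lo]
        p = float(np.exp(logp[logp <= obs + 1e-12]).sum())
    return min(p, 1.0), False


def deamination_test(
    counts_a: DeaminationCounts, counts_b: DeaminationCounts
) -> DeaminationResult:
    """Fisher comparison of two samples' antisense A/G counts."""
    table = ((counts_a.count_A, counts_a.count_G),
             (counts_b.count_A, counts_b.count_G))
    p, degenerate = fisher_exact_two_sided(table)
    return DeaminationResult(
        label_a=counts_a.label,
        label_b=counts_b.label,
        table=table,
        p=p,
        degenerate=degenerate,
        snv_fraction_a=counts_a.snv_fraction,
        snv_fraction_b=counts_b.snv_fraction,
    )


# ---------------------------------------------------------------------------
# on/off-target
# ---------------------------------------------------------------------------

@dataclass
class TargetStats:
    """On/off-target accounting for one sample."""

    label: str
    total_reads: int
    filtered_reads: int  # primary, non-duplicate, mapped
    on_target_reads: int
    off_target_regions: list[Region] = field(default_factory=list)

    @property
    def off_target_reads(self) -> int:
        return self.filtered_reads - self.on_target_reads

    @property
    def on_target_rate(self) -> float:
        return self.on_target_reads / self.filtered_reads if self.filtered_reads else float("nan")

    @property
    def off_target_bp(self) -> int:
        return sum(len(r) for r in self.off_target_regions)


def target_stats(
    reads: Iterable[AlignedRead],
    targets: Sequence[Region],
    label: str = "",
    merge_gap: int = 0,
) -> TargetStats:
    """Classify reads on/off target and merge off-target alignment spans."""
    merged = merge_regions(targets)
    if not merged:
        raise ValueError("empty target set")
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for r in merged:
        starts, ends = by_chrom.setdefault(r.chrom, ([], []))
        starts.append(r.start)
        ends.append(r.end)
    total = filtered = on = 0
    off_spans: list[Region] = []
    for read in reads:
        total += 1
        if read.is_unmapped or not read.is_primary or read.is_duplicate:
            continue
        filtered += 1
        start, end = read.pos, read.reference_end
        hit = False
        if read.chrom in by_chrom:
            starts, ends = by_chrom[read.chrom]
            i = bisect_right(starts, end - 1) - 1  # last target starting before read end
            hit = i >= 0 and ends[i] > start
        if hit:
            on += 1
        else:
            off_spans.append(Region(read.chrom, start, end))
    return TargetStats(
        label=label,
        total_reads=total,
        filtered_reads=filtered,
        on_target_reads=on,
        off_target_regions=merge_regions(off_spans, gap=merge_gap),
    )


def _intersection_bp(a: Sequence[Region], b: Sequence[Region]) -> int:
    """Total bp of overlap between two disjoint sorted region sets."""
    a = sort_regions(a)
    b = sort_regions(b)
    i = j = bp = 0
    while i < len(a) and j < len(b):
        ra, rb = a[i], b[j]
        if ra.chrom != rb.chrom:
            if ra.chrom < rb.chrom:
                i += 1
            else:
                j += 1
            continue
        lo = max(ra.start, rb.start)
        hi = min(ra.end, rb.end)
        if hi > lo:
            bp += hi - lo
        if ra.end <= rb.end:
            i += 1
        else:
            j += 1
    return bp


def offtarget_overlap(stats_by_sample: Mapping[str, TargetStats]) -> pd.DataFrame:
    """Pairwise off-target intersection sizes (bp) and shared fractions."""
    labels = list(stats_by_sample)
    if len(labels) < 2:
        raise ValueError("need at least 2 samples")
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            ra = stats_by_sample[la].off_target_regions
            rb = stats_by_sample[lb].off_target_regions
            inter = _intersection_bp(ra, rb)
            bpa = stats_by_sample[la].off_target_bp
            bpb = stats_by_sample[lb].off_target_bp
            rows.append((
                la, lb, inter,
                inter / bpa if bpa else float("nan"),
                inter / bpb if bpb else float("nan"),
            ))
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "intersection_bp",
                       "fraction_of_a", "fraction_of_b"]
    )


def offtarget_preservation_test(
    stats_by_sample: Mapping[str, TargetStats],
    preservation: Mapping[str, str],
) -> tuple[float, pd.DataFrame]:
    """Fisher test of preservation type vs off-target region sharing.

    One documented interpretation of a cross-sample test on off-target
    regions: each sample's off-target regions are split into bp shared with
    at least one sample of the *other* preservation type vs unique bp; the
    totals are scaled to region counts (divided by the mean region size) and
    compared between FFPE and FF in a 2x2 Fisher test.
    """
    groups: dict[str, list[str]] = {}
    for label, ptype in preservation.items():
        groups.setdefault(ptype, []).append(label)
    if len(groups) != 2:
        raise ValueError("need exactly two preservation types")
    (type_a, labels_a), (type_b, labels_b) = sorted(groups.items())
    rows = []
    table = []
    for ptype, own, other in ((type_a, labels_a, labels_b), (type_b, labels_b, labels_a)):
        shared = unique = 0
        n_regions = 0
        for label in own:
            regs = stats_by_sample[label].off_target_regions
            n_regions += len(regs)
            other_regs = [r for lb in other for r in stats_by_sample[lb].off_target_regions]
            inter = _intersection_bp(regs, merge_regions(other_regs))
            tot = stats_by_sample[label].off_target_bp
            shared += inter
            unique += tot - inter
        mean_size = (shared + unique) / n_regions if n_regions else 1.0
        scale = max(mean_size, 1.0)
        table.append((int(round(shared / scale)), int(round(unique / scale))))
        rows.append((ptype, shared, unique, n_regions))
    p, _ = fisher_exact_two_sided(table)
    return p, pd.DataFrame(rows, columns=["preservation", "shared_bp", "unique_bp", "n_regions"])
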