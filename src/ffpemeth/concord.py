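"""Profile intersection, consensus, discordance and sensitivity analysis.

Two strand-resolved profiles are joined site-by-site; a paired site is
concordant iff the two category calls (hypo / intermediate / hyper) match.
A replicate *consensus* keeps sites covered at >= min_cov in both
replicates and labels disagreeing sites 'off'; 'off' sites are excluded
entirely from the sensitivity analysis (not counted as false positives).

Discordant paired sites are binned by the signed proportion difference
d = proportion_A - proportion_B (the FFPE-minus-FF axis when A is the FFPE
sample) over [-1, 1] in 0.02-wide half-open bins, the last bin closed.

Sensitivity against a gold-standard consensus is TP/(TP+FP) among sample
calls at gold (non-'off') sites with sample coverage >= c, for each minimum
coverage c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bsio import GenomicSite, Region
from .methcall import MethProfile

__all__ = [
    "ConsensusProfile",
    "ConcordanceSummary",
    "intersect_profiles",
    "build_consensus",
    "discordance_histogram",
    "coverage_proportion_curve",
    "sensitivity_by_coverage",
    "select_validation_targets",
    "HIST_BIN_WIDTH",
]

HIST_BIN_WIDTH = 0.02
OFF = "off"


@dataclass
class ConcordanceSummary:
    """Headline numbers of a pairwise profile intersection."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_intersect: int
    n_concordant: int
    per_category: pd.DataFrame  # category, n_both, n_concordant, concordant_fraction

    @property
    def n_discordant(self) -> int:
        return self.n_intersect - self.n_concordant

    @property
    def overlap_fraction_a(self) -> float:
        return self.n_intersect / self.n_a if self.n_a else float("nan")

    @property
    def overlap_fraction_b(self) -> float:
        return self.n_intersect / self.n_b if self.n_b else float("nan")

    @property
    def concordant_fraction(self) -> float:
        return self.n_concordant / self.n_intersect if self.n_intersect else float("nan")


def intersect_profiles(
    profile_a: MethProfile, profile_b: MethProfile
) -> tuple[ConcordanceSummary, pd.DataFrame]:
    """Site-keyed join of two profiles.

    Returns the summary and the per-site paired records (chrom, pos, strand,
    coverage and proportion in each sample, both categories, concordant
    flag).  Profiles are dictionaries keyed by site, so duplicate sites
    cannot occur within one profile; the TSV reader enforces the same.
    """
    shared = sorted(profile_a.calls.keys() & profile_b.calls.keys())
    rows = []
    for s in shared:
        ca, cb = profile_a[s], profile_b[s]
        rows.append((
            s.chrom, s.pos, s.strand,
            ca.coverage, round(ca.proportion, 6), ca.category,
            cb.coverage, round(cb.proportion, 6), cb.category,
            ca.category == cb.category,
        ))
    paired = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand",
                 "coverage_a", "proportion_a", "category_a",
                 "coverage_b", "proportion_b", "category_b", "concordant"],
    )
    if len(paired):
        grp = paired.groupby("category_a", sort=True)
        per_cat = grp.agg(
            n_both=("concordant", "size"), n_concordant=("concordant", "sum")
        ).reset_index().rename(columns={"category_a": "category"})
        per_cat["concordant_fraction"] = per_cat["n_concordant"] / per_cat["n_both"]
    else:
        per_cat = pd.DataFrame(
            columns=["category", "n_both", "n_concordant", "concordant_fraction"]
        )
    summary = ConcordanceSummary(
        label_a=profile_a.label,
        label_b=profile_b.label,
        n_a=len(profile_a),
        n_b=len(profile_b),
        n_intersect=len(paired),
        n_concordant=int(paired["concordant"].sum()) if len(paired) else 0,
        per_category=per_cat,
    )
    return summary, paired


@dataclass
class ConsensusProfile:
    """Replicate-consensus categories; 'off' marks replicate disagreement."""

    category: dict[GenomicSite, str]
    proportion: dict[GenomicSite, float] = field(default_factory=dict)  # annotation: replicate mean
    min_cov: int = 10
    source_labels: tuple[str, str] = ("", "")

    def __len__(self) -> int:
        return len(self.category)

    @property
    def n_off(self) -> int:
        return sum(1 for c in self.category.values() if c == OFF)

    def without_off(self) -> dict[GenomicSite, str]:
        return {s: c for s, c in self.category.items() if c != OFF}


def build_consensus(
    replicate_a: MethProfile, replicate_b: MethProfile, min_cov: int = 10
) -> ConsensusProfile:
    """Consensus of two replicates of one biological source.

    Keeps sites covered >= min_cov in both replicates; matching categories
    give that category, disagreement gives 'off'.  Proportions are carried
    along as an annotation (replicate mean), not part of the consensus call.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    category: dict[GenomicSite, str] = {}
    proportion: dict[GenomicSite, float] = {}
    for s in replicate_a.calls.keys() & replicate_b.calls.keys():
        ca, cb = replicate_a[s], replicate_b[s]
        if ca.coverage < min_cov or cb.coverage < min_cov:
            continue
        category[s] = ca.category if ca.category == cb.category else OFF
        proportion[s] = (ca.proportion + cb.proportion) / 2.0
    return ConsensusProfile(
        category=category,
        proportion=proportion,
        min_cov=min_cov,
        source_labels=(replicate_a.label, replicate_b.label),
    )


def discordance_histogram(paired: pd.DataFrame) -> pd.DataFrame:
    """Histogram of d = proportion_a - proportion_b over discordant sites.

    Bins cover [-1, 1] at width 0.02, half-open [edge, edge+0.02) with the
    final bin closed at 1.  Returns (bin_start, bin_end, count); counts sum
    to the number of discordant sites.
    """
    # round the edges to exact decimals so d values like -0.5 or 0.30 land in
    # their half-open bin rather than straddling a floating-point boundary
    edges = np.round(np.linspace(-1.0, 1.0, int(round(2 / HIST_BIN_WIDTH)) + 1), 12)
    disc = paired[~paired["concordant"]] if len(paired) else paired
    d = (disc["proportion_a"] - disc["proportion_b"]).to_numpy() if len(disc) else np.array([])
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame({
        "bin_start": np.round(edges[:-1], 10),
        "bin_end": np.round(edges[1:], 10),
        "count": counts,
    })


def coverage_proportion_curve(profile: MethProfile) -> pd.DataFrame:
    """Fraction of calls with coverage >= c, for c = 1..max coverage.

    Non-increasing, starting at 1.0 at c = 1.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    cov = np.array([c.coverage for c in profile.calls.values()])
    cmax = int(cov.max())
    cs = np.arange(1, cmax + 1)
    frac = [(cov >= c).mean() for c in cs]
    return pd.DataFrame({"min_coverage": cs, "fraction": frac})


@dataclass
class SensitivityCurve:
    """TP/(TP+FP) against a gold consensus, by minimum sample coverage."""

    table: pd.DataFrame  # min_coverage, tp, fp, sensitivity
    label: str = ""

    def sensitivity_at(self, c: int) -> float:
        row = self.table[self.table["min_coverage"] == c]
        return float(row["sensitivity"].iloc[0]) if len(row) else float("nan")

    @property
    def plateau(self) -> float:
        """Mean sensitivity over the top third of the coverage range."""
        t = self.table.dropna(subset=["sensitivity"])
        k = max(1, len(t) // 3)
        return float(t["sensitivity"].tail(k).mean())


def sensitivity_by_coverage(
    gold: ConsensusProfile,
    sample: MethProfile,
    max_cov: int = 30,
) -> SensitivityCurve:
    """Classify sample calls at gold sites as TP/FP per coverage threshold.

    Gold 'off' sites are excluded entirely.  For each c in 1..max_cov the
    sample calls at remaining gold sites with coverage >= c are TP when the
    categories match and FP otherwise; sensitivity = TP/(TP+FP).
    """
    gold_cat = gold.without_off()
    if not gold_cat:
        raise ValueError("gold consensus is empty after removing 'off' sites")
    records = []
    for s, gcat in gold_cat.items():
        call = sample.calls.get(s)
        if call is None:
            continue
        records.append((call.coverage, call.category == gcat))
    cov = np.array([r[0] for r in records], dtype=int)
    tp_flag = np.array([r[1] for r in records], dtype=bool)
    rows = []
    for c in range(1, max_cov + 1):
        sel = cov >= c
        tp = int((tp_flag & sel).sum())
        fp = int((~tp_flag & sel).sum())
        sens = tp / (tp + fp) if tp + fp else float("nan")
        rows.append((c, tp, fp, sens))
    return SensitivityCurve(
        table=pd.DataFrame(rows, columns=["min_coverage", "tp", "fp", "sensitivity"]),
        label=sample.label,
    )


def select_validation_targets(
    regions: Sequence[Region],
    profiles: Mapping[str, MethProfile],
    golds: Mapping[str, ConsensusProfile],
    min_cov: int = 10,
) -> pd.DataFrame:
    """Filter and annotate candidate validation regions.

    A region qualifies when it contains at least one site that (i) is called
    with coverage >= min_cov in *every* profile and (ii) has a non-'off'
    call in *every* gold consensus, with all golds agreeing on the category.
    Annotation per region: TP/FP status ('TP' if every sample matches the
    gold category at every qualifying site, 'FP' if none does, else
    'mixed') and the sharing stratum of gold-concordant samples
    ('all' / 'subset' / 'unique' / 'none').
    """
    rows = []
    labels = sorted(profiles)
    for region in regions:
        qual_sites: list[tuple[GenomicSite, str]] = []
        some_gold = next(iter(golds.values()))
        for s in some_gold.category:
            if not (region.start <= s.pos < region.end and s.chrom == region.chrom):
                continue
            gcats = {g.category.get(s) for g in golds.values()}
            if None in gcats or OFF in gcats or len(gcats) != 1:
                continue
            if all(
                s in profiles[l] and profiles[l][s].coverage >= min_cov
                for l in labels
            ):
                qual_sites.append((s, next(iter(gcats))))
        if not qual_sites:
            continue
        match_counts = []
        site_status = []
        concordant_labels: set[str] = set()
        for s, gcat in qual_sites:
            matches = [l for l in labels if profiles[l][s].category == gcat]
            concordant_labels.update(matches)
            match_counts.append(len(matches))
            site_status.append(
                "TP" if len(matches) == len(labels)
                else ("FP" if not matches else "mixed")
            )
        if all(st == "TP" for st in site_status):
            status = "TP"
        elif all(st == "FP" for st in site_status):
            status = "FP"
        else:
            status = "mixed"
        n_conc = len(concordant_labels)
        stratum = (
            "none" if n_conc == 0
            else "unique" if n_conc == 1
            else "all" if n_conc == len(labels)
            else "subset"
        )
        rows.append((
            region.chrom, region.start, region.end,
            len(qual_sites), status, stratum,
            ",".join(sorted(concordant_labels)),
        ))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_sites", "status",
                 "sharing", "concordant_samples"],
    )
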