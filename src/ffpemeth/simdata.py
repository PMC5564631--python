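"""Synthetic matched FFPE / fresh-frozen directional bisulfite datasets.

The generator emits everything a real run would consume — reference FASTA,
target BED, aligned paired-end SAM, candidate C>T VCF — plus truth sidecars,
so every downstream stage is testable without external sequencing data.

Generative model
----------------
A random reference carries CpG-enriched target regions.  Each target CpG
(both strands of the dyad sharing one level) receives a true methylation
level *m* drawn from a hypo / intermediate / hyper mixture (uniform within
each category's range).  Fragments start on-target with probability
``p_on_target``, otherwise uniformly on the reference; each fragment is a
directional (Lister-type) library molecule whose bisulfite strand (OT/OB)
is chosen uniformly, with read 1 reporting the converted strand.

Per fragment, each cytosine on the bisulfite strand is methylated with
probability m(site); an unmethylated cytosine is read as T with the stated
conversion efficiency.  FFPE-specific "bowing" is modelled as excess
conversion of *methylated* cytosines, linearly decaying over the first
``bowing_extent`` bases of each read: at read cycle k <= L the methylated
base is additionally converted with probability b0 * (1 - (k-1)/L).  The
fresh-frozen generative process is identical except the bowing depth, so
any FFPE-FF difference detected downstream on matched seeds is attributable
to the bowing parameters.

Deamination artifacts are single-strand by construction (a forward-strand C
read as T on OT fragments with a per-fragment probability; antisense reads
are unaffected and keep showing G), which is exactly what makes the
strand-resolved A/G test informative.  True C>T SNVs affect both strands at
a configurable allele fraction, so antisense reads show A.

Base qualities are emitted at a constant Phred 37; quality-driven filtering
is exercised by dedicated low-quality fixtures rather than a quality model.
Sequencing errors, indels and adapter read-through are out of scope (removed
upstream in the workflow this emulates).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .bsio import (
    BS_STRAND_TAG,
    AlignedRead,
    GenomicSite,
    Region,
    write_bed,
    write_fasta,
    write_vcf_sites,
)

__all__ = [
    "SimConfig",
    "TruthProfile",
    "SimConfigError",
    "simulate_reference",
    "simulate_truth",
    "uniform_truth",
    "derive_related_truth",
    "simulate_variant_sites",
    "simulate_reads",
    "simulate_dataset",
]

CHROM = "chrSim"

CATEGORY_RANGES = {
    "hypo": (0.0, 0.20),
    "intermediate": (0.20, 0.80),
    "hyper": (0.80, 1.0),
}
CATEGORIES = ("hypo", "intermediate", "hyper")


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """All knobs of the generative model.

    Defaults emulate the study design this package targets: paired-end
    125 bp directional reads, FFPE bowing over the first ~35 cycles, shorter
    FFPE inserts (fragmentation), a 0.36/0.42/0.22 hypo/intermediate/hyper
    mixture, and 80% on-target capture.
    """

    reference_length: int = 100_000
    n_targets: int = 8
    target_size: int = 2_000
    cpg_period: int = 20  # mean spacing of seeded CpGs inside targets
    mean_coverage: float = 30.0  # mean on-target read-base depth
    p_on_target: float = 0.8
    read_length: int = 125
    insert_mean_ffpe: float = 180.0
    insert_sd_ffpe: float = 40.0
    insert_mean_ff: float = 250.0
    insert_sd_ff: float = 50.0
    max_insert: int = 420
    conversion_efficiency: float = 0.99
    bowing_depth_ffpe: float = 0.3
    bowing_depth_ff: float = 0.0
    bowing_extent: int = 35
    n_deamination_sites: int = 0
    deamination_prob: float = 0.3
    n_snv_sites: int = 0
    snv_allele_fraction: float = 1.0
    candidate_min_spacing: int = 450
    category_weights: tuple[float, float, float] = (0.36, 0.42, 0.22)
    mapq: int = 60
    base_quality: int = 37
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_on_target": self.p_on_target,
            "conversion_efficiency": self.conversion_efficiency,
            "bowing_depth_ffpe": self.bowing_depth_ffpe,
            "bowing_depth_ff": self.bowing_depth_ff,
            "deamination_prob": self.deamination_prob,
            "snv_allele_fraction": self.snv_allele_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"{name}={p} outside [0, 1]")
        if not self.bowing_extent < self.read_length:
            raise SimConfigError("bowing_extent must be < read_length")
        w = self.category_weights
        if len(w) != 3 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise SimConfigError(f"category_weights {w} must be 3 non-negatives summing to 1")
        if self.n_targets * self.target_size > self.reference_length:
            raise SimConfigError("targets cannot fit in reference")
        if self.read_length < 1 or self.target_size < self.read_length:
            raise SimConfigError("target_size must be >= read_length")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


@dataclass
class TruthProfile:
    """Ground-truth methylation: site -> level m in [0,1] plus its category."""

    m: dict[GenomicSite, float]
    category: dict[GenomicSite, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.category:
            self.category = {s: _category_of(v) for s, v in self.m.items()}

    def __len__(self) -> int:
        return len(self.m)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tstrand\tm\tcategory\n")
            for s in sorted(self.m):
                fh.write(
                    f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.strand}\t"
                    f"{self.m[s]:.6f}\t{self.category[s]}\n"
                )


def _category_of(m: float) -> str:
    if m < 0.20:
        return "hypo"
    if m > 0.80:
        return "hyper"
    return "intermediate"


# ---------------------------------------------------------------------------
# reference and truth
# ---------------------------------------------------------------------------

def simulate_reference(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[Region]]:
    """Random reference with CpG-enriched, non-overlapping, sorted targets."""
    config.validate()
    rng = config.rng(0) if rng is None else rng
    n, L = config.n_targets, config.reference_length
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=L).astype("U1")

    # evenly spaced targets with a uniform jitter inside each slot
    slot = L // n
    if slot < config.target_size:
        raise SimConfigError("targets cannot fit in reference")
    targets = []
    for i in range(n):
        room = slot - config.target_size
        start = i * slot + (int(rng.integers(0, room + 1)) if room > 0 else 0)
        targets.append(Region(CHROM, start, start + config.target_size))

    # seed CpG dinucleotides inside targets at ~cpg_period spacing
    for t in targets:
        p = t.start + int(rng.integers(2, config.cpg_period))
        while p + 2 <= t.end:
            seq[p] = "C"
            seq[p + 1] = "G"
            p += 2 + int(rng.integers(2, 2 * config.cpg_period - 3))
    # break CpGs straddling a target edge so all target CpGs are interior
    for t in targets:
        if t.start > 0 and seq[t.start - 1] == "C" and seq[t.start] == "G":
            seq[t.start - 1] = "A"
        if t.end < L and seq[t.end - 1] == "C" and seq[t.end] == "G":
            seq[t.end] = "A"
    return {CHROM: "".join(seq)}, targets


def cpg_dyads(seq: str, regions: Sequence[Region], chrom: str = CHROM) -> list[int]:
    """Positions p (0-based) of the C of every CpG dinucleotide in regions."""
    out = []
    for r in regions:
        p = seq.find("CG", r.start, r.end)
        while p != -1:
            out.append(p)
            p = seq.find("CG", p + 1, r.end)
    return out


def simulate_truth(
    reference: Mapping[str, str],
    targets: Sequence[Region],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> TruthProfile:
    """Assign every target CpG cytosine (both strands) a category and level.

    Categories are drawn from ``category_weights``; the level is uniform
    within the category's range.  Symmetric CpG pairs share the level.
    """
    config.validate()
    rng = config.rng(1) if rng is None else rng
    w = np.asarray(config.category_weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise SimConfigError("category_weights must sum to 1")
    m: dict[GenomicSite, float] = {}
    cat: dict[GenomicSite, str] = {}
    for chrom, seq in reference.items():
        dyads = cpg_dyads(seq, [r for r in targets if r.chrom == chrom], chrom)
        if not dyads:
            continue
        ci = rng.choice(3, size=len(dyads), p=w)
        u = rng.random(len(dyads))
        for p, c, x in zip(dyads, ci, u):
            lo, hi = CATEGORY_RANGES[CATEGORIES[c]]
            level = lo + x * (hi - lo)
            for site in (GenomicSite(chrom, p, "+"), GenomicSite(chrom, p + 1, "-")):
                m[site] = level
                cat[site] = CATEGORIES[c]
    return TruthProfile(m, cat)


def uniform_truth(
    reference: Mapping[str, str], targets: Sequence[Region], level: float
) -> TruthProfile:
    """All-CpG truth at one fixed level (handy for diagnostics fixtures)."""
    m: dict[GenomicSite, float] = {}
    for chrom, seq in reference.items():
        for p in cpg_dyads(seq, [r for r in targets if r.chrom == chrom], chrom):
            m[GenomicSite(chrom, p, "+")] = level
            m[GenomicSite(chrom, p + 1, "-")] = level
    return TruthProfile(m)


def derive_related_truth(
    base: TruthProfile,
    share_fraction: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> TruthProfile:
    """A truth sharing ``share_fraction`` of CpG dyads with ``base``.

    Non-shared dyads are re-drawn with a category *different* from the base
    category (uniform level within the new category), which makes the sharing
    fraction identifiable from a downstream sensitivity plateau.
    """
    w = np.asarray(config.category_weights, dtype=float)
    m = dict(base.m)
    cat = dict(base.category)
    # group per dyad: the '+' site and its '-' partner share the draw
    fwd = sorted(s for s in base.m if s.strand == "+")
    for s in fwd:
        partner = GenomicSite(s.chrom, s.pos + 1, "-")
        if rng.random() < share_fraction:
            continue
        base_cat = base.category[s]
        others = [i for i, c in enumerate(CATEGORIES) if c != base_cat]
        ww = w[others]
        ci = others[int(rng.choice(len(others), p=ww / ww.sum()))]
        lo, hi = CATEGORY_RANGES[CATEGORIES[ci]]
        level = lo + rng.random() * (hi - lo)
        for site in (s, partner):
            if site in m:
                m[site] = level
                cat[site] = CATEGORIES[ci]
    return TruthProfile(m, cat)


# ---------------------------------------------------------------------------
# candidate variant sites
# ---------------------------------------------------------------------------

def simulate_variant_sites(
    reference: Mapping[str, str],
    targets: Sequence[Region],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[GenomicSite], list[GenomicSite]]:
    """Pick deamination-artifact and true-SNV sites among target cytosines.

    Sites are forward-strand Cs outside CpG context (neither strand of the
    dyad), spaced at least ``candidate_min_spacing`` apart so no fragment
    spans two candidates — each informative read then carries evidence for
    exactly one candidate.
    """
    config.validate()
    rng = config.rng(2) if rng is None else rng
    n_needed = config.n_deamination_sites + config.n_snv_sites
    if n_needed == 0:
        return [], []
    eligible: list[tuple[str, int]] = []
    for chrom, seq in reference.items():
        for r in targets:
            if r.chrom != chrom:
                continue
            for p in range(max(r.start, 1), min(r.end, len(seq) - 1)):
                if seq[p] == "C" and seq[p + 1] != "G" and seq[p - 1] != "C":
                    eligible.append((chrom, p))
    spaced: list[tuple[str, int]] = []
    last: dict[str, int] = {}
    for chrom, p in eligible:
        if chrom not in last or p - last[chrom] >= config.candidate_min_spacing:
            spaced.append((chrom, p))
            last[chrom] = p
    if len(spaced) < n_needed:
        raise SimConfigError(
            f"only {len(spaced)} spaced candidate cytosines available, "
            f"need {n_needed}; enlarge targets or reduce spacing"
        )
    pick = rng.permutation(len(spaced))[:n_needed]
    sites = [GenomicSite(spaced[i][0], spaced[i][1], "+") for i in pick]
    deam = sorted(sites[: config.n_deamination_sites])
    snv = sorted(sites[config.n_deamination_sites :])
    return deam, snv


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def _phred_string(q: int, n: int) -> str:
    return chr(q + 33) * n


def simulate_reads(
    reference: Mapping[str, str],
    targets: Sequence[Region],
    truth: TruthProfile,
    config: SimConfig,
    label: str,
    preservation: str,
    rng: np.random.Generator,
    deamination_sites: Sequence[GenomicSite] = (),
    snv_sites: Sequence[GenomicSite] = (),
    n_fragments: int | None = None,
) -> list[AlignedRead]:
    """Generate paired-end directional bisulfite reads for one sample.

    ``preservation`` selects the insert-size and bowing parameters ("FFPE"
    or "FF").  Reads come back in fragment order, mates adjacent, ready for
    :func:`ffpemeth.bsio.write_sam`.
    """
    config.validate()
    if preservation not in ("FFPE", "FF"):
        raise SimConfigError(f"preservation must be 'FFPE' or 'FF', got {preservation!r}")
    ffpe = preservation == "FFPE"
    b0 = config.bowing_depth_ffpe if ffpe else config.bowing_depth_ff
    L = config.bowing_extent
    ins_mu = config.insert_mean_ffpe if ffpe else config.insert_mean_ff
    ins_sd = config.insert_sd_ffpe if ffpe else config.insert_sd_ff
    rl = config.read_length
    ce = config.conversion_efficiency

    chrom = next(iter(reference))
    seq = reference[chrom]
    ref_arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    ref_len = len(seq)

    # precomputed cytosine tracks (forward strand Cs; bottom-strand Cs sit at
    # forward G positions and are stored as G/A evidence)
    fwd_c = np.flatnonzero(ref_arr == "C")
    rev_c = np.flatnonzero(ref_arr == "G")
    m_fwd = np.zeros(fwd_c.size)  # methylation prob per forward C (0 outside CpG truth)
    m_rev = np.zeros(rev_c.size)
    fwd_index = {int(p): i for i, p in enumerate(fwd_c)}
    rev_index = {int(p): i for i, p in enumerate(rev_c)}
    for site, level in truth.m.items():
        if site.strand == "+" and site.pos in fwd_index:
            m_fwd[fwd_index[site.pos]] = level
        elif site.strand == "-" and site.pos in rev_index:
            m_rev[rev_index[site.pos]] = level
    deam_pos = np.array(sorted(s.pos for s in deamination_sites), dtype=int)
    snv_pos = np.array(sorted(s.pos for s in snv_sites), dtype=int)

    total_target = sum(len(t) for t in targets)
    if n_fragments is None:
        n_on = config.mean_coverage * total_target / (2 * rl)
        n_fragments = int(round(n_on / config.p_on_target))
    t_starts = np.array([t.start for t in targets])
    t_lens = np.array([len(t) for t in targets], dtype=float)
    t_weights = t_lens / t_lens.sum()

    reads: list[AlignedRead] = []
    qual = _phred_string(config.base_quality, rl)

    for i in range(n_fragments):
        flen = int(round(rng.normal(ins_mu, ins_sd)))
        flen = max(rl, min(config.max_insert, flen))
        if rng.random() < config.p_on_target:
            ti = int(rng.choice(len(targets), p=t_weights))
            t = targets[ti]
            f = min(flen, len(t))
            s = int(t_starts[ti] + rng.integers(0, len(t) - f + 1))
            flen = f
        else:
            s = int(rng.integers(0, ref_len - flen + 1))
        e = s + flen
        ot = bool(rng.integers(0, 2))

        frag = ref_arr[s:e].copy()
        if ot:
            lo, hi = np.searchsorted(fwd_c, [s, e])
            cpos = fwd_c[lo:hi]
            mv = m_fwd[lo:hi]
            meth = rng.random(cpos.size) < mv
            conv = (~meth) & (rng.random(cpos.size) < ce)
            frag[cpos[conv] - s] = "T"
            # single-strand deamination: top-strand C read as T
            for p in deam_pos[np.searchsorted(deam_pos, s) : np.searchsorted(deam_pos, e)]:
                if rng.random() < config.deamination_prob:
                    frag[p - s] = "T"
            meth_rel = cpos[meth] - s  # surviving methylated Cs (bowing applies)
            converted_char = "T"
        else:
            lo, hi = np.searchsorted(rev_c, [s, e])
            cpos = rev_c[lo:hi]
            mv = m_rev[lo:hi]
            meth = rng.random(cpos.size) < mv
            conv = (~meth) & (rng.random(cpos.size) < ce)
            frag[cpos[conv] - s] = "A"  # stored-forward view of a converted bottom C
            meth_rel = cpos[meth] - s
            converted_char = "A"
        # true SNVs hit both strands; stored-forward evidence is T either way
        for p in snv_pos[np.searchsorted(snv_pos, s) : np.searchsorted(snv_pos, e)]:
            if rng.random() < config.snv_allele_fraction:
                frag[p - s] = "T"

        # mate windows in fragment coordinates, and per-read cycle positions
        r1_off = 0 if ot else flen - rl
        r2_off = flen - rl if ot else 0
        r1 = frag[r1_off : r1_off + rl].copy()
        r2 = frag[r2_off : r2_off + rl].copy()
        if b0 > 0 and meth_rel.size:
            for arr, off, reverse in ((r1, r1_off, not ot), (r2, r2_off, ot)):
                inwin = meth_rel[(meth_rel >= off) & (meth_rel < off + rl)]
                if not inwin.size:
                    continue
                k = (off + rl - inwin) if reverse else (inwin - off + 1)
                ramp = b0 * (1.0 - (k - 1) / L)
                hit = (k <= L) & (rng.random(inwin.size) < ramp)
                arr[inwin[hit] - off] = converted_char
        name = f"{label}:frag{i}"
        flag1 = 0x1 | 0x2 | 0x40 | (0x10 if not ot else 0) | (0x20 if ot else 0)
        flag2 = 0x1 | 0x2 | 0x80 | (0x10 if ot else 0) | (0x20 if not ot else 0)
        tag = "OT" if ot else "OB"
        pos1, pos2 = s + r1_off, s + r2_off
        common = dict(chrom=chrom, mapq=config.mapq, cigar=f"{rl}M", qual=qual)
        reads.append(
            AlignedRead(
                name=name, flag=flag1, pos=pos1, seq="".join(r1),
                tags={BS_STRAND_TAG: tag, "__rnext": chrom, "__pnext": pos2,
                      "__tlen": flen if pos1 <= pos2 else -flen},
                **common,
            )
        )
        reads.append(
            AlignedRead(
                name=name, flag=flag2, pos=pos2, seq="".join(r2),
                tags={BS_STRAND_TAG: tag, "__rnext": chrom, "__pnext": pos1,
                      "__tlen": flen if pos2 < pos1 else -flen},
                **common,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """Simulate one matched FFPE/FF pair plus sidecars into ``outdir``.

    Writes reference FASTA, target BED, per-sample SAM, truth TSV,
    deamination-site BED, SNV and combined-candidate VCFs, and the resolved
    config JSON.  Returns a manifest dict of the written files.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, targets = simulate_reference(config)
    truth = simulate_truth(reference, targets, config)
    deam, snv = simulate_variant_sites(reference, targets, config)
    refs = {c: len(s) for c, s in reference.items()}

    manifest = {"config": asdict(config)}
    write_fasta(outdir / "reference.fa", reference)
    write_bed(outdir / "targets.bed", targets)
    truth.write_tsv(outdir / "truth.tsv")
    write_bed(outdir / "deamination_sites.bed",
              [Region(s.chrom, s.pos, s.pos + 1) for s in deam])
    write_vcf_sites(outdir / "snv_truth.vcf", snv, refs)
    write_vcf_sites(outdir / "ct_candidates.vcf", sorted(deam + snv), refs)

    from .bsio import write_sam  # local import to keep module import light

    for preservation, stream in (("FFPE", 3), ("FF", 4)):
        label = f"sample_{preservation}"
        reads = simulate_reads(
            reference, targets, truth, config, label, preservation,
            rng=config.rng(stream), deamination_sites=deam, snv_sites=snv,
        )
        write_sam(outdir / f"{label}.sam", reads, refs)
        manifest[label] = f"{label}.sam"
    manifest.update(
        reference="reference.fa", targets="targets.bed", truth="truth.tsv",
        deamination_sites="deamination_sites.bed", snv_truth="snv_truth.vcf",
        ct_candidates="ct_candidates.vcf",
    )
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(manifest["config"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def with_overrides(config: SimConfig, **kwargs) -> SimConfig:
    """Functional update helper (dataclasses.replace with validation)."""
    cfg = replace(config, **kwargs)
    cfg.validate()
    return cfg
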