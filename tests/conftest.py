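"""Shared fixtures: tiny references, handcrafted SAM builders, and small
simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from ffpemeth import simdata
from ffpemeth.bsio import BS_STRAND_TAG, AlignedRead, Region

CHROM = "chrT"


def make_reference(rng: np.random.Generator, length: int = 3000, cpg_every: int = 15) -> str:
    """Random sequence with CpGs planted roughly every ``cpg_every`` bp."""
    seq = rng.choice(list("ACGT"), size=length)
    p = int(rng.integers(2, cpg_every))
    while p + 2 < length:
        seq[p] = "C"
        seq[p + 1] = "G"
        p += 2 + int(rng.integers(2, 2 * cpg_every))
    return "".join(seq)


def make_read(
    name: str,
    pos: int,
    seq: str,
    *,
    flag: int | None = None,
    mate: int = 1,
    reverse: bool = False,
    bs_strand: str | None = "OT",
    mapq: int = 60,
    qual: str | None = None,
    cigar: str | None = None,
    duplicate: bool = False,
    secondary: bool = False,
    chrom: str = CHROM,
) -> AlignedRead:
    """Handcrafted alignment with sensible defaults for fixture building."""
    if flag is None:
        flag = 0x1 | 0x2
        flag |= 0x40 if mate == 1 else 0x80
        if reverse:
            flag |= 0x10
        if duplicate:
            flag |= 0x400
        if secondary:
            flag |= 0x100
    tags = {}
    if bs_strand is not None:
        tags[BS_STRAND_TAG] = bs_strand
    return AlignedRead(
        name=name,
        flag=flag,
        chrom=chrom,
        pos=pos,
        mapq=mapq,
        cigar=cigar or f"{len(seq)}M",
        seq=seq,
        qual=qual or chr(37 + 33) * len(seq),
        tags=tags,
    )


def bisulfite_seq(
    ref: str, start: int, length: int, strand: str, rng: np.random.Generator,
    p_meth: float = 0.5, noise: float = 0.0,
) -> str:
    """Reference-derived read sequence with per-read random CpG states.

    For OT reads each CpG C stays C (methylated, prob p_meth) or becomes T;
    non-CpG Cs become T.  For OB reads (stored forward) each CpG G stays G
    or becomes A; non-CpG Gs become A.  ``noise`` substitutes random bases.
    """
    out = list(ref[start : start + length])
    for i in range(length):
        p = start + i
        if strand == "OT" and ref[p] == "C":
            is_cpg = p + 1 < len(ref) and ref[p + 1] == "G"
            if not (is_cpg and rng.random() < p_meth):
                out[i] = "T"
        elif strand == "OB" and ref[p] == "G":
            is_cpg = p >= 1 and ref[p - 1] == "C"
            if not (is_cpg and rng.random() < p_meth):
                out[i] = "A"
    if noise:
        for i in range(length):
            if rng.random() < noise:
                out[i] = "ACGT"[int(rng.integers(4))]
    return "".join(out)


def make_mixed_fixture(seed: int = 123, n_pairs: int = 200):
    """A deliberately messy dataset: mixed mapq, base qualities, duplicates,
    secondary alignments, soft-clips, indels, and overlapping mates.

    Returns (reference dict, targets, reads).
    """
    rng = np.random.default_rng(seed)
    ref = make_reference(rng, 3000, cpg_every=12)
    reference = {CHROM: ref}
    targets = [Region(CHROM, 200, 1400), Region(CHROM, 1600, 2800)]
    reads: list[AlignedRead] = []
    rl = 80
    quals = np.array([10, 19, 20, 25, 37])
    for i in range(n_pairs):
        insert = int(rng.integers(rl, 2 * rl))  # mates always overlap somewhere
        s = int(rng.integers(0, 3000 - insert))
        strand = "OT" if rng.random() < 0.5 else "OB"
        mapq = int(rng.choice([20, 29, 30, 31, 60]))
        dup = rng.random() < 0.05
        sec = rng.random() < 0.03
        name = f"pair{i}"
        for mate in (1, 2):
            if strand == "OT":
                off = 0 if mate == 1 else insert - rl
                reverse = mate == 2
            else:
                off = insert - rl if mate == 1 else 0
                reverse = mate == 1
            seq = bisulfite_seq(ref, s + off, rl, strand, rng, noise=0.02)
            qual = "".join(chr(int(q) + 33) for q in rng.choice(quals, size=rl))
            cigar = f"{rl}M"
            r = rng.random()
            if r < 0.06:  # leading soft clip shifts the alignment window
                clip = 5
                cigar = f"{clip}S{rl - clip}M"
            elif r < 0.10:  # deletion mid-read
                cigar = f"30M2D{rl - 30}M"
            elif r < 0.14:  # insertion mid-read
                cigar = f"30M2I{rl - 32}M"
            reads.append(
                make_read(
                    name, s + off, seq, mate=mate, reverse=reverse,
                    bs_strand=strand, mapq=mapq, qual=qual, cigar=cigar,
                    duplicate=dup, secondary=sec,
                )
            )
    return reference, targets, reads


# ---------------------------------------------------------------------------
# independent brute-force pileup oracle
# ---------------------------------------------------------------------------

def oracle_pileup(reads, reference, targets, params):
    """Re-walk every read's alignment and tally per-site counts.

    Written independently of the package internals: plain loops over an
    explicit CIGAR interpreter, a per-(site, fragment) dict for overlap
    resolution, and direct string lookups in the reference.
    """
    import re

    ref = reference[CHROM]
    in_target = [False] * len(ref)
    for t in targets:
        for p in range(t.start, t.end):
            in_target[p] = True
    fwd_cpg = {p for p in range(len(ref) - 1)
               if ref[p] == "C" and ref[p + 1] == "G" and in_target[p]}
    rev_cpg = {p + 1 for p in range(len(ref) - 1)
               if ref[p] == "C" and ref[p + 1] == "G" and in_target[p + 1]}

    best: dict[tuple, tuple] = {}  # (pos, strand, qname) -> (qual, -mate, state)
    plain: dict[tuple, list] = {}
    for read in reads:
        if read.flag & 0x100 or read.flag & 0x800:
            continue
        if read.flag & 0x400:
            continue
        if read.mapq < params.min_mapq:
            continue
        tag = read.tags.get("XB")
        if tag in ("OT", "OB"):
            strand = tag
        else:
            mate1 = bool(read.flag & 0x40)
            rev = bool(read.flag & 0x10)
            strand = "OT" if mate1 != rev else "OB"
        mate = 1 if read.flag & 0x40 else 2
        qlen = len(read.seq)
        q = 0
        r = read.pos
        for num, op in re.findall(r"(\d+)([MIDNSHP=X])", read.cigar):
            num = int(num)
            if op in "M=X":
                for j in range(num):
                    qpos, rpos = q + j, r + j
                    cycle = qlen - qpos if read.flag & 0x10 else qpos + 1
                    if cycle <= params.trim5 or cycle > qlen - params.trim3:
                        continue
                    bq = ord(read.qual[qpos]) - 33
                    if bq < params.min_baseq:
                        continue
                    base = read.seq[qpos]
                    if strand == "OT" and rpos in fwd_cpg:
                        key = (rpos, "+")
                        state = {"C": "M", "T": "U"}.get(base, "other")
                    elif strand == "OB" and rpos in rev_cpg:
                        key = (rpos, "-")
                        state = {"G": "M", "A": "U"}.get(base, "other")
                    else:
                        continue
                    if params.clip_overlap:
                        k = (key, read.name)
                        cand = (bq, -mate, state)
                        if k not in best or cand[:2] > best[k][:2]:
                            best[k] = cand
                    else:
                        plain.setdefault(key, []).append(state)
                q += num
                r += num
            elif op in "IS":
                q += num
            elif op in "DN":
                r += num
    counts: dict[tuple, list] = {}
    if params.clip_overlap:
        for (key, _), (_, _, state) in best.items():
            c = counts.setdefault(key, [0, 0, 0])
            idx = {"M": 0, "U": 1}.get(state, 2)
            c[idx] += 1
    else:
        for key, states in plain.items():
            c = counts.setdefault(key, [0, 0, 0])
            for state in states:
                idx = {"M": 0, "U": 1}.get(state, 2)
                c[idx] += 1
    return {k: tuple(v) for k, v in counts.items() if v[0] + v[1] > 0}


@pytest.fixture(scope="session")
def mixed_fixture():
    return make_mixed_fixture()


@pytest.fixture(scope="session")
def small_sim():
    """One small matched pair with default-style parameters, reused widely."""
    cfg = simdata.SimConfig(
        seed=17, reference_length=30_000, n_targets=4, target_size=1_500,
        mean_coverage=25,
    )
    reference, targets = simdata.simulate_reference(cfg)
    truth = simdata.simulate_truth(reference, targets, cfg)
    ffpe = simdata.simulate_reads(
        reference, targets, truth, cfg, "P_FFPE", "FFPE", rng=cfg.rng(3))
    ff = simdata.simulate_reads(
        reference, targets, truth, cfg, "P_FF", "FF", rng=cfg.rng(4))
    return cfg, reference, targets, truth, ffpe, ff
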