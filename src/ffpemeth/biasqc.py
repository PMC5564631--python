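"""M-bias curves, bowing quantification, and the 5'-trim sweep.

The M-bias curve tallies, per mate and per read cycle (1-based, sequencing
order — a read-start phenomenon must be measured in cycle order, not
reference order), how many CpG-cytosine bases were observed and how many of
them were in the methylated state.  FFPE "bowing" appears as a depressed
methylated fraction over the first ~30-40 cycles that recovers to the
plateau; it is scored as plateau mean minus head mean.

The trim sweep re-calls methylation at a ladder of 5' trims on a matched
FFPE/FF pair and correlates the total number of FFPE calls with the number
of concordant calls (same site, same category in both samples) across trim
levels, the qualitative test that bowing does not disturb concordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bsio import AlignedRead, Region
from .methcall import (
    CallParams,
    FilterStats,
    MethProfile,
    SiteObservation,
    aggregate_observations,
    collect_observations,
)

__all__ = [
    "BiasCurve",
    "BowingScore",
    "SweepResult",
    "compute_bias_curve",
    "bowing_score",
    "trim_sweep",
    "spearman",
    "ConstantInputError",
]

#: a sample is flagged "bowed" above this plateau-minus-head score;
#: a calibration of this toolkit, not a published constant
BOWING_FLAG_THRESHOLD = 0.05


class ConstantInputError(ValueError):
    """Rank correlation is undefined for a constant vector."""


@dataclass
class BiasCurve:
    """Per-mate, per-cycle methylated-fraction curve."""

    read_length: int
    n_meth: np.ndarray  # shape (2, read_length); row 0 = mate 1
    n_total: np.ndarray

    @classmethod
    def empty(cls, read_length: int) -> "BiasCurve":
        return cls(
            read_length,
            np.zeros((2, read_length), dtype=np.int64),
            np.zeros((2, read_length), dtype=np.int64),
        )

    def fraction(self, mate: int | None = None) -> np.ndarray:
        """Methylated fraction per cycle; NaN where there is no coverage.

        ``mate`` 1 or 2 selects one mate; None pools both.
        """
        if mate is None:
            nm, nt = self.n_meth.sum(axis=0), self.n_total.sum(axis=0)
        else:
            nm, nt = self.n_meth[mate - 1], self.n_total[mate - 1]
        out = np.full(self.read_length, np.nan)
        np.divide(nm, nt, out=out, where=nt > 0)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for mate in (1, 2):
            frac = self.fraction(mate)
            for k in range(self.read_length):
                rows.append((
                    mate, k + 1,
                    int(self.n_meth[mate - 1, k]), int(self.n_total[mate - 1, k]),
                    round(float(frac[k]), 6) if not math.isnan(frac[k]) else float("nan"),
                ))
        return pd.DataFrame(rows, columns=["mate", "cycle", "n_meth", "n_total", "fraction"])


@dataclass
class BowingScore:
    """Plateau-minus-head depression of the M-bias curve."""

    head: float
    plateau: float
    k_head: int
    plateau_window: tuple[int, int]

    @property
    def score(self) -> float:
        return self.plateau - self.head

    @property
    def bowed(self) -> bool:
        return self.score > BOWING_FLAG_THRESHOLD


def compute_bias_curve(
    reads: Iterable[AlignedRead],
    reference: Mapping[str, str],
    targets: Sequence[Region],
    params: CallParams | None = None,
    stats: FilterStats | None = None,
) -> BiasCurve:
    """Tally CpG methylation state by read cycle (no end-trimming applied)."""
    params = params or CallParams()
    obs = collect_observations(reads, reference, targets, params, stats=stats)
    return bias_curve_from_observations(obs, params)


def bias_curve_from_observations(
    observations: Iterable[SiteObservation], params: CallParams
) -> BiasCurve:
    read_length = 0
    rows: list[SiteObservation] = []
    for o in observations:
        if o.baseq < params.min_baseq:
            continue
        read_length = max(read_length, o.read_length)
        rows.append(o)
    curve = BiasCurve.empty(read_length or 1)
    for o in rows:
        if o.state not in ("M", "U"):
            continue
        curve.n_total[o.mate - 1, o.cycle - 1] += 1
        if o.state == "M":
            curve.n_meth[o.mate - 1, o.cycle - 1] += 1
    return curve


def bowing_score(
    curve: BiasCurve,
    k_head: int = 30,
    plateau_window: tuple[int, int] = (60, 100),
    mate: int | None = None,
) -> BowingScore:
    """Score = mean fraction over the plateau window minus over cycles 1..k_head.

    Cycles without coverage are ignored inside each window; an entirely
    uncovered window is an error.
    """
    frac = curve.fraction(mate)
    head_vals = frac[:k_head]
    lo, hi = plateau_window
    if not 1 <= lo <= hi <= curve.read_length:
        raise ValueError(f"plateau window {plateau_window} outside read (1..{curve.read_length})")
    plateau_vals = frac[lo - 1 : hi]
    head_vals = head_vals[~np.isnan(head_vals)]
    plateau_vals = plateau_vals[~np.isnan(plateau_vals)]
    if head_vals.size == 0 or plateau_vals.size == 0:
        raise ValueError("bowing score needs coverage in both the head and plateau windows")
    return BowingScore(
        head=float(head_vals.mean()),
        plateau=float(plateau_vals.mean()),
        k_head=k_head,
        plateau_window=plateau_window,
    )


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def _rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)  # average ranks for ties
    ry = sps.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ConstantInputError("spearman rho undefined for a constant vector")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Average ranks are used for ties.  For n <= 8 the p-value is exact, by
    enumeration of all n! permutations (two-sided: fraction of permutations
    with |rho| >= |observed|); for larger n the usual t approximation on
    n-2 degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rho = _rho(x, y)
    if n <= 8:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(range(n)):
            r = _rho(x, y[list(perm)])
            total += 1
            if abs(r) >= target:
                count += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), n - 2)
    return rho, p


# ---------------------------------------------------------------------------
# trim sweep
# ---------------------------------------------------------------------------

DEFAULT_TRIMS = tuple(range(5, 91, 5))


@dataclass
class SweepResult:
    """Concordance of a matched pair across a ladder of 5' trims."""

    table: pd.DataFrame  # trim5, n_total_a, n_total_b, n_intersect, n_concordant, concordant_fraction
    rho: float
    p: float

    @property
    def trims(self) -> list[int]:
        return list(self.table["trim5"])


def _categories(profile: MethProfile) -> dict:
    return {s: c.category for s, c in profile.calls.items()}


def trim_sweep(
    reads_a: Iterable[AlignedRead] | list[SiteObservation],
    reads_b: Iterable[AlignedRead] | list[SiteObservation],
    reference: Mapping[str, str],
    targets: Sequence[Region],
    params: CallParams | None = None,
    trims: Sequence[int] = DEFAULT_TRIMS,
) -> SweepResult:
    """Call both samples at each 5' trim level and correlate totals.

    Sample A plays the FFPE role: ``n_total`` counts its methylation calls,
    ``n_concordant`` the sites called in both samples with the same category.
    The Spearman statistics are computed between the n_total and
    n_concordant vectors over trim levels.  Inputs may be read streams or
    pre-collected observation lists (one pass over the reads serves all trim
    levels).
    """
    params = params or CallParams()
    trims = sorted(set(int(t) for t in trims))
    if len(trims) < 3:
        raise ValueError("need at least 3 trim levels for a useful correlation")

    def as_obs(source):
        if isinstance(source, list) and (not source or isinstance(source[0], SiteObservation)):
            return source
        return collect_observations(source, reference, targets, params)

    obs_a = as_obs(reads_a)
    obs_b = as_obs(reads_b)
    rows = []
    for t in trims:
        p_t = replace(params, trim5=t)
        prof_a = aggregate_observations(obs_a, p_t)
        prof_b = aggregate_observations(obs_b, p_t)
        cat_a = _categories(prof_a)
        cat_b = _categories(prof_b)
        inter = cat_a.keys() & cat_b.keys()
        n_conc = sum(1 for s in inter if cat_a[s] == cat_b[s])
        frac = n_conc / len(inter) if inter else float("nan")
        rows.append((t, len(cat_a), len(cat_b), len(inter), n_conc, frac))
    table = pd.DataFrame(
        rows,
        columns=["trim5", "n_total_a", "n_total_b", "n_intersect",
                 "n_concordant", "concordant_fraction"],
    )
    rho, p = spearman(table["n_total_a"].to_numpy(), table["n_concordant"].to_numpy())
    return SweepResult(table=table, rho=rho, p=p)
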