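"""Recombinant counting, recombination-fraction estimation and Kosambi maps.

A maternal meiosis is *informative* for an adjacent marker interval when the
mother is heterozygous at both flanking markers and the grandparental origin
of the transmitted allele is known at both; it is *recombinant* when the two
origin labels differ.  The recombination fraction θ is estimated as the plain
binomial MLE r/n, and converted to map distance with the Kosambi function

    d = ¼ · ln((1 + 2θ) / (1 − 2θ))   Morgans  (×100 for cM),

whose inverse is θ = ½ · tanh(2d).  A two-point genetic map is the cumulative
sum of adjacent-interval Kosambi distances, anchored at 0 for the first
marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .genodata import MarkerPanel
from .xinherit import GameteOrigin, PhasedFemale


@dataclass(frozen=True)
class IntervalCounts:
    """(informative meioses, recombinants) for one analysis unit and one
    adjacent marker interval."""

    unit_id: str
    left: str
    right: str
    n: int
    r: int

    def __post_init__(self):
        if not 0 <= self.r <= self.n:
            raise ValueError(f"require 0 <= r <= n, got r={self.r}, n={self.n}")

    @property
    def interval(self) -> tuple[str, str]:
        return (self.left, self.right)


@dataclass(frozen=True)
class ThetaEstimate:
    theta: float
    r: int
    n: int
    kosambi_cM: Optional[float]   # None when theta >= 0.5


@dataclass(frozen=True)
class GeneticMap:
    """Cumulative two-point Kosambi positions, first marker at 0 cM."""

    markers: tuple[str, ...]
    positions_cM: tuple[float, ...]

    def position(self, marker: str) -> float:
        return self.positions_cM[self.markers.index(marker)]


def count_interval(
    origins: Iterable[GameteOrigin],
    mother: PhasedFemale,
    interval: tuple[str, str],
    panel: Optional[MarkerPanel] = None,
) -> IntervalCounts:
    """Count informative and recombinant meioses for one flanking-marker
    interval of one F1 female.

    When a panel is supplied the interval must be in panel order (left before
    right).  A mother homozygous or unresolved at either flank yields n = 0.
    """
    left, right = interval
    if panel is not None and panel.rank(left) >= panel.rank(right):
        raise ValueError(f"interval markers out of order: {left!r} !< {right!r}")
    if not (mother.is_heterozygous(left) and mother.is_heterozygous(right)):
        return IntervalCounts(mother.f1_id, left, right, 0, 0)
    n = r = 0
    for g in origins:
        o1, o2 = g.origin.get(left), g.origin.get(right)
        if o1 is None or o2 is None:
            continue
        n += 1
        if o1 != o2:
            r += 1
    return IntervalCounts(mother.f1_id, left, right, n, r)


def pool_counts(counts: Sequence[IntervalCounts],
                unit_id: str = "pooled") -> IntervalCounts:
    """Component-wise sum of counts for one and the same interval."""
    counts = list(counts)
    if not counts:
        raise ValueError("cannot pool an empty collection of counts")
    interval = counts[0].interval
    if any(c.interval != interval for c in counts):
        raise ValueError("cannot pool counts from mixed intervals")
    return IntervalCounts(unit_id, *interval,
                          n=sum(c.n for c in counts),
                          r=sum(c.r for c in counts))


def estimate_theta(counts: IntervalCounts) -> ThetaEstimate:
    """Binomial MLE θ̂ = r/n with the Kosambi distance attached when θ̂ < ½."""
    if counts.n == 0:
        raise ValueError(
            f"theta undefined for {counts.unit_id} "
            f"{counts.left}-{counts.right}: no informative meioses")
    theta = counts.r / counts.n
    cm = kosambi_cm(theta) if theta < 0.5 else None
    return ThetaEstimate(theta=theta, r=counts.r, n=counts.n, kosambi_cM=cm)


def kosambi_cm(theta: float) -> float:
    """Kosambi map distance in cM for a recombination fraction θ ∈ [0, ½)."""
    if not 0 <= theta < 0.5:
        raise ValueError(f"Kosambi distance requires 0 <= theta < 0.5, got {theta}")
    return 25.0 * math.log((1 + 2 * theta) / (1 - 2 * theta))


def kosambi_inverse(d_cm: float) -> float:
    """Recombination fraction for a Kosambi distance in cM (θ = ½·tanh(2d),
    d in Morgans)."""
    if d_cm < 0:
        raise ValueError(f"map distance must be non-negative, got {d_cm}")
    return 0.5 * math.tanh(2 * d_cm / 100.0)


def build_genetic_map(
    intervals: Sequence[tuple[str, str]],
    thetas: Sequence[float],
) -> GeneticMap:
    """Chain adjacent-interval θ̂ into cumulative Kosambi positions.

    ``intervals`` must form a chain in panel order (the right marker of each
    interval is the left marker of the next); every θ̂ must be < ½.
    """
    if len(intervals) != len(thetas):
        raise ValueError("need one theta per interval")
    if not intervals:
        raise ValueError("need at least one interval")
    for (l1, r1), (l2, _) in zip(intervals, intervals[1:]):
        if r1 != l2:
            raise ValueError(f"intervals do not chain: {r1!r} != {l2!r}")
    markers = [intervals[0][0]] + [iv[1] for iv in intervals]
    positions = [0.0]
    for theta in thetas:
        positions.append(positions[-1] + kosambi_cm(theta))
    return GeneticMap(markers=tuple(markers), positions_cM=tuple(positions))


def write_counts_tsv(estimates: Sequence[tuple[IntervalCounts, ThetaEstimate]],
                     path) -> None:
    """TSV dump (unit, left, right, n, r, theta, cM); θ printed to 3 dp and
    distances to 2 dp as is conventional for linkage tables, full precision
    retained in memory."""
    import pandas as pd

    rows = []
    for c, e in estimates:
        rows.append({
            "unit": c.unit_id, "left": c.left, "right": c.right,
            "n": c.n, "r": c.r,
            "theta": f"{e.theta:.3f}",
            "cM": "" if e.kosambi_cM is None else f"{e.kosambi_cM:.2f}",
        })
    pd.DataFrame(rows, columns=["unit", "left", "right", "n", "r", "theta",
                                "cM"]).to_csv(path, sep="\t", index=False)
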