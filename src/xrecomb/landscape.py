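"""Recombination-rate landscape (cM/Mb) and marker-order discordance.

The landscape divides each adjacent interval's genetic length (Kosambi cM) by
its physical length (Mb of point-coordinate difference) and classifies
intervals against the chromosome-wide average rate: *hotspot candidates*
exceed ``hot_factor`` × average (default 2×) and *coldspots* fall below
``cold_factor`` × average (default 0.1×); everything else is *normal*.  The
factors are configuration — there is no universal formal cutoff.

Order discordance between two maps is detected by a monotone-run scan: with
markers sorted by map-A coordinate, a discordant segment is a maximal run over
which map-B coordinates fail to be strictly increasing, extending from the
running-maximum marker through every marker whose B coordinate stays below
that maximum (merged transitively).  A map B that is predominantly decreasing
is flipped first, so a globally inverted map does not flood the report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

COLDSPOT = "coldspot"
NORMAL = "normal"
HOTSPOT = "hotspot_candidate"


@dataclass(frozen=True)
class LandscapeInterval:
    left: str
    right: str
    genetic_len: float    # cM
    physical_len: float   # Mb
    rate: float           # cM/Mb
    klass: Optional[str] = None


@dataclass(frozen=True)
class OrderComparison:
    """Result of a two-map marker-order comparison: the reference (map-A)
    order, map-B coordinates in that order, and the maximal discordant runs
    (each a tuple of >= 2 marker names)."""

    reference_order: tuple[str, ...]
    compared_positions: tuple[float, ...]
    discordant_segments: tuple[tuple[str, ...], ...]
    flipped: bool = False

    @property
    def n_segments(self) -> int:
        return len(self.discordant_segments)


def interval_rates(
    markers: Sequence[str],
    genetic_cM: Sequence[float],
    physical_Mb: Sequence[float],
) -> list[LandscapeInterval]:
    """Per-adjacent-interval cM/Mb rates.

    Physical coordinates must be strictly increasing along the marker order;
    genetic positions must be non-decreasing.
    """
    if not len(markers) == len(genetic_cM) == len(physical_Mb):
        raise ValueError("markers, genetic and physical coordinates must align")
    if len(markers) < 2:
        raise ValueError("need at least two markers")
    out = []
    for i in range(len(markers) - 1):
        d_mb = physical_Mb[i + 1] - physical_Mb[i]
        if d_mb <= 0:
            raise ValueError(
                f"non-positive physical span {markers[i]}-{markers[i+1]}: {d_mb}")
        d_cm = genetic_cM[i + 1] - genetic_cM[i]
        if d_cm < 0:
            raise ValueError(
                f"decreasing genetic position {markers[i]}-{markers[i+1]}")
        out.append(LandscapeInterval(
            left=markers[i], right=markers[i + 1],
            genetic_len=d_cm, physical_len=d_mb, rate=d_cm / d_mb))
    return out


def average_rate(intervals: Sequence[LandscapeInterval]) -> float:
    """Chromosome-wide average rate = total cM / total Mb."""
    tot_cm = sum(iv.genetic_len for iv in intervals)
    tot_mb = sum(iv.physical_len for iv in intervals)
    return tot_cm / tot_mb


def classify_regions(
    intervals: Sequence[LandscapeInterval],
    average: float,
    cold_factor: float = 0.1,
    hot_factor: float = 2.0,
) -> list[LandscapeInterval]:
    """Partition intervals into coldspot / normal / hotspot_candidate relative
    to the chromosome-wide average rate."""
    if average <= 0:
        raise ValueError(f"average rate must be positive, got {average}")
    if cold_factor <= 0 or hot_factor <= 0:
        raise ValueError("classification factors must be positive")
    out = []
    for iv in intervals:
        if iv.rate > hot_factor * average:
            klass = HOTSPOT
        elif iv.rate < cold_factor * average:
            klass = COLDSPOT
        else:
            klass = NORMAL
        out.append(LandscapeInterval(iv.left, iv.right, iv.genetic_len,
                                     iv.physical_len, iv.rate, klass))
    return out


def compare_orders(
    markers: Sequence[str],
    coords_a: Sequence[float],
    coords_b: Sequence[float],
) -> OrderComparison:
    """Detect marker-order discordance between two coordinate systems.

    Markers are sorted by map-A coordinate and map-B coordinates are scanned
    for maximal non-monotone runs (see module docstring).  Duplicate
    coordinates on either map are rejected — co-located assays must be
    deduplicated by the caller.
    """
    if len(markers) < 3:
        raise ValueError("need at least 3 markers with both coordinates")
    if not len(markers) == len(coords_a) == len(coords_b):
        raise ValueError("markers and coordinates must align")
    for label, coords in (("A", coords_a), ("B", coords_b)):
        if len(set(coords)) != len(coords):
            raise ValueError(f"duplicate coordinates on map {label}")
    order = sorted(range(len(markers)), key=lambda i: coords_a[i])
    names = [markers[i] for i in order]
    b = [coords_b[i] for i in order]
    # normalize global orientation: flip B if most adjacent steps decrease
    down = sum(1 for x, y in zip(b, b[1:]) if y < x)
    flipped = down > (len(b) - 1) / 2
    if flipped:
        b = [-x for x in b]
    segments: list[tuple[str, ...]] = []
    runmax_i = 0
    run: Optional[list[int]] = None   # [start, end] indices of current run
    for i in range(1, len(b)):
        if b[i] <= b[runmax_i]:
            if run is None:
                run = [runmax_i, i]
            else:
                run[1] = i
        else:
            if run is not None:
                segments.append(tuple(names[run[0]:run[1] + 1]))
                run = None
            runmax_i = i
    if run is not None:
        segments.append(tuple(names[run[0]:run[1] + 1]))
    return OrderComparison(
        reference_order=tuple(names),
        compared_positions=tuple(coords_b[i] for i in order),
        discordant_segments=tuple(segments),
        flipped=flipped)


def write_landscape_tsv(intervals: Sequence[LandscapeInterval], path) -> None:
    import pandas as pd

    rows = [{
        "left": iv.left, "right": iv.right,
        "cM": f"{iv.genetic_len:.2f}", "Mb": f"{iv.physical_len:.3f}",
        "rate": f"{iv.rate:.3f}", "class": iv.klass or "",
    } for iv in intervals]
    pd.DataFrame(rows, columns=["left", "right", "cM", "Mb", "rate",
                                "class"]).to_csv(path, sep="\t", index=False)
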