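"""Morton's likelihood-ratio test of recombination-fraction homogeneity.

Given k analysis units (F1 females, haplotype groups or families) with
recombinant counts r_i out of n_i informative meioses, the test compares the
sum of unit-wise maximized binomial log-likelihoods with the pooled-fraction
log-likelihood:

    X² = 2 · [ Σ_i lnL(r_i, n_i; θ̂_i) − lnL(R, N; θ̄) ],
    θ̂_i = r_i / n_i,   θ̄ = R / N,   X² ~ χ²_{k−1} under homogeneity,

with the convention 0·ln 0 := 0 so that units with r = 0 (θ̂ = 0) contribute
lnL = 0 and remain in the group count; units with n = 0 carry no information
and are dropped before k is counted.  No continuity correction and no map
transformation are applied: the statistic operates on the raw fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from scipy.special import xlogy
from scipy.stats import chi2

from .recomb import IntervalCounts, pool_counts
from .xinherit import HaplotypeLabel


def binomial_loglik(r: int, n: int, theta: float) -> float:
    """Binomial log-likelihood kernel r·ln θ + (n−r)·ln(1−θ) with 0·ln0 := 0.

    Returns −inf for impossible configurations (r > 0 at θ = 0, or r < n at
    θ = 1).
    """
    if not 0 <= r <= n:
        raise ValueError(f"require 0 <= r <= n, got r={r}, n={n}")
    if not 0 <= theta <= 1:
        raise ValueError(f"require 0 <= theta <= 1, got {theta}")
    return float(xlogy(r, theta) + xlogy(n - r, 1 - theta))


@dataclass(frozen=True)
class GroupResult:
    label: str
    n: int
    r: int
    theta: float
    loglik: float


@dataclass(frozen=True)
class HeterogeneityResult:
    interval: tuple[str, str]
    groups: tuple[GroupResult, ...]
    pooled_n: int
    pooled_r: int
    pooled_theta: float
    pooled_loglik: float
    statistic: float
    df: int
    p: float
    scheme: Optional[str] = None


def morton_lrt(groups: Sequence[IntervalCounts],
               scheme: Optional[str] = None) -> HeterogeneityResult:
    """Morton heterogeneity LRT across units sharing one marker interval.

    Units with n = 0 are dropped; at least two informative units are required.
    Units with r = 0 are retained (they carry information against a common
    nonzero θ).
    """
    groups = [g for g in groups if g.n > 0]
    if len(groups) < 2:
        raise ValueError("Morton test needs >= 2 units with informative meioses")
    interval = groups[0].interval
    if any(g.interval != interval for g in groups):
        raise ValueError("all units must share the same marker interval")
    rows = []
    for g in groups:
        th = g.r / g.n
        rows.append(GroupResult(label=g.unit_id, n=g.n, r=g.r, theta=th,
                                loglik=binomial_loglik(g.r, g.n, th)))
    N = sum(g.n for g in groups)
    R = sum(g.r for g in groups)
    theta_bar = R / N
    lnl_pooled = binomial_loglik(R, N, theta_bar)
    x2 = 2.0 * (sum(row.loglik for row in rows) - lnl_pooled)
    x2 = max(x2, 0.0)  # guard against tiny negative round-off
    df = len(groups) - 1
    return HeterogeneityResult(
        interval=interval, groups=tuple(rows),
        pooled_n=N, pooled_r=R, pooled_theta=theta_bar,
        pooled_loglik=lnl_pooled,
        statistic=x2, df=df, p=chi2_pvalue(x2, df), scheme=scheme)


def chi2_pvalue(x2: float, df: int) -> float:
    """Upper-tail χ² probability."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if x2 < 0:
        raise ValueError(f"statistic must be >= 0, got {x2}")
    return float(chi2.sf(x2, df))


@dataclass(frozen=True)
class GroupingScheme:
    """Assignment of analysis units (F1 female ids) to group labels."""

    name: str
    assignment: Mapping[str, str]

    def label_of(self, unit_id: str) -> str:
        return self.assignment[unit_id]


def group_by_haplotype(
    counts: Sequence[IntervalCounts],
    labels: Mapping[str, HaplotypeLabel],
    side: str,
    drop_unresolved: bool = True,
) -> tuple[list[IntervalCounts], GroupingScheme]:
    """Pool per-female counts by identical haplotype label on one side.

    ``labels`` maps each female id to her :class:`HaplotypeLabel` on the
    requested side.  Labels containing ``?`` (partially unresolved) are
    excluded when ``drop_unresolved`` is true, otherwise each distinct
    unresolved label forms its own group.  A female with n > 0 and no label
    raises.
    """
    if side not in ("maternal", "paternal"):
        raise ValueError(f"side must be 'maternal' or 'paternal', got {side!r}")
    assignment: dict[str, str] = {}
    by_label: dict[str, list[IntervalCounts]] = {}
    for c in counts:
        lab = labels.get(c.unit_id)
        if lab is None:
            if c.n > 0:
                raise ValueError(f"female {c.unit_id} has no {side} haplotype label")
            continue
        if lab.side != side:
            raise ValueError(
                f"label for {c.unit_id} is {lab.side}, expected {side}")
        if "?" in lab.label and drop_unresolved:
            continue
        assignment[c.unit_id] = lab.label
        by_label.setdefault(lab.label, []).append(c)
    grouped = [pool_counts(lst, unit_id=label)
               for label, lst in sorted(by_label.items())]
    return grouped, GroupingScheme(name=f"{side}-haplotype", assignment=assignment)


def heterogeneity_report(
    counts_by_interval: Mapping[tuple[str, str], Sequence[IntervalCounts]],
    schemes: Mapping[str, Mapping[str, str]],
) -> list[HeterogeneityResult]:
    """One Morton test per (interval, grouping scheme).

    ``schemes`` maps a scheme name to a unit→group assignment; the special
    assignment ``None`` means per-unit identity (each unit its own group).
    """
    results = []
    for interval, counts in counts_by_interval.items():
        for name, assignment in schemes.items():
            if assignment is None:
                grouped = list(counts)
            else:
                by_label: dict[str, list[IntervalCounts]] = {}
                for c in counts:
                    if c.unit_id not in assignment:
                        if c.n > 0:
                            raise ValueError(
                                f"unit {c.unit_id} missing from scheme {name!r}")
                        continue
                    by_label.setdefault(assignment[c.unit_id], []).append(c)
                grouped = [pool_counts(lst, unit_id=lab)
                           for lab, lst in sorted(by_label.items())]
            results.append(morton_lrt(grouped, scheme=name))
    return results


def render_report(results: Sequence[HeterogeneityResult]) -> str:
    """Human-readable layout: per-unit rows, then Kosambi distance / Morton
    test / df / P value footer rows, mirroring classical linkage tables."""
    from .recomb import kosambi_cm

    blocks = []
    for res in results:
        left, right = res.interval
        head = f"interval {left}-{right}" + (
            f"  [{res.scheme}]" if res.scheme else "")
        lines = [head, f"{'unit':<16}{'N':>6}{'r':>5}{'theta':>8}"]
        for g in res.groups:
            lines.append(f"{g.label:<16}{g.n:>6}{g.r:>5}{g.theta:>8.3f}")
        cm = (f"{kosambi_cm(res.pooled_theta):.2f}"
              if res.pooled_theta < 0.5 else "inf")
        lines.append(f"Kosambi distance (cM)  {cm}")
        lines.append(f"Morton test            {res.statistic:.2f}")
        lines.append(f"df                     {res.df}")
        lines.append(f"P value                {res.p:.4f}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks)


def write_report_tsv(results: Sequence[HeterogeneityResult], path) -> None:
    import pandas as pd

    rows = []
    for res in results:
        for g in res.groups:
            rows.append({
                "left": res.interval[0], "right": res.interval[1],
                "scheme": res.scheme or "", "group": g.label,
                "n": g.n, "r": g.r, "theta": f"{g.theta:.3f}",
                "X2": f"{res.statistic:.2f}", "df": res.df,
                "p": f"{res.p:.4g}",
            })
    pd.DataFrame(rows, columns=["left", "right", "scheme", "group", "n", "r",
                                "theta", "X2", "df", "p"]).to_csv(
        path, sep="\t", index=False)
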