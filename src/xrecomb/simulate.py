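"""Forward simulation of X-chromosome transmission in an F2 intercross.

The generator emulates the mating design of the large pig resource
populations this package targets: a handful of F0 boar × sow pairs from
divergent founder lines, a few F1 females per cross, and tens of genotyped F2
offspring per F1 female (defaults: 6 crosses, 3 F1 females each, 60 offspring
per female — the per-female litter sizes real designs reach on the order of
30–100 meioses).  Gametes follow a no-interference Markov model along the
marker order: the starting haplotype is chosen with probability ½ and an
independent switch occurs in each adjacent interval j with probability θ_j.

Heterogeneity models:

* ``per_female_multipliers`` — each listed F1 female's whole θ vector is
  scaled by her multiplier (individual variation);
* ``haplotype_effect`` — the θ vector of a female is scaled according to the
  maternal haplotype label she carries over a designated marker subset
  (haplotype-associated variation, e.g. a carrier haplotype with a 14-fold
  lower fraction).

Genotype corruption (missing calls, random allele miscalls) is applied to the
emitted genotype table only; the truth record is untouched.  Identical seeds
reproduce identical datasets byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .genodata import (
    FEMALE, MALE, GenotypeTable, Individual, MarkerPanel, Pedigree,
)
from .recomb import IntervalCounts
from .xinherit import GM, GP


@dataclass(frozen=True)
class HaplotypeEffect:
    """θ multiplier attached to designated maternal founder haplotypes, read
    over ``markers`` (a subset of the panel, in panel order)."""

    markers: tuple[str, ...]
    multipliers: Mapping[str, float]   # haplotype label -> multiplier


@dataclass
class SimConfig:
    """Study-design parameters of one simulated dataset.

    ``theta`` is the baseline per-adjacent-interval recombination-fraction
    vector (a scalar is broadcast); all effective θ must stay in [0, ½).
    ``founder_model`` is ``"divergent"`` (boar line fixed for allele ``1``,
    sow line fixed for ``2`` — every F1 female heterozygous everywhere),
    ``"two_sow_haplotypes"`` (each sow carries haplotypes ``2`` and ``3``,
    so full-sisters may inherit either grand-maternal haplotype) or
    ``"frequencies"`` (alleles drawn per line from ``n_alleles`` equifrequent
    codes, producing uninformative meioses).
    """

    panel: MarkerPanel
    seed: int = 0
    n_crosses: int = 6
    f1_females_per_cross: int = 3
    f1_males_per_cross: int = 1
    offspring_per_female: Union[int, Sequence[int]] = 60
    offspring_mean: Optional[float] = None      # Poisson mode (min 1)
    theta: Union[float, Sequence[float]] = 0.05
    founder_model: str = "divergent"
    n_alleles: int = 4
    per_female_multipliers: Optional[Mapping[str, float]] = None
    haplotype_effect: Optional[HaplotypeEffect] = None
    missing_rate: float = 0.0
    error_rate: float = 0.0
    sex_ratio: float = 0.5          # P(F2 is male)

    def theta_vector(self) -> np.ndarray:
        m = len(self.panel) - 1
        th = np.asarray(self.theta, dtype=float)
        if th.ndim == 0:
            th = np.full(m, float(th))
        if th.shape != (m,):
            raise ValueError(f"theta vector must have length {m}, got {th.shape}")
        if np.any((th < 0) | (th >= 0.5)):
            raise ValueError("all theta must lie in [0, 0.5)")
        return th

    def validate(self) -> None:
        self.theta_vector()
        for rate, what in ((self.missing_rate, "missing_rate"),
                           (self.error_rate, "error_rate"),
                           (self.sex_ratio, "sex_ratio")):
            if not 0 <= rate <= 1:
                raise ValueError(f"{what} must lie in [0, 1], got {rate}")
        if self.founder_model not in ("divergent", "two_sow_haplotypes",
                                      "frequencies"):
            raise ValueError(f"unknown founder model {self.founder_model!r}")
        if any(self.panel.is_par(m) for m in self.panel.names):
            raise ValueError("the simulator models X-specific (non-PAR) markers "
                             "only; drop PAR markers from the panel")


@dataclass
class MeiosisTruth:
    """True crossover indicators (per adjacent interval) and grandparental
    origins (per marker) of one transmitted maternal gamete."""

    offspring_id: str
    mother_id: str
    origins: tuple[str, ...]       # GM/GP per marker
    crossovers: tuple[bool, ...]   # per adjacent interval


@dataclass
class SimTruth:
    """Oracle record: per-female phased haplotypes and θ vectors, plus one
    :class:`MeiosisTruth` per F2 offspring."""

    paternal_hap: dict[str, tuple[str, ...]] = field(default_factory=dict)
    maternal_hap: dict[str, tuple[str, ...]] = field(default_factory=dict)
    theta_by_female: dict[str, np.ndarray] = field(default_factory=dict)
    meioses: list[MeiosisTruth] = field(default_factory=list)

    def meioses_of(self, mother_id: str) -> list[MeiosisTruth]:
        return [m for m in self.meioses if m.mother_id == mother_id]

    def true_counts(self, mother_id: str,
                    interval: tuple[str, str],
                    panel: MarkerPanel) -> tuple[int, int]:
        """(n, r) from truth: recombinant iff the number of true crossovers
        strictly between the flanking markers is odd."""
        i, j = panel.rank(interval[0]), panel.rank(interval[1])
        n = r = 0
        for m in self.meioses_of(mother_id):
            n += 1
            if sum(m.crossovers[i:j]) % 2 == 1:
                r += 1
        return n, r


@dataclass
class SimResult:
    pedigree: Pedigree
    genotypes: GenotypeTable
    truth: SimTruth


def simulate_gamete(
    rng: np.random.Generator,
    haplotypes: Sequence[Sequence[str]],
    theta_vector: Sequence[float],
) -> tuple[list[str], list[int], list[bool]]:
    """Draw one gamete from a pair of parental haplotypes.

    Returns ``(gamete alleles, per-marker source haplotype index, per-interval
    crossover indicators)``.  The starting haplotype is uniform and switches
    are independent Bernoulli(θ_j) — a Markov model without interference.
    """
    hap0, hap1 = haplotypes
    n_markers = len(hap0)
    th = np.asarray(theta_vector, dtype=float)
    if th.shape != (n_markers - 1,):
        raise ValueError("theta vector length must be number of markers - 1")
    if np.any((th < 0) | (th >= 0.5)):
        raise ValueError("all theta must lie in [0, 0.5)")
    current = int(rng.integers(2))
    switches = rng.random(n_markers - 1) < th
    sources = [current]
    for s in switches:
        if s:
            current = 1 - current
        sources.append(current)
    gamete = [hap0[i] if src == 0 else hap1[i]
              for i, src in enumerate(sources)]
    return gamete, sources, [bool(s) for s in switches]


def _founder_haps(cfg: SimConfig, rng: np.random.Generator):
    """Per-cross founder haplotypes: boar X plus the sow's two X's."""
    m = len(cfg.panel)
    boars, sows = [], []
    for _ in range(cfg.n_crosses):
        if cfg.founder_model == "divergent":
            boars.append(("1",) * m)
            sows.append((("2",) * m, ("2",) * m))
        elif cfg.founder_model == "two_sow_haplotypes":
            boars.append(("1",) * m)
            sows.append((("2",) * m, ("3",) * m))
        else:  # frequencies
            codes = [str(i + 1) for i in range(cfg.n_alleles)]
            draw = lambda: tuple(codes[i] for i in rng.integers(cfg.n_alleles, size=m))
            boars.append(draw())
            sows.append((draw(), draw()))
    return boars, sows


def _female_theta(cfg: SimConfig, f1_id: str,
                  maternal_hap: Sequence[str],
                  base: np.ndarray) -> np.ndarray:
    th = base.copy()
    mult = 1.0
    if cfg.per_female_multipliers:
        mult *= cfg.per_female_multipliers.get(f1_id, 1.0)
    if cfg.haplotype_effect is not None:
        eff = cfg.haplotype_effect
        idx = [cfg.panel.rank(m) for m in eff.markers]
        label = "".join(maternal_hap[i] for i in idx)
        mult *= eff.multipliers.get(label, 1.0)
    th = th * mult
    if np.any(th >= 0.5):
        raise ValueError("heterogeneity multipliers push theta to >= 0.5")
    return th


def simulate_dataset(config: SimConfig) -> SimResult:
    """Simulate pedigree, genotype table and truth record for one dataset.

    F1 females receive the boar X intact (paternal) and a recombined sow
    gamete (maternal); F1 males receive a sow gamete.  F2 sons carry the
    maternal gamete only; F2 daughters additionally carry their F1 father's X
    intact.  Missingness and allele miscalls corrupt the genotype table only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    markers = panel.names
    m = len(markers)
    base_theta = config.theta_vector()
    boars, sows = _founder_haps(config, rng)

    inds: list[Individual] = []
    truth = SimTruth()
    clean: dict[tuple[str, str], tuple[str, ...]] = {}

    def put(iid: str, marker: str, alleles: Sequence[str]) -> None:
        clean[(iid, marker)] = tuple(sorted(alleles))

    f1_females: list[tuple[str, tuple, tuple, np.ndarray]] = []
    f1_males: list[tuple[str, tuple]] = []
    for c in range(config.n_crosses):
        boar_id, sow_id = f"B{c+1}", f"S{c+1}"
        inds.append(Individual(boar_id, MALE, "F0", line="A"))
        inds.append(Individual(sow_id, FEMALE, "F0", line="B"))
        for i, mk in enumerate(markers):
            put(boar_id, mk, (boars[c][i],))
            put(sow_id, mk, (sows[c][0][i], sows[c][1][i]))
        for k in range(config.f1_females_per_cross):
            fid = f"F1F-{c+1}-{k+1}"
            gamete, _, _ = simulate_gamete(rng, sows[c], base_theta)
            pat, mat = boars[c], tuple(gamete)
            inds.append(Individual(fid, FEMALE, "F1",
                                   sire_id=boar_id, dam_id=sow_id))
            for i, mk in enumerate(markers):
                put(fid, mk, (pat[i], mat[i]))
            truth.paternal_hap[fid] = pat
            truth.maternal_hap[fid] = mat
            theta_f = _female_theta(config, fid, mat, base_theta)
            truth.theta_by_female[fid] = theta_f
            f1_females.append((fid, pat, mat, theta_f))
        for k in range(config.f1_males_per_cross):
            mid = f"F1M-{c+1}-{k+1}"
            gamete, _, _ = simulate_gamete(rng, sows[c], base_theta)
            inds.append(Individual(mid, MALE, "F1",
                                   sire_id=boar_id, dam_id=sow_id))
            for i, mk in enumerate(markers):
                put(mid, mk, (gamete[i],))
            f1_males.append((mid, tuple(gamete)))

    if not f1_males:
        raise ValueError("need at least one F1 male to sire F2 daughters")

    counts = config.offspring_per_female
    if config.offspring_mean is not None:
        n_fem = len(f1_females)
        counts = np.maximum(1, rng.poisson(config.offspring_mean, size=n_fem))
    elif isinstance(counts, int):
        counts = [counts] * len(f1_females)
    if len(counts) != len(f1_females):
        raise ValueError("offspring_per_female list must match number of F1 females")

    off_serial = 0
    for (fid, pat, mat, theta_f), n_off in zip(f1_females, counts):
        # mate each female to one F1 male from a different cross
        cross = int(fid.split("-")[1])
        mate_id, mate_hap = f1_males[cross % len(f1_males)]
        for _ in range(int(n_off)):
            off_serial += 1
            oid = f"F2-{off_serial}"
            gamete, sources, xovers = simulate_gamete(
                rng, (pat, mat), theta_f)
            origins = tuple(GP if s == 0 else GM for s in sources)
            is_male = rng.random() < config.sex_ratio
            if is_male:
                inds.append(Individual(oid, MALE, "F2",
                                       sire_id=mate_id, dam_id=fid))
                for i, mk in enumerate(markers):
                    put(oid, mk, (gamete[i],))
            else:
                inds.append(Individual(oid, FEMALE, "F2",
                                       sire_id=mate_id, dam_id=fid))
                for i, mk in enumerate(markers):
                    put(oid, mk, (mate_hap[i], gamete[i]))
            truth.meioses.append(MeiosisTruth(
                offspring_id=oid, mother_id=fid,
                origins=origins, crossovers=tuple(xovers)))

    pedigree = Pedigree(inds)
    genotypes = _corrupt(clean, config, rng)
    return SimResult(pedigree=pedigree, genotypes=genotypes, truth=truth)


def _corrupt(clean: Mapping[tuple[str, str], tuple[str, ...]],
             cfg: SimConfig, rng: np.random.Generator) -> GenotypeTable:
    """Apply missingness then allele miscalls, preserving call arity."""
    alleles_at: dict[str, set[str]] = {}
    for (_, mk), call in clean.items():
        alleles_at.setdefault(mk, set()).update(call)
    table = GenotypeTable()
    for (iid, mk), call in sorted(clean.items()):
        if cfg.missing_rate and rng.random() < cfg.missing_rate:
            continue
        if cfg.error_rate and rng.random() < cfg.error_rate:
            universe = sorted(alleles_at[mk] | {"0"})
            pos = int(rng.integers(len(call)))
            wrong = [a for a in universe if a != call[pos]]
            new = list(call)
            new[pos] = wrong[int(rng.integers(len(wrong)))]
            call = tuple(new)
        table.set(iid, mk, call)
    return table


# ---------------------------------------------------------------------------
# count-level fixtures
# ---------------------------------------------------------------------------

def table_fixture(
    rows: Sequence[tuple[str, int, float]],
    interval: tuple[str, str] = ("L", "R"),
    ties: str = "error",
) -> list[IntervalCounts]:
    """Reconstruct per-unit integer counts from published (unit, N, θ) rows.

    The recombinant count is r = round(N·θ).  When N·θ is exactly halfway
    between two integers the reconstruction is ambiguous: with
    ``ties="error"`` (default) an error is raised rather than guessing;
    ``ties="even"`` rounds half to even, which must be stated wherever such a
    fixture is used.
    """
    if ties not in ("error", "even"):
        raise ValueError(f"ties must be 'error' or 'even', got {ties!r}")
    out = []
    for unit, n, theta in rows:
        x = n * theta
        lo, hi = math.floor(x), math.ceil(x)
        if lo != hi and abs(x - lo - 0.5) < 1e-9:
            if ties == "error":
                raise ValueError(
                    f"ambiguous count for {unit!r}: N*theta = {x} is "
                    f"equidistant from {lo} and {hi}")
            r = lo if lo % 2 == 0 else hi
        else:
            r = int(round(x))
        out.append(IntervalCounts(unit, *interval, n=int(n), r=r))
    return out


def write_truth_tsv(truth: SimTruth, panel: MarkerPanel, path) -> None:
    """Truth dump: one row per meiosis with origin string and crossover mask."""
    import pandas as pd

    rows = [{
        "offspring": t.offspring_id, "mother": t.mother_id,
        "origins": ",".join(t.origins),
        "crossovers": "".join("1" if x else "0" for x in t.crossovers),
    } for t in truth.meioses]
    pd.DataFrame(rows, columns=["offspring", "mother", "origins",
                                "crossovers"]).to_csv(path, sep="\t", index=False)
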