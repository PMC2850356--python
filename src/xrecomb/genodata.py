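"""Domain model and file I/O for X-chromosome intercross datasets.

Three flat-file kinds are supported, all UTF-8 tab-separated with a mandatory
header row, ``#`` comment lines and empty fields for missing values:

* a **marker panel** (``name``, ``order``, optional ``cM``, ``Mb``, ``alt_Mb``,
  ``par``) giving the consensus marker order along the chromosome with optional
  genetic (Kosambi cM) and physical (Mb) coordinates;
* a **pedigree** (``id``, ``sex``, ``generation``, ``sire``, ``dam``, ``line``)
  describing a three-generation F2 intercross (divergent F0 founder lines,
  F1 hybrids, F2 offspring);
* a **genotype table** in long format (``id``, ``marker``, ``allele1``,
  ``allele2``), where females carry an unordered allele pair and males a single
  allele (hemizygous X), except at pseudoautosomal (PAR) markers where males may
  carry two alleles.

Allele codes are opaque short strings; no numeric semantics are assumed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

FEMALE = "F"
MALE = "M"
GENERATIONS = ("F0", "F1", "F2")

_SEX_ALIASES = {
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
    "m": MALE, "male": MALE, "1": MALE,
}


class DataError(ValueError):
    """Raised on malformed or internally inconsistent input files."""


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Marker:
    """A single X-chromosome marker.

    Coordinates are point positions: ``genetic_cM`` on the Kosambi genetic map,
    ``physical_Mb`` on the primary physical (clone) map and ``alt_physical_Mb``
    on an alternative physical map (e.g. a comparative map of the homologous
    chromosome in another species).  ``par`` flags pseudoautosomal markers,
    which behave diploid in males.
    """

    name: str
    order_index: int
    genetic_cM: Optional[float] = None
    physical_Mb: Optional[float] = None
    alt_physical_Mb: Optional[float] = None
    par: bool = False


class MarkerPanel:
    """An ordered panel of at least two markers with unique names and ranks."""

    def __init__(self, markers: Iterable[Marker]):
        markers = sorted(markers, key=lambda m: m.order_index)
        if len(markers) < 2:
            raise DataError("a marker panel needs at least 2 markers")
        names = [m.name for m in markers]
        if len(set(names)) != len(names):
            raise DataError("duplicate marker names in panel")
        orders = [m.order_index for m in markers]
        if len(set(orders)) != len(orders):
            raise DataError("duplicate marker order ranks in panel")
        cms = [m.genetic_cM for m in markers if m.genetic_cM is not None]
        if any(b < a for a, b in zip(cms, cms[1:])):
            raise DataError("genetic positions must be non-decreasing in panel order")
        self._markers = markers
        self._by_name = {m.name: m for m in markers}
        self._rank = {m.name: i for i, m in enumerate(markers)}

    def __len__(self) -> int:
        return len(self._markers)

    def __iter__(self):
        return iter(self._markers)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Marker:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [m.name for m in self._markers]

    def rank(self, name: str) -> int:
        """Position of a marker within the panel (0-based, panel order)."""
        return self._rank[name]

    def adjacent_pairs(self) -> list[tuple[str, str]]:
        n = self.names
        return list(zip(n, n[1:]))

    def is_par(self, name: str) -> bool:
        return self._by_name[name].par

    def subset(self, names: Sequence[str]) -> list[str]:
        """Return *names* sorted into panel order; unknown names raise."""
        for n in names:
            if n not in self._by_name:
                raise DataError(f"unknown marker {n!r}")
        return sorted(names, key=self.rank)


def _read_tsv(path: Union[str, Path, io.TextIOBase]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    return df


def _opt_float(value: str, what: str) -> Optional[float]:
    value = value.strip()
    if not value:
        return None
    try:
        return float(value)
    except ValueError:
        raise DataError(f"non-numeric {what}: {value!r}") from None


def read_marker_panel(path: Union[str, Path, io.TextIOBase]) -> MarkerPanel:
    """Read a marker panel TSV (columns ``name``, ``order`` and optionally
    ``cM``, ``Mb``, ``alt_Mb``, ``par``; unknown columns are ignored)."""
    df = _read_tsv(path)
    for col in ("name", "order"):
        if col not in df.columns:
            raise DataError(f"marker file lacks required column {col!r}")
    markers = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            order = int(d["order"])
        except ValueError:
            raise DataError(f"non-integer order for marker {d['name']!r}") from None
        markers.append(Marker(
            name=d["name"].strip(),
            order_index=order,
            genetic_cM=_opt_float(d.get("cM", ""), "cM"),
            physical_Mb=_opt_float(d.get("Mb", ""), "Mb"),
            alt_physical_Mb=_opt_float(d.get("alt_Mb", ""), "alt_Mb"),
            par=d.get("par", "").strip() in ("1", "true", "True"),
        ))
    return MarkerPanel(markers)


def write_marker_panel(panel: MarkerPanel, path: Union[str, Path]) -> None:
    rows = []
    for m in panel:
        rows.append({
            "name": m.name, "order": m.order_index,
            "cM": "" if m.genetic_cM is None else m.genetic_cM,
            "Mb": "" if m.physical_Mb is None else m.physical_Mb,
            "alt_Mb": "" if m.alt_physical_Mb is None else m.alt_physical_Mb,
            "par": int(m.par),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    id: str
    sex: str                      # FEMALE | MALE
    generation: str               # F0 | F1 | F2
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None
    line: Optional[str] = None    # founder breed tag


class Pedigree:
    """A validated collection of individuals spanning three generations.

    F0 founders have no parents; F1/F2 parents, when present, must belong to
    the previous generation, with male sires and female dams.  F2 individuals
    must have both parents recorded (an orphan F2 meiosis cannot be scored).
    """

    def __init__(self, individuals: Iterable[Individual]):
        inds = list(individuals)
        ids = [i.id for i in inds]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate individual ids in pedigree")
        self._by_id = {i.id: i for i in inds}
        for ind in inds:
            self._check(ind)

    def _check(self, ind: Individual) -> None:
        if ind.sex not in (FEMALE, MALE):
            raise DataError(f"{ind.id}: unknown sex {ind.sex!r}")
        if ind.generation not in GENERATIONS:
            raise DataError(f"{ind.id}: unknown generation {ind.generation!r}")
        if ind.generation == "F0":
            if ind.sire_id or ind.dam_id:
                raise DataError(f"F0 founder {ind.id} must not have parents")
            return
        prev = "F0" if ind.generation == "F1" else "F1"
        if ind.generation == "F2" and not (ind.sire_id and ind.dam_id):
            raise DataError(f"orphan F2 individual {ind.id}: both parents required")
        for pid, role, sex in ((ind.sire_id, "sire", MALE), (ind.dam_id, "dam", FEMALE)):
            if pid is None:
                continue
            parent = self._by_id.get(pid)
            if parent is None:
                raise DataError(f"{ind.id}: unknown {role} {pid!r}")
            if parent.sex != sex:
                raise DataError(f"{ind.id}: {role} {pid} is not {sex}")
            if parent.generation != prev:
                raise DataError(
                    f"{ind.id}: {role} {pid} is {parent.generation}, expected {prev}")

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    def generation(self, gen: str) -> list[Individual]:
        return [i for i in self._by_id.values() if i.generation == gen]

    def f1_females(self) -> list[Individual]:
        return [i for i in self.generation("F1") if i.sex == FEMALE]

    def offspring_of(self, dam_id: str) -> list[Individual]:
        return [i for i in self._by_id.values() if i.dam_id == dam_id]


def read_pedigree(path: Union[str, Path, io.TextIOBase]) -> Pedigree:
    """Read a pedigree TSV (columns ``id``, ``sex``, ``generation``, ``sire``,
    ``dam``, ``line``)."""
    df = _read_tsv(path)
    for col in ("id", "sex", "generation"):
        if col not in df.columns:
            raise DataError(f"pedigree file lacks required column {col!r}")
    inds = []
    for d in df.to_dict("records"):
        sex = _SEX_ALIASES.get(d["sex"].strip().lower())
        if sex is None:
            raise DataError(f"{d['id']}: unknown sex code {d['sex']!r}")
        inds.append(Individual(
            id=d["id"].strip(),
            sex=sex,
            generation=d["generation"].strip().upper(),
            sire_id=d.get("sire", "").strip() or None,
            dam_id=d.get("dam", "").strip() or None,
            line=d.get("line", "").strip() or None,
        ))
    return Pedigree(inds)


def write_pedigree(pedigree: Pedigree, path: Union[str, Path]) -> None:
    rows = [{
        "id": i.id, "sex": i.sex, "generation": i.generation,
        "sire": i.sire_id or "", "dam": i.dam_id or "", "line": i.line or "",
    } for i in pedigree]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

class GenotypeTable:
    """Mapping ``(individual id, marker name) -> allele call``.

    A call is a tuple of allele codes: length 2 for females (unordered; stored
    sorted), length 1 for hemizygous males, length 2 for males at PAR markers.
    Missing calls are simply absent.
    """

    def __init__(self, calls: Optional[Mapping[tuple[str, str], tuple[str, ...]]] = None):
        self._calls: dict[tuple[str, str], tuple[str, ...]] = {}
        if calls:
            for key, alleles in calls.items():
                self._calls[key] = tuple(sorted(alleles))

    def set(self, iid: str, marker: str, alleles: Sequence[str]) -> None:
        self._calls[(iid, marker)] = tuple(sorted(alleles))

    def get(self, iid: str, marker: str) -> Optional[tuple[str, ...]]:
        return self._calls.get((iid, marker))

    def items(self):
        return self._calls.items()

    def __len__(self) -> int:
        return len(self._calls)

    def markers_of(self, iid: str) -> list[str]:
        return [m for (i, m) in self._calls if i == iid]


def read_genotypes(
    path: Union[str, Path, io.TextIOBase],
    pedigree: Pedigree,
    panel: MarkerPanel,
) -> GenotypeTable:
    """Read a long-format genotype TSV (``id``, ``marker``, ``allele1``,
    ``allele2``), enforcing sex-consistent call arity on the X.

    Males must carry a single allele except at PAR-flagged markers, where a
    pair is allowed.  Rows absent from the file are missing calls, not errors.
    """
    df = _read_tsv(path)
    for col in ("id", "marker", "allele1"):
        if col not in df.columns:
            raise DataError(f"genotype file lacks required column {col!r}")
    table = GenotypeTable()
    for d in df.to_dict("records"):
        iid, marker = d["id"].strip(), d["marker"].strip()
        if iid not in pedigree:
            raise DataError(f"genotype for unknown individual {iid!r}")
        if marker not in panel:
            raise DataError(f"genotype for unknown marker {marker!r}")
        a1 = d["allele1"].strip()
        a2 = d.get("allele2", "").strip()
        if not a1 and not a2:
            continue  # explicit missing row
        alleles = tuple(a for a in (a1, a2) if a)
        ind = pedigree[iid]
        if ind.sex == FEMALE and len(alleles) != 2:
            raise DataError(f"{iid}@{marker}: female call must be an allele pair")
        if ind.sex == MALE and len(alleles) == 2 and not panel.is_par(marker):
            raise DataError(
                f"{iid}@{marker}: diploid male call at non-PAR X marker")
        table.set(iid, marker, alleles)
    return table


def write_genotypes(table: GenotypeTable, path: Union[str, Path]) -> None:
    rows = []
    for (iid, marker), alleles in sorted(table.items()):
        rows.append({
            "id": iid, "marker": marker,
            "allele1": alleles[0],
            "allele2": alleles[1] if len(alleles) > 1 else "",
        })
    pd.DataFrame(rows, columns=["id", "marker", "allele1", "allele2"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Report-only dataset audit: X-linked Mendelian inconsistencies plus
    genotyped-offspring coverage per F1 female."""

    mendelian_errors: list[tuple[str, str, str]] = field(default_factory=list)
    coverage: dict[str, int] = field(default_factory=dict)

    @property
    def n_errors(self) -> int:
        return len(self.mendelian_errors)

    def summary(self) -> str:
        lines = [f"Mendelian inconsistencies on X: {self.n_errors}"]
        for iid, marker, reason in self.mendelian_errors:
            lines.append(f"  {iid} @ {marker}: {reason}")
        lines.append("Genotyped offspring per F1 female:")
        for dam, n in sorted(self.coverage.items()):
            lines.append(f"  {dam}: {n}")
        return "\n".join(lines)


def _trio_errors(ind, geno, sire_g, dam_g, panel):
    """X-inheritance checks for one offspring at one marker."""
    for marker in panel.names:
        g = geno.get(ind.id, marker)
        if g is None:
            continue
        par = panel.is_par(marker)
        dam_call = dam_g.get(marker) if dam_g else None
        sire_call = sire_g.get(marker) if sire_g else None
        if ind.sex == MALE:
            if par:
                continue  # male PAR allele may be Y-borne; not checkable here
            if dam_call and g[0] not in dam_call:
                yield ind.id, marker, (
                    f"son allele {g[0]} absent from dam alleles {'/'.join(dam_call)}")
        else:
            sire_allele = None
            if sire_call and len(sire_call) == 1 and not par:
                sire_allele = sire_call[0]
            if sire_allele is not None:
                if sire_allele not in g:
                    yield ind.id, marker, (
                        f"daughter lacks sire allele {sire_allele}")
                    continue
                if dam_call:
                    rest = list(g)
                    rest.remove(sire_allele)
                    if rest[0] not in dam_call:
                        yield ind.id, marker, (
                            f"daughter maternal allele {rest[0]} absent from dam "
                            f"alleles {'/'.join(dam_call)}")
            elif dam_call and not any(a in dam_call for a in g):
                yield ind.id, marker, "no daughter allele matches the dam"


def validate_dataset(
    pedigree: Pedigree, panel: MarkerPanel, genotypes: GenotypeTable
) -> ValidationReport:
    """Audit a dataset: flag X-linked Mendelian inconsistencies (offspring
    allele impossible given the parents' calls) and count genotyped offspring
    per F1 female.  Never raises on inconsistent data — report only."""
    report = ValidationReport()
    geno_of = lambda iid: {m: genotypes.get(iid, m) for m in panel.names
                           if genotypes.get(iid, m) is not None}
    for ind in pedigree:
        if ind.generation == "F0":
            continue
        sire_g = geno_of(ind.sire_id) if ind.sire_id else None
        dam_g = geno_of(ind.dam_id) if ind.dam_id else None
        report.mendelian_errors.extend(
            _trio_errors(ind, genotypes, sire_g, dam_g, panel))
    for f1 in pedigree.f1_females():
        report.coverage[f1.id] = sum(
            1 for off in pedigree.offspring_of(f1.id)
            if genotypes.markers_of(off.id))
    return report
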