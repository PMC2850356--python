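"""X-specific phase determination and maternal-gamete deduction.

In a three-generation F2 intercross the F1 female's phase on the X is fully
determined by her father's genotype: the F0 boar is hemizygous, so his single
allele identifies the F1 female's paternal allele and the remaining allele of
her pair is maternal (from the F0 sow).  Because the paternal X is transmitted
to F2 daughters without male recombination and F2 sons receive only the
maternal X, every F2 offspring exposes one maternal meiosis whose
grandparental origin can be read marker by marker:

* origin ``GM`` (grand-maternal) — the transmitted allele came from the F0 sow;
* origin ``GP`` (grand-paternal) — it came from the F0 boar;
* ``unknown`` — mother homozygous/unphased at the marker, offspring genotype
  missing, or the call is Mendelianly impossible (flagged, never fatal).

PAR-flagged markers are excluded from all male-based deduction (males carry
X and Y copies there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .genodata import (
    FEMALE, MALE, DataError, GenotypeTable, Individual, MarkerPanel, Pedigree,
)

GM = "GM"  # grand-maternal: allele descends from the F0 sow
GP = "GP"  # grand-paternal: allele descends from the F0 boar


@dataclass
class PhasedFemale:
    """Phased F1 female: per-marker paternal (F0 boar) and maternal (F0 sow)
    alleles.  A marker is *resolved* when both are known; at resolved markers
    the two alleles reproduce the female's genotype as an unordered pair."""

    f1_id: str
    paternal: dict[str, str] = field(default_factory=dict)
    maternal: dict[str, str] = field(default_factory=dict)
    mendelian_errors: list[str] = field(default_factory=list)  # marker names

    def is_resolved(self, marker: str) -> bool:
        return marker in self.paternal and marker in self.maternal

    def is_heterozygous(self, marker: str) -> bool:
        return (self.is_resolved(marker)
                and self.paternal[marker] != self.maternal[marker])


@dataclass
class GameteOrigin:
    """Deduced maternal gamete of one F2 offspring with per-marker
    grandparental origin labels (``GM``/``GP``; absent where unknown)."""

    offspring_id: str
    mother_id: str
    allele: dict[str, str] = field(default_factory=dict)
    origin: dict[str, str] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)  # markers with impossible trios


@dataclass(frozen=True)
class HaplotypeLabel:
    """Concatenated phased alleles of one parental side over an ordered marker
    subset, e.g. ``"1122"``; ``?`` marks unresolved markers."""

    f1_id: str
    side: str                   # "maternal" | "paternal"
    markers: tuple[str, ...]
    label: str


def phase_f1_female(
    f1_id: str,
    f1_genotype: Mapping[str, Sequence[str]],
    sire_genotype: Mapping[str, Sequence[str]],
    panel: Optional[MarkerPanel] = None,
) -> PhasedFemale:
    """Phase an F1 female by paternal-allele subtraction.

    At each marker where both genotypes are present, the paternal allele is
    the hemizygous sire's allele and the maternal allele is the remaining
    member of the F1 pair.  A sire allele absent from the F1 pair is recorded
    as a Mendelian error and the marker left unknown.  PAR markers (where the
    sire call is not a single X allele) are skipped when a panel is given.
    """
    phased = PhasedFemale(f1_id=f1_id)
    for marker, pair in f1_genotype.items():
        if panel is not None and panel.is_par(marker):
            continue
        sire_call = sire_genotype.get(marker)
        if sire_call is None or pair is None:
            continue
        if len(sire_call) != 1:
            continue  # not usable for hemizygous subtraction
        sire_allele = sire_call[0]
        pair = tuple(pair)
        if len(pair) != 2:
            raise DataError(f"{f1_id}@{marker}: female genotype is not a pair")
        if sire_allele not in pair:
            phased.mendelian_errors.append(marker)
            continue
        rest = list(pair)
        rest.remove(sire_allele)
        phased.paternal[marker] = sire_allele
        phased.maternal[marker] = rest[0]
    return phased


def deduce_maternal_gamete(
    offspring: Individual,
    offspring_genotype: Mapping[str, Sequence[str]],
    mother: PhasedFemale,
    father_genotype: Optional[Mapping[str, Sequence[str]]] = None,
    panel: Optional[MarkerPanel] = None,
) -> GameteOrigin:
    """Deduce the maternal-gamete allele and its grandparental origin for one
    F2 offspring.

    Sons expose the maternal gamete directly (their single X allele).  For
    daughters the F1 father's allele is subtracted from the pair.  The origin
    is ``GM``/``GP`` according to which of the mother's phased alleles the
    gamete allele matches; it stays unknown where the mother is homozygous or
    unresolved.  Impossible configurations are flagged and left unknown.
    """
    result = GameteOrigin(offspring_id=offspring.id, mother_id=mother.f1_id)
    for marker, call in offspring_genotype.items():
        if call is None:
            continue
        par = panel is not None and panel.is_par(marker)
        call = tuple(call)
        if offspring.sex == MALE:
            if par:
                continue  # male PAR calls may include the Y copy: skip
            maternal_allele = call[0]
        else:
            father_call = father_genotype.get(marker) if father_genotype else None
            if father_call is None or len(father_call) != 1:
                continue
            pat = father_call[0]
            if pat not in call:
                result.flags.append(marker)
                continue
            rest = list(call)
            rest.remove(pat)
            maternal_allele = rest[0]
        result.allele[marker] = maternal_allele
        if not mother.is_heterozygous(marker):
            continue
        if maternal_allele == mother.maternal[marker]:
            result.origin[marker] = GM
        elif maternal_allele == mother.paternal[marker]:
            result.origin[marker] = GP
        else:
            result.flags.append(marker)
            del result.allele[marker]
    return result


def extract_f1_haplotype(
    mother: PhasedFemale,
    marker_subset: Sequence[str],
    side: str,
    panel: Optional[MarkerPanel] = None,
) -> HaplotypeLabel:
    """Concatenate the phased alleles of one parental side over an ordered
    marker subset into a haplotype label (``?`` where unresolved)."""
    if side not in ("maternal", "paternal"):
        raise ValueError(f"side must be 'maternal' or 'paternal', got {side!r}")
    if len(marker_subset) == 0:
        raise ValueError("empty marker subset")
    if panel is not None:
        marker_subset = panel.subset(list(marker_subset))
    alleles = mother.maternal if side == "maternal" else mother.paternal
    tokens = [alleles.get(m, "?") for m in marker_subset]
    return HaplotypeLabel(
        f1_id=mother.f1_id, side=side,
        markers=tuple(marker_subset), label="".join(tokens))


# ---------------------------------------------------------------------------
# dataset-level convenience
# ---------------------------------------------------------------------------

def phase_all_females(
    pedigree: Pedigree, panel: MarkerPanel, genotypes: GenotypeTable
) -> dict[str, PhasedFemale]:
    """Phase every F1 female whose F0 sire carries genotypes."""
    phased = {}
    for f1 in pedigree.f1_females():
        geno = {m: genotypes.get(f1.id, m) for m in panel.names
                if genotypes.get(f1.id, m) is not None}
        sire_geno = {}
        if f1.sire_id:
            sire_geno = {m: genotypes.get(f1.sire_id, m) for m in panel.names
                         if genotypes.get(f1.sire_id, m) is not None}
        phased[f1.id] = phase_f1_female(f1.id, geno, sire_geno, panel)
    return phased


def deduce_all_gametes(
    pedigree: Pedigree,
    panel: MarkerPanel,
    genotypes: GenotypeTable,
    phased: Mapping[str, PhasedFemale],
) -> dict[str, list[GameteOrigin]]:
    """Deduce the maternal gamete of every F2 offspring of every phased F1
    female; returns ``{f1 female id: [GameteOrigin, ...]}``."""
    out: dict[str, list[GameteOrigin]] = {}
    for f1_id, mother in phased.items():
        gametes = []
        for off in pedigree.offspring_of(f1_id):
            geno = {m: genotypes.get(off.id, m) for m in panel.names
                    if genotypes.get(off.id, m) is not None}
            father_geno = None
            if off.sex == FEMALE and off.sire_id:
                father_geno = {m: genotypes.get(off.sire_id, m)
                               for m in panel.names
                               if genotypes.get(off.sire_id, m) is not None}
            gametes.append(deduce_maternal_gamete(
                off, geno, mother, father_geno, panel))
        out[f1_id] = gametes
    return out


def write_gamete_origins(
    gametes: Mapping[str, Iterable[GameteOrigin]], path
) -> None:
    """Audit dump: one row per (offspring, marker) with the deduced maternal
    allele and its grandparental origin."""
    import pandas as pd

    rows = []
    for mother_id, lst in gametes.items():
        for g in lst:
            for marker, allele in sorted(g.allele.items()):
                rows.append({
                    "offspring": g.offspring_id, "mother": mother_id,
                    "marker": marker, "allele": allele,
                    "origin": g.origin.get(marker, ""),
                })
    pd.DataFrame(rows, columns=["offspring", "mother", "marker", "allele",
                                "origin"]).to_csv(path, sep="\t", index=False)
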