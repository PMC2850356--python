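"""Bundled reference data: two pig F2 intercross pedigrees on SSC-X.

Three small plain-text tables ship with the package, transcribed from the
published summaries of two large pig resource populations (INRA Large White ×
Meishan; JXAU White Duroc × Erhualian):

* :func:`marker_panel` — the 60-marker SSC-X consensus panel with clone-map
  (Mb), comparative human-X (Mb) and female linkage-map (Kosambi cM)
  coordinates;
* :func:`inra_region_counts` — per-F1-female recombination fractions over six
  broad (>10 cM) intervals;
* :func:`inra_fine_counts` / :func:`inra_fine_haplotypes` — per-female
  fractions and parental haplotype labels over the fine interval
  *UMNP891–UMNP93*;
* :func:`jxau_family_counts` / :func:`jxau_maternal_counts` — family-level
  and within-family maternal-haplotype fractions over *MCST96O22–MCSI0244D12*.

The published summaries report fractions, not raw recombinant counts; integer
counts are reconstructed as r = round(N·θ) (see
:func:`xrecomb.simulate.table_fixture`), which round-trips every printed θ.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genodata import MarkerPanel, read_marker_panel
from .recomb import IntervalCounts
from .simulate import table_fixture
from .xinherit import HaplotypeLabel

FINE_INTERVAL = ("UMNP891", "UMNP93")
JXAU_INTERVAL = ("MCST96O22", "MCSI0244D12")

# the four positions defining the published haplotype labels; the underlying
# marker identities are not part of the released summary tables
_HAP_POSITIONS = ("pos1", "pos2", "pos3", "pos4")


def _path(name: str):
    return resources.files("xrecomb.data").joinpath(name)


def _frame(name: str) -> pd.DataFrame:
    with _path(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype=str,
                           keep_default_na=False)


def marker_table() -> pd.DataFrame:
    """Raw marker table (all map coordinates, as strings; empty = unplaced)."""
    return _frame("sscx_markers.tsv")


def marker_panel() -> MarkerPanel:
    """The 60-marker SSC-X consensus panel (cM = INRA linkage map,
    Mb = clone map, alt_Mb = human X)."""
    with _path("sscx_markers.tsv").open("r", encoding="utf-8") as fh:
        return read_marker_panel(fh)


def inra_region_table() -> pd.DataFrame:
    return _frame("inra_region_theta.tsv")


def inra_region_counts() -> dict[tuple[str, str], list[IntervalCounts]]:
    """Per-female reconstructed counts for the six broad INRA intervals.

    Females uninformative for an interval (empty θ) are omitted from that
    interval's list — they carry n = 0 and are dropped by the Morton test
    anyway.  One female (910084, N = 50, θ = 0.190) yields N·θ = 9.5 in three
    broad intervals; those ties are resolved half-to-even (r = 10).
    """
    df = inra_region_table()
    out: dict[tuple[str, str], list[IntervalCounts]] = {}
    for interval_name, sub in df.groupby("interval", sort=False):
        left, right = interval_name.split("-")
        rows = [(r["female"], int(r["n_offspring"]), float(r["theta"]))
                for r in sub.to_dict("records") if r["theta"] != ""]
        out[(left, right)] = table_fixture(rows, interval=(left, right),
                                           ties="even")
    return out


def inra_fine_table() -> pd.DataFrame:
    return _frame("inra_umnp891_umnp93.tsv")


def inra_fine_counts() -> list[IntervalCounts]:
    """Per-female reconstructed counts for the fine interval UMNP891-UMNP93
    (17 INRA F1 females, 1028 meioses in total)."""
    df = inra_fine_table()
    rows = [(r["female"], int(r["n"]), float(r["theta"]))
            for r in df.to_dict("records")]
    return table_fixture(rows, interval=FINE_INTERVAL)


def inra_fine_haplotypes(side: str) -> dict[str, HaplotypeLabel]:
    """Published maternal (Meishan) or paternal (Large White) haplotype label
    of each INRA F1 female over the fine interval."""
    if side not in ("maternal", "paternal"):
        raise ValueError(f"side must be 'maternal' or 'paternal', got {side!r}")
    col = "maternal_hap" if side == "maternal" else "paternal_hap"
    out = {}
    for r in inra_fine_table().to_dict("records"):
        out[r["female"]] = HaplotypeLabel(
            f1_id=r["female"], side=side,
            markers=_HAP_POSITIONS, label=r[col])
    return out


def jxau_table() -> pd.DataFrame:
    return _frame("jxau_mcst96o22_mcsi0244d12.tsv")


def _jxau_rows(level: str) -> list[tuple[str, int, float]]:
    df = jxau_table()
    sub = df[df["level"] == level]
    if sub.empty:
        raise ValueError(f"unknown grouping level {level!r}")
    return [(f"{r['dam']}[{r['hap']}]{r['suffix']}", int(r["n"]),
             float(r["theta"])) for r in sub.to_dict("records")]


def jxau_family_counts() -> list[IntervalCounts]:
    """The two JXAU paternal half-sib families (one per F0 boar)."""
    return table_fixture(_jxau_rows("family"), interval=JXAU_INTERVAL)


def jxau_maternal_counts(family: str) -> list[IntervalCounts]:
    """Within-family maternal-haplotype groups for family ``"0F11"`` (9
    groups) or ``"0F21"`` (13 groups)."""
    if family not in ("0F11", "0F21"):
        raise ValueError(f"family must be '0F11' or '0F21', got {family!r}")
    return table_fixture(_jxau_rows(f"maternal_{family}"),
                         interval=JXAU_INTERVAL)


def order_comparison_coordinates(
    linkage_mapped_only: bool = True,
) -> tuple[list[str], list[float], list[float]]:
    """(markers, human-X Mb, pig clone-map Mb) for order-discordance scans.

    With ``linkage_mapped_only`` (default) only markers carrying a female
    linkage-map position are kept — the marker set over which the two physical
    maps were compared; this also removes the co-located assay pairs that
    share a coordinate.  With ``False`` every marker carrying both physical
    coordinates is returned (duplicates included; callers must deduplicate
    before :func:`xrecomb.landscape.compare_orders`).
    """
    df = marker_table()
    names, hsa, clone = [], [], []
    for r in df.to_dict("records"):
        if r["Mb"] == "" or r["alt_Mb"] == "":
            continue
        if linkage_mapped_only and r["cM"] == "" and r["jxau_cM"] == "":
            continue
        names.append(r["name"])
        clone.append(float(r["Mb"]))
        hsa.append(float(r["alt_Mb"]))
    return names, hsa, clone
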