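"""Shell-assemblage quantification: MNI, apportionment, abundance, diversity.

Shell-midden assemblages arrive as tallies of standardized fragmentation
categories per taxon and stratigraphic unit.  The minimum number of
individuals (MNI) is the smallest count of animals consistent with the
non-repetitive skeletal elements present:

* bivalves (per side): COMV + FRAV + FCH + max(AHF, PHF); the MNI is the
  greater of the left and right totals;
* spiralled gastropods: COMI + FRAI + max(APIF, STOF + UMBF);
* non-spiralled gastropods: COMI + FRAI + APIF.

Undiagnostic fragments (FTS, unsided bivalve fragments) are stored but never
enter the formulas.  Limpets too broken for species assignment are tallied
as an indeterminate taxon and redistributed over the identified limpet
species in proportion to their per-unit representation, with
largest-remainder rounding so the total is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "TaxonClass",
    "FragmentCounts",
    "BIVALVE_CATEGORIES",
    "SPIRALLED_CATEGORIES",
    "NON_SPIRALLED_CATEGORIES",
    "mni",
    "mni_bivalve",
    "mni_spiralled",
    "mni_non_spiralled",
    "apportion_indeterminate",
    "relative_abundance",
    "simpson_index",
    "read_fragments_csv",
    "mni_table",
]

BIVALVE_CATEGORIES = ("COMV", "FRAV", "FCH", "AHF", "PHF")
SPIRALLED_CATEGORIES = ("COMI", "FRAI", "APIF", "STOF", "UMBF", "FTS")
NON_SPIRALLED_CATEGORIES = ("COMI", "FRAI", "APIF", "FTS")

TaxonClass = str  # {"bivalve", "spiralled_gastropod", "non_spiralled_gastropod"}
_TAXON_CLASSES = {"bivalve", "spiralled_gastropod", "non_spiralled_gastropod"}


def _check_counts(counts: Mapping[str, int], label: str) -> None:
    for k, v in counts.items():
        if int(v) != v or v < 0:
            raise ValueError(f"{label}[{k}] must be a non-negative integer, got {v}")


@dataclass(frozen=True)
class FragmentCounts:
    """Per-taxon fragmentation-category tallies for one stratigraphic unit.

    For bivalves, ``left`` and ``right`` hold the per-side valve categories
    and ``unsided`` the undiagnostic fragment count; for gastropods the
    categories live in ``counts`` (FTS included but never counted).
    """

    unit_id: str
    taxon: str
    taxon_class: TaxonClass
    counts: dict[str, int] = field(default_factory=dict)
    left: dict[str, int] = field(default_factory=dict)
    right: dict[str, int] = field(default_factory=dict)
    unsided: int = 0

    def __post_init__(self) -> None:
        if self.taxon_class not in _TAXON_CLASSES:
            raise ValueError(f"unknown taxon_class {self.taxon_class!r}")
        _check_counts(self.counts, "counts")
        _check_counts(self.left, "left")
        _check_counts(self.right, "right")
        if int(self.unsided) != self.unsided or self.unsided < 0:
            raise ValueError("unsided must be a non-negative integer")


def mni_bivalve(counts: FragmentCounts) -> int:
    """MNI for a bivalve: max over sides of COMV + FRAV + FCH + max(AHF, PHF)."""
    if counts.taxon_class != "bivalve":
        raise ValueError(f"taxon {counts.taxon}: expected bivalve, got {counts.taxon_class}")

    def side_total(side: Mapping[str, int]) -> int:
        g = lambda k: int(side.get(k, 0))
        return g("COMV") + g("FRAV") + g("FCH") + max(g("AHF"), g("PHF"))

    return max(side_total(counts.left), side_total(counts.right))


def mni_spiralled(counts: FragmentCounts) -> int:
    """MNI for a spiralled gastropod: COMI + FRAI + max(APIF, STOF + UMBF)."""
    if counts.taxon_class != "spiralled_gastropod":
        raise ValueError(
            f"taxon {counts.taxon}: expected spiralled_gastropod, got {counts.taxon_class}"
        )
    g = lambda k: int(counts.counts.get(k, 0))
    return g("COMI") + g("FRAI") + max(g("APIF"), g("STOF") + g("UMBF"))


def mni_non_spiralled(counts: FragmentCounts) -> int:
    """MNI for a non-spiralled gastropod (e.g. a limpet): COMI + FRAI + APIF."""
    if counts.taxon_class != "non_spiralled_gastropod":
        raise ValueError(
            f"taxon {counts.taxon}: expected non_spiralled_gastropod, got {counts.taxon_class}"
        )
    g = lambda k: int(counts.counts.get(k, 0))
    return g("COMI") + g("FRAI") + g("APIF")


_MNI_DISPATCH = {
    "bivalve": mni_bivalve,
    "spiralled_gastropod": mni_spiralled,
    "non_spiralled_gastropod": mni_non_spiralled,
}


def mni(counts: FragmentCounts) -> int:
    """Dispatch to the MNI formula matching the taxon class."""
    return _MNI_DISPATCH[counts.taxon_class](counts)


def apportion_indeterminate(
    species_mni: Mapping[str, int],
    indeterminate_mni: int,
) -> dict[str, int]:
    """Distribute an indeterminate MNI over species pro rata.

    Shares follow each species' fraction of the identified total, rounded by
    the largest-remainder method so the grand total is conserved exactly.
    Remainder ties break by descending species MNI, then species name.  If no
    species has a positive MNI the indeterminate count cannot be assigned and
    a ValueError is raised (callers report it unassigned).
    """
    if int(indeterminate_mni) != indeterminate_mni or indeterminate_mni < 0:
        raise ValueError("indeterminate_mni must be a non-negative integer")
    if any(v < 0 for v in species_mni.values()):
        raise ValueError("species MNI values must be non-negative")
    total = sum(species_mni.values())
    if indeterminate_mni == 0:
        return dict(species_mni)
    if total == 0:
        raise ValueError("no identified individuals to apportion over")
    quotas = {sp: indeterminate_mni * n / total for sp, n in species_mni.items()}
    floors = {sp: int(q) for sp, q in quotas.items()}
    leftover = indeterminate_mni - sum(floors.values())
    order = sorted(
        species_mni,
        key=lambda sp: (-(quotas[sp] - floors[sp]), -species_mni[sp], sp),
    )
    for sp in order[:leftover]:
        floors[sp] += 1
    return {sp: species_mni[sp] + floors[sp] for sp in species_mni}


def relative_abundance(unit_mni: Mapping[str, int]) -> dict[str, float]:
    """Per-unit MNI fractions, summing to one."""
    total = sum(unit_mni.values())
    if total <= 0:
        raise ValueError("unit has no individuals")
    return {taxon: n / total for taxon, n in unit_mni.items()}


def simpson_index(unit_mni: Mapping[str, int], variant: str = "dominance") -> float:
    """Simpson's index over a taxon->MNI mapping.

    ``dominance`` (default) is D = sum(p_i^2), the probability that two
    random individuals belong to the same taxon — near 1 when a few taxa
    dominate.  ``diversity`` is its complement 1 - D.
    """
    total = sum(unit_mni.values())
    if total <= 0:
        raise ValueError("total MNI must be positive")
    d = sum((n / total) ** 2 for n in unit_mni.values())
    if variant == "dominance":
        return d
    if variant == "diversity":
        return 1.0 - d
    raise ValueError(f"unknown Simpson variant {variant!r}")


_FRAGMENT_COLUMNS = ["unit_id", "taxon", "taxon_class", "side", "category", "count"]


def read_fragments_csv(path) -> list[FragmentCounts]:
    """Read the long-format fragment table into per-(unit, taxon) tallies.

    Columns: unit_id, taxon, taxon_class, side (L/R/NA), category, count.
    Bivalve rows carry a side; the category 'FRAGMENTS' (or side NA with
    category FTS for gastropods) is stored as undiagnostic.
    """
    df = pd.read_csv(path)
    missing = [c for c in _FRAGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: list[FragmentCounts] = []
    for (unit_id, taxon), grp in df.groupby(["unit_id", "taxon"], sort=True):
        classes = grp["taxon_class"].unique()
        if len(classes) != 1:
            raise ValueError(f"unit {unit_id} taxon {taxon}: inconsistent taxon_class")
        tclass = classes[0]
        counts: dict[str, int] = {}
        left: dict[str, int] = {}
        right: dict[str, int] = {}
        unsided = 0
        for raw_side, raw_cat, raw_n in zip(grp["side"], grp["category"], grp["count"]):
            n = int(raw_n)
            if n < 0:
                raise ValueError(f"negative count for {taxon} in unit {unit_id}")
            cat = str(raw_cat)
            side = str(raw_side).upper()
            if tclass == "bivalve":
                if cat == "FRAGMENTS":
                    unsided += n
                elif side == "L":
                    left[cat] = left.get(cat, 0) + n
                elif side == "R":
                    right[cat] = right.get(cat, 0) + n
                else:
                    raise ValueError(
                        f"bivalve category {cat} in unit {unit_id} needs side L or R"
                    )
            else:
                counts[cat] = counts.get(cat, 0) + n
        out.append(
            FragmentCounts(
                unit_id=str(unit_id), taxon=str(taxon), taxon_class=str(tclass),
                counts=counts, left=left, right=right, unsided=unsided,
            )
        )
    return out


def mni_table(
    fragment_counts: list[FragmentCounts],
    indeterminate_taxon: str | None = None,
    apportion_within: tuple[str, ...] = (),
) -> pd.DataFrame:
    """MNI and relative abundance per (unit, taxon).

    If ``indeterminate_taxon`` is given, its MNI in each unit is apportioned
    over ``apportion_within`` species (largest-remainder) before abundances
    are computed; units where none of those species occur keep the
    indeterminate row as-is.
    """
    records: dict[str, dict[str, int]] = {}
    for fc in fragment_counts:
        records.setdefault(fc.unit_id, {})
        records[fc.unit_id][fc.taxon] = records[fc.unit_id].get(fc.taxon, 0) + mni(fc)
    rows = []
    for unit_id, taxa in sorted(records.items()):
        if indeterminate_taxon and indeterminate_taxon in taxa:
            pool = {sp: taxa[sp] for sp in apportion_within if sp in taxa}
            indet = taxa[indeterminate_taxon]
            if indet > 0 and sum(pool.values()) > 0:
                for sp, new in apportion_indeterminate(pool, indet).items():
                    taxa[sp] = new
                del taxa[indeterminate_taxon]
        abundance = relative_abundance(taxa) if sum(taxa.values()) > 0 else {}
        for taxon in sorted(taxa):
            rows.append(
                {
                    "unit_id": unit_id,
                    "taxon": taxon,
                    "mni": taxa[taxon],
                    "relative_abundance": abundance.get(taxon, float("nan")),
                }
            )
    return pd.DataFrame(rows, columns=["unit_id", "taxon", "mni", "relative_abundance"])
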