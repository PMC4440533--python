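"""Core data model for CAZyme domain annotation analysis.

A CAZyme (Carbohydrate-Active enZyme) domain belongs to one of five
classes -- GT (glycosyl transferase), GH (glycoside hydrolase),
PL (polysaccharide lyase), CE (carbohydrate esterase) and the
non-catalytic CBM (carbohydrate-binding module) -- and, within a class,
to a numbered family (GT2, GH17, CBM43, ...).  A gene is a "CAZyme gene"
if it carries at least one annotated CAZyme domain; the ordered list of
its domain hits is its domain architecture.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

#: CAZyme class labels in canonical reporting order.
CLASS_LABELS: tuple[str, ...] = ("GT", "GH", "PL", "CE", "CBM")

#: Lineage groups used when contrasting repertoires across the green
#: plant phylogeny.
LINEAGE_GROUPS: tuple[str, ...] = (
    "green_algae",
    "bryophyte_lycophyte",
    "monocot",
    "eudicot",
)

_CLASS_ORDER = {c: i for i, c in enumerate(CLASS_LABELS)}

# CBM must be matched before CE/GT/... since prefix matching is longest-first.
_FAMILY_RE = re.compile(r"^(CBM|GT|GH|PL|CE)(\d+)(?:_\S+)?$")


class FamilyParseError(ValueError):
    """Raised when a family string cannot be interpreted as a CAZyme family."""


@dataclass(frozen=True, order=True)
class FamilyID:
    """A CAZyme family such as GT41 or CBM43.

    Subfamily suffixes (``GH5_7``) are collapsed to the base family;
    ``raw`` keeps the original string for traceability.  Ordering is by
    class (GT < GH < PL < CE < CBM) then family number, matching the
    deterministic row order used in all outputs.
    """

    sort_key: tuple[int, int] = field(init=False, repr=False)
    class_label: str
    number: int
    raw: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if self.class_label not in _CLASS_ORDER:
            raise FamilyParseError(f"unknown CAZyme class prefix: {self.class_label!r}")
        if self.number < 1:
            raise FamilyParseError(f"family number must be >= 1, got {self.number}")
        object.__setattr__(self, "sort_key", (_CLASS_ORDER[self.class_label], self.number))
        if not self.raw:
            object.__setattr__(self, "raw", self.name)

    @property
    def name(self) -> str:
        """Base family name, e.g. ``"GH5"`` for raw ``"GH5_7"``."""
        return f"{self.class_label}{self.number}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def parse_family(raw: str) -> FamilyID:
    """Parse a dbCAN-style family string into a :class:`FamilyID`.

    The longest matching class prefix among GT/GH/PL/CE/CBM is the class;
    the trailing integer before any ``_`` subfamily suffix is the family
    number.  ``"GH5_7"`` therefore normalizes to family GH5.

    Raises
    ------
    FamilyParseError
        If the string has no valid class prefix or no family number.
    """
    m = _FAMILY_RE.match(raw.strip())
    if m is None:
        raise FamilyParseError(
            f"unknown CAZyme class prefix or malformed family string: {raw!r}"
        )
    return FamilyID(class_label=m.group(1), number=int(m.group(2)), raw=raw.strip())


def family_sort_key(name: str) -> tuple[int, int]:
    """Sort key (class order, family number) for a base family name string."""
    fam = parse_family(name)
    return (_CLASS_ORDER[fam.class_label], fam.number)


def class_of(name: str) -> str:
    """Class label of a family name string (``"GT41"`` -> ``"GT"``)."""
    return parse_family(name).class_label


@dataclass(frozen=True)
class DomainHit:
    """One annotated CAZyme domain within a gene.

    Coordinates are 1-based inclusive and optional: the repertoire
    analyses use family identity and per-gene multiplicity only.
    """

    family: FamilyID
    start: Optional[int] = None
    end: Optional[int] = None
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(f"domain hit start {self.start} > end {self.end}")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError(f"negative e-value: {self.evalue}")


@dataclass
class GeneAnnotation:
    """A gene's ordered CAZyme domain hits within one species."""

    species_id: str
    gene_id: str
    hits: list[DomainHit]

    @property
    def n_domains(self) -> int:
        return len(self.hits)

    @property
    def families(self) -> list[str]:
        """Base family names in architecture order (with repeats)."""
        return [h.family.name for h in self.hits]

    @property
    def distinct_families(self) -> frozenset[str]:
        return frozenset(h.family.name for h in self.hits)

    @property
    def category(self) -> str:
        """``single`` | ``repeat_only`` | ``mixed`` (a partition of CAZyme genes)."""
        if len(self.hits) == 1:
            return "single"
        if len(self.distinct_families) == 1:
            return "repeat_only"
        return "mixed"


@dataclass(frozen=True)
class GenomeSummary:
    """Per-species genome annotation summary."""

    species_id: str
    total_genes: int
    lineage_group: str

    def __post_init__(self) -> None:
        if self.lineage_group not in LINEAGE_GROUPS:
            raise ValueError(
                f"unknown lineage group {self.lineage_group!r}; "
                f"expected one of {LINEAGE_GROUPS}"
            )
        if self.total_genes < 0:
            raise ValueError("total_genes must be nonnegative")


#: Annotations for a set of genomes: species id -> genes in file order.
AnnotationsBySpecies = dict[str, list[GeneAnnotation]]


def sorted_families(names: Iterable[str]) -> list[str]:
    """Sort base family names by (class, number)."""
    return sorted(set(names), key=family_sort_key)


def combo_label(families: Iterable[str]) -> str:
    """Canonical label for a distinct-family combination, e.g. ``"CBM43+GH17"``.

    Families are ordered alphabetically by class label then numerically
    (the customary way such combinations are written), so the label is
    independent of domain order within the gene.
    """
    def _key(name: str) -> tuple[str, int]:
        fam = parse_family(name)
        return (fam.class_label, fam.number)

    return "+".join(sorted(set(families), key=_key))
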