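"""Phycobilisome architecture and bilin stoichiometry.

A phycobilisome (PBS) is described hierarchically: a set of structural
elements (core cylinders, rods, auxiliary hexamers), each a stack of
phycobiliprotein (PBP) trimers of a given class.  PBP classes differ in
how many bilin chromophores each (αβ) protomer carries: AP binds 1+1,
PC binds 1+2 and PE binds 2+3 per (α, β) subunit pair.  From this the
module computes trimer and bilin censuses for arbitrary composition
models, including the default composite model of the bundle-shaped
*Gloeobacter violaceus* PBS (pentacylindrical AP core, six rods in two
bundles, and auxiliary Rx phycocyanin hexamers belting the core).

Hexamers are represented as two stacked trimers throughout, so every
census is expressed in (αβ)₃-trimer units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

__all__ = [
    "PBPClass",
    "StructuralElement",
    "CompositionModel",
    "AP",
    "PC",
    "PE",
    "PBP_CLASSES",
    "build_default_gvipbs",
    "count_trimers",
    "count_bilins",
    "bilin_census_by_class",
]

_VALID_KINDS = ("core_cylinder", "rod", "auxiliary_hexamer")


@dataclass(frozen=True)
class PBPClass:
    """A phycobiliprotein class with its per-subunit bilin stoichiometry."""

    name: str
    bilins_per_alpha: int
    bilins_per_beta: int
    bilin_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.bilins_per_alpha < 0 or self.bilins_per_beta < 0:
            raise ValueError("bilin counts must be nonnegative")

    @property
    def bilins_per_protomer(self) -> int:
        """Bilins per αβ protomer (monomer)."""
        return self.bilins_per_alpha + self.bilins_per_beta

    @property
    def bilins_per_trimer(self) -> int:
        return 3 * self.bilins_per_protomer


#: Allophycocyanin: one phycocyanobilin on each of α and β.
AP = PBPClass("AP", 1, 1, frozenset({"PCB"}))
#: Phycocyanin: one PCB on α, two on β.
PC = PBPClass("PC", 1, 2, frozenset({"PCB"}))
#: Phycoerythrin: two bilins on α, three on β (PEB/PUB).
PE = PBPClass("PE", 2, 3, frozenset({"PEB", "PUB"}))

PBP_CLASSES: dict[str, PBPClass] = {"AP": AP, "PC": PC, "PE": PE}


@dataclass
class StructuralElement:
    """One architectural unit of the PBS (cylinder, rod or auxiliary hexamer).

    ``stacks`` lists (PBP class, number of trimers) pairs; a hexamer
    contributes two trimers.
    """

    id: str
    kind: str
    stacks: list[tuple[PBPClass, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown element kind {self.kind!r}; expected one of {_VALID_KINDS}")
        for pbp, n in self.stacks:
            if n < 1:
                raise ValueError(f"element {self.id!r}: n_trimers must be >= 1, got {n}")
            if not isinstance(pbp, PBPClass):
                raise TypeError(f"element {self.id!r}: stacks must pair PBPClass with a count")

    @property
    def n_trimers(self) -> int:
        return sum(n for _, n in self.stacks)

    @property
    def n_bilins(self) -> int:
        return sum(n * pbp.bilins_per_trimer for pbp, n in self.stacks)


@dataclass
class CompositionModel:
    """A full PBS composition: a named list of structural elements."""

    elements: list[StructuralElement] = field(default_factory=list)
    name: str = "unnamed"

    def __post_init__(self) -> None:
        ids = [e.id for e in self.elements]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate element ids: {dupes}")

    def __add__(self, other: "CompositionModel") -> "CompositionModel":
        return CompositionModel(
            elements=list(self.elements) + list(other.elements),
            name=f"{self.name}+{other.name}",
        )

    # -- censuses (also available as module-level functions) ------------

    def count_trimers(self) -> int:
        return count_trimers(self)

    def count_bilins(self) -> int:
        return count_bilins(self)

    def bilin_census_by_class(self) -> dict[str, int]:
        return bilin_census_by_class(self)

    # -- config round-trip ---------------------------------------------

    def to_yaml(self) -> str:
        """Serialise to a human-editable YAML document."""
        doc = {
            "name": self.name,
            "elements": [
                {
                    "id": e.id,
                    "kind": e.kind,
                    "stacks": [[pbp.name, n] for pbp, n in e.stacks],
                }
                for e in self.elements
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CompositionModel":
        doc = yaml.safe_load(text)
        elements = [
            StructuralElement(
                id=rec["id"],
                kind=rec["kind"],
                stacks=[(PBP_CLASSES[c], int(n)) for c, n in rec["stacks"]],
            )
            for rec in doc.get("elements", [])
        ]
        return cls(elements=elements, name=doc.get("name", "unnamed"))


def count_trimers(model: CompositionModel) -> int:
    """Total number of (αβ)₃ trimers in the model."""
    return sum(e.n_trimers for e in model.elements)


def count_bilins(model: CompositionModel) -> int:
    """Total number of bilin chromophores in the model.

    Each trimer of class *c* carries ``3 * (bilins_per_alpha + bilins_per_beta)``
    bilins.
    """
    return sum(e.n_bilins for e in model.elements)


def bilin_census_by_class(model: CompositionModel) -> dict[str, int]:
    """Bilin counts keyed by PBP class name; values sum to ``count_bilins``."""
    census: dict[str, int] = {}
    for e in model.elements:
        for pbp, n in e.stacks:
            census[pbp.name] = census.get(pbp.name, 0) + n * pbp.bilins_per_trimer
    return census


def build_default_gvipbs(include_tentative_rx: bool = False) -> CompositionModel:
    """The composite bundle-shaped *G. violaceus* PBS composition.

    Core: bottom cylinders A/A' with 3 AP trimers each (the fourth,
    ApcD-containing trimer is unresolved and excluded), top cylinder B
    with 4, lateral hexamers C/C' with 2 each — 14 AP trimers.  Rods
    R1/R1'/R3/R3' stack 3 PC + 2 PE hexamers; R2/R2' stack 3 PC + 3 PE;
    auxiliary Rx1/Rx1' are single PC hexamers.  Totals: 82 trimers and
    864 bilins.

    ``include_tentative_rx`` adds the tentatively placed Rx2/Rx2' and
    Rx3/Rx3' PC hexamers for what-if censuses; they are not part of the
    composite model.
    """
    elements = [
        StructuralElement("A", "core_cylinder", [(AP, 3)]),
        StructuralElement("A'", "core_cylinder", [(AP, 3)]),
        StructuralElement("B", "core_cylinder", [(AP, 4)]),
        StructuralElement("C", "core_cylinder", [(AP, 2)]),
        StructuralElement("C'", "core_cylinder", [(AP, 2)]),
    ]
    for rod in ("R1", "R1'", "R3", "R3'"):
        elements.append(StructuralElement(rod, "rod", [(PC, 6), (PE, 4)]))
    for rod in ("R2", "R2'"):
        elements.append(StructuralElement(rod, "rod", [(PC, 6), (PE, 6)]))
    for rx in ("Rx1", "Rx1'"):
        elements.append(StructuralElement(rx, "auxiliary_hexamer", [(PC, 2)]))
    if include_tentative_rx:
        for rx in ("Rx2", "Rx2'", "Rx3", "Rx3'"):
            elements.append(StructuralElement(rx, "auxiliary_hexamer", [(PC, 2)]))
    return CompositionModel(elements=elements, name="GviPBS-composite")
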