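"""Molecular building blocks: glycerophosphate core, headgroups, chains.

A glycerophospholipid is modelled as the *sn*-glycero-3-phosphate core
(C3H9O6P) plus a polar-headgroup composition delta at the *sn*-3 phosphate
and one substituent at each of *sn*-1 and *sn*-2.  A substituent is either
a free hydroxyl (a lyso position, written ``0:0``) or a carbon chain with
``c`` carbons and ``u`` double bonds attached through one of three linkage
chemistries:

=========  ========  =====================================  ==============
linkage    prefix    chemistry                              delta(c, u)
=========  ========  =====================================  ==============
acyl       (none)    ester (fatty acid condensed, -H2O)     C_c H_{2c-2u-2} O
alkyl      ``O-``    ether (plasmanyl)                      C_c H_{2c-2u}
alkenyl    ``P-``    vinyl ether (plasmenyl)                C_c H_{2c-2u-2}
=========  ========  =====================================  ==============

For alkenyl chains ``u`` counts only the double bonds *beyond* the
vinyl-ether bond at chain position 1, following standard plasmalogen
shorthand (``P-18:0`` carries exactly one C=C); note alkenyl(c, u) is
therefore an isomer of alkyl(c, u+1).

Sixteen headgroup variants are registered, covering twelve LIPID MAPS
glycerophospholipid subclasses; the eight-member glycerophosphoinositol
superfamily (PI and its 3/4/5-phosphorylated PIPx metabolites) differs
only by which inositol hydroxyls carry an extra phosphate (+HPO3 each).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, NamedTuple, Tuple

from .masses import EMPTY, ElementCount, average_mass, exact_mass

__all__ = [
    "Linkage",
    "Chain",
    "LYSO",
    "Headgroup",
    "HEADGROUPS",
    "PI_FAMILY_IDS",
    "NON_PI_IDS",
    "GLYCEROPHOSPHATE_CORE",
    "HPO3",
    "chain_delta",
    "species_composition",
    "Species",
]

GLYCEROPHOSPHATE_CORE = ElementCount.parse("C3H9O6P")
HPO3 = ElementCount.parse("HO3P")

C_MAX = 30
U_MAX = 6


class Linkage(enum.Enum):
    """Chemical linkage of an *sn* substituent to the glycerol backbone."""

    ACYL = "acyl"
    ALKYL = "alkyl"
    ALKENYL = "alkenyl"
    HYDROXYL = "hydroxyl"

    @property
    def prefix(self) -> str:
        return {"acyl": "", "alkyl": "O-", "alkenyl": "P-", "hydroxyl": ""}[self.value]

    @property
    def sort_key(self) -> int:
        return {"hydroxyl": 0, "acyl": 1, "alkyl": 2, "alkenyl": 3}[self.value]


class Chain(NamedTuple):
    """One *sn*-position substituent: linkage, carbon count, unsaturations."""

    linkage: Linkage
    c: int
    u: int

    def validate(self) -> "Chain":
        if self.linkage is Linkage.HYDROXYL:
            if self.c != 0 or self.u != 0:
                raise ValueError("hydroxyl substituent must be 0:0")
            return self
        if not 1 <= self.c <= C_MAX:
            raise ValueError(f"chain carbons out of range 1..{C_MAX}: {self.c}")
        if not 0 <= self.u <= U_MAX:
            raise ValueError(f"chain unsaturations out of range 0..{U_MAX}: {self.u}")
        if self.hydrogens < 0:
            raise ValueError(f"chain {self.c}:{self.u} ({self.linkage.value}) has no valid formula")
        return self

    @property
    def is_lyso(self) -> bool:
        return self.linkage is Linkage.HYDROXYL

    @property
    def hydrogens(self) -> int:
        if self.linkage is Linkage.HYDROXYL:
            return 0
        h = 2 * self.c - 2 * self.u
        if self.linkage in (Linkage.ACYL, Linkage.ALKENYL):
            h -= 2
        return h

    def token(self) -> str:
        """Shorthand token, e.g. ``18:0``, ``O-16:0``, ``P-18:1``, ``0:0``."""
        return f"{self.linkage.prefix}{self.c}:{self.u}"


LYSO = Chain(Linkage.HYDROXYL, 0, 0)


def chain_delta(chain: Chain) -> ElementCount:
    """Composition added to the core by one *sn* substituent.

    The deltas are condensation deltas: the free hydroxyl of the backbone
    position plus the free acid/alcohol/enol minus H2O, so a lyso position
    contributes nothing.
    """
    chain.validate()
    if chain.linkage is Linkage.HYDROXYL:
        return EMPTY
    counts = {"C": chain.c, "H": chain.hydrogens}
    if chain.linkage is Linkage.ACYL:
        counts["O"] = 1
    return ElementCount.of(**counts)


@dataclass(frozen=True)
class Headgroup:
    """A polar-headgroup variant with its composition delta.

    ``phosphate_positions`` lists the phosphorylated inositol carbons
    (PI family only, subset of {3, 4, 5}).
    """

    id: str
    lipidmaps_code: str
    display: str
    composition_delta: ElementCount
    phosphate_positions: Tuple[int, ...] = ()

    @property
    def is_pi_family(self) -> bool:
        return self.id == "PI" or bool(self.phosphate_positions)


def _pi_variant(positions: Tuple[int, ...], code: str) -> Headgroup:
    base = ElementCount.parse("C6H10O5")
    delta = base + len(positions) * HPO3
    if positions:
        pos = ",".join(str(p) for p in positions)
        sub = len(positions)
        display = f"PI[{pos}]P{sub if sub > 1 else ''}"
        hid = "PI" + "".join(str(p) for p in positions) + f"P{sub if sub > 1 else ''}"
    else:
        display, hid = "PI", "PI"
    return Headgroup(id=hid, lipidmaps_code=code, display=display,
                     composition_delta=delta, phosphate_positions=positions)


def _build_registry() -> Dict[str, Headgroup]:
    hg = [
        Headgroup("PA", "GP10", "PA", EMPTY),
        Headgroup("PPA", "GP11", "PPA", HPO3),
        Headgroup("PC", "GP01", "PC", ElementCount.parse("C5H11N")),
        Headgroup("PE", "GP02", "PE", ElementCount.parse("C2H5N")),
        Headgroup("PG", "GP04", "PG", ElementCount.parse("C3H6O2")),
        Headgroup("PGP", "GP05", "PGP", ElementCount.parse("C3H6O2") + HPO3),
        Headgroup("PS", "GP03", "PS", ElementCount.parse("C3H5NO2")),
        Headgroup("CDPDG", "GP13", "CDP-DG", ElementCount.parse("C9H12N3O7P")),
        _pi_variant((), "GP06"),
        _pi_variant((3,), "GP07"),
        _pi_variant((4,), "GP07"),
        _pi_variant((5,), "GP07"),
        _pi_variant((3, 4), "GP08"),
        _pi_variant((3, 5), "GP08"),
        _pi_variant((4, 5), "GP08"),
        _pi_variant((3, 4, 5), "GP09"),
    ]
    return {h.id: h for h in hg}


#: Registry of the 16 headgroup variants, in canonical (database) order.
HEADGROUPS: Dict[str, Headgroup] = _build_registry()

PI_FAMILY_IDS = tuple(h.id for h in HEADGROUPS.values() if h.is_pi_family)
NON_PI_IDS = tuple(h.id for h in HEADGROUPS.values() if not h.is_pi_family)

assert len(HEADGROUPS) == 16
assert len(set(h.lipidmaps_code for h in HEADGROUPS.values())) == 12


def species_composition(h: Headgroup, sn1: Chain, sn2: Chain) -> ElementCount:
    """Full elemental composition of a species (core + headgroup + chains)."""
    return GLYCEROPHOSPHATE_CORE + h.composition_delta + chain_delta(sn1) + chain_delta(sn2)


class Species(NamedTuple):
    """A single enumerated species: headgroup plus ordered (sn-1, sn-2) chains.

    *sn*-1/*sn*-2 inversions are distinct species (identical mass, distinct
    identity), mirroring how the two positions are reported in lipidomics.
    """

    headgroup: Headgroup
    sn1: Chain
    sn2: Chain

    @property
    def name(self) -> str:
        return f"{self.headgroup.display}({self.sn1.token()}/{self.sn2.token()})"

    @property
    def composition(self) -> ElementCount:
        return species_composition(self.headgroup, self.sn1, self.sn2)

    @property
    def exact_mass(self) -> float:
        return exact_mass(self.composition)

    @property
    def average_mass(self) -> float:
        return average_mass(self.composition)


def headgroup_registry_text() -> str:
    """Auditable key=value dump of the headgroup registry."""
    lines = ["# headgroup registry: id, LIPID MAPS subclass, composition delta vs C3H9O6P core"]
    for h in HEADGROUPS.values():
        pos = "".join(str(p) for p in h.phosphate_positions) or "-"
        lines.append(
            f"{h.id}\tlipidmaps={h.lipidmaps_code}\tdisplay={h.display}\t"
            f"delta={h.composition_delta.hill_formula() or '0'}\tphosphate_positions={pos}"
        )
    return "\n".join(lines) + "\n"
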