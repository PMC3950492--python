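"""Elemental-composition arithmetic and exact/average mass computation.

Glycerophospholipid masses are assembled by summing elemental compositions
of molecular building blocks (glycerophosphate core, headgroup, chains) and
converting the resulting composition to a mass with either monoisotopic
("exact") element masses or standard atomic weights ("average").  Adduct
m/z values for the six supported MS ion modes are derived from the neutral
mass by adding/removing the adduct atom and correcting for the electron
gained or lost on ionization.

All constants are pinned in ``data/atomic_masses.txt`` (key=value text,
with provenance) so that computed masses are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterator, Mapping, Tuple
import re

__all__ = [
    "ElementCount",
    "MassTables",
    "IonMode",
    "ION_MODES",
    "EMPTY",
    "CompositionError",
    "load_mass_tables",
    "exact_mass",
    "average_mass",
    "adduct_mz",
]

#: Elements that may appear in a lipid composition.
MOLECULE_ELEMENTS = ("C", "H", "N", "O", "P")
#: Additional elements that occur only as MS adducts.
ADDUCT_ELEMENTS = ("Na", "K", "Li")
SUPPORTED_ELEMENTS = MOLECULE_ELEMENTS + ADDUCT_ELEMENTS


class CompositionError(ValueError):
    """Raised for unsupported elements or negative element counts."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementCount:
    """An elemental composition: a mapping element symbol -> count >= 0.

    Instances are immutable and support element-wise addition, subtraction
    (which raises :class:`CompositionError` on underflow) and nonnegative
    integer scaling.
    """

    counts: Tuple[Tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        clean = []
        for el, n in self.counts:
            if el not in SUPPORTED_ELEMENTS:
                raise CompositionError(f"unsupported element symbol: {el!r}")
            if not isinstance(n, int) or n < 0:
                raise CompositionError(f"negative or non-integer count for {el}: {n!r}")
            if n:
                clean.append((el, n))
        clean.sort()
        object.__setattr__(self, "counts", tuple(clean))

    @classmethod
    def of(cls, **counts: int) -> "ElementCount":
        return cls(tuple(counts.items()))

    @classmethod
    def parse(cls, formula: str) -> "ElementCount":
        """Parse a plain molecular formula such as ``"C3H9O6P"``."""
        pos = 0
        acc: Dict[str, int] = {}
        for m in _FORMULA_TOKEN.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise CompositionError(f"cannot parse formula {formula!r}")
            pos = m.end()
            el, num = m.group(1), int(m.group(2) or 1)
            acc[el] = acc.get(el, 0) + num
        if pos != len(formula):
            raise CompositionError(f"cannot parse formula {formula!r}")
        return cls(tuple(acc.items()))

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, el: str) -> int:
        return dict(self.counts).get(el, 0)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "ElementCount") -> "ElementCount":
        return combine(self, other, +1)

    def __sub__(self, other: "ElementCount") -> "ElementCount":
        return combine(self, other, -1)

    def __mul__(self, k: int) -> "ElementCount":
        if not isinstance(k, int) or k < 0:
            raise CompositionError(f"can only scale by a nonnegative integer, got {k!r}")
        return ElementCount(tuple((el, n * k) for el, n in self.counts))

    __rmul__ = __mul__

    def hill_formula(self) -> str:
        """Molecular formula in Hill order (C, H, then alphabetical)."""
        d = self.as_dict()
        parts = []
        for el in ("C", "H"):
            n = d.pop(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        for el in sorted(d):
            parts.append(el + (str(d[el]) if d[el] > 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill_formula() or "(empty)"


EMPTY = ElementCount()


def combine(a: ElementCount, b: ElementCount, sign: int = +1) -> ElementCount:
    """Element-wise sum (``sign=+1``) or difference (``sign=-1``).

    Subtraction that would drive any element negative raises
    :class:`CompositionError` (composition underflow).
    """
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    acc = a.as_dict()
    for el, n in b:
        new = acc.get(el, 0) + sign * n
        if new < 0:
            raise CompositionError(
                f"composition underflow: cannot remove {el}{n} from {a.hill_formula() or '(empty)'}"
            )
        acc[el] = new
    return ElementCount(tuple(acc.items()))


@dataclass(frozen=True)
class MassTables:
    """Pinned element masses: monoisotopic, average, and the electron mass."""

    monoisotopic: Mapping[str, float]
    average: Mapping[str, float]
    electron_mass: float
    versions: str

    def __post_init__(self) -> None:
        for el in SUPPORTED_ELEMENTS:
            if el not in self.monoisotopic or el not in self.average:
                raise CompositionError(f"mass tables missing element {el}")


def load_mass_tables() -> MassTables:
    """Load the packaged constants file (``data/atomic_masses.txt``)."""
    text = resources.files("lipidenum").joinpath("data/atomic_masses.txt").read_text()
    mono: Dict[str, float] = {}
    avg: Dict[str, float] = {}
    electron = None
    version = ""
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        if key == "version":
            version = value
        elif key == "electron":
            electron = float(value)
        elif key.startswith("monoisotopic."):
            mono[key.split(".", 1)[1]] = float(value)
        elif key.startswith("average."):
            avg[key.split(".", 1)[1]] = float(value)
    assert electron is not None, "constants file lacks electron mass"
    return MassTables(monoisotopic=mono, average=avg, electron_mass=electron, versions=version)


TABLES = load_mass_tables()


def exact_mass(c: ElementCount, tables: MassTables = TABLES) -> float:
    """Monoisotopic mass in Da: sum of principal-isotope masses x counts."""
    return sum(tables.monoisotopic[el] * n for el, n in c)


def average_mass(c: ElementCount, tables: MassTables = TABLES) -> float:
    """Average mass in Da: sum of standard atomic weights x counts."""
    return sum(tables.average[el] * n for el, n in c)


@dataclass(frozen=True)
class IonMode:
    """An MS ion mode: label, charge, adduct composition and electron term.

    ``delta_composition`` is the atom added (positive adducts, e.g. H for
    [M+H]+) or removed (negative, [M-H]-); ``removes`` flags removal.
    The observed m/z for singly charged modes is::

        m/z = neutral_mass +/- adduct_atom_mass -/+ electron_mass

    A cation has lost one electron relative to the neutral-atoms sum, an
    anion has gained one.  For [M+H]+ this is equivalent to adding a bare
    proton (1.00727646 Da); the hydrogen-atom-vs-proton convention is thus
    explicit rather than implicit.
    """

    label: str
    charge: int
    delta_composition: ElementCount
    removes: bool = False

    def mz(self, neutral_mass: float, mass_type: str = "exact", tables: MassTables = TABLES,
           electron_correction: bool = True) -> float:
        if neutral_mass <= 0:
            raise ValueError("neutral mass must be positive")
        if self.charge == 0:
            return neutral_mass
        mass_fn = exact_mass if mass_type == "exact" else average_mass
        delta = mass_fn(self.delta_composition, tables)
        signed = -delta if self.removes else delta
        electron = tables.electron_mass if electron_correction else 0.0
        return (neutral_mass + signed - self.charge * electron) / abs(self.charge)


def _mode(label: str, charge: int, element: str = "", removes: bool = False) -> IonMode:
    delta = ElementCount.of(**{element: 1}) if element else EMPTY
    return IonMode(label=label, charge=charge, delta_composition=delta, removes=removes)


#: The six supported ion modes (label -> IonMode).
ION_MODES: Dict[str, IonMode] = {
    "M+H": _mode("M+H", +1, "H"),
    "M+K": _mode("M+K", +1, "K"),
    "M+Li": _mode("M+Li", +1, "Li"),
    "M+Na": _mode("M+Na", +1, "Na"),
    "M-H": _mode("M-H", -1, "H", removes=True),
    "Neutral": _mode("Neutral", 0),
}


def get_ion_mode(label: str) -> IonMode:
    """Look up an ion mode, accepting minor label variants ([M+H]+, m+h...)."""
    key = label.strip().strip("[]").split("]")[0]
    key = key.replace(" ", "").replace("−", "-").replace("–", "-")
    key = key.rstrip("+-") if key.lower() != "m-h" else key
    lookup = {k.lower(): v for k, v in ION_MODES.items()}
    norm = key.lower()
    if norm in ("m-h",):
        return ION_MODES["M-H"]
    if norm in lookup:
        return lookup[norm]
    raise KeyError(f"unknown ion mode {label!r}; expected one of {sorted(ION_MODES)}")


def adduct_mz(neutral_mass: float, mode: IonMode | str, mass_type: str = "exact",
              tables: MassTables = TABLES, electron_correction: bool = True) -> float:
    """m/z of a neutral species observed in the given ion mode.

    ``mass_type`` selects whether the adduct atom contributes its
    monoisotopic ("exact") or average mass, matching the mass scale used
    for the neutral species.  Neutral mode returns the mass unchanged.
    ``electron_correction=False`` switches [M+H]+ from proton arithmetic
    to hydrogen-atom arithmetic (and likewise for the other charged
    modes); the default applies the physically correct electron term,
    which matters at the tightest supported tolerance (0.0001 Da).
    """
    if isinstance(mode, str):
        mode = get_ion_mode(mode)
    return mode.mz(neutral_mass, mass_type=mass_type, tables=tables,
                   electron_correction=electron_correction)
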