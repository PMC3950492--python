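"""Exhaustive species enumeration under a configurable chain rule.

The species space is the cartesian product of the two *sn*-position chain
spaces for each registered headgroup.  A :class:`ChainRule` pins down what
counts as an admissible chain: the carbon and unsaturation ranges, which
linkages are allowed at each position, whether lyso (free hydroxyl)
positions are allowed, and whether a ``(c, u)`` combination must admit at
least one legal double-bond placement under the drawing constraints
(first double bond at carbon >= ``s_min`` for the linkage, consecutive
double-bond starts separated by >= ``d`` carbons).

The published per-class species count this enumeration is calibrated
against (92,073 per headgroup) is not a perfect square, while every rule
in this family yields ``|sn1 space| x |sn2 space|`` (minus one when the
di-lyso species is excluded).  :func:`calibrate_chain_rule` searches the
whole family honestly and reports matches, or — as with that target — the
absence of any match; :func:`nearest_rules` reports the closest
configurations.  The shipped :data:`DEFAULT_RULE` is the chemically
conventional member of the family, not a numerological fit.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from .components import (
    C_MAX,
    HEADGROUPS,
    LYSO,
    U_MAX,
    Chain,
    Headgroup,
    Linkage,
    Species,
)

__all__ = [
    "ChainRule",
    "DEFAULT_RULE",
    "chain_space",
    "enumerate_class",
    "class_count",
    "total_count",
    "species_name",
    "parse_name",
    "NameError_",
    "calibrate_chain_rule",
    "nearest_rules",
    "default_rule_family",
]

_CHAIN_LINKAGES = (Linkage.ACYL, Linkage.ALKYL, Linkage.ALKENYL)


@dataclass(frozen=True)
class ChainRule:
    """Constraints defining the admissible chain space at each *sn* position.

    ``s_min`` maps a linkage to the first admissible double-bond start
    carbon (for alkenyl this governs the bonds *beyond* the vinyl ether,
    which always occupies carbons 1-2).  ``d`` is the minimum start-to-start
    spacing between consecutive double bonds (``d >= 2``: two double bonds
    may not share a carbon; ``d = 2`` permits conjugation).
    """

    carbon_range: Tuple[int, int] = (0, C_MAX)
    max_unsaturations: int = U_MAX
    s_min_acyl: int = 2
    s_min_alkyl: int = 2
    s_min_alkenyl: int = 3
    d: int = 2
    sn1_linkages: Tuple[Linkage, ...] = _CHAIN_LINKAGES
    sn2_linkages: Tuple[Linkage, ...] = _CHAIN_LINKAGES
    allow_lyso_sn1: bool = True
    allow_lyso_sn2: bool = True
    allow_dilyso: bool = True
    enforce_feasible_unsaturation: bool = True

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("double-bond start spacing d must be >= 2")
        if self.s_min_acyl < 2:
            raise ValueError("acyl s_min must be >= 2 (carbon 1 is the carbonyl)")
        lo, hi = self.carbon_range
        if not (0 <= lo <= hi <= C_MAX):
            raise ValueError(f"carbon_range must lie within 0..{C_MAX}")
        if not 0 <= self.max_unsaturations <= U_MAX:
            raise ValueError(f"max_unsaturations must lie within 0..{U_MAX}")

    def s_min(self, linkage: Linkage) -> int:
        return {
            Linkage.ACYL: self.s_min_acyl,
            Linkage.ALKYL: self.s_min_alkyl,
            Linkage.ALKENYL: self.s_min_alkenyl,
        }[linkage]

    def chain_ok(self, chain: Chain) -> bool:
        """Is this chain admissible (ignoring per-position linkage sets)?"""
        if chain.is_lyso:
            return True
        lo, hi = self.carbon_range
        c_lo = max(lo, 2 if chain.linkage is Linkage.ALKENYL else 1)
        if not c_lo <= chain.c <= hi:
            return False
        if not 0 <= chain.u <= self.max_unsaturations:
            return False
        if chain.hydrogens < 0:
            return False
        if self.enforce_feasible_unsaturation and chain.u >= 1:
            # last double bond occupies carbons (s, s+1); earliest legal
            # packing puts start k at s_min + d*(k-1)
            if self.s_min(chain.linkage) + self.d * (chain.u - 1) + 1 > chain.c:
                return False
        return True


DEFAULT_RULE = ChainRule()


def chain_space(rule: ChainRule, position: str) -> List[Chain]:
    """All admissible chains at ``position`` ("sn1" or "sn2"), sorted.

    Deterministic, duplicate-free ordering: hydroxyl first, then by
    (linkage, carbons, unsaturations).
    """
    if position not in ("sn1", "sn2"):
        raise ValueError("position must be 'sn1' or 'sn2'")
    linkages = rule.sn1_linkages if position == "sn1" else rule.sn2_linkages
    lyso = rule.allow_lyso_sn1 if position == "sn1" else rule.allow_lyso_sn2
    out: List[Chain] = [LYSO] if lyso else []
    lo, hi = rule.carbon_range
    for linkage in sorted(set(linkages), key=lambda l: l.sort_key):
        if linkage is Linkage.HYDROXYL:
            continue
        for c in range(max(lo, 1), hi + 1):
            for u in range(0, rule.max_unsaturations + 1):
                ch = Chain(linkage, c, u)
                if rule.chain_ok(ch):
                    out.append(ch)
    return out


def enumerate_class(h: Headgroup, rule: ChainRule = DEFAULT_RULE) -> Iterator[Species]:
    """Stream every species of one headgroup class, in canonical order.

    Ordered (sn-1, sn-2) pairs over the two chain spaces; inversions are
    distinct species.  The di-lyso species is included iff
    ``rule.allow_dilyso``.  The stream is deterministic and duplicate-free.
    """
    sp1 = chain_space(rule, "sn1")
    sp2 = chain_space(rule, "sn2")
    skip_dilyso = not rule.allow_dilyso
    for c1 in sp1:
        for c2 in sp2:
            if skip_dilyso and c1.is_lyso and c2.is_lyso:
                continue
            yield Species(h, c1, c2)


@lru_cache(maxsize=None)
def _linkage_space_size(linkage: Linkage, carbon_range: Tuple[int, int], max_u: int,
                        s_min: int, d: int, enforce: bool) -> int:
    lo, hi = carbon_range
    c_lo = max(lo, 2 if linkage is Linkage.ALKENYL else 1)
    n = 0
    for c in range(c_lo, hi + 1):
        for u in range(0, max_u + 1):
            if Chain(linkage, c, u).hydrogens < 0:
                continue
            if enforce and u >= 1 and s_min + d * (u - 1) + 1 > c:
                continue
            n += 1
    return n


def _space_size(rule: ChainRule, position: str) -> int:
    linkages = rule.sn1_linkages if position == "sn1" else rule.sn2_linkages
    lyso = rule.allow_lyso_sn1 if position == "sn1" else rule.allow_lyso_sn2
    n = 1 if lyso else 0
    for linkage in set(linkages):
        if linkage is Linkage.HYDROXYL:
            continue
        n += _linkage_space_size(
            linkage, rule.carbon_range, rule.max_unsaturations,
            rule.s_min(linkage), rule.d, rule.enforce_feasible_unsaturation,
        )
    return n


def class_count(rule: ChainRule = DEFAULT_RULE) -> int:
    """Species count per class (identical for every headgroup)."""
    n1 = _space_size(rule, "sn1")
    n2 = _space_size(rule, "sn2")
    n = n1 * n2
    if not rule.allow_dilyso and rule.allow_lyso_sn1 and rule.allow_lyso_sn2:
        n -= 1
    return n


def total_count(rule: ChainRule = DEFAULT_RULE) -> int:
    """Species count over all 16 headgroup variants."""
    return len(HEADGROUPS) * class_count(rule)


# ---------------------------------------------------------------------------
# Shorthand names


def species_name(s: Species) -> str:
    """Canonical shorthand, e.g. ``PI[4,5]P2(O-16:0/20:4)``."""
    return s.name


_NAME_RE = re.compile(r"^(?P<head>[^()]+)\((?P<sn1>[^/]+)/(?P<sn2>[^/]+)\)$")
_CHAIN_RE = re.compile(r"^(?P<prefix>O-|P-)?(?P<c>\d+):(?P<u>\d+)$")


class NameError_(ValueError):
    """Raised for a malformed or out-of-range species shorthand."""


def _normalise(text: str) -> str:
    return text.replace(" ", "").replace("_", "").replace(" ", "")


def _lookup_headgroup(token: str) -> Headgroup:
    token = _normalise(token)
    for h in HEADGROUPS.values():
        if token.upper() in (h.id.upper(), _normalise(h.display).upper()):
            return h
    raise NameError_(
        f"unknown headgroup {token!r}; expected one of "
        f"{[h.display for h in HEADGROUPS.values()]}"
    )


def _parse_chain(token: str) -> Chain:
    token = _normalise(token)
    m = _CHAIN_RE.match(token)
    if not m:
        raise NameError_(
            f"malformed chain token {token!r}; expected forms like 18:0, O-16:0, P-18:1, 0:0"
        )
    c, u = int(m.group("c")), int(m.group("u"))
    prefix = m.group("prefix") or ""
    if c == 0:
        if u != 0 or prefix:
            raise NameError_(f"a 0-carbon position must be plain 0:0, got {token!r}")
        return LYSO
    linkage = {"": Linkage.ACYL, "O-": Linkage.ALKYL, "P-": Linkage.ALKENYL}[prefix]
    try:
        return Chain(linkage, c, u).validate()
    except ValueError as err:
        raise NameError_(str(err)) from err


def parse_name(text: str) -> Species:
    """Parse shorthand into a Species; tolerant of whitespace/subscripts.

    ``parse_name(species_name(s)) == s`` for every enumerable species.
    """
    m = _NAME_RE.match(_normalise(text.strip()))
    if not m:
        raise NameError_(
            f"cannot parse {text!r}; expected HEAD(chain/chain), e.g. PI(18:0/22:6)"
        )
    return Species(
        _lookup_headgroup(m.group("head")),
        _parse_chain(m.group("sn1")),
        _parse_chain(m.group("sn2")),
    )


# ---------------------------------------------------------------------------
# Calibration against a published per-class count


def default_rule_family() -> Iterator[ChainRule]:
    """The documented search family for per-class count calibration.

    Spans first-double-bond positions, start spacing, feasibility
    enforcement, per-position linkage sets, and the lyso/di-lyso toggles.
    """
    linkage_subsets = [
        tuple(sub)
        for r in (1, 2, 3)
        for sub in itertools.combinations(_CHAIN_LINKAGES, r)
    ]
    for s_acyl in (2, 3):
        for s_alkyl in (1, 2, 3):
            for s_alkenyl in (2, 3, 4):
                for d in (2, 3):
                    for enforce in (True, False):
                        for l1 in linkage_subsets:
                            for l2 in linkage_subsets:
                                for ly1, ly2 in ((True, True), (True, False), (False, True), (False, False)):
                                    for dilyso in ((True, False) if (ly1 and ly2) else (True,)):
                                        yield ChainRule(
                                            s_min_acyl=s_acyl,
                                            s_min_alkyl=s_alkyl,
                                            s_min_alkenyl=s_alkenyl,
                                            d=d,
                                            sn1_linkages=l1,
                                            sn2_linkages=l2,
                                            allow_lyso_sn1=ly1,
                                            allow_lyso_sn2=ly2,
                                            allow_dilyso=dilyso,
                                            enforce_feasible_unsaturation=enforce,
                                        )


def calibrate_chain_rule(
    target_per_class: int,
    family: Optional[Iterable[ChainRule]] = None,
) -> List[ChainRule]:
    """All family members whose per-class species count equals the target.

    Counts are computed by exact enumeration of the chain spaces.  An empty
    list is an honest negative result, not an error.
    """
    if family is None:
        family = default_rule_family()
    return [rule for rule in family if class_count(rule) == target_per_class]


def nearest_rules(
    target_per_class: int,
    family: Optional[Iterable[ChainRule]] = None,
    k: int = 5,
) -> List[Tuple[int, ChainRule]]:
    """The k family members with per-class count closest to the target."""
    if family is None:
        family = default_rule_family()
    scored = sorted(
        ((class_count(rule), rule) for rule in family),
        key=lambda cr: (abs(cr[0] - target_per_class), cr[0]),
    )
    out: List[Tuple[int, ChainRule]] = []
    seen_counts = set()
    for count, rule in scored:
        if count in seen_counts:
            continue
        seen_counts.add(count)
        out.append((count, rule))
        if len(out) >= k:
            break
    return out
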