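"""Indexed m/z search over the enumerated species database.

The index stores the *neutral* exact and average mass of every species in
sorted order; a query m/z is transformed back to a neutral-mass window by
inverting the ion-mode adduct arithmetic, so one index serves all six ion
modes.  Hits are filtered by headgroup class, chain-carbon parity and the
"predicted to be common" chain list, then sorted by |delta| (ascending,
ties broken by canonical name).

Mass tolerances are absolute, in Da (amu), symmetric and inclusive at both
window edges, and restricted to the supported range 0.0001..2 Da.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .components import (
    HEADGROUPS,
    NON_PI_IDS,
    PI_FAMILY_IDS,
    Chain,
    Headgroup,
    Linkage,
    Species,
)
from .enumerate import ChainRule, DEFAULT_RULE, chain_space
from .masses import (
    TABLES,
    ElementCount,
    IonMode,
    adduct_mz,
    average_mass,
    exact_mass,
    get_ion_mode,
)
from .components import GLYCEROPHOSPHATE_CORE, chain_delta

__all__ = [
    "TOLERANCE_MIN",
    "TOLERANCE_MAX",
    "CLASS_FILTERS",
    "Query",
    "SearchHit",
    "CommonChainList",
    "DEFAULT_COMMON_CHAINS",
    "class_filter_members",
    "best_prediction_filter",
    "LipidIndex",
    "build_index",
    "build_database_index",
]

TOLERANCE_MIN = 0.0001
TOLERANCE_MAX = 2.0

#: Aggregate class-filter labels (individual headgroup ids are also valid).
CLASS_FILTERS = ("ALL", "PI_PLUS_PIPX", "ALL_WITHOUT_PIPX")


def class_filter_members(filter_label: str) -> Set[str]:
    """Headgroup ids selected by a class filter.

    ``PI_PLUS_PIPX`` is the eight-member PI superfamily;
    ``ALL_WITHOUT_PIPX`` is everything except the phosphorylated PIPx
    metabolites (so the PI structural precursor itself is retained).
    """
    label = filter_label.strip().upper().replace("-", "_").replace("+", "_PLUS_")
    label = label.replace("__", "_")
    if label == "ALL":
        return set(HEADGROUPS)
    if label in ("PI_PLUS_PIPX", "PIPLUSPIPX"):
        return set(PI_FAMILY_IDS)
    if label == "ALL_WITHOUT_PIPX":
        return set(NON_PI_IDS) | {"PI"}
    # individual headgroup id / display form
    from .enumerate import _lookup_headgroup, NameError_

    try:
        return {_lookup_headgroup(filter_label).id}
    except NameError_ as err:
        raise ValueError(
            f"unknown class filter {filter_label!r}; expected a headgroup id, "
            f"'PI_PLUS_PIPX', 'ALL_WITHOUT_PIPX' or 'ALL'"
        ) from err


@dataclass(frozen=True)
class Query:
    """An m/z search request."""

    mz: float
    tolerance: float
    ion_mode: str = "Neutral"
    mass_type: str = "exact"
    class_filter: str = "ALL"
    parity: str = "all"
    best_prediction: bool = False

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("query m/z must be positive")
        if not TOLERANCE_MIN <= self.tolerance <= TOLERANCE_MAX:
            raise ValueError(
                f"tolerance {self.tolerance} outside supported range "
                f"[{TOLERANCE_MIN}, {TOLERANCE_MAX}] Da"
            )
        if self.mass_type not in ("exact", "average"):
            raise ValueError("mass_type must be 'exact' or 'average'")
        if self.parity not in ("all", "even_only"):
            raise ValueError("parity must be 'all' or 'even_only'")
        get_ion_mode(self.ion_mode)       # validates
        class_filter_members(self.class_filter)  # validates


@dataclass(frozen=True)
class SearchHit:
    """One matching species with its theoretical m/z and signed delta (Da)."""

    species: Species
    theoretical_mz: float
    delta: float

    @property
    def name(self) -> str:
        return self.species.name


@dataclass(frozen=True)
class CommonChainList:
    """Chains deemed prevalent in mammalian membranes ("common" filter)."""

    chains: Tuple[Chain, ...]
    source: str = ""

    def __contains__(self, chain: Chain) -> bool:
        return chain in self.chains


def _load_default_common() -> CommonChainList:
    text = resources.files("lipidenum").joinpath("data/common_chains.txt").read_text()
    chains = []
    source = ""
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            source += line.lstrip("# ") + " "
            continue
        linkage_s, token = line.split()
        c, u = token.split(":")
        chains.append(Chain(Linkage(linkage_s), int(c), int(u)).validate())
    return CommonChainList(chains=tuple(chains), source=source.strip())


DEFAULT_COMMON_CHAINS = _load_default_common()


def best_prediction_filter(
    hits: Sequence[SearchHit],
    common: CommonChainList = DEFAULT_COMMON_CHAINS,
) -> List[SearchHit]:
    """Keep hits whose every non-lyso chain is in the common-chain list.

    Idempotent; pure-lyso species always survive.
    """
    out = []
    for h in hits:
        chains = [c for c in (h.species.sn1, h.species.sn2) if not c.is_lyso]
        if all(c in common for c in chains):
            out.append(h)
    return out


class LipidIndex:
    """Sorted-array index over species neutral masses.

    Species are stored column-wise in numpy arrays (headgroup index and the
    two chain descriptors) with exact and average neutral masses; a search
    inverts the query's adduct transform and takes a ``searchsorted``
    window over the relevant mass column.
    """

    _HG_IDS = tuple(HEADGROUPS)

    def __init__(self, columns: Dict[str, np.ndarray]):
        self._c = columns
        n = len(columns["exact"])
        for v in columns.values():
            assert len(v) == n
        self._order = {
            "exact": np.argsort(columns["exact"], kind="stable"),
            "average": np.argsort(columns["average"], kind="stable"),
        }

    def __len__(self) -> int:
        return len(self._c["exact"])

    # -- construction -------------------------------------------------

    @classmethod
    def from_species(cls, species: Iterable[Species]) -> "LipidIndex":
        hg_pos = {hid: i for i, hid in enumerate(cls._HG_IDS)}
        link_pos = {l: i for i, l in enumerate(Linkage)}
        rows = []
        for s in species:
            rows.append((
                hg_pos[s.headgroup.id],
                link_pos[s.sn1.linkage], s.sn1.c, s.sn1.u,
                link_pos[s.sn2.linkage], s.sn2.c, s.sn2.u,
                s.exact_mass, s.average_mass,
            ))
        if rows:
            arr = np.array(rows, dtype=float)
        else:
            arr = np.zeros((0, 9))
        cols = {
            "hg": arr[:, 0].astype(np.int16),
            "l1": arr[:, 1].astype(np.int8), "c1": arr[:, 2].astype(np.int8),
            "u1": arr[:, 3].astype(np.int8),
            "l2": arr[:, 4].astype(np.int8), "c2": arr[:, 5].astype(np.int8),
            "u2": arr[:, 6].astype(np.int8),
            "exact": arr[:, 7], "average": arr[:, 8],
        }
        return cls(cols)

    @classmethod
    def build(
        cls,
        headgroup_ids: Optional[Sequence[str]] = None,
        rule: ChainRule = DEFAULT_RULE,
    ) -> "LipidIndex":
        """Vectorized full-database build (equivalent to streaming all
        species through :meth:`from_species`, but fast enough for the
        multi-million-species default space)."""
        if headgroup_ids is None:
            headgroup_ids = list(HEADGROUPS)
        link_pos = {l: i for i, l in enumerate(Linkage)}
        sp1 = chain_space(rule, "sn1")
        sp2 = chain_space(rule, "sn2")

        def chain_arrays(chains: List[Chain]):
            l = np.array([link_pos[c.linkage] for c in chains], dtype=np.int8)
            cc = np.array([c.c for c in chains], dtype=np.int8)
            uu = np.array([c.u for c in chains], dtype=np.int8)
            em = np.array([exact_mass(chain_delta(c)) for c in chains])
            am = np.array([average_mass(chain_delta(c)) for c in chains])
            return l, cc, uu, em, am

        l1, c1, u1, em1, am1 = chain_arrays(sp1)
        l2, c2, u2, em2, am2 = chain_arrays(sp2)
        n1, n2 = len(sp1), len(sp2)

        keep = np.ones(n1 * n2, dtype=bool)
        if not rule.allow_dilyso and rule.allow_lyso_sn1 and rule.allow_lyso_sn2:
            lyso_code = link_pos[Linkage.HYDROXYL]
            keep = ~((np.repeat(l1 == lyso_code, n2)) & (np.tile(l2 == lyso_code, n1)))

        hg_pos = {hid: i for i, hid in enumerate(cls._HG_IDS)}
        blocks = {k: [] for k in ("hg", "l1", "c1", "u1", "l2", "c2", "u2", "exact", "average")}
        pair = {
            "l1": np.repeat(l1, n2)[keep], "c1": np.repeat(c1, n2)[keep],
            "u1": np.repeat(u1, n2)[keep],
            "l2": np.tile(l2, n1)[keep], "c2": np.tile(c2, n1)[keep],
            "u2": np.tile(u2, n1)[keep],
        }
        chain_exact = (np.repeat(em1, n2) + np.tile(em2, n1))[keep]
        chain_avg = (np.repeat(am1, n2) + np.tile(am2, n1))[keep]
        core_exact = exact_mass(GLYCEROPHOSPHATE_CORE)
        core_avg = average_mass(GLYCEROPHOSPHATE_CORE)
        for hid in headgroup_ids:
            h = HEADGROUPS[hid]
            blocks["hg"].append(np.full(keep.sum(), hg_pos[hid], dtype=np.int16))
            for k in ("l1", "c1", "u1", "l2", "c2", "u2"):
                blocks[k].append(pair[k])
            blocks["exact"].append(core_exact + exact_mass(h.composition_delta) + chain_exact)
            blocks["average"].append(core_avg + average_mass(h.composition_delta) + chain_avg)
        cols = {k: np.concatenate(v) if v else np.zeros(0) for k, v in blocks.items()}
        return cls(cols)

    # -- row reconstruction -------------------------------------------

    def species_at(self, i: int) -> Species:
        c = self._c
        links = list(Linkage)
        return Species(
            HEADGROUPS[self._HG_IDS[int(c["hg"][i])]],
            Chain(links[int(c["l1"][i])], int(c["c1"][i]), int(c["u1"][i])),
            Chain(links[int(c["l2"][i])], int(c["c2"][i]), int(c["u2"][i])),
        )

    # -- search --------------------------------------------------------

    def search(self, q: Query, common: CommonChainList = DEFAULT_COMMON_CHAINS) -> List[SearchHit]:
        """All species whose theoretical m/z lies within ``mz +/- tolerance``
        and pass the class/parity/best-prediction filters."""
        mode = get_ion_mode(q.ion_mode)
        col = self._c[q.mass_type]
        order = self._order[q.mass_type]
        # invert the adduct transform: neutral mass window for the query
        if mode.charge == 0:
            lo_neutral, hi_neutral = q.mz - q.tolerance, q.mz + q.tolerance
        else:
            # mz = neutral + shift  =>  neutral = mz - shift
            shift = adduct_mz(1000.0, mode, q.mass_type) - 1000.0
            lo_neutral = q.mz - q.tolerance - shift
            hi_neutral = q.mz + q.tolerance - shift
        sorted_masses = col[order]
        lo = np.searchsorted(sorted_masses, lo_neutral - 1e-9, side="left")
        hi = np.searchsorted(sorted_masses, hi_neutral + 1e-9, side="right")
        cand = order[lo:hi]
        if len(cand) == 0:
            return []

        wanted = class_filter_members(q.class_filter)
        hg_ok = np.isin(self._c["hg"][cand],
                        [i for i, hid in enumerate(self._HG_IDS) if hid in wanted])
        cand = cand[hg_ok]
        if q.parity == "even_only":
            c = self._c
            lyso_code = list(Linkage).index(Linkage.HYDROXYL)
            ok1 = (c["l1"][cand] == lyso_code) | (c["c1"][cand] % 2 == 0)
            ok2 = (c["l2"][cand] == lyso_code) | (c["c2"][cand] % 2 == 0)
            cand = cand[ok1 & ok2]

        hits = []
        for i in cand:
            neutral = float(col[i])
            tmz = adduct_mz(neutral, mode, q.mass_type) if mode.charge else neutral
            delta = tmz - q.mz
            if abs(delta) <= q.tolerance + 1e-12:
                hits.append(SearchHit(self.species_at(int(i)), tmz, delta))
        if q.best_prediction:
            hits = best_prediction_filter(hits, common)
        hits.sort(key=lambda h: (abs(h.delta), h.name))
        return hits


def build_index(species: Iterable[Species]) -> LipidIndex:
    """Build a searchable index from any finite species stream."""
    return LipidIndex.from_species(species)


def build_database_index(
    headgroup_ids: Optional[Sequence[str]] = None,
    rule: ChainRule = DEFAULT_RULE,
) -> LipidIndex:
    """Build the index for whole headgroup classes via the fast path."""
    return LipidIndex.build(headgroup_ids, rule)
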