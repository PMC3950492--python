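"""CSV/config readers and writers.

All data files are plain text: UTF-8, comma-separated with a header row,
"." decimal separator, masses printed with 4 decimal places (the tightest
supported search tolerance is 0.0001 Da).  Outputs contain no timestamps,
so repeated runs are byte-identical.
"""

from __future__ import annotations

import csv
from dataclasses import asdict
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import yaml

from .components import HEADGROUPS, Linkage, Species
from .enumerate import ChainRule, DEFAULT_RULE, enumerate_class
from .search import Query, SearchHit

__all__ = [
    "DATABASE_COLUMNS",
    "RESULT_COLUMNS",
    "write_database_csv",
    "read_database_csv",
    "write_results_csv",
    "read_peaklist",
    "save_chain_rule",
    "load_chain_rule",
]

DATABASE_COLUMNS = (
    "name", "headgroup_id", "lipidmaps_code",
    "sn1_linkage", "sn1_c", "sn1_u", "sn2_linkage", "sn2_c", "sn2_u",
    "formula", "exact_mass", "average_mass",
)

RESULT_COLUMNS = (
    "query_mz", "tolerance", "ion_mode", "mass_type",
    "name", "lipidmaps_code", "formula", "theoretical_mz", "delta_da",
)


def _mass(x: float) -> str:
    return f"{x:.4f}"


def write_database_csv(
    path: str,
    headgroup_ids: Optional[Sequence[str]] = None,
    rule: ChainRule = DEFAULT_RULE,
    progress: Optional[Callable[[str, int], None]] = None,
) -> dict:
    """Write the species database; returns {headgroup_id: row count}."""
    if headgroup_ids is None:
        headgroup_ids = list(HEADGROUPS)
    counts = {}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DATABASE_COLUMNS)
        for hid in headgroup_ids:
            h = HEADGROUPS[hid]
            n = 0
            for s in enumerate_class(h, rule):
                w.writerow((
                    s.name, h.id, h.lipidmaps_code,
                    s.sn1.linkage.value, s.sn1.c, s.sn1.u,
                    s.sn2.linkage.value, s.sn2.c, s.sn2.u,
                    s.composition.hill_formula(),
                    _mass(s.exact_mass), _mass(s.average_mass),
                ))
                n += 1
            counts[hid] = n
            if progress:
                progress(hid, n)
    return counts


def read_database_csv(path: str) -> List[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def write_results_csv(path: str, blocks: Iterable[Tuple[Query, Sequence[SearchHit]]]) -> None:
    """One row per hit; empty queries contribute only to the header."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RESULT_COLUMNS)
        for q, hits in blocks:
            for h in hits:
                w.writerow((
                    q.mz, q.tolerance, q.ion_mode, q.mass_type,
                    h.species.name, h.species.headgroup.lipidmaps_code,
                    h.species.composition.hill_formula(),
                    _mass(h.theoretical_mz), _mass(h.delta),
                ))


class PeaklistError(ValueError):
    """Raised for a peak list whose m/z column cannot be parsed."""


def read_peaklist(path: str) -> List[float]:
    """Read a one-column peak list CSV (column "mz", header required).

    Non-numeric rows are reported with their line numbers.
    """
    mzs: List[float] = []
    bad: List[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "mz" not in reader.fieldnames:
            raise PeaklistError('peak list must have a header row with an "mz" column')
        for lineno, row in enumerate(reader, start=2):
            raw = (row.get("mz") or "").strip()
            if not raw:
                continue
            try:
                mzs.append(float(raw))
            except ValueError:
                bad.append(f"line {lineno}: {raw!r}")
    if bad:
        raise PeaklistError("non-numeric m/z values: " + "; ".join(bad))
    return mzs


def save_chain_rule(rule: ChainRule, path: str) -> None:
    data = asdict(rule)
    data["sn1_linkages"] = [l.value for l in rule.sn1_linkages]
    data["sn2_linkages"] = [l.value for l in rule.sn2_linkages]
    data["carbon_range"] = list(rule.carbon_range)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_chain_rule(path: str) -> ChainRule:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["sn1_linkages"] = tuple(Linkage(l) for l in data["sn1_linkages"])
    data["sn2_linkages"] = tuple(Linkage(l) for l in data["sn2_linkages"])
    data["carbon_range"] = tuple(data["carbon_range"])
    return ChainRule(**data)
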