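import random

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from lipidenum import (
    DEFAULT_COMMON_CHAINS,
    HEADGROUPS,
    ChainRule,
    Linkage,
    adduct_mz,
    enumerate_class,
)

REDUCED_RULE = ChainRule(carbon_range=(0, 8), max_unsaturations=2)


@pytest.fixture
def toy_rule():
    """Tiny chain space: hydroxyl + acyl 1:0 + acyl 2:0 at each position."""
    return ChainRule(
        carbon_range=(0, 2),
        max_unsaturations=0,
        sn1_linkages=(Linkage.ACYL,),
        sn2_linkages=(Linkage.ACYL,),
    )


@pytest.fixture
def reduced_rule():
    """A reduced but structurally complete space for search/oracle tests."""
    return REDUCED_RULE


@pytest.fixture(scope="session")
def oracle_records():
    """Flat per-species records for the brute-force search oracle.

    One tuple per species of the reduced space:
    (name, exact_mass, average_mass, all_chains_even, all_chains_common, headgroup_id).
    """
    records = []
    for hid in HEADGROUPS:
        for s in enumerate_class(HEADGROUPS[hid], REDUCED_RULE):
            chains = [c for c in (s.sn1, s.sn2) if not c.is_lyso]
            records.append((
                s.name,
                s.exact_mass,
                s.average_mass,
                all(c.c % 2 == 0 for c in chains),
                all(c in DEFAULT_COMMON_CHAINS for c in chains),
                hid,
            ))
    return records


def brute_force_search(q, records):
    """Independent linear scan over precomputed species records."""
    from lipidenum import class_filter_members

    wanted = class_filter_members(q.class_filter)
    shift = (
        0.0
        if q.ion_mode == "Neutral"
        else adduct_mz(1000.0, q.ion_mode, q.mass_type) - 1000.0
    )
    lo, hi = q.mz - q.tolerance - 1e-12, q.mz + q.tolerance + 1e-12
    out = []
    for name, exact, avg, even, common, hid in records:
        if hid not in wanted:
            continue
        if q.parity == "even_only" and not even:
            continue
        if q.best_prediction and not common:
            continue
        neutral = exact if q.mass_type == "exact" else avg
        if lo <= neutral + shift <= hi:
            out.append(name)
    return sorted(out)


@pytest.fixture
def rng():
    return random.Random(20240217)
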