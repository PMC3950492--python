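"""Indexed m/z search vs brute-force oracle, filters and query validation."""

import pytest

from lipidenum import (
    HEADGROUPS,
    LYSO,
    Chain,
    CommonChainList,
    Linkage,
    Query,
    best_prediction_filter,
    build_database_index,
    build_index,
    class_filter_members,
    enumerate_class,
)
from lipidenum.search import SearchHit

from conftest import brute_force_search


class TestClassFilters:
    def test_single_id_is_exclusive(self):
        assert class_filter_members("PI34P2") == {"PI34P2"}

    def test_all_is_sixteen(self):
        assert len(class_filter_members("ALL")) == 16

    def test_pi_plus_pipx_is_the_superfamily(self):
        members = class_filter_members("PI_PLUS_PIPX")
        assert members == {"PI", "PI3P", "PI4P", "PI5P", "PI34P2", "PI35P2", "PI45P2", "PI345P3"}

    def test_all_without_pipx_keeps_the_pi_precursor(self):
        members = class_filter_members("ALL_WITHOUT_PIPX")
        assert "PI" in members
        assert members & {"PI3P", "PI4P", "PI5P", "PI34P2", "PI35P2", "PI45P2", "PI345P3"} == set()
        assert members | class_filter_members("PI_PLUS_PIPX") == class_filter_members("ALL")

    def test_cli_style_spellings(self):
        assert class_filter_members("pi+pipx") == class_filter_members("PI_PLUS_PIPX")
        assert class_filter_members("all-without-pipx") == class_filter_members("ALL_WITHOUT_PIPX")
        assert class_filter_members("PI[3,4]P2") == {"PI34P2"}

    def test_unknown_filter_rejected(self):
        with pytest.raises(ValueError):
            class_filter_members("everything")


class TestQueryValidation:
    @pytest.mark.parametrize("tol", [0.00009, 2.5, 0, -1])
    def test_out_of_range_tolerance_rejected(self, tol):
        with pytest.raises(ValueError):
            Query(mz=700, tolerance=tol)

    @pytest.mark.parametrize("tol", [0.0001, 1, 2])
    def test_boundary_tolerances_accepted(self, tol):
        Query(mz=700, tolerance=tol)

    def test_negative_mz_rejected(self):
        with pytest.raises(ValueError):
            Query(mz=-1, tolerance=1)


class TestIndex:
    def test_empty_index(self):
        idx = build_index([])
        assert len(idx) == 0
        assert idx.search(Query(mz=700, tolerance=2)) == []

    def test_toy_index_size(self, toy_rule):
        idx = build_index(enumerate_class(HEADGROUPS["PA"], toy_rule))
        assert len(idx) == 9

    def test_fast_build_matches_streamed_build(self, toy_rule):
        fast = build_database_index(["PA", "PI45P2"], toy_rule)
        slow = build_index(
            list(enumerate_class(HEADGROUPS["PA"], toy_rule))
            + list(enumerate_class(HEADGROUPS["PI45P2"], toy_rule))
        )
        assert len(fast) == len(slow)
        q = Query(mz=172.0, tolerance=2, ion_mode="Neutral")
        assert [h.name for h in fast.search(q)] == [h.name for h in slow.search(q)]


class TestSearchVsOracle:
    def test_random_queries_match_brute_force(self, reduced_rule, oracle_records, rng):
        idx = build_database_index(rule=reduced_rule)
        modes = ["M+H", "M+K", "M+Li", "M+Na", "M-H", "Neutral"]
        filters = ["ALL", "PI_PLUS_PIPX", "ALL_WITHOUT_PIPX", "PA", "PI45P2"]
        for _ in range(250):
            q = Query(
                mz=rng.uniform(150, 900),
                tolerance=rng.choice([0.0001, 0.01, 0.5, 2.0]),
                ion_mode=rng.choice(modes),
                mass_type=rng.choice(["exact", "average"]),
                class_filter=rng.choice(filters),
                parity=rng.choice(["all", "even_only"]),
                best_prediction=rng.random() < 0.2,
            )
            assert sorted(h.name for h in idx.search(q)) == brute_force_search(q, oracle_records)

    def test_hits_sorted_by_abs_delta_then_name(self, reduced_rule):
        idx = build_database_index(["PA", "PE"], reduced_rule)
        hits = idx.search(Query(mz=500, tolerance=2, ion_mode="M+H"))
        keys = [(abs(h.delta), h.name) for h in hits]
        assert keys == sorted(keys)
        assert all(abs(h.delta) <= 2 for h in hits)

    def test_tolerance_monotonicity(self, reduced_rule, rng):
        idx = build_database_index(["PC", "PI"], reduced_rule)
        for _ in range(25):
            mz = rng.uniform(200, 800)
            prev: set = set()
            for tol in (0.001, 0.05, 0.5, 1.0, 2.0):
                hits = {h.name for h in idx.search(Query(mz=mz, tolerance=tol))}
                assert prev <= hits
                prev = hits

    def test_filter_algebra(self, reduced_rule, rng):
        idx = build_database_index(rule=reduced_rule)
        for _ in range(10):
            mz = rng.uniform(200, 800)
            base = dict(mz=mz, tolerance=1.0, ion_mode="M-H")
            pi_pipx = {h.name for h in idx.search(Query(class_filter="PI_PLUS_PIPX", **base))}
            without = {h.name for h in idx.search(Query(class_filter="ALL_WITHOUT_PIPX", **base))}
            everything = {h.name for h in idx.search(Query(class_filter="ALL", **base))}
            pi_only = {h.name for h in idx.search(Query(class_filter="PI", **base))}
            assert pi_pipx | without == everything
            assert pi_pipx & without == pi_only


class TestBestPrediction:
    def _hit(self, sn1, sn2):
        from lipidenum.components import Species

        s = Species(HEADGROUPS["PC"], sn1, sn2)
        return SearchHit(s, s.exact_mass, 0.0)

    def test_empty_common_list_keeps_only_pure_lyso(self):
        hits = [
            self._hit(LYSO, LYSO),
            self._hit(Chain(Linkage.ACYL, 18, 0), LYSO),
        ]
        out = best_prediction_filter(hits, CommonChainList(chains=()))
        assert [h.name for h in out] == ["PC(0:0/0:0)"]

    def test_default_list_keeps_common_species(self):
        keep = self._hit(Chain(Linkage.ACYL, 18, 0), Chain(Linkage.ACYL, 22, 6))
        drop = self._hit(Chain(Linkage.ACYL, 17, 0), Chain(Linkage.ACYL, 22, 6))
        out = best_prediction_filter([keep, drop])
        assert [h.name for h in out] == [keep.name]

    def test_idempotent_subset(self):
        hits = [
            self._hit(Chain(Linkage.ACYL, 18, 1), LYSO),
            self._hit(Chain(Linkage.ALKYL, 18, 1), LYSO),
        ]
        once = best_prediction_filter(hits)
        assert best_prediction_filter(once) == once
        assert set(h.name for h in once) <= set(h.name for h in hits)
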