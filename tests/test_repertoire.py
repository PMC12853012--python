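import math
from itertools import combinations

import numpy as np
import pytest

from drpeptidome import (
    SampleInfo,
    classify_sharing,
    dominance_ratio,
    overlap_matrix,
    sbwb_fractions,
)
from drpeptidome.models import (
    AssignmentMode,
    AssignmentTable,
    BindingCall,
    BindingClass,
    Group,
    SharingCategory,
)
from drpeptidome.repertoire import AlleleUnit, classify_all_sharing

A, B = "DRB1*03:01", "DRB1*13:01"
AA = "ACDEFGHIKLMNPQRSTVWY"


def _peps(n, tag="A"):
    return ["AAAAAA" + tag + x + y for x, y in combinations(AA, 2)][:n]


def _table(sample_id, entries, mode=AssignmentMode.FILTERED):
    return AssignmentTable(sample_id, mode, entries)


class TestDominance:
    def test_simple_ratio(self):
        entries = {p: {A} for p in _peps(21, "X")}
        entries.update({p: {B} for p in _peps(3, "Y")})
        sample = SampleInfo("s", Group.CONTROL, A, B)
        res = dominance_ratio(_table("s", entries), sample)
        assert res.ratio == pytest.approx(7.0)
        assert res.inverse_ratio == pytest.approx(1 / 7.0)

    def test_antisymmetry(self, rng):
        sample = SampleInfo("s", Group.CONTROL, A, B)
        for _ in range(20):
            n_x, n_y = int(rng.integers(1, 50)), int(rng.integers(1, 50))
            entries = {p: {A} for p in _peps(n_x, "X")}
            entries.update({p: {B} for p in _peps(n_y, "Y")})
            res = dominance_ratio(_table("s", entries), sample)
            assert res.ratio * res.inverse_ratio == pytest.approx(1.0)

    def test_degenerate_counts(self):
        sample = SampleInfo("s", Group.CONTROL, A, B)
        res = dominance_ratio(_table("s", {}), sample)
        assert math.isnan(res.ratio)
        only_x = _table("s", {p: {A} for p in _peps(2)})
        assert math.isinf(dominance_ratio(only_x, sample).ratio)

    def test_homozygous_not_applicable(self):
        sample = SampleInfo("h", Group.CONTROL, A, A)
        res = dominance_ratio(_table("h", {p: {A} for p in _peps(5)}), sample)
        assert not res.applicable
        assert math.isnan(res.ratio)


class TestSbWbFractions:
    def _calls(self, peps, allele, cls):
        rank = {"SB": 0.5, "WB": 3.0}[cls]
        return [BindingCall(p, allele, rank, BindingClass(cls)) for p in peps]

    def test_normalised_fractions(self):
        sb = _peps(8, "X")
        wb = _peps(2, "Y")
        entries = {p: {A} for p in sb + wb}
        table = _table("s", entries, AssignmentMode.NONFILTERED)
        calls = self._calls(sb, A, "SB") + self._calls(wb, A, "WB")
        sample = SampleInfo("s", Group.CONTROL, A, B)
        fr = sbwb_fractions(calls, table, sample)
        assert fr[A] == pytest.approx((0.8, 0.2))
        assert B not in fr  # no peptides -> missing

    def test_all_weak(self):
        wb = _peps(4)
        table = _table("s", {p: {A} for p in wb}, AssignmentMode.NONFILTERED)
        sample = SampleInfo("s", Group.CONTROL, A, B)
        fr = sbwb_fractions(self._calls(wb, A, "WB"), table, sample)
        assert fr[A] == (0.0, 1.0)


class TestOverlapMatrix:
    def _setup(self, items_by_unit):
        """items_by_unit: {(sample, allele): [peptides]} -> tables + samples."""
        samples = {}
        tables = {}
        for (sid, allele), items in items_by_unit.items():
            samples.setdefault(sid, set()).add(allele)
            tables.setdefault(sid, {})
            for p in items:
                tables[sid].setdefault(p, set()).add(allele)
        sample_objs = []
        for sid, alleles in samples.items():
            al = sorted(alleles)
            if len(al) == 1:
                al = al * 2
            sample_objs.append(SampleInfo(sid, Group.CONTROL, al[0], al[1]))
        table_objs = [
            AssignmentTable(sid, AssignmentMode.NONFILTERED, entries)
            for sid, entries in tables.items()
        ]
        return table_objs, sample_objs

    def test_identical_units_full_overlap(self):
        peps = _peps(10)
        tables, samples = self._setup({("s1", A): peps, ("s1", B): peps})
        om = overlap_matrix(tables, samples)
        assert np.allclose(om.values, [[0, 1], [1, 0]])

    def test_disjoint_units(self):
        tables, samples = self._setup(
            {("s1", A): _peps(5, "X"), ("s1", B): _peps(5, "Y")}
        )
        om = overlap_matrix(tables, samples)
        assert np.allclose(om.values, [[1, 0], [0, 1]])

    def test_three_unit_toy_matches_hand_enumeration(self):
        # unit1: {p1..p4}; unit2: {p3..p6}; unit3: {p6}
        p = _peps(6)
        tables, samples = self._setup(
            {
                ("s1", A): p[0:4],
                ("s1", B): p[2:6],
                ("s2", A): [p[5]],
            }
        )
        om = overlap_matrix(tables, samples)
        units = om.units
        idx = {u: i for i, u in enumerate(units)}
        i1, i2, i3 = idx[AlleleUnit("s1", A)], idx[AlleleUnit("s1", B)], idx[
            AlleleUnit("s2", A)
        ]
        assert om.values[i1, i2] == pytest.approx(2 / 4)
        assert om.values[i2, i1] == pytest.approx(2 / 4)
        assert om.values[i2, i3] == pytest.approx(1 / 4)
        assert om.values[i3, i2] == pytest.approx(1.0)
        assert om.values[i1, i1] == pytest.approx(2 / 4)  # p1, p2 exclusive
        assert om.values[i3, i3] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_set_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        universe = _peps(50)
        layout = {}
        for sid, allele in [("s1", A), ("s1", B), ("s2", A), ("s2", B), ("s3", A)]:
            k = int(rng.integers(1, 40))
            layout[(sid, allele)] = list(
                rng.choice(universe, size=k, replace=False)
            )
        tables, samples = self._setup(layout)
        om = overlap_matrix(tables, samples)
        sets = {u: set(layout[(u.sample_id, u.allele)]) for u in om.units}
        n = len(om.units)
        for i in range(n):
            ui = om.units[i]
            others = set().union(
                *(sets[om.units[j]] for j in range(n) if j != i)
            )
            assert om.values[i, i] == pytest.approx(
                len(sets[ui] - others) / len(sets[ui])
            )
            for j in range(n):
                if i != j:
                    expected = len(sets[ui] & sets[om.units[j]]) / len(sets[ui])
                    assert om.values[i, j] == pytest.approx(expected)

    def test_empty_unit_gives_nan_row(self):
        samples = [SampleInfo("s1", Group.CONTROL, A, B)]
        tables = [
            AssignmentTable(
                "s1", AssignmentMode.NONFILTERED, {p: {A} for p in _peps(3)}
            )
        ]
        om = overlap_matrix(tables, samples)
        i_b = om.units.index(AlleleUnit("s1", B))
        assert np.all(np.isnan(om.values[i_b]))


class TestSharingClassification:
    def _tables(self):
        # s1: A+B het; s2: A+C het; peptides planted per category
        C = "DRB1*07:01"
        t1 = AssignmentTable(
            "s1",
            AssignmentMode.NONFILTERED,
            {
                "AAAAAAAAC": {A},  # unique
                "AAAAAAAAD": {A, B},  # dual
                "AAAAAAAAE": {A},  # allele-exclusive (also s2 on A)
                "AAAAAAAAF": {B},  # multiple (s2 on C)
                "AAAAAAAAG": {A, B},  # multiple (dual here, also s2)
            },
        )
        t2 = AssignmentTable(
            "s2",
            AssignmentMode.NONFILTERED,
            {
                "AAAAAAAAE": {A},
                "AAAAAAAAF": {C},
                "AAAAAAAAG": {C},
            },
        )
        return [t1, t2], C

    def test_categories(self):
        tables, C = self._tables()
        u1a = AlleleUnit("s1", A)
        assert classify_sharing("AAAAAAAAC", u1a, tables) is SharingCategory.UNIQUE
        assert classify_sharing("AAAAAAAAD", u1a, tables) is SharingCategory.DUAL
        assert (
            classify_sharing("AAAAAAAAE", u1a, tables)
            is SharingCategory.ALLELE_EXCLUSIVE
        )
        assert (
            classify_sharing("AAAAAAAAF", AlleleUnit("s1", B), tables)
            is SharingCategory.MULTIPLE
        )
        # dual within s1 but also present in s2 -> cross-sample dominates
        assert (
            classify_sharing("AAAAAAAAG", u1a, tables) is SharingCategory.MULTIPLE
        )

    def test_absent_peptide_errors(self):
        tables, _ = self._tables()
        with pytest.raises(ValueError):
            classify_sharing("AAAAAAAAC", AlleleUnit("s1", B), tables)

    def test_partition_over_cohort(self, small_cohort):
        """Every (peptide, unit) association gets exactly one category and
        counts reconcile with the assignment totals."""
        from drpeptidome import assign_nonfiltered
        from drpeptidome.models import index_calls

        idx = index_calls(small_cohort.calls)
        sample_map = {s.sample_id: s for s in small_cohort.samples}
        by_sample = {}
        for rec in small_cohort.peptides:
            if len(rec.sequence) < 9 or len(rec.sequence) > 25:
                continue
            by_sample.setdefault(rec.sample_id, set()).add(rec.sequence)
        tables = []
        for sid, peps in sorted(by_sample.items()):
            sub = {
                (p, a): idx[(p, a)]
                for p in peps
                for a in dict.fromkeys(sample_map[sid].alleles)
            }
            tables.append(assign_nonfiltered(sample_map[sid], sub))
        cats = classify_all_sharing(tables)
        n_assoc = sum(len(al) for t in tables for al in t.entries.values())
        assert len(cats) == n_assoc
        assert set(cats.values()) <= set(SharingCategory)
        # spot-check consistency with the single-association classifier
        items = sorted(cats, key=lambda x: (x[0], x[1]))[::37]
        for pep, unit in items:
            assert classify_sharing(pep, unit, tables) is cats[(pep, unit)]
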