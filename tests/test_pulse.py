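import math

import numpy as np
import pytest
from scipy import stats

from drpeptidome import (
    abundance_representation_corr,
    compartment_enrichment,
    holm_sidak,
    identify_pulse_induced,
    immunopeptidome_shares,
)
from drpeptidome.models import PeptideRecord, ProteinRecord
from drpeptidome.pulse import compartment_percentages, peptide_representation


class TestInducedSetLogic:
    def test_worked_example(self):
        sets = identify_pulse_induced({"A", "B", "C"}, {"B"}, {"A", "C", "D"})
        assert sets.induced_proteins == {"A", "C"}

    def test_pulsed_subset_of_control_yields_nothing(self):
        sets = identify_pulse_induced({"A"}, {"A", "B"}, {"A", "B"})
        assert sets.induced_proteins == set()

    def test_empty_lysate_errors(self):
        with pytest.raises(ValueError):
            identify_pulse_induced({"A"}, {"B"}, set())

    @pytest.mark.parametrize("seed", range(10))
    def test_random_triples_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"P{i}" for i in range(30)]
        p = {x for x in universe if rng.random() < 0.4}
        c = {x for x in universe if rng.random() < 0.4}
        lys = {x for x in universe if rng.random() < 0.5} or {"P0"}
        sets = identify_pulse_induced(p, c, lys)
        brute = {x for x in universe if x in p and x in lys and x not in c}
        assert sets.induced_proteins == brute

    def test_induced_peptides_need_one_induced_accession(self):
        peps = [
            PeptideRecord("AAAAAAAAA", "P-1", frozenset({"A", "Z"})),
            PeptideRecord("CCCCCCCCC", "P-1", frozenset({"Z"})),
        ]
        sets = identify_pulse_induced({"A", "Z"}, set(), {"A"}, peps)
        assert sets.induced_peptides == {"AAAAAAAAA"}


class TestShares:
    def test_reported_lysate_share(self):
        lysate = {f"L{i}" for i in range(1292)}
        induced = set(list(lysate)[:58])
        sets = identify_pulse_induced(induced, set(), lysate)
        prot_pct, _ = immunopeptidome_shares(sets, n_pulsed_binder_peptides=100)
        assert round(prot_pct, 1) == 4.5

    def test_zero_induced(self):
        sets = identify_pulse_induced({"X"}, {"X"}, {"X"})
        prot_pct, pep_pct = immunopeptidome_shares(sets, 10)
        assert prot_pct == 0.0 and pep_pct == 0.0

    def test_zero_denominator_errors(self):
        sets = identify_pulse_induced({"A"}, set(), {"A"})
        with pytest.raises(ValueError):
            immunopeptidome_shares(sets, 0)

    def test_planted_cohort_fractions_recovered(self, small_cohort):
        """Set logic on generated tables recovers the planted induced set."""
        from drpeptidome import filter_repertoire
        from drpeptidome.models import Group
        from drpeptidome.simulate import CONTAMINANT_ACCESSIONS

        kept, _ = filter_repertoire(small_cohort.peptides, CONTAMINANT_ACCESSIONS)
        groups = {s.sample_id: s.group for s in small_cohort.samples}
        pulsed = [p for p in kept if groups[p.sample_id] is Group.PULSED]
        control = [p for p in kept if groups[p.sample_id] is Group.CONTROL]
        sets = identify_pulse_induced(
            {a for p in pulsed for a in p.source_accessions},
            {a for p in control for a in p.source_accessions},
            set(small_cohort.lysate_sequences),
            pulsed,
        )
        gt = small_cohort.ground_truth
        assert sets.induced_proteins == gt.induced_proteins
        assert sets.induced_peptides == gt.induced_peptides


class TestSpearman:
    def test_perfect_concordance_and_reversal(self):
        ab = {f"P{i}": float(i) for i in range(5)}
        rep_up = {f"P{i}": i + 1 for i in range(5)}
        rep_down = {f"P{i}": 10 - i for i in range(5)}
        assert abundance_representation_corr(ab, rep_up)[0] == pytest.approx(1.0)
        assert abundance_representation_corr(ab, rep_down)[0] == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self, rng):
        """Tie-free n=10 table matches 1 - 6*sum(d^2)/(n(n^2-1))."""
        x = rng.permutation(10).astype(float)
        y = rng.permutation(10).astype(float)
        ab = {f"P{i}": x[i] for i in range(10)}
        rep = {f"P{i}": int(y[i]) for i in range(10)}
        rho, _ = abundance_representation_corr(ab, rep)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = 1 - 6 * np.sum((rx - ry) ** 2) / (10 * (10**2 - 1))
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_missing(self):
        ab = {f"P{i}": 1.0 for i in range(5)}
        rep = {f"P{i}": i for i in range(5)}
        rho, p = abundance_representation_corr(ab, rep)
        assert math.isnan(rho) and math.isnan(p)

    def test_too_few_proteins_errors(self):
        with pytest.raises(ValueError):
            abundance_representation_corr({"A": 1.0}, {"A": 2})


class TestHolmSidak:
    def test_smallest_of_equal_ps(self):
        m, p = 8, 0.01
        adj = holm_sidak([p] * m)
        assert min(adj) == pytest.approx(1 - (1 - p) ** m)

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        ps = rng.uniform(0, 1, 12)
        adj = np.array(holm_sidak(list(ps)))
        assert np.all(adj >= ps - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCompartmentEnrichment:
    def _pct(self, values_by_sample):
        return {sid: dict(v) for sid, v in values_by_sample.items()}

    def test_identical_groups_not_significant(self):
        base = {"CM": 30.0, "C": 40.0, "N": 20.0}
        g = self._pct({f"s{i}": base for i in range(4)})
        res = compartment_enrichment(g, g)
        assert all(r.p_raw == pytest.approx(1.0) for r in res)
        assert not any(r.significant for r in res)

    def test_large_shift_survives_adjustment(self, rng):
        g_a, g_b = {}, {}
        for i in range(6):
            noise = rng.normal(0, 1.0, 2)
            g_a[f"a{i}"] = {"C": 60.0 + noise[0], "CM": 20.0 + noise[1]}
            g_b[f"b{i}"] = {"C": 30.0 + noise[0], "CM": 20.0 + noise[1]}
        res = {r.compartment: r for r in compartment_enrichment(g_a, g_b)}
        assert res["C"].significant
        assert not res["CM"].significant

    def test_small_group_errors(self):
        g = self._pct({"s1": {"C": 1.0}})
        with pytest.raises(ValueError):
            compartment_enrichment(g, g)

    def test_multilocalised_percentages_exceed_100(self):
        peps = [
            PeptideRecord("AAAAAAAAA", "s", frozenset({"P1"})),
            PeptideRecord("CCCCCCCCC", "s", frozenset({"P2"})),
        ]
        locs = {
            "P1": ProteinRecord("P1", frozenset({"CM", "C"})),
            "P2": ProteinRecord("P2", frozenset({"N"})),
        }
        pct = compartment_percentages(peps, locs)["s"]
        assert sum(pct.values()) == pytest.approx(150.0)
        assert sum(pct.values()) >= 100.0


def test_peptide_representation_counts_distinct_members():
    sets = identify_pulse_induced(
        {"A", "B"},
        set(),
        {"A", "B"},
        [
            PeptideRecord("AAAAAAAAA", "P-1", frozenset({"A"})),
            PeptideRecord("AAAAAAAAC", "P-1", frozenset({"A"})),
            PeptideRecord("AAAAAAAAA", "P-2", frozenset({"A"})),  # same seq, other sample
            PeptideRecord("CCCCCCCCC", "P-1", frozenset({"B"})),
        ],
    )
    counts = peptide_representation(
        sets,
        [
            PeptideRecord("AAAAAAAAA", "P-1", frozenset({"A"})),
            PeptideRecord("AAAAAAAAC", "P-1", frozenset({"A"})),
            PeptideRecord("AAAAAAAAA", "P-2", frozenset({"A"})),
            PeptideRecord("CCCCCCCCC", "P-1", frozenset({"B"})),
        ],
    )
    assert counts == {"A": 2, "B": 1}
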