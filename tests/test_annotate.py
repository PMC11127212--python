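"""The 4D matching engine: subscores, filters, ranking, confidence levels,
the identification funnel, and equivalence with an exhaustive filter oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twims4d.annotate import (
    ALL_DIMENSIONS,
    Feature,
    MatchTolerances,
    annotation_funnel,
    assign_msi_level,
    ccs_within_tolerance,
    composite_score,
    evaluate_candidate,
    generate_candidates,
    isotope_similarity,
    msms_score,
    rank_candidates,
)
from twims4d.chem import IsotopePattern, isotope_pattern
from twims4d.library4d import FragmentSpectrum
from twims4d.mobility import delta_ccs
from twims4d.synthetic import NoiseModel, simulate_features

from conftest import oracle_filter, random_instance


class TestIsotopeSimilarity:
    def test_identical(self):
        p = isotope_pattern("C6H12O6", 4)
        assert isotope_similarity(p, p) == 100.0

    def test_disjoint(self):
        a = IsotopePattern((1.0, 0.0))
        b = IsotopePattern((0.0, 1.0))
        assert isotope_similarity(a, b) == 0.0

    def test_l1_distance(self):
        a = IsotopePattern((0.9, 0.1))
        b = IsotopePattern((0.8, 0.2))
        assert isotope_similarity(a, b) == pytest.approx(90.0)

    def test_padding_shorter_pattern(self):
        a = IsotopePattern((0.95, 0.05))
        b = IsotopePattern((0.95, 0.04, 0.01))
        assert isotope_similarity(a, b) == pytest.approx(99.0)


class TestMsmsScore:
    spectrum = FragmentSpectrum(((91.0542, 60.0), (188.0706, 40.0)))

    def test_self_match(self):
        assert msms_score(self.spectrum, self.spectrum) == 100.0

    def test_nothing_in_tolerance(self):
        observed = FragmentSpectrum(((60.0, 100.0),))
        assert msms_score(observed, self.spectrum) == 0.0

    def test_intensity_weighted_partial_match(self):
        observed = FragmentSpectrum(((91.0542, 10.0),))
        assert msms_score(observed, self.spectrum) == pytest.approx(60.0)

    def test_each_observed_peak_used_once(self):
        # one observed peak cannot satisfy two distinct reference peaks
        reference = FragmentSpectrum(((100.0000, 50.0), (100.0015, 50.0)))
        observed = FragmentSpectrum(((100.0001, 10.0),))
        assert msms_score(observed, reference, fragment_ppm=20.0) == pytest.approx(50.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            msms_score(self.spectrum, None)


class TestCcsTolerance:
    tol = MatchTolerances()

    def test_percent_branch(self):
        assert ccs_within_tolerance(delta_ccs(101.9, 100.0), self.tol)

    def test_absolute_branch(self):
        # 3.25% but only 3.9 A^2: the absolute branch saves it
        assert ccs_within_tolerance(delta_ccs(123.9, 120.0), self.tol)

    def test_fails_both(self):
        assert not ccs_within_tolerance(delta_ccs(310.0, 300.0), self.tol)


class TestCompositeAndRanking:
    def test_perfect_match_scores_100(self, table1, tol):
        entry = next(e for e in table1 if e.name == "Taurine")
        record = entry.records[0]
        feature = Feature("f", record.mode, record.mz, record.rt, ccs=record.ccs,
                          isotope_envelope=isotope_pattern(entry.formula, 4))
        cand = evaluate_candidate(feature, entry, record, tol)
        assert cand.composite == pytest.approx(100.0)

    def test_mean_of_available_subscores(self, table1, tol):
        entry = next(e for e in table1 if e.name == "Taurine")
        record = entry.records[0]
        # dppm=10 of 20 and drt=0.15 of 0.3 -> both subscores 50
        feature = Feature("f", record.mode, record.mz * (1 + 10e-6),
                          record.rt + 0.15)
        cand = evaluate_candidate(feature, entry, record, tol)
        assert set(cand.subscores) == {"mz", "rt"}
        assert cand.composite == pytest.approx(50.0, abs=0.01)

    def test_rank_by_composite_then_dppm_then_name(self, funnel_fixture, tol):
        feature, library = funnel_fixture
        cands = generate_candidates(feature, library, tol, ("mz", "rt"))
        ranked = rank_candidates(cands)
        scores = [c.composite for c in ranked]
        assert scores == sorted(scores, reverse=True)

    @settings(derandomize=True, max_examples=25)
    @given(st.randoms(use_true_random=False))
    def test_permutation_invariance(self, funnel_fixture, rnd):
        feature, library = funnel_fixture
        cands = generate_candidates(feature, library, MatchTolerances(), ("mz", "rt"))
        shuffled = list(cands)
        rnd.shuffle(shuffled)
        assert [c.entry.name for c in rank_candidates(shuffled)] == [
            c.entry.name for c in rank_candidates(cands)
        ]


class TestMsiLevels:
    def _candidate(self, table1, tol, **feature_kwargs):
        entry = next(e for e in table1 if e.name == "l-Tryptophan")
        record = next(r for r in entry.records if r.mode == "positive")
        defaults = dict(feature_id="f", mode="positive", mz=record.mz, rt=record.rt)
        defaults.update(feature_kwargs)
        return evaluate_candidate(Feature(**defaults), entry, record, tol), entry

    def test_level1_needs_standard_plus_two_orthogonal(self, table1, tol):
        cand, _ = self._candidate(table1, tol, ccs=147.31)
        assert cand.msi_level == 1

    def test_level2_msms_against_nonstandard(self, funnel_fixture, tol):
        feature, library = funnel_fixture
        dtrp = next(e for e in library if e.name == "d-Tryptophan")
        cand = evaluate_candidate(feature, dtrp, dtrp.records[0], tol)
        assert "msms" in cand.passed_filters
        assert not ("ccs" in cand.passed_filters)
        assert cand.msi_level == 2

    def test_level3_mass_and_isotope_only(self, table1, tol):
        entry = next(e for e in table1 if e.name == "l-Tryptophan")
        record = next(r for r in entry.records if r.mode == "positive")
        feature = Feature("f", "positive", record.mz, record.rt + 1.0,
                          isotope_envelope=isotope_pattern(entry.formula, 4))
        cand = evaluate_candidate(feature, entry, record, tol)
        assert cand.msi_level == 3

    def test_level4_when_mass_fails(self, table1, tol):
        cand, _ = self._candidate(table1, tol, mz=205.11)
        assert cand.msi_level == 4


class TestGenerateCandidates:
    def test_empty_library(self, tol):
        feature = Feature("f", "positive", 205.0968, 5.71)
        assert generate_candidates(feature, [], tol) == []

    def test_empty_dimension_set_rejected(self, table1, tol):
        feature = Feature("f", "positive", 205.0968, 5.71)
        with pytest.raises(ValueError):
            generate_candidates(feature, table1, tol, ())

    def test_mode_separation(self, table1, tol):
        # taurine's record is negative mode; a positive feature never sees it
        feature = Feature("f", "positive", 124.0072, 6.29)
        names = {c.entry.name for c in generate_candidates(feature, table1, tol, ("mz",))}
        assert "Taurine" not in names

    def test_matches_oracle_on_random_instances(self):
        """Engine output equals the exhaustive filter oracle, 200 seeded trials."""
        rng = np.random.default_rng(20260927)
        for _ in range(200):
            feature, library, tolerances, dims = random_instance(rng)
            got = {
                (c.entry.hmdb_id, c.adduct)
                for c in generate_candidates(feature, library, tolerances, dims)
            }
            want = oracle_filter(feature, library, tolerances, dims)
            assert got == want

    def test_tolerance_monotonicity(self):
        """Widening any tolerance never shrinks the candidate set."""
        rng = np.random.default_rng(5)
        for _ in range(40):
            feature, library, tolerances, dims = random_instance(rng)
            base = {
                (c.entry.hmdb_id, c.adduct)
                for c in generate_candidates(feature, library, tolerances, dims)
            }
            for widened in (
                MatchTolerances(ppm=tolerances.ppm * 3, rt=tolerances.rt,
                                ccs_pct=tolerances.ccs_pct, ccs_abs=tolerances.ccs_abs,
                                isotope_min=tolerances.isotope_min),
                MatchTolerances(ppm=tolerances.ppm, rt=tolerances.rt * 3,
                                ccs_pct=tolerances.ccs_pct, ccs_abs=tolerances.ccs_abs,
                                isotope_min=tolerances.isotope_min),
                MatchTolerances(ppm=tolerances.ppm, rt=tolerances.rt,
                                ccs_pct=tolerances.ccs_pct * 3,
                                ccs_abs=tolerances.ccs_abs * 3,
                                isotope_min=tolerances.isotope_min / 2),
            ):
                wider = {
                    (c.entry.hmdb_id, c.adduct)
                    for c in generate_candidates(feature, library, widened, dims)
                }
                assert base <= wider


class TestSelfRetrieval:
    def test_every_fixture_record_retrieves_itself(self, table1, tol):
        """A zero-noise feature from any library record ranks its own entry
        first with a perfect composite and level-1 confidence."""
        for entry in table1:
            for record in entry.records:
                feature = Feature(
                    "probe", record.mode, record.mz, record.rt, ccs=record.ccs,
                    isotope_envelope=isotope_pattern(entry.formula, 4),
                )
                ranked = rank_candidates(generate_candidates(feature, table1, tol))
                top = ranked[0]
                assert top.entry.hmdb_id == entry.hmdb_id, entry.name
                assert top.composite == pytest.approx(100.0)
                assert top.msi_level == 1

    def test_noisy_recovery_rate(self, table1, tol):
        """Rank-1 recovery of the true compound at quarter-tolerance noise."""
        noise = NoiseModel(ppm_sd=5.0, rt_sd=0.075, ccs_sd_pct=0.5, seed=11)
        features = simulate_features(table1, 4, noise)[:220]
        hits = 0
        for f in features:
            ranked = rank_candidates(generate_candidates(f, table1, tol))
            if ranked and ranked[0].entry.hmdb_id == f.truth:
                hits += 1
        assert hits / len(features) >= 0.95


class TestFunnel:
    def test_worked_example_counts(self, funnel_fixture, tol):
        feature, library = funnel_fixture
        report = annotation_funnel(feature, library, tol)
        assert report.counts() == [10, 10, 5, 1]
        assert report.top_candidate.entry.name == "l-Tryptophan"
        assert report.top_candidate.msi_level == 1

    def test_no_match(self, table1, tol):
        feature = Feature("f", "positive", 999.9, 1.0)
        report = annotation_funnel(feature, table1, tol)
        assert report.counts()[0] == 0
        assert report.top_candidate is None

    def test_infinite_tolerances_keep_all_stages_equal(self, funnel_fixture):
        feature, library = funnel_fixture
        wide = MatchTolerances(ppm=1e9, rt=1e9, ccs_pct=1e9, ccs_abs=1e9,
                               isotope_min=1e-9, fragment_ppm=1e9)
        counts = annotation_funnel(feature, library, wide).counts()
        assert len(set(counts)) == 1

    def test_missing_ccs_skips_final_stage_filter(self, funnel_fixture, tol):
        feature, library = funnel_fixture
        no_ccs = Feature(feature.feature_id, feature.mode, feature.mz, feature.rt,
                         ccs=None, isotope_envelope=feature.isotope_envelope,
                         fragments=feature.fragments)
        assert annotation_funnel(no_ccs, library, tol).counts() == [10, 10, 5, 5]

    def test_counts_never_increase(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            feature, library, tolerances, _ = random_instance(rng)
            counts = annotation_funnel(feature, library, tolerances).counts()
            assert all(a >= b for a, b in zip(counts, counts[1:]))
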