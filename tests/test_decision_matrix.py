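"""Banded scoring, Bray-Curtis differential scoring and matrix assembly."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from darkzones import decision_matrix as dm
from darkzones.reference_criteria import Criterion


def oracle_band_score(local, apse):
    """Independent enumeration of the eleven score bands."""
    if apse == 0:
        raise ValueError
    if local != 0 and (local > 0) != (apse > 0):
        return 0.0
    r = abs(local - apse) / abs(apse)
    for k in range(10):
        if k / 10 <= r < (k + 1) / 10:
            return (10 - k) / 10
    return 0.0


class TestBandScore:
    def test_identical_variation_scores_one(self):
        res = dm.band_score(-3.093, -3.093)
        assert res == (0.0, 1.0, False)

    def test_hand_band(self):
        res = dm.band_score(1.7, 2.0)
        assert res.rel_deviation == pytest.approx(0.15)
        assert res.score == 0.9
        assert not res.opposite

    def test_opposite_sign_scores_zero(self):
        res = dm.band_score(0.4, -3.093)
        assert res.opposite and res.score == 0.0

    def test_zero_local_is_not_opposite(self):
        res = dm.band_score(0.0, 2.0)
        assert not res.opposite
        assert res.rel_deviation == pytest.approx(1.0)
        assert res.score == 0.0

    def test_zero_reference_is_error(self):
        with pytest.raises(ValueError, match="0"):
            dm.band_score(1.0, 0.0)

    def test_lower_band_edge_closed(self):
        # r = 0.1 exactly falls in the second band
        assert dm.band_score(1.1, 1.0).score == 0.9
        assert dm.band_score(2.0, 1.0).score == 0.0

    def test_agrees_with_oracle_on_dense_grid(self):
        apse_values = np.concatenate(
            [np.geomspace(0.01, 5, 60), -np.geomspace(0.01, 5, 60)]
        )
        local_values = np.linspace(-5, 5, 101)
        n = 0
        for a in apse_values:
            for l in local_values:
                assert dm.band_score(l, a).score == oracle_band_score(l, a)
                n += 1
            # boundary cases: local placed exactly at each band edge
            for k in range(12):
                for sgn in (1, -1):
                    l = a * (1 + sgn * k / 10)
                    assert dm.band_score(l, a).score == oracle_band_score(l, a)
                    n += 1
        assert n >= 10_000

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.floats(0.01, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
        k=st.floats(0.001, 100, allow_nan=False),
        sign=st.sampled_from([1.0, -1.0]),
    )
    def test_scale_invariance(self, a, b, k, sign):
        a, b = sign * a, sign * b
        r = abs(b - a) / abs(a)
        # exactly on a band edge the floating-point rescaling may legitimately
        # land on either side; the property concerns interior points
        assume(min(abs(r - e / 10) for e in range(11)) > 1e-6)
        assert dm.band_score(k * b, k * a).score == dm.band_score(b, a).score

    def test_monotone_in_deviation(self):
        for apse in (1.5, -2.3):
            devs = np.linspace(0, 2.5, 200)
            scores = [
                dm.band_score(apse + d * np.sign(apse), apse).score
                for d in devs
            ]
            assert all(s1 >= s2 for s1, s2 in zip(scores, scores[1:]))


class TestBCScore:
    def test_small_differential_scores_one(self):
        res = dm.bc_score(0.40, 0.42)
        assert res.rel_deviation == pytest.approx(0.05)
        assert res.score == 1.0

    def test_equal_distances_score_one(self):
        assert dm.bc_score(0.3, 0.3).score == 1.0

    def test_doubled_distance_scores_zero(self):
        res = dm.bc_score(0.2, 0.4)
        assert res.rel_deviation == pytest.approx(1.0)
        assert res.score == 0.0

    def test_negative_differential_flagged_opposite(self):
        res = dm.bc_score(0.4, 0.2)
        assert res.opposite and res.score == 0.0

    def test_alpha_zero(self):
        assert dm.bc_score(0.0, 0.0).score == 1.0
        with pytest.raises(ValueError, match="alpha"):
            dm.bc_score(0.0, 0.1)


def _dummy_grid(totals, n_criteria=47):
    """Criteria plus per-location scores whose positive sum hits each total."""
    criteria = [
        Criterion(f"c{i:02d}", "genus", "bacteria", 1.5)
        for i in range(n_criteria)
    ]
    scores = {}
    for loc, total in totals.items():
        whole = int(total)
        frac = round(total - whole, 1)
        values = [1.0] * whole + ([frac] if frac else [])
        values += [0.0] * (n_criteria - len(values))
        scores[loc] = [
            dm.CriterionScore(c.criterion_id, loc, 1.5, 0.0, v, False)
            for c, v in zip(criteria, values)
        ]
    return criteria, scores


class TestBuildMatrix:
    @pytest.mark.parametrize(
        "total,expected_percent",
        [
            (18.9, 40.2),
            (18.8, 40.0),
            (17.6, 37.4),
            (15.1, 32.1),
            (14.6, 31.1),
            (11.8, 25.1),
            (11.3, 24.0),
            (47.0, 100.0),
        ],
    )
    def test_total_to_percent_identity(self, total, expected_percent):
        criteria, scores = _dummy_grid({"L": total})
        m = dm.build_matrix(criteria, scores)
        assert m.totals["L"] == pytest.approx(total)
        assert m.percent["L"] == expected_percent

    def test_rank_descends_with_alphabetical_ties(self):
        criteria, scores = _dummy_grid({"B": 10.0, "A": 10.0, "C": 20.0})
        m = dm.build_matrix(criteria, scores)
        assert m.rank == {"C": 1, "A": 2, "B": 3}

    def test_ragged_grid_is_error(self):
        criteria, scores = _dummy_grid({"L": 10.0})
        scores["L"] = scores["L"][:-1]
        with pytest.raises(ValueError, match="ragged"):
            dm.build_matrix(criteria, scores)

    def test_round_half_up_away_from_zero(self):
        assert dm.round_half_up(20.85, 1) == 20.9
        assert dm.round_half_up(40.249, 1) == 40.2
        assert dm.round_half_up(-4.25, 1) == -4.3


class TestScenarioMatrix:
    def test_matrix_invariants(self, analysis):
        m = analysis.matrix
        n = len(m.criteria)
        assert sorted(m.rank.values()) == list(range(1, len(m.locations) + 1))
        for loc in m.locations:
            assert 0 <= m.totals[loc] <= n
            assert m.percent[loc] == dm.round_half_up(
                100 * m.totals[loc] / n, 1
            )
            # opposite cells contribute nothing
            assert m.totals[loc] == pytest.approx(
                sum(s.score for s in m.scores[loc] if not s.opposite)
            )
            assert all(s.score == 0.0 for s in m.scores[loc] if s.opposite)

    def test_reference_self_comparison(self, analysis):
        scores = dm.score_location(
            analysis.criteria,
            analysis.normalized,
            analysis.qpcr,
            analysis.samples,
            "Apse",
            "Apse",
        )
        for s in scores:
            assert s.score == 1.0, s.criterion_id
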