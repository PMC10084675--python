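"""Δlog computation, reference-taxon selection and criterion assembly."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from darkzones import reference_criteria as rc
from darkzones.tables_io import QPCRTable, SampleMeta

from conftest import make_table

SPECS_PAIRED = [
    ("C1", "Apse", "control", 1),
    ("C2", "Apse", "control", 2),
    ("D1", "Apse", "dark_zone", 1),
    ("D2", "Apse", "dark_zone", 2),
]


class TestDeltaLog:
    def test_equal_means_give_exact_zero(self):
        assert rc.delta_log(17.3, 17.3) == 0.0
        assert rc.delta_log(0.0, 0.0) == 0.0

    def test_zero_control_three_decades(self):
        assert rc.delta_log(0.0, 999.0, 1.0) == pytest.approx(3.0)

    def test_inverted_construction_reproduces_printed_value(self):
        # choose means so (dz+1)/(control+1) = 10**-3.093
        control = 10 ** 3.093 - 1
        assert rc.delta_log(control, 0.0) == pytest.approx(-3.093)

    def test_negative_mean_is_error(self):
        with pytest.raises(ValueError):
            rc.delta_log(-1.0, 2.0)

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.floats(0, 1e6, allow_nan=False),
        b=st.floats(0, 1e6, allow_nan=False),
    )
    def test_antisymmetry_and_sign(self, a, b):
        d = rc.delta_log(a, b)
        assert rc.delta_log(b, a) == pytest.approx(-d)
        # strict sign for differences resolvable in double precision
        if abs(b - a) > 1e-9 * (1 + max(a, b)):
            if b > a:
                assert d > 0
            else:
                assert d < 0


class TestGenusDeltaLogs:
    def test_hand_table(self):
        t = make_table(
            "bacteria",
            ["absent", "flat", "up"],
            SPECS_PAIRED,
            [[0, 0, 0, 0], [10, 10, 10, 10], [0, 2, 99, 99]],
        )
        recs = {r.criterion_id: r for r in rc.genus_delta_logs(t, "Apse")}
        assert recs["absent"].delta_log == 0.0
        assert recs["flat"].delta_log == 0.0
        assert recs["up"].delta_log == pytest.approx(
            math.log10(100) - math.log10(2)
        )
        assert recs["up"].mean_control == pytest.approx(1.0)
        assert recs["up"].mean_dz == pytest.approx(99.0)

    def test_missing_condition_is_error(self):
        t = make_table(
            "bacteria", ["a"], SPECS_PAIRED[:2], [[1, 2]]
        )
        with pytest.raises(ValueError, match="dark_zone"):
            rc.genus_delta_logs(t, "Apse")


class TestSelectReferenceTaxa:
    def _rec(self, name, d):
        return rc.DeltaLogRecord(name, "bacteria", 1.0, 1.0, d)

    def test_strict_threshold(self):
        recs = [
            self._rec("selected_up", 1.112),
            self._rec("too_small", 0.5),
            self._rec("boundary", 1.0),
            self._rec("selected_down", -3.093),
        ]
        out = rc.select_reference_taxa(recs)
        assert [c.criterion_id for c in out] == ["selected_down", "selected_up"]
        assert all(c.kind == "genus" for c in out)

    def test_order_invariant(self):
        recs = [self._rec(f"g{i}", 1.5 + i) for i in range(5)]
        fwd = rc.select_reference_taxa(recs)
        rev = rc.select_reference_taxa(recs[::-1])
        assert fwd == rev


def _tiny_archaea(control_totals, dz_totals):
    specs = [
        (f"C{i+1}", "Apse", "control", i + 1)
        for i in range(len(control_totals))
    ] + [
        (f"D{i+1}", "Apse", "dark_zone", i + 1) for i in range(len(dz_totals))
    ]
    counts = [list(control_totals) + list(dz_totals)]
    return make_table("archaea", ["arc"], specs, counts)


def _tiny_qpcr(sample_ids):
    rows = [
        {"sample_id": sid, "domain": d, "copies_per_ng": 100.0}
        for sid in sample_ids
        for d in ("bacteria", "archaea", "fungi")
    ]
    return QPCRTable(data=pd.DataFrame(rows))


class TestAssembleCriteria:
    def _genus(self, n, domain):
        return [
            rc.Criterion(f"{domain[:3]}{i}", "genus", domain, 1.5)
            for i in range(n)
        ]

    def _fixtures(self):
        arch = _tiny_archaea([108, 108], [9, 9])
        samples = arch.samples
        return arch, _tiny_qpcr([s.sample_id for s in samples]), samples

    @pytest.mark.parametrize("nb,nf", [(27, 14), (0, 0), (3, 5)])
    def test_count_identity(self, nb, nf):
        arch, qpcr, samples = self._fixtures()
        out = rc.assemble_criteria(
            self._genus(nb, "bacteria"),
            self._genus(nf, "fungi"),
            arch,
            qpcr,
            samples,
            "Apse",
        )
        assert len(out) == nb + nf + 6
        kinds = [c.kind for c in out]
        assert kinds.count("bray_curtis") == 2
        assert kinds.count("qpcr") == 3
        assert kinds.count("archaeal_reads") == 1

    def test_archaeal_reads_delta_matches_construction(self):
        # replicate totals chosen so (mean_dz+1)/(mean_control+1) ~= 10^-1.037
        arch, qpcr, samples = self._fixtures()
        out = rc.assemble_criteria([], [], arch, qpcr, samples, "Apse")
        by_id = {c.criterion_id: c for c in out}
        assert by_id["archaeal_reads"].delta_log_apse == pytest.approx(
            math.log10(10 / 109)
        )
        assert by_id["archaeal_reads"].delta_log_apse == pytest.approx(
            -1.037, abs=1e-3
        )

    def test_missing_qpcr_domain_is_error(self):
        arch, qpcr, samples = self._fixtures()
        trimmed = QPCRTable(
            data=qpcr.data[qpcr.data["domain"] != "fungi"].reset_index(
                drop=True
            )
        )
        with pytest.raises(KeyError, match="fungi"):
            rc.assemble_criteria([], [], arch, trimmed, samples, "Apse")


class TestScenarioRecovery:
    def test_planted_effects_recovered_for_abundant_genera(self, analysis):
        """Planted Δlog10 condition effects are recovered within ±0.15 for
        genera expected at >= 50 reads in both conditions at the reference."""
        s = analysis.scenario
        checked = 0
        for domain in ("bacteria", "fungi"):
            est = {
                r.criterion_id: r.delta_log
                for r in rc.genus_delta_logs(
                    analysis.normalized[domain], "Apse"
                )
            }
            exp = s.truth["reference_expected_proportions"][domain]
            depth = s.config.depths[domain]
            for genus, planted in s.config.dz_effects[domain].items():
                if (
                    min(exp["control"][genus], exp["dark_zone"][genus]) * depth
                    >= 50
                ):
                    assert est[genus] == pytest.approx(planted, abs=0.15)
                    checked += 1
        assert checked >= 5
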