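import dataclasses

import numpy as np
import pytest

from adnet.model import RATE_IDS, SPECIES, build_default_model
from adnet.sensitivity import (
    CLASS_MODERATE,
    CLASS_STRONG,
    CLASS_WEAK,
    RATE_OUTPUTS,
    SCHEME_CENTRAL,
    SCHEME_TENFOLD,
    SensitivityRecord,
    classify,
    classify_table,
    sens_ic,
    sens_rate,
    sens_table,
    write_class_csv,
    write_sensitivity_csv,
)


def by_key(records):
    return {(r.parameter, r.output, r.scheme): r for r in records}


class TestRateSensitivities:
    def test_neuron_survival_sign_pattern(self, full_sensitivity_table):
        """Survival is promoted by the astroglial support pathway (alpha_1)
        and degraded by reactive-microglia-driven death (alpha_3)."""
        recs = by_key(full_sensitivity_table)
        assert recs[("alpha_1", "Ns", SCHEME_CENTRAL)].value > 0
        assert recs[("alpha_3", "Ns", SCHEME_CENTRAL)].value < 0
        assert recs[("alpha_3", "Nd", SCHEME_CENTRAL)].value > 0

    @pytest.mark.parametrize("pair", [("Ns", "Nd"), ("M1", "M2")])
    def test_antisymmetry_within_conserved_pairs(self, full_sensitivity_table, pair):
        """Conservation forces S(a) = -S(b) for every rate, matching the
        published sign structure of the rate-sensitivity table.

        The pair totals are conserved to roundoff; dividing that roundoff
        by the quotient denominator 2*f*alpha sets the attainable
        tolerance."""
        model = build_default_model()
        recs = by_key(full_sensitivity_table)
        a, b = pair
        pair_total = model.initial_value(a) + model.initial_value(b)
        for rate_id in RATE_IDS:
            sa = recs[(rate_id, a, SCHEME_CENTRAL)].value
            sb = recs[(rate_id, b, SCHEME_CENTRAL)].value
            denom = 2 * 0.025 * model.rates[rate_id]
            tol = max(1e-6 * abs(sa), 1e-10 * pair_total / denom)
            assert abs(sa + sb) <= tol, rate_id

    def test_difference_quotient_converges_as_fraction_shrinks(self, default_model):
        for rate_id, output in [("alpha_3", "Ns"), ("alpha_13", "Nd")]:
            coarse = sens_rate(default_model, rate_id, output, 0.025).value
            fine = sens_rate(default_model, rate_id, output, 0.0125).value
            assert abs(fine - coarse) / abs(coarse) < 0.01

    def test_clamp_affected_runs_are_flagged(self, default_model):
        """The baseline 20-year run drives M1 onto the zero boundary, so
        rate records at the full horizon carry the clamp flag; a short
        horizon stays clear of the boundary and does not."""
        long_rec = sens_rate(default_model, "alpha_3", "Ns")
        assert long_rec.clamped
        short = dataclasses.replace(default_model, horizon=5.0)
        short_rec = sens_rate(short, "alpha_3", "Ns")
        assert not short_rec.clamped

    def test_unknown_ids_rejected(self, default_model):
        with pytest.raises(KeyError, match="alpha_99"):
            sens_rate(default_model, "alpha_99", "Ns")
        with pytest.raises(KeyError, match="unknown species"):
            sens_rate(default_model, "alpha_1", "Nx")
        with pytest.raises(ValueError, match="fraction"):
            sens_rate(default_model, "alpha_1", "Ns", fraction=0.7)


class TestInitialConditionSensitivities:
    def test_published_order_of_magnitude_anchors(self, full_sensitivity_table):
        """Self-sensitivity of surviving neurons is ~1; the reactive
        microglia pool amplifies its own initial perturbation (~1.2) and
        feeds neuronal death (~0.2)."""
        recs = by_key(full_sensitivity_table)
        assert recs[("Ns", "Ns", SCHEME_TENFOLD)].value == pytest.approx(1.0, abs=0.1)
        assert recs[("M1", "M1", SCHEME_TENFOLD)].value == pytest.approx(1.2, abs=0.1)
        assert recs[("M1", "Nd", SCHEME_TENFOLD)].value == pytest.approx(0.2, abs=0.1)

    def test_pair_sum_rule(self, full_sensitivity_table):
        """For any perturbed initial value, coefficients of a conserved pair
        sum to 1 if the perturbed species is in the pair, else 0."""
        recs = by_key(full_sensitivity_table)
        pairs = {("Ns", "Nd"), ("Aq", "Ap"), ("M1", "M2")}
        for perturbed in SPECIES:
            for a, b in pairs:
                total = (recs[(perturbed, a, SCHEME_TENFOLD)].value
                         + recs[(perturbed, b, SCHEME_TENFOLD)].value)
                expected = 1.0 if perturbed in (a, b) else 0.0
                assert total == pytest.approx(expected, abs=1e-8), (perturbed, a, b)

    def test_downward_variant_carried_on_record(self, default_model):
        rec = sens_ic(default_model, "Ns", "Ns")
        assert rec.scheme == SCHEME_TENFOLD
        assert rec.value_down is not None
        # both quotients estimate the same local derivative
        assert rec.value_down == pytest.approx(rec.value, rel=0.3)

    def test_zero_initial_value_rejected(self, default_model):
        zeroed = default_model.with_initial("Abeta", 0.0)
        with pytest.raises(ValueError, match="Abeta"):
            sens_ic(zeroed, "Abeta", "Ns")
        with pytest.raises(ValueError, match="factor"):
            sens_ic(default_model, "Ns", "Ns", factor=0.5)


class TestSensitivityTable:
    def test_record_counts_and_ordering(self, full_sensitivity_table):
        rate_recs = [r for r in full_sensitivity_table
                     if r.scheme == SCHEME_CENTRAL]
        ic_recs = [r for r in full_sensitivity_table
                   if r.scheme == SCHEME_TENFOLD]
        assert len(rate_recs) == 68  # 17 rates x 4 outputs
        assert len(ic_recs) == 49    # 7 initial values x 7 outputs
        assert [r.parameter for r in rate_recs[:4]] == ["alpha_1"] * 4
        assert [r.output for r in rate_recs[:4]] == list(RATE_OUTPUTS)

    def test_determinism(self, default_model):
        a = sens_rate(default_model, "alpha_13", "Nd")
        b = sens_rate(default_model, "alpha_13", "Nd")
        assert a == b  # bit-identical, no randomness anywhere

    def test_csv_writers(self, full_sensitivity_table, tmp_path):
        table_path = tmp_path / "sens.csv"
        write_sensitivity_csv(full_sensitivity_table, table_path)
        lines = table_path.read_text().splitlines()
        assert lines[0] == "parameter,output,scheme,horizon_years,S,clamped"
        assert len(lines) == 1 + 68 + 49

        classes = classify_table(full_sensitivity_table)
        class_path = tmp_path / "classes.csv"
        write_class_csv(classes, class_path)
        lines = class_path.read_text().splitlines()
        assert lines[0] == "rate,class"
        assert len(lines) == 1 + 17


class TestClassification:
    @staticmethod
    def records_for(rate_id, quadruple):
        return [
            SensitivityRecord(output=o, parameter=rate_id,
                              scheme=SCHEME_CENTRAL, horizon=20.0, value=v)
            for o, v in zip(RATE_OUTPUTS, quadruple)
        ]

    @pytest.mark.parametrize(
        "rate_id,quadruple,expected",
        [
            # published magnitude quadruples (S(Ns), S(Nd), S(M1), S(M2))
            ("alpha_1", (50000, -50000, -6000, 6000), CLASS_STRONG),
            ("alpha_2", (-500, 500, -60, 60), CLASS_WEAK),
            ("alpha_8", (-400, 400, 5000, -5000), CLASS_MODERATE),
            ("alpha_5", (0, 0, 0, 0), CLASS_WEAK),
        ],
    )
    def test_threshold_classification(self, rate_id, quadruple, expected):
        assert classify(self.records_for(rate_id, quadruple)) == expected

    def test_incomplete_or_mixed_sets_rejected(self):
        recs = self.records_for("alpha_1", (1, -1, 1, -1))
        with pytest.raises(ValueError, match="missing"):
            classify(recs[:2])
        mixed = recs[:3] + self.records_for("alpha_2", (1, -1, 1, -1))[3:]
        with pytest.raises(ValueError, match="mix"):
            classify(mixed)
        with pytest.raises(ValueError, match="empty"):
            classify([])
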