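"""Relative quantification: 2^-ddCt arithmetic, signal scaling, reference CV."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polydose import (
    AllelicConfiguration,
    AssayPanel,
    CalibratorSpec,
    CtRecord,
    IncompletePlateError,
    InvalidGenotypeError,
    allele_signals,
    dosage_from_signals,
    reference_stability,
    relative_quantity,
)
from polydose.exceptions import DegenerateDataError


def wells(sample, ct_assay, ct_ref, assay="allele_A", reps=1):
    out = []
    for r in range(1, reps + 1):
        out.append(CtRecord(sample, assay, r, ct_assay))
        out.append(CtRecord(sample, "reference", r, ct_ref))
    return out


class TestRelativeQuantity:
    @pytest.mark.parametrize(
        "s_assay,s_ref,c_assay,c_ref,expected",
        [
            (23.0, 20.0, 23.0, 20.0, 1.0),   # calibrator against itself
            (22.0, 20.0, 23.0, 20.0, 2.0),   # one cycle earlier = twice the template
            (24.0, 20.0, 23.0, 20.0, 0.5),   # ddCt = 4 - 3 = 1
        ],
    )
    def test_known_values(self, panel, s_assay, s_ref, c_assay, c_ref, expected):
        q = relative_quantity(
            wells("s", s_assay, s_ref), wells("c", c_assay, c_ref), "allele_A", panel
        )
        assert q == pytest.approx(expected)

    def test_replicates_average_ct_before_differencing(self, panel):
        sample = wells("s", 22.0, 20.0) + wells("s", 24.0, 20.0)
        # mean Ct 23 -> ddCt 0 -> quantity 1, not mean of per-replicate quantities
        sample = [
            CtRecord("s", r.assay, i + 1, r.ct) for i, r in enumerate(sample)
        ]
        q = relative_quantity(sample, wells("c", 23.0, 20.0), "allele_A", panel)
        assert q == pytest.approx(1.0)

    def test_efficiency_below_two(self):
        panel = AssayPanel(efficiency=1.9)
        q = relative_quantity(
            wells("s", 22.0, 20.0), wells("c", 23.0, 20.0), "allele_A", panel
        )
        assert q == pytest.approx(1.9)

    def test_missing_assay_is_an_incomplete_plate(self, panel):
        sample = [CtRecord("s", "reference", 1, 20.0)]
        with pytest.raises(IncompletePlateError, match="allele_A"):
            relative_quantity(sample, wells("c", 23.0, 20.0), "allele_A", panel)

    def test_missing_reference_is_an_incomplete_plate(self, panel):
        sample = [CtRecord("s", "allele_A", 1, 23.0)]
        with pytest.raises(IncompletePlateError, match="reference"):
            relative_quantity(sample, wells("c", 23.0, 20.0), "allele_A", panel)


class TestCtRecordValidation:
    @pytest.mark.parametrize("ct", [0.0, -1.0, math.nan, math.inf])
    def test_rejects_nonpositive_or_nonfinite_ct(self, ct):
        with pytest.raises(ValueError):
            CtRecord("s", "reference", 1, ct)

    def test_rejects_unknown_assay_and_bad_replicate(self):
        with pytest.raises(ValueError):
            CtRecord("s", "taqman", 1, 20.0)
        with pytest.raises(ValueError):
            CtRecord("s", "reference", 0, 20.0)

    def test_panel_requires_distinct_names_and_sane_efficiency(self):
        with pytest.raises(ValueError):
            AssayPanel(reference_name="x", allele_A_name="x")
        with pytest.raises(ValueError):
            AssayPanel(efficiency=2.5)
        with pytest.raises(ValueError):
            AssayPanel(efficiency=1.0)


class TestAlleleSignals:
    @pytest.mark.parametrize(
        "genotype,a1,a2,b,theta",
        [
            ("AA", 2.0, 0.0, 1.0, 0.0),
            ("Aa", 1.0, 1.0, 0.5, 45.0),
            ("aa", 0.0, 2.0, 0.0, 90.0),
        ],
    )
    def test_diploid_scaling_convention(self, measure_b, genotype, a1, a2, b, theta):
        config = AllelicConfiguration.from_string(genotype)
        d = measure_b(config.a_fraction)
        assert d.a1 == pytest.approx(a1, abs=1e-9)
        assert d.a2 == pytest.approx(a2, abs=1e-9)
        assert d.b == pytest.approx(b, abs=1e-9)
        assert d.theta == pytest.approx(theta, abs=1e-9)

    def test_triploid_heterozygote_dosage(self, measure_b):
        # two of three copies are A -> b = 2/3
        d = measure_b(AllelicConfiguration.from_string("AAa").a_fraction)
        assert d.b == pytest.approx(2.0 / 3.0, abs=1e-9)

    def test_noise_free_b_equals_a_fraction_on_grid(self, measure_b):
        for p in np.linspace(0.0, 1.0, 101):
            assert measure_b(float(p)).b == pytest.approx(p, abs=1e-9)

    def test_b_monotone_in_a_fraction(self, measure_b):
        bs = [measure_b(float(p)).b for p in np.linspace(0, 1, 21)]
        assert all(b2 > b1 for b1, b2 in zip(bs, bs[1:]))

    def test_recessive_calibrator_rejected(self, panel):
        cal = CalibratorSpec("c", AllelicConfiguration.from_string("aa"), 2)
        with pytest.raises(InvalidGenotypeError):
            allele_signals(wells("s", 23.0, 20.0), cal, wells("c", 23.0, 20.0), panel)

    def test_negative_a2_retained_flagged_theta_clamped(self):
        d = dosage_from_signals("s", a1=2.4, a3=2.0)
        assert d.a2 == pytest.approx(-0.4)
        assert "negative_a2" in d.flags
        assert d.theta == 0.0
        assert d.b > 1.0  # over-unity signals are reported, not clipped

    def test_no_signal_flagged(self):
        d = dosage_from_signals("s", a1=0.0, a3=0.0)
        assert math.isnan(d.b)
        assert "no_signal" in d.flags


@settings(derandomize=True, max_examples=50)
@given(b=st.floats(min_value=1e-6, max_value=1.0))
def test_theta_b_consistency(b):
    """theta = arctan((1-b)/b) degrees whenever a1, a2 >= 0 and 0 < b <= 1."""
    d = dosage_from_signals("s", a1=2 * b, a3=2.0)
    assert d.b == pytest.approx(b, abs=1e-12)
    assert d.theta == pytest.approx(math.degrees(math.atan2(1 - b, b)), abs=1e-9)


class TestReferenceStability:
    def test_identical_cts_have_zero_cv(self):
        cvs, ok = reference_stability({2: [20.0, 20.0, 20.0]})
        assert cvs[2] == 0.0 and ok

    def test_hand_computed_cv(self):
        # sd = sqrt(2), mean = 21 -> CV = 6.734%
        cvs, ok = reference_stability({3: [20.0, 22.0]})
        assert cvs[3] == pytest.approx(100 * math.sqrt(2) / 21, rel=1e-9)
        assert not ok

    def test_threshold_is_configurable(self):
        _, ok = reference_stability({3: [20.0, 22.0]}, threshold=10.0)
        assert ok

    def test_small_group_rejected_by_name(self):
        with pytest.raises(DegenerateDataError, match="4"):
            reference_stability({4: [20.0]})

    def test_ct_records_accepted(self):
        recs = [CtRecord("s", "reference", i + 1, ct) for i, ct in enumerate([20.0, 22.0])]
        cvs, _ = reference_stability({2: recs})
        assert cvs[2] == pytest.approx(6.734, abs=1e-3)
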