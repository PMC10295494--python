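"""Per-patient index formulas: frozen hand-computed values, domain errors,
and the algebraic invariants that tie the indices together."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aortastat import (
    DomainError,
    IndexConfig,
    PatientRecord,
    ao_distensibility,
    ao_stiffness_index,
    ao_strain,
    compute_bmi,
    compute_bsa,
    derive_all,
    derive_frame,
    eat_indices,
)

#: Published cohort means used as a convenient worked example throughout.
MEAN_RECORD = PatientRecord(
    id="mean",
    age=63.48,
    sex="female",
    height=1.67,
    body_mass=74.16,
    sbp=143.20,
    dbp=88.40,
    ao_diastolic_diameter=33.42,
    ao_systolic_diameter=34.50,
    eat_thickness=9.51,
    eat_volume=60.03,
)


class TestBsaBmi:
    @pytest.mark.parametrize(
        "height,mass,method,expected",
        [
            (1.67, 74.16, "du_bois", 1.8308716),  # direct Du Bois evaluation
            (1.67, 74.16, "mosteller", 1.8547776),  # direct Mosteller evaluation
            (2.0, 80.0, "du_bois", 0.007184 * 80.0**0.425 * 200.0**0.725),
        ],
    )
    def test_bsa_values(self, height, mass, method, expected):
        assert compute_bsa(height, mass, method) == pytest.approx(expected, rel=1e-6)

    @given(
        h=st.floats(1.4, 2.1),
        m=st.floats(40.0, 140.0),
        k=st.floats(0.5, 2.0),
    )
    def test_mosteller_sqrt_homogeneity_in_mass(self, h, m, k):
        assert compute_bsa(h, k * m, "mosteller") == pytest.approx(
            np.sqrt(k) * compute_bsa(h, m, "mosteller"), rel=1e-12
        )

    @pytest.mark.parametrize(
        "height,mass,expected",
        [(1.67, 74.16, 26.5911), (2.0, 80.0, 20.0), (1.0, 33.0, 33.0)],
    )
    def test_bmi(self, height, mass, expected):
        assert compute_bmi(height, mass) == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize("bad", [(0.0, 70.0), (1.7, 0.0), (-1.0, 70.0)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(DomainError):
            compute_bsa(*bad)
        if bad[0] <= 0:
            with pytest.raises(DomainError):
                compute_bmi(*bad)

    def test_du_bois_mosteller_agreement_over_cohort(self, cohort_frame):
        """The two BSA formulas agree within 3% in cohort mean; per-patient
        disagreement stays under 6%, the worst cases being tail-obesity
        records where Mosteller is known to read higher than Du Bois."""
        db = np.array([compute_bsa(h, m, "du_bois") for h, m in
                       zip(cohort_frame["height"], cohort_frame["body_mass"])])
        mo = np.array([compute_bsa(h, m, "mosteller") for h, m in
                       zip(cohort_frame["height"], cohort_frame["body_mass"])])
        assert abs(db.mean() / mo.mean() - 1.0) < 0.03
        assert np.abs(db / mo - 1.0).max() < 0.06


class TestStrainDistensibility:
    @pytest.mark.parametrize(
        "ds,dd,expected",
        [(34.50, 33.42, 3.23160), (30.0, 30.0, 0.0), (40.0, 20.0, 100.0)],
    )
    def test_strain_values(self, ds, dd, expected):
        assert ao_strain(ds, dd) == pytest.approx(expected, abs=1e-4)

    def test_strain_rejects_inverted_diameters(self):
        with pytest.raises(DomainError):
            ao_strain(30.0, 31.0)
        with pytest.warns(UserWarning):
            assert ao_strain(30.0, 31.0, clamp=True) == 0.0

    @pytest.mark.parametrize(
        "strain,sbp,dbp,expected",
        [
            (3.29, 143.20, 88.40, 0.120073),  # rounds to the reported mean 0.12
            (2.67, 143.20, 88.40, 0.097445),  # rounds to the reported median 0.10
            (0.0, 140.0, 80.0, 0.0),
        ],
    )
    def test_distensibility_values(self, strain, sbp, dbp, expected):
        assert ao_distensibility(strain, sbp, dbp) == pytest.approx(expected, abs=1e-5)

    def test_distensibility_requires_positive_pulse_pressure(self):
        with pytest.raises(DomainError):
            ao_distensibility(3.0, 90.0, 90.0)

    @given(
        strain=st.floats(0.0, 30.0),
        dbp=st.floats(50.0, 110.0),
        pp=st.floats(10.0, 90.0),
    )
    def test_distensibility_pulse_pressure_identity(self, strain, dbp, pp):
        d = ao_distensibility(strain, dbp + pp, dbp)
        assert d * pp == pytest.approx(2.0 * strain, rel=1e-12, abs=1e-12)


class TestStiffnessIndex:
    def test_log_of_ratio_matches_reported_median(self):
        # 2.67% median strain with mean pressures gives 4.105 -> prints 4.09
        assert ao_stiffness_index(143.20, 88.40, 2.67) == pytest.approx(4.10546, abs=1e-4)

    def test_classic_beta_is_an_order_of_magnitude_larger(self):
        assert ao_stiffness_index(143.20, 88.40, 2.67, "classic_beta") == pytest.approx(
            18.0663, abs=1e-3
        )

    @given(p=st.floats(60.0, 110.0), strain=st.floats(0.3, 30.0))
    def test_closed_form_at_pressure_ratio_e(self, p, strain):
        # sbp/dbp = e makes the index 1 - ln(strain/100)
        got = ao_stiffness_index(p * np.e, p, strain)
        assert got == pytest.approx(1.0 - np.log(strain / 100.0), rel=1e-10)

    @given(
        dbp=st.floats(60.0, 110.0),
        pp=st.floats(20.0, 90.0),
        strain=st.floats(0.3, 30.0),
    )
    def test_log_of_ratio_equals_difference_of_logs(self, dbp, pp, strain):
        direct = ao_stiffness_index(dbp + pp, dbp, strain)
        alt = np.log((dbp + pp) / dbp) - np.log(strain / 100.0)
        assert direct == pytest.approx(alt, rel=1e-12)

    @pytest.mark.parametrize("interpretation", ["log_of_ratio", "classic_beta"])
    def test_strictly_decreasing_in_strain(self, interpretation):
        strains = np.linspace(0.5, 20.0, 50)
        vals = [ao_stiffness_index(143.2, 88.4, s, interpretation) for s in strains]
        assert np.all(np.diff(vals) < 0)

    def test_zero_strain_is_undefined(self):
        with pytest.raises(DomainError):
            ao_stiffness_index(143.2, 88.4, 0.0)

    def test_epsilon_clamp_warns(self):
        with pytest.warns(UserWarning):
            clamped = ao_stiffness_index(143.2, 88.4, 0.01, clamp_epsilon=0.1)
        assert clamped == pytest.approx(ao_stiffness_index(143.2, 88.4, 0.1))


class TestEatIndices:
    def test_reported_mean_thickness_index(self):
        ti, vi = eat_indices(9.51, 60.03, 1.82)
        assert ti == pytest.approx(5.22527, abs=1e-4)  # prints 5.23
        assert vi == pytest.approx(32.9835, abs=1e-3)

    def test_zero_measurements(self):
        assert eat_indices(0.0, 0.0, 1.9) == (0.0, 0.0)

    def test_rejects_nonpositive_bsa(self):
        with pytest.raises(DomainError):
            eat_indices(9.0, 60.0, 0.0)

    @given(
        t=st.floats(0.0, 25.0),
        v=st.floats(0.0, 200.0),
        bsa=st.floats(1.2, 2.6),
    )
    def test_index_bsa_round_trip(self, t, v, bsa):
        ti, vi = eat_indices(t, v, bsa)
        assert ti * bsa == pytest.approx(t, rel=1e-12, abs=1e-12)
        assert vi * bsa == pytest.approx(v, rel=1e-12, abs=1e-12)


class TestDeriveAll:
    def test_composition_matches_per_operation_values(self):
        d = derive_all(MEAN_RECORD)
        assert d.bsa == pytest.approx(1.8308716, rel=1e-6)
        assert d.bmi == pytest.approx(26.5911, rel=1e-4)
        assert d.ao_strain == pytest.approx(3.23160, abs=1e-4)
        assert d.ao_distensibility == pytest.approx(2 * d.ao_strain / 54.80, rel=1e-12)
        assert d.ao_stiffness_index == pytest.approx(
            np.log((143.20 / 88.40) / (d.ao_strain / 100.0)), rel=1e-12
        )
        assert d.eat_thickness_index == pytest.approx(9.51 / d.bsa, rel=1e-12)
        assert d.eat_volume_index == pytest.approx(60.03 / d.bsa, rel=1e-12)

    def test_equal_diameters_zero_strain_errors_on_stiffness(self):
        rec = PatientRecord(
            id="flat", age=60, sex="male", height=1.7, body_mass=70, sbp=140, dbp=85,
            ao_diastolic_diameter=33.0, ao_systolic_diameter=33.0,
            eat_thickness=9.0, eat_volume=55.0,
        )
        with pytest.raises(DomainError, match="flat"):
            derive_all(rec)

    def test_anthropometrics_independent_of_aortic_fields(self):
        import dataclasses

        other = dataclasses.replace(
            MEAN_RECORD, ao_diastolic_diameter=30.0, ao_systolic_diameter=32.0,
            sbp=150.0, dbp=90.0,
        )
        a, b = derive_all(MEAN_RECORD), derive_all(other)
        assert (a.bsa, a.bmi) == (b.bsa, b.bmi)

    def test_frame_derivation_matches_scalar_path(self, cohort_frame):
        df = derive_frame(cohort_frame)
        from aortastat.records import frame_to_records

        for i, rec in enumerate(frame_to_records(cohort_frame)[:10]):
            d = derive_all(rec)
            for col in ["bsa", "bmi", "ao_strain", "ao_distensibility",
                        "ao_stiffness_index", "eat_thickness_index", "eat_volume_index"]:
                assert df.iloc[i][col] == pytest.approx(getattr(d, col), rel=1e-12)

    def test_mosteller_config_propagates(self, cohort_frame):
        df = derive_frame(cohort_frame, IndexConfig(bsa_method="mosteller"))
        h, m = cohort_frame.iloc[0][["height", "body_mass"]]
        assert df.iloc[0]["bsa"] == pytest.approx(compute_bsa(h, m, "mosteller"), rel=1e-12)
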