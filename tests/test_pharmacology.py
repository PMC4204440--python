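"""Glycine-site Hill pharmacodynamics: activation, ratio, extremum,
classification, and the per-subunit literature averages."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glyqsp.pharmacology import (
    GLYCINE_SUBUNIT_STUDIES,
    DoseResponseClass,
    DoseResponseCurve,
    HillParams,
    SynapseClassPD,
    classify_dose_response,
    effective_conductance,
    ei_over_ee_ratio,
    find_ratio_extremum,
    hill_activation,
    read_subunit_table,
    subunit_averages,
    write_subunit_table,
)


class TestHillActivation:
    @pytest.mark.parametrize(
        "gly,p,expected",
        [
            (0.25, HillParams(0.25, 1.1), 0.5),  # half-activation at EC50
            (7.7, HillParams(7.7, 3.2), 0.5),
            (0.0, HillParams(1.0, 2.0), 0.0),
            # longhand power/ratio evaluation frozen as oracle
            (1.1, HillParams(0.25, 1.1), 0.8361374429067134),
        ],
    )
    def test_values(self, gly, p, expected):
        assert hill_activation(gly, p) == pytest.approx(expected, abs=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            hill_activation(-1.0, HillParams(1.0, 1.0))
        with pytest.raises(ValueError):
            HillParams(0.0, 1.0)
        with pytest.raises(ValueError):
            HillParams(1.0, -2.0)

    @settings(deadline=None, max_examples=50)
    @given(
        ec50=st.floats(1e-2, 1e2),
        slope=st.floats(0.3, 4.0),
        factor=st.floats(1e-2, 1e2),
        step=st.floats(1.01, 10.0),
    )
    def test_strictly_increasing_and_bounded(self, ec50, slope, factor, step):
        # arguments kept within the float-resolvable part of the sigmoid
        p = HillParams(ec50, slope)
        lo = ec50 * factor
        hi = lo * step
        a, b = hill_activation(lo, p), hill_activation(hi, p)
        assert 0.0 <= a < 1.0 and 0.0 <= b < 1.0
        assert b > a

    def test_saturates_toward_one(self):
        assert hill_activation(1e9, HillParams(0.3, 1.5)) > 1 - 1e-6


class TestEffectiveConductance:
    def test_half_activation_without_internalization(self, pd_beneficial):
        g = effective_conductance(0.35, "ee", pd_beneficial)
        assert g == pytest.approx(0.5, abs=1e-12)

    def test_internalization_at_its_ec50_halves_potentiation(self):
        pd_ = SynapseClassPD(
            ee=HillParams(0.35, 1.84),
            ei=HillParams(0.25, 1.1),
            internalization_ee=HillParams(10.0, 1.0),
        )
        bare = SynapseClassPD(ee=HillParams(0.35, 1.84), ei=HillParams(0.25, 1.1))
        assert effective_conductance(10.0, "ee", pd_) == pytest.approx(
            0.5 * effective_conductance(10.0, "ee", bare), rel=1e-12
        )

    def test_two_factor_product(self):
        # independent hand computation: hill(10; 0.35, 1.84) * (1 - hill(10; 40, 1))
        pd_ = SynapseClassPD(
            ee=HillParams(0.35, 1.84),
            ei=HillParams(0.25, 1.1),
            internalization_ee=HillParams(40.0, 1.0),
        )
        assert effective_conductance(10.0, "ee", pd_) == pytest.approx(
            0.7983278836248383, abs=1e-12
        )

    def test_unknown_class_rejected(self, pd_beneficial):
        with pytest.raises(ValueError):
            effective_conductance(1.0, "ie", pd_beneficial)


class TestSubunitAverages:
    def test_reproduces_all_printed_literature_averages(self):
        avg = subunit_averages(GLYCINE_SUBUNIT_STUDIES)
        expected = {
            "NR2A": (1.78, 1.43),
            "NR2B": (0.83, 1.77),
            "NR2C": (0.36, 1.66),
            "NR2D": (0.77, 1.21),
        }
        for subunit, (ec50, slope) in expected.items():
            assert avg.loc[subunit, "ec50_uM"] == pytest.approx(ec50, abs=0.0051)
            assert avg.loc[subunit, "hill_slope"] == pytest.approx(slope, abs=0.0051)

    def test_missing_cells_excluded_not_zeroed(self):
        # NR2D column has one blank study; mean over the 4 reported values
        nr2d = GLYCINE_SUBUNIT_STUDIES.query("subunit == 'NR2D'")
        assert nr2d["ec50_uM"].isna().sum() == 1
        avg = subunit_averages(GLYCINE_SUBUNIT_STUDIES)
        assert avg.loc["NR2D", "ec50_uM"] == pytest.approx(
            np.mean([0.56, 0.096, 2.3, 0.13]), rel=1e-12
        )

    def test_single_record_table(self):
        t = pd.DataFrame(
            [{"study": "s", "subunit": "NR2A", "ec50_uM": 1.5, "hill_slope": 2.0}]
        )
        avg = subunit_averages(t)
        assert avg.loc["NR2A", "ec50_uM"] == 1.5
        assert avg.loc["NR2A", "hill_slope"] == 2.0

    def test_all_missing_subunit_raises(self):
        t = pd.DataFrame(
            [{"study": "s", "subunit": "NR2D", "ec50_uM": None, "hill_slope": None}]
        )
        with pytest.raises(ValueError, match="no data"):
            subunit_averages(t)

    def test_roundtrip_delimited_text(self, tmp_path):
        path = tmp_path / "table.tsv"
        write_subunit_table(GLYCINE_SUBUNIT_STUDIES, path)
        back = read_subunit_table(path)
        pd.testing.assert_frame_equal(
            back, GLYCINE_SUBUNIT_STUDIES, check_dtype=False
        )


class TestRatio:
    def test_identical_classes_give_unity(self, pd_flat):
        g = np.logspace(-3, 3, 20)
        assert np.allclose(ei_over_ee_ratio(g, pd_flat), 1.0, atol=1e-12)

    def test_saturation_limit(self, pd_beneficial):
        assert ei_over_ee_ratio(1e6, pd_beneficial) == pytest.approx(1.0, abs=1e-4)

    def test_caption_parameters_near_reported_minimum(self, pd_beneficial):
        # frozen longhand evaluation at the reported-minimum concentration
        assert ei_over_ee_ratio(1.1, pd_beneficial) == pytest.approx(
            0.9378092008732599, abs=1e-12
        )

    def test_small_glycine_divergence(self, pd_beneficial):
        # ei slope < ee slope: ratio blows up at vanishing glycine
        assert ei_over_ee_ratio(1e-4, pd_beneficial) > 1e2

    def test_zero_glycine_rejected(self, pd_beneficial):
        with pytest.raises(ValueError):
            ei_over_ee_ratio(0.0, pd_beneficial)


class TestRatioExtremum:
    def test_agrees_with_dense_grid_oracle(self, pd_beneficial, ratio_grid_oracle):
        g_star, r_star, interior = ratio_grid_oracle(pd_beneficial, 0.01, 100.0)
        ext = find_ratio_extremum(pd_beneficial, window=(0.01, 100.0))
        assert interior and ext.is_interior_minimum
        grid_step = g_star * (np.log(100 / 0.01) / 99_999)
        assert abs(ext.gly_star - g_star) < 2 * grid_step
        assert abs(ext.ratio_star - r_star) < 1e-6

    def test_caption_parameter_band(self, pd_beneficial):
        ext = find_ratio_extremum(pd_beneficial, window=(0.01, 100.0))
        assert 0.8 <= ext.gly_star <= 1.6
        assert 0.90 <= ext.ratio_star <= 0.96

    def test_flat_curve_not_flagged_interior(self, pd_flat):
        ext = find_ratio_extremum(pd_flat)
        assert not ext.is_interior_minimum

    def test_monotone_configuration_not_flagged(self, ratio_grid_oracle):
        # ei slope > ee slope with ei ec50 > ee ec50: d(log ratio)/d(log g)
        # keeps one sign; the grid oracle confirms no interior minimum
        pd_ = SynapseClassPD(ee=HillParams(0.3, 1.0), ei=HillParams(0.6, 2.0))
        _, _, interior = ratio_grid_oracle(pd_)
        ext = find_ratio_extremum(pd_)
        assert not interior and not ext.is_interior_minimum

    def test_bad_window_rejected(self, pd_beneficial):
        with pytest.raises(ValueError):
            find_ratio_extremum(pd_beneficial, window=(1.0, 0.1))


class TestClassification:
    def test_condition_d_is_beneficial_u(self):
        # ei (0.2 uM, slope 1) vs ee (0.35 uM, slope 2)
        pd_ = SynapseClassPD(ee=HillParams(0.35, 2.0), ei=HillParams(0.2, 1.0))
        assert classify_dose_response(pd_) is DoseResponseClass.beneficial_U

    def test_identical_params_monotonic(self, pd_flat):
        assert classify_dose_response(pd_flat) is DoseResponseClass.monotonic

    def test_subphysiological_minimum(self, ratio_grid_oracle):
        # the minimum location scales with the EC50 pair, so shrinking both
        # EC50s tenfold pushes it below 0.5 uM (confirmed by the grid oracle)
        pd_ = SynapseClassPD(ee=HillParams(0.035, 1.84), ei=HillParams(0.025, 1.1))
        g_star, _, interior = ratio_grid_oracle(pd_)
        assert interior and g_star < 0.5
        assert (
            classify_dose_response(pd_)
            is DoseResponseClass.subphysiological_minimum
        )

    def test_beneficial_region_grows_with_slope_ratio(self):
        # coarse version of the classification-map trend
        ec50s = np.logspace(-1.5, 0.5, 8)
        counts = []
        for ratio in (1.0, 1.5, 2.0):
            n = 0
            for e_ei in ec50s:
                for e_ee in ec50s:
                    pd_ = SynapseClassPD(
                        ee=HillParams(e_ee, ratio), ei=HillParams(e_ei, 1.0)
                    )
                    if classify_dose_response(pd_) is DoseResponseClass.beneficial_U:
                        n += 1
            counts.append(n)
        assert counts == sorted(counts)


class TestDoseResponseCurve:
    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            DoseResponseCurve(np.array([1.0, 1.0, 2.0]), np.zeros(3))

    def test_write_creates_table_and_sidecar(self, tmp_path):
        c = DoseResponseCurve(
            np.array([0.1, 1.0]), np.array([2.0, 3.0]), {"response": "ratio"}
        )
        path = tmp_path / "curve.tsv"
        c.write(path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["glycine_uM", "response"]
        assert (tmp_path / "curve.tsv.meta.json").exists()
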