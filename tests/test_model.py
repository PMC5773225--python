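"""Forward mass-balance model, its inversion, and the specialization index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isocell.experiment import LabelCalibration, LabelingExperiment, calibrate
from isocell.model import (
    SingleCellLabelingModel,
    channel_gains,
    forward_model,
    invert_cell,
    invert_table,
    specialization_index,
)

rates = st.floats(min_value=0.0, max_value=0.3, allow_nan=False)
pos_rates = st.floats(min_value=1e-6, max_value=0.3, allow_nan=False)


class TestForwardModel:
    def test_no_sugar_assimilation_no_enrichment(self, experiment, calibration):
        assert forward_model(0.0, 0.0, experiment, calibration) == (0.0, 0.0)

    def test_single_channel_labeling(self, experiment, calibration):
        xE13C, xE2H = forward_model(0.0, 0.02, experiment, calibration)
        assert xE13C > 0 and xE2H == 0.0
        xE13C, xE2H = forward_model(0.02, 0.0, experiment, calibration)
        assert xE13C == 0.0 and xE2H > 0

    def test_asymptotic_consistency_with_calibration(self, natural):
        """Growing on arabinose alone for ten generations with full label
        purity reproduces the calibration plateau 0.70 - natural."""
        # all growth through the arabinose pathway, no AOC, no washout
        exp = LabelingExperiment(
            mode="batch", batch_label_fraction=1.0, mu_AOC=0.0,
            T_label=10 * np.log(2) / 0.15,
        )
        cal = calibrate(LabelCalibration(), exp, natural)
        xE13C, _ = forward_model(0.0, 0.15, exp, cal)
        assert xE13C == pytest.approx(0.70 - 0.009928, rel=2e-3)

    def test_monotone_in_own_rate_diluted_by_other(self, experiment, calibration):
        grid = np.linspace(0.0, 0.3, 40)
        # increasing mu_ara at fixed mu_glc raises xE13C
        xC, _ = forward_model(np.full_like(grid, 0.05), grid, experiment, calibration)
        assert np.all(np.diff(xC) > 0)
        # increasing mu_glc at fixed mu_ara dilutes xE13C
        xC2, _ = forward_model(grid, np.full_like(grid, 0.05), experiment, calibration)
        assert np.all(np.diff(xC2) < 0)

    def test_negative_rates_rejected(self, experiment, calibration):
        with pytest.raises(ValueError):
            forward_model(-0.01, 0.0, experiment, calibration)


class TestInversion:
    def test_round_trip_at_population_means(self, experiment, calibration):
        xe = forward_model(0.010, 0.017, experiment, calibration)
        est = invert_cell(*xe, experiment, calibration)
        assert est.mu_glc == pytest.approx(0.010, rel=1e-8)
        assert est.mu_ara == pytest.approx(0.017, rel=1e-8)
        assert est.converged

    @given(mu_glc=rates, mu_ara=rates)
    @settings(derandomize=True, max_examples=150, deadline=None)
    def test_round_trip_identity_on_box(self, experiment, calibration, mu_glc, mu_ara):
        xe = forward_model(mu_glc, mu_ara, experiment, calibration)
        est = invert_cell(*xe, experiment, calibration)
        assert est.mu_glc == pytest.approx(mu_glc, rel=1e-8, abs=1e-10)
        assert est.mu_ara == pytest.approx(mu_ara, rel=1e-8, abs=1e-10)

    def test_zero_enrichment_means_aoc_only(self, experiment, calibration):
        est = invert_cell(0.0, 0.0, experiment, calibration)
        assert est.mu_glc == 0.0 and est.mu_ara == 0.0
        assert est.mu_total == experiment.mu_AOC
        assert np.isnan(est.s)
        assert est.converged

    def test_negative_inputs_clipped(self, experiment, calibration):
        est = invert_cell(-1e-4, -1e-5, experiment, calibration)
        assert est.mu_glc == 0.0 and est.mu_ara == 0.0

    def test_unattainable_enrichment_flagged(self, experiment, calibration):
        est = invert_cell(0.2, 0.03, experiment, calibration)
        assert not est.converged
        assert est.mu_total == pytest.approx(5 * experiment.mu_max)

    def test_nonfinite_input_rejected(self, experiment, calibration):
        with pytest.raises(ValueError):
            invert_cell(float("nan"), 0.0, experiment, calibration)

    def test_scale_consistency(self, experiment, calibration):
        """Shrinking both excess fractions by a common factor preserves the
        sugar-rate ratio, hence the specialization index."""
        xe = forward_model(0.012, 0.020, experiment, calibration)
        for k in (0.5, 0.2, 0.05):
            est = invert_cell(k * xe[0], k * xe[1], experiment, calibration)
            assert est.mu_ara / est.mu_glc == pytest.approx(0.020 / 0.012, rel=1e-6)

    def test_grid_search_oracle_agreement(self, experiment, calibration, rng):
        """Brute-force nearest-neighbour inversion over a dense forward-model
        grid agrees with the root finder to the grid resolution."""
        n_grid = 600
        axis = np.linspace(0.0, 0.2, n_grid)
        gg, aa = np.meshgrid(axis, axis, indexing="ij")
        xC, xH = forward_model(gg.ravel(), aa.ravel(), experiment, calibration)
        gain_C, gain_H = channel_gains(experiment, calibration)
        step = axis[1] - axis[0]
        for _ in range(25):
            mu_glc, mu_ara = rng.uniform(0.0, 0.2, size=2)
            x0, y0 = forward_model(mu_glc, mu_ara, experiment, calibration)
            d2 = ((xC - x0) / gain_C) ** 2 + ((xH - y0) / gain_H) ** 2
            i = int(np.argmin(d2))
            est = invert_cell(x0, y0, experiment, calibration)
            assert abs(gg.ravel()[i] - est.mu_glc) <= 1.5 * step
            assert abs(aa.ravel()[i] - est.mu_ara) <= 1.5 * step


class TestSpecializationIndex:
    def test_extremes_and_center(self):
        assert specialization_index(0.0, 0.02) == -1.0
        assert specialization_index(0.02, 0.0) == 1.0
        assert specialization_index(0.015, 0.015) == 0.0

    def test_population_mean_rates(self):
        assert specialization_index(0.010, 0.017) == pytest.approx(-0.259, abs=5e-4)

    def test_proportional_to_availability_gives_zero(self):
        # twice the glucose supply, twice the glucose assimilation: s = 0
        assert specialization_index(0.02, 0.01, supply_glc=20, supply_ara=10) == 0.0

    def test_undefined_when_no_sugar_growth(self):
        assert np.isnan(specialization_index(0.0, 0.0))

    @given(mu_glc=pos_rates, mu_ara=pos_rates,
           sg=st.floats(1.0, 100.0), sa=st.floats(1.0, 100.0))
    @settings(derandomize=True, max_examples=150)
    def test_antisymmetry_and_bounds(self, mu_glc, mu_ara, sg, sa):
        s = specialization_index(mu_glc, mu_ara, sg, sa)
        s_swapped = specialization_index(mu_ara, mu_glc, sa, sg)
        assert -1.0 <= s <= 1.0
        assert s == pytest.approx(-s_swapped, abs=1e-12)


class TestModelObjects:
    def test_fit_returns_estimates_with_qc(self, tiny_counts, experiment, calibration):
        counts, filters = tiny_counts
        model = SingleCellLabelingModel.from_counts(
            counts, filters, experiment, calibration
        )
        res = model.fit()
        # only the QC-passing cells are fitted
        assert res.n_cells == int(model.measurements.shape[0])
        assert {"mu_glc", "mu_ara", "mu_total", "s", "converged"} <= set(
            res.estimates.columns
        )
        assert "arabinose" in res.summary()

    def test_auto_calibration(self, tiny_counts):
        counts, filters = tiny_counts
        model = SingleCellLabelingModel.from_counts(counts, filters)
        assert model.calibration.kappa_C == pytest.approx(0.70410, abs=5e-5)

    def test_invert_table_carries_identifiers(self, experiment, calibration):
        meas = pd.DataFrame(
            {"replicate_id": ["R1", "R1"], "field_id": ["F1", "F1"],
             "roi_id": ["a", "b"], "xE13C": [0.002, 0.0], "xE2H": [0.0002, 0.0]}
        )
        est = invert_table(meas, experiment, calibration)
        assert list(est["roi_id"]) == ["a", "b"]
        assert est.loc[1, "mu_total"] == experiment.mu_AOC
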