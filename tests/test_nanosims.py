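"""Atom fractions, drift correction, Poisson counting errors, and QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isocell.nanosims import (
    atom_fraction,
    drift_correct,
    excess_fraction,
    poisson_ratio_error_pct,
    process_counts,
    qc_filter,
)

fractions = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestAtomFraction:
    def test_exact_ratio(self):
        assert atom_fraction(100, 9900) == pytest.approx(0.01)

    def test_no_heavy_isotope(self):
        assert atom_fraction(0, 1000) == 0.0

    def test_near_natural_abundance(self):
        # 264 heavy in ~1e6 total is natural 2H abundance to 3 significant figures
        assert atom_fraction(264, 999736) == pytest.approx(0.000264, rel=5e-3)
        assert atom_fraction(264, 999736) == pytest.approx(0.0002642, rel=5e-3)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="empty ROI"):
            atom_fraction(0, 0)


class TestPoissonRatioError:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (10000, 100, 10.0499),
            (10**6, 10**6, 0.1414),
            (1, 1, 141.42),
        ],
    )
    def test_formula(self, a, b, expected):
        assert poisson_ratio_error_pct(a, b) == pytest.approx(expected, abs=5e-3)

    def test_zero_count_gives_infinite_error(self):
        assert np.isinf(poisson_ratio_error_pct(0, 100))
        assert np.isinf(poisson_ratio_error_pct(100, 0))

    @pytest.mark.parametrize("n_total,x_true", [(10**4, 0.01), (10**5, 0.01), (10**6, 0.05)])
    def test_monte_carlo_matches_formula(self, rng, n_total, x_true):
        """Empirical sd of recovered fractions across redraws matches the
        Poisson error prediction within a factor 1.25."""
        n_rep = 400
        heavy = rng.poisson(n_total * x_true, size=n_rep)
        light = rng.poisson(n_total * (1 - x_true), size=n_rep)
        x_hat = heavy / (heavy + light)
        predicted_rel = poisson_ratio_error_pct(n_total * x_true, n_total * (1 - x_true)) / 100
        empirical_rel = x_hat.std(ddof=1) / x_true
        assert empirical_rel / predicted_rel == pytest.approx(1.0, abs=0.25)


class TestDriftCorrection:
    def test_identity_when_no_drift(self):
        assert drift_correct(0.02, 0.01, 0.01) == pytest.approx(0.02)

    def test_arithmetic(self):
        assert drift_correct(0.020, 0.012, 0.010) == pytest.approx(0.018)
        # drift below reference raises the value
        assert drift_correct(0.010, 0.008, 0.012) == pytest.approx(0.014)

    @given(x=fractions, f=fractions, nat=st.floats(0.0, 0.05))
    @settings(derandomize=True, max_examples=100)
    def test_round_trip_identity_drift(self, x, f, nat):
        assert excess_fraction(drift_correct(x, f, f), nat) + nat == pytest.approx(
            x, abs=1e-12
        )

    @given(
        xs=st.lists(fractions, min_size=2, max_size=10),
        fc=fractions,
        fr=fractions,
    )
    @settings(derandomize=True, max_examples=100)
    def test_order_preserved_within_field(self, xs, fc, fr):
        xs = np.asarray(xs)
        corrected = drift_correct(xs, fc, fr)
        # a constant shift is monotone: the corrected values sorted by the
        # raw order are non-decreasing (ties may appear at float resolution)
        assert np.all(np.diff(corrected[np.argsort(xs, kind="stable")]) >= 0)


class TestExcessFraction:
    def test_unlabeled_cell_maps_to_zero(self):
        assert excess_fraction(0.009928, 0.009928) == 0.0
        assert excess_fraction(0.0002642, 0.0002642) == 0.0

    def test_arithmetic(self):
        assert excess_fraction(0.109928, 0.009928) == pytest.approx(0.1)


class TestProcessCounts:
    def test_fractions_and_drift(self, tiny_counts):
        counts, filters = tiny_counts
        meas = process_counts(counts, filters)
        a = meas.set_index("roi_id")
        # cell 'a': natural-composition counts on a field with +0.002 C drift
        assert a.loc["a", "x13C_uncorrected"] == pytest.approx(9928 / 1e6)
        assert a.loc["a", "x13C_corrected"] == pytest.approx(9928 / 1e6 - 0.002)
        # cell 'c': same counts, zero-drift field -> excess ~ 0
        assert a.loc["c", "xE13C"] == pytest.approx(0.0, abs=1e-12)
        # hydrogen counts 264/999736 sit within rounding of natural abundance
        assert a.loc["c", "xE2H"] == pytest.approx(0.0, abs=1e-6)

    def test_qc_flags(self, tiny_counts):
        counts, filters = tiny_counts
        meas = process_counts(counts, filters).set_index("roi_id")
        # cell 'b': large counts in every channel -> passes both bounds
        assert bool(meas.loc["b", "qc_pass"])
        # cell 'a': c13C ~ 9928 -> carbon ratio error just above 1%
        assert meas.loc["a", "err_pct_CH"] > 1.0
        assert not bool(meas.loc["a", "qc_pass"])

    def test_missing_field_background_is_hard_error(self, tiny_counts):
        counts, filters = tiny_counts
        with pytest.raises(KeyError, match="F2"):
            process_counts(counts, filters[filters.field_id != "F2"])

    def test_zero_count_roi_dropped(self, tiny_counts):
        counts, filters = tiny_counts
        counts = counts.copy()
        counts.loc[0, ["c12C", "c13C"]] = 0
        meas = process_counts(counts, filters)
        assert "a" not in set(meas["roi_id"])
        assert len(meas) == 3

    def test_negative_counts_rejected(self, tiny_counts):
        counts, filters = tiny_counts
        counts = counts.copy()
        counts.loc[0, "c1H"] = -5
        with pytest.raises(ValueError, match="negative"):
            process_counts(counts, filters)

    def test_duplicate_filter_rows_averaged(self, tiny_counts):
        counts, filters = tiny_counts
        dup = pd.concat(
            [filters, pd.DataFrame([{"field_id": "F1", "x13C_filter": 0.014,
                                     "x2H_filter": 0.0004, "is_reference": 0}])],
            ignore_index=True,
        )
        meas = process_counts(counts, dup).set_index("roi_id")
        # F1 background becomes mean(0.012, 0.014) = 0.013
        assert meas.loc["a", "x13C_corrected"] == pytest.approx(9928 / 1e6 - 0.003)


class TestQCFilter:
    def _table(self, err_hh, err_ch):
        return pd.DataFrame({"err_pct_HH": err_hh, "err_pct_CH": err_ch})

    def test_strict_bounds(self):
        df = self._table([9.9, 10.0, 5.0], [0.9, 0.5, 1.0])
        kept = qc_filter(df)
        assert list(kept.index) == [0]

    def test_counted_subset(self, rng):
        err_hh = rng.uniform(0, 20, size=100)
        err_ch = rng.uniform(0, 2, size=100)
        df = self._table(err_hh, err_ch)
        expected = int(((err_hh < 10) & (err_ch < 1)).sum())
        kept = qc_filter(df)
        assert len(kept) == expected
        assert set(kept.index) <= set(df.index)

    def test_idempotent(self, rng):
        df = self._table(rng.uniform(0, 20, 50), rng.uniform(0, 2, 50))
        once = qc_filter(df)
        twice = qc_filter(once)
        pd.testing.assert_frame_equal(once, twice)
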