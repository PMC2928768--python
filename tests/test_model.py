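"""Log-linear Tm equation: published coefficients, prediction, OLS refitting."""

import math

import numpy as np
import pytest

from dnamelt import (
    MeltingConditions,
    ModelCoefficients,
    TmDatasetRecord,
    TmRegression,
    predict_tm,
    predict_tm_for_sequence,
    published_coefficients,
    reverse_complement,
)
from dnamelt.simulate import SyntheticDatasetSpec, synthetic_tm_dataset

WORKED_SEQ = "GACGACAAGACCGCG"

# Na+ (M), strand concentration (g/ml), and the model's printed genome-scale
# prediction (degC) for one bacterial genome across a salt series.  Used to
# cross-check the transcribed salt and strand-concentration coefficients:
# with sequence and window size fixed, predictions are linear in ln(Na+) and
# ln(DNA) alone.
ECOLI_SALT_SERIES = [
    (0.015, 0.000018, 77.9),
    (0.016, 0.00002, 78.3),
    (0.0732, 0.00005, 86.6),
    (0.075, 0.000018, 85.9),
    (0.01, 0.000018, 75.8),
    (0.02, 0.000018, 79.3),
    (0.035, 0.000018, 82.1),
    (0.05, 0.000018, 83.8),
    (0.1, 0.000018, 87.3),
    (0.12, 0.000018, 88.2),
    (0.195, 0.000018, 90.6),
    (0.6, 0.000018, 96.2),
]


class TestPublishedCoefficients:
    def test_worked_example_with_rounded_e(self, oligo_conditions):
        """E carried at 2 decimals reproduces the printed 65.04 degC."""
        tm = predict_tm_for_sequence(
            WORKED_SEQ, oligo_conditions, round_e_2dp=True
        )
        assert tm == pytest.approx(65.04, abs=0.01)

    def test_worked_example_full_precision(self, oligo_conditions):
        tm = predict_tm_for_sequence(WORKED_SEQ, oligo_conditions)
        assert tm == pytest.approx(65.04, abs=0.05)

    def test_all_slopes_positive(self):
        c = published_coefficients()
        assert c.a_e > 0 and c.a_len > 0 and c.a_salt > 0 and c.a_dna > 0

    def test_salt_series_cross_check(self):
        """OLS on the printed genome salt series recovers the salt and strand
        coefficients (strand weakly determined: only two distinct values)."""
        x = np.array([[math.log(na), math.log(dna), 1.0] for na, dna, _ in ECOLI_SALT_SERIES])
        y = np.array([tm for *_, tm in ECOLI_SALT_SERIES])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        c = published_coefficients()
        assert beta[0] == pytest.approx(c.a_salt, abs=0.05)
        assert beta[1] == pytest.approx(c.a_dna, abs=0.10)


class TestPredict:
    def test_salt_shift_separability(self, rng):
        """Tm(c2) - Tm(c1) = a_salt * ln(c2/c1), independent of sequence."""
        c = published_coefficients()
        for _ in range(20):
            n = int(rng.integers(10, 60))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            c1, c2 = float(rng.uniform(0.01, 0.3)), float(rng.uniform(0.3, 1.0))
            t1 = predict_tm_for_sequence(seq, MeltingConditions(c1, 2e-6))
            t2 = predict_tm_for_sequence(seq, MeltingConditions(c2, 2e-6))
            assert t2 - t1 == pytest.approx(c.a_salt * math.log(c2 / c1), abs=1e-9)

    def test_monotonicity_in_all_predictors(self):
        cond = MeltingConditions(0.1, 1e-6)
        base = predict_tm(8.0, 20, cond)
        assert predict_tm(9.0, 20, cond) > base
        assert predict_tm(8.0, 40, cond) > base
        assert predict_tm(8.0, 20, MeltingConditions(0.2, 1e-6)) > base
        assert predict_tm(8.0, 20, MeltingConditions(0.1, 2e-6)) > base

    def test_log_terms_vanish_at_unit_arguments(self):
        """ln(1) = 0 removes the salt and strand terms entirely."""
        c = published_coefficients()
        e = 11 * 19 / 20  # poly-G 20-mer
        tm = predict_tm(e, 20, MeltingConditions(1.0, 1.0))
        assert tm == pytest.approx(c.a_e * e + c.a_len * math.log(20) + c.intercept)

    def test_revcomp_same_tm(self, oligo_conditions):
        assert predict_tm_for_sequence(WORKED_SEQ, oligo_conditions) == pytest.approx(
            predict_tm_for_sequence(reverse_complement(WORKED_SEQ), oligo_conditions)
        )

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError, match="na_molar"):
            MeltingConditions(0.0, 1e-6)
        with pytest.raises(ValueError, match="strand_conc"):
            MeltingConditions(0.1, -1.0)

    def test_three_term_variant_ignores_strand_conc(self):
        c3 = ModelCoefficients(
            a_e=7.0, a_len=17.0, a_salt=5.0, intercept=-20.0,
            variant="three_term_no_dna",
        )
        t1 = predict_tm(8.0, 20, MeltingConditions(0.1, 1e-6), c3)
        t2 = predict_tm(8.0, 20, MeltingConditions(0.1, 1e-3), c3)
        assert t1 == t2

    def test_coefficient_variant_validation(self):
        with pytest.raises(ValueError, match="a_dna"):
            ModelCoefficients(a_e=7, a_len=17, a_salt=5, intercept=-25)
        with pytest.raises(ValueError, match="must not carry"):
            ModelCoefficients(
                a_e=7, a_len=17, a_salt=5, intercept=-25, a_dna=0.9,
                variant="three_term_no_dna",
            )


class TestRegression:
    def test_noiseless_recovery_exact(self):
        """OLS is exact on data generated noiselessly from known coefficients."""
        recs = synthetic_tm_dataset(SyntheticDatasetSpec(n_records=60, noise_sd=0.0, seed=11))
        res = TmRegression(recs).fit()
        truth = published_coefficients()
        assert res.coefficients.a_e == pytest.approx(truth.a_e, abs=1e-6)
        assert res.coefficients.a_len == pytest.approx(truth.a_len, abs=1e-6)
        assert res.coefficients.a_salt == pytest.approx(truth.a_salt, abs=1e-6)
        assert res.coefficients.a_dna == pytest.approx(truth.a_dna, abs=1e-6)
        assert res.coefficients.intercept == pytest.approx(truth.intercept, abs=1e-6)
        assert res.mean_abs_error < 1e-9

    def test_three_term_refit_runs(self):
        recs = synthetic_tm_dataset(SyntheticDatasetSpec(n_records=60, noise_sd=1.0, seed=12))
        res = TmRegression(recs).fit("three_term_no_dna")
        assert res.coefficients.a_dna is None
        assert res.coefficients.variant == "three_term_no_dna"
        assert 0 < res.r <= 1

    def test_r2_consistency_and_summary(self):
        recs = synthetic_tm_dataset(SyntheticDatasetSpec(n_records=80, noise_sd=1.36, seed=13))
        res = TmRegression(recs).fit()
        assert res.r**2 == pytest.approx(res.rsquared, abs=1e-10)
        s = res.summary()
        assert "a_E" in s and "r^2" in s and f"n = {len(recs)}" in s

    def test_evaluate_perfect_predictions(self):
        recs = synthetic_tm_dataset(SyntheticDatasetSpec(n_records=40, noise_sd=0.0, seed=14))
        ev = TmRegression(recs).evaluate(published_coefficients())
        assert ev.r == pytest.approx(1.0)
        assert ev.mean_abs_error == pytest.approx(0.0, abs=1e-9)
        for rec in recs:
            assert rec.pred_tm is not None
            assert rec.residual == pytest.approx(0.0, abs=1e-9)

    def test_single_record_mae_defined_r_nan(self, oligo_conditions):
        recs = [TmDatasetRecord("x", WORKED_SEQ, oligo_conditions, exp_tm=64.4)]
        with pytest.warns(UserWarning, match="correlation undefined"):
            ev = TmRegression(recs).evaluate()
        assert math.isnan(ev.r)
        assert ev.mean_abs_error == pytest.approx(abs(64.4 - recs[0].pred_tm))

    def test_underdetermined_dataset_rejected(self):
        recs = synthetic_tm_dataset(SyntheticDatasetSpec(n_records=3, noise_sd=0.5, seed=15))
        with pytest.raises(ValueError, match="at least"):
            TmRegression(recs).fit()

    def test_collinear_predictors_named(self, rng):
        """Records sharing one length and salt make ln(Len) collinear with the intercept."""
        cond = MeltingConditions(0.1, 1e-6)
        recs = [
            TmDatasetRecord(
                f"r{i}", "".join(rng.choice(list("ACGT"), size=20)), cond,
                exp_tm=float(60 + rng.normal()),
            )
            for i in range(20)
        ]
        with pytest.raises(ValueError, match="collinear"):
            TmRegression(recs).fit()

    def test_normal_probability_plot_data(self):
        recs = synthetic_tm_dataset(SyntheticDatasetSpec(n_records=50, noise_sd=1.0, seed=16))
        ev = TmRegression(recs).evaluate()
        q, r = ev.normal_probability_plot_data()
        assert len(q) == len(r) == 50
        assert np.all(np.diff(r) >= 0)


@pytest.fixture(scope="module")
def table():
    recs = synthetic_tm_dataset(SyntheticDatasetSpec(n_records=150, noise_sd=1.36, seed=17))
    return TmRegression(recs).parameter_combination_correlations()


class TestSubsetCorrelations:

    def test_all_15_subsets_reported(self, table):
        assert len(table) == 15
        assert set(table["parameters"]).issuperset({"E", "Len", "Conc", "DNA",
                                                    "E + Len + Conc + DNA"})

    def test_nested_subset_r_monotonicity(self, table):
        """Adding a predictor never decreases in-sample |r| (nested OLS)."""
        r = dict(zip(table["parameters"], table["r"].abs()))
        nested = [
            ("E", "E + Len"), ("E + Len", "E + Len + Conc"),
            ("E + Len + Conc", "E + Len + Conc + DNA"),
            ("Conc", "Conc + DNA"), ("Len", "Len + Conc"),
        ]
        for small, big in nested:
            assert r[big] >= r[small] - 1e-12

    def test_full_model_r_matches_fit(self, table):
        recs = synthetic_tm_dataset(SyntheticDatasetSpec(n_records=150, noise_sd=1.36, seed=17))
        res = TmRegression(recs).fit()
        full = float(table.loc[table["parameters"] == "E + Len + Conc + DNA", "r"].iloc[0])
        assert full == pytest.approx(res.r, abs=1e-10)

    def test_single_predictor_r_is_signed(self, table):
        """Single-predictor entries carry the sign of the simple correlation."""
        recs = synthetic_tm_dataset(SyntheticDatasetSpec(n_records=150, noise_sd=1.36, seed=17))
        import dnamelt.model as m

        design = m._design_frame(recs)
        for name, col in [("E", "e"), ("DNA", "dna")]:
            expected = np.corrcoef(design[col], design["exp_tm"])[0, 1]
            got = float(table.loc[table["parameters"] == name, "r"].iloc[0])
            assert got == pytest.approx(expected, abs=1e-10)
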