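import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from crossclock.age_models import AgeTransformSpec
from crossclock.clock import (
    ClockModel,
    evaluate_predictions,
    fit_clock,
    fit_dual_species_clock,
    loocv_evaluate,
    predict_age,
    subset_mappable_probes,
)

from .conftest import make_annotation, make_matrix, make_sheet

IDENTITY = AgeTransformSpec("identity")


class TestSubsetMappableProbes:
    def _setup(self):
        ann = make_annotation(
            [
                {"mappable_species": {"opossum"}},
                {"mappable_species": {"mouse"}},
                {"mappable_species": {"opossum", "mouse"}},
            ]
        )
        matrix = make_matrix(np.full((3, 4), 0.5))
        return matrix, ann

    def test_intersection_semantics(self):
        matrix, ann = self._setup()
        both = subset_mappable_probes(matrix, ann, {"opossum", "mouse"})
        assert both.probe_ids == ["cg002"]
        single = subset_mappable_probes(matrix, ann, {"opossum"})
        assert single.probe_ids == ["cg000", "cg002"]

    def test_empty_universe_raises(self):
        matrix, ann = self._setup()
        with pytest.raises(ValueError, match="no probes mappable"):
            subset_mappable_probes(matrix, ann, {"human", "opossum"})


class TestEvaluatePredictions:
    def test_perfect_and_shifted(self):
        ev = evaluate_predictions([1, 2, 3], [1, 2, 3])
        assert ev.pearson_r == pytest.approx(1.0) and ev.median_abs_error == 0.0
        ev = evaluate_predictions([1.5, 2.5, 3.5], [1, 2, 3])
        assert ev.pearson_r == pytest.approx(1.0)
        assert ev.median_abs_error == pytest.approx(0.5)

    def test_pearson_value(self):
        # closed form: r = sqrt(27/28) for these points
        ev = evaluate_predictions([1, 2, 3], [1, 2, 4])
        assert ev.pearson_r == pytest.approx(np.sqrt(27 / 28), abs=1e-9)

    def test_degenerate_predictions_flagged(self):
        ev = evaluate_predictions([2.0, 2.0, 2.0], [1, 2, 3])
        assert ev.pearson_r == 0.0 and ev.degenerate

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            evaluate_predictions([1.0], [1.0])


class TestPredictAge:
    def test_zero_coefficients_give_constant(self):
        model = ClockModel(
            intercept=1.7, coefficients={}, transform=IDENTITY, alpha=0.5, lambda_=1.0
        )
        matrix = make_matrix(np.full((2, 3), 0.2))
        sheet = make_sheet([1.0, 2.0, 3.0])
        np.testing.assert_allclose(predict_age(model, matrix, sheet), 1.7)

    def test_affine_arithmetic(self):
        model = ClockModel(
            intercept=1.0, coefficients={"cg000": 2.0}, transform=IDENTITY,
            alpha=0.5, lambda_=1.0,
        )
        matrix = make_matrix([[0.25, 0.5]])
        sheet = make_sheet([1.0, 2.0])
        np.testing.assert_allclose(predict_age(model, matrix, sheet), [1.5, 2.0])

    def test_invariant_to_probe_row_order(self, small_dataset):
        matrix, sheet, _, _ = small_dataset
        model = fit_clock(matrix, sheet, IDENTITY, seed=1)
        shuffled = matrix.subset_probes(list(reversed(matrix.probe_ids)))
        np.testing.assert_allclose(
            predict_age(model, matrix, sheet), predict_age(model, shuffled, sheet)
        )

    def test_missing_beta_flags_sample(self):
        model = ClockModel(
            intercept=0.0, coefficients={"cg000": 1.0}, transform=IDENTITY,
            alpha=0.5, lambda_=1.0,
        )
        matrix = make_matrix([[0.25, np.nan]])
        pred = predict_age(model, matrix, make_sheet([1.0, 2.0]))
        assert not np.isnan(pred[0]) and np.isnan(pred[1])


class TestFitClock:
    def test_constructed_signal_recovered(self):
        """A probe tracking transformed age exactly should dominate the fit,
        verified against an unpenalized least-squares oracle on the support."""
        rng = np.random.default_rng(4)
        n = 60
        ages = rng.uniform(0, 4.2, n)
        signal = (ages / 4.2) * 0.8 + 0.1  # exact linear image of age
        noise = rng.uniform(0.2, 0.8, (99, n))
        values = np.vstack([signal, noise])
        matrix = make_matrix(values)
        sheet = make_sheet(ages)
        model = fit_clock(matrix, sheet, IDENTITY, seed=0)
        assert "cg000" in model.coefficients
        top = max(model.coefficients, key=lambda p: abs(model.coefficients[p]))
        assert top == "cg000"
        ev = evaluate_predictions(predict_age(model, matrix, sheet), ages)
        assert ev.pearson_r >= 0.99
        # unpenalized oracle on the signal probe alone: slope 4.2 / 0.8
        ls_slope = np.polyfit(signal, ages, 1)[0]
        assert ls_slope == pytest.approx(4.2 / 0.8, rel=1e-6)
        assert np.sign(model.coefficients["cg000"]) == np.sign(ls_slope)

    def test_determinism(self, small_dataset):
        matrix, sheet, _, _ = small_dataset
        a = fit_clock(matrix, sheet, IDENTITY, seed=7)
        b = fit_clock(matrix, sheet, IDENTITY, seed=7)
        assert a.coefficients == b.coefficients
        assert a.lambda_ == b.lambda_

    def test_fewer_samples_than_folds(self):
        matrix = make_matrix(np.random.default_rng(0).random((5, 6)))
        with pytest.raises(ValueError, match="n_folds"):
            fit_clock(matrix, make_sheet(range(6)), IDENTITY, seed=0)

    def test_constant_target_rejected(self):
        matrix = make_matrix(np.random.default_rng(0).random((5, 12)))
        with pytest.raises(ValueError, match="constant"):
            fit_clock(matrix, make_sheet([1.0] * 12), IDENTITY, seed=0)

    def test_model_json_round_trip(self, small_dataset, tmp_path):
        matrix, sheet, _, _ = small_dataset
        model = fit_clock(matrix, sheet, IDENTITY, seed=2)
        path = tmp_path / "clock.json"
        model.to_json(path)
        back = ClockModel.from_json(path)
        assert back.coefficients == model.coefficients
        assert back.transform == model.transform

    def test_sparsity_monotone_in_lambda(self, small_dataset):
        """Along the regularization path, stronger penalties keep fewer probes."""
        from crossclock.clock import _enet_path, _lambda_grid, _standardize_drop

        matrix, sheet, _, _ = small_dataset
        X = matrix.values.T
        y = sheet.samples["age_years"].to_numpy()
        Xs, _, _ = _standardize_drop(X)
        yc = y - y.mean()
        lambdas = _lambda_grid(Xs.values, yc)
        _, coefs, _ = _enet_path(Xs.values, yc, lambdas)
        nnz = (np.abs(coefs) > 0).sum(axis=0)
        # descending lambda grid: sparsity non-increasing along the path
        assert np.all(np.diff(nnz) >= -3)  # small CD wobble tolerated
        assert nnz[0] <= nnz[-1]


class TestAgainstGlmnet:
    def test_coefficients_match_glmnet_at_fixed_lambda(self, tmp_path):
        """Independent oracle: R glmnet on the same standardized design and
        fixed lambda grid agrees with the coordinate-descent fit used here."""
        from crossclock.clock import _enet_path, _lambda_grid, _standardize_drop

        rng = np.random.default_rng(12)
        n, p = 40, 25
        X = rng.random((n, p))
        y = 2.0 * X[:, 0] - 1.5 * X[:, 3] + 0.1 * rng.standard_normal(n)
        Xs, _, _ = _standardize_drop(X)
        yc = y - y.mean()
        lambdas = _lambda_grid(Xs.values, yc)
        _, coefs, _ = _enet_path(Xs.values, yc, lambdas)
        pick = 40  # an interior lambda with a sparse, nontrivial model
        np.savetxt(tmp_path / "X.txt", Xs.values)
        np.savetxt(tmp_path / "y.txt", yc)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(glmnet))
                X <- as.matrix(read.table("{tmp_path}/X.txt"))
                y <- scan("{tmp_path}/y.txt", quiet=TRUE)
                fit <- glmnet(X, y, alpha=0.5, lambda={lambdas[pick]:.12g},
                              standardize=FALSE, intercept=FALSE,
                              thresh=1e-12)
                write(as.numeric(coef(fit))[-1], "{tmp_path}/coef.txt", ncolumns=1)
                """
            )
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        r_coef = np.loadtxt(tmp_path / "coef.txt")
        # same selected support and close weights (solvers differ in
        # convergence details; agreement to ~0.5% of the max coefficient)
        np.testing.assert_array_equal(
            np.abs(coefs[:, pick]) > 1e-3, np.abs(r_coef) > 1e-3
        )
        np.testing.assert_allclose(coefs[:, pick], r_coef, atol=5e-3)


class TestLoocv:
    def test_perfect_signal_short(self):
        rng = np.random.default_rng(3)
        n = 16
        ages = rng.uniform(0, 4.2, n)
        values = np.vstack(
            [(ages / 4.2) * 0.8 + 0.1, rng.uniform(0.2, 0.8, (40, n))]
        )
        matrix = make_matrix(values)
        preds, ev = loocv_evaluate(matrix, make_sheet(ages), IDENTITY, seed=1)
        assert ev.pearson_r > 0.95
        assert not ev.degenerate

    def test_needs_ten_samples(self):
        matrix = make_matrix(np.random.default_rng(0).random((5, 8)))
        with pytest.raises(ValueError, match="at least 10"):
            loocv_evaluate(matrix, make_sheet(range(8)), IDENTITY, seed=0)

    def test_zero_variance_betas_degenerate(self):
        matrix = make_matrix(np.full((5, 12), 0.5))
        ages = list(np.linspace(0.1, 3.0, 12))
        _, ev = loocv_evaluate(matrix, make_sheet(ages), IDENTITY, seed=0)
        assert ev.degenerate and ev.pearson_r == 0.0


class TestDualSpecies:
    def _two_species(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        out = []
        for label, lifespan, maturity in (
            ("shortlived", 4.2, 0.5), ("longlived", 122.5, 15.0),
        ):
            ages = rng.uniform(0, lifespan, n)
            g = ages / lifespan
            values = np.vstack([
                np.clip(g * 0.7 + 0.15 + 0.01 * rng.standard_normal((3, n)), 0, 1),
                rng.uniform(0.2, 0.8, (30, n)),
            ])
            matrix = make_matrix(values, sample_ids=[f"{label}{i}" for i in range(n)])
            sheet = make_sheet(
                ages, species=label, lifespan=lifespan, maturity=maturity
            )
            sheet.samples["sample_id"] = [f"{label}{i}" for i in range(n)]
            out.append((matrix, sheet))
        return out

    def test_single_species_reduces_to_fit_clock(self):
        (matrix, sheet), _ = self._two_species()
        dual = fit_dual_species_clock([(matrix, sheet)], mode="relative", seed=4)
        transform = AgeTransformSpec.from_sample_sheet("relative", sheet)
        single = fit_clock(matrix, sheet, transform, seed=4)
        assert dual.coefficients == single.coefficients

    def test_relative_mode_pools_species(self):
        datasets = self._two_species()
        model = fit_dual_species_clock(datasets, mode="relative", seed=4)
        assert model.transform.kind == "relative"
        assert model.training_meta["n_samples"] == 24
        # shared relative-age probes should carry the model
        assert model.n_nonzero >= 1

    def test_chronological_mode_uses_loglinear(self):
        datasets = self._two_species()
        model = fit_dual_species_clock(datasets, mode="chronological", seed=4)
        assert model.transform.kind == "loglinear"
        assert set(model.transform.maturities) == {"shortlived", "longlived"}

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            fit_dual_species_clock(self._two_species(), mode="both", seed=0)

    def test_relative_mode_removes_lifespan_rescaling(self):
        """A species and its lifespan-rescaled copy (ages and lifespan both
        scaled 29×) share relative-age trajectories exactly, so the
        relative-mode pooled clock recovers R >= 0.95."""
        from crossclock.clock import concat_datasets

        rng = np.random.default_rng(9)
        n, scale = 12, 122.5 / 4.2
        ages = rng.uniform(0.1, 4.2, n)
        g = ages / 4.2
        values = np.vstack([
            np.clip(g * 0.7 + 0.15 + 0.02 * rng.standard_normal((4, n)), 0, 1),
            rng.uniform(0.2, 0.8, (40, n)),
        ])
        short = (
            make_matrix(values, sample_ids=[f"a{i}" for i in range(n)]),
            make_sheet(ages, species="short", lifespan=4.2, maturity=0.5),
        )
        short[1].samples["sample_id"] = [f"a{i}" for i in range(n)]
        long = (
            make_matrix(values, sample_ids=[f"b{i}" for i in range(n)]),
            make_sheet(ages * scale, species="long", lifespan=122.5, maturity=14.6),
        )
        long[1].samples["sample_id"] = [f"b{i}" for i in range(n)]
        matrix, sheet = concat_datasets([short, long])
        transform = AgeTransformSpec.from_sample_sheet("relative", sheet)
        preds, ev = loocv_evaluate(
            matrix, sheet, transform, seed=0, target_scale=True
        )
        assert ev.pearson_r >= 0.95

    def test_disjoint_probe_universes_rejected(self):
        (m1, s1), (m2, s2) = self._two_species()
        m2 = make_matrix(m2.values, probe_ids=[f"other{i}" for i in range(m2.n_probes)],
                         sample_ids=m2.sample_ids)
        with pytest.raises(ValueError, match="share no probes"):
            fit_dual_species_clock([(m1, s1), (m2, s2)], mode="relative", seed=0)
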