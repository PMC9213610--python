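"""Elastic-net epigenetic clocks.

A clock is a penalized linear model predicting transformed age from beta
values.  The mixing parameter is fixed at α = 0.5 (midpoint between ridge
and lasso) and is not optimized; the penalty λ is chosen by internal
ten-fold cross-validation over a 100-value log-spaced grid, by default with
the one-standard-error rule (the largest λ within one SE of the CV-error
minimum — the CV minimum itself is available via ``lambda_rule='min'``),
mirroring cv.glmnet semantics: predictors are standardized to unit variance for the
penalized fit and coefficients are reported back on the beta scale;
λ_max is the smallest λ with an all-zero solution, and the grid descends to
λ_max·1e-4 when n > p and λ_max·1e-2 otherwise.  Ties in CV error resolve
toward the larger λ (sparser model).

Out-of-sample accuracy is measured by leave-one-sample-out cross-validation
(LOOCV): each sample is predicted by a clock fitted — including the internal
λ search — on the remaining n − 1 samples, and the evaluation reports the
Pearson correlation R between predicted and actual age and the median
absolute error (mae) in the target's units.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.linear_model import enet_path

from .age_models import AgeTransformSpec
from .io_formats import MethylationMatrix, ProbeAnnotation, SampleSheet

logger = logging.getLogger(__name__)

ALPHA = 0.5  # elastic-net mixing; fixed by design, not tuned
N_LAMBDA = 100
#: coordinate-descent iteration cap; near-converged fits suffice for λ search
MAX_ITER = 250


def _enet_path(X, y, alphas):
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return enet_path(X, y, l1_ratio=ALPHA, alphas=alphas, max_iter=MAX_ITER)


@dataclass
class ClockModel:
    """A fitted sparse linear age predictor plus its age-transform spec."""

    intercept: float
    coefficients: dict[str, float]  # beta-scale weights, nonzero entries only
    transform: AgeTransformSpec
    alpha: float
    lambda_: float
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alpha != ALPHA:
            raise ValueError(f"alpha is fixed at {ALPHA}")
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        universe = self.training_meta.get("probe_universe")
        if universe is not None:
            stray = set(self.coefficients) - set(universe)
            if stray:
                raise ValueError(f"coefficients outside training universe: {sorted(stray)[:5]}")

    @property
    def n_nonzero(self) -> int:
        return len(self.coefficients)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "coefficients": self.coefficients,
                    "transform": self.transform.to_dict(),
                    "alpha": self.alpha,
                    "lambda": self.lambda_,
                    "training_meta": self.training_meta,
                },
                fh, indent=1, sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "ClockModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            transform=AgeTransformSpec.from_dict(d["transform"]),
            alpha=float(d["alpha"]),
            lambda_=float(d["lambda"]),
            training_meta=d.get("training_meta", {}),
        )


@dataclass
class ClockEvaluation:
    """Accuracy summary: Pearson R and median absolute error (target units)."""

    pearson_r: float
    median_abs_error: float
    n: int
    degenerate: bool = False  # zero-variance predictions; r reported as 0


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------

def _lambda_grid(X_std: np.ndarray, y_c: np.ndarray) -> np.ndarray:
    n, p = X_std.shape
    lmax = np.abs(X_std.T @ y_c).max() / (n * ALPHA)
    if lmax <= 0:
        raise ValueError("all-constant target: cannot build a lambda grid")
    min_ratio = 1e-4 if n > p else 1e-2
    return np.geomspace(lmax, lmax * min_ratio, N_LAMBDA)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    return (X - mean) / sd, mean, sd


def _fold_assignment(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded uniform shuffle; folds are contiguous blocks of the shuffled order."""
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, block in enumerate(np.array_split(order, n_folds)):
        folds[block] = f
    return folds


def _cv_lambda(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
               n_folds: int, rng: np.random.Generator,
               rule: str = "1se") -> tuple[float, np.ndarray]:
    """Pick λ by k-fold CV squared error over a fixed grid.

    ``rule='min'`` takes the CV-error minimum; ``rule='1se'`` (default) the
    largest λ whose CV error is within one standard error of the minimum,
    which collapses pure-noise fits to the intercept-only model instead of
    chasing chance dips in the CV curve.  The grid descends, so argmin's
    first-hit rule resolves exact ties toward the larger λ (sparser model).
    """
    n = len(y)
    folds = _fold_assignment(n, n_folds, rng)
    sq_err = np.zeros((n, len(lambdas)))
    fold_means = np.zeros((n_folds, len(lambdas)))
    for f in range(n_folds):
        test = folds == f
        train = ~test
        Xs, mean, sd = _standardize_drop(X[train])
        yc = y[train] - y[train].mean()
        ret_lam, coefs, _ = _enet_path(Xs.values, yc, lambdas)
        assert np.allclose(ret_lam, lambdas)  # grid is descending; order preserved
        # back to original scale for prediction on the held-out block
        coefs_orig = coefs / sd[:, None]
        pred = X[test][:, Xs.keep] @ coefs_orig + (
            y[train].mean() - mean @ coefs_orig
        )
        sq_err[test] = (pred - y[test][:, None]) ** 2
        fold_means[f] = sq_err[test].mean(axis=0)
    mean_err = sq_err.mean(axis=0)
    best = int(np.argmin(mean_err))
    if rule == "1se":
        se = fold_means.std(axis=0, ddof=1)[best] / np.sqrt(n_folds)
        best = int(np.argmax(mean_err <= mean_err[best] + se))
    elif rule != "min":
        raise ValueError(f"unknown lambda rule {rule!r}")
    return float(lambdas[best]), mean_err


class _Std:
    """Standardized design with zero-variance columns dropped."""

    __slots__ = ("values", "keep")

    def __init__(self, values: np.ndarray, keep: np.ndarray):
        self.values = values
        self.keep = keep


def _standardize_drop(X: np.ndarray) -> tuple[_Std, np.ndarray, np.ndarray]:
    sd = X.std(axis=0)
    keep = sd > 0
    mean = X[:, keep].mean(axis=0)
    return _Std((X[:, keep] - mean) / sd[keep], keep), mean, sd[keep]


def _elastic_net_fit(X: np.ndarray, y: np.ndarray, n_folds: int,
                     rng: np.random.Generator,
                     lambda_rule: str = "1se") -> tuple[float, np.ndarray, float]:
    """Full cv.glmnet-style fit: grid from the full data, CV λ choice, final
    path fit; returns (intercept, beta-scale coefficients over X's columns, λ)."""
    Xs_full, mean_full, sd_full = _standardize_drop(X)
    if Xs_full.values.shape[1] == 0:
        # all predictors constant: intercept-only model (degenerate fit)
        logger.warning("no non-constant predictors; returning intercept-only model")
        return float(y.mean()), np.zeros(X.shape[1]), np.inf
    yc = y - y.mean()
    lambdas = _lambda_grid(Xs_full.values, yc)
    lam, _ = _cv_lambda(X, y, lambdas, n_folds, rng, rule=lambda_rule)
    ret_lam, coefs, _ = _enet_path(Xs_full.values, yc, lambdas)
    assert np.allclose(ret_lam, lambdas)
    coef_std = coefs[:, int(np.argmin(np.abs(lambdas - lam)))]
    coef = np.zeros(X.shape[1])
    coef[Xs_full.keep] = coef_std / sd_full
    intercept = float(y.mean() - mean_full @ (coef_std / sd_full))
    return intercept, coef, lam


def _prepare_training(matrix: MethylationMatrix, sheet: SampleSheet):
    """Align matrix columns to the sheet, drop probes with missing values."""
    m = matrix.subset_samples(sheet.sample_ids)
    X = m.values.T  # samples × probes
    complete = ~np.isnan(X).any(axis=0)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropping %d probe(s) with missing training betas", n_dropped)
    probes = [p for p, ok in zip(m.probe_ids, complete) if ok]
    return X[:, complete], probes


def fit_clock(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    transform: AgeTransformSpec,
    n_folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "1se",
) -> ClockModel:
    """Fit an elastic-net clock of transformed age on beta values."""
    n = len(sheet.sample_ids)
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples, got {n}")
    X, probes = _prepare_training(matrix, sheet)
    y = transform.forward(
        sheet.samples["age_years"].to_numpy(), sheet.samples["species"].tolist()
    )
    if np.ptp(y) == 0:
        raise ValueError("all-constant target age")
    rng = np.random.default_rng(seed)
    intercept, coef, lam = _elastic_net_fit(X, y, n_folds, rng, lambda_rule)
    nz = np.flatnonzero(coef)
    return ClockModel(
        intercept=intercept,
        coefficients={probes[j]: float(coef[j]) for j in nz},
        transform=transform,
        alpha=ALPHA,
        lambda_=lam,
        training_meta={
            "species": sorted(set(sheet.samples["species"])),
            "tissues": sorted(set(sheet.samples["tissue"])),
            "n_samples": n,
            "probe_universe": probes,
            "seed": seed,
            "lambda_rule": lambda_rule,
        },
    )


def predict_age(
    model: ClockModel, matrix: MethylationMatrix, sheet: SampleSheet
) -> np.ndarray:
    """Predict per-sample age: affine in betas, then inverse-transformed with
    each sample's species parameters.  Samples with a missing beta at a model
    probe come back NaN."""
    probes = sorted(model.coefficients)
    missing = set(probes) - set(matrix.probe_ids)
    if missing:
        raise KeyError(f"matrix lacks model probes: {sorted(missing)[:5]}")
    sub = matrix.subset_probes(probes).subset_samples(sheet.sample_ids)
    w = np.asarray([model.coefficients[p] for p in probes])
    lin = model.intercept + sub.values.T @ w if probes else np.full(
        len(sheet.sample_ids), model.intercept
    )
    bad = np.isnan(sub.values).any(axis=0) if probes else np.zeros(len(lin), bool)
    if bad.any():
        logger.warning("%d sample(s) with missing betas at model probes", int(bad.sum()))
    pred = model.transform.inverse(lin, sheet.samples["species"].tolist())
    pred = np.asarray(pred, dtype=float)
    pred[bad] = np.nan
    return pred


def evaluate_predictions(predicted, actual) -> ClockEvaluation:
    """Pearson R and median absolute error over complete pairs."""
    pred = np.asarray(predicted, dtype=float)
    act = np.asarray(actual, dtype=float)
    if pred.shape != act.shape:
        raise ValueError("predicted and actual must have equal length")
    ok = ~(np.isnan(pred) | np.isnan(act))
    pred, act = pred[ok], act[ok]
    if len(pred) < 2:
        raise ValueError("need at least 2 complete pairs")
    mae = float(np.median(np.abs(pred - act)))
    if np.ptp(pred) == 0 or np.ptp(act) == 0:
        return ClockEvaluation(0.0, mae, len(pred), degenerate=True)
    r = float(stats.pearsonr(pred, act)[0])
    return ClockEvaluation(r, mae, len(pred))


def loocv_evaluate(
    matrix: MethylationMatrix,
    sheet: SampleSheet,
    transform: AgeTransformSpec,
    n_folds: int = 10,
    seed: int = 0,
    target_scale: bool = False,
    lambda_rule: str = "1se",
) -> tuple[np.ndarray, ClockEvaluation]:
    """Leave-one-sample-out evaluation.

    Each held-out sample is predicted by a full :func:`fit_clock` (internal
    λ search included) on the other n − 1 samples; no information from the
    held-out sample enters fitting.  With ``target_scale=True`` predictions
    and actual ages are compared on the transformed scale (e.g. relative
    age); otherwise in years.

    Degenerate-fit rule: an iteration whose CV-selected model kept zero
    probes is a constant predictor — its prediction (the training-set mean,
    back-transformed) carries no methylation information and across
    iterations varies only through the one excluded target value, which is
    *anti*-correlated with the held-out age by construction.  Such
    iterations are excluded from the correlation, and when fewer than half
    of the iterations are informative the clock as a whole is declared
    degenerate (r reported as 0 with the flag): a predictor that usually has
    no features cannot support an out-of-sample correlation claim.  The
    returned predictions keep every iteration's value.
    """
    ids = sheet.sample_ids
    n = len(ids)
    if n < 10:
        raise ValueError("LOOCV needs at least 10 samples")
    rng = np.random.default_rng(seed)
    preds = np.full(n, np.nan)
    informative = np.zeros(n, dtype=bool)
    for i in range(n):
        rest = [s for j, s in enumerate(ids) if j != i]
        model = fit_clock(
            matrix, sheet.subset(rest), transform, n_folds=n_folds,
            seed=int(rng.integers(0, 2**31 - 1)), lambda_rule=lambda_rule,
        )
        preds[i] = predict_age(model, matrix, sheet.subset([ids[i]]))[0]
        informative[i] = model.n_nonzero > 0
    actual = sheet.samples["age_years"].to_numpy(dtype=float)
    species = sheet.samples["species"].tolist()
    if target_scale:
        pred_t = np.asarray(transform.forward(np.nan_to_num(preds), species), dtype=float)
        pred_t[np.isnan(preds)] = np.nan
        act_t = np.asarray(transform.forward(actual, species), dtype=float)
    else:
        pred_t, act_t = preds, actual
    ok = informative & ~np.isnan(pred_t)
    if ok.sum() < max(2, n // 2):
        mae = float(np.median(np.abs(pred_t[~np.isnan(pred_t)] - act_t[~np.isnan(pred_t)])))
        return preds, ClockEvaluation(0.0, mae, int(ok.sum()), degenerate=True)
    return preds, evaluate_predictions(pred_t[ok], act_t[ok])


# ---------------------------------------------------------------------------
# probe subsetting and dual-species clocks
# ---------------------------------------------------------------------------

def subset_mappable_probes(
    matrix: MethylationMatrix, annotation: ProbeAnnotation, species: set[str]
) -> MethylationMatrix:
    """Keep probes mappable to *every* requested species (order preserved)."""
    ann = annotation.indexed()
    missing = set(matrix.probe_ids) - set(ann.index)
    if missing:
        raise KeyError(f"unannotated probes in matrix: {sorted(missing)[:5]}")
    want = frozenset(species)
    keep = [p for p in matrix.probe_ids if want <= ann.at[p, "mappable_species"]]
    if not keep:
        raise ValueError(f"no probes mappable to all of {sorted(want)}")
    return matrix.subset_probes(keep)


def concat_datasets(
    datasets: list[tuple[MethylationMatrix, SampleSheet]]
) -> tuple[MethylationMatrix, SampleSheet]:
    """Concatenate per-species datasets on the intersection of their probes."""
    import pandas as pd

    common = list(datasets[0][0].probe_ids)
    for m, _ in datasets[1:]:
        have = set(m.probe_ids)
        common = [p for p in common if p in have]
    if not common:
        raise ValueError("datasets share no probes")
    mats = [m.subset_probes(common) for m, _ in datasets]
    values = np.concatenate([m.values for m in mats], axis=1)
    sample_ids = [s for m in mats for s in m.sample_ids]
    samples = pd.concat([sh.samples for _, sh in datasets], ignore_index=True)
    constants = (
        pd.concat([sh.species_constants for _, sh in datasets], ignore_index=True)
        .drop_duplicates(subset="species")
        .reset_index(drop=True)
    )
    matrix = MethylationMatrix(common, sample_ids, values)
    sheet = SampleSheet(samples, constants)
    return matrix, sheet


def fit_dual_species_clock(
    datasets: list[tuple[MethylationMatrix, SampleSheet]],
    mode: str = "relative",
    n_folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "1se",
) -> ClockModel:
    """Fit a clock on pooled samples from several species.

    ``mode='chronological'`` targets log-linear-transformed age with each
    species' own maturity; ``mode='relative'`` targets relative age.  A
    single-species input reduces exactly to :func:`fit_clock`.
    """
    if mode not in ("chronological", "relative"):
        raise ValueError(f"unknown mode {mode!r}")
    matrix, sheet = concat_datasets(datasets)
    kind = "loglinear" if mode == "chronological" else "relative"
    transform = AgeTransformSpec.from_sample_sheet(kind, sheet)
    return fit_clock(matrix, sheet, transform, n_folds=n_folds, seed=seed,
                     lambda_rule=lambda_rule)
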