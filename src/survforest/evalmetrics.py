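"""Prediction-error machinery: IPCW Brier score curves, integrated Brier
score, and the .632+ bootstrap cross-validated estimate.

The time-dependent Brier score on a test sample of size N is

    BS(t) = (1/N) sum_l [ S(t|x_l)^2 I(t_l <= t, d_l = 1) / G(t_l-)
                          + (1 - S(t|x_l))^2 I(t_l > t) / G(t) ]

with G the Kaplan-Meier estimate of the censoring survival function
(inverse probability of censoring weighting); subjects censored before t
contribute nothing. The integrated Brier score is the trapezoidal integral
of BS(t) over the evaluation grid divided by the grid span, so IBS is
unitless in [0, 1] and comparable across follow-up lengths; a coin-flip
predictor scores 0.25 and 0.5 is the conventional uselessness bound.

The .632+ bootstrap blends the apparent error with the bootstrap
out-of-bag error, guarded by the no-information error obtained by scoring
every prediction against every outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import SurvivalCurve, product_limit
from .datagen import SimDesign, SurvivalDataset, gen_dataset, resolve_design
from .rsf import default_eval_grid


def censoring_km(time, event) -> SurvivalCurve:
    """Kaplan-Meier estimate G(t) of the censoring survival function.

    Censorings play the role of events; at tied times censorings are taken
    to occur after events, so tied events remain in the censoring risk set.
    """
    return product_limit(time, event, reverse=True)


def brier_curve(
    surv: np.ndarray, time, event, grid, G: SurvivalCurve
) -> np.ndarray:
    """IPCW Brier score at every grid time.

    ``surv`` holds predicted survival probabilities, shape
    (n_subjects, len(grid)). Grid points where G vanishes are dropped from
    the weighting (their contributions are zeroed and a warning is issued).
    """
    surv = np.atleast_2d(np.asarray(surv, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    grid = np.asarray(grid, dtype=float)
    if surv.shape != (time.size, grid.size):
        raise ValueError("surv must have shape (n_subjects, len(grid))")
    g_tl_minus = G.left_limit(time)  # censoring survival just before t_l
    g_t = G(grid)
    if np.any(g_t <= 0):
        warnings.warn("censoring survival reaches 0 inside the grid; "
                      "contributions there are truncated")
    with np.errstate(divide="ignore", invalid="ignore"):
        w_event = np.where((event == 1) & (g_tl_minus > 0), 1.0 / g_tl_minus, 0.0)
    past_event = (time[:, None] <= grid[None, :]) & (event[:, None] == 1)
    still_at_risk = time[:, None] > grid[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        w_alive = np.where(g_t > 0, 1.0 / g_t, 0.0)
    contrib = (
        surv**2 * past_event * w_event[:, None]
        + (1.0 - surv) ** 2 * still_at_risk * w_alive[None, :]
    )
    return contrib.mean(axis=0)


def brier_score(surv_at_t, time, event, t: float, G: SurvivalCurve) -> float:
    """BS(t) at a single time point; ``surv_at_t`` is S(t|x_l) per subject."""
    surv_at_t = np.asarray(surv_at_t, dtype=float)
    return float(
        brier_curve(surv_at_t[:, None], time, event, np.array([t]), G)[0]
    )


def integrated_brier(bs_curve, grid) -> float:
    """Span-normalized trapezoidal integral of BS(t) over the grid."""
    bs_curve = np.asarray(bs_curve, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("integration grid needs at least two points")
    span = grid[-1] - grid[0]
    return float(np.trapezoid(bs_curve, grid) / span)


# ---------------------------------------------------------------------------
# model adapters


class ForestModel:
    """fit/predict adapter for the three forest models (rsf1, rsf2, cif)."""

    def __init__(self, name: str, n_trees: int = 100, **hyper):
        if name not in ("rsf1", "rsf2", "cif"):
            raise ValueError(f"unknown model {name!r}")
        self.name = name
        self.n_trees = n_trees
        self.hyper = hyper

    def fit(self, data: SurvivalDataset, seed: int = 0) -> "FittedForest":
        if self.name == "cif":
            from .cif import fit_cif

            forest = fit_cif(data, n_trees=self.n_trees, seed=seed, **self.hyper)
        else:
            from .rsf import MODEL_RULES, fit_rsf

            forest = fit_rsf(
                data,
                rule=MODEL_RULES[self.name],
                n_trees=self.n_trees,
                seed=seed,
                **self.hyper,
            )
        return FittedForest(forest)


class FittedForest:
    def __init__(self, forest):
        self.forest = forest

    def predict(self, X: pd.DataFrame, grid: np.ndarray) -> np.ndarray:
        from .rsf import predict_survival

        return predict_survival(self.forest, X, grid)


class MarginalKM:
    """Covariate-free reference model: the pooled Kaplan-Meier curve."""

    name = "km"

    def fit(self, data: SurvivalDataset, seed: int = 0) -> "_FittedKM":
        from .survtree import kaplan_meier

        return _FittedKM(kaplan_meier(data.time, data.event))


class _FittedKM:
    def __init__(self, curve: SurvivalCurve):
        self.curve = curve

    def predict(self, X: pd.DataFrame, grid: np.ndarray) -> np.ndarray:
        return np.tile(self.curve(grid), (len(X), 1))


def make_model(name: str, n_trees: int = 100, **hyper):
    if name == "km":
        return MarginalKM()
    return ForestModel(name, n_trees=n_trees, **hyper)


# ---------------------------------------------------------------------------
# .632+ bootstrap cross-validation


@dataclass
class PredErrorReport:
    model_id: str
    grid: np.ndarray
    bs_curve: np.ndarray  # the .632+ (or apparent) BS(t) curve
    ibs: float
    estimator: str  # "apparent" | "boot632plus"
    B: int
    n_test: int
    seed: int
    apparent_ibs: float = np.nan
    noinf_ibs: float = np.nan
    details: dict = field(default_factory=dict)


def _noinf_curve(
    surv: np.ndarray, time, event, grid, G: SurvivalCurve
) -> np.ndarray:
    """No-information Brier curve: every prediction vs every outcome.

    The double sum factorizes into (mean over predictions) x (mean over
    outcome-weight terms) per grid point.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    grid = np.asarray(grid, dtype=float)
    g_tl_minus = G.left_limit(time)
    g_t = G(grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_event = np.where((event == 1) & (g_tl_minus > 0), 1.0 / g_tl_minus, 0.0)
        w_alive = np.where(g_t > 0, 1.0 / g_t, 0.0)
    past_event = (time[:, None] <= grid[None, :]) & (event[:, None] == 1)
    still_at_risk = time[:, None] > grid[None, :]
    mean_s2 = np.mean(surv**2, axis=0)
    mean_1ms2 = np.mean((1.0 - surv) ** 2, axis=0)
    term_event = np.mean(past_event * w_event[:, None], axis=0)
    term_alive = np.mean(still_at_risk, axis=0) * w_alive
    return mean_s2 * term_event + mean_1ms2 * term_alive


def boot632plus(
    models: dict[str, object],
    data: SurvivalDataset,
    B: int = 5,
    eval_grid=None,
    seed: int = 0,
    max_redraws: int = 50,
) -> dict[str, PredErrorReport]:
    """Boot632+ cross-validated prediction error for each model.

    For each of B bootstrap samples every model is refit on the in-bag
    subjects and scored on the out-of-bag subjects; the .632+ estimate
    combines the averaged out-of-bag curve with the apparent and
    no-information curves pointwise, with the relative overfitting rate R
    clipped to [0, 1]. Bootstrap samples whose out-of-bag part has no event
    are redrawn (and logged via a warning).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    G = censoring_km(data.time, data.event)
    if eval_grid is None:
        eval_grid = default_eval_grid(data)
        eval_grid = eval_grid[G(eval_grid) > 0]
    grid = np.asarray(eval_grid, dtype=float)
    if grid.size < 2:
        raise ValueError("evaluation grid needs at least two points")
    ss = np.random.SeedSequence(seed)
    boot_rng = np.random.default_rng(ss.spawn(1)[0])
    fit_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(B + 1)]

    # bootstrap index sets, redrawn until the OOB part carries events
    idx_sets = []
    n = data.n
    while len(idx_sets) < B:
        for _ in range(max_redraws):
            idx = np.sort(boot_rng.integers(0, n, size=n))
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size and data.event[oob].sum() > 0 and data.event[idx].sum() > 0:
                idx_sets.append((idx, oob))
                break
        else:
            raise RuntimeError("could not draw a bootstrap sample with OOB events")

    reports: dict[str, PredErrorReport] = {}
    for m_i, (name, model) in enumerate(models.items()):
        fitted_full = model.fit(data, seed=fit_seeds[0] + m_i)
        surv_app = np.clip(fitted_full.predict(data.covariates, grid), 0.0, 1.0)
        err_app = brier_curve(surv_app, data.time, data.event, grid, G)
        err_noinf = _noinf_curve(surv_app, data.time, data.event, grid, G)
        boot_curves = []
        for b, (idx, oob) in enumerate(idx_sets):
            train = SurvivalDataset(
                data.time[idx],
                data.event[idx],
                data.covariates.iloc[idx].reset_index(drop=True),
                dict(data.kinds),
            )
            fitted = model.fit(train, seed=fit_seeds[b + 1] + m_i)
            surv_oob = np.clip(
                fitted.predict(data.covariates.iloc[oob], grid), 0.0, 1.0
            )
            boot_curves.append(
                brier_curve(surv_oob, data.time[oob], data.event[oob], grid, G)
            )
        err_boot = np.mean(boot_curves, axis=0)
        err_boot_prime = np.minimum(err_boot, err_noinf)
        denom = err_noinf - err_app
        with np.errstate(divide="ignore", invalid="ignore"):
            R = np.where(
                (denom > 0) & (err_boot_prime > err_app),
                (err_boot_prime - err_app) / denom,
                0.0,
            )
        R = np.clip(R, 0.0, 1.0)
        w = 0.632 / (1.0 - 0.368 * R)
        err632 = (1.0 - w) * err_app + w * err_boot_prime
        reports[name] = PredErrorReport(
            model_id=name,
            grid=grid,
            bs_curve=err632,
            ibs=integrated_brier(err632, grid),
            estimator="boot632plus",
            B=B,
            n_test=n,
            seed=seed,
            apparent_ibs=integrated_brier(err_app, grid),
            noinf_ibs=integrated_brier(err_noinf, grid),
            details=dict(err_boot_ibs=integrated_brier(err_boot, grid)),
        )
    return reports


def benchmark_repetitions(
    designs: list[SimDesign],
    models: dict[str, object],
    n_reps: int = 10,
    B: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format benchmark: one Boot632+ IBS per (design, model, repetition).

    Each repetition simulates a fresh dataset from the design with a seed
    derived from (base seed, design index, repetition), so rows are
    reproducible in isolation and order-independent.
    """
    rows = []
    for d_i, design in enumerate(designs):
        design = resolve_design(design)
        for rep in range(n_reps):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(d_i, rep))
            data_seed, eval_seed = [
                int(s % (2**31)) for s in ss.generate_state(2)
            ]
            dataset = gen_dataset(design, data_seed)
            try:
                reports = boot632plus(models, dataset, B=B, seed=eval_seed)
            except Exception as exc:  # keep the run going, record the failure
                warnings.warn(
                    f"repetition failed for {design.design_id} rep {rep}: {exc}"
                )
                continue
            for name, rep_out in reports.items():
                rows.append(
                    dict(
                        design=design.design_id,
                        model=name,
                        rep=rep,
                        ibs=rep_out.ibs,
                        estimator=rep_out.estimator,
                        B=B,
                        seed=data_seed,
                    )
                )
    return pd.DataFrame(
        rows, columns=["design", "model", "rep", "ibs", "estimator", "B", "seed"]
    )
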