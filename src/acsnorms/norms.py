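"""Demographic regression norming: model fitting and norm-score computation.

Standardized (mean 0, SD 1) scores from the reference sample are regressed
on centered age, centered-age squared, gender (0=female, 1=male) and binary
education (0=high, 1=low/medium), entered blockwise.  Predictors that are
not significant (p > .05) are removed and the model refit once; the
surviving coefficients, residual SD, R², and the transform reference
constants are frozen into a :class:`~acsnorms.data_model.NormModel`.

Scoring a new individual then works entirely from frozen constants:

1. ``z_actual``   = standardize(transform(raw))  — the individual's
   standardized, direction-aligned score;
2. ``z_predicted`` = constant + sum(beta_j x_j)  — the demographically
   expected score, with age centered at the reference-sample mean frozen
   at fit time;
3. ``norm``       = (z_actual - z_predicted) / sd_residual — the
   demographically corrected norm score.  Performance below demographic
   expectation yields a negative norm score.

Worked example for the packaged Connect the Dots I model (age centered at
49.19): a woman aged 55 has predicted score
``-.149 + (55-49.19)(-.042) + 0(.401) = -.39``; a raw completion time of
60 s standardizes to ``(1/60 - .0304)/.00793 = -1.73``; the norm score is
``(-1.73 - (-.39))/.819 = -1.64`` (chaining the two-decimal intermediates;
full precision gives -1.63).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .data_model import (
    COMPOSITE_MEASURE,
    Demographics,
    Direction,
    InsufficientDataError,
    MeasureSpec,
    ModelFitError,
    NormModel,
    ScoreTable,
    Transform,
    ValidationError,
)
from . import scaling

logger = logging.getLogger("acsnorms")

#: Reference-sample mean age the packaged ACS models center age on (years).
ACS_AGE_CENTER = 49.19

__all__ = [
    "FitConfig", "FitDiagnostics", "PredictorStats", "NormScoreResult",
    "fit_norm_model", "fit_norm_models", "predicted_score", "norm_score",
    "score_battery", "default_acs_norm_models", "ACS_AGE_CENTER",
]


@dataclass(frozen=True)
class FitConfig:
    """Configuration for norm-model fitting.

    ``predictors`` are entered blockwise in order; ``alpha_prune`` is the
    significance level below which a predictor survives pruning.  With
    ``iterative_prune`` the least significant predictor is removed one at
    a time until all survivors have p <= alpha (default is a single prune
    pass followed by one refit).  ``extra_covariates`` names continuous
    covariates looked up in ``Demographics.covariates``.
    """

    predictors: tuple[str, ...] = ("age", "age_squared", "gender", "education")
    alpha_prune: float = 0.05
    center_age: bool = True
    extra_covariates: tuple[str, ...] = ()
    iterative_prune: bool = False
    vif_limit: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_prune < 1:
            raise ValidationError("alpha_prune must be in (0, 1)")


@dataclass(frozen=True)
class PredictorStats:
    name: str
    beta: float
    se_beta: float
    standardized_beta: float
    t: float
    p: float
    vif: float


@dataclass
class FitDiagnostics:
    """Per-predictor statistics and model-level diagnostics of a fit."""

    predictors: list[PredictorStats]
    r_squared: float
    sd_residual: float
    n: int
    heteroscedasticity_suspect: bool
    nonnormal_residuals_suspect: bool
    pruned: list[str] = field(default_factory=list)


def _design_matrix(demographics: Sequence[Demographics], predictors: Sequence[str],
                   age_center: float) -> pd.DataFrame:
    cols: dict[str, list[float]] = {name: [] for name in predictors}
    for d in demographics:
        for name in predictors:
            if name == "age":
                cols[name].append(d.age - age_center)
            elif name == "age_squared":
                cols[name].append((d.age - age_center) ** 2)
            elif name == "gender":
                cols[name].append(float(d.gender))
            elif name == "education":
                if d.education_binary is None:
                    raise ValidationError(
                        f"participant {d.participant_id}: education required "
                        f"by the model but not provided")
                cols[name].append(float(d.education_binary))
            else:
                if name not in d.covariates:
                    raise ValidationError(
                        f"participant {d.participant_id}: covariate "
                        f"{name!r} required by the model but not provided")
                cols[name].append(d.covariates[name])
    return pd.DataFrame(cols, index=[d.participant_id for d in demographics])


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def _vifs(X: pd.DataFrame) -> dict[str, float]:
    if X.shape[1] < 2:
        return {name: 1.0 for name in X.columns}
    Xc = sm.add_constant(X, has_constant="add")
    return {name: float(variance_inflation_factor(Xc.to_numpy(),
                                                  list(Xc.columns).index(name)))
            for name in X.columns}


def fit_norm_model(
    measure: str,
    z_scores: Mapping[str, float] | pd.Series,
    demographics: Sequence[Demographics],
    config: FitConfig = FitConfig(),
    spec: MeasureSpec | None = None,
    ref_mean_transformed: float | None = None,
    ref_sd_transformed: float | None = None,
) -> tuple[NormModel, FitDiagnostics]:
    """Fit (and prune) the demographic regression for one measure.

    ``z_scores`` maps participant id -> standardized score; participants
    without demographics (or vice versa) are dropped.  Returns the frozen
    :class:`NormModel` (with the supplied transform reference constants)
    and fit diagnostics.  Raises :class:`ModelFitError` on degenerate
    scores or retained VIFs above ``config.vif_limit``.
    """
    z = pd.Series(dict(z_scores) if not isinstance(z_scores, pd.Series)
                  else z_scores, dtype=float)
    demo = [d for d in demographics if d.participant_id in z.index]
    z = z.loc[[d.participant_id for d in demo]]
    n = len(z)
    predictors = tuple(config.predictors) + tuple(config.extra_covariates)
    if n < 10 * len(predictors):
        raise InsufficientDataError(
            f"{measure}: need >= 10 participants per candidate predictor "
            f"({10 * len(predictors)}), got {n}")
    if float(z.std(ddof=1)) == 0.0:
        raise ModelFitError(f"{measure}: constant z-scores, degenerate fit")

    ages = np.array([d.age for d in demo])
    age_center = float(ages.mean()) if config.center_age else 0.0
    y = z.to_numpy()

    X = _design_matrix(demo, predictors, age_center)
    result = _ols(y, X)

    # prune nonsignificant predictors and refit on the survivors
    pruned: list[str] = []
    if config.iterative_prune:
        while X.shape[1] > 0:
            pvals = result.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] <= config.alpha_prune:
                break
            pruned.append(worst)
            X = X.drop(columns=[worst])
            result = _ols(y, X)
    else:
        pvals = result.pvalues.drop("const")
        drop = [name for name in X.columns if pvals[name] > config.alpha_prune]
        if drop:
            pruned.extend(drop)
            X = X.drop(columns=drop)
            result = _ols(y, X)

    vifs = _vifs(X)
    too_collinear = [name for name, v in vifs.items() if v > config.vif_limit]
    if too_collinear:
        raise ModelFitError(
            f"{measure}: variance inflation factors exceed "
            f"{config.vif_limit} for predictors {too_collinear}")

    sd_y = float(np.std(y, ddof=1))
    pred_stats = []
    for name in X.columns:
        beta = float(result.params[name])
        sd_x = float(X[name].std(ddof=1))
        pred_stats.append(PredictorStats(
            name=name,
            beta=beta,
            se_beta=float(result.bse[name]),
            standardized_beta=beta * sd_x / sd_y,
            t=float(result.tvalues[name]),
            p=float(result.pvalues[name]),
            vif=vifs[name],
        ))

    sd_residual = float(np.sqrt(result.mse_resid))
    resid = np.asarray(result.resid)
    if X.shape[1] > 0:
        _, bp_p, _, _ = het_breuschpagan(resid, sm.add_constant(X, has_constant="add"))
        hetero = bool(bp_p < 0.05)
    else:
        hetero = False
    nonnormal = bool(stats.shapiro(resid).pvalue < 0.05) if n <= 5000 else \
        bool(stats.normaltest(resid).pvalue < 0.05)

    diagnostics = FitDiagnostics(
        predictors=pred_stats,
        r_squared=float(result.rsquared) if X.shape[1] else 0.0,
        sd_residual=sd_residual,
        n=n,
        heteroscedasticity_suspect=hetero,
        nonnormal_residuals_suspect=nonnormal,
        pruned=pruned,
    )
    coefficients = {"constant": float(result.params["const"])}
    coefficients.update({name: float(result.params[name]) for name in X.columns})
    model = NormModel(
        measure=measure,
        direction=spec.direction if spec else Direction.HIGHER_IS_BETTER,
        transform=spec.transform if spec else Transform.NONE,
        age_center=age_center,
        coefficients=coefficients,
        sd_residual=sd_residual,
        r_squared=diagnostics.r_squared,
        n_reference=n,
        ref_mean_transformed=ref_mean_transformed,
        ref_sd_transformed=ref_sd_transformed,
    )
    return model, diagnostics


def fit_norm_models(
    table: ScoreTable,
    demographics: Sequence[Demographics],
    battery: Sequence[MeasureSpec],
    config: FitConfig = FitConfig(),
    include_composite: bool = True,
) -> tuple[dict[str, NormModel], dict[str, FitDiagnostics]]:
    """Standardize a cleaned reference table and fit one norm model per
    measure (occasion-1 data), plus the composite total-score model.

    Reference transform constants are estimated from the occasion-1
    non-excluded scores and frozen into each model; the composite model
    gets identity constants (its input is already a mean of z-scores).
    """
    constants = scaling.reference_constants(table, battery)
    ztable = scaling.standardized_table(table, battery, constants)
    occ1 = ztable[ztable["occasion"] == 1]
    models: dict[str, NormModel] = {}
    diags: dict[str, FitDiagnostics] = {}
    for spec in battery:
        if spec.name == COMPOSITE_MEASURE or spec.name not in constants:
            continue
        z = occ1[occ1["measure"] == spec.name].set_index("participant_id")["z"]
        mean, sd = constants[spec.name]
        try:
            models[spec.name], diags[spec.name] = fit_norm_model(
                spec.name, z, demographics, config, spec=spec,
                ref_mean_transformed=mean, ref_sd_transformed=sd)
        except (InsufficientDataError, ModelFitError) as exc:
            logger.warning("skipping %s: %s", spec.name, exc)
    if include_composite:
        comp = scaling.composite_by_occasion(occ1, battery)
        z = comp.set_index("participant_id")["z"]
        comp_spec = next((m for m in battery if m.name == COMPOSITE_MEASURE), None)
        if len(z) >= 10 * (len(config.predictors) + len(config.extra_covariates)):
            models[COMPOSITE_MEASURE], diags[COMPOSITE_MEASURE] = fit_norm_model(
                COMPOSITE_MEASURE, z, demographics, config, spec=comp_spec,
                ref_mean_transformed=0.0, ref_sd_transformed=1.0)
        else:
            logger.warning("composite model skipped: too few complete cases")
    return models, diags


def predicted_score(model: NormModel, demo: Demographics) -> float:
    """Demographically expected standardized score under a norm model.

    ``constant + sum(beta_j x_j)`` with age entered as ``age - age_center``
    and age_squared as its square; absent (pruned) coefficients contribute
    nothing.  Raises :class:`ValidationError` when the model references a
    demographic field the individual lacks.
    """
    value = model.coefficients["constant"]
    age_c = demo.age - model.age_center
    for name, beta in model.coefficients.items():
        if name == "constant":
            continue
        if name == "age":
            x = age_c
        elif name == "age_squared":
            x = age_c ** 2
        elif name == "gender":
            x = float(demo.gender)
        elif name == "education":
            if demo.education_binary is None:
                raise ValidationError(
                    f"{model.measure}: model requires education but "
                    f"participant {demo.participant_id} has none")
            x = float(demo.education_binary)
        else:
            if name not in demo.covariates:
                raise ValidationError(
                    f"{model.measure}: model requires covariate {name!r} "
                    f"missing for participant {demo.participant_id}")
            x = demo.covariates[name]
        value += beta * x
    return float(value)


@dataclass(frozen=True)
class NormScoreResult:
    measure: str
    z_actual: float
    z_predicted: float
    norm: float

    def __iter__(self):
        return iter((self.z_actual, self.z_predicted, self.norm))


def norm_score(model: NormModel, raw_score: float,
               demo: Demographics,
               spec: MeasureSpec | None = None) -> NormScoreResult:
    """Demographically corrected norm score for one raw observation.

    ``norm = (z_actual - z_predicted) / sd_residual``: below-expectation
    performance is negative.  Requires the model's transform reference
    constants; raises :class:`ValidationError` when they are unavailable.
    """
    if not model.has_reference_constants:
        raise ValidationError(
            f"{model.measure}: transform reference constants unavailable; "
            f"fit models on your own reference data to norm raw scores")
    if spec is None:
        spec = MeasureSpec(model.measure, model.direction, model.transform)
    z_actual = scaling.standardize(scaling.transform_raw(raw_score, spec),
                                   model.ref_mean_transformed,
                                   model.ref_sd_transformed)
    z_pred = predicted_score(model, demo)
    return NormScoreResult(model.measure, z_actual, z_pred,
                           (z_actual - z_pred) / model.sd_residual)


def score_battery(
    models: Mapping[str, NormModel],
    scores: Mapping[str, float],
    demo: Demographics,
    battery: Sequence[MeasureSpec] | None = None,
) -> tuple[dict[str, NormScoreResult], list[str]]:
    """Norm-score every supplied measure and, when possible, the composite.

    Returns ``(results, unscored)`` where ``unscored`` lists measures
    lacking a model (or usable reference constants).  The composite norm
    is computed by averaging the per-measure ``z_actual`` of the nine
    composite measures (complete cases only) and applying the total-score
    model to that composite z.
    """
    from .data_model import default_acs_battery
    battery = list(battery) if battery is not None else default_acs_battery()
    by_name = {m.name: m for m in battery}
    results: dict[str, NormScoreResult] = {}
    unscored: list[str] = []
    for measure, raw in scores.items():
        model = models.get(measure)
        if model is None or not model.has_reference_constants:
            unscored.append(measure)
            continue
        results[measure] = norm_score(model, raw, demo,
                                      spec=by_name.get(measure))
    comp_z = scaling.composite_score(
        {m: r.z_actual for m, r in results.items()}, battery)
    total_model = models.get(COMPOSITE_MEASURE)
    if comp_z is not None and total_model is not None:
        z_pred = predicted_score(total_model, demo)
        results[COMPOSITE_MEASURE] = NormScoreResult(
            COMPOSITE_MEASURE, comp_z, z_pred,
            (comp_z - z_pred) / total_model.sd_residual)
    return results, unscored


# ---------------------------------------------------------------------------
# packaged ACS models
# ---------------------------------------------------------------------------

def default_acs_norm_models() -> dict[str, NormModel]:
    """The published ACS demographic regression models.

    Coefficients, residual SDs and R² are the published reference-sample
    estimates (n=248; Place the Beads n=421 from its separate reference
    sample); age is centered at 49.19 years.  Transform reference constants
    are published only for Connect the Dots I (0.0304, 0.00793); the
    composite model carries identity constants because its input is
    already a mean of z-scores.  All other measures have no published
    constants and can therefore be used for prediction but not for
    norm-scoring raw values.
    """
    H, L = Direction.HIGHER_IS_BETTER, Direction.LOWER_IS_BETTER
    T = Transform

    def model(measure, direction, transform, coeffs, sd_resid, r2, n,
              ref=None):
        return NormModel(
            measure=measure, direction=direction, transform=transform,
            age_center=ACS_AGE_CENTER, coefficients=coeffs,
            sd_residual=sd_resid, r_squared=r2, n_reference=n,
            ref_mean_transformed=None if ref is None else ref[0],
            ref_sd_transformed=None if ref is None else ref[1],
        )

    models = [
        model("ConnectTheDotsI", L, T.INVERSE,
              {"constant": -0.149, "age": -0.042, "gender": 0.401},
              0.819, 0.324, 248, ref=(0.0304, 0.00793)),
        model("ConnectTheDotsII", L, T.LOG10,
              {"constant": 0.101, "age": -0.045, "age_squared": -0.001},
              0.815, 0.330, 248),
        model("WordlistLearning", H, T.NONE,
              {"constant": -0.001, "age": -0.027},
              0.938, 0.116, 248),
        model("WordlistDelayedRecall", H, T.NONE,
              {"constant": 0.102, "age": -0.018, "gender": -0.282},
              0.961, 0.068, 248),
        model("ReactionSpeed", L, T.INVERSE,
              {"constant": -0.106, "age": -0.019, "gender": 0.272},
              0.962, 0.067, 248),
        model("PlaceTheBeads", L, T.SQRT,
              {"constant": 0.109, "age": -0.014, "education": -0.226},
              0.968, 0.058, 421),
        model("BoxTapping", H, T.NONE,
              {"constant": -0.145, "age": -0.023, "gender": 0.372},
              0.939, 0.110, 248),
        model("FillTheGrid", L, T.INVERSE,
              {"constant": -0.144, "age": -0.040, "gender": 0.358},
              0.852, 0.267, 248),
        model("DigitSequencesI", H, T.NONE,
              {"constant": 0.103, "age": -0.010, "education": -0.350},
              0.978, 0.036, 248),
        model("DigitSequencesII", H, T.NONE,
              {"constant": 0.100, "age": -0.015, "education": -0.357},
              0.966, 0.060, 248),
        model(COMPOSITE_MEASURE, H, T.NONE,
              {"constant": 0.068, "age": -0.025, "age_squared": 0.000,
               "gender": 0.120, "education": -0.129},
              0.420, 0.351, 206, ref=(0.0, 1.0)),
    ]
    return {m.measure: m for m in models}
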