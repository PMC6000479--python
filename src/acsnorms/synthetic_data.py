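"""Synthetic two-occasion cohort generator.

Emulates the reference-data study conditions the pipeline is built for:
a cohort (default n=248, ages ~N(49.2, 13) truncated to 18-81, 63.3%
female, 71% high education) assessed twice on the ACS battery, with

* linear demographic fixed effects on the standardized scale taken from
  the published regression models,
* a stable person-level residual plus independent occasion noise, with
  the variance split solved so the population absolute-agreement ICC
  (including the systematic practice-shift component) hits a target,
* an occasion-2 practice shift specified in raw units and mapped onto the
  standardized scale through the measure's transform,
* optional injected outliers (for time-based measures) and zero scores
  (for count-based measures), recorded in ground truth.

Standardized latent scores are mapped to raw scores by inverting the
measure's transform against reference constants.  Published
transformed-scale constants exist only for Connect the Dots I; the default
constants for all other measures are synthetic (delta-method values derived
from published raw-score means/SDs) and are only meant to give raw scores
a realistic scale.

Generation is fully determined by the seed: the ground-truth record
(latent components, injected outliers and zeros, variance splits) lets
tests verify recovery exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    COMPOSITE_MEASURE,
    Demographics,
    FeasibilityError,
    MeasureSpec,
    NormModel,
    ScoreTable,
    Transform,
    ValidationError,
    default_acs_battery,
)
from .cleaning import OutlierConfig, age_group_index
from .norms import default_acs_norm_models, predicted_score
from .reliability import acs_reference_reliability
from . import scaling

logger = logging.getLogger("acsnorms")

__all__ = [
    "SimulationConfig", "SyntheticCohort", "default_generating_models",
    "default_simulation_config", "simulate_demographics", "simulate_scores",
    "simulate_cohort", "practice_shift_z",
]

#: Synthetic transformed-scale reference constants (mean, SD) for measures
#: whose real constants are unpublished; delta-method values derived from
#: published raw-score means/SDs.  Connect the Dots I uses the published
#: constants.
SYNTHETIC_REFERENCE_CONSTANTS: dict[str, tuple[float, float]] = {
    "ConnectTheDotsI": (0.0304, 0.00793),          # published
    "ConnectTheDotsII": (-1.763802, 0.138026),     # -log10(s)
    "WordlistLearning": (52.02, 10.13),
    "WordlistDelayedRecall": (11.15, 2.71),
    "WordlistRecognition": (44.17, 1.57),
    "ReactionSpeed": (0.0032375, 0.00046715),      # 1/ms
    "PlaceTheBeads": (-5.062608, 1.385702),        # -sqrt(moves)
    "BoxTapping": (9.17, 2.26),
    "FillTheGrid": (0.0159770, 0.00323927),        # 1/s
    "DigitSequencesI": (10.40, 2.22),
    "DigitSequencesII": (8.50, 2.72),
}


def default_generating_models() -> dict[str, NormModel]:
    """Published regression models with reference constants filled in
    (synthetic where unpublished) so every measure can generate raw scores."""
    models = {}
    for name, model in default_acs_norm_models().items():
        if name == COMPOSITE_MEASURE:
            continue
        mean, sd = SYNTHETIC_REFERENCE_CONSTANTS[name]
        models[name] = model.replace(ref_mean_transformed=mean,
                                     ref_sd_transformed=sd)
    # Wordlist Recognition has no published regression model (ceiling
    # effect); generate it as age-insensitive noise around its raw mean.
    mean, sd = SYNTHETIC_REFERENCE_CONSTANTS["WordlistRecognition"]
    models["WordlistRecognition"] = NormModel(
        measure="WordlistRecognition",
        direction="higher_is_better", transform="none",
        age_center=49.19, coefficients={"constant": 0.0},
        sd_residual=1.0, r_squared=0.0, n_reference=248,
        ref_mean_transformed=mean, ref_sd_transformed=sd)
    return models


@dataclass
class SimulationConfig:
    """Study conditions for cohort generation.

    Defaults reproduce the reference-sample conditions: demographic mix,
    published generating models, published occasion-2 mean shifts
    (``practice_shift``, raw units, occasion2 - occasion1) and published
    test-retest ICCs as calibration targets.  ``outlier_rate`` /
    ``zero_score_rate`` inject contamination for cleaning tests;
    injected outliers sit ``outlier_displacement`` scaled MADs above the
    group median (default 5, beyond the 3.5 scaled-MAD exclusion limit).
    """

    n_participants: int = 248
    age_mean: float = 49.2
    age_sd: float = 13.0
    age_range: tuple[float, float] = (18.0, 81.0)
    p_female: float = 0.633
    p_high_education: float = 0.71
    models: dict[str, NormModel] = field(default_factory=default_generating_models)
    practice_shift: dict[str, float] = field(default_factory=dict)
    target_icc: dict[str, float] = field(default_factory=dict)
    outlier_rate: float = 0.0
    zero_score_rate: float = 0.0
    outlier_displacement: float = 5.0
    outlier_config: OutlierConfig = field(default_factory=OutlierConfig)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValidationError("n_participants must be >= 2")
        lo, hi = self.age_range
        if lo >= hi:
            raise ValidationError("age_range must satisfy lo < hi")
        for p, name in ((self.p_female, "p_female"),
                        (self.p_high_education, "p_high_education"),
                        (self.outlier_rate, "outlier_rate"),
                        (self.zero_score_rate, "zero_score_rate")):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        for m, t in self.target_icc.items():
            if not 0.0 < t <= 1.0:
                raise ValidationError(f"target ICC for {m} must be in (0, 1]")


def default_simulation_config(**overrides) -> SimulationConfig:
    """Study-condition defaults: published ICC targets and practice shifts."""
    summaries = acs_reference_reliability()
    shifts = {m: s.mean2 - s.mean1 for m, s in summaries.items()
              if m != COMPOSITE_MEASURE}
    iccs = {m: s.icc for m, s in summaries.items() if m != COMPOSITE_MEASURE}
    config = SimulationConfig(practice_shift=shifts, target_icc=iccs,
                              **overrides)
    return config


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth that produced it."""

    demographics: list[Demographics]
    scores: ScoreTable
    latent: pd.DataFrame  # participant_id, measure, mu, person, z1, z2
    injected_outliers: list[tuple[str, int, str]]
    injected_zeros: list[tuple[str, int, str]]
    variance_split: dict[str, dict[str, float]]

    def ground_truth(self) -> dict:
        return {
            "injected_outliers": [list(x) for x in self.injected_outliers],
            "injected_zeros": [list(x) for x in self.injected_zeros],
            "variance_split": self.variance_split,
        }


def simulate_demographics(config: SimulationConfig,
                          rng: np.random.Generator) -> list[Demographics]:
    """Draw a demographic cohort: truncated-normal ages, Bernoulli gender
    (0=female) and education (0=high), Verhage levels consistent with the
    binary education code."""
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    ages = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                               size=config.n_participants, random_state=rng)
    genders = (rng.random(config.n_participants) >= config.p_female).astype(int)
    high_edu = rng.random(config.n_participants) < config.p_high_education
    width = len(str(config.n_participants))
    out = []
    for i in range(config.n_participants):
        verhage = int(rng.choice([6, 7]) if high_edu[i]
                      else rng.choice([3, 4, 5]))
        out.append(Demographics(
            participant_id=f"P{i + 1:0{width}d}",
            age=float(ages[i]),
            gender=int(genders[i]),
            verhage=verhage,
        ))
    return out


def practice_shift_z(model: NormModel, spec: MeasureSpec,
                     shift_raw: float) -> float:
    """Map a raw-units occasion-2 mean shift onto the standardized scale,
    evaluating the transform at the reference mean raw score."""
    if shift_raw == 0.0:
        return 0.0
    raw_ref = scaling.untransform(model.ref_mean_transformed, spec)
    t_shifted = scaling.transform_raw(raw_ref + shift_raw, spec)
    return (t_shifted - model.ref_mean_transformed) / model.ref_sd_transformed


def _solve_variance_split(measure: str, sigma_f2: float, target_icc: float,
                          d_z: float) -> tuple[float, float]:
    """Person-residual and occasion-noise variances hitting the target
    population ICC(A,1) with unit occasion-1 variance.

    Between-person variance B and occasion noise E satisfy B + E = 1 and
    ICC = B / (1 + d_z^2/2); the fixed-effect share sigma_f2 is part of B.
    Raises :class:`FeasibilityError` with the feasible ICC band when no
    nonnegative split exists.
    """
    theta = d_z ** 2 / 2.0
    B = target_icc * (1.0 + theta)
    icc_min = sigma_f2 / (1.0 + theta)
    icc_max = 1.0 / (1.0 + theta)
    if B > 1.0 + 1e-12 or B < sigma_f2 - 1e-12:
        raise FeasibilityError(
            f"{measure}: target ICC {target_icc} infeasible with practice "
            f"shift (z-scale {d_z:.3f}) and fixed-effect variance "
            f"{sigma_f2:.3f}; feasible ICC range is "
            f"[{icc_min:.3f}, {icc_max:.3f}]")
    sigma_p2 = min(max(B - sigma_f2, 0.0), 1.0)
    sigma_e2 = max(1.0 - B, 0.0)
    return sigma_p2, sigma_e2


def simulate_scores(demographics: Sequence[Demographics],
                    config: SimulationConfig,
                    rng: np.random.Generator) -> SyntheticCohort:
    """Generate raw two-occasion scores for a demographic cohort.

    Latent standardized scores are ``mu_i + p_i + e_ij`` (+ the practice
    shift at occasion 2); draws whose transformed value falls outside the
    transform's domain are redrawn.  Raw scores are obtained by inverting
    the transform against the model's reference constants.
    """
    battery = {m.name: m for m in default_acs_battery()}
    n = len(demographics)
    pids = [d.participant_id for d in demographics]
    rows: list[dict] = []
    latent_rows: list[dict] = []
    split: dict[str, dict[str, float]] = {}
    outliers: list[tuple[str, int, str]] = []
    zeros: list[tuple[str, int, str]] = []

    for measure, model in config.models.items():
        spec = battery.get(measure)
        if spec is None:
            spec = MeasureSpec(measure, model.direction, model.transform)
        if not model.has_reference_constants:
            raise ValidationError(f"{measure}: generating model needs "
                                  f"reference constants")
        mu = np.array([predicted_score(model, d) for d in demographics])
        sigma_f2 = float(mu.var())
        target = config.target_icc.get(measure, 1.0)
        shift_raw = config.practice_shift.get(measure, 0.0)
        d_z = practice_shift_z(model, spec, shift_raw)
        sigma_p2, sigma_e2 = _solve_variance_split(measure, sigma_f2,
                                                   target, d_z)
        split[measure] = {"sigma_f2": sigma_f2, "sigma_p2": sigma_p2,
                          "sigma_e2": sigma_e2, "d_z": d_z}

        person = rng.normal(0.0, math.sqrt(sigma_p2), size=n)
        noise = rng.normal(0.0, math.sqrt(sigma_e2), size=(n, 2))
        z = mu[:, None] + person[:, None] + noise
        z[:, 1] += d_z

        # domain rejection: redraw person + occasion noise where the
        # transformed value cannot be inverted to a raw score
        mean_t, sd_t = model.ref_mean_transformed, model.ref_sd_transformed
        for _ in range(1000):
            t = z * sd_t + mean_t
            if spec.transform is Transform.INVERSE:
                bad = (t <= 0).any(axis=1)
            elif spec.transform is Transform.SQRT and \
                    spec.direction.value == "lower_is_better":
                bad = (t > 0).any(axis=1)
            elif spec.transform is Transform.SQRT:
                bad = (t < 0).any(axis=1)
            else:
                bad = np.zeros(n, dtype=bool)
            if not bad.any():
                break
            k = int(bad.sum())
            person[bad] = rng.normal(0.0, math.sqrt(sigma_p2), size=k)
            redraw = rng.normal(0.0, math.sqrt(sigma_e2), size=(k, 2))
            z[bad] = mu[bad, None] + person[bad, None] + redraw
            z[bad, 1] += d_z
        else:
            raise FeasibilityError(
                f"{measure}: could not draw scores inside the transform "
                f"domain; reference constants too close to the boundary")

        t = z * sd_t + mean_t
        raw = np.empty_like(t)
        for i in range(n):
            for j in range(2):
                raw[i, j] = scaling.untransform(t[i, j], spec)

        for i, pid in enumerate(pids):
            latent_rows.append({"participant_id": pid, "measure": measure,
                                "mu": mu[i], "person": person[i],
                                "z1": z[i, 0], "z2": z[i, 1]})
            for j, occ in enumerate((1, 2)):
                rows.append({"participant_id": pid, "occasion": occ,
                             "measure": measure, "raw_score": raw[i, j]})

    df = pd.DataFrame(rows)

    # -- contamination ---------------------------------------------------
    demo_by_id = {d.participant_id: d for d in demographics}
    if config.zero_score_rate > 0:
        for idx in df.index:
            measure = df.at[idx, "measure"]
            spec = battery.get(measure)
            if spec is not None and spec.zero_is_invalid and \
                    rng.random() < config.zero_score_rate:
                df.at[idx, "raw_score"] = 0.0
                zeros.append((df.at[idx, "participant_id"],
                              int(df.at[idx, "occasion"]), measure))
    if config.outlier_rate > 0:
        cfg = config.outlier_config
        zero_keys = set(zeros)
        for (measure, occ), cell in df.groupby(["measure", "occasion"]):
            spec = battery.get(measure)
            if spec is None or not spec.mad_eligible:
                continue
            groups = cell["participant_id"].map(
                lambda p: age_group_index(demo_by_id[p].age, cfg))
            for _, gcell in cell.groupby(groups):
                values = gcell["raw_score"].to_numpy()
                med = float(np.median(values))
                mad = float(np.median(np.abs(values - med)))
                if mad == 0.0:
                    continue
                scaled_mad = cfg.consistency_constant * mad
                for idx in gcell.index:
                    key = (df.at[idx, "participant_id"], int(occ), measure)
                    if key in zero_keys:
                        continue
                    if rng.random() < config.outlier_rate:
                        df.at[idx, "raw_score"] = (
                            med + config.outlier_displacement * scaled_mad)
                        outliers.append(key)

    return SyntheticCohort(
        demographics=list(demographics),
        scores=ScoreTable(df),
        latent=pd.DataFrame(latent_rows),
        injected_outliers=outliers,
        injected_zeros=zeros,
        variance_split=split,
    )


def simulate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Convenience wrapper: demographics + scores from one seed."""
    if config is None:
        config = default_simulation_config()
    rng = np.random.default_rng(seed)
    demo = simulate_demographics(config, rng)
    return simulate_scores(demo, config, rng)
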