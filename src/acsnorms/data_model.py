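"""Shared domain types for the ACS normative-data pipeline.

The Amsterdam Cognition Scan (ACS) is an online self-administered
neuropsychological battery of seven tests yielding twelve outcome measures
(including a composite "total score").  Everything downstream — outlier
cleaning, standardization, test-retest reliability, and regression-based
norming — operates on the types defined here:

* :class:`MeasureSpec` — declarative description of one outcome measure
  (scoring direction, normalizing transform, validity rules);
* :class:`Demographics` — per-participant predictors (age, gender code,
  Verhage education level);
* :class:`ScoreTable` — long-format participant x occasion x measure raw
  scores with exclusion flags;
* :class:`NormModel` — the frozen product of the pipeline: transform
  reference constants plus demographic regression coefficients;
* :class:`VarianceDecomposition` / :class:`ReliabilityResult` — two-way
  ANOVA terms and the per-measure test-retest summary built from them.

Raw score tables are accepted in long or wide CSV layout (long is canonical
internally); norm models are serialized as versioned JSON.  Missing scores
are represented by row absence, never by sentinel values: a zero on a
count-based test is a (suspect) observation, an absent row is no observation.
"""

from __future__ import annotations

import enum
import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("acsnorms")

NORM_MODEL_SCHEMA_VERSION = 1

#: Name of the derived battery composite measure.
COMPOSITE_MEASURE = "TotalScore"


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class AcsNormsError(Exception):
    """Base class for all package errors."""


class ParseError(AcsNormsError):
    """A file could not be parsed (names the offending row/column)."""


class ValidationError(AcsNormsError):
    """A domain invariant was violated."""


class InsufficientDataError(AcsNormsError):
    """Too few observations for the requested computation."""


class SchemaVersionError(AcsNormsError):
    """A serialized file declares an unsupported schema version."""


class ModelFitError(AcsNormsError):
    """A regression norm model could not be fit (degenerate or collinear)."""


class FeasibilityError(AcsNormsError):
    """Requested simulation targets admit no valid variance decomposition."""


# ---------------------------------------------------------------------------
# enums
# ---------------------------------------------------------------------------

class Direction(str, enum.Enum):
    HIGHER_IS_BETTER = "higher_is_better"
    LOWER_IS_BETTER = "lower_is_better"


class Transform(str, enum.Enum):
    NONE = "none"
    INVERSE = "inverse"
    LOG10 = "log10"
    SQRT = "sqrt"


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    MAD_OUTLIER = "mad_outlier"
    ZERO_SCORE = "zero_score"
    AID_USED = "aid_used"
    MANUAL = "manual"


# ---------------------------------------------------------------------------
# MeasureSpec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasureSpec:
    """Declarative description of one test outcome measure.

    Parameters
    ----------
    name
        Unique identifier within a battery (e.g. ``"ConnectTheDotsI"``).
    direction
        Whether larger raw scores mean better performance.  Completion-time
        and error-count measures are ``lower_is_better``.
    transform
        Normalizing transform applied before standardization.  For
        lower-is-better measures the transform also realigns direction
        (see :func:`acsnorms.scaling.transform_raw`).
    zero_is_invalid
        True for count-based tests where a raw 0 reflects a usability
        failure rather than a true floor performance.
    in_composite
        Whether the measure enters the battery composite (total) score.
    unit
        Free-text raw-score unit (seconds, words, moves, sequences).
    time_based
        Explicit marker that the measure is a response-time outcome and
        therefore subject to the MAD outlier rule even when its transform
        is not inverse/log10.
    """

    name: str
    direction: Direction
    transform: Transform = Transform.NONE
    zero_is_invalid: bool = False
    in_composite: bool = False
    unit: str = ""
    time_based: bool = False

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ValidationError("measure name must be non-empty")

    @property
    def mad_eligible(self) -> bool:
        """Whether the per-age-group MAD outlier rule applies."""
        return self.time_based or self.transform in (Transform.INVERSE, Transform.LOG10)


def validate_battery(battery: Sequence[MeasureSpec]) -> None:
    """Check battery-level invariants (unique names)."""
    names = [m.name for m in battery]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValidationError(f"duplicate measure names in battery: {sorted(dupes)}")


def default_acs_battery() -> list[MeasureSpec]:
    """The twelve-measure Amsterdam Cognition Scan battery definition.

    Nine measures enter the composite; Wordlist Recognition (ceiling
    effect, near-zero variance), Place the Beads (normed on a separate
    reference sample), and the derived total score itself do not.
    Zero scores are invalid on the count-based tests Wordlist Learning,
    Box Tapping, and Digit Sequences I/II.
    """
    H, L = Direction.HIGHER_IS_BETTER, Direction.LOWER_IS_BETTER
    T = Transform
    return [
        MeasureSpec("ConnectTheDotsI", L, T.INVERSE, in_composite=True,
                    unit="seconds", time_based=True),
        MeasureSpec("ConnectTheDotsII", L, T.LOG10, in_composite=True,
                    unit="seconds", time_based=True),
        MeasureSpec("WordlistLearning", H, T.NONE, zero_is_invalid=True,
                    in_composite=True, unit="words"),
        MeasureSpec("ReactionSpeed", L, T.INVERSE, in_composite=True,
                    unit="milliseconds", time_based=True),
        MeasureSpec("PlaceTheBeads", L, T.SQRT, unit="moves"),
        MeasureSpec("BoxTapping", H, T.NONE, zero_is_invalid=True,
                    in_composite=True, unit="sequences"),
        MeasureSpec("FillTheGrid", L, T.INVERSE, in_composite=True,
                    unit="seconds", time_based=True),
        MeasureSpec("WordlistDelayedRecall", H, T.NONE, in_composite=True,
                    unit="words"),
        MeasureSpec("WordlistRecognition", H, T.NONE, unit="words"),
        MeasureSpec("DigitSequencesI", H, T.NONE, zero_is_invalid=True,
                    in_composite=True, unit="sequences"),
        MeasureSpec("DigitSequencesII", H, T.NONE, zero_is_invalid=True,
                    in_composite=True, unit="sequences"),
        MeasureSpec(COMPOSITE_MEASURE, H, T.NONE, unit="z"),
    ]


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------

def education_from_verhage(verhage: int) -> int:
    """Binary education code from the 7-level Dutch Verhage scale.

    Levels 6-7 are "high" (code 0); levels 1-5 are low/medium (code 1).
    """
    if not 1 <= int(verhage) <= 7:
        raise ValidationError(f"Verhage level must be 1-7, got {verhage}")
    return 0 if verhage >= 6 else 1


@dataclass
class Demographics:
    """Demographic predictors for one participant.

    ``gender`` is coded 0=female, 1=male; ``education_binary`` 0=high
    (Verhage 6-7), 1=low/medium (Verhage 1-5).  When ``verhage`` is given,
    ``education_binary`` is derived from it and may not contradict it.
    ``covariates`` holds optional extra continuous predictors (e.g. a
    computer-skills z-score).
    """

    participant_id: str
    age: float
    gender: int
    verhage: int | None = None
    education_binary: int | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.age) or self.age <= 0:
            raise ValidationError(
                f"participant {self.participant_id}: age must be a positive "
                f"finite number, got {self.age}")
        if self.gender not in (0, 1):
            raise ValidationError(
                f"participant {self.participant_id}: gender code must be 0 "
                f"(female) or 1 (male), got {self.gender}")
        if self.verhage is not None:
            derived = education_from_verhage(self.verhage)
            if self.education_binary is None:
                self.education_binary = derived
            elif self.education_binary != derived:
                raise ValidationError(
                    f"participant {self.participant_id}: education_binary="
                    f"{self.education_binary} contradicts Verhage "
                    f"{self.verhage} (implies {derived})")
        if self.education_binary is not None and self.education_binary not in (0, 1):
            raise ValidationError(
                f"participant {self.participant_id}: education_binary must "
                f"be 0 (high) or 1 (low/medium)")


def validate_ages(demographics: Iterable[Demographics],
                  age_range: tuple[float, float] = (18.0, 81.0)) -> None:
    """Raise if any participant's age is outside the plausible range."""
    lo, hi = age_range
    bad = [d.participant_id for d in demographics if not lo <= d.age <= hi]
    if bad:
        raise ValidationError(
            f"ages outside plausible range [{lo}, {hi}] for participants: {bad}")


def read_demographics(path: str | Path) -> list[Demographics]:
    """Read a demographics CSV (participant_id, age, gender[, verhage,
    education_binary, extra numeric covariate columns])."""
    df = pd.read_csv(path)
    required = {"participant_id", "age", "gender"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing demographic columns {sorted(missing)}")
    known = {"participant_id", "age", "gender", "verhage", "education_binary"}
    extra = [c for c in df.columns if c not in known]
    out = []
    for _, row in df.iterrows():
        cov = {c: float(row[c]) for c in extra if pd.notna(row[c])}
        out.append(Demographics(
            participant_id=str(row["participant_id"]),
            age=float(row["age"]),
            gender=int(row["gender"]),
            verhage=None if "verhage" not in df.columns or pd.isna(row.get("verhage"))
            else int(row["verhage"]),
            education_binary=None
            if "education_binary" not in df.columns or pd.isna(row.get("education_binary"))
            else int(row["education_binary"]),
            covariates=cov,
        ))
    return out


def write_demographics(demographics: Sequence[Demographics], path: str | Path) -> None:
    rows = []
    for d in demographics:
        row = {"participant_id": d.participant_id, "age": d.age,
               "gender": d.gender, "verhage": d.verhage,
               "education_binary": d.education_binary}
        row.update(d.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ScoreTable
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ["participant_id", "occasion", "measure", "raw_score",
                 "excluded", "exclusion_reason"]


class ScoreTable:
    """Long-format raw scores: one row per (participant, occasion, measure).

    Wraps a :class:`pandas.DataFrame` with columns ``participant_id``,
    ``occasion`` (1 or 2), ``measure``, ``raw_score``, ``excluded``,
    ``exclusion_reason``.  Invariants: at most one row per key triple, and
    ``excluded`` is true exactly when ``exclusion_reason != "none"``.
    Missing observations are absent rows.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col, default in (("excluded", False),
                             ("exclusion_reason", ExclusionReason.NONE.value)):
            if col not in df.columns:
                df[col] = default
        missing = set(SCORE_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"score table missing columns {sorted(missing)}")
        df = df[SCORE_COLUMNS].reset_index(drop=True)
        df["participant_id"] = df["participant_id"].astype(str)
        df["occasion"] = df["occasion"].astype(int)
        df["raw_score"] = df["raw_score"].astype(float)
        df["excluded"] = df["excluded"].astype(bool)
        self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        bad_occ = sorted(set(df["occasion"]) - {1, 2})
        if bad_occ:
            raise ValidationError(f"occasion must be 1 or 2, got {bad_occ}")
        if df["raw_score"].isna().any():
            bad = df[df["raw_score"].isna()]
            raise ValidationError(
                "missing scores must be absent rows, not NaN: "
                f"{bad[['participant_id', 'occasion', 'measure']].to_dict('records')}")
        valid_reasons = {r.value for r in ExclusionReason}
        bad_reason = sorted(set(df["exclusion_reason"]) - valid_reasons)
        if bad_reason:
            raise ValidationError(f"unknown exclusion reasons {bad_reason}")
        mismatch = df["excluded"] != (df["exclusion_reason"] != ExclusionReason.NONE.value)
        if mismatch.any():
            raise ValidationError(
                "excluded flag inconsistent with exclusion_reason for rows "
                f"{df.index[mismatch].tolist()}")
        key = df[["participant_id", "occasion", "measure"]]
        dup = key.duplicated()
        if dup.any():
            raise ValidationError(
                "duplicate (participant, occasion, measure) rows: "
                f"{key[dup].to_dict('records')}")

    # -- convenience accessors ------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ScoreTable) and self.df.equals(other.df)

    @property
    def measures(self) -> list[str]:
        return sorted(self.df["measure"].unique())

    @property
    def occasions(self) -> list[int]:
        return sorted(self.df["occasion"].unique())

    def active(self) -> pd.DataFrame:
        """Rows not flagged for exclusion."""
        return self.df[~self.df["excluded"]]

    def scores(self, measure: str, occasion: int,
               include_excluded: bool = False) -> pd.Series:
        """Raw scores for one measure/occasion, indexed by participant."""
        df = self.df if include_excluded else self.active()
        sub = df[(df["measure"] == measure) & (df["occasion"] == occasion)]
        return sub.set_index("participant_id")["raw_score"]

    def pairs(self, measure: str) -> pd.DataFrame:
        """Complete non-excluded occasion-1/2 pairs for one measure.

        Returns a DataFrame indexed by participant with columns ``score1``
        and ``score2``; participants excluded or missing at either occasion
        are dropped.
        """
        s1 = self.scores(measure, 1)
        s2 = self.scores(measure, 2)
        both = s1.index.intersection(s2.index)
        return pd.DataFrame({"score1": s1.loc[both], "score2": s2.loc[both]})

    def with_exclusions(
        self, flags: Iterable[tuple[str, int, str, ExclusionReason]]
    ) -> "ScoreTable":
        """Return a copy with the given (participant, occasion, measure,
        reason) rows flagged as excluded.  Raw values are preserved."""
        df = self.df.copy()
        idx = df.set_index(["participant_id", "occasion", "measure"]).index
        for pid, occ, measure, reason in flags:
            reason = ExclusionReason(reason)
            loc = idx.get_indexer([(str(pid), int(occ), measure)])
            if loc[0] < 0:
                raise ValidationError(
                    f"cannot exclude absent row ({pid}, {occ}, {measure})")
            df.loc[loc[0], "excluded"] = True
            df.loc[loc[0], "exclusion_reason"] = reason.value
        return ScoreTable(df)


def read_score_table(path: str | Path, battery: Sequence[MeasureSpec],
                     layout: str = "long") -> ScoreTable:
    """Read a score CSV in long or wide layout.

    Long layout: columns ``participant_id, occasion, measure, raw_score``
    (optional ``excluded``/``exclusion_reason``).  Wide layout: one row per
    participant, columns ``<measure>_<occasion>``; blank cells are treated
    as missing (row absent), never as zero.  Columns naming measures not in
    the battery are reported and ignored.
    """
    validate_battery(battery)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout not in ("long", "wide"):
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    known = {m.name for m in battery}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)

    def parse_number(text: str, row: int, col: str) -> float:
        try:
            return float(text)
        except ValueError:
            raise ParseError(
                f"{path}: malformed numeric value {text!r} at row {row}, "
                f"column {col!r}") from None

    rows: list[dict] = []
    if layout == "long":
        required = {"participant_id", "occasion", "measure", "raw_score"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        unknown = sorted(set(df["measure"]) - known)
        if unknown:
            logger.warning("%s: ignoring unknown measures %s", path, unknown)
        for i, rec in df.iterrows():
            if rec["measure"] not in known:
                continue
            if rec["raw_score"].strip() == "":
                continue  # missing observation, not zero
            row = {
                "participant_id": rec["participant_id"],
                "occasion": int(parse_number(rec["occasion"], i, "occasion")),
                "measure": rec["measure"],
                "raw_score": parse_number(rec["raw_score"], i, "raw_score"),
            }
            if "excluded" in df.columns:
                row["excluded"] = rec["excluded"].strip().lower() in ("true", "1")
            if "exclusion_reason" in df.columns and rec["exclusion_reason"].strip():
                row["exclusion_reason"] = rec["exclusion_reason"].strip()
            rows.append(row)
    else:
        if "participant_id" not in df.columns:
            raise ParseError(f"{path}: wide layout requires a participant_id column")
        score_cols: list[tuple[str, str, int]] = []
        unknown_cols = []
        for col in df.columns:
            if col == "participant_id":
                continue
            name, _, occ = col.rpartition("_")
            if name in known and occ in ("1", "2"):
                score_cols.append((col, name, int(occ)))
            else:
                unknown_cols.append(col)
        if unknown_cols:
            logger.warning("%s: ignoring unknown score columns %s",
                           path, unknown_cols)
        for i, rec in df.iterrows():
            for col, measure, occ in score_cols:
                if rec[col].strip() == "":
                    continue  # missing, row absent
                rows.append({
                    "participant_id": rec["participant_id"],
                    "occasion": occ,
                    "measure": measure,
                    "raw_score": parse_number(rec[col], i, col),
                })
    if not rows:
        return ScoreTable(pd.DataFrame(columns=SCORE_COLUMNS))
    return ScoreTable(pd.DataFrame(rows))


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write a score table in canonical long CSV layout."""
    table.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# NormModel
# ---------------------------------------------------------------------------

#: Coefficient keys with dedicated demographic semantics; any other key is
#: looked up in Demographics.covariates.
CORE_PREDICTORS = ("age", "age_squared", "gender", "education")


@dataclass
class NormModel:
    """Frozen regression-based norm model for one measure.

    ``coefficients`` maps predictor names (``constant``, ``age``,
    ``age_squared``, ``gender``, ``education``, or covariate names) to
    unstandardized betas; an absent key means the predictor was pruned.
    ``ref_mean_transformed``/``ref_sd_transformed`` are the reference
    sample's transformed-score mean/SD used to standardize raw scores;
    they may be ``None`` when unpublished, in which case the model can
    predict but not norm-score raw values.  Age enters predictions as
    ``age - age_center``.
    """

    measure: str
    direction: Direction
    transform: Transform
    age_center: float
    coefficients: dict[str, float]
    sd_residual: float
    r_squared: float
    n_reference: int
    ref_mean_transformed: float | None = None
    ref_sd_transformed: float | None = None

    def __post_init__(self) -> None:
        self.direction = Direction(self.direction)
        self.transform = Transform(self.transform)
        self.validate()

    def validate(self) -> None:
        if "constant" not in self.coefficients:
            raise ValidationError(
                f"{self.measure}: coefficients must contain 'constant'")
        if not self.sd_residual > 0:
            raise ValidationError(
                f"{self.measure}: sd_residual must be > 0, got {self.sd_residual}")
        if self.ref_sd_transformed is not None and not self.ref_sd_transformed > 0:
            raise ValidationError(
                f"{self.measure}: ref_sd_transformed must be > 0")
        if not 0 <= self.r_squared <= 1:
            raise ValidationError(
                f"{self.measure}: r_squared must be in [0, 1]")

    @property
    def has_reference_constants(self) -> bool:
        return (self.ref_mean_transformed is not None
                and self.ref_sd_transformed is not None)

    def to_dict(self) -> dict:
        return {
            "schema_version": NORM_MODEL_SCHEMA_VERSION,
            "measure": self.measure,
            "direction": self.direction.value,
            "transform": self.transform.value,
            "age_center": self.age_center,
            "coefficients": dict(self.coefficients),
            "sd_residual": self.sd_residual,
            "r_squared": self.r_squared,
            "n_reference": self.n_reference,
            "ref_mean_transformed": self.ref_mean_transformed,
            "ref_sd_transformed": self.ref_sd_transformed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "NormModel":
        version = data.get("schema_version")
        if version != NORM_MODEL_SCHEMA_VERSION:
            raise SchemaVersionError(
                f"unsupported norm-model schema version {version!r} "
                f"(expected {NORM_MODEL_SCHEMA_VERSION})")
        known = {"schema_version", "measure", "direction", "transform",
                 "age_center", "coefficients", "sd_residual", "r_squared",
                 "n_reference", "ref_mean_transformed", "ref_sd_transformed"}
        extra = sorted(set(data) - known)
        if extra:
            warnings.warn(f"norm model for {data.get('measure')}: ignoring "
                          f"unknown keys {extra}", stacklevel=2)
        return cls(
            measure=data["measure"],
            direction=Direction(data["direction"]),
            transform=Transform(data["transform"]),
            age_center=float(data["age_center"]),
            coefficients={k: float(v) for k, v in data["coefficients"].items()},
            sd_residual=float(data["sd_residual"]),
            r_squared=float(data["r_squared"]),
            n_reference=int(data["n_reference"]),
            ref_mean_transformed=(None if data.get("ref_mean_transformed") is None
                                  else float(data["ref_mean_transformed"])),
            ref_sd_transformed=(None if data.get("ref_sd_transformed") is None
                                else float(data["ref_sd_transformed"])),
        )

    def replace(self, **changes) -> "NormModel":
        return replace(self, **changes)


def write_norm_model(model: NormModel, path: str | Path) -> None:
    """Serialize a norm model to versioned JSON (refuses invalid models)."""
    model.validate()
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def read_norm_model(path: str | Path) -> NormModel:
    """Load a norm model from JSON, checking the schema version."""
    data = json.loads(Path(path).read_text())
    return NormModel.from_dict(data)


# ---------------------------------------------------------------------------
# reliability containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceDecomposition:
    """Two-way ANOVA mean squares for an n-subject x k-occasion score table.

    ``ms_rows`` is the between-subjects mean square, ``ms_cols`` the
    between-occasions mean square, ``ms_error`` the residual mean square
    (whose square root is the SEM).
    """

    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_occasions: int

    def __post_init__(self) -> None:
        if self.k_occasions < 2:
            raise ValidationError("k_occasions must be >= 2")
        for name in ("ms_rows", "ms_cols", "ms_error"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ReliabilityResult:
    """Per-measure test-retest summary (raw score units throughout)."""

    measure: str
    n_pairs: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    t_stat: float
    df: int
    p_value: float
    practice_effect: bool
    sem: float
    sdc: float
    sdc_group: float
    icc: float
    corr: float
    corr_type: str

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValidationError("sem must be >= 0")
        if np.isfinite(self.icc) and not -1.0 - 1e-12 <= self.icc <= 1.0 + 1e-12:
            raise ValidationError(f"icc out of range: {self.icc}")
        if not math.isclose(self.sdc, 1.96 * math.sqrt(2) * self.sem,
                            rel_tol=1e-12, abs_tol=1e-12):
            raise ValidationError("sdc must equal 1.96*sqrt(2)*sem")
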