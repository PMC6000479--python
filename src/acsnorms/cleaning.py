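"""Outlier exclusion rules for raw ACS scores.

Two rules, mirroring how reference data for the battery are screened:

* **MAD rule** — response-time outcomes (Connect the Dots I/II, Reaction
  Speed, Fill the Grid) are screened with the median-absolute-deviation
  method: within each age group (default <=40, 41-59, >=60 years) and each
  assessment occasion, scores outside ``median +/- 3.5 * MAD`` are flagged.
  The MAD is optionally scaled by the normal-consistency constant 1.4826
  (the default; set ``consistency_constant=1.0`` for the unscaled MAD —
  the choice is recorded in the cleaning report).
* **Zero rule** — on count-based tests where a zero almost certainly
  reflects a usability failure rather than true floor performance
  (Wordlist Learning, Box Tapping, Digit Sequences), raw zeros are
  excluded outright.

Flagged rows keep their raw values; they are only marked ``excluded`` with
a reason, so cleaning is non-destructive and auditable.  Manual/aid-based
exclusions present in the input are respected first; MAD limits are then
computed on the remaining rows.  Ties exactly at a limit are retained
(strict inequality flags).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_model import (
    Demographics,
    ExclusionReason,
    InsufficientDataError,
    MeasureSpec,
    ScoreTable,
    ValidationError,
)

logger = logging.getLogger("acsnorms")

__all__ = ["OutlierConfig", "CleaningReport", "GroupLimits",
           "age_group_label", "mad_limits", "apply_outlier_rules"]


@dataclass(frozen=True)
class OutlierConfig:
    """Parameters of the MAD outlier rule.

    ``age_group_bounds`` are the cut ages starting new groups: the default
    ``(41, 60)`` yields groups <=40, 41-59, >=60.  ``consistency_constant``
    scales the raw MAD (1.4826 makes it estimate the SD under normality;
    1.0 leaves it unscaled).  With ``two_sided=False`` only the upper limit
    is enforced (lower limit -inf).
    """

    mad_multiplier: float = 3.5
    age_group_bounds: tuple[float, ...] = (41.0, 60.0)
    consistency_constant: float = 1.4826
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not self.mad_multiplier > 0:
            raise ValidationError("mad_multiplier must be > 0")
        if not self.consistency_constant > 0:
            raise ValidationError("consistency_constant must be > 0")
        bounds = tuple(self.age_group_bounds)
        if any(b >= c for b, c in zip(bounds, bounds[1:])):
            raise ValidationError("age_group_bounds must be strictly increasing")


def age_group_index(age: float, config: OutlierConfig) -> int:
    """0-based age-group index for an age under the configured cuts."""
    return int(np.searchsorted(config.age_group_bounds, age, side="right"))


def age_group_label(index: int, config: OutlierConfig) -> str:
    bounds = config.age_group_bounds
    if not bounds:
        return "all"
    if index == 0:
        return f"<={bounds[0] - 1:g}"
    if index == len(bounds):
        return f">={bounds[-1]:g}"
    return f"{bounds[index - 1]:g}-{bounds[index] - 1:g}"


def mad_limits(values: Sequence[float],
               config: OutlierConfig = OutlierConfig()) -> tuple[float, float]:
    """Lower/upper outlier limits ``median +/- k * c * MAD``.

    Requires at least 3 finite values.  When the MAD is zero the limits
    collapse to the median and a warning is logged; callers must not flag
    anything in that case (see :func:`apply_outlier_rules`).  With
    ``two_sided=False`` the lower limit is ``-inf``.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 3:
        raise InsufficientDataError(
            f"MAD limits need >= 3 finite values, got {arr.size}")
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    if mad == 0.0:
        logger.warning("MAD is zero (degenerate spread); limits collapse to "
                       "the median %g and no exclusions apply", med)
        return (med, med)
    half_width = config.mad_multiplier * config.consistency_constant * mad
    lower = med - half_width if config.two_sided else -math.inf
    return (lower, med + half_width)


@dataclass
class GroupLimits:
    """Limits and counts for one (measure, occasion, age-group) cell."""

    measure: str
    occasion: int
    age_group: str
    n_checked: int
    lower_limit: float
    upper_limit: float
    n_flagged_mad: int = 0
    n_flagged_zero: int = 0


@dataclass
class CleaningReport:
    """Audit record of one cleaning pass."""

    config: OutlierConfig
    groups: list[GroupLimits] = field(default_factory=list)
    flagged: list[tuple[str, int, str, str]] = field(default_factory=list)

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)

    def to_dict(self) -> dict:
        return {
            "config": {
                "mad_multiplier": self.config.mad_multiplier,
                "age_group_bounds": list(self.config.age_group_bounds),
                "consistency_constant": self.config.consistency_constant,
                "two_sided": self.config.two_sided,
            },
            "groups": [vars(g).copy() for g in self.groups],
            "flagged": [list(f) for f in self.flagged],
        }


def apply_outlier_rules(
    table: ScoreTable,
    demographics: Mapping[str, Demographics] | Iterable[Demographics],
    battery: Sequence[MeasureSpec],
    config: OutlierConfig = OutlierConfig(),
) -> tuple[ScoreTable, CleaningReport]:
    """Apply the zero-score and per-age-group MAD rules to a score table.

    The MAD rule covers measures whose transform is inverse/log10 or that
    carry an explicit ``time_based`` marking; limits are computed on the
    raw scale, separately per occasion and age group, from rows not already
    excluded.  The zero rule covers ``zero_is_invalid`` measures and runs
    first.  Returns the flagged copy of the table and a
    :class:`CleaningReport` with limits and counts per cell.
    """
    if not isinstance(demographics, Mapping):
        demographics = {d.participant_id: d for d in demographics}
    report = CleaningReport(config=config)
    flags: list[tuple[str, int, str, ExclusionReason]] = []

    df = table.df
    # -- zero rule -------------------------------------------------------
    zero_flagged: set[tuple[str, int, str]] = set()
    for spec in battery:
        if not spec.zero_is_invalid:
            continue
        sub = df[(df["measure"] == spec.name) & ~df["excluded"]
                 & (df["raw_score"] == 0.0)]
        for _, rec in sub.iterrows():
            key = (rec["participant_id"], int(rec["occasion"]), spec.name)
            zero_flagged.add(key)
            flags.append((*key, ExclusionReason.ZERO_SCORE))
            report.flagged.append((*key, ExclusionReason.ZERO_SCORE.value))

    # -- MAD rule --------------------------------------------------------
    mad_measures = [m for m in battery if m.mad_eligible]
    if mad_measures:
        scored = set(df.loc[df["measure"].isin([m.name for m in mad_measures]),
                            "participant_id"])
        missing = sorted(p for p in scored if p not in demographics)
        if missing:
            raise ValidationError(
                f"MAD rule needs ages for all scored participants; missing "
                f"demographics for: {missing}")

    for spec in mad_measures:
        # Limits are computed from rows not excluded for *other* reasons
        # (manual, aid, zero); rows previously flagged as mad_outlier still
        # enter the limit computation, which makes re-running the rule on a
        # cleaned table a no-op (idempotence) instead of cascading.
        sub = df[(df["measure"] == spec.name)
                 & df["exclusion_reason"].isin(
                     [ExclusionReason.NONE.value,
                      ExclusionReason.MAD_OUTLIER.value])]
        sub = sub[~sub.apply(lambda r: (r["participant_id"], int(r["occasion"]),
                                        spec.name) in zero_flagged, axis=1)]
        if sub.empty:
            continue
        groups = sub["participant_id"].map(
            lambda p: age_group_index(demographics[p].age, config))
        for (occasion, gidx), cell in sub.groupby([sub["occasion"], groups]):
            label = age_group_label(int(gidx), config)
            values = cell["raw_score"].to_numpy()
            if len(values) < 3:
                logger.warning(
                    "%s occasion %d age group %s: only %d values, MAD rule "
                    "skipped", spec.name, occasion, label, len(values))
                continue
            lower, upper = mad_limits(values, config)
            rec = GroupLimits(spec.name, int(occasion), label,
                              n_checked=len(values),
                              lower_limit=lower, upper_limit=upper)
            if lower < upper:  # MAD > 0; strict inequality flags
                out = cell[((cell["raw_score"] < lower)
                            | (cell["raw_score"] > upper))
                           & ~cell["excluded"]]
                for _, row in out.iterrows():
                    key = (row["participant_id"], int(row["occasion"]), spec.name)
                    flags.append((*key, ExclusionReason.MAD_OUTLIER))
                    report.flagged.append((*key, ExclusionReason.MAD_OUTLIER.value))
                rec.n_flagged_mad = len(out)
            report.groups.append(rec)

    # count zero flags into report cells (zero rule is not age-grouped)
    for spec in battery:
        if not spec.zero_is_invalid:
            continue
        for occasion in table.occasions:
            n = sum(1 for (p, o, m) in zero_flagged
                    if m == spec.name and o == occasion)
            if n:
                checked = df[(df["measure"] == spec.name)
                             & (df["occasion"] == occasion) & ~df["excluded"]]
                report.groups.append(GroupLimits(
                    spec.name, occasion, "all", n_checked=len(checked),
                    lower_limit=-math.inf, upper_limit=math.inf,
                    n_flagged_zero=n))

    return table.with_exclusions(flags), report
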