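"""Reverse scoring, normalizing transforms, standardization, and the
battery composite score.

Raw ACS scores are put on a common "higher = better", approximately normal
scale in two steps.  First a measure-specific transform realigns direction
and normalizes shape:

* ``inverse``  — ``1/raw`` (completion times; the reciprocal itself reverses
  direction, so a slow 60 s becomes a small 0.0167),
* ``log10``    — ``-log10(raw)`` for lower-is-better times,
* ``sqrt``     — ``-sqrt(raw)`` for lower-is-better counts (extra moves),
* ``none``     — identity, sign-flipped when lower is better.

Second, the transformed score is standardized against the reference
sample's transformed mean and SD: ``z = (t - ref_mean) / ref_sd``.  The
reference constants always come from occasion-1 non-excluded reference data
and are frozen into the :class:`~acsnorms.data_model.NormModel`, so scoring
a new individual never depends on that individual's own cohort.

The battery composite ("total score") is the arithmetic mean of the nine
composite-eligible measures' z-scores, complete cases only: if any
component is missing the composite is absent, never zero.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    Direction,
    MeasureSpec,
    ScoreTable,
    Transform,
    ValidationError,
)

__all__ = [
    "transform_raw", "untransform", "standardize", "destandardize",
    "reference_constants", "standardized_table", "composite_score",
    "composite_by_occasion",
]


def transform_raw(raw: float, spec: MeasureSpec) -> float:
    """Apply the measure's normalizing, direction-aligning transform.

    Raises :class:`ValidationError` on a domain violation (non-positive
    time for inverse/log10, negative count for sqrt), naming the measure.
    """
    raw = float(raw)
    t = spec.transform
    if t is Transform.INVERSE:
        if raw <= 0:
            raise ValidationError(
                f"{spec.name}: inverse transform needs raw > 0, got {raw}")
        return 1.0 / raw
    if t is Transform.LOG10:
        if raw <= 0:
            raise ValidationError(
                f"{spec.name}: log10 transform needs raw > 0, got {raw}")
        value = math.log10(raw)
        return -value if spec.direction is Direction.LOWER_IS_BETTER else value
    if t is Transform.SQRT:
        if raw < 0:
            raise ValidationError(
                f"{spec.name}: sqrt transform needs raw >= 0, got {raw}")
        value = math.sqrt(raw)
        return -value if spec.direction is Direction.LOWER_IS_BETTER else value
    # Transform.NONE
    return -raw if spec.direction is Direction.LOWER_IS_BETTER else raw


def untransform(value: float, spec: MeasureSpec) -> float:
    """Inverse of :func:`transform_raw`; used by the cohort simulator.

    Raises :class:`ValidationError` when ``value`` is outside the image of
    the transform (e.g. a non-positive value for ``inverse``).
    """
    value = float(value)
    t = spec.transform
    flip = spec.direction is Direction.LOWER_IS_BETTER
    if t is Transform.INVERSE:
        if value <= 0:
            raise ValidationError(
                f"{spec.name}: transformed value must be > 0 to invert, "
                f"got {value}")
        return 1.0 / value
    if t is Transform.LOG10:
        return 10.0 ** (-value if flip else value)
    if t is Transform.SQRT:
        v = -value if flip else value
        if v < 0:
            raise ValidationError(
                f"{spec.name}: transformed value {value} outside sqrt image")
        return v * v
    return -value if flip else value


def standardize(transformed: float, ref_mean: float, ref_sd: float) -> float:
    """z-score a transformed value against reference constants."""
    if not ref_sd > 0:
        raise ValidationError(f"reference SD must be > 0, got {ref_sd}")
    return (transformed - ref_mean) / ref_sd


def destandardize(z: float, ref_mean: float, ref_sd: float) -> float:
    if not ref_sd > 0:
        raise ValidationError(f"reference SD must be > 0, got {ref_sd}")
    return z * ref_sd + ref_mean


def reference_constants(
    table: ScoreTable, battery: Sequence[MeasureSpec]
) -> dict[str, tuple[float, float]]:
    """Transformed-scale mean/SD per measure from occasion-1 non-excluded
    reference scores (the constants frozen into norm models)."""
    out: dict[str, tuple[float, float]] = {}
    for spec in battery:
        raw = table.scores(spec.name, 1)
        if len(raw) < 2:
            continue
        t = np.array([transform_raw(v, spec) for v in raw])
        sd = float(t.std(ddof=1))
        if sd <= 0:
            raise ValidationError(
                f"{spec.name}: zero variance in reference scores")
        out[spec.name] = (float(t.mean()), sd)
    return out


def standardized_table(
    table: ScoreTable,
    battery: Sequence[MeasureSpec],
    constants: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """z-scores per (participant, occasion, measure), non-excluded rows only.

    ``constants`` defaults to :func:`reference_constants` of the table
    itself (reference-sample use).  Occasion-2 scores are standardized with
    the occasion-1 constants, so practice effects remain visible as a mean
    shift.  Returns a long DataFrame with columns ``participant_id``,
    ``occasion``, ``measure``, ``z``.
    """
    by_name = {m.name: m for m in battery}
    if constants is None:
        constants = reference_constants(table, battery)
    rows = []
    for _, rec in table.active().iterrows():
        spec = by_name.get(rec["measure"])
        if spec is None or spec.name not in constants:
            continue
        mean, sd = constants[spec.name]
        rows.append({
            "participant_id": rec["participant_id"],
            "occasion": rec["occasion"],
            "measure": spec.name,
            "z": standardize(transform_raw(rec["raw_score"], spec), mean, sd),
        })
    return pd.DataFrame(rows, columns=["participant_id", "occasion", "measure", "z"])


def composite_score(
    z_scores: Mapping[str, float], battery: Sequence[MeasureSpec]
) -> float | None:
    """Mean of the composite measures' z-scores; ``None`` unless all are
    present (complete-case rule)."""
    members = [m.name for m in battery if m.in_composite]
    if not members:
        raise ValidationError("battery has no composite measures")
    try:
        values = [z_scores[name] for name in members]
    except KeyError:
        return None
    if any(v is None or not np.isfinite(v) for v in values):
        return None
    return float(np.mean(values))


def composite_by_occasion(
    ztable: pd.DataFrame, battery: Sequence[MeasureSpec]
) -> pd.DataFrame:
    """Composite z per (participant, occasion) from a standardized table.

    Complete cases only: participants missing any composite component at an
    occasion get no row for that occasion.
    """
    members = sorted(m.name for m in battery if m.in_composite)
    sub = ztable[ztable["measure"].isin(members)]
    wide = sub.pivot_table(index=["participant_id", "occasion"],
                           columns="measure", values="z")
    complete = wide.dropna()
    complete = complete[[m for m in members if m in complete.columns]]
    if len(complete.columns) < len(members):
        # some component absent for everyone
        return pd.DataFrame(columns=["participant_id", "occasion", "z"])
    out = complete.mean(axis=1).rename("z").reset_index()
    return out
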