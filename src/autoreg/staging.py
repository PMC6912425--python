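"""Differentiation-stage assignment and low-expression filtering.

The differentiation time course is partitioned into three stages by time
relative to induction: ``non`` (0 h and before), ``early`` (after 0 up to
48 h) and ``late`` (after 48 up to 260 h).  Boundaries are closed on the
right: 0 h is ``non`` and 48 h is ``early``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from autoreg.errors import EmptyResultError, StageError

logger = logging.getLogger(__name__)

#: Ordered stage labels.
STAGES = ("non", "early", "late")

#: Latest protocol time point (hours after induction).
MAX_TIME_H = 260.0


def assign_stage(time_h: float) -> str:
    """Map a time point (hours relative to induction) to its stage.

    Parameters
    ----------
    time_h
        Signed hours relative to induction; must be <= 260.

    Returns
    -------
    str
        ``"non"`` if ``time_h <= 0``, ``"early"`` if ``0 < time_h <= 48``,
        ``"late"`` if ``48 < time_h <= 260``.

    Raises
    ------
    StageError
        If ``time_h`` exceeds the 260 h protocol end.
    """
    t = float(time_h)
    if np.isnan(t):
        raise StageError("time_h is NaN")
    if t > MAX_TIME_H:
        raise StageError(f"time point {t} h is outside the protocol (> {MAX_TIME_H} h)")
    if t <= 0:
        return "non"
    if t <= 48:
        return "early"
    return "late"


def validate_sample_table(samples: pd.DataFrame) -> None:
    """Check SampleTable invariants; raise ``ValueError`` on violation.

    Required columns: ``sample_id, time_h, stage, assay, target, arm,
    quality_flag``.  The declared stage must agree with
    :func:`assign_stage` for every sample.
    """
    required = {"sample_id", "time_h", "stage", "assay", "target", "arm", "quality_flag"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table is missing columns: {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    for _, row in samples.iterrows():
        expect = assign_stage(row["time_h"])
        if row["stage"] != expect:
            raise ValueError(
                f"sample {row['sample_id']}: stage {row['stage']!r} inconsistent "
                f"with time {row['time_h']} h (expected {expect!r})"
            )


def filter_low_quality(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    min_count: int = 10,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Drop flagged samples and low-expressed features.

    Samples with ``quality_flag == False`` are removed; features are kept
    when they have ``count >= min_count`` in at least ``min_samples`` of the
    surviving samples.

    Raises
    ------
    EmptyResultError
        If no sample or no feature survives.
    """
    if min_count < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    flagged = samples.set_index("sample_id")["quality_flag"]
    keep_samples = [s for s in counts.columns if bool(flagged.get(s, True))]
    n_dropped_samples = counts.shape[1] - len(keep_samples)
    if not keep_samples:
        raise EmptyResultError("all samples were flagged low-quality")
    out = counts[keep_samples]
    keep_features = (out >= min_count).sum(axis=1) >= min_samples
    n_dropped_features = int((~keep_features).sum())
    out = out.loc[keep_features]
    if out.empty:
        raise EmptyResultError(
            f"no feature has count >= {min_count} in >= {min_samples} samples"
        )
    logger.info(
        "filter_low_quality: removed %d samples, %d features; kept %d x %d",
        n_dropped_samples, n_dropped_features, out.shape[0], out.shape[1],
    )
    return out


def stage_samples(samples: pd.DataFrame, stage: str, assay: str | None = None) -> list[str]:
    """Return sample ids belonging to *stage* (optionally one assay)."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    mask = samples["stage"] == stage
    if assay is not None:
        mask &= samples["assay"] == assay
    return samples.loc[mask, "sample_id"].tolist()
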