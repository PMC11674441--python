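"""IFN-gamma ELISpot activity scoring and fold-change positivity calls.

Per well, activity is the sum over spots of intensity x size, divided by
1000.  Replicate wells are aggregated as mean +/- sample SD; a peptide
condition is positive when its mean activity is at least 1.5x the control
condition's mean (inclusive), negative below, and indeterminate when the
control mean is zero.  The control condition is per-sample configuration:
studies switch between a mature-DC+lymphocyte background and plain PBMC
when background secretion is elevated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .synthetic_data import InputError

DEFAULT_THRESHOLD = 1.5


class ConditionError(KeyError):
    """A requested assay condition is absent from the plate."""


@dataclass(frozen=True)
class Spot:
    intensity: float
    size: float

    def __post_init__(self) -> None:
        ok = (math.isfinite(self.intensity) and math.isfinite(self.size)
              and self.intensity >= 0 and self.size >= 0)
        if not ok:
            raise InputError(f"spot intensity/size must be finite and non-negative, got {self!r}")


@dataclass(frozen=True)
class Well:
    well_id: str
    condition: str
    replicate: int
    spots: tuple[Spot, ...]

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise InputError("replicate index must be >= 1")


@dataclass(frozen=True)
class AssayResult:
    condition: str
    mean_activity: float
    sd_activity: float
    fold_change: float | None
    call: str  # positive | negative | indeterminate


def well_activity(well: Well) -> float:
    """Sum of per-spot intensity x size, divided by 1000; empty well -> 0."""
    return sum(s.intensity * s.size for s in well.spots) / 1000.0


def wells_from_frame(plate: pd.DataFrame) -> list[Well]:
    """Group a one-row-per-spot plate table into Well objects.

    Expects columns well_id, condition, replicate, spot_intensity, spot_size.
    A (well_id, condition, replicate) group with no spot rows cannot be
    represented in this format; emit a zero-spot row upstream if needed.
    """
    required = {"well_id", "condition", "replicate", "spot_intensity", "spot_size"}
    missing = required - set(plate.columns)
    if missing:
        raise InputError(f"plate table missing column(s): {sorted(missing)}")
    wells = []
    for (well_id, condition, replicate), grp in plate.groupby(
        ["well_id", "condition", "replicate"], sort=True
    ):
        spots = tuple(
            Spot(float(r.spot_intensity), float(r.spot_size)) for r in grp.itertuples(index=False)
        )
        wells.append(Well(str(well_id), str(condition), int(replicate), spots))
    return wells


def aggregate_condition(wells: list[Well], condition: str) -> tuple[float, float]:
    """Mean and sample SD (ddof=1; 0 when n=1) of per-well activities."""
    acts = [well_activity(w) for w in wells if w.condition == condition]
    if not acts:
        raise ConditionError(f"no wells for condition {condition!r}")
    mean = sum(acts) / len(acts)
    if len(acts) == 1:
        return mean, 0.0
    var = sum((a - mean) ** 2 for a in acts) / (len(acts) - 1)
    return mean, math.sqrt(var)


def call_positivity(
    wells: list[Well],
    control_condition: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[AssayResult], dict[str, int]]:
    """Fold-change positivity of every non-control condition vs the control.

    fold_change = condition mean / control mean; positive iff
    fold_change >= threshold (exact threshold counts as positive).  A zero
    control mean makes every call indeterminate, with a warning.  Returns
    the per-condition results and a {positive, negative, indeterminate}
    count summary.
    """
    conditions = sorted({w.condition for w in wells})
    if control_condition not in conditions:
        raise ConditionError(
            f"control condition {control_condition!r} absent; available: {conditions}"
        )
    control_mean, _ = aggregate_condition(wells, control_condition)
    if control_mean == 0:
        warnings.warn("control mean activity is 0: all calls indeterminate")
    results = []
    counts = {"positive": 0, "negative": 0, "indeterminate": 0}
    for condition in conditions:
        if condition == control_condition:
            continue
        mean, sd = aggregate_condition(wells, condition)
        if control_mean == 0:
            fold, call = None, "indeterminate"
        else:
            fold = mean / control_mean
            call = "positive" if fold >= threshold else "negative"
        counts[call] += 1
        results.append(AssayResult(condition, mean, sd, fold, call))
    return results, counts


def results_to_frame(results: list[AssayResult], counts: dict[str, int]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(r.condition, r.mean_activity, r.sd_activity,
          "" if r.fold_change is None else r.fold_change, r.call) for r in results],
        columns=["condition", "mean_activity", "sd_activity", "fold_change", "call"],
    )
    df.attrs["counts"] = dict(counts)
    return df


def read_plate_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
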