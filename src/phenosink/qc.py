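"""Quality control of leaf-level gas-exchange records.

Cleaning follows three ordered steps, applied after assigning every
record to the canonical (first) day of its measurement interval:

1. *Leaf-area correction* — a leaf too small to fill the measurement
   chamber dilutes the chamber-average flux; dividing the recorded net
   photosynthesis by the covered fraction re-expresses it per unit of
   actual leaf area.
2. *Plausibility screen* — records whose covariates are biologically
   impossible (the single default rule: stomatal conductance must be
   non-negative) are dropped, with the failing rule logged.
3. *Non-positive resolution* — a negative net photosynthesis is kept as
   zero when zero is biologically meaningful (the record is from the
   final measurement interval, or the tree had lost all its leaves by
   the next interval) and dropped otherwise.  A leafless tree with no
   record at season end receives an explicit zero.  An exactly-zero
   flux is kept untouched.

Every decision is logged, so ``kept + zeroed + dropped`` always accounts
for the full input (plus any injected leafless zeros).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = [
    "MeasurementSchedule",
    "QCRule",
    "DEFAULT_RULES",
    "ScheduleError",
    "assign_interval_day",
    "correct_leaf_area",
    "screen_plausibility",
    "resolve_nonpositive",
    "run_qc",
    "leafless_history",
]


class ScheduleError(ValueError):
    """Raised when an observation cannot be placed on the schedule."""


@dataclass(frozen=True)
class MeasurementSchedule:
    """Ordered, non-overlapping measurement intervals ``(first_doy, last_doy)``."""

    photosynthesis: tuple[tuple[int, int], ...]
    counts_spad: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for name, intervals in (("photosynthesis", self.photosynthesis),
                                ("counts_spad", self.counts_spad)):
            for (a, b) in intervals:
                if b < a:
                    raise ScheduleError(f"{name}: interval ({a}, {b}) is reversed")
            for (_, b), (a2, _) in zip(intervals, intervals[1:]):
                if a2 <= b:
                    raise ScheduleError(f"{name}: intervals overlap or are unordered")

    @classmethod
    def from_config(
        cls, config: SimulationConfig, photo_span: int = 10, count_span: int = 4
    ) -> "MeasurementSchedule":
        """Build the schedule from a simulation config.

        Campaign lengths default to the study's: gas exchange over up to
        ten days, counts/SPAD over up to four.
        """
        def bounded(doys: Sequence[int], span: int) -> tuple[tuple[int, int], ...]:
            out = []
            for i, d in enumerate(doys):
                last = d + span - 1
                if i + 1 < len(doys):
                    last = min(last, doys[i + 1] - 1)
                out.append((int(d), int(last)))
            return tuple(out)

        return cls(
            photosynthesis=bounded(config.photosynthesis_doys, photo_span),
            counts_spad=bounded(config.counts_spad_doys, count_span),
        )


def assign_interval_day(
    observations: pd.DataFrame, schedule: MeasurementSchedule
) -> pd.DataFrame:
    """Snap each photosynthesis record to its interval's first day.

    Measurements within one campaign are treated as comparable, so every
    record's ``doy`` is replaced by the campaign's first day and a 1-based
    ``interval_index`` is added.  A record outside all intervals raises
    :class:`ScheduleError` naming it.
    """
    out = observations.copy()
    firsts = np.full(len(out), -1, dtype=int)
    idx = np.full(len(out), -1, dtype=int)
    doys = out["doy"].to_numpy()
    for k, (a, b) in enumerate(schedule.photosynthesis, start=1):
        inside = (doys >= a) & (doys <= b)
        firsts[inside] = a
        idx[inside] = k
    if (idx < 0).any():
        bad = out.loc[idx < 0].iloc[0]
        raise ScheduleError(
            f"record tree_id={bad['tree_id']} doy={bad['doy']} lies outside every "
            "measurement interval"
        )
    out["doy"] = firsts
    out["interval_index"] = idx
    return out


def correct_leaf_area(a_net, covered_fraction):
    """Re-express a chamber-basis flux per unit of actual leaf area.

    ``a_net / covered_fraction``; applies element-wise.  Raises for a
    coverage outside ``(0, 1]``.
    """
    a = np.asarray(a_net, dtype=float)
    f = np.asarray(covered_fraction, dtype=float)
    if np.any(f <= 0) or np.any(f > 1):
        raise ValueError("covered_fraction must lie in (0, 1]")
    out = a / f
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class QCRule:
    """A named plausibility predicate over a record's covariates.

    ``check`` receives the record as a mapping/Series and returns True
    when the record passes.
    """

    name: str
    check: Callable[[pd.Series], bool]


#: The study's single documented plausibility rule.
DEFAULT_RULES: tuple[QCRule, ...] = (
    QCRule("negative_gsw", lambda rec: rec["gsw"] >= 0),
)


def screen_plausibility(
    observation: pd.Series, rules: Sequence[QCRule] = DEFAULT_RULES
) -> tuple[str, str | None]:
    """Evaluate one record against an ordered rule list.

    Returns ``("kept", None)`` or ``("dropped", failing_rule_name)``;
    the first failing rule wins.  An empty rule list keeps everything.
    """
    for rule in rules:
        if not bool(rule.check(observation)):
            return "dropped", rule.name
    return "kept", None


def leafless_history(photo: pd.DataFrame) -> dict[tuple[str, int], bool]:
    """Per-(tree, interval) leafless status from flagged records."""
    return {
        (r.tree_id, int(r.interval_index)): bool(r.leafless_flag)
        for r in photo.itertuples(index=False)
    }


def resolve_nonpositive(
    observation: pd.Series,
    tree_history: dict[tuple[str, int], bool],
    last_interval: int,
) -> str:
    """Decide the fate of one record based on the sign of its flux.

    Returns ``"kept"`` (non-negative flux), ``"zeroed"`` (negative flux
    that is biologically a zero: final interval, or the tree leafless by
    the next interval) or ``"dropped"``.  Raises ``KeyError`` when the
    tree's history is missing for a required interval.
    """
    a = float(observation["a_net_umol_m2_s"])
    if a >= 0:
        return "kept"
    interval = int(observation["interval_index"])
    if interval == last_interval:
        return "zeroed"
    key = (observation["tree_id"], interval + 1)
    if key not in tree_history:
        raise KeyError(f"no leafless history for tree {key[0]} at interval {key[1]}")
    return "zeroed" if tree_history[key] else "dropped"


def run_qc(
    photo: pd.DataFrame,
    schedule: MeasurementSchedule,
    rules: Sequence[QCRule] = DEFAULT_RULES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the full cleaning chain to a photosynthesis table.

    Order: interval-day assignment, leaf-area correction, plausibility
    screen, non-positive resolution, and injection of explicit zeros for
    trees that were leafless at season end but have no surviving final
    record.  The chain is idempotent on its own output.

    Returns
    -------
    clean : DataFrame
        Surviving records (``qc_status`` in {kept, zeroed}) with
        corrected ``a_net_umol_m2_s``, canonical ``doy`` and
        ``interval_index``.
    log : DataFrame
        One row per input (and injected) record: tree_id, doy,
        interval_index, action, rule.
    """
    df = assign_interval_day(photo, schedule)
    already = "qc_status" in df.columns
    if not already:
        df["qc_status"] = "raw"
        df["a_net_umol_m2_s"] = correct_leaf_area(
            df["a_net_umol_m2_s"], df["covered_fraction"]
        )
        df["covered_fraction"] = 1.0  # correction is recorded as applied

    last_interval = len(schedule.photosynthesis)
    history = leafless_history(df)
    log_rows = []
    statuses = []
    values = []
    for _, rec in df.iterrows():
        if rec["qc_status"] in ("kept", "zeroed"):  # idempotent re-run
            statuses.append(rec["qc_status"])
            values.append(float(rec["a_net_umol_m2_s"]))
            log_rows.append((rec["tree_id"], rec["doy"], rec["interval_index"],
                             rec["qc_status"], None))
            continue
        status, rule = screen_plausibility(rec, rules)
        if status == "dropped":
            statuses.append("dropped")
            values.append(float(rec["a_net_umol_m2_s"]))
            log_rows.append((rec["tree_id"], rec["doy"], rec["interval_index"],
                             "dropped", rule))
            continue
        fate = resolve_nonpositive(rec, history, last_interval)
        statuses.append(fate)
        values.append(0.0 if fate == "zeroed" else float(rec["a_net_umol_m2_s"]))
        log_rows.append((rec["tree_id"], rec["doy"], rec["interval_index"], fate,
                         None if fate != "dropped" else "negative_a_net"))
    df = df.assign(qc_status=statuses, a_net_umol_m2_s=values)

    # season-end zeros for leafless trees whose final record did not survive
    final_first = schedule.photosynthesis[-1][0]
    injected = []
    for tree_id in df["tree_id"].unique():
        if not history.get((tree_id, last_interval), False):
            continue
        has_final = (
            (df["tree_id"] == tree_id)
            & (df["interval_index"] == last_interval)
            & df["qc_status"].isin(["kept", "zeroed"])
        ).any()
        if not has_final:
            injected.append({
                "tree_id": tree_id, "doy": final_first,
                "a_net_umol_m2_s": 0.0, "covered_fraction": 1.0, "gsw": 0.0,
                "leafless_flag": True, "interval_index": last_interval,
                "qc_status": "zeroed",
            })
            log_rows.append((tree_id, final_first, last_interval, "zeroed",
                             "injected_leafless_zero"))
    if injected:
        df = pd.concat([df, pd.DataFrame(injected)], ignore_index=True)

    log = pd.DataFrame(log_rows, columns=["tree_id", "doy", "interval_index",
                                          "action", "rule"])
    clean = df[df["qc_status"].isin(["kept", "zeroed"])].reset_index(drop=True)
    clean = clean.sort_values(["tree_id", "interval_index"]).reset_index(drop=True)
    return clean, log
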