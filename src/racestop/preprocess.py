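"""Trial classification, outlier trimming and condition summaries.

Classification labels partition all trials:

* go trial, no response            -> ``go_miss``
* go trial, wrong name/disfluent   -> ``go_error``
* go trial, clean response         -> ``go_correct``
* stop trial, response emitted     -> ``stop_fail``
* stop trial, response withheld    -> ``stop_success``

Go-RT analyses use correct go trials only, trimmed to mean +/- k * SD
(sample SD, bounds computed once per participant x condition, closed
interval; default k = 2.5).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .racemodel import TrialRecord

__all__ = [
    "LABELS",
    "TRIAL_LOG_COLUMNS",
    "TrimResult",
    "SummaryTables",
    "classify_trials",
    "trim_outliers",
    "apply_trimming",
    "summarize",
    "write_trial_log",
    "read_trial_log",
]

LABELS = ("go_correct", "go_error", "go_miss", "stop_success", "stop_fail")

TRIAL_LOG_COLUMNS = [
    "participant",
    "block",
    "position",
    "picture",
    "condition",
    "trial_type",
    "ssd_ms",
    "responded",
    "rt_ms",
    "name_correct",
    "disfluent",
]


def _as_frame(records: Iterable[TrialRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    from .racemodel import records_to_frame

    return records_to_frame(list(records))


def classify_trials(records: Iterable[TrialRecord] | pd.DataFrame) -> pd.DataFrame:
    """Attach a ``label`` column partitioning trials into the five categories."""
    df = _as_frame(records)
    responded = df["responded"].astype(bool)
    if (responded & df["rt_ms"].isna()).any():
        raise ValueError("malformed record: responded without an RT")
    if ((~responded) & df["rt_ms"].notna()).any():
        raise ValueError("malformed record: RT present without a response")

    is_go = (df["trial_type"] == "go").to_numpy()
    responded = responded.to_numpy()
    name_ok = df["name_correct"].apply(lambda v: bool(v) if pd.notna(v) else False).to_numpy()
    disfluent = df["disfluent"].apply(lambda v: bool(v) if pd.notna(v) else False).to_numpy()
    clean = responded & name_ok & ~disfluent

    label = np.select(
        [
            is_go & ~responded,
            is_go & responded & clean,
            is_go & responded & ~clean,
            ~is_go & responded,
            ~is_go & ~responded,
        ],
        ["go_miss", "go_correct", "go_error", "stop_fail", "stop_success"],
        default="unlabeled",
    )
    df = df.copy()
    df["label"] = label
    return df


@dataclass(frozen=True)
class TrimResult:
    retained: np.ndarray
    removed_indices: np.ndarray
    warned: bool  # True when fewer than 2 values made trimming impossible


def trim_outliers(rts: Sequence[float], k: float = 2.5) -> TrimResult:
    """Single-pass trim: drop values outside mean +/- k * sample SD.

    Bounds are computed once from the full input (closed interval, values on
    the boundary are retained).  Inputs with fewer than two values pass
    through untrimmed with the warning flag set.
    """
    values = np.asarray(rts, dtype=float)
    if values.ndim != 1:
        raise ValueError("rts must be one-dimensional")
    if values.size < 2:
        return TrimResult(values, np.array([], dtype=int), warned=True)
    mean = values.mean()
    sd = values.std(ddof=1)
    if not math.isfinite(k):
        keep = np.ones(values.size, dtype=bool)
    else:
        lo, hi = mean - k * sd, mean + k * sd
        keep = (values >= lo) & (values <= hi)
    return TrimResult(values[keep], np.flatnonzero(~keep), warned=False)


def apply_trimming(classified: pd.DataFrame, k: float = 2.5) -> pd.DataFrame:
    """Flag trimmed-out correct go RTs per participant x condition.

    Adds a boolean ``rt_retained`` column: True for correct go trials inside
    the trimming bounds, False for trimmed ones, and False (not applicable)
    elsewhere.
    """
    df = classified.copy()
    df["rt_retained"] = False
    for (_, _), idx in df[df["label"] == "go_correct"].groupby(
        ["participant", "condition"]
    ).groups.items():
        res = trim_outliers(df.loc[idx, "rt_ms"].to_numpy(), k=k)
        keep = np.ones(len(idx), dtype=bool)
        keep[res.removed_indices] = False
        df.loc[np.asarray(idx)[keep], "rt_retained"] = True
    return df


@dataclass
class SummaryTables:
    """Per-participant condition summaries for go and stop trials."""

    go_summary: pd.DataFrame  # participant, condition, n_go, mean_rt, sd_rt, error_pct, miss_pct
    stop_summary: pd.DataFrame  # participant, ssd_ms, condition, n_stop, n_fail, p_fail, ...


def summarize(classified: pd.DataFrame, k: float = 2.5) -> SummaryTables:
    """Build Table-1/Table-2 shaped summaries from classified trials.

    Go means/SDs use trimmed correct go RTs; error and miss percentages are
    computed over all go trials of the cell.  The stop summary reports the
    failed-inhibition proportion and failed-RT moments per participant x SSD
    x condition; cells without stop trials or without failed responses are
    flagged via NaN plus the ``empty_cell`` / ``no_failed_rt`` columns rather
    than silently reported as zero.
    """
    if "label" not in classified.columns:
        classified = classify_trials(classified)
    df = apply_trimming(classified, k=k)

    go_rows = []
    stop_rows = []
    participants = sorted(df["participant"].unique())
    conditions = ["related", "unrelated"]
    ssds = sorted(df.loc[df["trial_type"] == "stop", "ssd_ms"].dropna().unique())

    for p in participants:
        sub = df[df["participant"] == p]
        for cond in conditions:
            cell = sub[(sub["trial_type"] == "go") & (sub["condition"] == cond)]
            n_go = len(cell)
            rts = cell.loc[cell["rt_retained"], "rt_ms"].to_numpy(dtype=float)
            go_rows.append(
                {
                    "participant": p,
                    "condition": cond,
                    "n_go": n_go,
                    "n_rt": rts.size,
                    "mean_rt": rts.mean() if rts.size else np.nan,
                    "sd_rt": rts.std(ddof=1) if rts.size > 1 else np.nan,
                    "error_pct": 100.0 * (cell["label"] == "go_error").mean() if n_go else np.nan,
                    "miss_pct": 100.0 * (cell["label"] == "go_miss").mean() if n_go else np.nan,
                    "empty_cell": n_go == 0,
                }
            )
        for ssd in ssds:
            for cond in conditions:
                cell = sub[
                    (sub["trial_type"] == "stop")
                    & (sub["condition"] == cond)
                    & (sub["ssd_ms"] == ssd)
                ]
                n_stop = len(cell)
                n_fail = int((cell["label"] == "stop_fail").sum())
                failed_rts = cell.loc[cell["label"] == "stop_fail", "rt_ms"].to_numpy(dtype=float)
                stop_rows.append(
                    {
                        "participant": p,
                        "ssd_ms": int(ssd),
                        "condition": cond,
                        "n_stop": n_stop,
                        "n_fail": n_fail,
                        "p_fail": n_fail / n_stop if n_stop else np.nan,
                        "mean_failed_rt": failed_rts.mean() if failed_rts.size else np.nan,
                        "sd_failed_rt": failed_rts.std(ddof=1) if failed_rts.size > 1 else np.nan,
                        "empty_cell": n_stop == 0,
                        "no_failed_rt": n_fail == 0,
                    }
                )

    return SummaryTables(
        go_summary=pd.DataFrame(go_rows),
        stop_summary=pd.DataFrame(stop_rows),
    )


# ---------------------------------------------------------------------------
# trial-log I/O


def write_trial_log(records: Iterable[TrialRecord] | pd.DataFrame, path: str | Path) -> None:
    """Write the trial-log CSV schema (empty fields for absent values)."""
    df = _as_frame(records)
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIAL_LOG_COLUMNS)
        for row in df.itertuples(index=False):
            writer.writerow(
                [
                    row.participant,
                    int(row.block),
                    int(row.position),
                    row.picture,
                    row.condition,
                    row.trial_type,
                    "" if pd.isna(row.ssd_ms) or row.ssd_ms is None else int(row.ssd_ms),
                    bool(row.responded),
                    "" if row.rt_ms is None or pd.isna(row.rt_ms) else f"{row.rt_ms:.3f}",
                    "" if row.name_correct is None or pd.isna(row.name_correct) else bool(row.name_correct),
                    "" if row.disfluent is None or pd.isna(row.disfluent) else bool(row.disfluent),
                ]
            )


def _parse_bool(s: str) -> bool | None:
    if s == "":
        return None
    return s == "True"


def read_trial_log(path: str | Path) -> pd.DataFrame:
    """Read a trial-log CSV back into the tidy DataFrame schema."""
    rows = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(TRIAL_LOG_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"trial log {path} is missing columns: {sorted(missing)}")
        for r in reader:
            rows.append(
                {
                    "participant": r["participant"],
                    "block": int(r["block"]),
                    "position": int(r["position"]),
                    "picture": r["picture"],
                    "condition": r["condition"],
                    "trial_type": r["trial_type"],
                    "ssd_ms": int(r["ssd_ms"]) if r["ssd_ms"] else None,
                    "responded": r["responded"] == "True",
                    "rt_ms": float(r["rt_ms"]) if r["rt_ms"] else None,
                    "name_correct": _parse_bool(r["name_correct"]),
                    "disfluent": _parse_bool(r["disfluent"]),
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)
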