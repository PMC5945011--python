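"""Stop-signal RT estimation (integration method, plus the mean method).

Integration method: rank-order the go RTs, find the nth one where
``n = round(N * p(respond | signal))`` (half-up, clamped to [1, N]), and
subtract the SSD.  Estimates are produced per participant x SSD x distractor
condition; the go-RT distribution of the matching condition is used
(correct go trials, untrimmed by default).

``p(respond | signal) = 0`` means the stop process always won in that cell;
the estimate is undefined and flagged missing rather than fabricated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import apply_trimming, classify_trials

__all__ = [
    "SSRTEstimate",
    "p_respond",
    "ssrt_integration",
    "ssrt_mean",
    "estimate_table",
    "table_to_estimates",
]


@dataclass(frozen=True)
class SSRTEstimate:
    """One cell of the participant x SSD x condition estimate table."""

    participant: str
    ssd_ms: int
    condition: str
    n_go: int
    n_stop: int
    n_respond: int
    p_respond: float
    nth_index: int | None
    nth_go_rt_ms: float | None
    ssrt_ms: float | None
    flag: str | None = None  # None = valid; else 'undefined_p_zero', 'empty_cell', 'no_go_rts'

    @property
    def valid(self) -> bool:
        return self.flag is None


def p_respond(
    classified: pd.DataFrame, participant: str, ssd_ms: int, condition: str
) -> tuple[float, int, int]:
    """P(respond | stop-signal) in one cell: responded-stop / total-stop counts.

    Returns ``(probability, n_respond, n_stop)``; an empty cell yields
    ``(nan, 0, 0)``.
    """
    cell = classified[
        (classified["participant"] == participant)
        & (classified["trial_type"] == "stop")
        & (classified["ssd_ms"] == ssd_ms)
        & (classified["condition"] == condition)
    ]
    n_stop = len(cell)
    n_resp = int(cell["responded"].astype(bool).sum())
    if n_stop == 0:
        return float("nan"), 0, 0
    return n_resp / n_stop, n_resp, n_stop


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def ssrt_integration(
    go_rts: Sequence[float], p: float, ssd_ms: int
) -> tuple[int | None, float | None, float | None]:
    """Core integration rule: ``(nth_index, nth_go_rt, ssrt)``.

    ``p = 0`` returns ``(None, None, None)`` (undefined estimate — the stop
    process always finished first, so the go distribution carries no
    information about its latency).
    """
    rts = np.sort(np.asarray(go_rts, dtype=float), kind="stable")
    if rts.size == 0:
        raise ValueError("go_rts must be non-empty")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p == 0.0:
        return None, None, None
    n = min(max(_round_half_up(rts.size * p), 1), rts.size)
    nth = float(rts[n - 1])
    return n, nth, nth - ssd_ms


def ssrt_mean(go_rts: Sequence[float], ssd_series: Sequence[float]) -> float:
    """Mean method for tracking data: mean go RT minus mean SSD.

    Valid when the staircase holds p(respond | signal) near 0.5.
    """
    go = np.asarray(go_rts, dtype=float)
    ssds = np.asarray(ssd_series, dtype=float)
    if go.size == 0 or ssds.size == 0:
        raise ValueError("go_rts and ssd_series must be non-empty")
    return float(go.mean() - ssds.mean())


def estimate_table(
    classified: pd.DataFrame,
    trimmed: bool = False,
    impute_misses: bool = False,
    pool_go_conditions: bool = False,
    trim_k: float = 2.5,
    response_window_ms: float = 1250.0,
) -> pd.DataFrame:
    """Integration-method SSRT per participant x SSD x condition.

    The go-RT distribution is the participant's correct go trials of the
    matching condition (all conditions pooled with ``pool_go_conditions``).
    ``trimmed`` applies the mean +/- 2.5 SD trim first; ``impute_misses``
    adds one RT at the response window per missed go trial.  Cells with an
    undefined estimate keep their counts but carry NaN SSRT and a non-null
    ``flag``.
    """
    if "label" not in classified.columns:
        classified = classify_trials(classified)
    if trimmed:
        classified = apply_trimming(classified, k=trim_k)

    rows = []
    participants = sorted(classified["participant"].unique())
    ssds = sorted(int(s) for s in classified.loc[
        classified["trial_type"] == "stop", "ssd_ms"
    ].dropna().unique())
    conditions = ["related", "unrelated"]

    for part in participants:
        sub = classified[classified["participant"] == part]
        for ssd in ssds:
            for cond in conditions:
                go_mask = sub["label"] == "go_correct"
                if not pool_go_conditions:
                    go_mask &= sub["condition"] == cond
                if trimmed:
                    go_mask &= sub["rt_retained"]
                go_rts = sub.loc[go_mask, "rt_ms"].to_numpy(dtype=float)
                if impute_misses:
                    miss_mask = sub["label"] == "go_miss"
                    if not pool_go_conditions:
                        miss_mask &= sub["condition"] == cond
                    n_miss = int(miss_mask.sum())
                    go_rts = np.concatenate(
                        [go_rts, np.full(n_miss, float(response_window_ms))]
                    )

                p, n_resp, n_stop = p_respond(sub, part, ssd, cond)
                flag = None
                nth_index = nth_rt = ssrt = None
                if n_stop == 0:
                    flag = "empty_cell"
                elif go_rts.size == 0:
                    flag = "no_go_rts"
                elif p == 0.0:
                    flag = "undefined_p_zero"
                else:
                    nth_index, nth_rt, ssrt = ssrt_integration(go_rts, p, ssd)

                rows.append(
                    {
                        "participant": part,
                        "ssd_ms": ssd,
                        "condition": cond,
                        "n_go": int(go_rts.size),
                        "n_stop": n_stop,
                        "n_respond": n_resp,
                        "p_respond": p,
                        "nth_index": nth_index,
                        "nth_go_rt_ms": nth_rt,
                        "ssrt_ms": ssrt,
                        "flag": flag,
                    }
                )
    return pd.DataFrame(rows)


def table_to_estimates(table: pd.DataFrame) -> list[SSRTEstimate]:
    """Rows of :func:`estimate_table` as typed records."""
    out = []
    for r in table.itertuples(index=False):
        out.append(
            SSRTEstimate(
                participant=r.participant,
                ssd_ms=int(r.ssd_ms),
                condition=r.condition,
                n_go=int(r.n_go),
                n_stop=int(r.n_stop),
                n_respond=int(r.n_respond),
                p_respond=float(r.p_respond),
                nth_index=None if pd.isna(r.nth_index) else int(r.nth_index),
                nth_go_rt_ms=None if pd.isna(r.nth_go_rt_ms) else float(r.nth_go_rt_ms),
                ssrt_ms=None if pd.isna(r.ssrt_ms) else float(r.ssrt_ms),
                flag=None if pd.isna(r.flag) else r.flag,
            )
        )
    return out
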