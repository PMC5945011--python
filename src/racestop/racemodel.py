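"""Independent horse-race simulator for go/stop trials.

A trial is a race between a go process (launched at picture onset) and, on
stop trials, a stop process launched at picture onset + SSD.  The response is
emitted iff the go process finishes first; go and stop finishing times are
sampled independently (context and stochastic independence are hard
assumptions of the model).  Latencies are ex-Gaussian by default; setting
``sigma = tau = 0`` gives the constant-latency mode used in analytic tests.

Responses escaping inhibition but landing beyond the response window are
unobservable and therefore count as successful stops.  Omissions, naming
errors and disfluencies are independent Bernoulli contamination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _st

from .design import ScheduleEntry

__all__ = [
    "ExGaussian",
    "RaceParameters",
    "TrialRecord",
    "run_trial",
    "simulate_experiment",
    "simulate_tracking",
]


@dataclass(frozen=True)
class ExGaussian:
    """Ex-Gaussian latency distribution (normal + exponential), in ms.

    ``sigma = tau = 0`` degenerates to a constant latency ``mu``.
    """

    mu: float
    sigma: float = 0.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.tau < 0:
            raise ValueError("sigma and tau must be non-negative")

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def sd(self) -> float:
        return math.hypot(self.sigma, self.tau)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        out = np.full(size if size is not None else (), self.mu, dtype=float)
        if self.sigma > 0:
            out = out + rng.normal(0.0, self.sigma, size=size)
        if self.tau > 0:
            out = out + rng.exponential(self.tau, size=size)
        return float(out) if size is None else out

    def cdf(self, x) -> np.ndarray | float:
        if self.sigma == 0 and self.tau == 0:
            return np.where(np.asarray(x, dtype=float) >= self.mu, 1.0, 0.0)
        if self.tau == 0:
            return _st.norm.cdf(x, loc=self.mu, scale=self.sigma)
        if self.sigma == 0:
            return _st.expon.cdf(x, loc=self.mu, scale=self.tau)
        return _st.exponnorm.cdf(x, K=self.tau / self.sigma, loc=self.mu, scale=self.sigma)

    def ppf(self, q) -> np.ndarray | float:
        if self.sigma == 0 and self.tau == 0:
            return np.full_like(np.asarray(q, dtype=float), self.mu)
        if self.tau == 0:
            return _st.norm.ppf(q, loc=self.mu, scale=self.sigma)
        if self.sigma == 0:
            return _st.expon.ppf(q, loc=self.mu, scale=self.tau)
        return _st.exponnorm.ppf(q, K=self.tau / self.sigma, loc=self.mu, scale=self.sigma)


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class RaceParameters:
    """Per-condition go/stop latency distributions plus contamination rates."""

    go: Mapping[str, ExGaussian]
    stop: Mapping[str, ExGaussian]
    p_omission: float = 0.0
    p_name_error: float = 0.0
    p_disfluency: float = 0.0
    response_window_ms: float = 1250.0

    def __post_init__(self) -> None:
        for cond in ("related", "unrelated"):
            if cond not in self.go or cond not in self.stop:
                raise ValueError(f"go/stop distributions must cover condition {cond!r}")
        _check_prob("p_omission", self.p_omission)
        _check_prob("p_name_error", self.p_name_error)
        _check_prob("p_disfluency", self.p_disfluency)
        if self.response_window_ms <= 0:
            raise ValueError("response_window_ms must be positive")

    def to_dict(self) -> dict:
        return {
            "go": {c: asdict(d) for c, d in self.go.items()},
            "stop": {c: asdict(d) for c, d in self.stop.items()},
            "p_omission": self.p_omission,
            "p_name_error": self.p_name_error,
            "p_disfluency": self.p_disfluency,
            "response_window_ms": self.response_window_ms,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RaceParameters":
        return cls(
            go={c: ExGaussian(**v) for c, v in d["go"].items()},
            stop={c: ExGaussian(**v) for c, v in d["stop"].items()},
            p_omission=d.get("p_omission", 0.0),
            p_name_error=d.get("p_name_error", 0.0),
            p_disfluency=d.get("p_disfluency", 0.0),
            response_window_ms=d.get("response_window_ms", 1250.0),
        )


@dataclass(frozen=True)
class TrialRecord:
    """One executed (simulated) trial."""

    participant: str
    block: int
    position: int
    picture: str
    condition: str
    trial_type: str
    ssd_ms: int | None
    responded: bool
    rt_ms: float | None
    name_correct: bool | None
    disfluent: bool | None

    def __post_init__(self) -> None:
        if self.responded != (self.rt_ms is not None):
            raise ValueError("rt_ms must be present iff responded")
        if self.rt_ms is not None and self.rt_ms <= 0:
            raise ValueError("rt_ms must be positive")


def run_trial(
    entry: ScheduleEntry, params: RaceParameters, rng: np.random.Generator
) -> TrialRecord:
    """Race a single trial and return its outcome record.

    Go trial: the response is emitted at the go finishing time unless an
    omission occurs or the finish exceeds the response window.  Stop trial:
    the response is emitted iff the go process beats SSD + stop latency (and
    lands within the window); its RT is the go finishing time.
    """
    go_finish = params.go[entry.condition].sample(rng)
    omitted = rng.random() < params.p_omission

    if entry.trial_type == "stop":
        stop_finish = params.stop[entry.condition].sample(rng)
        responded = (go_finish < entry.ssd_ms + stop_finish) and (
            go_finish <= params.response_window_ms
        )
    else:
        responded = (not omitted) and go_finish <= params.response_window_ms

    if responded:
        name_correct = rng.random() >= params.p_name_error
        disfluent = rng.random() < params.p_disfluency
        rt: float | None = float(go_finish)
    else:
        name_correct = disfluent = None
        rt = None

    return TrialRecord(
        participant=entry.participant,
        block=entry.block,
        position=entry.position,
        picture=entry.picture,
        condition=entry.condition,
        trial_type=entry.trial_type,
        ssd_ms=entry.ssd_ms,
        responded=responded,
        rt_ms=rt,
        name_correct=name_correct,
        disfluent=disfluent,
    )


def simulate_experiment(
    schedule: Sequence[ScheduleEntry], params: RaceParameters, seed: int | np.random.Generator
) -> list[TrialRecord]:
    """Simulate every trial of a schedule; fully reproducible from the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [run_trial(entry, params, rng) for entry in schedule]


def simulate_tracking(
    params: RaceParameters,
    initial_ssd_ms: int,
    n_stop_trials: int,
    rng: np.random.Generator,
    step_ms: int = 50,
    condition: str = "unrelated",
) -> list[tuple[int, bool]]:
    """One-up/one-down SSD staircase over consecutive stop trials.

    After each successful inhibition the SSD increases by ``step_ms``; after
    each failed inhibition it decreases by the same step, floored at 0.
    Returns the (ssd, responded) sequence.
    """
    if step_ms <= 0:
        raise ValueError("step_ms must be positive")
    ssd = int(initial_ssd_ms)
    out: list[tuple[int, bool]] = []
    go_dist = params.go[condition]
    stop_dist = params.stop[condition]
    for _ in range(n_stop_trials):
        go_finish = go_dist.sample(rng)
        stop_finish = stop_dist.sample(rng)
        responded = (go_finish < ssd + stop_finish) and go_finish <= params.response_window_ms
        out.append((ssd, responded))
        ssd = max(0, ssd - step_ms) if responded else ssd + step_ms
    return out


def records_to_frame(records: Iterable[TrialRecord]):
    """Trial records as a tidy pandas DataFrame (trial-log schema)."""
    import pandas as pd

    rows = [asdict(r) for r in records]
    df = pd.DataFrame(
        rows,
        columns=[
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
        ],
    )
    return df
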