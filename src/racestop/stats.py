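"""Within-subject permutation inference.

Paired contrasts are tested by sign-flip permutation of the per-participant
differences: under the null of no condition effect each participant's
difference is symmetric around zero, so flipping signs generates the null
distribution of the mean difference.  With few participants the full set of
2^n sign patterns is enumerated exactly; otherwise random flips with the
add-one Monte-Carlo correction are used.

For the 2 x 2 (SSD x distractor) layout the two main effects are marginal
paired contrasts and the interaction is the per-participant double
difference, each tested with the same sign-flip machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

__all__ = ["PairedEffect", "paired_permutation", "factorial_permutation"]


@dataclass(frozen=True)
class PairedEffect:
    """Mean within-participant difference with its permutation p-value."""

    effect: float
    n: int
    p_value: float
    n_permutations: int
    seed: int | None
    method: str  # 'exact' or 'monte-carlo'


@lru_cache(maxsize=8)
def _sign_matrix(n: int) -> np.ndarray:
    """All 2^n sign patterns, shape (2^n, n)."""
    bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
    return bits * 2.0 - 1.0


def _signflip_p(diffs: np.ndarray, n_perm: int, seed: int | None, method: str) -> PairedEffect:
    n = diffs.size
    if n < 2:
        raise ValueError("need at least 2 participants")
    obs = float(diffs.mean())

    if method == "auto":
        method = "exact" if 2**n <= n_perm else "monte-carlo"

    if method == "exact":
        signs = _sign_matrix(n)
        null = signs @ diffs / n
        # all patterns enumerated; the identity pattern makes p strictly positive
        p = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
        return PairedEffect(obs, n, p, signs.shape[0], seed, "exact")

    if method != "monte-carlo":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = signs @ diffs / n
    exceed = int(np.sum(np.abs(null) >= abs(obs) - 1e-12))
    p = (exceed + 1) / (n_perm + 1)
    return PairedEffect(obs, n, p, n_perm, seed, "monte-carlo")


def paired_permutation(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
) -> PairedEffect:
    """Two-sided sign-flip permutation test of mean(a - b) over participants.

    ``a`` and ``b`` must be aligned by participant.  ``method='auto'``
    enumerates all sign patterns exactly whenever ``2^n <= n_perm``.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape or av.ndim != 1:
        raise ValueError("a and b must be 1-d and aligned by participant")
    if np.isnan(av).any() or np.isnan(bv).any():
        raise ValueError("missing values must be dropped (listwise) before testing")
    return _signflip_p(av - bv, n_perm=n_perm, seed=seed, method=method)


def factorial_permutation(
    cells: np.ndarray | Sequence,
    n_perm: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
) -> dict[str, PairedEffect]:
    """2 x 2 within-subject permutation tests.

    ``cells`` has shape (n_participants, 2, 2): axis 1 indexes the first
    factor (e.g. SSD 250/325), axis 2 the second (e.g. unrelated/related).
    Participants with any missing cell are dropped (listwise).  Returns
    ``{'factor_a', 'factor_b', 'interaction'}`` effects, each defined so that
    a positive value means level 2 exceeds level 1 (interaction: the
    factor-b contrast grows from level 1 to level 2 of factor a).
    """
    arr = np.asarray(cells, dtype=float)
    if arr.ndim != 3 or arr.shape[1:] != (2, 2):
        raise ValueError("cells must have shape (n, 2, 2)")
    complete = ~np.isnan(arr).any(axis=(1, 2))
    arr = arr[complete]
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 complete participants")

    a_contrast = arr[:, 1, :].mean(axis=1) - arr[:, 0, :].mean(axis=1)
    b_contrast = arr[:, :, 1].mean(axis=1) - arr[:, :, 0].mean(axis=1)
    interaction = (arr[:, 1, 1] - arr[:, 1, 0]) - (arr[:, 0, 1] - arr[:, 0, 0])

    seeds = (
        (None, None, None)
        if seed is None
        else tuple(int(s) for s in np.random.SeedSequence(seed).generate_state(3))
    )
    return {
        "factor_a": _signflip_p(a_contrast, n_perm, seeds[0], method),
        "factor_b": _signflip_p(b_contrast, n_perm, seeds[1], method),
        "interaction": _signflip_p(interaction, n_perm, seeds[2], method),
    }
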