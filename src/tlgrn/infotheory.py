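"""Entropy, mutual information and their time-lagged variants on binary sequences.

All quantities are plug-in (maximum-likelihood) estimates from empirical
symbol frequencies, in bits (log base 2), with the 0·log 0 ≡ 0 convention and
no pseudocounts.  The time-lagged variants align a regulator's activity with
the delayed response of its target: for a lag τ the regulator (and any
conditioning gene) keeps time points 1…m−τ while the target keeps τ+1…m, and
the plain metric is evaluated on the trimmed, equal-length sequences.

Tiny negative floating-point results (within −1e−12) are clamped to zero;
anything more negative indicates a bug and raises.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import InternalConsistencyError, ValidationError

logger = logging.getLogger(__name__)

#: clamp window for floating-point noise in MI/CMI
EPS = 1e-12

#: minimum number of overlapping time points any lagged metric may use
MIN_OVERLAP = 4

__all__ = [
    "EPS",
    "MIN_OVERLAP",
    "entropy",
    "joint_entropy2",
    "joint_entropy3",
    "mutual_information",
    "conditional_mutual_information",
    "lag_trim_pair",
    "tlmi",
    "tlcmi",
]


def _as_binary(x, name: str = "sequence") -> np.ndarray:
    a = np.asarray(x)
    if a.ndim != 1 or a.size == 0:
        raise ValidationError(f"{name} must be a non-empty 1-D sequence")
    if not np.isin(a, (0, 1)).all():
        raise ValidationError(f"{name} must contain only 0 and 1")
    return a.astype(np.int64)


def _check_same_length(*seqs: np.ndarray) -> int:
    lengths = {s.size for s in seqs}
    if len(lengths) != 1:
        raise ValidationError(f"sequences differ in length: {sorted(lengths)}")
    return lengths.pop()


def _plugin_entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _clamp(value: float, what: str) -> float:
    if value < -EPS:
        raise InternalConsistencyError(f"{what} = {value} below -{EPS}")
    return max(value, 0.0)


def entropy(a) -> float:
    """Shannon entropy H(A) of a binary sequence, in bits (∈ [0, 1])."""
    a = _as_binary(a, "a")
    return _plugin_entropy(np.bincount(a, minlength=2))


def joint_entropy2(a, b) -> float:
    """Joint entropy H(A,B) over the four joint symbol frequencies."""
    a, b = _as_binary(a, "a"), _as_binary(b, "b")
    _check_same_length(a, b)
    return _plugin_entropy(np.bincount(2 * a + b, minlength=4))


def joint_entropy3(a, b, c) -> float:
    """Joint entropy H(A,B,C) over the eight joint cells."""
    a, b, c = _as_binary(a, "a"), _as_binary(b, "b"), _as_binary(c, "c")
    _check_same_length(a, b, c)
    return _plugin_entropy(np.bincount(4 * a + 2 * b + c, minlength=8))


def mutual_information(a, b) -> float:
    """MI(A;B) = H(A) + H(B) − H(A,B), clamped to be non-negative."""
    a, b = _as_binary(a, "a"), _as_binary(b, "b")
    _check_same_length(a, b)
    return _clamp(entropy(a) + entropy(b) - joint_entropy2(a, b), "MI")


def conditional_mutual_information(a, b, c) -> float:
    """CMI(A;B|C) = H(A,C) + H(B,C) − H(C) − H(A,B,C), clamped ≥ 0."""
    a, b, c = _as_binary(a, "a"), _as_binary(b, "b"), _as_binary(c, "c")
    _check_same_length(a, b, c)
    value = (
        joint_entropy2(a, c)
        + joint_entropy2(b, c)
        - entropy(c)
        - joint_entropy3(a, b, c)
    )
    return _clamp(value, "CMI")


def lag_trim_pair(a, b, tau: int, min_overlap: int = MIN_OVERLAP):
    """Trim a regulator/target pair to their lag-τ overlap.

    Returns ``(a[1..m−τ], b[τ+1..m])`` in 1-based terms: the regulator loses
    its last τ symbols, the target its first τ, leaving two aligned sequences
    of length m−τ.
    """
    a, b = _as_binary(a, "a"), _as_binary(b, "b")
    m = _check_same_length(a, b)
    if tau < 0:
        raise ValidationError(f"lag must be non-negative, got {tau}")
    if m - tau < min_overlap:
        raise ValidationError(
            f"lag {tau} leaves {m - tau} overlapping points, fewer than "
            f"min_overlap={min_overlap}"
        )
    if tau == 0:
        return a, b
    return a[:-tau], b[tau:]


def tlmi(a, b, tau: int, min_overlap: int = MIN_OVERLAP) -> float:
    """Time-lagged MI: MI over the lag-trimmed pair.  Equals MI at τ = 0.

    Not symmetric for τ > 0 — the regulator and target are trimmed at
    opposite ends.
    """
    ta, tb = lag_trim_pair(a, b, tau, min_overlap)
    return mutual_information(ta, tb)


def tlcmi(a, b, c, tau: int, min_overlap: int = MIN_OVERLAP) -> float:
    """Time-lagged CMI: CMI over (a[1..m−τ], b[τ+1..m], c[1..m−τ]).

    The conditioning gene is trimmed on the regulator side, keeping it
    synchronous with the regulator.  Equals CMI at τ = 0.
    """
    a, b, c = _as_binary(a, "a"), _as_binary(b, "b"), _as_binary(c, "c")
    m = _check_same_length(a, b, c)
    ta, tb = lag_trim_pair(a, b, tau, min_overlap)
    tc = c[: m - tau] if tau else c
    return conditional_mutual_information(ta, tb, tc)
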