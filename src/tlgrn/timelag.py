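"""Regulatory time lags between gene pairs.

A regulator can act on a target only while it is up-regulated (ON), so the
lag from gene A to gene B is defined as the time from A's initial
up-regulation to B's first expression change after that moment.  This
construction is non-negative by design, unlike the classic definition
(difference of the two genes' initial change times) which goes negative for
one direction of every asynchronous pair; both are provided, the classic one
(``zou_lag``) for comparison only.

All time points are 1-based and assumed equally spaced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .infotheory import MIN_OVERLAP
from .preprocess import BinaryExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LagMatrix",
    "initial_change_time",
    "initial_upregulation_time",
    "first_change_after",
    "proposed_lag",
    "zou_lag",
    "lag_matrix",
    "unit_lags",
]


@dataclass
class LagMatrix:
    """Per-ordered-pair lags τ(i→j) with a fallback flag.

    ``fallback[i, j]`` is set where no lag could be computed from the data
    (or the computed lag left too short an overlap) and the default was
    substituted.  The diagonal is unused.
    """

    tau: np.ndarray       # (n, n) non-negative int
    fallback: np.ndarray  # (n, n) bool

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=np.int64)
        self.fallback = np.asarray(self.fallback, dtype=bool)
        if self.tau.shape != self.fallback.shape or self.tau.ndim != 2:
            raise ValidationError("lag and fallback grids must share an (n, n) shape")
        if (self.tau < 0).any():
            raise ValidationError("lags must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.tau.shape[0]


def _seq(x) -> np.ndarray:
    a = np.asarray(x)
    if a.ndim != 1 or a.size == 0 or not np.isin(a, (0, 1)).all():
        raise ValidationError("expected a non-empty binary sequence")
    return a.astype(np.int64)


def initial_change_time(x) -> int | None:
    """First 1-based t ≥ 2 with x(t) ≠ x(t−1); ``None`` for a constant gene."""
    x = _seq(x)
    changes = np.flatnonzero(x[1:] != x[:-1])
    return int(changes[0]) + 2 if changes.size else None


def initial_upregulation_time(x) -> int | None:
    """1-based time of the first OFF→ON switch.

    A gene already ON at t = 1 has no observable switch and is taken to
    up-regulate at t = 1; a gene that is never ON has no up-regulation time.
    """
    x = _seq(x)
    if x[0] == 1:
        return 1
    ups = np.flatnonzero((x[:-1] == 0) & (x[1:] == 1))
    return int(ups[0]) + 2 if ups.size else None


def first_change_after(x, t0: int) -> int | None:
    """Smallest 1-based t > t0 with x(t) ≠ x(t−1), or ``None``."""
    x = _seq(x)
    if not 1 <= t0 <= x.size:
        raise ValidationError(f"t0={t0} outside [1, {x.size}]")
    changes = np.flatnonzero(x[1:] != x[:-1]) + 2  # 1-based change times, all ≥ 2
    later = changes[changes > t0]
    return int(later[0]) if later.size else None


def proposed_lag(a, b) -> int | None:
    """Non-negative lag τ(A→B): target's first change after A's up-regulation.

    Returns ``None`` (undefined, not an error) when A never up-regulates or
    B never changes afterwards; otherwise the result is ≥ 1 by construction.
    """
    ua = initial_upregulation_time(a)
    if ua is None:
        return None
    cb = first_change_after(b, ua)
    if cb is None:
        return None
    return cb - ua


def zou_lag(a, b) -> int:
    """Classic lag: target's initial change time minus the regulator's.

    May be negative; kept only to demonstrate the negative-lag problem the
    non-negative construction removes.
    """
    ia, ib = initial_change_time(a), initial_change_time(b)
    if ia is None or ib is None:
        raise ValidationError("classic lag undefined: a gene never changes state")
    return ib - ia


def lag_matrix(
    bm: BinaryExpressionMatrix,
    default_tau: int = 1,
    min_overlap: int = MIN_OVERLAP,
) -> LagMatrix:
    """Lags for every ordered gene pair, with fallback to ``default_tau``.

    A pair falls back (flag set) when its lag is undefined from the data or
    would leave fewer than ``min_overlap`` overlapping time points.
    """
    if default_tau < 1:
        raise ValidationError("default_tau must be ≥ 1")
    n, m = bm.n_genes, bm.n_timepoints
    if m - default_tau < min_overlap:
        raise ValidationError(
            f"default lag {default_tau} leaves under {min_overlap} points"
        )
    tau = np.full((n, n), default_tau, dtype=np.int64)
    fallback = np.zeros((n, n), dtype=bool)
    up_times = [initial_upregulation_time(bm.row(i)) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            lag = None
            if up_times[i] is not None:
                cb = first_change_after(bm.row(j), up_times[i])
                if cb is not None:
                    lag = cb - up_times[i]
            if lag is None or m - lag < min_overlap:
                fallback[i, j] = True
            else:
                tau[i, j] = lag
    n_fb = int(fallback.sum())
    if n_fb:
        logger.debug("lag fallback (τ=%d) applied to %d/%d ordered pairs",
                     default_tau, n_fb, n * (n - 1))
    return LagMatrix(tau, fallback)


def unit_lags(n: int) -> LagMatrix:
    """Unit-delay lag matrix (τ ≡ 1), the legacy MDL/PMDL assumption."""
    return LagMatrix(np.ones((n, n), dtype=np.int64), np.zeros((n, n), dtype=bool))
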