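"""Internal helpers: conditional code lengths and the threshold-sweep engine.

Both inference schemes score candidate networks gene by gene.  For a target
gene j with parent set S and per-parent lags τ(i→j), the target is read over
the common overlap window t ∈ [max τ + 1, m] (1-based) and each parent i at
t − τ(i→j); a parentless gene uses the default lag's window so that all
candidates for the same gene code a comparable stretch of the series.

Two coders are provided over the resulting (context, target-symbol) stream:

* a batch Laplace (add-½) code, used by the network-MDL data length;
* the Krichevsky–Trofimov sequential code — each symbol is predicted from
  the counts seen so far in its context, (c + ½)/(total + 1) — used by the
  predictive (PMDL) data length.

The sweep engine exploits that parent sets are nested along the threshold
sweep (parents(j) at θ is {i : score(i,j) ≥ θ}), so each gene has at most
n distinct parent sets to evaluate across all n² candidate thresholds.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError
from .timelag import LagMatrix

logger = logging.getLogger(__name__)

#: warn once a conditional probability table would exceed this many entries
CPT_WARN_ENTRIES = 2 ** 16


def context_target_stream(
    values: np.ndarray,
    j: int,
    parents: Sequence[int],
    lags: LagMatrix,
    default_tau: int,
) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """Aligned (parent-state context, target symbol) pairs for gene j.

    Contexts are tuples of the parents' symbols, each parent read τ(i→j)
    steps before the target symbol; the stream covers the common overlap
    window.  Time order is preserved (required by the sequential coder).
    """
    m = values.shape[1]
    taus = [int(lags.tau[i, j]) for i in parents]
    tau_max = max(taus, default=default_tau)
    if m - tau_max < 1:
        raise ValidationError(f"gene {j}: lag window empty (max lag {tau_max}, m={m})")
    window = range(tau_max, m)  # 0-based target positions
    targets = values[j, tau_max:m].astype(np.int64)
    if not parents:
        return [()] * len(targets), targets
    cols = [values[i, tau_max - t : m - t] for i, t in zip(parents, taus)]
    contexts = list(zip(*(c.astype(np.int64) for c in cols)))
    return contexts, targets


def laplace_code_length(contexts: list[tuple[int, ...]], targets: np.ndarray) -> float:
    """Batch add-½ code: Σ_t −log₂ [(n(x_t, c_t) + ½) / (n(c_t) + 1)]."""
    pair_counts: dict[tuple[tuple[int, ...], int], int] = {}
    ctx_counts: dict[tuple[int, ...], int] = {}
    for c, x in zip(contexts, targets):
        pair_counts[(c, int(x))] = pair_counts.get((c, int(x)), 0) + 1
        ctx_counts[c] = ctx_counts.get(c, 0) + 1
    bits = 0.0
    for (c, _x), n_cx in pair_counts.items():
        bits += n_cx * -math.log2((n_cx + 0.5) / (ctx_counts[c] + 1))
    return bits


def kt_code_length(contexts: list[tuple[int, ...]], targets: np.ndarray) -> float:
    """Krichevsky–Trofimov sequential code length in bits.

    Symbols are processed in time order; within each context the t-th symbol
    is predicted with probability (count so far + ½)/(total so far + 1).
    """
    counts: dict[tuple[int, ...], list[int]] = {}
    bits = 0.0
    for c, x in zip(contexts, targets):
        cnt = counts.setdefault(c, [0, 0])
        bits += -math.log2((cnt[int(x)] + 0.5) / (cnt[0] + cnt[1] + 1))
        cnt[int(x)] += 1
    return bits


def model_length_bits(k: int, n_genes: int, cpt_entry_bits: float) -> float:
    """Structure + CPT-memory cost of a gene with k parents; 0 for k = 0."""
    if k == 0:
        return 0.0
    if 2 ** k > CPT_WARN_ENTRIES:
        logger.warning(
            "conditional probability table with 2^%d entries; "
            "consider capping max_parents", k,
        )
    return k * math.log2(n_genes) + (2.0 ** k) * cpt_entry_bits


def sweep_thresholds(
    scores: np.ndarray,
    gene_objective: Callable[[int, tuple[int, ...]], tuple[float, float]],
    lam: float,
    max_parents: int | None = None,
) -> tuple[float, list[tuple[float, float, float, float]]]:
    """Exhaustive threshold sweep over every distinct score plus a +∞ sentinel.

    ``gene_objective(j, parents)`` returns (model_bits, data_bits) for gene j
    under the given parent set; the candidate total is λ·Σ model + Σ data.
    Returns the chosen threshold and the full trace of
    (threshold, model_bits, data_bits, total_bits), ties broken toward the
    larger threshold (the sparser network).  Candidates where any gene would
    exceed ``max_parents`` are skipped.
    """
    n = scores.shape[0]
    finite = scores[np.isfinite(scores)]
    thresholds = sorted(set(finite.tolist())) + [math.inf]

    # per gene: parent count at each threshold, and a nested-prefix cache
    col_scores = [scores[:, j] for j in range(n)]
    order = [
        np.argsort(-np.nan_to_num(col, nan=-math.inf), kind="stable")
        for col in col_scores
    ]
    cache: list[dict[int, tuple[float, float]]] = [dict() for _ in range(n)]

    def gene_terms(j: int, k: int) -> tuple[float, float]:
        if k not in cache[j]:
            parents = tuple(int(i) for i in order[j][:k])
            cache[j][k] = gene_objective(j, parents)
        return cache[j][k]

    trace: list[tuple[float, float, float, float]] = []
    best_theta, best_total = math.inf, math.inf
    for theta in thresholds:
        ks = [
            int(np.sum(col_scores[j][np.isfinite(col_scores[j])] >= theta))
            if theta != math.inf
            else 0
            for j in range(n)
        ]
        if max_parents is not None and any(k > max_parents for k in ks):
            continue
        model = data = 0.0
        for j, k in enumerate(ks):
            mj, dj = gene_terms(j, k)
            model += mj
            data += dj
        total = lam * model + data
        trace.append((theta, model, data, total))
        if total <= best_total:  # later thresholds are larger: sparser wins ties
            best_total, best_theta = total, theta
    return best_theta, trace
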