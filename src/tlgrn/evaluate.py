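"""Precision/recall scoring and data-size (saturation) studies.

Edges are matched directed: A→B in the inferred network counts as correct
only if A→B (not B→A) is in the true network.  Degenerate cases use logged
conventions — precision is 1 when nothing was inferred (nothing asserted
falsely) and recall is 1 when the true network is empty — so data-size
sweeps stay total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .infotheory import entropy, joint_entropy2, mutual_information
from .io import GeneNetwork
from .mdl import MDLConfig, infer_mdl
from .pmdl import PMDLConfig, infer_pmdl
from .preprocess import BinaryExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "confusion_counts",
    "precision_recall",
    "saturation_sweep",
    "mi_curve_study",
]


@dataclass
class EvaluationReport:
    """Directed-edge confusion counts and the derived accuracy fractions.

    ``ce``: edges in both networks; ``me``: true edges missed; ``fe``:
    inferred edges absent from the truth.  ``ratio`` is recall/precision
    (None when precision is 0).
    """

    ce: int
    me: int
    fe: int
    precision: float
    recall: float
    ratio: float | None


def _undirect(edges: frozenset[tuple[str, str]]) -> frozenset[tuple[str, str]]:
    return frozenset(tuple(sorted(e)) for e in edges)


def confusion_counts(
    true_net: GeneNetwork,
    inferred: GeneNetwork,
    undirected: bool = False,
) -> tuple[int, int, int]:
    """(Ce, Me, Fe) over directed edges (or undirected with the flag)."""
    if set(true_net.gene_ids) != set(inferred.gene_ids):
        raise ValidationError("true and inferred networks cover different genes")
    t, f = true_net.edges, inferred.edges
    if undirected:
        t, f = _undirect(t), _undirect(f)
    ce = len(t & f)
    return ce, len(t) - ce, len(f) - ce


def precision_recall(counts: tuple[int, int, int]) -> EvaluationReport:
    """P = Ce/(Ce+Fe), R = Ce/(Ce+Me), ratio = R/P.

    Conventions for empty denominators: P = 1 when no edges were inferred,
    R = 1 when the true network is empty (both logged).
    """
    ce, me, fe = counts
    if min(counts) < 0:
        raise ValidationError("confusion counts must be non-negative")
    if ce + fe == 0:
        logger.info("no edges inferred; precision set to 1 by convention")
        precision = 1.0
    else:
        precision = ce / (ce + fe)
    if ce + me == 0:
        logger.info("true network empty; recall set to 1 by convention")
        recall = 1.0
    else:
        recall = ce / (ce + me)
    ratio = recall / precision if precision > 0 else None
    return EvaluationReport(ce, me, fe, precision, recall, ratio)


def _run_algorithm(
    bm: BinaryExpressionMatrix, algorithm: str, time_lagged: bool, **cfg_kwargs
) -> GeneNetwork:
    if algorithm == "mdl":
        return infer_mdl(bm, MDLConfig(time_lagged=time_lagged, **cfg_kwargs)).network
    if algorithm == "pmdl":
        return infer_pmdl(bm, PMDLConfig(time_lagged=time_lagged, **cfg_kwargs)).network
    raise ValidationError(f"unknown algorithm {algorithm!r} (expected 'mdl' or 'pmdl')")


def saturation_sweep(
    bm: BinaryExpressionMatrix,
    true_net: GeneNetwork,
    algorithm: str = "pmdl",
    time_lagged: bool = True,
    start: int = 15,
    step: int = 5,
    **cfg_kwargs,
) -> list[tuple[int, float, float, float | None]]:
    """Run inference on growing prefixes of the series and score each run.

    Returns one (m_used, precision, recall, recall/precision) row per prefix
    length start, start+step, … ≤ m.  A 75-point series at the default
    start/step yields 13 rows.
    """
    m = bm.n_timepoints
    if m < start:
        raise ValidationError(f"series has {m} points, fewer than start={start}")
    rows = []
    for m_used in range(start, m + 1, step):
        net = _run_algorithm(bm.prefix(m_used), algorithm, time_lagged, **cfg_kwargs)
        rep = precision_recall(confusion_counts(true_net, net))
        rows.append((m_used, rep.precision, rep.recall, rep.ratio))
    return rows


def mi_curve_study(
    bm: BinaryExpressionMatrix,
    prefix_lengths: list[int],
) -> list[tuple[int, float, float, float]]:
    """Mean entropy, conditional entropy and MI as functions of data size.

    For each prefix length L: the mean over genes of H(gene), and the means
    over all ordered gene pairs (A, B), A ≠ B, of H(A|B) = H(A,B) − H(B) and
    MI(A;B), all computed on the first L time points.  Used to exhibit the
    saturation of pairwise MI with growing data size.
    """
    rows = []
    n = bm.n_genes
    for length in prefix_lengths:
        sub = bm.prefix(length)
        ents = [entropy(sub.row(i)) for i in range(n)]
        cond, mis = [], []
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                cond.append(joint_entropy2(sub.row(i), sub.row(j)) - ents[j])
                mis.append(mutual_information(sub.row(i), sub.row(j)))
        rows.append(
            (length, float(np.mean(ents)), float(np.mean(cond)), float(np.mean(mis)))
        )
    return rows
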