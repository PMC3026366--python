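"""Independent brute-force re-implementations used only as test oracles.

Everything here is written with plain Python loops and dicts, deliberately
sharing no code with the package internals: given a score matrix and a lag
grid, enumerate every distinct-threshold candidate network and price it
naively.
"""

import math


def stream(values, j, parents, tau, default_tau=1):
    """(context, target) pairs for gene j: target over the common overlap
    window, each parent read tau[i][j] steps earlier."""
    m = len(values[j])
    taus = [tau[i][j] for i in parents]
    tau_max = max(taus, default=default_tau)
    pairs = []
    for t in range(tau_max, m):
        ctx = tuple(values[i][t - d] for i, d in zip(parents, taus))
        pairs.append((ctx, values[j][t]))
    return pairs


def laplace_bits(pairs):
    ctx_n, pair_n = {}, {}
    for c, x in pairs:
        ctx_n[c] = ctx_n.get(c, 0) + 1
        pair_n[(c, x)] = pair_n.get((c, x), 0) + 1
    bits = 0.0
    for (c, x), ncx in pair_n.items():
        bits -= ncx * math.log2((ncx + 0.5) / (ctx_n[c] + 1))
    return bits


def kt_bits(pairs):
    counts = {}
    bits = 0.0
    for c, x in pairs:
        n0, n1 = counts.get(c, (0, 0))
        nx = n1 if x == 1 else n0
        bits -= math.log2((nx + 0.5) / (n0 + n1 + 1))
        counts[c] = (n0 + (x == 0), n1 + (x == 1))
    return bits


def model_bits(k, n, cpt_entry_bits):
    return 0.0 if k == 0 else k * math.log2(n) + 2 ** k * cpt_entry_bits


def parents_at(scores, j, theta):
    n = len(scores)
    return [
        i for i in range(n)
        if i != j and scores[i][j] == scores[i][j] and scores[i][j] >= theta
    ]


def candidate_totals(values, scores, tau, *, lam, cpt_entry_bits, default_tau,
                     predictive):
    """(threshold, total) for every distinct score plus the empty model."""
    n = len(scores)
    distinct = sorted(
        {scores[i][j] for i in range(n) for j in range(n)
         if i != j and scores[i][j] == scores[i][j]}
    )
    out = []
    for theta in distinct + [math.inf]:
        total = 0.0
        for j in range(n):
            ps = parents_at(scores, j, theta) if theta != math.inf else []
            pairs = stream(values, j, ps, tau, default_tau)
            if predictive:
                total += kt_bits(pairs)
            else:
                total += lam * model_bits(len(ps), n, cpt_entry_bits)
                total += laplace_bits(pairs)
        out.append((theta, total))
    return out
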