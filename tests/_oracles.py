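"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain loops, explicit
formulas, scipy.stats.pearsonr. They define the expected behaviour of the
module-partitioned scorer and of the area under the self-rank curve.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import pearsonr


def brute_force_scores(values, gene_ids, assignment, bait_genes, min_baits=1):
    """Direct module-partitioned scoring.

    values: (n_genes, n_samples) array; gene_ids: row labels;
    assignment: gene -> module (genes absent are unclustered);
    bait_genes: iterable of gene ids.

    Returns list of (gene_id, module_id, raw, z, rank) sorted by rank.
    """
    idx = {g: i for i, g in enumerate(gene_ids)}
    baits = [g for g in bait_genes if g in idx]
    modules = {}
    for g, m in assignment.items():
        modules.setdefault(m, []).append(g)
    scored = []
    for mod, members in modules.items():
        mod_baits = [g for g in members if g in baits]
        if len(mod_baits) < min_baits:
            continue
        cands = [g for g in members if g not in bait_genes]
        if not cands:
            continue
        raws = []
        for g in cands:
            rs = []
            for b in mod_baits:
                xg, xb = values[idx[g]], values[idx[b]]
                if np.std(xg) == 0 or np.std(xb) == 0:
                    rs.append(0.0)
                else:
                    rs.append(pearsonr(xg, xb)[0])
            raws.append(sum(rs) / len(rs))
        mean = sum(raws) / len(raws)
        var = sum((r - mean) ** 2 for r in raws) / len(raws)
        sd = math.sqrt(var)
        for g, raw in zip(cands, raws):
            z = (raw - mean) / sd if sd >= 1e-12 else 0.0
            scored.append((g, mod, raw, z))
    scored.sort(key=lambda t: (-t[3], t[0]))
    return [(g, m, raw, z, i + 1) for i, (g, m, raw, z) in enumerate(scored)]


def ausr_threshold_sum(ranks, r_max):
    """AUSR as the mean over thresholds t=1..r_max of the fraction of baits
    with self-rank <= t (UNSCORED = None never counts)."""
    n = len(ranks)
    total = 0.0
    for t in range(1, r_max + 1):
        total += sum(1 for r in ranks if r is not None and r <= t) / n
    return total / r_max


def bh_step_up(pvals):
    """Textbook Benjamini-Hochberg step-up q-values, input order preserved."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        val = min(prev, pvals[i] * m / (pos + 1))
        q[i] = val
        prev = val
    return q
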