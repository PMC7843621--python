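"""Independent brute-force oracles used by the test suite.

Each reimplements a statistic from first principles (enumeration, direct
formula, per-pair recomputation) without touching the library code paths
it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from lincnet.annotation import CLASS_LABELS


def bh_stepup(p):
    """Benjamini-Hochberg step-up from the definition: sort, p*m/i, enforce
    monotonicity from the largest rank down, cap at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def _u_statistic(xs, ys):
    u = 0.0
    for a in xs:
        for b in ys:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def mann_whitney_exact_p(x, y):
    """Two-sided exact MWU p by full enumeration of all C(n1+n2, n1)
    group assignments of the pooled sample."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    obs = _u_statistic(x, y)
    us = []
    idx = set(range(len(pooled)))
    for comb in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx - set(comb)]
        us.append(_u_statistic(xs, ys))
    us = np.asarray(us)
    cdf = (us <= obs).mean()
    sf = (us >= obs).mean()
    return min(1.0, 2.0 * min(cdf, sf))


def welch_t_p(x, y):
    """Textbook Welch two-sample t with Welch-Satterthwaite df."""
    from scipy import stats
    x, y = np.asarray(x, float), np.asarray(y, float)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    n1, n2 = x.size, y.size
    se2 = v1 / n1 + v2 / n2
    t = (y.mean() - x.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2.0 * stats.t.sf(abs(t), df)


def classify_oracle(lnc, genes, exons_by_gene, window):
    """Per-gene predicate evaluation with explicit precedence, brute force."""
    best = 6
    for gid, g in genes.iterrows():
        if g["chrom"] != lnc["chrom"]:
            continue
        same = lnc["strand"] == g["strand"]
        overlap = lnc["start"] < g["end"] and g["start"] < lnc["end"]
        exs = exons_by_gene.get(gid, [])
        exon_hit = any(lnc["start"] < e2 and e1 < lnc["end"]
                       for e1, e2 in exs)
        introns = [(exs[i][1], exs[i + 1][0]) for i in range(len(exs) - 1)
                   if exs[i][1] < exs[i + 1][0]]
        contained = any(i1 <= lnc["start"] and lnc["end"] <= i2
                        for i1, i2 in introns)
        gtss = g["start"] if g["strand"] == "+" else g["end"]
        ltss = lnc["start"] if lnc["strand"] == "+" else lnc["end"]
        if exon_hit and same:
            rank = 1
        elif contained and same:
            rank = 2
        elif contained and not same:
            rank = 3
        elif overlap and not same:
            rank = 4
        elif not overlap and not same and abs(ltss - gtss) <= window:
            rank = 5
        else:
            rank = 6
        best = min(best, rank)
    return CLASS_LABELS[best - 1]


def network_edges_oracle(study, lnc_ids, mrna_ids, timepoint,
                         r_threshold=0.995, p_threshold=0.05):
    """All-pairs recomputation with scipy.stats.pearsonr, strict thresholds."""
    from scipy import stats
    log2 = study.to_log2().intensities
    cols = study.samples_for(timepoint)
    edges = set()
    for ln_id in lnc_ids:
        x = log2.loc[ln_id, cols].to_numpy()
        for m_id in mrna_ids:
            y = log2.loc[m_id, cols].to_numpy()
            if x.std() == 0 or y.std() == 0:
                continue
            r, p = stats.pearsonr(x, y)
            if abs(r) > r_threshold and p < p_threshold:
                edges.add((ln_id, m_id))
    return edges
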