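"""Independent reference implementations used as test oracles.

These deliberately avoid the library's code paths: brute-force pairwise
logic, exhaustive enumeration and direct rule application on small inputs.
"""

from __future__ import annotations

import numpy as np


def reference_merge(intervals, gap):
    """Connected-components merge by exhaustive pairwise distance."""
    ivs = [(c, s, e) for c, s, e in intervals]
    n = len(ivs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = ivs[i]
            cj, sj, ej = ivs[j]
            if ci != cj:
                continue
            dist = max(sj - ei, si - ej, 0)
            if dist <= gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ivs[i])
    out = []
    for members in groups.values():
        c = members[0][0]
        out.append((c, min(s for _c, s, _e in members), max(e for _c, _s, e in members)))
    return sorted(out)


def reference_bh(pvals):
    """Benjamini-Hochberg step-up, written directly from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adj[idx] = running_min
    return adj


def reference_complex_loci(genes, flags, elements, domains):
    """Direct rule-by-rule reference for the complex-locus pipeline.

    genes: list of (name, start, end, coding: bool); elements: list of
    (name, start, end); domains: sorted list of (start, end) covering one
    chromosome. Returns list of dicts with members, span, sites.
    """
    borders_all = sorted({b for s, e in domains for b in (s, e)})
    coding = sorted([g for g in genes if g[3]], key=lambda g: g[1])

    # stage 1: maximal flagged runs over coding genes
    runs, cur = [], []
    for g in coding:
        if g[0] in flags:
            cur.append(g)
        else:
            if cur:
                runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)

    # stage 2: domain rules
    fragments = []
    for run in runs:
        lo = min(g[1] for g in run)
        hi = max(g[2] for g in run)
        inside = [b for b in borders_all if lo < b < hi]
        if not inside:
            fragments.append(run)
            continue
        if len(run) <= 2:
            continue
        buckets = {}
        for g in run:
            if any(g[1] < b < g[2] for b in inside):
                continue
            buckets.setdefault(sum(1 for b in inside if b <= g[1]), []).append(g)
        for _k, members in sorted(buckets.items()):
            if len(members) > 2:
                fragments.append(members)

    # stage 3: intergenic STAT5-site extension with border retraction
    results = []
    for members in fragments:
        names = {g[0] for g in members}
        lo = min(g[1] for g in members)
        hi = max(g[2] for g in members)
        left_limit = max([g[2] for g in coding if g[0] not in names and g[2] <= lo],
                         default=0)
        right_candidates = [g[1] for g in coding if g[0] not in names and g[1] >= hi]
        right_limit = min(right_candidates) if right_candidates else None

        left_sites = [e for e in elements if e[1] >= left_limit and e[2] <= lo]
        right_sites = [
            e for e in elements
            if e[1] >= hi and (right_limit is None or e[2] <= right_limit)
        ]
        new_lo = min([lo] + [e[1] for e in left_sites])
        new_hi = max([hi] + [e[2] for e in right_sites])
        lb = [b for b in borders_all if new_lo < b <= lo]
        if lb:
            b = max(lb)
            left_sites = [e for e in left_sites if e[1] >= b]
            new_lo = min([lo] + [e[1] for e in left_sites])
        rb = [b for b in borders_all if hi <= b < new_hi]
        if rb:
            b = min(rb)
            right_sites = [e for e in right_sites if e[2] <= b]
            new_hi = max([hi] + [e[2] for e in right_sites])

        # stage 4: final gene-count filter
        if len(members) >= 3:
            results.append(
                {
                    "members": [g[0] for g in members],
                    "span": (new_lo, new_hi),
                    "sites": sorted(e[0] for e in left_sites + right_sites),
                }
            )
    results.sort(key=lambda r: r["span"])
    return results


def random_genome(rng):
    """A small random single-chromosome genome for oracle comparisons."""
    n_genes = rng.integers(3, 11)
    starts = np.sort(rng.choice(np.arange(1, 100), n_genes, replace=False)) * 1_000
    genes = []
    for i, s in enumerate(starts):
        width = int(rng.integers(1, 9)) * 100
        coding = bool(rng.random() < 0.8)
        genes.append((f"g{i}", int(s), int(s) + width, coding))
    flags = {g[0] for g in genes if g[3] and rng.random() < 0.6}
    n_el = int(rng.integers(0, 6))
    el_starts = rng.choice(np.arange(0, 101_000, 250), n_el, replace=False)
    elements = []
    for j, s in enumerate(np.sort(el_starts)):
        elements.append((f"e{j}", int(s), int(s) + 200))
    # random domain partition of [0, 102000]
    n_borders = int(rng.integers(0, 4))
    cuts = sorted(rng.choice(np.arange(5_000, 100_000, 500), n_borders, replace=False))
    edges = [0] + [int(c) for c in cuts] + [102_000]
    domains = list(zip(edges[:-1], edges[1:]))
    return genes, flags, elements, domains
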