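"""Brute-force reference implementations used to cross-check set algebra.

These stay deliberately naive (all-pairs / exhaustive) and independent of the
package's data structures.
"""

import numpy as np


def brute_force_loop_partition(pr, cr, flank_bp):
    """All-pairs matcher: a loop is common when any loop of the other
    condition has both anchors within the flank allowance."""
    a = pr[["a1_start", "a1_end", "a2_start", "a2_end"]].to_numpy()
    b = cr[["a1_start", "a1_end", "a2_start", "a2_end"]].to_numpy()
    if len(a) == 0 or len(b) == 0:
        return np.zeros(len(a), bool), np.zeros(len(b), bool)
    m1 = np.minimum(a[:, None, 1], b[None, :, 1]) + flank_bp > \
        np.maximum(a[:, None, 0], b[None, :, 0])
    m2 = np.minimum(a[:, None, 3], b[None, :, 3]) + flank_bp > \
        np.maximum(a[:, None, 2], b[None, :, 2])
    match = m1 & m2
    return match.any(axis=1), match.any(axis=0)


def brute_force_anchor_clusters(anchors, flank_bp):
    """Connected components of the interval-overlap-within-flank graph.

    ``anchors`` is a list of (start, end, condition); returns sorted
    (merged_start, merged_end, category) tuples.
    """
    n = len(anchors)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            s1, e1, _ = anchors[i]
            s2, e2, _ = anchors[j]
            if min(e1, e2) + flank_bp > max(s1, s2):
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    clusters = []
    for i in range(n):
        if seen[i]:
            continue
        stack, members = [i], []
        seen[i] = True
        while stack:
            k = stack.pop()
            members.append(k)
            for nb in adj[k]:
                if not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        conds = {anchors[k][2] for k in members}
        cat = "common" if len(conds) == 2 else f"{conds.pop()}-specific"
        clusters.append((min(anchors[k][0] for k in members),
                         max(anchors[k][1] for k in members), cat))
    return sorted(clusters)


def brute_force_consensus(callsets, min_support, window_tra, window_other,
                          min_callers):
    """Greedy seed-matching clustering, naive dictionaries only."""
    calls = []
    for df in callsets:
        for _, r in df.iterrows():
            if r["support"] >= min_support:
                calls.append(dict(r))
    groups = {}
    for c in calls:
        groups.setdefault((c["type"], c["chrom1"], c["chrom2"]), []).append(c)
    out = []
    for (svtype, c1, c2), grp in sorted(groups.items()):
        w = window_tra if svtype == "TRA" else window_other
        grp = sorted(grp, key=lambda c: (c["pos1"], c["pos2"], c["caller"]))
        clusters = []
        for c in grp:
            for cl in clusters:
                seed = cl[0]
                if abs(c["pos1"] - seed["pos1"]) <= w and \
                        abs(c["pos2"] - seed["pos2"]) <= w:
                    cl.append(c)
                    break
            else:
                clusters.append([c])
        for cl in clusters:
            callers = {c["caller"] for c in cl}
            if len(callers) >= min_callers:
                out.append((c1, int(np.median([c["pos1"] for c in cl])),
                            c2, int(np.median([c["pos2"] for c in cl])), svtype))
    return sorted(out)
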