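"""Independent brute-force reference implementations used only in tests.

Deliberately written with explicit loops and no imports from nafkit so the
checks stay independent of the code paths they verify.
"""

import math


def brute_force_hits(met_percents, marker_percents, bounds=(5.0, 7.5, 10.0)):
    """Hit counts per compartment by exhaustive looping.

    met_percents: list of percent values, None = not detected.
    marker_percents: dict compartment -> full list of percents.
    Returns dict compartment -> hit count (pair-based path only).
    """
    f = len(met_percents)
    detected = [i for i in range(f) if met_percents[i] is not None]
    assert len(detected) >= 2, "brute force covers the pair-based path only"
    comps = list(marker_percents)
    hits = {c: 0 for c in comps}
    for a in range(len(detected)):
        for b in range(a + 1, len(detected)):
            i, j = detected[a], detected[b]
            met_delta = met_percents[j] - met_percents[i]
            psi = {}
            for c in comps:
                marker_delta = marker_percents[c][j] - marker_percents[c][i]
                psi[c] = abs(met_delta - marker_delta)
            minimum = min(psi.values())
            for c in comps:
                for bound in bounds:
                    if psi[c] - minimum < bound:
                        hits[c] += 1
    return hits


def brute_force_average_linkage(points):
    """Naive O(n^3) agglomeration with average linkage on Euclidean distance.

    points: list of coordinate lists.  Returns the list of merge heights in
    merge order and the list of merged member-sets (frozensets of leaf ids).
    """

    def dist(p, q):
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))

    clusters = {i: [i] for i in range(len(points))}
    heights = []
    merges = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                total = 0.0
                for i in clusters[a]:
                    for j in clusters[b]:
                        total += dist(points[i], points[j])
                d = total / (len(clusters[a]) * len(clusters[b]))
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters.pop(a) + clusters.pop(b)
        merges.append(frozenset(merged))
        clusters[min(a, b)] = merged
    return heights, merges
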