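"""Independent brute-force reference implementations used only by tests.

Each oracle deliberately takes the slowest, most literal route (full
pairwise scans, exhaustive enumeration, textbook formulas) and shares no
code with the package implementation it checks.
"""

import math

import numpy as np


def haversine_km_oracle(lon1, lat1, lon2, lat2, radius=6371.0088):
    """Textbook haversine, scalar, math-module only."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2) - math.radians(lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * radius * math.asin(math.sqrt(a))


def dbscan_oracle(points, eps, min_pts):
    """DBSCAN by full pairwise distances + breadth-first density expansion.

    Returns labels with clusters numbered in order of first core point in
    input order; the point counts toward its own neighbourhood.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=int)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    neighbours = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbours])
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cluster
        frontier = [i]
        while frontier:
            j = frontier.pop(0)
            for q in neighbours[j]:
                if labels[q] == -1:
                    labels[q] = cluster
                    if core[q]:
                        frontier.append(q)
        cluster += 1
    return labels


def partition_of(labels):
    """Set-of-frozensets view of a clustering (noise kept separate)."""
    clusters = {}
    noise = set()
    for i, l in enumerate(labels):
        if l == -1:
            noise.add(i)
        else:
            clusters.setdefault(l, set()).add(i)
    return frozenset(frozenset(c) for c in clusters.values()), frozenset(noise)


def viterbi_enumeration_oracle(initial, transition, means, covariances, coords):
    """Argmax over all K**T state sequences by direct joint probability.

    Ties resolved toward the lexicographically smallest sequence, matching
    a DP that breaks ties toward the lower state index.
    """
    import itertools

    K = len(initial)
    T = len(coords)

    def emission_logpdf(x, mean, cov):
        det = cov[0][0] * cov[1][1] - cov[0][1] * cov[1][0]
        inv = np.array([[cov[1][1], -cov[0][1]], [-cov[1][0], cov[0][0]]]) / det
        dvec = np.asarray(x) - np.asarray(mean)
        return float(-0.5 * (dvec @ inv @ dvec + math.log(det)) - math.log(2 * math.pi))

    best_seq, best_score = None, -math.inf
    for seq in itertools.product(range(K), repeat=T):
        with np.errstate(divide="ignore"):
            score = math.log(initial[seq[0]]) if initial[seq[0]] > 0 else -math.inf
        for t in range(1, T):
            a = transition[seq[t - 1]][seq[t]]
            score += math.log(a) if a > 0 else -math.inf
        for t in range(T):
            score += emission_logpdf(coords[t], means[seq[t]], covariances[seq[t]])
        if score > best_score:
            best_score, best_seq = score, seq
    return np.array(best_seq)


def max_filter_peaks_oracle(values, ny, nx, phi):
    """Per-cell centred-window scan; plateau ties keep the lex-smallest cell."""
    n_r, n_c = values.shape
    hy, hx = ny // 2, nx // 2
    kept = []
    for iy in range(n_r):
        for ix in range(n_c):
            v = values[iy, ix]
            if not v > phi:
                continue
            y0, y1 = max(0, iy - hy), min(n_r, iy + hy + 1)
            x0, x1 = max(0, ix - hx), min(n_c, ix + hx + 1)
            if v < values[y0:y1, x0:x1].max():
                continue
            dup = any(abs(ky - iy) <= hy and abs(kx - ix) <= hx
                      and values[ky, kx] == v for ky, kx in kept)
            if not dup:
                kept.append((iy, ix))
    return kept


def kendall_tau_b_oracle(a, b):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    concordant = discordant = 0
    ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                continue
            elif da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    # pairs tied in a (incl. both-tied) and in b
    ta = tb = tab = 0
    for i in range(n):
        for j in range(i + 1, n):
            if a[i] == a[j]:
                ta += 1
            if b[i] == b[j]:
                tb += 1
    denom = math.sqrt((n0 - ta) * (n0 - tb))
    return (concordant - discordant) / denom


def point_in_polygon_oracle(x, y, vertices):
    """Even-odd ray casting against a simple polygon (list of (x, y))."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside
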