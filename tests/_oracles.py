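"""Independent brute-force oracles used only by the test suite.

Everything here is written from first principles (naive enumeration, full
boundary-matrix reduction, recursive flood fill) and deliberately shares no
code with the package implementation it cross-checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# full boundary-matrix reduction over Z/2 (cubical V-construction)
# ---------------------------------------------------------------------------


def reduction_persistence(img: np.ndarray, essential_death: float = 1.0):
    """Persistence pairs of the sublevel V-construction complex of ``img``.

    Naive O(n^3) column reduction of the full boundary matrix.  Returns a
    dict {0: [(b, d), ...], 1: [...]} of finite-persistence pairs (b < d),
    with the essential component capped at ``essential_death``.
    """
    a = np.asarray(img, dtype=float)
    h, w = a.shape
    cells = []  # (value, dim, key); key identifies the cell

    def vval(i, j):
        return a[i, j]

    for i in range(h):
        for j in range(w):
            cells.append((vval(i, j), 0, ("v", i, j)))
    for i in range(h):
        for j in range(w):
            if j + 1 < w:
                cells.append((max(vval(i, j), vval(i, j + 1)), 1, ("eh", i, j)))
            if i + 1 < h:
                cells.append((max(vval(i, j), vval(i + 1, j)), 1, ("ev", i, j)))
    for i in range(h - 1):
        for j in range(w - 1):
            val = max(vval(i, j), vval(i, j + 1), vval(i + 1, j), vval(i + 1, j + 1))
            cells.append((val, 2, ("s", i, j)))

    order = sorted(range(len(cells)), key=lambda k: (cells[k][0], cells[k][1], k))
    pos = {cells[k][2]: r for r, k in enumerate(order)}

    def boundary(key):
        kind = key[0]
        if kind == "v":
            return []
        if kind == "eh":
            _, i, j = key
            return [("v", i, j), ("v", i, j + 1)]
        if kind == "ev":
            _, i, j = key
            return [("v", i, j), ("v", i + 1, j)]
        _, i, j = key
        return [("eh", i, j), ("eh", i + 1, j), ("ev", i, j), ("ev", i, j + 1)]

    columns = []
    for r, k in enumerate(order):
        columns.append(set(pos[b] for b in boundary(cells[k][2])))

    low_of = {}  # pivot row -> column index
    pairs = []
    for jcol in range(len(columns)):
        col = columns[jcol]
        while col:
            low = max(col)
            if low not in low_of:
                break
            col ^= columns[low_of[low]]
        if col:
            low_of[max(col)] = jcol
            columns[jcol] = col
            pairs.append((max(col), jcol))
        else:
            columns[jcol] = col

    paired = set()
    out = {0: [], 1: []}
    for i, j in pairs:
        paired.add(i)
        paired.add(j)
        ki, kj = order[i], order[j]
        b, d = cells[ki][0], cells[kj][0]
        dim = cells[ki][1]
        if d > b and dim in out:
            out[dim].append((b, d))
    for r in range(len(order)):
        if r not in paired:
            k = order[r]
            if cells[k][1] == 0:
                out[0].append((cells[k][0], essential_death))
    for dim in out:
        out[dim].sort()
    return out


# ---------------------------------------------------------------------------
# flood-fill counting
# ---------------------------------------------------------------------------

_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_N8 = _N4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def flood_fill_components(mask: np.ndarray, connectivity: int = 4) -> int:
    """Number of connected True-components via an explicit stack flood fill."""
    m = np.asarray(mask, dtype=bool)
    nbrs = _N4 if connectivity == 4 else _N8
    seen = np.zeros_like(m)
    count = 0
    h, w = m.shape
    for si in range(h):
        for sj in range(w):
            if m[si, sj] and not seen[si, sj]:
                count += 1
                stack = [(si, sj)]
                seen[si, sj] = True
                while stack:
                    i, j = stack.pop()
                    for di, dj in nbrs:
                        ni, nj = i + di, j + dj
                        if 0 <= ni < h and 0 <= nj < w and m[ni, nj] and not seen[ni, nj]:
                            seen[ni, nj] = True
                            stack.append((ni, nj))
    return count


def flood_fill_holes(mask: np.ndarray) -> int:
    """Enclosed 4-connected background regions (border-touching excluded)."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    seen = np.zeros_like(m)
    holes = 0
    for si in range(h):
        for sj in range(w):
            if not m[si, sj] and not seen[si, sj]:
                stack = [(si, sj)]
                seen[si, sj] = True
                region = [(si, sj)]
                while stack:
                    i, j = stack.pop()
                    for di, dj in _N4:
                        ni, nj = i + di, j + dj
                        if 0 <= ni < h and 0 <= nj < w and not m[ni, nj] and not seen[ni, nj]:
                            seen[ni, nj] = True
                            stack.append((ni, nj))
                            region.append((ni, nj))
                if not any(i in (0, h - 1) or j in (0, w - 1) for i, j in region):
                    holes += 1
    return holes


def euler_characteristic_8(mask: np.ndarray) -> int:
    """Euler characteristic of an 8-connected foreground via 2x2 quad counts.

    Gray's quad-count formula: chi = (Q1 - Q3 - 2 * Qd) / 4 over all 2x2
    windows of the zero-padded mask, where Q1/Q3 count windows with exactly
    one/three foreground pixels and Qd the two diagonal configurations.
    """
    m = np.pad(np.asarray(mask, dtype=int), 1)
    q1 = q3 = qd = 0
    h, w = m.shape
    for i in range(h - 1):
        for j in range(w - 1):
            quad = (m[i, j], m[i, j + 1], m[i + 1, j], m[i + 1, j + 1])
            s = sum(quad)
            if s == 1:
                q1 += 1
            elif s == 3:
                q3 += 1
            elif s == 2 and quad in ((1, 0, 0, 1), (0, 1, 1, 0)):
                qd += 1
    return (q1 - q3 - 2 * qd) // 4


# ---------------------------------------------------------------------------
# Wasserstein by exhaustive matching
# ---------------------------------------------------------------------------


def brute_force_wasserstein(a: np.ndarray, b: np.ndarray, p: float) -> float:
    """Exact W_p by enumerating all partial bijections with diagonal padding.

    ``a`` and ``b`` are (n, 2) arrays of off-diagonal points.  Every point is
    either matched to a point of the other diagram (infinity-norm cost) or to
    the diagonal (cost = persistence / 2).
    """
    a = np.asarray(a, float).reshape(-1, 2)
    b = np.asarray(b, float).reshape(-1, 2)
    na, nb = len(a), len(b)
    diag_a = (a[:, 1] - a[:, 0]) / 2.0 if na else np.empty(0)
    diag_b = (b[:, 1] - b[:, 0]) / 2.0 if nb else np.empty(0)
    best = np.inf
    for k in range(min(na, nb) + 1):
        for sub_a in itertools.combinations(range(na), k):
            rest_a = (diag_a**p).sum() - (diag_a[list(sub_a)] ** p).sum() if na else 0.0
            for sub_b in itertools.combinations(range(nb), k):
                rest_b = (
                    (diag_b**p).sum() - (diag_b[list(sub_b)] ** p).sum() if nb else 0.0
                )
                for perm in itertools.permutations(sub_b):
                    cost = rest_a + rest_b
                    for ia, ib in zip(sub_a, perm):
                        cost += np.abs(a[ia] - b[ib]).max() ** p
                    if cost < best:
                        best = cost
    return float(best ** (1.0 / p))


# ---------------------------------------------------------------------------
# exhaustive Otsu
# ---------------------------------------------------------------------------


def exhaustive_otsu(img: np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold by brute-force maximization of between-class variance
    over all histogram bin cut points."""
    a = np.asarray(img, float).ravel()
    hist, edges = np.histogram(a, bins=n_bins, range=(a.min(), a.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_t, best_var = centers[0], -1.0
    total = hist.sum()
    for cut in range(1, n_bins):
        w0 = hist[:cut].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:cut] * centers[:cut]).sum() / w0
        mu1 = (hist[cut:] * centers[cut:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var = var
            best_t = centers[cut - 1]
    return float(best_t)
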