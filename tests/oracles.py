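"""Independent brute-force oracles used to cross-check the package.

Everything here is written in plain loops, independent of the vectorized
implementation paths it validates.
"""

from __future__ import annotations

import numpy as np


def midranks(v) -> list[float]:
    """Average ranks for ties, computed by explicit grouping."""
    v = list(v)
    n = len(v)
    order = sorted(range(n), key=lambda i: v[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Pearson correlation of mid-ranks, all in scalar arithmetic."""
    rx, ry = midranks(x), midranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    if vx == 0 or vy == 0:
        return 0.0
    return cov / (vx * vy) ** 0.5


def spot_oracle(grid: np.ndarray, quantile: float, min_units: int):
    """Threshold + BFS flood-fill spot finder.

    Returns a list of (peak_value, sorted unit tuple) ordered the way the
    implementation labels spots: decreasing peak, then lowest unit index.
    A flat grid yields no spots.
    """
    h, w = grid.shape
    vals = grid.ravel()
    if vals.max() == vals.min():
        return []
    thr = float(np.quantile(vals, quantile))
    marked = {(r, c) for r in range(h) for c in range(w) if grid[r, c] >= thr}
    seen: set[tuple[int, int]] = set()
    comps = []
    for cell in sorted(marked):
        if cell in seen:
            continue
        stack, comp = [cell], []
        seen.add(cell)
        while stack:
            r, c = stack.pop()
            comp.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nb = (r + dr, c + dc)
                    if nb in marked and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
        if len(comp) >= min_units:
            units = tuple(sorted(r * w + c for r, c in comp))
            peak = max(grid[r, c] for r, c in comp)
            comps.append((float(peak), units))
    comps.sort(key=lambda t: (-t[0], t[1][0]))
    return comps


def silhouette_oracle(d: np.ndarray, labels) -> list[float]:
    """Classic silhouette from a distance matrix, scalar loops only."""
    labels = list(labels)
    n = len(labels)
    groups = sorted(set(labels))
    out = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            out.append(0.0)
            continue
        a = sum(d[i, j] for j in own) / len(own)
        b = min(
            sum(d[i, j] for j in range(n) if labels[j] == g)
            / sum(1 for j in range(n) if labels[j] == g)
            for g in groups
            if g != labels[i]
        )
        out.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return out
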