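"""Independent brute-force oracles used to cross-check the package.

Everything here is written as plain loops / first-principles definitions,
deliberately independent of the library code paths it checks.
"""

import math

import numpy as np


def masked_mean_loop(image, mask):
    """Per-pixel loop arithmetic mean over a boolean mask."""
    total, count = 0.0, 0
    it = np.nditer(mask, flags=["multi_index"])
    for val in it:
        if val:
            total += float(image[it.multi_index])
            count += 1
    return total / count


def pcc_two_pass(x, y):
    """Two-pass Pearson correlation from the textbook definition."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def distance_to_background_loop(mask):
    """Exact Euclidean distance of each foreground pixel to the nearest
    background pixel, by exhaustive search. Requires some background."""
    mask = np.asarray(mask, bool)
    bg = [idx for idx in np.ndindex(mask.shape) if not mask[idx]]
    if not bg:
        raise ValueError("mask has no background pixels")
    out = np.zeros(mask.shape)
    for idx in np.ndindex(mask.shape):
        if not mask[idx]:
            continue
        best = min(sum((a - c) ** 2 for a, c in zip(idx, b)) for b in bg)
        out[idx] = math.sqrt(best)
    return out


def flood_fill_components(binary, connectivity_full=True):
    """Connected-component volumes by iterative flood fill (BFS).

    ``connectivity_full`` uses the complete neighbour set (8 in 2D, 26 in
    3D); otherwise faces only.
    """
    binary = np.asarray(binary, bool)
    ndim = binary.ndim
    offsets = []
    for off in np.ndindex(*([3] * ndim)):
        off = tuple(o - 1 for o in off)
        if all(o == 0 for o in off):
            continue
        if not connectivity_full and sum(abs(o) for o in off) != 1:
            continue
        offsets.append(off)
    seen = np.zeros(binary.shape, bool)
    volumes = []
    for start in np.ndindex(binary.shape):
        if not binary[start] or seen[start]:
            continue
        stack, size = [start], 0
        seen[start] = True
        while stack:
            cur = stack.pop()
            size += 1
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if any(n < 0 or n >= s for n, s in zip(nb, binary.shape)):
                    continue
                if binary[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        volumes.append(size)
    return sorted(volumes)


def holm_by_definition(pvalues):
    """Holm step-down from its rejection-threshold definition.

    adjusted_i = max over j <= i (in the sorted order) of min(1, (m-j+1)*p_(j)).
    """
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adjusted[idx] = running
    return adjusted


def interp_mean_loop(base, curves):
    """Pointwise mean of curves linearly interpolated onto ``base`` by hand."""
    out = []
    for t in base:
        vals = []
        for tt, yy in curves:
            for j in range(len(tt) - 1):
                if tt[j] <= t <= tt[j + 1]:
                    w = 0.0 if tt[j + 1] == tt[j] else (t - tt[j]) / (tt[j + 1] - tt[j])
                    vals.append(yy[j] * (1 - w) + yy[j + 1] * w)
                    break
        out.append(sum(vals) / len(vals))
    return out
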