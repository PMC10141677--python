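"""Independent brute-force oracles for the matrix-family features and the
±3σ normalization.  Deliberately written as plain loops over definitions so
they share no code path with the package implementation."""

import math

import numpy as np


def cooccurrence_brute(quantized, offset, n_levels):
    """Symmetric normalized co-occurrence matrix by explicit pair listing."""
    q = np.asarray(quantized)
    dr, dc = offset
    rows, cols = q.shape
    mat = np.zeros((n_levels, n_levels))
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                mat[q[r, c], q[r2, c2]] += 1
                mat[q[r2, c2], q[r, c]] += 1
    return mat / mat.sum()


def glcm_stats_brute(p):
    """The 11 co-occurrence statistics straight from their definitions."""
    g = p.shape[0]
    mu = sum(i * p[i, j] for i in range(g) for j in range(g))
    var = sum((i - mu) ** 2 * p[i, j] for i in range(g) for j in range(g))
    sd = math.sqrt(var)
    out = {}
    out["asm"] = sum(p[i, j] ** 2 for i in range(g) for j in range(g))
    out["contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(g) for j in range(g))
    if sd > 0:
        out["correlation"] = (
            sum(i * j * p[i, j] for i in range(g) for j in range(g)) - mu * mu
        ) / (sd * sd)
    else:
        out["correlation"] = 0.0
    out["sum_of_squares"] = var
    out["idm"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(g) for j in range(g)
    )
    p_sum = [0.0] * (2 * g - 1)
    p_diff = [0.0] * g
    for i in range(g):
        for j in range(g):
            p_sum[i + j] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]
    out["sum_average"] = sum(k * v for k, v in enumerate(p_sum))
    out["sum_variance"] = sum(
        (k - out["sum_average"]) ** 2 * v for k, v in enumerate(p_sum)
    )
    out["sum_entropy"] = -sum(v * math.log(v) for v in p_sum if v > 0)
    out["entropy"] = -sum(
        p[i, j] * math.log(p[i, j]) for i in range(g) for j in range(g) if p[i, j] > 0
    )
    dmean = sum(k * v for k, v in enumerate(p_diff))
    out["difference_variance"] = sum(
        (k - dmean) ** 2 * v for k, v in enumerate(p_diff)
    )
    out["difference_entropy"] = -sum(v * math.log(v) for v in p_diff if v > 0)
    return out


def _lines_brute(q, angle):
    rows, cols = q.shape
    if angle == 0:
        return [list(q[r, :]) for r in range(rows)]
    if angle == 90:
        return [list(q[:, c]) for c in range(cols)]
    lines = []
    if angle == 45:
        starts = [(r, 0) for r in range(rows - 1, -1, -1)] + [
            (0, c) for c in range(1, cols)
        ]
        step = (1, 1)
    else:  # 135: down-left
        starts = [(r, cols - 1) for r in range(rows - 1, -1, -1)] + [
            (0, c) for c in range(cols - 2, -1, -1)
        ]
        step = (1, -1)
    for r0, c0 in starts:
        line, r, c = [], r0, c0
        while 0 <= r < rows and 0 <= c < cols:
            line.append(q[r, c])
            r, c = r + step[0], c + step[1]
        lines.append(line)
    return lines


def runs_brute(quantized, angle):
    """All maximal (value, length) runs along one direction."""
    runs = []
    for line in _lines_brute(np.asarray(quantized), angle):
        i = 0
        while i < len(line):
            j = i
            while j + 1 < len(line) and line[j + 1] == line[i]:
                j += 1
            runs.append((int(line[i]), j - i + 1))
            i = j + 1
    return runs


def rlm_stats_brute(quantized, angle, n_levels):
    """The five Galloway statistics from the raw run list."""
    runs = runs_brute(quantized, angle)
    n_runs = len(runs)
    n_pix = np.asarray(quantized).size
    sre = sum(1.0 / (l * l) for _, l in runs) / n_runs
    lre = sum(float(l * l) for _, l in runs) / n_runs
    by_level = [0] * n_levels
    by_length = {}
    for g, l in runs:
        by_level[g] += 1
        by_length[l] = by_length.get(l, 0) + 1
    gln = sum(v * v for v in by_level) / n_runs
    rln = sum(v * v for v in by_length.values()) / n_runs
    rp = n_runs / n_pix
    return {
        "sre": sre,
        "lre": lre,
        "gln": gln,
        "rln": rln,
        "run_percentage": rp,
    }


def normalize_brute(pixels, bit_depth):
    """Direct per-pixel evaluation of the ±3σ mapping and clamp."""
    arr = np.asarray(pixels, dtype=float)
    L = 2**bit_depth - 1
    mu = arr.mean()
    sigma = arr.std()
    out = np.empty_like(arr)
    for idx, value in np.ndenumerate(arr):
        if sigma == 0:
            out[idx] = math.floor(L / 2 + 0.5)
            continue
        n = L * (value - (mu - 3 * sigma)) / (6 * sigma)
        if n > L:
            out[idx] = L
        elif n < 0:
            out[idx] = 0
        else:
            out[idx] = min(L, math.floor(n + 0.5))
    return out.astype(np.int64)
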