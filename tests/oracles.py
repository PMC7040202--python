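"""Independent naive reference implementations used only by the tests.

Everything here enumerates pairs/runs/filter taps explicitly with Python
loops, deliberately sharing no code with the package's vectorized
implementations.
"""

from __future__ import annotations

import math

import numpy as np


def brute_glcm(levels: np.ndarray, ng: int, direction, delta=1, symmetric=True):
    """Co-occurrence matrix by explicit voxel-pair enumeration."""
    counts = np.zeros((ng, ng))
    nz, ny, nx = levels.shape
    dz, dy, dx = direction
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                a = levels[z, y, x]
                if a == 0:
                    continue
                z2, y2, x2 = z + dz * delta, y + dy * delta, x + dx * delta
                if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                    continue
                b = levels[z2, y2, x2]
                if b == 0:
                    continue
                counts[a - 1, b - 1] += 1
                if symmetric:
                    counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else None


def brute_glcm_features(p: np.ndarray) -> dict[str, float]:
    """All GLCM statistics via direct double loops over (i, j)."""
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sigx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(ng)))
    sigy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(ng)))

    def dsum(fn):
        return sum(
            fn(i + 1, j + 1, p[i, j]) for i in range(ng) for j in range(ng)
        )

    psum = {}
    pdiff = {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i, j]
    sum_avg = sum(k * v for k, v in psum.items())
    diff_avg = sum(k * v for k, v in pdiff.items())

    def h(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    hxy = h(p.ravel())
    hxy1 = -dsum(
        lambda i, j, v: v * math.log2(px[i - 1] * py[j - 1])
        if px[i - 1] * py[j - 1] > 0 and v > 0
        else 0.0
    )
    # note: HXY1 sums p*log(px*py) over all cells where px*py > 0
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0
    )
    hxy2 = h([px[i] * py[j] for i in range(ng) for j in range(ng)])
    hx, hy = h(px), h(py)

    return {
        "autocorrelation": dsum(lambda i, j, v: i * j * v),
        "cluster_prominence": dsum(lambda i, j, v: (i + j - mux - muy) ** 4 * v),
        "cluster_shade": dsum(lambda i, j, v: (i + j - mux - muy) ** 3 * v),
        "cluster_tendency": dsum(lambda i, j, v: (i + j - mux - muy) ** 2 * v),
        "contrast": dsum(lambda i, j, v: (i - j) ** 2 * v),
        "correlation": (
            (dsum(lambda i, j, v: i * j * v) - mux * muy) / (sigx * sigy)
            if sigx > 0 and sigy > 0
            else 0.0
        ),
        "difference_average": diff_avg,
        "difference_entropy": h(pdiff.values()),
        "difference_variance": sum(
            (k - diff_avg) ** 2 * v for k, v in pdiff.items()
        ),
        "dissimilarity": dsum(lambda i, j, v: abs(i - j) * v),
        "imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "inverse_difference": dsum(lambda i, j, v: v / (1 + abs(i - j))),
        "inverse_difference_moment": dsum(lambda i, j, v: v / (1 + (i - j) ** 2)),
        "inverse_difference_moment_normalized": dsum(
            lambda i, j, v: v / (1 + ((i - j) / ng) ** 2)
        ),
        "inverse_difference_normalized": dsum(
            lambda i, j, v: v / (1 + abs(i - j) / ng)
        ),
        "inverse_variance": dsum(
            lambda i, j, v: v / (i - j) ** 2 if i != j else 0.0
        ),
        "joint_energy": dsum(lambda i, j, v: v * v),
        "joint_entropy": hxy,
        "maximum_probability": max(p.ravel()),
        "sum_average": sum_avg,
        "sum_entropy": h(psum.values()),
        "sum_of_squares_variance": dsum(lambda i, j, v: (i - mux) ** 2 * v),
        "sum_variance": sum((k - sum_avg) ** 2 * v for k, v in psum.items()),
    }


def brute_glrlm(levels: np.ndarray, ng: int, direction):
    """Run-length matrix by explicit line walking."""
    nz, ny, nx = levels.shape
    d = tuple(direction)
    runs: list[tuple[int, int]] = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                lev = levels[z, y, x]
                if lev == 0:
                    continue
                pz, py_, px_ = z - d[0], y - d[1], x - d[2]
                if (
                    0 <= pz < nz
                    and 0 <= py_ < ny
                    and 0 <= px_ < nx
                    and levels[pz, py_, px_] == lev
                ):
                    continue  # not a run start
                length = 1
                cz, cy, cx = z + d[0], y + d[1], x + d[2]
                while (
                    0 <= cz < nz
                    and 0 <= cy < ny
                    and 0 <= cx < nx
                    and levels[cz, cy, cx] == lev
                ):
                    length += 1
                    cz, cy, cx = cz + d[0], cy + d[1], cx + d[2]
                runs.append((int(lev), length))
    if not runs:
        return None
    lmax = max(levels.shape)
    mat = np.zeros((ng, lmax))
    for lev, length in runs:
        mat[lev - 1, length - 1] += 1
    return mat


def brute_glrlm_features(r: np.ndarray) -> dict[str, float]:
    """Run-length statistics via direct loops over (i, l)."""
    ng, lmax = r.shape
    nr = r.sum()
    nvox = sum(r[i, l] * (l + 1) for i in range(ng) for l in range(lmax))

    def rsum(fn):
        return sum(fn(i + 1, l + 1, r[i, l]) for i in range(ng) for l in range(lmax))

    ri = [sum(r[i, l] for l in range(lmax)) for i in range(ng)]
    rl = [sum(r[i, l] for i in range(ng)) for l in range(lmax)]
    mu = sum((i + 1) * ri[i] for i in range(ng)) / nr
    return {
        "short_run_emphasis": rsum(lambda i, l, v: v / l**2) / nr,
        "long_run_emphasis": rsum(lambda i, l, v: v * l**2) / nr,
        "gray_level_nonuniformity": sum(v**2 for v in ri) / nr,
        "run_length_nonuniformity": sum(v**2 for v in rl) / nr,
        "run_percentage": nr / nvox,
        "low_gray_level_run_emphasis": rsum(lambda i, l, v: v / i**2) / nr,
        "high_gray_level_run_emphasis": rsum(lambda i, l, v: v * i**2) / nr,
        "short_run_low_gray_level_emphasis": rsum(lambda i, l, v: v / (i**2 * l**2)) / nr,
        "short_run_high_gray_level_emphasis": rsum(lambda i, l, v: v * i**2 / l**2) / nr,
        "long_run_low_gray_level_emphasis": rsum(lambda i, l, v: v * l**2 / i**2) / nr,
        "long_run_high_gray_level_emphasis": rsum(lambda i, l, v: v * i**2 * l**2) / nr,
        "gray_level_variance": sum((i + 1 - mu) ** 2 * ri[i] for i in range(ng)) / nr,
    }


def brute_correlate1d_reflect(arr: np.ndarray, filt: np.ndarray, axis: int) -> np.ndarray:
    """1-D correlation with reflect boundary, explicit loops (small arrays)."""
    arr = np.moveaxis(np.asarray(arr, dtype=float), axis, -1)
    n = arr.shape[-1]
    k = len(filt)
    origin = k // 2
    out = np.zeros_like(arr)
    idx = np.arange(n)

    def _reflect(i):
        # scipy 'reflect' mode: (d c b a | a b c d | d c b a)
        while i < 0 or i >= n:
            if i < 0:
                i = -i - 1
            else:
                i = 2 * n - i - 1
        return i

    for pos in range(n):
        acc = np.zeros(arr.shape[:-1])
        for m in range(k):
            acc = acc + filt[m] * arr[..., _reflect(pos + m - origin)]
        out[..., pos] = acc
    return np.moveaxis(out, -1, axis)


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Empirical AUC by pairwise comparison (cases = labels == 1)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))
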