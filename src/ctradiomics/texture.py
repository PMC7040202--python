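"""Gray-level co-occurrence (GLCM) and run-length (GLRLM) texture features.

Both families use the 13 unique 3D direction offsets (the 26-neighbourhood
up to sign), distance 1, computed on the discretized VOI (levels 1..Ng, 0
outside).  Feature values are computed per direction and averaged over the
directions that contain at least one voxel pair / run; directions with no
valid pairs are excluded from the average rather than zero-filled.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .errors import ExtractionError

#: the 13 unique 3D offsets: first nonzero component positive
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    d
    for d in product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and next(c for c in d if c != 0) > 0
)
assert len(DIRECTIONS_3D) == 13

GLCM_FEATURES = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "imc1",
    "imc2",
    "inverse_difference",
    "inverse_difference_moment",
    "inverse_difference_moment_normalized",
    "inverse_difference_normalized",
    "inverse_variance",
    "joint_energy",
    "joint_entropy",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_of_squares_variance",
    "sum_variance",
)

GLRLM_FEATURES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
    "gray_level_variance",
)


def _offset_slices(shape, d, delta=1):
    """Slices (src, dst) such that dst = src + delta*d, both in bounds."""
    src, dst = [], []
    for n, c in zip(shape, d):
        step = c * delta
        if step >= 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def glcm_build(
    levels: np.ndarray,
    n_levels: int,
    direction: tuple[int, int, int],
    delta: int = 1,
    symmetric: bool = True,
) -> np.ndarray | None:
    """Normalized co-occurrence matrix p(i, j) for one offset.

    Returns ``None`` when the direction yields no valid voxel pair.
    """
    src, dst = _offset_slices(levels.shape, direction, delta)
    a = levels[src]
    b = levels[dst]
    valid = (a > 0) & (b > 0)
    if not valid.any():
        return None
    ai = a[valid].astype(np.int64) - 1
    bi = b[valid].astype(np.int64) - 1
    counts = np.bincount(ai * n_levels + bi, minlength=n_levels * n_levels)
    mat = counts.reshape(n_levels, n_levels).astype(np.float64)
    if symmetric:
        mat = mat + mat.T
    return mat / mat.sum()


def _plog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


from functools import lru_cache


@lru_cache(maxsize=8)
def _glcm_grids(ng: int):
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj)
    sum_idx = (ii + jj).astype(np.int64).ravel()
    diff_idx = diff.astype(np.int64).ravel()
    ksum = np.arange(2 * ng + 1, dtype=np.float64)
    kdiff = np.arange(ng, dtype=np.float64)
    return i, ii, jj, diff, sum_idx, diff_idx, ksum, kdiff


def glcm_feature_values(p: np.ndarray) -> dict[str, float]:
    """All 24 GLCM statistics of one normalized matrix."""
    ng = p.shape[0]
    i, ii, jj, diff, sum_idx, diff_idx, ksum, kdiff = _glcm_grids(ng)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sigx = float(np.sqrt(((i - mux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((i - muy) ** 2 * py).sum()))

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    psum = np.bincount(sum_idx, weights=p.ravel(), minlength=2 * ng + 1)
    pdiff = np.bincount(diff_idx, weights=p.ravel(), minlength=ng)

    cshift = ii + jj - mux - muy
    hxy = float(-_plog2(p).sum())
    pxpy = np.outer(px, py)
    hxy1 = float(-(p * np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)).sum())
    hxy2 = float(-_plog2(pxpy).sum())
    hx = float(-_plog2(px).sum())
    hy = float(-_plog2(py).sum())

    sum_avg = float((ksum * psum).sum())
    diff_avg = float((kdiff * pdiff).sum())
    off = diff > 0

    out = {
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_prominence": float((cshift**4 * p).sum()),
        "cluster_shade": float((cshift**3 * p).sum()),
        "cluster_tendency": float((cshift**2 * p).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": (
            float(((ii * jj * p).sum() - mux * muy) / (sigx * sigy))
            if sigx > 0 and sigy > 0
            else 0.0
        ),
        "difference_average": diff_avg,
        "difference_entropy": float(-_plog2(pdiff).sum()),
        "difference_variance": float(((kdiff - diff_avg) ** 2 * pdiff).sum()),
        "dissimilarity": float((diff * p).sum()),
        "imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
        "inverse_difference": float((p / (1.0 + diff)).sum()),
        "inverse_difference_moment": float((p / (1.0 + diff**2)).sum()),
        "inverse_difference_moment_normalized": float(
            (p / (1.0 + (diff / ng) ** 2)).sum()
        ),
        "inverse_difference_normalized": float((p / (1.0 + diff / ng)).sum()),
        "inverse_variance": float((p[off] / diff[off] ** 2).sum()),
        "joint_energy": float((p**2).sum()),
        "joint_entropy": hxy,
        "maximum_probability": float(p.max()),
        "sum_average": sum_avg,
        "sum_entropy": float(-_plog2(psum).sum()),
        "sum_of_squares_variance": float(((ii - mux) ** 2 * p).sum()),
        "sum_variance": float(((ksum - sum_avg) ** 2 * psum).sum()),
    }
    return out


def glcm_features(
    levels: np.ndarray, n_levels: int, delta: int = 1, symmetric: bool = True
) -> dict[str, float]:
    """Direction-averaged GLCM features over the 13 unique 3D offsets."""
    per_dir = []
    for d in DIRECTIONS_3D:
        p = glcm_build(levels, n_levels, d, delta=delta, symmetric=symmetric)
        if p is not None:
            per_dir.append(glcm_feature_values(p))
    if not per_dir:
        raise ExtractionError("no GLCM direction contains a valid voxel pair")
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLCM_FEATURES
    }


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_build(
    levels: np.ndarray, n_levels: int, direction: tuple[int, int, int]
) -> np.ndarray | None:
    """Run-length count matrix r(i, l) along one direction.

    Runs are maximal collinear segments of constant gray level inside the
    VOI.  Shape is (Ng, Lmax) with Lmax the longest geometrically possible
    run.  Returns ``None`` for an all-background grid.
    """
    in_voi = levels > 0
    if not in_voi.any():
        return None
    src, dst = _offset_slices(levels.shape, direction)
    # linked[x]: x and x+d belong to the same run
    linked = np.zeros(levels.shape, dtype=bool)
    linked[src] = in_voi[src] & in_voi[dst] & (levels[src] == levels[dst])

    # run starts: in VOI, with no same-run predecessor at x-d
    pred_linked = np.zeros(levels.shape, dtype=bool)
    pred_linked[dst] = linked[src]
    starts = in_voi & ~pred_linked

    # run length by pointer doubling: after k rounds, length = min(run, 2^k)
    # and linked means "the run continues for >= 2^k further voxels"
    length = in_voi.astype(np.int64)
    step = 1
    while linked.any():
        s_src, s_dst = _offset_slices(levels.shape, direction, delta=step)
        shifted_len = np.zeros(levels.shape, dtype=np.int64)
        shifted_len[s_src] = length[s_dst]
        shifted_link = np.zeros(levels.shape, dtype=bool)
        shifted_link[s_src] = linked[s_dst]
        length = length + np.where(linked, shifted_len, 0)
        linked = linked & shifted_link
        step *= 2
        if step > max(levels.shape):
            break

    run_levels = levels[starts].astype(np.int64) - 1
    run_lengths = length[starts] - 1  # 0-based for bincount
    lmax = max(int(levels.shape[i]) for i in range(3) if direction[i] != 0)
    counts = np.bincount(
        run_levels * lmax + run_lengths, minlength=n_levels * lmax
    )
    return counts.reshape(n_levels, lmax).astype(np.float64)


def glrlm_feature_values(r: np.ndarray) -> dict[str, float]:
    """The 12 run-length statistics of one count matrix."""
    nr = r.sum()
    ng, lmax = r.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    ell = np.arange(1, lmax + 1, dtype=np.float64)[None, :]
    n_vox = float((r * ell).sum())  # voxels traversed along this direction
    ri = r.sum(axis=1)  # per gray level
    rl = r.sum(axis=0)  # per run length
    mu_i = float((i[:, 0] * ri).sum() / nr)
    return {
        "short_run_emphasis": float((r / ell**2).sum() / nr),
        "long_run_emphasis": float((r * ell**2).sum() / nr),
        "gray_level_nonuniformity": float((ri**2).sum() / nr),
        "run_length_nonuniformity": float((rl**2).sum() / nr),
        "run_percentage": float(nr / n_vox),
        "low_gray_level_run_emphasis": float((r / i**2).sum() / nr),
        "high_gray_level_run_emphasis": float((r * i**2).sum() / nr),
        "short_run_low_gray_level_emphasis": float((r / (i**2 * ell**2)).sum() / nr),
        "short_run_high_gray_level_emphasis": float((r * i**2 / ell**2).sum() / nr),
        "long_run_low_gray_level_emphasis": float((r * ell**2 / i**2).sum() / nr),
        "long_run_high_gray_level_emphasis": float((r * i**2 * ell**2).sum() / nr),
        "gray_level_variance": float(((i[:, 0] - mu_i) ** 2 * ri).sum() / nr),
    }


def glrlm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """Direction-averaged GLRLM features over the 13 unique 3D offsets."""
    per_dir = []
    for d in DIRECTIONS_3D:
        r = glrlm_build(levels, n_levels, d)
        if r is not None and r.sum() > 0:
            per_dir.append(glrlm_feature_values(r))
    if not per_dir:
        raise ExtractionError("no GLRLM direction contains a run")
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_FEATURES
    }
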