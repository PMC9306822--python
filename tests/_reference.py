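"""Independent brute-force reference implementations used as test oracles.

Deliberately slow and simple: explicit loops, no shared code with the
package internals they check.
"""

from __future__ import annotations

import numpy as np


def brute_refine(data: np.ndarray, mask: np.ndarray, radius: float = 5.0,
                 k_sd: float = 1.0) -> np.ndarray:
    """Reference border refinement: explicit triple loop over all voxels.

    Frozen mu/population-SD over the input mask; a voxel belongs to the
    shell iff its squared center distance to some 6-neighbor border voxel
    is <= radius²; shell voxels are relabeled by |I - mu| <= k_sd * s.
    """
    vals = data[mask]
    mu = vals.mean()
    s = vals.std()
    nx, ny, nz = mask.shape
    border = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    a, b, c = i + di, j + dj, k + dk
                    if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz) or not mask[a, b, c]:
                        border.append((i, j, k))
                        break
    out = mask.copy()
    r2 = radius * radius + 1e-9
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                for a, b, c in border:
                    if (i - a) ** 2 + (j - b) ** 2 + (k - c) ** 2 <= r2:
                        out[i, j, k] = abs(data[i, j, k] - mu) <= k_sd * s
                        break
    return out


def brute_ball_count(radius: float) -> int:
    """Number of integer offsets with Euclidean norm <= radius."""
    r = int(np.ceil(radius))
    count = 0
    for i in range(-r, r + 1):
        for j in range(-r, r + 1):
            for k in range(-r, r + 1):
                if i * i + j * j + k * k <= radius * radius + 1e-12:
                    count += 1
    return count


def icc_two_way_oracle(a, b):
    """ICC(A,1) from explicit ANOVA sums of squares (plain Python loops)."""
    a = list(map(float, a))
    b = list(map(float, b))
    n = len(a)
    k = 2
    grand = (sum(a) + sum(b)) / (n * k)
    ssr = 0.0
    for i in range(n):
        rm = (a[i] + b[i]) / 2.0
        ssr += k * (rm - grand) ** 2
    ca = sum(a) / n
    cb = sum(b) / n
    ssc = n * ((ca - grand) ** 2 + (cb - grand) ** 2)
    sst = 0.0
    for x in a + b:
        sst += (x - grand) ** 2
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def random_blob_fixture(rng: np.random.Generator, max_side: int = 16):
    """Small random grayscale volume + blobby mask for oracle comparisons."""
    shape = tuple(int(rng.integers(8, max_side + 1)) for _ in range(3))
    c = np.array(shape) / 2.0 + rng.uniform(-1.5, 1.5, 3)
    g = np.indices(shape).transpose(1, 2, 3, 0)
    r = rng.uniform(2.0, min(shape) / 2.0 - 1.0)
    mask = ((g - c) ** 2).sum(-1) <= r * r
    mask |= rng.random(shape) < 0.05
    if not mask.any():
        mask[tuple(np.array(shape) // 2)] = True
    data = np.clip(rng.normal(150.0, 40.0, shape), 0.0, 255.0)
    return data, mask
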