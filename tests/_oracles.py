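"""Independent reference implementations used only by the tests.

These are deliberately naive (explicit Python loops, no vectorization,
no reuse of the package's computational kernels) so they can serve as
oracles for the production code paths.
"""

from __future__ import annotations

import numpy as np

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def naive_local_moran(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Observed local Moran's I by explicit double loops.

    Standardized form: I_i = (z_i / m2) * sum_j W_ij z_j with
    z = x - xbar over on-mask pixels, m2 = mean(z^2), queen contiguity
    and row-standardized weights. Off-mask and isolated pixels are NaN.
    """
    h, w = values.shape
    xs = [values[r, c] for r in range(h) for c in range(w) if mask[r, c]]
    xbar = sum(xs) / len(xs)
    m2 = sum((x - xbar) ** 2 for x in xs) / len(xs)
    out = np.full((h, w), np.nan)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            neigh = []
            for dr, dc in _OFFSETS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                    neigh.append(values[rr, cc])
            if not neigh:
                continue
            lag = sum(v - xbar for v in neigh) / len(neigh)
            out[r, c] = (values[r, c] - xbar) / m2 * lag
    return out


def naive_conditional_p(
    values: np.ndarray, mask: np.ndarray, n_perm: int, seed: int,
    draw_indices,
) -> np.ndarray:
    """Conditional-permutation pseudo p-values by explicit loops.

    ``draw_indices(seed, flat_index, n_other, n_perm, k)`` must yield
    the same without-replacement index draws as the implementation
    under test (the permutation stream is shared; everything downstream
    of the draws — lags, I statistics, tail counts — is recomputed here
    independently, permutation by permutation).
    """
    h, w = values.shape
    on = [(r, c) for r in range(h) for c in range(w) if mask[r, c]]
    n = len(on)
    xs = [values[r, c] for r, c in on]
    xbar = sum(xs) / n
    z = [x - xbar for x in xs]
    m2 = sum(v * v for v in z) / n
    rank = {pos: i for i, pos in enumerate(on)}
    out = np.full((h, w), np.nan)
    for i, (r, c) in enumerate(on):
        neigh = []
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                neigh.append(rank[(rr, cc)])
        k = len(neigh)
        if k == 0:
            continue
        lag_obs = sum(z[j] for j in neigh) / k
        i_obs = z[i] / m2 * lag_obs
        draws = draw_indices(seed, r * w + c, n - 1, n_perm, k)
        count = 0
        for row in draws:
            lag_p = 0.0
            for d in row:
                j = d + 1 if d >= i else d  # skip the focal observation
                lag_p += z[j]
            i_p = z[i] / m2 * (lag_p / k)
            if i_obs >= 0 and i_p >= i_obs:
                count += 1
            elif i_obs < 0 and i_p <= i_obs:
                count += 1
        out[r, c] = (count + 1) / (n_perm + 1)
    return out
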