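"""Independent brute-force oracles used by the test suite.

Deliberately naive re-implementations (explicit loops, no shared code with
the package) of the quantities the fast implementations must reproduce.
"""

from itertools import combinations
import math

import numpy as np


def stepdown_oracle(stack_a: np.ndarray, stack_b: np.ndarray) -> dict:
    """Step-down and single-step adjusted p-values by exhaustive loops.

    No variance smoothing.  Returns flat arrays ordered like the flattened
    input grid.
    """
    n_a = stack_a.shape[0]
    n_b = stack_b.shape[0]
    data = np.concatenate([stack_a, stack_b]).reshape(n_a + n_b, -1)
    m = data.shape[1]
    labelings = list(combinations(range(n_a + n_b), n_a))
    n_perm = len(labelings)

    def t_image(a_idx):
        b_idx = [i for i in range(n_a + n_b) if i not in a_idx]
        t = np.empty(m)
        for i in range(m):
            a = data[list(a_idx), i]
            b = data[b_idx, i]
            va = sum((x - a.mean()) ** 2 for x in a) / (n_a - 1)
            vb = sum((x - b.mean()) ** 2 for x in b) / (n_b - 1)
            denom = math.sqrt(va / n_a + vb / n_b)
            d = a.mean() - b.mean()
            t[i] = d / denom if denom > 0 else (0.0 if d == 0 else math.copysign(math.inf, d))
        return t

    t_all = [t_image(lab) for lab in labelings]
    t_obs = t_all[0]
    order = np.argsort(t_obs, kind="stable")

    p_act = np.empty(m)
    p_deact = np.empty(m)
    p_single_act = np.empty(m)
    for pos in range(m):
        cell = order[pos]
        ca = cd = cs = 0
        for t in t_all:
            succ_max = max(t[order[q]] for q in range(pos + 1))
            succ_min = min(t[order[q]] for q in range(pos, m))
            if succ_max >= t_obs[cell]:
                ca += 1
            if succ_min <= t_obs[cell]:
                cd += 1
            if max(t) >= t_obs[cell]:
                cs += 1
        p_act[cell] = ca / n_perm
        p_deact[cell] = cd / n_perm
        p_single_act[cell] = cs / n_perm
    # enforce monotonicity along the sorted order
    for pos in range(m - 2, -1, -1):
        p_act[order[pos]] = max(p_act[order[pos]], p_act[order[pos + 1]])
        p_single_act[order[pos]] = max(
            p_single_act[order[pos]], p_single_act[order[pos + 1]]
        )
    for pos in range(1, m):
        p_deact[order[pos]] = max(p_deact[order[pos]], p_deact[order[pos - 1]])
    return {
        "t": t_obs,
        "p_activation": p_act,
        "p_deactivation": p_deact,
        "p_single_step_activation": p_single_act,
        "n": n_perm,
    }


def local_orthogonal_fit(points: np.ndarray, idx: int, half: int):
    """Unweighted total-least-squares line through a window (SVD route)."""
    lo = max(0, idx - half)
    hi = min(len(points), idx + half + 1)
    nbrs = points[lo:hi]
    centre = nbrs.mean(axis=0)
    _, _, vt = np.linalg.svd(nbrs - centre)
    direction = vt[0]
    return centre, direction


def orthogonal_residual_ss(points: np.ndarray, ref_points: np.ndarray, half: int) -> float:
    """Sum of squared orthogonal distances of ``points`` to local TLS lines
    fitted through ``ref_points`` windows."""
    total = 0.0
    for i in range(len(points)):
        centre, direction = local_orthogonal_fit(ref_points, i, half)
        rel = points[i] - centre
        total += float(rel @ rel - (rel @ direction) ** 2)
    return total


def arc_resample_oracle(points: np.ndarray, k: int) -> np.ndarray:
    """Equal-arc-length placement via dense cumulative chord length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    out = []
    for target in np.linspace(0.0, s[-1], k):
        j = int(np.searchsorted(s, target, side="right")) - 1
        j = min(j, len(points) - 2)
        frac = 0.0 if seg[j] == 0 else (target - s[j]) / seg[j]
        out.append(points[j] + frac * (points[j + 1] - points[j]))
    return np.asarray(out)
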