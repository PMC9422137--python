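"""Independent brute-force oracles used to check geometric and likelihood code.

Deliberately naive implementations — all-pairs orientation tests, per-segment
distance minimization, extended-precision softmax enumeration — kept separate
from the package so they share no code with what they verify.
"""

from __future__ import annotations

import numpy as np


def _orient(a, b, c) -> float:
    return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])


def segments_cross(p, q, a, b) -> bool:
    """Proper crossing of segment pq with segment ab (orientation tests)."""
    o1, o2 = _orient(p, q, a), _orient(p, q, b)
    o3, o4 = _orient(a, b, p), _orient(a, b, q)
    return (o1 > 0) != (o2 > 0) and (o3 > 0) != (o4 > 0)


def brute_crossing_count(p, q, polylines) -> int:
    """All-pairs crossing count of segment pq against a list of coordinate
    arrays (each (n,2)); counts each properly crossed sub-segment."""
    total = 0
    for coords in polylines:
        for i in range(len(coords) - 1):
            if segments_cross(p, q, coords[i], coords[i + 1]):
                total += 1
    return total


def point_segment_distance(pt, a, b) -> float:
    pt, a, b = map(np.asarray, (pt, a, b))
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return float(np.hypot(*(pt - a)))
    t = np.clip(float((pt - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t * ab
    return float(np.hypot(*(pt - proj)))


def brute_min_distance(pt, polylines) -> float:
    best = np.inf
    for coords in polylines:
        for i in range(len(coords) - 1):
            best = min(best, point_segment_distance(pt, coords[i], coords[i + 1]))
    return best


def enumerate_loglik(beta, X, strata_ids, case) -> float:
    """Stratum-by-stratum softmax log-likelihood in extended precision."""
    beta = np.asarray(beta, dtype=np.longdouble)
    X = np.asarray(X, dtype=np.longdouble)
    ll = np.longdouble(0)
    for sid in dict.fromkeys(strata_ids):  # preserve order
        mask = np.asarray([s == sid for s in strata_ids])
        eta = X[mask] @ beta
        used = eta[np.asarray(case)[mask]]
        assert len(used) == 1
        ll += used[0] - np.log(np.exp(eta).sum())
    return float(ll)


def nearest_rank_percentile_sorted(values, percentile) -> float:
    """Sort-based nearest-rank percentile (independent of the package's)."""
    v = sorted(values)
    import math

    rank = max(1, math.ceil(percentile / 100.0 * len(v)))
    return float(v[rank - 1])


def simulate_clogit_strata(beta, n_strata, rng, n_alt=6):
    """Matched strata straight from the conditional-logit model itself.

    Each stratum: n_alt candidates with N(0,1) covariates; the used one is
    drawn with probability softmax(X beta). Returns (X, strata_ids, case).
    """
    beta = np.asarray(beta, dtype=float)
    p = len(beta)
    X = rng.normal(size=(n_strata * n_alt, p))
    ids, case = [], np.zeros(n_strata * n_alt, dtype=bool)
    for s in range(n_strata):
        rows = slice(s * n_alt, (s + 1) * n_alt)
        eta = X[rows] @ beta
        prob = np.exp(eta - eta.max())
        prob /= prob.sum()
        case[s * n_alt + rng.choice(n_alt, p=prob)] = True
        ids.extend([s] * n_alt)
    return X, ids, case
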