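"""Independent brute-force reference implementations used by the tests.

These deliberately use plain loops and textbook formulas, sharing no code
with the package internals they check.
"""

import itertools

import numpy as np
from scipy import stats


def brute_force_plurality(votes):
    """Per-voxel plurality label, ties toward the smallest code."""
    stack = np.stack(votes)
    codes = np.unique(stack)
    out = np.zeros(votes[0].shape, dtype=stack.dtype)
    for idx in np.ndindex(votes[0].shape):
        vals = stack[(slice(None), *idx)]
        best, best_n = None, -1
        for c in codes:
            n = int((vals == c).sum())
            if n > best_n:
                best, best_n = c, n
        out[idx] = best
    return out


def flood_fill_components(supra, adj_lists):
    """Connected components of a suprathreshold vertex set via BFS."""
    seen, comps = set(), []
    for v in sorted(supra):
        if v in seen:
            continue
        stack, comp = [v], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(w for w in adj_lists[u] if w in supra and w not in comp)
        seen |= comp
        comps.append(comp)
    return comps


def loop_ols_tmap(Y, valid, X, contrast, min_valid_fraction=0.25):
    """Per-vertex OLS t statistics via explicit loops."""
    n, V = Y.shape
    p = X.shape[1]
    min_valid = int(np.ceil(min_valid_fraction * n))
    t = np.zeros(V)
    df = np.zeros(V, dtype=int)
    ok = np.zeros(V, dtype=bool)
    for j in range(V):
        m = valid[:, j]
        if m.sum() < max(min_valid, p + 1):
            continue
        Xm = X[m]
        if np.linalg.matrix_rank(Xm) < p:
            continue
        beta, *_ = np.linalg.lstsq(Xm, Y[m, j], rcond=None)
        r = Y[m, j] - Xm @ beta
        s2 = r @ r / (m.sum() - p)
        se = np.sqrt(s2 * (contrast @ np.linalg.inv(Xm.T @ Xm) @ contrast))
        t[j] = contrast @ beta / se if se > 0 else 0.0
        df[j] = m.sum() - p
        ok[j] = True
    return t, df, ok


def freedman_lane_exhaustive(Y, valid, X, contrast, adj_lists, cluster_p,
                             min_valid_fraction=0.25):
    """Exhaustive Freedman-Lane cluster FWE by plain enumeration.

    Returns the observed suprathreshold components and their exact
    corrected p-values (fraction of all n! permutations, identity included,
    whose max extent reaches the observed extent).
    """
    n, V = Y.shape
    nz = np.where(contrast == 0)[0]
    Z = X[:, nz]
    pz = Z.shape[1]

    def max_extent(t, df, ok):
        supra = {
            j for j in range(V)
            if ok[j] and stats.t.cdf(t[j], df[j]) < cluster_p
        }
        comps = flood_fill_components(supra, adj_lists)
        return (max((len(c) for c in comps), default=0), comps)

    t0, df0, ok0 = loop_ols_tmap(Y, valid, X, contrast, min_valid_fraction)
    _, obs_comps = max_extent(t0, df0, ok0)

    fit = np.zeros((n, V))
    resid = np.zeros((n, V))
    reduced_ok = np.zeros(V, dtype=bool)
    for j in range(V):
        m = valid[:, j]
        if m.sum() <= pz:
            continue
        g, *_ = np.linalg.lstsq(Z[m], Y[m, j], rcond=None)
        fit[m, j] = Z[m] @ g
        resid[m, j] = Y[m, j] - fit[m, j]
        reduced_ok[j] = True

    maxima = []
    vp = valid & reduced_ok[None, :]
    for perm in itertools.permutations(range(n)):
        perm = np.array(perm)
        rank = np.empty(n, dtype=int)
        rank[perm] = np.arange(n)
        # per vertex, reorder the valid rows by their global-permutation rank
        Yp = np.zeros((n, V))
        for j in range(V):
            rows = np.where(valid[:, j])[0]
            source = rows[np.argsort(rank[rows], kind="stable")]
            Yp[rows, j] = fit[rows, j] + resid[source, j]
        tp, dfp, okp = loop_ols_tmap(Yp, vp, X, contrast, min_valid_fraction)
        maxima.append(max_extent(tp, dfp, okp)[0])
    maxima = np.array(maxima)
    pvals = [(maxima >= len(c)).mean() for c in obs_comps]
    return obs_comps, pvals, maxima
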