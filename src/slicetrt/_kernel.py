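"""Numba hot loop for the slice-Gibbs sweeps.

The sweep order and truncation bounds mirror the pure-numpy reference
implementation in :mod:`slicetrt.sampler` (which is the oracle/debug path);
this module only makes the identical updates fast.  Randomness comes from
numba's internal np.random state, seeded once per chain, so a chain is
deterministic given its seed.

Truncated-normal draws use inverse-CDF sampling on the normal-CDF scale
(Acklam's rational approximation for the normal quantile plus one Halley
refinement) with an exponential-rejection fallback (Robert, 1995) once a
standardized bound is more than 5 SDs into a tail, where the CDF difference
underflows.
"""

import math

import numpy as np
from numba import njit

_SQRT_2PI = 2.5066282746310002
_GUARD = 1e-12

MODEL_CODE = {"2pl": 0, "t2pltm": 1, "n2pltm": 2}
FAMILY_CODE = {"normal": 0, "uniform": 1}


@njit(cache=True)
def _ndtr(x):
    return 0.5 * math.erfc(-x * 0.7071067811865476)


@njit(cache=True)
def _ndtri(p):
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    # Acklam's approximation, |relative error| < 1.15e-9 before refinement.
    if p < 0.02425:
        q = math.sqrt(-2.0 * math.log(p))
        x = (((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
              + 4.374664141464968e+00) * q + 2.938163982698783e+00) / \
            ((((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
               + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    elif p > 0.97575:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        x = -(((((-7.784894002430293e-03 * q - 3.223964580411365e-01) * q
                 - 2.400758277161838e+00) * q - 2.549732539343734e+00) * q
               + 4.374664141464968e+00) * q + 2.938163982698783e+00) / \
            ((((7.784695709041462e-03 * q + 3.224671290700398e-01) * q
               + 2.445134137142996e+00) * q + 3.754408661907416e+00) * q + 1.0)
    else:
        q = p - 0.5
        r = q * q
        x = (((((-3.969683028665376e+01 * r + 2.209460984245205e+02) * r
                - 2.759285104469687e+02) * r + 1.383577518672690e+02) * r
              - 3.066479806614716e+01) * r + 2.506628277459239e+00) * q / \
            (((((-5.447609879822406e+01 * r + 1.615858368580409e+02) * r
                - 1.556989798598866e+02) * r + 6.680131188771972e+01) * r
              - 1.328068155288572e+01) * r + 1.0)
    # One step of Halley's method against the exact CDF.
    e = _ndtr(x) - p
    u = e * _SQRT_2PI * math.exp(0.5 * x * x)
    x = x - u / (1.0 + 0.5 * x * u)
    return x


@njit(cache=True)
def _tail_right(lo, hi):
    """N(0,1) truncated to [lo, hi] with 5 <= lo; exponential rejection."""
    rate = 0.5 * (lo + math.sqrt(lo * lo + 4.0))
    for _ in range(20000):
        u = np.random.random()
        if u <= 0.0:
            continue
        z = lo - math.log(u) / rate
        if z > hi:
            continue
        if np.random.random() <= math.exp(-0.5 * (z - rate) * (z - rate)):
            return z
    # Extremely narrow far-tail interval: uniform rejection.
    for _ in range(200000):
        z = lo + np.random.random() * (hi - lo)
        if np.random.random() <= math.exp(0.5 * (lo * lo - z * z)):
            return z
    return lo


@njit(cache=True)
def _tn_standard(lo, hi):
    if hi <= lo:
        return 0.5 * (lo + hi)
    if hi - lo < 1e-13:
        return 0.5 * (lo + hi)
    if lo > 5.0:
        return _tail_right(lo, hi)
    if hi < -5.0:
        return -_tail_right(-hi, -lo)
    pa = _ndtr(lo)
    pb = _ndtr(hi)
    u = pa + np.random.random() * (pb - pa)
    if u < 1e-300:
        u = 1e-300
    if u > 1.0 - 1e-16:
        u = 1.0 - 1e-16
    x = _ndtri(u)
    if x < lo:
        x = lo
    if x > hi:
        x = hi
    return x


@njit(cache=True)
def _tn(mu, sd, lo, hi):
    return mu + sd * _tn_standard((lo - mu) / sd, (hi - mu) / sd)


@njit(cache=True)
def _inv_gamma(shape, scale):
    """Draw from InverseGamma(shape, scale): 1/X with X ~ Gamma(shape, 1/scale)."""
    g = np.random.gamma(shape, 1.0 / scale)
    if g <= 0.0:
        g = 1e-300
    return 1.0 / g


@njit(cache=True)
def run_chain_kernel(
    Y, assign, sizes, model, family,
    mu_a, mu_b, mu_eta,
    hier_items,
    a_lo_u, a_hi_u, b_lo_u, b_hi_u,
    v1, tau1, v2, tau2, v3, tau3,
    a, b, theta, eta, s2a, s2b, s2eta,
    fixed_item,
    upd_a, upd_b, upd_theta, upd_eta, upd_var,
    n_iter, burn, thin, seed,
    out_a, out_b, out_theta, out_eta, out_s2a, out_s2b, out_s2eta,
):
    """One chain of the auxiliary-variable slice-Gibbs sampler.

    Sweep order per iteration: auxiliary slice variables, then a_j (all
    non-fixed items), b_j, theta_i, eta_ik, then the variance parameters.
    ``T[i, j]`` stores the logit-scale slice constraint for each cell:
    a lower bound on the linear predictor where y=1 (log(lam/(1-lam))) and an
    upper bound where y=0 (log((1-phi)/phi)).  Every update is drawn inside
    bounds that keep all constraints satisfied, so no draw is ever rejected.

    Returns the number of bound inversions encountered (0 in a healthy run;
    on an inversion the parameter keeps its current, still-valid value).
    """
    np.random.seed(seed)
    n, J = Y.shape
    K = sizes.shape[0]
    tes_sum = np.zeros(K)
    for j in range(J):
        tes_sum[assign[j]] += a[j]
    # member lists: items of testlet k are members_flat[offsets[k]:offsets[k+1]]
    offsets = np.zeros(K + 1, dtype=np.int64)
    for k in range(K):
        offsets[k + 1] = offsets[k] + sizes[k]
    fill = offsets[:-1].copy()
    members_flat = np.empty(J, dtype=np.int64)
    for j in range(J):
        members_flat[fill[assign[j]]] = j
        fill[assign[j]] += 1
    T = np.empty((n, J))
    store = 0
    err = 0

    for it in range(n_iter):
        # --- Step 1: auxiliary slice variables (kept as logit-scale targets)
        for i in range(n):
            th = theta[i]
            for j in range(J):
                k = assign[j]
                if model == 2:
                    z = a[j] * (th - b[j]) + (tes_sum[k] / sizes[k]) * eta[i, k]
                elif model == 1:
                    z = a[j] * (th - b[j] + eta[i, k])
                else:
                    z = a[j] * (th - b[j])
                p = 1.0 / (1.0 + math.exp(-z))
                if p < _GUARD:
                    p = _GUARD
                elif p > 1.0 - _GUARD:
                    p = 1.0 - _GUARD
                u = np.random.random()
                if u < 1e-300:
                    u = 1e-300
                if Y[i, j] == 1:
                    lam = u * p
                    T[i, j] = math.log(lam / (1.0 - lam))
                else:
                    phi = u * (1.0 - p)
                    T[i, j] = math.log((1.0 - phi) / phi)

        # --- Step 2: discriminations.  Under the n2pltm a_j enters every
        # sibling item's linear predictor through alpha_d, so all cells of
        # the testlet constrain a_j (coefficient eta_ik / n_d for siblings).
        if upd_a == 1:
            for j in range(J):
                if fixed_item[j] == 1:
                    continue
                k = assign[j]
                inv_nd = 1.0 / sizes[k]
                sum_others = tes_sum[k] - a[j]
                lo = 0.0
                hi = np.inf
                if model == 2:
                    for idx in range(offsets[k], offsets[k + 1]):
                        jj = members_flat[idx]
                        for i in range(n):
                            e = eta[i, k]
                            if jj == j:
                                c = theta[i] - b[j] + e * inv_nd
                                t = T[i, j] - sum_others * inv_nd * e
                            else:
                                c = e * inv_nd
                                t = (T[i, jj] - a[jj] * (theta[i] - b[jj])
                                     - sum_others * inv_nd * e)
                            if c == 0.0:
                                continue
                            v = t / c
                            if Y[i, jj] == 1:
                                if c > 0.0:
                                    if v > lo:
                                        lo = v
                                else:
                                    if v < hi:
                                        hi = v
                            else:
                                if c > 0.0:
                                    if v < hi:
                                        hi = v
                                else:
                                    if v > lo:
                                        lo = v
                else:
                    for i in range(n):
                        if model == 1:
                            c = theta[i] - b[j] + eta[i, k]
                        else:
                            c = theta[i] - b[j]
                        if c == 0.0:
                            continue
                        v = T[i, j] / c
                        if Y[i, j] == 1:
                            if c > 0.0:
                                if v > lo:
                                    lo = v
                            else:
                                if v < hi:
                                    hi = v
                        else:
                            if c > 0.0:
                                if v < hi:
                                    hi = v
                            else:
                                if v > lo:
                                    lo = v
                if hi < lo:
                    err += 1
                    continue
                if family == 1:
                    l2 = max(lo, a_lo_u)
                    h2 = min(hi, a_hi_u)
                    if h2 < l2:
                        err += 1
                        continue
                    new = l2 + np.random.random() * (h2 - l2)
                else:
                    new = _tn(mu_a, math.sqrt(s2a), lo, hi)
                if new <= 0.0:
                    new = _GUARD
                tes_sum[k] += new - a[j]
                a[j] = new

        # --- Step 3: difficulties
        if upd_b == 1:
            for j in range(J):
                if fixed_item[j] == 1:
                    continue
                k = assign[j]
                if model == 2:
                    load = tes_sum[k] / sizes[k]
                elif model == 1:
                    load = a[j]
                else:
                    load = 0.0
                inv_a = 1.0 / a[j]
                lo = -np.inf
                hi = np.inf
                for i in range(n):
                    m = theta[i] - (T[i, j] - load * eta[i, k]) * inv_a
                    if Y[i, j] == 1:
                        if m < hi:
                            hi = m
                    else:
                        if m > lo:
                            lo = m
                if hi < lo:
                    err += 1
                    continue
                if family == 1:
                    l2 = max(lo, b_lo_u)
                    h2 = min(hi, b_hi_u)
                    if h2 < l2:
                        err += 1
                        continue
                    b[j] = l2 + np.random.random() * (h2 - l2)
                else:
                    b[j] = _tn(mu_b, math.sqrt(s2b), lo, hi)

        # --- Step 4: abilities (standard-normal prior, identification)
        if upd_theta == 1:
            for i in range(n):
                lo = -np.inf
                hi = np.inf
                for j in range(J):
                    k = assign[j]
                    if model == 2:
                        load = tes_sum[k] / sizes[k]
                    elif model == 1:
                        load = a[j]
                    else:
                        load = 0.0
                    v = (T[i, j] - load * eta[i, k]) / a[j] + b[j]
                    if Y[i, j] == 1:
                        if v > lo:
                            lo = v
                    else:
                        if v < hi:
                            hi = v
                if hi < lo:
                    err += 1
                    continue
                theta[i] = _tn(0.0, 1.0, lo, hi)

        # --- Step 5: testlet effects
        if upd_eta == 1 and model != 0:
            for k in range(K):
                sd = math.sqrt(s2eta[k])
                alpha_k = tes_sum[k] / sizes[k]
                for i in range(n):
                    lo = -np.inf
                    hi = np.inf
                    for idx in range(offsets[k], offsets[k + 1]):
                        j = members_flat[idx]
                        load = alpha_k if model == 2 else a[j]
                        v = (T[i, j] - a[j] * (theta[i] - b[j])) / load
                        if Y[i, j] == 1:
                            if v > lo:
                                lo = v
                        else:
                            if v < hi:
                                hi = v
                    if hi < lo:
                        err += 1
                        continue
                    eta[i, k] = _tn(mu_eta, sd, lo, hi)

        # --- Steps 6-8: conjugate variance updates
        if upd_var == 1:
            if family == 0 and hier_items == 1:
                ssa = 0.0
                ssb = 0.0
                for j in range(J):
                    ssa += (a[j] - mu_a) ** 2
                    ssb += (b[j] - mu_b) ** 2
                s2a = _inv_gamma(0.5 * J + v1, 0.5 * ssa + tau1)
                s2b = _inv_gamma(0.5 * J + v2, 0.5 * ssb + tau2)
            if model != 0:
                for k in range(K):
                    ss = 0.0
                    for i in range(n):
                        ss += (eta[i, k] - mu_eta) ** 2
                    s2eta[k] = _inv_gamma(0.5 * n + v3, 0.5 * ss + tau3)

        # --- store post-burn-in states
        if it >= burn and (it - burn) % thin == 0:
            for j in range(J):
                out_a[store, j] = a[j]
                out_b[store, j] = b[j]
            for i in range(n):
                out_theta[store, i] = theta[i]
                for k in range(K):
                    out_eta[store, i, k] = eta[i, k]
            out_s2a[store] = s2a
            out_s2b[store] = s2b
            for k in range(K):
                out_s2eta[store, k] = s2eta[k]
            store += 1

    return err
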