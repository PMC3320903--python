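"""Compiled inner loops for circular binary segmentation.

The hot quantity is the pooled-variance two-sample t-statistic between an
arc [i, j) of a (circular) series and its complement.  With centered
values, prefix sums s, total sum of squares ss, arc width k = j - i,
complement width kc = m - k and arc sum s1 = s[j] - s[i]:

    A   = s1 * m - T * k                   (T = total sum, ~0 after centering)
    B   = ss * k * kc - s1^2 * kc - (T - s1)^2 * k
    t^2 = A^2 * (m - 2) / (m * B)

Two structural facts keep the scans cheap:

* for fixed width k, t^2 is strictly increasing in the deviation of the
  arc sum from its expectation T * k / m, so only the max and min sliding
  sums of each width need evaluating;
* "t >= thresh" is "A^2 >= thresh^2 * m / (m - 2) * B", which needs no
  sqrt or division.

B is floored at a small multiple of ss * k * kc so that degenerate arcs
(zero within variance but a real mean difference, i.e. an infinite t) map
to a huge finite value; the floor depends only on (ss, k, kc), which
permutation preserves, so observed and permuted statistics stay
comparable.
"""

import numba as nb
import numpy as np

# Relative floor on the within sum of squares term B.
_B_RTOL = 1e-13


@nb.njit(cache=True)
def _prep(x):
    """Center x; return (prefix sums, total sum of squares, total sum)."""
    m = x.shape[0]
    mu = 0.0
    for k in range(m):
        mu += x[k]
    mu /= m
    s = np.empty(m + 1)
    s[0] = 0.0
    ss = 0.0
    for k in range(m):
        v = x[k] - mu
        s[k + 1] = s[k] + v
        ss += v * v
    return s, ss, s[m]


@nb.njit(cache=True)
def _row_r(s1, tot, k, m, ss):
    """r = A^2 / B for an arc of width k with arc sum s1 (t^2 up to the
    constant (m - 2) / m)."""
    fm = float(m)
    fk = float(k)
    fkc = float(m - k)
    a = s1 * fm - tot * fk
    u = tot - s1
    b = ss * (fk * fkc) - s1 * s1 * fkc - u * u * fk
    bf = _B_RTOL * ss * (fk * fkc)
    if b < bf:
        b = bf
    return a * a / b


@nb.njit(cache=True)
def max_arc_t(x, min_width):
    """Return (i, j, t): boundaries of the arc [i, j) maximizing |t| vs its
    complement, over all arcs with both sides >= min_width markers.

    On a circle every arc pair is {[i, j), complement}, so enumerating
    linear intervals covers wrapped arcs too.  Ties keep the smallest start
    index, then the shortest arc.  A constant series returns t = 0.
    """
    m = x.shape[0]
    s, ss, tot = _prep(x)
    if ss <= 0.0:
        return 0, min_width, 0.0
    k_lo = min_width
    k_hi = m - min_width
    # phase 1: per width, extreme sliding sums and their r values
    vmx = np.empty(k_hi + 1)
    vmn = np.empty(k_hi + 1)
    rmx = np.empty(k_hi + 1)
    rmn = np.empty(k_hi + 1)
    best_r = -1.0
    for k in range(k_lo, k_hi + 1):
        mx = s[k] - s[0]
        mn = mx
        for i in range(1, m - k + 1):
            d = s[i + k] - s[i]
            mx = max(mx, d)
            mn = min(mn, d)
        vmx[k] = mx
        vmn[k] = mn
        rmx[k] = _row_r(mx, tot, k, m, ss)
        rmn[k] = _row_r(mn, tot, k, m, ss)
        best_r = max(best_r, max(rmx[k], rmn[k]))
    # phase 2: recover the first (smallest start, then shortest arc) index
    # pair attaining best_r; only widths that tie need rescanning
    bi = -1
    bj = -1
    for k in range(k_lo, k_hi + 1):
        hit_mx = rmx[k] == best_r
        hit_mn = rmn[k] == best_r
        if not (hit_mx or hit_mn):
            continue
        for i in range(m - k + 1):
            d = s[i + k] - s[i]
            if (hit_mx and d == vmx[k]) or (hit_mn and d == vmn[k]):
                if bi < 0 or i < bi or (i == bi and k < bj - bi):
                    bi = i
                    bj = i + k
                break
    t = np.sqrt(best_r * (m - 2) / m)
    return bi, bj, t


@nb.njit(cache=True, fastmath={"reassoc", "nsz", "contract"})
def _arc_t_exceeds(s, ss, tot, m, c_thresh, min_width):
    """True iff any admissible arc satisfies A^2 >= c_thresh * B, i.e.
    |t| >= thresh with c_thresh = thresh^2 * m / (m - 2).

    Widths are visited in folded order (w, m - w, w + 1, ...): on
    exchangeable noise the maximal circular arc is usually narrow --
    either as a narrow interval or as the wide linear complement of a
    wrapped narrow arc -- so exceedances surface after a few rows.
    """
    fm = float(m)
    for w in range(min_width, m // 2 + 1):
        k = w
        while True:
            kc = m - k
            fk = float(k)
            fkc = float(kc)
            ck = ss * (fk * fkc)
            bf = _B_RTOL * ck
            tk = tot * fk / fm
            n = m - k + 1
            mx = s[k] - s[0]
            mn = mx
            for i in range(1, n):
                d = s[i + k] - s[i]
                mx = max(mx, d)
                mn = min(mn, d)
            # t^2 monotone in |arc sum - expected|: larger deviation wins
            s1 = mx if mx - tk >= tk - mn else mn
            a = s1 * fm - tot * fk
            u = tot - s1
            b = ck - s1 * s1 * fkc - u * u * fk
            if b < bf:
                b = bf
            if a * a - c_thresh * b >= 0.0:
                return True
            if k != w or k == kc or kc < min_width:
                break
            k = kc
    return False


@nb.njit(cache=True)
def perm_exceed_count(x, observed_t, n_perm, seed, min_width, stop_count):
    """Count permutations whose max arc |t| reaches observed_t.

    Runs uniform random shuffles (Fisher-Yates on numba's RNG, seeded with
    `seed`, so the draw sequence is reproducible) and stops early once
    `stop_count` exceedances are seen -- by then the add-one p-value is
    pinned above any threshold the caller cares about.  Returns
    (count, permutations_run).
    """
    np.random.seed(seed)
    m = x.shape[0]
    mu = 0.0
    for k in range(m):
        mu += x[k]
    mu /= m
    y = np.empty(m)
    for k in range(m):
        y[k] = x[k] - mu
    c_thresh = observed_t * observed_t * m / (m - 2)
    ss = 0.0
    for k in range(m):
        ss += y[k] * y[k]  # permutation-invariant
    s = np.empty(m + 1)
    count = 0
    for b in range(n_perm):
        for i in range(m - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = y[i]
            y[i] = y[j]
            y[j] = tmp
        s[0] = 0.0
        for k in range(m):
            s[k + 1] = s[k] + y[k]
        if _arc_t_exceeds(s, ss, s[m], m, c_thresh, min_width):
            count += 1
            if count >= stop_count:
                return count, b + 1
    return count, n_perm
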