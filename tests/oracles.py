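"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the governing equations with
plain Python loops and its own constants, independent of the package
internals it is used to check.
"""

from __future__ import annotations

import math

import numpy as np

R_KCAL = 1.987204258640832e-3
R_J = 8.31446261815324

# constants restated independently (same published parameter set)
A_ES = 6525.69
B_ES = 1.4859e8
C_HB = {
    ("oh", "oh"): 4013.78,
    ("ot", "ot"): 932.31,
    ("oh", "ot"): 3016.43,
    ("ot", "oh"): 3016.43,
}
A_EFF = 7.25


def residual_lngamma_oracle(segments_1, segments_2, x1, t, tol=1e-14, maxiter=200000):
    """ln γ^res of both components by a dense, undamped fixed-point solve.

    ``segments_i`` are lists of (sigma, hb_class, area) triples — the
    non-empty bins of a σ-profile.  Pure-Python loops throughout.
    """

    def exchange(s_m, c_m, s_n, c_n):
        c_es = A_ES + B_ES / (t * t)
        dw = c_es * (s_m + s_n) ** 2
        chb = C_HB.get((c_m, c_n), 0.0) if s_m * s_n < 0.0 else 0.0
        return dw - chb * (s_m - s_n) ** 2

    def solve_gamma(profile):
        total = sum(a for _, _, a in profile)
        p = [a / total for _, _, a in profile]
        n = len(profile)
        boltz = [
            [
                math.exp(
                    -exchange(profile[m][0], profile[m][1], profile[k][0], profile[k][1])
                    / (R_KCAL * t)
                )
                for k in range(n)
            ]
            for m in range(n)
        ]
        gamma = [1.0] * n
        for _ in range(maxiter):
            new = [
                1.0 / sum(p[k] * gamma[k] * boltz[m][k] for k in range(n))
                for m in range(n)
            ]
            err = max(abs(a - b) for a, b in zip(new, gamma))
            # halved step keeps the oscillatory HB fixed point contractive
            gamma = [0.5 * (a + b) for a, b in zip(new, gamma)]
            if err < tol:
                return new
        raise RuntimeError("oracle fixed point did not converge")

    x2 = 1.0 - x1
    a1 = sum(a for _, _, a in segments_1)
    a2 = sum(a for _, _, a in segments_2)
    # mixture profile over the union of segments
    mix = [(s, c, x1 * a) for s, c, a in segments_1] + [
        (s, c, x2 * a) for s, c, a in segments_2
    ]
    gamma_mix = solve_gamma(mix)
    gamma_1 = solve_gamma(segments_1)
    gamma_2 = solve_gamma(segments_2)

    ln1 = (a1 / A_EFF) * sum(
        (a / a1) * (math.log(gamma_mix[i]) - math.log(gamma_1[i]))
        for i, (s, c, a) in enumerate(segments_1)
    )
    off = len(segments_1)
    ln2 = (a2 / A_EFF) * sum(
        (a / a2) * (math.log(gamma_mix[off + i]) - math.log(gamma_2[i]))
        for i, (s, c, a) in enumerate(segments_2)
    )
    return ln1, ln2


def margules_gmix(x, a):
    return x * np.log(x) + (1 - x) * np.log(1 - x) + a * x * (1 - x)


def common_tangent_oracle(a, n=1_000_000):
    """Binodal of the symmetric Margules system from a dense convex hull.

    Builds the lower convex hull of (x, Δg_mix/RT) on an n-point grid and
    returns the end points of the longest hull segment (the tie-line), or
    None if the hull touches every grid point (single phase).
    """
    x = np.linspace(1e-9, 1 - 1e-9, n)
    g = margules_gmix(x, a)
    hull = []  # indices of the lower hull (Andrew monotone chain)
    for i in range(n):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = (x[i2] - x[i1]) * (g[i] - g[i1]) - (g[i2] - g[i1]) * (x[i] - x[i1])
            if cross <= 0.0:
                hull.pop()
            else:
                break
        hull.append(i)
    gaps = np.diff(np.asarray(hull))
    k = int(np.argmax(gaps))
    if gaps[k] <= 1:
        return None
    return float(x[hull[k]]), float(x[hull[k + 1]])


def spinodal_oracle(a, n=1_000_000):
    """Spinodal of the symmetric Margules system via second differences."""
    x = np.linspace(1e-6, 1 - 1e-6, n)
    g = margules_gmix(x, a)
    d2 = g[:-2] - 2 * g[1:-1] + g[2:]
    sign = np.sign(d2)
    roots = []
    for i in range(len(sign) - 1):
        if sign[i] != sign[i + 1] and sign[i] != 0:
            roots.append(0.5 * (x[i + 1] + x[i + 2]))
    if not roots:
        return None
    return min(roots), max(roots)


def ideal_solubility(t, tm, dh_fus_kj):
    """Closed-form ln x for γ ≡ 1 and Δfus c_p = 0 (van 't Hoff form)."""
    return -(dh_fus_kj * 1000.0 / R_J) * (1.0 / t - 1.0 / tm)
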