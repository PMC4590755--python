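"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library's own code paths: the HWE oracle uses
exact rational arithmetic over the full enumeration, and the REML oracle
maximizes the restricted likelihood by direct formula evaluation over a
heritability grid with a bounded 1-D refinement.
"""

from fractions import Fraction
from math import factorial

import numpy as np
from scipy.optimize import minimize_scalar


def hwe_exact_p_bruteforce(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact two-sided HWE p via Fraction arithmetic over all configurations."""
    n = n_hom_minor + n_het + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n_minor == 0 or n_minor == 2 * n:
        return 1.0

    def weight(het):
        hom_min = (n_minor - het) // 2
        hom_maj = n - hom_min - het
        if hom_min < 0 or hom_maj < 0:
            return Fraction(0)
        return Fraction(
            factorial(n) * 2**het,
            factorial(hom_min) * factorial(het) * factorial(hom_maj),
        )

    hets = range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def reml_profile_oracle(y, X, A):
    """Brute-force single-GRM REML: grid + bounded search over h = sg2/(sg2+se2).

    The total variance is profiled out analytically; returns (sg2, se2) at
    the restricted-likelihood maximum.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, c = X.shape
    I = np.eye(n)

    def parts(h):
        Vh = h * A + (1 - h) * I
        Vinv = np.linalg.inv(Vh)
        _, ld_v = np.linalg.slogdet(Vh)
        XtVX = X.T @ Vinv @ X
        _, ld_x = np.linalg.slogdet(XtVX)
        P = Vinv - Vinv @ X @ np.linalg.inv(XtVX) @ X.T @ Vinv
        s2 = float(y @ P @ y) / (n - c)
        nll = 0.5 * ((n - c) * np.log(s2) + ld_v + ld_x + (n - c))
        return s2, nll

    hs = np.linspace(1e-6, 0.999, 400)
    vals = [parts(h)[1] for h in hs]
    i = int(np.argmin(vals))
    lo, hi = hs[max(i - 1, 0)], hs[min(i + 1, len(hs) - 1)]
    res = minimize_scalar(lambda h: parts(h)[1], bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-10})
    h = float(res.x)
    s2, _ = parts(h)
    return h * s2, (1 - h) * s2
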