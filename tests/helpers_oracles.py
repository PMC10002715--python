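"""Independent oracles used by the test suite.

These deliberately avoid the package's solver path: the toy community is
reduced by hand to a two-variable problem solved by dense grid search / KKT
reasoning, and the Mann-Whitney p-value is obtained by full enumeration of
rank assignments.
"""

from itertools import combinations
from math import comb

import numpy as np

# ---- two-taxon glucose toy, reduced by hand -------------------------------
# mu_A = 0.2 * g_A (g_A <= 10), mu_B = 0.4 * g_B (g_B <= 10),
# shared glucose: 0.5 g_A + 0.5 g_B <= 10  =>  2 mu_A + mu_B <= 8.
TOY_MU_A_MAX = 2.0
TOY_MU_B_MAX = 4.0


def toy_feasible(mu_a: float, mu_b: float) -> bool:
    return (
        0 <= mu_a <= TOY_MU_A_MAX
        and 0 <= mu_b <= TOY_MU_B_MAX
        and 2 * mu_a + mu_b <= 8 + 1e-12
    )


def toy_max_growth_grid(step: float = 1e-3) -> float:
    """Step-1 optimum by brute-force grid over (mu_A, mu_B)."""
    best = 0.0
    for mu_a in np.arange(0, TOY_MU_A_MAX + step / 2, step):
        # at fixed mu_a the best mu_b is its largest feasible value
        mu_b = min(TOY_MU_B_MAX, 8 - 2 * mu_a)
        if toy_feasible(mu_a, mu_b):
            best = max(best, 0.5 * mu_a + 0.5 * mu_b)
    return best


def toy_ctfba_grid(tradeoff: float, mu_star: float = 3.0,
                   step: float = 1e-3) -> tuple[float, float]:
    """Step-2 optimum (min mu_A^2 + mu_B^2) by dense grid search."""
    best, arg = np.inf, (np.nan, np.nan)
    target = tradeoff * mu_star
    for mu_a in np.arange(0, TOY_MU_A_MAX + step / 2, step):
        # growth constraint: 0.5(mu_a + mu_b) >= target; smallest feasible mu_b
        mu_b = max(0.0, 2 * target - mu_a)
        if not toy_feasible(mu_a, mu_b):
            continue
        val = mu_a**2 + mu_b**2
        if val < best:
            best, arg = val, (mu_a, mu_b)
    return arg


def toy_ctfba_kkt(tradeoff: float, mu_star: float = 3.0
                  ) -> tuple[float, float]:
    """Closed-form KKT solution of the reduced QP.

    The unconstrained minimum on the active growth constraint
    mu_A + mu_B = 2 * tradeoff * mu_star is the symmetric point; when it
    violates mu_A <= 2 the solution clips to the box face.
    """
    total = 2 * tradeoff * mu_star
    half = total / 2
    if half <= TOY_MU_A_MAX:
        return half, half
    return TOY_MU_A_MAX, total - TOY_MU_A_MAX


# ---- Mann-Whitney exact p by enumeration ----------------------------------

def mannwhitney_enumerate(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p over all C(n_a+n_b, n_a) assignments.

    Assumes no ties. Returns (U of group a, p)."""
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires distinct values"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a, n_b = len(a), len(b)

    def u_of(index_set):
        r = sum(ranks[pooled[i - 1]] for i in index_set)
        return r - n_a * (n_a + 1) / 2

    observed = sum(ranks[v] for v in a) - n_a * (n_a + 1) / 2
    center = n_a * n_b / 2
    dev = abs(observed - center)
    total = comb(n_a + n_b, n_a)
    extreme = 0
    for idx in combinations(range(1, n_a + n_b + 1), n_a):
        if abs(u_of(idx) - center) >= dev - 1e-12:
            extreme += 1
    return observed, min(1.0, extreme / total)


# ---- lognormal attenuation of the Pearson correlation ---------------------

def lognormal_attenuated_r(predicted, sigma: float) -> float:
    """Expected Pearson r between p and p*exp(eps), eps ~ N(0, sigma^2),
    from the empirical moments of the predicted values."""
    p = np.asarray(predicted, dtype=float)
    m1, m2 = p.mean(), (p**2).mean()
    var_p = m2 - m1**2
    cov = np.exp(sigma**2 / 2) * var_p
    var_m = m2 * np.exp(2 * sigma**2) - m1**2 * np.exp(sigma**2)
    return cov / np.sqrt(var_p * var_m)
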