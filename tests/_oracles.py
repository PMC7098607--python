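"""Independent oracles used only by the test suite.

These deliberately avoid the code paths they check: optimal transport is
solved as an explicit linear program, and the telegraph stationary law is
evaluated from its closed-form confluent-hypergeometric expression.
"""

import numpy as np
from scipy.optimize import linprog
from scipy.special import gammaln, hyp1f1, poch


def transport_lp_distance(p, q, positions_p, positions_q) -> float:
    """Earth mover's distance between discrete distributions by LP.

    Minimizes sum_ij c_ij x_ij with c_ij = |pos_p[i] - pos_q[j]| subject to
    row sums p and column sums q.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p = p / p.sum()
    q = q / q.sum()
    n, m = len(p), len(q)
    cost = np.abs(positions_p[:, None] - positions_q[None, :]).ravel()
    a_eq = []
    b_eq = []
    for i in range(n):
        row = np.zeros((n, m))
        row[i, :] = 1.0
        a_eq.append(row.ravel())
        b_eq.append(p[i])
    for j in range(m):
        col = np.zeros((n, m))
        col[:, j] = 1.0
        a_eq.append(col.ravel())
        b_eq.append(q[j])
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success, res.message
    return float(res.fun)


def telegraph_pmf_analytic(k_on, k_off, k_ini, k_deg, m_max) -> np.ndarray:
    """Closed-form stationary pmf of the two-state birth-death model.

    With a = k_on/k_deg, b = k_off/k_deg, r = k_ini/k_deg:
    P(m) = r^m / m! * (a)_m / (a+b)_m * 1F1(a+m; a+b+m; -r).
    """
    a = k_on / k_deg
    b = k_off / k_deg
    r = k_ini / k_deg
    m = np.arange(m_max + 1)
    log_prefactor = m * np.log(r) - gammaln(m + 1)
    pmf = (
        np.exp(log_prefactor)
        * poch(a, m) / poch(a + b, m)
        * hyp1f1(a + m, a + b + m, -r)
    )
    return pmf
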