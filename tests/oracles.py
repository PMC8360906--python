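"""Independent oracles shared by the test suite."""

import numpy as np
from scipy.optimize import linprog


def transport_lp(a, b):
    """Brute-force optimal-transport cost between two small samples.

    Solves the discrete transport linear program directly; independent of
    the ECDF-based distance it is used to check.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :]).ravel()
    a_eq = []
    for i in range(n):
        row = np.zeros((n, m))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(m):
        col = np.zeros((n, m))
        col[:, j] = 1
        a_eq.append(col.ravel())
    b_eq = np.concatenate([np.full(n, 1.0 / n), np.full(m, 1.0 / m)])
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=b_eq, bounds=(0, None))
    assert res.success
    return res.fun
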