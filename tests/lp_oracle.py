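"""Brute-force LP oracle: enumerate vertices of {A x <= b, lb <= x <= ub}.

Independent of the package's solver: candidate vertices are intersections of
n constraint hyperplanes (inequality rows and variable bounds); feasible ones
are scored on the objective directly.
"""

from itertools import combinations

import numpy as np


def vertex_enumeration_max(c, a_ub, b_ub, lb, ub):
    """Max of c.x over {a_ub x <= b_ub, lb <= x <= ub} by vertex enumeration."""
    c = np.asarray(c, dtype=float)
    n = c.size
    rows = [np.asarray(a_ub, dtype=float)] if len(a_ub) else []
    rhs = [np.asarray(b_ub, dtype=float)] if len(b_ub) else []
    eye = np.eye(n)
    rows += [eye, -eye]
    rhs += [np.asarray(ub, dtype=float), -np.asarray(lb, dtype=float)]
    big_a = np.vstack(rows)
    big_b = np.concatenate(rhs)
    best = None
    m = big_a.shape[0]
    for idx in combinations(range(m), n):
        sq = big_a[list(idx)]
        if abs(np.linalg.det(sq)) < 1e-12:
            continue
        x = np.linalg.solve(sq, big_b[list(idx)])
        if np.all(big_a @ x <= big_b + 1e-9):
            val = float(c @ x)
            if best is None or val > best:
                best = val
    return best


def random_bounded_lp(rng, max_vars=6):
    """A random feasible, bounded LP (x=0 feasible; box bounds)."""
    n = int(rng.integers(2, max_vars + 1))
    m = int(rng.integers(1, 5))
    a = rng.normal(size=(m, n))
    b = rng.uniform(0.5, 2.0, size=m)  # x = 0 always feasible
    c = rng.normal(size=n)
    ub = rng.uniform(0.5, 3.0, size=n)
    lb = np.zeros(n)
    return c, a, b, lb, ub
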