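"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's LP / stats code paths: the LP
oracle enumerates polytope vertices by fixing coordinate subsets at
their bounds and solving the remaining square system; the enrichment
oracle sums hypergeometric terms with exact rational arithmetic.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def polytope_vertices(S, lb, ub, tol=1e-8):
    """All vertices of {v : S v = 0, lb <= v <= ub} (small n only)."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = S.shape[1]
    r = int(np.linalg.matrix_rank(S)) if S.size else 0
    k = n - r
    seen = []
    for fixed in itertools.combinations(range(n), k):
        free = [i for i in range(n) if i not in fixed]
        A = S[:, free]
        for pattern in itertools.product((0, 1), repeat=k):
            xf = np.array([lb[i] if p == 0 else ub[i] for i, p in zip(fixed, pattern)])
            if not np.isfinite(xf).all():
                continue
            b = -S[:, list(fixed)] @ xf if k else np.zeros(S.shape[0])
            if free:
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            else:
                sol = np.empty(0)
            x = np.empty(n)
            x[list(fixed)] = xf
            x[free] = sol
            if S.size and np.abs(S @ x).max() > 1e-6:
                continue
            if (x < lb - tol).any() or (x > ub + tol).any():
                continue
            if not any(np.allclose(x, y, atol=1e-7) for y in seen):
                seen.append(x)
    return seen


def lp_vertex_optimum(S, lb, ub, c, sense="max"):
    """Optimal objective over the polytope by exhaustive vertex enumeration."""
    c = np.asarray(c, dtype=float)
    values = [float(c @ x) for x in polytope_vertices(S, lb, ub)]
    if not values:
        return None
    return max(values) if sense == "max" else min(values)


def lexicographic_vertex_optimum(S, lb, ub, c1, c2, tol=1e-7):
    """Two-stage lexicographic max via vertex enumeration.

    The second-stage optimum lies on the optimal face of the first
    objective, whose vertices are vertices of the original polytope.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    vertices = polytope_vertices(S, lb, ub)
    z1 = max(float(c1 @ x) for x in vertices)
    face = [x for x in vertices if c1 @ x >= z1 - tol]
    z2 = max(float(c2 @ x) for x in face)
    return z1, z2


def exact_hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) as an exact rational."""
    total = comb(N, n)
    hits = sum(comb(K, i) * comb(N - K, n - i)
               for i in range(max(k, 0), min(K, n) + 1))
    return Fraction(hits, total)


def model_arrays(model):
    """S, lb, ub and the reaction order for a model (test convenience)."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    return S, lb, ub, rxn_ids
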