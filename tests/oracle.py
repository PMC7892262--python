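"""Independent brute-force reference for the association evidence.

Deliberately written without the package's vectorised machinery: plain
itertools enumeration of pathogenicity vectors, per-subject loops for the
configuration rule, and lgamma-based beta functions.  Used only as a test
oracle.
"""

import itertools
import math


def log_beta(a: float, b: float) -> float:
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


def log_marginal(n1: int, n0: int, a: float, b: float) -> float:
    return log_beta(a + n1, b + n0) - log_beta(a, b)


def config(row, z, moi) -> int:
    if moi == "dominant":
        return int(any(z[j] and row[j] >= 1 for j in range(len(z))))
    total = sum(row[j] for j in range(len(z)) if z[j])
    return int(total >= 2)


def brute_force_log_evidence(y, G, moi, a0, b0, a1, b1, w_a, w_b) -> float:
    """log sum over all z in {0,1}^k of p(z) * p(y | z)."""
    n, k = len(y), len(G[0]) if len(G) else 0
    total = None
    for z in itertools.product((0, 1), repeat=k):
        s = sum(z)
        lp = log_beta(w_a + s, w_b + k - s) - log_beta(w_a, w_b)
        x = [config(G[i], z, moi) for i in range(n)]
        n1c = sum(1 for i in range(n) if y[i] and x[i])
        n0c = sum(1 for i in range(n) if not y[i] and x[i])
        n1b = sum(1 for i in range(n) if y[i] and not x[i])
        n0b = sum(1 for i in range(n) if not y[i] and not x[i])
        ll = log_marginal(n1b, n0b, a0, b0) + log_marginal(n1c, n0c, a1, b1)
        term = lp + ll
        if total is None:
            total = term
        else:
            hi, lo = max(total, term), min(total, term)
            total = hi + math.log1p(math.exp(lo - hi))
    return total


def brute_force_variant_posterior(y, G, moi, a0, b0, a1, b1, w_a, w_b):
    """P(z_j = 1 | y) by direct enumeration."""
    n, k = len(y), len(G[0])
    num = [0.0] * k
    den = 0.0
    for z in itertools.product((0, 1), repeat=k):
        s = sum(z)
        lp = log_beta(w_a + s, w_b + k - s) - log_beta(w_a, w_b)
        x = [config(G[i], z, moi) for i in range(n)]
        n1c = sum(1 for i in range(n) if y[i] and x[i])
        n0c = sum(1 for i in range(n) if not y[i] and x[i])
        n1b = sum(1 for i in range(n) if y[i] and not x[i])
        n0b = sum(1 for i in range(n) if not y[i] and not x[i])
        w = math.exp(
            lp + log_marginal(n1b, n0b, a0, b0) + log_marginal(n1c, n0c, a1, b1)
        )
        den += w
        for j in range(k):
            if z[j]:
                num[j] += w
    return [nj / den for nj in num]
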