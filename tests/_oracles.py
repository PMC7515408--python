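"""Independent literal-summation oracles for the information functionals.

Pure-Python, term-by-term transcriptions of the defining sums, kept free
of numpy vectorisation and of any code path shared with the package, so
they can arbitrate the vectorised implementations on small distributions.
"""

import math


def oracle_shannon_entropy(p, base=2.0):
    return -sum(pi * math.log(pi, base) for pi in p if pi > 0)


def oracle_kl(p, q, base=2.0):
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            if qi == 0:
                return math.inf
            total += pi * math.log(pi / qi, base)
    return total


def oracle_arimoto_entropy(p, alpha):
    s = sum(pi ** alpha for pi in p if pi > 0)
    return alpha / (alpha - 1.0) * (1.0 - s ** (1.0 / alpha))


def oracle_arimoto_divergence(p, q, alpha):
    s = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            if qi == 0:
                return math.inf
            s += pi ** alpha * qi ** (1.0 - alpha)
    return alpha / (1.0 - alpha) * (1.0 - s ** (1.0 / alpha))


def _joint_marginals(joint):
    rows = [sum(row) for row in joint]
    cols = [sum(joint[i][j] for i in range(len(joint))) for j in range(len(joint[0]))]
    return rows, cols


def oracle_shannon_mi(joint, base=2.0):
    rows, cols = _joint_marginals(joint)
    total = 0.0
    for i, row in enumerate(joint):
        for j, pij in enumerate(row):
            if pij > 0:
                total += pij * math.log(pij / (rows[i] * cols[j]), base)
    return total


def oracle_arimoto_mi(joint, alpha):
    rows, cols = _joint_marginals(joint)
    s = 0.0
    for i, row in enumerate(joint):
        for j, pij in enumerate(row):
            if pij > 0:
                s += pij ** alpha * (rows[i] * cols[j]) ** (1.0 - alpha)
    return alpha / (1.0 - alpha) * (1.0 - s ** (1.0 / alpha))


def oracle_tsallis_mi(joint, q):
    rows, cols = _joint_marginals(joint)
    s = 0.0
    for i, row in enumerate(joint):
        for j, pij in enumerate(row):
            if pij > 0:
                s += pij ** q * (rows[i] * cols[j]) ** (1.0 - q)
    return (1.0 - s) / (1.0 - q)


def grid_distributions(n, step=0.05):
    """Every distribution on n bins whose masses are multiples of ``step``."""
    k = round(1.0 / step)
    out = []

    def rec(prefix, remaining, slots):
        if slots == 1:
            out.append(prefix + [remaining * step])
            return
        for c in range(remaining + 1):
            rec(prefix + [c * step], remaining - c, slots - 1)

    rec([], k, n)
    return out
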