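"""Independent brute-force oracles used to verify the model module.

Everything here deliberately avoids the package's computation paths:
probabilities are accumulated in linear space, the beta-binomial pmf is
evaluated through ``math.lgamma``/``math.comb`` rather than scipy, dropout
is enumerated copy-by-copy over all 2^k retention patterns, and the
doublet genotype prior is built from ordered pairs of singlet genotypes.
"""

import itertools
import math

SIGMA_SINGLET = (0.0, 0.5, 1.0)

ALPHA_FLOOR = 1e-6
P_EPS = 1e-9


def bb_pmf(v: int, c: int, p: float, s: float) -> float:
    """Beta-binomial pmf via log-gamma identities (independent of scipy)."""
    a, b = p * s, (1.0 - p) * s
    log_beta = lambda x, y: (
        math.lgamma(x) + math.lgamma(y) - math.lgamma(x + y)
    )
    return math.comb(c, v) * math.exp(log_beta(v + a, c - v + b) - log_beta(a, b))


def joint_loglik(v: int, c: int, z: int, mu: tuple, err) -> float:
    """log P(c, v | z) by linear-space enumeration of the full joint table.

    Sums over the constituent genotype(s) (ordered pairs for doublets) and
    over every per-copy dropout pattern, conditioning on at least one
    retained copy.
    """
    afp = max(err.alpha_fp, ALPHA_FLOOR)
    afn = max(err.alpha_fn, ALPHA_FLOOR)
    beta = err.beta
    # genotype configurations: VAF and prior weight
    if z == 0:
        configs = [(x, w) for x, w in zip(SIGMA_SINGLET, mu)]
    else:
        configs = []
        for (g, wg), (h, wh) in itertools.product(
            zip(SIGMA_SINGLET, mu), repeat=2
        ):
            configs.append(((g + h) / 2.0, wg * wh))
    n_copies = 2 * z + 2
    norm = 1.0 - beta**n_copies
    total = 0.0
    for x, wx in configs:
        if wx == 0.0:
            continue
        n_var = round(x * n_copies)
        copies = [1] * n_var + [0] * (n_copies - n_var)  # 1 = variant copy
        for pattern in itertools.product([False, True], repeat=n_copies):
            kept = [allele for allele, keep in zip(copies, pattern) if keep]
            if not kept:
                continue
            w_pattern = 1.0
            for keep in pattern:
                w_pattern *= (1.0 - beta) if keep else beta
            y = sum(kept) / len(kept)
            p = afp + (1.0 - afp - afn) * y
            p = min(max(p, P_EPS), 1.0 - P_EPS)
            total += wx * (w_pattern / norm) * bb_pmf(v, c, p, err.s)
    return math.log(total)


def best_assignment_bruteforce(ll_singlet, ll_doublet, delta: float):
    """Exhaustive argmax over all 2^n assignments of the joint posterior.

    Returns (assignment tuple, objective value).
    """
    n = ll_singlet.shape[0]
    row0 = ll_singlet.sum(axis=1)
    row1 = ll_doublet.sum(axis=1)
    best, best_obj = None, -math.inf
    for bits in itertools.product([0, 1], repeat=n):
        obj = 0.0
        for i, zi in enumerate(bits):
            obj += (row1[i] + math.log(delta)) if zi else (
                row0[i] + math.log(1.0 - delta)
            )
        if obj > best_obj:
            best, best_obj = bits, obj
    return best, best_obj
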