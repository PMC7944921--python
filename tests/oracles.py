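"""Independent high-precision and brute-force oracles used by the tests.

These deliberately avoid the package's own numerical paths: fixation
probabilities are evaluated in 50-digit arithmetic with sympy, and
likelihoods by dense summation over all internal-state assignments.
"""

import numpy as np
import sympy

DIGITS = 50


def pfix_oracle(s: float, N_p: int) -> float:
    """(1 - e^(-2s)) / (1 - e^(-4 N s)) at 50-digit precision."""
    s_ = sympy.Float(repr(s), DIGITS)
    N_ = sympy.Integer(N_p)
    if s == 0:
        return float(1 / (2 * N_))
    val = (1 - sympy.exp(-2 * s_)) / (1 - sympy.exp(-4 * N_ * s_))
    return float(sympy.N(val, DIGITS))


def pfix_reversible_oracle(s: float, N_p: int) -> float:
    """2 log(1+s) / (1 - e^(-4 N log(1+s))) at 50-digit precision."""
    s_ = sympy.log(1 + sympy.Float(repr(s), DIGITS))
    N_ = sympy.Integer(N_p)
    if s == 0:
        return float(sympy.Rational(1, 2 * N_p))
    val = 2 * s_ / (1 - sympy.exp(-4 * N_ * s_))
    return float(sympy.N(val, DIGITS))


def brute_force_log_likelihood(tree, engine) -> float:
    """Dense summation over all internal-node state assignments.

    Only usable on tiny trees (cost 61^(#internal nodes) per site); serves
    as the independent check of the pruning recursion.
    """
    rho = engine.root_distribution()
    P = {b: engine.branch_matrix(b) for b in tree.branches}
    internal = [v for v in range(tree.n_nodes) if not tree.is_leaf(v) and v != tree.root]
    n_pat = engine.patterns.shape[1]
    total = 0.0
    for pat in range(n_pat):
        leaf_state = {
            v: engine.patterns[engine.leaf_row[v], pat] for v in tree.leaves
        }
        site_lik = 0.0
        # enumerate root state and all internal states
        import itertools

        for states in itertools.product(range(61), repeat=len(internal) + 1):
            assign = {tree.root: states[0]}
            assign.update(dict(zip(internal, states[1:])))
            assign.update({v: int(s) for v, s in leaf_state.items()})
            lik = rho[assign[tree.root]]
            for b in tree.branches:
                if assign[b] == -1:  # missing leaf: marginalises to 1
                    continue
                lik *= P[b][assign[tree.parent[b]], assign[b]]
                if lik == 0.0:
                    break
            site_lik += lik
        total += engine.pattern_weights[pat] * np.log(site_lik)
    return float(total)


def yule_colless_expectation(n: int) -> float:
    """E[Colless index] of a Yule tree with n tips, by the exact recursion:
    under the Yule process the left-subtree size is uniform on 1..n-1."""
    E = {1: 0.0, 2: 0.0}
    for m in range(3, n + 1):
        acc = 0.0
        for i in range(1, m):
            acc += abs(m - 2 * i) + E[i] + E[m - i]
        E[m] = acc / (m - 1)
    return E[n]
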