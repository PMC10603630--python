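"""Independent brute-force oracles used by the biogeography tests.

These deliberately avoid the pruning/recursion code paths in
``phylocons.biogeo``: the likelihood is computed by explicit summation over
every assignment of ranges to internal nodes and cladogenetic events, with
transition probabilities taken from a truncated, scaled Taylor series.
"""

import math

import numpy as np

from phylocons import biogeo


def taylor_expm(Q: np.ndarray, t: float, terms: int = 30) -> np.ndarray:
    """Scaling-and-squaring Taylor-series matrix exponential."""
    A = Q * t
    scale = max(0, int(np.ceil(np.log2(max(1e-300, np.abs(A).max())))) + 1)
    A = A / (2**scale)
    out = np.eye(Q.shape[0])
    term = np.eye(Q.shape[0])
    for k in range(1, terms):
        term = term @ A / k
        out = out + term
    for _ in range(scale):
        out = out @ out
    return out


def enumeration_likelihood_and_marginals(tree, tips, space, model, d, e, j=0.0):
    """(lnL, marginals) by exhaustive summation over internal-node states and
    cladogenetic events; feasible only for very small trees."""
    clado = biogeo.cladogenesis_table(space, model, j)
    Q = biogeo.anagenetic_q(space, d, e)
    pcache = {}

    def P(t):
        if t not in pcache:
            pcache[t] = taylor_expm(Q, t)
        return pcache[t]

    internals = [n for n in tree.preorder() if not n.is_tip]
    nn = space.n_states
    total = 0.0
    marg = {id(n): np.zeros(nn) for n in internals}

    def daughter_start(node, assignment):
        _, (l, r, _) = assignment[id(node.parent)]
        return l if node is node.parent.children[0] else r

    def rec(i, assignment):
        nonlocal total
        if i == len(internals):
            w = 1.0 / (nn - 1)  # uniform root prior over non-null ranges
            for n in internals:
                s, (_, _, p) = assignment[id(n)]
                w *= p
                if n.parent is not None:
                    w *= P(n.length)[daughter_start(n, assignment), s]
            for tip in tree.tips:
                w *= P(tip.length)[
                    daughter_start(tip, assignment), space.index[tips[tip.label]]
                ]
            total += w
            for n in internals:
                marg[id(n)][assignment[id(n)][0]] += w
            return
        node = internals[i]
        for s in range(1, nn):
            for event in clado.events[s]:
                assignment[id(node)] = (s, event)
                rec(i + 1, assignment)
        del assignment[id(node)]

    rec(0, {})
    marginals = {tree.clade_key(n): marg[id(n)] / total for n in internals}
    return math.log(total), marginals


def enumeration_f81_loglik(tree, states, areas, pi, mu, rate=1.0):
    """Multistate single-character likelihood by summation over all internal
    node states, using the closed-form equal-input transition matrix."""
    k = len(areas)
    idx = {a: i for i, a in enumerate(areas)}

    def P(t):
        decay = math.exp(-mu * rate * t)
        return pi[None, :] * (1 - decay) + np.eye(k) * decay

    internals = [n for n in tree.preorder() if not n.is_tip]
    total = 0.0

    def rec(i, assignment):
        nonlocal total
        if i == len(internals):
            w = pi[assignment[id(tree.root)]]
            for n in internals:
                if n.parent is not None:
                    w *= P(n.length)[assignment[id(n.parent)], assignment[id(n)]]
            for tip in tree.tips:
                w *= P(tip.length)[assignment[id(tip.parent)], idx[states[tip.label]]]
            total += w
            return
        for s in range(k):
            assignment[id(internals[i])] = s
            rec(i + 1, assignment)
        del assignment[id(internals[i])]

    rec(0, {})
    return math.log(total)
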