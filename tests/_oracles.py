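"""Independent oracles used to validate the likelihood machinery.

These deliberately avoid the implementation's pruning/outside-pass code
paths: the DEC oracle sums exhaustively over every assignment of ranges to
internal nodes and every ordered cladogenetic outcome; the birth-death
oracle uses the Kendall/Stadler closed forms for the extinction and
per-lineage density functions of the constant-rate birth-death process with
species sampling.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm

from rangeflow.dec import (
    build_q_matrix,
    enumerate_cladogenetic_outcomes,
)


def brute_force_dec(tree, tips, params, space):
    """Exhaustive DEC likelihood and node marginals on a tiny tree.

    Sums over every assignment of permitted node states to internal nodes
    and every ordered cladogenetic outcome at each node, multiplying flat
    root prior, outcome weights and branch transition probabilities.

    Returns (loglik, marginals) where marginals maps each internal node's
    clade (frozenset of tip labels) to a dict {state mask: probability}.
    """
    Q = build_q_matrix(space, params)
    P = {}  # branch length -> transition matrix
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length not in P:
            P[node.edge.length] = expm(Q * node.edge.length)

    internals = list(tree.postorder_internal_node_iter())
    node_states = [space.states[i] for i in space.node_state_idx]
    prior = 1.0 / len(node_states)

    def leaf_label(n):
        return frozenset(lf.taxon.label for lf in n.leaf_iter())

    def node_factor(node, s, assign):
        """Sum over ordered cladogenetic outcomes of state s at `node` of
        weight x both daughter branch transition probabilities; outcomes at
        distinct nodes are independent given the node states."""
        c1, c2 = node.child_nodes()
        tgt = []
        for child in (c1, c2):
            if child.is_leaf():
                tgt.append(tips[child.taxon.label])
            else:
                tgt.append(assign[id(child)])
        acc = 0.0
        for (l, r), w in enumerate_cladogenetic_outcomes(s):
            acc += (w
                    * P[c1.edge.length][space.index[l], space.index[tgt[0]]]
                    * P[c2.edge.length][space.index[r], space.index[tgt[1]]])
        return acc

    total = 0.0
    marg = {id(n): {} for n in internals}
    for combo in itertools.product(node_states, repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        f = prior
        for node in internals:
            f *= node_factor(node, assign[id(node)], assign)
            if f == 0.0:
                break
        if f == 0.0:
            continue
        total += f
        for node, s in zip(internals, combo):
            d = marg[id(node)]
            d[s] = d.get(s, 0.0) + f

    marginals = {}
    for node in internals:
        d = marg[id(node)]
        marginals[leaf_label(node)] = {s: v / total for s, v in d.items()}
    return math.log(total), marginals


def bd_sampling_loglik(tree, lam, mu, rho, root_mode="obs"):
    """Constant-rate birth-death log-likelihood with species sampling rho.

    Closed-form per-lineage solution: with r = lam - mu and
    q(t) = rho*lam + (lam*(1-rho) - mu) * exp(-r*t),
    the probability a lineage alive at time t leaves no sampled descendant
    is E(t) = 1 - rho*r*exp(-r*t)*... (Kendall forms), and the density of a
    sampled-survival lineage is p1(t) = rho * r**2 * exp(-r*t) / q(t)**2.
    The pruning recursion D(tip)=rho, branch factor p1(t2)/p1(t1), node
    factor lam then reproduces the SSE D-equation exactly; no ODE solver is
    involved.  Root handling mirrors the observed-weights convention for a
    single state (the D value itself), with no survival conditioning.
    """
    lam, mu, rho = float(lam), float(mu), float(rho)
    r = lam - mu
    if abs(r) < 1e-12:
        raise ValueError("oracle requires lam != mu")

    def p1(t):
        q = rho * lam + (lam * (1.0 - rho) - mu) * math.exp(-r * t)
        return rho * r * r * math.exp(-r * t) / (q * q)

    logD = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            logD[node] = math.log(rho)
        else:
            c1, c2 = node.child_nodes()
            t = node.age
            val = math.log(lam)
            for c in (c1, c2):
                val += logD[c] + math.log(p1(t)) - math.log(p1(c.age))
            logD[node] = val
    if root_mode not in ("obs", "flat"):
        raise ValueError(root_mode)
    return logD[tree.seed_node]
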