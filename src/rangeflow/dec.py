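"""Dispersal–extinction–cladogenesis (DEC) ancestral-range model.

Geographic ranges are subsets of a small ordered codebook of areas, encoded
as integer bitmasks (bit *i* set = area *i* occupied).  Along branches ranges
evolve by single-area gains (dispersal, rate ``d`` per source area per Myr)
and single-area losses (local extinction, rate ``e`` per area per Myr) under
a continuous-time Markov chain whose generator is built by
:func:`build_q_matrix`; the empty range is an absorbing bookkeeping state.
At each split the ancestral range is partitioned between the daughters by
vicariance, peripheral isolation, or (for single-area ranges) duplication,
with uniform weights over the distinct ordered outcomes.

The likelihood is computed by Felsenstein pruning with a cladogenetic
convolution at every internal node; ``d`` and ``e`` are estimated by
bounded quasi-Newton on the log scale, and per-node marginal ancestral-range
probabilities come from a standard up–down (outside) pass.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .trees import require_binary

__all__ = [
    "DECParams",
    "RangeStateSpace",
    "DEFAULT_AREAS",
    "build_state_space",
    "build_q_matrix",
    "branch_transition_probs",
    "enumerate_cladogenetic_outcomes",
    "dec_loglik",
    "fit_dec_ml",
    "ancestral_range_marginals",
    "range_to_str",
    "str_to_range",
    "read_range_table",
    "write_range_table",
]

#: area codebook of the default analysis: A America, B Madagascar,
#: C sub-Saharan Africa, D Cape, E Mediterranean Basin, F Northern Europe,
#: G Middle East, H Asia.
DEFAULT_AREAS: tuple[str, ...] = tuple("ABCDEFGH")


@dataclass(frozen=True)
class DECParams:
    """Anagenetic DEC rates (events per area per Myr)."""

    d: float  # single-area dispersal (range expansion) rate
    e: float  # single-area local extinction (range contraction) rate

    def __post_init__(self):
        if not (np.isfinite(self.d) and np.isfinite(self.e)):
            raise ValueError("DEC rates must be finite")
        if self.d < 0 or self.e < 0:
            raise ValueError("DEC rates must be nonnegative")


def _popcount(mask: int) -> int:
    return bin(mask).count("1")


def range_to_str(mask: int, areas: Sequence[str]) -> str:
    """Bitmask -> concatenated area codes ('' for the null range)."""
    return "".join(a for i, a in enumerate(areas) if mask >> i & 1)


def str_to_range(s: str, areas: Sequence[str]) -> int:
    """Concatenated area codes -> bitmask; unknown codes raise."""
    mask = 0
    for ch in s:
        try:
            mask |= 1 << list(areas).index(ch)
        except ValueError:
            raise ValueError(f"unknown area code {ch!r} (codebook {areas})")
    return mask


class RangeStateSpace:
    """Enumerated set of permitted geographic ranges.

    States are all nonempty subsets of the codebook with at most
    ``max_range_size`` areas, the null range (index 0), and — to keep
    observed data representable — any observed tip range larger than the
    cap together with its oversized loss-chain subsets.  Node states
    (cladogenesis, root prior, reported marginals) are restricted to
    non-null ranges within the cap.
    """

    def __init__(self, areas: Sequence[str], max_range_size: int,
                 states: Sequence[int]):
        self.areas = tuple(areas)
        self.max_range_size = int(max_range_size)
        self.states = tuple(states)
        self.index = {s: i for i, s in enumerate(self.states)}
        self.n = len(self.states)
        sizes = np.array([_popcount(s) for s in self.states])
        self.sizes = sizes
        #: indices of states permitted at internal nodes (non-null, <= cap)
        self.node_state_idx = np.flatnonzero(
            (sizes >= 1) & (sizes <= self.max_range_size))
        self._clado_cache: dict[int, list[tuple[int, int]]] = {}

    def __len__(self) -> int:
        return self.n

    def __contains__(self, mask: int) -> bool:
        return mask in self.index

    def labels(self) -> list[str]:
        return [range_to_str(s, self.areas) or "0" for s in self.states]

    def __repr__(self) -> str:
        return (f"RangeStateSpace({len(self.areas)} areas, "
                f"max {self.max_range_size}, {self.n} states)")


def build_state_space(areas: Sequence[str] = DEFAULT_AREAS,
                      max_range_size: int = 3,
                      observed_ranges: Iterable[int] = ()) -> RangeStateSpace:
    """Enumerate permitted ranges in canonical order (size, then bit value)."""
    areas = tuple(areas)
    n_areas = len(areas)
    if not 1 <= max_range_size <= n_areas:
        raise ValueError("max_range_size must be in [1, number of areas]")
    full = (1 << n_areas) - 1
    states = {0}
    for mask in range(1, full + 1):
        if _popcount(mask) <= max_range_size:
            states.add(mask)
    for obs in observed_ranges:
        if obs & ~full:
            raise ValueError(
                f"observed range {obs:#x} is not a subset of the codebook")
        if _popcount(obs) > max_range_size:
            # oversized observed range: include it and its loss chain down
            # to the cap so it can decay by single-area losses
            k = _popcount(obs)
            states.add(obs)
            for sub_size in range(max_range_size + 1, k):
                for combo in itertools.combinations(
                        [i for i in range(n_areas) if obs >> i & 1], sub_size):
                    states.add(sum(1 << i for i in combo))
    ordered = sorted(states, key=lambda m: (_popcount(m), m))
    return RangeStateSpace(areas, max_range_size, ordered)


def build_q_matrix(space: RangeStateSpace, params: DECParams) -> np.ndarray:
    """Anagenetic generator over the state space.

    Gain of area *j* from range R has rate ``d * |R|`` (one dispersal source
    per occupied area, uniform multipliers) and is allowed only when the
    enlarged range is itself a permitted state; loss of area *j* has rate
    ``e``.  The null range is absorbing.  Rows sum to zero.
    """
    n = space.n
    Q = np.zeros((n, n))
    n_areas = len(space.areas)
    for i, R in enumerate(space.states):
        if R == 0:
            continue
        size = _popcount(R)
        for j in range(n_areas):
            bit = 1 << j
            if R & bit:
                tgt = R & ~bit
                k = space.index.get(tgt)
                if k is not None:
                    Q[i, k] += params.e
            else:
                tgt = R | bit
                k = space.index.get(tgt)
                if k is not None:
                    Q[i, k] += params.d * size
        Q[i, i] = -Q[i].sum()
    return Q


def branch_transition_probs(Q: np.ndarray, duration: float) -> np.ndarray:
    """exp(Q t): the stochastic matrix of range transitions over a branch."""
    if duration < 0:
        raise ValueError("branch duration must be nonnegative")
    if duration == 0:
        return np.eye(Q.shape[0])
    return linalg.expm(Q * duration)


class _Propagator:
    """Fast repeated exp(Qt) via eigendecomposition, expm fallback.

    The DEC generator is generically diagonalizable; when the eigenbasis is
    ill-conditioned (degenerate rates) we fall back to scipy's expm per
    branch.  Reconstruction is validated once at construction.
    """

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self._use_eig = False
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            recon = (V * w) @ Vinv
            if np.max(np.abs(recon - Q)) <= 1e-10 * max(1.0, np.abs(Q).max()):
                self._w, self._V, self._Vinv = w, V, Vinv
                self._use_eig = True
        except np.linalg.LinAlgError:
            pass

    def __call__(self, t: float) -> np.ndarray:
        if t == 0:
            return np.eye(self.Q.shape[0])
        if self._use_eig:
            P = (self._V * np.exp(self._w * t)) @ self._Vinv
            P = np.real(P)
        else:
            P = linalg.expm(self.Q * t)
        np.clip(P, 0.0, None, out=P)
        return P


def enumerate_cladogenetic_outcomes(mask: int) -> list[tuple[tuple[int, int], float]]:
    """Ordered daughter-range pairs and weights for a splitting range.

    A single-area range duplicates: one outcome ``(R, R)`` with weight 1.
    A multi-area range R yields, with uniform weight over the *distinct*
    ordered outcomes: vicariance pairs ``({a}, R\\{a})`` and peripheral
    isolate pairs ``({a}, R)`` for each occupied area ``a``, each in both
    daughter orders.
    """
    if mask == 0:
        raise ValueError("null range cannot undergo cladogenesis")
    if _popcount(mask) == 1:
        return [((mask, mask), 1.0)]
    outcomes: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    bits = [1 << i for i in range(mask.bit_length()) if mask >> i & 1]
    for a in bits:
        for pair in (((a, mask & ~a)), (mask & ~a, a),
                     (a, mask), (mask, a)):
            if pair not in seen:
                seen.add(pair)
                outcomes.append(pair)
    w = 1.0 / len(outcomes)
    return [(pair, w) for pair in outcomes]


def _clado_indices(space: RangeStateSpace, state_idx: int):
    """Per-node-state arrays (left idx, right idx, weight) for the pruning sum."""
    cache = space._clado_cache
    if state_idx not in cache:
        mask = space.states[state_idx]
        out = enumerate_cladogenetic_outcomes(mask)
        li = np.array([space.index[l] for (l, r), _ in out], dtype=np.intp)
        ri = np.array([space.index[r] for (l, r), _ in out], dtype=np.intp)
        w = np.array([w for _, w in out])
        cache[state_idx] = (li, ri, w)
    return cache[state_idx]


def _prepare_tip_vectors(tree, tips: Mapping[str, int], space: RangeStateSpace):
    vecs = {}
    for leaf in tree.leaf_node_iter():
        lab = leaf.taxon.label
        if lab not in tips:
            raise ValueError(f"tip {lab!r} has no observed range")
        mask = tips[lab]
        if mask == 0:
            raise ValueError(f"tip {lab!r} has a null observed range")
        if mask not in space.index:
            raise ValueError(
                f"tip {lab!r} range {range_to_str(mask, space.areas)} "
                "is not representable in the state space")
        v = np.zeros(space.n)
        v[space.index[mask]] = 1.0
        vecs[leaf] = v
    return vecs


def _downpass(tree, tips, params, space, prop=None):
    """Pruning pass.  Returns (log_scale, D_node, D_top) where

    D_node[node] — conditional likelihood vector at the node, *including*
    the cladogenetic convolution for internal nodes (the vector is indexed
    by the range immediately before the split);
    D_top[node] — D_node propagated along the node's subtending branch to
    its parent-end (absent for the root).
    """
    require_binary(tree, "DEC likelihood")
    if prop is None:
        prop = _Propagator(build_q_matrix(space, params))
    tipvec = _prepare_tip_vectors(tree, tips, space)
    D_node: dict = {}
    D_top: dict = {}
    log_scale = 0.0
    node_idx = space.node_state_idx
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            D = tipvec[node]
        else:
            c1, c2 = node.child_nodes()
            u1, u2 = D_top[c1], D_top[c2]
            D = np.zeros(space.n)
            for si in node_idx:
                li, ri, w = _clado_indices(space, si)
                D[si] = np.dot(w, u1[li] * u2[ri])
        s = D.max()
        if s <= 0.0:
            warnings.warn("all-zero partial likelihood: data impossible "
                          "under the state space", RuntimeWarning)
            return -np.inf, None, None
        D = D / s
        log_scale += np.log(s)
        D_node[node] = D
        if node.parent_node is not None:
            P = prop(node.edge.length)
            D_top[node] = P @ D
    return log_scale, D_node, D_top


def _root_prior(space: RangeStateSpace) -> np.ndarray:
    prior = np.zeros(space.n)
    prior[space.node_state_idx] = 1.0 / len(space.node_state_idx)
    return prior


def dec_loglik(tree: dendropy.Tree, tips: Mapping[str, int],
               params: DECParams, space: RangeStateSpace) -> float:
    """DEC log-likelihood of tip ranges on a chronogram.

    Tip partials are indicator vectors, branch propagation uses exp(Qt),
    internal nodes convolve the daughters over cladogenetic outcomes, and
    the root sums over non-null in-cap states under a flat prior.
    """
    log_scale, D_node, _ = _downpass(tree, tips, params, space)
    if not np.isfinite(log_scale):
        return -np.inf
    prior = _root_prior(space)
    L = float(prior @ D_node[tree.seed_node])
    if L <= 0:
        return -np.inf
    return np.log(L) + log_scale


def fit_dec_ml(tree, tips, space,
               bounds: tuple[tuple[float, float], tuple[float, float]] = ((1e-7, 10.0),) * 2,
               start: tuple[float, float] = (0.01, 0.01),
               multistart: int = 0) -> tuple[DECParams, float, dict]:
    """Maximum-likelihood estimate of (d, e).

    Bounded L-BFGS-B on log-transformed rates; optional random multistart
    for robustness on flat surfaces.  Returns the fitted params, the
    log-likelihood at the optimum, and a convergence report.
    """
    (dlo, dhi), (elo, ehi) = bounds

    def nll(x):
        p = DECParams(float(np.exp(x[0])), float(np.exp(x[1])))
        ll = dec_loglik(tree, tips, p, space)
        # large finite penalty: infs corrupt finite-difference gradients
        return -ll if np.isfinite(ll) else 1e10

    starts = [np.log(np.asarray(start, dtype=float))]
    if multistart:
        rng = np.random.default_rng(0)
        for _ in range(multistart):
            starts.append(np.array([
                rng.uniform(np.log(dlo), np.log(dhi)),
                rng.uniform(np.log(elo), np.log(ehi)),
            ]))
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B",
            bounds=[(np.log(dlo), np.log(dhi)), (np.log(elo), np.log(ehi))],
            options={"ftol": 1e-10, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    params = DECParams(float(np.exp(best.x[0])), float(np.exp(best.x[1])))
    report = {"converged": bool(best.success), "message": str(best.message),
              "n_eval": int(best.nfev), "neg_loglik": float(best.fun)}
    if not best.success:
        warnings.warn(f"DEC ML fit did not converge: {best.message}",
                      RuntimeWarning)
    return params, -float(best.fun), report


def ancestral_range_marginals(tree, tips, params: DECParams,
                              space: RangeStateSpace) -> pd.DataFrame:
    """Marginal ancestral-range probabilities per internal node.

    For each internal node the probability of range R is the relative
    likelihood of the whole data set with that node constrained to R (the
    range entering the split at the node), normalized over the permitted
    node states.  Computed by one down (pruning) and one up (outside) pass.

    Returns a table with columns: node_id, clade, age, range, probability.
    Node ids are stable postorder indices; reported per non-null range with
    probability above 1e-12.
    """
    prop = _Propagator(build_q_matrix(space, params))
    log_scale, D_node, D_top = _downpass(tree, tips, params, space, prop=prop)
    if D_node is None:
        raise ValueError("data impossible under the state space")
    prior = _root_prior(space)
    # up pass: G[node][R] ∝ P(data outside node's clade | node state R)
    G: dict = {tree.seed_node: prior.copy()}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        c1, c2 = node.child_nodes()
        g = G[node]
        for child, sib in ((c1, c2), (c2, c1)):
            M = np.zeros(space.n)
            usib = D_top[sib]
            for si in space.node_state_idx:
                gs = g[si]
                if gs == 0.0:
                    continue
                li, ri, w = _clado_indices(space, si)
                if child is c1:
                    np.add.at(M, li, gs * w * usib[ri])
                else:
                    np.add.at(M, ri, gs * w * usib[li])
            P = prop(child.edge.length)
            Gc = M @ P
            s = Gc.max()
            if s > 0:
                Gc = Gc / s
            G[child] = Gc

    labels = space.labels()
    rows = []
    from .trees import clade_key
    for node_id, node in enumerate(tree.postorder_internal_node_iter()):
        post = G[node] * D_node[node]
        mass = post[space.node_state_idx]
        total = mass.sum()
        if total <= 0:
            raise ValueError("zero marginal mass at an internal node")
        probs = mass / total
        for k, si in enumerate(space.node_state_idx):
            if probs[k] > 1e-12:
                rows.append({
                    "node_id": node_id,
                    "clade": ",".join(sorted(clade_key(node))),
                    "age": getattr(node, "age", np.nan),
                    "range": labels[si],
                    "probability": probs[k],
                })
    df = pd.DataFrame(rows)
    df.attrs["convention"] = "node state = range entering the split"
    return df


def read_range_table(path_or_buf, areas: Sequence[str] = DEFAULT_AREAS,
                     sep: str = "\t") -> dict[str, int]:
    """Read a species × area 0/1 table into tip-range bitmasks."""
    df = pd.read_csv(path_or_buf, sep=sep, index_col=0)
    missing = [a for a in areas if a not in df.columns]
    if missing:
        raise ValueError(f"range table lacks area columns: {missing}")
    out: dict[str, int] = {}
    for sp, row in df.iterrows():
        mask = 0
        for i, a in enumerate(areas):
            if int(row[a]):
                mask |= 1 << i
        out[str(sp)] = mask
    return out


def write_range_table(tips: Mapping[str, int], path_or_buf,
                      areas: Sequence[str] = DEFAULT_AREAS,
                      sep: str = "\t") -> None:
    recs = {sp: [(mask >> i) & 1 for i in range(len(areas))]
            for sp, mask in tips.items()}
    df = pd.DataFrame.from_dict(recs, orient="index", columns=list(areas))
    df.index.name = "species"
    df.to_csv(path_or_buf, sep=sep)
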