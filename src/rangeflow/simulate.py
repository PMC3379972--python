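"""Ground-truth simulators for every stage of the pipeline.

Each simulator is an exact (Gillespie-style) forward simulation seeded from
one integer: birth–death chronograms (extinct lineages pruned, crown
conditioned on survival of both root children), DEC range histories with
every true dispersal/extinction event recorded, three-state GeoSSE
forward simulation, and autocorrelated-rate phylograms with Poisson
substitution counts.  Random streams are per-module substreams of the one
seed, so adding a simulator never perturbs existing outputs.

The bundled :func:`paper_shaped_recipe` emulates the empirical study shape:
a ~256-tip crown chronogram of ~70.1 Ma, eight areas with occupancy
strongly skewed toward a sub-Saharan-Africa-like source area, and mostly
single-area tips.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import dendropy
import numpy as np

from .dec import (
    DECParams,
    DEFAULT_AREAS,
    RangeStateSpace,
    build_state_space,
    build_q_matrix,
    enumerate_cladogenetic_outcomes,
    range_to_str,
)
from .geosse import GeoSSEParams
from .scenario import BiogeographicEvent

__all__ = [
    "SimulationRecipe",
    "paper_shaped_recipe",
    "simulate_bd_tree",
    "simulate_dec_history",
    "simulate_geosse",
    "simulate_rate_variation",
]

_SUBSTREAMS = {"tree": 0, "dec": 1, "geosse": 2, "rates": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return np.random.default_rng(ss[_SUBSTREAMS[stream]])


@dataclass
class SimulationRecipe:
    """All knobs of the synthetic pipeline, with study-shaped defaults."""

    seed: int
    birth: float = 0.09          # speciation /Myr (pre-rescaling timescale)
    death: float = 0.02          # extinction /Myr
    n_tips: int = 256            # stop condition; crown rescaled afterwards
    crown_age: float = 70.1      # Ma; tree is rescaled so the crown sits here
    areas: tuple = DEFAULT_AREAS
    max_range_size: int = 3
    dec_d: float = 0.0005        # dispersal /area/Myr
    dec_e: float = 0.01          # local extinction /area/Myr
    root_range: str = "C"        # source area (sub-Saharan-Africa-like)
    geosse: GeoSSEParams = field(default_factory=lambda: GeoSSEParams(
        sA=0.15, sB=0.08, sAB=0.0, xA=0.03, xB=0.02, dA=0.02, dB=0.05))
    base_rate: float = 5e-4      # substitutions/site/Myr
    autocorr_sd: float = 0.3     # lognormal sd of parent→child rate change
    sites: int = 4000

    def provenance(self) -> dict:
        d = asdict(self)
        d["geosse"] = list(self.geosse.as_array())
        d["areas"] = "".join(self.areas)
        return d


def paper_shaped_recipe(seed: int) -> SimulationRecipe:
    """Defaults that emulate the empirical study's data shape."""
    return SimulationRecipe(seed=seed)


def simulate_recipe(recipe: SimulationRecipe) -> dict:
    """Run the full synthetic-data recipe.

    Simulates a crown birth–death tree conditioned on the recipe's tip
    count, rescales it so the crown age is exact, runs the DEC range
    history from the source-area root, and draws an autocorrelated-rate
    phylogram from the true chronogram.  Returns a dict with keys
    ``chronogram``, ``phylogram``, ``space``, ``tip_ranges``,
    ``node_states``, ``events`` and ``provenance`` (a machine-readable
    echo of the recipe).
    """
    tree = simulate_bd_tree(recipe.birth, recipe.death,
                            n_tips=recipe.n_tips, seed=recipe.seed)
    factor = recipe.crown_age / tree.seed_node.age
    for nd in tree.preorder_node_iter():
        nd.age *= factor
        if nd.parent_node is not None:
            nd.edge.length *= factor
    space = build_state_space(recipe.areas, recipe.max_range_size)
    from .dec import str_to_range
    root_mask = str_to_range(recipe.root_range, recipe.areas)
    tip_ranges, node_states, events = simulate_dec_history(
        tree, DECParams(recipe.dec_d, recipe.dec_e), space,
        seed=recipe.seed, root_range=root_mask)
    phylogram = simulate_rate_variation(
        tree, recipe.base_rate, recipe.autocorr_sd, recipe.sites,
        seed=recipe.seed)
    return {
        "chronogram": tree,
        "phylogram": phylogram,
        "space": space,
        "tip_ranges": tip_ranges,
        "node_states": node_states,
        "events": events,
        "provenance": recipe.provenance(),
    }


class _Lineage:
    __slots__ = ("parent", "birth_time", "death_time", "children", "state")

    def __init__(self, parent, birth_time, state=None):
        self.parent = parent
        self.birth_time = birth_time
        self.death_time = None
        self.children = []
        self.state = state


def _build_tree(root_lineages, crown_time, end_time, labels=None):
    """Convert surviving forward-simulation lineages into a dendropy tree.

    Times are forward (0 at the crown); ages become end_time - time.
    Extinct lineages must already be pruned from the lineage graph.
    """
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    counter = [0]

    def make(lin, node):
        t0 = lin.birth_time
        t1 = lin.death_time if lin.death_time is not None else end_time
        node.edge.length = t1 - t0
        if not lin.children:
            counter[0] += 1
            node.taxon = taxa.new_taxon(label=f"t{counter[0]}")
            node.sim_lineage = lin
            return
        node.sim_lineage = lin
        for ch in lin.children:
            child = dendropy.Node()
            node.add_child(child)
            make(ch, child)

    # crown: two root lineages joined at the seed node
    root = tree.seed_node
    root.edge.length = None
    root.sim_lineage = None
    for lin in root_lineages:
        child = dendropy.Node()
        root.add_child(child)
        make(lin, child)
    # ages
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            nd.age = end_time - crown_time
        else:
            nd.age = nd.parent_node.age - nd.edge.length
    for leaf in tree.leaf_node_iter():
        leaf.age = 0.0
    return tree


def _prune_extinct(lin) -> bool:
    """Drop extinct subtrees; collapse single-child chains.  True if alive."""
    if not lin.children:
        return lin.death_time is None
    alive = [c for c in lin.children if _prune_extinct(c)]
    if not alive:
        return False
    if len(alive) == 1:
        # collapse: this lineage absorbs the surviving child's span and fate
        c = alive[0]
        lin.children = c.children
        lin.death_time = c.death_time
        lin.state = c.state
        return True
    lin.children = alive
    return True


def simulate_bd_tree(birth: float, death: float = 0.0,
                     crown_age: Optional[float] = None,
                     n_tips: Optional[int] = None,
                     seed: int = 0, max_rejections: int = 1000,
                     rng: Optional[np.random.Generator] = None) -> dendropy.Tree:
    """Crown birth–death chronogram with extinct lineages pruned.

    Exactly one of ``crown_age`` (run for a fixed time) or ``n_tips`` (stop
    at the moment the extant count reaches n) must be given.  The crown is
    conditioned on both root children leaving extant descendants; failing
    draws are rejected up to ``max_rejections`` times.
    """
    if birth <= 0 or death < 0:
        raise ValueError("need birth > 0 and death >= 0")
    if (crown_age is None) == (n_tips is None):
        raise ValueError("give exactly one of crown_age or n_tips")
    if rng is None:
        rng = _rng(seed, "tree")
    for _attempt in range(max_rejections):
        left = _Lineage(None, 0.0)
        right = _Lineage(None, 0.0)
        extant = [left, right]
        t = 0.0
        ok = True
        while True:
            if n_tips is not None and len(extant) >= n_tips:
                # extend to just before the next would-be event so terminal
                # branches have positive length
                total = len(extant) * (birth + death)
                end = t + rng.exponential(1.0 / total)
                break
            if not extant:
                ok = False
                break
            total = len(extant) * (birth + death)
            t += rng.exponential(1.0 / total)
            if crown_age is not None and t >= crown_age:
                end = crown_age
                break
            lin = extant[rng.integers(len(extant))]
            if rng.uniform() < birth / (birth + death):
                c1 = _Lineage(lin, t)
                c2 = _Lineage(lin, t)
                lin.children = [c1, c2]
                lin.death_time = t
                extant.remove(lin)
                extant.extend([c1, c2])
            else:
                lin.death_time = t
                extant.remove(lin)
        if not ok:
            continue
        if not (_prune_extinct(left) and _prune_extinct(right)):
            continue
        tree = _build_tree([left, right], 0.0, end)
        if sum(1 for _ in tree.leaf_node_iter()) >= 2:
            return tree
    raise RuntimeError(
        f"total extinction in {max_rejections} consecutive attempts")


def _gillespie_branch(mask: int, duration: float, start_age: float,
                      Q_moves, rng, events_out, max_redraws: int = 1000):
    """Simulate anagenetic range evolution along one branch.

    ``Q_moves(mask)`` yields (target mask, rate, kind, area index) moves.
    The branch is redrawn if the range is absorbed in the null state
    (conditioning on lineage survival); returns the end mask and appends
    (kind, area index, age) events to events_out.
    """
    for _ in range(max_redraws):
        cur = mask
        t = 0.0
        local: list[tuple[str, int, float]] = []
        dead = False
        while True:
            moves = Q_moves(cur)
            total = sum(r for _, r, _, _ in moves)
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= duration:
                break
            u = rng.uniform() * total
            acc = 0.0
            for tgt, r, kind, area in moves:
                acc += r
                if u <= acc:
                    local.append((kind, area, start_age - t))
                    cur = tgt
                    break
            if cur == 0:
                dead = True
                break
        if not dead:
            events_out.extend(local)
            return cur
    raise RuntimeError("null-range redraw cap exceeded on a branch")


def simulate_dec_history(tree: dendropy.Tree, params: DECParams,
                         space: RangeStateSpace, seed: int = 0,
                         root_range: Optional[int] = None,
                         rng: Optional[np.random.Generator] = None):
    """Forward DEC simulation recording the true history.

    Anagenetic events are drawn by exact event-time simulation from the
    DEC generator restricted to the state space; cladogenetic outcomes are
    drawn with the model's uniform ordered-outcome weights; branches that
    hit the null range are redrawn (conditioning on lineage survival, with
    the redraw count available from the simulator's log).

    Returns (tip_ranges, node_states, events): tip label → mask, internal
    node postorder id → true mask at the split, and the recorded
    :class:`BiogeographicEvent` list (dispersals and extinctions with
    exact times).
    """
    if rng is None:
        rng = _rng(seed, "dec")
    n_areas = len(space.areas)

    def moves(mask):
        out = []
        size = bin(mask).count("1")
        for j in range(n_areas):
            bit = 1 << j
            if mask & bit:
                tgt = mask & ~bit
                if tgt in space.index:
                    out.append((tgt, params.e, "extinction", j))
            else:
                tgt = mask | bit
                if tgt in space.index:
                    out.append((tgt, params.d * size, "dispersal", j))
        return out

    node_state_masks = [space.states[i] for i in space.node_state_idx]
    if root_range is None:
        root_mask = node_state_masks[rng.integers(len(node_state_masks))]
    else:
        root_mask = root_range

    internals = list(tree.postorder_internal_node_iter())
    node_ids = {id(nd): i for i, nd in enumerate(internals)}

    tip_ranges: dict[str, int] = {}
    node_states: dict[int, int] = {}
    events: list[BiogeographicEvent] = []

    def recurse(node, mask):
        if node.is_leaf():
            tip_ranges[node.taxon.label] = mask
            return
        nid = node_ids[id(node)]
        node_states[nid] = mask
        outcomes = enumerate_cladogenetic_outcomes(mask)
        weights = np.array([w for _, w in outcomes])
        pick = rng.choice(len(outcomes), p=weights / weights.sum())
        daughters = outcomes[pick][0]
        for child, dmask in zip(node.child_nodes(), daughters):
            raw: list[tuple[str, int, float]] = []
            end_mask = _gillespie_branch(
                dmask, child.edge.length, node.age, moves, rng, raw)
            cid = node_ids.get(id(child), -1)
            for kind, area_idx, age in raw:
                events.append(BiogeographicEvent(
                    kind=kind, area=space.areas[area_idx],
                    source_range=range_to_str(mask, space.areas)
                    if kind == "dispersal" else "",
                    time=age, parent_id=nid, child_id=cid,
                    from_root=node.parent_node is None))
            recurse(child, end_mask)

    recurse(tree.seed_node, root_mask)
    return tip_ranges, node_states, events


_GEO_STATES = ("A", "B", "AB")


def simulate_geosse(params: GeoSSEParams,
                    crown_age: Optional[float] = None,
                    n_tips: Optional[int] = None,
                    seed: int = 0, root_state: str = "AB",
                    max_rejections: int = 1000):
    """Forward GeoSSE simulation: (chronogram, tip states).

    Three-state birth–death with state-dependent speciation (sA: AB or A
    parents split off an A daughter; sB symmetric; sAB: an AB parent splits
    into A and B), extinction of single-region lineages (xA, xB), range
    contraction of AB lineages (xA: AB→B, xB: AB→A) and range expansion
    (dA: A→AB, dB: B→AB).  Extinct lineages are pruned; the crown is
    conditioned on survival of both root children.
    """
    if max(params.sA, params.sB, params.sAB) <= 0:
        raise ValueError("at least one speciation rate must be positive")
    if (crown_age is None) == (n_tips is None):
        raise ValueError("give exactly one of crown_age or n_tips")
    rng = _rng(seed, "geosse")
    p = params

    def lineage_moves(state):
        # (rate, action, payload): action in {split, die, set_state}
        if state == "A":
            return [(p.sA, "split", ("A", "A")), (p.xA, "die", None),
                    (p.dA, "set", "AB")]
        if state == "B":
            return [(p.sB, "split", ("B", "B")), (p.xB, "die", None),
                    (p.dB, "set", "AB")]
        return [(p.sA, "split", ("A", "AB")), (p.sB, "split", ("B", "AB")),
                (p.sAB, "split", ("A", "B")),
                (p.xA, "set", "B"), (p.xB, "set", "A")]

    for _attempt in range(max_rejections):
        left = _Lineage(None, 0.0, state=root_state)
        right = _Lineage(None, 0.0, state=root_state)
        extant = [left, right]
        t = 0.0
        ok = True
        while True:
            if n_tips is not None and len(extant) >= n_tips:
                total = sum(sum(r for r, _, _ in lineage_moves(l.state))
                            for l in extant)
                end = t + rng.exponential(1.0 / total)
                break
            if not extant:
                ok = False
                break
            rates = [sum(r for r, _, _ in lineage_moves(l.state))
                     for l in extant]
            total = sum(rates)
            t += rng.exponential(1.0 / total)
            if crown_age is not None and t >= crown_age:
                end = crown_age
                break
            u = rng.uniform() * total
            acc = 0.0
            lin = None
            for l, r in zip(extant, rates):
                acc += r
                if u <= acc:
                    lin = l
                    u2 = rng.uniform() * r
                    break
            acc2 = 0.0
            for r, action, payload in lineage_moves(lin.state):
                acc2 += r
                if u2 <= acc2:
                    if action == "split":
                        s1, s2 = payload
                        if rng.uniform() < 0.5:
                            s1, s2 = s2, s1
                        c1 = _Lineage(lin, t, state=s1)
                        c2 = _Lineage(lin, t, state=s2)
                        lin.children = [c1, c2]
                        lin.death_time = t
                        extant.remove(lin)
                        extant.extend([c1, c2])
                    elif action == "die":
                        lin.death_time = t
                        extant.remove(lin)
                    else:
                        lin.state = payload
                    break
        if not ok:
            continue
        if not (_prune_extinct(left) and _prune_extinct(right)):
            continue
        tree = _build_tree([left, right], 0.0, end)
        if sum(1 for _ in tree.leaf_node_iter()) < 2:
            continue
        states = {leaf.taxon.label: leaf.sim_lineage.state
                  for leaf in tree.leaf_node_iter()}
        return tree, states
    raise RuntimeError(
        f"total extinction in {max_rejections} consecutive attempts")


def simulate_rate_variation(tree: dendropy.Tree, base_rate: float,
                            autocorr_sd: float, sites: int,
                            seed: int = 0,
                            rng: Optional[np.random.Generator] = None
                            ) -> dendropy.Tree:
    """Autocorrelated-rate phylogram from a chronogram.

    Each branch's substitution rate is its parent branch's rate times a
    lognormal(0, autocorr_sd) factor (root children start from the base
    rate); branch lengths are Poisson(rate × duration × sites)/sites.
    """
    if base_rate <= 0 or sites <= 0:
        raise ValueError("base_rate and sites must be positive")
    if rng is None:
        rng = _rng(seed, "rates")
    phylo = tree.clone(depth=1)
    rate_of = {}
    for nd in phylo.preorder_node_iter():
        if nd.parent_node is None:
            continue
        parent_rate = rate_of.get(id(nd.parent_node), base_rate)
        r = parent_rate * (np.exp(rng.normal(0.0, autocorr_sd))
                           if autocorr_sd > 0 else 1.0)
        rate_of[id(nd)] = r
        duration = nd.edge.length
        nd.edge.length = rng.poisson(r * duration * sites) / sites
    for nd in phylo.preorder_node_iter():
        if hasattr(nd, "age"):
            del nd.age
    return phylo
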