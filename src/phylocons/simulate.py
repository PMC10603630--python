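"""Synthetic inputs for every stage of the pipeline.

Provides seed-deterministic generators for dated Yule trees, tip ranges
simulated forward under the DEC process with known parameters, random IUCN
categories, and rectangular range polygons on a lat/lon lattice — plus the
packaged seven-species New World Vulture fixture.

The fixture mirrors the published topology, tip names, IUCN categories and
area codings of the Cathartidae, but its branch lengths are SYNTHETIC
placeholders: node heights are plausible round numbers guided by published
divergence-date prose (e.g. an Andean Condor split near 9 Ma, Miocene basal
splits) and the whole tree is rescaled so the total branch length is
exactly 62 Ma.  Outputs computed from it are therefore illustrative, not
the published per-species values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import box

from .biogeo import RangeStateSpace, anagenetic_q, build_state_space, cladogenesis_table
from .treeio import CladeKey, Node, TimeTree, TreeSample

__all__ = [
    "simulate_yule_tree",
    "simulate_dec_history",
    "random_ranges_polygons",
    "random_iucn_categories",
    "jitter_tree_sample",
    "vulture_fixture",
    "SimTruth",
]

Range = FrozenSet[str]


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> TimeTree:
    """Ultrametric pure-birth tree with *n_tips* labeled tips (t1..tn).

    Lineages split at total rate k*birth_rate; after the n-th lineage
    arises the process runs one final Exp(n*birth_rate) interval, so the
    expected root height is sum_{k=2..n} 1/(k*birth_rate).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    next_id = [0]

    def new_node() -> Node:
        next_id[0] += 1
        return Node(next_id[0])

    root = new_node()
    left, right = new_node(), new_node()
    root.children = [left, right]
    left.parent = right.parent = root
    active: List[Node] = [left, right]
    birth_time = {left.id: 0.0, right.id: 0.0}
    t = 0.0
    while True:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        if k == n_tips:
            break
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        parent.length = t - birth_time[parent.id]
        c1, c2 = new_node(), new_node()
        parent.children = [c1, c2]
        c1.parent = c2.parent = parent
        birth_time[c1.id] = birth_time[c2.id] = t
        active.extend([c1, c2])
    for i, tip in enumerate(active, start=1):
        tip.length = t - birth_time[tip.id]
        tip.label = f"t{i}"
    return TimeTree(root)


@dataclass
class SimTruth:
    """Replayable record of a forward DEC simulation."""

    model: str
    d: float
    e: float
    j: float
    root_range: Range
    node_ranges: Dict[CladeKey, Range]  # true range at each internal node
    seed: int
    rejected_replicates: int = 0
    n_anagenetic_events: int = 0


def simulate_dec_history(
    tree: TimeTree,
    space: RangeStateSpace,
    d: float,
    e: float,
    j: float = 0.0,
    model: str = "DEC",
    root_range: Optional[Range] = None,
    seed: int = 0,
    max_retries: int = 100,
) -> Tuple[Dict[str, Range], SimTruth]:
    """Forward-simulate ranges on *tree* under the given model.

    Anagenetic events are drawn by Gillespie simulation along each branch;
    at every internal node an ordered daughter-range pair is drawn from the
    model's cladogenetic table.  A replicate in which any lineage goes
    range-extinct (hits the null range) is discarded and resimulated, up to
    *max_retries* times; the rejection count is reported in the truth record.
    """
    tree.require_binary()
    if root_range is None:
        root_range = frozenset([space.areas[0]])
    if not root_range or root_range not in space.index:
        raise ValueError("root_range must be a non-null member of the state space")
    clado = cladogenesis_table(space, model, j)
    Q = anagenetic_q(space, d, e)
    rng = np.random.default_rng(seed)

    n_events = [0]

    def evolve(state_idx: int, t: float) -> int:
        remaining = t
        while True:
            total = -Q[state_idx, state_idx]
            if total <= 0:
                return state_idx
            wait = rng.exponential(1.0 / total)
            if wait > remaining:
                return state_idx
            remaining -= wait
            rates = Q[state_idx].copy()
            rates[state_idx] = 0.0
            state_idx = int(rng.choice(len(rates), p=rates / rates.sum()))
            n_events[0] += 1

    for attempt in range(max_retries + 1):
        node_ranges: Dict[CladeKey, Range] = {}
        tips_out: Dict[str, Range] = {}
        failed = False
        n_events[0] = 0

        def run(node: Node, state_idx: int) -> None:
            nonlocal failed
            if failed:
                return
            if node.is_tip:
                if state_idx == 0:
                    failed = True
                else:
                    tips_out[node.label] = space.states[state_idx]
                return
            node_ranges[tree.clade_key(node)] = space.states[state_idx]
            events = clado.events[state_idx]
            probs = np.array([p for _, _, p in events])
            l, r, _ = events[int(rng.choice(len(events), p=probs / probs.sum()))]
            for child, start in zip(node.children, (l, r)):
                end = evolve(start, child.length)
                if end == 0:
                    failed = True
                    return
                run(child, end)

        run(tree.root, space.index[root_range])
        if not failed:
            truth = SimTruth(
                model=model,
                d=d,
                e=e,
                j=j,
                root_range=root_range,
                node_ranges=node_ranges,
                seed=seed,
                rejected_replicates=attempt,
                n_anagenetic_events=n_events[0],
            )
            return tips_out, truth
    raise RuntimeError(
        f"range extinction in {max_retries} consecutive replicates; "
        "lower e (or raise d) and retry"
    )


def random_iucn_categories(species: Sequence[str], seed: int = 0) -> Dict[str, str]:
    """Random Red List categories, weighted toward the common LC/NT classes."""
    rng = np.random.default_rng(seed)
    cats = ["LC", "NT", "VU", "EN", "CR"]
    weights = np.array([0.5, 0.15, 0.15, 0.1, 0.1])
    return {sp: cats[int(rng.choice(5, p=weights))] for sp in species}


def random_ranges_polygons(
    species: Sequence[str],
    extent: Tuple[float, float, float, float] = (-85.0, -30.0, -35.0, 15.0),
    seed: int = 0,
):
    """Axis-aligned rectangular range per species, corners on a 0.5-degree
    lattice inside *extent* (min_lon, min_lat, max_lon, max_lat), each at
    least one degree on a side."""
    if not species:
        raise ValueError("empty species list")
    min_lon, min_lat, max_lon, max_lat = extent
    if not (min_lon < max_lon and min_lat < max_lat):
        raise ValueError("invalid extent box")
    rng = np.random.default_rng(seed)

    def snap(x: float) -> float:
        return round(x * 2.0) / 2.0

    out = {}
    for sp in species:
        while True:
            x0 = snap(rng.uniform(min_lon, max_lon - 1.0))
            y0 = snap(rng.uniform(min_lat, max_lat - 1.0))
            w = snap(rng.uniform(1.0, max(1.0, (max_lon - x0))))
            h = snap(rng.uniform(1.0, max(1.0, (max_lat - y0))))
            x1, y1 = min(x0 + w, max_lon), min(y0 + h, max_lat)
            if x1 - x0 >= 1.0 and y1 - y0 >= 1.0:
                out[sp] = box(x0, y0, x1, y1)
                break
    return out


def jitter_tree_sample(
    tree: TimeTree, n_trees: int, rel_sd: float = 0.1, seed: int = 0
) -> TreeSample:
    """A pseudo-posterior sample: copies of *tree* with branch lengths
    perturbed by independent lognormal factors (topology preserved)."""
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        clone = tree.copy()
        for node in clone.nodes:
            if node.parent is not None and node.length > 0:
                node.length *= float(rng.lognormal(0.0, rel_sd))
        trees.append(clone)
    return TreeSample(trees)


# ---------------------------------------------------------------------------
# the seven-species New World Vulture fixture

_VULTURE_NEWICK_UNSCALED = (
    "((Coragyps_atratus:12,(Cathartes_aura:5,(Cathartes_burrovianus:3,"
    "Cathartes_melambrotus:3):2):7):2,(Vultur_gryphus:9,"
    "(Gymnogyps_californianus:6,Sarcoramphus_papa:6):3):5);"
)

_VULTURE_CATEGORIES = {
    "Coragyps_atratus": "LC",
    "Cathartes_aura": "LC",
    "Cathartes_burrovianus": "LC",
    "Cathartes_melambrotus": "LC",
    "Sarcoramphus_papa": "LC",
    "Vultur_gryphus": "VU",
    "Gymnogyps_californianus": "CR",
}

# Two-region scheme: Nearctic (N), Neotropical (T).
_VULTURE_TWO_AREA = {
    "Coragyps_atratus": frozenset({"N", "T"}),
    "Cathartes_aura": frozenset({"N", "T"}),
    "Cathartes_burrovianus": frozenset({"T"}),
    "Cathartes_melambrotus": frozenset({"T"}),
    "Sarcoramphus_papa": frozenset({"T"}),
    "Vultur_gryphus": frozenset({"T"}),
    "Gymnogyps_californianus": frozenset({"N"}),
}

# Three-area scheme: North America (A), Central America (B), South America (C).
_VULTURE_THREE_AREA = {
    "Coragyps_atratus": frozenset({"A", "B", "C"}),
    "Cathartes_aura": frozenset({"A", "B", "C"}),
    "Cathartes_burrovianus": frozenset({"B", "C"}),
    "Cathartes_melambrotus": frozenset({"C"}),
    "Sarcoramphus_papa": frozenset({"B", "C"}),
    "Vultur_gryphus": frozenset({"C"}),
    "Gymnogyps_californianus": frozenset({"A"}),
}

# Max-one-area coding for the Bayesian multistate run: each widespread
# species is collapsed to its primary region (the region holding the bulk
# of its range); configurable per species in analyses.
VULTURE_PRIMARY_AREA = {
    "Coragyps_atratus": "C",
    "Cathartes_aura": "C",
    "Cathartes_burrovianus": "C",
    "Cathartes_melambrotus": "C",
    "Sarcoramphus_papa": "C",
    "Vultur_gryphus": "C",
    "Gymnogyps_californianus": "A",
}

TOTAL_FIXTURE_LENGTH = 62.0  # Ma, by construction


def vulture_fixture():
    """The packaged 7-taxon Cathartidae fixture.

    Returns ``(tree, two_area_coding, three_area_coding, categories)``.
    The topology, names, categories and codings follow the published
    account of the clade; branch lengths are synthetic (see module
    docstring) and scaled so the total tree length is exactly 62 Ma.
    """
    from .treeio import parse_newick

    tree = parse_newick(_VULTURE_NEWICK_UNSCALED)
    scale = TOTAL_FIXTURE_LENGTH / tree.total_length()
    for node in tree.nodes:
        node.length *= scale
    return tree, dict(_VULTURE_TWO_AREA), dict(_VULTURE_THREE_AREA), dict(
        _VULTURE_CATEGORIES
    )


def vulture_state_spaces() -> Tuple[RangeStateSpace, RangeStateSpace]:
    """State spaces for the two regionalization schemes (full subset spaces)."""
    return build_state_space(["N", "T"]), build_state_space(["A", "B", "C"])
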