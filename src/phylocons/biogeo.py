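"""Dispersal-Extinction-Cladogenesis model family for ancestral range estimation.

Implements the DEC, DIVALIKE and BAYAREALIKE models and their founder-event
(+J) variants on a dated, strictly binary phylogeny:

* a state space of area subsets (the "ranges"), with the empty range as an
  absorbing state;
* an anagenetic CTMC in which a lineage occupying range R expands to an
  adjacent-by-one-area range at rate |R|*d per target area and contracts by
  one area at rate e per occupied area;
* a per-model cladogenetic event table giving, for each parent range, the
  distribution over ordered daughter-range pairs (sympatry, subset
  sympatry, vicariance, exact inheritance, founder jumps weighted j);
* Felsenstein pruning over ranges for the likelihood, maximum-likelihood
  fitting with AICc ranking, and marginal ancestral-range probabilities by
  an up-down pass.

The root is weighted uniformly over non-null ranges (the classic LAGRANGE
convention); this shifts every model's log-likelihood by the same constant
and therefore does not affect model ranking, but it is configurable since
other tools condition differently.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .treeio import CladeKey, Node, TimeTree

__all__ = [
    "RangeStateSpace",
    "CladoTable",
    "BiogeoFit",
    "build_state_space",
    "anagenetic_q",
    "transition_probs",
    "cladogenesis_table",
    "range_likelihood",
    "fit_model",
    "rank_models",
    "ancestral_ranges",
    "read_geography",
    "write_geography",
]

MODELS = ("DEC", "DIVALIKE", "BAYAREALIKE")

Range = FrozenSet[str]


class RangeStateSpace:
    """Ordered area-subset state space with the null range at index 0.

    States are ordered by range size then lexicographically, which keeps
    indexing deterministic across runs.
    """

    def __init__(self, areas: Sequence[str], max_range_size: int):
        if len(set(areas)) != len(areas):
            raise ValueError("area labels must be unique")
        if not 1 <= max_range_size <= len(areas):
            raise ValueError("max_range_size must be in [1, n_areas]")
        if len(areas) > 8:
            raise ValueError(
                "at most 8 areas supported (the state space grows as 2^n and "
                "ancestral resolution degrades)"
            )
        self.areas: Tuple[str, ...] = tuple(areas)
        self.max_range_size = max_range_size
        states: List[Range] = [frozenset()]
        for size in range(1, max_range_size + 1):
            for combo in itertools.combinations(sorted(self.areas), size):
                states.append(frozenset(combo))
        self.states: Tuple[Range, ...] = tuple(states)
        self.index: Dict[Range, int] = {s: i for i, s in enumerate(states)}
        self.n_states = len(states)

    def label(self, state_index: int) -> str:
        s = self.states[state_index]
        return "+".join(sorted(s)) if s else "0"

    def nonnull_indices(self) -> np.ndarray:
        return np.arange(1, self.n_states)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RangeStateSpace({self.areas}, max={self.max_range_size}, {self.n_states} states)"


def build_state_space(areas: Sequence[str], max_range_size: Optional[int] = None) -> RangeStateSpace:
    """All area subsets up to *max_range_size* (default: all areas), null first."""
    if max_range_size is None:
        max_range_size = len(areas)
    return RangeStateSpace(areas, max_range_size)


def anagenetic_q(space: RangeStateSpace, d: float, e: float) -> np.ndarray:
    """DEC anagenetic rate matrix over ranges.

    Expansion R -> R+{a} at rate |R|*d for each area a not in R (if the
    result fits the size bound); contraction R -> R-{a} at rate e per
    occupied area; the null range is absorbing.  Rows sum to zero.
    """
    if d < 0 or e < 0:
        raise ValueError("rates must be non-negative")
    n = space.n_states
    Q = np.zeros((n, n))
    for i, R in enumerate(space.states):
        if not R:
            continue  # null range is absorbing
        for a in space.areas:
            if a in R:
                target = R - {a}
                Q[i, space.index[target]] += e
            elif len(R) + 1 <= space.max_range_size:
                target = R | {a}
                Q[i, space.index[target]] += len(R) * d
        Q[i, i] = -Q[i].sum()
    return Q


def transition_probs(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows must sum to 1 within 1e-10, entries clipped to [0, 1]."""
    if t < 0:
        raise ValueError("time must be non-negative")
    row_sums = Q.sum(axis=1)
    if np.max(np.abs(row_sums)) > 1e-8 or np.min(Q - np.diag(np.diag(Q))) < -1e-12:
        raise ValueError("Q is not a valid CTMC generator")
    P = expm(Q * t)
    dev = np.max(np.abs(P.sum(axis=1) - 1.0))
    if dev > 1e-10:
        raise ValueError(f"matrix exponential row-sum deviation {dev:.2e} exceeds 1e-10")
    return np.clip(P, 0.0, 1.0)


class CladoTable:
    """Cladogenetic event distribution: parent range -> ordered daughter pairs.

    ``events[i]`` is a list of ``(left_index, right_index, probability)``
    for parent state index ``i``; probabilities sum to 1 per parent.
    """

    def __init__(self, space: RangeStateSpace, events: Dict[int, List[Tuple[int, int, float]]]):
        self.space = space
        self.events = events

    def probabilities(self, parent_index: int) -> List[Tuple[int, int, float]]:
        return self.events.get(parent_index, [])


def _dec_events(space: RangeStateSpace, R: Range) -> List[Tuple[Range, Range]]:
    if len(R) == 1:
        return [(R, R)]
    out: List[Tuple[Range, Range]] = []
    seen = set()
    for a in sorted(R):
        single = frozenset([a])
        rest = R - single
        # subset sympatry: one daughter keeps the full range
        for pair in ((single, R), (R, single)):
            if pair not in seen:
                seen.add(pair)
                out.append(pair)
        # vicariance with a single-area side
        for pair in ((single, rest), (rest, single)):
            if pair not in seen:
                seen.add(pair)
                out.append(pair)
    return out


def _divalike_events(space: RangeStateSpace, R: Range) -> List[Tuple[Range, Range]]:
    if len(R) == 1:
        return [(R, R)]
    # widespread vicariance: every ordered split of R into two nonempty
    # disjoint parts (no subset sympatry)
    out = []
    members = sorted(R)
    for size in range(1, len(members)):
        for left in itertools.combinations(members, size):
            left_set = frozenset(left)
            right_set = R - left_set
            if (
                len(left_set) <= space.max_range_size
                and len(right_set) <= space.max_range_size
            ):
                out.append((left_set, right_set))
    return out


def _bayarealike_events(space: RangeStateSpace, R: Range) -> List[Tuple[Range, Range]]:
    return [(R, R)]


_EVENT_ENUM = {
    "DEC": _dec_events,
    "DIVALIKE": _divalike_events,
    "BAYAREALIKE": _bayarealike_events,
}


def cladogenesis_table(space: RangeStateSpace, model: str, j: float = 0.0) -> CladoTable:
    """Event table for a model; ``j > 0`` adds founder jumps (b, R) / (R, b)
    with weight j for every single area b outside the parent range, while
    each non-jump event instance keeps weight 1."""
    if model not in _EVENT_ENUM:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if j < 0:
        raise ValueError("j must be non-negative")
    enum = _EVENT_ENUM[model]
    events: Dict[int, List[Tuple[int, int, float]]] = {}
    for i, R in enumerate(space.states):
        if not R:
            continue
        weighted: List[Tuple[Range, Range, float]] = [
            (l, r, 1.0) for (l, r) in enum(space, R)
        ]
        if j > 0:
            for b in sorted(set(space.areas) - R):
                single = frozenset([b])
                weighted.append((single, R, j))
                weighted.append((R, single, j))
        total = sum(w for _, _, w in weighted)
        events[i] = [
            (space.index[l], space.index[r], w / total) for (l, r, w) in weighted
        ]
    return CladoTable(space, events)


# ---------------------------------------------------------------------------
# geography files (LAGRANGE / BioGeoBears PHYLIP-style dialect)


def read_geography(text: str, space: Optional[RangeStateSpace] = None) -> Tuple[RangeStateSpace, Dict[str, Range]]:
    """Parse a PHYLIP-style geography file.

    Header: ``ntax nareas (A B C)``; then one line per species with a
    binary presence string, e.g. ``Coragyps_atratus 11``.
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    header = lines[0].replace("(", " ").replace(")", " ").split()
    ntax, nareas = int(header[0]), int(header[1])
    labels = header[2:]
    if len(labels) != nareas:
        labels = [chr(ord("A") + i) for i in range(nareas)]
    if space is None:
        space = build_state_space(labels)
    coding: Dict[str, Range] = {}
    for ln in lines[1:]:
        name, bits = ln.rsplit(None, 1)
        if len(bits) != nareas or set(bits) - {"0", "1"}:
            raise ValueError(f"bad presence string for {name!r}: {bits!r}")
        R = frozenset(a for a, b in zip(space.areas, bits) if b == "1")
        if not R:
            raise ValueError(f"species {name!r} coded with the null range")
        coding[name] = R
    if len(coding) != ntax:
        raise ValueError(f"header says {ntax} taxa but {len(coding)} lines present")
    return space, coding


def write_geography(space: RangeStateSpace, coding: Mapping[str, Range]) -> str:
    lines = [f"{len(coding)}\t{len(space.areas)}\t({' '.join(space.areas)})"]
    for name in coding:
        bits = "".join("1" if a in coding[name] else "0" for a in space.areas)
        lines.append(f"{name}\t{bits}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# likelihood


def _check_tips(space: RangeStateSpace, tree: TimeTree, tips: Mapping[str, Range]) -> None:
    for label in tree.tip_labels:
        if label not in tips:
            raise ValueError(f"tip {label!r} has no range coding")
        R = tips[label]
        if not R or R not in space.index:
            raise ValueError(
                f"tip {label!r} coded with a range outside the state space: {sorted(R)}"
            )


def _conditional_likelihoods(
    tree: TimeTree,
    space: RangeStateSpace,
    tips: Mapping[str, Range],
    clado: CladoTable,
    Q: np.ndarray,
) -> Tuple[Dict[int, np.ndarray], Dict[int, np.ndarray]]:
    """Postorder pass.

    Returns (D, Dup) where D[node.id] is the conditional likelihood of the
    data below the node given the node's state (after cladogenesis for
    internal nodes, observation indicator for tips) and Dup[node.id] is D
    propagated up through the node's stem branch.
    """
    n = space.n_states
    D: Dict[int, np.ndarray] = {}
    Dup: Dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            v = np.zeros(n)
            v[space.index[tips[node.label]]] = 1.0
            D[node.id] = v
        else:
            if len(node.children) != 2:
                raise ValueError("biogeographic likelihood requires a binary tree")
            c1, c2 = node.children
            v = np.zeros(n)
            for parent_idx, events in clado.events.items():
                acc = 0.0
                u1, u2 = Dup[c1.id], Dup[c2.id]
                for l, r, p in events:
                    acc += p * u1[l] * u2[r]
                v[parent_idx] = acc
            D[node.id] = v
        if node.parent is not None:
            P = transition_probs(Q, node.length)
            Dup[node.id] = P @ D[node.id]
    return D, Dup


def range_likelihood(
    tree: TimeTree,
    tips: Mapping[str, Range],
    space: RangeStateSpace,
    model: str,
    d: float,
    e: float,
    j: float = 0.0,
) -> float:
    """Log-likelihood of the tip ranges under the model by Felsenstein pruning.

    The root is averaged uniformly over non-null ranges.
    """
    tree.require_binary()
    _check_tips(space, tree, tips)
    clado = cladogenesis_table(space, model, j)
    Q = anagenetic_q(space, d, e)
    D, _ = _conditional_likelihoods(tree, space, tips, clado, Q)
    root = D[tree.root.id]
    lik = root[1:].mean()
    if lik <= 0:
        return -math.inf
    return math.log(lik)


@dataclass
class BiogeoFit:
    """A fitted biogeographic model."""

    model: str
    plus_j: bool
    d: float
    e: float
    j: float
    lnL: float
    k: int
    n_tips: int
    converged: bool = True
    n_starts: int = 0
    data_id: Optional[str] = None

    @property
    def name(self) -> str:
        return self.model + ("+J" if self.plus_j else "")

    @property
    def aicc(self) -> float:
        n, k = self.n_tips, self.k
        if n - k - 1 <= 0:
            return math.inf
        return -2.0 * self.lnL + 2 * k + 2 * k * (k + 1) / (n - k - 1)


_BOUNDS_RATE = (1e-12, 5.0)
_BOUNDS_J = (0.0, 3.0)
_STARTS_BASE = [(0.01, 0.01), (0.1, 0.1), (0.001, 0.001)]
_STARTS_J = [(0.01, 0.01, 0.01), (0.1, 0.1, 0.1), (0.001, 0.001, 0.5)]


def fit_model(
    tree: TimeTree,
    tips: Mapping[str, Range],
    space: RangeStateSpace,
    model: str,
    plus_j: bool = False,
) -> BiogeoFit:
    """Maximum-likelihood fit of (d, e[, j]) by bounded Nelder-Mead from
    multiple documented starts; AICc uses n = number of tips."""
    tree.require_binary()
    _check_tips(space, tree, tips)
    starts = _STARTS_J if plus_j else _STARTS_BASE
    bounds = [_BOUNDS_RATE, _BOUNDS_RATE] + ([_BOUNDS_J] if plus_j else [])

    def neg_lnL(params: np.ndarray) -> float:
        d, e = params[0], params[1]
        j = params[2] if plus_j else 0.0
        ll = range_likelihood(tree, tips, space, model, d, e, j)
        return -ll if math.isfinite(ll) else 1e12

    best = None
    any_ok = False
    for start in starts:
        res = minimize(
            neg_lnL,
            np.array(start),
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    fit = BiogeoFit(
        model=model,
        plus_j=plus_j,
        d=float(best.x[0]),
        e=float(best.x[1]),
        j=float(best.x[2]) if plus_j else 0.0,
        lnL=-float(best.fun),
        k=3 if plus_j else 2,
        n_tips=len(tree.tips),
        converged=any_ok,
        n_starts=len(starts),
        data_id=_data_id(tree, tips),
    )
    if not any_ok:
        raise RuntimeError(f"optimizer failed to converge for {fit.name}; best lnL {fit.lnL}")
    return fit


def _data_id(tree: TimeTree, tips: Mapping[str, Range]) -> str:
    return "|".join(f"{t}:{''.join(sorted(tips[t]))}" for t in sorted(tree.tip_labels))


def rank_models(fits: Sequence[BiogeoFit]) -> pd.DataFrame:
    """Rank fitted models by ascending AICc; ties broken by fewer parameters."""
    if len(fits) < 2:
        raise ValueError("model ranking requires at least two fits")
    ids = {f.data_id for f in fits}
    if len(ids) > 1:
        raise ValueError("fits were computed on different datasets")
    rows = [
        {
            "model": f.name,
            "k": f.k,
            "d": f.d,
            "e": f.e,
            "j": f.j if f.plus_j else 0.0,
            "lnL": f.lnL,
            "AICc": f.aicc,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values(by=["AICc", "k"]).reset_index(drop=True)
    df["delta_AICc"] = df["AICc"] - df["AICc"].iloc[0]
    df.insert(0, "rank", range(1, len(df) + 1))
    return df


def ancestral_ranges(
    tree: TimeTree,
    tips: Mapping[str, Range],
    space: RangeStateSpace,
    model: str,
    d: float,
    e: float,
    j: float = 0.0,
) -> Dict[CladeKey, Dict[str, float]]:
    """Marginal ancestral-range probabilities at every internal node.

    Up-down pass: the downward conditionals from pruning are combined with
    an upward message passed through each node's stem branch and its
    sibling's subtree via the cladogenesis table.  Probabilities are over
    non-null ranges (keys are '+'.joined area labels), normalized to 1, and
    keyed by the node's descendant-tip set.
    """
    tree.require_binary()
    _check_tips(space, tree, tips)
    clado = cladogenesis_table(space, model, j)
    Q = anagenetic_q(space, d, e)
    D, Dup = _conditional_likelihoods(tree, space, tips, clado, Q)

    n = space.n_states
    prior = np.zeros(n)
    prior[1:] = 1.0 / (n - 1)

    U: Dict[int, np.ndarray] = {tree.root.id: prior}
    out: Dict[CladeKey, Dict[str, float]] = {}

    for node in tree.preorder():
        if node.is_tip:
            continue
        c1, c2 = node.children
        # marginal at this node (parent-range at the instant before cladogenesis)
        post = U[node.id] * D[node.id]
        total = post.sum()
        if total <= 0:
            raise RuntimeError("zero marginal likelihood at an internal node")
        post = post / total
        out[tree.clade_key(node)] = {
            space.label(i): float(post[i]) for i in range(1, n)
        }
        # messages to the children: for child c1, sum over parent range and
        # events, weighting by the sibling's propagated conditional
        for child, sibling in ((c1, c2), (c2, c1)):
            msg = np.zeros(n)
            u_sib = Dup[sibling.id]
            left_child = child is c1
            for parent_idx, events in clado.events.items():
                w = U[node.id][parent_idx]
                if w == 0.0:
                    continue
                for l, r, p in events:
                    if left_child:
                        msg[l] += w * p * u_sib[r]
                    else:
                        msg[r] += w * p * u_sib[l]
            P = transition_probs(Q, child.length)
            U[child.id] = msg @ P  # message flows root->tip through the stem
    return out
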