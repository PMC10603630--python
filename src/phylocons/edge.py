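"""Evolutionary Distinctiveness (fair proportion), GE coding, and EDGE scores.

ED partitions a tree's total branch length among its tips: each edge is
split equally among the tips descending from it, so per-species ED sums
exactly to Faith's PD of the whole tree.  GE maps IUCN Red List categories
onto integers 0-4, and EDGE = ln(1 + ED) + GE * ln(2) combines the two so
that each Red List step doubles a species' priority odds.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, Mapping

import pandas as pd

from .treeio import TimeTree, TreeSample

__all__ = [
    "GE_SCORES",
    "fair_proportion_ed",
    "ge_score",
    "edge_score",
    "edge_table",
]

# Isaac-style Red List weighting. DD/NE/EX/EW are deliberately outside the
# vocabulary: the score is undefined for them and inputs must be resolved
# upstream.
GE_SCORES: Dict[str, int] = {
    "LC": 0,
    "NT": 1,
    "LRcd": 1,
    "VU": 2,
    "EN": 3,
    "CR": 4,
}


def ge_score(category: str) -> int:
    """Integer GE score for an IUCN category (LC=0, NT/LRcd=1, VU=2, EN=3, CR=4)."""
    key = category.strip().replace("/", "")
    if key not in GE_SCORES:
        raise ValueError(
            f"IUCN category {category!r} has no GE score "
            f"(expected one of {sorted(GE_SCORES)})"
        )
    return GE_SCORES[key]


def edge_score(ed: float, ge: int) -> float:
    """EDGE = ln(1 + ED) + GE * ln 2 (natural logs; ED in Ma)."""
    if ed < 0:
        raise ValueError(f"ED must be non-negative, got {ed}")
    if ge not in (0, 1, 2, 3, 4):
        raise ValueError(f"GE must be an integer in 0..4, got {ge}")
    return math.log1p(ed) + ge * math.log(2.0)


def fair_proportion_ed(tree: TimeTree) -> Dict[str, float]:
    """Fair-proportion ED per tip, in Ma.

    ED(i) = sum over edges e on the root-to-i path of length(e) / n(e),
    where n(e) is the number of tips descending from e.  Polytomies are
    handled naturally since only descendant-tip counts matter.
    """
    counts = tree.tip_descendant_counts()
    ed: Dict[str, float] = {}
    # accumulate shares by a preorder walk carrying the running sum
    stack = [(tree.root, 0.0)]
    while stack:
        node, acc = stack.pop()
        if node is not tree.root:
            acc = acc + node.length / counts[node.id]
        if node.is_tip:
            ed[node.label] = acc
        else:
            for child in node.children:
                stack.append((child, acc))
    return ed


def mean_ed_over_sample(sample: TreeSample) -> Dict[str, float]:
    """Per-species ED averaged over a tree sample (optional alternative to
    computing ED on the MCC tree alone)."""
    totals: Dict[str, float] = {label: 0.0 for label in sample.tip_labels}
    for tree in sample:
        for label, value in fair_proportion_ed(tree).items():
            totals[label] += value
    n = len(sample)
    return {label: value / n for label, value in totals.items()}


def edge_table(tree: TimeTree, categories: Mapping[str, str]) -> pd.DataFrame:
    """Per-species ED/GE/EDGE table, ranked by EDGE descending.

    *categories* must cover every tip exactly once. Ties in EDGE are broken
    by ED descending, then species label. Columns: species, ED_Ma, GE,
    EDGE, rank_ED, rank_EDGE.
    """
    tips = set(tree.tip_labels)
    given = set(categories)
    if tips != given:
        missing = sorted(tips - given)
        extra = sorted(given - tips)
        raise ValueError(
            f"category table does not match tree tips; missing={missing}, extra={extra}"
        )
    ed = fair_proportion_ed(tree)
    rows = []
    for species in sorted(tips):
        ge = ge_score(categories[species])
        rows.append(
            {
                "species": species,
                "ED_Ma": ed[species],
                "GE": ge,
                "EDGE": edge_score(ed[species], ge),
            }
        )
    df = pd.DataFrame(rows)
    df["rank_ED"] = df["ED_Ma"].rank(method="min", ascending=False).astype(int)
    df = df.sort_values(
        by=["EDGE", "ED_Ma", "species"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df["rank_EDGE"] = range(1, len(df) + 1)
    return df


def read_categories_csv(path) -> Dict[str, str]:
    """Two-column CSV (species,category) -> mapping. Header row optional."""
    df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    if str(df.iloc[0, 0]).lower() in ("species", "taxon", "tip"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
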