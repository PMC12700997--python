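"""Small-parsimony engines for binary presence/absence characters.

Two models are provided. :func:`fitch_score` is unrestricted parsimony
(gains and losses cost equally, computed by a min-cost dynamic program that
is exact on multifurcating trees). :func:`dollo_losses` is Dollo parsimony:
the gene is gained exactly once — at the most recent common ancestor of the
present tips — and every absence below that gain is explained by loss
events on a unique minimal set of edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .trees import Phylogeny

__all__ = ["LossEvent", "fitch_score", "dollo_losses", "independent_loss_count"]


@dataclass(frozen=True)
class LossEvent:
    """A presence-to-absence transition on the edge above ``edge`` (child id)."""

    edge: str
    family_id: str


def fitch_score(
    tree: Phylogeny, tip_states: Mapping[str, int]
) -> tuple[int, dict[str, int]]:
    """Minimum number of binary state changes, plus one optimal labeling.

    Parameters
    ----------
    tree:
        Rooted tree; multifurcations allowed.
    tip_states:
        ``tip id -> 0/1``; every tip must be labeled (no imputation).

    Returns
    -------
    (score, labeling) where ``labeling`` maps every node id to 0/1 and
    realizes ``score`` state-changing edges.
    """
    tips = set(tree.tips)
    missing = tips - set(tip_states)
    if missing:
        raise ValueError(f"missing tip states: {sorted(missing)}")
    bad = {t: s for t, s in tip_states.items() if t in tips and s not in (0, 1)}
    if bad:
        raise ValueError(f"tip states must be 0/1, got {bad}")

    INF = float("inf")
    cost: dict[str, list[float]] = {}
    for node in tree.postorder():
        if tree.is_tip(node):
            s = tip_states[node]
            cost[node] = [0 if s == 0 else INF, 0 if s == 1 else INF]
        else:
            c0 = c1 = 0.0
            for child in tree.children[node]:
                k0, k1 = cost[child]
                c0 += min(k0, k1 + 1)
                c1 += min(k1, k0 + 1)
            cost[node] = [c0, c1]

    labeling: dict[str, int] = {}
    r0, r1 = cost[tree.root]
    labeling[tree.root] = 0 if r0 <= r1 else 1
    for node in tree.preorder():
        if node == tree.root:
            continue
        ps = labeling[tree.parent[node]]
        k0, k1 = cost[node]
        # keep parent's state on ties: favors fewer changes deterministically
        stay = k0 if ps == 0 else k1
        switch = (k1 if ps == 0 else k0) + 1
        labeling[node] = ps if stay <= switch else 1 - ps
    score = int(min(r0, r1))
    return score, labeling


def dollo_losses(
    tree: Phylogeny, tip_states: Mapping[str, int], family_id: str = ""
) -> list[LossEvent]:
    """Loss events under single-gain (Dollo) parsimony.

    The gain is fixed at the MRCA of present tips (the root when all tips
    are present). Losses are the maximal edges within the gain subtree whose
    entire tip set is absent; they are pairwise incomparable by construction.
    A character absent from every tip has no inferable gain and yields an
    empty event list.
    """
    tips = set(tree.tips)
    missing = tips - set(tip_states)
    if missing:
        raise ValueError(f"missing tip states: {sorted(missing)}")
    present = [t for t in tree.tips if tip_states[t] == 1]
    if not present:
        return []
    gain = tree.mrca(present)

    below = tree.clade_map()
    all_absent = {n: all(tip_states[t] == 0 for t in below[n]) for n in tree.postorder()}

    events: list[LossEvent] = []
    stack = list(tree.children.get(gain, ()))
    if tree.is_tip(gain):  # single present tip: no losses below it
        stack = []
    while stack:
        node = stack.pop()
        if all_absent[node]:
            events.append(LossEvent(edge=node, family_id=family_id))
        else:
            stack.extend(tree.children.get(node, ()))
    events.sort(key=lambda e: e.edge)
    return events


def independent_loss_count(events: Sequence[LossEvent], tree: Phylogeny) -> int:
    """Number of phylogenetically independent loss events.

    An event nested below another loss edge is not an independent loss;
    ancestor–descendant pairs are collapsed onto the ancestral edge. Dollo
    output contains no such pairs (asserted), so its count passes through.
    """
    known = set(tree.children)
    for e in events:
        if e.edge not in known:
            raise KeyError(f"event references unknown edge {e.edge!r}")
    edges = [e.edge for e in events]
    kept = [
        a
        for a in edges
        if not any(b != a and tree.is_ancestor(b, a) for b in edges)
    ]
    return len(set(kept))
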