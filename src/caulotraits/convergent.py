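"""Screens for gene modules convergently lost in independent lineages.

The headline pattern this formalizes: two (or more) unrelated clades on the
species tree that have each lost an entire suite of genes — flagellum,
holdfast, and a common set of developmental regulators — while the rest of
the family retains them. A family belongs to the convergently lost module
when it is (a) well conserved in the background, (b) absent from every
genome of every focal lineage, and (c) lost independently at least as many
times as there are focal lineages under Dollo parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .matrix import PresenceMatrix
from .parsimony import LossEvent, dollo_losses, independent_loss_count
from .trees import Phylogeny

__all__ = ["ConvergentModule", "co_loss_screen", "classify_absence", "discover_focal_sets"]


@dataclass
class ConvergentModule:
    """A co-lost gene set together with its focal lineages and per-family scores."""

    family_ids: frozenset[str]
    focal_lineages: frozenset[str]  # clade stem node ids (or tip sets' MRCAs)
    background_conservation: dict[str, float] = field(default_factory=dict)
    n_independent_losses: dict[str, int] = field(default_factory=dict)
    category: dict[str, str] = field(default_factory=dict)

    def report(self) -> pd.DataFrame:
        fams = sorted(self.family_ids)
        return pd.DataFrame(
            {
                "family_id": fams,
                "background_conservation": [self.background_conservation.get(f) for f in fams],
                "n_independent_losses": [self.n_independent_losses.get(f) for f in fams],
                "category": [self.category.get(f, "") for f in fams],
            }
        )


def co_loss_screen(
    matrix: PresenceMatrix,
    tree: Phylogeny,
    focal_sets: Sequence[frozenset[str] | set[str]],
    conservation_min: float = 0.75,
) -> ConvergentModule:
    """Families conserved in the background yet absent from every focal lineage.

    ``focal_sets`` are disjoint genome sets (typically clades discovered via
    :func:`discover_focal_sets`); the background is every other genome in
    the matrix. A family is returned when its background presence fraction
    is at least ``conservation_min``, it is absent from all focal genomes,
    and its Dollo losses collapse to at least ``len(focal_sets)``
    independent events on the tree.
    """
    if len(focal_sets) < 2:
        raise ValueError("need at least two focal sets for a convergence screen")
    focal_sets = [frozenset(s) for s in focal_sets]
    for i, a in enumerate(focal_sets):
        for b in focal_sets[i + 1 :]:
            if a & b:
                raise ValueError(f"focal sets overlap: {sorted(a & b)}")
    all_focal = frozenset().union(*focal_sets)
    genomes = matrix.genome_ids
    unknown = all_focal - set(genomes)
    if unknown:
        raise KeyError(f"focal genomes not in matrix: {sorted(unknown)}")
    background = [g for g in genomes if g not in all_focal]
    if not background:
        raise ValueError("background is empty: every genome is focal")

    pres = matrix.presence
    bg_frac = pres.loc[background].mean(axis=0)
    focal_absent = (~pres.loc[sorted(all_focal)]).all(axis=0)
    candidates = bg_frac.index[(bg_frac >= conservation_min) & focal_absent]

    kept: list[str] = []
    conservation: dict[str, float] = {}
    loss_counts: dict[str, int] = {}
    for fam in candidates:
        states = matrix.tip_states(fam)
        events = dollo_losses(tree, states, family_id=fam)
        # Dollo events are incomparable; the collapse is a no-op, asserted.
        n_indep = independent_loss_count(events, tree)
        assert n_indep == len(events), "Dollo events must be pairwise incomparable"
        if n_indep >= len(focal_sets):
            kept.append(fam)
            conservation[fam] = float(bg_frac[fam])
            loss_counts[fam] = n_indep

    stems = frozenset(tree.mrca(s) if len(s) > 1 else next(iter(s)) for s in focal_sets)
    return ConvergentModule(
        family_ids=frozenset(kept),
        focal_lineages=stems,
        background_conservation=conservation,
        n_independent_losses=loss_counts,
    )


def classify_absence(
    family_id: str,
    matrix: PresenceMatrix,
    focal_sets: Sequence[frozenset[str] | set[str]],
    relative_sets: Sequence[frozenset[str] | set[str]],
) -> str:
    """Classify a family's absence pattern relative to the focal lineages.

    ``focal_only``: absent from all focal genomes but present in at least
    one close relative of each focal lineage. ``focal_and_relatives``:
    absent from focal genomes and all their relatives. ``other``: anything
    else (including presence in a focal genome).
    """
    if len(relative_sets) != len(focal_sets):
        raise ValueError("one relative set is required per focal set")
    focal_sets = [frozenset(s) for s in focal_sets]
    relative_sets = [frozenset(s) for s in relative_sets]
    for f, r in zip(focal_sets, relative_sets):
        if f & r:
            raise ValueError(f"focal and relative sets overlap: {sorted(f & r)}")
    pres = matrix.presence[family_id]
    if any(pres[g] for s in focal_sets for g in s):
        return "other"
    per_focal_relative_presence = [
        any(pres[g] for g in rel) if rel else False for rel in relative_sets
    ]
    if all(per_focal_relative_presence):
        return "focal_only"
    if not any(pres[g] for rel in relative_sets for g in rel):
        return "focal_and_relatives"
    return "other"


def discover_focal_sets(
    matrix: PresenceMatrix,
    tree: Phylogeny,
    marker_families: Sequence[str] | frozenset[str],
    min_clade_size: int = 1,
) -> list[frozenset[str]]:
    """Maximal clades whose every genome lacks every marker family.

    Markers are e.g. the flagellar-category families; a returned clade is a
    candidate lineage that lost the marker trait. Results are maximal
    monophyletic tip sets; singletons are allowed at the default
    ``min_clade_size``.
    """
    markers = list(marker_families)
    if not markers:
        raise ValueError("marker_families must be non-empty")
    pres = matrix.presence[markers]
    lacks_all = (~pres).all(axis=1)
    lacking = set(lacks_all.index[lacks_all])

    below = tree.clade_map()
    found: list[frozenset[str]] = []

    stack = [tree.root]
    while stack:
        node = stack.pop()
        tips = below[node]
        if tips <= lacking:
            if len(tips) >= min_clade_size:
                found.append(tips)
        else:
            stack.extend(tree.children.get(node, ()))
    found.sort(key=lambda s: sorted(s)[0])
    return found
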