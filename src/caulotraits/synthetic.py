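"""Synthetic inputs with known ground truth for every downstream stage.

Three generators: (1) dimorphic/monomorphic division lineages with a
differentiation delay, division-site offset, imaging-interval quantization
and end-of-movie censoring; (2) random rooted trees carrying a gene
presence/absence matrix with a planted clade-restricted loss module over a
conserved background; (3) annotated genomes with a planted photosynthesis
gene cluster, optionally split across a contig edge or scattered.

Generation times are gamma-distributed with a given mean and CV (strictly
positive support, so no truncation artifacts); a CV of zero degenerates to
the deterministic mean. All generators are pure functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .convergent import ConvergentModule
from .lifecycle import LINEAGE_COLUMNS
from .matrix import KO_ONLY, PresenceMatrix
from .phototrophy import (
    ANNOTATION_COLUMNS,
    CBB_CLUSTER_GENES,
    GenomeAnnotation,
    PGC_CORE_ORDER,
)
from .trees import Phylogeny, random_coalescent_tree

__all__ = [
    "DimorphicParams",
    "PlantedLossSpec",
    "PlantedPGCSpec",
    "simulate_lineage",
    "simulate_loss_matrix",
    "simulate_annotated_genomes",
]


# ---------------------------------------------------------------------------
# lineages
# ---------------------------------------------------------------------------

@dataclass
class DimorphicParams:
    """Conditions of a simulated timelapse of a dimorphic (or monomorphic) strain.

    Times are minutes. ``swarmer_delay_mean = 0`` gives monomorphic timing;
    ``division_offset = 0`` gives mid-cell division. ``imaging_interval``
    quantizes all observed event times (0 or None = continuous recording).
    """

    stalked_gen_mean: float = 60.0
    stalked_gen_cv: float = 0.1
    swarmer_delay_mean: float = 30.0
    swarmer_delay_cv: float = 0.1
    division_offset: float = 0.07
    position_noise_sd: float = 0.02
    imaging_interval: float | None = 5.0
    duration: float = 600.0
    n_founders: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_founders < 1:
            raise ValueError("need at least one founder cell")
        if self.stalked_gen_mean <= 0:
            raise ValueError("stalked_gen_mean must be positive")
        if self.swarmer_delay_mean < 0 or self.stalked_gen_cv < 0 or self.swarmer_delay_cv < 0:
            raise ValueError("CVs and the swarmer delay must be non-negative")
        if not (0 <= self.division_offset < 0.5):
            raise ValueError("division_offset must lie in [0, 0.5)")
        if self.position_noise_sd < 0:
            raise ValueError("position_noise_sd must be non-negative")
        if self.division_offset + 3 * self.position_noise_sd >= 0.5:
            raise ValueError("division_offset + 3*position_noise_sd must stay below 0.5")
        if self.imaging_interval is not None and self.imaging_interval < 0:
            raise ValueError("imaging_interval must be non-negative")


def _gamma_draw(rng: np.random.Generator, mean: float, cv: float) -> float:
    if mean == 0:
        return 0.0
    if cv == 0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean / shape))


def simulate_lineage(params: DimorphicParams) -> pd.DataFrame:
    """Forest of tracked cells as a lineage table (one row per cell).

    Mechanism: every division yields one stalked-like daughter (next
    generation time drawn from the stalked distribution) and one
    swarmer-like daughter (the same draw plus a differentiation delay).
    The division site sits at 0.5 displaced by ``division_offset`` toward
    the cell's swarmer pole — the new pole it acquired at birth — plus
    Gaussian noise; the recorded position is in the cell's own unoriented
    frame, so offsets appear on either side of mid-cell. Event times are
    quantized to the imaging interval (first frame at or after the event);
    cells that have not divided by ``duration`` are emitted censored.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    interval = params.imaging_interval or 0.0

    def observe(t: float) -> float:
        if interval == 0:
            return t
        return math.ceil(round(t / interval, 9)) * interval

    rows: list[dict] = []
    # FIFO queue keeps draw order deterministic: (birth, role, parent, new_pole)
    from collections import deque

    queue: deque = deque()
    for i in range(params.n_founders):
        # founders enter as swarmer-like newborns with a random new pole
        new_pole = "right" if rng.random() < 0.5 else "left"
        queue.append((0.0, "swarmer", None, new_pole))

    counter = 0
    while queue:
        birth, role, parent, new_pole = queue.popleft()
        cell_id = f"c{counter:06d}"
        counter += 1
        gen = _gamma_draw(rng, params.stalked_gen_mean, params.stalked_gen_cv)
        if role == "swarmer":
            gen += _gamma_draw(rng, params.swarmer_delay_mean, params.swarmer_delay_cv)
        division = birth + gen
        obs_birth = observe(birth)
        obs_division = observe(division)
        censored = obs_division > params.duration
        if censored:
            rows.append(
                {
                    "cell_id": cell_id,
                    "parent_id": parent,
                    "birth_time_min": obs_birth,
                    "division_time_min": np.nan,
                    "censored": 1,
                    "division_position_fraction": np.nan,
                    "cell_length_um": np.nan,
                    "new_pole_side": new_pole,
                }
            )
            continue
        noise = params.position_noise_sd * rng.standard_normal() if params.position_noise_sd else 0.0
        toward = 1.0 if new_pole == "right" else -1.0
        position = 0.5 + toward * params.division_offset + noise
        position = float(min(max(position, 1e-6), 1 - 1e-6))
        length = float(2.5 * (1.0 + (0.05 * rng.standard_normal() if params.position_noise_sd else 0.0)))
        rows.append(
            {
                "cell_id": cell_id,
                "parent_id": parent,
                "birth_time_min": obs_birth,
                "division_time_min": obs_division,
                "censored": 0,
                "division_position_fraction": position,
                "cell_length_um": length,
                "new_pole_side": new_pole,
            }
        )
        # stalked daughter keeps the old pole; its new pole faces the site.
        stalked_pole = "left" if new_pole == "right" else "right"
        queue.append((division, "stalked", cell_id, new_pole))
        queue.append((division, "swarmer", cell_id, stalked_pole))
    table = pd.DataFrame(rows, columns=LINEAGE_COLUMNS)
    return table


# ---------------------------------------------------------------------------
# presence/absence matrices with planted convergent losses
# ---------------------------------------------------------------------------

@dataclass
class PlantedLossSpec:
    """Planted convergent-loss scenario over a random (or given) species tree."""

    n_tips: int = 200
    n_background_families: int = 2000
    background_conservation: float = 1.0
    sporadic_loss_rate: float = 0.0
    focal_clades: int = 2
    module_size: int = 26
    seed: int = 0
    clade_size_range: tuple[int, int | None] = (3, None)
    noise_on_module: bool = False

    def validate(self) -> None:
        if self.n_tips < 4:
            raise ValueError("need at least 4 tips")
        if not (0 < self.background_conservation <= 1):
            raise ValueError("background_conservation must be in (0, 1]")
        if not (0 <= self.sporadic_loss_rate < 1):
            raise ValueError("sporadic_loss_rate must be in [0, 1)")
        if self.focal_clades < 1:
            raise ValueError("need at least one focal clade")
        if self.module_size < 0 or self.n_background_families < 0:
            raise ValueError("family counts must be non-negative")


def _select_focal_clades(
    tree: Phylogeny, k: int, size_range: tuple[int, int | None], rng: np.random.Generator
) -> list[str] | None:
    lo, hi = size_range
    if hi is None:
        hi = max(lo, len(tree.tips) // 8)
    below = tree.clade_map()
    # Root children are excluded: losing such a clade is indistinguishable
    # from a later gain, so the planted loss would not be inferable. Sister
    # picks are excluded below for the same reason: two sister "losses"
    # collapse into one event on their shared stem.
    candidates = [
        n
        for n in tree.postorder()
        if lo <= len(below[n]) <= hi and n != tree.root and tree.parent[n] != tree.root
    ]
    rng.shuffle(candidates)
    chosen: list[str] = []
    for cand in candidates:
        disjoint = all(not (below[cand] & below[c]) for c in chosen)
        not_sibling = all(tree.parent[cand] != tree.parent[c] for c in chosen)
        if disjoint and not_sibling:
            chosen.append(cand)
            if len(chosen) == k:
                return sorted(chosen)
    return None


def simulate_loss_matrix(
    tree_or_params: Phylogeny | None,
    spec: PlantedLossSpec,
) -> tuple[Phylogeny, PresenceMatrix, ConvergentModule]:
    """Tree + presence matrix + planted module ground truth.

    Background families are present per tip with probability
    ``background_conservation`` and then flipped absent with
    ``sporadic_loss_rate``. Module families are present everywhere except
    in all tips of every focal clade (exactly, unless ``noise_on_module``
    asks for robustness-test noise on the module's background tips too).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if isinstance(tree_or_params, Phylogeny):
        tree = tree_or_params
        stems = _select_focal_clades(tree, spec.focal_clades, spec.clade_size_range, rng)
        if stems is None:
            raise ValueError("cannot select disjoint focal clades on the given tree")
    else:
        tree = None
        stems = None
        for _ in range(50):
            tree = random_coalescent_tree(spec.n_tips, rng)
            stems = _select_focal_clades(tree, spec.focal_clades, spec.clade_size_range, rng)
            if stems is not None:
                break
        if stems is None:
            raise ValueError("failed to generate a tree admitting the focal clades")

    below = tree.clade_map()
    tips = sorted(tree.tips)
    focal_tips = sorted(set().union(*(below[s] for s in stems)))
    focal_mask = np.array([t in set(focal_tips) for t in tips])

    n_bg = spec.n_background_families
    bg_names = [f"bg_{i:04d}" for i in range(n_bg)]
    mod_names = [f"mod_{i:03d}" for i in range(spec.module_size)]

    bg = rng.random((len(tips), n_bg)) < spec.background_conservation
    if spec.sporadic_loss_rate > 0:
        flips = rng.random((len(tips), n_bg)) < spec.sporadic_loss_rate
        bg = bg & ~flips

    mod = np.ones((len(tips), spec.module_size), dtype=bool)
    mod[focal_mask, :] = False
    if spec.noise_on_module and spec.module_size:
        keep = rng.random((len(tips), spec.module_size)) >= spec.sporadic_loss_rate
        mod[~focal_mask, :] &= keep[~focal_mask, :]

    presence = pd.DataFrame(
        np.hstack([mod, bg]), index=tips, columns=mod_names + bg_names
    )
    matrix = PresenceMatrix.from_presence(presence, code=KO_ONLY)
    truth = ConvergentModule(
        family_ids=frozenset(mod_names),
        focal_lineages=frozenset(stems),
        background_conservation={f: spec.background_conservation for f in mod_names},
        n_independent_losses={f: spec.focal_clades for f in mod_names},
    )
    return tree, matrix, truth


# ---------------------------------------------------------------------------
# annotated genomes with planted photosynthesis gene clusters
# ---------------------------------------------------------------------------

@dataclass
class PlantedPGCSpec:
    """Planted photosynthesis gene cluster scenario.

    ``pgc_gene_order`` is a list of (family, strand) pairs; the default is
    a canonical crt/bch/puf layout. An empty order plants nothing (pure
    background genomes). ``split_at`` breaks the cluster across two contigs
    after that many cluster genes; ``scatter`` keeps the gene content but
    destroys clustering.
    """

    n_genomes: int = 1
    genes_per_genome: int = 2000
    pgc_gene_order: Sequence[tuple[str, str]] = PGC_CORE_ORDER
    with_cbb: bool = False
    split_at: int | None = None
    scatter: bool = False
    seed: int = 0

    def effective_order(self) -> list[tuple[str, str]]:
        order = list(self.pgc_gene_order)
        if self.with_cbb and order:
            order += list(CBB_CLUSTER_GENES)
        return order

    def validate(self) -> None:
        if self.n_genomes < 1 or self.genes_per_genome < 1:
            raise ValueError("counts must be positive")
        order = self.effective_order()
        if self.split_at is not None:
            if not order:
                raise ValueError("split_at requires a planted cluster")
            if not (1 <= self.split_at <= len(order) - 1):
                raise ValueError(
                    f"split_at must fall inside the cluster (1..{len(order) - 1})"
                )


@dataclass
class PlantedClusterTruth:
    """Where the planted cluster ended up in one genome (None regions if scattered)."""

    genome_id: str
    regions: list[dict] = field(default_factory=list)  # contig_id, first/last gene_index, edge flag


def _gene_rows(genome: str, contig: str, families: list[tuple[str, str]]) -> list[dict]:
    rows = []
    for idx, (fam, strand) in enumerate(families):
        start = idx * 1000 + 50
        rows.append(
            {
                "genome_id": genome,
                "contig_id": contig,
                "gene_index": idx,
                "start": start,
                "end": start + 900,
                "strand": strand,
                "family_id": fam,
            }
        )
    return rows


def simulate_annotated_genomes(
    spec: PlantedPGCSpec,
) -> tuple[list[GenomeAnnotation], list[PlantedClusterTruth]]:
    """Annotated genomes with planted-cluster coordinates as ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    order = spec.effective_order()
    annotations: list[GenomeAnnotation] = []
    truths: list[PlantedClusterTruth] = []

    for g in range(spec.n_genomes):
        gid = f"G{g:03d}"
        n_bg = spec.genes_per_genome
        background = [
            (f"hk_{int(k):04d}", "+" if rng.random() < 0.5 else "-")
            for k in rng.integers(0, 3000, size=n_bg)
        ]
        truth = PlantedClusterTruth(genome_id=gid)

        if not order:
            rows = _gene_rows(gid, f"{gid}_c1", background)
        elif spec.scatter:
            genes = background + list(order)
            perm = rng.permutation(len(genes))
            rows = _gene_rows(gid, f"{gid}_c1", [genes[i] for i in perm])
        elif spec.split_at is not None:
            insert = int(rng.integers(0, n_bg + 1))
            left = background[:insert] + list(order[: spec.split_at])
            right = list(order[spec.split_at :]) + background[insert:]
            rows = _gene_rows(gid, f"{gid}_c1", left) + _gene_rows(gid, f"{gid}_c2", right)
            truth.regions = [
                {
                    "contig_id": f"{gid}_c1",
                    "first_index": len(left) - spec.split_at,
                    "last_index": len(left) - 1,
                    "at_contig_end": "right",
                },
                {
                    "contig_id": f"{gid}_c2",
                    "first_index": 0,
                    "last_index": len(order) - spec.split_at - 1,
                    "at_contig_end": "left",
                },
            ]
        else:
            insert = int(rng.integers(0, n_bg + 1))
            genes = background[:insert] + list(order) + background[insert:]
            rows = _gene_rows(gid, f"{gid}_c1", genes)
            truth.regions = [
                {
                    "contig_id": f"{gid}_c1",
                    "first_index": insert,
                    "last_index": insert + len(order) - 1,
                    "at_contig_end": None,
                }
            ]
        genes_df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
        annotations.append(GenomeAnnotation(genome_id=gid, genes=genes_df))
        truths.append(truth)
    return annotations, truths
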