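"""Genome × gene-family presence/absence matrices.

Presence evidence comes from two channels, mirroring how comparative
surveys annotate genomes: KEGG-ortholog (KO) assignments and reciprocal
best hits (RBH) against a reference proteome. Each matrix cell records
which channels support presence; presence itself is their union. Clade
aggregation averages binary presence into fractions for heatmap-style
summaries, and genome sizes are corrected for assembly incompleteness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "ABSENT",
    "KO_ONLY",
    "RBH_ONLY",
    "BOTH",
    "PresenceMatrix",
    "GenomeRecord",
    "rbh_pairs",
    "build_matrix",
    "aggregate_by_clade",
    "estimated_genome_size",
    "environment_summary",
    "load_family_defs",
]


def load_family_defs(path=None) -> dict[str, dict]:
    """Family definitions (KO ids, reference locus ids, category).

    With no path, the defaults shipped with the package are returned:
    flagellum/chemotaxis/T4P/holdfast marker families, developmental
    regulators, crescentin and S-layer genes, and photosynthesis families.
    """
    import json
    from pathlib import Path as _Path

    if path is None:
        path = _Path(__file__).parent / "data" / "family_defs.json"
    defs = json.loads(_Path(path).read_text())
    defs.pop("_comment", None)
    return defs

ABSENT, KO_ONLY, RBH_ONLY, BOTH = 0, 1, 2, 3

ENVIRONMENT_VOCABULARY = (
    "aquatic_freshwater",
    "aquatic_marine",
    "terrestrial",
    "host_plant",
    "host_animal",
    "engineered",
    "unclassified",
)


@dataclass
class PresenceMatrix:
    """Evidence-coded genome × family matrix.

    ``codes`` holds one of ``ABSENT/KO_ONLY/RBH_ONLY/BOTH`` per cell
    (rows = genomes, columns = families); ``presence`` collapses the codes
    to a boolean DataFrame (any evidence ⇒ present).
    """

    codes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.codes.index.duplicated().any():
            raise ValueError("duplicate genome ids")
        if self.codes.columns.duplicated().any():
            raise ValueError("duplicate family ids")
        vals = self.codes.to_numpy()
        if not np.isin(vals, [ABSENT, KO_ONLY, RBH_ONLY, BOTH]).all():
            raise ValueError("matrix cells must be evidence codes 0..3")

    @property
    def genome_ids(self) -> list[str]:
        return list(self.codes.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def presence(self) -> pd.DataFrame:
        return self.codes != ABSENT

    def tip_states(self, family_id: str) -> dict[str, int]:
        col = self.presence[family_id]
        return {g: int(v) for g, v in col.items()}

    @classmethod
    def from_presence(cls, presence: pd.DataFrame, code: int = KO_ONLY) -> "PresenceMatrix":
        return cls(presence.astype(int) * code)


@dataclass
class GenomeRecord:
    genome_id: str
    assembly_size: float
    completeness: float
    contamination: float = 0.0
    environment_category: str = "unclassified"
    genus: str | None = None
    family: str | None = None


def rbh_pairs(
    ab: pd.DataFrame, ba: pd.DataFrame, evalue_max: float = 1e-3
) -> set[tuple[str, str]]:
    """Reciprocal best hits from two directional hit tables.

    Each table needs columns ``query_id, subject_id, bitscore, e_value``.
    Hits with e-value above ``evalue_max`` are discarded first. The best hit
    of a query is the maximal bitscore, ties broken by minimal e-value then
    lexicographically smallest subject id, so the outcome is deterministic.
    A pair (a, b) is emitted iff b is a's best hit in ``ab`` and a is b's
    best hit in ``ba``.
    """
    required = {"query_id", "subject_id", "bitscore", "e_value"}
    for name, tbl in (("ab", ab), ("ba", ba)):
        missing = required - set(tbl.columns)
        if missing:
            raise ValueError(f"hit table {name} missing columns {sorted(missing)}")
        bad = tbl.index[~np.isfinite(tbl["bitscore"]) | (tbl["e_value"] < 0)]
        if len(bad):
            raise ValueError(f"malformed rows in table {name} at lines {list(bad)}")

    def best_hits(tbl: pd.DataFrame) -> dict[str, str]:
        kept = tbl[tbl["e_value"] <= evalue_max]
        if kept.empty:
            return {}
        ranked = kept.sort_values(
            ["query_id", "bitscore", "e_value", "subject_id"],
            ascending=[True, False, True, True],
            kind="mergesort",
        )
        return ranked.groupby("query_id", sort=False)["subject_id"].first().to_dict()

    fwd = best_hits(ab)
    rev = best_hits(ba)
    return {(a, b) for a, b in fwd.items() if rev.get(b) == a}


def build_matrix(
    ko_tables: Mapping[str, Iterable[str]],
    rbh_maps: Mapping[str, Iterable[str]],
    family_defs: Mapping[str, Mapping[str, Iterable[str]]],
) -> PresenceMatrix:
    """Evidence-coded matrix from per-genome KO sets and RBH reference hits.

    ``family_defs`` maps family id -> {"ko": [...ids...], "ref": [...ids...]};
    a family must define at least one id in either channel. A genome's cell
    is ``BOTH``/``KO_ONLY``/``RBH_ONLY``/``ABSENT`` according to which
    channels contain any of the family's ids. Multi-copy hits collapse to
    presence.
    """
    genomes = sorted(set(ko_tables) | set(rbh_maps))
    families = list(family_defs)
    for fam, defs in family_defs.items():
        kos = set(defs.get("ko", ()))
        refs = set(defs.get("ref", ()))
        if not kos and not refs:
            raise ValueError(f"family {fam!r} has no defining KO or reference ids")
    codes = np.zeros((len(genomes), len(families)), dtype=int)
    for i, g in enumerate(genomes):
        ko_set = set(ko_tables.get(g, ()))
        ref_set = set(rbh_maps.get(g, ()))
        for j, fam in enumerate(families):
            defs = family_defs[fam]
            has_ko = bool(ko_set & set(defs.get("ko", ())))
            has_ref = bool(ref_set & set(defs.get("ref", ())))
            codes[i, j] = (
                BOTH if has_ko and has_ref else KO_ONLY if has_ko else RBH_ONLY if has_ref else ABSENT
            )
    return PresenceMatrix(pd.DataFrame(codes, index=genomes, columns=families))


def aggregate_by_clade(
    matrix: PresenceMatrix, clade_map: Mapping[str, str]
) -> pd.DataFrame:
    """Average presence per clade: (clade × family) fractions in [0, 1]."""
    unmapped = [g for g in matrix.genome_ids if g not in clade_map]
    if unmapped:
        raise ValueError(f"genomes missing from clade map: {unmapped}")
    pres = matrix.presence.astype(float)
    clades = pd.Series({g: clade_map[g] for g in matrix.genome_ids}, name="clade")
    return pres.groupby(clades).mean()


def estimated_genome_size(record: GenomeRecord) -> float:
    """Assembly size divided by estimated completeness.

    Completeness is accepted either as a fraction in (0, 1] or as a percent
    in (1, 100] (auto-detected, with a warning); values outside both ranges
    are rejected.
    """
    c = record.completeness
    if c > 1.0:
        if c > 100.0:
            raise ValueError(f"completeness {c} out of range for {record.genome_id}")
        warnings.warn(
            f"completeness {c} for {record.genome_id} looks like a percent; dividing by 100",
            stacklevel=2,
        )
        c = c / 100.0
    if not (0.0 < c <= 1.0):
        raise ValueError(f"completeness must be in (0, 1], got {record.completeness}")
    return record.assembly_size / c


def environment_summary(
    records: Sequence[GenomeRecord],
    group_by: str = "family",
    vocabulary: Sequence[str] = ENVIRONMENT_VOCABULARY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-clade environment-category fractions and genome-size summaries.

    Returns ``(fractions, sizes)``: fractions is clade × category (rows sum
    to 1, categories outside the vocabulary mapped to "unclassified");
    sizes has one row per (clade, category) with n, median and quartiles of
    estimated genome size.
    """
    if not records:
        raise ValueError("no genome records supplied")
    rows = []
    for r in records:
        cat = r.environment_category if r.environment_category in vocabulary else "unclassified"
        clade = getattr(r, group_by, None) or "unassigned"
        rows.append(
            {
                "genome_id": r.genome_id,
                "clade": clade,
                "category": cat,
                "est_size": estimated_genome_size(r),
            }
        )
    df = pd.DataFrame(rows)
    counts = df.pivot_table(
        index="clade", columns="category", values="genome_id", aggfunc="count", fill_value=0
    )
    for cat in vocabulary:
        if cat not in counts.columns:
            counts[cat] = 0
    counts = counts[list(vocabulary)]
    fractions = counts.div(counts.sum(axis=1), axis=0)
    sizes = (
        df.groupby(["clade", "category"])["est_size"]
        .agg(n="count", median="median", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return fractions, sizes
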