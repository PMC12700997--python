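"""Readers/writers for the interchange formats and table validation.

All tabular interchange is TSV (UTF-8, '.' decimal, mandatory headers);
trees are Newick; gene coordinates are 0-based half-open. Writes are
atomic: content goes to a temporary file in the target directory which is
renamed into place, so a partial file never parses as complete.
"""

from __future__ import annotations

import hashlib
import os
import tempfile
import warnings
from contextlib import contextmanager
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .lifecycle import LINEAGE_COLUMNS, validate_lineage
from .matrix import PresenceMatrix
from .phototrophy import ANNOTATION_COLUMNS, GenomeAnnotation
from .trees import Phylogeny

__all__ = [
    "atomic_write",
    "sha256_file",
    "read_newick",
    "write_newick",
    "read_lineage",
    "write_lineage",
    "read_matrix",
    "write_matrix",
    "read_annotations",
    "write_annotations",
    "validate_tables",
]


@contextmanager
def atomic_write(path: str | Path) -> Iterator[Path]:
    """Yield a temporary path; on clean exit it is renamed onto *path*."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    tmp_path = Path(tmp)
    try:
        yield tmp_path
        os.replace(tmp_path, path)
    finally:
        if tmp_path.exists():
            tmp_path.unlink()


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ------------------------------------------------------------------- newick

def read_newick(path: str | Path) -> Phylogeny:
    """Rooted tree from a Newick file (duplicate tip labels rejected).

    A trifurcating root is accepted as a multifurcation with a warning.
    """
    tree = Phylogeny.from_newick(Path(path).read_text())
    if len(tree.children[tree.root]) > 2:
        warnings.warn(
            "root is multifurcating; treated as a rooted polytomy", stacklevel=2
        )
    return tree


def write_newick(tree: Phylogeny, path: str | Path) -> None:
    with atomic_write(path) as tmp:
        tmp.write_text(tree.to_newick() + "\n")


# ------------------------------------------------------------------ tables

def write_lineage(table: pd.DataFrame, path: str | Path) -> None:
    out = table[LINEAGE_COLUMNS].copy()
    with atomic_write(path) as tmp:
        out.to_csv(tmp, sep="\t", index=False, float_format="%.6g")


def read_lineage(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "parent_id": str})
    missing = set(LINEAGE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"lineage table missing columns {sorted(missing)}")
    return validate_lineage(table)


def write_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    with atomic_write(path) as tmp:
        matrix.codes.rename_axis("genome_id").to_csv(tmp, sep="\t")


def read_matrix(path: str | Path) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("matrix has duplicate genome ids")
    df.index.name = None
    df.columns.name = None
    return PresenceMatrix(df.astype(int))


def write_annotations(annotations: list[GenomeAnnotation], path: str | Path) -> None:
    frames = [ann.genes[ANNOTATION_COLUMNS] for ann in annotations]
    with atomic_write(path) as tmp:
        pd.concat(frames, ignore_index=True).to_csv(tmp, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[GenomeAnnotation]:
    df = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    return [
        GenomeAnnotation(genome_id=str(gid), genes=grp.reset_index(drop=True))
        for gid, grp in df.groupby("genome_id", sort=False)
    ]


# --------------------------------------------------------------- validation

def _check_lineage(path: Path) -> list[str]:
    errors: list[str] = []
    table = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "parent_id": str})
    missing = set(LINEAGE_COLUMNS) - set(table.columns)
    if missing:
        return [f"{path}: missing columns {sorted(missing)}"]
    dup = table.index[table["cell_id"].duplicated()]
    errors += [f"{path}:{i + 2}: duplicate cell_id" for i in dup]
    known = set(table["cell_id"])
    for i, pid in table["parent_id"].items():
        if pd.notna(pid) and pid not in known:
            errors.append(f"{path}:{i + 2}: unknown parent_id {pid!r}")
    divided = table[table["censored"] == 0]
    bad = divided.index[divided["division_time_min"] <= divided["birth_time_min"]]
    errors += [f"{path}:{i + 2}: division_time_min <= birth_time_min" for i in bad]
    return errors


def _check_matrix(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    errors = [
        f"{path}: duplicate genome id {g!r}"
        for g in df.index[df.index.duplicated()]
    ]
    if not np.isin(df.to_numpy(), [0, 1, 2, 3]).all():
        errors.append(f"{path}: matrix values must be evidence codes 0..3")
    return errors


def _check_hits(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    missing = {"query_id", "subject_id", "bitscore", "e_value"} - set(df.columns)
    if missing:
        return [f"{path}: missing columns {sorted(missing)}"]
    errors = [f"{path}:{i + 2}: negative e_value" for i in df.index[df["e_value"] < 0]]
    errors += [
        f"{path}:{i + 2}: non-finite bitscore"
        for i in df.index[~np.isfinite(df["bitscore"])]
    ]
    return errors


def _check_annotations(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        return [f"{path}: missing columns {sorted(missing)}"]
    errors = [
        f"{path}:{i + 2}: start >= end" for i in df.index[df["start"] >= df["end"]]
    ]
    return errors


SCHEMAS = {
    "lineage": _check_lineage,
    "matrix": _check_matrix,
    "hits": _check_hits,
    "annotations": _check_annotations,
}


def validate_tables(paths: dict[str, str | Path]) -> list[str]:
    """Validate each path against its declared schema kind.

    ``paths`` maps schema kind (lineage/matrix/hits/annotations) to a file.
    Returns a flat list of human-readable errors with 1-based file line
    numbers (header = line 1); empty list means all tables are well formed.
    """
    errors: list[str] = []
    for kind, path in paths.items():
        if kind not in SCHEMAS:
            raise KeyError(f"unknown schema kind {kind!r}")
        p = Path(path)
        if not p.exists():
            errors.append(f"{p}: file not found")
            continue
        try:
            errors.extend(SCHEMAS[kind](p))
        except Exception as exc:  # unparseable file is itself a finding
            errors.append(f"{p}: unreadable ({exc})")
    return errors
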