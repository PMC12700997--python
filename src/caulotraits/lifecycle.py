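"""Replicative-asymmetry statistics from tracked single-cell lineages.

The central quantity is the *degree of asymmetry* of a daughter-cell pair:
after a mother divides, her two daughters divide again after generation
times t1 <= t2; the degree is (t2 - t1) / t2, i.e. how much extra time the
late daughter needs as a fraction of its own generation time. Dimorphic
bacteria like Caulobacter crescentus show broad degree distributions and
bimodal generation times (swarmer daughters pay a differentiation delay);
monomorphic species cluster near zero and are unimodal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "AsymmetryRecord",
    "Histogram",
    "ModalityCall",
    "pair_asymmetry",
    "asymmetry_histogram",
    "generation_time_histogram",
    "classify_modality",
    "constriction_summary",
]

LINEAGE_COLUMNS = [
    "cell_id",
    "parent_id",
    "birth_time_min",
    "division_time_min",
    "censored",
    "division_position_fraction",
    "cell_length_um",
    "new_pole_side",
]


@dataclass(frozen=True)
class AsymmetryRecord:
    mother_id: str
    t1: float
    t2: float

    @property
    def delta_t(self) -> float:
        return self.t2 - self.t1

    @property
    def degree(self) -> float:
        return self.delta_t / self.t2


@dataclass
class Histogram:
    """Binned counts with an explicit right-hand overflow bin.

    Bins are half-open ``[lo, hi)``; values at or above
    ``overflow_threshold`` are pooled into ``overflow_count`` (the display
    convention for 'degrees above 50%' / 'generation times above 150 min').
    ``n_excluded`` counts inputs that never entered the histogram (censored
    cells etc.), so counts + overflow + exclusions add up to the input size.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    overflow_count: int = 0
    overflow_threshold: float | None = None
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return int(self.counts.sum()) + self.overflow_count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "count": self.counts,
            }
        )


@dataclass
class ModalityCall:
    n_components: int
    component_means: tuple[float, ...]
    component_weights: tuple[float, ...]
    peak_separation: float
    criterion_scores: dict[int, float]


def validate_lineage(table: pd.DataFrame) -> pd.DataFrame:
    """Check the lineage-table invariants; returns the table unchanged."""
    if table["cell_id"].duplicated().any():
        dup = table.loc[table["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell ids: {dup}")
    known = set(table["cell_id"])
    parents = table["parent_id"].dropna()
    unknown = set(parents) - known
    if unknown:
        raise ValueError(f"parent ids not present as cells: {sorted(unknown)}")
    divided = table[~table["censored"].astype(bool)]
    bad = divided[divided["division_time_min"] <= divided["birth_time_min"]]
    if len(bad):
        raise ValueError(
            f"division_time must exceed birth_time; offending cells {bad['cell_id'].tolist()}"
        )
    return table


def pair_asymmetry(
    table: pd.DataFrame,
) -> tuple[list[AsymmetryRecord], dict[str, int]]:
    """One asymmetry record per mother whose both daughters divided.

    Mothers with a censored daughter are excluded (counted under
    ``censored_pair``); mothers with a number of daughters other than two
    are malformed input and counted under ``malformed_mother``. The result
    is invariant to row order and daughter labeling (t1 <= t2 by sorting).
    """
    validate_lineage(table)
    records: list[AsymmetryRecord] = []
    exclusions = {"censored_pair": 0, "malformed_mother": 0}
    daughters = table[table["parent_id"].notna()]
    for mother, group in sorted(daughters.groupby("parent_id"), key=lambda kv: str(kv[0])):
        if len(group) != 2:
            exclusions["malformed_mother"] += 1
            continue
        if group["censored"].astype(bool).any():
            exclusions["censored_pair"] += 1
            continue
        gen = (group["division_time_min"] - group["birth_time_min"]).to_numpy(float)
        t1, t2 = np.sort(gen)
        records.append(AsymmetryRecord(mother_id=str(mother), t1=float(t1), t2=float(t2)))
    return records, exclusions


def _overflow_histogram(
    values: np.ndarray,
    bin_width: float,
    overflow_threshold: float,
    n_excluded: int,
) -> Histogram:
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(overflow_threshold / bin_width)) if overflow_threshold > 0 else 0
    edges = np.arange(n_bins + 1) * bin_width
    in_range = values[values < overflow_threshold]
    overflow = int((values >= overflow_threshold).sum())
    counts, _ = np.histogram(in_range, bins=edges) if n_bins else (np.zeros(0, int), edges)
    return Histogram(
        bin_edges=edges,
        counts=counts.astype(int),
        overflow_count=overflow,
        overflow_threshold=overflow_threshold,
        n_excluded=n_excluded,
    )


def asymmetry_histogram(
    records: Sequence[AsymmetryRecord],
    bin_width: float = 0.05,
    overflow_threshold: float = 0.5,
) -> Histogram:
    """Histogram of degrees of asymmetry with overflow above the threshold."""
    degrees = np.array([r.degree for r in records], dtype=float)
    return _overflow_histogram(degrees, bin_width, overflow_threshold, n_excluded=0)


def generation_time_histogram(
    table: pd.DataFrame,
    bin_width: float = 10.0,
    overflow_threshold: float = 150.0,
) -> Histogram:
    """Histogram of single-cell generation times (censored cells excluded).

    The overflow convention follows the display: e.g. 150 min for fast
    growers, or 1200 min (20 h) for slow ones.
    """
    validate_lineage(table)
    censored = table["censored"].astype(bool)
    times = (
        table.loc[~censored, "division_time_min"] - table.loc[~censored, "birth_time_min"]
    ).to_numpy(float)
    return _overflow_histogram(
        times, bin_width, overflow_threshold, n_excluded=int(censored.sum())
    )


def _icl(gm: GaussianMixture, x: np.ndarray) -> float:
    tau = gm.predict_proba(x)
    entropy = -float(np.sum(tau * np.log(np.clip(tau, 1e-300, None))))
    return float(gm.bic(x)) + 2.0 * entropy


def classify_modality(
    times: Sequence[float],
    min_n: int = 50,
    n_restarts: int = 3,
    seed: int = 0,
) -> ModalityCall:
    """Unimodal-vs-bimodal call for a generation-time sample.

    Fits 1- and 2-component Gaussian mixtures by EM with multiple restarts
    and selects by ICL (BIC plus twice the assignment entropy), which
    penalizes heavily overlapping two-component solutions and so does not
    mistake the mild right skew of single-population generation times for
    bimodality. ``peak_separation`` is |mu2 - mu1| when two components are
    selected, else 0.
    """
    x = np.asarray(times, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} finite values, got {len(x)}")
    if np.ptp(x) == 0:  # degenerate: a point mass is unimodal by definition
        return ModalityCall(1, (float(x[0]),), (1.0,), 0.0, {1: float("-inf"), 2: float("inf")})
    X = x.reshape(-1, 1)
    scores: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in (1, 2):
        gm = GaussianMixture(
            n_components=k, n_init=n_restarts, random_state=seed, reg_covar=1e-6
        )
        gm.fit(X)
        scores[k] = _icl(gm, X)
        fits[k] = gm
    k_best = 1 if scores[1] <= scores[2] else 2
    gm = fits[k_best]
    order = np.argsort(gm.means_.ravel())
    means = tuple(float(m) for m in gm.means_.ravel()[order])
    weights = tuple(float(w) for w in gm.weights_.ravel()[order])
    sep = float(means[1] - means[0]) if k_best == 2 else 0.0
    return ModalityCall(k_best, means, weights, sep, scores)


def constriction_summary(
    table: pd.DataFrame,
    n_bins: int = 100,
    midcell_halfwidth: float = 0.05,
    seed: int = 0,
) -> tuple[Histogram, float, float]:
    """Division-site position display and mid-cell statistics.

    Positions are pole-unoriented: each value x is replaced by x or 1-x
    with equal probability (seeded), mirroring displays where constriction
    positions are not sorted by cell polarity, so the null is symmetric
    about 0.5. Returns the 100-bin histogram of randomized positions, the
    fraction of cells constricting within ``midcell_halfwidth`` of mid-cell
    (computed from the raw, orientation-free values min(x, 1-x)), and the
    p-value of a two-sample KS test of {x} vs {1-x}.
    """
    pos = table["division_position_fraction"].dropna().to_numpy(float)
    bad = table.loc[
        table["division_position_fraction"].notna()
        & ~table["division_position_fraction"].between(0, 1, inclusive="neither"),
        "cell_id",
    ]
    if len(bad):
        raise ValueError(f"division positions outside (0,1) for cells {bad.tolist()}")
    rng = np.random.default_rng(seed)
    flip = rng.random(len(pos)) < 0.5
    randomized = np.where(flip, 1.0 - pos, pos)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(randomized, bins=edges)
    hist = Histogram(bin_edges=edges, counts=counts.astype(int))
    midcell = float(np.mean(np.minimum(pos, 1.0 - pos) >= 0.5 - midcell_halfwidth)) if len(pos) else float("nan")
    if len(pos):
        symmetry_p = float(stats.ks_2samp(randomized, 1.0 - randomized).pvalue)
    else:
        symmetry_p = float("nan")
    return hist, midcell, symmetry_p
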