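"""Succession-pattern analysis of abundance matrices.

Mirrors the heatmap workflow for time-resolved MAG abundances: each row
(taxon) is Z-score normalized, rows are clustered by average linkage on a
1 - Spearman rank-correlation distance, and each taxon's epilimnion +
hypolimnion trajectory is assigned to one of four succession archetypes:

  A  generalists: abundant at both the start and the end of the window;
  B  cold-adapted: epilimnion-high early, transitioning to the hypolimnion;
  C  warm-adapted: monotone rise peaking in the clear-water phase;
  D  bloom specialists: short-lived epilimnion spikes.

The categories are verbal in origin; the rule set here operationalizes
them with explicit thresholds on Z-scored levels (theta_high = +0.5,
theta_low = 0, peak prominence theta_peak = 1.5) and window definitions,
all configurable.  Precedence D > B > C > A: sharper patterns win.

Concordance between observation channels (metagenomic vs CARD-FISH) is a
Pearson correlation on day-matched pairs (Spearman available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.signal import find_peaks, peak_widths
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, rankdata, spearmanr

__all__ = [
    "Thresholds",
    "Windows",
    "PatternCall",
    "zscore_rows",
    "spearman_distance",
    "cluster_rows",
    "ClusterResult",
    "linkage_to_newick",
    "is_monophyletic",
    "classify_pattern",
    "concordance",
]


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z score (sample SD, n-1).  Constant rows map to all zeros."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least two columns per row")
    values = matrix.to_numpy(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    out = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def spearman_distance(matrix: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Pairwise 1 - Spearman rho between rows (square matrix).

    Rank ties get mean ranks.  Rows with zero rank variance (constant)
    have undefined rho; they are assigned distance 1 to every other row
    and returned in the flagged list.
    """
    values = matrix.to_numpy(float)
    ranks = np.apply_along_axis(rankdata, 1, values)
    sd = ranks.std(axis=1, ddof=1)
    flat = sd == 0
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.where(flat, 1.0, np.sqrt((centered**2).sum(axis=1)))
    unit = centered / norm[:, None]
    rho = unit @ unit.T
    dist = 1.0 - rho
    dist[flat, :] = 1.0
    dist[:, flat] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    flagged = [matrix.index[i] for i in np.where(flat)[0]]
    return dist, flagged


@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaf_order: list
    labels: list
    flagged_constant: list

    @property
    def newick(self) -> str:
        return linkage_to_newick(self.linkage, self.labels)


def cluster_rows(matrix: pd.DataFrame) -> ClusterResult:
    """Average-linkage (UPGMA) clustering under 1 - Spearman distance."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least two rows")
    dist, flagged = spearman_distance(matrix)
    # squareform requires exact symmetry; rho computation is symmetric up
    # to float rounding.
    dist = (dist + dist.T) / 2.0
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [matrix.index[i] for i in hierarchy.leaves_list(z)]
    return ClusterResult(z, order, list(matrix.index), flagged)


def linkage_to_newick(z: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(z)

    def walk(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def is_monophyletic(result: ClusterResult, members) -> bool:
    """True if ``members`` form an exact cluster (clade) of the dendrogram."""
    want = {result.labels.index(m) for m in members}
    if len(want) <= 1:
        return True
    n = len(result.labels)
    clusters = {i: {i} for i in range(n)}
    for k, (a, b, _, _) in enumerate(result.linkage):
        merged = clusters[int(a)] | clusters[int(b)]
        if merged == want:
            return True
        clusters[n + k] = merged
    return False


@dataclass(frozen=True)
class Thresholds:
    theta_high: float = 0.5  # Z level counted as "abundant"
    theta_low: float = 0.0  # Z level counted as "not abundant"
    theta_peak: float = 1.5  # minimum peak prominence, Z units
    max_peak_width: float = 2.0  # sampling intervals


@dataclass(frozen=True)
class Windows:
    """Study-phase day windows: mixis, bloom, clear-water, late hypolimnion."""

    start: tuple[float, float] = (1, 4)
    bloom: tuple[float, float] = (7, 18)
    clear: tuple[float, float] = (30, 37)
    late_hypo_from: float = 21


@dataclass
class PatternCall:
    taxon_id: str
    category: str  # A | B | C | D | unclassified
    features: dict = field(default_factory=dict)
    reason: str = ""


def _zscore_series(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1) if len(values) > 1 else 0.0
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / sd


def _window_mean(days, z, lo, hi):
    mask = (days >= lo) & (days <= hi)
    return float(z[mask].mean()) if mask.any() else None


def classify_pattern(
    epi: pd.Series,
    hypo: pd.Series,
    thresholds: Thresholds = Thresholds(),
    windows: Windows = Windows(),
    taxon_id: str = "",
) -> PatternCall:
    """Rule-based archetype assignment for one taxon.

    ``epi`` and ``hypo`` are abundance series indexed by sampling day.
    Features are computed on per-depth Z-scored values; see module
    docstring for the rules and precedence.
    """
    epi = epi.sort_index()
    hypo = hypo.sort_index()
    days = epi.index.to_numpy(float)
    z_epi = _zscore_series(epi.to_numpy(float))
    z_hypo = _zscore_series(hypo.to_numpy(float))
    hypo_days = hypo.index.to_numpy(float)

    start = _window_mean(days, z_epi, *windows.start)
    end = _window_mean(days, z_epi, *windows.clear)
    bloom_ok = _window_mean(days, z_epi, *windows.bloom) is not None
    late_mask = hypo_days >= windows.late_hypo_from
    late_hypo = float(z_hypo[late_mask].mean()) if late_mask.any() else None
    if start is None or end is None or not bloom_ok or late_hypo is None:
        return PatternCall(taxon_id, "unclassified", {}, "missing window coverage")

    peaks, props = find_peaks(z_epi, prominence=thresholds.theta_peak)
    narrow = 0
    widths = []
    if len(peaks):
        widths = peak_widths(z_epi, peaks, rel_height=0.5)[0]
        narrow = int(np.sum(widths <= thresholds.max_peak_width))
    if np.all(z_epi == 0):
        return PatternCall(taxon_id, "unclassified", {}, "flat series")

    trend = spearmanr(days, z_epi).statistic if len(days) > 2 else 0.0
    features = {
        "start_epi_level": start,
        "end_epi_level": end,
        "late_hypo_level": late_hypo,
        "peak_count": int(len(peaks)),
        "narrow_peak_count": narrow,
        "peak_widths": [float(w) for w in widths],
        "peak_prominence": float(props["prominences"].max()) if len(peaks) else 0.0,
        "trend": float(trend),
    }

    th, tl = thresholds.theta_high, thresholds.theta_low
    if narrow >= 1 and late_hypo < tl:
        cat = "D"
    elif start >= th and late_hypo >= th and end < tl:
        cat = "B"
    elif end >= th and trend > 0 and late_hypo < tl:
        cat = "C"
    elif start >= th and end >= th:
        cat = "A"
    else:
        cat = "unclassified"
    return PatternCall(taxon_id, cat, features, "" if cat != "unclassified" else "no rule matched")


def matrix_from_long(frame: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Pivot a long abundance table to rows = taxa, columns = (depth, day).

    Columns are ordered chronologically within each depth, epilimnion first.
    """
    wide = frame.pivot_table(index="taxon_id", columns=["depth", "day"], values=value_col)
    wide = wide.sort_index(axis=1)
    wide.columns = [f"{depth}_d{int(day):02d}" for depth, day in wide.columns]
    return wide


def pattern_calls_from_long(
    frame: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    windows: Windows = Windows(),
) -> dict[str, PatternCall]:
    """Classify every taxon of a long abundance table (needs both depths)."""
    calls = {}
    for taxon in sorted(frame.taxon_id.unique()):
        epi = frame[(frame.taxon_id == taxon) & (frame.depth == "epi")].set_index("day").value
        hypo = frame[(frame.taxon_id == taxon) & (frame.depth == "hypo")].set_index("day").value
        calls[taxon] = classify_pattern(epi, hypo, thresholds, windows, taxon_id=taxon)
    return calls


@dataclass
class Concordance:
    r: float
    method: str
    paired: pd.DataFrame
    dropped_days: list
    flagged: str = ""


def concordance(a: pd.Series, b: pd.Series, method: str = "pearson") -> Concordance:
    """Correlation between two observers of the same taxon on matched days."""
    common = a.index.intersection(b.index)
    dropped = sorted(set(a.index).symmetric_difference(b.index))
    if len(common) < 3:
        raise ValueError("need at least three matched sampling days")
    x = a.loc[common].to_numpy(float)
    y = b.loc[common].to_numpy(float)
    paired = pd.DataFrame({"day": common, "a": x, "b": y})
    if x.std() == 0 or y.std() == 0:
        return Concordance(float("nan"), method, paired, dropped, "zero variance")
    if method == "pearson":
        r = float(pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return Concordance(r, method, paired, dropped)
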