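"""Two-stage clustering of predictor-target patterns and Cohen's-d profiling.

Participants are clustered on their standardized predictor columns plus the
saturated wave's (re-standardized) index estimate.  Stage one grows a Ward
tree on Euclidean distances and picks the number of clusters by the largest
relative jump in merge heights within ``k_range``; stage two refines the cut
with k-means seeded from the Ward centroids.  Clusters are then ordered by
mean health behavior index (high -> very low engagement) and every study
variable is profiled per cluster with Cohen's d against all other clusters
combined; a variable is *salient* for a cluster when ``|d| >= 0.50``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .data import PredictorBlocks, StandardizedDataset
from .network import WaveResult

logger = logging.getLogger(__name__)

ENGAGEMENT_VOCAB = ("high", "moderate", "low", "very_low")
SALIENCE_THRESHOLD = 0.50

FEATURE_MODES = ("predictors_plus_estimate", "predictors_only", "hidden_activations")


def cohens_d(group_values, rest_values) -> float:
    """Pooled-SD Cohen's d, positive when the group mean exceeds the rest.

    ``d = (mean_g - mean_r) / s_p`` with
    ``s_p = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2))``.
    A zero pooled SD yields 0 for equal means and signed infinity otherwise.
    """
    a = np.asarray(group_values, dtype=float)
    b = np.asarray(rest_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("cohens_d needs at least two values per side")
    diff = a.mean() - b.mean()
    pooled = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2))
    if pooled == 0:
        return 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
    return float(diff / pooled)


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------


def build_cluster_matrix(
    blocks: PredictorBlocks,
    saturated: WaveResult | None = None,
    feature_mode: str = "predictors_plus_estimate",
) -> pd.DataFrame:
    """Participant feature matrix for clustering; every column re-standardized."""
    if feature_mode not in FEATURE_MODES:
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    base = blocks.saturated()
    if feature_mode == "predictors_only":
        out = base.copy()
    elif feature_mode == "predictors_plus_estimate":
        if saturated is None:
            raise ValueError("predictors_plus_estimate requires the saturated wave")
        out = base.copy()
        out["saturated_estimate"] = np.asarray(saturated.estimates, dtype=float)
    else:  # hidden_activations
        if saturated is None or saturated.model is None:
            raise ValueError("hidden_activations requires the saturated wave's fitted model")
        acts = saturated.model.hidden_activations(base)
        out = pd.DataFrame(acts, columns=[f"hidden_{i}" for i in range(acts.shape[1])])
    arr = out.to_numpy(dtype=float)
    sd = arr.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - arr.mean(axis=0)) / sd, columns=out.columns)


# ---------------------------------------------------------------------------
# two-stage clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterSolution:
    assignments: np.ndarray
    k: int
    group_sizes: tuple[int, ...]
    centroids: np.ndarray
    engagement_order: tuple[int, ...] | None = None  # raw group index per rank
    engagement_labels: dict[int, str] = field(default_factory=dict)
    engagement_d: dict[int, float] = field(default_factory=dict)

    def label_of(self, group: int) -> str:
        return self.engagement_labels.get(group, f"group_{group}")


class TwoStageClusterer(ClusterMixin, BaseEstimator):
    """Ward tree for choosing k, k-means for refining the partition.

    ``k`` is the value in ``k_range`` maximizing the relative jump between
    the merge height that destroys k clusters and the previous merge height
    (``k_override`` skips selection).  Groups are relabeled by descending size
    for stable output.  With a named feature frame, columns are sorted before
    clustering so results are invariant to column order.
    """

    def __init__(
        self,
        k_range: tuple[int, int] = (2, 8),
        k_override: int | None = None,
        refine_with_kmeans: bool = True,
        min_cluster_size: int = 1,
        random_state: int = 0,
    ):
        self.k_range = k_range
        self.k_override = k_override
        self.refine_with_kmeans = refine_with_kmeans
        self.min_cluster_size = min_cluster_size
        self.random_state = random_state

    @staticmethod
    def _normalized_heights(Z: np.ndarray, n: int) -> np.ndarray:
        """Ward merge heights divided by the size factor sqrt(2 n1 n2/(n1+n2)).

        The raw Ward height scales with the sizes of the merged clusters, so a
        small-but-distant cluster (the kind the analysis wants to retain) can
        never produce a top-level jump.  Dividing by the size factor turns each
        height into the between-centroid separation of the merged pair, which
        puts merges of unequal-size clusters on a common scale.

        Centroids of small clusters are noisy: in d dimensions a pure-noise
        Ward merge has squared height ~ 2*sigma^2*d independent of the sizes,
        so the median squared height estimates that noise constant.  It is
        subtracted (with a small ridge to keep ratios finite) before the size
        normalization, which de-inflates chance separations of tiny clumps.
        """
        sizes = np.ones(2 * n - 1)
        sizes[n:] = Z[:, 3]
        n1 = sizes[Z[:, 0].astype(int)]
        n2 = sizes[Z[:, 1].astype(int)]
        factor_sq = 2.0 * n1 * n2 / (n1 + n2)
        h_sq = Z[:, 2] ** 2
        noise = float(np.median(h_sq))
        return np.sqrt((np.maximum(h_sq - noise, 0.0) + 0.05 * noise) / factor_sq)

    def _select_k(self, Z: np.ndarray, n: int) -> int:
        lo, hi = self.k_range
        hi = min(hi, n - 1)
        if self.k_override is not None:
            if not (lo <= self.k_override <= self.k_range[1]):
                raise ValueError(f"k_override {self.k_override} outside k_range {self.k_range}")
            return self.k_override
        heights = Z[:, 2]
        if heights[-1] <= 1e-12:  # all rows identical
            warnings.warn("all rows identical; returning a single cluster")
            return 1
        norm = self._normalized_heights(Z, n)
        sizes = np.ones(2 * n - 1)
        sizes[n:] = Z[:, 3]
        smaller = np.minimum(sizes[Z[:, 0].astype(int)], sizes[Z[:, 1].astype(int)])
        # merges that split off only a trace clump (< 2% of the sample, and
        # never the paper-scale minority cluster) carry no evidence about k
        floor = max(2.0, np.ceil(0.02 * n))
        eligible = smaller >= floor
        best_k, best_ratio = lo, -np.inf
        for k in range(lo, hi + 1):
            i_break = n - k  # merge reducing k clusters to k-1
            if not eligible[i_break]:
                continue
            prev = [j for j in range(i_break - 1, -1, -1) if eligible[j]]
            h_prev = norm[prev[0]] if prev else 0.0
            ratio = np.inf if h_prev <= 1e-12 else norm[i_break] / h_prev
            if ratio > best_ratio:
                best_k, best_ratio = k, ratio
        return best_k

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            Xc = X[sorted(X.columns.astype(str))].to_numpy(dtype=float)
        else:
            Xc = np.asarray(X, dtype=float)
        n = Xc.shape[0]
        if n < 2:
            raise ValueError("need at least two rows to cluster")
        Z = linkage(Xc, method="ward")
        k = self._select_k(Z, n)
        if k == 1:
            labels = np.zeros(n, dtype=int)
        else:
            labels = fcluster(Z, t=k, criterion="maxclust") - 1
            if self.refine_with_kmeans:
                centroids = np.vstack([Xc[labels == g].mean(axis=0) for g in range(k)])
                km = KMeans(n_clusters=k, init=centroids, n_init=1, random_state=self.random_state)
                labels = km.fit_predict(Xc)
        # stable relabeling by descending size (ties: first occurrence)
        sizes = np.bincount(labels, minlength=k)
        order = sorted(range(k), key=lambda g: (-sizes[g], np.argmax(labels == g) if sizes[g] else n))
        remap = {old: new for new, old in enumerate(order)}
        labels = np.asarray([remap[v] for v in labels])
        sizes = np.bincount(labels, minlength=k)
        if sizes.min() < self.min_cluster_size:
            warnings.warn(f"cluster sizes {sizes.tolist()} below min_cluster_size={self.min_cluster_size}")
        self.labels_ = labels
        self.k_ = k
        self.linkage_ = Z
        self.cluster_centers_ = np.vstack([Xc[labels == g].mean(axis=0) for g in range(k)])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def solution(self) -> ClusterSolution:
        sizes = tuple(int(c) for c in np.bincount(self.labels_, minlength=self.k_))
        return ClusterSolution(self.labels_.copy(), self.k_, sizes, self.cluster_centers_.copy())


def two_stage_cluster(X, **params) -> ClusterSolution:
    """Functional wrapper over :class:`TwoStageClusterer`."""
    est = TwoStageClusterer(**params).fit(X)
    return est.solution()


# ---------------------------------------------------------------------------
# engagement ordering and salience
# ---------------------------------------------------------------------------


def engagement_ordering(solution: ClusterSolution, health_index) -> ClusterSolution:
    """Rank clusters by mean health index; label and compute group-vs-rest d."""
    y = np.asarray(health_index, dtype=float).ravel()
    k = solution.k
    if k == 1:
        return replace(solution, engagement_order=(0,), engagement_labels={0: "all"}, engagement_d={})
    means = np.asarray([y[solution.assignments == g].mean() for g in range(k)])
    sizes = np.asarray(solution.group_sizes)
    tied = len(np.unique(np.round(means, 12))) < k
    if tied:
        logger.warning("tied engagement means; breaking ties by group size")
    order = sorted(range(k), key=lambda g: (-means[g], -sizes[g]))
    if k == 2:
        vocab = ("high", "low")
    elif k == 3:
        vocab = ("high", "moderate", "low")
    else:
        vocab = ENGAGEMENT_VOCAB
    labels = {}
    d_vals = {}
    for rank, g in enumerate(order):
        labels[g] = vocab[rank] if rank < len(vocab) else f"level_{rank + 1}"
        mask = solution.assignments == g
        if mask.sum() >= 2 and (~mask).sum() >= 2:
            d_vals[g] = cohens_d(y[mask], y[~mask])
        else:
            warnings.warn(f"group {g} too small for an engagement effect size")
            d_vals[g] = float("nan")
    return replace(solution, engagement_order=tuple(order), engagement_labels=labels, engagement_d=d_vals)


@dataclass
class SalienceProfile:
    """Groups x variables Cohen's-d matrix with the salience mask applied."""

    d: pd.DataFrame  # index: variables; columns: group labels in engagement order
    salient: pd.DataFrame  # boolean, |d| >= threshold
    threshold: float
    group_sizes: dict[str, int]

    def to_json_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "group_sizes": self.group_sizes,
            "d": {col: self.d[col].round(6).to_dict() for col in self.d.columns},
            "salient": {col: self.salient[col].to_dict() for col in self.salient.columns},
        }


def salience_profile(
    solution: ClusterSolution,
    std: StandardizedDataset,
    blocks: PredictorBlocks,
    threshold: float = SALIENCE_THRESHOLD,
) -> SalienceProfile:
    """Cohen's d of every predictor variable, each group vs the rest combined."""
    if solution.k < 2:
        raise ValueError("salience profiling needs at least two groups")
    if solution.engagement_order is None:
        solution = engagement_ordering(solution, std.health_index)
    variables = blocks.saturated()
    if len(variables) != len(solution.assignments):
        raise ValueError("solution and dataset participant counts differ")
    cols = {}
    sizes = {}
    for g in solution.engagement_order:
        label = solution.label_of(g)
        mask = solution.assignments == g
        sizes[label] = int(mask.sum())
        if mask.sum() < 2:
            warnings.warn(f"group {label!r} has fewer than 2 members; d undefined")
            cols[label] = pd.Series(np.nan, index=variables.columns)
            continue
        vals = {}
        for var in variables.columns:
            v = variables[var].to_numpy()
            vals[var] = cohens_d(v[mask], v[~mask])
        cols[label] = pd.Series(vals)
    d = pd.DataFrame(cols)
    return SalienceProfile(d=d, salient=d.abs() >= threshold, threshold=threshold, group_sizes=sizes)


def render_salience_table(profile: SalienceProfile, full: bool = False) -> str:
    """TSV with groups as columns; sub-threshold cells blank unless ``full``."""
    header = ["variable"] + [f"{c} (n={profile.group_sizes[c]})" for c in profile.d.columns]
    lines = ["\t".join(header)]
    for var in profile.d.index:
        cells = [var]
        for col in profile.d.columns:
            v = profile.d.loc[var, col]
            show = full or bool(profile.salient.loc[var, col])
            cells.append(f"{v:.2f}" if show and np.isfinite(v) else ("nan" if show else ""))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
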