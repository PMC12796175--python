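"""Non-parametric normative SPM outlier detection.

A test map, registered to its side's template, is compared pixel-wise
against a normative cohort of registered valid maps: each pixel gets a
two-tailed empirical (rank) p-value.  Contiguous suprathreshold pixels
(p < alpha_forming) form candidate clusters; clusters below a minimum
size are discarded.  Family-wise error over the 4096 simultaneous tests
is controlled at cluster level: a permutation null of maximum surviving
cluster sizes is built by repeatedly treating one cohort member as a
pseudo-test sample against the remaining members (leave-one-out), and
only candidate clusters strictly exceeding the (1 - alpha_fwe) nearest
-rank percentile of that null are significant.  A map is flagged as an
outlier when at least one significant cluster remains.

Background pixels (zero everywhere in the cohort) are tested like any
other pixel — that is what lets off-footprint pressure (double-foot,
inverted maps) form suprathreshold clusters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dataio import Dataset
from .metrics import binary_f1
from .types import GRID_SIZE, LABEL_VALID, Side


@dataclass
class SPMConfig:
    alpha_forming: float = 0.05   # cluster-forming (uncorrected) threshold
    min_cluster: int = 0          # minimum cluster size in px
    n_permutations: int = 1000
    alpha_fwe: float = 0.05
    connectivity: int = 8         # 4 or 8 neighbourhood

    def __post_init__(self) -> None:
        if not 0 < self.alpha_forming < 1:
            raise ValueError("alpha_forming must be in (0, 1)")
        if self.min_cluster < 0:
            raise ValueError("min_cluster must be >= 0")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def structure(self) -> np.ndarray:
        if self.connectivity == 8:
            return np.ones((3, 3), dtype=bool)
        return ndimage.generate_binary_structure(2, 1)


@dataclass
class NormativeModel:
    """Per-side stack of registered valid maps (the reference cohort)."""

    side: Side
    stack: np.ndarray            # (n, 64, 64)

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=np.float64)
        if self.stack.ndim != 3 or self.stack.shape[1:] != (GRID_SIZE, GRID_SIZE):
            raise ValueError("stack must have shape (n, 64, 64)")
        if len(self.stack) < 1:
            raise ValueError("empty normative cohort")
        self.side = Side(self.side)

    @property
    def n(self) -> int:
        return len(self.stack)

    @classmethod
    def from_dataset(cls, ds: Dataset, side: Side) -> "NormativeModel":
        side = Side(side)
        mask = ((ds.manifest["label"].astype(int) == LABEL_VALID)
                & (ds.manifest["side"] == side.value)).to_numpy()
        if not mask.any():
            raise ValueError(f"no valid samples of side {side.value}")
        return cls(side=side, stack=ds.grids[mask])


@dataclass
class Cluster:
    pixels: frozenset
    size: int


@dataclass
class SPMDecision:
    pmap: np.ndarray
    clusters: list          # candidate clusters (after min_cluster filter)
    fwe_threshold: int
    significant: list
    is_outlier: bool


# ---------------------------------------------------------------------
# p-values
# ---------------------------------------------------------------------
def pixel_pvalue(t: float, cohort_values) -> float:
    """Two-tailed empirical p-value of one intensity against a cohort.

    Ties count on both tails and the test value itself is included
    (add-one correction), so p is always in (0, 1]:
    ``p = min(1, 2 * min((1 + #{x >= t}), (1 + #{x <= t})) / (n + 1))``.
    """
    x = np.asarray(cohort_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty cohort")
    n = x.size
    p_high = (1 + np.count_nonzero(x >= t)) / (n + 1)
    p_low = (1 + np.count_nonzero(x <= t)) / (n + 1)
    return min(1.0, 2.0 * min(p_high, p_low))


def compute_pmap(grid: np.ndarray, model: NormativeModel) -> np.ndarray:
    """Element-wise two-tailed empirical p-values over all 4096 pixels."""
    return _pmap_against(np.asarray(grid, dtype=np.float64), model.stack)


def _pmap_against(grid: np.ndarray, stack: np.ndarray) -> np.ndarray:
    n = len(stack)
    ge = np.count_nonzero(stack >= grid[None], axis=0)
    le = np.count_nonzero(stack <= grid[None], axis=0)
    p = 2.0 * (1 + np.minimum(ge, le)) / (n + 1)
    return np.minimum(p, 1.0)


# ---------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------
def find_clusters(pmap: np.ndarray, alpha_forming: float, min_cluster: int,
                  connectivity: int = 8) -> list[Cluster]:
    """Connected components of {p < alpha_forming}, dropping those
    smaller than ``min_cluster``."""
    structure = (np.ones((3, 3), dtype=bool) if connectivity == 8
                 else ndimage.generate_binary_structure(2, 1))
    labelled, n = ndimage.label(np.asarray(pmap) < alpha_forming,
                                structure=structure)
    clusters = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labelled == lab)
        if len(coords) >= max(min_cluster, 1):
            clusters.append(Cluster(
                pixels=frozenset(map(tuple, coords)), size=len(coords)))
    return clusters


def _max_surviving_size(pmap: np.ndarray, config: SPMConfig) -> int:
    labelled, n = ndimage.label(pmap < config.alpha_forming,
                                structure=config.structure)
    if n == 0:
        return 0
    sizes = np.bincount(labelled.ravel())[1:]
    sizes = sizes[sizes >= max(config.min_cluster, 1)]
    return int(sizes.max()) if sizes.size else 0


# ---------------------------------------------------------------------
# permutation null and decision
# ---------------------------------------------------------------------
def null_max_cluster_distribution(model: NormativeModel, config: SPMConfig,
                                  seed: int = 0) -> np.ndarray:
    """Null distribution of maximum surviving cluster sizes.

    Each permutation draws one cohort member uniformly (with
    replacement across permutations), computes its p-map against the
    remaining n-1 members and records the maximum surviving cluster
    size (0 when no cluster survives).  The per-member p-map is
    deterministic, so it is computed once per member and reused.
    """
    if model.n < 2:
        raise ValueError("null distribution needs a cohort of n >= 2")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, model.n, size=config.n_permutations)
    max_sizes = {}
    out = np.empty(config.n_permutations, dtype=int)
    for k, i in enumerate(draws):
        i = int(i)
        if i not in max_sizes:
            rest = np.delete(model.stack, i, axis=0)
            pmap = _pmap_against(model.stack[i], rest)
            max_sizes[i] = _max_surviving_size(pmap, config)
        out[k] = max_sizes[i]
    return out


def nearest_rank_percentile(values, q: float) -> float:
    """Nearest-rank (ceil) percentile: smallest x with cdf(x) >= q."""
    values = np.sort(np.asarray(values))
    rank = int(np.ceil(q * len(values)))
    rank = min(max(rank, 1), len(values))
    return float(values[rank - 1])


def classify_spm(grid: np.ndarray, model: NormativeModel, config: SPMConfig,
                 null_sizes: np.ndarray) -> SPMDecision:
    """Flag a registered map as an outlier via cluster-level FWER control.

    Candidate clusters must *strictly* exceed the (1 - alpha_fwe)
    nearest-rank percentile of the null maximum-cluster-size
    distribution to count as significant.
    """
    pmap = compute_pmap(grid, model)
    clusters = find_clusters(pmap, config.alpha_forming, config.min_cluster,
                             config.connectivity)
    threshold = int(nearest_rank_percentile(null_sizes, 1 - config.alpha_fwe))
    significant = [c for c in clusters if c.size > threshold]
    return SPMDecision(pmap=pmap, clusters=clusters, fwe_threshold=threshold,
                       significant=significant, is_outlier=bool(significant))


# ---------------------------------------------------------------------
# detector facade + hyperparameter tuning
# ---------------------------------------------------------------------
@dataclass
class SPMDetector:
    """Two-sided (left + right cohort) SPM outlier detector.

    Holds one normative model and one null distribution per side; a
    test sample is evaluated against the cohort of its *recorded* side,
    which is exactly what lets a swapped side annotation surface as a
    deviation from the wrong-side norm.
    """

    models: dict = field(default_factory=dict)        # Side -> NormativeModel
    nulls: dict = field(default_factory=dict)         # Side -> np.ndarray
    config: SPMConfig = field(default_factory=SPMConfig)

    @classmethod
    def fit(cls, train: Dataset, config: SPMConfig, seed: int = 0
            ) -> "SPMDetector":
        det = cls(config=config)
        for k, side in enumerate(Side):
            model = NormativeModel.from_dataset(train, side)
            det.models[side] = model
            det.nulls[side] = null_max_cluster_distribution(
                model, config, seed=seed + k)
        return det

    def decide(self, grid: np.ndarray, side: Side) -> SPMDecision:
        side = Side(side)
        return classify_spm(grid, self.models[side], self.config,
                            self.nulls[side])

    def predict(self, ds: Dataset) -> np.ndarray:
        """Binary outlier flags (1 = outlier) for every sample."""
        flags = np.zeros(len(ds), dtype=int)
        for i in range(len(ds)):
            side = Side(ds.manifest.iloc[i]["side"])
            flags[i] = int(self.decide(ds.grids[i], side).is_outlier)
        return flags


def sample_config_space(rng: np.random.Generator, n_candidates: int,
                        alpha_range=(0.01, 0.05), min_cluster_range=(0, 30),
                        **kwargs) -> list[SPMConfig]:
    """Randomized search candidates: alpha_forming uniform continuous,
    min_cluster uniform integer."""
    return [SPMConfig(alpha_forming=float(rng.uniform(*alpha_range)),
                      min_cluster=int(rng.integers(min_cluster_range[0],
                                                   min_cluster_range[1] + 1)),
                      **kwargs)
            for _ in range(n_candidates)]


def tune_spm(train: Dataset, val: Dataset, n_candidates: int = 10,
             seed: int = 0, n_permutations: int = 1000,
             connectivity: int = 8) -> tuple[SPMConfig, float]:
    """Pick (alpha_forming, min_cluster) maximizing binary F1 on the
    validation set.

    Ties are broken toward the more conservative setting: larger
    min_cluster first, then smaller alpha_forming.
    """
    val_labels = (val.manifest["label"].astype(int) != LABEL_VALID).to_numpy()
    if val_labels.all() or not val_labels.any():
        raise ValueError("validation set must contain both classes")
    rng = np.random.default_rng(seed)
    candidates = sample_config_space(rng, n_candidates,
                                     n_permutations=n_permutations,
                                     connectivity=connectivity)
    best: tuple | None = None
    for config in candidates:
        det = SPMDetector.fit(train, config, seed=seed)
        flags = det.predict(val).astype(bool)
        f1 = binary_f1(val_labels, flags)
        key = (f1, config.min_cluster, -config.alpha_forming)
        if best is None or key > best[0]:
            best = (key, config, f1)
    return best[1], best[2]
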