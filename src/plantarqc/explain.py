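"""Per-pixel attributions for CNN predictions, and the comparison figure.

The attribution backend is *expected gradients*: integrated gradients
along the straight path from each background sample to the explained
sample (midpoint Riemann rule), averaged over a background set drawn
from the training data.  Because the network is piecewise linear, the
path integral closely satisfies the Shapley-style additivity identity

    sum(pixel attributions) + sum(embedding attributions)
        ~= f_target(x) - mean_b f_target(b)

which is asserted to 1% relative tolerance by the test-suite contract.
The side label is attributed through its continuous embedding vector
(the path interpolates between the two embeddings).

For display, attributions below 20% of the maximum absolute value are
zeroed and the map is smoothed with a bilateral filter; the three-panel
figure shows the raw map, the SPM significant clusters as green
contours, and the attribution heatmap (blue = pushes toward the
predicted class, red = pushes away).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from skimage.restoration import denoise_bilateral

from .cnn import SIDE_INDEX, PlantarCNN
from .spm import SPMDecision
from .types import GRID_SIZE, PressureSample, Side


@dataclass
class AttributionMap:
    values: np.ndarray                 # (64, 64) signed pixel contributions
    embedding_values: np.ndarray       # (embedding_dim,) side contributions
    target_class: int
    baseline_expectation: float        # mean_b f_target(b)
    model_output: float                # f_target(x)
    n_background: int
    sample_id: str | None = None

    @property
    def additivity_gap(self) -> float:
        """Relative gap of the additivity identity."""
        total = float(self.values.sum() + self.embedding_values.sum())
        diff = self.model_output - self.baseline_expectation
        return abs(total - diff) / max(abs(diff), 1e-8)


@dataclass
class RenderConfig:
    threshold_frac: float = 0.20
    bilateral_win: int = 5          # filter window (px)
    bilateral_sigma_color: float = 0.1   # in units of the normalized map
    bilateral_sigma_spatial: float = 2.0  # px
    positive_color: str = "blue"
    negative_color: str = "red"
    contour_color: str = "green"

    def __post_init__(self):
        if not 0 <= self.threshold_frac < 1:
            raise ValueError("threshold_frac must be in [0, 1)")


def compute_attribution(model: PlantarCNN, grid: np.ndarray, side: Side,
                        background_grids: np.ndarray, background_sides,
                        fold_stats: tuple[float, float],
                        target_class: int | None = None, n_steps: int = 64,
                        batch: int = 32,
                        sample_id: str | None = None) -> AttributionMap:
    """Expected-gradients attribution of one sample's target logit.

    ``background_grids``/``background_sides`` should be a random subset
    of the training data (100 samples by default upstream); grids are
    raw [0, 1] maps and are standardized internally with ``fold_stats``.
    """
    bg = np.asarray(background_grids, dtype=np.float64)
    if bg.ndim != 3 or len(bg) == 0:
        raise ValueError("background set must be a non-empty (n, 64, 64) stack")
    mean, sd = fold_stats
    x = (np.asarray(grid, dtype=np.float64) - mean) / sd
    bg = (bg - mean) / sd
    side_idx = SIDE_INDEX[Side(side)]
    bg_sides = np.array([SIDE_INDEX[Side(s)] if not isinstance(s, (int,
                        np.integer)) else int(s) for s in background_sides])
    emb_table = model.embedding.params["E"].astype(np.float64)
    e_x = emb_table[side_idx]
    e_bg = emb_table[bg_sides]

    # target = predicted class unless specified
    logits_x = model.forward(x[None], np.array([side_idx]), training=False)[0]
    target = int(np.argmax(logits_x)) if target_class is None else int(target_class)
    f_x = float(logits_x[target])

    n_bg = len(bg)
    alphas = (np.arange(n_steps) + 0.5) / n_steps      # midpoint rule
    dx = x[None] - bg                                   # (B, 64, 64)
    de = e_x[None] - e_bg                               # (B, E)

    grad_x_sum = np.zeros((n_bg, GRID_SIZE, GRID_SIZE))
    grad_e_sum = np.zeros_like(de)
    onehot = np.zeros(model.config.n_classes, dtype=np.float64)
    onehot[target] = 1.0

    points = [(b, a) for b in range(n_bg) for a in alphas]
    for start in range(0, len(points), batch):
        chunk = points[start:start + batch]
        xs = np.stack([bg[b] + a * dx[b] for b, a in chunk])
        es = np.stack([e_bg[b] + a * de[b] for b, a in chunk])
        model.forward(xs, training=False, embedding_override=es)
        d = np.tile(onehot, (len(chunk), 1)).astype(np.float32)
        gx, ge = model.backward(d)
        for j, (b, a) in enumerate(chunk):
            grad_x_sum[b] += gx[j]
            grad_e_sum[b] += ge[j]

    ig_x = dx * grad_x_sum / n_steps                   # (B, 64, 64)
    ig_e = de * grad_e_sum / n_steps
    f_bg = []
    for start in range(0, n_bg, batch):
        lo = model.forward(bg[start:start + batch],
                           bg_sides[start:start + batch], training=False)
        f_bg.extend(lo[:, target].tolist())

    return AttributionMap(
        values=ig_x.mean(axis=0), embedding_values=ig_e.mean(axis=0),
        target_class=target, baseline_expectation=float(np.mean(f_bg)),
        model_output=f_x, n_background=n_bg, sample_id=sample_id)


def threshold_attribution(values: np.ndarray, frac: float = 0.20) -> np.ndarray:
    """Zero attributions below ``frac`` of the maximum absolute value."""
    v = np.asarray(values, dtype=np.float64).copy()
    peak = np.abs(v).max()
    if peak == 0:
        return v
    v[np.abs(v) < frac * peak] = 0.0
    return v


def threshold_and_smooth(attr: AttributionMap,
                         config: RenderConfig | None = None) -> AttributionMap:
    """Apply the display post-processing: threshold then bilateral-smooth.

    Positive and negative parts are filtered separately (the bilateral
    filter operates on non-negative intensity maps) and recombined, so
    the sign pattern of the surviving extremes is preserved.
    """
    config = config or RenderConfig()
    v = threshold_attribution(attr.values, config.threshold_frac)
    peak = np.abs(v).max()
    if peak == 0:
        smoothed = v
    else:
        smoothed = np.zeros_like(v)
        for sign in (1.0, -1.0):
            part = np.clip(sign * v, 0, None) / peak
            if part.max() == 0:
                continue
            sm = denoise_bilateral(
                part, win_size=config.bilateral_win,
                sigma_color=config.bilateral_sigma_color,
                sigma_spatial=config.bilateral_sigma_spatial)
            sm = np.where(part > 0, sm, 0.0)   # no spill into the zeroed zone
            smoothed += sign * sm * peak
    out = AttributionMap(
        values=smoothed, embedding_values=attr.embedding_values.copy(),
        target_class=attr.target_class,
        baseline_expectation=attr.baseline_expectation,
        model_output=attr.model_output, n_background=attr.n_background,
        sample_id=attr.sample_id)
    return out


def render_triptych(sample: PressureSample, spm_decision: SPMDecision,
                    attr: AttributionMap, out_path: str,
                    config: RenderConfig | None = None,
                    survey_parity: bool = False,
                    spm_sample_id: str | None = None) -> str:
    """Write the three-panel comparison figure for one sample.

    Panels: raw grayscale map; SPM significant clusters as green
    contours over the map; thresholded + smoothed attribution heatmap
    over the map.  ``survey_parity`` suppresses the outlier subtype in
    the title (binary wording only).
    """
    config = config or RenderConfig()
    if attr.sample_id is not None and attr.sample_id != sample.sample_id:
        raise ValueError(f"attribution belongs to {attr.sample_id!r}, "
                         f"not {sample.sample_id!r}")
    if spm_sample_id is not None and spm_sample_id != sample.sample_id:
        raise ValueError(f"SPM decision belongs to {spm_sample_id!r}, "
                         f"not {sample.sample_id!r}")

    display = threshold_and_smooth(attr, config)
    sig_mask = np.zeros((GRID_SIZE, GRID_SIZE))
    for cluster in spm_decision.significant:
        for (r, c) in cluster.pixels:
            sig_mask[r, c] = 1.0

    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    for ax in axes:
        ax.set_xticks([])
        ax.set_yticks([])
    axes[0].imshow(sample.grid, cmap="gray_r", vmin=0, vmax=1)
    axes[0].set_title("pressure")
    axes[1].imshow(sample.grid, cmap="gray_r", vmin=0, vmax=1)
    if sig_mask.any():
        axes[1].contour(sig_mask, levels=[0.5], colors=config.contour_color,
                        linewidths=1.5)
    axes[1].set_title("SPM clusters")
    axes[2].imshow(sample.grid, cmap="gray_r", vmin=0, vmax=1)
    peak = np.abs(display.values).max()
    if peak > 0:
        overlay = np.ma.masked_where(display.values == 0, display.values)
        axes[2].imshow(overlay, cmap="RdBu", vmin=-peak, vmax=peak, alpha=0.7)
    axes[2].set_title("attribution")
    verdict = ("outlier" if spm_decision.is_outlier else "valid")
    if survey_parity:
        fig.suptitle(f"sample {sample.sample_id}: {verdict}")
    else:
        from .types import LABEL_NAMES
        fig.suptitle(f"sample {sample.sample_id}: "
                     f"{LABEL_NAMES[attr.target_class]}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path
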