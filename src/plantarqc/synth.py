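"""Synthetic plantar pressure data and outlier injection.

The foot simulator is an analytic stand-in for real acquisitions (which
are not publicly available): a left-foot pressure pattern is composed of
anatomically placed Gaussian blobs — heel, a lateral midfoot band, five
metatarsal heads, hallux and four lesser toes — with a medial arch void.
Right feet are the column-mirrored left pattern.  Subject-level effects
(foot size, orientation, regional loading) and per-sample noise (smooth
multiplicative field, small pose jitter) are layered on top so that a
cohort of valid maps has realistic within- and between-subject spread.

The four outlier generators apply the corruption recipes used for
dataset augmentation: forefoot/heel crops, double-foot composites,
upside-down maps and swapped side annotations.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .dataio import Dataset
from .types import (GRID_SIZE, LABEL_DOUBLE_FOOT, LABEL_GENERAL_ERROR,
                    LABEL_INVERTED, LABEL_SIDE_SWAP, LABEL_VALID, Condition,
                    PressureSample, Provenance, Side)

# ---------------------------------------------------------------------
# Foot shape model
# ---------------------------------------------------------------------

#: (row, col, sigma_r, sigma_c, intensity) of each left-foot region blob.
#: Medial side (hallux, arch) is at high column indices for a LEFT foot.
_HEEL = (50.0, 31.0, 6.5, 5.5, 1.00)
_MIDFOOT = [(44.0, 28.0, 5.0, 4.0, 0.50),
            (38.0, 26.5, 5.0, 3.5, 0.40)]
_METATARSALS = [(24.0, 42.0, 3.5, 3.0, 0.95),   # MT1, medial
                (21.0, 37.0, 3.0, 2.8, 0.85),
                (20.0, 32.0, 3.0, 2.8, 0.75),
                (20.0, 27.0, 3.0, 2.6, 0.60),
                (21.0, 22.0, 3.0, 2.5, 0.55)]   # MT5, lateral
_TOES = [(11.0, 42.0, 3.0, 2.6, 0.80),          # hallux
         (9.0, 36.0, 2.0, 1.8, 0.40),
         (9.0, 32.0, 2.0, 1.8, 0.35),
         (10.0, 28.0, 2.0, 1.7, 0.30),
         (11.0, 24.0, 1.8, 1.6, 0.25)]
_ARCH = (38.0, 42.0, 7.0, 5.0)                  # medial arch void (suppression)


@dataclass
class FootShapeParams:
    """Parameters of the analytic foot model (left-foot frame).

    Blob tuples are ``(row, col, sigma_r, sigma_c, intensity)`` in
    pixels / normalized intensity units.
    """

    heel: tuple = _HEEL
    midfoot: list = field(default_factory=lambda: list(_MIDFOOT))
    metatarsals: list = field(default_factory=lambda: list(_METATARSALS))
    toes: list = field(default_factory=lambda: list(_TOES))
    arch: tuple = _ARCH
    arch_depth: float = 0.85          # fraction of pressure removed in the void
    noise_sd: float = 0.10            # sd of the multiplicative noise field
    noise_smoothness: float = 3.0     # spatial sigma (px) of the noise field
    floor: float = 0.02               # intensities below this become exact 0
    subject_rotation_deg: float = 6.0  # subject pose spread (uniform half-width)
    subject_shift_px: float = 2.0
    sample_rotation_deg: float = 2.0   # per-sample pose jitter
    sample_shift_px: float = 1.0
    mirror_right: bool = True         # derive RIGHT by column reflection

    def all_blobs(self):
        return [self.heel] + self.midfoot + self.metatarsals + self.toes


@dataclass
class _SubjectEffects:
    length_scale: float = 1.0
    width_scale: float = 1.0
    rotation_deg: float = 0.0
    shift: tuple = (0.0, 0.0)
    gains: tuple = (1.0, 1.0, 1.0, 1.0)   # heel, midfoot, metatarsals, toes
    arch_depth_scale: float = 1.0


def subject_effects(rng: np.random.Generator,
                    params: FootShapeParams) -> _SubjectEffects:
    """Draw the anatomy/pose effects shared by all samples of a subject."""
    return _SubjectEffects(
        length_scale=rng.uniform(0.92, 1.06),
        width_scale=rng.uniform(0.90, 1.08),
        rotation_deg=rng.uniform(-params.subject_rotation_deg,
                                 params.subject_rotation_deg),
        shift=(rng.uniform(-params.subject_shift_px, params.subject_shift_px),
               rng.uniform(-params.subject_shift_px, params.subject_shift_px)),
        gains=tuple(rng.uniform(0.85, 1.15, size=4)),
        arch_depth_scale=rng.uniform(0.80, 1.15),
    )


def _render_blobs(blobs, center, rot_deg, scales, shift) -> np.ndarray:
    """Evaluate a sum of Gaussian blobs whose centers are scaled about
    the canvas center, rotated and shifted."""
    rr, cc = np.mgrid[0:GRID_SIZE, 0:GRID_SIZE].astype(np.float64)
    th = np.deg2rad(rot_deg)
    cos, sin = np.cos(th), np.sin(th)
    out = np.zeros((GRID_SIZE, GRID_SIZE))
    for (r0, c0, sr, sc, inten) in blobs:
        dr = (r0 - center) * scales[0]
        dc = (c0 - center) * scales[1]
        r = center + cos * dr - sin * dc + shift[0]
        c = center + sin * dr + cos * dc + shift[1]
        sr_s, sc_s = sr * scales[0], sc * scales[1]
        out += inten * np.exp(-((rr - r) ** 2 / (2 * sr_s ** 2)
                                + (cc - c) ** 2 / (2 * sc_s ** 2)))
    return out


def simulate_valid_foot(params: FootShapeParams, side: Side, subject_id: str,
                        seed: int, condition: Condition = Condition.STATIC,
                        effects: _SubjectEffects | None = None,
                        sample_id: str | None = None) -> PressureSample:
    """Simulate one valid (label 0) pressure map.

    Deterministic for a fixed ``seed``.  All randomness is drawn in the
    left-foot frame; a RIGHT sample is the column reflection of the
    LEFT sample produced from the same seed and effects.
    """
    side = Side(side)
    rng = np.random.default_rng(seed)
    eff = effects or _SubjectEffects()
    rot = eff.rotation_deg + rng.uniform(-params.sample_rotation_deg,
                                         params.sample_rotation_deg)
    shift = (eff.shift[0] + rng.uniform(-params.sample_shift_px,
                                        params.sample_shift_px),
             eff.shift[1] + rng.uniform(-params.sample_shift_px,
                                        params.sample_shift_px))
    scales = (eff.length_scale, eff.width_scale)
    center = (GRID_SIZE - 1) / 2.0

    g_heel, g_mid, g_met, g_toe = eff.gains
    blobs = ([_scale_intensity(params.heel, g_heel)]
             + [_scale_intensity(b, g_mid) for b in params.midfoot]
             + [_scale_intensity(b, g_met) for b in params.metatarsals]
             + [_scale_intensity(b, g_toe) for b in params.toes])
    grid = _render_blobs(blobs, center, rot, scales, shift)

    # medial arch void (suppression field)
    ar, ac, asr, asc = params.arch
    arch_blob = _render_blobs([(ar, ac, asr, asc, 1.0)], center, rot,
                              scales, shift)
    depth = np.clip(params.arch_depth * eff.arch_depth_scale, 0.0, 1.0)
    grid *= 1.0 - depth * arch_blob

    if condition is Condition.DYNAMIC:
        # roll-over emphasis: more forefoot, less heel loading
        rows = np.arange(GRID_SIZE)[:, None]
        grid = grid * np.where(rows < 32, 1.12, 1.0) \
                    * np.where(rows > 40, 0.92, 1.0)

    if params.noise_sd > 0:
        noise = rng.standard_normal((GRID_SIZE, GRID_SIZE))
        noise = gaussian_filter(noise, params.noise_smoothness)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd * params.noise_sd
        grid = grid * np.clip(1.0 + noise, 0.5, 1.5)

    grid = np.clip(grid, 0.0, None)
    grid[grid < params.floor] = 0.0
    peak = grid.max()
    if peak > 0:
        grid = grid / peak

    if side is Side.RIGHT and params.mirror_right:
        grid = np.fliplr(grid)

    return PressureSample(
        sample_id=sample_id or f"{subject_id}-{side.value}-{seed}",
        grid=grid, subject_id=subject_id, side=side, condition=condition,
        label=LABEL_VALID, provenance=Provenance.REAL)


def _scale_intensity(blob, gain):
    r, c, sr, sc, inten = blob
    return (r, c, sr, sc, min(inten * gain, 1.0))


# ---------------------------------------------------------------------
# Outlier generators
# ---------------------------------------------------------------------
FOREFOOT = "forefoot"
HEEL = "heel"
#: crop-fraction bands: distal 50% +/- 5%, proximal 65% +/- 5%
CROP_BANDS = {FOREFOOT: (0.45, 0.55), HEEL: (0.60, 0.70)}


def _require_valid(sample: PressureSample, op: str) -> None:
    if sample.label != LABEL_VALID:
        raise ValueError(f"{op} requires a valid (label 0) source sample, "
                         f"got label {sample.label}")


def make_general_error(sample: PressureSample, mode: str, seed: int,
                       fraction: float | None = None,
                       sample_id: str | None = None) -> PressureSample:
    """Crop away the forefoot or the heel (label 1).

    FOREFOOT zeroes the distal rows ``0 .. ceil(f*64)-1`` with
    ``f ~ U(0.45, 0.55)``; HEEL zeroes the proximal rows
    ``64-ceil(f*64) .. 63`` with ``f ~ U(0.60, 0.70)``.  Untouched
    pixels are preserved exactly and the side annotation is retained.
    """
    _require_valid(sample, "make_general_error")
    if mode not in CROP_BANDS:
        raise ValueError(f"unknown crop mode {mode!r}")
    if fraction is None:
        lo, hi = CROP_BANDS[mode]
        fraction = float(np.random.default_rng(seed).uniform(lo, hi))
    n_rows = int(np.ceil(fraction * GRID_SIZE))
    grid = sample.grid.copy()
    if mode == FOREFOOT:
        grid[:n_rows, :] = 0.0
    else:
        grid[GRID_SIZE - n_rows:, :] = 0.0
    return sample.replace(
        sample_id=sample_id or f"{sample.sample_id}-crop",
        grid=grid, label=LABEL_GENERAL_ERROR, provenance=Provenance.SYNTHETIC,
        source_ids=[sample.sample_id])


def make_double_foot(left: PressureSample, right: PressureSample, seed: int,
                     sample_id: str | None = None) -> PressureSample:
    """Composite both feet of one subject into one frame (label 2).

    Each foot is downscaled to a 32x32 tile and placed into diagonally
    opposite quadrants (upper-left + lower-right); which foot goes
    upper-left is chosen at random, and each tile is independently
    shifted 0-2 px in a random cardinal direction.  The side annotation
    is meaningless for such composites and is assigned at random.
    """
    _require_valid(left, "make_double_foot")
    _require_valid(right, "make_double_foot")
    if left.subject_id != right.subject_id:
        raise ValueError("double-foot sources must share a subject")
    if left.side == right.side:
        raise ValueError("double-foot sources must be opposite sides")
    if left.side is Side.RIGHT:
        left, right = right, left

    from skimage.transform import resize
    rng = np.random.default_rng(seed)
    half = GRID_SIZE // 2
    tiles = [np.clip(resize(s.grid.astype(np.float64), (half, half), order=1,
                            mode="constant", anti_aliasing=True,
                            preserve_range=True), 0, 1)
             for s in (left, right)]
    if rng.random() < 0.5:           # reverse configuration
        tiles = tiles[::-1]
    origins = [(0, 0), (half, half)]  # upper-left, lower-right quadrants

    grid = np.zeros((GRID_SIZE, GRID_SIZE), dtype=np.float64)
    for tile, (r0, c0) in zip(tiles, origins):
        k = int(rng.integers(0, 3))                       # 0..2 px
        direction = rng.choice(4)                         # N/S/W/E
        dr, dc = [(-k, 0), (k, 0), (0, -k), (0, k)][direction]
        rr, cc = r0 + dr, c0 + dc
        rs, cs = max(rr, 0), max(cc, 0)
        re, ce = min(rr + half, GRID_SIZE), min(cc + half, GRID_SIZE)
        grid[rs:re, cs:ce] = np.maximum(
            grid[rs:re, cs:ce],
            tile[rs - rr:re - rr, cs - cc:ce - cc])

    side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
    return PressureSample(
        sample_id=sample_id or f"{left.sample_id}+{right.sample_id}",
        grid=grid, subject_id=left.subject_id, side=side,
        condition=left.condition, label=LABEL_DOUBLE_FOOT,
        provenance=Provenance.SYNTHETIC,
        source_ids=[left.sample_id, right.sample_id])


def make_inverted(sample: PressureSample, mode: str = "flip_rows",
                  sample_id: str | None = None) -> PressureSample:
    """Turn the map upside-down (label 3); side annotation retained.

    ``flip_rows`` reverses rows only; ``rot180`` additionally mirrors
    columns (a true 180-degree rotation).
    """
    _require_valid(sample, "make_inverted")
    if mode == "flip_rows":
        grid = sample.grid[::-1, :].copy()
    elif mode == "rot180":
        grid = sample.grid[::-1, ::-1].copy()
    else:
        raise ValueError(f"unknown inversion mode {mode!r}")
    return sample.replace(
        sample_id=sample_id or f"{sample.sample_id}-inv",
        grid=grid, label=LABEL_INVERTED, provenance=Provenance.SYNTHETIC,
        source_ids=[sample.sample_id])


def make_side_swap(sample: PressureSample,
                   sample_id: str | None = None) -> PressureSample:
    """Toggle the side annotation, leaving the map untouched (label 4)."""
    _require_valid(sample, "make_side_swap")
    return sample.replace(
        sample_id=sample_id or f"{sample.sample_id}-swap",
        side=sample.side.other, label=LABEL_SIDE_SWAP,
        provenance=Provenance.SYNTHETIC, source_ids=[sample.sample_id])


def apply_priority_rule(labels: set[int]) -> int:
    """Resolve multiple applicable labels to the most critical one.

    The swapped-side annotation (4) has the lowest priority among the
    outlier classes and is superseded by any other outlier label; no
    ranking exists between the other outlier classes, so co-occurring
    non-4 outliers are an error.
    """
    labels = set(labels)
    if not labels or not labels <= {0, 1, 2, 3, 4}:
        raise ValueError(f"labels must be a non-empty subset of 0..4, "
                         f"got {sorted(labels)}")
    critical = labels - {LABEL_VALID, LABEL_SIDE_SWAP}
    if len(critical) > 1:
        raise ValueError(f"ambiguous outlier labels {sorted(critical)}: "
                         "no priority is defined between them")
    if critical:
        return critical.pop()
    if LABEL_SIDE_SWAP in labels:
        return LABEL_SIDE_SWAP
    return LABEL_VALID


# ---------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------
def augment_to_target(ds: Dataset, target: int = 500,
                      seed: int = 0) -> Dataset:
    """Top up every outlier category to ``target`` samples.

    Synthetic outliers are derived from randomly chosen valid samples
    (same-subject left/right pairs for double-foot composites) and
    inherit the source subject id, so grouped cross-validation keeps
    them with their source subject.
    """
    rng = np.random.default_rng(seed)
    counts = ds.counts_by_label()
    for cat in (1, 2, 3, 4):
        if counts[cat] > target:
            raise ValueError(f"category {cat} already has {counts[cat]} "
                             f"samples, above target {target}")
    valid_idx = np.flatnonzero(ds.manifest["label"].astype(int).to_numpy()
                               == LABEL_VALID)
    if len(valid_idx) == 0 and any(target > counts[c] for c in (1, 2, 3, 4)):
        raise ValueError("no valid samples to derive synthetic outliers from")

    valid = [ds.sample(int(i)) for i in valid_idx]
    # subjects owning at least one valid sample of each side
    by_subject: dict[str, dict[Side, list[PressureSample]]] = {}
    for s in valid:
        by_subject.setdefault(s.subject_id, {}).setdefault(s.side, []).append(s)
    paired = [subj for subj, sides in by_subject.items()
              if Side.LEFT in sides and Side.RIGHT in sides]

    new: list[PressureSample] = []
    for cat in (1, 2, 3, 4):
        need = target - counts[cat]
        for k in range(need):
            sid = f"syn{cat}-{k:05d}"
            sub_seed = int(rng.integers(0, 2**31 - 1))
            if cat == LABEL_GENERAL_ERROR:
                src = valid[int(rng.integers(len(valid)))]
                mode = FOREFOOT if rng.random() < 0.5 else HEEL
                new.append(make_general_error(src, mode, sub_seed,
                                              sample_id=sid))
            elif cat == LABEL_DOUBLE_FOOT:
                if not paired:
                    raise ValueError("no subject has valid samples of both "
                                     "sides for double-foot synthesis")
                subj = paired[int(rng.integers(len(paired)))]
                lefts = by_subject[subj][Side.LEFT]
                rights = by_subject[subj][Side.RIGHT]
                left = lefts[int(rng.integers(len(lefts)))]
                right = rights[int(rng.integers(len(rights)))]
                new.append(make_double_foot(left, right, sub_seed,
                                            sample_id=sid))
            elif cat == LABEL_INVERTED:
                src = valid[int(rng.integers(len(valid)))]
                new.append(make_inverted(src, sample_id=sid))
            else:
                src = valid[int(rng.integers(len(valid)))]
                new.append(make_side_swap(src, sample_id=sid))
    if not new:
        return ds
    return ds.concat(Dataset.from_samples(new))


def generate_dataset(n_subjects: int = 200, valid_per_subject: int = 4,
                     target: int = 500, seed: int = 0,
                     real_outlier_counts: dict[int, int] | None = None,
                     params: FootShapeParams | None = None,
                     n_valid: int | None = None) -> Dataset:
    """Generate a full study dataset.

    ``n_subjects`` subjects contribute up to ``valid_per_subject`` valid
    maps each (left/right x static/dynamic); ``n_valid`` optionally caps
    the total valid count.  ``real_outlier_counts`` (category -> count)
    adds pre-existing outliers marked with REAL provenance, emulating an
    annotated curated set; they are derived from additional subjects not
    in the valid cohort.  Finally every outlier category is topped up to
    ``target`` with synthetic samples.
    """
    params = params or FootShapeParams()
    rng = np.random.default_rng(seed)
    combos = [(Side.LEFT, Condition.STATIC), (Side.RIGHT, Condition.STATIC),
              (Side.LEFT, Condition.DYNAMIC), (Side.RIGHT, Condition.DYNAMIC)]

    samples: list[PressureSample] = []
    total = 0
    cap = n_valid if n_valid is not None else n_subjects * valid_per_subject
    for i in range(n_subjects):
        subj = f"S{i:04d}"
        eff = subject_effects(rng, params)
        for side, cond in combos[:valid_per_subject]:
            if total >= cap:
                break
            samples.append(simulate_valid_foot(
                params, side, subj, seed=int(rng.integers(0, 2**31 - 1)),
                condition=cond, effects=eff,
                sample_id=f"{subj}-{side.value}-{cond.value[:3]}"))
            total += 1

    # pre-existing ("real") outliers from extra subjects
    if real_outlier_counts:
        extra = 0
        for cat, count in sorted(real_outlier_counts.items()):
            for k in range(count):
                subj = f"X{extra:04d}"
                extra += 1
                eff = subject_effects(rng, params)

                def _foot(side):
                    return simulate_valid_foot(
                        params, side, subj,
                        seed=int(rng.integers(0, 2**31 - 1)), effects=eff,
                        sample_id=f"{subj}-{side.value}")

                sub_seed = int(rng.integers(0, 2**31 - 1))
                sid = f"real{cat}-{k:04d}"
                if cat == LABEL_GENERAL_ERROR:
                    mode = FOREFOOT if rng.random() < 0.5 else HEEL
                    out = make_general_error(_foot(Side.LEFT), mode, sub_seed,
                                             sample_id=sid)
                elif cat == LABEL_DOUBLE_FOOT:
                    out = make_double_foot(_foot(Side.LEFT), _foot(Side.RIGHT),
                                           sub_seed, sample_id=sid)
                elif cat == LABEL_INVERTED:
                    out = make_inverted(_foot(Side.LEFT), sample_id=sid)
                elif cat == LABEL_SIDE_SWAP:
                    out = make_side_swap(_foot(Side.LEFT), sample_id=sid)
                else:
                    raise ValueError(f"unknown outlier category {cat}")
                out = replace_provenance_real(out)
                samples.append(out)

    ds = Dataset.from_samples(samples)
    return augment_to_target(ds, target=target,
                             seed=int(rng.integers(0, 2**31 - 1)))


def replace_provenance_real(sample: PressureSample) -> PressureSample:
    """Mark a derived sample as REAL (emulates a curated real outlier)."""
    return sample.replace(provenance=Provenance.REAL, source_ids=[])
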