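"""Dataset I/O and grid standardization.

Raw acquisitions from different pressure plates come on grids of
different size and sensor pitch.  :func:`embed_to_grid` harmonizes them
into the standard 64x64 canvas (aspect-preserving resample plus
zero-padding) and :func:`normalize_intensity` rescales intensities to
[0, 1], removing body-weight effects.

Datasets are stored either as a single HDF5 container (``grids`` array
plus an embedded ``manifest`` CSV) or as a plain directory of per-sample
CSV matrices next to a ``manifest.csv``; both dialects round-trip
losslessly.
"""
from __future__ import annotations

import hashlib
import io
import os
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from skimage.transform import resize

from .types import (ALL_LABELS, GRID_SIZE, Condition, PressureSample,
                    Provenance, Side)

MANIFEST_COLUMNS = ["sample_id", "subject_id", "side", "condition",
                    "label", "provenance", "source_ids"]


def embed_to_grid(raw: np.ndarray, row_spacing: float = 1.0,
                  col_spacing: float = 1.0) -> np.ndarray:
    """Embed a raw H x W grid into the standard 64x64 canvas.

    The physical aspect ratio (H*row_spacing : W*col_spacing) is
    preserved: the content is resampled so its longer physical side
    spans 64 pixels, then centered and zero-padded.  Intensities are
    rescaled to max 1 whenever resampling occurred.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2 or raw.size == 0:
        raise ValueError("raw grid must be a non-empty 2D array")
    if raw.min() < 0:
        raise ValueError("raw grid must be non-negative")
    if row_spacing <= 0 or col_spacing <= 0:
        raise ValueError("sensor spacings must be positive")

    h_phys = raw.shape[0] * row_spacing
    w_phys = raw.shape[1] * col_spacing
    scale = GRID_SIZE / max(h_phys, w_phys)
    h = max(1, int(round(h_phys * scale)))
    w = max(1, int(round(w_phys * scale)))
    # rounding must keep the longer side exactly at 64
    if h_phys >= w_phys:
        h = GRID_SIZE
    else:
        w = GRID_SIZE

    if (h, w) == raw.shape:
        content = raw
    else:
        content = resize(raw, (h, w), order=1, mode="constant",
                         anti_aliasing=raw.shape[0] > h or raw.shape[1] > w,
                         preserve_range=True)
        content = np.clip(content, 0, None)
        if content.max() > 0:
            content = content / content.max()

    out = np.zeros((GRID_SIZE, GRID_SIZE), dtype=np.float64)
    r0 = (GRID_SIZE - h) // 2
    c0 = (GRID_SIZE - w) // 2
    out[r0:r0 + h, c0:c0 + w] = content
    return out


def normalize_intensity(grid: np.ndarray) -> np.ndarray:
    """Divide by the grid maximum so intensities span [0, 1]."""
    grid = np.asarray(grid, dtype=np.float64)
    if grid.min() < 0:
        raise ValueError("grid must be non-negative")
    peak = grid.max()
    if peak == 0:
        raise ValueError("cannot normalize an all-zero grid")
    return grid / peak


@dataclass
class Dataset:
    """A stack of pressure grids plus a tabular manifest.

    ``grids[i]`` belongs to ``manifest.iloc[i]``; manifest columns are
    ``sample_id, subject_id, side, condition, label, provenance,
    source_ids`` with ``source_ids`` semicolon-joined.
    """

    grids: np.ndarray
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        self.grids = np.asarray(self.grids, dtype=np.float32)
        if self.grids.ndim != 3 or self.grids.shape[1:] != (GRID_SIZE, GRID_SIZE):
            raise ValueError("grids must have shape (n, 64, 64)")
        self.manifest = self.manifest.reset_index(drop=True)
        if len(self.grids) != len(self.manifest):
            raise ValueError("grids and manifest length mismatch")
        self.validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_samples(cls, samples: list[PressureSample]) -> "Dataset":
        if not samples:
            return cls.empty()
        grids = np.stack([s.grid for s in samples]).astype(np.float32)
        manifest = pd.DataFrame({
            "sample_id": [s.sample_id for s in samples],
            "subject_id": [s.subject_id for s in samples],
            "side": [s.side.value for s in samples],
            "condition": [s.condition.value for s in samples],
            "label": [s.label for s in samples],
            "provenance": [s.provenance.value for s in samples],
            "source_ids": [";".join(s.source_ids) for s in samples],
        })
        return cls(grids, manifest)

    @classmethod
    def empty(cls) -> "Dataset":
        return cls(np.zeros((0, GRID_SIZE, GRID_SIZE), np.float32),
                   pd.DataFrame(columns=MANIFEST_COLUMNS))

    # -- access -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.manifest)

    def sample(self, i: int) -> PressureSample:
        row = self.manifest.iloc[i]
        src = str(row.source_ids) if row.source_ids else ""
        return PressureSample(
            sample_id=str(row.sample_id), grid=self.grids[i],
            subject_id=str(row.subject_id), side=Side(row.side),
            condition=Condition(row.condition), label=int(row.label),
            provenance=Provenance(row.provenance),
            source_ids=[s for s in src.split(";") if s])

    def samples(self) -> list[PressureSample]:
        return [self.sample(i) for i in range(len(self))]

    def subset(self, indices) -> "Dataset":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return Dataset(self.grids[indices],
                       self.manifest.iloc[indices].reset_index(drop=True))

    def counts_by_label(self) -> dict[int, int]:
        counts = self.manifest["label"].astype(int).value_counts().to_dict()
        return {lab: int(counts.get(lab, 0)) for lab in ALL_LABELS}

    def concat(self, other: "Dataset") -> "Dataset":
        return Dataset(np.concatenate([self.grids, other.grids]),
                       pd.concat([self.manifest, other.manifest],
                                 ignore_index=True))

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        m = self.manifest
        if len(m) == 0:
            return
        ids = m["sample_id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        for i, row in m.iterrows():
            try:
                Side(row.side)
                Condition(row.condition)
                Provenance(row.provenance)
                if int(row.label) not in ALL_LABELS:
                    raise ValueError(f"label {row.label} outside 0..4")
                if (Provenance(row.provenance) is Provenance.SYNTHETIC
                        and not str(row.source_ids)):
                    raise ValueError("synthetic sample without source_ids")
            except ValueError as exc:
                raise ValueError(
                    f"manifest row {i} (sample_id={row.sample_id!r}): {exc}"
                ) from exc
        if self.grids.min() < 0 or self.grids.max() > 1 + 1e-6:
            raise ValueError("grid intensities outside [0, 1]")


def deduplicate(ds: Dataset) -> Dataset:
    """Drop exact duplicates, keeping the first occurrence.

    Two records are duplicates when the standardized grid is
    byte-identical *and* subject, side and condition all agree.
    """
    seen: set[bytes] = set()
    keep: list[int] = []
    for i, row in ds.manifest.iterrows():
        key = (ds.grids[i].tobytes()
               + f"|{row.subject_id}|{row.side}|{row.condition}".encode())
        digest = hashlib.sha1(key).digest()
        if digest not in seen:
            seen.add(digest)
            keep.append(i)
    return ds.subset(np.array(keep, dtype=int)) if keep else Dataset.empty()


# -- storage ----------------------------------------------------------
def write_dataset(ds: Dataset, path: str | os.PathLike) -> None:
    """Write a dataset; ``.h5``/``.hdf5`` suffix selects the HDF5
    container, anything else a plain directory of CSV matrices."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("grids", data=ds.grids)
            csv = ds.manifest.to_csv(index=False)
            f.create_dataset("manifest", data=np.bytes_(csv.encode()))
    else:
        os.makedirs(path, exist_ok=True)
        ds.manifest.to_csv(os.path.join(path, "manifest.csv"), index=False)
        for i, sid in enumerate(ds.manifest["sample_id"].astype(str)):
            np.savetxt(os.path.join(path, f"{sid}.csv"), ds.grids[i],
                       delimiter=",", fmt="%.9g")


def read_dataset(path: str | os.PathLike) -> Dataset:
    path = str(path)
    if os.path.isdir(path):
        manifest = _read_manifest(os.path.join(path, "manifest.csv"))
        grids = []
        for sid in manifest["sample_id"].astype(str):
            fp = os.path.join(path, f"{sid}.csv")
            if not os.path.exists(fp):
                raise ValueError(f"missing grid file for sample {sid!r}")
            grids.append(np.loadtxt(fp, delimiter=",", ndmin=2))
        stack = (np.stack(grids).astype(np.float32) if grids
                 else np.zeros((0, GRID_SIZE, GRID_SIZE), np.float32))
        return Dataset(stack, manifest)
    with h5py.File(path, "r") as f:
        grids = np.asarray(f["grids"], dtype=np.float32)
        csv = bytes(f["manifest"][()]).decode()
    return Dataset(grids, _read_manifest_text(csv))


def _read_manifest(path: str) -> pd.DataFrame:
    with open(path) as fh:
        return _read_manifest_text(fh.read())


def _read_manifest_text(text: str) -> pd.DataFrame:
    df = pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    df["label"] = df["label"].astype(int)
    return df[MANIFEST_COLUMNS]
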