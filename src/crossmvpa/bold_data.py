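"""Data containers and file I/O for BOLD volumes, masks, atlases and event tables.

The pipeline works on three in-memory objects:

* :class:`SessionData` — one participant-session: a 4D BOLD volume (x, y, z, t),
  its repetition time, a modality tag ("audio" or "ortho") and the trial event
  table.
* :class:`MaskedSeries` — the 2D (time x voxels) matrix obtained by restricting
  a volume to a binary (grey-matter) mask, with the voxel coordinates of every
  column retained so results can be mapped back into the volume.
* :class:`LabelVolume` — an integer-labeled parcellation (atlas) with a
  label -> region-name map, used for counting informative voxels by region.

On disk, volumes/masks/atlases are NIfTI-1 (via nibabel) and event tables are
tab-separated files with BIDS-style columns
(onset, duration, trial_type, stimulus_id, run, repetition).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: required columns of an in-memory event table
EVENT_COLUMNS = ("onset", "duration", "stimulus_id", "category", "run", "repetition")

#: on disk the category column follows the BIDS "trial_type" convention
_DISK_RENAME = {"category": "trial_type"}
_MEMORY_RENAME = {"trial_type": "category"}


class ValidationError(ValueError):
    """Input data violates a documented contract (shape, schema, ordering)."""


@dataclasses.dataclass
class SessionData:
    """One participant-session of 4D BOLD data plus its event table.

    ``volume`` has axes (x, y, z, t); ``tr`` is the volume repetition time in
    seconds; ``modality_tag`` identifies the stimulus modality of the session.
    """

    volume: np.ndarray
    tr: float
    modality_tag: str
    participant_id: str
    events: pd.DataFrame
    affine: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(4))

    @property
    def n_volumes(self) -> int:
        return int(self.volume.shape[3])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.volume.shape[:3])

    def validate(self) -> None:
        errors = []
        if self.volume.ndim != 4:
            errors.append(f"volume must be 4-dimensional, got ndim={self.volume.ndim}")
        if not self.tr > 0:
            errors.append(f"tr must be positive, got {self.tr}")
        errors.extend(validate_events(self.events))
        if not errors and len(self.events):
            last = float(self.events["onset"].iloc[-1])
            if last >= self.n_volumes * self.tr:
                errors.append(
                    f"last event onset {last} s does not fit in "
                    f"{self.n_volumes} volumes at TR={self.tr}"
                )
        if errors:
            raise ValidationError("; ".join(errors))


@dataclasses.dataclass
class MaskedSeries:
    """Time x voxels matrix with per-column 3D voxel coordinates.

    Columns are ordered by ascending linearized coordinate with x fastest,
    i.e. by ``x + nx*(y + ny*z)``; this ordering is stable and is the contract
    relied on by feature-index bookkeeping downstream.
    """

    data: np.ndarray
    voxel_coords: np.ndarray
    tr: float

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_voxels(self) -> int:
        return int(self.data.shape[1])


@dataclasses.dataclass
class LabelVolume:
    """Integer-labeled 3D parcellation; 0 means unlabeled."""

    labels: np.ndarray
    name_map: dict[int, str]

    def validate(self) -> None:
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = sorted(present - set(self.name_map))
        if missing:
            raise ValidationError(f"labels without a region name: {missing}")


# ---------------------------------------------------------------------------
# event tables


def validate_events(events: pd.DataFrame) -> list[str]:
    """Return a list of schema/content violations (empty when valid)."""
    errors = []
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        errors.append(f"events table missing column(s): {', '.join(missing)}")
        return errors
    onsets = events["onset"].to_numpy(dtype=float)
    if len(onsets) and not np.all(np.diff(onsets) > 0):
        bad = int(np.flatnonzero(np.diff(onsets) <= 0)[0]) + 1
        errors.append(f"onsets not strictly increasing (first violation at row {bad})")
    if len(events) and (events["duration"].to_numpy(dtype=float) <= 0).any():
        errors.append("durations must be positive")
    return errors


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated events file (BIDS-style columns)."""
    df = pd.read_csv(path, sep="\t").rename(columns=_MEMORY_RENAME)
    errors = validate_events(df)
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    return df


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.loc[:, list(EVENT_COLUMNS)].rename(columns=_DISK_RENAME)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_session(
    volume_path: str | Path,
    events_path: str | Path,
    tr: float | None = None,
    modality_tag: str = "audio",
    participant_id: str = "P0",
) -> SessionData:
    """Load a 4D NIfTI volume and its events table into a :class:`SessionData`.

    ``tr`` overrides the header pixdim[4] when given (headers of synthetic or
    converted files are not always trustworthy).
    """
    img = nib.load(str(volume_path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValidationError(
            f"{volume_path}: expected a 4-dimensional volume, got ndim={data.ndim}"
        )
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    events = read_events(events_path)
    session = SessionData(
        volume=data,
        tr=float(tr),
        modality_tag=modality_tag,
        participant_id=participant_id,
        events=events,
        affine=np.asarray(img.affine),
    )
    session.validate()
    return session


def write_session(session: SessionData, volume_path: str | Path, events_path: str | Path) -> None:
    """Write the volume as float32 NIfTI-1 (TR in the header) and the events TSV."""
    img = nib.Nifti1Image(session.volume.astype(np.float32), session.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (session.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(volume_path))
    write_events(session.events, events_path)


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"{path}: mask must be 3-dimensional, got ndim={data.ndim}")
    return data > 0


def write_mask(mask: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def read_label_volume(labels_path: str | Path, names_path: str | Path) -> LabelVolume:
    """Read an integer-label NIfTI atlas plus a two-column (label, name) TSV."""
    img = nib.load(str(labels_path))
    labels = np.asarray(img.dataobj).astype(int)
    names = pd.read_csv(names_path, sep="\t", header=None, names=["label", "name"])
    atlas = LabelVolume(labels=labels, name_map=dict(zip(names["label"].astype(int), names["name"])))
    atlas.validate()
    return atlas


def write_label_volume(atlas: LabelVolume, labels_path: str | Path, names_path: str | Path,
                       affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine), str(labels_path))
    pd.DataFrame(sorted(atlas.name_map.items())).to_csv(
        names_path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# masking


def mask_coords(mask: np.ndarray) -> np.ndarray:
    """Coordinates of true mask voxels ordered by linearized index, x fastest."""
    nx, ny, _ = mask.shape
    coords = np.argwhere(mask)
    lin = coords[:, 0] + nx * (coords[:, 1] + ny * coords[:, 2])
    return coords[np.argsort(lin)]


def apply_mask(session: SessionData, mask: np.ndarray) -> MaskedSeries:
    """Restrict a session's volume to mask voxels, yielding time x voxels data.

    Column order follows :func:`mask_coords`. The data is copied, never a view.
    """
    if tuple(mask.shape) != session.grid_shape:
        raise ValidationError(
            f"mask shape {tuple(mask.shape)} != volume spatial shape {session.grid_shape}"
        )
    if not mask.any():
        raise ValidationError("mask selects no voxels")
    coords = mask_coords(mask)
    data = session.volume[coords[:, 0], coords[:, 1], coords[:, 2], :].T.copy()
    return MaskedSeries(data=np.ascontiguousarray(data, dtype=float),
                        voxel_coords=coords, tr=session.tr)
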