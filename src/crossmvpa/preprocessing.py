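"""Voxel time-series conditioning and trial feature extraction.

The fixed preprocessing order is: per-run linear detrending, then per-session
z-scoring of every voxel time course, then conversion of the continuous series
into a trials x voxels feature matrix under one of three response models:

* boxcar — unweighted mean of the volumes in a post-stimulus window
  (delay, width), both in seconds; the study default is delay 4 s, width 4 s;
* HRF-weighted — gamma-kernel weighted mean over a window from onset;
* single volume — one volume at a fixed latency after onset, used for
  temporal accuracy profiling.

Window timing is measured from stimulus onset by default; a
``delay_origin="offset"`` switch measures it from stimulus offset instead
(the window then starts at onset + duration + delay). Windows are half-open,
``[start, start + width)``, so at TR = 1 s a width in seconds equals a number
of volumes.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .bold_data import MaskedSeries, ValidationError
from .synthetic_data import HRFParams, gamma_hrf

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class BoxcarSpec:
    """Post-stimulus averaging window: delay to window start and width, seconds."""

    delay: float = 4.0
    width: float = 4.0

    def validate(self, tr: float = 1.0) -> None:
        if not 0 <= self.delay <= 20:
            raise ValidationError(f"boxcar delay must be in [0, 20] s, got {self.delay}")
        if self.width < tr:
            raise ValidationError(f"boxcar width must cover >= 1 volume, got {self.width}")


@dataclasses.dataclass
class TrialFeatureMatrix:
    """Trials x voxels features with per-trial labels and bookkeeping.

    ``kept_rows`` indexes back into the event table the matrix was built from
    (trials whose window overran the series may have been dropped).
    """

    features: np.ndarray
    labels: np.ndarray
    stimulus_ids: np.ndarray
    repetitions: np.ndarray
    runs: np.ndarray
    voxel_coords: np.ndarray
    kept_rows: np.ndarray

    @property
    def n_trials(self) -> int:
        return int(self.features.shape[0])

    @property
    def n_voxels(self) -> int:
        return int(self.features.shape[1])

    def validate(self) -> None:
        if not np.isfinite(self.features).all():
            raise ValidationError("feature matrix contains non-finite values")
        if len(np.unique(self.labels)) > 2:
            raise ValidationError("more than two classes in labels")

    def subset_trials(self, rows: np.ndarray) -> "TrialFeatureMatrix":
        rows = np.asarray(rows)
        return TrialFeatureMatrix(
            features=self.features[rows],
            labels=self.labels[rows],
            stimulus_ids=self.stimulus_ids[rows],
            repetitions=self.repetitions[rows],
            runs=self.runs[rows],
            voxel_coords=self.voxel_coords,
            kept_rows=self.kept_rows[rows],
        )


# ---------------------------------------------------------------------------
# detrend / normalize


def run_boundaries(events: pd.DataFrame, n_volumes: int, tr: float) -> list[tuple[int, int]]:
    """Partition [0, n_volumes) into per-run segments.

    Each run's segment starts at its first stimulus onset (run 1 is extended
    back to volume 0) and ends where the next run starts; the final segment
    absorbs the trailing fixation block.
    """
    starts_s = events.groupby("run")["onset"].min().sort_index().to_numpy(dtype=float)
    starts = [int(np.floor(s / tr)) for s in starts_s]
    if starts:
        starts[0] = 0
    bounds = starts + [n_volumes]
    return [(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def detrend_linear(series: MaskedSeries, boundaries: list[tuple[int, int]]) -> MaskedSeries:
    """Subtract each voxel's least-squares line within every run segment."""
    segs = sorted(boundaries)
    covered = [v for a, b in segs for v in (a, b)]
    expected = [0] + [x for s in segs[1:] for x in (s[0], s[0])] + [series.n_timepoints]
    if covered != expected:
        raise ValidationError(f"boundaries {segs} do not partition [0, {series.n_timepoints})")
    out = series.data.copy()
    for a, b in segs:
        if b - a < 3:
            raise ValidationError(f"segment [{a}, {b}) shorter than 3 volumes")
        t = np.arange(b - a, dtype=float)
        tc = t - t.mean()
        seg = out[a:b]
        slope = (tc @ seg) / (tc @ tc)
        out[a:b] = seg - seg.mean(axis=0) - np.outer(tc, slope)
    return MaskedSeries(data=out, voxel_coords=series.voxel_coords, tr=series.tr)


def zscore(series: MaskedSeries) -> MaskedSeries:
    """Per voxel over the whole session: mean 0, population s.d. 1.

    Zero-variance voxels are set to all-zero with a logged warning rather than
    raising, matching how an empty cortical voxel should behave downstream.
    """
    mean = series.data.mean(axis=0)
    sd = series.data.std(axis=0)
    flat = sd == 0
    if flat.any():
        logger.warning("zscore: %d zero-variance voxel(s) set to 0", int(flat.sum()))
        sd = np.where(flat, 1.0, sd)
    out = (series.data - mean) / sd
    out[:, flat] = 0.0
    return MaskedSeries(data=out, voxel_coords=series.voxel_coords, tr=series.tr)


def preprocess(series: MaskedSeries, events: pd.DataFrame) -> MaskedSeries:
    """Standard conditioning chain: per-run detrend, then session z-score."""
    bounds = run_boundaries(events, series.n_timepoints, series.tr)
    return zscore(detrend_linear(series, bounds))


# ---------------------------------------------------------------------------
# trial extraction


def _window_starts(
    events: pd.DataFrame,
    series: MaskedSeries,
    delay: float,
    n_window: int,
    delay_origin: str,
    on_overrun: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Start volume of each trial's window; drop or reject overruns."""
    if delay_origin not in ("onset", "offset"):
        raise ValidationError(f"delay_origin must be 'onset' or 'offset', got {delay_origin!r}")
    base = events["onset"].to_numpy(dtype=float)
    if delay_origin == "offset":
        base = base + events["duration"].to_numpy(dtype=float)
    starts = np.round((base + delay) / series.tr).astype(int)
    bad = (starts < 0) | (starts + n_window > series.n_timepoints)
    if bad.any():
        if on_overrun == "drop":
            logger.info(
                "dropping %d trial(s) whose window overruns the series", int(bad.sum())
            )
        else:
            onsets = events["onset"].to_numpy(dtype=float)[bad]
            raise ValidationError(
                "trial window exceeds series extent for onsets "
                + ", ".join(f"{o:g}s" for o in onsets[:10])
                + ("..." if bad.sum() > 10 else "")
            )
    keep = np.flatnonzero(~bad)
    return starts[keep], keep


def _gather(series: MaskedSeries, starts: np.ndarray, n_window: int) -> np.ndarray:
    """(n_trials, n_window, n_voxels) stack of windows."""
    idx = starts[:, None] + np.arange(n_window)[None, :]
    return series.data[idx]


def _build_fm(series, events, feats, keep) -> TrialFeatureMatrix:
    ev = events.iloc[keep]
    fm = TrialFeatureMatrix(
        features=np.asarray(feats, dtype=float),
        labels=ev["category"].to_numpy(dtype=object).astype(str),
        stimulus_ids=ev["stimulus_id"].to_numpy(dtype=object).astype(str),
        repetitions=ev["repetition"].to_numpy(dtype=int),
        runs=ev["run"].to_numpy(dtype=int),
        voxel_coords=series.voxel_coords,
        kept_rows=np.asarray(keep, dtype=int),
    )
    fm.validate()
    return fm


def _warn_if_wide(events: pd.DataFrame, delay: float, width: float) -> None:
    onsets = events["onset"].to_numpy(dtype=float)
    if len(onsets) > 1:
        spacing = float(np.median(np.diff(onsets)))
        if delay + width > spacing + 1e-9:
            warnings.warn(
                f"window delay+width = {delay + width:g} s exceeds the "
                f"inter-trial interval ({spacing:g} s); features will mix "
                "adjacent trials",
                stacklevel=3,
            )


def extract_trials_boxcar(
    series: MaskedSeries,
    events: pd.DataFrame,
    spec: BoxcarSpec | None = None,
    delay_origin: str = "onset",
    on_overrun: str = "error",
) -> TrialFeatureMatrix:
    """Feature = unweighted mean of the volumes in [start+delay, start+delay+width)."""
    spec = BoxcarSpec() if spec is None else spec
    spec.validate(series.tr)
    _warn_if_wide(events, spec.delay, spec.width)
    n_window = int(round(spec.width / series.tr))
    starts, keep = _window_starts(events, series, spec.delay, n_window, delay_origin, on_overrun)
    feats = _gather(series, starts, n_window).mean(axis=1)
    return _build_fm(series, events, feats, keep)


def extract_trials_weighted(
    series: MaskedSeries,
    events: pd.DataFrame,
    weights: np.ndarray,
    delay_origin: str = "onset",
    on_overrun: str = "error",
) -> TrialFeatureMatrix:
    """Feature = normalized weighted mean over a window starting at onset.

    The generic primitive behind :func:`extract_trials_hrf`; ``weights`` has
    one entry per volume of the window and must not sum to zero.
    """
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total == 0:
        raise ValidationError("window weights sum to zero")
    starts, keep = _window_starts(events, series, 0.0, len(weights), delay_origin, on_overrun)
    stack = _gather(series, starts, len(weights))
    feats = np.tensordot(stack, weights / total, axes=([1], [0]))
    return _build_fm(series, events, feats, keep)


def extract_trials_hrf(
    series: MaskedSeries,
    events: pd.DataFrame,
    hrf: HRFParams | None = None,
    window_len: float = 12.0,
    delay_origin: str = "onset",
    on_overrun: str = "error",
) -> TrialFeatureMatrix:
    """Feature = gamma-kernel weighted mean over [onset, onset + window_len)."""
    hrf = HRFParams() if hrf is None else hrf
    n_window = int(round(window_len / series.tr))
    if n_window < 2:
        raise ValidationError("window_len must span at least 2 volumes")
    kernel = gamma_hrf(hrf, np.arange(n_window) * series.tr)
    return extract_trials_weighted(series, events, kernel, delay_origin, on_overrun)


def extract_single_volume(
    series: MaskedSeries,
    events: pd.DataFrame,
    latency: float,
    on_overrun: str = "error",
) -> TrialFeatureMatrix:
    """Feature = the single volume at onset + latency (latency in [0, 20] s)."""
    if not 0 <= latency <= 20:
        raise ValidationError(f"latency must be in [0, 20] s, got {latency}")
    starts, keep = _window_starts(events, series, latency, 1, "onset", on_overrun)
    feats = series.data[starts]
    return _build_fm(series, events, feats, keep)
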