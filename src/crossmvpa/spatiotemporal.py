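"""Event-related averages, category-difference time-courses and the
cross-session spatio-temporal similarity statistic, plus atlas region counts.

The cross-session fit statistic asks whether the *joint* spatial and temporal
shape of the category code is preserved between two sessions of the same
participant: for the voxels selected on the training session, each session's
per-voxel event-related average (ERA) over an 11 s trial window is computed
separately for mammals and tools; the mammal-minus-tool difference
time-courses are flattened (voxel-major) into one vector per session; and the
fit is their cosine similarity. Because voxel selection depends on the
training session, the statistic is direction-specific (audio->ortho vs
ortho->audio). A trial-level bootstrap (both sessions resampled
independently, stratified by category) provides a standard error.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .bold_data import LabelVolume, ValidationError
from .evaluation import PreparedSession
from .mvpa_core import anova_rank, select_top_k
from .preprocessing import BoxcarSpec, extract_trials_boxcar

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class EventRelatedAverage:
    """Per-voxel mean trial time-course of one category (voxels x timepoints)."""

    values: np.ndarray
    window: np.ndarray
    category: str
    n_trials: int
    voxel_subset: np.ndarray


@dataclasses.dataclass
class DifferenceTimecourse:
    """ERA(mammal) - ERA(tool), in that fixed order, per voxel."""

    values: np.ndarray
    voxel_subset: np.ndarray
    session_tag: str = ""


@dataclasses.dataclass
class SimilarityResult:
    """Cosine similarity of two sessions' difference time-courses."""

    cosine: float
    se: float
    direction_tag: str
    n_voxels: int


def trial_epochs(
    series,
    events: pd.DataFrame,
    voxel_subset: np.ndarray | None = None,
    window_len: float = 11.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """(n_trials, n_voxels, n_timepoints) stack of per-trial windows.

    Trials whose window overruns the series end are dropped with a log entry.
    """
    n_w = int(round(window_len / series.tr))
    starts = np.round(events["onset"].to_numpy(dtype=float) / series.tr).astype(int)
    ok = starts + n_w <= series.n_timepoints
    if (~ok).any():
        logger.info("trial_epochs: dropping %d overrunning trial(s)", int((~ok).sum()))
    starts = starts[ok]
    data = series.data if voxel_subset is None else series.data[:, voxel_subset]
    idx = starts[:, None] + np.arange(n_w)[None, :]
    return data[idx].transpose(0, 2, 1), events.iloc[np.flatnonzero(ok)].reset_index(drop=True)


def event_related_average(
    series,
    events: pd.DataFrame,
    category: str,
    voxel_subset: np.ndarray | None = None,
    window_len: float = 11.0,
) -> EventRelatedAverage:
    """Mean over one category's trials of the 11 s post-onset window."""
    if category not in set(events["category"]):
        raise ValidationError(f"category {category!r} absent from events")
    epochs, kept = trial_epochs(series, events, voxel_subset, window_len)
    rows = kept["category"].to_numpy() == category
    n_w = epochs.shape[2]
    if voxel_subset is None:
        voxel_subset = np.arange(series.n_voxels)
    return EventRelatedAverage(
        values=epochs[rows].mean(axis=0),
        window=np.arange(n_w) * series.tr,
        category=category,
        n_trials=int(rows.sum()),
        voxel_subset=np.asarray(voxel_subset),
    )


def difference_timecourse(
    era_mammal: EventRelatedAverage, era_tool: EventRelatedAverage
) -> DifferenceTimecourse:
    """Elementwise ERA(mammal) - ERA(tool)."""
    if not np.array_equal(era_mammal.voxel_subset, era_tool.voxel_subset):
        raise ValidationError("ERAs computed on different voxel subsets")
    if era_mammal.values.shape != era_tool.values.shape:
        raise ValidationError("ERA window shapes differ")
    return DifferenceTimecourse(
        values=era_mammal.values - era_tool.values,
        voxel_subset=era_mammal.voxel_subset,
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """dot(a, b) / (||a|| ||b||); undefined (error) for a zero-norm vector."""
    a = np.ravel(np.asarray(a, dtype=float))
    b = np.ravel(np.asarray(b, dtype=float))
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("cosine similarity undefined for a zero-norm vector")
    return float(a @ b / (na * nb))


def _category_diff(epochs: np.ndarray, labels: np.ndarray, rows_m=None, rows_t=None) -> np.ndarray:
    rows_m = np.flatnonzero(labels == "mammal") if rows_m is None else rows_m
    rows_t = np.flatnonzero(labels == "tool") if rows_t is None else rows_t
    return epochs[rows_m].mean(axis=0) - epochs[rows_t].mean(axis=0)


def cross_session_fit(
    train: PreparedSession,
    test: PreparedSession,
    k_voxels: int = 500,
    boxcar: BoxcarSpec | None = None,
    window_len: float = 11.0,
    bootstrap_B: int = 1000,
    seed: int = 0,
    direction_tag: str | None = None,
) -> SimilarityResult:
    """Cosine spatio-temporal fit between two sessions of one participant.

    Voxels are the top-k ANOVA-ranked on the *training* session's boxcar
    features (so the statistic is direction-specific). Each session's
    mammal-minus-tool difference time-courses over those voxels are flattened
    voxel-major and compared by cosine similarity; the SE is the s.d. of the
    statistic over ``bootstrap_B`` trial-level resamples.
    """
    fm = extract_trials_boxcar(train.series, train.events, boxcar)
    subset = select_top_k(anova_rank(fm), k_voxels)
    if direction_tag is None:
        direction_tag = f"{train.modality_tag}-{test.modality_tag}"

    ep_a, ev_a = trial_epochs(train.series, train.events, subset, window_len)
    ep_b, ev_b = trial_epochs(test.series, test.events, subset, window_len)
    lab_a = ev_a["category"].to_numpy().astype(str)
    lab_b = ev_b["category"].to_numpy().astype(str)
    cos = cosine_similarity(_category_diff(ep_a, lab_a), _category_diff(ep_b, lab_b))

    rng = np.random.default_rng(seed)
    groups = [
        [np.flatnonzero(lab == c) for c in ("mammal", "tool")]
        for lab in (lab_a, lab_b)
    ]
    boots = np.empty(bootstrap_B)
    for i in range(bootstrap_B):
        diffs = []
        for ep, (rows_m, rows_t) in zip((ep_a, ep_b), groups):
            rm = rng.choice(rows_m, size=len(rows_m), replace=True)
            rt = rng.choice(rows_t, size=len(rows_t), replace=True)
            diffs.append(_category_diff(ep, None, rm, rt))
        boots[i] = cosine_similarity(diffs[0], diffs[1])
    se = float(np.std(boots, ddof=1)) if bootstrap_B > 1 else 0.0
    return SimilarityResult(cosine=cos, se=se, direction_tag=direction_tag,
                            n_voxels=int(k_voxels))


# ---------------------------------------------------------------------------
# region counting


def count_by_region(
    selected_voxel_coords: np.ndarray,
    atlas: LabelVolume,
    top_n: int = 50,
) -> pd.DataFrame:
    """Count the top-n selected voxels per atlas region.

    ``selected_voxel_coords`` is assumed ranked most-informative first; only
    the first ``top_n`` rows are counted. Voxels on label 0 are reported as
    "unlabeled". Returns a frame with columns (label, region, count) sorted by
    descending count.
    """
    coords = np.asarray(selected_voxel_coords)[:top_n]
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError("selected_voxel_coords must be (n, 3)")
    shape = atlas.labels.shape
    if (coords < 0).any() or (coords >= np.asarray(shape)).any():
        raise ValidationError(
            f"voxel coordinates fall outside the atlas grid {shape}"
        )
    labels = atlas.labels[coords[:, 0], coords[:, 1], coords[:, 2]]
    values, counts = np.unique(labels, return_counts=True)
    rows = [
        {
            "label": int(v),
            "region": atlas.name_map.get(int(v), "unlabeled") if v != 0 else "unlabeled",
            "count": int(c),
        }
        for v, c in zip(values, counts)
    ]
    df = pd.DataFrame(rows, columns=["label", "region", "count"])
    return df.sort_values(["count", "label"], ascending=[False, True]).reset_index(drop=True)
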