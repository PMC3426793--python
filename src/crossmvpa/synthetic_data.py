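"""Synthetic two-session slow event-related fMRI generator.

Emulates the experimental design the decoding pipeline assumes: 40 concrete
concepts (20 land-mammals, 20 work tools) each presented once per run in
randomized order, 6 runs per session (240 trials), 3 s stimulus + 7 s rest
per trial, a 40 s fixation block after each run, TR = 1 s. The same stimuli
are presented in two sessions ("audio" and "ortho" modality tags) whose
category-informative voxel populations are partly shared and partly
session-specific, controlled by an overlap fraction rho.

The BOLD model is deliberately simple: per voxel,

    signal(t) = baseline + run-local linear drift
                + sum_trials amplitude(voxel, category) * HRF(t - onset)
                + iid Gaussian noise

with a single-gamma haemodynamic response parameterized directly by its peak
latency and full width at half maximum (defaults 7 s and 6 s). Informative
voxels carry +/-effect amplitudes with a randomized sign per voxel, so the
category code is a distributed pattern rather than a uniform contrast.
Everything is deterministic given the seeds.
"""

from __future__ import annotations

import dataclasses
import functools
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bold_data import LabelVolume, SessionData, mask_coords

MAMMALS = (
    "anteater", "armadillo", "beaver", "camel", "deer", "elephant", "fox",
    "giraffe", "gorilla", "hare", "hedgehog", "hippopotamus", "kangaroo",
    "koala", "mole", "monkey", "panda", "rhinoceros", "skunk", "zebra",
)
TOOLS = (
    "allen_key", "axe", "chainsaw", "craft_knife", "file", "hammer", "nail",
    "paint_roller", "plaster_trowel", "pliers", "plunger", "power_drill",
    "rake", "saw", "scraper", "scissors", "screw", "sickle", "spanner",
    "tape_measure",
)

CATEGORIES = ("mammal", "tool")

#: default category-effect amplitude, in units of the noise s.d.; chosen so
#: that the default cohort decodes within-session in the 80-90% regime typical
#: of slow event-related category decoding, with a cross-session penalty into
#: the 65-75% range at the default half-shared coding (see docs/methods.md)
DEFAULT_EFFECT_SIZE = 0.12


class InvalidSpecError(ValueError):
    """A design/noise/HRF specification violates its invariants."""


class CapacityError(ValueError):
    """More informative voxels requested than the mask contains."""


class GammaParameterizationError(ValueError):
    """No positive gamma shape/scale yields the requested peak and FWHM."""


# ---------------------------------------------------------------------------
# design


@dataclasses.dataclass
class DesignSpec:
    """Trial/run/session structure of one scanning session."""

    n_stimuli_per_category: int = 20
    n_runs: int = 6
    stim_duration: float = 3.0
    rest_duration: float = 7.0
    fixation_duration: float = 40.0
    tr: float = 1.0
    seed: int = 0

    #: number of categories is fixed by the mammal/tool decoding task
    n_categories = 2

    @property
    def trial_spacing(self) -> float:
        return self.stim_duration + self.rest_duration

    @property
    def trials_per_run(self) -> int:
        return self.n_stimuli_per_category * self.n_categories

    @property
    def n_trials(self) -> int:
        return self.trials_per_run * self.n_runs

    @property
    def run_span(self) -> float:
        """Seconds from a run's first onset to the end of its fixation block."""
        return self.trials_per_run * self.trial_spacing + self.fixation_duration

    @property
    def session_duration(self) -> float:
        return self.n_runs * self.run_span

    @property
    def n_volumes(self) -> int:
        return int(math.ceil(self.session_duration / self.tr))

    def validate(self) -> None:
        if self.n_stimuli_per_category < 1 or self.n_runs < 1:
            raise InvalidSpecError("counts must be positive")
        if min(self.stim_duration, self.rest_duration, self.tr) <= 0:
            raise InvalidSpecError("durations and tr must be positive")
        if self.fixation_duration < 0:
            raise InvalidSpecError("fixation_duration must be non-negative")


def _stimulus_ids(n_per_category: int) -> list[tuple[str, str]]:
    out = []
    for cat, names in (("mammal", MAMMALS), ("tool", TOOLS)):
        for i in range(n_per_category):
            name = names[i] if i < len(names) else f"{cat}_{i + 1:02d}"
            out.append((name, cat))
    return out


def make_design(spec: DesignSpec) -> pd.DataFrame:
    """Build the event table of one session.

    Each stimulus appears exactly once per run, in an order randomized per run
    by ``spec.seed``; a fixation block follows each run's final rest period.
    The returned frame carries ``attrs`` with tr, n_volumes and run_starts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    stimuli = _stimulus_ids(spec.n_stimuli_per_category)
    rows = []
    for run in range(1, spec.n_runs + 1):
        run_start = (run - 1) * spec.run_span
        order = rng.permutation(len(stimuli))
        for slot, j in enumerate(order):
            sid, cat = stimuli[j]
            rows.append(
                {
                    "onset": run_start + slot * spec.trial_spacing,
                    "duration": spec.stim_duration,
                    "stimulus_id": sid,
                    "category": cat,
                    "run": run,
                    "repetition": run,
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["tr"] = spec.tr
    df.attrs["n_volumes"] = spec.n_volumes
    df.attrs["run_starts"] = [(r - 1) * spec.run_span for r in range(1, spec.n_runs + 1)]
    return df


# ---------------------------------------------------------------------------
# ground truth


@dataclasses.dataclass
class GroundTruthMap:
    """Which voxels carry category information, and how strongly, per session.

    ``shared_*`` voxels code category identically in both sessions;
    ``a_*`` / ``b_*`` voxels are active only in session A ("audio") or
    session B ("ortho"). Amplitudes are signed: a voxel's amplitude applies to
    "mammal" trials and its negation to "tool" trials. The three sets are
    pairwise disjoint and lie inside the mask.
    """

    grid_shape: tuple[int, int, int]
    mask: np.ndarray
    shared_coords: np.ndarray
    shared_amp: np.ndarray
    a_coords: np.ndarray
    a_amp: np.ndarray
    b_coords: np.ndarray
    b_amp: np.ndarray
    overlap_rho: float
    effect_size: float

    _TAGS = {"A": "a", "audio": "a", "B": "b", "ortho": "b"}

    def active(self, session_tag: str) -> tuple[np.ndarray, np.ndarray]:
        """(coords, amplitudes) of all voxels informative in the given session."""
        side = self._TAGS.get(session_tag)
        if side is None:
            raise ValueError(f"unknown session_tag {session_tag!r}")
        coords = getattr(self, f"{side}_coords")
        amp = getattr(self, f"{side}_amp")
        return (
            np.concatenate([self.shared_coords, coords], axis=0),
            np.concatenate([self.shared_amp, amp]),
        )

    def informative_coord_set(self, session_tag: str) -> set[tuple[int, int, int]]:
        coords, _ = self.active(session_tag)
        return {tuple(int(v) for v in c) for c in coords}


def make_ground_truth(
    grid_shape: tuple[int, int, int] = (20, 20, 10),
    n_shared: int = 80,
    n_specific_per_session: int = 80,
    effect_size: float = DEFAULT_EFFECT_SIZE,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> GroundTruthMap:
    """Draw disjoint shared/session-specific informative voxel sets.

    Amplitude signs are randomized per voxel so the category code is a
    multivoxel pattern. ``overlap_rho = n_shared / (n_shared + n_specific)``.
    """
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if tuple(mask.shape) != tuple(grid_shape):
        raise InvalidSpecError("mask shape must equal grid_shape")
    if n_shared < 0 or n_specific_per_session < 0:
        raise InvalidSpecError("voxel counts must be non-negative")
    need = n_shared + 2 * n_specific_per_session
    available = int(mask.sum())
    if need > available:
        raise CapacityError(
            f"requested {need} informative voxels but mask holds only {available}"
        )
    rng = np.random.default_rng(seed)
    coords = mask_coords(mask)
    pick = rng.choice(available, size=need, replace=False)
    signs = rng.choice([-1.0, 1.0], size=need)
    amps = effect_size * signs
    s, a = n_shared, n_shared + n_specific_per_session
    denom = n_shared + n_specific_per_session
    return GroundTruthMap(
        grid_shape=tuple(grid_shape),
        mask=mask,
        shared_coords=coords[pick[:s]],
        shared_amp=amps[:s],
        a_coords=coords[pick[s:a]],
        a_amp=amps[s:a],
        b_coords=coords[pick[a:]],
        b_amp=amps[a:],
        overlap_rho=(n_shared / denom) if denom else float("nan"),
        effect_size=effect_size,
    )


# ---------------------------------------------------------------------------
# haemodynamic response


@dataclasses.dataclass
class HRFParams:
    """Single-gamma HRF described by its mode (peak) and FWHM, both in seconds."""

    peak: float = 7.0
    fwhm: float = 6.0
    amplitude: float = 1.0
    duration: float = 24.0

    def validate(self) -> None:
        if self.peak <= 0 or self.fwhm <= 0 or self.duration <= 0:
            raise InvalidSpecError("peak, fwhm and duration must be positive")


def unit_gamma(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    """Gamma density t^(k-1) e^(-t/theta) rescaled to a continuous max of 1.

    The mode sits at (k-1)*theta; the value there is 1 and the value at t=0
    is 0 (for k > 1).
    """
    t = np.asarray(t, dtype=float)
    mode = (shape - 1.0) * scale
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp((shape - 1.0) * np.log(tp / mode) + (mode - tp) / scale)
    return out


def numeric_fwhm(curve_fn, mode: float, scale_hint: float, dt: float = 0.01) -> float:
    """FWHM of a unimodal curve (max 1 at ``mode``) by linear interpolation."""
    t_max = mode + 5.0 * scale_hint
    # keep the grid bounded for absurdly wide curves; precision only matters
    # for sensible widths
    dt = max(dt, t_max / 2e6)
    t = np.arange(0.0, t_max, dt)
    g = curve_fn(t)
    while g[-1] > 0.4:
        t_max *= 2.0
        dt = max(dt, t_max / 2e6)
        t = np.arange(0.0, t_max, dt)
        g = curve_fn(t)

    def crossing(idx_a: int, idx_b: int) -> float:
        ga, gb = g[idx_a], g[idx_b]
        return t[idx_a] + (0.5 - ga) / (gb - ga) * dt

    imode = int(np.argmax(g))
    left = np.flatnonzero(g[:imode] < 0.5)
    i = left[-1] if len(left) else 0
    t_left = crossing(i, i + 1) if len(left) else 0.0
    right = imode + np.flatnonzero(g[imode:] < 0.5)[0]
    t_right = crossing(right - 1, right)
    return float(t_right - t_left)


@functools.lru_cache(maxsize=512)
def solve_gamma_shape(peak: float, fwhm: float) -> tuple[float, float]:
    """Find (shape k, scale theta) with mode = peak and numeric FWHM = fwhm.

    The FWHM at fixed mode is strictly decreasing in k, so a 1-D bracketing
    root find on log(k-1) suffices. Raises when no positive solution exists.
    """
    if peak <= 0 or fwhm <= 0:
        raise GammaParameterizationError("peak and fwhm must be positive")

    def width_minus_target(log_km1: float) -> float:
        k = 1.0 + math.exp(log_km1)
        theta = peak / (k - 1.0)
        # short-circuit: still above half max well beyond the target width
        # means the curve is certainly wider than requested
        if unit_gamma(np.array([peak + 2.0 * fwhm]), k, theta)[0] > 0.5:
            return 2.0 * fwhm
        w = numeric_fwhm(lambda t: unit_gamma(t, k, theta), peak, min(max(theta, fwhm / 4), 10 * fwhm))
        return w - fwhm

    lo, hi = math.log(1e-6), math.log(1e5)
    try:
        f_lo, f_hi = width_minus_target(lo), width_minus_target(hi)
        if f_lo * f_hi > 0:
            raise GammaParameterizationError(
                f"no gamma shape solves peak={peak}, fwhm={fwhm}"
            )
        root = brentq(width_minus_target, lo, hi, xtol=1e-10, rtol=1e-12)
    except (OverflowError, FloatingPointError) as exc:  # pragma: no cover
        raise GammaParameterizationError(str(exc)) from exc
    k = 1.0 + math.exp(root)
    return k, peak / (k - 1.0)


def gamma_hrf(params: HRFParams, t_grid: np.ndarray) -> np.ndarray:
    """Sample the HRF kernel on a non-negative, evenly spaced time grid.

    The continuous curve has its mode at ``params.peak``, numeric FWHM
    ``params.fwhm`` and maximum ``params.amplitude``; the kernel is zero at
    t = 0 and non-negative everywhere.
    """
    params.validate()
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0 or t_grid[0] < 0:
        raise InvalidSpecError("t_grid must be a non-negative 1-D grid")
    if len(t_grid) > 2:
        steps = np.diff(t_grid)
        if not np.allclose(steps, steps[0]):
            raise InvalidSpecError("t_grid must be evenly spaced")
    shape, scale = solve_gamma_shape(params.peak, params.fwhm)
    return params.amplitude * unit_gamma(t_grid, shape, scale)


# ---------------------------------------------------------------------------
# simulation


@dataclasses.dataclass
class NoiseSpec:
    """Additive nuisance model: baseline + run-local linear drift + iid noise."""

    sigma: float = 1.0
    drift_slope_sd: float = 0.01
    baseline: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.sigma < 0 or self.drift_slope_sd < 0:
            raise InvalidSpecError("sigma and drift_slope_sd must be non-negative")


def _design_meta(design: pd.DataFrame, tr: float | None):
    """(tr, n_volumes, run start volumes) from design attrs, or inferred."""
    tr = float(design.attrs.get("tr", 1.0) if tr is None else tr)
    run_starts_s = design.attrs.get("run_starts")
    if run_starts_s is None:
        run_starts_s = design.groupby("run")["onset"].min().sort_index().tolist()
    n_volumes = design.attrs.get("n_volumes")
    if n_volumes is None:
        # fall back: runs assumed equally long
        span = run_starts_s[1] - run_starts_s[0] if len(run_starts_s) > 1 else (
            float(design["onset"].max()) + 50.0
        )
        n_volumes = int(math.ceil(len(run_starts_s) * span / tr))
    starts_vol = [int(round(s / tr)) for s in run_starts_s]
    return tr, int(n_volumes), starts_vol


def simulate_session(
    design: pd.DataFrame,
    truth: GroundTruthMap,
    session_tag: str = "audio",
    hrf: HRFParams | None = None,
    noise: NoiseSpec | None = None,
    tr: float | None = None,
    participant_id: str = "sim",
) -> SessionData:
    """Simulate one session's 4D BOLD volume from a design and a ground truth.

    Each voxel's series is baseline + run-wise linear drift (re-zeroed at run
    boundaries) + the superposition of HRF kernels at trial onsets scaled by
    the voxel's signed category amplitude + iid Gaussian noise. Deterministic
    given ``noise.seed`` (RNG order: drift slopes per run, then noise).
    """
    hrf = HRFParams() if hrf is None else hrf
    noise = NoiseSpec() if noise is None else noise
    noise.validate()
    tr, n_vols, run_starts = _design_meta(design, tr)
    grid = truth.grid_shape

    kernel = gamma_hrf(hrf, np.arange(0.0, hrf.duration, tr))
    onset_vols = np.round(design["onset"].to_numpy(dtype=float) / tr).astype(int)
    impulses = {c: np.zeros(n_vols) for c in CATEGORIES}
    for vol_idx, cat in zip(onset_vols, design["category"]):
        impulses[cat][vol_idx] += 1.0
    reg = {c: np.convolve(impulses[c], kernel)[:n_vols] for c in CATEGORIES}
    # amplitude applies to mammal trials, its negation to tool trials
    diff_reg = reg["mammal"] - reg["tool"]

    rng = np.random.default_rng(noise.seed)
    volume = np.full(grid + (n_vols,), float(noise.baseline))

    bounds = run_starts + [n_vols]
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e <= s:
            continue
        slopes = rng.normal(0.0, noise.drift_slope_sd, size=grid)
        volume[..., s:e] += slopes[..., None] * np.arange(e - s, dtype=float)

    coords, amps = truth.active(session_tag)
    if len(coords):
        volume[coords[:, 0], coords[:, 1], coords[:, 2], :] += (
            amps[:, None] * diff_reg[None, :]
        )

    if noise.sigma > 0:
        volume += rng.normal(0.0, noise.sigma, size=volume.shape)

    modality = {"A": "audio", "B": "ortho"}.get(session_tag, session_tag)
    return SessionData(
        volume=volume,
        tr=tr,
        modality_tag=modality,
        participant_id=participant_id,
        events=design,
    )


def participant_seeds(seed: int, n: int = 4) -> list[int]:
    """Derive independent sub-seeds (< 2^31) from one base seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def make_participant(
    design_spec: DesignSpec | None = None,
    truth: GroundTruthMap | None = None,
    hrf: HRFParams | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    participant_id: str = "P1",
) -> tuple[SessionData, SessionData]:
    """Simulate the audio and ortho sessions of one participant.

    Both sessions share the same stimulus set and ground-truth shared voxels;
    stimulus orders and noise are independently randomized per session.
    """
    design_spec = DesignSpec() if design_spec is None else design_spec
    truth = make_ground_truth(seed=seed) if truth is None else truth
    noise = NoiseSpec() if noise is None else noise
    s_design_a, s_design_b, s_noise_a, s_noise_b = participant_seeds(seed)
    sessions = []
    for tag, ds, ns in (("audio", s_design_a, s_noise_a), ("ortho", s_design_b, s_noise_b)):
        spec = dataclasses.replace(design_spec, seed=ds)
        design = make_design(spec)
        n = dataclasses.replace(noise, seed=ns)
        sessions.append(
            simulate_session(design, truth, tag, hrf=hrf, noise=n,
                             participant_id=participant_id)
        )
    return sessions[0], sessions[1]


def make_synthetic_atlas(grid_shape: tuple[int, int, int], n_regions: int = 4) -> LabelVolume:
    """A simple parcellation splitting the grid into slabs along x.

    Synthetic stand-in for an anatomical atlas, for region-count reporting on
    simulated data.
    """
    nx = grid_shape[0]
    labels = np.zeros(grid_shape, dtype=int)
    edges = np.linspace(0, nx, n_regions + 1).astype(int)
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:]), start=1):
        labels[a:b, :, :] = i
    return LabelVolume(labels=labels, name_map={i: f"region_{i:02d}" for i in range(1, n_regions + 1)})


def write_participant_dataset(
    out_dir: str | Path,
    audio: SessionData,
    ortho: SessionData,
    mask: np.ndarray,
) -> None:
    """Write a two-session dataset (NIfTI volumes + mask + events TSVs)."""
    from .bold_data import write_mask, write_session

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tag, sess in (("audio", audio), ("ortho", ortho)):
        write_session(sess, out / f"bold_{tag}.nii.gz", out / f"events_{tag}.tsv")
    write_mask(mask, out / "mask.nii.gz")
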