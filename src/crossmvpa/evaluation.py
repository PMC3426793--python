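"""Cross-validation, accuracy statistics, grid search and temporal profiling.

Two evaluation schemes mirror the study design:

* within-session — leave-one-repetition-out 6-fold cross-validation: every
  stimulus contributes exactly five trials to each training partition and one
  to the corresponding test partition, and each of the 240 trials is tested
  exactly once;
* cross-session — a single split: train on all trials of one session (one
  stimulus modality), test on all trials of the other.

Feature selection (ANOVA top-k) is recomputed inside every training
partition, never on test data. Significance of an accuracy is assessed with
a one-sided exact binomial test against chance 0.5; for n = 240 trials the
smallest significant accuracy at alpha = 0.05 is 134/240 = 55.8%.

Temporal profiling decodes from one volume at a time at latencies 0..20 s
after stimulus onset; the resulting accuracy-vs-latency curve is summarized
by fitting baseline + amplitude * gamma(peak, fwhm) with multistart bounded
least squares.
"""

from __future__ import annotations

import dataclasses
import typing

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bold_data import MaskedSeries, SessionData, ValidationError, apply_mask
from .mvpa_core import anova_rank, predict, select_top_k, train_plr
from .preprocessing import (
    BoxcarSpec,
    TrialFeatureMatrix,
    extract_single_volume,
    extract_trials_boxcar,
    preprocess,
)
from .synthetic_data import numeric_fwhm, solve_gamma_shape, unit_gamma

CONDITION_TAGS = ("audio-audio", "ortho-ortho", "audio-ortho", "ortho-audio")


class PreparedSession(typing.NamedTuple):
    """A preprocessed (masked, detrended, z-scored) session plus its events."""

    series: MaskedSeries
    events: pd.DataFrame
    modality_tag: str = ""


def prepare_session(session: SessionData, mask: np.ndarray) -> PreparedSession:
    """Mask, detrend and z-score one session."""
    series = preprocess(apply_mask(session, mask), session.events)
    return PreparedSession(series=series, events=session.events,
                           modality_tag=session.modality_tag)


# ---------------------------------------------------------------------------
# fold schemes


@dataclasses.dataclass
class FoldScheme:
    """Train/test trial-index partitions plus a tag naming the scheme."""

    folds: list[tuple[np.ndarray, np.ndarray]]
    scheme_tag: str


def make_within_folds(events: pd.DataFrame) -> FoldScheme:
    """Leave-one-repetition-out folds; fold i tests repetition i+1.

    Requires every stimulus to appear exactly once per repetition index.
    """
    reps = events["repetition"].to_numpy(dtype=int)
    rep_values = np.unique(reps)
    for sid, grp in events.groupby("stimulus_id"):
        got = sorted(grp["repetition"].tolist())
        if got != rep_values.tolist():
            raise ValidationError(
                f"stimulus {sid!r} has repetitions {got}, expected {rep_values.tolist()}"
            )
    folds = []
    for r in rep_values:
        test = np.flatnonzero(reps == r)
        train = np.flatnonzero(reps != r)
        folds.append((train, test))
    return FoldScheme(folds=folds, scheme_tag=f"within-{len(rep_values)}fold")


# ---------------------------------------------------------------------------
# accuracy bookkeeping


@dataclasses.dataclass
class AccuracyResult:
    """Pooled trial-wise decoding outcome with its exact binomial p-value."""

    n_correct: int
    n_total: int
    accuracy: float
    p_value: float
    per_trial_outcomes: np.ndarray

    @classmethod
    def from_outcomes(cls, outcomes: np.ndarray, chance: float = 0.5) -> "AccuracyResult":
        outcomes = np.asarray(outcomes, dtype=int)
        n = len(outcomes)
        k = int(outcomes.sum())
        p = float(stats.binom.sf(k - 1, n, chance)) if n else 1.0
        return cls(n_correct=k, n_total=n, accuracy=k / n if n else np.nan,
                   p_value=p, per_trial_outcomes=outcomes)


@dataclasses.dataclass
class ThresholdResult:
    """Smallest accuracy significantly above chance (one-sided exact binomial)."""

    n: int
    chance: float
    alpha: float
    k: int
    fraction: float
    percent: float


def binomial_threshold(n: int, chance: float = 0.5, alpha: float = 0.05) -> ThresholdResult:
    """Smallest k/n with one-sided exact tail P(X >= k | n, chance) < alpha."""
    if n < 1 or not (0 < chance < 1) or not (0 < alpha < 1):
        raise ValidationError("need n >= 1, chance and alpha in (0, 1)")
    ks = np.arange(n + 1)
    tails = stats.binom.sf(ks - 1, n, chance)
    k = int(ks[np.flatnonzero(tails < alpha)[0]]) if (tails < alpha).any() else n + 1
    frac = k / n
    return ThresholdResult(n=n, chance=chance, alpha=alpha, k=k,
                           fraction=frac, percent=round(100.0 * frac, 1))


def chance_band(n: int, chance: float = 0.5, level: float = 0.95) -> tuple[float, float]:
    """Central binomial acceptance band for an accuracy on n trials."""
    lo = stats.binom.ppf((1 - level) / 2, n, chance) / n
    hi = stats.binom.ppf(1 - (1 - level) / 2, n, chance) / n
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# decoding


def decode_feature_matrices(
    train_fm: TrialFeatureMatrix,
    test_fm: TrialFeatureMatrix | None = None,
    folds: FoldScheme | None = None,
    k: int = 500,
    lam: float = 1.0,
    return_models: bool = False,
):
    """Core decode loop on already-extracted features.

    Within-session: iterate folds, rank + select + train on the training rows
    only, test on the held-out rows; outcomes are pooled in original trial
    order. Cross-session: a single split using all of ``train_fm``.
    """
    models = []
    if test_fm is not None:
        ranking = anova_rank(train_fm)
        subset = select_top_k(ranking, k)
        model = train_plr(train_fm, lam=lam, feature_subset=subset)
        _, labels = predict(model, test_fm)
        outcomes = (labels == test_fm.labels).astype(int)
        models.append(model)
    else:
        if folds is None:
            raise ValidationError("within-session decoding needs a fold scheme")
        outcomes = np.full(train_fm.n_trials, -1, dtype=int)
        for train_idx, test_idx in folds.folds:
            tr = train_fm.subset_trials(train_idx)
            te = train_fm.subset_trials(test_idx)
            ranking = anova_rank(tr)
            subset = select_top_k(ranking, k)
            model = train_plr(tr, lam=lam, feature_subset=subset)
            _, labels = predict(model, te)
            outcomes[test_idx] = (labels == te.labels).astype(int)
            models.append(model)
        if (outcomes < 0).any():
            raise ValidationError("fold scheme does not test every trial exactly once")
    result = AccuracyResult.from_outcomes(outcomes)
    return (result, models) if return_models else result


def _extract(prepared: PreparedSession, extract: str, boxcar: BoxcarSpec | None,
             latency: float, delay_origin: str, on_overrun: str) -> TrialFeatureMatrix:
    if extract == "boxcar":
        return extract_trials_boxcar(prepared.series, prepared.events,
                                     boxcar, delay_origin, on_overrun)
    if extract == "single":
        return extract_single_volume(prepared.series, prepared.events, latency, on_overrun)
    raise ValidationError(f"unknown extraction model {extract!r}")


def run_decoding(
    train: PreparedSession,
    test: PreparedSession | None = None,
    scheme: str = "within",
    boxcar: BoxcarSpec | None = None,
    k: int = 500,
    lam: float = 1.0,
    extract: str = "boxcar",
    latency: float = 0.0,
    delay_origin: str = "onset",
    on_overrun: str = "error",
    return_models: bool = False,
):
    """One full decoding analysis on preprocessed sessions.

    ``scheme='within'`` runs leave-one-repetition-out cross-validation on
    ``train``; ``scheme='cross'`` trains on all of ``train`` and tests on all
    of ``test`` (feature selection then uses all training-session trials,
    since the cross-session scheme is a single split).
    """
    boxcar = BoxcarSpec() if boxcar is None else boxcar
    train_fm = _extract(train, extract, boxcar, latency, delay_origin, on_overrun)
    if scheme == "within":
        if test is not None:
            raise ValidationError("within-session scheme takes a single session")
        folds = make_within_folds(train.events.iloc[train_fm.kept_rows].reset_index(drop=True))
        return decode_feature_matrices(train_fm, folds=folds, k=k, lam=lam,
                                       return_models=return_models)
    if scheme == "cross":
        if test is None:
            raise ValidationError("cross-session scheme needs a test session")
        test_fm = _extract(test, extract, boxcar, latency, delay_origin, on_overrun)
        return decode_feature_matrices(train_fm, test_fm=test_fm, k=k, lam=lam,
                                       return_models=return_models)
    raise ValidationError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# boxcar parameter grid


@dataclasses.dataclass
class AccuracyGrid:
    """Decoding accuracy over a (delay, width) boxcar grid for one condition.

    ``accuracy[i, j]`` is the accuracy at width ``widths[i]`` and delay
    ``delays[j]`` (delay on the horizontal axis, width on the vertical).
    """

    delays: np.ndarray
    widths: np.ndarray
    accuracy: np.ndarray
    condition_tag: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.accuracy,
                            index=pd.Index(self.widths, name="width"),
                            columns=pd.Index(self.delays, name="delay"))


def grid_search(
    train: PreparedSession,
    test: PreparedSession | None = None,
    scheme: str = "within",
    delays: typing.Sequence[float] = tuple(range(1, 10)),
    widths: typing.Sequence[float] = tuple(range(1, 10)),
    k: int = 500,
    lam: float = 1.0,
    delay_origin: str = "onset",
    condition_tag: str = "",
    manifest: list | None = None,
) -> AccuracyGrid:
    """Run one decoding per (delay, width) cell; 9 x 9 = 81 cells by default.

    Cells whose window exceeds the data are recorded as NaN, never fabricated.
    Every run is appended to ``manifest`` (if given) for auditability.
    """
    delays = np.asarray(list(delays), dtype=float)
    widths = np.asarray(list(widths), dtype=float)
    acc = np.full((len(widths), len(delays)), np.nan)
    for i, width in enumerate(widths):
        for j, delay in enumerate(delays):
            spec = BoxcarSpec(delay=float(delay), width=float(width))
            entry = {
                "condition": condition_tag,
                "scheme": scheme,
                "delay": float(delay),
                "width": float(width),
                "k": k,
                "lambda": lam,
            }
            try:
                res = run_decoding(train, test, scheme=scheme, boxcar=spec, k=k,
                                   lam=lam, delay_origin=delay_origin)
                acc[i, j] = res.accuracy
                entry.update(accuracy=res.accuracy, n=res.n_total, status="ok")
            except ValidationError as exc:
                entry.update(accuracy=np.nan, n=0, status=f"missing: {exc}")
            if manifest is not None:
                manifest.append(entry)
    return AccuracyGrid(delays=delays, widths=widths, accuracy=acc,
                        condition_tag=condition_tag)


# ---------------------------------------------------------------------------
# temporal profile and gamma fit


@dataclasses.dataclass
class TemporalProfile:
    """Decoding accuracy as a function of single-volume latency after onset."""

    latencies: np.ndarray
    accuracy: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"latency": self.latencies, "accuracy": self.accuracy})


def temporal_profile(
    train: PreparedSession,
    test: PreparedSession | None = None,
    scheme: str = "within",
    latencies: typing.Sequence[float] = tuple(range(21)),
    k: int = 500,
    lam: float = 1.0,
) -> TemporalProfile:
    """Single-volume decoding accuracy at each latency (default 0..20 s).

    Trials whose volume at a long latency falls beyond the series end are
    dropped (logged), so late-latency accuracies may pool fewer trials.
    """
    latencies = np.asarray(list(latencies), dtype=float)
    acc = np.empty(len(latencies))
    for i, lat in enumerate(latencies):
        res = run_decoding(train, test, scheme=scheme, extract="single",
                           latency=float(lat), k=k, lam=lam, on_overrun="drop")
        acc[i] = res.accuracy
    return TemporalProfile(latencies=latencies, accuracy=acc)


@dataclasses.dataclass
class GammaFit:
    """baseline + amplitude * gamma(peak, fwhm) fitted to an accuracy profile."""

    peak: float
    fwhm: float
    amplitude: float
    baseline: float
    rss: float
    ok: bool


def fit_gamma_profile(profile: TemporalProfile, chance_floor: float = 0.5) -> GammaFit:
    """Multistart bounded least-squares gamma fit of a temporal profile.

    The curve is parameterized internally by gamma (shape, scale); starts are
    seeded at peaks {3, 5, 7, 9} s with FWHM 6 s and the best residual sum of
    squares is kept. The reported peak is the fitted mode and the FWHM is
    computed numerically from the fitted curve. A flat profile (amplitude
    below 0.02, i.e. two accuracy points) or fewer than 5 points above the
    chance floor yields an explicit no-fit result (``ok=False``).
    """
    t = np.asarray(profile.latencies, dtype=float)
    a = np.asarray(profile.accuracy, dtype=float)
    keep = np.isfinite(a)
    t, a = t[keep], a[keep]
    if int((a > chance_floor).sum()) < 5:
        return GammaFit(np.nan, np.nan, 0.0, float(np.mean(a)) if len(a) else np.nan,
                        np.nan, ok=False)

    def residuals(params):
        base, amp, shape, scale = params
        return base + amp * unit_gamma(t, shape, scale) - a

    best = None
    for peak0 in (3.0, 5.0, 7.0, 9.0):
        k0, theta0 = solve_gamma_shape(peak0, 6.0)
        x0 = [chance_floor, max(float(a.max() - chance_floor), 0.05), k0, theta0]
        try:
            sol = optimize.least_squares(
                residuals, x0,
                bounds=([0.0, 0.0, 1.01, 1e-3], [1.0, 2.0, 2000.0, 50.0]),
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        return GammaFit(np.nan, np.nan, np.nan, np.nan, np.nan, ok=False)
    rss, (base, amp, shape, scale) = best
    peak = (shape - 1.0) * scale
    if amp < 0.02 or not (0 < peak < 20):
        return GammaFit(float(peak), np.nan, float(amp), float(base), rss, ok=False)
    fwhm = numeric_fwhm(lambda tt: unit_gamma(tt, shape, scale), peak,
                        max(scale, 1.0))
    return GammaFit(float(peak), float(fwhm), float(amp), float(base), rss, ok=True)


def profile_correlation(a: TemporalProfile, b: TemporalProfile) -> float:
    """Pearson correlation between two accuracy profiles on the same grid."""
    if not np.array_equal(a.latencies, b.latencies):
        raise ValidationError("profiles have different latency grids")
    if np.std(a.accuracy) == 0 or np.std(b.accuracy) == 0:
        raise ValidationError("zero-variance profile has no defined correlation")
    return float(stats.pearsonr(a.accuracy, b.accuracy).statistic)
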