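"""Dwell-time survival analysis and two-exponential dissociation kinetics.

The pipeline implemented here turns tracks of stationary single molecules into
dissociation rates:

1. each track contributes one dwell time, ``(last frame - first frame) *
   frame_interval``, with gap-bridged frames counted as bound;
2. dwells are pooled into an empirical survival curve ``S(t) = P(dwell >= t)``;
3. a two-component exponential decay ``S(t) = f e^{-k_fast (t - t0)} +
   (1 - f) e^{-k_slow (t - t0)}`` is fitted; the slow component is the
   apparent dissociation rate of the specific bound state, while the fast
   component absorbs transient, non-specific interactions;
4. the apparent rate is corrected for photobleaching by subtracting the
   apparent rate of a stably bound histone (H2B) control measured the same
   way; the residence time is the inverse of the corrected rate.

The time at which the fitted model falls to 1% bound is also reported, as a
fit-shape-robust summary of binding stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .tracking import Track

logger = logging.getLogger(__name__)

__all__ = [
    "DwellRecord",
    "SurvivalCurve",
    "BiExpFit",
    "KineticSummary",
    "ConditionComparison",
    "InsufficientDataError",
    "FitFailureError",
    "CorrectionInvalidError",
    "extract_dwells",
    "build_survival",
    "fit_biexponential",
    "fit_biexponential_mle",
    "time_to_fraction",
    "correct_photobleach",
    "summarize_conditions",
]


class InsufficientDataError(ValueError):
    """Too few dwell times to build a survival curve."""


class FitFailureError(RuntimeError):
    """The survival-curve fit failed to converge from every start."""


class CorrectionInvalidError(ValueError):
    """Photobleach correction produced a non-positive rate."""


@dataclass(frozen=True)
class DwellRecord:
    track_id: int
    duration: float  # s, (end - start) * frame_interval
    n_frames: int  # frames spanned, gaps included
    censored: bool  # track reaches the final movie frame
    cell_id: str = ""
    replicate_id: str = ""
    condition: str = ""


@dataclass(frozen=True)
class SurvivalCurve:
    """Empirical fraction of molecules still bound as a function of dwell time."""

    times: np.ndarray
    survival: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly ascending")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")


@dataclass(frozen=True)
class BiExpFit:
    f: float  # fast fraction
    k_fast: float  # 1/s
    k_slow: float  # 1/s
    t0: float  # origin shift, s (minimum resolvable dwell)
    rss: float
    converged: bool
    collapsed: bool  # True when the two components are indistinguishable

    def survival(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.f * np.exp(-self.k_fast * (t - self.t0)) + (1.0 - self.f) * np.exp(
            -self.k_slow * (t - self.t0)
        )


@dataclass(frozen=True)
class KineticSummary:
    k_apparent: float  # slow component of the fit, 1/s
    k_h2b: float  # apparent rate of the H2B photobleach control, 1/s
    k_corrected: float  # 1/s
    residence_time: float  # s
    t_1pct: float  # s
    replicate_id: str = ""
    condition: str = ""


@dataclass
class ConditionComparison:
    """Replicate-level mitosis vs interphase comparison."""

    table: pd.DataFrame  # per condition: mean/sem of k_corrected, residence_time, t_1pct, n
    ratio_residence: float  # mitotic / interphase mean residence time
    ratio_t1pct: float
    paired_ratios: pd.DataFrame | None  # per-replicate ratios when replicates pair up
    p_value: float | None  # two-tailed t-test on replicate residence times
    t_statistic: float | None


# ---------------------------------------------------------------------------


def extract_dwells(
    tracks: list[Track],
    frame_interval: float,
    n_frames_movie: int,
    min_frames: int = 3,
    *,
    cell_id: str = "",
    replicate_id: str = "",
    condition: str = "",
) -> list[DwellRecord]:
    """One dwell record per track spanning at least ``min_frames`` frames.

    Duration is (end frame - first frame) * frame_interval; a track that is
    still present on the movie's last frame is right-censored.
    """
    if min_frames < 2:
        raise ValueError("min_frames must be >= 2")
    records = []
    for t in tracks:
        if t.n_frames_spanned < min_frames:
            continue
        records.append(
            DwellRecord(
                track_id=t.id,
                duration=t.duration(frame_interval),
                n_frames=t.n_frames_spanned,
                censored=t.end_frame == n_frames_movie - 1,
                cell_id=cell_id,
                replicate_id=replicate_id,
                condition=condition,
            )
        )
    return records


def build_survival(dwells, min_dwells: int = 10) -> SurvivalCurve:
    """Empirical survival curve S(t) = (# dwells >= t) / n.

    ``dwells`` is a sequence of DwellRecord (censored records are excluded)
    or of raw durations in seconds.  S is evaluated at each distinct observed
    duration; by construction the first point is (min duration, 1).
    """
    if len(dwells) and isinstance(dwells[0], DwellRecord):
        durations = np.array([d.duration for d in dwells if not d.censored])
    else:
        durations = np.asarray(dwells, dtype=float)
    n = len(durations)
    if n < min_dwells:
        raise InsufficientDataError(
            f"need at least {min_dwells} uncensored dwells to build a survival curve, got {n}"
        )
    times = np.unique(durations)
    # S(t) = fraction of dwells >= t; at the i-th distinct time that is
    # 1 - (number strictly smaller) / n
    smaller = np.searchsorted(np.sort(durations), times, side="left")
    survival = 1.0 - smaller / n
    return SurvivalCurve(times=times, survival=survival, n=n)


# ---------------------------------------------------------------------------


def _biexp_residuals(p, t, s, t0):
    f, k_slow, ratio = p
    k_fast = k_slow * ratio
    return (f * np.exp(-k_fast * (t - t0)) + (1 - f) * np.exp(-k_slow * (t - t0))) - s


def _biexp_jacobian(p, t, s, t0):
    f, k_slow, ratio = p
    dt = t - t0
    ef = np.exp(-k_slow * ratio * dt)
    es = np.exp(-k_slow * dt)
    return np.stack(
        [ef - es, -f * ratio * dt * ef - (1 - f) * dt * es, -f * k_slow * dt * ef], axis=1
    )


def fit_biexponential(
    curve: SurvivalCurve,
    t0: float | None = None,
    *,
    collapse_ratio: float = 1.5,
) -> BiExpFit:
    """Unweighted least-squares fit of the two-exponential survival model.

    The fit is parametrized as ``(f, k_slow, ratio = k_fast / k_slow >= 1)``
    so the constraint ``k_fast >= k_slow > 0`` holds by construction, and is
    restarted from a grid of log-spaced rate pairs around a data-driven rate
    scale; the best (lowest-RSS) solution wins.  When the best fit is
    effectively single-exponential (``k_fast / k_slow < collapse_ratio`` or f
    outside [0.01, 0.99]) a single exponential is refitted and returned with
    ``collapsed=True`` and both rates set to the single rate.
    """
    t = curve.times
    s = curve.survival
    if t0 is None:
        t0 = float(t[0])

    # data-driven rate scale: overall decay between first and last point
    span = max(float(t[-1] - t0), 1e-9)
    k_mid = -np.log(max(float(s[-1]), 1e-6)) / span
    starts = [
        (f0, max(ks, 1e-8), r0)
        for ks in (0.3 * k_mid, k_mid, 3.0 * k_mid)
        for r0 in (5.0, 20.0)
        for f0 in (0.3, 0.7)
    ]
    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                _biexp_residuals,
                x0=list(x0),
                jac=_biexp_jacobian,
                args=(t, s, t0),
                bounds=([0.0, 1e-9, 1.0], [1.0, np.inf, np.inf]),
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitFailureError(
            f"two-exponential fit failed from all {len(starts)} starts "
            f"(n={curve.n}, span={span:.3g}s)"
        )
    rss = float(2 * best.cost)
    f, k_slow, ratio = best.x
    f = float(f)
    k_slow = float(k_slow)
    k_fast = k_slow * float(ratio)

    if k_fast / k_slow < collapse_ratio or not 0.01 <= f <= 0.99:
        k_single, rss1 = _fit_single_exponential(t, s, t0, k_mid)
        return BiExpFit(f=0.0, k_fast=k_single, k_slow=k_single, t0=t0, rss=rss1,
                        converged=True, collapsed=True)
    return BiExpFit(f=f, k_fast=k_fast, k_slow=k_slow, t0=t0, rss=rss,
                    converged=True, collapsed=False)


def _fit_single_exponential(t, s, t0, k_init):
    def resid(k):
        return np.exp(-k[0] * (t - t0)) - s

    best = None
    for k0 in (0.1 * k_init, k_init, 10 * k_init):
        res = optimize.least_squares(resid, x0=[max(k0, 1e-8)], bounds=([1e-9], [np.inf]))
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[1]:
            best = (float(res.x[0]), rss)
    return best


def fit_biexponential_mle(
    durations: np.ndarray,
    t0: float,
    *,
    collapse_ratio: float = 1.5,
) -> BiExpFit:
    """Maximum-likelihood cross-check fit on raw dwell times.

    Maximizes the likelihood of the two-component exponential mixture
    left-truncated at ``t0`` (only dwells >= t0 are observable).  Provided as
    an independent check on the least-squares survival-curve fit; the two
    should agree on the slow rate within sampling error.
    """
    x = np.asarray(durations, dtype=float)
    x = x[x >= t0]
    if len(x) < 10:
        raise InsufficientDataError(f"need >= 10 dwells above t0 for the MLE, got {len(x)}")

    def nll(theta):
        f = 1.0 / (1.0 + np.exp(-theta[0]))
        k_slow = np.exp(theta[1])
        k_fast = k_slow * (1.0 + np.exp(theta[2]))
        # truncated mixture density: f ke^{-k(x-t0)} terms reweighted by
        # component survival at t0
        w_fast = f * np.exp(-k_fast * t0)
        w_slow = (1 - f) * np.exp(-k_slow * t0)
        z = w_fast + w_slow
        dens = (w_fast * k_fast * np.exp(-k_fast * (x - t0))
                + w_slow * k_slow * np.exp(-k_slow * (x - t0))) / z
        return -np.sum(np.log(np.maximum(dens, 1e-300)))

    k_init = 1.0 / max(np.mean(x) - t0, 1e-6)
    best = None
    for f0 in (-1.0, 0.0, 1.0):
        for lk in (np.log(k_init) - 1, np.log(k_init)):
            for lr in (0.0, 2.0):
                res = optimize.minimize(nll, x0=[f0, lk, lr], method="Nelder-Mead",
                                        options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
                if best is None or res.fun < best.fun:
                    best = res
    f = 1.0 / (1.0 + np.exp(-best.x[0]))
    k_slow = float(np.exp(best.x[1]))
    k_fast = k_slow * (1.0 + float(np.exp(best.x[2])))
    collapsed = k_fast / k_slow < collapse_ratio or not 0.01 <= f <= 0.99
    if collapsed:
        k = 1.0 / max(np.mean(x) - t0, 1e-9)  # truncated-exponential MLE closed form
        return BiExpFit(f=0.0, k_fast=k, k_slow=k, t0=t0, rss=np.nan,
                        converged=bool(best.success), collapsed=True)
    return BiExpFit(f=f, k_fast=k_fast, k_slow=k_slow, t0=t0, rss=np.nan,
                    converged=bool(best.success), collapsed=False)


# ---------------------------------------------------------------------------


def time_to_fraction(fit: BiExpFit, p: float, t0: float | None = None) -> float:
    """Time at which the fitted survival model falls to fraction ``p``.

    For a collapsed (single-exponential) fit the closed form
    ``t0 + ln(1/p) / k_slow`` is used; otherwise the root of
    ``S(t) - p = 0`` is found by bisection to a relative tolerance of 1e-6.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if t0 is None:
        t0 = fit.t0
    if p == 1.0:
        return t0
    if fit.collapsed or fit.f in (0.0, 1.0) or fit.k_fast == fit.k_slow:
        k = fit.k_fast if fit.f == 1.0 else fit.k_slow
        return t0 + np.log(1.0 / p) / k

    def g(t):
        return (fit.f * np.exp(-fit.k_fast * (t - t0))
                + (1 - fit.f) * np.exp(-fit.k_slow * (t - t0)) - p)

    # bracket: S is strictly decreasing from 1 at t0 and S(hi) < p because
    # the fast component decays strictly faster than the slow one
    hi = t0 + np.log(1.0 / p) / fit.k_slow
    return float(optimize.bisect(g, t0, hi, rtol=1e-6))


def correct_photobleach(k_apparent: float, k_h2b: float) -> tuple[float, float]:
    """Subtract the H2B control's apparent rate; return (k_corrected, residence).

    Raises :class:`CorrectionInvalidError` when the correction is non-positive
    (the TF would appear more stable than the histone control) — never
    silently clamped.
    """
    if k_apparent <= 0 or k_h2b < 0:
        raise ValueError("rates must be positive (k_h2b may be 0)")
    k_corrected = k_apparent - k_h2b
    if k_corrected <= 0:
        raise CorrectionInvalidError(
            f"k_apparent ({k_apparent:.4g}) <= k_h2b ({k_h2b:.4g}): "
            "TF appears more stable than the H2B photobleaching control"
        )
    return k_corrected, 1.0 / k_corrected


def summarize_replicate(
    dwells,
    h2b_fit: BiExpFit,
    *,
    t0: float | None = None,
    p: float = 0.01,
    replicate_id: str = "",
    condition: str = "",
) -> KineticSummary:
    """Survival → fit → bleach correction for one biological replicate."""
    curve = build_survival(dwells)
    fit = fit_biexponential(curve, t0)
    k_apparent = fit.k_slow
    k_h2b = h2b_fit.k_slow
    k_corr, residence = correct_photobleach(k_apparent, k_h2b)
    return KineticSummary(
        k_apparent=k_apparent,
        k_h2b=k_h2b,
        k_corrected=k_corr,
        residence_time=residence,
        t_1pct=time_to_fraction(fit, p),
        replicate_id=replicate_id,
        condition=condition,
    )


def summarize_conditions(summaries: list[KineticSummary]) -> ConditionComparison:
    """Aggregate per-replicate summaries into a mitosis/interphase comparison.

    Means and SEMs are computed over biological replicates (never over cells);
    the headline ratio is (mean mitotic residence) / (mean interphase
    residence), with per-replicate ratios also reported when replicate ids
    pair up across conditions.  Significance is a standard two-tailed t-test
    on the replicate residence times.  With a single replicate per condition,
    means are reported and SEM / test are marked unavailable (None / NaN).
    """
    df = pd.DataFrame(
        {
            "replicate_id": [s.replicate_id for s in summaries],
            "condition": [s.condition for s in summaries],
            "k_corrected": [s.k_corrected for s in summaries],
            "residence_time": [s.residence_time for s in summaries],
            "t_1pct": [s.t_1pct for s in summaries],
        }
    )
    conditions = set(df["condition"])
    if not conditions <= {"interphase", "mitosis"}:
        raise ValueError(f"conditions must be 'interphase'/'mitosis', got {conditions}")

    agg = df.groupby("condition")[["k_corrected", "residence_time", "t_1pct"]].agg(
        ["mean", "sem", "count"]
    )
    mito = df[df["condition"] == "mitosis"]
    inter = df[df["condition"] == "interphase"]
    ratio_res = float(mito["residence_time"].mean() / inter["residence_time"].mean())
    ratio_t1 = float(mito["t_1pct"].mean() / inter["t_1pct"].mean())

    paired = None
    shared = sorted(set(mito["replicate_id"]) & set(inter["replicate_id"]))
    if shared and all(len(g) == 1 for _, g in mito.groupby("replicate_id")) and all(
        len(g) == 1 for _, g in inter.groupby("replicate_id")
    ):
        m = mito.set_index("replicate_id").loc[shared]
        i = inter.set_index("replicate_id").loc[shared]
        paired = pd.DataFrame(
            {
                "replicate_id": shared,
                "ratio_residence": (m["residence_time"] / i["residence_time"]).to_numpy(),
                "ratio_t1pct": (m["t_1pct"] / i["t_1pct"]).to_numpy(),
            }
        )

    if len(mito) >= 2 and len(inter) >= 2:
        t_stat, p_val = stats.ttest_ind(mito["residence_time"], inter["residence_time"])
        t_stat, p_val = float(t_stat), float(p_val)
        if np.isnan(p_val) and np.isclose(
            mito["residence_time"].mean(), inter["residence_time"].mean()
        ):
            # zero within-group variance with equal means: no evidence of difference
            t_stat, p_val = 0.0, 1.0
    else:
        t_stat = p_val = None
    return ConditionComparison(
        table=agg,
        ratio_residence=ratio_res,
        ratio_t1pct=ratio_t1,
        paired_ratios=paired,
        p_value=p_val,
        t_statistic=t_stat,
    )
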