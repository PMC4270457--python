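"""Focus-trajectory statistics: MSD, subdiffusion fits, segregation events.

Input is a table of time-stamped planar focus positions (one row per
cell, focus and frame).  Mean square displacements are pooled over every
overlapping pair of frames at each time lag across all foci; the pooled
curve is fitted with the anomalous-diffusion law

    r²(τ) = 4 D τ^α + β

by weighted nonlinear least squares (weights 1/SEM(τ)), where α < 1
indicates subdiffusion, D is the generalized diffusion coefficient
(µm² s^-α) and the static offset β absorbs the time-independent
localization error (⟨(r+ε)²⟩ = ⟨r²⟩ + ⟨ε²⟩; the cross term averages
out).  Rapid segregation events — two foci initially close that move a
further fixed distance apart within a short window — are detected per
cell, and their mobility is compared to the full data set by a
resampling test on per-trajectory maximal MSDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.optimize

__all__ = [
    "TrajectorySet",
    "MSDCurve",
    "SubdiffusionFit",
    "compute_msd",
    "fit_subdiffusion",
    "detect_segregation_events",
    "max_msd_resampling_test",
    "free_diffusion_bound",
]

#: camera pixel size of the reference imaging setup (µm)
DEFAULT_PIXEL = 0.066

TRACK_COLUMNS = ["cell", "focus", "t_s", "x_um", "y_um"]


@dataclass
class TrajectorySet:
    """Per-focus time-stamped planar positions.

    ``records`` has columns cell, focus, t_s, x_um, y_um; times must be
    strictly increasing within each focus (gaps allowed).
    """

    records: pd.DataFrame
    frame_interval: float = 1.0
    pixel: float = DEFAULT_PIXEL

    def __post_init__(self) -> None:
        missing = set(TRACK_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"track table missing columns {sorted(missing)}")
        self.records = self.records[TRACK_COLUMNS].copy()
        for (_, _), g in self.records.groupby(["cell", "focus"], sort=False):
            if np.any(np.diff(g["t_s"].to_numpy()) <= 0):
                raise ValueError("times must be strictly increasing per focus")

    def __len__(self) -> int:
        return self.records.groupby(["cell", "focus"]).ngroups

    def tracks(self) -> Iterable[tuple[tuple, np.ndarray, np.ndarray, np.ndarray]]:
        """Yield (key, t, x, y) per focus."""
        for key, g in self.records.groupby(["cell", "focus"], sort=False):
            yield (key, g["t_s"].to_numpy(), g["x_um"].to_numpy(),
                   g["y_um"].to_numpy())

    def subset(self, keys) -> "TrajectorySet":
        keyset = set(map(tuple, keys))
        mask = self.records.apply(
            lambda r: (r["cell"], r["focus"]) in keyset, axis=1
        )
        return TrajectorySet(self.records[mask], self.frame_interval, self.pixel)


@dataclass
class MSDCurve:
    lags: np.ndarray      # τ (s)
    msd: np.ndarray       # ⟨r²(τ)⟩ (µm²)
    sem: np.ndarray
    n: np.ndarray         # displacement counts per lag

    def __post_init__(self) -> None:
        if np.any(self.n < 1) or np.any(self.sem < 0):
            raise ValueError("invalid MSD curve")


@dataclass(frozen=True)
class SubdiffusionFit:
    alpha: float
    D: float              # µm² s^-α
    beta: float           # µm²
    alpha_se: float
    D_se: float
    beta_se: float
    r_squared: float

    def alpha_ci(self, k: float = 1.96) -> tuple[float, float]:
        return self.alpha - k * self.alpha_se, self.alpha + k * self.alpha_se


def _pair_displacements(t, x, y, frame_interval):
    """All overlapping-window squared displacements, keyed by lag index."""
    n = len(t)
    i, j = np.triu_indices(n, k=1)
    lag = t[j] - t[i]
    k = np.rint(lag / frame_interval).astype(int)
    ok = np.abs(lag - k * frame_interval) <= 1e-6 * frame_interval + 1e-9
    dr2 = (x[j] - x[i]) ** 2 + (y[j] - y[i]) ** 2
    return k[ok], dr2[ok]


def _per_track_aggregates(tracks: TrajectorySet):
    """Per-track (count, sum, sum-of-squares) of r² per integer lag."""
    per_track = []
    width = 0
    for _, t, x, y in tracks.tracks():
        if len(t) < 2:
            continue
        ks, dr2 = _pair_displacements(t, x, y, tracks.frame_interval)
        if len(ks) == 0:
            continue
        m = int(ks.max()) + 1
        per_track.append((
            np.bincount(ks, minlength=m),
            np.bincount(ks, weights=dr2, minlength=m),
            np.bincount(ks, weights=dr2 ** 2, minlength=m),
        ))
        width = max(width, m)
    return per_track, width


def _aggregate_to_curve(agg_list, width, frame_interval) -> MSDCurve:
    n = np.zeros(width)
    s = np.zeros(width)
    ss = np.zeros(width)
    for cn, cs, css in agg_list:
        n[: len(cn)] += cn
        s[: len(cs)] += cs
        ss[: len(css)] += css
    sel = (n > 0) & (np.arange(width) > 0)
    lags = np.flatnonzero(sel)
    nn = n[lags]
    mean = s[lags] / nn
    var = np.zeros_like(mean)
    mult = nn > 1
    var[mult] = (ss[lags][mult] - nn[mult] * mean[mult] ** 2) / (nn[mult] - 1)
    sem = np.sqrt(np.maximum(var, 0.0) / nn)
    return MSDCurve(lags * frame_interval, mean, sem, nn.astype(int))


def compute_msd(tracks: TrajectorySet) -> MSDCurve:
    """Pooled MSD over all foci: every frame pair contributes to its lag.

    Gaps in a track are no obstacle: surviving frame pairs spanning a gap
    still contribute.  Returns mean, SEM and count per lag (τ = 0
    excluded); the result is invariant to the order of tracks.
    """
    agg, width = _per_track_aggregates(tracks)
    if not agg:
        raise ValueError("no displacement pairs in input")
    return _aggregate_to_curve(agg, width, tracks.frame_interval)


def fit_subdiffusion(msd: MSDCurve) -> SubdiffusionFit:
    """Weighted fit of r²(τ) = 4 D τ^α + β (weights 1/SEM).

    Lags with zero SEM are excluded from weighting (they would carry
    infinite weight); at least 4 positive-SEM lags are required.
    """
    sel = msd.sem > 0
    if sel.sum() < 4:
        raise ValueError("need >= 4 lags with positive SEM")
    tau = msd.lags[sel]
    y = msd.msd[sel]
    w = msd.sem[sel]

    def model(tau, d, alpha, beta):
        return 4.0 * d * tau ** alpha + beta

    # log-log initial slope for alpha, amplitude for D
    slope, logd = np.polyfit(np.log(tau), np.log(np.maximum(y, 1e-12)), 1)
    p0 = (max(np.exp(logd) / 4.0, 1e-12), float(np.clip(slope, 0.05, 2.0)), 0.0)
    popt, pcov = scipy.optimize.curve_fit(
        model, tau, y, p0=p0, sigma=w, absolute_sigma=False,
        bounds=([0.0, 1e-3, -np.inf], [np.inf, 3.0, np.inf]), maxfev=20000,
    )
    perr = np.sqrt(np.diag(pcov))
    resid = y - model(tau, *popt)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SubdiffusionFit(
        alpha=float(popt[1]), D=float(popt[0]), beta=float(popt[2]),
        alpha_se=float(perr[1]), D_se=float(perr[0]), beta_se=float(perr[2]),
        r_squared=r2,
    )


def bootstrap_subdiffusion(
    tracks: TrajectorySet, n_boot: int = 100, seed: int = 0,
    ci_level: float = 0.95,
):
    """Trajectory bootstrap of the subdiffusion fit.

    Pooled-MSD points share underlying trajectories and are strongly
    correlated across lags, so least-squares standard errors understate
    the uncertainty of the anomalous exponent.  Resampling whole
    trajectories with replacement propagates that correlation.  Returns
    ``(fit, alpha_ci, alpha_samples)`` where ``fit`` is the full-data
    fit and ``alpha_ci`` the percentile confidence interval.
    """
    agg, width = _per_track_aggregates(tracks)
    if not agg:
        raise ValueError("no displacement pairs in input")
    fit = fit_subdiffusion(_aggregate_to_curve(agg, width, tracks.frame_interval))
    rng = np.random.default_rng(seed)
    alphas = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(agg), len(agg))
        curve = _aggregate_to_curve([agg[i] for i in idx], width,
                                    tracks.frame_interval)
        try:
            alphas.append(fit_subdiffusion(curve).alpha)
        except (ValueError, RuntimeError):
            continue
    alphas = np.asarray(alphas)
    lo, hi = np.quantile(alphas, [(1 - ci_level) / 2, (1 + ci_level) / 2])
    return fit, (float(lo), float(hi)), alphas


def free_diffusion_bound(tau: np.ndarray, D_f: float = 10e-4) -> np.ndarray:
    """Planar MSD of hypothetical free diffusion, 4·D_f·τ (upper bound)."""
    return 4.0 * D_f * np.asarray(tau, dtype=float)


def detect_segregation_events(
    tracks: TrajectorySet,
    window: float = 20.0,
    init_sep: float = 0.3,
    extra_sep: float = 0.8,
) -> pd.DataFrame:
    """Rapid segregation events among per-cell focus pairs.

    An event is a pair of foci in one cell whose separation is at most
    ``init_sep`` µm at some start frame and which move at least
    ``extra_sep`` µm further apart within ``window`` s of that frame.  A
    merged focus that splits enters at separation ~0 (the first frame
    where both tracks exist).  The first qualifying start per pair is
    reported.  Returns a table (cell, focus_a, focus_b, t_start,
    init_separation, max_extra_separation); empty if no event qualifies.
    """
    rows = []
    for cell, cell_g in tracks.records.groupby("cell", sort=False):
        foci = sorted(cell_g["focus"].unique())
        for ia in range(len(foci)):
            for ib in range(ia + 1, len(foci)):
                a = cell_g[cell_g["focus"] == foci[ia]]
                b = cell_g[cell_g["focus"] == foci[ib]]
                merged = pd.merge(a, b, on="t_s", suffixes=("_a", "_b"))
                if len(merged) < 2:
                    continue
                t = merged["t_s"].to_numpy()
                d = np.hypot(
                    merged["x_um_b"].to_numpy() - merged["x_um_a"].to_numpy(),
                    merged["y_um_b"].to_numpy() - merged["y_um_a"].to_numpy(),
                )
                for k in range(len(t) - 1):
                    if d[k] > init_sep:
                        continue
                    in_win = (t > t[k]) & (t <= t[k] + window)
                    if not np.any(in_win):
                        continue
                    extra = float(np.max(d[in_win]) - d[k])
                    if extra >= extra_sep:
                        rows.append(dict(
                            cell=cell, focus_a=foci[ia], focus_b=foci[ib],
                            t_start=float(t[k]), init_separation=float(d[k]),
                            max_extra_separation=extra,
                        ))
                        break
    return pd.DataFrame(
        rows, columns=["cell", "focus_a", "focus_b", "t_start",
                       "init_separation", "max_extra_separation"],
    )


def _max_msd_per_track(tracks: TrajectorySet) -> dict:
    """Per-trajectory maximum of the time-averaged MSD curve."""
    out = {}
    for key, t, x, y in tracks.tracks():
        if len(t) < 2:
            continue
        ks, dr2 = _pair_displacements(t, x, y, tracks.frame_interval)
        sums: dict[int, list] = {}
        for k, v in zip(ks, dr2):
            sums.setdefault(int(k), []).append(v)
        out[key] = max(np.mean(v) for v in sums.values())
    return out


def max_msd_resampling_test(
    event_tracks: TrajectorySet,
    all_tracks: TrajectorySet,
    n_resample: int = 10_000,
    seed: int = 0,
):
    """Empirical p-value for elevated mobility of an event trajectory set.

    Statistic: the mean over the event set of each trajectory's maximal
    (time-averaged) MSD.  Null: equally sized subsets sampled uniformly
    without replacement from the full data set.  Returns
    ``(p_value, observed, null_samples)`` with the +1-corrected
    p = (1 + #{null >= observed}) / (1 + n_resample).
    """
    all_max = _max_msd_per_track(all_tracks)
    ev_max = _max_msd_per_track(event_tracks)
    if len(ev_max) == 0:
        raise ValueError("empty event set")
    if len(ev_max) > len(all_max):
        raise ValueError("event set larger than the full data set")
    observed = float(np.mean(list(ev_max.values())))
    pool = np.asarray(list(all_max.values()))
    rng = np.random.default_rng(seed)
    k = len(ev_max)
    null = np.empty(n_resample)
    for i in range(n_resample):
        null[i] = pool[rng.choice(len(pool), size=k, replace=False)].mean()
    tol = 1e-9 * abs(observed)  # summation-order round-off guard
    p = (1.0 + np.sum(null >= observed - tol)) / (1.0 + n_resample)
    return float(p), observed, null
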