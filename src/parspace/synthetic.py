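"""Synthetic inputs: subdiffusive focus tracks and two-channel cell stacks.

The generators emulate the two kinds of data the statistics consume:

* planar focus trajectories with a prescribed anomalous exponent —
  fractional Brownian motion per coordinate, synthesised by circulant
  embedding (Davies–Harte), which realises the exact fBm covariance —
  degraded by Gaussian localization noise and pixelation, optionally
  confined to a reflecting box;
* per-cell two-channel intensity stacks I(z, x) with a pole-to-pole
  nucleoid envelope (flat-topped or half-sine), optional helical
  modulation, a nested or identical second channel, punctate Gaussian
  foci, and Poisson-like noise.

Every generator is seed-deterministic and emits its ground truth
(true positions, edges, focus parameters) alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .localization import IntensityStack
from .trajectories import DEFAULT_PIXEL, TrajectorySet

__all__ = [
    "SynthTrackSpec",
    "SynthCellSpec",
    "generate_fbm_tracks",
    "generate_cell_stack",
    "fgn_autocovariance",
]


@dataclass(frozen=True)
class SynthTrackSpec:
    """Specification of a synthetic subdiffusive track ensemble.

    ``alpha`` is the target anomalous exponent (Hurst index alpha/2 per
    coordinate); ``D`` the generalized diffusion coefficient scaled so
    the ensemble planar MSD is 4·D·τ^alpha; ``sigma`` the localization
    noise s.d. per coordinate (µm); ``pixel`` the camera pixel for
    rounding (0 disables); ``confinement`` an optional reflecting box
    half-width (µm).
    """

    n_tracks: int = 100
    duration: float = 60.0
    frame_interval: float = 4.0
    alpha: float = 0.73
    D: float = 9.7e-4
    sigma: float = 0.02
    pixel: float = DEFAULT_PIXEL
    confinement: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        for name in ("n_tracks", "duration", "frame_interval", "D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def fgn_autocovariance(alpha: float, n: int) -> np.ndarray:
    """Autocovariance of unit-variance fractional Gaussian noise.

    gamma(k) = 0.5 (|k+1|^alpha - 2|k|^alpha + |k-1|^alpha) with
    alpha = 2H; gamma(0) = 1.
    """
    k = np.arange(n, dtype=float)
    return 0.5 * (np.abs(k + 1) ** alpha - 2 * np.abs(k) ** alpha
                  + np.abs(k - 1) ** alpha)


def _fgn_davies_harte(n: int, alpha: float, rng: np.random.Generator,
                      n_series: int) -> np.ndarray:
    """Exact fGn samples (n_series, n) by circulant embedding."""
    gamma = fgn_autocovariance(alpha, n + 1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    m = len(row)
    lam = np.fft.fft(row).real
    # the embedding is nonnegative-definite for fBm (H <= 1); clip the
    # tiny negative round-off eigenvalues
    lam = np.maximum(lam, 0.0)
    out = np.empty((n_series, n))
    half = m // 2
    for s in range(n_series):
        v = np.zeros(m, dtype=complex)
        v[0] = np.sqrt(lam[0]) * rng.standard_normal()
        v[half] = np.sqrt(lam[half]) * rng.standard_normal()
        re = rng.standard_normal(half - 1)
        im = rng.standard_normal(half - 1)
        v[1:half] = np.sqrt(lam[1:half] / 2) * (re + 1j * im)
        v[half + 1:] = np.conj(v[1:half][::-1])
        x = np.fft.fft(v) / np.sqrt(m)
        out[s] = x[:n].real
    return out


def _reflect(x: np.ndarray, half_width: float) -> np.ndarray:
    """Fold a path into [-half_width, half_width] by reflection."""
    period = 4.0 * half_width
    y = np.mod(x + half_width, period)
    y = np.where(y > 2 * half_width, period - y, y)
    return y - half_width


def generate_fbm_tracks(spec: SynthTrackSpec):
    """Planar fBm tracks with localization noise and pixelation.

    Returns ``(tracks, truth)``: the degraded TrajectorySet and a table
    of the true (noise-free, unpixelated) positions.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration / spec.frame_interval)) + 1
    n_steps = n_frames - 1
    scale = np.sqrt(2.0 * spec.D) * spec.frame_interval ** (spec.alpha / 2.0)
    rows = []
    true_rows = []
    for tr in range(spec.n_tracks):
        steps = _fgn_davies_harte(n_steps, spec.alpha, rng, 2) * scale
        x = np.concatenate([[0.0], np.cumsum(steps[0])])
        y = np.concatenate([[0.0], np.cumsum(steps[1])])
        if spec.confinement is not None:
            x = _reflect(x, spec.confinement)
            y = _reflect(y, spec.confinement)
        t = np.arange(n_frames) * spec.frame_interval
        xn = x + rng.normal(0.0, spec.sigma, n_frames)
        yn = y + rng.normal(0.0, spec.sigma, n_frames)
        if spec.pixel > 0:
            xn = np.round(xn / spec.pixel) * spec.pixel
            yn = np.round(yn / spec.pixel) * spec.pixel
        for k in range(n_frames):
            rows.append(("cell0", tr, t[k], xn[k], yn[k]))
            true_rows.append(("cell0", tr, t[k], x[k], y[k]))
    cols = ["cell", "focus", "t_s", "x_um", "y_um"]
    tracks = TrajectorySet(pd.DataFrame(rows, columns=cols),
                           frame_interval=spec.frame_interval,
                           pixel=spec.pixel)
    truth = pd.DataFrame(true_rows, columns=cols)
    return tracks, truth


@dataclass(frozen=True)
class SynthCellSpec:
    """Specification of a synthetic two-channel cell stack.

    The nucleoid channel is an envelope between ``nucleoid_span`` edges
    (``envelope`` = 'halfsine' or 'flat'), optionally helically modulated
    as 1 + a·cos(2π x/λ + φ·z); the second channel is either a copy or a
    nested (support-shrunken) version.  ``in_focus_start`` places a
    9-plane in-focus band; out-of-focus planes are attenuated.
    """

    cell_length: float = 3.0
    nucleoid_span: tuple[float, float] = (0.5, 2.5)
    dx: float = 0.0625
    dz: float = 0.1
    n_planes: int = 21
    in_focus_start: int = 6
    envelope: str = "halfsine"
    modulation_amplitude: float = 0.0
    modulation_period: float = 0.5
    modulation_phase_per_z: float = 0.7
    channel_b: str = "nested"
    nested_shrink: float = 0.25
    foci: Sequence[tuple[float, float, float]] = field(default_factory=tuple)
    noise_sigma: float = 0.0
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.nucleoid_span
        if not (0 <= lo < hi <= self.cell_length):
            raise ValueError("nucleoid span must lie within the cell")
        if self.n_planes < 9:
            raise ValueError("need at least 9 planes")
        if self.envelope not in ("halfsine", "flat"):
            raise ValueError("envelope must be 'halfsine' or 'flat'")
        if self.channel_b not in ("copy", "nested"):
            raise ValueError("channel_b must be 'copy' or 'nested'")


def _envelope(x, lo, hi, kind):
    inside = (x >= lo) & (x <= hi)
    if kind == "halfsine":
        prof = np.where(inside, np.sin(np.pi * (x - lo) / (hi - lo)), 0.0)
    else:
        prof = inside.astype(float)
    return np.clip(prof, 0.0, None)


def generate_cell_stack(spec: SynthCellSpec):
    """Two-channel synthetic stack with ground truth.

    Returns ``(stack_a, stack_b, truth)`` where truth records the true
    nucleoid edges, the in-focus plane band and the focus list.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.arange(0.0, spec.cell_length + spec.dx / 2, spec.dx)
    lo, hi = spec.nucleoid_span
    z_weight = np.full(spec.n_planes, 0.2)
    band = slice(spec.in_focus_start, spec.in_focus_start + 9)
    z_weight[band] = 1.0

    def build(lo_c, hi_c, with_foci):
        grid = np.zeros((spec.n_planes, len(x)))
        for z in range(spec.n_planes):
            prof = _envelope(x, lo_c, hi_c, spec.envelope)
            if spec.modulation_amplitude > 0:
                mod = 1.0 + spec.modulation_amplitude * np.cos(
                    2 * np.pi * x / spec.modulation_period
                    + spec.modulation_phase_per_z * z
                )
                prof = prof * mod
            if with_foci:
                for pos, width, amp in spec.foci:
                    prof = prof + amp * np.exp(-0.5 * ((x - pos) / width) ** 2)
            grid[z] = z_weight[z] * np.clip(prof, 0.0, None)
        if spec.noise_sigma > 0:
            grid = grid + rng.normal(0.0, spec.noise_sigma, grid.shape) \
                * np.sqrt(np.maximum(grid, 0.05))
        grid = np.clip(grid + spec.baseline, 0.0, None)
        return grid

    grid_a = build(lo, hi, with_foci=False)
    if spec.channel_b == "copy":
        grid_b = grid_a.copy()
        lo_b, hi_b = lo, hi
    else:
        shrink = spec.nested_shrink * (hi - lo) / 2
        lo_b, hi_b = lo + shrink, hi - shrink
        grid_b = build(lo_b, hi_b, with_foci=True)
    foci_pos = np.array([f[0] for f in spec.foci])
    stack_a = IntensityStack(x=x, I=grid_a, dz=spec.dz,
                             poles=(0.0, spec.cell_length))
    stack_b = IntensityStack(x=x, I=grid_b, dz=spec.dz,
                             poles=(0.0, spec.cell_length), foci=foci_pos)

    def halfmax_edges(lo_c, hi_c):
        # ground truth for edge recovery: where the noise-free envelope
        # crosses half its maximum (inboard of the support for a half-sine)
        if spec.envelope == "halfsine":
            inset = (hi_c - lo_c) / 6.0  # sin(pi u) = 1/2 at u = 1/6, 5/6
            return lo_c + inset, hi_c - inset
        return lo_c, hi_c

    truth = dict(
        support_a=(lo, hi), support_b=(lo_b, hi_b),
        edges_a=halfmax_edges(lo, hi), edges_b=halfmax_edges(lo_b, hi_b),
        in_focus_planes=tuple(range(spec.in_focus_start,
                                    spec.in_focus_start + 9)),
        foci=tuple(spec.foci),
    )
    return stack_a, stack_b, truth


def generate_mobility_dataset(
    seed: int = 0,
    n_short: int = 500,
    n_long: int = 120,
    alpha: float = 0.73,
    D: float = 9.7e-4,
    sigma: float = 0.02,
) -> TrajectorySet:
    """Combined short/long time-lapse focus-track ensemble.

    Emulates the structure of the reference mobility study: short
    time-lapses (1 min at 4 s frames) pooled with long ones (15 min at
    30 s frames), both fBm with the same anomalous exponent and
    generalized diffusion coefficient plus localization noise and
    pixelation.  The pooled lag range spans 4 s to 900 s, which is what
    pins down the anomalous exponent in the weighted fit.
    """
    short_spec = SynthTrackSpec(
        n_tracks=n_short, duration=60.0, frame_interval=4.0,
        alpha=alpha, D=D, sigma=sigma, seed=seed,
    )
    long_spec = SynthTrackSpec(
        n_tracks=n_long, duration=900.0, frame_interval=30.0,
        alpha=alpha, D=D, sigma=sigma, seed=seed + 10_000,
    )
    t_short, _ = generate_fbm_tracks(short_spec)
    t_long, _ = generate_fbm_tracks(long_spec)
    long_rec = t_long.records.assign(focus=t_long.records["focus"] + n_short)
    rec = pd.concat([t_short.records, long_rec], ignore_index=True)
    # 2 s grid embeds both frame intervals exactly
    return TrajectorySet(rec, frame_interval=2.0, pixel=short_spec.pixel)
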