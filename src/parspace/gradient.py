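"""Closed-form steady state of the 1D nucleoid ParA-ATP gradient model.

The nucleoid is a 1D domain [0, L].  ParA-ATP binds uniformly along it with
flux density ``R`` (molecules per µm per s), diffuses with constant ``D`` and
is released only at plasmid positions, where the plasmid-associated ParB-parC
complex hydrolyses it.  On the slow timescale of plasmid motion the profile
``A(x)`` relaxes to a steady state obeying

    D * A''(x) + R = 0

on every interval between plasmids, with reflecting (zero-derivative)
boundaries at both nucleoid ends.  At a plasmid position ``x_i`` either

* ``A(x_i) = 0`` (absorbing plasmid, the limit of very fast hydrolysis), or
* the total diffusive flux arriving at the plasmid balances a point sink
  proportional to the local concentration, ``J- + J+ = k_B * A(x_i)``,
  for a finite hydrolysis rate ``k_B``.

The solution is piecewise quadratic.  The per-plasmid arrival fluxes encode
the distances to the neighbouring plasmids/nucleoid ends: a plasmid closer to
one end receives less flux from that side, and flux balance at every plasmid
holds exactly at the equally spaced configuration x_i = (2i-1) L / (2 n_p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GradientParams",
    "GradientSolution",
    "solve_steady_state",
    "equal_spacing_positions",
    "flux_imbalance_relaxation",
]


@dataclass(frozen=True)
class GradientParams:
    """Parameters of the 1D gradient model.

    Parameters
    ----------
    L : float
        Nucleoid length (µm).
    R : float
        Uniform ParA-ATP binding flux per unit length (molecules µm⁻¹ s⁻¹).
    D : float
        Diffusion constant of nucleoid-bound ParA-ATP (µm² s⁻¹).
    kB : float
        Hydrolysis rate at a plasmid (s⁻¹); ``math.inf`` means absorbing
        plasmids, i.e. A(x_i) = 0.
    plasmid_positions : sequence of float
        Strictly increasing positions in the open interval (0, L).
    """

    L: float
    R: float
    D: float
    kB: float = math.inf
    plasmid_positions: Sequence[float] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError("nucleoid length L must be positive")
        if self.R < 0:
            raise ValueError("binding flux R must be nonnegative")
        if not self.D > 0:
            raise ValueError("diffusion constant D must be positive")
        if not self.kB > 0:
            raise ValueError("hydrolysis rate kB must be positive (inf allowed)")
        pos = np.asarray(self.plasmid_positions, dtype=float)
        if pos.size:
            if np.any(pos <= 0) or np.any(pos >= self.L):
                raise ValueError("plasmid positions must lie strictly inside (0, L)")
            if np.any(np.diff(pos) <= 0):
                raise ValueError("plasmid positions must be strictly increasing")
        object.__setattr__(self, "plasmid_positions", tuple(pos.tolist()))


@dataclass(frozen=True)
class GradientSolution:
    """Piecewise-quadratic steady-state profile and per-plasmid fluxes.

    ``segments[s]`` holds ``(c2, c1, c0)`` with
    ``A(x) = c2 x² + c1 x + c0`` on the s-th interval between plasmids
    (interval edges are 0, x_1, …, x_np, L).  ``fluxes[i] = (J-, J+)`` are
    the nonnegative ParA-ATP arrival rates at plasmid i from the left and
    right; ``plasmid_concentrations[i] = A(x_i)``.
    """

    params: GradientParams
    segments: np.ndarray          # (np+1, 3)
    fluxes: np.ndarray            # (np, 2)
    plasmid_concentrations: np.ndarray  # (np,)

    @property
    def breakpoints(self) -> np.ndarray:
        p = self.params
        return np.concatenate(([0.0], np.asarray(p.plasmid_positions), [p.L]))

    def profile(self, x: np.ndarray) -> np.ndarray:
        """Evaluate A(x) on an array of positions in [0, L]."""
        x = np.asarray(x, dtype=float)
        bp = self.breakpoints
        seg = np.clip(np.searchsorted(bp, x, side="right") - 1, 0, len(self.segments) - 1)
        c2, c1, c0 = self.segments[seg, 0], self.segments[seg, 1], self.segments[seg, 2]
        return c2 * x * x + c1 * x + c0

    @property
    def total_flux(self) -> float:
        """Total arrival flux over all plasmids; equals R·L at steady state."""
        return float(self.fluxes.sum())


def solve_steady_state(params: GradientParams) -> GradientSolution:
    """Solve D·A'' + R = 0 with no-flux edges and plasmid sink conditions.

    On segment s the profile is A_s(x) = -R/(2D) x² + a_s x + b_s.  The
    2(n_p+1) unknowns (a_s, b_s) are fixed by A'(0)=0, A'(L)=0, continuity at
    every plasmid and either A(x_i)=0 (kB=inf) or the point-sink balance
    D(a_i - a_{i-1}) = kB · A(x_i).
    """
    L, R, D, kB = params.L, params.R, params.D, params.kB
    xs = np.asarray(params.plasmid_positions, dtype=float)
    n = xs.size
    nseg = n + 1
    # unknown vector u = [a_0, b_0, a_1, b_1, ...]
    M = np.zeros((2 * nseg, 2 * nseg))
    rhs = np.zeros(2 * nseg)

    def a_idx(s: int) -> int:
        return 2 * s

    def b_idx(s: int) -> int:
        return 2 * s + 1

    row = 0
    # A'(0) = 0  ->  a_0 = 0
    M[row, a_idx(0)] = 1.0
    row += 1
    # A'(L) = 0  ->  -R/D * L + a_last = 0
    M[row, a_idx(nseg - 1)] = 1.0
    rhs[row] = R * L / D
    row += 1
    for i, xi in enumerate(xs):
        sl, sr = i, i + 1
        # continuity: A_{sl}(xi) = A_{sr}(xi)
        M[row, a_idx(sl)] = xi
        M[row, b_idx(sl)] = 1.0
        M[row, a_idx(sr)] = -xi
        M[row, b_idx(sr)] = -1.0
        row += 1
        if math.isinf(kB):
            # absorbing: A(xi) = 0 on the left segment (continuity gives right)
            M[row, a_idx(sl)] = xi
            M[row, b_idx(sl)] = 1.0
            rhs[row] = R * xi * xi / (2 * D)
            row += 1
        else:
            # D (a_r - a_l) = kB * A(xi);  A(xi) = -R/(2D) xi² + a_l xi + b_l
            M[row, a_idx(sr)] = D
            M[row, a_idx(sl)] = -D - kB * xi
            M[row, b_idx(sl)] = -kB
            rhs[row] = -kB * R * xi * xi / (2 * D)
            row += 1

    u = np.linalg.solve(M, rhs)
    segs = np.empty((nseg, 3))
    segs[:, 0] = -R / (2 * D)
    segs[:, 1] = u[0::2]
    segs[:, 2] = u[1::2]

    fluxes = np.empty((n, 2))
    conc = np.empty(n)
    for i, xi in enumerate(xs):
        a_l, b_l = segs[i, 1], segs[i, 2]
        a_r = segs[i + 1, 1]
        # arrival flux from the left: J- = -D A'(xi-) with A' = -R/D x + a
        fluxes[i, 0] = R * xi - D * a_l
        # arrival from the right: J+ = +D A'(xi+)
        fluxes[i, 1] = D * a_r - R * xi
        conc[i] = -R / (2 * D) * xi * xi + a_l * xi + b_l
    # clamp tiny negative round-off
    fluxes[np.abs(fluxes) < 1e-12 * max(1.0, R * L)] = np.abs(
        fluxes[np.abs(fluxes) < 1e-12 * max(1.0, R * L)]
    )
    return GradientSolution(params=params, segments=segs, fluxes=fluxes,
                            plasmid_concentrations=conc)


def equal_spacing_positions(L: float, n_p: int) -> np.ndarray:
    """Equally spaced fixed points x_i = (2i-1)·L/(2·n_p), i = 1..n_p.

    These are exactly the configurations at which every plasmid receives
    balanced fluxes from both sides (inter-plasmid spacing L/n_p, half that
    to each nucleoid end).
    """
    if not L > 0:
        raise ValueError("L must be positive")
    if n_p < 1:
        raise ValueError("n_p must be at least 1")
    i = np.arange(1, n_p + 1, dtype=float)
    return (2 * i - 1) * L / (2 * n_p)


def flux_imbalance_relaxation(
    params: GradientParams,
    step: float = None,
    n_iter: int = 10_000,
    tol_factor: float = 1e-9,
) -> np.ndarray:
    """Quasi-static relaxation of plasmid positions along flux imbalance.

    Each iteration re-solves the steady-state profile (separation of
    timescales: the gradient equilibrates instantly relative to plasmid
    motion) and moves every plasmid by its current step towards the side
    delivering the larger arrival flux.  A per-plasmid step is halved
    whenever its flux-imbalance sign flips, so the iteration converges to
    the equal-spacing fixed point to within tol_factor·L.

    Returns the (n_iter_used+1, n_p) position trajectory including the
    initial configuration.  Raises if a move would cross plasmids or exit
    the domain (the step was too large).
    """
    L = params.L
    xs = np.asarray(params.plasmid_positions, dtype=float).copy()
    n = xs.size
    if n == 0:
        raise ValueError("at least one plasmid required")
    if step is None:
        step = 0.01 * L
    steps = np.full(n, float(step))
    prev_sign = np.zeros(n)
    tol = tol_factor * L
    traj = [xs.copy()]
    for _ in range(n_iter):
        sol = solve_steady_state(
            GradientParams(L=L, R=params.R, D=params.D, kB=params.kB,
                           plasmid_positions=tuple(xs))
        )
        imb = sol.fluxes[:, 1] - sol.fluxes[:, 0]  # >0: more flux from right
        imb[np.abs(imb) < 1e-12 * max(1.0, params.R * L)] = 0.0
        sign = np.sign(imb)
        flipped = (sign * prev_sign) < 0
        steps[flipped] *= 0.5
        # persistent direction: grow the step (capped) to cross long distances
        steps[(sign * prev_sign) > 0] = np.minimum(
            steps[(sign * prev_sign) > 0] * 1.2, float(step)
        )
        prev_sign = sign.copy()
        if np.all((steps < tol) | (sign == 0)):
            break
        new = xs + np.where(steps >= tol, sign * steps, 0.0)
        if np.any(new <= 0) or np.any(new >= L) or np.any(np.diff(new) <= 0):
            raise RuntimeError(
                f"relaxation step {steps.max():g} caused plasmid collision or "
                f"domain exit at positions {new}; reduce the step gain"
            )
        xs = new
        traj.append(xs.copy())
    return np.asarray(traj)
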