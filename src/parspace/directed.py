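"""Directed-motion model: competing ParA polymers position plasmids.

The nucleoid is a thin rectangular lattice (native site size 5 nm, short
axis 25–30 nm).  Mobile nucleoid-bound ParA-ATP diffuses in all four
directions; two mobile molecules adjacent along the long axis nucleate an
immobile two-subunit polymer (rate ``k_p``), which elongates at its tips
by capturing adjacent mobile molecules and shrinks by spontaneous
per-subunit depolymerization (``k_dp``).  A plasmid occupies one long-axis
column across the full width.  Polymeric ParA in or next to the plasmid's
column tethers it (no diffusion); each adjacent-column polymeric subunit
also drives a directed step at rate ``k_dm``: the plasmid moves onto the
subunit's column while the subunit is hydrolysed to cytoplasmic ParA-ADP
(a burnt-bridge ratchet).  Competition between polymer structures on
either side of the plasmid biases the net motion towards the side with
more ParA — the side with more free nucleoid — producing equal spacing.

For wild-type runs the plasmid column is a hard wall to mobile ParA-ATP
diffusion; the perturbed-nucleoid variants let mobile ParA-ATP leak past
at a fraction of the normal hop rate and reduce ``k_mB`` ten-fold.

Scaled-down mode: on a coarsened lattice (``dx`` > 5 nm) the polymer
occupancy limit of one subunit per site reduces the lattice's polymer
capacity per µm, so :func:`scale_down` shrinks the total ParA density by
the capacity ratio, preserving per-site occupancies and therefore the
polymerization statistics and the positioning regime; hop rates follow
1/dx² automatically.  At the default coarsening (dx = 30 nm, one row)
the maximal directed drift speed k_dm·(subunits per column)·dx equals
its native value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._kernels import dm_run
from .engine import PARA_DENSITY_PER_UM

__all__ = [
    "DMParams",
    "DMResult",
    "variant_params",
    "scale_down",
    "simulate_dm",
    "model_asymmetry_series",
    "polymer_lengths",
]

NATIVE_DX = 0.005  # µm


@dataclass(frozen=True)
class DMParams:
    """Rate parameters of the directed-motion model (short-polymer WT
    defaults; use :func:`variant_params` for the other variants)."""

    D_A: float = 1.0          # mobile nucleoid-bound ParA-ATP diffusion, µm²/s
    D_P: float = 3e-4         # free plasmid diffusion, µm²/s
    k_on: float = 50.0
    k_B: float = 68.5         # polymeric-at-plasmid hydrolysis, s⁻¹ per subunit
    k_mB: float = 40.0        # mobile-at-plasmid hydrolysis, s⁻¹ per molecule
    k_W: float = 1.0 / 15.0
    k_dm: float = 0.8         # directed step per adjacent polymeric subunit, s⁻¹
    k_p: float = 800.0        # polymerization, s⁻¹
    k_dp: float = 10.0        # depolymerization per subunit, s⁻¹
    S: float = 0.030          # short-axis width, µm
    wall: bool = True         # plasmid column blocks mobile ParA-ATP hops
    leak_fraction: float = 0.1  # hop-past fraction when wall is off
    density: float = PARA_DENSITY_PER_UM
    dx: float = NATIVE_DX

    def __post_init__(self) -> None:
        if not 0 <= self.leak_fraction <= 1:
            raise ValueError("leak_fraction must be in [0, 1]")
        if self.S <= 0 or self.dx <= 0:
            raise ValueError("S and dx must be positive")
        for name in ("D_A", "D_P", "k_on", "k_B", "k_mB", "k_W", "k_dm",
                     "k_p", "k_dp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_short(self) -> int:
        return max(1, int(round(self.S / self.dx)))


_VARIANTS = {
    "short": dict(k_p=800.0, k_dp=10.0, S=0.030, k_mB=40.0, wall=True,
                  leak_fraction=0.1),
    "long": dict(k_p=1e6, k_dp=1e-4, S=0.025, k_mB=40.0, wall=True,
                 leak_fraction=1.0),
    "perturbed_short": dict(k_p=800.0, k_dp=10.0, S=0.030, k_mB=4.0,
                            wall=False, leak_fraction=0.1),
    "perturbed_long": dict(k_p=1e6, k_dp=1e-4, S=0.010, k_mB=4.0,
                           wall=False, leak_fraction=1.0),
}


def variant_params(variant: str) -> DMParams:
    """Parameter sets of the four published model variants.

    ``short``/``long`` control the extent of ParA polymerization
    (k_p/k_dp and the polymerizing width S); the ``perturbed_*`` variants
    emulate a disordered nucleoid: mobile ParA-ATP can diffuse past a
    plasmid (10% of the normal rate for short polymers, 100% for long,
    with S = 10 nm) and k_mB is reduced ten-fold.
    """
    if variant not in _VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {sorted(_VARIANTS)}"
        )
    return DMParams(**_VARIANTS[variant])


def scale_down(params: DMParams, dx: float = 0.030) -> DMParams:
    """Coarsened desk-scale parameterisation (see module docstring).

    Total ParA density is reduced by the polymer-capacity ratio
    (n_short/dx vs the native lattice) so per-site occupancies are
    preserved.
    """
    native_cap = max(1, int(round(params.S / NATIVE_DX))) / NATIVE_DX
    coarse = replace(params, dx=dx)
    coarse_cap = coarse.n_short / dx
    return replace(coarse, density=params.density * coarse_cap / native_cap)


@dataclass
class DMResult:
    """Snapshot stream of a directed-motion run.

    ``mobile_kymo``/``poly_kymo`` are per-column mobile and polymeric
    ParA-ATP counts (short axis summed); ``P_grid`` is the full 0/1
    polymer occupancy per snapshot.
    """

    times: np.ndarray
    plasmid_cols: np.ndarray
    n_plasmids: np.ndarray
    mobile_kymo: np.ndarray
    poly_kymo: np.ndarray
    P_grid: np.ndarray
    A_ADP: np.ndarray
    A_CYTO: np.ndarray
    n_cols: np.ndarray
    dx: float
    seed: int

    @property
    def positions_um(self) -> np.ndarray:
        pos = (self.plasmid_cols + 0.5) * self.dx
        return np.where(self.plasmid_cols >= 0, pos, np.nan)

    @property
    def lengths_um(self) -> np.ndarray:
        return self.n_cols * self.dx

    def relative_positions(self) -> np.ndarray:
        return self.positions_um / self.lengths_um[:, None]

    def position_histogram(self, n_bins: int = 40, t_min: float = 0.0):
        rel = self.relative_positions()[self.times >= t_min]
        vals = rel[np.isfinite(rel)]
        hist, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
        return hist, edges


def simulate_dm(
    params: DMParams,
    L0: float = 1.5,
    n_plasmids: int = 1,
    plasmid_positions: Sequence[float] | str = "random",
    T: float = 2400.0,
    seed: int = 0,
    growth_interval: float | None = None,
    final_length: float | None = None,
    duplication_times: Sequence[float] = (),
    output_interval: float = 5.0,
    replenish: bool = True,
) -> DMResult:
    """Run the directed-motion simulator.

    Initial condition: a quarter of total ParA as cytoplasmic ParA-ADP,
    the rest distributed uniformly at random on the nucleoid as mobile
    ParA-ATP; no polymers.
    """
    dx = params.dx
    if L0 <= 0 or T <= 0:
        raise ValueError("L0 and T must be positive")
    rng = np.random.default_rng(seed)
    if final_length is not None:
        n_events = int(round((final_length - L0) / (2 * dx)))
        if n_events > 0:
            growth_interval = T / (n_events + 1)
    max_L = final_length if final_length else L0 + 0.01
    if growth_interval and not final_length:
        max_L = L0 + 2 * dx * (T / growth_interval + 2)
    n_cols = int(round(L0 / dx))
    max_cols = int(round(max_L / dx)) + 4
    n_short = params.n_short
    total = int(round(params.density * n_cols * dx))
    a_adp = total // 4
    n_mobile = total - a_adp
    A0 = np.zeros((max_cols, n_short), dtype=np.int64)
    cols = rng.integers(0, n_cols, n_mobile)
    rows = rng.integers(0, n_short, n_mobile)
    np.add.at(A0, (cols, rows), 1)
    if isinstance(plasmid_positions, str):
        if plasmid_positions == "random":
            sites = rng.integers(0, n_cols, n_plasmids)
        elif plasmid_positions == "mid":
            sites = np.full(n_plasmids, n_cols // 2)
        elif plasmid_positions == "edge":
            sites = np.zeros(n_plasmids, dtype=np.int64)
        else:
            raise ValueError(f"unknown placement {plasmid_positions!r}")
    else:
        sites = np.array([int(np.clip(p / dx, 0, n_cols - 1))
                          for p in plasmid_positions], dtype=np.int64)
    leak = params.leak_fraction if not params.wall else 0.0
    out = dm_run(
        int(rng.integers(0, 2**31 - 1)),
        dx,
        params.D_A / dx**2,
        params.D_P / dx**2,
        params.k_on,
        params.k_B,
        params.k_mB,
        params.k_W,
        params.k_dm,
        params.k_p,
        params.k_dp,
        leak,
        A0,
        n_cols,
        np.asarray(sites, dtype=np.int64),
        a_adp,
        0,
        T,
        output_interval,
        growth_interval if growth_interval else -1.0,
        np.asarray(sorted(duplication_times), dtype=np.float64),
        params.density if replenish else -1.0,
    )
    (times, pcols, n_p, mob, pol, P, adp, cyto, ncols, status) = out
    if status != 0:
        raise RuntimeError("polymer occupancy invariant breached in dm_run")
    return DMResult(times, pcols, n_p, mob, pol, P, adp, cyto, ncols, dx, seed)


def model_asymmetry_series(result: DMResult, t_max: float | None = None) -> np.ndarray:
    """ParA asymmetry |I_L - I_R| / (I_L + I_R) per snapshot.

    For single-plasmid snapshots: the nucleoid-bound ParA (mobile +
    polymeric) on each side of the plasmid is summed and divided by that
    side's length, giving the densities I_L and I_R.  Cytoplasmic ParA is
    uniformly distributed, so it adds the same amount to both densities
    (raising the denominator only).  Snapshots after ``t_max`` or with
    more than one plasmid are skipped; zero-ParA snapshots are dropped
    with a warning.
    """
    vals = []
    for k in range(len(result.times)):
        if t_max is not None and result.times[k] > t_max:
            break
        if result.n_plasmids[k] != 1:
            continue
        c = result.plasmid_cols[k, 0]
        n = result.n_cols[k]
        left = float(result.mobile_kymo[k, :c].sum()
                     + result.poly_kymo[k, :c].sum())
        right = float(result.mobile_kymo[k, c + 1:n].sum()
                      + result.poly_kymo[k, c + 1:n].sum())
        len_l = c * result.dx
        len_r = (n - c - 1) * result.dx
        if len_l <= 0 or len_r <= 0:
            continue
        cyto_density = (result.A_ADP[k] + result.A_CYTO[k]) / (n * result.dx)
        i_l = left / len_l + cyto_density
        i_r = right / len_r + cyto_density
        if i_l + i_r == 0:
            warnings.warn("snapshot with no ParA at all; asymmetry undefined")
            continue
        vals.append(abs(i_l - i_r) / (i_l + i_r))
    return np.asarray(vals)


def polymer_lengths(result: DMResult, t_min: float = 0.0) -> np.ndarray:
    """Lengths (in subunits) of all polymers in all snapshots >= t_min.

    A polymer is a maximal run of occupied sites along the long axis
    within one row; by construction every polymer has >= 2 subunits.
    """
    lengths = []
    for k in range(len(result.times)):
        if result.times[k] < t_min:
            continue
        n = result.n_cols[k]
        grid = result.P_grid[k, :n]
        for j in range(grid.shape[1]):
            run = 0
            for i in range(n):
                if grid[i, j]:
                    run += 1
                elif run:
                    lengths.append(run)
                    run = 0
            if run:
                lengths.append(run)
    return np.asarray(lengths)
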