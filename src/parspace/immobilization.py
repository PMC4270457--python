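"""Diffusion/immobilization model of plasmid positioning on a 1D lattice.

Plasmids diffuse freely along the nucleoid and are anchored wherever
enough nucleoid-bound ParA-ATP accumulates: up to ``max_bound`` ParA-ATP
at the plasmid's site can bind the plasmid's ParB-parC complex, and two
or more bound molecules immobilize it.  Bound ParA-ATP is hydrolysed at
the plasmid (rate ``k_B`` per molecule) to cytoplasmic ParA-ADP, which
slowly matures back to DNA-binding-competent ParA-ATP (``k_W``) and
rebinds anywhere on the nucleoid (``k_on``).  Because hydrolysis only
happens at plasmids, ParA-ATP is depleted around them; a plasmid
released from its anchor therefore tends to be recaptured on the side
with more ParA-ATP — the side with more free space — which pushes the
population towards equal spacing.

Default rates follow the reference parameterisation of this model:
D_A = 1e-2 µm²/s, D_P = 1e-1 µm²/s, k_on = 50/s, k_AB = 100/s,
k_B = 68.5/s, k_W = 1/15 s⁻¹, 2400 ParA dimers per µm of nucleoid.

The native site size is 5 nm.  A coarsened lattice (larger ``dx``) is
supported for desk-scale runs: hop rates scale as 1/dx² automatically and
the same-site binding rate is rescaled by (5 nm / dx) so the ParA capture
flux per unit length is preserved (binding is mass action in the ParA-ATP
count at the plasmid's site, which grows with the site size).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._kernels import di_run
from .engine import PARA_DENSITY_PER_UM

__all__ = ["DIParams", "DIResult", "simulate_di", "duplication_assay"]

NATIVE_DX = 0.005  # µm


@dataclass(frozen=True)
class DIParams:
    """Rate parameters of the diffusion/immobilization model."""

    D_A: float = 1e-2        # nucleoid-bound ParA-ATP diffusion, µm²/s
    D_P: float = 1e-1        # free plasmid diffusion, µm²/s
    k_on: float = 50.0       # cytoplasmic ParA-ATP -> nucleoid, s⁻¹
    k_AB: float = 100.0      # ParA-ATP -> plasmid binding (at 5 nm sites), s⁻¹
    k_B: float = 68.5        # plasmid-bound hydrolysis, s⁻¹ per bound molecule
    k_W: float = 1.0 / 15.0  # ParA-ADP -> ParA-ATP maturation, s⁻¹
    k_off: float = 0.0       # spontaneous hydrolysis of nucleoid ParA-ATP, s⁻¹
    max_bound: int = 35
    immobilize_threshold: int = 2
    density: float = PARA_DENSITY_PER_UM  # ParA dimers per µm of nucleoid

    def __post_init__(self) -> None:
        for name in ("D_A", "D_P", "k_on", "k_AB", "k_B", "k_W", "k_off"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.max_bound < self.immobilize_threshold:
            raise ValueError("max_bound must be >= immobilize_threshold")


@dataclass
class DIResult:
    """Snapshot stream of a diffusion/immobilization run.

    Arrays are indexed by snapshot; plasmid slots not yet created hold -1
    (sites) / 0 (bound counts).  ``kymograph[k, i]`` is the mobile
    ParA-ATP count in column i at snapshot k.
    """

    times: np.ndarray
    plasmid_sites: np.ndarray
    plasmid_bound: np.ndarray
    n_plasmids: np.ndarray
    kymograph: np.ndarray
    A_ADP: np.ndarray
    A_CYTO: np.ndarray
    n_cols: np.ndarray
    dx: float
    seed: int

    @property
    def positions_um(self) -> np.ndarray:
        """Plasmid positions (µm, column centres); NaN for absent slots."""
        pos = (self.plasmid_sites + 0.5) * self.dx
        return np.where(self.plasmid_sites >= 0, pos, np.nan)

    @property
    def lengths_um(self) -> np.ndarray:
        return self.n_cols * self.dx

    def relative_positions(self) -> np.ndarray:
        """Positions scaled to the current nucleoid length, per snapshot."""
        return self.positions_um / self.lengths_um[:, None]

    def position_histogram(self, n_bins: int = 40, t_min: float = 0.0):
        """Time-averaged relative-position histogram (all plasmid slots)."""
        rel = self.relative_positions()[self.times >= t_min]
        vals = rel[np.isfinite(rel)]
        hist, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
        return hist, edges


def _initial_state(
    params: DIParams,
    L0: float,
    dx: float,
    plasmid_positions: Sequence[float] | str,
    n_plasmids: int,
    max_L: float,
    rng: np.random.Generator,
):
    n_cols = int(round(L0 / dx))
    max_cols = int(round(max_L / dx)) + 4
    total = int(round(params.density * n_cols * dx))
    a_adp = total // 4
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
    sites = np.asarray(sites, dtype=np.int64)
    bound = np.full(len(sites), 11)  # 11 ParA-ATP per plasmid anchors it
    n_bound = int(bound.sum())
    n_nucleoid = total - a_adp - n_bound
    if n_nucleoid < 0:
        raise ValueError("too many plasmids for the available ParA")
    A0 = np.zeros(max_cols, dtype=np.int64)
    placed = rng.integers(0, n_cols, n_nucleoid)
    np.add.at(A0, placed, 1)
    return A0, n_cols, max_cols, sites, bound.astype(np.int64), a_adp, 0


def simulate_di(
    params: DIParams,
    L0: float = 1.5,
    n_plasmids: int = 1,
    plasmid_positions: Sequence[float] | str = "random",
    T: float = 2400.0,
    seed: int = 0,
    dx: float = NATIVE_DX,
    growth_interval: float | None = None,
    final_length: float | None = None,
    duplication_times: Sequence[float] = (),
    output_interval: float = 5.0,
    replenish: bool = True,
) -> DIResult:
    """Run the diffusion/immobilization simulator.

    ``L0`` is the initial nucleoid length (µm).  To grow the nucleoid,
    either give ``growth_interval`` directly (seconds between two-column
    extension events) or ``final_length``, from which the interval needed
    to reach that length at time T is derived.  Initial condition per the
    model definition: a quarter of total ParA as cytoplasmic ParA-ADP,
    11 ParA-ATP bound to each plasmid, the rest placed uniformly at
    random on the nucleoid.
    """
    if dx <= 0 or L0 <= 0 or T <= 0:
        raise ValueError("dx, L0 and T must be positive")
    rng = np.random.default_rng(seed)
    if final_length is not None:
        n_events = int(round((final_length - L0) / (2 * dx)))
        if n_events > 0:
            growth_interval = T / (n_events + 1)
    max_L = final_length if final_length else L0 + 0.01
    if growth_interval and not final_length:
        max_L = L0 + 2 * dx * (T / growth_interval + 2)
    A0, n_cols, max_cols, sites, bound, a_adp, a_cyto = _initial_state(
        params, L0, dx, plasmid_positions, n_plasmids, max_L, rng
    )
    k_AB_eff = params.k_AB * (NATIVE_DX / dx)
    out = di_run(
        int(rng.integers(0, 2**31 - 1)),
        dx,
        params.D_A / dx**2,
        params.D_P / dx**2,
        params.k_on,
        k_AB_eff,
        params.k_B,
        params.k_W,
        params.k_off,
        params.max_bound,
        params.immobilize_threshold,
        A0,
        n_cols,
        sites,
        bound,
        a_adp,
        a_cyto,
        T,
        output_interval,
        growth_interval if growth_interval else -1.0,
        np.asarray(sorted(duplication_times), dtype=np.float64),
        params.density if replenish else -1.0,
    )
    (times, psites, pbound, n_p, kymo, adp, cyto, ncols, status) = out
    if status != 0:
        raise RuntimeError("bound-count invariant breached in di_run")
    return DIResult(times, psites, pbound, n_p, kymo, adp, cyto, ncols, dx, seed)


def duplication_assay(
    params: DIParams,
    D_P_override: float | None = None,
    n_events: int = 300,
    seed: int = 0,
    L: float = 3.0,
    dx: float = NATIVE_DX,
    relax_time: float = 100.0,
    window: float = 20.0,
    threshold: float = 0.8,
    output_interval: float = 0.5,
):
    """Fraction of duplication events separating >= ``threshold`` µm.

    Each replicate relaxes a single plasmid (started mid-nucleoid on a
    fixed-length nucleoid) for ``relax_time`` s, duplicates it, and
    records the maximal additional inter-plasmid separation within
    ``window`` s of the duplication instant.  Returns
    ``(fraction, max_separations)``.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    p = params if D_P_override is None else replace(params, D_P=D_P_override)
    seeds = np.random.SeedSequence(seed).generate_state(n_events) % (2**31 - 1)
    max_seps = np.empty(n_events)
    for k in range(n_events):
        res = simulate_di(
            p,
            L0=L,
            n_plasmids=1,
            plasmid_positions="mid",
            T=relax_time + window,
            seed=int(seeds[k]),
            dx=dx,
            duplication_times=[relax_time],
            output_interval=output_interval,
        )
        after = res.times >= relax_time
        pos = res.positions_um[after]
        two = res.n_plasmids[after] >= 2
        if not np.any(two):
            max_seps[k] = 0.0
            continue
        sep = np.abs(pos[two, 1] - pos[two, 0])
        max_seps[k] = sep.max()  # initial separation is zero by construction
    fraction = float(np.mean(max_seps >= threshold))
    return fraction, max_seps
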