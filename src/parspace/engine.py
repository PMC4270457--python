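"""Exact stochastic simulation kernel shared by both lattice simulators.

The engine provides:

* :class:`LatticeState` — the full state of a lattice simulation (per-site
  mobile ParA-ATP counts, polymer occupancy, plasmids, cytoplasmic pools).
* :func:`run_ssa` — a generic Gillespie direct-method loop over an arbitrary
  set of reaction channels with scheduled (deterministic-time) events and
  periodic state sampling.  Used directly for engine-level contracts and
  small models; the two production simulators compile specialised loops
  (see ``parspace._kernels``) with incrementally maintained per-category
  propensity sums, which realise the same process much faster.
* :func:`grow_nucleoid` / :func:`duplicate_plasmid` — the timed-event
  semantics (lattice extension by two empty columns at a uniformly random
  position, duplication of a uniformly chosen plasmid into an unloaded
  copy at the same site) shared by both simulators.

Exactness notes: reflecting boundaries and hard walls are realised in the
specialised kernels by *null events* (a hop channel whose target is
forbidden leaves the state unchanged).  Adding self-loop transitions to a
continuous-time Markov chain does not change its law (uniformization), so
the sampled trajectory remains exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "LatticeState",
    "ScheduledEvents",
    "Reaction",
    "run_ssa",
    "grow_nucleoid",
    "duplicate_plasmid",
]

#: target ParA density maintained on growth (dimers per µm of long axis)
PARA_DENSITY_PER_UM = 2400.0


@dataclass
class LatticeState:
    """Full stochastic-model state.

    ``mobile`` has shape (n_long, n_short): nucleoid-bound mobile ParA-ATP
    counts per site.  ``polymer`` has the same shape with 0/1 occupancy.
    ``plasmid_sites`` are long-axis column indices, ``plasmid_bound`` the
    per-plasmid bound ParA-ATP counts (diffusion/immobilization model).
    Cytoplasmic pools are global counts (no spatial resolution needed on
    the fast cytoplasmic diffusion timescale).
    """

    t: float
    dx: float
    mobile: np.ndarray
    polymer: np.ndarray
    plasmid_sites: np.ndarray
    plasmid_bound: np.ndarray
    A_ADP: int
    A_CYTO: int

    @property
    def n_long(self) -> int:
        return self.mobile.shape[0]

    @property
    def n_short(self) -> int:
        return self.mobile.shape[1]

    @property
    def total_parA(self) -> int:
        return int(
            self.mobile.sum()
            + self.polymer.sum()
            + self.plasmid_bound.sum()
            + self.A_ADP
            + self.A_CYTO
        )

    def validate(self) -> None:
        if np.any(self.mobile < 0) or self.A_ADP < 0 or self.A_CYTO < 0:
            raise ValueError("negative molecule count")
        if not np.isin(self.polymer, (0, 1)).all():
            raise ValueError("polymer occupancy must be 0/1")
        if np.any(self.plasmid_sites < 0) or np.any(self.plasmid_sites >= self.n_long):
            raise ValueError("plasmid site outside lattice")
        if np.any(self.plasmid_bound < 0):
            raise ValueError("negative plasmid-bound count")

    def copy(self) -> "LatticeState":
        return LatticeState(
            t=self.t,
            dx=self.dx,
            mobile=self.mobile.copy(),
            polymer=self.polymer.copy(),
            plasmid_sites=self.plasmid_sites.copy(),
            plasmid_bound=self.plasmid_bound.copy(),
            A_ADP=self.A_ADP,
            A_CYTO=self.A_CYTO,
        )


@dataclass(frozen=True)
class ScheduledEvents:
    """Deterministically timed events interleaved with the SSA."""

    growth_interval: float | None = None
    duplication_times: Sequence[float] = field(default_factory=tuple)
    output_interval: float = 5.0

    def __post_init__(self) -> None:
        if self.growth_interval is not None and not self.growth_interval > 0:
            raise ValueError("growth_interval must be positive")
        if not self.output_interval > 0:
            raise ValueError("output_interval must be positive")


@dataclass(frozen=True)
class Reaction:
    """A reaction channel: a propensity function and a state update."""

    name: str
    propensity: Callable[[LatticeState], float]
    apply: Callable[[LatticeState, np.random.Generator], None]


def run_ssa(
    state: LatticeState,
    reactions: Sequence[Reaction],
    events: ScheduledEvents,
    T: float,
    seed: int,
    replenish_density: float | None = PARA_DENSITY_PER_UM,
) -> list[LatticeState]:
    """Gillespie direct method to horizon T with scheduled events.

    Returns state snapshots taken at every ``events.output_interval``
    (including t=0 and the final time).  Scheduled growth/duplication
    events fire at their exact times; propensities are re-evaluated after
    every event.  Determinism contract: same seed and inputs give the
    identical event sequence.
    """
    rng = np.random.default_rng(seed)
    s = state.copy()
    snapshots = [s.copy()]
    next_out = events.output_interval
    next_growth = events.growth_interval or np.inf
    dup_times = sorted(t for t in events.duplication_times if t > s.t)
    dup_i = 0

    while s.t < T:
        props = np.array([r.propensity(s) for r in reactions], dtype=float)
        if np.any(props < 0):
            bad = reactions[int(np.argmin(props))]
            raise RuntimeError(f"negative propensity for reaction {bad.name!r}")
        total = props.sum()
        t_react = s.t + rng.exponential(1.0 / total) if total > 0 else np.inf
        t_next_dup = dup_times[dup_i] if dup_i < len(dup_times) else np.inf
        t_event = min(t_react, next_growth, t_next_dup, T)

        while next_out <= min(t_event, T):
            snap = s.copy()
            snap.t = next_out
            snapshots.append(snap)
            next_out += events.output_interval

        s.t = t_event
        if t_event >= T:
            s.t = T
            break
        if t_event == next_growth:
            grow_nucleoid(s, rng, replenish_density=replenish_density)
            next_growth += events.growth_interval
        elif t_event == t_next_dup:
            duplicate_plasmid(s, rng)
            dup_i += 1
        else:
            k = rng.choice(len(reactions), p=props / total)
            reactions[k].apply(s, rng)

    if snapshots[-1].t < T:
        snap = s.copy()
        snap.t = T
        snapshots.append(snap)
    return snapshots


def grow_nucleoid(
    state: LatticeState,
    rng: np.random.Generator,
    replenish_density: float | None = PARA_DENSITY_PER_UM,
) -> LatticeState:
    """Extend the lattice by two empty long-axis columns, in place.

    The two columns (n_short sites each, holding no ParA and no plasmid)
    are inserted at one uniformly random long-axis position; all site
    indices at or right of the insertion shift by two.  If
    ``replenish_density`` is given, cytoplasmic ParA-ADP is topped up so
    the total ParA per µm of long axis is restored (newly synthesised
    protein enters through the slow ADP→ATP maturation step); ``None``
    keeps the absolute copy number fixed.
    """
    n_long, n_short = state.mobile.shape
    pos = int(rng.integers(0, n_long + 1))
    empty = np.zeros((2, n_short), dtype=state.mobile.dtype)
    state.mobile = np.concatenate([state.mobile[:pos], empty, state.mobile[pos:]])
    state.polymer = np.concatenate(
        [state.polymer[:pos], empty.copy(), state.polymer[pos:]]
    )
    state.plasmid_sites = np.where(
        state.plasmid_sites >= pos, state.plasmid_sites + 2, state.plasmid_sites
    )
    if replenish_density is not None:
        target = int(round(replenish_density * (n_long + 2) * state.dx))
        deficit = target - state.total_parA
        if deficit > 0:
            state.A_ADP += deficit
    return state


def duplicate_plasmid(state: LatticeState, rng: np.random.Generator) -> LatticeState:
    """Duplicate one uniformly chosen plasmid, in place.

    The new plasmid appears at the same long-axis site with zero bound
    ParA-ATP; the original keeps its bound count.
    """
    n = len(state.plasmid_sites)
    if n == 0:
        raise RuntimeError("duplication scheduled with no plasmid present")
    k = int(rng.integers(0, n))
    state.plasmid_sites = np.append(state.plasmid_sites, state.plasmid_sites[k])
    state.plasmid_bound = np.append(state.plasmid_bound, 0)
    return state


def empty_lattice(n_long: int, n_short: int = 1, dx: float = 0.005) -> LatticeState:
    """Convenience constructor for an empty lattice state at t=0."""
    return LatticeState(
        t=0.0,
        dx=dx,
        mobile=np.zeros((n_long, n_short), dtype=np.int64),
        polymer=np.zeros((n_long, n_short), dtype=np.int64),
        plasmid_sites=np.zeros(0, dtype=np.int64),
        plasmid_bound=np.zeros(0, dtype=np.int64),
        A_ADP=0,
        A_CYTO=0,
    )
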