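"""Stochastic rejoining of DSB free ends over a 24 h repair window.

Simple breaks rejoin correctly: each pair of cognate simple ends closes with
probability δt/τ1 per time step.  Complex ends attempt repair with
probability 0.5·δt/τ2 per end per step (the 0.5 compensating for each end
being counted twice) and, when an attempt fires, choose a partner among all
other open complex ends with the Gaussian proximity weight

    I(r) = (1/W) · exp(-r²/σ²),

the cognate end (r = 0) being a candidate like any other.  Choosing the
cognate restores the break (proper repair); any other choice is a
misrejoining.  By default the weights are normalised, so every fired
attempt closes and the 0.5/τ2 firing rate fixes the complex-break decay at
exp(-t/τ2) — the bi-exponential kinetics the model is built around.
Setting ``normalize_kernel=False`` treats the weights as absolute
per-candidate probabilities instead (the attempt aborts with probability
1 - ΣI/max(ΣI, 1)), which preserves a role for the absolute scale W but
slows complex repair far below 1/τ2 at the default W = 50.

Two drivers are provided: ``step_repair`` is the literal per-second sweep;
``simulate_repair`` samples the identical process event-by-event (geometric
waiting steps, conditional-binomial firing sets) and is what the experiment
pipeline uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._rng import as_rng
from .damage import DSBRecord


@dataclass(frozen=True)
class RepairParameters:
    """Repair time constants and proximity-kernel parameters.

    τ1 and τ2 are the fast (simple-break) and slow (complex-break) repair
    times of the bi-exponential decay; W and σ² set the absolute scale and
    range of the misrejoining kernel; δt is the sweep step; the horizon is
    24 h for fibroblast-style protocols (lymphocytes are typically given
    ~50 h).
    """

    tau1_h: float = 1.7
    tau2_h: float = 23.7
    w: float = 50.0
    sigma2_um2: float = 0.8
    dt_s: float = 1.0
    horizon_h: float = 24.0
    normalize_kernel: bool = True

    def __post_init__(self):
        if min(self.tau1_h, self.tau2_h, self.w, self.sigma2_um2,
               self.dt_s, self.horizon_h) <= 0:
            raise ValueError("all repair parameters must be positive")
        if self.dt_s / (self.tau1_h * 3600.0) > 0.1 or \
                0.5 * self.dt_s / (self.tau2_h * 3600.0) > 0.1:
            raise ValueError("δt too large for valid per-step probabilities")

    @property
    def p_simple(self) -> float:
        return self.dt_s / (self.tau1_h * 3600.0)

    @property
    def p_complex(self) -> float:
        return 0.5 * self.dt_s / (self.tau2_h * 3600.0)

    @property
    def n_steps(self) -> int:
        return round(self.horizon_h * 3600.0 / self.dt_s)


def misrepair_kernel(r_um, params: RepairParameters | None = None):
    """Proximity weight I(r) = (1/W)·exp(-r²/σ²)."""
    params = params or RepairParameters()
    r = np.asarray(r_um, dtype=float)
    out = np.exp(-r ** 2 / params.sigma2_um2) / params.w
    return float(out) if out.ndim == 0 else out


@dataclass
class RejoinEvent:
    time_s: float
    end_a: int
    end_b: int
    kind: str                    # "proper" | "improper"


@dataclass
class RepairState:
    """Open/closed status of all free ends plus the junction log."""

    n_dsbs: int
    is_complex: np.ndarray       # (k,) bool per DSB
    positions_um: np.ndarray     # (k, 3) break positions
    end_open: np.ndarray = field(init=False)
    partner: np.ndarray = field(init=False)
    events: list[RejoinEvent] = field(default_factory=list)
    time_s: float = 0.0

    def __post_init__(self):
        self.end_open = np.ones(2 * self.n_dsbs, dtype=bool)
        self.partner = np.full(2 * self.n_dsbs, -1, dtype=np.int64)

    @classmethod
    def from_dsbs(cls, dsbs: list[DSBRecord]) -> "RepairState":
        for i, d in enumerate(dsbs):
            if d.id != i:
                raise ValueError("DSB ids must be 0..k-1 in list order")
        k = len(dsbs)
        is_complex = np.array([d.complexity == "complex" for d in dsbs],
                              dtype=bool)
        pos = (np.stack([d.position_um for d in dsbs])
               if k else np.zeros((0, 3)))
        return cls(k, is_complex, pos)

    @property
    def n_open_ends(self) -> int:
        return int(self.end_open.sum())

    @property
    def remaining_breaks(self) -> int:
        """Unrepaired breaks: one per two open ends (end count stays even)."""
        return self.n_open_ends // 2

    def close(self, end_a: int, end_b: int, time_s: float) -> None:
        if not (self.end_open[end_a] and self.end_open[end_b]):
            raise ValueError("attempt to close an already-closed end")
        self.end_open[end_a] = self.end_open[end_b] = False
        self.partner[end_a] = end_b
        self.partner[end_b] = end_a
        kind = "proper" if end_a ^ 1 == end_b else "improper"
        self.events.append(RejoinEvent(time_s, end_a, end_b, kind))


def _choose_partner(end: int, open_complex: np.ndarray, state: RepairState,
                    params: RepairParameters, rng: np.random.Generator) -> int:
    """Partner for a fired complex end, or -1 if the attempt aborts."""
    cands = open_complex[open_complex != end]
    if cands.size == 0:
        return -1
    r = np.linalg.norm(state.positions_um[cands // 2]
                       - state.positions_um[end // 2], axis=1)
    weights = misrepair_kernel(r, params)
    total = float(weights.sum())
    if total <= 0:
        return -1
    if not params.normalize_kernel:
        norm = max(total, 1.0)
        if rng.random() >= total / norm:
            return -1
    return int(rng.choice(cands, p=weights / total))


def step_repair(state: RepairState, params: RepairParameters | None = None,
                seed=None, allow_misrepair: bool = True) -> RepairState:
    """One literal δt sweep over all free ends (mutates and returns state)."""
    params = params or RepairParameters()
    rng = as_rng(seed)
    state.time_s += params.dt_s
    t = state.time_s

    # simple pairs: proper repair with probability δt/τ1 per pair
    simple = np.flatnonzero(~state.is_complex)
    for d in simple:
        a, b = 2 * d, 2 * d + 1
        if state.end_open[a] and state.end_open[b] \
                and rng.random() < params.p_simple:
            state.close(a, b, t)

    # complex ends: fire with probability 0.5·δt/τ2, sequential random order
    complex_ends = np.flatnonzero(
        np.repeat(state.is_complex, 2) & state.end_open)
    rng.shuffle(complex_ends)
    for e in complex_ends:
        if not state.end_open[e]:
            continue
        if rng.random() >= params.p_complex:
            continue
        if allow_misrepair:
            open_now = np.flatnonzero(
                np.repeat(state.is_complex, 2) & state.end_open)
            partner = _choose_partner(int(e), open_now, state, params, rng)
        else:
            partner = int(e) ^ 1 if state.end_open[int(e) ^ 1] else -1
        if partner >= 0:
            state.close(int(e), partner, t)
    return state


def _sample_lowest_firing(m: int, p: float, rng: np.random.Generator) -> int:
    """Index (1-based) of the lowest firing end given that at least one of m
    independent Bernoulli(p) fires."""
    q = 1.0 - p
    u = rng.random()
    j = int(math.floor(math.log1p(-u * (1.0 - q ** m)) / math.log(q))) + 1
    return min(max(j, 1), m)


def simulate_repair(dsbs: list[DSBRecord],
                    params: RepairParameters | None = None,
                    seed=None, allow_misrepair: bool = True,
                    ) -> tuple[RepairState, list[RejoinEvent]]:
    """Run the repair process to the horizon; exact event-driven sampling.

    Distributionally identical to iterating ``step_repair``: simple-pair
    closure steps are geometric; complex firing steps are geometric in the
    any-end-fires probability with the firing set drawn from the conditional
    binomial law; fired ends are processed in random order within a step.
    Deterministic given seed.  Ends still open at the horizon stay open
    (unrepaired at 24 h).
    """
    params = params or RepairParameters()
    rng = as_rng(seed)
    state = RepairState.from_dsbs(dsbs)
    n_steps = params.n_steps
    dt = params.dt_s

    # simple pairs close independently of everything else
    simple = np.flatnonzero(~state.is_complex)
    if simple.size:
        steps = rng.geometric(params.p_simple, size=simple.size)
        for d, k in zip(simple, steps):
            if k <= n_steps:
                state.close(2 * int(d), 2 * int(d) + 1, k * dt)

    # complex ends: jump between firing steps
    p = params.p_complex
    step_now = 0
    while True:
        open_complex = np.flatnonzero(
            np.repeat(state.is_complex, 2) & state.end_open)
        m = open_complex.size
        if m == 0:
            break
        p_any = 1.0 - (1.0 - p) ** m
        step_now += int(rng.geometric(p_any))
        if step_now > n_steps:
            break
        j = _sample_lowest_firing(m, p, rng)
        fired = [open_complex[j - 1]]
        if j < m:
            more = rng.random(m - j) < p
            fired.extend(open_complex[j:][more])
        fired = np.array(fired)
        rng.shuffle(fired)
        t = step_now * dt
        for e in fired:
            if not state.end_open[e]:
                continue
            if allow_misrepair:
                open_now = np.flatnonzero(
                    np.repeat(state.is_complex, 2) & state.end_open)
                partner = _choose_partner(int(e), open_now, state, params, rng)
            else:
                partner = int(e) ^ 1 if state.end_open[int(e) ^ 1] else -1
            if partner >= 0:
                state.close(int(e), partner, t)

    state.time_s = params.horizon_h * 3600.0
    state.events.sort(key=lambda ev: ev.time_s)
    return state, state.events


def remaining_break_trace(state: RepairState, times_h) -> np.ndarray:
    """N(t): breaks with at least one open end at each requested time."""
    k = state.n_dsbs
    close_time = np.full(2 * k, np.inf)
    for ev in state.events:
        close_time[ev.end_a] = ev.time_s
        close_time[ev.end_b] = ev.time_s
    break_done = np.maximum(close_time[0::2], close_time[1::2])
    times_s = np.asarray(times_h, dtype=float) * 3600.0
    return (break_done[None, :] > times_s[:, None]).sum(axis=1)


def theoretical_decay(n1: float, n2: float, t_h,
                      params: RepairParameters | None = None):
    """Bi-exponential expected remaining breaks
    N(t) = N1·exp(-t/τ1) + N2·exp(-t/τ2)."""
    params = params or RepairParameters()
    t = np.asarray(t_h, dtype=float)
    if (t < 0).any():
        raise ValueError("t must be non-negative")
    out = n1 * np.exp(-t / params.tau1_h) + n2 * np.exp(-t / params.tau2_h)
    return float(out) if out.ndim == 0 else out
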