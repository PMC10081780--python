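"""2-D lattice Monte Carlo of bead diffusion onto an absorbing fibrin fiber.

The model: beads perform independent random walks on a square grid inside a
2 μm × 2 μm box.  The top, left and right walls reflect; the bottom row of
nodes represents a fibrin fiber and absorbs — a bead landing there is bound
irreversibly at that node and time.  At every time step a bead either stays
put or moves to one of its 4 nearest neighbours, each of the 5 outcomes with
probability 1/5 (the ``lazy5`` rule).  A ``move4`` variant without the stay
option is provided; it is the rule that realises D = Δx²/(4Δt) exactly,
whereas lazy5 yields an effective per-axis diffusivity of Δx²/(5Δt).

"Reflecting" is ambiguous on a lattice, so two wall rules are offered:
``reject_stay`` (an off-domain move is rejected and the bead stays that
step; preserves a uniform stationary distribution) and ``mirror`` (the move
is folded back about the wall).

The inner loop is compiled with numba; each simulation consumes its own
deterministic random stream spawned from a master seed, so ensembles are
bit-for-bit reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "SimConfig",
    "BeadState",
    "SimResult",
    "BindingSummary",
    "timestep_from_D",
    "step_variance_per_axis",
    "step",
    "run_simulation",
    "run_ensemble",
    "msd_diagnostic",
    "export_trace",
]

STEP_RULES = ("lazy5", "move4")
REFLECTION_RULES = ("reject_stay", "mirror")


def timestep_from_D(dx: float, D: float) -> float:
    """Time step (s) from the grid spacing and diffusion coefficient.

    Inverts D ≈ Δx²/(4Δt): for Δx = 0.02 μm and D = 10 μm²/s
    (1×10⁻⁷ cm²/s, a 24 nm bead) this gives 1×10⁻⁵ s.
    """
    if dx <= 0 or D <= 0:
        raise ValueError("dx and D must both be > 0")
    return dx * dx / (4.0 * D)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one diffusion–absorption simulation.

    Distances in μm, times in s.  The domain must be an exact multiple of
    ``space_step``; node indices run 0..W/Δx and 0..H/Δx inclusive, with
    j = 0 the absorbing fiber row.
    """

    domain_width: float = 2.0
    domain_height: float = 2.0
    space_step: float = 0.02
    time_step: float = 1e-5
    diffusion_coefficient: float = 10.0
    n_beads: int = 100
    max_time: float = 60.0
    step_rule: str = "lazy5"
    reflection_rule: str = "reject_stay"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.space_step <= 0 or self.time_step <= 0:
            raise ValueError("space_step and time_step must be > 0")
        for name, extent in (
            ("domain_width", self.domain_width),
            ("domain_height", self.domain_height),
        ):
            n = extent / self.space_step
            if abs(n - round(n)) > 1e-9 or extent <= 0:
                raise ValueError(f"{name} must be a positive multiple of space_step")
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if self.max_time < 0:
            raise ValueError("max_time must be >= 0")
        if self.step_rule not in STEP_RULES:
            raise ValueError(f"step_rule must be one of {STEP_RULES}")
        if self.reflection_rule not in REFLECTION_RULES:
            raise ValueError(f"reflection_rule must be one of {REFLECTION_RULES}")

    @property
    def nx(self) -> int:
        """Highest x node index (W/Δx)."""
        return round(self.domain_width / self.space_step)

    @property
    def ny(self) -> int:
        """Highest y node index (H/Δx)."""
        return round(self.domain_height / self.space_step)

    @property
    def max_steps(self) -> int:
        return round(self.max_time / self.time_step)


@dataclass(frozen=True)
class BeadState:
    """Final state of one bead: grid node, and binding time/location if bound."""

    i: int
    j: int
    bound: bool
    bind_time: float | None = None
    bind_location: float | None = None


def step_variance_per_axis(step_rule: str, dx: float) -> float:
    """Per-step displacement variance along one axis for a step rule.

    lazy5 moves ±Δx on a given axis with probability 1/5 each (variance
    (2/5)Δx²); move4 with probability 1/4 each (variance (1/2)Δx²).
    """
    if step_rule == "lazy5":
        return 0.4 * dx * dx
    if step_rule == "move4":
        return 0.5 * dx * dx
    raise ValueError(f"unknown step_rule {step_rule!r}")


def step(
    i: int, j: int, config: SimConfig, rng: np.random.Generator
) -> tuple[int, int, bool]:
    """Advance one unbound bead by a single time step.

    Returns the new node ``(i, j)`` and whether the move bound the bead
    (landed on the absorbing row j = 0).  Pure-Python reference for the
    compiled kernel; used for exact per-outcome probability checks.
    """
    if j == 0:
        raise ValueError("cannot step a bound bead (j == 0)")
    nx, ny = config.nx, config.ny
    if config.step_rule == "lazy5":
        c = int(rng.integers(0, 5))
    else:  # move4: options 1..4
        c = int(rng.integers(0, 4)) + 1
    di = dj = 0
    if c == 1:
        di = 1
    elif c == 2:
        di = -1
    elif c == 3:
        dj = 1
    elif c == 4:
        dj = -1
    ti, tj = i + di, j + dj
    if config.reflection_rule == "reject_stay":
        if ti < 0 or ti > nx or tj > ny:
            ti, tj = i, j
    else:  # mirror
        if ti < 0:
            ti = -ti
        elif ti > nx:
            ti = 2 * nx - ti
        if tj > ny:
            tj = 2 * ny - tj
    return ti, tj, tj == 0


@njit(cache=True)
def _sim_kernel(
    seed: np.uint32,
    n_beads: int,
    nx: int,
    ny: int,
    max_steps: int,
    lazy: int,
    mirror: int,
    trace_every: int,
    trace: np.ndarray,
):  # pragma: no cover - exercised via run_simulation
    np.random.seed(seed)
    xi = np.empty(n_beads, np.int64)
    yj = np.empty(n_beads, np.int64)
    bind_step = np.full(n_beads, -1, np.int64)
    # initial placement: uniform over grid nodes in the top half (j >= ny//2)
    for k in range(n_beads):
        xi[k] = np.random.randint(0, nx + 1)
        yj[k] = np.random.randint(ny // 2, ny + 1)
    n_frames = trace.shape[0]
    for k in range(n_beads):
        i = xi[k]
        j = yj[k]
        if n_frames > 0:
            trace[0, k, 0] = i
            trace[0, k, 1] = j
        for t in range(1, max_steps + 1):
            if lazy == 1:
                c = np.random.randint(0, 5)
            else:
                c = np.random.randint(0, 4) + 1
            ti = i
            tj = j
            if c == 1:
                ti = i + 1
            elif c == 2:
                ti = i - 1
            elif c == 3:
                tj = j + 1
            elif c == 4:
                tj = j - 1
            if mirror == 1:
                if ti < 0:
                    ti = -ti
                elif ti > nx:
                    ti = 2 * nx - ti
                if tj > ny:
                    tj = 2 * ny - tj
            else:
                if ti < 0 or ti > nx or tj > ny:
                    ti = i
                    tj = j
            i = ti
            j = tj
            bound = j == 0
            if bound:
                bind_step[k] = t
            if n_frames > 0 and t % trace_every == 0:
                f = t // trace_every
                if f < n_frames:
                    trace[f, k, 0] = i
                    trace[f, k, 1] = j
            if bound:
                # bound beads stop updating; freeze remaining trace frames
                if n_frames > 0:
                    f0 = t // trace_every + 1
                    for f in range(f0, n_frames):
                        trace[f, k, 0] = i
                        trace[f, k, 1] = j
                break
        xi[k] = i
        yj[k] = j
    return xi, yj, bind_step


@dataclass(frozen=True)
class SimResult:
    """Final bead states of one simulation (arrays over beads)."""

    config: SimConfig
    seed: int
    x_node: np.ndarray
    y_node: np.ndarray
    bind_step: np.ndarray  # -1 for censored (never-bound) beads
    trace: np.ndarray | None = None  # (n_frames, n_beads, 2) node indices
    trace_every: int = 0

    @property
    def bound(self) -> np.ndarray:
        return self.bind_step >= 0

    @property
    def bind_time(self) -> np.ndarray:
        """Bind times in s; NaN for censored beads."""
        t = self.bind_step * self.config.time_step
        return np.where(self.bound, t, np.nan)

    @property
    def bind_location(self) -> np.ndarray:
        """Binding x coordinates in μm; NaN for censored beads."""
        x = self.x_node * self.config.space_step
        return np.where(self.bound, x, np.nan)

    def bead_states(self) -> list[BeadState]:
        out = []
        for k in range(self.config.n_beads):
            b = bool(self.bound[k])
            out.append(
                BeadState(
                    i=int(self.x_node[k]),
                    j=int(self.y_node[k]),
                    bound=b,
                    bind_time=float(self.bind_time[k]) if b else None,
                    bind_location=float(self.bind_location[k]) if b else None,
                )
            )
        return out


def _spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-simulation kernel seeds from a master seed.

    Children of ``SeedSequence(master_seed)`` in spawn order; each
    contributes one uint32 state word.
    """
    ss = np.random.SeedSequence(master_seed)
    return np.array(
        [child.generate_state(1, np.uint32)[0] for child in ss.spawn(n)],
        dtype=np.uint32,
    )


def run_simulation(
    config: SimConfig, seed: int | None = None, trace_every: int = 0
) -> SimResult:
    """Run one simulation of ``config.n_beads`` independent beads.

    Beads start uniformly at random on grid nodes in the top half of the
    domain and walk until they bind (land on j = 0) or ``max_time`` is
    reached; never-bound beads are censored.  ``trace_every`` > 0 records
    every k-th step's positions for animation/export.
    """
    if seed is None:
        seed = int(_spawn_seeds(config.master_seed, 1)[0])
    n_frames = (config.max_steps // trace_every + 1) if trace_every > 0 else 0
    trace = np.zeros((n_frames, config.n_beads, 2), np.int64)
    xi, yj, bind_step = _sim_kernel(
        np.uint32(seed),
        config.n_beads,
        config.nx,
        config.ny,
        config.max_steps,
        1 if config.step_rule == "lazy5" else 0,
        1 if config.reflection_rule == "mirror" else 0,
        trace_every if trace_every > 0 else 1,
        trace,
    )
    return SimResult(
        config=config,
        seed=int(seed),
        x_node=xi,
        y_node=yj,
        bind_step=bind_step,
        trace=trace if trace_every > 0 else None,
        trace_every=trace_every,
    )


@dataclass(frozen=True)
class BindingSummary:
    """Ensemble summary of where and when beads bound.

    ``bind_fraction_pct[i]`` is the percentage of all bead trajectories in
    the ensemble that bound at x node i; the per-node fractions sum to the
    overall bound percentage.  ``mean_bind_time_s[i]`` averages over beads
    bound at node i (NaN where none bound); censored beads are excluded
    from all time averages.
    """

    config: SimConfig
    n_sims: int
    x_um: np.ndarray
    n_bound: np.ndarray
    bind_fraction_pct: np.ndarray
    mean_bind_time_s: np.ndarray
    overall_bound_fraction: float
    mean_bind_time_overall_s: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": self.x_um,
                "bind_fraction_pct": self.bind_fraction_pct,
                "mean_bind_time_s": self.mean_bind_time_s,
                "n_bound": self.n_bound,
            }
        )


def run_ensemble(config: SimConfig, n_sims: int) -> BindingSummary:
    """Aggregate ``n_sims`` independent simulations into a BindingSummary.

    Per-simulation seeds are spawned deterministically from
    ``config.master_seed``, so the result is bit-for-bit reproducible.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    seeds = _spawn_seeds(config.master_seed, n_sims)
    nx = config.nx
    n_bound = np.zeros(nx + 1, np.int64)
    time_sum = np.zeros(nx + 1, float)
    total_bound = 0
    total_time = 0.0
    total = config.n_beads * n_sims
    for s in seeds:
        res = run_simulation(config, seed=int(s))
        b = res.bound
        nodes = res.x_node[b]
        times = res.bind_step[b] * config.time_step
        np.add.at(n_bound, nodes, 1)
        np.add.at(time_sum, nodes, times)
        total_bound += int(b.sum())
        total_time += float(times.sum())
    with np.errstate(invalid="ignore"):
        mean_t = np.where(n_bound > 0, time_sum / np.maximum(n_bound, 1), np.nan)
    return BindingSummary(
        config=config,
        n_sims=n_sims,
        x_um=np.arange(nx + 1) * config.space_step,
        n_bound=n_bound,
        bind_fraction_pct=100.0 * n_bound / total,
        mean_bind_time_s=mean_t,
        overall_bound_fraction=total_bound / total,
        mean_bind_time_overall_s=(total_time / total_bound) if total_bound else math.nan,
    )


def msd_diagnostic(
    config: SimConfig,
    n_steps: int,
    n_walkers: int,
    seed: int = 0,
    record_every: int | None = None,
) -> pd.DataFrame:
    """Free-space displacement-variance trace validating the walk's diffusivity.

    Walls and absorption are disabled; walkers start at the origin.  Under
    lazy5 the per-axis variance after n steps is (2/5)·Δx²·n, under move4
    (1/2)·Δx²·n (which corresponds to D = Δx²/(4Δt)).  Returns a frame
    with columns ``step``, ``var_x``, ``var_y`` at recorded steps.
    """
    if record_every is None:
        record_every = max(1, n_steps // 100)
    rng = np.random.default_rng(seed)
    x = np.zeros(n_walkers, np.int64)
    y = np.zeros(n_walkers, np.int64)
    steps, vx, vy = [0], [0.0], [0.0]
    lazy = config.step_rule == "lazy5"
    for t in range(1, n_steps + 1):
        c = rng.integers(0, 5, n_walkers) if lazy else rng.integers(1, 5, n_walkers)
        x += (c == 1).astype(np.int64) - (c == 2).astype(np.int64)
        y += (c == 3).astype(np.int64) - (c == 4).astype(np.int64)
        if t % record_every == 0 or t == n_steps:
            dx2 = config.space_step ** 2
            steps.append(t)
            vx.append(float(np.var(x)) * dx2)
            vy.append(float(np.var(y)) * dx2)
    return pd.DataFrame({"step": steps, "var_x": vx, "var_y": vy})


def export_trace(result: SimResult, path) -> pd.DataFrame:
    """Write a recorded trace to CSV (one row per frame per bead).

    Columns: frame, time_s, bead, x_um, y_um, bound.  Frame spacing in time
    is ``trace_every·Δt``.
    """
    if result.trace is None:
        raise ValueError("simulation was run without trace recording")
    n_frames, n_beads, _ = result.trace.shape
    dt, dx = result.config.time_step, result.config.space_step
    frame = np.repeat(np.arange(n_frames), n_beads)
    bead = np.tile(np.arange(n_beads), n_frames)
    x = result.trace[:, :, 0].ravel() * dx
    y = result.trace[:, :, 1].ravel() * dx
    step_of_frame = frame * result.trace_every
    bound = (result.bind_step[bead] >= 0) & (
        step_of_frame >= np.where(result.bind_step[bead] >= 0, result.bind_step[bead], 0)
    )
    df = pd.DataFrame(
        {
            "frame": frame,
            "time_s": step_of_frame * dt,
            "bead": bead,
            "x_um": x,
            "y_um": y,
            "bound": bound,
        }
    )
    df.to_csv(path, index=False)
    return df
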