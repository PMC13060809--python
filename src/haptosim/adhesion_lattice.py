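"""Stochastic nascent-adhesion lattice.

Potential adhesion sites live on a planar ``Nx x Ny`` grid with spacing
``ell`` (in units of the initial cell radius).  Each site is either occupied
(``n = 1``) or not (``n = 0``).  The expected occupancy follows an exponential
gradient in ``y``,

    chi_n(y) = n0 * exp(g * (y - y0)),

so that the fractional change across one cell radius is the constant relative
steepness ``g``.  At every stochastic step each site draws a ranking score

    s_n = -ln(u) / chi_n,   u ~ U[0, 1),

an exponential "race" key: selecting the lowest scores is weighted sampling
without replacement with weights ``chi_n``.  Occupied sites turn over with a
fixed mean lifetime ``tau``: per step, ``round((dt/tau) * Nn)`` occupied sites
are relegated uniformly at random and the same number (adjusted when ECM
removal shrinks ``Nn``) of previously unoccupied sites are promoted by lowest
updated score.

ECM removal by the migrating cell degrades the per-site occupancy as

    d(chi_n)/dt = -k_rem(t) * phi * chi_n,

with ``k_rem = 0`` before ``t_start`` and ``k_rem0`` afterwards; the update is
integrated exactly over each step for the piecewise-constant cell footprint
``phi``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

__all__ = [
    "LatticeConfig",
    "OccupancyProfile",
    "AdhesionState",
    "SchedulePack",
    "occupancy_profile",
    "expected_count",
    "build_profile",
    "initialize_state",
    "step",
    "apply_removal",
    "pack_schedule",
    "unpack_schedule",
    "save_schedule",
    "load_schedule",
    "fit_gradient",
    "completed_lifetimes",
]

# RNG stream labels: one master seed per superset expands into independent
# streams for the per-site score draws and for the relegation permutations.
_STREAM_SCORES = 0
_STREAM_FLIP = 1


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry and rates of the stochastic adhesion lattice.

    Attributes
    ----------
    Nx, Ny : int
        Site counts per axis.
    ell : float
        Lattice spacing, in units of the initial cell radius.
    n0 : float
        Fractional occupancy at the initial centroid row (0 < n0 < 1).
    g : float
        Relative gradient steepness per cell radius (0 for uniform).
    x0, y0 : float
        Initial centroid coordinates (cell radii).
    tau : float
        Mean adhesion lifetime, in units of ``dt``.
    dt : float
        Stochastic update interval, seconds.
    krem0 : float
        ECM-removal rate constant (per second of model time).
    tstart : float
        Removal onset time, seconds.
    """

    Nx: int = 200
    Ny: int = 200
    ell: float = 0.1
    n0: float = 0.05
    g: float = 0.0
    x0: float = 10.0
    y0: float = 8.0
    tau: float = 30.0
    dt: float = 2.0
    krem0: float = 0.0
    tstart: float = 0.0

    def __post_init__(self) -> None:
        if self.Nx < 1 or self.Ny < 1:
            raise ValueError("site counts must be >= 1")
        if not 0.0 < self.n0 < 1.0:
            raise ValueError("n0 must lie in (0, 1)")
        if self.ell <= 0:
            raise ValueError("lattice spacing must be positive")
        if self.tau <= 0:
            raise ValueError("mean lifetime must be positive")
        if self.krem0 < 0:
            raise ValueError("removal rate must be non-negative")
        # occupancy is a probability-like weight; reject configurations in
        # which the exponential profile reaches 1 anywhere on the lattice
        ymax = self.site_y().max()
        ymin = self.site_y().min()
        for y in (ymin, ymax):
            if occupancy_profile(self, y) >= 1.0:
                raise ValueError(
                    "chi_n >= 1 on the lattice; reduce n0 or the gradient"
                )

    def site_x(self) -> np.ndarray:
        """Site-center x coordinates, shape ``(Nx,)``."""
        return (np.arange(self.Nx) + 0.5) * self.ell

    def site_y(self) -> np.ndarray:
        """Site-center y coordinates, shape ``(Ny,)``."""
        return (np.arange(self.Ny) + 0.5) * self.ell

    def to_dict(self) -> dict:
        return asdict(self)


def occupancy_profile(config: LatticeConfig, y) -> np.ndarray | float:
    """Pristine fractional occupancy ``chi_n(y) = n0 exp(g (y - y0))``."""
    return config.n0 * np.exp(config.g * (np.asarray(y, dtype=float) - config.y0))


@dataclass
class OccupancyProfile:
    """Per-site fractional occupancy ``chi`` (row-major ``(Ny, Nx)`` array).

    Starts as a pure function of the row coordinate ``y``; becomes genuinely
    per-site once ECM removal acts.  ``pristine`` records whether the closed
    form of the generating exponential still applies.
    """

    chi: np.ndarray
    pristine: bool = True

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        if np.any(self.chi < 0) or np.any(self.chi >= 1.0):
            raise ValueError("chi entries must lie in [0, 1)")

    def copy(self) -> "OccupancyProfile":
        return OccupancyProfile(self.chi.copy(), pristine=self.pristine)


def build_profile(config: LatticeConfig) -> OccupancyProfile:
    """Materialize the generating exponential on the site grid."""
    chi_row = occupancy_profile(config, config.site_y())
    chi = np.broadcast_to(chi_row[:, None], (config.Ny, config.Nx)).copy()
    return OccupancyProfile(chi, pristine=True)


def expected_count(config: LatticeConfig, profile: OccupancyProfile) -> float:
    """Expected number of occupied sites ``Nn``.

    For the pristine exponential profile this is the closed form

        Nn = n0 Nx (exp(g (Ny ell - y0)) - exp(-g y0)) / (g ell),

    (limit ``n0 Nx Ny`` as ``g -> 0``); after removal it is the midpoint
    quadrature ``(1/ell^2) \\iint chi dx dy = sum(chi)``.
    """
    if profile.pristine:
        if config.g == 0.0:
            return config.n0 * config.Nx * config.Ny
        g, ell, y0 = config.g, config.ell, config.y0
        return (
            config.n0
            * config.Nx
            * (np.exp(g * (config.Ny * ell - y0)) - np.exp(-g * y0))
            / (g * ell)
        )
    return float(profile.chi.sum())


def _round_half_even(x: float) -> int:
    """Round half to even, as a plain int (platform-stable counts)."""
    return int(np.rint(x))


def _rng(superset_id: int, stream: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([int(superset_id), stream]))
    )


@dataclass
class AdhesionState:
    """Boolean occupancy plus per-site scores and bookkeeping.

    ``occupied`` is a ``(Ny, Nx)`` boolean matrix; ``scores`` carries the
    current ranking scores ``s_n``; ``t_on`` records the step index at which
    each currently occupied site last became occupied (-1 if never), for
    lifetime statistics.  ``lifetimes`` accumulates completed occupancy
    episodes as ``(t_on, t_off)`` step-index pairs.
    """

    occupied: np.ndarray
    scores: np.ndarray
    t_on: np.ndarray
    t_index: int = 0
    score_rng: np.random.Generator | None = None
    flip_rng: np.random.Generator | None = None
    lifetimes: list = field(default_factory=list)

    @property
    def count(self) -> int:
        return int(self.occupied.sum())


def initialize_state(
    config: LatticeConfig,
    profile: OccupancyProfile,
    rng: np.random.Generator | int,
) -> AdhesionState:
    """Draw initial scores and occupy exactly the ``round(Nn)`` lowest.

    ``rng`` may be a numpy Generator or a superset id (int); in the latter
    case the documented two-stream expansion (scores, relegation shuffles)
    is derived from it so that replays are bit-for-bit identical.
    """
    if isinstance(rng, (int, np.integer)):
        score_rng = _rng(rng, _STREAM_SCORES)
        flip_rng = _rng(rng, _STREAM_FLIP)
    else:
        score_rng = rng
        flip_rng = rng
    target = _round_half_even(expected_count(config, profile))
    n_sites = config.Nx * config.Ny
    if target >= n_sites:
        raise ValueError("expected count must be smaller than the lattice")
    scores = _draw_scores(profile.chi, score_rng)
    occupied = np.zeros((config.Ny, config.Nx), dtype=bool)
    if target > 0:
        flat = scores.ravel()
        # argpartition + row-major index tie-break (ties have measure zero)
        idx = np.argpartition(flat, target - 1)[:target]
        occupied.ravel()[idx] = True
    t_on = np.where(occupied, 0, -1)
    return AdhesionState(
        occupied=occupied,
        scores=scores,
        t_on=t_on,
        t_index=0,
        score_rng=score_rng,
        flip_rng=flip_rng,
    )


def _draw_scores(chi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Exponential race keys ``-ln(u)/chi``; chi == 0 gives +inf (never wins)."""
    u = rng.random(chi.shape)
    with np.errstate(divide="ignore"):
        return np.where(chi > 0, -np.log1p(-u) / np.where(chi > 0, chi, 1.0), np.inf)


def step(
    state: AdhesionState,
    config: LatticeConfig,
    profile: OccupancyProfile,
    rng: np.random.Generator | None = None,
) -> AdhesionState:
    """Advance the occupancy pattern by one stochastic step (in place).

    Exactly ``k = round((dt/tau) Nn(t))`` occupied sites are relegated
    uniformly at random; every site receives an updated score and the lowest
    scoring previously-unoccupied sites are promoted so that the post-step
    occupied count equals ``round(Nn(t))`` (which may have decreased under
    removal).
    """
    score_rng = state.score_rng if rng is None else rng
    flip_rng = state.flip_rng if rng is None else rng
    nn = expected_count(config, profile)
    target = _round_half_even(nn)
    k = _round_half_even((1.0 / config.tau) * nn)
    occ_count = state.count
    if k > occ_count:
        raise ValueError("turnover count exceeds occupied count")

    t_next = state.t_index + 1
    # fresh scores for every site ("updated s_n"); constant per-step draw
    # count keeps superset streams aligned across model variants
    state.scores = _draw_scores(profile.chi, score_rng)

    was_occupied = state.occupied.copy()
    if k > 0:
        occ_idx = np.flatnonzero(state.occupied.ravel())
        drop = occ_idx[flip_rng.permutation(occ_count)[:k]]
        state.occupied.ravel()[drop] = False
        for j in drop:
            state.lifetimes.append((int(state.t_on.ravel()[j]), t_next))
        state.t_on.ravel()[drop] = -1

    # promote from sites unoccupied *before* this step
    n_promote = target - state.count
    if n_promote > 0:
        pool = np.flatnonzero(~was_occupied.ravel())
        s_pool = state.scores.ravel()[pool]
        pick = pool[np.argpartition(s_pool, n_promote - 1)[:n_promote]]
        state.occupied.ravel()[pick] = True
        state.t_on.ravel()[pick] = t_next
    elif n_promote < 0:
        # removal shrank the target below the post-relegation count: relegate
        # additional occupied sites uniformly at random
        occ_idx = np.flatnonzero(state.occupied.ravel())
        extra = occ_idx[flip_rng.permutation(occ_idx.size)[: -n_promote]]
        state.occupied.ravel()[extra] = False
        for j in extra:
            state.lifetimes.append((int(state.t_on.ravel()[j]), t_next))
        state.t_on.ravel()[extra] = -1

    state.t_index = t_next
    return state


def apply_removal(
    profile: OccupancyProfile,
    phi_footprint: np.ndarray,
    dt: float,
    config: LatticeConfig,
    t: float,
) -> OccupancyProfile:
    """Decay ``chi`` under the cell footprint: ``chi *= exp(-krem0 phi dt)``.

    Exact exponential integration of the removal ODE over a step during which
    ``phi`` is held constant.  No-op before ``tstart`` or when ``krem0 = 0``.
    """
    if dt < 0:
        raise ValueError("negative step duration")
    if config.krem0 == 0.0 or t < config.tstart:
        return profile
    phi_footprint = np.asarray(phi_footprint, dtype=float)
    if phi_footprint.shape != profile.chi.shape:
        raise ValueError("footprint shape does not match the lattice")
    decay = np.exp(-config.krem0 * np.clip(phi_footprint, 0.0, 1.0) * dt)
    if np.any(decay < 1.0):
        profile.chi *= decay
        profile.pristine = False
    return profile


def completed_lifetimes(
    state: AdhesionState, margin_steps: int = 0
) -> np.ndarray:
    """Durations (in steps) of occupancy episodes completed within the run.

    Episodes that begin at step 0 (initial occupancy, left-censored) are
    excluded, as are episodes that begin within ``margin_steps`` of the
    current step: the latter guard removes the right-censoring bias that
    otherwise shortens the mean (episodes starting near the end can only be
    counted if they happen to be short).  A margin of ~20 lifetimes makes the
    residual censoring probability e^-20, i.e. negligible.
    """
    eps = np.asarray(
        [(on, off) for on, off in state.lifetimes if on > 0], dtype=float
    )
    if eps.size == 0:
        return np.empty(0)
    keep = eps[:, 0] <= state.t_index - margin_steps
    return eps[keep, 1] - eps[keep, 0]


def fit_gradient(
    row_fraction: np.ndarray,
    y: np.ndarray,
    link: str = "logit",
) -> tuple[float, float]:
    """Recover the relative steepness ``g`` from time-averaged row occupancy.

    Under the exponential-race selection scheme the stationary per-site
    occupancy is ``lam*chi / (1 + lam*chi)`` for some global constant ``lam``
    (promotion is weighted sampling without replacement, so occupancy
    saturates at high ``chi``).  Hence the *log-odds* of the row-averaged
    occupancy is exactly linear in ``y`` with slope ``g``, while a plain log
    fit is biased low by the saturation factor.  ``link`` selects
    ``"logit"`` (unbiased) or ``"log"`` (the naive fit).

    Returns ``(slope, stderr)`` of the linear fit.
    """
    from scipy import stats

    row_fraction = np.asarray(row_fraction, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = (row_fraction > 0) & (row_fraction < 1)
    f, yy = row_fraction[mask], y[mask]
    if link == "logit":
        resp = np.log(f / (1.0 - f))
    elif link == "log":
        resp = np.log(f)
    else:
        raise ValueError(f"unknown link {link!r}")
    res = stats.linregress(yy, resp)
    return float(res.slope), float(res.stderr)


# ---------------------------------------------------------------------------
# schedule packing


@dataclass
class SchedulePack:
    """A replayable record of ``n(x, y, t)`` for one random superset.

    ``schedule`` is a ``(T, Ny, Nx)`` boolean array; the pack round-trips
    bit-for-bit through :func:`save_schedule` / :func:`load_schedule`
    (bit-packed booleans in an HDF5 container).
    """

    superset_id: int
    schedule: np.ndarray
    config: LatticeConfig

    def __post_init__(self) -> None:
        self.schedule = np.asarray(self.schedule, dtype=bool)
        if self.schedule.ndim != 3:
            raise ValueError("schedule must be (T, Ny, Nx)")


def pack_schedule(
    states: list[np.ndarray] | np.ndarray,
    config: LatticeConfig,
    superset_id: int,
) -> SchedulePack:
    """Bundle a sequence of occupancy matrices into a SchedulePack."""
    arr = np.stack([np.asarray(s, dtype=bool) for s in states])
    return SchedulePack(superset_id=int(superset_id), schedule=arr, config=config)


def unpack_schedule(pack: SchedulePack) -> np.ndarray:
    """Occupancy matrices ``(T, Ny, Nx)`` from a pack."""
    return pack.schedule


def simulate_schedule(
    config: LatticeConfig, n_steps: int, superset_id: int
) -> SchedulePack:
    """Run the lattice for ``n_steps`` (no removal) and pack every frame."""
    profile = build_profile(config)
    state = initialize_state(config, profile, superset_id)
    frames = [state.occupied.copy()]
    for _ in range(n_steps):
        step(state, config, profile)
        frames.append(state.occupied.copy())
    return pack_schedule(frames, config, superset_id)


def save_schedule(pack: SchedulePack, path) -> None:
    """Write a SchedulePack to an HDF5 container (bit-packed booleans)."""
    import h5py

    t, ny, nx = pack.schedule.shape
    bits = np.packbits(pack.schedule.reshape(t, -1), axis=1)
    with h5py.File(path, "w") as f:
        d = f.create_dataset(
            "occupancy_bits", data=bits, chunks=True, compression="gzip"
        )
        d.attrs["shape"] = (t, ny, nx)
        f.attrs["superset_id"] = pack.superset_id
        f.attrs["config"] = json.dumps(pack.config.to_dict())


def load_schedule(path) -> SchedulePack:
    """Read a SchedulePack written by :func:`save_schedule`."""
    import h5py

    try:
        with h5py.File(path, "r") as f:
            bits = f["occupancy_bits"][...]
            t, ny, nx = f["occupancy_bits"].attrs["shape"]
            superset_id = int(f.attrs["superset_id"])
            config = LatticeConfig(**json.loads(f.attrs["config"]))
    except (OSError, KeyError) as exc:
        raise ValueError(f"corrupted or unreadable schedule file: {path}") from exc
    sched = np.unpackbits(bits, axis=1, count=ny * nx).astype(bool)
    return SchedulePack(
        superset_id=superset_id,
        schedule=sched.reshape(t, ny, nx),
        config=config,
    )
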