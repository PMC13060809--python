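"""Time integration of the coupled stochastic/deterministic system.

The PDE window is a ``box_size x box_size`` inset (mesh pitch ``voxel``)
moving inside the larger square domain on which the adhesion lattice lives
(pitch ``lattice_pitch``).  Each 1-second PDE step runs a 4-stage loop:

1. solve the ``phi, a, px, py`` equations (diffusion, advection, decay,
   and the area feedback implicit; the double well and the autocatalytic
   saturation semi-implicitly linearized) with preconditioned Krylov
   iterations (CG / BiCGSTAB) to tolerance ``solver_tol``; if a solve has
   not converged within ``max_solver_iters`` iterations the step is re-done
   as two half-steps;
2. (with ECM removal) decay the fractional occupancy under the cell
   footprint;
3. on an even iteration (every 2 s) advance the stochastic adhesion matrix
   and re-rasterize it onto the mesh;
4. recenter the window when the centroid drifts more than
   ``recenter_threshold`` from its center, translating fields by whole
   voxels quantized to the lattice pitch.

Centroid positions are recorded in absolute domain coordinates so window
shifts never discontinue the track.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, bicgstab, cg, spilu

from . import adhesion_lattice as al
from . import morphodynamics as md
from .metrics import Track, centroid

__all__ = [
    "SimulationConfig",
    "RunState",
    "initialize_cell",
    "advance",
    "couple_adhesions",
    "recenter_window",
    "run_simulation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Mesh, window, and solver settings.

    Defaults are the full-scale configuration: an 8x8 window of 0.05-pitch
    voxels inside a 20x20 domain with 0.1-pitch adhesion lattice, 1-second
    PDE steps (half the 2-second stochastic interval) for 20,000 steps.
    """

    box_size: float = 8.0
    voxel: float = 0.05
    domain_size: float = 20.0
    lattice_pitch: float = 0.1
    pde_dt: float = 1.0
    n_steps: int = 20000
    relax_steps: int = 50
    recenter_threshold: float = 0.5
    solver_tol: float = 1e-10
    max_solver_iters: int = 10
    max_step_splits: int = 6
    max_sweeps: int = 20
    sweep_tol: float = 1e-5
    precond_refresh: int = 20
    sample_every: int = 60
    snapshot_every: int = 0
    a_floor_tol: float = 1e-8
    a_cap: float = 500.0
    radius_um: float = 20.0

    def __post_init__(self) -> None:
        if self.box_size > self.domain_size:
            raise ValueError("window must fit inside the domain")
        r = self.lattice_pitch / self.voxel
        if abs(r - round(r)) > 1e-9:
            raise ValueError("voxel must divide the lattice pitch")
        for name in ("box_size", "domain_size"):
            q = getattr(self, name) / self.lattice_pitch
            if abs(q - round(q)) > 1e-9:
                raise ValueError(f"{name} must be a multiple of lattice_pitch")

    @property
    def mesh_n(self) -> int:
        return int(round(self.box_size / self.voxel))

    @property
    def raster_ratio(self) -> int:
        return int(round(self.lattice_pitch / self.voxel))

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# linear algebra workspace


def _face_coeffs(c: np.ndarray | float, shape: tuple[int, int]):
    """East/west/north/south face diffusivities with zero-flux boundaries."""
    if np.isscalar(c):
        ce = np.full(shape, float(c))
        cw = ce.copy()
        cn = ce.copy()
        cs = ce.copy()
    else:
        cp = np.pad(c, 1, mode="edge")
        ce = 0.5 * (cp[1:-1, 1:-1] + cp[1:-1, 2:])
        cw = 0.5 * (cp[1:-1, 1:-1] + cp[1:-1, :-2])
        cn = 0.5 * (cp[1:-1, 1:-1] + cp[2:, 1:-1])
        cs = 0.5 * (cp[1:-1, 1:-1] + cp[:-2, 1:-1])
    ce[:, -1] = 0.0
    cw[:, 0] = 0.0
    cn[-1, :] = 0.0
    cs[0, :] = 0.0
    return ce, cw, cn, cs


def _assemble(shape, h, dt, diag_r, c, vel=None) -> sparse.csr_matrix:
    """Matrix of ``u/dt + r u - div(c grad u) + v . grad u`` (backward Euler).

    Diffusion uses arithmetic-mean face coefficients with zero-flux edges;
    the optional advection ``v . grad u`` is discretized with first-order
    upwinding, implicit so there is no CFL restriction (the matrix becomes
    non-symmetric and is solved with BiCGSTAB instead of CG).
    """
    ny, nx = shape
    ce, cw, cn, cs = _face_coeffs(c, shape)
    h2 = h * h
    main = 1.0 / dt + np.asarray(diag_r, dtype=float) + (ce + cw + cn + cs) / h2
    oe = -(ce / h2)
    ow = -(cw / h2)
    on = -(cn / h2)
    os_ = -(cs / h2)
    if vel is not None:
        vx, vy = vel
        vxp, vxm = np.maximum(vx, 0.0), np.minimum(vx, 0.0)
        vyp, vym = np.maximum(vy, 0.0), np.minimum(vy, 0.0)
        # no advective coupling across the window boundary
        vxm = vxm.copy(); vxm[:, -1] = 0.0
        vxp = vxp.copy(); vxp[:, 0] = 0.0
        vym = vym.copy(); vym[-1, :] = 0.0
        vyp = vyp.copy(); vyp[0, :] = 0.0
        main = main + (vxp - vxm + vyp - vym) / h
        oe = oe + vxm / h
        ow = ow - vxp / h
        on = on + vym / h
        os_ = os_ - vyp / h
    n = nx * ny
    diags = [
        main.ravel(),
        oe.ravel()[:-1],
        ow.ravel()[1:],
        on.ravel()[:-nx],
        os_.ravel()[nx:],
    ]
    return sparse.diags(diags, [0, 1, -1, nx, -nx], shape=(n, n), format="csr")


def _advection_operator(shape, h, vel) -> sparse.csr_matrix:
    """Pure first-order-upwind matrix for ``v . grad u`` (zero-gradient edges)."""
    ny, nx = shape
    vx, vy = vel
    vxp, vxm = np.maximum(vx, 0.0).copy(), np.minimum(vx, 0.0).copy()
    vyp, vym = np.maximum(vy, 0.0).copy(), np.minimum(vy, 0.0).copy()
    vxm[:, -1] = 0.0
    vxp[:, 0] = 0.0
    vym[-1, :] = 0.0
    vyp[0, :] = 0.0
    main = (vxp - vxm + vyp - vym) / h
    oe = vxm / h
    ow = -vxp / h
    on = vym / h
    os_ = -vyp / h
    n = nx * ny
    return sparse.diags(
        [main.ravel(), oe.ravel()[:-1], ow.ravel()[1:],
         on.ravel()[:-nx], os_.ravel()[nx:]],
        [0, 1, -1, nx, -nx], shape=(n, n), format="csr")


class _Workspace:
    """Per-run solver context: cached preconditioners and solve bookkeeping."""

    def __init__(self, config: SimulationConfig, params: md.ModelParams):
        self.config = config
        self.params = params
        self._precond: dict = {}
        self._age: dict = {}
        self.solves = 0
        self.half_steps = 0
        self.last_failure: str | None = None
        self.a_substeps = 1        # adaptive activator sub-cycling hint
        self.budget_breaches = 0
        self.max_a_substeps = 32

    def _refresh(self, name: str, A: sparse.csr_matrix) -> None:
        # incomplete LU: much cheaper to apply than a full factorization and
        # close enough that the Krylov loop converges in a few iterations
        lu = spilu(A.tocsc(), drop_tol=1e-5, fill_factor=20)
        self._precond[name] = LinearOperator(A.shape, matvec=lu.solve)
        self._age[name] = 0

    def solve(self, name: str, A: sparse.csr_matrix, rhs: np.ndarray,
              x0: np.ndarray, symmetric: bool = False) -> np.ndarray | None:
        """Preconditioned Krylov solve; None if not converged.

        CG for the symmetric (diffusion-reaction) operators, BiCGSTAB for
        the upwind-advective ones; the preconditioner is a cached sparse LU
        of the operator, refreshed when stale.
        """
        cfg = self.config
        if name not in self._precond or self._age[name] >= cfg.precond_refresh:
            self._refresh(name, A)
        krylov = cg if symmetric else bicgstab
        b = rhs.ravel()
        for attempt in range(2):
            x, info = krylov(
                A, b, x0=x0.ravel(), rtol=cfg.solver_tol, atol=0.0,
                maxiter=cfg.max_solver_iters, M=self._precond[name],
            )
            self.solves += 1
            if info == 0:
                self._age[name] += 1
                return x.reshape(rhs.shape)
            if attempt == 0:
                self._refresh(name, A)  # stale preconditioner: rebuild, retry
        return None

    def invalidate(self) -> None:
        self._precond.clear()


# ---------------------------------------------------------------------------
# run state


@dataclass
class RunState:
    """Everything needed to continue (or replay) a run."""

    t_index: int
    mesh: md.Mesh
    fields: md.CellFields
    adhesion: al.AdhesionState | None
    profile: al.OccupancyProfile | None
    lattice_config: al.LatticeConfig | None
    n_field: np.ndarray
    chemo: md.ChemoInput
    workspace: _Workspace
    sim_config: SimulationConfig
    params: md.ModelParams
    centroid_history: list = field(default_factory=list)
    status: str = "running"
    boundary_violations: int = 0
    schedule: np.ndarray | None = None  # replayed occupancy frames

    @property
    def window_offset(self) -> tuple[float, float]:
        return self.mesh.offset

    def centroid_domain(self) -> tuple[float, float]:
        return centroid(self.fields.phi, self.mesh)


# ---------------------------------------------------------------------------
# initialization


def initialize_cell(center: tuple[float, float], config: SimulationConfig,
                    params: md.ModelParams,
                    mesh: md.Mesh | None = None) -> tuple[md.CellFields, md.Mesh]:
    """Sharp unit disc, relaxation without protrusion, then a, p, b.

    Returns the relaxed fields (with ``phi0`` set to the relaxed profile and
    ``a = (k0 / (kar b0)) phi``) and the mesh the window occupies.
    """
    n = config.mesh_n
    if mesh is None:
        ox = center[0] - config.box_size / 2.0
        oy = center[1] - config.box_size / 2.0
        # align the window to the lattice pitch
        ox = round(ox / config.lattice_pitch) * config.lattice_pitch
        oy = round(oy / config.lattice_pitch) * config.lattice_pitch
        mesh = md.Mesh(n, n, config.voxel, (ox, oy))
    if (
        center[0] - 1 < mesh.offset[0] or center[1] - 1 < mesh.offset[1]
        or center[0] + 1 > mesh.offset[0] + config.box_size
        or center[1] + 1 > mesh.offset[1] + config.box_size
    ):
        raise ValueError("unit circle does not fit inside the window")
    X, Y = mesh.coords()
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2
    phi = (r2 <= 1.0).astype(float)
    zeros = np.zeros_like(phi)
    fields = md.CellFields(phi=phi, a=zeros.copy(), px=zeros.copy(),
                           py=zeros.copy(), phi0=phi.copy(), b=params.b0)
    ws = _Workspace(config, params)
    dt = config.pde_dt
    for _ in range(config.relax_steps):
        ok = _solve_phi(fields, params, mesh, ws, dt, relax=True)
        if not ok:  # sharp initial data: fall back to half-steps
            _solve_phi(fields, params, mesh, ws, dt / 2, relax=True)
            _solve_phi(fields, params, mesh, ws, dt / 2, relax=True)
    fields.phi0 = fields.phi.copy()
    fields.a = (params.k0 / (params.kar * params.b0)) * fields.phi
    fields.px = np.zeros_like(fields.phi)
    fields.py = np.zeros_like(fields.phi)
    fields.b = md.precursor_concentration(fields.phi, fields.a, fields.phi0,
                                          params.b0)
    return fields, mesh


def _solve_phi_system(phi, phi0, pmag, vel, params, mesh, ws, dt):
    """Backward-Euler phase-field solve with area feedback and advection
    implicit.

    The double well is linearized around the old field; the advection by the
    protrusion velocity enters the operator as implicit upwinding; the global
    area term ``delta(phi_new)`` couples to the solution as a rank-one
    perturbation ``w 1^T`` of the sparse operator and is folded in exactly
    via the Sherman-Morrison identity (two Krylov solves).  Returns the new
    field or None if the solver failed to converge.
    """
    delta0 = md.area_deficit(phi, phi0, params.mu, mesh.voxel_area)
    G = md.double_well(phi, delta0, pmag, params.sigma)
    Gp = md.double_well_dphi(phi, delta0, pmag, params.sigma)
    gamma_eps = params.Gamma_phi / params.eps
    c_imp = gamma_eps * np.maximum(Gp, 0.0)
    rhs = phi / dt + c_imp * phi - gamma_eps * G
    w = gamma_eps * params.mu * mesh.voxel_area * phi * (1.0 - phi)
    A = _assemble(phi.shape, mesh.h, dt, c_imp,
                  params.Gamma_phi * params.eps, vel=vel)
    s1 = ws.solve("phi", A, rhs + w * phi.sum(), phi, symmetric=vel is None)
    if s1 is None:
        return None
    s2 = ws.solve("phi", A, w, np.zeros_like(phi), symmetric=vel is None)
    if s2 is None:
        return None
    return s1 - s2 * (s1.sum() / (1.0 + s2.sum()))


def _solve_phi(fields, params, mesh, ws, dt, relax=False) -> bool:
    """One phase-field step (in place).  True on convergence."""
    phi = fields.phi
    pmag = 0.0 if relax else fields.p_mag
    vel = None if relax else (params.alpha * fields.px,
                              params.alpha * fields.py)
    out = _solve_phi_system(phi, fields.phi0, pmag, vel, params, mesh, ws, dt)
    if out is None:
        return False
    fields.phi = out
    return True


# ---------------------------------------------------------------------------
# the 4-step loop


def _attempt_step(rs: RunState, dt: float) -> bool:
    """Try one coupled PDE step of size dt; commit only if all solves converge."""
    params, config, mesh, ws = rs.params, rs.sim_config, rs.mesh, rs.workspace
    f = rs.fields
    phi, a, px, py = f.phi, f.a, f.px, f.py
    h = mesh.h

    gx, gy = md.grad(phi, h)
    gmag = np.hypot(gx, gy)
    # the equilibrium interface profile bounds |grad phi| at 1/(4 sqrt2 eps);
    # steeper discrete excursions are artifacts, so the gradient entering the
    # generation terms is rescaled onto that bound (25% margin)
    gcap = 1.25 / (4.0 * np.sqrt(2.0) * params.eps)
    with np.errstate(invalid="ignore", divide="ignore"):
        gscale = np.where(gmag > gcap, gcap / np.where(gmag > 0, gmag, 1.0),
                          1.0)
    gx_s, gy_s = gx * gscale, gy * gscale
    gmag_s = np.minimum(gmag, gcap)

    # phase field: double well linearized; diffusion, advection, and area
    # feedback implicit
    vel_phi = (params.alpha * px, params.alpha * py)
    phi_new = _solve_phi_system(phi, f.phi0, f.p_mag, vel_phi, params, mesh,
                                ws, dt)
    if phi_new is None:
        ws.last_failure = "phi"
        return False

    # protrusion force: decay implicit, generation (outward) explicit
    dec_p = md.decay_profile(phi, params.kpr, params.kpr2)
    gen_p = params.kpf * a * rs.n_field / (1.0 + params.beta * a)
    A_p = _assemble(phi.shape, h, dt, dec_p, params.Dp)
    px_new = ws.solve("p", A_p, px / dt - gen_p * gx_s, px, symmetric=True)
    if px_new is None:
        ws.last_failure = "p"
        return False
    py_new = ws.solve("p", A_p, py / dt - gen_p * gy_s, py, symmetric=True)
    if py_new is None:
        ws.last_failure = "p"
        return False

    # activator: phi-gated diffusion and decay implicit; the autocatalytic
    # generation and the precursor b are relaxed by Picard sweeps within the
    # step, so the mass-conservation brake on the autocatalysis acts inside
    # the step rather than one step late.  Non-convergence (or b driven
    # negative by a stiff transient) fails the attempt and halves the step.
    dec_a = md.decay_profile(phi, params.kar, params.kar2)
    drive = params.kaf * rs.n_field
    if rs.chemo.orientation != "none":
        drive = drive + rs.chemo.field
    # advection -alpha p.grad(phi a): upwind the advected quantity phi*a
    # directly (operator T for velocity alpha*p composed with diag(phi)),
    # which avoids any spurious discrete source from splitting the product
    T_adv = _advection_operator(phi.shape, h,
                                (params.alpha * px, params.alpha * py))
    A_adv = (T_adv @ sparse.diags(phi.ravel())).tocsr()
    # the in-iteration precursor estimate uses phi clipped to [0, 1]: the
    # phase field's tiny negative overshoots must not flip the sign of the
    # activator mass they weight
    phi_pos = np.clip(phi_new, 0.0, 1.0)
    vol = float(phi_pos.sum())
    mass0 = float((f.phi0 * params.b0).sum())

    # The autocatalytic generation is linear in a at lagged saturation, so
    # its coefficient joins the implicit operator each sweep; the saturation
    # factor and the precursor b are relaxed across sweeps.  Ignition of a
    # fresh signaling hotspot is locally supercritical (the linearized gain
    # exceeds the decay until saturation or precursor depletion brakes it),
    # which defeats the sweeps at the full step size, so the activator
    # subsystem is sub-cycled adaptively: on sweep failure the activator
    # substep count doubles (phi, p stay frozen at the step level) before
    # the whole coupled step is halved.
    def _a_sweep_chain(n_sub: int):
        dt_s = dt / n_sub
        v, b_ref = a, f.b
        fl = 0.0
        for _ in range(n_sub):
            v_start, v_prev = v, v
            done = False
            for _ in range(config.max_sweeps):
                c_gen = (params.eps * drive * gmag_s * b_ref
                         / (1.0 + params.beta_a * v_prev))
                A_k = (_assemble(phi.shape, h, dt_s, dec_a - c_gen,
                                 params.Da * phi) + A_adv).tocsr()
                v_try = ws.solve("a", A_k, v_start / dt_s
                                 + params.k0 * phi * b_ref, v_prev)
                if v_try is None:
                    return None, 0.0
                fl = min(fl, float(v_try.min()))
                if not np.all(np.isfinite(v_try)):
                    return None, 0.0
                # floor at 0 and cap at a_cap: the advective term can
                # amplify a without bound at a quasi-stalled protruding
                # front (gain alpha|p.grad phi| exceeding the local decay),
                # a linear mode the precursor budget cannot brake; the cap
                # sits far above the saturated hotspot scale (~40)
                np.clip(v_try, 0.0, config.a_cap, out=v_try)
                vmax = float(v_try.max())
                # precursor clamped at 0 while iterating: intermediate
                # iterates may overshoot the mass budget transiently
                b_ref = max(0.0,
                            (mass0 - float((phi_pos * v_try).sum())) / vol)
                change = float(np.abs(v_try - v_prev).max())
                v_prev = v_try
                if change <= config.sweep_tol * max(1.0, vmax):
                    done = True
                    break
            if not done:
                return None, 0.0
            v = v_prev
        return v, fl

    a_new = None
    n_sub = ws.a_substeps
    while n_sub <= ws.max_a_substeps:
        a_new, floored = _a_sweep_chain(n_sub)
        if a_new is not None:
            break
        n_sub *= 2
    if a_new is None:
        ws.last_failure = "a-sweeps"
        return False
    # remember the working substep count; probe a coarser one next step
    ws.a_substeps = max(1, n_sub // 2 if n_sub == ws.a_substeps else n_sub)

    if floored < -config.a_floor_tol:
        warnings.warn(
            f"activator floored at 0 (min {floored:.3e})", stacklevel=2
        )

    # committed b uses phi clipped to [0, 1]: discrete over/undershoots of
    # the phase field carry no activator mass
    raw_b = (mass0 - float((phi_pos * a_new).sum())) / max(vol, 1e-12)
    if raw_b < -1e-9:
        # activator mass transiently exceeds the precursor budget (floor/cap
        # effects during violent protrusion episodes); b clamps at 0, which
        # shuts off all generation until the excess decays
        ws.budget_breaches += 1
        if ws.budget_breaches == 1:
            warnings.warn("precursor budget breached; b clamped at 0",
                          stacklevel=2)
    f.phi, f.a, f.px, f.py = phi_new, a_new, px_new, py_new
    f.b = max(0.0, raw_b)
    return True


def _advance_dt(rs: RunState, dt: float, depth: int = 0) -> None:
    if _attempt_step(rs, dt):
        return
    if depth >= rs.sim_config.max_step_splits:
        raise RuntimeError(
            f"solver failed to converge at t_index={rs.t_index} even at "
            f"sub-step dt={dt}"
        )
    rs.workspace.half_steps += 1
    _advance_dt(rs, dt / 2, depth + 1)
    _advance_dt(rs, dt / 2, depth + 1)


def advance(rs: RunState) -> RunState:
    """Advance the coupled fields by one PDE step (``pde_dt``)."""
    _advance_dt(rs, rs.sim_config.pde_dt)
    rs.t_index += 1
    phi = rs.fields.phi
    edge = max(phi[0, :].max(), phi[-1, :].max(),
               phi[:, 0].max(), phi[:, -1].max())
    if edge > 0.01:
        rs.boundary_violations += 1
        if rs.boundary_violations == 1:
            log.warning("cell touched the window boundary (quality failure)")
    return rs


def _lattice_footprint(rs: RunState) -> np.ndarray:
    """Down-sample phi onto the full adhesion lattice (zero off-window)."""
    cfg, lat = rs.sim_config, rs.lattice_config
    foot = md.downsample_to_lattice(rs.fields.phi, cfg.raster_ratio)
    full = np.zeros((lat.Ny, lat.Nx))
    ox, oy = rs.mesh.offset
    ix0 = int(round(ox / lat.ell))
    iy0 = int(round(oy / lat.ell))
    ny_w, nx_w = foot.shape
    x_lo, x_hi = max(ix0, 0), min(ix0 + nx_w, lat.Nx)
    y_lo, y_hi = max(iy0, 0), min(iy0 + ny_w, lat.Ny)
    full[y_lo:y_hi, x_lo:x_hi] = foot[y_lo - iy0:y_hi - iy0,
                                      x_lo - ix0:x_hi - ix0]
    return full


def couple_adhesions(rs: RunState) -> RunState:
    """Stochastic adhesion update (even iterations): removal, turnover, raster."""
    cfg = rs.sim_config
    if rs.schedule is not None:
        k = rs.t_index // max(1, int(round(rs.lattice_config.dt / cfg.pde_dt)))
        frame = rs.schedule[min(k, len(rs.schedule) - 1)]
        rs.n_field = md.rasterize_adhesions(frame, cfg.lattice_pitch, rs.mesh)
        return rs
    lat = rs.lattice_config
    if lat.krem0 > 0.0:
        t = rs.t_index * cfg.pde_dt
        al.apply_removal(rs.profile, _lattice_footprint(rs), lat.dt, lat, t)
    al.step(rs.adhesion, lat, rs.profile)
    rs.n_field = md.rasterize_adhesions(
        rs.adhesion.occupied, cfg.lattice_pitch, rs.mesh)
    return rs


def _translate(u: np.ndarray, sx: int, sy: int, fill: float = 0.0) -> np.ndarray:
    """Field content after the window moved by (sx, sy) voxels."""
    out = np.full_like(u, fill)
    ny, nx = u.shape
    j_lo, j_hi = max(-sy, 0), min(ny - sy, ny)
    i_lo, i_hi = max(-sx, 0), min(nx - sx, nx)
    if j_lo < j_hi and i_lo < i_hi:
        out[j_lo:j_hi, i_lo:i_hi] = u[j_lo + sy:j_hi + sy, i_lo + sx:i_hi + sx]
    return out


def recenter_window(rs: RunState) -> RunState:
    """Shift the window (lattice-pitch-aligned) when the centroid drifts.

    Translating by whole voxels preserves the field integrals exactly; the
    reference field phi0 rides with the window (only its integral matters).
    """
    cfg = rs.sim_config
    cx, cy = rs.centroid_domain()
    ox, oy = rs.mesh.offset
    half = cfg.box_size / 2.0
    dev_x = cx - (ox + half)
    dev_y = cy - (oy + half)
    if max(abs(dev_x), abs(dev_y)) <= cfg.recenter_threshold:
        return rs
    pitch = cfg.lattice_pitch
    shift_x = round(dev_x / pitch) * pitch
    shift_y = round(dev_y / pitch) * pitch
    new_ox, new_oy = ox + shift_x, oy + shift_y
    if (new_ox < -1e-9 or new_oy < -1e-9
            or new_ox + cfg.box_size > cfg.domain_size + 1e-9
            or new_oy + cfg.box_size > cfg.domain_size + 1e-9):
        rs.status = "domain_exit"
        return rs
    vx = int(round(shift_x / cfg.voxel))
    vy = int(round(shift_y / cfg.voxel))
    f = rs.fields
    f.phi = _translate(f.phi, vx, vy)
    f.a = _translate(f.a, vx, vy)
    f.px = _translate(f.px, vx, vy)
    f.py = _translate(f.py, vx, vy)
    # phi0 is untouched: it translates with the window by construction
    rs.mesh = rs.mesh.shifted(shift_x, shift_y)
    rs.chemo = md.chemo_field(rs.params, rs.mesh, rs.chemo.orientation)
    if rs.schedule is not None:
        k = rs.t_index // max(1, int(round(rs.lattice_config.dt / cfg.pde_dt)))
        frame = rs.schedule[min(k, len(rs.schedule) - 1)]
        rs.n_field = md.rasterize_adhesions(frame, cfg.lattice_pitch, rs.mesh)
    else:
        rs.n_field = md.rasterize_adhesions(
            rs.adhesion.occupied, cfg.lattice_pitch, rs.mesh)
    rs.workspace.invalidate()
    return rs


# ---------------------------------------------------------------------------
# orchestration


def run_simulation(
    sim_config: SimulationConfig,
    params: md.ModelParams,
    lattice_config: al.LatticeConfig,
    adhesion_source: int | al.SchedulePack,
    chemo_orientation: str = "none",
    start: tuple[float, float] | None = None,
) -> tuple[Track, list, dict]:
    """Run the full 4-step loop and return (track, snapshots, manifest).

    ``adhesion_source`` is either a superset id (int; the lattice is
    simulated live, which permits ECM removal) or a pre-generated
    :class:`~haptosim.adhesion_lattice.SchedulePack` to replay.
    """
    if start is None:
        start = (lattice_config.x0, lattice_config.y0)
    params = md.ModelParams(**{**params.to_dict(),
                               "x0": start[0], "y0": start[1]})
    lattice_config = al.LatticeConfig(**{**lattice_config.to_dict(),
                                         "x0": start[0], "y0": start[1]})
    fields, mesh = initialize_cell(start, sim_config, params)
    ws = _Workspace(sim_config, params)
    chemo = md.chemo_field(params, mesh, chemo_orientation)

    schedule = None
    if isinstance(adhesion_source, al.SchedulePack):
        if lattice_config.krem0 > 0:
            raise ValueError("ECM removal requires a live lattice, not a replay")
        schedule = al.unpack_schedule(adhesion_source)
        superset_id = adhesion_source.superset_id
        profile = None
        adhesion = None
        n_field = md.rasterize_adhesions(schedule[0],
                                         sim_config.lattice_pitch, mesh)
    else:
        superset_id = int(adhesion_source)
        profile = al.build_profile(lattice_config)
        adhesion = al.initialize_state(lattice_config, profile, superset_id)
        n_field = md.rasterize_adhesions(adhesion.occupied,
                                         sim_config.lattice_pitch, mesh)

    rs = RunState(
        t_index=0, mesh=mesh, fields=fields, adhesion=adhesion,
        profile=profile, lattice_config=lattice_config, n_field=n_field,
        chemo=chemo, workspace=ws, sim_config=sim_config, params=params,
        schedule=schedule,
    )
    samples = [(0.0, *rs.centroid_domain())]
    snapshots = []
    adh_every = max(1, int(round(lattice_config.dt / sim_config.pde_dt)))

    for _ in range(sim_config.n_steps):
        advance(rs)
        if rs.t_index % adh_every == 0:
            couple_adhesions(rs)
        recenter_window(rs)
        if rs.status == "domain_exit":
            break
        t = rs.t_index * sim_config.pde_dt
        if rs.t_index % sim_config.sample_every == 0:
            samples.append((t, *rs.centroid_domain()))
        if sim_config.snapshot_every and rs.t_index % sim_config.snapshot_every == 0:
            snapshots.append({
                "t": t, "offset": rs.mesh.offset,
                "phi": rs.fields.phi.copy(), "a": rs.fields.a.copy(),
            })
    if rs.status == "running":
        rs.status = "completed"
    t_final = rs.t_index * sim_config.pde_dt
    if samples[-1][0] < t_final:
        samples.append((t_final, *rs.centroid_domain()))

    track = Track(samples=np.asarray(samples), radius_um=sim_config.radius_um)
    manifest = {
        "status": rs.status,
        "t_final": rs.t_index * sim_config.pde_dt,
        "superset_id": superset_id,
        "start": list(start),
        "chemo_orientation": chemo_orientation,
        "sim_config": sim_config.to_dict(),
        "lattice_config": lattice_config.to_dict(),
        "params": params.to_dict(),
        "boundary_violations": rs.boundary_violations,
        "half_steps": ws.half_steps,
        "budget_breaches": ws.budget_breaches,
        "version": 1,
    }
    return track, snapshots, manifest
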