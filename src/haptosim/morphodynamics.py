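"""Deterministic phase-field model of adhesion-based sensing and protrusion.

Fields live on a uniform cell-centered mesh (pitch ``voxel``) covering the
moving PDE window.  The cell is the region ``phi ~ 1`` of an auxiliary phase
field ``phi in [0, 1]`` whose steep transition zone replaces an explicit
boundary:

    dphi/dt = Gamma_phi (eps lap(phi) - G(phi)/eps) - alpha p . grad(phi)

with double-well potential ``G(phi) = phi (1-phi) (delta - sigma |p| - phi)``
and global area-conservation feedback ``delta = 1/2 + mu \\iint (phi0-phi) dA``.

An activator species ``a`` (proxy for Rac/PI3K-axis signaling) is generated
basally and autocatalytically at the periphery where nascent adhesions ``n``
(and, optionally, a chemotactic receptor input) reside, from a well-mixed
precursor pool ``b`` fixed by mass conservation; ``a`` and ``n`` jointly
generate the outward protrusion force field ``p`` that advects the interface.

All right-hand sides here are the plain mathematical forms, used for
equilibrium and symmetry checks; the time integrator in
:mod:`haptosim.solver` treats their stiff parts semi-implicitly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "CellFields",
    "ChemoInput",
    "Mesh",
    "area_deficit",
    "double_well",
    "precursor_concentration",
    "phi_rhs",
    "p_rhs",
    "a_rhs",
    "chemo_field",
    "rasterize_adhesions",
    "grad",
    "laplacian",
    "div_flux",
]


@dataclass(frozen=True)
class ModelParams:
    """Phase-field model parameters (dimensionless; lengths in cell radii).

    Defaults follow the published parameterization: interface mobility
    ``Gamma_phi = 0.5``, interface width ``eps = 0.05``, protrusion-potential
    coupling ``sigma = 1``, advection scaling ``alpha = 1``, protrusion
    dissipation ``Dp = 3``, saturation constants ``beta = beta_a = 0.1``,
    decay constants ``kpr = kar = 3`` and ``kpr2 = kar2 = 10``, activator
    diffusivity ``Da = 1``, autocatalytic rate ``kaf = 100``, protrusion
    generation ``kpf = 30``, area weight ``mu = 1``, precursor scale
    ``b0 = 1``, chemotactic magnitude ``ka_C = 30``.  The basal generation
    rate ``k0`` has no published value; the default 0.1 keeps the basal
    activator level small against autocatalytic peaks (see docs/methods.md).
    """

    Gamma_phi: float = 0.5
    eps: float = 0.05
    sigma: float = 1.0
    alpha: float = 1.0
    mu: float = 1.0
    Dp: float = 3.0
    kpf: float = 30.0
    beta: float = 0.1
    kpr: float = 3.0
    kpr2: float = 10.0
    Da: float = 1.0
    k0: float = 0.1
    kaf: float = 100.0
    beta_a: float = 0.1
    kar: float = 3.0
    kar2: float = 10.0
    b0: float = 1.0
    ka_C: float = 30.0
    g_C: float = 0.0
    x0: float = 10.0
    y0: float = 8.0

    def __post_init__(self) -> None:
        for name in (
            "Gamma_phi", "sigma", "alpha", "mu", "Dp", "kpf", "beta", "kpr",
            "kpr2", "Da", "k0", "kaf", "beta_a", "kar", "kar2", "b0", "ka_C",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Mesh:
    """Uniform cell-centered mesh of the (moving) PDE window.

    ``offset`` is the window's lower-left corner in domain coordinates; voxel
    centers sit at ``offset + (i + 1/2) h``.
    """

    nx: int
    ny: int
    h: float
    offset: tuple[float, float] = (0.0, 0.0)

    @property
    def voxel_area(self) -> float:
        return self.h * self.h

    def x(self) -> np.ndarray:
        return self.offset[0] + (np.arange(self.nx) + 0.5) * self.h

    def y(self) -> np.ndarray:
        return self.offset[1] + (np.arange(self.ny) + 0.5) * self.h

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Broadcastable (X, Y) voxel-center coordinate arrays."""
        return self.x()[None, :], self.y()[:, None]

    def shifted(self, dx: float, dy: float) -> "Mesh":
        return Mesh(self.nx, self.ny, self.h,
                    (self.offset[0] + dx, self.offset[1] + dy))


@dataclass
class CellFields:
    """State of the deterministic submodel on the mesh.

    ``phi`` phase field, ``a`` activator, ``(px, py)`` protrusion force,
    ``phi0`` reference phase field for area conservation (translated with the
    window, so only its integral matters), ``b`` spatially uniform precursor.
    """

    phi: np.ndarray
    a: np.ndarray
    px: np.ndarray
    py: np.ndarray
    phi0: np.ndarray
    b: float = 1.0

    def copy(self) -> "CellFields":
        return CellFields(self.phi.copy(), self.a.copy(), self.px.copy(),
                          self.py.copy(), self.phi0.copy(), self.b)

    @property
    def p_mag(self) -> np.ndarray:
        return np.hypot(self.px, self.py)


@dataclass
class ChemoInput:
    """Deterministic chemotactic drive added to the autocatalytic term.

    ``field`` holds ``ka_C exp(g_C (s - s0))`` on the mesh with ``s`` the
    oriented coordinate; ``orientation`` is one of ``none`` (zero field),
    ``orthogonal-x`` (gradient along +x) or ``antiparallel-y`` (gradient
    along -y, opposing haptotaxis).
    """

    field: np.ndarray
    orientation: str = "none"


ORIENTATIONS = ("none", "orthogonal-x", "antiparallel-y")


def chemo_field(params: ModelParams, mesh: Mesh, orientation: str) -> ChemoInput:
    """Build the chemotactic input for the given orientation."""
    X, Y = mesh.coords()
    shape = (mesh.ny, mesh.nx)
    if orientation == "none":
        f = np.zeros(shape)
    elif orientation == "orthogonal-x":
        f = params.ka_C * np.exp(params.g_C * (X - params.x0))
        f = np.broadcast_to(f, shape).copy()
    elif orientation == "antiparallel-y":
        f = params.ka_C * np.exp(-params.g_C * (Y - params.y0))
        f = np.broadcast_to(f, shape).copy()
    else:
        raise ValueError(f"unknown chemo orientation {orientation!r}")
    return ChemoInput(field=f, orientation=orientation)


# ---------------------------------------------------------------------------
# discrete operators (zero-flux boundaries throughout)


def grad(u: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient with reflecting (zero-flux) edges."""
    up = np.pad(u, 1, mode="edge")
    gx = (up[1:-1, 2:] - up[1:-1, :-2]) / (2 * h)
    gy = (up[2:, 1:-1] - up[:-2, 1:-1]) / (2 * h)
    return gx, gy


def laplacian(u: np.ndarray, h: float) -> np.ndarray:
    """5-point Laplacian with zero-flux boundaries."""
    up = np.pad(u, 1, mode="edge")
    return (
        up[1:-1, 2:] + up[1:-1, :-2] + up[2:, 1:-1] + up[:-2, 1:-1]
        - 4.0 * u
    ) / (h * h)


def div_flux(c: np.ndarray, u: np.ndarray, h: float) -> np.ndarray:
    """Finite-volume ``div(c grad u)`` with arithmetic-mean face coefficients."""
    cp = np.pad(c, 1, mode="edge")
    up = np.pad(u, 1, mode="edge")
    ce = 0.5 * (cp[1:-1, 1:-1] + cp[1:-1, 2:])
    cw = 0.5 * (cp[1:-1, 1:-1] + cp[1:-1, :-2])
    cn = 0.5 * (cp[1:-1, 1:-1] + cp[2:, 1:-1])
    cs = 0.5 * (cp[1:-1, 1:-1] + cp[:-2, 1:-1])
    return (
        ce * (up[1:-1, 2:] - u)
        + cw * (up[1:-1, :-2] - u)
        + cn * (up[2:, 1:-1] - u)
        + cs * (up[:-2, 1:-1] - u)
    ) / (h * h)


# ---------------------------------------------------------------------------
# model terms


def area_deficit(phi: np.ndarray, phi0: np.ndarray, mu: float,
                 voxel_area: float) -> float:
    """Area-conservation feedback ``delta = 1/2 + mu \\iint (phi - phi0) dA``.

    The well ``G = phi (1-phi) (delta - sigma |p| - phi)`` lets the cell phase
    invade wherever ``delta - sigma |p| < 1/2`` (bistable front speed
    ``c ~ 1 - 2 delta_eff``), so an oversized cell must *raise* delta above
    1/2 to shrink back: the area integral enters with the sign that makes the
    feedback restoring.
    """
    if phi.shape != phi0.shape:
        raise ValueError("phi and phi0 live on different meshes")
    return 0.5 + mu * float((phi - phi0).sum()) * voxel_area


def double_well(phi: np.ndarray, delta: float, p_mag: np.ndarray | float,
                sigma: float) -> np.ndarray:
    """Tilted double well ``G = phi (1-phi) (delta - sigma |p| - phi)``."""
    return phi * (1.0 - phi) * (delta - sigma * p_mag - phi)


def double_well_dphi(phi: np.ndarray, delta: float,
                     p_mag: np.ndarray | float, sigma: float) -> np.ndarray:
    """``dG/dphi`` at fixed well tilt (used for semi-implicit linearization)."""
    q = delta - sigma * p_mag
    return (1.0 - 2.0 * phi) * (q - phi) - phi * (1.0 - phi)


def precursor_concentration(phi: np.ndarray, a: np.ndarray,
                            phi0: np.ndarray, b0: float) -> float:
    """Uniform precursor from mass conservation.

    ``b = \\iint (phi0 b0 - phi a) dA / \\iint phi dA``; the voxel area cancels
    in the quotient.  Negative ``b`` signals parameter blow-up and raises.
    """
    denom = float(phi.sum())
    if denom <= 1e-12:
        raise ValueError("degenerate cell: integral of phi vanished")
    b = float((phi0 * b0 - phi * a).sum()) / denom
    if b < 0:
        raise ValueError("negative precursor concentration (mass blow-up)")
    return b


def decay_profile(phi: np.ndarray, k1: float, k2: float) -> np.ndarray:
    """Decay coefficient ``k1 + k2 / (1 + (100 phi)^2)``.

    Roughly ``k1`` inside the cell and ``k1 + k2`` outside, which rapidly
    eliminates the species beyond the interface.
    """
    return k1 + k2 / (1.0 + (100.0 * phi) ** 2)


def phi_rhs(fields: CellFields, params: ModelParams, mesh: Mesh,
            delta: float | None = None) -> np.ndarray:
    """Right-hand side of the phase-field equation."""
    if delta is None:
        delta = area_deficit(fields.phi, fields.phi0, params.mu,
                             mesh.voxel_area)
    G = double_well(fields.phi, delta, fields.p_mag, params.sigma)
    gx, gy = grad(fields.phi, mesh.h)
    return (
        params.Gamma_phi
        * (params.eps * laplacian(fields.phi, mesh.h) - G / params.eps)
        - params.alpha * (fields.px * gx + fields.py * gy)
    )


def p_rhs(fields: CellFields, n_field: np.ndarray,
          params: ModelParams, mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Right-hand side of the protrusion force balance (both components).

    Generation is directed opposite the phase-field gradient (outward) and
    requires both activator and mechanical clutching by adhesions.
    """
    gx, gy = grad(fields.phi, mesh.h)
    gen = params.kpf * fields.a * n_field / (1.0 + params.beta * fields.a)
    dec = decay_profile(fields.phi, params.kpr, params.kpr2)
    rx = params.Dp * laplacian(fields.px, mesh.h) - gen * gx - dec * fields.px
    ry = params.Dp * laplacian(fields.py, mesh.h) - gen * gy - dec * fields.py
    return rx, ry


def a_rhs(fields: CellFields, n_field: np.ndarray, chemo: ChemoInput | None,
          params: ModelParams, mesh: Mesh) -> np.ndarray:
    """Right-hand side of the activator balance.

    Generation couples a basal rate ``k0`` gated by the cell phase (the
    stated initialization ``a = k0 phi / (kar b0)`` is exactly the interior
    fixed point of ``k0 phi b - kar a``) with peripheral
    autocatalysis driven by adhesions and the optional chemotactic input,
    saturable in ``a``, all drawing on the precursor ``b``; diffusion is
    confined to the cell phase.  The peripheral localizer is the
    dimensionless interface weight ``eps |grad phi|`` (of order one across
    the transition region): with the bare gradient, whose magnitude reaches
    ``1/(4 sqrt2 eps) ~ 3.5``, the autocatalytic gain ``kaf |grad phi|``
    would exceed the decay ``kar`` at any precursor level above ~1%, so
    every adhesion touching the interface would ignite and the precursor
    pool would collapse (see docs/methods.md).
    """
    gpx, gpy = grad(fields.phi, mesh.h)
    gmag = np.hypot(gpx, gpy)
    drive = params.kaf * n_field
    if chemo is not None and chemo.orientation != "none":
        drive = drive + chemo.field
    gen = (
        params.k0 * fields.phi
        + drive * fields.a * params.eps * gmag
        / (1.0 + params.beta_a * fields.a)
    ) * fields.b
    dec = decay_profile(fields.phi, params.kar, params.kar2)
    pa = fields.phi * fields.a
    gax, gay = grad(pa, mesh.h)
    return (
        params.Da * div_flux(fields.phi, fields.a, mesh.h)
        + gen
        - dec * fields.a
        - params.alpha * (fields.px * gax + fields.py * gay)
    )


def rasterize_adhesions(occupied: np.ndarray, lattice_ell: float,
                        mesh: Mesh) -> np.ndarray:
    """Indicator field of occupied adhesion sites on the PDE mesh.

    Each occupied ``ell x ell`` lattice cell covers an integer block of mesh
    voxels (``(ell/h)^2`` of them); sites outside the window are ignored.
    The window offset must align to the lattice pitch so blocks map cleanly.
    """
    ratio = lattice_ell / mesh.h
    r = int(round(ratio))
    if abs(ratio - r) > 1e-9:
        raise ValueError("mesh pitch must divide the lattice pitch")
    ox, oy = mesh.offset
    ix0 = ox / lattice_ell
    iy0 = oy / lattice_ell
    if abs(ix0 - round(ix0)) > 1e-9 or abs(iy0 - round(iy0)) > 1e-9:
        raise ValueError("window is not aligned to the lattice pitch")
    ix0, iy0 = int(round(ix0)), int(round(iy0))
    ny_l, nx_l = occupied.shape
    nxw = mesh.nx // r
    nyw = mesh.ny // r
    sub = np.zeros((nyw, nxw), dtype=bool)
    x_lo, x_hi = max(ix0, 0), min(ix0 + nxw, nx_l)
    y_lo, y_hi = max(iy0, 0), min(iy0 + nyw, ny_l)
    if x_lo < x_hi and y_lo < y_hi:
        sub[y_lo - iy0 : y_hi - iy0, x_lo - ix0 : x_hi - ix0] = occupied[
            y_lo:y_hi, x_lo:x_hi
        ]
    return np.repeat(np.repeat(sub, r, axis=0), r, axis=1).astype(float)


def downsample_to_lattice(u: np.ndarray, ratio: int) -> np.ndarray:
    """Block-average a mesh field onto the lattice pitch (ratio x ratio)."""
    ny, nx = u.shape
    return u.reshape(ny // ratio, ratio, nx // ratio, ratio).mean(axis=(1, 3))
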