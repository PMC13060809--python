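"""Shared fixtures: desk-scale simulation states reused across tests.

The desk-scale configuration (6x6 window, 0.1-pitch mesh with matching
interface width, 16x16 domain) keeps multi-hundred-step runs to a few
seconds while exercising every part of the coupled loop.
"""

import numpy as np
import pytest

from haptosim import adhesion_lattice as al
from haptosim import morphodynamics as md
from haptosim import solver as sv
from haptosim.harness import desk_scale_configs


def make_run_state(sim, params, lattice, adhesion_source,
                   chemo_orientation="none", start=None):
    """Assemble a RunState the way run_simulation does, but keep it."""
    if start is None:
        start = (lattice.x0, lattice.y0)
    fields, mesh = sv.initialize_cell(start, sim, params)
    ws = sv._Workspace(sim, params)
    chemo = md.chemo_field(params, mesh, chemo_orientation)
    schedule = None
    profile = None
    adhesion = None
    if isinstance(adhesion_source, al.SchedulePack):
        schedule = al.unpack_schedule(adhesion_source)
        n_field = md.rasterize_adhesions(schedule[0], sim.lattice_pitch, mesh)
    else:
        profile = al.build_profile(lattice)
        adhesion = al.initialize_state(lattice, profile, adhesion_source)
        n_field = md.rasterize_adhesions(adhesion.occupied,
                                         sim.lattice_pitch, mesh)
    return sv.RunState(
        t_index=0, mesh=mesh, fields=fields, adhesion=adhesion,
        profile=profile, lattice_config=lattice, n_field=n_field,
        chemo=chemo, workspace=ws, sim_config=sim, params=params,
        schedule=schedule,
    )


def step_n(rs, n):
    """Advance a RunState through n iterations of the 4-stage loop."""
    adh_every = max(1, int(round(rs.lattice_config.dt / rs.sim_config.pde_dt)))
    for _ in range(n):
        sv.advance(rs)
        if rs.t_index % adh_every == 0:
            sv.couple_adhesions(rs)
        sv.recenter_window(rs)
        if rs.status == "domain_exit":
            break
    return rs


@pytest.fixture(scope="session")
def desk_sim():
    sim, params = desk_scale_configs(n_steps=400)
    return sim, params


@pytest.fixture(scope="session")
def desk_lattice(desk_sim):
    sim, _ = desk_sim
    n = int(round(sim.domain_size / sim.lattice_pitch))
    return al.LatticeConfig(Nx=n, Ny=n, ell=sim.lattice_pitch, n0=0.075,
                            g=0.10, x0=8.0, y0=6.0)


@pytest.fixture(scope="session")
def active_state(desk_sim, desk_lattice):
    """400 iterations of a gradient-driven cell (live adhesions)."""
    sim, params = desk_sim
    rs = make_run_state(sim, params, desk_lattice, adhesion_source=3)
    return step_n(rs, 400)


@pytest.fixture(scope="session")
def quiet_state(desk_sim, desk_lattice):
    """400 iterations with an empty adhesion schedule (zero input)."""
    sim, params = desk_sim
    n = desk_lattice
    empty = al.SchedulePack(
        superset_id=0,
        schedule=np.zeros((201, n.Ny, n.Nx), dtype=bool),
        config=n,
    )
    rs = make_run_state(sim, params, n, adhesion_source=empty)
    rs.initial_centroid = rs.centroid_domain()
    return step_n(rs, 400)
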