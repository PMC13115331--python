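"""Shared fixtures: meshes, protocol, solvers, independent oracles."""

import numpy as np
import pytest

from eitgest.forward import FEMSolver
from eitgest.mesh import build_disk_mesh
from eitgest.protocol import adjacent_protocol


@pytest.fixture(scope="session")
def protocol():
    return adjacent_protocol()


@pytest.fixture(scope="session")
def mesh_small():
    """Level-1 working mesh (~500 elements)."""
    return build_disk_mesh(1)


@pytest.fixture(scope="session")
def mesh_refined():
    """Level-3 refined mesh (~1500 elements) for accuracy checks."""
    return build_disk_mesh(3)


@pytest.fixture(scope="session")
def solver_small(mesh_small, protocol):
    return FEMSolver(mesh_small, protocol)


@pytest.fixture(scope="session")
def homogeneous_voltages_small(mesh_small, solver_small):
    return solver_small.solve(np.ones(mesh_small.n_elements))


# ---------------------------------------------------------------------------
# Independent analytic oracle: Neumann Green's function of the unit disk.
# For a boundary source point a, N(x, a) = -(1/pi) ln|x - a| + const, so a
# source/sink pair (a, b) driving current I through a homogeneous disk of
# conductivity sigma gives u(x) = (I / (pi*sigma)) * ln(|x - b| / |x - a|).
# The electrode model injects a uniform current density over each arc, so
# the oracle integrates the point-source kernel over the drive arcs and
# averages the potential over the measurement arcs with Gauss-Legendre
# quadrature.  Implemented here independently of the FEM path.


def disk_point_voltages(protocol, sigma=1.0, current=1.0):
    """Closed-form voltages for point electrodes at the arc centres."""
    n = protocol.n_electrodes
    centers = np.array(
        [[np.cos(2 * np.pi * k / n), np.sin(2 * np.pi * k / n)] for k in range(n)]
    )

    def u(x, a, b):
        return (current / (np.pi * sigma)) * np.log(
            np.linalg.norm(x - centers[b]) / np.linalg.norm(x - centers[a])
        )

    V = np.empty(protocol.n_channels)
    for ch, (a, b), (c, d) in protocol.channels():
        V[ch] = u(centers[c], a, b) - u(centers[d], a, b)
    return V


def disk_arc_voltages(protocol, arc, sigma=1.0, current=1.0, order=48):
    """Green's-function oracle with uniform current density over the arcs."""
    from numpy.polynomial.legendre import leggauss

    n = protocol.n_electrodes
    gq, gw = leggauss(order)
    gw = gw / gw.sum()

    def arc_points(k):
        th = 2 * np.pi * k / n + gq * arc / 2
        return np.column_stack([np.cos(th), np.sin(th)])

    pts = [arc_points(k) for k in range(n)]

    def u_at(x, a, b):
        da = np.linalg.norm(pts[a] - x, axis=1)
        db = np.linalg.norm(pts[b] - x, axis=1)
        return (current / (np.pi * sigma)) * (
            (gw * np.log(db)).sum() - (gw * np.log(da)).sum()
        )

    V = np.empty(protocol.n_channels)
    for ch, (a, b), (c, d) in protocol.channels():
        uc = sum(w * u_at(p, a, b) for p, w in zip(pts[c], gw))
        ud = sum(w * u_at(p, a, b) for p, w in zip(pts[d], gw))
        V[ch] = uc - ud
    return V


@pytest.fixture(scope="session")
def arc_oracle_voltages(protocol, mesh_small):
    return disk_arc_voltages(protocol, mesh_small.electrode_arc)
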