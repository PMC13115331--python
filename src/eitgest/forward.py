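"""Finite-element EIT forward solver on the meshed disk.

Solves the 2-D conduction equation ``div(sigma grad u) = 0`` with current
injected through boundary electrode node sets (gap/point electrode model:
no contact-impedance term; contact effects are modelled at the measurement
level by the phantom generator).  Linear (P1) triangular elements; one
sparse LU factorisation is shared by all drives of a frame.

Units: conductivity in S/m, current in mA, voltages in mV (2-D problem of
unit thickness, so mA / (S/m) gives mV per unit length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from eitgest.mesh import Mesh
from eitgest.protocol import DriveProtocol, MeasurementFrame


@dataclass
class SensitivityMatrix:
    """Linearised forward operator ``J`` (n_channels x n_elements).

    Maps a small element-wise conductivity change ``delta_sigma`` to the
    boundary-voltage change ``delta_v = J @ delta_sigma`` around the
    reference conductivity ``sigma_ref``.
    """

    J: np.ndarray
    sigma_ref: np.ndarray

    @property
    def shape(self):
        return self.J.shape


class FEMSolver:
    """Reusable FEM machinery for one mesh + protocol.

    Precomputes element shape-function coefficients and the electrode
    weight vectors, and caches per-conductivity factorisations are the
    caller's concern (see :class:`eitgest.phantom.SessionSimulator`).
    """

    def __init__(self, mesh: Mesh, protocol: DriveProtocol):
        if protocol.n_electrodes != mesh.n_electrodes:
            raise ValueError("protocol electrode count does not match mesh")
        self.mesh = mesh
        self.protocol = protocol

        tri = mesh.elements
        p = mesh.node_coords[tri]  # (m, 3, 2)
        # P1 gradients: grad(phi_i) = (b_i, c_i) / (2A)
        x, y = p[..., 0], p[..., 1]
        self._b = np.stack(
            [y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1
        )
        self._c = np.stack(
            [x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1
        )
        self._area = mesh.element_areas()

        # COO pattern for assembly, built once.
        m = mesh.n_elements
        rows = np.repeat(tri, 3, axis=1).reshape(m, 9)  # i index
        cols = np.tile(tri, (1, 3)).reshape(m, 9)  # j index
        self._rows = rows.ravel()
        self._cols = cols.ravel()
        # local stiffness K_ij = (b_i b_j + c_i c_j) / (4A), scaled by sigma_e
        bb = self._b[:, :, None] * self._b[:, None, :]
        cc = self._c[:, :, None] * self._c[:, None, :]
        self._klocal = (bb + cc) / (4.0 * self._area)[:, None, None]  # (m, 3, 3)

        # Electrode weight vectors: unit current spread over electrode nodes
        # (arc-length weighted when the mesh provides weights).
        n = mesh.n_nodes
        self._w = np.zeros((mesh.n_electrodes, n))
        for k, nodes in enumerate(mesh.electrode_nodes):
            if mesh.electrode_weights is not None:
                self._w[k, nodes] = mesh.electrode_weights[k]
            else:
                self._w[k, nodes] = 1.0 / len(nodes)
        self._ground = 0  # centre node is grounded

    def assemble(self, sigma: np.ndarray) -> sp.csc_matrix:
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape != (self.mesh.n_elements,):
            raise ValueError("sigma length must equal the number of elements")
        if np.any(sigma <= 0):
            raise ValueError("conductivity must be strictly positive")
        vals = (self._klocal * sigma[:, None, None]).ravel()
        n = self.mesh.n_nodes
        K = sp.coo_matrix((vals, (self._rows, self._cols)), shape=(n, n)).tocsc()
        return K

    def electrode_fields(self, sigma: np.ndarray) -> np.ndarray:
        """Nodal potential field for unit current into each electrode.

        Returns ``H`` of shape (n_electrodes, n_nodes); the return current
        exits at the grounded centre node, which cancels in any pair
        difference, so the field for a (source, sink) pair is
        ``H[source] - H[sink]``.
        """
        K = self.assemble(sigma)
        g = self._ground
        keep = np.arange(self.mesh.n_nodes) != g
        Kred = K[keep][:, keep]
        try:
            lu = spla.splu(Kred.tocsc())
        except RuntimeError as exc:  # pragma: no cover - disconnected mesh
            raise ValueError(f"singular FEM system: {exc}") from exc
        B = self._w[:, keep].T
        U = lu.solve(B)
        H = np.zeros((self.mesh.n_electrodes, self.mesh.n_nodes))
        H[:, keep] = U.T
        return H

    def voltages_from_fields(self, H: np.ndarray) -> np.ndarray:
        """Assemble the canonical channel vector from electrode fields."""
        prot = self.protocol
        V = np.empty(prot.n_channels)
        meas_pot = self._w @ H.T  # (n_el, n_el): potential averaged on electrode i for field j
        for ch, (a, b), (c, d) in prot.channels():
            V[ch] = (meas_pot[c, a] - meas_pot[c, b] - meas_pot[d, a] + meas_pot[d, b])
        return V * prot.current_amplitude

    def solve(self, sigma: np.ndarray) -> np.ndarray:
        return self.voltages_from_fields(self.electrode_fields(sigma))

    def jacobian(self, sigma_ref: np.ndarray) -> np.ndarray:
        """Adjoint-field sensitivity: J[ch, e] = -area_e * grad(u_drive).grad(u_meas)."""
        H = self.electrode_fields(sigma_ref)
        # per-element gradients of each electrode field: (n_el, m, 2)
        tri = self.mesh.elements
        Htri = H[:, tri]  # (n_el, m, 3)
        gx = np.einsum("kmi,mi->km", Htri, self._b) / (2.0 * self._area)
        gy = np.einsum("kmi,mi->km", Htri, self._c) / (2.0 * self._area)
        prot = self.protocol
        J = np.empty((prot.n_channels, self.mesh.n_elements))
        amp = prot.current_amplitude
        for ch, (a, b), (c, d) in prot.channels():
            gdx, gdy = gx[a] - gx[b], gy[a] - gy[b]
            gmx, gmy = gx[c] - gx[d], gy[c] - gy[d]
            J[ch] = -self._area * (gdx * gmx + gdy * gmy) * amp
        return J


def solve_forward(
    mesh: Mesh, sigma: np.ndarray, protocol: DriveProtocol, t: float = 0.0
) -> MeasurementFrame:
    """Solve the forward problem and return one canonical measurement frame.

    Voltages scale linearly with ``protocol.current_amplitude`` and as
    ``1/c`` when the conductivity is scaled by ``c``.
    """
    solver = FEMSolver(mesh, protocol)
    return MeasurementFrame(voltages=solver.solve(sigma), t=t)


def compute_jacobian(
    mesh: Mesh, sigma_ref: np.ndarray, protocol: DriveProtocol
) -> SensitivityMatrix:
    """Sensitivity matrix at ``sigma_ref`` by the adjoint-field method.

    Satisfies ``solve_forward(sigma_ref + ds) - solve_forward(sigma_ref)
    ~= J @ ds`` for small element-wise perturbations ``ds``.
    """
    solver = FEMSolver(mesh, protocol)
    sigma_ref = np.asarray(sigma_ref, dtype=float)
    if np.any(sigma_ref <= 0):
        raise ValueError("conductivity must be strictly positive")
    return SensitivityMatrix(J=solver.jacobian(sigma_ref), sigma_ref=sigma_ref.copy())
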