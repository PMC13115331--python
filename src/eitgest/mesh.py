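"""Structured triangular mesh of the unit disk with boundary electrodes.

The forearm cross-section is idealised as the unit disk.  Nodes lie on
concentric rings whose counts are multiples of the electrode count, so the
mesh is exactly symmetric under rotation by one electrode pitch.  The
outermost rings use an electrode-aligned angular pattern: every electrode
arc is delimited by nodes exactly at its edges, with uniformly spaced
nodes inside the arc and inside the gap.  Current is injected with the
consistent (tent-function) load for a uniform current density over the
arc, which makes the electrode model independent of the refinement level.

Electrode ``k`` is centred at angle ``2*pi*k/n_electrodes`` (electrode 0
at angle 0, counter-clockwise ordering) and covers half of the
inter-electrode pitch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Fraction of the inter-electrode pitch covered by each electrode.
ELECTRODE_COVERAGE = 0.5


@dataclass
class Mesh:
    """Triangulated unit disk with electrode node sets.

    Attributes
    ----------
    node_coords : (n_nodes, 2) float array
        Positions in units of the domain radius.
    elements : (n_elements, 3) int array
        Counter-clockwise node triples.
    electrode_nodes : list of int arrays
        Ordered boundary node indices of each electrode.
    electrode_arc : float
        Angular width of each electrode (radians).
    electrode_weights : list of float arrays or None
        Per-node current/measurement weights (sum to 1 per electrode);
        uniform if ``None``.
    """

    node_coords: np.ndarray
    elements: np.ndarray
    electrode_nodes: list
    electrode_arc: float
    electrode_weights: list | None = None

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_nodes)

    def element_areas(self) -> np.ndarray:
        p = self.node_coords[self.elements]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def element_centroids(self) -> np.ndarray:
        return self.node_coords[self.elements].mean(axis=1)

    def validate(self) -> None:
        if self.elements.min() < 0 or self.elements.max() >= self.n_nodes:
            raise ValueError("element references a node out of range")
        areas = self.element_areas()
        if np.any(areas <= 0):
            raise ValueError("mesh contains degenerate or inverted elements")
        total = areas.sum()
        if abs(total - np.pi) > 0.01 * np.pi:
            raise ValueError(f"mesh area {total:.4f} deviates from pi by more than 1%")
        flat = np.concatenate([np.asarray(e) for e in self.electrode_nodes])
        if len(set(flat.tolist())) != len(flat):
            raise ValueError("electrode node sets are not disjoint")


def _ring_angles(count: int) -> np.ndarray:
    return 2.0 * np.pi * np.arange(count) / count


def _boundary_pattern(mult: int, n_electrodes: int):
    """Electrode-aligned boundary layout with ``mult`` nodes per pitch.

    Returns sorted angles, per-electrode local node indices, and the
    consistent load weights for a uniform current density over the arc
    (half weight on the two edge nodes).
    """
    pitch = 2 * np.pi / n_electrodes
    h = ELECTRODE_COVERAGE * pitch / 2
    m_e = int(np.ceil(mult / 2))
    m_g = mult - m_e
    elec_off = np.linspace(-h, h, m_e + 1)
    if m_g > 0:
        gap_off = h + (pitch - 2 * h) * np.arange(1, m_g) / m_g
        offsets = np.concatenate([elec_off, gap_off])
    else:
        offsets = elec_off
    per = len(offsets)
    angs = np.concatenate([k * pitch + offsets for k in range(n_electrodes)])
    eidx = [np.arange(k * per, k * per + m_e + 1) for k in range(n_electrodes)]
    weights = np.full(m_e + 1, 1.0 / m_e)
    weights[0] = weights[-1] = 0.5 / m_e
    angs = np.mod(angs, 2 * np.pi)
    order = np.argsort(angs)
    inv = np.argsort(order)
    return angs[order], [inv[ix] for ix in eidx], weights


def _merge_strip(inner_idx, inner_ang, outer_idx, outer_ang):
    """Triangulate the annulus between two rings by angular merge.

    Both angle arrays are sorted ascending from ~0; the walk advances the
    ring whose next vertex has the smaller angle (inner preferred on ties),
    producing ``len(inner) + len(outer)`` triangles.
    """
    p, q = len(inner_idx), len(outer_idx)
    ia = np.append(inner_ang, inner_ang[0] + 2 * np.pi)
    oa = np.append(outer_ang, outer_ang[0] + 2 * np.pi)
    tris = []
    i = j = 0
    while i < p or j < q:
        if i < p and (j == q or ia[i + 1] <= oa[j + 1]):
            tris.append((inner_idx[i % p], inner_idx[(i + 1) % p], outer_idx[j % q]))
            i += 1
        else:
            tris.append((inner_idx[i % p], outer_idx[(j + 1) % q], outer_idx[j % q]))
            j += 1
    return tris


def build_disk_mesh(refinement_level: int, n_electrodes: int = 16) -> Mesh:
    """Build a conforming triangulation of the unit disk with electrodes.

    ``refinement_level`` controls resolution: level 1 gives ~500 elements,
    level 2 (the default working mesh) ~900, level 3 ~1500.  Outer rings
    that carry the full boundary node count share the electrode-aligned
    angular pattern, so near-boundary edges run radially and the electrode
    discretisation is structurally identical at every level.
    Deterministic for fixed arguments.
    """
    if refinement_level < 1:
        raise ValueError("refinement_level must be >= 1 to host disjoint electrodes")
    if n_electrodes < 4:
        raise ValueError("need at least 4 electrodes")
    mult = refinement_level + 2
    n_rings = 4 * refinement_level + 6

    ring_mult = [max(1, round(mult * i / n_rings)) for i in range(1, n_rings + 1)]
    ring_mult[-1] = mult
    for i in range(n_rings - 2, -1, -1):
        ring_mult[i] = min(ring_mult[i], ring_mult[i + 1])

    pat_ang, pat_eidx, pat_w = _boundary_pattern(mult, n_electrodes)

    coords = [np.zeros((1, 2))]
    ring_indices = []
    ring_angles = []
    start = 1
    for i, m in enumerate(ring_mult, start=1):
        r = i / n_rings
        ang = pat_ang if m == mult else _ring_angles(n_electrodes * m)
        coords.append(r * np.column_stack([np.cos(ang), np.sin(ang)]))
        ring_indices.append(np.arange(start, start + len(ang)))
        ring_angles.append(ang)
        start += len(ang)
    node_coords = np.vstack(coords)

    tris = []
    first = ring_indices[0]
    k0 = len(first)
    for j in range(k0):
        tris.append((0, first[j], first[(j + 1) % k0]))
    for i in range(n_rings - 1):
        if np.array_equal(ring_angles[i], ring_angles[i + 1]):
            # aligned rings: regular strip of quads split into triangles
            p = len(ring_angles[i])
            ii, oo = ring_indices[i], ring_indices[i + 1]
            for j in range(p):
                jn = (j + 1) % p
                tris.append((ii[j], ii[jn], oo[j]))
                tris.append((ii[jn], oo[jn], oo[j]))
        else:
            tris.extend(
                _merge_strip(
                    ring_indices[i], ring_angles[i], ring_indices[i + 1], ring_angles[i + 1]
                )
            )
    elements = np.asarray(tris, dtype=np.int64)

    # Fix orientation to counter-clockwise.
    p = node_coords[elements]
    signed = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = signed < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]

    bidx = ring_indices[-1]
    electrode_nodes = [bidx[ix] for ix in pat_eidx]
    electrode_weights = [pat_w.copy() for _ in range(n_electrodes)]
    arc = ELECTRODE_COVERAGE * 2 * np.pi / n_electrodes

    mesh = Mesh(node_coords, elements, electrode_nodes, arc, electrode_weights)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Plain-text mesh serialisation (documented header + whitespace tables).

_HEADER = "# eitgest mesh v1"


def save_mesh(mesh: Mesh, path) -> None:
    """Write a mesh as a simple self-describing text file."""
    with open(path, "w") as fh:
        fh.write(f"{_HEADER}\n")
        fh.write(f"nodes {mesh.n_nodes}\n")
        for x, y in mesh.node_coords:
            fh.write(f"{x:.17g} {y:.17g}\n")
        fh.write(f"elements {mesh.n_elements}\n")
        for a, b, c in mesh.elements:
            fh.write(f"{a} {b} {c}\n")
        fh.write(f"electrodes {mesh.n_electrodes} {mesh.electrode_arc:.17g}\n")
        for k, nodes in enumerate(mesh.electrode_nodes):
            fh.write(" ".join(str(i) for i in nodes) + "\n")
            if mesh.electrode_weights is not None:
                fh.write(" ".join(f"{w:.17g}" for w in mesh.electrode_weights[k]) + "\n")


def load_mesh(path) -> Mesh:
    """Read a mesh written by :func:`save_mesh`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _HEADER:
        raise ValueError("not an eitgest mesh file")
    pos = 1
    tag, n = lines[pos].split()
    assert tag == "nodes"
    n = int(n)
    pos += 1
    node_coords = np.array(
        [[float(v) for v in lines[pos + i].split()] for i in range(n)]
    )
    pos += n
    tag, m = lines[pos].split()
    assert tag == "elements"
    m = int(m)
    pos += 1
    elements = np.array(
        [[int(v) for v in lines[pos + i].split()] for i in range(m)], dtype=np.int64
    )
    pos += m
    tag, ne, arc = lines[pos].split()
    assert tag == "electrodes"
    ne = int(ne)
    pos += 1
    electrode_nodes = []
    electrode_weights = []
    for _ in range(ne):
        electrode_nodes.append(
            np.array([int(v) for v in lines[pos].split()], dtype=np.int64)
        )
        electrode_weights.append(np.array([float(v) for v in lines[pos + 1].split()]))
        pos += 2
    mesh = Mesh(node_coords, elements, electrode_nodes, float(arc), electrode_weights)
    mesh.validate()
    return mesh
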