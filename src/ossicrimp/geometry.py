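"""Parametric solid geometry and tetrahedral meshing of the incus-prosthesis assembly.

The lenticular process of the incus is idealised as a cortical-bone cylinder
(0.8 mm diameter).  The prosthesis is a split loop (coverage angle ``theta``)
wrapped around it, with a prismatic stem extending radially outward from the
middle of the covered arc; the stem's far face stands in for the distal end of
the piston body, which surgery anchors at the stapes footplate.

Meshes are built from structured polar cross-sections extruded along the
incus axis.  Each extruded wedge (triangular prism) is split into three
tetrahedra using the minimum-global-vertex diagonal rule, which guarantees
that the triangulations of shared quadrilateral faces agree between
neighbouring cells, so the mesh is conforming by construction.  Quadratic
(10-node) tetrahedra are obtained by inserting midside nodes, which are
projected onto the curved cylindrical surfaces they straddle.

All named boundary patches needed by the contact solver are recovered
geometrically from the boundary faces:

``contact_inner_loop``
    inner (incus-facing) surface of the loop,
``target_incus_surface``
    incus surface directly under the loop arc,
``fixed_posterior_incus``
    posterior end face of the incus cylinder,
``fixed_shaft_tip``
    far face of the prosthesis stem,
``loop_load_surface``
    outer surface of the loop band (crimp-force application).

Units: mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .analytical import Material, RingSpec, CORTICAL_BONE, PTFE

__all__ = [
    "AssemblySpec",
    "AssemblyMesh",
    "MeshingError",
    "build_assembly",
    "mesh_quality_report",
    "cylinder_sector_mesh",
    "annulus_sector_mesh",
    "press_fit_assembly",
    "merge_meshes",
    "PressFitSpec",
]

REGION_INCUS = 1
REGION_LOOP = 2
REGION_SHAFT = 3
REGION_NAMES = {REGION_INCUS: "incus", REGION_LOOP: "loop", REGION_SHAFT: "shaft"}

#: Corner-node triples of the four outward-oriented faces of a positive tet.
_TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])

#: Local edge numbering of the 10-node tetrahedron (VTK quadratic-tet order).
TET10_EDGES = np.array([[0, 1], [1, 2], [2, 0], [0, 3], [1, 3], [2, 3]])


class MeshingError(RuntimeError):
    """Raised when a parameter set produces a degenerate or invalid mesh."""


@dataclass(frozen=True)
class AssemblySpec:
    """Parameters of the incus-prosthesis assembly.

    ``ring.interference_dr`` is built into the geometry: the loop inner
    surface is placed at ``incus radius - interference_dr`` so the
    interference appears as an initial overlap resolved by the contact
    algorithm.  Force- or pressure-driven load cases normally use a ring with
    zero interference (surfaces just touching).
    """

    ring: RingSpec
    incus_diameter: float = 0.8
    incus_length: float = 3.0
    shaft_diameter: float = 0.4
    functional_length: float = 3.4
    crimp_offset_from_tip: float = 1.3
    loop_opening_deg: float | None = None  # derived from ring coverage if None
    material_map: dict[str, Material] = field(
        default_factory=lambda: {"incus": CORTICAL_BONE, "loop": PTFE, "shaft": PTFE}
    )

    def __post_init__(self) -> None:
        if not 0 < self.crimp_offset_from_tip < self.incus_length:
            raise MeshingError(
                "crimp_offset_from_tip must lie inside the incus "
                f"(got {self.crimp_offset_from_tip} for length {self.incus_length})"
            )
        if self.incus_diameter <= 0 or self.shaft_diameter <= 0:
            raise MeshingError("incus and shaft diameters must be positive")

    @property
    def incus_radius(self) -> float:
        return 0.5 * self.incus_diameter

    @property
    def loop_inner_radius(self) -> float:
        """Loop bore radius as meshed: incus radius minus the radial interference."""
        return self.incus_radius - self.ring.interference_dr

    @property
    def loop_outer_radius(self) -> float:
        return self.loop_inner_radius + self.ring.thickness

    @property
    def shaft_length(self) -> float:
        """Radial stem length so that the overall span matches the functional length."""
        return max(self.functional_length - 2.0 * self.loop_outer_radius, 0.5)


@dataclass
class AssemblyMesh:
    """Tagged tetrahedral mesh (4- or 10-node elements).

    ``patches`` maps patch names to facet arrays of shape (nf, 3) for linear
    or (nf, 6) for quadratic meshes, with corner triples oriented so the
    right-hand normal points out of the solid.
    """

    nodes: np.ndarray
    elements: np.ndarray
    region_tags: np.ndarray
    patches: dict[str, np.ndarray]
    order: int
    region_names: dict[int, str] = field(default_factory=lambda: dict(REGION_NAMES))
    spec: AssemblySpec | None = None
    seed: int = 0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def region_elements(self, name: str) -> np.ndarray:
        rid = {v: k for k, v in self.region_names.items()}[name]
        return self.elements[self.region_tags == rid]

    def region_node_ids(self, name: str) -> np.ndarray:
        return np.unique(self.region_elements(name))

    def patch_node_ids(self, patch: str) -> np.ndarray:
        return np.unique(self.patches[patch])

    def element_volumes(self) -> np.ndarray:
        """Signed corner-tet volumes (curvature of quadratic edges ignored)."""
        x = self.nodes[self.elements[:, :4]]
        v = np.einsum(
            "ij,ij->i",
            np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
            x[:, 3] - x[:, 0],
        )
        return v / 6.0


# ---------------------------------------------------------------------------
# low-level building blocks
# ---------------------------------------------------------------------------

def _graded_segment(a: float, b: float, h: float) -> np.ndarray:
    """Uniform subdivision of [a, b] with spacing close to h (at least 1 cell)."""
    n = max(1, int(round(abs(b - a) / h)))
    return np.linspace(a, b, n + 1)


def _merge_breaks(breaks: list[tuple[float, float, float]]) -> np.ndarray:
    """Concatenate graded segments sharing endpoints into one sorted level set."""
    levels = [np.array([breaks[0][0]])]
    for a, b, h in breaks:
        levels.append(_graded_segment(a, b, h)[1:])
    return np.concatenate(levels)


def _split_wedges(wedges: np.ndarray) -> np.ndarray:
    """Split triangular prisms into 3 tets each with the min-vertex rule.

    ``wedges``: (nw, 6) global node ids, bottom triangle then top triangle,
    both with the same in-plane orientation.  The diagonal of every
    quadrilateral face is chosen to emanate from the face's smallest global
    node id, which makes the decomposition conforming across shared faces.
    """
    rot = np.array([1, 2, 0, 4, 5, 3])  # cyclic rotation about the prism axis
    flip = np.array([3, 5, 4, 0, 2, 1])  # top-bottom swap (orientation-preserving)
    w = wedges.copy()
    # bring the global minimum vertex to local position 0
    for _ in range(2):
        amin = np.argmin(w, axis=1)
        sel = (amin == 1) | (amin == 4)
        w[sel] = w[sel][:, rot]
        amin = np.argmin(w, axis=1)
        sel = (amin == 2) | (amin == 5)
        w[sel] = w[sel][:, rot[rot]]
    amin = np.argmin(w, axis=1)
    sel = amin != 0
    w[sel] = w[sel][:, flip]
    if np.argmin(w, axis=1).any():
        raise MeshingError("prism rotation failed to normalise the minimum vertex")
    # quad face (1,2,5,4): diagonal from its smallest vertex
    case_a = np.minimum(w[:, 1], w[:, 5]) < np.minimum(w[:, 2], w[:, 4])
    tets = np.empty((w.shape[0], 3, 4), dtype=wedges.dtype)
    wa, wb = w[case_a], w[~case_a]
    tets[case_a] = np.stack(
        [wa[:, [0, 1, 2, 5]], wa[:, [0, 1, 5, 4]], wa[:, [0, 4, 5, 3]]], axis=1
    )
    tets[~case_a] = np.stack(
        [wb[:, [0, 1, 2, 4]], wb[:, [0, 4, 2, 5]], wb[:, [0, 4, 5, 3]]], axis=1
    )
    return tets.reshape(-1, 4)


def _extrude(points2d: np.ndarray, tris: np.ndarray, z_levels: np.ndarray,
             node_offset: int) -> tuple[np.ndarray, np.ndarray]:
    """Extrude a 2D triangulation along z into wedges.

    Returns (nodes (n,3), wedges (nw,6)) with global ids starting at
    ``node_offset``.  Wedge bottom/top triangles keep the 2D orientation.
    """
    n2 = points2d.shape[0]
    nz = z_levels.size
    nodes = np.empty((n2 * nz, 3))
    nodes[:, :2] = np.tile(points2d, (nz, 1))
    nodes[:, 2] = np.repeat(z_levels, n2)
    layers_lo = (np.arange(nz - 1)[:, None, None] * n2 + tris[None, :, :])
    wedges = np.concatenate([layers_lo, layers_lo + n2], axis=2).reshape(-1, 6)
    return nodes, wedges + node_offset


def _polar_grid_section(radii: np.ndarray, phis: np.ndarray, close_centre: bool,
                        closed_loop: bool) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated polar patch.

    ``radii`` ascending (first entry may be > 0 for an annulus), ``phis`` in
    radians.  ``close_centre`` adds a centre vertex fanned to the innermost
    ring (full disk).  ``closed_loop`` wraps phi around (full 360 ring).
    Returns (points (n,2), tris (nt,3)).
    """
    nphi = phis.size - 1 if closed_loop else phis.size
    ring_ids = np.arange(radii.size * nphi).reshape(radii.size, nphi)
    pts = np.empty((radii.size * nphi, 2))
    use_phis = phis[:-1] if closed_loop else phis
    pts[:, 0] = (radii[:, None] * np.cos(use_phis)[None, :]).ravel()
    pts[:, 1] = (radii[:, None] * np.sin(use_phis)[None, :]).ravel()
    tris = []
    cols = np.arange(nphi) if closed_loop else np.arange(nphi - 1)
    nxt = (cols + 1) % nphi if closed_loop else cols + 1
    for j in range(radii.size - 1):
        a, b = ring_ids[j, cols], ring_ids[j, nxt]
        c, d = ring_ids[j + 1, nxt], ring_ids[j + 1, cols]
        # split each quad along a fixed diagonal (conformity is restored by
        # the min-vertex rule at the wedge level)
        tris.append(np.stack([a, b, c], axis=1))
        tris.append(np.stack([a, c, d], axis=1))
    if close_centre:
        centre = pts.shape[0]
        pts = np.vstack([pts, [0.0, 0.0]])
        a, b = ring_ids[0, cols], ring_ids[0, nxt]
        tris.append(np.stack([np.full_like(a, centre), a, b], axis=1))
    tri_arr = np.concatenate(tris, axis=0)
    # enforce counter-clockwise orientation
    p = pts[tri_arr]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = area2 < 0
    tri_arr[flip] = tri_arr[flip][:, [0, 2, 1]]
    return pts, tri_arr


def _boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented triangular faces occurring exactly once."""
    faces = tets[:, _TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def _ensure_positive(tets: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    x = nodes[tets]
    v = np.einsum(
        "ij,ij->i", np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), x[:, 3] - x[:, 0]
    )
    out = tets.copy()
    out[v < 0] = out[v < 0][:, [0, 2, 1, 3]]
    return out


def _to_quadratic(nodes: np.ndarray, tets: np.ndarray,
                  surface_radii: list[tuple[np.ndarray, float]]) -> tuple[np.ndarray, np.ndarray]:
    """Insert midside nodes; project those lying on a cylindrical surface.

    ``surface_radii``: list of (node mask, radius); a midnode is pulled onto
    the cylinder r=radius about the z axis whenever both its edge endpoints
    are flagged in the same mask.
    """
    edges = tets[:, TET10_EDGES].reshape(-1, 2)
    edges_sorted = np.sort(edges, axis=1)
    uniq, inv = np.unique(edges_sorted, axis=0, return_inverse=True)
    mid = 0.5 * (nodes[uniq[:, 0]] + nodes[uniq[:, 1]])
    for mask, radius in surface_radii:
        on_surf = mask[uniq[:, 0]] & mask[uniq[:, 1]]
        if not on_surf.any():
            continue
        xy = mid[on_surf, :2]
        r = np.linalg.norm(xy, axis=1)
        good = r > 1e-12
        scale = np.ones_like(r)
        scale[good] = radius / r[good]
        mid[on_surf, :2] = xy * scale[:, None]
    mid_ids = np.arange(uniq.shape[0]) + nodes.shape[0]
    all_nodes = np.vstack([nodes, mid])
    tet10 = np.concatenate([tets, mid_ids[inv].reshape(-1, 6)], axis=1)
    return all_nodes, tet10


def _facets_with_midnodes(faces: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Upgrade corner-triangle facets to 6-node facets using the element edge map."""
    edges = elements[:, TET10_EDGES[:, 0]], elements[:, TET10_EDGES[:, 1]]
    lo = np.minimum(edges[0], edges[1]).ravel()
    hi = np.maximum(edges[0], edges[1]).ravel()
    mid = elements[:, 4:10].ravel()
    lookup: dict[tuple[int, int], int] = {}
    for a, b, m in zip(lo.tolist(), hi.tolist(), mid.tolist()):
        lookup[(a, b)] = m
    out = np.empty((faces.shape[0], 6), dtype=faces.dtype)
    out[:, :3] = faces
    fe = [(0, 1), (1, 2), (2, 0)]
    for k, (i, j) in enumerate(fe):
        for row in range(faces.shape[0]):
            a, b = int(faces[row, i]), int(faces[row, j])
            out[row, 3 + k] = lookup[(min(a, b), max(a, b))]
    return out


# ---------------------------------------------------------------------------
# simple verification shapes (also used by the solver test oracles)
# ---------------------------------------------------------------------------

def _finish_mesh(nodes: np.ndarray, wedges: np.ndarray, region: np.ndarray,
                 order: int, surfaces: list[tuple[str, "callable"]],
                 surface_radii_masks, region_names, curved: bool = True) -> AssemblyMesh:
    tets = _split_wedges(wedges)
    region_tags = np.repeat(region, 3)
    tets = _ensure_positive(tets, nodes)
    if order == 2:
        masks = [(m(nodes), r) for m, r in surface_radii_masks] if curved else []
        nodes, elements = _to_quadratic(nodes, tets, masks)
    else:
        elements = tets
    corner_faces = _boundary_faces(elements[:, :4])
    if order == 2:
        all_faces = _facets_with_midnodes(corner_faces, elements)
    else:
        all_faces = corner_faces
    centroids = nodes[corner_faces].mean(axis=1)
    patches: dict[str, np.ndarray] = {}
    for name, predicate in surfaces:
        sel = predicate(nodes, corner_faces, centroids)
        patches[name] = all_faces[sel]
    return AssemblyMesh(
        nodes=nodes, elements=elements, region_tags=region_tags,
        patches=patches, order=order, region_names=region_names,
    )


def _faces_on_radius(nodes, faces, radius, tol):
    r = np.linalg.norm(nodes[faces][:, :, :2], axis=2)
    return np.all(np.abs(r - radius) < tol, axis=1)


def _faces_on_z(nodes, faces, z, tol):
    return np.all(np.abs(nodes[faces][:, :, 2] - z) < tol, axis=1)


def cylinder_sector_mesh(radius: float, length: float, h: float,
                         phi_span_deg: float = 360.0, order: int = 2,
                         curved: bool = True) -> AssemblyMesh:
    """Solid cylinder (or angular sector) about the z axis, z in [0, length].

    Patches: ``lateral`` (r = radius), ``z0``/``z1`` end faces, and for
    sectors ``phi0``/``phi1`` cut planes.  Region tag: incus/cortical bone by
    default (material assignment happens in the solver).
    """
    closed = abs(phi_span_deg - 360.0) < 1e-9
    nr = max(2, int(round(radius / h)))
    radii = np.linspace(radius / nr, radius, nr)
    arc = math.radians(phi_span_deg)
    nphi = max(3 if closed else 2, int(round(arc * radius / h)))
    phis = np.linspace(0.0, arc, nphi + 1)
    pts, tris = _polar_grid_section(radii, phis, close_centre=True, closed_loop=closed)
    zl = _graded_segment(0.0, length, h)
    nodes, wedges = _extrude(pts, tris, zl, 0)
    region = np.full(wedges.shape[0], REGION_INCUS)
    tol = 1e-6 * max(radius, length)
    surfaces = [
        ("lateral", lambda n, f, c: _faces_on_radius(n, f, radius, 1e-4 + tol)),
        ("z0", lambda n, f, c: _faces_on_z(n, f, 0.0, tol)),
        ("z1", lambda n, f, c: _faces_on_z(n, f, length, tol)),
    ]
    if not closed:
        surfaces += [
            ("phi0", lambda n, f, c: np.all(np.abs(n[f][:, :, 1]) < tol, axis=1)),
            ("phi1", lambda n, f, c: np.all(
                np.abs(n[f][:, :, 1] * math.cos(arc) - n[f][:, :, 0] * math.sin(arc)) < tol,
                axis=1) & np.all(
                (n[f][:, :, 0] * math.cos(arc) + n[f][:, :, 1] * math.sin(arc)) > -tol, axis=1)),
        ]
    surf_masks = [
        (lambda n: np.abs(np.linalg.norm(n[:, :2], axis=1) - radius) < 1e-4, radius)
    ]
    return _finish_mesh(nodes, wedges, region, order, surfaces, surf_masks,
                        {REGION_INCUS: "body"}, curved=curved)


def annulus_sector_mesh(r_inner: float, r_outer: float, length: float, h: float,
                        phi_span_deg: float = 360.0, order: int = 2,
                        n_radial_min: int = 2, curved: bool = True) -> AssemblyMesh:
    """Thick-walled annulus (or sector) about z, z in [0, length].

    Patches: ``inner``, ``outer``, ``z0``, ``z1`` (+ ``phi0``/``phi1`` for
    sectors).
    """
    if not 0 < r_inner < r_outer:
        raise MeshingError("need 0 < r_inner < r_outer")
    closed = abs(phi_span_deg - 360.0) < 1e-9
    t = r_outer - r_inner
    nr = max(n_radial_min, int(round(t / h)))
    radii = np.linspace(r_inner, r_outer, nr + 1)
    arc = math.radians(phi_span_deg)
    rm = 0.5 * (r_inner + r_outer)
    nphi = max(3 if closed else 2, int(round(arc * rm / h)))
    phis = np.linspace(0.0, arc, nphi + 1)
    pts, tris = _polar_grid_section(radii, phis, close_centre=False, closed_loop=closed)
    zl = _graded_segment(0.0, length, h)
    nodes, wedges = _extrude(pts, tris, zl, 0)
    region = np.full(wedges.shape[0], REGION_LOOP)
    tol = 1e-6 * max(r_outer, length)
    surfaces = [
        ("inner", lambda n, f, c: _faces_on_radius(n, f, r_inner, 1e-4 + tol)),
        ("outer", lambda n, f, c: _faces_on_radius(n, f, r_outer, 1e-4 + tol)),
        ("z0", lambda n, f, c: _faces_on_z(n, f, 0.0, tol)),
        ("z1", lambda n, f, c: _faces_on_z(n, f, length, tol)),
    ]
    if not closed:
        surfaces += [
            ("phi0", lambda n, f, c: np.all(np.abs(n[f][:, :, 1]) < tol, axis=1)),
            ("phi1", lambda n, f, c: np.all(
                np.abs(n[f][:, :, 1] * math.cos(arc) - n[f][:, :, 0] * math.sin(arc)) < tol,
                axis=1)),
        ]
    surf_masks = [
        (lambda n: np.abs(np.linalg.norm(n[:, :2], axis=1) - r_inner) < 1e-4, r_inner),
        (lambda n: np.abs(np.linalg.norm(n[:, :2], axis=1) - r_outer) < 1e-4, r_outer),
    ]
    return _finish_mesh(nodes, wedges, region, order, surfaces, surf_masks,
                        {REGION_LOOP: "body"}, curved=curved)


@dataclass(frozen=True)
class PressFitSpec:
    """Minimal geometry record for the two-cylinder press-fit shape."""

    incus_radius: float       # shaft outer radius (the inner body)
    loop_inner_radius: float  # hub bore radius (shaft radius - interference)


def merge_meshes(parts: list[tuple[AssemblyMesh, int, dict[str, str]]],
                 region_names: dict[int, str]) -> AssemblyMesh:
    """Concatenate single-region meshes into one multi-body mesh.

    ``parts``: (mesh, region id, patch rename map); patches absent from the
    map are dropped.  Bodies stay disconnected (no node merging) -- they
    interact through contact only.
    """
    orders = {m.order for m, _, _ in parts}
    if len(orders) != 1:
        raise MeshingError("cannot merge meshes of mixed element order")
    offset = 0
    nodes, elems, tags = [], [], []
    patches: dict[str, np.ndarray] = {}
    for m, rid, rename in parts:
        nodes.append(m.nodes)
        elems.append(m.elements + offset)
        tags.append(np.full(m.n_elements, rid))
        for old, new in rename.items():
            patches[new] = m.patches[old] + offset
        offset += m.n_nodes
    return AssemblyMesh(
        nodes=np.vstack(nodes), elements=np.vstack(elems),
        region_tags=np.concatenate(tags), patches=patches,
        order=orders.pop(), region_names=dict(region_names),
    )


def press_fit_assembly(r_shaft: float, r_hub_outer: float, interference: float,
                       length: float, h: float, phi_span_deg: float = 90.0,
                       order: int = 2) -> AssemblyMesh:
    """Coaxial solid shaft + hub with radial interference (contact oracle shape).

    The hub bore is undersized by ``interference``; an angular sector is
    produced for use with symmetry boundary conditions.  Patch names follow
    the assembly convention (``target_incus_surface`` = shaft surface,
    ``contact_inner_loop`` = hub bore) so the contact solver applies
    unchanged; body-local faces are exposed as ``shaft_*`` / ``hub_*``.
    """
    if not 0 < interference < r_shaft:
        raise MeshingError("interference must be positive and below the shaft radius")
    shaft = cylinder_sector_mesh(r_shaft, length, h, phi_span_deg, order)
    hub = annulus_sector_mesh(r_shaft - interference, r_hub_outer, length, h,
                              phi_span_deg, order)
    shaft_map = {"lateral": "target_incus_surface", "z0": "shaft_z0",
                 "z1": "shaft_z1"}
    hub_map = {"inner": "contact_inner_loop", "outer": "hub_outer",
               "z0": "hub_z0", "z1": "hub_z1"}
    if phi_span_deg < 360.0:
        shaft_map |= {"phi0": "shaft_phi0", "phi1": "shaft_phi1"}
        hub_map |= {"phi0": "hub_phi0", "phi1": "hub_phi1"}
    mesh = merge_meshes(
        [(shaft, REGION_INCUS, shaft_map), (hub, REGION_LOOP, hub_map)],
        {REGION_INCUS: "incus", REGION_LOOP: "loop"},
    )
    mesh.spec = PressFitSpec(incus_radius=r_shaft,
                             loop_inner_radius=r_shaft - interference)
    return mesh


# ---------------------------------------------------------------------------
# the incus-prosthesis assembly
# ---------------------------------------------------------------------------

def build_assembly(spec: AssemblySpec, target_element_size: float = 0.15,
                   order: int = 2, seed: int = 0,
                   refine_band: float = 0.4) -> AssemblyMesh:
    """Build the tagged incus + loop + stem mesh.

    The axial grid of the incus is refined to ``target_element_size`` within
    ``refine_band`` mm of the loop and coarsened (2.5x) elsewhere.  The
    construction is fully deterministic; ``seed`` is recorded for provenance
    and reserved for future perturbation studies.
    """
    h = float(target_element_size)
    if not 0.02 < h < 0.5:
        raise MeshingError(f"target_element_size {h} outside the supported (0.02, 0.5) mm range")
    ring = spec.ring
    R = spec.incus_radius
    ri_l, ro_l = spec.loop_inner_radius, spec.loop_outer_radius
    if ri_l <= 0 or ro_l <= ri_l:
        raise MeshingError("loop radii degenerate; check ring spec vs incus diameter")
    w = ring.band_width_w
    zc = spec.crimp_offset_from_tip
    z_lo, z_hi = zc - 0.5 * w, zc + 0.5 * w
    if z_lo <= 0 or z_hi >= spec.incus_length:
        raise MeshingError("loop band extends beyond the incus cylinder")
    theta = math.radians(ring.coverage_angle_theta)
    phi_a = math.pi - 0.5 * theta   # arc start (opening centred at phi=0)
    phi_b = math.pi + 0.5 * theta
    stem_half = 0.5 * spec.shaft_diameter / ro_l
    if stem_half >= 0.45 * theta:
        raise MeshingError("stem angular footprint exceeds the loop arc")

    # ---- incus: full disk section, phi grid aligned with the arc ends ----
    nr = max(2, int(round(R / h)))
    radii_incus = np.linspace(R / nr, R, nr)
    # phi levels: opening segment, then the covered arc split at the stem edges
    def _seg(a, b):
        n = max(2, int(round((b - a) * R / h)))
        return np.linspace(a, b, n + 1)
    gap_n = max(2, int(round((2 * math.pi - theta) * R / h)))
    seg_gap = np.linspace(phi_b - 2 * math.pi, phi_a, gap_n + 1)  # opening, wraps
    seg_arc1 = _seg(phi_a, math.pi - stem_half)
    seg_stem = np.linspace(math.pi - stem_half, math.pi + stem_half,
                           max(2, int(round(2 * stem_half * R / h))) + 1)
    seg_arc2 = _seg(math.pi + stem_half, phi_b)
    # spans [phi_b - 2*pi, phi_b]; the final entry coincides with the first
    # modulo 2*pi and is dropped inside _polar_grid_section (closed loop)
    phis = np.concatenate([seg_gap[:-1], seg_arc1, seg_stem[1:], seg_arc2[1:]])
    pts_i, tris_i = _polar_grid_section(radii_incus, phis, close_centre=True,
                                        closed_loop=True)
    z_breaks = [(0.0, max(z_lo - refine_band, 0.0), 2.5 * h),
                (max(z_lo - refine_band, 0.0), z_lo, h),
                (z_lo, z_hi, h),
                (z_hi, min(z_hi + refine_band, spec.incus_length), h),
                (min(z_hi + refine_band, spec.incus_length), spec.incus_length, 2.5 * h)]
    z_breaks = [(a, b, hh) for a, b, hh in z_breaks if b - a > 1e-12]
    z_incus = _merge_breaks(z_breaks)
    nodes_i, wedges_i = _extrude(pts_i, tris_i, z_incus, 0)
    region_i = np.full(wedges_i.shape[0], REGION_INCUS)

    # ---- prosthesis: loop sector + radial stem, extruded over the band ----
    nrl = max(2, int(round(ring.thickness / h)))
    radii_loop = np.linspace(ri_l, ro_l, nrl + 1)
    stem_len = spec.shaft_length
    n_stem = max(2, int(round(stem_len / (2.0 * h))))
    radii_stem = ro_l + (stem_len / n_stem) * np.arange(1, n_stem + 1)
    radii_p = np.concatenate([radii_loop, radii_stem])
    l_arc1 = _seg(phi_a, math.pi - stem_half)
    l_stem = np.linspace(math.pi - stem_half, math.pi + stem_half,
                         max(2, int(round(2 * stem_half * ri_l / h))) + 1)
    l_arc2 = _seg(math.pi + stem_half, phi_b)
    phis_p = np.concatenate([l_arc1, l_stem[1:], l_arc2[1:]])
    pts_p, tris_p = _polar_grid_section(radii_p, phis_p, close_centre=False,
                                        closed_loop=False)
    # drop stem cells outside the stem angular footprint
    cent = pts_p[tris_p].mean(axis=1)
    cent_r = np.linalg.norm(cent, axis=1)
    cent_phi = np.arctan2(cent[:, 1], cent[:, 0]) % (2 * math.pi)
    in_stem_phi = np.abs(cent_phi - math.pi) <= stem_half + 1e-9
    keep = (cent_r <= ro_l + 1e-9) | in_stem_phi
    tris_p = tris_p[keep]
    is_stem = cent_r[keep] > ro_l + 1e-9
    # compact unused points
    used = np.unique(tris_p)
    remap = -np.ones(pts_p.shape[0], dtype=int)
    remap[used] = np.arange(used.size)
    pts_p, tris_p = pts_p[used], remap[tris_p]
    nzw = max(2, int(round(w / h)))
    z_band = np.linspace(z_lo, z_hi, nzw + 1)
    nodes_p, wedges_p = _extrude(pts_p, tris_p, z_band, nodes_i.shape[0])
    region_p = np.where(np.tile(is_stem, z_band.size - 1), REGION_SHAFT, REGION_LOOP)

    nodes = np.vstack([nodes_i, nodes_p])
    wedges = np.vstack([wedges_i, wedges_p])
    region = np.concatenate([region_i, region_p])
    n_incus_nodes = nodes_i.shape[0]

    tol_r = 1e-4
    r_tip = ro_l + stem_len

    def incus_mask(n):
        m = np.zeros(n.shape[0], dtype=bool)
        m[:n_incus_nodes] = np.abs(
            np.linalg.norm(n[:n_incus_nodes, :2], axis=1) - R) < tol_r
        return m

    def pros_mask_at(n, radius):
        m = np.zeros(n.shape[0], dtype=bool)
        m[n_incus_nodes:] = np.abs(
            np.linalg.norm(n[n_incus_nodes:, :2], axis=1) - radius) < tol_r
        return m

    surf_masks = [
        (incus_mask, R),
        (lambda n: pros_mask_at(n, ri_l), ri_l),
        (lambda n: pros_mask_at(n, ro_l), ro_l),
        (lambda n: pros_mask_at(n, r_tip), r_tip),
    ]

    def _is_incus_face(n, f):
        return np.all(f < n_incus_nodes, axis=1)

    def _face_phi(n, f):
        c = n[f].mean(axis=1)
        return np.arctan2(c[:, 1], c[:, 0]) % (2 * math.pi)

    tol_z = 1e-9 + 1e-6 * spec.incus_length

    def p_target(n, f, c):
        on_r = _faces_on_radius(n, f, R, tol_r) & _is_incus_face(n, f)
        zc_f = n[f][:, :, 2]
        in_z = np.all((zc_f > z_lo - tol_z) & (zc_f < z_hi + tol_z), axis=1)
        phi = _face_phi(n, f)
        in_arc = (phi > phi_a - 1e-9) & (phi < phi_b + 1e-9)
        return on_r & in_z & in_arc

    def p_posterior(n, f, c):
        return _faces_on_z(n, f, spec.incus_length, tol_z) & _is_incus_face(n, f)

    def p_tip(n, f, c):
        return _faces_on_z(n, f, 0.0, tol_z) & _is_incus_face(n, f)

    def p_contact(n, f, c):
        return _faces_on_radius(n, f, ri_l, tol_r) & ~_is_incus_face(n, f)

    def p_load(n, f, c):
        return _faces_on_radius(n, f, ro_l, tol_r) & ~_is_incus_face(n, f)

    def p_shaft_tip(n, f, c):
        return _faces_on_radius(n, f, r_tip, tol_r) & ~_is_incus_face(n, f)

    surfaces = [
        ("target_incus_surface", p_target),
        ("fixed_posterior_incus", p_posterior),
        ("incus_tip", p_tip),
        ("contact_inner_loop", p_contact),
        ("loop_load_surface", p_load),
        ("fixed_shaft_tip", p_shaft_tip),
    ]
    mesh = _finish_mesh(nodes, wedges, region, order, surfaces, surf_masks,
                        dict(REGION_NAMES))
    mesh.spec = spec
    mesh.seed = seed
    required = ["contact_inner_loop", "target_incus_surface",
                "fixed_posterior_incus", "fixed_shaft_tip", "loop_load_surface"]
    for name in required:
        if mesh.patches[name].shape[0] == 0:
            raise MeshingError(f"patch '{name}' is empty for this parameter set: {spec}")
    vols = mesh.element_volumes()
    if (vols <= 0).any():
        raise MeshingError(f"{int((vols <= 0).sum())} inverted elements for spec {spec}")
    return mesh


def mesh_quality_report(mesh: AssemblyMesh) -> dict:
    """Per-region counts and shape-quality statistics.

    Quality is the mean-ratio measure q = 12 (3 V)^(2/3) / sum(edge^2),
    1 for the regular tetrahedron, -> 0 for slivers; the minimum corner-tet
    Jacobian (6V) is reported as ``min_jacobian``.
    """
    if mesh.n_elements == 0:
        raise MeshingError("empty mesh")
    x = mesh.nodes[mesh.elements[:, :4]]
    vols = mesh.element_volumes()
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    ssq = sum(((x[:, i] - x[:, j]) ** 2).sum(axis=1) for i, j in pairs)
    q = 12.0 * np.cbrt(3.0 * np.abs(vols)) ** 2 / ssq
    aspect = np.sqrt(
        max(((x[:, i] - x[:, j]) ** 2).sum(axis=1).max() for i, j in pairs)
    )
    per_region = {
        name: int((mesh.region_tags == rid).sum())
        for rid, name in mesh.region_names.items()
    }
    return {
        "n_nodes": mesh.n_nodes,
        "n_elements": mesh.n_elements,
        "order": mesh.order,
        "min_scaled_jacobian": float(6.0 * vols.min()),
        "min_jacobian": float(6.0 * vols.min()),
        "min_quality": float(q.min()),
        "median_quality": float(np.median(q)),
        "max_edge_mm": float(aspect),
        "elements_per_region": per_region,
        "total_volume_mm3": float(vols.sum()),
    }
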