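"""Small-strain isoparametric finite elements on tagged tetrahedral meshes.

Linear (4-node) and quadratic (10-node) tetrahedra, isotropic linear
elasticity, consistent surface tractions on boundary patches, direct sparse
solution, and nodal stress recovery by intra-region averaging.

Voigt convention: (xx, yy, zz, xy, yz, zx) with engineering shear strains.
Units mm-MPa-N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .analytical import Material
from .geometry import AssemblyMesh, TET10_EDGES

__all__ = ["FESystem", "UnderConstrainedError", "von_mises", "assemble_system"]

_CHUNK = 8192  # elements per assembly chunk (bounds peak memory)


class UnderConstrainedError(RuntimeError):
    """The constrained system still contains rigid-body modes."""


def von_mises(voigt: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress from Voigt tensors, shape (..., 6)."""
    s = np.asarray(voigt)
    xx, yy, zz, xy, yz, zx = (s[..., i] for i in range(6))
    return np.sqrt(
        0.5 * ((xx - yy) ** 2 + (yy - zz) ** 2 + (zz - xx) ** 2)
        + 3.0 * (xy**2 + yz**2 + zx**2)
    )


def _lame(mat: Material) -> tuple[float, float]:
    e, nu = mat.youngs_modulus_E, mat.poisson_nu
    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    return lam, mu


def _elastic_c(mat: Material) -> np.ndarray:
    lam, mu = _lame(mat)
    c = np.zeros((6, 6))
    c[:3, :3] = lam
    c[np.arange(3), np.arange(3)] += 2 * mu
    c[np.arange(3, 6), np.arange(3, 6)] = mu
    return c


# --- tet shape functions (barycentric L0 = 1-x-y-z, L1=x, L2=y, L3=z) -----

_DL = np.array([[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])

_GP4 = np.array(
    [
        [0.5854101966249685, 0.1381966011250105, 0.1381966011250105, 0.1381966011250105],
        [0.1381966011250105, 0.5854101966249685, 0.1381966011250105, 0.1381966011250105],
        [0.1381966011250105, 0.1381966011250105, 0.5854101966249685, 0.1381966011250105],
        [0.1381966011250105, 0.1381966011250105, 0.1381966011250105, 0.5854101966249685],
    ]
)  # barycentric coords of the 4-point, degree-2 rule
_GW4 = np.full(4, 1.0 / 24.0)  # weights including the 1/6 reference volume


def _keast11() -> tuple[np.ndarray, np.ndarray]:
    """Keast 11-point, degree-4 rule (barycentric points, weights sum 1/6).

    Exactness to degree 4 keeps the stiffness of curved (projected-midnode)
    quadratic tets consistent enough for the verification oracles.
    """
    pts = [np.full(4, 0.25)]
    wts = [-0.0131555555555556]
    a, b = 11.0 / 14.0, 1.0 / 14.0
    for i in range(4):
        p = np.full(4, b)
        p[i] = a
        pts.append(p)
        wts.append(0.0076222222222222)
    c, d = 0.3994035761667992, 0.1005964238332008
    for i in range(4):
        for j in range(i + 1, 4):
            p = np.full(4, d)
            p[i] = c
            p[j] = c
            pts.append(p)
            wts.append(0.0248888888888889)
    return np.array(pts), np.array(wts)


_GP11, _GW11 = _keast11()

#: barycentric coordinates of the 10 nodes of the quadratic tet
_TET10_BARY = np.zeros((10, 4))
_TET10_BARY[:4] = np.eye(4)
for _k, (_i, _j) in enumerate(TET10_EDGES):
    _TET10_BARY[4 + _k, _i] = 0.5
    _TET10_BARY[4 + _k, _j] = 0.5


def _shape_tet(order: int, bary: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape values and reference-coordinate gradients at barycentric points.

    Returns (N (npts, nn), dN (npts, nn, 3)).
    """
    L = np.asarray(bary)
    if order == 1:
        n = L.copy()
        dn = np.broadcast_to(_DL, (L.shape[0], 4, 3)).copy()
        return n, dn
    npts = L.shape[0]
    n = np.empty((npts, 10))
    dn = np.empty((npts, 10, 3))
    for a in range(4):
        n[:, a] = L[:, a] * (2 * L[:, a] - 1)
        dn[:, a, :] = (4 * L[:, a, None] - 1) * _DL[a]
    for k, (i, j) in enumerate(TET10_EDGES):
        n[:, 4 + k] = 4 * L[:, i] * L[:, j]
        dn[:, 4 + k, :] = 4 * (L[:, i, None] * _DL[j] + L[:, j, None] * _DL[i])
    return n, dn


def _inv3(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized inverse and determinant of (..., 3, 3) matrices."""
    det = (
        a[..., 0, 0] * (a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1])
        - a[..., 0, 1] * (a[..., 1, 0] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 0])
        + a[..., 0, 2] * (a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0])
    )
    inv = np.empty_like(a)
    inv[..., 0, 0] = a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1]
    inv[..., 0, 1] = a[..., 0, 2] * a[..., 2, 1] - a[..., 0, 1] * a[..., 2, 2]
    inv[..., 0, 2] = a[..., 0, 1] * a[..., 1, 2] - a[..., 0, 2] * a[..., 1, 1]
    inv[..., 1, 0] = a[..., 1, 2] * a[..., 2, 0] - a[..., 1, 0] * a[..., 2, 2]
    inv[..., 1, 1] = a[..., 0, 0] * a[..., 2, 2] - a[..., 0, 2] * a[..., 2, 0]
    inv[..., 1, 2] = a[..., 0, 2] * a[..., 1, 0] - a[..., 0, 0] * a[..., 1, 2]
    inv[..., 2, 0] = a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0]
    inv[..., 2, 1] = a[..., 0, 1] * a[..., 2, 0] - a[..., 0, 0] * a[..., 2, 1]
    inv[..., 2, 2] = a[..., 0, 0] * a[..., 1, 1] - a[..., 0, 1] * a[..., 1, 0]
    return inv / det[..., None, None], det


# --- surface quadrature on (possibly curved) 3/6-node triangles ------------

_TRI_GP = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]])
_TRI_GW = np.full(3, 1.0 / 6.0)  # weights including the 1/2 reference area
_DTRI = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # dL/d(u,v), L=(1-u-v,u,v)


def _shape_tri(nn: int, bary: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    L = np.asarray(bary)
    if nn == 3:
        return L.copy(), np.broadcast_to(_DTRI, (L.shape[0], 3, 2)).copy()
    n = np.empty((L.shape[0], 6))
    dn = np.empty((L.shape[0], 6, 2))
    edges = [(0, 1), (1, 2), (2, 0)]
    for a in range(3):
        n[:, a] = L[:, a] * (2 * L[:, a] - 1)
        dn[:, a, :] = (4 * L[:, a, None] - 1) * _DTRI[a]
    for k, (i, j) in enumerate(edges):
        n[:, 3 + k] = 4 * L[:, i] * L[:, j]
        dn[:, 3 + k, :] = 4 * (L[:, i, None] * _DTRI[j] + L[:, j, None] * _DTRI[i])
    return n, dn


def integrate_traction(nodes: np.ndarray, facets: np.ndarray, traction) -> np.ndarray:
    """Consistent nodal forces for a traction field on a facet set.

    ``traction`` is either a constant 3-vector or a callable
    ``t(points (m,3), outward_normals (m,3)) -> (m,3)`` evaluated at surface
    quadrature points.  Returns a dense (n_nodes, 3) force array.
    """
    nn = facets.shape[1]
    n_sh, dn_sh = _shape_tri(nn, _TRI_GP)
    x = nodes[facets]  # (nf, nn, 3)
    f = np.zeros_like(nodes)
    for g in range(_TRI_GP.shape[0]):
        pts = np.einsum("a,fai->fi", n_sh[g], x)
        xu = np.einsum("au,fai->fui", dn_sh[g], x)  # (nf, 2, 3)
        nvec = np.cross(xu[:, 0], xu[:, 1])
        jac = np.linalg.norm(nvec, axis=1)
        nrm = nvec / jac[:, None]
        if callable(traction):
            t = traction(pts, nrm)
        else:
            t = np.broadcast_to(np.asarray(traction, dtype=float), pts.shape)
        w = _TRI_GW[g] * jac
        contrib = np.einsum("a,f,fi->fai", n_sh[g], w, t)
        np.add.at(f, facets, contrib)
    return f


def patch_area(nodes: np.ndarray, facets: np.ndarray) -> float:
    """Area of a facet set, including quadratic curvature."""
    nn = facets.shape[1]
    _, dn_sh = _shape_tri(nn, _TRI_GP)
    x = nodes[facets]
    area = 0.0
    for g in range(_TRI_GP.shape[0]):
        xu = np.einsum("au,fai->fui", dn_sh[g], x)
        area += _TRI_GW[g] * np.linalg.norm(np.cross(xu[:, 0], xu[:, 1]), axis=1).sum()
    return float(area)


def lumped_patch_areas(nodes: np.ndarray, facets: np.ndarray) -> np.ndarray:
    """Positive nodal (tributary) areas for a facet set.

    Linear facets: A/3 per corner.  Quadratic facets: A/12 per corner and
    A/4 per midside node (a positive lumping; the consistent rule puts zero
    weight on corners, which is unusable for contact scaling).
    """
    nn = facets.shape[1]
    _, dn_sh = _shape_tri(nn, _TRI_GP)
    x = nodes[facets]
    areas = np.zeros(facets.shape[0])
    for g in range(_TRI_GP.shape[0]):
        xu = np.einsum("au,fai->fui", dn_sh[g], x)
        areas += _TRI_GW[g] * np.linalg.norm(np.cross(xu[:, 0], xu[:, 1]), axis=1)
    if nn == 3:
        wts = np.full(3, 1.0 / 3.0)
    else:
        wts = np.array([1 / 12, 1 / 12, 1 / 12, 1 / 4, 1 / 4, 1 / 4])
    out = np.zeros(nodes.shape[0])
    np.add.at(out, facets, areas[:, None] * wts[None, :])
    return out


# ---------------------------------------------------------------------------


@dataclass
class FESystem:
    """Assembled linear-elastic system on a tagged mesh.

    Materials are given per region name; the stiffness is assembled once at
    construction.  Loads and single-point constraints accumulate; ``solve``
    eliminates fixed dofs and returns nodal displacements.
    """

    mesh: AssemblyMesh
    materials: dict[str, Material]
    K: sp.csr_matrix = field(init=False, repr=False)
    f: np.ndarray = field(init=False, repr=False)
    fixed: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        mesh = self.mesh
        for rid, name in mesh.region_names.items():
            if (mesh.region_tags == rid).any() and name not in self.materials:
                raise KeyError(f"no material assigned to region '{name}'")
        self.K = self._assemble()
        self.f = np.zeros(3 * mesh.n_nodes)
        self.fixed = np.zeros(3 * mesh.n_nodes, dtype=bool)

    # -- assembly ----------------------------------------------------------
    def _assemble(self) -> sp.csr_matrix:
        mesh = self.mesh
        nn = mesh.elements.shape[1]
        order = mesh.order
        if order == 1:
            bary = np.array([[0.25, 0.25, 0.25, 0.25]])
            wts = np.array([1.0 / 6.0])
        else:
            bary, wts = _GP11, _GW11
        _, dn = _shape_tet(order, bary)
        ndof = 3 * mesh.n_nodes
        blocks = []
        for rid, name in mesh.region_names.items():
            emask = mesh.region_tags == rid
            if not emask.any():
                continue
            lam, mu = _lame(self.materials[name])
            elems = mesh.elements[emask]
            for lo in range(0, elems.shape[0], _CHUNK):
                e = elems[lo:lo + _CHUNK]
                x = mesh.nodes[e]  # (ne, nn, 3)
                ke = np.zeros((e.shape[0], nn, 3, nn, 3))
                for g in range(bary.shape[0]):
                    dng = dn[g]
                    # J_ij = dx_i/dxi_j; dN/dx_i = dN/dxi_j * (J^-1)_ji
                    jac = np.einsum("eai,aj->eij", x, dng)
                    inv, det = _inv3(jac)
                    if (det <= 0).any():
                        raise RuntimeError("non-positive Jacobian during assembly")
                    dndx = np.einsum("aj,eji->eai", dng, inv)
                    w = wts[g] * det
                    gram = np.einsum("eak,ebk->eab", dndx, dndx)
                    ke += lam * np.einsum("e,eai,ebj->eaibj", w, dndx, dndx)
                    ke += mu * np.einsum("e,eaj,ebi->eaibj", w, dndx, dndx)
                    ke += mu * np.einsum("e,eab,ij->eaibj", w, gram, np.eye(3))
                dof = (3 * e[:, :, None] + np.arange(3)[None, None, :]).reshape(
                    e.shape[0], 3 * nn
                )
                rows = np.repeat(dof, 3 * nn, axis=1).ravel()
                cols = np.tile(dof, (1, 3 * nn)).ravel()
                blocks.append(
                    sp.coo_matrix(
                        (ke.reshape(e.shape[0], 3 * nn, 3 * nn).ravel(), (rows, cols)),
                        shape=(ndof, ndof),
                    ).tocsr()
                )
        K = blocks[0]
        for b in blocks[1:]:
            K = K + b
        return K

    # -- loads and constraints ---------------------------------------------
    def add_traction(self, patch, traction) -> np.ndarray:
        """Apply a traction (constant vector or callable) on a patch.

        ``patch`` is a patch name or an explicit facet array.
        """
        facets = self.mesh.patches[patch] if isinstance(patch, str) else patch
        fn = integrate_traction(self.mesh.nodes, facets, traction)
        self.f += fn.ravel()
        return fn

    def add_pressure(self, patch: str, p: float) -> np.ndarray:
        """Compressive pressure p (MPa) acting against the outward normal."""
        return self.add_traction(patch, lambda pts, nrm: -p * nrm)

    def add_radial_traction(self, patch, magnitude: float,
                            inward: bool = True) -> np.ndarray:
        """Traction of given magnitude along +-r_hat (about the z axis)."""
        sign = -1.0 if inward else 1.0

        def t(pts, nrm):
            rhat = pts.copy()
            rhat[:, 2] = 0.0
            rhat /= np.linalg.norm(rhat[:, :2], axis=1)[:, None]
            return sign * magnitude * rhat

        return self.add_traction(patch, t)

    def add_nodal_forces(self, forces: np.ndarray) -> None:
        self.f += forces.ravel()

    def fix_patch(self, patch: str, components: str = "xyz") -> None:
        ids = self.mesh.patch_node_ids(patch)
        for c, k in (("x", 0), ("y", 1), ("z", 2)):
            if c in components:
                self.fixed[3 * ids + k] = True

    def fix_nodes(self, node_ids: np.ndarray, components: str = "xyz") -> None:
        for c, k in (("x", 0), ("y", 1), ("z", 2)):
            if c in components:
                self.fixed[3 * np.asarray(node_ids) + k] = True

    # -- solution ----------------------------------------------------------
    def solve(self, K_extra: sp.spmatrix | None = None,
              f_extra: np.ndarray | None = None) -> np.ndarray:
        """Solve (K + K_extra) u = f + f_extra with fixed dofs eliminated."""
        K = self.K if K_extra is None else (self.K + K_extra).tocsr()
        f = self.f if f_extra is None else self.f + f_extra
        free = ~self.fixed
        Kff = K[free][:, free].tocsc()
        try:
            lu = spla.splu(Kff)
        except RuntimeError as exc:  # pragma: no cover - singular factorization
            raise UnderConstrainedError(
                "stiffness factorization failed; model is under-constrained"
            ) from exc
        uf = lu.solve(f[free])
        # SuperLU can "factorize" a singular matrix without complaint; a
        # residual check catches rigid-body modes reliably
        fnorm = np.linalg.norm(f[free])
        resid = np.linalg.norm(Kff @ uf - f[free])
        if not np.isfinite(uf).all() or (fnorm > 0 and resid > 1e-6 * fnorm):
            raise UnderConstrainedError(
                "solution residual too large; model is under-constrained "
                f"(|Ku-f|/|f| = {resid / max(fnorm, 1e-300):.2e})")
        u = np.zeros(3 * self.mesh.n_nodes)
        u[free] = uf
        return u.reshape(-1, 3)

    def reactions(self, u: np.ndarray,
                  K_extra: sp.spmatrix | None = None,
                  f_extra: np.ndarray | None = None) -> np.ndarray:
        """Reaction forces (n_nodes, 3): (K u - f) at fixed dofs, 0 elsewhere."""
        K = self.K if K_extra is None else (self.K + K_extra).tocsr()
        f = self.f if f_extra is None else self.f + f_extra
        r = K @ u.ravel() - f
        r[~self.fixed] = 0.0
        return r.reshape(-1, 3)

    # -- stress recovery ----------------------------------------------------
    def nodal_stress(self, u: np.ndarray) -> dict[str, np.ndarray]:
        """Region-wise averaged nodal stress tensors (Voigt, MPa).

        Averaging never crosses a material interface: each region gets its
        own (n_nodes, 6) array, NaN away from the region's nodes.
        """
        mesh = self.mesh
        nn = mesh.elements.shape[1]
        order = mesh.order
        bary = _TET10_BARY if order == 2 else np.eye(4)
        _, dn = _shape_tet(order, bary)
        out: dict[str, np.ndarray] = {}
        for rid, name in mesh.region_names.items():
            emask = mesh.region_tags == rid
            if not emask.any():
                continue
            cmat = _elastic_c(self.materials[name])
            elems = mesh.elements[emask]
            acc = np.zeros((mesh.n_nodes, 6))
            cnt = np.zeros(mesh.n_nodes)
            for lo in range(0, elems.shape[0], _CHUNK):
                e = elems[lo:lo + _CHUNK]
                x = mesh.nodes[e]
                ue = u[e]  # (ne, nn, 3)
                sig_nodes = np.empty((e.shape[0], nn, 6))
                for a in range(nn):
                    jac = np.einsum("ebi,bj->eij", x, dn[a])
                    inv, _ = _inv3(jac)
                    dndx = np.einsum("bj,eji->ebi", dn[a], inv)
                    grad = np.einsum("ebi,ebk->eik", dndx, ue)  # du_k/dx_i
                    eps = np.empty((e.shape[0], 6))
                    eps[:, 0] = grad[:, 0, 0]
                    eps[:, 1] = grad[:, 1, 1]
                    eps[:, 2] = grad[:, 2, 2]
                    eps[:, 3] = grad[:, 0, 1] + grad[:, 1, 0]
                    eps[:, 4] = grad[:, 1, 2] + grad[:, 2, 1]
                    eps[:, 5] = grad[:, 2, 0] + grad[:, 0, 2]
                    sig_nodes[:, a] = eps @ cmat.T
                np.add.at(acc, e, sig_nodes)
                np.add.at(cnt, e, 1.0)
            with np.errstate(invalid="ignore"):
                avg = acc / cnt[:, None]
            avg[cnt == 0] = np.nan
            out[name] = avg
        return out


    def centroid_stress(self, u: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-element centroid stress, region -> (centroids (ne,3), stress (ne,6)).

        Interior sampling points carry less extrapolation error than nodal
        recovery and are the preferred comparison points for verification
        against closed-form fields.
        """
        mesh = self.mesh
        order = mesh.order
        bary = np.array([[0.25, 0.25, 0.25, 0.25]])
        n_sh, dn = _shape_tet(order, bary)
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for rid, name in mesh.region_names.items():
            emask = mesh.region_tags == rid
            if not emask.any():
                continue
            cmat = _elastic_c(self.materials[name])
            elems = mesh.elements[emask]
            x = mesh.nodes[elems]
            ue = u[elems]
            jac = np.einsum("ebi,bj->eij", x, dn[0])
            inv, _ = _inv3(jac)
            dndx = np.einsum("bj,eji->ebi", dn[0], inv)
            grad = np.einsum("ebi,ebk->eik", dndx, ue)
            eps = np.empty((elems.shape[0], 6))
            eps[:, 0] = grad[:, 0, 0]
            eps[:, 1] = grad[:, 1, 1]
            eps[:, 2] = grad[:, 2, 2]
            eps[:, 3] = grad[:, 0, 1] + grad[:, 1, 0]
            eps[:, 4] = grad[:, 1, 2] + grad[:, 2, 1]
            eps[:, 5] = grad[:, 2, 0] + grad[:, 0, 2]
            cent = np.einsum("a,eai->ei", n_sh[0], x)
            out[name] = (cent, eps @ cmat.T)
        return out


def assemble_system(mesh: AssemblyMesh, materials: dict[str, Material]) -> FESystem:
    """Build the assembled stiffness/load interface for a tagged mesh."""
    return FESystem(mesh, materials)
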