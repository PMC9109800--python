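"""Idealized septal wedge meshes and rule-based fiber fields.

The wedge is a structured box (x = circumferential, y = transmural with the
LV face at y=0 and the RV face at y=Ly, z = apicobasal) whose cells are each
split into five tetrahedra with alternating parity so that neighboring cubes
share conforming faces. Fiber/sheet/normal triads are per-element.

Rule-based fibers rotate the circumferential direction about the transmural
axis by a helix angle interpolated linearly in the transmural coordinate,
then rotate the sheet direction about the fiber axis by the interpolated
sheet angle. The RV-side layer scenarios overwrite the fiber direction in
the outermost transmural fraction with a single helix angle, emulating the
abrupt apicobasal layer seen on the RV side of the septum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

__all__ = [
    "TetMesh",
    "FiberField",
    "LayerScenario",
    "build_wedge_mesh",
    "rule_based_fibers",
    "apply_rv_layer",
    "idw_map_angles",
    "carve_uvc_region",
    "analytic_slab_uvc",
    "laplace_transmural",
    "UVC_LAYER_PRESETS",
    "write_vtk_mesh",
]

# tetrahedra per cube, by parity; corner bit order (ix, iy, iz) -> ix*4+iy*2+iz
# gives corners 0..7 with 0=(0,0,0), 1=(0,0,1), 2=(0,1,0), ... 7=(1,1,1).
_CORNER_OFFSETS = np.array(
    [[0, 0, 0], [0, 0, 1], [0, 1, 0], [0, 1, 1], [1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]]
)
# five-tet split: a central tetrahedron on the odd-bit corners plus four
# corner tets; the odd-parity cube uses the mirrored split (central tet on
# the even-bit corners) so that shared faces carry the same diagonal.
_TETS_EVEN = np.array([[0, 1, 2, 4], [3, 1, 2, 7], [5, 1, 4, 7], [6, 2, 4, 7], [1, 2, 4, 7]])
_TETS_ODD = np.array([[1, 0, 3, 5], [2, 0, 3, 6], [4, 0, 5, 6], [7, 3, 5, 6], [0, 3, 5, 6]])


@dataclass
class TetMesh:
    """Tetrahedral mesh with optional structured-lattice metadata."""

    points: np.ndarray  # (n, 3) mm
    tets: np.ndarray  # (m, 4) int
    lattice_shape: tuple | None = None  # node counts per axis for structured meshes
    spacing: np.ndarray | None = None  # (3,) mm for structured meshes
    surface_tags: dict = field(default_factory=dict)  # name -> node index array

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        used = np.zeros(len(self.points), dtype=bool)
        used[self.tets.ravel()] = True
        if not used.all():
            raise ValueError("mesh has unreferenced nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def element_volumes(self) -> np.ndarray:
        p = self.points[self.tets]
        e = p[:, 1:] - p[:, :1]
        return np.linalg.det(e) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.points[self.tets].mean(axis=1)

    def edges(self) -> np.ndarray:
        """Unique undirected node pairs appearing in any tetrahedron."""
        pairs = []
        for a in range(4):
            for b in range(a + 1, 4):
                pairs.append(self.tets[:, [a, b]])
        e = np.vstack(pairs)
        e.sort(axis=1)
        return np.unique(e, axis=0)


@dataclass
class FiberField:
    """Per-element orthonormal fiber (f), sheet (s), sheet-normal (n) triads."""

    f: np.ndarray  # (m, 3)
    s: np.ndarray
    n: np.ndarray

    def check(self, tol: float = 1e-8) -> None:
        for name, a in (("f", self.f), ("s", self.s), ("n", self.n)):
            if np.abs(np.linalg.norm(a, axis=1) - 1.0).max() > tol:
                raise ValueError(f"{name} not unit norm")
        if np.abs(np.einsum("ij,ij->i", self.f, self.s)).max() > tol:
            raise ValueError("f and s not orthogonal")
        if np.abs(np.einsum("ij,ij->i", self.f, self.n)).max() > tol:
            raise ValueError("f and n not orthogonal")
        handed = np.einsum("ij,ij->i", np.cross(self.f, self.s), self.n)
        if (handed < 1.0 - tol).any():
            raise ValueError("triads are not right-handed")


@dataclass
class LayerScenario:
    """One cell of the layer-study grid: depth fraction and layer angle."""

    depth_fraction: float
    layer_angle_deg: float

    def __post_init__(self) -> None:
        if not 0.0 < self.depth_fraction <= 0.5:
            raise ValueError("depth_fraction must be in (0, 0.5]")


def scenario_grid(
    depths=(0.05, 0.10, 0.15, 0.20),
    angles=(-90.0, -60.0, -45.0, 0.0, 45.0),
) -> list[LayerScenario]:
    return [LayerScenario(d, a) for d in depths for a in angles]


def build_wedge_mesh(dimensions=(21.0, 18.0, 35.0), spacing=0.3) -> TetMesh:
    """Structured wedge of five-tet cubes with alternating parity.

    Cell counts round the dimension/spacing ratio to the nearest integer.
    At the reference septal dimensions (21 x 18 x 35 mm) and 0.3 mm spacing
    this yields ~0.5 M nodes and ~2.5 M tetrahedra.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    dims = np.asarray(dimensions, dtype=float)
    ncells = np.maximum(np.round(dims / spacing).astype(int), 1)
    nx, ny, nz = ncells
    h = dims / ncells  # actual spacing after rounding

    gx = np.arange(nx + 1) * h[0]
    gy = np.arange(ny + 1) * h[1]
    gz = np.arange(nz + 1) * h[2]
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
    points = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    def node_id(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    corners = np.stack(
        [node_id(I + o[0], J + o[1], K + o[2]) for o in _CORNER_OFFSETS], axis=1
    )  # (ncubes, 8)
    parity = (I + J + K) % 2

    tets = np.empty((corners.shape[0], 5, 4), dtype=np.int64)
    even = parity == 0
    tets[even] = corners[even][:, _TETS_EVEN]
    tets[~even] = corners[~even][:, _TETS_ODD]
    tets = tets.reshape(-1, 4)

    mesh = TetMesh(
        points=points,
        tets=tets,
        lattice_shape=(nx + 1, ny + 1, nz + 1),
        spacing=h,
    )
    # fix any negatively oriented tets by swapping two nodes
    vol = mesh.element_volumes()
    flip = vol < 0
    mesh.tets[flip] = mesh.tets[flip][:, [0, 1, 3, 2]]

    node_idx = np.arange(mesh.n_nodes).reshape(nx + 1, ny + 1, nz + 1)
    mesh.surface_tags = {
        "lv_endo": node_idx[:, 0, :].ravel(),  # y = 0
        "rv_endo": node_idx[:, -1, :].ravel(),  # y = Ly
        "apex": node_idx[:, :, 0].ravel(),
        "base": node_idx[:, :, -1].ravel(),
        "x0": node_idx[0, :, :].ravel(),
        "x1": node_idx[-1, :, :].ravel(),
    }
    return mesh


def analytic_slab_uvc(mesh: TetMesh) -> np.ndarray:
    """Per-node UVC (rho, z, phi) of a structured slab, computed analytically.

    rho = transmural (0 on the LV face, 1 on the RV face), z = apicobasal,
    phi = circumferential, each normalized to [0, 1] by the slab extent.
    """
    if mesh.lattice_shape is None:
        raise ValueError("analytic UVC requires a structured slab mesh")
    p = mesh.points
    lo, hi = p.min(axis=0), p.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    norm = (p - lo) / span
    return np.stack([norm[:, 1], norm[:, 2], norm[:, 0]], axis=1)  # (rho, z, phi)


def _element_gradients(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients (m, 4, 3) and element volumes (m,)."""
    p = mesh.points[mesh.tets]
    E = p[:, 1:] - p[:, :1]  # (m, 3, 3) rows = edge vectors
    vol = np.linalg.det(E) / 6.0
    invE = np.linalg.inv(E)
    grads = np.empty((len(mesh.tets), 4, 3))
    grads[:, 1:, :] = np.swapaxes(invE, 1, 2)  # grad of node i+1 = row i of invE^T
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    return grads, vol


def assemble_stiffness(mesh: TetMesh, sigma: np.ndarray) -> sp.csr_matrix:
    """P1 FEM stiffness matrix for a per-element conductivity tensor.

    ``sigma`` may be (3, 3) (uniform) or (m, 3, 3). Entries are
    ``K_ab = V_e grad(phi_a) . sigma grad(phi_b)`` summed over elements.
    """
    grads, vol = _element_gradients(mesh)
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim == 2:
        sigma = np.broadcast_to(sigma, (len(mesh.tets), 3, 3))
    flux = np.einsum("mij,maj->mai", sigma, grads)  # sigma grad(phi_a)
    ke = np.einsum("mai,mbi,m->mab", grads, flux, np.abs(vol))
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    K = sp.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    return K.tocsr()


def lumped_mass(mesh: TetMesh) -> np.ndarray:
    """Row-sum lumped mass: a quarter of each element volume per node."""
    vol = np.abs(mesh.element_volumes())
    m = np.zeros(mesh.n_nodes)
    np.add.at(m, mesh.tets.ravel(), np.repeat(vol / 4.0, 4))
    return m


def laplace_transmural(
    mesh: TetMesh, endo_tag: str = "lv_endo", epi_tag: str = "rv_endo"
) -> np.ndarray:
    """Transmural coordinate by a Laplace solve with Dirichlet 0/1 walls.

    On a rectangular slab the P1 solution is the exact linear ramp (the
    linear function lies in the finite-element space), so this agrees with
    the analytic coordinate to solver tolerance; on general geometries it is
    the standard Laplace-Dirichlet transmural coordinate.
    """
    for tag in (endo_tag, epi_tag):
        if tag not in mesh.surface_tags:
            raise ValueError(f"mesh lacks surface tag '{tag}'")
    K = assemble_stiffness(mesh, np.eye(3))
    n = mesh.n_nodes
    rho = np.zeros(n)
    fixed = np.zeros(n, dtype=bool)
    fixed[mesh.surface_tags[endo_tag]] = True
    fixed[mesh.surface_tags[epi_tag]] = True
    rho[mesh.surface_tags[epi_tag]] = 1.0

    free = ~fixed
    Kff = K[free][:, free]
    rhs = -K[free][:, fixed] @ rho[fixed]
    sol, info = spla.cg(Kff, rhs, rtol=1e-10, maxiter=5000)
    if info != 0:
        sol = spla.spsolve(Kff.tocsc(), rhs)
    rho[free] = sol
    return rho


def slab_element_frames(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Constant slab frames (c, t, l) = (x, y, z) per element."""
    m = mesh.n_tets
    c = np.tile([1.0, 0.0, 0.0], (m, 1))
    t = np.tile([0.0, 1.0, 0.0], (m, 1))
    l = np.tile([0.0, 0.0, 1.0], (m, 1))
    return c, t, l


def _orthonormalize(f, s):
    f = f / np.linalg.norm(f, axis=1, keepdims=True)
    s = s - np.einsum("ij,ij->i", s, f)[:, None] * f
    s = s / np.linalg.norm(s, axis=1, keepdims=True)
    n = np.cross(f, s)
    return f, s, n


def rule_based_fibers(
    mesh: TetMesh,
    rho_elem: np.ndarray,
    alpha_endo: float = 60.0,
    alpha_epi: float = -60.0,
    beta_endo: float = -65.0,
    beta_epi: float = 25.0,
    frames=None,
) -> FiberField:
    """Linear-in-depth rule-based fiber construction.

    The fiber helix angle interpolates ``alpha_endo -> alpha_epi`` with the
    transmural coordinate and rotates the circumferential axis toward the
    longitudinal axis within the wall-tangent plane. The sheet direction
    starts transmural and is rotated about the fiber axis by the
    interpolated sheet angle ``beta``; the triad is orthonormalized.
    """
    if frames is None:
        frames = slab_element_frames(mesh)
    c, t, l = frames
    rho = np.asarray(rho_elem, dtype=float)
    alpha = np.deg2rad(alpha_endo * (1.0 - rho) + alpha_epi * rho)
    beta = np.deg2rad(beta_endo * (1.0 - rho) + beta_epi * rho)

    f = np.cos(alpha)[:, None] * c + np.sin(alpha)[:, None] * l
    # rotate the transmural direction about f by beta (t is orthogonal to f)
    s = np.cos(beta)[:, None] * t + np.sin(beta)[:, None] * np.cross(f, t)
    f, s, n = _orthonormalize(f, s)
    return FiberField(f=f, s=s, n=n)


def apply_rv_layer(
    fibers: FiberField,
    rho_elem: np.ndarray,
    scenario: LayerScenario,
    frames=None,
    mesh: TetMesh | None = None,
) -> FiberField:
    """Overwrite the outermost transmural fraction with an abrupt layer.

    Elements whose centroid transmural coordinate exceeds
    ``1 - depth_fraction`` (i.e. nearest the RV endocardium at rho=1) get a
    fiber at the scenario helix angle; sheet and normal are rebuilt so the
    triad stays orthonormal. Elements outside the layer are untouched.
    """
    if frames is None:
        if mesh is None:
            raise ValueError("need frames or a slab mesh to derive them")
        frames = slab_element_frames(mesh)
    c, t, l = frames
    rho = np.asarray(rho_elem, dtype=float)
    sel = rho > 1.0 - scenario.depth_fraction

    f = fibers.f.copy()
    s = fibers.s.copy()
    a = np.deg2rad(scenario.layer_angle_deg)
    f[sel] = np.cos(a) * c[sel] + np.sin(a) * l[sel]
    s[sel] = t[sel]
    f, s, n = _orthonormalize(f, s)
    return FiberField(f=f, s=s, n=n)


def idw_map_angles(
    sample_points: np.ndarray,
    sample_values: np.ndarray,
    query_points: np.ndarray,
    power: float = 2.0,
) -> np.ndarray:
    """Shepard inverse-distance-weighted interpolation (exact at samples)."""
    xs = np.atleast_2d(np.asarray(sample_points, dtype=float))
    vs = np.asarray(sample_values, dtype=float).ravel()
    if len(xs) != len(vs) or len(xs) == 0:
        raise ValueError("need matching, nonempty samples")
    q = np.atleast_2d(np.asarray(query_points, dtype=float))

    out = np.empty(len(q))
    chunk = 65536
    tree = cKDTree(xs)
    d_near, i_near = tree.query(q)
    coincident = d_near < 1e-12
    out[coincident] = vs[i_near[coincident]]
    todo = np.flatnonzero(~coincident)
    for start in range(0, todo.size, chunk):
        rows = todo[start : start + chunk]
        d = np.linalg.norm(q[rows, None, :] - xs[None, :, :], axis=-1)
        w = d ** (-power)
        out[rows] = (w @ vs) / w.sum(axis=1)
    return out


UVC_LAYER_PRESETS = {
    "layer40": {"rho_min": 0.6, "z_range": (0.35, 0.95), "phi_range": (0.3, 0.7)},
    "layer30": {"rho_min": 0.7, "z_range": (0.35, 0.95), "phi_range": (0.3, 0.7)},
    "layer20": {"rho_min": 0.8, "z_range": (0.35, 0.95), "phi_range": (0.3, 0.7)},
}


def carve_uvc_region(
    mesh: TetMesh,
    uvc: np.ndarray,
    rho_min: float,
    z_range=(0.0, 1.0),
    phi_range=(0.0, 1.0),
) -> np.ndarray:
    """Boolean element selection by centroid UVC ranges.

    ``uvc`` is the per-node (rho, z, phi) array; an element is selected when
    its centroid coordinate satisfies rho > rho_min and lies inside both the
    apicobasal and circumferential ranges. The named presets reproduce the
    layer40/layer30/layer20 carvings (rho > 0.6 / 0.7 / 0.8).
    """
    uvc = np.asarray(uvc, dtype=float)
    cent = uvc[mesh.tets].mean(axis=1)
    sel = (
        (cent[:, 0] > rho_min)
        & (cent[:, 1] > z_range[0])
        & (cent[:, 1] < z_range[1])
        & (cent[:, 2] > phi_range[0])
        & (cent[:, 2] < phi_range[1])
    )
    if not sel.any():
        import warnings

        warnings.warn("UVC carve selected no elements", stacklevel=2)
    return sel


def write_vtk_mesh(mesh: TetMesh, path, cell_data=None, point_data=None) -> None:
    """Minimal legacy-VTK (ASCII) unstructured-grid writer.

    Supports scalar and 3-vector arrays per cell or per point; sufficient to
    inspect meshes, fiber triads, tags and activation maps in ParaView.
    """
    cell_data = cell_data or {}
    point_data = point_data or {}
    with open(Path(path), "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nseptumkit mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        np.savetxt(fh, mesh.points, fmt="%.6g")
        fh.write(f"CELLS {mesh.n_tets} {mesh.n_tets * 5}\n")
        cells = np.hstack([np.full((mesh.n_tets, 1), 4), mesh.tets])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_tets}\n")
        fh.write("\n".join(["10"] * mesh.n_tets) + "\n")

        def dump(block, arrays, count):
            fh.write(f"{block} {count}\n")
            for name, arr in arrays.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.6g")
                else:
                    fh.write(f"VECTORS {name} float\n")
                    np.savetxt(fh, arr, fmt="%.6g")

        if cell_data:
            dump("CELL_DATA", cell_data, mesh.n_tets)
        if point_data:
            dump("POINT_DATA", point_data, mesh.n_nodes)
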