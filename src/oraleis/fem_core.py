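"""Complex-valued quasi-static harmonic FEM on graded structured hex grids.

The electrical problem solved here is the charge-conservation equation
``div(sigma* grad phi) = 0`` with complex admittivity
``sigma* = sigma + j*omega*eps`` (time convention e^{+j omega t}), discretised
with trilinear 8-node hexahedra on tensor-product grids.  The discrete system
is ``(K_sigma + j*omega*K_eps) phi = I`` where the two global matrices hold
the conductive and capacitive parts and ``I`` collects nodal currents.

Boundary conditions supported: fixed complex potentials on named node sets,
equipotential (coupled) sets with a prescribed total injected current
(zero for floating sense electrodes), and the natural zero-normal-current
condition everywhere else.  Coupling is implemented by merging degrees of
freedom onto a master node per set.  Reaction currents on constrained sets
are recovered from the residual of the unconstrained equations.

Magnetic induction is neglected throughout; materials are linear and
time-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import AnisotropicMaterial, DispersiveMaterial

__all__ = [
    "HexMesh",
    "HarmonicSystem",
    "BoundaryConditions",
    "PotentialSolution",
    "build_graded_grid",
    "graded_axis",
    "geometric_axis",
    "assemble",
    "solve",
    "reaction_current",
    "analytic_series_layers",
    "export_vtk",
]


# --------------------------------------------------------------------------
# Element matrices
# --------------------------------------------------------------------------

def _unit_matrices():
    """8x8 direction-split stiffness blocks of a trilinear unit-cube hex.

    For a brick with edges (a, b, c) and diagonal admittivity
    (sx, sy, sz), the element matrix is
    ``sx*(b*c/a)*UX + sy*(a*c/b)*UY + sz*(a*b/c)*UZ``.
    Local node l = ix + 2*iy + 4*iz.
    """
    k1 = np.array([[1.0, -1.0], [-1.0, 1.0]])
    m1 = np.array([[1.0 / 3.0, 1.0 / 6.0], [1.0 / 6.0, 1.0 / 3.0]])
    UX = np.zeros((8, 8))
    UY = np.zeros((8, 8))
    UZ = np.zeros((8, 8))
    for l in range(8):
        ix, iy, iz = l & 1, (l >> 1) & 1, (l >> 2) & 1
        for m in range(8):
            jx, jy, jz = m & 1, (m >> 1) & 1, (m >> 2) & 1
            UX[l, m] = k1[ix, jx] * m1[iy, jy] * m1[iz, jz]
            UY[l, m] = m1[ix, jx] * k1[iy, jy] * m1[iz, jz]
            UZ[l, m] = m1[ix, jx] * m1[iy, jy] * k1[iz, jz]
    return UX, UY, UZ


_UX, _UY, _UZ = _unit_matrices()


def element_conductance_matrix(a: float, b: float, c: float,
                               sx: complex, sy: complex, sz: complex):
    """Exact 8x8 trilinear hex element matrix for a brick (a, b, c) with
    diagonal admittivity tensor diag(sx, sy, sz)."""
    return (sx * (b * c / a) * _UX
            + sy * (a * c / b) * _UY
            + sz * (a * b / c) * _UZ)


# --------------------------------------------------------------------------
# Mesh
# --------------------------------------------------------------------------

class HexMesh:
    """Tensor-product hexahedral grid with element region labels and named
    node sets.

    Node id = i + nx*(j + ny*k); element id likewise over (nx-1, ny-1, nz-1).
    Grid planes must conform to every material interface: a region label is
    constant within each element.
    """

    def __init__(self, xs, ys, zs):
        self.xs = np.asarray(xs, dtype=float)
        self.ys = np.asarray(ys, dtype=float)
        self.zs = np.asarray(zs, dtype=float)
        for name, axis in (("x", self.xs), ("y", self.ys), ("z", self.zs)):
            if axis.ndim != 1 or axis.size < 2:
                raise ValueError(f"axis {name}: need >= 2 planes")
            if np.any(np.diff(axis) <= 0):
                raise ValueError(f"axis {name}: planes must strictly increase "
                                 "(degenerate element)")
        self.region_names: list[str] = ["domain"]
        self.region = np.zeros(self.n_elements, dtype=np.int32)
        self.node_sets: dict[str, np.ndarray] = {}
        self._geom_cache = None

    # -- sizes ------------------------------------------------------------
    @property
    def shape(self):
        return self.xs.size, self.ys.size, self.zs.size

    @property
    def n_nodes(self):
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def n_elements(self):
        nx, ny, nz = self.shape
        return (nx - 1) * (ny - 1) * (nz - 1)

    # -- coordinates ------------------------------------------------------
    def node_coords(self):
        """(X, Y, Z) arrays of node coordinates, each length n_nodes."""
        nx, ny, nz = self.shape
        X = np.tile(self.xs, ny * nz)
        Y = np.tile(np.repeat(self.ys, nx), nz)
        Z = np.repeat(self.zs, nx * ny)
        return X, Y, Z

    def element_centroids(self):
        cx = 0.5 * (self.xs[:-1] + self.xs[1:])
        cy = 0.5 * (self.ys[:-1] + self.ys[1:])
        cz = 0.5 * (self.zs[:-1] + self.zs[1:])
        ex, ey, ez = cx.size, cy.size, cz.size
        X = np.tile(cx, ey * ez)
        Y = np.tile(np.repeat(cy, ex), ez)
        Z = np.repeat(cz, ex * ey)
        return X, Y, Z

    def element_sizes(self):
        dx = np.diff(self.xs)
        dy = np.diff(self.ys)
        dz = np.diff(self.zs)
        ex, ey, ez = dx.size, dy.size, dz.size
        A = np.tile(dx, ey * ez)
        B = np.tile(np.repeat(dy, ex), ez)
        C = np.repeat(dz, ex * ey)
        return A, B, C

    def connectivity(self):
        """(n_elements, 8) node ids, local ordering ix + 2*iy + 4*iz."""
        nx, ny, nz = self.shape
        i = np.arange(nx - 1)
        j = np.arange(ny - 1)
        k = np.arange(nz - 1)
        I = np.tile(i, (ny - 1) * (nz - 1))
        J = np.tile(np.repeat(j, nx - 1), nz - 1)
        K = np.repeat(k, (nx - 1) * (ny - 1))
        base = I + nx * (J + ny * K)
        offsets = np.array([0, 1, nx, nx + 1,
                            nx * ny, nx * ny + 1, nx * ny + nx, nx * ny + nx + 1])
        return base[:, None] + offsets[None, :]

    # -- labelling --------------------------------------------------------
    def label_regions(self, labeller, names):
        """Assign element regions: ``labeller(cx, cy, cz)`` returns an int
        array indexing into ``names`` (evaluated at element centroids)."""
        cx, cy, cz = self.element_centroids()
        idx = np.asarray(labeller(cx, cy, cz), dtype=np.int32)
        if idx.shape != (self.n_elements,):
            raise ValueError("labeller must return one region per element")
        if idx.min() < 0 or idx.max() >= len(names):
            raise ValueError("region index out of range")
        self.region = idx
        self.region_names = list(names)
        return self

    def define_node_set(self, name, mask_fn):
        """Create a named node set from ``mask_fn(X, Y, Z) -> bool array``."""
        X, Y, Z = self.node_coords()
        mask = np.asarray(mask_fn(X, Y, Z), dtype=bool)
        ids = np.nonzero(mask)[0]
        if ids.size == 0:
            raise ValueError(f"node set {name!r} is empty")
        self.node_sets[name] = ids
        return ids

    def plane_node_set(self, name, axis, value, tol=None):
        """All nodes on the grid plane ``axis = value``."""
        coords = {"x": 0, "y": 1, "z": 2}[axis]
        ax = (self.xs, self.ys, self.zs)[coords]
        if tol is None:
            tol = 1e-9 * max(1.0, np.abs(ax).max())
        return self.define_node_set(
            name, lambda X, Y, Z: np.abs((X, Y, Z)[coords] - value) <= tol)


def graded_axis(breakpoints, sizes):
    """1-D axis through every breakpoint, each segment meshed uniformly at
    (or below) its target element size.  ``sizes`` is a scalar or one target
    per segment.  Every segment receives at least one element."""
    bp = np.asarray(breakpoints, dtype=float)
    if bp.ndim != 1 or bp.size < 2 or np.any(np.diff(bp) <= 0):
        raise ValueError("breakpoints must be strictly increasing, >= 2 values")
    nseg = bp.size - 1
    sizes = np.broadcast_to(np.asarray(sizes, dtype=float), (nseg,))
    if np.any(sizes <= 0):
        raise ValueError("target element sizes must be positive")
    pts = [bp[:1]]
    for s in range(nseg):
        n = max(1, int(np.ceil((bp[s + 1] - bp[s]) / sizes[s] - 1e-12)))
        pts.append(np.linspace(bp[s], bp[s + 1], n + 1)[1:])
    return np.concatenate(pts)


def geometric_axis(x0, x1, h0, ratio, max_ratio_to=None):
    """Axis from x0 to x1 starting at element size h0, growing geometrically
    by ``ratio`` per element (graded coarsening away from a focus region)."""
    if ratio < 1.0 or h0 <= 0:
        raise ValueError("need ratio >= 1 and h0 > 0")
    L = x1 - x0
    sign = np.sign(L)
    L = abs(L)
    sizes = []
    total = 0.0
    h = h0
    while total + h < L:
        sizes.append(h)
        total += h
        h *= ratio
    last = L - total
    if sizes and last < 0.25 * sizes[-1]:
        sizes[-1] += last  # avoid a sliver element at the far end
    else:
        sizes.append(last)
    pts = x0 + sign * np.concatenate([[0.0], np.cumsum(sizes)])
    return pts


def build_graded_grid(extents, interface_planes=((), (), ()), targets=(None, None, None)):
    """Tensor-product grid over ``[0, Lx] x [0, Ly] x [0, Lz]`` whose grid
    planes include every interface plane; each inter-interface segment is
    meshed uniformly at the per-axis target size.

    Parameters
    ----------
    extents:
        (Lx, Ly, Lz) in metres.
    interface_planes:
        Per axis, sorted interior coordinates that grid planes must hit
        (material boundaries never cross an element interior).
    targets:
        Per axis target element size (scalar or per-segment); ``None``
        means one element per segment.
    """
    axes = []
    for L, planes, tgt in zip(extents, interface_planes, targets):
        planes = np.asarray(sorted(planes), dtype=float)
        if planes.size and (planes[0] <= 0 or planes[-1] >= L):
            raise ValueError("interface planes must lie strictly inside extents")
        bp = np.concatenate([[0.0], planes, [L]])
        if np.any(np.diff(bp) <= 0):
            raise ValueError("duplicate interface plane")
        axes.append(graded_axis(bp, L if tgt is None else tgt))
    return HexMesh(*axes)


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------

@dataclass
class HarmonicSystem:
    """Assembled global system K = K_sigma + j*omega*K_eps at one frequency."""

    mesh: HexMesh
    f: float
    K: sp.csr_matrix  # full (unconstrained) complex system matrix


def _as_aniso(m):
    if isinstance(m, AnisotropicMaterial):
        return m
    if isinstance(m, DispersiveMaterial):
        return AnisotropicMaterial.isotropic(m)
    raise TypeError(f"not a material: {m!r}")


def assemble(mesh: HexMesh, materials: dict, f: float) -> HarmonicSystem:
    """Assemble the complex system matrix at frequency ``f`` (Hz).

    ``materials`` maps region name -> AnisotropicMaterial (isotropic
    DispersiveMaterial accepted).  The element admittivity tensor is
    diag(sxy, sxy, sz) evaluated at ``f``.
    """
    missing = [r for r in mesh.region_names if r not in materials]
    if missing:
        raise KeyError(f"no material assigned for region(s) {missing}")

    nreg = len(mesh.region_names)
    sxy = np.empty(nreg, dtype=complex)
    sz = np.empty(nreg, dtype=complex)
    for r, name in enumerate(mesh.region_names):
        mat = _as_aniso(materials[name])
        sxy[r] = mat.xy.admittivity(f)
        sz[r] = mat.z.admittivity(f)

    if mesh._geom_cache is None:
        A, B, C = mesh.element_sizes()
        conn = mesh.connectivity()
        rows = np.repeat(conn, 8, axis=1).ravel()
        cols = np.tile(conn, (1, 8)).ravel()
        mesh._geom_cache = (B * C / A, A * C / B, A * B / C, rows, cols)
    gx, gy, gz, rows, cols = mesh._geom_cache

    reg = mesh.region
    cx = sxy[reg] * gx
    cy = sxy[reg] * gy
    cz = sz[reg] * gz
    data = (cx[:, None, None] * _UX
            + cy[:, None, None] * _UY
            + cz[:, None, None] * _UZ).ravel()
    n = mesh.n_nodes
    K = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return HarmonicSystem(mesh=mesh, f=f, K=K)


# --------------------------------------------------------------------------
# Constraints and solve
# --------------------------------------------------------------------------

@dataclass
class BoundaryConditions:
    """Named-set boundary conditions.

    fixed:
        node-set name -> complex potential (V); the whole set is implicitly
        equipotential (a grounded or driven electrode).
    currents:
        node-set name -> total complex current (A) injected into the set;
        the set is coupled to a single potential (a driven electrode fed by
        a current source).
    coupled:
        further equipotential sets with zero net injected current
        (floating sense electrodes).
    """

    fixed: dict = field(default_factory=dict)
    currents: dict = field(default_factory=dict)
    coupled: tuple = ()

    def constrained_sets(self):
        return (tuple(self.fixed) + tuple(self.currents) + tuple(self.coupled))


@dataclass
class PotentialSolution:
    """Complex nodal potentials plus the bookkeeping needed to recover
    constraint reaction currents."""

    phi: np.ndarray  # complex potentials, one per node
    f: float
    set_potential: dict  # constrained set name -> complex potential
    _set_dof: dict
    _residual: np.ndarray  # K_reduced @ phi_reduced - injected currents


def solve(system: HarmonicSystem, bc: BoundaryConditions) -> PotentialSolution:
    """Solve the constrained harmonic system by sparse direct factorisation.

    Every named set is reduced to one degree of freedom (equipotential
    coupling by DOF merging); fixed potentials become Dirichlet constraints
    on the merged DOF.  At least one fixed potential is required (the
    potential reference).
    """
    mesh = system.mesh
    if not bc.fixed:
        raise ValueError("ill-posed: at least one fixed-potential set is "
                         "required as a reference")
    names = bc.constrained_sets()
    seen = set()
    for nm in names:
        if nm not in mesh.node_sets:
            raise KeyError(f"unknown node set {nm!r}")
        if nm in seen:
            raise ValueError(f"node set {nm!r} constrained twice")
        seen.add(nm)

    n = mesh.n_nodes
    # master map: node -> representative node of its coupled set
    master = np.arange(n)
    for nm in names:
        ids = mesh.node_sets[nm]
        master[ids] = ids.min()
    # detect overlapping sets (a node claimed by two sets)
    claimed = np.zeros(n, dtype=bool)
    for nm in names:
        ids = mesh.node_sets[nm]
        if np.any(claimed[ids]):
            raise ValueError(f"node set {nm!r} overlaps another constrained set")
        claimed[ids] = True

    reps, dof_of_node = np.unique(master, return_inverse=True)
    ndof = reps.size
    P = sp.coo_matrix((np.ones(n), (np.arange(n), dof_of_node)),
                      shape=(n, ndof)).tocsr()
    Kr = (P.T @ system.K @ P).tocsr()

    set_dof = {nm: int(dof_of_node[mesh.node_sets[nm].min()]) for nm in names}

    b = np.zeros(ndof, dtype=complex)
    for nm, cur in bc.currents.items():
        b[set_dof[nm]] += cur

    fixed_dofs = np.array([set_dof[nm] for nm in bc.fixed], dtype=int)
    fixed_vals = np.array([bc.fixed[nm] for nm in bc.fixed], dtype=complex)
    free = np.ones(ndof, dtype=bool)
    free[fixed_dofs] = False
    fidx = np.nonzero(free)[0]

    phi_r = np.zeros(ndof, dtype=complex)
    phi_r[fixed_dofs] = fixed_vals
    if fidx.size:
        Kff = Kr[fidx][:, fidx].tocsc()
        rhs = b[fidx] - Kr[fidx][:, fixed_dofs] @ fixed_vals
        try:
            # system is complex symmetric: symmetric-mode minimum-degree
            # ordering roughly halves the LU fill relative to COLAMD
            lu = spla.splu(Kff, permc_spec="MMD_AT_PLUS_A",
                           options={"SymmetricMode": True})
        except RuntimeError as err:  # pragma: no cover - singular systems
            raise RuntimeError(f"sparse factorisation failed: {err}") from err
        phi_r[fidx] = lu.solve(rhs)

    residual = Kr @ phi_r - b
    phi = phi_r[dof_of_node]
    set_potential = {nm: complex(phi_r[d]) for nm, d in set_dof.items()}
    return PotentialSolution(phi=phi, f=system.f, set_potential=set_potential,
                             _set_dof=set_dof, _residual=residual)


def reaction_current(solution: PotentialSolution, system: HarmonicSystem,
                     node_set: str) -> complex:
    """Net current (A) flowing *into* the mesh through a constrained set.

    For a grounded electrode this is the (negative of the) current leaving
    through it; drive/ground reactions sum to zero by conservation.
    """
    if node_set not in solution._set_dof:
        raise KeyError(f"{node_set!r} was not a constrained set in this solve")
    return complex(solution._residual[solution._set_dof[node_set]])


# --------------------------------------------------------------------------
# Analytic oracle and export
# --------------------------------------------------------------------------

def analytic_series_layers(layers, area: float, f: float) -> complex:
    """Closed-form impedance of a laterally uniform layer stack with
    insulated sides: ``Z = sum_i t_i / (sigma*_i(f) * A)``.

    Serves as ground truth for FEM solutions on 1-D stacks, including the
    Maxwell-Wagner interfacial dispersion of resistive/capacitive bilayers.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    z = 0.0 + 0.0j
    for thickness, mat in layers:
        if thickness <= 0:
            raise ValueError("layer thicknesses must be positive")
        z += thickness / (_as_aniso(mat).z.admittivity(f) * area)
    return z


def export_vtk(mesh: HexMesh, path, point_data=None):
    """Write the grid as a legacy-ASCII VTK rectilinear grid for inspection
    (region labels as cell data; optional complex point data split into
    real/imaginary components)."""
    nx, ny, nz = mesh.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\noraleis mesh\nASCII\n")
        fh.write("DATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        for label, ax in (("X", mesh.xs), ("Y", mesh.ys), ("Z", mesh.zs)):
            fh.write(f"{label}_COORDINATES {ax.size} double\n")
            fh.write(" ".join(f"{v:.9g}" for v in ax) + "\n")
        fh.write(f"CELL_DATA {mesh.n_elements}\n")
        fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(r)) for r in mesh.region) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                parts = [(name, arr)]
                if np.iscomplexobj(arr):
                    parts = [(f"{name}_re", arr.real), (f"{name}_im", arr.imag)]
                for pname, values in parts:
                    fh.write(f"SCALARS {pname} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.9g}" for v in values) + "\n")
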