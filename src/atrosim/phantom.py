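"""Synthetic labeled brain phantoms on a voxel-hexahedral grid.

A phantom emulates the topology of an MRI-derived hexahedral brain mesh:
a cortical ribbon on the outside of the cerebrum, corona radiata beneath
it, corpus callosum and deep gray nuclei centrally, a brainstem chain
(midbrain-pons-medulla) and the cerebellum inferiorly, interior
ventricular cavities, and a contiguous cerebrospinal-fluid shell
surrounding everything.  The anatomy is parametric (nested ellipsoids
with lateralized nuclei), so the same seed and geometry parameters
always reproduce the same labels.

Axes convention: x is left-right, y is posterior-anterior, z is
inferior-superior.  All coordinates are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .regions import (
    ALL_LABELS,
    ANATOMICAL_LABELS,
    BRAINSTEM_LABELS,
    CORTICAL_LABELS,
    CSF,
    SCHEMES,
    VENTRICLE,
    scheme_map,
)


class GeometryError(ValueError):
    """Raised when a phantom specification cannot be realized on its grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic brain phantom.

    ``grid_shape`` is the voxel count per axis, ``voxel_size`` the element
    edge length in mm.  ``csf_thickness`` (mm) is the thickness of the
    outer CSF shell (default 3 mm).  ``ventricle_radius_fraction`` scales
    the ventricular cavities relative to the brain semi-axes.
    ``region_geometry`` may override the default layer thicknesses and
    nucleus placements (fractions of the brain semi-axes).
    """

    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size: float = 1.0
    csf_thickness: float = 3.0
    ventricle_radius_fraction: float = 0.14
    random_seed: int = 0
    region_geometry: dict = field(default_factory=dict)

    def __post_init__(self):
        shape = self.grid_shape
        if isinstance(shape, (int, np.integer)):
            object.__setattr__(self, "grid_shape", (int(shape),) * 3)
        elif len(shape) != 3:
            raise GeometryError("grid_shape must be an int or a 3-tuple")
        else:
            object.__setattr__(self, "grid_shape", tuple(int(s) for s in shape))
        if self.voxel_size <= 0:
            raise GeometryError("voxel_size must be positive")
        if self.csf_thickness <= 0:
            raise GeometryError("csf_thickness must be positive")
        if not (0 < self.ventricle_radius_fraction < 0.5):
            raise GeometryError("ventricle_radius_fraction must lie in (0, 0.5)")

    @property
    def csf_layers(self) -> int:
        """CSF thickness in whole voxel layers (rounded, at least 1)."""
        return max(1, round(self.csf_thickness / self.voxel_size))


@dataclass
class LabeledHexMesh:
    """Voxel-hexahedral mesh with one region label per element.

    ``node_coords`` are positions in mm, ``element_connectivity`` holds
    8 node ids per hexahedron in VTK ordering, ``element_region`` one
    label per element, and ``outer_boundary_nodes`` the node ids on the
    exterior surface (all of which belong to CSF elements).
    """

    node_coords: np.ndarray          # (n_nodes, 3) float
    element_connectivity: np.ndarray  # (n_elem, 8) int
    element_region: np.ndarray       # (n_elem,) str
    outer_boundary_nodes: np.ndarray  # (n_bnd,) int
    voxel_size: float

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.element_connectivity.shape[0]

    def element_centroids(self) -> np.ndarray:
        return self.node_coords[self.element_connectivity].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        """Undeformed element volumes (identical for a voxel mesh)."""
        return np.full(self.n_elements, self.voxel_size**3)

    def region_census(self) -> dict[str, int]:
        labels, counts = np.unique(self.element_region, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def with_labels(self, labels: np.ndarray) -> "LabeledHexMesh":
        return LabeledHexMesh(
            node_coords=self.node_coords,
            element_connectivity=self.element_connectivity,
            element_region=np.asarray(labels, dtype="<U32"),
            outer_boundary_nodes=self.outer_boundary_nodes,
            voxel_size=self.voxel_size,
        )


# default geometry parameters: fractions of the brain semi-axes (a, b, c)
_DEFAULT_GEOMETRY = {
    "cortex_layers": 1,          # thickness of the cortical ribbon, in voxels
    "brainstem_radius": 0.22,    # of semi-axis a
    "brainstem_top": -0.10,      # z_n where the brainstem column starts
    "cerebellum_center": (0.0, -0.45, -0.60),
    "cerebellum_axes": (0.50, 0.40, 0.32),
    "nucleus_jitter": 0.03,      # seed-controlled placement jitter (of semi-axis)
    # paired (lateralized) deep structures: center (x_n, y_n, z_n), axes fractions
    "nuclei": {
        "NC": ((0.30, 0.20, 0.15), (0.12, 0.16, 0.12)),
        "Pa": ((0.30, -0.02, 0.00), (0.10, 0.10, 0.10)),
        "Pu": ((0.45, 0.05, 0.00), (0.12, 0.14, 0.12)),
        "Th": ((0.16, -0.15, -0.02), (0.14, 0.16, 0.14)),
        "Am": ((0.48, 0.12, -0.38), (0.11, 0.11, 0.11)),
        "Hi": ((0.42, -0.20, -0.32), (0.12, 0.20, 0.12)),
    },
    "cc_halfwidth": (0.26, 0.38, 0.12),   # central slab half-extents
    "cc_center_z": 0.30,
    "ventricle_center": (0.18, -0.05, 0.08),
}


def _ellipsoid(coords, center, axes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _paint_paired(vol, avail, coords, label_id, center_n, axes_n, semi, center):
    """Paint a lateralized (mirror +-x) pair of ellipsoidal nuclei.

    Falls back to the nearest still-available voxel when the ellipsoid
    captures no voxel center (possible on coarse grids).
    """
    a, b, c = semi
    painted_any = False
    for sx in (+1.0, -1.0):
        cn = (center[0] + sx * center_n[0] * a,
              center[1] + center_n[1] * b,
              center[2] + center_n[2] * c)
        axes = (max(axes_n[0] * a, 0.6), max(axes_n[1] * b, 0.6), max(axes_n[2] * c, 0.6))
        mask = _ellipsoid(coords, cn, axes) & avail
        if not mask.any():
            d2 = ((coords[0] - cn[0]) ** 2 + (coords[1] - cn[1]) ** 2
                  + (coords[2] - cn[2]) ** 2)
            d2 = np.where(avail, d2, np.inf)
            if not np.isfinite(d2.min()):
                return False
            idx = np.unravel_index(np.argmin(d2), d2.shape)
            mask = np.zeros_like(avail)
            mask[idx] = True
        vol[mask] = label_id
        avail &= ~mask
        painted_any = True
    return painted_any


def build_label_volume(spec: PhantomSpec) -> np.ndarray:
    """Construct the integer label volume of a phantom.

    Returns an array of shape ``spec.grid_shape`` where 0 is background
    and positive integers index into :data:`atrosim.regions.ALL_LABELS`
    (1-based).
    """
    geo = dict(_DEFAULT_GEOMETRY)
    geo.update(spec.region_geometry)
    nx, ny, nz = spec.grid_shape
    n_csf = spec.csf_layers
    rng = np.random.default_rng(spec.random_seed)

    label_id = {lab: i + 1 for i, lab in enumerate(ALL_LABELS)}

    ii, jj, kk = np.meshgrid(
        np.arange(nx) + 0.5, np.arange(ny) + 0.5, np.arange(nz) + 0.5, indexing="ij"
    )
    coords = (ii, jj, kk)
    center = (nx / 2.0, ny / 2.0, nz / 2.0)

    # brain ellipsoid: leave room for the CSF shell plus one free voxel
    margin = n_csf + 1
    semi = (nx / 2.0 - margin, ny / 2.0 - margin, nz / 2.0 - margin)
    if min(semi) < 5.0:
        raise GeometryError(
            f"grid {spec.grid_shape} too small for csf_thickness "
            f"{spec.csf_thickness} mm: brain semi-axes {semi} fall below 5 voxels"
        )
    a, b, c = semi
    brain = _ellipsoid(coords, center, semi)

    vol = np.zeros(spec.grid_shape, dtype=np.int32)

    # --- inferior structures -------------------------------------------------
    zn = (kk - center[2]) / c
    bs_r = geo["brainstem_radius"] * a
    brainstem = (
        brain
        & (zn <= geo["brainstem_top"])
        & (((ii - center[0]) ** 2 + (jj - center[1] + 0.10 * b) ** 2) <= bs_r**2)
    )
    cb_c = tuple(center[d] + geo["cerebellum_center"][d] * semi[d] for d in range(3))
    cb_ax = tuple(geo["cerebellum_axes"][d] * semi[d] for d in range(3))
    cerebellum = brain & _ellipsoid(coords, cb_c, cb_ax) & ~brainstem

    # split the brainstem column into thirds along z: midbrain, pons, medulla
    if brainstem.any():
        z_vals = kk[brainstem]
        z_lo, z_hi = z_vals.min(), z_vals.max()
        cuts = np.linspace(z_lo, z_hi, 4)
        for lab, (lo, hi) in zip(("Me", "P", "M"), zip(cuts[:-1], cuts[1:])):
            sel = brainstem & (kk >= lo - 1e-9) & (kk <= hi + 1e-9) & (vol == 0)
            vol[sel] = label_id[lab]
    vol[cerebellum & (vol == 0)] = label_id["CB"]

    cerebrum = brain & (vol == 0)

    # --- cortical ribbon: outermost anatomical layer of the cerebrum --------
    interior_brain = ndimage.binary_erosion(
        brain, structure=np.ones((3, 3, 3)), iterations=int(geo["cortex_layers"])
    )
    ribbon = cerebrum & ~interior_brain
    yn = (jj - center[1]) / b
    xn = (ii - center[0]) / a
    cortex_rules = [
        ("VC", yn < -0.50),
        ("FC", yn > 0.40),
        ("MC", zn > 0.45),
        ("TL", (zn < -0.05) | (np.abs(xn) > 0.75)),
        ("CI", np.ones_like(ribbon)),
    ]
    assigned = np.zeros_like(ribbon)
    for lab, rule in cortex_rules:
        sel = ribbon & rule & ~assigned
        vol[sel] = label_id[lab]
        assigned |= sel

    # --- deep structures inside the remaining white matter -------------------
    avail = cerebrum & ~ribbon

    jit = geo["nucleus_jitter"]

    def jittered(p):
        return tuple(p[d] + jit * rng.uniform(-1, 1) for d in range(3))

    # ventricles: paired interior cavities adjacent to the deep nuclei
    vf = spec.ventricle_radius_fraction
    ok = _paint_paired(
        vol, avail, coords, label_id[VENTRICLE],
        jittered(geo["ventricle_center"]), (vf, 1.6 * vf, vf), semi, center,
    )
    if not ok:
        raise GeometryError("no interior space left for the ventricles")

    # corpus callosum: central superior slab arching over the ventricles
    hw = geo["cc_halfwidth"]
    cc = (
        avail
        & (np.abs(xn) <= hw[0])
        & (np.abs(yn) <= hw[1])
        & (np.abs(zn - geo["cc_center_z"]) <= hw[2])
    )
    if not cc.any():
        raise GeometryError("corpus callosum slab captured no voxels")
    vol[cc] = label_id["CC"]
    avail &= ~cc

    for lab, (cn, axn) in geo["nuclei"].items():
        ok = _paint_paired(vol, avail, coords, label_id[lab], jittered(cn), axn,
                           semi, center)
        if not ok:
            raise GeometryError(f"no interior space left for nucleus {lab}")

    # everything else inside the cerebrum is corona radiata (white matter)
    vol[avail] = label_id["CR"]

    # --- CSF shell: n_csf complete voxel layers around the anatomy ----------
    shell = ndimage.binary_dilation(
        brain, structure=np.ones((3, 3, 3)), iterations=n_csf
    )
    if shell[0, :, :].any() or shell[-1, :, :].any() or shell[:, 0, :].any() \
            or shell[:, -1, :].any() or shell[:, :, 0].any() or shell[:, :, -1].any():
        raise GeometryError("CSF shell touches the grid boundary; enlarge the grid")
    vol[shell & (vol == 0)] = label_id[CSF]

    missing = [lab for lab in ALL_LABELS if not (vol == label_id[lab]).any()]
    if missing:
        raise GeometryError(f"labels {missing} are empty on grid {spec.grid_shape}")
    return vol


def mesh_from_label_volume(vol: np.ndarray, voxel_size: float) -> LabeledHexMesh:
    """Extract the hexahedral mesh of all labeled (nonzero) voxels."""
    nx, ny, nz = vol.shape
    eli, elj, elk = np.nonzero(vol)
    n_elem = eli.size
    if n_elem == 0:
        raise GeometryError("label volume is empty")

    # node grid ids (nx+1, ny+1, nz+1), compressed to used nodes
    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    # VTK_HEXAHEDRON ordering: bottom face CCW, then top face CCW
    offsets = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
               (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
    conn_global = np.stack(
        [nid(eli + di, elj + dj, elk + dk) for di, dj, dk in offsets], axis=1
    )
    used, conn = np.unique(conn_global, return_inverse=True)
    conn = conn.reshape(n_elem, 8)

    gi = used // ((ny + 1) * (nz + 1))
    gj = (used // (nz + 1)) % (ny + 1)
    gk = used % (nz + 1)
    node_coords = np.stack([gi, gj, gk], axis=1).astype(float) * voxel_size

    # exterior faces: element faces whose voxel neighbor is background
    domain = vol != 0
    face_nodes = {
        (-1, 0, 0): (0, 3, 7, 4), (1, 0, 0): (1, 2, 6, 5),
        (0, -1, 0): (0, 1, 5, 4), (0, 1, 0): (3, 2, 6, 7),
        (0, 0, -1): (0, 1, 2, 3), (0, 0, 1): (4, 5, 6, 7),
    }
    padded = np.pad(domain, 1, constant_values=False)
    bnd: list[np.ndarray] = []
    for (dx, dy, dz), locals_ in face_nodes.items():
        nbr = padded[1 + dx:1 + nx + dx, 1 + dy:1 + ny + dy, 1 + dz:1 + nz + dz]
        exposed = ~nbr[eli, elj, elk]
        if exposed.any():
            bnd.append(conn[exposed][:, list(locals_)].ravel())
    outer_boundary_nodes = np.unique(np.concatenate(bnd))

    labels = np.asarray(ALL_LABELS, dtype="<U32")[vol[eli, elj, elk] - 1]

    return LabeledHexMesh(
        node_coords=node_coords,
        element_connectivity=conn.astype(np.int64),
        element_region=labels,
        outer_boundary_nodes=outer_boundary_nodes.astype(np.int64),
        voxel_size=voxel_size,
    )


def generate_phantom(spec: PhantomSpec) -> LabeledHexMesh:
    """Generate a synthetic labeled brain phantom mesh.

    Deterministic for a fixed ``spec.random_seed``; raises
    :class:`GeometryError` when the requested geometry does not fit on
    the grid.
    """
    vol = build_label_volume(spec)
    return mesh_from_label_volume(vol, spec.voxel_size)


def uniform_box_mesh(shape, voxel_size: float = 1.0, label: str = "CR") -> LabeledHexMesh:
    """A full rectangular box of voxels carrying a single region label.

    Useful for analytic verification problems (patch test, free
    shrinkage) where anatomy is irrelevant.
    """
    if label not in ALL_LABELS:
        raise ValueError(f"unknown region label {label!r}")
    if isinstance(shape, (int, np.integer)):
        shape = (int(shape),) * 3
    vol = np.full(shape, ALL_LABELS.index(label) + 1, dtype=np.int32)
    return mesh_from_label_volume(vol, voxel_size)


def phantom_family(mesh: LabeledHexMesh) -> dict[str, LabeledHexMesh]:
    """All five region-scheme variants of one phantom.

    Geometry and connectivity are shared; only element labels are
    remapped through the merge hierarchy.  CSF and VENTRICLE are never
    merged into anatomical groups.
    """
    unknown = set(np.unique(mesh.element_region)) - set(ALL_LABELS)
    if unknown:
        raise ValueError(f"unknown region labels {sorted(unknown)}")
    family = {}
    for scheme in SCHEMES:
        family[scheme] = remap_mesh(mesh, scheme)
    return family


def remap_mesh(mesh: LabeledHexMesh, scheme: str) -> LabeledHexMesh:
    """Relabel a 17R mesh into the given scheme (labels only)."""
    m = scheme_map(scheme)
    try:
        new = np.asarray([m[lab] for lab in mesh.element_region], dtype="<U32")
    except KeyError as exc:
        raise ValueError(f"unknown region label {exc.args[0]!r}") from exc
    return mesh.with_labels(new)


def save_nifti(vol: np.ndarray, voxel_size: float, path) -> None:
    """Write the integer label volume as a NIfTI image."""
    import nibabel as nib

    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.int16), affine), str(path))
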