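"""Parametric idealized L4-L5 post-PLIF construct mesh.

The construct stands in for a CT-derived post-surgical fusion model: two
vertebral blocks (1 mm cortical shell around a trabecular core), an
interbody callus filling the disc space, two solid interbody cages and a
posterior fixation bridge, all meshed conformingly so that every interface
is tied by shared nodes.

Coordinate frame (mm): x lateral (sagittal midline at x=0), y
antero-posterior (anterior face at y=0), z axial (caudal face at z=0).

Meshing is a deterministic tensor-product grid whose breakpoints coincide
with every region boundary, subdivided to the target edge lengths and split
into tetrahedra by the Kuhn (orthoscheme) triangulation.  This makes region
volumes exact, interfaces node-conforming by construction, and the mesh
bit-identical for identical parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, ParameterError

# Region labels (cell data "region" in VTU exports)
CORTICAL = 1
TRABECULAR = 2
CALLUS = 3
CAGE = 4
FIXATION = 5

REGION_NAMES = {
    CORTICAL: "CORTICAL",
    TRABECULAR: "TRABECULAR",
    CALLUS: "CALLUS",
    CAGE: "CAGE",
    FIXATION: "FIXATION",
}

BONE_REGIONS = (CORTICAL, TRABECULAR)
IMPLANT_REGIONS = (CAGE, FIXATION)

# Kuhn triangulation of the unit cube: 6 orthoschemes along the main
# diagonal (0,0,0)-(1,1,1).  Corner index = i + 2*j + 4*k.
_KUHN_PATHS = [
    (0, 1, 3, 7),  # x, y, z
    (0, 1, 5, 7),  # x, z, y
    (0, 2, 3, 7),  # y, x, z
    (0, 2, 6, 7),  # y, z, x
    (0, 4, 5, 7),  # z, x, y
    (0, 4, 6, 7),  # z, y, x
]


@dataclass(frozen=True)
class ConstructParams:
    """Geometric parameters of the idealized fusion construct (mm)."""

    vertebra_width: float = 40.0
    vertebra_depth: float = 30.0
    vertebra_height: float = 20.0
    cortical_thickness: float = 1.0
    disc_space_height: float = 9.0
    cage_height: float = 9.0
    cage_width: float = 10.0
    cage_depth: float = 22.0
    cage_lateral_offset: float = 8.0   # centerline distance from midline
    fixation_rod_section: float = 25.0  # mm^2, square section
    fixation_lateral_offset: float = 13.0  # rod centerline from midline
    # target edge lengths; the disc space is meshed finer than the vertebrae
    inplane_edge: float = 2.5
    callus_axial_edge: float = 1.8
    vertebra_axial_edge: float = 3.0

    def validate(self) -> None:
        lengths = {
            "vertebra_width": self.vertebra_width,
            "vertebra_depth": self.vertebra_depth,
            "vertebra_height": self.vertebra_height,
            "cortical_thickness": self.cortical_thickness,
            "disc_space_height": self.disc_space_height,
            "cage_height": self.cage_height,
            "cage_width": self.cage_width,
            "cage_depth": self.cage_depth,
            "fixation_rod_section": self.fixation_rod_section,
            "inplane_edge": self.inplane_edge,
            "callus_axial_edge": self.callus_axial_edge,
            "vertebra_axial_edge": self.vertebra_axial_edge,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ParameterError(f"{name} must be > 0, got {value}")
        if self.cage_height > self.disc_space_height:
            raise ParameterError(
                f"cage_height ({self.cage_height}) exceeds disc_space_height "
                f"({self.disc_space_height})"
            )
        if 2 * self.cortical_thickness >= min(self.vertebra_width, self.vertebra_depth):
            raise ParameterError(
                "2*cortical_thickness must be smaller than the vertebral footprint"
            )
        if self.cage_lateral_offset - self.cage_width / 2 < 0:
            raise ParameterError("cages overlap at the midline")
        if self.cage_lateral_offset + self.cage_width / 2 > self.vertebra_width / 2:
            raise ParameterError("cage extends beyond the lateral vertebral footprint")
        if self.cage_depth > self.vertebra_depth:
            raise ParameterError("cage_depth exceeds vertebra_depth")
        rod_side = math.sqrt(self.fixation_rod_section)
        if self.fixation_lateral_offset - rod_side / 2 < 0:
            raise ParameterError("fixation rods overlap at the midline")
        if self.fixation_lateral_offset + rod_side / 2 > self.vertebra_width / 2:
            raise ParameterError("fixation rod extends beyond the vertebral width")

    # Derived extents -------------------------------------------------
    @property
    def rod_side(self) -> float:
        return math.sqrt(self.fixation_rod_section)

    @property
    def z_disc(self) -> tuple[float, float]:
        return self.vertebra_height, self.vertebra_height + self.disc_space_height

    @property
    def z_top(self) -> float:
        return 2 * self.vertebra_height + self.disc_space_height

    @property
    def cage_z(self) -> tuple[float, float]:
        z0, z1 = self.z_disc
        pad = (self.disc_space_height - self.cage_height) / 2
        return z0 + pad, z1 - pad

    @property
    def cage_y(self) -> tuple[float, float]:
        pad = (self.vertebra_depth - self.cage_depth) / 2
        return pad, self.vertebra_depth - pad

    def analytic_region_volumes(self) -> dict[int, float]:
        """Closed-form region volumes of the parametric geometry (mm^3)."""
        w, d, h = self.vertebra_width, self.vertebra_depth, self.vertebra_height
        t = self.cortical_thickness
        v_vert = w * d * h
        v_trab = (w - 2 * t) * (d - 2 * t) * (h - 2 * t)
        v_cage = 2 * self.cage_width * self.cage_depth * self.cage_height
        v_disc = w * d * self.disc_space_height
        s = self.rod_side
        v_rod = 2 * s * s * (self.vertebra_height + self.disc_space_height)
        return {
            CORTICAL: 2 * (v_vert - v_trab),
            TRABECULAR: 2 * v_trab,
            CALLUS: v_disc - v_cage,
            CAGE: v_cage,
            FIXATION: v_rod,
        }


@dataclass
class LabeledMesh:
    """Tetrahedral mesh with per-element region labels and named node sets."""

    node_coords: np.ndarray          # (N, 3) mm
    tets: np.ndarray                 # (E, 4) int node indices
    element_region: np.ndarray       # (E,) int region labels
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_volumes: np.ndarray | None = None  # (E,) mm^3

    def __post_init__(self):
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.element_region = np.asarray(self.element_region, dtype=np.int32)
        if self.element_volumes is None:
            self.element_volumes = tet_volumes(self.node_coords, self.tets)

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def elements_of(self, *regions: int) -> np.ndarray:
        """Indices of elements whose label is in ``regions``."""
        return np.flatnonzero(np.isin(self.element_region, regions))

    def region_volume(self, *regions: int) -> float:
        return float(self.element_volumes[self.elements_of(*regions)].sum())


def tet_volumes(coords: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed tetrahedron volumes (positive for correctly oriented tets)."""
    p = coords[tets]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def _subdivide(breaks: list[float], targets: list[float]) -> np.ndarray:
    """Refine consecutive breakpoints so no interval exceeds its target."""
    out = [breaks[0]]
    for a, b, t in zip(breaks[:-1], breaks[1:], targets):
        n = max(1, int(math.ceil((b - a) / t - 1e-9)))
        out.extend(a + (b - a) * (i + 1) / n for i in range(n))
    return np.asarray(out)


def _axis_breaks(raw: list[float], target_for_interval) -> np.ndarray:
    uniq = sorted(set(round(v, 9) for v in raw))
    dedup = [uniq[0]]
    for v in uniq[1:]:
        if v - dedup[-1] > 1e-9:
            dedup.append(v)
    targets = [target_for_interval(0.5 * (a + b)) for a, b in zip(dedup[:-1], dedup[1:])]
    return _subdivide(dedup, targets)


def structured_tet_grid(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kuhn-tetrahedralized tensor grid.

    Returns (coords, tets, cell_index) where ``cell_index`` maps each tet to
    its parent hexahedral cell (6 tets per cell, cells in C order over
    (ix, iy, iz)).
    """
    nx, ny, nz = len(x), len(y), len(z)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    coords = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    ix, iy, iz = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    ix, iy, iz = ix.ravel(), iy.ravel(), iz.ravel()
    # corner c = (dx, dy, dz) -> index dx + 2*dy + 4*dz
    corners = np.empty((ix.size, 8), dtype=np.int64)
    for c in range(8):
        dx, dy, dz = c & 1, (c >> 1) & 1, (c >> 2) & 1
        corners[:, c] = nid(ix + dx, iy + dy, iz + dz)

    tets = np.concatenate([corners[:, path] for path in _KUHN_PATHS], axis=0)
    cell_index = np.tile(np.arange(ix.size), 6)
    # fix orientation: swap last two nodes of negative-volume tets
    vols = tet_volumes(coords, tets)
    neg = vols < 0
    tets[neg, 2], tets[neg, 3] = tets[neg, 3].copy(), tets[neg, 2].copy()
    return coords, tets, cell_index


def box_mesh(
    lx: float, ly: float, lz: float, edge: float | tuple[float, float, float]
) -> LabeledMesh:
    """Uniform Kuhn tet mesh of a box [0,lx]x[0,ly]x[0,lz] (single region).

    Utility for verification problems (bars, slabs, patch tests); the
    region label is CALLUS and ``caudal_fixed``/``cranial_load`` hold
    the z=0 and z=lz node sets.
    """
    ex, ey, ez = (edge, edge, edge) if np.isscalar(edge) else edge
    x = _subdivide([0.0, lx], [ex])
    y = _subdivide([0.0, ly], [ey])
    z = _subdivide([0.0, lz], [ez])
    coords, tets, _ = structured_tet_grid(x, y, z)
    mesh = LabeledMesh(coords, tets, np.full(len(tets), CALLUS, dtype=np.int32))
    tol = 1e-9
    mesh.node_sets["caudal_fixed"] = np.flatnonzero(coords[:, 2] < tol)
    mesh.node_sets["cranial_load"] = np.flatnonzero(coords[:, 2] > lz - tol)
    return mesh


def _classify_centroids(c: np.ndarray, p: ConstructParams) -> np.ndarray:
    """Region label per hex-cell centroid; 0 = outside every region."""
    x, y, z = c[:, 0], c[:, 1], c[:, 2]
    w2 = p.vertebra_width / 2
    d, h, t = p.vertebra_depth, p.vertebra_height, p.cortical_thickness
    zd0, zd1 = p.z_disc
    ztop = p.z_top
    labels = np.zeros(len(c), dtype=np.int32)

    footprint = (np.abs(x) < w2) & (y > 0) & (y < d)
    lower = footprint & (z > 0) & (z < zd0)
    upper = footprint & (z > zd1) & (z < ztop)
    for vert, zlo, zhi in ((lower, 0.0, zd0), (upper, zd1, ztop)):
        shell = (
            (np.abs(x) > w2 - t)
            | (y < t)
            | (y > d - t)
            | (z < zlo + t)
            | (z > zhi - t)
        )
        labels[vert & shell] = CORTICAL
        labels[vert & ~shell] = TRABECULAR

    disc = footprint & (z > zd0) & (z < zd1)
    cy0, cy1 = p.cage_y
    cz0, cz1 = p.cage_z
    in_cage = (
        (np.abs(np.abs(x) - p.cage_lateral_offset) < p.cage_width / 2)
        & (y > cy0)
        & (y < cy1)
        & (z > cz0)
        & (z < cz1)
    )
    labels[disc & in_cage] = CAGE
    labels[disc & ~in_cage] = CALLUS

    s2 = p.rod_side / 2
    rod = (
        (np.abs(np.abs(x) - p.fixation_lateral_offset) < s2)
        & (y > d)
        & (y < d + p.rod_side)
        & (z > h / 2)
        & (z < zd1 + h / 2)
    )
    labels[rod] = FIXATION
    return labels


def build_construct(params: ConstructParams | None = None) -> LabeledMesh:
    """Generate the labeled construct mesh (deterministic for fixed params)."""
    p = params if params is not None else ConstructParams()
    p.validate()

    w2 = p.vertebra_width / 2
    t = p.cortical_thickness
    d, h = p.vertebra_depth, p.vertebra_height
    zd0, zd1 = p.z_disc
    cz0, cz1 = p.cage_z
    cy0, cy1 = p.cage_y
    s = p.rod_side
    co, ro = p.cage_lateral_offset, p.fixation_lateral_offset

    xb = [-w2, -w2 + t, w2 - t, w2]
    for off, half in ((co, p.cage_width / 2), (ro, s / 2)):
        xb += [-off - half, -off + half, off - half, off + half]
    yb = [0.0, t, cy0, cy1, d - t, d, d + s]
    zb = [0.0, t, h - t, zd0, cz0, cz1, zd1, zd1 + t, p.z_top - t, p.z_top,
          h / 2, zd1 + h / 2]

    def z_target(zmid: float) -> float:
        return p.callus_axial_edge if zd0 < zmid < zd1 else p.vertebra_axial_edge

    x = _axis_breaks(xb, lambda _: p.inplane_edge)
    y = _axis_breaks(yb, lambda _: p.inplane_edge)
    z = _axis_breaks(zb, z_target)

    coords, tets, cell_index = structured_tet_grid(x, y, z)

    # hex-cell centroids for labeling
    n_cells = cell_index.max() + 1
    hex_centroid = np.zeros((n_cells, 3))
    counts = np.zeros(n_cells)
    # centroid of the 6 tets of a cell equals the hex centroid on average;
    # compute directly from tet centroids weighted by volume
    vols = tet_volumes(coords, tets)
    tc = coords[tets].mean(axis=1)
    np.add.at(hex_centroid, cell_index, tc * vols[:, None])
    np.add.at(counts, cell_index, vols)
    hex_centroid /= counts[:, None]

    cell_labels = _classify_centroids(hex_centroid, p)
    keep = cell_labels[cell_index] != 0
    tets = tets[keep]
    labels = cell_labels[cell_index[keep]]

    # compact node numbering
    used, inverse = np.unique(tets, return_inverse=True)
    tets = inverse.reshape(tets.shape)
    coords = coords[used]

    mesh = LabeledMesh(coords, tets, labels)
    return extract_node_sets(mesh)


def extract_node_sets(mesh: LabeledMesh) -> LabeledMesh:
    """Populate caudal_fixed, cranial_load and endplate_source node sets."""
    z = mesh.node_coords[:, 2]
    tol = 1e-9
    caudal = np.flatnonzero(z < z.min() + tol)
    cranial = np.flatnonzero(z > z.max() - tol)

    bone_nodes = np.unique(mesh.tets[mesh.elements_of(*BONE_REGIONS)])
    callus_elems = mesh.elements_of(CALLUS)
    if callus_elems.size == 0:
        raise GeometryError("mesh has no CALLUS region; no endplate interface exists")
    callus_nodes = np.unique(mesh.tets[callus_elems])
    source = np.intersect1d(bone_nodes, callus_nodes)

    for name, nodes in (
        ("caudal_fixed", caudal),
        ("cranial_load", cranial),
        ("endplate_source", source),
    ):
        if nodes.size == 0:
            raise GeometryError(f"node set {name!r} is empty")
        mesh.node_sets[name] = nodes
    return mesh


# ---------------------------------------------------------------------------
# topology helpers shared by the front rule and the bridging metric


def _element_faces(tets: np.ndarray) -> np.ndarray:
    """(E*4, 3) sorted node triples of every tet face."""
    faces = np.concatenate(
        [tets[:, idx] for idx in ((1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2))],
        axis=0,
    )
    return np.sort(faces, axis=1)


def face_adjacency(mesh: LabeledMesh, elements: np.ndarray):
    """Pairs (i, j) of positions into ``elements`` sharing a triangular face."""
    tets = mesh.tets[elements]
    faces = _element_faces(tets)
    owner = np.tile(np.arange(len(elements)), 4)
    order = np.lexsort(faces.T)
    faces, owner = faces[order], owner[order]
    same = np.all(faces[1:] == faces[:-1], axis=1)
    return np.column_stack([owner[:-1][same], owner[1:][same]])


def interface_elements(mesh: LabeledMesh, region: int, other_regions) -> np.ndarray:
    """Elements of ``region`` sharing a face with any element of ``other_regions``.

    Returns (indices into the region's element list, side flag) where the
    side flag is +1 if the touching neighbor lies cranial (above) and -1 if
    caudal (below), judged by element centroid.
    """
    own = mesh.elements_of(region)
    others = mesh.elements_of(*other_regions)
    f_own = _element_faces(mesh.tets[own])
    f_oth = _element_faces(mesh.tets[others])
    own_idx = np.tile(np.arange(len(own)), 4)
    oth_idx = np.tile(np.arange(len(others)), 4)

    all_faces = np.concatenate([f_own, f_oth], axis=0)
    tags = np.concatenate([np.zeros(len(f_own), int), np.ones(len(f_oth), int)])
    owners = np.concatenate([own_idx, oth_idx])
    order = np.lexsort(all_faces.T)
    all_faces, tags, owners = all_faces[order], tags[order], owners[order]
    same = np.all(all_faces[1:] == all_faces[:-1], axis=1)
    cross = same & (tags[1:] != tags[:-1])

    c_own = mesh.node_coords[mesh.tets[own]].mean(axis=1)[:, 2]
    c_oth = mesh.node_coords[mesh.tets[others]].mean(axis=1)[:, 2]
    pairs = []
    for a, b in zip(np.flatnonzero(cross), np.flatnonzero(cross) + 1):
        i = owners[a] if tags[a] == 0 else owners[b]
        j = owners[b] if tags[a] == 0 else owners[a]
        side = 1 if c_oth[j] > c_own[i] else -1
        pairs.append((i, side))
    if not pairs:
        return np.empty((0, 2), dtype=int)
    return np.unique(np.asarray(pairs, dtype=int), axis=0)


# ---------------------------------------------------------------------------


def validate_mesh(mesh: LabeledMesh) -> dict:
    """Quality report: volumes, aspect ratios, conformity, inverted tets."""
    vols = tet_volumes(mesh.node_coords, mesh.tets)
    inverted = np.flatnonzero(vols <= 0)

    p = mesh.node_coords[mesh.tets]
    edges = np.stack(
        [p[:, a] - p[:, b] for a, b in
         ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))],
        axis=1,
    )
    lmax = np.linalg.norm(edges, axis=2).max(axis=1)
    # aspect ratio: longest edge / smallest altitude
    areas = []
    for idx in ((1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)):
        tri = p[:, idx]
        areas.append(
            0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
            )
        )
    amax = np.max(areas, axis=0)
    hmin = 3.0 * np.abs(vols) / amax
    aspect = lmax / np.maximum(hmin, 1e-300)

    faces = _element_faces(mesh.tets)
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    nonconforming = int((counts > 2).sum())

    region_counts = {
        REGION_NAMES[r]: int((mesh.element_region == r).sum())
        for r in REGION_NAMES
    }
    return {
        "n_nodes": mesh.n_nodes,
        "n_elements": mesh.n_elements,
        "min_volume": float(vols.min()),
        "max_volume": float(vols.max()),
        "inverted_elements": inverted.tolist(),
        "aspect_ratio_max": float(aspect.max()),
        "aspect_ratio_mean": float(aspect.mean()),
        "nonconforming_faces": nonconforming,
        "region_counts": region_counts,
        "node_set_sizes": {k: int(v.size) for k, v in mesh.node_sets.items()},
    }


def refined(params: ConstructParams, factor: float) -> ConstructParams:
    """Params with all target edge lengths scaled by ``factor``."""
    return replace(
        params,
        inplane_edge=params.inplane_edge * factor,
        callus_axial_edge=params.callus_axial_edge * factor,
        vertebra_axial_edge=params.vertebra_axial_edge * factor,
    )
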