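"""Source spaces, sensor arrays and the single-sphere MEG forward model.

The source space is a triangulated surface whose vertices carry current
dipoles oriented along the outward surface normal (orientation-constrained
model).  The forward solution is the closed-form magnetic field of a current
dipole inside a spherically symmetric conductor (Sarvas solution), which
depends only on the sphere *center*, not on its radius or conductivity
profile, and which is exactly silent for radially oriented dipoles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import (
    GeometryError,
    InsufficientMeshError,
    MeshFormatError,
    ParameterError,
    SingularGeometryError,
    UnsupportedMeshError,
)

MU0_OVER_4PI = 1e-7  # T·m/A

__all__ = [
    "SourceSpace",
    "SensorArray",
    "LeadField",
    "Patch",
    "build_sphere_source_space",
    "build_wrinkled_source_space",
    "load_mesh",
    "build_sensor_cap",
    "compute_lead_field",
    "normalize_lead_field",
    "grow_patch",
    "write_obj",
    "write_sensor_table",
]


@dataclass
class SourceSpace:
    """Triangulated surface hosting the source dipoles.

    Attributes
    ----------
    vertex_positions : (n_vertices, 3) float array, meters.
    triangles : (n_triangles, 3) int array of vertex indices.
    normals : (n_vertices, 3) unit outward orientation per vertex.
    vertex_area : (n_vertices,) float array, m²; barycentric lumping
        (one third of each incident triangle's area).
    """

    vertex_positions: np.ndarray
    triangles: np.ndarray
    normals: np.ndarray
    vertex_area: np.ndarray
    _adjacency: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertex_positions = np.asarray(self.vertex_positions, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.normals = np.asarray(self.normals, dtype=float)
        self.vertex_area = np.asarray(self.vertex_area, dtype=float)
        n = self.n_vertices
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ParameterError("triangles must be an (n, 3) index array")
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= n:
            raise ParameterError("triangle indices out of range")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ParameterError("vertex normals must be unit length")
        if np.any(self.vertex_area <= 0):
            raise ParameterError("every vertex must carry positive area")

    @property
    def n_vertices(self) -> int:
        return self.vertex_positions.shape[0]

    @property
    def total_area(self) -> float:
        """Total mesh area in m² (equals the sum of vertex areas)."""
        return float(self.vertex_area.sum())

    def adjacency(self) -> list:
        """Vertex adjacency as a list of sorted index arrays (cached)."""
        if self._adjacency is None:
            nbrs: list[set] = [set() for _ in range(self.n_vertices)]
            for a, b, c in self.triangles:
                nbrs[a].update((b, c))
                nbrs[b].update((a, c))
                nbrs[c].update((a, b))
            self._adjacency = [np.array(sorted(s), dtype=int) for s in nbrs]
        return self._adjacency


@dataclass
class SensorArray:
    """MEG sensor positions and sensing directions.

    ``sensor_type`` is ``"magnetometer"`` or ``"axial_gradiometer"``; axial
    gradiometers difference the field between the pickup coil and a second
    coil offset by ``baseline`` meters along the coil orientation.
    """

    positions: np.ndarray
    orientations: np.ndarray
    sensor_type: str = "magnetometer"
    baseline: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.positions.shape != self.orientations.shape:
            raise ParameterError("positions and orientations must match in shape")
        if not np.allclose(np.linalg.norm(self.orientations, axis=1), 1.0, atol=1e-9):
            raise ParameterError("sensor orientations must be unit vectors")
        if self.sensor_type not in ("magnetometer", "axial_gradiometer"):
            raise ParameterError(f"unknown sensor_type {self.sensor_type!r}")
        if self.sensor_type == "axial_gradiometer" and not (
            self.baseline and self.baseline > 0
        ):
            raise ParameterError("axial gradiometers need a positive baseline")

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


@dataclass
class LeadField:
    """Forward gain matrix: field per unit dipole moment.

    ``gain`` is (n_channels, n_sources); column *j* is the sensor pattern of
    a unit dipole at source *j* oriented along its vertex normal.
    """

    gain: np.ndarray
    source_space: SourceSpace
    sensor_array: SensorArray
    sphere_center: np.ndarray

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.sphere_center = np.asarray(self.sphere_center, dtype=float)
        if not np.all(np.isfinite(self.gain)):
            raise GeometryError("lead field contains non-finite entries")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class Patch:
    """A contiguous set of source vertices sharing one time series.

    ``member_vertices`` is stored in growth order (seed first); a point-like
    source is the degenerate patch {seed}.
    Areas are in cm² to match the study's factor levels.
    """

    seed_vertex: int
    member_vertices: np.ndarray
    target_area: float
    achieved_area: float

    def __post_init__(self) -> None:
        self.member_vertices = np.asarray(self.member_vertices, dtype=int)
        if self.seed_vertex not in self.member_vertices:
            raise ParameterError("seed vertex must belong to the patch")

    @property
    def members(self) -> np.ndarray:
        return self.member_vertices


def _vertex_normals_and_areas(
    vertices: np.ndarray, triangles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted vertex normals (outward from centroid) and lumped areas."""
    v = vertices
    t = triangles
    cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    tri_area = 0.5 * np.linalg.norm(cross, axis=1)
    if np.any(tri_area <= 0):
        raise MeshFormatError("mesh contains degenerate (zero-area) triangles")
    vertex_area = np.zeros(len(v))
    normals = np.zeros_like(v)
    for k in range(3):
        np.add.at(vertex_area, t[:, k], tri_area / 3.0)
        np.add.at(normals, t[:, k], cross)  # cross = 2·area·unit normal
    lengths = np.linalg.norm(normals, axis=1)
    if np.any(lengths == 0):
        raise MeshFormatError("mesh has a vertex with undefined normal")
    normals /= lengths[:, None]
    # re-orient outward from the centroid
    centroid = v.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, v - centroid) < 0
    normals[flip] *= -1.0
    return normals, vertex_area


def build_sphere_source_space(
    subdivision_level: int, radius: float, center=(0.0, 0.0, 0.0)
) -> SourceSpace:
    """Icosphere source space: 12 vertices at level 0, 10·4^L + 2 in general.

    Normals are exactly radial (outward from ``center``); vertex areas come
    from barycentric lumping of the flat triangles, so their sum slightly
    underestimates the analytic sphere area at coarse subdivision.
    """
    if subdivision_level < 0:
        raise ParameterError("subdivision_level must be >= 0")
    if radius <= 0:
        raise ParameterError("radius must be positive")
    mesh = trimesh.creation.icosphere(subdivisions=subdivision_level, radius=radius)
    vertices = np.asarray(mesh.vertices, dtype=float)
    triangles = np.asarray(mesh.faces, dtype=int)
    normals = vertices / np.linalg.norm(vertices, axis=1)[:, None]
    _, vertex_area = _vertex_normals_and_areas(vertices, triangles)
    return SourceSpace(vertices + np.asarray(center, float), triangles, normals, vertex_area)


def build_wrinkled_source_space(
    subdivision_level: int,
    radius: float,
    bump_amplitude: float = 0.1,
    center=(0.0, 0.0, 0.0),
) -> SourceSpace:
    """Icosphere with smooth deterministic radial corrugations.

    A source shell concentric with the conductor sphere would make every
    normal-constrained dipole exactly radial and hence magnetically silent;
    real cortex is folded, so source orientations vary.  This surface
    emulates that: the radius is modulated by a fixed smooth angular pattern
    (relative amplitude ``bump_amplitude``), tilting the mesh normals away
    from radial by up to ~40° while keeping all sources within
    ``radius·(1 + bump_amplitude)`` of the center.
    """
    if not 0 <= bump_amplitude < 1:
        raise ParameterError("bump_amplitude must lie in [0, 1)")
    base = build_sphere_source_space(subdivision_level, 1.0)
    u = base.vertex_positions
    f = (
        np.sin(4.0 * np.pi * u[:, 0] + 1.0)
        + np.sin(4.0 * np.pi * u[:, 1] + 2.0)
        + np.sin(4.0 * np.pi * u[:, 2] + 3.0)
    )
    f = f - f.mean()
    f = f / np.max(np.abs(f))
    r = radius * (1.0 + bump_amplitude * f)
    vertices = r[:, None] * u
    normals, vertex_area = _vertex_normals_and_areas(vertices, base.triangles)
    return SourceSpace(
        vertices + np.asarray(center, float), base.triangles, normals, vertex_area
    )


def _parse_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "v":
                if len(parts) < 4:
                    raise MeshFormatError(f"{path}: line {lineno}: malformed vertex record")
                try:
                    vertices.append([float(x) for x in parts[1:4]])
                except ValueError as exc:
                    raise MeshFormatError(
                        f"{path}: line {lineno}: non-numeric vertex coordinate"
                    ) from exc
            elif parts[0] == "f":
                idx = []
                for token in parts[1:]:
                    head = token.split("/")[0]
                    try:
                        i = int(head)
                    except ValueError as exc:
                        raise MeshFormatError(
                            f"{path}: line {lineno}: malformed face index {token!r}"
                        ) from exc
                    idx.append(i - 1 if i > 0 else len(vertices) + i)
                if len(idx) != 3:
                    raise UnsupportedMeshError(
                        f"{path}: line {lineno}: only triangular faces are supported "
                        f"(got {len(idx)} vertices)"
                    )
                faces.append(idx)
            # other OBJ records (vn, vt, o, g, s, usemtl ...) are ignored
    if not vertices or not faces:
        raise MeshFormatError(f"{path}: no vertices/faces found")
    return np.asarray(vertices, float), np.asarray(faces, int)


def _parse_freesurfer_ascii(path: Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        lines = fh.readlines()
    body = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if not ln.startswith("#")]
    body = [(n, ln) for n, ln in body if ln]
    try:
        counts = body[0][1].split()
        n_vert, n_tri = int(counts[0]), int(counts[1])
    except (IndexError, ValueError) as exc:
        raise MeshFormatError(f"{path}: missing vertex/triangle count header") from exc
    if len(body) - 1 < n_vert + n_tri:
        raise MeshFormatError(f"{path}: truncated file ({len(body)-1} records, "
                              f"expected {n_vert + n_tri})")
    vertices = np.empty((n_vert, 3))
    for row, (lineno, ln) in enumerate(body[1 : 1 + n_vert]):
        parts = ln.split()
        try:
            vertices[row] = [float(x) for x in parts[:3]]
        except (IndexError, ValueError) as exc:
            raise MeshFormatError(f"{path}: line {lineno}: malformed vertex record") from exc
    faces = np.empty((n_tri, 3), dtype=int)
    for row, (lineno, ln) in enumerate(body[1 + n_vert : 1 + n_vert + n_tri]):
        parts = ln.split()
        try:
            faces[row] = [int(x) for x in parts[:3]]
        except (IndexError, ValueError) as exc:
            raise MeshFormatError(f"{path}: line {lineno}: malformed face record") from exc
    return vertices, faces


def load_mesh(path) -> SourceSpace:
    """Load a triangle mesh (Wavefront OBJ or FreeSurfer ASCII ``.asc``).

    Normals are area-weighted averages of incident triangle normals,
    re-oriented to point away from the mesh centroid.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if path.suffix.lower() == ".asc" or first.startswith("#!ascii"):
        vertices, triangles = _parse_freesurfer_ascii(path)
    else:
        vertices, triangles = _parse_obj(path)
    if triangles.min(initial=0) < 0 or triangles.max(initial=-1) >= len(vertices):
        raise MeshFormatError(f"{path}: face index out of range")
    normals, vertex_area = _vertex_normals_and_areas(vertices, triangles)
    return SourceSpace(vertices, triangles, normals, vertex_area)


def build_sensor_cap(
    n_sensors: int,
    shell_radius: float,
    coverage_fraction: float,
    center=(0.0, 0.0, 0.0),
    sensor_type: str = "magnetometer",
    baseline: float | None = None,
    conductor_radius: float | None = None,
) -> SensorArray:
    """Quasi-uniform (Fibonacci lattice) radial sensors on an upper spherical cap.

    ``coverage_fraction`` is the fraction of the full sphere covered by the
    cap, centered on the +z pole: 1.0 covers the whole sphere, 0.5 the upper
    hemisphere.
    """
    if n_sensors < 1:
        raise ParameterError("n_sensors must be >= 1")
    if not (0 < coverage_fraction <= 1):
        raise ParameterError("coverage_fraction must lie in (0, 1]")
    if conductor_radius is not None and shell_radius <= conductor_radius:
        raise GeometryError("sensor shell must lie outside the conductor sphere")
    i = np.arange(n_sensors)
    z = 1.0 - 2.0 * coverage_fraction * (i + 0.5) / n_sensors
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    unit = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    positions = shell_radius * unit + np.asarray(center, float)
    return SensorArray(positions, unit, sensor_type=sensor_type, baseline=baseline)


def _sarvas_field(dip_pos: np.ndarray, dip_mom: np.ndarray, sens_pos: np.ndarray) -> np.ndarray:
    """Magnetic field of current dipoles in a spherical conductor.

    Positions are relative to the sphere center.  Returns B with shape
    (n_sensors, n_dipoles, 3) in tesla for moments in A·m.
    """
    r = sens_pos[:, None, :]
    r0 = dip_pos[None, :, :]
    q = dip_mom[None, :, :]
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=-1)
    rn = np.linalg.norm(sens_pos, axis=-1)[:, None]
    if np.any(a < 1e-12):
        raise SingularGeometryError("a dipole coincides with a sensor position")
    ar = np.einsum("csk,csk->cs", a_vec, np.broadcast_to(r, a_vec.shape))
    r0r = np.einsum("csk,csk->cs", np.broadcast_to(r0, a_vec.shape),
                    np.broadcast_to(r, a_vec.shape))
    F = a * (rn * a + rn**2 - r0r)
    if np.any(np.abs(F) < 1e-30):
        raise SingularGeometryError("singular Sarvas geometry (F = 0)")
    coef_r = a**2 / rn + ar / a + 2.0 * a + 2.0 * rn
    coef_r0 = a + 2.0 * rn + ar / a
    gradF = coef_r[..., None] * r - coef_r0[..., None] * r0
    qxr0 = np.cross(q, r0)
    qxr0_r = np.einsum("csk,csk->cs", np.broadcast_to(qxr0, gradF.shape),
                       np.broadcast_to(r, gradF.shape))
    return (
        MU0_OVER_4PI
        / F[..., None] ** 2
        * (F[..., None] * qxr0 - qxr0_r[..., None] * gradF)
    )


def compute_lead_field(
    ss: SourceSpace,
    sa: SensorArray,
    sphere_center=(0.0, 0.0, 0.0),
    conductor_radius: float | None = None,
) -> LeadField:
    """Single-sphere lead field with the cortical orientation constraint.

    Each source is a unit-moment dipole along its vertex normal; the Sarvas
    closed form gives its field at every sensor, projected on the sensor
    orientation.  Axial gradiometers subtract the field at the second coil
    (position + baseline·orientation).
    """
    center = np.asarray(sphere_center, dtype=float)
    dip_pos = ss.vertex_positions - center
    sens_pos = sa.positions - center
    dip_r = np.linalg.norm(dip_pos, axis=1)
    sens_r = np.linalg.norm(sens_pos, axis=1)
    if np.any(dip_r < 1e-9):
        raise SingularGeometryError("a source lies at the sphere center")
    if conductor_radius is not None:
        if np.any(dip_r >= conductor_radius):
            raise GeometryError("all sources must lie strictly inside the conductor")
        if np.any(sens_r <= conductor_radius):
            raise GeometryError("all sensors must lie strictly outside the conductor")
    elif np.any(sens_r <= dip_r.max()):
        raise GeometryError("sensors must lie outside the source shell")

    B = _sarvas_field(dip_pos, ss.normals, sens_pos)
    gain = np.einsum("csk,ck->cs", B, sa.orientations)
    if sa.sensor_type == "axial_gradiometer":
        far_pos = sens_pos + sa.baseline * sa.orientations
        B_far = _sarvas_field(dip_pos, ss.normals, far_pos)
        gain = gain - np.einsum("csk,ck->cs", B_far, sa.orientations)
    return LeadField(gain, ss, sa, center)


def normalize_lead_field(lf: LeadField) -> LeadField:
    """Rescale the gain by one global scalar: the median source column norm.

    Removes the arbitrary physical amplitude scale (tesla per unit dipole
    moment) so that regularization weights are comparable across geometries,
    without introducing per-source depth weighting.
    """
    col_norms = np.linalg.norm(lf.gain, axis=0)
    scale = float(np.median(col_norms))
    if scale <= 0:
        raise GeometryError("cannot normalize an all-zero lead field")
    return LeadField(lf.gain / scale, lf.source_space, lf.sensor_array, lf.sphere_center)


def grow_patch(ss: SourceSpace, seed: int, target_area: float) -> Patch:
    """Grow a patch of ~``target_area`` cm² around ``seed`` by mesh-ring growth.

    Vertices join in order of (edge-hop distance, Euclidean distance to the
    seed, index); growth stops as soon as the accumulated vertex area reaches
    the target, so removing the last-added vertex would drop it below.
    ``target_area == 0`` yields a point-like source.
    """
    if not 0 <= seed < ss.n_vertices:
        raise ParameterError(f"seed vertex {seed} out of range")
    if target_area < 0:
        raise ParameterError("target_area must be >= 0")
    total_cm2 = ss.total_area * 1e4
    if target_area > total_cm2:
        raise InsufficientMeshError(
            f"target area {target_area} cm² exceeds total mesh area {total_cm2:.2f} cm²"
        )
    area_cm2 = ss.vertex_area * 1e4
    members = [seed]
    achieved = float(area_cm2[seed])
    if target_area <= 0:
        return Patch(seed, np.array(members), target_area, achieved)

    # stop once the accumulated area reaches the target, with a relative
    # slack absorbing float accumulation error on uniform meshes
    stop_at = target_area * (1.0 - 1e-9)
    adjacency = ss.adjacency()
    pos = ss.vertex_positions
    visited = {seed}
    frontier = [seed]
    hop = 0
    while achieved < stop_at:
        hop += 1
        ring = sorted(
            {v for u in frontier for v in adjacency[u] if v not in visited}
        )
        if not ring:
            break  # component exhausted; cannot happen when target <= total area
        dist = np.linalg.norm(pos[ring] - pos[seed], axis=1)
        for d, v in sorted(zip(dist, ring)):
            visited.add(v)
            members.append(v)
            achieved += float(area_cm2[v])
            if achieved >= stop_at:
                break
        frontier = ring
    if achieved < stop_at:
        raise InsufficientMeshError(
            f"mesh component around seed {seed} has only {achieved:.2f} cm²"
        )
    return Patch(seed, np.array(members), target_area, achieved)


def write_obj(ss: SourceSpace, path) -> None:
    """Export the source space as a Wavefront OBJ file (1-based indices)."""
    with open(path, "w") as fh:
        fh.write("# megcoh source space export\n")
        for x, y, z in ss.vertex_positions:
            fh.write(f"v {x:.9g} {y:.9g} {z:.9g}\n")
        for a, b, c in ss.triangles:
            fh.write(f"f {a + 1} {b + 1} {c + 1}\n")


def write_sensor_table(sa: SensorArray, path) -> None:
    """Plain-text sensor table: x y z ox oy oz, one row per channel."""
    table = np.hstack([sa.positions, sa.orientations])
    header = "x\ty\tz\tox\toy\toz"
    np.savetxt(path, table, delimiter="\t", header=header, comments="")
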