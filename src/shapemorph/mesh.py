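"""Triangle-mesh data model and discrete surface geometry.

Surfaces are closed, consistently oriented triangle meshes with vertex
coordinates in millimetres.  All structures analysed by this package live on a
single *template* parameterization: every subject surface shares the template's
face list, so vertex ``k`` denotes the same anatomical location on every
subject (vertex correspondence is declared, never estimated here).

The central quantity is the per-vertex *deformation marker*: the ratio of the
discrete surface-area element of a subject surface to that of the template.
It is the surface analogue of the Jacobian determinant of a template-to-subject
deformation — a marker above 1 (log above 0) means local surface expansion in
the subject relative to the template, below 1 means local atrophy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "TriangleMesh",
    "SubregionLabeling",
    "MarkerField",
    "MeshValidationError",
    "CorrespondenceError",
    "vertex_areas",
    "mesh_volume",
    "vertex_normals",
    "smooth_field",
    "deformation_marker",
    "compute_marker_field",
]


class MeshValidationError(ValueError):
    """A surface failed closed-2-manifold validation.

    ``offending_edges`` lists the undirected edges (i, j) that break the
    "every edge shared by exactly two consistently oriented faces" rule.
    """

    def __init__(self, message: str, offending_edges: Sequence[tuple[int, int]] = ()):
        super().__init__(message)
        self.offending_edges = list(offending_edges)


class CorrespondenceError(ValueError):
    """Two meshes claimed to be vertex-corresponded are not."""


@dataclass
class TriangleMesh:
    """Closed, consistently oriented triangle surface.

    Parameters
    ----------
    vertices : (N, 3) float array
        Vertex coordinates in mm.
    faces : (M, 3) int array
        0-based vertex indices per triangle, counter-clockwise when viewed
        from outside (outward orientation gives a positive enclosed volume).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        self.faces = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError(f"vertices must be (N, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError(f"faces must be (M, 3), got {self.faces.shape}")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshValidationError(
                f"face indices out of range [0, {len(self.vertices)})"
            )

    # -- basic properties ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    # -- validation ---------------------------------------------------------

    def validate(self, area_tol: float = 1e-12) -> "TriangleMesh":
        """Check closed-2-manifold structure; return self for chaining.

        Raises :class:`MeshValidationError` listing offending edges when the
        surface is open, non-manifold or inconsistently oriented; also rejects
        degenerate (zero-area) faces and unreferenced vertices.
        """
        referenced = np.zeros(self.n_vertices, dtype=bool)
        referenced[self.faces.ravel()] = True
        if not referenced.all():
            bad = np.flatnonzero(~referenced)
            raise MeshValidationError(f"unreferenced vertices: {bad[:10].tolist()}")

        fa = self.face_areas()
        if (fa <= area_tol).any():
            bad = np.flatnonzero(fa <= area_tol)
            raise MeshValidationError(f"degenerate (zero-area) faces: {bad[:10].tolist()}")

        # directed half-edges: each must occur exactly once and have its twin
        he = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        n = self.n_vertices
        code = he[:, 0].astype(np.int64) * n + he[:, 1]
        uniq, counts = np.unique(code, return_counts=True)
        offending: list[tuple[int, int]] = []
        if (counts > 1).any():
            for c in uniq[counts > 1][:10]:
                offending.append((int(c // n), int(c % n)))
            raise MeshValidationError(
                f"duplicated directed edges (non-manifold or inconsistent orientation): {offending}",
                offending,
            )
        twin = he[:, 1].astype(np.int64) * n + he[:, 0]
        missing = np.setdiff1d(code, twin)
        if missing.size:
            for c in missing[:10]:
                offending.append((int(c // n), int(c % n)))
            raise MeshValidationError(
                f"open surface: {missing.size} boundary edge(s), e.g. {offending}",
                offending,
            )
        return self

    # -- geometry -----------------------------------------------------------

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def vertex_areas(self) -> np.ndarray:
        return vertex_areas(self)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def volume(self) -> float:
        return mesh_volume(self, validate=False)

    def vertex_normals(self) -> np.ndarray:
        return vertex_normals(self)

    def edges(self) -> np.ndarray:
        """Unique undirected edges, (E, 2) with i < j."""
        he = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        he.sort(axis=1)
        return np.unique(he, axis=0)

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 vertex adjacency (one-ring graph)."""
        e = self.edges()
        n = self.n_vertices
        data = np.ones(len(e), dtype=np.float64)
        a = sparse.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
        a = a + a.T
        return a.tocsr()

    def mean_edge_length(self) -> float:
        e = self.edges()
        d = self.vertices[e[:, 0]] - self.vertices[e[:, 1]]
        return float(np.linalg.norm(d, axis=1).mean())


@dataclass
class SubregionLabeling:
    """Per-vertex assignment of each template vertex to one named subregion.

    ``labels[k]`` is a contiguous id starting at 0; ``names[id]`` is the
    subregion name (e.g. hippocampal "CA1" or amygdalar "basolateral").
    """

    labels: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.names = tuple(self.names)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        present = np.unique(self.labels)
        if present.size and (present[0] < 0 or present[-1] >= len(self.names)):
            raise ValueError("label ids must index into names")

    @property
    def n_subregions(self) -> int:
        return len(self.names)

    def mask(self, name: str) -> np.ndarray:
        if name not in self.names:
            raise KeyError(f"unknown subregion {name!r}; have {self.names}")
        return self.labels == self.names.index(name)

    def check_matches(self, mesh: TriangleMesh) -> None:
        if len(self.labels) != mesh.n_vertices:
            raise ValueError(
                f"labeling covers {len(self.labels)} vertices, mesh has {mesh.n_vertices}"
            )


@dataclass
class MarkerField:
    """Per-vertex deformation markers for a cohort on one shared template.

    ``values`` is (N_vertices, N_subjects); column ``s`` is subject ``s``'s
    marker against the template, in the order of ``subject_ids`` (aligned with
    the cohort table).  ``log_scale`` says whether values are natural logs of
    the area ratio (the default scale for statistics) or the raw ratio.
    """

    values: np.ndarray
    subject_ids: tuple[str, ...]
    log_scale: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.subject_ids = tuple(self.subject_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_vertices, n_subjects)")
        if self.values.shape[1] != len(self.subject_ids):
            raise ValueError("one column per subject required")
        if not self.log_scale and (self.values <= 0).any():
            raise ValueError("raw markers must be strictly positive")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# geometric measures


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Barycentric vertex area: one third of the incident triangle areas (mm^2).

    Sums over vertices to the total surface area exactly.
    """
    fa = mesh.face_areas()
    va = np.zeros(mesh.n_vertices)
    third = fa / 3.0
    for c in range(3):
        np.add.at(va, mesh.faces[:, c], third)
    return va


def mesh_volume(mesh: TriangleMesh, validate: bool = True) -> float:
    """Signed enclosed volume by the divergence theorem (mm^3).

    Positive for outward-oriented closed surfaces.  With ``validate`` the mesh
    is first checked to be closed (an open surface has no enclosed volume).
    """
    if validate:
        mesh.validate()
    v = mesh.vertices
    f = mesh.faces
    return float(np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0)


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Unit outward vertex normals (area-weighted average of face normals)."""
    v = mesh.vertices
    f = mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # 2*area-weighted
    vn = np.zeros_like(v)
    for c in range(3):
        np.add.at(vn, f[:, c], fn)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return vn / norm


def smooth_field(
    mesh: TriangleMesh,
    values: np.ndarray,
    iterations: int,
    weight: float = 0.5,
) -> np.ndarray:
    """Iterated convex one-ring averaging of a per-vertex field.

    Each iteration replaces ``f`` by ``(1-w) f + w * mean(f over neighbours)``.
    Constant fields are fixed points and the output range is contained in the
    input range (discrete maximum principle).  ``iterations=0`` is the
    identity.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not (0.0 < weight <= 1.0):
        raise ValueError("weight must be in (0, 1]")
    f = np.asarray(values, dtype=np.float64).copy()
    if f.shape[0] != mesh.n_vertices:
        raise ValueError("field length must equal vertex count")
    if iterations == 0:
        return f
    adj = mesh.adjacency()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    for _ in range(iterations):
        avg = adj @ f
        if f.ndim == 1:
            avg = avg / deg
        else:
            avg = avg / deg[:, None]
        f = (1.0 - weight) * f + weight * avg
    return f


def deformation_marker(
    template: TriangleMesh,
    subject: TriangleMesh,
    log_scale: bool = False,
) -> np.ndarray:
    """Per-vertex surface-area-element ratio of subject to template.

    The discrete surface analogue of the Jacobian determinant of the
    template-to-subject deformation: marker > 1 (log > 0) is local expansion,
    < 1 (log < 0) local atrophy.  Requires declared vertex correspondence —
    identical face lists and vertex counts.
    """
    if subject.n_vertices != template.n_vertices or not np.array_equal(
        subject.faces, template.faces
    ):
        raise CorrespondenceError(
            "subject is not vertex-corresponded to template (face lists differ)"
        )
    ratio = vertex_areas(subject) / vertex_areas(template)
    return np.log(ratio) if log_scale else ratio


def compute_marker_field(
    template: TriangleMesh,
    subjects: Sequence[TriangleMesh],
    subject_ids: Sequence[str] | None = None,
    log_scale: bool = True,
) -> MarkerField:
    """Assemble the (vertices x subjects) deformation-marker matrix.

    Statistics default to the log scale, which treats expansion and
    contraction symmetrically.
    """
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(len(subjects))]
    va_t = vertex_areas(template)
    cols = []
    for subj in subjects:
        if subj.n_vertices != template.n_vertices or not np.array_equal(
            subj.faces, template.faces
        ):
            raise CorrespondenceError("all subjects must share the template face list")
        cols.append(vertex_areas(subj) / va_t)
    values = np.column_stack(cols) if cols else np.empty((template.n_vertices, 0))
    if log_scale:
        values = np.log(values)
    return MarkerField(values=values, subject_ids=tuple(subject_ids), log_scale=log_scale)
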