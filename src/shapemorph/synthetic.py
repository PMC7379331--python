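"""Synthetic cohort generator with planted, recoverable morphometric effects.

Real deformation-based morphometry pipelines hand this package a template
surface, a subregion parcellation and vertex-corresponded subject surfaces
produced by segmentation and diffeomorphic registration.  Those stages are out
of scope here, so this module manufactures the same objects with known ground
truth: anisotropic ellipsoid templates (subdivided icosahedra) partitioned
into four edge-connected subregions, and subject surfaces displaced along
vertex normals by

* a group effect — a spatially tapered inward contraction of fractional
  amplitude ``a`` on designated target subregions, applied to patients only
  (so a whole-structure effect contracts the surface like similarity scaling
  by ``1 - a`` and multiplies area elements by ``(1 - a)^2``);
* linear covariate effects (age, sex, intracranial volume), and
* a smooth zero-mean random displacement field.

The default cohort composition mirrors a first-episode schizophrenia (FES)
case-control study: 92 patients vs 106 healthy controls (HC), group-specific
age and sex distributions, and four structures (left/right amygdala and
hippocampus) each carrying four named subregions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csgraph

from .mesh import (
    MarkerField,
    SubregionLabeling,
    TriangleMesh,
    compute_marker_field,
    mesh_volume,
    smooth_field,
    vertex_normals,
)

__all__ = [
    "AMYGDALA_SUBREGIONS",
    "HIPPOCAMPUS_SUBREGIONS",
    "EffectSpec",
    "GroundTruth",
    "GroupModel",
    "StructureConfig",
    "CohortConfig",
    "SimulatedCohort",
    "make_template",
    "simulate_subject",
    "simulate_cohort",
    "effect_taper",
    "icosphere",
    "subregion_connected_components",
]

AMYGDALA_SUBREGIONS = ("basolateral", "basomedial", "centromedial", "lateral")
HIPPOCAMPUS_SUBREGIONS = ("CA1", "CA2", "CA3/DG", "subiculum")

# default covariate displacement coefficients (mm per covariate unit, applied
# along vertex normals); ICV is in mm^3 so 1e-6 mm/mm^3 gives ~0.15 mm per ICV SD
DEFAULT_COVARIATE_COEFFICIENTS: dict[str, float] = {
    "age": -0.01,
    "sex": 0.1,
    "icv": 1.0e-6,
}


# ---------------------------------------------------------------------------
# template geometry


def icosphere(subdivision_level: int = 3) -> TriangleMesh:
    """Unit sphere by recursive midpoint subdivision of an icosahedron.

    Level ``L`` has ``10 * 4**L + 2`` vertices (level 3: 642).
    """
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(subdivision_level):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            if key not in cache:
                m = vlist[i] + vlist[j]
                m = m / np.linalg.norm(m)
                cache[key] = len(vlist)
                vlist.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    mesh = TriangleMesh(verts, faces)
    if mesh.volume() < 0:  # enforce outward orientation
        mesh = TriangleMesh(verts, faces[:, ::-1])
    return mesh


def _subregion_names_for(structure_name: str) -> tuple[str, ...]:
    return HIPPOCAMPUS_SUBREGIONS if "hipp" in structure_name.lower() else AMYGDALA_SUBREGIONS


def make_template(
    structure_name: str,
    subdivision_level: int = 3,
    axis_lengths: Sequence[float] = (10.0, 7.0, 5.8),
    seed: int | np.random.SeedSequence | None = None,
    bend: float = 0.0,
    irregularity: float = 0.0,
) -> tuple[TriangleMesh, SubregionLabeling]:
    """Build a labeled ellipsoid template for one structure.

    The mesh is a subdivided icosahedron scaled anisotropically by
    ``axis_lengths`` (semi-axes in mm; axis 0 is the long axis).  Vertices are
    partitioned into four subregions by the anterior/posterior split along the
    long axis crossed with a medial/lateral split — four non-empty,
    edge-connected sectors.  Hippocampal templates may be curved with a gentle
    quadratic ``bend``; ``irregularity`` adds a small seeded smooth radial
    perturbation (fraction of the radius) so templates are not perfectly
    symmetric.

    Subregion names follow the structure: amygdalae get basolateral /
    basomedial / centromedial / lateral, hippocampi CA1 / CA2 / CA3-with-
    dentate-gyrus / subiculum.
    """
    if subdivision_level < 1:
        raise ValueError("subdivision_level must be >= 1")
    axis_lengths = np.asarray(axis_lengths, dtype=np.float64)
    if axis_lengths.shape != (3,) or (axis_lengths <= 0).any():
        raise ValueError(f"axis_lengths must be 3 positive semi-axes, got {axis_lengths}")

    sphere = icosphere(subdivision_level)
    unit = sphere.vertices
    radii = np.ones(len(unit))
    if irregularity > 0.0:
        rng = np.random.default_rng(seed)
        bump = smooth_field(sphere, rng.standard_normal(len(unit)), iterations=10)
        bump = (bump - bump.mean()) / max(bump.std(), 1e-12)
        radii = 1.0 + irregularity * bump
    verts = unit * radii[:, None] * axis_lengths
    if bend != 0.0:
        # quadratic banana bend of the long axis, recentred
        a = axis_lengths[0]
        verts = verts.copy()
        verts[:, 1] += bend * verts[:, 0] ** 2 / a
        verts[:, 1] -= verts[:, 1].mean()
    mesh = TriangleMesh(verts, sphere.faces).validate()

    # angular sectors on the reference sphere: anterior/posterior x medial/lateral
    labels = np.where(unit[:, 0] >= 0, 0, 2) + np.where(unit[:, 1] >= 0, 0, 1)
    labeling = SubregionLabeling(labels, _subregion_names_for(structure_name))
    return mesh, labeling


def subregion_connected_components(mesh: TriangleMesh, labeling: SubregionLabeling) -> dict[str, int]:
    """Number of edge-connected components of each subregion's vertex set."""
    adj = mesh.adjacency()
    out = {}
    for i, name in enumerate(labeling.names):
        idx = np.flatnonzero(labeling.labels == i)
        if idx.size == 0:
            out[name] = 0
            continue
        sub = adj[np.ix_(idx, idx)]
        ncomp, _ = csgraph.connected_components(sub, directed=False)
        out[name] = int(ncomp)
    return out


# ---------------------------------------------------------------------------
# effect specification and ground truth


@dataclass(frozen=True)
class EffectSpec:
    """Planted group/covariate effect for one structure.

    ``atrophy_amplitude`` is the fractional linear contraction in [0, 1)
    applied (tapered) to patients on ``target_subregions``;
    ``spatial_smoothness`` is the correlation length in mm used both for the
    boundary taper of the effect and for the noise field; covariate
    coefficients are mm of normal displacement per (centred) covariate unit;
    ``noise_sd`` is the SD in mm of the smooth random displacement field.
    """

    target_subregions: frozenset[str] = frozenset()
    atrophy_amplitude: float = 0.0
    spatial_smoothness: float = 3.0
    covariate_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_COEFFICIENTS)
    )
    noise_sd: float = 0.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_subregions", frozenset(self.target_subregions))
        if not (0.0 <= self.atrophy_amplitude < 1.0):
            raise ValueError("atrophy_amplitude must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spatial_smoothness < 0:
            raise ValueError("spatial_smoothness must be >= 0")

    def check_against(self, labeling: SubregionLabeling) -> None:
        unknown = self.target_subregions - set(labeling.names)
        if unknown:
            raise ValueError(
                f"unknown target subregion(s) {sorted(unknown)}; structure has {labeling.names}"
            )


@dataclass
class GroundTruth:
    """What was planted, on the template parameterization.

    ``effect_mask`` is True wherever the tapered group effect is non-zero;
    ``expected_marker_shift`` is the expected FES-minus-HC difference of the
    log marker, ``2 log(1 - a * taper)`` (zero outside the mask).
    """

    effect_mask: np.ndarray
    expected_marker_shift: np.ndarray
    taper: np.ndarray
    target_subregions: frozenset[str]
    atrophy_amplitude: float

    def to_dict(self) -> dict:
        return {
            "target_subregions": sorted(self.target_subregions),
            "atrophy_amplitude": self.atrophy_amplitude,
            "effect_mask": self.effect_mask.astype(int).tolist(),
            "taper": self.taper.tolist(),
            "expected_marker_shift": self.expected_marker_shift.tolist(),
        }


def effect_taper(
    mesh: TriangleMesh,
    labeling: SubregionLabeling,
    target_subregions: frozenset[str] | set[str],
    smoothness: float,
) -> np.ndarray:
    """Smooth-step taper of the target-subregion indicator.

    Uses the signed graph-geodesic distance to the subregion boundary
    (positive inside the target set) and a cubic smoothstep over one
    correlation length ``smoothness`` centred on the boundary, so the planted
    effect fades from full strength half a length inside to zero half a
    length outside — no sharp crease, no mesh self-intersection.
    """
    target = np.zeros(mesh.n_vertices, dtype=bool)
    for name in target_subregions:
        target |= labeling.mask(name)
    if not target.any():
        return np.zeros(mesh.n_vertices)
    if target.all():
        return np.ones(mesh.n_vertices)
    if smoothness <= 0:
        return target.astype(np.float64)

    e = mesh.edges()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    from scipy import sparse

    n = mesh.n_vertices
    g = sparse.coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
    g = (g + g.T).tocsr()
    # distance from every vertex to the nearest vertex of the opposite set
    d_to_out = csgraph.dijkstra(g, indices=np.flatnonzero(~target), min_only=True)
    d_to_in = csgraph.dijkstra(g, indices=np.flatnonzero(target), min_only=True)
    signed = np.where(target, d_to_out, -d_to_in)
    s = np.clip(signed / smoothness + 0.5, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


# ---------------------------------------------------------------------------
# subject simulation


def _smooth_noise(
    mesh: TriangleMesh,
    rng: np.random.Generator,
    sd: float,
    correlation_length: float,
) -> np.ndarray:
    """Smooth zero-mean scalar field with SD ``sd`` (mm of normal displacement).

    White vertex noise is diffused by iterated one-ring averaging until its
    correlation length is roughly ``correlation_length`` (the iteration count
    scales with the squared length in edge units, as for a random walk), then
    re-standardized to the requested SD.
    """
    if sd == 0.0:
        return np.zeros(mesh.n_vertices)
    h = mesh.mean_edge_length()
    n_iter = int(np.ceil((correlation_length / h) ** 2)) if correlation_length > 0 else 0
    f = rng.standard_normal(mesh.n_vertices)
    f = smooth_field(mesh, f, iterations=n_iter)
    f = f - f.mean()
    scale = f.std()
    if scale < 1e-12:
        return np.zeros(mesh.n_vertices)
    return f / scale * sd


def simulate_subject(
    template: TriangleMesh,
    labeling: SubregionLabeling,
    group: int,
    covariates: Mapping[str, float],
    effect_spec: EffectSpec,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    taper: np.ndarray | None = None,
) -> TriangleMesh:
    """Displace the template along vertex normals into one subject surface.

    ``group`` is 1 for a patient (receives the planted contraction) and 0 for
    a control.  ``covariates`` should be centred at the cohort reference
    values — the coefficients act on deviations.  The subject shares the
    template's face list, so vertex correspondence holds by construction;
    the result is deterministic given the seed.
    """
    if group not in (0, 1):
        raise ValueError("group must be 0 (control) or 1 (patient)")
    labeling.check_matches(template)
    effect_spec.check_against(labeling)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    normals = vertex_normals(template)
    disp = np.zeros(template.n_vertices)

    for name, coef in effect_spec.covariate_coefficients.items():
        if name in covariates:
            disp += coef * float(covariates[name])

    disp += _smooth_noise(rng=rng, mesh=template, sd=effect_spec.noise_sd,
                          correlation_length=effect_spec.spatial_smoothness)

    if group == 1 and effect_spec.atrophy_amplitude > 0 and effect_spec.target_subregions:
        if taper is None:
            taper = effect_taper(
                template, labeling, effect_spec.target_subregions, effect_spec.spatial_smoothness
            )
        # inward contraction emulating local scaling by (1 - a*taper):
        # remove a*taper times the normal component of the position vector
        radial = np.einsum("ij,ij->i", template.vertices, normals)
        disp -= effect_spec.atrophy_amplitude * taper * radial

    return TriangleMesh(template.vertices + disp[:, None] * normals, template.faces)


# ---------------------------------------------------------------------------
# cohort configuration


@dataclass(frozen=True)
class GroupModel:
    """Sampling model for one group's demographics."""

    n: int
    age_mean: float
    age_sd: float
    male_fraction: float


@dataclass(frozen=True)
class StructureConfig:
    axis_lengths: tuple[float, float, float]
    bend: float = 0.0
    effect: EffectSpec = field(default_factory=EffectSpec)


def _default_structures(null: bool = False) -> dict[str, StructureConfig]:
    def eff(targets: set[str], amp: float) -> EffectSpec:
        if null:
            return EffectSpec()
        return EffectSpec(target_subregions=frozenset(targets), atrophy_amplitude=amp)

    return {
        "left_amygdala": StructureConfig(
            (10.0, 7.0, 5.8), effect=eff({"basolateral", "centromedial"}, 0.06)
        ),
        "right_amygdala": StructureConfig(
            (10.4, 7.1, 5.9), effect=eff({"basolateral", "centromedial"}, 0.10)
        ),
        "left_hippocampus": StructureConfig(
            (20.0, 7.0, 5.8), bend=0.25, effect=eff({"CA1", "CA2"}, 0.03)
        ),
        "right_hippocampus": StructureConfig(
            (20.2, 7.1, 5.85), bend=0.25, effect=eff({"CA1", "CA2"}, 0.06)
        ),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for a reproducible synthetic cohort.

    Defaults mirror the FES/HC study design this package targets: 92 patients
    (42 male, age 22.40 +/- 5.59 y) vs 106 controls (59 male, age
    23.68 +/- 4.04 y), intracranial volume ~ N(1.45e6, 1.5e5) mm^3 in both
    groups, four bilateral amygdalar/hippocampal structures with atrophy
    planted in the basolateral/centromedial and CA1/CA2 subregions.
    """

    fes: GroupModel = GroupModel(n=92, age_mean=22.40, age_sd=5.59, male_fraction=42 / 92)
    hc: GroupModel = GroupModel(n=106, age_mean=23.68, age_sd=4.04, male_fraction=59 / 106)
    icv_mean: float = 1.45e6
    icv_sd: float = 1.5e5
    structures: Mapping[str, StructureConfig] = field(default_factory=_default_structures)
    subdivision_level: int = 3
    irregularity: float = 0.02

    def __post_init__(self) -> None:
        if self.fes.n < 2 or self.hc.n < 2:
            raise ValueError("need at least 2 subjects per group")
        if not self.structures:
            raise ValueError("at least one structure required")

    @property
    def n_total(self) -> int:
        return self.fes.n + self.hc.n


def null_config(**overrides) -> CohortConfig:
    """A configuration with no planted group effect (global null)."""
    cfg = CohortConfig(structures=_default_structures(null=True))
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SimulatedCohort:
    """A generated cohort: templates, subject meshes, covariates, ground truth."""

    cohort: pd.DataFrame
    templates: dict[str, tuple[TriangleMesh, SubregionLabeling]]
    meshes: dict[str, list[TriangleMesh]]
    ground_truth: dict[str, GroundTruth]
    config: CohortConfig
    seed: int | None

    def marker_field(self, structure: str, log_scale: bool = True) -> MarkerField:
        template, _ = self.templates[structure]
        return compute_marker_field(
            template,
            self.meshes[structure],
            subject_ids=self.cohort["subject_id"].tolist(),
            log_scale=log_scale,
        )


def simulate_cohort(
    config: CohortConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> SimulatedCohort:
    """Draw a full cohort: demographics, per-structure subject surfaces, volumes.

    Patients are listed first, then controls.  Ages and ICV are Gaussian per
    the group models, sex is Bernoulli (1 = male).  Covariate displacement
    acts on deviations from the cohort-level expected means, so the template
    represents the average head.  Structure volumes are measured from the
    generated meshes.  The same (config, seed) pair reproduces the cohort
    bit-identically.
    """
    config = config or CohortConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_int = None if isinstance(seed, np.random.SeedSequence) else seed
    demo_ss, template_ss, subject_ss = ss.spawn(3)

    rng = np.random.default_rng(demo_ss)
    rows = []
    for group, gm, prefix in ((1, config.fes, "FES"), (0, config.hc, "HC")):
        age = rng.normal(gm.age_mean, gm.age_sd, gm.n)
        sex = (rng.random(gm.n) < gm.male_fraction).astype(int)
        icv = rng.normal(config.icv_mean, config.icv_sd, gm.n)
        for i in range(gm.n):
            rows.append(
                {
                    "subject_id": f"{prefix}{i + 1:03d}",
                    "group": group,
                    "age": age[i],
                    "sex": int(sex[i]),
                    "icv_mm3": icv[i],
                }
            )
    cohort = pd.DataFrame(rows)

    # centre covariates at the cohort-level expected values (not the sample
    # means, which would leak group composition into the template)
    n_tot = config.n_total
    ref = {
        "age": (config.fes.n * config.fes.age_mean + config.hc.n * config.hc.age_mean) / n_tot,
        "sex": (config.fes.n * config.fes.male_fraction + config.hc.n * config.hc.male_fraction)
        / n_tot,
        "icv": config.icv_mean,
    }

    templates: dict[str, tuple[TriangleMesh, SubregionLabeling]] = {}
    meshes: dict[str, list[TriangleMesh]] = {}
    truths: dict[str, GroundTruth] = {}
    t_children = template_ss.spawn(len(config.structures))
    s_children = subject_ss.spawn(len(config.structures))

    for (name, scfg), t_ss, s_ss in zip(config.structures.items(), t_children, s_children):
        template, labeling = make_template(
            name,
            subdivision_level=config.subdivision_level,
            axis_lengths=scfg.axis_lengths,
            bend=scfg.bend,
            irregularity=config.irregularity,
            seed=t_ss,
        )
        scfg.effect.check_against(labeling)
        if scfg.effect.atrophy_amplitude > 0 and scfg.effect.target_subregions:
            taper = effect_taper(
                template, labeling, scfg.effect.target_subregions, scfg.effect.spatial_smoothness
            )
        else:
            taper = np.zeros(template.n_vertices)
        truths[name] = GroundTruth(
            effect_mask=taper > 0,
            expected_marker_shift=2.0 * np.log1p(-scfg.effect.atrophy_amplitude * taper),
            taper=taper,
            target_subregions=scfg.effect.target_subregions,
            atrophy_amplitude=scfg.effect.atrophy_amplitude,
        )
        templates[name] = (template, labeling)

        subj_meshes = []
        volumes = np.empty(n_tot)
        per_subject = s_ss.spawn(n_tot)
        for i, (row, subj_seed) in enumerate(zip(cohort.itertuples(index=False), per_subject)):
            cov = {
                "age": row.age - ref["age"],
                "sex": row.sex - ref["sex"],
                "icv": row.icv_mm3 - ref["icv"],
            }
            m = simulate_subject(
                template,
                labeling,
                group=row.group,
                covariates=cov,
                effect_spec=scfg.effect,
                seed=np.random.default_rng(subj_seed),
                taper=taper,
            )
            subj_meshes.append(m)
            volumes[i] = mesh_volume(m, validate=False)
        meshes[name] = subj_meshes
        cohort[f"{name}_volume_mm3"] = volumes

    return SimulatedCohort(
        cohort=cohort,
        templates=templates,
        meshes=meshes,
        ground_truth=truths,
        config=config,
        seed=seed_int,
    )
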