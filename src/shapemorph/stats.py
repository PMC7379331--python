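"""Vertex-wise GLM with permutation-based family-wise error control.

The shape model at each template vertex ``k`` is the linear model

    J_k(s) = beta_{k,0} + beta_{k,1} * gamma(s) + sum_cov alpha_cov X_cov(s) + eps_k(s)

where ``J_k(s)`` is subject ``s``'s deformation marker at vertex ``k``,
``gamma(s)`` the binary group indicator (1 = patient, 0 = control) and
``X_cov`` the nuisance covariates (age, sex, intracranial volume by default).
The per-vertex null ``beta_{k,1} = 0`` is tested with the OLS t statistic, and
multiplicity over vertices is handled by max-statistic permutation inference:
each observed |t| is referred to the permutation distribution of the maximum
|t| over all vertices, which controls the family-wise error rate (FWER) at the
nominal level.  Permutation of nuisance-adjusted residuals (Freedman-Lane) is
the default scheme; plain group-label permutation is available.

Volume analysis uses the same machinery on the single z-scored volume
"vertex", with no multiplicity correction, plus pooled-SD Cohen's d effect
sizes.

The module exposes both function surfaces (``fit_vertex_glm``,
``permutation_fwer``, ...) and statsmodels-style model objects (``ShapeGLM``,
``VolumeGLM``) whose ``fit()`` returns a results object with a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .mesh import MarkerField

__all__ = [
    "DesignError",
    "build_design",
    "fit_vertex_glm",
    "permutation_fwer",
    "volume_zscore",
    "cohens_d",
    "cohens_d_from_samples",
    "volume_group_comparison",
    "VertexGLMFit",
    "VertexStatResult",
    "VolumeComparisonResult",
    "ShapeGLM",
    "ShapeGLMResults",
    "VolumeGLM",
    "PERMUTATION_SCHEMES",
]

PERMUTATION_SCHEMES = ("freedman-lane", "label-permutation")


class DesignError(ValueError):
    """Invalid or rank-deficient design matrix."""


# ---------------------------------------------------------------------------
# design


def build_design(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "icv"),
    group_col: str = "group",
) -> tuple[np.ndarray, list[str]]:
    """Design matrix ``[intercept, group, covariates...]`` from a cohort table.

    Covariates are mean-centred (the group column is left as a 0/1
    indicator, so the intercept is the covariate-adjusted control mean).
    Accepts either bare covariate names or the cohort's column names
    (``icv`` resolves to ``icv_mm3`` when present).  Raises
    :class:`DesignError` naming collinear columns on rank deficiency.
    """
    if group_col not in cohort.columns:
        raise DesignError(f"cohort table lacks group column {group_col!r}")
    group = cohort[group_col].to_numpy(dtype=np.float64)
    uniq = np.unique(group)
    if not np.isin(uniq, (0.0, 1.0)).all() or uniq.size < 2:
        raise DesignError("group must be binary 0/1 with both groups present")

    cols = [np.ones(len(cohort)), group]
    names = ["intercept", group_col]
    for cov in covariates:
        col = cov if cov in cohort.columns else f"{cov}_mm3"
        if col not in cohort.columns:
            raise DesignError(f"covariate {cov!r} not found in cohort table")
        x = cohort[col].to_numpy(dtype=np.float64)
        if np.isnan(x).any():
            raise DesignError(f"covariate {cov!r} has missing values")
        cols.append(x - x.mean())
        names.append(cov)
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the first column that adds no rank
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise DesignError(f"design matrix is rank deficient; collinear column(s): {bad}")
    return X, names


# ---------------------------------------------------------------------------
# vertex-wise OLS


class VertexGLMFit(NamedTuple):
    """Per-vertex OLS estimates for one design."""

    beta: np.ndarray  # (p, V)
    tstat: np.ndarray  # (V,) t for the group coefficient
    se: np.ndarray  # (V,) SE of the group coefficient
    sigma2: np.ndarray  # (V,) residual variance
    df_resid: int


def _ols_group_t(
    X: np.ndarray,
    Y: np.ndarray,
    pinvX: np.ndarray,
    c_var: float,
    df: int,
    group_index: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised OLS over response columns; returns (beta, t, se, sigma2)."""
    beta = pinvX @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    # residual variance at pure roundoff level (e.g. a perfectly fitted or
    # constant marker) must not produce spurious t statistics
    response_scale = np.einsum("ij,ij->j", Y, Y) / df
    degenerate = sigma2 <= 1e-24 * np.maximum(response_scale, 1e-300)
    se = np.sqrt(np.maximum(sigma2 * c_var, 0.0))
    b1 = beta[group_index]
    ok = (se > 0) & ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ok, b1 / np.where(se > 0, se, 1.0), 0.0)
    return beta, t, se, sigma2


def fit_vertex_glm(
    marker_field: MarkerField | np.ndarray,
    design: np.ndarray,
    group_index: int = 1,
) -> VertexGLMFit:
    """Ordinary least squares at every vertex, vectorised.

    ``marker_field`` may be a :class:`MarkerField` or a raw
    (n_vertices, n_subjects) array; design rows must align with subjects.
    Results are numerically identical to fitting each vertex separately.
    A marker constant across subjects yields beta1 = 0 and t = 0 (guarded
    standard error).
    """
    values = marker_field.values if isinstance(marker_field, MarkerField) else np.asarray(marker_field)
    if values.ndim != 2:
        raise ValueError("marker values must be 2-D (vertices x subjects)")
    n, p = design.shape
    if values.shape[1] != n:
        raise ValueError(f"marker columns ({values.shape[1]}) != design rows ({n})")
    if n <= p:
        raise DesignError(f"need more subjects ({n}) than design columns ({p})")
    if np.linalg.matrix_rank(design) < p:
        raise DesignError("design matrix is rank deficient")

    Y = values.T  # (n, V)
    pinvX = np.linalg.pinv(design)
    xtx_inv = pinvX @ pinvX.T
    c_var = float(xtx_inv[group_index, group_index])
    df = n - p
    beta, t, se, sigma2 = _ols_group_t(design, Y, pinvX, c_var, df, group_index)
    return VertexGLMFit(beta=beta, tstat=t, se=se, sigma2=sigma2, df_resid=df)


# ---------------------------------------------------------------------------
# effect sizes


def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Pooled-SD standardized mean difference (mean1 - mean2) / s_pooled."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("degenerate pooled SD (both groups constant)")
    return float((mean1 - mean2) / pooled)


def cohens_d_from_samples(x1: np.ndarray, x2: np.ndarray) -> float:
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    return cohens_d(
        x1.mean(), x1.std(ddof=1), len(x1), x2.mean(), x2.std(ddof=1), len(x2)
    )


def _vertexwise_cohens_d(values: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Per-vertex pooled-SD d, sign = patient mean minus control mean."""
    g1 = values[:, group == 1]
    g0 = values[:, group == 0]
    n1, n0 = g1.shape[1], g0.shape[1]
    m1, m0 = g1.mean(axis=1), g0.mean(axis=1)
    v1 = g1.var(axis=1, ddof=1)
    v0 = g0.var(axis=1, ddof=1)
    pooled = np.sqrt(((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(pooled > 0, (m1 - m0) / np.where(pooled > 0, pooled, 1.0), 0.0)
    return d


# ---------------------------------------------------------------------------
# permutation inference


@dataclass
class VertexStatResult:
    """Per-vertex group-difference statistics with permutation-corrected p.

    ``p_fwer`` refers each observed |t| to the permutation distribution of
    the maximum |t| over vertices (single-step max-statistic FWER control);
    ``p_uncorrected`` is the per-vertex two-sided permutation p.  Both use
    the add-one estimator (b + 1) / (B + 1), so the attainable minimum is
    1 / (B + 1) and ties count as exceedances (conservative).
    """

    beta1: np.ndarray
    tstat: np.ndarray
    p_uncorrected: np.ndarray
    p_fwer: np.ndarray
    d: np.ndarray
    alpha: float
    n_permutations: int
    scheme: str
    max_null: np.ndarray  # (B,) permutation maxima, for diagnostics

    @property
    def significant(self) -> np.ndarray:
        return self.p_fwer <= self.alpha

    @property
    def n_vertices(self) -> int:
        return len(self.tstat)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex": np.arange(self.n_vertices),
                "beta1": self.beta1,
                "t": self.tstat,
                "p_unc": self.p_uncorrected,
                "p_fwer": self.p_fwer,
                "d": self.d,
                "significant": self.significant.astype(int),
            }
        )


def _draw_permutation(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random permutation, resampled if it is the identity."""
    idx = np.arange(n)
    while True:
        perm = rng.permutation(n)
        if n > 1 and np.array_equal(perm, idx):
            continue
        return perm


def permutation_fwer(
    marker_field: MarkerField | np.ndarray,
    design: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    alpha: float = 0.05,
    scheme: str = "freedman-lane",
    group_index: int = 1,
) -> VertexStatResult:
    """Vertex-wise GLM with max-statistic permutation FWER correction.

    Two-sided inference on the group coefficient: vertex ``k`` is declared
    significant when ``p_fwer(k) <= alpha`` with

        p_fwer(k) = (1 + #{b : max_j |t_b(j)| >= |t_obs(k)|}) / (B + 1).

    ``scheme`` is ``"freedman-lane"`` (permute nuisance-model residuals,
    covariate-safe; the default) or ``"label-permutation"`` (permute the
    group indicator).  Sampled uniformly with replacement, identity excluded;
    reproducible given ``seed``.
    """
    if scheme not in PERMUTATION_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {PERMUTATION_SCHEMES}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")

    values = marker_field.values if isinstance(marker_field, MarkerField) else np.asarray(marker_field)
    n, p = design.shape
    if n <= 2:
        raise ValueError("too few subjects to permute")
    obs = fit_vertex_glm(values, design, group_index)
    abs_t_obs = np.abs(obs.tstat)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Y = values.T
    pinvX = np.linalg.pinv(design)
    c_var = float((pinvX @ pinvX.T)[group_index, group_index])
    df = n - p

    if scheme == "freedman-lane":
        Z = np.delete(design, group_index, axis=1)
        pinvZ = np.linalg.pinv(Z)
        fitted = Z @ (pinvZ @ Y)
        resid = Y - fitted

    exceed_unc = np.zeros(values.shape[0], dtype=np.int64)
    max_null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = _draw_permutation(rng, n)
        if scheme == "freedman-lane":
            Yb = fitted + resid[perm]
            _, t_b, _, _ = _ols_group_t(design, Yb, pinvX, c_var, df, group_index)
        else:
            Xb = design.copy()
            Xb[:, group_index] = design[perm, group_index]
            pinvXb = np.linalg.pinv(Xb)
            c_var_b = float((pinvXb @ pinvXb.T)[group_index, group_index])
            _, t_b, _, _ = _ols_group_t(Xb, Y, pinvXb, c_var_b, df, group_index)
        abs_tb = np.abs(t_b)
        max_null[b] = abs_tb.max()
        exceed_unc += abs_tb >= abs_t_obs

    p_unc = (1.0 + exceed_unc) / (n_permutations + 1.0)
    exceed_max = (max_null[:, None] >= abs_t_obs[None, :]).sum(axis=0)
    p_fwer = (1.0 + exceed_max) / (n_permutations + 1.0)

    group = design[:, group_index]
    d = _vertexwise_cohens_d(values, group)
    return VertexStatResult(
        beta1=obs.beta[group_index].copy(),
        tstat=obs.tstat,
        p_uncorrected=p_unc,
        p_fwer=np.maximum(p_fwer, p_unc),
        d=d,
        alpha=alpha,
        n_permutations=n_permutations,
        scheme=scheme,
        max_null=max_null,
    )


# ---------------------------------------------------------------------------
# volumes


def volume_zscore(volumes: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Standardize volumes against the control group: (v - mean_HC) / sd_HC.

    The SD uses the n-1 denominator over controls only, so the control group
    itself maps to mean 0, SD 1.
    """
    volumes = np.asarray(volumes, dtype=np.float64)
    group = np.asarray(group)
    hc = volumes[group == 0]
    if len(hc) < 2:
        raise ValueError("need at least 2 control subjects for z-scoring")
    sd = hc.std(ddof=1)
    if sd == 0:
        raise ValueError("control volumes have zero variance")
    return (volumes - hc.mean()) / sd


@dataclass
class VolumeComparisonResult:
    """Group comparison of one structure's (z-scored) volume."""

    structure: str
    beta_group: float
    pvalue: float
    tstat: float
    cohens_d: float
    zscores: np.ndarray
    n_permutations: int
    scheme: str

    def summary(self) -> str:
        return (
            f"{self.structure}: beta_group(z) = {self.beta_group:+.4f}, "
            f"t = {self.tstat:+.3f}, perm p = {self.pvalue:.4g}, d = {self.cohens_d:+.3f}"
        )


def volume_group_comparison(
    cohort: pd.DataFrame,
    structure: str,
    covariates: Sequence[str] = ("age", "sex", "icv"),
    n_permutations: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    scheme: str = "freedman-lane",
) -> VolumeComparisonResult:
    """Volume GLM: same linear model and permutation machinery, one 'vertex'.

    The volume is z-scored against controls first; no multiplicity correction
    is needed for a single outcome, so the reported p is the per-outcome
    permutation p.
    """
    col = f"{structure}_volume_mm3" if f"{structure}_volume_mm3" in cohort.columns else structure
    if col not in cohort.columns:
        raise KeyError(f"no volume column for structure {structure!r}")
    group = cohort["group"].to_numpy()
    z = volume_zscore(cohort[col].to_numpy(dtype=np.float64), group)
    X, _ = build_design(cohort, covariates)
    res = permutation_fwer(
        z[None, :], X, n_permutations=n_permutations, seed=seed, scheme=scheme
    )
    d = cohens_d_from_samples(
        cohort.loc[group == 1, col].to_numpy(), cohort.loc[group == 0, col].to_numpy()
    )
    return VolumeComparisonResult(
        structure=structure,
        beta_group=float(res.beta1[0]),
        pvalue=float(res.p_uncorrected[0]),
        tstat=float(res.tstat[0]),
        cohens_d=d,
        zscores=z,
        n_permutations=n_permutations,
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# model objects


class ShapeGLM:
    """Vertex-wise shape model for a marker field and cohort table.

    Parameters
    ----------
    markers : MarkerField
        Deformation markers on the shared template (subjects aligned with
        the cohort rows).
    cohort : DataFrame
        Must contain ``group`` (1 = patient) and the requested covariates.
    covariates : sequence of str
        Nuisance covariates; default age, sex, intracranial volume.
    """

    def __init__(
        self,
        markers: MarkerField,
        cohort: pd.DataFrame,
        covariates: Sequence[str] = ("age", "sex", "icv"),
    ):
        if markers.n_subjects != len(cohort):
            raise ValueError("marker columns must align with cohort rows")
        self.markers = markers
        self.cohort = cohort.reset_index(drop=True)
        self.covariates = tuple(covariates)
        self.design, self.exog_names = build_design(self.cohort, self.covariates)

    def fit(
        self,
        n_permutations: int = 10_000,
        alpha: float = 0.05,
        seed: int | np.random.SeedSequence | None = None,
        scheme: str = "freedman-lane",
    ) -> "ShapeGLMResults":
        res = permutation_fwer(
            self.markers,
            self.design,
            n_permutations=n_permutations,
            seed=seed,
            alpha=alpha,
            scheme=scheme,
        )
        return ShapeGLMResults(self, res)


class ShapeGLMResults:
    """Results of a fitted :class:`ShapeGLM`.

    Exposes the per-vertex arrays of the underlying
    :class:`VertexStatResult` plus a structure-level summary.  The
    structure-level p reported by :attr:`structure_pvalue` is the minimum
    FWER-corrected vertex p — a conservative "any vertex significant"
    summary, labelled as such.
    """

    def __init__(self, model: ShapeGLM, result: VertexStatResult):
        self.model = model
        self._result = result

    @property
    def vertex_stats(self) -> VertexStatResult:
        return self._result

    beta1 = property(lambda self: self._result.beta1)
    tstat = property(lambda self: self._result.tstat)
    p_uncorrected = property(lambda self: self._result.p_uncorrected)
    p_fwer = property(lambda self: self._result.p_fwer)
    d = property(lambda self: self._result.d)
    significant = property(lambda self: self._result.significant)
    alpha = property(lambda self: self._result.alpha)

    @property
    def structure_pvalue(self) -> float:
        """Minimum FWER-corrected vertex p (structure-level summary)."""
        return float(self._result.p_fwer.min())

    def to_frame(self) -> pd.DataFrame:
        return self._result.to_frame()

    def summary(self) -> str:
        r = self._result
        sig = r.significant
        lines = [
            "Vertex-wise shape GLM (max-statistic permutation FWER)",
            f"  vertices: {r.n_vertices}   subjects: {self.model.design.shape[0]}",
            f"  design:   {' + '.join(self.model.exog_names)}",
            f"  scheme:   {r.scheme}   permutations: {r.n_permutations}   alpha: {r.alpha}",
            f"  significant vertices: {int(sig.sum())} ({100.0 * sig.mean():.2f}%)",
            f"  min p_fwer (structure-level): {self.structure_pvalue:.4g}",
        ]
        if sig.any():
            absd = np.abs(r.d[sig])
            sd = absd.std(ddof=1) if absd.size > 1 else float("nan")
            lines.append(f"  |d| over significant vertices: {absd.mean():.3f} +/- {sd:.3f}")
        return "\n".join(lines)


class VolumeGLM:
    """Volume model for one structure: z-scoring + GLM + permutation p."""

    def __init__(
        self,
        cohort: pd.DataFrame,
        structure: str,
        covariates: Sequence[str] = ("age", "sex", "icv"),
    ):
        self.cohort = cohort.reset_index(drop=True)
        self.structure = structure
        self.covariates = tuple(covariates)

    def fit(
        self,
        n_permutations: int = 10_000,
        seed: int | np.random.SeedSequence | None = None,
        scheme: str = "freedman-lane",
    ) -> VolumeComparisonResult:
        return volume_group_comparison(
            self.cohort,
            self.structure,
            covariates=self.covariates,
            n_permutations=n_permutations,
            seed=seed,
            scheme=scheme,
        )
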