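"""Pathway deregulation scores (PDS) from per-pathway principal curves.

For each pathway, the samples form a point cloud in the space spanned by the
pathway's member metabolites (z-scored against the control samples, then
optionally PCA-reduced). A principal curve — a smooth one-dimensional curve
through the middle of the cloud, self-consistent under projection — is fitted
with Hastie & Stuetzle's alternating projection/smoothing algorithm. Each
sample is projected onto the curve, and its deregulation score is the
arc-length distance from the curve's start (oriented so the control samples
sit at the low end) to the projection, normalized by the per-pathway maximum
so that scores lie in [0, 1]. Higher score = farther from the control state
of that pathway, for that individual sample.

Curves are fitted on training samples only and frozen; held-out samples are
standardized, projected and normalized with the stored parameters (scores
clipped to [0, 1]), so no test information leaks into the transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.nonparametric.smoothers_lowess import lowess

from .db import PathwayDatabase, PathwayRecord
from .errors import DegenerateCloudError, EmptyResultError, InputError, PathwaySkipped, ProfileFormatError

logger = logging.getLogger(__name__)


@dataclass
class MetaboliteProfile:
    """Metabolite×sample intensity matrix with a binary phenotype per sample.

    ``intensities`` rows are metabolites (HMDB accessions after mapping),
    columns are samples; ``phenotype`` is indexed by sample with exactly two
    levels, one of which is ``control_label``.
    """

    intensities: pd.DataFrame
    phenotype: pd.Series
    control_label: str

    def __post_init__(self):
        cols = list(self.intensities.columns)
        if len(set(cols)) != len(cols):
            raise ProfileFormatError("duplicate sample ids in intensity matrix")
        if list(self.phenotype.index) != cols:
            self.phenotype = self.phenotype.reindex(cols)
            if self.phenotype.isna().any():
                raise ProfileFormatError("phenotype missing for some samples")
        levels = self.phenotype.value_counts()
        if len(levels) != 2:
            raise ProfileFormatError(f"phenotype must have exactly 2 levels, got {len(levels)}")
        if self.control_label not in levels.index:
            raise ProfileFormatError(f"control label {self.control_label!r} absent from phenotype")
        if (levels < 2).any():
            raise ProfileFormatError("each phenotype level needs at least 2 samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def case_label(self) -> str:
        return next(l for l in self.phenotype.unique() if l != self.control_label)

    def subset_samples(self, sample_ids) -> "MetaboliteProfile":
        return MetaboliteProfile(
            self.intensities[list(sample_ids)],
            self.phenotype.loc[list(sample_ids)],
            self.control_label,
        )


@dataclass
class PdsConfig:
    """Tunables of the metabolite→pathway transform."""

    min_pathway_size: int = 3      # mapped members required to fit a curve
    use_pca: bool = True
    var_explained: float = 0.99    # variance retained by the PCA reduction
    tol: float = 1e-4              # relative objective change at convergence
    max_iter: int = 30
    smoother_span: float = 0.6     # LOWESS fraction for the coordinate smoother
    max_missing_rate: float = 0.2  # metabolites above this are dropped


# --------------------------------------------------------------------------
# missing-value policy: drop heavily missing metabolites, impute the rest at
# the metabolite's observed minimum (limit-of-detection convention)

def preprocess_missing(profile: MetaboliteProfile, max_missing_rate: float = 0.2) -> MetaboliteProfile:
    X = profile.intensities
    frac = X.isna().mean(axis=1)
    dropped = frac[frac > max_missing_rate].index
    if len(dropped):
        logger.warning("dropping %d metabolites with >%d%% missing values", len(dropped), int(100 * max_missing_rate))
        X = X.drop(index=dropped)
    if X.isna().any().any():
        X = X.apply(lambda row: row.fillna(row.min()), axis=1)
    X = X.dropna(axis=0, how="all")
    return MetaboliteProfile(X, profile.phenotype, profile.control_label)


# --------------------------------------------------------------------------
# the pathway point cloud

@dataclass
class PathwaySampleCloud:
    pathway_id: str
    points: np.ndarray            # samples × dims, after standardization (+ PCA)
    member_ids: list[str]         # metabolites retained after variance filtering
    standardized: np.ndarray      # samples × members, pre-PCA z-scores
    ctrl_mean: np.ndarray
    ctrl_sd: np.ndarray
    pca_mean: np.ndarray | None = None
    pca_components: np.ndarray | None = None  # dims × members


def build_cloud(profile: MetaboliteProfile, pathway: PathwayRecord, config: PdsConfig) -> PathwaySampleCloud:
    """Standardize the pathway's member intensities against controls and
    optionally PCA-reduce. Raises :class:`PathwaySkipped` when too few
    informative members remain."""
    members = sorted(pathway.members.intersection(profile.intensities.index))
    if len(members) < config.min_pathway_size:
        raise PathwaySkipped(pathway.pathway_id, "too_few_members")
    sub = profile.intensities.loc[members].T.to_numpy(dtype=float)  # samples × members
    ctrl = (profile.phenotype == profile.control_label).to_numpy()
    mean = sub[ctrl].mean(axis=0)
    sd = sub[ctrl].std(axis=0, ddof=0)
    keep = sd > 1e-12
    if keep.sum() < config.min_pathway_size:
        raise PathwaySkipped(pathway.pathway_id, "too_few_members_after_variance_filter")
    members = [m for m, k in zip(members, keep) if k]
    mean, sd, sub = mean[keep], sd[keep], sub[:, keep]
    Z = (sub - mean) / sd

    pca_mean = pca_components = None
    points = Z
    if config.use_pca and Z.shape[1] > 1:
        pca_mean = Z.mean(axis=0)
        Xc = Z - pca_mean
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        var = s**2
        total = var.sum()
        if total <= 1e-24:
            raise PathwaySkipped(pathway.pathway_id, "degenerate_cloud")
        k = int(np.searchsorted(np.cumsum(var) / total, config.var_explained) + 1)
        k = max(1, min(k, Xc.shape[1]))
        pca_components = Vt[:k]
        points = Xc @ pca_components.T
    return PathwaySampleCloud(
        pathway_id=pathway.pathway_id,
        points=points,
        member_ids=members,
        standardized=Z,
        ctrl_mean=mean,
        ctrl_sd=sd,
        pca_mean=pca_mean,
        pca_components=pca_components,
    )


# --------------------------------------------------------------------------
# principal curves (Hastie–Stuetzle)

@dataclass
class PrincipalCurve:
    """Piecewise-linear principal curve: ordered vertices with arc-length
    parameters starting at 0."""

    vertices: np.ndarray          # k × d
    lambdas: np.ndarray           # k, non-decreasing, lambdas[0] == 0
    converged: bool
    n_iter: int
    objective_path: list[float] = field(default_factory=list)

    @property
    def length(self) -> float:
        return float(self.lambdas[-1])


def _dedupe_vertices(vertices: np.ndarray) -> np.ndarray:
    if len(vertices) < 2:
        return vertices
    keep = np.ones(len(vertices), dtype=bool)
    diffs = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    keep[1:] = diffs > 1e-12
    return vertices[keep]


def _arclength(vertices: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _project_points(vertices: np.ndarray, lambdas: np.ndarray, points: np.ndarray):
    """Exact segment-wise projection of each point onto the polyline.

    Returns (arc-length coordinates, euclidean distances)."""
    points = np.atleast_2d(points)
    if len(vertices) == 1:
        d = np.linalg.norm(points - vertices[0], axis=1)
        return np.zeros(len(points)), d
    a = vertices[:-1]
    seg = vertices[1:] - a                              # (k-1, d)
    seglen2 = (seg**2).sum(axis=1)
    seglen = np.sqrt(seglen2)
    diff = points[:, None, :] - a[None, :, :]           # (n, k-1, d)
    t = np.einsum("nkd,kd->nk", diff, seg) / seglen2
    t = np.clip(t, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * seg[None, :, :]
    d2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    j = np.argmin(d2, axis=1)
    rows = np.arange(len(points))
    lam = lambdas[j] + t[rows, j] * seglen[j]
    return lam, np.sqrt(d2[rows, j])


def project_onto_curve(curve: PrincipalCurve, point: np.ndarray) -> tuple[float, float]:
    """Arc-length coordinate and distance of the nearest point on the curve."""
    lam, dist = _project_points(curve.vertices, curve.lambdas, np.asarray(point, float))
    return float(lam[0]), float(dist[0])


def fit_principal_curve(
    points: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 30,
    smoother_span: float = 0.6,
) -> PrincipalCurve:
    """Fit a principal curve by alternating projection and smoothing.

    Initialization projects onto the first principal-component line; each
    iteration smooths every coordinate as a function of the current arc-length
    parameter (LOWESS), re-projects all points onto the resulting polyline and
    re-parameterizes by cumulative arc length. A candidate curve is accepted
    only if it does not increase the total squared projection distance, so the
    objective is non-increasing and the final curve never does worse than the
    first-PC line. Stops when the relative objective change drops below
    ``tol`` or after ``max_iter`` iterations.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n, d = points.shape
    if n < 4:
        raise InputError(f"principal curve needs at least 4 points, got {n}")
    if np.allclose(points, points[0], atol=1e-12):
        raise DegenerateCloudError("all points identical")

    center = points.mean(axis=0)
    Xc = points - center
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    pc1 = Vt[0]
    lam0 = Xc @ pc1
    order = np.argsort(lam0, kind="stable")
    vertices = _dedupe_vertices(center + np.outer(lam0[order], pc1))
    if len(vertices) < 2:
        raise DegenerateCloudError("points project to a single location on the first PC")
    lambdas = _arclength(vertices)
    lam_cur, dist = _project_points(vertices, lambdas, points)
    objective = float((dist**2).sum())
    path = [objective]

    converged = objective <= 1e-20  # e.g. exactly collinear clouds
    it = 0
    while not converged and it < max_iter:
        it += 1
        order = np.argsort(lam_cur, kind="stable")
        lam_s = lam_cur[order]
        smoothed = np.column_stack(
            [
                lowess(points[order, j], lam_s, frac=smoother_span, it=0, return_sorted=False)
                for j in range(d)
            ]
        )
        cand_vertices = _dedupe_vertices(smoothed)
        if len(cand_vertices) < 2:
            break
        cand_lambdas = _arclength(cand_vertices)
        lam_new, dist_new = _project_points(cand_vertices, cand_lambdas, points)
        obj_new = float((dist_new**2).sum())
        if obj_new > objective:
            # smoothing stopped helping; keep the best curve so far
            converged = obj_new - objective <= tol * max(objective, 1e-12)
            break
        vertices, lambdas, lam_cur = cand_vertices, cand_lambdas, lam_new
        path.append(obj_new)
        if objective - obj_new <= tol * max(objective, 1e-12):
            converged = True
        objective = obj_new

    return PrincipalCurve(vertices=vertices, lambdas=lambdas, converged=converged, n_iter=it, objective_path=path)


# --------------------------------------------------------------------------
# the PDS matrix

@dataclass
class PathwayCurveModel:
    """Frozen per-pathway transform: standardization, PCA basis, curve,
    orientation and normalization constant."""

    pathway_id: str
    member_ids: list[str]
    ctrl_mean: np.ndarray
    ctrl_sd: np.ndarray
    pca_mean: np.ndarray | None
    pca_components: np.ndarray | None
    curve: PrincipalCurve
    flipped: bool
    lambda_max: float


@dataclass
class PDSModel:
    pathway_models: dict[str, PathwayCurveModel]
    control_label: str
    config: PdsConfig


@dataclass
class PDSMatrix:
    scores: pd.DataFrame                 # pathways × samples, values in [0, 1]
    skipped_pathways: list[tuple[str, str]]
    phenotype: pd.Series | None = None

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def _oriented_lambdas(curve: PrincipalCurve, points: np.ndarray, flipped: bool) -> np.ndarray:
    lam, _ = _project_points(curve.vertices, curve.lambdas, points)
    return curve.length - lam if flipped else lam


def fit_pds(
    profile: MetaboliteProfile,
    pathway_db: PathwayDatabase,
    config: PdsConfig | None = None,
) -> tuple[PDSMatrix, PDSModel]:
    """Fit per-pathway curves on ``profile`` and score its samples.

    Curves are oriented so the control-sample mean arc length sits at the low
    end, and scores are normalized by the per-pathway maximum (so the maximum
    over fit samples is exactly 1).
    """
    config = config or PdsConfig()
    profile = preprocess_missing(profile, config.max_missing_rate)
    ctrl = (profile.phenotype == profile.control_label).to_numpy()

    rows: dict[str, np.ndarray] = {}
    models: dict[str, PathwayCurveModel] = {}
    skipped: list[tuple[str, str]] = []
    for pathway in pathway_db.sorted_records():
        try:
            cloud = build_cloud(profile, pathway, config)
            curve = fit_principal_curve(
                cloud.points, tol=config.tol, max_iter=config.max_iter, smoother_span=config.smoother_span
            )
        except PathwaySkipped as exc:
            skipped.append((pathway.pathway_id, exc.reason))
            continue
        except DegenerateCloudError:
            skipped.append((pathway.pathway_id, "degenerate_cloud"))
            continue
        lam, _ = _project_points(curve.vertices, curve.lambdas, cloud.points)
        flipped = bool(lam[ctrl].mean() > lam[~ctrl].mean())
        if flipped:
            lam = curve.length - lam
        lam_max = float(lam.max())
        if lam_max <= 1e-12:
            skipped.append((pathway.pathway_id, "zero_spread"))
            continue
        rows[pathway.pathway_id] = lam / lam_max
        models[pathway.pathway_id] = PathwayCurveModel(
            pathway_id=pathway.pathway_id,
            member_ids=cloud.member_ids,
            ctrl_mean=cloud.ctrl_mean,
            ctrl_sd=cloud.ctrl_sd,
            pca_mean=cloud.pca_mean,
            pca_components=cloud.pca_components,
            curve=curve,
            flipped=flipped,
            lambda_max=lam_max,
        )
    if not rows:
        raise EmptyResultError("no pathway passed eligibility filters")
    scores = pd.DataFrame(rows, index=profile.sample_ids).T
    scores.index.name = "pathway_id"
    for pid, reason in skipped:
        logger.info("pathway %s skipped (%s)", pid, reason)
    matrix = PDSMatrix(scores=scores, skipped_pathways=skipped, phenotype=profile.phenotype)
    return matrix, PDSModel(pathway_models=models, control_label=profile.control_label, config=config)


def compute_pds(
    profile: MetaboliteProfile,
    pathway_db: PathwayDatabase,
    config: PdsConfig | None = None,
) -> PDSMatrix:
    """Fit-and-score convenience wrapper around :func:`fit_pds`."""
    matrix, _ = fit_pds(profile, pathway_db, config)
    return matrix


def score_new_samples(model: PDSModel, new_profile: MetaboliteProfile) -> PDSMatrix:
    """Score unseen samples with frozen curves and stored normalization.

    Applies the stored control-derived standardization and PCA basis,
    projects onto the frozen curve, applies the stored orientation and
    normalization constant, then clips to [0, 1]. Pathways whose member
    metabolites are missing from the new profile are skipped with a warning.
    """
    new_profile = preprocess_missing(new_profile, model.config.max_missing_rate)
    rows: dict[str, np.ndarray] = {}
    skipped: list[tuple[str, str]] = []
    for pid in sorted(model.pathway_models):
        pm = model.pathway_models[pid]
        missing = [m for m in pm.member_ids if m not in new_profile.intensities.index]
        if missing:
            logger.warning("pathway %s: members %s missing from new profile; skipped", pid, missing)
            skipped.append((pid, "missing_members"))
            continue
        sub = new_profile.intensities.loc[pm.member_ids].T.to_numpy(dtype=float)
        Z = (sub - pm.ctrl_mean) / pm.ctrl_sd
        pts = Z if pm.pca_components is None else (Z - pm.pca_mean) @ pm.pca_components.T
        lam = _oriented_lambdas(pm.curve, pts, pm.flipped)
        rows[pid] = np.clip(lam / pm.lambda_max, 0.0, 1.0)
    if not rows:
        raise EmptyResultError("no pathway could be scored on the new profile")
    scores = pd.DataFrame(rows, index=new_profile.sample_ids).T
    scores.index.name = "pathway_id"
    return PDSMatrix(scores=scores, skipped_pathways=skipped, phenotype=new_profile.phenotype)


# --------------------------------------------------------------------------
# ordering for heat maps

def cluster_for_heatmap(pds: PDSMatrix) -> tuple[list[str], list[str]]:
    """Row/column orders for a PDS heat map.

    Pathways are ordered by average-linkage hierarchical clustering on
    euclidean distances; samples are grouped by phenotype (controls first
    when a control level is known) and clustered within each group.
    """
    scores = pds.scores

    def _cluster_order(matrix: np.ndarray, labels: list[str]) -> list[str]:
        if len(labels) < 3:
            if len(labels) == 2 and np.allclose(matrix[0], matrix[1]):
                return labels
            return labels
        Z = linkage(pdist(matrix), method="average")
        return [labels[i] for i in leaves_list(Z)]

    row_order = _cluster_order(scores.to_numpy(), list(scores.index))
    if pds.phenotype is not None:
        col_order: list[str] = []
        for level in sorted(pds.phenotype.unique()):
            group = [s for s in scores.columns if pds.phenotype[s] == level]
            sub = scores[group].to_numpy().T
            col_order.extend(_cluster_order(sub, group))
    else:
        col_order = _cluster_order(scores.to_numpy().T, list(scores.columns))
    return row_order, col_order
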