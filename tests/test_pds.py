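import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from pdskit.db import PathwayRecord, build_pathway_db
from pdskit.errors import DegenerateCloudError, EmptyResultError, InputError, PathwaySkipped
from pdskit.pds import (
    MetaboliteProfile,
    PdsConfig,
    build_cloud,
    cluster_for_heatmap,
    compute_pds,
    fit_pds,
    fit_principal_curve,
    preprocess_missing,
    project_onto_curve,
    score_new_samples,
)


def make_profile(values: np.ndarray, metabolites, n_ctrl: int, seed_prefix: str = "s") -> MetaboliteProfile:
    n = values.shape[1]
    samples = [f"{seed_prefix}{i:03d}" for i in range(n)]
    labels = ["control"] * n_ctrl + ["case"] * (n - n_ctrl)
    return MetaboliteProfile(
        pd.DataFrame(values, index=metabolites, columns=samples),
        pd.Series(labels, index=samples),
        control_label="control",
    )


def pca_line_residual(points: np.ndarray) -> float:
    """Total squared distance to the first principal-component line, computed
    directly from the eigendecomposition of the covariance matrix."""
    X = points - points.mean(axis=0)
    cov = X.T @ X
    w, V = np.linalg.eigh(cov)
    direction = V[:, np.argmax(w)]
    coords = X @ direction
    return float((X**2).sum() - (coords**2).sum())


def dense_polyline_distance(vertices: np.ndarray, point: np.ndarray, n_dense: int = 2000) -> float:
    """Brute-force distance via dense resampling of the polyline."""
    seg = np.diff(vertices, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    total = lens.sum()
    ts = np.linspace(0, total, n_dense)
    cum = np.concatenate([[0], np.cumsum(lens)])
    pts = []
    for t in ts:
        j = min(np.searchsorted(cum, t, side="right") - 1, len(seg) - 1)
        frac = (t - cum[j]) / lens[j] if lens[j] > 0 else 0.0
        pts.append(vertices[j] + frac * seg[j])
    return float(np.min(np.linalg.norm(np.asarray(pts) - point, axis=1)))


class TestBuildCloud:
    def test_too_few_members_skipped(self, mini_pathway_db):
        rng = np.random.default_rng(0)
        profile = make_profile(rng.normal(size=(2, 10)), ["HMDB0000161", "HMDB0000056"], n_ctrl=5)
        with pytest.raises(PathwaySkipped, match="too_few_members"):
            build_cloud(profile, mini_pathway_db.pathways["PW0001"], PdsConfig())

    def test_control_standardization(self, mini_pathway_db):
        rng = np.random.default_rng(1)
        mets = ["HMDB0000122", "HMDB0000161", "HMDB0000056"]
        profile = make_profile(rng.normal(5, 2, size=(3, 20)), mets, n_ctrl=10)
        cloud = build_cloud(profile, mini_pathway_db.pathways["PW0001"], PdsConfig(use_pca=False))
        ctrl = cloud.standardized[:10]
        assert np.allclose(ctrl.mean(axis=0), 0, atol=1e-8)
        assert np.allclose(ctrl.std(axis=0, ddof=0), 1, atol=1e-8)

    def test_pca_rank_deficiency(self):
        """A duplicated member contributes no extra variance: the retained
        basis has at most 3 dimensions, matching the covariance rank."""
        rng = np.random.default_rng(2)
        base = rng.normal(size=(3, 30))
        values = np.vstack([base, base[0]])  # 4th member duplicates the 1st
        mets = [f"HMDB000000{i}" for i in range(1, 5)]
        pw = PathwayRecord("PWX", "dup", set(mets))
        profile = make_profile(values, mets, n_ctrl=15)
        cloud = build_cloud(profile, pw, PdsConfig(var_explained=0.99))
        Z = cloud.standardized - cloud.standardized.mean(axis=0)
        rank = np.linalg.matrix_rank(Z.T @ Z, tol=1e-8)
        assert cloud.points.shape[1] <= 3
        assert cloud.points.shape[1] <= rank

    def test_zero_variance_member_dropped(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(4, 20))
        values[3, :] = 7.0  # constant member
        mets = [f"HMDB000000{i}" for i in range(1, 5)]
        pw = PathwayRecord("PWX", "const", set(mets))
        cloud = build_cloud(make_profile(values, mets, n_ctrl=10), pw, PdsConfig())
        assert len(cloud.member_ids) == 3


class TestFitPrincipalCurve:
    def test_collinear_points_recovered_exactly(self):
        t = np.linspace(0, 5, 10)
        direction = np.array([1.0, 2.0, -0.5])
        points = np.outer(t, direction) + np.array([1.0, 0.0, 3.0])
        curve = fit_principal_curve(points)
        lam = np.array([project_onto_curve(curve, p)[0] for p in points])
        dist = np.array([project_onto_curve(curve, p)[1] for p in points])
        assert np.allclose(dist, 0, atol=1e-8)
        assert np.all(np.diff(lam) > 0)  # ordering along the line preserved
        assert curve.converged

    @pytest.mark.parametrize("seed", range(10))
    def test_never_worse_than_first_pc_line(self, seed):
        rng = np.random.default_rng(seed)
        points = rng.normal(size=(40, rng.integers(2, 5)))
        curve = fit_principal_curve(points)
        baseline = pca_line_residual(points)
        assert curve.objective_path[-1] <= baseline + 1e-8

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(42)
        theta = rng.uniform(0, np.pi / 2, 200)
        points = np.column_stack([np.cos(theta), np.sin(theta)]) + rng.normal(0, 0.05, (200, 2))
        curve = fit_principal_curve(points)
        path = np.array(curve.objective_path)
        assert np.all(np.diff(path) <= 1e-10)

    def test_quarter_circle_beats_pca_line(self):
        """On a curved cloud the fitted curve must fit strictly better than
        the straight first-PC line; both residuals measured by brute-force
        projection onto dense polylines."""
        rng = np.random.default_rng(7)
        theta = rng.uniform(0, np.pi / 2, 200)
        points = np.column_stack([np.cos(theta), np.sin(theta)]) + rng.normal(0, 0.05, (200, 2))
        curve = fit_principal_curve(points)
        # PCA line as a long dense polyline
        X = points - points.mean(axis=0)
        w, V = np.linalg.eigh(X.T @ X)
        direction = V[:, np.argmax(w)]
        extent = np.abs(X @ direction).max() * 1.5
        line = np.outer(np.array([-extent, extent]), direction) + points.mean(axis=0)
        curve_msd = np.mean([dense_polyline_distance(curve.vertices, p) ** 2 for p in points])
        line_msd = np.mean([dense_polyline_distance(line, p) ** 2 for p in points])
        assert curve_msd < line_msd

    def test_identical_points_rejected(self):
        with pytest.raises(DegenerateCloudError):
            fit_principal_curve(np.ones((10, 3)))

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            fit_principal_curve(np.random.default_rng(0).normal(size=(3, 2)))


class TestProjectOntoCurve:
    @pytest.fixture()
    def curve(self):
        rng = np.random.default_rng(5)
        theta = np.sort(rng.uniform(0, np.pi / 2, 50))
        points = np.column_stack([np.cos(theta), np.sin(theta)])
        return fit_principal_curve(points)

    def test_curve_endpoints(self, curve):
        lam0, d0 = project_onto_curve(curve, curve.vertices[0])
        lam1, d1 = project_onto_curve(curve, curve.vertices[-1])
        assert (lam0, d0) == (0.0, 0.0)
        assert lam1 == pytest.approx(curve.length)
        assert d1 == pytest.approx(0.0, abs=1e-12)

    def test_matches_dense_sampling_argmin(self, curve):
        rng = np.random.default_rng(9)
        max_seg = np.max(np.linalg.norm(np.diff(curve.vertices, axis=0), axis=1))
        n_dense = 1000
        seg = np.diff(curve.vertices, axis=0)
        lens = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0], np.cumsum(lens)])
        ts = np.linspace(0, cum[-1], n_dense)
        dense = []
        for t in ts:
            j = min(np.searchsorted(cum, t, side="right") - 1, len(seg) - 1)
            frac = (t - cum[j]) / lens[j] if lens[j] > 0 else 0.0
            dense.append(curve.vertices[j] + frac * seg[j])
        dense = np.asarray(dense)
        for _ in range(20):
            p = rng.normal(0.5, 0.5, size=2)
            lam, _ = project_onto_curve(curve, p)
            lam_dense = ts[np.argmin(np.linalg.norm(dense - p, axis=1))]
            assert abs(lam - lam_dense) <= max_seg + cum[-1] / n_dense


@pytest.fixture(scope="module")
def scored():
    from pdskit.simulate import SimulationConfig, generate_profile, generate_toy_db

    _, pdb = generate_toy_db(40, 8, 5, 2, seed=21, allow_overlap=False)
    config = SimulationConfig(
        n_cases=30, n_controls=30, n_metabolites=40, pathway_db=pdb,
        deregulated_pathways=["PW0001"], effect_size=2.0, seed=21,
    )
    profile, _ = generate_profile(config)
    matrix, model = fit_pds(profile, pdb)
    return profile, matrix, model


class TestComputePds:
    def test_score_contract(self, scored):
        _, matrix, _ = scored
        values = matrix.scores.to_numpy()
        assert values.min() >= 0.0 and values.max() <= 1.0
        assert np.allclose(matrix.scores.max(axis=1), 1.0)

    def test_perturbed_pathway_separates_case_from_control(self, scored):
        profile, matrix, _ = scored
        case = profile.phenotype == "case"
        gaps = matrix.scores.loc[:, case.values].mean(axis=1) - matrix.scores.loc[:, ~case.values].mean(axis=1)
        assert gaps["PW0001"] > 0
        assert gaps["PW0001"] == gaps.max()

    def test_location_shift_invariance(self, scored):
        profile, matrix, _ = scored
        from pdskit.simulate import generate_toy_db

        _, pdb = generate_toy_db(40, 8, 5, 2, seed=21, allow_overlap=False)
        shifted = profile.intensities.copy()
        shifted.iloc[0] = shifted.iloc[0] + 1234.5
        profile2 = MetaboliteProfile(shifted, profile.phenotype, "control")
        matrix2, _ = fit_pds(profile2, pdb)
        pd.testing.assert_frame_equal(matrix.scores, matrix2.scores)

    def test_duplicated_samples_get_identical_scores(self, mini_pathway_db):
        rng = np.random.default_rng(11)
        mets = ["HMDB0000122", "HMDB0000161", "HMDB0000056"]
        values = rng.normal(size=(3, 12))
        values = np.concatenate([values, values[:, :3]], axis=1)  # duplicate 3 samples
        samples = [f"s{i}" for i in range(12)] + [f"dup{i}" for i in range(3)]
        labels = ["control"] * 6 + ["case"] * 6 + ["control"] * 3
        profile = MetaboliteProfile(
            pd.DataFrame(values, index=mets, columns=samples),
            pd.Series(labels, index=samples),
            "control",
        )
        matrix = compute_pds(profile, mini_pathway_db)
        for i in range(3):
            np.testing.assert_allclose(matrix.scores[f"s{i}"], matrix.scores[f"dup{i}"])

    def test_collinear_cloud_scores_equal_normalized_position(self):
        """For an exactly collinear cloud the PDS is the normalized position
        along the line, oriented with controls at the low end."""
        t = np.array([0.0, 0.2, 0.5, 0.8, 1.0, 2.0, 2.5, 3.0, 4.0, 5.0])
        coeffs = np.array([1.0, -2.0, 0.5])
        values = np.outer(coeffs, t) + np.array([[3.0], [1.0], [0.0]])
        mets = ["HMDB0000001", "HMDB0000002", "HMDB0000003"]
        pdb = build_pathway_db([PathwayRecord("PW0001", "line", set(mets))])
        profile = make_profile(values, mets, n_ctrl=5)  # controls have the small t
        matrix = compute_pds(profile, pdb)
        expected = (t - t.min()) / (t.max() - t.min())
        np.testing.assert_allclose(matrix.scores.loc["PW0001"].to_numpy(), expected, atol=1e-8)

    def test_ineligible_pathways_reported(self, mini_pathway_db):
        rng = np.random.default_rng(13)
        mets = ["HMDB0000122", "HMDB0000161", "HMDB0000056"]
        profile = make_profile(rng.normal(size=(3, 16)), mets, n_ctrl=8)
        matrix = compute_pds(profile, mini_pathway_db)
        skipped = dict(matrix.skipped_pathways)
        assert skipped["PW0002"] == "too_few_members"
        assert skipped["PW0003"] == "too_few_members"
        assert set(matrix.scores.index) == {"PW0001", "PW0004"}

    def test_all_pathways_ineligible_raises(self, mini_pathway_db):
        rng = np.random.default_rng(14)
        profile = make_profile(rng.normal(size=(1, 10)), ["HMDB0000122"], n_ctrl=5)
        with pytest.raises(EmptyResultError):
            compute_pds(profile, mini_pathway_db)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(31)
    mets = ["HMDB0000122", "HMDB0000161", "HMDB0000056"]
    values = rng.normal(size=(3, 24))
    pdb = build_pathway_db([PathwayRecord("PW0001", "p", set(mets))])
    profile = make_profile(values, mets, n_ctrl=12)
    matrix, model = fit_pds(profile, pdb)
    return profile, pdb, matrix, model


class TestScoreNewSamples:
    def test_training_profile_reproduced(self, fitted):
        profile, _, matrix, model = fitted
        rescored = score_new_samples(model, profile)
        pd.testing.assert_frame_equal(rescored.scores, matrix.scores)

    def test_sample_identical_to_control_scores_identically(self, fitted):
        profile, _, matrix, model = fitted
        clone = profile.intensities.iloc[:, [0]].copy()
        clone.columns = ["clone"]
        picked = list(range(4)) + list(range(12, 16))  # 4 controls + 4 cases
        new = MetaboliteProfile(
            pd.concat([profile.intensities.iloc[:, picked], clone], axis=1),
            pd.Series(
                list(profile.phenotype.iloc[picked]) + [profile.phenotype.iloc[0]],
                index=list(profile.intensities.columns[picked]) + ["clone"],
            ),
            "control",
        )
        scored = score_new_samples(model, new)
        assert scored.scores.loc["PW0001", "clone"] == pytest.approx(
            matrix.scores.loc["PW0001", profile.intensities.columns[0]]
        )

    def test_extreme_sample_clipped_to_one(self, fitted):
        profile, _, _, model = fitted
        extreme = profile.intensities.copy() * 0 + profile.intensities.max(axis=1).to_numpy()[:, None] * 50
        new = MetaboliteProfile(extreme, profile.phenotype, "control")
        scored = score_new_samples(model, new)
        assert scored.scores.to_numpy().max() <= 1.0

    def test_missing_member_skips_pathway(self, fitted):
        profile, _, _, model = fitted
        truncated = MetaboliteProfile(
            profile.intensities.iloc[:2], profile.phenotype, "control"
        )
        with pytest.raises(EmptyResultError):
            score_new_samples(model, truncated)


class TestMissingValues:
    def test_heavily_missing_metabolite_dropped_and_rest_imputed(self):
        rng = np.random.default_rng(41)
        values = rng.normal(10, 1, size=(3, 10))
        frame = pd.DataFrame(values, index=["m1", "m2", "m3"], columns=[f"s{i}" for i in range(10)])
        frame.iloc[0, :5] = np.nan          # 50% missing -> dropped
        frame.iloc[1, 0] = np.nan           # 10% missing -> imputed at min
        profile = MetaboliteProfile(frame, pd.Series(["control"] * 5 + ["case"] * 5, index=frame.columns), "control")
        cleaned = preprocess_missing(profile, max_missing_rate=0.2)
        assert list(cleaned.intensities.index) == ["m2", "m3"]
        assert cleaned.intensities.loc["m2", "s0"] == pytest.approx(frame.loc["m2"].min())


class TestHeatmapOrdering:
    def test_identical_rows_adjacent(self):
        rng = np.random.default_rng(51)
        scores = pd.DataFrame(rng.uniform(size=(5, 8)), index=[f"PW{i}" for i in range(5)])
        scores.loc["PW4"] = scores.loc["PW0"]
        from pdskit.pds import PDSMatrix

        row_order, _ = cluster_for_heatmap(PDSMatrix(scores=scores, skipped_pathways=[]))
        assert abs(row_order.index("PW0") - row_order.index("PW4")) == 1

    def test_single_pathway(self):
        from pdskit.pds import PDSMatrix

        scores = pd.DataFrame([[0.1, 0.9]], index=["PW0"], columns=["a", "b"])
        row_order, col_order = cluster_for_heatmap(PDSMatrix(scores=scores, skipped_pathways=[]))
        assert row_order == ["PW0"]
        assert sorted(col_order) == ["a", "b"]

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(52)
        scores = pd.DataFrame(rng.uniform(size=(5, 6)), index=[f"PW{i}" for i in range(5)])
        Z = linkage(pdist(scores.to_numpy()), method="average")
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_samples_grouped_by_phenotype(self):
        from pdskit.pds import PDSMatrix

        rng = np.random.default_rng(53)
        cols = [f"s{i}" for i in range(8)]
        scores = pd.DataFrame(rng.uniform(size=(4, 8)), index=[f"PW{i}" for i in range(4)], columns=cols)
        pheno = pd.Series(["case"] * 4 + ["control"] * 4, index=cols)
        _, col_order = cluster_for_heatmap(PDSMatrix(scores=scores, skipped_pathways=[], phenotype=pheno))
        groups = [pheno[c] for c in col_order]
        assert groups == sorted(groups)  # one contiguous block per phenotype
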