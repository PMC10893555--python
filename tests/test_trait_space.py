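"""Signal-space PCA and convex-hull niche construction."""

import numpy as np
import pandas as pd
import pytest

import signalniche as sn
from signalniche.errors import (
    DataIntegrityError,
    DegenerateInputError,
    DegenerateNicheError,
)
from signalniche.synthetic import TRAIT_COLUMNS
from signalniche.trait_space import (
    SignalSpacePCA,
    polygon_centroid,
    shoelace_area,
)

from helpers import gift_wrap_hull, point_in_convex


def songs_frame(rows):
    return pd.DataFrame(rows, columns=["species", "status", "individual_id", *TRAIT_COLUMNS])


class TestPerMaleMeans:
    def test_single_song_identity(self):
        df = songs_frame([("A", "breeding", "A_1", 2.0, 5, 5000, 4000, 7000, 3000)])
        means = sn.per_male_means(df)
        assert len(means) == 1
        assert means.loc[0, "duration"] == 2.0
        assert means.loc[0, "peak_freq"] == 5000

    def test_two_song_average(self):
        df = songs_frame(
            [
                ("A", "breeding", "A_1", 1.0, 5, 5000, 4000, 7000, 3000),
                ("A", "breeding", "A_1", 3.0, 7, 5200, 4100, 7100, 3000),
            ]
        )
        means = sn.per_male_means(df)
        assert means.loc[0, "duration"] == pytest.approx(2.0)
        assert means.loc[0, "n_notes"] == pytest.approx(6.0)

    def test_matches_bruteforce_group_average(self, rng, demo_community):
        songs = demo_community["traits"]
        means = sn.per_male_means(songs)
        # independent oracle: per-individual python-loop averaging
        for ind in rng.choice(songs["individual_id"].unique(), size=10, replace=False):
            sub = songs[songs["individual_id"] == ind]
            got = means[means["individual_id"] == ind].iloc[0]
            for col in TRAIT_COLUMNS:
                assert got[col] == pytest.approx(sum(sub[col]) / len(sub), rel=1e-12)

    def test_individual_under_two_species_rejected(self):
        df = songs_frame(
            [
                ("A", "breeding", "X_1", 1.0, 5, 5000, 4000, 7000, 3000),
                ("B", "migrant", "X_1", 1.0, 5, 5000, 4000, 7000, 3000),
            ]
        )
        with pytest.raises(DataIntegrityError):
            sn.per_male_means(df)


class TestSignalSpacePCA:
    def test_perfectly_correlated_traits_rank_one(self, rng):
        base = rng.normal(size=40)
        X = pd.DataFrame({c: base for c in TRAIT_COLUMNS})
        with pytest.warns(UserWarning):
            est = SignalSpacePCA().fit(X)
        assert est.eigenvalues_full_[0] == pytest.approx(6.0, abs=1e-8)
        assert np.allclose(est.eigenvalues_full_[1:], 0.0, atol=1e-8)
        assert est.n_components_ == 1
        assert est.explained_fraction_[0] == pytest.approx(1.0)

    def test_identity_correlation_retains_nothing(self, rng):
        # columns orthogonalized exactly -> sample correlation = identity
        M = rng.normal(size=(30, 6))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        X = pd.DataFrame(Q, columns=TRAIT_COLUMNS)
        with pytest.warns(UserWarning):
            est = SignalSpacePCA().fit(X)
        assert np.allclose(est.eigenvalues_full_, 1.0, atol=1e-8)
        assert est.n_components_ == 0  # strict > 1 rule

    def test_two_trait_closed_form(self, rng):
        # sample correlation exactly 0.5 -> eigenvalues 1.5 and 0.5
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=1)
        z -= z.mean()
        z -= x * (x @ z) / (x @ x)  # orthogonal to x
        z /= z.std(ddof=1)
        y = 0.5 * x + np.sqrt(1 - 0.25) * z
        X = pd.DataFrame({"a": x, "b": y})
        with pytest.warns(UserWarning):
            est = SignalSpacePCA(trait_columns=["a", "b"]).fit(X)
        assert est.eigenvalues_full_ == pytest.approx([1.5, 0.5], abs=1e-10)

    def test_constant_column_raises_naming_column(self, demo_community):
        means = demo_community["means"].copy()
        means["duration"] = 1.0
        with pytest.raises(DegenerateInputError, match="duration"):
            SignalSpacePCA().fit(means)

    def test_full_projection_reconstructs_standardized_data(self, demo_community):
        means = demo_community["means"]
        est = SignalSpacePCA().fit(means)
        M = means[list(TRAIT_COLUMNS)].to_numpy()
        Z = (M - est.mean_) / est.scale_
        recon = (Z @ est.loadings_full_) @ est.loadings_full_.T
        assert np.allclose(recon, Z, atol=1e-8)

    def test_score_columns_centered_with_eigenvalue_variance(self, demo_community):
        space = demo_community["space"]
        for j, col in enumerate(space.score_columns):
            assert space.scores[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert space.scores[col].var(ddof=1) == pytest.approx(
                space.eigenvalues[j], rel=1e-8
            )
        assert space.eigenvalues_full.sum() == pytest.approx(6.0, abs=1e-8)

    def test_sign_convention_largest_loading_positive(self, demo_community):
        loadings = demo_community["space"].loadings.to_numpy()
        for k in range(loadings.shape[1]):
            i = np.argmax(np.abs(loadings[:, k]))
            assert loadings[i, k] > 0

    def test_sklearn_param_interface(self):
        est = SignalSpacePCA(eigenvalue_threshold=1.5)
        assert est.get_params()["eigenvalue_threshold"] == 1.5
        est.set_params(eigenvalue_threshold=0.5)
        assert est.eigenvalue_threshold == 0.5


class TestNiches:
    def test_triangle_with_interior_point(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [0.25, 0.25]])
        verts = gift_wrap_hull(pts)
        assert len(verts) == 3
        assert shoelace_area(verts) == pytest.approx(0.5)

    def test_unit_square_area_and_centroid(self):
        verts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert shoelace_area(verts) == pytest.approx(1.0)
        assert polygon_centroid(verts) == pytest.approx([0.5, 0.5])

    def test_hull_matches_gift_wrapping_oracle(self, rng):
        pts = rng.normal(size=(50, 2))
        scores = pd.DataFrame(
            {
                "species": "A",
                "status": "breeding",
                "individual_id": [f"A_{i}" for i in range(50)],
                "PC1": pts[:, 0],
                "PC2": pts[:, 1],
            }
        )
        from signalniche.trait_space import niches_from_scores

        niche = niches_from_scores(scores)[0]
        oracle = gift_wrap_hull(pts)
        assert {tuple(v) for v in niche.vertices} == {tuple(v) for v in oracle}
        assert niche.area == pytest.approx(shoelace_area(oracle))

    def test_every_score_inside_own_hull(self, demo_community):
        space, niches = demo_community["space"], demo_community["niches"]
        by_species = {n.species: n for n in niches}
        for sp, grp in space.scores.groupby("species"):
            pts = grp[["PC1", "PC2"]].to_numpy()
            assert point_in_convex(by_species[sp].vertices, pts, tol=1e-7).all()

    def test_collinear_points_raise_named_error(self):
        from signalniche.trait_space import niches_from_scores

        scores = pd.DataFrame(
            {
                "species": "BAD",
                "status": "migrant",
                "individual_id": list("abcd"),
                "PC1": [0.0, 1.0, 2.0, 3.0],
                "PC2": [0.0, 1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(DegenerateNicheError, match="BAD"):
            niches_from_scores(scores)

    def test_adding_exterior_point_grows_area(self, rng):
        from signalniche.trait_space import niches_from_scores

        pts = rng.normal(size=(20, 2))

        def area_of(p):
            scores = pd.DataFrame(
                {
                    "species": "A",
                    "status": "breeding",
                    "individual_id": [f"i{k}" for k in range(len(p))],
                    "PC1": p[:, 0],
                    "PC2": p[:, 1],
                }
            )
            return niches_from_scores(scores)[0].area

        base = area_of(pts)
        grown = area_of(np.vstack([pts, [10.0, 10.0]]))
        assert grown > base

    def test_shoelace_matches_monte_carlo(self, rng):
        from helpers import random_convex_polygon

        for _ in range(5):
            poly = random_convex_polygon(rng, 10)
            lo, hi = poly.min(axis=0), poly.max(axis=0)
            n = 100_000
            pts = rng.random((n, 2)) * (hi - lo) + lo
            p = point_in_convex(poly, pts).mean()
            box = np.prod(hi - lo)
            se = box * np.sqrt(p * (1 - p) / n)
            assert abs(shoelace_area(poly) - box * p) < 3 * se


class TestCommunityArea:
    def test_community_area_contains_all_species(self, demo_community):
        area = sn.community_area(demo_community["space"])
        assert area >= max(n.area for n in demo_community["niches"])

    def test_union_area_not_larger_than_spanning_hull(self, demo_community):
        spanning = sn.community_area(demo_community["space"], method="all_points")
        union = sn.community_area(demo_community["space"], method="union")
        assert union <= spanning + 1e-9

    def test_disjoint_squares_use_spanning_hull_convention(self):
        # two unit squares at x=0 and x=10: spanning hull covers the gap
        pts = []
        for x0 in (0.0, 10.0):
            pts += [[x0, 0], [x0 + 1, 0], [x0 + 1, 1], [x0, 1]]
        hull = gift_wrap_hull(np.array(pts))
        assert shoelace_area(hull) == pytest.approx(11.0)


class TestSampleSizeRegression:
    def test_noiseless_log_linear_recovery(self):
        from signalniche.trait_space import Niche

        a, b = -1.0, 0.1
        niches = [
            Niche(f"S{i}", "breeding", np.zeros((3, 2)), float(np.exp(a + b * n)),
                  np.zeros(2), int(n))
            for i, n in enumerate(range(4, 25, 2))
        ]
        reg = sn.sample_size_regression(niches)
        assert reg.slope == pytest.approx(b, abs=1e-10)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_slope_ci_coverage(self):
        from scipy import stats

        from signalniche.trait_space import Niche

        b = 0.1
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            ns = r.integers(4, 25, size=100)
            areas = np.exp(-1.0 + b * ns + r.normal(0, 0.3, size=100))
            niches = [
                Niche(f"S{i}", "migrant", np.zeros((3, 2)), float(a), np.zeros(2), int(n))
                for i, (n, a) in enumerate(zip(ns, areas))
            ]
            reg = sn.sample_size_regression(niches)
            # 95% CI from slope +/- t * se, se backed out of the t stat
            se = abs(reg.slope) / stats.t.isf(reg.slope_pvalue / 2, 98)
            tcrit = stats.t.ppf(0.975, 98)
            hits += abs(reg.slope - b) <= tcrit * se
        assert hits >= 90

    def test_collinear_predictors_flagged_by_vif(self):
        from signalniche.trait_space import Niche

        # all migrants share n=10, all breeders n=20: status is a linear
        # function of n, so VIFs blow past the 10 threshold
        niches = [
            Niche(f"M{i}", "migrant", np.zeros((3, 2)), 1.0 + 0.01 * i, np.zeros(2), 10)
            for i in range(10)
        ] + [
            Niche(f"B{i}", "breeding", np.zeros((3, 2)), 2.0 + 0.01 * i, np.zeros(2), 20)
            for i in range(10)
        ]
        reg = sn.sample_size_regression(niches)
        assert max(reg.vif.values()) > 10
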