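import numpy as np
import pytest

from osteosex import (
    FEMALE,
    MALE,
    MEASUREMENTS,
    StudyDataset,
    classify_lda,
    config_from_summaries,
    fit_lda,
    generate,
    load_fixture,
    loocv,
    resubstitution,
    score,
)
from conftest import make_record


def toy_1d_exact():
    """Female {0, 2}, male {4, 6} shifted into the plausible mm range."""
    shift = 20.0
    recs = [make_record(i, FEMALE, v + shift) for i, v in enumerate([0.0, 2.0])]
    recs += [make_record(i + 10, MALE, v + shift) for i, v in enumerate([4.0, 6.0])]
    return StudyDataset(records=recs), shift


def table2_dataset(seed, n_female=18, n_male=14):
    """Trivariate-normal draws matching the burnt-sample summaries.

    With zero shrinkage and no missingness the burnt side of the generated
    dataset reproduces the base distribution draw-for-draw.
    """
    cfg = config_from_summaries(
        load_fixture("table2_burnt"),
        seed=seed,
        n_female=n_female,
        n_male=n_male,
        shrinkage_mean_female=0.0,
        shrinkage_mean_male=0.0,
        shrinkage_sd=0.0,
        missing_prob_burnt=0.0,
    )
    return generate(cfg).subset(burn_state="burnt")


class TestFitLda:
    def test_1d_toy_hand_computation(self):
        # pooled within-group variance 2 -> coefficient 1/sqrt(2)
        ds, shift = toy_1d_exact()
        model = fit_lda(ds, ("maxh",))
        assert model.coefficients[0] == pytest.approx(2 ** -0.5, abs=1e-12)
        assert model.constant == pytest.approx(-(3.0 + shift) / np.sqrt(2), abs=1e-12)
        assert model.centroid_female == pytest.approx(-np.sqrt(2), abs=1e-12)
        assert model.centroid_male == pytest.approx(np.sqrt(2), abs=1e-12)
        assert model.threshold == pytest.approx(0.0, abs=1e-12)

    def test_weighted_centroid_sum_is_zero(self):
        ds = table2_dataset(seed=5)
        model = fit_lda(ds, MEASUREMENTS)
        total = model.n_female * model.centroid_female + model.n_male * model.centroid_male
        assert total == pytest.approx(0.0, abs=1e-8)

    def test_pooled_within_score_variance_is_one(self):
        ds = table2_dataset(seed=8)
        model = fit_lda(ds, MEASUREMENTS)
        sf = np.array([score(model, [r.maxh, r.maxt, r.maxw]) for r in ds if r.sex == FEMALE])
        sm = np.array([score(model, [r.maxh, r.maxt, r.maxw]) for r in ds if r.sex == MALE])
        pooled = ((sf.size - 1) * np.var(sf, ddof=1) + (sm.size - 1) * np.var(sm, ddof=1)) / (
            sf.size + sm.size - 2
        )
        assert pooled == pytest.approx(1.0, abs=1e-8)

    def test_recovers_population_direction_at_large_n(self):
        cfg = config_from_summaries(
            load_fixture("table2_burnt"),
            seed=31,
            n_female=2000,
            n_male=2000,
            shrinkage_mean_female=0.0,
            shrinkage_mean_male=0.0,
            shrinkage_sd=0.0,
            missing_prob_burnt=0.0,
        )
        ds = generate(cfg).subset(burn_state="burnt")
        model = fit_lda(ds, MEASUREMENTS)
        pooled = (cfg.covariance(FEMALE) + cfg.covariance(MALE)) / 2.0
        pop_dir = np.linalg.solve(pooled, cfg.mean(MALE) - cfg.mean(FEMALE))
        w = np.asarray(model.coefficients)
        cosine = w @ pop_dir / (np.linalg.norm(w) * np.linalg.norm(pop_dir))
        assert np.degrees(np.arccos(np.clip(cosine, -1, 1))) < 5.0

    def test_singular_covariance_is_error(self):
        # maxt duplicates maxh -> pooled covariance is singular
        recs = [
            make_record(i, FEMALE if i < 4 else MALE, float(30 + i), maxt=float(30 + i))
            for i in range(8)
        ]
        with pytest.raises(ValueError, match="singular"):
            fit_lda(StudyDataset(records=recs), ("maxh", "maxt"))

    def test_incomplete_cases_dropped(self):
        recs = [
            make_record("a", FEMALE, 30.0, maxt=17.0),
            make_record("b", FEMALE, 31.0, maxt=16.0),
            make_record("c", FEMALE, 33.0, maxt=None),
            make_record("d", MALE, 40.0, maxt=19.0),
            make_record("e", MALE, 39.0, maxt=21.0),
        ]
        model = fit_lda(StudyDataset(records=recs), ("maxh", "maxt"))
        assert (model.n_female, model.n_male) == (2, 2)


class TestScoreClassify:
    def test_zero_vector_returns_constant(self):
        ds, shift = toy_1d_exact()
        model = fit_lda(ds, ("maxh",))
        # score is affine: coefficient * value + constant
        assert score(model, [shift]) == pytest.approx(
            model.coefficients[0] * shift + model.constant
        )

    def test_toy_classification_sides(self):
        ds, shift = toy_1d_exact()
        model = fit_lda(ds, ("maxh",))
        assert classify_lda(model, [5.0 + shift]) == MALE
        assert classify_lda(model, [1.0 + shift]) == FEMALE

    def test_boundary_goes_to_female(self):
        from osteosex import DiscriminantModel

        # exact-arithmetic model: score(3.0) lands exactly on the threshold
        model = DiscriminantModel(
            measurements=("maxh",),
            coefficients=(1.0,),
            constant=-3.0,
            centroid_female=-1.0,
            centroid_male=1.0,
            threshold=0.0,
            n_female=2,
            n_male=2,
        )
        assert score(model, [3.0]) == model.threshold
        assert classify_lda(model, [3.0]) == FEMALE

    def test_missing_component_is_error(self):
        ds, _ = toy_1d_exact()
        model = fit_lda(ds, ("maxh",))
        with pytest.raises(ValueError):
            score(model, {"maxh": None})

    def test_matches_sklearn_equal_priors(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        ds = table2_dataset(seed=13)
        model = fit_lda(ds, MEASUREMENTS)
        X = np.array([[r.maxh, r.maxt, r.maxw] for r in ds])
        y = np.array([r.sex for r in ds])
        ref = sklearn.LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        ours = np.array([classify_lda(model, row) for row in X])
        assert (ours == ref.predict(X)).all()

    def test_resubstitution_invariant_under_affine_rescaling(self):
        ds = table2_dataset(seed=21)
        base = resubstitution(ds, MEASUREMENTS)
        scaled = StudyDataset(
            records=[
                type(r)(
                    individual_id=r.individual_id,
                    sex=r.sex,
                    side=r.side,
                    burn_state=r.burn_state,
                    maxh=r.maxh * 2.0,
                    maxt=r.maxt,
                    maxw=r.maxw,
                )
                for r in ds
            ]
        )
        rescaled = resubstitution(scaled, MEASUREMENTS)
        assert rescaled.percent_correct_total == base.percent_correct_total
        assert rescaled.percent_correct_female == base.percent_correct_female


class TestLoocv:
    def test_well_separated_toy_is_perfect(self):
        recs = [make_record(i, FEMALE, 20.0 + i * 0.5) for i in range(4)]
        recs += [make_record(i + 10, MALE, 45.0 + i * 0.5) for i in range(4)]
        rep = loocv(StudyDataset(records=recs), ("maxh",))
        assert rep.percent_correct_total == 100.0

    def test_duplicated_dataset_is_stable_at_large_separation(self):
        recs = [make_record(i, FEMALE, 20.0 + i * 0.5) for i in range(4)]
        recs += [make_record(i + 10, MALE, 45.0 + i * 0.5) for i in range(4)]
        base = loocv(StudyDataset(records=recs), ("maxh",))
        doubled = recs + [
            make_record(f"{r.individual_id}-dup", r.sex, r.maxh) for r in recs
        ]
        dup = loocv(StudyDataset(records=doubled), ("maxh",))
        assert dup.percent_correct_total == base.percent_correct_total == 100.0

    def test_study_sized_accuracy_band(self):
        """Mean cross-validated accuracy over replicates of the study design
        (n = 18/14, burnt-sample parameters) sits in a plausible band."""
        totals = []
        for i in range(60):
            ds = table2_dataset(seed=1000 + i)
            totals.append(loocv(ds, MEASUREMENTS).percent_correct_total)
        assert 60.0 <= float(np.mean(totals)) <= 85.0

    def test_deterministic(self):
        ds = table2_dataset(seed=3)
        a = loocv(ds, MEASUREMENTS)
        b = loocv(ds, MEASUREMENTS)
        assert a == b
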