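import numpy as np
import pandas as pd
import pytest

from odorkin import pipeline, synthetic_data as sd
from odorkin.compound_lmm import (
    ModelError,
    fit_model,
    lrt,
    predictor_tests,
    slope_table,
    vectorize,
)
from odorkin.pedigree import PedigreeTable
from odorkin.profile_io import IndividualMetadata


def toy_dataset(n_samples=8, n_compounds=3, seed=0, sex_effect=0.0):
    rng = np.random.default_rng(seed)
    inds = [f"i{k}" for k in range(max(2, n_samples // 2))]
    sample_ids = [f"s{k}" for k in range(n_samples)]
    smap = pd.Series([inds[k % len(inds)] for k in range(n_samples)],
                     index=pd.Index(sample_ids, name="sample_id"))
    sexes = ["F" if k % 2 == 0 else "M" for k in range(len(inds))]
    individuals = pd.DataFrame(
        {"sex": sexes, "group": ["G0" if k < len(inds) // 2 else "G1" for k in range(len(inds))],
         "age": rng.uniform(5, 20, len(inds)), "rank": rng.uniform(0, 1, len(inds))},
        index=pd.Index(inds, name="individual_id"),
    )
    meta = IndividualMetadata(individuals, smap)
    ped = PedigreeTable({i: (f"m{i}", f"f{i}") for i in inds})
    values = rng.normal(0, 1, (n_samples, n_compounds))
    if sex_effect:
        is_f = np.array([individuals.loc[smap[s], "sex"] == "F" for s in sample_ids])
        values[:, 0] += sex_effect * np.where(is_f, 0.5, -0.5)
    frame = pd.DataFrame(values, index=sample_ids,
                         columns=[f"c{j}" for j in range(n_compounds)])
    return frame, meta, ped


class TestVectorize:
    def test_row_count_is_product(self, study):
        rel, _ = pipeline.preprocess_peaks(study["peaks"], study["blanks"])
        from odorkin.preprocess import transform_model
        frame = pd.DataFrame(transform_model(rel), index=rel.sample_ids,
                             columns=rel.compound_ids)
        data = vectorize(frame, study["meta"], study["ped"])
        assert len(data) == data.n_samples * data.n_compounds
        assert len(data) == len(rel.sample_ids) * len(rel.compound_ids)

    def test_toy_joins(self):
        frame, meta, ped = toy_dataset(n_samples=2, n_compounds=3)
        data = vectorize(frame, meta, ped)
        assert len(data) == 6
        row = data.frame.iloc[0]
        assert row["individual_id"] == meta.sample_map[row["sample_id"]]
        assert row["mother_id"] == ped.parents_of(row["individual_id"])[0]

    def test_zero_abundance_rows_present(self):
        frame, meta, ped = toy_dataset()
        frame.iloc[0, 0] = -4.60517  # transform of a zero abundance
        data = vectorize(frame, meta, ped)
        assert (data.frame["y"] == -4.60517).sum() == 1


class TestFitModel:
    def test_null_data_recovery(self):
        # pure residual noise: variance components shrink to ~0,
        # fixed effects within 3 SE-ish of zero
        frame, meta, ped = toy_dataset(n_samples=60, n_compounds=6, seed=3)
        data = vectorize(frame, meta, ped)
        fit = fit_model(data, ("sex", "group", "age"), with_slopes=True, seed=0)
        assert fit.converged
        for name, v in fit.variance_components.items():
            assert v <= 0.25 * fit.sigma2, name
        assert abs(fit.beta["sex(F-M)"]) < 0.5

    def test_linearity_in_response(self):
        frame, meta, ped = toy_dataset(n_samples=40, n_compounds=4, seed=1)
        data1 = vectorize(frame, meta, ped)
        data2 = vectorize(2.0 * frame, meta, ped)
        f1 = fit_model(data1, ("sex", "age"), seed=0)
        f2 = fit_model(data2, ("sex", "age"), seed=0)
        np.testing.assert_allclose(2.0 * f1.beta.to_numpy(), f2.beta.to_numpy(),
                                   rtol=1e-3, atol=1e-4)
        s1 = slope_table(f1).table.xs("slope", axis=1, level="field")
        s2 = slope_table(f2).table.xs("slope", axis=1, level="field")
        np.testing.assert_allclose(2.0 * s1.to_numpy(), s2.to_numpy(), rtol=5e-3, atol=5e-3)

    def test_response_matters(self):
        frame, meta, ped = toy_dataset(n_samples=30, n_compounds=4, seed=2)
        data = vectorize(frame, meta, ped)
        shuffled = frame.sample(frac=1.0, random_state=0)
        shuffled.index = frame.index
        data_perm = vectorize(shuffled, meta, ped)
        f1 = fit_model(data, ("sex",), seed=0)
        f2 = fit_model(data_perm, ("sex",), seed=0)
        assert f1.loglik != pytest.approx(f2.loglik)

    def test_missing_rank_errors(self):
        frame, meta, ped = toy_dataset()
        meta.individuals.loc[meta.individuals.index[0], "rank"] = np.nan
        data = vectorize(frame, meta, ped)
        with pytest.raises(ModelError, match="rank"):
            fit_model(data, ("sex", "rank"))


class TestLrt:
    def test_identical_models_chi_zero(self):
        frame, meta, ped = toy_dataset(n_samples=20, n_compounds=3)
        data = vectorize(frame, meta, ped)
        fit = fit_model(data, ("sex",), seed=0)
        res = lrt(fit, fit)
        assert res.chi_sq == 0.0 and res.p == 1.0

    def test_df_bookkeeping(self):
        frame, meta, ped = toy_dataset(n_samples=30, n_compounds=4)
        data = vectorize(frame, meta, ped)
        full = fit_model(data, ("sex", "group", "age"), with_slopes=True, seed=0)
        null = fit_model(data, ("sex", "group", "age"), with_slopes=False, seed=0)
        no_sex = fit_model(data, ("sex", "group", "age"), drop_slopes=("sex",), seed=0)
        assert lrt(full, null).df == 3  # one slope variance per predictor
        assert lrt(full, no_sex).df == 1
        # fixed effects identical across the slope reductions
        assert list(full.beta.index) == list(null.beta.index)

    def test_non_nested_rejected(self):
        frame, meta, ped = toy_dataset(n_samples=20, n_compounds=3)
        data = vectorize(frame, meta, ped)
        f_sex = fit_model(data, ("sex",), seed=0)
        f_age = fit_model(data, ("age",), seed=0)
        with pytest.raises(ModelError, match="nested"):
            lrt(f_sex, f_age)


class TestPredictorTests:
    def test_result_count_and_layout(self):
        frame, meta, ped = toy_dataset(n_samples=40, n_compounds=4, seed=5)
        data = vectorize(frame, meta, ped)
        fit, tests = predictor_tests(data, ("sex", "group", "age"), seed=0)
        names = [n for n, _ in tests]
        assert names == ["omnibus", "sex", "group", "age"]
        assert all(r.chi_sq >= 0 for _, r in tests)

    def test_female_subset_structure(self, study):
        res = pipeline.composition_analysis(
            study["peaks"], study["blanks"], study["meta"], study["ped"],
            subset="females", seed=0,
        )
        assert res.lrt_table["model"].tolist() == ["omnibus", "group", "age", "rank"]
        assert "sex(F-M)" not in res.fit.beta.index
        assert res.lrt_table.loc[res.lrt_table["model"] == "omnibus", "df"].item() == 3


class TestSlopeTable:
    def test_selection_rule_hand_example(self):
        # |slopes| (0.1,0.1,0.1,0.9): mean 0.3, sample SD 0.4 -> only 0.9 selected
        a = np.array([0.1, 0.1, 0.1, 0.9])
        thr = a.mean() + a.std(ddof=1)
        assert thr == pytest.approx(0.7)
        assert (a >= thr).tolist() == [False, False, False, True]

    def test_no_slopes_fit_rejected(self):
        frame, meta, ped = toy_dataset(n_samples=20, n_compounds=3)
        data = vectorize(frame, meta, ped)
        fit = fit_model(data, ("sex",), with_slopes=False, seed=0)
        with pytest.raises(ModelError, match="slopes"):
            slope_table(fit)

    def test_group_slope_reference_invariance(self):
        # relabeling groups must not change the largest-difference summary
        frame, meta, ped = toy_dataset(n_samples=40, n_compounds=4, seed=8)
        data = vectorize(frame, meta, ped)
        f1 = fit_model(data, ("group",), seed=0)
        g1 = slope_table(f1).table[("group", "slope")].to_numpy()
        relabeled = meta.individuals.copy()
        relabeled["group"] = relabeled["group"].map({"G0": "Z1", "G1": "A0"})
        meta2 = IndividualMetadata(relabeled, meta.sample_map)
        f2 = fit_model(vectorize(frame, meta2, ped), ("group",), seed=0)
        g2 = slope_table(f2).table[("group", "slope")].to_numpy()
        np.testing.assert_allclose(g1, g2, rtol=1e-2, atol=1e-3)

    def test_planted_sex_compound_found_through_pipeline(self):
        # end-to-end: the compositional standardization transmits planted
        # effects to other compounds, so demand most (not all) of the
        # planted set in the top ranks
        cfg = sd.SimulationConfig(
            seed=21, sex_sd=1.0, residual_sd=0.3, group_sd=0.0,
            maternal_family_sd=0.0, individual_sd=0.3,
            age_slope_sd=0.0, rank_slope_sd=0.0, detection_threshold=0.0,
        )
        meta, ped, peaks, blanks = sd.simulate_study(cfg, planted_sex_compounds=3)
        res = pipeline.composition_analysis(peaks, blanks, meta, ped, subset="all", seed=0)
        slopes = res.slopes.table[("sex", "slope")].abs()
        planted = {f"RT{20 + 0.5 * k:.2f}" for k in range(3)}
        top3 = set(slopes.nlargest(3).index)
        assert len(top3 & planted) >= 2
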