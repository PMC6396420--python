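import math

import numpy as np
import pandas as pd
import pytest

from plasmacall.bayes import EmissionModel, genotype_all
from plasmacall.fetal_fraction import FetalFractionProfile, estimate_per_length_ff
from plasmacall.recalibrate import (
    FEATURE_COLUMNS,
    RecalibrationModel,
    SchemaMismatchError,
    apply,
    extract_feature_table,
    extract_features,
    filter_by_score,
    load_model,
    save_model,
    train,
)
from plasmacall.simulate import SimulationConfig, generate_trio
from plasmacall.store import ALT, REF

from .conftest import make_obs, make_site, store_of


def _one_call(observations=None, gm=1, gf=0):
    site = make_site(gm, gf, pos=500)
    obs = observations if observations is not None else [
        make_obs(site.site_id, REF, tlen=160, idx=0),
        make_obs(site.site_id, ALT, tlen=140, idx=1),
    ]
    profile = FetalFractionProfile.constant(0.15)
    store = store_of(obs)
    (res,) = genotype_all(store, [site], profile, EmissionModel())
    return site, obs, res, profile


def test_feature_schema_complete_and_finite():
    site, obs, res, profile = _one_call()
    row = extract_features(site, obs, res, profile)
    assert set(row) == set(FEATURE_COLUMNS)
    assert all(np.isfinite(v) for v in row.values())
    assert row["depth"] == 2 and row["n_alt"] == 1
    assert row["allelic_balance"] == 0.5
    assert row["cat_maternal_only"] == 1.0 and row["cat_double_het"] == 0.0
    assert row["gm_1"] == 1.0 and row["gf_0"] == 1.0


def test_missing_allele_side_is_imputed_with_presence_flag():
    site, obs, res, profile = _one_call(
        observations=[make_obs("chr1:500:A:G", REF, tlen=166, idx=0)]
    )
    row = extract_features(site, obs, res, profile)
    assert row["alt_present"] == 0.0
    assert row["alt_tlen_mean"] == 0.0 and row["alt_baseq_mean"] == 0.0
    assert row["ref_present"] == 1.0 and row["ref_tlen_mean"] == 166.0


def test_prior_entropy_is_log3_for_uniform():
    # a double-het prior (1/4, 1/2, 1/4) has entropy 1.5*ln2; a uniform one ln3
    site, obs, res, profile = _one_call(gm=1, gf=1)
    row = extract_features(site, obs, res, profile)
    assert row["prior_entropy"] == pytest.approx(1.5 * math.log(2))
    res.prior = (1 / 3, 1 / 3, 1 / 3)
    row = extract_features(site, obs, res, profile)
    assert row["prior_entropy"] == pytest.approx(math.log(3))


def _toy_table(n=400, seed=0, separable=True):
    """Feature table in which (when separable) depth alone predicts correctness."""
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(0.0, index=range(n), columns=list(FEATURE_COLUMNS))
    table["var_type_snp"] = 1.0
    table["cat_maternal_only"] = 1.0
    correct = rng.random(n) < 0.5
    if separable:
        table["depth"] = np.where(correct, 100.0, 10.0)
    else:
        table["depth"] = rng.integers(10, 100, n).astype(float)
    table["max_posterior"] = rng.random(n)
    table["site_id"] = [f"chr1:{i}:A:G" for i in range(n)]
    table["category"] = "MATERNAL_ONLY_HET"
    table["var_type"] = "SNP"
    table["called"] = 1
    return table, correct


def test_train_separable_reaches_perfect_holdout_auc():
    table, correct = _toy_table(separable=True)
    model = train(table, correct, "MATERNAL_ONLY_HET", seed=1)
    assert model.provenance["holdout_auc"] == pytest.approx(1.0)
    scores = apply(model, table)
    assert np.all((scores >= 0) & (scores <= 1))
    assert scores[correct].mean() > scores[~correct].mean()


def test_train_null_features_near_chance():
    table, correct = _toy_table(separable=False, seed=3)
    model = train(table, correct, "MATERNAL_ONLY_HET", seed=1)
    assert abs(model.provenance["holdout_auc"] - 0.5) < 0.2


def test_train_rejects_single_class_labels():
    table, correct = _toy_table()
    with pytest.raises(ValueError):
        train(table, np.ones(len(table), dtype=bool), "MATERNAL_ONLY_HET", seed=1)


def test_paper_strategy_pools_categories():
    table, correct = _toy_table()
    half = len(table) // 2
    table.loc[half:, "category"] = "DOUBLE_HET"
    table.loc[half:, ["cat_maternal_only", "cat_double_het"]] = [0.0, 1.0]
    # paternal SNP model pools all categories; maternal trains within category
    pat = train(table, correct, "PATERNAL_ONLY_HET", strategy="paper", seed=1)
    assert pat.provenance["n_train"] + pat.provenance["n_holdout"] == len(table)
    mat = train(table, correct, "MATERNAL_ONLY_HET", strategy="paper", seed=1)
    assert mat.provenance["n_train"] + mat.provenance["n_holdout"] == half


def test_model_serialization_bit_identical_scores(tmp_path):
    table, correct = _toy_table()
    model = train(table, correct, "MATERNAL_ONLY_HET", seed=7)
    path = tmp_path / "model.joblib"
    save_model(model, path)
    back = load_model(path)
    assert isinstance(back, RecalibrationModel)
    assert back.provenance == model.provenance
    assert np.array_equal(apply(back, table), apply(model, table))


def test_apply_schema_mismatch_raises(tmp_path):
    table, correct = _toy_table()
    model = train(table, correct, "MATERNAL_ONLY_HET", seed=1)
    model.schema_version = 99
    with pytest.raises(SchemaMismatchError):
        apply(model, table)
    model.schema_version = 1
    with pytest.raises(SchemaMismatchError):
        apply(model, table.drop(columns=["depth"]))


def test_load_model_rejects_foreign_objects(tmp_path):
    import joblib

    path = tmp_path / "junk.joblib"
    joblib.dump({"not": "a model"}, path)
    with pytest.raises(SchemaMismatchError):
        load_model(path)


def test_filter_by_score_report():
    cfg = SimulationConfig(seed=2, n_maternal_only=60, n_paternal_only=0,
                           n_double_het=0, n_informative=200, depth_mean=40.0)
    sites, store, truth = generate_trio(cfg)
    profile = estimate_per_length_ff(store, sites, min_count=20)
    results = genotype_all(store, sites, profile, include_informative=False)
    scores = np.linspace(0, 1, len(results))
    kept, report = filter_by_score(results, scores, 0.5, sites=sites, truth=truth.genotypes)
    assert report["n_retained"] == len(kept) == int(np.sum(scores >= 0.5))
    assert "MATERNAL_ONLY_HET" in report["per_category"]
    assert 0.0 <= report["accuracy"] <= 1.0
    with pytest.raises(ValueError):
        filter_by_score(results, scores[:-1], 0.5)


def test_feature_table_metadata_columns():
    site, obs, res, profile = _one_call()
    table = extract_feature_table([site], store_of(obs), [res], profile)
    assert list(table.columns) == list(FEATURE_COLUMNS) + ["site_id", "category", "var_type", "called"]
    assert table.iloc[0].site_id == site.site_id
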