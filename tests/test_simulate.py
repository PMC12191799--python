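"""Synthetic-cohort generator: determinism, null behaviour, planted effects."""

import numpy as np
import pandas as pd
import pytest

import ratiosurv as rs
from ratiosurv.io import read_gmt, write_gmt
from ratiosurv.simulate import feature_ids


class TestConfigValidation:
    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError):
            rs.SimulationConfig(n_subjects=10)

    def test_anchor_cannot_be_effect(self):
        with pytest.raises(ValueError):
            rs.SimulationConfig(effect_feature_ids=("OPCML",))

    def test_unknown_effect_feature(self):
        with pytest.raises(ValueError):
            rs.SimulationConfig(n_features=10, effect_feature_ids=("G99999",))

    def test_unknown_noise_model(self):
        with pytest.raises(ValueError):
            rs.SimulationConfig(noise_model="cauchy")


class TestExpression:
    def test_seed_determinism(self):
        cfg = rs.SimulationConfig(n_subjects=20, n_features=3, seed=1)
        a = rs.generate_expression(cfg)
        b = rs.generate_expression(cfg)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_non_negative_and_shape(self):
        cfg = rs.SimulationConfig(n_subjects=25, n_features=40, seed=2)
        expr = rs.generate_expression(cfg)
        assert expr.shape == (40, 25)
        assert expr.values.to_numpy().min() >= 0

    def test_negative_binomial_counts(self):
        cfg = rs.SimulationConfig(n_subjects=30, n_features=20,
                                  noise_model="negative-binomial", seed=3)
        vals = rs.generate_expression(cfg).values.to_numpy()
        assert np.allclose(vals, np.round(vals)) and vals.min() >= 0

    def test_null_features_uncorrelated_with_survival(self):
        cfg = rs.SimulationConfig(n_subjects=100, n_features=1000, seed=4)
        expr = rs.generate_expression(cfg)
        cohort = rs.generate_survival(cfg, expr)
        days = cohort["days_to_death"].to_numpy(float)
        x = expr.values.to_numpy()
        xc = x - x.mean(axis=1, keepdims=True)
        dc = days - days.mean()
        corr = (xc @ dc) / (
            np.sqrt((xc**2).sum(axis=1)) * np.sqrt((dc**2).sum())
        )
        se = 1.0 / np.sqrt(cfg.n_subjects - 3)  # per-feature Fisher-z scale
        assert abs(corr.mean()) < 3 * se / np.sqrt(cfg.n_features)


class TestSurvival:
    def test_horizon_bound_events_only(self, small_cohort):
        _, _, cohort = small_cohort
        assert (cohort["days_to_death"] < 3650).all()
        assert cohort["event"].all()
        assert (cohort["days_to_death"] > 0).all()

    def test_censoring_mode_flags_horizon(self):
        cfg = rs.SimulationConfig(n_subjects=500, n_features=5, seed=5,
                                  events_only=False, baseline_hazard=2e-4)
        cohort = rs.generate_survival(cfg, rs.generate_expression(cfg))
        censored = cohort.loc[~cohort["event"]]
        assert len(censored) > 0
        assert (censored["days_to_death"] == 3650).all()
        assert (cohort.loc[cohort["event"], "days_to_death"] < 3650).all()

    def test_planted_effect_shortens_high_ratio_survival(self):
        cfg = rs.SimulationConfig(n_subjects=1000, n_features=20, seed=6,
                                  effect_feature_ids=("G00003",),
                                  true_log_hazard=np.log(2))
        expr = rs.generate_expression(cfg)
        cohort = rs.generate_survival(cfg, expr)
        log_expr = rs.log2p4_transform(expr)
        ratio = log_expr.values.loc["OPCML"] / log_expr.values.loc["G00003"]
        high = (ratio > ratio.median()).to_numpy()
        days = cohort["days_to_death"].to_numpy()
        assert days[high].mean() < days[~high].mean()

    def test_null_config_reproducible(self):
        cfg = rs.SimulationConfig(n_subjects=30, n_features=10, seed=7)
        expr = rs.generate_expression(cfg)
        pd.testing.assert_frame_equal(
            rs.generate_survival(cfg, expr), rs.generate_survival(cfg, expr)
        )

    def test_missing_anchor_errors(self):
        cfg = rs.SimulationConfig(n_subjects=30, n_features=10, seed=8)
        expr = rs.generate_expression(cfg)
        bad = rs.ExpressionMatrix(expr.values.drop(index="OPCML"))
        with pytest.raises(KeyError):
            rs.generate_survival(cfg, bad)


class TestGeneSets:
    def test_planted_full_overlap_is_exactly_effects(self):
        effects = ("G00002", "G00005", "G00009")
        cfg = rs.SimulationConfig(n_subjects=30, n_features=50, seed=9,
                                  effect_feature_ids=effects)
        coll = rs.generate_gene_sets(cfg, n_sets=5, set_size_range=(5, 15),
                                     planted_overlap=1.0)
        planted = coll.sets[0]
        assert planted.set_id == "PLANTED_EFFECT"
        assert set(planted.members) == set(effects)

    def test_partial_overlap_fraction(self):
        effects = tuple(f"G{i:05d}" for i in range(1, 11))
        cfg = rs.SimulationConfig(n_subjects=30, n_features=200, seed=10,
                                  effect_feature_ids=effects)
        planted = rs.generate_gene_sets(cfg, n_sets=3, set_size_range=(5, 15),
                                        planted_overlap=0.5).sets[0]
        assert len(planted.members) == 20
        assert len(set(planted.members) & set(effects)) == 10

    def test_empty_collection_valid_gmt(self, tmp_path):
        cfg = rs.SimulationConfig(n_subjects=30, n_features=20, seed=11)
        coll = rs.generate_gene_sets(cfg, n_sets=0, set_size_range=(5, 10))
        path = tmp_path / "empty.gmt"
        write_gmt(coll, path)
        assert len(read_gmt(path)) == 0

    def test_sizes_and_universe(self):
        cfg = rs.SimulationConfig(n_subjects=30, n_features=100, seed=12)
        coll = rs.generate_gene_sets(cfg, n_sets=10, set_size_range=(5, 15))
        uni = set(coll.universe)
        assert "OPCML" not in uni
        for s in coll:
            assert 5 <= len(s.members) <= 15
            assert set(s.members) <= uni

    def test_oversized_sets_rejected(self):
        cfg = rs.SimulationConfig(n_subjects=30, n_features=10, seed=13)
        with pytest.raises(ValueError):
            rs.generate_gene_sets(cfg, n_sets=2, set_size_range=(5, 50))

    def test_gmt_round_trip_and_gseapy_agreement(self, tmp_path):
        import gseapy

        cfg = rs.SimulationConfig(n_subjects=30, n_features=60, seed=14)
        coll = rs.generate_gene_sets(cfg, n_sets=6, set_size_range=(4, 10))
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert [(s.set_id, s.description, s.members) for s in back] == [
            (s.set_id, s.description, s.members) for s in coll
        ]
        theirs = gseapy.read_gmt(str(path))
        assert {s.set_id: list(s.members) for s in back} == theirs


def test_citation_counts_deterministic_with_boost():
    effects = ("G00004",)
    cfg = rs.SimulationConfig(n_subjects=30, n_features=30, seed=15,
                              effect_feature_ids=effects)
    a = rs.generate_citation_counts(cfg, effect_boost=10.0)
    b = rs.generate_citation_counts(cfg, effect_boost=10.0)
    pd.testing.assert_frame_equal(a, b)
    assert set(a["gene_id"]) == set(feature_ids(cfg)) - {"OPCML"}
    assert (a["count"] >= 0).all()


def test_expression_tsv_round_trip(tmp_path, small_cohort):
    _, expr, _ = small_cohort
    path = tmp_path / "expr.tsv"
    expr.to_tsv(path)
    back = rs.ExpressionMatrix.from_tsv(path)
    assert back.feature_ids == expr.feature_ids
    assert back.subject_ids == expr.subject_ids
    np.testing.assert_allclose(
        back.values.to_numpy(), expr.values.to_numpy(), rtol=1e-9
    )
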