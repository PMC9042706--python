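import numpy as np
import pandas as pd
import pytest

from sbcln import (
    CascadeConfig,
    CascadeModel,
    GenePanel,
    REFERENCE_MARKERS,
    SyntheticConfig,
    entity_dbi_order,
    fit_cascade,
    labels_series,
    loo_evaluate,
    normalize_single_cohort,
    predict,
    refine_markers,
    select_housekeeping,
    simulate_cohort,
    train_step,
)
from sbcln.cascade import CascadeStep
from sbcln.core_io import UNDETERMINED

from conftest import make_norm_df


def brute_force_dbi(points: dict) -> dict:
    """Independent Davies-Bouldin: explicit pairwise max of scatter ratios."""
    centroids = {e: np.mean(p, axis=0) for e, p in points.items()}
    scatter = {
        e: np.mean([np.linalg.norm(x - centroids[e]) for x in p]) for e, p in points.items()
    }
    out = {}
    for e in points:
        out[e] = max(
            (scatter[e] + scatter[f]) / np.linalg.norm(centroids[e] - centroids[f])
            for f in points
            if f != e
        )
    return out


def df_from_points(points: dict):
    cols, labels, data = [], {}, []
    for e, pts in points.items():
        for i, p in enumerate(pts):
            name = f"{e}{i}"
            cols.append(name)
            labels[name] = e
            data.append(p)
    df = pd.DataFrame(np.array(data).T, columns=cols)
    df.index = [f"g{i}" for i in range(df.shape[0])]
    return df, pd.Series(labels)


class TestDBIOrder:
    def test_zero_spread_clusters_have_zero_dbi_alphabetical_ties(self):
        points = {"B": [(0.0, 0.0), (0.0, 0.0)], "A": [(10.0, 0.0), (10.0, 0.0)]}
        df, labels = df_from_points(points)
        ordered = entity_dbi_order(df, labels)
        assert [e for e, _ in ordered] == ["A", "B"]
        assert all(d == 0.0 for _, d in ordered)

    def test_hand_worked_two_cluster_value(self):
        points = {"A": [(0.0, 0.0), (2.0, 0.0)], "B": [(10.0, 0.0), (12.0, 0.0)]}
        df, labels = df_from_points(points)
        ordered = dict(entity_dbi_order(df, labels))
        assert ordered["A"] == pytest.approx(0.2)
        assert ordered["B"] == pytest.approx(0.2)

    def test_shrinking_centroid_distance_increases_dbi(self):
        prev = None
        for gap in (20.0, 10.0, 5.0):
            points = {"A": [(0.0, 0.0), (2.0, 0.0)], "B": [(gap, 0.0), (gap + 2.0, 0.0)]}
            df, labels = df_from_points(points)
            d = dict(entity_dbi_order(df, labels))
            if prev is not None:
                assert d["A"] > prev["A"] and d["B"] > prev["B"]
            prev = d

    def test_matches_brute_force_on_toy_sets(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            points = {
                e: [tuple(rng.normal(loc, 1.0, size=3)) for _ in range(rng.integers(2, 4))]
                for e, loc in (("A", 0.0), ("B", 6.0), ("C", -6.0))
            }
            df, labels = df_from_points(points)
            got = dict(entity_dbi_order(df, labels))
            expected = brute_force_dbi(points)
            for e in points:
                assert got[e] == pytest.approx(expected[e], rel=1e-12)

    def test_coincident_centroids_rejected(self):
        points = {"A": [(0.0, 0.0), (2.0, 0.0)], "B": [(-1.0, 0.0), (3.0, 0.0)]}
        df, labels = df_from_points(points)
        with pytest.raises(ValueError, match="coincident"):
            entity_dbi_order(df, labels)


class TestTrainStep:
    def test_separable_target_confident(self, small_sim, small_cascade_config):
        norm, labels = small_sim["norm"], small_sim["labels"]
        step = train_step(norm, labels, "FL", small_sim["candidates"], small_cascade_config)
        p = step.probability(norm.values)
        target = (labels.reindex(norm.sample_ids) == "FL").to_numpy()
        assert (p[target] > 0.5).mean() >= 0.95
        # importances normalized
        assert step.gini_importances.sum() == pytest.approx(1.0)

    def test_permuted_labels_destroy_signal(self, small_sim, small_cascade_config):
        rng = np.random.default_rng(0)
        norm, labels = small_sim["norm"], small_sim["labels"]
        permuted = pd.Series(
            rng.permutation(labels.reindex(norm.sample_ids).to_numpy()), index=norm.sample_ids
        )
        step = train_step(norm, permuted, "FL", small_sim["candidates"], small_cascade_config)
        # hold-out-free probabilities on shuffled labels should hover near the
        # base rate; the planted markers must no longer dominate importances
        planted = set(small_sim["config"].planted_markers["FL"])
        top = set(step.gini_importances.nlargest(4).index)
        assert top != planted

    def test_deterministic_given_seed(self, small_sim, small_cascade_config):
        norm, labels = small_sim["norm"], small_sim["labels"]
        s1 = train_step(norm, labels, "FL", small_sim["candidates"], small_cascade_config)
        s2 = train_step(norm, labels, "FL", small_sim["candidates"], small_cascade_config)
        assert np.array_equal(s1.probability(norm.values), s2.probability(norm.values))

    def test_single_class_rejected(self, small_sim, small_cascade_config):
        norm = small_sim["norm"]
        labels = pd.Series("FL", index=norm.sample_ids)
        with pytest.raises(ValueError, match="single-class"):
            train_step(norm, labels, "FL", small_sim["candidates"], small_cascade_config)


class TestRefineMarkers:
    def test_downregulated_high_gini_gene_excluded(self):
        # g_down separates the classes perfectly but is LOWER in the target
        rng = np.random.default_rng(1)
        n = 16
        target = np.array([True] * 8 + [False] * 8)
        df = make_norm_df(
            np.vstack(
                [
                    np.where(target, 2.0, 8.0) + rng.normal(0, 0.1, n),  # g_down
                    np.where(target, 8.0, 5.0) + rng.normal(0, 0.3, n),  # g_up1
                    np.where(target, 7.0, 5.0) + rng.normal(0, 0.3, n),  # g_up2
                ]
            ),
            genes=["g_down", "g_up1", "g_up2"],
        )
        labels = pd.Series(np.where(target, "T", "rest"), index=df.columns)
        cfg = CascadeConfig(n_estimators=50, markers_per_entity=2, seed=3)
        step = train_step(df, labels, "T", ["g_down", "g_up1", "g_up2"], cfg)
        refined = refine_markers(step, df, labels, k=2, config=cfg)
        assert "g_down" not in refined.marker_genes
        assert set(refined.marker_genes) == {"g_up1", "g_up2"}

    def test_k_exceeding_upregulated_keeps_all(self, small_sim, small_cascade_config):
        norm, labels = small_sim["norm"], small_sim["labels"]
        step = train_step(norm, labels, "FL", small_sim["candidates"], small_cascade_config)
        refined = refine_markers(step, norm, labels, k=10_000, config=small_cascade_config)
        up_count = len(refined.marker_genes)
        assert 0 < up_count <= len(small_sim["candidates"])

    def test_no_upregulated_gene_rejected(self):
        df = make_norm_df([[2.0, 2.0, 8.0, 8.0]], genes=["g"], samples=["t0", "t1", "r0", "r1"])
        labels = pd.Series(["T", "T", "rest", "rest"], index=df.columns)
        cfg = CascadeConfig(n_estimators=20, markers_per_entity=1, seed=0)
        step = train_step(df, labels, "T", ["g"], cfg)
        with pytest.raises(ValueError, match="upregulated"):
            refine_markers(step, df, labels, k=1, config=cfg)


class TestFitCascade:
    def test_recovers_planted_marker_blocks(self, small_model, small_sim):
        planted = {g for gs in small_sim["config"].planted_markers.values() for g in gs}
        assert set(small_model.marker_union) == planted

    def test_reference_marker_sets_union_is_35(self):
        panel = GenePanel(
            candidate_genes=sorted({g for gs in REFERENCE_MARKERS.values() for g in gs}),
            refined_markers={e: list(g) for e, g in REFERENCE_MARKERS.items()},
        )
        assert len(panel.marker_union) == 35
        shared = [
            g
            for g in panel.marker_union
            if sum(g in gs for gs in REFERENCE_MARKERS.values()) > 1
        ]
        assert shared == ["CCND1"]

    def test_single_entity_gives_one_step(self, small_sim):
        cfg = CascadeConfig(n_estimators=30, markers_per_entity=4, seed=2)
        norm, labels = small_sim["norm"], small_sim["labels"]
        keep = labels[labels.isin(["FL", "control"])].index
        model = fit_cascade(norm.values[list(keep)], labels[keep], small_sim["candidates"], cfg)
        assert model.entity_order == ["FL"]

    def test_fixed_seed_bit_identical(self, small_sim, small_cascade_config):
        norm, labels = small_sim["norm"], small_sim["labels"]
        m1 = fit_cascade(norm, labels, small_sim["candidates"], small_cascade_config)
        m2 = fit_cascade(norm, labels, small_sim["candidates"], small_cascade_config)
        assert m1.entity_order == m2.entity_order
        for a, b in zip(m1.steps, m2.steps):
            assert a.marker_genes == b.marker_genes
        p1 = predict(m1, norm, full_profile=True)
        p2 = predict(m2, norm, full_profile=True)
        for x, y in zip(p1, p2):
            assert x.probabilities == y.probabilities and x.final_call == y.final_call


class _StubStep(CascadeStep):
    """Step with a canned probability, for exercising the cascade decision rule."""

    def __init__(self, entity, probs):
        super().__init__(entity, ["g"], classifier=None, gini_importances=pd.Series({"g": 1.0}))
        self._probs = probs

    def probability(self, values):
        return np.array([self._probs[s] for s in values.columns])


def stub_model(step_probs: dict[str, dict[str, float]]) -> CascadeModel:
    return CascadeModel(steps=[_StubStep(e, p) for e, p in step_probs.items()])


class TestPredictRule:
    def test_first_firing_step_wins(self):
        model = stub_model({"E1": {"s": 0.7}, "E2": {"s": 0.9}})
        (r,) = predict(model, make_norm_df([[1.0]], genes=["g"], samples=["s"]))
        assert r.final_call == "E1" and r.stopped_at_step == 0

    def test_boundary_half_assigns(self):
        model = stub_model({"E1": {"s": 0.4}, "E2": {"s": 0.5}, "E3": {"s": 0.9}})
        (r,) = predict(model, make_norm_df([[1.0]], genes=["g"], samples=["s"]))
        assert r.final_call == "E2" and r.stopped_at_step == 1
        assert list(r.probabilities) == ["E1", "E2"]  # later steps not evaluated

    def test_all_subthreshold_is_undetermined(self):
        model = stub_model({"E1": {"s": 0.4}, "E2": {"s": 0.49}})
        (r,) = predict(model, make_norm_df([[1.0]], genes=["g"], samples=["s"]))
        assert r.final_call == UNDETERMINED and r.stopped_at_step is None

    def test_exactly_one_call_per_sample(self, small_model, small_sim):
        results = predict(small_model, small_sim["norm"])
        assert len(results) == len(small_sim["norm"].sample_ids)
        valid = set(small_model.entity_order) | {UNDETERMINED}
        assert all(r.final_call in valid for r in results)

    def test_missing_marker_gene_named(self, small_model, small_sim):
        values = small_sim["norm"].values.drop(index=small_model.steps[0].marker_genes[0])
        with pytest.raises(ValueError, match=small_model.steps[0].marker_genes[0]):
            predict(small_model, values)

    def test_out_of_distribution_class_never_asserted(self, small_model, small_sim):
        # control samples are no entity: the cascade must reject, not guess
        labels = small_sim["labels"]
        controls = labels[labels == "control"].index
        results = predict(small_model, small_sim["norm"].values[list(controls)])
        assert all(r.final_call == UNDETERMINED for r in results)


class TestLOOEvaluate:
    def test_perfectly_separable_two_entity(self):
        cfg = SyntheticConfig(
            entities=("CLL/SLL", "FL"),
            samples_per_entity=6,
            n_controls=6,
            markers_per_entity=3,
            n_background_genes=10,
            n_housekeeping_genes=3,
            effect_size=3.0,
            seed=21,
        )
        cm, anns = simulate_cohort(cfg)
        norm = normalize_single_cohort(cm, select_housekeeping(cm, cm.housekeeping_candidates))
        ccfg = CascadeConfig(n_estimators=50, markers_per_entity=3, seed=1)
        _, summary = loo_evaluate(norm, labels_series(anns), cfg.panel().candidate_genes, ccfg)
        assert summary.accuracy == 1.0
        assert summary.n_misclassified == 0

    def test_planted_ambiguous_sample_rejected_not_misclassified(self):
        cfg = SyntheticConfig(
            entities=("CLL/SLL", "FL"),
            samples_per_entity=8,
            n_controls=8,
            markers_per_entity=3,
            n_background_genes=10,
            n_housekeeping_genes=3,
            effect_size=3.0,
            # per-sample purity list: the last CLL/SLL sample is diluted to
            # near-background, everyone else is pure
            purity=[1.0] * 7 + [0.02] + [1.0] * 8,
            seed=22,
        )
        cm, anns = simulate_cohort(cfg)
        diluted = [a.sample_id for a in anns if a.tumor_cell_content is not None
                   and a.tumor_cell_content < 0.1]
        assert len(diluted) >= 1
        norm = normalize_single_cohort(cm, select_housekeeping(cm, cm.housekeeping_candidates))
        ccfg = CascadeConfig(n_estimators=100, markers_per_entity=3, seed=1)
        results, summary = loo_evaluate(norm, labels_series(anns), cfg.panel().candidate_genes, ccfg)
        by_id = {r.sample_id: r for r in results}
        for s in diluted:
            assert by_id[s].final_call == UNDETERMINED
        assert summary.n_misclassified == 0
        assert summary.accuracy == pytest.approx(
            (summary.n_entity_samples - len(diluted)) / summary.n_entity_samples
        )

    def test_small_entity_rejected(self, small_sim, small_cascade_config):
        norm, labels = small_sim["norm"], small_sim["labels"]
        labels = labels.copy()
        labels.iloc[0] = "rare_entity"
        with pytest.raises(ValueError, match="<2 samples"):
            loo_evaluate(norm, labels, small_sim["candidates"], small_cascade_config)
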