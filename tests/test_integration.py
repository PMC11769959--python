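import numpy as np
import pytest

from metabolink import (ConcentrationMatrix, PipelineConfig, StageSequence,
                        empirical_covariance, generate_dataset, graphical_lasso,
                        make_truth, metabolink_full, metabolink_transition,
                        network_from_precision, plant_markers, run_all_transitions,
                        zscore_normalize)
from metabolink.synth import SyntheticTruth
from oracles import f1_edges


@pytest.fixture(scope="module")
def pipeline_run():
    stages = StageSequence(["hESC", "EB", "Rosette", "hNPC", "Neuron"])
    truth = make_truth(20, stages, density=0.08, seed=7)
    truth = plant_markers(truth, ("EB", "Rosette"), ["M003", "M011", "M017"], 3.0)
    data = generate_dataset(truth, n_rep=8, seed=70)
    cfg = PipelineConfig(seed=0)
    full, nets = run_all_transitions(data, stages, cfg)
    return stages, truth, data, cfg, full, nets


class TestRunAllTransitions:
    def test_five_stages_four_networks(self, pipeline_run):
        _, _, _, _, _, nets = pipeline_run
        assert len(nets) == 4

    def test_two_stages_one_network(self):
        stages = StageSequence(["a", "b"])
        truth = make_truth(8, stages, density=0.1, seed=2)
        data = generate_dataset(truth, n_rep=6, seed=20)
        _, nets = run_all_transitions(data, stages, PipelineConfig(seed=1))
        assert len(nets) == 1

    def test_background_shared_across_transitions(self, pipeline_run):
        _, _, _, _, full, nets = pipeline_run
        hashes = set()
        for net in nets:
            import hashlib

            h = hashlib.sha256(repr(net.background_edges).encode()).hexdigest()
            hashes.add(h)
        assert len(hashes) == 1
        assert nets[0].background_edges == full.network.edges

    def test_graphml_exports_deterministic(self, tmp_path, pipeline_run):
        stages, _, data, cfg, _, _ = pipeline_run
        outs = []
        for tag in ("x", "y"):
            _, nets = run_all_transitions(data, stages, cfg)
            p = tmp_path / f"{tag}.graphml"
            nets[1].write_graphml(p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_all_metabolites_annotated(self, pipeline_run):
        _, _, data, _, _, nets = pipeline_run
        for net in nets:
            assert set(net.node_attrs) == set(data.metabolite_names)
            for attrs in net.node_attrs.values():
                assert 0.0 <= attrs["score_intensity"] <= 1.0
                assert attrs["delta_magnitude"] >= 0.0
                assert attrs["delta_sign"] in (-1, 0, 1)

    def test_transition_edge_endpoints_annotated(self, pipeline_run):
        _, _, _, _, _, nets = pipeline_run
        for net in nets:
            for a, b, _ in net.transition_edges:
                assert a in net.node_attrs and b in net.node_attrs


class TestMetabolinkFull:
    def test_planted_isolated_features_dropped(self):
        """Features disconnected in the planted precision should leave the
        background network at a well-chosen penalty."""
        stages = StageSequence(["a", "b"])
        rng = np.random.default_rng(12)
        p = 12
        theta = np.zeros((p, p))
        # a connected cluster among features 0..8; features 9, 10, 11 isolated
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 8), (0, 8)]:
            theta[i, j] = theta[j, i] = -0.35
        np.fill_diagonal(theta, np.abs(theta).sum(axis=1) + 0.5)
        truth = SyntheticTruth(
            theta_true=theta,
            support={(i, j) for i in range(p) for j in range(i + 1, p) if theta[i, j] != 0},
            stage_means=np.zeros((2, p)), stages=stages,
            metabolite_names=[f"M{j:03d}" for j in range(p)])
        data = generate_dataset(truth, n_rep=150, seed=121)
        norm = zscore_normalize(data)
        S = empirical_covariance(norm)
        best_alpha, best_f1 = 0.1, 0.0
        for a in np.linspace(0.05, 0.4, 15):
            est = graphical_lasso(S, alpha=float(a))
            edges = {(i, j) for i in range(p) for j in range(i + 1, p)
                     if abs(est.theta[i, j]) > 1e-8}
            s = f1_edges(edges, truth.support)
            if s > best_f1:
                best_alpha, best_f1 = float(a), s
        est = graphical_lasso(S, alpha=best_alpha)
        net = network_from_precision(est, truth.metabolite_names)
        assert best_f1 > 0.8
        for isolated in ("M009", "M010", "M011"):
            assert isolated not in net.nodes

    def test_large_alpha_empty_network(self):
        stages = StageSequence(["a", "b"])
        truth = make_truth(10, stages, density=1e-9, seed=5)  # independent features
        data = generate_dataset(truth, n_rep=30, seed=50)
        norm = zscore_normalize(data)
        S = empirical_covariance(norm)
        alpha = float(np.abs(S.S - np.diag(np.diag(S.S))).max())
        est = graphical_lasso(S, alpha=alpha)
        net = network_from_precision(est, norm.metabolite_names)
        assert net.n_edges == 0

    def test_metabolite_permutation_equivariance(self):
        stages = StageSequence(["a", "b"])
        truth = make_truth(10, stages, density=0.15, seed=8)
        data = generate_dataset(truth, n_rep=40, seed=80)
        # tight solver tolerance: the optimum is unique, so the estimate is
        # column-order independent up to numerical error
        cfg = PipelineConfig(seed=3, tol=1e-8)
        full1 = metabolink_full(data, stages, cfg)
        perm = list(np.random.default_rng(1).permutation(10))
        data2 = ConcentrationMatrix(
            values=data.values[:, perm],
            sample_ids=data.sample_ids, stage_labels=data.stage_labels,
            replicate_ids=data.replicate_ids,
            metabolite_names=[data.metabolite_names[j] for j in perm])
        full2 = metabolink_full(data2, stages, cfg)
        e1 = {(min(a, b), max(a, b)): w for a, b, w in full1.network.edges}
        e2 = {(min(a, b), max(a, b)): w for a, b, w in full2.network.edges}
        assert set(e1) == set(e2)
        for k in e1:
            assert e1[k] == pytest.approx(e2[k], abs=1e-5)

    def test_provenance_recorded(self, pipeline_run):
        _, _, _, cfg, full, nets = pipeline_run
        assert full.alpha in full.cv_table
        for net in nets:
            assert net.provenance["transition_alpha"] == cfg.transition_alpha
            assert isinstance(net.provenance["component_index"], int)


class TestMetabolinkTransition:
    def test_stage_swap_antisymmetry(self, pipeline_run):
        stages, _, data, _, full, _ = pipeline_run
        cfg = PipelineConfig(seed=0, allow_nonconsecutive=True)
        fwd = metabolink_transition(data, ("EB", "Rosette"), full.network, stages, cfg)
        rev = metabolink_transition(data, ("Rosette", "EB"), full.network, stages, cfg)
        for m in data.metabolite_names:
            fa, ra = fwd.node_attrs[m], rev.node_attrs[m]
            assert fa["delta_sign"] == -ra["delta_sign"]
            assert fa["delta_magnitude"] == pytest.approx(ra["delta_magnitude"])
            assert fa["score_intensity"] == pytest.approx(ra["score_intensity"], abs=1e-10)
            # the signed loading flips with the orientation, but each
            # metabolite stays associated with the same biological stage
            assert fa["feature_score"] == pytest.approx(-ra["feature_score"], abs=1e-10)
            if fa["assigned_stage"] is not None:
                assert fa["assigned_stage"] == ra["assigned_stage"]

    def test_non_consecutive_pair_needs_flag(self, pipeline_run):
        stages, _, data, _, full, _ = pipeline_run
        with pytest.raises(ValueError, match="consecutive"):
            metabolink_transition(data, ("hESC", "Neuron"), full.network, stages,
                                  PipelineConfig())
        cfg = PipelineConfig(allow_nonconsecutive=True)
        net = metabolink_transition(data, ("hESC", "Neuron"), full.network, stages, cfg)
        assert net.pair == ("hESC", "Neuron")

    def test_planted_marker_overlay(self):
        """A marker shifted +3 sigma with two strong conditional partners:
        assigned to the later stage, maximal intensity, edges to partners."""
        stages = StageSequence(["a", "b"])
        p = 6
        theta = np.zeros((p, p))
        theta[0, 1] = theta[1, 0] = -0.45
        theta[0, 2] = theta[2, 0] = -0.45
        np.fill_diagonal(theta, np.abs(theta).sum(axis=1) + 0.5)
        names = [f"M{j:03d}" for j in range(p)]
        truth = SyntheticTruth(
            theta_true=theta, support={(0, 1), (0, 2)},
            stage_means=np.zeros((2, p)), stages=stages, metabolite_names=names)
        truth = plant_markers(truth, ("a", "b"), ["M000"], shift=3.0)
        data = generate_dataset(truth, n_rep=60, seed=42)
        cfg = PipelineConfig(seed=0, transition_alpha=0.2)
        full = metabolink_full(data, stages, cfg)
        net = metabolink_transition(data, ("a", "b"), full.network, stages, cfg)
        attrs = net.node_attrs["M000"]
        assert attrs["assigned_stage"] == "b"
        assert attrs["score_intensity"] == pytest.approx(1.0)
        edges = net.transition_edges
        partners = {b for a, b, _ in edges if a == "M000"} | {a for a, b, _ in edges if b == "M000"}
        assert {"M001", "M002"} <= partners

    def test_identical_stages_give_small_deltas(self):
        stages = StageSequence(["a", "b"])
        truth = make_truth(15, stages, density=0.05, seed=31)  # no shifts planted
        n_rep = 50
        data = generate_dataset(truth, n_rep=n_rep, seed=310)
        cfg = PipelineConfig(seed=0)
        full = metabolink_full(data, stages, cfg)
        net = metabolink_transition(data, ("a", "b"), full.network, stages, cfg)
        max_delta = max(a["delta_magnitude"] for a in net.node_attrs.values())
        # each delta is ~ N(0, 2/n_rep); 3.5 sd bounds the max over 15
        # metabolites with high probability
        assert max_delta < 3.5 * np.sqrt(2.0 / n_rep)

    def test_marker_recovery_by_intensity(self, stages5):
        """Planted 3-sigma markers occupy the top intensity ranks."""
        passes = 0
        for seed in range(10):
            truth = make_truth(30, stages5, density=0.05, seed=seed)
            markers = ["M003", "M011", "M019", "M027"]
            truth = plant_markers(truth, ("EB", "Rosette"), markers, shift=3.0)
            data = generate_dataset(truth, n_rep=50, seed=seed + 500)
            cfg = PipelineConfig(seed=seed)
            full = metabolink_full(data, stages5, cfg)
            net = metabolink_transition(data, ("EB", "Rosette"), full.network, stages5, cfg)
            intens = {n: a["score_intensity"] for n, a in net.node_attrs.items()}
            top = sorted(intens, key=intens.get, reverse=True)[:len(markers)]
            passes += set(top) == set(markers)
        assert passes >= 8


class TestPipelineConfig:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("transition_alpha: 0.5\nseed: 3\ncv_folds: 3\n")
        cfg = PipelineConfig.from_yaml(path)
        assert cfg.transition_alpha == 0.5
        assert cfg.seed == 3
        assert cfg.cv_folds == 3
        assert cfg.n_components == 10  # default preserved

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("alpha_typo: 0.5\n")
        with pytest.raises(ValueError, match="alpha_typo"):
            PipelineConfig.from_yaml(path)
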