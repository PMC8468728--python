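import numpy as np
import pandas as pd
import pytest

from fabrynet import SimulationConfig, simulate_cohort, preprocess
from fabrynet.network import (
    NetworkConfig,
    PcorNetwork,
    build_network,
    consensus_signature,
    disease_specific_network,
    estimate_pcor,
    patient_specific_signatures,
    prune,
    shrinkage_lambda,
    SignatureSet,
)


def exact_correlation_data(r: np.ndarray, n: int = 50, seed: int = 0) -> pd.DataFrame:
    """Data whose *sample* correlation matrix equals ``r`` exactly."""
    rng = np.random.default_rng(seed)
    p = r.shape[0]
    z = rng.normal(size=(n, p))
    z -= z.mean(axis=0)
    # whiten so sample covariance is the identity, then colour by chol(r)
    cov = z.T @ z / (n - 1)
    w = np.linalg.cholesky(np.linalg.inv(cov))
    x = z @ w @ np.linalg.cholesky(r).T
    return pd.DataFrame(x, columns=[f"v{i}" for i in range(p)])


class TestEstimatePcor:
    def test_three_variable_closed_form_at_lambda_zero(self):
        r = np.full((3, 3), 0.5)
        np.fill_diagonal(r, 1.0)
        data = exact_correlation_data(r)
        pcor, lam = estimate_pcor(data, shrinkage=0.0)
        assert lam == 0.0
        # closed form: (0.5 - 0.25) / (1 - 0.25) = 1/3
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            assert pcor.iloc[i, j] == pytest.approx(1 / 3, abs=1e-10)

    def test_six_variable_matrix_inversion_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 6))
        data = pd.DataFrame(x, columns=list("abcdef"))
        pcor, _ = estimate_pcor(data, shrinkage=0.0)
        r = np.corrcoef(x, rowvar=False)
        omega = np.linalg.inv(r)
        d = np.sqrt(np.diag(omega))
        expected = -omega / np.outer(d, d)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(pcor.to_numpy(), expected, atol=1e-10)

    def test_full_shrinkage_zeroes_partial_correlations(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(size=(20, 5)))
        pcor, _ = estimate_pcor(data, shrinkage=1.0)
        off = pcor.to_numpy()[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_independent_variables_have_small_pcor(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(5000, 30)))
        pcor, _ = estimate_pcor(data)
        off = np.abs(pcor.to_numpy()[~np.eye(30, dtype=bool)])
        assert off.max() < 0.05

    def test_symmetric_unit_diagonal_and_invertible_when_p_exceeds_n(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.normal(size=(30, 60)))  # p > n
        pcor, lam = estimate_pcor(data)
        arr = pcor.to_numpy()
        np.testing.assert_allclose(arr, arr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(arr), 1.0)
        assert 0 < lam <= 1
        r = np.corrcoef(data.to_numpy(), rowvar=False)
        r_star = (1 - lam) * r + lam * np.eye(60)
        assert np.linalg.eigvalsh(r_star)[0] >= lam - 1e-8

    def test_too_few_samples_rejected(self):
        data = pd.DataFrame(np.ones((2, 4)))
        with pytest.raises(ValueError):
            estimate_pcor(data)

    def test_analytic_lambda_in_unit_interval(self):
        rng = np.random.default_rng(5)
        lam = shrinkage_lambda(rng.normal(size=(25, 40)))
        assert 0 < lam <= 1


class TestBuildNetwork:
    def pcor_frame(self, arr, ids=None):
        ids = ids or [f"v{i}" for i in range(arr.shape[0])]
        return pd.DataFrame(arr, index=ids, columns=ids)

    def test_quantile_keeps_single_strongest_edge(self):
        arr = np.eye(3)
        arr[0, 1] = arr[1, 0] = 0.9
        arr[0, 2] = arr[2, 0] = 0.1
        arr[1, 2] = arr[2, 1] = 0.2
        net = build_network(self.pcor_frame(arr), edge_rule="quantile", q=0.3)
        assert net.n_edges == 1
        assert net.nodes == {"v0", "v1"}

    def test_absolute_threshold_may_leave_empty_network(self):
        rng = np.random.default_rng(6)
        arr = rng.uniform(-0.1, 0.1, size=(4, 4))
        arr = (arr + arr.T) / 2
        np.fill_diagonal(arr, 1.0)
        net = build_network(self.pcor_frame(arr), edge_rule="absolute", tau=0.999)
        assert net.n_edges == 0 and net.nodes == set()

    def test_quantile_edge_count_matches_ceiling(self):
        rng = np.random.default_rng(7)
        m = 20
        arr = rng.uniform(-1, 1, size=(m, m)) * 0.9
        arr = (arr + arr.T) / 2
        np.fill_diagonal(arr, 1.0)
        for q in (0.01, 0.05, 0.2):
            net = build_network(self.pcor_frame(arr), edge_rule="quantile", q=q)
            assert net.n_edges == int(np.ceil(q * m * (m - 1) / 2))

    def test_bad_parameters_rejected(self):
        frame = self.pcor_frame(np.eye(3))
        with pytest.raises(ValueError):
            build_network(frame, edge_rule="quantile", q=0.0)
        with pytest.raises(ValueError):
            build_network(frame, edge_rule="absolute", tau=1.5)
        with pytest.raises(ValueError):
            build_network(frame, edge_rule="nonsense")

    def test_edge_list_and_graphml_roundtrip(self, tmp_path):
        arr = np.eye(3)
        arr[0, 1] = arr[1, 0] = -0.5
        net = build_network(self.pcor_frame(arr), edge_rule="absolute", tau=0.3)
        net.write_edge_list(tmp_path / "edges.csv")
        frame = pd.read_csv(tmp_path / "edges.csv")
        assert list(frame.columns) == ["node_a", "node_b", "pcor"]
        assert frame["pcor"].iloc[0] == pytest.approx(-0.5)
        net.write_graphml(tmp_path / "net.graphml")
        import networkx as nx

        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_edges() == 1


def net(*pairs, provenance="test"):
    return PcorNetwork({frozenset(p): 0.5 for p in pairs}, provenance=provenance)


class TestPrune:
    def test_set_difference_semantics(self):
        general = net(("a", "b"), ("b", "c"), ("c", "d"))
        specific = net(("b", "c"))
        out = prune(general, specific)
        assert out.edge_set() == {frozenset(("a", "b")), frozenset(("c", "d"))}
        assert out.nodes == {"a", "b", "c", "d"}

    def test_prune_by_self_is_empty(self):
        n = net(("a", "b"), ("b", "c"))
        assert prune(n, n).n_edges == 0

    def test_prune_by_empty_is_identity(self):
        n = net(("a", "b"))
        out = prune(n, PcorNetwork({}))
        assert out.edge_set() == n.edge_set()

    def test_matching_ignores_weights(self):
        general = PcorNetwork({frozenset(("a", "b")): 0.9})
        specific = PcorNetwork({frozenset(("a", "b")): -0.1})
        assert prune(general, specific).n_edges == 0

    def test_anti_monotone_in_specific_argument(self):
        rng = np.random.default_rng(8)
        nodes = [f"n{i}" for i in range(10)]
        pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        general = net(*[pairs[i] for i in rng.choice(len(pairs), 20, replace=False)])
        small_idx = rng.choice(len(pairs), 5, replace=False)
        small = net(*[pairs[i] for i in small_idx])
        big = net(*([pairs[i] for i in small_idx] + [pairs[i] for i in rng.choice(len(pairs), 10, replace=False)]))
        assert prune(general, big).n_edges <= prune(general, small).n_edges


class TestDiseaseStage:
    def test_duplicated_control_group_gives_mostly_pruned_network(self):
        """When 'patients' are a copy of the controls, the combined network
        nearly coincides with the control network and almost everything is
        pruned away."""
        cfg = SimulationConfig(seed=30, n_differential=0, disease_module_size=0, missing_rate=0.0)
        matrix, meta, _, _ = simulate_cohort(cfg)
        ctrl_ids = meta.ids_of("control")
        dup = matrix.data.loc[ctrl_ids].copy()
        dup.index = [f"DUP{i}" for i in range(len(dup))]
        data = pd.concat([matrix.data.loc[ctrl_ids], dup])
        from fabrynet.core_data import MetaboliteMatrix, SampleMetadata

        mat2 = MetaboliteMatrix(data, scale="raw")
        meta2 = SampleMetadata(
            pd.DataFrame(
                {
                    "group": ["control"] * len(ctrl_ids) + ["fabry"] * len(dup),
                    "sex": ["F", "M"] * len(ctrl_ids),
                    "age": 40.0,
                },
                index=data.index,
            )
        )
        processed, _ = preprocess(mat2)
        ncfg = NetworkConfig()
        from fabrynet.network import disease_plus_control_network, control_network

        both = disease_plus_control_network(processed, meta2, ncfg)
        d = disease_specific_network(processed, meta2, ncfg)
        if both.n_edges:
            ctrl = control_network(processed, meta2, ncfg, for_pruning=True)
            overlap = len(both.edge_set() & ctrl.edge_set()) / both.n_edges
            assert overlap >= 0.95
        assert d.n_edges <= max(2, 0.05 * max(1, both.n_edges))

    def test_signature_cardinality_and_determinism(self):
        cfg = SimulationConfig(seed=31, n_control=20, n_fabry=4, n_metabolites=30,
                               n_differential=10, disease_module_size=5, missing_rate=0.0)
        matrix, meta, _, _ = simulate_cohort(cfg)
        processed, _ = preprocess(matrix)
        sigs1 = patient_specific_signatures(processed, meta)
        sigs2 = patient_specific_signatures(processed, meta)
        assert len(sigs1.per_patient) == 4
        assert sigs1.per_patient == sigs2.per_patient

    def test_duplicated_patient_gets_identical_signature(self):
        cfg = SimulationConfig(seed=32, n_control=15, n_fabry=3, n_metabolites=25,
                               n_differential=8, disease_module_size=4, missing_rate=0.0)
        matrix, meta, _, _ = simulate_cohort(cfg)
        pid = meta.ids_of("fabry")[0]
        dup_row = matrix.data.loc[[pid]].rename(index={pid: "FABDUP"})
        from fabrynet.core_data import MetaboliteMatrix, SampleMetadata

        mat2 = MetaboliteMatrix(pd.concat([matrix.data, dup_row]), scale="raw")
        meta_row = meta.table.loc[[pid]].rename(index={pid: "FABDUP"})
        meta2 = SampleMetadata(pd.concat([meta.table, meta_row]))
        processed, _ = preprocess(mat2)
        sigs = patient_specific_signatures(processed, meta2)
        assert sigs.per_patient[pid] == sigs.per_patient["FABDUP"]

    def test_requires_both_groups(self, processed_cohort):
        processed, meta, _, _ = processed_cohort
        only_ctrl = meta.copy()
        only_ctrl.table = only_ctrl.table[only_ctrl.table.group == "control"]
        sub = processed.with_data(processed.data.loc[only_ctrl.sample_ids])
        with pytest.raises(ValueError, match="both groups"):
            disease_specific_network(sub, only_ctrl)


class TestConsensus:
    def sigset(self, *sigs):
        per_patient = {f"P{i}": sorted(s) for i, s in enumerate(sigs)}
        return SignatureSet.from_per_patient(per_patient)

    def test_strict_intersection(self):
        cons = consensus_signature(self.sigset({"m1", "m2"}, {"m1", "m3"}, {"m1"}))
        assert cons.members == ["m1"]
        assert cons.frequency["m1"] == 3

    def test_disjoint_signatures_yield_empty_consensus_with_frequencies(self):
        cons = consensus_signature(self.sigset({"m1"}, {"m2"}))
        assert cons.members == []
        assert cons.frequency == {"m1": 1, "m2": 1}

    def test_fraction_threshold(self):
        cons = consensus_signature(
            self.sigset({"m1", "m2"}, {"m1", "m3"}, {"m2", "m3"}), fraction=0.5
        )
        assert cons.members == ["m1", "m2", "m3"]

    def test_all_empty_signatures_error(self):
        with pytest.raises(ValueError, match="relax"):
            consensus_signature(self.sigset(set(), set()))

    def test_duplicates_collapsed_before_consensus(self):
        ss = self.sigset({"m1", "m2"}, {"m1", "m2"}, {"m1"})
        assert ss.n_signatures == 2  # deduplicated
        cons = consensus_signature(ss)
        assert cons.members == ["m1"]

    def test_fallback_to_most_redundant(self):
        cons = consensus_signature(self.sigset({"m1", "m2"}, {"m1"}, {"m3"}), fallback_to_top=True)
        assert cons.members == ["m1"]
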