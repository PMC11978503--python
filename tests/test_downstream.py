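"""Module analytics: activation, states, markers, graphs, confidence."""

import numpy as np
import pandas as pd
import pytest

from modvelo import downstream as ds
from modvelo.inference import PosteriorBundle, PriorConfig, fit
from modvelo.kinetics import GeneRates, ModuleKinetics, module_spliced
from modvelo.simulate import SimulationConfig, simulate


def bundle_from_params(kin, rates, times, S=3):
    """Degenerate posterior: every sample equals the given parameter set."""
    C = len(times)
    M, G = kin.target_rate.shape

    def rep(x):
        return np.repeat(np.asarray(x, float)[None], S, axis=0)

    samples = {
        "t": rep(times),
        "l_cell": rep(np.ones(C)),
        "l_mod": rep(np.ones(2)),
        "beta": rep(rates.splicing),
        "gamma": rep(rates.degradation),
        "a": rep(np.full((G, 2), 5.0)),
        "ahat": rep(kin.target_rate),
        "lam_on": rep(kin.activation_rate),
        "lam_off": rep(kin.deactivation_rate),
        "t_on": rep(kin.switch_on),
        "t_off": rep(kin.switch_off),
    }
    return PosteriorBundle(
        samples=samples,
        elbo_trace=np.zeros(1),
        seed=0,
        n_modules=M,
        t_max=10.0,
        gene_names=pd.Index([f"gene_{i}" for i in range(G)]),
        cell_names=pd.Index([f"cell_{i}" for i in range(C)]),
    )


@pytest.fixture
def two_module_bundle():
    kin = ModuleKinetics(
        target_rate=np.array([[2.0, 0.5, 0.0], [0.0, 0.5, 1.2]]),
        activation_rate=[1.5, 2.0],
        deactivation_rate=[1.0, 1.0],
        switch_on=[0.0, 2.0],
        switch_off=[np.inf, np.inf],
    )
    rates = GeneRates(splicing=[0.8, 1.0, 0.6], degradation=[0.4, 0.5, 0.3])
    times = np.array([0.0, 1.0, 3.0, 8.0, 60.0])
    return bundle_from_params(kin, rates, times), kin, rates, times


class TestModuleActivation:
    def test_zero_before_switch_on(self, two_module_bundle):
        pb, kin, rates, times = two_module_bundle
        act = ds.module_activation(pb)
        assert act.activation[0, 0] == 0.0  # t=0 = switch-on of module 0
        assert act.activation[1, 1] == 0.0  # t=1 < switch-on (2.0) of module 1

    def test_matches_kinetics_evaluation(self, two_module_bundle):
        """Internal consistency: activation equals the closed forms."""
        pb, kin, rates, times = two_module_bundle
        act = ds.module_activation(pb)
        expected = module_spliced(times, kin, rates).sum(axis=-1)
        assert np.allclose(act.activation, expected, rtol=1e-12)

    def test_long_time_reaches_steady_state_sum(self, two_module_bundle):
        pb, kin, rates, _ = two_module_bundle
        act = ds.module_activation(pb)
        ss = (kin.target_rate / rates.degradation).sum(axis=-1)
        assert act.activation[-1] == pytest.approx(ss, rel=1e-6)


class TestNormalizedActivation:
    def test_bounds_and_endpoints(self, two_module_bundle):
        pb, _, _, _ = two_module_bundle
        norm = ds.normalized_activation(pb)
        assert norm[0, 0] == pytest.approx(0.0, abs=1e-12)  # at switch-on
        assert norm[-1, 0] == pytest.approx(1.0, rel=1e-6)  # at steady state
        assert np.all(norm >= -1e-9) and np.all(norm <= 1.0 + 1e-9)

    def test_monotone_during_induction(self):
        kin = ModuleKinetics([[1.0]], [2.0], [1.0], [1.0], [9.0])
        rates = GeneRates([0.7], [0.4])
        times = np.linspace(1.0, 9.0, 40)
        pb = bundle_from_params(kin, rates, times)
        norm = ds.normalized_activation(pb)[:, 0]
        assert np.all(np.diff(norm) >= -1e-12)

    def test_zero_steady_state_flagged(self):
        kin = ModuleKinetics([[0.0]], [1.0], [1.0], [0.0], [np.inf])
        pb = bundle_from_params(kin, GeneRates([1.0], [1.0]), np.array([1.0]))
        act = ds.module_activation(pb)
        assert act.undefined[0]
        assert np.isnan(act.normalized[0, 0])


class TestModuleState:
    def test_threshold_rules(self):
        # below switch-on or norm < 0.05 -> OFF; norm > 0.95 -> ON;
        # otherwise induction/repression split at the switch-off time
        assert ds.module_state(0.01, t=5.0, t_on=1.0, t_off=9.0) == "OFF"
        assert ds.module_state(0.5, t=0.5, t_on=1.0, t_off=9.0) == "OFF"
        assert ds.module_state(0.96, t=5.0, t_on=1.0, t_off=9.0) == "ON"
        assert ds.module_state(0.5, t=5.0, t_on=1.0, t_off=9.0) == "induction"
        assert ds.module_state(0.5, t=9.5, t_on=1.0, t_off=9.0) == "repression"

    def test_states_partition_all_pairs(self):
        rng = np.random.default_rng(0)
        norm = rng.uniform(-0.02, 1.02, (50, 3))
        t = rng.uniform(0, 10, (50, 1))
        labels = ds.module_state(norm, t, t_on=2.0, t_off=7.0)
        assert set(np.unique(labels)) <= set(ds.STATE_LABELS)

    def test_all_four_states_on_synthetic_trace(self):
        """A module switched on then off traverses OFF->induction->ON->repression."""
        kin = ModuleKinetics([[5.0]], [3.0], [0.4], [2.0], [6.0])
        rates = GeneRates([2.0], [2.0])
        times = np.linspace(0.0, 12.0, 60)
        pb = bundle_from_params(kin, rates, times)
        act = ds.module_activation(pb)
        labels = ds.module_state(
            act.normalized[:, 0], times, kin.switch_on[0], kin.switch_off[0]
        )
        seen = list(pd.unique(labels))
        assert seen == ["OFF", "induction", "ON", "repression"]


class TestVelocityGraph:
    def test_rows_are_probability_vectors(self):
        data, truth = simulate(SimulationConfig(n_cells=60, n_genes=25, seed=2))
        pb = bundle_from_params(truth.kinetics, truth.rates, truth.times, S=4)
        trans, idx, isolated = ds.velocity_graph(pb, data, n_samples=3, n_neighbors=8)
        assert np.allclose(trans.sum(axis=1), 1.0)
        assert trans.min() >= 0
        assert not isolated.any()

    def test_single_sample_reproduces_single_graph(self):
        data, truth = simulate(SimulationConfig(n_cells=40, n_genes=20, seed=3))
        pb = bundle_from_params(truth.kinetics, truth.rates, truth.times, S=1)
        t1, idx1, _ = ds.velocity_graph(pb, data, n_samples=1, n_neighbors=6)
        t2, _, _ = ds.velocity_graph(pb, data, n_samples=1, n_neighbors=6)
        assert np.array_equal(t1, t2)

    def test_aligned_velocity_gets_max_probability(self):
        """5-cell brute-force check of the cosine-kernel transition rule."""
        data, truth = simulate(SimulationConfig(n_cells=5, n_genes=12, seed=4))
        pb = bundle_from_params(truth.kinetics, truth.rates, truth.times, S=1)
        trans, idx, _ = ds.velocity_graph(pb, data, n_samples=1, n_neighbors=3)
        # independent reimplementation
        smoothed, idx2 = ds._log_smoothed_expression(data, n_pcs=30, n_neighbors=3)
        from modvelo.kinetics import velocity

        v = velocity(truth.times, truth.kinetics, truth.rates) / (
            data.spliced.astype(float) + 1.0
        )
        expect = np.zeros_like(trans)
        for c in range(5):
            cos = np.zeros(idx2.shape[1])
            for jpos, j in enumerate(idx2[c]):
                d = smoothed[j] - smoothed[c]
                denom = np.linalg.norm(d) * np.linalg.norm(v[c])
                cos[jpos] = (d @ v[c]) / denom if denom > 0 else 0.0
            k = np.exp(cos / 0.25)
            expect[c] = k / k.sum()
        assert np.allclose(trans, expect, rtol=1e-10)


class TestMarkersAndReference:
    def test_exclusive_gene_tops_its_module(self, two_module_bundle):
        pb, _, _, _ = two_module_bundle
        top = ds.module_markers(pb, module=0, k=3)
        assert top.iloc[0]["gene"] == "gene_0"
        assert top.iloc[0]["fraction"] == pytest.approx(1.0)

    def test_shared_gene_fraction_half(self, two_module_bundle):
        pb, _, _, _ = two_module_bundle
        top0 = ds.module_markers(pb, module=0, k=3)
        row = top0[top0["gene"] == "gene_1"].iloc[0]
        assert row["fraction"] == pytest.approx(0.5)

    def test_fractions_sum_to_one_across_modules(self, two_module_bundle):
        pb, _, _, _ = two_module_bundle
        ahat = pb.posterior_mean("ahat")
        total = ahat.sum(axis=0)
        frac = ahat / total
        assert np.allclose(frac.sum(axis=0), 1.0)

    def test_unknown_module_rejected(self, two_module_bundle):
        pb, _, _, _ = two_module_bundle
        with pytest.raises(ValueError, match="unknown module"):
            ds.module_markers(pb, module=5)

    def test_simulation_markers_recovered(self):
        data, truth = simulate(SimulationConfig(n_cells=200, n_genes=60, n_modules=2, seed=8))
        pb = bundle_from_params(truth.kinetics, truth.rates, truth.times, S=1)
        for m in range(2):
            true_markers = set(
                np.asarray(data.gene_names)[truth.primary_module == m]
            )
            top = ds.module_markers(pb, m, k=len(true_markers))
            hits = len(true_markers & set(top["gene"]))
            assert hits / len(true_markers) >= 0.8

    def test_steady_state_formula_and_roundtrip(self, tmp_path, two_module_bundle):
        pb, kin, rates, _ = two_module_bundle
        ref = ds.steady_state_reference(pb)
        # single gene check: ahat=2, gamma=0.5... gene_0 module_0: 2.0/0.4 = 5
        assert ref.table.loc["gene_0", "module_0"] == pytest.approx(2.0 / 0.4)
        # OFF-only module column is zero where ahat = 0
        assert ref.table.loc["gene_0", "module_1"] == 0.0
        path = tmp_path / "ref.csv"
        ref.to_csv(path)
        back = ds.SteadyStateReference.from_csv(path)
        assert np.allclose(back.table.values, ref.table.values, rtol=1e-9)


class TestTransitionConfidence:
    def test_fully_separated_clusters(self):
        anc = np.random.default_rng(0).uniform(0, 1, 500)
        dec = anc + 2.0
        assert ds.transition_confidence(anc, dec) == 1.0
        assert ds.transition_confidence(dec, anc) == 0.0

    def test_iid_null_expectation_is_ten_percent(self):
        rng = np.random.default_rng(1)
        n = 100_000
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        score = ds.transition_confidence(a, b)
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(score - 0.10) < 3 * se + 1e-3  # +quantile-estimation slack

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            ds.transition_confidence(np.array([]), np.array([1.0]))
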