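"""Penalized batch energy, Gibbs conditionals, and the three optimizers."""

import numpy as np
import pytest

from evhdesign import (
    Alignment,
    DesignConfig,
    batch_energy,
    design_batch,
    enumerate_boltzmann,
    evh,
    greedy_design,
    penalty_terms,
    planted_model,
    tempering_design,
)
from evhdesign.design import conditional_probs, gibbs_update, sample_state_counts
from evhdesign.potts import PottsModel


def free_config(**kw):
    """Config with all penalties off unless overridden."""
    defaults = dict(lambda_target=0.0, lambda_diversity=0.0, lambda_alignment=0.0,
                    d_min=0.3)
    defaults.update(kw)
    return DesignConfig(**defaults)


class TestConfig:
    def test_defaults_follow_published_setting(self):
        cfg = DesignConfig(d_min=0.30)
        assert cfg.d_max == pytest.approx(0.35)
        assert cfg.d_diversity == cfg.d_alignment == 0.30
        assert (cfg.lambda_target, cfg.lambda_diversity, cfg.lambda_alignment) == (1000, 10, 10)
        assert (cfg.beta_start, cfg.beta_end, cfg.n_sweeps, cfg.M) == (0.5, 10.0, 1000, 6)

    @pytest.mark.parametrize("kw", [
        dict(d_min=0.5, d_max=0.4),
        dict(d_min=-0.1),
        dict(M=0),
        dict(n_sweeps=0),
        dict(lambda_target=-1.0),
        dict(mode="anneal"),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            DesignConfig(**kw)


class TestPenaltyTerms:
    def test_target_penalty_at_zero_distance(self, dense_model):
        cfg = DesignConfig(d_min=0.3)
        tgt = dense_model._as_indices("ACDEA")
        tpen, dpen, apen = penalty_terms(tgt, [], tgt, None, cfg)
        assert tpen == pytest.approx(1000 * 0.3)
        assert dpen == 0.0 and apen == 0.0

    def test_diversity_penalty_per_offending_neighbour(self, dense_model):
        cfg = DesignConfig(d_min=0.3)
        s = dense_model._as_indices("ACDEA")
        _, dpen, _ = penalty_terms(s, [s.copy(), s.copy()], s, None, cfg)
        assert dpen == pytest.approx(2 * 10.0)

    def test_all_constraints_satisfied_gives_zero(self):
        # L=25 so distances hit the band [0.30, 0.35] exactly: 8/25 = 0.32
        L, q = 25, 4
        m = PottsModel(h=np.zeros((L, q)), J=np.zeros((L, L, q, q)), alphabet="ACDE")
        cfg = DesignConfig(d_min=0.30)
        tgt = np.zeros(L, dtype=int)
        s = tgt.copy()
        s[:8] = 1
        far = np.full(L, 2)
        assert penalty_terms(s, [far], tgt, far[None, :], cfg) == (0.0, 0.0, 0.0)


class TestBatchEnergy:
    def test_zero_model_zero_penalties(self, zero_model):
        cfg = free_config()
        batch = ["ACDA", "DDCC"]
        U, total = batch_energy(batch, zero_model, "ACDA", None, cfg)
        assert np.allclose(U, 0.0) and total == 0.0

    def test_member_equal_to_target_in_band(self, dense_model):
        cfg = DesignConfig(d_min=0.0, d_max=0.05)
        U, _ = batch_energy(["ACDEA"], dense_model, "ACDEA", None, cfg)
        assert U[0] == pytest.approx(-evh(dense_model, "ACDEA"))

    def test_lambda_zero_reduces_to_negative_evh_sum(self, dense_model):
        cfg = free_config()
        batch = ["ACDEA", "EDCAA", "CCCCC"]
        U, total = batch_energy(batch, dense_model, "ACDEA", None, cfg)
        assert total == pytest.approx(-sum(evh(dense_model, s) for s in batch))

    def test_penalties_are_nonnegative(self, dense_model):
        rng = np.random.default_rng(3)
        cfg = DesignConfig(d_min=0.4)
        tgt = rng.integers(0, 4, 5)
        msa = rng.integers(0, 4, (6, 5))
        for _ in range(20):
            s = rng.integers(0, 4, 5)
            others = [rng.integers(0, 4, 5) for _ in range(2)]
            assert min(penalty_terms(s, others, tgt, msa, cfg)) >= 0.0


class TestGibbsConditional:
    def test_flat_energy_gives_uniform(self):
        L, q = 3, 21  # 20 amino acids + gap; gap never proposed
        m = PottsModel(h=np.zeros((L, q)), J=np.zeros((L, L, q, q)))
        S = np.zeros((1, L), dtype=np.int64)
        p = conditional_probs(m, S, 0, 1, beta=1.0, target=S[0], msa=None,
                              cfg=free_config())
        assert p.shape == (20,)
        assert np.allclose(p, 1 / 20)

    def test_softmax_arithmetic_single_site(self):
        # two states, h = (0, ln 2), beta=1 -> probabilities (1/3, 2/3)
        h = np.array([[0.0, np.log(2.0)]])
        m = PottsModel(h=h, J=np.zeros((1, 1, 2, 2)), alphabet="AC")
        S = np.zeros((1, 1), dtype=np.int64)
        p = conditional_probs(m, S, 0, 0, beta=1.0, target=S[0], msa=None,
                              cfg=free_config())
        assert np.allclose(p, [1 / 3, 2 / 3])

    def test_conditional_normalizes(self, tiny_model):
        rng = np.random.default_rng(1)
        S = rng.integers(0, 3, (2, 6)).astype(np.int64)
        cfg = DesignConfig(d_min=0.3)
        p = conditional_probs(tiny_model, S, 1, 4, beta=2.0, target=S[0],
                              msa=S.copy(), cfg=cfg)
        assert p.sum() == pytest.approx(1.0)

    def test_gibbs_update_changes_only_one_slot(self, tiny_model):
        rng = np.random.default_rng(2)
        S = rng.integers(0, 3, (3, 6)).astype(np.int64)
        before = S.copy()
        gibbs_update(tiny_model, S, 2, 3, 1.0, np.random.default_rng(0),
                     before[0], None, free_config())
        changed = S != before
        assert changed[:2].sum() == 0 and changed[2, :3].sum() == 0 \
            and changed[2, 4:].sum() == 0


class TestStationaryDistribution:
    def test_long_run_frequencies_match_boltzmann(self, tiny_model):
        counts = sample_state_counts(tiny_model, beta=1.0, n_sweeps=30_000, seed=11)
        _, p = enumerate_boltzmann(tiny_model, 1.0)
        tv = 0.5 * np.abs(counts / counts.sum() - p).sum()
        assert tv < 0.05

    def test_kernel_equals_python_reference(self, tiny_model):
        fast = sample_state_counts(tiny_model, beta=1.0, n_sweeps=300, seed=5)
        slow = sample_state_counts(tiny_model, beta=1.0, n_sweeps=300, seed=5,
                                   _reference=True)
        assert np.array_equal(fast, slow)

    def test_raising_lambda_cannot_favour_band_violations(self, tiny_model):
        # exact single-sequence equilibrium under -EVH + target penalty
        m = tiny_model
        states, _ = enumerate_boltzmann(m, 1.0)
        tgt = states[0]
        d = (states != tgt).mean(axis=1)
        cfg0 = DesignConfig(d_min=0.3, d_max=0.5)
        viol = (d < cfg0.d_min) | (d > cfg0.d_max)
        energies = np.array([evh(m, s) for s in states])
        prev = None
        for lam in (0.0, 5.0, 50.0):
            U = -energies + lam * np.where(viol, np.abs(d - cfg0.d_min), 0.0)
            w = np.exp(-(U - U.min()))
            pviol = w[viol].sum() / w.sum()
            if prev is not None:
                assert pviol <= prev + 1e-12
            prev = pviol


class TestDesignBatch:
    def test_default_batch_size_is_six(self, tiny_model):
        cfg = free_config(n_sweeps=5)
        res = design_batch(tiny_model, cfg, target_seq=tiny_model.decode(
            np.zeros(6, dtype=int)))
        assert len(res.sequences) == 6

    def test_same_seed_reproduces_everything(self, tiny_model):
        cfg = DesignConfig(d_min=0.3, n_sweeps=20, seed=123, M=3)
        tgt = tiny_model.decode(np.zeros(6, dtype=int))
        r1 = design_batch(tiny_model, cfg, target_seq=tgt)
        r2 = design_batch(tiny_model, cfg, target_seq=tgt)
        assert r1.sequences == r2.sequences
        assert np.array_equal(r1.trace_total_U, r2.trace_total_U)

    def test_kernel_and_reference_agree_with_penalties(self, tiny_model):
        rng = np.random.default_rng(8)
        msa = Alignment(["a", "b"],
                        [tiny_model.decode(rng.integers(0, 3, 6)) for _ in range(2)],
                        alphabet=tiny_model.alphabet)
        cfg = DesignConfig(d_min=0.3, n_sweeps=15, seed=7, M=2)
        tgt = tiny_model.decode(rng.integers(0, 3, 6))
        fast = design_batch(tiny_model, cfg, target_seq=tgt, msa=msa)
        slow = design_batch(tiny_model, cfg, target_seq=tgt, msa=msa, _reference=True)
        assert fast.sequences == slow.sequences
        assert np.allclose(fast.trace_total_U, slow.trace_total_U, atol=1e-9)

    def test_trace_lengths_and_beta_schedule(self, tiny_model):
        cfg = free_config(n_sweeps=10, beta_start=0.5, beta_end=10.0)
        res = design_batch(tiny_model, cfg,
                           target_seq=tiny_model.decode(np.zeros(6, dtype=int)))
        assert len(res.trace_total_U) == 10
        assert res.trace_beta[0] == pytest.approx(0.5)
        assert res.trace_beta[-1] == pytest.approx(10.0)

    def test_constraint_flags_recomputable_from_sequences(self, tiny_model):
        from evhdesign import normalized_hamming

        cfg = DesignConfig(d_min=0.3, n_sweeps=50, seed=3, M=3)
        tgt = tiny_model.decode(np.zeros(6, dtype=int))
        res = design_batch(tiny_model, cfg, target_seq=tgt)
        for a, seq in enumerate(res.sequences):
            d = normalized_hamming(seq, tgt)
            assert res.target_band_ok[a] == (cfg.d_min - 1e-12 <= d <= cfg.d_max + 1e-12)

    def test_infeasible_distance_band_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            DesignConfig(d_min=1.0)


class TestGreedy:
    def test_global_optimum_is_fixed_point(self, tiny_model):
        states, _ = enumerate_boltzmann(tiny_model, 1.0)
        energies = [evh(tiny_model, s) for s in states]
        opt = tiny_model.decode(states[int(np.argmax(energies))])
        assert greedy_design(tiny_model, opt) == opt

    def test_zero_model_returns_start(self, zero_model):
        assert greedy_design(zero_model, "ACDA") == "ACDA"

    def test_never_decreases_energy(self, dense_model):
        rng = np.random.default_rng(4)
        for _ in range(5):
            start = dense_model.decode(rng.integers(0, 4, 5))
            out = greedy_design(dense_model, start)
            assert evh(dense_model, out) >= evh(dense_model, start)
            # local optimality of the endpoint
            s = dense_model._as_indices(out)
            for i in range(5):
                for x in range(4):
                    if x != s[i]:
                        s2 = s.copy()
                        s2[i] = x
                        assert evh(dense_model, s2) <= evh(dense_model, out) + 1e-12

    def test_matches_exhaustive_hillclimb_oracle(self):
        from evhdesign.benchmarks import exhaustive_hillclimb

        rng = np.random.default_rng(9)
        for k in range(10):
            pm = planted_model(5, 3, n_edges=4, coupling_strength=1.0,
                               field_scale=0.7, seed=500 + k, topology="chain")
            start = pm.model.decode(rng.integers(0, 3, 5))
            assert greedy_design(pm.model, start) == \
                exhaustive_hillclimb(pm.model, start)


class TestTempering:
    def test_schedule_closed_form(self):
        assert 1.002 ** 1000 == pytest.approx(7.374, abs=5e-4)

    def test_deterministic_given_seed(self, tiny_model):
        cfg = DesignConfig(mode="tempering", seed=21, n_sweeps=50)
        assert tempering_design(tiny_model, cfg) == tempering_design(tiny_model, cfg)

    def test_returns_best_ever_energy(self, tiny_model):
        cfg = DesignConfig(mode="tempering", seed=2, n_sweeps=100)
        seq, best = tempering_design(tiny_model, cfg)
        assert best == pytest.approx(evh(tiny_model, seq), abs=1e-9)

    def test_finds_two_basin_global_optimum(self):
        from evhdesign import two_basin_model

        m = two_basin_model()
        states, _ = enumerate_boltzmann(m, 1.0)
        energies = [evh(m, s) for s in states]
        opt = m.decode(states[int(np.argmax(energies))])
        seq, _ = tempering_design(m, DesignConfig(mode="tempering", seed=0))
        assert seq == opt

    def test_single_replica_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tempering_design(tiny_model, DesignConfig(mode="tempering", n_replicas=1))
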