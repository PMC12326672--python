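import numpy as np
import pytest

from gbadti.config import RunConfig
from gbadti.errors import ValidationError
from gbadti.featurize import feature_similarity_matrix
from gbadti.io import InteractionSet
from gbadti.model import TwoTowerModel, cosine_distance
from gbadti.reldist import RelativeDistanceBundle, build_bundle
from gbadti.train import (
    Adam,
    LossReport,
    TrainingBatch,
    gba_loss,
    make_batches,
    oi_loss,
    sample_negatives,
    train,
)
from tests.conftest import dice_matrix_from_bits


def brute_force_gba(Zd, Zp, RDd, RDp, pairs, lam):
    """Independent double-loop implementation of the loss."""
    def phi(u, v):
        return 1 - u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
    m, n = len(Zd), len(Zp)
    l_drug = np.mean([(phi(Zd[i], Zd[j]) - RDd[i, j]) ** 2
                      for i in range(m) for j in range(m) if i != j])
    l_protein = np.mean([(phi(Zp[i], Zp[j]) - RDp[i, j]) ** 2
                         for i in range(n) for j in range(n) if i != j])
    l_int = np.mean([(phi(Zd[i], Zp[j]) - rd) ** 2 for i, j, rd in pairs])
    return l_drug, l_protein, l_int, l_drug + l_protein + lam * l_int


def random_instance(rng, m=None, n=None, d=None):
    m = m or int(rng.integers(2, 16))
    n = n or int(rng.integers(2, 16))
    d = d or int(rng.integers(2, 9))
    Zd = rng.normal(size=(m, d))
    Zp = rng.normal(size=(n, d))
    RDd = rng.random((m, m)); RDd = (RDd + RDd.T) / 2; np.fill_diagonal(RDd, 0)
    RDp = rng.random((n, n)); np.fill_diagonal(RDp, 0)
    k = int(rng.integers(1, m * n // 2 + 2))
    pi = rng.integers(0, m, size=k)
    pj = rng.integers(0, n, size=k)
    rd = rng.integers(0, 2, size=k).astype(float)
    return Zd, Zp, RDd, RDp, pi, pj, rd


class TestGbaLoss:
    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(50):
            Zd, Zp, RDd, RDp, pi, pj, rd = random_instance(rng)
            rep = gba_loss(Zd, Zp, RDd, RDp, (pi, pj, rd), 1 / 3)
            ld, lp, li, tot = brute_force_gba(
                Zd, Zp, RDd, RDp, list(zip(pi, pj, rd)), 1 / 3)
            assert rep.l_drug == pytest.approx(ld, abs=1e-6)
            assert rep.l_protein == pytest.approx(lp, abs=1e-6)
            assert rep.l_interaction == pytest.approx(li, abs=1e-6)
            assert rep.total == pytest.approx(tot, abs=1e-6)

    def test_perfect_fit_gives_zero(self, rng):
        # build RD targets from the embeddings themselves
        Zd = rng.normal(size=(4, 5))
        Zp = rng.normal(size=(3, 5))
        RDd = np.array([[cosine_distance(Zd[i], Zd[j]) if i != j else 0
                         for j in range(4)] for i in range(4)])
        RDp = np.array([[cosine_distance(Zp[i], Zp[j]) if i != j else 0
                         for j in range(3)] for i in range(3)])
        pi, pj = np.array([0, 1]), np.array([1, 2])
        rd = np.array([cosine_distance(Zd[0], Zp[1]),
                       cosine_distance(Zd[1], Zp[2])])
        rep = gba_loss(Zd, Zp, np.clip(RDd, 0, 1), np.clip(RDp, 0, 1),
                       (pi, pj, rd), 1 / 3)
        # RD targets may exceed 1 for anti-aligned pairs; clip only if within
        if (RDd <= 1).all() and (RDp <= 1).all() and (rd <= 1).all():
            assert rep.total == pytest.approx(0.0, abs=1e-12)

    def test_lambda_zero_ignores_labels(self, rng):
        Zd, Zp, RDd, RDp, pi, pj, rd = random_instance(rng)
        t1 = gba_loss(Zd, Zp, RDd, RDp, (pi, pj, rd), 0.0).total
        t2 = gba_loss(Zd, Zp, RDd, RDp, (pi, pj, 1 - rd), 0.0).total
        assert t1 == t2

    def test_report_total_identity_at_one_third(self, rng):
        Zd, Zp, RDd, RDp, pi, pj, rd = random_instance(rng)
        rep = gba_loss(Zd, Zp, RDd, RDp, (pi, pj, rd), 1 / 3)
        assert rep.total == pytest.approx(
            rep.l_drug + rep.l_protein + rep.l_interaction / 3, abs=1e-12)

    def test_analytic_gradients_match_numerical(self, rng):
        cfg = RunConfig.small(seed=3, d_m=20, d_t=10, d_h=8, d_s=4)
        model = TwoTowerModel(cfg)
        Xd, Xp = rng.random((5, 20)), rng.random((4, 10))
        RDd = rng.random((5, 5)); RDd = (RDd + RDd.T) / 2; np.fill_diagonal(RDd, 0)
        RDp = rng.random((4, 4)); np.fill_diagonal(RDp, 0)
        bp = (np.array([0, 1, 2]), np.array([1, 0, 3]), np.array([0., 1., 0.]))

        def total():
            Zd = model.encode_drugs(Xd, training=True, update_stats=False)
            Zp = model.encode_proteins(Xp, training=True, update_stats=False)
            return gba_loss(Zd, Zp, RDd, RDp, bp, 1 / 3).total

        Zd = model.encode_drugs(Xd, training=True, update_stats=False)
        Zp = model.encode_proteins(Xp, training=True, update_stats=False)
        _, dZd, dZp = gba_loss(Zd, Zp, RDd, RDp, bp, 1 / 3, with_grad=True)
        gd = model.drug_tower.backward(dZd)
        gp = model.protein_tower.backward(dZp)
        eps = 1e-6
        for tower, grads in ((model.drug_tower, gd), (model.protein_tower, gp)):
            for name in tower.PARAM_NAMES:
                P = getattr(tower, name)
                idx = tuple(rng.integers(0, s) for s in P.shape)
                orig = P[idx]
                P[idx] = orig + eps; lo = total()
                P[idx] = orig - eps; hi = total()
                P[idx] = orig
                num = (lo - hi) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, abs=1e-5)


class TestOiLoss:
    def test_equals_gba_interaction_component(self, rng):
        Zd, Zp, RDd, RDp, pi, pj, rd = random_instance(rng)
        assert oi_loss(Zd, Zp, (pi, pj, rd)).l_interaction == pytest.approx(
            gba_loss(Zd, Zp, RDd, RDp, (pi, pj, rd), 1 / 3).l_interaction,
            abs=1e-12)

    def test_zero_when_every_pair_fits(self):
        Zd = np.array([[1.0, 0.0], [0.0, 1.0]])
        Zp = np.array([[1.0, 0.0], [0.0, 1.0]])
        # pair (0,0): identical -> phi 0 = rd for y=1; (0,1): orthogonal -> phi 1
        bp = (np.array([0, 0]), np.array([0, 1]), np.array([0.0, 1.0]))
        assert oi_loss(Zd, Zp, bp).total == pytest.approx(0.0, abs=1e-12)

    def test_positive_on_any_deviation(self, rng):
        Zd, Zp, _, _, pi, pj, rd = random_instance(rng)
        rep = oi_loss(Zd, Zp, (pi, pj, rd))
        assert rep.l_drug == rep.l_protein == 0.0
        assert rep.l_interaction > 0


class TestSampleNegatives:
    DRUGS = [f"d{i}" for i in range(5)]
    PROTS = [f"p{j}" for j in range(4)]

    def _positives(self, k=10):
        pairs = [(f"d{i % 5}", f"p{(i * 2 + i // 5) % 4}", 1) for i in range(20)]
        uniq = list(dict.fromkeys(pairs))[:k]
        return InteractionSet(pairs=uniq)

    def test_count_and_disjointness(self):
        pos = self._positives(10)
        neg = sample_negatives(pos, self.DRUGS, self.PROTS, 1, seed=0)
        assert len(neg) == 10
        assert not set(neg.negatives()) & set(pos.positives())

    def test_seed_determinism(self):
        pos = self._positives(5)
        a = sample_negatives(pos, self.DRUGS, self.PROTS, 1, seed=3)
        b = sample_negatives(pos, self.DRUGS, self.PROTS, 1, seed=3)
        c = sample_negatives(pos, self.DRUGS, self.PROTS, 1, seed=4)
        assert a.pairs == b.pairs
        assert a.pairs != c.pairs

    def test_universe_arithmetic(self):
        drugs = ["a", "b", "c"]
        prots = ["x", "y", "z"]
        # 9 cells, 4 positives -> 5 free pairs: ratio 1 fits, ratio 2 does not
        pos = InteractionSet(pairs=[(d, p, 1) for d in drugs for p in prots][:4])
        neg = sample_negatives(pos, drugs, prots, 1, seed=0)
        assert len(neg) == 4
        with pytest.raises(ValidationError, match="unlabeled"):
            sample_negatives(pos, drugs, prots, 2, seed=0)


class TestSampleNegativesSmallRatio:
    def test_ratio_one_with_one_free_cell(self):
        drugs, prots = ["a", "b", "c"], ["x", "y", "z"]
        pos = InteractionSet(pairs=[(d, p, 1) for d in drugs for p in prots][:1])
        neg = sample_negatives(pos, drugs, prots, 1, seed=0)
        assert len(neg) == 1


class TestMakeBatches:
    def _pairs(self, n, rng):
        return [(int(rng.integers(0, 20)), int(rng.integers(0, 15)), float(rng.integers(0, 2)))
                for _ in range(n)]

    def test_merge_rule_100_over_32(self, rng):
        batches = make_batches(self._pairs(100, rng), 32, np.random.default_rng(1))
        assert [len(b) for b in batches] == [32, 32, 36]

    def test_partition_covers_pairs_exactly_once(self, rng):
        pairs = self._pairs(75, rng)
        batches = make_batches(pairs, 20, np.random.default_rng(2))
        got = sorted(
            (int(b.drug_indices[b.pair_drug[k]]),
             int(b.protein_indices[b.pair_protein[k]]), float(b.pair_rd[k]))
            for b in batches for k in range(len(b)))
        assert got == sorted(pairs)

    def test_same_seed_same_batches(self, rng):
        pairs = self._pairs(64, rng)
        a = make_batches(pairs, 16, np.random.default_rng(5))
        b = make_batches(pairs, 16, np.random.default_rng(5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.pair_rd, y.pair_rd)
            np.testing.assert_array_equal(x.drug_indices, y.drug_indices)

    def test_too_few_entities_rejected(self):
        with pytest.raises(ValidationError):
            make_batches([(0, 0, 1.0), (0, 1, 0.0)], 2, np.random.default_rng(0))


class TestTrainingBatch:
    def test_duplicate_entities_rejected(self):
        with pytest.raises(ValidationError):
            TrainingBatch(np.array([1, 1]), np.array([0, 1]),
                          np.array([0]), np.array([0]), np.array([0.0]))

    def test_needs_two_of_each(self):
        with pytest.raises(ValidationError):
            TrainingBatch(np.array([1]), np.array([0, 1]),
                          np.array([0]), np.array([0]), np.array([0.0]))


def _study_inputs(ds, cfg, seed):
    s_r = dice_matrix_from_bits(ds.drug_features, ds.drug_ids)
    s_p = feature_similarity_matrix(ds.protein_features, ds.protein_ids)
    pos = ds.interactions
    neg = sample_negatives(pos, ds.drug_ids, ds.protein_ids, 1, seed)
    train_set = InteractionSet(pairs=pos.pairs + neg.pairs)
    bundle = build_bundle(s_r, s_p, train_set, cfg.t_root)
    return bundle, train_set


class TestTrainLoop:
    def test_one_step_pulls_a_positive_pair_together(self, rng):
        cfg = RunConfig.small(seed=2, d_m=16, d_t=8, d_h=8, d_s=4,
                              learning_rate=1e-3)
        model = TwoTowerModel(cfg)
        Xd, Xp = rng.random((2, 16)), rng.random((2, 8))
        bp = (np.array([0]), np.array([0]), np.array([0.0]))  # one positive
        Zd = model.encode_drugs(Xd, training=True)
        Zp = model.encode_proteins(Xp, training=True)
        before = 1 - cosine_distance(
            model.encode_drugs(Xd, training=False)[0],
            model.encode_proteins(Xp, training=False)[0])
        _, dZd, dZp = oi_loss(Zd, Zp, bp, with_grad=True)
        opt = Adam([model.drug_tower, model.protein_tower], lr=1e-3)
        opt.step([model.drug_tower.backward(dZd),
                  model.protein_tower.backward(dZp)])
        after = 1 - cosine_distance(
            model.encode_drugs(Xd, training=False)[0],
            model.encode_proteins(Xp, training=False)[0])
        assert after > before

    def test_identical_seeds_identical_logs(self, tiny_dataset):
        cfg = RunConfig.small(seed=9, d_m=32, d_t=16, d_h=16, d_s=8,
                              max_iterations=30, batch_size=32)
        bundle, train_set = _study_inputs(tiny_dataset, cfg, seed=9)
        r1 = train(tiny_dataset.drug_features, tiny_dataset.protein_features,
                   bundle, train_set, cfg, loss_kind="gba")
        r2 = train(tiny_dataset.drug_features, tiny_dataset.protein_features,
                   bundle, train_set, cfg, loss_kind="gba")
        assert [e["total"] for e in r1.log] == [e["total"] for e in r2.log]

    def test_oi_log_has_zero_prior_terms(self, tiny_dataset):
        cfg = RunConfig.small(seed=9, d_m=32, d_t=16, d_h=16, d_s=8,
                              max_iterations=20, batch_size=32)
        bundle, train_set = _study_inputs(tiny_dataset, cfg, seed=9)
        res = train(tiny_dataset.drug_features, tiny_dataset.protein_features,
                    bundle, train_set, cfg, loss_kind="oi")
        assert all(e["l_drug"] == 0 and e["l_protein"] == 0 for e in res.log)

    def test_smoothed_loss_decreases_on_noiseless_fixture(self, tiny_dataset):
        cfg = RunConfig.small(seed=4, d_m=32, d_t=16, d_h=16, d_s=8,
                              max_iterations=200, batch_size=64)
        bundle, train_set = _study_inputs(tiny_dataset, cfg, seed=4)
        res = train(tiny_dataset.drug_features, tiny_dataset.protein_features,
                    bundle, train_set, cfg, loss_kind="gba")
        totals = np.array([e["total"] for e in res.log])
        k = 50
        smoothed = np.convolve(totals, np.ones(k) / k, mode="valid")
        assert smoothed[-1] < smoothed[0]
        assert smoothed[-1] < 0.9 * smoothed[0]
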