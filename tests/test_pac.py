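"""Unit and property tests of the particle adaptive classifier."""

import numpy as np
import pytest

from pacemg import lssvm
from pacemg.kernel import KernelParams, distance_matrix
from pacemg.pac import (
    PAC,
    PACConfig,
    RPState,
    attractive_zone_decision,
    boundary_rp_proportion,
    init_rps,
    kmedoids_cluster,
    nearest_rp,
    ovo_predict,
    pac_process_sample,
)

from conftest import two_blobs


def small_config(**kw):
    kw.setdefault("m", 10)
    kw.setdefault("p", 0.2)
    kw.setdefault("C", 10.0)
    kw.setdefault("gamma", 0.5)
    kw.setdefault("seed", 0)
    return PACConfig(**kw)


# ---------------------------------------------------------------------------
# clustering


def test_kmedoids_single_cluster_brute_force(rng, kp):
    X = rng.random((15, 7))
    assign, medoids = kmedoids_cluster(X, 1, kp, seed=0)
    assert np.all(assign == 0)
    D = distance_matrix(X, kp)
    assert medoids[0] == np.argmin(D.sum(axis=1))


def test_kmedoids_recovers_separated_blobs(kp):
    X, y = two_blobs(n_per=25, sep=12.0)
    assign, _ = kmedoids_cluster(X, 2, kp, seed=3)
    # each blob lands wholly in one cluster
    assert np.unique(assign[:25]).size == 1
    assert np.unique(assign[25:]).size == 1
    assert assign[0] != assign[-1]


def test_kmedoids_partitions_dataset(rng, kp):
    X = rng.random((40, 7))
    assign, _ = kmedoids_cluster(X, 5, kp, seed=1)
    assert assign.shape == (40,)
    assert np.bincount(assign, minlength=5).sum() == 40


def test_kmedoids_deterministic_and_validated(rng, kp):
    X = rng.random((20, 7))
    a1, m1 = kmedoids_cluster(X, 4, kp, seed=9)
    a2, m2 = kmedoids_cluster(X, 4, kp, seed=9)
    np.testing.assert_array_equal(a1, a2)
    np.testing.assert_array_equal(m1, m2)
    with pytest.raises(ValueError):
        kmedoids_cluster(X, 21, kp, seed=0)


# ---------------------------------------------------------------------------
# initialization


def test_init_rp_count_is_fraction_of_session(medium_session):
    cfg = small_config(p=0.10)
    state, ens = init_rps(medium_session.features, medium_session.labels, cfg)
    assert state.count == round(0.10 * medium_session.n_samples)
    assert np.all(state.t == 0)
    # each particle serves n_classes - 1 pairwise models
    appearances = np.zeros(state.count, dtype=int)
    for gidx in ens.index_map.values():
        for i in gidx:
            appearances[i] += 1
    assert np.all(appearances == len(np.unique(state.labels)) - 1)


def test_init_with_full_fraction_keeps_everything(small_session):
    cfg = small_config(p=1.0, m=1)
    state, _ = init_rps(small_session.features, small_session.labels, cfg)
    assert state.count == small_session.n_samples


def test_init_requires_two_classes(rng):
    X = rng.random((20, 7))
    with pytest.raises(ValueError):
        init_rps(X, np.ones(20, dtype=int), small_config())


# ---------------------------------------------------------------------------
# nearest particle and attractive zone


def make_state(X, labels, t=None):
    return RPState(
        particles=np.asarray(X, dtype=float),
        labels=np.asarray(labels, dtype=int),
        t=np.zeros(len(X), dtype=np.int64) if t is None else np.asarray(t),
    )


def test_nearest_rp_reduces_to_nn_when_times_zero(rng):
    cfg = small_config()
    X = rng.random((12, 7))
    state = make_state(X, np.ones(12))
    x = rng.random(7)
    idx, wd = nearest_rp(x, state, cfg)
    D = np.array([np.sqrt(2 - 2 * np.exp(-cfg.gamma * ((x - xi) ** 2).sum()))
                  for xi in X])
    assert idx == np.argmin(D)
    assert wd == pytest.approx(D.min(), abs=1e-12)


def test_nearest_rp_time_weighting_brute_force():
    """Weighted scores (0.5, 0.3 e^2, 0.4) -> the third particle wins."""
    cfg = small_config(lam=1e5)
    # craft particles at exact kernel distances 0.5, 0.3, 0.4 from origin
    gamma = cfg.gamma
    x = np.zeros(7)
    dists = [0.5, 0.3, 0.4]
    X = []
    for d in dists:
        k = (2 - d**2) / 2
        r = np.sqrt(-np.log(k) / gamma)
        v = np.zeros(7)
        v[0] = r
        X.append(v)
    state = make_state(X, [1, 1, 1], t=[0, 200000, 0])
    idx, wd = nearest_rp(x, state, cfg)
    scores = np.exp(np.array([0, 200000, 0]) / cfg.lam) * np.array(dists)
    assert idx == int(np.argmin(scores)) == 2
    assert wd == pytest.approx(0.4, abs=1e-9)


def test_nearest_rp_duplicate_wins_with_zero_distance(rng):
    cfg = small_config()
    X = rng.random((5, 7))
    state = make_state(X, [1, 1, 2, 2, 1])
    idx, wd = nearest_rp(X[3], state, cfg)
    assert idx == 3 and wd == pytest.approx(0.0, abs=1e-12)


def test_nearest_rp_supervised_restriction(rng):
    cfg = small_config()
    X = rng.random((6, 7))
    state = make_state(X, [1, 1, 1, 2, 2, 2])
    idx, _ = nearest_rp(X[0], state, cfg, restrict_label=2)
    assert idx in (3, 4, 5)
    from pacemg.pac import EmptyCandidateSet
    with pytest.raises(EmptyCandidateSet):
        nearest_rp(X[0], state, cfg, restrict_label=7)


def test_attractive_zone_arithmetic():
    cfg = small_config(d_th=0.99)
    assert attractive_zone_decision(0.5, cfg) is True      # D = 0.49 > 0
    assert attractive_zone_decision(0.99, cfg) is False    # D = 0, strict
    zero = small_config(d_th=0.0)
    assert attractive_zone_decision(0.0, zero) is False    # never at d_th = 0


def test_lambda_limit_matches_unweighted_nn(rng):
    cfg_inf = small_config(lam=1e12)
    X = rng.random((10, 7))
    state = make_state(X, np.ones(10), t=rng.integers(0, 50, 10))
    x = rng.random(7)
    i1, _ = nearest_rp(x, state, cfg_inf)
    state0 = make_state(X, np.ones(10))
    i2, _ = nearest_rp(x, state0, small_config())
    assert i1 == i2


# ---------------------------------------------------------------------------
# streaming updates


def test_self_replacement_leaves_decisions_unchanged(medium_session):
    cfg = small_config(p=0.15)
    state, ens = init_rps(medium_session.features, medium_session.labels, cfg)
    probe = medium_session.features[::37]
    before = [ovo_predict(x, state, ens, cfg) for x in probe]
    # feed an exact copy of a particle: replacement must be a no-op
    i = 4
    x, lbl = state.particles[i].copy(), int(state.labels[i])
    pred = pac_process_sample(x, lbl, state, ens, cfg)
    after = [ovo_predict(x, state, ens, cfg) for x in probe]
    for (p1, v1), (p2, v2) in zip(before, after):
        assert p1 == p2
        np.testing.assert_array_equal(v1, v2)
    assert pred in range(1, 9)


def test_far_sample_only_ages_pool(medium_session):
    cfg = small_config(p=0.15)
    state, ens = init_rps(medium_session.features, medium_session.labels, cfg)
    particles_before = state.particles.copy()
    t_before = state.t.copy()
    far = np.full(7, 100.0)  # weighted distance ~ sqrt(2) > d_th everywhere
    pac_process_sample(far, 1, state, ens, cfg)
    np.testing.assert_array_equal(state.particles, particles_before)
    np.testing.assert_array_equal(state.t, t_before + 1)


def test_pool_and_model_sizes_constant_over_stream(medium_session, rng):
    """Replacement-only updating: sizes are invariant over 1000 samples."""
    cfg = small_config(p=0.15, mode="unsupervised")
    pac = PAC(cfg).initialize(medium_session.features, medium_session.labels)
    size0 = pac.model_size()
    pair_sizes0 = pac.pair_sizes()
    idx = rng.integers(0, medium_session.n_samples, 1000)
    for i in idx:
        pac.process_sample(
            medium_session.features[i] + rng.normal(0, 0.05, 7),
            int(medium_session.labels[i]),
        )
    assert pac.model_size() == size0
    assert pac.pair_sizes() == pair_sizes0


def test_replacement_consistency_with_batch_retraining(medium_session, rng):
    """After streaming, every pairwise model equals batch retraining on the
    current pool within 1e-8 (dense oracle)."""
    cfg = small_config(p=0.12, mode="unsupervised")
    pac = PAC(cfg).initialize(medium_session.features, medium_session.labels)
    for i in rng.integers(0, medium_session.n_samples, 200):
        pac.process_sample(
            medium_session.features[i] + rng.normal(0, 0.1, 7),
            int(medium_session.labels[i]),
        )
    state, ens = pac.state, pac.ensemble
    for (a, b), model in ens.models.items():
        gidx = ens.index_map[(a, b)]
        X = state.particles[gidx]
        y = np.where(state.labels[gidx] == a, 1.0, -1.0)
        ref = lssvm.batch_solve(X, y, cfg.C, cfg.kernel)
        assert np.abs(model.alpha - ref.alpha).max() < 1e-8
        assert abs(model.b - ref.b) < 1e-8


def test_supervised_mode_ignores_misclassified_samples(medium_session):
    cfg = small_config(p=0.15, mode="supervised")
    pac = PAC(cfg).initialize(medium_session.features, medium_session.labels)
    x = pac.state.particles[0].copy()
    wrong_label = int(pac.state.labels[0] % 8 + 1)
    particles_before = pac.state.particles.copy()
    pred = pac.process_sample(x, wrong_label)
    assert pred != wrong_label  # duplicate of a particle: predicted as its class
    np.testing.assert_array_equal(pac.state.particles, particles_before)


# ---------------------------------------------------------------------------
# one-vs-one voting


def test_ovo_two_class_reduces_to_decision_sign():
    X, y = two_blobs(n_per=20)
    cfg = small_config(p=0.5, m=2, gamma=0.1)
    state, ens = init_rps(X, y, cfg)
    assert len(ens.models) == 1
    for x in X[::7]:
        pred, votes = ovo_predict(x, state, ens, cfg)
        (model,) = ens.models.values()
        val = lssvm.decision_value(model, x)
        assert pred == (1 if val >= 0 else 2)
        assert votes.sum() == 1


def test_ovo_vote_total(small_session):
    cfg = small_config(p=0.3)
    state, ens = init_rps(small_session.features, small_session.labels, cfg)
    n_cls = np.unique(small_session.labels).size
    _, votes = ovo_predict(small_session.features[0], state, ens, cfg)
    assert votes.sum() == n_cls * (n_cls - 1) // 2


# ---------------------------------------------------------------------------
# boundary-particle diagnostic


def test_boundary_proportion_low_on_separated_blobs():
    X, y = two_blobs(n_per=40, sep=15.0)
    state = RPState(particles=X, labels=y, t=np.zeros(80, dtype=np.int64))
    prop = boundary_rp_proportion(state, C=10.0, gamma=0.1)
    assert 0.0 <= prop < 0.5


def test_boundary_proportion_single_class_rejected(rng):
    state = RPState(particles=rng.random((10, 7)),
                    labels=np.ones(10, dtype=int),
                    t=np.zeros(10, dtype=np.int64))
    with pytest.raises(ValueError):
        boundary_rp_proportion(state, 1.0, 0.5)


# ---------------------------------------------------------------------------
# serialization


def test_checkpoint_roundtrip(tmp_path, medium_session, rng):
    cfg = small_config(p=0.15, mode="unsupervised")
    pac = PAC(cfg).initialize(medium_session.features, medium_session.labels)
    for i in rng.integers(0, medium_session.n_samples, 50):
        pac.process_sample(medium_session.features[i], int(medium_session.labels[i]))
    pac.save(tmp_path / "ckpt")
    restored = PAC.load(tmp_path / "ckpt")
    probe = medium_session.features[::31]
    for x in probe:
        assert restored.predict(x) == pac.predict(x)
    np.testing.assert_array_equal(restored.state.t, pac.state.t)
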