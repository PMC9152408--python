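"""PPO losses, advantage estimation, environment dynamics and training."""
import numpy as np
import pytest
from scipy import ndimage

from dtseg.errors import ValidationError
from dtseg.phantom import PhantomSpec, generate_phantom
from dtseg.rl_refinement import (
    PPOConfig,
    PolicyValueParams,
    SegmentationEnv,
    Trajectory,
    _loss_and_grads,
    compute_advantages,
    entropy_term,
    policy_loss,
    ppo_update,
    refine,
    run_episode,
    train_refiner,
    value_loss,
)


def _traj(rewards, values, obs_dim=3):
    T = len(rewards)
    return Trajectory(
        observations=np.zeros((T, obs_dim)),
        actions=np.zeros(T, dtype=int),
        rewards=np.asarray(rewards, float),
        action_probs=np.full(T, 0.5),
        values=np.asarray(values, float),
    )


def test_value_loss_cases():
    assert value_loss(3.0, 3.0) == 0.0
    assert value_loss(1.0, 0.0) == pytest.approx(0.5)
    assert value_loss(-2.0, 1.0) == pytest.approx(4.5)


def test_policy_loss_clip_cases():
    assert policy_loss(1.0, 2.0, 0.2) == pytest.approx(-2.0)
    assert policy_loss(2.0, 1.0, 0.2) == pytest.approx(-1.2)
    assert policy_loss(0.5, -1.0, 0.2) == pytest.approx(0.8)
    with pytest.raises(ValidationError):
        policy_loss(0.0, 1.0, 0.2)


def test_policy_loss_clip_dead_zones_have_zero_slope():
    eps = 1e-6
    # r > 1+sigma with positive advantage: flat
    g = (policy_loss(1.5 + eps, 2.0, 0.2) - policy_loss(1.5 - eps, 2.0, 0.2)) / (2 * eps)
    assert abs(g) < 1e-9
    # r < 1-sigma with negative advantage: flat
    g = (policy_loss(0.5 + eps, -2.0, 0.2) - policy_loss(0.5 - eps, -2.0, 0.2)) / (2 * eps)
    assert abs(g) < 1e-9
    # inside the trust region the slope is -advantage
    g = (policy_loss(1.0 + eps, 2.0, 0.2) - policy_loss(1.0 - eps, 2.0, 0.2)) / (2 * eps)
    assert g == pytest.approx(-2.0, rel=1e-5)


def test_entropy_term_cases():
    assert entropy_term([0.25] * 4) == pytest.approx(-np.log(4))
    assert entropy_term([1.0, 0.0, 0.0]) == 0.0
    assert entropy_term([0.5, 0.5]) == pytest.approx(-np.log(2))
    with pytest.raises(ValidationError):
        entropy_term([0.5, 0.6])


def test_gae_single_step_and_zeros():
    adv, ret = compute_advantages(_traj([1.0], [0.0]), gamma=0.9, gae_lambda=0.95)
    assert adv[0] == pytest.approx(1.0) and ret[0] == pytest.approx(1.0)
    adv, ret = compute_advantages(_traj([0.0] * 4, [0.0] * 4), 0.9, 0.95)
    assert np.all(adv == 0.0) and np.all(ret == 0.0)


def test_gae_matches_double_loop_oracle():
    g, lam = 0.9, 0.95
    rewards = [1.0, 0.0, 2.0, -1.0, 0.5]
    values = [0.3, -0.2, 0.1, 0.4, 0.0]
    adv, ret = compute_advantages(_traj(rewards, values), g, lam)
    T = 5
    deltas = [rewards[t] + g * (values[t + 1] if t + 1 < T else 0.0) - values[t]
              for t in range(T)]
    brute = [sum((g * lam) ** (j - t) * deltas[j] for j in range(t, T)) for t in range(T)]
    np.testing.assert_allclose(adv, brute, rtol=1e-12)
    np.testing.assert_allclose(ret, np.asarray(brute) + values, rtol=1e-12)


def test_gradients_match_finite_differences():
    rng = np.random.default_rng(0)
    cfg = PPOConfig()
    p = PolicyValueParams.initialize(6, 4, hidden=5, seed=1)
    obs = rng.normal(size=(8, 6))
    acts = rng.integers(0, 4, 8)
    oldp = rng.uniform(0.1, 0.9, 8)
    adv = rng.normal(size=8)
    ret = rng.normal(size=8)
    _, grads = _loss_and_grads(p, obs, acts, oldp, adv, ret, cfg)
    eps = 1e-6
    for f in p._fields():
        arr = getattr(p, f)
        for _ in range(5):
            ix = tuple(rng.integers(0, s) for s in arr.shape)
            old = arr[ix]
            arr[ix] = old + eps
            l1, _ = _loss_and_grads(p, obs, acts, oldp, adv, ret, cfg)
            arr[ix] = old - eps
            l2, _ = _loss_and_grads(p, obs, acts, oldp, adv, ret, cfg)
            arr[ix] = old
            assert (l1 - l2) / (2 * eps) == pytest.approx(grads[f][ix], abs=1e-7)


def test_zero_advantage_update_moves_only_through_entropy():
    obs = np.random.default_rng(1).normal(size=(6, 4))
    p = PolicyValueParams.initialize(4, 3, hidden=5, seed=0)
    # single-step episodes with reward == V(obs): advantages are exactly 0
    # and the return equals the current value estimate
    trajs = []
    for o in obs:
        probs = p.policy_probs(o)
        v = p.value(o)
        trajs.append(Trajectory(
            observations=o[None], actions=np.zeros(1, dtype=int),
            rewards=np.array([v]), action_probs=np.array([probs[0]]),
            values=np.array([v])))
    O = np.concatenate([t.observations for t in trajs])
    A = np.concatenate([t.actions for t in trajs])
    OP = np.concatenate([t.action_probs for t in trajs])
    adv = np.zeros(6)
    ret = np.concatenate([t.values for t in trajs])
    # without the entropy term every gradient vanishes ...
    _, g0 = _loss_and_grads(p, O, A, OP, adv, ret,
                            PPOConfig(entropy_coef=0.0, value_coef=0.5))
    assert all(np.abs(g).max() < 1e-12 for g in g0.values())
    # ... with it, only the policy head feels a force
    _, g1 = _loss_and_grads(p, O, A, OP, adv, ret,
                            PPOConfig(entropy_coef=0.05, value_coef=0.5))
    assert max(np.abs(g1[f]).max() for f in ("w1", "b1", "w2", "b2")) > 1e-6
    assert max(np.abs(g1[f]).max() for f in ("v1", "c1", "v2", "c2")) < 1e-12


def test_ppo_update_deterministic_for_fixed_seed():
    rng = np.random.default_rng(2)
    trajs = [_traj(rng.normal(size=5), rng.normal(size=5), obs_dim=4) for _ in range(3)]
    p = PolicyValueParams.initialize(4, 3, hidden=6, seed=3)
    cfg = PPOConfig(seed=11)
    a = ppo_update(trajs, p, cfg)
    b = ppo_update(trajs, p, cfg)
    np.testing.assert_array_equal(a.flat(), b.flat())
    with pytest.raises(ValidationError):
        ppo_update([], p, cfg)


def test_action_probabilities_form_a_distribution():
    rng = np.random.default_rng(3)
    p = PolicyValueParams.initialize(10, 7, hidden=8, seed=0)
    probs = p.policy_probs(rng.normal(size=(20, 10)))
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)


def _flat_phantom_env(cfg, corrupt=True):
    spec = PhantomSpec(height=64, width=64, n_classes=4, tumor_count_range=(1, 2),
                       class_means=(0.05, 0.95, 0.35, 0.75),
                       class_texture_sd=(0.0,) * 4, seed=3)
    clean, truth = generate_phantom(spec)
    segs = np.zeros_like(truth)
    nid = 0
    for k in range(4):
        lab, n = ndimage.label(truth == k)
        for i in range(1, n + 1):
            segs[lab == i] = nid
            nid += 1
    init = truth.copy()
    if corrupt:
        init[segs == nid - 1] = 0
    env = SegmentationEnv(clean, init, 4, cfg, truth=truth, segments=segs)
    return env, truth, init


def test_scripted_oracle_policy_reaches_perfect_f():
    cfg = PPOConfig(episode_cap=500, n_superpixels=32)
    env, truth, _ = _flat_phantom_env(cfg)
    assert env._macro_f(env.labels) < 1.0
    for _ in range(env.n_segments):
        focus = env._segment_masks[env.t % env.n_segments]
        maj = int(np.bincount(truth[focus]).argmax())
        env.step(maj * 3 + 2)  # relabel focus to the majority truth class
    assert env._macro_f(env.labels) == 1.0


def test_environment_step_is_deterministic():
    cfg = PPOConfig(episode_cap=50, n_superpixels=32)
    env_a, _, _ = _flat_phantom_env(cfg)
    env_b, _, _ = _flat_phantom_env(cfg)
    for a in (0, 4, 8, 2):
        env_a.step(a)
        env_b.step(a)
    np.testing.assert_array_equal(env_a.labels, env_b.labels)


def test_stop_policy_keeps_mask_and_episode_cap_bounds_length():
    cfg = PPOConfig(episode_cap=7, n_superpixels=16)
    env, truth, init = _flat_phantom_env(cfg)
    obs = env.observation()
    params = PolicyValueParams.initialize(obs.size, env.n_actions, hidden=8, seed=0)
    # force STOP: crank the STOP bias
    params.b2[-1] = 100.0
    traj, mask = run_episode(None, init, params, cfg, train_mode=False, env=env)
    np.testing.assert_array_equal(mask, init)
    assert len(traj) == 1
    # an always-dilate policy is bounded by the cap
    params.b2[-1] = -100.0
    params.b2[0] = 100.0
    env2, _, init2 = _flat_phantom_env(cfg)
    traj2, _ = run_episode(None, init2, params, cfg, train_mode=False, env=env2)
    assert len(traj2) == cfg.episode_cap


def test_refined_label_values_stay_within_model_classes():
    cfg = PPOConfig(episode_cap=20, n_superpixels=16)
    env, truth, init = _flat_phantom_env(cfg)
    obs = env.observation()
    params = PolicyValueParams.initialize(obs.size, env.n_actions, hidden=8, seed=1)
    _, mask = run_episode(None, init, params, cfg, train_mode=False, env=env)
    assert set(np.unique(mask)) <= set(range(4))


def test_greedy_inference_is_deterministic():
    cfg = PPOConfig(episode_cap=20, n_superpixels=16)
    _, truth, init = _flat_phantom_env(cfg)
    spec_img = generate_phantom(PhantomSpec(height=64, width=64, n_classes=4,
                                            tumor_count_range=(1, 2),
                                            class_means=(0.05, 0.95, 0.35, 0.75),
                                            class_texture_sd=(0.0,) * 4, seed=3))[0]
    params = PolicyValueParams.initialize(
        cfg.patch**2 * 5 + 1, 13, hidden=8, seed=2)
    a = refine(spec_img, init, params, cfg, n_classes=4)
    b = refine(spec_img, init, params, cfg, n_classes=4)
    np.testing.assert_array_equal(a, b)


def test_train_refiner_zero_updates_returns_initial_params():
    spec = PhantomSpec(height=64, width=64, n_classes=4, tumor_count_range=(1, 1),
                       class_means=(0.05, 0.95, 0.35, 0.75),
                       class_texture_sd=(0.02,) * 4)
    from dtseg.phantom import make_dataset

    ds = make_dataset(2, spec, 0.05, seed=0)
    cfg = PPOConfig(updates=0, n_superpixels=16, seed=5)

    def segment_fn(s):
        return s.clean, s.truth.copy()

    params = train_refiner(ds, segment_fn, cfg, n_classes=4)
    fresh = PolicyValueParams.initialize(
        cfg.patch**2 * 5 + 1, 13, hidden=cfg.hidden, seed=cfg.seed)
    np.testing.assert_array_equal(params.flat(), fresh.flat())
    with pytest.raises(ValidationError):
        train_refiner(ds[:1], segment_fn, cfg)


def test_train_refiner_reproducible_for_fixed_seed():
    spec = PhantomSpec(height=64, width=64, n_classes=4, tumor_count_range=(1, 1),
                       class_means=(0.05, 0.95, 0.35, 0.75),
                       class_texture_sd=(0.02,) * 4)
    from dtseg.phantom import make_dataset

    ds = make_dataset(3, spec, 0.05, seed=1)
    cfg = PPOConfig(updates=2, episodes_per_update=2, episode_cap=10,
                    n_superpixels=16, seed=9)

    def segment_fn(s):
        return s.clean, s.truth.copy()

    a = train_refiner(ds, segment_fn, cfg, n_classes=4)
    b = train_refiner(ds, segment_fn, cfg, n_classes=4)
    np.testing.assert_array_equal(a.flat(), b.flat())
    assert len(a.history) == 2
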