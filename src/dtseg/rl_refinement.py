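"""Segmentation refinement by a policy-gradient agent (clipped-surrogate PPO).

The agent walks over the superpixels of the image in raster order and, at
each step, observes a local window (image patch, one-hot label patch and a
normalized step counter) and picks a discrete action: dilate or erode one
class by one pixel inside the focus superpixel, relabel the whole focus
superpixel to a class, or STOP.  During training the reward is the change
in macro F-measure against the ground truth; at inference the policy is
applied greedily with no rewards.

Training uses proximal policy optimization: the action network's
probability ratio is clipped to ``[1 - clip, 1 + clip]`` in the surrogate
loss, the value network regresses the empirical return with a squared loss
``(V - R)^2 / 2``, advantages come from generalized advantage estimation
(GAE), and a negative-entropy regularizer keeps exploration alive.  Both
networks are single-hidden-layer tanh MLPs implemented in numpy with
hand-derived gradients and Adam updates, sized for CPU-scale training.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import slic

from .errors import ValidationError
from .metrics import MaskPair, f_measure

__all__ = [
    "PPOConfig",
    "Trajectory",
    "PolicyValueParams",
    "SegmentationEnv",
    "value_loss",
    "policy_loss",
    "entropy_term",
    "compute_advantages",
    "ppo_update",
    "run_episode",
    "train_refiner",
    "refine",
]


@dataclass(frozen=True)
class PPOConfig:
    """Hyperparameters of the refinement agent and its PPO trainer."""

    clip: float = 0.2
    gamma: float = 0.99
    gae_lambda: float = 0.95
    value_coef: float = 0.5
    entropy_coef: float = 0.01
    learning_rate: float = 1e-3
    epochs_per_update: int = 4
    minibatch_size: int = 64
    updates: int = 30
    episodes_per_update: int = 4
    episode_cap: int = 64
    action_cost: float = 1e-3
    n_superpixels: int = 64
    patch: int = 11
    hidden: int = 64
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.clip < 1.0:
            raise ValidationError("clip must lie in (0, 1)")
        if not 0.0 < self.gamma <= 1.0:
            raise ValidationError("gamma must lie in (0, 1]")
        if not 0.0 <= self.gae_lambda <= 1.0:
            raise ValidationError("gae_lambda must lie in [0, 1]")
        if self.patch % 2 == 0:
            raise ValidationError("patch must be odd")


@dataclass
class Trajectory:
    """One episode's transitions, in collection order."""

    observations: np.ndarray  # (T, obs_dim)
    actions: np.ndarray  # (T,)
    rewards: np.ndarray  # (T,)
    action_probs: np.ndarray  # (T,) probability of the taken action
    values: np.ndarray  # (T,) value estimates at collection time
    terminal: bool = True

    def __post_init__(self):
        if len(self.actions) == 0:
            raise ValidationError("trajectory must contain at least one step")
        if np.any(self.action_probs <= 0) or np.any(self.action_probs > 1):
            raise ValidationError("stored action probabilities must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.actions)


# ---------------------------------------------------------------------------
# losses (scalar forms; the batched gradient lives in ppo_update)
# ---------------------------------------------------------------------------

def value_loss(value: float, ret: float) -> float:
    """Squared valuation loss ``(value - return)^2 / 2``."""
    return 0.5 * (value - ret) ** 2


def policy_loss(ratio: float, advantage: float, clip: float) -> float:
    """Negated clipped surrogate ``-min(r k, clip(r, 1-c, 1+c) k)``."""
    if ratio <= 0:
        raise ValidationError("probability ratio must be positive")
    clipped = min(max(ratio, 1.0 - clip), 1.0 + clip)
    return -min(ratio * advantage, clipped * advantage)


def entropy_term(probs) -> float:
    """Negative entropy ``sum p log p`` with ``0 log 0 := 0``.

    Added to the loss scaled by ``entropy_coef``; minimizing it maximizes
    entropy, encouraging exploration.
    """
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValidationError("probs must be a probability vector")
    nz = p[p > 0]
    return float(np.sum(nz * np.log(nz)))


def compute_advantages(traj: Trajectory, gamma: float, gae_lambda: float):
    """GAE advantages and returns for one trajectory.

    ``delta_t = r_t + gamma V_{t+1} - V_t`` (bootstrap 0 past the end) and
    ``A_t = delta_t + gamma lambda A_{t+1}``; returns are ``A_t + V_t``.
    """
    r = traj.rewards.astype(float)
    v = traj.values.astype(float)
    T = len(r)
    adv = np.empty(T)
    nxt = 0.0
    for t in range(T - 1, -1, -1):
        v_next = v[t + 1] if t + 1 < T else 0.0
        delta = r[t] + gamma * v_next - v[t]
        nxt = delta + gamma * gae_lambda * nxt
        adv[t] = nxt
    return adv, adv + v


# ---------------------------------------------------------------------------
# function approximators
# ---------------------------------------------------------------------------


@dataclass
class PolicyValueParams:
    """Parameters of the action scorer and the state-value network.

    Two independent single-hidden-layer tanh MLPs on the flattened
    observation: the policy head outputs one score per action (softmax ->
    probabilities), the value head a scalar.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    v1: np.ndarray
    c1: np.ndarray
    v2: np.ndarray
    c2: np.ndarray

    @classmethod
    def initialize(cls, obs_dim: int, n_actions: int, hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)

        def glorot(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-s, s, (n_in, n_out))

        return cls(
            w1=glorot(obs_dim, hidden),
            b1=np.zeros(hidden),
            w2=glorot(hidden, n_actions) * 0.01,
            b2=np.zeros(n_actions),
            v1=glorot(obs_dim, hidden),
            c1=np.zeros(hidden),
            v2=glorot(hidden, 1) * 0.1,
            c2=np.zeros(1),
        )

    @property
    def n_actions(self) -> int:
        return self.w2.shape[1]

    def _fields(self):
        return ("w1", "b1", "w2", "b2", "v1", "c1", "v2", "c2")

    def copy(self) -> "PolicyValueParams":
        return PolicyValueParams(**{f: getattr(self, f).copy() for f in self._fields()})

    def flat(self) -> np.ndarray:
        """The full parameter vector (lambda)."""
        return np.concatenate([getattr(self, f).ravel() for f in self._fields()])

    def policy_probs(self, obs: np.ndarray) -> np.ndarray:
        obs = np.atleast_2d(obs)
        h = np.tanh(obs @ self.w1 + self.b1)
        logits = h @ self.w2 + self.b2
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        p = e / e.sum(axis=1, keepdims=True)
        return p[0] if p.shape[0] == 1 else p

    def value(self, obs: np.ndarray):
        obs = np.atleast_2d(obs)
        h = np.tanh(obs @ self.v1 + self.c1)
        out = (h @ self.v2 + self.c2).ravel()
        return float(out[0]) if out.size == 1 else out


def _loss_and_grads(params, obs, actions, old_probs, advantages, returns, cfg):
    """Total PPO loss and analytic gradients over one minibatch."""
    n, _ = obs.shape
    # policy forward
    h = np.tanh(obs @ params.w1 + params.b1)
    logits = h @ params.w2 + params.b2
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    idx = np.arange(n)
    p_a = probs[idx, actions]
    ratio = p_a / old_probs
    clipped = np.clip(ratio, 1.0 - cfg.clip, 1.0 + cfg.clip)
    surr = np.minimum(ratio * advantages, clipped * advantages)
    # value forward
    hv = np.tanh(obs @ params.v1 + params.c1)
    val = (hv @ params.v2 + params.c2).ravel()
    vloss = 0.5 * (val - returns) ** 2
    logp = np.log(np.clip(probs, 1e-12, None))
    ent_neg = np.sum(probs * logp, axis=1)  # sum p log p (negative entropy)
    loss = float(np.mean(-surr + cfg.value_coef * vloss + cfg.entropy_coef * ent_neg))

    # --- gradients ---
    # policy surrogate: d(-surr)/dlogits. Clip dead zone has zero gradient.
    active = (ratio * advantages) <= (clipped * advantages) + 1e-12
    # within the dead zone (ratio clipped AND clipped branch strictly larger) grad is 0
    coef = np.where(active, -advantages * ratio, 0.0) / n  # d/dlogp_a of -surr, per sample
    dlogits = probs * (-coef[:, None])  # from -coef * dlogp_a/dlogits cross terms
    dlogits[idx, actions] += coef
    # entropy: d(sum p log p)/dlogits = p * (logp + 1 - sum p(logp+1))
    w = logp + 1.0
    dent = probs * (w - np.sum(probs * w, axis=1, keepdims=True))
    dlogits += cfg.entropy_coef * dent / n
    # backprop policy MLP
    gw2 = h.T @ dlogits
    gb2 = dlogits.sum(axis=0)
    dh = (dlogits @ params.w2.T) * (1.0 - h**2)
    gw1 = obs.T @ dh
    gb1 = dh.sum(axis=0)
    # value head
    dval = cfg.value_coef * (val - returns) / n
    gv2 = hv.T @ dval[:, None]
    gc2 = np.array([dval.sum()])
    dhv = np.outer(dval, params.v2.ravel()) * (1.0 - hv**2)
    gv1 = obs.T @ dhv
    gc1 = dhv.sum(axis=0)
    grads = {"w1": gw1, "b1": gb1, "w2": gw2, "b2": gb2,
             "v1": gv1, "c1": gc1, "v2": gv2, "c2": gc2}
    return loss, grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {f: np.zeros_like(getattr(params, f)) for f in params._fields()}
        self.v = {f: np.zeros_like(getattr(params, f)) for f in params._fields()}

    def step(self, params, grads):
        self.t += 1
        for f in params._fields():
            g = grads[f]
            self.m[f] = self.b1 * self.m[f] + (1 - self.b1) * g
            self.v[f] = self.b2 * self.v[f] + (1 - self.b2) * g * g
            mhat = self.m[f] / (1 - self.b1**self.t)
            vhat = self.v[f] / (1 - self.b2**self.t)
            getattr(params, f)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def ppo_update(
    trajectories: list[Trajectory],
    params: PolicyValueParams,
    config: PPOConfig,
    optimizer: _Adam | None = None,
    rng: np.random.Generator | None = None,
) -> PolicyValueParams:
    """One PPO update over a batch of trajectories.

    Advantages are standardized over the batch (mean 0, SD 1); the total
    loss is minimized by Adam over ``epochs_per_update`` shuffled minibatch
    passes.  Deterministic given ``config.seed`` (or the supplied rng).
    """
    if not trajectories:
        raise ValidationError("ppo_update needs at least one trajectory")
    obs = np.concatenate([t.observations for t in trajectories])
    actions = np.concatenate([t.actions for t in trajectories]).astype(int)
    old_probs = np.concatenate([t.action_probs for t in trajectories])
    advs, rets = [], []
    for t in trajectories:
        a, r = compute_advantages(t, config.gamma, config.gae_lambda)
        advs.append(a)
        rets.append(r)
    advantages = np.concatenate(advs)
    returns = np.concatenate(rets)
    sd = advantages.std()
    advantages = (advantages - advantages.mean()) / (sd if sd > 1e-12 else 1.0)

    new = params.copy()
    opt = optimizer if optimizer is not None else _Adam(new, config.learning_rate)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = obs.shape[0]
    mb = min(config.minibatch_size, n)
    for _ in range(config.epochs_per_update):
        order = rng.permutation(n)
        for start in range(0, n, mb):
            sel = order[start:start + mb]
            _, grads = _loss_and_grads(
                new, obs[sel], actions[sel], old_probs[sel],
                advantages[sel], returns[sel], config,
            )
            opt.step(new, grads)
    return new


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------


class SegmentationEnv:
    """Mask-editing environment over the superpixels of one image.

    Focus regions are SLIC superpixels (or a caller-supplied ``segments``
    partition), visited in raster order of their centroids, cyclically.
    Actions: for every class k — dilate k by one pixel inside the focus,
    erode k by one pixel inside the focus, relabel the focus to k — plus
    STOP, which ends the episode.  With a ground truth the per-step reward
    is the change in macro F-measure; the dynamics are deterministic.
    """

    def __init__(
        self,
        image: np.ndarray,
        init_labels: np.ndarray,
        n_classes: int,
        config: PPOConfig,
        truth: np.ndarray | None = None,
        segments: np.ndarray | None = None,
    ):
        self.image = np.asarray(image, dtype=float)
        self.n_classes = int(n_classes)
        self.config = config
        self.truth = None if truth is None else np.asarray(truth)
        if init_labels.shape != self.image.shape:
            raise ValidationError("init_labels shape does not match the image")
        if segments is None:
            segments = slic(
                self.image,
                n_segments=config.n_superpixels,
                compactness=0.1,
                channel_axis=None,
                start_label=0,
                enforce_connectivity=True,
            )
        self.segments = self._order_segments(np.asarray(segments))
        self.n_segments = int(self.segments.max()) + 1
        self._segment_masks = [self.segments == i for i in range(self.n_segments)]
        self._centroids = [
            np.argwhere(m).mean(axis=0) for m in self._segment_masks
        ]
        pad = config.patch // 2
        self._padded_image = np.pad(self.image, pad, mode="edge")
        self.reset(init_labels)

    @staticmethod
    def _order_segments(segments: np.ndarray) -> np.ndarray:
        ids = np.unique(segments)
        cents = ndimage.center_of_mass(np.ones_like(segments, dtype=float),
                                       segments, index=ids)
        order = sorted(range(len(ids)), key=lambda i: (cents[i][0], cents[i][1]))
        remap = np.empty(ids.max() + 1, dtype=np.int64)
        for newid, i in enumerate(order):
            remap[ids[i]] = newid
        return remap[segments]

    def reset(self, init_labels: np.ndarray):
        self.labels = np.asarray(init_labels, dtype=np.int64).copy()
        self.t = 0
        self.done = False
        if self.truth is not None:
            self._f = self._macro_f(self.labels)
        return self.observation()

    # -- actions ----------------------------------------------------------
    @property
    def n_actions(self) -> int:
        return 3 * self.n_classes + 1

    def action_name(self, a: int) -> str:
        if a == self.n_actions - 1:
            return "stop"
        kind = ("dilate", "erode", "relabel")[a % 3]
        return f"{kind}_{a // 3}"

    @property
    def obs_dim(self) -> int:
        return self.config.patch**2 * (1 + self.n_classes) + 1

    def observation(self) -> np.ndarray:
        p = self.config.patch
        pad = p // 2
        cy, cx = self._centroids[self.t % self.n_segments]
        r, c = int(round(cy)), int(round(cx))
        img = self._padded_image[r:r + p, c:c + p]
        lab = np.pad(self.labels, pad, mode="edge")[r:r + p, c:c + p]
        onehot = (lab[..., None] == np.arange(self.n_classes)).astype(float)
        frac = self.t / max(self.config.episode_cap, 1)
        return np.concatenate([img.ravel(), onehot.ravel(), [frac]])

    def _macro_f(self, labels: np.ndarray) -> float:
        pair = MaskPair(self.truth, labels)
        classes = np.unique(self.truth)
        return float(np.mean([f_measure(pair, int(k)) for k in classes]))

    def _apply(self, labels: np.ndarray, focus: np.ndarray, a: int) -> np.ndarray:
        kind, k = a % 3, a // 3
        out = labels.copy()
        mask_k = labels == k
        if kind == 0:  # dilate class k by one pixel inside the focus
            grow = ndimage.binary_dilation(mask_k) & focus & ~mask_k
            out[grow] = k
        elif kind == 1:  # erode class k by one pixel inside the focus
            if mask_k.any():
                shrink = mask_k & focus & ~ndimage.binary_erosion(mask_k)
                if shrink.any() and not mask_k.all():
                    _, (ir, ic) = ndimage.distance_transform_edt(
                        mask_k, return_indices=True
                    )
                    out[shrink] = labels[ir[shrink], ic[shrink]]
        else:  # relabel the focus superpixel to class k
            out[focus] = k
        return out

    def step(self, action: int):
        """Apply an action; returns (observation, reward, done)."""
        if self.done:
            raise ValidationError("episode already finished")
        if not 0 <= action < self.n_actions:
            raise ValidationError(f"action {action} out of range")
        reward = 0.0
        if action == self.n_actions - 1:
            self.done = True
        else:
            focus = self._segment_masks[self.t % self.n_segments]
            self.labels = self._apply(self.labels, focus, action)
            if self.truth is not None:
                f_new = self._macro_f(self.labels)
                # small edit cost: stopping strictly beats idle editing
                reward = f_new - self._f - self.config.action_cost
                self._f = f_new
        self.t += 1
        if self.t >= self.config.episode_cap:
            self.done = True
        return (None if self.done else self.observation()), reward, self.done


# ---------------------------------------------------------------------------
# episode / training / inference
# ---------------------------------------------------------------------------


def run_episode(
    sample,
    init_labels: np.ndarray,
    params: PolicyValueParams,
    config: PPOConfig,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    env: SegmentationEnv | None = None,
    n_classes: int | None = None,
):
    """Roll out one episode; returns ``(Trajectory, refined labels)``.

    ``sample`` is a :class:`dtseg.phantom.NoisySample` (its denoised or
    noisy image is the caller's choice of ``env``) or a bare image array.
    In training mode actions are sampled from the policy and rewards are
    the per-step change in macro F-measure (requires a ground truth);
    inference is greedy (ties to the lowest action id) with zero rewards.
    """
    if env is None:
        image = getattr(sample, "noisy", sample)
        truth = getattr(sample, "truth", None)
        if n_classes is None:
            if truth is None:
                raise ValidationError("n_classes required without a ground truth")
            n_classes = int(truth.max()) + 1
        env = SegmentationEnv(
            image, init_labels, n_classes, config,
            truth=truth if train_mode else None,
        )
    else:
        env.reset(init_labels)
    if train_mode and env.truth is None:
        raise ValidationError("train_mode requires a ground truth")
    if train_mode and rng is None:
        rng = np.random.default_rng(config.seed)

    obs_list, act_list, rew_list, prob_list, val_list = [], [], [], [], []
    obs = env.observation()
    while not env.done:
        probs = params.policy_probs(obs)
        if train_mode:
            a = int(rng.choice(len(probs), p=probs))
        else:
            a = int(np.argmax(probs))
        obs_list.append(obs)
        act_list.append(a)
        prob_list.append(max(probs[a], 1e-12))
        val_list.append(params.value(obs))
        nxt, reward, done = env.step(a)
        rew_list.append(reward)
        obs = nxt
    traj = Trajectory(
        observations=np.asarray(obs_list),
        actions=np.asarray(act_list),
        rewards=np.asarray(rew_list),
        action_probs=np.asarray(prob_list),
        values=np.asarray(val_list),
        terminal=True,
    )
    return traj, env.labels.copy()


def train_refiner(
    dataset,
    segment_fn,
    config: PPOConfig,
    n_classes: int | None = None,
):
    """Train the refinement agent on a dataset of noisy samples.

    ``segment_fn(sample) -> (image, init_labels)`` supplies the working
    image (normally the denoised slice) and the initial MAP segmentation
    for each sample.  Episodes cycle over the samples; every
    ``episodes_per_update`` episodes one PPO update runs.  Returns the
    final parameters; ``params.history`` holds the mean collected reward
    per update.  Deterministic for a fixed ``config.seed``.
    """
    if len(dataset) < 2:
        raise ValidationError("train_refiner needs at least 2 samples")
    if n_classes is None:
        n_classes = int(max(int(s.truth.max()) for s in dataset)) + 1
    # build environments once (SLIC + initial masks are reusable)
    envs, inits = [], []
    for s in dataset:
        image, init = segment_fn(s)
        env = SegmentationEnv(image, init, n_classes, config, truth=s.truth)
        envs.append(env)
        inits.append(init)
    probe = envs[0].observation()
    params = PolicyValueParams.initialize(
        probe.size, envs[0].n_actions, hidden=config.hidden, seed=config.seed
    )
    params.history = []
    if config.updates == 0:
        return params
    rng = np.random.default_rng(config.seed + 1)
    ep = 0
    for _ in range(config.updates):
        batch = []
        for _ in range(config.episodes_per_update):
            i = ep % len(envs)
            traj, _ = run_episode(
                dataset[i], inits[i], params, config,
                train_mode=True, rng=rng, env=envs[i],
            )
            batch.append(traj)
            ep += 1
        history = params.history
        params = ppo_update(batch, params, config, rng=rng)
        params.history = history
        params.history.append(float(np.mean([t.rewards.sum() for t in batch])))
    return params


def refine(
    image: np.ndarray,
    init_labels: np.ndarray,
    params: PolicyValueParams,
    config: PPOConfig,
    n_classes: int | None = None,
) -> np.ndarray:
    """Greedy inference: run one episode without rewards, return the mask."""
    if n_classes is None:
        n_classes = (params.n_actions - 1) // 3
    env = SegmentationEnv(image, init_labels, n_classes, config, truth=None)
    _, labels = run_episode(
        image, init_labels, params, config, train_mode=False, env=env
    )
    return labels
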