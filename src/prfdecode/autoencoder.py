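"""Tied-weight denoising autoencoder and imagery classifier.

The autoencoder has a single hidden layer of k = floor(0.1 * v) units and
tied weights (decoder = encoder transpose, enforced structurally):

    y_c = y + eps,            eps ~ N(0, sd^2) i.i.d. per voxel
    h   = phi(W_e y_c + b_e)
    y_r = W_e^T h + b_d       (linear output)

It is trained only on the four average *perceptual* patterns plus an equal
number of zero patterns (so inputs without signal are restored toward
zero), each corrupted afresh at every optimizer step, with MSE loss and
Adam. The corruption sd (default 12 z-units) deliberately dwarfs the
unit-variance patterns, shaping an attractor landscape with one attractor
per perceived letter plus a zero attractor.

The classifier replaces the decoder with a four-unit softmax head on the
frozen hidden layer (equivalent to multinomial logistic regression on the
pretrained hidden representations) and is trained on single-trial imagery
patterns; significance of leave-one-run-out accuracy is assessed against a
1000-permutation scrambled-label null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patterns import PatternSet
from .stimuli import LETTERS

CORRUPTION_SD = 12.0


@dataclass
class TrainConfig:
    """Adam training schedule."""

    learning_rate: float
    batch_size: int
    iterations: int
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.iterations < 1 or self.batch_size < 1:
            raise ValueError("iterations and batch size must be >= 1")


def autoencoder_config(seed: int = 0) -> TrainConfig:
    """Default autoencoder schedule: batch 100, 2000 Adam steps.

    Adam's per-parameter step is bounded by the learning rate, so total
    weight movement over training is at most lr * iterations. Reaching the
    weight scale the tied attractor solution needs on unit-variance
    patterns within the 2000-step budget requires lr >= ~1e-4; the default
    is 1e-3, which trains to attractor behavior across pattern sizes from
    a few hundred to a few thousand voxels.
    """
    return TrainConfig(learning_rate=1e-3, batch_size=100, iterations=2000,
                       seed=seed)


def classifier_config(seed: int = 0) -> TrainConfig:
    """Published classifier schedule: lr 1e-4, batch 96, 250 steps."""
    return TrainConfig(learning_rate=1e-4, batch_size=96, iterations=250,
                       seed=seed)


class _Adam:
    """Minimal Adam optimizer over a list of arrays."""

    def __init__(self, shapes, cfg: TrainConfig):
        self.cfg = cfg
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1**self.t
        bc2 = 1.0 - c.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * g * g
            p -= c.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + c.eps)


def _phi(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "logistic":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown activation {activation!r}")


def _phi_prime_from(h: np.ndarray, z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return (z > 0).astype(float)
    return h * (1.0 - h)


@dataclass
class AutoencoderParams:
    """Tied-weight autoencoder parameters; W_d = W_e^T is never stored."""

    W_e: np.ndarray  # (k, v)
    b_e: np.ndarray  # (k,)
    b_d: np.ndarray  # (v,)
    activation: str = "relu"
    corruption_sd: float = CORRUPTION_SD
    trained: bool = False
    loss_history: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        k, v = self.W_e.shape
        if k < 1:
            raise ValueError("hidden size must be >= 1")
        if self.b_e.shape != (k,) or self.b_d.shape != (v,):
            raise ValueError("bias shapes do not match W_e")

    @property
    def k(self) -> int:
        return self.W_e.shape[0]

    @property
    def v(self) -> int:
        return self.W_e.shape[1]


def hidden_size(n_voxels: int) -> int:
    """k = floor(0.1 * n_voxels), at least 1."""
    return max(1, int(np.floor(0.1 * n_voxels)))


def init_autoencoder(
    n_voxels: int,
    activation: str = "relu",
    corruption_sd: float = CORRUPTION_SD,
    seed: int = 0,
) -> AutoencoderParams:
    """Small random init (scaled by 1/sqrt(v)); biases zero."""
    k = hidden_size(n_voxels)
    rng = np.random.default_rng(seed)
    return AutoencoderParams(
        W_e=rng.normal(0.0, 1.0 / np.sqrt(n_voxels), size=(k, n_voxels)),
        b_e=np.zeros(k),
        b_d=np.zeros(n_voxels),
        activation=activation,
        corruption_sd=corruption_sd,
    )


def corrupt(y: np.ndarray, sd: float, seed_or_rng=0) -> np.ndarray:
    """Additive zero-mean Gaussian corruption, i.i.d. per voxel."""
    if sd < 0:
        raise ValueError("corruption sd must be nonnegative")
    y = np.asarray(y, dtype=float)
    if sd == 0:
        return y.copy()
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    return y + rng.normal(0.0, sd, size=y.shape)


def ae_forward(
    params: AutoencoderParams, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass (no corruption): returns (hidden, restoration)."""
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = np.atleast_2d(y)
    if Y.shape[1] != params.v:
        raise ValueError(f"pattern length {Y.shape[1]} != v = {params.v}")
    Z = Y @ params.W_e.T + params.b_e
    H = _phi(Z, params.activation)
    Yr = H @ params.W_e + params.b_d
    if single:
        return H[0], Yr[0]
    return H, Yr


def _ae_loss_grads(
    params: AutoencoderParams, Yc: np.ndarray, Y: np.ndarray
) -> tuple[float, list[np.ndarray]]:
    """MSE loss (mean over batch and voxels) and analytic gradients.

    The tied weight receives both the decoder contribution H^T dYr and the
    encoder contribution dZ^T Yc.
    """
    n, v = Y.shape
    Z = Yc @ params.W_e.T + params.b_e
    H = _phi(Z, params.activation)
    Yr = H @ params.W_e + params.b_d
    R = Yr - Y
    loss = float((R * R).mean())
    dYr = 2.0 * R / (n * v)
    g_bd = dYr.sum(axis=0)
    gW_dec = H.T @ dYr
    dH = dYr @ params.W_e.T
    dZ = dH * _phi_prime_from(H, Z, params.activation)
    g_be = dZ.sum(axis=0)
    gW_enc = dZ.T @ Yc
    return loss, [gW_dec + gW_enc, g_be, g_bd]


def train_autoencoder(
    perceptual_averages: np.ndarray,
    config: TrainConfig | None = None,
    activation: str = "relu",
    corruption_sd: float = CORRUPTION_SD,
) -> AutoencoderParams:
    """Train the denoiser on the 4 average perceptual patterns + 4 zeros.

    Each optimizer step draws ``batch_size`` items from the 8-item training
    set with replacement and corrupts them afresh; the clean item is the
    regression target. Deterministic under ``config.seed``.
    """
    P = np.asarray(perceptual_averages, dtype=float)
    if P.ndim != 2 or P.shape[0] != len(LETTERS):
        raise ValueError("need the 4 average perceptual patterns, shape (4, v)")
    if config is None:
        config = autoencoder_config()
    v = P.shape[1]
    items = np.vstack([P, np.zeros_like(P)])  # 4 letters + 4 zero targets
    params = init_autoencoder(v, activation, corruption_sd, seed=config.seed)
    opt = _Adam([params.W_e.shape, params.b_e.shape, params.b_d.shape], config)
    rng = np.random.default_rng(config.seed + 1)
    losses = np.empty(config.iterations)
    theta = [params.W_e, params.b_e, params.b_d]
    for it in range(config.iterations):
        idx = rng.integers(0, items.shape[0], size=config.batch_size)
        Y = items[idx]
        Yc = corrupt(Y, corruption_sd, rng)
        loss, grads = _ae_loss_grads(params, Yc, Y)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"autoencoder training diverged at step {it} (loss={loss})"
            )
        opt.step(theta, grads)
        losses[it] = loss
    params.trained = True
    params.loss_history = losses
    return params


def denoise(params: AutoencoderParams, y: np.ndarray) -> np.ndarray:
    """Restoration y_r of a pattern (no corruption at inference)."""
    if not params.trained:
        raise ValueError("autoencoder has not been trained")
    _, yr = ae_forward(params, y)
    return yr


# -- classifier head ---------------------------------------------------------


@dataclass
class ClassifierHead:
    """Softmax read-out over {H, T, S, C} on the frozen hidden layer."""

    W_c: np.ndarray  # (k, 4)
    b_c: np.ndarray  # (4,)
    loss_history: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.W_c.shape[1] != len(LETTERS) or self.b_c.shape != (len(LETTERS),):
            raise ValueError("head must have one output unit per letter")


def hidden_representation(params: AutoencoderParams, y: np.ndarray) -> np.ndarray:
    """Frozen-encoder hidden activations phi(W_e y + b_e)."""
    h, _ = ae_forward(params, y)
    return h


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=-1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=-1, keepdims=True)


def labels_to_indices(labels) -> np.ndarray:
    return np.asarray([LETTERS.index(l) for l in labels], dtype=int)


def predict_proba(
    head: ClassifierHead, params: AutoencoderParams, y: np.ndarray
) -> np.ndarray:
    """Class probabilities (rows sum to 1)."""
    H = np.atleast_2d(hidden_representation(params, y))
    return _softmax(H @ head.W_c + head.b_c)


def predict_letters(
    head: ClassifierHead, params: AutoencoderParams, y: np.ndarray
) -> list[str]:
    idx = predict_proba(head, params, y).argmax(axis=1)
    return [LETTERS[i] for i in idx]


def train_classifier_head(
    params: AutoencoderParams,
    patterns: np.ndarray,
    labels,
    config: TrainConfig | None = None,
) -> ClassifierHead:
    """Train the softmax head with cross-entropy; the encoder is frozen.

    With the default batch size (96 = training-set size) every step uses
    the full batch and training is deterministic (zero init, convex
    problem); smaller batches are sampled with replacement from
    ``config.seed``.
    """
    if config is None:
        config = classifier_config()
    t = labels_to_indices(labels)
    if len(set(t.tolist())) < len(LETTERS):
        missing = [L for i, L in enumerate(LETTERS) if i not in t]
        raise ValueError(f"missing training class(es): {missing}")
    H = hidden_representation(params, np.asarray(patterns, dtype=float))
    onehot = np.eye(len(LETTERS))[t]
    head = ClassifierHead(
        W_c=np.zeros((params.k, len(LETTERS))), b_c=np.zeros(len(LETTERS))
    )
    opt = _Adam([head.W_c.shape, head.b_c.shape], config)
    rng = np.random.default_rng(config.seed)
    full_batch = config.batch_size >= H.shape[0]
    losses = np.empty(config.iterations)
    for it in range(config.iterations):
        if full_batch:
            Hb, Lb = H, onehot
        else:
            idx = rng.integers(0, H.shape[0], size=config.batch_size)
            Hb, Lb = H[idx], onehot[idx]
        S = _softmax(Hb @ head.W_c + head.b_c)
        losses[it] = float(
            -(Lb * np.log(np.clip(S, 1e-300, None))).sum(axis=1).mean()
        )
        G = (S - Lb) / Hb.shape[0]
        opt.step([head.W_c, head.b_c], [Hb.T @ G, G.sum(axis=0)])
    head.loss_history = losses
    return head


# -- leave-one-run-out cross-validation --------------------------------------


@dataclass
class LoroResult:
    fold_accuracies: np.ndarray  # one per held-out run
    mean_accuracy: float
    fold_runs: list[int]
    train_sizes: list[int]
    test_sizes: list[int]


def _imagery_arrays(pset: PatternSet):
    sub = pset.subset(condition="imagery")
    runs = sorted(sub.manifest["run"].unique().tolist())
    values = sub.values
    labels = labels_to_indices(sub.manifest["letter"].tolist())
    run_ids = sub.manifest["run"].to_numpy()
    sizes = {r: int((run_ids == r).sum()) for r in runs}
    if len(runs) != 4 or len(set(sizes.values())) != 1:
        raise ValueError(
            f"expected 4 balanced imagery runs, got sizes {sizes}"
        )
    return values, labels, run_ids, runs


def loro_cross_validate(
    pset: PatternSet,
    params: AutoencoderParams,
    config: TrainConfig | None = None,
) -> LoroResult:
    """Leave-one-run-out decoding of imagined letters.

    For each of the 4 imagery runs, the head is trained on the other three
    (96 patterns at the full design) and evaluated on the held-out run
    (32 patterns); the mean over folds is the reported accuracy.
    """
    values, labels, run_ids, runs = _imagery_arrays(pset)
    accs, train_n, test_n = [], [], []
    for held in runs:
        tr = run_ids != held
        te = ~tr
        if len(set(labels[tr].tolist())) < 2:
            raise ValueError("training labels constant within fold")
        head = train_classifier_head(
            params, values[tr], [LETTERS[i] for i in labels[tr]], config
        )
        pred = np.asarray(
            labels_to_indices(predict_letters(head, params, values[te]))
        )
        accs.append(float((pred == labels[te]).mean()))
        train_n.append(int(tr.sum()))
        test_n.append(int(te.sum()))
    accs = np.asarray(accs)
    return LoroResult(
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        fold_runs=runs,
        train_sizes=train_n,
        test_sizes=test_n,
    )


# -- permutation test --------------------------------------------------------


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    threshold: float  # nearest-rank 95th percentile of the null
    significant: bool
    n_permutations: int

    @property
    def null_mean(self) -> float:
        return float(self.null.mean())


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q*n)-th smallest value."""
    s = np.sort(np.asarray(values))
    rank = int(np.ceil(q / 100.0 * s.size))
    return float(s[max(rank, 1) - 1])


def _train_heads_batched(
    H: np.ndarray, labels_perm: np.ndarray, config: TrainConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Train one softmax head per permutation simultaneously.

    ``labels_perm`` is (P, n) of class indices. Exactly mirrors
    ``train_classifier_head`` in the full-batch regime (zero init, same
    Adam); vectorization changes nothing but wall time.
    """
    P, n = labels_perm.shape
    k, C = H.shape[1], len(LETTERS)
    onehot = np.eye(C)[labels_perm]  # (P, n, C)
    W = np.zeros((P, k, C))
    b = np.zeros((P, 1, C))
    opt = _Adam([W.shape, b.shape], config)
    Hb = H[None, :, :]  # (1, n, k) broadcasts over permutations
    for _ in range(config.iterations):
        S = _softmax(np.matmul(Hb, W) + b)
        G = (S - onehot) / n
        gW = np.matmul(Hb.transpose(0, 2, 1), G)  # (P, k, C)
        gb = G.sum(axis=1, keepdims=True)
        opt.step([W, b], [gW, gb])
    return W, b


def permutation_test(
    pset: PatternSet,
    params: AutoencoderParams,
    config: TrainConfig | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    observed: LoroResult | None = None,
) -> PermutationResult:
    """Scrambled-label LORO null for the mean decoding accuracy.

    Each permutation scrambles the labels of the 96 training patterns
    (test labels intact), repeats the full leave-one-run-out procedure,
    and records the mean accuracy; the observed accuracy is significant if
    it exceeds the nearest-rank 95th percentile of the null.
    """
    import warnings as _warnings

    if n_permutations < 100:
        _warnings.warn(
            "fewer than 100 permutations gives an unstable 95th percentile",
            stacklevel=2,
        )
    if config is None:
        config = classifier_config()
    if config.batch_size < 96:
        raise ValueError(
            "permutation null requires the full-batch classifier schedule"
        )
    if observed is None:
        observed = loro_cross_validate(pset, params, config)

    values, labels, run_ids, runs = _imagery_arrays(pset)
    H = hidden_representation(params, values)
    rng = np.random.default_rng(seed)
    fold_acc = np.empty((len(runs), n_permutations))
    for fi, held in enumerate(runs):
        tr = run_ids != held
        te = ~tr
        perm_labels = np.stack(
            [rng.permutation(labels[tr]) for _ in range(n_permutations)]
        )
        W, b = _train_heads_batched(H[tr], perm_labels, config)
        S = np.matmul(H[te][None, :, :], W) + b  # (P, n_te, C)
        pred = S.argmax(axis=2)
        fold_acc[fi] = (pred == labels[te][None, :]).mean(axis=1)
    null = fold_acc.mean(axis=0)
    threshold = nearest_rank_percentile(null, 95.0)
    return PermutationResult(
        observed=observed.mean_accuracy,
        null=null,
        threshold=threshold,
        significant=observed.mean_accuracy > threshold,
        n_permutations=n_permutations,
    )
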