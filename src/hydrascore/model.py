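"""Pose scoring model: losses, a scikit-learn style classifier, ranking.

The classifier separates native (RMSD < 2 A to the reference binding mode)
from decoy poses on the multi-channel voxel image. The loss combines

* two-class log loss on the softmaxed class logits, and
* an optional contact-score head: a pseudo-Huber regression on the predicted
  contact mode score, hinged so that poses whose true score is below the
  0.44 cutoff only incur loss when the prediction exceeds that cutoff
  (non-overlapping poses should not be graded on contact quality).

Training is plain SGD with momentum; everything is deterministic per seed.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .nn import Network, build_network, softmax

CMS_CUTOFF = 0.44
P_CLAMP = 1e-7


def _octahedral_rotations():
    """The 24 proper rotations of a cube as (axis permutation, axis flips)."""
    import itertools

    out = []
    for perm in itertools.permutations(range(3)):
        # permutation parity
        parity = 1
        p = list(perm)
        for i in range(3):
            for j in range(i + 1, 3):
                if p[i] > p[j]:
                    parity = -parity
        for flips in itertools.product((False, True), repeat=3):
            det = parity * (-1) ** sum(flips)
            if det == 1:
                out.append((perm, flips))
    return out


_OCT_ROTATIONS = _octahedral_rotations()
assert len(_OCT_ROTATIONS) == 24


def augment_stack_batch(X: np.ndarray, rng: np.random.Generator,
                        rotations: str = "c2",
                        max_shift: int = 0) -> np.ndarray:
    """Random rotation (and optional translation) of the input images.

    Rotations are exact on the cell-centered grid and applied identically
    to all channels of a stack, so protein/ligand/hydration stay
    co-registered. ``rotations="c2"`` flips each stack through a two-fold
    rotation about the grid z axis with probability 1/2 — the symmetry
    group of the C2-ambiguous study systems, and a cheap invariance that
    small networks absorb quickly. ``rotations="octahedral"`` draws from
    all 24 proper cube rotations; ``max_shift`` adds a periodic shift of
    up to that many voxels per axis.
    """
    if rotations == "c2":
        out = np.array(X)
        flip = rng.uniform(size=len(X)) < 0.5
        out[flip] = np.flip(np.flip(out[flip], axis=2), axis=3)
        return out
    if rotations != "octahedral":
        raise ValueError(f"unknown rotation group {rotations!r}")
    out = np.empty_like(X)
    for k in range(len(X)):
        perm, flips = _OCT_ROTATIONS[rng.integers(len(_OCT_ROTATIONS))]
        a = np.transpose(X[k], (0, 1 + perm[0], 1 + perm[1], 1 + perm[2]))
        for ax, f in enumerate(flips):
            if f:
                a = np.flip(a, axis=1 + ax)
        if max_shift:
            shift = rng.integers(-max_shift, max_shift + 1, size=3)
            a = np.roll(a, tuple(shift), axis=(1, 2, 3))
        out[k] = a
    return out

#: profile -> (filters, iterations)
PROFILES = {
    "desk": ((8, 16, 32), 2000),
    "full": ((32, 64, 128), 40000),
}


def classification_loss(p_native: float, is_native: bool) -> float:
    """Two-class log loss; probabilities are clamped into (0, 1) at 1e-7."""
    p = float(p_native)
    if not 0.0 < p < 1.0:
        warnings.warn(f"probability {p} outside (0,1); clamped")
        p = min(max(p, P_CLAMP), 1.0 - P_CLAMP)
    return float(-np.log(p) if is_native else -np.log1p(-p))


def pseudo_huber(a, delta: float = 1.0):
    """delta^2 (sqrt(1 + (a/delta)^2) - 1); quadratic near 0, linear far out."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    a = np.asarray(a, float)
    out = delta**2 * (np.sqrt(1.0 + (a / delta) ** 2) - 1.0)
    return out if out.shape else float(out)


def cms_loss(cms_pred: float, cms_true: float, delta: float = 1.0,
             cutoff: float = CMS_CUTOFF) -> float:
    """Hinged pseudo-Huber contact-score loss.

    True score >= cutoff: pseudo-Huber on the residual. True score below the
    cutoff ("undefined" pose): loss only when the prediction strays above
    the cutoff, pseudo-Huber on that excess.
    """
    if cms_true >= cutoff:
        return pseudo_huber(cms_pred - cms_true, delta)
    return pseudo_huber(max(0.0, cms_pred - cutoff), delta)


def _cms_loss_grad(s: np.ndarray, cms_true: np.ndarray, delta: float,
                   cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized hinged pseudo-Huber loss and d loss / d s (s = prediction)."""
    defined = cms_true >= cutoff
    a = np.where(defined, s - cms_true, np.maximum(0.0, s - cutoff))
    loss = delta**2 * (np.sqrt(1.0 + (a / delta) ** 2) - 1.0)
    dl_da = a / np.sqrt(1.0 + (a / delta) ** 2)
    da_ds = np.where(defined, 1.0, (s > cutoff).astype(float))
    return loss, dl_da * da_ds


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class PoseScoringCNN(BaseEstimator, ClassifierMixin):
    """3D-CNN binding pose classifier.

    Parameters
    ----------
    filters : tuple of int
        Feature maps of the three conv blocks (desk default (8, 16, 32);
        the full-scale profile uses (32, 64, 128)).
    n_iter : int
        SGD iterations (mini-batches); desk default 2000.
    batch_size, learning_rate, momentum : SGD hyperparameters.
    lambda_cls, lambda_cms : loss weights for the classification and
        contact-score terms.
    use_cms_head : bool
        Add the contact-score regression output; requires ``cms`` targets
        at fit time.
    huber_delta, cms_cutoff : contact-score loss shape.
    augment : False | True | "c2" | "octahedral"
        Training-time rotation augmentation of the input images (True means
        "c2"; see :func:`augment_stack_batch`). Default "c2".
    random_state : int
        Seeds initialization and batch sampling; same seed, same model.

    Attributes
    ----------
    network_ : the fitted :class:`hydrascore.nn.Network`
    loss_trace_ : per-iteration training loss
    classes_ : [0, 1] (decoy, native)
    """

    def __init__(self, filters=(8, 16, 32), n_iter=2000, batch_size=16,
                 learning_rate=0.01, momentum=0.9, lambda_cls=1.0,
                 lambda_cms=1.0, use_cms_head=False, huber_delta=1.0,
                 cms_cutoff=CMS_CUTOFF, augment="c2", random_state=None):
        self.filters = filters
        self.n_iter = n_iter
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.lambda_cls = lambda_cls
        self.lambda_cms = lambda_cms
        self.use_cms_head = use_cms_head
        self.huber_delta = huber_delta
        self.cms_cutoff = cms_cutoff
        self.augment = augment
        self.random_state = random_state

    @classmethod
    def from_profile(cls, profile: str = "desk", **kwargs) -> "PoseScoringCNN":
        filters, n_iter = PROFILES[profile]
        kwargs.setdefault("filters", filters)
        kwargs.setdefault("n_iter", n_iter)
        return cls(**kwargs)

    # ------------------------------------------------------------------
    def fit(self, X, y, cms=None):
        """Fit on stacks X (n, C, D, D, D) and binary labels y (1 = native).

        ``cms`` supplies true contact mode scores when the contact-score
        head is enabled.
        """
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 5:
            raise ValueError("X must have shape (n, C, D, D, D)")
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError(
                "training set must contain at least one native and one decoy pose"
            )
        if self.use_cms_head:
            if cms is None:
                raise ValueError("use_cms_head=True requires cms targets")
            cms = np.asarray(cms, dtype=np.float64)
        n, C, D = X.shape[0], X.shape[1], X.shape[2]
        rng = np.random.default_rng(self.random_state)
        n_out = 3 if self.use_cms_head else 2
        net = build_network(C, dims=D, filters=self.filters, n_outputs=n_out,
                            seed=rng)
        velocity = [np.zeros_like(W) for W, _ in net.params]
        trace = np.zeros(self.n_iter)
        bs = min(self.batch_size, n)
        for it in range(self.n_iter):
            idx = rng.choice(n, size=bs, replace=False)
            batch = X[idx]
            if self.augment:
                group = "c2" if self.augment is True else self.augment
                batch = augment_stack_batch(batch, rng, rotations=group)
            logits = net.forward(batch)
            p = softmax(logits[:, :2])
            onehot = np.zeros_like(p)
            onehot[np.arange(bs), y[idx]] = 1.0
            pc = np.clip(p[np.arange(bs), y[idx]], P_CLAMP, 1 - P_CLAMP)
            loss = self.lambda_cls * float(np.mean(-np.log(pc)))
            dlogits = np.zeros_like(logits)
            dlogits[:, :2] = self.lambda_cls * (p - onehot) / bs
            if self.use_cms_head:
                s = _sigmoid(logits[:, 2].astype(np.float64))
                l_cms, dl_ds = _cms_loss_grad(
                    s, cms[idx], self.huber_delta, self.cms_cutoff
                )
                loss += self.lambda_cms * float(l_cms.mean())
                dlogits[:, 2] = (
                    self.lambda_cms * dl_ds * s * (1.0 - s) / bs
                ).astype(logits.dtype)
            net.backward(dlogits)
            lr = self.learning_rate
            for (W, dW), v in zip(net.params, velocity):
                v *= self.momentum
                v -= lr * dW
                W += v
            trace[it] = loss
        self.network_ = net
        self.loss_trace_ = trace
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = C
        return self

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict_proba(self, X, batch_size: int = 64):
        check_is_fitted(self, "network_")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 4:
            X = X[None]
        out = []
        for k in range(0, len(X), batch_size):
            logits = self.network_.forward(X[k:k + batch_size])
            out.append(softmax(logits[:, :2]))
        return np.concatenate(out)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_cms(self, X, batch_size: int = 64):
        check_is_fitted(self, "network_")
        if not self.use_cms_head:
            raise ValueError("model was fitted without a contact-score head")
        X = np.asarray(X, dtype=np.float32)
        out = []
        for k in range(0, len(X), batch_size):
            logits = self.network_.forward(X[k:k + batch_size])
            out.append(_sigmoid(logits[:, 2]))
        return np.concatenate(out)


# ---------------------------------------------------------------------------
# ranking

def score_and_rank(model: PoseScoringCNN, stacks: np.ndarray, pose_ids=None):
    """Score one system's poses and order them by descending native
    probability; ties broken by lexicographic pose id.

    Returns a list of (pose_id, p_native) in rank order.
    """
    stacks = np.asarray(stacks, dtype=np.float32)
    if pose_ids is None:
        pose_ids = [f"pose_{k}" for k in range(len(stacks))]
    p = model.predict_proba(stacks)[:, 1]
    order = sorted(range(len(p)), key=lambda k: (-p[k], str(pose_ids[k])))
    return [(pose_ids[k], float(p[k])) for k in order]


def topn_success(rankings: dict, labels: dict, n: int) -> float:
    """Fraction of systems with >= 1 native-labeled pose in the first n ranks.

    ``rankings`` maps system -> ordered pose ids; ``labels`` maps system ->
    {pose_id: is_native}.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not rankings:
        raise ValueError("no systems to evaluate")
    hits = 0
    for system, ranked in rankings.items():
        lab = labels[system]
        if any(lab[pid] for pid in list(ranked)[:n]):
            hits += 1
    return hits / len(rankings)
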