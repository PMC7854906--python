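"""The two-level adaptation objective.

Components:

* classification cross-entropy ``L_C`` on labeled source samples;
* multi-kernel MMD ``L_MMD`` between source and target feature sets, with an
  RBF kernel bank kappa(x, y) = sum_n eta_n exp(-||x - y||^2 / (2 sigma_n));
* domain-adversarial cross-entropy ``H`` of the discriminator (by the sign
  convention used throughout, ``L_D = -H``: the discriminator minimizes H,
  the generator minimizes ``-H`` and thereby maximizes domain confusion);
* a Lipschitz gradient penalty ``(||grad_x s(x)||_2 - 1)^2`` on the
  discriminator's penalized scalar s;
* an L2 term ``||W||^2`` over the configured dense weight matrices.

Combined objectives:

    generator/classifier:  L_G = L_C + lambda_d * (-H) + lambda_m * L_MMD
                                 + lambda_z * ||W||^2
    discriminator:         H + lambda_L * gradient_penalty

The MMD cross-term coefficient defaults to 2 (the standard biased estimator,
which is nonnegative); ``cross_coefficient=1`` reproduces the plain
three-term form verbatim, at the cost of possible small negative values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "KernelBank",
    "LossReport",
    "classification_loss",
    "mk_kernel",
    "mmd2",
    "mmd2_feature_grads",
    "median_heuristic_bank",
    "domain_adversarial_loss",
    "gradient_penalty",
    "generator_objective",
    "discriminator_objective",
]

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class KernelBank:
    """A bank of RBF kernels: bandwidths sigma_n (squared-distance scale) and
    weights eta_n (normalized to sum to 1)."""

    sigmas: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.sigmas) != len(self.weights):
            raise ValueError("sigmas and weights must have equal length")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("all bandwidths must be positive")
        if any(w < 0 for w in self.weights):
            raise ValueError("kernel weights must be nonnegative")
        total = float(sum(self.weights))
        if total <= 0:
            raise ValueError("kernel weights must not all be zero")
        object.__setattr__(self, "weights", tuple(w / total for w in self.weights))


@dataclass
class LossReport:
    """Scalar loss components of one training step (or epoch average)."""

    L_C: float = np.nan
    L_MMD: float = np.nan
    H: float = np.nan               # domain cross-entropy
    gradient_penalty: float = np.nan
    l2_term: float = np.nan
    L_G: float = np.nan
    L_disc: float = np.nan

    @property
    def L_D(self) -> float:
        return -self.H

    def as_dict(self) -> dict[str, float]:
        return {
            "L_C": self.L_C, "L_MMD": self.L_MMD, "H": self.H, "L_D": self.L_D,
            "gradient_penalty": self.gradient_penalty, "l2_term": self.l2_term,
            "L_G": self.L_G, "L_disc": self.L_disc,
        }


def _check_prob_rows(scores: np.ndarray, what: str) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError(f"{what} must be [n, k] probability rows")
    return scores


def classification_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class (source samples only).

    Probabilities are clamped at 1e-12 before the log.
    """
    scores = _check_prob_rows(scores, "class scores")
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1 or labels.shape[0] != scores.shape[0]:
        raise ValueError("labels must have one entry per score row")
    if labels.min() < 0 or labels.max() >= scores.shape[1]:
        raise ValueError(
            f"label out of range: valid classes are 0..{scores.shape[1] - 1}"
        )
    p = np.clip(scores[np.arange(len(labels)), labels], _PROB_FLOOR, None)
    return float(-np.mean(np.log(p)))


def domain_adversarial_loss(scores: np.ndarray, domain_labels: np.ndarray) -> float:
    """Mean cross-entropy H of the domain prediction over the joint batch.

    The adversarial loss in the combined objective is L_D = -H; callers use H
    directly for the discriminator step and -H (scaled by lambda_d) for the
    generator step.
    """
    scores = _check_prob_rows(scores, "domain scores")
    labels = np.asarray(domain_labels, dtype=int)
    if labels.ndim != 1 or labels.shape[0] != scores.shape[0]:
        raise ValueError("domain labels must have one entry per score row")
    if labels.min() < 0 or labels.max() >= scores.shape[1]:
        raise ValueError(
            f"domain label out of range: valid domains are 0..{scores.shape[1] - 1}"
        )
    p = np.clip(scores[np.arange(len(labels)), labels], _PROB_FLOOR, None)
    return float(-np.mean(np.log(p)))


def mk_kernel(x: np.ndarray, y: np.ndarray, bank: KernelBank) -> float:
    """Multi-kernel RBF value sum_n eta_n exp(-||x - y||^2 / (2 sigma_n))."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    d2 = float(np.sum((x - y) ** 2))
    return float(sum(w * np.exp(-d2 / (2.0 * s)) for s, w in zip(bank.sigmas, bank.weights)))


def _kernel_matrix(a: np.ndarray, b: np.ndarray, bank: KernelBank) -> np.ndarray:
    d2 = cdist(a, b, metric="sqeuclidean")
    out = np.zeros_like(d2)
    for s, w in zip(bank.sigmas, bank.weights):
        out += w * np.exp(-d2 / (2.0 * s))
    return out


def mmd2(
    features_s: np.ndarray,
    features_t: np.ndarray,
    bank: KernelBank,
    cross_coefficient: int = 2,
) -> float:
    """Biased squared-MMD estimate between two feature sets.

    (1/nS^2) sum k(S,S) - c (1/(nS nT)) sum k(S,T) + (1/nT^2) sum k(T,T),
    with c = `cross_coefficient`.  c = 2 (default) is the standard biased
    estimator and is nonnegative; c = 1 matches the plain three-term form.
    """
    if cross_coefficient not in (1, 2):
        raise ValueError("cross_coefficient must be 1 or 2")
    s = np.atleast_2d(np.asarray(features_s, dtype=float))
    t = np.atleast_2d(np.asarray(features_t, dtype=float))
    if s.shape[0] == 0 or t.shape[0] == 0:
        raise ValueError("both feature sets must be nonempty")
    kss = _kernel_matrix(s, s, bank).mean()
    ktt = _kernel_matrix(t, t, bank).mean()
    kst = _kernel_matrix(s, t, bank).mean()
    return float(kss - cross_coefficient * kst + ktt)


def mmd2_feature_grads(
    features_s: np.ndarray,
    features_t: np.ndarray,
    bank: KernelBank,
    cross_coefficient: int = 2,
) -> tuple[float, np.ndarray, np.ndarray]:
    """MMD^2 and its exact gradients with respect to both feature sets.

    d/dx_i of w e^{-||x_i - y_j||^2 / (2 sigma)} is
    -(w/sigma) e^{...} (x_i - y_j); terms are accumulated over the bank.
    """
    s = np.atleast_2d(np.asarray(features_s, dtype=float))
    t = np.atleast_2d(np.asarray(features_t, dtype=float))
    ns, nt = s.shape[0], t.shape[0]
    if ns == 0 or nt == 0:
        raise ValueError("both feature sets must be nonempty")

    def weighted(a, b):
        d2 = cdist(a, b, metric="sqeuclidean")
        k = np.zeros_like(d2)
        kw = np.zeros_like(d2)          # sum_n (eta_n / sigma_n) exp(...)
        for sig, w in zip(bank.sigmas, bank.weights):
            e = np.exp(-d2 / (2.0 * sig))
            k += w * e
            kw += (w / sig) * e
        return k, kw

    kss, wss = weighted(s, s)
    ktt, wtt = weighted(t, t)
    kst, wst = weighted(s, t)
    c = float(cross_coefficient)
    value = float(kss.mean() - c * kst.mean() + ktt.mean())

    # grad wrt s_i: (2/ns^2) sum_j -wss_ij (s_i - s_j)  +  cross term
    gs = (-2.0 / ns**2) * (wss.sum(axis=1)[:, None] * s - wss @ s)
    gs += (c / (ns * nt)) * (wst.sum(axis=1)[:, None] * s - wst @ t)
    gt = (-2.0 / nt**2) * (wtt.sum(axis=1)[:, None] * t - wtt @ t)
    gt += (c / (ns * nt)) * (wst.sum(axis=0)[:, None] * t - wst.T @ s)
    return value, gs, gt


def median_heuristic_bank(
    features_s: np.ndarray,
    features_t: np.ndarray,
    n_kernels: int = 5,
    spacing: float = 2.0,
) -> KernelBank:
    """Kernel bank centered on the median pairwise squared distance of the
    pooled set, with bandwidths center * spacing^k for k symmetric around 0
    and equal weights."""
    pooled = np.vstack([np.atleast_2d(features_s), np.atleast_2d(features_t)])
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 pooled points for the median heuristic")
    d2 = cdist(pooled, pooled, metric="sqeuclidean")
    upper = d2[np.triu_indices(pooled.shape[0], k=1)]
    center = float(np.median(upper))
    if center <= 0:
        raise ValueError("median pairwise distance is zero (all points identical)")
    ks = np.arange(n_kernels) - (n_kernels - 1) / 2.0
    sigmas = tuple(center * spacing**k for k in ks)
    return KernelBank(sigmas=sigmas, weights=(1.0,) * n_kernels)


def gradient_penalty(discriminator, eval_points: np.ndarray) -> float:
    """Mean over eval points of (||grad_x s(x)||_2 - 1)^2.

    `discriminator` must expose exact input gradients: either a
    ``gradient_penalty(points)`` method (as `MLPDiscriminator` does) or an
    ``input_gradient(points)`` method returning grad_x s.  There is no
    finite-difference fallback.
    """
    pts = np.atleast_2d(np.asarray(eval_points, dtype=float))
    if hasattr(discriminator, "gradient_penalty"):
        return float(discriminator.gradient_penalty(pts))
    if hasattr(discriminator, "input_gradient"):
        g = discriminator.input_gradient(pts)
        g = g[0] if isinstance(g, tuple) else np.asarray(g, dtype=float)
        norms = np.linalg.norm(np.atleast_2d(g), axis=1)
        return float(np.mean((norms - 1.0) ** 2))
    raise TypeError(
        "discriminator provides no exact input gradient "
        "(need .gradient_penalty or .input_gradient); finite differences are not used"
    )


def l2_term(weight_matrices: list[np.ndarray]) -> float:
    """Sum of squared entries over the configured weight matrices."""
    return float(sum(np.sum(w * w) for w in weight_matrices))


def generator_objective(
    L_C: float,
    H: float,
    L_MMD: float,
    w_norm2: float,
    lambda_d: float,
    lambda_m: float,
    lambda_z: float,
) -> float:
    """L_G = L_C + lambda_d * (-H) + lambda_m * L_MMD + lambda_z * ||W||^2."""
    return float(L_C + lambda_d * (-H) + lambda_m * L_MMD + lambda_z * w_norm2)


def discriminator_objective(H: float, penalty: float, lambda_L: float) -> float:
    """Discriminator step objective: H + lambda_L * gradient penalty."""
    return float(H + lambda_L * penalty)
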