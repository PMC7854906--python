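"""Feature generator, emotion classifier and domain discriminator.

Two CNN presets are provided, mirroring the reference cross-day and
cross-subject architectures, plus a small ``compact`` preset for desk-scale
experiments.  Convolutions are valid (unpadded) and pooling is 2x2 ceil-mode,
the only standard convention under which the cross-day flatten size works out
to 7 x 7 x 64 for a 32 x 32 input (32 -> 30 -> 15 -> 13 -> 7).  The
cross-subject architecture's quoted flatten size (6 x 6 x 128) is not reproducible
for a 32 x 32 input under any single standard convention; the layer list is
honored and the true flatten size (3 x 3 x 128) is computed dynamically.

The generator is shared between source and target domains -- only the AdaBN
statistics are domain-specific.  Classifier and discriminator are softmax
heads on the 256-d (resp. preset-width) feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nn import (
    AdaBN,
    Context,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    Layer,
    MaxPool2x2,
    ReLU,
    Sequential,
    softmax,
)

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "MLPDiscriminator",
    "TDANNetworks",
    "build_preset",
    "PRESETS",
]


@dataclass(frozen=True)
class LayerSpec:
    kind: str                    # conv | maxpool | dense | adabn | dropout | activation
    in_dim: int | None = None
    out_dim: int | None = None
    kernel: int | None = None
    stride: int | None = None
    rate: float | None = None


@dataclass
class NetworkSpec:
    generator_layers: list[LayerSpec]
    classifier_layers: list[LayerSpec]
    discriminator_layers: list[LayerSpec]
    feature_dim: int
    preset: str
    input_hw: int
    flatten_hw: int
    flatten_ch: int


def _propagate_hw(hw: int, convs: list[int]) -> int:
    """Spatial size after a run of valid convs (kernel sizes) then ceil-pool."""
    for k in convs:
        hw = hw - k + 1
        if hw < 1:
            raise ValueError("input too small for the convolution stack")
    return math.ceil(hw / 2)


# (conv groups as lists of (in, out, kernel), dense widths)
PRESETS: dict[str, dict] = {
    "cross_day": {
        "conv_groups": [[(5, 6, 3)], [(6, 64, 3)]],
        "dense": [512, 256],
    },
    "cross_subject": {
        "conv_groups": [[(5, 32, 3), (32, 32, 3)],
                        [(32, 64, 3), (64, 64, 3), (64, 128, 3), (128, 128, 3)]],
        "dense": [1024, 512, 256],
    },
    # desk-scale preset for synthetic benchmarks; same topology family
    "compact": {
        "conv_groups": [[(5, 8, 3)], [(8, 16, 3)]],
        "dense": [64, 32],
    },
}


class MLPDiscriminator:
    """Domain discriminator: dense (optionally ReLU-hidden) softmax head.

    Beyond the ordinary forward/backward used for the domain cross-entropy,
    the discriminator exposes the machinery for the Lipschitz gradient
    penalty: the penalized scalar s(x) is the pre-softmax logit of domain 0
    (a probability output would bound the gradient below 1 and make the
    unit-norm target unreachable), and both its input gradient and the exact
    parameter gradient of (||grad_x s|| - 1)^2 are computed analytically
    (double backprop; ReLU masks treated as locally constant, which is exact
    almost everywhere).
    """

    def __init__(self, in_dim: int, n_domains: int, rng: np.random.Generator,
                 hidden: tuple[int, ...] = ()):
        if n_domains < 2:
            raise ValueError("need at least 2 domains")
        self.in_dim, self.n_domains, self.hidden = in_dim, n_domains, tuple(hidden)
        dims = [in_dim, *hidden, n_domains]
        self.denses: list[Dense] = []
        layers: list[Layer] = []
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            d = Dense(a, b, rng, scale=2.0 if i < len(dims) - 2 else 1.0)
            self.denses.append(d)
            layers.append(d)
            if i < len(dims) - 2:
                layers.append(ReLU())
        self.net = Sequential(layers)

    # ordinary use ------------------------------------------------------
    def forward(self, x: np.ndarray, ctx: Context | None = None) -> np.ndarray:
        """Domain logits [B, N]."""
        return self.net.forward(x, ctx or Context(mode="eval"))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))

    def backward(self, glogits: np.ndarray) -> np.ndarray:
        """Backprop a logit gradient; accumulates parameter grads, returns
        the gradient with respect to the input features."""
        return self.net.backward(glogits)

    def zero_grad(self) -> None:
        self.net.zero_grad()

    def named_params(self, prefix: str = "d.") -> list[tuple[str, Layer, str]]:
        return self.net.named_params(prefix)

    # gradient-penalty machinery ---------------------------------------
    def _masks_for(self, x: np.ndarray) -> list[np.ndarray]:
        masks = []
        h = x
        for i, d in enumerate(self.denses):
            a = h @ d.params["weight"].T + d.params["bias"]
            if i < len(self.denses) - 1:
                masks.append(a > 0)
                h = np.where(a > 0, a, 0.0)
        return masks

    def input_gradient(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """grad_x s(x) for the penalized scalar s = logit of domain 0.

        Returns the gradient [B, in_dim] and the per-hidden-layer deltas
        (used by `penalty_param_grads`).
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        masks = self._masks_for(x)
        b = x.shape[0]
        delta = np.tile(np.eye(self.n_domains)[0], (b, 1))   # d s / d a_L
        deltas = [delta]
        for i in range(len(self.denses) - 1, 0, -1):
            delta = (delta @ self.denses[i].params["weight"]) * masks[i - 1]
            deltas.append(delta)
        deltas.reverse()                                      # delta at layer l's output
        g = delta @ self.denses[0].params["weight"]
        return g, deltas

    def gradient_penalty(self, x: np.ndarray) -> float:
        """Mean over eval points of (||grad_x s||_2 - 1)^2."""
        g, _ = self.input_gradient(x)
        norms = np.linalg.norm(g, axis=1)
        return float(np.mean((norms - 1.0) ** 2))

    def penalty_param_grads(self, x: np.ndarray, scale: float = 1.0) -> float:
        """Accumulate `scale` times the exact d/d(theta_d) of the mean
        gradient penalty into the discriminator grads; returns the
        (unscaled) penalty value.

        With ReLU masks D_l fixed, grad_x s = W_1^T D_1 ... W_L^T e_0 is
        multilinear in the weight matrices, so d(v . g)/dW_l is the outer
        product of the backward delta at layer l with the forward sweep of
        v = dP/dg through the masked chain.  Biases do not enter g.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        g, deltas = self.input_gradient(x)
        b = x.shape[0]
        norms = np.linalg.norm(g, axis=1)
        penalty = float(np.mean((norms - 1.0) ** 2))
        safe = np.where(norms > 0, norms, 1.0)
        v = scale * (2.0 * (norms - 1.0) / safe)[:, None] * g / b   # dP/dg per point
        masks = self._masks_for(x)
        p = v                                                  # forward-left sweep
        for l, d in enumerate(self.denses):
            self.grads_add(d, deltas[l], p)
            if l < len(self.denses) - 1:
                p = (p @ d.params["weight"].T) * masks[l]
        return penalty

    @staticmethod
    def grads_add(dense: Dense, delta: np.ndarray, p: np.ndarray) -> None:
        dense.grads["weight"] += np.einsum("bo,bi->oi", delta, p)

    def state_dict(self) -> dict:
        return self.net.state_dict()

    def load_state_dict(self, state: dict) -> None:
        self.net.load_state_dict(state)


@dataclass
class TDANNetworks:
    """Generator + classifier + discriminator with their shared spec."""

    spec: NetworkSpec
    generator: Sequential
    classifier: Sequential
    discriminator: MLPDiscriminator

    def forward_generator(self, images: np.ndarray, ctx: Context) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.ndim != 4 or images.shape[1:] != (5, self.spec.input_hw, self.spec.input_hw):
            raise ValueError(
                f"expected images [B, 5, {self.spec.input_hw}, {self.spec.input_hw}], "
                f"got {images.shape}"
            )
        return self.generator.forward(images, ctx)

    def forward_classifier(self, features: np.ndarray, ctx: Context | None = None) -> np.ndarray:
        """Class probabilities [B, M] (softmax rows)."""
        logits = self.classifier.forward(features, ctx or Context(mode="eval"))
        return softmax(logits)

    def forward_discriminator(self, features: np.ndarray) -> np.ndarray:
        """Domain probabilities [B, N] (softmax rows)."""
        return self.discriminator.predict_proba(features)

    def zero_grad(self) -> None:
        self.generator.zero_grad()
        self.classifier.zero_grad()
        self.discriminator.zero_grad()

    def bn_layers(self):
        return self.generator.bn_layers()

    def l2_weights(self) -> list[np.ndarray]:
        """The ||W||^2 parameter set: dense weights of generator + classifier."""
        return self.generator.dense_weights() + self.classifier.dense_weights()

    def state_dict(self) -> dict:
        return {
            "generator": self.generator.state_dict(),
            "classifier": self.classifier.state_dict(),
            "discriminator": self.discriminator.state_dict(),
        }

    def load_state_dict(self, state: dict) -> None:
        self.generator.load_state_dict(state["generator"])
        self.classifier.load_state_dict(state["classifier"])
        self.discriminator.load_state_dict(state["discriminator"])


def build_preset(
    name: str,
    n_classes: int = 2,
    n_domains: int = 2,
    seed: int | np.random.Generator = 0,
    input_hw: int = 32,
    adaptive_norm: bool = True,
    discriminator_hidden: tuple[int, ...] = (),
    dropout_rate: float = 0.5,
    dtype=np.float32,
) -> TDANNetworks:
    """Instantiate one of the architecture presets.

    The flatten size is always computed from the actual spatial dimensions.
    AdaBN follows every conv group and dense layer; dense layers carry
    dropout (rate 0.5).  ``adaptive_norm=False`` replaces AdaBN with plain
    batch normalization (shared statistics) for source-only baselines.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    if n_classes < 2 or n_domains < 2:
        raise ValueError("need n_classes >= 2 and n_domains >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = PRESETS[name]

    layers: list[Layer] = []
    gspec: list[LayerSpec] = []
    hw = input_hw
    ch = None
    for group in cfg["conv_groups"]:
        for (cin, cout, k) in group:
            layers.append(Conv2D(cin, cout, k, rng, dtype=dtype))
            gspec.append(LayerSpec("conv", in_dim=cin, out_dim=cout, kernel=k, stride=1))
            ch = cout
        layers += [AdaBN(ch, adaptive=adaptive_norm, dtype=dtype), ReLU(), MaxPool2x2()]
        gspec += [LayerSpec("adabn", in_dim=ch, out_dim=ch),
                  LayerSpec("activation", in_dim=ch, out_dim=ch),
                  LayerSpec("maxpool", in_dim=ch, out_dim=ch, kernel=2, stride=2)]
        hw = _propagate_hw(hw, [k for (_, _, k) in group])
    flat = hw * hw * ch
    layers.append(Flatten())
    gspec.append(LayerSpec("dense", in_dim=flat, out_dim=flat))  # flatten marker
    prev = flat
    for width in cfg["dense"]:
        layers += [Dense(prev, width, rng, dtype=dtype),
                   AdaBN(width, adaptive=adaptive_norm, dtype=dtype),
                   ReLU(), Dropout(dropout_rate)]
        gspec += [LayerSpec("dense", in_dim=prev, out_dim=width),
                  LayerSpec("adabn", in_dim=width, out_dim=width),
                  LayerSpec("activation", in_dim=width, out_dim=width),
                  LayerSpec("dropout", in_dim=width, out_dim=width, rate=dropout_rate)]
        prev = width
    feature_dim = prev

    generator = Sequential(layers)
    classifier = Sequential([Dense(feature_dim, n_classes, rng, scale=1.0, dtype=dtype)])
    discriminator = MLPDiscriminator(feature_dim, n_domains, rng, hidden=discriminator_hidden)

    spec = NetworkSpec(
        generator_layers=gspec,
        classifier_layers=[LayerSpec("dense", in_dim=feature_dim, out_dim=n_classes)],
        discriminator_layers=[LayerSpec("dense", in_dim=feature_dim, out_dim=n_domains)],
        feature_dim=feature_dim,
        preset=name,
        input_hw=input_hw,
        flatten_hw=hw,
        flatten_ch=ch,
    )
    return TDANNetworks(spec=spec, generator=generator,
                        classifier=classifier, discriminator=discriminator)
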