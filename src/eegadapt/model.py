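"""Two-level adversarial training, evaluation and leave-one-domain-out CV.

The public surface follows the Model/Results convention: `TDANN` holds the
data and an `AdaptationConfig`; `TDANN.fit()` runs the alternating
discriminator/generator optimization and returns a `TDANNResults` carrying
the trained networks, per-epoch loss traces, and evaluation helpers.
`leave_one_domain_out` wraps the full cross-validation protocol: each domain
(day or subject) serves once as the unlabeled target/test set while the
remaining domains form the labeled source.

Training is transductive by default: the unlabeled target pool participates
in every batch (half source, half target), driving the AdaBN statistics, the
MMD alignment and the domain discriminator.  Target labels are never read
anywhere in the training path -- `TDANN` does not accept them.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from . import losses as L
from .losses import KernelBank, LossReport
from .networks import TDANNetworks, build_preset
from .nn import Context, softmax
from .topomap import TopoImages

__all__ = [
    "AdaptationConfig",
    "Metrics",
    "TDANN",
    "TDANNResults",
    "LOOCVResults",
    "make_domain_batches",
    "leave_one_domain_out",
]


@dataclass(frozen=True)
class AdaptationConfig:
    """Hyperparameters of the two-level objective and its optimization.

    Defaults follow the reference cross-day TDANN protocol: loss weights
    lambda_d = 0.1, lambda_m = 0.1, lambda_z = 0.01, lambda_L = 10; Adam with
    learning rate 5e-4; batches of 160 samples split half source / half
    target; 15% validation split.  The stopping rule (early stopping on
    validation classification loss, patience 20, cap 300 epochs) is this
    package's choice.
    """

    preset: str = "cross_day"
    n_classes: int = 2
    lambda_d: float = 0.1
    lambda_m: float = 0.1
    lambda_z: float = 0.01
    lambda_L: float = 10.0
    batch_source: int = 80
    batch_target: int = 80
    learning_rate: float = 5e-4
    max_epochs: int = 300
    patience: int = 20
    val_fraction: float = 0.15
    seed: int = 0
    adaptive_norm: bool = True
    use_target: bool = True            # transductive protocol
    mmd_cross_coefficient: int = 2
    mmd_n_kernels: int = 5
    mmd_spacing: float = 2.0
    kernel_bank: KernelBank | None = None   # None -> per-batch median heuristic
    gp_eval_points: str = "interpolates"    # | at_source_target
    discriminator_hidden: tuple[int, ...] = ()
    disc_steps: int = 1
    adapt_chunk: int = 1024

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 0.5):
            raise ValueError("val_fraction must be in (0, 0.5)")
        if min(self.lambda_d, self.lambda_m, self.lambda_z, self.lambda_L) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.gp_eval_points not in ("interpolates", "at_source_target"):
            raise ValueError(f"unknown gp_eval_points {self.gp_eval_points!r}")

    @property
    def batch_total(self) -> int:
        return self.batch_source + (self.batch_target if self.use_target else 0)

    def replace(self, **kw) -> "AdaptationConfig":
        return dc_replace(self, **kw)

    def variant(self, name: str) -> "AdaptationConfig":
        """Named ablations of the two-level objective.

        tdann: the full method.  mmd_only: no adversarial term.  dann_only:
        no MMD term.  source_only: no adaptation at all -- plain batch
        normalization and no target data in training.
        """
        if name == "tdann":
            return self
        if name == "mmd_only":
            return self.replace(lambda_d=0.0)
        if name == "dann_only":
            return self.replace(lambda_m=0.0)
        if name == "source_only":
            return self.replace(lambda_d=0.0, lambda_m=0.0,
                                adaptive_norm=False, use_target=False)
        raise ValueError(f"unknown variant {name!r}")

    def hash(self) -> str:
        payload = asdict(self)
        payload["kernel_bank"] = None if self.kernel_bank is None else [
            list(self.kernel_bank.sigmas), list(self.kernel_bank.weights)
        ]
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class Metrics:
    """Classification metrics on one evaluation set."""

    accuracy: float
    per_class_accuracy: np.ndarray      # [M]; nan for absent classes
    confusion: np.ndarray               # [M, M], rows = true class
    n: int
    domain: int | None = None
    seed: int | None = None
    config_hash: str | None = None

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray,
                         n_classes: int, **kw) -> "Metrics":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        conf = np.zeros((n_classes, n_classes), dtype=int)
        np.add.at(conf, (y_true, y_pred), 1)
        row = conf.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_class = np.where(row > 0, np.diag(conf) / np.maximum(row, 1), np.nan)
        return cls(
            accuracy=float(np.trace(conf) / max(len(y_true), 1)),
            per_class_accuracy=per_class,
            confusion=conf,
            n=len(y_true),
            **kw,
        )


def _as_network_input(images) -> np.ndarray:
    if isinstance(images, TopoImages):
        return images.to_network_input()
    arr = np.asarray(images, dtype=float)
    if arr.ndim != 4:
        raise ValueError("expected images [n, bands, H, W] or a TopoImages")
    return arr


def make_domain_batches(
    n_source: int,
    n_target: int,
    batch_source: int,
    batch_target: int,
    rng: np.random.Generator,
):
    """One epoch of paired index batches.

    Source indices are a seeded permutation cut into full batches (every
    source sample appears exactly once per epoch; a short final batch is
    dropped).  Target indices are drawn without replacement from a shuffled
    cycle that reshuffles when exhausted.
    """
    if n_source < batch_source:
        raise ValueError(f"source pool ({n_source}) smaller than one batch ({batch_source})")
    n_batches = n_source // batch_source
    src_perm = rng.permutation(n_source)
    tgt_order = rng.permutation(n_target) if n_target else np.empty(0, dtype=int)
    if n_target and n_target < batch_target:
        raise ValueError(f"target pool ({n_target}) smaller than one batch ({batch_target})")
    tpos = 0
    for b in range(n_batches):
        src = src_perm[b * batch_source:(b + 1) * batch_source]
        if n_target:
            if tpos + batch_target > n_target:
                tgt_order = rng.permutation(n_target)
                tpos = 0
            tgt = tgt_order[tpos:tpos + batch_target]
            tpos += batch_target
        else:
            tgt = np.empty(0, dtype=int)
        yield src, tgt


def _stratified_val_split(labels, domains, val_fraction, rng):
    """Hold out ~val_fraction of each (source-domain, class) cell."""
    labels = np.asarray(labels, dtype=int)
    domains = np.asarray(domains, dtype=int)
    val_mask = np.zeros(len(labels), dtype=bool)
    for d in np.unique(domains):
        for c in np.unique(labels):
            idx = np.nonzero((domains == d) & (labels == c))[0]
            if len(idx) == 0:
                continue
            k = max(1, int(round(val_fraction * len(idx))))
            val_mask[rng.permutation(idx)[:k]] = True
    return ~val_mask, val_mask


class TDANN:
    """The two-level domain adaptation model, bound to one source/target pair.

    Parameters
    ----------
    source_images : TopoImages or array [n_S, n_bands, H, W]
        Labeled source pool (multiple source domains merged; their original
        domain ids, if given, only stratify the validation split).
    source_labels : int array [n_S]
    target_images : TopoImages, array, or None
        Unlabeled target pool.  Required unless the config disables target
        use (source-only baseline).  Target labels are never accepted.
    config : AdaptationConfig
    """

    def __init__(self, source_images, source_labels, target_images,
                 config: AdaptationConfig, source_domains=None):
        self.config = config
        self.xs = _as_network_input(source_images)
        self.ys = np.asarray(source_labels, dtype=int)
        if self.ys.shape != (self.xs.shape[0],):
            raise ValueError("source_labels must have one entry per source image")
        if self.ys.min() < 0 or self.ys.max() >= config.n_classes:
            raise ValueError("source label out of range for config.n_classes")
        if source_domains is None and isinstance(source_images, TopoImages):
            source_domains = source_images.domains
        self.source_domains = (
            np.zeros(len(self.ys), dtype=int) if source_domains is None
            else np.asarray(source_domains, dtype=int)
        )
        if config.use_target:
            if target_images is None:
                raise ValueError("config.use_target=True requires a target pool")
            self.xt = _as_network_input(target_images)
        else:
            self.xt = None

    # ------------------------------------------------------------------
    def fit(self, verbose: bool = False) -> "TDANNResults":
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        init_s, split_s, batch_s, drop_s = ss.spawn(4)
        nets = build_preset(
            cfg.preset,
            n_classes=cfg.n_classes,
            n_domains=2,
            seed=np.random.default_rng(init_s),
            input_hw=self.xs.shape[-1],
            adaptive_norm=cfg.adaptive_norm,
            discriminator_hidden=cfg.discriminator_hidden,
        )
        train_mask, val_mask = _stratified_val_split(
            self.ys, self.source_domains, cfg.val_fraction,
            np.random.default_rng(split_s),
        )
        xs_tr, ys_tr = self.xs[train_mask], self.ys[train_mask]
        xs_va, ys_va = self.xs[val_mask], self.ys[val_mask]

        gen_targets = nets.generator.named_params("f.") + nets.classifier.named_params("c.")
        gen_opt = _adam(gen_targets, cfg.learning_rate)
        disc_opt = _adam(nets.discriminator.named_params(), cfg.learning_rate)

        batch_rng = np.random.default_rng(batch_s)
        drop_rng = np.random.default_rng(drop_s)
        n_t = 0 if self.xt is None else self.xt.shape[0]

        history: list[dict] = []
        best = {"val_loss": np.inf, "epoch": -1, "state": None}
        epochs_no_improve = 0
        t0 = time.perf_counter()
        for epoch in range(cfg.max_epochs):
            reports = []
            for src_idx, tgt_idx in make_domain_batches(
                xs_tr.shape[0], n_t, cfg.batch_source,
                cfg.batch_target if self.xt is not None else 0, batch_rng,
            ):
                rep = self._step(nets, gen_opt, disc_opt,
                                 xs_tr[src_idx], ys_tr[src_idx],
                                 None if self.xt is None else self.xt[tgt_idx],
                                 drop_rng)
                reports.append(rep)
            val_loss = self._validation_loss(nets, xs_va, ys_va)
            row = {k: float(np.mean([r.as_dict()[k] for r in reports]))
                   for k in reports[0].as_dict()}
            row.update(epoch=epoch, val_loss=val_loss)
            history.append(row)
            if verbose:
                print(f"epoch {epoch:3d}  L_G={row['L_G']:.4f}  val={val_loss:.4f}")
            if val_loss < best["val_loss"] - 1e-9:
                best = {"val_loss": val_loss, "epoch": epoch,
                        "state": nets.state_dict()}
                epochs_no_improve = 0
            else:
                epochs_no_improve += 1
                if epochs_no_improve > cfg.patience:
                    break
        if best["state"] is not None:
            nets.load_state_dict(best["state"])
        results = TDANNResults(
            networks=nets,
            config=cfg,
            history=pd.DataFrame(history),
            best_epoch=best["epoch"],
            best_val_loss=best["val_loss"],
            fit_seconds=time.perf_counter() - t0,
        )
        if self.xt is not None:
            results.adapt(self.xt)
        return results

    # ------------------------------------------------------------------
    def _step(self, nets: TDANNetworks, gen_opt, disc_opt,
              xb_s, yb_s, xb_t, drop_rng) -> LossReport:
        cfg = self.config
        n_s = xb_s.shape[0]
        if xb_t is not None:
            x = np.concatenate([xb_s, xb_t])
            dom = np.r_[np.zeros(n_s, dtype=int), np.ones(xb_t.shape[0], dtype=int)]
        else:
            x = xb_s
            dom = np.zeros(n_s, dtype=int)
        ctx = Context(mode="train", domain_ids=dom, rng=drop_rng)
        feats = nets.forward_generator(x, ctx)
        f_s, f_t = feats[:n_s], feats[n_s:]
        rep = LossReport()

        # ---- discriminator step: minimize H + lambda_L * GP over theta_d
        if xb_t is not None and cfg.lambda_d > 0:
            for _ in range(cfg.disc_steps):
                nets.discriminator.zero_grad()
                logits = nets.discriminator.forward(feats)
                probs = softmax(logits)
                H = L.domain_adversarial_loss(probs, dom)
                donehot = np.eye(2)[dom]
                nets.discriminator.backward((probs - donehot) / len(dom))
                pts = self._gp_points(f_s, f_t, drop_rng)
                gp = nets.discriminator.penalty_param_grads(pts, scale=cfg.lambda_L)
                disc_opt.step()
                rep.H, rep.gradient_penalty = H, gp
                rep.L_disc = L.discriminator_objective(H, gp, cfg.lambda_L)

        # ---- generator/classifier step: minimize L_G over theta_f, theta_c
        nets.generator.zero_grad()
        nets.classifier.zero_grad()
        dfeat = np.zeros_like(feats)

        probs_c = softmax(nets.classifier.forward(f_s, Context(mode="train", rng=drop_rng)))
        rep.L_C = L.classification_loss(probs_c, yb_s)
        donehot_c = np.eye(cfg.n_classes)[yb_s]
        dfeat[:n_s] += nets.classifier.backward((probs_c - donehot_c) / n_s)

        if xb_t is not None and cfg.lambda_d > 0:
            nets.discriminator.zero_grad()      # scratch; disc params step not taken here
            logits = nets.discriminator.forward(feats)
            probs_d = softmax(logits)
            rep.H = L.domain_adversarial_loss(probs_d, dom)
            donehot_d = np.eye(2)[dom]
            # generator minimizes -lambda_d * H
            dfeat += nets.discriminator.backward(
                -cfg.lambda_d * (probs_d - donehot_d) / len(dom)
            )

        if xb_t is not None and cfg.lambda_m > 0:
            bank = cfg.kernel_bank or L.median_heuristic_bank(
                f_s, f_t, cfg.mmd_n_kernels, cfg.mmd_spacing)
            mmd, gs, gt = L.mmd2_feature_grads(
                f_s, f_t, bank, cfg.mmd_cross_coefficient)
            rep.L_MMD = mmd
            dfeat[:n_s] += cfg.lambda_m * gs
            dfeat[n_s:] += cfg.lambda_m * gt

        w_mats = nets.l2_weights()
        rep.l2_term = L.l2_term(w_mats)
        for w, layer_key in zip(w_mats, _dense_layers(nets)):
            layer, key = layer_key
            layer.grads[key] += 2.0 * cfg.lambda_z * w

        nets.generator.backward(dfeat)
        gen_opt.step()

        rep.L_G = L.generator_objective(
            rep.L_C, rep.H if np.isfinite(rep.H) else 0.0,
            rep.L_MMD if np.isfinite(rep.L_MMD) else 0.0,
            rep.l2_term, cfg.lambda_d, cfg.lambda_m, cfg.lambda_z,
        )
        if not np.isfinite(rep.L_G):
            bad = [k for k, v in rep.as_dict().items() if not np.isfinite(v)]
            raise RuntimeError(f"non-finite loss component(s): {bad}")
        return rep

    def _gp_points(self, f_s, f_t, rng) -> np.ndarray:
        if self.config.gp_eval_points == "at_source_target":
            return np.concatenate([f_s, f_t])
        k = min(f_s.shape[0], f_t.shape[0])
        eps = rng.random((k, 1))
        return eps * f_s[:k] + (1.0 - eps) * f_t[:k]

    def _validation_loss(self, nets: TDANNetworks, xs_va, ys_va) -> float:
        ctx = Context(mode="eval", domain_ids=np.zeros(xs_va.shape[0], dtype=int))
        feats = nets.forward_generator(xs_va, ctx)
        probs = nets.forward_classifier(feats)
        return L.classification_loss(probs, ys_va)


def _adam(targets, lr):
    from .nn import Adam
    return Adam(targets, lr=lr)


def _dense_layers(nets: TDANNetworks):
    from .nn import Dense
    out = []
    for seq in (nets.generator, nets.classifier):
        for layer in seq.layers:
            if isinstance(layer, Dense):
                out.append((layer, "weight"))
    return out


@dataclass
class TDANNResults:
    """Trained networks plus training diagnostics."""

    networks: TDANNetworks
    config: AdaptationConfig
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    fit_seconds: float = np.nan

    # ------------------------------------------------------------------
    def adapt(self, target_images) -> None:
        """Recompute target-domain AdaBN statistics from an unlabeled pool.

        Runs the pool through the generator in adapt mode (dropout off) in
        fixed-size chunks, merging chunk statistics exactly.
        """
        xt = _as_network_input(target_images)
        for bn in self.networks.bn_layers():
            bn.reset_adapt()
        chunk = self.config.adapt_chunk
        for start in range(0, xt.shape[0], chunk):
            part = xt[start:start + chunk]
            ctx = Context(mode="adapt", domain_ids=np.ones(part.shape[0], dtype=int))
            self.networks.forward_generator(part, ctx)

    def predict_proba(self, images, domain: int = 1) -> np.ndarray:
        x = _as_network_input(images)
        ctx = Context(mode="eval", domain_ids=np.full(x.shape[0], domain, dtype=int))
        feats = self.networks.forward_generator(x, ctx)
        return self.networks.forward_classifier(feats)

    def predict(self, images, domain: int = 1) -> np.ndarray:
        return self.predict_proba(images, domain=domain).argmax(axis=1)

    def evaluate(self, images, labels, domain: int = 1) -> Metrics:
        """Accuracy, per-class accuracy and confusion matrix; no updates."""
        pred = self.predict(images, domain=domain)
        return Metrics.from_predictions(
            np.asarray(labels, dtype=int), pred, self.config.n_classes,
            domain=domain, seed=self.config.seed, config_hash=self.config.hash(),
        )

    def summary(self) -> str:
        cfg = self.config
        last = self.history.iloc[-1] if len(self.history) else {}
        lines = [
            "Two-level domain adaptation results",
            "=" * 51,
            f"preset: {cfg.preset:>14}    feature dim: {self.networks.spec.feature_dim}",
            f"lambda_d={cfg.lambda_d}  lambda_m={cfg.lambda_m}  "
            f"lambda_z={cfg.lambda_z}  lambda_L={cfg.lambda_L}",
            f"batch: {cfg.batch_source}+{cfg.batch_target}  lr={cfg.learning_rate}  "
            f"seed={cfg.seed}  config={cfg.hash()}",
            f"epochs run: {len(self.history)}  best epoch: {self.best_epoch}  "
            f"best val loss: {self.best_val_loss:.4f}",
        ]
        if len(self.history):
            lines.append(
                "final losses: "
                f"L_C={last['L_C']:.4f}  L_MMD={last['L_MMD']:.4f}  "
                f"H={last['H']:.4f}  L_G={last['L_G']:.4f}"
            )
        lines.append("=" * 51)
        return "\n".join(lines)


@dataclass
class LOOCVResults:
    """Per-fold metrics of leave-one-domain-out cross-validation."""

    folds: list[Metrics]
    fold_domains: list[int]
    config: AdaptationConfig

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([m.accuracy for m in self.folds])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=0))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "target_domain": self.fold_domains,
            "accuracy": self.accuracies,
            "n_test": [m.n for m in self.folds],
        })

    def summary(self) -> str:
        frame = self.as_frame().to_string(index=False)
        return (
            f"Leave-one-domain-out ({len(self.folds)} folds)\n{frame}\n"
            f"mean = {self.mean_accuracy:.4f}  std = {self.std_accuracy:.4f}"
        )


def leave_one_domain_out(
    images,
    labels=None,
    domains=None,
    config: AdaptationConfig = AdaptationConfig(),
    verbose: bool = False,
) -> LOOCVResults:
    """Each domain serves once as the unlabeled target/test set.

    `images` may be a TopoImages (labels/domains taken from it) or an array
    with explicit `labels` and `domains`.  Within each fold the remaining
    domains form the merged labeled source; 15% of each source domain is
    held out for validation (stratified by class).  Test labels are used for
    scoring only, after training.
    """
    if isinstance(images, TopoImages):
        labels = images.labels if labels is None else np.asarray(labels, dtype=int)
        domains = images.domains if domains is None else np.asarray(domains, dtype=int)
        x = images.to_network_input()
    else:
        if labels is None or domains is None:
            raise ValueError("array input requires explicit labels and domains")
        x = _as_network_input(images)
        labels = np.asarray(labels, dtype=int)
        domains = np.asarray(domains, dtype=int)
    uniq = np.unique(domains)
    if len(uniq) < 2:
        raise ValueError("leave-one-domain-out needs at least 2 domains")
    folds, fold_domains = [], []
    for d in uniq:
        test = domains == d
        model = TDANN(
            x[~test], labels[~test],
            x[test] if config.use_target else None,
            config, source_domains=domains[~test],
        )
        res = model.fit(verbose=verbose)
        if config.use_target:
            res.adapt(x[test])
            metrics = res.evaluate(x[test], labels[test], domain=1)
        else:
            metrics = res.evaluate(x[test], labels[test], domain=0)
        metrics.domain = int(d)
        folds.append(metrics)
        fold_domains.append(int(d))
        if verbose:
            print(f"fold target={d}: accuracy {metrics.accuracy:.4f}")
    return LOOCVResults(folds=folds, fold_domains=fold_domains, config=config)
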