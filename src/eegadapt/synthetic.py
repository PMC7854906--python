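"""Synthetic labeled, domain-structured multichannel EEG.

Each trial is a sum over the five canonical bands of band-limited Gaussian
noise whose per-channel standard deviation is base_sd multiplied by the
class's (band, region) multiplier, plus a domain-specific constant offset and
domain-scaled broadband noise; a per-channel domain gain is applied last:

    x_c(t) = gain_d(c) * ( sum_b  n_b,c(t) * base_sd * mult_class(b, region(c))
                           + offset_d + noise_sd_d * w_c(t) )

Band-limited noise is synthesized with the same zero-phase Butterworth bank
the feature extractor uses, so generator and extractor agree exactly on band
definitions.  Classes therefore differ in per-band, per-region power (the
signal the classifier must learn), while domains differ by multiplicative
gain and additive noise (the shift the adaptation must remove).  Per-channel
gain multiplies every band equally, so class-conditional band-power *ratios*
are domain-invariant even though absolute feature distributions shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import BandSpec, CANONICAL_BANDS, EpochedEEG, _design_band_sos, segment_windows
from .montage import Montage, packaged_montage
from scipy import signal as sps

__all__ = [
    "ClassEffect",
    "DomainEffect",
    "SyntheticSpec",
    "default_region_map",
    "generate",
    "generate_epochs",
    "benchmark_fixture",
]

#: Region labels used by the default region map.
REGIONS = ("frontal", "central", "temporal", "parietal", "occipital")


def default_region_map(channel_names: list[str]) -> dict[str, str]:
    """Assign every channel to exactly one scalp region by its 10-20 name."""
    out: dict[str, str] = {}
    for name in channel_names:
        key = name.upper()
        if key.startswith(("FP", "AF")) or (key.startswith("F") and not key.startswith("FC") and not key.startswith("FT")):
            out[name] = "frontal"
        elif key.startswith(("FC", "C")) and not key.startswith("CP"):
            out[name] = "central"
        elif key.startswith(("FT", "T", "TP")):
            out[name] = "temporal"
        elif key.startswith(("CP", "P")) and not key.startswith("PO"):
            out[name] = "parietal"
        else:  # PO*, O*, CB*
            out[name] = "occipital"
    return out


@dataclass(frozen=True)
class ClassEffect:
    """Per-band, per-region amplitude multipliers for one emotion class.

    `multipliers` maps (band_name, region) -> multiplier; omitted pairs
    default to 1.  All multipliers must be positive.
    """

    name: str
    multipliers: dict = field(default_factory=dict)

    def get(self, band: str, region: str) -> float:
        m = float(self.multipliers.get((band, region), 1.0))
        if m <= 0:
            raise ValueError(f"class {self.name!r}: multiplier for ({band}, {region}) must be > 0")
        return m


@dataclass(frozen=True)
class DomainEffect:
    """Per-domain signal drift: per-region gain, constant offset, broadband
    noise standard-deviation multiplier."""

    name: str
    gain: dict = field(default_factory=dict)   # region -> gain (default 1)
    offset: float = 0.0
    noise_sd: float = 0.0

    def gain_for(self, region: str) -> float:
        g = float(self.gain.get(region, 1.0))
        if g <= 0:
            raise ValueError(f"domain {self.name!r}: gain for {region} must be > 0")
        return g


@dataclass
class SyntheticSpec:
    """Full description of a synthetic data set."""

    classes: list[ClassEffect]
    domains: list[DomainEffect]
    n_channels: int = 61
    fs: float = 128.0
    duration_s: float = 50.0
    n_trials_per_class: int = 6          # per class per domain
    base_sd: float = 1.0
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.classes or not self.domains:
            raise ValueError("need at least one class and one domain")


def _band_noise(rng: np.random.Generator, sos: np.ndarray, n_ch: int, n_samp: int) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise, [n_ch, n_samp]."""
    white = rng.standard_normal((n_ch, n_samp))
    banded = sps.sosfiltfilt(sos, white, axis=-1)
    sd = banded.std(axis=-1, keepdims=True)
    return banded / np.where(sd > 0, sd, 1.0)


def generate(spec: SyntheticSpec, montage: Montage | None = None):
    """Generate raw trials.

    Returns ``(trials, labels, domains, montage)`` where `trials` is
    [n_trials, n_channels, n_samples].  Trials are mutually independent given
    the seed; the montage is the packaged 61-channel layout truncated to
    `n_channels`.
    """
    if montage is None:
        montage = packaged_montage()
    if spec.n_channels > montage.n_channels:
        raise ValueError(
            f"n_channels={spec.n_channels} exceeds montage size {montage.n_channels}"
        )
    montage = montage.subset(montage.names[: spec.n_channels])
    region_map = default_region_map(montage.names)
    regions = np.array([region_map[n] for n in montage.names])
    n_samp = int(round(spec.duration_s * spec.fs))
    sos_bank = [_design_band_sos(b, spec.fs) for b in spec.bands]

    rng = np.random.default_rng(spec.seed)
    trials, labels, domains = [], [], []
    for d, dom in enumerate(spec.domains):
        gain = np.array([dom.gain_for(r) for r in regions])[:, None]
        for c, cls in enumerate(spec.classes):
            # [n_ch, 1] sd multiplier per band
            mults = [
                np.array([cls.get(b.name, r) for r in regions])[:, None]
                for b in spec.bands
            ]
            for _ in range(spec.n_trials_per_class):
                x = np.zeros((spec.n_channels, n_samp))
                for sos, mult in zip(sos_bank, mults):
                    x += _band_noise(rng, sos, spec.n_channels, n_samp) * spec.base_sd * mult
                x += dom.offset
                if dom.noise_sd > 0:
                    x += dom.noise_sd * rng.standard_normal(x.shape)
                trials.append(gain * x)
                labels.append(c)
                domains.append(d)
    return (
        np.stack(trials),
        np.asarray(labels, dtype=int),
        np.asarray(domains, dtype=int),
        montage,
    )


def generate_epochs(
    spec: SyntheticSpec,
    window_s: float = 2.0,
    overlap_frac: float = 0.5,
    montage: Montage | None = None,
) -> tuple[EpochedEEG, Montage]:
    """Generate trials and window them into one `EpochedEEG`."""
    trials, labels, domains, montage = generate(spec, montage=montage)
    parts = [
        segment_windows(trial, spec.fs, window_s, overlap_frac,
                        label=int(lab), domain=int(dom),
                        channel_names=montage.names)
        for trial, lab, dom in zip(trials, labels, domains)
    ]
    data = np.concatenate([p.data for p in parts])
    return (
        EpochedEEG(
            data=data,
            fs=spec.fs,
            labels=np.concatenate([p.labels for p in parts]),
            domains=np.concatenate([p.domains for p in parts]),
            channel_names=montage.names,
        ),
        montage,
    )


def benchmark_fixture(difficulty: str = "easy", seed: int = 0) -> SyntheticSpec:
    """The packaged 2-class x 3-domain benchmark.

    Classes differ in where alpha power concentrates (frontal vs parietal);
    domains differ by region-dependent gains and broadband noise level, so a
    source-only classifier trained on two domains degrades on the held-out
    third while per-domain normalization plus distribution alignment can
    recover the class structure (the gain shift moves DE features additively
    but leaves the class contrast direction intact).

    Each domain holds 12 trials (6 per class) of 50 s, so 2-s windows with
    50% overlap give 49 windows per trial and 588 per domain.
    """
    if difficulty not in ("easy", "hard"):
        raise ValueError(f"unknown difficulty {difficulty!r}")
    if difficulty == "easy":
        m = 2.2
        gains = [
            {"temporal": 1.6},
            {"frontal": 2.6, "parietal": 0.4, "occipital": 1.8, "central": 0.7},
            {"frontal": 0.35, "parietal": 2.8, "central": 1.9, "occipital": 0.5},
        ]
        noise = [0.3, 0.7, 1.1]
    else:
        m = 1.6
        gains = [
            {"temporal": 1.6},
            {"frontal": 3.0, "parietal": 0.35, "occipital": 2.0, "central": 0.6},
            {"frontal": 0.3, "parietal": 3.2, "central": 2.1, "occipital": 0.45},
        ]
        noise = [0.5, 1.0, 1.5]
    classes = [
        ClassEffect("alpha_frontal", {("alpha", "frontal"): m}),
        ClassEffect("alpha_parietal", {("alpha", "parietal"): m}),
    ]
    domains = [
        DomainEffect(f"day{i}", gain=g, offset=0.1 * i, noise_sd=n)
        for i, (g, n) in enumerate(zip(gains, noise))
    ]
    return SyntheticSpec(
        classes=classes,
        domains=domains,
        n_channels=61,
        fs=128.0,
        duration_s=50.0,
        n_trials_per_class=6,
        seed=seed,
    )
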