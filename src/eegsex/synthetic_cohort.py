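"""Synthetic EEG-like cohort with a controllable sex-linked regularity gap.

No public recordings accompany the study design this package implements,
so every pipeline stage is exercised on a generated cohort.  Each channel
of a subject is a regularity mixture

    x_c(t) = rho * osc_c(t) + (1 - rho) * n_c(t)

of a unit-variance alpha-band sinusoid (subject-specific frequency,
random phase per channel) and unit-variance noise (pink by default,
spectrally shaped 1/f).  The mixing weight rho controls signal
regularity and hence entropy: higher rho -> more regular -> lower
entropy.  Sex enters only through rho: males get ``rho0 + delta`` and
females ``rho0 - delta`` (plus subject- and channel-level Gaussian
variation), reproducing the observed direction that female epochs carry
higher entropy than male epochs.  With ``delta = 0`` the sexes are
statistically exchangeable — the no-signal null.

The generator makes no claim of physiological realism (no artifacts,
volume conduction or channel covariance); it is the simplest process
whose entropy ordering is controllable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError
from .signal_io import CHANNELS_1020_30, Recording

log = logging.getLogger(__name__)


@dataclass
class CohortConfig:
    """Cohort geometry and signal parameters.

    Defaults reproduce the study conditions: 13 male and 15 female
    subjects, 30 channels at 1000 Hz, 300 s retained per subject, 1-s
    epochs (300 epochs/subject, 8400 total).  ``base_regularity`` (rho0)
    and ``effect`` (delta) set the sex-linked regularity gap:
    rho_male = rho0 + delta, rho_female = rho0 - delta, clipped to
    (0.01, 0.99).  ``subject_sd`` (tau) and ``channel_jitter`` add
    between-subject and between-channel regularity variation.
    """

    n_male: int = 13
    n_female: int = 15
    n_channels: int = 30
    fs: float = 1000.0
    duration_s: float = 300.0
    epoch_len_s: float = 1.0
    base_regularity: float = 0.5
    effect: float = 0.3
    subject_sd: float = 0.05
    channel_jitter: float = 0.02
    osc_freq_range: tuple[float, float] = (8.0, 12.0)
    noise_spectrum: str = "pink"
    seed: int = 0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_male < 1 or self.n_female < 1 or self.n_channels < 1:
            raise ValidationError("subject and channel counts must be positive")
        if not (0 < self.base_regularity < 1):
            raise ValidationError("base_regularity must lie in (0, 1)")
        if self.effect < 0:
            raise ValidationError("effect size must be >= 0")
        if self.subject_sd < 0 or self.channel_jitter < 0:
            raise ValidationError("regularity SDs must be >= 0")
        if self.noise_spectrum not in ("white", "pink"):
            raise ValidationError("noise_spectrum must be 'white' or 'pink'")
        lo, hi = self.osc_freq_range
        if not 0 < lo <= hi < self.fs / 2:
            raise ValidationError("osc_freq_range must lie inside (0, fs/2)")
        if not self.channel_names:
            if self.n_channels <= len(CHANNELS_1020_30):
                self.channel_names = CHANNELS_1020_30[: self.n_channels]
            else:
                self.channel_names = [f"CH{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValidationError("channel_names length != n_channels")

    def rho_for(self, sex: str) -> float:
        delta = self.effect if sex == "male" else -self.effect
        return float(np.clip(self.base_regularity + delta, 0.01, 0.99))

    @classmethod
    def fixture(cls, **overrides) -> "CohortConfig":
        """Miniature cohort (2M/2F, 3 channels, 20 s at 250 Hz) for fast tests."""
        base = dict(
            n_male=2, n_female=2, n_channels=3, fs=250.0, duration_s=20.0
        )
        base.update(overrides)
        return cls(**base)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise by spectral amplitude shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5  # power ~ 1/f; DC removed
    x = np.fft.irfft(spec * scale, n)
    return (x - x.mean()) / x.std()


def generate_subject(
    sex: str, cfg: CohortConfig, subject_seed, subject_id: str | None = None
) -> Recording:
    """Generate one subject's multichannel recording.

    Deterministic given ``subject_seed`` (an int or ``SeedSequence``).
    Channel c mixes a subject-frequency sinusoid with noise at weight
    ``rho = clip(rho_sex + N(0, tau) + N(0, jitter_c), 0.01, 0.99)``.
    """
    if sex not in ("male", "female"):
        raise ValidationError(f"sex must be 'male' or 'female', got {sex!r}")
    rng = np.random.default_rng(subject_seed)
    n = round(cfg.duration_s * cfg.fs)
    t = np.arange(n) / cfg.fs
    f_osc = rng.uniform(*cfg.osc_freq_range)
    subject_shift = rng.normal(0.0, cfg.subject_sd) if cfg.subject_sd else 0.0
    rho_sex = cfg.rho_for(sex)
    data = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        jitter = rng.normal(0.0, cfg.channel_jitter) if cfg.channel_jitter else 0.0
        rho = float(np.clip(rho_sex + subject_shift + jitter, 0.01, 0.99))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        osc = np.sqrt(2.0) * np.sin(2.0 * np.pi * f_osc * t + phase)
        if cfg.noise_spectrum == "pink":
            noise = _pink_noise(n, rng)
        else:
            noise = rng.standard_normal(n)
        data[c] = rho * osc + (1.0 - rho) * noise
    return Recording(
        subject_id=subject_id or f"{sex[0].upper()}{rng.integers(1e6):06d}",
        sex=sex,
        fs=cfg.fs,
        channels=list(cfg.channel_names),
        data=data,
    )


def generate_cohort(cfg: CohortConfig | None = None) -> list[Recording]:
    """Generate the full cohort (males first, then females).

    Subject seeds are spawned from the master seed via ``SeedSequence``
    so cohorts are bit-reproducible and subjects independent.
    """
    cfg = cfg or CohortConfig()
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_male + cfg.n_female)
    recs = []
    for i in range(cfg.n_male):
        recs.append(generate_subject("male", cfg, children[i], subject_id=f"M{i + 1:02d}"))
    for i in range(cfg.n_female):
        recs.append(generate_subject(
            "female", cfg, children[cfg.n_male + i], subject_id=f"F{i + 1:02d}"
        ))
    log.info(
        "generated cohort: %d male + %d female subjects, %d channels, %.0f s at %g Hz",
        cfg.n_male, cfg.n_female, cfg.n_channels, cfg.duration_s, cfg.fs,
    )
    return recs


def null_config(cfg: CohortConfig | None = None) -> CohortConfig:
    """The matching no-signal configuration (delta = 0, same everything else)."""
    cfg = cfg or CohortConfig()
    return replace(cfg, effect=0.0)
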