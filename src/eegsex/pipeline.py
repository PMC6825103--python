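"""End-to-end convenience chain: filter -> retain -> epoch -> features.

Thin composition of the signal_io and entropy_features operations used
by the CLI, the test suite and the reproduction script.
"""

from __future__ import annotations

import logging

from .entropy_features import (
    EntropyConfig,
    FeatureMatrix,
    MEASURES,
    extract_features,
    minmax_normalize,
)
from .signal_io import (
    EpochSet,
    Recording,
    apply_bandpass,
    apply_notch,
    retain_final_segment,
    segment_epochs,
)

log = logging.getLogger(__name__)


def preprocess_recording(
    rec: Recording,
    notch_freq: float | None = 50.0,
    notch_q: float = 30.0,
    band: tuple[float, float] | None = (0.15, 45.0),
    band_order: int = 4,
    retain_s: float | None = 300.0,
) -> Recording:
    """Apply the standard filtering chain and keep the final segment.

    Any stage can be disabled by passing ``None``; ``retain_s`` longer
    than the recording falls back to the full recording with a warning.
    """
    if notch_freq is not None:
        rec = apply_notch(rec, notch_freq, notch_q)
    if band is not None:
        rec = apply_bandpass(rec, band[0], band[1], band_order)
    if retain_s is not None:
        if rec.duration_s >= retain_s:
            rec = retain_final_segment(rec, retain_s)
        else:
            log.warning(
                "recording %s is %.1f s, shorter than retain_s=%.1f s; keeping all",
                rec.subject_id, rec.duration_s, retain_s,
            )
    return rec


def cohort_epochs(
    recordings: list[Recording],
    epoch_len_s: float = 1.0,
    **preprocess_kwargs,
) -> EpochSet:
    """Preprocess and epoch every recording, stacked into one EpochSet."""
    sets = [
        segment_epochs(preprocess_recording(rec, **preprocess_kwargs), epoch_len_s)
        for rec in recordings
    ]
    return EpochSet.concatenate(sets)


def cohort_features(
    recordings: list[Recording],
    entropy_cfg: EntropyConfig | None = None,
    measures: tuple[str, ...] = MEASURES,
    epoch_len_s: float = 1.0,
    normalize: str | None = "per_subject",
    **preprocess_kwargs,
) -> FeatureMatrix:
    """Full chain from raw recordings to a (normalised) feature matrix."""
    epochs = cohort_epochs(recordings, epoch_len_s, **preprocess_kwargs)
    fm = extract_features(epochs, entropy_cfg, measures)
    if normalize is not None:
        fm, _ = minmax_normalize(fm, grouping=normalize)
    return fm
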