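"""Entropy estimators and feature-matrix assembly.

Four regularity/complexity measures are computed per epoch per channel:

* **Approximate entropy (AE)** — Pincus-style ``Phi^m - Phi^{m+1}`` with
  Chebyshev template distance, self-matches included (always finite).
* **Sample entropy (SE)** — Richman–Moorman ``-ln(A/B)`` over template
  pair counts excluding self-matches; undefined (flagged) at zero counts.
* **Fuzzy entropy (FE)** — Chen-style variant with mean-centred templates
  and a continuous membership ``exp(-(d/r)^n)`` instead of a hard
  threshold; always finite for ``r > 0``.
* **Permutation entropy (PE)** — Shannon entropy of the ordinal-pattern
  distribution (Bandt–Pompe), ties broken by order of appearance,
  optionally normalised by ``ln(order!)``.

The tolerance for AE/SE/FE is ``r = r_coeff * SD`` with the population
standard deviation of the individual epoch/channel series (each 1-s
window treated as its own stationary segment).  All logarithms are
natural, so values are in nats (PE in [0, 1] when normalised).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ValidationError
from .signal_io import EpochSet

log = logging.getLogger(__name__)

#: Canonical measure order used for feature-column layout.
MEASURES = ("FE", "SE", "AE", "PE")


@dataclass
class EntropyConfig:
    """Estimator parameters.

    m : embedding dimension for AE/SE/FE (template length).
    r_coeff : tolerance coefficient; r = r_coeff * SD(series).
    fuzzy_n : fuzzy membership exponent n in exp(-d^n / r).
    pe_order : ordinal pattern order (number of points per pattern).
    pe_delay : ordinal pattern delay (samples between points).
    pe_normalized : divide PE by ln(order!) so it lies in [0, 1].
    """

    m: int = 2
    r_coeff: float = 0.25
    fuzzy_n: float = 2.0
    pe_order: int = 4
    pe_delay: int = 1
    pe_normalized: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValidationError(f"embedding dimension m must be >= 1, got {self.m}")
        if not self.r_coeff > 0:
            raise ValidationError("r_coeff must be positive")
        if not self.fuzzy_n > 0:
            raise ValidationError("fuzzy exponent must be positive")
        if self.pe_order < 2:
            raise ValidationError("pe_order must be >= 2")
        if self.pe_delay < 1:
            raise ValidationError("pe_delay must be >= 1")


# ---------------------------------------------------------------------------
# Scalar estimators

def compute_tolerance(x: np.ndarray, r_coeff: float = 0.25) -> float:
    """Similarity tolerance r = r_coeff * population SD of the series."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 samples to compute a tolerance")
    sd = float(x.std())
    if sd == 0.0:
        log.warning("constant series: tolerance r = 0")
    return r_coeff * sd


def _embed(x: np.ndarray, k: int) -> np.ndarray:
    """All length-k templates of x as rows, shape (len(x)-k+1, k)."""
    return sliding_window_view(x, k)


def _cheb(emb: np.ndarray) -> np.ndarray:
    """Full pairwise Chebyshev distance matrix between template rows."""
    return np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=-1)


def _check_series(x: np.ndarray, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_len:
        raise ValidationError(f"series of length {x.size} too short (need >= {min_len})")
    return x


def approximate_entropy(x: np.ndarray, m: int = 2, r: float = 0.0) -> float:
    """Approximate entropy ApEn(m, r) in nats.

    ``Phi^k`` is the mean over templates of the log fraction of templates
    (self included) within Chebyshev distance r; ApEn = Phi^m - Phi^{m+1}.
    """
    x = _check_series(x, m + 2)
    if r < 0:
        raise ValidationError("tolerance r must be >= 0")

    def phi(k: int) -> float:
        d = _cheb(_embed(x, k))
        frac = (d <= r).mean(axis=1)  # self-match keeps frac >= 1/n
        return float(np.log(frac).mean())

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.0) -> float:
    """Sample entropy SampEn(m, r) = -ln(A/B) in nats; NaN when undefined.

    A and B count ordered template pairs (i != j) of length m+1 and m
    within r (Chebyshev, self-matches excluded), both over the same
    N - m template start points.  Zero counts give NaN (no-match flag).
    """
    x = _check_series(x, m + 2)
    if r < 0:
        raise ValidationError("tolerance r must be >= 0")
    n_t = x.size - m  # template count for both lengths
    d_m = _cheb(_embed(x, m)[:n_t])
    d_m1 = _cheb(_embed(x, m + 1))
    b = int((d_m <= r).sum()) - n_t  # drop the diagonal self-matches
    a = int((d_m1 <= r).sum()) - n_t
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def fuzzy_entropy(x: np.ndarray, m: int = 2, r: float = 0.0, n: float = 2.0) -> float:
    """Fuzzy entropy FuzzyEn(m, r, n) in nats.

    Templates are mean-centred; pairwise similarity is the fuzzy
    membership ``exp(-(d/r)^n)`` with Chebyshev d over i != j, and
    FuzzyEn = ln(phi^m) - ln(phi^{m+1}) with phi^k the grand mean
    similarity.  Finite for every r > 0.  Expressing the membership in
    the dimensionless ratio d/r makes the estimate invariant under
    affine transforms of the series when r is tied to the series SD,
    matching the scale behaviour of ApEn/SampEn.
    """
    x = _check_series(x, m + 2)
    if not r > 0:
        raise ValidationError("fuzzy entropy requires tolerance r > 0")
    n_t = x.size - m

    def phi(k: int) -> float:
        emb = _embed(x, k)[:n_t]
        emb = emb - emb.mean(axis=1, keepdims=True)
        sim = np.exp(-((_cheb(emb) / r) ** n))
        # remove the diagonal (similarity 1 with itself)
        return float((sim.sum() - n_t) / (n_t * (n_t - 1)))

    phi_m, phi_m1 = phi(m), phi(m + 1)
    if phi_m == 0.0 or phi_m1 == 0.0:
        # exact-arithmetic FuzzyEn is finite for r > 0, but for extreme
        # d/r every membership underflows to 0; flag as undefined
        log.warning("fuzzy similarity underflow at r=%g; returning NaN", r)
        return float("nan")
    return math.log(phi_m) - math.log(phi_m1)


def permutation_entropy(
    x: np.ndarray, order: int = 4, delay: int = 1, normalized: bool = True
) -> float:
    """Permutation entropy of the ordinal-pattern distribution.

    Patterns are the rank orderings of ``order`` points spaced ``delay``
    samples apart; ties rank by order of appearance (stable sort).  The
    Shannon entropy (nats) of the empirical pattern distribution is
    returned, divided by ``ln(order!)`` when ``normalized``.
    """
    if order < 2:
        raise ValidationError("pe order must be >= 2")
    if delay < 1:
        raise ValidationError("pe delay must be >= 1")
    x = _check_series(x, (order - 1) * delay + 2)
    n_pat = x.size - (order - 1) * delay
    idx = np.arange(n_pat)[:, None] + np.arange(order)[None, :] * delay
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    if math.factorial(order) > n_pat:
        log.warning(
            "order! = %d exceeds the %d available patterns; PE estimate is coarse",
            math.factorial(order), n_pat,
        )
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / math.log(math.factorial(order)) if normalized else h


# ---------------------------------------------------------------------------
# Feature matrix

@dataclass
class FeatureMatrix:
    """Epochs x (channel, measure) entropy features with labels.

    ``feature_names`` are ``"<channel>:<measure>"`` strings laid out
    channel-major then measure (stable order); ``nan_mask`` flags cells
    whose estimate is undefined (sample entropy with zero matches).
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    subject_ids: np.ndarray
    normalized: bool = False
    nan_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.nan_mask is None:
            self.nan_mask = ~np.isfinite(self.values)
        self.nan_mask = np.asarray(self.nan_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D (epochs x features)")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValidationError("feature_names length != n_features")
        if len(self.labels) != len(self.values) or len(self.subject_ids) != len(self.values):
            raise ValidationError("labels/subject_ids length != n_epochs")
        if self.nan_mask.shape != self.values.shape:
            raise ValidationError("nan_mask shape mismatch")
        if self.normalized:
            ok = self.values[~self.nan_mask]
            if ok.size and (ok.min() < -1 - 1e-12 or ok.max() > 1 + 1e-12):
                raise ValidationError("normalized values must lie in [-1, 1]")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> list[str]:
        seen: list[str] = []
        for name in self.feature_names:
            ch = name.rsplit(":", 1)[0]
            if ch not in seen:
                seen.append(ch)
        return seen

    def select_channels(self, channels: list[str]) -> "FeatureMatrix":
        """Subset the feature columns to the given channels (order preserved)."""
        channels = list(channels)
        unknown = set(channels) - set(self.channels)
        if unknown:
            raise ValidationError(f"unknown channels: {sorted(unknown)}")
        cols = [i for i, n in enumerate(self.feature_names)
                if n.rsplit(":", 1)[0] in channels]
        return replace(
            self,
            values=self.values[:, cols],
            feature_names=[self.feature_names[i] for i in cols],
            nan_mask=self.nan_mask[:, cols],
        )

    def select_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            values=self.values[mask],
            labels=self.labels[mask],
            subject_ids=self.subject_ids[mask],
            nan_mask=self.nan_mask[mask],
        )

    def drop_undefined(self) -> "FeatureMatrix":
        """Drop epochs containing any undefined estimate (logged count)."""
        bad = self.nan_mask.any(axis=1)
        if bad.any():
            log.info("dropping %d epochs with undefined entropy estimates", int(bad.sum()))
        return self.select_rows(~bad)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.labels)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, normalized: bool = False) -> "FeatureMatrix":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("subject_id", "label")]
        return cls(
            values=df[names].to_numpy(dtype=float),
            feature_names=names,
            labels=df["label"].to_numpy(),
            subject_ids=df["subject_id"].to_numpy(),
            normalized=normalized,
        )


def _epoch_entropies(
    x: np.ndarray, cfg: EntropyConfig, measures: tuple[str, ...]
) -> dict[str, float]:
    out: dict[str, float] = {}
    if {"FE", "SE", "AE"} & set(measures):
        r = compute_tolerance(x, cfg.r_coeff)
    if "FE" in measures:
        # constant series: centred templates coincide, FuzzyEn = 0 by definition
        out["FE"] = 0.0 if r == 0 else fuzzy_entropy(x, cfg.m, r, cfg.fuzzy_n)
    if "SE" in measures:
        out["SE"] = sample_entropy(x, cfg.m, r)
    if "AE" in measures:
        out["AE"] = approximate_entropy(x, cfg.m, r)
    if "PE" in measures:
        out["PE"] = permutation_entropy(x, cfg.pe_order, cfg.pe_delay, cfg.pe_normalized)
    return out


def extract_features(
    epochs: EpochSet,
    cfg: EntropyConfig | None = None,
    measures: tuple[str, ...] = MEASURES,
) -> FeatureMatrix:
    """Compute entropy features for every (epoch, channel, measure).

    The tolerance for AE/SE/FE is recomputed per epoch per channel as
    ``r_coeff * SD`` of that series.  Columns are channel-major then
    measure, measures in canonical ``("FE", "SE", "AE", "PE")`` order.
    """
    cfg = cfg or EntropyConfig()
    measures = tuple(m for m in MEASURES if m in set(measures))
    if not measures:
        raise ValidationError(f"measures must be a non-empty subset of {MEASURES}")
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValidationError(f"unknown measures: {sorted(unknown)}")
    if len(epochs) == 0:
        raise ValidationError("cannot extract features from an empty EpochSet")

    names = [f"{ch}:{meas}" for ch in epochs.channels for meas in measures]
    values = np.empty((len(epochs), len(names)))
    for e in range(len(epochs)):
        col = 0
        for c in range(epochs.n_channels):
            ent = _epoch_entropies(epochs.epochs[e, c], cfg, measures)
            for meas in measures:
                values[e, col] = ent[meas]
                col += 1
    return FeatureMatrix(
        values=values,
        feature_names=names,
        labels=epochs.labels,
        subject_ids=epochs.subject_ids,
        normalized=False,
    )


def minmax_normalize(
    fm: FeatureMatrix,
    grouping: str = "per_subject",
    fit_stats: pd.DataFrame | None = None,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Min-max scale each feature to [-1, 1].

    ``grouping="per_subject"`` rescales each subject's epochs with that
    subject's own min/max (the protocol applied before cross-validation,
    which leaks no *label* information but does use all of a subject's
    epochs); ``grouping="global"`` uses dataset-wide min/max and supports
    the leakage-safe train/test split: pass the stats returned from the
    training portion as ``fit_stats`` and test values are transformed with
    them and clipped to [-1, 1].

    Returns the normalised matrix and the min/max stats used.
    """
    if fm.normalized:
        raise ValidationError("feature matrix is already normalized")
    if grouping not in ("per_subject", "global"):
        raise ValidationError(f"unknown grouping {grouping!r}")
    if fit_stats is not None and grouping != "global":
        raise ValidationError("fit_stats reuse requires grouping='global'")

    vals = fm.values.copy()
    vals[fm.nan_mask] = np.nan

    def transform(block: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        span = hi - lo
        out = np.zeros_like(block)
        ok = span > 0
        out[:, ok] = 2.0 * (block[:, ok] - lo[ok]) / span[ok] - 1.0
        return out

    if grouping == "global":
        if fit_stats is not None:
            lo = fit_stats["min"].to_numpy()
            hi = fit_stats["max"].to_numpy()
        else:
            lo = np.nanmin(vals, axis=0)
            hi = np.nanmax(vals, axis=0)
        new = np.clip(transform(vals, lo, hi), -1.0, 1.0)
        stats = pd.DataFrame({"min": lo, "max": hi}, index=fm.feature_names)
    else:
        new = np.empty_like(vals)
        rows = []
        for sid in pd.unique(fm.subject_ids):
            sel = fm.subject_ids == sid
            lo = np.nanmin(vals[sel], axis=0)
            hi = np.nanmax(vals[sel], axis=0)
            new[sel] = transform(vals[sel], lo, hi)
            rows.append(pd.DataFrame(
                {"subject_id": sid, "feature": fm.feature_names, "min": lo, "max": hi}
            ))
        stats = pd.concat(rows, ignore_index=True)

    new[fm.nan_mask] = np.nan
    out = replace(fm, values=new, normalized=True, nan_mask=fm.nan_mask.copy())
    return out, stats
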