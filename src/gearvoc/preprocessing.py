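"""Per-channel cleaning of raw sensor series and tensor assembly.

Order of operations per channel: numeric coercion, windowed imputation of
missing values, interquartile-range outlier treatment (flagged values are
re-imputed), then z-score standardization.  A binary mask records every cell
that was filled in at either stage.

Windowed imputation rule: for a missing index, take up to ``gamma`` nearest
previous and up to ``omega`` nearest subsequent *originally valid*
observations.  With both windows present, compare the window means mu_prev
and mu_next through the relative difference

    delta = |mu_prev - mu_next| / max(mu_prev, mu_next, eps);

if delta <= tau the windows agree and the imputed value is their
length-weighted mean, otherwise the series is locally non-stationary and the
value is linearly interpolated (on the index axis) between the last previous
and first subsequent valid observation.  One-sided windows use the available
mean; a series with no valid observation at all falls back to 0, which is
neutral after standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import DataTensor, GearRecording

__all__ = [
    "ImputationParams",
    "impute_series",
    "iqr_bounds",
    "treat_outliers",
    "standardize",
    "center",
    "preprocess_recording",
    "pooled_channel_scale",
    "assemble_tensor",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationParams:
    """Tunable constants of the cleaning stage.

    gamma/omega: previous/subsequent window sizes (observations); tau:
    relative tolerance deciding between window averaging and interpolation;
    eps: guard against division by zero; alpha: IQR sensitivity factor.
    """

    gamma: int = 10
    omega: int = 10
    tau: float = 0.5
    eps: float = 1e-12
    alpha: float = 1.5
    fallback: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma < 1 or self.omega < 1:
            raise ValueError("window sizes gamma and omega must be positive")
        if self.tau <= 0 or self.eps <= 0 or self.alpha < 0:
            raise ValueError("tau and eps must be positive, alpha nonnegative")


def impute_series(
    series: np.ndarray, params: ImputationParams = ImputationParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing entries of a 1-D series; return (filled, imputed-mask).

    Donor windows contain only originally valid observations — imputed values
    are never recycled as donors.  Observed values are never altered.
    """
    x = np.asarray(series, dtype=float).copy()
    n = x.size
    if n < 1:
        raise ValueError("series must have at least one element")
    valid = ~np.isnan(x)
    mask = np.zeros(n, dtype=np.int8)
    if valid.all():
        return x, mask
    original = x.copy()
    valid_idx = np.flatnonzero(valid)
    if valid_idx.size == 0:
        logger.warning("series has no valid observations; using fallback value")
        x[:] = params.fallback
        mask[:] = 1
        return x, mask

    for i in np.flatnonzero(~valid):
        pos = np.searchsorted(valid_idx, i)
        prev_idx = valid_idx[max(0, pos - params.gamma) : pos]
        next_idx = valid_idx[pos : pos + params.omega]
        prev_vals = original[prev_idx]
        next_vals = original[next_idx]
        if prev_vals.size and next_vals.size:
            mu_prev = prev_vals.mean()
            mu_next = next_vals.mean()
            delta = abs(mu_prev - mu_next) / max(mu_prev, mu_next, params.eps)
            if delta <= params.tau:
                w_prev, w_next = prev_vals.size, next_vals.size
                x[i] = (w_prev * mu_prev + w_next * mu_next) / (w_prev + w_next)
            else:
                i0, i1 = prev_idx[-1], next_idx[0]
                frac = (i - i0) / (i1 - i0)
                x[i] = original[i0] + frac * (original[i1] - original[i0])
        elif prev_vals.size:
            x[i] = prev_vals.mean()
        else:
            x[i] = next_vals.mean()
        mask[i] = 1
    return x, mask


def iqr_bounds(series: np.ndarray, alpha: float = 1.5) -> tuple[float, float]:
    """Tukey-style interval (Q1 - alpha*IQR, Q3 + alpha*IQR) on valid values.

    Quartiles use linear interpolation between order statistics.
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("cannot compute IQR bounds of an all-missing series")
    q1, q3 = np.percentile(x, [25.0, 75.0])
    iqr = q3 - q1
    return float(q1 - alpha * iqr), float(q3 + alpha * iqr)


def treat_outliers(
    series: np.ndarray, params: ImputationParams = ImputationParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Replace values strictly outside the IQR interval by their windowed
    imputation; return (treated, treated-mask).

    Bounds are computed once on the input series; flagging is strict
    (value < lower or value > upper), so a zero-IQR series flags nothing.
    """
    x = np.asarray(series, dtype=float).copy()
    lower, upper = iqr_bounds(x, params.alpha)
    flagged = (~np.isnan(x)) & ((x < lower) | (x > upper))
    if not flagged.any():
        return x, np.zeros(x.size, dtype=np.int8)
    x[flagged] = np.nan
    filled, _ = impute_series(x, params)
    mask = np.zeros(x.size, dtype=np.int8)
    mask[flagged] = 1
    return filled, mask


def standardize(series: np.ndarray) -> np.ndarray:
    """Z-score a complete series (population standard deviation); a constant
    series maps to all zeros."""
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def center(series: np.ndarray) -> np.ndarray:
    """Remove the series mean (baseline) without touching its scale."""
    x = np.asarray(series, dtype=float)
    return x - x.mean()


def preprocess_recording(
    recording: GearRecording,
    params: ImputationParams = ImputationParams(),
    scale: str = "standardize",
) -> GearRecording:
    """Clean every channel of a recording: impute, outlier-treat, then scale.

    ``scale='standardize'`` z-scores each channel within the recording.
    ``scale='center'`` removes only the per-channel mean: within-recording
    z-scoring equalizes every channel's variance and therefore erases the
    gear-to-gear amplitude differences the impact statistic quantifies, so
    the tensor pipeline centers here and defers scaling to
    :func:`pooled_channel_scale`, which divides by the across-recording
    channel standard deviation instead.

    The returned recording is complete (no NaN) and carries the merged 0/1
    mask of imputed-or-treated cells.
    """
    if scale not in ("standardize", "center"):
        raise ValueError("scale must be 'standardize' or 'center'")
    values = np.empty_like(recording.values)
    mask = np.zeros_like(recording.values, dtype=np.int8)
    for j in range(recording.n_channels):
        col = recording.values[:, j]
        if np.all(np.isnan(col)):
            logger.warning(
                "channel %s of %s rep %s has no valid observations",
                recording.channels[j], recording.gear, recording.replicate,
            )
            filled = np.full(col.shape, params.fallback)
            m_imp = np.ones(col.size, dtype=np.int8)
            m_out = np.zeros(col.size, dtype=np.int8)
        else:
            filled, m_imp = impute_series(col, params)
            filled, m_out = treat_outliers(filled, params)
        values[:, j] = standardize(filled) if scale == "standardize" else center(filled)
        mask[:, j] = np.maximum(m_imp, m_out)
    return GearRecording(
        gear=recording.gear,
        replicate=recording.replicate,
        times=recording.times.copy(),
        values=values,
        channels=list(recording.channels),
        imputed_mask=mask,
        injected_missing=recording.injected_missing,
        injected_outliers=recording.injected_outliers,
    )


def pooled_channel_scale(
    recordings: list[GearRecording],
) -> tuple[list[GearRecording], np.ndarray]:
    """Divide every channel by its standard deviation pooled across all
    recordings (time instances stacked over gears and replicates).

    Applied after per-recording centering this puts every sensor variable on
    a comparable unit without equalizing the per-gear signal amplitude, so
    gears that perturb the volatile profile more strongly retain larger
    tensor entries.  Returns the rescaled recordings and the scale vector.
    """
    if not recordings:
        raise ValueError("no recordings to scale")
    channels = recordings[0].channels
    for rec in recordings:
        if rec.channels != channels:
            raise ValueError("recordings have inconsistent channel lists")
        if np.isnan(rec.values).any():
            raise ValueError("impute recordings before pooled scaling")
    pooled = np.vstack([rec.values for rec in recordings])
    scale = pooled.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    rescaled = [
        GearRecording(
            gear=rec.gear,
            replicate=rec.replicate,
            times=rec.times.copy(),
            values=rec.values / scale,
            channels=list(rec.channels),
            imputed_mask=rec.imputed_mask,
            injected_missing=rec.injected_missing,
            injected_outliers=rec.injected_outliers,
        )
        for rec in recordings
    ]
    return rescaled, scale


def assemble_tensor(
    recordings: list[GearRecording],
    policy: str = "mean",
    gear_order: list[str] | None = None,
) -> DataTensor:
    """Stack preprocessed recordings into the three-way tensor X (I x J x K).

    ``policy='mean'`` averages replicates elementwise per gear;
    ``policy='single'`` requires exactly one replicate per gear.  The gear
    axis follows ``gear_order`` when given, otherwise order of first
    appearance.
    """
    if not recordings:
        raise ValueError("no recordings to assemble")
    if policy not in ("mean", "single"):
        raise ValueError(f"unknown replicate policy {policy!r}")
    ref = recordings[0]
    for rec in recordings:
        if rec.channels != ref.channels:
            raise ValueError(
                f"channel mismatch between {ref.gear} and {rec.gear} recordings"
            )
        if rec.n_time != ref.n_time:
            raise ValueError("recordings have inconsistent time lengths")
        if np.isnan(rec.values).any():
            raise ValueError(
                f"recording {rec.gear} rep {rec.replicate} still has missing "
                "values; preprocess before assembly"
            )
    if gear_order is None:
        gear_order = list(dict.fromkeys(rec.gear for rec in recordings))
    by_gear: dict[str, list[GearRecording]] = {g: [] for g in gear_order}
    for rec in recordings:
        if rec.gear not in by_gear:
            raise ValueError(f"recording gear {rec.gear!r} not in gear_order")
        by_gear[rec.gear].append(rec)
    slices = []
    for gear in gear_order:
        group = by_gear[gear]
        if not group:
            raise ValueError(f"gear {gear!r} has no recordings")
        if policy == "single":
            if len(group) != 1:
                raise ValueError(
                    f"policy 'single' needs exactly one replicate per gear; "
                    f"{gear!r} has {len(group)}"
                )
            slices.append(group[0].values)
        else:
            slices.append(np.mean([rec.values for rec in group], axis=0))
    values = np.stack(slices, axis=2)
    return DataTensor(
        values=values,
        time_labels=ref.times,
        channel_labels=list(ref.channels),
        gear_labels=list(gear_order),
    )
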