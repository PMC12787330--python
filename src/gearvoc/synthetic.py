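"""Synthetic E-nose study generator.

The sensor recordings behind the study are not publicly deposited, so this
module generates labelled recordings with *known* low-rank latent structure:
smooth temporal release kinetics (time mode), sensor-selective channel
patterns (sensor mode), and gear loadings calibrated so that the weighted
L2-norm impact of each gear — computed by the same formula as the estimator —
lands on the configured per-gear targets.

Generative model.  The clean I x J slice of gear k (replicate aside) is the
canonical polyadic (CP) form

    X_k = sum_r  a_r  (b_r * c_kr)^T ,

with nonnegative temporal curves a_r, nonnegative channel patterns b_r and a
gear loading row c_k.  Replicate variation is multiplicative Gaussian jitter
on the loading row; measurement noise is i.i.d. additive Gaussian; missing
cells are MCAR; outlier spikes multiply the stored value.

Calibration.  The analysis pipeline centers every channel within a recording
and scales it by the pooled (across-gear) channel standard deviation, so the
estimator sees the *centered, pooled-scaled* tensor.  Both operations map a
CP tensor to another CP tensor with known factors (centering re-expresses
the temporal mode through centered curves; pooled scaling rescales the
channel mode), so the ground-truth impacts on the analysis scale are exact
closed-form quantities.  Gear loading rows are iteratively rescaled until
those analysis-scale impacts equal ``calibration * impact_targets``, where
the common calibration constant reflects the (arbitrary) unit of the sensor
scale; relative differences between gears — the severity scale — are
realized exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import CHANNEL_NAMES, DEFAULT_GEAR_LABELS, GearRecording
from .impact import weighted_loading_norms

__all__ = [
    "DEFAULT_IMPACT_TARGETS",
    "SimulationConfig",
    "SimulationTruth",
    "generate_temporal_profiles",
    "generate_channel_factors",
    "synthesize_dataset",
]

logger = logging.getLogger(__name__)

# Default per-gear target impact magnitudes (arbitrary units).  The values
# reproduce the longline-lowest / aquaculture-highest severity hierarchy;
# only relative differences are meaningful.
DEFAULT_IMPACT_TARGETS: dict[str, float] = {
    "Longline": 164.0,
    "Hook and line": 166.0,
    "Gillnet (two panels)": 193.0,
    "Gillnet (single panel)": 204.0,
    "Gillnet (three panels)": 209.0,
    "Trawl": 223.0,
    "Purse seine": 226.0,
    "Aquaculture": 247.0,
}

#: sampling period of the sensor loop, minutes (2600 instances ~ 36 h)
SAMPLE_PERIOD_MIN = 0.65


@dataclass
class SimulationConfig:
    """Study design for one synthetic dataset.

    Defaults mirror the real acquisition campaign: 2600 time instances per
    recording at 0.65 min sampling, 35 sensor variables, 8 acquisition
    methods, 10 biological replicates per method.  ``noise_sd`` is relative
    to the clean signal, whose average channel standard deviation is pinned
    to 1.
    """

    n_time: int = 2600
    n_channels: int = 35
    gear_labels: list[str] = field(default_factory=lambda: list(DEFAULT_GEAR_LABELS))
    n_replicates: int = 10
    true_rank: int = 4
    impact_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IMPACT_TARGETS)
    )
    noise_sd: float = 0.05
    missing_rate: float = 0.01
    outlier_rate: float = 0.005
    outlier_scale: float = 5.0
    replicate_jitter_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_time < 2 or self.n_channels < 1:
            raise ValueError("n_time must be >= 2 and n_channels >= 1")
        if self.n_replicates < 1 or self.true_rank < 1:
            raise ValueError("n_replicates and true_rank must be positive")
        if len(self.gear_labels) < 2:
            raise ValueError("at least two gear classes are required")
        if len(set(self.gear_labels)) != len(self.gear_labels):
            raise ValueError("gear_labels must be unique")
        missing = [g for g in self.gear_labels if g not in self.impact_targets]
        if missing:
            raise ValueError(f"impact_targets missing gears: {missing}")
        extra = [g for g in self.impact_targets if g not in self.gear_labels]
        if extra:
            raise ValueError(f"impact_targets has unknown gears: {extra}")
        if any(v <= 0 for v in self.impact_targets.values()):
            raise ValueError("impact targets must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 <= self.missing_rate < 1 and 0 <= self.outlier_rate < 1):
            raise ValueError("missing_rate and outlier_rate must lie in [0, 1)")
        if self.missing_rate + self.outlier_rate >= 1:
            raise ValueError("missing_rate + outlier_rate must be < 1")
        if self.outlier_rate > 0 and self.outlier_scale <= 1:
            raise ValueError("outlier_scale must exceed 1")
        if self.replicate_jitter_sd < 0:
            raise ValueError("replicate_jitter_sd must be nonnegative")

    @property
    def n_gears(self) -> int:
        return len(self.gear_labels)


@dataclass
class SimulationTruth:
    """Generating factors on the analysis scale and the impacts they imply.

    ``temporal_factors``, ``channel_factors`` and ``gear_factors`` describe
    the centered, pooled-scaled tensor the estimator decomposes: unit-norm
    columns with all magnitude absorbed into ``weights``.  ``true_impacts``
    follow from them by the same weighted-loading-norm formula the impact
    estimator uses, and equal ``calibration * impact_targets`` exactly.
    The raw (uncentered, unscaled) factors used to emit the recordings are
    kept alongside for reconstruction checks.
    """

    temporal_factors: np.ndarray  # [n_time x R], centered, unit-norm columns
    channel_factors: np.ndarray  # [n_channels x R], unit-norm columns
    gear_factors: np.ndarray  # [n_gears x R], unit-norm columns
    weights: np.ndarray  # [R], positive
    gear_labels: list[str]
    true_impacts: dict[str, float]
    calibration: float  # true_impacts = calibration * impact_targets
    raw_temporal_factors: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    raw_channel_factors: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    raw_gear_rows: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    channel_scale: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    replicate_loadings: dict[tuple[str, int], np.ndarray] = field(
        repr=False, default_factory=dict
    )


def generate_temporal_profiles(
    n_time: int,
    rank: int,
    rng: np.random.Generator,
    max_abs_corr: float = 0.9,
) -> np.ndarray:
    """Smooth, nonnegative, unit-norm temporal release profiles.

    The first component is a saturating rise (first-order uptake kinetics,
    monotone non-decreasing); the remaining components are smooth release
    pulses staggered across the measurement window with randomized timing
    and width.  Two guards keep the curves analysis-friendly: widths are
    floored so no clean series trips the downstream Tukey fences by its own
    shape, and the whole set is redrawn when any pairwise correlation
    reaches ``max_abs_corr`` (near-collinear kinetics make the
    decomposition ill-conditioned).
    """
    if n_time < 2 or rank < 1:
        raise ValueError("n_time must be >= 2 and rank >= 1")
    t = np.linspace(0.0, 1.0, n_time)
    n_pulses = max(rank - 1, 1)
    spacing = 0.75 / n_pulses
    profiles = None
    for _ in range(200):
        cols = []
        for r in range(rank):
            if r == 0:
                tau = rng.uniform(0.35, 0.6)
                col = 1.0 - np.exp(-t / tau)
            else:
                mode = 0.12 + spacing * (r - 1) + rng.uniform(0.2, 0.8) * spacing
                width = np.clip(rng.uniform(0.4, 0.55) * spacing, 0.095, 0.16)
                col = np.exp(-0.5 * ((t - mode) / width) ** 2)
            cols.append(col)
        profiles = np.column_stack(cols)
        if rank == 1:
            break
        corr = np.corrcoef(profiles, rowvar=False)
        if np.max(np.abs(corr[np.triu_indices(rank, 1)])) < max_abs_corr:
            break
    else:
        logger.warning("temporal profiles remained correlated after redraws")
    norms = np.linalg.norm(profiles, axis=0)
    return profiles / np.where(norms > 0, norms, 1.0)


def generate_channel_factors(
    n_channels: int, rank: int, rng: np.random.Generator
) -> np.ndarray:
    """Nonnegative unit-norm sensor-sensitivity columns.

    Each latent volatile pattern excites its own random subset of sensors
    strongly on top of a weak cross-sensitive background — mirroring the
    partial selectivity of MQ modules and keeping the channel mode
    well-conditioned.
    """
    if n_channels < 1 or rank < 1:
        raise ValueError("n_channels and rank must be positive")
    b = 0.05 + 0.08 * rng.random((n_channels, rank))
    perm = rng.permutation(n_channels)
    bounds = np.linspace(0, n_channels, rank + 1).astype(int)
    for r in range(rank):
        idx = perm[bounds[r] : bounds[r + 1]]
        if idx.size == 0:  # more components than channels: reuse random picks
            idx = rng.choice(n_channels, size=1)
        b[idx, r] += 0.7 + 0.3 * rng.random(idx.size)
    return b / np.linalg.norm(b, axis=0)


def _gear_directions(
    targets: np.ndarray, rank: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit loading directions varying smoothly with the impact target, so
    gears of similar severity also have similar volatile profiles."""
    e0 = np.abs(rng.normal(size=rank)) + 0.1
    e0 /= np.linalg.norm(e0)
    e1 = np.abs(rng.normal(size=rank)) + 0.1
    e1 -= (e1 @ e0) * e0
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.ones(rank) - (np.ones(rank) @ e0) * e0
    if np.linalg.norm(e1) < 1e-8:  # rank == 1: no second direction
        e1 = e0
    e1 /= np.linalg.norm(e1)
    lo, hi = targets.min(), targets.max()
    span = hi - lo if hi > lo else 1.0
    u = np.empty((len(targets), rank))
    for k, target in enumerate(targets):
        frac = (target - lo) / span
        direction = (
            np.cos(1.2 * frac) * e0
            + np.sin(1.2 * frac) * e1
            + 0.5 * np.abs(rng.normal(size=rank))
        )
        u[k] = direction / np.linalg.norm(direction)
    return u


def _calibrate(
    targets: np.ndarray,
    directions: np.ndarray,
    nu_a: np.ndarray,
    gram_centered: np.ndarray,
    b: np.ndarray,
    n_time: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scale each gear's loading row so the analysis-scale impacts equal
    ``calibration * targets`` exactly.

    On the analysis scale every channel is centered per recording and
    divided by its pooled standard deviation; both are exact factor
    transformations of the CP model, so the impacts have the closed form
    ``|| (nu_a * nu_b) o c_k ||`` with ``nu_b`` the column norms of the
    pooled-rescaled channel factors.  The fixed point is reached by
    multiplicative updates of the row scales.
    """
    rho = targets.copy()
    c_cal = 1.0
    for _ in range(100):
        rows = rho[:, None] * directions
        coef = nu_a[None, None, :] * b[:, None, :] * rows[None, :, :]
        var_jk = np.einsum("jkr,rs,jks->jk", coef, gram_centered, coef) / n_time
        pooled_sd = np.sqrt(var_jk.mean(axis=1))
        nu_b = np.linalg.norm(b / pooled_sd[:, None], axis=0)
        impacts = np.sqrt((((nu_a * nu_b)[None, :] * rows) ** 2).sum(axis=1))
        c_cal = float(np.exp(np.mean(np.log(impacts) - np.log(targets))))
        err = np.max(np.abs(impacts - c_cal * targets) / (c_cal * targets))
        rho *= c_cal * targets / impacts
        if err < 1e-13:
            break
    rows = rho[:, None] * directions
    # pin the raw amplitude: clean signal's mean channel sd = 1, so noise_sd
    # is a signal-relative quantity; the analysis-scale impacts are invariant
    coef = nu_a[None, None, :] * b[:, None, :] * rows[None, :, :]
    var_jk = np.einsum("jkr,rs,jks->jk", coef, gram_centered, coef) / n_time
    rows /= np.sqrt(var_jk.mean())
    return rows, c_cal * targets, c_cal


def synthesize_dataset(
    config: SimulationConfig,
) -> tuple[list[GearRecording], SimulationTruth]:
    """Generate all recordings of the study plus the generating truth.

    Identical config (including seed) yields identical output.  Injected
    missing and outlier positions are recorded on each ``GearRecording`` as
    (row, col) index pairs.
    """
    rng = np.random.default_rng(config.seed)
    targets = np.array(
        [config.impact_targets[g] for g in config.gear_labels], dtype=float
    )
    a_raw = generate_temporal_profiles(config.n_time, config.true_rank, rng)
    centered = a_raw - a_raw.mean(axis=0)
    nu_a = np.linalg.norm(centered, axis=0)
    a_centered = centered / np.where(nu_a > 0, nu_a, 1.0)
    gram = a_centered.T @ a_centered

    if config.n_channels == len(CHANNEL_NAMES):
        channels = list(CHANNEL_NAMES)
    else:
        channels = [f"ch{j:02d}" for j in range(config.n_channels)]
    b = generate_channel_factors(config.n_channels, config.true_rank, rng)
    directions = _gear_directions(targets, config.true_rank, rng)
    rows, true_impacts, calibration = _calibrate(
        targets, directions, nu_a, gram, b, config.n_time
    )

    # analysis-scale factor set: centered temporal mode, pooled-scaled
    # channel mode, unit columns everywhere, magnitudes in the weights
    coef = nu_a[None, None, :] * b[:, None, :] * rows[None, :, :]
    var_jk = np.einsum("jkr,rs,jks->jk", coef, gram, coef) / config.n_time
    pooled_sd = np.sqrt(var_jk.mean(axis=1))
    b_scaled = b / pooled_sd[:, None]
    nu_b = np.linalg.norm(b_scaled, axis=0)
    col_norm_c = np.linalg.norm(rows, axis=0)
    col_norm_c = np.where(col_norm_c > 0, col_norm_c, 1.0)
    truth = SimulationTruth(
        temporal_factors=a_centered,
        channel_factors=b_scaled / nu_b,
        gear_factors=rows / col_norm_c,
        weights=nu_a * nu_b * col_norm_c,
        gear_labels=list(config.gear_labels),
        true_impacts={g: float(v) for g, v in zip(config.gear_labels, true_impacts)},
        calibration=calibration,
        raw_temporal_factors=a_raw,
        raw_channel_factors=b,
        raw_gear_rows=rows,
        channel_scale=pooled_sd,
    )
    # stored representation must reproduce the calibrated impacts exactly
    assert np.allclose(
        weighted_loading_norms(truth.weights, truth.gear_factors), true_impacts
    )

    times = SAMPLE_PERIOD_MIN * np.arange(config.n_time)
    recordings: list[GearRecording] = []
    for k, gear in enumerate(config.gear_labels):
        for rep in range(1, config.n_replicates + 1):
            jitter = 1.0 + config.replicate_jitter_sd * rng.standard_normal(
                config.true_rank
            )
            loading = rows[k] * jitter
            truth.replicate_loadings[(gear, rep)] = loading
            values = (a_raw * loading) @ b.T
            if config.noise_sd > 0:
                values = values + config.noise_sd * rng.standard_normal(values.shape)

            miss_mask = rng.random(values.shape) < config.missing_rate
            out_mask = (rng.random(values.shape) < config.outlier_rate) & ~miss_mask
            values[out_mask] *= config.outlier_scale
            values[miss_mask] = np.nan

            recordings.append(
                GearRecording(
                    gear=gear,
                    replicate=rep,
                    times=times,
                    values=values,
                    channels=channels,
                    injected_missing=np.argwhere(miss_mask),
                    injected_outliers=np.argwhere(out_mask),
                )
            )
    return recordings, truth
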