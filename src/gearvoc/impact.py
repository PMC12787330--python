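"""Per-gear impact statistic and the relative severity scale.

The deviation of gear k from the basal volatile profile is scored from one
fitted CP model as the L2 norm of its weighted gear-mode loadings,

    I_k = sqrt( sum_r (w_r * C_kr)^2 ),

i.e. the magnitude of the gear's accumulated contribution across the latent
components.  Because each random initialization yields a slightly different
decomposition, the point impact is averaged over seeds and reported with an
empirical confidence interval.  The severity scale re-expresses mean impacts
as percentage increases over the minimum-impact gear (the basal profile).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parafac import CPModel

__all__ = [
    "ImpactResult",
    "SeverityTable",
    "weighted_loading_norms",
    "point_impact",
    "aggregate_impacts",
    "severity_scale",
    "write_impact_tables",
]


def weighted_loading_norms(weights: np.ndarray, gear_factors: np.ndarray) -> np.ndarray:
    """L2 norm of (w_r * C_kr) per gear row — shared by the estimator and the
    synthetic generator's ground truth so both use the identical formula."""
    contributions = np.asarray(gear_factors, dtype=float) * np.asarray(
        weights, dtype=float
    )
    return np.sqrt(np.sum(contributions**2, axis=1))


@dataclass
class ImpactResult:
    """Seed-resolved impacts at one rank: per-seed matrix, means and CIs."""

    gear_labels: list[str]
    per_seed_impacts: np.ndarray  # [K x S]
    mean_impact: np.ndarray  # [K]
    ci_low: np.ndarray
    ci_high: np.ndarray
    rank_used: int
    n_seeds: int

    def __post_init__(self) -> None:
        if not np.allclose(self.mean_impact, self.per_seed_impacts.mean(axis=1)):
            raise ValueError("mean_impact must equal the per-seed row means")
        if np.any(self.ci_low > self.mean_impact + 1e-12) or np.any(
            self.ci_high < self.mean_impact - 1e-12
        ):
            raise ValueError("confidence bounds must bracket the mean")


@dataclass
class SeverityTable:
    """Relative impact increase (percent) over the basal (minimum) gear,
    sorted from most to least severe."""

    gear_labels: list[str]
    relative_pct: np.ndarray
    rel_ci_low: np.ndarray
    rel_ci_high: np.ndarray
    baseline_gear: str

    def __post_init__(self) -> None:
        base = self.gear_labels.index(self.baseline_gear)
        if abs(self.relative_pct[base]) > 1e-12:
            raise ValueError("baseline gear must sit at 0%")
        if np.any(np.diff(self.relative_pct) > 1e-12):
            raise ValueError("severity table must be sorted descending")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gear": self.gear_labels,
                "relative_impact_pct": self.relative_pct,
                "ci_low_pct": self.rel_ci_low,
                "ci_high_pct": self.rel_ci_high,
            }
        )


def point_impact(model: CPModel) -> np.ndarray:
    """Point impact I_k per gear from one fitted model; invariant under the
    model's column-permutation and sign indeterminacies."""
    return weighted_loading_norms(model.weights, model.C)


def _ci(samples: np.ndarray, level: float, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-row CI of a [K x S] sample matrix."""
    if method == "percentile":
        lo_q = 100.0 * (1.0 - level) / 2.0
        hi_q = 100.0 - lo_q
        return (
            np.percentile(samples, lo_q, axis=1),
            np.percentile(samples, hi_q, axis=1),
        )
    if method == "normal":
        from scipy import stats

        z = stats.norm.ppf(0.5 + level / 2.0)
        mean = samples.mean(axis=1)
        sd = samples.std(axis=1, ddof=1) if samples.shape[1] > 1 else np.zeros(samples.shape[0])
        return mean - z * sd, mean + z * sd
    raise ValueError(f"unknown CI method {method!r}")


def aggregate_impacts(
    models: list[CPModel],
    ci_level: float = 0.95,
    ci_method: str = "percentile",
    gear_labels: list[str] | None = None,
) -> ImpactResult:
    """Average point impacts over the seeds of a fixed-rank model ensemble.

    CIs are empirical percentiles of the per-seed distribution by default
    (``ci_method='normal'`` gives mean +/- z*sd instead).
    """
    if not models:
        raise ValueError("no models to aggregate")
    rank = models[0].rank
    k_dim = models[0].C.shape[0]
    if any(m.rank != rank for m in models):
        raise ValueError("all models must share the same rank")
    if any(m.C.shape[0] != k_dim for m in models):
        raise ValueError("all models must share the gear axis")
    if gear_labels is None:
        gear_labels = models[0].gear_labels or [f"gear{k}" for k in range(k_dim)]
    per_seed = np.column_stack([point_impact(m) for m in models])
    ci_low, ci_high = _ci(per_seed, ci_level, ci_method)
    # degenerate spread: clamp bounds onto the mean so they always bracket it
    mean = per_seed.mean(axis=1)
    ci_low = np.minimum(ci_low, mean)
    ci_high = np.maximum(ci_high, mean)
    return ImpactResult(
        gear_labels=list(gear_labels),
        per_seed_impacts=per_seed,
        mean_impact=mean,
        ci_low=ci_low,
        ci_high=ci_high,
        rank_used=rank,
        n_seeds=per_seed.shape[1],
    )


def severity_scale(
    result: ImpactResult, ci_level: float = 0.95, ci_method: str = "percentile"
) -> SeverityTable:
    """Relative severity of every gear versus the basal profile.

    The baseline is the gear with the minimum *mean* impact, held fixed
    across seeds; per-seed relative differences
    100*(I_ks - I_base,s)/I_base,s provide the CI.  Negative CI bounds are
    reported as-is.
    """
    base_idx = int(np.argmin(result.mean_impact))
    base_mean = result.mean_impact[base_idx]
    if base_mean <= 0:
        raise ValueError("severity scale undefined: baseline mean impact <= 0")
    rel_mean = 100.0 * (result.mean_impact - base_mean) / base_mean

    base_seed = result.per_seed_impacts[base_idx]
    if np.any(base_seed <= 0):
        raise ValueError("severity scale undefined: baseline impact <= 0 in a seed")
    rel_per_seed = 100.0 * (result.per_seed_impacts - base_seed) / base_seed
    lo, hi = _ci(rel_per_seed, ci_level, ci_method)

    order = np.argsort(-rel_mean, kind="stable")
    return SeverityTable(
        gear_labels=[result.gear_labels[i] for i in order],
        relative_pct=rel_mean[order],
        rel_ci_low=lo[order],
        rel_ci_high=hi[order],
        baseline_gear=result.gear_labels[base_idx],
    )


def write_impact_tables(
    result: ImpactResult, table: SeverityTable, directory: str | Path
) -> None:
    """Emit impact and severity CSVs plus a machine-readable JSON summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "gear": result.gear_labels,
            "mean_impact": result.mean_impact,
            "ci_low": result.ci_low,
            "ci_high": result.ci_high,
        }
    ).to_csv(directory / "impact.csv", index=False)
    table.to_frame().to_csv(directory / "severity.csv", index=False)
    summary = {
        "rank_used": result.rank_used,
        "n_seeds": result.n_seeds,
        "baseline_gear": table.baseline_gear,
        "mean_impact": {
            g: float(v) for g, v in zip(result.gear_labels, result.mean_impact)
        },
        "relative_pct": {
            g: float(v) for g, v in zip(table.gear_labels, table.relative_pct)
        },
    }
    (directory / "impact.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
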