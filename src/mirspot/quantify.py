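"""Region-wise counting, log-linear calibration, LOD and selectivity.

The assay's readout is the number N of accepted (single-molecule) Cy5 spots
per imaged region, averaged over ten regions per sample.  N is linear in
log10 of the target concentration (in pM) or of the cell number, so
calibration is an ordinary least-squares fit of mean count against the
decadic log; the limit of detection is where that line crosses the blank
mean + 3 SD; selectivity is the fold-ratio of mean counts between the
perfect-match sample and a mismatched one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .detect import Spot

__all__ = [
    "RegionCounts",
    "CalibrationFit",
    "LodEstimate",
    "SelectivityResult",
    "count_regions",
    "fit_calibration",
    "estimate_lod",
    "selectivity_ratios",
    "plot_calibration",
]


class QuantificationError(ValueError):
    pass


@dataclass
class RegionCounts:
    label: str
    counts: list[int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise QuantificationError("need at least one region")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise QuantificationError("counts must be non-negative integers")
        self.counts = [int(c) for c in self.counts]

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sd(self) -> float:
        """Sample standard deviation (n − 1); 0.0 for a single region."""
        return float(np.std(self.counts, ddof=1)) if len(self.counts) > 1 else 0.0


@dataclass
class CalibrationFit:
    slope: float  # counts per decade
    intercept: float  # counts
    r_squared: float
    x_kind: str  # "log10_conc_pM" or "log10_cells"
    x_range: tuple[float, float]  # of the log10-transformed axis

    def predict(self, x_value: float) -> float:
        """Predicted count at a raw (untransformed) concentration/cell number."""
        return self.slope * math.log10(x_value) + self.intercept


@dataclass
class LodEstimate:
    lod_value: float  # pM or cells, same axis as the fit
    criterion: str
    blank_mean: float
    blank_sd: float


@dataclass
class SelectivityResult:
    reference: str
    folds: dict[str, float] = field(default_factory=dict)


def count_regions(
    region_results: Sequence[Sequence[Spot] | int], label: str = ""
) -> RegionCounts:
    """Per-region accepted-spot totals with mean and sample SD.

    Accepts either lists of accepted spots per region or bare counts.
    """
    if len(region_results) == 0:
        raise QuantificationError("need at least one region")
    counts = [r if isinstance(r, (int, np.integer)) else len(r) for r in region_results]
    return RegionCounts(label=label, counts=counts)


def fit_calibration(
    x_values: Sequence[float],
    mean_counts: Sequence[float],
    x_kind: str = "log10_conc_pM",
) -> CalibrationFit:
    """OLS fit of mean accepted count vs log10(concentration or cell number).

    ``x_values`` are raw concentrations in pM (or raw cell numbers) and are
    log10-transformed here; R² is the ordinary coefficient of determination.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(mean_counts, dtype=float)
    if x.size != y.size:
        raise QuantificationError("x and y must have equal length")
    if x.size < 3:
        raise QuantificationError("need at least 3 calibration points")
    if np.any(x <= 0):
        raise QuantificationError("concentrations / cell numbers must be > 0")
    logx = np.log10(x)
    if np.ptp(logx) == 0:
        raise QuantificationError("zero variance in x")
    res = stats.linregress(logx, y)
    ss_res = float(np.sum((y - (res.slope * logx + res.intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        x_kind=x_kind,
        x_range=(float(logx.min()), float(logx.max())),
    )


def estimate_lod(fit: CalibrationFit, blank: RegionCounts) -> LodEstimate:
    """Limit of detection from the blank + 3 SD crossing of the fitted line.

    lod = 10^((blank_mean + 3·blank_sd − intercept) / slope).  The criterion
    string records the rule; a LOD below the fitted range is flagged there as
    an extrapolation.
    """
    if fit.slope <= 0:
        raise QuantificationError("LOD requires a positive calibration slope")
    threshold = blank.mean + 3.0 * blank.sd
    log_lod = (threshold - fit.intercept) / fit.slope
    criterion = (
        f"calibration line crosses blank mean + 3 SD ({threshold:.3f} counts)"
    )
    if log_lod < fit.x_range[0]:
        criterion += "; extrapolated below the fitted range"
    return LodEstimate(
        lod_value=10.0**log_lod,
        criterion=criterion,
        blank_mean=blank.mean,
        blank_sd=blank.sd,
    )


def plot_calibration(
    fit: CalibrationFit,
    x_values: Sequence[float],
    mean_counts: Sequence[float],
    path,
    sds: Sequence[float] | None = None,
) -> None:
    """Save a count vs log10(x) scatter with the fitted line and error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    logx = np.log10(np.asarray(x_values, dtype=float))
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.errorbar(logx, mean_counts, yerr=sds, fmt="o", capsize=3, color="crimson")
    grid = np.linspace(logx.min(), logx.max(), 50)
    ax.plot(grid, fit.slope * grid + fit.intercept, "k-",
            label=f"N = {fit.slope:.1f}·x + {fit.intercept:.1f}\nR² = {fit.r_squared:.4f}")
    xlabel = "log10(C / pM)" if fit.x_kind == "log10_conc_pM" else "log10(cell number)"
    ax.set_xlabel(xlabel)
    ax.set_ylabel("accepted Cy5 spots per region")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def selectivity_ratios(
    reference: RegionCounts, variants: Sequence[RegionCounts]
) -> SelectivityResult:
    """Fold-ratio of mean counts, reference species over each variant."""
    result = SelectivityResult(reference=reference.label)
    for variant in variants:
        if variant.mean == 0:
            warnings.warn(
                f"variant {variant.label!r} has zero mean count; fold is infinite",
                stacklevel=2,
            )
            result.folds[variant.label] = math.inf
        else:
            result.folds[variant.label] = reference.mean / variant.mean
    return result
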