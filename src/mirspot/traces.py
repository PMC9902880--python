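"""Photobleaching-trace extraction and single-molecule filtering.

The single-molecule check of the assay: a spot hosting one Cy5 dye bleaches
in a single downward step (a one-level trace), while a spot hosting several
dyes bleaches successively and produces a multi-level staircase.  Traces are
extracted by aperture photometry with a local-annulus background, fitted as
piecewise-constant signals by penalized binary segmentation, and spots whose
traces show more than one downward level change (or any upward change) are
rejected from counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detect import Spot
from .simulate import Movie

__all__ = [
    "Trace",
    "StepFit",
    "extract_trace",
    "extract_traces",
    "estimate_noise_sd",
    "count_steps",
    "filter_single_molecules",
]


class TraceError(ValueError):
    pass


@dataclass
class Trace:
    spot: Spot
    intensities: np.ndarray  # background-corrected counts, one per frame
    background_level: float  # mean annulus median, counts / px

    def __len__(self) -> int:
        return len(self.intensities)


@dataclass
class StepFit:
    n_levels: int
    change_frames: list[int]  # first frame of each new level, strictly increasing
    level_means: list[float]
    reaches_baseline: bool
    noise_sd: float

    @property
    def n_down(self) -> int:
        return sum(
            1 for a, b in zip(self.level_means, self.level_means[1:]) if b < a
        )

    @property
    def n_up(self) -> int:
        return sum(
            1 for a, b in zip(self.level_means, self.level_means[1:]) if b > a
        )


def _masks(aperture_radius: float, annulus_inner: float, annulus_outer: float):
    r = int(math.ceil(annulus_outer))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = dy**2 + dx**2
    aperture = d2 <= aperture_radius**2
    annulus = (d2 >= annulus_inner**2) & (d2 <= annulus_outer**2)
    return r, aperture, annulus


def extract_trace(
    movie: Movie | np.ndarray,
    spot: Spot,
    aperture_radius: float = 3.0,
    annulus_inner: float = 4.0,
    annulus_outer: float = 6.0,
) -> Trace:
    """Aperture photometry of one spot across all frames.

    Per frame: sum of the pixels within ``aperture_radius`` of the spot's
    (rounded) center, minus the aperture pixel count times the median of the
    background annulus.  Raises :class:`TraceError` if the annulus extends
    past the image edge; batch callers flag and exclude such spots.
    """
    if not annulus_outer > annulus_inner >= aperture_radius:
        raise TraceError("need annulus_outer > annulus_inner >= aperture_radius")
    data = movie.data if isinstance(movie, Movie) else np.asarray(movie)
    n_frames, h, w = data.shape
    r, aperture, annulus = _masks(aperture_radius, annulus_inner, annulus_outer)
    cy, cx = int(round(spot.y)), int(round(spot.x))
    if cy - r < 0 or cx - r < 0 or cy + r >= h or cx + r >= w:
        raise TraceError(f"aperture of spot at ({spot.x:.1f}, {spot.y:.1f}) exceeds image")

    patch = data[:, cy - r : cy + r + 1, cx - r : cx + r + 1].astype(float)
    ap = patch[:, aperture]  # frames × aperture pixels
    bg = np.median(patch[:, annulus], axis=1)  # per-frame annulus median
    intensities = ap.sum(axis=1) - aperture.sum() * bg
    return Trace(spot=spot, intensities=intensities, background_level=float(bg.mean()))


def extract_traces(movie: Movie | np.ndarray, spots: list[Spot], **kwargs) -> list[Trace | None]:
    """Traces for all spots; edge spots yield ``None`` and are marked rejected."""
    out: list[Trace | None] = []
    for spot in spots:
        try:
            out.append(extract_trace(movie, spot, **kwargs))
        except TraceError:
            spot.accepted = False
            out.append(None)
    return out


def estimate_noise_sd(y: np.ndarray) -> float:
    """Robust per-frame noise SD from median absolute successive differences.

    Successive differencing removes the piecewise-constant signal; the
    median-based scale (0.6745·√2 for Gaussian noise) is immune to the few
    step-straddling differences.
    """
    y = np.asarray(y, dtype=float)
    d = np.abs(np.diff(y))
    if d.size == 0:
        return 0.0
    return float(np.median(d) / (0.6745 * math.sqrt(2.0)))


def _segment_cost(cum: np.ndarray, cum2: np.ndarray, a: int, b: int) -> float:
    """Within-segment sum of squared residuals of y[a:b] about its mean."""
    n = b - a
    s = cum[b] - cum[a]
    return float(cum2[b] - cum2[a] - s * s / n)


def _binary_segmentation(y: np.ndarray, beta: float, min_size: int = 2) -> list[int]:
    """Greedy penalized binary segmentation; returns sorted change points.

    A split is accepted while the best single split of some current segment
    lowers the residual sum of squares by more than ``beta``.
    """
    cum = np.concatenate(([0.0], np.cumsum(y)))
    cum2 = np.concatenate(([0.0], np.cumsum(y * y)))

    def best_split(a: int, b: int) -> tuple[float, int]:
        best_gain, best_k = -np.inf, -1
        base = _segment_cost(cum, cum2, a, b)
        for k in range(a + min_size, b - min_size + 1):
            gain = base - _segment_cost(cum, cum2, a, k) - _segment_cost(cum, cum2, k, b)
            if gain > best_gain:
                best_gain, best_k = gain, k
        return best_gain, best_k

    changes: list[int] = []
    stack = [(0, len(y))]
    while stack:
        a, b = stack.pop()
        if b - a < 2 * min_size:
            continue
        gain, k = best_split(a, b)
        if gain > beta:
            changes.append(k)
            stack.append((a, k))
            stack.append((k, b))
    return sorted(changes)


def count_steps(
    trace: Trace | np.ndarray,
    penalty: float = 5.0,
    noise_sd_estimate: float | None = None,
) -> StepFit:
    """Piecewise-constant step fit of one intensity trace.

    Change points are found by binary segmentation under an L2 cost with an
    acceptance penalty of ``penalty · σ² · log(n)`` per change point, σ being
    ``noise_sd_estimate`` or the robust successive-difference estimate.  A
    trace whose final level mean sits within 2σ of zero is flagged as having
    bleached to baseline.
    """
    y = np.asarray(trace.intensities if isinstance(trace, Trace) else trace, dtype=float)
    n = y.size
    if n < 4:
        raise TraceError("trace must have at least 4 frames")
    if penalty <= 0:
        raise TraceError("penalty must be > 0")
    sd = estimate_noise_sd(y) if noise_sd_estimate is None else float(noise_sd_estimate)
    beta = penalty * max(sd, 1e-12) ** 2 * math.log(n)

    changes = _binary_segmentation(y, beta)
    bounds = [0] + changes + [n]
    means = [float(y[a:b].mean()) for a, b in zip(bounds, bounds[1:])]
    reaches_baseline = abs(means[-1]) <= 2.0 * sd
    return StepFit(
        n_levels=len(means),
        change_frames=changes,
        level_means=means,
        reaches_baseline=reaches_baseline,
        noise_sd=sd,
    )


def filter_single_molecules(
    spots: list[Spot],
    traces: list[Trace | None],
    policy: str = "counting",
    penalty: float = 5.0,
) -> list[Spot]:
    """Accept only spots whose traces are consistent with a single fluorophore.

    ``counting`` mode (the 30-frame, 3-s protocol) accepts zero or one
    downward step and no upward step — a single dye need not bleach within
    the short movie.  ``validation`` mode (longer acquisitions) additionally
    requires the trace to end at baseline, i.e. the dye was observed to
    bleach fully.  Sets ``spot.accepted`` on every spot and returns the
    accepted ones.
    """
    if policy not in ("counting", "validation"):
        raise TraceError(f"unknown policy {policy!r}")
    if len(spots) != len(traces):
        raise TraceError("need exactly one trace per spot")
    accepted: list[Spot] = []
    for spot, trace in zip(spots, traces):
        if trace is None:
            spot.accepted = False
            continue
        fit = count_steps(trace, penalty=penalty)
        ok = fit.n_up == 0 and fit.n_down <= 1
        if policy == "validation":
            ok = ok and fit.reaches_baseline
        spot.accepted = ok
        if ok:
            accepted.append(spot)
    return accepted
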