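"""End-to-end experiment templates: calibration, selectivity, cell series.

These functions wire the full chain — emitter placement from an expected
count, movie rendering, spot detection, trace filtering, region counting,
and the final regression — into the three quantitative experiment designs of
the assay:

* a concentration series whose expected accepted counts follow a given
  log-linear response line (the concentration calibration),
* a selectivity comparison of the perfect-match target against mismatched
  species through the competitive-binding model, and
* cell-number series for the two cell-line response lines.

Because some emitters are lost between placement and the accepted-count
table (close pairs merge below the detector's minimum separation, emitters
bleaching within the first frames are missed on the detection average, and
merged multi-fluorophore spots are rejected by the trace filter), the
expected *accepted* count is mapped back to an emitter density through
:class:`CountingEfficiencyModel`, an a priori forward model of those losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .binding import AssayConfig, solve_competitive_occupancy
from .detect import DetectionParams, Spot, detect_spots
from .quantify import CalibrationFit, RegionCounts, count_regions, fit_calibration, selectivity_ratios, SelectivityResult
from .simulate import GroundTruth, ImagingConfig, Movie, simulate_region_set
from .traces import extract_traces, filter_single_molecules

__all__ = [
    "CountingEfficiencyModel",
    "run_sample",
    "run_concentration_series",
    "run_selectivity",
    "run_cell_series",
    "FIG2B_LINE",
    "MB231_LINE",
    "MCF10A_LINE",
    "SAMPLING_MARGIN",
]

# Published response lines: count N vs log10(concentration/pM) or log10(cells).
FIG2B_LINE = (111.21, 120.84)
MB231_LINE = (58.046, -120.14)
MCF10A_LINE = (59.976, -45.627)

#: Emitters are sampled this many px inside the field so the detector's
#: border margin (default 8 px) plus localization jitter never clips them.
SAMPLING_MARGIN = 10.0


def expected_count_on_line(line: tuple[float, float], x_value: float) -> float:
    """Expected count on a log-linear response line, clamped at zero."""
    slope, intercept = line
    return max(0.0, slope * math.log10(x_value) + intercept)


class CountingEfficiencyModel:
    """Forward model mapping emitter density to expected accepted-spot count.

    The loss terms, all fixed by the imaging/detection configuration before
    any pipeline run:

    * close-pair merging — candidate maxima closer than ``min_separation``
      collapse into one detection.  Modelled by a position-only Monte Carlo
      of the Poisson point process with the detector's greedy suppression
      rule (internal fixed random stream; independent of run seeds).
    * early bleaching — an emitter dark for most of the detection averaging
      window is missed; survival of half the window, exp(−rate·m/2), is used.
    * merged-spot rejection — a merged cluster of k single-dye emitters is
      rejected by the trace filter when at least two of its dyes bleach
      within the movie (two distinct downward steps).

    ``expected_accepted(mu)`` evaluates the model at emitter mean ``mu`` per
    field; ``invert(n)`` returns the ``mu`` whose expected accepted count is
    ``n`` via a monotone interpolation table.
    """

    _MC_REPS = 120
    _GRID_SIZE = 15

    def __init__(
        self,
        img: ImagingConfig,
        det: DetectionParams = DetectionParams(),
        margin: float = SAMPLING_MARGIN,
    ) -> None:
        self.img = img
        self.det = det
        self.margin = margin
        self._box = (img.width - 1 - 2 * margin, img.height - 1 - 2 * margin)
        if min(self._box) <= 0:
            raise ValueError("margin leaves no usable field")
        self.p_bleach = 1.0 - math.exp(-img.bleach_rate * img.n_frames)
        self.p_early = math.exp(-img.bleach_rate * det.averaging_frames / 2.0)
        self._mu_grid: np.ndarray | None = None
        self._acc_grid: np.ndarray | None = None

    def _p_reject_cluster(self, k: int) -> float:
        """P(trace filter rejects a merged cluster of k single-dye emitters)."""
        if k < 2:
            return 0.0
        p = self.p_bleach
        return 1.0 - (1.0 - p) ** k - k * p * (1.0 - p) ** (k - 1)

    def expected_accepted(self, mu: float, seed: int = 20260924) -> float:
        """Monte-Carlo expected accepted count at emitter mean ``mu``/field."""
        if mu <= 0:
            return 0.0
        rng = np.random.default_rng(seed)
        # candidate maxima sit on the pixel grid, so pairs up to half a pixel
        # beyond min_separation can still quantize below it
        d = self.det.min_separation + 0.5
        total = 0.0
        for _ in range(self._MC_REPS):
            n = rng.poisson(mu)
            if n == 0:
                continue
            pts = rng.uniform(0.0, 1.0, size=(n, 2)) * self._box
            # greedy suppression in random priority order (spot brightnesses
            # are i.i.d., so priority is exchangeable)
            order = rng.permutation(n)
            tree = cKDTree(pts)
            pairs = tree.query_pairs(d)
            rank = np.empty(n, dtype=int)
            rank[order] = np.arange(n)
            suppressed_by = np.full(n, -1)
            for i in order:
                if suppressed_by[i] >= 0:
                    continue
                for j in _neighbors(pairs, i):
                    if suppressed_by[j] < 0 and rank[j] > rank[i]:
                        suppressed_by[j] = i
            cluster_sizes: dict[int, int] = {}
            for i in range(n):
                root = i if suppressed_by[i] < 0 else suppressed_by[i]
                cluster_sizes[root] = cluster_sizes.get(root, 0) + 1
            for k in cluster_sizes.values():
                if k == 1:
                    total += self.p_early
                else:
                    total += 1.0 - self._p_reject_cluster(k)
        return total / self._MC_REPS

    def _build_table(self, mu_max: float) -> None:
        grid = np.linspace(0.0, mu_max, self._GRID_SIZE)
        acc = np.array(
            [self.expected_accepted(mu, seed=20260924 + i) for i, mu in enumerate(grid)]
        )
        self._mu_grid = grid
        self._acc_grid = np.maximum.accumulate(acc)

    def invert(self, n_accepted: float) -> float:
        """Emitter mean per field whose expected accepted count is ``n_accepted``."""
        if n_accepted <= 0:
            return 0.0
        need = 2.5 * n_accepted + 50.0
        if self._mu_grid is None or self._mu_grid[-1] < need:
            self._build_table(need)
        return float(np.interp(n_accepted, self._acc_grid, self._mu_grid))

    def density_for_count(self, n_accepted: float) -> float:
        """Emitter density (per µm²) whose expected accepted count is given."""
        return self.invert(n_accepted) / self.img.field_area_um2


def _neighbors(pairs: set[tuple[int, int]], i: int):
    for a, b in pairs:
        if a == i:
            yield b
        elif b == i:
            yield a


@dataclass
class SampleResult:
    """One sample analyzed end to end."""

    label: str
    region_counts: RegionCounts
    spots: list[list[Spot]] = field(default_factory=list)
    truths: list[GroundTruth] = field(default_factory=list)


def run_sample(
    density: float,
    img: ImagingConfig,
    det: DetectionParams = DetectionParams(),
    n_regions: int = 10,
    seed: int | np.random.SeedSequence | None = None,
    label: str = "",
    policy: str = "counting",
    penalty: float = 5.0,
    multi_emitter_fraction: float = 0.0,
    species: str | None = None,
) -> SampleResult:
    """Simulate, detect, trace-filter and count one sample's regions."""
    regions = simulate_region_set(
        density, img, n_regions=n_regions, seed=seed,
        multi_emitter_fraction=multi_emitter_fraction,
        margin=SAMPLING_MARGIN, species=species,
    )
    accepted_per_region: list[list[Spot]] = []
    all_spots: list[list[Spot]] = []
    truths: list[GroundTruth] = []
    for movie, truth in regions:
        spots = detect_spots(movie, det)
        traces = extract_traces(movie, spots)
        accepted = filter_single_molecules(spots, traces, policy=policy, penalty=penalty)
        accepted_per_region.append(accepted)
        all_spots.append(spots)
        truths.append(truth)
    return SampleResult(
        label=label,
        region_counts=count_regions(accepted_per_region, label=label),
        spots=all_spots,
        truths=truths,
    )


def _series(
    line: tuple[float, float],
    x_values: Sequence[float],
    img: ImagingConfig,
    det: DetectionParams,
    n_regions: int,
    seed,
    x_kind: str,
    label_fmt: str,
) -> tuple[CalibrationFit, list[RegionCounts]]:
    model = CountingEfficiencyModel(img, det)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(x_values))
    per_sample: list[RegionCounts] = []
    for x, child in zip(x_values, children):
        density = model.density_for_count(expected_count_on_line(line, x))
        result = run_sample(
            density, img, det, n_regions=n_regions, seed=child,
            label=label_fmt.format(x),
        )
        per_sample.append(result.region_counts)
    fit = fit_calibration(x_values, [rc.mean for rc in per_sample], x_kind=x_kind)
    return fit, per_sample


def run_concentration_series(
    concentrations_pM: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
    line: tuple[float, float] = FIG2B_LINE,
    img: ImagingConfig = ImagingConfig(),
    det: DetectionParams = DetectionParams(),
    n_regions: int = 10,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[CalibrationFit, list[RegionCounts]]:
    """Concentration calibration: counts configured on ``line``, then refit.

    Emitter densities are set so the expected accepted count at each
    concentration sits on the given response line; the returned fit is the
    pipeline's recovery of that line from the simulated movies.
    """
    return _series(
        line, list(concentrations_pM), img, det, n_regions, seed,
        "log10_conc_pM", "{:g} pM",
    )


def run_cell_series(
    line: tuple[float, float],
    cell_numbers: Sequence[float] = (100, 1_000, 10_000, 100_000),
    img: ImagingConfig = ImagingConfig(),
    det: DetectionParams = DetectionParams(),
    n_regions: int = 10,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[CalibrationFit, list[RegionCounts]]:
    """Cell-number calibration for one cell line's response line.

    Expected counts below zero (the steep line extrapolated to few cells)
    are clamped to zero before density inversion.
    """
    return _series(
        line, list(cell_numbers), img, det, n_regions, seed,
        "log10_cells", "{:g} cells",
    )


def run_selectivity(
    efficiencies: dict[str, float],
    target_conc_pM: float = 10.0,
    line: tuple[float, float] = FIG2B_LINE,
    img: ImagingConfig = ImagingConfig(),
    det: DetectionParams = DetectionParams(),
    n_regions: int = 10,
    seed: int | np.random.SeedSequence | None = None,
    reference: str = "miR-126",
) -> tuple[SelectivityResult, dict[str, RegionCounts]]:
    """Selectivity comparison across species through the binding model.

    All species are assayed at the same target concentration; each species'
    occupancy comes from the competitive isotherm with its relative capture
    efficiency, in the dilute capture regime (target far below its Kd) where
    the occupancy ratio tracks the efficiency ratio.  The probe-1 surface
    density is set so the reference species' expected accepted count sits on
    the concentration response line at ``target_conc_pM``.
    """
    if reference not in efficiencies or efficiencies[reference] != 1.0:
        raise ValueError("efficiencies must include the reference species at 1.0")
    model = CountingEfficiencyModel(img, det)
    n_ref = expected_count_on_line(line, target_conc_pM)
    # dilute regime: target concentration two orders below its Kd
    base = AssayConfig(
        target_conc=target_conc_pM * 1e-12,
        kd_target=max(1e-9, target_conc_pM * 1e-12 * 100.0),
    )
    theta = {
        label: solve_competitive_occupancy(
            base.with_(relative_capture_efficiency=eff, species=label)
        ).theta_target
        for label, eff in efficiencies.items()
    }
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(efficiencies))
    counts: dict[str, RegionCounts] = {}
    for (label, eff), child in zip(efficiencies.items(), children):
        n_expected = n_ref * theta[label] / theta[reference]
        density = model.density_for_count(n_expected)
        counts[label] = run_sample(
            density, img, det, n_regions=n_regions, seed=child,
            label=label, species=label,
        ).region_counts
    variants = [counts[label] for label in efficiencies if label != reference]
    return selectivity_ratios(counts[reference], variants), counts
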