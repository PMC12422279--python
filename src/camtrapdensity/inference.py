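"""Simulation-matching density estimation with a random-forest regressor.

The estimator is simulation-based inference: populations of known
abundance (a gradient, by default 1..20 individuals) are simulated moving
through the camera grid, each simulated survey is reduced to the same
per-camera independent-event counts as the field data, and a random
forest regressing abundance on those count vectors is applied to the
observed vector. The forest-mean prediction is the abundance estimate;
the 2.5th/97.5th percentiles of the per-tree predictions give the 95% CI;
abundance converts to density through the effective sampling area (the
camera-grid bounding box buffered by the home-range radius). An estimate
is flagged reliable only when the CI excludes zero, the per-tree
prediction distribution is bell-shaped (unimodal), and enough independent
events were observed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .detection import CameraGrid, detect
from .events import EventTable, count_events, filter_independent
from .movement import MovementParams, Region, simulate_population, subseed

__all__ = [
    "SimConfig",
    "RFConfig",
    "TrainingSet",
    "DensityEstimate",
    "effective_area",
    "region_for_grid",
    "build_training",
    "estimate_density",
    "check_reliability",
    "DensityModel",
    "DensityResults",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the abundance-labelled simulation training set."""

    abundance_grid: tuple[int, ...] = tuple(range(1, 21))
    replicates_per_abundance: int = 100
    region: Region | None = None  # None: derived from grid + home range
    months: int = 13
    base_seed: int = 0
    survey_start: str = "2021-03-01"
    apply_filter: bool = True  # pass simulated records through the same
    window_min: float = 60.0   # independence filter as observed ones
    monthly_features: bool = False

    def __post_init__(self):
        g = tuple(int(n) for n in self.abundance_grid)
        object.__setattr__(self, "abundance_grid", g)
        if len(g) == 0:
            raise ValueError("abundance_grid must be non-empty")
        if any(b <= a for a, b in zip(g, g[1:])) or any(n < 0 for n in g):
            raise ValueError("abundance_grid must be strictly increasing, >= 0")
        if self.replicates_per_abundance < 1:
            raise ValueError("replicates_per_abundance must be >= 1")


@dataclass(frozen=True)
class RFConfig:
    """Random-forest settings: 5,000 trees and sqrt(#cameras) candidate
    variables per split by default."""

    n_trees: int = 5000
    vars_per_split: int | None = None  # None -> floor(sqrt(#features))
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.vars_per_split is not None and self.vars_per_split < 1:
            raise ValueError("vars_per_split must be >= 1")


@dataclass
class TrainingSet:
    """Simulation library: one feature row of per-camera event counts per
    simulated survey, labelled with the simulated abundance."""

    features: np.ndarray  # (runs, n_features)
    labels: np.ndarray    # (runs,)
    camera_order: list[str]
    monthly: bool = False

    def __post_init__(self):
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels row counts differ")

    @property
    def n_runs(self) -> int:
        return int(self.features.shape[0])


@dataclass
class DensityEstimate:
    """Point estimate, 95% CI and reliability diagnostics for one
    site × species."""

    species: str
    site: str
    n_hat: float
    density: float          # individuals / km²
    ci_low: float
    ci_high: float
    tree_predictions: np.ndarray = field(repr=False)
    effective_area_km2: float = float("nan")
    reliable: bool | None = None
    reasons: list[str] = field(default_factory=list)
    n_events: int | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tree_predictions"] = np.asarray(self.tree_predictions).tolist()
        return d


def effective_area(grid: CameraGrid, params: MovementParams) -> float:
    """Effective sampling area in km².

    The bounding box of the camera positions, buffered on every side by
    the home-range disc radius. The same rectangle defines the simulation
    arena, so simulated abundance and reported density refer to one area.
    """
    pos = grid.positions()
    w = float(pos[:, 0].max() - pos[:, 0].min())
    h = float(pos[:, 1].max() - pos[:, 1].min())
    r = params.home_range_radius_m
    return (w + 2 * r) * (h + 2 * r) / 1e6


def region_for_grid(grid: CameraGrid, params: MovementParams) -> Region:
    """Simulation arena matching :func:`effective_area`."""
    pos = grid.positions()
    x0, y0 = float(pos[:, 0].min()), float(pos[:, 1].min())
    w = max(float(pos[:, 0].max()) - x0, 1e-9)
    h = max(float(pos[:, 1].max()) - y0, 1e-9)
    return Region(origin=(x0, y0), width_m=w, height_m=h,
                  buffer_m=params.home_range_radius_m)


def _monthly_counts(records: pd.DataFrame, grid: CameraGrid, species: str,
                    survey_start, months: int, window_min: float) -> np.ndarray:
    """Camera × month independent-event counts, flattened camera-major."""
    start = pd.Timestamp(survey_start)
    bounds = pd.Series([start + pd.DateOffset(months=k)
                        for k in range(months + 1)])
    sub = records[(records["species"] == species)
                  & (records["site"] == grid.site)]
    month_idx = np.searchsorted(bounds.to_numpy("datetime64[ns]"),
                                sub["timestamp"].to_numpy("datetime64[ns]"),
                                side="right") - 1
    out = np.zeros((len(grid.cameras), months))
    cam_lookup = {cid: i for i, cid in enumerate(grid.camera_ids)}
    for cid, m in zip(sub["camera_id"], month_idx):
        if 0 <= m < months:
            out[cam_lookup[cid], m] += 1
    return out.ravel()


def _simulate_features(n: int, params: MovementParams, grid: CameraGrid,
                       sim: SimConfig, region: Region, seed: int) -> np.ndarray:
    """One simulated survey of n individuals -> feature vector."""
    rng = np.random.default_rng(subseed(seed, 0))
    g = grid.with_random_facings(rng)
    trajs = simulate_population(n, params, region, sim.survey_start,
                                sim.months, subseed(seed, 1))
    records = detect(trajs, g)
    if sim.apply_filter:
        records = filter_independent(records, window_min=sim.window_min)
    if sim.monthly_features:
        return _monthly_counts(records, g, params.species_label,
                               sim.survey_start, sim.months, sim.window_min)
    table = count_events(records, g, params.species_label)
    return table.feature_vector(g.camera_ids)


def build_training(params: MovementParams, grid: CameraGrid,
                   sim: SimConfig) -> TrainingSet:
    """Simulate the abundance gradient and assemble the training set.

    For each abundance in the grid and each replicate the full pipeline
    runs: simulate_population -> detect -> filter_independent ->
    count_events. Deterministic for a fixed ``sim.base_seed``.
    """
    region = sim.region or region_for_grid(grid, params)
    rows, labels = [], []
    for n in sim.abundance_grid:
        for rep in range(sim.replicates_per_abundance):
            rows.append(_simulate_features(
                n, params, grid, sim, region,
                subseed(sim.base_seed, n, rep)))
            labels.append(n)
    return TrainingSet(features=np.array(rows, dtype=float),
                       labels=np.array(labels, dtype=float),
                       camera_order=list(grid.camera_ids),
                       monthly=sim.monthly_features)


def _fit_forest(training: TrainingSet, rf: RFConfig) -> RandomForestRegressor:
    p = training.features.shape[1]
    mtry = rf.vars_per_split or max(1, int(math.isqrt(p)))
    forest = RandomForestRegressor(
        n_estimators=rf.n_trees, max_features=min(mtry, p),
        random_state=rf.seed, n_jobs=1)
    forest.fit(training.features, training.labels)
    return forest


def _tree_predictions(forest: RandomForestRegressor,
                      x: np.ndarray) -> np.ndarray:
    x = x.reshape(1, -1)
    return np.array([t.predict(x)[0] for t in forest.estimators_])


def estimate_density(training: TrainingSet, observed: EventTable,
                     rf: RFConfig, area_km2: float,
                     min_events: int = 100) -> DensityEstimate:
    """Fit the forest and convert the observed count vector to a density.

    n_hat is the forest-mean abundance prediction; the CI is the
    (2.5, 97.5) percentile band of the per-tree predictions; all three
    divide by ``area_km2`` to give individuals/km².
    """
    obs_cams = list(observed.counts.index)
    if set(obs_cams) != set(training.camera_order):
        raise ValueError(
            "observed cameras do not match training columns: "
            f"{sorted(set(obs_cams) ^ set(training.camera_order))}")
    x = observed.feature_vector(training.camera_order)
    forest = _fit_forest(training, rf)
    tree_preds = _tree_predictions(forest, x)
    n_hat = float(tree_preds.mean())
    lo, hi = np.percentile(tree_preds, [2.5, 97.5])
    est = DensityEstimate(
        species=observed.species, site=observed.site,
        n_hat=n_hat, density=n_hat / area_km2,
        ci_low=float(lo) / area_km2, ci_high=float(hi) / area_km2,
        tree_predictions=tree_preds, effective_area_km2=area_km2,
        n_events=observed.n_events)
    return check_reliability(est, observed.n_events, min_events=min_events)


def _is_unimodal(values: np.ndarray, bins: int = 20) -> bool:
    """Bell-shape proxy: one local maximum in the smoothed histogram.

    Histogram over ``bins`` bins, 3-bin moving-average smoothing,
    consecutive equal bins collapsed before counting strict local maxima.
    """
    hist, _ = np.histogram(values, bins=bins)
    smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    collapsed = smooth[np.concatenate([[True], np.diff(smooth) != 0])]
    if len(collapsed) == 1:
        return True
    padded = np.concatenate([[-1.0], collapsed, [-1.0]])
    n_max = int(np.sum((padded[1:-1] > padded[:-2])
                       & (padded[1:-1] > padded[2:])))
    return n_max == 1


def check_reliability(estimate: DensityEstimate, n_events: int,
                      min_events: int = 100) -> DensityEstimate:
    """Apply the reliability rules and return the annotated estimate.

    Reliable iff the CI lower bound is above zero, the per-tree
    prediction histogram is bell-shaped, and at least ``min_events``
    independent events back the observed vector.
    """
    if len(estimate.tree_predictions) == 0:
        raise ValueError("tree_predictions must be non-empty")
    reasons = []
    if estimate.ci_low <= 0:
        reasons.append("CI lower bound ≤ 0")
    if not _is_unimodal(np.asarray(estimate.tree_predictions)):
        reasons.append("tree-prediction distribution not bell-shaped")
    if n_events < min_events:
        reasons.append(f"insufficient events ({n_events} < {min_events})")
    return dataclasses.replace(estimate, reliable=not reasons,
                               reasons=reasons, n_events=int(n_events))


class DensityModel:
    """Camera-trap density model for one species at one site.

    Ties together the observed per-camera independent-event counts, the
    camera grid, and the species' movement parameters; ``fit()`` builds
    the simulation training set, fits the random forest, and returns a
    :class:`DensityResults`.

    Parameters
    ----------
    observed : EventTable
        Independent-event counts per camera (post filtering).
    grid : CameraGrid
        Camera deployments sharing the observed table's site.
    params : MovementParams
        Species movement parameters including home-range area.
    sim_config, rf_config : optional
        Simulation and forest settings; defaults follow the study design
        (abundance 1..20, 13 months, 5,000 trees, mtry = sqrt(#cameras)).
    min_events : int
        Reliability threshold on the observed independent-event count.
    """

    def __init__(self, observed: EventTable, grid: CameraGrid,
                 params: MovementParams, sim_config: SimConfig | None = None,
                 rf_config: RFConfig | None = None, min_events: int = 100):
        if observed.site != grid.site:
            raise ValueError("observed table and grid refer to different sites")
        self.observed = observed
        self.grid = grid
        self.params = params
        self.sim_config = sim_config or SimConfig()
        self.rf_config = rf_config or RFConfig()
        self.min_events = min_events
        self.effective_area_km2 = effective_area(grid, params)
        self.training_: TrainingSet | None = None

    @classmethod
    def from_records(cls, records: pd.DataFrame, grid: CameraGrid,
                     species: str, params: MovementParams,
                     window_min: float = 60.0, **kwargs) -> "DensityModel":
        """Build the model from raw photo records (filters, then counts)."""
        events = filter_independent(records, window_min=window_min)
        observed = count_events(events, grid, species)
        return cls(observed, grid, params, **kwargs)

    def simulate(self, n: int, seed: int = 0) -> list:
        """Simulate one population of n individuals in the model's arena."""
        region = self.sim_config.region or region_for_grid(self.grid, self.params)
        return simulate_population(n, self.params, region,
                                   self.sim_config.survey_start,
                                   self.sim_config.months, seed)

    def fit(self, training: TrainingSet | None = None) -> "DensityResults":
        """Build (or reuse) the training set, fit the forest, estimate."""
        if training is None:
            if self.training_ is None:
                self.training_ = build_training(self.params, self.grid,
                                                self.sim_config)
            training = self.training_
        else:
            self.training_ = training
        est = estimate_density(training, self.observed, self.rf_config,
                               self.effective_area_km2,
                               min_events=self.min_events)
        return DensityResults(self, est, training)


class DensityResults:
    """Fit results: density point estimate, CI, diagnostics, summary."""

    def __init__(self, model: DensityModel, estimate: DensityEstimate,
                 training: TrainingSet):
        self.model = model
        self.estimate = estimate
        self.training = training

    # Pass-through accessors for the quantities users read off first.
    @property
    def n_hat(self) -> float:
        return self.estimate.n_hat

    @property
    def density(self) -> float:
        return self.estimate.density

    @property
    def tree_predictions(self) -> np.ndarray:
        return self.estimate.tree_predictions

    @property
    def reliable(self) -> bool:
        return bool(self.estimate.reliable)

    def conf_int(self) -> tuple[float, float]:
        return (self.estimate.ci_low, self.estimate.ci_high)

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Camera-trap density estimate (simulation matching, random forest)",
            "=" * 66,
            f"Species:              {e.species}",
            f"Site:                 {e.site}",
            f"Independent events:   {e.n_events}",
            f"Training simulations: {self.training.n_runs} "
            f"(abundance {min(self.model.sim_config.abundance_grid)}"
            f"..{max(self.model.sim_config.abundance_grid)})",
            f"Forest:               {self.model.rf_config.n_trees} trees",
            "-" * 66,
            f"Abundance n_hat:      {e.n_hat:.2f} individuals",
            f"Effective area:       {e.effective_area_km2:.2f} km²",
            f"Density:              {e.density:.2f} individuals/km²",
            f"95% CI:               ({e.ci_low:.2f}, {e.ci_high:.2f})",
            f"Reliable:             {e.reliable}"
            + (f"  [{'; '.join(e.reasons)}]" if e.reasons else ""),
            "=" * 66,
        ]
        return "\n".join(lines)

    def plot_distribution(self, ax=None):
        """Histogram + KDE of the per-tree density predictions."""
        from .plotting import plot_tree_distribution
        return plot_tree_distribution(self, ax=ax)

    def to_dict(self) -> dict:
        return self.estimate.to_dict()
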