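"""Seeded virtual lake landscapes for SDM benchmarking.

Generates a lake-level table emulating a regional invasion survey: lake
coordinates on a planar extent, spatially autocorrelated environmental
covariates with realistic marginal moments, a monotone-plateau habitat
suitability surface, Bernoulli presence/absence for a fixed number of
surveyed lakes, a pool of unsurveyed lakes, and a point-intercept-derived
frequency of occurrence (lake-level abundance proxy) with a right-skewed,
wedge-shaped relation to suitability.

The default configuration mirrors the Minnesota Eurasian-watermilfoil
survey design: 184 surveyed presences, 284 surveyed absences, 801
unsurveyed lakes, and the published summary statistics of the 11
lake-level predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "LandscapeError",
    "three_driver_config",
    "strong_residual_config",
    "generate_landscape",
    "simulate_point_intercept",
    "assign_abundance",
    "true_suitability",
    "write_lake_table",
    "read_lake_table",
    "validate_lake_table",
    "DEFAULT_COVARIATES",
]


class LandscapeError(RuntimeError):
    """Raised when a landscape cannot be generated under the config."""


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal moments, support and spatial range of one covariate.

    ``spatial_range`` (km) is the distance-decay scale of the Gaussian
    kernel field used to generate the covariate surface. ``lognormal``
    selects a log-normal marginal (used for heavy-tailed variables whose
    SD is of the order of the mean or larger).
    """

    mean: float
    sd: float
    minimum: float
    maximum: float
    spatial_range: float = 80.0
    lognormal: bool = False
    #: share of the field variance carried by a fixed north-south linear
    #: trend (regional climatic gradient); 0 = pure kernel field
    gradient: float = 0.0

    def validate(self, name: str) -> None:
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError(f"{name}: need min <= mean <= max")
        if self.sd <= 0 or self.spatial_range <= 0:
            raise ValueError(f"{name}: sd and spatial_range must be > 0")
        if not 0 <= self.gradient <= 1:
            raise ValueError(f"{name}: gradient share must be in [0, 1]")


#: Published lake-level summary statistics (mean, SD, min, max) of the 11
#: predictors; units as in the source survey (m^-1, ug/L, uS/cm, degC*days,
#: m, acres, pH units, mg/L, m/ha, m, m/ha).
DEFAULT_COVARIATES: dict[str, CovariateSpec] = {
    "cdom_a440": CovariateSpec(2.38, 2.27, 0.0, 15.1),
    "chlorophyll_a": CovariateSpec(31.0, 84.0, 0.093, 2231.0, lognormal=True),
    "conductance": CovariateSpec(313.0, 215.0, 8.53, 1750.0),
    # regional climate: dominant latitudinal trend (warmer south) plus a
    # longer-range kernel component than the limnological variables
    "gdd_wtr_10c": CovariateSpec(
        1671.0, 225.0, 1078.0, 2465.0, spatial_range=150.0, gradient=0.95
    ),
    "lake_depth": CovariateSpec(10.2, 9.58, 0.914, 141.0),
    "lake_size": CovariateSpec(759.0, 4984.0, 8.82, 128251.0, lognormal=True),
    "ph": CovariateSpec(8.03, 0.633, 6.02, 9.71),
    "phosphorus": CovariateSpec(0.090, 0.116, 0.004, 1.18, lognormal=True),
    "road_density": CovariateSpec(40.6, 29.3, 0.0, 211.0),
    "secchi_depth": CovariateSpec(2.35, 1.48, 0.167, 12.9),
    "stream_density": CovariateSpec(4.18, 3.5, 0.0, 21.2),
}

#: Saturating-ramp plateau locations of the active (suitability-driving)
#: covariates: growing degree days plateau near 1,750 degC*days, lake depth
#: near 30 m, road density near 75 m/ha.
DEFAULT_PLATEAUS: dict[str, float] = {
    "gdd_wtr_10c": 1750.0,
    "lake_depth": 30.0,
    "road_density": 75.0,
}

RESPONSE_COLUMNS = ["id", "x", "y", "surveyed", "presence", "freq_occ"]


@dataclass
class SimulationConfig:
    """Full recipe for one synthetic landscape; the seed fixes everything."""

    n_presence: int = 184
    n_absence: int = 284
    n_unsurveyed: int = 801
    extent: tuple[float, float] = (600.0, 560.0)  # km
    covariate_spec: dict[str, CovariateSpec] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    active_covariates: tuple[str, ...] = ("gdd_wtr_10c", "lake_depth", "road_density")
    plateaus: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PLATEAUS))
    #: logistic weight of each active ramp; a scalar applies to all active
    #: covariates, a dict sets them individually. The climatic driver gets
    #: the largest weight, mirroring its leading importance in the field.
    effect_weight: float | dict = field(
        default_factory=lambda: {"gdd_wtr_10c": 24.0, "lake_depth": 4.0, "road_density": 4.0}
    )
    target_prevalence: float = 0.36   # calibrated mean suitability
    latent_weight: float = 1.0        # unmeasured spatially structured driver
    latent_range: float = 40.0        # km
    cluster_scale: float | None = 10.0  # Thomas process sigma; None = uniform
    n_clusters: int = 60
    n_points_per_lake: int = 100      # point-intercept grid size
    abundance_beta: tuple[float, float] = (1.2, 3.0)  # latent cover multiplier
    cover_cap: float = 0.8            # max attainable true cover
    survey_bias: float = 0.0          # >0: surveyed lakes skew to high suitability
    n_field_nodes: int = 150
    nugget: float = 0.2               # white-noise variance share per covariate
    resample_budget: int = 100
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_presence, self.n_absence, self.n_unsurveyed) <= 0:
            raise ValueError("lake counts must be positive")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must be in (0, 1)")
        if not 0 < self.cover_cap <= 1:
            raise ValueError("cover_cap must be in (0, 1]")
        if self.n_points_per_lake < 1:
            raise ValueError("n_points_per_lake must be >= 1")
        for name, spec in self.covariate_spec.items():
            spec.validate(name)
        for name in self.active_covariates:
            if name not in self.covariate_spec:
                raise ValueError(f"active covariate {name!r} not in covariate_spec")
            spec = self.covariate_spec[name]
            if not (spec.minimum < self.plateaus[name] <= spec.maximum):
                raise ValueError(f"plateau for {name!r} outside covariate range")

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariate_spec)

    @property
    def n_total(self) -> int:
        return self.n_presence + self.n_absence + self.n_unsurveyed


def three_driver_config(seed: int = 0) -> SimulationConfig:
    """Landscape where exactly the 3 active covariates generate suitability.

    Used to probe driver recovery by permutation importance: the latent
    (unmeasured) effect is switched off so nothing outside the covariate
    table drives occurrence, all three driver fields get the same spatial
    range (no regional gradient), and the degree-day weight is raised
    relative to depth/road to offset its plateau saturation (most lakes
    sit above the 1,750 degC*day plateau, so its effective variation is
    smaller).
    """
    spec = dict(DEFAULT_COVARIATES)
    spec["gdd_wtr_10c"] = replace(spec["gdd_wtr_10c"], gradient=0.0, spatial_range=80.0)
    return SimulationConfig(
        seed=seed,
        covariate_spec=spec,
        effect_weight={"gdd_wtr_10c": 8.0, "lake_depth": 5.0, "road_density": 5.0},
        latent_weight=0.0,
    )


def strong_residual_config(seed: int = 0) -> SimulationConfig:
    """Landscape with strong residual spatial structure.

    Triples the latent spatially structured effect so that occurrence
    carries spatial autocorrelation no covariate can explain — the regime
    in which a spatial-lag autocovariate becomes the leading predictor.
    """
    return SimulationConfig(seed=seed, latent_weight=3.0)


def _place_lakes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Lake coordinates: Thomas cluster process, or uniform if unclustered."""
    w, h = config.extent
    n = config.n_total
    if config.cluster_scale is None:
        return rng.uniform([0, 0], [w, h], size=(n, 2))
    parents = rng.uniform([0, 0], [w, h], size=(config.n_clusters, 2))
    idx = rng.integers(config.n_clusters, size=n)
    pts = parents[idx] + rng.normal(scale=config.cluster_scale, size=(n, 2))
    # redraw offsets falling outside the window (keeps cluster structure)
    for _ in range(100):
        bad = (pts[:, 0] < 0) | (pts[:, 0] > w) | (pts[:, 1] < 0) | (pts[:, 1] > h)
        if not bad.any():
            break
        pts[bad] = parents[idx[bad]] + rng.normal(
            scale=config.cluster_scale, size=(int(bad.sum()), 2)
        )
    np.clip(pts[:, 0], 0, w, out=pts[:, 0])
    np.clip(pts[:, 1], 0, h, out=pts[:, 1])
    return pts


def _gaussian_field(
    coords: np.ndarray,
    spatial_range: float,
    nugget: float,
    n_nodes: int,
    extent: tuple[float, float],
    rng: np.random.Generator,
    gradient: float = 0.0,
) -> np.ndarray:
    """Standardized spatially autocorrelated field.

    Distance-decay kernel mixing of white noise at random node points:
    f(x) = sum_k exp(-d(x, node_k)^2 / (2 rho^2)) z_k, plus a white-noise
    nugget, standardized to zero mean / unit variance over the lakes.
    ``gradient`` blends in a fixed north-south linear trend (variance
    share), emulating regional climatic gradients.
    """
    nodes = rng.uniform([0, 0], list(extent), size=(n_nodes, 2))
    z = rng.standard_normal(n_nodes)
    d2 = ((coords[:, None, :] - nodes[None, :, :]) ** 2).sum(axis=2)
    kern = np.exp(-d2 / (2.0 * spatial_range**2))
    f = kern @ z
    sd = f.std()
    if sd < 1e-12:  # pathological range; fall back to pure noise
        f = rng.standard_normal(len(coords))
        sd = f.std()
    f = f / sd
    if nugget > 0:
        eps = rng.standard_normal(len(coords))
        f = math.sqrt(1 - nugget) * f + math.sqrt(nugget) * eps
    f = (f - f.mean()) / f.std()
    if gradient > 0:
        trend = -(coords[:, 1] - coords[:, 1].mean())
        trend = trend / trend.std()
        f = math.sqrt(gradient) * trend + math.sqrt(1 - gradient) * f
        f = (f - f.mean()) / f.std()
    return f


def _to_marginal(field_std: np.ndarray, spec: CovariateSpec) -> np.ndarray:
    """Map a standardized Gaussian field onto the covariate's marginal."""
    if spec.lognormal:
        m, s = spec.mean, spec.sd
        sigma2 = math.log1p((s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        x = np.exp(mu + math.sqrt(sigma2) * field_std)
    else:
        x = spec.mean + spec.sd * field_std
    return np.clip(x, spec.minimum, spec.maximum)


def _ramp(x: np.ndarray, lo: float, plateau: float) -> np.ndarray:
    """Saturating ramp: 0 at lo, rises linearly, flat at 1 beyond plateau."""
    return np.clip((x - lo) / (plateau - lo), 0.0, 1.0)


def true_suitability(
    table: pd.DataFrame, config: SimulationConfig, latent: np.ndarray | None = None
) -> np.ndarray:
    """Suitability in [0,1]: logistic of the weighted active-covariate ramps.

    Each active covariate enters through a saturating ramp rising from its
    observed landscape minimum to its plateau, then flat. The intercept is
    calibrated by bisection so the landscape-mean suitability equals
    ``config.target_prevalence``. ``latent`` optionally adds an unmeasured
    spatially structured term (standardized scale).
    """
    eta = np.zeros(len(table))
    for name in config.active_covariates:
        x = table[name].to_numpy()
        w = (
            config.effect_weight[name]
            if isinstance(config.effect_weight, dict)
            else config.effect_weight
        )
        eta += w * _ramp(x, float(x.min()), config.plateaus[name])
    if latent is not None:
        eta = eta + config.latent_weight * latent
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(mid + eta).mean() < config.target_prevalence:
            lo = mid
        else:
            hi = mid
    return expit(0.5 * (lo + hi) + eta)


def simulate_point_intercept(true_cover, n_points: int, rng: np.random.Generator):
    """Frequency of occurrence from a rake-based point-intercept survey.

    Detections at the lake's sample grid are Binomial(n_points, true_cover);
    the returned proportion detections/n_points lies in [0, 1]. Accepts a
    scalar or an array of true cover values.
    """
    cover = np.asarray(true_cover, dtype=float)
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if np.any(cover < 0) or np.any(cover > 1):
        raise ValueError("true_cover must lie in [0, 1]")
    out = rng.binomial(n_points, cover) / n_points
    return float(out) if np.isscalar(true_cover) else out


def assign_abundance(
    table: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Attach frequency of occurrence to surveyed lakes.

    For presences, true within-lake cover is cover_cap * s_i * u_i with
    u_i a right-skewed Beta multiplier (mean < 0.5): suitability bounds
    attainable cover but does not determine it, yielding the wedge-shaped
    abundance-suitability relation. Absences get freq_occ = 0. A presence
    whose binomial draw is 0 is redrawn once, then floored at 1/n_points so
    presence implies nonzero frequency.
    """
    table = table.copy()
    a, b = config.abundance_beta
    freq = np.full(len(table), np.nan)
    surveyed = table["surveyed"].to_numpy(dtype=bool)
    pres = surveyed & (table["presence"].to_numpy(dtype=float) == 1.0)
    absent = surveyed & ~pres
    s = table["true_suitability"].to_numpy()
    u = rng.beta(a, b, size=int(pres.sum()))
    cover = config.cover_cap * s[pres] * u
    f = simulate_point_intercept(cover, config.n_points_per_lake, rng)
    zero = f == 0
    if np.any(zero):
        f[zero] = simulate_point_intercept(cover[zero], config.n_points_per_lake, rng)
    f = np.maximum(f, 1.0 / config.n_points_per_lake)
    freq[pres] = f
    freq[absent] = 0.0
    table["freq_occ"] = freq
    return table


def generate_landscape(config: SimulationConfig | None = None) -> pd.DataFrame:
    """Generate one seeded landscape as a lake table.

    Returns a DataFrame with columns id, x, y, surveyed, presence,
    freq_occ, the 11 covariates, and true_suitability (simulation ground
    truth; dropped by default when written to CSV). Exactly
    n_presence + n_absence surveyed lakes and n_unsurveyed unsurveyed
    lakes; presence is drawn Bernoulli(s_i) and redrawn up to
    ``resample_budget`` times until the configured counts are feasible.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    coords = _place_lakes(config, rng)
    table = pd.DataFrame(
        {"id": [f"lake_{i:04d}" for i in range(n)], "x": coords[:, 0], "y": coords[:, 1]}
    )
    for name, spec in config.covariate_spec.items():
        f = _gaussian_field(
            coords, spec.spatial_range, config.nugget, config.n_field_nodes,
            config.extent, rng, gradient=spec.gradient,
        )
        table[name] = _to_marginal(f, spec)
    latent = _gaussian_field(
        coords, config.latent_range, config.nugget, config.n_field_nodes,
        config.extent, rng,
    )
    s = true_suitability(table, config, latent=latent)
    table["true_suitability"] = s

    for _ in range(config.resample_budget):
        z = rng.random(n) < s
        if z.sum() >= config.n_presence and (n - z.sum()) >= config.n_absence:
            break
    else:
        raise LandscapeError(
            f"could not draw >= {config.n_presence} presences and "
            f">= {config.n_absence} absences from the suitability surface "
            f"within the resampling budget of {config.resample_budget} draws"
        )

    def _pick(pool: np.ndarray, k: int) -> np.ndarray:
        if config.survey_bias > 0:
            w = np.exp(config.survey_bias * s[pool])
            p = w / w.sum()
            return rng.choice(pool, size=k, replace=False, p=p)
        return rng.choice(pool, size=k, replace=False)

    pres_idx = _pick(np.flatnonzero(z), config.n_presence)
    abs_idx = _pick(np.flatnonzero(~z), config.n_absence)
    surveyed = np.zeros(n, dtype=bool)
    surveyed[pres_idx] = True
    surveyed[abs_idx] = True
    presence = np.full(n, np.nan)
    presence[pres_idx] = 1.0
    presence[abs_idx] = 0.0
    table["surveyed"] = surveyed
    table["presence"] = presence
    table = assign_abundance(table, config, rng)
    cols = RESPONSE_COLUMNS + config.covariate_names + ["true_suitability"]
    table = table[cols]
    validate_lake_table(table)
    return table


def validate_lake_table(table: pd.DataFrame, allow_missing_covariates: bool = False) -> None:
    """Check the lake-table invariants; raise ValueError on violation.

    ``allow_missing_covariates`` tolerates NaN covariate cells (loaded
    field data before the complete-case filter); generated landscapes are
    always complete.
    """
    if table["id"].duplicated().any():
        raise ValueError("lake ids must be unique")
    surveyed = table["surveyed"].astype(bool)
    pres = table.loc[surveyed, "presence"]
    freq = table.loc[surveyed, "freq_occ"]
    if pres.isna().any() or freq.isna().any():
        raise ValueError("surveyed lakes must carry presence and freq_occ")
    if ((pres == 0) & (freq != 0)).any():
        raise ValueError("freq_occ must be 0 for absences")
    if ((pres == 1) & (freq <= 0)).any():
        raise ValueError("freq_occ must be > 0 for presences")
    covs = [c for c in table.columns if c not in RESPONSE_COLUMNS + ["true_suitability"]]
    values = table[covs].to_numpy(dtype=float)
    if allow_missing_covariates:
        if np.isinf(values).any():
            raise ValueError("covariates must not be infinite")
    elif not np.isfinite(values).all():
        raise ValueError("covariates must be finite")


def write_lake_table(table: pd.DataFrame, path, include_truth: bool = False) -> None:
    """Write the fixed-header CSV; missing responses become empty fields."""
    out = table if include_truth else table.drop(columns=["true_suitability"], errors="ignore")
    out = out.copy()
    out["surveyed"] = out["surveyed"].astype(bool)
    out["presence"] = out["presence"].astype("Int64")
    out.to_csv(path, index=False)


def read_lake_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    table["surveyed"] = table["surveyed"].astype(bool)
    table["presence"] = table["presence"].astype(float)
    return table
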