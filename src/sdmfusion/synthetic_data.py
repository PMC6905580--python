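"""Synthetic landscapes, surveys and expert panels with the statistical
structure the analysis assumes.

The generator emulates a small riverside parkland: sites scattered over a
bounded planar region, foliage cover (FPC) densest near the river edge,
remnant food-tree vegetation (REV) more likely where cover is high, and a
path network from which ground observers work.  True occupancy follows a
logistic model on the standardized covariates; ground surveys detect
occupied sites with probability declining in distance-to-path (observer
bias) while the thermal channel detects without spatial bias; absences are
drawn from undetected sites, count-matched to the presences.  Six experts
view a clustered subset of sites and report Beta-distributed suitability
probabilities around a logit-linear mean with a per-expert random intercept.

Everything is driven by a single integer seed through independent
sub-streams per channel, so identical (seed, config) gives byte-identical
tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.special import expit

from .data_model import (
    COVARIATE_COLUMNS,
    CONFIDENCE_CATEGORIES,
    ReferenceScaling,
    assign_weight,
    compute_reference_scaling,
    standardize,
)
from .survey_model import TERMS, design_matrix

__all__ = [
    "TruthParameters",
    "SurveyConfig",
    "ElicitationConfig",
    "StudyData",
    "default_study_region",
    "generate_landscape",
    "occupancy_probability",
    "simulate_census",
    "simulate_surveys",
    "simulate_elicitation",
    "generate_prediction_grid",
    "simulate_study",
]


@dataclass(frozen=True)
class TruthParameters:
    """Simulation truth: coefficient vectors on the logit scale (intercept +
    six covariates in :data:`~sdmfusion.data_model.COVARIATE_COLUMNS` order),
    expert random-intercept SD, Beta precision, and the per-metre decay of
    ground detection with distance-to-path (observer bias)."""

    beta_true: np.ndarray = field(
        default_factory=lambda: np.array([-0.65, 0.1, 0.3, 0.6, 0.5, -0.2, -0.8])
    )
    beta_suit_true: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 0.2, 0.8, 0.6, -0.3, -0.9])
    )
    sigma_expert: float = 0.4
    phi: float = 30.0
    observer_bias: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta_true", np.asarray(self.beta_true, dtype=float))
        object.__setattr__(
            self, "beta_suit_true", np.asarray(self.beta_suit_true, dtype=float)
        )
        if self.phi <= 0:
            raise ValueError("Beta precision phi must be > 0")
        if self.sigma_expert < 0:
            raise ValueError("sigma_expert must be >= 0")
        if self.observer_bias < 0:
            raise ValueError("observer_bias must be >= 0")


@dataclass(frozen=True)
class SurveyConfig:
    """Detection and weighting configuration of the two survey channels.

    ``thermal_class_probs`` distributes thermal detections over the
    confidence classes (1.00, 0.90, 0.50); the study does not report the
    realized mixture, so it is a free parameter.
    """

    ground_detect0: float = 0.52  # ground detection probability at a path
    thermal_detect: float = 0.95  # bias-free thermal detection probability
    thermal_class_probs: tuple[float, float, float] = (0.45, 0.35, 0.20)
    absence_weight: float = 0.90
    balance: bool = True  # match absence count to presence count


@dataclass(frozen=True)
class ElicitationConfig:
    """Confidence-category mixtures for the two elicited quantities, ordered
    (not_very_sure, quite_sure, very_sure).  Defaults reproduce the observed
    skew: ~98.3% of suitability answers and ~76.7% of presence answers at
    quite/very sure."""

    suitability_confidence_probs: tuple[float, float, float] = (0.017, 0.430, 0.553)
    presence_confidence_probs: tuple[float, float, float] = (0.233, 0.450, 0.317)


def default_study_region() -> tuple[shapely.Polygon, shapely.LineString]:
    """A right-triangle park of ~0.20 km^2 (legs 640 m), bordered by the
    river along its two legs and by housing along the hypotenuse.

    Running the river along two sides (as in a park sitting in a river
    bend) keeps distance-to-water piecewise — a straight single-edge river
    would make it an exact linear combination of the coordinate covariates
    and the design matrix singular."""
    region = shapely.Polygon([(0.0, 0.0), (640.0, 0.0), (0.0, 640.0)])
    river = shapely.LineString([(0.0, 640.0), (0.0, 0.0), (640.0, 0.0)])
    return region, river


def _path_network(region: shapely.Polygon, rng: np.random.Generator) -> shapely.MultiLineString:
    """Three random chords of the region boundary, standing in for the
    walking-track network ground observers use."""
    boundary = region.exterior
    L = boundary.length
    chords = []
    for _ in range(3):
        a, b = rng.uniform(0.0, L, size=2)
        p1, p2 = boundary.interpolate(a), boundary.interpolate(b)
        if p1.distance(p2) < 1e-6:
            p2 = boundary.interpolate((b + 0.25 * L) % L)
        chords.append(shapely.LineString([p1, p2]))
    return shapely.MultiLineString(chords)


def _covariates_at(
    pts: np.ndarray,
    river: shapely.LineString,
    paths: shapely.MultiLineString,
    rng: np.random.Generator,
    site_ids: Sequence,
) -> pd.DataFrame:
    points = shapely.points(pts)
    dist_water = shapely.distance(points, river)
    dist_path = shapely.distance(points, paths)
    # foliage cover densest near the river, with site-level noise
    fpc = np.clip(78.0 - 0.085 * dist_water + rng.normal(0.0, 8.0, len(pts)), 0.0, 100.0)
    rev = (rng.random(len(pts)) < expit(-2.5 + 0.055 * fpc)).astype(int)
    return pd.DataFrame(
        {
            "site_id": list(site_ids),
            "longitude": pts[:, 0],
            "latitude": pts[:, 1],
            "fpc": fpc,
            "rev": rev,
            "dist_path": dist_path,
            "dist_water": dist_water,
        }
    )


def generate_landscape(
    n_sites: int,
    seed: int,
    region: shapely.Polygon | None = None,
    river: shapely.LineString | None = None,
    return_geometry: bool = False,
):
    """Scatter ``n_sites`` uniformly over the region and derive the six
    habitat covariates (see module docstring for the generative structure).

    With ``return_geometry=True`` also returns the (region, river, paths)
    geometries so surveys and grids can share one landscape.
    """
    if region is None:
        region, default_river = default_study_region()
        river = river if river is not None else default_river
    elif river is None:
        # designate the first boundary edge as the river
        xy = list(region.exterior.coords)
        river = shapely.LineString(xy[:2])
    if region.area <= 0 or not region.is_valid:
        raise ValueError("degenerate region polygon (zero area or invalid)")
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")

    rng = np.random.default_rng(seed)
    paths = _path_network(region, rng)
    minx, miny, maxx, maxy = region.bounds
    pts = np.empty((n_sites, 2))
    got = 0
    while got < n_sites:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(max(2 * (n_sites - got), 16), 2))
        inside = shapely.contains(region, shapely.points(cand))
        take = cand[inside][: n_sites - got]
        pts[got : got + len(take)] = take
        got += len(take)
    cov = _covariates_at(pts, river, paths, rng, range(1, n_sites + 1))
    if return_geometry:
        return cov, (region, river, paths)
    return cov


def occupancy_probability(
    cov: pd.DataFrame,
    truth: TruthParameters,
    scaling: ReferenceScaling | None = None,
) -> np.ndarray:
    """True occupancy probability expit(z' beta_true) per site; covariates
    standardized by ``scaling`` (default: the table's own moments)."""
    scaling = scaling or compute_reference_scaling(cov)
    X = design_matrix(standardize(cov, scaling), TERMS)
    return expit(X @ truth.beta_true)


def simulate_census(
    cov: pd.DataFrame,
    truth: TruthParameters,
    seed: int,
    scaling: ReferenceScaling | None = None,
) -> pd.DataFrame:
    """Unbiased full-census observations: every site reported with its true
    occupancy state at weight 1 — the idealized dataset used to verify
    parameter recovery of the survey model."""
    rng = np.random.default_rng(seed)
    p = occupancy_probability(cov, truth, scaling)
    y = (rng.random(len(cov)) < p).astype(int)
    return pd.DataFrame(
        {
            "site_id": cov["site_id"].to_numpy(),
            "source": "ground",
            "y": y,
            "weight": 1.0,
        }
    )


_THERMAL_CLASSES = (
    "hotspot_confirmed_certain",
    "hotspot_confirmed_uncertain",
    "hotspot_unconfirmed",
)


def simulate_surveys(
    cov: pd.DataFrame,
    truth: TruthParameters,
    seed: int,
    config: SurveyConfig = SurveyConfig(),
    scaling: ReferenceScaling | None = None,
) -> pd.DataFrame:
    """Simulate the two survey channels over a landscape.

    Occupancy ~ Bernoulli(expit(z' beta_true)).  Ground observers detect an
    occupied site with probability ``ground_detect0 * exp(-observer_bias *
    dist_path)`` (weight 1.00); the thermal channel detects occupied sites
    with probability ``thermal_detect`` independent of location, and each
    thermal-only detection draws a confidence class from
    ``thermal_class_probs``.  Absences are sampled from undetected sites at
    weight 0.90, count-matched to the presences; a count-matched share is
    tagged ground-source so the base-model subset is balanced like the
    ground survey data.
    """
    if len(cov) == 0:
        raise ValueError("landscape is empty")
    rng = np.random.default_rng(seed)
    p_occ = occupancy_probability(cov, truth, scaling)
    occ = rng.random(len(cov)) < p_occ
    p_ground = config.ground_detect0 * np.exp(
        -truth.observer_bias * cov["dist_path"].to_numpy()
    )
    det_g = occ & (rng.random(len(cov)) < p_ground)
    det_t = occ & (rng.random(len(cov)) < config.thermal_detect)

    site_id = cov["site_id"].to_numpy()
    rows: list[dict] = []
    for sid in site_id[det_g]:
        rows.append(
            {"site_id": sid, "source": "ground", "y": 1, "weight": assign_weight("ground", "presence")}
        )
    thermal_only = det_t & ~det_g
    classes = rng.choice(
        _THERMAL_CLASSES, size=int(thermal_only.sum()), p=config.thermal_class_probs
    )
    for sid, cls in zip(site_id[thermal_only], classes):
        rows.append(
            {"site_id": sid, "source": "thermal", "y": 1, "weight": assign_weight("thermal", cls)}
        )
    n_pres = len(rows)
    if not occ.any():
        warnings.warn("no occupied sites under the given truth; presence set is empty", stacklevel=2)

    undetected = ~(det_g | det_t)
    n_abs = int(undetected.sum())
    if config.balance:
        n_abs = min(n_pres, n_abs)
    abs_sites = rng.choice(site_id[undetected], size=n_abs, replace=False)
    n_ground_abs = min(int(det_g.sum()), n_abs)
    for k, sid in enumerate(abs_sites):
        src = "ground" if k < n_ground_abs else "thermal"
        rows.append(
            {"site_id": sid, "source": src, "y": 0, "weight": config.absence_weight}
        )
    return pd.DataFrame(rows, columns=["site_id", "source", "y", "weight"])


def simulate_elicitation(
    sites: pd.DataFrame,
    truth: TruthParameters,
    n_experts: int,
    seed: int,
    scaling: ReferenceScaling | None = None,
    config: ElicitationConfig = ElicitationConfig(),
    sites_per_expert: Sequence[Sequence] | None = None,
) -> pd.DataFrame:
    """Simulate an expert-elicitation panel over the given sites.

    Per expert e a random intercept u_e ~ Normal(0, sigma_expert^2); per
    viewed site the suitability mean is mu = expit(z' beta_suit_true + u_e)
    and the stated probability draws from Beta(mu phi, (1 - mu) phi).
    Presence answers (min/mode/max) draw analogously from beta_true with the
    mode bracketed by ordered random perturbations.  Confidence categories
    draw from the configured mixtures and map deterministically to weights.

    ``sites_per_expert`` optionally lists the site_ids each expert views
    (default: every expert views every row of ``sites``).
    """
    if n_experts < 1:
        raise ValueError("need at least one expert")
    scaling = scaling or compute_reference_scaling(sites)
    z = standardize(sites, scaling)
    X = design_matrix(z, TERMS)
    eta_suit = X @ truth.beta_suit_true
    eta_pres = X @ truth.beta_true
    by_site = pd.Series(np.arange(len(sites)), index=sites["site_id"].to_numpy())

    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, truth.sigma_expert, size=n_experts)
    rows: list[dict] = []
    for e in range(n_experts):
        if sites_per_expert is None:
            idx = np.arange(len(sites))
        else:
            idx = by_site[list(sites_per_expert[e])].to_numpy()
        mu_s = expit(eta_suit[idx] + u[e])
        p_suit = rng.beta(mu_s * truth.phi, (1.0 - mu_s) * truth.phi)
        mu_p = expit(eta_pres[idx] + u[e])
        p_mode = rng.beta(mu_p * truth.phi, (1.0 - mu_p) * truth.phi)
        p_min = p_mode * rng.uniform(0.2, 0.8, size=len(idx))
        p_max = p_mode + (1.0 - p_mode) * rng.uniform(0.2, 0.8, size=len(idx))
        conf_s = rng.choice(CONFIDENCE_CATEGORIES, size=len(idx), p=config.suitability_confidence_probs)
        conf_p = rng.choice(CONFIDENCE_CATEGORIES, size=len(idx), p=config.presence_confidence_probs)
        for k, i in enumerate(idx):
            rows.append(
                {
                    "expert_id": e + 1,
                    "site_id": sites["site_id"].iloc[i],
                    "p_min": p_min[k],
                    "p_mode": p_mode[k],
                    "p_max": p_max[k],
                    "presence_confidence": conf_p[k],
                    "p_suitability": p_suit[k],
                    "suitability_confidence": conf_s[k],
                    "weight": assign_weight("expert", conf_s[k]),
                }
            )
    return pd.DataFrame(rows)


def generate_prediction_grid(
    region: shapely.Polygon | None = None,
    n: int = 636,
    seed: int = 0,
    river: shapely.LineString | None = None,
    paths: shapely.MultiLineString | None = None,
) -> pd.DataFrame:
    """A regular grid of ~``n`` unobserved sites clipped to the region, with
    covariates derived as in :func:`generate_landscape`.

    The spacing is bisected until the clipped point count is as close to
    ``n`` as a square lattice allows; the realized count is reported in the
    table length (and noted in a warning when it cannot match exactly).
    """
    if region is None:
        region, default_river = default_study_region()
        river = river if river is not None else default_river
    elif river is None:
        xy = list(region.exterior.coords)
        river = shapely.LineString(xy[:2])
    if region.area <= 0 or not region.is_valid:
        raise ValueError("degenerate region polygon")
    rng = np.random.default_rng(seed)
    if paths is None:
        paths = _path_network(region, rng)

    minx, miny, maxx, maxy = region.bounds

    def grid_points(spacing: float) -> np.ndarray:
        xs = np.arange(minx + spacing / 2.0, maxx, spacing)
        ys = np.arange(miny + spacing / 2.0, maxy, spacing)
        gx, gy = np.meshgrid(xs, ys)
        cand = np.column_stack([gx.ravel(), gy.ravel()])
        inside = shapely.contains(region, shapely.points(cand))
        return cand[inside]

    # smallest lattice spacing whose clipped count reaches n, then trim the
    # trailing rows down to exactly n
    lo, hi = 0.25 * np.sqrt(region.area / n), 4.0 * np.sqrt(region.area / n)
    best = None
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        pts = grid_points(mid)
        if len(pts) >= n:
            if best is None or len(pts) <= len(best):
                best = pts
            lo = mid
        else:
            hi = mid
    if best is None:
        best = grid_points(lo)
        warnings.warn(
            f"regular grid cannot realize {n} points in this region; "
            f"using {len(best)}",
            stacklevel=2,
        )
    best = best[:n]
    ids = [f"grid_{i}" for i in range(1, len(best) + 1)]
    return _covariates_at(best, river, paths, rng, ids)


@dataclass
class StudyData:
    """One synthetic replicate of the full study: landscape, surveys, expert
    panel, prediction grid, and the truth that generated them."""

    truth: TruthParameters
    covariates: pd.DataFrame
    observations: pd.DataFrame
    elicitations: pd.DataFrame
    grid: pd.DataFrame
    cluster_labels: pd.Series
    geometry: tuple


def simulate_study(
    seed: int = 0,
    n_sites: int = 120,
    n_experts: int = 6,
    n_clusters: int = 10,
    grid_n: int = 636,
    truth: TruthParameters | None = None,
    survey_config: SurveyConfig = SurveyConfig(),
    elicitation_config: ElicitationConfig = ElicitationConfig(),
) -> StudyData:
    """Generate one study-mimic dataset end to end.

    Channel seeds split off one root seed.  Observation sites are clustered
    on mixed-type habitat features (Gower distance, ten clusters) and each
    expert views one randomly drawn site per cluster, mirroring the
    image-subset design; every expert then contributes n_clusters records.
    """
    from .elicitation_design import cluster_sites, gower_distance, sample_image_subset

    truth = truth or TruthParameters(seed=seed)
    ss = np.random.SeedSequence(seed)
    s_land, s_surv, s_elic, s_grid, s_feat, *s_sub = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5 + n_experts)
    ]

    cov, geom = generate_landscape(n_sites, s_land, return_geometry=True)
    region, river, paths = geom
    obs = simulate_surveys(cov, truth, s_surv, survey_config)

    # mixed-type clustering features at the observed sites (one row per site)
    site_y = obs.groupby("site_id")["y"].max()
    obs_cov = cov.set_index("site_id").loc[site_y.index]
    rng = np.random.default_rng(s_feat)
    open_frac = 1.0 - obs_cov["fpc"].to_numpy() / 100.0
    features = pd.DataFrame(
        {
            "site_id": site_y.index,
            "veg_height": np.clip(
                np.rint(1.0 + 4.0 * open_frac + rng.normal(0, 0.5, len(site_y))), 1, 5
            ).astype(int),
            "veg_density": np.clip(
                np.rint(1.0 + 3.0 * open_frac + rng.normal(0, 0.4, len(site_y))), 1, 4
            ).astype(int),
            "dist_water": obs_cov["dist_water"].to_numpy(),
            "fpc": obs_cov["fpc"].to_numpy(),
            "presence": site_y.to_numpy(),
        }
    )
    dist = gower_distance(features.drop(columns="site_id"))
    labels = pd.Series(
        cluster_sites(dist, n_clusters), index=site_y.index, name="cluster"
    )

    scaling = compute_reference_scaling(cov)
    sites_per_expert = []
    for e in range(n_experts):
        picked = sample_image_subset(labels.to_numpy(), s_sub[e])
        sites_per_expert.append(list(labels.index[picked]))
    viewed = sorted({s for sub in sites_per_expert for s in sub})
    elic = simulate_elicitation(
        cov[cov["site_id"].isin(viewed)].reset_index(drop=True),
        truth,
        n_experts,
        s_elic,
        scaling=scaling,
        config=elicitation_config,
        sites_per_expert=sites_per_expert,
    )
    grid = generate_prediction_grid(region, grid_n, s_grid, river=river, paths=paths)
    return StudyData(
        truth=truth,
        covariates=cov,
        observations=obs,
        elicitations=elic,
        grid=grid,
        cluster_labels=labels,
        geometry=geom,
    )
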