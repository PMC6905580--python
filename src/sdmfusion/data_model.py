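"""Domain tables, delimited-file I/O, confidence-weight mapping and
reference standardization shared by every modelling stage.

Tables are plain :class:`pandas.DataFrame` objects with validated schemas:

``site covariates``
    ``site_id, longitude, latitude, fpc, rev, dist_path, dist_water`` —
    one row per site; FPC is percent foliage projective cover in [0, 100],
    REV a binary remnant-Eucalyptus indicator, distances in metres.
``observations``
    ``site_id, source, y, weight`` — one weighted presence/absence record
    per row; ``source`` is ``"ground"`` or ``"thermal"``.
``elicitations``
    ``expert_id, site_id, p_min, p_mode, p_max, presence_confidence,
    p_suitability, suitability_confidence, weight`` — one expert's
    judgement of one site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

__all__ = [
    "COVARIATE_COLUMNS",
    "OBSERVATION_COLUMNS",
    "ELICITATION_COLUMNS",
    "CONFIDENCE_CATEGORIES",
    "WEIGHT_TABLE",
    "SchemaError",
    "ValidationError",
    "ReferenceScaling",
    "assign_weight",
    "compute_reference_scaling",
    "standardize",
    "unstandardize",
    "distance_to_features",
    "load_observations",
    "load_elicitations",
    "load_grid",
    "validate_site_covariates",
    "validate_observations",
    "validate_elicitations",
]

#: Model covariates, in the fixed order used by every design matrix.
COVARIATE_COLUMNS: tuple[str, ...] = (
    "longitude",
    "latitude",
    "fpc",
    "rev",
    "dist_path",
    "dist_water",
)

OBSERVATION_COLUMNS: tuple[str, ...] = ("site_id", "source", "y", "weight")

ELICITATION_COLUMNS: tuple[str, ...] = (
    "expert_id",
    "site_id",
    "p_min",
    "p_mode",
    "p_max",
    "presence_confidence",
    "p_suitability",
    "suitability_confidence",
    "weight",
)

CONFIDENCE_CATEGORIES: tuple[str, ...] = ("not_very_sure", "quite_sure", "very_sure")

#: Confidence-rating table mapping (data source, detection/confidence class)
#: to the weight each record carries in the statistical models.  Ground
#: sightings are unambiguous (1.00); thermal hotspots are down-weighted by
#: how they were confirmed; randomly generated absences carry 0.90 because
#: false negatives are possible; expert categories span the same range.
WEIGHT_TABLE: dict[tuple[str, str], float] = {
    ("ground", "presence"): 1.00,
    ("thermal", "hotspot_confirmed_certain"): 1.00,
    ("thermal", "hotspot_confirmed_uncertain"): 0.90,
    ("thermal", "hotspot_unconfirmed"): 0.50,
    ("ground", "absence"): 0.90,
    ("thermal", "absence"): 0.90,
    ("expert", "not_very_sure"): 0.50,
    ("expert", "quite_sure"): 0.75,
    ("expert", "very_sure"): 1.00,
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A value violates a domain invariant; the message names the row."""


def assign_weight(source: str, category: str) -> float:
    """Map a (data source, detection/confidence class) pair to its model weight.

    Pure lookup into :data:`WEIGHT_TABLE`.  Raises ``KeyError`` listing the
    valid pairs for an unknown combination.
    """
    try:
        return WEIGHT_TABLE[(source, category)]
    except KeyError:
        valid = ", ".join(f"{s}/{c}" for s, c in sorted(WEIGHT_TABLE))
        raise KeyError(
            f"unknown (source, category) pair ({source!r}, {category!r}); "
            f"valid pairs: {valid}"
        ) from None


# ---------------------------------------------------------------------------
# Reference standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceScaling:
    """Per-covariate means and sample SDs of the base (ground-survey) data.

    Every dataset entering the models — including the expert-elicitation
    design and the prediction grid — is centred and scaled with *these*
    moments, so coefficients from all models live on a common scale and can
    be pooled elementwise.
    """

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            bad = list(self.sd.index[self.sd <= 0])
            raise ValidationError(f"non-positive reference SD for covariates {bad}")

    def transform(self, cov: pd.DataFrame) -> pd.DataFrame:
        return standardize(cov, self)

    def inverse_transform(self, z: pd.DataFrame) -> pd.DataFrame:
        return unstandardize(z, self)


def compute_reference_scaling(
    base_covariates: pd.DataFrame,
    columns: Sequence[str] = COVARIATE_COLUMNS,
) -> ReferenceScaling:
    """Means and sample SDs (n-1 denominator) over the base dataset rows.

    Raises :class:`ValidationError` if any covariate is constant (SD = 0),
    since a degenerate scale cannot be inverted.
    """
    cols = list(columns)
    missing = [c for c in cols if c not in base_covariates.columns]
    if missing:
        raise SchemaError(f"missing covariate columns {missing}")
    sub = base_covariates[cols].astype(float)
    if len(sub) < 2:
        raise ValidationError("need at least 2 rows to compute a reference scaling")
    mean = sub.mean()
    sd = sub.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValidationError(f"constant covariate(s) {bad}: SD is zero")
    return ReferenceScaling(mean=mean, sd=sd)


def standardize(cov: pd.DataFrame, ref: ReferenceScaling) -> pd.DataFrame:
    """z = (x - mean_ref) / sd_ref, per covariate in the reference.

    The binary REV indicator is z-scored like every other covariate so the
    fused models see identical covariate scales.
    """
    cols = list(ref.mean.index)
    missing = [c for c in cols if c not in cov.columns]
    if missing:
        raise SchemaError(f"covariates {missing} absent from table")
    return (cov[cols].astype(float) - ref.mean) / ref.sd


def unstandardize(z: pd.DataFrame, ref: ReferenceScaling) -> pd.DataFrame:
    """Inverse of :func:`standardize`: x = z * sd_ref + mean_ref."""
    cols = list(ref.mean.index)
    return z[cols].astype(float) * ref.sd + ref.mean


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def distance_to_features(
    point: tuple[float, float] | shapely.Geometry,
    features: Iterable[shapely.Geometry] | shapely.Geometry,
) -> float:
    """Minimum planar Euclidean distance (m) from a point to a feature set.

    ``features`` may be any shapely geometry or an iterable of geometries
    (polylines, polygons).  Distance to a polygon is measured to its
    boundary, matching the GIS convention of distance to a mapped feature
    (a site inside a vegetation polygon is still some metres from its edge).
    Coordinates must share one planar metric system.
    """
    pt = point if isinstance(point, shapely.Geometry) else shapely.Point(point)
    if isinstance(features, shapely.Geometry):
        features = [features]
    dists = []
    for geom in features:
        if geom.is_empty:
            continue
        target = geom.boundary if isinstance(geom, (shapely.Polygon, shapely.MultiPolygon)) else geom
        dists.append(pt.distance(target))
    if not dists:
        raise ValueError("empty feature set: no geometry to measure distance to")
    return float(min(dists))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s) {missing}")


def _first_bad_row(mask: pd.Series) -> int:
    return int(np.flatnonzero(mask.to_numpy())[0])


def validate_site_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Enforce the covariate invariants; returns the (typed) table."""
    _check_columns(cov, ("site_id",) + COVARIATE_COLUMNS, "site covariate")
    if len(cov) == 0:
        return cov
    out = cov.copy()
    for c in COVARIATE_COLUMNS:
        out[c] = pd.to_numeric(out[c])
    if out["site_id"].duplicated().any():
        row = _first_bad_row(out["site_id"].duplicated())
        raise ValidationError(f"duplicate site_id at row {row}")
    checks = {
        "fpc outside [0, 100]": ~out["fpc"].between(0, 100),
        "rev not in {0, 1}": ~out["rev"].isin([0, 1]),
        "negative dist_path": out["dist_path"] < 0,
        "negative dist_water": out["dist_water"] < 0,
    }
    for msg, bad in checks.items():
        if bad.any():
            raise ValidationError(f"{msg} at row {_first_bad_row(bad)}")
    return out


def validate_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Enforce observation invariants: binary y, weight in (0, 1], known source."""
    _check_columns(obs, OBSERVATION_COLUMNS, "observation")
    if len(obs) == 0:
        return obs
    out = obs.copy()
    out["y"] = pd.to_numeric(out["y"])
    out["weight"] = pd.to_numeric(out["weight"])
    checks = {
        "y not in {0, 1}": ~out["y"].isin([0, 1]),
        "weight outside (0, 1]": ~((out["weight"] > 0) & (out["weight"] <= 1)),
        "unknown source (expected 'ground' or 'thermal')": ~out["source"].isin(
            ["ground", "thermal"]
        ),
    }
    for msg, bad in checks.items():
        if bad.any():
            raise ValidationError(f"{msg} at row {_first_bad_row(bad)}")
    return out


def validate_elicitations(elic: pd.DataFrame) -> pd.DataFrame:
    """Enforce elicitation invariants: ordered probabilities, known categories,
    weight equal to the image of the suitability-confidence category."""
    _check_columns(elic, ELICITATION_COLUMNS, "elicitation")
    if len(elic) == 0:
        return elic
    out = elic.copy()
    for c in ("p_min", "p_mode", "p_max", "p_suitability", "weight"):
        out[c] = pd.to_numeric(out[c])
    for c in ("p_min", "p_mode", "p_max", "p_suitability"):
        bad = ~out[c].between(0, 1)
        if bad.any():
            raise ValidationError(f"{c} outside [0, 1] at row {_first_bad_row(bad)}")
    bad = ~((out["p_min"] <= out["p_mode"]) & (out["p_mode"] <= out["p_max"]))
    if bad.any():
        raise ValidationError(
            f"presence probabilities not ordered p_min <= p_mode <= p_max "
            f"at row {_first_bad_row(bad)}"
        )
    for c in ("presence_confidence", "suitability_confidence"):
        bad = ~out[c].isin(CONFIDENCE_CATEGORIES)
        if bad.any():
            raise ValidationError(
                f"unknown {c} category at row {_first_bad_row(bad)}; "
                f"expected one of {CONFIDENCE_CATEGORIES}"
            )
    expected = out["suitability_confidence"].map(
        lambda c: WEIGHT_TABLE[("expert", c)]
    )
    bad = (out["weight"] - expected).abs() > 1e-12
    if bad.any():
        raise ValidationError(
            "weight is not the image of the suitability confidence category "
            f"at row {_first_bad_row(bad)}"
        )
    return out


# ---------------------------------------------------------------------------
# Delimited-file I/O
# ---------------------------------------------------------------------------


def _read_csv(path, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if column_map:
        # column_map: {logical name: name in the file}
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    return df


def load_observations(
    path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an observation CSV into (observations, site covariates).

    The file carries one row per weighted presence/absence record with the
    site's covariates alongside; ``column_map`` maps logical column names to
    the header names actually in the file, so external tables load without
    editing.  Row order is preserved.  A header-only file yields two empty
    tables.
    """
    df = _read_csv(path, column_map)
    _check_columns(df, OBSERVATION_COLUMNS + COVARIATE_COLUMNS[:], "observation")
    obs = validate_observations(df[list(OBSERVATION_COLUMNS)])
    cov = validate_site_covariates(
        df[["site_id", *COVARIATE_COLUMNS]].drop_duplicates("site_id")
    )
    return obs.reset_index(drop=True), cov.reset_index(drop=True)


def load_elicitations(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read an elicitation CSV (one expert x site judgement per row)."""
    df = _read_csv(path, column_map)
    _check_columns(df, ELICITATION_COLUMNS, "elicitation")
    return validate_elicitations(df[list(ELICITATION_COLUMNS)]).reset_index(drop=True)


def load_grid(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a prediction-grid covariate CSV (site_id + the six covariates)."""
    df = _read_csv(path, column_map)
    return validate_site_covariates(df[["site_id", *COVARIATE_COLUMNS]]).reset_index(
        drop=True
    )
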