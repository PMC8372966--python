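"""Pairwise niche overlap and its distance covariates.

Schoener's D and Warren's I compare two normalized suitability surfaces
on a shared pixel grid:

    D(p, q) = 1 - 0.5 * sum |p - q|
    I(p, q) = 1 - 0.5 * sum (sqrt(p) - sqrt(q))^2

both ranging from 0 (disjoint niches) to 1 (identical niches). The pair
table adds two covariates per species pair: the great-circle distance (in
km, on the WGS84 ellipsoid) between mean occurrence points, and the
phylogenetic distance from the Brownian covariance matrix, plus the pair
type (AA, AT or TT) under the active microhabitat classification.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WGS84_A = 6378.137  # equatorial radius, km
WGS84_F = 1.0 / 298.257223563
EARTH_RADIUS_KM = 6371.0088  # mean radius for the spherical fallback


class OverlapError(ValueError):
    pass


def _check_surfaces(p, q) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise OverlapError(f"surface shapes differ: {p.shape} vs {q.shape}")
    out = []
    for name, s in (("p", p), ("q", q)):
        if np.any(s < 0):
            raise OverlapError(f"surface {name} has negative mass")
        total = s.sum()
        if total <= 0:
            raise OverlapError(f"surface {name} has zero total mass")
        if not np.isclose(total, 1.0, atol=1e-8):
            warnings.warn(
                f"surface {name} sums to {total:.6g}; normalizing", stacklevel=3
            )
            s = s / total
        out.append(s)
    return out[0], out[1]


def schoener_d(p, q) -> float:
    """Schoener's D: one minus half the L1 distance between surfaces."""
    p, q = _check_surfaces(p, q)
    d = 1.0 - 0.5 * np.abs(p - q).sum()
    return float(min(max(d, 0.0), 1.0))


def warren_i(p, q) -> float:
    """Warren's I: one minus half the squared Hellinger distance."""
    p, q = _check_surfaces(p, q)
    i = 1.0 - 0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum()
    return float(min(max(i, 0.0), 1.0))


def species_mean_point(occurrences: pd.DataFrame) -> tuple[float, float]:
    """Arithmetic mean (longitude, latitude) of one species' records."""
    if len(occurrences) == 0:
        raise OverlapError("cannot take the mean point of zero occurrences")
    return (
        float(occurrences["longitude"].mean()),
        float(occurrences["latitude"].mean()),
    )


def great_circle_km(
    point_a: tuple[float, float],
    point_b: tuple[float, float],
    ellipsoid: str = "WGS84",
) -> float:
    """Geodesic distance in km between (lon, lat) points in decimal degrees.

    ``ellipsoid="WGS84"`` solves the inverse geodesic problem by
    Vincenty's iteration; ``ellipsoid="sphere"`` uses the haversine
    formula on the mean-radius sphere. Vincenty can fail to converge for
    nearly antipodal points, in which case the spherical value is
    returned with a warning.
    """
    lon1, lat1 = point_a
    lon2, lat2 = point_b
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise OverlapError(f"latitude {lat} outside [-90, 90]")
    if ellipsoid == "sphere":
        return _haversine_km(lon1, lat1, lon2, lat2)
    if ellipsoid != "WGS84":
        raise OverlapError(f"unknown ellipsoid {ellipsoid!r}")
    if lon1 == lon2 and lat1 == lat2:
        return 0.0
    d = _vincenty_km(lon1, lat1, lon2, lat2)
    if d is None:
        warnings.warn(
            "Vincenty iteration failed to converge (near-antipodal points); "
            "falling back to the spherical distance",
            stacklevel=2,
        )
        return _haversine_km(lon1, lat1, lon2, lat2)
    return d


def _haversine_km(lon1, lat1, lon2, lat2) -> float:
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2 - lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def _vincenty_km(lon1, lat1, lon2, lat2, max_iter=200, tol=1e-12) -> float | None:
    """Vincenty's inverse solution on the WGS84 ellipsoid (km), or None."""
    a = WGS84_A
    f = WGS84_F
    b = a * (1 - f)
    u1 = np.arctan((1 - f) * np.tan(np.radians(lat1)))
    u2 = np.arctan((1 - f) * np.tan(np.radians(lat2)))
    L = np.radians(lon2 - lon1)
    sin_u1, cos_u1 = np.sin(u1), np.cos(u1)
    sin_u2, cos_u2 = np.sin(u2), np.cos(u2)

    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.sqrt(
            (cos_u2 * sin_lam) ** 2
            + (cos_u1 * sin_u2 - sin_u1 * cos_u2 * cos_lam) ** 2
        )
        if sin_sigma == 0:
            return 0.0  # coincident points
        cos_sigma = sin_u1 * sin_u2 + cos_u1 * cos_u2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        sin_alpha = cos_u1 * cos_u2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        if cos2_alpha == 0:  # equatorial line
            cos_2sigma_m = 0.0
        else:
            cos_2sigma_m = cos_sigma - 2 * sin_u1 * sin_u2 / cos2_alpha
        Cc = f / 16 * cos2_alpha * (4 + f * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - Cc) * f * sin_alpha * (
            sigma
            + Cc
            * sin_sigma
            * (cos_2sigma_m + Cc * cos_sigma * (-1 + 2 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    else:
        return None

    u_sq = cos2_alpha * (a**2 - b**2) / b**2
    A = 1 + u_sq / 16384 * (4096 + u_sq * (-768 + u_sq * (320 - 175 * u_sq)))
    B = u_sq / 1024 * (256 + u_sq * (-128 + u_sq * (74 - 47 * u_sq)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos_2sigma_m
            + B
            / 4
            * (
                cos_sigma * (-1 + 2 * cos_2sigma_m**2)
                - B
                / 6
                * cos_2sigma_m
                * (-3 + 4 * sin_sigma**2)
                * (-3 + 4 * cos_2sigma_m**2)
            )
        )
    )
    return float(b * A * (sigma - delta_sigma))


def build_pair_table(
    surfaces: dict[str, np.ndarray],
    labels: dict[str, str],
    occurrences: pd.DataFrame,
    C: np.ndarray,
    species_order: list[str],
    ellipsoid: str = "WGS84",
) -> pd.DataFrame:
    """Assemble the per-pair overlap table.

    Includes every unordered pair of species classified A or T that have a
    suitability surface; species missing from the covariance matrix are
    excluded with a diagnostic. ``occurrences`` should be the
    post-pruning table (mean points are computed from it).
    """
    from .rrpp_models import phylo_pair_distance

    index = {sp: i for i, sp in enumerate(species_order)}
    included = []
    for sp in sorted(surfaces):
        if labels.get(sp) not in ("A", "T"):
            continue
        if sp not in index:
            logger.warning("pair table: %s missing from the tree; excluded", sp)
            continue
        included.append(sp)

    pdist = phylo_pair_distance(C)
    means = {
        sp: species_mean_point(occurrences[occurrences["species"] == sp])
        for sp in included
    }
    rows = []
    for sa, sb in combinations(included, 2):
        pair_type = "".join(sorted(labels[sa] + labels[sb]))
        rows.append(
            {
                "species_a": sa,
                "species_b": sb,
                "pair_type": pair_type,
                "D": schoener_d(surfaces[sa], surfaces[sb]),
                "I": warren_i(surfaces[sa], surfaces[sb]),
                "geo_km": great_circle_km(means[sa], means[sb], ellipsoid),
                "phylo_dist": pdist[index[sa], index[sb]],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "species_a", "species_b", "pair_type", "D", "I", "geo_km", "phylo_dist",
        ],
    )
    table.attrs["ellipsoid"] = ellipsoid
    table.attrs["overlap_extent"] = "full shared raster"
    return table
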