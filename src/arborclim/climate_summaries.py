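"""Per-species climate envelopes.

Occurrences are first thinned to one record per climate pixel per species
(avoiding spatial pseudo-replication), climate values are extracted from
the containing pixel, and each species' envelope is summarized by five
statistics per variable: the 5th percentile, 25th percentile, mean, 75th
percentile and 95th percentile. Percentiles use linear interpolation
between order statistics. The resulting species x 60 matrix is converted
to standard normal deviates column-wise (sample SD, n-1 denominator)
before multivariate analysis and PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import ClimateRaster

logger = logging.getLogger(__name__)

STAT_NAMES = ("p5", "p25", "mean", "p75", "p95")


class SummaryError(ValueError):
    pass


def prune_to_pixels(
    occurrences: pd.DataFrame, raster: ClimateRaster
) -> pd.DataFrame:
    """Keep at most one occurrence per (species, pixel), first wins.

    Records falling outside the raster extent or on masked pixels are
    dropped (counts logged).
    """
    if occurrences.empty:
        return occurrences.copy()
    rows, cols, inside = raster.lonlat_to_rowcol(
        occurrences["longitude"].to_numpy(), occurrences["latitude"].to_numpy()
    )
    valid = inside & raster.validity_mask[rows, cols]
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("prune_to_pixels: dropped %d invalid-pixel records", n_dropped)
    out = occurrences.loc[valid].copy()
    out["_row"] = rows[valid]
    out["_col"] = cols[valid]
    before = len(out)
    out = out.drop_duplicates(subset=["species", "_row", "_col"], keep="first")
    logger.info(
        "prune_to_pixels: %d duplicate same-pixel records removed", before - len(out)
    )
    return out.drop(columns=["_row", "_col"]).reset_index(drop=True)


def extract_climate(
    points: pd.DataFrame, raster: ClimateRaster, drop_invalid: bool = True
) -> pd.DataFrame:
    """Climate of the containing pixel for each point (no interpolation).

    Returns the input columns plus one column per climate variable.
    Points outside the extent or on masked pixels are flagged in column
    ``valid`` and, by default, dropped (count logged).
    """
    rows, cols, inside = raster.lonlat_to_rowcol(
        points["longitude"].to_numpy(), points["latitude"].to_numpy()
    )
    valid = inside & raster.validity_mask[rows, cols]
    values = raster.pixel_values(rows, cols)
    out = points.copy().reset_index(drop=True)
    for i, code in enumerate(raster.variable_codes):
        out[code] = values[:, i]
    out["valid"] = valid
    if drop_invalid:
        n_bad = int((~valid).sum())
        if n_bad:
            logger.info("extract_climate: excluded %d out-of-extent points", n_bad)
        out = out.loc[valid].drop(columns=["valid"]).reset_index(drop=True)
    return out


def summarize_species(
    values: pd.DataFrame,
    variable_codes: tuple[str, ...],
    min_pixels: int = 3,
) -> pd.DataFrame:
    """Five-statistic envelope per species.

    ``values`` holds one row per retained pixel with a ``species`` column
    and one column per climate variable. Species with fewer than
    ``min_pixels`` rows are excluded (logged). Output is wide: one row
    per species with columns ``{var}_{stat}`` plus ``n_pixels``.
    """
    records = []
    for sp, grp in values.groupby("species", sort=True):
        n = len(grp)
        if n < min_pixels:
            logger.info(
                "summarize_species: %s excluded (%d < %d pixels)", sp, n, min_pixels
            )
            continue
        row: dict[str, object] = {"species": sp, "n_pixels": n}
        for code in variable_codes:
            x = grp[code].to_numpy(dtype=float)
            p5, p25, p75, p95 = np.percentile(
                x, [5, 25, 75, 95], method="linear"
            )
            row[f"{code}_p5"] = p5
            row[f"{code}_p25"] = p25
            row[f"{code}_mean"] = x.mean()
            row[f"{code}_p75"] = p75
            row[f"{code}_p95"] = p95
        records.append(row)
    cols = ["species", "n_pixels"] + [
        f"{c}_{s}" for c in variable_codes for s in STAT_NAMES
    ]
    return pd.DataFrame.from_records(records, columns=cols)


def summary_matrix(
    summaries: pd.DataFrame, variable_codes: tuple[str, ...]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Species x 60 matrix plus species and column name lists."""
    cols = [f"{c}_{s}" for c in variable_codes for s in STAT_NAMES]
    X = summaries[cols].to_numpy(dtype=float)
    return X, summaries["species"].tolist(), cols


def standardize_matrix(
    X: np.ndarray, column_names: list[str] | None = None
) -> np.ndarray:
    """Column-wise standard normal deviates (mean 0, SD 1 with n-1)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise SummaryError("standardization needs at least 2 species")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        names = (
            [column_names[i] for i in bad] if column_names else bad.tolist()
        )
        raise SummaryError(f"constant column(s), cannot standardize: {names}")
    return (X - mu) / sd


@dataclass
class PCAResult:
    """Principal components of the standardized envelope matrix.

    ``variance_fraction`` covers *all* rank axes (sums to 1);
    ``loadings``/``scores`` are truncated to the requested axes. Each
    loading vector's largest-magnitude entry is made positive so signs
    are reproducible.
    """

    loadings: np.ndarray  # (n_features, n_axes)
    scores: np.ndarray  # (n_species, n_axes)
    variance_fraction: np.ndarray  # (rank,)
    n_axes: int


def pca(X: np.ndarray, n_axes: int = 5) -> PCAResult:
    """PCA via SVD of the centered matrix, axes by decreasing variance."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise SummaryError("PCA needs more than one species")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max() * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if n_axes > rank:
        logger.warning("pca: n_axes=%d exceeds rank %d; truncating", n_axes, rank)
        n_axes = rank
    var = s[:rank] ** 2
    variance_fraction = var / var.sum()
    loadings = Vt[:n_axes].T.copy()
    # sign convention: largest-|.| entry of each loading vector positive
    for k in range(n_axes):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
    scores = Xc @ loadings
    return PCAResult(
        loadings=loadings,
        scores=scores,
        variance_fraction=variance_fraction,
        n_axes=n_axes,
    )
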