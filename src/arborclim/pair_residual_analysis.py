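"""Residualized pair-type test of niche overlap.

Niche-overlap values are not independent across species pairs: nearby and
closely related species overlap more. The test therefore first regresses
overlap on geographic and phylogenetic distance (ordinary least squares
with intercept), then compares the residuals across the three pair types
(AA, AT, TT) with a residual-randomization ANOVA and all three pairwise
mean-difference contrasts.

Caveat (recorded in result metadata): pairs sharing a species remain
non-independent beyond what the two distance covariates absorb; the
default row-wise residual permutation ignores this. A Mantel-style
species-level permutation mode is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .rrpp_models import Z_CUTOFF, ModelError, _effect_size

PAIR_TYPES = ("AA", "AT", "TT")


class PairTestError(ValueError):
    pass


def residualize(
    overlap: np.ndarray, geo_km: np.ndarray, phylo_dist: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """OLS residuals of overlap on [1, geographic, phylogenetic distance].

    Returns ``(residuals, coefficients)`` with coefficients ordered
    (intercept, geo slope, phylo slope).
    """
    y = np.asarray(overlap, dtype=float)
    g = np.asarray(geo_km, dtype=float)
    ph = np.asarray(phylo_dist, dtype=float)
    if len(y) < 4:
        raise PairTestError("need at least 4 pairs to residualize")
    X = np.column_stack([np.ones_like(y), g, ph])
    cond = np.linalg.cond(X)
    if cond > 1e10:
        raise PairTestError(
            f"collinear covariates (design condition number {cond:.3g})"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid, beta


@dataclass
class Contrast:
    type_a: str
    type_b: str
    mean_difference: float
    Z: float
    p: float
    significant: bool


@dataclass
class PairTestResult:
    coefficients: np.ndarray  # intercept, geo slope, phylo slope (if residualized)
    residuals: np.ndarray
    F_obs: float
    Z: float
    p: float
    group_means: dict[str, float]
    contrasts: list[Contrast]
    n_perm: int
    seed: int | None
    mode: str
    metadata: dict = field(default_factory=dict)


def _group_f(resid: np.ndarray, onehot: np.ndarray, counts: np.ndarray) -> float:
    """One-way ANOVA F of residual values over pair types."""
    n = resid.shape[-1]
    g = onehot.shape[1]
    grand = resid.mean(axis=-1, keepdims=True)
    means = (resid @ onehot) / counts  # (..., g)
    ss_b = (counts * (means - grand) ** 2).sum(axis=-1)
    ss_t = ((resid - grand) ** 2).sum(axis=-1)
    ss_w = ss_t - ss_b
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ss_b / (g - 1)) / (ss_w / (n - g))


def pair_type_test(
    residuals: np.ndarray,
    pair_types,
    n_perm: int = 999,
    seed: int | None = 0,
    mode: str = "rows",
    pair_species: np.ndarray | None = None,
    stat_scale: str = "log",
) -> PairTestResult:
    """Permutation ANOVA of residual overlap across AA/AT/TT pair types.

    ``mode="rows"`` (default) shuffles residual values freely across pair
    rows. ``mode="species"`` instead permutes species identities (a
    Mantel-style scheme that respects the pair structure); it requires
    ``pair_species``, an ``(n_pairs, 2)`` array of species ids per row.
    """
    resid = np.asarray(residuals, dtype=float)
    types = np.asarray(pair_types)
    n = len(resid)
    if len(types) != n:
        raise PairTestError("pair_types length does not match residuals")
    present, counts = np.unique(types, return_counts=True)
    missing = sorted(set(PAIR_TYPES) - set(present))
    if missing:
        raise PairTestError(f"pair type(s) absent from the table: {missing}")
    if counts.min() < 2:
        small = present[counts < 2].tolist()
        raise PairTestError(f"pair type(s) with fewer than 2 pairs: {small}")

    onehot = np.column_stack([(types == t).astype(float) for t in PAIR_TYPES])
    cts = onehot.sum(axis=0)
    group_means = {
        t: float(resid[types == t].mean()) for t in PAIR_TYPES
    }

    degenerate = np.allclose(resid, resid[0])
    rng = np.random.default_rng(seed)

    if mode == "rows":
        perm_idx = np.empty((n_perm + 1, n), dtype=int)
        perm_idx[0] = np.arange(n)
        for k in range(1, n_perm + 1):
            perm_idx[k] = rng.permutation(n)
        Rp = resid[perm_idx]  # (P, n)
        type_matrix = np.broadcast_to(onehot, (n_perm + 1,) + onehot.shape)
    elif mode == "species":
        if pair_species is None:
            raise PairTestError("mode='species' requires pair_species")
        pair_species = np.asarray(pair_species)
        species = np.unique(pair_species)
        sp_type = _infer_species_labels(pair_species, types)
        Rp = np.broadcast_to(resid, (n_perm + 1, n)).copy()
        mats = [onehot]
        for _ in range(n_perm):
            perm = dict(zip(species, species[rng.permutation(len(species))]))
            relabeled = np.array([
                "".join(sorted(sp_type[perm[a]] + sp_type[perm[b]]))
                for a, b in pair_species
            ])
            mats.append(
                np.column_stack([(relabeled == t).astype(float) for t in PAIR_TYPES])
            )
        type_matrix = np.stack(mats)
    else:
        raise PairTestError(f"unknown permutation mode {mode!r}")

    if degenerate:
        stats = np.zeros(n_perm + 1)
        F_obs, p, Z = 0.0, 1.0, float("nan")
    else:
        if mode == "rows":
            stats = _group_f(Rp, onehot, cts)
        else:
            stats = np.array([
                _group_f(resid, type_matrix[k], type_matrix[k].sum(axis=0))
                for k in range(n_perm + 1)
            ])
        F_obs = float(stats[0])
        p = float(np.mean(stats >= F_obs))
        Z = _effect_size(stats, F_obs, stat_scale)

    # pairwise mean-difference contrasts on the same schedule
    contrasts = []
    for ta, tb in combinations(PAIR_TYPES, 2):
        ia, ib = PAIR_TYPES.index(ta), PAIR_TYPES.index(tb)
        if mode == "rows":
            means_p = (Rp @ onehot) / cts  # (P, 3)
            diffs = np.abs(means_p[:, ia] - means_p[:, ib])
        else:
            diffs = np.empty(n_perm + 1)
            for k in range(n_perm + 1):
                m = type_matrix[k]
                c = m.sum(axis=0)
                c[c == 0] = np.nan
                mm = (resid @ m) / c
                diffs[k] = abs(mm[ia] - mm[ib])
        d_obs = float(diffs[0])
        if degenerate:
            pc, zc = 1.0, float("nan")
        else:
            valid = np.isfinite(diffs)
            pc = float(np.mean(diffs[valid] >= d_obs))
            zc = _effect_size(diffs[valid], d_obs, stat_scale)
        contrasts.append(
            Contrast(
                type_a=ta,
                type_b=tb,
                mean_difference=float(
                    group_means[ta] - group_means[tb]
                ),
                Z=zc,
                p=pc,
                significant=bool(np.isfinite(zc) and zc > Z_CUTOFF),
            )
        )

    return PairTestResult(
        coefficients=np.array([]),
        residuals=resid,
        F_obs=F_obs,
        Z=Z,
        p=p,
        group_means=group_means,
        contrasts=contrasts,
        n_perm=n_perm,
        seed=seed,
        mode=mode,
        metadata={
            "caveat": (
                "pairs sharing a species are non-independent beyond the "
                "distance covariates; row permutation ignores this"
            )
        },
    )


def _infer_species_labels(pair_species: np.ndarray, types: np.ndarray) -> dict:
    """Recover per-species A/T labels from pair types (AA/AT/TT rows)."""
    label: dict = {}
    for (a, b), t in zip(pair_species, types):
        if t == "AA":
            label[a] = label[b] = "A"
        elif t == "TT":
            label[a] = label[b] = "T"
    for (a, b), t in zip(pair_species, types):
        if t == "AT":
            if a in label and b not in label:
                label[b] = "T" if label[a] == "A" else "A"
            elif b in label and a not in label:
                label[a] = "T" if label[b] == "A" else "A"
    missing = {s for pair in pair_species for s in pair} - set(label)
    if missing:
        raise PairTestError(
            f"cannot infer A/T labels for species {sorted(missing)}"
        )
    return label


def analyze_overlap(
    table: pd.DataFrame,
    metric: str = "D",
    n_perm: int = 999,
    seed: int | None = 0,
    mode: str = "rows",
) -> PairTestResult:
    """Residualize one overlap metric and run the pair-type test."""
    if metric not in table.columns:
        raise PairTestError(f"metric column {metric!r} not in table")
    resid, beta = residualize(
        table[metric].to_numpy(),
        table["geo_km"].to_numpy(),
        table["phylo_dist"].to_numpy(),
    )
    result = pair_type_test(
        resid,
        table["pair_type"].to_numpy(),
        n_perm=n_perm,
        seed=seed,
        mode=mode,
        pair_species=table[["species_a", "species_b"]].to_numpy()
        if mode == "species"
        else None,
    )
    result.coefficients = beta
    result.metadata["metric"] = metric
    return result
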