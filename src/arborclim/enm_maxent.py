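"""Presence-background maximum-entropy suitability models.

A species' niche model is the Gibbs distribution over background pixels

    p(x) = exp(w . f(x)) / sum_background exp(w . f(x'))

whose feature expectations match the presence sample, subject to an L2
penalty on the weights. Features are each climate variable's linear and
quadratic term, standardized by the background mean and SD. The problem
is convex, optimized by deterministic quasi-Newton (L-BFGS) from a zero
start, so fitting involves no randomness.

Model quality is summarized by the presence-background AUC: the
probability that a random presence pixel outscores a random background
pixel (ties count one half).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .raster import ClimateRaster

logger = logging.getLogger(__name__)

#: Minimum distinct presence pixels for a species to be modelled.
MIN_PRESENCE = 15


class MaxentError(ValueError):
    pass


class InsufficientPresenceError(MaxentError):
    """Species has too few distinct presence pixels for niche modelling."""


@dataclass
class SuitabilityModel:
    variable_codes: tuple[str, ...]
    bg_means: np.ndarray
    bg_sds: np.ndarray
    weights: np.ndarray  # (2 * n_vars,): linear then quadratic, interleaved
    log_normalizer: float  # log sum over the training background
    n_presence: int
    l2_penalty: float
    n_iter: int
    converged: bool
    auc: float | None = None

    def features(self, X: np.ndarray) -> np.ndarray:
        """Standardized linear + quadratic features, shape (n, 2*n_vars)."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.variable_codes):
            raise MaxentError(
                f"expected {len(self.variable_codes)} variables, got {X.shape[1]}"
            )
        z = (X - self.bg_means) / self.bg_sds
        return np.concatenate([z, z**2], axis=1)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Unnormalized log-suitability w . f(x)."""
        return self.features(X) @ self.weights


def _standardize_params(background: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = background.mean(axis=0)
    sd = background.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return mu, sd


def fit_maxent(
    presence: np.ndarray,
    background: np.ndarray,
    variable_codes: tuple[str, ...],
    l2_penalty: float = 0.01,
    max_iter: int = 500,
    tol: float = 1e-6,
    init: np.ndarray | None = None,
) -> SuitabilityModel:
    """Fit the penalized maximum-entropy model.

    ``presence`` and ``background`` are pixel climate matrices
    ``(n, n_vars)``; the background must be strictly larger than the
    presence set and presences need at least 15 distinct pixels.
    """
    presence = np.asarray(presence, dtype=float)
    background = np.asarray(background, dtype=float)
    n_pres = len(np.unique(presence, axis=0))
    if n_pres < MIN_PRESENCE:
        raise InsufficientPresenceError(
            f"{n_pres} distinct presence pixels < required {MIN_PRESENCE}"
        )
    if len(background) <= n_pres:
        raise MaxentError(
            "background must be strictly larger than the distinct presence set"
        )
    if not (np.isfinite(presence).all() and np.isfinite(background).all()):
        raise MaxentError("non-finite feature values in presence/background")

    mu, sd = _standardize_params(background)
    zb = (background - mu) / sd
    zp = (presence - mu) / sd
    Fb = np.concatenate([zb, zb**2], axis=1)
    Fp = np.concatenate([zp, zp**2], axis=1)
    f_pres_mean = Fp.mean(axis=0)

    def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
        eta = Fb @ w
        lse = logsumexp(eta)
        nll = -float(f_pres_mean @ w) + lse + l2_penalty * float(w @ w)
        q = np.exp(eta - lse)
        grad = -f_pres_mean + q @ Fb + 2.0 * l2_penalty * w
        return nll, grad

    w0 = np.zeros(Fb.shape[1]) if init is None else np.asarray(init, dtype=float)
    res = minimize(
        objective,
        w0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14},
    )
    grad_norm = float(np.max(np.abs(objective(res.x)[1])))
    converged = grad_norm <= max(tol, 1e-5)
    if not converged:
        logger.warning(
            "maxent did not converge (grad norm %.3g after %d iters)",
            grad_norm,
            res.nit,
        )
    model = SuitabilityModel(
        variable_codes=tuple(variable_codes),
        bg_means=mu,
        bg_sds=sd,
        weights=res.x,
        log_normalizer=float(logsumexp(Fb @ res.x)),
        n_presence=int(n_pres),
        l2_penalty=l2_penalty,
        n_iter=int(res.nit),
        converged=converged,
    )
    model.auc = auc_presence_background(model, presence, background)
    return model


def project_suitability(
    model: SuitabilityModel, raster: ClimateRaster
) -> np.ndarray:
    """Per-pixel suitability surface, normalized to sum 1 over valid pixels."""
    missing = [c for c in model.variable_codes if c not in raster.variable_codes]
    if missing:
        raise MaxentError(f"raster lacks model variables: {missing}")
    if tuple(raster.variable_codes) != tuple(model.variable_codes):
        # reorder raster layers to the model's variable order
        sel = [raster.variable_codes.index(c) for c in model.variable_codes]
        values = raster.values[sel]
    else:
        values = raster.values
    rows, cols = np.nonzero(raster.validity_mask)
    X = values[:, rows, cols].T
    eta = model.scores(X)
    p = np.exp(eta - logsumexp(eta))
    surface = np.zeros((raster.n_rows, raster.n_cols))
    surface[rows, cols] = p
    return surface


def auc_presence_background(
    model: SuitabilityModel, presence: np.ndarray, background: np.ndarray
) -> float:
    """Probability a random presence outscores a random background pixel.

    Rank (Mann-Whitney) formulation; ties count 0.5.
    """
    presence = np.asarray(presence, dtype=float)
    background = np.asarray(background, dtype=float)
    if len(presence) == 0 or len(background) == 0:
        raise MaxentError("presence and background sets must be nonempty")
    sp = model.scores(presence)
    sb = model.scores(background)
    ranks = rankdata(np.concatenate([sp, sb]))
    n_p, n_b = len(sp), len(sb)
    u = ranks[:n_p].sum() - n_p * (n_p + 1) / 2.0
    return float(u / (n_p * n_b))


# ----------------------------------------------------------------------
# plain-text serialization
# ----------------------------------------------------------------------

def write_model_text(model: SuitabilityModel, path: str | Path) -> None:
    lines = [
        "format: arborclim-maxent-1",
        "variables: " + ",".join(model.variable_codes),
        "bg_means: " + ",".join(repr(float(v)) for v in model.bg_means),
        "bg_sds: " + ",".join(repr(float(v)) for v in model.bg_sds),
        "weights: " + ",".join(repr(float(v)) for v in model.weights),
        f"log_normalizer: {float(model.log_normalizer)!r}",
        f"n_presence: {model.n_presence}",
        f"l2_penalty: {float(model.l2_penalty)!r}",
        f"n_iter: {model.n_iter}",
        f"converged: {model.converged}",
        f"auc: {None if model.auc is None else float(model.auc)!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_model_text(path: str | Path) -> SuitabilityModel:
    kv = {}
    for line in Path(path).read_text().splitlines():
        key, _, val = line.partition(": ")
        kv[key.rstrip(":")] = val
    if kv.get("format") != "arborclim-maxent-1":
        raise MaxentError(f"unrecognized model file format in {path}")
    arr = lambda s: np.array([float(x) for x in s.split(",")])
    return SuitabilityModel(
        variable_codes=tuple(kv["variables"].split(",")),
        bg_means=arr(kv["bg_means"]),
        bg_sds=arr(kv["bg_sds"]),
        weights=arr(kv["weights"]),
        log_normalizer=float(kv["log_normalizer"]),
        n_presence=int(kv["n_presence"]),
        l2_penalty=float(kv["l2_penalty"]),
        n_iter=int(kv["n_iter"]),
        converged=kv["converged"] == "True",
        auc=None if kv["auc"] == "None" else float(kv["auc"]),
    )
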