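"""Synthetic study worlds with known, configurable effect sizes.

Every downstream stage (envelope summarization, phylogenetic ANOVA, niche
modelling, overlap testing) is exercised on worlds generated here:
spatially autocorrelated, cross-correlated climate layers with a
latitudinal temperature gradient; a pure-birth chronogram; arboreal /
terrestrial labels evolved under an asymmetric two-state Markov process;
Brownian-motion niche centers with an additive arboreal shift; and
occurrences sampled from Gaussian niche suitability.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import VARIABLE_CODES, ClimateRaster


class WorldConfigError(ValueError):
    """Raised when a world configuration violates its invariants."""


class SamplingError(RuntimeError):
    """Raised when occurrence sampling cannot produce valid points."""


N_VARS = len(VARIABLE_CODES)

#: Per-variable (mean, sd) in native units the synthetic layers are scaled
#: to. Loosely modelled on new-world temperate-to-tropical climate ranges:
#: temperatures in deg C, precipitation in mm, PET in mm/yr, elevation in m,
#: climatic moisture as an index, cloud cover in percent.
VARIABLE_BASELINES: dict[str, tuple[float, float]] = {
    "BIO1": (15.0, 6.0),
    "BIO5": (28.0, 6.0),
    "BIO6": (2.0, 7.0),
    "BIO12": (1200.0, 500.0),
    "BIO16": (500.0, 220.0),
    "BIO17": (120.0, 90.0),
    "PET.A": (1000.0, 250.0),
    "PET.W": (350.0, 120.0),
    "PET.D": (180.0, 80.0),
    "Elev": (800.0, 550.0),
    "CM": (0.3, 0.5),
    "CC": (55.0, 15.0),
}

BASELINE_MEANS = np.array([VARIABLE_BASELINES[c][0] for c in VARIABLE_CODES])
BASELINE_SDS = np.array([VARIABLE_BASELINES[c][1] for c in VARIABLE_CODES])


def default_layer_correlation() -> np.ndarray:
    """A realistic positive-semi-definite correlation among the 12 layers.

    Temperature variables correlate strongly with each other and with PET;
    precipitation variables with each other and climatic moisture;
    elevation anti-correlates with temperature. Built from a factor model
    (two latent axes: thermal and hygric), which guarantees PSD.
    """
    # loadings on (thermal, hygric) latent factors
    load = np.array([
        [0.85, 0.10],   # BIO1
        [0.75, -0.05],  # BIO5
        [0.80, 0.15],   # BIO6
        [0.05, 0.80],   # BIO12
        [0.05, 0.75],   # BIO16
        [0.10, 0.60],   # BIO17
        [0.80, -0.10],  # PET.A
        [0.70, 0.00],   # PET.W
        [0.60, -0.20],  # PET.D
        [-0.65, 0.05],  # Elev
        [-0.20, 0.70],  # CM
        [-0.10, 0.50],  # CC
    ])
    corr = load @ load.T
    np.fill_diagonal(corr, 1.0)
    return corr


def _default_arboreal_shift() -> np.ndarray:
    """Default injected effect: arboreal niches warmer, lower, higher PET.

    Roughly one global SD on the temperature variables and elevation,
    smaller on PET, zero on precipitation/moisture/cloud.
    """
    shift = np.zeros(N_VARS)
    idx = {c: i for i, c in enumerate(VARIABLE_CODES)}
    shift[idx["BIO1"]] = 1.0 * VARIABLE_BASELINES["BIO1"][1]
    shift[idx["BIO5"]] = 0.7 * VARIABLE_BASELINES["BIO5"][1]
    shift[idx["BIO6"]] = 1.0 * VARIABLE_BASELINES["BIO6"][1]
    shift[idx["PET.A"]] = 0.4 * VARIABLE_BASELINES["PET.A"][1]
    shift[idx["Elev"]] = -1.0 * VARIABLE_BASELINES["Elev"][1]
    return shift


@dataclass
class WorldConfig:
    """Full recipe for one synthetic world.

    Defaults describe the study conditions used throughout the test suite:
    a desk-scale stand-in for the real system (hundreds of species over a
    continental 2.5 arc-minute raster) with a strong arboreal climate
    shift on the temperature/elevation axes.
    """

    n_species: int = 60
    grid_rows: int = 80
    grid_cols: int = 80
    lon_origin: float = -100.0
    lat_origin: float = 35.0
    pixel_size: float = 2.5  # arc-minutes
    smoothing_radius: float = 2.0  # pixels; Gaussian sigma
    layer_correlation: np.ndarray = field(default_factory=default_layer_correlation)
    temp_lat_gradient: float = 0.7  # deg C lost per degree |latitude|
    birth_rate: float = 1.0
    gain_rate: float = 0.3  # terrestrial -> arboreal, per unit time
    loss_rate: float = 0.9  # arboreal -> terrestrial; loss-biased asymmetry
    root_state: str = "terrestrial"
    bm_sigma: np.ndarray = field(default_factory=lambda: 0.4 * BASELINE_SDS)
    arboreal_shift: np.ndarray = field(default_factory=_default_arboreal_shift)
    niche_breadth: np.ndarray = field(default_factory=lambda: 0.6 * BASELINE_SDS)
    points_per_species: tuple[int, int] = (20, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        self.layer_correlation = np.asarray(self.layer_correlation, dtype=float)
        self.bm_sigma = np.broadcast_to(
            np.asarray(self.bm_sigma, dtype=float), (N_VARS,)
        ).copy()
        self.arboreal_shift = np.broadcast_to(
            np.asarray(self.arboreal_shift, dtype=float), (N_VARS,)
        ).copy()
        self.niche_breadth = np.broadcast_to(
            np.asarray(self.niche_breadth, dtype=float), (N_VARS,)
        ).copy()
        self.validate()

    def validate(self) -> None:
        if self.n_species < 2:
            raise WorldConfigError("n_species must be at least 2")
        if min(self.grid_rows, self.grid_cols) < 1:
            raise WorldConfigError("grid dimensions must be positive")
        if self.pixel_size <= 0:
            raise WorldConfigError("pixel_size must be positive")
        if self.smoothing_radius < 0:
            raise WorldConfigError("smoothing_radius must be >= 0")
        if self.birth_rate <= 0:
            raise WorldConfigError("birth_rate must be positive")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise WorldConfigError("transition rates must be >= 0")
        if np.any(self.bm_sigma < 0):
            raise WorldConfigError("bm_sigma must be >= 0")
        if np.any(self.niche_breadth <= 0):
            raise WorldConfigError("niche_breadth must be strictly positive")
        R = self.layer_correlation
        if R.shape != (N_VARS, N_VARS):
            raise WorldConfigError("layer_correlation must be 12x12")
        if not np.allclose(R, R.T, atol=1e-10):
            raise WorldConfigError("layer_correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise WorldConfigError("layer_correlation must have unit diagonal")
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-10:
            raise WorldConfigError(
                f"layer_correlation is not positive semi-definite "
                f"(min eigenvalue {eig.min():.3g})"
            )
        lo, hi = self.points_per_species
        if lo < 1 or hi < lo:
            raise WorldConfigError("points_per_species must be a valid range")


# ----------------------------------------------------------------------
# climate raster
# ----------------------------------------------------------------------

def generate_climate_raster(config: WorldConfig) -> ClimateRaster:
    """Simulate the 12-layer climate raster.

    Independent standard-normal fields are mixed through a symmetric square
    root of ``layer_correlation``, Gaussian-smoothed for spatial
    autocorrelation, re-standardized per layer, scaled to each variable's
    native units, and given a deterministic latitudinal gradient on BIO1.
    Elevation is clipped at zero.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    z = rng.standard_normal((N_VARS,) + shape)

    # cross-layer mix by symmetric PSD square root
    w, V = np.linalg.eigh(config.layer_correlation)
    A = (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T
    mixed = np.tensordot(A, z, axes=(1, 0))

    if config.smoothing_radius > 0:
        for i in range(N_VARS):
            mixed[i] = ndimage.gaussian_filter(
                mixed[i], sigma=config.smoothing_radius, mode="reflect"
            )
        # restore unit variance (same factor structure, so cross-layer
        # correlation is preserved)
        sds = mixed.reshape(N_VARS, -1).std(axis=1, ddof=0)
        sds[sds == 0] = 1.0
        mixed /= sds[:, None, None]

    values = BASELINE_MEANS[:, None, None] + BASELINE_SDS[:, None, None] * mixed

    # deterministic latitudinal trend on BIO1: cooler away from the equator,
    # centered so the grid mean is unchanged
    lat = config.lat_origin - (np.arange(config.grid_rows) + 0.5) * (
        config.pixel_size / 60.0
    )
    trend = -config.temp_lat_gradient * np.abs(lat)
    trend = trend - trend.mean()
    bio1 = VARIABLE_CODES.index("BIO1")
    values[bio1] += trend[:, None]

    elev = VARIABLE_CODES.index("Elev")
    values[elev] = np.clip(values[elev], 0.0, None)

    return ClimateRaster(
        values=values,
        lon_origin=config.lon_origin,
        lat_origin=config.lat_origin,
        pixel_size=config.pixel_size,
    )


# ----------------------------------------------------------------------
# chronogram
# ----------------------------------------------------------------------

def simulate_chronogram(
    n_species: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Pure-birth (Yule) chronogram conditioned on the tip count.

    Lineages split at rate ``birth_rate`` each. The process starts at the
    root split (two lineages), grows until ``n_species`` tips exist, then
    runs one further exponential waiting time with all ``n_species``
    lineages extant; the tree is cut there, so it is ultrametric with
    height distributed as the sum of Exp(k*birth_rate) intervals for
    k = 2..n_species.
    """
    if n_species < 2:
        raise ValueError("n_species must be at least 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    # children[i] = (a, b) node indices or None for a tip; birth_time[i]
    children: list[tuple[int, int] | None] = [None]
    birth_time = [0.0]
    active = [0]
    t = 0.0
    next_id = 1
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        pick = int(rng.integers(k))
        node = active.pop(pick)
        a, b = next_id, next_id + 1
        next_id += 2
        children[node] = (a, b)
        children.extend([None, None])
        birth_time.extend([t, t])
        active.extend([a, b])
    t_end = t + rng.exponential(1.0 / (birth_rate * n_species))

    # label tips in index order for stable naming
    labels = {}
    width = max(3, len(str(n_species)))
    counter = 0
    for i, ch in enumerate(children):
        if ch is None:
            counter += 1
            labels[i] = f"sp{counter:0{width}d}"

    # build the newick string iteratively to avoid recursion-depth limits
    nwk = _newick_string(children, birth_time, labels, t_end)
    tree = dendropy.Tree.get(data=nwk + ";", schema="newick")
    tree.seed_node.edge.length = None
    return tree


def _newick_string(children, birth_time, labels, t_end) -> str:
    # a node's edge runs from its birth (parent's split) to its own split
    # (= its children's birth time), or to t_end for a tip
    length = {}
    for i, ch in enumerate(children):
        end = t_end if ch is None else birth_time[ch[0]]
        length[i] = end - birth_time[i]
    expr: dict[int, str] = {}
    stack = [(0, False)]
    while stack:
        node, done = stack.pop()
        ch = children[node]
        if ch is None:
            expr[node] = f"{labels[node]}:{t_end - birth_time[node]!r}"
            continue
        if not done:
            stack.append((node, True))
            stack.extend((c, False) for c in ch)
        else:
            a, b = ch
            expr[node] = f"({expr[a]},{expr[b]}):{length[node]!r}"
    return expr[0]


def tree_height(tree: dendropy.Tree) -> float:
    """Root-to-tip depth (max over tips)."""
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def write_newick(trees, path) -> None:
    """Write one tree (or an iterable of trees) as Newick, one per line."""
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick", suppress_rooting=True).strip())
            fh.write("\n")


def read_newick(path) -> list[dendropy.Tree]:
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    return list(trees)


# ----------------------------------------------------------------------
# microhabitat evolution
# ----------------------------------------------------------------------

ARBOREAL = "arboreal"
TERRESTRIAL = "terrestrial"


def _transition_probs(state: str, gain: float, loss: float, t: float) -> float:
    """P(end = arboreal | start = state) for the 2-state chain after time t."""
    s = gain + loss
    if s == 0:
        return 1.0 if state == ARBOREAL else 0.0
    pi_a = gain / s
    decay = np.exp(-s * t)
    start_a = 1.0 if state == ARBOREAL else 0.0
    return pi_a + (start_a - pi_a) * decay


def assign_microhabitats(
    tree: dendropy.Tree,
    gain_rate: float,
    loss_rate: float,
    root_state: str = TERRESTRIAL,
    seed: int = 0,
) -> dict[str, str]:
    """Evolve arboreal/terrestrial labels along the tree.

    A two-state continuous-time Markov chain with gain (terrestrial ->
    arboreal) and loss (arboreal -> terrestrial) rates; states are sampled
    node by node from the exact endpoint transition probabilities.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("transition rates must be >= 0")
    if root_state not in (ARBOREAL, TERRESTRIAL):
        raise ValueError(f"unknown root_state {root_state!r}")
    rng = np.random.default_rng(seed)
    states: dict[int, str] = {id(tree.seed_node): root_state}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        p_arb = _transition_probs(parent_state, gain_rate, loss_rate, t)
        states[id(node)] = ARBOREAL if rng.random() < p_arb else TERRESTRIAL
    return {
        leaf.taxon.label: states[id(leaf)] for leaf in tree.leaf_node_iter()
    }


# ----------------------------------------------------------------------
# niche centers
# ----------------------------------------------------------------------

def evolve_niche_centers(
    tree: dendropy.Tree,
    labels: dict[str, str],
    bm_sigma: np.ndarray,
    arboreal_shift: np.ndarray,
    root_value: np.ndarray,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Brownian-motion niche centers with an additive arboreal offset.

    Each branch adds independent Gaussian increments with per-variable
    standard deviation ``bm_sigma * sqrt(branch length)``; arboreal tips
    then receive ``arboreal_shift`` on top of their Brownian value.
    """
    bm_sigma = np.broadcast_to(np.asarray(bm_sigma, float), (N_VARS,))
    if np.any(bm_sigma < 0):
        raise ValueError("bm_sigma must be >= 0")
    arboreal_shift = np.broadcast_to(np.asarray(arboreal_shift, float), (N_VARS,))
    root_value = np.broadcast_to(np.asarray(root_value, float), (N_VARS,))
    rng = np.random.default_rng(seed)
    values: dict[int, np.ndarray] = {id(tree.seed_node): root_value.copy()}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = values[id(node.parent_node)]
        t = node.edge.length or 0.0
        step = rng.standard_normal(N_VARS) * bm_sigma * np.sqrt(t)
        values[id(node)] = parent + step
    centers = {}
    for leaf in tree.leaf_node_iter():
        v = values[id(leaf)].copy()
        if labels.get(leaf.taxon.label) == ARBOREAL:
            v = v + arboreal_shift
        centers[leaf.taxon.label] = v
    return centers


# ----------------------------------------------------------------------
# occurrence sampling
# ----------------------------------------------------------------------

def suitability_surface(
    center: np.ndarray, niche_breadth: np.ndarray, raster: ClimateRaster
) -> np.ndarray:
    """Product-Gaussian suitability of each valid pixel around ``center``.

    Returned as a probability over valid pixels (sums to 1); invalid
    pixels are zero.
    """
    center = np.broadcast_to(np.asarray(center, float), (N_VARS,))
    breadth = np.broadcast_to(np.asarray(niche_breadth, float), (N_VARS,))
    rows, cols, X = raster.valid_pixel_matrix()
    logs = -0.5 * (((X - center) / breadth) ** 2).sum(axis=1)
    if not np.isfinite(logs).any():
        raise SamplingError("suitability undefined on every valid pixel")
    m = logs.max()
    if m < -700.0:
        raise SamplingError(
            "all-zero suitability: niche center lies too far outside the "
            f"raster climate (best log-suitability {m:.1f})"
        )
    p = np.exp(logs - m)
    p /= p.sum()
    surface = np.zeros((raster.n_rows, raster.n_cols))
    surface[rows, cols] = p
    return surface


def sample_occurrences(
    center: np.ndarray,
    niche_breadth: np.ndarray,
    raster: ClimateRaster,
    n_points: int,
    seed: int = 0,
    species_id: str = "sp",
) -> pd.DataFrame:
    """Sample occurrence points at pixel centers, by niche suitability."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    rows, cols, X = raster.valid_pixel_matrix()
    center = np.broadcast_to(np.asarray(center, float), (N_VARS,))
    breadth = np.broadcast_to(np.asarray(niche_breadth, float), (N_VARS,))
    logs = -0.5 * (((X - center) / breadth) ** 2).sum(axis=1)
    m = logs.max()
    if m < -700.0:
        raise SamplingError(
            "all-zero suitability: niche center lies too far outside the "
            f"raster climate (best log-suitability {m:.1f})"
        )
    p = np.exp(logs - m)
    p /= p.sum()
    idx = rng.choice(len(p), size=n_points, p=p)
    lon, lat = raster.pixel_center(rows[idx], cols[idx])
    return pd.DataFrame(
        {"species": species_id, "longitude": lon, "latitude": lat}
    )


# ----------------------------------------------------------------------
# whole worlds
# ----------------------------------------------------------------------

@dataclass
class World:
    """A complete synthetic study system."""

    config: WorldConfig
    raster: ClimateRaster
    tree: dendropy.Tree
    labels: dict[str, str]
    niche_centers: dict[str, np.ndarray]
    occurrences: pd.DataFrame
    microhabitats: pd.DataFrame  # species, primary, secondary, mcentire, sw_override

    @property
    def species(self) -> list[str]:
        return sorted(self.labels)


def build_world(config: WorldConfig) -> World:
    """Generate raster, chronogram, labels, niche centers and occurrences."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    raster = generate_climate_raster(replace(config, seed=seeds[0]))
    tree = simulate_chronogram(config.n_species, config.birth_rate, seeds[1])
    labels = assign_microhabitats(
        tree, config.gain_rate, config.loss_rate, config.root_state, seeds[2]
    )
    centers = evolve_niche_centers(
        tree,
        labels,
        config.bm_sigma,
        config.arboreal_shift,
        BASELINE_MEANS,
        seeds[3],
    )
    rng = np.random.default_rng(seeds[4])
    lo, hi = config.points_per_species
    frames = []
    for sp in sorted(labels):
        n = int(rng.integers(lo, hi + 1))
        pt_seed = int(rng.integers(2**31))
        frames.append(
            sample_occurrences(
                centers[sp], config.niche_breadth, raster, n, pt_seed, sp
            )
        )
    occurrences = pd.concat(frames, ignore_index=True)
    micro = pd.DataFrame(
        {
            "species": sorted(labels),
            "primary": ["A" if labels[s] == ARBOREAL else "T" for s in sorted(labels)],
            "secondary": [None] * len(labels),
            "mcentire_arboreal": [False] * len(labels),
            "sw_override": [None] * len(labels),
        }
    )
    return World(
        config=config,
        raster=raster,
        tree=tree,
        labels=labels,
        niche_centers=centers,
        occurrences=occurrences,
        microhabitats=micro,
    )


def sample_posterior_trees(
    tree: dendropy.Tree, n_trees: int, jitter_sd: float = 0.1, seed: int = 0
) -> list[dendropy.Tree]:
    """Stand-in for a posterior chronogram sample: node-age jitter.

    Synthetic: the topology is fixed and each internal node age is
    perturbed by an independent lognormal factor, constrained (postorder)
    to stay above its children, then the whole tree is rescaled by a
    global lognormal rate factor. Emulates posterior divergence-time
    spread without rerunning any inference.
    """
    rng = np.random.default_rng(seed)
    out = []
    base = tree.as_string(schema="newick")
    for _ in range(n_trees):
        t = dendropy.Tree.get(data=base, schema="newick")
        t.calc_node_ages(ultrametricity_precision=1e-6)
        scale = float(np.exp(rng.normal(0.0, jitter_sd)))
        new_age: dict[int, float] = {}
        for node in t.postorder_node_iter():
            if node.is_leaf():
                new_age[id(node)] = 0.0
                continue
            jit = float(np.exp(rng.normal(0.0, jitter_sd)))
            age = node.age * jit
            floor_age = max(new_age[id(c)] for c in node.child_nodes())
            new_age[id(node)] = max(age, floor_age * 1.0001 + 1e-9)
        for node in t.postorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = (
                    new_age[id(node.parent_node)] - new_age[id(node)]
                ) * scale
        out.append(t)
    return out


def simulate_pair_overlap_table(
    n_species: int = 24,
    arboreal_fraction: float = 0.4,
    type_effects: dict[str, float] | None = None,
    beta_geo: float = -5e-5,
    beta_phylo: float = -0.03,
    noise_sd: float = 0.05,
    base_overlap: float = 0.5,
    clustered_labels: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Pair-level overlap table with a built-in pair-type effect.

    Species get random mean points and a pure-birth tree; overlap for each
    pair is a linear function of geographic and phylogenetic distance plus
    the pair-type effect plus Gaussian noise. ``type_effects`` maps
    AA/AT/TT to additive offsets (default zero: a null world). With
    ``clustered_labels`` the arboreal species are the phylogenetically
    closest block (one clade-like cluster) instead of a random draw.
    """
    from .niche_overlap import great_circle_km
    from .rrpp_models import phylo_covariance, phylo_pair_distance

    if type_effects is None:
        type_effects = {"AA": 0.0, "AT": 0.0, "TT": 0.0}
    rng = np.random.default_rng(seed)
    tree = simulate_chronogram(n_species, 1.0, int(rng.integers(2**31)))
    C, species = phylo_covariance(tree)
    pd_mat = phylo_pair_distance(C)
    n_arb = max(2, int(round(arboreal_fraction * n_species)))
    is_arb = np.zeros(n_species, dtype=bool)
    if clustered_labels:
        # the seed species plus its nearest relatives form the arboreal set
        anchor = int(rng.integers(n_species))
        nearest = np.argsort(pd_mat[anchor])[:n_arb]
        is_arb[nearest] = True
    else:
        is_arb[rng.choice(n_species, size=n_arb, replace=False)] = True
    lon = rng.uniform(-110, -60, n_species)
    lat = rng.uniform(-10, 40, n_species)
    rows = []
    for i in range(n_species):
        for j in range(i + 1, n_species):
            ptype = "".join(sorted(
                ("A" if is_arb[i] else "T") + ("A" if is_arb[j] else "T")
            ))
            geo = great_circle_km((lon[i], lat[i]), (lon[j], lat[j]))
            phylo = pd_mat[i, j]
            overlap = (
                base_overlap
                + beta_geo * geo
                + beta_phylo * phylo
                + type_effects[ptype]
                + rng.normal(0.0, noise_sd)
            )
            rows.append(
                {
                    "species_a": species[i],
                    "species_b": species[j],
                    "pair_type": ptype,
                    "overlap": overlap,
                    "geo_km": geo,
                    "phylo_dist": phylo,
                }
            )
    return pd.DataFrame(rows)
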