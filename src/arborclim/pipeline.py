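"""Config-driven orchestration of the full analysis.

Two entry points mirror the study's two arms:

* :func:`run_comparative` — species climate envelopes, standardization,
  PCA, and the family of phylogenetic ANOVAs (all statistics jointly,
  the first five PC axes, and each climate variable as a five-dimensional
  block), with Holm sequential Bonferroni within the PC family and within
  the per-variable family, an optional tropical-species subset, and
  optional posterior-chronogram robustness intervals.
* :func:`run_enm` — per-species maximum-entropy niche models, the
  pairwise overlap table (Schoener's D, Warren's I, geographic and
  phylogenetic distance), and the residualized pair-type tests.

Inputs are either a synthetic :class:`~arborclim.synthetic_world.WorldConfig`
or paths to delimited-text occurrence/microhabitat tables, a plain-text
raster bundle, and Newick trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .climate_summaries import (
    extract_climate,
    pca,
    prune_to_pixels,
    standardize_matrix,
    summarize_species,
    summary_matrix,
)
from .enm_maxent import InsufficientPresenceError, fit_maxent, project_suitability
from .microhabitat_schemes import SCHEMES, classify_table
from .niche_overlap import build_pair_table
from .pair_residual_analysis import PairTestResult, analyze_overlap
from .raster import ClimateRaster, read_raster_text
from .rrpp_models import (
    pairwise_comparisons,
    phylo_covariance,
    posterior_robustness,
    rrpp_anova,
    sequential_bonferroni,
)
from .synthetic_world import (
    World,
    WorldConfig,
    build_world,
    read_newick,
    sample_posterior_trees,
)

logger = logging.getLogger(__name__)

#: Tropic of Cancer/Capricorn latitude used for the tropical subset.
TROPICAL_LATITUDE = 23.43655


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """One analysis run: either a synthetic world or input paths."""

    world: WorldConfig | None = None
    paths: dict | None = None  # occurrences, raster_dir, microhabitats, tree
    scheme: str = "6-M"
    comparative_floor: int = 3
    enm_floor: int = 15
    n_perm: int = 999
    family_alpha: float = 0.05
    tropical_filter: bool = False
    tropical_latitude: float = TROPICAL_LATITUDE
    n_posterior_trees: int = 0
    posterior_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.world is None) == (self.paths is None):
            raise PipelineError("supply exactly one of world or paths")
        if self.scheme not in SCHEMES:
            raise PipelineError(f"unknown scheme {self.scheme!r}")
        if self.comparative_floor < 1 or self.enm_floor < 1:
            raise PipelineError("floors must be >= 1")
        if self.n_perm < 99:
            raise PipelineError("n_perm must be >= 99")

    def hash(self) -> str:
        payload = {
            "world": None if self.world is None else repr(self.world),
            "paths": self.paths,
            "scheme": self.scheme,
            "comparative_floor": self.comparative_floor,
            "enm_floor": self.enm_floor,
            "n_perm": self.n_perm,
            "family_alpha": self.family_alpha,
            "tropical_filter": self.tropical_filter,
            "tropical_latitude": self.tropical_latitude,
            "n_posterior_trees": self.n_posterior_trees,
            "posterior_jitter": self.posterior_jitter,
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class Inputs:
    raster: ClimateRaster
    occurrences: pd.DataFrame
    microhabitats: pd.DataFrame
    tree: dendropy.Tree
    posterior_trees: list | None = None


def load_inputs(config: RunConfig) -> Inputs:
    if config.world is not None:
        world: World = build_world(config.world)
        post = (
            sample_posterior_trees(
                world.tree,
                config.n_posterior_trees,
                config.posterior_jitter,
                seed=config.seed + 1,
            )
            if config.n_posterior_trees
            else None
        )
        return Inputs(
            raster=world.raster,
            occurrences=world.occurrences,
            microhabitats=world.microhabitats,
            tree=world.tree,
            posterior_trees=post,
        )
    paths = config.paths
    raster = read_raster_text(paths["raster_dir"])
    occurrences = pd.read_csv(paths["occurrences"])
    micro = pd.read_csv(paths["microhabitats"])
    trees = read_newick(paths["tree"])
    post = None
    if "posterior_trees" in paths and paths["posterior_trees"]:
        post = read_newick(paths["posterior_trees"])
    return Inputs(
        raster=raster,
        occurrences=occurrences,
        microhabitats=micro,
        tree=trees[0],
        posterior_trees=post,
    )


def prune_tree(tree: dendropy.Tree, species: list[str]) -> dendropy.Tree:
    pruned = tree.extract_tree_with_taxa_labels(labels=set(species))
    return pruned


# ----------------------------------------------------------------------
# comparative arm
# ----------------------------------------------------------------------

@dataclass
class ComparativeReport:
    table2: pd.DataFrame  # Variable, Z, P, Alpha, Significant
    table3: pd.DataFrame  # per-axis variance fraction, overall/pairwise Z & P
    summaries: pd.DataFrame
    pca_variance: np.ndarray
    species: list[str]
    groups: list[str]
    robustness_interval: tuple[float, float] | None
    config_hash: str
    seed: int
    version: str = __version__

    def provenance(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
        }


def _species_groups(
    summaries: pd.DataFrame,
    micro_wide: pd.DataFrame,
    scheme: str,
) -> pd.Series:
    lookup = micro_wide.set_index("species")[scheme]
    return summaries["species"].map(lookup)


def run_comparative(config: RunConfig) -> ComparativeReport:
    inputs = load_inputs(config)
    raster = inputs.raster

    pruned = prune_to_pixels(inputs.occurrences, raster)
    values = extract_climate(pruned, raster)
    summaries = summarize_species(
        values, raster.variable_codes, min_pixels=config.comparative_floor
    )
    if summaries.empty:
        raise PipelineError("no species cleared the comparative pixel floor")

    micro_wide = classify_table(inputs.microhabitats)
    groups_all = _species_groups(summaries, micro_wide, config.scheme)
    summaries = summaries.loc[groups_all.notna()].reset_index(drop=True)
    groups_all = groups_all.dropna().reset_index(drop=True)

    # restrict to the arboreal/terrestrial grouping factor
    keep = groups_all.isin(["A", "T"])
    if config.tropical_filter:
        mean_lat = summaries["species"].map(
            pruned.groupby("species")["latitude"].mean()
        )
        keep &= mean_lat.abs() <= config.tropical_latitude
    summaries = summaries.loc[keep].reset_index(drop=True)
    groups = groups_all.loc[keep].to_numpy()
    if len(set(groups)) < 2 or min(np.bincount(pd.factorize(groups)[0])) < 2:
        raise PipelineError(
            "fewer than 2 usable microhabitat groups after filtering"
        )

    species = summaries["species"].tolist()
    tree = prune_tree(inputs.tree, species)
    C, tree_species = phylo_covariance(tree)
    order = [tree_species.index(sp) for sp in species]
    C = C[np.ix_(order, order)]

    X, _, columns = summary_matrix(summaries, raster.variable_codes)
    Xz = standardize_matrix(X, columns)

    rows = []  # table2-shaped records
    # (i) all statistics jointly: its own family of one
    seed0 = config.seed
    overall_all = rrpp_anova(Xz, groups, C, n_perm=config.n_perm, seed=seed0)
    pair_all = pairwise_comparisons(
        Xz, groups, C, n_perm=config.n_perm, seed=seed0
    )[0]
    rows.append(
        {
            "Variable": "All",
            "Z": pair_all.Z,
            "P": pair_all.p,
            "Alpha": config.family_alpha,
            "Significant": pair_all.p <= config.family_alpha,
        }
    )

    # (ii) first five PC axes, each a univariate test; Holm family of 5
    pca_res = pca(Xz, n_axes=5)
    pc_overall, pc_pair = [], []
    for k in range(pca_res.n_axes):
        yk = pca_res.scores[:, [k]]
        pc_overall.append(
            rrpp_anova(yk, groups, C, n_perm=config.n_perm, seed=seed0 + 10 + k)
        )
        pc_pair.append(
            pairwise_comparisons(
                yk, groups, C, n_perm=config.n_perm, seed=seed0 + 10 + k
            )[0]
        )
    holm_pc = sequential_bonferroni(
        [c.p for c in pc_pair], config.family_alpha
    )
    for k, comp in enumerate(pc_pair):
        rows.append(
            {
                "Variable": f"PC{k + 1}",
                "Z": comp.Z,
                "P": comp.p,
                "Alpha": holm_pc.adjusted_alpha[k],
                "Significant": bool(holm_pc.significant[k]),
            }
        )

    # (iii) each climate variable as its 5-statistic block (native units);
    # Holm family of 12
    var_pair = []
    for v, code in enumerate(raster.variable_codes):
        block = X[:, 5 * v : 5 * v + 5]
        var_pair.append(
            pairwise_comparisons(
                block, groups, C, n_perm=config.n_perm, seed=seed0 + 100 + v
            )[0]
        )
    holm_var = sequential_bonferroni(
        [c.p for c in var_pair], config.family_alpha
    )
    for v, code in enumerate(raster.variable_codes):
        rows.append(
            {
                "Variable": code,
                "Z": var_pair[v].Z,
                "P": var_pair[v].p,
                "Alpha": holm_var.adjusted_alpha[v],
                "Significant": bool(holm_var.significant[v]),
            }
        )

    table2 = pd.DataFrame(rows)

    table3 = pd.DataFrame(
        {
            f"PC{k + 1}": {
                "Variation": 100.0 * pca_res.variance_fraction[k],
                "Overall Z": pc_overall[k].Z,
                "Overall P": pc_overall[k].p,
                "Pairwise Z": pc_pair[k].Z,
                "Pairwise P": pc_pair[k].p,
                "Alpha": holm_pc.adjusted_alpha[k],
            }
            for k in range(pca_res.n_axes)
        }
    )

    interval = None
    if inputs.posterior_trees:
        rob = posterior_robustness(
            Xz,
            groups,
            species,
            inputs.posterior_trees,
            n_perm=config.n_perm,
            seed=config.seed + 1000,
            pairwise=("A", "T"),
        )
        interval = rob.interval

    return ComparativeReport(
        table2=table2,
        table3=table3,
        summaries=summaries,
        pca_variance=pca_res.variance_fraction,
        species=species,
        groups=list(groups),
        robustness_interval=interval,
        config_hash=config.hash(),
        seed=config.seed,
    )


# ----------------------------------------------------------------------
# niche-modelling arm
# ----------------------------------------------------------------------

@dataclass
class ENMReport:
    pair_table: pd.DataFrame
    model_stats: pd.DataFrame  # species, n_presence, auc, converged
    results: dict[str, PairTestResult]  # per metric ("D", "I")
    group_means: pd.DataFrame  # Fig-3-shaped: residual group means per metric
    config_hash: str
    seed: int
    version: str = __version__


def run_enm(config: RunConfig) -> ENMReport:
    inputs = load_inputs(config)
    raster = inputs.raster

    pruned = prune_to_pixels(inputs.occurrences, raster)
    values = extract_climate(pruned, raster)
    micro_wide = classify_table(inputs.microhabitats)
    lookup = micro_wide.set_index("species")[config.scheme].to_dict()

    _, _, background = raster.valid_pixel_matrix()
    surfaces: dict[str, np.ndarray] = {}
    stats_rows = []
    for sp, grp in values.groupby("species", sort=True):
        if lookup.get(sp) not in ("A", "T"):
            continue
        presence = grp[list(raster.variable_codes)].to_numpy()
        try:
            model = fit_maxent(presence, background, raster.variable_codes)
        except InsufficientPresenceError as exc:
            logger.info("ENM: %s skipped (%s)", sp, exc)
            continue
        if not model.converged:
            logger.warning(
                "ENM: %s model did not converge; overlaps may be unstable", sp
            )
        surfaces[sp] = project_suitability(model, raster)
        stats_rows.append(
            {
                "species": sp,
                "n_presence": model.n_presence,
                "auc": model.auc,
                "converged": model.converged,
            }
        )
    model_stats = pd.DataFrame(
        stats_rows, columns=["species", "n_presence", "auc", "converged"]
    )

    labels = {sp: lookup[sp] for sp in surfaces}
    for lab in ("A", "T"):
        if sum(1 for v in labels.values() if v == lab) < 2:
            raise PipelineError(
                f"fewer than 2 modelled species with label {lab!r}"
            )

    species = sorted(surfaces)
    tree = prune_tree(inputs.tree, species)
    C, tree_species = phylo_covariance(tree)
    order = [tree_species.index(sp) for sp in species if sp in tree_species]
    C = C[np.ix_(order, order)]
    on_tree = [sp for sp in species if sp in tree_species]

    pair_table = build_pair_table(
        {sp: surfaces[sp] for sp in on_tree},
        labels,
        pruned,
        C,
        on_tree,
    )

    results = {}
    means_rows = []
    for metric in ("D", "I"):
        res = analyze_overlap(
            pair_table, metric, n_perm=config.n_perm, seed=config.seed
        )
        results[metric] = res
        for ptype, m in res.group_means.items():
            means_rows.append(
                {"metric": metric, "pair_type": ptype, "residual_mean": m}
            )
    group_means = pd.DataFrame(means_rows)

    return ENMReport(
        pair_table=pair_table,
        model_stats=model_stats,
        results=results,
        group_means=group_means,
        config_hash=config.hash(),
        seed=config.seed,
    )


# ----------------------------------------------------------------------
# report writing
# ----------------------------------------------------------------------

def _write_provenance(path: Path, report) -> None:
    payload = {
        "config_hash": report.config_hash,
        "seed": report.seed,
        "version": report.version,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def write_comparative_report(report: ComparativeReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.table2.to_csv(out / "table2_pairwise_anovas.csv", index=False)
    report.table3.to_csv(out / "table3_pc_axes.csv")
    report.summaries.to_csv(out / "species_climate_summaries.csv", index=False)
    _write_provenance(out / "provenance.json", report)


def write_enm_report(report: ENMReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.pair_table.to_csv(out / "pair_overlap_table.csv", index=False)
    report.model_stats.to_csv(out / "enm_model_stats.csv", index=False)
    report.group_means.to_csv(out / "pairtype_group_means.csv", index=False)
    rows = []
    for metric, res in report.results.items():
        rows.append(
            {
                "metric": metric,
                "scope": "overall",
                "contrast": "",
                "Z": res.Z,
                "p": res.p,
            }
        )
        for c in res.contrasts:
            rows.append(
                {
                    "metric": metric,
                    "scope": "contrast",
                    "contrast": f"{c.type_a}-vs-{c.type_b}",
                    "Z": c.Z,
                    "p": c.p,
                }
            )
    pd.DataFrame(rows).to_csv(out / "pairtype_tests.csv", index=False)
    _write_provenance(out / "provenance.json", report)
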