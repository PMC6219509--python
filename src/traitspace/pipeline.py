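"""End-to-end orchestration: datasets x habitats x comparisons.

For each habitat pool and each alien group (naturalized, invasive) the
pipeline runs the per-trait median randomization tests and the trait-space
ΔCDF test, on up to three dataset variants: the raw traits (species with
missing values dropped per test), an imputed trait table, and residuals of
phylogenetic eigenvector models (phylogenetic models are fit once on the
global species set; habitats then subset the residuals). p-values are
BH-adjusted within configurable families. Everything is reproducible from
(config, seed): each (dataset, habitat, comparison, analysis) gets its own
RNG stream by stable hashing, so adding a habitat does not perturb the
other results.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import impute as impute_mod
from .io import (
    COMPARISONS,
    TRAITS,
    HabitatPool,
    Phylogeny,
    SpeciesRecord,
    Status,
    filter_pool,
    read_habitat_table,
    read_newick,
    read_trait_table,
    records_to_frame,
    result_table,
    write_results,
)
from .phylo import (
    abouheif_proximity,
    phylo_eigenvectors,
    phylo_residuals,
    select_eigenvectors,
)
from .simulate import ScenarioConfig, simulate_scenario
from .space import (
    assign_octants,
    build_trait_space,
    centroid_distances,
    distance_summary,
    octant_proportions,
    randomization_test_cdf,
)
from .univariate import bh_adjust, randomization_test_median

log = logging.getLogger("traitspace")

__all__ = ["RunConfig", "RunBundle", "run_full_analysis", "derive_rng"]


def derive_rng(seed: int, *keys: object) -> np.random.Generator:
    """Independent RNG stream for a named pipeline step (stable hashing)."""
    entropy = [seed] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class RunConfig:
    trait_csv: str | None = None
    habitat_csv: str | None = None
    newick: str | None = None
    scenario: ScenarioConfig | None = None
    datasets: tuple[str, ...] = ("raw",)
    imputation_method: str = "rf_phylo"  # taxonomic | rf | rf_phylo
    k_eigenvectors: int = 10
    n_perm: int = 999
    alpha: float = 0.05
    bh_family: str = "per_trait_comparison"  # | per_comparison | global
    fixed_centroid: bool = False
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.datasets) - {"raw", "imputed", "phylo_residual"}
        if unknown:
            raise ValueError(f"unknown dataset tags {sorted(unknown)}")
        if self.scenario is None and not (
            self.trait_csv and self.habitat_csv and self.newick
        ):
            raise ValueError(
                "either a scenario or all three input paths must be given"
            )


@dataclass
class RunBundle:
    results: pd.DataFrame
    octant_counts: pd.DataFrame
    octant_proportions: pd.DataFrame
    distance_summaries: pd.DataFrame
    selections: pd.DataFrame
    cdf_results: list
    provenance: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        tables = {
            "results": self.results,
            "octant_counts": self.octant_counts,
            "octant_proportions": self.octant_proportions,
            "distance_summaries": self.distance_summaries,
            "eigenvector_selections": self.selections,
        }
        return write_results(tables, out_dir, summary=self.provenance)


def _load_inputs(
    config: RunConfig,
) -> tuple[list[SpeciesRecord], list[HabitatPool], Phylogeny]:
    if config.scenario is not None:
        ds = simulate_scenario(config.scenario)
        return ds.records, ds.pools, ds.tree
    records = read_trait_table(config.trait_csv)
    pools = read_habitat_table(config.habitat_csv)
    tree = read_newick(config.newick)
    known = {r.species_id for r in records}
    for pool in pools:
        missing = pool.member_ids - known
        if missing:
            raise ValueError(
                f"habitat {pool.habitat_id!r}: species absent from the trait "
                f"table: {sorted(missing)[:5]}"
            )
    return records, pools, tree


def _tree_species(
    records: Sequence[SpeciesRecord], tree: Phylogeny
) -> list[SpeciesRecord]:
    tips = set(tree.tip_labels)
    kept = [r for r in records if r.species_id in tips]
    dropped = len(records) - len(kept)
    if dropped:
        log.warning(
            "%d species absent from the phylogeny; excluded from "
            "phylogeny-aware analyses", dropped,
        )
    return kept


def _global_residuals(
    records: Sequence[SpeciesRecord],
    tree: Phylogeny,
    config: RunConfig,
) -> tuple[dict[str, pd.Series], pd.DataFrame, list[dict]]:
    """Fit eigenvector models once on the full species table.

    Returns per-trait residual series (for univariate tests), the
    multivariate residual table (for trait-space analyses), and tidy rows
    describing each selection.
    """
    phylo_records = _tree_species(list(records), tree)
    frame = records_to_frame(phylo_records)
    selection_rows: list[dict] = []
    per_trait: dict[str, pd.Series] = {}

    for trait in TRAITS:
        observed = frame[trait].dropna()
        subset = list(observed.index)
        sub_tree = subset_phylogeny(tree, subset)
        prox = abouheif_proximity(sub_tree)
        order = list(prox.tip_order)
        eig = phylo_eigenvectors(prox)
        target = np.log10(observed.loc[order].to_numpy(dtype=float))
        rng = derive_rng(config.seed, "select", trait)
        sel = select_eigenvectors(
            target, eig, prox.W,
            alpha=config.alpha, n_perm=config.n_perm, seed=rng,
        )
        resid = phylo_residuals(target, sel, eig)
        per_trait[trait] = pd.Series(resid, index=order)
        selection_rows.append(
            {
                "target": trait,
                "n_species": len(order),
                "n_selected": len(sel.selected),
                "selected": ";".join(map(str, sel.selected)),
                "initial_stat": sel.trajectory[0],
                "final_stat": sel.trajectory[-1],
                "final_p": sel.final_p,
                "stopped_by_max_k": sel.stopped_by_max_k,
            }
        )

    complete = frame[list(TRAITS)].dropna()
    subset = list(complete.index)
    sub_tree = subset_phylogeny(tree, subset)
    prox = abouheif_proximity(sub_tree)
    order = list(prox.tip_order)
    eig = phylo_eigenvectors(prox)
    X = np.log10(complete.loc[order].to_numpy(dtype=float))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    rng = derive_rng(config.seed, "select", "multivariate")
    sel = select_eigenvectors(
        X, eig, prox.W, alpha=config.alpha, n_perm=config.n_perm, seed=rng,
    )
    resid = phylo_residuals(X, sel, eig)
    multivariate = pd.DataFrame(resid, index=order, columns=list(TRAITS))
    selection_rows.append(
        {
            "target": "multivariate",
            "n_species": len(order),
            "n_selected": len(sel.selected),
            "selected": ";".join(map(str, sel.selected)),
            "initial_stat": sel.trajectory[0],
            "final_stat": sel.trajectory[-1],
            "final_p": sel.final_p,
            "stopped_by_max_k": sel.stopped_by_max_k,
        }
    )
    return per_trait, multivariate, selection_rows


def subset_phylogeny(phylogeny: Phylogeny, labels: Sequence[str]) -> Phylogeny:
    """Tree restricted to the given tips (unifurcations suppressed)."""
    sub = phylogeny.tree.extract_tree_with_taxa_labels(labels=set(labels))
    sub.is_rooted = True
    return Phylogeny(sub)


def _impute_records(
    records: list[SpeciesRecord], tree: Phylogeny, config: RunConfig
) -> list[SpeciesRecord]:
    method = config.imputation_method
    if method == "taxonomic":
        return impute_mod.impute_taxonomic(records).records
    if method == "rf":
        features = impute_mod.compute_rf_features(records)
        return impute_mod.impute_random_forest(
            records, features, seed=config.seed,
        ).records
    if method == "rf_phylo":
        phylo_records = _tree_species(records, tree)
        sub_tree = subset_phylogeny(
            tree, [r.species_id for r in phylo_records]
        )
        eig = phylo_eigenvectors(abouheif_proximity(sub_tree))
        features = impute_mod.compute_rf_features(
            phylo_records, eig, k=config.k_eigenvectors
        )
        completed = impute_mod.impute_random_forest(
            phylo_records, features, seed=config.seed,
        ).records
        by_id = {r.species_id: r for r in completed}
        return [by_id.get(r.species_id, r) for r in records]
    raise ValueError(f"unknown imputation method {method!r}")


def _univariate_values(
    frame: pd.DataFrame,
    pool: HabitatPool,
    trait: str,
    dataset: str,
    residuals: dict[str, pd.Series] | None,
) -> pd.DataFrame:
    """(species, status, value) rows for one habitat x trait, NA dropped."""
    members = sorted(pool.member_ids & set(frame.index))
    if dataset == "phylo_residual":
        series = residuals[trait]
        members = [m for m in members if m in series.index]
        values = series.loc[members]
    else:
        values = frame.loc[members, trait].astype(float).dropna()
        members = list(values.index)
    return pd.DataFrame(
        {"value": values, "status": frame.loc[members, "status"]}
    )


def run_full_analysis(config: RunConfig) -> RunBundle:
    """Run every configured dataset x habitat x comparison analysis."""
    records, pools, tree = _load_inputs(config)
    records = [r for r in records if r.status is not Status.casual]
    pools = [filter_pool(p, records) for p in pools]

    residuals_by_trait: dict[str, pd.Series] | None = None
    residual_table: pd.DataFrame | None = None
    selection_rows: list[dict] = []
    dataset_records: dict[str, list[SpeciesRecord]] = {}
    for tag in config.datasets:
        if tag == "raw":
            dataset_records[tag] = records
        elif tag == "imputed":
            dataset_records[tag] = _impute_records(records, tree, config)
        elif tag == "phylo_residual":
            residuals_by_trait, residual_table, selection_rows = (
                _global_residuals(records, tree, config)
            )
            dataset_records[tag] = records

    result_rows: list[dict] = []
    octant_count_rows: list[pd.DataFrame] = []
    octant_prop_rows: list[pd.DataFrame] = []
    distance_rows: list[pd.DataFrame] = []
    cdf_results: list = []

    for tag, tag_records in dataset_records.items():
        frame = records_to_frame(tag_records)
        for pool in pools:
            # --- univariate tests ---
            for trait in TRAITS:
                table = _univariate_values(
                    frame, pool, trait, tag,
                    residuals_by_trait,
                )
                native = table.loc[
                    table["status"] == Status.native.value, "value"
                ].to_numpy()
                for comparison, alien_status in COMPARISONS:
                    alien = table.loc[
                        table["status"] == alien_status.value, "value"
                    ].to_numpy()
                    if native.size < 2 or alien.size < 2:
                        log.warning(
                            "%s/%s/%s/%s: too few species, skipped",
                            tag, pool.habitat_id, comparison, trait,
                        )
                        continue
                    rng = derive_rng(
                        config.seed, tag, pool.habitat_id, comparison,
                        "median", trait,
                    )
                    res = randomization_test_median(
                        native, alien, n_perm=config.n_perm, seed=rng,
                    )
                    result_rows.append(
                        {
                            "habitat_id": pool.habitat_id,
                            "comparison": comparison,
                            "trait": trait,
                            "statistic": "median_difference",
                            "value": res.delta,
                            "p": res.p,
                            "p_adj": np.nan,
                            "n_perm": config.n_perm,
                            "seed": config.seed,
                            "dataset": tag,
                        }
                    )

            # --- trait space ---
            mode = "residual" if tag == "phylo_residual" else "raw"
            try:
                space = build_trait_space(
                    pool, tag_records, mode=mode, residuals=residual_table,
                )
            except ValueError as exc:
                log.warning("%s/%s: %s", tag, pool.habitat_id, exc)
                continue
            labels = assign_octants(space)
            counts, props = octant_proportions(labels, space.statuses)
            for name, tbl, sink in (
                ("counts", counts, octant_count_rows),
                ("props", props, octant_prop_rows),
            ):
                t = tbl.reset_index().rename(columns={"index": "octant"})
                t.insert(0, "dataset", tag)
                t.insert(1, "habitat_id", pool.habitat_id)
                sink.append(t)
            profile = centroid_distances(space)
            summary = distance_summary(space, profile)
            summary.insert(0, "dataset", tag)
            summary.insert(1, "habitat_id", pool.habitat_id)
            distance_rows.append(summary)

            for comparison, alien_status in COMPARISONS:
                rng = derive_rng(
                    config.seed, tag, pool.habitat_id, comparison, "cdf",
                )
                try:
                    res = randomization_test_cdf(
                        space, comparison, n_perm=config.n_perm, seed=rng,
                        fixed_centroid=config.fixed_centroid,
                    )
                except ValueError as exc:
                    log.warning(
                        "%s/%s/%s: %s", tag, pool.habitat_id, comparison, exc,
                    )
                    continue
                cdf_results.append((tag, res))
                result_rows.append(
                    {
                        "habitat_id": pool.habitat_id,
                        "comparison": comparison,
                        "trait": "multivariate",
                        "statistic": "delta_cdf",
                        "value": res.delta_cdf,
                        "p": res.p,
                        "p_adj": np.nan,
                        "n_perm": config.n_perm,
                        "seed": config.seed,
                        "dataset": tag,
                    }
                )

    results = result_table(result_rows)
    results["p_adj"] = _apply_bh(results, config.bh_family)

    bundle = RunBundle(
        results=results,
        octant_counts=(
            pd.concat(octant_count_rows, ignore_index=True)
            if octant_count_rows else pd.DataFrame()
        ),
        octant_proportions=(
            pd.concat(octant_prop_rows, ignore_index=True)
            if octant_prop_rows else pd.DataFrame()
        ),
        distance_summaries=(
            pd.concat(distance_rows, ignore_index=True)
            if distance_rows else pd.DataFrame()
        ),
        selections=pd.DataFrame(selection_rows),
        cdf_results=cdf_results,
        provenance={
            "seed": config.seed,
            "n_perm": config.n_perm,
            "alpha": config.alpha,
            "datasets": list(config.datasets),
            "bh_family": config.bh_family,
            "imputation_method": config.imputation_method,
            "scenario": (
                None if config.scenario is None else vars(config.scenario)
            ),
        },
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle


def _apply_bh(results: pd.DataFrame, policy: str) -> np.ndarray:
    """BH adjustment within the configured family structure."""
    if policy == "per_trait_comparison":
        keys = ["dataset", "comparison", "trait", "statistic"]
    elif policy == "per_comparison":
        keys = ["dataset", "comparison", "statistic"]
    elif policy == "global":
        keys = ["dataset", "statistic"]
    else:
        raise ValueError(f"unknown BH family policy {policy!r}")
    adjusted = np.full(len(results), np.nan)
    for _, idx in results.groupby(keys, sort=False).groups.items():
        loc = results.index.get_indexer(idx)
        adjusted[loc] = bh_adjust(results.loc[idx, "p"].to_numpy())
    return adjusted
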