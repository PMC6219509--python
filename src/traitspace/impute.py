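"""Missing-trait imputation: taxonomic means and iterative random forests.

Three strategies produce completed trait tables: (1) taxonomic averaging —
genus mean, falling back to family mean, then the global mean; (2) an
iterative random-forest imputer in the style of missForest, fitting one
forest per trait column on the currently completed data until the
normalized change of the imputed values first increases; (3) the same
forest imputer with the first k phylogenetic eigenvectors as additional
predictors, so phylogenetically clumped gaps can borrow strength from
relatives. Forest imputation runs on the log10 trait scale (the analysis
scale) and back-transforms; observed cells are never touched.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .io import TRAITS, SpeciesRecord, records_to_frame
from .phylo import PhyloEigenvectors

__all__ = [
    "ImputationResult",
    "impute_taxonomic",
    "compute_rf_features",
    "impute_random_forest",
    "imputation_rmse",
]


@dataclass
class ImputationResult:
    records: list[SpeciesRecord]
    method: str  # taxonomic | rf | rf_phylo
    #: per-cell provenance: DataFrame of {"observed", "imputed"} strings,
    #: rows = species_id, columns = traits
    provenance: pd.DataFrame
    n_iterations: int = 0


def _completed_records(
    records: list[SpeciesRecord], values: pd.DataFrame
) -> list[SpeciesRecord]:
    out = []
    for r in records:
        fills = {}
        for t in TRAITS:
            if getattr(r, t) is None:
                v = float(values.loc[r.species_id, t])
                if not v > 0:
                    raise ValueError(
                        f"imputed non-positive value {v} for {r.species_id}/{t}"
                    )
                fills[t] = v
        out.append(dataclasses.replace(r, **fills) if fills else r)
    return out


def _provenance(records: list[SpeciesRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            t: ["observed" if getattr(r, t) is not None else "imputed"
                for r in records]
            for t in TRAITS
        },
        index=[r.species_id for r in records],
    )


def impute_taxonomic(records: list[SpeciesRecord]) -> ImputationResult:
    """Fill missing traits with the genus mean of observed values, then the
    family mean if the whole genus is missing, then the global mean."""
    frame = records_to_frame(records)
    values = frame[list(TRAITS)].astype(float)
    for trait in TRAITS:
        col = values[trait]
        if col.notna().sum() == 0:
            raise ValueError(f"trait {trait}: no observed values at all")
        genus_mean = col.groupby(frame["genus"]).transform("mean")
        family_mean = col.groupby(frame["family"]).transform("mean")
        filled = col.fillna(genus_mean).fillna(family_mean).fillna(col.mean())
        values[trait] = filled
    return ImputationResult(
        records=_completed_records(records, values),
        method="taxonomic",
        provenance=_provenance(records),
    )


def compute_rf_features(
    records: list[SpeciesRecord],
    eigenvectors: PhyloEigenvectors | None = None,
    k: int = 10,
) -> pd.DataFrame:
    """Feature table for forest imputation: log10 traits, optionally joined
    with the first ``k`` phylogenetic eigenvector scores.

    The eigenvector tip order must cover (and align to) the species ids.
    """
    frame = records_to_frame(records)
    features = np.log10(frame[list(TRAITS)].astype(float))
    if eigenvectors is None:
        return features
    order = list(eigenvectors.tip_order)
    missing = set(features.index) - set(order)
    if missing:
        raise ValueError(
            f"{len(missing)} species absent from the eigenvector tip order"
        )
    k = min(k, eigenvectors.m)
    ev = pd.DataFrame(
        eigenvectors.vectors[:, :k],
        index=order,
        columns=[f"phylo_ev{i + 1}" for i in range(k)],
    )
    return features.join(ev.loc[features.index])


def _fit_seed(seed: int | None, iteration: int, column: int) -> int | None:
    if seed is None:
        return None
    return (seed * 1000003 + iteration * 131 + column) % (2 ** 31)


def impute_random_forest(
    records: list[SpeciesRecord],
    features: pd.DataFrame,
    seed: int | None = 0,
    max_iter: int = 10,
    n_trees: int = 100,
) -> ImputationResult:
    """missForest-style iterative random-forest imputation.

    Missing cells start at column means; trait columns are then revisited in
    order of increasing missingness, each refit by a random-forest
    regression (``n_trees`` trees, mtry = floor(sqrt(p))) of the observed
    entries on all other feature columns and re-predicted for the missing
    entries. Iteration stops the first time the normalized squared change of
    the imputed values increases, returning the previous iteration's values
    (or at ``max_iter``). Runs on the log10 scale; results back-transform to
    natural units.
    """
    X = features.copy().astype(float)
    trait_cols = [c for c in TRAITS if c in X.columns]
    na_mask = X[trait_cols].isna()
    for c in X.columns:
        if c not in trait_cols and X[c].isna().any():
            raise ValueError(f"predictor column {c!r} has missing values")
    for c in trait_cols:
        if na_mask[c].all():
            raise ValueError(f"trait {c}: all values missing")

    # column-mean initialization, then iterate in increasing missingness
    current = X.copy()
    for c in trait_cols:
        current[c] = current[c].fillna(current[c].mean())
    visit = sorted(
        (c for c in trait_cols if na_mask[c].any()),
        key=lambda c: na_mask[c].sum(),
    )
    if not visit:
        return ImputationResult(
            records=list(records), method="rf", provenance=_provenance(records),
        )

    mtry = max(1, int(math.floor(math.sqrt(X.shape[1] - 1))))
    previous = current.copy()
    last_diff = np.inf
    n_done = 0
    for iteration in range(max_iter):
        before = current[trait_cols].copy()
        for j, col in enumerate(visit):
            predictors = [c for c in X.columns if c != col]
            obs = ~na_mask[col]
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=mtry,
                random_state=_fit_seed(seed, iteration, j),
                n_jobs=1,
            )
            forest.fit(current.loc[obs, predictors], X.loc[obs, col])
            current.loc[na_mask[col], col] = forest.predict(
                current.loc[na_mask[col], predictors]
            )
        n_done = iteration + 1
        num = den = 0.0
        for col in visit:
            new = current.loc[na_mask[col], col].to_numpy()
            old = before.loc[na_mask[col], col].to_numpy()
            num += float(((new - old) ** 2).sum())
            den += float((new ** 2).sum())
        diff = num / den if den > 0 else 0.0
        if diff >= last_diff:
            current = previous  # the change grew: keep the previous iterate
            break
        previous = current.copy()
        last_diff = diff

    values = 10.0 ** current[trait_cols]
    method = "rf" if X.shape[1] == len(trait_cols) else "rf_phylo"
    return ImputationResult(
        records=_completed_records(records, values),
        method=method,
        provenance=_provenance(records),
        n_iterations=n_done,
    )


def imputation_rmse(
    result: ImputationResult, truth: pd.DataFrame, log_scale: bool = True
) -> dict[str, float]:
    """RMSE of imputed cells against the known truth, per trait (log10 scale
    by default — errors on strictly positive traits are multiplicative)."""
    frame = records_to_frame(result.records)
    out: dict[str, float] = {}
    for t in TRAITS:
        mask = result.provenance[t] == "imputed"
        if not mask.any():
            continue
        ids = result.provenance.index[mask]
        est = frame.loc[ids, t].astype(float).to_numpy()
        ref = truth.loc[ids, t].astype(float).to_numpy()
        if log_scale:
            est, ref = np.log10(est), np.log10(ref)
        out[t] = float(np.sqrt(np.mean((est - ref) ** 2)))
    return out
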