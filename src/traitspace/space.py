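"""Per-habitat trait-space geometry and the CDF-area randomization test.

Each habitat's species pool is placed in a 3-D space of standardized
log10 traits (SLA, maximum height, seed weight). The native species define
a centroid; octant membership, distances to the centroid, and the signed
area between the empirical CDFs of relative centroid distances (ΔCDF)
summarize where naturalized and invasive species sit relative to natives.
A negative ΔCDF means the alien group's CDF lies (mostly) below the native
one, i.e. the aliens are displaced toward the edge of the trait space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import TRAITS, HabitatPool, SpeciesRecord, Status, records_to_frame

__all__ = [
    "TraitSpace",
    "DistanceProfile",
    "CDFComparisonResult",
    "OCTANTS",
    "build_trait_space",
    "assign_octants",
    "octant_proportions",
    "centroid_distances",
    "delta_cdf",
    "randomization_test_cdf",
    "distance_summary",
]

_SIGN_EPS = 1e-12


@dataclass(frozen=True)
class TraitSpace:
    habitat_id: str
    species_ids: tuple[str, ...]
    Z: np.ndarray                  # n x 3, columns: SLA, height, seed weight
    statuses: tuple[str, ...]
    native_centroid: np.ndarray    # 3-vector, column means of native rows
    scale_mean: np.ndarray | None  # standardization params (raw mode only)
    scale_sd: np.ndarray | None
    mode: str                      # "raw" | "residual"

    @property
    def n(self) -> int:
        return len(self.species_ids)

    def status_mask(self, status: str) -> np.ndarray:
        return np.array([s == status for s in self.statuses])


@dataclass(frozen=True)
class DistanceProfile:
    """Distances of every species to the native centroid, in SD units and
    as a percentage of the most distant species in the habitat."""

    distances: np.ndarray
    relative: np.ndarray  # 100 * d / max(d)


@dataclass(frozen=True)
class CDFComparisonResult:
    habitat_id: str
    comparison: str
    delta_cdf: float
    p: float
    n_perm: int
    seed: int | None
    n_crossings: int
    dominant_fraction: float
    n_native: int
    n_alien: int
    null: np.ndarray


def build_trait_space(
    pool: HabitatPool,
    records: Sequence[SpeciesRecord],
    mode: str = "raw",
    residuals: pd.DataFrame | None = None,
) -> TraitSpace:
    """Standardized 3-trait space for one habitat pool.

    raw mode: traits are log10-transformed and z-scored over all species of
    the pool with complete trait triples (species missing any trait are
    dropped). residual mode: ``residuals`` supplies phylogeny-corrected
    trait triples (rows indexed by species_id) which are used as-is, with no
    re-standardization — their scale carries meaning.
    """
    frame = records_to_frame(records)
    members = sorted(pool.member_ids & set(frame.index))
    if mode == "raw":
        sub = frame.loc[members, list(TRAITS)].astype(float)
        complete = sub.dropna().index.tolist()
        X = np.log10(sub.loc[complete].to_numpy())
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError(f"habitat {pool.habitat_id!r}: constant trait column")
        Z = (X - mean) / sd
    elif mode == "residual":
        if residuals is None:
            raise ValueError("residual mode requires a residuals table")
        complete = [m for m in members if m in residuals.index]
        Z = residuals.loc[complete].to_numpy(dtype=float)
        mean = sd = None
    else:
        raise ValueError(f"unknown mode {mode!r}")

    statuses = tuple(frame.loc[complete, "status"])
    native = np.array([s == Status.native.value for s in statuses])
    if native.sum() < 3:
        raise ValueError(
            f"habitat {pool.habitat_id!r}: fewer than 3 native species with "
            "complete traits"
        )
    return TraitSpace(
        habitat_id=pool.habitat_id,
        species_ids=tuple(complete),
        Z=Z,
        statuses=statuses,
        native_centroid=Z[native].mean(axis=0),
        scale_mean=mean,
        scale_sd=sd,
        mode=mode,
    )


#: Octant labels from the sign pattern of (SLA, height, seed weight) relative
#: to the native centroid; a coordinate equal to the centroid counts as above.
OCTANTS = {
    (True, True, True): "I",
    (True, True, False): "II",
    (False, True, False): "III",
    (False, True, True): "IV",
    (True, False, True): "V",
    (True, False, False): "VI",
    (False, False, False): "VII",
    (False, False, True): "VIII",
}
OCTANT_ORDER = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]


def assign_octants(space: TraitSpace) -> list[str]:
    """Octant label per species: octants I–IV hold above-average height,
    I/II/V/VI above-average SLA, I/IV/V/VIII above-average seed weight."""
    above = space.Z >= space.native_centroid
    return [OCTANTS[tuple(row)] for row in above]


def octant_proportions(
    labels: Sequence[str], statuses: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(counts, within-status proportions), octants I–VIII by status."""
    if len(labels) != len(statuses):
        raise ValueError("labels and statuses must align")
    frame = pd.DataFrame({"octant": list(labels), "status": list(statuses)})
    counts = (
        frame.groupby(["octant", "status"], sort=False).size().unstack(fill_value=0)
    )
    counts = counts.reindex(OCTANT_ORDER, fill_value=0)
    proportions = counts / counts.sum(axis=0).replace(0, np.nan)
    return counts, proportions


def centroid_distances(space: TraitSpace) -> DistanceProfile:
    """Euclidean distance of each species to the native centroid (SD units),
    plus the 100·d/max(d) relative scale."""
    d = np.linalg.norm(space.Z - space.native_centroid, axis=1)
    dmax = d.max()
    relative = 100 * d / dmax if dmax > 0 else np.zeros_like(d)
    return DistanceProfile(distances=d, relative=relative)


def _ecdf_segments(native: np.ndarray, alien: np.ndarray):
    """Piecewise-constant g = F_alien − F_nat on the pooled support.

    Returns (widths, g-levels) over the maximal intervals between unique
    pooled values. Per-value weights are aggregated from integer counts so
    the construction is exactly antisymmetric under a group swap.
    """
    pooled = np.concatenate([native, alien])
    xs, inverse = np.unique(pooled, return_inverse=True)
    n_nat, n_al = native.size, alien.size
    nat_counts = np.bincount(inverse[:n_nat], minlength=xs.size)
    al_counts = np.bincount(inverse[n_nat:], minlength=xs.size)
    jumps = al_counts / n_al - nat_counts / n_nat
    g = np.cumsum(jumps)
    return np.diff(xs), g[:-1]


def _regions(widths: np.ndarray, g: np.ndarray):
    """Signed areas of the maximal sign-constant regions of g, plus the
    number of sign crossings. Zero-level stretches carry no area and merge
    with the adjacent region."""
    areas_seg = g * widths
    s = np.where(np.abs(g) > _SIGN_EPS, np.sign(g), 0.0)
    region_areas: list[float] = []
    crossings = 0
    current_sign = 0.0
    acc = 0.0
    for sign_k, area_k in zip(s, areas_seg):
        if sign_k != 0 and current_sign != 0 and sign_k != current_sign:
            region_areas.append(acc)
            acc = 0.0
            crossings += 1
        if sign_k != 0:
            current_sign = sign_k
        acc += area_k
    region_areas.append(acc)
    return np.array(region_areas), crossings


def delta_cdf(
    native_rel_dists: np.ndarray, alien_rel_dists: np.ndarray
) -> tuple[float, int, float]:
    """Signed dominant-region area between the two distance CDFs.

    The difference g(x) = F_alien(x) − F_nat(x) of the right-continuous
    empirical CDFs is integrated exactly (it is piecewise constant). Where
    the CDFs cross, [0, 100] splits into sign-constant regions and the
    region of largest absolute area gives the statistic, with
    ``dominant_fraction`` = |delta| / Σ|region areas| as a diagnostic.
    Positive delta ⇔ the alien CDF is (mostly) above the native one, i.e.
    aliens sit closer to the native centroid.
    """
    native = np.asarray(native_rel_dists, dtype=float)
    alien = np.asarray(alien_rel_dists, dtype=float)
    if native.size < 2 or alien.size < 2:
        raise ValueError("each group needs at least 2 distance values")
    widths, g = _ecdf_segments(native, alien)
    region_areas, crossings = _regions(widths, g)
    total = np.abs(region_areas).sum()
    if total <= _SIGN_EPS:
        return 0.0, 0, 1.0
    k = int(np.argmax(np.abs(region_areas)))
    delta = float(region_areas[k])
    return delta, crossings, float(abs(delta) / total)


def _delta_cdf_batch(values: np.ndarray, n_native: int) -> np.ndarray:
    """Dominant-region ΔCDF for B replicates at once.

    ``values[b]`` holds the relative distances of one replicate, the first
    ``n_native`` entries being the native group. Matches :func:`delta_cdf`
    on every row (cross-checked in the test suite).
    """
    B, n = values.shape
    n_alien = n - n_native
    order = np.argsort(values, axis=1, kind="stable")
    xs = np.take_along_axis(values, order, axis=1)
    w = np.where(order >= n_native, 1.0 / n_alien, -1.0 / n_native)
    g = np.cumsum(w, axis=1)[:, :-1]
    dx = np.diff(xs, axis=1)
    seg = g * dx
    # sign sequence over non-empty intervals; empty (dx==0) or zero-level
    # segments merge with whatever non-zero-signed region precedes them
    s = np.where((dx > 0) & (np.abs(g) > _SIGN_EPS), np.sign(g), 0.0)
    idx = np.arange(s.shape[1])[None, :]
    last_nz = np.maximum.accumulate(np.where(s != 0, idx, -1), axis=1)
    filled = np.where(
        last_nz >= 0,
        np.take_along_axis(s, np.maximum(last_nz, 0), axis=1),
        0.0,
    )
    prev = np.concatenate([np.zeros((B, 1)), filled[:, :-1]], axis=1)
    change = (filled != prev) & (filled != 0) & (prev != 0)
    region_id = np.cumsum(change, axis=1)
    K = int(region_id.max()) + 1 if region_id.size else 1
    gid = (np.arange(B)[:, None] * K + region_id).ravel()
    areas = np.bincount(gid, weights=seg.ravel(), minlength=B * K).reshape(B, K)
    # regions beyond each row's own count stay exactly 0 and never win argmax
    # unless all real regions are 0 too, in which case delta is 0 anyway
    k = np.argmax(np.abs(areas), axis=1)
    return areas[np.arange(B), k]


def _comparison_alien_status(comparison: str) -> str:
    table = {
        "naturalized_vs_native": Status.naturalized.value,
        "invasive_vs_native": Status.invasive.value,
    }
    if comparison not in table:
        raise ValueError(f"unknown comparison {comparison!r}")
    return table[comparison]


def _pooled_delta(Z: np.ndarray, n_native: int) -> tuple[float, int, float]:
    """Observed ΔCDF of a native/alien pooled block (native rows first)."""
    centroid = Z[:n_native].mean(axis=0)
    d = np.linalg.norm(Z - centroid, axis=1)
    rel = 100 * d / d.max() if d.max() > 0 else np.zeros_like(d)
    return delta_cdf(rel[:n_native], rel[n_native:])


def randomization_test_cdf(
    space: TraitSpace,
    comparison: str,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    fixed_centroid: bool = False,
) -> CDFComparisonResult:
    """Two-tailed randomization test of the ΔCDF statistic.

    Each replicate re-shuffles the native/alien labels among the pooled
    native + alien species (group sizes preserved; any third status group is
    excluded from the pool) and recomputes the native centroid, distances,
    the 100/max relative scaling, and the dominant-region area. By default
    the centroid moves with the permuted labels; ``fixed_centroid`` keeps
    the observed centroid, as a sensitivity variant.
    """
    alien_status = _comparison_alien_status(comparison)
    native_mask = space.status_mask(Status.native.value)
    alien_mask = space.status_mask(alien_status)
    n_native, n_alien = int(native_mask.sum()), int(alien_mask.sum())
    if n_native < 2 or n_alien < 2:
        raise ValueError(
            f"habitat {space.habitat_id!r}, {comparison}: needs >= 2 species "
            f"per group (native={n_native}, alien={n_alien})"
        )
    Z = np.concatenate([space.Z[native_mask], space.Z[alien_mask]])
    n = n_native + n_alien
    obs, crossings, dominant = _pooled_delta(Z, n_native)

    rng = np.random.default_rng(seed)
    P = np.argsort(rng.random((n_perm, n)), axis=1)
    Zp = Z[P]  # (B, n, 3)
    if fixed_centroid:
        centroids = np.broadcast_to(Z[:n_native].mean(axis=0), (n_perm, 3))
    else:
        centroids = Zp[:, :n_native, :].mean(axis=1)
    d = np.linalg.norm(Zp - centroids[:, None, :], axis=2)
    rel = 100 * d / d.max(axis=1, keepdims=True)
    null = _delta_cdf_batch(rel, n_native)
    p = float((1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1))
    return CDFComparisonResult(
        habitat_id=space.habitat_id,
        comparison=comparison,
        delta_cdf=obs,
        p=p,
        n_perm=n_perm,
        seed=seed if isinstance(seed, int) else None,
        n_crossings=crossings,
        dominant_fraction=dominant,
        n_native=n_native,
        n_alien=n_alien,
        null=null,
    )


def distance_summary(space: TraitSpace, profile: DistanceProfile) -> pd.DataFrame:
    """Mean centroid distance per status group, in SD units and % of the
    most distant species. Empty status groups are omitted."""
    rows = []
    for status in sorted(set(space.statuses)):
        mask = space.status_mask(status)
        rows.append(
            {
                "status": status,
                "n": int(mask.sum()),
                "mean_distance_sd": float(profile.distances[mask].mean()),
                "mean_distance_pct": float(profile.relative[mask].mean()),
            }
        )
    return pd.DataFrame(rows)
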