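"""Median-difference randomization tests for single-trait comparisons.

For each habitat and trait, the median of an alien group (naturalized or
invasive) is compared with the median of the native group; the null
distribution comes from re-shuffling values between the two groups with
group sizes preserved, and p-values within a family of habitats are
adjusted by the Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MedianTestResult",
    "median_difference",
    "randomization_test_median",
    "bh_adjust",
]


@dataclass(frozen=True)
class MedianTestResult:
    delta: float          # alien median - native median
    p: float
    null: np.ndarray      # null replicate deltas
    n_native: int
    n_alien: int
    n_perm: int
    seed: int | None


def _validate_group(values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"{name} group needs at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} group contains non-finite values")
    return arr


def median_difference(native_vals: np.ndarray, alien_vals: np.ndarray) -> float:
    """median(alien) - median(native); even counts use the midpoint rule."""
    native = _validate_group(native_vals, "native")
    alien = _validate_group(alien_vals, "alien")
    return float(np.median(alien) - np.median(native))


def randomization_test_median(
    native_vals: np.ndarray,
    alien_vals: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> MedianTestResult:
    """Two-tailed randomization test of the median difference.

    Each replicate pools both groups, reassigns labels uniformly at random
    with group sizes preserved, and recomputes the difference;
    p = (1 + #{|delta_sim| >= |delta_obs|}) / (n_perm + 1).
    """
    native = _validate_group(native_vals, "native")
    alien = _validate_group(alien_vals, "alien")
    rng = np.random.default_rng(seed)
    obs = float(np.median(alien) - np.median(native))

    pooled = np.concatenate([native, alien])
    n = pooled.size
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    shuffled = pooled[order]
    sim_alien = np.median(shuffled[:, : alien.size], axis=1)
    sim_native = np.median(shuffled[:, alien.size:], axis=1)
    null = sim_alien - sim_native
    p = float((1 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1))
    return MedianTestResult(
        delta=obs,
        p=p,
        null=null,
        n_native=native.size,
        n_alien=alien.size,
        n_perm=n_perm,
        seed=seed if isinstance(seed, int) else None,
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
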