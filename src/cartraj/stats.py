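"""Replicate-level inference.

The unit of replication is the trajectory, never the frame: frames within a
replicate are strongly autocorrelated, so every metric is first reduced to
one mean per replicate and tests are run on those means (n = number of
replicates per condition).

Provides Welch two-sample t-tests with Bonferroni correction, the
cross-trajectory divergence derived from a pooled pairwise-RMSD matrix, and
a seeded bootstrap for the core-vs-backbone RMSD-gap comparison between
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .superpose import Rms2dMatrix


@dataclass(frozen=True)
class TestResult:
    label: str
    statistic: float
    p_value: float
    p_corrected: float
    n_a: int
    n_b: int
    family_size: int

    def as_row(self) -> dict:
        return {"comparison": self.label, "t": self.statistic,
                "p": self.p_value, "p_bonferroni": self.p_corrected,
                "n_A": self.n_a, "n_B": self.n_b, "m": self.family_size}


def replicate_means(series_per_replicate: dict[int, np.ndarray] | list,
                    ) -> pd.DataFrame:
    """One mean per replicate; the replication unit for all tests."""
    if isinstance(series_per_replicate, dict):
        items = series_per_replicate.items()
    else:
        items = enumerate(series_per_replicate)
    rows = []
    for rep_id, series in items:
        arr = np.asarray(series, dtype=float)
        if arr.size == 0:
            raise ValueError(f"replicate {rep_id} has an empty series")
        rows.append({"replicate": rep_id, "mean": float(arr.mean()),
                     "n_frames": int(arr.size)})
    if not rows:
        raise ValueError("no replicates given")
    return pd.DataFrame(rows)


def welch_test(group_a, group_b, family_size: int = 1,
               label: str = "") -> TestResult:
    """Two-sided Welch (unequal-variance) t-test on per-replicate means,
    Bonferroni-corrected with the given family size."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicate means")
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        # degenerate: no within-group variance
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(label, float(t), float(p),
                      float(min(1.0, family_size * p)),
                      int(a.size), int(b.size), int(family_size))


def cross_traj_divergence(matrix: Rms2dMatrix) -> pd.DataFrame:
    """Per-trajectory mean RMSD to all frames of the *other* trajectories.

    D(e) = mean over pairs (i in e, j not in e) of matrix[i, j].
    """
    ids = np.asarray(matrix.trajectory_ids)
    unique = np.unique(ids)
    if unique.size < 2:
        raise ValueError("divergence needs at least 2 trajectories")
    rows = []
    for e in unique:
        inside = ids == e
        if not inside.any():
            raise ValueError(f"trajectory {e} has zero frames")
        block = matrix.values[np.ix_(inside, ~inside)]
        rows.append({"trajectory": int(e),
                     "divergence_A": float(block.mean()),
                     "n_frames": int(inside.sum()),
                     "rule": matrix.rule})
    return pd.DataFrame(rows)


def gap_statistics(div_core: pd.DataFrame, div_backbone: pd.DataFrame,
                   condition: str = "") -> pd.DataFrame:
    """Per-trajectory core-vs-backbone divergence gap D_core - D_backbone."""
    merged = div_core.merge(div_backbone, on="trajectory",
                            suffixes=("_core", "_backbone"))
    return pd.DataFrame({
        "trajectory": merged["trajectory"],
        "D_core_A": merged["divergence_A_core"],
        "D_backbone_A": merged["divergence_A_backbone"],
        "gap_A": merged["divergence_A_core"] - merged["divergence_A_backbone"],
        "condition": condition,
    })


@dataclass(frozen=True)
class BootstrapResult:
    observed_delta: float
    p_value: float
    n_boot: int
    seed: int
    method: str = "centered-pooled-resampling"


def gap_bootstrap(gaps_a, gaps_b, n_boot: int = 10_000,
                  seed: int = 0) -> BootstrapResult:
    """Two-sided bootstrap test for a difference in mean gap between groups.

    The null is built by resampling, with replacement and at the original
    group sizes, from the pooled values after centering each group on its own
    mean; p = (1 + #{|delta*| >= |delta|}) / (n_boot + 1).
    """
    a = np.asarray(gaps_a, dtype=float)
    b = np.asarray(gaps_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 per-trajectory gaps")
    delta = a.mean() - b.mean()
    # sorting makes the resample exactly invariant to relabeling within groups
    pooled = np.sort(np.concatenate([a - a.mean(), b - b.mean()]))
    if np.allclose(pooled, pooled[0]):
        return BootstrapResult(float(delta), 1.0, n_boot, seed)
    rng = np.random.default_rng(seed)
    draws_a = rng.choice(pooled, size=(n_boot, a.size), replace=True)
    draws_b = rng.choice(pooled, size=(n_boot, b.size), replace=True)
    delta_null = draws_a.mean(1) - draws_b.mean(1)
    exceed = int(np.count_nonzero(np.abs(delta_null) >= abs(delta)))
    p = (1.0 + exceed) / (n_boot + 1.0)
    return BootstrapResult(float(delta), float(p), n_boot, seed)


def permutation_test(gaps_a, gaps_b, n_perm: int = 10_000,
                     seed: int = 0) -> BootstrapResult:
    """Label-permutation alternative to the bootstrap (same p convention)."""
    a = np.asarray(gaps_a, dtype=float)
    b = np.asarray(gaps_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 per-trajectory gaps")
    delta = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    if np.allclose(pooled, pooled[0]):
        return BootstrapResult(float(delta), 1.0, n_perm, seed, "permutation")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = perm[:a.size].mean() - perm[a.size:].mean()
        if abs(d) >= abs(delta):
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return BootstrapResult(float(delta), float(p), n_perm, seed, "permutation")
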