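"""Resampling statistics for adhesion-force datasets.

Three layers, matching how the adhesion study summarises its data:

* per-condition, per-contact-time medians and two-tailed Mann-Whitney tests
  between median adhesion forces;
* the adhesion-strengthening statistic: the average of discrete slopes
  ``(F2 - F1) / (t2 - t1)`` over adjacent contact times of the per-time
  medians, compared between groups on equal-size bootstrap resamples of
  whole cells (cells are the repeated-measures unit — a single fibroblast is
  probed at all contact times);
* the additive-null interaction statistic between two receptor classes,
  ``epsilon = F_AB + F_0 - F_A - F_B`` per contact time, with a bootstrap
  test of ``epsilon = 0``.

Two inference methods are provided for the bootstrap tests.  The default,
``method="percentile"``, is the standard two-sided bootstrap percentile test
on the replicate statistic (calibrated close to nominal level).  The
alternative, ``method="wilcoxon"``, applies a two-tailed Wilcoxon test
directly to the B bootstrap replicates (rank-sum between the two groups'
slope replicates; signed-rank of the epsilon replicates against zero, zeros
handled by Pratt's method).  Treating bootstrap replicates as exchangeable
observations makes that variant strongly anti-conservative — its rejection
rate under a true null is far above the nominal level — so it is kept for
comparability, not recommended for inference (see docs/methods.md).

All tests are reproducible bit for bit under a fixed seed and invariant to
record order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AdhesionDataset",
    "SlopeResult",
    "InteractionResult",
    "median_forces",
    "mann_whitney_medians",
    "discrete_slope",
    "average_slope",
    "bootstrap_resample",
    "slope_difference_test",
    "interaction_epsilon",
    "interaction_test",
    "significance_stars",
    "holm_adjust",
]

MIN_BOOTSTRAP = 10
DATASET_COLUMNS = ("cell_id", "condition", "contact_time_s", "adhesion_force_N")


@dataclass(frozen=True)
class AdhesionDataset:
    """Tidy table of (cell, condition, contact time, adhesion force)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("dataset has no records")
        if (df["adhesion_force_N"] < 0).any():
            raise ValueError("adhesion forces must be >= 0")
        object.__setattr__(self, "df", df.reset_index(drop=True))

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "AdhesionDataset":
        return cls(pd.DataFrame(records, columns=list(DATASET_COLUMNS)))

    @property
    def conditions(self) -> list[str]:
        return sorted(self.df["condition"].unique())

    def contact_times(self, condition: str | None = None) -> np.ndarray:
        df = self.df if condition is None else self._require(condition)
        return np.sort(df["contact_time_s"].unique())

    def _require(self, condition: str) -> pd.DataFrame:
        sub = self.df[self.df["condition"] == condition]
        if len(sub) == 0:
            raise KeyError(f"unknown condition {condition!r}")
        return sub

    def forces(self, condition: str, contact_time: float) -> np.ndarray:
        sub = self._require(condition)
        sub = sub[np.isclose(sub["contact_time_s"], contact_time)]
        if len(sub) == 0:
            raise KeyError(f"no records for {condition!r} at t={contact_time}")
        return sub["adhesion_force_N"].to_numpy()

    def condition_matrix(self, condition: str
                         ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(cells x times) force matrix for one condition, with the sorted
        time grid and the sorted cell ids.  Cells missing a time are dropped
        with a warning (the protocol probes every cell at every time)."""
        sub = self._require(condition)
        pivot = sub.pivot_table(index="cell_id", columns="contact_time_s",
                                values="adhesion_force_N", aggfunc="mean")
        pivot = pivot.sort_index()
        complete = pivot.dropna()
        if len(complete) < len(pivot):
            warnings.warn(f"condition {condition!r}: dropped "
                          f"{len(pivot) - len(complete)} cells with "
                          "incomplete time coverage")
        if len(complete) == 0:
            raise ValueError(f"condition {condition!r} has no complete cells")
        times = complete.columns.to_numpy(dtype=float)
        return complete.to_numpy(dtype=float), times, list(complete.index)


def median_forces(ds: AdhesionDataset, condition: str
                  ) -> dict[float, float]:
    """Per-contact-time sample median (midpoint rule for even n)."""
    sub = ds._require(condition)
    out = {}
    for t, grp in sub.groupby("contact_time_s", sort=True):
        out[float(t)] = float(np.median(grp["adhesion_force_N"]))
    return out


def mann_whitney_medians(a: np.ndarray, b: np.ndarray
                         ) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test between two force samples.

    Uses the exact null distribution for small tie-free samples (both n <= 8)
    and the tie-corrected normal approximation (with continuity correction)
    otherwise.  Returns (U of the first sample, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(1.0, res.pvalue))


def discrete_slope(F1: float, F2: float, t1: float, t2: float) -> float:
    """Discrete slope ``(F2 - F1) / (t2 - t1)`` between two contact times;
    antisymmetric under swapping the points."""
    if t1 == t2:
        raise ValueError("t1 and t2 must differ")
    return (F2 - F1) / (t2 - t1)


def average_slope(medians: Mapping[float, float]) -> float:
    """Adhesion strengthening: unweighted mean of discrete slopes over
    consecutive time pairs on the sorted grid.  Needs >= 2 time points."""
    if len(medians) < 2:
        raise ValueError("slope undefined: need at least 2 time points")
    times = np.array(sorted(medians))
    forces = np.array([medians[t] for t in times], dtype=float)
    return float(np.mean(np.diff(forces) / np.diff(times)))


def _avg_slopes_from_medians(med: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Vectorised average slope for a (B x T) matrix of per-time medians."""
    return np.mean(np.diff(med, axis=-1) / np.diff(times), axis=-1)


def bootstrap_resample(ds: AdhesionDataset, condition: str, size: int,
                       rng: np.random.Generator) -> AdhesionDataset:
    """Resample whole cells (all their time points) with replacement to
    ``size`` cells for one condition.  Cell ids are kept (so resampled cells
    trace back to the originals); a ``replicate`` column distinguishes
    repeated draws of the same cell."""
    mat, times, cells = ds.condition_matrix(condition)
    if size < 1 or size > len(cells):
        raise ValueError("size must be in [1, number of cells]")
    idx = rng.integers(0, len(cells), size)
    rows = []
    for k, i in enumerate(idx):
        for j, t in enumerate(times):
            rows.append((cells[i], condition, float(t), mat[i, j], k))
    df = pd.DataFrame(rows, columns=list(DATASET_COLUMNS) + ["replicate"])
    return AdhesionDataset(df)


def _boot_median_matrix(mat: np.ndarray, B: int, size: int,
                        rng: np.random.Generator) -> np.ndarray:
    """B x T per-time medians of cell resamples of a (cells x T) matrix."""
    idx = rng.integers(0, mat.shape[0], (B, size))
    return np.median(mat[idx, :], axis=1)


def _percentile_p(values: np.ndarray) -> float:
    """Two-sided bootstrap percentile p for H0: statistic = 0."""
    B = values.size
    n_le = int(np.sum(values <= 0))
    n_ge = int(np.sum(values >= 0))
    return float(min(1.0, 2.0 * min(n_le, n_ge) / B))


def significance_stars(p: float) -> str:
    """The study's star convention: ****<0.0001, ***<0.001, **<0.01, *<0.05,
    NS otherwise."""
    for threshold, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"),
                             (5e-2, "*")):
        if p < threshold:
            return stars
    return "NS"


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adjusted[i] = min(1.0, running)
    return adjusted


@dataclass(frozen=True)
class SlopeResult:
    """Observed and bootstrap adhesion-strengthening slopes for two groups."""

    slope_obs: dict[str, float]          # N/s per group
    boot_slopes: dict[str, np.ndarray]   # B-length arrays per group
    p_value: float
    B: int
    seed: int | None
    method: str
    n_cells: dict[str, int] = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def _single_condition(ds: AdhesionDataset, condition: str | None) -> str:
    if condition is not None:
        return condition
    conds = ds.conditions
    if len(conds) != 1:
        raise ValueError("dataset holds several conditions; pass one "
                         f"explicitly (found {conds})")
    return conds[0]


def slope_difference_test(ds_a: AdhesionDataset, ds_b: AdhesionDataset,
                          B: int = 100, seed: int | None = None,
                          condition_a: str | None = None,
                          condition_b: str | None = None,
                          method: str = "percentile") -> SlopeResult:
    """Test for a difference in adhesion strengthening between two groups.

    Each bootstrap replicate resamples both groups to the smaller group's
    cell count ("samples of equal size"), computes per-time medians on the
    common contact-time grid, and takes the average slope.  Both groups draw
    their resampling indices from identically seeded generators, so comparing
    a group with itself under one seed gives identical replicates and p = 1.

    ``method="percentile"`` (default) tests the B replicate slope differences
    against zero with the two-sided bootstrap percentile rule;
    ``method="wilcoxon"`` is the rank-sum between the two replicate samples
    (anti-conservative; see module docstring).
    """
    if B < MIN_BOOTSTRAP:
        raise ValueError(f"B must be >= {MIN_BOOTSTRAP}")
    cond_a = _single_condition(ds_a, condition_a)
    cond_b = _single_condition(ds_b, condition_b)
    mat_a, times_a, _ = ds_a.condition_matrix(cond_a)
    mat_b, times_b, _ = ds_b.condition_matrix(cond_b)
    common = np.intersect1d(times_a, times_b)
    if common.size < 2:
        raise ValueError("groups share fewer than 2 contact times")
    mat_a = mat_a[:, np.isin(times_a, common)]
    mat_b = mat_b[:, np.isin(times_b, common)]
    size = min(mat_a.shape[0], mat_b.shape[0])

    rng_a = np.random.default_rng(seed)
    rng_b = np.random.default_rng(seed)
    boot_a = _avg_slopes_from_medians(
        _boot_median_matrix(mat_a, B, size, rng_a), common)
    boot_b = _avg_slopes_from_medians(
        _boot_median_matrix(mat_b, B, size, rng_b), common)

    if method == "percentile":
        p = _percentile_p(boot_a - boot_b)
    elif method == "wilcoxon":
        res = sps.mannwhitneyu(boot_a, boot_b, alternative="two-sided",
                               method="asymptotic")
        p = float(min(1.0, res.pvalue))
    else:
        raise ValueError(f"unknown method {method!r}")

    label_a = cond_a
    label_b = cond_b if cond_b != cond_a else f"{cond_b} (B)"
    obs_a = _avg_slopes_from_medians(np.median(mat_a, axis=0)[None, :],
                                     common)[0]
    obs_b = _avg_slopes_from_medians(np.median(mat_b, axis=0)[None, :],
                                     common)[0]
    return SlopeResult(
        slope_obs={label_a: obs_a, label_b: obs_b},
        boot_slopes={label_a: boot_a, label_b: boot_b},
        p_value=p, B=B, seed=seed, method=method,
        n_cells={label_a: mat_a.shape[0], label_b: mat_b.shape[0]},
    )


def interaction_epsilon(F_AB: float, F_0: float, F_A: float,
                        F_B: float) -> float:
    """Deviation from the additive null: ``F_AB + F_0 - F_A - F_B``.

    Positive epsilon means the joint condition exceeds the sum of the single
    contributions (positive interaction); negative epsilon indicates
    competition.  Symmetric under exchanging A and B."""
    return F_AB + F_0 - F_A - F_B


@dataclass(frozen=True)
class InteractionResult:
    """Per-contact-time interaction statistic with bootstrap inference."""

    contact_times: np.ndarray            # s
    epsilon_obs: np.ndarray              # N, per contact time
    boot_epsilon: np.ndarray             # B x T
    p_per_time: np.ndarray               # raw two-sided p per time
    p_holm: np.ndarray                   # Holm-adjusted p per time
    p_pooled: float                      # min Holm-adjusted p
    sign: tuple[str, ...]                # "positive" | "negative" | "none"
    conditions: dict[str, str]           # roles AB/A/B/0 -> condition names
    B: int
    seed: int | None
    method: str
    alpha: float


def interaction_test(ds: AdhesionDataset,
                     conditions: Mapping[str, str] | Sequence[str],
                     B: int = 100, seed: int | None = None,
                     alpha: float = 0.05,
                     method: str = "percentile") -> InteractionResult:
    """Bootstrap test of no interaction (epsilon = 0) at each contact time.

    ``conditions`` maps the roles ``AB``, ``A``, ``B`` and ``0`` to condition
    labels in the dataset (or is a sequence in that order).  Per replicate,
    every condition is resampled to the smallest condition's cell count,
    per-time medians are taken on the shared grid, and epsilon is evaluated
    per time.  ``method="percentile"`` (default) applies the two-sided
    bootstrap percentile rule per time; ``method="wilcoxon"`` is the one-
    sample Wilcoxon signed-rank of the B replicate epsilons against zero
    (Pratt zero handling, normal approximation; anti-conservative).  Per-time
    p-values are Holm-adjusted across the grid; the pooled p is the smallest
    adjusted value.  The per-time sign is reported where the raw p is below
    ``alpha``.
    """
    if B < MIN_BOOTSTRAP:
        raise ValueError(f"B must be >= {MIN_BOOTSTRAP}")
    roles = ("AB", "A", "B", "0")
    if not isinstance(conditions, Mapping):
        if len(conditions) != 4:
            raise ValueError("need 4 condition labels in order AB, A, B, 0")
        conditions = dict(zip(roles, conditions))
    missing_roles = [r for r in roles if r not in conditions]
    if missing_roles:
        raise ValueError(f"missing roles: {missing_roles}")
    present = set(ds.conditions)
    absent = [conditions[r] for r in roles if conditions[r] not in present]
    if absent:
        raise ValueError(f"dataset is missing conditions: {absent}")

    mats, times_list = {}, []
    for r in roles:
        mat, times, _ = ds.condition_matrix(conditions[r])
        mats[r] = mat
        times_list.append(times)
    grid = times_list[0]
    for times in times_list[1:]:
        if times.shape != grid.shape or not np.allclose(times, grid):
            raise ValueError("all four conditions must share the "
                             "contact-time grid")
    size = min(m.shape[0] for m in mats.values())

    rng = np.random.default_rng(seed)
    boot_med = {r: _boot_median_matrix(mats[r], B, size, rng) for r in roles}
    boot_eps = (boot_med["AB"] + boot_med["0"]
                - boot_med["A"] - boot_med["B"])          # B x T
    obs_med = {r: np.median(mats[r], axis=0) for r in roles}
    eps_obs = obs_med["AB"] + obs_med["0"] - obs_med["A"] - obs_med["B"]

    p_per_time = np.empty(grid.size)
    for j in range(grid.size):
        col = boot_eps[:, j]
        if method == "percentile":
            p_per_time[j] = _percentile_p(col)
        elif method == "wilcoxon":
            if np.all(col == 0):
                p_per_time[j] = 1.0
            else:
                res = sps.wilcoxon(col, zero_method="pratt",
                                   alternative="two-sided", method="approx")
                p_per_time[j] = float(min(1.0, res.pvalue))
        else:
            raise ValueError(f"unknown method {method!r}")

    p_holm = holm_adjust(p_per_time)
    signs = tuple(
        ("positive" if np.median(boot_eps[:, j]) > 0 else "negative")
        if p_per_time[j] < alpha and np.median(boot_eps[:, j]) != 0 else "none"
        for j in range(grid.size))
    return InteractionResult(
        contact_times=grid,
        epsilon_obs=eps_obs,
        boot_epsilon=boot_eps,
        p_per_time=p_per_time,
        p_holm=p_holm,
        p_pooled=float(p_holm.min()),
        sign=signs,
        conditions=dict(conditions),
        B=B, seed=seed, method=method, alpha=alpha,
    )
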