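"""Permutation-based group comparison of network parameters.

Because a structural covariance network describes a *group* of subjects,
group differences in its parameters cannot be tested subject-wise.
Instead, the whole network estimation is repeated under random
reallocation of subjects to two groups of the original sizes: for each
shuffle both group networks are re-estimated at the same penalty rho (the
whole-sample cross-validated value) and the metric difference is recorded,
building a permutation null distribution for the observed low - high
difference.

The reported p-value is the add-one two-tailed count,

    p = (1 + #{ |null diff| >= |observed diff| }) / (1 + n_perm),

an equivalent decision rule at alpha = 0.05 to thresholding at the 95th
percentile of |null diff| over 5,000 shuffles, but usable as a p-value
per contrast.  p is never exactly 0.

For the longitudinal design, the omnibus change contrast is the
difference-in-differences

    (metric_low,T2 - metric_low,T1) - (metric_high,T2 - metric_high,T1),

permuted by reallocating subjects (both of their timepoints together).

Every shuffle draws from its own child of a ``numpy.random.SeedSequence``
rooted at ``seed``, so results are reproducible and independent of how
shuffles are batched across workers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._glasso import GlassoNonConvergence, glasso
from .grouping import GroupAssignment
from .metrics import METRIC_NAMES, network_metric
from .network import EDGE_FLOOR


@dataclass
class PermutationResult:
    """Observed group difference, its permutation null, and p-values."""

    component_name: str
    metric_name: str
    contrast: str  # "T2", "T1", or "T2-T1"
    observed_low: float
    observed_high: float
    observed_diff: float  # low - high
    null_diffs: np.ndarray
    p_raw: float
    n_perm: int
    seed: int
    p_fdr: float | None = None

    def __post_init__(self) -> None:
        self.null_diffs = np.asarray(self.null_diffs, dtype=np.float64)
        if self.null_diffs.size != self.n_perm:
            raise ValueError("null_diffs length must equal n_perm")
        if not (0 < self.p_raw <= 1):
            raise ValueError("p_raw must lie in (0, 1]")


def _values_and_subjects(thickness) -> tuple[np.ndarray, list[str]]:
    if hasattr(thickness, "values") and hasattr(thickness, "subject_ids"):
        return np.asarray(thickness.values, float), list(thickness.subject_ids)
    if isinstance(thickness, pd.DataFrame):
        return thickness.to_numpy(float), list(thickness.index.astype(str))
    X = np.asarray(thickness, float)
    return X, [str(i) for i in range(X.shape[0])]


def _group_adjacency(X, rho, warm):
    """Lean version of estimate_sparse_network for the permutation hot loop:
    same estimator, same edge rule, no container construction."""
    S = np.corrcoef(X, rowvar=False)
    _, Theta, _ = glasso(
        S, rho, W_init=warm[0], Theta_init=warm[1], check_input=False
    )
    d = np.sqrt(np.diag(Theta))
    R = np.abs(Theta) / np.outer(d, d)
    A = (R > EDGE_FLOOR).astype(np.int8)
    np.fill_diagonal(A, 0)
    return A, None


def _default_shuffler(rng: np.random.Generator, n: int, n_low: int) -> np.ndarray:
    """Random reallocation preserving the original group sizes; returns a
    boolean low-group mask."""
    perm = rng.permutation(n)
    mask = np.zeros(n, dtype=bool)
    mask[perm[:n_low]] = True
    return mask


def _two_tailed_p(observed: float, null: np.ndarray) -> float:
    return float((1 + np.sum(np.abs(null) >= abs(observed))) / (1 + null.size))


def _whole_sample_warm(X: np.ndarray, rho: float):
    """One whole-sample fit whose solution warm-starts every group fit."""
    S = np.corrcoef(X, rowvar=False)
    W, Theta, _ = glasso(S, rho)
    return W, Theta


def permutation_test(
    thickness,
    group_assignment: GroupAssignment,
    metric_name: str,
    rho: float,
    n_perm: int = 5000,
    resolution: float = 1.0,
    seed: int = 0,
    *,
    contrast: str = "T2",
    shuffler: Callable[[np.random.Generator, int, int], np.ndarray] | None = None,
    jobs: int = 1,
) -> PermutationResult:
    """Cross-sectional permutation test of a network metric at one timepoint.

    Parameters
    ----------
    thickness
        ThicknessMatrix or (subjects x regions) DataFrame for the timepoint
        under test.  Only column correlations enter the networks.
    group_assignment
        Low/high labels from :func:`scovnet.grouping.median_split`.
    metric_name
        One of ``local_efficiency``, ``global_efficiency``,
        ``participation``.
    rho
        Penalty shared by every network (the whole-sample CV value).
    shuffler
        Test hook replacing the random reallocation; same signature and
        return (boolean low mask) as the default.
    jobs
        Permutations may be evaluated in parallel; results are
        seed-identical for any value.
    """
    if metric_name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric_name!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X, subjects = _values_and_subjects(thickness)
    n = X.shape[0]
    low_mask = group_assignment.mask(subjects, "low")
    n_low = int(low_mask.sum())
    if n_low < 3 or n - n_low < 3:
        raise ValueError("each group needs at least 3 subjects")
    warm = _whole_sample_warm(X, rho)
    if shuffler is None:
        shuffler = _default_shuffler

    def metric_diff(mask: np.ndarray) -> float:
        a_lo, _ = _group_adjacency(X[mask], rho, warm)
        a_hi, _ = _group_adjacency(X[~mask], rho, warm)
        m_lo = network_metric(a_lo, metric_name, resolution, seed=seed, validate=False)
        m_hi = network_metric(a_hi, metric_name, resolution, seed=seed, validate=False)
        return m_lo, m_hi

    obs_lo, obs_hi = metric_diff(low_mask)
    observed = obs_lo - obs_hi

    null = _null_distribution(
        lambda mask: (lambda lo_hi: lo_hi[0] - lo_hi[1])(metric_diff(mask)),
        shuffler, n, n_low, n_perm, seed, jobs,
    )
    return PermutationResult(
        component_name=group_assignment.component_name,
        metric_name=metric_name,
        contrast=contrast,
        observed_low=float(obs_lo),
        observed_high=float(obs_hi),
        observed_diff=float(observed),
        null_diffs=null,
        p_raw=_two_tailed_p(observed, null),
        n_perm=n_perm,
        seed=int(seed),
    )


def omnibus_change_test(
    thickness_t1,
    thickness_t2,
    group_assignment: GroupAssignment,
    metric_name: str,
    rho: float,
    n_perm: int = 5000,
    resolution: float = 1.0,
    seed: int = 0,
    *,
    shuffler: Callable[[np.random.Generator, int, int], np.ndarray] | None = None,
    jobs: int = 1,
) -> PermutationResult:
    """Permutation test of the group difference in Time2 - Time1 change.

    The statistic is the difference-in-differences of the metric; each
    shuffle reallocates subjects (carrying both their timepoints) to
    groups of the original sizes.
    """
    if metric_name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric_name!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X1, subjects1 = _values_and_subjects(thickness_t1)
    X2, subjects2 = _values_and_subjects(thickness_t2)
    if subjects1 != subjects2:
        raise ValueError("timepoints must be aligned to the same subjects")
    n = X1.shape[0]
    low_mask = group_assignment.mask(subjects1, "low")
    n_low = int(low_mask.sum())
    warm1 = _whole_sample_warm(X1, rho)
    warm2 = _whole_sample_warm(X2, rho)
    if shuffler is None:
        shuffler = _default_shuffler

    def changes(mask: np.ndarray) -> tuple[float, float]:
        out = []
        for grp_mask in (mask, ~mask):
            a1, _ = _group_adjacency(X1[grp_mask], rho, warm1)
            a2, _ = _group_adjacency(X2[grp_mask], rho, warm2)
            m1 = network_metric(a1, metric_name, resolution, seed=seed, validate=False)
            m2 = network_metric(a2, metric_name, resolution, seed=seed, validate=False)
            out.append(m2 - m1)
        return out[0], out[1]

    ch_lo, ch_hi = changes(low_mask)
    observed = ch_lo - ch_hi
    null = _null_distribution(
        lambda mask: (lambda c: c[0] - c[1])(changes(mask)),
        shuffler, n, n_low, n_perm, seed, jobs,
    )
    return PermutationResult(
        component_name=group_assignment.component_name,
        metric_name=metric_name,
        contrast="T2-T1",
        observed_low=float(ch_lo),
        observed_high=float(ch_hi),
        observed_diff=float(observed),
        null_diffs=null,
        p_raw=_two_tailed_p(observed, null),
        n_perm=n_perm,
        seed=int(seed),
    )


def _null_distribution(
    statistic: Callable[[np.ndarray], float],
    shuffler,
    n: int,
    n_low: int,
    n_perm: int,
    seed: int,
    jobs: int,
) -> np.ndarray:
    """Evaluate the statistic over seeded shuffles.

    Each draw owns a SeedSequence child, so the result is independent of
    batching.  A draw whose network fit fails to converge is redrawn (a
    fresh child), within a total budget of 2 * n_perm draws.
    """
    max_draws = 2 * n_perm
    children = np.random.SeedSequence(seed).spawn(max_draws)

    def evaluate(k: int) -> float | None:
        rng = np.random.default_rng(children[k])
        mask = shuffler(rng, n, n_low)
        try:
            return statistic(np.asarray(mask, dtype=bool))
        except GlassoNonConvergence:
            return None

    if jobs != 1:
        from joblib import Parallel, delayed

        # evaluate in fixed-size batches until n_perm successes, preserving
        # draw order so any jobs value gives identical output
        null: list[float] = []
        k = 0
        batch = max(n_perm // 4, 1)
        while len(null) < n_perm and k < max_draws:
            hi = min(k + batch, max_draws)
            vals = Parallel(n_jobs=jobs)(delayed(evaluate)(i) for i in range(k, hi))
            null.extend(v for v in vals if v is not None)
            k = hi
        null = null[:n_perm]
    else:
        null = []
        k = 0
        while len(null) < n_perm and k < max_draws:
            v = evaluate(k)
            if v is not None:
                null.append(v)
            k += 1
    if len(null) < n_perm:
        raise RuntimeError(
            f"permutation redraw budget exhausted: only {len(null)} of "
            f"{n_perm} shuffles converged within {max_draws} draws"
        )
    return np.asarray(null, dtype=np.float64)


def fdr_adjust(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1).

    ``q`` is the nominal FDR level used downstream for significance calls;
    the adjusted values themselves do not depend on it.
    """
    p = np.asarray(list(p_values), dtype=np.float64)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[1]
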