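"""Median-split grouping on behavioral component scores and covariate screening.

Structural covariance networks are group-level objects (one network per
group of subjects), so continuous behavioral scores must be dichotomized
before networks can be compared.  Following the reference design, each of
four parenting-behavior component scores is split at its sample median into
equally sized low/high groups, and candidate confounders (age, sex, symptom
scores, ...) are screened with per-covariate two-group tests under a joint
Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: component names in the reference design, in fixed order
DEFAULT_COMPONENTS = (
    "negativity_epi",
    "warmth",
    "negativity_psi",
    "communication",
)


@dataclass
class ComponentScores:
    """Per-subject standardized behavioral component scores."""

    subject_ids: list[str]
    component_names: tuple[str, ...]
    scores: np.ndarray  # (n_subjects, n_components)

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.component_names = tuple(str(c) for c in self.component_names)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        n, k = len(self.subject_ids), len(self.component_names)
        if self.scores.shape != (n, k):
            raise ValueError(
                f"scores shape {self.scores.shape} != ({n} subjects, {k} components)"
            )
        if not np.isfinite(self.scores).all():
            raise ValueError("component scores contain missing/non-finite values")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ComponentScores":
        return cls(
            list(df.index.astype(str)),
            tuple(df.columns.astype(str)),
            df.to_numpy(dtype=np.float64),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=pd.Index(self.subject_ids, name="subject"),
            columns=list(self.component_names),
        )

    def column(self, component_name: str) -> np.ndarray:
        if component_name not in self.component_names:
            raise KeyError(
                f"unknown component {component_name!r}; "
                f"available: {list(self.component_names)}"
            )
        return self.scores[:, self.component_names.index(component_name)]


@dataclass
class GroupAssignment:
    """Low/high labels for one component's median split."""

    component_name: str
    labels: dict[str, str]  # subject_id -> "low" | "high"

    @property
    def n_low(self) -> int:
        return sum(1 for v in self.labels.values() if v == "low")

    @property
    def n_high(self) -> int:
        return sum(1 for v in self.labels.values() if v == "high")

    def subjects(self, group: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == group]

    def mask(self, subject_ids: list[str], group: str) -> np.ndarray:
        return np.array([self.labels[s] == group for s in subject_ids])


def median_split(scores: ComponentScores, component_name: str) -> GroupAssignment:
    """Dichotomize one component score at the sample median.

    Subjects strictly below the median go to "low", strictly above to
    "high".  Subjects tied with the median are assigned in stable
    subject-ID order, each to the currently smaller group (ties between
    group sizes broken toward "low"), so sizes differ by at most one and
    the assignment is deterministic across runs.  The split depends only
    on the ordering of scores, so it is invariant to strictly monotone
    increasing transforms.
    """
    if len(scores.subject_ids) < 4:
        raise ValueError("median split needs at least 4 subjects")
    s = scores.column(component_name)
    med = float(np.median(s))
    labels: dict[str, str] = {}
    for subj, val in zip(scores.subject_ids, s):
        if val < med:
            labels[subj] = "low"
        elif val > med:
            labels[subj] = "high"
    n_low = sum(1 for v in labels.values() if v == "low")
    n_high = sum(1 for v in labels.values() if v == "high")
    for subj, val in zip(scores.subject_ids, s):
        if subj in labels:
            continue
        if n_low <= n_high:
            labels[subj] = "low"
            n_low += 1
        else:
            labels[subj] = "high"
            n_high += 1
    # preserve original subject order in the mapping
    ordered = {s_: labels[s_] for s_ in scores.subject_ids}
    return GroupAssignment(component_name=component_name, labels=ordered)


def screen_covariates(
    groups: list[GroupAssignment],
    covariates: pd.DataFrame,
    *,
    fdr_q: float = 0.05,
    binary_covariates: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Screen covariates for low/high group differences per component.

    Continuous covariates use a one-way ANOVA (two groups, so F equals the
    squared pooled-variance t statistic); binary covariates (detected as
    two-valued, or named explicitly) use a Pearson chi-squared test on the
    2x2 contingency table.  All component x covariate p-values form one
    Benjamini-Hochberg FDR family (24 comparisons in the reference design:
    4 components x 6 covariates).  Comparisons with zero within-group
    variance are reported as NA with a warning and excluded from the family.

    Returns a table with columns component, covariate, test, stat, p, p_fdr,
    one row per comparison.
    """
    if binary_covariates is None:
        binary_covariates = tuple(
            c for c in covariates.columns if covariates[c].dropna().nunique() <= 2
        )
    rows: list[dict] = []
    for ga in groups:
        for cov in covariates.columns:
            vals = covariates[cov].dropna()
            subj = [s for s in vals.index.astype(str) if s in ga.labels]
            lo = np.asarray([vals.loc[s] for s in subj if ga.labels[s] == "low"], float)
            hi = np.asarray([vals.loc[s] for s in subj if ga.labels[s] == "high"], float)
            row = {"component": ga.component_name, "covariate": cov}
            if len(lo) < 2 or len(hi) < 2:
                raise ValueError(
                    f"fewer than 2 non-missing values per group for covariate "
                    f"{cov!r} on component {ga.component_name!r}"
                )
            if cov in binary_covariates:
                levels = np.unique(np.concatenate([lo, hi]))
                table = np.array(
                    [[np.sum(g == lev) for lev in levels] for g in (lo, hi)]
                )
                if table.shape[1] < 2 or (table.sum(axis=0) == 0).any():
                    warnings.warn(
                        f"covariate {cov!r} is constant for component "
                        f"{ga.component_name!r}; reported as NA",
                        stacklevel=2,
                    )
                    row.update(test="chi2", stat=np.nan, p=np.nan)
                else:
                    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                    row.update(test="chi2", stat=float(chi2), p=float(p))
            else:
                if lo.std(ddof=1) == 0 and hi.std(ddof=1) == 0:
                    if lo.mean() == hi.mean():
                        warnings.warn(
                            f"covariate {cov!r} has zero within-group variance for "
                            f"component {ga.component_name!r}; reported as NA",
                            stacklevel=2,
                        )
                        row.update(test="anova", stat=np.nan, p=np.nan)
                    else:
                        row.update(test="anova", stat=np.inf, p=0.0)
                else:
                    F, p = stats.f_oneway(lo, hi)
                    row.update(test="anova", stat=float(F), p=float(p))
            rows.append(row)
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_fdr"] = multipletests(
            out.loc[ok, "p"].to_numpy(), alpha=fdr_q, method="fdr_bh"
        )[1]
    return out
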