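"""Synthetic longitudinal cortical-thickness cohorts with planted structure.

The generator emulates the statistical design the analysis assumes: a
cohort of mother-child dyads (n = 114 in the reference design) with
regional cortical thickness measured at two timepoints ~18 months apart
over 148 Destrieux regions, four skewed parenting-behavior component
scores, and a handful of demographic/symptom covariates.

Thickness is drawn from a multivariate normal whose region x region
correlation matrix is block-structured: regions are partitioned into
``n_modules`` modules of as-equal-as-possible size, with correlation
``within_module_corr`` between every pair inside a module, and
``between_module_corr`` between *slot-matched* cross-module pairs only
(region i of module A with region i of module B, mimicking homotopic or
long-range association pairs); all other cross-module pairs are
marginally uncorrelated.  The slot-matched design is deliberate: a
*uniform* between-module correlation is a single global factor that
partial-correlation networks remove by construction, leaving nothing for
a between-module group effect to act on, whereas slot-matched bridges
carry substantial partial correlations and therefore appear as
cross-module edges in the estimated sparse networks.

Longitudinal dependence is equicorrelated per region: the Time-1 and
Time-2 latent fields share correlation ``timepoint_corr`` coordinate-wise,
i.e. the joint 2p-dimensional covariance is the Kronecker product of a 2x2
test-retest block with the regional correlation matrix (when both
timepoints share that matrix).

A group effect, when planted, scales the between-module correlation by
``group_effect`` for subjects in the *low* half of the second ("warmth")
component's median split — making the low group's networks more modular
(more segregated, lower participation coefficient) when
``group_effect < 1``.  ``group_effect = 1`` yields a fully exchangeable
null cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import optimize

from .grouping import ComponentScores, DEFAULT_COMPONENTS, median_split
from .io import ThicknessMatrix, write_thickness_table

import pandas as pd

#: reference-cohort skewness targets for the four component scores
DEFAULT_SCORE_SKEWS = (1.98, 0.23, 0.89, -1.80)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the reference design: 114 subjects, 148 regions,
    4 modules, two timepoints.  Correlation defaults (within 0.50,
    slot-matched between 0.25, test-retest 0.70) are chosen to give
    sparse networks with clear modular structure at realistic sample
    sizes.
    """

    n_subjects: int = 114
    n_regions: int = 148
    n_modules: int = 4
    within_module_corr: float = 0.50
    between_module_corr: float = 0.25
    group_effect: float = 1.0
    effect_timepoints: tuple[str, ...] = ("T1", "T2")
    timepoint_corr: float = 0.70
    mean_thickness: float = 2.5
    thickness_sd: float = 0.25
    score_skew: tuple[float, ...] | float = DEFAULT_SCORE_SKEWS
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if self.n_regions < 2 or self.n_modules < 1:
            raise ValueError("need n_regions >= 2 and n_modules >= 1")
        if self.n_modules > self.n_regions:
            raise ValueError("n_modules cannot exceed n_regions")
        w, b = self.within_module_corr, self.between_module_corr
        if not (0 <= b <= w < 1):
            raise ValueError(
                f"require 0 <= between_module_corr ({b}) <= "
                f"within_module_corr ({w}) < 1"
            )
        if not (0 <= self.timepoint_corr < 1):
            raise ValueError("timepoint_corr must be in [0, 1)")
        if self.thickness_sd <= 0 or self.mean_thickness <= 0:
            raise ValueError("mean_thickness and thickness_sd must be > 0")
        if self.group_effect < 0:
            raise ValueError("group_effect must be >= 0")
        for tp in self.effect_timepoints:
            if tp not in ("T1", "T2"):
                raise ValueError(f"effect_timepoints entries must be T1/T2, got {tp!r}")
        # the scaled (low-group) matrix must remain positive definite
        for grp in ("high", "low"):
            R = population_covariance(self, group=grp, _validated=True)
            lam = float(np.linalg.eigvalsh(R)[0])
            if lam <= 1e-10:
                raise ValueError(
                    f"implied correlation matrix for the {grp} group is not "
                    f"positive definite (min eigenvalue {lam:.3e}); offending "
                    f"parameters: within_module_corr={w}, "
                    f"between_module_corr={b}, group_effect={self.group_effect}"
                )

    @property
    def score_skews(self) -> tuple[float, ...]:
        if isinstance(self.score_skew, (int, float)):
            return (float(self.score_skew),) * len(DEFAULT_COMPONENTS)
        return tuple(float(s) for s in self.score_skew)


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth that produced it."""

    thickness_t1: ThicknessMatrix
    thickness_t2: ThicknessMatrix
    component_scores: ComponentScores
    covariates: pd.DataFrame
    truth: dict


def module_assignment(config: SyntheticConfig) -> np.ndarray:
    """Region -> module ids, modules sized as evenly as possible."""
    sizes = np.full(config.n_modules, config.n_regions // config.n_modules)
    sizes[: config.n_regions % config.n_modules] += 1
    return np.repeat(np.arange(config.n_modules), sizes)


def region_labels(n_regions: int) -> list[str]:
    """Hemisphere-prefixed generic parcel labels (any unique strings work)."""
    half = n_regions // 2
    labels = [f"lh_reg{i + 1:03d}" for i in range(half)]
    labels += [f"rh_reg{i + 1:03d}" for i in range(n_regions - half)]
    return labels


def slot_assignment(config: SyntheticConfig) -> np.ndarray:
    """Within-module slot index per region; slot-matched cross-module
    pairs carry the between-module correlation."""
    mods = module_assignment(config)
    slots = np.empty(config.n_regions, dtype=np.int64)
    for m in range(config.n_modules):
        idx = np.flatnonzero(mods == m)
        slots[idx] = np.arange(idx.size)
    return slots


def population_covariance(
    config: SyntheticConfig, group: str = "high", *, _validated: bool = False
) -> np.ndarray:
    """The exact planted region x region correlation matrix (diagonal 1).

    Entries: ``within_module_corr`` for pairs in the same module;
    ``between_module_corr`` for slot-matched pairs in different modules;
    0 for all other cross-module pairs.  ``group="low"`` applies the
    ``group_effect`` scaling to the between-module (bridge) correlations.
    """
    if not _validated:
        config.validate()
    if group not in ("low", "high"):
        raise ValueError("group must be 'low' or 'high'")
    mods = module_assignment(config)
    slots = slot_assignment(config)
    b = config.between_module_corr
    if group == "low":
        b *= config.group_effect
    same_mod = mods[:, None] == mods[None, :]
    same_slot = slots[:, None] == slots[None, :]
    R = np.where(same_mod, config.within_module_corr,
                 np.where(same_slot, b, 0.0))
    np.fill_diagonal(R, 1.0)
    return R


def _lognormal_sigma_for_skew(target: float) -> float:
    """sigma of a log-normal whose skewness is |target|."""

    def skew_of(s: float) -> float:
        e = np.exp(s * s)
        return (e + 2.0) * np.sqrt(e - 1.0)

    return float(optimize.brentq(lambda s: skew_of(s) - abs(target), 1e-6, 3.0))


def _skewed_scores(rng: np.random.Generator, n: int, skew: float) -> np.ndarray:
    """Standardized scores with approximately the requested skewness.

    Shifted log-normal standardized by its analytic mean/SD; the sign of
    ``skew`` mirrors the distribution.  ``skew = 0`` falls back to normal.
    """
    if abs(skew) < 1e-12:
        return rng.standard_normal(n)
    sigma = _lognormal_sigma_for_skew(skew)
    x = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    mu = np.exp(sigma**2 / 2)
    sd = np.sqrt((np.exp(sigma**2) - 1) * np.exp(sigma**2))
    z = (x - mu) / sd
    return z if skew >= 0 else -z


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort for ``config.seed``.

    Component scores are drawn first; the median split of the second
    component ("warmth") defines the low/high groups; thickness at both
    timepoints is then drawn from the group's planted correlation matrix
    with per-region test-retest correlation ``timepoint_corr``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_regions
    subjects = [f"S{i + 1:04d}" for i in range(n)]
    regions = region_labels(p)

    skews = config.score_skews
    comp = np.column_stack([_skewed_scores(rng, n, s) for s in skews])
    scores = ComponentScores(subjects, DEFAULT_COMPONENTS, comp)
    split = median_split(scores, DEFAULT_COMPONENTS[1])
    low_mask = split.mask(subjects, "low")

    # latent fields: Z1, Z2 i.i.d. N(0, I_p); T2 latent = t*Z1 + sqrt(1-t^2)*Z2
    t = config.timepoint_corr
    Z1 = rng.standard_normal((n, p))
    Z2 = rng.standard_normal((n, p))
    G = {"T1": Z1, "T2": t * Z1 + np.sqrt(1.0 - t * t) * Z2}

    chol = {
        grp: np.linalg.cholesky(population_covariance(config, group=grp, _validated=True))
        for grp in ("high", "low")
    }
    values = {}
    for tp in ("T1", "T2"):
        X = np.empty((n, p))
        for grp, mask in (("high", ~low_mask), ("low", low_mask)):
            use = grp if (grp == "low" and tp in config.effect_timepoints) else "high"
            X[mask] = G[tp][mask] @ chol[use].T
        values[tp] = config.mean_thickness + config.thickness_sd * X

    thickness = {
        tp: ThicknessMatrix(subjects, regions, values[tp], timepoint=tp)
        for tp in ("T1", "T2")
    }

    covariates = pd.DataFrame(
        {
            "age_years": np.round(rng.normal(8.4, 0.35, size=n), 2),
            "sex": rng.integers(0, 2, size=n),
            "depression_tscore": np.round(rng.normal(48.0, 8.0, size=n), 1),
            "anxiety_tscore": np.round(rng.normal(49.0, 8.0, size=n), 1),
            "trauma_events": rng.poisson(1.0, size=n),
            "maternal_occupation": rng.integers(0, 2, size=n),
        },
        index=pd.Index(subjects, name="subject"),
    )

    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "module_assignment": module_assignment(config).tolist(),
        "group_labels": dict(split.labels),
        "effect_component": DEFAULT_COMPONENTS[1],
        "group_effect": config.group_effect,
    }
    return SyntheticCohort(
        thickness_t1=thickness["T1"],
        thickness_t2=thickness["T2"],
        component_scores=scores,
        covariates=covariates,
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write a cohort as plain-text tables plus a JSON truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "thickness_t1": outdir / "thickness_t1.csv",
        "thickness_t2": outdir / "thickness_t2.csv",
        "component_scores": outdir / "component_scores.csv",
        "covariates": outdir / "covariates.csv",
        "truth": outdir / "truth.json",
    }
    write_thickness_table(cohort.thickness_t1, paths["thickness_t1"])
    write_thickness_table(cohort.thickness_t2, paths["thickness_t2"])
    cohort.component_scores.to_frame().to_csv(
        paths["component_scores"], float_format="%.17g"
    )
    cohort.covariates.to_csv(paths["covariates"])
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}


def config_from_file(path) -> SyntheticConfig:
    """Load a SyntheticConfig from a JSON or YAML file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if "score_skew" in raw and isinstance(raw["score_skew"], list):
        raw["score_skew"] = tuple(raw["score_skew"])
    if "effect_timepoints" in raw:
        raw["effect_timepoints"] = tuple(raw["effect_timepoints"])
    return SyntheticConfig(**raw)
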