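"""End-to-end orchestration: from thickness tables (or a synthetic cohort)
to the comparison tables.

A single :class:`RunConfig` drives the full analysis:

1. read and align the two timepoints (or simulate a cohort),
2. quality-screen by regional z-score (report only),
3. standardize regions,
4. cross-validate one whole-sample penalty rho (reused for *every*
   network, group or permuted),
5. median-split subjects per behavioral component,
6. per component x metric: Time-1 descriptives, Time-2 permutation test,
   omnibus Time2 - Time1 change test,
7. Benjamini-Hochberg FDR per metric x contrast family (4 components),
8. write the three metric tables, group networks, and a JSON bundle
   embedding every seed, rho and the CV curve.

All randomness descends from ``master_seed`` through named child seeds, so
any single (component, metric, contrast) cell can be recomputed in
isolation with its recorded child seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .grouping import DEFAULT_COMPONENTS, ComponentScores, GroupAssignment, median_split
from .inference import PermutationResult, fdr_adjust, omnibus_change_test, permutation_test
from .metrics import METRIC_NAMES, compute_network_metrics
from .network import estimate_sparse_network, select_regularization, write_network
from .synthetic import SyntheticConfig, generate_cohort

log = logging.getLogger("scovnet")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    # either explicit input paths ...
    thickness_t1: str | None = None
    thickness_t2: str | None = None
    component_scores: str | None = None
    covariates: str | None = None
    # ... or a synthetic cohort
    synthetic: SyntheticConfig | None = None

    rho: float | str = "cv"  # "cv" or a fixed penalty
    rho_grid: list[float] | None = None
    k_folds: int = 3
    n_perm: int = 5000
    resolution: float = 1.0
    z_threshold: float = 3.0
    fdr_q: float = 0.05
    master_seed: int = 0
    outdir: str = "scovnet_out"
    jobs: int = 1
    test_t1: bool = False  # also permutation-test the Time-1 cross-section
    write_networks: bool = True

    def validate(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        have_paths = self.thickness_t1 and self.thickness_t2 and self.component_scores
        if self.synthetic is None and not have_paths:
            raise ValueError(
                "provide thickness_t1/thickness_t2/component_scores paths "
                "or a synthetic block"
            )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if raw.get("synthetic") is not None:
            syn = dict(raw["synthetic"])
            for key in ("score_skew", "effect_timepoints"):
                if isinstance(syn.get(key), list):
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = SyntheticConfig(**syn)
        return cls(**raw)


def _child_seeds(master_seed: int, names: list[str]) -> dict[str, int]:
    """Deterministic named child seeds below 2**31."""
    rng = np.random.default_rng(master_seed)
    return {name: int(rng.integers(2**31)) for name in names}


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        syn = config.synthetic
        cohort = generate_cohort(syn)
        return cohort.thickness_t1, cohort.thickness_t2, cohort.component_scores, cohort.covariates
    t1 = mio.read_thickness_table(config.thickness_t1, timepoint="T1")
    t2 = mio.read_thickness_table(config.thickness_t2, timepoint="T2")
    scores = ComponentScores.from_frame(
        pd.read_csv(config.component_scores, index_col=0)
    )
    cov = (
        pd.read_csv(config.covariates, index_col=0)
        if config.covariates
        else None
    )
    if cov is not None:
        cov.index = cov.index.astype(str)
    return t1, t2, scores, cov


def _restrict_scores(scores: ComponentScores, subjects: list[str]) -> ComponentScores:
    frame = scores.to_frame().loc[subjects]
    return ComponentScores.from_frame(frame)


def results_table(results: list[PermutationResult], metric_name: str) -> pd.DataFrame:
    """Mirror of the published per-metric comparison table layout.

    One row per component x {Time 1, Time 2, Time 2 - Time 1, Omnibus p};
    columns: low, high, diff (low - high), p, p_fdr.
    """
    by_key = {(r.component_name, r.contrast): r for r in results if r.metric_name == metric_name}
    rows = []
    components = sorted({r.component_name for r in results}, key=lambda c: DEFAULT_COMPONENTS.index(c) if c in DEFAULT_COMPONENTS else 99)
    for comp in components:
        for contrast, label in (("T1", "Time 1"), ("T2", "Time 2"), ("T2-T1", "Time 2 - Time 1")):
            r = by_key.get((comp, contrast))
            if r is None:
                continue
            rows.append(
                {
                    "component": comp,
                    "row": label if contrast != "T2-T1" else "Time 2 - Time 1",
                    "low": round(r.observed_low, 6),
                    "high": round(r.observed_high, 6),
                    "diff": round(r.observed_diff, 6),
                    "p": (np.nan if r.p_raw is None or np.isnan(r.p_raw) else round(r.p_raw, 6))
                    if contrast != "T2-T1"
                    else np.nan,
                    "p_fdr": np.nan if r.p_fdr is None else round(r.p_fdr, 6),
                }
            )
            if contrast == "T2-T1":
                rows.append(
                    {
                        "component": comp,
                        "row": "Omnibus p",
                        "low": np.nan,
                        "high": np.nan,
                        "diff": np.nan,
                        "p": round(r.p_raw, 6),
                        "p_fdr": np.nan if r.p_fdr is None else round(r.p_fdr, 6),
                    }
                )
    return pd.DataFrame(rows, columns=["component", "row", "low", "high", "diff", "p", "p_fdr"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the results bundle (also written
    to ``config.outdir``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"complete": False, "stages": []}

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        t1, t2, scores, covariates = _load_inputs(config)

        stage("align")
        t1, t2, dropped = mio.align_timepoints(t1, t2)
        scores = _restrict_scores(scores, t1.subject_ids)

        stage("qc")
        qc = {tp: mio.detect_outliers(m, config.z_threshold) for tp, m in (("T1", t1), ("T2", t2))}
        for tp, rep in qc.items():
            rep.to_frame().to_csv(outdir / f"qc_{tp}.csv", index=False)

        stage("standardize")
        z1 = mio.standardize_regions(t1)
        z2 = mio.standardize_regions(t2)

        stage("regularization")
        names = ["cv"] + [
            f"{c}:{m}:{ctr}"
            for c in scores.component_names
            for m in METRIC_NAMES
            for ctr in ("T1", "T2", "omnibus")
        ]
        seeds = _child_seeds(config.master_seed, names)
        if config.rho == "cv":
            # one whole-sample penalty for every network; selected per
            # timepoint at the true sample size (group networks are fit on
            # ~n/2 subjects, so the penalty must not be tuned to a larger
            # pooled sample) and averaged across the two timepoints
            rho_by_tp = {}
            for tp, z in (("T1", z1), ("T2", z2)):
                rho_tp, curve = select_regularization(
                    z, rho_grid=config.rho_grid, k_folds=config.k_folds,
                    seed=seeds["cv"],
                )
                rho_by_tp[tp] = rho_tp
                curve.to_csv(outdir / f"cv_curve_{tp}.csv", index=False)
            rho = 0.5 * (rho_by_tp["T1"] + rho_by_tp["T2"])
        else:
            rho = float(config.rho)

        stage("whole_group_networks")
        whole = {}
        for tp, z in (("T1", z1), ("T2", z2)):
            net = estimate_sparse_network(z, rho)
            met = compute_network_metrics(net, config.resolution, seed=seeds["cv"])
            whole[tp] = {
                "local_efficiency": met.mean_local_efficiency,
                "global_efficiency": met.global_efficiency,
                "participation": met.mean_participation,
                "n_edges": net.n_edges,
                "n_modules": met.partition.n_modules,
                "modularity_q": met.partition.quality,
            }
            if config.write_networks:
                write_network(net, outdir / f"network_whole_{tp}")

        stage("median_split")
        groups = {c: median_split(scores, c) for c in scores.component_names}
        pd.DataFrame(
            [
                (s_, c, ga.labels[s_])
                for c, ga in groups.items()
                for s_ in t1.subject_ids
            ],
            columns=["subject", "component", "group"],
        ).to_csv(outdir / "group_assignments.csv", index=False)

        if covariates is not None:
            stage("covariate_screen")
            from .grouping import screen_covariates

            cov = covariates.loc[[s for s in t1.subject_ids if s in covariates.index]]
            screen = screen_covariates(list(groups.values()), cov, fdr_q=config.fdr_q)
            screen.to_csv(outdir / "covariate_screen.csv", index=False)

        stage("compare")
        results: list[PermutationResult] = []
        for comp, ga in groups.items():
            for metric in METRIC_NAMES:
                if config.test_t1:
                    results.append(
                        permutation_test(
                            z1, ga, metric, rho, config.n_perm, config.resolution,
                            seeds[f"{comp}:{metric}:T1"], contrast="T1", jobs=config.jobs,
                        )
                    )
                else:
                    results.append(_descriptive_t1(z1, ga, metric, rho, config, seeds))
                results.append(
                    permutation_test(
                        z2, ga, metric, rho, config.n_perm, config.resolution,
                        seeds[f"{comp}:{metric}:T2"], contrast="T2", jobs=config.jobs,
                    )
                )
                results.append(
                    omnibus_change_test(
                        z1, z2, ga, metric, rho, config.n_perm, config.resolution,
                        seeds[f"{comp}:{metric}:omnibus"], jobs=config.jobs,
                    )
                )

        stage("fdr")
        # family = the 4 components within one metric x contrast
        for metric in METRIC_NAMES:
            for contrast in ("T1", "T2", "T2-T1"):
                fam = [
                    r for r in results
                    if r.metric_name == metric and r.contrast == contrast
                    and not np.isnan(r.p_raw)
                ]
                if not fam:
                    continue
                adj = fdr_adjust([r.p_raw for r in fam], q=config.fdr_q)
                for r, a in zip(fam, adj):
                    r.p_fdr = float(a)

        stage("tables")
        for metric in METRIC_NAMES:
            results_table(results, metric).to_csv(
                outdir / f"table_{metric}.csv", index=False
            )

        stage("bundle")
        bundle = {
            "rho": rho,
            "rho_source": "cv" if config.rho == "cv" else "fixed",
            "n_perm": config.n_perm,
            "resolution": config.resolution,
            "fdr_q": config.fdr_q,
            "master_seed": config.master_seed,
            "child_seeds": seeds,
            "n_subjects": t1.n_subjects,
            "n_regions": t1.n_regions,
            "dropped_subjects": dropped,
            "qc_flags": {tp: len(rep.flags) for tp, rep in qc.items()},
            "whole_group": whole,
            "results": [
                {
                    "component": r.component_name,
                    "metric": r.metric_name,
                    "contrast": r.contrast,
                    "low": r.observed_low,
                    "high": r.observed_high,
                    "diff": r.observed_diff,
                    "p_raw": None if np.isnan(r.p_raw) else r.p_raw,
                    "p_fdr": r.p_fdr,
                    "n_perm": r.n_perm,
                    "seed": r.seed,
                }
                for r in results
            ],
        }
        with open(outdir / "results.json", "w") as fh:
            json.dump(bundle, fh, indent=2)
        manifest["complete"] = True
        return bundle
    finally:
        with open(outdir / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def _descriptive_t1(z1, ga, metric, rho, config, seeds) -> PermutationResult:
    """Time-1 group metric values without a permutation test (the default:
    the cross-section was tested elsewhere in the reference design)."""
    from .metrics import network_metric

    X = z1.to_numpy()
    subjects = list(z1.index.astype(str))
    mask = ga.mask(subjects, "low")
    seed = seeds[f"{ga.component_name}:{metric}:T1"]
    m_lo = network_metric(
        estimate_sparse_network(X[mask], rho).adjacency, metric,
        config.resolution, seed=seed,
    )
    m_hi = network_metric(
        estimate_sparse_network(X[~mask], rho).adjacency, metric,
        config.resolution, seed=seed,
    )
    r = PermutationResult.__new__(PermutationResult)
    r.component_name = ga.component_name
    r.metric_name = metric
    r.contrast = "T1"
    r.observed_low = float(m_lo)
    r.observed_high = float(m_hi)
    r.observed_diff = float(m_lo - m_hi)
    r.null_diffs = np.empty(0)
    r.p_raw = float("nan")
    r.n_perm = 0
    r.seed = seed
    r.p_fdr = None
    return r
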