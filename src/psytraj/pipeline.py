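"""End-to-end orchestration: simulate → impute → score → standardize →
select K → cluster → regress, with reporting and sensitivity variants."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import round_half_up, spawn_seed
from .cohort import WAVES, CohortSpec, GeneratedCohort, generate_cohort
from .preprocessing import TrajectoryTensor, attrition_report, impute_items, score_table, standardize
from .predictors import run_predictor_analysis
from .selection import choose_k, prediction_strength_curve
from .vader import VaderConfig, assign, fit

ARCHETYPES = {
    "unaffected": "flat-low",
    "internalizing": "internalizing-high",
    "discrepant": "self-over-caregiver",
    "externalizing": "externalizing-high",
    "severe": "all-high",
}


@dataclass
class PipelineConfig:
    """Run settings; the master seed derives every stage's sub-seed."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    vader: VaderConfig = field(default_factory=VaderConfig)
    k_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    select_k: bool = True
    ps_repeats: int = 20
    ps_threshold: float = 0.8
    ps_epoch_factor: float = 1.0
    run_regression: bool = True
    reference_cluster_archetype: str = "flat-low"
    m_imputations: int = 20
    missforest_trees: int = 100
    seed: int = 0
    # sensitivity variants
    all_baseline_participants: bool = False
    skip_item_imputation: bool = False
    raw_binary_selfharm: bool = False

    def to_yaml(self, path):
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["cohort"] = CohortSpec.from_dict(d["cohort"])
        d["vader"] = VaderConfig(**d["vader"])
        d["k_values"] = tuple(d["k_values"])
        return cls(**d)


# ---------------------------------------------------------------------------
# reporting operations
# ---------------------------------------------------------------------------


def cluster_shares(labels) -> pd.DataFrame:
    """Counts and percentage shares (half-up, one decimal), largest first."""
    labels = pd.Series(labels)
    if labels.empty:
        raise ValueError("empty label vector")
    counts = labels.value_counts()
    total = int(counts.sum())
    out = pd.DataFrame({"cluster": counts.index, "count": counts.to_numpy()})
    out["share_pct"] = [round_half_up(100.0 * c / total, 1) for c in out["count"]]
    return out.reset_index(drop=True)


def mean_trajectories(tensor: TrajectoryTensor, labels: np.ndarray) -> pd.DataFrame:
    """Masked per-cluster mean z and standard error per (assessment, wave).

    Cells with no observation for a cluster are absent from the output
    rather than reported as zero.
    """
    labels = np.asarray(labels)
    if len(labels) != tensor.n:
        raise ValueError("labels do not align with the tensor's participants")
    rows = []
    for cluster in np.unique(labels):
        sel = labels == cluster
        vals = tensor.values[sel]
        mask = tensor.mask[sel]
        for ti, wave in enumerate(tensor.wave_labels):
            for di, a in enumerate(tensor.assessment_names):
                col = vals[:, ti, di]
                obs = mask[:, ti, di] > 0
                n_obs = int(obs.sum())
                if n_obs == 0:
                    continue
                mean = float(col[obs].mean())
                se = float(col[obs].std(ddof=1) / np.sqrt(n_obs)) if n_obs > 1 else 0.0
                rows.append({"cluster": cluster, "assessment": a, "wave": wave,
                             "mean": mean, "se": se, "n": n_obs})
    return pd.DataFrame(rows)


def name_clusters(traj: pd.DataFrame, profiles: dict, assessments) -> dict[int, str]:
    """Cosmetic archetype naming by nearest mean-trajectory correlation.

    Each cluster's mean z-trajectory (flattened over assessments × waves)
    is correlated with each archetype profile; the best-correlated
    archetype lends its name.  Labels stay integers everywhere else.
    """
    spec_by_name = {a.name: a for a in assessments}
    keys = [(a.name, w) for a in assessments for w in WAVES
            if w in a.waves_administered]

    def profile_vector(prof):
        out = []
        for name, w in keys:
            b0, b1 = prof.get(name, prof.get("__default__", (0.0, 0.0)))
            out.append(b0 + b1 * WAVES.index(w))
        return np.asarray(out)

    arch_vecs = {cls: profile_vector(p) for cls, p in profiles.items()}
    naming = {}
    for cluster, g in traj.groupby("cluster"):
        vec = {(r.assessment, r.wave): r.mean for r in g.itertuples()}
        obs_keys = [k for k in keys if k in vec and k[0] in spec_by_name]
        v = np.asarray([vec[k] for k in obs_keys])
        best, best_r = None, -np.inf
        for cls, av in arch_vecs.items():
            a = np.asarray([av[keys.index(k)] for k in obs_keys])
            r = np.corrcoef(v, a)[0, 1] if v.std() > 0 and a.std() > 0 else -np.inf
            if r > best_r:
                best, best_r = cls, r
        naming[cluster] = ARCHETYPES.get(best, str(best))
    return naming


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _log_event(log_path: Path, record: dict):
    with log_path.open("a") as fh:
        fh.write(json.dumps(record) + "\n")


def analysis_population(cohort: GeneratedCohort, all_baseline: bool) -> np.ndarray:
    """Participants with records at all four waves, or everyone at baseline."""
    if all_baseline:
        return np.sort(cohort.covariate_table["participant"].unique())
    by_wave = cohort.scale_table.groupby("participant")["wave"].nunique()
    return np.sort(by_wave[by_wave == len(WAVES)].index.to_numpy())


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages, persisting artifacts and a JSON-lines log.

    Returns a result dictionary with the cluster report, the
    prediction-strength curve (when K selection runs), and the pooled
    regression table.  Every artifact can be regenerated from the config
    echo and master seed alone.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    config.to_yaml(out / "config_echo.yaml")
    results: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        _log_event(log_path, {"stage": name, "event": "start", "seed": config.seed})
        try:
            value = fn()
        except Exception as exc:  # halt with stage context, keep prior artifacts
            _log_event(log_path, {"stage": name, "event": "error", "error": str(exc)})
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        _log_event(log_path, {"stage": name, "event": "done",
                              "seconds": round(time.perf_counter() - t0, 3)})
        return value

    # -- simulate ----------------------------------------------------------
    def do_simulate():
        spec = config.cohort
        spec.seed = spawn_seed(config.seed, 101)
        cohort = generate_cohort(spec)
        cohort.write(out / "cohort")
        return cohort

    cohort = stage("simulate", do_simulate)

    # -- analysis population and attrition bookkeeping ----------------------
    pop = analysis_population(cohort, config.all_baseline_participants)
    per_wave = {w: int(cohort.scale_table.loc[cohort.scale_table["wave"] == w,
                                              "participant"].nunique())
                for w in WAVES}
    attrition = attrition_report(per_wave)
    attrition.to_csv(out / "attrition.csv", index=False)

    items = cohort.item_table[cohort.item_table["participant"].isin(pop)]
    covariates = cohort.covariate_table[
        cohort.covariate_table["participant"].isin(pop)].set_index("participant")

    # -- item imputation ----------------------------------------------------
    def do_impute():
        if config.skip_item_imputation:
            return items, None
        return impute_items(items, config.cohort.assessments,
                            n_trees=config.missforest_trees,
                            seed=spawn_seed(config.seed, 103))

    completed_items, imputation_report = stage("impute-items", do_impute)
    if imputation_report is not None:
        (out / "imputation_report.json").write_text(json.dumps({
            "fraction_missing_before": imputation_report.fraction_missing_before,
            "fraction_missing_after": imputation_report.fraction_missing_after,
        }, indent=1))

    # -- score and standardize ----------------------------------------------
    scales = stage("score", lambda: score_table(completed_items, config.cohort.assessments))
    raw = ("selfharm_self",) if config.raw_binary_selfharm else ()
    tensor = stage("standardize", lambda: standardize(
        scales, config.cohort.assessments, raw_assessments=raw))
    tensor.save(out / "tensor")

    # -- choose K ------------------------------------------------------------
    if config.select_k:
        def do_select():
            curve = prediction_strength_curve(
                tensor, config.k_values, config.vader, repeats=config.ps_repeats,
                seed=spawn_seed(config.seed, 107),
                epoch_factor=config.ps_epoch_factor)
            curve.entries.to_csv(out / "prediction_strength.csv", index=False)
            return curve

        curve = stage("select-k", do_select)
        k = choose_k(curve, config.ps_threshold)
        results["prediction_strength"] = curve.entries
    else:
        k = config.vader.k
    results["k"] = k

    # -- final clustering ----------------------------------------------------
    def do_cluster():
        from dataclasses import replace
        cfg = replace(config.vader, k=k, seed=spawn_seed(config.seed, 109))
        model, log = fit(tensor, cfg)
        model.save(out / "vader_model")
        pd.DataFrame(log).to_csv(out / "training_log.csv", index=False)
        return assign(model, tensor)

    assignment = stage("cluster", do_cluster)
    shares = cluster_shares(assignment.labels)
    traj = mean_trajectories(tensor, assignment.labels)
    naming = name_clusters(traj, config.cohort.class_profiles, config.cohort.assessments)
    shares["archetype"] = shares["cluster"].map(naming)
    shares.to_csv(out / "cluster_report.csv", index=False)
    traj.to_csv(out / "mean_trajectories.csv", index=False)
    results.update({"cluster_report": shares, "mean_trajectories": traj,
                    "labels": assignment.labels, "tensor": tensor,
                    "true_labels": cohort.true_labels.loc[pop].to_numpy(),
                    "naming": naming})

    # -- predictors ----------------------------------------------------------
    if config.run_regression:
        def do_predictors():
            ref = next((c for c, n in naming.items()
                        if n == config.reference_cluster_archetype),
                       int(shares.iloc[0]["cluster"]))
            labels = pd.Series(assignment.labels, index=covariates.index)
            return run_predictor_analysis(
                covariates.reset_index(), labels.reset_index(drop=True),
                reference_cluster=ref, m=config.m_imputations,
                seed=spawn_seed(config.seed, 113))

        analysis = stage("predictors", do_predictors)
        analysis.pooled.reset_index().to_csv(out / "odds_ratios.csv", index=False)
        (out / "model_fit.json").write_text(json.dumps({
            "nagelkerke_r2": analysis.nagelkerke,
            "vif": analysis.vif.to_dict(),
            "m": analysis.m,
        }, indent=1))
        results["regression"] = analysis

    results["attrition"] = attrition
    return results
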