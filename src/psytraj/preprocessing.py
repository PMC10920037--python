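"""Item-level random-forest imputation, scale scoring and z-standardization.

The preprocessing contract: impute partially answered scales at the item
level with an iterative random-forest scheme, sum items to fractional
scale scores without rounding, and z-standardize each assessment by
pooling all waves and participants, producing a masked participant × wave
× assessment tensor for clustering.  Scales with no responses at all are
never imputed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from ._util import round_half_up
from .cohort import WAVES, AssessmentSpec


@dataclass
class TrajectoryTensor:
    """Masked z-score array, participants × waves × assessments."""

    values: np.ndarray  # (N, T, D) float, NaN where mask == 0
    mask: np.ndarray  # (N, T, D) {0, 1}
    participant_ids: np.ndarray
    wave_labels: tuple[str, ...]
    assessment_names: tuple[str, ...]

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, indices) -> "TrajectoryTensor":
        idx = np.asarray(indices)
        return TrajectoryTensor(self.values[idx], self.mask[idx],
                                self.participant_ids[idx], self.wave_labels,
                                self.assessment_names)

    def filled(self, fill: np.ndarray | float = 0.0) -> np.ndarray:
        """Values with masked cells replaced (by a scalar or a (T, D) array)."""
        out = np.where(self.mask > 0, np.nan_to_num(self.values), 0.0)
        return out + (1 - self.mask) * fill

    def save(self, path):
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), values=self.values, mask=self.mask,
                            participant_ids=self.participant_ids)
        meta = {"wave_labels": list(self.wave_labels),
                "assessment_names": list(self.assessment_names)}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "TrajectoryTensor":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(arrays["values"], arrays["mask"], arrays["participant_ids"],
                   tuple(meta["wave_labels"]), tuple(meta["assessment_names"]))


@dataclass
class ImputationReport:
    fraction_missing_before: float
    fraction_missing_after: float
    iterations_used: dict = field(default_factory=dict)  # (assessment, wave) -> int
    per_assessment: dict = field(default_factory=dict)  # name -> imputed cell count

    def __post_init__(self):
        if self.fraction_missing_after > self.fraction_missing_before + 1e-12:
            raise ValueError("imputation cannot increase missingness")


# ---------------------------------------------------------------------------
# MissForest
# ---------------------------------------------------------------------------


def missforest_impute(matrix: np.ndarray, n_trees: int = 100, max_iter: int = 10,
                      seed: int = 0, bounds: tuple[float, float] | None = None
                      ) -> tuple[np.ndarray, int]:
    """Iterative random-forest imputation of a records × variables matrix.

    Blanks are initialized at column means; columns are revisited in order
    of increasing missingness, each refit with a ``n_trees``-tree random
    forest on the currently completed data.  Iteration stops the first time
    the normalized squared change over imputed cells increases (the iterate
    before the increase is returned) or after ``max_iter`` sweeps.  Observed
    cells are never altered; predictions stay fractional (optionally clipped
    to ``bounds``).  Rows with every variable blank are left blank — no
    responses means no imputation.

    Returns (completed matrix, iterations used).
    """
    X = np.asarray(matrix, float).copy()
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    obs = ~np.isnan(X)
    if not obs.any():
        raise ValueError("no responses were provided: nothing to learn from")
    if obs.all():
        return X, 0

    all_blank_rows = ~obs.any(axis=1)
    work_rows = np.where(~all_blank_rows)[0]
    Xw = X[work_rows]
    obs_w = obs[work_rows]
    miss_w = ~obs_w

    col_frac = miss_w.mean(axis=0)
    incomplete = [j for j in np.argsort(col_frac, kind="stable") if 0 < col_frac[j]]
    usable_cols = [j for j in range(X.shape[1]) if obs_w[:, j].any()]
    if not incomplete:
        return X, 0

    col_means = np.array([Xw[obs_w[:, j], j].mean() if obs_w[:, j].any() else 0.0
                          for j in range(Xw.shape[1])])
    for j in range(Xw.shape[1]):
        Xw[miss_w[:, j], j] = col_means[j]

    rng = np.random.default_rng(seed)
    prev = Xw.copy()
    prev_delta = np.inf
    iterations = 0
    for it in range(1, max_iter + 1):
        current = prev.copy()
        for j in incomplete:
            if not obs_w[:, j].any():
                continue  # nothing observed in this column: keep mean init
            predictors = [c for c in usable_cols if c != j]
            if not predictors:
                continue
            train = obs_w[:, j]
            rf = RandomForestRegressor(n_estimators=n_trees,
                                       random_state=int(rng.integers(2**31)))
            rf.fit(current[train][:, predictors], current[train, j])
            pred = rf.predict(current[miss_w[:, j]][:, predictors])
            if bounds is not None:
                pred = np.clip(pred, bounds[0], bounds[1])
            current[miss_w[:, j], j] = pred
        num = float(((current - prev)[miss_w] ** 2).sum())
        den = float((current[miss_w] ** 2).sum())
        delta = num / den if den > 0 else 0.0
        if delta >= prev_delta:
            break  # change grew: keep the previous iterate
        prev = current
        prev_delta = delta
        iterations = it
        if delta == 0.0:
            break

    out = X.copy()
    filled = prev.copy()
    filled[obs_w] = Xw[obs_w]  # observed cells stay exact
    out[work_rows] = filled
    out[all_blank_rows] = np.nan
    np.copyto(out, np.asarray(matrix, float), where=obs)
    return out, iterations


def impute_items(item_table: pd.DataFrame, assessments: list[AssessmentSpec],
                 n_trees: int = 100, max_iter: int = 10, seed: int = 0
                 ) -> tuple[pd.DataFrame, ImputationReport]:
    """MissForest per (assessment, wave) block, predictors = sibling items.

    Single-item assessments have no sibling predictors and are passed
    through.  The report's missing fractions are measured on scale scores
    (a score is missing while any of its items is blank).
    """
    spec_by_name = {a.name: a for a in assessments}
    items = item_table.copy()
    before = _scale_missing_fraction(items)
    iterations: dict = {}
    per_assessment: dict = {}
    for (name, wave), block in items.groupby(["assessment", "wave"], sort=True):
        spec = spec_by_name[name]
        if spec.n_items < 2:
            continue
        wide = block.pivot(index="participant", columns="item", values="value")
        wide = wide.reindex(columns=range(spec.n_items))
        arr = wide.to_numpy(float)
        n_miss = np.isnan(arr).sum()
        if n_miss == 0 or not (~np.isnan(arr)).any():
            continue
        block_seed = (seed + zlib.crc32(f"{name}|{wave}".encode())) % (2**31)
        completed, used = missforest_impute(arr, n_trees=n_trees, max_iter=max_iter,
                                            seed=block_seed,
                                            bounds=(spec.item_min, spec.item_max))
        iterations[(name, wave)] = used
        per_assessment[name] = per_assessment.get(name, 0) + int(
            n_miss - np.isnan(completed).sum())
        long = pd.DataFrame(completed, index=wide.index, columns=wide.columns).stack(
            future_stack=True).rename("value").reset_index()
        key = ["participant", "item"]
        merged = block.drop(columns="value").merge(long, on=key, how="left")
        items.loc[block.index, "value"] = merged["value"].to_numpy()
    after_items = items
    after = _scale_missing_fraction(after_items)
    report = ImputationReport(before, after, iterations, per_assessment)
    return after_items, report


def _scale_missing_fraction(item_table: pd.DataFrame) -> float:
    per_scale = item_table.groupby(["participant", "wave", "assessment"])["value"].apply(
        lambda v: v.isna().any())
    return float(per_scale.mean())


# ---------------------------------------------------------------------------
# scoring and standardization
# ---------------------------------------------------------------------------


def score_scale(item_values, spec: AssessmentSpec) -> float:
    """Sum the items of one scale; fractional values (post-imputation) kept.

    Returns NaN when any item is blank; rejects observed out-of-bounds items.
    """
    v = np.asarray(item_values, float)
    if v.shape != (spec.n_items,):
        raise ValueError(f"{spec.name}: expected {spec.n_items} items, got {v.shape}")
    obs = ~np.isnan(v)
    if ((v[obs] < spec.item_min) | (v[obs] > spec.item_max)).any():
        raise ValueError(f"{spec.name}: item value outside [{spec.item_min}, {spec.item_max}]")
    if not obs.all():
        return float("nan")
    return float(v.sum())


def score_table(item_table: pd.DataFrame, assessments: list[AssessmentSpec]) -> pd.DataFrame:
    """Scale scores for every (participant, wave, assessment) with full items."""
    spec_by_name = {a.name: a for a in assessments}
    g = item_table.groupby(["participant", "wave", "assessment"], sort=True)["value"]
    counts = g.count()
    sums = g.sum(min_count=1)
    out = counts.reset_index().rename(columns={"value": "n_obs"})
    out["score"] = sums.to_numpy()
    need = out["assessment"].map(lambda a: spec_by_name[a].n_items)
    out.loc[out["n_obs"] < need, "score"] = np.nan
    lo = out["assessment"].map(lambda a: spec_by_name[a].score_min)
    hi = out["assessment"].map(lambda a: spec_by_name[a].score_max)
    ok = out["score"].isna() | ((out["score"] >= lo - 1e-9) & (out["score"] <= hi + 1e-9))
    if not ok.all():
        bad = out.loc[~ok, "assessment"].iloc[0]
        raise ValueError(f"{bad}: score outside its admissible range")
    return out[["participant", "wave", "assessment", "score"]]


def standardize(scale_table: pd.DataFrame, assessments: list[AssessmentSpec] | None = None,
                raw_assessments: tuple[str, ...] = (), ddof: int = 1) -> TrajectoryTensor:
    """Pooled z-standardization into a masked trajectory tensor.

    Per assessment, all observed scores across waves and participants are
    pooled; z = (x − mean) / sd with the n−1 (sample) denominator by
    default.  Assessments named in ``raw_assessments`` are passed through
    unstandardized (sensitivity variant for binary scales).  Structural and
    observed missingness both appear as mask = 0.
    """
    if assessments is not None:
        order = [a.name for a in assessments if a.name in set(scale_table["assessment"])]
    else:
        order = sorted(scale_table["assessment"].unique())
    participants = np.sort(scale_table["participant"].unique())
    waves = [w for w in WAVES if w in set(scale_table["wave"])]

    wide = scale_table.pivot_table(index="participant", columns=["wave", "assessment"],
                                   values="score", dropna=False)
    N, T, D = len(participants), len(waves), len(order)
    values = np.full((N, T, D), np.nan)
    for ti, w in enumerate(waves):
        for di, a in enumerate(order):
            if (w, a) in wide.columns:
                values[:, ti, di] = wide[(w, a)].reindex(participants).to_numpy()

    for di, a in enumerate(order):
        col = values[:, :, di]
        obs = ~np.isnan(col)
        if a in raw_assessments:
            continue
        vals = col[obs]
        if len(np.unique(vals)) < 2:
            raise ValueError(f"{a}: zero variance, cannot standardize")
        mu, sd = vals.mean(), vals.std(ddof=ddof)
        values[:, :, di] = (col - mu) / sd

    mask = (~np.isnan(values)).astype(float)
    return TrajectoryTensor(values, mask, participants, tuple(waves), tuple(order))


def attrition_report(per_wave_counts: dict[str, int]) -> pd.DataFrame:
    """Follow-up percentages relative to the first wave, half-up to 1 decimal."""
    waves = list(per_wave_counts)
    baseline = per_wave_counts[waves[0]]
    if baseline <= 0:
        raise ValueError("baseline count must be positive")
    rows = [{"wave": w, "n": per_wave_counts[w],
             "followup_rate": round_half_up(100.0 * per_wave_counts[w] / baseline, 1)}
            for w in waves]
    return pd.DataFrame(rows)
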