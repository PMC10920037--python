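"""Synthetic multi-informant longitudinal cohorts with known trajectory classes.

A cohort is generated top-down: baseline covariates are sampled from their
marginals, a latent trajectory class is drawn for each participant from a
multinomial-logit model with known coefficients, per-(assessment, wave)
latent severities follow class-specific trajectory profiles, and bounded
item responses are drawn conditionally on severity.  Item-, scale- and
participant-level missingness is applied last.  Because the class labels
and the covariate-to-class coefficients are known, every downstream stage
(imputation, clustering, model selection, regression) can be tested for
recovery of the truth.

The default assessment catalog mirrors a four-wave adolescent cohort
(ages 10/12/14/16) with 14 instruments: self- and caregiver-reported
symptom scales with their published score ranges, four caregiver checklist
scales not administered at the third wave, and two single-item self-report
measures (self-harm, suicidal ideation) not asked at baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

WAVES = ("T1", "T2", "T3", "T4")


# ---------------------------------------------------------------------------
# assessment catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssessmentSpec:
    """One psychometric instrument: informant, item structure, score bounds.

    ``item_slope``/``item_offset`` parameterize the item-response link: each
    item is Binomial(item_max − item_min, logistic(slope·severity + offset))
    + item_min, so the offset sets the endorsement rate of an average
    (severity-0) participant and the slope the severity discrimination.
    """

    name: str
    informant: str  # "self" | "caregiver"
    n_items: int
    item_min: int
    item_max: int
    waves_administered: tuple[str, ...] = WAVES
    item_slope: float = 1.2
    item_offset: float = -1.4

    def __post_init__(self):
        if self.informant not in ("self", "caregiver"):
            raise ValueError(f"{self.name}: informant must be 'self' or 'caregiver'")
        if self.n_items < 1:
            raise ValueError(f"{self.name}: n_items must be >= 1")
        if self.item_max <= self.item_min:
            raise ValueError(f"{self.name}: empty item range")
        unknown = set(self.waves_administered) - set(WAVES)
        if unknown:
            raise ValueError(f"{self.name}: unknown waves {sorted(unknown)}")

    @property
    def score_min(self) -> int:
        return self.n_items * self.item_min

    @property
    def score_max(self) -> int:
        return self.n_items * self.item_max


def default_assessments() -> list[AssessmentSpec]:
    """The 14-instrument catalog with published score bounds.

    Item counts are chosen so summed items reproduce the published score
    ranges (e.g. 13 items scored 0-2 for the 0-26 self-report depression
    scale, five-item 0-2 checklist subscales for the 0-10 ranges).
    """
    A = AssessmentSpec
    not_t3 = ("T1", "T2", "T4")
    not_t1 = ("T2", "T3", "T4")
    return [
        A("depression_self", "self", 13, 0, 2),
        A("emotional_caregiver", "caregiver", 5, 0, 2),
        A("psychotic_self", "self", 5, 0, 2),
        A("psychotic_caregiver", "caregiver", 4, 0, 2, waves_administered=not_t3),
        A("obsession_caregiver", "caregiver", 2, 0, 2, waves_administered=not_t3),
        A("dissociation_caregiver", "caregiver", 3, 0, 2),
        A("sociality_caregiver", "caregiver", 5, 0, 2),
        A("hyperactivity_caregiver", "caregiver", 5, 0, 2),
        A("conduct_caregiver", "caregiver", 5, 0, 2),
        A("somatic_caregiver", "caregiver", 9, 0, 2, waves_administered=not_t3),
        A("withdrawal_caregiver", "caregiver", 9, 0, 2, waves_administered=not_t3),
        A("slim_desire_self", "self", 1, 0, 3),
        A("selfharm_self", "self", 1, 0, 1, waves_administered=not_t1, item_offset=-2.5),
        A("suicidal_self", "self", 1, 0, 3, waves_administered=not_t1, item_offset=-2.0),
    ]


# ---------------------------------------------------------------------------
# covariates and class-assignment model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateSpec:
    """A baseline covariate and its marginal distribution.

    ``effect_sign`` flips the direction of the (standardized) covariate in
    the class-assignment design matrix, so a positive coefficient can mean
    "shorter gestation raises risk" while the stored variable remains the
    raw gestation length.
    """

    name: str
    kind: str  # "binary" | "continuous"
    p: float = 0.5  # binary: success probability
    mean: float = 0.0  # continuous: marginal mean
    sd: float = 1.0  # continuous: marginal sd
    effect_sign: float = 1.0

    def __post_init__(self):
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"{self.name}: kind must be 'binary' or 'continuous'")


def default_covariates() -> list[CovariateSpec]:
    C = CovariateSpec
    return [
        C("female_sex", "binary", p=0.47),
        C("autistic_traits", "continuous"),
        C("bullying_victim", "binary", p=0.20),
        C("bullying_perpetrator", "binary", p=0.10),
        C("helpseek_avoidance", "binary", p=0.25),
        C("caregiver_distress", "continuous"),
        C("caregiver_psych_dx", "binary", p=0.08),
        C("maternal_smoking", "binary", p=0.10),
        C("gestation_weeks", "continuous", mean=39.0, sd=1.5, effect_sign=-1.0),
        C("family_dissatisfaction", "continuous"),
    ]


DEFAULT_CLASS_NAMES = ("unaffected", "internalizing", "discrepant", "externalizing", "severe")
# the printed shares sum to 100.1% after rounding; normalize to a simplex
_RAW_SHARES = np.array([0.605, 0.162, 0.099, 0.096, 0.039])
DEFAULT_CLASS_SHARES = tuple(_RAW_SHARES / _RAW_SHARES.sum())


def default_true_beta() -> pd.DataFrame:
    """Known log-odds of class membership vs the reference (first) class.

    Rows: intercept + covariates (continuous entries are per standardized
    unit, after any sign flip); columns: non-reference classes.  Intercepts
    are placeholders — they are recalibrated at generation time so expected
    class shares hit their targets.
    """
    cols = list(DEFAULT_CLASS_NAMES[1:])
    rows = ["intercept"] + [c.name for c in default_covariates()]
    beta = pd.DataFrame(0.0, index=rows, columns=cols)
    beta.loc["intercept"] = [-1.3, -1.8, -1.8, -2.7]
    beta.loc["female_sex"] = [0.68, 0.38, -0.39, 0.0]
    beta.loc["autistic_traits"] = [0.67, 0.35, 0.46, 0.80]
    beta.loc["bullying_victim"] = [0.65, 0.59, 0.75, 1.26]
    beta.loc["bullying_perpetrator", "severe"] = 0.88
    beta.loc["helpseek_avoidance", "discrepant"] = 0.60
    beta.loc["caregiver_distress", "severe"] = 0.63
    beta.loc["caregiver_psych_dx", "discrepant"] = 0.73
    beta.loc["maternal_smoking", "severe"] = 1.04
    beta.loc["gestation_weeks", "severe"] = 0.17
    beta.loc["family_dissatisfaction", "severe"] = 0.46
    return beta


def default_class_profiles() -> dict[str, dict[str, tuple[float, float]]]:
    """Latent-severity trajectory per class: assessment -> (base z, z per wave).

    Archetypes: a flat low class; an internalizing class with worsening
    somatic/withdrawal/suicidal trends; a self-caregiver discrepant class
    elevated on self-report only; an externalizing class elevated on
    hyperactivity/conduct; and a small severe class high everywhere.
    Unlisted assessments sit at the class baseline below.
    """
    internal = ["depression_self", "emotional_caregiver", "sociality_caregiver",
                "dissociation_caregiver"]
    self_rep = ["depression_self", "psychotic_self", "slim_desire_self"]
    caregiver = [a.name for a in default_assessments() if a.informant == "caregiver"]
    profiles: dict[str, dict[str, tuple[float, float]]] = {
        "unaffected": {"__default__": (-0.3, 0.0)},
        "internalizing": {
            "__default__": (0.0, 0.0),
            **{a: (0.8, 0.0) for a in internal},
            "somatic_caregiver": (0.8, 0.3),
            "withdrawal_caregiver": (0.8, 0.3),
            "suicidal_self": (0.5, 0.3),
        },
        "discrepant": {
            "__default__": (0.0, 0.0),
            **{a: (0.8, 0.0) for a in self_rep},
            "selfharm_self": (1.2, 0.0),
            "suicidal_self": (1.2, 0.0),
        },
        "externalizing": {
            "__default__": (-0.1, 0.0),
            "hyperactivity_caregiver": (1.0, 0.0),
            "conduct_caregiver": (1.0, 0.0),
        },
        "severe": {
            "__default__": (1.0, 0.0),
            **{a: (1.5, 0.0) for a in caregiver},
        },
    }
    return profiles


@dataclass
class CohortSpec:
    """Everything needed to generate a cohort deterministically."""

    n_participants: int = 500
    assessments: list[AssessmentSpec] = field(default_factory=default_assessments)
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    class_shares_target: tuple[float, ...] = DEFAULT_CLASS_SHARES
    class_profiles: dict = field(default_factory=default_class_profiles)
    within_class_sd: float = 0.3
    random_intercept_sd: float = 0.2
    covariate_catalog: list[CovariateSpec] = field(default_factory=default_covariates)
    true_beta: pd.DataFrame = field(default_factory=default_true_beta)
    item_missing_rate: float = 0.02
    scale_missing_rate: float = 0.02
    dropout_rate: float = 0.0
    seed: int = 0

    def validate(self):
        shares = np.asarray(self.class_shares_target, float)
        if abs(shares.sum() - 1.0) > 1e-8 or (shares <= 0).any():
            raise ValueError("class_shares_target: must be a positive simplex vector")
        if len(self.class_names) != len(shares):
            raise ValueError("class_names: length mismatch with class_shares_target")
        for r in ("item_missing_rate", "scale_missing_rate", "dropout_rate"):
            v = getattr(self, r)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{r}: must lie in [0, 1]")
        if self.within_class_sd <= 0:
            raise ValueError("within_class_sd: must be positive")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd: must be non-negative")
        known = {a.name for a in self.assessments}
        for cls, prof in self.class_profiles.items():
            if cls not in self.class_names:
                raise ValueError(f"class_profiles: unknown class {cls!r}")
            for a in prof:
                if a != "__default__" and a not in known:
                    raise ValueError(f"class_profiles[{cls!r}]: unknown assessment {a!r}")
        expected_rows = ["intercept"] + [c.name for c in self.covariate_catalog]
        if list(self.true_beta.index) != expected_rows:
            raise ValueError("true_beta: rows must be intercept + covariate_catalog names")
        if list(self.true_beta.columns) != list(self.class_names[1:]):
            raise ValueError("true_beta: columns must be the non-reference class names")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "assessments": [vars_frozen(a) for a in self.assessments],
            "class_names": list(self.class_names),
            "class_shares_target": list(map(float, self.class_shares_target)),
            "class_profiles": {c: {k: list(v) for k, v in p.items()}
                               for c, p in self.class_profiles.items()},
            "within_class_sd": self.within_class_sd,
            "random_intercept_sd": self.random_intercept_sd,
            "covariate_catalog": [vars_frozen(c) for c in self.covariate_catalog],
            "true_beta": {"index": list(self.true_beta.index),
                          "columns": list(self.true_beta.columns),
                          "values": self.true_beta.values.tolist()},
            "item_missing_rate": self.item_missing_rate,
            "scale_missing_rate": self.scale_missing_rate,
            "dropout_rate": self.dropout_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["assessments"] = [AssessmentSpec(**{**a, "waves_administered": tuple(a["waves_administered"])})
                            for a in d["assessments"]]
        d["class_names"] = tuple(d["class_names"])
        d["class_shares_target"] = tuple(d["class_shares_target"])
        d["class_profiles"] = {c: {k: tuple(v) for k, v in p.items()}
                               for c, p in d["class_profiles"].items()}
        d["covariate_catalog"] = [CovariateSpec(**c) for c in d["covariate_catalog"]]
        tb = d["true_beta"]
        d["true_beta"] = pd.DataFrame(tb["values"], index=tb["index"], columns=tb["columns"])
        return cls(**d)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def low_noise_cohort_spec(n_participants: int = 500, seed: int = 0) -> CohortSpec:
    """The benchmark condition for cluster-recovery experiments.

    Well-separated default profiles with small within-class and
    random-intercept variation and light scale-level missingness; the
    binomial item noise remains, so trajectories are still discretized and
    bounded like real scale scores.
    """
    return CohortSpec(n_participants=n_participants, within_class_sd=0.25,
                      random_intercept_sd=0.1, item_missing_rate=0.0,
                      scale_missing_rate=0.02, seed=seed)


def vars_frozen(obj) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in ((f, getattr(obj, f)) for f in obj.__dataclass_fields__)}


@dataclass
class GeneratedCohort:
    item_table: pd.DataFrame  # participant, wave, informant, assessment, item, value
    scale_table: pd.DataFrame  # participant, wave, assessment, score
    covariate_table: pd.DataFrame  # participant + one column per covariate
    true_labels: pd.Series  # participant -> class name
    spec_echo: CohortSpec

    def write(self, directory):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.item_table.to_csv(d / "item_table.csv", index=False)
        self.scale_table.to_csv(d / "scale_table.csv", index=False)
        self.covariate_table.to_csv(d / "covariate_table.csv", index=False)
        sidecar = {
            "true_labels": self.true_labels.to_dict(),
            "true_beta": self.spec_echo.to_dict()["true_beta"],
            "spec": self.spec_echo.to_dict(),
        }
        (d / "truth.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read(cls, directory) -> "GeneratedCohort":
        d = Path(directory)
        sidecar = json.loads((d / "truth.json").read_text())
        spec = CohortSpec.from_dict(sidecar["spec"])
        labels = pd.Series(sidecar["true_labels"], name="class")
        labels.index = labels.index.astype(int)
        labels.index.name = "participant"
        return cls(
            item_table=pd.read_csv(d / "item_table.csv"),
            scale_table=pd.read_csv(d / "scale_table.csv"),
            covariate_table=pd.read_csv(d / "covariate_table.csv"),
            true_labels=labels,
            spec_echo=spec,
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def design_matrix(covariate_table: pd.DataFrame, catalog: list[CovariateSpec]) -> np.ndarray:
    """Intercept + covariates on the scale the coefficients refer to.

    Continuous covariates are standardized by their *marginal* moments and
    multiplied by their effect sign; binaries enter as 0/1.
    """
    cols = [np.ones(len(covariate_table))]
    for c in catalog:
        x = covariate_table[c.name].to_numpy(float)
        if c.kind == "continuous":
            x = c.effect_sign * (x - c.mean) / c.sd
        cols.append(x)
    return np.column_stack(cols)


def _class_probabilities(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Softmax over [0, X @ beta] — reference class has logit 0."""
    logits = np.column_stack([np.zeros(len(X)), X @ beta])
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def calibrate_intercepts(X: np.ndarray, beta: pd.DataFrame,
                         target_shares: np.ndarray, tol: float = 0.005,
                         max_iter: int = 200) -> pd.DataFrame:
    """Shift the intercept row so expected class shares match the target.

    Fixed-point iteration on log share ratios: each non-reference intercept
    moves by log(target/current) − log(target_ref/current_ref).  Converges
    to within ``tol`` on every share for any full-support target.
    """
    beta = beta.copy()
    b = beta.values.astype(float).copy()
    target = np.asarray(target_shares, float)
    for _ in range(max_iter):
        shares = _class_probabilities(X, b).mean(axis=0)
        if np.abs(shares - target).max() < tol / 2:
            break
        adj = np.log(target[1:] / shares[1:]) - np.log(target[0] / shares[0])
        b[0, :] += adj
    beta.iloc[0, :] = b[0, :]
    return beta


def severity_to_items(severity: float, assessment: AssessmentSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw one bounded item-response vector given a latent severity (z-units)."""
    return _items_matrix(np.asarray([severity], float), assessment, rng)[0]


def _items_matrix(severity: np.ndarray, assessment: AssessmentSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Vectorized item draws: rows follow ``severity``, columns are items."""
    p = expit(assessment.item_slope * severity + assessment.item_offset)
    span = assessment.item_max - assessment.item_min
    draws = rng.binomial(span, p[:, None], size=(len(severity), assessment.n_items))
    return assessment.item_min + draws


def generate_cohort(spec: CohortSpec) -> GeneratedCohort:
    """Generate covariates, classes, trajectories, items and missingness."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    pid = np.arange(n)

    # covariates
    cov = {"participant": pid}
    for c in spec.covariate_catalog:
        if c.kind == "binary":
            cov[c.name] = rng.binomial(1, c.p, size=n)
        else:
            cov[c.name] = rng.normal(c.mean, c.sd, size=n)
    covariate_table = pd.DataFrame(cov)

    # class labels from the multinomial-logit model, intercepts calibrated
    X = design_matrix(covariate_table, spec.covariate_catalog)
    beta = calibrate_intercepts(X, spec.true_beta, np.asarray(spec.class_shares_target))
    probs = _class_probabilities(X, beta.values)
    u = rng.random(n)
    label_idx = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    labels = pd.Series([spec.class_names[i] for i in label_idx],
                       index=pd.Index(pid, name="participant"), name="class")
    spec_echo = replace(spec, true_beta=beta)

    # latent severities and item responses per administered (assessment, wave)
    item_rows = []
    scale_rows = []
    for a in spec.assessments:
        intercepts = rng.normal(0.0, spec.random_intercept_sd, size=n)
        for w, wave in enumerate(WAVES[: 4]):
            if wave not in a.waves_administered:
                continue
            base = np.empty(n)
            slope = np.empty(n)
            for ci, cls in enumerate(spec.class_names):
                prof = spec.class_profiles.get(cls, {})
                b0, b1 = prof.get(a.name, prof.get("__default__", (0.0, 0.0)))
                sel = label_idx == ci
                base[sel], slope[sel] = b0, b1
            severity = base + slope * w + intercepts + rng.normal(0.0, spec.within_class_sd, n)
            items = _items_matrix(severity, a, rng).astype(float)
            item_rows.append(pd.DataFrame({
                "participant": np.repeat(pid, a.n_items),
                "wave": wave,
                "informant": a.informant,
                "assessment": a.name,
                "item": np.tile(np.arange(a.n_items), n),
                "value": items.ravel(),
            }))
            scale_rows.append(pd.DataFrame({
                "participant": pid, "wave": wave, "assessment": a.name,
                "score": items.sum(axis=1),
            }))

    item_table = pd.concat(item_rows, ignore_index=True)
    scale_table = pd.concat(scale_rows, ignore_index=True)

    cohort = GeneratedCohort(item_table, scale_table, covariate_table, labels, spec_echo)
    return apply_missingness(cohort, spec.item_missing_rate, spec.scale_missing_rate,
                             spec.dropout_rate, rng)


def apply_missingness(cohort: GeneratedCohort, item_missing_rate: float,
                      scale_missing_rate: float, dropout_rate: float,
                      rng: np.random.Generator) -> GeneratedCohort:
    """Structural removal, then scale blanks, then item blanks, then dropout.

    Blanked cells stay in the tables as NaN; dropout removes all records of
    a participant after a uniformly chosen wave.  A scale score becomes NaN
    as soon as any of its items is blank (imputation may later restore it).
    """
    for r, name in ((item_missing_rate, "item_missing_rate"),
                    (scale_missing_rate, "scale_missing_rate"),
                    (dropout_rate, "dropout_rate")):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name}: must lie in [0, 1]")
    spec = cohort.spec_echo
    administered = {(a.name, w) for a in spec.assessments for w in a.waves_administered}

    items = cohort.item_table.copy()
    scales = cohort.scale_table.copy()
    keep = [(a, w) in administered for a, w in zip(items["assessment"], items["wave"])]
    items = items.loc[keep].reset_index(drop=True)
    keep = [(a, w) in administered for a, w in zip(scales["assessment"], scales["wave"])]
    scales = scales.loc[keep].reset_index(drop=True)

    # whole-scale blanks
    if scale_missing_rate > 0:
        blank = rng.random(len(scales)) < scale_missing_rate
        blank_keys = set(map(tuple, scales.loc[blank, ["participant", "wave", "assessment"]]
                             .itertuples(index=False, name=None)))
        scales.loc[blank, "score"] = np.nan
        if blank_keys:
            hit = [(p, w, a) in blank_keys for p, w, a in
                   zip(items["participant"], items["wave"], items["assessment"])]
            items.loc[hit, "value"] = np.nan

    # item blanks among remaining observed items
    if item_missing_rate > 0:
        observed = items["value"].notna().to_numpy()
        blank = observed & (rng.random(len(items)) < item_missing_rate)
        items.loc[blank, "value"] = np.nan
        affected = set(map(tuple, items.loc[blank, ["participant", "wave", "assessment"]]
                           .itertuples(index=False, name=None)))
        if affected:
            hit = [(p, w, a) in affected for p, w, a in
                   zip(scales["participant"], scales["wave"], scales["assessment"])]
            scales.loc[hit, "score"] = np.nan

    # dropout after a uniformly chosen wave
    if dropout_rate > 0:
        wave_order = {w: i for i, w in enumerate(WAVES)}
        pids = cohort.covariate_table["participant"].to_numpy()
        drops = rng.random(len(pids)) < dropout_rate
        last_wave = rng.integers(0, len(WAVES) - 1, size=len(pids))  # inclusive last index
        cutoff = {p: (last_wave[i] if drops[i] else len(WAVES)) for i, p in enumerate(pids)}
        items = items.loc[[wave_order[w] <= cutoff[p]
                           for p, w in zip(items["participant"], items["wave"])]]
        scales = scales.loc[[wave_order[w] <= cutoff[p]
                             for p, w in zip(scales["participant"], scales["wave"])]]
        items = items.reset_index(drop=True)
        scales = scales.reset_index(drop=True)

    return GeneratedCohort(items, scales, cohort.covariate_table, cohort.true_labels,
                           cohort.spec_echo)
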