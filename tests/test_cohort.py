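"""Synthetic-cohort generator: bounds, determinism, calibration, missingness."""

import numpy as np
import pandas as pd
import pytest

from psytraj.cohort import (AssessmentSpec, CohortSpec,
                            apply_missingness, calibrate_intercepts,
                            default_assessments, design_matrix, generate_cohort,
                            severity_to_items, _class_probabilities)


def test_default_catalog_reproduces_published_bounds():
    cat = {a.name: a for a in default_assessments()}
    assert len(cat) == 14
    assert (cat["depression_self"].score_min, cat["depression_self"].score_max) == (0, 26)
    assert cat["emotional_caregiver"].score_max == 10
    assert cat["selfharm_self"].score_max == 1
    assert cat["slim_desire_self"].score_max == 3
    assert cat["somatic_caregiver"].score_max == 18
    # structurally missing waves
    for name in ("psychotic_caregiver", "obsession_caregiver",
                 "somatic_caregiver", "withdrawal_caregiver"):
        assert "T3" not in cat[name].waves_administered
    assert "T3" in cat["dissociation_caregiver"].waves_administered
    for name in ("selfharm_self", "suicidal_self"):
        assert "T1" not in cat[name].waves_administered
    # summed-item invariant
    for a in default_assessments():
        assert a.score_max == a.n_items * a.item_max
        assert a.score_min == a.n_items * a.item_min


def test_generation_is_deterministic_under_seed():
    a = generate_cohort(CohortSpec(n_participants=60, seed=11))
    b = generate_cohort(CohortSpec(n_participants=60, seed=11))
    assert a.scale_table.equals(b.scale_table)
    assert a.item_table.equals(b.item_table)
    assert a.covariate_table.equals(b.covariate_table)
    assert a.true_labels.equals(b.true_labels)


def test_bounds_and_administered_waves_respected(small_cohort):
    spec = small_cohort.spec_echo
    by_name = {a.name: a for a in spec.assessments}
    items = small_cohort.item_table.dropna(subset=["value"])
    lo = items["assessment"].map(lambda a: by_name[a].item_min)
    hi = items["assessment"].map(lambda a: by_name[a].item_max)
    assert ((items["value"] >= lo) & (items["value"] <= hi)).all()
    administered = {(a.name, w) for a in spec.assessments for w in a.waves_administered}
    seen = set(zip(small_cohort.scale_table["assessment"], small_cohort.scale_table["wave"]))
    assert seen <= administered


def test_degenerate_noise_gives_identical_class_members():
    # saturated item link makes items deterministic given severity
    assessments = [AssessmentSpec("a1", "self", 3, 0, 2, item_slope=1e3, item_offset=0.0),
                   AssessmentSpec("a2", "caregiver", 2, 0, 2, item_slope=1e3, item_offset=0.0)]
    profiles = {"lo": {"__default__": (-1.0, 0.0)}, "hi": {"__default__": (1.0, 0.0)}}
    beta = pd.DataFrame({"hi": [0.0]}, index=["intercept"])
    spec = CohortSpec(n_participants=40, assessments=assessments,
                      class_names=("lo", "hi"), class_shares_target=(0.5, 0.5),
                      class_profiles=profiles, within_class_sd=1e-9,
                      random_intercept_sd=0.0, covariate_catalog=[],
                      true_beta=beta, item_missing_rate=0, scale_missing_rate=0,
                      dropout_rate=0, seed=5)
    cohort = generate_cohort(spec)
    wide = cohort.scale_table.pivot_table(index="participant",
                                          columns=["assessment", "wave"], values="score")
    for cls in ("lo", "hi"):
        members = wide.loc[cohort.true_labels[cohort.true_labels == cls].index]
        assert (members.nunique() == 1).all(), f"class {cls} not homogeneous"


def test_intercept_calibration_hits_target_shares():
    """Empirical shares pooled over 20 seeds stay within 3 binomial SE."""
    labels = []
    spec0 = CohortSpec(n_participants=500)
    for seed in range(20):
        spec = CohortSpec(n_participants=500, seed=1000 + seed,
                          item_missing_rate=0, scale_missing_rate=0)
        labels.append(generate_cohort(spec).true_labels)
    pooled = pd.concat(labels)
    n = len(pooled)
    target = dict(zip(spec0.class_names, spec0.class_shares_target))
    for cls, p in target.items():
        phat = (pooled == cls).mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(phat - p) < 3 * se + 0.005, f"{cls}: {phat:.3f} vs {p:.3f}"


def test_calibrated_expected_shares_within_contract():
    spec = CohortSpec(n_participants=2000, seed=3)
    rng = np.random.default_rng(0)
    cov = {"participant": np.arange(2000)}
    for c in spec.covariate_catalog:
        cov[c.name] = (rng.binomial(1, c.p, 2000) if c.kind == "binary"
                       else rng.normal(c.mean, c.sd, 2000))
    X = design_matrix(pd.DataFrame(cov), spec.covariate_catalog)
    beta = calibrate_intercepts(X, spec.true_beta, np.asarray(spec.class_shares_target))
    shares = _class_probabilities(X, beta.values).mean(axis=0)
    assert np.abs(shares - np.asarray(spec.class_shares_target)).max() < 0.005


@pytest.mark.parametrize("severity,expected", [(-1e6, "min"), (1e6, "max")])
def test_item_link_saturates(severity, expected):
    spec = AssessmentSpec("x", "self", 5, 0, 2)
    rng = np.random.default_rng(0)
    items = severity_to_items(severity, spec, rng)
    target = spec.item_min if expected == "min" else spec.item_max
    assert (items == target).all()


def test_item_link_mean_matches_binomial():
    """severity 0, offset 0: summed score averages n_items * item_max / 2."""
    spec = AssessmentSpec("x", "self", 5, 0, 2, item_slope=1.2, item_offset=0.0)
    rng = np.random.default_rng(1)
    sums = [severity_to_items(0.0, spec, rng).sum() for _ in range(4000)]
    assert np.mean(sums) == pytest.approx(5.0, abs=3 * np.std(sums) / np.sqrt(len(sums)))


def test_missingness_rates_and_structure():
    base = CohortSpec(n_participants=1000, item_missing_rate=0,
                      scale_missing_rate=0, dropout_rate=0, seed=21)
    clean = generate_cohort(base)
    assert clean.scale_table["score"].notna().all()

    rng = np.random.default_rng(2)
    blanked = apply_missingness(clean, 0.02, 0.01, 0.0, rng)
    # whole-scale blanks are only identifiable on multi-item scales (a
    # single-item scale blanked at the item level looks identical)
    multi = {a.name for a in base.assessments if a.n_items >= 3}
    mi = blanked.item_table[blanked.item_table["assessment"].isin(multi)]
    scale_frac = (mi.groupby(["participant", "wave", "assessment"])["value"]
                  .apply(lambda v: v.isna().all()).mean())
    n_scales = mi.groupby(["participant", "wave", "assessment"]).ngroups
    se = np.sqrt(0.01 * 0.99 / n_scales)
    assert abs(scale_frac - 0.01) < 3 * se
    # item blanks among cells not already scale-blanked (multi-item scales,
    # where the two mechanisms are distinguishable)
    nontotal = mi.groupby(["participant", "wave", "assessment"])[
        "value"].transform(lambda v: ~v.isna().all())
    sub = mi[nontotal]
    item_frac = sub["value"].isna().mean()
    se = np.sqrt(0.02 * 0.98 / len(sub))
    assert abs(item_frac - 0.02) < 3 * se


def test_item_rate_one_blanks_everything():
    base = CohortSpec(n_participants=30, item_missing_rate=0,
                      scale_missing_rate=0, seed=4)
    cohort = generate_cohort(base)
    out = apply_missingness(cohort, 1.0, 0.0, 0.0, np.random.default_rng(0))
    assert out.item_table["value"].isna().all()
    assert out.scale_table["score"].isna().all()


def test_dropout_removes_trailing_waves():
    base = CohortSpec(n_participants=300, item_missing_rate=0,
                      scale_missing_rate=0, seed=8)
    cohort = generate_cohort(base)
    out = apply_missingness(cohort, 0.0, 0.0, 0.5, np.random.default_rng(3))
    waves = out.scale_table.groupby("participant")["wave"].agg(set)
    order = {"T1": 0, "T2": 1, "T3": 2, "T4": 3}
    for seen in waves:
        idx = sorted(order[w] for w in seen)
        assert idx == list(range(idx[0], idx[-1] + 1)) and idx[0] == 0
    assert (waves.apply(len) < 4).any()


def test_labels_depend_on_covariates_iff_beta_nonzero():
    """Permutation test of mutual information at alpha = 0.01."""
    from sklearn.metrics import mutual_info_score

    def mi_pvalue(cohort, covariate, perms=200):
        x = (cohort.covariate_table[covariate] > 0).astype(int).to_numpy()
        y = cohort.true_labels.to_numpy()
        obs = mutual_info_score(x, y)
        rng = np.random.default_rng(0)
        null = [mutual_info_score(rng.permutation(x), y) for _ in range(perms)]
        return (1 + sum(v >= obs for v in null)) / (1 + perms)

    linked = generate_cohort(CohortSpec(n_participants=2000, seed=31,
                                        item_missing_rate=0, scale_missing_rate=0))
    assert mi_pvalue(linked, "autistic_traits") < 0.01

    flat = CohortSpec(n_participants=2000, seed=32, item_missing_rate=0,
                      scale_missing_rate=0)
    flat.true_beta = flat.true_beta.copy()
    flat.true_beta.iloc[1:, :] = 0.0
    null_cohort = generate_cohort(flat)
    assert mi_pvalue(null_cohort, "autistic_traits") > 0.01


def test_spec_validation_rejects_bad_inputs():
    with pytest.raises(ValueError, match="class_shares_target"):
        CohortSpec(class_shares_target=(0.5, 0.2, 0.1, 0.1, 0.05)).validate()
    spec = CohortSpec()
    spec.class_profiles = {**spec.class_profiles,
                           "severe": {"not_an_assessment": (1.0, 0.0)}}
    with pytest.raises(ValueError, match="not_an_assessment"):
        spec.validate()


def test_cohort_spec_round_trips_through_yaml(tmp_path):
    spec = CohortSpec(n_participants=77, seed=9, within_class_sd=0.4)
    spec.to_yaml(tmp_path / "spec.yaml")
    back = CohortSpec.from_yaml(tmp_path / "spec.yaml")
    assert back.n_participants == 77 and back.within_class_sd == 0.4
    pd.testing.assert_frame_equal(back.true_beta, spec.true_beta)
    a = generate_cohort(spec)
    b = generate_cohort(back)
    assert a.scale_table.equals(b.scale_table)


def test_cohort_round_trips_through_csv(tmp_path, small_cohort):
    small_cohort.write(tmp_path / "cohort")
    back = type(small_cohort).read(tmp_path / "cohort")
    assert back.true_labels.equals(small_cohort.true_labels)
    pd.testing.assert_frame_equal(back.covariate_table, small_cohort.covariate_table)
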