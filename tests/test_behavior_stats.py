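"""Behavioural regressions, group contrasts and subjective-report model."""

import warnings

import numpy as np
import pandas as pd
import pytest

import placebo_rl as p
from placebo_rl.behavior_stats import (
    BehaviorResults,
    Contrast,
    RegressionSpec,
    SubjectiveRegression,
    SubjectiveSpec,
    build_design,
    category_probs,
    fit_behavior,
    fit_subjective,
    subjective_design_row,
    subjective_frame,
)
from placebo_rl.io_cli import cohort_to_frame


# -- design construction -----------------------------------------------------


def test_design_trial_z_and_baselines(tiny_cohort):
    design = build_design(tiny_cohort, RegressionSpec(outcome="accuracy"))
    assert design.X["trial_z"].mean() == pytest.approx(0.0, abs=1e-10)
    assert np.std(design.X["trial_z"].to_numpy()) == pytest.approx(1.0, rel=1e-6)
    df = cohort_to_frame(tiny_cohort)
    df = df[df["task_label"].isin(["task1_default", "task3_default"])].reset_index(drop=True)
    nhg_day1 = (df["group"] == "NHG") & (df["day"] == 1)
    dummies = [c for c in design.X.columns if c.startswith(("group", "day2"))]
    assert (design.X.loc[nhg_day1.to_numpy(), dummies] == 0).all().all()


def test_design_matches_hand_coded_oracle():
    rows = []
    for day, pid, t in [(1, "AB", 1), (1, "CD", 2), (2, "EF", 1), (2, "AB", 2)]:
        rows.append(
            {
                "subject_id": "S1",
                "group": "placebo",
                "day": day,
                "task_label": "task1_default" if day == 1 else "task3_default",
                "block": 1,
                "trial_in_session": t,
                "pair_id": pid,
                "better_on_left": 1,
                "chosen_better": 1,
                "reward": 1,
                "rt_ms": 700.0,
            }
        )
    design = build_design(pd.DataFrame(rows), RegressionSpec(outcome="accuracy"))
    t = np.array([1, 2, 1, 2], dtype=float)
    tz = (t - t.mean()) / t.std()
    assert np.allclose(design.X["trial_z"], tz)
    assert design.X["pair_CD"].tolist() == [0, 1, 0, 0]
    assert design.X["pair_EF"].tolist() == [0, 0, 1, 0]
    assert design.X["day2"].tolist() == [0, 0, 1, 1]
    assert design.X["group[placebo]"].tolist() == [1, 1, 1, 1]
    assert design.X["day2:group[placebo]"].tolist() == [0, 0, 1, 1]
    assert np.allclose(design.X["trial_z:day2"], tz * design.X["day2"])


def test_design_missing_columns_named():
    with pytest.raises(ValueError, match="chosen_better"):
        build_design(pd.DataFrame({"subject_id": []}), RegressionSpec())
    with pytest.raises(ValueError, match="rt_ms"):
        build_design(
            pd.DataFrame(
                {
                    "subject_id": ["a"],
                    "group": ["NHG"],
                    "day": [1],
                    "task_label": ["task1_default"],
                    "trial_in_session": [1],
                    "pair_id": ["AB"],
                    "chosen_better": [1],
                    "reward": [1],
                }
            ),
            RegressionSpec(outcome="rt"),
        )


# -- hierarchical GLM --------------------------------------------------------


def _logistic_day_cohort(n_subj=12, n_trials=120, b0=0.4, b_day=0.5, sd_u=0.3, seed=1):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        u = sd_u * rng.standard_normal()
        for day in (1, 2):
            for t in range(1, n_trials + 1):
                eta = b0 + b_day * (day == 2) + u
                y = rng.random() < 1.0 / (1.0 + np.exp(-eta))
                rows.append(
                    {
                        "subject_id": f"S{s:02d}",
                        "group": "NHG",
                        "day": day,
                        "task_label": "task1_default" if day == 1 else "task3_default",
                        "block": 1,
                        "trial_in_session": t,
                        "pair_id": "AB",
                        "better_on_left": 1,
                        "chosen_better": int(y),
                        "reward": int(y),
                        "rt_ms": float(600 + 100 * rng.random()),
                    }
                )
    return pd.DataFrame(rows)


def test_accuracy_regression_recovers_day_effect():
    df = _logistic_day_cohort()
    spec = RegressionSpec(outcome="accuracy", terms=("trial", "day"), random=("intercept",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", p.ConvergenceWarning)
        res = fit_behavior(
            df,
            spec,
            config=p.SamplerConfig(sampler="ensemble", chains=4, warmup=2500, draws=500, thin=5),
            seed=0,
        )
    s = res.summary()
    assert s.loc["day2", "hdi_low"] < 0.5 < s.loc["day2", "hdi_high"]
    assert abs(s.loc["day2", "mean"] - 0.5) < 0.2


def test_rt_regression_reports_in_milliseconds(tiny_cohort):
    spec = RegressionSpec(outcome="rt", terms=("trial", "day"), random=("intercept",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", p.ConvergenceWarning)
        res = fit_behavior(
            tiny_cohort,
            spec,
            config=p.SamplerConfig(sampler="ensemble", chains=2, warmup=800, draws=300, thin=3),
            seed=0,
        )
    inter = res.coef_draws("intercept")
    # synthetic RTs live near exp(6.7) ~ 810 ms
    assert 400 < inter.mean() < 1400


def test_null_data_covers_zero():
    rng = np.random.default_rng(1)
    df = _logistic_day_cohort(b0=0.0, b_day=0.0, sd_u=0.0, seed=1)
    spec = RegressionSpec(outcome="accuracy", terms=("day",), random=("intercept",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", p.ConvergenceWarning)
        res = fit_behavior(
            df,
            spec,
            config=p.SamplerConfig(sampler="ensemble", chains=4, warmup=1500, draws=400, thin=4),
            seed=1,
        )
    s = res.summary()
    for name in ("intercept", "day2"):
        assert s.loc[name, "hdi_low"] < 0.0 < s.loc[name, "hdi_high"]
    del rng


# -- contrasts ---------------------------------------------------------------


def _fake_results(coefs: dict[str, np.ndarray]) -> BehaviorResults:
    names = list(coefs)
    chains = np.stack([np.stack([coefs[n] for n in names], axis=-1)])

    class _Design:
        X = pd.DataFrame(columns=names)
        subjects = []

    class _Model:
        param_names = names
        gaussian = False
        design = _Design()

    class _Diag:
        max_rhat = 1.0

    return BehaviorResults(_Model(), chains, _Diag())


def test_contrast_antisymmetry_and_self_zero():
    rng = np.random.default_rng(0)
    res = _fake_results(
        {
            "day2:group[placebo]": 0.55 + 0.1 * rng.standard_normal(400),
            "day2:group[placebo_control]": 0.24 + 0.1 * rng.standard_normal(400),
        }
    )
    ab = res.contrast("placebo", "placebo_control")
    ba = res.contrast("placebo_control", "placebo")
    assert np.allclose(ab.draws, -ba.draws)
    assert ab.mean == pytest.approx(0.31, abs=0.02)
    lo, hi = ab.interval
    assert lo < 0.31 < hi
    self_c = res.contrast("placebo", "placebo")
    assert np.all(self_c.draws == 0)
    with pytest.raises(KeyError):
        res.contrast("placebo", "nocebo")
    assert isinstance(ab, Contrast) and "delta" in repr(ab)


# -- subjective reports ------------------------------------------------------


def test_subjective_frame_and_design_rows(tiny_cohort):
    df = subjective_frame(tiny_cohort)
    assert set(df["group"]) == {"placebo"}  # only manipulated groups included
    assert set(df["question"]) == {"expected", "perceived"}
    x = subjective_design_row("nocebo", "perceived")
    assert x.tolist() == [1, 1, 1, 1, 1, 1]
    x = subjective_design_row("placebo_control", "expected")
    assert x.tolist() == [1, 0, 0, 0, 0, 0]
    with pytest.raises(KeyError):
        subjective_design_row("NHG", "expected")


def test_implied_probabilities_normalise_and_zero_case():
    coefs = np.zeros((50, 2, 6))
    x = subjective_design_row("placebo", "expected")
    probs = category_probs(coefs, x, "neutral")
    assert np.allclose(probs, 1.0 / 3.0)
    rng = np.random.default_rng(0)
    coefs = rng.standard_normal((200, 2, 6))
    probs = category_probs(coefs, x, "neutral")
    assert np.allclose(probs.sum(axis=1), 1.0)


def test_reference_category_invariance():
    """Re-expressing the coefficients against another reference category
    leaves the implied probabilities unchanged."""
    rng = np.random.default_rng(3)
    coefs = rng.standard_normal((300, 2, 6))  # (decline, improve) vs neutral
    x = subjective_design_row("nocebo", "expected")
    base = category_probs(coefs, x, "neutral")
    # reference switched to 'decline': coefficients become
    # (neutral - decline, improve - decline)
    switched = np.stack([-coefs[:, 0, :], coefs[:, 1, :] - coefs[:, 0, :]], axis=1)
    alt = category_probs(switched, x, "decline")
    assert np.allclose(base, alt, atol=1e-10)


def test_subjective_fit_recovers_generating_cells():
    """Cell probabilities generated from a known coefficient vector are
    recovered within Monte-Carlo tolerance at n = 16 per group."""
    rng = np.random.default_rng(4)
    true_coefs = np.array(
        [[-1.2, 0.8, 0.2, -0.8, 0.3, 1.5], [0.8, -1.0, 0.1, 1.0, 0.2, -1.8]]
    )  # (decline, improve) vs neutral
    rows = []
    cats = ("decline", "neutral", "improve")
    for g in p.MANIPULATED_GROUPS:
        for q in ("expected", "perceived"):
            x = subjective_design_row(g, q)
            pr = category_probs(true_coefs[None], x, "neutral")[0]
            for i in range(16):
                rows.append(
                    {
                        "subject_id": f"{g}_{i}",
                        "group": g,
                        "question": q,
                        "response": cats[rng.choice(3, p=pr)],
                    }
                )
    df = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", p.ConvergenceWarning)
        res = fit_subjective(
            df,
            config=p.SamplerConfig(sampler="ensemble", chains=4, warmup=2500, draws=500, thin=5),
            seed=2,
        )
    for g, q in [("nocebo", "expected"), ("placebo", "perceived")]:
        x = subjective_design_row(g, q)
        truth = category_probs(true_coefs[None], x, "neutral")[0]
        est = res.implied_probabilities(g, q)
        assert np.allclose(est.draws.sum(axis=1), 1.0)
        for j, cat in enumerate(cats):
            assert est.mean[cat] == pytest.approx(truth[j], abs=0.15)
    table = res.probability_table()
    assert len(table) == 4 * 2 * 3
    sums = table.groupby(["group", "question"])["mean"].sum()
    assert np.allclose(sums, 1.0, atol=0.02)


def test_subjective_input_validation():
    with pytest.raises(ValueError, match="response"):
        SubjectiveRegression(pd.DataFrame({"group": ["placebo"], "question": ["expected"]}))
    df = pd.DataFrame(
        {"subject_id": ["a"], "group": ["placebo"], "question": ["expected"], "response": ["maybe"]}
    )
    with pytest.raises(ValueError, match="maybe"):
        SubjectiveRegression(df)
    with pytest.raises(ValueError, match="reference"):
        SubjectiveSpec(reference="unsure")
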