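"""End-to-end seeded experiment: simulate → train → compensate → evaluate.

The default conditions mirror a population-based normative study:
2223 healthy training eyes, a 1:1 validation set of 254 glaucomatous and
254 healthy eyes, 768-point profiles, and covariate marginals from the
study-population table.  Evaluation compares glaucoma discrimination of
the original versus the compensated profiles within axial-length
percentile subgroups.
"""

from __future__ import annotations

from .compensation import ProfileCompensator, ResidualCompensator, ScaleShiftCompensator
from .age import AgeCompensator
from .config import RunConfig, child_seed
from .detection import (
    al_subgroup,
    detection_scores,
    fit_normative_limits,
    mean_absolute_compensation,
    performance_at,
    relative_auroc_gain,
    roc,
)
from .exceptions import ContractError
from .profiles import Cohort, filter_quality
from .simulate import generate_cohort

__all__ = ["simulate_cohorts", "train_compensator", "evaluate_cohorts", "run_experiment"]


def simulate_cohorts(config: RunConfig) -> tuple[Cohort, Cohort]:
    """Training (normals only) and validation (1:1) cohorts."""
    template = config.make_template()
    effects = config.make_effects()
    train = generate_cohort(
        n_normal=config.n_train,
        n_glaucoma=0,
        template=template,
        effects=effects,
        seed=child_seed(config.seed, "simulate-train"),
        P=config.P,
        id_prefix="T",
    )
    val = generate_cohort(
        n_normal=config.n_val_normal,
        n_glaucoma=config.n_val_glaucoma,
        template=template,
        effects=effects,
        seed=child_seed(config.seed, "simulate-val"),
        P=config.P,
        id_prefix="V",
    )
    return train, val


def train_compensator(train: Cohort, config: RunConfig, allow_mixed: bool = False) -> ProfileCompensator:
    """Fit the three-stage compensator on the (quality-filtered) normals."""
    cohort, _ = filter_quality(train, config.min_quality)
    if not allow_mixed and (cohort.labels == "glaucoma").any():
        raise ContractError(
            "training cohort contains glaucoma labels; the compensation is "
            "trained on normative eyes only (pass allow_mixed=True to override)"
        )
    if allow_mixed:
        age_kwargs = dict(config.age)
        age_kwargs.setdefault("check_labels", False)
    else:
        cohort = cohort.subset(cohort.frame["label"] == "normal")
        age_kwargs = dict(config.age)
    seed = child_seed(config.seed, "train")
    fcn_kwargs = {"random_state": seed, **config.fcn}
    rbf_kwargs = {"random_state": seed, **config.rbfn}
    model = ProfileCompensator(
        age=AgeCompensator(**age_kwargs),
        scale_shift=ScaleShiftCompensator(**fcn_kwargs),
        residual=ResidualCompensator(**rbf_kwargs),
    )
    model.fit(cohort.to_frame())
    return model


def _arm_report(scores, labels, threshold) -> dict:
    r = roc(scores, labels)
    perf = performance_at(scores, labels, threshold)
    return {"auroc": r.auroc, "performance": perf.to_dict()}


def evaluate_cohorts(
    train: Cohort, val: Cohort, model: ProfileCompensator, config: RunConfig
) -> dict:
    """Before/after discrimination report with AL-percentile subgroups."""
    from .compensation import compensate

    train_n = train.subset(train.frame["label"] == "normal")
    train_comp = compensate(train_n, model)
    val_comp = compensate(val, model)

    limits_orig = fit_normative_limits(train_n.profiles, config.limit_method)
    limits_comp = fit_normative_limits(train_comp.profiles, config.limit_method)

    report = {"subgroups": {}, "variance_trajectory": list(model.variance_trajectory_)}
    for fraction in config.subgroup_fractions:
        sub = al_subgroup(val, fraction)
        sub_comp = al_subgroup(val_comp, fraction)
        # al_subgroup sorts identically (same AL/eye_id), rows stay aligned
        orig_scores = detection_scores(sub.profiles, limits_orig)
        comp_scores = detection_scores(sub_comp.profiles, limits_comp)
        labels = sub.labels
        block = {
            "n": len(sub),
            "n_glaucoma": int((labels == "glaucoma").sum()),
            "mean_axial_length": float(sub.frame["axial_length"].mean()),
            "original": _arm_report(orig_scores, labels, config.detection_threshold),
            "compensated": _arm_report(comp_scores, labels, config.detection_threshold),
            "mean_absolute_compensation": mean_absolute_compensation(
                sub.profiles, sub_comp.profiles
            ),
        }
        block["relative_auroc_gain_pct"] = relative_auroc_gain(
            block["original"]["auroc"], block["compensated"]["auroc"]
        )
        report["subgroups"][f"{fraction:g}"] = block
    report["mean_profile_original"] = val.profiles.mean(axis=0).tolist()
    report["mean_profile_compensated"] = val_comp.profiles.mean(axis=0).tolist()
    return report


def run_experiment(config: RunConfig | None = None) -> dict:
    """Full seeded pipeline; returns the evaluation report."""
    config = config or RunConfig()
    train, val = simulate_cohorts(config)
    model = train_compensator(train, config)
    report = evaluate_cohorts(train, val, model, config)
    report["config"] = config.to_dict()
    return report
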