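"""End-to-end orchestration of the breath-VOC analysis.

``run_pipeline`` executes the full experiment on a synthetic cohort (or a
user-supplied CSV feature table): preprocessing, batch correction, the
one-class CRC screen (Model 1), marker-panel discovery for AA vs control
with panel transfer to the CRC contrasts (Model 2), and the hierarchical
midlevel-fusion 3-class model (Model 3).  Every stage seed derives from a
single master seed, so a config + seed pair reproduces the report exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .batch_correct import BatchDesign, class_covariates, combat
from .containers import FeatureTable
from .evaluation import evaluate, ppv
from .hierarchical_fusion import Submodel, fit_final, fit_submodel, fuse, submodel_scores_for
from .isolation_forest import one_class_loo, representative_split
from .preprocess import normalize, prevalence_filter, scale
from .rf_panel import (
    fit_rf,
    iterative_importance,
    oob_proximity,
    oob_scores,
    pcoa,
    predict_scores,
    select_panel,
    transfer_panel,
)
from .synthetic_data import CohortSpec, generate_feature_table, read_dataset

log = logging.getLogger("breathpanel")

#: Enrolment bookkeeping of the emulated screening study: patients recruited,
#: and exclusions applied in declared order before analysis.
DEFAULT_ENROLLED = 448
DEFAULT_EXCLUSION_COUNTS = {
    "missing_records": 10,
    "low_bowel_prep": 3,
    "ibd": 2,
    "incomplete_colonoscopy": 3,
    "failed_measurement": 48,
}


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run.

    ``cohort`` holds CohortSpec keyword overrides (ignored when
    ``input_dir`` points at an existing dataset written by
    :func:`breathpanel.synthetic_data.write_dataset`).  Model budgets
    default to desk-scale settings; ``study_scale`` raises the iteration
    budgets to the original 1000 x 1000 and pins the panel size at 10.
    """

    cohort: dict = field(default_factory=dict)
    input_dir: str | None = None
    prevalence_threshold: float = 0.20
    scale_mode: str = "pareto"
    batch_correction: bool = True
    combat_parametric: bool = True
    model1_trees: int = 200
    model2_n_iter: int = 100
    model2_trees_per_iter: int = 100
    model2_final_trees: int = 500
    model2_n_test_per_class: int = 10
    model2_k_grid: tuple[int, ...] = (3, 5, 10, 15, 20)
    model2_force_k: int | None = None
    transfer_panel_size: int = 5
    model3_trees: int = 500
    model3_n_validation_per_class: int = 15
    spec_target: float = 0.70
    study_scale: bool = False
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence_threshold <= 1.0:
            raise ValueError("prevalence_threshold must lie in [0, 1]")
        if self.study_scale:
            self.model2_n_iter = 1000
            self.model2_trees_per_iter = 1000
            self.model2_force_k = 10
            self.model1_trees = 500

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        _check_keys(d, {f.name for f in dataclasses.fields(cls)}, "pipeline config")
        if "cohort" in d:
            _check_keys(
                d["cohort"], {f.name for f in dataclasses.fields(CohortSpec)}, "cohort spec"
            )
        if "model2_k_grid" in d:
            d = {**d, "model2_k_grid": tuple(d["model2_k_grid"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model2_k_grid"] = list(d["model2_k_grid"])
        return d


def _stage_seeds(master: int, n: int = 16) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % (2**31)]


def exclusion_cascade(samples: pd.DataFrame, rules: list[str]) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply ordered exclusion rules to an annotated roster.

    ``samples`` carries one boolean column per exclusion flag.  Each sample
    is counted under the *first* rule (in ``rules`` order) that flags it;
    the kept roster is the unflagged remainder — so permuting the rule
    order can move samples between per-rule counts but never changes the
    kept set.
    """
    missing = [r for r in rules if r not in samples.columns]
    if missing:
        raise ValueError(f"unknown exclusion flags: {missing}")
    counts: dict[str, int] = {}
    remaining = samples
    for rule in rules:
        flagged = remaining[remaining[rule].astype(bool)]
        counts[rule] = len(flagged)
        remaining = remaining[~remaining[rule].astype(bool)]
    return remaining, counts


def default_exclusion_roster(
    n_enrolled: int = DEFAULT_ENROLLED,
    flag_counts: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic enrolment roster with the study-scale exclusion flags.

    Flags are assigned to distinct randomly chosen samples so the cascade's
    per-rule counts match ``flag_counts`` regardless of rule order.
    """
    flag_counts = dict(DEFAULT_EXCLUSION_COUNTS if flag_counts is None else flag_counts)
    total_flagged = sum(flag_counts.values())
    if total_flagged > n_enrolled:
        raise ValueError("more exclusions than enrolled samples")
    rng = np.random.default_rng(seed)
    ids = pd.Index([f"P{i:04d}" for i in range(n_enrolled)], name="patient")
    roster = pd.DataFrame({flag: False for flag in flag_counts}, index=ids)
    flagged = rng.choice(n_enrolled, size=total_flagged, replace=False)
    pos = 0
    for flag, k in flag_counts.items():
        roster.iloc[flagged[pos : pos + k], roster.columns.get_loc(flag)] = True
        pos += k
    return roster


def _preprocess_table(table: FeatureTable, config: PipelineConfig) -> FeatureTable:
    t = normalize(table)
    t = prevalence_filter(t, threshold=config.prevalence_threshold)
    t = scale(t, mode=config.scale_mode)
    if config.batch_correction and t.batches.nunique() > 1:
        design = BatchDesign(t.batches, covariates=class_covariates(t))
        t = combat(t, design, parametric=config.combat_parametric)
    return t


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full experiment and return the run report (JSON-safe dict)."""
    t0 = time.time()
    seeds = _stage_seeds(config.seed)
    timings: dict[str, float] = {}

    # ---- cohort -----------------------------------------------------------
    truth = None
    if config.input_dir:
        table, truth = read_dataset(config.input_dir)
        log.info("loaded cohort from %s: %d samples x %d features",
                 config.input_dir, table.n_samples, table.n_features)
    else:
        spec = CohortSpec(**{**config.cohort, "rng_seed": config.cohort.get("rng_seed", seeds[0])})
        table, truth = generate_feature_table(spec)
        log.info("generated synthetic cohort: %d samples x %d features",
                 table.n_samples, table.n_features)
    timings["cohort"] = time.time() - t0

    # ---- preprocessing + batch correction ---------------------------------
    t1 = time.time()
    corrected = _preprocess_table(table, config)
    log.info("preprocessed: %d features retained by the %.0f%% prevalence filter",
             corrected.n_features, 100 * config.prevalence_threshold)
    timings["preprocess"] = time.time() - t1

    classes = corrected.classes
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.as_dict(),
        "data_source": "synthetic" if not config.input_dir else str(config.input_dir),
        "cohort": {
            "n_samples": int(corrected.n_samples),
            "n_per_class": {c: int((classes == c).sum()) for c in sorted(set(classes))},
            "n_features_input": int(table.n_features),
            "n_features_retained": int(corrected.n_features),
        },
    }

    # ---- Model 1: one-class CRC screen ------------------------------------
    t1 = time.time()
    ctrl = corrected.values[classes == "control"].to_numpy(float)
    crc = corrected.values[classes == "CRC"].to_numpy(float)
    m1 = one_class_loo(ctrl, crc, n_trees=config.model1_trees, seed=seeds[1],
                       spec_target=config.spec_target)
    report["model1"] = m1.as_dict()
    timings["model1"] = time.time() - t1
    log.info("model 1 (CRC vs control, one-class LOO): AUC=%.3f sens=%.3f spec=%.3f",
             m1.auc_roc, m1.sensitivity, m1.specificity)

    # ---- Model 2: AA vs control marker panel ------------------------------
    t1 = time.time()
    aa_ctrl = corrected.subset_samples(corrected.values.index[classes.isin(["AA", "control"])])
    y_all = (aa_ctrl.classes == "AA").astype(int).to_numpy()
    train_ids, test_ids = representative_split(
        aa_ctrl, aa_ctrl.classes.to_numpy(), config.model2_n_test_per_class, seed=seeds[2]
    )
    train = aa_ctrl.subset_samples(train_ids)
    test = aa_ctrl.subset_samples(test_ids)
    y_train = (train.classes == "AA").astype(int).to_numpy()
    y_test = (test.classes == "AA").astype(int).to_numpy()

    ranking = iterative_importance(
        train.values.to_numpy(float), y_train,
        n_iter=config.model2_n_iter, trees_per_iter=config.model2_trees_per_iter,
        seed=seeds[3], feature_names=list(train.values.columns),
    )
    panel = select_panel(
        ranking, train.values.to_numpy(float), y_train,
        k_grid=config.model2_k_grid, n_trees=config.model2_final_trees,
        seed=seeds[4], force_k=config.model2_force_k,
    )
    final_m2 = fit_rf(
        train.values[panel.features].to_numpy(float), y_train,
        n_trees=config.model2_final_trees, seed=seeds[5], feature_names=panel.features,
    )
    oob_report = evaluate(oob_scores(final_m2), y_train, spec_target=config.spec_target)
    test_scores = predict_scores(final_m2, test.values[panel.features].to_numpy(float))
    test_report = evaluate(test_scores, y_test, spec_target=config.spec_target)
    prox, _ = oob_proximity(final_m2)
    emb = pcoa(prox, sample_ids=train_ids)
    m2_sub = Submodel(model=final_m2, pcoa=emb, train_ids=train_ids,
                      proximity=prox, submodel_id="Model2")

    report["model2"] = {
        "train_sizes": {c: int((train.classes == c).sum()) for c in ("AA", "control")},
        "test_sizes": {c: int((test.classes == c).sum()) for c in ("AA", "control")},
        "panel": list(panel.features),
        "panel_signed_importance": {
            f: float(panel.signed_importance[f]) for f in panel.features
        },
        "oob": oob_report.as_dict(),
        "test": test_report.as_dict(),
        "test_ppv": float(
            ppv(test_report.sensitivity, test_report.specificity,
                int(y_test.sum()), int((1 - y_test).sum()))
        ),
        "pcoa_pc1_fraction": float(emb.proportion_explained[0]),
    }
    if truth is not None:
        planted = set(truth.marker_indices)
        recovered = planted & set(panel.features)
        report["model2"]["marker_recovery"] = {
            "n_planted": len(planted),
            "n_recovered": len(recovered),
            "recovered": sorted(recovered),
        }
    timings["model2"] = time.time() - t1
    log.info("model 2 (AA vs control): panel=%d features, OOB AUC=%.3f, test AUC=%.3f",
             len(panel), oob_report.auc_roc, test_report.auc_roc)

    # ---- Model 2 transfer: CRC and CRC+AA vs control ----------------------
    t1 = time.time()
    small = panel.truncate(min(config.transfer_panel_size, len(panel)))
    for name, case_classes in (("transfer_crc", ["CRC"]), ("transfer_crc_aa", ["CRC", "AA"])):
        mask = classes.isin(case_classes + ["control"])
        sub = corrected.subset_samples(corrected.values.index[mask])
        y_sub = sub.classes.isin(case_classes).astype(int).to_numpy()
        rep = transfer_panel(small, sub.values, y_sub, spec_target=config.spec_target,
                             n_trees=config.model2_final_trees, seed=seeds[6])
        report["model2"][name] = rep.as_dict()
    timings["transfer"] = time.time() - t1

    # ---- Model 3: hierarchical fusion 3-class -----------------------------
    t1 = time.time()
    three = corrected.subset_samples(corrected.values.index[classes.isin(["AA", "NAA", "control"])])
    train3_ids, val3_ids = representative_split(
        three, three.classes.to_numpy(), config.model3_n_validation_per_class, seed=seeds[7]
    )
    train3 = three.subset_samples(train3_ids)
    y3 = train3.classes

    sub_a = fit_submodel(train3.values, (y3 == "AA").astype(int).to_numpy(),
                         n_trees=config.model3_trees, seed=seeds[8], submodel_id="A")
    b_rows = train3.values.index[y3.isin(["NAA", "control"])]
    sub_b = fit_submodel(train3.values.loc[b_rows],
                         (y3.loc[b_rows] == "NAA").astype(int).to_numpy(),
                         n_trees=config.model3_trees, seed=seeds[9], submodel_id="B")

    all3 = three.values
    scores_a = submodel_scores_for(sub_a, all3)
    scores_b = submodel_scores_for(sub_b, all3)
    scores_m2 = submodel_scores_for(m2_sub, all3[list(panel.features)])
    fused = fuse(scores_a, scores_b, scores_m2)

    final3, rep3 = fit_final(fused, three.classes, n_trees=config.model3_trees,
                             seed=seeds[10], validation_ids=val3_ids)
    prox3, _ = oob_proximity(final3)
    emb3 = pcoa(prox3)
    pc12 = float(emb3.proportion_explained[: min(2, emb3.proportion_explained.size)].sum())
    report["model3"] = {
        "validation_scope": "internal validation only (no independent test set)",
        "train_sizes": {c: int((y3 == c).sum()) for c in ("AA", "NAA", "control")},
        "validation_sizes": {
            c: int((three.classes.loc[val3_ids] == c).sum()) for c in ("AA", "NAA", "control")
        },
        **rep3.as_dict(),
        "pcoa_pc12_fraction": pc12,
    }
    timings["model3"] = time.time() - t1
    log.info("model 3 (AA/NAA/control fusion): weighted accuracy=%.3f", rep3.weighted_accuracy)

    # ---- exclusion-cascade bookkeeping ------------------------------------
    roster = default_exclusion_roster(seed=seeds[11])
    kept, counts = exclusion_cascade(roster, list(DEFAULT_EXCLUSION_COUNTS))
    report["exclusion_cascade"] = {
        "n_enrolled": int(len(roster)),
        "per_rule": {k: int(v) for k, v in counts.items()},
        "n_analyzable": int(len(kept)),
    }

    timings["total"] = time.time() - t0
    report["timings_seconds"] = {k: round(v, 3) for k, v in timings.items()}

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run_report.json").write_text(json.dumps(report, indent=2))
        corrected.values.to_csv(out / "corrected_feature_table.csv")
        pd.DataFrame(
            emb.coordinates[:, :2], index=train_ids, columns=["PCo1", "PCo2"]
        ).to_csv(out / "model2_pcoa_coordinates.csv")
        fused.to_csv(out / "model3_fused_scores.csv")
    return report
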