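"""Configuration-driven orchestration of the full analysis pipeline.

Stages run in order — simulate (or load), build-scales, score, flags,
validate — with every stage's outputs persisted (CSV for tables, JSON
for model objects) before the next begins, plus a run manifest carrying
the seed, configuration echo and package versions.  Each stage can also
be re-run from its persisted inputs through the CLI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core_data import AGE_POINTS, Cohort, filter_by_outcome, load_cohort, save_cohort
from .flags import (
    DEFAULT_AGE_POLICY,
    FlagThreshold,
    assign_flags,
    evaluate_flags,
    fit_thresholds,
    weeks_saved,
)
from .items import ALL_ITEMS
from .scales import ScaleDefinition, build_scale_scores, build_scales
from .synthetic import MEASURE_TABLE, GeneratorConfig, generate_cohort
from .validity import (
    DEFAULT_CONCURRENT_HYPOTHESES,
    DEFAULT_CONSTRUCT_HYPOTHESES,
    association_tests,
    construct_matrix,
    mean_temporal_rho,
    regression_table,
    temporal_consistency,
)
from .zscores import SCHEMES, ZScoreSet, apply_zscores, fit_zscores

log = logging.getLogger("pupscales")


@dataclass
class PipelineConfig:
    """Tunables for every stage; defaults follow the development study
    (salience 0.40, alpha floor 0.70, alpha-gain 0.05, p < 0.05 item
    screen, temporal criterion 0.30, construct criterion 0.40, test-PCA
    salience 0.50, KMO floor 0.6)."""

    n_dogs: int = 1401
    seed: int = 0
    salience: float = 0.40
    alpha_floor: float = 0.70
    gain_threshold: float = 0.05
    screen_alpha: float = 0.05
    min_support: int = 5
    min_group: int = 10
    temporal_criterion: float = 0.30
    construct_criterion: float = 0.40
    concurrent_alpha: float = 0.05
    kmo_floor: float = 0.6
    test_salience: float = 0.50
    age_policy: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_AGE_POLICY.items()})

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


# ---- serialization helpers -------------------------------------------------

def scales_to_json(scales: list[ScaleDefinition], path) -> None:
    payload = [
        {
            "name": s.name,
            "items": s.items,
            "direction": s.direction,
            "alpha_by_age": {a: float(v) for a, v in s.alpha_by_age.items()},
            "provenance": s.provenance,
        }
        for s in scales
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def scales_from_json(path) -> list[ScaleDefinition]:
    return [ScaleDefinition(**d) for d in json.loads(Path(path).read_text())]


def thresholds_to_json(thresholds: list[FlagThreshold], path) -> None:
    Path(path).write_text(json.dumps([vars(t) for t in thresholds], indent=1))


def thresholds_from_json(path) -> list[FlagThreshold]:
    return [FlagThreshold(**d) for d in json.loads(Path(path).read_text())]


def zset_to_json(zset: ZScoreSet, path) -> None:
    payload = {
        "scheme": zset.scheme,
        "min_group": zset.min_group,
        "reference": zset.reference.to_dict(orient="list"),
        "fallbacks": {
            k: (v.to_dict(orient="list") if v is not None else None)
            for k, v in zset.fallbacks.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def zset_from_json(path) -> ZScoreSet:
    d = json.loads(Path(path).read_text())
    return ZScoreSet(
        scheme=d["scheme"],
        reference=pd.DataFrame(d["reference"]),
        z=pd.DataFrame(),
        min_group=d["min_group"],
        fallbacks={
            k: (pd.DataFrame(v) if v is not None else None)
            for k, v in d["fallbacks"].items()
        },
    )


# ---- stages ---------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> Cohort:
    gc = GeneratorConfig(n_dogs=config.n_dogs, seed=config.seed)
    cohort, truth = generate_cohort(gc)
    save_cohort(
        cohort,
        outdir / "registry.csv",
        outdir / "responses.csv",
        outdir / "test_records.csv",
    )
    flat = truth.latents.copy()
    flat.columns = [f"{t}|{a}" for t, a in flat.columns]
    flat.join(truth.p_withdrawn).to_csv(outdir / "truth.csv")
    log.info("simulate: %d dogs, %d responses", cohort.n_dogs, cohort.n_responses)
    return cohort


def stage_build_scales(cohort: Cohort, config: PipelineConfig, outdir: Path) -> list[ScaleDefinition]:
    scales, screen = build_scales(
        cohort,
        list(ALL_ITEMS),
        salience=config.salience,
        gain_threshold=config.gain_threshold,
        alpha_floor=config.alpha_floor,
        screen_alpha=config.screen_alpha,
    )
    scales_to_json(scales, outdir / "scales.json")
    if screen is not None:
        screen.to_csv(outdir / "item_screen.csv", index=False)
    log.info("build-scales: %d accepted scales", len(scales))
    return scales


def stage_score(
    cohort: Cohort, scales: list[ScaleDefinition], config: PipelineConfig, outdir: Path
) -> tuple[pd.DataFrame, dict[str, ZScoreSet]]:
    scores = build_scale_scores(scales, cohort)
    scores.to_csv(outdir / "scale_scores.csv", index=False)
    zsets: dict[str, ZScoreSet] = {}
    for scheme in SCHEMES:
        zs = fit_zscores(scores, cohort.dogs, scheme, min_group=config.min_group)
        zsets[scheme] = zs
        zs.z.to_csv(outdir / f"zscores_{scheme}.csv", index=False)
        zset_to_json(zs, outdir / f"reference_{scheme}.json")
    log.info("score: %d scale-score rows", len(scores))
    return scores, zsets


def stage_flags(
    cohort: Cohort,
    scores: pd.DataFrame,
    zsets: dict[str, ZScoreSet],
    config: PipelineConfig,
    outdir: Path,
) -> dict:
    dev = filter_by_outcome(cohort, {"qualified", "withdrawn_behaviour"})
    outcomes = dev.outcome_of()
    z_dev = {s: zs.z[zs.z["dog_id"].isin(outcomes.index)] for s, zs in zsets.items()}
    thresholds = fit_thresholds(z_dev, outcomes, min_support=config.min_support)
    thresholds_to_json(thresholds, outdir / "thresholds.json")

    # apply to the evaluation cohort (all outcomes except transfer/death)
    eval_cohort = filter_by_outcome(
        cohort,
        {"qualified", "withdrawn_behaviour", "withdrawn_health",
         "withdrawn_health_behaviour", "breeding"},
    )
    eval_scores = scores[scores["dog_id"].isin(set(eval_cohort.dogs["dog_id"]))]
    z_eval = {
        s: fit_zscores(eval_scores, eval_cohort.dogs, s, min_group=config.min_group).z
        for s in SCHEMES
    }
    age_policy = {k: tuple(v) for k, v in config.age_policy.items()}
    assignments = assign_flags(z_eval, thresholds, age_policy)
    assignments.to_csv(outdir / "flag_assignments.csv", index=False)
    evaluation = evaluate_flags(assignments, eval_cohort)
    evaluation.to_csv(outdir / "flag_evaluation.csv", index=False)
    pw_weeks, tr_weeks = weeks_saved(assignments, eval_cohort)
    log.info(
        "flags: %d assignments; %.0f puppy-walking / %.0f training weeks savable",
        len(assignments), pw_weeks, tr_weeks,
    )
    return {
        "thresholds": thresholds,
        "assignments": assignments,
        "evaluation": evaluation,
        "weeks_saved": {"puppy_walking": pw_weeks, "formal_training": tr_weeks},
    }


def stage_validate(
    cohort: Cohort, scores: pd.DataFrame, config: PipelineConfig, outdir: Path
) -> dict:
    consistency = temporal_consistency(scores, criterion=config.temporal_criterion)
    consistency.to_csv(outdir / "temporal_consistency.csv", index=False)
    means = mean_temporal_rho(consistency)

    s12 = scores[scores["age_point"] == "12M"]
    have = set(s12["scale"].unique())
    hyps = [
        h for h in DEFAULT_CONSTRUCT_HYPOTHESES
        if h.scale in have and h.counterpart in have
    ]
    matrix, verdicts = construct_matrix(s12, hyps, criterion=config.construct_criterion)
    matrix.to_csv(outdir / "construct_matrix.csv")
    verdicts.to_csv(outdir / "construct_verdicts.csv", index=False)

    dev = filter_by_outcome(cohort, {"qualified", "withdrawn_behaviour"})
    regressions = regression_table(scores, dev)
    regressions.to_csv(outdir / "predictive_regressions.csv", index=False)

    concurrent = pd.DataFrame()
    if cohort.test_records is not None and len(cohort.test_records):
        kinds = {m: k for m, (k, _, _) in MEASURE_TABLE.items()}
        frames = []
        for age in ("5M", "8M"):
            meas = cohort.test_records[cohort.test_records["age_point"] == age]
            s_age = scores[scores["age_point"] == age]
            hyps_c = [
                h for h in DEFAULT_CONCURRENT_HYPOTHESES
                if h.scale in set(s_age["scale"])
            ]
            res = association_tests(
                hyps_c, meas, s_age, kinds, alpha=config.concurrent_alpha
            )
            res.insert(0, "age_point", age)
            frames.append(res)
        concurrent = pd.concat(frames, ignore_index=True)
        concurrent.to_csv(outdir / "concurrent_associations.csv", index=False)
    log.info(
        "validate: mean temporal rho %s; %d/%d construct hypotheses accepted",
        {k: round(v, 2) for k, v in means.items()},
        int(verdicts["accepted"].sum()) if len(verdicts) else 0,
        len(verdicts),
    )
    return {
        "temporal": consistency,
        "mean_temporal_rho": means,
        "construct_matrix": matrix,
        "construct_verdicts": verdicts,
        "regressions": regressions,
        "concurrent": concurrent,
    }


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage in order, persisting outputs and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True)
    manifest = {
        "pupscales_version": __version__,
        "seed": config.seed,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }
    cohort = stage_simulate(config, outdir)
    scales = stage_build_scales(cohort, config, outdir)
    if not scales:
        log.warning("no scales accepted; downstream outputs will be empty")
        for name in ("scale_scores.csv", "flag_assignments.csv"):
            pd.DataFrame().to_csv(outdir / name, index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return {"cohort": cohort, "scales": [], "manifest": manifest}
    scores, zsets = stage_score(cohort, scales, config, outdir)
    flags_out = stage_flags(cohort, scores, zsets, config, outdir)
    validity_out = stage_validate(cohort, scores, config, outdir)
    manifest["n_scales"] = len(scales)
    manifest["n_flag_assignments"] = len(flags_out["assignments"])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "cohort": cohort,
        "scales": scales,
        "scores": scores,
        "zsets": zsets,
        **flags_out,
        **validity_out,
        "manifest": manifest,
    }
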