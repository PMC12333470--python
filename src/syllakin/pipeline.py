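"""End-to-end experiment driver: simulate -> preprocess -> segment -> compare.

``run_experiment`` reproduces a control-vs-lesion(-vs-treatment) analysis
from a single :class:`~syllakin.config.ExperimentConfig`: cohorts are
simulated with condition transforms, preprocessed and (optionally) segmented
with the kappa-scanned AR-HMM, per-animal metrics are computed, and group
statistics (per-syllable KW + BH, Mann-Whitney on session velocity,
entropy/transition-frequency summaries, delta-metric regressions) are
assembled into a results bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from syllakin import metrics as mx
from syllakin import stats as st
from syllakin.config import ExperimentConfig
from syllakin.preprocess import egocentric_align, fit_pca, gate_and_interpolate, transform_pca
from syllakin.segmentation import ARHMMHyper, SyllableSequence, decode, kappa_scan
from syllakin.synthetic import (
    ConditionTransform,
    apply_condition,
    build_repertoire,
    build_transition_model,
    calibrate_noise,
    lesion_transform,
    simulate_session,
    treatment_transform,
)

logger = logging.getLogger(__name__)

__all__ = ["AnimalRecord", "ExperimentResult", "simulate_cohorts", "run_experiment"]


@dataclass
class AnimalRecord:
    cohort: str
    animal_id: str
    recording: object
    truth: object
    pose: object = None
    sequence: SyllableSequence = None
    velocity: dict = None
    usage: dict = None
    session_velocity: float = None
    transition_summary: object = None


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    animals: list
    retained_alphabet: list
    stats_by_group: dict  # group -> per-syllable DataFrame
    velocity_comparison: pd.DataFrame
    usage_comparison: pd.DataFrame
    session_table: pd.DataFrame  # per-animal scalar metrics
    scalar_tests: pd.DataFrame  # pairwise Mann-Whitney on scalar metrics
    delta_regressions: dict  # other group -> regression dict
    model: object = None
    scan_table: pd.DataFrame = None


def _condition_transform(spec, repertoire) -> ConditionTransform:
    if spec.condition == "control":
        return ConditionTransform()
    lesion = lesion_transform(repertoire, severity=spec.severity)
    if spec.condition == "lesion":
        return lesion
    return treatment_transform(lesion)


def simulate_cohorts(config: ExperimentConfig):
    """Simulate every animal of every cohort; returns list of AnimalRecord."""
    config.validate()
    repertoire = build_repertoire(config.n_syllables, config.speed_range, seed=config.seed)
    transitions = build_transition_model(
        config.n_syllables, config.target_mean_duration_s, config.fps, seed=config.seed
    )
    jitter = calibrate_noise(config.baseline_speed, config.fps)
    animals = []
    session_seed = config.seed * 100003 + 17
    for name, spec in config.cohorts.items():
        rep_c, trans_c = apply_condition(repertoire, transitions, _condition_transform(spec, repertoire))
        for i in range(spec.n_animals):
            rec, truth = simulate_session(
                rep_c,
                trans_c,
                duration=config.session_duration_s,
                fps=config.fps,
                jitter_sd=jitter,
                seed=session_seed,
                arena_size=config.arena_size,
            )
            animals.append(AnimalRecord(cohort=name, animal_id=f"{name}_{i}", recording=rec, truth=truth))
            session_seed += 1
    return animals


def _segment(config: ExperimentConfig, animals):
    """Fill each animal's pose series and syllable sequence; returns (model, scan_table)."""
    for a in animals:
        gated = gate_and_interpolate(a.recording, config.likelihood_threshold)
        a.pose = egocentric_align(gated)
    if config.labels_source == "ground_truth":
        for a in animals:
            a.sequence = SyllableSequence(labels=a.truth.labels, fps=config.fps, session_id=a.animal_id)
        return None, None
    pca = fit_pca([a.pose for a in animals], n_components=config.n_pcs)
    latents = [transform_pca(pca, a.pose) for a in animals]
    hyper = ARHMMHyper(
        alpha=config.alpha,
        gamma=config.gamma,
        K_max=config.K_max,
        ar_order=config.ar_order,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        seed=config.seed,
    )
    scan = kappa_scan(latents, hyper, list(config.kappa_grid),
                      target_duration_ms=config.target_duration_ms, fps=config.fps)
    logger.info("kappa scan selected kappa=%g", scan.kappa)
    for a, latent in zip(animals, latents):
        a.sequence = decode(scan.model, latent, fps=config.fps, session_id=a.animal_id)
    return scan.model, scan.table


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentResult:
    """Run the full pipeline; optionally write tables under ``out_dir``."""
    stage = "simulate"
    try:
        animals = simulate_cohorts(config)
        stage = "segment"
        model, scan_table = _segment(config, animals)
        stage = "metrics"
        for a in animals:
            speeds = mx.centroid_speed_series(a.pose.centroid_track, config.fps)
            a.velocity = mx.syllable_velocity(speeds, a.sequence)
            a.usage = mx.usage(a.sequence)
            a.session_velocity = mx.session_velocity(a.pose.centroid_track, config.fps)

        pooled = np.concatenate([a.sequence.labels for a in animals])
        pooled_usage = mx.usage(pooled)
        retained = mx.filter_expressed(pooled_usage, config.usage_threshold)
        # entropy alphabet = every syllable the model emits (not the filter)
        full_alphabet = sorted(pooled_usage)
        for a in animals:
            a.transition_summary = mx.summarize_transitions(
                a.sequence, full_alphabet, fps=config.fps,
                log_base=config.entropy_base, entropy_mode=config.entropy_mode,
            )

        stage = "stats"
        groups = list(config.cohorts)
        by_group = {g: [a for a in animals if a.cohort == g] for g in groups}
        stats_by_group = {
            g: mx.group_syllable_stats([{"velocity": a.velocity, "usage": a.usage} for a in members])
            for g, members in by_group.items()
        }

        def metric_samples(extract):
            out = {}
            for g, members in by_group.items():
                per_syll = {}
                for s in retained:
                    vals = [extract(a).get(s) for a in members]
                    vals = [v for v in vals if v is not None]
                    if len(vals) >= 2:
                        per_syll[s] = np.asarray(vals)
                out[g] = per_syll
            return out

        velocity_cmp = usage_cmp = None
        if len(groups) >= 2:
            velocity_cmp = st.compare_metric_across_groups(
                metric_samples(lambda a: a.velocity), q=config.fdr_q)
            usage_cmp = st.compare_metric_across_groups(
                metric_samples(lambda a: {s: a.usage.get(s, 0.0) for s in retained}), q=config.fdr_q)

        session_table = pd.DataFrame([
            {
                "cohort": a.cohort,
                "animal": a.animal_id,
                "session_velocity": a.session_velocity,
                "entropy": a.transition_summary.entropy_,
                "transition_frequency": a.transition_summary.transition_frequency_,
                "mean_duration_ms": 1000.0 * a.sequence.n_frames /
                                    (config.fps * max(len(mx.run_length_encode(a.sequence.labels)[0]), 1)),
            }
            for a in animals
        ])
        scalar_rows = []
        for metric in ("session_velocity", "entropy", "transition_frequency"):
            for i, g1 in enumerate(groups):
                for g2 in groups[i + 1:]:
                    u, p = st.mann_whitney(
                        session_table.loc[session_table.cohort == g1, metric],
                        session_table.loc[session_table.cohort == g2, metric],
                    )
                    scalar_rows.append({"metric": metric, "group_a": g1, "group_b": g2, "U": u, "p": p})
        scalar_tests = pd.DataFrame(scalar_rows)

        delta_regressions = {}
        control = groups[0]
        for other in groups[1:]:
            table = mx.delta_table(stats_by_group[control].loc[
                                       stats_by_group[control].index.intersection(retained)],
                                   stats_by_group[other])
            if len(table) >= 3:
                sv, iv, r2v, pv = st.ols_regression(table["control_velocity"], table["delta_velocity"])
                su, iu, r2u, pu = st.ols_regression(table["control_velocity"], table["delta_usage"])
                delta_regressions[other] = {
                    "velocity": {"slope": sv, "intercept": iv, "r2": r2v, "p": pv},
                    "usage": {"slope": su, "intercept": iu, "r2": r2u, "p": pu},
                }
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc

    result = ExperimentResult(
        config=config,
        animals=animals,
        retained_alphabet=retained,
        stats_by_group=stats_by_group,
        velocity_comparison=velocity_cmp,
        usage_comparison=usage_cmp,
        session_table=session_table,
        scalar_tests=scalar_tests,
        delta_regressions=delta_regressions,
        model=model,
        scan_table=scan_table,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: ExperimentResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    from syllakin.io import save_model, write_labels_csv

    result.config.to_yaml(out_dir / "config.yaml")
    for g, table in result.stats_by_group.items():
        table.to_csv(out_dir / f"syllable_stats_{g}.csv")
    if result.velocity_comparison is not None:
        result.velocity_comparison.to_csv(out_dir / "comparison_velocity.csv")
        result.usage_comparison.to_csv(out_dir / "comparison_usage.csv")
    result.session_table.to_csv(out_dir / "session_metrics.csv", index=False)
    result.scalar_tests.to_csv(out_dir / "scalar_tests.csv", index=False)
    with open(out_dir / "delta_regressions.json", "w") as f:
        json.dump(result.delta_regressions, f, indent=1)
    write_labels_csv([a.sequence for a in result.animals], out_dir / "labels.csv")
    for a in result.animals:
        summary = a.transition_summary
        pd.DataFrame(summary.A, index=summary.alphabet, columns=summary.alphabet).to_csv(
            out_dir / f"transition_matrix_{a.animal_id}.csv")
    if result.model is not None:
        save_model(result.model, out_dir / "model.json", out_dir / "model.h5")
        result.scan_table.to_csv(out_dir / "kappa_scan.csv", index=False)
    with open(out_dir / "run.json", "w") as f:
        json.dump({"seed": result.config.seed, "retained_alphabet": [int(s) for s in result.retained_alphabet]}, f)
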