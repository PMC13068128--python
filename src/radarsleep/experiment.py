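"""The scratch-vs-transfer staging experiment.

Pipeline: simulate a large reference-modality cohort and pretrain the LSTM
on its feature tables; simulate a small radar cohort (train:test in the
28:8 proportions of the radar study); train one model from random
initialization on the radar training nights and fine-tune a copy of the
pretrained model on the same nights; evaluate both on the identical
held-out radar test nights in the five-class and merged three-class
schemes.  Only the initialization differs between the two radar models —
data, feature schema, training protocol and metric code are shared.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import SimConfig, StagingModelConfig
from .dsp import process_radar_night
from .evaluation import (
    CohortSummary,
    ConfusionMatrix,
    cohort_summary,
    confusion_matrix,
    participant_metrics,
)
from .features import assemble_epoch_table, reference_epoch_table
from .hypnogram import Hypnogram, SCHEME_MERGED3, get_scheme, map_labels
from .simulate import simulate_cohort, simulate_night
from .staging import LSTMSleepStager, fine_tune as _fine_tune, prepare_sequences, train as _train

__all__ = ["ExperimentConfig", "TransferReport", "radar_night_table", "run_transfer_experiment"]


@dataclass
class ExperimentConfig:
    """Problem sizes and components of the transfer experiment.

    The experiment is a scaled-down rendition of the study design: training
    nights of 120 epochs (1 h) instead of full nights, a 100-night reference
    cohort standing in for the large wearable pretraining corpus, and a
    small radar cohort whose train:test split mirrors the radar study's 28:8
    proportions.  Scaling the training nights down keeps the radar cohort in
    the data-scarce regime relative to pretraining (roughly the source:target
    epoch ratio of the full-size study) — the regime in which the
    scratch-vs-transfer comparison is scientifically interesting — and keeps
    the whole experiment at minutes on one CPU.  Held-out test nights are
    longer (480 epochs) purely to tighten the evaluation: more test epochs
    per participant stabilize the pooled per-stage recalls without touching
    the training conditions.
    """

    n_reference: int = 100
    n_radar_train: int = 12
    n_radar_test: int = 6
    night_len_epochs: int = 120
    test_night_len_epochs: int = 480
    n_seeds: int = 3
    sim: SimConfig = field(default_factory=SimConfig)
    model: StagingModelConfig = field(default_factory=lambda: StagingModelConfig(
        max_epochs=150, patience=10))

    def __post_init__(self) -> None:
        if min(self.n_reference, self.n_radar_train, self.n_radar_test) <= 0:
            raise ValueError("cohort sizes must be positive")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


@dataclass
class TransferReport:
    """Side-by-side summaries for every (model, scheme) combination."""

    summaries: dict[tuple[str, str], CohortSummary]
    pooled_cms: dict[tuple[str, str], ConfusionMatrix]
    timings_s: dict[str, float]
    config: ExperimentConfig

    def to_markdown(self) -> str:
        lines = ["# Scratch vs transfer sleep staging", ""]
        lines.append("| model | scheme | accuracy % | F1 % | MCC | precision % | "
                     "recall % | specificity % |")
        lines.append("|---|---|---|---|---|---|---|---|")
        for (model, scheme), s in sorted(self.summaries.items()):
            m, q = s.median, s.iqr
            lines.append(
                f"| {model} | {scheme} | {m['accuracy']:.2f} ({q['accuracy']:.2f}) | "
                f"{m['f1']:.2f} ({q['f1']:.2f}) | {m['mcc']:.2f} ({q['mcc']:.2f}) | "
                f"{m['precision']:.2f} ({q['precision']:.2f}) | "
                f"{m['recall']:.2f} ({q['recall']:.2f}) | "
                f"{m['specificity']:.2f} ({q['specificity']:.2f}) |")
        lines.append("")
        for (model, scheme), cm in sorted(self.pooled_cms.items()):
            lines.append(f"## Pooled confusion matrix — {model}, {scheme} "
                         "(rows true, % row-normalized)")
            pct = cm.row_percentages()
            header = " | ".join(cm.classes)
            lines.append(f"| | {header} |")
            lines.append("|" + "---|" * (len(cm.classes) + 1))
            for i, c in enumerate(cm.classes):
                cells = " | ".join(
                    "--" if not np.isfinite(p) else f"{p:.1f}" for p in pct[i])
                lines.append(f"| **{c}** | {cells} |")
            lines.append("")
        return "\n".join(lines)


def radar_night_table(night, sim: SimConfig) -> pd.DataFrame:
    """Radar front end + feature extraction for one simulated night."""
    movement, beats, breaths = process_radar_night(
        night.radar, saturation_level=0.93 * sim.clip_level)
    return assemble_epoch_table(night.hypnogram, movement, beats, breaths,
                                participant_id=night.participant_id)


def _evaluate(model: LSTMSleepStager, test_tables: list[pd.DataFrame],
              test_hyps: list[Hypnogram],
              ) -> dict[str, tuple[list, list]]:
    """Per-participant metrics/CMs in both schemes from 5-class predictions."""
    out: dict[str, tuple[list, list]] = {"aasm5": ([], []), "merged3": ([], [])}
    for table, hyp in zip(test_tables, test_hyps):
        pred5 = model.predict_series(table).to_hypnogram()
        for scheme_name in ("aasm5", "merged3"):
            if scheme_name == "aasm5":
                t, p = hyp, pred5
            else:
                t, p = map_labels(hyp, SCHEME_MERGED3), map_labels(pred5, SCHEME_MERGED3)
            cm = confusion_matrix(t, p, get_scheme(scheme_name))
            pid = str(table["participant_id"].iloc[0])
            out[scheme_name][0].append(participant_metrics(cm, participant_id=pid))
            out[scheme_name][1].append(cm)
    return out


def run_transfer_experiment(config: ExperimentConfig | None = None,
                            seed: int = 0) -> TransferReport:
    """Run the full scratch-vs-transfer comparison.

    The pretrained model is fit once; the scratch and fine-tuned radar
    models are each trained ``config.n_seeds`` times with different
    training seeds (identical data), and their test metrics are pooled
    across seeds and participants.
    """
    config = config or ExperimentConfig()
    timings: dict[str, float] = {}
    sim = replace(copy.deepcopy(config.sim), night_len_epochs=config.night_len_epochs)

    # --- reference cohort & pretraining ---
    t0 = time.perf_counter()
    ref_cohort = simulate_cohort(sim, config.n_reference, 1, seed)
    ref_tables = []
    for pid in ref_cohort.participants("train"):
        night = ref_cohort.night(pid, modalities=("reference",))
        ref_tables.append(reference_epoch_table(night.hypnogram, night.reference))
    timings["simulate_reference_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pretrained = _train(ref_tables, config.model, seed=seed)
    timings["pretrain_s"] = time.perf_counter() - t0

    # --- radar cohort (longer held-out nights tighten the evaluation) ---
    t0 = time.perf_counter()
    sim_test = replace(copy.deepcopy(config.sim),
                       night_len_epochs=config.test_night_len_epochs)
    radar_cohort = simulate_cohort(sim, config.n_radar_train, config.n_radar_test,
                                   seed + 1)
    train_pids = set(radar_cohort.participants("train"))
    train_tables, test_tables, test_hyps = [], [], []
    for _, row in radar_cohort.manifest.iterrows():
        pid, night_seed = row["participant_id"], int(row["seed"])
        cfg_night = sim if pid in train_pids else sim_test
        night = simulate_night(cfg_night, night_seed, pid, modalities=("radar",))
        table = radar_night_table(night, cfg_night)
        if pid in train_pids:
            train_tables.append(table)
        else:
            test_tables.append(table)
            test_hyps.append(night.hypnogram)
    timings["simulate_radar_s"] = time.perf_counter() - t0

    # --- scratch vs fine-tune across training seeds ---
    results: dict[tuple[str, str], tuple[list, list]] = {}
    t0 = time.perf_counter()
    for k in range(config.n_seeds):
        run_seed = seed + 100 + k
        scratch_cfg = copy.deepcopy(config.model)
        scratch = _train(train_tables, scratch_cfg, seed=run_seed)
        tuned = copy.deepcopy(pretrained)
        tuned = _fine_tune(tuned, train_tables, random_state=run_seed)
        for name, model in (("scratch", scratch), ("transfer", tuned)):
            evals = _evaluate(model, test_tables, test_hyps)
            for scheme_name, (mets, cms) in evals.items():
                key = (name, scheme_name)
                acc = results.setdefault(key, ([], []))
                acc[0].extend(mets)
                acc[1].extend(cms)
    timings["train_eval_s"] = time.perf_counter() - t0

    summaries = {}
    pooled = {}
    for key, (mets, cms) in results.items():
        s = cohort_summary(mets, cms, label=f"{key[0]}/{key[1]}")
        summaries[key] = s
        pooled[key] = s.pooled_cm
    return TransferReport(summaries, pooled, timings, config)
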