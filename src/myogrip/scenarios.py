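"""Reproducible end-to-end benchmark scenarios on synthetic data.

These are the package's self-contained recovery checks: they generate data
with the synthetic session generator, run the full pipeline, and measure
how well the known ground truth is recovered.  Each function is a pure
function of its seed.
"""

from __future__ import annotations

from dataclasses import replace

from myogrip.classify import TrainingConfig, build_model, train
from myogrip.dataio import AnalysisWindow, segment
from myogrip.evaluate import EvaluationReport, PipelineConfig, featurize_windows, kfold_cv
from myogrip.realtime import stream_classify
from myogrip.synthgen import (
    EventSchedule,
    GeneratorConfig,
    ProtocolConfig,
    build_schedule,
    single_task_recording,
    synthesize_recording,
)

__all__ = [
    "task_windows",
    "separable_cv_report",
    "confusion_structure_report",
    "streaming_polarity_fraction",
]


def task_windows(
    n_per_class: int,
    seed: int,
    class2_overlap: float = 0.0,
    window_s: float = 2.0,
    protocol: ProtocolConfig | None = None,
    gen: GeneratorConfig | None = None,
) -> list[AnalysisWindow]:
    """Balanced labeled analysis windows, one per synthetic single-task trial."""
    protocol = protocol or ProtocolConfig()
    gen = gen or GeneratorConfig(class2_overlap=class2_overlap, seed=seed)
    windows = []
    idx = 0
    n_win = int(round(window_s * protocol.sampling_rate))
    for trial in range(n_per_class):
        for cls in protocol.task_classes:
            rec = single_task_recording(
                cls, protocol, replace(gen, seed=seed * 1_000_003 + idx), f"t{trial:02d}"
            )
            windows.append(
                AnalysisWindow(
                    samples=rec.emg[:n_win],
                    sampling_rate=protocol.sampling_rate,
                    duration=window_s,
                    label=cls,
                )
            )
            idx += 1
    return windows


def separable_cv_report(
    seed: int, n_per_class: int = 20, k: int = 10, epochs: int = 300
) -> EvaluationReport:
    """10-fold multiclass CV on the fully separable configuration (overlap 0)."""
    windows = task_windows(n_per_class, seed, class2_overlap=0.0)
    pipeline = PipelineConfig(training=TrainingConfig(epochs=epochs, seed=seed))
    return kfold_cv(windows, k=k, pipeline=pipeline, seed=seed)


def confusion_structure_report(
    seed: int, n_per_class: int = 20, k: int = 10, epochs: int = 300,
    class2_overlap: float = 0.8,
) -> EvaluationReport:
    """CV at high class-2 overlap, where the fist class becomes the hardest."""
    windows = task_windows(n_per_class, seed, class2_overlap=class2_overlap)
    pipeline = PipelineConfig(training=TrainingConfig(epochs=epochs, seed=seed))
    return kfold_cv(windows, k=k, pipeline=pipeline, seed=seed)


def streaming_polarity_fraction(
    seed: int, n_alternations: int = 10, reps_train: int = 40, epochs: int = 300,
    threshold: float = 0.70,
) -> float:
    """End-to-end close/open recovery on an alternating flexion/extension stream.

    A two-class (wrist flexion / wrist extension) model is trained on windows
    from the same generator configuration, then an alternating stream of
    back-to-back 2 s bursts is classified and confidence-gated.  Returns the
    fraction of decision steps whose emitted command has the correct polarity
    (+20 deg gripper close for flexion, -20 deg open for extension); gated
    steps count as incorrect.
    """
    protocol = ProtocolConfig(
        task_duration=2.0, rest_duration=0.0, task_classes=(1, 3),
        repetitions_per_task=reps_train,
    )
    gen = GeneratorConfig(seed=seed, amplitude_jitter=0.1)

    sched = build_schedule(protocol, seed=seed)
    train_rec = synthesize_recording(sched, protocol, replace(gen, seed=seed * 31 + 1), tail=0.0)
    windows = segment(train_rec, sched, 2.0)
    data = featurize_windows(windows, PipelineConfig())
    model = build_model(data.X.shape[1], data.classes, seed=seed)
    train(model, data, TrainingConfig(epochs=epochs, seed=seed, splits=(1.0, 0.0, 0.0)),
          presplit=True)

    classes = [1, 3] * n_alternations
    events = tuple((c, i * 2.0, i * 2.0 + 2.0) for i, c in enumerate(classes))
    stream_rec = synthesize_recording(
        EventSchedule(events), protocol, replace(gen, seed=seed * 77 + 5), tail=0.0
    )
    steps = stream_classify(stream_rec.emg, model, threshold=threshold)
    correct = 0
    for step, true_cls in zip(steps, classes):
        want = +20.0 if true_cls == 1 else -20.0
        if step.command is not None and step.command.target == "gripper" \
                and step.command.delta_angle == want:
            correct += 1
    return correct / len(steps)
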