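"""End-to-end glue: recordings -> preprocessing -> features -> CV.

Two operating modes mirror the two ways the discriminant protocol can be
run:

* **epoch mode** — every preprocessed recording is cut into
  non-overlapping 2-s epochs and each epoch is one row of the feature
  matrix (10 rows per 20-s subject recording);
* **subject mode** — the whole preprocessed 20-s signal is one row per
  subject, with Welch windows widened to 2 s for a finer frequency grid.

Feature families can be restricted (``families``) and the multiscale
entropy scales trimmed, which is how large simulation studies keep the
cost of the quadratic-time entropies proportionate.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

from .cohort import EEGRecording
from .connectivity import connectivity_feature_table
from .discrimination import CVResult, run_cv
from .features import FeatureMatrix, assemble_features
from .nonlinear import DEFAULT_SCALES, nonlinear_feature_table
from .preprocessing import Epoch, PreprocessConfig, preprocess, segment_epochs
from .spectral import spectral_feature_table

__all__ = ["extract_features", "epoch_mode_run", "subject_mode_run"]

FAMILIES = ("spectral", "nonlinear", "connectivity")


def _whole_signal_epoch(recording: EEGRecording) -> Epoch:
    return Epoch(
        subject_id=recording.subject_id,
        group=recording.group,
        epoch_index=0,
        channel_names=recording.channel_names,
        fs=recording.fs,
        data=recording.data,
    )


def extract_features(
    recordings: Iterable[EEGRecording],
    config: PreprocessConfig = PreprocessConfig(),
    mode: str = "epoch",
    families: Sequence[str] = FAMILIES,
    scales: Sequence[int] = DEFAULT_SCALES,
    nonlinear_features: Sequence[str] = ("pe", "ae", "se", "lz", "hurst", "mdcpsr"),
) -> FeatureMatrix:
    """Preprocess recordings and build the labelled feature matrix.

    In epoch mode, Welch windows are 1 s; in subject mode the whole
    signal is one row and windows are 2 s.
    """
    if mode not in ("epoch", "subject"):
        raise ValueError("mode must be 'epoch' or 'subject'")
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown feature families: {sorted(unknown)}")
    if not families:
        raise ValueError("at least one feature family required")

    epochs: List[Epoch] = []
    group_of: Dict[str, str] = {}
    for rec in recordings:
        clean = preprocess(rec, config)
        group_of[rec.subject_id] = rec.group
        if mode == "epoch":
            epochs.extend(segment_epochs(clean, config))
        else:
            epochs.append(_whole_signal_epoch(clean))
    if not epochs:
        raise ValueError("no epochs produced")

    window_seconds = 1.0 if mode == "epoch" else 2.0
    tables = []
    if "spectral" in families:
        tables.append(spectral_feature_table(epochs, window_seconds=window_seconds))
    if "nonlinear" in families:
        tables.append(nonlinear_feature_table(
            epochs, scales=scales, features=nonlinear_features
        ))
    if "connectivity" in families:
        tables.append(connectivity_feature_table(
            epochs, window_seconds=window_seconds
        ))
    return assemble_features(tables, group_of)


def epoch_mode_run(
    recordings: Iterable[EEGRecording],
    config: PreprocessConfig = PreprocessConfig(),
    classifiers=("KNN",),
    k: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    families: Sequence[str] = FAMILIES,
    scales: Sequence[int] = DEFAULT_SCALES,
) -> CVResult:
    """Epoch-based discriminant run: 2-s epochs as rows, subject-level CV."""
    matrix = extract_features(recordings, config, mode="epoch",
                              families=families, scales=scales)
    return run_cv(matrix, classifiers=classifiers, alpha=alpha, k=k, seed=seed)


def subject_mode_run(
    recordings: Iterable[EEGRecording],
    config: PreprocessConfig = PreprocessConfig(),
    classifiers=("KNN",),
    k: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    families: Sequence[str] = FAMILIES,
    scales: Sequence[int] = DEFAULT_SCALES,
) -> CVResult:
    """Subject-based run: one whole-signal feature vector per subject."""
    matrix = extract_features(recordings, config, mode="subject",
                              families=families, scales=scales)
    return run_cv(matrix, classifiers=classifiers, alpha=alpha, k=k, seed=seed)
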