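"""Epoched multichannel recordings and local-global trial bookkeeping.

The central container is :class:`EpochsSet`: a ``trials x channels x samples``
array of field amplitudes with a time axis (seconds, 0 = onset of the
critical stimulus) and one :class:`TrialLabel` per trial.  Labels encode the
2x2 local/global oddball design: each five-sound trial is a *local*
standard or deviant (fifth sound identical to or different from the first
four) and a *global* standard or deviant (frequent or rare sequence within
its block).  Habituation trials and trials immediately following a global
deviant are flagged ``analyzed=False`` and dropped from every contrast.

Containers are stored as a ``.npy`` array (little-endian float64) plus a
JSON sidecar holding times, sampling rate, labels and channel ids, so they
round-trip bit-exactly and stay readable from any platform or language with
an npy/JSON reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

LocalClass = Literal["standard", "deviant"]

#: subclass name implied by the (local_class, global_class) pair
SUBCLASS_FROM_PAIR = {
    ("standard", "standard"): "LSGS",
    ("deviant", "standard"): "LDGS",
    ("standard", "deviant"): "LSGD",
    ("deviant", "deviant"): "LDGD",
}


@dataclass(frozen=True)
class TrialLabel:
    """Condition bookkeeping for one five-sound trial.

    ``subclass`` is redundant with ``(local_class, global_class)`` and is
    validated against it; ``analyzed`` is False for habituation trials and
    for trials immediately following a global deviant.
    """

    local_class: str
    global_class: str
    subclass: str
    block_id: int
    block_type: int
    analyzed: bool = True

    def __post_init__(self) -> None:
        if self.local_class not in ("standard", "deviant"):
            raise ValueError(f"invalid local_class {self.local_class!r}")
        if self.global_class not in ("standard", "deviant"):
            raise ValueError(f"invalid global_class {self.global_class!r}")
        expected = SUBCLASS_FROM_PAIR[(self.local_class, self.global_class)]
        if self.subclass != expected:
            raise ValueError(
                f"subclass {self.subclass!r} inconsistent with "
                f"(local={self.local_class}, global={self.global_class}); "
                f"expected {expected!r}"
            )
        if self.block_type not in (1, 2):
            raise ValueError(f"block_type must be 1 or 2, got {self.block_type}")

    @classmethod
    def from_classes(
        cls,
        local_class: str,
        global_class: str,
        block_id: int = 0,
        block_type: int = 1,
        analyzed: bool = True,
    ) -> "TrialLabel":
        return cls(
            local_class=local_class,
            global_class=global_class,
            subclass=SUBCLASS_FROM_PAIR[(local_class, global_class)],
            block_id=block_id,
            block_type=block_type,
            analyzed=analyzed,
        )

    def to_dict(self) -> dict:
        return {
            "local_class": self.local_class,
            "global_class": self.global_class,
            "subclass": self.subclass,
            "block_id": self.block_id,
            "block_type": self.block_type,
            "analyzed": self.analyzed,
        }


@dataclass
class EpochsSet:
    """Epoched recordings: ``data[trial, channel, sample]`` plus metadata.

    Parameters
    ----------
    data
        Field amplitudes, shape ``(n_trials, n_channels, n_samples)``.
    times
        Sample times in seconds relative to the critical-stimulus onset;
        evenly spaced at ``1 / sample_rate``.
    sample_rate
        Sampling rate in Hz.
    labels
        One :class:`TrialLabel` per trial.
    """

    data: np.ndarray
    times: np.ndarray
    sample_rate: float
    labels: list[TrialLabel]
    subject_id: str = ""
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        n_trials, n_channels, n_samples = self.data.shape
        if self.times.shape != (n_samples,):
            raise ValueError(
                f"times length {self.times.size} != n_samples {n_samples}"
            )
        steps = np.diff(self.times)
        if n_samples > 1 and not np.allclose(steps, 1.0 / self.sample_rate, rtol=1e-6, atol=1e-9):
            raise ValueError("times not evenly spaced at 1/sample_rate")
        if len(self.labels) != n_trials:
            raise ValueError(
                f"label/trial count mismatch: {len(self.labels)} labels, "
                f"{n_trials} trials"
            )
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:03d}" for i in range(n_channels)]
        if len(self.channel_ids) != n_channels:
            raise ValueError("channel_ids length != n_channels")
        if np.isnan(self.data).any():
            raise ValueError("data contains NaN values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def labels_frame(self) -> pd.DataFrame:
        """Per-trial labels as a DataFrame (CSV-exportable)."""
        return pd.DataFrame([lab.to_dict() for lab in self.labels])


@dataclass
class ContrastSpec:
    """A binary decoding contrast over the analyzed trials of an EpochsSet.

    ``y`` is -1 for standard and +1 for deviant (of the chosen contrast);
    ``subclass`` is kept per trial for stratification and sample weighting.
    ``trial_indices`` index into the parent EpochsSet.
    """

    name: str
    trial_indices: np.ndarray
    y: np.ndarray
    subclass: np.ndarray

    def __post_init__(self) -> None:
        self.trial_indices = np.asarray(self.trial_indices, dtype=np.intp)
        self.y = np.asarray(self.y, dtype=np.int8)
        self.subclass = np.asarray(self.subclass, dtype=object)
        if not (len(self.trial_indices) == len(self.y) == len(self.subclass)):
            raise ValueError("trial_indices, y and subclass must align")
        if not np.isin(self.y, (-1, 1)).all():
            raise ValueError("y must be in {-1, +1}")

    @property
    def n_trials(self) -> int:
        return len(self.y)


def make_contrast(epochs: EpochsSet, name: str) -> ContrastSpec:
    """Build the local or global contrast from an EpochsSet.

    Only ``analyzed`` trials are included.  For the local contrast, y follows
    ``local_class`` (deviant = +1); for the global contrast, ``global_class``.
    Both contrasts therefore select the identical trial set and differ only
    in the class assignment, which keeps them balanced across blocks.
    """
    if name not in ("local", "global"):
        raise ValueError(f"contrast name must be 'local' or 'global', got {name!r}")
    attr = "local_class" if name == "local" else "global_class"
    idx = np.array(
        [i for i, lab in enumerate(epochs.labels) if lab.analyzed], dtype=np.intp
    )
    if idx.size == 0:
        raise ValueError("no analyzed trials in epochs")
    y = np.array(
        [1 if getattr(epochs.labels[i], attr) == "deviant" else -1 for i in idx],
        dtype=np.int8,
    )
    for cls, sign in (("standard", -1), ("deviant", 1)):
        if not (y == sign).any():
            raise ValueError(f"contrast {name!r}: no analyzed {cls} trials")
    subclass = np.array([epochs.labels[i].subclass for i in idx], dtype=object)
    return ContrastSpec(name=name, trial_indices=idx, y=y, subclass=subclass)


def baseline_correct(
    epochs: EpochsSet, window: tuple[float, float]
) -> EpochsSet:
    """Subtract the per-trial per-channel mean over a baseline window.

    The window is half-open ``[t_start, t_end)`` in seconds.  The correction
    is a constant shift per trial and channel, so it is idempotent and linear.
    """
    t_start, t_end = window
    if t_start >= t_end:
        raise ValueError("baseline window requires t_start < t_end")
    times = epochs.times
    if t_start < times[0] - 0.5 / epochs.sample_rate or t_end > times[-1] + 1.5 / epochs.sample_rate:
        raise ValueError(
            f"baseline window [{t_start}, {t_end}) outside recorded range "
            f"[{times[0]}, {times[-1]}]"
        )
    mask = (times >= t_start) & (times < t_end)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    corrected = epochs.data - epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochsSet(
        data=corrected,
        times=epochs.times.copy(),
        sample_rate=epochs.sample_rate,
        labels=list(epochs.labels),
        subject_id=epochs.subject_id,
        channel_ids=list(epochs.channel_ids),
    )


# ---------------------------------------------------------------------------
# container I/O: <stem>.npy (little-endian float64) + <stem>.json sidecar

_SIDECAR_VERSION = 1


def _stem(path: str | Path) -> Path:
    path = Path(path)
    if path.suffix in (".npy", ".json"):
        path = path.with_suffix("")
    return path


def save_epochs(epochs: EpochsSet, path: str | Path) -> Path:
    """Write an EpochsSet as ``<path>.npy`` + ``<path>.json``.

    The array is stored as little-endian float64 so the byte layout is
    platform independent; the sidecar carries every other field.
    """
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.save(stem.with_suffix(".npy"), epochs.data.astype("<f8"))
    sidecar = {
        "format_version": _SIDECAR_VERSION,
        "subject_id": epochs.subject_id,
        "sample_rate": epochs.sample_rate,
        "times": epochs.times.tolist(),
        "channel_ids": list(epochs.channel_ids),
        "labels": [lab.to_dict() for lab in epochs.labels],
    }
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)
    return stem


def load_epochs(path: str | Path) -> EpochsSet:
    """Load an EpochsSet written by :func:`save_epochs`.

    Raises a descriptive error when the sidecar is missing or inconsistent
    with the array (trial count, sample count).
    """
    stem = _stem(path)
    npy = stem.with_suffix(".npy")
    sidecar_path = stem.with_suffix(".json")
    if not npy.exists():
        raise FileNotFoundError(f"missing array file {npy}")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar_path}")
    data = np.load(npy).astype(np.float64, copy=False)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    labels = [TrialLabel(**d) for d in meta["labels"]]
    if data.ndim != 3:
        raise ValueError(f"array in {npy} is not 3-D")
    if len(labels) != data.shape[0]:
        raise ValueError(
            f"label/trial count mismatch: sidecar declares {len(labels)} "
            f"trials, array has {data.shape[0]}"
        )
    times = np.asarray(meta["times"], dtype=np.float64)
    if times.size != data.shape[2]:
        raise ValueError(
            f"times/sample count mismatch: sidecar declares {times.size} "
            f"samples, array has {data.shape[2]}"
        )
    return EpochsSet(
        data=data,
        times=times,
        sample_rate=float(meta["sample_rate"]),
        labels=labels,
        subject_id=meta.get("subject_id", ""),
        channel_ids=list(meta.get("channel_ids", [])),
    )


def export_labels_csv(epochs: EpochsSet, path: str | Path) -> None:
    """Write per-trial labels as CSV."""
    epochs.labels_frame().to_csv(path, index=False)
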