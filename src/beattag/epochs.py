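"""Epoched multichannel EEG-like data: trials x channels x samples in microvolts.

The container the whole analysis operates on. Each trial carries three
labels mirroring the experimental design: beat-strength ``condition``
(strong / weak / non), EEG ``session`` (pre / post training), and
``rhythm_set`` (trained / untrained half of the stimulus set).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import pandas as pd

__all__ = ["EpochedEEG", "LABELS"]

LABELS = ("condition", "session", "rhythm_set")


@dataclass
class EpochedEEG:
    """Equal-length EEG epochs with per-trial design labels.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)``, in microvolts.
    sample_rate
        Sampling frequency in Hz.
    trials
        DataFrame with one row per trial and columns ``condition``,
        ``session``, ``rhythm_set``.
    meta
        Free-form metadata (generator seed, ground truth, ...), JSON-serialisable.
    """

    data: np.ndarray
    sample_rate: float
    trials: pd.DataFrame
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("label table length must equal the trial count")
        missing = [c for c in LABELS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"label table is missing columns {missing}")
        if self.trials[list(LABELS)].isna().any().any():
            raise ValueError("labels must be complete (no missing values)")
        self.trials = self.trials.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def select(self, **labels: str) -> "EpochedEEG":
        """Subset trials by label equality, e.g. ``select(condition="strong")``."""
        mask = np.ones(self.n_trials, dtype=bool)
        for key, value in labels.items():
            if key not in self.trials.columns:
                raise KeyError(f"unknown label {key!r}")
            mask &= (self.trials[key] == value).to_numpy()
        return self.take(np.flatnonzero(mask))

    def take(self, indices: np.ndarray) -> "EpochedEEG":
        """Subset trials by positional index."""
        indices = np.asarray(indices, dtype=int)
        return EpochedEEG(
            data=self.data[indices],
            sample_rate=self.sample_rate,
            trials=self.trials.iloc[indices].reset_index(drop=True),
            meta=dict(self.meta),
        )

    def iter_cells(self) -> Iterator[tuple[dict[str, str], "EpochedEEG"]]:
        """Yield (labels, subset) for each observed condition x session x set cell."""
        for keys, idx in self.trials.groupby(list(LABELS), sort=True).groups.items():
            labels = dict(zip(LABELS, keys))
            yield labels, self.take(np.asarray(idx))

    def save(self, path: str | Path) -> None:
        """Write the dataset as ``<path>.npz`` plus a JSON metadata sidecar."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), data=self.data)
        sidecar = {
            "sample_rate": self.sample_rate,
            "trials": self.trials.to_dict(orient="list"),
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EpochedEEG":
        path = Path(path)
        data = np.load(path.with_suffix(".npz"))["data"]
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            data=data,
            sample_rate=float(sidecar["sample_rate"]),
            trials=pd.DataFrame(sidecar["trials"]),
            meta=sidecar.get("meta", {}),
        )
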