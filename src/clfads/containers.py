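"""Trial-structured spike-count containers and their HDF5 round trip.

A :class:`TrialSet` is the universal input of the package: binned spike
counts shaped (trials, time, channels), plus per-trial metadata (condition
label, acquisition order) and, for synthetic data, the generating latent
state kept for validation.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Any

import h5py
import numpy as np

__all__ = ["TrialSet", "read_trialset", "write_trialset", "TrialSetFormatError"]


class TrialSetFormatError(ValueError):
    """Raised when an HDF5 container does not hold a valid TrialSet."""


@dataclasses.dataclass
class TrialSet:
    """Binned spike counts with per-trial metadata.

    Parameters
    ----------
    spikes
        Integer counts, shape (n_trials, n_bins, n_channels).
    bin_width
        Bin width in seconds.
    condition_label
        Per-trial condition identifier (any 1-D array-like; stored as float
        for numeric labels, bytes for strings).
    acquisition_index
        Per-trial integer giving the order in which trials were collected;
        the axis along which slow non-stationarity unfolds.
    ground_truth_state
        Optional (n_trials, n_bins, state_dim) latent state that generated
        the spikes; kept only for validation of synthetic data.
    trial_info
        Optional per-trial numeric metadata (e.g. true speed factors),
        dict of name -> 1-D array.
    provenance
        JSON-serializable record of how the set was generated.
    """

    spikes: np.ndarray
    bin_width: float
    condition_label: np.ndarray
    acquisition_index: np.ndarray
    ground_truth_state: np.ndarray | None = None
    trial_info: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    provenance: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.spikes = np.asarray(self.spikes)
        if self.spikes.ndim != 3:
            raise TrialSetFormatError(
                f"spikes must be 3-D (trials, time, channels); got shape {self.spikes.shape}")
        if not np.issubdtype(self.spikes.dtype, np.integer):
            if np.any(self.spikes != np.round(self.spikes)) or np.any(self.spikes < 0):
                raise TrialSetFormatError("spike counts must be non-negative integers")
            self.spikes = self.spikes.astype(np.uint32)
        elif np.any(self.spikes < 0):
            raise TrialSetFormatError("spike counts must be non-negative integers")
        self.condition_label = np.asarray(self.condition_label)
        self.acquisition_index = np.asarray(self.acquisition_index, dtype=np.int64)
        n = self.spikes.shape[0]
        if self.condition_label.shape[0] != n or self.acquisition_index.shape[0] != n:
            raise TrialSetFormatError("per-trial metadata length must equal trial count")
        if self.ground_truth_state is not None:
            self.ground_truth_state = np.asarray(self.ground_truth_state, dtype=np.float64)
            if self.ground_truth_state.shape[:2] != self.spikes.shape[:2]:
                raise TrialSetFormatError("ground_truth_state must align with spikes")

    @property
    def n_trials(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[1]

    @property
    def n_channels(self) -> int:
        return self.spikes.shape[2]

    def subset(self, idx) -> "TrialSet":
        """Select trials by index array; metadata follows."""
        idx = np.asarray(idx)
        return TrialSet(
            spikes=self.spikes[idx],
            bin_width=self.bin_width,
            condition_label=self.condition_label[idx],
            acquisition_index=self.acquisition_index[idx],
            ground_truth_state=None if self.ground_truth_state is None
            else self.ground_truth_state[idx],
            trial_info={k: np.asarray(v)[idx] for k, v in self.trial_info.items()},
            provenance=dict(self.provenance),
        )


def write_trialset(trials: TrialSet, path) -> None:
    """Write a TrialSet to an HDF5 file (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=trials.spikes.astype(np.uint32))
        f.create_dataset("bin_width", data=float(trials.bin_width))
        label = trials.condition_label
        if label.dtype.kind in "US":
            label = label.astype(h5py.string_dtype())
        f.create_dataset("condition_label", data=label)
        f.create_dataset("acquisition_index", data=trials.acquisition_index)
        if trials.ground_truth_state is not None:
            f.create_dataset("ground_truth_state", data=trials.ground_truth_state)
        info = f.create_group("trial_info")
        for k, v in trials.trial_info.items():
            info.create_dataset(k, data=np.asarray(v))
        f.create_dataset("provenance",
                         data=json.dumps(trials.provenance, sort_keys=True))


def read_trialset(path) -> TrialSet:
    """Read a TrialSet from HDF5; validates structure and dtypes."""
    with h5py.File(path, "r") as f:
        if "spikes" not in f:
            raise TrialSetFormatError("missing required dataset '/spikes'")
        spikes = f["spikes"][...]
        if not np.issubdtype(spikes.dtype, np.integer):
            raise TrialSetFormatError(
                "'/spikes' must hold integer counts; got dtype "
                f"{spikes.dtype} (counts-must-be-integer)")
        label = f["condition_label"][...]
        if label.dtype.kind in ("O", "S"):
            label = np.array([x.decode() if isinstance(x, bytes) else str(x)
                              for x in label])
        gts = f["ground_truth_state"][...] if "ground_truth_state" in f else None
        trial_info = {}
        if "trial_info" in f:
            for k in f["trial_info"]:
                trial_info[k] = f["trial_info"][k][...]
        prov = json.loads(f["provenance"][()]) if "provenance" in f else {}
        return TrialSet(
            spikes=spikes,
            bin_width=float(f["bin_width"][()]),
            condition_label=label,
            acquisition_index=f["acquisition_index"][...],
            ground_truth_state=gts,
            trial_info=trial_info,
            provenance=prov,
        )
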