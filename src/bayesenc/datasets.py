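"""Stimulus-response dataset container and HDF5 I/O.

A dataset holds single-trial train/validation blocks plus a repeated test
block (the structure of calcium-imaging recordings where test stimuli are
shown several times and evaluation uses repeat means).  Stimuli are
(trials, channels, height, width); responses are (trials, neurons); the
test block is (test stimuli, repeats, neurons).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np


@dataclass
class RepeatBlock:
    """Responses to repeated test stimuli: (stimuli t, repeats r, neurons)."""

    responses: np.ndarray

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 3:
            raise ValueError("repeat block must be (stimuli, repeats, neurons)")

    @property
    def n_repeats(self) -> int:
        return self.responses.shape[1]

    def mean_over_repeats(self) -> np.ndarray:
        return self.responses.mean(axis=1)


@dataclass
class ImageStats:
    """Per-channel mean and std of the training stimuli.

    Generated MEIs are constrained to these statistics.
    """

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.std = np.atleast_1d(np.asarray(self.std, dtype=float))
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std must have matching shapes")
        if np.any(self.std <= 0):
            raise ValueError("std must be positive")

    @classmethod
    def from_stimuli(cls, stimuli) -> "ImageStats":
        s = np.asarray(stimuli, dtype=float)
        return cls(mean=s.mean(axis=(0, 2, 3)), std=s.std(axis=(0, 2, 3)))


@dataclass
class StimulusResponseDataset:
    """Train/validation single-trial data plus a repeated test block."""

    train_stimuli: np.ndarray
    train_responses: np.ndarray
    val_stimuli: np.ndarray
    val_responses: np.ndarray
    test_stimuli: np.ndarray
    test_block: RepeatBlock
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("train_stimuli", "val_stimuli", "test_stimuli"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("train_responses", "val_responses"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not isinstance(self.test_block, RepeatBlock):
            self.test_block = RepeatBlock(self.test_block)
        self.validate()

    # ------------------------------------------------------------ invariants
    def validate(self):
        errors = []
        for sname, rname in (("train_stimuli", "train_responses"),
                             ("val_stimuli", "val_responses")):
            s, r = getattr(self, sname), getattr(self, rname)
            if s.ndim != 4:
                errors.append(f"{sname}: expected 4-D (trials, ch, h, w), got {s.ndim}-D")
            if r.ndim != 2:
                errors.append(f"{rname}: expected 2-D (trials, neurons), got {r.ndim}-D")
            elif s.shape[0] != r.shape[0]:
                errors.append(f"{sname}/{rname}: trial counts differ "
                              f"({s.shape[0]} vs {r.shape[0]})")
            if np.any(r < 0):
                errors.append(f"{rname}: negative responses")
        if self.test_stimuli.shape[0] != self.test_block.responses.shape[0]:
            errors.append("test_stimuli/test_block: stimulus counts differ")
        if self.test_block.responses.shape[2] != self.train_responses.shape[1]:
            errors.append("test_block: neuron count differs from training")
        if np.any(self.test_block.responses < 0):
            errors.append("test_block: negative responses")
        shapes = {self.train_stimuli.shape[1:], self.val_stimuli.shape[1:],
                  self.test_stimuli.shape[1:]}
        if len(shapes) > 1:
            errors.append(f"stimulus shapes differ across splits: {shapes}")
        if errors:
            raise ValueError("dataset validation failed:\n  " + "\n  ".join(errors))

    # ------------------------------------------------------------ properties
    @property
    def n_neurons(self) -> int:
        return self.train_responses.shape[1]

    @property
    def in_channels(self) -> int:
        return self.train_stimuli.shape[1]

    @property
    def input_hw(self) -> tuple:
        return tuple(self.train_stimuli.shape[2:])

    @property
    def image_stats(self) -> ImageStats:
        return ImageStats.from_stimuli(self.train_stimuli)

    def test_means(self) -> np.ndarray:
        return self.test_block.mean_over_repeats()

    # ------------------------------------------------------------------ I/O
    def save(self, path):
        """HDF5 with groups train/validation/test plus a metadata JSON attr."""
        with h5py.File(path, "w") as f:
            tr = f.create_group("train")
            tr.create_dataset("stimuli", data=self.train_stimuli)
            tr.create_dataset("responses", data=self.train_responses)
            va = f.create_group("validation")
            va.create_dataset("stimuli", data=self.val_stimuli)
            va.create_dataset("responses", data=self.val_responses)
            te = f.create_group("test")
            te.create_dataset("stimuli", data=self.test_stimuli)
            te.create_dataset("responses", data=self.test_block.responses)
            f.attrs["metadata"] = json.dumps(self.metadata)

    @classmethod
    def load(cls, path) -> "StimulusResponseDataset":
        with h5py.File(path, "r") as f:
            missing = [g for g in ("train", "validation", "test") if g not in f]
            if missing:
                raise ValueError(
                    f"file {path} is missing group(s) {missing}; expected the "
                    "three-split schema train/validation/test (regenerate or "
                    "convert the file)"
                )
            meta = json.loads(f.attrs.get("metadata", "{}"))
            return cls(
                train_stimuli=f["train/stimuli"][...],
                train_responses=f["train/responses"][...],
                val_stimuli=f["validation/stimuli"][...],
                val_responses=f["validation/responses"][...],
                test_stimuli=f["test/stimuli"][...],
                test_block=RepeatBlock(f["test/responses"][...]),
                metadata=meta,
            )


def load_dataset(path) -> StimulusResponseDataset:
    return StimulusResponseDataset.load(path)


def save_dataset(ds: StimulusResponseDataset, path):
    ds.save(path)
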