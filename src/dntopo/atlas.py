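"""Inter-subject group atlases: per-voxel modal label and probability maps.

Per-subject parcellations sharing one grid and label dictionary are
combined by assigning each voxel the most frequent nonzero label across
subjects (the mode — the standard way of averaging categorical values),
alongside per-label probability maps giving the fraction of subjects
carrying each label at each voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import LabelVolume, ScalarVolume, require_same_grid

__all__ = ["CohortLabels", "modal_atlas", "label_probability_maps"]


@dataclass
class CohortLabels:
    """Per-subject label volumes on one grid with one label dictionary."""

    subject_ids: list[str]
    atlases: list[LabelVolume]

    def __post_init__(self) -> None:
        if len(self.atlases) < 2:
            raise ValueError("need at least 2 subjects")
        if len(self.subject_ids) != len(self.atlases):
            raise ValueError("one subject id per atlas")
        require_same_grid(self.atlases, "subject atlases")
        ref = self.atlases[0].label_names
        for a in self.atlases[1:]:
            if a.label_names != ref:
                raise ValueError("subject atlases must share one label dictionary")

    @property
    def labels_stack(self) -> np.ndarray:
        """(n_subjects, X, Y, Z) stacked label arrays."""
        return np.stack([a.labels for a in self.atlases])

    @property
    def all_labels(self) -> list[int]:
        return sorted(self.atlases[0].label_names)


def modal_atlas(cohort: CohortLabels, min_support: float = 0.0) -> LabelVolume:
    """Per-voxel mode of the nonzero labels across subjects.

    A subject whose voxel is unassigned (0) casts no vote.  Ties go to
    the lowest label.  Voxels where the winning label is carried by
    fewer than ``min_support`` (fraction of *all* subjects), or where no
    subject has a nonzero label, are set to 0.
    """
    if not (0.0 <= min_support <= 1.0):
        raise ValueError("min_support must be in [0, 1]")
    stack = cohort.labels_stack
    n_subjects = stack.shape[0]
    labels = cohort.all_labels
    # votes[k] = number of subjects with label k at each voxel
    votes = np.stack([(stack == k).sum(axis=0) for k in labels])
    best = np.argmax(votes, axis=0)  # ties -> lowest label (labels sorted)
    best_votes = np.take_along_axis(votes, best[None], axis=0)[0]
    out = np.asarray(labels, dtype=np.int32)[best]
    out[best_votes == 0] = 0
    out[best_votes < min_support * n_subjects] = 0
    return LabelVolume(
        grid=cohort.atlases[0].grid,
        labels=out,
        label_names=dict(cohort.atlases[0].label_names),
    )


def label_probability_maps(cohort: CohortLabels) -> dict[int, ScalarVolume]:
    """Fraction of subjects carrying each label at each voxel.

    Per-voxel sums over labels are <= 1, with equality exactly where
    every subject assigns the voxel some nonzero label.
    """
    stack = cohort.labels_stack
    n = stack.shape[0]
    grid = cohort.atlases[0].grid
    return {
        k: ScalarVolume(grid=grid, values=(stack == k).sum(axis=0) / n, units="probability")
        for k in cohort.all_labels
    }
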