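"""Synthetic multi-subject dentate-nucleus cohort with planted ground truth.

Real inputs to the pipeline are per-subject track-density maps (one per
connectivity target) and seven diffusion-metric maps, all masked to the
dentate nuclei (DN).  This module fabricates a cohort with the same
statistical structure so that every downstream stage — winner-takes-all
connectivity parcellation, fuzzy c-means microstructural clustering,
modal group atlases, overlap matrices — can be validated against a known
answer:

* each DN is an ellipsoid of realistic voxel count (~900 voxels at
  1.25 mm isotropic), mirrored across the mid-sagittal plane;
* connectivity truth is a partition into contiguous medio-lateral bands
  with prescribed volume fractions; per-target streamline counts are
  Poisson around a per-parcel rate, with a controllable fraction of each
  voxel's counts leaking to the other targets;
* microstructure truth is a two-band medial/lateral split; the seven
  metrics are Gaussian around per-cluster means (truncated at zero);
* inter-subject variability is injected as i.i.d. label noise on the
  per-subject truth before counts and metrics are simulated.

Default volume fractions and per-parcel streamline totals follow the
across-subject left-DN means reported for healthy young adults
(cerebellar targets: lobules I-VI, Crus I-II, VIIb, VIIIa, VIIIb, IX-X;
thalamic targets: motor, prefrontal, sensory, posterior parietal,
occipital, temporal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import stats as _sps

from .volume import CountMapSet, LabelVolume, ScalarVolume, VoxelGrid, mask_indices

__all__ = [
    "PhantomSpec",
    "SubjectBundle",
    "METRIC_NAMES",
    "CEREBELLAR_TARGETS",
    "THALAMIC_TARGETS",
    "default_grid",
    "make_dn_phantom",
    "combined_phantom",
    "simulate_tdi",
    "simulate_metrics",
    "simulate_cohort",
]

METRIC_NAMES = ("FA", "MD", "AD", "RD", "MK", "AK", "RK")
METRIC_UNITS = {
    "FA": "",
    "MD": "1e-3 mm^2/s",
    "AD": "1e-3 mm^2/s",
    "RD": "1e-3 mm^2/s",
    "MK": "",
    "AK": "",
    "RK": "",
}

CEREBELLAR_TARGETS = ("I-VI", "CrusI-II", "VIIb", "VIIIa", "VIIIb", "IX-X")
THALAMIC_TARGETS = (
    "motor",
    "prefrontal",
    "sensory",
    "posterior_parietal",
    "occipital",
    "temporal",
)

# Across-subject left-DN means: volume fractions of the DN and total
# streamline counts per target (cerebellar / thalamic connectivity).
_DEFAULT_CONN_FRACTIONS = (0.289, 0.395, 0.080, 0.030, 0.042, 0.164)
_DEFAULT_PARCEL_COUNTS = (18_900.0, 38_000.0, 9_200.0, 2_700.0, 2_000.0, 11_800.0)
_DEFAULT_THALAMIC_COUNTS = (330.0, 390.0, 50.0, 60.0, 1.0, 30.0)

# Two planted microstructural profiles over (FA, MD, AD, RD, MK, AK, RK);
# diffusivities in 1e-3 mm^2/s.  Row 0 = lateral cluster (label 1),
# row 1 = medial cluster (label 2).  Per-metric means differ by 4 sd so
# the clusters are well separated but still overlap in single metrics.
_DEFAULT_MICRO_MEANS = (
    (0.32, 0.75, 0.98, 0.64, 1.21, 0.90, 1.55),
    (0.28, 0.81, 1.05, 0.70, 1.16, 0.85, 1.45),
)
_DEFAULT_MICRO_SD = (0.010, 0.015, 0.0175, 0.015, 0.0125, 0.0125, 0.025)


def default_grid(shape: tuple[int, int, int] = (48, 28, 24), voxel_mm: float = 1.25) -> VoxelGrid:
    """Isotropic grid whose world origin sits at the grid centre.

    The x axis crosses the mid-sagittal plane at x = 0, which the
    medial/lateral naming convention downstream relies on.
    """
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_mm
    affine[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return VoxelGrid(shape=shape, affine=affine)


@dataclass
class PhantomSpec:
    """Generative parameters for a synthetic DN cohort.

    The defaults emulate the study conditions: 25 subjects, six
    connectivity targets with the reported left-DN mean volume fractions
    and streamline totals, 10% count leakage between targets, and 20%
    per-voxel label noise across subjects.
    """

    grid: VoxelGrid = field(default_factory=default_grid)
    dn_semi_axes: tuple[float, float, float] = (9.0, 6.0, 8.0)  # mm
    dn_center_offset_mm: float = 13.0  # |world x| of each DN centre
    n_conn_parcels: int = 6
    conn_fractions: tuple[float, ...] = _DEFAULT_CONN_FRACTIONS
    parcel_counts: tuple[float, ...] = _DEFAULT_PARCEL_COUNTS
    thalamic_parcel_counts: tuple[float, ...] = _DEFAULT_THALAMIC_COUNTS
    leakage: float = 0.1
    micro_cluster_means: tuple[tuple[float, ...], ...] = _DEFAULT_MICRO_MEANS
    micro_cluster_sd: tuple[float, ...] = _DEFAULT_MICRO_SD
    micro_lateral_fraction: float = 0.55
    n_subjects: int = 25
    label_noise: float = 0.2
    seed: int = 0
    conn_target_names: tuple[str, ...] = CEREBELLAR_TARGETS
    thalamic_target_names: tuple[str, ...] = THALAMIC_TARGETS

    def __post_init__(self) -> None:
        if abs(sum(self.conn_fractions) - 1.0) > 1e-9:
            raise ValueError("conn_fractions must sum to 1")
        if len(self.conn_fractions) != self.n_conn_parcels:
            raise ValueError("conn_fractions length must equal n_conn_parcels")
        if len(self.parcel_counts) != self.n_conn_parcels:
            raise ValueError("parcel_counts length must equal n_conn_parcels")
        if not (0.0 <= self.leakage < 0.5):
            raise ValueError("leakage must be in [0, 0.5)")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if any(sd <= 0 for sd in self.micro_cluster_sd):
            raise ValueError("micro_cluster_sd must be positive")
        means = np.asarray(self.micro_cluster_means, dtype=float)
        if means.shape[0] < 2:
            raise ValueError("need at least 2 microstructural clusters")
        for a in range(means.shape[0]):
            for b in range(a + 1, means.shape[0]):
                if np.array_equal(means[a], means[b]):
                    raise ValueError("micro_cluster_means rows must be distinct")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass
class SubjectBundle:
    """One synthetic subject: masks, count maps, metrics, and true labels."""

    subject_id: str
    dn_mask_left: LabelVolume
    dn_mask_right: LabelVolume
    tdi_cerebellar: CountMapSet
    tdi_thalamic: CountMapSet
    metrics: dict[str, ScalarVolume]
    truth_conn: LabelVolume
    truth_micro: LabelVolume


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

def make_dn_phantom(
    spec: PhantomSpec, side: str
) -> tuple[LabelVolume, LabelVolume, LabelVolume]:
    """Build one DN ellipsoid with planted connectivity/microstructure truth.

    Returns ``(dn_mask, truth_conn, truth_micro)``.  The connectivity
    truth partitions the mask into ``n_conn_parcels`` contiguous bands
    ordered medial to lateral (band k has volume fraction
    ``conn_fractions[k-1]``); the microstructure truth splits the mask
    into a lateral band (label 1) and a medial band (label 2).  Left and
    right masks are mirror images in world x.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    grid = spec.grid
    semi = np.asarray(spec.dn_semi_axes, dtype=float)
    if np.any(semi < 2.0 * grid.voxel_size):
        raise ValueError("degenerate ellipsoid: each semi-axis must span >= 2 voxels")

    sign = -1.0 if side == "left" else 1.0
    center = np.array([sign * spec.dn_center_offset_mm, 0.0, 0.0])

    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in grid.shape), indexing="ij")
    ijk = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = grid.world_coordinates(ijk)
    inside = (np.sum(((world - center) / semi) ** 2, axis=1) <= 1.0).reshape(grid.shape)
    if not inside.any():
        raise ValueError("ellipsoid does not intersect the grid")

    mask = LabelVolume(
        grid=grid, labels=inside.astype(np.int32), label_names={1: "DN"}
    )
    idx = mask_indices(mask, 1)
    x_world = grid.world_coordinates(idx)[:, 0]
    # Medial-to-lateral ordering = increasing distance from the
    # mid-sagittal plane; lexicographic tiebreak keeps it deterministic.
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], np.abs(x_world)))

    truth_conn = _banded_labels(
        mask, idx, order, np.asarray(spec.conn_fractions),
        {k + 1: name for k, name in enumerate(spec.conn_target_names)},
    )
    micro_fracs = np.array(
        [1.0 - spec.micro_lateral_fraction, spec.micro_lateral_fraction]
    )
    # Medial band first in the ordering -> label 2, lateral band -> label 1.
    truth_micro = _banded_labels(
        mask, idx, order, micro_fracs, {2: "medial", 1: "lateral"},
        band_labels=(2, 1),
    )
    return mask, truth_conn, truth_micro


def _banded_labels(
    mask: LabelVolume,
    idx: np.ndarray,
    order: np.ndarray,
    fractions: np.ndarray,
    label_names: dict[int, str],
    band_labels: tuple[int, ...] | None = None,
) -> LabelVolume:
    """Split ordered mask voxels into bands with the given volume fractions."""
    n = len(order)
    bounds = np.rint(np.cumsum(fractions) * n).astype(int)
    bounds[-1] = n  # guard against rounding drift
    labels = np.zeros(mask.grid.shape, dtype=np.int32)
    start = 0
    if band_labels is None:
        band_labels = tuple(range(1, len(fractions) + 1))
    for lab, stop in zip(band_labels, bounds):
        sel = idx[order[start:stop]]
        labels[sel[:, 0], sel[:, 1], sel[:, 2]] = lab
        start = stop
    return LabelVolume(grid=mask.grid, labels=labels, label_names=label_names)


def combined_phantom(
    spec: PhantomSpec,
) -> tuple[LabelVolume, LabelVolume, LabelVolume, LabelVolume]:
    """Both hemispheres on one grid.

    Returns ``(mask_left, mask_right, truth_conn, truth_micro)`` where the
    truth volumes cover both DNs (same label meanings on either side).
    """
    mask_l, conn_l, micro_l = make_dn_phantom(spec, "left")
    mask_r, conn_r, micro_r = make_dn_phantom(spec, "right")
    if np.any((mask_l.labels > 0) & (mask_r.labels > 0)):
        raise ValueError("left and right DN ellipsoids overlap; widen the grid")
    conn = LabelVolume(
        grid=spec.grid,
        labels=conn_l.labels + conn_r.labels,
        label_names=conn_l.label_names,
    )
    micro = LabelVolume(
        grid=spec.grid,
        labels=micro_l.labels + micro_r.labels,
        label_names=micro_l.label_names,
    )
    return mask_l, mask_r, conn, micro


# ---------------------------------------------------------------------------
# Count and metric simulation
# ---------------------------------------------------------------------------

def simulate_tdi(
    truth_conn: LabelVolume,
    spec: PhantomSpec,
    rng: np.random.Generator,
    parcel_counts: tuple[float, ...] | None = None,
    target_names: tuple[str, ...] | None = None,
) -> CountMapSet:
    """Poisson streamline-count maps consistent with a planted parcellation.

    A voxel of true parcel p receives Poisson counts at rate
    ``lambda_p * (1 - leakage)`` on its own target and
    ``lambda_p * leakage / (n_targets - 1)`` on every other target, where
    ``lambda_p = parcel_counts[p] / n_voxels(p)``; so summed over targets
    the expected total per parcel equals ``parcel_counts[p]`` regardless
    of leakage.  Counts outside the DN are zero.

    ``parcel_counts`` are totals for the parcellation passed in; when a
    truth volume covers a single DN they are per-nucleus totals, which is
    how :func:`simulate_cohort` applies them (one draw per hemisphere).
    """
    if parcel_counts is None:
        parcel_counts = spec.parcel_counts
    if target_names is None:
        target_names = spec.conn_target_names
    n_targets = len(target_names)
    if len(parcel_counts) != n_targets:
        raise ValueError("parcel_counts length must match target_names")
    labels = truth_conn.labels
    if not (labels > 0).any():
        raise ValueError("truth_conn has no labelled voxels")

    lam = np.zeros(n_targets + 1)
    for p in range(1, n_targets + 1):
        n_vox = int(np.count_nonzero(labels == p))
        if n_vox:
            lam[p] = parcel_counts[p - 1] / n_vox

    lam_vox = lam[labels]  # (X, Y, Z) per-voxel own-parcel rate
    counts = np.zeros((n_targets, *truth_conn.grid.shape), dtype=np.int64)
    off_rate = spec.leakage / (n_targets - 1) if n_targets > 1 else 0.0
    for t in range(1, n_targets + 1):
        own = labels == t
        rate = np.where(own, lam_vox * (1.0 - spec.leakage), lam_vox * off_rate)
        rate[labels == 0] = 0.0
        counts[t - 1] = rng.poisson(rate)
    return CountMapSet(
        grid=truth_conn.grid, target_names=list(target_names), counts=counts
    )


def simulate_metrics(
    truth_micro: LabelVolume,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> dict[str, ScalarVolume]:
    """Seven diffusion-metric maps with planted per-cluster means.

    Metric m at a voxel of true cluster k is drawn from a normal
    distribution N(micro_cluster_means[k-1, m], micro_cluster_sd[m]^2)
    truncated at zero (all seven metrics are nonnegative); voxels outside
    the DN are set to zero.
    """
    means = np.asarray(spec.micro_cluster_means, dtype=float)
    sds = np.asarray(spec.micro_cluster_sd, dtype=float)
    labels = truth_micro.labels
    out: dict[str, ScalarVolume] = {}
    for m, name in enumerate(METRIC_NAMES):
        values = np.zeros(truth_micro.grid.shape)
        for k in range(1, means.shape[0] + 1):
            sel = labels == k
            n = int(np.count_nonzero(sel))
            if n == 0:
                continue
            a = (0.0 - means[k - 1, m]) / sds[m]
            values[sel] = _sps.truncnorm.rvs(
                a, np.inf, loc=means[k - 1, m], scale=sds[m], size=n, random_state=rng
            )
        out[name] = ScalarVolume(
            grid=truth_micro.grid, values=values, units=METRIC_UNITS[name]
        )
    return out


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _perturb_labels(
    truth: LabelVolume, n_labels: int, noise: float, rng: np.random.Generator
) -> LabelVolume:
    """Replace each nonzero label with a random *other* label w.p. ``noise``."""
    labels = truth.labels.copy()
    inside = labels > 0
    flip = inside & (rng.random(labels.shape) < noise)
    if flip.any():
        current = labels[flip]
        # draw uniformly from the n_labels - 1 other labels
        shift = rng.integers(1, n_labels, size=current.shape)
        labels[flip] = ((current - 1 + shift) % n_labels) + 1
    return LabelVolume(grid=truth.grid, labels=labels, label_names=truth.label_names)


def _per_hemisphere_tdi(
    truth_conn: LabelVolume,
    mask_l: LabelVolume,
    mask_r: LabelVolume,
    spec: PhantomSpec,
    rng: np.random.Generator,
    parcel_counts: tuple[float, ...],
    target_names: tuple[str, ...],
) -> CountMapSet:
    """Simulate counts per hemisphere and merge the disjoint maps."""
    parts = []
    for mask in (mask_l, mask_r):
        side_truth = LabelVolume(
            grid=truth_conn.grid,
            labels=np.where(mask.labels > 0, truth_conn.labels, 0),
            label_names=truth_conn.label_names,
        )
        parts.append(
            simulate_tdi(side_truth, spec, rng, parcel_counts, target_names)
        )
    return CountMapSet(
        grid=truth_conn.grid,
        target_names=list(target_names),
        counts=parts[0].counts + parts[1].counts,
    )


def simulate_cohort(spec: PhantomSpec) -> list[SubjectBundle]:
    """Generate the full synthetic cohort.

    All subjects share the phantom grid and DN masks; per subject the
    connectivity and microstructure truths are independently perturbed by
    label noise before streamline counts and metrics are simulated.  The
    whole cohort is reproducible bit-for-bit from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mask_l, mask_r, truth_conn, truth_micro = combined_phantom(spec)
    n_micro = len(spec.micro_cluster_means)
    bundles = []
    for s in range(spec.n_subjects):
        subj_conn = _perturb_labels(truth_conn, spec.n_conn_parcels, spec.label_noise, rng)
        subj_micro = _perturb_labels(truth_micro, n_micro, spec.label_noise, rng)
        # parcel_counts are per-nucleus totals: draw each hemisphere
        # separately and add the (disjoint-support) count maps.
        tdi_cb = _per_hemisphere_tdi(
            subj_conn, mask_l, mask_r, spec, rng,
            spec.parcel_counts, spec.conn_target_names,
        )
        tdi_th = _per_hemisphere_tdi(
            subj_conn, mask_l, mask_r, spec, rng,
            spec.thalamic_parcel_counts, spec.thalamic_target_names,
        )
        metrics = simulate_metrics(subj_micro, spec, rng)
        bundles.append(
            SubjectBundle(
                subject_id=f"sub-{s + 1:02d}",
                dn_mask_left=mask_l,
                dn_mask_right=mask_r,
                tdi_cerebellar=tdi_cb,
                tdi_thalamic=tdi_th,
                metrics=metrics,
                truth_conn=subj_conn,
                truth_micro=subj_micro,
            )
        )
    return bundles
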