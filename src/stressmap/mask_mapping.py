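"""Map expression samples into the stress-network mask and apply region filters.

A sample belongs to the network iff its MNI coordinate, pushed through the
inverse mask affine and rounded to the nearest voxel index (half-to-even per
axis), lands on an in-mask voxel.  Samples mapping outside the volume are
out-of-network.  An optional maximum mm distance between the sample and the
matched voxel center (default: half the voxel diagonal) rejects implausible
matches; with nearest-voxel rounding, any sample within half a voxel width of
a center always passes this gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas_io import StressMask

logger = logging.getLogger("stressmap")


class ContrastError(ValueError):
    """Raised when no donor has enough in-network samples for a contrast."""


@dataclass(frozen=True)
class ContrastSpec:
    """Which samples enter a differential-expression contrast.

    scope: ``cortex`` (cortical samples only, both sides),
    ``whole_brain_minus_cerebellum`` (drop cerebellar samples), or
    ``region:<structure>`` (only samples with that structure label).
    Donors with fewer than ``min_in_samples`` in-network samples in scope are
    excluded from the contrast.
    """

    scope: str = "cortex"
    min_in_samples: int = 2

    def __post_init__(self) -> None:
        if self.min_in_samples < 1:
            raise ValueError("min_in_samples must be >= 1")
        if self.scope not in ("cortex", "whole_brain_minus_cerebellum") and not (
            self.scope.startswith("region:") and len(self.scope) > 7
        ):
            raise ValueError(f"unknown contrast scope {self.scope!r}")


def assign_membership(
    samples: pd.DataFrame, mask: StressMask, max_distance_mm: float | None = None
) -> pd.DataFrame:
    """Return the membership table: one row per sample with ``in_network``.

    ``samples`` must carry sample_id, donor_id, mni_x/y/z, structure and
    is_cortex columns.  ``max_distance_mm`` defaults to half the voxel
    diagonal.
    """
    if max_distance_mm is None:
        max_distance_mm = 0.5 * float(np.linalg.norm(mask.voxel_size))
    xyz = samples[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)
    inv = np.linalg.inv(mask.affine)
    ijk = nib.affines.apply_affine(inv, xyz)
    # np.rint rounds half to even, which makes ties at voxel faces deterministic
    idx = np.rint(ijk).astype(int)
    shape = np.asarray(mask.shape)
    in_bounds = ((idx >= 0) & (idx < shape)).all(axis=1)
    centers = nib.affines.apply_affine(mask.affine, idx.astype(float))
    dist = np.linalg.norm(centers - xyz, axis=1)
    in_network = np.zeros(len(samples), dtype=bool)
    voxels = mask.voxels
    for i in np.nonzero(in_bounds & (dist <= max_distance_mm))[0]:
        in_network[i] = tuple(idx[i]) in voxels
    n_oob = int((~in_bounds).sum())
    if n_oob:
        logger.info("%d sample(s) map outside the mask volume (out-of-network)", n_oob)
    out = samples[["sample_id", "donor_id", "structure", "is_cortex"]].copy()
    out.insert(2, "in_network", in_network)
    return out.reset_index(drop=True)


def _scope_filter(membership: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == "cortex":
        return membership[membership["is_cortex"]]
    if scope == "whole_brain_minus_cerebellum":
        return membership[membership["structure"].str.lower() != "cerebellum"]
    region = scope.split(":", 1)[1]
    return membership[membership["structure"].str.lower() == region.lower()]


def select_contrast(
    membership: pd.DataFrame, spec: ContrastSpec
) -> dict[str, tuple[list[str], list[str]]]:
    """Per-donor in/out sample ids for one contrast scope.

    Applies the scope filter to both sides of the contrast, then drops donors
    with fewer than ``spec.min_in_samples`` in-network samples in scope.
    Raises :class:`ContrastError` if no donor survives.
    """
    if membership.empty:
        raise ContrastError("empty membership table")
    scoped = _scope_filter(membership, spec.scope)
    result: dict[str, tuple[list[str], list[str]]] = {}
    for donor_id, grp in scoped.groupby("donor_id", sort=True):
        in_ids = grp.loc[grp["in_network"], "sample_id"].tolist()
        out_ids = grp.loc[~grp["in_network"], "sample_id"].tolist()
        if len(in_ids) < spec.min_in_samples:
            logger.info(
                "donor %s excluded from scope %r: %d in-network sample(s) < %d",
                donor_id,
                spec.scope,
                len(in_ids),
                spec.min_in_samples,
            )
            continue
        result[str(donor_id)] = (in_ids, out_ids)
    if not result:
        raise ContrastError(
            f"no donor has >= {spec.min_in_samples} in-network samples in scope {spec.scope!r}"
        )
    return result
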