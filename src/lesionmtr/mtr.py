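"""Magnetisation transfer ratio maps.

MTR = 100 * (MToff - MTon) / MToff, in percentage units (pu).  MToff is the
intensity without the magnetisation transfer saturation pulse, MTon with it;
myelinated tissue transfers more magnetisation and so shows a higher ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class MtrVolume:
    """An MTR (or MTR-change) map with a validity mask.

    ``values`` are pu; voxels outside ``mask`` are NaN and carry no meaning.
    """

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.isfinite(self.values[self.mask]).all():
            raise ValueError("non-finite MTR values inside the validity mask")


def compute_mtr(mt_off: np.ndarray, mt_on: np.ndarray, mask: np.ndarray | None = None) -> MtrVolume:
    """Compute an MTR map from an MToff / MTon intensity pair.

    Voxels where MToff <= 0 inside the requested mask are removed from the
    validity mask with a logged count rather than propagating NaN/inf.
    """
    mt_off = np.asarray(mt_off, dtype=float)
    mt_on = np.asarray(mt_on, dtype=float)
    if mt_off.shape != mt_on.shape:
        raise ValueError(f"MToff shape {mt_off.shape} != MTon shape {mt_on.shape}")
    if mask is None:
        mask = np.ones(mt_off.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != mt_off.shape:
            raise ValueError("mask shape differs from volumes")

    valid = mask & (mt_off > 0) & np.isfinite(mt_off) & np.isfinite(mt_on)
    n_dropped = int(mask.sum() - valid.sum())
    if n_dropped:
        logger.warning("compute_mtr: %d masked voxels with MToff <= 0 or non-finite input dropped", n_dropped)

    values = np.full(mt_off.shape, np.nan)
    np.divide(mt_off - mt_on, mt_off, out=values, where=valid)
    values[valid] *= 100.0
    return MtrVolume(values=values, mask=valid)


def change_map(baseline: MtrVolume, followup: MtrVolume) -> MtrVolume:
    """Voxelwise follow-up minus baseline MTR (pu); validity is the mask intersection."""
    if baseline.values.shape != followup.values.shape:
        raise ValueError("baseline and follow-up shapes differ")
    mask = baseline.mask & followup.mask
    values = np.full(baseline.values.shape, np.nan)
    values[mask] = followup.values[mask] - baseline.values[mask]
    return MtrVolume(values=values, mask=mask)
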