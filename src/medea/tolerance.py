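"""Position-specific tolerance boxes for LC-MS peak matching.

A matched group of peaks ("cluster") must fit inside an axis-aligned box
around its center.  The m/z half-width is relative (parts per million), so
the box grows with the m/z position — this is the position-specific
constraint on cluster variance.  The retention-time half-width is absolute
(minutes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Standardized-residual cutoff used throughout: the scale of each coordinate
#: is set to one third of the box half-width, so a residual of 3 standardized
#: units sits exactly on the box edge.
CUTOFF = 3.0


@dataclass(frozen=True)
class ToleranceModel:
    """Half-widths of the tolerance box.

    Parameters
    ----------
    mz_ppm : float
        Relative m/z half-width in parts per million; the absolute
        half-width at position ``m`` is ``mz_ppm * 1e-6 * m``.
    rt_halfwidth : float
        Absolute retention-time half-width in minutes.
    """

    mz_ppm: float
    rt_halfwidth: float

    def __post_init__(self) -> None:
        if not self.mz_ppm > 0:
            raise ValueError(f"mz_ppm must be > 0, got {self.mz_ppm}")
        if not self.rt_halfwidth > 0:
            raise ValueError(
                f"rt_halfwidth must be > 0, got {self.rt_halfwidth}"
            )

    def delta_mz(self, mz):
        """Absolute m/z half-width of the box centered at ``mz`` (Thomson)."""
        return self.mz_ppm * 1e-6 * np.asarray(mz, dtype=float)

    def sigma_mz(self, mz):
        """Scale of the m/z coordinate: one third of the half-width."""
        return self.delta_mz(mz) / CUTOFF

    @property
    def sigma_rt(self) -> float:
        """Scale of the RT coordinate: one third of the half-width."""
        return self.rt_halfwidth / CUTOFF
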