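"""Two-pool tissue parameters and the per-offset MT signal container.

The binary spin-bath description of tissue couples a free water pool (f) to
a restricted macromolecular pool (r) by magnetization exchange.  The pool
size ratio ``f`` (equilibrium restricted-pool magnetization relative to the
free pool) is the proxy for macromolecular content; exchange obeys detailed
balance ``kf = f * kr``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

R1R_DEFAULT = 1.0  # s^-1; restricted-pool R1 is not identifiable from MT data


class TissueParameterError(ValueError):
    """Raised for unphysical tissue parameters."""


@dataclass(frozen=True)
class TissueParameters:
    """Parameters of the binary spin-bath model for one voxel or ROI.

    Attributes
    ----------
    f:
        Restricted-to-free pool size ratio (dimensionless, >= 0).
    kr:
        Exchange rate restricted -> free (s^-1).
    t2r:
        Transverse relaxation time of the restricted pool (s; microsecond scale).
    t2f:
        Transverse relaxation time of the free pool (s; millisecond scale).
    t1f:
        Longitudinal relaxation time of the free pool (s).
    sdf:
        Effective spin density of the free pool (signal scale, a.u.).
    r1r:
        Longitudinal rate of the restricted pool (s^-1); conventionally fixed.
    """

    f: float
    kr: float
    t2r: float
    t2f: float
    t1f: float
    sdf: float = 1.0
    r1r: float = R1R_DEFAULT

    def __post_init__(self) -> None:
        vals = (self.f, self.kr, self.t2r, self.t2f, self.t1f, self.sdf, self.r1r)
        if any(not math.isfinite(v) for v in vals):
            raise TissueParameterError("tissue parameters must be finite")
        if any(v < 0 for v in vals):
            raise TissueParameterError("tissue parameters must be nonnegative")
        if self.t2r <= 0 or self.t2f <= 0 or self.t1f <= 0:
            raise TissueParameterError("relaxation times must be positive")
        if not self.t2r < self.t2f:
            raise TissueParameterError("restricted-pool T2 must be shorter than free-pool T2")
        if not self.sdf > 0:
            raise TissueParameterError("spin density must be positive")

    @property
    def kf(self) -> float:
        """Exchange rate free -> restricted (s^-1); detailed balance kf = f*kr."""
        return self.f * self.kr

    @property
    def r1f(self) -> float:
        """Free-pool longitudinal rate 1/T1f (s^-1)."""
        return 1.0 / self.t1f

    def with_(self, **kwargs) -> "TissueParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MTSignal:
    """Unsaturated signal M0 plus per-offset saturated signals.

    ``values`` is aligned with the acquisition's ``offsets_hz``;
    ``normalized`` is ``values / m0`` and lies in (0, 1] for noiseless model
    output.
    """

    m0: float
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("values must be a nonempty 1-D array")
        if not np.all(np.isfinite(values)) or not math.isfinite(self.m0):
            raise ValueError("signal values must be finite")
        if not self.m0 > 0:
            raise ValueError("m0 must be positive")

    @property
    def normalized(self) -> np.ndarray:
        return self.values / self.m0

    def __len__(self) -> int:
        return int(self.values.size)
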