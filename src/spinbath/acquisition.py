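"""Acquisition descriptor for the pulsed off-resonance saturation experiment.

An MT-weighted FLASH protocol is described by the set of saturation offset
frequencies, the repetition/echo times, the excitation and saturation flip
angles, the shape and duration of the saturation pulse, and the lineshape
assumed for the restricted (macromolecular) pool.  The defaults reproduce a
3 T protocol with Gaussian presaturation pulses at seven offsets between
1 and 16 kHz (TR 300 ms, TE 4.18 ms, excitation 20 deg, saturation 540 deg).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

DEFAULT_OFFSETS_HZ = (1000.0, 2000.0, 4000.0, 8000.0, 10000.0, 12000.0, 16000.0)

_LINESHAPES = ("gaussian", "super_lorentzian")
_PULSE_SHAPES = ("gaussian",)


class AcquisitionError(ValueError):
    """Raised for an inconsistent or unphysical acquisition descriptor."""


@dataclass(frozen=True)
class MTAcquisition:
    """Saturation-experiment descriptor.

    Parameters
    ----------
    offsets_hz:
        Off-resonance frequencies of the saturation pulse, strictly positive
        and strictly increasing (Hz).
    tr_s, te_s:
        Repetition and echo time of the FLASH readout (s).
    exc_flip_deg:
        Excitation flip angle (deg).
    mt_flip_deg:
        Nominal flip angle of the saturation pulse (deg); 540 deg by default.
    mt_pulse_shape:
        Envelope of the saturation pulse; only ``"gaussian"`` is supported.
    mt_pulse_duration_s:
        Duration of the saturation pulse (s); must fit inside TR.
    lineshape:
        Absorption lineshape of the restricted pool, ``"gaussian"`` or
        ``"super_lorentzian"``.
    n_slices:
        Number of interleaved 2-D sections.  In an interleaved multislice
        FLASH protocol one saturation module plays per slice acquisition,
        so ``n_slices`` pulses are deposited per TR; this multiplies the
        mean-square saturation power by the same factor.
    """

    offsets_hz: tuple[float, ...] = DEFAULT_OFFSETS_HZ
    tr_s: float = 0.300
    te_s: float = 0.00418
    exc_flip_deg: float = 20.0
    mt_flip_deg: float = 540.0
    mt_pulse_shape: str = "gaussian"
    mt_pulse_duration_s: float = 0.012
    lineshape: str = "gaussian"
    n_slices: int = 16

    def __post_init__(self) -> None:
        offsets = tuple(float(f) for f in self.offsets_hz)
        object.__setattr__(self, "offsets_hz", offsets)
        if len(offsets) == 0:
            raise AcquisitionError("at least one saturation offset is required")
        if any(f <= 0 for f in offsets):
            raise AcquisitionError("saturation offsets must be strictly positive")
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise AcquisitionError(
                "saturation offsets must be strictly increasing with no duplicates"
            )
        if not self.mt_pulse_duration_s > 0:
            raise AcquisitionError("mt_pulse_duration_s must be positive")
        if not self.tr_s > self.mt_pulse_duration_s:
            raise AcquisitionError("tr_s must exceed the saturation pulse duration")
        if self.te_s <= 0 or self.te_s >= self.tr_s:
            raise AcquisitionError("te_s must lie in (0, tr_s)")
        if self.exc_flip_deg < 0 or self.mt_flip_deg < 0:
            raise AcquisitionError("flip angles must be nonnegative")
        if self.n_slices < 1:
            raise AcquisitionError("n_slices must be >= 1")
        if self.n_slices * self.mt_pulse_duration_s >= self.tr_s:
            raise AcquisitionError("saturation modules do not fit inside TR")
        if self.mt_pulse_shape not in _PULSE_SHAPES:
            raise AcquisitionError(f"unsupported pulse shape {self.mt_pulse_shape!r}")
        if self.lineshape not in _LINESHAPES:
            raise AcquisitionError(f"unsupported lineshape {self.lineshape!r}")

    @property
    def n_offsets(self) -> int:
        return len(self.offsets_hz)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "MTAcquisition":
        allowed = set(cls.__dataclass_fields__)  # type: ignore[attr-defined]
        unknown = set(d) - allowed
        if unknown:
            raise AcquisitionError(f"unknown acquisition keys: {sorted(unknown)}")
        d = dict(d)
        if "offsets_hz" in d:
            d["offsets_hz"] = tuple(d["offsets_hz"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "MTAcquisition":
        return cls.from_dict(json.loads(Path(path).read_text()))
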