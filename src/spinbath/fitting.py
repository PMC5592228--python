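"""Voxelwise inversion of the binary spin-bath model.

Each voxel's normalized saturation spectrum is fit by damped least squares
(Levenberg-Marquardt: normal equations with an adaptive damping term) over
the free parameters {pool ratio f, exchange rate kr, restricted-pool T2}
within physiological box bounds; candidate steps are projected onto the
bounds and only cost-decreasing steps are accepted, so the cost trace is
nonincreasing by construction.  T1f (and by default T2f) are taken from
separately supplied relaxometry maps; the free-pool spin density is read
off the unsaturated M0 amplitude, decoupling signal scale from spectrum
shape.  Initialization is a deterministic coarse grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .acquisition import MTAcquisition
from .model import lineshape_value, mtr, omega1_cwpe
from .stack_io import MTImageStack
from .tissue import MTSignal, R1R_DEFAULT, TissueParameters

__all__ = [
    "FitOptions",
    "FitResult",
    "ParameterMaps",
    "initial_guess",
    "fit_voxel",
    "fit_volume",
    "compute_mtr_map",
]

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "f": (0.001, 0.5),
    "kr": (1.0, 100.0),
    "t2r": (2e-6, 50e-6),
    "t2f": (10e-3, 300e-3),
}

MAP_NAMES = ("f", "kf", "kr", "t2r", "t2f", "sdf", "mtr", "residual", "converged", "n_iter")

_GRID_FRACTIONS = (0.2, 0.5, 0.8)


class FitConfigError(ValueError):
    """Raised for inconsistent fitting configuration or missing inputs."""


@dataclass(frozen=True)
class FitOptions:
    """Solver options for the voxelwise inversion."""

    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    fix_t2f: bool = True  # take T2f from the relaxometry map instead of fitting it
    max_iter: int = 200
    cost_rtol: float = 1e-10
    gtol: float = 1e-10


@dataclass(frozen=True)
class FitResult:
    """Outcome of one voxel fit."""

    params: TissueParameters
    residual_norm: float  # sum of squared residuals
    n_iter: int
    converged: bool
    cost_trace: tuple[float, ...]  # cost at accepted steps, nonincreasing


class _SpectrumModel:
    """Fast normalized-spectrum evaluator with per-voxel constants folded in."""

    def __init__(self, acq: MTAcquisition, t1f: float, t2f: float | None):
        if not t1f > 0:
            raise FitConfigError("t1f must be positive")
        self.offsets = np.asarray(acq.offsets_hz, dtype=float)
        self.lineshape = acq.lineshape
        self.w1sq = omega1_cwpe(acq) ** 2
        self.r1f = 1.0 / t1f
        self.r1r = R1R_DEFAULT
        self._two_pi_off = 2.0 * np.pi * self.offsets
        self.t2f_fixed = t2f
        if t2f is not None:
            self._wf_fixed = self.w1sq * t2f / (1.0 + (self._two_pi_off * t2f) ** 2)

    def mf(self, f: float, kr: float, t2r: float, t2f: float | None = None) -> np.ndarray:
        if self.lineshape == "gaussian":
            g = t2r / np.sqrt(2.0 * np.pi) * np.exp(-0.5 * (self._two_pi_off * t2r) ** 2)
        else:
            g = lineshape_value(self.offsets, t2r, self.lineshape)
        wr = np.pi * self.w1sq * g
        if t2f is None:
            wf = self._wf_fixed
        else:
            wf = self.w1sq * t2f / (1.0 + (self._two_pi_off * t2f) ** 2)
        kf = f * kr
        num = self.r1f * (self.r1r + kr + wr) + kr * self.r1r * f
        den = (self.r1f + kf + wf) * (self.r1r + kr + wr) - kf * kr
        return num / den


def _lm_minimize(residual, x0, lb, ub, *, max_iter, cost_rtol, gtol):
    """Bound-constrained damped least squares with a nonincreasing cost trace."""
    x = np.clip(np.asarray(x0, dtype=float), lb, ub)
    scale = ub - lb
    r = residual(x)
    cost = 0.5 * float(r @ r)
    trace = [cost]
    if cost < 1e-28:
        return x, trace, 0, True
    lam = 1e-3
    nu = 2.0
    n_iter = 0
    converged = False
    n_par = x.size
    for it in range(max_iter):
        # forward-difference Jacobian, stepping inward at the upper bound
        J = np.empty((r.size, n_par))
        for j in range(n_par):
            h = 1e-7 * scale[j]
            xj = x.copy()
            xj[j] = x[j] + h if x[j] + h <= ub[j] else x[j] - h
            J[:, j] = (residual(xj) - r) / (xj[j] - x[j])
        g = J.T @ r
        if np.max(np.abs(g * scale)) < gtol:
            converged = True
            break
        jtj = J.T @ J
        d = np.diag(jtj).copy()
        d[d <= 0] = 1e-12
        accepted = False
        for _ in range(60):
            try:
                delta = np.linalg.solve(jtj + lam * np.diag(d), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                nu = 2.0
                continue
            x_new = np.clip(x + delta, lb, ub)
            step = x_new - x
            r_new = residual(x_new)
            if not np.all(np.isfinite(r_new)):
                lam *= nu
                nu *= 2.0
                continue
            cost_new = 0.5 * float(r_new @ r_new)
            if cost_new <= cost:
                # Nielsen gain-ratio damping: shrink lambda in proportion to
                # how well the quadratic model predicted the reduction
                predicted = 0.5 * float(step @ (lam * d * step - g))
                rho = (cost - cost_new) / predicted if predicted > 0 else 1.0
                lam = max(lam * max(1.0 / 3.0, 1.0 - (2.0 * rho - 1.0) ** 3), 1e-14)
                nu = 2.0
                accepted = True
                break
            lam *= nu
            nu *= 2.0
        if not accepted:
            converged = True  # no descent direction left: local minimum
            break
        prev = cost
        x, r, cost = x_new, r_new, cost_new
        trace.append(cost)
        n_iter = it + 1
        if cost < 1e-28 or prev - cost <= cost_rtol * max(prev, 1e-300):
            converged = True
            break
        if np.all(np.abs(step) <= 1e-13 * scale):
            converged = True
            break
    return x, trace, n_iter, converged


def _free_names(options: FitOptions) -> tuple[str, ...]:
    return ("f", "kr", "t2r") if options.fix_t2f else ("f", "kr", "t2r", "t2f")


def initial_guess(
    signal: MTSignal,
    acq: MTAcquisition,
    t1f: float,
    t2f: float,
    options: FitOptions | None = None,
) -> TissueParameters:
    """Deterministic coarse 3x3x3 grid search over (f, kr, t2r).

    T2f and T1f are held at their supplied values.  A degenerate all-equal
    spectrum falls back to the mid-bounds start.
    """
    options = options or FitOptions()
    if len(signal) < 4:
        raise FitConfigError("need at least 4 saturation offsets for initialization")
    y = signal.normalized
    b = options.bounds
    mid = TissueParameters(
        f=0.5 * (b["f"][0] + b["f"][1]),
        kr=0.5 * (b["kr"][0] + b["kr"][1]),
        t2r=0.5 * (b["t2r"][0] + b["t2r"][1]),
        t2f=t2f,
        t1f=t1f,
        sdf=signal.m0,
    )
    if np.allclose(y, y[0]):
        return mid
    model = _SpectrumModel(acq, t1f, t2f)
    nodes = {
        name: [b[name][0] + fr * (b[name][1] - b[name][0]) for fr in _GRID_FRACTIONS]
        for name in ("f", "kr", "t2r")
    }
    best, best_cost = None, np.inf
    for f in nodes["f"]:
        for kr in nodes["kr"]:
            for t2r in nodes["t2r"]:
                resid = model.mf(f, kr, t2r) - y
                cost = float(resid @ resid)
                if cost < best_cost:
                    best, best_cost = (f, kr, t2r), cost
    return mid.with_(f=best[0], kr=best[1], t2r=best[2])


def fit_voxel(
    signal: MTSignal,
    acq: MTAcquisition,
    fixed: Mapping[str, float],
    options: FitOptions | None = None,
) -> FitResult:
    """Fit one voxel's normalized spectrum.

    ``fixed`` must supply ``t1f`` and, unless ``options.fix_t2f`` is False,
    ``t2f`` (both in seconds).  The spin density is recovered from M0.
    """
    options = options or FitOptions()
    if "t1f" not in fixed:
        raise FitConfigError("fixed parameters must include 't1f'")
    t1f = float(fixed["t1f"])
    if options.fix_t2f:
        if "t2f" not in fixed:
            raise FitConfigError("fixed parameters must include 't2f' when fix_t2f is set")
        t2f_fixed = float(fixed["t2f"])
    else:
        t2f_fixed = None
    y = signal.normalized
    if not np.all(np.isfinite(y)):
        raise FitConfigError("signal contains non-finite values")

    model = _SpectrumModel(acq, t1f, t2f_fixed)
    names = _free_names(options)
    # optimize in log-parameter space: the f-kr trade-off is multiplicative,
    # so log coordinates straighten the cost valley and condition the solve
    lb = np.log([options.bounds[n][0] for n in names])
    ub = np.log([options.bounds[n][1] for n in names])

    start = initial_guess(
        signal, acq, t1f, t2f_fixed if t2f_fixed is not None else float(fixed.get("t2f", 60e-3)), options
    )
    x0 = np.log([getattr(start, n) for n in names])

    def residual(x):
        return model.mf(*np.exp(x)) - y

    x, trace, n_iter, converged = _lm_minimize(
        residual, x0, lb, ub,
        max_iter=options.max_iter, cost_rtol=options.cost_rtol, gtol=options.gtol,
    )
    fitted = dict(zip(names, np.exp(x)))
    t2f_out = fitted.get("t2f", t2f_fixed)
    params = TissueParameters(
        f=fitted["f"], kr=fitted["kr"], t2r=fitted["t2r"],
        t2f=t2f_out, t1f=t1f, sdf=signal.m0,
    )
    return FitResult(
        params=params,
        residual_norm=2.0 * trace[-1],
        n_iter=n_iter,
        converged=converged,
        cost_trace=tuple(trace),
    )


@dataclass
class ParameterMaps:
    """Voxelwise parameter maps plus fit diagnostics on the source grid.

    Out-of-mask voxels are NaN (absent), never zero.
    """

    maps: dict[str, np.ndarray]
    affine: np.ndarray
    mask: np.ndarray

    @property
    def converged_fraction(self) -> float:
        conv = self.maps["converged"][self.mask]
        return float(np.mean(conv)) if conv.size else float("nan")

    @property
    def median_residual(self) -> float:
        res = self.maps["residual"][self.mask]
        return float(np.median(res)) if res.size else float("nan")

    def to_dir(self, out_dir) -> None:
        import nibabel as nib
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, vol in self.maps.items():
            nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), self.affine),
                     str(out / f"{name}.nii.gz"))

    @classmethod
    def from_dir(cls, in_dir) -> "ParameterMaps":
        import nibabel as nib
        from pathlib import Path

        d = Path(in_dir)
        maps = {}
        affine = None
        for name in MAP_NAMES:
            p = d / f"{name}.nii.gz"
            if not p.exists():
                raise FitConfigError(f"missing parameter map {p}")
            img = nib.load(str(p))
            maps[name] = np.asarray(img.get_fdata(), dtype=float)
            affine = img.affine
        mask = np.isfinite(maps["f"])
        return cls(maps=maps, affine=affine, mask=mask)


def compute_mtr_map(
    stack: MTImageStack,
    acq: MTAcquisition,
    mask: np.ndarray | None = None,
    offset_hz: float = 1000.0,
) -> np.ndarray:
    """Voxelwise magnetization transfer ratio (percent) at the 1 kHz offset.

    Restricted to ``mask`` when given (NaN outside); otherwise computed for
    the whole volume.  Requires the 1 kHz offset in the acquisition.
    """
    matches = [i for i, f in enumerate(acq.offsets_hz) if np.isclose(f, offset_hz)]
    if not matches:
        raise FitConfigError(f"acquisition has no {offset_hz:g} Hz offset; cannot compute MTR")
    msat = stack.offset_volumes[matches[0]]
    m0 = stack.m0_volume
    out = np.full(m0.shape, np.nan)
    sel = np.ones(m0.shape, bool) if mask is None else mask.astype(bool)
    sel = sel & (m0 > 0)
    out[sel] = 100.0 * (m0[sel] - msat[sel]) / m0[sel]
    return out


def fit_volume(
    stack: MTImageStack,
    mask: np.ndarray | str,
    acq: MTAcquisition,
    options: FitOptions | None = None,
) -> ParameterMaps:
    """Apply :func:`fit_voxel` to every in-mask voxel, independently.

    Voxels are processed in lexicographic index order, but each fit depends
    only on its own voxel, so any processing order yields identical maps.
    """
    options = options or FitOptions()
    if isinstance(mask, str):
        if mask not in stack.masks:
            raise FitConfigError(f"stack has no mask named {mask!r}")
        mask = stack.masks[mask]
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise FitConfigError("mask is empty")
    if stack.t1_map is None:
        raise FitConfigError("fit_volume requires a t1_map on the stack")
    if options.fix_t2f and stack.t2f_map is None:
        raise FitConfigError("fit_volume requires a t2f_map when fix_t2f is set")

    maps = {name: np.full(stack.shape, np.nan) for name in MAP_NAMES}
    mtr_map = compute_mtr_map(stack, acq, mask=mask)
    for idx in map(tuple, np.argwhere(mask)):
        m0, vals = stack.voxel_signal(idx)
        fixed = {"t1f": float(stack.t1_map[idx])}
        if stack.t2f_map is not None:
            fixed["t2f"] = float(stack.t2f_map[idx])
        res = fit_voxel(MTSignal(m0=m0, values=vals), acq, fixed, options)
        p = res.params
        for name, val in (
            ("f", p.f), ("kf", p.kf), ("kr", p.kr), ("t2r", p.t2r),
            ("t2f", p.t2f), ("sdf", p.sdf), ("mtr", mtr_map[idx]),
            ("residual", res.residual_norm), ("converged", float(res.converged)),
            ("n_iter", float(res.n_iter)),
        ):
            maps[name][idx] = val
    return ParameterMaps(maps=maps, affine=stack.affine, mask=mask)
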