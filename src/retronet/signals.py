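"""Time-varying input and perturbation signals.

Concentrations are in nM and time in hours throughout the package.  Every
signal carries both a value ``u(t)`` and an analytic derivative ``du(t)``:
the derivative enters the reduced dynamics through the external
retroactivity term, so a signal is not just a callable but a C^1 pair.
Pulses therefore use smooth logistic edges rather than hard steps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = [
    "InputSignal",
    "constant",
    "pulse",
    "sinusoid",
    "signal_from_dict",
    "load_signals",
    "check_signal_consistency",
]


@dataclass(frozen=True)
class InputSignal:
    """A nonnegative concentration signal with an explicit time derivative.

    Attributes
    ----------
    id:
        Name used to bind the signal to a module input or a perturbable node.
    value, derivative:
        Scalar callables ``u(t)`` [nM] and ``du/dt`` [nM/h].
    shape, params:
        Declarative description used for (de)serialization and metadata.
    """

    id: str
    value: Callable[[float], float]
    derivative: Callable[[float], float]
    shape: str = "custom"
    params: Mapping[str, float] = field(default_factory=dict)

    def __call__(self, t: float) -> float:
        return self.value(t)

    def to_dict(self) -> dict:
        if self.shape == "custom":
            raise ConfigurationError(
                f"signal {self.id!r} is a custom callable and cannot be serialized"
            )
        return {"id": self.id, "shape": self.shape, "params": dict(self.params)}


def constant(sid: str, level: float) -> InputSignal:
    if level < 0:
        raise ValidationError(f"signal {sid!r}: constant level must be >= 0, got {level}")
    return InputSignal(
        id=sid,
        value=lambda t: level,
        derivative=lambda t: 0.0,
        shape="constant",
        params={"level": float(level)},
    )


def _logistic(z: float) -> float:
    # overflow-safe logistic
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def _dlogistic(z: float) -> float:
    s = _logistic(z)
    return s * (1.0 - s)


def pulse(
    sid: str,
    height: float,
    start: float,
    width: float,
    edge: float = 0.01,
    baseline: float = 0.0,
) -> InputSignal:
    """Smooth rectangular pulse: logistic rise at ``start``, fall at ``start+width``.

    ``edge`` is the logistic time constant in hours (default 0.01 h ~ 36 s),
    so the pulse is effectively rectangular on the gene-expression time scale
    while keeping the derivative bounded.
    """
    if height < 0 or baseline < 0:
        raise ValidationError(f"signal {sid!r}: pulse height/baseline must be >= 0")
    if width <= 0 or edge <= 0:
        raise ValidationError(f"signal {sid!r}: pulse width and edge must be > 0")
    t0, t1 = float(start), float(start) + float(width)

    def value(t: float) -> float:
        return baseline + height * (_logistic((t - t0) / edge) - _logistic((t - t1) / edge))

    def derivative(t: float) -> float:
        return height / edge * (_dlogistic((t - t0) / edge) - _dlogistic((t - t1) / edge))

    return InputSignal(
        id=sid,
        value=value,
        derivative=derivative,
        shape="pulse",
        params={
            "height": float(height),
            "start": float(start),
            "width": float(width),
            "edge": float(edge),
            "baseline": float(baseline),
        },
    )


def sinusoid(
    sid: str,
    mean: float,
    amplitude: float,
    period: float,
    phase: float = 0.0,
) -> InputSignal:
    """``u(t) = mean + amplitude * sin(2*pi*(t - phase)/period)``, clipped-free.

    Requires ``mean >= amplitude`` so that u(t) >= 0 without clipping (a
    clipped sinusoid would have a discontinuous derivative).
    """
    if amplitude < 0 or period <= 0:
        raise ValidationError(f"signal {sid!r}: amplitude >= 0 and period > 0 required")
    if mean < amplitude:
        raise ValidationError(
            f"signal {sid!r}: mean ({mean}) must be >= amplitude ({amplitude}) "
            "so the signal stays nonnegative"
        )
    w = 2.0 * math.pi / period

    return InputSignal(
        id=sid,
        value=lambda t: mean + amplitude * math.sin(w * (t - phase)),
        derivative=lambda t: amplitude * w * math.cos(w * (t - phase)),
        shape="sinusoid",
        params={
            "mean": float(mean),
            "amplitude": float(amplitude),
            "period": float(period),
            "phase": float(phase),
        },
    )


_SHAPES = {"constant": constant, "pulse": pulse, "sinusoid": sinusoid}


def signal_from_dict(d: Mapping) -> InputSignal:
    try:
        sid, shape, params = d["id"], d["shape"], dict(d.get("params", {}))
    except KeyError as exc:
        raise ValidationError(f"signal entry missing key {exc}") from exc
    if shape not in _SHAPES:
        raise ValidationError(f"signal {sid!r}: unknown shape {shape!r}")
    return _SHAPES[shape](sid, **params)


def load_signals(path) -> dict[str, InputSignal]:
    """Read a JSON list of ``{id, shape, params}`` entries."""
    with open(path) as fh:
        entries = json.load(fh)
    if not isinstance(entries, list):
        raise ValidationError("signals file must contain a JSON list")
    sigs = [signal_from_dict(e) for e in entries]
    out: dict[str, InputSignal] = {}
    for s in sigs:
        if s.id in out:
            raise ValidationError(f"duplicate signal id {s.id!r}")
        out[s.id] = s
    return out


def check_signal_consistency(
    sig: InputSignal, t_grid: Iterable[float], rtol: float = 1e-3, atol: float = 1e-6
) -> None:
    """Verify u(t) >= 0 and that ``derivative`` matches a finite difference of
    ``value`` on the given grid.  Raises ValidationError on failure."""
    ts = np.asarray(list(t_grid), dtype=float)
    u = np.array([sig.value(t) for t in ts])
    if np.any(u < -atol):
        raise ValidationError(f"signal {sig.id!r} is negative on the grid")
    h = 1e-6
    for t in ts:
        fd = (sig.value(t + h) - sig.value(t - h)) / (2 * h)
        an = sig.derivative(t)
        scale = max(abs(fd), abs(an), 1.0)
        if abs(fd - an) > rtol * scale + atol:
            raise ValidationError(
                f"signal {sig.id!r}: derivative inconsistent at t={t} "
                f"(analytic {an:.6g}, finite-difference {fd:.6g})"
            )
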