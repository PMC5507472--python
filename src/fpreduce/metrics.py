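"""Reproduction-accuracy measures for spike-rate time series."""

from __future__ import annotations

import numpy as np

from .signals import Signal

__all__ = ["pearson_rho", "rms_distance"]


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, Signal) else np.asarray(x, dtype=float)


def pearson_rho(x, y) -> float:
    """Pearson correlation coefficient between two equally long series."""
    xv, yv = _values(x), _values(y)
    if xv.size != yv.size or xv.size < 2:
        raise ValueError("series must have equal length >= 2")
    xd = xv - xv.mean()
    yd = yv - yv.mean()
    sx = np.sqrt(np.sum(xd ** 2))
    sy = np.sqrt(np.sum(yd ** 2))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.sum(xd * yd) / (sx * sy))


def rms_distance(x, y) -> float:
    """Root-mean-square distance between two equally long series (kHz)."""
    xv, yv = _values(x), _values(y)
    if xv.size != yv.size:
        raise ValueError("series must have equal length")
    return float(np.sqrt(np.mean((xv - yv) ** 2)))
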