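"""Conversion of self-affinity exponents to informed dimension estimates.

A scaling exponent alone does not determine a dimension: the same estimator
output means different things for a stationary increments-like process (fGn,
Hurst exponent H, graph dimension D = 2 - H) and for its cumulative sum (fBm).
The conversions here first classify the exponent into the fGn or fBm regime
and then map it through the known (H, D) correspondences:

* PSD slope ``s``:  fGn for ``-1 <= s <= 1`` with ``H = (1 - s)/2``; fBm for
  ``s < -1`` with ``H = -(1 + s)/2``; in both regimes ``D = 2 - H``.
* DFA exponent ``alpha``:  fGn for ``0 < alpha < 1`` with ``H = alpha``
  (``D = 2 - alpha``); fBm for ``1 <= alpha <= 2`` with ``H = alpha - 1``
  (``D = 3 - alpha``).
* SDA slope:  fGn-only by construction, ``D = 1 - slope``.

The white-noise / Brownian anchors come out right on both branches:
``s = 0`` and ``s = -2`` both give H = 0.5, D = 1.5, as do ``alpha = 0.5``
and ``alpha = 1.5`` and an SDA slope of -0.5.  These piecewise rules
approximate well-known (H, D) pairs; they are a conversion convention, not an
analytic identity.  The dichotomy is inherently discontinuous at the branch
boundary; the ``boundary`` flag picks which branch owns it.

All dimension outputs are clamped to [1, 2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DimensionEstimate

__all__ = [
    "RegimeClassification",
    "classify_regime",
    "dimension_from_psd",
    "dimension_from_dfa",
    "dimension_from_sda",
]


@dataclass(frozen=True)
class RegimeClassification:
    """fGn/fBm regime assignment of a scaling exponent and its mapped H."""

    regime: str            # "fgn" | "fbm" | "out_of_band"
    H: float               # mapped Hurst exponent, clamped to [0, 1]
    source_method: str     # "psd" | "dfa" | "sda"
    source_exponent: float


def _clamp(v: float, lo: float, hi: float) -> float:
    return float(min(max(v, lo), hi))


def classify_regime(method: str, exponent: float,
                    boundary: str = "default") -> RegimeClassification:
    """Assign a scaling exponent to the fGn or fBm regime.

    ``boundary`` controls which branch owns the boundary values: ``"default"``
    puts ``s = -1`` on the fGn branch and ``alpha = 1`` on the fBm branch;
    ``"alternative"`` swaps both assignments.  The mapped H (and hence
    D) differs across the boundary — the dichotomy is discontinuous there by
    construction.
    """
    if not np.isfinite(exponent):
        raise ValueError("exponent must be finite")
    if boundary not in ("default", "alternative"):
        raise ValueError(f"unknown boundary policy {boundary!r}")
    e = float(exponent)
    if method == "psd":
        fbm = e < -1.0 if boundary == "default" else e <= -1.0
        if fbm:
            return RegimeClassification("fbm", _clamp(-(1.0 + e) / 2.0, 0.0, 1.0), "psd", e)
        if e <= 1.0:
            return RegimeClassification("fgn", _clamp((1.0 - e) / 2.0, 0.0, 1.0), "psd", e)
        return RegimeClassification("out_of_band", 0.0, "psd", e)
    if method == "dfa":
        in_fgn = (0.0 < e < 1.0) if boundary == "default" else (0.0 < e <= 1.0)
        if in_fgn:
            return RegimeClassification("fgn", _clamp(e, 0.0, 1.0), "dfa", e)
        if e <= 2.0 and e > 0.0:
            return RegimeClassification("fbm", _clamp(e - 1.0, 0.0, 1.0), "dfa", e)
        # alpha <= 0: rougher than any graph; alpha > 2: smoother than a line
        return RegimeClassification("out_of_band", 0.0 if e <= 0 else 1.0, "dfa", e)
    if method == "sda":
        return RegimeClassification("fgn", _clamp(1.0 + e, 0.0, 1.0), "sda", e)
    raise ValueError(f"unknown method tag {method!r}")


def dimension_from_psd(s: float, boundary: str = "default") -> DimensionEstimate:
    """Informed dimension from a periodogram slope.

    ``s < -1`` is read as fBm (H = -(1+s)/2), ``-1 <= s <= 1`` as fGn
    (H = (1-s)/2); either way D = 2 - H.  Slopes beyond +1 are flatter than
    any fGn graph and clamp to D = 2.
    """
    cls = classify_regime("psd", s, boundary)
    if cls.regime == "out_of_band":
        value = 2.0
    else:
        value = 2.0 - cls.H
    return DimensionEstimate(value=_clamp(value, 1.0, 2.0), method="informed_psd",
                             diagnostics={"slope": float(s), "regime": cls.regime,
                                          "H": cls.H})


def dimension_from_dfa(alpha: float, boundary: str = "default") -> DimensionEstimate:
    """Informed dimension from a DFA exponent.

    fGn branch (0 < alpha < 1): D = 2 - alpha; fBm branch (1 <= alpha <= 2):
    D = 3 - alpha.  Values outside (0, 2] clamp to the nearest branch end.
    """
    cls = classify_regime("dfa", alpha, boundary)
    if cls.regime == "fgn":
        value = 2.0 - alpha
    elif cls.regime == "fbm":
        value = 3.0 - alpha
    else:
        value = 2.0 if alpha <= 0 else 1.0
    return DimensionEstimate(value=_clamp(value, 1.0, 2.0), method="informed_dfa",
                             diagnostics={"alpha": float(alpha), "regime": cls.regime,
                                          "H": cls.H})


def dimension_from_sda(slope: float) -> DimensionEstimate:
    """Informed dimension from an SDA slope: ``D = 1 - slope`` (fGn-only)."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    return DimensionEstimate(value=_clamp(1.0 - slope, 1.0, 2.0), method="informed_sda",
                             diagnostics={"slope": float(slope), "regime": "fgn"})
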