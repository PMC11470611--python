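"""Training-data identification and construction.

Specimens whose stress-stretch curves hug the horizontal axis far into the
stretch range (very low toe-region slope and low stress at 40% strain) make
poor network training data: they drive the optimizer toward weights that
generalize badly.  This module scores each direction's curve on two
features -- the toe-region secant slope and the flatness ratio (stress at
stretch 1.4 over the curve's maximum) -- and labels it ``good`` or ``poor``.

It also builds the three target kinds used to train the surrogate network:
the raw measured curve, a straight-line fit ``y = p1 * lambda + p2``, and a
Holzapfel-model fit evaluated on the same grid.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import holzapfel as hz
from .curves import AXIAL, CIRCUMFERENTIAL, DIRECTIONS, BiaxialTest, StretchStressCurve

GOOD = "good"
POOR = "poor"
TRAINING_CURVE_KINDS = ("raw", "linear", "holzapfel")

#: default decision thresholds; the features come from the data description,
#: the cutoffs are calibration choices (see docs/methods.md)
FLATNESS_THRESHOLD = 0.15
SLOPE_THRESHOLD = 0.0
TOE_STRETCH = 1.4


@dataclass
class LinearCurve:
    """Straight-line stress model ``y = p1 * lambda + p2`` (kPa)."""

    p1: float  # slope, kPa per unit stretch
    p2: float  # intercept, kPa

    def __call__(self, lam: np.ndarray) -> np.ndarray:
        return self.p1 * np.asarray(lam, dtype=float) + self.p2


@dataclass
class DirectionFeatures:
    slope_toe: float  # secant slope over the toe window, kPa/stretch
    max_stress: float  # kPa
    flatness_ratio: float  # stress at stretch 1.4 / max stress, in [0, 1]
    label: str


def fit_linear_curve(curve: StretchStressCurve) -> LinearCurve:
    """Ordinary least squares of stress on stretch over all points."""
    if np.ptp(curve.stretch) == 0:
        raise ValueError("cannot fit a line to a constant stretch sequence")
    p1, p2 = np.polyfit(curve.stretch, curve.stress, 1)
    return LinearCurve(p1=float(p1), p2=float(p2))


def _direction_features(
    curve: StretchStressCurve,
    flatness_threshold: float,
    slope_threshold: float,
    toe_stretch: float,
) -> DirectionFeatures:
    hi = curve.stretch[-1]
    if hi < toe_stretch:
        _warnings.warn(
            f"curve range ends at stretch {hi:.3f} < {toe_stretch}; "
            "features computed on the available range",
            stacklevel=3,
        )
    lam_toe = min(toe_stretch, hi)
    slope = float((curve.stress_at(lam_toe) - curve.stress[0]) / (lam_toe - 1.0))
    max_stress = float(curve.stress.max())
    flatness = (
        float(np.clip(curve.stress_at(lam_toe) / max_stress, 0.0, 1.0))
        if max_stress > 0
        else 0.0
    )
    label = POOR if (flatness < flatness_threshold or slope <= slope_threshold) else GOOD
    return DirectionFeatures(
        slope_toe=slope, max_stress=max_stress, flatness_ratio=flatness, label=label
    )


def classify_training_data(
    test: BiaxialTest,
    flatness_threshold: float = FLATNESS_THRESHOLD,
    slope_threshold: float = SLOPE_THRESHOLD,
    toe_stretch: float = TOE_STRETCH,
) -> dict[str, DirectionFeatures]:
    """Label each direction ``good`` or ``poor`` and return the features.

    A direction is poor when its flatness ratio falls below the threshold or
    its toe-region secant slope is not positive.  Both features are
    ratios/slopes, so the labels are invariant to a uniform rescaling of all
    stresses.
    """
    return {
        direction: _direction_features(
            test.curve(direction), flatness_threshold, slope_threshold, toe_stretch
        )
        for direction in DIRECTIONS
    }


def overall_label(features: dict[str, DirectionFeatures]) -> str:
    """``good`` only when both directions are good; ``mixed`` when they split."""
    labels = {f.label for f in features.values()}
    if labels == {GOOD}:
        return GOOD
    if labels == {POOR}:
        return POOR
    return "mixed"


def classification_report(
    tests: list[BiaxialTest], **thresholds
) -> pd.DataFrame:
    """Per-direction feature/label table for an ensemble."""
    rows = []
    for test in tests:
        feats = classify_training_data(test, **thresholds)
        for direction in DIRECTIONS:
            f = feats[direction]
            rows.append(
                dict(
                    test_id=test.test_id,
                    direction=direction,
                    slope_toe=f.slope_toe,
                    max_stress_kPa=f.max_stress,
                    flatness_ratio=f.flatness_ratio,
                    label=f.label,
                )
            )
    return pd.DataFrame(rows)


def build_training_curve(
    test: BiaxialTest,
    kind: str,
    direction: str,
    stress_scale: float | None = None,
    holz_params: hz.HolzapfelParams | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Build one training pair (strain input, stress target, provenance).

    raw
        the measured curve itself;
    linear
        the straight-line fit evaluated on the test's own grid;
    holzapfel
        the constitutive fit evaluated on the grid (``holz_params`` may be
        supplied to reuse an existing fit; otherwise a per-direction fit is
        run here).

    The target is divided by ``stress_scale`` when given, so the network
    trains on the normalized scale.
    """
    if kind not in TRAINING_CURVE_KINDS:
        raise ValueError(f"unknown training-curve kind {kind!r}")
    curve = test.curve(direction)
    lam = curve.stretch
    provenance: dict = {"kind": kind, "test_id": test.test_id, "direction": direction}
    if kind == "raw":
        target = curve.stress.copy()
    elif kind == "linear":
        line = fit_linear_curve(curve)
        target = line(lam)
        provenance["p1"], provenance["p2"] = line.p1, line.p2
    else:
        if holz_params is None:
            result = hz.fit_holzapfel(test, mode="per-direction")
            if not result.converged:
                raise RuntimeError(
                    f"constitutive fit did not converge for {test.test_id}/{direction}"
                )
            holz_params = result.params[direction]
        pred = hz.predicted_test_stresses(holz_params, holz_params, lam)
        target = pred[direction]
        provenance["params"] = holz_params
    if stress_scale is not None:
        target = target / stress_scale
        provenance["stress_scale"] = stress_scale
    return curve.strain.copy(), target, provenance
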