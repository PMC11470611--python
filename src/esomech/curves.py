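"""Data model and I/O for planar-biaxial stretch-stress records.

A specimen record is a pair of :class:`StretchStressCurve` objects, one per
in-plane direction (axial and circumferential), sampled on a common stretch
grid as produced by an equibiaxial protocol.  Curves are stored against the
stretch ratio ``lambda = 1 + engineering strain``; stresses are Cauchy
stresses in kPa.
"""

from __future__ import annotations

import glob
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AXIAL = "axial"
CIRCUMFERENTIAL = "circumferential"
DIRECTIONS = (AXIAL, CIRCUMFERENTIAL)

#: id conventionally given to the ensemble-average record
MEAN_TEST_ID = "T14"


class ValidationError(ValueError):
    """Raised when a curve or record violates a structural invariant."""


class FormatError(ValueError):
    """Raised when a delimited-text file does not match the expected schema."""


def _collapse_duplicates(
    stretch: np.ndarray, stress: np.ndarray, time: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Average stresses (and times) sharing an identical stretch value.

    Raw biaxial testers emit repeated frames at the same grip position;
    collapsing them keeps the grid strictly increasing.
    """
    uniq, inverse, counts = np.unique(stretch, return_inverse=True, return_counts=True)
    if uniq.size == stretch.size:
        return stretch, stress, time
    mean_stress = np.bincount(inverse, weights=stress) / counts
    mean_time = None
    if time is not None:
        mean_time = np.bincount(inverse, weights=time) / counts
    return uniq, mean_stress, mean_time


@dataclass
class StretchStressCurve:
    """One direction's loading curve: stretch ratio vs Cauchy stress (kPa)."""

    stretch: np.ndarray
    stress: np.ndarray
    direction: str
    time: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")
        self.stretch = np.asarray(self.stretch, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            if self.time.shape != self.stretch.shape:
                raise ValidationError("time and stretch must have equal length")
        if self.stretch.ndim != 1 or self.stretch.shape != self.stress.shape:
            raise ValidationError("stretch and stress must be 1-d and of equal length")
        if not np.all(np.isfinite(self.stretch)) or not np.all(np.isfinite(self.stress)):
            raise ValidationError("stretch and stress must be finite (no NaN/inf)")
        decreasing = np.flatnonzero(np.diff(self.stretch) < 0)
        if decreasing.size:
            # 1-based data-row numbering, matching how testers report frames
            raise ValidationError(
                f"stretch must be non-decreasing; first offending row {decreasing[0] + 2}"
            )
        self.stretch, self.stress, self.time = _collapse_duplicates(
            self.stretch, self.stress, self.time
        )
        if self.stretch.size < 2:
            raise ValidationError("a curve needs at least 2 distinct stretch samples")
        if abs(self.stretch[0] - 1.0) > 1e-9:
            raise ValidationError(
                f"curve must start at the reference state lambda=1, got {self.stretch[0]!r}"
            )

    @property
    def n(self) -> int:
        return self.stretch.size

    @property
    def strain(self) -> np.ndarray:
        """Engineering strain, ``lambda - 1``."""
        return self.stretch - 1.0

    def stress_at(self, lam: float | np.ndarray) -> float | np.ndarray:
        """Linearly interpolated stress at the given stretch ratio(s)."""
        return np.interp(lam, self.stretch, self.stress)

    def resampled(self, grid: np.ndarray) -> "StretchStressCurve":
        return StretchStressCurve(
            stretch=np.asarray(grid, dtype=float),
            stress=np.interp(grid, self.stretch, self.stress),
            direction=self.direction,
        )


@dataclass
class BiaxialTest:
    """One specimen's paired axial/circumferential curves on a common grid."""

    test_id: str
    axial: StretchStressCurve
    circumferential: StretchStressCurve

    def __post_init__(self) -> None:
        if self.axial.direction != AXIAL or self.circumferential.direction != CIRCUMFERENTIAL:
            raise ValidationError("curves assigned to the wrong direction slot")
        if self.axial.n != self.circumferential.n or not np.allclose(
            self.axial.stretch, self.circumferential.stretch, rtol=0, atol=1e-9
        ):
            raise ValidationError(
                f"test {self.test_id}: axial and circumferential curves must share "
                "one equibiaxial stretch grid"
            )

    @property
    def stretch(self) -> np.ndarray:
        return self.axial.stretch

    def curve(self, direction: str) -> StretchStressCurve:
        if direction == AXIAL:
            return self.axial
        if direction == CIRCUMFERENTIAL:
            return self.circumferential
        raise ValidationError(f"unknown direction {direction!r}")

    def scaled(self, factor: float) -> "BiaxialTest":
        return BiaxialTest(
            test_id=self.test_id,
            axial=replace(self.axial, stress=self.axial.stress * factor),
            circumferential=replace(
                self.circumferential, stress=self.circumferential.stress * factor
            ),
        )


@dataclass
class TestEnsemble:
    """An ordered collection of biaxial tests plus optional average record."""

    tests: list[BiaxialTest] = field(default_factory=list)
    mean_test: BiaxialTest | None = None
    stress_scale: float | None = None

    def __post_init__(self) -> None:
        if self.stress_scale is not None and not self.stress_scale > 0:
            raise ValidationError("stress_scale must be positive when set")

    def __len__(self) -> int:
        return len(self.tests)

    def __iter__(self):
        return iter(self.tests)

    def get(self, test_id: str) -> BiaxialTest:
        for t in self.tests:
            if t.test_id == test_id:
                return t
        if self.mean_test is not None and self.mean_test.test_id == test_id:
            return self.mean_test
        raise KeyError(f"no test with id {test_id!r}")

    @property
    def test_ids(self) -> list[str]:
        return [t.test_id for t in self.tests]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_STRETCH_COLS = {AXIAL: "stretch_axial", CIRCUMFERENTIAL: "stretch_circ"}
_STRAIN_COLS = {AXIAL: "strain_axial", CIRCUMFERENTIAL: "strain_circ"}
_STRESS_COLS = {AXIAL: "stress_axial_kPa", CIRCUMFERENTIAL: "stress_circ_kPa"}


def read_biaxial_file(path: str | os.PathLike, delimiter: str = ",") -> BiaxialTest:
    """Read one delimited-text test record.

    Expected columns: optional ``time_s``; per direction either a stretch
    column (``stretch_axial``/``stretch_circ``) or an engineering-strain
    column (``strain_axial``/``strain_circ``, converted via ``lambda = 1 +
    strain``), plus the stress columns ``stress_axial_kPa``/``stress_circ_kPa``.
    """
    try:
        frame = pd.read_csv(path, sep=delimiter)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimited text
        raise FormatError(f"{path}: could not parse delimited text: {exc}") from exc
    frame.columns = [c.strip() for c in frame.columns]
    time = frame["time_s"].to_numpy(float) if "time_s" in frame.columns else None

    curves = {}
    for direction in DIRECTIONS:
        if _STRETCH_COLS[direction] in frame.columns:
            stretch = frame[_STRETCH_COLS[direction]].to_numpy(float)
        elif _STRAIN_COLS[direction] in frame.columns:
            stretch = 1.0 + frame[_STRAIN_COLS[direction]].to_numpy(float)
        else:
            raise FormatError(
                f"{path}: missing column {_STRETCH_COLS[direction]!r} "
                f"(or {_STRAIN_COLS[direction]!r})"
            )
        if _STRESS_COLS[direction] not in frame.columns:
            raise FormatError(f"{path}: missing column {_STRESS_COLS[direction]!r}")
        stress = frame[_STRESS_COLS[direction]].to_numpy(float)
        curves[direction] = StretchStressCurve(
            stretch=stretch, stress=stress, direction=direction, time=time
        )

    test_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return BiaxialTest(test_id=test_id, axial=curves[AXIAL], circumferential=curves[CIRCUMFERENTIAL])


def write_biaxial_file(test: BiaxialTest, path: str | os.PathLike, delimiter: str = ",") -> None:
    """Write a test record; numeric fields keep 17 significant digits."""
    data = {}
    if test.axial.time is not None:
        data["time_s"] = test.axial.time
    data["stretch_axial"] = test.axial.stretch
    data["stress_axial_kPa"] = test.axial.stress
    data["stretch_circ"] = test.circumferential.stretch
    data["stress_circ_kPa"] = test.circumferential.stress
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def read_ensemble(source: str | os.PathLike, delimiter: str = ",") -> TestEnsemble:
    """Load an ensemble from a directory of ``*.csv`` files or a manifest file.

    A manifest is a plain-text file listing one record path per line,
    relative to the manifest's own directory.
    """
    source = os.fspath(source)
    if os.path.isdir(source):
        paths = sorted(glob.glob(os.path.join(source, "*.csv")))
    else:
        base = os.path.dirname(source)
        with open(source) as fh:
            paths = [
                os.path.join(base, line.strip()) for line in fh if line.strip() and not line.startswith("#")
            ]
    if not paths:
        raise FormatError(f"{source}: no test records found")
    tests = [read_biaxial_file(p, delimiter=delimiter) for p in paths]
    mean = None
    plain = [t for t in tests if t.test_id != MEAN_TEST_ID]
    for t in tests:
        if t.test_id == MEAN_TEST_ID:
            mean = t
    return TestEnsemble(tests=plain, mean_test=mean)


# ---------------------------------------------------------------------------
# ensemble operations
# ---------------------------------------------------------------------------


def common_grid(ensemble: TestEnsemble, grid_size: int = 100) -> np.ndarray:
    """Uniform stretch grid spanning the intersection of all tests' ranges."""
    if not ensemble.tests:
        raise ValidationError("ensemble is empty")
    lo = max(t.stretch[0] for t in ensemble.tests)
    hi = min(t.stretch[-1] for t in ensemble.tests)
    if not hi > lo:
        raise ValidationError(f"degenerate stretch overlap: [{lo}, {hi}]")
    return np.linspace(lo, hi, grid_size)


def compute_mean_test(ensemble: TestEnsemble, grid_size: int = 100) -> BiaxialTest:
    """Pointwise-mean record over all member tests, resampled to one grid.

    All tests are linearly interpolated onto a uniform grid spanning the
    intersection of their stretch ranges; the returned record carries the
    conventional id ``"T14"``.
    """
    grid = common_grid(ensemble, grid_size)
    curves = {}
    for direction in DIRECTIONS:
        stresses = np.vstack(
            [t.curve(direction).resampled(grid).stress for t in ensemble.tests]
        )
        curves[direction] = StretchStressCurve(
            stretch=grid, stress=stresses.mean(axis=0), direction=direction
        )
    return BiaxialTest(
        test_id=MEAN_TEST_ID, axial=curves[AXIAL], circumferential=curves[CIRCUMFERENTIAL]
    )


def global_max_stress(ensemble: TestEnsemble) -> float:
    return max(
        float(max(t.axial.stress.max(), t.circumferential.stress.max()))
        for t in ensemble.tests
    )


def normalize_stresses(ensemble: TestEnsemble) -> TestEnsemble:
    """Divide every stress by the single global maximum over the ensemble.

    The maximum is taken over all member tests and both directions; it is
    stored as ``stress_scale`` so that :func:`denormalize_stresses` is an
    exact inverse.  Normalisation protects a saturating network from targets
    far outside its activation range.
    """
    if not ensemble.tests:
        raise ValidationError("ensemble is empty")
    scale = global_max_stress(ensemble)
    if not scale > 0:
        raise ValidationError("all stresses are zero; normalization scale undefined")
    return TestEnsemble(
        tests=[t.scaled(1.0 / scale) for t in ensemble.tests],
        mean_test=None if ensemble.mean_test is None else ensemble.mean_test.scaled(1.0 / scale),
        stress_scale=scale,
    )


def denormalize_stresses(ensemble: TestEnsemble) -> TestEnsemble:
    if ensemble.stress_scale is None:
        raise ValidationError("ensemble carries no stress_scale")
    scale = ensemble.stress_scale
    return TestEnsemble(
        tests=[t.scaled(scale) for t in ensemble.tests],
        mean_test=None if ensemble.mean_test is None else ensemble.mean_test.scaled(scale),
        stress_scale=None,
    )


def strain_rate_profile(curve: StretchStressCurve) -> tuple[np.ndarray, np.ndarray]:
    """Engineering strain rate in %/s along the record's time stamps.

    Central finite differences in the interior, one-sided at the ends.
    """
    if curve.time is None:
        raise ValidationError("curve carries no time stamps")
    if curve.n < 3:
        raise ValidationError("strain-rate profile needs at least 3 samples")
    if np.any(np.diff(curve.time) <= 0):
        raise ValidationError("time stamps must be strictly increasing")
    rate = np.gradient(100.0 * curve.strain, curve.time)
    return curve.time.copy(), rate
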