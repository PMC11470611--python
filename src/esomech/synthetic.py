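"""Synthetic equibiaxial test ensembles.

The generator emulates the statistical envelope of a 13-specimen ovine
esophagus campaign: an equibiaxial ramp to 50% strain over 8.5 s with the
strain rate decaying from about 8 %/s to about 4 %/s, a toe region
extending to roughly 40% strain, linear-region secant moduli of a few
hundred kPa axially (axial stresses a bit more than twice circumferential),
and a minority of "poor" specimens whose curves stay close to the
horizontal axis up to stretch 1.4.

Each specimen is a forward simulation of the Holzapfel-type model along the
equibiaxial path: base parameters are jittered multiplicatively
(log-normal), the model stresses are evaluated on the protocol grid, and
additive Gaussian measurement noise is applied.  A single fiber family at
57.3 degrees from the circumferential axis loads the axial direction through
``sin^2(theta)`` and the circumferential direction through ``cos^2(theta)``,
which reproduces the observed axial-to-circumferential stress ratio of
about 2.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import holzapfel as hz
from .curves import (
    AXIAL,
    CIRCUMFERENTIAL,
    BiaxialTest,
    StretchStressCurve,
    TestEnsemble,
    compute_mean_test,
)

GOOD = "good"
POOR = "poor"

# Stress-like parameters anchor to the published axial-direction estimates,
# scaled so the forward curves land inside the measured envelope (terminal
# axial stress ~40 kPa, toe to ~40% strain, secant moduli in the published
# ranges).  See docs/methods.md for the calibration argument.
_ANCHOR_SCALE = 0.03
_GOOD_PARAMS = hz.HolzapfelParams(
    c=9.0966 * _ANCHOR_SCALE, k1=9.3158 * _ANCHOR_SCALE, k2=1.8472, theta=1.0002
)
# Poor specimens: ground matrix and fiber stiffness cut to 5%, stiffening
# exponent doubled -- the curve hugs the axis up to stretch 1.4 (stress there
# under 10% of its own maximum) yet still rises near the end of the ramp.
_POOR_PARAMS = hz.HolzapfelParams(
    c=_GOOD_PARAMS.c * 0.05, k1=_GOOD_PARAMS.k1 * 0.05, k2=_GOOD_PARAMS.k2 * 2.0,
    theta=_GOOD_PARAMS.theta,
)


@dataclass(frozen=True)
class ProtocolSpec:
    """Displacement-controlled equibiaxial ramp settings."""

    max_strain: float = 0.50  # terminal engineering strain
    duration: float = 8.5  # s
    rate_start: float = 8.0  # %/s at the start of the ramp
    rate_end: float = 4.0  # %/s at the end
    n_samples: int = 100

    def __post_init__(self) -> None:
        if not self.max_strain > 0:
            raise ValueError("max_strain must be positive")
        if not self.rate_start >= self.rate_end > 0:
            raise ValueError("need rate_start >= rate_end > 0")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Statistical recipe for one specimen class."""

    class_label: str = GOOD
    base_params_axial: hz.HolzapfelParams = _GOOD_PARAMS
    base_params_circ: hz.HolzapfelParams = _GOOD_PARAMS
    param_jitter: float = 0.10  # relative (log-normal) spread of the parameters
    noise_sd: float = 1.0  # additive measurement noise, kPa
    axial_to_circ_ratio: float = 2.0  # nominal terminal-stress ratio (informational)

    def __post_init__(self) -> None:
        if self.param_jitter < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise must be non-negative")


GOOD_ARCHETYPE = ArchetypeSpec()
POOR_ARCHETYPE = ArchetypeSpec(
    class_label=POOR, base_params_axial=_POOR_PARAMS, base_params_circ=_POOR_PARAMS
)


def generate_protocol(spec: ProtocolSpec = ProtocolSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Time stamps and stretch ratios of the decaying-rate ramp.

    The strain rate falls linearly from ``rate_start`` to ``rate_end`` over
    the ramp; the whole profile is then rescaled so the terminal strain
    equals ``max_strain`` exactly.
    """
    t = np.linspace(0.0, spec.duration, spec.n_samples)
    # closed-form integral of the linear rate profile (rates are %/s)
    strain = (spec.rate_start * t + (spec.rate_end - spec.rate_start) * t**2 / (2 * spec.duration)) / 100.0
    strain *= spec.max_strain / strain[-1]
    return t, 1.0 + strain


def generate_test(
    archetype: ArchetypeSpec,
    protocol: ProtocolSpec = ProtocolSpec(),
    seed: int | np.random.SeedSequence = 0,
    test_id: str = "T1",
    return_params: bool = False,
) -> BiaxialTest | tuple[BiaxialTest, dict[str, hz.HolzapfelParams]]:
    """Forward-simulate one specimen record.

    Per direction the base parameters are jittered log-normally, the model
    stresses are evaluated along the equibiaxial path (axial direction from
    the zz stress component, circumferential from the tt component), and
    additive Gaussian noise is applied; negative noisy stresses are clipped
    to zero.
    """
    rng = np.random.default_rng(seed)
    time, stretch = generate_protocol(protocol)
    curves = {}
    drawn: dict[str, hz.HolzapfelParams] = {}
    # one specimen, one material: a single set of jitter factors perturbs
    # both directions' base parameters, so the axial-to-circumferential
    # stress ratio set by the fiber angle is preserved per specimen
    factors = (
        np.exp(rng.normal(0.0, archetype.param_jitter, size=4))
        if archetype.param_jitter > 0
        else np.ones(4)
    )
    for direction, base in (
        (AXIAL, archetype.base_params_axial),
        (CIRCUMFERENTIAL, archetype.base_params_circ),
    ):
        params = hz.HolzapfelParams(
            c=base.c * factors[0],
            k1=base.k1 * factors[1],
            k2=base.k2 * factors[2],
            theta=float(np.clip(base.theta * factors[3], 1e-6, np.pi)),
        )
        drawn[direction] = params
        sig_tt, sig_zz = hz.equibiaxial_stresses(params, stretch)
        stress = sig_zz if direction == AXIAL else sig_tt
        if archetype.noise_sd > 0:
            stress = stress + rng.normal(0.0, archetype.noise_sd, size=stress.shape)
        stress = np.clip(stress, 0.0, None)
        curves[direction] = StretchStressCurve(
            stretch=stretch, stress=stress, direction=direction, time=time
        )
    test = BiaxialTest(
        test_id=test_id, axial=curves[AXIAL], circumferential=curves[CIRCUMFERENTIAL]
    )
    return (test, drawn) if return_params else test


def generate_ensemble(
    n_tests: int = 13,
    good_fraction: float = 7.0 / 13.0,
    seed: int = 0,
    protocol: ProtocolSpec = ProtocolSpec(),
    good: ArchetypeSpec = GOOD_ARCHETYPE,
    poor: ArchetypeSpec = POOR_ARCHETYPE,
    grid_size: int = 100,
) -> TestEnsemble:
    """Generate a mixed good/poor ensemble plus its average record.

    A master seed spawns one independent substream per specimen, so
    removing one test does not shift the others.  The first
    ``round(good_fraction * n_tests)`` ids (T1, T2, ...) are good-class
    specimens, the remainder poor-class.  The ensemble-average record is
    appended under id "T14".
    """
    if n_tests < 2:
        raise ValueError("need at least 2 tests")
    n_good = int(round(good_fraction * n_tests))
    children = np.random.SeedSequence(seed).spawn(n_tests)
    tests = []
    for i in range(n_tests):
        archetype = good if i < n_good else poor
        tests.append(
            generate_test(archetype, protocol, seed=children[i], test_id=f"T{i + 1}")
        )
    ensemble = TestEnsemble(tests=tests)
    ensemble.mean_test = compute_mean_test(ensemble, grid_size=grid_size)
    mean_ax = ensemble.mean_test.axial.stress[-1]
    mean_ci = ensemble.mean_test.circumferential.stress[-1]
    if not mean_ax > mean_ci:
        raise RuntimeError(
            "generated ensemble violates the axial > circumferential stress ordering"
        )
    return ensemble


def class_labels(n_tests: int = 13, good_fraction: float = 7.0 / 13.0) -> dict[str, str]:
    """Ground-truth archetype labels by test id, as assigned by the generator."""
    n_good = int(round(good_fraction * n_tests))
    return {f"T{i + 1}": (GOOD if i < n_good else POOR) for i in range(n_tests)}
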