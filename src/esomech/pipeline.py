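"""End-to-end analysis: curation, constitutive fit, surrogate training, scoring.

The full run mirrors the study workflow: load or generate an ensemble of
equibiaxial tests, normalize all stresses by the global maximum, classify
every specimen, fit the Holzapfel model to the designated training test,
derive the three training-target kinds (raw / linear / constitutive fit),
cyclically train one NARX network per kind and direction, simulate every
network closed-loop on every test, and summarize fit errors, correlations
and the across-kind ANOVA.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import curation, evaluation, holzapfel as hz, narx, synthetic
from .curves import (
    AXIAL,
    CIRCUMFERENTIAL,
    DIRECTIONS,
    BiaxialTest,
    StretchStressCurve,
    TestEnsemble,
    normalize_stresses,
    read_ensemble,
)

log = logging.getLogger("esomech.pipeline")

_MODEL_NAMES = {"raw": "raw_narx", "linear": "linear_narx", "holzapfel": "holzapfel_narx"}


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run; one master seed drives
    every random operation."""

    source: str = "synthetic"  # "synthetic" or a directory/manifest path
    n_tests: int = 13
    good_fraction: float = 7.0 / 13.0
    training_test: str = "T6"
    kinds: tuple[str, ...] = ("raw", "linear", "holzapfel")
    seed: int = 1
    outdir: str | None = None
    grid_size: int = 100
    training: narx.TrainingConfig = field(default_factory=narx.TrainingConfig)
    narx_arch: narx.NarxArchitecture = field(default_factory=narx.NarxArchitecture)
    fit_mode: str = "per-direction"

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        training = narx.TrainingConfig(**raw.pop("training", {}))
        arch = narx.NarxArchitecture(**raw.pop("narx_arch", {}))
        if "kinds" in raw:
            raw["kinds"] = tuple(raw["kinds"])
        return cls(training=training, narx_arch=arch, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kinds"] = list(self.kinds)
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    ensemble: TestEnsemble  # normalized; stress_scale carries the kPa maximum
    classification: pd.DataFrame
    fit_result: hz.FitResult
    networks: dict[tuple[str, str], narx.NarxWeights]
    training_reports: dict[tuple[str, str], list[narx.TrainingReport]]
    fit_table: pd.DataFrame
    anova: dict[str, evaluation.AnovaResult]
    strain_energy: pd.DataFrame
    predictions: dict[tuple[str, str, str], np.ndarray]  # (kind, test_id, direction)


def _load_ensemble(config: PipelineConfig) -> TestEnsemble:
    if config.source == "synthetic":
        return synthetic.generate_ensemble(
            n_tests=config.n_tests,
            good_fraction=config.good_fraction,
            seed=config.seed,
            grid_size=config.grid_size,
        )
    return read_ensemble(config.source)


def simulate_network_on_test(
    w: narx.NarxWeights, test: BiaxialTest, direction: str, stress_scale: float
) -> np.ndarray:
    """Closed-loop simulation of a trained network on one (kPa) record.

    The input is the test's strain sequence; the delay line is primed with
    the test's first measured stresses on the normalized scale.  Returns
    predicted stresses in kPa.
    """
    curve = test.curve(direction)
    d = w.arch.max_delay
    y_prime = curve.stress[:d] / stress_scale
    yhat = narx.simulate_closed_loop(w, curve.strain, y_prime)
    return yhat * stress_scale


def run_full_analysis(config: PipelineConfig) -> PipelineResult:
    """Execute every stage; deterministic under a fixed config seed."""
    stage = "load"
    try:
        ensemble_kpa = _load_ensemble(config)
        log.info("loaded %d tests", len(ensemble_kpa))

        stage = "normalize"
        ensemble = normalize_stresses(ensemble_kpa)
        scale = ensemble.stress_scale
        log.info("global stress scale %.4g kPa", scale)

        stage = "classify"
        classification = curation.classification_report(ensemble_kpa.tests)

        stage = "fit_holzapfel"
        training_test_kpa = ensemble_kpa.get(config.training_test)
        fit_result = hz.fit_holzapfel(training_test_kpa, mode=config.fit_mode)
        for direction in DIRECTIONS:
            p = fit_result.params[direction]
            log.info(
                "%s fit: c=%.4g k1=%.4g k2=%.4g theta=%.4g rad (%.1f deg)",
                direction, p.c, p.k1, p.k2, p.theta, hz.theta_degrees(p),
            )

        stage = "train"
        networks: dict[tuple[str, str], narx.NarxWeights] = {}
        reports: dict[tuple[str, str], list[narx.TrainingReport]] = {}
        for ki, kind in enumerate(config.kinds):
            for di, direction in enumerate(DIRECTIONS):
                u, target, _ = curation.build_training_curve(
                    training_test_kpa,
                    kind,
                    direction,
                    stress_scale=scale,
                    holz_params=fit_result.params[direction] if kind == "holzapfel" else None,
                )
                sub_seed = int(
                    np.random.SeedSequence([config.seed, 100 + ki * 2 + di]).generate_state(1)[0]
                    % (2**31)
                )
                w0 = narx.init_weights(config.narx_arch, seed=sub_seed)
                cfg = dataclasses.replace(config.training, seed=sub_seed)
                w, reps = narx.cyclic_train(w0, u, target, cfg, stress_scale=scale)
                networks[(kind, direction)] = w
                reports[(kind, direction)] = reps
                log.info(
                    "trained %s/%s: final mse %.3g, stop=%s",
                    kind, direction, reps[-1].final_mse, reps[-1].stop_reason,
                )

        stage = "simulate"
        fit_reports: list[evaluation.FitReport] = []
        predictions: dict[tuple[str, str, str], np.ndarray] = {}
        for kind in config.kinds:
            for test in ensemble_kpa.tests:
                pred_curves = {}
                for direction in DIRECTIONS:
                    yhat = simulate_network_on_test(
                        networks[(kind, direction)], test, direction, scale
                    )
                    predictions[(kind, test.test_id, direction)] = yhat
                    pred_curves[direction] = StretchStressCurve(
                        stretch=test.stretch, stress=np.clip(yhat, 0.0, None),
                        direction=direction,
                    )
                pred_test = BiaxialTest(
                    test_id=test.test_id,
                    axial=pred_curves[AXIAL],
                    circumferential=pred_curves[CIRCUMFERENTIAL],
                )
                fit_reports.append(
                    evaluation.score_prediction(
                        pred_test, test, q=0, model=_MODEL_NAMES[kind]
                    )
                )

        stage = "summarize"
        fit_table = evaluation.summarize_fit_table(fit_reports)
        anova = {}
        if len(config.kinds) >= 2:
            for direction, col in ((AXIAL, "fit_error_axial"), (CIRCUMFERENTIAL, "fit_error_circ")):
                groups = [
                    fit_table.loc[fit_table.index != "Mean", f"{col}_{_MODEL_NAMES[k]}"].to_numpy()
                    for k in config.kinds
                ]
                anova[direction] = evaluation.anova_single_factor(groups)
                log.info(
                    "%s across-kind ANOVA: F=%.4f p=%.4g", direction,
                    anova[direction].f_stat, anova[direction].p_value,
                )

        grid = np.linspace(1.0, training_test_kpa.stretch[-1], config.grid_size)
        energy = {
            "stretch": grid,
            **{
                f"W_{direction}_kPa": [
                    hz.strain_energy(
                        fit_result.params[direction], hz.StretchState(lam, lam)
                    )
                    for lam in grid
                ]
                for direction in DIRECTIONS
            },
        }
        strain_energy = pd.DataFrame(energy)

        result = PipelineResult(
            config=config,
            ensemble=ensemble,
            classification=classification,
            fit_result=fit_result,
            networks=networks,
            training_reports=reports,
            fit_table=fit_table,
            anova=anova,
            strain_energy=strain_energy,
            predictions=predictions,
        )
        if config.outdir:
            write_outputs(result, config.outdir)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def write_outputs(result: PipelineResult, outdir: str | os.PathLike) -> None:
    outdir = os.fspath(outdir)
    os.makedirs(os.path.join(outdir, "weights"), exist_ok=True)
    params_rows = [
        dict(direction=direction, **dataclasses.asdict(result.fit_result.params[direction]),
             theta_deg=hz.theta_degrees(result.fit_result.params[direction]))
        for direction in DIRECTIONS
    ]
    pd.DataFrame(params_rows).to_csv(os.path.join(outdir, "params.csv"), index=False)
    result.fit_table.to_csv(os.path.join(outdir, "fit_table.csv"))
    result.classification.to_csv(os.path.join(outdir, "classification.csv"), index=False)
    for direction, name in ((AXIAL, "anova_axial.csv"), (CIRCUMFERENTIAL, "anova_circ.csv")):
        if direction in result.anova:
            result.anova[direction].to_frame().to_csv(os.path.join(outdir, name), index=False)
    result.strain_energy.to_csv(os.path.join(outdir, "strain_energy.csv"), index=False)
    for (kind, direction), w in result.networks.items():
        narx.save_weights(w, os.path.join(outdir, "weights", f"{kind}_{direction}.txt"))
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(result.config.to_dict(), fh)
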