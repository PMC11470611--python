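"""Scoring of stress predictions and one-way ANOVA summaries.

Per-test scores are the normalized RMS fitting error and the Pearson
correlation between predicted and observed stresses, per direction.  The
single-factor ANOVA compares groups of such scores; its full sum-of-squares
decomposition is emitted so the classical summary table (SS/df/MS/F/p/F
crit) can be written out.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from . import holzapfel as hz
from .curves import AXIAL, CIRCUMFERENTIAL, BiaxialTest

_ERROR_COLUMNS = [
    "err_axial_holzapfel",
    "err_circ_holzapfel",
    "err_axial_linear",
    "err_circ_linear",
    "err_axial_raw",
    "err_circ_raw",
]


@dataclass
class FitReport:
    """Per-test prediction score in the comparison-table schema."""

    test_id: str
    model: str  # e.g. "holzapfel_narx", "linear_narx", "raw_narx", "holzapfel_direct"
    fit_error_axial: float
    fit_error_circ: float
    corr_axial: float
    corr_circ: float


@dataclass
class AnovaResult:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    f_stat: float
    p_value: float
    f_crit: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(source="between_groups", SS=self.ss_between, df=self.df_between,
                     MS=self.ms_between, F=self.f_stat, p_value=self.p_value,
                     F_crit=self.f_crit),
                dict(source="within_groups", SS=self.ss_within, df=self.df_within,
                     MS=self.ms_within, F=np.nan, p_value=np.nan, F_crit=np.nan),
                dict(source="total", SS=self.ss_total, df=self.df_between + self.df_within,
                     MS=np.nan, F=np.nan, p_value=np.nan, F_crit=np.nan),
            ]
        )


def score_prediction(
    pred: BiaxialTest, obs: BiaxialTest, q: int = 0, model: str = "narx"
) -> FitReport:
    """Score a predicted record against the measured one, per direction.

    ``q`` is the number of parameters the scored model fitted *to this very
    record* -- 0 for a network simulated on fresh data, 4 for a direct
    constitutive fit.
    """
    if pred.stretch.size != obs.stretch.size or not np.allclose(
        pred.stretch, obs.stretch, rtol=0, atol=1e-9
    ):
        raise ValueError("prediction and observation grids do not match")
    return FitReport(
        test_id=obs.test_id,
        model=model,
        fit_error_axial=hz.fit_error_metric(pred.axial.stress, obs.axial.stress, q=q),
        fit_error_circ=hz.fit_error_metric(
            pred.circumferential.stress, obs.circumferential.stress, q=q
        ),
        corr_axial=hz.correlation_coefficient(pred.axial.stress, obs.axial.stress),
        corr_circ=hz.correlation_coefficient(
            pred.circumferential.stress, obs.circumferential.stress
        ),
    )


def summarize_fit_table(reports: list[FitReport]) -> pd.DataFrame:
    """Wide per-test table (one row per test, models side by side) + mean row."""
    if not reports:
        raise ValueError("no reports to summarize")
    frame = pd.DataFrame(
        [
            dict(
                test_id=r.test_id,
                model=r.model,
                fit_error_axial=r.fit_error_axial,
                fit_error_circ=r.fit_error_circ,
                corr_axial=r.corr_axial,
                corr_circ=r.corr_circ,
            )
            for r in reports
        ]
    )
    wide = frame.pivot_table(
        index="test_id",
        columns="model",
        values=["fit_error_axial", "fit_error_circ", "corr_axial", "corr_circ"],
        sort=False,
    )
    wide.columns = [f"{metric}_{model}" for metric, model in wide.columns]
    wide = wide.reindex(sorted(wide.index, key=lambda s: (len(s), s)))
    wide.loc["Mean"] = wide.mean(axis=0)
    return wide


def anova_single_factor(groups: list[np.ndarray], alpha: float = 0.05) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA on >= 2 groups of values."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need at least two groups with at least two values each")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    if ss_within == 0 and ss_between == 0:
        raise ValueError("all values identical across all groups; F undefined")
    df_between = len(groups) - 1
    df_within = allv.size - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f_stat = ms_between / ms_within
    return AnovaResult(
        ss_between=ss_between,
        ss_within=ss_within,
        ss_total=ss_between + ss_within,
        df_between=df_between,
        df_within=df_within,
        ms_between=ms_between,
        ms_within=ms_within,
        f_stat=f_stat,
        p_value=float(stats.f.sf(f_stat, df_between, df_within)),
        f_crit=float(stats.f.ppf(1.0 - alpha, df_between, df_within)),
        alpha=alpha,
    )


def group_summary(groups: list[np.ndarray], names: list[str] | None = None) -> pd.DataFrame:
    """Count/sum/average/variance block accompanying the ANOVA table."""
    names = names or [f"Column {i + 1}" for i in range(len(groups))]
    return pd.DataFrame(
        [
            dict(group=name, count=g.size, sum=float(np.sum(g)),
                 average=float(np.mean(g)), variance=float(np.var(g, ddof=1)))
            for name, g in zip(names, (np.asarray(g, float) for g in groups))
        ]
    )


def compare_training_classes(
    groups_a: list[np.ndarray], groups_b: list[np.ndarray], alpha: float = 0.05
) -> tuple[AnovaResult, AnovaResult]:
    """One-way ANOVA on two sets of correlation columns drawn from the two
    data classes; each result flags significance at the given level."""
    return (
        anova_single_factor(groups_a, alpha=alpha),
        anova_single_factor(groups_b, alpha=alpha),
    )


# ---------------------------------------------------------------------------
# packaged transcriptions of the published result tables
# ---------------------------------------------------------------------------


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("esomech.fixtures").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_fit_error_table() -> pd.DataFrame:
    """Published per-test fit errors and correlations (13 tests x 3 models)."""
    return _fixture("table2_fit_errors.csv").set_index("test_id")


def load_class_correlation_table() -> pd.DataFrame:
    """Published correlation columns for two tests per data class."""
    return _fixture("table4_correlations.csv")


def load_published_params() -> dict[str, hz.HolzapfelParams]:
    """Published per-direction constitutive parameters."""
    frame = _fixture("table5_params.csv")
    out = {}
    for _, row in frame.iterrows():
        out[row["direction"]] = hz.HolzapfelParams(
            c=row["c_kPa"], k1=row["k1_kPa"], k2=row["k2"], theta=row["theta_rad"]
        )
    return out


def published_error_anova(alpha: float = 0.05) -> dict[str, AnovaResult]:
    """One-way ANOVA across the three training-curve kinds, per direction,
    on the published per-test fit errors."""
    table = load_fit_error_table()
    axial = [table[c].to_numpy() for c in _ERROR_COLUMNS[::2]]
    circ = [table[c].to_numpy() for c in _ERROR_COLUMNS[1::2]]
    return {
        AXIAL: anova_single_factor(axial, alpha=alpha),
        CIRCUMFERENTIAL: anova_single_factor(circ, alpha=alpha),
    }


def published_class_anova(alpha: float = 0.05) -> tuple[AnovaResult, AnovaResult]:
    """The two published four-column class-comparison ANOVAs."""
    table = load_class_correlation_table()
    a = [table[c].to_numpy() for c in table.columns if c.startswith("a_")]
    b = [table[c].to_numpy() for c in table.columns if c.startswith("b_")]
    return compare_training_classes(a, b, alpha=alpha)
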