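"""Correlation and hierarchical incremental-validity regression.

The actual health behavior index is regressed on the network's five wave
estimates in four fixed steps: (1) health-cognition estimate, (2) +
personality estimate, (3) + lifestyle-cognition and lifestyle-activity
estimates together, (4) + baseline-health estimate.  Each step reports the
cumulative adjusted R-squared, the change in both raw and adjusted R-squared
(reports print both, since the two conventions differ and published tables do
not always say which they used), the F-change test computed from the raw
R-squared difference, and standardized betas for every predictor currently in
the model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .network import WaveSet
from .data import BLOCK_NAMES

logger = logging.getLogger(__name__)

#: entry order of the wave estimates (step 3 enters two predictors at once)
STEP_PLAN: tuple[tuple[str, ...], ...] = (
    ("health_cognitions",),
    ("personality",),
    ("lifestyle_cognitions", "lifestyle_activities"),
    ("baseline_health",),
)

_COND_WARN = 1e10


@dataclass
class RegressionStep:
    step_index: int
    entered: tuple[str, ...]
    predictors: tuple[str, ...]  # all predictors in the model at this step
    r_squared: float
    adj_r_squared: float
    delta_r_squared: float
    delta_adj_r_squared: float
    f_change: float
    df: tuple[int, int]
    p_value: float
    betas: dict[str, float] = field(default_factory=dict)


@dataclass
class HierarchicalRegressionResult:
    correlations: dict[str, float]
    steps: list[RegressionStep]
    final_adj_r_squared: float
    final_f: float
    final_df: tuple[int, int]
    final_p: float
    n: int

    def to_json_dict(self) -> dict:
        return {
            "n": self.n,
            "correlations": self.correlations,
            "steps": [
                {
                    "step": s.step_index,
                    "entered": list(s.entered),
                    "r_squared": s.r_squared,
                    "adj_r_squared": s.adj_r_squared,
                    "delta_r_squared": s.delta_r_squared,
                    "delta_adj_r_squared": s.delta_adj_r_squared,
                    "f_change": s.f_change,
                    "df": list(s.df),
                    "p_value": s.p_value,
                    "betas": s.betas,
                }
                for s in self.steps
            ],
            "final": {
                "adj_r_squared": self.final_adj_r_squared,
                "f": self.final_f,
                "df": list(self.final_df),
                "p": self.final_p,
            },
        }


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance vector cannot be standardized")
    return (v - v.mean()) / sd


def correlate_waves(waves: WaveSet, y) -> dict[str, float]:
    """Pearson r between each non-saturated wave's estimates and the index."""
    y = np.asarray(y, dtype=float).ravel()
    out: dict[str, float] = {}
    for name in BLOCK_NAMES:
        est = waves[name].estimates
        if np.std(est) == 0:
            raise ValueError(f"wave {name!r} produced zero-variance estimates")
        out[name] = float(stats.pearsonr(est, y).statistic)
    return out


def _ols(Xcols: list[np.ndarray], y: np.ndarray):
    X = sm.add_constant(np.column_stack(Xcols))
    cond = np.linalg.cond(X)
    if cond > _COND_WARN:
        warnings.warn(f"near-collinear design (condition number {cond:.2e}); pseudo-inverse fit", stacklevel=3)
    model = sm.OLS(y, X).fit()
    return model


def hierarchical_regression(waves: WaveSet, y) -> HierarchicalRegressionResult:
    """Four-step hierarchical OLS of the index on the wave estimates."""
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    z_y = _zscore(y)
    z_est = {name: _zscore(np.asarray(waves[name].estimates, dtype=float)) for name in BLOCK_NAMES}

    steps: list[RegressionStep] = []
    entered: list[str] = []
    prev_r2 = 0.0
    for i, new in enumerate(STEP_PLAN, start=1):
        entered.extend(new)
        p_full = len(entered)
        if n <= p_full + 1:
            raise ValueError(f"n = {n} too small for {p_full} predictors")
        model = _ols([z_est[m] for m in entered], z_y)
        r2 = float(model.rsquared)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p_full - 1)
        q = len(new)
        df2 = n - p_full - 1
        num = (r2 - prev_r2) / q
        den = (1.0 - r2) / df2
        if den <= 0:
            f_change = 0.0 if num <= 0 else float("inf")
        else:
            f_change = num / den
        p_value = float(stats.f.sf(f_change, q, df2)) if np.isfinite(f_change) else 0.0
        betas = {m: float(model.params[j + 1]) for j, m in enumerate(entered)}
        prev_adj = steps[-1].adj_r_squared if steps else 0.0
        steps.append(
            RegressionStep(
                step_index=i,
                entered=tuple(new),
                predictors=tuple(entered),
                r_squared=r2,
                adj_r_squared=adj,
                delta_r_squared=r2 - prev_r2,
                delta_adj_r_squared=adj - prev_adj,
                f_change=float(f_change),
                df=(q, df2),
                p_value=p_value,
                betas=betas,
            )
        )
        prev_r2 = r2

    final = steps[-1]
    p_full = len(final.predictors)
    df2 = n - p_full - 1
    r2 = final.r_squared
    f_final = (r2 / p_full) / ((1 - r2) / df2) if r2 < 1 else float("inf")
    p_final = float(stats.f.sf(f_final, p_full, df2)) if np.isfinite(f_final) else 0.0
    return HierarchicalRegressionResult(
        correlations=correlate_waves(waves, y),
        steps=steps,
        final_adj_r_squared=final.adj_r_squared,
        final_f=float(f_final),
        final_df=(p_full, df2),
        final_p=p_final,
        n=n,
    )


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

_LABELS = {
    "health_cognitions": "Health behavior cognitions",
    "personality": "Personality factors",
    "lifestyle_cognitions": "Lifestyle cognitions",
    "lifestyle_activities": "Ongoing lifestyle activities",
    "baseline_health": "Baseline health behaviors",
}


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return ""


def render_regression_table(result: HierarchicalRegressionResult) -> str:
    """Regression summary as TSV: one row per predictor type, step-wise betas."""
    header = ["Step", "Predictor", "r", "Adj R2", "Adj R2 change", "R2 change", "F change"]
    header += [f"Step {i} beta" for i in range(1, len(result.steps) + 1)]
    lines = ["\t".join(header)]
    for step in result.steps:
        for j, name in enumerate(step.entered):
            cells = [
                str(step.step_index) if j == 0 else "",
                _LABELS.get(name, name),
                f"{result.correlations[name]:.2f}",
            ]
            if j == len(step.entered) - 1:  # step statistics on the last row of the step
                cells += [
                    f"{step.adj_r_squared:.2f}",
                    f"{step.delta_adj_r_squared:.2f}{_stars(step.p_value)}",
                    f"{step.delta_r_squared:.2f}",
                    f"{step.f_change:.2f}",
                ]
            else:
                cells += ["", "", "", ""]
            for later in result.steps:
                cells.append(f"{later.betas[name]:.2f}" if name in later.betas else "")
            lines.append("\t".join(cells))
    lines.append(
        "\t".join(
            [
                "Final",
                f"F({result.final_df[0]}, {result.final_df[1]}) = {result.final_f:.2f}{_stars(result.final_p)}",
                "",
                f"{result.final_adj_r_squared:.2f}",
            ]
        )
    )
    return "\n".join(lines) + "\n"
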