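"""Regression performance measures for drug-response prediction.

Three measures are reported for a prediction vector f against labels y:

* coefficient of determination  R^2 = 1 - SS_res / SS_tot,
  with SS_tot = sum (y_i - ybar)^2 and SS_res = sum (y_i - f_i)^2
  (SS_reg = sum (f_i - ybar)^2 is carried along for completeness);
* Pearson correlation  Rp = cov(Y, F) / (sigma_Y * sigma_F), using
  population (1/n) moments;
* RMSE = sqrt(mean (y_i - f_i)^2).

Repeated runs are summarized by the per-metric mean and top quartile
(75th percentile, linear interpolation).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["UndefinedMetricError", "MetricsReport", "evaluate",
           "summarize_repetitions"]


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. zero label variance)."""


@dataclass(frozen=True)
class MetricsReport:
    r2: float
    rp: float
    rmse: float
    n: int
    ss_tot: float
    ss_reg: float
    ss_res: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    def to_csv_row(self) -> str:
        return f"{self.r2:.6f},{self.rp:.6f},{self.rmse:.6f},{self.n}"

    @staticmethod
    def csv_header() -> str:
        return "r2,rp,rmse,n"


def evaluate(labels, predictions) -> MetricsReport:
    """Compute R^2, Rp and RMSE for predictions against labels."""
    y = np.asarray(labels, dtype=float)
    f = np.asarray(predictions, dtype=float)
    if y.shape != f.shape or y.ndim != 1:
        raise ValueError(f"shape mismatch: labels {y.shape} vs predictions {f.shape}")
    n = y.size
    if n < 2:
        raise ValueError("need at least two observations")

    ybar = y.mean()
    ss_tot = float(((y - ybar) ** 2).sum())
    ss_reg = float(((f - ybar) ** 2).sum())
    ss_res = float(((y - f) ** 2).sum())
    if ss_tot == 0.0:
        raise UndefinedMetricError("R2 and Rp undefined: labels have zero variance")
    sigma_f = f.std()  # population
    cov = float(((y - ybar) * (f - f.mean())).mean())
    # Constant predictions leave Rp 0/0; report NaN so R2 (well-defined: 1
    # minus residual fraction) is still usable for the null model.
    rp = cov / (y.std() * sigma_f) if sigma_f > 0.0 else float("nan")
    return MetricsReport(
        r2=1.0 - ss_res / ss_tot,
        rp=rp,
        rmse=float(np.sqrt(ss_res / n)),
        n=n,
        ss_tot=ss_tot,
        ss_reg=ss_reg,
        ss_res=ss_res,
    )


def summarize_repetitions(reports: list[MetricsReport]) -> dict[str, dict[str, float]]:
    """Mean and top quartile of each metric across repeated runs."""
    if not reports:
        raise ValueError("no reports to summarize")
    out: dict[str, dict[str, float]] = {}
    for metric in ("r2", "rp", "rmse"):
        vals = np.array([getattr(r, metric) for r in reports])
        out[metric] = {
            "mean": float(vals.mean()),
            "top_quartile": float(np.percentile(vals, 75)),
        }
    return out
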