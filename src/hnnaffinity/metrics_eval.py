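"""Regression metrics and the repeated-simulation evaluation protocol.

For predictions yhat and observations y of length n:

    MSE  = sum((yhat_i - y_i)^2) / n
    RMSE = sqrt(MSE)
    MAE  = sum(|yhat_i - y_i|) / n
    PCC  = cov(yhat, y) / (sd(yhat) * sd(y))

PCC uses the population (divide-by-n) convention consistently in both
numerator and denominator, so it equals the n-1 version exactly.  A
zero-variance vector leaves the PCC undefined (``None``), while the
error metrics are still reported.

Because the neural network's fit varies between random seeds, models
are evaluated by repeating the train+predict cycle (default 10
simulations with consecutive seeds) on a fixed split and averaging the
per-simulation metric reports; the spread (SD and interquartile range)
is reported alongside the means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class MetricReport:
    rmse: float
    mae: float
    mse: float
    pcc: float | None
    n: int

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "mse": self.mse,
                "pcc": self.pcc, "n": self.n}


@dataclass
class RepeatedReport:
    per_sim: list[MetricReport]
    mean_report: MetricReport
    spread: dict[str, dict[str, float]]
    manifest: list[str] | None = None

    @property
    def n_sims(self) -> int:
        return len(self.per_sim)


def compute_metrics(predicted: Sequence[float], observed: Sequence[float]) -> MetricReport:
    yhat = np.asarray(predicted, dtype=np.float64)
    y = np.asarray(observed, dtype=np.float64)
    if yhat.shape != y.shape or yhat.ndim != 1:
        raise ValueError(f"shape mismatch: {yhat.shape} vs {y.shape}")
    n = y.shape[0]
    if n == 0:
        raise ValueError("cannot compute metrics on empty vectors")
    if not (np.all(np.isfinite(yhat)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in inputs")
    err = yhat - y
    mse = float(np.mean(err ** 2))
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(mse))
    pcc: float | None = None
    if n >= 2:
        sd_hat = float(np.std(yhat))
        sd_obs = float(np.std(y))
        if sd_hat > 0 and sd_obs > 0:
            cov = float(np.mean((yhat - yhat.mean()) * (y - y.mean())))
            pcc = cov / (sd_hat * sd_obs)
    return MetricReport(rmse=rmse, mae=mae, mse=mse, pcc=pcc, n=n)


_METRICS = ("rmse", "mae", "mse", "pcc")


def aggregate(reports: Sequence[MetricReport],
              manifest: Sequence[str] | None = None) -> RepeatedReport:
    """Field-wise mean and spread (SD, IQR) over per-simulation reports."""
    if not reports:
        raise ValueError("no reports to aggregate")
    values = {
        m: np.array([getattr(r, m) for r in reports], dtype=np.float64)
        if all(getattr(r, m) is not None for r in reports) else None
        for m in _METRICS
    }
    means = {m: (float(v.mean()) if v is not None else None)
             for m, v in values.items()}
    mean_report = MetricReport(
        rmse=means["rmse"], mae=means["mae"], mse=means["mse"],
        pcc=means["pcc"], n=reports[0].n,
    )
    spread = {}
    for m, v in values.items():
        if v is None:
            continue
        q1, q3 = np.percentile(v, [25, 75])
        spread[m] = {"sd": float(v.std()), "iqr": float(q3 - q1)}
    return RepeatedReport(per_sim=list(reports), mean_report=mean_report,
                          spread=spread,
                          manifest=list(manifest) if manifest else None)


def run_repeated(
    train_fn: Callable[[int], np.ndarray],
    observed: Sequence[float],
    n_sims: int = 10,
    base_seed: int = 0,
    manifest: Sequence[str] | None = None,
) -> RepeatedReport:
    """Repeat train+predict over seeds base_seed..base_seed+n_sims-1.

    ``train_fn(seed)`` must return predictions aligned with ``observed``
    (the split is fixed; only the seed varies).  Any simulation failure
    aborts the whole run with the failing seed identified.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    reports = []
    for seed in range(base_seed, base_seed + n_sims):
        try:
            pred = train_fn(seed)
            reports.append(compute_metrics(pred, observed))
        except Exception as exc:
            raise RuntimeError(f"simulation with seed {seed} failed: {exc}") from exc
    return aggregate(reports, manifest=manifest)


def compare_arms(reports: Mapping[str, RepeatedReport]) -> pd.DataFrame:
    """Mean +/- SD and IQR per metric for each evaluation arm.

    All arms must have been evaluated on the same test manifest when
    manifests are recorded.
    """
    manifests = {name: r.manifest for name, r in reports.items()
                 if r.manifest is not None}
    if len({tuple(m) for m in manifests.values()}) > 1:
        raise ValueError(f"arms evaluated on different test manifests: "
                         f"{sorted(manifests)}")
    rows = []
    for name, rep in reports.items():
        row: dict[str, object] = {"arm": name, "n_sims": rep.n_sims,
                                  "n_test": rep.mean_report.n}
        for m in _METRICS:
            row[f"{m}_mean"] = getattr(rep.mean_report, m)
            row[f"{m}_sd"] = rep.spread.get(m, {}).get("sd")
            row[f"{m}_iqr"] = rep.spread.get(m, {}).get("iqr")
        rows.append(row)
    return pd.DataFrame(rows).set_index("arm")
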