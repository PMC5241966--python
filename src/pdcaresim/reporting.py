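"""Replication statistics, scenario comparison, and table export.

Replication means are summarised with empirical 95% intervals (2.5th and
97.5th percentiles across replications, linear interpolation): published
replication intervals are asymmetric about the mean, which a symmetric
t-interval cannot produce.  A Student-t interval is available by option.

Percent changes between scenarios are computed from unrounded means;
rounding (whole visits, whole percents, 2 d.p. FTEs) is applied only when
rendering, never fed back into computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .accounting import INDICATOR_ORDER, all_indicators
from .config import ParameterSet
from .engine import ReplicationResult

__all__ = [
    "SummaryStatistic",
    "summarize",
    "summarize_experiment",
    "compare_scenarios",
    "export_results",
    "load_results",
    "render_percent",
    "INDICATOR_FAMILIES",
]

#: Indicator families mirroring the published table layout.
INDICATOR_FAMILIES: dict[str, tuple[str, ...]] = {
    "activity": tuple(n for n in INDICATOR_ORDER if n.endswith("_visits")),
    "resources": tuple(
        n for n in INDICATOR_ORDER if n.endswith("_hours") or n.endswith("_fte")
    ),
    "costs": tuple(n for n in INDICATOR_ORDER if n.endswith("_cost")),
}


@dataclass(frozen=True)
class SummaryStatistic:
    """Mean and 95% interval of one indicator across replications."""

    indicator: str
    mean: float
    lci: float
    uci: float


def summarize(values: Sequence[float], indicator: str = "",
              method: str = "percentile") -> SummaryStatistic:
    """Mean and 95% interval of per-replication values.

    ``method='percentile'`` (default) uses the empirical 2.5th/97.5th
    percentiles with linear interpolation; ``method='t'`` uses the
    Student-t interval for the mean.  Requires at least 2 values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("summarize requires at least 2 replication values")
    mean = float(arr.mean())
    if method == "percentile":
        lci, uci = (float(q) for q in np.quantile(arr, [0.025, 0.975]))
    elif method == "t":
        sem = stats.sem(arr)
        if sem == 0:
            lci = uci = mean
        else:
            lci, uci = stats.t.interval(0.95, df=arr.size - 1, loc=mean, scale=sem)
    else:
        raise ValueError(f"unknown interval method {method!r}")
    return SummaryStatistic(indicator=indicator, mean=mean,
                            lci=float(lci), uci=float(uci))


def summarize_experiment(results: Iterable[ReplicationResult], p: ParameterSet,
                         method: str = "percentile") -> pd.DataFrame:
    """Per-indicator mean/lci/uci across an experiment's replications.

    The returned frame is the machine twin of one scenario column of the
    published results tables: indexed by indicator, columns
    ``mean``, ``lci``, ``uci``.
    """
    rows = [all_indicators(r.ledger, p) for r in results]
    frame = pd.DataFrame(rows, columns=list(INDICATOR_ORDER))
    summary = {
        name: summarize(frame[name].to_numpy(), name, method=method)
        for name in INDICATOR_ORDER
    }
    return pd.DataFrame(
        {
            "mean": {k: s.mean for k, s in summary.items()},
            "lci": {k: s.lci for k, s in summary.items()},
            "uci": {k: s.uci for k, s in summary.items()},
        }
    ).loc[list(INDICATOR_ORDER)]


def compare_scenarios(base: pd.DataFrame, scen: pd.DataFrame) -> pd.DataFrame:
    """Per-indicator percent change of scenario means against baseline.

    ``percent_change = 100 x (scenario - baseline) / baseline`` from
    unrounded means; a zero baseline with nonzero scenario mean yields NaN
    (undefined, not an error).
    """
    if not base.index.equals(scen.index):
        raise ValueError("baseline and scenario tables must share an indicator set")
    baseline_mean = base["mean"]
    scenario_mean = scen["mean"]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (scenario_mean - baseline_mean) / baseline_mean
    pct = pct.where(baseline_mean != 0, np.where(scenario_mean == 0, 0.0, np.nan))
    return pd.DataFrame(
        {
            "baseline_mean": baseline_mean,
            "scenario_mean": scenario_mean,
            "percent_change": pct,
        }
    )


def render_percent(x: float, decimals: int = 0) -> str:
    """Render a percent change for display: whole percents by default
    (``-25.26`` prints ``-25``), with ``decimals=1`` available where a
    sub-point difference between scenarios would otherwise be hidden."""
    if np.isnan(x):
        return "n/a"
    if decimals == 0:
        return str(int(round(x)))
    return f"{round(x, decimals):.{decimals}f}"


def export_results(tables: Mapping[str, pd.DataFrame], path: str | Path,
                   format: str = "csv") -> list[Path]:
    """Write one machine-readable table per indicator family.

    ``tables`` maps scenario name -> summary frame (as produced by
    :func:`summarize_experiment`).  Each family file has columns
    ``indicator, scenario, mean, lci, uci`` in stable order and
    round-trips through :func:`load_results`.
    """
    if format not in ("csv", "json"):
        raise ValueError(f"unknown export format {format!r}")
    out_dir = Path(path)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for family, indicators in INDICATOR_FAMILIES.items():
        records = []
        for scenario, table in tables.items():
            for name in indicators:
                row = table.loc[name]
                records.append(
                    {"indicator": name, "scenario": scenario,
                     "mean": float(row["mean"]), "lci": float(row["lci"]),
                     "uci": float(row["uci"])}
                )
        frame = pd.DataFrame(records,
                             columns=["indicator", "scenario", "mean", "lci", "uci"])
        target = out_dir / f"{family}.{format}"
        if format == "csv":
            frame.to_csv(target, index=False)
        else:
            target.write_text(json.dumps(records, indent=1))
        written.append(target)
    return written


def load_results(path: str | Path, format: str = "csv") -> dict[str, pd.DataFrame]:
    """Re-import exported tables: scenario name -> summary frame."""
    out_dir = Path(path)
    frames = []
    for family in INDICATOR_FAMILIES:
        target = out_dir / f"{family}.{format}"
        if format == "csv":
            frames.append(pd.read_csv(target))
        else:
            frames.append(pd.DataFrame(json.loads(target.read_text())))
    long = pd.concat(frames, ignore_index=True)
    tables = {}
    for scenario, group in long.groupby("scenario", sort=False):
        table = group.set_index("indicator")[["mean", "lci", "uci"]]
        tables[scenario] = table.loc[[n for n in INDICATOR_ORDER if n in table.index]]
    return tables
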