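"""Raw scoring, min-max normalization, log processing, outlier screening,
and descriptive statistics.

Raw scores follow the battery's scoring rules: complex spans use
partial-credit load scoring (proportion of memory items recalled in the
correct serial position over the 60 test items), the n-back counts correct
responses on scored target trials (0-12; false alarms are reported but do
not enter the raw score), memory updating counts correctly reported final
digits (0-36), the multimodal span scores the length of the last correctly
reproduced sequence (0, or 3-11), and the binding task counts correct
judgments (0-16). Normalization divides by the theoretical maximum, so
scores live on a 0.00-1.00 scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from openwmb.engine import TASKS, records_to_frame, read_log
from openwmb.errors import ConfigurationError, SchemaError

#: theoretical maximum raw score per task (minimum is 0 for all)
TASK_MAX = {
    "reading": 1.0, "operation": 1.0, "symmetry": 1.0,
    "nback": 12, "updating": 36, "multimodal": 11, "binding": 16,
}

PERCENTILES = (5, 25, 33, 50, 66, 75, 95)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def compute_raw_score(task: str, records) -> float:
    """Raw score for one (participant, task) from its test-phase records."""
    if task not in TASK_MAX:
        raise ConfigurationError(f"unknown task {task!r}")
    df = _as_frame(records)
    if df["task"].nunique() > 1:
        raise SchemaError("records mix multiple tasks")
    test = df[(df["phase"] == "test")]
    if test.empty:
        raise SchemaError(f"no test-phase records for {task}")
    if task in ("reading", "operation", "symmetry"):
        mem = test[test["segment"] == "memory"]
        return float(mem["correct"].astype(bool).mean())
    if task == "nback":
        scored = test[(test["segment"] == "item") & test["scored"]]
        targets = scored[scored["set_size"] == "target"]
        return float(targets["correct"].astype(bool).sum())
    if task == "updating":
        trials = test[test["segment"] == "trial"]
        total = 0
        for _, row in trials.iterrows():
            stim = json.loads(row["stimulus"])
            resp = json.loads(row["response"])
            total += sum(d == f for d, f in zip(resp["digits"], stim["final"]))
        return float(total)
    if task == "binding":
        trials = test[test["segment"] == "trial"]
        return float(trials["correct"].astype(bool).sum())
    # multimodal: adaptive, so the last correct sequence is the longest one
    trials = test[test["segment"] == "trial"]
    ok = trials[trials["correct"].astype(bool)]
    return float(ok["set_size"].astype(int).max()) if not ok.empty else 0.0


def nback_counts(records) -> dict:
    """Hits, misses, false alarms, and correct rejections on scored test
    items (false alarms are logged and reported, not scored)."""
    df = _as_frame(records)
    scored = df[(df["phase"] == "test") & (df["segment"] == "item") & df["scored"]]
    is_target = scored["set_size"] == "target"
    correct = scored["correct"].astype(bool)
    return {
        "hits": int((is_target & correct).sum()),
        "misses": int((is_target & ~correct).sum()),
        "false_alarms": int((~is_target & ~correct).sum()),
        "correct_rejections": int((~is_target & correct).sum()),
    }


def normalize(raw: float, task: str) -> float:
    """Min-max normalization against the theoretical range [0, max]."""
    if task not in TASK_MAX:
        raise ConfigurationError(f"unknown task {task!r}")
    mx = TASK_MAX[task]
    if not 0 <= raw <= mx:
        raise ConfigurationError(f"raw score {raw} outside [0, {mx}] for {task}")
    return float(raw) / float(mx)


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

@dataclass
class ScoreTable:
    """Participants x tasks score matrix with screening annotations.

    ``data`` holds one row per participant with ``<task>_raw`` and
    ``<task>_norm`` columns (NaN marks missing). ``excluded`` lists
    participants dropped for zero scores on more than one task.
    """

    data: pd.DataFrame
    excluded: list = field(default_factory=list)
    annotations: list = field(default_factory=list)

    @property
    def norm_columns(self) -> list:
        return [c for c in self.data.columns if c.endswith("_norm")]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, encoding="utf-8")

    @classmethod
    def read_csv(cls, path) -> "ScoreTable":
        df = pd.read_csv(path, index_col=0, encoding="utf-8")
        bad = [c for c in df.columns
               if not (c.endswith("_raw") or c.endswith("_norm"))]
        if bad:
            raise SchemaError(f"{path}: unexpected columns {bad}")
        return cls(df)


@dataclass
class ScreeningReport:
    univariate: list = field(default_factory=list)  # (task, participant, z)
    zero_scores: list = field(default_factory=list)  # (task, participant)
    multivariate: list = field(default_factory=list)  # (participant, D2, p)
    skipped_columns: list = field(default_factory=list)


def process_logs(logs, exclude_multi_zero: bool = True) -> ScoreTable:
    """Convert trial logs into an analysis-ready wide score table.

    ``logs`` may be a directory of per-participant CSVs, a list of paths,
    a single long DataFrame, or a mapping participant -> DataFrame.
    Participants scoring zero on more than one task are excluded (and
    listed on the returned table).
    """
    if isinstance(logs, (str, Path)):
        path = Path(logs)
        paths = sorted(path.glob("*.csv")) if path.is_dir() else [path]
        frames = [read_log(p) for p in paths]
        df = pd.concat(frames, ignore_index=True)
    elif isinstance(logs, pd.DataFrame):
        df = logs
    elif isinstance(logs, dict):
        df = pd.concat([_as_frame(v) for v in logs.values()], ignore_index=True)
    else:
        df = pd.concat([_as_frame(v) for v in logs], ignore_index=True)
    missing = set(("participant_id", "task", "phase", "segment")) - set(df.columns)
    if missing:
        raise SchemaError(f"log is missing columns {sorted(missing)}")

    rows = {}
    for pid, part in df.groupby("participant_id", sort=True):
        row = {}
        for task in TASKS:
            sub = part[part["task"] == task]
            if sub.empty or sub[sub["phase"] == "test"].empty:
                row[f"{task}_raw"] = np.nan
                row[f"{task}_norm"] = np.nan
                continue
            raw = compute_raw_score(task, sub)
            row[f"{task}_raw"] = raw
            row[f"{task}_norm"] = normalize(raw, task)
        rows[pid] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "participant_id"

    excluded = []
    if exclude_multi_zero:
        norm = table[[f"{t}_norm" for t in TASKS]]
        n_zero = (norm == 0).sum(axis=1)
        excluded = list(table.index[n_zero > 1])
        table = table.drop(index=excluded)
    return ScoreTable(table, excluded=excluded)


def screen_univariate(table: ScoreTable, z_cut: float = 3.0):
    """Flag |z| > z_cut cells and zero scores; set them to missing.

    Screening never creates values — it only introduces missingness.
    Degenerate columns (SD = 0) are skipped with a warning.
    """
    data = table.data.copy()
    report = ScreeningReport()
    for col in table.norm_columns:
        task = col[: -len("_norm")]
        vals = data[col]
        present = vals.dropna()
        if len(present) < 3:
            raise ConfigurationError(f"{col}: need at least 3 non-missing values")
        zero_idx = present.index[present == 0]
        for pid in zero_idx:
            report.zero_scores.append((task, pid))
        sd = present.std(ddof=1)
        if sd == 0:
            report.skipped_columns.append(col)
            warnings.warn(f"{col}: zero variance, outlier screening skipped")
        else:
            z = (present - present.mean()) / sd
            for pid, zv in z[np.abs(z) > z_cut].items():
                report.univariate.append((task, pid, float(zv)))
                data.loc[pid, col] = np.nan
                data.loc[pid, f"{task}_raw"] = np.nan
        for pid in zero_idx:
            data.loc[pid, col] = np.nan
            data.loc[pid, f"{task}_raw"] = np.nan
    out = ScoreTable(data, excluded=list(table.excluded),
                     annotations=list(table.annotations) + ["univariate screening"])
    return out, report


def mahalanobis_d2(df: pd.DataFrame) -> pd.Series:
    """Squared Mahalanobis distance of each row from the column means."""
    x = df.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ConfigurationError("multivariate screening requires a complete table")
    centered = x - x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    try:
        inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("singular covariance matrix") from exc
    d2 = np.einsum("ij,jk,ik->i", centered, inv, centered)
    return pd.Series(d2, index=df.index, name="D2")


def screen_multivariate(df: pd.DataFrame, alpha: float = 0.001) -> ScreeningReport:
    """Mahalanobis screening on a complete table (run after imputation):
    exclude rows whose chi-square upper-tail p (df = number of variables)
    falls below ``alpha``."""
    d2 = mahalanobis_d2(df)
    p = stats.chi2.sf(d2, df=df.shape[1])
    report = ScreeningReport()
    for pid, dv, pv in zip(df.index, d2, p):
        if pv < alpha:
            report.multivariate.append((pid, float(dv), float(pv)))
    return report


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def descriptives(table) -> pd.DataFrame:
    """Per-task mean, SD, range, skewness, excess kurtosis, percentiles, and
    univariate-normality flags (|skew| < 2, |excess kurtosis| < 4)."""
    df = table.data[table.norm_columns] if isinstance(table, ScoreTable) else table
    if df.empty:
        raise ConfigurationError("empty table")
    out = {}
    for col in df.columns:
        vals = df[col].dropna().to_numpy(dtype=float)
        row = {"n": len(vals), "mean": vals.mean(), "sd": vals.std(ddof=1),
               "min": vals.min(), "max": vals.max()}
        if row["sd"] == 0:
            row["skew"] = np.nan
            row["kurtosis"] = np.nan
            row["normal"] = np.nan
        else:
            row["skew"] = stats.skew(vals, bias=False)
            row["kurtosis"] = stats.kurtosis(vals, fisher=True, bias=False)
            row["normal"] = bool(abs(row["skew"]) < 2 and abs(row["kurtosis"]) < 4)
        for q in PERCENTILES:
            row[f"p{q}"] = np.percentile(vals, q)  # linear interpolation
        out[col] = row
    return pd.DataFrame.from_dict(out, orient="index")


def mardia_kurtosis(df: pd.DataFrame) -> dict:
    """Mardia's multivariate kurtosis coefficient with its normal-theory
    z statistic and two-sided p-value."""
    x = df.dropna().to_numpy(dtype=float)
    n, p = x.shape
    centered = x - x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1) * (n - 1) / n  # ML covariance
    inv = np.linalg.inv(cov)
    d2 = np.einsum("ij,jk,ik->i", centered, inv, centered)
    b2p = float(np.mean(d2**2))
    expected = p * (p + 2)
    z = (b2p - expected * (n - 1) / (n + 1)) / np.sqrt(8.0 * p * (p + 2) / n)
    return {"b2p": b2p, "z": float(z), "p_value": float(2 * stats.norm.sf(abs(z))),
            "kappa": float(b2p - expected)}
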