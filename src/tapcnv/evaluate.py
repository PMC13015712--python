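"""Metrics, confusion matrices, the naive diploid baseline, and benchmark grids.

The evaluation unit is the (cell, chromosome) pair.  Besides overall accuracy
the suite reports class-balanced metrics (macro-F1, balanced accuracy,
per-class sensitivity over copy-number states 1..5) and binary alteration
detection (CN != 2 vs CN = 2): sensitivity, precision, and their F1.  Macro
averages run over the classes present in truth or predictions; 0/0 ratios are
defined as 0 (so a predictor that never calls an alteration has alteration
F1 exactly 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CallSet
from . import simulate as sim_mod
from . import hmm as hmm_mod
from . import gmm as gmm_mod

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "metrics",
    "naive_baseline",
    "evaluate_calls",
    "benchmark_study2",
    "benchmark_study1",
]

K_STATES = 5


@dataclass
class ConfusionMatrix:
    """K x K counts: entry [j-1, k-1] = pairs with true state j, predicted k."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (K_STATES, K_STATES):
            raise ValueError(f"confusion matrix must be {K_STATES}x{K_STATES}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _as_frame(calls) -> pd.DataFrame:
    if isinstance(calls, CallSet):
        return calls.to_frame()
    return pd.DataFrame(calls)


def confusion(calls, truth) -> ConfusionMatrix:
    """Tabulate cell-by-chromosome calls against truth into a 5x5 matrix.

    Both arguments are CallSets or cells x chromosomes frames covering the
    same cells and chromosomes (order-insensitive).
    """
    cf = _as_frame(calls)
    tf = _as_frame(truth)
    if set(cf.index) != set(tf.index) or set(cf.columns) != set(tf.columns):
        raise ValueError("calls and truth must cover the same cells and chromosomes")
    cf = cf.loc[tf.index, tf.columns]
    t = tf.to_numpy(dtype=int).ravel()
    p = cf.to_numpy(dtype=int).ravel()
    m = np.zeros((K_STATES, K_STATES), dtype=int)
    np.add.at(m, (t - 1, p - 1), 1)
    return ConfusionMatrix(m)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


@dataclass
class MetricReport:
    accuracy: float
    macro_f1: float
    balanced_accuracy: float
    per_class_sensitivity: dict
    alteration_sensitivity: float
    alteration_precision: float
    alteration_f1: float
    confusion: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "balanced_accuracy": self.balanced_accuracy,
            "per_class_sensitivity": {str(k): v for k, v in self.per_class_sensitivity.items()},
            "alteration_sensitivity": self.alteration_sensitivity,
            "alteration_precision": self.alteration_precision,
            "alteration_f1": self.alteration_f1,
            "confusion": self.confusion.tolist(),
        }


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """All evaluation metrics from a confusion matrix.

    Macro-F1 and balanced accuracy average over the classes present in truth
    or predictions (union); per-class sensitivities are reported for all five
    states, with 0/0 = 0.
    """
    m = cm.counts
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = np.trace(m) / cm.total
    row = m.sum(axis=1)  # true counts per class
    col = m.sum(axis=0)  # predicted counts per class
    present = np.flatnonzero((row + col) > 0)
    recalls = np.array([_safe_div(m[k, k], row[k]) for k in range(K_STATES)])
    precis = np.array([_safe_div(m[k, k], col[k]) for k in range(K_STATES)])
    f1 = np.array(
        [_safe_div(2 * precis[k] * recalls[k], precis[k] + recalls[k]) for k in range(K_STATES)]
    )
    macro_f1 = float(f1[present].mean())
    balanced = float(recalls[present].mean())
    per_class = {k + 1: float(recalls[k]) for k in range(K_STATES)}

    diploid = 1  # index of CN=2
    tp = cm.total - row[diploid] - col[diploid] + m[diploid, diploid]  # true!=2 and pred!=2
    fn = row.sum() - row[diploid] - tp
    fp = col.sum() - col[diploid] - tp
    alt_sens = _safe_div(tp, tp + fn)
    alt_prec = _safe_div(tp, tp + fp)
    alt_f1 = _safe_div(2 * alt_prec * alt_sens, alt_prec + alt_sens)
    return MetricReport(
        float(accuracy),
        macro_f1,
        balanced,
        per_class,
        float(alt_sens),
        float(alt_prec),
        float(alt_f1),
        m.copy(),
    )


def naive_baseline(truth) -> CallSet:
    """The performance floor: CN = 2 for every cell and chromosome."""
    tf = _as_frame(truth)
    return CallSet(list(tf.index), list(tf.columns), np.full(tf.shape, 2, dtype=int))


def evaluate_calls(calls, truth) -> MetricReport:
    """Convenience: confusion + metrics in one call."""
    return metrics(confusion(calls, truth))


# ---------------------------------------------------------------------------
# benchmark orchestration
# ---------------------------------------------------------------------------


def _run_methods(ds: sim_mod.SimDataset, methods, seed: int) -> dict:
    out = {}
    truth = ds.truth.cn
    for method in methods:
        if method == "hmm":
            calls = hmm_mod.call_cells(ds.counts, ds.baf, ds.panel, ds.reference)
        elif method == "gmm":
            rng = sim_mod.rng_for(seed, "gmm-synthesis")
            calls = gmm_mod.call_cells_gmm(ds.counts, ds.panel, ds.reference, rng=rng)
        elif method == "naive":
            calls = naive_baseline(truth)
        else:
            raise ValueError(f"unknown method {method!r}")
        out[method] = evaluate_calls(calls, truth)
    return out


def _report_row(rep: MetricReport) -> dict:
    d = rep.to_dict()
    d.pop("confusion")
    sens = d.pop("per_class_sensitivity")
    for k, v in sens.items():
        d[f"sensitivity_cn{k}"] = v
    return d


def benchmark_study2(
    direction: str = "gain",
    varied_param: str | None = None,
    value=None,
    methods=("hmm", "gmm", "naive"),
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Run one study-2 condition for several methods and replicates.

    Returns a tidy frame with one row per (replicate, method) and one column
    per metric; replicate seeds are derived from the master seed.
    """
    rows = []
    cond = f"{direction}:{varied_param}={value}" if varied_param else f"{direction}:baseline"
    for rep in range(replicates):
        rep_seed = int(
            sim_mod.rng_for(seed, f"study2/{cond}/rep{rep}").integers(0, 2**31 - 1)
        )
        ds = sim_mod.build_study2(direction, varied_param, value, seed=rep_seed)
        results = _run_methods(ds, methods, rep_seed)
        for method, report in results.items():
            rows.append(
                {"condition": cond, "replicate": rep, "method": method, **_report_row(report)}
            )
    return pd.DataFrame(rows)


def benchmark_study1(
    methods=("hmm", "gmm", "naive"),
    replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the six-population study for several methods and replicates."""
    rows = []
    for rep in range(replicates):
        rep_seed = int(sim_mod.rng_for(seed, f"study1/rep{rep}").integers(0, 2**31 - 1))
        ds = sim_mod.build_study1(seed=rep_seed)
        results = _run_methods(ds, methods, rep_seed)
        for method, report in results.items():
            rows.append({"condition": "study1", "replicate": rep, "method": method, **_report_row(report)})
    return pd.DataFrame(rows)
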