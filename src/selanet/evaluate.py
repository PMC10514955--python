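"""Selective-prediction evaluation statistics.

Covers the confusion-matrix metrics (accuracy, sensitivity, specificity,
false-negative/false-positive rates, F1, G-mean), the coverage diagnostics
(mean empirical coverage, coverage violation over evaluation units, selective
risk on selected samples) and per-class rejection profiles including the
ambiguous (RERA-like) stream.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .selective import (Decision, REJECT, SelectiveClassifier,
                        empirical_coverage)


@dataclass(frozen=True)
class ConfusionCounts:
    """Two-class counts with apnea as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred, positive: str = "apnea") -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(tp=int(np.sum(pos_t & pos_p)), tn=int(np.sum(~pos_t & ~pos_p)),
                   fp=int(np.sum(~pos_t & pos_p)), fn=int(np.sum(pos_t & ~pos_p)))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan  # undefined, not zero


def classification_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, FNR, FPR and F1 from counts.

    Zero-denominator metrics come back as NaN.  By construction
    FNR = 1 - sensitivity and FPR = 1 - specificity.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    return {
        "accuracy": _ratio(tp + tn, counts.total),
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "fnr": _ratio(fn, fn + tp),
        "fpr": _ratio(fp, fp + tn),
        "f1": _ratio(2 * tp, 2 * tp + fp + fn),
    }


def gmean(sensitivity: float, specificity: float) -> float:
    """Geometric mean of sensitivity and specificity."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("inputs must lie in [0, 1]")
    return math.sqrt(sensitivity * specificity)


def coverage_violation(g_scores, c: float, block_size: int = 64,
                       groups=None) -> float:
    """Mean over evaluation units of |c - phi_hat(unit)|.

    Units default to consecutive blocks of ``block_size`` samples (the
    training minibatch size); pass ``groups`` (one hashable id per sample,
    e.g. subject ids) for an alternative grouping.  A trailing partial block
    counts as a unit.
    """
    g = np.asarray(g_scores, dtype=np.float64)
    if g.size == 0:
        raise ValueError("no samples for coverage violation")
    units: list[np.ndarray] = []
    if groups is not None:
        groups = np.asarray(groups)
        if groups.shape != g.shape:
            raise ValueError("groups must align with g_scores")
        for key in pd_unique(groups):
            units.append(g[groups == key])
    else:
        for start in range(0, g.size, block_size):
            units.append(g[start:start + block_size])
    return float(np.mean([abs(c - unit.mean()) for unit in units]))


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Order-preserving unique (keeps subjects in recording order)."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def rejection_profile(decisions: list[Decision], streams,
                      expected: tuple[str, ...] = ()) -> dict[str, dict[str, float]]:
    """Per-stream percentages of rejected / predicted-apnea / predicted-normal.

    ``streams`` assigns each decision to "apnea", "normal" or "ambiguous"
    by its ground-truth annotation.  ``expected`` streams that turn out empty
    are omitted with a warning.  Percentages per stream sum to 100.
    """
    streams = np.asarray(streams)
    if len(decisions) != len(streams):
        raise ValueError("decisions and streams must align")
    profile: dict[str, dict[str, float]] = {}
    names = list(pd_unique(streams))
    for name in expected:
        if name not in names:
            warnings.warn(f"empty stream {name!r} omitted from profile")
    for name in names:
        sel = [d for d, s in zip(decisions, streams) if s == name]
        if not sel:
            warnings.warn(f"empty stream {name!r} omitted from profile")
            continue
        n = len(sel)
        profile[str(name)] = {
            "rejected_pct": 100.0 * sum(d.predicted_class == REJECT for d in sel) / n,
            "predicted_apnea_pct": 100.0 * sum(d.predicted_class == "apnea" for d in sel) / n,
            "predicted_normal_pct": 100.0 * sum(d.predicted_class == "normal" for d in sel) / n,
        }
    return profile


@dataclass
class EvalReport:
    """Full selective-prediction evaluation of one trained model."""

    target_coverage: float
    tau: float
    n_test: int
    mean_empirical_coverage: float        # soft: mean g over the test set
    selected_fraction: float              # hard: share with g >= tau
    coverage_violation: float
    selective_risk: float                 # error rate on selected samples
    selected: dict[str, float]            # metrics on selected samples
    no_selection: dict[str, float]        # same metrics, tau = 0 path
    gmean_selected: float
    per_class_rejection: dict[str, dict[str, float]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def summarize_reports(reports: list[EvalReport]):
    """Mean ± sd of the scalar metrics across seeded repeat runs.

    Returns a pandas DataFrame indexed by metric with columns mean/sd.
    """
    import pandas as pd
    if not reports:
        raise ValueError("no reports to summarize")
    rows = []
    for rep in reports:
        row = {"mean_empirical_coverage": rep.mean_empirical_coverage,
               "selected_fraction": rep.selected_fraction,
               "coverage_violation": rep.coverage_violation,
               "selective_risk": rep.selective_risk,
               "gmean_selected": rep.gmean_selected}
        row.update({f"selected_{k}": v for k, v in rep.selected.items()})
        row.update({f"no_selection_{k}": v for k, v in rep.no_selection.items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1 if len(df) > 1 else 0)})


def evaluate_model(clf: SelectiveClassifier, Z_test, y_test, Z_ambiguous=None,
                   tau: float | None = None, block_size: int = 64,
                   groups=None) -> EvalReport:
    """Evaluate selective prediction on a held-out two-class set, plus an
    optional ambiguous stream for the rejection profile.

    Classification metrics are computed on the selected samples only, with a
    parallel no-selection (tau = 0) report for the with/without comparison.
    """
    y_test = np.asarray(y_test)
    tau_eff = clf._effective_tau(tau)
    decisions = clf.decide(Z_test, tau=tau_eff)
    g = np.array([d.g_score for d in decisions])
    pred_all = clf.predict(Z_test, tau=0.0)
    selected_mask = np.array([d.selected for d in decisions])

    notes: list[str] = []
    c = clf.target_coverage
    soft_cov = empirical_coverage(g)
    violation = coverage_violation(g, c, block_size=block_size, groups=groups)

    no_sel = classification_metrics(ConfusionCounts.from_labels(y_test, pred_all))
    if selected_mask.any():
        pred_sel = np.array([d.predicted_class for d in decisions], dtype=object)
        counts_sel = ConfusionCounts.from_labels(y_test[selected_mask],
                                                 pred_sel[selected_mask])
        sel_metrics = classification_metrics(counts_sel)
        sel_risk = 1.0 - sel_metrics["accuracy"]
        gm = gmean(sel_metrics["sensitivity"], sel_metrics["specificity"]) \
            if not (math.isnan(sel_metrics["sensitivity"])
                    or math.isnan(sel_metrics["specificity"])) else math.nan
    else:
        notes.append("no samples selected at tau; selective metrics undefined")
        sel_metrics = {k: math.nan for k in no_sel}
        sel_risk = math.nan
        gm = math.nan

    report = EvalReport(
        target_coverage=c, tau=tau_eff, n_test=len(y_test),
        mean_empirical_coverage=soft_cov,
        selected_fraction=float(selected_mask.mean()),
        coverage_violation=violation, selective_risk=sel_risk,
        selected=sel_metrics, no_selection=no_sel, gmean_selected=gm,
        notes=notes)

    if Z_ambiguous is not None and len(Z_ambiguous):
        amb_dec = clf.decide(Z_ambiguous, tau=tau_eff)
        all_dec = decisions + amb_dec
        streams = np.concatenate([y_test.astype(object),
                                  np.full(len(amb_dec), "ambiguous", dtype=object)])
        report.per_class_rejection = rejection_profile(all_dec, streams)
    else:
        report.per_class_rejection = rejection_profile(decisions, y_test.astype(object))
    return report
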