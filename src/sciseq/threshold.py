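"""Detection-threshold estimation from FPKM confidence intervals.

An expression estimate is *reliable* when the lower bound of its 95%
confidence interval is strictly above zero, and *unreliable* when the lower
bound is zero (the estimate has a possibility of being truly absent).
Counting reliable and unreliable estimates along an FPKM grid yields a
detection curve; the working threshold is the smallest FPKM level at which
the probability that an estimate at or above that level is reliable reaches
a target (0.99 by default).  Values below the chosen threshold are floored
to it before fold-change computation to avoid ratio inflation.

The false-positive / false-negative operationalization used here:

* ``reliability(t)`` — fraction of estimates with FPKM ≥ t that are reliable;
* ``fp_rate(t) = 1 − reliability(t)`` — calling an estimate detected at level
  t although its CI admits zero;
* ``fn_rate(t)`` — fraction of all reliable estimates falling below t, i.e.
  genuine signal discarded by thresholding at t.

Calls are pooled across all samples: the study uses one global threshold,
not per-sample thresholds.  Alternative rate definitions can be built from
the returned call table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionStudy, ValidationError


def default_grid(lo: float = 0.001, hi: float = 10.0, n: int = 50) -> np.ndarray:
    """Logarithmic FPKM threshold grid (50 points, 0.001–10 by default)."""
    return np.geomspace(lo, hi, n)


def label_reliability(study: ExpressionStudy) -> pd.DataFrame:
    """One reliable/unreliable call per feature × sample.

    Returns a table with columns ``feature``, ``sample``, ``fpkm``,
    ``reliable`` (bool) and ``label``.
    """
    if not study.has_ci():
        raise ValidationError(
            "study has no confidence bounds; reliability labelling needs "
            "CI-bearing input (e.g. .fpkm_tracking files)"
        )
    long = study.values.stack()
    lo = study.ci_lo.stack()
    calls = pd.DataFrame(
        {
            "feature": long.index.get_level_values(0),
            "sample": long.index.get_level_values(1),
            "fpkm": long.to_numpy(),
            "reliable": lo.to_numpy() > 0,
        }
    ).reset_index(drop=True)
    calls["label"] = np.where(calls["reliable"], "reliable", "unreliable")
    return calls


def compute_detection_curve(calls: pd.DataFrame, grid=None) -> pd.DataFrame:
    """Reliability / FP / FN rates at each grid threshold.

    Grid points where no estimate reaches the threshold are flagged
    ``defined == False`` (rates NaN) rather than reported as zero.
    """
    if len(calls) == 0:
        raise ValidationError("no reliability calls provided")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if len(grid) and (np.diff(grid) <= 0).any() or (grid <= 0).any():
        raise ValidationError("grid must be strictly increasing and positive")
    fpkm = calls["fpkm"].to_numpy()
    reliable = calls["reliable"].to_numpy(dtype=bool)
    # counts above each threshold via sorted cumulative sums
    order = np.argsort(fpkm)
    f_sorted = fpkm[order]
    r_sorted = reliable[order].astype(np.int64)
    n_total = len(fpkm)
    n_rel_total = int(r_sorted.sum())
    cum_rel = np.concatenate([[0], np.cumsum(r_sorted)])
    idx = np.searchsorted(f_sorted, grid, side="left")
    n_at_or_above = n_total - idx
    rel_at_or_above = n_rel_total - cum_rel[idx]
    defined = n_at_or_above > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        reliability = np.where(defined, rel_at_or_above / n_at_or_above, np.nan)
        fn = (
            np.full(len(grid), np.nan)
            if n_rel_total == 0
            else (n_rel_total - rel_at_or_above) / n_rel_total
        )
    return pd.DataFrame(
        {
            "threshold": grid,
            "reliability": reliability,
            "fp_rate": 1.0 - reliability,
            "fn_rate": fn,
            "n_at_or_above": n_at_or_above,
            "n_reliable_at_or_above": rel_at_or_above,
            "defined": defined,
        }
    )


@dataclass
class ThresholdSelection:
    threshold: float
    reliability: float
    fn_rate: float


def select_threshold(
    curve: pd.DataFrame, target_reliability: float = 0.99
) -> ThresholdSelection:
    """Smallest grid threshold whose reliability meets the target."""
    defined = curve[curve["defined"]]
    if len(defined) < 2:
        raise ValidationError("detection curve defined on fewer than 2 grid points")
    ok = defined[defined["reliability"] >= target_reliability]
    if len(ok) == 0:
        best = float(defined["reliability"].max())
        raise ValidationError(
            f"target reliability {target_reliability} unattainable on grid; "
            f"maximum achievable is {best:.4f}"
        )
    row = ok.iloc[0]
    return ThresholdSelection(
        threshold=float(row["threshold"]),
        reliability=float(row["reliability"]),
        fn_rate=float(row["fn_rate"]),
    )


def floor_fpkm(study: ExpressionStudy, floor: float = 0.1) -> ExpressionStudy:
    """Replace values below ``floor`` by ``floor`` (CI matrices untouched).

    Idempotent and order-preserving; used before every fold-change ratio.
    """
    if floor <= 0:
        raise ValidationError("floor must be positive")
    from dataclasses import replace

    return replace(
        study, values=study.values.clip(lower=floor), validate_ci_brackets=False
    )


def plot_detection_curve(curve: pd.DataFrame, selection=None, ax=None):
    """Plot FP/FN rates against the threshold grid (log x-axis)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    d = curve[curve["defined"]]
    ax.plot(d["threshold"], d["fp_rate"], label="false positive rate")
    ax.plot(d["threshold"], d["fn_rate"], label="false negative rate")
    if selection is not None:
        ax.axvline(selection.threshold, ls="--", color="grey",
                   label=f"threshold {selection.threshold:.3g}")
    ax.set_xscale("log")
    ax.set_xlabel("detection threshold (FPKM)")
    ax.set_ylabel("rate")
    ax.legend()
    return ax
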