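"""Differential-expression calling between injury stages.

A gene is called differentially expressed in a contrast (treated vs control
stage) when its floored fold change exceeds 2 in either direction and an
unpaired two-sided t-test on the replicate FPKM values gives p < 0.05.
Pooled-variance Student's t is the default (the classic unpaired test, with
groups as small as 2 vs 3 replicates); Welch's correction and log-scale
testing are available as options.  No multiple-testing correction enters the
significance call; Benjamini–Hochberg q-values are reported alongside for
transparency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionStudy, ValidationError


def _stage_matrix(study: ExpressionStudy, stage: str) -> np.ndarray:
    cols = study.samples_of_stage(stage)
    return study.values[cols].to_numpy()


def fold_change(study: ExpressionStudy, contrast: tuple[str, str]) -> pd.DataFrame:
    """Per-gene fold change mean(treated) / mean(control).

    The study must already be floored (see :func:`sciseq.threshold.floor_fpkm`)
    so that near-zero denominators cannot inflate ratios.
    """
    treated, control = contrast
    m_t = _stage_matrix(study, treated).mean(axis=1)
    m_c = _stage_matrix(study, control).mean(axis=1)
    fc = m_t / m_c
    return pd.DataFrame(
        {
            "mean_treated": m_t,
            "mean_control": m_c,
            "fold_change": fc,
            "log2_fc": np.log2(fc),
        },
        index=study.features,
    )


def _pooled_t(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided unpaired t-test over rows of a and b.

    Degenerate rows (zero variance in both groups) get p = 1 when the means
    are equal and p = 0 when they differ, rather than NaN.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    diff = ma - mb
    with np.errstate(invalid="ignore", divide="ignore"):
        if welch:
            se2 = va / na + vb / nb
            t = diff / np.sqrt(se2)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
            df = np.full_like(t, float(na + nb - 2))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        equal = np.isclose(diff, 0.0)
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
        t = np.where(degenerate, np.where(equal, 0.0, np.inf * np.sign(diff)), t)
        if (degenerate & ~equal).any():
            warnings.warn(
                f"{int((degenerate & ~equal).sum())} gene(s) with zero variance "
                "but differing means; p set to 0",
                stacklevel=2,
            )
    return t, p


def t_test(
    study: ExpressionStudy,
    contrast: tuple[str, str],
    log_scale: bool = False,
    welch: bool = False,
) -> pd.Series:
    """Two-sided unpaired t-test p-value per gene for a stage contrast.

    Tests raw FPKM values by default; ``log_scale`` tests log2(FPKM + 1e-9)
    instead.  Requires at least 2 replicates per stage.
    """
    a = _stage_matrix(study, contrast[0])
    b = _stage_matrix(study, contrast[1])
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("t-test needs at least 2 replicates per stage")
    if log_scale:
        a = np.log2(a + 1e-9)
        b = np.log2(b + 1e-9)
    _, p = _pooled_t(a, b, welch=welch)
    return pd.Series(p, index=study.features, name="p_value")


def call_de(
    study: ExpressionStudy,
    contrast: tuple[str, str],
    fc_cutoff: float = 2.0,
    p_cutoff: float = 0.05,
    log_scale: bool = False,
    welch: bool = False,
) -> pd.DataFrame:
    """Full DE table: fold change, p, BH q, direction, significance call.

    Significant iff (FC > fc_cutoff or FC < 1/fc_cutoff) and p < p_cutoff.
    Direction is up/down by the sign of log2 FC, ``flat`` at exactly 1.
    """
    table = fold_change(study, contrast)
    table["p_value"] = t_test(study, contrast, log_scale=log_scale, welch=welch)
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    fc = table["fold_change"].to_numpy()
    beyond = (fc > fc_cutoff) | (fc < 1.0 / fc_cutoff)
    table["is_significant"] = beyond & (table["p_value"].to_numpy() < p_cutoff)
    table["direction"] = np.select(
        [fc > 1.0, fc < 1.0], ["up", "down"], default="flat"
    )
    table.index.name = "gene"
    table.attrs["contrast"] = contrast
    return table


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class VennPartition:
    """Set partition of DE genes between two contrasts, per direction."""

    up_a: set[str]
    up_b: set[str]
    down_a: set[str]
    down_b: set[str]
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = {}
        for name, s_a, s_b in (
            ("up", self.up_a, self.up_b),
            ("down", self.down_a, self.down_b),
        ):
            c[f"{name}_a"] = len(s_a)
            c[f"{name}_b"] = len(s_b)
            c[f"{name}_shared"] = len(s_a & s_b)
            c[f"{name}_a_only"] = len(s_a - s_b)
            c[f"{name}_b_only"] = len(s_b - s_a)
            c[f"{name}_union"] = len(s_a | s_b)
        all_a = self.up_a | self.down_a
        all_b = self.up_b | self.down_b
        c["de_a"] = len(all_a)
        c["de_b"] = len(all_b)
        c["de_shared"] = len(all_a & all_b)
        self.counts = c

    @property
    def shared_up(self) -> set[str]:
        return self.up_a & self.up_b

    @property
    def shared_down(self) -> set[str]:
        return self.down_a & self.down_b


def venn_partition(de_a: pd.DataFrame, de_b: pd.DataFrame) -> VennPartition:
    """Partition significant genes of two contrasts into shared/exclusive sets."""
    if set(de_a.index) != set(de_b.index):
        raise ValidationError("DE tables cover different gene universes")

    def _sets(de: pd.DataFrame) -> tuple[set[str], set[str]]:
        sig = de[de["is_significant"]]
        return (
            set(sig.index[sig["direction"] == "up"]),
            set(sig.index[sig["direction"] == "down"]),
        )

    up_a, down_a = _sets(de_a)
    up_b, down_b = _sets(de_b)
    return VennPartition(up_a=up_a, up_b=up_b, down_a=down_a, down_b=down_b)


def select_top_fraction(
    de: pd.DataFrame, fraction: float = 0.10
) -> dict[str, list[str]]:
    """Top fraction of significant genes per direction by |log2 FC|.

    Among significant up-regulated genes, the ``ceil(fraction × count)`` with
    the largest log2 FC (most negative for down); ties break by gene id for
    determinism.  The denominator is the count of significant genes in that
    direction.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    out: dict[str, list[str]] = {}
    for direction, ascending in (("up", False), ("down", True)):
        sub = de[(de["is_significant"]) & (de["direction"] == direction)]
        if len(sub) == 0:
            warnings.warn(f"no significant {direction}-regulated genes", stacklevel=2)
            out[direction] = []
            continue
        n = math.ceil(fraction * len(sub))
        # sort on log2_fc, resolving ties lexicographically by gene id
        ordered = (
            sub.assign(_g=sub.index)
            .sort_values(["log2_fc", "_g"], ascending=[ascending, True], kind="mergesort")
        )
        out[direction] = list(ordered.index[:n])
    return out
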