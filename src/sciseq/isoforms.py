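"""Isoform-level expression summaries: expressed-isoform counts, major
isoforms, switch detection and stage-wise one-way ANOVA.

An isoform counts as expressed in a stage when its stage-mean FPKM reaches
the detection threshold (0.1 FPKM by default, the same global threshold the
gene level uses).  The *major isoform* of a gene in a stage carries the
largest stage-mean FPKM; an *isoform switch* is a change of major isoform
between stages — e.g. one isoform declining after injury while another
rises to dominance.  An optional margin ratio (require the new major to
exceed the old by a factor) guards against noise-driven flips; margin 1.0
reproduces the literal argmax rule and is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionStudy, ValidationError


def _require_isoforms(study: ExpressionStudy) -> None:
    if study.feature_kind != "isoform" or study.isoform_to_gene is None:
        raise ValidationError("an isoform-level study with an isoform→gene map is required")


def isoform_stage_means(study: ExpressionStudy) -> pd.DataFrame:
    _require_isoforms(study)
    means = study.stage_means()
    means["gene"] = study.isoform_to_gene.loc[means.index].to_numpy()
    return means


def count_expressed_isoforms(
    study: ExpressionStudy, threshold: float = 0.1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene per-stage expressed-isoform counts plus the all-stage
    isoforms-per-gene histogram.

    Returns ``(counts, histogram)``: counts has one row per gene with one
    column per stage and an ``all_stages`` column (isoforms expressed in
    every stage); histogram tallies genes by number of isoforms expressed
    in all stages.
    """
    means = isoform_stage_means(study)
    stages = study.stages
    expressed = means[stages] >= threshold
    counts = expressed.groupby(means["gene"]).sum().astype(int)
    counts["all_stages"] = (
        expressed.all(axis=1).groupby(means["gene"]).sum().astype(int)
    )
    counts.index.name = "gene"
    hist = (
        counts["all_stages"].value_counts().sort_index().rename("n_genes").to_frame()
    )
    hist.index.name = "n_isoforms"
    return counts, hist


def major_isoform(stage_means: pd.Series) -> tuple[str | None, bool]:
    """Major isoform for one gene in one stage.

    ``stage_means`` maps isoform id → stage-mean FPKM for the expressed
    isoforms.  Ties take the lexicographically smallest id and set the tie
    flag; an empty series yields ``(None, False)`` (no expressed isoform).
    """
    if len(stage_means) == 0:
        return None, False
    top = stage_means.max()
    winners = sorted(stage_means.index[stage_means == top])
    return winners[0], len(winners) > 1


def detect_switch(
    majors: dict[str, str | None], stage_order: list[str]
) -> tuple[bool, tuple[str, str] | None]:
    """True when the major isoform differs between any two stages.

    Reports the earliest differing stage pair in stage order (stages without
    a defined major isoform are skipped).
    """
    defined = [(s, majors[s]) for s in stage_order if majors.get(s) is not None]
    for i in range(len(defined)):
        for j in range(i + 1, len(defined)):
            if defined[i][1] != defined[j][1]:
                return True, (defined[i][0], defined[j][0])
    return False, None


def anova_across_stages(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classic one-way fixed-effects ANOVA over replicate FPKMs per stage.

    Degenerate inputs: identical values everywhere give p = 1; zero
    within-group variance with differing means gives p = 0 with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 stages")
    ns = np.array([len(g) for g in groups])
    if ns.sum() - len(groups) < 1:
        raise ValidationError("ANOVA needs positive within-group degrees of freedom")
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b = len(groups) - 1
    df_w = int(ns.sum()) - len(groups)
    if ss_within <= 1e-300:
        if ss_between <= 1e-300:
            return 0.0, 1.0
        warnings.warn("zero within-group variance with differing means; p = 0",
                      stacklevel=2)
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, float(stats.f.sf(f, df_b, df_w))


@dataclass
class IsoformProfile:
    gene: str
    isoforms: list[str]
    stage_means: pd.DataFrame           # isoforms × stages
    n_expressed: dict[str, int]
    majors: dict[str, str | None]
    major_ties: dict[str, bool]
    is_switch: bool
    switch_pair: tuple[str, str] | None
    anova_p: pd.Series                  # per isoform


def profile_gene(
    study: ExpressionStudy,
    gene: str,
    threshold: float = 0.1,
    margin: float = 1.0,
) -> IsoformProfile:
    """Full isoform profile for one gene (counts, majors, switch, ANOVA)."""
    _require_isoforms(study)
    isos = list(study.isoform_to_gene.index[study.isoform_to_gene == gene])
    if not isos:
        raise ValidationError(f"no isoforms mapped to gene {gene!r}")
    means = study.stage_means().loc[isos]
    stages = study.stages
    majors: dict[str, str | None] = {}
    ties: dict[str, bool] = {}
    n_expressed: dict[str, int] = {}
    for s in stages:
        expr = means[s][means[s] >= threshold]
        n_expressed[s] = int(len(expr))
        majors[s], ties[s] = major_isoform(expr)
    is_switch, pair = detect_switch(majors, stages)
    if is_switch and margin > 1.0 and pair is not None:
        a, b = pair
        new, old = majors[b], majors[a]
        if means.loc[new, b] < margin * means.loc[old, b]:
            is_switch, pair = False, None
    anova_p = {}
    for iso in isos:
        groups = [study.values.loc[iso, study.samples_of_stage(s)].to_numpy()
                  for s in stages]
        _, anova_p[iso] = anova_across_stages(groups)
    return IsoformProfile(
        gene=gene,
        isoforms=isos,
        stage_means=means,
        n_expressed=n_expressed,
        majors=majors,
        major_ties=ties,
        is_switch=is_switch,
        switch_pair=pair,
        anova_p=pd.Series(anova_p),
    )


def _anova_all(study: ExpressionStudy) -> pd.Series:
    """Vectorized one-way ANOVA p across stages for every isoform."""
    stages = study.stages
    blocks = [study.values[study.samples_of_stage(s)].to_numpy() for s in stages]
    ns = np.array([b.shape[1] for b in blocks])
    total = sum(b.sum(axis=1) for b in blocks)
    grand = total / ns.sum()
    stage_means = [b.mean(axis=1) for b in blocks]
    ss_between = sum(n * (m - grand) ** 2 for n, m in zip(ns, stage_means))
    ss_within = sum(((b - m[:, None]) ** 2).sum(axis=1)
                    for b, m in zip(blocks, stage_means))
    df_b = len(stages) - 1
    df_w = int(ns.sum()) - len(stages)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
        p = stats.f.sf(f, df_b, df_w)
    degenerate = ss_within <= 1e-300
    p = np.where(degenerate, np.where(ss_between <= 1e-300, 1.0, 0.0), p)
    return pd.Series(p, index=study.features, name="anova_p")


def profile_all_genes(
    study: ExpressionStudy, threshold: float = 0.1, margin: float = 1.0
) -> pd.DataFrame:
    """Per-gene summary table over the whole isoform study."""
    _require_isoforms(study)
    stages = study.stages
    means = study.stage_means()
    anova_p = _anova_all(study)
    rows = []
    by_gene = pd.Index(study.isoform_to_gene.loc[means.index])
    for gene, sub in means.groupby(by_gene):
        majors: dict[str, str | None] = {}
        n_expressed: dict[str, int] = {}
        for s in stages:
            expr = sub[s][sub[s] >= threshold]
            n_expressed[s] = int(len(expr))
            majors[s], _ = major_isoform(expr)
        is_switch, pair = detect_switch(majors, stages)
        if is_switch and margin > 1.0 and pair is not None:
            a, b = pair
            if sub.loc[majors[b], b] < margin * sub.loc[majors[a], b]:
                is_switch, pair = False, None
        row = {
            "gene": gene,
            "n_isoforms": len(sub),
            "is_switch": is_switch,
            "switch_from": pair[0] if pair else "",
            "switch_to": pair[1] if pair else "",
            "min_anova_p": float(anova_p.loc[sub.index].min()),
        }
        for s in stages:
            row[f"major_{s}"] = majors[s] or ""
            row[f"n_expressed_{s}"] = n_expressed[s]
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene").sort_index()
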