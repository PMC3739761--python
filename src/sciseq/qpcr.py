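"""qPCR fold changes by the 2^-ΔΔCt method and concordance with
expression-derived fold changes.

Technical replicate Ct values are averaged per gene × sample; ΔCt is the
housekeeping-normalized Ct per biological sample; biological replicates are
then averaged on the ΔCt scale per stage; ΔΔCt = mean ΔCt(treated) −
mean ΔCt(control) and fold = 2^−ΔΔCt.  Amplification efficiency is fixed at
2 (the method's assumption).  Adding a constant to all Ct values of a sample
(a plate offset) cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError

CT_COLUMNS = ("gene", "sample_id", "stage", "ct")


def validate_ct_table(ct: pd.DataFrame, housekeeping: str) -> pd.DataFrame:
    for col in CT_COLUMNS:
        if col not in ct.columns:
            raise ValidationError(f"Ct table missing column {col!r}")
    if (ct["ct"] <= 0).any():
        raise ValidationError("Ct values must be positive")
    hk_samples = set(ct.loc[ct["gene"] == housekeeping, "sample_id"])
    missing = set(ct["sample_id"]) - hk_samples
    if missing:
        raise ValidationError(
            f"housekeeping gene {housekeeping!r} missing in sample(s) "
            f"{sorted(missing)}"
        )
    return ct


@dataclass
class DdctResult:
    gene: str
    contrast: tuple[str, str]
    ddct: float
    fold_change: float
    dct_treated: np.ndarray  # per biological replicate
    dct_control: np.ndarray
    fold_sd: float           # sd across replicate-level 2^-ΔΔCt


def delta_delta_ct(
    ct: pd.DataFrame,
    gene: str,
    contrast: tuple[str, str],
    housekeeping: str,
) -> DdctResult:
    """ΔΔCt and relative fold change 2^−ΔΔCt for one gene and contrast."""
    ct = validate_ct_table(ct, housekeeping)
    treated, control = contrast

    def _dct(stage: str) -> np.ndarray:
        sub = ct[ct["stage"] == stage]
        g = sub[sub["gene"] == gene].groupby("sample_id")["ct"].mean()
        hk = sub[sub["gene"] == housekeeping].groupby("sample_id")["ct"].mean()
        if len(g) == 0:
            raise ValidationError(f"gene {gene!r} not measured in stage {stage!r}")
        shared = g.index.intersection(hk.index)
        if len(shared) == 0:
            raise ValidationError(
                f"housekeeping gene {housekeeping!r} missing in stage {stage!r}"
            )
        return (g.loc[shared] - hk.loc[shared]).to_numpy()

    dct_t, dct_c = _dct(treated), _dct(control)
    ddct = float(dct_t.mean() - dct_c.mean())
    # spread across treated biological replicates, each normalized to the
    # control-stage mean ΔCt
    rep_folds = 2.0 ** (-(dct_t - dct_c.mean()))
    return DdctResult(
        gene=gene,
        contrast=contrast,
        ddct=ddct,
        fold_change=2.0**-ddct,
        dct_treated=dct_t,
        dct_control=dct_c,
        fold_sd=float(rep_folds.std(ddof=1)) if len(rep_folds) > 1 else 0.0,
    )


def qpcr_fold_table(
    ct: pd.DataFrame,
    genes,
    contrasts: list[tuple[str, str]],
    housekeeping: str,
) -> pd.DataFrame:
    rows = []
    for gene in genes:
        if gene == housekeeping:
            continue
        for contrast in contrasts:
            r = delta_delta_ct(ct, gene, contrast, housekeeping)
            rows.append(
                {
                    "gene": gene,
                    "contrast": f"{contrast[0]}_vs_{contrast[1]}",
                    "ddct": r.ddct,
                    "fold_change": r.fold_change,
                    "fold_sd": r.fold_sd,
                }
            )
    return pd.DataFrame(rows)


def concordance(
    qpcr_folds: pd.DataFrame, expression_folds: pd.DataFrame
) -> dict:
    """Agreement between qPCR and expression fold changes.

    Both inputs need columns ``gene``, ``contrast``, ``fold_change``.
    Returns Pearson and Spearman correlations of log2 folds, the
    sign-agreement fraction, and the merged side-by-side table.
    """
    merged = qpcr_folds.merge(
        expression_folds,
        on=["gene", "contrast"],
        suffixes=("_qpcr", "_expr"),
    )
    if len(merged) < 3:
        raise ValidationError(
            f"need at least 3 shared gene×contrast pairs, found {len(merged)}"
        )
    lq = np.log2(merged["fold_change_qpcr"].to_numpy())
    le = np.log2(merged["fold_change_expr"].to_numpy())
    pearson = float(stats.pearsonr(lq, le)[0])
    spearman = float(stats.spearmanr(lq, le)[0])
    sign_agree = float(np.mean(np.sign(lq) == np.sign(le)))
    merged = merged.assign(log2_fold_qpcr=lq, log2_fold_expr=le)
    return {
        "pearson": pearson,
        "spearman": spearman,
        "sign_agreement": sign_agree,
        "n_pairs": int(len(merged)),
        "table": merged,
    }
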