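"""Count normalization, NB differential testing and effect-size readouts.

The differential test is a transparent negative-binomial Wald test:
median-of-ratios size factors, per-gene method-of-moments dispersion pooled
across the two groups, and a t-referenced Wald statistic on the log ratio
of pseudo-counted group means. Multiple testing is controlled with
Benjamini-Hochberg. This is deliberately simpler than DESeq2's shrinkage
machinery — the consumed interface downstream is only the fold-change and
adjusted-p thresholds, and the percent-reduction / fold-change estimators
below.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors",
    "differential_expression",
    "percent_reduction",
    "fold_change",
    "mrna_fraction",
    "ddct",
]

PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors, rescaled to geometric mean 1.

    ``counts`` is genes x samples. Genes with a zero count in any sample are
    excluded from the median; if no gene is positive everywhere the factors
    fall back to total-count ratios (with a warning).
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        logs = np.log(mat[all_pos])
        log_geo = logs.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logs - log_geo, axis=0))
    else:
        warnings.warn(
            "no gene with nonzero counts in all samples; "
            "falling back to total-count size factors",
            stacklevel=2,
        )
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot compute size factors: empty library")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def differential_expression(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    prefilter_total: int = 10,
) -> pd.DataFrame:
    """NB Wald test of group B versus group A (A is the reference).

    Genes with fewer than ``prefilter_total`` raw reads across the used
    samples are excluded from testing (marked ``excluded``). Returns one row
    per gene with normalized group means, log2 fold change (pseudo-count
    0.5), raw and BH-adjusted p-values.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group requires at least two samples")
    cols = group_a + group_b
    sub = counts[cols]
    sf = size_factors(sub)
    norm = sub / sf

    na, nb = len(group_a), len(group_b)
    m_a = norm[group_a].mean(axis=1).to_numpy()
    m_b = norm[group_b].mean(axis=1).to_numpy()
    v_a = norm[group_a].var(axis=1, ddof=1).to_numpy()
    v_b = norm[group_b].var(axis=1, ddof=1).to_numpy()

    # pooled method-of-moments NB dispersion: var = mu + alpha * mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = np.where(m_a > 0, (v_a - m_a) / np.square(m_a), 0.0)
        alpha_b = np.where(m_b > 0, (v_b - m_b) / np.square(m_b), 0.0)
    alpha = np.clip((alpha_a + alpha_b) / 2.0, DISPERSION_FLOOR, 10.0)

    var_mean_a = (m_a + alpha * np.square(m_a)) / na
    var_mean_b = (m_b + alpha * np.square(m_b)) / nb
    se2 = var_mean_a / np.square(m_a + PSEUDOCOUNT) + var_mean_b / np.square(
        m_b + PSEUDOCOUNT
    )
    log_ratio = np.log(m_b + PSEUDOCOUNT) - np.log(m_a + PSEUDOCOUNT)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log_ratio / np.sqrt(se2)
    df = na + nb - 2
    pvals = np.where(se2 > 0, 2.0 * stats.t.sf(np.abs(z), df), 1.0)

    excluded = sub.sum(axis=1).to_numpy() < prefilter_total
    padj = np.full(len(pvals), np.nan)
    tested = ~excluded
    if tested.any():
        _, padj_t, _, _ = multipletests(pvals[tested], method="fdr_bh")
        padj[tested] = padj_t

    return pd.DataFrame(
        {
            "gene": counts.index,
            "base_mean_a": m_a,
            "base_mean_b": m_b,
            "log2_fc": np.log2(m_b + PSEUDOCOUNT) - np.log2(m_a + PSEUDOCOUNT),
            "pvalue": np.where(excluded, np.nan, pvals),
            "padj": padj,
            "excluded": excluded,
        }
    ).set_index("gene", drop=False)


def _means_for(de: pd.DataFrame, gene: str) -> tuple[float, float] | None:
    if gene not in de.index or bool(de.loc[gene, "excluded"]):
        return None
    return float(de.loc[gene, "base_mean_a"]), float(de.loc[gene, "base_mean_b"])


def percent_reduction(de: pd.DataFrame, gene: str) -> float | None:
    """100 x (1 - mutant/WT) from normalized pseudo-counted group means.

    Group A is wild type, group B the mutant. Negative values indicate an
    increase. ``None`` for untested (prefiltered) genes.
    """
    means = _means_for(de, gene)
    if means is None:
        return None
    m_wt, m_mut = means
    return 100.0 * (1.0 - (m_mut + PSEUDOCOUNT) / (m_wt + PSEUDOCOUNT))


def fold_change(de: pd.DataFrame, gene: str) -> float | None:
    """Linear fold change mutant/WT from pseudo-counted normalized means."""
    means = _means_for(de, gene)
    if means is None:
        return None
    m_wt, m_mut = means
    return (m_mut + PSEUDOCOUNT) / (m_wt + PSEUDOCOUNT)


def mrna_fraction(
    counts: pd.DataFrame,
    gene_set: Iterable[str],
    samples: Sequence[str] | None = None,
) -> tuple[pd.Series, float]:
    """Per-sample share of library counts in ``gene_set`` and the group mean."""
    genes = [g for g in gene_set]
    if not genes:
        raise ValueError("gene_set must be non-empty")
    sub = counts[list(samples)] if samples is not None else counts
    totals = sub.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("empty library in requested samples")
    frac = sub.loc[sub.index.intersection(genes)].sum(axis=0) / totals
    return frac, float(frac.mean())


def ddct(
    ct_table: pd.DataFrame,
    target: str,
    reference_gene: str = "Gapdh",
    calibrator_group: str = "WT",
) -> pd.DataFrame:
    """Comparative-Ct quantification: relative expression = 2^(-ddCt).

    ``ct_table`` columns: sample, group, gene, ct. dCt is target minus the
    reference gene (Gapdh) per sample; ddCt subtracts the calibrator-group
    mean dCt. Samples with a missing Ct are skipped with a warning.
    """
    wide = ct_table.pivot_table(index=["sample", "group"], columns="gene", values="ct")
    if reference_gene not in wide.columns:
        raise ValueError(f"reference gene {reference_gene!r} missing from Ct table")
    if target not in wide.columns:
        raise ValueError(f"target gene {target!r} missing from Ct table")
    dct = wide[target] - wide[reference_gene]
    missing = dct.isna()
    if missing.any():
        warnings.warn(
            f"skipping {int(missing.sum())} sample(s) with missing Ct", stacklevel=2
        )
        dct = dct[~missing]
    groups = dct.index.get_level_values("group")
    if calibrator_group not in set(groups):
        raise ValueError(f"calibrator group {calibrator_group!r} absent")
    cal_mean = dct[groups == calibrator_group].mean()
    ddct_vals = dct - cal_mean
    out = pd.DataFrame(
        {
            "sample": dct.index.get_level_values("sample"),
            "group": groups,
            "dct": dct.to_numpy(),
            "ddct": ddct_vals.to_numpy(),
            "relative_expression": np.power(2.0, -ddct_vals.to_numpy()),
        }
    )
    return out.reset_index(drop=True)
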