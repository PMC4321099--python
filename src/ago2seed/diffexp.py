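"""Replicate-level differential statistics and selection rules.

The selection rule throughout is the classic array-era one: a feature is
differential when its mean log2 ratio is at least 1 in magnitude (2-fold)
and a two-sided one-sample t-test of the replicate log2 ratios against zero
gives P < 0.05.  Thresholds are closed (|log2| = 1 passes) and no
multiple-testing correction is applied by default; an optional
Benjamini-Hochberg flag exists for sensitivity analyses.

Cross-genotype responsiveness classification selects features upregulated in
wild type but downregulated in both the Tlr4 and NF-kB knockouts.
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .arrays import ExpressionMatrix

GENOTYPE_COLUMNS = ("wildtype", "tlr4_ko", "nfkb_ko")

Direction = Literal["up", "down", "both"]


def replicate_stats(matrix: ExpressionMatrix | pd.DataFrame,
                    columns: Sequence[str] | None = None,
                    test: Literal["ttest", "wilcoxon"] = "ttest",
                    fdr: bool = False) -> pd.DataFrame:
    """Per-feature mean log2 ratio and P value across replicate columns.

    The location test is a two-sided one-sample t-test of the replicate log2
    ratios against 0 (``test='wilcoxon'`` switches to a signed-rank test for
    robustness checks).  Features with fewer than 2 finite replicates are
    dropped; if no feature has 2 replicates an error is raised.  Returns a
    DataFrame indexed by feature with columns ``mean_log2, p_value,
    n_replicates, passes``.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if columns is not None:
        values = values[list(columns)]
    arr = values.to_numpy(dtype=float)
    n_rep = np.isfinite(arr).sum(axis=1)
    if arr.shape[1] < 2 or n_rep.max() < 2:
        raise ValueError("at least 2 replicates required for a P value")
    usable = n_rep >= 2
    rows = []
    for feature, row, n in zip(values.index[usable], arr[usable], n_rep[usable]):
        vals = row[np.isfinite(row)]
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd == 0.0:
            p = 1.0 if mean == 0.0 else 0.0
        elif test == "wilcoxon":
            p = float(stats.wilcoxon(vals).pvalue)
        else:
            p = float(stats.ttest_1samp(vals, 0.0).pvalue)
        rows.append((feature, mean, p, int(n)))
    out = pd.DataFrame(rows, columns=["feature_id", "mean_log2", "p_value",
                                      "n_replicates"]).set_index("feature_id")
    if fdr:
        out["p_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["passes"] = (out["mean_log2"].abs() >= 1.0) & (out["p_value"] < 0.05)
    return out


def select_differential(results: pd.DataFrame, min_abs_log2: float = 1.0,
                        max_p: float = 0.05,
                        direction: Direction = "both") -> list[str]:
    """Sorted feature list passing both the fold and P-value clauses.

    ``direction`` restricts the sign of the mean log2 ratio; thresholds are
    closed on the fold clause (>= / <=) and open on the P clause (<).
    """
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    fold = results["mean_log2"]
    if direction == "up":
        fold_ok = fold >= min_abs_log2
    elif direction == "down":
        fold_ok = fold <= -min_abs_log2
    else:
        fold_ok = fold.abs() >= min_abs_log2
    selected = results.index[fold_ok & (results["p_value"] < max_p)]
    return sorted(set(selected))


def fold_lists(matrix: ExpressionMatrix | pd.DataFrame, arm: str,
               min_fold: float = 2.0) -> tuple[list[str], list[str]]:
    """2-fold up/down transcript lists from an mRNA-arm ratio matrix.

    The mean log2 ratio over replicate columns is thresholded at
    +/- log2(min_fold), boundary inclusive.  Returns (up, down), each sorted.
    """
    if arm not in ("mrna_total", "mrna_ago2ip"):
        raise ValueError(f"unknown mRNA arm {arm!r}")
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    mean = values.mean(axis=1, skipna=True)
    mean = mean[np.isfinite(mean)]
    cut = np.log2(min_fold)
    up = sorted(mean.index[mean >= cut])
    down = sorted(mean.index[mean <= -cut])
    return up, down


def genotype_fold_table(per_genotype: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Assemble a feature x genotype table of mean log2 folds.

    ``per_genotype`` maps genotype label -> replicate_stats output.  Only
    features present in all three genotypes are retained; wild-type P values
    ride along as ``wildtype_p``.
    """
    missing = [g for g in GENOTYPE_COLUMNS if g not in per_genotype]
    if missing:
        raise ValueError(f"missing genotype column(s): {', '.join(missing)}")
    table = pd.DataFrame({g: per_genotype[g]["mean_log2"] for g in GENOTYPE_COLUMNS})
    table["wildtype_p"] = per_genotype["wildtype"]["p_value"]
    return table.dropna()


def classify_responsive(table: pd.DataFrame, wt_min: float = 1.0,
                        ko_max: float = -1.0,
                        p_values: pd.Series | None = None,
                        max_p: float = 0.05) -> list[str]:
    """Features upregulated in wild type and downregulated in both knockouts.

    A feature is responsive when its wild-type log2 fold is >= ``wt_min``
    (and its wild-type P value is < ``max_p`` when P values are supplied,
    either via ``p_values`` or a ``wildtype_p`` column) and both knockout
    log2 folds are <= ``ko_max``.  Returns the sorted responsive feature list.
    """
    missing = [g for g in GENOTYPE_COLUMNS if g not in table.columns]
    if missing:
        raise ValueError(f"missing genotype column(s): {', '.join(missing)}")
    ok = ((table["wildtype"] >= wt_min)
          & (table["tlr4_ko"] <= ko_max)
          & (table["nfkb_ko"] <= ko_max))
    if p_values is None and "wildtype_p" in table.columns:
        p_values = table["wildtype_p"]
    if p_values is not None:
        ok &= p_values.reindex(table.index) < max_p
    return sorted(table.index[ok])


def write_results(results: pd.DataFrame, path, direction_of=None) -> None:
    """Serialize replicate_stats output as a tab-delimited table."""
    out = results.copy()
    out["direction"] = np.where(out["mean_log2"] > 0, "up",
                                np.where(out["mean_log2"] < 0, "down", "flat"))
    out.to_csv(path, sep="\t", index_label="feature_id")
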