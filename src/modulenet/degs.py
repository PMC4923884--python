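"""Differential expression filtering between risk groups.

Per-gene two-sided Student's t-test (pooled variance) between the high-
and low-risk groups; genes with p < alpha are selected, deliberately
without multiple-testing correction — the filter's purpose is dimension
reduction before network estimation, not inference.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .expression_io import RISK_EXCLUDED, RISK_HIGH, RISK_LOW, ExpressionMatrix


def ttest_degs(
    mat: ExpressionMatrix,
    labels: Mapping[str, str],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Test every gene for a mean difference between risk groups.

    ``labels`` maps sample id -> {high, low, excluded}; excluded samples
    are removed before testing. The t statistic is computed as
    (mean(high) - mean(low)) / pooled standard error. Genes constant in
    both groups are degenerate: reported with t=0, p=1, never selected.

    Returns a DataFrame indexed by gene with columns
    ``t_statistic, p_value, selected, degenerate``.
    """
    if not 0 < alpha < 1:
        raise DataError(f"alpha must be in (0, 1), got {alpha}")
    unknown = sorted({v for v in labels.values()} - {RISK_HIGH, RISK_LOW, RISK_EXCLUDED})
    if unknown:
        raise DataError(f"unknown risk labels: {unknown}")
    high = [s for s in mat.sample_ids if labels.get(s) == RISK_HIGH]
    low = [s for s in mat.sample_ids if labels.get(s) == RISK_LOW]
    if len(high) < 2 or len(low) < 2:
        raise DataError(
            f"each group needs >=2 samples (high={len(high)}, low={len(low)})"
        )
    idx = {s: j for j, s in enumerate(mat.sample_ids)}
    a = mat.values[:, [idx[s] for s in high]]
    b = mat.values[:, [idx[s] for s in low]]

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant genes trigger a scipy precision warning; they are
        # reported as degenerate below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = ~np.isfinite(t) | ~np.isfinite(p)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {
            "t_statistic": t,
            "p_value": p,
            "selected": p < alpha,
            "degenerate": degenerate,
        },
        index=pd.Index(mat.gene_ids, name="gene_id"),
    )


def selected_genes(result: pd.DataFrame) -> list[str]:
    return list(result.index[result["selected"]])


def write_deg_table(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t", lineterminator="\n")


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
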