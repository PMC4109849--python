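"""Population-level variability statistics.

The coefficient of variation (CV, standard deviation over mean) is the
work-horse dispersion measure for expression plasticity: it is scale-free, so
genes expressed at very different absolute levels can be compared.  For an
expression matrix with replicated conditions the per-gene summary is the
unweighted mean of per-condition CVs across replicates ("mean CV").

Also provided: the 2^(-dCT) transform for qRT-PCR abundances relative to a
control transcript, and a two-sided F-test comparing variances between two
groups of population summaries (used for colony-to-colony plasticity before
versus after liquid passaging).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (DegenerateTestError, InsufficientDataError, ParameterError,
                     UndefinedStatisticError)

logger = logging.getLogger(__name__)


def coefficient_of_variation(values) -> float:
    """Sample CV: standard deviation (n-1 denominator) divided by the mean.

    Raises
    ------
    InsufficientDataError
        Fewer than two finite values.
    UndefinedStatisticError
        Non-positive mean (the ratio would be meaningless or infinite).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise InsufficientDataError("CV needs at least 2 finite values")
    m = x.mean()
    if m <= 0:
        raise UndefinedStatisticError(f"CV undefined for mean {m!r} <= 0")
    return float(x.std(ddof=1) / m)


@dataclass(frozen=True)
class GeneVariability:
    """Per-gene cross-condition variability summary."""

    gene_id: str
    condition_cvs: dict
    mean_cv: float          # NaN when no condition had >= 2 replicates
    n_conditions_used: int


def gene_condition_cv(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-condition CV across replicates, averaged (unweighted) over conditions.

    Parameters
    ----------
    matrix
        Genes as rows; columns as a two-level MultiIndex
        ``(condition, replicate)`` (as produced by
        :func:`tagen.synthetic.simulate_expression_matrix` or
        :func:`tagen.io.read_expression_matrix`).

    Returns
    -------
    DataFrame indexed by gene with one column per condition plus ``mean_cv``
    and ``n_conditions_used``.  Conditions with fewer than two non-missing
    replicates for a gene are skipped, not imputed; genes with no usable
    condition get ``mean_cv = NaN`` and are expected to be dropped downstream.
    """
    if not isinstance(matrix.columns, pd.MultiIndex) or matrix.columns.nlevels != 2:
        raise ParameterError("matrix columns must be a (condition, replicate) MultiIndex")
    conditions = matrix.columns.get_level_values(0).unique()
    per_cond = {}
    for cond in conditions:
        sub = matrix[cond].astype(float)
        n_ok = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1, skipna=True)
        sd = sub.std(axis=1, ddof=1, skipna=True)
        cv = sd / mean
        cv[(n_ok < 2) | (mean <= 0)] = np.nan
        per_cond[cond] = cv
    cvs = pd.DataFrame(per_cond)
    out = cvs.copy()
    out["mean_cv"] = cvs.mean(axis=1, skipna=True)
    out["n_conditions_used"] = cvs.notna().sum(axis=1)
    n_skipped = int((cvs.isna()).to_numpy().sum())
    if n_skipped:
        logger.info("gene_condition_cv: skipped %d gene-condition cells "
                    "(<2 replicates or non-positive mean)", n_skipped)
    out.index.name = "gene_id"
    return out


def delta_ct_abundance(ct_gene, ct_control):
    """Relative abundance 2^-(ct_gene - ct_control) from qRT-PCR cycle values.

    Accepts scalars or arrays; one cycle difference halves the abundance.
    """
    g = np.asarray(ct_gene, dtype=float)
    c = np.asarray(ct_control, dtype=float)
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(c))):
        raise ParameterError("CT values must be finite")
    out = np.power(2.0, -(g - c))
    return float(out) if out.ndim == 0 else out


def variance_ratio_test(sample_a, sample_b) -> dict:
    """Two-sided F-test of equality of variances, F = var(a) / var(b).

    Returns ``{"F": ..., "df": (dfa, dfb), "p": ...}`` with sample variances
    (n-1 denominators) and the two-sided p-value ``2 * min(tail, 1 - tail)``
    capped at 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("variance ratio needs n >= 2 per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise DegenerateTestError("zero variance in denominator sample")
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    cdf = stats.f.cdf(f, dfa, dfb)
    p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    return {"F": float(f), "df": (dfa, dfb), "p": float(p)}
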