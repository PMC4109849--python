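"""Bootstrap and permutation procedures for variability comparisons.

Three bespoke resampling tests plus a cell subsampler:

* :func:`geneset_variability_test` — is a gene set's mean cross-condition CV
  higher than that of random gene sets of the same size?  The null is built
  from uniformly drawn gene sets (without replacement within a set); the
  97.5% quantile of the null is the critical value.
* :func:`cv_ratio_test` — is the CV of one cell population larger than
  another's beyond what label exchange explains?
* :func:`pedigree_permutation_test` — are mother-derived and daughter-derived
  populations more similar in mean ln(expression) than randomly re-affiliated
  pairs?  Lower-tailed: similarity means a *small* observed statistic.
* :func:`subsample_cells` — seeded uniform subsampling used to equalise cell
  counts between strains before noise comparisons.

All empirical p-values use the add-one estimator
``p = (1 + #{null at least as extreme}) / (n_resamples + 1)`` and can never
be zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import (DataError, DegenerateTestError, IdentifierError,
                     InsufficientDataError, ParameterError)
from .variability import coefficient_of_variation

logger = logging.getLogger(__name__)

_QUANTS = (2.5, 5.0, 95.0, 97.5)


@dataclass(frozen=True)
class ResamplingResult:
    """Observed statistic against a resampled null distribution."""

    observed: float
    null_quantiles: dict          # {2.5, 5.0, 95.0, 97.5} -> value
    critical_value: float
    empirical_p: float
    n_resamples: int
    seed: int
    tail: str                     # "upper" or "lower"
    significant: bool
    null: np.ndarray | None = field(default=None, repr=False, compare=False)

    def as_dict(self, include_null: bool = False) -> dict:
        d = asdict(self)
        if not include_null:
            d.pop("null")
        else:
            d["null"] = None if self.null is None else self.null.tolist()
        return d


def _finish(observed: float, null: np.ndarray, seed: int, tail: str,
            keep_null: bool) -> ResamplingResult:
    qs = {q: float(np.percentile(null, q)) for q in _QUANTS}
    n = null.size
    # summation order differs between observed and resampled means, so exact
    # ties must be recognised up to float round-off
    ties = np.isclose(null, observed, rtol=1e-12, atol=0.0)
    if tail == "upper":
        p = (1 + int(np.count_nonzero((null >= observed) | ties))) / (n + 1)
        crit = qs[97.5]
        sig = observed > crit and not np.isclose(observed, crit, rtol=1e-12)
    else:
        p = (1 + int(np.count_nonzero((null <= observed) | ties))) / (n + 1)
        crit = qs[5.0]
        sig = observed < crit and not np.isclose(observed, crit, rtol=1e-12)
    return ResamplingResult(
        observed=float(observed), null_quantiles=qs, critical_value=crit,
        empirical_p=float(p), n_resamples=int(n), seed=int(seed), tail=tail,
        significant=bool(sig), null=null if keep_null else None)


def geneset_variability_test(gene_cvs: pd.Series, target_set, n_boot: int = 50_000,
                             seed: int = 0, keep_null: bool = False) -> ResamplingResult:
    """Bootstrap test: mean CV of a gene set vs random sets of equal size.

    Parameters
    ----------
    gene_cvs
        Series mapping gene_id -> mean CV (e.g. the ``mean_cv`` column of
        :func:`tagen.variability.gene_condition_cv`).  Genes with missing CV
        are dropped from the universe.
    target_set
        Gene identifiers to test; must all be present in the universe.
    n_boot
        Number of random sets (default 50,000, the study's choice); the
        97.5% null quantile is the critical value, with an upper-tailed
        add-one empirical p alongside.
    """
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    universe = gene_cvs.dropna()
    target = list(dict.fromkeys(target_set))
    if len(target) < 1:
        raise ParameterError("target set must contain at least one gene")
    missing = [g for g in target if g not in universe.index]
    if missing:
        raise IdentifierError(
            f"{len(missing)} target gene(s) absent from universe: "
            f"{', '.join(map(str, missing[:10]))}", missing=missing)
    values = universe.to_numpy(dtype=float)
    k, n = len(target), values.size
    if k > n:
        raise ParameterError("target set larger than gene universe")
    observed = float(universe.loc[target].mean())

    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    # Gumbel-top-k in chunks: argpartition of uniform keys gives a uniform
    # k-subset per row without replacement, vectorised across resamples.
    chunk = max(1, min(n_boot, int(4e7 // max(n, 1))))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null[done:done + m] = values[idx].mean(axis=1)
        done += m
    return _finish(observed, null, seed, "upper", keep_null)


def cv_ratio_test(cells_a, cells_b, n_boot: int = 10_000, seed: int = 0,
                  keep_null: bool = False) -> ResamplingResult:
    """Permutation test of the CV ratio CV(b) / CV(a).

    Pools both groups, randomly re-assigns group labels preserving sizes, and
    recomputes the ratio; upper-tailed (is group b more variable than group a
    beyond exchangeability?).
    """
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    a = np.asarray(cells_a, dtype=float)
    b = np.asarray(cells_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each group needs >= 3 cells")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise DegenerateTestError("zero variance in a group")
    observed = coefficient_of_variation(b) / coefficient_of_variation(a)

    pool = np.concatenate([a, b])
    na, n = a.size, pool.size
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(4e7 // n)))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        perm = rng.permuted(np.broadcast_to(pool, (m, n)).copy(), axis=1)
        pa, pb = perm[:, :na], perm[:, na:]
        cv_a = pa.std(axis=1, ddof=1) / pa.mean(axis=1)
        cv_b = pb.std(axis=1, ddof=1) / pb.mean(axis=1)
        null[done:done + m] = cv_b / cv_a
        done += m
    return _finish(observed, null, seed, "upper", keep_null)


def _population_mean_ln(cells: pd.DataFrame, column: str) -> pd.Series:
    """Mean ln(intensity) per population; non-positive intensities excluded."""
    vals = cells[column].to_numpy(dtype=float)
    pos = vals > 0
    n_dropped = int((~pos).sum())
    if n_dropped:
        logger.info("pedigree test: excluded %d non-positive intensities from ln",
                    n_dropped)
    sub = cells.loc[pos, ["population_id"]].copy()
    sub["ln"] = np.log(vals[pos])
    means = sub.groupby("population_id", sort=True)["ln"].mean()
    empty = set(cells["population_id"].unique()) - set(means.index)
    if empty:
        raise DataError(f"population(s) with no positive intensities: {sorted(empty)}")
    return means


def pedigree_permutation_test(pairs: pd.DataFrame, n_perm: int = 10_000,
                              seed: int = 0, intensity_column: str = "channel1_intensity",
                              keep_null: bool = False) -> ResamplingResult:
    """Mother-daughter heritability test by randomised re-affiliation.

    The observed statistic is the mean over true pairs of
    ``|mean ln(mother) - mean ln(daughter)|`` where the means are per-cell
    ln(intensity) averaged within each population.  The null permutes
    daughter population labels among mothers (full random relabelings, the
    identity permutation allowed).  Heritability shows as an observed value
    *below* the 5% null quantile (lower tail).
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    needed = {"pedigree_pair_id", "role", "population_id", intensity_column}
    if not needed.issubset(pairs.columns):
        raise DataError(f"pedigree table needs columns {sorted(needed)}")
    means = _population_mean_ln(pairs, intensity_column)
    meta = (pairs[["population_id", "pedigree_pair_id", "role"]]
            .drop_duplicates().set_index("population_id"))
    mothers = meta[meta["role"] == "mother"]["pedigree_pair_id"]
    daughters = meta[meta["role"] == "daughter"]["pedigree_pair_id"]
    pair_ids = sorted(set(mothers) & set(daughters))
    if len(pair_ids) < 2:
        raise InsufficientDataError("need >= 2 complete mother-daughter pairs")
    m = np.array([means[mothers.index[mothers == p][0]] for p in pair_ids])
    d = np.array([means[daughters.index[daughters == p][0]] for p in pair_ids])
    observed = float(np.mean(np.abs(m - d)))

    rng = np.random.default_rng(seed)
    k = len(pair_ids)
    null = np.empty(n_perm)
    chunk = max(1, min(n_perm, 200_000 // k))
    done = 0
    while done < n_perm:
        mm = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((mm, k)), axis=1)
        null[done:done + mm] = np.abs(m[None, :] - d[perms]).mean(axis=1)
        done += mm
    return _finish(observed, null, seed, "lower", keep_null)


def subsample_cells(cells: pd.DataFrame, n: int, seed: int = 0) -> pd.DataFrame:
    """Uniform sample of ``n`` rows without replacement, original order kept.

    Used to equalise cell counts across strains before comparing noise
    statistics.  ``n`` equal to the table size returns the table unchanged.
    """
    total = len(cells)
    if n > total:
        raise InsufficientDataError(f"requested {n} cells from {total}")
    if n == total:
        return cells.copy()
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(total, size=n, replace=False))
    return cells.iloc[idx].reset_index(drop=True)
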