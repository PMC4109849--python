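"""Chromosomal position of genes relative to telomeres, and positional scans
of expression variability.

Genes are assigned to the chromosome arm whose telomere is nearer (arms split
at the centromere midpoint when a centromere table is supplied, at half the
chromosome length otherwise).  Within an arm, the telomere rank orders genes
by their distance to that arm's telomere (rank 1 = most telomere-proximal),
measured from the gene edge nearest the telomere, with 0-based half-open
coordinates.

The positional group scan then asks, for each rank k, whether the group of
the ``group_size`` most telomere-proximal genes *starting at rank k* (ordered
by rank, then distance) is more transcriptionally variable than random gene
sets of the same size — stepping sequentially from the telomere into
chromosome-internal genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateTestError, InsufficientDataError, ParameterError
from .resampling import ResamplingResult, geneset_variability_test

logger = logging.getLogger(__name__)


def assign_telomere_ranks(genes: pd.DataFrame, chrom_lengths: pd.Series | dict,
                          centromeres: pd.Series | dict | None = None) -> pd.DataFrame:
    """Assign arm, distance-to-telomere and telomere rank to each gene.

    Parameters
    ----------
    genes
        Columns ``chromosome, start, end, gene_id`` (BED-like, 0-based
        half-open).
    chrom_lengths
        Mapping chromosome -> length in bp.
    centromeres
        Optional mapping chromosome -> centromere midpoint; splits arms
        there instead of at length / 2.

    Returns a GenePosition table: ``gene_id, chromosome, arm, start, end,
    telomere_rank, distance_to_telomere``.  Ranks are 1-based, unique within
    an arm; distance ties are broken by gene_id (logged).
    """
    lengths = pd.Series(chrom_lengths)
    cens = None if centromeres is None else pd.Series(centromeres)
    missing = set(genes["chromosome"]) - set(lengths.index)
    if missing:
        raise DataError(f"no length for chromosome(s): {sorted(missing)}")

    g = genes[["gene_id", "chromosome", "start", "end"]].copy()
    g["length"] = g["chromosome"].map(lengths)
    if ((g["start"] < 0) | (g["end"] > g["length"]) | (g["start"] >= g["end"])).any():
        bad = g[(g["start"] < 0) | (g["end"] > g["length"]) | (g["start"] >= g["end"])]
        raise DataError(f"coordinates out of bounds for: {list(bad['gene_id'])}")

    split = (g["chromosome"].map(cens) if cens is not None
             else g["length"] / 2.0)
    mid = (g["start"] + g["end"]) / 2.0
    left = mid < split
    g["arm"] = np.where(left, "left", "right")
    g["distance_to_telomere"] = np.where(left, g["start"], g["length"] - g["end"]).astype(int)

    ties = g.duplicated(subset=["chromosome", "arm", "distance_to_telomere"], keep=False)
    if ties.any():
        logger.info("assign_telomere_ranks: %d distance ties broken by gene_id",
                    int(ties.sum()))
    g = g.sort_values(["chromosome", "arm", "distance_to_telomere", "gene_id"],
                      kind="mergesort")
    g["telomere_rank"] = g.groupby(["chromosome", "arm"]).cumcount() + 1
    cols = ["gene_id", "chromosome", "arm", "start", "end",
            "telomere_rank", "distance_to_telomere"]
    return g[cols].reset_index(drop=True)


def positional_group_scan(variability: pd.Series, positions: pd.DataFrame,
                          group_size: int = 16, n_boot: int = 50_000,
                          seed: int = 0, max_rank: int | None = None) -> pd.DataFrame:
    """Test telomere-rank gene groups for elevated variability.

    For each starting rank k the group is the first ``group_size`` genes with
    ``telomere_rank >= k``, ordered by (rank, distance, gene_id) so the group
    pools rank-k genes across arms before dipping into rank k+1.  Each group
    is tested with :func:`tagen.resampling.geneset_variability_test` against
    the full gene universe; the scan covers k = 1 .. ``max_rank`` (default:
    the largest rank with a full group, then one truncated group with a
    warning).

    Returns a DataFrame with one row per rank: observed mean CV, critical
    value (97.5% null quantile), empirical p and significance.
    """
    if group_size < 2:
        raise ParameterError("group_size must be >= 2")
    uni = variability.dropna()
    pos = positions[positions["gene_id"].isin(uni.index)]
    if pos.empty:
        raise DataError("no overlap between variability and position tables")
    ordered = pos.sort_values(["telomere_rank", "distance_to_telomere", "gene_id"],
                              kind="mergesort")
    ranks = ordered["telomere_rank"].to_numpy()
    ids = ordered["gene_id"].to_numpy()
    top = int(ranks.max()) if max_rank is None else int(max_rank)

    root = np.random.SeedSequence(seed)
    rows = []
    for k, ss in zip(range(1, top + 1), root.spawn(top)):
        sel = ids[ranks >= k]
        if sel.size == 0:
            break
        group = list(sel[:group_size])
        if len(group) < group_size:
            logger.warning("rank %d: only %d genes available (< group_size %d), "
                           "group truncated", k, len(group), group_size)
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        res = geneset_variability_test(uni, group, n_boot=n_boot, seed=sub_seed)
        rows.append({"rank": k, "n_genes": len(group),
                     "observed_mean_cv": res.observed,
                     "critical_value": res.critical_value,
                     "empirical_p": res.empirical_p,
                     "significant": res.significant})
    return pd.DataFrame(rows)


def distance_trend(variability: pd.Series, positions: pd.DataFrame,
                   coordinate: str = "telomere") -> dict:
    """Least-squares trend of mean CV against a genomic distance coordinate.

    ``coordinate='telomere'`` regresses on distance-to-telomere;
    ``'centromere'`` uses the distance from the arm split point instead
    (computed as arm span minus distance-to-telomere), matching analyses that
    frame position relative to the centromere.
    """
    merged = positions.merge(variability.rename("mean_cv"),
                             left_on="gene_id", right_index=True).dropna(subset=["mean_cv"])
    if len(merged) < 3:
        raise InsufficientDataError("distance trend needs >= 3 genes")
    if coordinate == "telomere":
        x = merged["distance_to_telomere"].to_numpy(dtype=float)
    elif coordinate == "centromere":
        span = merged.groupby(["chromosome", "arm"])["distance_to_telomere"].transform("max")
        x = (span - merged["distance_to_telomere"]).to_numpy(dtype=float)
    else:
        raise ParameterError("coordinate must be 'telomere' or 'centromere'")
    y = merged["mean_cv"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("zero variance in distance or variability")
    res = stats.linregress(x, y)
    return {"slope_per_bp": float(res.slope), "pearson_r": float(res.rvalue),
            "p": float(res.pvalue), "n": int(len(merged)),
            "coordinate": coordinate}
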