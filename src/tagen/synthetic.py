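"""Synthetic data generators with the statistical structure of telomere-adjacent
gene expression noise experiments.

The central object is a two-state ("telegraph") promoter: a locus toggles
between an active chromatin state with mean expression ``mu_on`` and a silent
state with mean ``mu_off``.  A population sampled at a single time point is a
mixture of the two states at the stationary occupancy ``k_on / (k_on + k_off)``.
On top of the state mixture, three noise sources act per cell:

* a *shared extrinsic* lognormal scale factor (cell size, ribosome content, ...)
  with log-scale standard deviation ``sigma_extrinsic`` and mean 1, common to
  every allele in the cell;
* an *intrinsic* lognormal factor per allele (coefficient of variation
  ``cv_intrinsic``, mean 1), independent between alleles;
* additive Gaussian *measurement* noise with standard deviation
  ``cv_measurement`` times the expected population mean, truncated at zero.

Locked modes emulate selection experiments in which a subtelomeric marker is
held constitutively active (growth without uracil) or silent (5-FOA
counterselection): every cell is forced into one state and the mixture
component of the noise disappears.

Colony and pedigree generators grow populations as synchronous binary division
trees with per-division epigenetic state flips, so a founder cell's state is
heritably propagated — the "founder effect" that makes colony-to-colony
variability exceed cell-to-cell variability for slowly toggling loci.

Randomness contract
-------------------
Every generator takes an integer ``seed`` and is bit-deterministic given it.
``make_telegraph_population`` draws, in this fixed order, from a single
``numpy.random.default_rng(seed)`` stream:

1. ``rng.random(n_cells)`` state uniforms (drawn in every lock mode, ignored
   unless toggling);
2. ``rng.standard_normal(n_cells)`` extrinsic log-deviates;
3. ``rng.standard_normal((n_cells, n_alleles))`` intrinsic log-deviates;
4. ``rng.standard_normal((n_cells, n_alleles))`` measurement deviates.

Tests re-derive expression values from this documented stream to validate the
arithmetic independently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GeometryError, ParameterError

logger = logging.getLogger(__name__)

_LOCK_MODES = ("toggling", "locked_on", "locked_off")


@dataclass(frozen=True)
class TelegraphParams:
    """Parameters of the two-state promoter and its noise sources.

    Rates are per generation; expression means are in arbitrary fluorescence
    units (AU); all coefficients of variation are dimensionless.
    """

    k_on: float = 0.1
    k_off: float = 0.1
    mu_on: float = 100.0
    mu_off: float = 5.0
    cv_intrinsic: float = 0.1
    sigma_extrinsic: float = 0.1
    cv_measurement: float = 0.05
    lock_mode: str = "toggling"

    def __post_init__(self):
        vals = (self.k_on, self.k_off, self.mu_on, self.mu_off,
                self.cv_intrinsic, self.sigma_extrinsic, self.cv_measurement)
        if not all(math.isfinite(v) for v in vals):
            raise ParameterError("telegraph parameters must be finite")
        if min(vals) < 0:
            raise ParameterError("rates, means and CVs must be >= 0")
        if not self.mu_on > self.mu_off:
            raise ParameterError(
                f"mu_on ({self.mu_on}) must exceed mu_off ({self.mu_off})")
        if self.lock_mode not in _LOCK_MODES:
            raise ParameterError(
                f"lock_mode must be one of {_LOCK_MODES}, got {self.lock_mode!r}")
        if self.lock_mode == "toggling" and self.k_on == 0 and self.k_off == 0:
            raise ConfigurationError(
                "k_on = k_off = 0 leaves the stationary state undefined")

    @property
    def p_active(self) -> float:
        """Stationary probability of the active state (0 or 1 when locked)."""
        if self.lock_mode == "locked_on":
            return 1.0
        if self.lock_mode == "locked_off":
            return 0.0
        return self.k_on / (self.k_on + self.k_off)


@dataclass(frozen=True)
class TelegraphMoments:
    """Closed-form population moments implied by a :class:`TelegraphParams`.

    Derived for the multiplicative model ``X = E * S * I + M`` with
    ``E`` lognormal(mean 1, log-sd sigma), ``S`` the two-point state mean,
    ``I`` lognormal(mean 1, CV c_i) and ``M`` additive Gaussian noise
    (truncation at zero ignored; negligible for the CV ranges used here).
    ``eta_*2`` are the dual-reporter squared-noise components expected when
    two alleles share ``E`` and ``S`` but draw independent ``I`` and ``M``.
    """

    mean: float
    variance: float
    cv: float
    eta_int2: float
    eta_ext2: float
    eta_tot2: float


def telegraph_moments(params: TelegraphParams) -> TelegraphMoments:
    p = params.p_active
    mean_s = p * params.mu_on + (1 - p) * params.mu_off
    if mean_s <= 0:
        raise ParameterError("expected state mean must be positive for moments")
    s2 = (p * params.mu_on**2 + (1 - p) * params.mu_off**2) / mean_s**2
    v_e = math.expm1(params.sigma_extrinsic**2)
    v_i = params.cv_intrinsic**2
    v_m = params.cv_measurement**2
    eta_ext2 = (1 + v_e) * s2 - 1
    eta_int2 = (1 + v_e) * s2 * v_i + v_m
    cv2 = (1 + v_e) * (1 + v_i) * s2 - 1 + v_m
    return TelegraphMoments(
        mean=mean_s,
        variance=cv2 * mean_s**2,
        cv=math.sqrt(cv2),
        eta_int2=eta_int2,
        eta_ext2=eta_ext2,
        eta_tot2=eta_int2 + eta_ext2,
    )


@dataclass(frozen=True)
class ColonyModel:
    """Founder-seeded colony growth model.

    A colony grows from one founder through ``generations`` synchronous
    divisions; each daughter's epigenetic state flips with probability
    ``p_switch_per_division``.  ``region_id`` partitions the ordered leaves of
    the division tree into ``n_regions_per_colony`` contiguous blocks, a proxy
    for sampling spatially distinct sectors of a colony.
    """

    n_colonies: int = 6
    cells_per_colony: int = 200
    generations: int = 10
    p_founder_on: float = 0.5
    p_switch_per_division: float = 0.02
    n_regions_per_colony: int = 2

    def __post_init__(self):
        for name in ("n_colonies", "cells_per_colony", "generations",
                     "n_regions_per_colony"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        for name in ("p_founder_on", "p_switch_per_division"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.cells_per_colony < self.n_regions_per_colony:
            raise ConfigurationError(
                "cells_per_colony must be >= n_regions_per_colony")
        if self.cells_per_colony > 2 ** self.generations:
            raise ConfigurationError(
                f"{self.generations} generations yield only "
                f"{2 ** self.generations} leaves; cannot sample "
                f"{self.cells_per_colony} cells")


# ---------------------------------------------------------------------------
# core sampling helpers
# ---------------------------------------------------------------------------

def _expression_given_states(states: np.ndarray, params: TelegraphParams,
                             rng: np.random.Generator,
                             n_alleles: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-cell intensities given boolean chromatin states.

    Implements stages 2-4 of the documented randomness contract.  Returns
    ``(intensity, true_signal)`` with shape ``(n_cells, n_alleles)``.
    """
    n = states.shape[0]
    sigma = params.sigma_extrinsic
    extrinsic = np.exp(sigma * rng.standard_normal(n) - 0.5 * sigma**2)

    s_int = math.sqrt(math.log1p(params.cv_intrinsic**2))
    intrinsic = np.exp(s_int * rng.standard_normal((n, n_alleles))
                       - 0.5 * s_int**2)

    state_mean = np.where(states, params.mu_on, params.mu_off)
    signal = extrinsic[:, None] * state_mean[:, None] * intrinsic

    p = params.p_active
    pop_mean = p * params.mu_on + (1 - p) * params.mu_off
    meas_sd = params.cv_measurement * pop_mean
    intensity = signal + meas_sd * rng.standard_normal((n, n_alleles))
    n_clipped = int(np.count_nonzero(intensity < 0))
    if n_clipped:
        logger.info("measurement noise clipped %d/%d intensities at zero",
                    n_clipped, intensity.size)
        intensity = np.clip(intensity, 0.0, None)
    return intensity, signal


def _draw_states(params: TelegraphParams, n_cells: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Stationary (or locked) chromatin states; stage 1 of the contract."""
    u = rng.random(n_cells)
    if params.lock_mode == "locked_on":
        return np.ones(n_cells, dtype=bool)
    if params.lock_mode == "locked_off":
        return np.zeros(n_cells, dtype=bool)
    return u < params.p_active


def make_telegraph_population(params: TelegraphParams, n_cells: int,
                              seed: int, n_alleles: int = 1,
                              population_id: str = "pop0") -> pd.DataFrame:
    """Sample a single-time-point population from the telegraph model.

    Returns a cell table with ``channel1_intensity`` (and
    ``channel2_intensity`` when ``n_alleles == 2``) plus latent truth columns
    ``true_state`` and ``true_signal``.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if n_alleles not in (1, 2):
        raise ParameterError("n_alleles must be 1 or 2")
    rng = np.random.default_rng(seed)
    states = _draw_states(params, n_cells, rng)
    intensity, signal = _expression_given_states(states, params, rng, n_alleles)

    table = pd.DataFrame({
        "cell_id": [f"c{i:06d}" for i in range(n_cells)],
        "population_id": population_id,
        "colony_id": pd.NA,
        "region_id": pd.NA,
        "pedigree_pair_id": pd.NA,
        "role": "none",
        "channel1_intensity": intensity[:, 0],
        "true_state": np.where(states, "active", "silent"),
        "true_signal": signal[:, 0],
    })
    if n_alleles == 2:
        table.insert(7, "channel2_intensity", intensity[:, 1])
    return table


def _grow_state_tree(founders: np.ndarray, generations: int,
                     p_on_to_off: float, p_off_to_on: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Synchronous binary division tree of chromatin states.

    ``founders`` is a boolean array (one entry per independent lineage);
    returns a ``(n_lineages, 2**generations)`` boolean leaf array in tree
    order.  Each daughter switches state independently at division.
    """
    states = np.asarray(founders, dtype=bool)[:, None]
    for _ in range(generations):
        states = np.repeat(states, 2, axis=1)
        u = rng.random(states.shape)
        switched = np.where(states, u < p_on_to_off, u < p_off_to_on)
        states = states ^ switched
    return states


def _evenly_spaced_leaves(n_leaves: int, n_sample: int) -> np.ndarray:
    """Indices of ``n_sample`` leaves spread evenly across tree order."""
    return np.unique(np.linspace(0, n_leaves - 1, n_sample).round().astype(int)) \
        if n_sample < n_leaves else np.arange(n_leaves)


def simulate_colonies(params: TelegraphParams, colony_model: ColonyModel,
                      seed: int) -> pd.DataFrame:
    """Grow founder-seeded colonies and sample cells with region labels."""
    cm = colony_model
    rng = np.random.default_rng(seed)

    if params.lock_mode == "locked_on":
        founders = np.ones(cm.n_colonies, dtype=bool)
        p_switch = 0.0
    elif params.lock_mode == "locked_off":
        founders = np.zeros(cm.n_colonies, dtype=bool)
        p_switch = 0.0
    else:
        founders = rng.random(cm.n_colonies) < cm.p_founder_on
        p_switch = cm.p_switch_per_division

    leaves = _grow_state_tree(founders, cm.generations, p_switch, p_switch, rng)
    idx = _evenly_spaced_leaves(leaves.shape[1], cm.cells_per_colony)
    if idx.size < cm.cells_per_colony:  # rounding collisions cannot occur, guard anyway
        raise ConfigurationError("could not sample distinct leaves")
    states = leaves[:, idx]                       # (n_colonies, cells_per_colony)

    region_edges = np.linspace(0, cm.cells_per_colony,
                               cm.n_regions_per_colony + 1).astype(int)
    region_of_cell = np.searchsorted(region_edges[1:], np.arange(cm.cells_per_colony),
                                     side="right")

    frames = []
    for c in range(cm.n_colonies):
        intensity, signal = _expression_given_states(states[c], params, rng)
        frames.append(pd.DataFrame({
            "cell_id": [f"col{c:03d}_c{i:05d}" for i in range(cm.cells_per_colony)],
            "population_id": f"colony{c:03d}",
            "colony_id": f"colony{c:03d}",
            "region_id": [f"colony{c:03d}_r{r}" for r in region_of_cell],
            "pedigree_pair_id": pd.NA,
            "role": "none",
            "channel1_intensity": intensity[:, 0],
            "true_state": np.where(states[c], "active", "silent"),
            "true_signal": signal[:, 0],
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_pedigree(params: TelegraphParams, n_pairs: int = 10,
                      cells_per_population: int = 50,
                      p_switch_per_division: float = 0.02,
                      generations: int = 10, seed: int = 0,
                      p_founder_on: float | None = None) -> pd.DataFrame:
    """Mother/daughter pedigree populations sharing a founder state.

    Each pair starts from one founder cell; after the first division the
    mother and the bud grow into separate populations of
    ``cells_per_population`` cells over ``generations`` divisions, inheriting
    (and occasionally flipping) the founder's epigenetic state.
    """
    if n_pairs < 2:
        raise ConfigurationError("pedigree analysis needs n_pairs >= 2")
    if cells_per_population > 2 ** generations:
        raise ConfigurationError("not enough generations for the population size")
    rng = np.random.default_rng(seed)
    p_on = params.p_active if p_founder_on is None else p_founder_on
    founders = rng.random(n_pairs) < p_on
    if params.lock_mode != "toggling":
        p_switch_per_division = 0.0

    # lineages interleaved as (pair0 mother, pair0 daughter, pair1 mother, ...)
    lineage_founders = np.repeat(founders, 2)
    leaves = _grow_state_tree(lineage_founders, generations,
                              p_switch_per_division, p_switch_per_division, rng)
    idx = _evenly_spaced_leaves(leaves.shape[1], cells_per_population)
    states = leaves[:, idx]

    frames = []
    for lineage in range(2 * n_pairs):
        pair, is_daughter = divmod(lineage, 2)
        role = "daughter" if is_daughter else "mother"
        intensity, signal = _expression_given_states(states[lineage], params, rng)
        frames.append(pd.DataFrame({
            "cell_id": [f"p{pair:02d}_{role[0]}{i:04d}"
                        for i in range(cells_per_population)],
            "population_id": f"pair{pair:02d}_{role}",
            "colony_id": pd.NA,
            "region_id": pd.NA,
            "pedigree_pair_id": f"pair{pair:02d}",
            "role": role,
            "channel1_intensity": intensity[:, 0],
            "true_state": np.where(states[lineage], "active", "silent"),
            "true_signal": signal[:, 0],
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# expression-matrix generator (RNA-Seq-like replicate structure)
# ---------------------------------------------------------------------------

def _resolve_rank_params(rank_params: Mapping[int, TelegraphParams],
                         rank: int) -> TelegraphParams:
    """Largest configured rank <= ``rank`` (the mapping defines breakpoints)."""
    keys = sorted(rank_params)
    chosen = keys[0]
    for k in keys:
        if k <= rank:
            chosen = k
    return rank_params[chosen]


def simulate_expression_matrix(rank_params: Mapping[int, TelegraphParams],
                               n_genes: int, n_conditions: int = 11,
                               n_replicates: int = 2, seed: int = 0,
                               n_arms: int = 8, cells_per_replicate: int = 64,
                               replicate_generations: int = 6,
                               condition_sd: float = 0.25,
                               gene_length: int = 1500,
                               intergenic: int = 4000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x (condition, replicate) abundance matrix with positional structure.

    Each replicate abundance is the mean expression of a founder-seeded
    population grown for ``replicate_generations`` divisions with per-division
    switch probabilities ``k_on`` (silent->active) and ``k_off``
    (active->silent): slow toggling leaves replicate populations dominated by
    their founder's state and therefore highly variable between replicates.
    Condition-specific lognormal mean shifts (log-sd ``condition_sd``) are
    shared by a condition's replicates so they inflate cross-condition spread
    but not the within-condition replicate CV.

    Genes are laid out round-robin across ``n_arms`` chromosome arms, so
    telomere rank ``r`` appears once per arm; the telegraph parameters of a
    gene are taken from ``rank_params`` at the largest configured rank not
    exceeding the gene's rank.
    """
    if not rank_params:
        raise ConfigurationError("rank_params must configure at least one rank")
    if n_replicates < 2:
        raise ConfigurationError("CV analysis needs n_replicates >= 2")
    if cells_per_replicate > 2 ** replicate_generations:
        raise ConfigurationError("not enough generations per replicate population")
    rng = np.random.default_rng(seed)

    ranks = np.arange(n_genes) // n_arms + 1
    arms_idx = np.arange(n_genes) % n_arms
    max_rank = int(ranks.max())
    chrom_length = 2 * (intergenic + max_rank * (gene_length + intergenic)) + 50_000

    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    chroms = [f"chr{arms_idx[i] // 2 + 1}" for i in range(n_genes)]
    arm_side = np.where(arms_idx % 2 == 0, "left", "right")
    dist = intergenic + (ranks - 1) * (gene_length + intergenic)
    start = np.where(arm_side == "left", dist, chrom_length - dist - gene_length)
    end = start + gene_length
    positions = pd.DataFrame({
        "gene_id": gene_ids, "chromosome": chroms, "arm": arm_side,
        "start": start, "end": end, "telomere_rank": ranks,
        "distance_to_telomere": dist,
    })

    n_pop = n_conditions * n_replicates
    values = np.empty((n_genes, n_pop))
    cond_shift = np.exp(condition_sd * rng.standard_normal((n_genes, n_conditions))
                        - 0.5 * condition_sd**2)

    for g in range(n_genes):
        p = _resolve_rank_params(rank_params, int(ranks[g]))
        if p.lock_mode == "toggling":
            founders = rng.random(n_pop) < p.p_active
            p_a2s, p_s2a = min(p.k_off, 1.0), min(p.k_on, 1.0)
        else:
            founders = np.full(n_pop, p.lock_mode == "locked_on")
            p_a2s = p_s2a = 0.0
        leaves = _grow_state_tree(founders, replicate_generations, p_a2s, p_s2a, rng)
        idx = _evenly_spaced_leaves(leaves.shape[1], cells_per_replicate)
        states = leaves[:, idx]
        intensity, _ = _expression_given_states(states.ravel(), p, rng)
        pop_means = intensity[:, 0].reshape(n_pop, -1).mean(axis=1)
        values[g] = pop_means * np.repeat(cond_shift[g], n_replicates)

    columns = pd.MultiIndex.from_product(
        [[f"cond{c + 1:02d}" for c in range(n_conditions)],
         [f"rep{r + 1}" for r in range(n_replicates)]],
        names=["condition", "replicate"])
    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                          columns=columns)
    return matrix, positions


# ---------------------------------------------------------------------------
# flow cytometry events
# ---------------------------------------------------------------------------

def simulate_flow_events(params: TelegraphParams, n_events: int = 100_000,
                         frac_debris: float = 0.02, seed: int = 0,
                         fsc_median: float = 500.0, ssc_median: float = 300.0,
                         scatter_log_sd: float = 0.25) -> pd.DataFrame:
    """Flow-cytometry event table (fsc, ssc, fl1) with a debris fraction.

    FL1 follows the telegraph model; forward and side scatter are lognormal.
    A ``frac_debris`` fraction of events receives zero FSC or SSC so that
    gating on measurable scatter has something to remove.
    """
    if n_events < 1:
        raise ParameterError("n_events must be >= 1")
    if not 0.0 <= frac_debris <= 1.0:
        raise ParameterError("frac_debris must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cells = make_telegraph_population(params, n_events, seed=int(rng.integers(2**31)))
    fsc = fsc_median * np.exp(scatter_log_sd * rng.standard_normal(n_events))
    ssc = ssc_median * np.exp(scatter_log_sd * rng.standard_normal(n_events))
    debris = rng.random(n_events) < frac_debris
    which = rng.random(n_events) < 0.5
    fsc[debris & which] = 0.0
    ssc[debris & ~which] = 0.0
    events = pd.DataFrame({"fsc": fsc, "ssc": ssc,
                           "fl1": cells["channel1_intensity"].to_numpy()})
    events.attrs["gated"] = False
    return events


# ---------------------------------------------------------------------------
# nuclear image rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageGeometry:
    """Frame layout for rendered nuclei.

    Nuclei are 2-D Gaussian spots of width ``spot_sigma`` placed on a regular
    grid with ``spacing`` pixels between centres and ``margin`` pixels kept
    clear at the frame edge (annotation boxes must fit around each spot).
    Signal is spread over ``n_z`` focal planes with a Gaussian axial profile
    of width ``z_sigma`` planes, mirroring a z-stack acquired in 1 µm steps.
    """

    shape: tuple[int, int] = (256, 256)
    n_z: int = 8
    spot_sigma: float = 2.5
    spacing: int = 32
    margin: int = 16
    z_sigma: float = 1.5

    def grid_centres(self, n_cells: int) -> np.ndarray:
        h, w = self.shape
        rows = np.arange(self.margin, h - self.margin + 1, self.spacing)
        cols = np.arange(self.margin, w - self.margin + 1, self.spacing)
        if rows.size * cols.size < n_cells:
            raise GeometryError(
                f"geometry fits {rows.size * cols.size} nuclei, need {n_cells}")
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])[:n_cells]


@dataclass(frozen=True)
class ImagingNoiseModel:
    """Background and noise applied to each rendered focal plane."""

    background_level: float = 0.0        # per-plane uniform offset, AU
    gradient: tuple[float, float] = (0.0, 0.0)   # per-pixel slope (d/drow, d/dcol)
    read_noise_sd: float = 0.0           # per-plane Gaussian sd, AU
    counting_noise: bool = False         # Poisson resampling of plane values

    def __post_init__(self):
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ParameterError("background and noise levels must be >= 0")


def render_nuclei_stack(truth: pd.DataFrame, geometry: ImageGeometry,
                        noise_model: ImagingNoiseModel, seed: int = 0,
                        signal_column: str = "true_signal"):
    """Render a z-stack of Gaussian nuclei plus region annotations and truth.

    Returns ``(stack, annotations, truth_table)``.  The stack is float64 with
    shape ``(n_z, H, W)``; quantisation to 16-bit happens only when writing
    TIFF.  Each cell's ``expected_signal`` in the truth table is exactly what
    :func:`tagen.imaging.nuclear_intensity` computes on the *noiseless*
    summed projection, so recovery error under noise is purely noise-driven.
    """
    from .imaging import RegionAnnotation, nuclear_intensity, project_zstack

    rng = np.random.default_rng(seed)
    signals = truth[signal_column].to_numpy(dtype=float)
    n_cells = signals.size
    centres = geometry.grid_centres(n_cells)

    h, w = geometry.shape
    yy, xx = np.mgrid[0:h, 0:w]
    clean = np.zeros((h, w))
    two_s2 = 2.0 * geometry.spot_sigma**2
    for (cy, cx), a in zip(centres, signals):
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        near = r2 < (6 * geometry.spot_sigma) ** 2
        clean[near] += a * np.exp(-r2[near] / two_s2)

    z = np.arange(geometry.n_z)
    zw = np.exp(-0.5 * ((z - (geometry.n_z - 1) / 2) / geometry.z_sigma) ** 2)
    zw /= zw.sum()

    annotations = []
    for cid, (cy, cx) in zip(truth["cell_id"], centres):
        cy, cx = int(cy), int(cx)
        annotations.append(RegionAnnotation(
            cell_id=str(cid),
            nuclear=((cy - 4, cx - 4), (cy - 4, cx), (cy, cx - 2)),
            background=((cy - 12, cx - 12), (cy - 12, cx + 8), (cy + 8, cx - 12)),
        ))

    expected = [nuclear_intensity(clean, ann)["signal"] for ann in annotations]
    truth_table = truth[["cell_id"]].copy()
    truth_table["true_signal"] = signals
    truth_table["expected_signal"] = expected

    nm = noise_model
    grad = nm.gradient[0] * yy + nm.gradient[1] * xx
    stack = np.empty((geometry.n_z, h, w))
    for k in range(geometry.n_z):
        plane = clean * zw[k] + nm.background_level + grad
        if nm.counting_noise:
            plane = rng.poisson(np.clip(plane, 0, None)).astype(float)
        if nm.read_noise_sd > 0:
            plane = plane + nm.read_noise_sd * rng.standard_normal((h, w))
        stack[k] = plane

    # sanity: noiseless geometry round-trips through the projection
    assert project_zstack(stack).shape == clean.shape
    return stack, annotations, truth_table
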