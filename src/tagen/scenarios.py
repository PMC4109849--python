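"""End-to-end scenario orchestration on synthetic data.

Each scenario generates the inputs it needs with :mod:`tagen.synthetic`, runs
the corresponding analysis chain, optionally writes intermediates plus a
provenance record to an output directory, and returns a JSON-serialisable
report.  Scenarios mirror the experimental designs the analyses were built
for:

``geneset_cv``       gene-set bootstrap on a cross-condition expression matrix
``positional_scan``  telomere-rank variability scan
``dual_reporter``    two-channel populations, noise decomposition, paired test
``pedigree``         mother-daughter heritability permutation test
``colony_founder``   founder effects: slow vs fast epigenetic switching
``flow_noise``       flow-event gating and Robust CV summary
``lock_selection``   toggling vs locked-state population CV comparison
``image_recovery``   rendered nuclei, quantification, truth recovery error

All randomness in a scenario flows from the single mandatory ``seed`` through
named ``numpy.random.SeedSequence`` substreams, so reports are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .errors import ConfigurationError
from .flow import flow_summary, gate_events, robust_cv
from .imaging import quantify_stack
from .noise import decompose_by_population, paired_component_test
from .positional import positional_group_scan
from .resampling import (geneset_variability_test, pedigree_permutation_test)
from .synthetic import (ColonyModel, ImageGeometry, ImagingNoiseModel,
                        TelegraphParams, make_telegraph_population,
                        render_nuclei_stack, simulate_colonies,
                        simulate_expression_matrix, simulate_flow_events,
                        simulate_pedigree)
from .variability import (coefficient_of_variation, gene_condition_cv,
                          variance_ratio_test)

SCENARIOS = ("geneset_cv", "positional_scan", "dual_reporter", "pedigree",
             "colony_founder", "flow_noise", "lock_selection", "image_recovery")


@dataclass(frozen=True)
class ScenarioConfig:
    """A named scenario with its seed and parameter overrides."""

    scenario: str
    seed: int
    out_dir: str | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {"scenario", "seed", "out_dir", "params"}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ConfigurationError("config must set a seed")
        return cls(scenario=d["scenario"], seed=int(d["seed"]),
                   out_dir=d.get("out_dir"), params=dict(d.get("params", {})))


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _noisy_params(**over) -> TelegraphParams:
    base = dict(k_on=0.05, k_off=0.05, mu_on=100.0, mu_off=5.0,
                cv_intrinsic=0.2, sigma_extrinsic=0.2, cv_measurement=0.05)
    base.update(over)
    return TelegraphParams(**base)


# ---------------------------------------------------------------------------
# individual scenarios
# ---------------------------------------------------------------------------

def _scenario_geneset_cv(p: dict, seed: int, out: Path | None) -> dict:
    n_genes = p.get("n_genes", 400)
    n_boot = p.get("n_boot", 5_000)
    set_size = p.get("set_size", 13)
    s1, s2 = _sub_seeds(seed, 2)
    rank_params = {1: _noisy_params(), 4: _noisy_params(k_on=0.5, k_off=0.5)}
    matrix, positions = simulate_expression_matrix(rank_params, n_genes, seed=s1)
    cvs = gene_condition_cv(matrix)["mean_cv"]
    target = (positions.sort_values(["telomere_rank", "distance_to_telomere"])
              ["gene_id"].head(set_size).tolist())
    res = geneset_variability_test(cvs, target, n_boot=n_boot, seed=s2)
    if out:
        tio.write_expression_matrix(matrix, out / "expression_matrix.tsv")
        positions.to_csv(out / "gene_positions.tsv", sep="\t", index=False)
    return {"target_set": target, "result": res.as_dict()}


def _scenario_positional_scan(p: dict, seed: int, out: Path | None) -> dict:
    n_genes = p.get("n_genes", 400)
    n_boot = p.get("n_boot", 2_000)
    group_size = p.get("group_size", 16)
    max_rank = p.get("max_rank", 8)
    s1, s2 = _sub_seeds(seed, 2)
    rank_params = {1: _noisy_params(), 4: _noisy_params(k_on=0.5, k_off=0.5)}
    matrix, positions = simulate_expression_matrix(rank_params, n_genes, seed=s1)
    cvs = gene_condition_cv(matrix)["mean_cv"]
    scan = positional_group_scan(cvs, positions, group_size=group_size,
                                 n_boot=n_boot, seed=s2, max_rank=max_rank)
    if out:
        scan.to_csv(out / "positional_scan.tsv", sep="\t", index=False)
    return {"scan": scan.to_dict(orient="records")}


def _scenario_dual_reporter(p: dict, seed: int, out: Path | None) -> dict:
    n_pop = p.get("n_populations", 12)
    n_cells = p.get("cells_per_population", 50)
    params = _noisy_params(**p.get("telegraph", {}))
    seeds = _sub_seeds(seed, n_pop)
    tables = [make_telegraph_population(params, n_cells, seed=s, n_alleles=2,
                                        population_id=f"pop{i:02d}")
              for i, s in enumerate(seeds)]
    cells = pd.concat(tables, ignore_index=True)
    decomps = decompose_by_population(cells)
    test = paired_component_test(decomps)
    if out:
        tio.write_cell_table(cells, out / "dual_reporter_cells.csv")
        pd.DataFrame([d.as_dict() for d in decomps]).to_csv(
            out / "noise_decompositions.tsv", sep="\t", index=False)
    return {"decompositions": [d.as_dict() for d in decomps],
            "paired_test": test}


def _scenario_pedigree(p: dict, seed: int, out: Path | None) -> dict:
    s1, s2 = _sub_seeds(seed, 2)
    params = _noisy_params(**p.get("telegraph", {}))
    cells = simulate_pedigree(params, n_pairs=p.get("n_pairs", 10),
                              cells_per_population=p.get("cells_per_population", 50),
                              p_switch_per_division=p.get("p_switch_per_division", 0.02),
                              generations=p.get("generations", 10), seed=s1)
    res = pedigree_permutation_test(cells, n_perm=p.get("n_perm", 10_000), seed=s2)
    if out:
        tio.write_cell_table(cells, out / "pedigree_cells.csv")
    return {"result": res.as_dict()}


def _scenario_colony_founder(p: dict, seed: int, out: Path | None) -> dict:
    s1, s2 = _sub_seeds(seed, 2)
    params = _noisy_params(**p.get("telegraph", {}))
    n_colonies = p.get("n_colonies", 12)
    slow = ColonyModel(n_colonies=n_colonies, cells_per_colony=p.get("cells_per_colony", 200),
                       p_switch_per_division=p.get("p_switch_slow", 0.02))
    fast = ColonyModel(n_colonies=n_colonies, cells_per_colony=slow.cells_per_colony,
                       p_switch_per_division=p.get("p_switch_fast", 0.5))
    cells_slow = simulate_colonies(params, slow, seed=s1)
    cells_fast = simulate_colonies(params, fast, seed=s2)

    def colony_means(cells):
        return cells.groupby("colony_id")["channel1_intensity"].mean()

    m_slow, m_fast = colony_means(cells_slow), colony_means(cells_fast)
    vr = variance_ratio_test(m_slow, m_fast)
    if out:
        tio.write_cell_table(cells_slow, out / "colonies_slow.csv")
        tio.write_cell_table(cells_fast, out / "colonies_fast.csv")
    return {"colony_means_slow": m_slow.round(4).to_dict(),
            "colony_means_fast": m_fast.round(4).to_dict(),
            "between_colony_var_slow": float(m_slow.var(ddof=1)),
            "between_colony_var_fast": float(m_fast.var(ddof=1)),
            "variance_ratio_test": vr}


def _scenario_flow_noise(p: dict, seed: int, out: Path | None) -> dict:
    params = _noisy_params(**p.get("telegraph", {}))
    events = simulate_flow_events(params, n_events=p.get("n_events", 100_000),
                                  frac_debris=p.get("frac_debris", 0.02),
                                  seed=_sub_seeds(seed, 1)[0])
    gated = gate_events(events)
    summary = flow_summary(gated, "fl1")
    if out:
        tio.write_flow_events(events, out / "flow_events.csv")
    return {"n_total": int(len(events)), "n_gated": int(len(gated)),
            "mean": summary["mean"], "robust_cv": summary["robust_cv"]}


def _scenario_lock_selection(p: dict, seed: int, out: Path | None) -> dict:
    n_cells = p.get("n_cells", 20_000)
    base = p.get("telegraph", {})
    seeds = _sub_seeds(seed, 3)
    cvs = {}
    for mode, s in zip(("toggling", "locked_on", "locked_off"), seeds):
        params = _noisy_params(lock_mode=mode, **base)
        pop = make_telegraph_population(params, n_cells, seed=s)
        cvs[mode] = coefficient_of_variation(pop["channel1_intensity"])
    report = {"cv": cvs,
              "cv_ratio_toggling_vs_locked_on": cvs["toggling"] / cvs["locked_on"],
              "cv_ratio_toggling_vs_locked_off": cvs["toggling"] / cvs["locked_off"]}
    return report


def _scenario_image_recovery(p: dict, seed: int, out: Path | None) -> dict:
    n_cells = p.get("n_cells", 25)
    s1, s2 = _sub_seeds(seed, 2)
    params = _noisy_params(**p.get("telegraph", {}))
    truth = make_telegraph_population(params, n_cells, seed=s1)
    geometry = ImageGeometry(shape=p.get("shape", (192, 192)))
    # read noise sized for roughly SNR 10 at the mean spot amplitude
    snr = p.get("snr", 10.0)
    read_sd = float(truth["true_signal"].mean() / snr / np.sqrt(geometry.n_z))
    noise = ImagingNoiseModel(background_level=p.get("background_level", 20.0),
                              read_noise_sd=read_sd)
    stack, annotations, truth_table = render_nuclei_stack(truth, geometry, noise,
                                                          seed=s2)
    measured = pd.DataFrame(quantify_stack(stack, annotations))
    merged = truth_table.merge(measured, on="cell_id")
    err = merged["signal"] - merged["expected_signal"]
    rel_rmse = float(np.sqrt(np.mean(err**2)) /
                     np.sqrt(np.mean(merged["expected_signal"]**2)))
    if out:
        tio.write_stack_tiff(stack, out / "stack.tif")
        tio.write_annotations(annotations, out / "annotations.json")
        merged.to_csv(out / "recovery.csv", index=False)
    return {"n_cells": int(n_cells), "relative_rms_error": rel_rmse,
            "snr": snr}


_RUNNERS = {
    "geneset_cv": _scenario_geneset_cv,
    "positional_scan": _scenario_positional_scan,
    "dual_reporter": _scenario_dual_reporter,
    "pedigree": _scenario_pedigree,
    "colony_founder": _scenario_colony_founder,
    "flow_noise": _scenario_flow_noise,
    "lock_selection": _scenario_lock_selection,
    "image_recovery": _scenario_image_recovery,
}


def run_scenario(config: ScenarioConfig) -> dict:
    """Generate inputs, run the analysis chain and return the report.

    When ``config.out_dir`` is set, intermediates, the report
    (``report.json``) and a provenance record are written there.
    """
    out = None
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
    report = {"scenario": config.scenario, "seed": int(config.seed),
              "schema_version": 1}
    report.update(_RUNNERS[config.scenario](dict(config.params), config.seed, out))
    if out is not None:
        (out / "report.json").write_text(json.dumps(tio._jsonable(report),
                                                    indent=1, sort_keys=True))
        tio.write_provenance(out, {"scenario": config.scenario,
                                   "params": config.params}, config.seed)
    return report
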