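"""End-to-end orchestration: simulate → normalise → call → associate → combine.

A single YAML-loadable config drives the full run for two cohorts. Per-stage
seeds are derived from the master seed as SeedSequence((master, stage_index)),
so any stage can be re-run in isolation and reproduce its outputs exactly.
The run manifest records seeds, package version and SHA-256 checksums of
every written file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .association import multivariate_signature, univariate_assoc
from .beacon import beacon_frame, build_beacon, match_by_position
from .cnv_hmm import HMMParams, call_panel, cnv_allele_frequency
from .io import (
    read_gwas,
    write_association_records,
    write_matrix,
    write_probe_map,
    write_segments,
    write_signature_records,
)
from .meta_pool import common_probes, meta_analyze, pooled_assoc
from .preprocess import compute_lrr_pcs, gc_correct, wave_correct
from .simulate import (
    CNVRegion,
    SimulationConfig,
    default_regions,
    simulate_cnv_truth,
    simulate_intensities,
    simulate_phenotypes,
    simulate_probe_map,
)

logger = logging.getLogger("cnvmetabo")

_STAGE_SEED = {"cohort_a": 11, "cohort_b": 23}

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "n_samples",
    "n_probes",
    "n_metabolites",
    "n_chromosomes",
    "n_pcs",
    "window_bp",
    "drop_alpha",
    "regions",
    "effect_table",
    "maf_threshold",
    "gwas_path",
    "lrr_noise_sd",
    "wave_amplitude",
    "gc_coefficient",
    "region_frequency",
    "region_n_probes",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a full two-cohort run."""

    seed: int = 0
    out_dir: str = "cnvmetabo_run"
    n_samples: int = 200
    n_probes: int = 500
    n_metabolites: int = 12
    n_chromosomes: int = 2
    n_pcs: int = 10
    window_bp: int = 500_000
    drop_alpha: float = 0.05
    regions: tuple | None = None  # None → auto default regions
    effect_table: tuple = ()
    maf_threshold: float = 0.01  # only polymorphic probes are associated
    gwas_path: str | None = None
    lrr_noise_sd: float = 0.20
    wave_amplitude: float = 0.05
    gc_coefficient: float = 0.5
    region_frequency: float = 0.2
    region_n_probes: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "regions" in raw and raw["regions"] is not None:
            raw["regions"] = tuple(tuple(r) for r in raw["regions"])
        if "effect_table" in raw:
            raw["effect_table"] = tuple(tuple(e) for e in raw["effect_table"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence((int(master), _STAGE_SEED[stage]))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages for two simulated cohorts; return the run manifest."""
    if config.gwas_path and not Path(config.gwas_path).exists():
        raise FileNotFoundError(f"gwas_path not found: {config.gwas_path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "version": __version__, "stages": [], "files": {}}

    def _write(name: str, writer, *args) -> None:
        path = out / name
        writer(*args, path)
        manifest["files"][name] = _sha256(path)

    def _write_assoc(records, probe_map, cohort, path):
        write_association_records(records, path, probe_map, cohort)

    def _write_sigs(records, cohort, path):
        write_signature_records(records, path, cohort)

    cohorts = {}
    for stage in ("cohort_a", "cohort_b"):
        seed = _stage_seed(config.seed, stage)
        sim = SimulationConfig(
            n_samples=config.n_samples,
            n_probes=config.n_probes,
            n_metabolites=config.n_metabolites,
            n_chromosomes=config.n_chromosomes,
            lrr_noise_sd=config.lrr_noise_sd,
            wave_amplitude=config.wave_amplitude,
            gc_coefficient=config.gc_coefficient,
            seed=seed,
        )
        try:
            probe_map = simulate_probe_map(sim)
            if config.regions is None:
                regions = default_regions(
                    probe_map,
                    n_probes_per_region=config.region_n_probes,
                    frequency=config.region_frequency,
                )
            else:
                regions = tuple(CNVRegion(*r) for r in config.regions)
            sim = replace(sim, regions=regions, effect_table=tuple(config.effect_table))
            truth = simulate_cnv_truth(probe_map, sim)
            panel = simulate_intensities(truth, probe_map, sim)
            phen = simulate_phenotypes(truth, sim)
        except Exception as exc:  # pragma: no cover - error surface
            raise RuntimeError(f"stage simulate[{stage}] failed: {exc}") from exc
        logger.info("simulated %s: %d samples × %d probes", stage, panel.n_samples, probe_map.n_probes)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            panel_gc, _ = gc_correct(panel, probe_map)
            panel_corr, _ = wave_correct(panel_gc, probe_map, window_bp=config.window_bp)
            pcs = compute_lrr_pcs(panel_corr, k=config.n_pcs)
        sex_ind = (panel.sex == "male").astype(float)[:, None]
        covariates = np.hstack([sex_ind, pcs])

        posterior, dosages, segments = call_panel(
            panel_corr.lrr, panel_corr.baf, probe_map, HMMParams(), panel.sample_id
        )
        cohorts[stage] = dict(
            probe_map=probe_map,
            truth=truth,
            panel=panel_corr,
            phen=phen,
            covariates=covariates,
            dosages=dosages,
            segments=segments,
        )
        tag = stage[-1]
        _write(f"probes_{tag}.bed", write_probe_map, probe_map)
        _write(
            f"lrr_corrected_{tag}.tsv",
            write_matrix,
            panel_corr.lrr,
            panel.sample_id,
            probe_map.probe_id,
        )
        _write(
            f"countall_{tag}.tsv",
            write_matrix,
            dosages.count_all,
            panel.sample_id,
            probe_map.probe_id,
        )
        _write(f"segments_{tag}.bed", write_segments, segments)
        manifest["stages"].append(f"simulate+normalize+call[{stage}]")

    # association per cohort at polymorphic probes
    results = {}
    for stage, tag in (("cohort_a", "a"), ("cohort_b", "b")):
        c = cohorts[stage]
        count_all = c["dosages"].count_all
        mafs = np.array([cnv_allele_frequency(count_all[:, j]) for j in range(count_all.shape[1])])
        poly = np.flatnonzero(mafs >= config.maf_threshold)
        uni, sigs = [], []
        for j in poly:
            pid = str(c["probe_map"].probe_id[j])
            uni.extend(univariate_assoc(count_all[:, j], c["phen"], c["covariates"], probe_id=pid))
            sigs.append(
                multivariate_signature(
                    count_all[:, j],
                    c["phen"],
                    c["covariates"],
                    drop_alpha=config.drop_alpha,
                    probe_id=pid,
                )
            )
        results[stage] = dict(uni=uni, sigs=sigs, poly=poly)
        _write(f"assoc_univariate_{tag}.tsv", _write_assoc, uni, c["probe_map"], stage)
        _write(f"signatures_{tag}.tsv", _write_sigs, sigs, stage)
        manifest["stages"].append(f"associate[{stage}]")

    # cross-cohort: meta-analysis + pooled regression over common probes
    pm_a, pm_b = cohorts["cohort_a"]["probe_map"], cohorts["cohort_b"]["probe_map"]
    pairs = common_probes(pm_a, pm_b)
    meta = meta_analyze(results["cohort_a"]["uni"], results["cohort_b"]["uni"])
    meta_rows = [
        {
            "probe_id": m.probe_id,
            "metabolite": m.metabolite_name,
            "beta_meta": m.beta_meta,
            "se_meta": m.se_meta,
            "p_meta": m.p_meta,
            "q": m.heterogeneity_q,
            "cohorts": "|".join(m.cohorts),
        }
        for m in meta
    ]
    import pandas as pd

    path = out / "meta.tsv"
    pd.DataFrame(meta_rows).to_csv(path, sep="\t", index=False)
    manifest["files"]["meta.tsv"] = _sha256(path)
    manifest["stages"].append(f"meta[{len(pairs)} common probes]")

    pooled = []
    idx_a = {str(p): i for i, p in enumerate(pm_a.probe_id)}
    idx_b = {str(p): i for i, p in enumerate(pm_b.probe_id)}
    for pid_a, pid_b in pairs:
        ja, jb = idx_a[pid_a], idx_b[pid_b]
        da = cohorts["cohort_a"]["dosages"].count_all[:, ja]
        db = cohorts["cohort_b"]["dosages"].count_all[:, jb]
        if cnv_allele_frequency(np.concatenate([da, db])) < config.maf_threshold:
            continue
        pooled.extend(
            pooled_assoc(
                [da, db],
                [cohorts["cohort_a"]["phen"], cohorts["cohort_b"]["phen"]],
                [cohorts["cohort_a"]["covariates"], cohorts["cohort_b"]["covariates"]],
                probe_id=pid_a,
            )
        )
    _write("pooled.tsv", _write_assoc, pooled, pm_a, "pooled")
    manifest["stages"].append("pooled")

    # beacon annotation on cohort A's probe map
    matches = None
    if config.gwas_path:
        if not Path(config.gwas_path).exists():
            raise FileNotFoundError(f"gwas_path not found: {config.gwas_path}")
        matches = match_by_position(pm_a, read_gwas(config.gwas_path), window_bp=0)
    rows = build_beacon(
        pm_a,
        signature_records=results["cohort_a"]["sigs"],
        lrr_records=None,
        segments_a=cohorts["cohort_a"]["segments"],
        segments_b=cohorts["cohort_b"]["segments"],
        matches=matches,
    )
    path = out / "beacon.tsv"
    beacon_frame(rows).to_csv(path, sep="\t", index=False)
    manifest["files"]["beacon.tsv"] = _sha256(path)
    manifest["stages"].append("beacon")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
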