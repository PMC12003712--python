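"""Synthetic SNP-array cohorts with embedded CNVs and metabolite phenotypes.

Generates the four objects every downstream stage consumes:

* a probe map (chromosome, position, GC fraction) with spatially correlated GC,
* per-sample integer copy-number truth (states 0–4) from declared CNV regions,
* LRR/BAF intensity matrices carrying state-dependent signal, a GC-linear
  artifact, a low-frequency genomic wave and Gaussian noise,
* a metabolite matrix with block correlation and planted linear dosage effects.

All randomness flows from ``SimulationConfig.seed`` through named
``numpy.random.SeedSequence`` children, so e.g. turning the wave amplitude up
leaves the noise draws untouched (paired simulations stay paired).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMap",
    "CNVRegion",
    "CNVTruth",
    "IntensityPanel",
    "PhenotypePanel",
    "SimulationConfig",
    "STATE_LRR_MEANS",
    "simulate_probe_map",
    "simulate_cnv_truth",
    "simulate_intensities",
    "simulate_phenotypes",
    "simulate_cohort",
    "default_regions",
]

# Conventional array LRR levels for copy numbers 0..4 (homozygous deletion is a
# deep, noisy dropout; duplications compress toward the neutral level).
STATE_LRR_MEANS = np.array([-3.5, -0.66, 0.0, 0.40, 0.68])

_STREAMS = {"map": 0, "truth": 1, "noise": 2, "wave": 3, "baf": 4, "pheno": 5, "sex": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named child generator so streams are independent and order-insensitive."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[stream])))


@dataclass(frozen=True)
class ProbeMap:
    """Ordered genomic probes: the coordinate backbone of the pipeline.

    Positions are 1-based basepairs, strictly increasing within a chromosome.
    """

    probe_id: np.ndarray  # str array
    chrom: np.ndarray  # str array
    pos: np.ndarray  # int array, 1-based
    gc_fraction: np.ndarray  # float in [0, 1]

    def __post_init__(self) -> None:
        n = len(self.probe_id)
        if not (len(self.chrom) == len(self.pos) == len(self.gc_fraction) == n):
            raise ValueError("probe map fields must have equal length")
        if len(np.unique(self.probe_id)) != n:
            raise ValueError("probe_ids must be unique")
        if np.any((self.gc_fraction < 0) | (self.gc_fraction > 1)):
            raise ValueError("gc_fraction must lie in [0, 1]")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions must strictly increase on {c}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_id)

    def chrom_slices(self) -> list[tuple[str, np.ndarray]]:
        """(chrom, boolean mask) in first-appearance order."""
        seen: list[str] = []
        for c in self.chrom:
            if c not in seen:
                seen.append(c)
        return [(c, self.chrom == c) for c in seen]

    def to_bed(self) -> pd.DataFrame:
        """BED-like frame: 0-based half-open coordinates for on-disk use."""
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.pos - 1,
                "end": self.pos,
                "probe_id": self.probe_id,
                "gc_fraction": self.gc_fraction,
            }
        )

    @classmethod
    def from_bed(cls, frame: pd.DataFrame) -> "ProbeMap":
        return cls(
            probe_id=frame["probe_id"].to_numpy(dtype=str),
            chrom=frame["chrom"].to_numpy(dtype=str),
            pos=frame["end"].to_numpy(dtype=np.int64),
            gc_fraction=frame["gc_fraction"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class CNVRegion:
    """A declared polymorphic CNV region carried at a population frequency."""

    chrom: str
    start: int  # bp, 1-based inclusive
    end: int  # bp, 1-based inclusive
    state: int  # copy number in {0, 1, 3, 4}
    frequency: float  # carrier frequency in (0, 1]

    def __post_init__(self) -> None:
        if self.state not in (0, 1, 3, 4):
            raise ValueError("region state must be a non-neutral copy number")
        if not 0 < self.frequency <= 1:
            raise ValueError("region frequency must lie in (0, 1]")
        if self.end < self.start:
            raise ValueError("region end before start")


@dataclass(frozen=True)
class CNVTruth:
    """Ground-truth integer copy state per sample × probe, plus the regions."""

    copy_state: np.ndarray  # int matrix (samples × probes), values 0..4
    regions: tuple[CNVRegion, ...]

    @property
    def n_samples(self) -> int:
        return self.copy_state.shape[0]


@dataclass(frozen=True)
class IntensityPanel:
    """Per-cohort LRR/BAF matrices (samples × probes) and sample metadata."""

    lrr: np.ndarray
    baf: np.ndarray
    sex: np.ndarray  # str array of {"male", "female"}
    cohort_id: str = "cohort"
    sample_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lrr.shape != self.baf.shape:
            raise ValueError("lrr and baf shapes differ")
        if np.any((self.baf < 0) | (self.baf > 1)):
            raise ValueError("baf must lie in [0, 1]")
        if not np.all(np.isfinite(self.lrr)):
            raise ValueError("lrr must be finite")
        if self.sample_id is None:
            ids = np.array([f"{self.cohort_id}_s{i:04d}" for i in range(self.lrr.shape[0])])
            object.__setattr__(self, "sample_id", ids)

    @property
    def n_samples(self) -> int:
        return self.lrr.shape[0]


@dataclass(frozen=True)
class PhenotypePanel:
    """Metabolite matrix (samples × M) plus association covariates."""

    metabolites: np.ndarray
    metabolite_names: list[str]
    covariates: np.ndarray  # includes the sex indicator as first column
    covariate_names: list[str]

    def __post_init__(self) -> None:
        if np.any(np.ptp(self.metabolites, axis=0) == 0):
            raise ValueError("constant metabolite column")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the package's stated study conditions."""

    n_samples: int = 500
    n_probes: int = 2000
    n_metabolites: int = 228
    n_chromosomes: int = 2
    mean_spacing_bp: int = 3000
    wave_amplitude: float = 0.05
    wave_period_bp: float = 1.0e6
    gc_coefficient: float = 0.5
    lrr_noise_sd: float = 0.20
    baf_noise_sd: float = 0.03
    state_lrr_means: tuple[float, ...] = tuple(STATE_LRR_MEANS)
    regions: tuple[CNVRegion, ...] = ()
    effect_table: tuple[tuple[int, int, float], ...] = ()  # (probe, metabolite, beta)
    block_size: int = 12
    block_correlation: float = 0.6
    pheno_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block correlation must lie in [0, 1)")


def simulate_probe_map(config: SimulationConfig) -> ProbeMap:
    """Probe coordinates with exponential spacing and smoothly varying GC.

    GC fraction is a moving-average (window 25) of white noise around 0.41, so
    neighbouring probes share GC context — what the GC-correction stage needs
    to have something spatially coherent to remove.
    """
    if config.n_probes < 2:
        raise ValueError("n_probes must be at least 2")
    rng = _rng(config.seed, "map")
    per_chrom = np.full(config.n_chromosomes, config.n_probes // config.n_chromosomes)
    per_chrom[: config.n_probes % config.n_chromosomes] += 1
    chroms, positions = [], []
    for ci, k in enumerate(per_chrom):
        gaps = rng.exponential(config.mean_spacing_bp, size=k).astype(np.int64) + 1
        positions.append(np.cumsum(gaps) + 10_000)
        chroms.append(np.full(k, f"chr{ci + 1}"))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    raw = rng.normal(0.0, 0.35, size=config.n_probes + 24)
    smooth = np.convolve(raw, np.ones(25) / 25.0, mode="valid")
    gc = np.clip(0.41 + smooth, 0.2, 0.8)
    pid = np.array([f"p{c}_{p}" for c, p in zip(chrom, pos)])
    return ProbeMap(probe_id=pid, chrom=chrom, pos=pos, gc_fraction=gc)


def default_regions(
    probe_map: ProbeMap,
    n_probes_per_region: int = 20,
    frequency: float = 0.2,
    states: tuple[int, ...] = (1, 3, 0, 4),
) -> tuple[CNVRegion, ...]:
    """Evenly spaced CNV regions cycling through the non-neutral states."""
    regions = []
    slices = probe_map.chrom_slices()
    k = 0
    for chrom, mask in slices:
        pos = probe_map.pos[mask]
        n = len(pos)
        n_here = max(1, len(states) // len(slices))
        for j in range(n_here):
            lo = int((j + 0.5) * n / (n_here + 0.5))
            hi = lo + n_probes_per_region - 1
            if hi >= n:
                continue
            regions.append(
                CNVRegion(chrom, int(pos[lo]), int(pos[hi]), states[k % len(states)], frequency)
            )
            k += 1
    return tuple(regions)


def _region_mask(probe_map: ProbeMap, region: CNVRegion) -> np.ndarray:
    return (
        (probe_map.chrom == region.chrom)
        & (probe_map.pos >= region.start)
        & (probe_map.pos <= region.end)
    )


def simulate_cnv_truth(probe_map: ProbeMap, config: SimulationConfig) -> CNVTruth:
    """Assign carriers per region frequency; non-region probes stay copy-neutral."""
    rng = _rng(config.seed, "truth")
    state = np.full((config.n_samples, probe_map.n_probes), 2, dtype=np.int8)
    claimed = np.zeros(probe_map.n_probes, dtype=bool)
    for region in config.regions:
        mask = _region_mask(probe_map, region)
        if not mask.any():
            warnings.warn(f"region {region} covers no probes", stacklevel=2)
            continue
        if (claimed & mask).any():
            raise ValueError(f"region {region} overlaps a previously declared region")
        claimed |= mask
        carriers = rng.random(config.n_samples) < region.frequency
        state[np.ix_(carriers, mask)] = region.state
    return CNVTruth(copy_state=state, regions=tuple(config.regions))


# BAF cluster means per copy state: allelic ratios attainable at each total copy
# number (state 0 has no allelic signal — modelled as uniform noise).
_BAF_MEANS = {
    1: np.array([0.0, 1.0]),
    2: np.array([0.0, 0.5, 1.0]),
    3: np.array([0.0, 1 / 3, 2 / 3, 1.0]),
    4: np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
}


def _baf_weights(state: int, p: float = 0.5) -> np.ndarray:
    """Binomial allele counts at allele frequency p give the cluster weights."""
    from scipy.stats import binom

    k = np.arange(state + 1)
    return binom.pmf(k, state, p)


def simulate_intensities(
    truth: CNVTruth, probe_map: ProbeMap, config: SimulationConfig
) -> IntensityPanel:
    """State-mean LRR + GC term + genomic wave + noise; BAF from state clusters.

    The wave is a per-chromosome sinusoid with sample-specific magnitude,
    mimicking the long-range intensity oscillation of array data; the GC term
    is linear in (gc − mean gc), shared across samples.
    """
    if truth.copy_state.shape != (config.n_samples, probe_map.n_probes):
        raise ValueError("truth dimensions do not match probe map / config")
    noise_rng = _rng(config.seed, "noise")
    wave_rng = _rng(config.seed, "wave")
    baf_rng = _rng(config.seed, "baf")
    sex_rng = _rng(config.seed, "sex")

    means = np.asarray(config.state_lrr_means)
    lrr = means[truth.copy_state].astype(float)
    gc = probe_map.gc_fraction
    lrr += config.gc_coefficient * (gc - gc.mean())

    wave = np.zeros(probe_map.n_probes)
    for _, mask in probe_map.chrom_slices():
        phase = wave_rng.uniform(0, 2 * np.pi)
        wave[mask] = np.sin(2 * np.pi * probe_map.pos[mask] / config.wave_period_bp + phase)
    # per-sample wave strength: positive, median 1, varying ~±30%
    sample_scale = wave_rng.lognormal(0.0, 0.3, size=config.n_samples)
    lrr += config.wave_amplitude * sample_scale[:, None] * wave[None, :]
    lrr += noise_rng.normal(0.0, config.lrr_noise_sd, size=lrr.shape)

    baf = np.empty_like(lrr)
    flat_state = truth.copy_state.ravel()
    flat_baf = baf_rng.uniform(0, 1, size=flat_state.shape)  # state-0 default
    for s in (1, 2, 3, 4):
        idx = np.flatnonzero(flat_state == s)
        if idx.size == 0:
            continue
        comp = baf_rng.choice(len(_BAF_MEANS[s]), size=idx.size, p=_baf_weights(s))
        vals = _BAF_MEANS[s][comp] + baf_rng.normal(0, config.baf_noise_sd, size=idx.size)
        flat_baf[idx] = vals
    baf = np.clip(flat_baf.reshape(lrr.shape), 0.0, 1.0)

    sex = np.where(sex_rng.random(config.n_samples) < 0.5, "female", "male")
    return IntensityPanel(lrr=lrr, baf=baf, sex=sex, cohort_id=f"cohort_seed{config.seed}")


def simulate_phenotypes(truth: CNVTruth, config: SimulationConfig) -> PhenotypePanel:
    """Block-correlated Gaussian metabolites plus planted linear dosage effects.

    Each block shares a latent factor: x = sqrt(r)·z_block + sqrt(1−r)·eps, so
    the within-block correlation is exactly ``block_correlation``. Effects add
    beta·(copy_state − 2) at the declared (probe, metabolite) pairs. Sex is
    simulated independently and enters the covariates, not the metabolites.
    """
    rng = _rng(config.seed, "pheno")
    sex_rng = _rng(config.seed, "sex")
    n, m = config.n_samples, config.n_metabolites
    r = config.block_correlation
    n_blocks = int(np.ceil(m / config.block_size))
    z = rng.normal(size=(n, n_blocks))
    eps = rng.normal(size=(n, m))
    block_of = np.arange(m) // config.block_size
    met = config.pheno_noise_sd * (np.sqrt(r) * z[:, block_of] + np.sqrt(1 - r) * eps)

    varying = np.ptp(truth.copy_state, axis=0) > 0
    for probe_idx, met_idx, beta in config.effect_table:
        if not (0 <= probe_idx < truth.copy_state.shape[1]) or not (0 <= met_idx < m):
            raise IndexError("effect_table index out of range")
        if not varying[probe_idx]:
            warnings.warn(
                f"effect planted at probe {probe_idx} with no CNV variation is unidentifiable",
                stacklevel=2,
            )
        met[:, met_idx] += beta * (truth.copy_state[:, probe_idx].astype(float) - 2.0)

    sex = np.where(sex_rng.random(n) < 0.5, "female", "male")
    sex_ind = (sex == "male").astype(float)
    names = [f"met_{i:03d}" for i in range(m)]
    return PhenotypePanel(
        metabolites=met,
        metabolite_names=names,
        covariates=sex_ind[:, None],
        covariate_names=["sex_male"],
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ProbeMap, CNVTruth, IntensityPanel, PhenotypePanel]:
    """One cohort end to end; call twice with distinct seeds for two cohorts."""
    probe_map = simulate_probe_map(config)
    truth = simulate_cnv_truth(probe_map, config)
    panel = simulate_intensities(truth, probe_map, config)
    phen = simulate_phenotypes(truth, config)
    return probe_map, truth, panel, phen


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
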