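"""Copy-number genotyping HMM over LRR/BAF and expected-dosage computation.

A five-state hidden Markov model over copy numbers {0, 1, 2, 3, 4} is run
along each sample's ordered probes, per chromosome. Emissions combine a
Gaussian on LRR with a truncated-normal mixture on BAF whose components sit at
the allelic ratios attainable at each copy number (state 0 carries no allelic
signal and uses a uniform BAF term). Transitions are distance-aware: the
probability of leaving the current state grows with the basepair gap to the
next probe and the off-diagonal mass follows the stationary state prior.

Forward–backward smoothing yields per-probe posterior state probabilities,
from which the expected copy-number dosage ("countAll") is the posterior
weighted sum of states — e.g. posterior 0.7 on one copy and 0.3 on two copies
gives 1*0.7 + 2*0.3 = 1.3. countAll therefore lives in [0, 4] and is the
continuous genotype used by all association models. Deletion-only and
duplication-only dosages restrict the expectation to states {0,1,2} and
{2,3,4} (renormalised). Viterbi decoding provides discrete CNV segments
(breakpoints) for reporting and annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .simulate import ProbeMap

__all__ = [
    "HMMParams",
    "StatePosterior",
    "DosageSet",
    "CNVSegment",
    "transition_matrix",
    "emission_loglik",
    "emission_loglik_matrix",
    "forward_backward",
    "viterbi_segments",
    "call_panel",
    "expected_genotypes",
    "cnv_allele_frequency",
]

STATES = np.arange(5)

_BAF_COMPONENTS: dict[int, list[tuple[float, float, float]]] = {
    # state -> [(mean, sd, weight)]; binomial weights at allele frequency 0.5
    0: [],  # uniform on [0, 1]
    1: [(0.0, 0.03, 0.5), (1.0, 0.03, 0.5)],
    2: [(0.0, 0.03, 0.25), (0.5, 0.04, 0.5), (1.0, 0.03, 0.25)],
    3: [(0.0, 0.03, 0.125), (1 / 3, 0.04, 0.375), (2 / 3, 0.04, 0.375), (1.0, 0.03, 0.125)],
    4: [
        (0.0, 0.03, 0.0625),
        (0.25, 0.04, 0.25),
        (0.5, 0.04, 0.375),
        (0.75, 0.04, 0.25),
        (1.0, 0.03, 0.0625),
    ],
}


@dataclass(frozen=True)
class HMMParams:
    """Emission and transition parameters of the five-state copy-number HMM."""

    lrr_mean: tuple[float, ...] = (-3.5, -0.66, 0.0, 0.40, 0.68)
    lrr_sd: tuple[float, ...] = (1.0, 0.30, 0.20, 0.25, 0.28)
    baf_components: dict[int, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {s: list(v) for s, v in _BAF_COMPONENTS.items()}
    )
    stationary_prior: tuple[float, ...] = (0.001, 0.010, 0.978, 0.008, 0.003)
    switch_rate_per_bp: float = 2.0e-6
    min_switch_prob: float = 1.0e-4
    max_switch_prob: float = 0.2

    def __post_init__(self) -> None:
        if len(self.lrr_mean) != 5 or len(self.lrr_sd) != 5:
            raise ValueError("five states required")
        if np.any(np.diff(self.lrr_mean) <= 0):
            raise ValueError("lrr_mean must strictly increase with copy number")
        if abs(sum(self.stationary_prior) - 1.0) > 1e-9:
            raise ValueError("stationary prior must sum to 1")
        for s, comps in self.baf_components.items():
            if comps and abs(sum(w for _, _, w in comps) - 1.0) > 1e-9:
                raise ValueError(f"BAF weights for state {s} must sum to 1")
        if not (0 <= self.min_switch_prob <= self.max_switch_prob < 1):
            raise ValueError("switch probabilities must satisfy 0 <= min <= max < 1")


@dataclass(frozen=True)
class StatePosterior:
    """Posterior state probabilities, (samples × probes × 5), rows normalised."""

    gamma: np.ndarray
    log_likelihood: np.ndarray | float | None = None

    def __post_init__(self) -> None:
        g = self.gamma
        if g.shape[-1] != 5:
            raise ValueError("last axis must have 5 states")
        if np.any(g < -1e-12) or np.any(np.abs(g.sum(axis=-1) - 1.0) > 1e-9):
            raise ValueError("posterior rows must be probabilities summing to 1")


@dataclass(frozen=True)
class DosageSet:
    """Expected-genotype vectors: all-state (countAll), deletion- and duplication-only."""

    count_all: np.ndarray
    del_only: np.ndarray
    dup_only: np.ndarray


@dataclass(frozen=True)
class CNVSegment:
    """A maximal run of one non-neutral Viterbi state in one sample."""

    sample_id: str
    chrom: str
    start_pos: int  # 1-based inclusive, first probe
    end_pos: int  # 1-based inclusive, last probe
    state: int
    n_probes: int
    mean_posterior: float


def transition_matrix(distance_bp: int, params: HMMParams) -> np.ndarray:
    """Distance-aware 5×5 stochastic matrix.

    P(switch) = clip(1 − exp(−rate·d), min, max); leaving mass is shared among
    the other states in proportion to the stationary prior, so at large
    distances every row forgets toward the prior.
    """
    if distance_bp < 0:
        raise ValueError("distance must be non-negative")
    p_switch = float(
        np.clip(
            -np.expm1(-params.switch_rate_per_bp * distance_bp),
            params.min_switch_prob,
            params.max_switch_prob,
        )
    )
    pi = np.asarray(params.stationary_prior)
    A = np.empty((5, 5))
    for i in range(5):
        others = pi.copy()
        others[i] = 0.0
        others /= others.sum()
        A[i] = p_switch * others
        A[i, i] = 1.0 - p_switch
    return A


def _baf_log_density(baf: np.ndarray, state: int, params: HMMParams) -> np.ndarray:
    """Truncated-normal mixture density on [0, 1]; uniform for empty components."""
    comps = params.baf_components[state]
    if not comps:
        return np.zeros_like(baf)  # log Uniform(0,1) = 0
    dens = np.zeros_like(baf, dtype=float)
    for mean, sd, weight in comps:
        z = norm.cdf(1.0, mean, sd) - norm.cdf(0.0, mean, sd)
        dens += weight * norm.pdf(baf, mean, sd) / z
    return np.log(np.maximum(dens, 1e-300))


def emission_loglik(
    lrr_value: float, baf_value: float | None, state: int, params: HMMParams
) -> float:
    """Joint log density of one (LRR, BAF) observation under one state."""
    if state not in range(5):
        raise ValueError("state must be in 0..4")
    if not np.isfinite(lrr_value):
        raise ValueError("non-finite LRR")
    ll = norm.logpdf(lrr_value, params.lrr_mean[state], params.lrr_sd[state])
    if baf_value is not None and np.isfinite(baf_value):
        ll += float(_baf_log_density(np.asarray([baf_value]), state, params)[0])
    elif baf_value is not None:
        raise ValueError("non-finite BAF")
    return float(ll)


def emission_loglik_matrix(
    lrr: np.ndarray, baf: np.ndarray | None, params: HMMParams
) -> np.ndarray:
    """Log emission densities, shape (..., 5), NaN BAF treated as missing."""
    lrr = np.asarray(lrr, dtype=float)
    if not np.all(np.isfinite(lrr)):
        raise ValueError("non-finite LRR")
    out = np.empty(lrr.shape + (5,))
    for s in range(5):
        out[..., s] = norm.logpdf(lrr, params.lrr_mean[s], params.lrr_sd[s])
        if baf is not None:
            b = np.asarray(baf, dtype=float)
            ok = np.isfinite(b)
            contrib = np.zeros_like(b)
            contrib[ok] = _baf_log_density(b[ok], s, params)
            out[..., s] += contrib
    return out


def _chrom_distances(pos: np.ndarray) -> np.ndarray:
    return np.diff(pos.astype(np.int64))


def forward_backward(
    sample_lrr: np.ndarray,
    sample_baf: np.ndarray | None,
    probe_map: ProbeMap,
    params: HMMParams,
) -> StatePosterior:
    """Exact smoothing posteriors for one sample, chromosome by chromosome.

    Scaled forward–backward recursions (normalised alphas), so sequences of
    10^5 probes do not underflow; returns the total log-likelihood as well.
    """
    n = probe_map.n_probes
    if sample_lrr.shape != (n,):
        raise ValueError("LRR not aligned to probe map")
    gamma = np.empty((n, 5))
    total_ll = 0.0
    for _, mask in probe_map.chrom_slices():
        idx = np.flatnonzero(mask)
        lrr_c = sample_lrr[idx]
        baf_c = sample_baf[idx] if sample_baf is not None else None
        if not np.any(np.isfinite(lrr_c)):
            warnings.warn("all-missing chromosome; uniform posterior", stacklevel=2)
            gamma[idx] = 0.2
            total_ll += 0.0
            continue
        logB = emission_loglik_matrix(lrr_c, baf_c, params)
        g, ll = _forward_backward_chrom(logB, probe_map.pos[idx], params)
        gamma[idx] = g
        total_ll += ll
    return StatePosterior(gamma=gamma, log_likelihood=total_ll)


def _transition_stack(pos: np.ndarray, params: HMMParams) -> np.ndarray:
    d = _chrom_distances(pos)
    return np.stack([transition_matrix(int(di), params) for di in d]) if len(d) else np.empty((0, 5, 5))


def _forward_backward_chrom(
    logB: np.ndarray, pos: np.ndarray, params: HMMParams
) -> tuple[np.ndarray, float]:
    T = logB.shape[0]
    pi = np.asarray(params.stationary_prior)
    A = _transition_stack(pos, params)
    # emission scaling keeps everything in linear space without underflow
    bmax = logB.max(axis=1, keepdims=True)
    B = np.exp(logB - bmax)
    alpha = np.empty((T, 5))
    c = np.empty(T)
    a = pi * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A[t - 1]) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, 5))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A[t] * (B[t + 1] * beta[t + 1])[None, :]).sum(axis=1) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    ll = float(np.log(c).sum() + bmax.sum())
    return gamma, ll


def _viterbi_chrom(logB: np.ndarray, pos: np.ndarray, params: HMMParams) -> tuple[np.ndarray, float]:
    T = logB.shape[0]
    logA = np.log(np.maximum(_transition_stack(pos, params), 1e-300))
    delta = np.log(np.asarray(params.stationary_prior)) + logB[0]
    back = np.zeros((T, 5), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, None] + logA[t - 1]
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logB[t]
    path = np.empty(T, dtype=np.int8)
    path[-1] = int(delta.argmax())
    best = float(delta.max())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path, best


def viterbi_segments(
    sample_lrr: np.ndarray,
    sample_baf: np.ndarray | None,
    probe_map: ProbeMap,
    params: HMMParams,
    sample_id: str = "sample",
    posterior: StatePosterior | None = None,
) -> list[CNVSegment]:
    """MAP state path; maximal non-neutral runs reported as CNV segments."""
    if posterior is None:
        posterior = forward_backward(sample_lrr, sample_baf, probe_map, params)
    segments: list[CNVSegment] = []
    for chrom, mask in probe_map.chrom_slices():
        idx = np.flatnonzero(mask)
        baf_c = sample_baf[idx] if sample_baf is not None else None
        logB = emission_loglik_matrix(sample_lrr[idx], baf_c, params)
        path, _ = _viterbi_chrom(logB, probe_map.pos[idx], params)
        pos = probe_map.pos[idx]
        start = 0
        for j in range(1, len(path) + 1):
            if j == len(path) or path[j] != path[start]:
                s = int(path[start])
                if s != 2:
                    g = posterior.gamma[idx[start] : idx[j - 1] + 1, s]
                    segments.append(
                        CNVSegment(
                            sample_id=sample_id,
                            chrom=chrom,
                            start_pos=int(pos[start]),
                            end_pos=int(pos[j - 1]),
                            state=s,
                            n_probes=j - start,
                            mean_posterior=float(g.mean()),
                        )
                    )
                start = j
    return segments


def call_panel(
    lrr: np.ndarray,
    baf: np.ndarray | None,
    probe_map: ProbeMap,
    params: HMMParams | None = None,
    sample_ids: np.ndarray | None = None,
) -> tuple[StatePosterior, DosageSet, list[CNVSegment]]:
    """Run the HMM over every sample of a panel; posterior, dosages, segments."""
    params = params or HMMParams()
    n_samples = lrr.shape[0]
    gamma = np.empty((n_samples, probe_map.n_probes, 5))
    lls = np.empty(n_samples)
    segments: list[CNVSegment] = []
    for i in range(n_samples):
        sid = str(sample_ids[i]) if sample_ids is not None else f"s{i:04d}"
        post = forward_backward(lrr[i], None if baf is None else baf[i], probe_map, params)
        gamma[i] = post.gamma
        lls[i] = post.log_likelihood
        segments.extend(
            viterbi_segments(
                lrr[i], None if baf is None else baf[i], probe_map, params, sid, post
            )
        )
    posterior = StatePosterior(gamma=gamma, log_likelihood=lls)
    return posterior, expected_genotypes(posterior), segments


def expected_genotypes(posterior: StatePosterior, tol: float = 1e-6) -> DosageSet:
    """Posterior-expected copy numbers.

    countAll = Σ_s s·γ_s over all five states (so 0.7 on state 1 and 0.3 on
    state 2 gives 1.3); deletion-only and duplication-only restrict to states
    {0,1,2} and {2,3,4} with the restricted mass renormalised.
    """
    g = posterior.gamma
    sums = g.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > tol):
        raise ValueError("posterior not normalised")
    count_all = g @ STATES.astype(float)
    del_mass = g[..., :3].sum(axis=-1)
    dup_mass = g[..., 2:].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        del_only = np.where(
            del_mass > 0, (g[..., :3] @ np.array([0.0, 1.0, 2.0])) / del_mass, 2.0
        )
        dup_only = np.where(
            dup_mass > 0, (g[..., 2:] @ np.array([2.0, 3.0, 4.0])) / dup_mass, 2.0
        )
    return DosageSet(count_all=count_all, del_only=del_only, dup_only=dup_only)


def cnv_allele_frequency(count_all: np.ndarray) -> float:
    """Folded dosage-based allele frequency in [0, 0.5].

    f = Σ_i |countAll_i − 2| / (2n), folded to min(f, 1 − f): the mean
    absolute copy-number deviation per haploid genome.
    """
    c = np.asarray(count_all, dtype=float)
    if c.size == 0:
        raise ValueError("empty dosage vector")
    f = float(np.abs(c - 2.0).sum() / (2.0 * c.size))
    return min(f, 1.0 - f)
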