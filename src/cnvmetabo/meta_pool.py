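"""Cross-cohort combination over common probes: meta-analysis and pooling.

Two cohorts genotyped on different platforms share only the probes whose
(chromosome, position) coincide exactly; those common probes support either a
fixed-effect inverse-variance meta-analysis of per-cohort summary statistics,
or a pooled regression on the stacked samples with a cohort indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

from .association import AssociationRecord, univariate_assoc
from .simulate import PhenotypePanel, ProbeMap

__all__ = ["MetaRecord", "common_probes", "meta_analyze", "pooled_assoc"]


@dataclass(frozen=True)
class MetaRecord:
    probe_id: str
    metabolite_name: str
    beta_meta: float
    se_meta: float
    p_meta: float
    cohorts: tuple[str, ...]
    heterogeneity_q: float
    q_pvalue: float


def common_probes(map_a: ProbeMap, map_b: ProbeMap) -> list[tuple[str, str]]:
    """Probes matched on exact (chrom, pos); pairs of (probe_id_a, probe_id_b).

    Order follows genomic position of map_a. Duplicate positions within a map
    are a data error and are reported by position.
    """
    for name, pm in (("a", map_a), ("b", map_b)):
        keys = list(zip(pm.chrom, pm.pos))
        if len(set(keys)) != len(keys):
            seen: set = set()
            dups = [k for k in keys if k in seen or seen.add(k)]
            raise ValueError(f"duplicate positions in map {name}: {dups[:5]}")
    index_b = {(c, p): pid for c, p, pid in zip(map_b.chrom, map_b.pos, map_b.probe_id)}
    out = []
    for c, p, pid in zip(map_a.chrom, map_a.pos, map_a.probe_id):
        hit = index_b.get((c, p))
        if hit is not None:
            out.append((pid, hit))
    return out


def meta_analyze(
    records_a: list[AssociationRecord],
    records_b: list[AssociationRecord],
    cohort_names: tuple[str, str] = ("a", "b"),
) -> list[MetaRecord]:
    """Fixed-effect inverse-variance meta-analysis over matched records.

    Records are matched on (probe_id, metabolite_name). Weights w = 1/se²,
    β_meta = Σwβ/Σw, se_meta = 1/√Σw, two-sided normal p; Cochran's Q is
    reported for heterogeneity. A record with se = 0 is skipped with warning;
    a pair present in only one cohort passes through unchanged.
    """
    def keyed(recs):
        return {(r.probe_id, r.metabolite_name): r for r in recs}

    a, b = keyed(records_a), keyed(records_b)
    out: list[MetaRecord] = []
    for key in list(a) + [k for k in b if k not in a]:
        pair = [(cohort_names[0], a.get(key)), (cohort_names[1], b.get(key))]
        usable = []
        for name, r in pair:
            if r is None:
                continue
            if r.se == 0 or not np.isfinite(r.se):
                warnings.warn(f"skipping {key} in cohort {name}: se=0", stacklevel=2)
                continue
            usable.append((name, r))
        if not usable:
            continue
        w = np.array([1.0 / r.se**2 for _, r in usable])
        betas = np.array([r.beta for _, r in usable])
        beta_meta = float((w * betas).sum() / w.sum())
        se_meta = float(1.0 / np.sqrt(w.sum()))
        z = beta_meta / se_meta
        p_meta = float(2.0 * norm.sf(abs(z)))
        q = float((w * (betas - beta_meta) ** 2).sum())
        df = len(usable) - 1
        q_p = float(chi2.sf(q, df)) if df > 0 else 1.0
        out.append(
            MetaRecord(
                probe_id=key[0],
                metabolite_name=key[1],
                beta_meta=beta_meta,
                se_meta=se_meta,
                p_meta=max(p_meta, 5e-324),
                cohorts=tuple(name for name, _ in usable),
                heterogeneity_q=q,
                q_pvalue=q_p,
            )
        )
    return out


def pooled_assoc(
    dosage_by_cohort: list[np.ndarray],
    phenotypes_by_cohort: list[PhenotypePanel],
    covariates_by_cohort: list[np.ndarray | None],
    probe_id: str = "probe",
) -> list[AssociationRecord]:
    """Single regression on stacked samples with cohort fixed effects.

    Phenotype columns are harmonised by name; covariates are computed per
    cohort (PCs are cohort-specific) and block-stacked so each cohort's
    covariate effects are estimated within cohort.
    """
    if not dosage_by_cohort:
        raise ValueError("no cohorts supplied")
    names0 = phenotypes_by_cohort[0].metabolite_names
    for ph in phenotypes_by_cohort[1:]:
        if ph.metabolite_names != names0:
            missing = set(names0).symmetric_difference(ph.metabolite_names)
            raise ValueError(f"phenotype columns differ between cohorts: {sorted(missing)[:5]}")
    if len(dosage_by_cohort) == 1:
        return univariate_assoc(
            dosage_by_cohort[0],
            phenotypes_by_cohort[0],
            covariates_by_cohort[0],
            probe_id=probe_id,
        )
    dosage = np.concatenate(dosage_by_cohort)
    mets = np.vstack([ph.metabolites for ph in phenotypes_by_cohort])
    sizes = [len(d) for d in dosage_by_cohort]
    # block-diagonal stack of per-cohort covariates + cohort indicators
    blocks = []
    offset = 0
    total = sum(sizes)
    for cov, sz in zip(covariates_by_cohort, sizes):
        if cov is not None and cov.size:
            block = np.zeros((total, cov.shape[1]))
            block[offset : offset + sz] = cov
            blocks.append(block)
        offset += sz
    cohort_ind = np.zeros((total, len(sizes) - 1))
    offset = sizes[0]
    for k, sz in enumerate(sizes[1:]):
        cohort_ind[offset : offset + sz, k] = 1.0
        offset += sz
    cov_stacked = np.hstack(blocks + [cohort_ind]) if blocks else cohort_ind
    pooled_panel = PhenotypePanel(
        metabolites=mets,
        metabolite_names=list(names0),
        covariates=cov_stacked,
        covariate_names=[f"cov{k}" for k in range(cov_stacked.shape[1])],
    )
    return univariate_assoc(dosage, pooled_panel, cov_stacked, probe_id=probe_id)
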