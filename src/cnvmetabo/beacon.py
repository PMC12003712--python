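"""Beacon cross-reference table and variant-agnostic GWAS position matching.

External GWAS summary rows are joined to array probes purely by genomic
coordinate (the rsid is carried for reporting but never used for matching),
optionally within a small basepair window. The beacon table then gives one
row per probe with strictly binary evidence flags — signature presence, CNV
presence per cohort, external overlaps — so any locus can be looked up across
all result tables without re-deriving them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import GLOBAL_P_FILTER, AssociationRecord, SignatureRecord
from .cnv_hmm import CNVSegment
from .simulate import ProbeMap

__all__ = [
    "GWASRecord",
    "BeaconRow",
    "DEFAULT_FLAGS",
    "match_by_position",
    "build_beacon",
    "rank_matched_loci",
]

DEFAULT_FLAGS = (
    "metabolomic_signature",
    "lrr_signature",
    "cnv_cohort_a",
    "cnv_cohort_b",
    "gwas_overlap",
)


@dataclass(frozen=True)
class GWASRecord:
    chrom: str
    pos: int  # 1-based
    rsid: str
    p: float
    maf: float
    group: str  # e.g. "susceptibility|EUR|all"

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("GWAS p must lie in (0, 1]")
        if self.pos <= 0:
            raise ValueError("position must be positive")


@dataclass(frozen=True)
class BeaconRow:
    probe_id: str
    chrom: str
    pos: int
    flags: dict[str, int] = field(default_factory=dict)
    matched_gwas: tuple[tuple[str, str, float], ...] = ()  # (group, rsid, p)


def match_by_position(
    probes: ProbeMap,
    gwas: list[GWASRecord],
    window_bp: int = 0,
) -> list[tuple[str, GWASRecord]]:
    """All (probe_id, GWAS record) pairs with |Δpos| ≤ window_bp on one chrom.

    Linear merge per chromosome via sorted position arrays and binary search;
    unsorted GWAS input is sorted internally with a warning. Many-to-many:
    every in-window pair is returned exactly once.
    """
    by_chrom: dict[str, list[GWASRecord]] = {}
    for rec in gwas:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    matches: list[tuple[str, GWASRecord]] = []
    for chrom, mask in probes.chrom_slices():
        recs = by_chrom.get(chrom, [])
        if not recs:
            continue
        pos = np.array([r.pos for r in recs])
        if np.any(np.diff(pos) < 0):
            warnings.warn(f"GWAS records unsorted on {chrom}; sorting", stacklevel=2)
            order = np.argsort(pos, kind="stable")
            recs = [recs[i] for i in order]
            pos = pos[order]
        ppos = probes.pos[mask]
        pids = probes.probe_id[mask]
        lo = np.searchsorted(pos, ppos - window_bp, side="left")
        hi = np.searchsorted(pos, ppos + window_bp, side="right")
        for pid, l, h in zip(pids, lo, hi):
            for r in recs[l:h]:
                matches.append((str(pid), r))
    return matches


def rank_matched_loci(
    matches: list[tuple[str, GWASRecord]],
) -> list[tuple[str, GWASRecord]]:
    """Matched loci ordered by ascending GWAS p; ties broken by (chrom, pos)."""
    if not matches:
        raise ValueError("no matches to rank")
    return sorted(matches, key=lambda m: (m[1].p, m[1].chrom, m[1].pos))


def build_beacon(
    probes: ProbeMap,
    signature_records: list[SignatureRecord | AssociationRecord] | None = None,
    lrr_records: list[AssociationRecord] | None = None,
    segments_a: list[CNVSegment] | None = None,
    segments_b: list[CNVSegment] | None = None,
    matches: list[tuple[str, GWASRecord]] | None = None,
    flag_schema: tuple[str, ...] = DEFAULT_FLAGS,
) -> list[BeaconRow]:
    """One row per probe with 0/1 flags; evidence respects the p ≤ 0.05 filter.

    * ``metabolomic_signature`` / ``lrr_signature``: a reportable association
      or signature record at the probe.
    * ``cnv_cohort_a`` / ``cnv_cohort_b``: a called CNV segment spanning the
      probe position in that cohort.
    * ``gwas_overlap``: at least one position-matched external GWAS row.
    """
    known = set(DEFAULT_FLAGS)
    for f in flag_schema:
        if f not in known:
            raise ValueError(f"unknown flag name {f!r}; registered: {sorted(known)}")

    sig_probes = {
        r.probe_id
        for r in (signature_records or [])
        if getattr(r, "reportable", False)
    }
    lrr_probes = {r.probe_id for r in (lrr_records or []) if r.reportable}
    match_map: dict[str, list[tuple[str, str, float]]] = {}
    for pid, rec in matches or []:
        match_map.setdefault(pid, []).append((rec.group, rec.rsid, rec.p))

    def _covered(segs: list[CNVSegment] | None) -> np.ndarray:
        cov = np.zeros(probes.n_probes, dtype=bool)
        for seg in segs or []:
            cov |= (
                (probes.chrom == seg.chrom)
                & (probes.pos >= seg.start_pos)
                & (probes.pos <= seg.end_pos)
            )
        return cov

    cov_a, cov_b = _covered(segments_a), _covered(segments_b)
    rows = []
    for i, pid in enumerate(probes.probe_id):
        pid = str(pid)
        values = {
            "metabolomic_signature": int(pid in sig_probes),
            "lrr_signature": int(pid in lrr_probes),
            "cnv_cohort_a": int(cov_a[i]),
            "cnv_cohort_b": int(cov_b[i]),
            "gwas_overlap": int(pid in match_map),
        }
        rows.append(
            BeaconRow(
                probe_id=pid,
                chrom=str(probes.chrom[i]),
                pos=int(probes.pos[i]),
                flags={f: values[f] for f in flag_schema},
                matched_gwas=tuple(match_map.get(pid, ())),
            )
        )
    return rows


def beacon_frame(rows: list[BeaconRow]) -> pd.DataFrame:
    """Flat TSV-ready view of the beacon table."""
    recs = []
    for r in rows:
        d = {"probe_id": r.probe_id, "chrom": r.chrom, "pos": r.pos}
        d.update(r.flags)
        d["n_gwas_matches"] = len(r.matched_gwas)
        recs.append(d)
    return pd.DataFrame(recs)
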