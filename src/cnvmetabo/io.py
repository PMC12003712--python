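"""On-disk formats: BED-like probe maps, TSV matrices, result tables.

Matrices are TSV with a header row of probe/metabolite IDs and a first
column of sample IDs. Probe maps and CNV segments use 0-based half-open BED
coordinates on disk (1-based inclusive in memory).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .association import AssociationRecord, SignatureRecord
from .beacon import GWASRecord
from .cnv_hmm import CNVSegment
from .simulate import ProbeMap

__all__ = [
    "write_probe_map",
    "read_probe_map",
    "write_matrix",
    "read_matrix",
    "write_segments",
    "read_segments",
    "write_association_records",
    "write_signature_records",
    "read_gwas",
    "write_gwas",
]


def write_probe_map(probe_map: ProbeMap, path: str | Path) -> None:
    probe_map.to_bed().to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> ProbeMap:
    return ProbeMap.from_bed(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_matrix(
    matrix: np.ndarray, row_ids: np.ndarray, col_ids: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame(matrix, index=pd.Index(row_ids, name="sample_id"), columns=col_ids).to_csv(
        path, sep="\t"
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), df.index.to_numpy(dtype=str), df.columns.to_numpy(dtype=str)


def write_segments(segments: list[CNVSegment], path: str | Path) -> None:
    """BED: chrom, start (0-based), end, name=sample:state, score=mean_posterior*1000."""
    rows = [
        {
            "chrom": s.chrom,
            "start": s.start_pos - 1,
            "end": s.end_pos,
            "name": f"{s.sample_id}:{s.state}",
            "score": int(round(s.mean_posterior * 1000)),
            "n_probes": s.n_probes,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "n_probes"]).to_csv(
        path, sep="\t", index=False
    )


def read_segments(path: str | Path) -> list[CNVSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        sample_id, state = row.name.rsplit(":", 1)
        out.append(
            CNVSegment(
                sample_id=sample_id,
                chrom=row.chrom,
                start_pos=int(row.start) + 1,
                end_pos=int(row.end),
                state=int(state),
                n_probes=int(row.n_probes),
                mean_posterior=row.score / 1000.0,
            )
        )
    return out


def write_association_records(
    records: list[AssociationRecord], path: str | Path, probe_map: ProbeMap | None = None, cohort: str = ""
) -> None:
    pos_of = {}
    if probe_map is not None:
        pos_of = {
            str(pid): (c, int(p))
            for pid, c, p in zip(probe_map.probe_id, probe_map.chrom, probe_map.pos)
        }
    rows = []
    for r in records:
        chrom, pos = pos_of.get(r.probe_id, ("", -1))
        rows.append(
            {
                "probe_id": r.probe_id,
                "chrom": chrom,
                "pos": pos,
                "metabolite": r.metabolite_name,
                "beta": r.beta,
                "se": r.se,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "n": r.n,
                "maf": r.maf,
                "model": r.model,
                "cohort": cohort,
                "reportable": int(r.reportable),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_signature_records(records: list[SignatureRecord], path: str | Path, cohort: str = "") -> None:
    rows = [
        {
            "probe_id": r.probe_id,
            "selected_metabolites": ",".join(r.selected_metabolites),
            "n_selected": len(r.selected_metabolites),
            "joint_p_raw": r.joint_p_raw,
            "joint_p_adjusted": r.joint_p_adjusted,
            "n": r.n,
            "maf": r.maf,
            "model": r.model,
            "cohort": cohort,
            "reportable": int(r.reportable),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gwas(records: list[GWASRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"chrom": r.chrom, "pos": r.pos, "rsid": r.rsid, "p": r.p, "maf": r.maf, "group": r.group}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gwas(path: str | Path) -> list[GWASRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "rsid": str})
    return [
        GWASRecord(
            chrom=row.chrom,
            pos=int(row.pos),
            rsid="" if pd.isna(row.rsid) else str(row.rsid),
            p=float(row.p),
            maf=float(row.maf),
            group=str(row.group),
        )
        for row in df.itertuples(index=False)
    ]
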