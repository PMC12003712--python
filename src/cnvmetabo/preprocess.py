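"""Intensity normalisation: GC correction, genomic-wave removal, LRR PCs.

The corrections operate on LRR only (BAF is a ratio and carries no wave).
GC correction regresses each sample's LRR on probe GC fraction and keeps the
residuals; wave correction removes a position-local linear trend (tricube
weighted, degree 1) fitted in a fixed basepair window per chromosome. Both
re-add the per-sample mean so the global intensity level is preserved for the
copy-number HMM. The principal components of the corrected LRR matrix are the
batch/structure covariates of every association model downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.decomposition import PCA

from .simulate import IntensityPanel, ProbeMap

__all__ = ["CorrectionReport", "gc_correct", "wave_correct", "compute_lrr_pcs"]

DEFAULT_WINDOW_BP = 500_000


@dataclass(frozen=True)
class CorrectionReport:
    gc_slope: np.ndarray | None  # per-sample regression slope on GC
    variance_before: np.ndarray  # per-sample LRR variance
    variance_after: np.ndarray
    window_bp: int | None = None


def gc_correct(
    panel: IntensityPanel, probe_map: ProbeMap
) -> tuple[IntensityPanel, CorrectionReport]:
    """Per-sample least-squares removal of the linear GC term from LRR."""
    gc = probe_map.gc_fraction
    if np.ptp(gc) == 0:
        warnings.warn("constant GC column; GC correction skipped", stacklevel=2)
        v = panel.lrr.var(axis=1)
        return panel, CorrectionReport(None, v, v)
    gc_c = gc - gc.mean()
    lrr = panel.lrr
    row_mean = lrr.mean(axis=1, keepdims=True)
    # slope per sample: cov(lrr, gc) / var(gc), vectorised across samples
    slope = (lrr - row_mean) @ gc_c / (gc_c @ gc_c)
    corrected = lrr - slope[:, None] * gc_c[None, :]
    report = CorrectionReport(
        gc_slope=slope,
        variance_before=lrr.var(axis=1),
        variance_after=corrected.var(axis=1),
    )
    return replace(panel, lrr=corrected), report


def _loess_design(pos: np.ndarray, window_bp: int, min_points: int = 5):
    """Per-probe neighbour slices and tricube weights for local linear fits.

    Returns a list of (slice, weights, centred positions) reused across all
    samples — the geometry depends only on the probe map.
    """
    half = window_bp / 2.0
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    designs = []
    for j in range(len(pos)):
        sl = slice(lo[j], hi[j])
        x = pos[sl].astype(float) - pos[j]
        if hi[j] - lo[j] < min_points:
            designs.append((sl, None, None))
            continue
        span = max(np.abs(x).max(), 1.0)
        w = (1 - (np.abs(x) / (span * 1.0001)) ** 3) ** 3
        designs.append((sl, w, x))
    return designs


def wave_correct(
    panel: IntensityPanel,
    probe_map: ProbeMap,
    window_bp: int = DEFAULT_WINDOW_BP,
    winsor: float = 0.5,
) -> tuple[IntensityPanel, CorrectionReport]:
    """Subtract a loess-style local linear trend of LRR on position.

    Degree-1 tricube-weighted fits in a ±window_bp/2 neighbourhood of each
    probe, per sample and chromosome; windows with too few probes fall back to
    the window mean. The per-sample mean is re-added afterwards.

    The trend is estimated on a winsorized copy of the LRR (clipped to the
    per-sample median ± ``winsor``) so that genuine CNV signal — a −3.5 LRR
    homozygous-deletion block would drag the local trend down and push its
    neighbourhood up after subtraction — does not leak into the wave estimate.
    Set ``winsor`` to ``inf`` for a plain fit.
    """
    lrr = panel.lrr
    med = np.median(lrr, axis=1, keepdims=True)
    fit_y = np.clip(lrr, med - winsor, med + winsor)
    trend = np.zeros_like(lrr)
    warned = False
    for chrom, mask in probe_map.chrom_slices():
        pos = probe_map.pos[mask]
        y = fit_y[:, mask]  # samples × probes_on_chrom
        t = np.empty_like(y)
        for j, (sl, w, x) in enumerate(_loess_design(pos, window_bp)):
            block = y[:, sl]
            if w is None:
                if not warned:
                    warnings.warn(
                        f"fewer than 5 probes in a {window_bp} bp window on {chrom}; "
                        "falling back to window mean",
                        stacklevel=2,
                    )
                    warned = True
                t[:, j] = block.mean(axis=1)
                continue
            sw = w.sum()
            swx = w @ x
            swxx = w @ (x * x)
            swy = block @ w
            swxy = block @ (w * x)
            det = sw * swxx - swx * swx
            if det <= 1e-12 * max(sw * swxx, 1.0):
                t[:, j] = swy / sw
                continue
            a = (swxx * swy - swx * swxy) / det  # intercept = fit at x=0
            t[:, j] = a
        trend[:, mask] = t
    corrected = lrr - trend
    corrected += (lrr.mean(axis=1) - corrected.mean(axis=1))[:, None]
    report = CorrectionReport(
        gc_slope=None,
        variance_before=lrr.var(axis=1),
        variance_after=corrected.var(axis=1),
        window_bp=window_bp,
    )
    return replace(panel, lrr=corrected), report


def compute_lrr_pcs(panel: IntensityPanel, k: int = 50) -> np.ndarray:
    """First k principal-component scores of the column-centred LRR matrix.

    Scores are ordered by decreasing explained variance; k is capped at the
    matrix rank bound with a warning, and a parameter error is raised only for
    non-positive k.
    """
    n, p = panel.lrr.shape
    max_k = min(n, p) - 1
    if k < 1:
        raise ValueError("k must be positive")
    if k > max_k:
        warnings.warn(f"k={k} exceeds rank bound {max_k}; capping", stacklevel=2)
        k = max_k
    pca = PCA(n_components=k, svd_solver="full")
    return pca.fit_transform(panel.lrr)
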