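"""Read-depth normalization and reference-derived per-amplicon baselines.

The normalization follows the Mission Bio "mb" scheme in three steps:

1. *Good barcodes*: keep cells whose total read count exceeds 10% of the
   11th-largest cell total (drops empty/debris droplets).
2. *Cell-depth adjustment*: divide each count by the cell's mean count per
   amplicon plus 1 (the +1 stabilizes near-empty cells).
3. *Amplicon scaling*: divide by the per-amplicon median over good barcodes
   (plus 0.05) and multiply by 2, so a typical diploid amplicon sits near 2.

Reference cells of known karyotype then provide per-amplicon baselines
``beta_i = median_ref(y_i) * 2 / CN_ref,i`` and the depth signal used by the
copy-number callers, ``d_norm = y / beta`` (about ``CN/2`` for a cell carrying
``CN`` copies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import CountMatrix, AmpliconPanel, ReferenceSpec

__all__ = [
    "NormalizationResult",
    "good_barcodes",
    "mb_normalize",
    "reference_baselines",
    "depth_normalize",
]

GOOD_BARCODE_FRACTION = 0.10
MIN_AMPLICON_MEDIAN = 0.01


def good_barcodes(raw: CountMatrix, fraction: float = GOOD_BARCODE_FRACTION) -> list[str]:
    """Cells whose total count exceeds ``fraction`` of the 11th-largest total.

    With fewer than 11 cells the pivot falls back to the smallest total, so
    every cell is retained (the filter exists to drop debris barcodes, which
    cannot be told apart at toy scale).
    """
    if raw.n_cells < 1:
        raise ValueError("count matrix has no cells")
    totals = raw.values.sum(axis=0)
    if np.all(totals == 0):
        warnings.warn("all-zero count matrix: no good barcodes")
        return []
    order = np.sort(totals)[::-1]
    pivot = order[10] if len(order) >= 11 else order[-1]
    keep = totals > fraction * pivot
    return [c for c, k in zip(raw.cell_ids, keep) if k]


@dataclass
class NormalizationResult:
    good_barcodes: list[str]
    normalized: CountMatrix          # y_{i,c}, all input cells
    amplicon_medians: np.ndarray     # m_i over good barcodes
    low_median_amplicons: list[str]  # flagged near-zero-median amplicons


def mb_normalize(
    raw: CountMatrix,
    fraction: float = GOOD_BARCODE_FRACTION,
    min_amplicon_median: float = MIN_AMPLICON_MEDIAN,
) -> NormalizationResult:
    """Apply the mb scheme; returns y values for all cells plus QC flags.

    ``y_{i,c} = (d_{i,c} / (mean_c + 1)) / (m_i + 0.05) * 2`` where ``m_i`` is
    the per-amplicon median of depth-adjusted counts over good barcodes.
    Amplicons with ``m_i < min_amplicon_median`` are flagged for exclusion
    (near-zero median, no usable depth signal); zeros simply propagate to 0.
    """
    good = good_barcodes(raw, fraction=fraction)
    cell_mean = raw.values.mean(axis=0)  # mean over amplicons, per cell
    dtilde = raw.values / (cell_mean + 1.0)[None, :]
    if good:
        good_idx = raw.cell_index(good)
        m = np.median(dtilde[:, good_idx], axis=1)
    else:
        m = np.zeros(raw.n_amplicons)
    y = dtilde / (m + 0.05)[:, None] * 2.0
    low = [a for a, mi in zip(raw.amplicon_ids, m) if mi < min_amplicon_median]
    if low:
        warnings.warn(f"{len(low)} amplicon(s) with near-zero median flagged")
    norm = CountMatrix(list(raw.amplicon_ids), list(raw.cell_ids), y)
    return NormalizationResult(good, norm, m, low)


def reference_baselines(
    norm: CountMatrix, panel: AmpliconPanel, spec: ReferenceSpec
) -> np.ndarray:
    """Per-amplicon baselines ``beta_i`` learned from reference cells.

    ``beta_i = median over reference cells of y_{i,c} * 2 / CN_ref,i`` where
    ``CN_ref,i`` is the template copy number of the amplicon's chromosome.
    Division by beta then maps a reference cell's median signal to
    ``CN_ref,i / 2``, i.e. 1.0 on diploid reference chromosomes.  Amplicons
    with ``beta = 0`` carry no reference signal and get ``beta = NaN`` (the
    callers drop them with a warning).
    """
    ref_idx = norm.cell_index(spec.reference_cells)
    amp_chrom = dict(zip(panel.amplicons["amplicon_id"], panel.amplicons["chrom"]))
    cn_ref = np.array([spec.cn(amp_chrom[a]) for a in norm.amplicon_ids], dtype=float)
    med = np.median(norm.values[:, ref_idx], axis=1)
    beta = med * 2.0 / cn_ref
    zero = beta <= 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} amplicon(s) with zero reference baseline dropped")
        beta = beta.copy()
        beta[zero] = np.nan
    return beta


def depth_normalize(norm: CountMatrix, beta: np.ndarray) -> CountMatrix:
    """Divide mb-normalized values by per-amplicon baselines: d_norm = y / beta.

    Amplicons with NaN baselines yield NaN depth (treated as missing by the
    callers).
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (norm.n_amplicons,):
        raise ValueError("baseline vector length does not match amplicon count")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = norm.values / beta[:, None]
    return CountMatrix(list(norm.amplicon_ids), list(norm.cell_ids), np.where(np.isfinite(d), d, np.nan))
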