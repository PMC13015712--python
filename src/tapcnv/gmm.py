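"""Depth-only baseline caller: per-probe Weibull fits plus segment-level GMM.

The procedure mirrors the established depth-only approach for targeted
single-cell panels:

1. fit a Weibull distribution (shape ``alpha_i``, scale ``lambda_i``) to each
   amplicon's mb-normalized values in the reference cells;
2. generate synthetic cells for each copy-number state ``k`` by scaling the
   Weibull scale by ``k / CN_ref``;
3. summarize probe values to whole-chromosome segments by the median, fit one
   Gaussian component per state to the synthetic segment medians (moment
   matching — the component memberships are known by construction);
4. classify each real cell's segment median by maximum posterior under equal
   priors, ties broken toward the lower state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hmm import ChainLayout
from .io import AmpliconPanel, CallSet, CountMatrix, ReferenceSpec
from . import normalization as norm_mod

__all__ = [
    "GmmConfig",
    "ProbeWeibull",
    "SegmentGmm",
    "fit_probe_weibulls",
    "synthesize_cells",
    "fit_segment_gmm",
    "classify",
    "call_cells_gmm",
]

_ZERO_OFFSET = 1e-3  # added to exact zeros before Weibull fitting


@dataclass
class GmmConfig:
    n_states: int = 5
    n_syn: int = 500                # synthetic cells per state
    min_reference_cells: int = 5
    min_amplicon_median: float = 0.01
    good_barcode_fraction: float = 0.10


@dataclass
class ProbeWeibull:
    """Per-amplicon Weibull fits on reference-normalized counts."""

    amplicon_ids: list[str]
    shape: np.ndarray   # alpha_i, NaN when the fit failed
    scale: np.ndarray   # lambda_i

    @property
    def ok(self) -> np.ndarray:
        return np.isfinite(self.shape) & np.isfinite(self.scale) & (self.shape > 0) & (self.scale > 0)


@dataclass
class SegmentGmm:
    """Per-chromosome, per-state Gaussian components on segment medians."""

    chromosomes: list[str]
    means: np.ndarray      # (n_chr, K)
    variances: np.ndarray  # (n_chr, K)


def fit_probe_weibulls(norm: CountMatrix, spec: ReferenceSpec, config: GmmConfig | None = None) -> ProbeWeibull:
    """Maximum-likelihood Weibull fit per amplicon on reference-cell values.

    Exact zeros are offset by a small constant before fitting (the Weibull has
    no mass at 0 for shape > 1).  Degenerate inputs (constant values) are
    flagged with NaN parameters and excluded from synthesis.
    """
    cfg = config or GmmConfig()
    ref_idx = norm.cell_index(spec.reference_cells)
    if len(ref_idx) < cfg.min_reference_cells:
        raise ValueError(
            f"need at least {cfg.min_reference_cells} reference cells, got {len(ref_idx)}"
        )
    vals = norm.values[:, ref_idx]
    n_amp = norm.n_amplicons
    shape = np.full(n_amp, np.nan)
    scale = np.full(n_amp, np.nan)
    for i in range(n_amp):
        x = vals[i].astype(float)
        x = np.where(x <= 0, _ZERO_OFFSET, x)
        if np.ptp(x) <= 0:
            continue  # constant input: no ML fit exists
        try:
            a, _, lam = stats.weibull_min.fit(x, floc=0)
        except Exception:
            continue
        if np.isfinite(a) and np.isfinite(lam) and a > 0 and lam > 0:
            shape[i] = a
            scale[i] = lam
    n_bad = int(np.sum(~(np.isfinite(shape))))
    if n_bad:
        warnings.warn(f"Weibull fit failed for {n_bad} amplicon(s); excluded from synthesis")
    return ProbeWeibull(list(norm.amplicon_ids), shape, scale)


def synthesize_cells(
    weibulls: ProbeWeibull,
    k: int,
    n_syn: int,
    cn_ref: np.ndarray,
    rng: np.random.Generator,
) -> CountMatrix:
    """Draw synthetic cells at copy-number state k: Weibull(alpha_i, lambda_i * k / CN_ref,i)."""
    if not 1 <= k <= 5:
        raise ValueError("copy-number state must lie in 1..5")
    cn_ref = np.asarray(cn_ref, dtype=float)
    n_amp = len(weibulls.amplicon_ids)
    vals = np.full((n_amp, n_syn), np.nan)
    ok = weibulls.ok
    scales = weibulls.scale[ok] * (k / cn_ref[ok])
    u = rng.random((int(ok.sum()), n_syn))
    # inverse-CDF sampling keeps the draw count per amplicon stable
    vals[ok] = scales[:, None] * (-np.log1p(-u)) ** (1.0 / weibulls.shape[ok][:, None])
    ids = [f"syn_k{k}_{j}" for j in range(n_syn)]
    return CountMatrix(list(weibulls.amplicon_ids), ids, np.nan_to_num(vals, nan=0.0))


def _segment_medians(values: np.ndarray, layout: ChainLayout) -> np.ndarray:
    """(n_amp, n_cells) probe values -> (n_chr, n_cells) per-chromosome medians."""
    out = np.zeros((layout.n_chromosomes, values.shape[1]))
    for ci in range(layout.n_chromosomes):
        out[ci] = np.median(values[layout.chrom_index == ci], axis=0)
    return out


def fit_segment_gmm(
    weibulls: ProbeWeibull,
    layout: ChainLayout,
    cn_ref: np.ndarray,
    config: GmmConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SegmentGmm:
    """Fit per-chromosome Gaussian components from synthetic cells at each state.

    Components are moment-matched (mean and variance of the synthetic segment
    medians) since each synthetic cell's state is known by construction.
    """
    cfg = config or GmmConfig()
    rng = rng or np.random.default_rng()
    K = cfg.n_states
    means = np.zeros((layout.n_chromosomes, K))
    variances = np.zeros((layout.n_chromosomes, K))
    amp_order = {a: i for i, a in enumerate(weibulls.amplicon_ids)}
    sel = np.array([amp_order[a] for a in layout.amplicon_ids])
    w = ProbeWeibull(list(layout.amplicon_ids), weibulls.shape[sel], weibulls.scale[sel])
    for k in range(1, K + 1):
        syn = synthesize_cells(w, k, cfg.n_syn, cn_ref, rng)
        seg = _segment_medians(syn.values, layout)
        means[:, k - 1] = seg.mean(axis=1)
        variances[:, k - 1] = np.maximum(seg.var(axis=1), 1e-8)
    return SegmentGmm(list(layout.chromosomes), means, variances)


def classify(segment_medians: np.ndarray, gmm: SegmentGmm) -> np.ndarray:
    """Assign each (chromosome, cell) segment median to the max-posterior state.

    ``segment_medians`` is (n_chr, n_cells); posteriors use equal state priors,
    so the argmax of the per-state Gaussian density decides; exact ties go to
    the lower state.
    """
    n_chr, n_cells = segment_medians.shape
    calls = np.zeros((n_chr, n_cells), dtype=int)
    for ci in range(n_chr):
        logp = stats.norm.logpdf(
            segment_medians[ci][:, None], gmm.means[ci][None, :], np.sqrt(gmm.variances[ci])[None, :]
        )
        calls[ci] = np.argmax(logp, axis=1) + 1  # argmax ties resolve to lower index
    return calls


def call_cells_gmm(
    counts: CountMatrix,
    panel: AmpliconPanel,
    spec: ReferenceSpec,
    config: GmmConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CallSet:
    """End-to-end depth-only baseline calling for every cell in the count matrix."""
    cfg = config or GmmConfig()
    rng = rng or np.random.default_rng()
    res = norm_mod.mb_normalize(
        counts, fraction=cfg.good_barcode_fraction, min_amplicon_median=cfg.min_amplicon_median
    )
    keep = [a for a in counts.amplicon_ids if a not in set(res.low_median_amplicons)]
    layout = ChainLayout.from_panel(panel, keep_amplicons=keep)
    frame = res.normalized.to_frame().loc[layout.amplicon_ids]
    y = frame.to_numpy()

    amp_chrom = dict(zip(panel.amplicons["amplicon_id"], panel.amplicons["chrom"]))
    cn_ref = np.array([spec.cn(amp_chrom[a]) for a in layout.amplicon_ids], dtype=float)

    sub = CountMatrix(list(layout.amplicon_ids), list(counts.cell_ids), y)
    weib = fit_probe_weibulls(sub, spec, cfg)
    usable = weib.ok
    if not usable.all():
        keep_ids = [a for a, u in zip(layout.amplicon_ids, usable) if u]
        layout = ChainLayout.from_panel(panel, keep_amplicons=keep_ids)
        order = [sub.amplicon_ids.index(a) for a in layout.amplicon_ids]
        y = y[order]
        cn_ref = cn_ref[order]
        weib = ProbeWeibull(list(layout.amplicon_ids), weib.shape[order], weib.scale[order])

    gmm = fit_segment_gmm(weib, layout, cn_ref, cfg, rng)
    seg = _segment_medians(y, layout)
    calls = classify(seg, gmm).T  # (cells, chromosomes)
    return CallSet(list(counts.cell_ids), list(layout.chromosomes), calls)
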