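"""Joint depth + B-allele-frequency HMM copy-number caller.

Model
-----
Each chromosome of each cell is an independent Markov chain over hidden copy
number states ``k in {1..K}`` (default K=5) with a persistence transition
matrix: diagonal ``1 - epsilon``, off-diagonal ``epsilon / (K-1)``.  At each
amplicon the emission factorizes into

* a Gaussian read-depth term ``N(d_norm | mu_k, sigma_d^2)`` with
  ``mu_k`` initialized at ``k/2`` on the baseline-normalized scale, and
* a genotype-marginalized allele-frequency term: folded minor allele
  frequencies ``b = min(BAF, 1-BAF)`` are modeled per variant by a truncated
  normal on [0, 0.5] centered on the genotype's expected MAF
  ``min(m, k-m)/k`` (m = minor-allele copies), summed over the genotypes
  compatible with state k, weighted by priors anchored at the per-amplicon
  heterozygosity rate ``h_i``.

Parameters ``mu, sigma_d^2, sigma_b, epsilon`` are refined per cell by
Baum-Welch EM (forward-backward per chromosome, M-step pooled across the
cell's chromosomes); when the mean heterozygosity is low the depth means are
regularized toward their ``k/2`` priors to prevent collapse.  Viterbi paths
are decoded per chromosome and aggregated to whole-chromosome calls by the
mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtr, logsumexp

from .hmm_core import PosteriorSet, forward_backward, forward_backward_batch, viterbi, viterbi_batch
from .io import AmpliconPanel, BafTable, CallSet, CountMatrix, ReferenceSpec
from . import normalization as norm_mod

__all__ = [
    "CallerConfig",
    "HmmParams",
    "ChainLayout",
    "CellObservations",
    "transition_matrix",
    "expected_maf",
    "genotype_priors",
    "truncnorm_maf_density",
    "emission_logprob",
    "baum_welch",
    "aggregate_segments",
    "learn_reference",
    "call_cells",
    "forward_backward",
    "viterbi",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class CallerConfig:
    """Tunable knobs of the HMM caller (defaults are the recommended values)."""

    n_states: int = 5
    epsilon0: float = 1e-3          # initial breakpoint probability per step
    max_iter: int = 50
    tol: float = 1e-5               # EM stop: max absolute parameter change
    het_threshold: float = 0.15     # MAF above this counts as heterozygous in reference
    reg_weight_scale: float = 10.0  # pseudo-observation weight w0 for depth-mean shrinkage
    het_reg_threshold: float = 0.25  # shrinkage active when mean heterozygosity below this
    good_barcode_fraction: float = 0.10
    min_amplicon_median: float = 0.01
    sigma_b_floor: float = 0.01
    sigma_d2_floor: float = 1e-4
    depth_outlier_cap: float = 5.0  # d_norm above this is treated as missing


@dataclass
class HmmParams:
    """HMM parameter set (per cell once fitted; shared initial values before EM)."""

    mu: np.ndarray                 # (K,) state depth means
    sigma_d2: float                # depth variance
    sigma_b: float                 # MAF standard deviation
    epsilon: float                 # state switch probability per step
    het_rates: np.ndarray          # (n_amplicons,) per-amplicon heterozygosity h_i
    n_states: int = 5
    reg_weight_scale: float = 10.0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.het_rates = np.asarray(self.het_rates, dtype=float)
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError(f"epsilon must lie in (0, 1), got {self.epsilon}")
        if self.sigma_d2 <= 0 or self.sigma_b <= 0:
            raise ValueError("sigma_d2 and sigma_b must be positive")
        if np.any((self.het_rates < 0) | (self.het_rates > 1)):
            raise ValueError("heterozygosity rates must lie in [0, 1]")


def transition_matrix(epsilon: float, K: int = 5) -> np.ndarray:
    """Persistence transition matrix: diagonal 1-eps, off-diagonal eps/(K-1)."""
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must lie in (0, 1), got {epsilon}")
    if K < 2:
        raise ValueError("need at least two states")
    T = np.full((K, K), epsilon / (K - 1))
    np.fill_diagonal(T, 1.0 - epsilon)
    return T


def expected_maf(m: int, k: int) -> float:
    """Expected minor allele frequency min(m, k-m)/k of a genotype with m minor copies."""
    if k < 1:
        raise ValueError("copy number must be >= 1")
    if not 0 <= m <= k:
        raise ValueError(f"minor-copy count {m} outside 0..{k}")
    return min(m, k - m) / k


@dataclass
class GenotypePrior:
    """Genotype mixture for one state: minor-copy counts, priors, expected MAFs."""

    minor_copies: np.ndarray
    prior: np.ndarray
    expected_maf: np.ndarray


def genotype_priors(k: int, h: float) -> GenotypePrior:
    """Genotype prior for copy-number state k at an amplicon with heterozygosity h.

    The diploid case places mass ``h`` on AB and ``(1-h)/2`` on each homozygote.
    For other k the homozygous mass ``1-h`` splits equally between the all-A and
    all-B genotypes and the heterozygous mass ``h`` splits uniformly over the
    ``k-1`` mixed genotypes (maximum-entropy interpolation that reproduces the
    diploid rule at k=2).  At k=1 no heterozygote exists and the two
    single-allele genotypes get mass 1/2 each.
    """
    if k < 1:
        raise ValueError("copy number must be >= 1")
    if not 0.0 <= h <= 1.0:
        raise ValueError("heterozygosity must lie in [0, 1]")
    ms = np.arange(k + 1)
    if k == 1:
        prior = np.array([0.5, 0.5])
    else:
        prior = np.full(k + 1, h / (k - 1))
        prior[0] = prior[k] = (1.0 - h) / 2.0
    mus = np.minimum(ms, k - ms) / k
    return GenotypePrior(ms, prior, mus)


def truncnorm_maf_density(b, mu_g: float, sigma_b: float):
    """Density of the [0, 0.5]-truncated normal MAF model at b.

    ``f(b) = phi((b - mu_g)/sigma_b) / (sigma_b * (Phi((0.5-mu_g)/sigma_b) - Phi((0-mu_g)/sigma_b)))``
    """
    if sigma_b <= 0:
        raise ValueError("sigma_b must be positive")
    b = np.asarray(b, dtype=float)
    Z = ndtr((0.5 - mu_g) / sigma_b) - ndtr((0.0 - mu_g) / sigma_b)
    if Z <= 0:
        raise ValueError("degenerate truncated-normal normalizer")
    z = (b - mu_g) / sigma_b
    phi = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    out = phi / (sigma_b * Z)
    return float(out) if out.ndim == 0 else out


def emission_logprob(
    d_norm: float | None,
    mafs,
    k: int,
    params: HmmParams,
    h: float,
) -> float:
    """Log emission probability of one amplicon's observations under state k.

    ``log N(d_norm | mu_k, sigma_d^2) + log sum_g P(g|k) prod_v f(b_v | g)``;
    a missing depth or an empty MAF vector drops the corresponding factor
    (both missing gives log 1 = 0).
    """
    total = 0.0
    if d_norm is not None and np.isfinite(d_norm):
        var = params.sigma_d2
        total += -0.5 * (_LOG2PI + np.log(var)) - (d_norm - params.mu[k - 1]) ** 2 / (2 * var)
    mafs = np.asarray(mafs, dtype=float)
    mafs = mafs[np.isfinite(mafs)]
    if mafs.size:
        gp = genotype_priors(k, h)
        terms = []
        with np.errstate(divide="ignore"):
            for p, mu_g in zip(gp.prior, gp.expected_maf):
                ll = np.sum(np.log(truncnorm_maf_density(mafs, mu_g, params.sigma_b)))
                terms.append(np.log(p) + ll)
        total += logsumexp(terms)
    return float(total)


# ---------------------------------------------------------------------------
# chain layout and observation containers
# ---------------------------------------------------------------------------


@dataclass
class ChainLayout:
    """Genomic ordering of amplicons into per-chromosome chains plus variant mapping."""

    amplicon_ids: list[str]        # genomic order (chromosome, then start)
    chromosomes: list[str]         # natural genome order
    chrom_index: np.ndarray        # (n_amp,) chain id per amplicon
    pos_in_chain: np.ndarray       # (n_amp,) 0-based position within chain
    lengths: np.ndarray            # (n_chr,) amplicons per chromosome
    variant_ids: list[str]         # sorted by host amplicon's genomic order
    variant_amp: np.ndarray        # (n_var,) amplicon index of each variant

    @classmethod
    def from_panel(cls, panel: AmpliconPanel, keep_amplicons=None) -> "ChainLayout":
        amp = panel.sorted_amplicons()
        if keep_amplicons is not None:
            keep = set(keep_amplicons)
            amp = amp[amp["amplicon_id"].isin(keep)].reset_index(drop=True)
        if len(amp) == 0:
            raise ValueError("no amplicons left in panel")
        chroms = [c for c in sorted(set(amp["chrom"]), key=_chrom_key) ]
        dropped = [c for c in panel.chromosomes if c not in chroms]
        if dropped:
            warnings.warn(f"chromosome(s) with no usable amplicons dropped: {dropped}")
        cpos = {c: i for i, c in enumerate(chroms)}
        chrom_index = np.array([cpos[c] for c in amp["chrom"]], dtype=int)
        lengths = np.bincount(chrom_index, minlength=len(chroms))
        pos_in_chain = np.zeros(len(amp), dtype=int)
        counters = np.zeros(len(chroms), dtype=int)
        for i, ci in enumerate(chrom_index):
            pos_in_chain[i] = counters[ci]
            counters[ci] += 1
        amp_ids = amp["amplicon_id"].tolist()
        apos = {a: i for i, a in enumerate(amp_ids)}
        var = panel.variants[panel.variants["amplicon_id"].isin(apos)].copy()
        var["_ai"] = var["amplicon_id"].map(apos)
        var = var.sort_values(["_ai", "pos", "variant_id"], kind="stable")
        return cls(
            amp_ids,
            chroms,
            chrom_index,
            pos_in_chain,
            lengths,
            var["variant_id"].tolist(),
            var["_ai"].to_numpy(dtype=int),
        )

    @property
    def n_amplicons(self) -> int:
        return len(self.amplicon_ids)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def variants_per_amplicon(self) -> np.ndarray:
        return np.bincount(self.variant_amp, minlength=self.n_amplicons)


def _chrom_key(label):
    from .io import natural_chrom_key

    return natural_chrom_key(label)


@dataclass
class CellObservations:
    """One cell's observations in layout order.

    ``depth``: (n_amplicons,) baseline-normalized depth, NaN when missing;
    ``maf``: (n_variants,) folded minor allele frequencies in [0, 0.5], NaN
    when missing.
    """

    layout: ChainLayout
    depth: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.depth.shape != (self.layout.n_amplicons,):
            raise ValueError("depth vector does not match layout amplicon count")
        if self.maf.shape != (len(self.layout.variant_ids),):
            raise ValueError("MAF vector does not match layout variant count")
        with np.errstate(invalid="ignore"):
            if np.any((self.maf < 0) | (self.maf > 0.5)):
                raise ValueError("MAF values must lie in [0, 0.5]")


# ---------------------------------------------------------------------------
# batched emission computation
# ---------------------------------------------------------------------------


class _GenotypeTables:
    """Precomputed per-amplicon genotype priors and expected-MAF lookups."""

    def __init__(self, het_rates: np.ndarray, K: int):
        self.K = K
        mus = sorted({expected_maf(m, k) for k in range(1, K + 1) for m in range(k + 1)})
        self.unique_mus = np.array(mus)
        mu_pos = {m: i for i, m in enumerate(mus)}
        h = np.asarray(het_rates, dtype=float)
        n_amp = h.shape[0]
        self.log_prior = []   # per k: (n_amp, k+1)
        self.mu_idx = []      # per k: (k+1,) index into unique_mus
        self.mubar = np.zeros((n_amp, K))  # prior-weighted expected MAF per state
        for k in range(1, K + 1):
            prior = np.empty((n_amp, k + 1))
            if k == 1:
                prior[:] = 0.5
            else:
                prior[:] = (h / (k - 1))[:, None]
                prior[:, 0] = prior[:, k] = (1.0 - h) / 2.0
            with np.errstate(divide="ignore"):
                self.log_prior.append(np.log(prior))
            emaf = np.array([expected_maf(m, k) for m in range(k + 1)])
            self.mu_idx.append(np.array([mu_pos[v] for v in emaf]))
            self.mubar[:, k - 1] = prior @ emaf


def _depth_logprobs(d0, depth_obs, mu, sd2):
    """Gaussian depth log-likelihood (C, n_amp, K); missing depth contributes 0."""
    var = sd2[:, None, None]
    logd = -0.5 * (_LOG2PI + np.log(var)) - (d0[:, :, None] - mu[:, None, :]) ** 2 / (2 * var)
    return logd * depth_obs[:, :, None]


def _baf_logprobs(b0, maf_obs, sb, layout, tables, n_amp):
    """Genotype-marginalized MAF log-likelihood (C, n_amp, K); amplicons with no
    observed variants contribute 0 (the factor drops)."""
    C = b0.shape[0]
    K = tables.K
    out = np.zeros((C, n_amp, K))
    if not b0.shape[1]:
        return out
    mus = tables.unique_mus
    sbb = sb[:, None, None]
    z = (b0[:, :, None] - mus[None, None, :]) / sbb
    logZ = np.log(ndtr((0.5 - mus[None, :]) / sb[:, None]) - ndtr(-mus[None, :] / sb[:, None]))
    logpdf = (-0.5 * z * z - 0.5 * _LOG2PI) - np.log(sbb) - logZ[:, None, :]
    logpdf = logpdf * maf_obs[:, :, None]
    # per-amplicon sums over each amplicon's variants (variant_amp is sorted)
    S = np.zeros((C, n_amp, len(mus)))
    counts = np.bincount(layout.variant_amp, minlength=n_amp)
    amps_with = np.flatnonzero(counts > 0)
    starts = np.searchsorted(layout.variant_amp, amps_with)
    seg = np.add.reduceat(logpdf, starts, axis=1)
    S[:, amps_with] = seg
    with np.errstate(invalid="ignore"):
        for k in range(1, K + 1):
            scores = tables.log_prior[k - 1][None, :, :] + S[:, :, tables.mu_idx[k - 1]]
            out[:, :, k - 1] = logsumexp(scores, axis=2)
    return out


def _emission_logprobs(d0, depth_obs, b0, maf_obs, mu, sd2, sb, layout, tables):
    """Log emission scores (C, n_amp, K) for a batch of cells.

    ``d0``/``b0`` are NaN-free copies of depth/MAF with ``depth_obs``/``maf_obs``
    the observation masks; ``mu`` (C, K), ``sd2``/``sb`` (C,) are per-cell
    parameters.
    """
    n_amp = d0.shape[1]
    return _depth_logprobs(d0, depth_obs, mu, sd2) + _baf_logprobs(
        b0, maf_obs, sb, layout, tables, n_amp
    )


def _pad_chains(emit, layout):
    """(C, n_amp, K) amplicon-order emissions -> (C * n_chr, Lmax, K) padded chains."""
    C, n_amp, K = emit.shape
    Lmax = int(layout.lengths.max())
    pad = np.zeros((C, layout.n_chromosomes, Lmax, K))
    pad[:, layout.chrom_index, layout.pos_in_chain] = emit
    return pad.reshape(C * layout.n_chromosomes, Lmax, K), Lmax


# ---------------------------------------------------------------------------
# Baum-Welch EM (batched across cells)
# ---------------------------------------------------------------------------


@dataclass
class _FitResult:
    mu: np.ndarray          # (C, K)
    sigma_d2: np.ndarray    # (C,)
    sigma_b: np.ndarray     # (C,)
    epsilon: np.ndarray     # (C,)
    loglik: np.ndarray      # (C,) final data log-likelihood
    n_iter: np.ndarray      # (C,)
    gamma: np.ndarray       # (C, n_amp, K) posteriors under the final parameters
    loglik_history: list    # list over iterations of (C,) log-likelihood arrays


def _fit_batch(depth, maf, layout, params0: HmmParams, config: CallerConfig) -> _FitResult:
    """Run per-cell Baum-Welch for every row of ``depth``/``maf`` at once.

    Each cell is an independent EM problem (forward-backward per chromosome,
    M-step pooled over the cell's chromosomes); batching is purely a
    vectorization across cells.  A cell stops updating once its largest
    parameter change drops below ``config.tol``.
    """
    K = params0.n_states
    C, n_amp = depth.shape
    depth_obs = np.isfinite(depth)
    d0 = np.nan_to_num(depth)
    maf_obs = np.isfinite(maf)
    b0 = np.nan_to_num(maf)
    tables = _GenotypeTables(params0.het_rates, K)

    hbar = float(np.mean(params0.het_rates)) if n_amp else 0.0
    # shrinkage weight in pseudo-observations *per amplicon*: it must outweigh
    # the data term (sum_i gamma_i(k) <= n) at zero heterozygosity or the
    # depth means collapse onto the cell's depth distribution
    w = (
        params0.reg_weight_scale
        * n_amp
        * max(0.0, config.het_reg_threshold - hbar)
        / config.het_reg_threshold
    )
    mu_prior = np.arange(1, K + 1) / 2.0

    mu = np.tile(np.asarray(params0.mu, dtype=float), (C, 1))
    sd2 = np.full(C, float(params0.sigma_d2))
    sb = np.full(C, float(params0.sigma_b))
    eps = np.full(C, float(params0.epsilon))

    lengths_all = np.tile(layout.lengths, C)
    trans_mask = (np.arange(int(layout.lengths.max()) - 1)[None, :] < (layout.lengths - 1)[:, None]) if layout.lengths.max() > 1 else np.zeros((layout.n_chromosomes, 0), dtype=bool)
    n_trans = int((layout.lengths - 1).clip(min=0).sum())
    log_pi = np.full(K, -np.log(K))
    n_d = depth_obs.sum(axis=1)
    n_b = maf_obs.sum(axis=1)
    gv_resid = None
    if maf.shape[1]:
        # squared residuals of each MAF about the prior-weighted state mean
        gv_resid = (b0[:, :, None] - tables.mubar[layout.variant_amp][None, :, :]) ** 2
        gv_resid = gv_resid * maf_obs[:, :, None]

    active = np.ones(C, dtype=bool)
    n_iter = np.zeros(C, dtype=int)
    loglik = np.full(C, -np.inf)
    hist: list[np.ndarray] = []
    gamma_amp = np.zeros((C, n_amp, K))

    for it in range(config.max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        baf_cur = _baf_logprobs(b0[idx], maf_obs[idx], sb[idx], layout, tables, n_amp)
        emit = _depth_logprobs(d0[idx], depth_obs[idx], mu[idx], sd2[idx]) + baf_cur
        padded, Lmax = _pad_chains(emit, layout)
        with np.errstate(divide="ignore"):
            logT = np.log(np.stack([transition_matrix(e, K) for e in eps[idx]]))
        logT_rep = np.repeat(logT, layout.n_chromosomes, axis=0)
        g, xi, ll = forward_backward_batch(padded, logT_rep, log_pi, np.tile(layout.lengths, idx.size))
        g = g.reshape(idx.size, layout.n_chromosomes, Lmax, K)
        ga = g[:, layout.chrom_index, layout.pos_in_chain]  # (c, n_amp, K)
        gamma_amp[idx] = ga
        ll_cell = ll.reshape(idx.size, layout.n_chromosomes).sum(axis=1)
        loglik[idx] = ll_cell
        full_ll = np.array(loglik)  # frozen cells keep their last value
        hist.append(full_ll)
        n_iter[idx] = it + 1

        # ---- M-step ----
        wd = ga * depth_obs[idx][:, :, None]
        num = (wd * d0[idx][:, :, None]).sum(axis=1)
        den = wd.sum(axis=1)
        if w > 0:
            num = num + w * mu_prior[None, :]
            den = den + w
        mu_new = np.where(den > 1e-12, num / np.maximum(den, 1e-300), mu[idx])

        resid2 = (d0[idx][:, :, None] - mu_new[:, None, :]) ** 2
        sd2_new = (wd * resid2).sum(axis=(1, 2)) / np.maximum(n_d[idx], 1)
        sd2_new = np.maximum(sd2_new, config.sigma_d2_floor)
        sd2_new = np.where(n_d[idx] > 0, sd2_new, sd2[idx])

        if gv_resid is not None and maf.shape[1]:
            gvar = ga[:, layout.variant_amp, :]  # (c, n_var, K)
            ssb = (gvar * gv_resid[idx]).sum(axis=(1, 2))
            sb_new = np.sqrt(ssb / np.maximum(n_b[idx], 1))
            sb_new = np.maximum(sb_new, config.sigma_b_floor)
            sb_new = np.where(n_b[idx] > 0, sb_new, sb[idx])
            # the sigma_b update is an approximate M-step (residuals about the
            # prior-weighted state mean, no truncation correction), so it can
            # lower the EM objective; accept it only when it improves its own
            # Q-term sum_{i,k} gamma_i(k) log P(b_i | k, sigma_b) — a
            # generalized-EM safeguard that restores monotone likelihood ascent
            changed = np.abs(sb_new - sb[idx]) > 1e-12
            if np.any(changed):
                baf_cand = _baf_logprobs(
                    b0[idx], maf_obs[idx], sb_new, layout, tables, n_amp
                )
                q_new = (ga * baf_cand).sum(axis=(1, 2))
                q_old = (ga * baf_cur).sum(axis=(1, 2))
                sb_new = np.where(q_new >= q_old, sb_new, sb[idx])
        else:
            sb_new = sb[idx]

        if n_trans > 0:
            xi = xi.reshape(idx.size, layout.n_chromosomes, max(Lmax - 1, 0), K, K)
            off = xi.sum(axis=(3, 4)) - np.trace(xi, axis1=3, axis2=4)
            off = (off * trans_mask[None, :, :]).sum(axis=(1, 2))
            eps_new = np.clip(off / n_trans, 1e-8, 1.0 - 1e-8)
        else:
            eps_new = eps[idx]

        change = np.max(np.abs(mu_new - mu[idx]), axis=1)
        change = np.maximum(change, np.abs(sd2_new - sd2[idx]))
        change = np.maximum(change, np.abs(sb_new - sb[idx]))
        change = np.maximum(change, np.abs(eps_new - eps[idx]))

        mu[idx] = mu_new
        sd2[idx] = sd2_new
        sb[idx] = sb_new
        eps[idx] = eps_new
        done = change < config.tol
        active[idx[done]] = False

    # final E-step under the fitted parameters (posteriors + likelihood)
    emit = _emission_logprobs(d0, depth_obs, b0, maf_obs, mu, sd2, sb, layout, tables)
    padded, Lmax = _pad_chains(emit, layout)
    with np.errstate(divide="ignore"):
        logT = np.log(np.stack([transition_matrix(e, K) for e in eps]))
    g, _, ll = forward_backward_batch(
        padded, np.repeat(logT, layout.n_chromosomes, axis=0), log_pi, lengths_all
    )
    g = g.reshape(C, layout.n_chromosomes, Lmax, K)
    gamma_amp = g[:, layout.chrom_index, layout.pos_in_chain]
    loglik = ll.reshape(C, layout.n_chromosomes).sum(axis=1)
    hist.append(np.array(loglik))
    return _FitResult(mu, sd2, sb, eps, loglik, n_iter, gamma_amp, hist)


def baum_welch(
    cell: CellObservations,
    params0: HmmParams,
    max_iter: int = 50,
    tol: float = 1e-5,
    config: CallerConfig | None = None,
):
    """Fit the HMM to one cell by Baum-Welch EM.

    Returns ``(fitted HmmParams, PosteriorSet, log-likelihood history)``.
    The PosteriorSet carries per-amplicon state posteriors (chains
    concatenated in layout order) under the fitted parameters; the history has
    one entry per E-step and is non-decreasing.
    """
    cfg = replace(config or CallerConfig(), max_iter=max_iter, tol=tol)
    cfg.n_states = params0.n_states
    fit = _fit_batch(cell.depth[None, :], cell.maf[None, :], cell.layout, params0, cfg)
    fitted = HmmParams(
        fit.mu[0],
        float(fit.sigma_d2[0]),
        float(fit.sigma_b[0]),
        float(fit.epsilon[0]),
        params0.het_rates,
        params0.n_states,
        params0.reg_weight_scale,
    )
    hist = [float(h[0]) for h in fit.loglik_history]
    post = PosteriorSet(fit.gamma[0], np.zeros((0, params0.n_states, params0.n_states)), hist[-1])
    return fitted, post, hist


def viterbi_paths(cell: CellObservations, params: HmmParams) -> np.ndarray:
    """Per-amplicon Viterbi copy-number states (1..K) for one cell."""
    layout = cell.layout
    K = params.n_states
    tables = _GenotypeTables(params.het_rates, K)
    depth_obs = np.isfinite(cell.depth)[None, :]
    maf_obs = np.isfinite(cell.maf)[None, :]
    emit = _emission_logprobs(
        np.nan_to_num(cell.depth)[None, :],
        depth_obs,
        np.nan_to_num(cell.maf)[None, :],
        maf_obs,
        params.mu[None, :],
        np.array([params.sigma_d2]),
        np.array([params.sigma_b]),
        layout,
        tables,
    )
    padded, Lmax = _pad_chains(emit, layout)
    with np.errstate(divide="ignore"):
        logT = np.log(transition_matrix(params.epsilon, K))
    paths = viterbi_batch(padded, logT, np.full(K, -np.log(K)), layout.lengths)
    paths = paths.reshape(1, layout.n_chromosomes, Lmax)
    return paths[0, layout.chrom_index, layout.pos_in_chain] + 1


def aggregate_segments(path: np.ndarray, layout: ChainLayout) -> np.ndarray:
    """Modal copy number per chromosome from a per-amplicon state path.

    Ties are broken toward the state nearest diploid, then the lower state
    (conservative: prefers not calling an alteration).
    """
    path = np.asarray(path, dtype=int)
    calls = np.zeros(layout.n_chromosomes, dtype=int)
    for ci in range(layout.n_chromosomes):
        states = path[layout.chrom_index == ci]
        vals, counts = np.unique(states, return_counts=True)
        best = vals[counts == counts.max()]
        calls[ci] = min(best, key=lambda k: (abs(k - 2), k))
    return calls


# ---------------------------------------------------------------------------
# reference learning and the end-to-end caller
# ---------------------------------------------------------------------------


@dataclass
class ReferenceModel:
    """Everything learned from reference cells plus prepared observations."""

    layout: ChainLayout
    beta: np.ndarray              # (n_amp,) per-amplicon baselines
    params0: HmmParams            # shared EM starting point
    depth: np.ndarray             # (n_cells, n_amp) baseline-normalized depth
    maf: np.ndarray               # (n_cells, n_var) folded MAF
    cell_ids: list[str]


def _fold_maf(baf_values: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.minimum(baf_values, 1.0 - baf_values)


def learn_reference(
    counts: CountMatrix,
    baf: BafTable,
    panel: AmpliconPanel,
    spec: ReferenceSpec,
    config: CallerConfig | None = None,
) -> ReferenceModel:
    """Normalize counts and learn baselines and noise parameters from reference cells.

    Learned quantities: per-amplicon baselines ``beta_i``; depth variance
    ``sigma_d^2`` (variance of reference d_norm about CN_ref/2); MAF standard
    deviation ``sigma_b`` (spread of reference MAFs about the nearest
    genotype mean of the reference copy number); per-amplicon heterozygosity
    ``h_i`` (fraction of reference MAF observations above the het threshold).
    """
    cfg = config or CallerConfig()
    if not spec.reference_cells:
        raise ValueError("reference cell set is empty")
    res = norm_mod.mb_normalize(
        counts, fraction=cfg.good_barcode_fraction, min_amplicon_median=cfg.min_amplicon_median
    )
    keep_ids = [a for a in counts.amplicon_ids if a not in set(res.low_median_amplicons)]
    beta_full = norm_mod.reference_baselines(res.normalized, panel, spec)
    beta_by_amp = dict(zip(res.normalized.amplicon_ids, beta_full))
    keep_ids = [a for a in keep_ids if np.isfinite(beta_by_amp[a])]
    layout = ChainLayout.from_panel(panel, keep_amplicons=keep_ids)

    norm_frame = res.normalized.to_frame()
    y = norm_frame.loc[layout.amplicon_ids].to_numpy()
    beta = np.array([beta_by_amp[a] for a in layout.amplicon_ids])
    depth = (y / beta[:, None]).T  # (cells, amplicons)
    # depth far beyond the largest modeled state carries no copy-number
    # gradient and destabilizes the Gaussian channel (heavy-tailed amplicons);
    # treat it as missing
    with np.errstate(invalid="ignore"):
        depth[depth > cfg.depth_outlier_cap] = np.nan
    cell_ids = list(counts.cell_ids)

    # MAF matrix in layout variant order; panel variants missing from the BAF
    # table are treated as unobserved
    n_var = len(layout.variant_ids)
    maf = np.full((len(cell_ids), n_var), np.nan)
    if n_var and baf.n_variants:
        baf_frame = baf.to_frame()
        present = [v for v in layout.variant_ids if v in baf_frame.index]
        if present:
            sub = baf_frame.loc[present, cell_ids].to_numpy()
            folded = _fold_maf(sub)
            vpos = {v: i for i, v in enumerate(layout.variant_ids)}
            rows = np.array([vpos[v] for v in present])
            maf[:, rows] = folded.T

    ref_idx = np.array([cell_ids.index(c) for c in spec.reference_cells])
    amp_chrom = dict(zip(panel.amplicons["amplicon_id"], panel.amplicons["chrom"]))
    cn_ref = np.array([spec.cn(amp_chrom[a]) for a in layout.amplicon_ids], dtype=float)

    rd = depth[ref_idx]  # (n_ref, n_amp)
    resid = rd - (cn_ref / 2.0)[None, :]
    ok = np.isfinite(resid)
    if ok.any():
        r = resid[ok]
        # Gaussian-consistent MAD: robust to the occasional heavy-tailed amplicon
        sigma_d = 1.4826 * float(np.median(np.abs(r - np.median(r))))
        sigma_d2 = sigma_d**2 if sigma_d > 0 else float(np.mean(r**2))
    else:
        sigma_d2 = 0.25
    sigma_d2 = max(sigma_d2, cfg.sigma_d2_floor)

    K = cfg.n_states
    het = np.zeros(layout.n_amplicons)
    sigma_b = cfg.sigma_b_floor
    if n_var:
        rm = maf[ref_idx]  # (n_ref, n_var)
        obs = np.isfinite(rm)
        # per-amplicon heterozygosity: fraction of observed reference MAFs
        # above the het threshold among the amplicon's variants
        is_het = (rm > cfg.het_threshold) & obs
        het_num = np.zeros(layout.n_amplicons)
        het_den = np.zeros(layout.n_amplicons)
        np.add.at(het_num, layout.variant_amp, is_het.sum(axis=0))
        np.add.at(het_den, layout.variant_amp, obs.sum(axis=0))
        het = np.where(het_den > 0, het_num / np.maximum(het_den, 1), 0.0)
        # sigma_b: residual spread about the nearest genotype mean of the
        # reference copy number at each variant's chromosome
        var_cn = cn_ref[layout.variant_amp].astype(int)
        resids = []
        for c in np.unique(var_cn):
            mus = np.unique([expected_maf(m, int(c)) for m in range(int(c) + 1)])
            cols = var_cn == c
            vals = rm[:, cols]
            vobs = obs[:, cols]
            if not vobs.any():
                continue
            d = np.abs(vals[:, :, None] - mus[None, None, :])
            nearest = mus[np.nanargmin(np.where(np.isfinite(d), d, np.inf), axis=2)]
            resids.append((vals - nearest)[vobs])
        if resids:
            allr = np.concatenate(resids)
            if allr.size:
                sigma_b = max(float(np.sqrt(np.mean(allr**2))), cfg.sigma_b_floor)

    params0 = HmmParams(
        mu=np.arange(1, K + 1) / 2.0,
        sigma_d2=sigma_d2,
        sigma_b=sigma_b,
        epsilon=cfg.epsilon0,
        het_rates=het,
        n_states=K,
        reg_weight_scale=cfg.reg_weight_scale,
    )
    return ReferenceModel(layout, beta, params0, depth, maf, cell_ids)


def call_cells(
    counts: CountMatrix,
    baf: BafTable,
    panel: AmpliconPanel,
    spec: ReferenceSpec,
    config: CallerConfig | None = None,
) -> CallSet:
    """End-to-end joint depth+BAF HMM calling for every cell in the count matrix.

    Reference learning, then one EM fit per cell (vectorized across cells),
    Viterbi decoding per chromosome, and modal aggregation to whole-chromosome
    calls.  Returns a CallSet that also carries the per-amplicon Viterbi paths.
    """
    cfg = config or CallerConfig()
    ref = learn_reference(counts, baf, panel, spec, cfg)
    layout = ref.layout
    K = cfg.n_states
    fit = _fit_batch(ref.depth, ref.maf, layout, ref.params0, cfg)

    tables = _GenotypeTables(ref.params0.het_rates, K)
    depth_obs = np.isfinite(ref.depth)
    maf_obs = np.isfinite(ref.maf)
    emit = _emission_logprobs(
        np.nan_to_num(ref.depth), depth_obs, np.nan_to_num(ref.maf), maf_obs,
        fit.mu, fit.sigma_d2, fit.sigma_b, layout, tables,
    )
    padded, Lmax = _pad_chains(emit, layout)
    C = ref.depth.shape[0]
    with np.errstate(divide="ignore"):
        logT = np.log(np.stack([transition_matrix(e, K) for e in fit.epsilon]))
    paths = viterbi_batch(
        padded, np.repeat(logT, layout.n_chromosomes, axis=0),
        np.full(K, -np.log(K)), np.tile(layout.lengths, C),
    )
    paths = paths.reshape(C, layout.n_chromosomes, Lmax)
    amp_paths = paths[:, layout.chrom_index, layout.pos_in_chain] + 1  # states 1..K

    calls = np.zeros((C, layout.n_chromosomes), dtype=int)
    for ci in range(layout.n_chromosomes):
        cols = layout.chrom_index == ci
        seg = amp_paths[:, cols]
        for c in range(C):
            vals, cnt = np.unique(seg[c], return_counts=True)
            best = vals[cnt == cnt.max()]
            calls[c, ci] = min(best, key=lambda k: (abs(k - 2), k))
    return CallSet(ref.cell_ids, list(layout.chromosomes), calls, list(layout.amplicon_ids), amp_paths)
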