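"""Synthetic targeted-panel datasets with known copy-number ground truth.

Two study designs are generated:

* **Study 1** — six equal-size cell populations (CN 1, a diploid reference,
  a diploid population with per-cell "mixed" genotypes, CN 3, CN 4, CN 5);
  each aneuploid population carries its copy number uniformly on a random
  subset of chromosomes.  Replicates jitter the population sizes (+-10%) and
  the BAF noise (+-15%).
* **Study 2** — a diploid reference plus one altered population (gain CN 3 or
  loss CN 1) with 30% of chromosomes (7 of 22) altered; one design parameter
  is varied per condition around the baseline (BAF sd 9, 3 variants per
  amplicon, 4 amplicons per chromosome, 100 cells per group, 100%
  heterozygosity).

Read counts are Weibull draws per amplicon with shape ``k_i ~ N(2, 0.8^2) + 0.3``
(truncated at 0.3) and scale ``lambda_i`` rank-inversely related to ``k_i``
and min-max rescaled to [0.5, 2.5], scaled by ``CN/2``.  The [0.5, 2.5]
scale range places the draws on the normalized-count scale, so they are kept
continuous by default (``integer_counts=True`` rounds them, but at these
magnitudes rounding quantizes away most of the depth signal and drops many
amplicons at the near-zero-median filter).  Amplicon parameters are shared
across populations to preserve amplicon-specific capture biases.  B-allele frequencies add Gaussian noise
(sd on the percent scale) to the genotype's expected BAF and truncate to
[0, 1].  Founder diploid genotypes are heterozygous with probability
``het_rate`` and shared within a population (cell-line behavior); altered
genotypes are derived by sequentially duplicating or deleting a uniformly
chosen existing allele copy.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import AmpliconPanel, BafTable, CountMatrix, ReferenceSpec

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "STUDY2_BASELINE",
    "STUDY2_GRID",
    "rng_for",
    "make_amplicon_params",
    "make_panel",
    "simulate_counts",
    "simulate_baf",
    "build_study1",
    "build_study2",
    "write_dataset",
    "write_truth",
    "read_truth",
]

STUDY2_GRID: dict[str, list] = {
    "baf_sd": [6, 9, 12],
    "variants_per_amplicon": [0, 1, 3, 5],
    "amplicons_per_chr": [2, 4, 6],
    "cells_per_group": [50, 100, 200],
    "het_rate": [0.0, 0.25, 0.5, 0.75, 1.0],
}


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Deterministic namespaced generator: the stream depends on (seed, label) only."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


@dataclass
class SimConfig:
    """Design parameters of one simulated dataset."""

    study: int = 2
    direction: str = "gain"          # study 2: gain (CN 3) or loss (CN 1)
    n_chromosomes: int = 22
    amplicons_per_chr: int = 4
    variants_per_amplicon: int = 3
    cells_per_group: int = 100
    baf_sd: float = 9.0              # percent scale: noise sd on BAF is baf_sd / 100
    het_rate: float = 1.0
    altered_fraction: float = 7 / 22
    jitter: bool = False             # +-10% cells, +-15% BAF sd (study-1 replicates)
    integer_counts: bool = False     # counts live on the normalized scale; see module docs

    def __post_init__(self) -> None:
        if self.baf_sd < 0:
            raise ValueError("baf_sd must be >= 0")
        if not 0.0 <= self.het_rate <= 1.0:
            raise ValueError("het_rate must lie in [0, 1]")
        if not 0.0 <= self.altered_fraction <= 1.0:
            raise ValueError("altered_fraction must lie in [0, 1]")
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")


STUDY2_BASELINE = SimConfig()


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    cn: pd.DataFrame                 # cells x chromosomes, int copy numbers
    population: pd.Series            # population label per cell
    founder_minor: pd.DataFrame      # variants x populations, diploid minor-copy count
    #                                  (NaN for per-cell "mixed" genotypes)
    amplicon_shape: np.ndarray       # Weibull shape k_i
    amplicon_scale: np.ndarray       # Weibull scale lambda_i
    altered_chromosomes: dict        # population -> list of altered chromosome labels


@dataclass
class SimDataset:
    counts: CountMatrix
    baf: BafTable
    panel: AmpliconPanel
    reference: ReferenceSpec
    truth: SimTruth
    config: SimConfig


def make_amplicon_params(n_amplicons: int, rng: np.random.Generator):
    """Per-amplicon Weibull (shape, scale): k_i ~ N(2, 0.8^2) + 0.3 (floor 0.3);
    scale = 1/k_i min-max rescaled to [0.5, 2.5] (rank-inverse to the shape)."""
    if n_amplicons < 1:
        raise ValueError("need at least one amplicon")
    k = np.maximum(0.3, rng.normal(2.0, 0.8, size=n_amplicons) + 0.3)
    raw = 1.0 / k
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        lam = 0.5 + (raw - lo) / (hi - lo) * 2.0
    else:
        lam = np.full(n_amplicons, 1.5)
    return k, lam


def make_panel(n_chromosomes: int, amplicons_per_chr: int, variants_per_amplicon: int) -> AmpliconPanel:
    """Synthetic panel: chromosomes "1".."n", fixed amplicons and variants per amplicon."""
    amp_rows, var_rows = [], []
    for c in range(1, n_chromosomes + 1):
        for j in range(amplicons_per_chr):
            aid = f"chr{c}_amp{j + 1}"
            start = j * 5000 + 1
            amp_rows.append({"amplicon_id": aid, "chrom": str(c), "start": start, "end": start + 249})
            for v in range(variants_per_amplicon):
                var_rows.append(
                    {"variant_id": f"{aid}_v{v + 1}", "amplicon_id": aid, "pos": start + 10 * (v + 1)}
                )
    amp = pd.DataFrame(amp_rows)
    var = (
        pd.DataFrame(var_rows)
        if var_rows
        else pd.DataFrame(columns=["variant_id", "amplicon_id", "pos"])
    )
    return AmpliconPanel(amp, var)


def simulate_counts(
    truth_cn: pd.DataFrame,
    panel: AmpliconPanel,
    shape: np.ndarray,
    scale: np.ndarray,
    rng: np.random.Generator,
    integer_counts: bool = True,
) -> CountMatrix:
    """Draw read counts: d ~ Weibull(k_i, lambda_i * CN / 2), optionally rounded."""
    amp = panel.amplicons
    cn_mat = truth_cn[amp["chrom"].tolist()].to_numpy().T  # (n_amp, n_cells)
    scales = scale[:, None] * cn_mat / 2.0
    draws = scales * rng.weibull(shape[:, None], size=cn_mat.shape)
    if integer_counts:
        draws = np.rint(draws)
    return CountMatrix(amp["amplicon_id"].tolist(), list(truth_cn.index), np.maximum(draws, 0.0))


def _founder_diploid(n: int, het_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Minor (B) copy counts of founder diploid genotypes: 1 w.p. het_rate, else 0 or 2."""
    out = np.where(rng.random(n) < het_rate, 1, 0)
    hom_b = (out == 0) & (rng.random(n) < 0.5)
    out = out + np.where(hom_b, 2, 0)
    return out


def _derive_genotype(n_b: int, cn: int, rng: np.random.Generator) -> tuple[int, int]:
    """(nA, nB) at copy number cn, derived from a diploid genotype with n_b B copies
    by sequentially duplicating (gain) or deleting (loss) uniformly chosen copies."""
    a, b = 2 - int(n_b), int(n_b)
    while a + b < cn:
        if rng.random() < b / (a + b):
            b += 1
        else:
            a += 1
    while a + b > cn:
        if rng.random() < b / (a + b):
            b -= 1
        else:
            a -= 1
    return a, b


def simulate_baf(
    truth: SimTruth,
    panel: AmpliconPanel,
    config: SimConfig,
    rng: np.random.Generator,
    mixed_population: str | None = None,
) -> BafTable:
    """Observed BAF per variant and cell: expected BAF (B copies / CN) plus
    Gaussian noise of sd ``baf_sd / 100``, truncated to [0, 1].

    Genotypes come from the population founders in ``truth`` (per-cell draws
    for the mixed population); the derived genotype on altered chromosomes is
    shared within each population (cell-line behavior).
    """
    variants = panel.variants
    if len(variants) == 0:
        return BafTable([], list(truth.cn.index), np.zeros((0, len(truth.cn.index))))
    amp_chrom = dict(zip(panel.amplicons["amplicon_id"], panel.amplicons["chrom"]))
    var_chrom = variants["amplicon_id"].map(amp_chrom).to_numpy()
    var_ids = variants["variant_id"].tolist()
    n_var = len(var_ids)
    cells = list(truth.cn.index)
    exp_baf = np.zeros((n_var, len(cells)))

    for pop in truth.population.unique():
        cols = np.flatnonzero((truth.population == pop).to_numpy())
        pop_cells = truth.cn.iloc[cols]
        if mixed_population is not None and pop == mixed_population:
            # heterogeneous genotypes: independent founder draw per cell
            for ci in cols:
                nb = _founder_diploid(n_var, config.het_rate, rng)
                exp_baf[:, ci] = nb / 2.0
            continue
        founder = truth.founder_minor[pop].to_numpy()
        pop_cn = pop_cells.iloc[0]  # uniform within population by design
        eb = np.empty(n_var)
        for v in range(n_var):
            cn = int(pop_cn[var_chrom[v]])
            if cn == 2:
                eb[v] = founder[v] / 2.0
            else:
                _, b = _derive_genotype(int(founder[v]), cn, rng)
                eb[v] = b / cn
        exp_baf[:, cols] = eb[:, None]

    noise = rng.normal(0.0, config.baf_sd / 100.0, size=exp_baf.shape)
    obs = np.clip(exp_baf + noise, 0.0, 1.0)
    return BafTable(var_ids, cells, obs)


def _build(config: SimConfig, populations, seed: int, mixed_population=None) -> SimDataset:
    """Shared dataset assembly: populations is a list of
    (label, copy_number, n_cells, n_altered_chromosomes)."""
    rng = rng_for(seed, f"study{config.study}")
    panel = make_panel(config.n_chromosomes, config.amplicons_per_chr, config.variants_per_amplicon)
    n_amp = len(panel.amplicons)
    shape, scale = make_amplicon_params(n_amp, rng)
    chroms = [str(c) for c in range(1, config.n_chromosomes + 1)]

    cell_ids, pop_labels, cn_rows = [], [], []
    altered: dict[str, list[str]] = {}
    for label, cn, n_cells, n_alt in populations:
        sel = sorted(rng.choice(config.n_chromosomes, size=n_alt, replace=False)) if n_alt else []
        alt_set = {chroms[i] for i in sel}
        altered[label] = sorted(alt_set, key=int)
        row = np.array([cn if c in alt_set else 2 for c in chroms])
        for j in range(n_cells):
            cell_ids.append(f"{label}_c{j + 1:04d}")
            pop_labels.append(label)
            cn_rows.append(row)
    cn = pd.DataFrame(np.array(cn_rows, dtype=int), index=cell_ids, columns=chroms)
    population = pd.Series(pop_labels, index=cell_ids, name="population")

    n_var = len(panel.variants)
    founder = {}
    for label, *_ in populations:
        if mixed_population is not None and label == mixed_population:
            founder[label] = np.full(n_var, np.nan)
        else:
            founder[label] = _founder_diploid(n_var, config.het_rate, rng).astype(float)
    founder_minor = pd.DataFrame(founder, index=panel.variants["variant_id"].tolist())

    truth = SimTruth(cn, population, founder_minor, shape, scale, altered)
    counts = simulate_counts(cn, panel, shape, scale, rng, config.integer_counts)
    baf = simulate_baf(truth, panel, config, rng, mixed_population=mixed_population)
    ref_label = next(label for label, k, *_ in populations if k == 2)
    reference = ReferenceSpec([c for c, p in zip(cell_ids, pop_labels) if p == ref_label], {})
    return SimDataset(counts, baf, panel, reference, truth, config)


def build_study1(seed: int, config: SimConfig | None = None) -> SimDataset:
    """Six-population balanced design (CN 1..5 plus a mixed-genotype diploid group).

    With ``config.jitter`` (the replicate default) population sizes are scaled
    by Uniform(0.9, 1.1) and the BAF sd by Uniform(0.85, 1.15), drawn per
    replicate.  Aneuploid populations each alter an independent random subset
    of ``round(altered_fraction * 22)`` chromosomes.
    """
    cfg = replace(
        config
        or SimConfig(study=1, cells_per_group=80, jitter=True),
        study=1,
    )
    jrng = rng_for(seed, "study1-jitter")
    baf_sd = cfg.baf_sd
    base_cells = cfg.cells_per_group
    if cfg.jitter:
        baf_sd = baf_sd * jrng.uniform(0.85, 1.15)
        sizes = [int(np.rint(base_cells * jrng.uniform(0.9, 1.1))) for _ in range(6)]
    else:
        sizes = [base_cells] * 6
    n_alt = int(np.rint(cfg.altered_fraction * cfg.n_chromosomes))
    pops = [
        ("cn1", 1, sizes[0], n_alt),
        ("ref", 2, sizes[1], 0),
        ("mixed", 2, sizes[2], 0),
        ("cn3", 3, sizes[3], n_alt),
        ("cn4", 4, sizes[4], n_alt),
        ("cn5", 5, sizes[5], n_alt),
    ]
    return _build(replace(cfg, baf_sd=baf_sd), pops, seed, mixed_population="mixed")


def build_study2(
    direction: str = "gain",
    varied_param: str | None = None,
    value=None,
    seed: int = 0,
    config: SimConfig | None = None,
) -> SimDataset:
    """Two-population design: diploid reference vs one altered population.

    ``varied_param``/``value`` override one baseline parameter (one of
    ``STUDY2_GRID``'s keys); the altered population carries CN 3 (gain) or
    CN 1 (loss) on ``round(altered_fraction * 22)`` chromosomes.
    """
    cfg = replace(config or STUDY2_BASELINE, study=2, direction=direction)
    if varied_param is not None:
        if varied_param not in STUDY2_GRID:
            raise ValueError(f"unknown study-2 parameter {varied_param!r}")
        kwargs = {varied_param: type(getattr(cfg, varied_param))(value)}
        cfg = replace(cfg, **kwargs)
    cn = 3 if cfg.direction == "gain" else 1
    n_alt = int(np.rint(cfg.altered_fraction * cfg.n_chromosomes))
    pops = [
        ("ref", 2, cfg.cells_per_group, 0),
        ("alt", cn, cfg.cells_per_group, n_alt),
    ]
    return _build(cfg, pops, seed)


# ---------------------------------------------------------------------------
# on-disk form
# ---------------------------------------------------------------------------


def write_truth(truth: SimTruth, path) -> None:
    df = truth.cn.copy()
    df.insert(0, "population", truth.population)
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t")


def read_truth(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read truth.tsv back as (cells x chromosomes CN frame, population labels)."""
    df = pd.read_csv(path, sep="\t", index_col="cell_id", dtype={"cell_id": str})
    pop = df["population"]
    cn = df.drop(columns="population").astype(int)
    cn.columns = [str(c) for c in cn.columns]
    return cn, pop


def write_dataset(ds: SimDataset, outdir) -> None:
    """Write counts.tsv, baf.tsv, panel.tsv, variants.tsv, reference.json, truth.tsv."""
    from pathlib import Path

    from . import io as io_mod

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io_mod.write_count_matrix(ds.counts, out / "counts.tsv")
    io_mod.write_baf_table(ds.baf, out / "baf.tsv")
    io_mod.write_panel(ds.panel, out / "panel.tsv", out / "variants.tsv")
    io_mod.write_reference_spec(ds.reference, out / "reference.json")
    write_truth(ds.truth, out / "truth.tsv")
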