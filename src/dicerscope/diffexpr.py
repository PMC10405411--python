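"""Gene-level counting and a simplified negative-binomial Wald test.

The test follows the standard RNA-seq recipe: median-of-ratios library
normalisation, a per-gene method-of-moments NB dispersion (floored near
zero), a log2 fold change of normalized condition means with a 0.5
pseudo-count, and a Wald statistic whose standard error comes from the
NB variance mu + alpha*mu^2 of each condition mean. P-values are
Benjamini–Hochberg adjusted across genes. No dispersion shrinkage,
Cook's filtering or independent filtering is applied; in the small-
dispersion (Poisson) limit the p-values agree with the exact
conditional-binomial two-sample Poisson test.

Significance uses the joint rule padj < 0.05 AND baseMean > 50 AND
|log2FC| > 0.585 (fold change > 1.5).

Also provides the delta-delta-Ct (2^-ddCt) relative-expression
computation used to validate knockdown by qPCR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .align import SmallReadAlignment, five_prime_position
from .synthetic.genome import GeneModel

PADJ_CUTOFF = 0.05
BASEMEAN_CUTOFF = 50.0
LOG2FC_CUTOFF = 0.585  # |FC| > 1.5
DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DEResult:
    gene: str
    baseMean: float
    log2FC: float
    p: float
    padj: float
    significant: bool


def count_genes(
    alignments_per_read: dict[str, list[SmallReadAlignment]],
    genes: list[GeneModel],
) -> pd.Series:
    """Strand-aware gene counts from RNA-seq alignments of one sample.

    A read counts for the gene whose interval contains its 5' end on
    the matching strand. Ambiguous reads — multi-mapped, or with a 5'
    end inside zero or several candidate genes — are discarded, so
    counts are plain integers.
    """
    counts = pd.Series(0, index=[g.id for g in genes], dtype=int)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for placements in alignments_per_read.values():
        if len(placements) != 1:
            continue
        a = placements[0]
        p5 = five_prime_position(a)
        hits = [
            g
            for g in by_chrom.get(a.reference, [])
            if g.strand == a.strand and g.start <= p5 < g.end
        ]
        if len(hits) == 1:
            counts[hits[0].id] += 1
    return counts


def normalize_median_of_ratios(matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Median-of-ratios size factors and normalized baseMean per gene.

    Size factor of a sample is the median, over genes with nonzero
    counts in every sample, of that sample's count divided by the
    gene's geometric mean. A single-sample matrix gets factor 1.
    """
    if (matrix.values < 0).any():
        raise ValueError("counts must be non-negative")
    if matrix.shape[1] == 1:
        sf = pd.Series(1.0, index=matrix.columns)
        return sf, matrix.iloc[:, 0].astype(float)
    positive = (matrix > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with nonzero counts in all samples")
    log_counts = np.log(matrix.loc[positive].astype(float))
    log_gm = log_counts.mean(axis=1)
    sf = np.exp((log_counts.sub(log_gm, axis=0)).median(axis=0))
    base_mean = matrix.div(sf, axis=1).mean(axis=1)
    return sf, base_mean


def nb_wald_test(
    matrix: pd.DataFrame,
    conditions: list[str],
    reference: str | None = None,
) -> list[DEResult]:
    """Per-gene NB Wald test between two conditions.

    ``conditions`` labels the columns of ``matrix``; ``reference`` names
    the baseline condition (default: first label encountered). Requires
    two conditions with at least 2 replicates each; a sample with an
    all-zero library is an error.
    """
    conditions = list(conditions)
    if len(conditions) != matrix.shape[1]:
        raise ValueError("one condition label per sample required")
    if (matrix.sum(axis=0) == 0).any():
        raise ValueError("a sample has an all-zero library")
    levels = list(dict.fromkeys(conditions))
    if len(levels) != 2:
        raise ValueError("exactly two conditions required")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"unknown reference condition {reference!r}")
    other = next(l for l in levels if l != reference)
    cond = np.array(conditions)
    ref_cols = matrix.columns[cond == reference]
    trt_cols = matrix.columns[cond == other]
    if len(ref_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")

    sf, base_mean = normalize_median_of_ratios(matrix)
    norm = matrix.div(sf, axis=1).astype(float)

    # per-gene method-of-moments dispersion; with few replicates the
    # per-gene estimate is noisy and chance-underdispersed genes would
    # collapse to the Poisson floor with wildly overconfident z-scores,
    # so each gene is additionally floored at the genome-wide median
    # moment dispersion (the max-of-gene-and-pooled rule)
    raw_alpha = {}
    n_ref, n_trt = len(ref_cols), len(trt_cols)
    stats_by_gene = {}
    for gene in matrix.index:
        x_ref = norm.loc[gene, ref_cols].to_numpy()
        x_trt = norm.loc[gene, trt_cols].to_numpy()
        m_ref, m_trt = x_ref.mean(), x_trt.mean()
        mu = base_mean[gene]
        ss = ((x_ref - m_ref) ** 2).sum() + ((x_trt - m_trt) ** 2).sum()
        var_w = ss / (n_ref + n_trt - 2)
        raw_alpha[gene] = (var_w - mu) / mu**2 if mu > 0 else 0.0
        stats_by_gene[gene] = (m_ref, m_trt, mu)
    alpha_prior = max(float(np.median(list(raw_alpha.values()))), 0.0)

    results = []
    for gene in matrix.index:
        m_ref, m_trt, mu = stats_by_gene[gene]
        alpha = max(raw_alpha[gene], alpha_prior, DISPERSION_FLOOR)
        log2fc = float(np.log2((m_trt + PSEUDOCOUNT) / (m_ref + PSEUDOCOUNT)))
        v_trt = (m_trt + alpha * m_trt**2) / n_trt
        v_ref = (m_ref + alpha * m_ref**2) / n_ref
        ln2 = np.log(2.0)
        se2 = v_trt / ((m_trt + PSEUDOCOUNT) ** 2 * ln2**2) + v_ref / (
            (m_ref + PSEUDOCOUNT) ** 2 * ln2**2
        )
        if se2 <= 0:
            p = 1.0
        else:
            z = log2fc / np.sqrt(se2)
            p = float(2.0 * stats.norm.sf(abs(z)))
        results.append((gene, float(mu), log2fc, min(p, 1.0)))

    pvals = np.array([r[3] for r in results])
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    out = []
    for (gene, mu, log2fc, p), q in zip(results, padj):
        sig = bool(q < PADJ_CUTOFF and mu > BASEMEAN_CUTOFF and abs(log2fc) > LOG2FC_CUTOFF)
        out.append(DEResult(gene, mu, log2fc, p, float(q), sig))
    return out


def poisson_limit_grid() -> list[tuple[int, int]]:
    """A 50-gene (control, treated) count grid for Poisson-limit checks.

    Replicates within a condition are constant at these values, so the
    method-of-moments dispersion sits at its floor and the NB Wald test
    reduces to its Poisson limit. The grid is ratio-symmetric (26 null
    genes plus 12 mirrored up/down pairs), which pins the
    median-of-ratios size factors at exactly 1 — the regime in which
    the exact two-sample Poisson (conditional-binomial, p0 = 1/2) test
    is the matching null. Group totals of 1,500–2,200 keep the normal
    approximation within |dp| <= 0.02 of the exact test.
    """
    grid = [(300 + 20 * i, 300 + 20 * i) for i in range(26)]
    for d in (6, 12, 20, 30, 45, 60, 80, 100, 130, 160, 200, 240):
        grid.append((500, 500 + d))
        grid.append((500 + d, 500))
    return grid


def filter_significant(results: list[DEResult]) -> list[DEResult]:
    """Subset meeting padj<0.05, baseMean>50 and |log2FC|>0.585."""
    return [
        r
        for r in results
        if r.padj < PADJ_CUTOFF and r.baseMean > BASEMEAN_CUTOFF and abs(r.log2FC) > LOG2FC_CUTOFF
    ]


def results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene, r.baseMean, r.log2FC, r.p, r.padj, r.significant) for r in results],
        columns=["gene", "baseMean", "log2FC", "p", "padj", "significant"],
    )


@dataclass(frozen=True)
class DdctResult:
    """Relative expression by the delta-delta-Ct method."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float
    ddct: float
    relative_expression: float


def compute_ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> DdctResult:
    """ddCt = (Ct_tgt,treated - Ct_ref,treated) - (Ct_tgt,ctrl - Ct_ref,ctrl);
    relative expression = 2^-ddCt."""
    cts = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return DdctResult(*cts, ddct, float(2.0 ** (-ddct)))
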