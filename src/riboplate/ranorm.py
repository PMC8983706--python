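"""Normalization and ribosome-association (RA) computation.

RA for gene g in well w is the log-scale ratio of normalized ribo-library
counts over normalized total-library counts; on a log2 transform this is
simply their difference. lfcRA subtracts, per gene, the mean RA over
vehicle-control wells. Spike-in / ncRNA depletion reports quantify the
specificity of the ribosome IP: RNA not bound by ribosomes (ERCC spike-ins,
most ncRNA) should show systematically lower RA than coding transcripts.

Normalization is median-of-ratios: the size factor of a well is the median,
over genes with all-positive counts, of that well's count divided by the
gene's geometric mean across wells. The variance-stabilizing transform is
log2(count / size_factor + pseudocount) — a fully specified log-shift
stand-in for parametric VSTs, matching log-ratio semantics in the
moderate-count regime where RA is interpretable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .plateio import GeneAnno, PairedCounts, PlateMeta

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# rank tests with exact small-sample nulls
# ---------------------------------------------------------------------------

def paired_wilcoxon(
    x: np.ndarray, y: np.ndarray, alternative: str = "less"
) -> tuple[float, float, int]:
    """One-sample signed-rank test on paired differences x - y.

    Zero differences are dropped. The exact null is used for n <= 25 when
    |differences| are tie-free; with ties and n <= 12 the null is computed
    by enumeration over the 2^n sign assignments using midranks; otherwise
    the normal approximation with tie correction applies.

    Returns (W statistic, p-value, n pairs used).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return np.nan, 1.0, 0
    absd = np.abs(d)
    has_ties = len(np.unique(absd)) < n
    if n <= 25 and not has_ties:
        res = scipy.stats.wilcoxon(d, alternative=alternative, method="exact")
        return float(res.statistic), float(res.pvalue), n
    if n <= 12:
        ranks = scipy.stats.rankdata(absd)
        w_obs = float(ranks[d > 0].sum())
        sums = np.array(
            [ranks[list(signs)].sum() for signs in _subsets(n)], dtype=float
        )
        if alternative == "less":
            p = np.mean(sums <= w_obs)
        elif alternative == "greater":
            p = np.mean(sums >= w_obs)
        else:
            p = min(1.0, 2 * min(np.mean(sums <= w_obs), np.mean(sums >= w_obs)))
        return w_obs, float(p), n
    res = scipy.stats.wilcoxon(d, alternative=alternative, method="approx", correction=True)
    return float(res.statistic), float(res.pvalue), n


def _subsets(n: int):
    idx = list(range(n))
    for r in range(n + 1):
        yield from itertools.combinations(idx, r)


def mann_whitney(
    x: np.ndarray, y: np.ndarray, alternative: str = "less"
) -> tuple[float, float]:
    """Two-sample Mann-Whitney U; exact null for small tie-free samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    small = x.size + y.size <= 25
    tie_free = len(np.unique(pooled)) == pooled.size
    method = "exact" if (small and tie_free) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# size factors and transforms
# ---------------------------------------------------------------------------

def size_factors(counts: np.ndarray, gene_mask: np.ndarray | None = None) -> np.ndarray:
    """Median-of-ratios size factors for one library type.

    ``counts`` is genes x wells; ``gene_mask`` selects the reference genes
    (typically excluding spike-ins and blacklisted genes). Only genes with
    all-positive counts across wells enter the median. Factors are returned
    unscaled (no re-centering).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise NormalizationError("counts must be a genes x wells matrix")
    sub = counts if gene_mask is None else counts[np.asarray(gene_mask, dtype=bool)]
    allpos = np.all(sub > 0, axis=1)
    if not allpos.any():
        raise NormalizationError(
            "no gene has positive counts in every well; "
            "median-of-ratios size factors are undefined for this matrix"
        )
    ref = sub[allpos]
    log_geomean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    s = np.exp(np.median(ratios, axis=0))
    return s


def vst(
    counts: np.ndarray, size_factors_: np.ndarray, pseudocount: float = 1.0
) -> np.ndarray:
    """Log2 shift transform of normalized counts: log2(count/s + pseudocount)."""
    if pseudocount <= 0:
        raise NormalizationError("pseudocount must be positive")
    s = np.asarray(size_factors_, dtype=float)
    if np.any(s <= 0):
        raise NormalizationError("size factors must be positive")
    return np.log2(np.asarray(counts, dtype=float) / s[None, :] + pseudocount)


def ribosome_association(vst_ribo: np.ndarray, vst_total: np.ndarray) -> np.ndarray:
    """RA = transformed ribo minus transformed total, per gene and well."""
    vst_ribo = np.asarray(vst_ribo)
    vst_total = np.asarray(vst_total)
    if vst_ribo.shape != vst_total.shape:
        raise NormalizationError(
            f"shape mismatch: ribo {vst_ribo.shape} vs total {vst_total.shape}"
        )
    return vst_ribo - vst_total


def lfc_ra(
    ra: np.ndarray, wells: list[str], meta: PlateMeta, control: str = "DMSO"
) -> np.ndarray:
    """Per-well RA minus the per-gene mean RA over control wells.

    Returned for every well (control wells included, so their per-gene mean
    lfcRA is 0 by construction); ``ra`` is genes x wells in ``wells`` order.
    """
    control_wells = [w for w in wells if meta.condition_of(w) == control]
    if len(control_wells) < 2:
        raise NormalizationError(
            f"need >= 2 control ({control!r}) wells; found {len(control_wells)}"
        )
    idx = [wells.index(w) for w in control_wells]
    baseline = np.asarray(ra)[:, idx].mean(axis=1, keepdims=True)
    return np.asarray(ra) - baseline


# ---------------------------------------------------------------------------
# IP-specificity QC
# ---------------------------------------------------------------------------

@dataclass
class DepletionReport:
    """Per-well spike-in vs gene-background depletion after ribosome IP.

    For each spike-in-bearing well: the log2 ratio of summed normalized
    ribo counts over summed normalized total counts, computed separately
    over spike-ins and over genes; ``difference`` = spike - gene. The
    one-tailed paired Wilcoxon tests whether spike-in components are lower.
    """

    per_well: pd.DataFrame  # index well; spike_dep, gene_dep, difference
    mean_spike_ra: float  # mean over wells of the spike-in ratio (linear scale)
    mean_gene_ra: float
    statistic: float
    pvalue: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return self.per_well.reset_index()


def spikein_depletion(
    pc: PairedCounts,
    sf_ribo: np.ndarray,
    sf_total: np.ndarray,
    anno: GeneAnno,
    meta: PlateMeta,
) -> DepletionReport:
    """Spike-in depletion QC over spike-in-bearing wells.

    Counts are normalized per library (count / size factor) before summing,
    then per-well log2 ratios are formed for the spike-in and gene
    components and compared with a one-tailed paired Wilcoxon signed-rank
    test (alternative: spike-in component < gene component).
    """
    spike_mask = anno.biotype_mask(pc.genes, "spikein")
    if not spike_mask.any():
        raise NormalizationError("no spike-in genes in annotation")
    gene_mask = ~spike_mask

    norm_ribo = pc.ribo / np.asarray(sf_ribo)[None, :]
    norm_total = pc.total / np.asarray(sf_total)[None, :]

    bearing = [w for w in pc.wells if bool(meta.table.loc[w, "spikein"])]
    if not bearing:
        raise NormalizationError("no spike-in-bearing wells in plate metadata")

    rows = []
    for w in bearing:
        j = pc.wells.index(w)
        s_r = norm_ribo[spike_mask, j].sum()
        s_t = norm_total[spike_mask, j].sum()
        g_r = norm_ribo[gene_mask, j].sum()
        g_t = norm_total[gene_mask, j].sum()
        if s_r == 0 and s_t == 0:
            logger.warning("well %s has zero spike-in counts in both libraries; excluded", w)
            continue
        if s_t == 0 or g_t == 0:
            logger.warning("well %s has a zero denominator; excluded", w)
            continue
        spike_dep = np.log2(s_r / s_t) if s_r > 0 else -np.inf
        gene_dep = np.log2(g_r / g_t)
        rows.append((w, spike_dep, gene_dep, spike_dep - gene_dep, s_r / s_t, g_r / g_t))
    if not rows:
        raise NormalizationError("no usable spike-in-bearing wells")
    per_well = pd.DataFrame(
        rows,
        columns=["well", "spike_dep", "gene_dep", "difference", "spike_ra", "gene_ra"],
    ).set_index("well")

    finite = per_well.replace([np.inf, -np.inf], np.nan).dropna(subset=["spike_dep"])
    stat, p, n = paired_wilcoxon(
        finite["spike_dep"].to_numpy(), finite["gene_dep"].to_numpy(), alternative="less"
    )
    return DepletionReport(
        per_well=per_well[["spike_dep", "gene_dep", "difference"]],
        mean_spike_ra=float(per_well["spike_ra"].mean()),
        mean_gene_ra=float(per_well["gene_ra"].mean()),
        statistic=stat,
        pvalue=p,
        n=n,
    )


@dataclass
class AbundanceStratification:
    """Per-gene mean RA vs mean abundance, stratified by biotype."""

    table: pd.DataFrame  # gene, mean_abundance, mean_ra, biotype
    mw_statistic: float  # ncRNA-vs-coding one-tailed Mann-Whitney U
    mw_pvalue: float


def ra_vs_abundance(
    ra: np.ndarray, vst_total: np.ndarray, genes: list[str], anno: GeneAnno
) -> AbundanceStratification:
    """Summarize the RA / abundance relationship per gene and biotype.

    Includes a one-tailed two-sample Mann-Whitney U test of whether ncRNA
    mean RA is lower than coding mean RA (the expected signature of the IP
    depleting non-ribosome-bound RNA).
    """
    table = pd.DataFrame(
        {
            "gene": genes,
            "mean_abundance": np.asarray(vst_total).mean(axis=1),
            "mean_ra": np.asarray(ra).mean(axis=1),
            "biotype": anno.table["biotype"].reindex(genes).to_numpy(),
        }
    )
    strata = {}
    for bt, sub in table.groupby("biotype"):
        if len(sub) < 2:
            logger.warning("biotype %s has < 2 genes; stratum skipped", bt)
            continue
        strata[bt] = sub
    stat, p = np.nan, np.nan
    if "ncRNA" in strata and "coding" in strata:
        stat, p = mann_whitney(
            strata["ncRNA"]["mean_ra"].to_numpy(),
            strata["coding"]["mean_ra"].to_numpy(),
            alternative="less",
        )
    table = table[table["biotype"].isin(strata)]
    return AbundanceStratification(table=table, mw_statistic=stat, mw_pvalue=p)
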