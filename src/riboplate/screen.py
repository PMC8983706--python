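"""Screen-level analytics over per-condition differential-RA results.

Covers: PCA of RA / lfcRA matrices restricted to significant genes with
robust outlier flagging; construction of per-drug up/down target sets
(optionally mutually exclusive across drugs); one-tailed Mann-Whitney shift
tests of gene-set lfc distributions; classic (unweighted) preranked gene-set
enrichment with gene-label permutation nulls; attenuation analysis of drug
combinations against their constituent drugs; and a kinase-target network
whose intersection regions are tested for TOP-gene enrichment with
one-sided Fisher's exact tests and BH adjustment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA

from .diffra import bh_adjust
from .ranorm import mann_whitney

logger = logging.getLogger(__name__)


class ScreenError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PCA and outliers
# ---------------------------------------------------------------------------

def pca_ra(
    matrix: pd.DataFrame,
    gene_subset: Sequence[str] | None = None,
    n_components: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Column-centered PCA of an RA or lfcRA matrix (genes x wells).

    The domain is restricted to ``gene_subset`` (e.g. genes with significant
    differential RA in any condition). Returns (scores wells x PCs,
    loadings genes x PCs, explained-variance fractions).
    """
    if matrix.shape[1] < 2:
        raise ScreenError("need >= 2 samples for PCA")
    if gene_subset is not None:
        keep = [g for g in gene_subset if g in matrix.index]
        if not keep:
            raise ScreenError("gene subset is disjoint from the matrix")
        matrix = matrix.loc[keep]
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    n_components = min(n_components, min(X.shape) - 0 if min(X.shape) > 1 else 1)
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        pd.DataFrame(pca.components_.T, index=matrix.index, columns=cols),
        pca.explained_variance_ratio_,
    )


def detect_outliers(scores: pd.DataFrame, k: float = 4.0) -> pd.DataFrame:
    """Flag wells with robust |z| > k on either of the first two components.

    The robust z of a well on a component is |x - median| / (1.4826 * MAD).
    Components with zero MAD are skipped (logged). Returns a table of
    distances with an ``outlier`` flag.
    """
    if len(scores) < 4:
        raise ScreenError("need >= 4 samples for outlier detection")
    use = [c for c in scores.columns[:2]]
    z = pd.DataFrame(index=scores.index)
    for c in use:
        x = scores[c].to_numpy(dtype=float)
        mad = np.median(np.abs(x - np.median(x)))
        if mad == 0:
            logger.warning("component %s has zero MAD; skipped", c)
            continue
        z[f"z_{c}"] = np.abs(x - np.median(x)) / (1.4826 * mad)
    if z.shape[1] == 0:
        z["z_none"] = 0.0
    z["outlier"] = (z > k).any(axis=1)
    return z


# ---------------------------------------------------------------------------
# target sets
# ---------------------------------------------------------------------------

@dataclass
class TargetSets:
    """Per-condition significant up/down gene sets (optionally exclusive)."""

    up: dict[str, set[str]]
    down: dict[str, set[str]]
    q: float
    exclusive: bool

    def set_for(self, condition: str, direction: str) -> set[str]:
        return {"up": self.up, "down": self.down}[direction].get(condition, set())


def build_target_sets(
    results: Mapping[str, pd.DataFrame], q: float = 0.05, exclusive: bool = False
) -> TargetSets:
    """Threshold differential-RA tables into up/down target sets per condition.

    up = {fdr < q, lfcRA > 0}; down = {fdr < q, lfcRA < 0}. With
    ``exclusive``, any gene appearing in the same-direction set of more than
    one condition is removed from all of them, so no two conditions share an
    up- or downregulated gene.
    """
    up: dict[str, set[str]] = {}
    down: dict[str, set[str]] = {}
    for cond, tab in results.items():
        sig = tab[(tab["fdr"] < q) & tab["lfcRA"].notna()]
        up[cond] = set(sig.index[sig["lfcRA"] > 0])
        down[cond] = set(sig.index[sig["lfcRA"] < 0])
    if exclusive:
        for sets in (up, down):
            counts: dict[str, int] = {}
            for members in sets.values():
                for g in members:
                    counts[g] = counts.get(g, 0) + 1
            shared = {g for g, c in counts.items() if c > 1}
            for cond in sets:
                sets[cond] = sets[cond] - shared
    return TargetSets(up=up, down=down, q=q, exclusive=exclusive)


def shift_test(
    values_a: np.ndarray, values_b: np.ndarray, alternative: str = "less"
) -> tuple[float, float]:
    """One-tailed two-sample Mann-Whitney U comparing two lfc distributions.

    ``alternative='less'`` tests whether group A values are shifted below
    group B (e.g. TOP genes vs background under mTOR-axis inhibition).
    """
    return mann_whitney(np.asarray(values_a), np.asarray(values_b), alternative)


# ---------------------------------------------------------------------------
# preranked enrichment (classic / unweighted)
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    pvalue: float
    fwer: float  # Bonferroni over the reported family; filled by the caller
    direction: str
    n_hits: int


def _classic_es(is_hit: np.ndarray) -> float:
    """Signed maximum deviation of the classic running sum over a ranking."""
    n = is_hit.size
    nh = int(is_hit.sum())
    if nh == 0 or nh == n:
        return 1.0 if nh else 0.0
    step = np.where(is_hit, 1.0 / nh, -1.0 / (n - nh))
    run = np.cumsum(step)
    i_max, i_min = np.argmax(run), np.argmin(run)
    return float(run[i_max]) if run[i_max] >= -run[i_min] else float(run[i_min])


def _null_es(n: int, nh: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """ES values under random placement of nh hit labels among n ranks."""
    out = np.empty(n_perm)
    pos_w = 1.0 / nh
    neg_w = 1.0 / (n - nh)
    for b in range(n_perm):
        pos = np.sort(rng.choice(n, size=nh, replace=False))
        i = np.arange(1, nh + 1)
        # running sum just after hit i and just before hit i
        dev_hi = i * pos_w - (pos + 1 - i) * neg_w
        dev_lo = (i - 1) * pos_w - (pos - (i - 1)) * neg_w
        hi = dev_hi.max()
        lo = dev_lo.min()
        out[b] = hi if hi >= -lo else lo
    return out


def gsea_preranked(
    scores: pd.Series,
    gene_set: Sequence[str],
    set_name: str = "set",
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Classic (unweighted) preranked enrichment of one gene set.

    Genes are ranked by score descending with lexicographic gene-ID
    tie-break. The running sum gains 1/Nh at set members and loses
    1/(N - Nh) elsewhere; ES is its signed maximum deviation. The null is
    gene-label permutation; NES divides ES by the mean |null ES| of
    matching sign and the one-sided nominal p is (b + 1) / (n_perm + 1)
    over same-sign, more-extreme null values.
    """
    scores = scores.sort_index()
    order = np.lexsort((scores.index.to_numpy(), -scores.to_numpy()))
    ranked_genes = scores.index.to_numpy()[order]
    members = set(gene_set) & set(ranked_genes)
    if not members:
        logger.warning("gene set %r has no overlap with the ranked universe", set_name)
        return EnrichmentResult(set_name, np.nan, np.nan, np.nan, np.nan, "none", 0)
    is_hit = np.isin(ranked_genes, list(members))
    es = _classic_es(is_hit)
    n, nh = is_hit.size, int(is_hit.sum())
    if nh == n:
        logger.warning("gene set %r covers the entire universe", set_name)
        return EnrichmentResult(set_name, es, np.nan, np.nan, np.nan, "degenerate", nh)
    rng = np.random.default_rng(seed)
    null = _null_es(n, nh, n_perm, rng)
    sign = 1.0 if es >= 0 else -1.0
    same = null * sign > 0
    mean_same = np.abs(null[same]).mean() if same.any() else np.nan
    nes = es / mean_same if mean_same and np.isfinite(mean_same) else np.nan
    b = int(np.sum(same & (np.abs(null) >= abs(es))))
    p = (b + 1) / (n_perm + 1)
    return EnrichmentResult(
        set_name=set_name,
        es=es,
        nes=float(nes),
        pvalue=float(p),
        fwer=np.nan,
        direction="up" if es >= 0 else "down",
        n_hits=nh,
    )


def gsea_preranked_many(
    scores: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run classic preranked enrichment over a family of sets.

    The family-wise value is Bonferroni: nominal p times the number of
    reported sets, capped at 1.
    """
    rows = []
    for i, (name, members) in enumerate(gene_sets.items()):
        r = gsea_preranked(scores, members, set_name=name, n_perm=n_perm, seed=seed + i)
        rows.append(r)
    df = pd.DataFrame(
        [
            (r.set_name, r.es, r.nes, r.pvalue, r.direction, r.n_hits)
            for r in rows
        ],
        columns=["set", "es", "nes", "pvalue", "direction", "n_hits"],
    )
    m = df["pvalue"].notna().sum()
    df["fwer"] = np.minimum(df["pvalue"] * m, 1.0)
    return df


# ---------------------------------------------------------------------------
# attenuation of drug combinations
# ---------------------------------------------------------------------------

def attenuation_analysis(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    res_combo: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Classify combination effects against the strongest single-drug effect.

    For every gene significant (fdr < q) in drug A or drug B: x is the
    lfcRA of whichever constituent has the larger |lfcRA| and y the
    combination lfcRA. Classes: ``attenuated`` (same sign, |y| < |x|; y = 0
    included), ``enhanced`` (same sign, |y| >= |x|), ``reversed``
    (opposite sign). Returns one row per gene with x, y, the direction of
    x, and the class.
    """
    if res_combo is None or len(res_combo) == 0:
        raise ScreenError("combination results are required")
    common = res_a.index.intersection(res_b.index).intersection(res_combo.index)
    a = res_a.loc[common]
    b = res_b.loc[common]
    c = res_combo.loc[common]
    sig = ((a["fdr"] < q) & a["lfcRA"].notna()) | (
        (b["fdr"] < q) & b["lfcRA"].notna()
    )
    genes = common[sig & c["lfcRA"].notna()]
    la = a.loc[genes, "lfcRA"].to_numpy()
    lb = b.loc[genes, "lfcRA"].to_numpy()
    x = np.where(np.abs(la) >= np.abs(lb), la, lb)
    y = c.loc[genes, "lfcRA"].to_numpy()
    same_sign = np.sign(y) == np.sign(x)
    zero_y = y == 0
    cls = np.where(
        zero_y,
        "attenuated",
        np.where(
            same_sign,
            np.where(np.abs(y) < np.abs(x), "attenuated", "enhanced"),
            "reversed",
        ),
    )
    return pd.DataFrame(
        {
            "x_individual": x,
            "y_combination": y,
            "direction": np.where(x > 0, "up", "down"),
            "class": cls,
        },
        index=pd.Index(genes, name="gene"),
    )


def attenuation_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Fraction of genes in each class, split by direction of the x effect."""
    rows = []
    for direction, sub in table.groupby("direction"):
        n = len(sub)
        for cls in ("attenuated", "enhanced", "reversed"):
            rows.append((direction, cls, (sub["class"] == cls).sum() / n, n))
    return pd.DataFrame(rows, columns=["direction", "class", "fraction", "n"])


# ---------------------------------------------------------------------------
# kinase-target enrichment network
# ---------------------------------------------------------------------------

def fisher_enrichment(
    region: set[str], top_set: set[str], universe: set[str], two_sided: bool = False
) -> float:
    """One-sided (enrichment) Fisher's exact p for region x TOP membership."""
    a = len(region & top_set)
    b_ = len(region - top_set)
    c_ = len((top_set & universe) - region)
    d = len(universe - region - top_set)
    table = [[a, b_], [c_, d]]
    alt = "two-sided" if two_sided else "greater"
    return float(scipy.stats.fisher_exact(table, alternative=alt)[1])


def enrichment_network(
    kinase_targets: Mapping[str, set[str]],
    top_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    two_sided: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TOP-gene enrichment over the intersection regions of kinase target sets.

    Every nonempty region of the Venn partition of the kinase target sets
    (e.g. mTOR-only, mTOR & PI3K, mTOR & PI3K & MNK1) is tested for
    enrichment of each TOP set with a one-sided Fisher's exact test over
    ``universe``; p-values are BH-adjusted across all (region, set) tests.

    Returns (region table, edge list). The edge list (kinase, gene) is
    importable by standard graph tools. Set members missing from the
    universe are dropped with a warning.
    """
    if len(kinase_targets) < 2:
        raise ScreenError("need >= 2 kinase target sets")
    uni = set(universe)
    kt = {}
    for k, members in kinase_targets.items():
        missing = set(members) - uni
        if missing:
            logger.warning("%d targets of %s missing from universe; dropped", len(missing), k)
        kt[k] = set(members) & uni
    tops = {}
    for name, members in top_sets.items():
        missing = set(members) - uni
        if missing:
            logger.warning("%d members of %s missing from universe; dropped", len(missing), name)
        tops[name] = set(members) & uni

    kinases = sorted(kt)
    rows = []
    region_defs = []
    for r in range(1, len(kinases) + 1):
        for combo in itertools.combinations(kinases, r):
            inside = set.intersection(*[kt[k] for k in combo])
            outside = set.union(
                *[kt[k] for k in kinases if k not in combo], set()
            ) if len(combo) < len(kinases) else set()
            region = inside - outside
            if not region:
                continue
            region_defs.append(("&".join(combo), region))
    for name, region in region_defs:
        for top_name, top in tops.items():
            p = fisher_enrichment(region, top, uni, two_sided=two_sided)
            rows.append(
                (
                    name,
                    top_name,
                    len(region),
                    len(region & top),
                    p,
                )
            )
    table = pd.DataFrame(
        rows, columns=["region", "top_set", "region_size", "n_top", "pvalue"]
    )
    table["fdr"] = bh_adjust(table["pvalue"].to_numpy())

    edges = pd.DataFrame(
        [(k, g) for k in kinases for g in sorted(kt[k])], columns=["kinase", "gene"]
    )
    return table, edges
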