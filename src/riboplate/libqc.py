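"""Library saturation, complexity and IP-efficiency QC.

Saturation curves subsample each library (multivariate hypergeometric
thinning of the gene-assigned read multiset) and count genes detected at
each depth. Library "complexity" after gene-level counting is proxied by
genes detected at a fixed common subsampled depth (default: the largest
depth feasible for >= 90% of libraries), with the raw library-size ratio
available as an alternative proxy. The per-well ribo:total complexity
ratio, corrected for the fraction of lysate routed to each arm, averaged
over wells and divided by an assumed polysome-associated fraction of
polyadenylated mRNA (f_p, default 0.80 from the literature) estimates the
efficiency of the ribosome IP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plateio import PairedCounts, PlateMeta

logger = logging.getLogger(__name__)


class QCError(ValueError):
    pass


def subsample_counts(
    counts: np.ndarray, target_depth: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Thin a count vector to an exact target depth without replacement.

    Draws ``target_depth`` reads from the multiset of gene-assigned reads
    (multivariate hypergeometric), so the result sums to the target exactly.
    """
    counts = np.asarray(counts, dtype=np.int64)
    size = int(counts.sum())
    if target_depth > size:
        raise QCError(f"target depth {target_depth} exceeds library size {size}")
    if target_depth == size:
        return counts.copy()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return rng.multivariate_hypergeometric(counts, int(target_depth), method="marginals")


def saturation_curve(
    pc: PairedCounts,
    depths: list[int],
    seeds: list[int] | None = None,
) -> pd.DataFrame:
    """Genes detected per library at each subsampled depth.

    Returns a long-format table (library_type, well, depth, seed,
    genes_detected). Libraries smaller than a depth are omitted at that
    depth. Depths must be sorted ascending.
    """
    if list(depths) != sorted(depths):
        raise QCError("depths must be sorted ascending")
    seeds = seeds or [0]
    rows = []
    for lib, mat in (("ribo", pc.ribo), ("total", pc.total)):
        sizes = mat.sum(axis=0)
        for j, well in enumerate(pc.wells):
            for d in depths:
                if d > sizes[j]:
                    continue
                for s in seeds:
                    thinned = subsample_counts(mat[:, j], d, seed=s)
                    rows.append((lib, well, d, s, int((thinned > 0).sum())))
    return pd.DataFrame(
        rows, columns=["library_type", "well", "depth", "seed", "genes_detected"]
    )


@dataclass
class ComplexitySummary:
    """Per-well complexity ratios and the plate mean."""

    per_well: pd.Series  # rho_w indexed by well
    mean_rho: float
    proxy: str
    common_depth: int | None


def _common_depth(sizes: np.ndarray, feasible_fraction: float = 0.9) -> int:
    """Largest depth at which >= feasible_fraction of libraries are usable."""
    return int(np.quantile(sizes, 1 - feasible_fraction, method="lower"))


def complexity_ratio(
    pc: PairedCounts,
    meta: PlateMeta,
    proxy: str = "genes_at_depth",
    common_depth: int | None = None,
    seed: int = 0,
) -> ComplexitySummary:
    """Ribo:total complexity ratio per well, corrected for input fractions.

    rho_w = (complexity of ribo / complexity of total) *
            (input_fraction_total / input_fraction_ribo)

    With ``proxy='genes_at_depth'`` complexity is genes detected after
    thinning both libraries of a well to a common depth (libraries smaller
    than that depth are skipped, logged). With ``proxy='library_size'`` it
    is the summed gene counts (no subsampling).
    """
    if proxy not in ("genes_at_depth", "library_size"):
        raise QCError(f"unknown complexity proxy {proxy!r}")
    sizes_r = pc.ribo.sum(axis=0)
    sizes_t = pc.total.sum(axis=0)
    depth = None
    if proxy == "genes_at_depth":
        depth = (
            int(common_depth)
            if common_depth is not None
            else _common_depth(np.concatenate([sizes_r, sizes_t]))
        )
    rng = np.random.default_rng(seed)
    rho = {}
    for j, well in enumerate(pc.wells):
        fr = float(meta.table.loc[well, "input_fraction_ribo"])
        ft = float(meta.table.loc[well, "input_fraction_total"])
        if proxy == "library_size":
            if sizes_t[j] == 0:
                logger.warning("well %s has an empty total library; skipped", well)
                continue
            c_r, c_t = float(sizes_r[j]), float(sizes_t[j])
        else:
            if sizes_r[j] < depth or sizes_t[j] < depth:
                logger.warning(
                    "well %s smaller than common depth %d; skipped", well, depth
                )
                continue
            c_r = float((subsample_counts(pc.ribo[:, j], depth, rng) > 0).sum())
            c_t = float((subsample_counts(pc.total[:, j], depth, rng) > 0).sum())
        if c_t == 0:
            logger.warning("well %s has zero total complexity; skipped", well)
            continue
        rho[well] = (c_r / c_t) * (ft / fr)
    if not rho:
        raise QCError("no wells with both libraries usable for complexity")
    per_well = pd.Series(rho, name="rho")
    return ComplexitySummary(
        per_well=per_well,
        mean_rho=float(per_well.mean()),
        proxy=proxy,
        common_depth=depth,
    )


def ip_efficiency(mean_rho: float, polysome_fraction: float = 0.80) -> float:
    """IP efficiency eta = mean complexity ratio / polysome-associated fraction.

    ``polysome_fraction`` (f_p) is the assumed fraction of polyadenylated
    mRNA that is polysome-associated; 0.80 is the literature default.
    Returned as a fraction (multiply by 100 for percent).
    """
    if not (0 < polysome_fraction <= 1):
        raise QCError("polysome fraction must lie in (0, 1]")
    if mean_rho < 0:
        raise QCError("complexity ratio must be nonnegative")
    return mean_rho / polysome_fraction


def qc_summary(
    pc: PairedCounts,
    meta: PlateMeta,
    depths: list[int] | None = None,
    seeds: list[int] | None = None,
    polysome_fraction: float = 0.80,
    seed: int = 0,
) -> dict:
    """Convenience bundle: sizes, detection, saturation, complexity, efficiency."""
    sizes = pd.DataFrame(
        {
            "ribo_size": pc.ribo.sum(axis=0),
            "total_size": pc.total.sum(axis=0),
            "ribo_genes": (pc.ribo > 0).sum(axis=0),
            "total_genes": (pc.total > 0).sum(axis=0),
        },
        index=pd.Index(pc.wells, name="well"),
    )
    if depths is None:
        top = int(max(sizes["ribo_size"].max(), sizes["total_size"].max()))
        depths = sorted({max(1, top // 2**k) for k in range(6)})
    curves = saturation_curve(pc, depths, seeds=seeds)
    complexity = complexity_ratio(pc, meta, seed=seed)
    eta = ip_efficiency(complexity.mean_rho, polysome_fraction)
    return {
        "per_well": sizes,
        "saturation": curves,
        "complexity": complexity,
        "ip_efficiency": eta,
    }
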