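"""Synthetic paired-plate generator.

Emulates the statistical structure of a plate-based ribosome-association
screen: a gene-by-well total-RNA count matrix and a paired ribosome-IP
("ribo") matrix that share per-gene abundance and per-well depth, with
gene-wise baseline ribosome association (RA), low capture of spike-ins and
ncRNA by the IP, per-condition multiplicative RA effects concentrated on
designated target sets (TOP genes by default), and attenuated effects under
pairwise drug combinations.

Counts are negative-binomial with the mean/dispersion parameterization
``var = mu + alpha * mu**2`` and a dispersion trend ``alpha(mu) = a0 + a1/mu``.

Random number consumption order (fixed so seeds are portable): gene
abundances, RA jitter, extra-set membership, per-condition affected-target
choice (conditions in sorted order), total depths, ribo depths, total
counts, ribo counts.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .plateio import (
    GeneAnno,
    PairedCounts,
    PlateMeta,
    write_counts_mtx,
    write_counts_tsv,
    write_gene_sets,
)

logger = logging.getLogger(__name__)

CONTROL = "DMSO"


class SimConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class EffectSpec:
    """One condition's RA perturbation: which set, how strong, what fraction."""

    target_set: str
    log2fc: float
    fraction: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated paired-plate experiment.

    Defaults follow the screen design the generator emulates: a vehicle
    control ("DMSO") plus drug arms of 8 wells each, ~2000 coding genes,
    total-library depth of 5e5 reads per well, and a ribo library sequenced
    at 0.17x the total depth (the observed complexity ratio of IP to total
    libraries). Capture fractions default to 0.9 for coding genes and far
    lower for ncRNA (0.3) and spike-ins (0.2), reproducing the depletion of
    non-ribosome-bound RNA by the IP.
    """

    n_coding: int = 2000
    n_ncrna: int = 200
    n_spikein: int = 92
    n_wells_per_condition: int = 8
    conditions: tuple[str, ...] = (CONTROL,)
    depth_mean: float = 5e5
    depth_cv: float = 0.2
    abundance_logmean: float = 0.0
    abundance_logsd: float = 1.0
    baseline_ra_coding: float = 0.9
    baseline_ra_ncrna: float = 0.3
    baseline_ra_spikein: float = 0.2
    ra_jitter_sd: float = 0.25
    ip_efficiency: float = 1.0
    ribo_depth_factor: float = 0.17
    equal_depth: bool = False
    dispersion_a0: float = 0.01
    dispersion_a1: float = 2.0
    effect_map: Mapping[str, EffectSpec] = field(default_factory=dict)
    attenuation_factor: float = 0.5
    spikein_half_plate: bool = True
    spikein_fraction: float = 0.02
    n_top_canonical: int = 97
    n_top_candidate: int = 182
    extra_sets: Mapping[str, int] = field(default_factory=dict)
    n_blacklist: int = 0
    seed: int = 0

    def validate(self) -> None:
        fractions = {
            "baseline_ra_coding": self.baseline_ra_coding,
            "baseline_ra_ncrna": self.baseline_ra_ncrna,
            "baseline_ra_spikein": self.baseline_ra_spikein,
            "ip_efficiency": self.ip_efficiency,
        }
        for name, val in fractions.items():
            if not (0 < val <= 1):
                raise SimConfigError(f"{name} must lie in (0, 1]; got {val}")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise SimConfigError("dispersion parameters must be nonnegative")
        if CONTROL not in self.conditions:
            raise SimConfigError(f"conditions must include the control {CONTROL!r}")
        if self.depth_mean <= 0 or self.ribo_depth_factor <= 0:
            raise SimConfigError("depths must be positive")
        if not (0 <= self.attenuation_factor <= 1):
            raise SimConfigError("attenuation_factor must lie in [0, 1]")
        known_sets = set(self._set_sizes())
        for cond, spec in self.effect_map.items():
            if cond == CONTROL:
                raise SimConfigError("control condition cannot carry an effect")
            if spec.target_set not in known_sets:
                raise SimConfigError(
                    f"effect_map for {cond!r} names unknown gene set {spec.target_set!r}"
                )
            if not (0 < spec.fraction <= 1):
                raise SimConfigError("effect fraction must lie in (0, 1]")
        n_top = self.n_top_canonical + self.n_top_candidate
        if n_top + sum(self.extra_sets.values()) > self.n_coding:
            raise SimConfigError("gene sets exceed the number of coding genes")

    def _set_sizes(self) -> dict[str, int]:
        sizes = {
            "TOP_canonical": self.n_top_canonical,
            "TOP_candidate": self.n_top_candidate,
        }
        sizes.update({k: int(v) for k, v in self.extra_sets.items()})
        return sizes


@dataclass
class SimTruth:
    """Generator ground truth for parameter-recovery tests.

    ``effect_gc`` holds per-gene, per-condition log2 RA multipliers (0 for
    unaffected genes and for the control). Under a combination "A+B" the
    truth obeys ``effect = attenuation_factor * (effect_A + effect_B)``
    exactly.
    """

    abundance: pd.Series  # relative abundance per gene (sums to 1)
    ra: pd.Series  # baseline RA fraction per gene
    effect: pd.DataFrame  # genes x conditions, log2 RA multipliers
    depth: pd.DataFrame  # wells x [total, ribo] expected depths
    gene_sets: dict[str, list[str]]
    dispersion: pd.Series | None = None  # per-gene NB alpha used for the draws

    def targets(self, condition: str) -> list[str]:
        col = self.effect[condition]
        return list(col.index[col != 0.0])


def _split_combination(label: str) -> list[str]:
    return [p.strip() for p in label.split("+")] if "+" in label else [label]


def simulate_experiment(
    config: SimConfig,
) -> tuple[PairedCounts, PlateMeta, GeneAnno, SimTruth]:
    """Draw one paired plate (ribo + total counts) plus metadata and truth.

    The total-library mean for gene g in well w is ``depth_w * p_g`` with
    ``p_g`` the normalized relative abundance; the ribo mean is
    ``ribo_depth_w * p_g * ra_g * 2**effect_g(condition_w) * ip_efficiency``
    (renormalized to the ribo depth only when ``equal_depth`` is set).
    Spike-ins appear only in flagged wells (alternating plate columns when
    ``spikein_half_plate``). Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = (
        [f"GENE{i:05d}" for i in range(config.n_coding)]
        + [f"NCRNA{i:04d}" for i in range(config.n_ncrna)]
        + [f"ERCC-{i:05d}" for i in range(config.n_spikein)]
    )
    n_genes = len(genes)
    biotype = np.array(
        ["coding"] * config.n_coding
        + ["ncRNA"] * config.n_ncrna
        + ["spikein"] * config.n_spikein
    )
    is_spike = biotype == "spikein"

    # 1) abundances: log-normal for transcripts, fixed half-log ladder for
    #    spike-ins scaled to a small fraction of the transcript pool
    abund = np.empty(n_genes)
    n_tx = config.n_coding + config.n_ncrna
    abund[:n_tx] = rng.lognormal(
        mean=config.abundance_logmean, sigma=config.abundance_logsd, size=n_tx
    )
    if config.n_spikein:
        ladder = 10.0 ** (0.5 * (np.arange(config.n_spikein) % 8))
        ladder = ladder / ladder.sum()
        abund[n_tx:] = (
            ladder * config.spikein_fraction / (1 - config.spikein_fraction)
        ) * abund[:n_tx].sum()
    p_gene = abund / abund.sum()

    # 2) baseline RA per gene: biotype capture fraction with log2 jitter, capped at 1
    base_ra = np.where(
        biotype == "coding",
        config.baseline_ra_coding,
        np.where(biotype == "ncRNA", config.baseline_ra_ncrna, config.baseline_ra_spikein),
    ).astype(float)
    jitter = rng.normal(0.0, config.ra_jitter_sd, size=n_genes)
    ra = np.minimum(base_ra * 2.0**jitter, 1.0)

    # 3) gene sets over coding genes: canonical TOP, candidate TOP, extras
    coding_ids = genes[: config.n_coding]
    sets: dict[str, list[str]] = {
        "TOP_canonical": coding_ids[: config.n_top_canonical],
        "TOP_candidate": coding_ids[
            config.n_top_canonical : config.n_top_canonical + config.n_top_candidate
        ],
    }
    pool_start = config.n_top_canonical + config.n_top_candidate
    pool = np.array(coding_ids[pool_start:])
    for name, size in config.extra_sets.items():
        chosen = rng.choice(pool, size=int(size), replace=False)
        sets[name] = sorted(chosen)
        pool = pool[~np.isin(pool, chosen)]

    # 4) per-condition effects; combinations derive from their constituents
    gene_index = pd.Index(genes, name="gene")
    effect = pd.DataFrame(0.0, index=gene_index, columns=list(config.conditions))
    single_effects: dict[str, pd.Series] = {}
    for cond in sorted(config.effect_map):
        spec = config.effect_map[cond]
        members = np.array(sets[spec.target_set])
        n_hit = int(np.ceil(spec.fraction * len(members)))
        hit = rng.choice(members, size=n_hit, replace=False)
        col = pd.Series(0.0, index=gene_index)
        col.loc[hit] = spec.log2fc
        single_effects[cond] = col
    for cond in config.conditions:
        if cond == CONTROL:
            continue
        parts = _split_combination(cond)
        if len(parts) == 1:
            if cond in single_effects:
                effect[cond] = single_effects[cond]
        else:
            combined = sum(
                (single_effects.get(p, pd.Series(0.0, index=gene_index)) for p in parts),
                pd.Series(0.0, index=gene_index),
            )
            effect[cond] = config.attenuation_factor * combined

    # plate layout: wells filled column-major (A01, B01, ... H01, A02, ...)
    n_wells = config.n_wells_per_condition * len(config.conditions)
    rows = "ABCDEFGHIJKLMNOP"
    n_rows = 8 if n_wells <= 96 else 16
    wells = [
        f"{rows[i % n_rows]}{i // n_rows + 1:02d}" for i in range(n_wells)
    ]
    condition_of = np.repeat(list(config.conditions), config.n_wells_per_condition)
    col_number = np.array([int(w[1:]) for w in wells])
    spike_flag = (col_number % 2 == 1) if config.spikein_half_plate else np.ones(
        n_wells, dtype=bool
    )
    if config.n_spikein == 0:
        spike_flag = np.zeros(n_wells, dtype=bool)

    # 5-6) per-well expected depths
    shape = 1.0 / config.depth_cv**2
    depth_total = rng.gamma(shape, config.depth_mean / shape, size=n_wells)
    ribo_mean = config.depth_mean * (
        1.0 if config.equal_depth else config.ribo_depth_factor
    )
    depth_ribo = rng.gamma(shape, ribo_mean / shape, size=n_wells)

    # mean structure
    eff = effect.to_numpy()  # genes x conditions
    cond_idx = {c: j for j, c in enumerate(config.conditions)}
    well_cond = np.array([cond_idx[c] for c in condition_of])
    mu_total = np.outer(p_gene, depth_total)
    ra_eff = ra[:, None] * 2.0 ** eff[:, well_cond]
    mu_ribo = p_gene[:, None] * ra_eff * config.ip_efficiency * depth_ribo[None, :]
    if config.equal_depth:
        mu_ribo = mu_ribo / mu_ribo.sum(axis=0, keepdims=True) * depth_ribo[None, :]
    # zero out spike-ins in wells without spike-in addition
    mu_total[np.ix_(is_spike, ~spike_flag)] = 0.0
    mu_ribo[np.ix_(is_spike, ~spike_flag)] = 0.0

    # 7-8) NB draws. The dispersion trend alpha(mu) = a0 + a1/mu is evaluated
    # per gene at its mean expected count over all libraries, yielding one
    # alpha per gene shared by the ribo and total draws — the structure the
    # downstream gene-wise NB model assumes.
    mean_mu = (mu_total.sum(axis=1) + mu_ribo.sum(axis=1)) / (2 * n_wells)
    alpha_g = config.dispersion_a0 + config.dispersion_a1 / np.maximum(mean_mu, 1e-12)

    def draw(mu: np.ndarray) -> np.ndarray:
        counts = np.zeros_like(mu, dtype=np.int64)
        pos = mu > 0
        m = mu[pos]
        alpha = np.broadcast_to(alpha_g[:, None], mu.shape)[pos]
        if np.all(alpha <= 1e-12):
            counts[pos] = rng.poisson(m)
        else:
            r = 1.0 / np.maximum(alpha, 1e-12)
            counts[pos] = rng.negative_binomial(r, r / (r + m))
        return counts

    total_counts = draw(mu_total)
    ribo_counts = draw(mu_ribo)

    pc = PairedCounts(genes=genes, wells=wells, ribo=ribo_counts, total=total_counts)

    meta = PlateMeta(
        pd.DataFrame(
            {
                "condition": condition_of,
                "spikein": spike_flag,
                "input_fraction_ribo": 0.67,
                "input_fraction_total": 0.33,
            },
            index=pd.Index(wells, name="well"),
        )
    )

    top_status = np.array(["none"] * n_genes, dtype=object)
    canon = set(sets["TOP_canonical"])
    cand = set(sets["TOP_candidate"])
    for i, g in enumerate(genes):
        if g in canon:
            top_status[i] = "canonical"
        elif g in cand:
            top_status[i] = "candidate"
    blacklisted = np.zeros(n_genes, dtype=bool)
    if config.n_blacklist:
        # blacklist the tail of non-TOP coding genes (poly(A)-minus stand-in)
        tail = [
            i
            for i in range(config.n_coding - 1, -1, -1)
            if top_status[i] == "none"
        ][: config.n_blacklist]
        blacklisted[tail] = True
    anno = GeneAnno(
        pd.DataFrame(
            {"biotype": biotype, "top_status": top_status, "blacklisted": blacklisted},
            index=gene_index,
        )
    )

    truth = SimTruth(
        abundance=pd.Series(p_gene, index=gene_index, name="abundance"),
        ra=pd.Series(ra, index=gene_index, name="ra"),
        effect=effect,
        depth=pd.DataFrame(
            {"total": depth_total, "ribo": depth_ribo},
            index=pd.Index(wells, name="well"),
        ),
        gene_sets=sets,
        dispersion=pd.Series(alpha_g, index=gene_index, name="alpha"),
    )
    return pc, meta, anno, truth


def expected_means(
    config: SimConfig, meta: PlateMeta, anno: GeneAnno, truth: SimTruth
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct the configured NB means (ribo, total) from ground truth."""
    p_gene = truth.abundance.to_numpy()
    ra = truth.ra.to_numpy()
    conds = [meta.condition_of(w) for w in meta.wells]
    eff = truth.effect[conds].to_numpy()
    d_total = truth.depth["total"].to_numpy()
    d_ribo = truth.depth["ribo"].to_numpy()
    mu_total = np.outer(p_gene, d_total)
    mu_ribo = p_gene[:, None] * ra[:, None] * 2.0**eff * config.ip_efficiency * d_ribo
    if config.equal_depth:
        mu_ribo = mu_ribo / mu_ribo.sum(axis=0, keepdims=True) * d_ribo[None, :]
    spike = anno.biotype_mask(truth.abundance.index.tolist(), "spikein")
    bearing = meta.table["spikein"].to_numpy(dtype=bool)
    mu_total[np.ix_(spike, ~bearing)] = 0.0
    mu_ribo[np.ix_(spike, ~bearing)] = 0.0
    return mu_ribo, mu_total


def write_fixture(
    pc: PairedCounts,
    meta: PlateMeta,
    anno: GeneAnno,
    truth: SimTruth,
    directory: Path,
) -> dict[str, str]:
    """Write a complete on-disk fixture; returns {filename: sha256} manifest.

    Emits both TSV and MatrixMarket renderings of each count matrix, the
    sample sheet, gene annotation, gene sets (GMT) and the truth table.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    ribo_df = pc.frame("ribo")
    total_df = pc.frame("total")
    write_counts_tsv(ribo_df, directory / "ribo_counts.tsv")
    write_counts_tsv(total_df, directory / "total_counts.tsv")
    write_counts_mtx(ribo_df, directory / "ribo_counts.mtx")
    write_counts_mtx(total_df, directory / "total_counts.mtx")

    sheet = meta.table.reset_index().rename(columns={"index": "well"})
    if sheet.columns[0] != "well":
        sheet = sheet.rename(columns={sheet.columns[0]: "well"})
    sheet.insert(2, "library_type", "paired")
    sheet.to_csv(directory / "sample_sheet.csv", index=False, lineterminator="\n")

    anno_out = anno.table.reset_index()
    anno_out = anno_out.rename(columns={anno_out.columns[0]: "gene"})
    anno_out.to_csv(directory / "gene_anno.tsv", sep="\t", index=False, lineterminator="\n")

    write_gene_sets(truth.gene_sets, directory / "gene_sets.gmt")

    truth_table = pd.concat([truth.abundance, truth.ra, truth.effect], axis=1)
    truth_table.index.name = "gene"
    truth_table.to_csv(directory / "truth.tsv", sep="\t", lineterminator="\n")
    truth.depth.to_csv(directory / "depths.tsv", sep="\t", lineterminator="\n")

    manifest: dict[str, str] = {}
    for f in sorted(directory.iterdir()):
        if f.is_file():
            manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (directory / "MANIFEST.txt").write_text(
        "\n".join(f"{sha}  {name}" for name, sha in manifest.items()) + "\n"
    )
    return manifest
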