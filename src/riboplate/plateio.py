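"""Readers, writers and validated containers for paired plate-based count data.

The central object is :class:`PairedCounts`: two gene-by-well integer count
matrices — one from the ribosome-immunoprecipitated ("ribo") library and one
from the total-RNA library — sharing identical gene and well orderings.
Sample-level metadata (:class:`PlateMeta`) and gene-level annotation
(:class:`GeneAnno`) ride alongside.

Supported external formats: TSV count matrices (genes as rows, wells as
columns), MatrixMarket coordinate matrices with sidecar gene/well index
files, CSV sample sheets, GMT gene-set files and one-gene-per-line lists.
Gene identity is an opaque string; no genome coordinates appear anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

BIOTYPES = ("coding", "ncRNA", "spikein")
TOP_STATUSES = ("canonical", "candidate", "none")

RESULT_COLUMNS = ["gene", "lfcRA", "stat", "pvalue", "fdr", "condition", "status"]


class PlateIOError(ValueError):
    """Raised for malformed or inconsistent plate inputs."""


@dataclass
class PairedCounts:
    """Paired ribo/total count matrices with shared gene and well orderings."""

    genes: list[str]
    wells: list[str]
    ribo: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.ribo = np.asarray(self.ribo)
        self.total = np.asarray(self.total)
        shape = (len(self.genes), len(self.wells))
        if self.ribo.shape != shape or self.total.shape != shape:
            raise PlateIOError(
                f"count matrices must both be genes x wells = {shape}; "
                f"got ribo {self.ribo.shape}, total {self.total.shape}"
            )
        for name, mat in (("ribo", self.ribo), ("total", self.total)):
            if np.any(mat < 0):
                raise PlateIOError(f"{name} matrix contains negative entries")
            if not np.allclose(mat, np.round(mat)):
                raise PlateIOError(f"{name} matrix contains non-integer entries")
        self.ribo = self.ribo.astype(np.int64)
        self.total = self.total.astype(np.int64)
        dupes = pd.Index(self.genes)[pd.Index(self.genes).duplicated()]
        if len(dupes):
            raise PlateIOError(f"duplicate gene IDs: {sorted(set(dupes))}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    def frame(self, which: str) -> pd.DataFrame:
        """Return one matrix as a DataFrame indexed by gene with well columns."""
        mat = {"ribo": self.ribo, "total": self.total}[which]
        return pd.DataFrame(mat, index=self.genes, columns=self.wells)

    def subset_genes(self, keep: np.ndarray | list[str]) -> "PairedCounts":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {g: i for i, g in enumerate(self.genes)}
            idx = np.array([pos[g] for g in keep], dtype=int)
        return PairedCounts(
            genes=[self.genes[i] for i in idx],
            wells=list(self.wells),
            ribo=self.ribo[idx],
            total=self.total[idx],
        )

    def subset_wells(self, keep: list[str]) -> "PairedCounts":
        pos = {w: i for i, w in enumerate(self.wells)}
        idx = np.array([pos[w] for w in keep], dtype=int)
        return PairedCounts(
            genes=list(self.genes),
            wells=[self.wells[i] for i in idx],
            ribo=self.ribo[:, idx],
            total=self.total[:, idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairedCounts):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.wells == other.wells
            and np.array_equal(self.ribo, other.ribo)
            and np.array_equal(self.total, other.total)
        )


@dataclass
class PlateMeta:
    """Per-well metadata: condition, spike-in flag, and lysate input fractions.

    ``input_fraction_ribo`` / ``input_fraction_total`` record which fraction of
    each well's lysate was routed to the IP and total arms; the complexity
    ratio is corrected by their quotient.
    """

    table: pd.DataFrame  # index: well; columns: condition, spikein, input fractions

    REQUIRED = ("condition", "spikein", "input_fraction_ribo", "input_fraction_total")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise PlateIOError(f"sample sheet missing columns: {missing}")
        if self.table.index.duplicated().any():
            dupes = self.table.index[self.table.index.duplicated()]
            raise PlateIOError(f"duplicate wells in sample sheet: {sorted(set(dupes))}")
        for col in ("input_fraction_ribo", "input_fraction_total"):
            frac = self.table[col].to_numpy(dtype=float)
            if np.any((frac <= 0) | (frac > 1)):
                raise PlateIOError(f"{col} must lie in (0, 1]")
        self.table = self.table.copy()
        self.table["spikein"] = self.table["spikein"].astype(bool)

    @property
    def wells(self) -> list[str]:
        return list(self.table.index)

    def condition_of(self, well: str) -> str:
        return str(self.table.loc[well, "condition"])

    def wells_for(self, condition: str) -> list[str]:
        mask = self.table["condition"] == condition
        return list(self.table.index[mask])

    def subset_wells(self, keep: list[str]) -> "PlateMeta":
        return PlateMeta(self.table.loc[keep].copy())


@dataclass
class GeneAnno:
    """Per-gene biotype, TOP status and poly(A)-minus blacklist flag."""

    table: pd.DataFrame  # index: gene; columns: biotype, top_status, blacklisted

    def __post_init__(self) -> None:
        for col in ("biotype", "top_status", "blacklisted"):
            if col not in self.table.columns:
                raise PlateIOError(f"gene annotation missing column {col!r}")
        bad_bt = set(self.table["biotype"]) - set(BIOTYPES)
        if bad_bt:
            raise PlateIOError(f"unknown biotypes: {sorted(bad_bt)}")
        bad_top = set(self.table["top_status"]) - set(TOP_STATUSES)
        if bad_top:
            raise PlateIOError(f"unknown TOP statuses: {sorted(bad_top)}")
        spike_top = (self.table["biotype"] == "spikein") & (
            self.table["top_status"] != "none"
        )
        if spike_top.any():
            raise PlateIOError("spike-in genes cannot carry TOP status")
        self.table = self.table.copy()
        self.table["blacklisted"] = self.table["blacklisted"].astype(bool)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def biotype_mask(self, genes: list[str], biotype: str) -> np.ndarray:
        bt = self.table["biotype"].reindex(genes)
        return (bt == biotype).to_numpy()

    def analysis_mask(self, genes: list[str]) -> np.ndarray:
        """True for genes that enter normalization: not spike-in, not blacklisted."""
        sub = self.table.reindex(genes)
        return ((sub["biotype"] != "spikein") & ~sub["blacklisted"].fillna(False)).to_numpy()


# ---------------------------------------------------------------------------
# count matrix I/O
# ---------------------------------------------------------------------------

def _read_counts_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _read_counts_mtx(path: Path) -> pd.DataFrame:
    genes_path = Path(str(path) + ".genes")
    wells_path = Path(str(path) + ".wells")
    for p in (genes_path, wells_path):
        if not p.exists():
            raise PlateIOError(f"MatrixMarket sidecar index file missing: {p}")
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = genes_path.read_text().splitlines()
    wells = wells_path.read_text().splitlines()
    return pd.DataFrame(np.asarray(mat), index=genes, columns=wells)


def _read_counts(path: Path, fmt: str | None) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        return _read_counts_tsv(path)
    if fmt == "mtx":
        return _read_counts_mtx(path)
    raise PlateIOError(f"unknown count format {fmt!r} (expected 'tsv' or 'mtx')")


def write_counts_tsv(df: pd.DataFrame, path: Path) -> None:
    df = df.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", lineterminator="\n")


def write_counts_mtx(df: pd.DataFrame, path: Path) -> None:
    path = Path(path)
    sparse = scipy.sparse.coo_matrix(df.to_numpy())
    scipy.io.mmwrite(path, sparse, field="integer")
    Path(str(path) + ".genes").write_text("\n".join(map(str, df.index)) + "\n")
    Path(str(path) + ".wells").write_text("\n".join(map(str, df.columns)) + "\n")


def load_sample_sheet(path: Path) -> PlateMeta:
    df = pd.read_csv(path)
    if "well" not in df.columns:
        raise PlateIOError("sample sheet must contain a 'well' column")
    df["well"] = df["well"].astype(str)
    df = df.set_index("well")
    # accept a single 'input_fraction' column as the total arm's fraction with
    # the remainder going to the ribo arm
    if "input_fraction" in df.columns and "input_fraction_total" not in df.columns:
        df["input_fraction_total"] = df["input_fraction"].astype(float)
        df["input_fraction_ribo"] = 1.0 - df["input_fraction_total"]
    return PlateMeta(df)


def load_paired_counts(
    ribo_path: Path,
    total_path: Path,
    sample_sheet_path: Path,
    fmt: str | None = None,
) -> tuple[PairedCounts, PlateMeta]:
    """Load both count matrices plus the sample sheet and reconcile orderings.

    Genes and wells are reconciled by ID: the intersection is kept in the
    ribo matrix's order and every drop is logged. A well present in the
    counts but absent from the sample sheet is an error (the converse — a
    sheet row without data, e.g. a failed well — is merely dropped).
    """
    ribo = _read_counts(Path(ribo_path), fmt)
    total = _read_counts(Path(total_path), fmt)
    meta = load_sample_sheet(Path(sample_sheet_path))

    for name, df in (("ribo", ribo), ("total", total)):
        dup = df.index[df.index.duplicated()]
        if len(dup):
            raise PlateIOError(f"duplicate gene IDs in {name} matrix: {sorted(set(dup))}")

    genes = [g for g in ribo.index if g in set(total.index)]
    dropped_genes = (set(ribo.index) | set(total.index)) - set(genes)
    if dropped_genes:
        logger.warning("dropping %d genes absent from one matrix", len(dropped_genes))

    wells = [w for w in ribo.columns if w in set(total.columns)]
    dropped_wells = (set(ribo.columns) | set(total.columns)) - set(wells)
    if dropped_wells:
        logger.warning(
            "dropping wells absent from one matrix: %s", sorted(dropped_wells)
        )

    missing_meta = [w for w in wells if w not in set(meta.table.index)]
    if missing_meta:
        raise PlateIOError(
            f"wells present in counts but absent from sample sheet: {missing_meta}"
        )

    pc = PairedCounts(
        genes=genes,
        wells=wells,
        ribo=ribo.loc[genes, wells].to_numpy(),
        total=total.loc[genes, wells].to_numpy(),
    )
    return pc, meta.subset_wells(wells)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def load_gene_sets(path: Path, fmt: str | None = None) -> dict[str, list[str]]:
    """Load gene sets from a GMT file or a plain one-gene-per-line list.

    Returns a mapping from set name to the unique member gene IDs (original
    order preserved). Unknown genes are retained; filtering against an
    analysis universe happens at use time.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gmt" if path.suffix.lower() == ".gmt" else "list"
    sets: dict[str, list[str]] = {}
    if fmt == "gmt":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise PlateIOError(
                    f"{path}:{lineno}: malformed GMT line (need name, description, genes)"
                )
            name, _desc, *members = fields
            unique = list(dict.fromkeys(m for m in members if m))
            if not unique:
                logger.warning("gene set %r at %s:%d is empty", name, path, lineno)
            sets[name] = unique
    elif fmt == "list":
        members = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        sets[path.stem] = list(dict.fromkeys(members))
    else:
        raise PlateIOError(f"unknown gene-set format {fmt!r}")
    return sets


def write_gene_sets(sets: Mapping[str, list[str]], path: Path) -> None:
    lines = [
        "\t".join([name, "riboplate"] + list(members)) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def apply_blacklist(pc: PairedCounts, anno: GeneAnno) -> PairedCounts:
    """Drop blacklisted (poly(A)-minus) genes from both matrices."""
    flags = anno.table["blacklisted"].reindex(pc.genes)
    if flags.isna().any():
        missing = [g for g, v in flags.items() if pd.isna(v)]
        raise PlateIOError(f"annotation does not cover genes: {missing[:10]}")
    keep = ~flags.to_numpy(dtype=bool)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("blacklist removed %d of %d genes", n_removed, pc.n_genes)
    if keep.sum() == 0:
        logger.warning("blacklist removed every gene; returning empty object")
    return pc.subset_genes(keep)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def write_results(tables: Mapping[str, pd.DataFrame], directory: Path) -> dict[str, str]:
    """Write tidy result tables as TSV; returns {filename: sha256} manifest."""
    import hashlib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, df in tables.items():
        fname = f"{name}.tsv"
        out = directory / fname
        df.to_csv(out, sep="\t", index=False, lineterminator="\n")
        manifest[fname] = hashlib.sha256(out.read_bytes()).hexdigest()
    return manifest
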