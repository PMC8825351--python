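"""Readers for 10x-style V(D)J contig tables and expression matrices.

Covers the two per-sample artifacts the pipeline consumes: the
``filtered_contig_annotations.csv`` table emitted by ``cellranger vdj`` (one
assembled chain per row) and the MatrixMarket expression triplet
(matrix.mtx + barcodes.tsv + features.tsv).  Also computes the per-sample
chain-reconstruction summary (fraction of cells with a CDR3-annotated alpha
chain, beta chain, and a full-length productive pair) and the VDJ/GEX
barcode match rate.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .vdj_reference import Chain

__all__ = [
    "ContigRecord",
    "CellVDJ",
    "ChainSummary",
    "DEFAULT_MITO_PREFIXES",
    "read_contig_annotations",
    "chain_summary",
    "read_mtx",
    "write_mtx",
    "match_vdj_to_gex",
]

REQUIRED_CONTIG_COLUMNS = ("barcode", "chain", "cdr3_nt", "full_length", "productive", "umis")

#: Mitochondrial feature-name prefixes; rhesus annotations name mito genes
#: inconsistently, so this is a configurable list rather than just "MT-".
DEFAULT_MITO_PREFIXES = ("MT-", "mt-", "ND1", "ND2", "ND4", "COX1", "COX2", "CYTB")


@dataclass(frozen=True)
class ContigRecord:
    barcode: str
    contig_id: str
    chain: Chain
    v_gene: str | None = None
    d_gene: str | None = None
    j_gene: str | None = None
    c_gene: str | None = None
    cdr3_nt: str | None = None
    cdr3_aa: str | None = None
    full_length: bool = False
    productive: bool = False
    umis: int = 0
    reads: int = 0

    def __post_init__(self) -> None:
        if not self.barcode:
            raise ValueError("contig with empty barcode")
        if self.umis < 0 or self.reads < 0:
            raise ValueError("negative umis/reads")


@dataclass
class CellVDJ:
    barcode: str
    contigs: list[ContigRecord] = field(default_factory=list)
    sample_id: str = ""

    def __post_init__(self) -> None:
        for c in self.contigs:
            if c.barcode != self.barcode:
                raise ValueError(
                    f"contig barcode {c.barcode} != cell barcode {self.barcode}"
                )

    def contigs_of(self, chain: Chain) -> list[ContigRecord]:
        return [c for c in self.contigs if c.chain is chain]


@dataclass(frozen=True)
class ChainSummary:
    """Per-sample chain reconstruction rates, as percentages of all cells."""

    sample_id: str
    n_cells: int
    pct_cdr3_alpha: float
    pct_cdr3_beta: float
    pct_productive_pair: float


_TRUTHY = {"true": True, "false": False, "none": False}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    key = str(value).strip().lower()
    if key in _TRUTHY:
        return _TRUTHY[key]
    raise ValueError(f"unparseable boolean {value!r}")


def _parse_seq(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s in ("", "None", "none", "NA") else s


def read_contig_annotations(path: str | Path, sample_id: str = "") -> list[CellVDJ]:
    """Read a ``filtered_contig_annotations.csv`` into per-cell records.

    Rows are grouped by barcode; boolean columns accept the True/False/None
    spellings cellranger emits, and "None" in sequence/gene columns maps to
    absent.  Missing mandatory columns raise a ``ValueError`` naming them.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"contig CSV is missing mandatory column(s): {missing}")
    cells: dict[str, CellVDJ] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        rec = row._asdict()
        try:
            chain = Chain(rec["chain"])
        except ValueError:
            chain = Chain.OTHER
        contig = ContigRecord(
            barcode=rec["barcode"],
            contig_id=rec.get("contig_id") or f"{rec['barcode']}_contig_{i + 1}",
            chain=chain,
            v_gene=_parse_seq(rec.get("v_gene")),
            d_gene=_parse_seq(rec.get("d_gene")),
            j_gene=_parse_seq(rec.get("j_gene")),
            c_gene=_parse_seq(rec.get("c_gene")),
            cdr3_nt=_parse_seq(rec.get("cdr3_nt")),
            cdr3_aa=_parse_seq(rec.get("cdr3") or rec.get("cdr3_aa")),
            full_length=_parse_bool(rec["full_length"]),
            productive=_parse_bool(rec["productive"]),
            umis=int(rec["umis"] or 0),
            reads=int(rec.get("reads") or 0),
        )
        cell = cells.get(contig.barcode)
        if cell is None:
            cells[contig.barcode] = cell = CellVDJ(contig.barcode, [], sample_id)
        cell.contigs.append(contig)
    return list(cells.values())


def pad_cells(
    cells: list[CellVDJ], all_barcodes: list[str], sample_id: str = ""
) -> list[CellVDJ]:
    """Extend a contig-derived cell list with contig-less droplets.

    Contig tables only list detected chains, so a valid cell whose chains
    all failed reconstruction has no rows; when the full droplet barcode
    list is known (e.g. from the matched GEX library or a simulation), this
    restores those cells so summary denominators count every cell.
    """
    present = {c.barcode for c in cells}
    padded = list(cells)
    for b in all_barcodes:
        if b not in present:
            padded.append(CellVDJ(b, [], sample_id))
    return padded


def chain_summary(cells: list[CellVDJ], sample_id: str | None = None) -> ChainSummary:
    """Summarize chain reconstruction for one sample.

    * alpha / beta rates count cells with at least one TRA / TRB contig
      carrying a CDR3 nucleotide annotation;
    * the productive-pair rate counts cells with a TRA and a TRB contig
      that are each both productive and full length.

    All cells — including those with only non-TRA/TRB contigs — stay in the
    denominator, mirroring "all droplets called as cells".
    """
    if not cells:
        raise ValueError("chain_summary requires at least one cell")
    n = len(cells)
    has_a = has_b = pair = 0
    for cell in cells:
        tra = cell.contigs_of(Chain.TRA)
        trb = cell.contigs_of(Chain.TRB)
        has_a += any(c.cdr3_nt for c in tra)
        has_b += any(c.cdr3_nt for c in trb)
        pair += any(c.productive and c.full_length for c in tra) and any(
            c.productive and c.full_length for c in trb
        )
    sid = sample_id if sample_id is not None else (cells[0].sample_id or "")
    return ChainSummary(
        sample_id=sid,
        n_cells=n,
        pct_cdr3_alpha=100.0 * has_a / n,
        pct_cdr3_beta=100.0 * has_b / n,
        pct_productive_pair=100.0 * pair / n,
    )


# ---------------------------------------------------------------------------
# Expression matrices


def _read_tsv_column(path: str | Path) -> list[str]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_mtx(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    mito_prefixes: tuple[str, ...] = DEFAULT_MITO_PREFIXES,
) -> ad.AnnData:
    """Load a MatrixMarket triplet as cells x genes AnnData.

    The MTX on disk is genes x cells (the cellranger convention) and is
    transposed on read.  Per-cell QC metadata (``total_counts``,
    ``n_genes``, ``pct_mito`` as a 0-1 fraction) is populated from the
    counts; mitochondrial genes are identified by name prefix.
    """
    mat = scipy.io.mmread(str(matrix_path)).tocsr().T.tocsr()
    barcodes = _read_tsv_column(barcodes_path)
    features = _read_tsv_column(features_path)
    if mat.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(barcodes)} barcodes "
            f"x {len(features)} features"
        )
    adata = ad.AnnData(
        X=mat.astype(np.float64),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(features, name="gene")),
    )
    annotate_cell_qc(adata, mito_prefixes)
    return adata


def annotate_cell_qc(
    adata: ad.AnnData, mito_prefixes: tuple[str, ...] = DEFAULT_MITO_PREFIXES
) -> None:
    """(Re)compute per-cell totals, genes detected, and mito fraction."""
    X = sp.csr_matrix(adata.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    is_mito = np.array(
        [any(g.startswith(p) for p in mito_prefixes) for g in adata.var_names]
    )
    mito_counts = (
        np.asarray(X[:, is_mito].sum(axis=1)).ravel() if is_mito.any() else np.zeros(X.shape[0])
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    adata.obs["total_counts"] = totals
    adata.obs["n_genes"] = n_genes
    adata.obs["pct_mito"] = frac
    adata.var["is_mito"] = is_mito


def write_mtx(
    adata: ad.AnnData,
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> None:
    """Write a cells x genes AnnData back to the genes x cells MTX triplet."""
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(sp.csr_matrix(adata.X).T))
    Path(barcodes_path).write_text("\n".join(adata.obs_names) + "\n")
    Path(features_path).write_text("\n".join(adata.var_names) + "\n")


def _strip_suffix(barcode: str) -> str:
    stem, sep, tail = barcode.rpartition("-")
    return stem if sep and tail.isdigit() else barcode


def match_vdj_to_gex(
    cells: list[CellVDJ],
    gex: ad.AnnData,
    normalize_suffix: bool = True,
) -> tuple[float, list[str]]:
    """Fraction of VDJ cells whose barcode also appears in the GEX matrix.

    10x aggregation appends "-<well>" GEM suffixes, so a single trailing
    "-<digits>" is stripped from both sides by default before matching.
    Returns (fraction, matched VDJ barcodes in input order).
    """
    if not cells:
        raise ValueError("no VDJ barcodes to match")
    norm = _strip_suffix if normalize_suffix else (lambda b: b)
    gex_barcodes = {norm(b) for b in gex.obs_names}
    matched = [c.barcode for c in cells if norm(c.barcode) in gex_barcodes]
    return len(matched) / len(cells), matched
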