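"""CDR3-based clonotype assignment, cross-sample tracking, and MLR tagging.

A clonotype is a set of cells sharing identical CDR3 nucleotide sequence(s)
under a chosen mode: alpha chain, beta chain, or the paired alpha+beta
combination.  Single-chain modes deliberately allow a clonotype key to be
shared across donors, which is what makes cross-donor overlap statistics a
meaningful specificity control.

MLR tagging labels tissue cells by whether their clonotype matches a set of
allo-proliferating clonotypes identified in a mixed lymphocyte reaction
(cells matching are "MLR+", assigned-but-unmatched cells "MLR-", cells
without the required chains unassigned).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tenx_io import CellVDJ, ContigRecord
from .vdj_reference import Chain

__all__ = [
    "Mode",
    "MLRStatus",
    "ClonotypeKey",
    "ClonotypeTable",
    "MLRLabel",
    "assign_clonotypes",
    "occurrence_matrix",
    "track_clonotypes",
    "tag_alloreactive",
    "alloreactive_key_set",
]


class Mode(str, enum.Enum):
    ALPHA_NT = "alpha_nt"
    BETA_NT = "beta_nt"
    PAIRED_NT = "paired_nt"


class MLRStatus(str, enum.Enum):
    MLR_PLUS = "MLR_plus"
    MLR_MINUS = "MLR_minus"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True, order=True)
class ClonotypeKey:
    mode: Mode
    alpha_cdr3_nt: str | None = None
    beta_cdr3_nt: str | None = None

    def __post_init__(self) -> None:
        need_alpha = self.mode in (Mode.ALPHA_NT, Mode.PAIRED_NT)
        need_beta = self.mode in (Mode.BETA_NT, Mode.PAIRED_NT)
        if need_alpha and not self.alpha_cdr3_nt:
            raise ValueError(f"mode {self.mode.value} requires alpha_cdr3_nt")
        if need_beta and not self.beta_cdr3_nt:
            raise ValueError(f"mode {self.mode.value} requires beta_cdr3_nt")


@dataclass
class ClonotypeTable:
    """Clonotype x sample occurrence counts plus per-cell assignments."""

    mode: Mode
    keys: list[ClonotypeKey]
    samples: list[str]
    counts: np.ndarray  # (n_keys, n_samples) nonnegative ints
    assignments: dict[str, ClonotypeKey | None] = field(default_factory=dict)
    multi_chain_cells: int = 0  # cells with >1 contig of a required chain

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.keys), len(self.samples)):
            raise ValueError("counts shape inconsistent with keys/samples")
        if (self.counts < 0).any():
            raise ValueError("negative clonotype counts")

    def to_frame(self) -> pd.DataFrame:
        idx = [_key_label(k) for k in self.keys]
        return pd.DataFrame(self.counts, index=idx, columns=self.samples)

    def sample_counts(self, sample: str) -> dict[ClonotypeKey, int]:
        j = self.samples.index(sample)
        return {k: int(c) for k, c in zip(self.keys, self.counts[:, j]) if c > 0}


@dataclass(frozen=True)
class MLRLabel:
    barcode: str
    label: MLRStatus


def _key_label(key: ClonotypeKey) -> str:
    parts = [p for p in (key.alpha_cdr3_nt, key.beta_cdr3_nt) if p]
    return "+".join(parts)


def _best_contig(contigs: list[ContigRecord]) -> ContigRecord:
    # highest UMI wins; ties go to the lexicographically smallest contig_id
    return min(contigs, key=lambda c: (-c.umis, c.contig_id))


def _cell_key(cell: CellVDJ, mode: Mode) -> tuple[ClonotypeKey | None, bool]:
    """Clonotype key for one cell, or None if a required chain is missing.

    Second element reports whether the cell had multiple candidate contigs
    for any required chain (doublet-like)."""
    multi = False
    parts: dict[str, str | None] = {"alpha_cdr3_nt": None, "beta_cdr3_nt": None}
    for chain, slot in ((Chain.TRA, "alpha_cdr3_nt"), (Chain.TRB, "beta_cdr3_nt")):
        contigs = [c for c in cell.contigs_of(chain) if c.cdr3_nt]
        if len(contigs) > 1:
            multi = True
        if contigs:
            parts[slot] = _best_contig(contigs).cdr3_nt
    need_alpha = mode in (Mode.ALPHA_NT, Mode.PAIRED_NT)
    need_beta = mode in (Mode.BETA_NT, Mode.PAIRED_NT)
    if (need_alpha and parts["alpha_cdr3_nt"] is None) or (
        need_beta and parts["beta_cdr3_nt"] is None
    ):
        return None, multi
    return (
        ClonotypeKey(
            mode,
            alpha_cdr3_nt=parts["alpha_cdr3_nt"] if need_alpha else None,
            beta_cdr3_nt=parts["beta_cdr3_nt"] if need_beta else None,
        ),
        multi,
    )


def assign_clonotypes(
    cells: list[CellVDJ], mode: Mode | str = Mode.ALPHA_NT, sample_id: str | None = None
) -> ClonotypeTable:
    """Group cells into clonotypes by CDR3 nucleotide identity.

    Each cell with the chain(s) the mode requires is assigned to exactly
    one key; when a cell carries several contigs of a required chain, the
    highest-UMI contig is used (ties by contig_id).  Cells lacking a
    required chain stay unassigned.
    """
    mode = Mode(mode)
    sid = sample_id if sample_id is not None else (
        cells[0].sample_id if cells and cells[0].sample_id else "sample"
    )
    assignments: dict[str, ClonotypeKey | None] = {}
    tally: dict[ClonotypeKey, int] = {}
    multi_count = 0
    for cell in cells:
        key, multi = _cell_key(cell, mode)
        multi_count += multi
        assignments[cell.barcode] = key
        if key is not None:
            tally[key] = tally.get(key, 0) + 1
    keys = sorted(tally)
    counts = np.array([[tally[k]] for k in keys], dtype=np.int64).reshape(len(keys), 1)
    return ClonotypeTable(
        mode=mode,
        keys=keys,
        samples=[sid],
        counts=counts,
        assignments=assignments,
        multi_chain_cells=multi_count,
    )


def occurrence_matrix(tables: list[ClonotypeTable]) -> ClonotypeTable:
    """Union per-sample tables into one clonotype x sample count matrix."""
    if not tables:
        raise ValueError("no tables")
    mode = tables[0].mode
    if any(t.mode is not mode for t in tables):
        raise ValueError("clonotype mode mismatch across samples")
    samples: list[str] = []
    for t in tables:
        for s in t.samples:
            if s in samples:
                raise ValueError(f"duplicate sample id {s!r}")
            samples.append(s)
    keys = sorted({k for t in tables for k in t.keys})
    key_row = {k: i for i, k in enumerate(keys)}
    counts = np.zeros((len(keys), len(samples)), dtype=np.int64)
    assignments: dict[str, ClonotypeKey | None] = {}
    col = 0
    for t in tables:
        for j in range(len(t.samples)):
            for k, c in zip(t.keys, t.counts[:, j]):
                counts[key_row[k], col] = c
            col += 1
        assignments.update(t.assignments)
    return ClonotypeTable(
        mode=mode,
        keys=keys,
        samples=samples,
        counts=counts,
        assignments=assignments,
        multi_chain_cells=sum(t.multi_chain_cells for t in tables),
    )


def track_clonotypes(
    matrix: ClonotypeTable, focal_sample: str, top_k: int = 10
) -> pd.DataFrame:
    """Cross-sample counts for the focal sample's top-k clonotypes.

    Ranked by focal count descending, ties broken by key order; zero counts
    in other samples are reported, which is what makes the result a
    clone-tracking table.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if focal_sample not in matrix.samples:
        raise ValueError(f"focal sample {focal_sample!r} not in matrix")
    j = matrix.samples.index(focal_sample)
    order = sorted(
        range(len(matrix.keys)), key=lambda i: (-matrix.counts[i, j], matrix.keys[i])
    )[:top_k]
    df = pd.DataFrame(
        matrix.counts[order, :],
        index=[_key_label(matrix.keys[i]) for i in order],
        columns=matrix.samples,
    )
    df.index.name = "clonotype"
    return df


def alloreactive_key_set(
    table: ClonotypeTable, sample: str, min_cells: int = 2
) -> set[ClonotypeKey]:
    """Allo-proliferating clonotypes: those seen >= min_cells times in the
    highly proliferated (CTV-Low) MLR fraction."""
    return {k for k, c in table.sample_counts(sample).items() if c >= min_cells}


def tag_alloreactive(
    tissue_cells: list[CellVDJ],
    allo_keys: set[ClonotypeKey],
    mode: Mode | str = Mode.PAIRED_NT,
) -> tuple[list[MLRLabel], dict[MLRStatus, int]]:
    """Label tissue cells MLR+/MLR- against an allo-proliferating key set.

    MLR+ = the cell's clonotype key is in ``allo_keys``; MLR- = the cell is
    assigned to a clonotype but not a matching one; unassigned = required
    chain(s) missing.  Returns the labels and per-status counts.
    """
    mode = Mode(mode)
    if not allo_keys:
        raise ValueError("allo_keys is empty")
    bad = [k for k in allo_keys if k.mode is not mode]
    if bad:
        raise ValueError(f"{len(bad)} allo keys have mode inconsistent with {mode.value}")
    labels = []
    counts = {s: 0 for s in MLRStatus}
    for cell in tissue_cells:
        key, _ = _cell_key(cell, mode)
        if key is None:
            status = MLRStatus.UNASSIGNED
        elif key in allo_keys:
            status = MLRStatus.MLR_PLUS
        else:
            status = MLRStatus.MLR_MINUS
        labels.append(MLRLabel(cell.barcode, status))
        counts[status] += 1
    return labels, counts
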