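"""Synthetic MLR / tissue / expression data with known ground truth.

Emulates the experimental design the pipeline targets: a donor T-cell
repertoire with heavy-tailed clone sizes; a mixed lymphocyte reaction whose
sorted CTV fractions (High = non-proliferating, Mid, Low = highly
proliferating) progressively expand a planted set of alloreactive clones;
tissue samples seeded with a subset of those clones; 10x-style contig
tables with partial chain-detection dropout; and negative-binomial
expression matrices with planted cytotoxic-gene upregulation in
alloreactive cells plus mitochondrial/library-size outliers to exercise QC.

Every output is deterministic given the config seed, and the generator
keeps full bookkeeping (true clone ids, the alloreactive set, planted DE
genes) so pipeline recovery can be checked exactly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Repertoire",
    "MLRSimulation",
    "sample_repertoire",
    "simulate_mlr",
    "sample_tissue",
    "emit_contig_csv",
    "simulate_gex",
    "write_manifest",
]

BASES = np.array(list("ACGT"))

#: Default study-design parameters. Expansion multipliers follow the sorted
#: CTV fractions (Low = highly proliferated, so most expanded); dropout
#: rates sit inside the observed per-chain reconstruction ranges (alpha
#: 50-67%, beta 83-94% of cells).
DEFAULTS = dict(
    n_clones=30000,
    clone_dist="lognormal",
    sigma=1.0,
    alpha_dirichlet=1.0,
    n_cells=5000,
    allo_fraction=0.01,
    expansion={"CTV-High": 1.0, "CTV-Mid": 5.0, "CTV-Low": 50.0},
    p_alpha=0.6,
    p_beta=0.9,
    corrupt_fraction=0.0,
)


@dataclass
class SimConfig:
    seed: int = 0
    n_clones: int = DEFAULTS["n_clones"]
    clone_dist: str = DEFAULTS["clone_dist"]  # "lognormal" | "dirichlet"
    sigma: float = DEFAULTS["sigma"]  # lognormal log-sd
    alpha_dirichlet: float = DEFAULTS["alpha_dirichlet"]
    n_cells: int = DEFAULTS["n_cells"]  # cells per sorted fraction
    allo_fraction: float = DEFAULTS["allo_fraction"]
    expansion: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULTS["expansion"])
    )
    p_alpha: float = DEFAULTS["p_alpha"]
    p_beta: float = DEFAULTS["p_beta"]
    corrupt_fraction: float = DEFAULTS["corrupt_fraction"]
    # expression model
    n_genes: int = 200
    nb_mean: float = 15.0  # per-gene baseline; ~3,000 counts/cell at 200 genes
    nb_dispersion: float = 10.0  # NB size parameter theta; variance mu + mu^2/theta
    planted_genes: tuple[str, ...] = ("GZMB-like",)
    planted_effect: float = 2.5
    n_mito_genes: int = 5
    n_outlier_cells: int = 0
    mito_outlier_fraction: float = 0.2
    outlier_total_counts: int = 100

    def __post_init__(self) -> None:
        for p in (self.p_alpha, self.p_beta, self.allo_fraction, self.corrupt_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0,1]")
        if any(m < 1 for m in self.expansion.values()):
            raise ValueError("expansion multipliers must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be positive")
        if self.clone_dist not in ("lognormal", "dirichlet"):
            raise ValueError(f"unknown clone_dist {self.clone_dist!r}")


@dataclass
class Repertoire:
    """A donor repertoire: clone frequencies and per-clone CDR3 sequences."""

    freqs: np.ndarray  # (n_clones,), sums to 1
    alpha_nt: list[str]
    beta_nt: list[str]
    alpha_aa: list[str]
    beta_aa: list[str]
    allo_clones: np.ndarray  # indices of planted alloreactive clones
    seed: int

    @property
    def n_clones(self) -> int:
        return len(self.freqs)


@dataclass
class MLRSimulation:
    repertoire: Repertoire
    samples: dict[str, np.ndarray]  # sample name -> per-cell clone ids
    config: SimConfig

    def clone_counts(self, sample: str) -> np.ndarray:
        return np.bincount(self.samples[sample], minlength=self.repertoire.n_clones)


_STOPS = {"TAA", "TAG", "TGA"}
_AA = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}


def _translate(nt: str) -> str:
    return "".join(_AA.get(nt[i : i + 3], "X") for i in range(0, len(nt) - 2, 3))


def _unique_cdr3s(rng: np.random.Generator, n: int, n_codons: int = 5) -> list[str]:
    """Stop-free CDR3 junctions, unique by construction (regenerate on
    collision; deterministic given the generator state)."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        batch = rng.integers(0, 4, size=(max(n - len(out), 64), n_codons, 3))
        # TAA=300, TAG=302, TGA=320 in base-4 digit encoding (A,C,G,T -> 0..3)
        codes = batch[:, :, 0] * 100 + batch[:, :, 1] * 10 + batch[:, :, 2]
        clean = ~np.isin(codes, (300, 302, 320)).any(axis=1)
        flat = batch[clean].reshape(clean.sum(), -1)
        for row in flat:
            seq = "TGT" + "".join(BASES[row]) + "TTT"  # canonical C...F frame
            if seq not in seen:
                seen.add(seq)
                out.append(seq)
                if len(out) == n:
                    break
    return out


def sample_repertoire(cfg: SimConfig) -> Repertoire:
    """Draw a donor repertoire: clone frequency vector plus unique alpha and
    beta CDR3 nucleotide/amino-acid sequences per clone, and the planted
    alloreactive clone set."""
    if cfg.n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    if cfg.clone_dist == "lognormal":
        w = rng.lognormal(mean=0.0, sigma=cfg.sigma, size=cfg.n_clones)
    else:
        if cfg.alpha_dirichlet <= 0:
            raise ValueError("dirichlet concentration must be positive")
        w = rng.dirichlet(np.full(cfg.n_clones, cfg.alpha_dirichlet))
    freqs = w / w.sum()
    # CDR3 lengths vary per clone; uniqueness enforced within each chain
    alpha_nt = _unique_cdr3s(rng, cfg.n_clones, n_codons=5)
    beta_nt = _unique_cdr3s(rng, cfg.n_clones, n_codons=6)
    n_allo = int(round(cfg.allo_fraction * cfg.n_clones))
    allo = rng.choice(cfg.n_clones, size=n_allo, replace=False)
    return Repertoire(
        freqs=freqs,
        alpha_nt=alpha_nt,
        beta_nt=beta_nt,
        alpha_aa=[_translate(s) for s in alpha_nt],
        beta_aa=[_translate(s) for s in beta_nt],
        allo_clones=np.sort(allo),
        seed=cfg.seed,
    )


def _expanded_freqs(rep: Repertoire, multiplier: float) -> np.ndarray:
    f = rep.freqs.copy()
    f[rep.allo_clones] *= multiplier
    return f / f.sum()


def simulate_mlr(rep: Repertoire, cfg: SimConfig) -> MLRSimulation:
    """Simulate the pre-MLR blood sample and the three sorted CTV fractions.

    Alloreactive clone frequencies are multiplied by each fraction's
    expansion factor and renormalized; cells are drawn multinomially.  The
    returned per-cell clone ids are the ground truth for every downstream
    recovery check.
    """
    mult = cfg.expansion
    order = ["CTV-High", "CTV-Mid", "CTV-Low"]
    if not all(k in mult for k in order):
        raise ValueError(f"expansion must define {order}")
    if not (mult["CTV-Low"] >= mult["CTV-Mid"] >= mult["CTV-High"]):
        raise ValueError("expansion must be ordered Low >= Mid >= High")
    if len(rep.allo_clones) == 0 and any(m > 1 for m in mult.values()):
        raise ValueError("allo_fraction is 0 but expansion multipliers exceed 1")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    samples: dict[str, np.ndarray] = {
        "Blood": rng.choice(rep.n_clones, size=cfg.n_cells, p=rep.freqs)
    }
    for name in order:
        f = _expanded_freqs(rep, mult[name])
        samples[name] = rng.choice(rep.n_clones, size=cfg.n_cells, p=f)
    return MLRSimulation(repertoire=rep, samples=samples, config=cfg)


def sample_tissue(
    rep: Repertoire,
    cfg: SimConfig,
    n_cells: int,
    allo_cell_fraction: float = 0.05,
    name: str = "tissue",
) -> np.ndarray:
    """Per-cell clone ids for a tissue (spleen/liver-like) sample: a
    background draw from the repertoire with ``allo_cell_fraction`` of the
    cells replaced by draws from the planted alloreactive clones."""
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 2, zlib.crc32(name.encode()) % (2**31)])
    )
    clones = rng.choice(rep.n_clones, size=n_cells, p=rep.freqs)
    n_allo_cells = int(round(allo_cell_fraction * n_cells))
    if n_allo_cells and len(rep.allo_clones):
        idx = rng.choice(n_cells, size=n_allo_cells, replace=False)
        clones[idx] = rng.choice(rep.allo_clones, size=n_allo_cells)
    return clones


def emit_contig_csv(
    clone_ids: np.ndarray,
    rep: Repertoire,
    cfg: SimConfig,
    path: str | Path,
    sample_id: str = "S",
    salt: int = 3,
) -> pd.DataFrame:
    """Write a 10x-dialect filtered_contig_annotations CSV for one sample.

    Per cell, the alpha contig is emitted with probability ``p_alpha`` and
    the beta contig with ``p_beta``, independently; a ``corrupt_fraction``
    of emitted contigs have productive/full_length set false.  Barcodes are
    retained even when both chains drop out (the droplet was still a cell).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))
    rows = []
    for i, clone in enumerate(np.asarray(clone_ids)):
        barcode = f"{sample_id}_CELL{i:06d}-1"
        for chain, p_detect, nt, aa, vg, jg, cg in (
            ("TRA", cfg.p_alpha, rep.alpha_nt[clone], rep.alpha_aa[clone],
             "TRAV1-1", "TRAJ1", "TRAC"),
            ("TRB", cfg.p_beta, rep.beta_nt[clone], rep.beta_aa[clone],
             "TRBV1", "TRBJ1-1", "TRBC1"),
        ):
            if rng.random() >= p_detect:
                continue
            corrupt = rng.random() < cfg.corrupt_fraction
            rows.append(
                dict(
                    barcode=barcode,
                    contig_id=f"{barcode}_contig_{1 if chain == 'TRA' else 2}",
                    chain=chain,
                    v_gene=vg,
                    d_gene="None",
                    j_gene=jg,
                    c_gene=cg,
                    cdr3_nt=nt,
                    cdr3=aa,
                    full_length=not corrupt,
                    productive=not corrupt,
                    umis=int(rng.integers(1, 20)),
                    reads=int(rng.integers(100, 2000)),
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "barcode", "contig_id", "chain", "v_gene", "d_gene", "j_gene",
            "c_gene", "cdr3_nt", "cdr3", "full_length", "productive", "umis",
            "reads",
        ],
    )
    df.to_csv(path, index=False)
    return df


def make_cells(
    clone_ids: np.ndarray,
    rep: Repertoire,
    cfg: SimConfig,
    sample_id: str = "S",
    salt: int = 3,
    dropout: bool = True,
):
    """In-memory CellVDJ list for a sample, chain dropout applied.

    Unlike the contig CSV (which can only list detected chains), the
    returned list keeps chain-less droplets as cells with zero contigs, so
    summary denominators match the simulated cell count exactly.  Same
    RNG stream layout as :func:`emit_contig_csv`.
    """
    from .tenx_io import CellVDJ, ContigRecord
    from .vdj_reference import Chain

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))
    cells = []
    for i, clone in enumerate(np.asarray(clone_ids)):
        barcode = f"{sample_id}_CELL{i:06d}-1"
        contigs = []
        for chain, p_detect, nt, aa in (
            (Chain.TRA, cfg.p_alpha if dropout else 1.0, rep.alpha_nt[clone], rep.alpha_aa[clone]),
            (Chain.TRB, cfg.p_beta if dropout else 1.0, rep.beta_nt[clone], rep.beta_aa[clone]),
        ):
            if rng.random() >= p_detect:
                continue
            corrupt = rng.random() < cfg.corrupt_fraction
            contigs.append(
                ContigRecord(
                    barcode=barcode,
                    contig_id=f"{barcode}_contig_{1 if chain is Chain.TRA else 2}",
                    chain=chain,
                    cdr3_nt=nt,
                    cdr3_aa=aa,
                    full_length=not corrupt,
                    productive=not corrupt,
                    umis=int(rng.integers(1, 20)),
                    reads=int(rng.integers(100, 2000)),
                )
            )
        cells.append(CellVDJ(barcode, contigs, sample_id))
    return cells


def simulate_gex(
    mlr_status: np.ndarray,
    cfg: SimConfig,
    outdir: str | Path | None = None,
    barcodes: list[str] | None = None,
    salt: int = 4,
):
    """Negative-binomial expression matrix with planted effects.

    ``mlr_status`` is a per-cell array of "MLR_plus"/"MLR_minus" strings.
    Counts are NB(mu_g * size_factor_c, theta); planted genes' means are
    multiplied by ``planted_effect`` in MLR+ cells.  ``n_outlier_cells``
    extra QC-violating cells (high mito fraction, tiny library) are
    appended, labelled "outlier" in the returned status array.  Writes
    matrix.mtx/barcodes.tsv/features.tsv when ``outdir`` is given.

    Returns (AnnData, status array incl. outliers, planted gene names).
    """
    import anndata as ad
    import scipy.sparse as sp

    from .tenx_io import annotate_cell_qc, write_mtx

    mlr_status = np.asarray(mlr_status)
    if cfg.planted_effect > 0 and len(cfg.planted_genes) == 0:
        raise ValueError("planted effect requested but no planted genes")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))
    n_cells = len(mlr_status)
    n_bg = cfg.n_genes - len(cfg.planted_genes) - cfg.n_mito_genes
    if n_bg < 1:
        raise ValueError("n_genes too small for planted + mito genes")
    genes = (
        list(cfg.planted_genes)
        + [f"MT-SIM{i}" for i in range(cfg.n_mito_genes)]
        + [f"GENE{i:04d}" for i in range(n_bg)]
    )
    # per-gene baseline means: heavy-tailed around nb_mean; mito genes at
    # half mean so the baseline mito fraction stays ~1-2%, clear of the QC bound
    mu_g = rng.lognormal(np.log(cfg.nb_mean), 0.5, size=len(genes))
    mito_cols = np.arange(len(cfg.planted_genes), len(cfg.planted_genes) + cfg.n_mito_genes)
    mu_g[mito_cols] *= 0.5
    size_factor = rng.lognormal(0.0, 0.1, size=n_cells)
    mu = np.outer(size_factor, mu_g)
    is_plus = mlr_status == "MLR_plus"
    mu[np.ix_(is_plus, np.arange(len(cfg.planted_genes)))] *= cfg.planted_effect
    theta = cfg.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    status = mlr_status.copy()

    if cfg.n_outlier_cells:
        # QC bait: near-empty droplets with a high mitochondrial fraction
        out_rows = np.zeros((cfg.n_outlier_cells, len(genes)), dtype=counts.dtype)
        n_mito_counts = int(cfg.mito_outlier_fraction * cfg.outlier_total_counts)
        n_bg_counts = cfg.outlier_total_counts - n_mito_counts
        bg_start = len(cfg.planted_genes) + cfg.n_mito_genes
        bg_cols = np.arange(bg_start, bg_start + min(20, n_bg))
        out_rows[:, bg_cols] = n_bg_counts // len(bg_cols)
        if len(mito_cols):
            out_rows[:, mito_cols] = n_mito_counts // len(mito_cols)
        counts = np.vstack([counts, out_rows])
        status = np.concatenate([status, np.repeat("outlier", cfg.n_outlier_cells)])

    if barcodes is None:
        barcodes = [f"GEX_CELL{i:06d}-1" for i in range(counts.shape[0])]
    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.float64)),
        obs=pd.DataFrame({"mlr_status": status}, index=barcodes),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    annotate_cell_qc(adata)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_mtx(
            adata,
            outdir / "matrix.mtx",
            outdir / "barcodes.tsv",
            outdir / "features.tsv",
        )
    return adata, status, list(cfg.planted_genes)


def write_manifest(cfg: SimConfig, path: str | Path, files: dict[str, str] | None = None) -> None:
    """Run manifest: config (seed included) plus optional file checksums."""
    import hashlib

    payload = {"config": asdict(cfg), "files": {}}
    for name, fp in (files or {}).items():
        payload["files"][name] = hashlib.sha256(Path(fp).read_bytes()).hexdigest()
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
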