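"""Repertoire diversity and overlap statistics.

Shannon entropy (in nats) with the analytic variance estimate used by the
Hutcheson two-sample t-test, and the Morisita index of community similarity
for pairwise repertoire overlap.  Count vectors are clonotype cell counts;
the statistics are agnostic to whether clonotypes were keyed by alpha,
beta, or paired CDR3s.

The Hutcheson test compares two Shannon indices:

    t  = (H1 - H2) / sqrt(var H1 + var H2)
    df = (var H1 + var H2)^2 / ((var H1)^2/N1 + (var H2)^2/N2)

with var H = (sum p ln^2 p - H^2)/N + (S - 1)/(2 N^2), the first-order
delta-method variance plus the small-sample bias correction term.

The classical Morisita index for integer counts x, y on a common label set:

    lambda_x = sum x_i (x_i - 1) / (N_x (N_x - 1))
    MI = 2 sum x_i y_i / ((lambda_x + lambda_y) N_x N_y)

MI is ~0 for disjoint repertoires and ~1 for proportionally identical
ones; it can exceed 1 when both communities concentrate on shared clones
more than within themselves.  When both samples are all singletons
(lambda_x + lambda_y = 0) the Morisita-Horn variant (lambda replaced by
sum (x_i/N)^2) is substituted and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountVector",
    "DiversityResult",
    "HutchesonResult",
    "OverlapResult",
    "shannon",
    "hutcheson_test",
    "morisita",
    "pairwise_overlap",
]


@dataclass(frozen=True)
class DiversityResult:
    H: float
    varH: float
    N: int
    S: int


@dataclass(frozen=True)
class HutchesonResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class OverlapResult:
    mi: float
    variant: str = "morisita"  # "morisita" | "horn"


class CountVector:
    """Labelled nonnegative integer clonotype counts for one sample."""

    def __init__(self, counts: Mapping[Hashable, int] | Sequence[int]):
        if isinstance(counts, Mapping):
            labels = list(counts.keys())
            x = np.asarray([counts[k] for k in labels])
        else:
            x = np.asarray(list(counts))
            labels = list(range(len(x)))
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate labels")
        if x.size and (x < 0).any():
            raise ValueError("negative counts")
        if not np.issubdtype(x.dtype, np.integer):
            if x.size and not np.allclose(x, np.round(x)):
                raise ValueError("counts must be integers")
            x = x.astype(np.int64)
        self.labels = labels
        self.x = x.astype(np.int64)

    @property
    def N(self) -> int:
        return int(self.x.sum())

    @property
    def S(self) -> int:
        return int((self.x > 0).sum())

    def aligned_to(self, labels: Sequence[Hashable]) -> np.ndarray:
        lut = dict(zip(self.labels, self.x))
        return np.asarray([lut.get(l, 0) for l in labels], dtype=np.int64)


def _as_counts(x) -> CountVector:
    return x if isinstance(x, CountVector) else CountVector(x)


def shannon(counts) -> DiversityResult:
    """Shannon diversity H (nats) with its Hutcheson variance estimate."""
    cv = _as_counts(counts)
    if cv.N < 1:
        raise ValueError("all-zero count vector")
    x = cv.x[cv.x > 0]
    p = x / cv.N
    logp = np.log(p)
    H = float(-(p * logp).sum())
    varH = float(((p * logp**2).sum() - H**2) / cv.N + (cv.S - 1) / (2 * cv.N**2))
    return DiversityResult(H=H, varH=max(varH, 0.0), N=cv.N, S=cv.S)


def hutcheson_test(counts1, counts2) -> HutchesonResult:
    """Two-sided Hutcheson t-test comparing two Shannon indices."""
    cv1, cv2 = _as_counts(counts1), _as_counts(counts2)
    if cv1.N < 2 or cv2.N < 2:
        raise ValueError("Hutcheson test requires N >= 2 in both samples")
    d1, d2 = shannon(cv1), shannon(cv2)
    var_sum = d1.varH + d2.varH
    if var_sum == 0.0:
        if d1.H == d2.H:
            return HutchesonResult(t=0.0, df=1.0, p=1.0)
        raise ZeroDivisionError("zero variance with unequal H")
    t = (d1.H - d2.H) / np.sqrt(var_sum)
    df = var_sum**2 / (d1.varH**2 / d1.N + d2.varH**2 / d2.N)
    df = max(df, 1.0)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return HutchesonResult(t=float(t), df=float(df), p=min(max(p, np.nextafter(0, 1)), 1.0))


def morisita(counts_x, counts_y, variant: str = "morisita") -> OverlapResult:
    """Morisita similarity between two repertoires.

    Counts are aligned on the union of labels.  ``variant`` selects the
    classical integer-count estimator (default) or "horn" for the
    Morisita-Horn form; the classical form falls back to Horn (flagged in
    the result) when both samples are all singletons.
    """
    cvx, cvy = _as_counts(counts_x), _as_counts(counts_y)
    if cvx.N < 2 or cvy.N < 2:
        raise ValueError("Morisita requires N >= 2 in both samples")
    labels = list(dict.fromkeys(list(cvx.labels) + list(cvy.labels)))
    x = cvx.aligned_to(labels).astype(np.float64)
    y = cvy.aligned_to(labels).astype(np.float64)
    nx, ny = x.sum(), y.sum()
    cross = float((x * y).sum())
    if variant not in ("morisita", "horn"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "morisita":
        lam_x = float((x * (x - 1)).sum()) / (nx * (nx - 1))
        lam_y = float((y * (y - 1)).sum()) / (ny * (ny - 1))
        if lam_x + lam_y > 0:
            return OverlapResult(
                mi=2.0 * cross / ((lam_x + lam_y) * nx * ny), variant="morisita"
            )
        # all-singleton degenerate case: classical denominator vanishes
    lam_x = float(((x / nx) ** 2).sum())
    lam_y = float(((y / ny) ** 2).sum())
    return OverlapResult(mi=2.0 * cross / ((lam_x + lam_y) * nx * ny), variant="horn")


def pairwise_overlap(
    samples: Mapping[str, Mapping[Hashable, int]] | Mapping[str, "CountVector"],
    variant: str = "morisita",
) -> pd.DataFrame:
    """Symmetric sample x sample Morisita matrix (diagonal self-vs-self)."""
    names = list(samples.keys())
    if len(names) < 2:
        raise ValueError("pairwise overlap needs >= 2 samples")
    cvs = {n: _as_counts(samples[n]) for n in names}
    mat = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j < i:
                continue
            mi = morisita(cvs[a], cvs[b], variant=variant).mi
            mat[i, j] = mat[j, i] = mi
    return pd.DataFrame(mat, index=names, columns=names)


def plot_overlap_heatmap(matrix: pd.DataFrame, path: str, cmap: str = "viridis") -> None:
    """Save a pairwise-overlap heatmap image (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(matrix), 1 + 0.5 * len(matrix)))
    im = ax.imshow(matrix.to_numpy(), cmap=cmap, vmin=0.0)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    fig.colorbar(im, ax=ax, label="Morisita index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
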