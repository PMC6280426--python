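"""Anchor-gene co-expression screening by dual correlation statistics.

Every gene in an expression matrix is tested against a fixed anchor gene
(EGFR in the motivating GBM analysis) with two complementary dependence
measures:

* Spearman's rank correlation — Pearson correlation of average-tie ranks,
  sensitive to monotone association and robust to the zero-heavy marginals
  of single-cell data;
* distance correlation — built from pairwise Euclidean distance matrices.
  Two variants are provided: the standard Székely statistic (double-centred
  distance matrices; zero iff empirical independence, 1 for affine
  dependence in 1D) and a mean-scaled distance-covariance variant in which
  each gene's distance matrix is divided by its off-diagonal grand mean and
  the statistic is the off-diagonal average of entrywise products minus 1.

Significance for both statistics comes from a permutation null; p-values
are Benjamini-Hochberg adjusted across the screen and the co-expressed
gene list is the intersection of the two pass sets.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Literal, Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenParams",
    "CorrelationRecord",
    "spearman",
    "pairwise_distance_matrix",
    "distance_correlation",
    "permutation_p",
    "bh_adjust",
    "screen_genes",
]


class DegenerateInputError(ValueError):
    """A statistic is undefined on the given input (constant vector)."""


@dataclasses.dataclass
class ScreenParams:
    """Configuration of an anchor-vs-all co-expression screen.

    n_permutations defaults to 999; genome-scale screens should raise it so
    the permutation floor 1/(B+1) sits below the BH threshold for the
    expected number of true positives (see docs/methods.md).
    """

    anchor: str
    n_permutations: int = 999
    alpha: float = 0.05
    dcor_variant: Literal["standard", "paper"] = "standard"
    min_nonzero_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.min_nonzero_fraction <= 1:
            raise ValueError("min_nonzero_fraction must be in [0, 1]")
        if self.dcor_variant not in ("standard", "paper"):
            raise ValueError(f"unknown dcor variant {self.dcor_variant!r}")


@dataclasses.dataclass
class CorrelationRecord:
    gene_id: str
    rho: float
    rho_p: float
    dcor: float
    dcor_p: float
    rho_q: float
    dcor_q: float
    pass_rho: bool
    pass_dcor: bool
    in_intersection: bool


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of average-tie ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("Spearman correlation undefined for a constant vector")
    return float(scipy.stats.spearmanr(x, y).statistic)


def pairwise_distance_matrix(x: Sequence[float]) -> np.ndarray:
    """n x n matrix of |x_i - x_j| (Euclidean distances of scalars)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("need a 1-D vector of length >= 4")
    return np.abs(x[:, None] - x[None, :])


def _double_center(D: np.ndarray) -> np.ndarray:
    return D - D.mean(axis=0) - D.mean(axis=1)[:, None] + D.mean()


def _mean_scale(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    off_mean = D.sum() / (n * (n - 1))  # diagonal is zero, excluded from the mean
    if off_mean == 0:
        raise DegenerateInputError("mean-scaled variant undefined: zero off-diagonal mean")
    return D / off_mean


def distance_correlation(
    x: Sequence[float],
    y: Sequence[float],
    variant: Literal["standard", "paper"] = "standard",
) -> float:
    """Distance-based dependence between two scalar samples.

    "standard": Székely distance correlation, dCov / sqrt(dVar_x * dVar_y)
    with double-centred distance matrices, clipped to [0, 1].
    "paper": each distance matrix is divided by its off-diagonal grand mean
    and the statistic is the off-diagonal average of entrywise products,
    minus 1 (a covariance-style quantity, unbounded above).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    Dx = pairwise_distance_matrix(x)
    Dy = pairwise_distance_matrix(y)
    if variant == "standard":
        A = _double_center(Dx)
        B = _double_center(Dy)
        dvar_x = (A * A).mean()
        dvar_y = (B * B).mean()
        if dvar_x == 0 or dvar_y == 0:
            raise DegenerateInputError("zero distance variance (constant input)")
        dcov2 = (A * B).mean()
        val = np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y))
        return float(min(max(val, 0.0), 1.0))
    if variant == "paper":
        Sx = _mean_scale(Dx)
        Sy = _mean_scale(Dy)
        n = len(x)
        # diagonals are zero, so the full sum is the off-diagonal sum
        return float((Sx * Sy).sum() / (n * (n - 1)) - 1.0)
    raise ValueError(f"unknown variant {variant!r}")


def permutation_p(
    stat_fn: Callable[[np.ndarray, np.ndarray], float],
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int,
    seed: int,
    two_sided: bool = True,
) -> float:
    """Permutation p-value: p = (1 + #{perm stat >= observed}) / (B + 1).

    Only y is shuffled. For signed statistics the comparison is two-sided
    via absolute values; set ``two_sided=False`` for non-negative statistics.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = stat_fn(x, y)
    obs_cmp = abs(obs) if two_sided else obs
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = stat_fn(x, rng.permutation(y))
        if (abs(perm) if two_sided else perm) >= obs_cmp:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; output order matches input."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --- batched screen internals -------------------------------------------------

def _centred_rank_rows(X: np.ndarray) -> np.ndarray:
    """Average-tie ranks per row, centred and scaled to unit norm."""
    R = scipy.stats.rankdata(X, axis=1).astype(np.float64)
    R -= R.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(R, axis=1, keepdims=True)
    return R / norms


def _distance_stack(X: np.ndarray, variant: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene flattened distance-derived matrices for the batched screen.

    Returns (stack of shape (G, n*n) float32, per-gene distance variance for
    the standard variant or zeros for the paper variant).
    """
    G, n = X.shape
    D = np.abs(X[:, :, None] - X[:, None, :]).astype(np.float32)
    if variant == "standard":
        # row-centre then column-centre: together this is full double centering
        D -= D.mean(axis=2, keepdims=True)
        D -= D.mean(axis=1, keepdims=True)
        dvar = (D * D).mean(axis=(1, 2)).astype(np.float64)
    else:
        off_mean = D.sum(axis=(1, 2)) / (n * (n - 1))
        D /= off_mean[:, None, None]
        dvar = np.zeros(G)
    return D.reshape(G, n * n), dvar


def _batched_screen(
    X: np.ndarray,
    x_anchor: np.ndarray,
    params: ScreenParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Observed statistics and permutation p-values for all genes at once.

    Both statistics are symmetric in their arguments, so shuffling the
    anchor yields the same per-pair null as shuffling each gene; one set of
    B anchor permutations is shared across all genes, which turns the
    permutation null for the distance statistics into a single matrix
    product per block.
    """
    G, n = X.shape
    B = params.n_permutations
    rng = np.random.default_rng(params.seed)
    perms = np.stack([rng.permutation(n) for _ in range(B)])

    # Spearman: observed and null via centred unit-norm ranks
    Rn = _centred_rank_rows(X)
    rn = _centred_rank_rows(x_anchor[None, :])[0]
    rho_obs = Rn @ rn
    null_rho = np.abs(Rn @ rn[perms].T)  # (G, B)
    rho_hits = (null_rho >= np.abs(rho_obs)[:, None]).sum(axis=1)
    rho_p = (1 + rho_hits) / (B + 1)

    # distance statistic: observed and null via flattened-matrix products
    M, dvar_g = _distance_stack(X, params.dcor_variant)
    if params.dcor_variant == "standard":
        Ax = _double_center(pairwise_distance_matrix(x_anchor)).astype(np.float32)
        dvar_x = float((Ax.astype(np.float64) ** 2).mean())
        if dvar_x == 0:
            raise DegenerateInputError("anchor has zero distance variance")
        denom = np.sqrt(dvar_g * dvar_x) * (n * n)
        ok = dvar_g > 0
    else:
        Ax = _mean_scale(pairwise_distance_matrix(x_anchor)).astype(np.float32)
        denom = np.full(G, float(n * (n - 1)))
        ok = np.ones(G, dtype=bool)

    ax = Ax.reshape(-1)
    raw_obs = (M @ ax).astype(np.float64)
    dcor_hits = np.zeros(G, dtype=np.int64)
    block = max(1, min(B, int(2.5e8 // (n * n))))  # cap permutation-block memory
    for start in range(0, B, block):
        idx = perms[start : start + block]
        Aperm = Ax[idx[:, :, None], idx[:, None, :]].reshape(len(idx), n * n)
        null_raw = (M @ Aperm.T).astype(np.float64)  # (G, b)
        dcor_hits += (null_raw >= raw_obs[:, None]).sum(axis=1)
    dcor_p = (1 + dcor_hits) / (B + 1)

    if params.dcor_variant == "standard":
        with np.errstate(invalid="ignore", divide="ignore"):
            dcor_obs = np.sqrt(np.clip(raw_obs, 0.0, None) / denom)
        dcor_obs = np.clip(np.where(ok, dcor_obs, np.nan), 0.0, 1.0)
    else:
        dcor_obs = raw_obs / denom - 1.0

    return rho_obs, rho_p, dcor_obs, dcor_p


def screen_genes(matrix: ExpressionMatrix, params: ScreenParams) -> list[CorrelationRecord]:
    """Screen every non-anchor gene against the anchor.

    Genes expressed (nonzero) in fewer than ``min_nonzero_fraction`` of
    samples are filtered out before testing, as are constant genes (both
    statistics are undefined on them; the dropped count is logged). Counts-
    scale matrices are screened on log2(1 + x). Pass flags are BH q < alpha
    per statistic; the co-expressed list is the intersection of the two
    pass sets. Output is sorted by descending distance statistic, then
    descending |rho|, then gene id.
    """
    if params.anchor not in matrix.gene_ids:
        raise KeyError(f"anchor gene {params.anchor!r} not in matrix")
    if matrix.n_samples < 4:
        raise ValueError("screen requires at least 4 samples")

    values = matrix.values
    if matrix.scale == "counts":
        values = np.log2(1.0 + values)

    anchor_idx = matrix.gene_ids.index(params.anchor)
    x_anchor = values[anchor_idx]
    if np.ptp(x_anchor) == 0:
        raise DegenerateInputError(f"anchor {params.anchor!r} is constant")

    gene_ids = np.array(matrix.gene_ids)
    mask = np.ones(matrix.n_genes, dtype=bool)
    mask[anchor_idx] = False
    nonzero_frac = (matrix.values != 0).mean(axis=1)
    mask &= nonzero_frac >= params.min_nonzero_fraction
    constant = np.ptp(values, axis=1) == 0
    n_constant = int((mask & constant).sum())
    if n_constant:
        logger.info("screen_genes: dropping %d constant genes", n_constant)
    mask &= ~constant

    X = values[mask]
    ids = gene_ids[mask]
    if X.shape[0] == 0:
        return []

    rho, rho_p, dcor, dcor_p = _batched_screen(X, x_anchor, params)
    rho_q = bh_adjust(rho_p)
    dcor_q = bh_adjust(dcor_p)
    pass_rho = rho_q < params.alpha
    pass_dcor = dcor_q < params.alpha

    records = [
        CorrelationRecord(
            gene_id=str(ids[i]),
            rho=float(rho[i]),
            rho_p=float(rho_p[i]),
            dcor=float(dcor[i]),
            dcor_p=float(dcor_p[i]),
            rho_q=float(rho_q[i]),
            dcor_q=float(dcor_q[i]),
            pass_rho=bool(pass_rho[i]),
            pass_dcor=bool(pass_dcor[i]),
            in_intersection=bool(pass_rho[i] and pass_dcor[i]),
        )
        for i in range(len(ids))
    ]
    records.sort(key=lambda r: (-r.dcor, -abs(r.rho), r.gene_id))
    return records
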