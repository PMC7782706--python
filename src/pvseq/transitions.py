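"""Age-transition detection for binary gene expression via Gini impurity.

For each gene, cells are ordered by postnatal age and expression is reduced
to a boolean (TPM strictly above a low cutoff, default 0.6).  Candidate
change points are the boundaries between consecutive distinct ages (splits
inside an age tie are disallowed, which makes the statistic invariant to the
arbitrary ordering of same-age cells).  The best split maximizes the loss of
Gini impurity; significance is calibrated against a Monte Carlo null that
shuffles which cells express the gene, with exhaustive enumeration available
as an exact small-n oracle.  Benjamini-Hochberg FDR is applied across all
tested genes.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import Dataset, GeneSet, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_TPM = 0.6
DEFAULT_MIN_CELLS = 6
DEFAULT_N_SIMS = 100_000
DEFAULT_FDR = 0.10


@dataclass
class BinaryExpression:
    """Boolean expressed indicators (genes x cells) with cell ages attached."""

    df: pd.DataFrame  # bool, genes x cells
    ages: pd.Series  # int, indexed by cell id, same order as df columns
    cutoff_tpm: float


def binarize(ds: Dataset, cutoff_tpm: float = DEFAULT_CUTOFF_TPM) -> BinaryExpression:
    """Expressed iff TPM strictly greater than ``cutoff_tpm``."""
    return BinaryExpression(df=ds.expr.df > cutoff_tpm,
                            ages=ds.meta.ages.copy(),
                            cutoff_tpm=cutoff_tpm)


def eligible_genes(bx: BinaryExpression, min_cells: int = DEFAULT_MIN_CELLS) -> GeneSet:
    """Genes expressed in >= min_cells AND not expressed in >= min_cells cells."""
    n_on = bx.df.sum(axis=1)
    n_off = bx.df.shape[1] - n_on
    kept = bx.df.index[(n_on >= min_cells) & (n_off >= min_cells)].tolist()
    return GeneSet(method=f"eligible(min_cells={min_cells})", genes=kept)


def gini_impurity(counts) -> float:
    """1 - sum(p_i^2) over category fractions; in [0, 0.5] for two groups."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("Gini impurity undefined for an empty set")
    p = counts / total
    return float(1.0 - np.sum(p * p))


def _two_group_gini(k: np.ndarray, n) -> np.ndarray:
    """Vectorized two-group Gini: 2 p (1 - p) with p = k / n."""
    p = k / n
    return 2.0 * p * (1.0 - p)


def candidate_boundaries(ages: np.ndarray) -> np.ndarray:
    """Split positions b (left block = cells [0, b)) between distinct ages."""
    ages = np.asarray(ages)
    if np.any(np.diff(ages) < 0):
        raise ValidationError("ages must be non-decreasing")
    return np.flatnonzero(np.diff(ages) != 0) + 1


@dataclass
class BestSplit:
    position: int  # left block size at the best boundary
    loss: float
    tied_positions: list[int] = field(default_factory=list)


def _losses_at_boundaries(k_left: np.ndarray, bounds: np.ndarray,
                          k_total: float, n: int) -> np.ndarray:
    """Gini losses for splits at ``bounds`` given left expressed counts.

    Works for k_left of shape (..., len(bounds)); broadcast over leading axes.
    """
    parent = _two_group_gini(np.asarray(k_total, dtype=float), n)
    g_left = _two_group_gini(k_left, bounds)
    g_right = _two_group_gini(k_total - k_left, n - bounds)
    if np.ndim(parent):
        parent = parent[..., None]
    return parent - (bounds * g_left + (n - bounds) * g_right) / n


def best_split(expressed: np.ndarray, ages: np.ndarray) -> BestSplit:
    """Maximum Gini-impurity-loss split of an age-ordered binary vector.

    Candidate splits fall only between cells of different age.  Ties are
    broken by the earliest position; all tied positions are reported.
    """
    x = np.asarray(expressed, dtype=float)
    n = len(x)
    if n < 2:
        raise ValidationError("need at least 2 cells")
    bounds = candidate_boundaries(ages)
    if len(bounds) == 0:
        raise ValidationError("all cells share one age; no candidate split")
    k_left = np.cumsum(x)[bounds - 1]
    losses = _losses_at_boundaries(k_left, bounds, x.sum(), n)
    best = losses.max()
    tied = bounds[np.isclose(losses, best, rtol=0, atol=1e-12)]
    return BestSplit(position=int(tied[0]), loss=float(best),
                     tied_positions=[int(b) for b in tied])


def _null_max_losses_simulated(n: int, k: int, bounds: np.ndarray,
                               n_sims: int, rng: np.random.Generator) -> np.ndarray:
    """Max-loss null distribution from uniform arrangements of k ones in n slots."""
    # float64 so null losses are bit-identical to the enumeration arithmetic
    template = np.zeros((n_sims, n), dtype=np.float64)
    template[:, :k] = 1.0
    arrangements = rng.permuted(template, axis=1)
    k_left = np.cumsum(arrangements, axis=1)[:, bounds - 1]
    losses = _losses_at_boundaries(k_left, bounds.astype(float), float(k), n)
    return losses.max(axis=1)


def enumerate_max_losses(n: int, k: int, ages) -> np.ndarray:
    """Exact null: max loss for every C(n, k) arrangement (oracle, n <= ~20)."""
    if n > 22:
        raise ValidationError("exhaustive enumeration is limited to n <= 22")
    bounds = candidate_boundaries(np.sort(np.asarray(ages)))
    out = []
    for ones in itertools.combinations(range(n), k):
        x = np.zeros(n)
        x[list(ones)] = 1.0
        k_left = np.cumsum(x)[bounds - 1]
        out.append(_losses_at_boundaries(k_left, bounds.astype(float), float(k), n).max())
    return np.asarray(out)


class NullCache:
    """Cache of null max-loss distributions keyed by the split structure.

    The key is (n_cells, n_expressed, age multiplicities) because the
    candidate-boundary layout — not the age values themselves — determines
    the null.
    """

    def __init__(self, n_sims: int = DEFAULT_N_SIMS, seed: int | None = None):
        self.n_sims = n_sims
        self._rng = np.random.default_rng(seed)
        self._store: dict[tuple, np.ndarray] = {}

    @staticmethod
    def key(n: int, k: int, ages) -> tuple:
        ages = np.sort(np.asarray(ages))
        _, mult = np.unique(ages, return_counts=True)
        return (n, k, tuple(int(c) for c in mult))

    def null(self, n: int, k: int, ages) -> np.ndarray:
        key = self.key(n, k, ages)
        if key not in self._store:
            bounds = candidate_boundaries(np.sort(np.asarray(ages)))
            self._store[key] = _null_max_losses_simulated(n, k, bounds,
                                                          self.n_sims, self._rng)
        return self._store[key]


def monte_carlo_p(
    n_cells: int,
    n_expressed: int,
    ages,
    observed_loss: float,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int | None = None,
    mode: str = "simulate",
    cache: NullCache | None = None,
) -> float:
    """P-value of an observed max Gini loss under random expression placement.

    ``simulate`` draws ``n_sims`` uniform arrangements and applies an add-one
    correction, p = (1 + #{loss >= observed}) / (1 + n_sims), so p is never
    exactly zero.  ``enumerate`` computes the exact uncorrected fraction over
    all C(n, k) arrangements (feasible for small n; the oracle).
    """
    if not 0 < n_expressed < n_cells:
        raise ValidationError("gene must be expressed in some but not all cells")
    tol = 1e-12  # float-safe >= comparison
    if mode == "enumerate":
        losses = enumerate_max_losses(n_cells, n_expressed, ages)
        return float((losses >= observed_loss - tol).mean())
    if mode != "simulate":
        raise ValueError(f"unknown mode {mode!r}")
    if cache is not None and cache.n_sims == n_sims:
        losses = cache.null(n_cells, n_expressed, ages)
    else:
        bounds = candidate_boundaries(np.sort(np.asarray(ages)))
        rng = np.random.default_rng(seed)
        losses = _null_max_losses_simulated(n_cells, n_expressed, bounds, n_sims, rng)
    exceed = int((losses >= observed_loss - tol).sum())
    return (1 + exceed) / (1 + n_sims)


def detect_transitions(
    ds: Dataset,
    cutoff_tpm: float = DEFAULT_CUTOFF_TPM,
    min_cells: int = DEFAULT_MIN_CELLS,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int | None = None,
    fdr_threshold: float = DEFAULT_FDR,
    mode: str = "simulate",
    gate_on: str = "fdr",
) -> pd.DataFrame:
    """Full transition scan: binarize, filter, split, calibrate, adjust.

    Returns one row per *tested* (eligible, splittable) gene with columns
    ``gene, split_position, split_age_days, pre_age_days, gini_loss,
    direction, p, fdr, n_expressed, significant``; sorted by split age then
    FDR.  ``split_age_days`` is the first age at/after the boundary;
    ``pre_age_days`` the last age before it.  ``significant`` gates on BH
    FDR by default (``gate_on="p"`` gates on the raw p instead).
    """
    order = np.argsort(ds.meta.ages.to_numpy(), kind="stable")
    cells = ds.cells[order]
    ages = ds.meta.ages.to_numpy()[order]
    if len(np.unique(ages)) < 2:
        raise ValidationError("cells must span at least 2 distinct ages")
    bx = binarize(ds, cutoff_tpm)
    sub = bx.df[cells]
    eligible = eligible_genes(BinaryExpression(sub, bx.ages[cells], cutoff_tpm), min_cells)
    if len(eligible) == 0:
        logger.warning("detect_transitions: no eligible gene")
        return pd.DataFrame(columns=[
            "gene", "split_position", "split_age_days", "pre_age_days", "gini_loss",
            "direction", "p", "fdr", "n_expressed", "significant"])

    cache = NullCache(n_sims=n_sims, seed=seed)
    rows = []
    n = len(cells)
    for gene in eligible.genes:
        x = sub.loc[gene].to_numpy().astype(float)
        split = best_split(x, ages)
        k = int(x.sum())
        if mode == "enumerate":
            p = monte_carlo_p(n, k, ages, split.loss, mode="enumerate")
        else:
            p = monte_carlo_p(n, k, ages, split.loss, n_sims=n_sims, cache=cache)
        b = split.position
        pre_frac = x[:b].mean()
        post_frac = x[b:].mean()
        rows.append({
            "gene": gene,
            "split_position": b,
            "split_age_days": int(ages[b]),
            "pre_age_days": int(ages[b - 1]),
            "gini_loss": split.loss,
            "direction": "up" if post_frac > pre_frac else "down",
            "p": p,
            "n_expressed": k,
        })
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    gate_col = "fdr" if gate_on == "fdr" else "p"
    table["significant"] = table[gate_col] < fdr_threshold
    table = table.sort_values(["split_age_days", "fdr"], kind="stable").reset_index(drop=True)
    return table[["gene", "split_position", "split_age_days", "pre_age_days",
                  "gini_loss", "direction", "p", "fdr", "n_expressed", "significant"]]
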