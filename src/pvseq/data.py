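"""Core data containers for Patch-seq expression matrices and cell metadata.

Expression values are stored in linear TPM (transcripts per million)
throughout; log transforms are applied per operation, never at rest, because
every gating threshold in the pipeline (0.6, 15, 32 TPM) is stated in linear
units.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


#: Morphological PV types plus the SST-OLM control type.  hAAC is absent by
#: design: no recorded CA1 cell resembled that morphology, so the token is
#: rejected rather than silently accepted.
MORPH_TYPES = ("vAAC", "vBIC", "hBIC", "vBC", "hBC", "SST-OLM", "unclassified")

#: morph_type -> (dendritic orientation, axonal target class)
_MORPH_DECOMPOSITION = {
    "vAAC": ("vertical", "AAC"),
    "vBIC": ("vertical", "BIC"),
    "hBIC": ("horizontal", "BIC"),
    "vBC": ("vertical", "BC"),
    "hBC": ("horizontal", "BC"),
    "SST-OLM": ("NA", "NA"),
    "unclassified": ("NA", "NA"),
}

DENDRO_VALUES = ("vertical", "horizontal", "NA")
AXO_VALUES = ("AAC", "BC", "BIC", "NA")
REGION_VALUES = ("CA1", "cortex")


class ExpressionMatrix:
    """A gene x cell TPM matrix with unique gene symbols and cell ids.

    Parameters
    ----------
    df
        DataFrame with gene symbols as index and cell ids as columns.
    collapse_duplicates
        If True, rows sharing a gene symbol are summed (the policy used when
        several Ensembl gene IDs map to one symbol).  If False, duplicate
        symbols raise :class:`ValidationError`.
    """

    def __init__(self, df: pd.DataFrame, *, collapse_duplicates: bool = False):
        df = df.astype(float)
        if collapse_duplicates and df.index.has_duplicates:
            n_dup = int(df.index.duplicated().sum())
            logger.info("summing %d duplicated gene symbol rows", n_dup)
            df = df.groupby(level=0, sort=False).sum()
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dups[:10]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate cell ids: {dups[:10]}")
        values = df.to_numpy()
        if not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise ValidationError("expression matrix contains negative TPM values")
        self.df = df

    @property
    def genes(self) -> pd.Index:
        return self.df.index

    @property
    def cells(self) -> pd.Index:
        return self.df.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.df.loc[:, list(cell_ids)])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.df.loc[list(genes)])

    def log2p1(self) -> pd.DataFrame:
        """log2(TPM + 1), the scale used by correlation- and SVM-based steps."""
        return np.log2(self.df + 1.0)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} cells)"


class CellTable:
    """Per-cell metadata: age, morphological labels, region, transcriptomic type.

    The dendritic (vertical/horizontal) and axonal (AAC/BC/BIC) labels are
    derived from ``morph_type`` when absent, and checked for consistency when
    present.
    """

    REQUIRED = ("cell_id", "age_days")
    OPTIONAL = ("morph_type", "dendro", "axo", "region", "transcriptomic_type")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        for col in self.OPTIONAL:
            if col not in df.columns:
                df[col] = pd.NA
        if df["cell_id"].duplicated().any():
            raise ValidationError("duplicate cell_id in metadata")
        ages = pd.to_numeric(df["age_days"], errors="raise")
        if (ages < 0).any():
            raise ValidationError("age_days must be >= 0")
        if not (ages == ages.round()).all():
            raise ValidationError("age_days must be integer postnatal days")
        df["age_days"] = ages.astype(int)

        df["morph_type"] = df["morph_type"].fillna("unclassified").replace("", "unclassified")
        bad = set(df["morph_type"]) - set(MORPH_TYPES)
        if bad:
            raise ValidationError(
                f"unknown morph_type token(s) {sorted(bad)}; allowed: {list(MORPH_TYPES)}"
            )

        derived = df["morph_type"].map(_MORPH_DECOMPOSITION)
        for i, col in enumerate(("dendro", "axo")):
            auto = derived.map(lambda t, i=i: t[i])
            given = df[col].replace("", pd.NA)
            filled = given.fillna(auto)
            allowed = DENDRO_VALUES if col == "dendro" else AXO_VALUES
            bad = set(filled.dropna()) - set(allowed)
            if bad:
                raise ValidationError(f"invalid {col} token(s) {sorted(bad)}")
            # consistency with morph_type for genuine PV types
            pv = df["morph_type"].isin(("vAAC", "vBIC", "hBIC", "vBC", "hBC"))
            mismatch = pv & (filled != auto)
            if mismatch.any():
                raise ValidationError(
                    f"{col} inconsistent with morph_type for cells "
                    f"{df.loc[mismatch, 'cell_id'].tolist()[:5]}"
                )
            df[col] = filled
        region = df["region"].replace("", pd.NA)
        bad = set(region.dropna()) - set(REGION_VALUES)
        if bad:
            raise ValidationError(f"invalid region token(s) {sorted(bad)}")
        df["region"] = region
        self.df = df.set_index("cell_id", drop=False)

    @property
    def cells(self) -> pd.Index:
        return self.df.index

    @property
    def ages(self) -> pd.Series:
        return self.df["age_days"]

    def subset(self, cell_ids: Sequence[str]) -> "CellTable":
        return CellTable(self.df.loc[list(cell_ids)].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CellTable({len(self)} cells)"


@dataclass
class Dataset:
    """An aligned expression matrix + metadata pair (same cells, same order)."""

    expr: ExpressionMatrix
    meta: CellTable

    def __post_init__(self):
        if list(self.expr.cells) != list(self.meta.cells):
            raise ValidationError(
                "Dataset requires identical cell order in expression and metadata; "
                "use align_dataset()"
            )

    @property
    def cells(self) -> pd.Index:
        return self.expr.cells

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_genes(self) -> int:
        return len(self.expr.genes)


def align_dataset(expr: ExpressionMatrix, meta: CellTable) -> Dataset:
    """Intersect cells of an expression matrix and a metadata table.

    Cell order after alignment is the metadata order (the transition detector
    downstream sorts by metadata age).  Dropped ids on either side are logged.
    Aligning an already aligned pair is a no-op.
    """
    common = [c for c in meta.cells if c in set(expr.cells)]
    if not common:
        raise ValidationError("expression and metadata share no cell ids")
    dropped_expr = sorted(set(expr.cells) - set(common))
    dropped_meta = sorted(set(meta.cells) - set(common))
    if dropped_expr:
        logger.info("align_dataset: dropping %d expression-only cells: %s",
                    len(dropped_expr), dropped_expr[:10])
    if dropped_meta:
        logger.info("align_dataset: dropping %d metadata-only cells: %s",
                    len(dropped_meta), dropped_meta[:10])
    return Dataset(expr.subset_cells(common), meta.subset(common))


@dataclass
class GeneSet:
    """An ordered, duplicate-free list of gene symbols with optional scores."""

    method: str
    genes: list[str]
    scores: list[float] | None = None

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("GeneSet contains duplicate gene symbols")
        if self.scores is not None and len(self.scores) != len(self.genes):
            raise ValidationError("scores length must match genes length")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)
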