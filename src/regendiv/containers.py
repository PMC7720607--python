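"""Shared in-memory containers for the pipeline.

The central object is :class:`CountMatrix`: an integer gene x sample count
table plus per-sample metadata (organ, timepoint, replicate).  All downstream
stages (normalization, differential expression, divergence calling) consume
it.  Samples belong to one of seven tissue groups: AO (ampullary organs,
electrosensory) and NM (neuromasts, mechanosensory) each sampled at 12 h and
24 h post neomycin treatment and untreated, plus EP (general epithelium), the
non-sensory reference tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ORGANS = ("AO", "NM", "EP")
TIMEPOINTS = ("12hpt", "24hpt", "untreated", "na")

#: The six organ x timepoint conditions, in the canonical profile order.
SENSORY_CONDITIONS = (
    "AO_12hpt",
    "AO_24hpt",
    "AO_untreated",
    "NM_12hpt",
    "NM_24hpt",
    "NM_untreated",
)

#: The reference condition (general epithelium, no timepoint).
REFERENCE_CONDITION = "EP"

ALL_CONDITIONS = SENSORY_CONDITIONS + (REFERENCE_CONDITION,)

METADATA_COLUMNS = ("organ", "timepoint", "replicate")


def condition_label(organ: str, timepoint: str) -> str:
    """Canonical condition name: ``"AO_12hpt"`` ... or ``"EP"``."""
    if organ == "EP":
        return REFERENCE_CONDITION
    return f"{organ}_{timepoint}"


@dataclass
class CountMatrix:
    """Gene x sample integer counts with aligned sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = gene ids (unique),
        columns = sample ids (unique).
    metadata
        DataFrame indexed by sample id with columns ``organ``, ``timepoint``
        and ``replicate``; must cover exactly the count columns.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if not np.issubdtype(self.counts.to_numpy().dtype, np.integer):
            arr = self.counts.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if set(self.metadata.index) != set(self.counts.columns):
            extra = sorted(set(self.metadata.index) - set(self.counts.columns))
            absent = sorted(set(self.counts.columns) - set(self.metadata.index))
            raise ValueError(
                f"metadata/sample mismatch (metadata-only: {extra}, counts-only: {absent})"
            )
        # keep metadata rows in count-column order
        self.metadata = self.metadata.loc[list(self.counts.columns)]
        bad_org = set(self.metadata["organ"]) - set(ORGANS)
        if bad_org:
            raise ValueError(f"unknown organs: {sorted(bad_org)}")
        bad_tp = set(self.metadata["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_sizes(self) -> pd.Series:
        """Total counts per sample."""
        return self.counts.sum(axis=0)

    def condition_of(self) -> pd.Series:
        """Per-sample condition label (e.g. ``AO_12hpt`` or ``EP``)."""
        return pd.Series(
            [
                condition_label(o, t)
                for o, t in zip(self.metadata["organ"], self.metadata["timepoint"])
            ],
            index=self.metadata.index,
        )

    def samples_of(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition, in column order."""
        cond = self.condition_of()
        return [s for s in self.samples if cond[s] == condition]

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.metadata.copy())


@dataclass
class NormalizedExpression:
    """TMM factors, effective library sizes, TPM and log2(TPM+1) expression."""

    tmm_factors: pd.Series
    effective_lib_size: pd.Series
    tpm: pd.DataFrame
    log_expr: pd.DataFrame


@dataclass
class Dendrogram:
    """Hierarchical-clustering result: scipy merge matrix plus a Newick string."""

    labels: list[str]
    merges: np.ndarray  # scipy linkage matrix, (n-1) x 4
    newick: str


@dataclass
class GseaResult:
    """Pre-ranked gene-set enrichment result.

    ``es`` is the signed extremum of the weighted Kolmogorov-Smirnov running
    sum; ``running_sum`` has one entry per ranked gene; ``leading_edge`` holds
    the member genes at or before (after, for negative ES) the extremum.
    """

    gene_set: str
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]
    pvalue: float | None = None
    n_perm: int = 0
    hits: list[str] = field(default_factory=list)
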