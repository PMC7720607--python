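"""Between- and within-sample normalization and sample-level clustering.

Implements trimmed-mean-of-M-values (TMM) scale factors for count matrices,
TPM (transcripts per million) abundances, log2(TPM+1) expression, pairwise
Euclidean sample distances and agglomerative hierarchical clustering with a
Newick export.

TMM follows the Robinson-Oshlack procedure: for each sample against a
reference, per-gene log ratios M and log abundances A are computed on
library-size-scaled counts, genes with a zero in either sample are dropped,
the M distribution is trimmed by 30% on each tail and the A distribution by
5%, and the factor is 2 to the precision-weighted mean of the surviving M
values (weights = inverse asymptotic binomial variance).  Factors are finally
rescaled to geometric mean 1 across samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .containers import CountMatrix, Dendrogram, NormalizedExpression


def _as_counts_df(counts) -> pd.DataFrame:
    if isinstance(counts, CountMatrix):
        return counts.counts
    return counts


def _quantile_reference(frac: pd.DataFrame) -> str:
    """edgeR's convention: sample whose 75th-percentile count fraction is
    closest to the mean of those quantiles across samples."""
    q = frac.quantile(0.75, axis=0)
    if (q == 0).all():
        raise ValueError("all samples have zero 75th-percentile counts")
    return (q - q.mean()).abs().idxmin()


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, abs_trim: float) -> float:
    """Unscaled TMM factor of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        warnings.warn("no genes expressed in both sample and reference; factor set to 1")
        return 1.0
    y_s, y_r = obs[keep].astype(float), ref[keep].astype(float)
    p_s, p_r = y_s / n_obs, y_r / n_ref
    m = np.log2(p_s / p_r)
    a = 0.5 * np.log2(p_s * p_r)
    # inverse of the weight: asymptotic variance of M under binomial sampling
    v = (n_obs - y_s) / (n_obs * y_s) + (n_ref - y_r) / (n_ref * y_r)

    if np.max(np.abs(m)) < 1e-6:  # identical proportions
        return 1.0

    n = len(m)
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abs_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    trimmed = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not trimmed.any():
        warnings.warn("no genes survive TMM trimming; factor set to 1")
        return 1.0
    f = np.sum(m[trimmed] / v[trimmed]) / np.sum(1.0 / v[trimmed])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def compute_tmm_factors(counts, ref_sample: str | None = None,
                        logratio_trim: float = 0.3,
                        abs_trim: float = 0.05) -> pd.Series:
    """TMM scale factors, one per sample, rescaled to geometric mean 1.

    Parameters
    ----------
    counts
        CountMatrix or genes x samples DataFrame with >= 2 samples.
    ref_sample
        Reference sample id; default picks the sample whose 75th-percentile
        count fraction is closest to the across-sample mean.
    logratio_trim, abs_trim
        Fraction trimmed from each tail of the M (log-ratio) and A (log
        abundance) distributions; defaults 0.3 and 0.05.
    """
    df = _as_counts_df(counts)
    if df.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = df.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    if ref_sample is None:
        ref_sample = _quantile_reference(df / lib)
    elif ref_sample not in df.columns:
        raise KeyError(f"reference sample {ref_sample!r} not in matrix")

    ref = df[ref_sample].to_numpy()
    n_ref = lib[ref_sample]
    factors = pd.Series(
        {
            s: _tmm_pair(df[s].to_numpy(), ref, lib[s], n_ref, logratio_trim, abs_trim)
            for s in df.columns
        },
        name="tmm_factor",
    )
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return factors


def compute_tpm(counts, gene_lengths: pd.Series,
                factors: pd.Series | None = None,
                scale_by_factors: bool = False) -> pd.DataFrame:
    """Transcripts per million from counts and gene lengths (bp).

    Per sample: rate_g = count_g / length_g, TPM_g = rate_g / sum(rate) * 1e6,
    so every column sums to one million.  Within-sample TPM is invariant to a
    per-sample count rescaling, so the TMM ``factors`` only matter with
    ``scale_by_factors=True``, which divides each column by its factor to make
    values comparable across samples (columns then no longer sum to 1e6).
    """
    df = _as_counts_df(counts)
    missing = df.index.difference(gene_lengths.index)
    if len(missing):
        raise ValueError(f"missing gene length(s) for: {missing.tolist()}")
    lengths = gene_lengths.loc[df.index].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive gene length(s) for: {bad}")
    rate = df.div(lengths, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    if scale_by_factors:
        if factors is None:
            raise ValueError("scale_by_factors=True requires factors")
        tpm = tpm.div(factors.loc[tpm.columns], axis=1)
    return tpm


def log_expression(tpm: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(TPM + pseudocount); the pseudocount keeps zeros finite."""
    return np.log2(tpm + pseudocount)


def normalize(counts, gene_lengths: pd.Series,
              pseudocount: float = 1.0) -> NormalizedExpression:
    """One-stop TMM + TPM + log expression for a count matrix."""
    df = _as_counts_df(counts)
    factors = compute_tmm_factors(df)
    lib = df.sum(axis=0).astype(float)
    tpm = compute_tpm(df, gene_lengths, factors)
    return NormalizedExpression(
        tmm_factors=factors,
        effective_lib_size=lib * factors,
        tpm=tpm,
        log_expr=log_expression(tpm, pseudocount),
    )


def sample_distance_matrix(log_expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between samples (columns)."""
    if log_expr.isna().to_numpy().any():
        bad = log_expr.columns[log_expr.isna().any(axis=0)].tolist()
        raise ValueError(f"NaN expression values in sample(s): {bad}")
    if log_expr.shape[1] < 2:
        raise ValueError("need at least two samples")
    d = squareform(pdist(log_expr.to_numpy().T, metric="euclidean"))
    return pd.DataFrame(d, index=log_expr.columns, columns=log_expr.columns)


def _to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Newick string from a scipy linkage matrix, ultrametric branch lengths."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}

    for i, (_, _, h, _) in enumerate(z):
        height[n + i] = h

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = z[i - n]
        a, b = int(a), int(b)
        return (
            f"({node(a)}:{h / 2 - height[a] / 2:.6g},"
            f"{node(b)}:{h / 2 - height[b] / 2:.6g})"
        )

    return node(2 * n - 2) + ";"


def hierarchical_cluster(dist: pd.DataFrame, linkage_method: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a sample distance matrix.

    Returns the scipy merge matrix and a Newick string (ultrametric: leaf
    depth = merge height / 2).  scipy's linkage is deterministic; ties merge
    in input order, so sample order fixes the dendrogram.
    """
    if dist.isna().to_numpy().any():
        raise ValueError("distance matrix contains NaN")
    labels = list(dist.columns)
    z = linkage(squareform(dist.to_numpy(), checks=False), method=linkage_method)
    return Dendrogram(labels=labels, merges=z, newick=_to_newick(z, labels))
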