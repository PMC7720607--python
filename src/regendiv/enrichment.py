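"""Gene-set enrichment: hypergeometric over-representation and pre-ranked GSEA.

Over-representation follows the classical urn model with all annotated genes
as the background: for a study set of size n containing k members of a term
of size K in a background of N genes, p = P(X >= k) for
X ~ Hypergeometric(N, K, n) (upper tail including the observed k, the
``phyper(k-1, ..., lower.tail=FALSE)`` convention).  P-values are BH-adjusted
across terms with the same step-up code used for differential expression.

Pre-ranked GSEA computes the weighted Kolmogorov-Smirnov running sum over a
descending score-ranked gene list: member genes add |score|^p normalized by
the member total, non-members subtract 1/(N - N_hits); the enrichment score
is the signed extremum of largest magnitude, and significance comes from
gene-label permutations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GseaResult
from .diffexpr import bh_adjust


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file: one tab-delimited line per term
    (term, description, gene, gene, ...)."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs term, description and "
                    f"at least one gene"
                )
            term = parts[0]
            if term in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            terms[term] = {g for g in parts[2:] if g}
    return terms


def hypergeometric_enrichment(study_genes, term_to_genes: dict[str, set[str]],
                              background_genes) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a study set per term.

    Term gene sets are intersected with the background before counting;
    terms with no background overlap are skipped with a warning.  Study
    genes must all belong to the background.

    Returns a DataFrame (one row per tested term, sorted by p-value) with
    columns ``term, k, n, K, N, pvalue, fdr``.
    """
    background = set(background_genes)
    study = set(study_genes)
    strays = sorted(study - background)
    if strays:
        raise ValueError(f"study gene(s) absent from background: {strays}")
    n, big_n = len(study), len(background)
    rows = []
    skipped = []
    for term, genes in term_to_genes.items():
        in_bg = genes & background
        big_k = len(in_bg)
        if big_k == 0:
            skipped.append(term)
            continue
        k = len(in_bg & study)
        # P(X >= k), including the observed count
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"term": term, "k": k, "n": n, "K": big_k, "N": big_n,
                     "pvalue": min(1.0, p)})
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} term(s) with no background genes: "
            f"{skipped[:10]}"
        )
    result = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "pvalue"])
    if len(result):
        result["fdr"] = bh_adjust(result["pvalue"].to_numpy())
        result = result.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
    else:
        result["fdr"] = pd.Series(dtype=float)
    return result


def _running_sum(scores: np.ndarray, hit_mask: np.ndarray,
                 weight_exponent: float) -> np.ndarray:
    n = len(scores)
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must hit a strict subset of the ranked list")
    if weight_exponent == 0:
        inc = np.where(hit_mask, 1.0 / n_hits, 0.0)
    else:
        w = np.abs(scores) ** weight_exponent
        total = w[hit_mask].sum()
        if total == 0:
            raise ValueError(
                "all member scores are zero; weighted running sum undefined"
            )
        inc = np.where(hit_mask, w / total, 0.0)
    dec = np.where(hit_mask, 0.0, 1.0 / (n - n_hits))
    return np.cumsum(inc - dec)


def _extremum(running: np.ndarray) -> float:
    i = int(np.argmax(np.abs(running)))  # first index on ties
    return float(running[i])


def gsea_preranked(ranked_scores: pd.Series, gene_set, set_name: str = "set",
                   weight_exponent: float = 1.0, n_perm: int = 1000,
                   seed: int | None = None) -> GseaResult:
    """Pre-ranked GSEA enrichment score with a gene-permutation p-value.

    Parameters
    ----------
    ranked_scores
        Gene-indexed ranking scores; sorted into descending order internally
        (ties keep their input order).  Gene ids must be unique.
    gene_set
        Member genes; the overlap with the ranked list must be non-empty and
        proper.
    weight_exponent
        p in |score|^p hit weighting; p = 0 is the unweighted (classic KS)
        statistic, p = 1 the standard weighted form.
    n_perm
        Gene-label permutations for the p-value; 0 skips it.  The p-value is
        (1 + #{|ES_perm| >= |ES|}) / (n_perm + 1), so it is bounded below by
        1/(n_perm+1).
    """
    if ranked_scores.index.duplicated().any():
        raise ValueError("ranked gene ids must be unique")
    ordered = ranked_scores.sort_values(ascending=False, kind="mergesort")
    genes = ordered.index.to_numpy()
    scores = ordered.to_numpy(dtype=float)
    members = set(gene_set)
    hit_mask = np.fromiter((g in members for g in genes), bool, len(genes))
    if not hit_mask.any():
        raise ValueError("gene set does not overlap the ranked list")
    running = _running_sum(scores, hit_mask, weight_exponent)
    es = _extremum(running)
    i_ext = int(np.argmax(np.abs(running)))
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_ext + 1], hit_mask[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext:], hit_mask[i_ext:]) if h]

    pvalue = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        n_hits = int(hit_mask.sum())
        exceed = 0
        for _ in range(n_perm):
            perm = np.zeros(len(genes), dtype=bool)
            perm[rng.choice(len(genes), size=n_hits, replace=False)] = True
            if abs(_extremum(_running_sum(scores, perm, weight_exponent))) >= abs(es):
                exceed += 1
        pvalue = (1 + exceed) / (n_perm + 1)

    return GseaResult(
        gene_set=set_name,
        es=es,
        running_sum=running,
        leading_edge=list(leading),
        pvalue=pvalue,
        n_perm=n_perm,
        hits=[g for g, h in zip(genes, hit_mask) if h],
    )
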