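"""Exact conditional count tests between two sample groups.

The test mirrors the classic exact strategy for two-group count data:
replicate counts within each group are scaled to a common effective library
size (TMM-corrected) and pooled, giving one observed split (y_A, y_B) of the
per-gene total t with group offsets N_A, N_B.

* ``mode="binomial"`` — conditional on t, y_A ~ Binomial(t, N_A/(N_A+N_B))
  under the null; two-sided p by tail doubling, capped at 1.
* ``mode="nb"`` — negative-binomial with common dispersion phi
  (variance = mu + phi mu^2).  The null conditional distribution of the split
  is obtained by enumerating s = 0..t with mass
  f(s; mu = t pi, phi) * f(t - s; mu = t (1 - pi), phi), renormalized; the
  two-sided p sums all outcomes no more probable than the observed one.
  phi = 0 reduces to the Poisson limit, whose conditional is exactly the
  binomial.

Fold changes are log2((y_A + prior) / N_A) - log2((y_B + prior) / N_B) with a
half-count prior so they stay finite; the prior never enters the test.
Both tails are computed from the same CDF expression in both orientations, so
swapping the groups negates log2FC and reproduces the p-value bit for bit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    REFERENCE_CONDITION,
    SENSORY_CONDITIONS,
    CountMatrix,
)
from .normalization import compute_tmm_factors


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_common_dispersion(counts, groups) -> float:
    """Method-of-moments common NB dispersion phi.

    ``groups`` is an iterable of sample-id lists.  Counts are scaled to a
    common library size; for every replicated group, each gene contributes
    (s^2 - m) / m^2 (sample variance vs mean); phi-hat is the mean over genes
    and groups, floored at 0.  Genes with tiny within-group means are skipped
    (the moment ratio is numerically unstable there).  Without any replicated
    group the estimate falls back to 0 (Poisson) with a warning.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    lib = df.sum(axis=0).astype(float)
    scaled = df / lib * lib.mean()
    contributions = []
    any_replicated = False
    for group in groups:
        group = list(group)
        if len(group) < 2:
            continue
        any_replicated = True
        sub = scaled[group].to_numpy()
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        ok = m >= 1.0
        if ok.any():
            contributions.append((s2[ok] - m[ok]) / m[ok] ** 2)
    if not any_replicated:
        warnings.warn("no group has replicates; dispersion set to 0 (Poisson)")
        return 0.0
    if not contributions:
        return 0.0
    return float(max(0.0, np.concatenate(contributions).mean()))


def _pool_groups(df: pd.DataFrame, group_a, group_b,
                 factors: pd.Series) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Scale each sample to the common effective library size and pool.

    Returns pooled integer counts y_A, y_B and offsets N_A, N_B (group size
    times the common library size).
    """
    lib = df.sum(axis=0).astype(float)
    eff = lib * factors
    involved = list(group_a) + list(group_b)
    common = float(np.exp(np.mean(np.log(eff[involved]))))
    scaled = df[involved] * (common / eff[involved])
    y_a = np.rint(scaled[list(group_a)].sum(axis=1).to_numpy()).astype(np.int64)
    y_b = np.rint(scaled[list(group_b)].sum(axis=1).to_numpy()).astype(np.int64)
    return y_a, y_b, len(group_a) * common, len(group_b) * common


def _binomial_pvalues(y_a: np.ndarray, t: np.ndarray, pi: float) -> np.ndarray:
    """Two-sided tail-doubled binomial p-values, vectorized over genes.

    Both tails use the same CDF form (upper tail via the mirrored binomial),
    which makes the group-swap symmetry exact in floating point.
    """
    lower = stats.binom.cdf(y_a, t, pi)
    upper = stats.binom.cdf(t - y_a, t, 1.0 - pi)
    p = 2.0 * np.minimum(lower, upper)
    p = np.minimum(p, 1.0)
    p[t == 0] = 1.0
    return p


def _nb_conditional_pvalue(y: int, t: int, pi: float, phi: float,
                           max_enum: int) -> float:
    """Minimum-likelihood two-sided p for the NB split of a fixed total.

    Enumerates the conditional support exactly; for totals beyond
    ``max_enum`` only a +/- 20 SD window around the mean is enumerated (the
    mass outside is far below double precision).
    """
    if t == 0:
        return 1.0
    mu_a, mu_b = t * pi, t * (1.0 - pi)
    if t <= max_enum:
        s = np.arange(t + 1)
    else:
        sd = np.sqrt(mu_a + phi * mu_a**2)
        lo = max(0, int(np.floor(mu_a - 20 * sd)))
        hi = min(t, int(np.ceil(mu_a + 20 * sd)))
        s = np.arange(lo, hi + 1)
        if y < lo or y > hi:
            s = np.concatenate([[y], s])
    if phi > 0:
        r = 1.0 / phi
        mass = stats.nbinom.pmf(s, r, r / (r + mu_a)) * stats.nbinom.pmf(
            t - s, r, r / (r + mu_b)
        )
    else:
        mass = stats.poisson.pmf(s, mu_a) * stats.poisson.pmf(t - s, mu_b)
    total = mass.sum()
    if total <= 0:
        return 1.0
    obs = mass[s == y][0]
    return float(min(1.0, mass[mass <= obs * (1.0 + 1e-10)].sum() / total))


def exact_test(counts, group_a, group_b, mode: str = "nb",
               dispersion: float | None = None, prior_count: float = 0.5,
               factors: pd.Series | None = None, max_enum: int = 10_000,
               contrast: str | None = None) -> pd.DataFrame:
    """Exact two-group test for every gene.

    Parameters
    ----------
    counts
        CountMatrix or genes x samples DataFrame.
    group_a, group_b
        Disjoint, non-empty sample-id lists; log2FC is A relative to B.
    mode
        ``"binomial"`` (Poisson/conditional-binomial null) or ``"nb"``
        (common-dispersion negative binomial).
    dispersion
        NB dispersion phi; estimated by moments from within-group replicates
        when omitted in nb mode.
    prior_count
        Half-count prior added to the pooled counts for log2FC only.
    factors
        TMM factors; computed from ``counts`` when omitted.

    Returns
    -------
    DataFrame indexed by gene with columns ``log2fc``, ``pvalue``, ``fdr``,
    ``significant`` (|log2FC| > 1 and FDR < 0.01) and ``contrast``.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError(f"groups overlap: {sorted(set(group_a) & set(group_b))}")
    missing = [s for s in group_a + group_b if s not in df.columns]
    if missing:
        raise KeyError(f"unknown sample id(s): {missing}")
    if mode not in ("binomial", "nb"):
        raise ValueError(f"unknown mode {mode!r}")
    if dispersion is not None and dispersion < 0:
        raise ValueError("dispersion must be >= 0")

    if factors is None:
        factors = compute_tmm_factors(df)
    y_a, y_b, n_a, n_b = _pool_groups(df, group_a, group_b, factors)
    t = y_a + y_b
    pi = n_a / (n_a + n_b)

    if mode == "nb" and dispersion is None:
        dispersion = estimate_common_dispersion(df, [group_a, group_b])

    if mode == "binomial" or dispersion == 0:
        # Poisson-limit conditional is exactly binomial; still honour the
        # mode-specific two-sided rule.
        if mode == "binomial":
            pvals = _binomial_pvalues(y_a, t, pi)
        else:
            pvals = np.array(
                [_nb_conditional_pvalue(y, tt, pi, 0.0, max_enum)
                 for y, tt in zip(y_a, t)]
            )
    else:
        pvals = np.array(
            [_nb_conditional_pvalue(y, tt, pi, dispersion, max_enum)
             for y, tt in zip(y_a, t)]
        )

    log2fc = np.log2((y_a + prior_count) / n_a) - np.log2((y_b + prior_count) / n_b)
    log2fc[t == 0] = 0.0
    fdr = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "significant": (np.abs(log2fc) > 1.0) & (fdr < 0.01),
            "contrast": contrast or "A vs B",
        },
        index=df.index,
    )
    return out


def classify_de(de_table: pd.DataFrame, lfc_threshold: float = 1.0,
                fdr_threshold: float = 0.01) -> tuple[int, int, int, pd.Series]:
    """Label genes up/down/ns by the strict |log2FC| > 1 and FDR < 0.01 rule.

    Returns (n_up, n_down, n_ns, labels).  Both inequalities are strict, as
    the rule is stated: a gene at exactly log2FC = 1 is not called.
    """
    if lfc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    sig = (de_table["log2fc"].abs() > lfc_threshold) & (
        de_table["fdr"] < fdr_threshold
    )
    labels = pd.Series("ns", index=de_table.index, name="de_label")
    labels[sig & (de_table["log2fc"] > 0)] = "up"
    labels[sig & (de_table["log2fc"] < 0)] = "down"
    return int((labels == "up").sum()), int((labels == "down").sum()), int(
        (labels == "ns").sum()
    ), labels


def fold_change_to_reference(cm: CountMatrix, reference_organ: str = "EP",
                             mode: str = "nb", dispersion: float | None = None,
                             prior_count: float = 0.5,
                             ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """log2FC-to-EP profile for every gene across the six sensory conditions.

    Runs the exact test of each organ x timepoint condition against the
    reference organ and collects the per-gene log2 fold changes into a
    genes x 6 profile table (columns in canonical condition order).

    Returns (profiles, DE tables keyed by condition).
    """
    if reference_organ != "EP":
        raise ValueError("the reference tissue in this design is EP")
    cond = cm.condition_of()
    ref_samples = cm.samples_of(REFERENCE_CONDITION)
    if not ref_samples:
        raise ValueError("no EP reference samples in the matrix")
    missing = [c for c in SENSORY_CONDITIONS if not (cond == c).any()]
    if missing:
        raise ValueError(f"missing condition(s): {missing}")

    factors = compute_tmm_factors(cm)
    if mode == "nb" and dispersion is None:
        groups = [cm.samples_of(c) for c in SENSORY_CONDITIONS] + [ref_samples]
        dispersion = estimate_common_dispersion(cm, groups)

    tables: dict[str, pd.DataFrame] = {}
    profile = {}
    for c in SENSORY_CONDITIONS:
        tab = exact_test(
            cm, cm.samples_of(c), ref_samples, mode=mode, dispersion=dispersion,
            prior_count=prior_count, factors=factors, contrast=f"{c} vs EP",
        )
        tables[c] = tab
        profile[c] = tab["log2fc"]
    profiles = pd.DataFrame(profile, columns=list(SENSORY_CONDITIONS))
    return profiles, tables


def write_de_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
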