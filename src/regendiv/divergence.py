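"""Calling genes whose AO-NM expression divergence grows during regeneration.

A gene is called divergent when, across the AO-vs-NM contrasts at 12 hpt,
24 hpt and untreated, it simultaneously satisfies four criteria:

1. significant AO/NM difference in untreated (mature) organs
   (|log2FC| > 1 and FDR < 0.01, both strict);
2. no AO/NM difference at 12 hpt (the freshly regenerating state);
3. a smaller AO/NM fold change at 24 hpt than in untreated organs
   (|log2FC_24| < |log2FC_untreated|);
4. a consistent direction: the gene is higher in AO than NM at both 24 hpt
   and untreated, or lower at both.

The passing set splits by the sign of the untreated log2FC into AO-high and
NM-high genes.  Criterion 2 defaults to "fails the significance rule"; a
stricter FDR-only null rule is available.

Group-level divergence is measured as the Euclidean distance between two
log2FC-to-EP profile vectors over the shared gene universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FLAG_COLUMNS = (
    "c1_sig_untreated",
    "c2_null_at_12h",
    "c3_shrinking_back_in_time",
    "c4_sign_consistent",
)


def _check_universe(de_12h: pd.DataFrame, de_24h: pd.DataFrame,
                    de_untreated: pd.DataFrame) -> pd.Index:
    u12, u24, uut = set(de_12h.index), set(de_24h.index), set(de_untreated.index)
    if not (u12 == u24 == uut):
        union = u12 | u24 | uut
        diffs = {
            "missing_from_12h": sorted(union - u12),
            "missing_from_24h": sorted(union - u24),
            "missing_from_untreated": sorted(union - uut),
        }
        raise ValueError(f"gene universe mismatch between DE tables: {diffs}")
    return de_untreated.index


def divergence_filter(de_12h: pd.DataFrame, de_24h: pd.DataFrame,
                      de_untreated: pd.DataFrame, lfc_threshold: float = 1.0,
                      fdr_threshold: float = 0.01,
                      null_rule: str = "not-significant") -> pd.DataFrame:
    """Evaluate the four divergence criteria for every gene.

    The three DE tables must share one gene universe and one contrast
    orientation (AO relative to NM; positive log2FC = higher in AO).

    Parameters
    ----------
    null_rule
        How "no difference at 12 hpt" is operationalized:
        ``"not-significant"`` (default) — the gene fails the significance
        rule, i.e. NOT(|log2FC| > lfc AND FDR < fdr); ``"fdr-only"`` —
        FDR_12h >= fdr_threshold regardless of fold change.

    Returns
    -------
    DataFrame indexed by gene with the four boolean criterion flags,
    ``passes`` (their conjunction) and ``direction`` (``AO_high`` /
    ``NM_high`` where passing, empty string otherwise).
    """
    if null_rule not in ("not-significant", "fdr-only"):
        raise ValueError(f"unknown null_rule {null_rule!r}")
    genes = _check_universe(de_12h, de_24h, de_untreated)
    d12 = de_12h.loc[genes]
    d24 = de_24h.loc[genes]
    dut = de_untreated.loc[genes]

    def significant(tab: pd.DataFrame) -> pd.Series:
        return (tab["log2fc"].abs() > lfc_threshold) & (tab["fdr"] < fdr_threshold)

    c1 = significant(dut)
    if null_rule == "not-significant":
        c2 = ~significant(d12)
    else:
        c2 = d12["fdr"] >= fdr_threshold
    c3 = d24["log2fc"].abs() < dut["log2fc"].abs()
    sign24 = np.sign(d24["log2fc"])
    signut = np.sign(dut["log2fc"])
    c4 = (sign24 == signut) & (sign24 != 0)  # zero log2FC has no direction
    passes = c1 & c2 & c3 & c4

    direction = pd.Series("", index=genes, name="direction")
    direction[passes & (dut["log2fc"] > 0)] = "AO_high"
    direction[passes & (dut["log2fc"] < 0)] = "NM_high"
    return pd.DataFrame(
        {
            "c1_sig_untreated": c1,
            "c2_null_at_12h": c2,
            "c3_shrinking_back_in_time": c3,
            "c4_sign_consistent": c4,
            "passes": passes,
            "direction": direction,
        },
        index=genes,
    )


def split_by_direction(calls: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    """(AO-high genes, NM-high genes) among the passing set; the two counts
    sum to the total passing count by construction."""
    ao = calls.index[(calls["passes"]) & (calls["direction"] == "AO_high")]
    nm = calls.index[(calls["passes"]) & (calls["direction"] == "NM_high")]
    return ao, nm


def group_distance(profiles_a, profiles_b) -> float:
    """Euclidean distance between two gene-indexed log2FC-to-EP vectors.

    Both vectors must be aligned to the same gene order; NaNs are rejected.
    """
    a = np.asarray(profiles_a, dtype=float)
    b = np.asarray(profiles_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("NaN entries in profiles")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def organ_distance_by_timepoint(profiles: pd.DataFrame) -> pd.Series:
    """AO-NM group distance at each timepoint from a genes x 6 profile table.

    Columns must be the canonical six conditions; the result is indexed by
    timepoint (12hpt, 24hpt, untreated).
    """
    out = {}
    for tp in ("12hpt", "24hpt", "untreated"):
        out[tp] = group_distance(profiles[f"AO_{tp}"], profiles[f"NM_{tp}"])
    return pd.Series(out, name="ao_nm_distance")


def write_divergence_calls(calls: pd.DataFrame, path) -> None:
    out = calls.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
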