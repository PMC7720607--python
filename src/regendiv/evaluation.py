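"""Self-evaluation studies of the pipeline on simulated study designs.

These routines run the full pipeline on data from :mod:`.synthetic_data`
and score it against the planted truth: divergence-call sensitivity and
precision on the standard dataset, the AO-NM group-distance ordering along
the regeneration course, and the type-I error of the exact test on Poisson
null data.  They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .containers import ALL_CONDITIONS
from .diffexpr import estimate_common_dispersion, exact_test, fold_change_to_reference
from .divergence import divergence_filter, organ_distance_by_timepoint, split_by_direction
from .synthetic_data import GENE_CLASSES, SimulationConfig, simulate_counts

_DIVERGENT = ("divergent_ao", "divergent_nm")


def _seed_stream(base_seed: int, n: int) -> list[int]:
    """n child seeds derived from one base seed, each below 2**31."""
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_divergence_recovery(seed: int,
                            config: SimulationConfig | None = None) -> dict:
    """One standard-dataset run: simulate, test, call divergence, score.

    Returns sensitivity/precision against the planted divergent classes plus
    the AO-high/NM-high split of the passing set.
    """
    cfg = config or SimulationConfig()
    cfg = dataclasses.replace(cfg, seed=seed)
    cm, truth = simulate_counts(cfg)
    phi = estimate_common_dispersion(cm, [cm.samples_of(c) for c in ALL_CONDITIONS])
    tables = {}
    for tp in ("12hpt", "24hpt", "untreated"):
        tables[tp] = exact_test(
            cm, cm.samples_of(f"AO_{tp}"), cm.samples_of(f"NM_{tp}"),
            mode="nb", dispersion=phi, contrast=f"AO_{tp} vs NM_{tp}",
        )
    calls = divergence_filter(tables["12hpt"], tables["24hpt"], tables["untreated"])
    called = set(calls.index[calls["passes"]])
    planted = set(truth.index[truth["gene_class"].isin(_DIVERGENT)])
    tp_n = len(called & planted)
    ao, nm = split_by_direction(calls)
    return {
        "seed": seed,
        "n_genes": cfg.n_genes,
        "n_planted": len(planted),
        "n_called": len(called),
        "true_positives": tp_n,
        "sensitivity": tp_n / len(planted) if planted else float("nan"),
        "precision": tp_n / len(called) if called else float("nan"),
        "n_ao_high": len(ao),
        "n_nm_high": len(nm),
        "dispersion_hat": phi,
    }


def divergence_recovery_study(base_seed: int = 0, n_seeds: int = 5,
                              config: SimulationConfig | None = None) -> dict:
    """Average divergence-call recovery over several simulated datasets."""
    runs = [run_divergence_recovery(s, config)
            for s in _seed_stream(base_seed, n_seeds)]
    return {
        "runs": runs,
        "mean_sensitivity": float(np.mean([r["sensitivity"] for r in runs])),
        "mean_precision": float(np.mean([r["precision"] for r in runs])),
        "direction_split_consistent": all(
            r["n_ao_high"] + r["n_nm_high"] == r["n_called"] for r in runs
        ),
    }


def distance_ordering_study(base_seed: int = 0, n_runs: int = 20,
                            n_genes: int = 2000) -> dict:
    """How often the AO-NM profile distance is larger untreated than at 12 hpt.

    Each run simulates a planted-divergence dataset, computes log2FC-to-EP
    profiles and compares the group Euclidean distances at the two ends of
    the regeneration course.
    """
    ordered = 0
    distances = []
    for s in _seed_stream(base_seed, n_runs):
        cfg = SimulationConfig(n_genes=n_genes, seed=s)
        cm, _ = simulate_counts(cfg)
        profiles, _ = fold_change_to_reference(cm)
        d = organ_distance_by_timepoint(profiles)
        distances.append({"seed": s, "d_12hpt": float(d["12hpt"]),
                          "d_24hpt": float(d["24hpt"]),
                          "d_untreated": float(d["untreated"])})
        if d["untreated"] > d["12hpt"]:
            ordered += 1
    return {
        "n_runs": n_runs,
        "n_genes": n_genes,
        "fraction_ordered": ordered / n_runs,
        "distances": distances,
    }


def type_one_error_study(seed: int = 0, n_genes: int = 10_000,
                         alpha: float = 0.05) -> dict:
    """Fraction of binomial-mode p-values below alpha on a Poisson null.

    No planted effects, dispersion 0, fixed library sizes, 2 vs 2 samples:
    the empirical rejection rate should sit near alpha (the exact test is
    mildly conservative through tail doubling and discreteness).
    """
    fractions = {c: 0.0 for c in GENE_CLASSES}
    fractions["background"] = 1.0
    cfg = SimulationConfig(
        n_genes=n_genes, dispersion=0.0, lib_size_cv=0.0,
        class_fractions=fractions, seed=seed,
    )
    cm, _ = simulate_counts(cfg)
    tab = exact_test(
        cm, cm.samples_of("AO_12hpt"), cm.samples_of("NM_12hpt"),
        mode="binomial", contrast="null AO_12hpt vs NM_12hpt",
    )
    frac = float((tab["pvalue"] < alpha).mean())
    se = float(np.sqrt(alpha * (1 - alpha) / n_genes))
    return {"n_genes": n_genes, "alpha": alpha, "fraction_rejected": frac,
            "standard_error": se, "z": (frac - alpha) / se}
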