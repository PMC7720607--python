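"""Negative-binomial count simulation emulating the regeneration study design.

Seven tissue groups (AO and NM at 12 hpt, 24 hpt and untreated, plus EP) with
a fixed number of replicates each.  Genes fall into six planted classes:

``background``
    identical mean in every condition (no signal).
``common_enriched``
    elevated by ``effect_lfc`` log2 units over EP in all six sensory
    conditions (shared sensory-organ program).
``ao_specific`` / ``nm_specific``
    elevated by ``effect_lfc`` in one organ at all timepoints.
``divergent_ao`` / ``divergent_nm``
    the favoured organ climbs away from the other along the regeneration
    course: the true AO-NM log2 difference is exactly 0 at 12 hpt,
    ``divergence_delta``/2 at 24 hpt and ``divergence_delta`` when untreated
    (mature organs).  This is the minimal trajectory an expression-divergence
    caller should recover.

Counts are independent negative binomials with variance mu + phi * mu**2,
scaled per sample by a log-normal library-size factor.  A truth table records
every gene's class, per-condition true mean and true AO-NM log2 difference at
each timepoint, so recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ALL_CONDITIONS,
    METADATA_COLUMNS,
    REFERENCE_CONDITION,
    SENSORY_CONDITIONS,
    CountMatrix,
)

GENE_CLASSES = (
    "background",
    "common_enriched",
    "ao_specific",
    "nm_specific",
    "divergent_ao",
    "divergent_nm",
)

_TIMEPOINT_FRACTION = {"12hpt": 0.0, "24hpt": 0.5, "untreated": 1.0}


@dataclass
class SimulationConfig:
    """Study-design parameters for the count simulator.

    Defaults encode the standard synthetic dataset used throughout the test
    suite: 10,000 genes, 2 replicates per condition, NB dispersion phi = 0.1,
    organ-specific effects of 3 log2 units and a planted divergence of
    delta = 3 log2 units reached at the untreated (mature) timepoint.
    Baseline per-gene means are log-normal, floored at ``baseline_floor`` so
    every gene is comfortably detectable at desk-scale depth.
    """

    n_genes: int = 10_000
    n_reps: int = 2
    lib_size_mean: float | None = None  # None: implied by the gene means
    lib_size_cv: float = 0.1
    dispersion: float = 0.1  # NB phi, variance = mu + phi mu^2
    baseline_logmean_mu: float = float(np.log(500.0))
    baseline_logmean_sigma: float = 0.8
    baseline_floor: float = 200.0
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "background": 0.925,
            "common_enriched": 0.02,
            "ao_specific": 0.02,
            "nm_specific": 0.02,
            "divergent_ao": 0.01,
            "divergent_nm": 0.005,
        }
    )
    effect_lfc: float = 3.0
    divergence_delta: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total!r}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("effect_lfc", "divergence_delta", "lib_size_cv",
                     "baseline_logmean_mu", "baseline_logmean_sigma"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.lib_size_mean is not None and not np.isfinite(self.lib_size_mean):
            raise ValueError("lib_size_mean must be finite")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _class_counts(n_genes: int, fractions: dict[str, float]) -> dict[str, int]:
    """Integer class sizes by largest-remainder apportionment (deterministic)."""
    raw = {c: n_genes * fractions.get(c, 0.0) for c in GENE_CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n_genes - sum(counts.values())
    remainders = sorted(
        GENE_CLASSES, key=lambda c: (-(raw[c] - counts[c]), GENE_CLASSES.index(c))
    )
    for c in remainders[:short]:
        counts[c] += 1
    return counts


def _condition_multiplier(gene_class: str, condition: str, effect_lfc: float,
                          delta: float) -> float:
    """Fold multiplier over the baseline mean for one gene class/condition."""
    if condition == REFERENCE_CONDITION or gene_class == "background":
        return 1.0
    organ, timepoint = condition.split("_")
    if gene_class == "common_enriched":
        return 2.0 ** effect_lfc
    if gene_class == "ao_specific":
        return 2.0 ** effect_lfc if organ == "AO" else 1.0
    if gene_class == "nm_specific":
        return 2.0 ** effect_lfc if organ == "NM" else 1.0
    if gene_class == "divergent_ao":
        return 2.0 ** (delta * _TIMEPOINT_FRACTION[timepoint]) if organ == "AO" else 1.0
    if gene_class == "divergent_nm":
        return 2.0 ** (delta * _TIMEPOINT_FRACTION[timepoint]) if organ == "NM" else 1.0
    raise ValueError(gene_class)


def true_mean_matrix(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene true mean for each of the 7 conditions, plus class labels.

    Deterministic given ``config.seed``; the baseline draw consumes the first
    block of the RNG stream, so it matches :func:`simulate_counts`.
    """
    rng = np.random.default_rng(config.seed)
    baseline = rng.lognormal(
        config.baseline_logmean_mu, config.baseline_logmean_sigma, config.n_genes
    )
    if config.lib_size_mean is not None:
        baseline *= config.lib_size_mean / baseline.sum()
    baseline = np.maximum(baseline, config.baseline_floor)

    sizes = _class_counts(config.n_genes, config.class_fractions)
    labels = np.concatenate(
        [np.repeat(c, sizes[c]) for c in GENE_CLASSES]
    )
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    classes = pd.Series(labels, index=gene_ids, name="gene_class")

    mult = np.empty((config.n_genes, len(ALL_CONDITIONS)))
    for j, cond in enumerate(ALL_CONDITIONS):
        per_class = {
            c: _condition_multiplier(c, cond, config.effect_lfc, config.divergence_delta)
            for c in GENE_CLASSES
        }
        mult[:, j] = [per_class[c] for c in labels]
    means = pd.DataFrame(
        baseline[:, None] * mult, index=gene_ids, columns=list(ALL_CONDITIONS)
    )
    return means, classes


def _truth_table(means: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    truth = pd.DataFrame({"gene_class": classes})
    for cond in ALL_CONDITIONS:
        truth[f"mean_{cond}"] = means[cond]
    for tp in ("12hpt", "24hpt", "untreated"):
        truth[f"true_lfc_{tp}"] = np.log2(means[f"AO_{tp}"] / means[f"NM_{tp}"])
    truth.index.name = "gene_id"
    return truth


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a count matrix and its truth table from the study design.

    Returns
    -------
    (CountMatrix, truth table)
        The truth table is indexed by gene id with the class label, the true
        mean in each condition, and the true AO-NM log2 difference at each
        timepoint.  Identical config (including seed) gives identical output.
    """
    means, classes = true_mean_matrix(config)
    rng = np.random.default_rng(config.seed)
    rng.lognormal(  # skip the baseline block so sampling stays aligned
        config.baseline_logmean_mu, config.baseline_logmean_sigma, config.n_genes
    )

    sample_ids, organs, timepoints, replicates = [], [], [], []
    for cond in ALL_CONDITIONS:
        organ = cond.split("_")[0] if cond != REFERENCE_CONDITION else "EP"
        tp = cond.split("_")[1] if cond != REFERENCE_CONDITION else "na"
        for r in range(1, config.n_reps + 1):
            sample_ids.append(f"{cond}_r{r}")
            organs.append(organ)
            timepoints.append(tp)
            replicates.append(r)
    metadata = pd.DataFrame(
        {"organ": organs, "timepoint": timepoints, "replicate": replicates},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    if config.lib_size_cv > 0:
        sigma2 = np.log1p(config.lib_size_cv**2)
        lib_factors = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), len(sample_ids))
    else:
        lib_factors = np.ones(len(sample_ids))

    counts = np.empty((config.n_genes, len(sample_ids)), dtype=np.int64)
    phi = config.dispersion
    for j, sid in enumerate(sample_ids):
        cond = "_".join(sid.split("_")[:-1])
        mu = means[cond].to_numpy() * lib_factors[j]
        if phi == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / phi
            p = r / (r + mu)
            counts[:, j] = rng.negative_binomial(r, p)

    cm = CountMatrix(
        pd.DataFrame(counts, index=means.index, columns=sample_ids), metadata
    )
    return cm, _truth_table(means, classes)


# -- plain-TSV IO -------------------------------------------------------------


def write_counts(cm: CountMatrix, counts_path, metadata_path=None) -> None:
    """Write counts (and optionally metadata) as tab-delimited text."""
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    if metadata_path is not None:
        md = cm.metadata.copy()
        md.index.name = "sample_id"
        md.to_csv(metadata_path, sep="\t")


def read_counts(counts_path, metadata_path=None,
                expected_samples=None) -> CountMatrix | pd.DataFrame:
    """Read a counts TSV (gene ids in the first column, sample ids as header).

    With ``metadata_path`` the result is a validated :class:`CountMatrix`;
    without it, a plain integer DataFrame.  Non-integer cells and duplicate
    gene ids are rejected with the offending row/column named; when
    ``expected_samples`` is given, any missing header column raises an error
    listing the expected sample ids.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in {counts_path}: {dupes}")
    if expected_samples is not None:
        missing = [s for s in expected_samples if s not in df.columns]
        if missing:
            raise ValueError(
                f"count file {counts_path} is missing sample column(s) {missing}; "
                f"expected samples: {list(expected_samples)}"
            )
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        frac = df != np.floor(df)
        if frac.to_numpy().any():
            gene = frac.any(axis=1).idxmax()
            sample = frac.loc[gene].idxmax()
            raise ValueError(
                f"non-integer count at gene {gene!r}, sample {sample!r}: "
                f"{df.loc[gene, sample]!r}"
            )
        df = df.astype(np.int64)
    if metadata_path is None:
        return df
    md = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return CountMatrix(df, md)


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the truth table as TSV (gene ids in the first column)."""
    out = truth.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
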