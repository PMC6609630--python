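"""Synthetic study-level abundance data with known ground truth.

Each simulated laboratory j receives a multiplicative bias
``b_j ~ lognormal(0, bias_sd_log)`` and measures ``n_j`` donors whose
abundances are lognormal with geometric mean ``true_gm * b_j`` and
within-study geometric CV ``gcv_within``; the study then reports its sample
mean, SD and n, exactly the summary statistics a published abundance paper
would.  With the default bias the generator reproduces the regime the
curated literature shows: inter-laboratory spread exceeding the biological
spread within any one laboratory.

The population-level (all labs, all donors) distribution is lognormal with
log-variance ``sigma_within**2 + bias_sd_log**2``, which gives closed forms
for the quantities estimators should recover:

* arithmetic population mean ``true_gm * exp(sigma_total**2 / 2)`` —
  the target of the sample-size-weighted mean;
* total CV ``sqrt(exp(sigma_total**2) - 1)`` — the target of the pooled
  (method II) %CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .records import ProteinAbundanceRecord, StudyObservation, StudySet

__all__ = [
    "SynthConfig",
    "generate_study_set",
    "generate_repository_fixture",
    "expected_arithmetic_mean",
    "expected_total_cv_pct",
]


@dataclass
class SynthConfig:
    """Ground-truth parameters for one simulated study set.

    Defaults describe a typical hepatic UGT meta-analysis: a geometric mean
    of 40 pmol/mg, 50% biological (within-study) geometric CV, lab bias with
    log-SD 0.5, ten laboratories of 5–40 donors each.
    """

    true_geometric_mean: float = 40.0
    gcv_within: float = 0.5
    bias_sd_log: float = 0.5
    k: int = 10
    n_range: tuple[int, int] = (5, 40)
    seed: int = 0
    protein: str = "SYNTH1"
    tissue: str = "liver"

    def __post_init__(self) -> None:
        if self.true_geometric_mean <= 0:
            raise ValueError("true_geometric_mean must be positive")
        if self.gcv_within < 0 or self.bias_sd_log < 0:
            raise ValueError("variability parameters must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_range[0] < 2 or self.n_range[1] < self.n_range[0]:
            raise ValueError("n_range must satisfy 2 <= min <= max")

    @property
    def sigma_within(self) -> float:
        return math.sqrt(math.log(self.gcv_within**2 + 1.0))

    @property
    def sigma_total(self) -> float:
        return math.sqrt(self.sigma_within**2 + self.bias_sd_log**2)


def expected_arithmetic_mean(cfg: SynthConfig) -> float:
    """Population arithmetic mean implied by the generator."""
    return cfg.true_geometric_mean * math.exp(cfg.sigma_total**2 / 2.0)


def expected_total_cv_pct(cfg: SynthConfig) -> float:
    """Population %CV pooling donors across all laboratories."""
    return 100.0 * math.sqrt(math.exp(cfg.sigma_total**2) - 1.0)


def _study_rng(seed: int, j: int) -> np.random.Generator:
    # counter-based substreams: study j is identical whatever k is, so
    # enlarging a simulated literature never rewrites its early studies
    return np.random.default_rng([seed, j])


def generate_study_set(cfg: SynthConfig) -> tuple[StudySet, dict]:
    """Simulate one per-protein study set plus its ground-truth record."""
    observations = []
    truth_bias = []
    mu = math.log(cfg.true_geometric_mean)
    for j in range(cfg.k):
        rng = _study_rng(cfg.seed, j)
        bias = float(rng.lognormal(0.0, cfg.bias_sd_log)) \
            if cfg.bias_sd_log > 0 else 1.0
        n_j = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        if cfg.sigma_within > 0:
            values = rng.lognormal(mu + math.log(bias), cfg.sigma_within,
                                   size=n_j)
            mean = float(np.mean(values))
            sd = float(np.std(values, ddof=0))
        else:
            mean = cfg.true_geometric_mean * bias
            sd = 0.0
        truth_bias.append(bias)
        observations.append(StudyObservation(
            label=f"Lab{j + 1}, {2000 + j}", mean=mean, sd=sd, n=n_j,
            source=f"Lab{j + 1}",
        ))
    truth = {
        "true_geometric_mean": cfg.true_geometric_mean,
        "sigma_within": cfg.sigma_within,
        "bias_sd_log": cfg.bias_sd_log,
        "study_bias": truth_bias,
        "expected_arithmetic_mean": expected_arithmetic_mean(cfg),
        "expected_total_cv_pct": expected_total_cv_pct(cfg),
        "seed": cfg.seed,
    }
    return StudySet(protein=cfg.protein, tissue=cfg.tissue,
                    observations=observations), truth


def generate_repository_fixture(
    n_proteins: int = 2,
    records_per_protein: int = 5,
    frac_pooled: float = 0.0,
    frac_relative: float = 0.0,
    frac_mrna: float = 0.0,
    seed: int = 0,
    base_config: SynthConfig | None = None,
) -> tuple[list[ProteinAbundanceRecord], dict]:
    """Build a contaminated repository with known exclusion counts.

    The first ``frac_pooled + frac_relative + frac_mrna`` share of each
    protein's records is turned, in order, into pooled-donor, relative-unit
    and mRNA rows; the remainder stays eligible.  Returns the records plus a
    dict of the per-criterion counts the inclusion filter must report.
    """
    if frac_pooled + frac_relative + frac_mrna > 1.0 + 1e-9:
        raise ValueError("contamination fractions must sum to <= 1")
    base = base_config or SynthConfig()
    rng = np.random.default_rng(seed)
    records: list[ProteinAbundanceRecord] = []
    n_pooled = n_rel = n_mrna = 0
    for p in range(n_proteins):
        cfg = SynthConfig(
            true_geometric_mean=base.true_geometric_mean * (1 + 0.5 * p),
            gcv_within=base.gcv_within, bias_sd_log=base.bias_sd_log,
            k=records_per_protein, n_range=base.n_range,
            seed=int(rng.integers(2**31)), protein=f"SYNTH{p + 1}",
        )
        study_set, _ = generate_study_set(cfg)
        quota_pooled = round(frac_pooled * records_per_protein)
        quota_rel = round(frac_relative * records_per_protein)
        quota_mrna = round(frac_mrna * records_per_protein)
        for i, obs in enumerate(study_set.observations):
            kwargs: dict = {}
            if i < quota_pooled:
                kwargs["pooled"] = True
                n_pooled += 1
            elif i < quota_pooled + quota_rel:
                kwargs.update(quant_mode="relative", unit="arbitrary units")
                n_rel += 1
            elif i < quota_pooled + quota_rel + quota_mrna:
                kwargs["method"] = "mRNA"
                n_mrna += 1
            records.append(ProteinAbundanceRecord(
                protein_name=cfg.protein,
                gene_name=cfg.protein,
                tissue="liver",
                value=obs.mean,
                value_sd=obs.sd,
                n_donors=obs.n,
                source=obs.source,
                year=2000 + i,
                **kwargs,
            ))
    truth = {
        "n_records": len(records),
        "pooled": n_pooled,
        "relative": n_rel,
        "mrna": n_mrna,
        "eligible": len(records) - n_pooled - n_rel - n_mrna,
    }
    return records, truth
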