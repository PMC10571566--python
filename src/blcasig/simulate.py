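"""Synthetic bladder-cancer cohorts with planted expression signal.

The generator emulates the statistical structure a SCAN-normalized
microarray cohort presents to the downstream analysis: non-negative,
right-skewed expression values with occasional outliers; a large mass of
near-zero uninformative genes that a mean-expression filter removes; a
small set of planted genes whose location differs between the two classes
of a binary clinical endpoint; right-censored survival times with a
group-dependent hazard; and categorical clinical fields (therapy-response
codes, predominant/secondary histology, AJCC T-stage).

Expression values follow a two-component mixture: "low" genes have mean
~U(0.01, 0.5) and "expressed" genes mean ~U(0.7, 2.0); per-sample values
are gamma-distributed around the gene mean (shape 4, so the per-gene SD
is half the mean), with a small fraction of entries inflated to mimic
outliers.  Event labels are drawn first; planted genes receive a location
shift of ``effect_size`` expression units in the event class, with a
random sign per gene.  Censoring is administrative: a single cutoff time
chosen as the (1 - censor_rate) quantile of the drawn event times.

All randomness derives from one master seed through numpy's
``SeedSequence`` spawning mechanism (PCG64 bit generator), so cohorts are
bit-identical across runs and platforms for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError

T_STAGE_LABELS = (
    "Ta", "Tis", "T1", "T2", "T2a", "T2b", "T3", "T3a", "T3b", "T4", "T4a", "T4b",
)

#: weights roughly favouring muscle-invasive stages, as in a NAC cohort
_T_STAGE_WEIGHTS = (
    0.03, 0.02, 0.10, 0.20, 0.12, 0.10, 0.08, 0.10, 0.10, 0.05, 0.05, 0.05,
)

CLINICAL_COLUMNS = (
    "sample_id", "turbt_path", "therapy_response_code", "predominant_histology",
    "secondary_histology", "t_stage", "progression_event", "time_to_event_days",
    "followup_days",
)

_GAMMA_SHAPE = 4.0          # per-gene SD = mean / 2
_OUTLIER_FRACTION = 0.005   # entries inflated to emulate normalization outliers
_MISSING_SECONDARY = 0.4    # fraction of samples with no secondary histology
_NEUROENDOCRINE_FRACTION = 0.04


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults are the study conditions the package is exercised under: a
    cohort of 120 patients and 2,000 genes (a scaled-down surrogate for a
    46,050-gene array), 20 planted informative genes with a one-unit
    (roughly one pooled-SD) location shift, 40% event prevalence, half of
    the genes in the filterable near-zero mass, an exponential baseline
    hazard of 1/1000 events per day tripled in the event-positive group,
    and 30% administrative censoring.
    """

    n_samples: int = 120
    n_genes: int = 2000
    n_informative: int = 20
    effect_size: float = 1.0
    prevalence: float = 0.4
    frac_low_expressed: float = 0.5
    baseline_hazard: float = 1e-3
    hazard_ratio_event: float = 3.0
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ConfigError(
                f"n_informative ({self.n_informative}) exceeds n_genes ({self.n_genes})"
            )
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        n_pos = _round_half_up(self.prevalence * self.n_samples)
        if n_pos < 2 or self.n_samples - n_pos < 2:
            raise ConfigError(
                "prevalence yields fewer than 2 samples in one endpoint class"
            )
        if not 0.0 <= self.frac_low_expressed <= 1.0:
            raise ConfigError("frac_low_expressed must lie in [0, 1]")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be non-negative")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError("censor_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0 or self.hazard_ratio_event <= 0:
            raise ConfigError("hazards must be positive")


@dataclass
class SyntheticCohort:
    """A generated cohort together with its ground truth."""

    expression: pd.DataFrame            # genes x samples
    clinical: pd.DataFrame              # indexed by sample_id
    truth: list[str]                    # planted informative gene IDs
    truth_direction: dict[str, str]     # gene -> "over" | "under" (in event class)
    event: pd.Series                    # latent binary endpoint per sample
    config: SimConfig


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw a cohort under ``config``; deterministic given ``config.seed``."""
    n, g = config.n_samples, config.n_genes
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_assign = np.random.default_rng(streams[0])
    rng_expr = np.random.default_rng(streams[1])
    rng_clin = np.random.default_rng(streams[2])
    rng_surv = np.random.default_rng(streams[3])
    rng_out = np.random.default_rng(streams[4])

    sample_ids = [f"S{i:03d}" for i in range(n)]
    gene_ids = [f"G{i:05d}" for i in range(g)]

    # endpoint labels: fixed class sizes, randomly assigned to samples
    n_pos = _round_half_up(config.prevalence * n)
    event = np.zeros(n, dtype=int)
    event[rng_assign.choice(n, size=n_pos, replace=False)] = 1

    # gene tiers: per-gene Bernoulli membership in the near-zero mass
    low = rng_assign.random(g) < config.frac_low_expressed
    means = np.where(
        low,
        rng_assign.uniform(0.01, 0.5, size=g),
        rng_assign.uniform(0.7, 2.0, size=g),
    )

    expressed_idx = np.flatnonzero(~low)
    if expressed_idx.size < config.n_informative:
        raise ConfigError(
            "not enough expressed genes to plant the requested informative set"
        )
    planted = np.sort(rng_assign.choice(expressed_idx, size=config.n_informative,
                                        replace=False))
    # keep room for a downward shift: planted means redrawn in the upper band
    means[planted] = rng_assign.uniform(1.2, 2.0, size=planted.size)
    signs = rng_assign.choice([1.0, -1.0], size=planted.size)

    # per-gene, per-sample target means (genes x samples)
    mu = np.repeat(means[:, None], n, axis=1)
    shift = signs * config.effect_size
    mu[planted[:, None], np.flatnonzero(event)[None, :]] += shift[:, None]
    np.clip(mu, 0.05, None, out=mu)

    values = rng_expr.gamma(shape=_GAMMA_SHAPE, scale=mu / _GAMMA_SHAPE)
    outliers = rng_out.random(values.shape) < _OUTLIER_FRACTION
    values[outliers] *= rng_out.uniform(3.0, 8.0, size=int(outliers.sum()))

    expression = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    expression.index.name = "gene_id"

    # survival: exponential with a multiplicative hazard in the event class,
    # administratively censored at the (1 - censor_rate) quantile
    rate = config.baseline_hazard * np.where(event == 1,
                                             config.hazard_ratio_event, 1.0)
    latent = rng_surv.exponential(1.0 / rate)
    if config.censor_rate > 0:
        cutoff = float(np.quantile(latent, 1.0 - config.censor_rate))
    else:
        cutoff = float(latent.max())
    observed = np.minimum(latent, cutoff)
    progression = (latent <= cutoff).astype(int)

    response_code = np.where(
        event == 1,
        rng_clin.choice([2, 3], size=n),   # stable / progressive disease
        rng_clin.choice([0, 1], size=n),   # partial / complete response
    )
    predominant = np.where(
        rng_clin.random(n) < _NEUROENDOCRINE_FRACTION,
        "neuroendocrine", "urothelial",
    )
    secondary = []
    for _ in range(n):
        if rng_clin.random() < _MISSING_SECONDARY:
            secondary.append("")
        else:
            k = int(rng_clin.integers(1, 3))
            codes = sorted(rng_clin.choice(np.arange(1, 9), size=k, replace=False))
            secondary.append("+".join(str(c) for c in codes))
    t_stage = rng_clin.choice(T_STAGE_LABELS, size=n, p=_T_STAGE_WEIGHTS)

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "turbt_path": [f"SR-{i:04d}" for i in range(n)],
            "therapy_response_code": response_code,
            "predominant_histology": predominant,
            "secondary_histology": secondary,
            "t_stage": t_stage,
            "progression_event": progression,
            "time_to_event_days": np.round(observed, 6),
            "followup_days": np.round(observed, 6),
        }
    ).set_index("sample_id")

    truth = [gene_ids[i] for i in planted]
    truth_direction = {
        gene_ids[i]: ("over" if s > 0 else "under")
        for i, s in zip(planted, signs)
    }
    return SyntheticCohort(
        expression=expression,
        clinical=clinical,
        truth=truth,
        truth_direction=truth_direction,
        event=pd.Series(event, index=sample_ids, name="event"),
        config=config,
    )


def write_fixtures(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as the plain-text files the ingest readers consume.

    Emits ``expression.tsv`` (genes x samples, columns named after CEL
    files), ``clinical.csv``, ``metadata.csv`` (external ID to CEL-file
    map) and ``truth.tsv``.  Values are written with six decimals, so a
    read-back cohort matches the in-memory one to that precision.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / fname for name, fname in [
        ("expression", "expression.tsv"),
        ("clinical", "clinical.csv"),
        ("metadata", "metadata.csv"),
        ("truth", "truth.tsv"),
    ]}

    expr = cohort.expression.copy()
    cel_names = {sid: f"{sid}.CEL" for sid in expr.columns}
    expr.columns = [cel_names[c] for c in expr.columns]
    expr.to_csv(paths["expression"], sep="\t", float_format="%.6f")

    cohort.clinical.to_csv(paths["clinical"], float_format="%.6f")

    pd.DataFrame(
        {"external_id": list(cel_names), "cel_file": list(cel_names.values())}
    ).to_csv(paths["metadata"], index=False)

    pd.DataFrame(
        {"gene_id": cohort.truth,
         "direction": [cohort.truth_direction[gid] for gid in cohort.truth]}
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def config_from_dict(d: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a plain dict (e.g. a YAML section)."""
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
    return SimConfig(**d)
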