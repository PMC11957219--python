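"""Synthetic biobank-style cohorts with a known CNV → sleep → cognition structure.

The generator emulates the five inputs the downstream analyses consume: a
gene model with LOEUF constraint scores, per-individual CNV calls, a
recurrent-locus table, carrier implants at those loci, and a phenotype /
covariate table.  The phenotype model encodes the study conditions the
analyses are designed to detect:

* CNV burden (Σ1/LOEUF, deletions + duplications) scales the *magnitude* of
  an individual's deviation from the cohort mean sleep duration; the
  direction of the deviation is an independent fair coin.  This produces a
  U-shaped burden–sleep relationship with a zero linear effect.
* Cognition decreases linearly with deletion and duplication burden
  (direct effects) and with the sleep deviation magnitude (the mediated
  path), so the implied proportion mediated is θλ/(β+θλ) for each type.
* Probable insomnia is Bernoulli noise, independent of burden — a null
  effect by construction.

Self-reported sleep is rounded to whole hours; a configurable accelerometer
subset keeps the continuous value and gains a sleep-efficiency measure.
A small fraction of out-of-range records is injected so the QC filters have
work to do in every run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import burden as burden_mod

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "simulate_genome",
    "simulate_cnvs",
    "simulate_recurrent_loci",
    "implant_recurrent_cnvs",
    "simulate_phenotypes",
    "simulate_cohort",
]

# substream ids: one global seed derives independent per-stage generators,
# so re-running one stage never perturbs another's randomness
_STREAMS = {
    "genome": 0,
    "cnvs": 1,
    "loci": 2,
    "implant": 3,
    "phenotypes": 4,
}

INSOMNIA_CATEGORIES = ("never_rarely", "sometimes", "usually", "prefer_not_answer")


class ConfigError(ValueError):
    """Raised when a simulation configuration is infeasible or invalid."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Effect-size defaults mirror the published genome-wide estimates
    (cognition ~ burden: β = 0.04 per unit Σ1/LOEUF for deletions, 0.0919
    for duplications) and Table-1 style descriptives (mean self-reported
    sleep 7.15 h, total SD ≈ 1.09 h, insomnia prevalence 0.28,
    accelerometer subsample fraction 0.19).  theta_sleep × lambda_sleep_cog
    is calibrated so the implied proportion mediated for deletions is 4.5%.
    """

    n_individuals: int = 20_000
    n_genes: int = 2_000
    genome_length: int = 200_000_000
    chrom: str = "1"
    # ("uniform", low, high) or ("beta", a, b) rescaled onto [0.03, 2]
    loeuf_distribution: tuple = ("uniform", 0.03, 2.0)
    gene_length_range: tuple = (2_000, 100_000)
    cnv_rate: float = 0.3  # mean events per individual per type (Poisson)
    # ("lognormal", mu, sigma) in bp, or ("uniform", low, high)
    cnv_length_distribution: tuple = ("lognormal", math.log(5e4), 0.8)
    min_cnv_length: int = 1_000
    beta_cog_del: float = 0.04    # z lost per unit deletion Σ1/LOEUF
    beta_cog_dup: float = 0.0919  # z lost per unit duplication Σ1/LOEUF
    theta_sleep: float = 0.02     # hours of |sleep deviation| per unit Σ1/LOEUF
    lambda_sleep_cog: float = 0.0943  # z lost per hour of |sleep deviation|
    mean_sleep: float = 7.15
    sleep_noise_sd: float = 0.1       # symmetric reporting noise (hours)
    deviation_noise_scale: float = 1.0  # half-normal scale of deviation noise (hours)
    insomnia_base_rate: float = 0.28
    insomnia_burden_effect: float = 0.0  # log-odds per unit Σ1/LOEUF (null default)
    prefer_not_answer_rate: float = 0.01
    accel_fraction: float = 0.19
    efficiency_mean: float = 0.76
    efficiency_sd: float = 0.07
    outlier_rate: float = 0.01  # out-of-range sleep records injected for QC
    medication_rate: float = 0.15
    n_recurrent_loci: int = 10
    recurrent_locus_genes: int = 3
    recurrent_carrier_freq: float = 0.002
    recurrent_effect_cog: float = 0.0  # direct z shift in carriers (beyond burden path)
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ConfigError("n_individuals must be positive")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.cnv_rate < 0:
            raise ConfigError("cnv_rate must be >= 0")
        if self.sleep_noise_sd <= 0:
            raise ConfigError("sleep_noise_sd must be > 0")
        if not 0 <= self.outlier_rate < 1:
            raise ConfigError("outlier_rate must be in [0, 1)")
        if self.gene_length_range[0] * self.n_genes > self.genome_length:
            raise ConfigError(
                "infeasible packing: n_genes * minimal gene length exceeds genome_length"
            )

    def rng(self, stage: str) -> np.random.Generator:
        """Per-stage generator derived from the single global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=(int(self.seed), _STREAMS[stage]))
        )

    @property
    def implied_prop_mediated_del(self) -> float:
        return _implied_prop(self.theta_sleep, self.lambda_sleep_cog, self.beta_cog_del)

    @property
    def implied_prop_mediated_dup(self) -> float:
        return _implied_prop(self.theta_sleep, self.lambda_sleep_cog, self.beta_cog_dup)

    def to_dict(self) -> dict:
        return asdict(self)


def _implied_prop(theta: float, lam: float, beta: float) -> float:
    denom = beta + theta * lam
    if denom == 0:
        return float("nan")
    return theta * lam / denom


@dataclass
class GroundTruth:
    """Latent quantities of a simulated cohort, for parameter-recovery tests."""

    burden_del: np.ndarray  # true Σ1/LOEUF per individual, deletions
    burden_dup: np.ndarray
    deviation: np.ndarray   # d_i >= 0, hours of deviation from mean sleep
    sign: np.ndarray        # ±1 direction of the deviation
    implied_prop_mediated_del: float = float("nan")
    implied_prop_mediated_dup: float = float("nan")


@dataclass
class SimResult:
    genes: pd.DataFrame
    calls: pd.DataFrame
    loci: pd.DataFrame
    carriers: pd.DataFrame
    burden: pd.DataFrame
    cohort: pd.DataFrame
    truth: GroundTruth
    config: SimConfig = field(repr=False, default=None)


def _draw(rng: np.random.Generator, spec: tuple, size: int) -> np.ndarray:
    name = spec[0]
    if name == "uniform":
        return rng.uniform(spec[1], spec[2], size)
    if name == "lognormal":
        return rng.lognormal(spec[1], spec[2], size)
    if name == "beta":
        lo, hi = burden_mod.LOEUF_MIN, burden_mod.LOEUF_MAX
        return lo + (hi - lo) * rng.beta(spec[1], spec[2], size)
    raise ConfigError(f"unknown distribution spec: {spec!r}")


def simulate_genome(config: SimConfig) -> pd.DataFrame:
    """Non-overlapping genes on one synthetic chromosome, with LOEUF values."""
    config.validate()
    rng = config.rng("genome")
    n = config.n_genes
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, n)
    slack = config.genome_length - int(lengths.sum())
    if slack < 0:
        raise ConfigError(
            f"infeasible packing: {n} genes need {lengths.sum()} bp "
            f"but genome_length is {config.genome_length}"
        )
    gaps = np.sort(rng.integers(0, slack + 1, n))
    starts = gaps + np.concatenate([[0], np.cumsum(lengths[:-1])])
    loeuf = burden_mod.clamp_loeuf(
        _draw(rng, config.loeuf_distribution, n), warn=False
    )
    return pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts.astype(np.int64),
            "end": (starts + lengths).astype(np.int64),
            "gene_id": [f"G{i:06d}" for i in range(n)],
            "loeuf": loeuf,
        }
    )[["chrom", "start", "end", "gene_id", "loeuf"]]


def individual_ids(n: int) -> list[str]:
    return [f"I{i:06d}" for i in range(n)]


def simulate_cnvs(config: SimConfig, genes: pd.DataFrame) -> pd.DataFrame:
    """Poisson(cnv_rate) deletions and duplications per individual,
    uniformly placed, with lengths from the configured distribution."""
    config.validate()
    rng = config.rng("cnvs")
    ids = np.array(individual_ids(config.n_individuals))
    frames = []
    for cnv_type in burden_mod.CNV_TYPES:
        counts = rng.poisson(config.cnv_rate, config.n_individuals)
        total = int(counts.sum())
        lengths = np.maximum(
            _draw(rng, config.cnv_length_distribution, total),
            config.min_cnv_length,
        ).astype(np.int64)
        lengths = np.minimum(lengths, config.genome_length - 1)
        starts = (rng.random(total) * (config.genome_length - lengths)).astype(np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": np.repeat(ids, counts),
                    "chrom": config.chrom,
                    "start": starts,
                    "end": starts + lengths,
                    "cnv_type": cnv_type,
                }
            )
        )
    calls = pd.concat(frames, ignore_index=True)
    return calls.sort_values(
        ["individual_id", "cnv_type", "start"], kind="mergesort"
    ).reset_index(drop=True)


def simulate_recurrent_loci(config: SimConfig, genes: pd.DataFrame) -> pd.DataFrame:
    """Recurrent-CNV locus definitions spanning a few consecutive genes each."""
    rng = config.rng("loci")
    n_loci = config.n_recurrent_loci
    span = config.recurrent_locus_genes
    if n_loci == 0:
        return pd.DataFrame(columns=["label", "chrom", "start", "end", "cnv_type"])
    max_start = max(len(genes) - span, 1)
    first = np.sort(rng.choice(max_start, size=min(n_loci, max_start), replace=False))
    rows = []
    for i, gi in enumerate(first):
        sub = genes.iloc[gi : gi + span]
        cnv_type = burden_mod.CNV_TYPES[i % 2]
        rows.append(
            {
                "label": f"locus{i + 1:02d}_{cnv_type}",
                "chrom": config.chrom,
                "start": int(sub["start"].min()),
                "end": int(sub["end"].max()),
                "cnv_type": cnv_type,
            }
        )
    return pd.DataFrame(rows)


def implant_recurrent_cnvs(
    config: SimConfig, loci: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bernoulli carrier draws per locus; carriers get a call at the locus coords.

    Returns (extra_calls, carrier_matrix) where carrier_matrix is indexed by
    individual_id with one boolean column per locus label.
    """
    rng = config.rng("implant")
    ids = individual_ids(config.n_individuals)
    carrier = pd.DataFrame(index=pd.Index(ids, name="individual_id"))
    rows = []
    for _, locus in loci.iterrows():
        is_carrier = rng.random(config.n_individuals) < config.recurrent_carrier_freq
        carrier[locus["label"]] = is_carrier
        for ind in np.array(ids)[is_carrier]:
            rows.append(
                {
                    "individual_id": ind,
                    "chrom": locus["chrom"],
                    "start": locus["start"],
                    "end": locus["end"],
                    "cnv_type": locus["cnv_type"],
                }
            )
    extra = pd.DataFrame(rows, columns=["individual_id", "chrom", "start", "end", "cnv_type"])
    return extra, carrier


OUT_OF_RANGE_HOURS = np.array([0.0, 1.0, 2.0, 13.0, 14.0, 15.0])


def simulate_phenotypes(
    config: SimConfig,
    burden: pd.DataFrame,
    carriers: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Phenotype/covariate table from per-individual burden scores.

    ``burden`` is the table produced by :func:`cnvsleep.burden.burden_scores`
    for the simulated calls (the generator consumes the same scoring code the
    analyses use).  ``carriers`` optionally adds a direct cognitive shift of
    ``recurrent_effect_cog`` z to recurrent-locus carriers.
    """
    config.validate()
    rng = config.rng("phenotypes")
    n = config.n_individuals
    ids = individual_ids(n)
    b = burden.set_index("individual_id")
    if not b.index.equals(pd.Index(ids, name="individual_id")):
        missing = set(ids) - set(b.index)
        raise ValueError(
            f"burden table does not match cohort individual ids "
            f"({len(missing)} missing)"
        )
    b_del = b["del_sum_inv_loeuf"].to_numpy(float)
    b_dup = b["dup_sum_inv_loeuf"].to_numpy(float)

    # U-shape mechanism: burden scales the deviation magnitude, the direction
    # is a fair coin; half-normal noise keeps the magnitude non-negative
    deviation = config.theta_sleep * (b_del + b_dup) + np.abs(
        rng.normal(0.0, config.deviation_noise_scale, n)
    )
    sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    sleep_cont = (
        config.mean_sleep
        + sign * deviation
        + rng.normal(0.0, config.sleep_noise_sd, n)
    )
    sleep_cont = np.clip(sleep_cont, 3.0, 12.0)  # plausible range pre-QC
    sleep_selfreport = np.round(sleep_cont)  # responses in 1-h increments

    cog_raw = (
        -config.beta_cog_del * b_del
        - config.beta_cog_dup * b_dup
        - config.lambda_sleep_cog * deviation
        + rng.standard_normal(n)
    )
    if carriers is not None and config.recurrent_effect_cog != 0.0:
        any_carrier = carriers.reindex(ids).fillna(False).any(axis=1).to_numpy()
        cog_raw = cog_raw + config.recurrent_effect_cog * any_carrier
    cognition = (cog_raw - cog_raw.mean()) / cog_raw.std()

    # executive-function tasks: same genetic/sleep signal, attenuated + noisier
    def _task(scale: float) -> np.ndarray:
        raw = scale * (cog_raw - cog_raw.mean()) + rng.standard_normal(n)
        return (raw - raw.mean()) / raw.std()

    trail_making = _task(0.6)
    tower = _task(0.5)

    # probable insomnia: null burden effect by default (configurable log-odds)
    logit = np.log(config.insomnia_base_rate / (1 - config.insomnia_base_rate)) + (
        config.insomnia_burden_effect * (b_del + b_dup)
    )
    p_insomnia = 1.0 / (1.0 + np.exp(-logit))
    insomnia = rng.random(n) < p_insomnia
    response = np.where(insomnia, np.where(rng.random(n) < 0.5, "sometimes", "usually"),
                        "never_rarely")
    pna = rng.random(n) < config.prefer_not_answer_rate
    response = np.where(pna, "prefer_not_answer", response)

    age = rng.uniform(40.0, 70.0, n).round(1)
    sex = (rng.random(n) < 0.54).astype(int)
    pcs = rng.standard_normal((n, 10))
    medication = rng.random(n) < config.medication_rate

    has_accel = rng.random(n) < config.accel_fraction
    sleep_accel = np.where(has_accel, sleep_cont, np.nan)
    wear_days = np.where(
        has_accel, rng.choice([4, 5, 6, 7], p=[0.05, 0.15, 0.4, 0.4], size=n), np.nan
    )
    a, bshape = _beta_params(config.efficiency_mean, config.efficiency_sd)
    efficiency = np.where(has_accel, rng.beta(a, bshape, n), np.nan)

    # out-of-range injection so the QC filters are exercised in every run
    bad_self = rng.random(n) < config.outlier_rate
    sleep_selfreport = np.where(
        bad_self, rng.choice(OUT_OF_RANGE_HOURS, n), sleep_selfreport
    )
    bad_accel = has_accel & (rng.random(n) < config.outlier_rate)
    sleep_accel = np.where(bad_accel, rng.choice(OUT_OF_RANGE_HOURS, n), sleep_accel)

    cohort = pd.DataFrame(
        {
            "individual_id": ids,
            "sleep_selfreport": sleep_selfreport,
            "sleep_accel": sleep_accel,
            "sleep_efficiency": efficiency,
            "accel_wear_days": wear_days,
            "insomnia_response": response,
            "cognition": cognition,
            "trail_making": trail_making,
            "tower": tower,
            "age": age,
            "sex": sex,
            "medication_flag": medication,
            "over65_flag": age > 65.0,
        }
    )
    for j in range(10):
        cohort[f"pc{j + 1}"] = pcs[:, j]

    truth = GroundTruth(
        burden_del=b_del,
        burden_dup=b_dup,
        deviation=deviation,
        sign=sign,
        implied_prop_mediated_del=config.implied_prop_mediated_del,
        implied_prop_mediated_dup=config.implied_prop_mediated_dup,
    )
    return cohort, truth


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    nu = mean * (1 - mean) / sd**2 - 1
    return mean * nu, (1 - mean) * nu


def simulate_cohort(config: SimConfig) -> SimResult:
    """Run the full generator: genome → CNVs (+ recurrent implants) →
    burden scores (via the scoring module) → phenotypes."""
    genes = simulate_genome(config)
    calls = simulate_cnvs(config, genes)
    loci = simulate_recurrent_loci(config, genes)
    extra, carriers = implant_recurrent_cnvs(config, loci)
    if len(extra):
        calls = pd.concat([calls, extra], ignore_index=True)
        calls = calls.sort_values(
            ["individual_id", "cnv_type", "start"], kind="mergesort"
        ).reset_index(drop=True)
    scores = burden_mod.burden_scores(
        calls, genes, individual_ids=individual_ids(config.n_individuals)
    )
    cohort, truth = simulate_phenotypes(config, scores, carriers)
    return SimResult(
        genes=genes, calls=calls, loci=loci, carriers=carriers,
        burden=scores, cohort=cohort, truth=truth, config=config,
    )
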