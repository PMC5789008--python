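"""Synthetic study generator for the gene-by-climate analysis.

Emulates the statistical structure the pipeline assumes, so every stage can
be exercised without any external data:

* one latent dopaminergic-function factor per population drives all nine
  polymorphism frequencies on the logit scale, with mixed-sign weights
  (defaulting to the published first-component loading pattern);
* several literature "samples" per population observe each frequency with
  binomial counting noise scaled by their participant numbers;
* climatic demand is induced through four monthly temperature extremes whose
  summed deviation from 22 °C spans a configurable range;
* trait means follow the interaction model
  ``Y = β0 + β1·DA + β2·CD + β3·DA·CD + ε`` where DA is the generator's
  *true* (noise-free) 0–100 index, CD the true demand, both mean-centred as
  in the analysis, so a downstream moderated regression on noise-free data
  recovers the β exactly;
* wealth and parasite-stress covariates are drawn with the climate and
  dopamine correlations reported for real nations, and continent labels
  stratify populations by latent score to give dummy-code robustness checks
  something to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import gene_index
from .polymorphisms import CANONICAL_IDS, POLYMORPHISMS, REFERENCE_LOADINGS

#: plausible worldwide mean canonical-allele frequencies, one per locus
DEFAULT_BASE_FREQS: tuple[float, ...] = (
    0.40,  # rs28363170 9R carrier
    0.35,  # rs1800497 A1
    0.30,  # rs1079597 B1
    0.60,  # rs1800498 D1
    0.60,  # rs6275 C
    0.50,  # rs6277 C
    0.85,  # rs1799732 ins
    0.60,  # rs6280 Ser
    0.45,  # rs1800955 T
)

CONTINENTS = ("Africa", "Americas", "Asia", "Europe")


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the reference study conditions."""

    n_populations: int = 40
    samples_per_population: tuple[int, int] = (2, 6)
    sample_size_range: tuple[int, int] = (50, 400)
    loadings: tuple[float, ...] = REFERENCE_LOADINGS
    base_freqs: tuple[float, ...] = DEFAULT_BASE_FREQS
    latent_sd: float = 1.0
    #: binomial-dispersion multiplier for observed sample frequencies:
    #: 1 = pure binomial counting noise at 2N chromosomes, 0 = noise-free
    freq_noise_sd: float = 1.0
    beta0: float = 50.0
    beta1: float = 1.5
    beta2: float = 1.0
    beta3: float = 0.8
    trait_noise_sd: float = 5.0
    climate_range: tuple[float, float] = (10.0, 120.0)
    seed: int = 0
    instruments: tuple[str, ...] = ("bfi", "neo", "opq")

    def validate(self) -> None:
        if self.n_populations < 5:
            raise ValueError("need at least 5 populations")
        if len(self.loadings) != len(CANONICAL_IDS):
            raise ValueError(f"need {len(CANONICAL_IDS)} loadings")
        if len(self.base_freqs) != len(CANONICAL_IDS):
            raise ValueError(f"need {len(CANONICAL_IDS)} base frequencies")
        if not all(0.0 < f < 1.0 for f in self.base_freqs):
            raise ValueError("base frequencies must lie strictly in (0, 1)")
        lo, hi = self.samples_per_population
        if not (1 <= lo <= hi):
            raise ValueError("invalid samples_per_population range")
        lo, hi = self.sample_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid sample_size_range")
        if self.latent_sd < 0 or self.freq_noise_sd < 0 or self.trait_noise_sd < 0:
            raise ValueError("noise scales must be nonnegative")
        if not (0 <= self.climate_range[0] <= self.climate_range[1]):
            raise ValueError("climate_range must be ordered and nonnegative")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        cfg = cls(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in d.items()
        })
        cfg.validate()
        return cfg


@dataclass
class SyntheticDataset:
    """The four study tables plus the generating truth (for validation)."""

    sample_table: pd.DataFrame
    climate_table: pd.DataFrame
    covariate_table: pd.DataFrame
    trait_table: pd.DataFrame
    #: per-population generating quantities: latent factor, the true 0-100
    #: index and demand, and their mean-centred analysis-scale versions
    truth: pd.DataFrame
    config: SyntheticConfig

    def write_csv(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sample_table.to_csv(outdir / "sample_table.csv", index=False)
        self.climate_table.to_csv(outdir / "climate_table.csv", index=False)
        self.covariate_table.to_csv(outdir / "covariate_table.csv", index=False)
        self.trait_table.to_csv(outdir / "trait_table.csv", index=False)
        self.config.to_json(outdir / "synthetic_config.json")


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _true_index(true_freqs: pd.DataFrame) -> pd.Series:
    """Index the full estimation pipeline yields on noise-free frequencies.

    Defined as the noise-free limit of the estimator (correlation → PSD
    smoothing → PCA → orientation → weighted scoring → 0–100 scaling), so
    that with all noise switched off the estimated and true index coincide
    exactly.
    """
    result = gene_index.build_gene_index(true_freqs, min_items=len(true_freqs.columns))
    return result.scaled_scores


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one complete synthetic study; the seed fully determines the output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pop = config.n_populations
    pops = [f"P{i + 1:03d}" for i in range(n_pop)]
    lam = np.asarray(config.loadings, dtype=float)
    base = np.asarray(config.base_freqs, dtype=float)

    # latent dopaminergic factor and noise-free frequencies
    u = rng.normal(0.0, config.latent_sd, n_pop)
    true = expit(logit(base)[None, :] + np.outer(u, lam))
    for j, poly in enumerate(POLYMORPHISMS):
        col = true[:, j]
        if np.all(col < 1e-3) or np.all(col > 1 - 1e-3):
            raise ValueError(
                f"degenerate configuration: frequencies for {poly.rsid} are all "
                "~0 or ~1; adjust base_freqs/loadings/latent_sd"
            )
    true_df = pd.DataFrame(true, index=pops, columns=list(CANONICAL_IDS))

    # continents stratify the latent factor (coarse population structure)
    order = np.argsort(u)
    continent = np.empty(n_pop, dtype=object)
    for block, chunk in enumerate(np.array_split(order, len(CONTINENTS))):
        continent[chunk] = CONTINENTS[block]
    continent = pd.Series(continent, index=pops)

    # literature samples: each reports all nine loci with binomial noise
    records = []
    for i, pop in enumerate(pops):
        k = int(rng.integers(config.samples_per_population[0],
                             config.samples_per_population[1] + 1))
        sizes = rng.integers(config.sample_size_range[0],
                             config.sample_size_range[1] + 1, size=k)
        for s in range(k):
            n_part = int(sizes[s])
            for j, poly in enumerate(POLYMORPHISMS):
                p_true = true[i, j]
                if config.freq_noise_sd == 0:
                    f_obs = p_true
                else:
                    # overdispersion folds into an effective chromosome count
                    m = max(1, round(2 * n_part / config.freq_noise_sd**2))
                    f_obs = rng.binomial(m, p_true) / m
                records.append({
                    "sample_id": f"{pop}_s{s + 1}",
                    "population_id": pop,
                    "continent": continent[pop],
                    "polymorphism_id": poly.rsid,
                    "allele": poly.canonical_allele,
                    "freq": float(f_obs),
                    "n": n_part,
                })
    sample_table = pd.DataFrame.from_records(records)

    # climate: four extremes constructed to hit a target demand exactly
    demand = rng.uniform(config.climate_range[0], config.climate_range[1], n_pop)
    cold_share = rng.uniform(0.3, 0.7, n_pop)
    cold_split = rng.uniform(0.5, 1.0, n_pop)   # share of cold demand in the low extreme
    hot_split = rng.uniform(0.5, 1.0, n_pop)    # share of hot demand in the high extreme
    cold = demand * cold_share
    hot = demand - cold
    climate_table = pd.DataFrame({
        "population_id": pops,
        "t_cold_low": 22.0 - cold * cold_split,
        "t_cold_high": 22.0 - cold * (1.0 - cold_split),
        "t_hot_low": 22.0 + hot * (1.0 - hot_split),
        "t_hot_high": 22.0 + hot * hot_split,
    })

    # generating (true) analysis-scale predictors: mean-centred 0-100 index
    # and mean-centred demand, mirroring the moderated-regression convention
    da_true = _true_index(true_df)
    da_c = da_true.to_numpy() - da_true.to_numpy().mean()
    cd_c = demand - demand.mean()
    z_da = _zscore(da_true.to_numpy())
    z_cd = _zscore(demand)

    # covariates with the reported real-world correlation pattern
    err = rng.multivariate_normal(
        [0.0, 0.0],
        [[0.694, -0.359], [-0.359, 0.453]],
        size=n_pop,
    )
    wealth = 0.42 * z_cd + 0.36 * z_da + err[:, 0]
    parasite = -0.74 * z_cd + err[:, 1]
    covariate_table = pd.DataFrame({
        "population_id": pops,
        "wealth": wealth,
        "parasite_stress": parasite,
        "continent": continent.to_numpy(),
    })

    # trait means per instrument: extraversion-like (positive interaction)
    # and neuroticism-like (mirrored dopamine effects)
    inter = da_c * cd_c
    trait_cols = {"population_id": pops}
    for inst in config.instruments:
        noise_e = rng.normal(0.0, config.trait_noise_sd, n_pop)
        noise_n = rng.normal(0.0, config.trait_noise_sd, n_pop)
        trait_cols[f"extraversion_{inst}"] = (
            config.beta0 + config.beta1 * da_c + config.beta2 * cd_c
            + config.beta3 * inter + noise_e
        )
        trait_cols[f"neuroticism_{inst}"] = (
            config.beta0 - config.beta1 * da_c + config.beta2 * cd_c
            - config.beta3 * inter + noise_n
        )
    trait_table = pd.DataFrame(trait_cols)
    if not np.isfinite(trait_table.drop(columns="population_id").to_numpy()).all():
        raise ValueError("non-finite trait means generated")

    truth = pd.DataFrame({
        "population_id": pops,
        "latent_u": u,
        "da_true": da_true.to_numpy(),
        "da_centred": da_c,
        "demand_true": demand,
        "cd_centred": cd_c,
    })

    return SyntheticDataset(
        sample_table=sample_table,
        climate_table=climate_table,
        covariate_table=covariate_table,
        trait_table=trait_table,
        truth=truth,
        config=config,
    )
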