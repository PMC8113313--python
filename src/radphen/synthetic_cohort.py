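"""Synthetic cohorts with known ground truth.

Emulates a small advanced-NSCLC cohort (~40 patients) profiled with CT
radiomics and ctDNA liquid biopsy: a tumor-by-feature matrix with planted
correlated feature clusters, two (or more) latent tumor phenotypes that shift
a subset of those clusters, clinical/ctDNA covariates with realistic
marginals, and exponential progression/death times under a proportional-
hazards model with independent censoring.  Every generator is deterministic
given its config seed, and the planted labels are returned so downstream
stages have parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_feature_matrix",
    "generate_clinical",
    "generate_survival",
    "generate_cohort",
    "generate_phantom",
    "encode_covariates",
]


class ConfigError(ValueError):
    """Invalid cohort configuration."""


def _default_hazards() -> dict[str, float]:
    # Phenotype 2 vs 1 log-HR ~ ln 2.7, ECOG per-grade ~ ln 2: the effect
    # sizes of the covariates that carried signal in the motivating cohort.
    return {"phenotype": math.log(2.7), "ecog": math.log(2.0)}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults describe the emulated study: 40 tumors, 429 z-scorable radiomic
    features in correlated blocks, two phenotypes at 52.5/47.5% prevalence,
    daily event/censoring rates giving roughly half the cohort an observed
    progression within the follow-up window.
    """

    n_tumors: int = 40
    n_features: int = 429
    k_feature_clusters: int = 27
    within_cluster_corr: float = 0.8
    n_phenotypes: int = 2
    phenotype_proportions: tuple[float, ...] = (0.525, 0.475)
    phenotype_shift: float = 2.0          # mean separation, in feature-sd units
    affected_cluster_fraction: float = 0.5
    hazard_coefficients: dict[str, float] = field(default_factory=_default_hazards)
    baseline_rate: float = math.log(2) / 300.0   # per day; median PFS ~300 d at lp=0
    censor_rate: float = 1.0 / 450.0             # per day, independent of covariates
    os_rate_factor: float = 0.35                 # death hazard relative to progression
    max_followup: float = 835.0                  # days, administrative cutoff
    line_therapy_log_or: float = 0.0  # phenotype-2 log-odds shift for front-line therapy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < self.k_feature_clusters or self.k_feature_clusters < 1:
            raise ConfigError(
                f"need n_features >= k_feature_clusters >= 1, got "
                f"{self.n_features} < {self.k_feature_clusters}"
            )
        if not (0.0 <= self.within_cluster_corr < 1.0):
            raise ConfigError("within_cluster_corr must be in [0, 1)")
        if self.phenotype_shift < 0:
            raise ConfigError("phenotype_shift must be >= 0")
        if not (0.0 < self.affected_cluster_fraction <= 1.0):
            raise ConfigError("affected_cluster_fraction must be in (0, 1]")
        if len(self.phenotype_proportions) != self.n_phenotypes:
            raise ConfigError("phenotype_proportions length must equal n_phenotypes")
        if abs(sum(self.phenotype_proportions) - 1.0) > 1e-9:
            raise ConfigError("phenotype proportions must sum to 1")
        if self.baseline_rate <= 0 or self.censor_rate <= 0:
            raise ConfigError("baseline_rate and censor_rate must be > 0")


@dataclass
class SyntheticCohort:
    features: pd.DataFrame            # tumors x features
    clinical: pd.DataFrame            # one row per patient, incl. outcomes
    true_feature_cluster: pd.Series   # feature name -> planted cluster id
    true_phenotype: pd.Series         # tumor id -> planted phenotype id (1-based)
    config: CohortConfig


# Streams are spawned from the config seed so each generator draws from its
# own seeded generator and the four stages stay reproducible independently.
_STREAMS = {"features": 0, "clinical": 1, "survival": 2, "phantom": 3}


def _rng(config_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config_seed, _STREAMS[stream])))


def _phenotype_labels(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic 1-based phenotype labels at the configured proportions."""
    counts = np.floor(np.asarray(config.phenotype_proportions) * config.n_tumors).astype(int)
    # distribute remainder to the largest fractional parts
    frac = np.asarray(config.phenotype_proportions) * config.n_tumors - counts
    for i in np.argsort(-frac)[: config.n_tumors - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.arange(1, config.n_phenotypes + 1), counts)
    rng.shuffle(labels)
    return labels


def generate_feature_matrix(config: CohortConfig) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Tumor-by-feature matrix with planted correlated feature clusters.

    Features in planted cluster c share a latent tumor-level factor:
    ``x = sqrt(rho) * z_c + sqrt(1 - rho) * eps`` so the expected pairwise
    within-cluster correlation is exactly ``rho``.  Phenotypes differ by
    ``phenotype_shift`` feature-sd units on the first
    ``ceil(affected_cluster_fraction * k)`` clusters; shifts are centered
    across phenotypes.

    Returns (features, true_feature_cluster, true_phenotype).
    """
    rng = _rng(config.seed, "features")
    n, p, k = config.n_tumors, config.n_features, config.k_feature_clusters
    rho = config.within_cluster_corr

    phenotype = _phenotype_labels(config, rng)
    # near-equal cluster sizes, deterministic
    cluster_of = np.sort(np.arange(p) % k) + 1
    n_affected = math.ceil(config.affected_cluster_fraction * k)
    affected = np.arange(1, n_affected + 1)

    # centered per-phenotype offsets: adjacent phenotypes differ by `shift`
    offsets = config.phenotype_shift * (
        np.arange(config.n_phenotypes) - (config.n_phenotypes - 1) / 2.0
    )

    factors = rng.standard_normal((n, k))
    noise = rng.standard_normal((n, p))
    x = np.sqrt(rho) * factors[:, cluster_of - 1] + np.sqrt(1.0 - rho) * noise
    shift_mask = np.isin(cluster_of, affected)
    x[:, shift_mask] += offsets[phenotype - 1][:, None]

    tumor_ids = [f"P{i + 1:03d}" for i in range(n)]
    feat_names = [f"feat_{cluster_of[j]:02d}_{j:04d}" for j in range(p)]
    features = pd.DataFrame(x, index=pd.Index(tumor_ids, name="patient_id"), columns=feat_names)
    true_cluster = pd.Series(cluster_of, index=feat_names, name="true_feature_cluster")
    true_phen = pd.Series(phenotype, index=features.index, name="true_phenotype")
    return features, true_cluster, true_phen


_EGFR_CATEGORIES = ["Exon 19 deletion", "Exon 20 insertion", "G719C/S768I", "L858R", "T790M"]
_EGFR_PROBS = [0.35, 0.025, 0.025, 0.20, 0.40]
_ECOG_PROBS = [0.50, 0.45, 0.05]  # mean 0.55, range 0-2


def generate_clinical(config: CohortConfig, true_phenotype: np.ndarray | pd.Series) -> pd.DataFrame:
    """Clinical + ctDNA covariates (no outcomes) at the study's marginals.

    Age ~ round(N(62, 8)) clipped to [45, 82]; 72.5% female; 52.5% former
    smokers; ECOG on {0,1,2}; 57.5% front-line therapy (optionally
    phenotype-dependent through ``line_therapy_log_or``); number of ctDNA
    mutations = 1 + Poisson(3) capped at 8; driver allele fraction from a
    skewed Gamma on a 0-53% scale.
    """
    phenotype = np.asarray(true_phenotype)
    if phenotype.shape[0] != config.n_tumors:
        raise ConfigError("phenotype labels must have length n_tumors")
    rng = _rng(config.seed, "clinical")
    n = config.n_tumors
    index = (
        true_phenotype.index
        if isinstance(true_phenotype, pd.Series)
        else pd.Index([f"P{i + 1:03d}" for i in range(n)], name="patient_id")
    )

    age = np.clip(np.round(rng.normal(62.0, 8.0, n)), 45, 82).astype(int)
    sex = np.where(rng.random(n) < 0.725, "F", "M")
    smoking = np.where(rng.random(n) < 0.525, "former", "never")
    ecog = rng.choice([0, 1, 2], size=n, p=_ECOG_PROBS)

    base_logit = math.log(0.575 / 0.425)
    logit = base_logit + config.line_therapy_log_or * (phenotype == 2)
    p_first = 1.0 / (1.0 + np.exp(-logit))
    line = np.where(rng.random(n) < p_first, "first", "later")

    n_mut = np.minimum(1 + rng.poisson(3.0, n), 8)
    driver_af = np.round(np.minimum(rng.gamma(1.0, 7.6, n), 53.0), 1)
    egfr = rng.choice(_EGFR_CATEGORIES, size=n, p=_EGFR_PROBS)

    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "smoking_status": smoking,
            "ecog": ecog,
            "line_of_therapy": line,
            "n_mutations": n_mut,
            "egfr_mutation": egfr,
            "driver_af": driver_af,
        },
        index=index,
    )


def encode_covariates(clinical: pd.DataFrame, phenotype: np.ndarray | pd.Series | None = None) -> pd.DataFrame:
    """Numeric design encoding shared by the generator and the Cox models.

    Binary codings: sex M=1; smoking_status never=1 (vs former); line_of_therapy
    later=1 (vs first); phenotype 2-vs-1 as 1/0.  ECOG and number of mutations
    stay continuous ("per one increment").
    """
    out = pd.DataFrame(index=clinical.index)
    if "age" in clinical:
        out["age"] = clinical["age"].astype(float)
    if "sex" in clinical:
        out["sex"] = (clinical["sex"] == "M").astype(float)
    if "smoking_status" in clinical:
        out["smoking_status"] = (clinical["smoking_status"] == "never").astype(float)
    if "ecog" in clinical:
        out["ecog"] = clinical["ecog"].astype(float)
    if "line_of_therapy" in clinical:
        out["line_of_therapy"] = (clinical["line_of_therapy"] == "later").astype(float)
    if "n_mutations" in clinical:
        out["n_mutations"] = clinical["n_mutations"].astype(float)
    if "driver_af" in clinical:
        out["driver_af"] = clinical["driver_af"].astype(float)
    if phenotype is not None:
        out["phenotype"] = (np.asarray(phenotype) == 2).astype(float)
    return out


def generate_survival(
    clinical: pd.DataFrame,
    true_phenotype: np.ndarray | pd.Series,
    config: CohortConfig,
) -> pd.DataFrame:
    """Progression and death times under proportional hazards.

    Event time ~ Exponential(rate * exp(x'beta)) per endpoint (death hazard
    scaled by ``os_rate_factor``); censoring ~ Exponential(censor_rate)
    truncated at ``max_followup``, shared by both endpoints and independent of
    covariates.  Observed time = min(event, censor); ties are event-first.
    """
    rng = _rng(config.seed, "survival")
    design = encode_covariates(clinical, true_phenotype)
    unknown = set(config.hazard_coefficients) - set(design.columns)
    if unknown:
        raise ConfigError(f"hazard coefficients reference unknown covariates: {sorted(unknown)}")
    lp = np.zeros(len(design))
    for name, beta in config.hazard_coefficients.items():
        lp += beta * design[name].to_numpy()

    n = len(design)
    censor = np.minimum(rng.exponential(1.0 / config.censor_rate, n), config.max_followup)
    out = pd.DataFrame(index=clinical.index)
    for endpoint, rate_factor in (("progression", 1.0), ("death", config.os_rate_factor)):
        rate = config.baseline_rate * rate_factor * np.exp(lp)
        t_event = rng.exponential(1.0 / rate)
        observed = np.minimum(t_event, censor)
        flag = (t_event <= censor).astype(int)
        col = "time_to_progression" if endpoint == "progression" else "time_to_death"
        out[col] = observed
        out[endpoint] = flag
    return out


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Full cohort: features, clinical table with outcomes, planted labels."""
    features, true_cluster, true_phen = generate_feature_matrix(config)
    clinical = generate_clinical(config, true_phen)
    outcomes = generate_survival(clinical, true_phen, config)
    return SyntheticCohort(
        features=features,
        clinical=pd.concat([clinical, outcomes], axis=1),
        true_feature_cluster=true_cluster,
        true_phenotype=true_phen,
        config=config,
    )


def generate_phantom(
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    shape_kind: str = "sphere",
    texture: str = "smooth-noise",
    noise_sd: float = 0.0,
    seed: int = 0,
    radius: float | tuple[float, float, float] | None = None,
    checker_period: int = 4,
):
    """3D test phantom: image + single-connected binary mask.

    ``radius`` is in voxels (a scalar for spheres, a triple of semi-axes for
    ellipsoids); defaults to 35% of the smallest grid dimension.  Textures:
    ``constant`` (flat 100), ``checker`` (two intensities in alternating
    blocks of ``checker_period`` voxels), ``smooth-noise`` (Gaussian-smoothed
    white noise); i.i.d. Gaussian noise of sd ``noise_sd`` is added on top.
    """
    from scipy import ndimage

    if shape_kind not in ("sphere", "ellipsoid"):
        raise ValueError(f"unknown shape_kind {shape_kind!r}")
    if texture not in ("constant", "checker", "smooth-noise"):
        raise ValueError(f"unknown texture {texture!r}")
    shape = tuple(int(s) for s in grid_shape)
    if radius is None:
        radius = 0.35 * min(shape)
    radii = np.broadcast_to(np.asarray(radius, float), (3,)).copy()
    if shape_kind == "sphere":
        radii[:] = radii[0]
    center = (np.asarray(shape) - 1) / 2.0
    if np.any(radii < 0.5):
        raise ValueError("radius too small: empty mask")
    if np.any(center - radii < -0.5) or np.any(center + radii > np.asarray(shape) - 0.5):
        raise ValueError("mask does not fit inside grid")

    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip((zz, yy, xx), center, radii))
    mask = d2 <= 1.0
    if not mask.any():
        raise ValueError("empty mask")

    rng = np.random.default_rng(np.random.SeedSequence((seed, _STREAMS["phantom"])))
    if texture == "constant":
        image = np.full(shape, 100.0)
    elif texture == "checker":
        blocks = (zz // checker_period + yy // checker_period + xx // checker_period) % 2
        image = 50.0 + 100.0 * blocks
    else:  # smooth-noise
        image = 100.0 + 25.0 * ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, shape)
    return image, mask, tuple(float(s) for s in spacing)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write the cohort as delimited text: features, clinical, ground truth.

    The ground-truth file is never read by the analysis path; it exists for
    recovery checks only.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": str(outdir / "features.csv"),
        "clinical": str(outdir / "clinical.csv"),
        "ground_truth": str(outdir / "ground_truth.csv"),
    }
    cohort.features.to_csv(paths["features"])
    cohort.clinical.to_csv(paths["clinical"])
    truth = pd.DataFrame({"true_phenotype": cohort.true_phenotype})
    truth.to_csv(paths["ground_truth"])
    pd.DataFrame({"true_feature_cluster": cohort.true_feature_cluster}).to_csv(
        outdir / "ground_truth_features.csv"
    )
    return paths
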