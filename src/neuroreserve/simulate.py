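"""Synthetic family-cohort generator.

Emulates a multicentre presymptomatic genetic-FTD cohort: families carrying
GRN, C9orf72 or MAPT mutations recruited across research sites, each
first-degree relative at 50% prior risk of carrying the family mutation,
genotyped for the TMEM106B rs1990622 C/T polymorphism. The default
configuration reproduces the published cohort's structure (77 families, 13
sites, 231 expected subjects, T-allele frequency 0.634, education
13.8 +/- 3.2 years, ~64% female) and the default truth parameters are the
published fixed-effect estimates and random-intercept variances, so the
whole analysis pipeline can be exercised and validated by parameter
recovery without any data download.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellation import ParcellationScheme, default_scheme
from .volumes import SUBJECT_COL, TIV_COL

__all__ = [
    "CohortConfig",
    "TruthParams",
    "genfi_truth",
    "generate_cohort",
    "generate_outcome_and_volumes",
    "write_cohort",
    "write_sidecar",
]

GENES = ("GRN", "C9orf72", "MAPT")

#: plausible per-region mean volumes (mm^3) for the default 27-measure scheme
REGION_MEAN_MM3 = {
    "frontal": 85_000.0, "temporal": 60_000.0, "parietal": 55_000.0,
    "occipital": 35_000.0, "cingulate": 13_000.0, "insula": 7_000.0,
    "hippocampus": 3_800.0, "amygdala": 1_500.0, "caudate": 3_500.0,
    "putamen": 4_500.0, "accumbens": 550.0, "pallidum": 1_600.0,
    "thalamus": 7_200.0, "cerebellum": 130_000.0,
}
TIV_REFERENCE_MM3 = 1.45e6
#: fraction of a region's mean volume gained per unit latent score, per unit
#: loading weight
LOADING_SCALE = 0.01
#: lobes that dominate the composite by default (weight 3 vs 1)
HIGH_LOADING_STRUCTURES = ("frontal", "parietal", "temporal")

EDUCATION_RANGE = (5.0, 25.0)


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"configuration field {name!r} must be finite, got {value!r}")
    return value


def _require_prob(name: str, value: float) -> float:
    value = _require_finite(name, value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"configuration field {name!r} must be in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation settings (defaults emulate the published cohort)."""

    n_families: int = 77
    mean_family_size: float = 3.0
    n_sites: int = 13
    gene_mix: dict = field(default_factory=lambda: {"GRN": 33 / 77, "C9orf72": 29 / 77, "MAPT": 15 / 77})
    carrier_prob: float = 0.5  # autosomal-dominant 50% prior risk
    t_allele_freq: float = 0.634
    education_mean: float = 13.8
    education_sd: float = 3.2
    age_mean: float = 47.2
    age_sd: float = 13.0
    age_min: float = 19.0
    age_max: float = 86.0
    female_prob: float = 0.64
    missing_mri_prob: float = 22 / 294
    missing_genotype_prob: float = 41 / 272

    def __post_init__(self) -> None:
        if int(self.n_families) < 1:
            raise ValueError(f"configuration field 'n_families' must be >= 1, got {self.n_families}")
        if int(self.n_sites) < 1:
            raise ValueError(f"configuration field 'n_sites' must be >= 1, got {self.n_sites}")
        if _require_finite("mean_family_size", self.mean_family_size) < 1:
            raise ValueError("configuration field 'mean_family_size' must be >= 1")
        mix = {g: _require_finite(f"gene_mix[{g}]", p) for g, p in self.gene_mix.items()}
        if set(mix) != set(GENES):
            raise ValueError(f"configuration field 'gene_mix' must cover genes {GENES}")
        if abs(sum(mix.values()) - 1.0) > 1e-8 or any(p < 0 for p in mix.values()):
            raise ValueError("configuration field 'gene_mix' must be non-negative and sum to 1")
        for name in ("carrier_prob", "t_allele_freq", "female_prob",
                     "missing_mri_prob", "missing_genotype_prob"):
            _require_prob(name, getattr(self, name))
        for name in ("education_mean", "education_sd", "age_mean", "age_sd", "age_min", "age_max"):
            _require_finite(name, getattr(self, name))
        if self.education_sd < 0 or self.age_sd < 0:
            raise ValueError("configuration fields 'education_sd'/'age_sd' must be >= 0")
        if not self.age_min < self.age_max:
            raise ValueError(
                f"configuration field 'age_min' ({self.age_min}) must be < 'age_max' ({self.age_max})"
            )


@dataclass(frozen=True)
class TruthParams:
    """Generative parameters of the latent grey-matter composite and volumes.

    The beta coefficients act on the same centred coding the model uses
    (education minus ``education_center``, T-allele count minus
    ``tmem_center``), so refitted estimates are directly comparable with the
    truth. ``loading_profile`` holds per-region relative weights w_j; region
    j's volume responds to the latent score g as
    ``mu_j * (1 + LOADING_SCALE * w_j * g)``. ``region_noise_sd`` is the
    fractional residual scale per region (scalar broadcast), with correlation
    ``lr_corr`` between left-right homologue noise and zero elsewhere.
    """

    beta0: float = 0.0
    beta_gs: float = -0.262
    beta_edu: float = 0.035
    beta_tmem: float = -0.035
    beta_gs_edu: float = -0.046
    beta_gs_tmem: float = 0.055
    beta_edu_tmem: float = -0.0005
    beta_gs_edu_tmem: float = 0.110
    beta_age: float = -0.052
    beta_sex: float = -0.527
    var_pedigree: float = 0.085
    var_site: float = 0.004
    var_resid: float = 0.227
    loading_profile: tuple | None = None
    region_noise_sd: float | tuple = 0.03
    lr_corr: float = 0.8
    tiv_log_sd: float = 0.07
    tiv_sex_log_offset: float = 0.05  # males larger by ~e^0.05
    education_center: float = 13.8
    tmem_center: float = 1.268

    def __post_init__(self) -> None:
        for name in ("var_pedigree", "var_site", "var_resid"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise ValueError(f"truth field {name!r} must be >= 0, got {v}")
        if not 0.0 <= _require_finite("lr_corr", self.lr_corr) < 1.0:
            raise ValueError(f"truth field 'lr_corr' must be in [0, 1), got {self.lr_corr}")

    def resolved_loadings(self, scheme: ParcellationScheme) -> np.ndarray:
        """Per-region weights w_j, defaulting to 3 for frontal/parietal/temporal
        and 1 elsewhere."""
        if self.loading_profile is None:
            return np.array(
                [3.0 if r.structure in HIGH_LOADING_STRUCTURES else 1.0 for r in scheme.regions]
            )
        w = np.asarray(self.loading_profile, dtype=float)
        if w.shape != (len(scheme),):
            raise ValueError(
                f"loading_profile has {w.size} entries; scheme has {len(scheme)} measures"
            )
        return w

    def resolved_noise_sd(self, scheme: ParcellationScheme) -> np.ndarray:
        s = np.asarray(self.region_noise_sd, dtype=float)
        if s.ndim == 0:
            return np.full(len(scheme), float(s))
        if s.shape != (len(scheme),):
            raise ValueError(
                f"region_noise_sd has {s.size} entries; scheme has {len(scheme)} measures"
            )
        return s

    def fixed_effect_truth(self) -> dict[str, float]:
        """Truth keyed by the model's term names."""
        return {
            "Intercept": self.beta0,
            "GS": self.beta_gs,
            "Education": self.beta_edu,
            "TMEM106B": self.beta_tmem,
            "GS x Education": self.beta_gs_edu,
            "GS x TMEM106B": self.beta_gs_tmem,
            "Education x TMEM106B": self.beta_edu_tmem,
            "GS x Education x TMEM106B": self.beta_gs_edu_tmem,
            "Age": self.beta_age,
            "Sex(F)": self.beta_sex,
        }


def genfi_truth(**overrides) -> TruthParams:
    """Truth parameters at the published GENFI fixed-effect estimates and
    random-intercept variances (residual variance calibrated to the reported
    standard errors; intercept set to 0 as it is not reported)."""
    return TruthParams(**overrides)


def generate_cohort(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Draw a cohort table: one row per subject.

    Families get one gene and one site each; per subject the mutation-carrier
    status is Bernoulli(carrier_prob), the TMEM106B genotype is
    Hardy-Weinberg at the configured T-allele frequency, education is a
    truncated normal rounded to half-years, age a truncated normal, and the
    MRI/genotype missingness flags independent Bernoulli draws.
    """
    rng = np.random.default_rng(seed)
    genes = list(GENES)
    gene_p = np.array([config.gene_mix[g] for g in genes])
    rows = []
    sid = 0
    for fam in range(int(config.n_families)):
        family_id = f"F{fam + 1:03d}"
        gene = genes[rng.choice(len(genes), p=gene_p)]
        site_id = f"S{rng.integers(int(config.n_sites)) + 1:02d}"
        size = rng.poisson(config.mean_family_size - 1.0) + 1
        for _ in range(size):
            sid += 1
            gs = int(rng.random() < config.carrier_prob)
            n_t = int(rng.binomial(2, config.t_allele_freq))
            genotype = {0: "CC", 1: "CT", 2: "TT"}[n_t]
            edu = float(np.clip(rng.normal(config.education_mean, config.education_sd),
                                *EDUCATION_RANGE))
            edu = round(edu * 2.0) / 2.0
            age = float(np.clip(rng.normal(config.age_mean, config.age_sd),
                                config.age_min, config.age_max))
            female = int(rng.random() < config.female_prob)
            rows.append(
                {
                    SUBJECT_COL: f"P{sid:04d}",
                    "family_id": family_id,
                    "site_id": site_id,
                    "gene": gene,
                    "gs": gs,
                    "tmem": genotype,
                    "education": edu,
                    "age": age,
                    "female": female,
                    "has_mri": bool(rng.random() >= config.missing_mri_prob),
                    "has_genotype": bool(rng.random() >= config.missing_genotype_prob),
                }
            )
    return pd.DataFrame(rows)


def generate_outcome_and_volumes(
    cohort: pd.DataFrame,
    truth: TruthParams,
    scheme: ParcellationScheme | None = None,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Draw the latent composite and a raw volume table for *cohort*.

    The latent score is the linear mixed model evaluated at the truth
    parameters (centred coding) plus pedigree/site random intercepts and a
    residual. Raw volumes scale allometrically with the subject's TIV, so
    percent-of-TIV normalization recovers
    ``100 * mu_j * (1 + LOADING_SCALE * w_j * g + eta_j) / TIV_REFERENCE``;
    the noise eta is correlated ``lr_corr`` between homologue pairs.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(seed)
    n = len(cohort)

    gs = cohort["gs"].to_numpy(dtype=float)
    from .lmm import t_allele_count  # local import to avoid a cycle at module load

    t = cohort["tmem"].map(t_allele_count).to_numpy(dtype=float)
    e_c = cohort["education"].to_numpy(dtype=float) - truth.education_center
    t_c = t - truth.tmem_center
    age = cohort["age"].to_numpy(dtype=float)
    female = cohort["female"].to_numpy(dtype=float)

    fams, fam_idx = np.unique(cohort["family_id"], return_inverse=True)
    sites, site_idx = np.unique(cohort["site_id"], return_inverse=True)
    u_ped = rng.normal(0.0, np.sqrt(truth.var_pedigree), len(fams))
    u_site = rng.normal(0.0, np.sqrt(truth.var_site), len(sites))
    resid = rng.normal(0.0, np.sqrt(truth.var_resid), n)

    g = (
        truth.beta0
        + truth.beta_gs * gs
        + truth.beta_edu * e_c
        + truth.beta_tmem * t_c
        + truth.beta_gs_edu * gs * e_c
        + truth.beta_gs_tmem * gs * t_c
        + truth.beta_edu_tmem * e_c * t_c
        + truth.beta_gs_edu_tmem * gs * e_c * t_c
        + truth.beta_age * age
        + truth.beta_sex * female
        + u_ped[fam_idx]
        + u_site[site_idx]
        + resid
    )
    latent = pd.Series(g, index=cohort.index, name="latent")

    w = truth.resolved_loadings(scheme)
    noise_sd = truth.resolved_noise_sd(scheme)
    names = scheme.names
    mu = np.array([REGION_MEAN_MM3[scheme[nm].structure] for nm in names])

    # homologue-correlated fractional noise
    eta = np.empty((n, len(names)))
    done = set()
    name_idx = {nm: j for j, nm in enumerate(names)}
    for left, right in scheme.homologue_pairs():
        i, j = name_idx[left], name_idx[right]
        z_common = rng.normal(size=n)
        rho = truth.lr_corr
        eta[:, i] = z_common
        eta[:, j] = rho * z_common + np.sqrt(1 - rho**2) * rng.normal(size=n)
        done.update((i, j))
    for j in range(len(names)):
        if j not in done:
            eta[:, j] = rng.normal(size=n)
    eta *= noise_sd

    # TIV: log-normal around the reference, males larger
    log_tiv = (
        rng.normal(np.log(TIV_REFERENCE_MM3), truth.tiv_log_sd, n)
        + truth.tiv_sex_log_offset * (1 - 2 * female) / 2.0
    )
    tiv = np.exp(log_tiv)
    rel = 1.0 + LOADING_SCALE * w[None, :] * g[:, None] + eta
    raw = (tiv[:, None] / TIV_REFERENCE_MM3) * mu[None, :] * rel

    volumes = pd.DataFrame(raw, columns=names, index=cohort.index)
    volumes.insert(0, SUBJECT_COL, cohort[SUBJECT_COL])
    volumes[TIV_COL] = tiv
    return latent, volumes


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def write_sidecar(path, config: CohortConfig, truth: TruthParams, seed: int) -> None:
    """JSON sidecar recording how a synthetic dataset was produced."""
    payload = {
        "config": dataclasses.asdict(config),
        "truth": dataclasses.asdict(truth),
        "seed": int(seed),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
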