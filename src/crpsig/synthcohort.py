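"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a 91-patient incident kidney-transplant cohort in
which 359 plasma proteins were quantified as iTRAQ abundance ratios against
a pooled healthy-control channel, and the outcome is whether next-day
C-reactive protein (CRP) rose relative to the index day (59 events / 32
non-events).

Signal model
------------
The informative proteins are organised into a small number of independent
latent "modules" u_1..u_m ~ N(0, 1) -- stand-ins for the major co-regulated
plasma protein groups (positive and negative acute-phase reactants,
complement, coagulation, immunoglobulins, lipoproteins, protease
inhibitors, transport proteins). Proteins are assigned to modules by the
magnitude of their target correlation, so each module is a stratum of
effect sizes:

* informative protein log-ratios load on their module's factor with
  alternating sign, each loading calibrated so the protein's *population*
  Pearson correlation with the CRP change equals its target magnitude
  (targets evenly spaced over ``target_abs_correlation_range``);
* the CRP change is ``delta = mu + sigma_delta * (sum_g c_g u_g + resid)``
  where c_g is the smallest module-outcome correlation that makes the
  module's targets attainable at the configured within-module loading cap,
  and the intercept ``mu`` is solved in closed form so the expected event
  fraction (P(delta > 0)) equals ``event_prevalence_target``;
* non-informative proteins are independent log-normal noise.

Correlated modules, rather than mutually independent informative proteins,
are the only way dozens of proteins can each correlate with the same
outcome at |r| up to ~0.4 (the squared correlations of independent
predictors would have to sum to at most 1); several *independent* modules,
rather than one global factor, keep the marginal proteins informative
instead of making the whole signature redundant with its top few members.
Measurement error is multiplicative log-normal at coefficient of variation
``noise_cv`` (default 10%, the stated technical variability of the assay).
Event-associated covariates reproduce the cohort's descriptive statistics:
older donors, fewer deceased donors, shorter pre-transplant dialysis and
longer hospitalization among events.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohortio import (
    ClinicalTable,
    OutcomeVector,
    ProteinMatrix,
    derive_outcome,
    write_clinical_table,
    write_protein_matrix,
)

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "null_cohort", "write_cohort"]


#: Default event-conditional covariate effects, in each covariate's own
#: units, chosen to match the cohort's published descriptive statistics.
DEFAULT_COVARIATE_EFFECTS: Mapping[str, float] = {
    "donor_age_event_shift": 8.0,          # years: median 54 (events) vs 46
    "deceased_prob_event": 19 / 59,        # deceased-donor fraction in events
    "deceased_prob_nonevent": 21 / 32,     # ... and in non-events
    "dialysis_log_median_event": math.log(8.0),   # months, median 8 vs 21
    "dialysis_log_median_nonevent": math.log(21.0),
    "hospitalization_log_median_event": math.log(7.0),   # days, median 7 vs 5.5
    "hospitalization_log_median_nonevent": math.log(5.5),
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study design: 91 patients, 359 proteins, 82
    outcome-informative proteins with |Pearson r| targets spanning
    0.15-0.40, 10% multiplicative technical noise, and a 59/91 event
    fraction.
    """

    n_patients: int = 91
    n_proteins: int = 359
    n_informative: int = 82
    target_abs_correlation_range: tuple[float, float] = (0.15, 0.40)
    noise_cv: float = 0.10
    event_prevalence_target: float = 59 / 91
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    seed: int = 0

    #: Number of independent latent protein modules the informative proteins
    #: are spread over (major co-regulated plasma protein groups).
    n_modules: int = 8
    #: Upper bound on a protein's correlation with its module factor; keeps
    #: within-module collinearity below perfect redundancy.
    module_loading_cap: float = 0.9
    #: SD of biological between-patient log-ratio variation (log scale).
    log_ratio_sd: float = 0.25
    #: SD of the CRP change (mg/L); sets the scale of delta-CRP.
    delta_crp_sd: float = 45.0

    def __post_init__(self) -> None:
        lo, hi = self.target_abs_correlation_range
        if not (0 < lo <= hi):
            raise ValueError("correlation range bounds must satisfy 0 < lo <= hi")
        if hi >= 1:
            raise ValueError(f"impossible correlation target: upper bound {hi} >= 1")
        if not 0 < self.event_prevalence_target < 1:
            raise ValueError("event_prevalence_target must lie in (0, 1)")
        if self.n_informative > self.n_proteins:
            raise ValueError("n_informative cannot exceed n_proteins")
        if self.n_informative < 0 or self.n_proteins < 1 or self.n_patients < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.module_loading_cap <= 1 or self.n_modules < 1:
            raise ValueError("module_loading_cap must be in (0, 1], n_modules >= 1")
        _module_structure(self)  # validates target feasibility


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus the ground truth used to generate it."""

    protein_matrix: ProteinMatrix
    clinical: ClinicalTable
    outcome: OutcomeVector
    truth: pd.DataFrame  # columns: protein_id, target_r (signed)

    def __post_init__(self) -> None:
        n = self.protein_matrix.n_patients
        if self.clinical.n_patients != n or len(self.outcome.patient_ids) != n:
            raise ValueError("component row counts disagree")

    @property
    def informative_proteins(self) -> list[str]:
        return list(self.truth["protein_id"])


def _noise_log_sd(cv: float) -> float:
    # CV of a log-normal: cv^2 = exp(sigma^2) - 1
    return math.sqrt(math.log(1.0 + cv * cv))


def _signed_targets(config: CohortConfig) -> np.ndarray:
    lo, hi = config.target_abs_correlation_range
    k = config.n_informative
    if k == 0:
        return np.empty(0)
    mags = np.linspace(lo, hi, k) if k > 1 else np.array([(lo + hi) / 2])
    signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    return mags * signs


def _module_structure(config: CohortConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Targets, per-protein module index, and module-outcome correlations.

    Modules are consecutive strata of the magnitude-ordered targets. Each
    module's outcome correlation c_g is the smallest value that keeps every
    within-module loading (|r_j| / c_g) at or below the loading cap. The
    c_g must satisfy sum(c_g^2) < 1 for the latent outcome model to exist.
    """
    targets = _signed_targets(config)
    k = len(targets)
    if k == 0:
        return targets, np.empty(0, dtype=int), np.empty(0)
    m = min(config.n_modules, k)
    module_idx = np.concatenate(
        [np.full(len(chunk), g) for g, chunk in enumerate(np.array_split(np.arange(k), m))]
    )
    c = np.array(
        [np.abs(targets[module_idx == g]).max() / config.module_loading_cap for g in range(m)]
    )
    if (c >= 1).any() or (c**2).sum() >= 1:
        raise ValueError(
            "impossible correlation targets: module-outcome correlations "
            f"(sum of squares {float((c**2).sum()):.3f}) must stay below 1; "
            "lower the targets, raise module_loading_cap, or use fewer modules"
        )
    return targets, module_idx, c


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort; identical config and seed give identical output."""
    rng = np.random.default_rng(config.seed)
    n, p, k = config.n_patients, config.n_proteins, config.n_informative
    sigma_b = config.log_ratio_sd
    sigma_e = _noise_log_sd(config.noise_cv)

    patient_ids = [f"P{i + 1:04d}" for i in range(n)]
    protein_ids = [f"PROT_{j + 1:04d}" for j in range(p)]

    targets, module_idx, c = _module_structure(config)
    m = len(c)
    U = rng.standard_normal((n, m)) if m else np.empty((n, 0))

    # Per-protein loading on its module factor, corrected for measurement-
    # noise attenuation so corr(observed log-ratio, delta-CRP) hits target:
    # corr(x_j, u_g) * corr(u_g, delta) = (|r_j|/c_g) * c_g = |r_j|.
    dilution = math.sqrt(sigma_b**2 + sigma_e**2) / sigma_b
    loadings = np.zeros(k)
    if k:
        loadings = targets / c[module_idx] * dilution
    if np.any(np.abs(loadings) >= 1):
        raise ValueError("impossible correlation targets at current noise settings")

    log_ratios = np.empty((n, p))
    if k:
        unique = rng.standard_normal((n, k))
        log_ratios[:, :k] = sigma_b * (
            U[:, module_idx] * loadings[None, :] + unique * np.sqrt(1 - loadings**2)[None, :]
        )
    log_ratios[:, k:] = sigma_b * rng.standard_normal((n, p - k))
    log_ratios += sigma_e * rng.standard_normal((n, p))  # technical noise
    ratios = np.exp(log_ratios)

    # delta-CRP: intercept solved so P(delta > 0) = prevalence target.
    signal_var = float((c**2).sum())
    latent = U @ c + math.sqrt(1 - signal_var) * rng.standard_normal(n) if m else (
        rng.standard_normal(n)
    )
    mu = config.delta_crp_sd * norm.ppf(config.event_prevalence_target)
    delta = mu + config.delta_crp_sd * latent
    event = delta > 0

    clinical = _draw_clinical(rng, patient_ids, delta, event, config)
    matrix = ProteinMatrix(
        pd.DataFrame(
            ratios, index=pd.Index(patient_ids, name="patient_id"), columns=protein_ids
        )
    )
    truth = pd.DataFrame(
        {"protein_id": protein_ids[:k], "target_r": targets, "module": module_idx.astype(int)}
    )
    return SyntheticCohort(
        protein_matrix=matrix,
        clinical=clinical,
        outcome=derive_outcome(clinical),
        truth=truth,
    )


def null_cohort(config: CohortConfig) -> SyntheticCohort:
    """Negative control: no protein carries outcome information."""
    return generate_cohort(replace(config, n_informative=0))


def _draw_clinical(
    rng: np.random.Generator,
    patient_ids: list[str],
    delta: np.ndarray,
    event: np.ndarray,
    config: CohortConfig,
) -> ClinicalTable:
    n = len(patient_ids)
    eff = {**DEFAULT_COVARIATE_EFFECTS, **dict(config.covariate_effects)}

    # Index CRP: log-normal around median 35 mg/L (IQR ~16-67), floored so
    # next-day CRP stays positive even for large decreases. Large decreases
    # thereby start from high baselines, as observed clinically.
    crp_index = 35.0 * np.exp(1.06 * rng.standard_normal(n))
    crp_index = np.maximum(crp_index, 1.0 - np.minimum(delta, 0.0))
    crp_next = crp_index + delta

    donor_age = 46.0 + eff["donor_age_event_shift"] * event + 9.0 * rng.standard_normal(n)
    donor_age = np.clip(donor_age, 18, 85).round(0)

    p_deceased = np.where(event, eff["deceased_prob_event"], eff["deceased_prob_nonevent"])
    donor_status = np.where(rng.random(n) < p_deceased, "deceased", "living")

    dial_logmed = np.where(
        event, eff["dialysis_log_median_event"], eff["dialysis_log_median_nonevent"]
    )
    dialysis = np.exp(dial_logmed + 1.3 * rng.standard_normal(n)).round(0)

    hosp_logmed = np.where(
        event,
        eff["hospitalization_log_median_event"],
        eff["hospitalization_log_median_nonevent"],
    )
    hospitalization = np.maximum(np.exp(hosp_logmed + 0.35 * rng.standard_normal(n)), 1.0).round(1)

    table = pd.DataFrame(
        {
            "crp_index": crp_index,
            "crp_next": crp_next,
            "donor_age": donor_age,
            "donor_sex": np.where(rng.random(n) < 0.45, "male", "female"),
            "donor_status": donor_status,
            "recipient_age": np.clip(51 + 10 * rng.standard_normal(n), 18, 85).round(0),
            "recipient_sex": np.where(rng.random(n) < 0.60, "male", "female"),
            "dialysis_months": dialysis,
            "methylprednisolone": (rng.random(n) < 29 / 91).astype(int),
            "hospitalization_days": hospitalization,
            "hla_mismatches": rng.binomial(6, 0.5, size=n),
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )
    return ClinicalTable(table)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path, dialect: str = "csv") -> dict[str, str]:
    """Write matrix + clinical CSVs and a JSON truth file; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "tsv" if dialect == "tsv" else "csv"
    paths = {
        "protein_matrix": str(outdir / f"protein_matrix.{ext}"),
        "clinical": str(outdir / f"clinical.{ext}"),
        "truth": str(outdir / "truth.json"),
    }
    write_protein_matrix(cohort.protein_matrix, paths["protein_matrix"], dialect)
    write_clinical_table(cohort.clinical, paths["clinical"], dialect)
    truth = {
        "informative_proteins": [
            {"protein_id": row.protein_id, "target_r": float(row.target_r), "module": int(row.module)}
            for row in cohort.truth.itertuples()
        ]
    }
    Path(paths["truth"]).write_text(json.dumps(truth, indent=1))
    return paths
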