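"""Seeded synthetic student cohorts with the survey schema.

The generator emulates a first-year student well-being survey: ordinal
symptom items driven by a latent severity per instrument (producing
realistic inter-item correlation), yes/no history items coded 1 = Yes /
2 = No, substance-use frequency items on their per-variable scales, and a
Spring follow-up whose positive/negative status is drawn from a planted
logistic model on baseline quantities.  The logistic intercept is solved
numerically so the empirical follow-up prevalence matches its target.

It is a test harness with known ground truth, not a clinically validated
population simulator: binary history variables are sampled independently
of the symptom latents, and the planted coefficients are generator
defaults, not estimates from any study population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .instruments import (
    BINARY_VARS,
    GAD7_ITEMS,
    GAD7_ITEMS_T2,
    PHQ9_ITEMS,
    PHQ9_ITEMS_T2,
    STRESS_ITEMS,
    SUBSTANCE_VARS,
)

AUX_COLUMNS = ("SEX", "AGE_BAND", "PROGRAM")

#: default lifetime/family/adversity/suicidality prevalences
DEFAULT_PREVALENCES: dict[str, float] = {
    "ANXIETY_1": 0.15, "MOOD_1": 0.10, "PSYCHOTIC_1": 0.01, "EATING_1": 0.06,
    "NEURO_1": 0.07, "SUBSTANCE_1": 0.03, "EMERGE_1": 0.06,
    "FANXIETY_1": 0.15, "FMOOD_1": 0.20, "FPSYCHOTIC_1": 0.03,
    "FSUBSTANCE_1": 0.10,
    "REJECTED_1": 0.15, "PHYSABUSE_1": 0.06, "BULLYING_1": 0.25,
    "SABUSE_1": 0.08, "PDEATH_1": 0.02,
    "WISHDEAD_1": 0.30, "SUICIDEA_1": 0.20, "SUICATMP_1": 0.05,
    "SELFHARM_1": 0.18,
}

#: per-category probabilities of the substance frequency codes
DEFAULT_SUBSTANCE_PROBS: dict[str, tuple[float, ...]] = {
    # weekly dialect, codes 0-4
    "SLEEPING_1": (0.92, 0.04, 0.02, 0.013, 0.007),
    "STIM_1": (0.94, 0.03, 0.015, 0.010, 0.005),
    "OPIATE_1": (0.96, 0.02, 0.010, 0.007, 0.003),
    "PSYCHEDELIC_1": (0.93, 0.045, 0.015, 0.007, 0.003),
    "BINGE_1": (0.35, 0.25, 0.20, 0.15, 0.05),
    # monthly dialect, codes 0-5
    "COCAINE_1": (0.95, 0.025, 0.013, 0.007, 0.003, 0.002),
    "STREET_1": (0.96, 0.020, 0.010, 0.006, 0.003, 0.001),
    "RXMISUSE_1": (0.95, 0.025, 0.013, 0.007, 0.003, 0.002),
    "ACADEMIC_1": (0.93, 0.035, 0.020, 0.009, 0.004, 0.002),
    # cannabis uses the early (0-4) or late (0-5) dialect per term
    "CANNABIS_1": (0.70, 0.13, 0.07, 0.06, 0.04),
    "CANNABIS_1_LATE": (0.70, 0.10, 0.06, 0.07, 0.04, 0.03),
}

#: planted logistic coefficients on decoded baseline quantities
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "phq9_total": 0.15,
    "gad7_total": 0.10,
    "ANXIETY_1": 0.5,
    "FMOOD_1": 0.4,
    "BULLYING_1": 0.4,
    "STRESS_4_1": 0.2,
}

# ordinal item thresholds on a standard-normal latent; item value =
# number of thresholds exceeded.  Chosen so full-cohort PHQ-9/GAD-7 total
# means sit near the published descriptive statistics of entry surveys
# (~7.7 and ~8.0 with SD ~5-6).  Items within an instrument are
# exchangeable except the two rare PHQ-9 items (psychomotor change and
# suicidal thoughts), which carry positive threshold offsets.
PHQ9_THRESHOLDS = (-0.18, 0.60, 1.40)
GAD7_THRESHOLDS = (-0.45, 0.35, 1.20)
STRESS_THRESHOLDS = (-0.80, 0.00, 0.80, 1.60)
DIFF_THRESHOLDS = (0.50, 1.30, 2.10)
PHQ9_ITEM_OFFSETS = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.2, 0.9)
ITEM_LOADING = 0.75  # latent loading; residual sd = sqrt(1 - loading^2)


@dataclass
class CohortConfig:
    """Study conditions of a simulated cohort."""

    n: int = 2285
    seed: int = 0
    target_prevalence: float = 0.21           # per outcome, at follow-up
    prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    substance_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTANCE_PROBS))
    latent_corr: float = 0.6                  # depression-anxiety latent corr
    missing_rate: float = 0.05
    missing_mechanism: str = "MCAR"           # or "MAR"
    followup_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be positive")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target prevalence must be in (0, 1)")
        for name, p in self.prevalences.items():
            if not 0 < p < 1:
                raise ValueError(f"prevalence for {name} must be in (0, 1)")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ValueError("missing mechanism must be MCAR or MAR")
        if not 0 <= self.missing_rate <= 0.9:
            raise ValueError("missing rate must be in [0, 0.9]")


def _ordinal_items(
    z: np.ndarray,
    n_items: int,
    thresholds: tuple[float, ...],
    rng: np.random.Generator,
    offsets: tuple[float, ...] | None = None,
) -> np.ndarray:
    """Graded items from a shared latent plus item-specific noise."""
    resid = np.sqrt(1.0 - ITEM_LOADING**2)
    v = ITEM_LOADING * z[:, None] + resid * rng.standard_normal((z.shape[0], n_items))
    if offsets is not None:
        v = v - np.asarray(offsets)[None, :]
    t = np.asarray(thresholds)
    return (v[:, :, None] > t[None, None, :]).sum(axis=2).astype(float)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Baseline survey table in raw coding (yes/no as 1/2), seeded."""
    rng = np.random.default_rng([config.seed, 1])
    n = config.n
    out: dict[str, object] = {
        "student_id": [f"S{i:06d}" for i in range(n)],
        "term_index": rng.integers(1, 6, size=n),
    }
    # auxiliaries (used by MAR missingness and as imputation predictors)
    out["SEX"] = rng.choice([1, 2, 3], size=n, p=[0.27, 0.72, 0.01]).astype(float)
    out["AGE_BAND"] = rng.choice([1, 2, 3], size=n, p=[0.94, 0.05, 0.01]).astype(float)
    out["PROGRAM"] = rng.integers(1, 6, size=n).astype(float)

    corr = config.latent_corr
    cov = np.array([[1.0, corr], [corr, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    z_dep, z_anx = z[:, 0], z[:, 1]
    z_stress = 0.6 * (z_dep + z_anx) / np.sqrt(2 * (1 + corr)) \
        + np.sqrt(1 - 0.36) * rng.standard_normal(n)

    phq = _ordinal_items(z_dep, 9, PHQ9_THRESHOLDS, rng, PHQ9_ITEM_OFFSETS)
    for j, name in enumerate(PHQ9_ITEMS):
        out[name] = phq[:, j]
    gad = _ordinal_items(z_anx, 7, GAD7_THRESHOLDS, rng)
    for j, name in enumerate(GAD7_ITEMS):
        out[name] = gad[:, j]
    out["PHQ9_DIFF_1"] = _ordinal_items(z_dep, 1, DIFF_THRESHOLDS, rng)[:, 0]
    out["GAD7_DIFF_1"] = _ordinal_items(z_anx, 1, DIFF_THRESHOLDS, rng)[:, 0]
    stress = _ordinal_items(z_stress, 4, STRESS_THRESHOLDS, rng)
    stress[:, 1] = 4 - stress[:, 1]   # items 2 and 3 are positively worded
    stress[:, 2] = 4 - stress[:, 2]
    for j, name in enumerate(STRESS_ITEMS):
        out[name] = stress[:, j]

    for name in BINARY_VARS:
        yes = rng.random(n) < config.prevalences[name]
        out[name] = np.where(yes, 1.0, 2.0)    # raw coding: 1 = Yes, 2 = No

    term = np.asarray(out["term_index"])
    for name in SUBSTANCE_VARS:
        if name == "CANNABIS_1":
            early = rng.choice(5, size=n, p=_norm(config.substance_probs[name]))
            late = rng.choice(
                6, size=n, p=_norm(config.substance_probs["CANNABIS_1_LATE"]))
            out[name] = np.where(term <= 2, early, late).astype(float)
        else:
            p = _norm(config.substance_probs[name])
            out[name] = rng.choice(len(p), size=n, p=p).astype(float)
    return pd.DataFrame(out)


def _norm(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return p / p.sum()


def planted_linear_predictor(
    baseline: pd.DataFrame, coefficients: dict[str, float]
) -> np.ndarray:
    """Intercept-free linear predictor of the planted outcome model."""
    lp = np.zeros(len(baseline))
    phq_total = baseline[list(PHQ9_ITEMS)].sum(axis=1).to_numpy()
    gad_total = baseline[list(GAD7_ITEMS)].sum(axis=1).to_numpy()
    for name, coef in coefficients.items():
        if name == "phq9_total":
            lp += coef * phq_total
        elif name == "gad7_total":
            lp += coef * gad_total
        elif name in BINARY_VARS:
            yes = (baseline[name].to_numpy() == 1).astype(float)
            lp += coef * yes
        else:
            lp += coef * baseline[name].to_numpy(dtype=float)
    return lp


def calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Solve mean(expit(b0 + lp)) = target for the intercept b0."""
    return brentq(lambda b0: expit(b0 + lp).mean() - target, -30.0, 30.0)


def _fill_items(
    totals: np.ndarray, n_items: int, cap: int, rng: np.random.Generator
) -> np.ndarray:
    """Distribute each row's total over items uniformly, capped per item."""
    n = totals.shape[0]
    values = np.zeros((n, n_items), dtype=float)
    remaining = totals.astype(int).copy()
    guard = 0
    while remaining.any():
        guard += 1
        if guard > 2000:  # pragma: no cover
            raise RuntimeError("item allocation failed to converge")
        active = remaining > 0
        cols = rng.integers(0, n_items, size=n)
        ok = active & (values[np.arange(n), cols] < cap)
        values[np.nonzero(ok)[0], cols[ok]] += 1
        remaining[ok] -= 1
    return values


def label_followup(baseline: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Append time-2 PHQ-9/GAD-7 items consistent with planted outcomes.

    Positive status per outcome is Bernoulli with probability
    expit(b0 + lp); positive rows receive time-2 items totalling >= 10,
    negative rows < 10.  Students without a follow-up (when
    ``followup_rate`` < 1) get missing time-2 items.
    """
    rng = np.random.default_rng([config.seed, 2])
    out = baseline.copy()
    n = len(out)
    lp = planted_linear_predictor(out, config.coefficients)
    b0 = calibrate_intercept(lp, config.target_prevalence)
    p = expit(b0 + lp)
    dep_pos = rng.random(n) < p
    anx_pos = rng.random(n) < p

    dep_total = np.where(
        dep_pos, 10 + rng.binomial(17, 0.15, size=n), rng.binomial(9, 0.35, size=n))
    anx_total = np.where(
        anx_pos, 10 + rng.binomial(11, 0.15, size=n), rng.binomial(9, 0.35, size=n))
    phq2 = _fill_items(dep_total, 9, 3, rng)
    gad2 = _fill_items(anx_total, 7, 3, rng)
    for j, name in enumerate(PHQ9_ITEMS_T2):
        out[name] = phq2[:, j]
    for j, name in enumerate(GAD7_ITEMS_T2):
        out[name] = gad2[:, j]
    if config.followup_rate < 1.0:
        absent = rng.random(n) >= config.followup_rate
        out.loc[absent, list(PHQ9_ITEMS_T2 + GAD7_ITEMS_T2)] = np.nan
    return out


#: baseline columns eligible for missingness injection
def _blankable_columns(cohort: pd.DataFrame) -> list[str]:
    eligible = (
        PHQ9_ITEMS + GAD7_ITEMS + ("PHQ9_DIFF_1", "GAD7_DIFF_1")
        + STRESS_ITEMS + BINARY_VARS + SUBSTANCE_VARS
    )
    return [c for c in eligible if c in cohort.columns]


def inject_missingness(
    cohort: pd.DataFrame, config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank baseline cells at the configured rate; returns (cohort, mask).

    Follow-up outcome columns and the auxiliaries that drive the MAR
    mechanism are never blanked.  The boolean mask marks blanked cells for
    truth-recovery tests.
    """
    rng = np.random.default_rng([config.seed, 3])
    out = cohort.copy()
    cols = _blankable_columns(out)
    n = len(out)
    if config.missing_mechanism == "MAR":
        male = (out["SEX"].to_numpy() == 1).astype(float)
        older = (out["AGE_BAND"].to_numpy() > 1).astype(float)
        row_rate = np.clip(
            config.missing_rate * (0.7 + 0.6 * male + 0.6 * older), 0, 0.9)
    else:
        row_rate = np.full(n, config.missing_rate)
    mask = rng.random((n, len(cols))) < row_rate[:, None]
    frame = out[cols].to_numpy(dtype=float)
    frame[mask] = np.nan
    out[cols] = frame
    mask_df = pd.DataFrame(mask, columns=cols, index=out.index)
    return out, mask_df


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """generate -> label follow-up -> inject missingness; returns (cohort, mask)."""
    baseline = generate_cohort(config)
    labeled = label_followup(baseline, config)
    return inject_missingness(labeled, config)
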