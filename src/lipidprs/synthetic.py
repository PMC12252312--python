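"""Synthetic genotype-phenotype-lifestyle cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes, so every stage of the pipeline is testable without access to the
private study registry:

* genotypes drawn from Hardy-Weinberg proportions at configurable allele
  frequencies, with optional pairwise LD induced by index-SNP copying;
* normally distributed HDL-C and log-normally distributed (right-skewed)
  triglycerides, with additive per-allele genetic effects, a sex shift,
  and binary lifestyle/metabolic exposure shifts that may differ between
  the high and low genetic-risk strata (additive, amplification, or
  ceiling patterns);
* binary outcomes (CVD and others) drawn from declared logistic models;
* a registry with mutually exclusive exclusion flags replicating a
  participant-selection flowchart.

All randomness derives from a single integer seed expanded into named
per-stage substreams; identical ``(spec, seed)`` give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import lognorm, norm

from .cohort_filter import EXCLUSION_ORDER

_STAGE_IDS = {"genotypes": 1, "phenotypes": 2, "registry": 3}

#: Participant-selection flowchart defaults: registry size and per-reason
#: exclusion counts leaving 5584 eligible subjects.
DEFAULT_REGISTRY_TOTAL = 12626
DEFAULT_EXCLUSION_COUNTS = {
    "underage": 245,
    "missing_medical_lifestyle": 705,
    "missing_labs": 3930,
    "missing_genotype": 2162,
}

#: Cohort female fraction: 3861 of 5584 subjects (69.1%).
DEFAULT_FEMALE_FRACTION = 3861 / 5584

#: Exposure columns derived from continuous traits rather than drawn as
#: Bernoulli flags.
_DERIVED_EXPOSURES = ("obesity", "hba1c_high", "male")


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STAGE_IDS[stage])))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


# ---------------------------------------------------------------------------
# Specification types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpSpec:
    """One simulated SNP.

    ``maf`` is the effect-allele frequency (may exceed 0.5; the QC stage
    folds it).  ``ld_block`` names the rsID of an index SNP whose genotype
    this SNP copies with probability ``ld_copy_prob`` (drawing
    independently otherwise), inducing pairwise LD of r ~= copy prob.
    """

    rsid: str
    maf: float
    ld_block: str | None = None
    ld_copy_prob: float = 0.0
    effect_allele: str = "A"
    other_allele: str = "G"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf < 1.0):
            raise ValueError(
                f"SNP {self.rsid!r}: maf must be in (0, 1), got {self.maf!r}"
            )
        if not (0.0 <= self.ld_copy_prob <= 1.0):
            raise ValueError(
                f"SNP {self.rsid!r}: ld_copy_prob must be in [0, 1]"
            )
        if self.ld_block == self.rsid:
            raise ValueError(f"SNP {self.rsid!r} cannot copy itself")


@dataclass(frozen=True)
class TraitSpec:
    """One simulated continuous trait (mg/dL unless stated otherwise).

    The trait value is::

        noise + score_effect * sum_j(score_weights[j] * dosage_j)
              + sum_j(per_allele_effects[j] * dosage_j)
              + sex_effect * [male] + exposure shifts

    where ``noise`` is normal or lognormal with the given baseline mean
    and SD.  ``score_effect`` is the planted per-unit effect of the true
    weighted genetic score — the quantity the association stage recovers.
    ``stratify_by_sex`` controls whether the trait's high/low genetic-risk
    stratum (90th percentile of the true score) is defined within sex.
    """

    name: str
    baseline_mean: float
    baseline_sd: float
    distribution: str = "normal"
    score_weights: Mapping[str, float] = field(default_factory=dict)
    score_effect: float = 0.0
    per_allele_effects: Mapping[str, float] = field(default_factory=dict)
    sex_effect: float = 0.0
    stratify_by_sex: bool = False

    def __post_init__(self) -> None:
        if self.baseline_sd <= 0:
            raise ValueError(f"trait {self.name!r}: baseline_sd must be > 0")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError(
                f"trait {self.name!r}: distribution must be normal|lognormal"
            )
        if self.distribution == "lognormal" and self.baseline_mean <= 0:
            raise ValueError(f"trait {self.name!r}: lognormal mean must be > 0")


@dataclass(frozen=True)
class ExposureEffect:
    """Shift (mg/dL) a binary exposure adds to a trait, by genetic stratum.

    ``effect_low`` applies in the low genetic-risk stratum and
    ``effect_high`` in the high stratum of the *same trait*.  The three
    canonical patterns are additive (equal shifts), amplification
    (larger in the high stratum) and ceiling (zero in the high stratum).
    """

    trait: str
    exposure: str
    effect_low: float
    effect_high: float

    @classmethod
    def additive(cls, trait: str, exposure: str, effect: float) -> "ExposureEffect":
        return cls(trait, exposure, effect, effect)

    @classmethod
    def amplified(
        cls, trait: str, exposure: str, effect_low: float, effect_high: float
    ) -> "ExposureEffect":
        return cls(trait, exposure, effect_low, effect_high)

    @classmethod
    def ceiling(cls, trait: str, exposure: str, effect_low: float) -> "ExposureEffect":
        return cls(trait, exposure, effect_low, 0.0)


@dataclass(frozen=True)
class LogisticModel:
    """Binary-outcome model: logit(p) = intercept + sum(coef * column)."""

    intercept: float
    coefficients: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimSpec:
    """Full generative specification for one synthetic cohort."""

    n_subjects: int
    snp_specs: Sequence[SnpSpec] = ()
    trait_specs: Sequence[TraitSpec] = ()
    covariate_prevalences: Mapping[str, float] = field(default_factory=dict)
    exposure_effects: Sequence[ExposureEffect] = ()
    cvd_model: LogisticModel = LogisticModel(float(logit(0.087)))
    extra_binary_models: Mapping[str, LogisticModel] = field(default_factory=dict)
    female_fraction: float = DEFAULT_FEMALE_FRACTION
    #: centre each trait's combined genetic/sex/exposure shift at zero, so
    #: baseline_mean is the marginal trait mean; slopes and group contrasts
    #: are unaffected (a constant offset per cohort).
    center_shifts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction must be in [0, 1]")
        rsids = [s.rsid for s in self.snp_specs]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsIDs in snp_specs")
        declared = set(rsids)
        for snp in self.snp_specs:
            if snp.ld_block is not None and snp.ld_block not in declared:
                raise ValueError(
                    f"SNP {snp.rsid!r} references unknown ld_block index "
                    f"{snp.ld_block!r}"
                )
        for trait in self.trait_specs:
            for rsid in list(trait.score_weights) + list(trait.per_allele_effects):
                if rsid not in declared:
                    raise ValueError(
                        f"trait {trait.name!r} references undeclared SNP {rsid!r}"
                    )
        for name, prev in self.covariate_prevalences.items():
            if not (0.0 <= prev <= 1.0):
                raise ValueError(f"prevalence of {name!r} must be in [0, 1]")
        trait_names = {t.name for t in self.trait_specs}
        for eff in self.exposure_effects:
            if eff.trait not in trait_names:
                raise ValueError(
                    f"exposure effect references undeclared trait {eff.trait!r}"
                )
            if (
                eff.exposure not in self.covariate_prevalences
                and eff.exposure not in _DERIVED_EXPOSURES
            ):
                raise ValueError(
                    f"exposure effect references absent exposure {eff.exposure!r}"
                )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(spec: SimSpec) -> pd.DataFrame:
    """Draw a subjects x SNPs effect-allele dosage matrix under HWE.

    Each SNP's dosage is Binomial(2, maf) — equivalently the HWE genotype
    frequencies p², 2pq, q².  A SNP with an ``ld_block`` copies its index
    SNP's genotype per subject with probability ``ld_copy_prob`` and keeps
    its independent draw otherwise.
    """
    rng = _rng(spec.seed, "genotypes")
    n = spec.n_subjects
    independent: dict[str, np.ndarray] = {}
    for snp in spec.snp_specs:
        independent[snp.rsid] = rng.binomial(2, snp.maf, size=n).astype(float)
    columns: dict[str, np.ndarray] = {}
    for snp in spec.snp_specs:
        d = independent[snp.rsid]
        if snp.ld_block is not None and snp.ld_copy_prob > 0.0:
            copy_mask = rng.random(n) < snp.ld_copy_prob
            d = np.where(copy_mask, columns.get(snp.ld_block, independent[snp.ld_block]), d)
        columns[snp.rsid] = d
    frame = pd.DataFrame(columns, index=pd.RangeIndex(n))
    frame.index.name = "subject"
    return frame


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _high_stratum(score: np.ndarray, male: np.ndarray, within_sex: bool) -> np.ndarray:
    high = np.zeros(score.shape, dtype=bool)
    if within_sex:
        for is_male in (False, True):
            idx = male == (1 if is_male else 0)
            if idx.any():
                cut = np.quantile(score[idx], 0.90)
                high[idx] = score[idx] >= cut
    else:
        cut = np.quantile(score, 0.90)
        high = score >= cut
    return high


def simulate_phenotypes(genotypes: pd.DataFrame, spec: SimSpec) -> pd.DataFrame:
    """Generate the phenotype/covariate table for a genotype matrix.

    Sex is assigned by exact count (``round(female_fraction * n)`` females,
    positions permuted); lifestyle flags are Bernoulli at their declared
    prevalences; traits follow their :class:`TraitSpec`; binary outcomes
    follow their logistic models.  The returned frame carries the true
    per-trait genetic scores (``score_true_<trait>``) and risk strata
    (``high_true_<trait>``) for parameter-recovery tests, and stores the
    generating spec in ``frame.attrs["spec"]``.
    """
    n = spec.n_subjects
    if len(genotypes) != n:
        raise ValueError(
            f"genotype matrix has {len(genotypes)} subjects, spec says {n}"
        )
    rng = _rng(spec.seed, "phenotypes")
    cohort = pd.DataFrame(index=genotypes.index.copy())
    cohort["subject_id"] = [f"S{i:06d}" for i in range(n)]

    # sex: exact female count, permuted positions
    n_female = int(round(spec.female_fraction * n))
    sex = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sex)
    cohort["sex"] = sex
    male = (sex == "M").astype(int)
    cohort["male"] = male

    # binary lifestyle/medical flags
    for name, prev in spec.covariate_prevalences.items():
        cohort[name] = rng.binomial(1, prev, size=n)

    # continuous traits
    for trait in spec.trait_specs:
        score = np.zeros(n)
        for rsid, w in trait.score_weights.items():
            score += w * genotypes[rsid].to_numpy(dtype=float)
        shift = trait.score_effect * score
        for rsid, e in trait.per_allele_effects.items():
            shift += e * genotypes[rsid].to_numpy(dtype=float)
        shift = shift + trait.sex_effect * male
        if trait.score_weights or trait.per_allele_effects:
            high = _high_stratum(score, male, trait.stratify_by_sex)
            cohort[f"score_true_{trait.name}"] = score
            cohort[f"high_true_{trait.name}"] = high.astype(int)
        else:
            high = np.zeros(n, dtype=bool)
        for eff in spec.exposure_effects:
            if eff.trait != trait.name:
                continue
            exposed = _exposure_column(cohort, eff.exposure, spec)
            shift = shift + np.where(
                exposed.astype(bool), np.where(high, eff.effect_high, eff.effect_low), 0.0
            )
        if spec.center_shifts and np.any(shift):
            shift = shift - shift.mean()
        if trait.distribution == "normal":
            noise = rng.normal(trait.baseline_mean, trait.baseline_sd, size=n)
            value = noise + shift
        else:
            mu, sigma = _lognormal_params(trait.baseline_mean, trait.baseline_sd)
            noise = rng.lognormal(mu, sigma, size=n)
            value = np.maximum(noise + shift, 0.1)
        cohort[trait.name] = value
        # derived metabolic categories, available to later traits' effects
        if trait.name == "bmi":
            cohort["obesity"] = (cohort["bmi"] >= 30.0).astype(int)
        elif trait.name == "hba1c":
            cohort["hba1c_high"] = (cohort["hba1c"] >= 5.7).astype(int)

    # binary outcome models
    models = {"cvd": spec.cvd_model, **spec.extra_binary_models}
    for name, model in models.items():
        eta = np.full(n, model.intercept, dtype=float)
        for col, coef in model.coefficients.items():
            if col not in cohort.columns:
                raise ValueError(
                    f"binary model {name!r} references absent predictor {col!r}"
                )
            eta += coef * cohort[col].to_numpy(dtype=float)
        cohort[name] = rng.binomial(1, expit(eta))

    cohort.attrs["spec"] = spec
    return cohort


def _exposure_column(cohort: pd.DataFrame, exposure: str, spec: SimSpec) -> np.ndarray:
    if exposure in cohort.columns:
        return cohort[exposure].to_numpy()
    # derived exposures may be requested before their base trait is built
    raise ValueError(
        f"exposure {exposure!r} not available yet; declare its base trait "
        "before traits that depend on it"
    )


def simulate_cohort(spec: SimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: genotypes and phenotypes in one call."""
    genotypes = simulate_genotypes(spec)
    return genotypes, simulate_phenotypes(genotypes, spec)


# ---------------------------------------------------------------------------
# Registry with exclusion flags
# ---------------------------------------------------------------------------

def simulate_registry(
    n_total: int, exclusion_counts: Mapping[str, int], seed: int = 0
) -> pd.DataFrame:
    """Build a registry with exactly the requested exclusion-flag counts.

    Flags are assigned mutually exclusively in cascade order, so each
    record carries at most one exclusion reason; record order is shuffled
    by the seed (same inputs give identical counts for any seed).
    """
    unknown = set(exclusion_counts) - set(EXCLUSION_ORDER)
    if unknown:
        raise ValueError(f"unknown exclusion reasons: {sorted(unknown)}")
    counts = {r: int(exclusion_counts.get(r, 0)) for r in EXCLUSION_ORDER}
    if any(c < 0 for c in counts.values()):
        raise ValueError("exclusion counts must be non-negative")
    total_excluded = sum(counts.values())
    if total_excluded > n_total:
        raise ValueError(
            f"exclusion counts sum to {total_excluded} > n_total {n_total}"
        )
    flags = {r: np.zeros(n_total, dtype=bool) for r in EXCLUSION_ORDER}
    start = 0
    for reason in EXCLUSION_ORDER:
        flags[reason][start:start + counts[reason]] = True
        start += counts[reason]
    registry = pd.DataFrame(flags)
    registry["subject_id"] = [f"R{i:06d}" for i in range(n_total)]
    rng = _rng(seed, "registry")
    order = rng.permutation(n_total)
    registry = registry.iloc[order].reset_index(drop=True)
    return registry[["subject_id", *EXCLUSION_ORDER]]


def default_registry(seed: int = 0) -> pd.DataFrame:
    """Flowchart-replica registry: 12,626 records, 5,584 eligible."""
    return simulate_registry(DEFAULT_REGISTRY_TOTAL, DEFAULT_EXCLUSION_COUNTS, seed)


# ---------------------------------------------------------------------------
# Default, study-calibrated specification
# ---------------------------------------------------------------------------

# Allele frequencies and true score weights for the packaged panel rsIDs.
# Chosen once as plausible common-variant values; the weights emulate the
# magnitude of in-cohort univariate logistic betas.
_HDL_PANEL_PARAMS = {
    "rs5882": (0.31, 0.21), "rs3764261": (0.28, 0.34), "rs1800961": (0.12, 0.18),
    "rs2338104": (0.42, 0.27), "rs10850219": (0.25, 0.45), "rs1532085": (0.38, 0.30),
    "rs2000813": (0.19, 0.16), "rs2156552": (0.22, 0.38), "rs17411031": (0.35, 0.24),
    "rs2075440": (0.15, 0.29), "rs4660293": (0.27, 0.20), "rs7679": (0.44, 0.33),
    "rs13107325": (0.09, 0.26),
}
_TG_PANEL_PARAMS = {
    "rs2072560": (0.14, 0.28), "rs7557067": (0.33, 0.17), "rs157582": (0.21, 0.24),
    "rs439401": (0.36, 0.31), "rs5128": (0.26, 0.22), "rs2068888": (0.41, 0.19),
    "rs10889353": (0.18, 0.26), "rs174546": (0.30, 0.35), "rs2929282": (0.11, 0.15),
    "rs780092": (0.38, 0.29), "rs1260326": (0.29, 0.40), "rs2247056": (0.23, 0.18),
    "rs12678919": (0.12, 0.33), "rs17145738": (0.32, 0.21), "rs1495741": (0.22, 0.25),
    "rs7679": (0.44, 0.16), "rs11776767": (0.17, 0.27), "rs2954029": (0.35, 0.30),
    "rs998584": (0.27, 0.23),
}

#: Cohort-descriptive targets for the default generator: prevalence of the
#: binary covariates and mean/SD of the continuous traits.
DEFAULT_PREVALENCES = {
    "t2dm": 0.084,
    "smoking": 0.091,
    "ssb": 0.167,
    "coffee": 0.758,
    "wine": 0.308,
    "treatment": 0.10,
}
DEFAULT_TRAIT_TARGETS = {
    "age": (58.0, 14.2),
    "bmi": (31.3, 5.8),
    "hba1c": (5.1, 2.7),
    "total_chol": (183.4, 48.6),
    "ldl": (109.2, 37.2),
    "hdl": (52.9, 12.5),
    "tg": (130.5, 65.8),
}
#: Planted per-unit effects of the true weighted genetic scores (mg/dL).
DEFAULT_SCORE_EFFECT_HDL = -4.07
DEFAULT_SCORE_EFFECT_TG = 26.47
#: Male-vs-female trait shifts (mg/dL).
DEFAULT_SEX_EFFECT_HDL = -11.5
DEFAULT_SEX_EFFECT_TG = 18.5

# Default additive exposure shifts (mg/dL): (trait, exposure, effect).
_DEFAULT_EXPOSURE_SHIFTS = [
    ("tg", "obesity", 20.0), ("tg", "hba1c_high", 25.0), ("tg", "smoking", 9.0),
    ("tg", "wine", -8.0), ("tg", "ssb", 9.0),
    ("hdl", "obesity", -3.5), ("hdl", "hba1c_high", -2.0), ("hdl", "smoking", -2.0),
    ("hdl", "wine", 1.5), ("hdl", "ssb", -1.0), ("hdl", "coffee", 0.5),
]


def _derived_prevalence(exposure: str) -> float:
    """Prevalence of a derived exposure under the default trait targets."""
    if exposure == "obesity":
        m, s = DEFAULT_TRAIT_TARGETS["bmi"]
        return float(norm.sf(30.0, loc=m, scale=s))
    if exposure == "hba1c_high":
        m, s = DEFAULT_TRAIT_TARGETS["hba1c"]
        mu, sigma = _lognormal_params(m, s)
        return float(lognorm.sf(5.7, s=sigma, scale=np.exp(mu)))
    raise ValueError(exposure)


def default_simspec(
    n_subjects: int = 5584,
    seed: int = 0,
    score_effect_hdl: float = DEFAULT_SCORE_EFFECT_HDL,
    score_effect_tg: float = DEFAULT_SCORE_EFFECT_TG,
    exposure_effects: Sequence[ExposureEffect] | None = None,
    cvd_model: LogisticModel | None = None,
    extra_binary_models: Mapping[str, LogisticModel] | None = None,
) -> SimSpec:
    """Study-calibrated default specification.

    Shifts are mean-centred (``center_shifts``), so each baseline mean is
    the marginal target directly; baseline SDs are solved by subtracting
    the analytic shift variances (independent components) from the target
    variances.
    """
    if exposure_effects is None:
        exposure_effects = [
            ExposureEffect.additive(t, e, v) for t, e, v in _DEFAULT_EXPOSURE_SHIFTS
        ]
    if cvd_model is None:
        cvd_model = LogisticModel(float(logit(0.087)))

    rsids = dict(_HDL_PANEL_PARAMS)
    for rsid, (maf, _) in _TG_PANEL_PARAMS.items():
        rsids.setdefault(rsid, (maf, 0.0))
    snp_specs = [SnpSpec(rsid=r, maf=maf) for r, (maf, _) in rsids.items()]

    male_frac = 1.0 - DEFAULT_FEMALE_FRACTION

    def shift_variance(trait, weights, score_effect, sex_effect):
        var = sex_effect**2 * male_frac * (1 - male_frac)
        for rsid, w in weights.items():
            p = rsids[rsid][0]
            c = score_effect * w
            var += c**2 * 2 * p * (1 - p)
        for eff in exposure_effects:
            if eff.trait != trait:
                continue
            if eff.exposure in DEFAULT_PREVALENCES:
                prev = DEFAULT_PREVALENCES[eff.exposure]
            else:
                prev = _derived_prevalence(eff.exposure)
            e_mean = 0.9 * eff.effect_low + 0.1 * eff.effect_high
            e_sq = 0.9 * eff.effect_low**2 + 0.1 * eff.effect_high**2
            var += prev * e_sq - (prev * e_mean) ** 2
        return var

    hdl_weights = {r: w for r, (_, w) in _HDL_PANEL_PARAMS.items()}
    tg_weights = {r: w for r, (_, w) in _TG_PANEL_PARAMS.items()}

    trait_specs = []
    for name, (target_mean, target_sd) in DEFAULT_TRAIT_TARGETS.items():
        if name == "hdl":
            weights, s_eff, sex_eff = hdl_weights, score_effect_hdl, DEFAULT_SEX_EFFECT_HDL
            dist, within_sex = "normal", True
        elif name == "tg":
            weights, s_eff, sex_eff = tg_weights, score_effect_tg, DEFAULT_SEX_EFFECT_TG
            dist, within_sex = "lognormal", False
        else:
            weights, s_eff, sex_eff = {}, 0.0, 0.0
            dist = "lognormal" if name == "hba1c" else "normal"
            within_sex = False
        v_shift = shift_variance(name, weights, s_eff, sex_eff)
        base_mean = target_mean
        base_var = max(target_sd**2 - v_shift, (0.05 * target_sd) ** 2)
        trait_specs.append(
            TraitSpec(
                name=name,
                baseline_mean=base_mean,
                baseline_sd=float(np.sqrt(base_var)),
                distribution=dist,
                score_weights=weights,
                score_effect=s_eff,
                sex_effect=sex_eff,
                stratify_by_sex=within_sex,
            )
        )

    return SimSpec(
        n_subjects=n_subjects,
        snp_specs=snp_specs,
        trait_specs=trait_specs,
        covariate_prevalences=DEFAULT_PREVALENCES,
        exposure_effects=list(exposure_effects),
        cvd_model=cvd_model,
        extra_binary_models=dict(extra_binary_models or {}),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Flat key-value serialisation (dotted keys)
# ---------------------------------------------------------------------------

def simspec_to_flat(spec: SimSpec) -> dict[str, str]:
    """Serialise a SimSpec to a flat dotted-key mapping.

    Keys: ``n_subjects``, ``seed``, ``female_fraction``, ``center_shifts``,
    ``snp.<rsid>.<field>``, ``trait.<name>.<field>``,
    ``trait.<name>.score_weights.<rsid>``, ``prevalence.<exposure>``,
    ``exposure_effect.<i>.<field>``, ``model.<name>.intercept`` and
    ``model.<name>.coef.<column>`` (the ``cvd`` model included).
    """
    flat: dict[str, str] = {
        "n_subjects": str(spec.n_subjects),
        "seed": str(spec.seed),
        "female_fraction": repr(spec.female_fraction),
        "center_shifts": str(spec.center_shifts).lower(),
    }
    for snp in spec.snp_specs:
        base = f"snp.{snp.rsid}"
        flat[f"{base}.maf"] = repr(snp.maf)
        flat[f"{base}.effect_allele"] = snp.effect_allele
        flat[f"{base}.other_allele"] = snp.other_allele
        if snp.ld_block is not None:
            flat[f"{base}.ld_block"] = snp.ld_block
            flat[f"{base}.ld_copy_prob"] = repr(snp.ld_copy_prob)
    for trait in spec.trait_specs:
        base = f"trait.{trait.name}"
        flat[f"{base}.baseline_mean"] = repr(trait.baseline_mean)
        flat[f"{base}.baseline_sd"] = repr(trait.baseline_sd)
        flat[f"{base}.distribution"] = trait.distribution
        flat[f"{base}.score_effect"] = repr(trait.score_effect)
        flat[f"{base}.sex_effect"] = repr(trait.sex_effect)
        flat[f"{base}.stratify_by_sex"] = str(trait.stratify_by_sex).lower()
        for rsid, w in trait.score_weights.items():
            flat[f"{base}.score_weights.{rsid}"] = repr(w)
        for rsid, e in trait.per_allele_effects.items():
            flat[f"{base}.per_allele_effects.{rsid}"] = repr(e)
    for name, prev in spec.covariate_prevalences.items():
        flat[f"prevalence.{name}"] = repr(prev)
    for i, eff in enumerate(spec.exposure_effects):
        base = f"exposure_effect.{i}"
        flat[f"{base}.trait"] = eff.trait
        flat[f"{base}.exposure"] = eff.exposure
        flat[f"{base}.effect_low"] = repr(eff.effect_low)
        flat[f"{base}.effect_high"] = repr(eff.effect_high)
    models = {"cvd": spec.cvd_model, **spec.extra_binary_models}
    for name, model in models.items():
        flat[f"model.{name}.intercept"] = repr(model.intercept)
        for col, coef in model.coefficients.items():
            flat[f"model.{name}.coef.{col}"] = repr(coef)
    return flat


def simspec_from_flat(flat: Mapping[str, str]) -> SimSpec:
    """Rebuild a SimSpec from its flat dotted-key mapping."""
    snps: dict[str, dict] = {}
    traits: dict[str, dict] = {}
    prevalences: dict[str, float] = {}
    effects: dict[int, dict] = {}
    models: dict[str, dict] = {}
    top: dict[str, str] = {}
    for key, raw in flat.items():
        parts = key.split(".")
        if parts[0] == "snp":
            snps.setdefault(parts[1], {})[parts[2]] = raw
        elif parts[0] == "trait":
            entry = traits.setdefault(parts[1], {})
            if parts[2] in ("score_weights", "per_allele_effects"):
                entry.setdefault(parts[2], {})[parts[3]] = float(raw)
            else:
                entry[parts[2]] = raw
        elif parts[0] == "prevalence":
            prevalences[parts[1]] = float(raw)
        elif parts[0] == "exposure_effect":
            effects.setdefault(int(parts[1]), {})[parts[2]] = raw
        elif parts[0] == "model":
            entry = models.setdefault(parts[1], {"coef": {}})
            if parts[2] == "coef":
                entry["coef"][parts[3]] = float(raw)
            else:
                entry[parts[2]] = raw
        else:
            top[key] = raw

    snp_specs = [
        SnpSpec(
            rsid=rsid,
            maf=float(v["maf"]),
            ld_block=v.get("ld_block"),
            ld_copy_prob=float(v.get("ld_copy_prob", 0.0)),
            effect_allele=v.get("effect_allele", "A"),
            other_allele=v.get("other_allele", "G"),
        )
        for rsid, v in snps.items()
    ]
    trait_specs = [
        TraitSpec(
            name=name,
            baseline_mean=float(v["baseline_mean"]),
            baseline_sd=float(v["baseline_sd"]),
            distribution=v.get("distribution", "normal"),
            score_weights=v.get("score_weights", {}),
            score_effect=float(v.get("score_effect", 0.0)),
            per_allele_effects=v.get("per_allele_effects", {}),
            sex_effect=float(v.get("sex_effect", 0.0)),
            stratify_by_sex=v.get("stratify_by_sex", "false") == "true",
        )
        for name, v in traits.items()
    ]
    exposure_effects = [
        ExposureEffect(
            trait=v["trait"], exposure=v["exposure"],
            effect_low=float(v["effect_low"]), effect_high=float(v["effect_high"]),
        )
        for _, v in sorted(effects.items())
    ]
    logistic = {
        name: LogisticModel(float(v["intercept"]), v["coef"])
        for name, v in models.items()
    }
    cvd_model = logistic.pop("cvd", LogisticModel(float(logit(0.087))))
    return SimSpec(
        n_subjects=int(top["n_subjects"]),
        snp_specs=snp_specs,
        trait_specs=trait_specs,
        covariate_prevalences=prevalences,
        exposure_effects=exposure_effects,
        cvd_model=cvd_model,
        extra_binary_models=logistic,
        female_fraction=float(top.get("female_fraction", DEFAULT_FEMALE_FRACTION)),
        center_shifts=top.get("center_shifts", "true") == "true",
        seed=int(top.get("seed", 0)),
    )


def write_simspec(spec: SimSpec, path) -> None:
    """Write a SimSpec as a flat ``key = value`` file with dotted keys."""
    with open(path, "w") as fh:
        for key, value in simspec_to_flat(spec).items():
            fh.write(f"{key} = {value}\n")


def read_simspec(path) -> SimSpec:
    """Read a SimSpec from a flat dotted-key file."""
    flat: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            flat[key.strip()] = value.strip()
    return simspec_from_flat(flat)
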