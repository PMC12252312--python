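"""Weighted polygenic risk scores: weight fitting, scoring, stratification.

The score for subject *s* is the number of risk alleles at each retained
SNP multiplied by that SNP's in-cohort univariate logistic effect size:

    wPRS_s = sum_i oriented_dosage(s, i) * weight_i

Weights are oriented so that the counted allele is the risk allele: a SNP
with a negative fitted log-OR has its dosage flipped (d -> 2 - d) and its
weight stored as the positive magnitude.  Subjects are stratified at the
empirical 90th percentile of the score (>= cutoff is "high").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panel_qc import SnpRecord, _impute_mean, snp_association

logger = logging.getLogger(__name__)

#: AHA clinical thresholds (mg/dL).
TG_THRESHOLD = 150.0
HDL_THRESHOLD_MALE = 40.0
HDL_THRESHOLD_FEMALE = 50.0


@dataclass(frozen=True)
class WeightedSnp:
    """One panel SNP with its fitted, risk-allele-oriented weight."""

    rsid: str
    weight: float
    flipped: bool = False
    effect_allele: str = "A"
    other_allele: str = "G"
    assoc_p: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight):
            raise ValueError(f"SNP {self.rsid!r}: weight must be finite")
        if self.weight < 0:
            raise ValueError(
                f"SNP {self.rsid!r}: oriented weight must be >= 0, got {self.weight}"
            )


@dataclass(frozen=True)
class WeightedPanel:
    """Ordered collection of weighted SNPs (unique rsIDs)."""

    snps: tuple[WeightedSnp, ...]
    trait_tag: str = "combined"

    def __post_init__(self) -> None:
        rsids = [s.rsid for s in self.snps]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsIDs in weighted panel")

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    def __len__(self) -> int:
        return len(self.snps)


@dataclass
class ScoreSet:
    """Per-subject scores with optional 90th-percentile stratification.

    ``risk_group`` holds ``"high"``/``"low"`` labels once
    :func:`stratify` has been applied; ``cutoff`` is the empirical
    quantile used (linear-interpolation convention, membership by >=).
    """

    scores: pd.Series
    trait_tag: str = "combined"
    cutoff: float | None = None
    risk_group: pd.Series | None = None

    @property
    def high_mask(self) -> pd.Series:
        if self.risk_group is None:
            raise ValueError("ScoreSet has not been stratified yet")
        return self.risk_group == "high"

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"wprs": self.scores})
        frame["risk_group"] = self.risk_group if self.risk_group is not None else ""
        frame["trait_tag"] = self.trait_tag
        return frame


# ---------------------------------------------------------------------------
# Clinical threshold outcomes
# ---------------------------------------------------------------------------

def define_threshold_outcome(
    cohort: pd.DataFrame, trait: str, sex_stratum: str | None = None
) -> pd.Series:
    """Dichotomize a lipid trait at its clinical threshold.

    TG: positive iff TG >= 150 mg/dL (boundary inclusive).
    HDL: positive iff HDL-C < 40 mg/dL in males, < 50 mg/dL in females
    (strict).  Pass ``sex_stratum`` ("M" or "F") to restrict the returned
    vector to one sex; HDL analyses are run sex-stratified.
    """
    trait = trait.upper()
    if trait == "TG":
        if "tg" not in cohort.columns:
            raise ValueError("cohort has no 'tg' column")
        out = (cohort["tg"] >= TG_THRESHOLD).astype(int)
    elif trait == "HDL":
        if "hdl" not in cohort.columns:
            raise ValueError("cohort has no 'hdl' column")
        if "sex" not in cohort.columns:
            raise ValueError("HDL threshold outcome requires a 'sex' column")
        cut = np.where(
            cohort["sex"].to_numpy() == "M", HDL_THRESHOLD_MALE, HDL_THRESHOLD_FEMALE
        )
        out = pd.Series(
            (cohort["hdl"].to_numpy() < cut).astype(int), index=cohort.index
        )
    else:
        raise ValueError(f"trait must be 'TG' or 'HDL', got {trait!r}")
    if sex_stratum is not None:
        if "sex" not in cohort.columns:
            raise ValueError("sex_stratum given but cohort has no 'sex' column")
        out = out[cohort["sex"] == sex_stratum]
    return out


# ---------------------------------------------------------------------------
# Weight fitting
# ---------------------------------------------------------------------------

def fit_weights(
    genotypes: pd.DataFrame,
    outcome: Sequence[int],
    retained_panel: Sequence[SnpRecord] | Sequence[str],
    trait_tag: str = "combined",
) -> WeightedPanel:
    """Fit one univariate logistic regression per retained SNP.

    The weight is the fitted per-effect-allele log-OR, oriented to the
    risk allele: a negative beta sets ``flipped`` and stores the positive
    magnitude (the scoring stage counts ``2 - dosage``).  SNPs whose fit
    separates are dropped with a logged reason.
    """
    if len(retained_panel) == 0:
        raise ValueError("retained panel is empty")
    snps: list[WeightedSnp] = []
    y = np.asarray(outcome, dtype=float)
    for item in retained_panel:
        if isinstance(item, SnpRecord):
            rsid, ea, oa = item.rsid, item.effect_allele, item.other_allele
        else:
            rsid, ea, oa = str(item), "A", "G"
        if rsid not in genotypes.columns:
            raise KeyError(f"panel SNP {rsid!r} absent from genotype matrix")
        beta, p = snp_association(genotypes[rsid].to_numpy(dtype=float), y)
        if not np.isfinite(beta):
            logger.warning("dropping SNP %s: separated/degenerate fit", rsid)
            continue
        flipped = beta < 0
        snps.append(
            WeightedSnp(
                rsid=rsid,
                weight=abs(beta),
                flipped=bool(flipped),
                effect_allele=oa if flipped else ea,
                other_allele=ea if flipped else oa,
                assoc_p=p,
            )
        )
    return WeightedPanel(snps=tuple(snps), trait_tag=trait_tag)


# ---------------------------------------------------------------------------
# Scoring and stratification
# ---------------------------------------------------------------------------

def compute_wprs(genotypes: pd.DataFrame, panel: WeightedPanel) -> ScoreSet:
    """Weighted sum of risk-allele dosages for every subject.

    Missing dosages are mean-imputed per SNP before weighting; flipped
    SNPs contribute ``2 - dosage``.
    """
    absent = [r for r in panel.rsids if r not in genotypes.columns]
    if absent:
        raise KeyError(f"panel SNPs absent from genotype matrix: {absent}")
    total = np.zeros(len(genotypes))
    for snp in panel.snps:
        d = _impute_mean(genotypes[snp.rsid].to_numpy(dtype=float))
        if snp.flipped:
            d = 2.0 - d
        total += snp.weight * d
    return ScoreSet(
        scores=pd.Series(total, index=genotypes.index, name="wprs"),
        trait_tag=panel.trait_tag,
    )


def stratify(scores: ScoreSet, percentile: float = 0.90) -> ScoreSet:
    """Label subjects high/low at the empirical score percentile.

    The cutoff is the linear-interpolation empirical quantile; membership
    in the high group is by ``score >= cutoff``.  Requires at least 10
    subjects (a decile of fewer is not meaningful).
    """
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must be in (0, 1)")
    vals = scores.scores.to_numpy(dtype=float)
    if vals.size < 10:
        raise ValueError(f"need >= 10 subjects to stratify, got {vals.size}")
    cutoff = float(np.quantile(vals, percentile))
    high = vals >= cutoff
    if high.all():
        warnings.warn(
            "all scores are >= the cutoff (degenerate ties); entire cohort "
            "labelled high",
            stacklevel=2,
        )
    group = pd.Series(
        np.where(high, "high", "low"), index=scores.scores.index, name="risk_group"
    )
    return ScoreSet(
        scores=scores.scores, trait_tag=scores.trait_tag,
        cutoff=cutoff, risk_group=group,
    )


def combined_high(a: ScoreSet, b: ScoreSet) -> pd.Series:
    """Subjects in the high group of *both* score sets (intersection).

    Score sets may cover different subject subsets (e.g. sex-stratified
    HDL scores); subjects absent from either set are False.
    """
    mask_a = a.high_mask
    mask_b = b.high_mask
    idx = mask_a.index.union(mask_b.index)
    return (
        mask_a.reindex(idx, fill_value=False)
        & mask_b.reindex(idx, fill_value=False)
    ).rename("combined_high")
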