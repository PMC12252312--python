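"""SNP panel quality control and clumping-and-thresholding selection.

Implements the per-SNP QC primitives used to build a trait panel from
cohort genotypes: the Hardy-Weinberg exact test, allele-frequency/MAF
computation, composite LD r² from unphased dosages, univariate logistic
association, and the greedy p-value-ranked clump-and-threshold pipeline
(HWE -> MAF -> association p -> LD pruning at r² >= 0.8).

Dosage convention: per-subject count of the effect allele in {0, 1, 2},
``NaN`` for missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln

logger = logging.getLogger(__name__)

#: Exclusion reasons, in the order the filters are applied.
EXCLUSION_REASONS = ("hwe", "maf", "pvalue", "ld")

#: Names of the panel files shipped with the package.  Only the rsID lists
#: and retained status are published values; allele and numeric columns in
#: those files are synthetic placeholders (weights are always re-fitted
#: in-cohort).
PACKAGED_PANELS = ("hdl_male", "hdl_female", "tg")

PANEL_COLUMNS = [
    "rsid", "effect_allele", "other_allele", "beta", "assoc_p",
    "maf", "hwe_p", "status", "reason",
]


@dataclass(frozen=True)
class QcThresholds:
    """Thresholds for panel QC.

    ld_r2_max : SNP pairs at or above this r² are clumped (default 0.8).
    maf_min   : SNPs below this minor allele frequency are excluded (0.01).
    assoc_p_max : SNPs with association p at or above this are excluded (0.05).
    hwe_p_min : SNPs with HWE exact p below this are excluded (1e-3).
    """

    ld_r2_max: float = 0.8
    maf_min: float = 0.01
    assoc_p_max: float = 0.05
    hwe_p_min: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("ld_r2_max", "maf_min", "assoc_p_max", "hwe_p_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"QcThresholds.{name} must be in (0, 1), got {v!r}")


@dataclass
class SnpRecord:
    """Per-SNP QC outcome.

    ``status`` is ``"retained"`` or ``"excluded"``; excluded records carry
    exactly one ``reason`` from :data:`EXCLUSION_REASONS`.
    """

    rsid: str
    effect_allele: str = "A"
    other_allele: str = "G"
    maf: float = float("nan")
    hwe_p: float = float("nan")
    assoc_beta: float = float("nan")
    assoc_p: float = float("nan")
    status: str = "retained"
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.status not in ("retained", "excluded"):
            raise ValueError(f"invalid status {self.status!r}")
        if self.status == "excluded" and self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"excluded SNP needs a reason from {EXCLUSION_REASONS}")
        if self.status == "retained" and self.reason is not None:
            raise ValueError("retained SNP must not carry an exclusion reason")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_het_log_probs(n_a: int, n_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of every admissible heterozygote count.

    Conditional on the observed allele counts ``n_a`` (reference) and
    ``n_b`` (alternate), the heterozygote count h under Hardy-Weinberg
    random mating follows the Levene-Haldane distribution

        P(h) = n! / (n_aa! h! n_bb!) * 2^h * n_a! n_b! / (2n)!

    with h running over the same parity as ``n_b`` up to ``min(n_a, n_b)``.
    """
    n = (n_a + n_b) // 2
    h_max = min(n_a, n_b)
    # h shares the parity of n_b (and of n_a: their sum is even)
    h = np.arange(h_max % 2, h_max + 1, 2)
    n_bb = (n_b - h) // 2
    n_aa = (n_a - h) // 2
    logp = (
        gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(h + 1) - gammaln(n_bb + 1)
        + h * np.log(2.0)
        + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1)
    )
    return h, logp


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium test p-value.

    Conditions on the observed allele counts and sums, over all admissible
    heterozygote counts, the probabilities of configurations no more
    probable than the observed one.

    Parameters are the three genotype counts.  Returns a p-value in (0, 1].
    Raises ``ValueError`` for negative or all-zero counts.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(int(c) != c or c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers, got {counts}")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0  # monomorphic: only one configuration exists
    h, logp = _hwe_het_log_probs(n_a, n_b)
    logp_obs = logp[np.searchsorted(h, n_het)]
    # normalise in probability space for numerical robustness
    p_all = np.exp(logp - logp.max())
    p_all /= p_all.sum()
    p_obs = p_all[np.searchsorted(h, n_het)]
    pval = float(p_all[p_all <= p_obs * (1.0 + 1e-12)].sum())
    return min(pval, 1.0)


# ---------------------------------------------------------------------------
# Allele frequency and LD
# ---------------------------------------------------------------------------

def allele_frequency(dosages: Sequence[float]) -> tuple[float, float]:
    """Effect-allele frequency and folded MAF from a dosage vector.

    Missing dosages (NaN) are ignored; an all-missing vector raises
    ``ValueError``.
    """
    d = np.asarray(dosages, dtype=float)
    mask = ~np.isnan(d)
    if not mask.any():
        raise ValueError("all dosages missing; allele frequency undefined")
    freq = float(d[mask].sum() / (2.0 * mask.sum()))
    return freq, min(freq, 1.0 - freq)


def ld_r2(dosages_a: Sequence[float], dosages_b: Sequence[float]) -> float:
    """Composite LD r²: squared Pearson correlation of unphased dosages.

    Computed over pairwise-complete subjects.  A zero-variance vector makes
    r² undefined; it is treated as 0.0 for clumping and logged.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dosage vectors differ in length: {a.shape} vs {b.shape}")
    mask = ~(np.isnan(a) | np.isnan(b))
    if mask.sum() < 2:
        raise ValueError("need at least 2 complete pairs for r^2")
    a, b = a[mask], b[mask]
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        logger.warning("zero-variance dosage vector; r^2 undefined, using 0.0")
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


# ---------------------------------------------------------------------------
# Univariate logistic association
# ---------------------------------------------------------------------------

def _impute_mean(d: np.ndarray) -> np.ndarray:
    d = d.astype(float).copy()
    miss = np.isnan(d)
    if miss.any():
        d[miss] = d[~miss].mean()
    return d


def snp_association(
    dosages: Sequence[float], outcome: Sequence[int]
) -> tuple[float, float]:
    """Univariate additive logistic regression of a binary outcome on dosage.

    Returns ``(beta, p)``: the per-effect-allele log-odds ratio and its Wald
    p-value.  Missing dosages are mean-imputed.  Degenerate fits return a
    flagged value instead of raising: a constant dosage gives
    ``(nan, 1.0)``; (quasi-)separation gives a non-finite beta with p = 1.
    A single-class outcome raises ``ValueError``.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if d.shape != y.shape:
        raise ValueError("dosage and outcome lengths differ")
    if d.size < 10:
        raise ValueError(f"need at least 10 subjects, got {d.size}")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        if classes.size < 2:
            raise ValueError("outcome has a single class; association undefined")
        raise ValueError(f"outcome must be binary 0/1, found values {classes}")
    d = _impute_mean(d)
    if d.var() == 0.0:
        logger.warning("constant dosage; association undefined (p = 1)")
        return float("nan"), 1.0
    X = sm.add_constant(d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:  # separation or non-convergence
            logger.warning("logistic fit failed (separation?); flagged beta")
            return float("inf"), 1.0
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 30:
        logger.warning("quasi-separation detected; flagged non-finite beta")
        return float(np.sign(beta) * np.inf) if np.isfinite(beta) else float("inf"), 1.0
    return beta, float(fit.pvalues[1])


# ---------------------------------------------------------------------------
# Clumping and thresholding
# ---------------------------------------------------------------------------

def _genotype_counts(d: np.ndarray) -> tuple[int, int, int]:
    d = d[~np.isnan(d)]
    rounded = np.rint(d).astype(int)
    return (
        int((rounded == 0).sum()),
        int((rounded == 1).sum()),
        int((rounded == 2).sum()),
    )


def clump_and_threshold(
    genotypes: pd.DataFrame,
    outcome: Sequence[int],
    thresholds: QcThresholds | None = None,
    alleles: Mapping[str, tuple[str, str]] | None = None,
) -> list[SnpRecord]:
    """Run the full SNP selection pipeline on a dosage matrix.

    Filters are applied in order — Hardy-Weinberg exact test, MAF,
    association p-value — and survivors are greedily clumped: SNPs are
    ranked by ascending association p (ties broken by rsID), the
    best-ranked SNP is retained, and every remaining SNP with
    r² >= ``ld_r2_max`` against it is excluded as ``"ld"``.

    Each SNP receives exactly one exclusion reason (its first failing
    filter).  Returns one :class:`SnpRecord` per input column, in input
    column order.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    if genotypes.shape[1] < 1:
        raise ValueError("genotype matrix has no SNPs")
    alleles = alleles or {}
    y = np.asarray(outcome, dtype=float)

    records: dict[str, SnpRecord] = {}
    survivors: list[str] = []
    for rsid in genotypes.columns:
        d = genotypes[rsid].to_numpy(dtype=float)
        ea, oa = alleles.get(rsid, ("A", "G"))
        hwe_p = hwe_exact_test(*_genotype_counts(d))
        _, maf = allele_frequency(d)
        rec = SnpRecord(rsid=rsid, effect_allele=ea, other_allele=oa,
                        maf=maf, hwe_p=hwe_p)
        if hwe_p < thresholds.hwe_p_min:
            rec.status, rec.reason = "excluded", "hwe"
        elif maf < thresholds.maf_min:
            rec.status, rec.reason = "excluded", "maf"
        else:
            beta, p = snp_association(d, y)
            rec.assoc_beta, rec.assoc_p = beta, p
            if not np.isfinite(beta) or p >= thresholds.assoc_p_max:
                rec.status, rec.reason = "excluded", "pvalue"
            else:
                survivors.append(rsid)
        records[rsid] = rec

    # greedy p-ranked clumping; deterministic tie-break on rsID
    ranked = sorted(survivors, key=lambda r: (records[r].assoc_p, r))
    while ranked:
        index_snp = ranked.pop(0)
        index_d = genotypes[index_snp].to_numpy(dtype=float)
        still = []
        for rsid in ranked:
            r2 = ld_r2(index_d, genotypes[rsid].to_numpy(dtype=float))
            if r2 >= thresholds.ld_r2_max:
                records[rsid].status, records[rsid].reason = "excluded", "ld"
            else:
                still.append(rsid)
        ranked = still

    return [records[rsid] for rsid in genotypes.columns]


# ---------------------------------------------------------------------------
# Panel TSV interchange
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[SnpRecord]) -> pd.DataFrame:
    """SnpRecords as a panel-TSV-dialect DataFrame."""
    return pd.DataFrame(
        [
            {
                "rsid": r.rsid,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "beta": r.assoc_beta,
                "assoc_p": r.assoc_p,
                "maf": r.maf,
                "hwe_p": r.hwe_p,
                "status": r.status,
                "reason": r.reason if r.reason is not None else "",
            }
            for r in records
        ],
        columns=PANEL_COLUMNS,
    )


def write_panel_tsv(records: Sequence[SnpRecord] | pd.DataFrame, path) -> None:
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    frame.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> pd.DataFrame:
    """Read a panel TSV (lines starting with ``#`` are comments)."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"rsid": str})
    missing = [c for c in ("rsid", "effect_allele", "other_allele") if c not in frame]
    if missing:
        raise ValueError(f"panel file {path} missing columns: {missing}")
    return frame


def load_packaged_panel(name: str) -> pd.DataFrame:
    """Load one of the panels shipped with the package.

    ``name`` is one of ``"hdl_male"`` (13 SNPs), ``"hdl_female"`` (10 SNPs)
    or ``"tg"`` (19 SNPs).  Only the rsID lists are literature values;
    alleles in the files are synthetic placeholders and weights must be
    fitted in-cohort.
    """
    if name not in PACKAGED_PANELS:
        raise ValueError(f"unknown panel {name!r}; choose from {PACKAGED_PANELS}")
    ref = resources.files("lipidprs").joinpath(f"data/panel_{name}.tsv")
    with resources.as_file(ref) as path:
        return read_panel_tsv(path)
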