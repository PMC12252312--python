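"""File formats, run configuration, and the end-to-end pipeline.

Canonical interchange formats:

* dosage CSV — header row ``subject_id,<rsid>,...``; one subject per row;
  an empty cell is a missing dosage;
* minimal VCF — GT-only, unphased (``0/1`` style), REF = other allele,
  ALT = effect allele, ``./.`` for missing;
* panel / weights TSV — tab-separated with a declared header;
* phenotype CSV — one subject per row with documented column names.

:func:`run_pipeline` ties the stages together: registry filtering, SNP
QC, in-cohort weight fitting, scoring, 90th-percentile stratification,
association models and the stratified gene-environment tables, writing
every intermediate artifact plus a run log (seed, versions, thresholds).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cohort_filter import EXCLUSION_ORDER, apply_exclusions, write_report
from .models import (
    DEFAULT_ADJUSTMENT,
    AssocResult,
    linear_trait_on_score,
    logistic_outcome_on_group,
    tg_hdl_ratio,
)
from .panel_qc import (
    QcThresholds,
    clump_and_threshold,
    load_packaged_panel,
    write_panel_tsv,
)
from .strata import build_strata_table, default_exposures, descriptive_table
from .synthetic import (
    DEFAULT_EXCLUSION_COUNTS,
    DEFAULT_REGISTRY_TOTAL,
    default_simspec,
    simulate_cohort,
    simulate_registry,
)
from .wprs import (
    WeightedPanel,
    WeightedSnp,
    compute_wprs,
    define_threshold_outcome,
    fit_weights,
    stratify,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Dosage CSV
# ---------------------------------------------------------------------------

def write_dosage_csv(genotypes: pd.DataFrame, path) -> None:
    """Write a subjects x SNPs dosage matrix (empty cell = missing)."""
    out = genotypes.copy()
    out.insert(0, "subject_id", [str(i) for i in genotypes.index])
    out.to_csv(path, index=False, na_rep="")


def read_dosage_csv(path) -> pd.DataFrame:
    """Read a dosage CSV back into a subjects x SNPs float matrix."""
    frame = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in frame.columns:
        raise ValueError(f"{path}: dosage CSV must have a subject_id column")
    frame = frame.set_index("subject_id")
    frame.index.name = "subject"
    try:
        frame.index = frame.index.astype(int)
    except (TypeError, ValueError):
        pass
    return frame.astype(float)


# ---------------------------------------------------------------------------
# Minimal VCF (GT only)
# ---------------------------------------------------------------------------

_GT_BY_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(
    genotypes: pd.DataFrame,
    path,
    alleles: Mapping[str, tuple[str, str]] | None = None,
) -> None:
    """Emit genotypes as a minimal unphased GT-only VCF.

    ALT is the effect allele (the dosage-counted allele), REF the other
    allele; ``alleles`` maps rsid -> (effect, other) and defaults to
    ("A", "G").
    """
    alleles = alleles or {}
    samples = [f"S{i}" if not str(i).startswith("S") else str(i) for i in genotypes.index]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lipidprs\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for pos, rsid in enumerate(genotypes.columns, start=1):
            ea, oa = alleles.get(rsid, ("A", "G"))
            dosages = genotypes[rsid].to_numpy(dtype=float)
            gts = [
                "./." if np.isnan(d) else _GT_BY_DOSAGE[int(round(d))]
                for d in dosages
            ]
            fh.write(f"1\t{pos * 100}\t{rsid}\t{oa}\t{ea}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def _prevalidate_vcf(path) -> None:
    """Cheap structural scan so malformed rows fail with a line number."""
    n_fields = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                if len(fields) < 10:
                    raise ValueError(
                        f"{path}:{lineno}: VCF header has no sample columns"
                    )
                n_fields = len(fields)
                continue
            if n_fields is None:
                raise ValueError(f"{path}:{lineno}: data before #CHROM header")
            if len(fields) != n_fields:
                raise ValueError(
                    f"{path}:{lineno}: malformed row ({len(fields)} fields, "
                    f"expected {n_fields})"
                )


def read_vcf(
    path, panel_alleles: Mapping[str, tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Read a VCF into an effect-allele dosage matrix.

    ``panel_alleles`` maps rsid -> (effect_allele, other_allele); the GT
    alt-allele count is flipped when the panel's effect allele is the
    REF.  An allele pair matching neither orientation raises a
    ``ValueError`` naming the rsID.  Without a panel the ALT allele is
    taken as the effect allele.  Missing genotypes (``./.``) become NaN.
    Subject order is taken from the file.
    """
    from cyvcf2 import VCF  # deferred: import cost and optional at runtime

    _prevalidate_vcf(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for variant in vcf:
        rsid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        alt = variant.ALT[0] if variant.ALT else ""
        ref = variant.REF
        counts = np.array(
            [sum(1 for a in gt[:2] if a == 1) if -1 not in gt[:2] else -1
             for gt in variant.genotypes],
            dtype=float,
        )
        counts[counts == -1] = np.nan
        if panel_alleles is not None and rsid in panel_alleles:
            ea, oa = panel_alleles[rsid]
            if ea == alt and oa == ref:
                dosage = counts
            elif ea == ref and oa == alt:
                dosage = 2.0 - counts
            else:
                raise ValueError(
                    f"allele mismatch for {rsid}: VCF {ref}/{alt} vs panel "
                    f"{oa}/{ea}"
                )
        else:
            dosage = counts
        columns[rsid] = dosage
    vcf.close()
    frame = pd.DataFrame(columns, index=samples)
    frame.index.name = "subject"
    return frame


def read_genotypes(
    path,
    format: str = "dosage_csv",
    panel_alleles: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Read a genotype matrix in either supported dialect.

    ``format`` is ``"dosage_csv"`` or ``"vcf"``; for VCF input
    ``panel_alleles`` orients dosages to the panel's effect alleles.
    """
    if format == "dosage_csv":
        return read_dosage_csv(path)
    if format == "vcf":
        return read_vcf(path, panel_alleles)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Phenotypes and weights
# ---------------------------------------------------------------------------

def write_phenotypes_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, na_rep="")


def read_phenotypes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str, "sex": str})


def weights_to_frame(panel: WeightedPanel) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"rsid": s.rsid, "weight": s.weight, "flipped": s.flipped,
             "effect_allele": s.effect_allele, "other_allele": s.other_allele,
             "assoc_p": s.assoc_p, "trait_tag": panel.trait_tag}
            for s in panel.snps
        ]
    )


def read_weights_tsv(path) -> WeightedPanel:
    frame = pd.read_csv(path, sep="\t")
    tags = frame["trait_tag"].unique() if "trait_tag" in frame else ["combined"]
    snps = tuple(
        WeightedSnp(
            rsid=row["rsid"], weight=float(row["weight"]),
            flipped=bool(row["flipped"]),
            effect_allele=row.get("effect_allele", "A"),
            other_allele=row.get("other_allele", "G"),
            assoc_p=float(row.get("assoc_p", float("nan"))),
        )
        for _, row in frame.iterrows()
    )
    return WeightedPanel(snps=snps, trait_tag=str(tags[0]))


def write_weights_tsv(panel: WeightedPanel, path) -> None:
    weights_to_frame(panel).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration for one pipeline run (flags mirror these keys)."""

    output_dir: str = "lipidprs_run"
    seed: int = 0
    registry_total: int = DEFAULT_REGISTRY_TOTAL
    exclusion_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_COUNTS)
    )
    percentile: float = 0.90
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_ADJUSTMENT))
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    genotype_format: str = "dosage_csv"
    write_vcf: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.percentile < 1.0):
            raise ValueError("percentile must be in (0, 1)")
        if self.genotype_format not in ("dosage_csv", "vcf"):
            raise ValueError("genotype_format must be dosage_csv|vcf")


def parse_config(path) -> RunConfig:
    """Parse a flat key=value config file with dotted keys.

    Example::

        seed = 7
        percentile = 0.90
        qc.ld_r2_max = 0.8
        registry.total = 12626
        registry.underage = 245
    """
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
    return config_from_flat(flat)


def config_from_flat(flat: Mapping[str, str]) -> RunConfig:
    cfg = RunConfig()
    qc_kwargs: dict[str, float] = {}
    for key, raw in flat.items():
        if key.startswith("qc."):
            qc_kwargs[key[3:]] = float(raw)
        elif key == "registry.total":
            cfg.registry_total = int(raw)
        elif key.startswith("registry."):
            reason = key[len("registry."):]
            if reason not in EXCLUSION_ORDER:
                raise ValueError(f"unknown exclusion reason {reason!r}")
            cfg.exclusion_counts[reason] = int(raw)
        elif key == "covariates":
            cfg.covariates = [c.strip() for c in raw.split(",") if c.strip()]
        elif key in ("seed", "registry_total"):
            setattr(cfg, key, int(raw))
        elif key == "percentile":
            cfg.percentile = float(raw)
        elif key == "write_vcf":
            cfg.write_vcf = raw.lower() in ("1", "true", "yes")
        elif key in ("output_dir", "genotypes_path", "phenotypes_path",
                     "genotype_format", "log_level"):
            setattr(cfg, key, raw)
        else:
            raise ValueError(f"unknown config key {key!r}")
    if qc_kwargs:
        cfg.thresholds = QcThresholds(**qc_kwargs)
    cfg.__post_init__()
    return cfg


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def _panel_rsids(name: str, genotypes: pd.DataFrame) -> tuple[list[str], dict]:
    panel = load_packaged_panel(name)
    rsids = [r for r in panel["rsid"] if r in genotypes.columns]
    alleles = {
        row["rsid"]: (row["effect_allele"], row["other_allele"])
        for _, row in panel.iterrows()
    }
    return rsids, alleles


def run_pipeline(config: RunConfig) -> dict:
    """Execute filter -> QC -> weights -> score -> stratify -> associations
    -> strata tables, writing every intermediate artifact.

    Returns the report bundle (in-memory objects keyed by stage).  With no
    input paths the built-in synthetic cohort is generated at the
    registry's eligible size.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    bundle: dict = {"config": config}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    # --- filter ---
    stage("filter")
    registry = simulate_registry(
        config.registry_total, config.exclusion_counts, config.seed
    )
    survivors, report = apply_exclusions(registry)
    write_report(report, out / "exclusion_report.json", out / "exclusion_report.csv")
    bundle["exclusion_report"] = report

    # --- cohort ---
    stage("cohort")
    if config.genotypes_path is not None:
        if config.genotype_format == "vcf":
            genotypes = read_vcf(config.genotypes_path)
        else:
            genotypes = read_dosage_csv(config.genotypes_path)
        if config.phenotypes_path is None:
            raise ValueError("phenotypes_path required when genotypes_path given")
        cohort = read_phenotypes_csv(config.phenotypes_path)
        cohort.index = genotypes.index
    else:
        spec = default_simspec(n_subjects=report.n_final, seed=config.seed)
        genotypes, cohort = simulate_cohort(spec)
    write_dosage_csv(genotypes, out / "genotypes.csv")
    if config.write_vcf:
        write_vcf(genotypes, out / "genotypes.vcf")
    write_phenotypes_csv(cohort, out / "cohort.csv")
    bundle["genotypes"], bundle["cohort"] = genotypes, cohort

    # --- QC + weights + scores per trait ---
    stage("qc/score")
    results: list[AssocResult] = []

    # TG: pooled cohort
    tg_rsids, tg_alleles = _panel_rsids("tg", genotypes)
    outcome_tg = define_threshold_outcome(cohort, "TG")
    records_tg = clump_and_threshold(
        genotypes[tg_rsids], outcome_tg, config.thresholds, tg_alleles
    )
    write_panel_tsv(records_tg, out / "panel_tg_qc.tsv")
    retained_tg = [r for r in records_tg if r.status == "retained"]
    panel_tg = fit_weights(genotypes, outcome_tg, retained_tg, trait_tag="TG")
    write_weights_tsv(panel_tg, out / "weights_tg.tsv")
    scores_tg = stratify(compute_wprs(genotypes, panel_tg), config.percentile)
    bundle["scores_tg"] = scores_tg

    # HDL: fitted and stratified within sex
    hdl_scoresets = {}
    for sex, panel_name in (("M", "hdl_male"), ("F", "hdl_female")):
        hdl_rsids, hdl_alleles = _panel_rsids(panel_name, genotypes)
        outcome = define_threshold_outcome(cohort, "HDL", sex_stratum=sex)
        geno_sex = genotypes.loc[outcome.index]
        records = clump_and_threshold(
            geno_sex[hdl_rsids], outcome, config.thresholds, hdl_alleles
        )
        write_panel_tsv(records, out / f"panel_{panel_name}_qc.tsv")
        retained = [r for r in records if r.status == "retained"]
        if not retained:
            logger.warning("no HDL SNPs retained for sex %s", sex)
            continue
        panel = fit_weights(geno_sex, outcome, retained, trait_tag=f"HDL_{sex}")
        write_weights_tsv(panel, out / f"weights_{panel_name}.tsv")
        hdl_scoresets[sex] = stratify(compute_wprs(geno_sex, panel), config.percentile)
    bundle["scores_hdl"] = hdl_scoresets

    scores_frames = [scores_tg.to_frame()]
    scores_frames += [s.to_frame() for s in hdl_scoresets.values()]
    pd.concat(scores_frames).to_csv(out / "scores.csv", index_label="subject")

    # --- associations ---
    stage("associations")
    covs = [c for c in config.covariates if c in cohort.columns or c == "sex"]
    covs_nosex = [c for c in covs if c != "sex"]
    results.append(linear_trait_on_score(cohort, scores_tg, "tg", covs))
    results.append(
        logistic_outcome_on_group(
            cohort, outcome_tg, scores_tg.high_mask.astype(int),
            [c for c in covs if c != "treatment"], term="high_wprs_tg",
        )
    )
    results.append(
        logistic_outcome_on_group(
            cohort, cohort["cvd"], scores_tg.high_mask.astype(int), covs,
            term="cvd~high_wprs_tg",
        )
    )
    for sex, scoreset in hdl_scoresets.items():
        sub = cohort.loc[scoreset.scores.index]
        results.append(
            linear_trait_on_score(sub, scoreset, "hdl", covs_nosex)
        )
        results.append(
            logistic_outcome_on_group(
                sub, define_threshold_outcome(cohort, "HDL", sex_stratum=sex),
                scoreset.high_mask.astype(int),
                [c for c in covs_nosex if c != "treatment"],
                term=f"high_wprs_hdl_{sex}",
            )
        )
        results.append(
            logistic_outcome_on_group(
                sub, sub["cvd"], scoreset.high_mask.astype(int), covs_nosex,
                term=f"cvd~high_wprs_hdl_{sex}",
            )
        )

    # combined high group: high on both the TG and (sex-specific) HDL scores
    if hdl_scoresets:
        hdl_high = pd.concat([s.high_mask for s in hdl_scoresets.values()])
    else:
        hdl_high = pd.Series(False, index=cohort.index)
    combined = (
        scores_tg.high_mask.reindex(cohort.index, fill_value=False)
        & hdl_high.reindex(cohort.index, fill_value=False)
    )
    bundle["combined_high"] = combined
    ratio = tg_hdl_ratio(cohort)
    bundle["tg_hdl_ratio"] = ratio
    ratio.to_csv(out / "tg_hdl_ratio.csv", index_label="subject")
    results.append(
        logistic_outcome_on_group(
            cohort, (ratio["above_2"] == 1).astype(int), combined.astype(int),
            [c for c in covs if c != "treatment"], term="ratio2~combined_high",
        )
    )
    results.append(
        logistic_outcome_on_group(
            cohort, cohort["cvd"], combined.astype(int), covs,
            term="cvd~combined_high",
        )
    )
    assoc_frame = pd.DataFrame([r.to_dict() for r in results])
    assoc_frame.to_csv(out / "associations.csv", index=False)
    bundle["associations"] = results

    # --- strata tables ---
    stage("strata")
    exposures = default_exposures()
    exposures_nosex = [e for e in exposures if e.name != "sex"]
    table_tg = build_strata_table(cohort, scores_tg, "tg", exposures)
    table_tg.cells.to_csv(out / "strata_tg_cells.csv", index=False)
    table_tg.comparisons.to_csv(out / "strata_tg_comparisons.csv", index=False)
    bundle["strata_tg"] = table_tg
    for sex, scoreset in hdl_scoresets.items():
        sub = cohort.loc[scoreset.scores.index]
        table = build_strata_table(sub, scoreset, "hdl", exposures_nosex)
        table.cells.to_csv(out / f"strata_hdl_{sex}_cells.csv", index=False)
        table.comparisons.to_csv(out / f"strata_hdl_{sex}_comparisons.csv", index=False)
        bundle[f"strata_hdl_{sex}"] = table

    desc = descriptive_table(
        cohort, scores_tg,
        continuous=["age", "bmi", "hba1c", "total_chol", "hdl", "ldl", "tg"],
        categorical=["sex", "t2dm", "cvd", "smoking", "ssb", "coffee", "wine"],
    )
    desc.to_csv(out / "descriptive_table.csv", index=False)
    bundle["descriptive"] = desc

    # --- run log ---
    run_log = {
        "package_version": _pkg_version,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "percentile": config.percentile,
        "thresholds": asdict(config.thresholds),
        "registry_total": config.registry_total,
        "exclusion_counts": config.exclusion_counts,
        "n_final": report.n_final,
    }
    with open(out / "run.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    bundle["run_log"] = run_log
    return bundle
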