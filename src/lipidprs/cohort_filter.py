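"""Exclusion cascade applied to a participant registry.

Records are excluded in a fixed order — underage, missing medical/lifestyle
data, missing laboratory values, missing genotype data — and each record is
counted under its *first* failing criterion, so the per-reason counts are
disjoint and sum, with the survivors, to the registry size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
import pandas as pd

#: Exclusion reasons in cascade order.
EXCLUSION_ORDER = (
    "underage",
    "missing_medical_lifestyle",
    "missing_labs",
    "missing_genotype",
)


@dataclass(frozen=True)
class ExclusionReport:
    """Per-reason exclusion counts for one cascade run."""

    n_input: int
    excluded: dict[str, int]
    n_final: int

    def __post_init__(self) -> None:
        if self.n_input < 0 or self.n_final < 0 or any(
            v < 0 for v in self.excluded.values()
        ):
            raise ValueError("exclusion counts must be non-negative")
        if self.n_final != self.n_input - sum(self.excluded.values()):
            raise ValueError("n_final must equal n_input minus total exclusions")

    def to_json(self) -> str:
        return json.dumps(
            {"n_input": self.n_input, "excluded": self.excluded,
             "n_final": self.n_final},
            indent=2,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(reason, n) for reason, n in self.excluded.items()]
        rows.append(("final", self.n_final))
        return pd.DataFrame(rows, columns=["reason", "n"])


def apply_exclusions(
    registry: pd.DataFrame, min_age: float = 18.0
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the exclusion cascade and report survivor counts.

    ``registry`` must carry one boolean column per reason in
    :data:`EXCLUSION_ORDER`; if the ``underage`` column is absent but an
    ``age`` column exists, the flag is derived as ``age < min_age``.
    Returns the eligible records (flag columns retained, all ``False``)
    and an :class:`ExclusionReport`.
    """
    if len(registry) == 0:
        raise ValueError("registry is empty")
    registry = registry.copy()
    if "underage" not in registry.columns and "age" in registry.columns:
        registry["underage"] = registry["age"] < min_age
    for col in EXCLUSION_ORDER:
        if col not in registry.columns:
            raise ValueError(f"registry is missing required flag column {col!r}")

    excluded: dict[str, int] = {}
    already_out = pd.Series(False, index=registry.index)
    for reason in EXCLUSION_ORDER:
        flag = registry[reason].astype(bool)
        newly = flag & ~already_out
        excluded[reason] = int(newly.sum())
        already_out |= newly

    survivors = registry.loc[~already_out].copy()
    report = ExclusionReport(
        n_input=len(registry), excluded=excluded, n_final=len(survivors)
    )
    return survivors, report


def write_report(report: ExclusionReport, json_path=None, csv_path=None) -> None:
    """Write an exclusion report as JSON and/or two-column CSV."""
    if json_path is not None:
        with open(json_path, "w") as fh:
            fh.write(report.to_json() + "\n")
    if csv_path is not None:
        report.to_frame().to_csv(csv_path, index=False)
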