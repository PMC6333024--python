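"""SNP panel quality control: call rate, minor allele frequency, invariance.

A marker is retained when its call rate and MAF both reach their thresholds
(inclusive, defaults 90% and 5%) and it shows genetic variance among the
individuals.  The invariance filter targets the allopolyploid "false SNP"
artefact: a marker called polymorphic (often heterozygous) but identical in
every individual carries no segregating variance and must be dropped.

Removals are attributed to the first failing filter in the fixed order
call rate -> MAF -> invariance, so the per-filter counts are reproducible;
the retained set itself does not depend on this order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MarkerPanel


def call_rate(marker_column: np.ndarray) -> float:
    """Fraction of non-missing calls for one marker."""
    col = np.asarray(marker_column, dtype=float)
    if col.size == 0:
        raise ValueError("marker column is empty")
    return float(np.sum(~np.isnan(col)) / col.size)


def minor_allele_frequency(marker_column: np.ndarray) -> float:
    """MAF from dosages: min(p, 1-p) with p the alternative-allele frequency.

    Computed on non-missing calls only; raises if every call is missing.
    """
    col = np.asarray(marker_column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise ValueError("MAF is undefined for an all-missing marker")
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def maf_critical_level(n_individuals: int) -> float:
    """The advisory MAF floor 1/(2N): one allele copy among N individuals."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    return 1.0 / (2.0 * n_individuals)


def is_invariant(marker_column: np.ndarray) -> bool:
    """True iff all non-missing calls are identical (no genetic variance)."""
    col = np.asarray(marker_column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        return True
    return bool(np.all(obs == obs[0]))


@dataclass
class QCReport:
    """Counting summary of one QC pass."""

    n_input: int
    n_retained: int
    n_removed_callrate: int
    n_removed_maf: int
    n_removed_invariant: int
    cr_threshold: float
    maf_threshold: float
    per_chromosome: pd.DataFrame = field(repr=False)  # chromosome, n_input, n_retained, reduction_percent

    @property
    def n_removed(self) -> int:
        return self.n_removed_callrate + self.n_removed_maf + self.n_removed_invariant

    @property
    def reduction_percent(self) -> float:
        return 100.0 * (self.n_input - self.n_retained) / self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed_callrate": self.n_removed_callrate,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_invariant": self.n_removed_invariant,
            "reduction_percent": round(self.reduction_percent, 2),
            "cr_threshold": self.cr_threshold,
            "maf_threshold": self.maf_threshold,
            "per_chromosome": self.per_chromosome.to_dict(orient="records"),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        """Human-readable table with per-chromosome retention."""
        lines = [
            f"markers in: {self.n_input}",
            f"markers retained: {self.n_retained}",
            f"removed (call rate < {self.cr_threshold:.2f}): {self.n_removed_callrate}",
            f"removed (MAF < {self.maf_threshold:.2f}): {self.n_removed_maf}",
            f"removed (invariant): {self.n_removed_invariant}",
            f"reduction: {self.reduction_percent:.2f}%",
            "",
            self.per_chromosome.to_string(index=False),
        ]
        return "\n".join(lines)


@dataclass
class PanelSummary:
    """Headline arithmetic of a panel before/after QC."""

    n_input: int
    n_retained: int
    n_groups: int

    @property
    def reduction_percent(self) -> float:
        return 100.0 * (self.n_input - self.n_retained) / self.n_input

    @property
    def mean_per_group(self) -> float:
        return self.n_retained / self.n_groups


def panel_summary(n_input: int, n_retained: int, n_groups: int = 13) -> PanelSummary:
    """Reduction percentage and mean retained markers per linkage group."""
    if n_input < 1 or n_groups < 1 or not 0 <= n_retained <= n_input:
        raise ValueError("invalid panel counts")
    return PanelSummary(n_input=n_input, n_retained=n_retained, n_groups=n_groups)


def run_qc(
    panel: MarkerPanel,
    cr_threshold: float = 0.90,
    maf_threshold: float = 0.05,
) -> tuple[MarkerPanel, QCReport]:
    """Filter a marker panel and report retention, overall and per chromosome.

    Thresholds are inclusive: a marker passes with CR >= ``cr_threshold``
    and MAF >= ``maf_threshold`` and non-constant observed genotypes.
    """
    if panel.n_markers == 0:
        raise ValueError("cannot run QC on an empty panel")
    g = panel.genotypes
    n_ind, m = g.shape

    observed = ~np.isnan(g)
    n_obs = observed.sum(axis=0)
    cr = n_obs / n_ind

    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, np.nansum(g, axis=0) / (2.0 * np.maximum(n_obs, 1)), np.nan)
    maf = np.minimum(p, 1.0 - p)

    filled = np.where(observed, g, np.nan)
    col_min = np.nanmin(np.where(n_obs > 0, filled, np.inf), axis=0)
    col_max = np.nanmax(np.where(n_obs > 0, filled, -np.inf), axis=0)
    invariant = (n_obs == 0) | (col_min == col_max)

    fail_cr = cr < cr_threshold
    fail_maf = (~fail_cr) & (np.isnan(maf) | (maf < maf_threshold))
    fail_inv = (~fail_cr) & (~fail_maf) & invariant
    keep = ~(fail_cr | fail_maf | fail_inv)

    chrom = pd.Series(panel.chromosomes)
    per_chrom = (
        pd.DataFrame({"chromosome": chrom, "kept": keep})
        .groupby("chromosome", sort=False)
        .agg(n_input=("kept", "size"), n_retained=("kept", "sum"))
        .reset_index()
    )
    per_chrom["reduction_percent"] = (
        100.0 * (per_chrom["n_input"] - per_chrom["n_retained"]) / per_chrom["n_input"]
    ).round(2)

    report = QCReport(
        n_input=m,
        n_retained=int(keep.sum()),
        n_removed_callrate=int(fail_cr.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_removed_invariant=int(fail_inv.sum()),
        cr_threshold=cr_threshold,
        maf_threshold=maf_threshold,
        per_chromosome=per_chrom,
    )
    return panel.subset_markers(np.nonzero(keep)[0]), report
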