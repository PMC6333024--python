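"""In-memory containers and on-disk formats shared across the pipeline.

The two central objects are :class:`MarkerPanel` (an individuals x markers
dosage matrix with a chromosome map) and the long-format phenotype table,
which is a plain :class:`pandas.DataFrame` validated by
:func:`validate_phenotypes`.

Genotype dosages are stored as ``float64`` with ``numpy.nan`` for missing
calls; observed values are restricted to {0, 1, 2} (counts of the
alternative allele of a biallelic, codominant SNP in a diploid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Columns of the long-format phenotype table, in canonical order.
PHENOTYPE_COLUMNS = ("individual", "family", "pop_type", "plot", "year", "trait", "value")

#: Default linkage-group labels: 11 chromosomes, the unanchored-scaffold
#: group "chr0", and markers placed only on transcriptome unigenes.
DEFAULT_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 12)) + ("chr0", "UNIGENE")


class ConfigurationError(ValueError):
    """Raised when a simulation or analysis is configured inconsistently."""


@dataclass
class MarkerPanel:
    """A genotype-dosage matrix together with its marker map.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_markers)`` float array with entries in
        {0, 1, 2} or ``nan`` for a missing call.
    individual_ids
        Unique identifier per row.
    marker_ids
        Unique identifier per column.
    chromosomes
        Linkage-group label per marker (same length as ``marker_ids``).
    metadata
        Free-form provenance (e.g. simulation truth bookkeeping).
    """

    genotypes: np.ndarray
    individual_ids: list[str]
    marker_ids: list[str]
    chromosomes: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.individual_ids = list(self.individual_ids)
        self.marker_ids = list(self.marker_ids)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        g = self.genotypes
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if g.shape[0] != len(self.individual_ids):
            raise ValueError("row count does not match number of individual ids")
        if g.shape[1] != len(self.marker_ids):
            raise ValueError("column count does not match number of marker ids")
        if len(self.chromosomes) != g.shape[1]:
            raise ValueError("every marker needs a chromosome label")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids must be unique")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids must be unique")
        observed = g[~np.isnan(g)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype dosages must be 0, 1, 2 or missing")

    def subset_markers(self, index: Sequence[int] | np.ndarray) -> "MarkerPanel":
        """Return a new panel restricted to the marker columns in ``index``."""
        index = np.asarray(index, dtype=int)
        return MarkerPanel(
            genotypes=self.genotypes[:, index].copy(),
            individual_ids=self.individual_ids,
            marker_ids=[self.marker_ids[i] for i in index],
            chromosomes=self.chromosomes[index].copy(),
            metadata=dict(self.metadata),
        )

    def chromosome_counts(self) -> pd.Series:
        """Marker count per chromosome, ordered by first appearance."""
        return pd.Series(self.chromosomes).value_counts(sort=False)

    # -- I/O ---------------------------------------------------------------
    def to_files(self, genotype_path: str | Path, map_path: str | Path) -> None:
        """Write the tab-separated dosage matrix and its marker map.

        The matrix file has one header row of marker ids, a first column of
        individual ids, and values ``0``, ``1``, ``2`` or ``NA``. The map
        file has two columns: marker id and chromosome label.
        """
        df = pd.DataFrame(self.genotypes, index=self.individual_ids, columns=self.marker_ids)
        df.index.name = "individual"
        # render dosages as integers, missing as NA
        df.to_csv(genotype_path, sep="\t", na_rep="NA", float_format="%.0f")
        pd.DataFrame({"marker": self.marker_ids, "chromosome": self.chromosomes}).to_csv(
            map_path, sep="\t", index=False
        )

    @classmethod
    def from_files(cls, genotype_path: str | Path, map_path: str | Path) -> "MarkerPanel":
        df = pd.read_csv(genotype_path, sep="\t", index_col=0, na_values=["NA"])
        marker_map = pd.read_csv(map_path, sep="\t", dtype=str)
        chrom = marker_map.set_index("marker")["chromosome"]
        try:
            chromosomes = chrom.loc[df.columns].to_numpy()
        except KeyError as exc:
            raise ValueError(f"marker map is missing entries for the genotype file: {exc}")
        return cls(
            genotypes=df.to_numpy(dtype=float),
            individual_ids=[str(i) for i in df.index],
            marker_ids=[str(c) for c in df.columns],
            chromosomes=chromosomes,
        )


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format phenotype table and return it with canonical columns.

    Required columns: individual, family, pop_type, plot, year, trait, value.
    Unbalanced data (missing records) are allowed; ``value`` may contain NaN.
    """
    missing = set(PHENOTYPE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"phenotype table is missing columns: {sorted(missing)}")
    out = table.loc[:, list(PHENOTYPE_COLUMNS)].copy()
    out["year"] = out["year"].astype(int)
    out["value"] = out["value"].astype(float)
    for col in ("individual", "family", "pop_type", "plot", "trait"):
        out[col] = out[col].astype(str)
    return out


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path))


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(table).to_csv(path, index=False)
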