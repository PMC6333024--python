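"""Derived breeding-design statistics of a genomic-selection study.

Four closed-form quantities link the cross-validation output to
breeding-program design:

* selective accuracy of GS:      r_gg = r_gy / sqrt(h2)
* effective number of QTL:       nQTL = (1 - r_gg^2) N h2 / r_gg^2
* individuals needed for a
  target accuracy r_ggd:         Ni = r_ggd^2 nQTL / ((1 - r_ggd^2) h2)
* selective efficiency per
  unit time vs phenotyping:      Ef = (r_gg L_f) / (r_yy L_GS)

with N the population size, h2 the individual (genomic) heritability,
r_yy the accuracy of phenotypic selection and L_f / L_GS the cycle
lengths of phenotypic and genomic selection in years.  nQTL and Ni are
algebraic inverses of each other: Ni evaluated at the model's own
accuracy returns N exactly.

``density_experiment`` measures the marker-density response: panels of
increasing size are drawn by chromosome-stratified proportional
subsampling and the cross-validated accuracy is recorded per size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ConfigurationError, MarkerPanel
from .crossval import CVScheme, cv_run, make_folds

#: Target accuracies reported in the population-size table.
DEFAULT_TARGET_ACCURACIES = (0.5, 0.6, 0.7, 0.8, 0.9)


def accuracy_gs(r_gy: float, h2: float) -> float | None:
    """Selective accuracy r_gg = r_gy / sqrt(h2).

    Undefined (``None``) when the predictive capacity is not positive —
    the convention used for traits whose GS model failed to predict.
    """
    if h2 <= 0 or h2 > 1:
        raise ValueError("h2 must be in (0, 1]")
    if r_gy <= 0:
        return None
    return float(r_gy / np.sqrt(h2))


def n_qtl(r_gg: float, n: int, h2: float) -> float:
    """Effective number of QTL: (1 - r_gg^2) N h2 / r_gg^2."""
    if not 0 < r_gg <= 1:
        raise ValueError("r_gg must be in (0, 1]")
    if n <= 0 or h2 <= 0:
        raise ValueError("population size and heritability must be positive")
    return float((1.0 - r_gg**2) * n * h2 / r_gg**2)


def n_individuals(r_ggd: float, n_qtl_value: float, h2: float) -> float:
    """Individuals needed for target accuracy: r_ggd^2 nQTL / ((1 - r_ggd^2) h2)."""
    if not 0 <= r_ggd < 1:
        raise ValueError("target accuracy must be in [0, 1); the formula diverges at 1")
    if n_qtl_value < 0 or h2 <= 0:
        raise ValueError("nQTL must be nonnegative and h2 positive")
    return float(r_ggd**2 * n_qtl_value / ((1.0 - r_ggd**2) * h2))


def efficiency(r_gg: float, r_yy: float, l_f: float, l_gs: float) -> float:
    """Selective efficiency per unit time: (r_gg L_f) / (r_yy L_GS).

    Values above 1 mean genomic selection beats phenotypic selection per
    year of breeding-cycle time.
    """
    if r_yy <= 0:
        raise ValueError("phenotypic accuracy r_yy must be positive")
    if l_gs <= 0 or l_f <= 0:
        raise ValueError("cycle lengths must be positive")
    return float(r_gg * l_f / (r_yy * l_gs))


# ---------------------------------------------------------------------------
# per-trait record and table rendering
# ---------------------------------------------------------------------------

@dataclass
class DerivedStats:
    """All derived statistics of one trait (one table row)."""

    trait: str
    h2_phen: float
    r_yy: float
    h2_genomic: float
    r_gy: float
    sd_r: float
    b: float
    sd_b: float
    n_population: int
    l_f: float = 24.0
    l_gs_short: float = 12.0
    l_gs_long: float = 24.0
    target_accuracies: tuple[float, ...] = DEFAULT_TARGET_ACCURACIES
    r_gg: float | None = field(init=False)
    n_qtl: float | None = field(init=False)
    ni: dict[float, float] = field(init=False)
    ef_short: float | None = field(init=False)
    ef_long: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.r_gg = accuracy_gs(self.r_gy, self.h2_genomic)
        if self.r_gg is None or self.r_gg > 1:
            # accuracy undefined or out of range: downstream stats undefined
            self.r_gg = None if self.r_gg is None else float(self.r_gg)
        if self.r_gg is None:
            self.n_qtl = None
            self.ni = {t: None for t in self.target_accuracies}
            self.ef_short = None
            self.ef_long = None
            return
        r = min(self.r_gg, 1.0)
        self.n_qtl = n_qtl(r, self.n_population, self.h2_genomic)
        self.ni = {
            t: n_individuals(t, self.n_qtl, self.h2_genomic)
            for t in self.target_accuracies
        }
        self.ef_short = efficiency(self.r_gg, self.r_yy, self.l_f, self.l_gs_short)
        self.ef_long = efficiency(self.r_gg, self.r_yy, self.l_f, self.l_gs_long)


def _fmt(value, kind: str) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "-"
    if kind == "ratio":
        return f"{value:.2f}"
    return f"{round(value):,.0f}"


def build_tables(stats: list[DerivedStats]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render the genetic-parameter table and the efficiency table.

    The first table has one row per trait with phenotypic parameters, GS
    results, nQTL and the Ni columns; the second carries the efficiency
    ratios for the short and long GS horizons.  Undefined cells (traits
    with non-positive predictive capacity) are rendered as "-".
    """
    rows3, rows4 = [], []
    for s in stats:
        row = {
            "trait": s.trait,
            "h2_phen": _fmt(s.h2_phen, "ratio"),
            "r_yy": _fmt(s.r_yy, "ratio"),
            "h2_genomic": _fmt(s.h2_genomic, "ratio"),
            "r_gy": f"{s.r_gy:.2f}",
            "sd_r": _fmt(s.sd_r, "ratio"),
            "b": _fmt(s.b, "ratio"),
            "sd_b": _fmt(s.sd_b, "ratio"),
            "r_gg": _fmt(s.r_gg, "ratio"),
            "n_qtl": _fmt(s.n_qtl, "count"),
        }
        for t in s.target_accuracies:
            row[f"ni_{t:g}"] = _fmt(s.ni[t], "count")
        rows3.append(row)
        rows4.append(
            {
                "trait": s.trait,
                f"ef_{s.l_gs_short:g}y": _fmt(s.ef_short, "ratio"),
                f"ef_{s.l_gs_long:g}y": _fmt(s.ef_long, "ratio"),
            }
        )
    return pd.DataFrame(rows3), pd.DataFrame(rows4)


def parse_stats_table(table: pd.DataFrame) -> pd.DataFrame:
    """Parse a rendered genetic-parameter table back to numeric values."""
    out = table.copy()
    for col in out.columns:
        if col == "trait":
            continue
        out[col] = (
            out[col]
            .astype(str)
            .str.replace(",", "", regex=False)
            .replace("-", np.nan)
            .astype(float)
        )
    return out


# ---------------------------------------------------------------------------
# marker-density experiment
# ---------------------------------------------------------------------------

def stratified_marker_subsample(
    panel: MarkerPanel, size: int, seed: int = 0
) -> np.ndarray:
    """Indices of a chromosome-stratified proportional marker subsample.

    Per-chromosome counts follow largest-remainder proportional allocation
    (within one marker of exact proportionality); markers are drawn without
    replacement within each chromosome.
    """
    if size > panel.n_markers:
        raise ConfigurationError("requested subsample exceeds the panel width")
    rng = np.random.default_rng(seed)
    chrom = np.asarray(panel.chromosomes)
    labels = list(dict.fromkeys(chrom))
    counts = np.array([(chrom == c).sum() for c in labels], dtype=float)
    raw = counts / counts.sum() * size
    take = np.floor(raw).astype(int)
    short = size - take.sum()
    if short > 0:
        order = np.argsort(-(raw - take))
        take[order[:short]] += 1
    picked = []
    for c, k in zip(labels, take):
        idx = np.nonzero(chrom == c)[0]
        if k > idx.size:
            k = idx.size
        picked.append(rng.choice(idx, size=k, replace=False))
    return np.sort(np.concatenate(picked))


def density_experiment(
    panel: MarkerPanel,
    phenotypes: pd.Series,
    panel_sizes: list[int],
    h2: float,
    scheme: CVScheme | None = None,
    seed: int = 0,
    families: pd.Series | None = None,
) -> pd.DataFrame:
    """Cross-validated accuracy as a function of marker-panel size.

    For each requested size a stratified subsample of markers is drawn,
    the 13-fold cross-validation is rerun (same folds for all sizes), and
    predictive capacity and selective accuracy r_gg = r_gy/sqrt(h2) are
    recorded.  Phenotypic variance is split by ``h2`` to set the
    shrinkage.
    """
    from .gblup import impute_missing

    scheme = scheme or CVScheme()
    for size in panel_sizes:
        if size > panel.n_markers:
            raise ConfigurationError(f"panel size {size} exceeds {panel.n_markers} markers")
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")

    y = phenotypes
    vy = float(y.var(ddof=1))
    sigma_g2, sigma_e2 = h2 * vy, (1.0 - h2) * vy
    folds = make_folds(list(y.index), scheme, seed=seed, families=families)

    rows = []
    for j, size in enumerate(panel_sizes):
        idx = stratified_marker_subsample(panel, size, seed=seed + 1000 + j)
        W = impute_missing(panel.genotypes[:, idx])
        res = cv_run(W, y, folds, sigma_g2=sigma_g2, sigma_e2=sigma_e2)
        r_gg = accuracy_gs(res.r_gy, h2) if res.r_gy > 0 else None
        rows.append(
            {
                "n_markers": size,
                "r_gy": res.r_gy,
                "sd_r": res.sd_r,
                "b": res.b,
                "r_gg": np.nan if r_gg is None else r_gg,
            }
        )
    return pd.DataFrame(rows)
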