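"""k-fold cross-validation of genomic predictions.

The population is split into folds (default 13, so that 195 individuals
give 180 training / 15 validation per fold, or one fold per family with
the ``by_family`` strategy).  For each fold a G-BLUP model is fitted on
the training individuals and GEBVs are predicted for the validation
individuals.  Reported statistics:

* predictive capacity ``r_gy``: the mean across folds of the Pearson
  correlation between validation GEBVs and the corrected phenotypes
  (a pooled all-validation-predictions correlation is also reported);
* prediction bias ``b``: the mean across folds of the slope of the
  regression of the corrected phenotype on the GEBV (b near 1 means the
  spread of the predictions matches the phenotypic signal; b > 1 means
  the GEBVs are under-dispersed);
* the standard deviations of both across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ConfigurationError
from .gblup import GenomicModel, solve_direct

logger = logging.getLogger(__name__)


@dataclass
class CVScheme:
    n_folds: int = 13
    strategy: str = "random"  # "random" | "by_family"

    def validate(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("need at least 2 folds")
        if self.strategy not in ("random", "by_family"):
            raise ConfigurationError("strategy must be 'random' or 'by_family'")


@dataclass
class CVResult:
    r_gy: float
    sd_r: float
    b: float
    sd_b: float
    r_gy_pooled: float
    per_fold: pd.DataFrame
    n_folds: int
    excluded_folds: list[int] = field(default_factory=list)
    predictions: pd.DataFrame | None = None


def make_folds(
    individuals: list[str],
    scheme: CVScheme | None = None,
    seed: int = 0,
    families: pd.Series | None = None,
) -> pd.Series:
    """Assign each individual to a fold.

    ``random`` deals a seeded permutation round-robin, so fold sizes differ
    by at most one; ``by_family`` puts each family wholly into one fold and
    requires exactly one family per fold.
    """
    scheme = scheme or CVScheme()
    scheme.validate()
    n = len(individuals)
    if scheme.n_folds > n:
        raise ConfigurationError("more folds than individuals")
    if scheme.strategy == "by_family":
        if families is None:
            raise ConfigurationError("by_family folding needs family labels")
        families = families.reindex(individuals) if isinstance(families, pd.Series) else pd.Series(
            list(families), index=individuals
        )
        fams = sorted(families.unique())
        if len(fams) != scheme.n_folds:
            raise ConfigurationError(
                f"{len(fams)} families cannot fill {scheme.n_folds} folds one-to-one"
            )
        fold_of_family = {fam: k for k, fam in enumerate(fams)}
        return pd.Series([fold_of_family[f] for f in families], index=individuals, name="fold")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % scheme.n_folds
    return pd.Series(folds, index=individuals, name="fold")


def fold_statistics(gebv: np.ndarray, phenotype: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and phenotype-on-GEBV regression slope for one fold.

    Returns (nan, nan) when either vector has zero variance.
    """
    gebv = np.asarray(gebv, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    if gebv.size < 2 or np.std(gebv) == 0 or np.std(phenotype) == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(gebv, phenotype)[0, 1])
    slope = float(np.cov(phenotype, gebv, ddof=1)[0, 1] / np.var(gebv, ddof=1))
    return r, slope


def cv_run(
    W: np.ndarray,
    phenotypes: pd.Series,
    folds: pd.Series,
    sigma_g2: float,
    sigma_e2: float,
    nQ: int | None = None,
    keep_predictions: bool = False,
) -> CVResult:
    """Cross-validate G-BLUP predictions of ``phenotypes`` from dosages ``W``.

    ``phenotypes`` and ``folds`` are indexed by individual, aligned with
    the rows of ``W``.  The shrinkage of every training fit uses the given
    variance components (``nQ`` defaults to the panel width).  Folds whose
    GEBVs have zero variance are excluded from the averages with a warning.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if len(phenotypes) != n or len(folds) != n:
        raise ConfigurationError("phenotypes and folds must match the rows of W")
    y = phenotypes.to_numpy(dtype=float)
    fold_ids = folds.to_numpy()

    rows = []
    excluded = []
    pred_frames = []
    for k in sorted(pd.unique(fold_ids)):
        val = fold_ids == k
        train = ~val
        model = GenomicModel(
            y=y[train], W=W[train], sigma_g2=sigma_g2, sigma_e2=sigma_e2, nQ=nQ
        )
        fit = solve_direct(model)
        gebv_val = W[val] @ fit.m_hat
        r, slope = fold_statistics(gebv_val, y[val])
        if np.isnan(r):
            logger.warning("fold %s: zero-variance GEBV; excluded from averages", k)
            excluded.append(int(k))
        rows.append({"fold": int(k), "n_val": int(val.sum()), "r": r, "b": slope})
        pred_frames.append(
            pd.DataFrame(
                {
                    "individual": phenotypes.index[val],
                    "fold": int(k),
                    "gebv": gebv_val,
                    "phenotype": y[val],
                }
            )
        )

    per_fold = pd.DataFrame(rows)
    ok = per_fold.dropna(subset=["r"])
    predictions = pd.concat(pred_frames, ignore_index=True)
    pooled = fold_statistics(predictions["gebv"].to_numpy(), predictions["phenotype"].to_numpy())[0]
    return CVResult(
        r_gy=float(ok["r"].mean()) if len(ok) else np.nan,
        sd_r=float(ok["r"].std(ddof=1)) if len(ok) > 1 else np.nan,
        b=float(ok["b"].mean()) if len(ok) else np.nan,
        sd_b=float(ok["b"].std(ddof=1)) if len(ok) > 1 else np.nan,
        r_gy_pooled=pooled,
        per_fold=per_fold,
        n_folds=int(per_fold.shape[0]),
        excluded_folds=excluded,
        predictions=predictions if keep_predictions else None,
    )
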