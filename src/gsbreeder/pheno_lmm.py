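"""REML/BLUP analysis of multi-year phenotypes.

The observation model is the six-random-effect linear mixed model

    y = Xu + Zg + Wp + Vr + Tb + Ri + e

with fixed year means ``u`` and independent random effects: genotype ``g``,
permanent plant environment ``p``, population type ``r``, plot/block ``b``,
genotype-by-year (at the family level) interaction ``i`` and residual ``e``.

Variance components are estimated by EM-REML on Henderson's mixed-model
equations (MME): dense, monotone in the restricted likelihood, and with
all components kept nonnegative by construction.  The population scale
targeted here (a few hundred records) makes the dense formulation exact
and fast.

Identifiability with one plant per genotype
-------------------------------------------
When every genotype is a single plant measured repeatedly, the permanent-
plant effect ``p`` shares its incidence with ``g`` (only their sum is
identifiable), and an individual-by-year interaction has one record per
cell (confounded with ``e``).  ``build_design`` detects such aliasing and
constrains the aliased component to zero, attributing the identifiable sum
to the first factor; the variance report flags which components were
aliased.  With ``genetic_level="family"`` the design instead places ``g``
at the family level, ``p`` at the plant level and ``i`` at family-by-year
— the fully identifiable progeny-level variant of the same model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import validate_phenotypes

logger = logging.getLogger(__name__)

FACTOR_NAMES = ("g", "p", "r", "b", "i")
COMPONENT_NAMES = FACTOR_NAMES + ("e",)


@dataclass
class RandomFactor:
    """One random effect: a level per record plus bookkeeping."""

    name: str
    levels: list
    codes: np.ndarray  # int level index per record
    aliased_with: str | None = None  # "residual" or another factor name

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def incidence(self) -> np.ndarray:
        Z = np.zeros((self.codes.size, self.n_levels))
        Z[np.arange(self.codes.size), self.codes] = 1.0
        return Z

    def partition_signature(self) -> tuple:
        """Canonical relabelling of the grouping, for alias detection."""
        seen: dict[int, int] = {}
        out = []
        for c in self.codes:
            out.append(seen.setdefault(int(c), len(seen)))
        return tuple(out)


@dataclass
class LMMDesign:
    """Response, fixed design and random incidence structure of one trait."""

    y: np.ndarray
    X: np.ndarray
    fixed_levels: list
    factors: list[RandomFactor]
    records: pd.DataFrame  # individual, family, pop_type, plot, year per row
    n_dropped: int = 0

    def factor(self, name: str) -> RandomFactor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def active_factors(self) -> list[RandomFactor]:
        return [f for f in self.factors if f.aliased_with is None]


@dataclass
class VarianceComponents:
    """EM-REML estimates of the six variance components."""

    sigma2: dict[str, float]
    converged: bool
    n_iterations: int
    loglik: float
    loglik_trace: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))
    aliased: dict[str, str] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.sigma2.values()))


@dataclass
class PhenoFit:
    """Everything downstream stages need from one trait's phenotypic analysis."""

    components: VarianceComponents
    fixed_estimates: pd.Series
    blups: dict[str, pd.Series]
    pev: dict[str, pd.Series]
    h2_phen: float
    r_yy: float
    corrected_phenotypes: pd.Series


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _codes(values: pd.Series, sort: bool = True) -> tuple[list, np.ndarray]:
    levels = sorted(values.unique()) if sort else list(pd.unique(values))
    lookup = {lev: k for k, lev in enumerate(levels)}
    return levels, values.map(lookup).to_numpy(dtype=int)


def _mark_aliases(factors: list[RandomFactor], n_records: int) -> None:
    seen: dict[tuple, str] = {}
    for f in factors:
        sig = f.partition_signature()
        if f.n_levels == n_records:
            f.aliased_with = "residual"
        elif f.n_levels == 1:
            f.aliased_with = "intercept"
        elif sig in seen:
            f.aliased_with = seen[sig]
        else:
            seen[sig] = f.name


def build_design(
    table: pd.DataFrame,
    trait: str,
    genetic_level: str = "individual",
) -> LMMDesign:
    """Assemble the mixed-model design for one trait.

    Factor levels are enumerated in sorted order; records with a missing
    value are dropped (and counted).  ``genetic_level`` chooses whether the
    genetic effect ``g`` indexes individuals (default) or families.
    """
    if genetic_level not in ("individual", "family"):
        raise ValueError("genetic_level must be 'individual' or 'family'")
    table = validate_phenotypes(table)
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present in the phenotype table")
    n_all = len(sub)
    sub = sub.dropna(subset=["value"]).reset_index(drop=True)
    n_dropped = n_all - len(sub)
    if n_dropped:
        logger.info("trait %s: dropped %d records with missing values", trait, n_dropped)

    if sub["individual"].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    if sub["year"].nunique() < 2:
        raise ValueError("need at least 2 years (year means are inestimable otherwise)")

    year_levels, year_codes = _codes(sub["year"])
    X = np.zeros((len(sub), len(year_levels)))
    X[np.arange(len(sub)), year_codes] = 1.0

    ind_levels, ind_codes = _codes(sub["individual"])
    fam_levels, fam_codes = _codes(sub["family"])
    pop_levels, pop_codes = _codes(sub["pop_type"])
    plot_levels, plot_codes = _codes(sub["plot"])

    if genetic_level == "individual":
        g = RandomFactor("g", ind_levels, ind_codes)
        p = RandomFactor("p", ind_levels, ind_codes.copy())
        inter_key = sub["individual"].astype(str) + ":" + sub["year"].astype(str)
    else:
        g = RandomFactor("g", fam_levels, fam_codes)
        p = RandomFactor("p", ind_levels, ind_codes)
        inter_key = sub["family"].astype(str) + ":" + sub["year"].astype(str)
    i_levels, i_codes = _codes(inter_key)
    factors = [
        g,
        p,
        RandomFactor("r", pop_levels, pop_codes),
        RandomFactor("b", plot_levels, plot_codes),
        RandomFactor("i", i_levels, i_codes),
    ]
    _mark_aliases(factors, len(sub))

    return LMMDesign(
        y=sub["value"].to_numpy(dtype=float),
        X=X,
        fixed_levels=year_levels,
        factors=factors,
        records=sub[["individual", "family", "pop_type", "plot", "year"]].copy(),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# EM-REML
# ---------------------------------------------------------------------------

def _assemble_mme(
    X: np.ndarray,
    Zs: list[np.ndarray],
    lambdas: np.ndarray,
    y: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[slice]]:
    blocks = [X] + Zs
    A = np.hstack(blocks)
    C = A.T @ A
    rhs = A.T @ y
    p = X.shape[1]
    slices = []
    start = p
    for Z, lam in zip(Zs, lambdas):
        q = Z.shape[1]
        sl = slice(start, start + q)
        C[sl, sl] += np.eye(q) * lam
        slices.append(sl)
        start += q
    return C, rhs, slices


def _restricted_loglik(
    C: np.ndarray,
    sol: np.ndarray,
    rhs: np.ndarray,
    y: np.ndarray,
    sigma_e: float,
    sigmas: np.ndarray,
    q_sizes: np.ndarray,
    n: int,
    p: int,
) -> float:
    """REML log-likelihood via the MME determinant identity (up to a constant)."""
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    q = int(q_sizes.sum())
    quad = (y @ y - sol @ rhs) / sigma_e
    m2l = (n - p - q) * np.log(sigma_e) + float(q_sizes @ np.log(sigmas)) + logdet + quad
    return -0.5 * m2l


def reml_fit(
    design: LMMDesign,
    max_iter: int = 2000,
    tol: float = 1e-6,
    init: dict[str, float] | None = None,
    boundary_check_every: int = 25,
) -> VarianceComponents:
    """EM-REML for the variance components of a design.

    Iterates Henderson's MME-based EM updates until the largest relative
    change of any component falls below ``tol``.  Components are positive
    throughout (EM never crosses zero); aliased factors are held at zero.
    The restricted log-likelihood is recorded each iteration and is
    non-decreasing up to numerical round-off.

    EM approaches a zero boundary only harmonically, so every
    ``boundary_check_every`` iterations each small component is tested
    against the boundary: if removing it does not lower the restricted
    likelihood, it is projected to exactly zero and dropped from the
    model.  This keeps the likelihood non-decreasing while avoiding the
    long tail of iterations that a vanishing component would otherwise
    cost.
    """
    y, X = design.y, design.X
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")
    active = list(design.active_factors)
    all_Zs = {f.name: f.incidence() for f in active}

    vy = float(np.var(y, ddof=1)) if n > 1 else 1.0
    if vy <= 0:
        vy = 1.0
    k = len(active)
    sigmas = np.full(k, vy / (k + 1.0))
    sigma_e = vy / (k + 1.0)
    if init:
        for j, f in enumerate(active):
            if f.name in init:
                sigmas[j] = max(float(init[f.name]), 1e-10 * vy)
        sigma_e = max(float(init.get("e", sigma_e)), 1e-10 * vy)

    def em_pass(names, sig, sig_e):
        """One EM update; returns (loglik, new_sigmas, new_sigma_e)."""
        Zs = [all_Zs[nm] for nm in names]
        q_sizes = np.array([Z.shape[1] for Z in Zs]) if Zs else np.empty(0, dtype=int)
        lambdas = sig_e / np.maximum(sig, 1e-300)
        C, rhs, slices = _assemble_mme(X, Zs, lambdas, y)
        Cinv = np.linalg.inv(C)
        sol = Cinv @ rhs
        ll = _restricted_loglik(C, sol, rhs, y, sig_e, sig, q_sizes, n, p)
        new_sig = np.empty_like(sig)
        for j, sl in enumerate(slices):
            u = sol[sl]
            new_sig[j] = (u @ u + sig_e * np.trace(Cinv[sl, sl])) / q_sizes[j]
        new_sig_e = (y @ y - sol @ rhs) / (n - p)
        return ll, new_sig, max(new_sig_e, 1e-12 * vy)

    names = [f.name for f in active]
    zeroed: dict[str, float] = {}
    trace = []
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        ll, new_sigmas, new_sigma_e = em_pass(names, sigmas, sigma_e)
        trace.append(ll)
        rel = 0.0
        if names:
            rel = float(
                np.max(np.abs(new_sigmas - sigmas) / (sigmas + 1e-12 * vy))
            )
        rel = max(rel, abs(new_sigma_e - sigma_e) / (sigma_e + 1e-12 * vy))
        sigmas, sigma_e = new_sigmas, new_sigma_e
        if rel < tol:
            converged = True
            break
        if it % boundary_check_every == 0 and names:
            small = [j for j, s in enumerate(sigmas) if s < 1e-2 * vy]
            for j in sorted(small, reverse=True):
                cand_names = names[:j] + names[j + 1:]
                cand_sig = np.delete(sigmas, j)
                cand_ll, _, _ = em_pass(cand_names, cand_sig, sigma_e)
                if cand_ll >= trace[-1] - 1e-10 * abs(trace[-1]):
                    zeroed[names[j]] = 0.0
                    names, sigmas = cand_names, cand_sig

    if not converged:
        logger.warning("EM-REML did not converge in %d iterations", max_iter)

    sigma2 = {name: 0.0 for name in COMPONENT_NAMES}
    for nm, s in zip(names, sigmas):
        sigma2[nm] = float(s)
    sigma2["e"] = float(sigma_e)
    aliased = {f.name: f.aliased_with for f in design.factors if f.aliased_with}
    return VarianceComponents(
        sigma2=sigma2,
        converged=converged,
        n_iterations=it,
        loglik=trace[-1] if trace else np.nan,
        loglik_trace=np.asarray(trace),
        aliased=aliased,
    )


def restricted_loglik_direct(design: LMMDesign, components: VarianceComponents) -> float:
    """Dense-V REML log-likelihood (independent of the MME identity).

    O(n^3) in the number of records; used as a numerical cross-check.
    """
    y, X = design.y, design.X
    n, p = X.shape
    V = np.eye(n) * components.sigma2["e"]
    for f in design.active_factors:
        Z = f.incidence()
        V += components.sigma2[f.name] * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    resid = y - X @ beta
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtVX)
    return -0.5 * (ld_v + ld_x + resid @ Vinv @ resid)


# ---------------------------------------------------------------------------
# BLUP and derived quantities
# ---------------------------------------------------------------------------

@dataclass
class BLUPSolution:
    fixed_estimates: pd.Series
    blups: dict[str, pd.Series]
    pev: dict[str, pd.Series]


def blup_solve(design: LMMDesign, components: VarianceComponents) -> BLUPSolution:
    """Solve Henderson's MME jointly for fixed effects and all BLUPs.

    Factors whose variance is (numerically) zero, including aliased ones,
    get zero BLUPs.  Prediction-error variances come from the diagonal of
    the inverted coefficient matrix.
    """
    y, X = design.y, design.X
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        bad = ", ".join(str(l) for l in design.fixed_levels)
        raise ValueError(f"fixed-effect design is singular; check levels: {bad}")
    vy = float(np.var(y, ddof=1)) if n > 1 else 1.0
    fitted = [
        f
        for f in design.active_factors
        if components.sigma2[f.name] > 1e-10 * max(vy, components.total)
    ]
    sigma_e = components.sigma2["e"]
    Zs = [f.incidence() for f in fitted]
    lambdas = np.array([sigma_e / components.sigma2[f.name] for f in fitted])
    C, rhs, slices = _assemble_mme(X, Zs, lambdas, y)
    Cinv = np.linalg.inv(C)
    sol = Cinv @ rhs

    fixed = pd.Series(sol[:p], index=design.fixed_levels, name="year_mean")
    blups: dict[str, pd.Series] = {}
    pev: dict[str, pd.Series] = {}
    for f in design.factors:
        blups[f.name] = pd.Series(0.0, index=f.levels)
        pev[f.name] = pd.Series(float(components.sigma2[f.name]), index=f.levels)
    for f, sl in zip(fitted, slices):
        blups[f.name] = pd.Series(sol[sl], index=f.levels)
        pev[f.name] = pd.Series(np.diag(Cinv)[sl] * sigma_e, index=f.levels)
    return BLUPSolution(fixed_estimates=fixed, blups=blups, pev=pev)


def phenotypic_accuracy(
    design: LMMDesign,
    components: VarianceComponents,
    blup: BLUPSolution | None = None,
    method: str = "pev",
) -> tuple[float, float]:
    """Phenotypic heritability and selective accuracy of the genetic BLUPs.

    ``h2_phen`` is the heritability of adjusted across-year genotype means:
    interaction and residual variances are attenuated by the (harmonic
    mean) number of records per genotype, while the separately modeled —
    and therefore corrected-for — population-type and plot variances do
    not dilute it.  ``r_yy`` is the mean per-genotype accuracy
    sqrt(1 - PEV/sigma_g^2) from the MME inverse (default), or
    sqrt(h2_phen) with ``method="sqrt_h2"``; for well-replicated traits
    the two track each other closely.
    """
    s = components.sigma2
    sig_g = s["g"]
    gf = design.factor("g")
    counts = np.bincount(gf.codes, minlength=gf.n_levels).astype(float)
    counts = counts[counts > 0]
    m_h = counts.size / np.sum(1.0 / counts)

    denom = sig_g + s["p"] + (s["i"] + s["e"]) / m_h
    h2_phen = float(sig_g / denom) if denom > 0 else 0.0

    if sig_g <= 0:
        return h2_phen, 0.0
    if method == "sqrt_h2":
        return h2_phen, float(np.sqrt(h2_phen))
    if method != "pev":
        raise ValueError("method must be 'pev' or 'sqrt_h2'")
    blup = blup or blup_solve(design, components)
    rel = 1.0 - blup.pev["g"].to_numpy() / sig_g
    r_yy = float(np.mean(np.sqrt(np.clip(rel, 0.0, 1.0))))
    return h2_phen, r_yy


def correct_phenotypes(design: LMMDesign, blup: BLUPSolution) -> pd.Series:
    """Year/plot/interaction-corrected phenotype, one value per individual.

    Each record has the estimated year mean, the plot BLUP and the
    genotype-by-year interaction BLUP subtracted; the corrected records of
    an individual are then averaged across years.
    """
    rec = design.records
    year_adj = rec["year"].map(blup.fixed_estimates).to_numpy()
    plot_adj = rec["plot"].map(blup.blups["b"]).to_numpy()
    i_factor = design.factor("i")
    inter_adj = blup.blups["i"].to_numpy()[i_factor.codes]
    corrected = design.y - year_adj - plot_adj - inter_adj
    out = (
        pd.DataFrame({"individual": rec["individual"], "corrected": corrected})
        .groupby("individual", sort=True)["corrected"]
        .mean()
    )
    out.name = "corrected_phenotype"
    return out


def individual_h2(components: VarianceComponents) -> float:
    """Individual (record-level) heritability sigma_g^2 / total variance."""
    total = components.total
    if total <= 0:
        raise ValueError("total variance is zero; heritability undefined")
    return components.sigma2["g"] / total


def fit_trait(
    table: pd.DataFrame,
    trait: str,
    genetic_level: str = "individual",
    max_iter: int = 2000,
    tol: float = 1e-6,
    accuracy_method: str = "pev",
) -> PhenoFit:
    """Full phenotypic analysis of one trait: REML, BLUP, accuracy, correction."""
    design = build_design(table, trait, genetic_level=genetic_level)
    components = reml_fit(design, max_iter=max_iter, tol=tol)
    blup = blup_solve(design, components)
    h2_phen, r_yy = phenotypic_accuracy(design, components, blup, method=accuracy_method)
    corrected = correct_phenotypes(design, blup)
    return PhenoFit(
        components=components,
        fixed_estimates=blup.fixed_estimates,
        blups=blup.blups,
        pev=blup.pev,
        h2_phen=h2_phen,
        r_yy=r_yy,
        corrected_phenotypes=corrected,
    )
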