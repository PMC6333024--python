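"""Synthetic breeding populations for genomic-selection analysis.

The generator emulates a small perennial (arabica-coffee-style) breeding
population: two contrasting founder groups (a commercial "Catuai" group and
an introgression-donor "HdT" group) are crossed to F1 hybrids, from which
families are derived as resistant backcrosses (BCr, hybrid x donor parent),
susceptible backcrosses (BCs, hybrid x commercial parent) and F2 (hybrid
selfed).  Defaults reproduce the canonical design: 13 families of 15
individuals (195 plants), genotyped at biallelic SNPs spread over 11
chromosomes plus an unanchored "chr0" group and a UNIGENE group, and
phenotyped over three years under the six-random-effect observation model

    y = Xu + Zg + Wp + Vr + Tb + Ri + e

(year means u fixed; genotype g, permanent-plant p, population-type r,
plot/block b, family-by-year interaction i, and residual e random).

Markers segregate independently (gene dropping without linkage); founders
are treated as inbred lines, consistent with the near-disomic meiosis of
the allotetraploid and with cultivar-derived parents.  The "false SNP"
artefact of homeologous polymorphism — markers that are called polymorphic
but show the same genotype in every individual — is emulated by forcing a
configurable fraction of markers invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import (
    DEFAULT_CHROMOSOMES,
    ConfigurationError,
    MarkerPanel,
    validate_phenotypes,
)

POP_TYPES = ("BCr", "BCs", "F2")

#: Family-type sequence of the default design: 4 resistant backcrosses,
#: 5 susceptible backcrosses and 4 F2 families, interleaved as in the
#: original field trial.
DEFAULT_FAMILY_TYPES = (
    "BCr", "BCs", "BCr", "BCs", "BCr", "BCs", "BCr", "BCs", "BCs",
    "F2", "F2", "F2", "F2",
)

#: Stylized marker allocation over linkage groups (fractions of the panel).
#: The shape mimics a real transcriptome-anchored SNP panel: one large
#: chromosome, a sizeable unanchored-scaffold bin ("chr0") and a tiny
#: UNIGENE group.
DEFAULT_CHROMOSOME_WEIGHTS = {
    "chr1": 1637, "chr2": 2804, "chr3": 1637, "chr4": 1637, "chr5": 1637,
    "chr6": 1637, "chr7": 1637, "chr8": 1637, "chr9": 1637, "chr10": 1637,
    "chr11": 1636, "chr0": 1989, "UNIGENE": 49,
}


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

@dataclass
class PedigreeSpec:
    """Structure of the crossing design.

    ``family_types`` lists the generation of each family in field order;
    its length must equal ``n_families``.
    """

    n_families: int = 13
    family_types: tuple[str, ...] = DEFAULT_FAMILY_TYPES
    individuals_per_family: int = 15
    n_catuai_parents: int = 3
    n_hdt_parents: int = 3
    n_hybrids: int = 5

    def validate(self) -> None:
        if self.n_families < 1 or self.individuals_per_family < 1:
            raise ConfigurationError("family counts must be positive")
        if len(self.family_types) != self.n_families:
            raise ConfigurationError(
                f"family_types has {len(self.family_types)} entries for "
                f"{self.n_families} families"
            )
        if not set(self.family_types) <= set(POP_TYPES):
            raise ConfigurationError(f"family types must be among {POP_TYPES}")
        if min(self.n_catuai_parents, self.n_hdt_parents, self.n_hybrids) < 1:
            raise ConfigurationError("founder and hybrid counts must be positive")

    @property
    def n_individuals(self) -> int:
        return self.n_families * self.individuals_per_family


@dataclass
class Pedigree:
    """Parent assignments for founders, F1 hybrids and the study individuals.

    ``individuals`` has one row per study plant with columns
    individual, family, pop_type, plot, parent1, parent2.  ``hybrids``
    maps each F1 id to its (catuai, hdt) founder pair.
    """

    spec: PedigreeSpec
    founders_catuai: list[str]
    founders_hdt: list[str]
    hybrids: dict[str, tuple[str, str]]
    families: pd.DataFrame  # family, pop_type, parent1 (hybrid), parent2
    individuals: pd.DataFrame

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def family_of(self) -> pd.Series:
        return self.individuals.set_index("individual")["family"]


def simulate_pedigree(spec: PedigreeSpec | None = None, seed: int = 0) -> Pedigree:
    """Build the crossing design deterministically.

    Hybrids are formed by cycling over the founder pools; each backcross
    family returns to the relevant founder parent of its own hybrid (donor
    parent for BCr, commercial parent for BCs) and each F2 family selfs its
    hybrid.  The layout is fully determined by the spec; ``seed`` is kept in
    the signature so that callers can treat every simulation stage
    uniformly, and is reserved for future randomized designs.
    """
    spec = spec or PedigreeSpec()
    spec.validate()

    catuai = [f"C{i + 1}" for i in range(spec.n_catuai_parents)]
    hdt = [f"T{i + 1}" for i in range(spec.n_hdt_parents)]
    hybrids = {
        f"H{j + 1}": (catuai[j % len(catuai)], hdt[j % len(hdt)])
        for j in range(spec.n_hybrids)
    }
    hybrid_ids = list(hybrids)

    fam_rows = []
    ind_rows = []
    k = 0
    for f, ftype in enumerate(spec.family_types):
        fam = f"fam{f + 1:02d}"
        hyb = hybrid_ids[f % len(hybrid_ids)]
        cat_parent, hdt_parent = hybrids[hyb]
        if ftype == "BCr":
            p1, p2 = hyb, hdt_parent
        elif ftype == "BCs":
            p1, p2 = hyb, cat_parent
        else:  # F2: selfed hybrid
            p1 = p2 = hyb
        fam_rows.append({"family": fam, "pop_type": ftype, "parent1": p1, "parent2": p2})
        for r in range(spec.individuals_per_family):
            k += 1
            ind_rows.append(
                {
                    "individual": f"G{k:03d}",
                    "family": fam,
                    "pop_type": ftype,
                    # replication index doubles as the field block ("plot"):
                    # plant r of every family sits in block r.
                    "plot": f"plot{r + 1:02d}",
                    "parent1": p1,
                    "parent2": p2,
                }
            )

    return Pedigree(
        spec=spec,
        founders_catuai=catuai,
        founders_hdt=hdt,
        hybrids=hybrids,
        families=pd.DataFrame(fam_rows),
        individuals=pd.DataFrame(ind_rows),
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _allocate_chromosomes(n_markers: int, weights: Mapping[str, float]) -> np.ndarray:
    """Largest-remainder allocation of markers to linkage groups."""
    labels = list(weights)
    w = np.asarray([weights[c] for c in labels], dtype=float)
    w = w / w.sum()
    raw = w * n_markers
    counts = np.floor(raw).astype(int)
    short = n_markers - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return np.repeat(np.asarray(labels, dtype=object), counts)


def simulate_genotypes(
    pedigree: Pedigree,
    n_markers: int = 5000,
    founder_maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.01,
    invariant_fraction: float = 0.015,
    low_callrate_fraction: float = 0.01,
    low_callrate_missing: float = 0.15,
    chromosome_weights: Mapping[str, float] | None = None,
    seed: int = 0,
) -> MarkerPanel:
    """Gene-drop founder alleles through the pedigree to dosage genotypes.

    Founder lines are inbred: each founder is homozygous at every marker,
    carrying the alternative allele with a probability drawn per marker from
    ``founder_maf_range`` (uniform).  Offspring receive one gamete from each
    parent with independent Mendelian segregation per marker (no linkage).

    Panel artefacts are then injected: ``invariant_fraction`` of markers are
    forced to a constant genotype in all individuals (half of them
    heterozygous — the homeolog "false SNP" signature), a
    ``low_callrate_fraction`` of markers get an elevated missing rate of
    ``low_callrate_missing``, and all remaining entries are masked at
    ``missing_rate``.

    Returns a :class:`MarkerPanel`; ``panel.metadata`` records the forced
    invariant markers, the low-call-rate markers and the parental dosage
    vectors of each family (used by Mendelian-consistency checks).
    """
    if n_markers < 1:
        raise ConfigurationError("n_markers must be >= 1")
    for name, rate in (
        ("missing_rate", missing_rate),
        ("invariant_fraction", invariant_fraction),
        ("low_callrate_fraction", low_callrate_fraction),
        ("low_callrate_missing", low_callrate_missing),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1]")
    lo, hi = founder_maf_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ConfigurationError("founder_maf_range must satisfy 0 <= lo <= hi <= 1")

    rng = np.random.default_rng(seed)
    m = n_markers

    # founder haplotypes (inbred lines: a single 0/1 haplotype each).
    # SNP discovery panels are ascertained for polymorphism across
    # accessions, so markers are resampled until the minor allele is
    # carried by at least two founder lines.
    founder_ids = pedigree.founders_catuai + pedigree.founders_hdt
    n_founders = len(founder_ids)
    min_carriers = 2 if n_founders >= 4 else 1
    freqs = rng.uniform(lo, hi, size=m)
    alleles = np.empty((n_founders, m), dtype=np.int8)
    todo = np.arange(m)
    for _ in range(200):
        if todo.size == 0:
            break
        draw = (rng.random((n_founders, todo.size)) < freqs[todo]).astype(np.int8)
        alleles[:, todo] = draw
        carriers = draw.sum(axis=0)
        ok = (carriers >= min_carriers) & (carriers <= n_founders - min_carriers)
        todo = todo[~ok]
    founder_hap = {fid: alleles[j].copy() for j, fid in enumerate(founder_ids)}

    # F1 hybrids: one haplotype from each (inbred) parent, deterministically
    hybrid_haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for hyb, (cat, don) in pedigree.hybrids.items():
        hybrid_haps[hyb] = (founder_hap[cat].copy(), founder_hap[don].copy())

    def gametes(node: str, k: int) -> np.ndarray:
        """k independent gametes (k x m) from a founder or hybrid."""
        if node in founder_hap:
            return np.tile(founder_hap[node], (k, 1))
        h1, h2 = hybrid_haps[node]
        pick = rng.integers(0, 2, size=(k, m))
        return np.where(pick == 0, h1, h2)

    n_ind = pedigree.n_individuals
    geno = np.empty((n_ind, m), dtype=float)
    family_parent_dosage: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    inds = pedigree.individuals
    for fam, block in inds.groupby("family", sort=False):
        p1 = block["parent1"].iloc[0]
        p2 = block["parent2"].iloc[0]
        k = len(block)
        rows = block.index.to_numpy()
        geno[rows] = gametes(p1, k) + gametes(p2, k)

        def dosage(node: str) -> np.ndarray:
            if node in founder_hap:
                return 2.0 * founder_hap[node]
            h1, h2 = hybrid_haps[node]
            return (h1 + h2).astype(float)

        family_parent_dosage[fam] = (dosage(p1), dosage(p2))

    # forced invariant markers ("false SNPs")
    n_forced = int(np.floor(invariant_fraction * m))
    forced = rng.choice(m, size=n_forced, replace=False)
    for j, col in enumerate(forced):
        geno[:, col] = 1.0 if j % 2 == 0 else float(2 * (j % 4 == 1))

    # missingness: a few badly-called markers plus background dropout
    remaining = np.setdiff1d(np.arange(m), forced)
    n_badcall = int(np.floor(low_callrate_fraction * m))
    badcall = rng.choice(remaining, size=min(n_badcall, remaining.size), replace=False)
    mask = rng.random((n_ind, m)) < missing_rate
    if badcall.size:
        mask[:, badcall] = rng.random((n_ind, badcall.size)) < low_callrate_missing
    geno[mask] = np.nan

    weights = dict(chromosome_weights or DEFAULT_CHROMOSOME_WEIGHTS)
    chromosomes = _allocate_chromosomes(m, weights)
    width = max(5, len(str(m)))
    marker_ids = [f"SNP{j + 1:0{width}d}" for j in range(m)]

    return MarkerPanel(
        genotypes=geno,
        individual_ids=list(inds["individual"]),
        marker_ids=marker_ids,
        chromosomes=chromosomes,
        metadata={
            "forced_invariant": [marker_ids[j] for j in sorted(forced)],
            "low_callrate": [marker_ids[j] for j in sorted(badcall)],
            "family_parent_dosage": family_parent_dosage,
            "founder_allele_freqs": freqs,
        },
    )


# ---------------------------------------------------------------------------
# traits and phenotypes
# ---------------------------------------------------------------------------

VARIANCE_KEYS = ("genotype", "permanent", "pop_type", "plot", "interaction", "residual")


@dataclass
class TraitSpec:
    """Generative definition of one trait.

    ``variance`` maps the six observation-model components to nonnegative
    variances: genotype (additive genetic, at the individual level),
    permanent (time-constant plant environment), pop_type (population-type
    deviation), plot (field block), interaction (family x year) and
    residual.  Score traits are produced by cutting the latent continuous
    value into ``score_levels`` ordered classes of approximately equal
    occupancy.
    """

    name: str
    kind: str = "continuous"  # "continuous" | "score"
    score_levels: int = 0
    variance: Mapping[str, float] = field(default_factory=dict)
    n_qtl: int = 100
    year_means: tuple[float, ...] | None = None

    def validate(self, n_years: int) -> None:
        if self.kind not in ("continuous", "score"):
            raise ConfigurationError(f"unknown trait kind {self.kind!r}")
        if self.kind == "score" and self.score_levels < 2:
            raise ConfigurationError("score traits need score_levels >= 2")
        unknown = set(self.variance) - set(VARIANCE_KEYS)
        if unknown:
            raise ConfigurationError(f"unknown variance components {sorted(unknown)}")
        v = self.full_variance()
        if any(x < 0 for x in v.values()):
            raise ConfigurationError("variances must be nonnegative")
        if sum(v.values()) <= 0:
            raise ConfigurationError("at least one variance must be positive")
        if self.n_qtl < 1:
            raise ConfigurationError("n_qtl must be >= 1")
        if self.year_means is not None and len(self.year_means) != n_years:
            raise ConfigurationError("year_means must have one entry per year")

    def full_variance(self) -> dict[str, float]:
        return {k: float(self.variance.get(k, 0.0)) for k in VARIANCE_KEYS}


def make_trait(
    name: str,
    h2: float,
    n_qtl: int,
    kind: str = "continuous",
    score_levels: int = 0,
    year_means: tuple[float, ...] | None = None,
) -> TraitSpec:
    """TraitSpec with individual heritability ``h2`` on a unit total variance.

    The non-genetic variance is split in fixed proportions (population type
    5%, plot 10%, family-by-year interaction 15%, residual 70% of the
    non-genetic part; permanent-plant variance 0, which is indistinguishable
    from the genetic component in a one-plant-per-genotype design).
    """
    if not 0.0 <= h2 <= 1.0:
        raise ConfigurationError("h2 must be in [0, 1]")
    rest = 1.0 - h2
    return TraitSpec(
        name=name,
        kind=kind,
        score_levels=score_levels,
        variance={
            "genotype": h2,
            "permanent": 0.0,
            "pop_type": 0.05 * rest,
            "plot": 0.10 * rest,
            "interaction": 0.15 * rest,
            "residual": 0.70 * rest,
        },
        n_qtl=n_qtl,
        year_means=year_means,
    )


#: (name, kind, score levels, target individual h2, nominal QTL count) of the
#: 18 default traits: 11 continuous agronomic measurements and 7 score-scale
#: traits.  h2 and QTL counts are set to the magnitudes typical of a small
#: perennial breeding population (yield-like traits polygenic with low h2;
#: architecture traits such as plant height moderately heritable).
_DEFAULT_TRAIT_TABLE = (
    ("Y", "continuous", 0, 0.26, 751),
    ("LL", "continuous", 0, 0.29, 3981),
    ("LW", "continuous", 0, 0.32, 17758),
    ("BL", "continuous", 0, 0.41, 244),
    ("NRN", "continuous", 0, 0.23, 4000),
    ("NVN", "continuous", 0, 0.46, 199),
    ("NF", "continuous", 0, 0.34, 1157),
    ("FV", "continuous", 0, 0.25, 1081),
    ("PH", "continuous", 0, 0.46, 202),
    ("CD", "continuous", 0, 0.45, 149),
    ("SD", "continuous", 0, 0.16, 1658),
    ("RFS", "score", 3, 0.36, 394),
    ("MU", "score", 4, 0.28, 14775),
    ("MC", "score", 5, 0.31, 1313),
    ("Rus", "score", 5, 0.31, 221),
    ("Cer", "score", 5, 0.44, 304),
    ("LM", "score", 5, 0.30, 476),
    ("Vig", "score", 10, 0.34, 440),
)


def default_traits(max_qtl: int | None = None) -> list[TraitSpec]:
    """The 18-trait default set; QTL counts are capped at ``max_qtl``."""
    traits = []
    for name, kind, levels, h2, nq in _DEFAULT_TRAIT_TABLE:
        if max_qtl is not None:
            nq = min(nq, max_qtl)
        ym = (10.0, 11.0, 9.5) if kind == "continuous" else (0.0, 0.2, -0.2)
        traits.append(make_trait(name, h2, nq, kind, levels, year_means=ym))
    return traits


@dataclass
class SimulationTruth:
    """Ground truth of one phenotype simulation, keyed by trait name."""

    true_breeding_values: dict[str, pd.Series]
    true_qtl_markers: dict[str, list[str]]
    true_qtl_effects: dict[str, np.ndarray]
    realized_h2: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Long CSV-friendly view of the true breeding values."""
        rows = []
        for trait, bv in self.true_breeding_values.items():
            for ind, val in bv.items():
                rows.append({"trait": trait, "individual": ind, "true_bv": val})
        return pd.DataFrame(rows)


def simulate_phenotypes(
    panel: MarkerPanel,
    pedigree: Pedigree,
    traits: Iterable[TraitSpec],
    n_years: int = 3,
    year_labels: tuple[int, ...] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate multi-year records under the six-component observation model.

    For each trait, ``n_qtl`` markers are sampled among the segregating
    markers of the panel; their effects are drawn standard-normal and then
    rescaled so that the realized variance of the breeding values across the
    population equals the specified genotype variance exactly.  All other
    random effects are drawn independently normal at their own level
    (individual, population type, plot, family x year, record) with the
    specified variances, and year means are added.

    Returns the long-format phenotype table and the simulation truth.
    """
    traits = list(traits)
    for t in traits:
        t.validate(n_years)
    names = [t.name for t in traits]
    if len(set(names)) != len(names):
        raise ConfigurationError("trait names must be unique")

    inds = pedigree.individuals
    if list(inds["individual"]) != list(panel.individual_ids):
        raise ConfigurationError("panel individuals do not match the pedigree")

    rng = np.random.default_rng(seed)
    years = tuple(year_labels) if year_labels is not None else tuple(range(1, n_years + 1))
    if len(years) != n_years:
        raise ConfigurationError("year_labels must have n_years entries")

    n = panel.n_individuals
    # dosage matrix with missing calls mean-imputed for the QTL machinery
    W = panel.genotypes.copy()
    col_mean = np.nanmean(np.where(np.isnan(W), np.nan, W), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.nonzero(np.isnan(W))
    W[nan_r, nan_c] = col_mean[nan_c]
    segregating = np.nonzero(W.std(axis=0) > 0)[0]

    fam_codes = pd.Categorical(inds["family"]).codes
    pop_codes = pd.Categorical(inds["pop_type"]).codes
    plot_codes = pd.Categorical(inds["plot"]).codes
    n_fam = fam_codes.max() + 1
    n_pop = pop_codes.max() + 1
    n_plot = plot_codes.max() + 1

    records = []
    true_bv: dict[str, pd.Series] = {}
    true_qtl: dict[str, list[str]] = {}
    true_eff: dict[str, np.ndarray] = {}
    realized: dict[str, float] = {}

    for t in traits:
        v = t.full_variance()
        if t.n_qtl > panel.n_markers:
            raise ConfigurationError(
                f"trait {t.name}: n_qtl={t.n_qtl} exceeds panel size {panel.n_markers}"
            )
        if t.n_qtl > segregating.size:
            raise ConfigurationError(
                f"trait {t.name}: n_qtl={t.n_qtl} exceeds the number of "
                f"segregating markers ({segregating.size})"
            )
        qtl = rng.choice(segregating, size=t.n_qtl, replace=False)
        eff = rng.standard_normal(t.n_qtl)
        bv = W[:, qtl] @ eff
        bv -= bv.mean()
        sd = bv.std()
        if v["genotype"] > 0 and sd > 0:
            scale = np.sqrt(v["genotype"]) / sd
        else:
            scale = 0.0
        bv *= scale
        eff = eff * scale

        perm = rng.normal(0.0, np.sqrt(v["permanent"]), size=n)
        pop_eff = rng.normal(0.0, np.sqrt(v["pop_type"]), size=n_pop)
        plot_eff = rng.normal(0.0, np.sqrt(v["plot"]), size=n_plot)
        inter_eff = rng.normal(0.0, np.sqrt(v["interaction"]), size=(n_fam, n_years))
        resid = rng.normal(0.0, np.sqrt(v["residual"]), size=(n, n_years))
        year_means = t.year_means if t.year_means is not None else tuple([0.0] * n_years)

        base = bv + perm + pop_eff[pop_codes] + plot_eff[plot_codes]
        latent = (
            base[:, None]
            + inter_eff[fam_codes, :]
            + resid
            + np.asarray(year_means)[None, :]
        )

        if t.kind == "score":
            flat = latent.ravel()
            # class boundaries at equal-occupancy quantiles of the latent scale
            qs = np.quantile(flat, np.linspace(0, 1, t.score_levels + 1)[1:-1])
            values = (np.searchsorted(qs, flat, side="right") + 1).astype(float)
            values = values.reshape(latent.shape)
        else:
            values = latent

        deviations = (
            bv.repeat(n_years).var(),
            perm.repeat(n_years).var(),
            pop_eff[pop_codes].repeat(n_years).var(),
            plot_eff[plot_codes].repeat(n_years).var(),
            inter_eff[fam_codes, :].ravel().var(),
            resid.ravel().var(),
        )
        total = sum(deviations)
        realized[t.name] = deviations[0] / total if total > 0 else 0.0
        true_bv[t.name] = pd.Series(bv, index=panel.individual_ids, name=t.name)
        true_qtl[t.name] = [panel.marker_ids[j] for j in qtl]
        true_eff[t.name] = eff

        for yi, year in enumerate(years):
            for r in range(n):
                records.append(
                    (
                        inds["individual"].iat[r],
                        inds["family"].iat[r],
                        inds["pop_type"].iat[r],
                        inds["plot"].iat[r],
                        year,
                        t.name,
                        values[r, yi],
                    )
                )

    table = pd.DataFrame(
        records,
        columns=["individual", "family", "pop_type", "plot", "year", "trait", "value"],
    )
    truth = SimulationTruth(
        true_breeding_values=true_bv,
        true_qtl_markers=true_qtl,
        true_qtl_effects=true_eff,
        realized_h2=realized,
    )
    return validate_phenotypes(table), truth
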