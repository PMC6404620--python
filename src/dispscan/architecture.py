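"""Quantitative architecture of a dispersion locus.

From a fitted locus model (dispersion regressed on a 3-level genotype
factor, P2 homozygote as reference) this module derives the three
genotypic means, tests additivity and dominance with single-row Wald
contrasts, computes Griffing's potence ratio, and assigns the
architecture labels used in the scan report:

* A   — additive (homozygote linear contrast +1 0 -1 significant)
* D+  — positive dominance (heterozygote resembles the high-dispersion
        homozygote)
* D-  — negative dominance (heterozygote resembles the low-dispersion
        homozygote; high dispersion is recessive)
* OD / UD — heterozygote significantly above / below both homozygotes

A locus may carry multiple labels (partial dominance reports {D-, A} as
two stacked entries); contradictory simultaneous families are reported
and flagged ambiguous rather than suppressed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort_io import HET, HOM_P1, HOM_P2
from .tobit import ContrastResult, TobitFit, wald_contrast

log = logging.getLogger(__name__)

#: Genotype display order used throughout: (CC, CA, AA) where CC is the
#: P1 homozygote and AA the P2 (reference) homozygote.
CLASS_ORDER = (HOM_P1, HET, HOM_P2)

# Dominance test vectors over (CC, CA, AA) means.  A significantly
# *positive* estimate identifies the pattern named in the key.
DOMINANCE_VECTORS: dict[str, np.ndarray] = {
    # positive dominance: heterozygote travels with the high homozygote
    "pos_CC_high": np.array([+0.5, +0.5, -1.0]),
    "pos_AA_high": np.array([-1.0, +0.5, +0.5]),
    # negative dominance: one homozygote is the isolated high class
    "neg_CC_high": np.array([+1.0, -0.5, -0.5]),
    "neg_AA_high": np.array([-0.5, -0.5, +1.0]),
}

LINEAR_VECTOR = np.array([+1.0, 0.0, -1.0])
MIDPARENT_VECTOR = np.array([-0.5, +1.0, -0.5])
HET_MINUS_CC = np.array([-1.0, +1.0, 0.0])
HET_MINUS_AA = np.array([0.0, +1.0, -1.0])


class IncompleteLocusError(ValueError):
    """Raised when architecture tests need all three genotype classes."""


@dataclass
class GenotypeMeans:
    """Fitted dispersion means (and SEs) per genotype class, from one fit."""

    mu: np.ndarray           # (mu_CC, mu_CA, mu_AA)
    se: np.ndarray
    cov: np.ndarray          # 3x3

    @property
    def mu_cc(self) -> float:
        return float(self.mu[0])

    @property
    def mu_ca(self) -> float:
        return float(self.mu[1])

    @property
    def mu_aa(self) -> float:
        return float(self.mu[2])


@dataclass
class ArchitectureCall:
    """Architecture labels and supporting contrasts for one locus."""

    labels: list[dict] = field(default_factory=list)  # {"form", "p", "allele"}
    potence: float | None = None
    potence_defined: bool = True
    means: GenotypeMeans | None = None
    linear: ContrastResult | None = None
    midparent: ContrastResult | None = None
    dominance: dict[str, ContrastResult] = field(default_factory=dict)
    het_pairwise: dict[str, ContrastResult] = field(default_factory=dict)
    high_pd_allele: str | None = None
    ambiguous: bool = False

    @property
    def forms(self) -> list[str]:
        return [lab["form"] for lab in self.labels]


def _mean_rows(fit: TobitFit, locus_levels: dict[int, int | None]) -> np.ndarray:
    """Rows mapping beta to genotypic means in CLASS_ORDER.

    Non-locus covariate columns get zero weight; since every contrast
    used downstream has weights summing to zero, covariates held at any
    common value cancel and only mean *differences* are interpreted.
    """
    p = len(fit.beta)
    if set(locus_levels) != set(CLASS_ORDER):
        raise IncompleteLocusError(
            f"need all three genotype classes, have {sorted(locus_levels)}"
        )
    M = np.zeros((3, p))
    M[:, 0] = 1.0  # intercept
    for row, cls in enumerate(CLASS_ORDER):
        col = locus_levels[cls]
        if col is not None:
            M[row, col] = 1.0
    return M


def genotype_means(fit: TobitFit, locus_levels: dict[int, int | None]) -> GenotypeMeans:
    M = _mean_rows(fit, locus_levels)
    mu = M @ fit.beta
    cov = M @ fit.vcov_beta @ M.T
    return GenotypeMeans(mu=mu, se=np.sqrt(np.maximum(np.diag(cov), 0.0)), cov=cov)


def potence_ratio(
    means: GenotypeMeans | np.ndarray,
    orient: str = "high",
    tol: float = 1e-12,
) -> tuple[float | None, bool]:
    """Griffing's potence ratio h_P = Q / L = (2 mu_CA - mu_CC - mu_AA) / (mu_CC - mu_AA).

    ``orient="strain"`` keeps the raw strain-ordered sign (positive =
    dominance toward the P1 homozygote); ``orient="high"`` (default)
    orients the denominator toward the high-mean homozygote so +1 means
    complete dominance toward the high parent and -1 toward the low.
    Returns (value, defined); undefined (None, False) when the
    homozygote means coincide within ``tol``.
    """
    mu = means.mu if isinstance(means, GenotypeMeans) else np.asarray(means, float)
    q = 2.0 * mu[1] - (mu[0] + mu[2])
    lin = mu[0] - mu[2]
    if abs(lin) <= tol:
        return None, False
    if orient == "strain":
        return float(q / lin), True
    if orient == "high":
        return float(q / abs(lin)), True
    raise ValueError(f"unknown orientation {orient!r}")


def _mean_contrast(fit: TobitFit, locus_levels, weights: np.ndarray) -> ContrastResult:
    M = _mean_rows(fit, locus_levels)
    return wald_contrast(fit, weights @ M)


def test_additivity(fit: TobitFit, locus_levels: dict[int, int | None]) -> dict[str, ContrastResult]:
    """Homozygote linear contrast (+1 0 -1) and heterozygote-vs-midparent.

    The linear contrast estimates mu_CC - mu_AA and feeds the "A" label;
    the midparent contrast (-0.5 +1 -0.5) estimates the dominance
    deviation of the heterozygote.  Both are emitted.
    """
    return {
        "linear": _mean_contrast(fit, locus_levels, LINEAR_VECTOR),
        "midparent": _mean_contrast(fit, locus_levels, MIDPARENT_VECTOR),
    }


def test_dominance(fit: TobitFit, locus_levels: dict[int, int | None]) -> dict[str, ContrastResult]:
    """The four positive/negative dominance vectors, signs preserved."""
    return {
        name: _mean_contrast(fit, locus_levels, w)
        for name, w in DOMINANCE_VECTORS.items()
    }


def classify_architecture(
    fit: TobitFit,
    locus_levels: dict[int, int | None],
    strains: tuple[str, str] = ("P1", "P2"),
    alpha_label: float = 0.05,
) -> ArchitectureCall:
    """Assign architecture labels at the nominal per-contrast threshold.

    Dominance-family labels require the stated vector to be significant
    with a positive estimate (the vectors are oriented so the named class
    is high).  OD/UD come from the two pairwise heterozygote contrasts
    and, when present, absorb the corresponding same-pattern dominance
    family (both D+ vectors positive is exactly the OD configuration and
    both D- vectors positive the UD one).  Contradictory remaining
    families are flagged ambiguous.
    """
    means = genotype_means(fit, locus_levels)
    add = test_additivity(fit, locus_levels)
    dom = test_dominance(fit, locus_levels)
    het = {
        "het_minus_cc": _mean_contrast(fit, locus_levels, HET_MINUS_CC),
        "het_minus_aa": _mean_contrast(fit, locus_levels, HET_MINUS_AA),
    }
    hp, hp_defined = potence_ratio(means)

    sig = lambda c: c.p < alpha_label
    labels: list[dict] = []

    od = sig(het["het_minus_cc"]) and sig(het["het_minus_aa"]) and \
        het["het_minus_cc"].estimate > 0 and het["het_minus_aa"].estimate > 0
    ud = sig(het["het_minus_cc"]) and sig(het["het_minus_aa"]) and \
        het["het_minus_cc"].estimate < 0 and het["het_minus_aa"].estimate < 0
    if od:
        p_od = max(het["het_minus_cc"].p, het["het_minus_aa"].p)
        labels.append({"form": "OD", "p": p_od, "allele": None})
    if ud:
        p_ud = max(het["het_minus_cc"].p, het["het_minus_aa"].p)
        labels.append({"form": "UD", "p": p_ud, "allele": None})

    # The four family vectors all turn positive whenever one homozygote is
    # high, so the heterozygote's dominance deviation (midparent contrast
    # Q) disambiguates: positive dominance pulls the heterozygote above
    # the midparent (toward the high-dispersion class), negative below.
    q_est = add["midparent"].estimate

    def dom_hit(name: str) -> bool:
        c = dom[name]
        family_sign = 1.0 if name.startswith("pos") else -1.0
        return sig(c) and c.estimate > 0 and family_sign * q_est > 0

    # OD is the two D+ vectors firing jointly; UD the two D- vectors.
    if not od:
        if dom_hit("pos_CC_high"):
            labels.append({"form": "D+", "p": dom["pos_CC_high"].p, "allele": strains[0]})
        if dom_hit("pos_AA_high"):
            labels.append({"form": "D+", "p": dom["pos_AA_high"].p, "allele": strains[1]})
    if not ud:
        if dom_hit("neg_CC_high"):
            labels.append({"form": "D-", "p": dom["neg_CC_high"].p, "allele": strains[0]})
        if dom_hit("neg_AA_high"):
            labels.append({"form": "D-", "p": dom["neg_AA_high"].p, "allele": strains[1]})

    if sig(add["linear"]):
        allele = strains[0] if add["linear"].estimate > 0 else strains[1]
        labels.append({"form": "A", "p": add["linear"].p, "allele": allele})

    forms = [lab["form"] for lab in labels]
    alleles = {lab["allele"] for lab in labels if lab["allele"] is not None}
    ambiguous = ("D+" in forms and "D-" in forms) or len(alleles) > 1

    high_idx = int(np.argmax(means.mu))
    if labels:
        high_pd_allele = {0: strains[0], 1: "heterozygote", 2: strains[1]}[high_idx]
    else:
        high_pd_allele = None

    return ArchitectureCall(
        labels=labels,
        potence=hp,
        potence_defined=hp_defined,
        means=means,
        linear=add["linear"],
        midparent=add["midparent"],
        dominance=dom,
        het_pairwise=het,
        high_pd_allele=high_pd_allele,
        ambiguous=ambiguous,
    )
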