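"""Phenotypic dispersion: covariate models and externally Studentized residuals.

The dispersion phenotype PD is the absolute externally Studentized
residual of a trait from a linear covariate model.  The model for a trait
y at marker locus i is

    y_j = mu + alpha_i(g_j) + beta_MLH * MLH_j + beta_UCrea * UCrea_j + eps_j

where alpha_i is a 3-level genotype factor (reference = P2 homozygote),
MLH is multilocus heterozygosity (fraction of typed markers that are
heterozygous, an inbreeding proxy) and the creatinine term enters only
for albumin (creatinine proxies glomerular throughput, i.e. urine
concentration).  Each observation's residual is scaled by a standard
error whose variance estimate excludes that observation (leave-one-out),
so a single aberrant individual does not deflate its own dispersion
score.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cohort, GenotypeMatrix, HET, HOM_P1, HOM_P2, MISSING

log = logging.getLogger(__name__)


class DegenerateFitError(ValueError):
    """Raised when a model design is rank deficient (e.g. monomorphic locus)."""


@dataclass
class CovariateModelSpec:
    """Which terms enter the trait's covariate model."""

    trait: str
    include_locus: str | None = None
    include_mlh: bool = False
    include_ucrea: bool = False

    def __post_init__(self) -> None:
        if self.include_ucrea and self.trait != "ualb":
            raise ValueError("creatinine covariate permitted only for albumin")


@dataclass
class LinearFit:
    """An OLS fit on casewise-complete data (QR factorization)."""

    params: np.ndarray
    colnames: list[str]
    X: np.ndarray
    y: np.ndarray
    resid: np.ndarray
    leverage: np.ndarray
    index: pd.Index          # individuals retained
    locus_levels: dict[int, int | None] | None = None  # genotype code -> column (None=reference)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def rank(self) -> int:
        return self.X.shape[1]

    @property
    def sigma2(self) -> float:
        return float(self.resid @ self.resid / (self.n - self.rank))


@dataclass
class DispersionResult:
    """Externally Studentized residuals and the PD phenotype for one context."""

    index: pd.Index
    raw_residual: np.ndarray
    leverage: np.ndarray
    deleted_scale: np.ndarray
    t: np.ndarray
    pd: np.ndarray
    n: int
    df_model: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.pd, index=self.index, name="pd")


def compute_mlh(genotypes: GenotypeMatrix) -> pd.Series:
    """Multilocus heterozygosity: n_het / n_typed per individual.

    Missing genotypes are excluded from the denominator; an individual
    with zero typed markers gets NaN with a warning.
    """
    g = genotypes.data.to_numpy()
    typed = (g != MISSING).sum(axis=1)
    het = (g == HET).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mlh = np.where(typed > 0, het / np.maximum(typed, 1), np.nan)
    if (typed == 0).any():
        bad = genotypes.individuals[typed == 0].tolist()
        log.warning("individuals with no typed markers get missing MLH: %s", bad)
    return pd.Series(mlh, index=genotypes.individuals, name="mlh")


def _locus_columns(
    geno: np.ndarray, reference: int = HOM_P2
) -> tuple[np.ndarray, list[str], dict[int, int | None]]:
    """Dummy-code a genotype vector with the P2 homozygote as reference.

    Only classes present in the data get a column; the returned mapping
    records, for each present class, its dummy column offset (None for
    the reference class).
    """
    label = {HOM_P1: "P1hom", HET: "het", HOM_P2: "P2hom"}
    present = [c for c in (HOM_P1, HET, HOM_P2) if (geno == c).any()]
    ref = reference if reference in present else present[-1]
    cols, names = [], []
    levels: dict[int, int | None] = {}
    for c in present:
        if c == ref:
            levels[c] = None
            continue
        levels[c] = len(cols)
        cols.append((geno == c).astype(float))
        names.append(f"locus[{label[c]}]")
    dummies = np.column_stack(cols) if cols else np.empty((len(geno), 0))
    return dummies, names, levels


def build_design(
    cohort: Cohort,
    spec: CovariateModelSpec,
    mlh: pd.Series | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], pd.Index, dict[int, int | None] | None]:
    """Assemble (y, X) on casewise-complete individuals for ``spec``."""
    y_all = cohort.phenotypes.values(spec.trait)
    parts: dict[str, pd.Series] = {}
    if spec.include_mlh:
        parts["mlh"] = compute_mlh(cohort.genotypes) if mlh is None else mlh
    if spec.include_ucrea:
        parts["ucrea"] = cohort.phenotypes.values("ucrea")

    mask = y_all.notna()
    for s in parts.values():
        mask &= s.notna()
    geno_col = None
    if spec.include_locus is not None:
        geno_col = pd.Series(
            cohort.genotypes.column(spec.include_locus),
            index=cohort.genotypes.individuals,
        )
        mask &= geno_col != MISSING

    idx = y_all.index[mask]
    y = y_all.loc[idx].to_numpy(float)
    cols = [np.ones(len(idx))]
    names = ["intercept"]
    locus_levels = None
    if geno_col is not None:
        gvals = geno_col.loc[idx].to_numpy()
        if len(np.unique(gvals)) < 2:
            raise DegenerateFitError(
                f"locus {spec.include_locus!r} is monomorphic on complete cases"
            )
        dummies, dnames, levels = _locus_columns(gvals)
        # offsets are relative to the locus block; shift to absolute columns
        off = len(cols)
        locus_levels = {
            c: (None if j is None else off + j) for c, j in levels.items()
        }
        if dummies.shape[1]:
            cols.append(dummies)
            names.extend(dnames)
    for name, s in parts.items():
        cols.append(s.loc[idx].to_numpy(float)[:, None].ravel())
        names.append(name)
    X = np.column_stack(cols)
    return y, X, names, idx, locus_levels


def fit_covariate_model(
    cohort: Cohort,
    spec: CovariateModelSpec,
    mlh: pd.Series | None = None,
) -> LinearFit:
    """OLS fit of the covariate model on casewise-complete data."""
    y, X, names, idx, locus_levels = build_design(cohort, spec, mlh=mlh)
    if len(y) < X.shape[1] + 2:
        raise DegenerateFitError(
            f"only {len(y)} complete cases for {X.shape[1]} model columns"
        )
    return _ols_qr(y, X, names, idx, locus_levels)


def _ols_qr(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    idx: pd.Index,
    locus_levels=None,
) -> LinearFit:
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= 1e-10 * max(diag.max(), 1.0):
        raise DegenerateFitError(
            f"rank-deficient design (columns {names}); is the locus monomorphic?"
        )
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    leverage = np.einsum("ij,ij->i", Q, Q)
    return LinearFit(
        params=beta,
        colnames=names,
        X=X,
        y=y,
        resid=resid,
        leverage=leverage,
        index=idx,
        locus_levels=locus_levels,
    )


def studentize_external(fit: LinearFit) -> DispersionResult:
    """Externally Studentized residuals t_i and the dispersion score |t_i|.

    t_i = e_i / (s_(i) * sqrt(1 - h_ii)) with s_(i)^2 the residual
    variance of the model refit without observation i, computed in closed
    form from the full fit.  Observations with numerical leverage >= 1
    are dropped with a warning.
    """
    n, m = fit.n, fit.rank
    if n - m - 1 < 1:
        raise DegenerateFitError("need n - m - 1 >= 1 to studentize externally")
    e, h = fit.resid, fit.leverage
    keep = h < 1.0 - 1e-10
    if not keep.all():
        log.warning(
            "%d observations with leverage ~1 dropped from dispersion", (~keep).sum()
        )
    e, h, idx = e[keep], h[keep], fit.index[keep]
    ssr = float(fit.resid @ fit.resid)
    s2_del = (ssr - e**2 / (1.0 - h)) / (n - m - 1)
    s2_del = np.maximum(s2_del, 0.0)
    scale = np.sqrt(s2_del)
    denom = scale * np.sqrt(1.0 - h)
    with np.errstate(invalid="ignore"):
        t = np.where(denom > 0, e / np.where(denom > 0, denom, 1.0),
                     np.sign(e) * np.inf)
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    return DispersionResult(
        index=idx,
        raw_residual=e,
        leverage=h,
        deleted_scale=scale,
        t=t,
        pd=np.abs(t),
        n=n,
        df_model=m,
    )


def dispersion_for_spec(
    cohort: Cohort, spec: CovariateModelSpec, mlh: pd.Series | None = None
) -> DispersionResult:
    """Convenience: fit the covariate model and studentize in one step."""
    return studentize_external(fit_covariate_model(cohort, spec, mlh=mlh))


def select_covariates(
    cohort: Cohort,
    trait: str,
    mlh: pd.Series | None = None,
    probe_p: float = 0.1,
) -> CovariateModelSpec:
    """Decide the covariate set for a trait's genomic models.

    Creatinine enters only for albumin.  MLH enters when it is
    associated (two-sided P < ``probe_p``) with the dispersion score from
    the locus-free covariate model: fit the trait on the non-MLH
    covariates, form PD, and regress PD on MLH by OLS.
    """
    if mlh is None:
        mlh = compute_mlh(cohort.genotypes)
    base = CovariateModelSpec(
        trait=trait, include_ucrea=(trait == "ualb" and cohort.phenotypes.available("ucrea"))
    )
    disp = dispersion_for_spec(cohort, base, mlh=mlh)
    pd_series = disp.as_series()
    joined = pd.concat([pd_series, mlh.rename("mlh")], axis=1, join="inner").dropna()
    probe = _ols_qr(
        joined["pd"].to_numpy(),
        np.column_stack([np.ones(len(joined)), joined["mlh"].to_numpy()]),
        ["intercept", "mlh"],
        joined.index,
    )
    se = np.sqrt(probe.sigma2 * np.linalg.inv(probe.X.T @ probe.X)[1, 1])
    tval = probe.params[1] / se
    pval = 2 * stats.t.sf(abs(tval), probe.n - probe.rank)
    include_mlh = bool(pval < probe_p)
    log.info(
        "MLH probe for %s: beta=%.4g se=%.4g P=%.4g -> include_mlh=%s",
        trait, probe.params[1], se, pval, include_mlh,
    )
    return CovariateModelSpec(
        trait=trait,
        include_mlh=include_mlh,
        include_ucrea=base.include_ucrea,
    )
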