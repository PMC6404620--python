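"""Per-marker dispersion genome scan and cross-cohort consensus loci.

For each marker the pipeline is: covariate model for the trait including
the locus term -> absolute externally Studentized residuals (PD) ->
left-bounded (Tobit) regression of PD on the locus (+MLH when selected)
-> joint Wald nonequivalence test of all genotype effects against the
reference homozygote -> architecture contrasts -> variance explained;
finally Benjamini-Hochberg FDR with a nominal floor across the tested
markers of the trait.

Markers where only two genotype classes occur (hemizygous X in all-male
F2s) keep the joint test with one degree of freedom but get no
three-class architecture call; markers with a present class below
``min_class_n`` are skipped and excluded from the FDR family.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import ArchitectureCall, classify_architecture
from .cohort_io import (
    Cohort,
    HET,
    HOM_P1,
    HOM_P2,
    MISSING,
    chromosome_sort_key,
)
from .config import RunConfig
from .dispersion import (
    CovariateModelSpec,
    DegenerateFitError,
    compute_mlh,
    dispersion_for_spec,
    fit_covariate_model,
    select_covariates,
    studentize_external,
)
from .mtc import bh_with_floor
from .tobit import TobitFit, TobitSpec, fit_tobit, wald_contrast

log = logging.getLogger(__name__)

TRAIT_DISPLAY = {"ualb": "UAlb", "ucrea": "UCrea", "bun": "BUN", "weight": "Wt"}


@dataclass
class ScanTable:
    """Scan results: one record per tested marker plus a skip list."""

    trait: str
    cohort_name: str
    records: list[dict]
    skipped: list[dict]
    config: RunConfig
    map_build: str
    covariates: CovariateModelSpec | None = None

    def as_frame(self) -> pd.DataFrame:
        cols = [
            "marker", "chromosome", "position_bp", "position_cm", "n_used",
            "p_joint", "r2", "forms", "high_pd_allele", "fdr_reject", "locus",
        ]
        if not self.records:
            return pd.DataFrame(columns=cols)
        df = pd.DataFrame(self.records)
        df["forms"] = [
            [lab["form"] for lab in (rec.get("labels") or [])] for rec in self.records
        ]
        return df[cols]

    def rejected(self) -> pd.DataFrame:
        df = self.as_frame()
        return df[df["fdr_reject"]]


def _class_counts(g: np.ndarray) -> dict[int, int]:
    return {c: int((g == c).sum()) for c in (HOM_P1, HET, HOM_P2)}


def variance_explained(fit: TobitFit, locus_cols: list[int], pd_values: np.ndarray) -> float:
    """Proportion of dispersion explained: squared Pearson correlation
    between the genotype-class fitted values and observed PD.

    Only the intercept+locus part of the linear predictor varies between
    individuals here, so the fitted values are the class means; covariate
    terms (a common shift at any fixed covariate value) cannot change the
    correlation.
    """
    if fit.X is None:
        raise ValueError("fit retains no design matrix")
    cols = [0] + list(locus_cols)
    fitted = fit.X[:, cols] @ fit.beta[cols]
    if np.std(pd_values) == 0:
        log.warning("zero variance in PD; r2 set to 0")
        return 0.0
    if np.std(fitted) == 0:
        return 0.0
    r = np.corrcoef(fitted, pd_values)[0, 1]
    return float(r**2)


def scan_trait(
    cohort: Cohort,
    trait: str,
    config: RunConfig | None = None,
    mlh: pd.Series | None = None,
) -> ScanTable:
    """Scan every mapped marker of ``cohort`` for dispersion in ``trait``.

    ``mlh`` accepts a precomputed multilocus-heterozygosity series (e.g.
    from a marker superset) so covariates can be held fixed across
    marker-subset analyses.
    """
    config = config or RunConfig()
    if not cohort.phenotypes.available(trait):
        raise ValueError(f"trait {trait!r} unavailable in cohort {cohort.name!r}")

    if mlh is None:
        mlh = compute_mlh(cohort.genotypes)
    covs = select_covariates(cohort, trait, mlh=mlh, probe_p=config.mlh_probe_p)
    tspec = TobitSpec(tau=0.0, variant=config.tobit_variant)
    map_sorted = cohort.map.sorted().table

    global_disp = None
    if config.residualization == "global":
        global_disp = dispersion_for_spec(cohort, covs, mlh=mlh)

    records: list[dict] = []
    skipped: list[dict] = []
    for marker in cohort.markers_in_map_order():
        row = map_sorted.loc[marker]
        base = {
            "marker": marker,
            "chromosome": str(row["chromosome"]),
            "position_bp": int(row["position_bp"]),
            "position_cm": float(row["position_cm"]),
        }

        try:
            rec = _scan_marker(
                cohort, trait, marker, covs, mlh, tspec, config, global_disp
            )
        except DegenerateFitError as exc:
            skipped.append({**base, "reason": str(exc)})
            continue
        except _SkipMarker as exc:
            skipped.append({**base, "reason": str(exc)})
            continue
        records.append({**base, **rec})

    fdr = bh_with_floor(
        [rec["p_joint"] for rec in records],
        alpha_fdr=config.alpha_fdr,
        floor=config.floor,
    )
    for rec, (_, fr) in zip(records, fdr.table.iterrows()):
        rec["fdr_bh_pass"] = bool(fr["bh_pass"])
        rec["fdr_floor_pass"] = bool(fr["floor_pass"])
        rec["fdr_reject"] = bool(fr["reject"])
        rec["locus"] = None

    log.info(
        "scan %s/%s: %d markers tested, %d skipped, %d FDR rejections",
        cohort.name, trait, len(records), len(skipped), fdr.n_reject,
    )
    return ScanTable(
        trait=trait,
        cohort_name=cohort.name,
        records=records,
        skipped=skipped,
        config=config,
        map_build=cohort.map_build,
        covariates=covs,
    )


class _SkipMarker(Exception):
    pass


def _scan_marker(
    cohort: Cohort,
    trait: str,
    marker: str,
    covs: CovariateModelSpec,
    mlh: pd.Series,
    tspec: TobitSpec,
    config: RunConfig,
    global_disp,
) -> dict:
    g_all = pd.Series(cohort.genotypes.column(marker), index=cohort.genotypes.individuals)

    if config.residualization == "per-marker":
        mspec = CovariateModelSpec(
            trait=trait,
            include_locus=marker,
            include_mlh=covs.include_mlh,
            include_ucrea=covs.include_ucrea,
        )
        fit1 = fit_covariate_model(cohort, mspec, mlh=mlh)
        disp = studentize_external(fit1)
    else:
        disp = global_disp

    pd_series = disp.as_series()
    g = g_all.loc[g_all.index.intersection(pd_series.index)]
    ok = (g != MISSING) & pd_series.loc[g.index].notna()
    g = g[ok]
    y = pd_series.loc[g.index].to_numpy()

    counts = _class_counts(g.to_numpy())
    present = {c: k for c, k in counts.items() if k > 0}
    if len(present) < 2:
        raise _SkipMarker(f"monomorphic ({counts})")
    if any(k < config.min_class_n for k in present.values()):
        raise _SkipMarker(
            f"genotype class below min_class_n={config.min_class_n} ({counts})"
        )

    # Tobit design: intercept + locus dummies (reference = P2 homozygote
    # when present) + MLH if selected.
    from .dispersion import _locus_columns  # same dummy coding as stage 1

    dummies, dnames, levels = _locus_columns(g.to_numpy())
    cols = [np.ones(len(y)), dummies]
    names = ["intercept"] + dnames
    locus_levels = {c: (None if j is None else 1 + j) for c, j in levels.items()}
    if covs.include_mlh:
        mvals = mlh.loc[g.index]
        keep = mvals.notna().to_numpy()
        if not keep.all():
            g, y = g[keep], y[keep]
            dummies, dnames, levels = _locus_columns(g.to_numpy())
            cols = [np.ones(len(y)), dummies]
            names = ["intercept"] + dnames
            locus_levels = {c: (None if j is None else 1 + j) for c, j in levels.items()}
            mvals = mvals[keep]
        cols.append(mvals.to_numpy()[:, None])
        names.append("mlh")
    X = np.column_stack(cols)

    fit = fit_tobit(y, X, tspec, colnames=names)
    locus_cols = [j for j in locus_levels.values() if j is not None]
    C = np.zeros((len(locus_cols), len(fit.beta)))
    for i, j in enumerate(locus_cols):
        C[i, j] = 1.0
    joint = wald_contrast(fit, C)
    r2 = variance_explained(fit, locus_cols, y)

    arch: ArchitectureCall | None = None
    labels = []
    high_allele = None
    potence = None
    if set(locus_levels) == {HOM_P1, HET, HOM_P2}:
        arch = classify_architecture(
            fit, locus_levels, strains=cohort.genotypes.strains,
            alpha_label=config.alpha_label,
        )
        labels = arch.labels
        high_allele = arch.high_pd_allele
        potence = arch.potence

    return {
        "n_used": int(len(y)),
        "p_joint": joint.p,
        "joint_stat": joint.stat,
        "joint_df": joint.df,
        "r2": r2,
        "labels": labels,
        "high_pd_allele": high_allele,
        "potence": potence,
        "converged": fit.converged,
        "sigma": fit.sigma,
        "arch": arch,
    }


def consensus_loci(
    scans: list[ScanTable],
    window_mb: float | None = None,
    require_same_allele: bool | None = None,
) -> dict:
    """Group FDR-passing markers across cohorts into consensus loci.

    Markers from *different* cohorts on the same chromosome whose
    positions single-link within ``window_mb`` (and, optionally, that
    share the same high-dispersion allele) form one named locus
    PD<Trait><k>, numbered by chromosome then position.  Same-position
    groups with opposite high-dispersion alleles are reported as
    contrast pairs, not consensus loci.  All scans must share a map
    build.  Scan records are annotated in place with their locus name.
    """
    if len(scans) < 2:
        raise ValueError("consensus requires at least two scans")
    builds = {s.map_build for s in scans}
    if len(builds) > 1:
        raise ValueError(f"scans on different map builds: {sorted(builds)}")
    traits = {s.trait for s in scans}
    if len(traits) > 1:
        raise ValueError(f"scans for different traits: {sorted(traits)}")
    trait = scans[0].trait
    cfg = scans[0].config
    window_mb = cfg.window_mb if window_mb is None else window_mb
    require_same_allele = (
        cfg.require_same_allele if require_same_allele is None else require_same_allele
    )

    hits = []
    for si, scan in enumerate(scans):
        for rec in scan.records:
            if rec.get("fdr_reject"):
                hits.append(
                    {
                        "scan": si,
                        "cohort": scan.cohort_name,
                        "marker": rec["marker"],
                        "chromosome": rec["chromosome"],
                        "position_bp": rec["position_bp"],
                        "allele": rec.get("high_pd_allele"),
                        "record": rec,
                    }
                )

    loci = []
    contrast_pairs = []
    window_bp = window_mb * 1e6
    by_chrom: dict[str, list[dict]] = {}
    for h in hits:
        by_chrom.setdefault(h["chromosome"], []).append(h)

    clusters = []
    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        chrom_hits = sorted(by_chrom[chrom], key=lambda h: h["position_bp"])
        cluster = [chrom_hits[0]]
        for h in chrom_hits[1:]:
            if h["position_bp"] - cluster[-1]["position_bp"] <= window_bp:
                cluster.append(h)
            else:
                clusters.append((chrom, cluster))
                cluster = [h]
        clusters.append((chrom, cluster))

    display = TRAIT_DISPLAY.get(trait, trait.upper())
    k = 0
    for chrom, cluster in clusters:
        cohorts = {h["cohort"] for h in cluster}
        if len(cohorts) < 2:
            continue
        alleles = {h["allele"] for h in cluster if h["allele"] is not None}
        if require_same_allele and len(alleles) > 1:
            contrast_pairs.append(
                {
                    "chromosome": chrom,
                    "markers": [h["marker"] for h in cluster],
                    "cohorts": sorted(cohorts),
                    "alleles": sorted(alleles),
                }
            )
            continue
        k += 1
        name = f"PD{display}{k}"
        for h in cluster:
            h["record"]["locus"] = name
        loci.append(
            {
                "locus": name,
                "chromosome": chrom,
                "bp_min": min(h["position_bp"] for h in cluster),
                "bp_max": max(h["position_bp"] for h in cluster),
                "markers": [h["marker"] for h in cluster],
                "cohorts": sorted(cohorts),
                "allele": sorted(alleles)[0] if len(alleles) == 1 else None,
            }
        )

    return {
        "loci": pd.DataFrame(loci),
        "contrast_pairs": pd.DataFrame(contrast_pairs),
    }
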