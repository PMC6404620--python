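"""Synthetic F2 intercross cohorts with dispersion (vQTL) effects.

The generator emulates the statistical structure of an all-male F2 urine
phenotyping study: ~100 markers over 19 autosomes plus X at roughly
17 cM spacing, Mendelian 1:2:1 segregation with Haldane recombination
along each chromosome, a creatinine trait, an albumin trait positively
regressed on creatinine and negatively on multilocus heterozygosity, a
genotype-dependent residual standard deviation (the vQTL effect, acting
multiplicatively), a multiplicative MLH effect on that residual SD, an
optional detection floor at zero, and per-trait missingness.

The X chromosome in all-male F2s is hemizygous: each male carries a
single maternal X allele, coded here as the corresponding homozygote
class, so X markers show only two genotype classes.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort_io import (
    Cohort,
    GenotypeMatrix,
    HET,
    HOM_P1,
    HOM_P2,
    MISSING,
    MarkerMap,
    PhenotypeTable,
)
from .dispersion import compute_mlh

log = logging.getLogger(__name__)

#: Approximate genetic lengths (cM) of the 19 mouse autosomes and X.
DEFAULT_CHROM_LENGTHS_CM: dict[str, float] = {
    "1": 98, "2": 103, "3": 82, "4": 88, "5": 90, "6": 79, "7": 89,
    "8": 76, "9": 75, "10": 77, "11": 88, "12": 64, "13": 67, "14": 66,
    "15": 59, "16": 57, "17": 61, "18": 59, "19": 57, "X": 75,
}


def haldane_r(d_cm: float | np.ndarray) -> np.ndarray:
    """Haldane map function: recombination fraction for distance d (cM)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, float) / 100.0))


@dataclass
class ChromSpec:
    name: str
    length_cm: float
    positions_cm: list[float]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_cm, float)
        if len(pos) < 1:
            raise ValueError(f"chromosome {self.name} needs >= 1 marker")
        if (pos < 0).any() or (pos > self.length_cm).any():
            raise ValueError(f"marker positions outside [0, {self.length_cm}] on {self.name}")
        if not (np.diff(pos) >= 0).all():
            raise ValueError(f"marker positions not sorted on {self.name}")


@dataclass
class SimMapSpec:
    """Chromosomes with marker positions; synthetic bp = cM * bp_per_cm."""

    chromosomes: list[ChromSpec]
    bp_per_cm: float = 2e6

    def marker_map(self) -> MarkerMap:
        rows = []
        for chrom in self.chromosomes:
            for k, cm in enumerate(chrom.positions_cm):
                rows.append(
                    {
                        "marker": f"m{chrom.name}_{k:02d}",
                        "chromosome": chrom.name,
                        "position_bp": int(round(cm * self.bp_per_cm)) + 3_000_000,
                        "position_cm": float(cm),
                    }
                )
        df = pd.DataFrame(rows).set_index("marker")
        return MarkerMap(df)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.marker_map().marker_ids)


def default_map(spacing_cm: float = 17.0, include_x: bool = True) -> SimMapSpec:
    """~100 evenly spaced markers over the 19 autosomes (+X)."""
    chroms = []
    for name, length in DEFAULT_CHROM_LENGTHS_CM.items():
        if name == "X" and not include_x:
            continue
        positions = list(np.arange(0.0, length + 1e-9, spacing_cm))
        chroms.append(ChromSpec(name=name, length_cm=length, positions_cm=positions))
    return SimMapSpec(chromosomes=chroms)


def small_map(
    n_chrom: int = 3, markers_per_chrom: int = 6, spacing_cm: float = 15.0
) -> SimMapSpec:
    """Compact autosome-only map for fast tests."""
    chroms = [
        ChromSpec(
            name=str(i + 1),
            length_cm=spacing_cm * (markers_per_chrom - 1),
            positions_cm=[spacing_cm * k for k in range(markers_per_chrom)],
        )
        for i in range(n_chrom)
    ]
    return SimMapSpec(chromosomes=chroms)


#: Dominance presets: residual-SD multiplier per (CC, CA, AA) class given
#: a sigma ratio rho and the high-dispersion side ("P1" or "P2").
def _preset_sigmas(preset: str, rho: float, high_allele: str) -> tuple[float, ...]:
    hi, lo = rho, 1.0
    flip = high_allele == "P1"
    patterns = {
        "null": (lo, lo, lo),
        "additive": (lo, (lo + hi) / 2.0, hi),
        "D+": (lo, hi, hi),
        "D-": (lo, lo, hi),
        "OD": (lo, hi, lo),
        "UD": (hi, lo, hi),
    }
    if preset not in patterns:
        raise ValueError(f"unknown architecture preset {preset!r}")
    pat = patterns[preset]
    return tuple(reversed(pat)) if flip else pat


@dataclass
class VqtlEffect:
    """One locus effect: mean shifts and residual-SD factors per class."""

    marker_id: str
    mean_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sigma: tuple[float, float, float] = (1.0, 1.0, 1.0)
    preset: str | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma):
            raise ValueError("sigma factors must be positive")

    @classmethod
    def from_preset(
        cls,
        marker_id: str,
        preset: str,
        sigma_ratio: float = 2.0,
        high_allele: str = "P2",
    ) -> "VqtlEffect":
        return cls(
            marker_id=marker_id,
            sigma=_preset_sigmas(preset, sigma_ratio, high_allele),
            preset=preset,
        )


@dataclass
class SimConfig:
    """Cohort-level generative parameters.

    Defaults emulate a ~300-male F2 urine study: creatinine mean 76
    mg/dl (SD 20), albumin regressed on creatinine with slope 0.013 and
    on MLH with slope -4.87 so the cohort albumin mean lands near 0.7
    mg/dl, base residual SD 0.5 mg/dl, a negative multiplicative MLH
    effect on residual SD (log-slope -2), a detection floor at 0 for
    albumin, and modest per-trait and genotype missingness.
    """

    n: int = 300
    ucrea_mean: float = 76.0
    ucrea_sd: float = 20.0
    ualb_intercept: float = 2.17
    ucrea_slope: float = 0.013
    mlh_ualb_slope: float = -4.87
    mlh_disp_slope: float = -2.0
    base_sigma: float = 0.5
    detection_floor: bool = True
    missing_ualb: float = 0.05
    missing_ucrea: float = 0.01
    geno_missing: float = 0.02
    include_bun: bool = False
    bun_mean: float = 20.4
    bun_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("n must be >= 10")
        for name in ("missing_ualb", "missing_ucrea", "geno_missing"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")


def _simulate_gametes(
    positions_cm: np.ndarray, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """Gamete haplotypes along one chromosome (0 = P1 allele, 1 = P2).

    Markov chain with Haldane recombination between adjacent markers, no
    interference; d = 0 between markers copies the allele exactly.
    """
    k = len(positions_cm)
    out = np.empty((n_gametes, k), dtype=np.int8)
    out[:, 0] = rng.random(n_gametes) < 0.5
    r = haldane_r(np.diff(positions_cm))
    for j in range(1, k):
        flip = rng.random(n_gametes) < r[j - 1]
        out[:, j] = np.where(flip, 1 - out[:, j - 1], out[:, j - 1])
    return out


def simulate_f2_genotypes(
    map_spec: SimMapSpec,
    n: int,
    seed: int | np.random.Generator = 0,
    geno_missing: float = 0.0,
) -> GenotypeMatrix:
    """F2 genotypes: two independent gametes per individual per autosome.

    X markers (chromosome name "X") receive a single maternal gamete and
    are coded as the matching homozygote class (hemizygous males).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blocks = []
    names = []
    for chrom in map_spec.chromosomes:
        pos = np.asarray(chrom.positions_cm, float)
        if chrom.name == "X":
            g = 2 * _simulate_gametes(pos, n, rng)  # 0 or 2
        else:
            g = _simulate_gametes(pos, n, rng) + _simulate_gametes(pos, n, rng)
        blocks.append(g.astype(np.int8))
        names.extend(f"m{chrom.name}_{k:02d}" for k in range(len(pos)))
    geno = np.concatenate(blocks, axis=1)
    if geno_missing > 0:
        mask = rng.random(geno.shape) < geno_missing
        geno = np.where(mask, MISSING, geno).astype(np.int8)
    ids = [f"ind{i:04d}" for i in range(n)]
    return GenotypeMatrix(
        pd.DataFrame(geno, index=pd.Index(ids, name="id"), columns=names)
    )


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    effects: list[VqtlEffect],
    config: SimConfig,
    seed: int | np.random.Generator = 0,
    true_genotypes: GenotypeMatrix | None = None,
) -> PhenotypeTable:
    """Draw creatinine, then albumin with vQTL residual-SD structure.

    ``true_genotypes`` (pre-missingness) can be supplied so effect
    lookups never hit a missing cell; missing effect genotypes otherwise
    fall back to the heterozygote class.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(genotypes.individuals)
    src = true_genotypes or genotypes
    mlh = compute_mlh(genotypes).to_numpy()
    mlh_centred = np.nan_to_num(mlh - 0.5, nan=0.0)

    ucrea = rng.normal(config.ucrea_mean, config.ucrea_sd, n)
    ucrea = np.maximum(ucrea, 0.0)

    mean = (
        config.ualb_intercept
        + config.ucrea_slope * ucrea
        + config.mlh_ualb_slope * np.nan_to_num(mlh, nan=0.5)
    )
    sd = np.full(n, config.base_sigma) * np.exp(config.mlh_disp_slope * mlh_centred)
    for eff in effects:
        g = src.column(eff.marker_id).copy()
        g[g == MISSING] = HET
        mean = mean + np.asarray(eff.mean_shift)[g]
        sd = sd * np.asarray(eff.sigma)[g]
    ualb = mean + rng.normal(0.0, 1.0, n) * sd
    if config.detection_floor:
        ualb = np.maximum(ualb, 0.0)

    data = {"ualb": ualb, "ucrea": ucrea}
    if config.include_bun:
        data["bun"] = np.maximum(rng.normal(config.bun_mean, config.bun_sd, n), 0.0)

    df = pd.DataFrame(data, index=genotypes.individuals)
    for trait, rate in (("ualb", config.missing_ualb), ("ucrea", config.missing_ucrea)):
        if rate > 0:
            df.loc[rng.random(n) < rate, trait] = np.nan
    return PhenotypeTable(df)


def simulate_cohort(
    map_spec: SimMapSpec | None = None,
    effects: list[VqtlEffect] | None = None,
    config: SimConfig | None = None,
    seed: int = 0,
    name: str = "synthetic",
    strains: tuple[str, str] = ("C57BL/6J", "A/J"),
) -> tuple[Cohort, dict]:
    """Generate a full cohort plus a truth record for recovery scoring."""
    map_spec = map_spec or default_map()
    effects = effects or []
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    true_geno = simulate_f2_genotypes(map_spec, config.n, rng, geno_missing=0.0)
    true_geno = GenotypeMatrix(true_geno.data, strains=strains)
    if config.geno_missing > 0:
        mask = rng.random(true_geno.data.shape) < config.geno_missing
        observed = np.where(mask, MISSING, true_geno.data.to_numpy()).astype(np.int8)
        geno = GenotypeMatrix(
            pd.DataFrame(observed, index=true_geno.individuals, columns=true_geno.markers),
            strains=strains,
        )
    else:
        geno = true_geno
    pheno = simulate_phenotypes(geno, effects, config, rng, true_genotypes=true_geno)
    cohort = Cohort(
        name=name,
        genotypes=geno,
        phenotypes=pheno,
        map=map_spec.marker_map(),
        map_build=f"synthetic-bp{int(map_spec.bp_per_cm)}",
    )
    truth = {
        "seed": seed,
        "config": asdict(config),
        "effects": [asdict(e) for e in effects],
    }
    return cohort, truth


def adjacent_markers(map_spec: SimMapSpec, marker_id: str) -> set[str]:
    """The marker itself plus its immediate map neighbors on its chromosome."""
    mm = map_spec.marker_map().sorted().table
    chrom = mm.loc[marker_id, "chromosome"]
    on_chrom = mm[mm["chromosome"] == chrom].index.tolist()
    i = on_chrom.index(marker_id)
    return set(on_chrom[max(i - 1, 0): i + 2])


def recovery_suite(
    scenarios: list[dict],
    replicates: int,
    seed: int,
    run_config=None,
    map_spec: SimMapSpec | None = None,
    trait: str = "ualb",
) -> pd.DataFrame:
    """Run scans over simulated scenarios and score recovery.

    Each scenario dict: {"name", "effects" (list of VqtlEffect),
    "config" (SimConfig, optional)}.  Reports per scenario the nominal
    joint-test rejection rate, FDR-level any-rejection rate, the rate at
    which the top marker is the causal marker or an immediate neighbor,
    architecture-label counts at the causal marker, and the mean
    estimated sigma ratio (residual-SD ratio, high class over low).
    """
    from .config import RunConfig
    from .scan import scan_trait

    run_config = run_config or RunConfig()
    map_spec = map_spec or default_map()
    ss = np.random.SeedSequence(seed)
    rows = []
    for scen in scenarios:
        effects = scen.get("effects", [])
        cfg = scen.get("config", SimConfig())
        causal = effects[0].marker_id if effects else None
        near = adjacent_markers(map_spec, causal) if causal else set()
        child_seeds = ss.spawn(replicates)
        n_tests = n_nominal = 0
        fdr_any = 0
        top_near = 0
        label_counts: dict[str, int] = {}
        sigma_ratios = []
        for cs in child_seeds:
            rep_seed = int(cs.generate_state(1)[0] % (2**31 - 1))
            cohort, _ = simulate_cohort(map_spec, effects, cfg, seed=rep_seed)
            scan = scan_trait(cohort, trait, run_config)
            tab = scan.as_frame()
            n_tests += len(tab)
            n_nominal += int((tab["p_joint"] < 0.05).sum())
            fdr_any += int(tab["fdr_reject"].any())
            if causal is not None and len(tab):
                top = tab.loc[tab["p_joint"].idxmin(), "marker"]
                top_near += int(top in near)
                row = tab[tab["marker"] == causal]
                if len(row):
                    forms = row.iloc[0]["forms"]
                    key = "+".join(sorted(forms)) if forms else "none"
                    label_counts[key] = label_counts.get(key, 0) + 1
                sigma_ratios.append(
                    _sigma_ratio_estimate(cohort, causal, trait)
                )
        rows.append(
            {
                "scenario": scen.get("name", "unnamed"),
                "replicates": replicates,
                "nominal_rejection_rate": n_nominal / max(n_tests, 1),
                "fdr_any_rate": fdr_any / replicates,
                "top_near_causal_rate": (top_near / replicates) if causal else np.nan,
                "label_counts": json.dumps(label_counts, sort_keys=True),
                "modal_labels": max(label_counts, key=label_counts.get)
                if label_counts
                else "",
                "mean_sigma_ratio": float(np.mean(sigma_ratios))
                if sigma_ratios
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _sigma_ratio_estimate(cohort: Cohort, marker: str, trait: str) -> float:
    """Residual-SD ratio at a marker: max over min homozygote-class SD.

    The trait is first residualized on the locus-containing covariate
    model (genotype class + MLH + creatinine where applicable) so the
    class-wise residual SDs estimate the generative sigma contrast.
    """
    from .dispersion import CovariateModelSpec, fit_covariate_model

    spec = CovariateModelSpec(
        trait=trait,
        include_locus=marker,
        include_mlh=True,
        include_ucrea=(trait == "ualb" and cohort.phenotypes.available("ucrea")),
    )
    fit = fit_covariate_model(cohort, spec)
    resid = pd.Series(fit.resid, index=fit.index)
    g = pd.Series(cohort.genotypes.column(marker), index=cohort.genotypes.individuals)
    sds = {}
    for cls in (HOM_P1, HOM_P2):
        vals = resid[g.loc[resid.index] == cls]
        if len(vals) > 2:
            sds[cls] = float(vals.std())
    if len(sds) < 2 or min(sds.values()) == 0:
        return np.nan
    return max(sds.values()) / min(sds.values())
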