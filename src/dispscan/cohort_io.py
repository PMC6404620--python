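"""Cohort file I/O and validation.

A mapping cohort bundles three delimited text tables: a genotype matrix
(individuals x markers, three-class F2 codes plus missing), a phenotype
table (urinary albumin and creatinine in mg/dl, optionally BUN and body
weight), and a marker map (chromosome, base-pair and centiMorgan
positions).  Genotype code dictionaries vary between archives, so the
mapping from file codes to the three genotype classes is configuration
supplied by the caller, never inferred.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# Genotype class codes (int8).  P1/P2 are the two parental strains; an F2
# individual is HOM_P1, HET or HOM_P2 at each autosomal marker.
HOM_P1: int = 0
HET: int = 1
HOM_P2: int = 2
MISSING: int = -1

#: Default file-code dictionary: "A" = P1 homozygote, "H" = heterozygote,
#: "B" = P2 homozygote (the R/qtl-style convention).
DEFAULT_GENOTYPE_CODES: dict[str, int] = {"A": HOM_P1, "H": HET, "B": HOM_P2}
DEFAULT_MISSING_CODES: tuple[str, ...] = ("-", "", "NA", "N", "nan")

TRAITS: tuple[str, ...] = ("ualb", "ucrea", "bun", "weight")

VALID_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 20)) + ("X",)


class CohortValidationError(ValueError):
    """Raised when a cohort table violates a structural invariant."""


def chromosome_sort_key(chrom: str) -> tuple[int, int]:
    """Order autosomes numerically with X last."""
    c = str(chrom)
    return (0, int(c)) if c.isdigit() else (1, 0)


@dataclass
class MarkerMap:
    """Marker positions on a physical (bp) and genetic (cM) map.

    ``table`` is indexed by marker id with columns ``chromosome`` (str),
    ``position_bp`` (int) and ``position_cm`` (float).  Positions must be
    strictly increasing within each chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chromosome", "position_bp", "position_cm"}
        if not required.issubset(t.columns):
            raise CohortValidationError(
                f"marker map missing columns {sorted(required - set(t.columns))}"
            )
        if t.index.duplicated().any():
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise CohortValidationError(f"duplicated marker ids in map: {dups}")
        if (t["position_bp"] < 0).any():
            raise CohortValidationError("negative base-pair positions in map")
        t["chromosome"] = t["chromosome"].astype(str)
        t["position_bp"] = t["position_bp"].astype(np.int64)
        t["position_cm"] = t["position_cm"].astype(float)
        for chrom, grp in t.groupby("chromosome", sort=False):
            pos = grp.sort_values("position_bp")["position_bp"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise CohortValidationError(
                    f"non-increasing bp positions on chromosome {chrom}"
                )

    @property
    def marker_ids(self) -> pd.Index:
        return self.table.index

    def sorted(self) -> "MarkerMap":
        t = self.table.copy()
        t["_ck"] = [chromosome_sort_key(c) for c in t["chromosome"]]
        t = t.sort_values(["_ck", "position_bp"]).drop(columns="_ck")
        return MarkerMap(t)


@dataclass
class GenotypeMatrix:
    """Individuals x markers matrix of int8 genotype classes.

    ``strains`` names the (P1, P2) parental strains so downstream reports
    can state which strain carries the high-dispersion allele.
    """

    data: pd.DataFrame
    strains: tuple[str, str] = ("P1", "P2")

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise CohortValidationError(f"duplicated individual ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise CohortValidationError(f"duplicated marker ids: {dups}")
        vals = self.data.to_numpy()
        ok = np.isin(vals, (HOM_P1, HET, HOM_P2, MISSING))
        if not ok.all():
            bad = np.unique(vals[~ok]).tolist()
            raise CohortValidationError(f"invalid genotype codes: {bad}")
        self.data = self.data.astype(np.int8)

    @property
    def individuals(self) -> pd.Index:
        return self.data.index

    @property
    def markers(self) -> pd.Index:
        return self.data.columns

    def column(self, marker: str) -> np.ndarray:
        return self.data[marker].to_numpy()


@dataclass
class PhenotypeTable:
    """Per-individual phenotype records; NaN marks a missing record.

    Units: ualb and ucrea in mg/dl, bun in mg/dl, weight in g.  Negative
    values are rejected (all four are physically non-negative).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise CohortValidationError(f"duplicated individual ids: {dups}")
        unknown = [c for c in self.data.columns if c not in TRAITS]
        if unknown:
            raise CohortValidationError(f"unknown phenotype columns: {unknown}")
        self.data = self.data.astype(float)
        for col in self.data.columns:
            neg = self.data[col] < 0
            if neg.any():
                raise CohortValidationError(
                    f"{int(neg.sum())} negative {col} values, e.g. individuals "
                    f"{self.data.index[neg].tolist()[:10]}"
                )

    def available(self, trait: str) -> bool:
        return trait in self.data.columns and self.data[trait].notna().any()

    def values(self, trait: str) -> pd.Series:
        if trait not in self.data.columns:
            raise KeyError(f"trait {trait!r} unavailable in this cohort")
        return self.data[trait]


@dataclass
class Cohort:
    """A named F2 mapping population: genotypes + phenotypes + map."""

    name: str
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    map: MarkerMap
    map_build: str = "synthetic"

    def __post_init__(self) -> None:
        g_ind = set(self.genotypes.individuals)
        p_ind = set(self.phenotypes.data.index)
        if g_ind != p_ind:
            only_g = sorted(g_ind - p_ind)
            only_p = sorted(p_ind - g_ind)
            raise CohortValidationError(
                "individual ids disagree between genotype and phenotype tables; "
                f"genotype-only={only_g[:10]}, phenotype-only={only_p[:10]}"
            )
        missing_in_map = [
            m for m in self.genotypes.markers if m not in set(self.map.marker_ids)
        ]
        if missing_in_map:
            raise CohortValidationError(
                f"genotyped markers absent from map: {missing_in_map[:10]}"
            )
        # align phenotype rows to genotype row order
        self.phenotypes = PhenotypeTable(
            self.phenotypes.data.loc[self.genotypes.individuals]
        )

    @property
    def n(self) -> int:
        return len(self.genotypes.individuals)

    def markers_in_map_order(self) -> list[str]:
        ordered = self.map.sorted().marker_ids
        present = set(self.genotypes.markers)
        return [m for m in ordered if m in present]


def read_cohort(
    geno_path: str | Path,
    pheno_path: str | Path,
    map_path: str | Path,
    strain_names: tuple[str, str] = ("P1", "P2"),
    genotype_codes: dict[str, int] | None = None,
    missing_codes: tuple[str, ...] = DEFAULT_MISSING_CODES,
    name: str | None = None,
    map_build: str = "synthetic",
) -> Cohort:
    """Read and validate the three cohort CSVs.

    ``genotype_codes`` maps file codes to the three classes (defaults to
    A/H/B); any code not in the dictionary or in ``missing_codes`` becomes
    MISSING with a logged count.  Phenotype columns absent from the file
    simply leave that trait unavailable.
    """
    codes = dict(DEFAULT_GENOTYPE_CODES if genotype_codes is None else genotype_codes)

    geno_raw = pd.read_csv(geno_path, dtype=str).set_index("id")
    geno_raw.index = geno_raw.index.astype(str)
    mapped = pd.DataFrame(index=geno_raw.index, columns=geno_raw.columns, dtype=float)
    unmappable = 0
    declared_missing = 0
    for col in geno_raw.columns:
        s = geno_raw[col].astype(str).str.strip()
        out = s.map(codes)
        is_missing = s.isin(missing_codes) | geno_raw[col].isna()
        declared_missing += int(is_missing.sum())
        unknown = out.isna() & ~is_missing
        unmappable += int(unknown.sum())
        out[out.isna()] = MISSING
        mapped[col] = out
    if declared_missing:
        log.warning("%d genotype cells carry a declared missing code", declared_missing)
    if unmappable:
        log.warning("%d unmappable genotype codes set to MISSING", unmappable)
    genotypes = GenotypeMatrix(mapped.astype(np.int8), strains=tuple(strain_names))

    pheno_raw = pd.read_csv(pheno_path).set_index("id")
    pheno_raw.index = pheno_raw.index.astype(str)
    keep = [c for c in pheno_raw.columns if c in TRAITS]
    dropped = [c for c in pheno_raw.columns if c not in TRAITS]
    if dropped:
        log.info("ignoring phenotype columns %s", dropped)
    phenotypes = PhenotypeTable(pheno_raw[keep])

    map_raw = pd.read_csv(map_path).set_index("marker")
    map_raw.index = map_raw.index.astype(str)
    marker_map = MarkerMap(
        map_raw.rename(
            columns={"chr": "chromosome", "bp": "position_bp", "cm": "position_cm"}
        )
    )

    return Cohort(
        name=name or Path(geno_path).stem,
        genotypes=genotypes,
        phenotypes=phenotypes,
        map=marker_map,
        map_build=map_build,
    )


def write_cohort(cohort: Cohort, out_prefix: str | Path) -> dict[str, Path]:
    """Write geno/pheno/map CSVs with the default A/H/B code dictionary."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    inv = {HOM_P1: "A", HET: "H", HOM_P2: "B", MISSING: "-"}

    geno = cohort.genotypes.data.replace(inv)
    geno.index.name = "id"
    geno_path = prefix.with_name(prefix.name + "_geno.csv")
    geno.to_csv(geno_path)

    pheno = cohort.phenotypes.data.copy()
    pheno.index.name = "id"
    pheno_path = prefix.with_name(prefix.name + "_pheno.csv")
    pheno.to_csv(pheno_path)

    m = cohort.map.table.rename(
        columns={"chromosome": "chr", "position_bp": "bp", "position_cm": "cm"}
    )
    m.index.name = "marker"
    map_path = prefix.with_name(prefix.name + "_map.csv")
    m.to_csv(map_path)

    return {"geno": geno_path, "pheno": pheno_path, "map": map_path}


SCAN_COLUMNS = [
    "Chr",
    "MB",
    "cM",
    "Marker",
    "P",
    "r2",
    "Form",
    "P_arch",
    "HighPDAllele",
    "FDR_pass",
    "Locus",
    "bp",
    "n_used",
]


def write_scan_table(scan, out_path: str | Path, header_lines: list[str] | None = None):
    """Write a scan as TSV, one row per (marker, architecture-label) entry.

    Markers carrying several architecture labels (e.g. partial negative
    dominance = D- plus A) emit stacked rows sharing the marker fields.
    ``MB`` is the bp position in megabases at one decimal for display; the
    exact ``bp`` column makes the file round-trippable.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in scan.records:
        base = {
            "Chr": rec["chromosome"],
            "MB": round(rec["position_bp"] / 1e6, 1),
            "cM": rec["position_cm"],
            "Marker": rec["marker"],
            "P": rec["p_joint"],
            "r2": rec["r2"],
            "HighPDAllele": rec.get("high_pd_allele") or "",
            "FDR_pass": bool(rec.get("fdr_reject", False)),
            "Locus": rec.get("locus") or "",
            "bp": rec["position_bp"],
            "n_used": rec["n_used"],
        }
        labels = rec.get("labels") or []
        if not labels:
            rows.append({**base, "Form": "", "P_arch": ""})
        else:
            for lab in labels:
                rows.append(
                    {**base, "Form": lab["form"], "P_arch": lab["p"]}
                )
    df = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    with open(out_path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
    return out_path


def read_scan_table(path: str | Path) -> pd.DataFrame:
    """Read a scan TSV back (header comment lines skipped)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("Form", "HighPDAllele", "Locus"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df
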