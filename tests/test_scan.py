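"""End-to-end marker scans, variance explained, consensus loci."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import dispscan as ds
from dispscan.cohort_io import GenotypeMatrix, HET, HOM_P1, HOM_P2
from dispscan.config import RunConfig
from dispscan.scan import ScanTable, consensus_loci, variance_explained
from dispscan.tobit import TobitSpec, fit_tobit


class TestScanTrait:
    def test_causal_marker_is_top_hit(self, dminus_cohort):
        cohort, causal = dminus_cohort
        scan = ds.scan_trait(cohort, "ualb")
        df = scan.as_frame()
        top = df.loc[df["p_joint"].idxmin()]
        assert top["marker"] == causal
        assert top["fdr_reject"]
        assert top["r2"] > 0.02

    def test_monomorphic_marker_skipped_and_out_of_fdr(self, null_cohort):
        geno = null_cohort.genotypes.data.copy()
        mono = null_cohort.genotypes.markers[0]
        geno[mono] = HET
        cohort = ds.Cohort(
            name="x",
            genotypes=GenotypeMatrix(geno, strains=null_cohort.genotypes.strains),
            phenotypes=null_cohort.phenotypes,
            map=null_cohort.map,
        )
        scan = ds.scan_trait(cohort, "ualb")
        skipped = {s["marker"] for s in scan.skipped}
        assert mono in skipped
        tested = {r["marker"] for r in scan.records}
        assert mono not in tested

    def test_deterministic_output(self, tmp_path, null_cohort):
        cfg = RunConfig(seed=3)
        paths = []
        for k in range(2):
            scan = ds.scan_trait(null_cohort, "ualb", cfg)
            p = tmp_path / f"scan{k}.tsv"
            ds.write_scan_table(scan, p, header_lines=cfg.header_lines())
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_removing_nonsignificant_marker_keeps_per_marker_stats(self, null_cohort):
        """With heterozygosity held fixed, dropping a marker touches only
        the m-dependent FDR columns, never the other markers' statistics."""
        mlh = ds.compute_mlh(null_cohort.genotypes)
        full = ds.scan_trait(null_cohort, "ualb", mlh=mlh)
        df_full = full.as_frame()
        drop = df_full.loc[df_full["p_joint"].idxmax(), "marker"]
        geno = null_cohort.genotypes.data.drop(columns=[drop])
        cohort = ds.Cohort(
            name="x",
            genotypes=GenotypeMatrix(geno, strains=null_cohort.genotypes.strains),
            phenotypes=null_cohort.phenotypes,
            map=null_cohort.map,
        )
        sub = ds.scan_trait(cohort, "ualb", mlh=mlh).as_frame().set_index("marker")
        for _, row in df_full[df_full["marker"] != drop].iterrows():
            assert sub.loc[row["marker"], "p_joint"] == pytest.approx(
                row["p_joint"], rel=1e-12
            )

    def test_x_markers_tested_without_architecture(self, genome_map):
        cohort, _ = ds.simulate_cohort(genome_map, [], ds.SimConfig(n=250), seed=9)
        scan = ds.scan_trait(cohort, "ualb")
        df = scan.as_frame()
        x_rows = df[df["chromosome"] == "X"]
        assert len(x_rows) > 0
        assert all(f == [] for f in x_rows["forms"])

    def test_global_residualization_mode(self, null_cohort):
        cfg = RunConfig(residualization="global")
        scan = ds.scan_trait(null_cohort, "ualb", cfg)
        assert len(scan.records) > 0


class TestVarianceExplained:
    def _fit_classes(self, y, g, variant="censored", tau=-1e9):
        X = np.column_stack(
            [np.ones(len(y)), (g == HOM_P1).astype(float), (g == HET).astype(float)]
        )
        return fit_tobit(y, X, TobitSpec(tau, variant)), [1, 2]

    def test_perfect_fit_gives_one(self):
        g = np.repeat([HOM_P1, HET, HOM_P2], 20)
        y = np.select([g == HOM_P1, g == HET], [1.0, 2.0], 3.0)
        y = y + np.random.default_rng(0).normal(0, 1e-8, len(y))
        fit, cols = self._fit_classes(y, g)
        assert variance_explained(fit, cols, y) == pytest.approx(1.0, abs=1e-6)

    def test_constant_fitted_gives_zero(self):
        rng = np.random.default_rng(1)
        g = np.repeat([HOM_P1, HET, HOM_P2], 20)
        y = rng.normal(5, 1, len(g))
        fit, cols = self._fit_classes(y, g)
        fit.beta[1] = fit.beta[2] = 0.0
        assert variance_explained(fit, cols, y) == pytest.approx(0.0, abs=1e-12)

    def test_equals_ols_r2_without_censoring(self):
        """Far from the bound the Tobit r2 equals the OLS class-model R2."""
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, 300)
        y = 10.0 + 0.5 * (g == HOM_P2) + rng.normal(0, 1, 300)
        fit, cols = self._fit_classes(y, g)
        r2 = variance_explained(fit, cols, y)
        X = sm.add_constant(
            np.column_stack([(g == HOM_P1).astype(float), (g == HET).astype(float)])
        )
        assert r2 == pytest.approx(sm.OLS(y, X).fit().rsquared, abs=1e-5)


def _mk_scan(cohort_name, markers, trait="ualb", map_build="b"):
    """markers: list of (marker, chrom, bp, allele, reject)."""
    records = []
    for marker, chrom, bp, allele, reject in markers:
        records.append(
            {
                "marker": marker, "chromosome": chrom, "position_bp": bp,
                "position_cm": bp / 2e6, "n_used": 300, "p_joint": 0.001,
                "r2": 0.05, "labels": [{"form": "D-", "p": 0.001, "allele": allele}],
                "high_pd_allele": allele, "fdr_reject": reject, "locus": None,
            }
        )
    return ScanTable(
        trait=trait, cohort_name=cohort_name, records=records, skipped=[],
        config=RunConfig(), map_build=map_build,
    )


class TestConsensus:
    def test_nearby_same_allele_peaks_group(self):
        a = _mk_scan("A", [("mA", "1", 22_600_000, "A/J", True)])
        b = _mk_scan("B", [("mB", "1", 35_700_000, "A/J", True)])
        out = consensus_loci([a, b], window_mb=15.0)
        loci = out["loci"]
        assert len(loci) == 1
        assert loci.iloc[0]["locus"] == "PDUAlb1"
        assert a.records[0]["locus"] == "PDUAlb1"

    def test_distant_peaks_do_not_group(self):
        a = _mk_scan("A", [("mA", "1", 10_000_000, "A/J", True)])
        b = _mk_scan("B", [("mB", "1", 60_000_000, "A/J", True)])
        out = consensus_loci([a, b], window_mb=10.0)
        assert len(out["loci"]) == 0

    def test_opposite_alleles_become_contrast_pair(self):
        a = _mk_scan("A", [("mA", "15", 92_000_000, "A/J", True)])
        b = _mk_scan("B", [("mB", "15", 93_000_000, "C57BL/6J", True)])
        out = consensus_loci([a, b], window_mb=10.0, require_same_allele=True)
        assert len(out["loci"]) == 0
        assert len(out["contrast_pairs"]) == 1

    def test_single_cohort_hits_never_form_locus(self):
        a = _mk_scan("A", [("mA", "2", 10_000_000, "A/J", True),
                           ("mA2", "2", 12_000_000, "A/J", True)])
        b = _mk_scan("B", [("mB", "7", 50_000_000, "A/J", True)])
        out = consensus_loci([a, b], window_mb=10.0)
        assert len(out["loci"]) == 0

    def test_loci_numbered_by_position(self):
        a = _mk_scan("A", [("m1", "1", 20_000_000, "A/J", True),
                           ("m8", "8", 40_000_000, "A/J", True)])
        b = _mk_scan("B", [("n1", "1", 25_000_000, "A/J", True),
                           ("n8", "8", 44_000_000, "A/J", True)])
        out = consensus_loci([a, b], window_mb=10.0)
        assert out["loci"]["locus"].tolist() == ["PDUAlb1", "PDUAlb2"]

    def test_mismatched_map_builds_rejected(self):
        a = _mk_scan("A", [("mA", "1", 1_000_000, "A/J", True)], map_build="b1")
        b = _mk_scan("B", [("mB", "1", 2_000_000, "A/J", True)], map_build="b2")
        with pytest.raises(ValueError, match="map builds"):
            consensus_loci([a, b])

    def test_requires_two_scans(self):
        a = _mk_scan("A", [("mA", "1", 1_000_000, "A/J", True)])
        with pytest.raises(ValueError, match="two scans"):
            consensus_loci([a])
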