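import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from phosphonet.errors import ParameterError, SchemaError, ValidationError
from phosphonet.quant import (
    COMPARISONS,
    PhosphoPeptideRecord,
    build_hc_dataset,
    build_qp_dataset,
    classify_regulation,
    hc_qp_protein_overlap,
    load_quant_table,
    parse_sites,
    select_significant_sites,
    significance_b,
    strict_filter,
    summarise_comparison,
)
from phosphonet.synthetic import SyntheticSpec, gen_quant_table

from conftest import make_summary


def rec(protein="P1", sites=((10, "S"),), replicate=1, fdr=0.005, context=None, **intens):
    intensities = {"WT": 100.0, "WT_FGF": 100.0, "FUS": 100.0, "FUS_FGF": 100.0}
    intensities.update(intens)
    intensities = {k: v for k, v in intensities.items() if v is not None}
    return PhosphoPeptideRecord(
        peptide_id=f"{protein}-{replicate}",
        protein_accession=protein,
        gene_symbol=protein,
        sites=list(sites),
        replicate_id=replicate,
        intensities=intensities,
        id_fdr=fdr,
        total_intensity=sum(intensities.values()),
        context=context,
    )


class TestLoadQuantTable:
    def test_identity_row_count(self, quant_table_path):
        records = load_quant_table(quant_table_path)
        assert len(records) == 10

    def test_single_site_parse(self, tmp_path):
        df = pd.DataFrame(
            [
                {
                    "peptide_id": "p1",
                    "protein": "HGS",
                    "gene": "HGS",
                    "sites": "Y132",
                    "replicate": 1,
                    "WT": 1.0,
                    "WT_FGF": 1.0,
                    "FUS": 2.0,
                    "FUS_FGF": 2.0,
                    "id_fdr": 0.001,
                }
            ]
        )
        path = tmp_path / "q.tsv"
        df.to_csv(path, sep="\t", index=False)
        (record,) = load_quant_table(path)
        assert record.sites == [(132, "Y")]
        assert record.site_key == "HGS(Y132)"

    def test_invalid_residue_names_row(self, tmp_path):
        df = pd.DataFrame(
            [
                {
                    "peptide_id": "p1",
                    "protein": "X",
                    "gene": "X",
                    "sites": "A70",
                    "replicate": 1,
                    "WT": 1.0,
                    "WT_FGF": 1.0,
                    "FUS": 1.0,
                    "FUS_FGF": 1.0,
                    "id_fdr": 0.001,
                }
            ]
        )
        path = tmp_path / "q.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError, match="row 1"):
            load_quant_table(path)

    def test_missing_column_named(self, tmp_path):
        df = pd.DataFrame([{"peptide_id": "p1", "protein": "X"}])
        path = tmp_path / "q.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="sites"):
            load_quant_table(path)

    def test_missing_cells_become_missing(self, tmp_path):
        df = pd.DataFrame(
            [
                {
                    "peptide_id": "p1",
                    "protein": "X",
                    "gene": "X",
                    "sites": "S5",
                    "replicate": 1,
                    "WT": 1.0,
                    "WT_FGF": np.nan,
                    "FUS": 2.0,
                    "FUS_FGF": 2.0,
                    "id_fdr": 0.001,
                }
            ]
        )
        path = tmp_path / "q.tsv"
        df.to_csv(path, sep="\t", index=False)
        (record,) = load_quant_table(path)
        assert "WT_FGF" not in record.intensities


class TestSiteParsing:
    def test_multi_site(self):
        assert parse_sites("T401/S405") == [(401, "T"), (405, "S")]

    def test_unparsable(self):
        with pytest.raises(ValidationError):
            parse_sites("notasite")

    def test_positions_must_increase(self):
        with pytest.raises(ValidationError):
            rec(sites=((405, "S"), (401, "T")))


class TestDatasets:
    def test_hc_threshold(self):
        records = [rec(fdr=0.005), rec(fdr=0.03)]
        kept = build_hc_dataset(records, hc_fdr=0.01)
        assert [r.id_fdr for r in kept] == [0.005]

    def test_hc_empty(self):
        assert build_hc_dataset([]) == []

    def test_hc_derived_count(self):
        # oracle: direct filter over a list with known fdr values
        fdrs = [0.001 * (i % 25 + 1) for i in range(100)]  # 40 values <= 0.010
        expected = sum(1 for f in fdrs if f <= 0.01)
        assert expected == 40
        records = [rec(protein=f"P{i}", fdr=f) for i, f in enumerate(fdrs)]
        assert len(build_hc_dataset(records, 0.01)) == expected

    def test_qp_keeps_complete_record(self):
        assert len(build_qp_dataset([rec(fdr=0.03)])) == 1

    def test_qp_drops_incomplete_channels(self):
        assert build_qp_dataset([rec(fdr=0.03, WT=None)]) == []

    def test_qp_drops_high_fdr(self):
        assert build_qp_dataset([rec(fdr=0.06)]) == []


class TestSummarise:
    def test_constant_replicates(self):
        records = [
            rec(replicate=1, FUS=200.0, WT=100.0),
            rec(replicate=2, FUS=200.0, WT=100.0),
        ]
        (s,) = summarise_comparison(records, COMPARISONS["C1"])
        assert s.mu == pytest.approx(1.0)
        assert s.sigma == 0.0

    def test_equal_channels_mu_zero(self):
        (s,) = summarise_comparison([rec(), rec(replicate=2)], COMPARISONS["C1"])
        assert s.mu == 0.0

    def test_three_replicates_hand_arithmetic(self):
        ratios = [1.6, 2.1, 1.9]
        records = [
            rec(replicate=i + 1, FUS=100.0 * r, WT=100.0) for i, r in enumerate(ratios)
        ]
        (s,) = summarise_comparison(records, COMPARISONS["C1"])
        expected = sum(math.log2(r) for r in ratios) / 3  # hand oracle
        assert s.mu == pytest.approx(expected, abs=1e-12)
        assert s.n_replicates == 3

    def test_missing_channel_skipped(self):
        records = [rec(replicate=1, FUS=200.0), rec(replicate=2, FUS=None)]
        (s,) = summarise_comparison(records, COMPARISONS["C1"])
        assert s.n_replicates == 1

    def test_all_channels_equal_gives_mu_zero_everywhere(self):
        records = [rec(protein=f"P{i}", replicate=j) for i in range(5) for j in (1, 2)]
        for comp in COMPARISONS.values():
            for s in summarise_comparison(records, comp):
                assert s.mu == 0.0


class TestClassifyRegulation:
    @pytest.mark.parametrize(
        "mu,expected",
        [(0.5, "up"), (-0.5, "down"), (0.49, "unchanged"), (-0.49, "unchanged"), (2.0, "up")],
    )
    def test_thresholds_inclusive(self, mu, expected):
        assert classify_regulation(make_summary(mu)) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ParameterError):
            classify_regulation(make_summary(0.0), threshold=-0.1)

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        mus = rng.normal(0, 1, 500)
        labels = [classify_regulation(make_summary(m)) for m in mus]
        flipped = [classify_regulation(make_summary(-m)) for m in mus]
        assert labels.count("up") == flipped.count("down")
        assert labels.count("down") == flipped.count("up")


class TestStrictFilter:
    def test_single_replicate_always_fails(self):
        assert not strict_filter(make_summary(5.0, sigma=0.0, n=1))

    def test_ci_excludes_zero(self):
        # [0.8 - 1.96*0.1, 0.8 + 1.96*0.1] = [0.604, 0.996]
        assert strict_filter(make_summary(0.8, sigma=0.1, n=3))

    def test_ci_includes_zero(self):
        # [0.3 - 1.96*0.2, 0.3 + 1.96*0.2] = [-0.092, 0.692]
        assert not strict_filter(make_summary(0.3, sigma=0.2, n=2))

    def test_strict_implies_multireplicate(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            s = make_summary(
                rng.normal(), sigma=abs(rng.normal(0, 0.3)), n=int(rng.integers(1, 4))
            )
            if strict_filter(s):
                assert s.n_replicates >= 2


class TestSignificanceB:
    def test_median_site_gets_half(self):
        rng = np.random.default_rng(0)
        mus = list(rng.normal(0, 1, 101))
        med = float(np.median(mus))
        summaries = [
            make_summary(m, site_key=f"P{i}(S1)", mean_total_intensity=1e6)
            for i, m in enumerate(mus)
        ]
        significance_b(summaries, bin_size=300)
        at_median = [s for s in summaries if s.mu == med]
        assert at_median and at_median[0].sigb_p == pytest.approx(0.5)

    def test_extreme_site_smallest_p(self):
        rng = np.random.default_rng(1)
        summaries = [
            make_summary(m, site_key=f"P{i}(S1)") for i, m in enumerate(rng.normal(0, 1, 400))
        ]
        significance_b(summaries, bin_size=500)
        top = max(summaries, key=lambda s: s.mu)
        assert top.sigb_p == min(s.sigb_p for s in summaries)

    def test_null_uniform(self):
        rng = np.random.default_rng(11)
        summaries = [
            make_summary(
                float(m),
                site_key=f"P{i}(S1)",
                mean_total_intensity=float(t),
            )
            for i, (m, t) in enumerate(
                zip(rng.normal(0, 0.5, 10_000), rng.lognormal(14, 1, 10_000))
            )
        ]
        significance_b(summaries, bin_size=300)
        pvals = np.array([s.sigb_p for s in summaries])
        assert kstest(pvals, "uniform").statistic < 0.02

    def test_degenerate_bin(self):
        # 20 identical values pin the median and both spread percentiles to 0
        summaries = [make_summary(0.0, site_key=f"P{i}(S1)") for i in range(20)]
        summaries.append(make_summary(1.0, site_key="PX(S1)"))
        significance_b(summaries, bin_size=300)
        assert summaries[0].sigb_p == 1.0  # at the (degenerate) median
        assert summaries[-1].sigb_p is None  # undefined off-median

    def test_bad_bin_size(self):
        with pytest.raises(ParameterError):
            significance_b([make_summary(0.0)], bin_size=0)


class TestSelectSignificantSites:
    def test_planted_recovery(self, tmp_path):
        spec = SyntheticSpec(
            seed=5,
            n_sites=200,
            n_proteins=200,
            n_regulated_per_comparison=12,
            effect_log2=1.0,
            replicate_cv=0.1,
            n_replicates=3,
            hc_fraction=1.0,
            qp_only_fraction=0.0,
        )
        table, truth = gen_quant_table(spec, comparisons=("C1",))
        path = tmp_path / "q.tsv"
        table.to_csv(path, sep="\t", index=False)
        records = load_quant_table(path)
        hc = build_hc_dataset(records)
        summaries = summarise_comparison(hc, COMPARISONS["C1"])
        significance_b(summaries)
        selected = select_significant_sites(summaries)
        selected_keys = {s.site_key: s.regulation for s in selected}
        expected = dict(zip(truth["site_key"], truth["direction"]))
        assert set(expected) <= set(selected_keys)
        for key, direction in expected.items():
            assert selected_keys[key] == direction

    def test_empty_when_nothing_passes(self):
        assert select_significant_sites([make_summary(0.1, sigma=0.01, n=3)]) == []

    def test_threshold_excludes_mild_effect(self):
        # passes the CI criterion but |mu| < 0.5
        s = make_summary(0.4, sigma=0.05, n=3)
        assert select_significant_sites([s]) == []

    def test_sorted_by_abs_mu(self):
        a = make_summary(0.6, sigma=0.05, n=3, site_key="A(S1)")
        b = make_summary(-1.2, sigma=0.05, n=3, site_key="B(S1)")
        out = select_significant_sites([a, b])
        assert [s.site_key for s in out] == ["B(S1)", "A(S1)"]


class TestOverlap:
    def test_identical(self):
        records = [rec(protein=p) for p in "ABC"]
        assert hc_qp_protein_overlap(records, records) == pytest.approx(100.0)

    def test_disjoint(self):
        a = [rec(protein="A")]
        b = [rec(protein="B")]
        assert hc_qp_protein_overlap(a, b) == pytest.approx(0.0)

    def test_hand_enumeration(self):
        hc = [rec(protein=p) for p in "ABC"]
        qp = [rec(protein=p) for p in "BCD"]
        # |{B,C}| / |{A,B,C,D}| = 2/4
        assert hc_qp_protein_overlap(hc, qp) == pytest.approx(50.0)
        # HC denominator: 2/3
        assert hc_qp_protein_overlap(hc, qp, denominator="hc") == pytest.approx(200 / 3)

    def test_both_empty_undefined(self):
        assert hc_qp_protein_overlap([], []) is None
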