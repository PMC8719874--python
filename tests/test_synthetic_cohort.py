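"""Statistical structure and determinism of the cohort simulator."""

import numpy as np
import pytest
from scipy import stats

from trioburden.genome import toy_genome
from trioburden.rate_model import geneset_expected
from trioburden.synthetic_cohort import (
    CohortConfig,
    read_cohort,
    simulate_cohort,
    write_cohort,
)
from trioburden.variant_io import Genotype


def lean_config(**kwargs) -> CohortConfig:
    """Events-only configuration (no background/noise) for speed."""
    defaults = dict(
        mean_background_het_per_trio=0.0,
        mean_qualifying_het_per_trio=0.0,
        mean_biallelic_opportunities_per_trio=0.0,
        noise_sites_per_trio=0,
    )
    defaults.update(kwargs)
    return CohortConfig(**defaults)


class TestConfigValidation:
    def test_zero_trios_rejected(self):
        with pytest.raises(ValueError, match="at least one trio"):
            simulate_cohort(CohortConfig(n_case_trios=0, n_control_trios=0))

    def test_unknown_enriched_gene_rejected(self, toy_genes, calibrated_table):
        config = CohortConfig(enriched_geneset=("NOT_A_GENE",))
        with pytest.raises(ValueError, match="unknown genes"):
            simulate_cohort(config, genes=toy_genes, rate_table=calibrated_table)

    @pytest.mark.parametrize(
        "field,value",
        [("mosaic_fraction", 1.5), ("transmission_bias", -0.1),
         ("nonsyn_enrichment_factor", 0.5), ("mean_coding_snv_dnms_per_trio", -1.0)],
    )
    def test_out_of_range_parameters(self, field, value):
        with pytest.raises(ValueError):
            CohortConfig(**{field: value}).validate()


def test_zero_rates_give_empty_truth(toy_genes, calibrated_table):
    config = lean_config(
        n_case_trios=20, n_control_trios=0,
        mean_coding_snv_dnms_per_trio=0.0, mean_coding_indel_dnms_per_trio=0.0,
        mosaic_fraction=0.0, seed=4,
    )
    cohort = simulate_cohort(config, genes=toy_genes, rate_table=calibrated_table)
    assert cohort.truth.empty
    assert all(len(r) == 0 for r in cohort.records.values())


def test_same_seed_is_reproducible(toy_genes, calibrated_table):
    config = lean_config(n_case_trios=15, n_control_trios=5, seed=9)
    a = simulate_cohort(config, genes=toy_genes, rate_table=calibrated_table)
    b = simulate_cohort(config, genes=toy_genes, rate_table=calibrated_table)
    assert a.truth.equals(b.truth)
    assert a.records == b.records
    assert a.annotations.equals(b.annotations)


def test_dnm_count_mean_converges(toy_genes, calibrated_table):
    """Per-trio DNM SNV counts are Poisson with the configured mean."""
    n = 2000
    config = lean_config(
        n_case_trios=n, n_control_trios=0, mosaic_fraction=0.0,
        mean_coding_indel_dnms_per_trio=0.0, seed=10,
    )
    cohort = simulate_cohort(config, genes=toy_genes, rate_table=calibrated_table)
    counts = cohort.truth[cohort.truth.kind == "dnm-snv"].groupby("family_id").size()
    total = counts.reindex([t.family_id for t in cohort.trios], fill_value=0)
    se = np.sqrt(1.0 / n)
    assert abs(total.mean() - 1.0) < 3 * se
    # dispersion consistent with Poisson (variance ~ mean)
    assert 0.8 < total.var() / total.mean() < 1.2


def test_mosaic_fraction_converges(toy_genes, calibrated_table):
    config = lean_config(
        n_case_trios=1500, n_control_trios=0, mosaic_fraction=0.2,
        mean_coding_indel_dnms_per_trio=0.0, seed=11,
    )
    cohort = simulate_cohort(config, genes=toy_genes, rate_table=calibrated_table)
    kinds = cohort.truth.kind.value_counts()
    m = kinds.get("parental-mosaic", 0)
    d = kinds.get("dnm-snv", 0)
    frac = m / (m + d)
    se = np.sqrt(0.2 * 0.8 / (m + d))
    assert abs(frac - 0.2) < 3 * se


def test_null_transmission_is_fair_coin(toy_genes, calibrated_table):
    config = lean_config(
        n_case_trios=400, n_control_trios=0, mosaic_fraction=0.0,
        mean_coding_snv_dnms_per_trio=0.0, mean_coding_indel_dnms_per_trio=0.0,
        mean_qualifying_het_per_trio=1.0, transmission_bias=0.5, seed=12,
    )
    cohort = simulate_cohort(config, genes=toy_genes, rate_table=calibrated_table)
    q = cohort.truth[cohort.truth.kind == "inherited-het"]
    k = int(q.transmitted.astype(bool).sum())
    n = len(q)
    assert stats.binomtest(k, n, 0.5).pvalue > 0.001


def test_enriched_set_receives_scaled_nonsynonymous_rate(toy_genes, calibrated_table, enriched_symbols):
    factor = 10.0
    n = 500
    config = lean_config(
        n_case_trios=n, n_control_trios=0, mosaic_fraction=0.0,
        mean_coding_indel_dnms_per_trio=0.0,
        enriched_geneset=tuple(enriched_symbols),
        nonsyn_enrichment_factor=factor, seed=5,
    )
    cohort = simulate_cohort(config, genes=toy_genes, rate_table=calibrated_table)
    snv = cohort.truth[cohort.truth.kind == "dnm-snv"]
    in_set_nonsyn = snv[snv.gene.isin(enriched_symbols) & (snv.effect != "synonymous")]
    baseline, _ = geneset_expected(toy_genes, enriched_symbols, calibrated_table, "nonsynonymous", n)
    estimated = len(in_set_nonsyn) / baseline
    mc_se = factor * np.sqrt(1.0 / (factor * baseline))
    assert abs(estimated - factor) < 3 * mc_se


def test_truth_events_all_have_emitted_records(default_cohort):
    emitted = {
        (fam, rec.variant_key)
        for fam, recs in default_cohort.records.items()
        for rec in recs
    }
    for row in default_cohort.truth.itertuples(index=False):
        assert (row.family_id, row.variant_key) in emitted


def test_mosaic_events_sit_below_het_threshold(default_cohort):
    mosaics = default_cohort.truth[default_cohort.truth.kind == "parental-mosaic"]
    assert len(mosaics) > 0
    af = mosaics.parental_allele_fraction
    assert (af >= 0.03).all() and (af <= 0.20).all() and (af < 0.30).all()


def test_single_dnm_trio_vcf_structure(toy_genes, calibrated_table, tmp_path):
    """With exactly one injected DNM, the trio VCF holds one child-het,
    parents-hom-ref site."""
    config = lean_config(
        n_case_trios=1, n_control_trios=0, mosaic_fraction=0.0,
        mean_coding_indel_dnms_per_trio=0.0, missing_rate=0.0, seed=21,
    )
    cohort = None
    for seed in range(21, 40):  # find a replicate whose Poisson draw is exactly 1
        cohort = simulate_cohort(
            lean_config(
                n_case_trios=1, n_control_trios=0, mosaic_fraction=0.0,
                mean_coding_indel_dnms_per_trio=0.0, missing_rate=0.0, seed=seed,
            ),
            genes=toy_genes, rate_table=calibrated_table,
        )
        if len(cohort.truth) == 1:
            break
    assert len(cohort.truth) == 1
    (records,) = cohort.records.values()
    assert len(records) == 1
    rec = records[0]
    assert rec.child.gt is Genotype.HET
    assert rec.mother.gt is Genotype.HOM_REF and rec.father.gt is Genotype.HOM_REF


def test_disk_round_trip_identity(toy_genes, calibrated_table, tmp_path):
    config = CohortConfig(n_case_trios=4, n_control_trios=3, seed=6)
    cohort = simulate_cohort(config, genes=toy_genes, rate_table=calibrated_table)
    write_cohort(cohort, tmp_path)
    back = read_cohort(tmp_path)
    assert [t.family_id for t in back.trios] == [t.family_id for t in cohort.trios]
    assert back.records == cohort.records
    assert back.annotations["variant_key"].tolist() == cohort.annotations["variant_key"].tolist()
    assert back.truth["variant_key"].tolist() == cohort.truth["variant_key"].tolist()
    assert all(back.genes[s].cds == cohort.genes[s].cds for s in cohort.genes)
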