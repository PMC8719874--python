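"""Shared fixtures: toy genome, calibrated rate table, and a fully
simulated + called default cohort (built once per session)."""

from __future__ import annotations

import pytest

from trioburden.genome import select_gene_set, toy_genome
from trioburden.rate_model import calibrate_rate_table, default_rate_table
from trioburden.synthetic_cohort import CohortConfig, simulate_cohort
from trioburden.trio_calling import (
    QCThresholds,
    build_control_carrier_index,
    call_dnms,
    call_transmitted_mosaics,
    exclude_outlier_trios,
)


@pytest.fixture(scope="session")
def toy_genes():
    return toy_genome()


@pytest.fixture(scope="session")
def calibrated_table(toy_genes):
    return calibrate_rate_table(default_rate_table(), toy_genes, 1.0)


@pytest.fixture(scope="session")
def enriched_symbols(toy_genes):
    return select_gene_set(toy_genes, 137, seed=11)


@pytest.fixture(scope="session")
def default_cohort(toy_genes, calibrated_table):
    """The default study conditions: 124 case + 573 control trios."""
    config = CohortConfig(seed=1)
    return simulate_cohort(config, genes=toy_genes, rate_table=calibrated_table)


@pytest.fixture(scope="session")
def default_callset(default_cohort):
    """DNM + mosaic calls over the default cohort under default QC."""
    cohort = default_cohort
    thresholds = QCThresholds()
    index = build_control_carrier_index(
        cohort.records, [t.family_id for t in cohort.control_trios]
    )
    dnms, mosaics = [], []
    for trio in cohort.trios:
        recs = cohort.records[trio.family_id]
        dnms.extend(call_dnms(recs, trio, thresholds, index if trio.is_case else None))
        mosaics.extend(call_transmitted_mosaics(recs, trio, thresholds))
    dnms, excluded = exclude_outlier_trios(dnms, thresholds)
    mosaics = [m for m in mosaics if m.trio_id not in set(excluded)]
    return dnms, mosaics, excluded
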