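"""Trimer-context de novo mutation rate model.

Expected de novo SNV counts per gene and effect class are the null model for
every Poisson burden test. A rate table assigns each of the 64 trimers x 3
alternate central bases (192 rows) a per-chromosome per-generation mutation
probability; the expected count of a gene/class combination in a cohort of n
trios is the sum of the table rates over all substitutions of that class in
the gene's CDS, scaled by 2n chromosomes.

Indel de novo expectations are not context-based: they are a single
genome-wide per-trio rate apportioned by coding length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import (
    BASES,
    BASE_INDEX,
    LOF,
    MISSENSE,
    SYNONYMOUS,
    GeneModel,
    classify_substitutions,
    encode_sequence,
)

#: accepted effect-class selectors for expectations
EFFECT_CLASSES = ("synonymous", "missense", "nonsynonymous", "LoF", "all")


class TrimerRateTable:
    """Complete per-generation mutation probabilities for 64 trimers x 3 alts.

    Internally a (4,4,4,4) array indexed as [left, center, right, alt]; the
    alt == center diagonal is undefined (zero). Lookups with an unknown
    flanking base ('N', e.g. at a CDS edge) use the mean rate over the four
    compatible trimers.
    """

    def __init__(self, rates: np.ndarray):
        if rates.shape != (4, 4, 4, 4):
            raise ValueError("rate array must have shape (4,4,4,4)")
        self._rates = rates.astype(float)
        # index 4 on a flank axis = mean over the four bases ('N' imputation)
        ext = np.zeros((5, 4, 5, 4))
        ext[:4, :, :4, :] = self._rates
        ext[4, :, :4, :] = self._rates.mean(axis=0)
        ext[:4, :, 4, :] = self._rates.mean(axis=2)
        ext[4, :, 4, :] = self._rates.mean(axis=(0, 2))
        self._ext = ext

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrimerRateTable":
        """Build from a (trimer, alt, rate) table, validating completeness."""
        required = {"trimer", "alt", "rate"}
        if not required.issubset(frame.columns):
            raise ValueError(f"rate table needs columns {sorted(required)}")
        rates = np.full((4, 4, 4, 4), np.nan)
        seen: set[tuple[str, str]] = set()
        for row in frame.itertuples(index=False):
            trimer = str(row.trimer).upper()
            alt = str(row.alt).upper()
            if len(trimer) != 3 or any(b not in BASE_INDEX for b in trimer):
                raise ValueError(f"malformed trimer {trimer!r}")
            if alt not in BASE_INDEX or alt == trimer[1]:
                raise ValueError(f"invalid alt {alt!r} for trimer {trimer!r}")
            if (trimer, alt) in seen:
                raise ValueError(f"duplicate rate row ({trimer}, {alt})")
            seen.add((trimer, alt))
            rate = float(row.rate)
            if not (0.0 < rate < 1.0):
                raise ValueError(
                    f"rate for ({trimer}, {alt}) must be in (0,1), got {rate}"
                )
            l, c, r = (BASE_INDEX[b] for b in trimer)
            rates[l, c, r, BASE_INDEX[alt]] = rate
        mask = np.ones((4, 4, 4, 4), dtype=bool)
        for c in range(4):
            mask[:, c, :, c] = False  # alt == center is not a substitution
        if np.isnan(rates[mask]).any():
            n_missing = int(np.isnan(rates[mask]).sum())
            raise ValueError(f"rate table incomplete: {n_missing} contexts missing")
        rates[~mask] = 0.0
        return cls(rates)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for l in range(4):
            for c in range(4):
                for r in range(4):
                    for a in range(4):
                        if a == c:
                            continue
                        rows.append(
                            {
                                "trimer": BASES[l] + BASES[c] + BASES[r],
                                "alt": BASES[a],
                                "rate": self._rates[l, c, r, a],
                            }
                        )
        return pd.DataFrame(rows)

    # -- lookup ------------------------------------------------------------

    def rate(self, trimer: str, alt: str) -> float:
        """Rate for one substitution; 'N' flanks are mean-imputed."""
        trimer = trimer.upper()
        l = 4 if trimer[0] == "N" else BASE_INDEX[trimer[0]]
        r = 4 if trimer[2] == "N" else BASE_INDEX[trimer[2]]
        c = BASE_INDEX[trimer[1]]
        a = BASE_INDEX[alt.upper()]
        if a == c:
            raise ValueError("alt equals the central base")
        return float(self._ext[l, c, r, a])

    def rates_for(self, seq_idx: np.ndarray, pos: np.ndarray, alt: np.ndarray) -> np.ndarray:
        """Vectorized lookup for substitutions of one encoded sequence."""
        left = np.where(pos > 0, seq_idx[np.maximum(pos - 1, 0)], 4)
        right = np.where(pos < seq_idx.size - 1, seq_idx[np.minimum(pos + 1, seq_idx.size - 1)], 4)
        return self._ext[left, seq_idx[pos], right, alt]

    def scaled(self, factor: float) -> "TrimerRateTable":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return TrimerRateTable(self._rates * factor)


def default_rate_table(seed: int = 777) -> TrimerRateTable:
    """A synthetic but realistically shaped trimer rate table.

    Transitions run ~4x transversions and CpG-context C>T (and its reverse
    strand G>A) ~12x further, echoing the dominant features of empirical
    trimer mutation spectra; a mild lognormal jitter breaks symmetry between
    contexts. Magnitudes (~1e-8 per generation) land near empirical
    per-site de novo rates; cohort-level analyses calibrate the overall
    scale explicitly (see :func:`calibrate_rate_table`).
    """
    rng = np.random.default_rng(seed)
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    rates = np.zeros((4, 4, 4, 4))
    base = 1.2e-8
    for l in range(4):
        for c in range(4):
            for r in range(4):
                for a in range(4):
                    if a == c:
                        continue
                    rate = base * rng.lognormal(0.0, 0.35)
                    if (c, a) in transitions:
                        rate *= 4.0
                    # CpG deamination: C>T with 3' G, or G>A with 5' C
                    if (c == 1 and a == 3 and r == 2) or (c == 2 and a == 0 and l == 1):
                        rate *= 12.0
                    rates[l, c, r, a] = rate
    return TrimerRateTable(rates)


# ---------------------------------------------------------------------------
# expectations
# ---------------------------------------------------------------------------

def _class_mask(klass: np.ndarray, effect_class: str) -> np.ndarray:
    if effect_class == "synonymous":
        return klass == SYNONYMOUS
    if effect_class == "missense":
        return klass == MISSENSE
    if effect_class == "LoF":
        return klass == LOF
    if effect_class == "nonsynonymous":
        return klass != SYNONYMOUS
    if effect_class == "all":
        return np.ones(klass.shape, dtype=bool)
    raise ValueError(f"unknown effect class {effect_class!r}; choose from {EFFECT_CLASSES}")


def gene_probability(gene: GeneModel, rate_table: TrimerRateTable, effect_class: str) -> float:
    """Per-chromosome per-generation probability of a de novo SNV of the
    requested effect class anywhere in the gene's CDS."""
    gene.require_frame()
    if gene.coding_length < 3:
        raise ValueError(f"{gene.symbol}: need at least one codon")
    pos, alt, klass = classify_substitutions(gene.cds)
    seq_idx = encode_sequence(gene.cds)
    rates = rate_table.rates_for(seq_idx, pos, alt)
    return float(rates[_class_mask(klass, effect_class)].sum())


def expected_count(
    gene: GeneModel,
    rate_table: TrimerRateTable,
    effect_class: str,
    n_trios: int,
    splice_lof_rate_per_intron: float = 0.0,
    n_introns: int = 0,
) -> float:
    """Cohort-scaled expected de novo SNV count: gene probability x 2 x n.

    Splice donor/acceptor LoF mutations fall outside the CDS substitution
    space; they can be approximated by a per-intron constant added to the
    LoF (hence nonsynonymous/all) classes. The default of 0 matches
    intron-free gene models.
    """
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    prob = gene_probability(gene, rate_table, effect_class)
    if effect_class in ("LoF", "nonsynonymous", "all"):
        prob += splice_lof_rate_per_intron * n_introns
    return prob * 2 * n_trios


def geneset_expected(
    genes: dict[str, GeneModel],
    symbols: list[str] | None,
    rate_table: TrimerRateTable,
    effect_class: str,
    n_trios: int,
) -> tuple[float, list[str]]:
    """Summed expectation over a gene set.

    Returns (expectation, missing symbols). Symbols absent from the catalogue
    are reported, never silently dropped; an entirely unresolvable set is an
    error. ``symbols=None`` means the whole catalogue.
    """
    if symbols is None:
        symbols = list(genes)
    missing = [s for s in symbols if s not in genes]
    known = [s for s in symbols if s in genes]
    if not known:
        raise ValueError("no gene in the set is present in the catalogue")
    total = sum(expected_count(genes[s], rate_table, effect_class, n_trios) for s in known)
    return total, missing


def calibrate_rate_table(
    rate_table: TrimerRateTable,
    genes: dict[str, GeneModel],
    mean_coding_snvs_per_trio: float = 1.0,
) -> TrimerRateTable:
    """Rescale a rate table so the whole-catalogue expected coding de novo
    SNV count is ``mean_coding_snvs_per_trio`` per trio (over 2 chromosomes).

    The shape of the trimer spectrum is preserved; only the overall scale
    moves. This pins the simulator and the null model to the same exome-wide
    mutation rate.
    """
    if mean_coding_snvs_per_trio <= 0:
        raise ValueError("target mean must be positive")
    total, _ = geneset_expected(genes, None, rate_table, "all", 1)
    return rate_table.scaled(mean_coding_snvs_per_trio / total)


@dataclass(frozen=True)
class IndelRateModel:
    """Genome-wide coding indel de novo rate apportioned by coding length."""

    mean_per_trio: float = 0.1

    def expected_count(
        self, genes: dict[str, GeneModel], symbols: list[str] | None, n_trios: int
    ) -> float:
        total_len = sum(g.coding_length for g in genes.values())
        if symbols is None:
            subset_len = total_len
        else:
            subset_len = sum(genes[s].coding_length for s in symbols if s in genes)
        return self.mean_per_trio * n_trios * subset_len / total_len
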