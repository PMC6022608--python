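"""Quality metrics for genome binnings.

Two families of metrics are computed from the bin x genome contingency
table:

*Per-bin metrics under a bin-to-genome mapping.*  Purity
p_x = TP_x / (TP_x + FP_x) (precision), completeness
r_x = TP_x / (TP_x + FN_x) (recall) and contamination c_x = 1 - p_x,
macro-averaged into p̄ (over bins) and r̄ (over genomes, where unmapped
genomes contribute completeness zero).  The truncated average purity
p̄_α discards the smallest bins totalling (100-α)% of the assigned base
pairs before averaging, because tiny bins are of little practical
interest yet weigh as much as large bins in a macro average.

*Sample-wide (size-weighted) metrics.*  Per-base-pair purity and
completeness weight bins/genomes by size; accuracy divides the
correctly assigned base pairs by *all* base pairs including unassigned
ones; the adjusted Rand index measures chance-corrected partition
agreement on the assigned portion of the data only (including the
unassigned portion would make the ARI meaningless for binners that
leave data out), so the percentage of assigned data is reported
alongside.

Size-weighted purity, size-weighted completeness and accuracy always
use the majority-overlap maxima (the mapping g), independent of the
mapping criterion selected for per-bin metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

from .contingency import (
    MAJORITY_OVERLAP,
    BinGenomeMapping,
    ContingencyTable,
    build_contingency,
    make_mapping,
)
from .model import Binning, GoldStandard

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 99.0
DEFAULT_CONTAMINATION_BOUNDS = (0.05, 0.10)
DEFAULT_COMPLETENESS_BOUNDS = (0.5, 0.7, 0.9)

RANK_PURITY = "purity"
RANK_COMPLETENESS = "completeness"
RANK_SUM = "purity_plus_completeness"


@dataclass
class BinMetrics:
    """Per-bin quality record: purity, completeness, contamination."""

    bin_id: str
    size_bp: int
    purity: float
    completeness: float
    contamination: float
    mapped_genome: str


@dataclass
class AssessmentSummary:
    """All scalar metrics for one binning against one gold standard."""

    label: str
    avg_purity: float
    avg_contamination: float
    truncated_avg_purity: float
    alpha: float
    avg_completeness: float
    avg_purity_bp: float
    avg_completeness_bp: float
    accuracy: float
    ari_bp: float
    ari_seq: float
    pct_assigned_bp: float
    recovery_counts: dict[tuple[float, float], int]
    n_bins: int
    n_bins_after_truncation: int
    n_genomes: int
    n_r: int
    std_error_purity: float
    std_error_completeness: float
    dropped_sequences: int = 0
    empty_binning: bool = False

    def as_dict(self) -> dict[str, float | int | str]:
        """Flat scalar view used by the reporting layer."""
        out: dict[str, float | int | str] = {
            "label": self.label,
            "avg_purity": self.avg_purity,
            "avg_contamination": self.avg_contamination,
            "truncated_avg_purity": self.truncated_avg_purity,
            "alpha": self.alpha,
            "avg_completeness": self.avg_completeness,
            "avg_purity_bp": self.avg_purity_bp,
            "avg_completeness_bp": self.avg_completeness_bp,
            "accuracy": self.accuracy,
            "ari_bp": self.ari_bp,
            "ari_seq": self.ari_seq,
            "pct_assigned_bp": self.pct_assigned_bp,
            "n_bins": self.n_bins,
            "n_bins_after_truncation": self.n_bins_after_truncation,
            "n_genomes": self.n_genomes,
            "std_error_purity": self.std_error_purity,
            "std_error_completeness": self.std_error_completeness,
        }
        for (c_bound, r_bound), count in sorted(self.recovery_counts.items()):
            out[f"recovered_c<{c_bound:g}_r>{r_bound:g}"] = count
        return out


def per_bin_metrics(
    ct: ContingencyTable, mapping: BinGenomeMapping
) -> list[BinMetrics]:
    """Purity, completeness and contamination for every predicted bin.

    Unmapped genomes produce no record here; their completeness of zero
    enters the genome-averaged completeness instead.
    """
    records = []
    for x in sorted(ct.bin_totals_bp):
        tp, fp, fn = mapping.tp_bp[x], mapping.fp_bp[x], mapping.fn_bp[x]
        records.append(
            BinMetrics(
                bin_id=x,
                size_bp=ct.bin_totals_bp[x],
                purity=tp / (tp + fp),
                completeness=tp / (tp + fn),
                contamination=fp / (tp + fp),
                mapped_genome=mapping.mapped_genome[x],
            )
        )
    return records


def _mean_and_stderr(values: Sequence[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var) / math.sqrt(n)


def truncated_bin_set(
    bins: Sequence[BinMetrics], alpha: float
) -> list[BinMetrics]:
    """Bins retained by the α-percentile size threshold.

    Bins are sorted by size; the smallest bins adding up to (100-α)% of
    the assigned base pairs are removed.  The bin that straddles the
    threshold is retained, as is any removed bin of the same size as the
    smallest retained bin (equally sized bins are kept together).
    """
    if not 0 < alpha <= 100:
        raise ValueError(f"alpha must be in (0, 100], got {alpha}")
    total = sum(b.size_bp for b in bins)
    threshold = (100.0 - alpha) / 100.0 * total
    ascending = sorted(bins, key=lambda b: (b.size_bp, b.bin_id))
    cum = 0
    cut = 0  # number of removed bins
    for b in ascending:
        if cum + b.size_bp <= threshold:
            cum += b.size_bp
            cut += 1
        else:
            break
    retained = ascending[cut:]
    if retained and cut:
        smallest_kept = retained[0].size_bp
        while cut and ascending[cut - 1].size_bp == smallest_kept:
            cut -= 1
        retained = ascending[cut:]
    return retained


def average_purity(
    bins: Sequence[BinMetrics], alpha: float = DEFAULT_ALPHA
) -> tuple[float, float, float, int, int, float]:
    """Macro-averaged purity, contamination, and the truncated variant.

    Returns (p̄, c̄, p̄_α, n_p, n_{p,α}, std_error) where the standard
    error is over the truncated set (the set shown in plots).
    """
    if not bins:
        raise ValueError("average_purity requires at least one bin")
    # sum in size order so that the alpha=100 average is bit-identical
    # to the untruncated one (the truncated set is a suffix of this order)
    ordered = sorted(bins, key=lambda b: (b.size_bp, b.bin_id))
    p_bar = sum(b.purity for b in ordered) / len(ordered)
    retained = truncated_bin_set(bins, alpha)
    p_alpha, stderr = _mean_and_stderr([b.purity for b in retained])
    return p_bar, 1.0 - p_bar, p_alpha, len(bins), len(retained), stderr


def average_completeness(
    bins: Sequence[BinMetrics], mapping: BinGenomeMapping
) -> tuple[float, int, float]:
    """Genome-averaged completeness r̄ with its standard error.

    The average runs over n_r = n_p + |Z| values: one completeness per
    bin plus a zero for every unmapped genome.
    """
    values = [b.completeness for b in bins]
    values += [0.0] * len(mapping.unmapped_genomes)
    if not values:
        return 0.0, 0, 0.0
    mean, stderr = _mean_and_stderr(values)
    return mean, len(values), stderr


def per_bp_purity_completeness(ct: ContingencyTable) -> tuple[float, float]:
    """Size-weighted purity and completeness.

    p̄_bp divides the summed per-bin maxima (the majority-overlap true
    positives) by the total assigned base pairs; r̄_bp divides the
    summed per-genome maxima by the total gold-standard base pairs.  A
    genome intersecting no bin contributes zero to the numerator but its
    full size to the denominator.
    """
    bin_max: dict[str, int] = {}
    genome_max: dict[str, int] = {}
    for (x, y), bp in ct.cells_bp.items():
        bin_max[x] = max(bin_max.get(x, 0), bp)
        genome_max[y] = max(genome_max.get(y, 0), bp)
    total_assigned = sum(ct.bin_totals_bp.values())
    total_gold = sum(ct.genome_sizes.values())
    p_bp = sum(bin_max.values()) / total_assigned if total_assigned else 0.0
    r_bp = sum(genome_max.values()) / total_gold if total_gold else 0.0
    return p_bp, r_bp


def accuracy(ct: ContingencyTable) -> float:
    """Correctly assigned base pairs over all base pairs, U included.

    The numerator is the summed majority-overlap true positives; the
    denominator is the full gold-standard size in scope.
    """
    bin_max: dict[str, int] = {}
    for (x, _y), bp in ct.cells_bp.items():
        bin_max[x] = max(bin_max.get(x, 0), bp)
    denom = ct.unassigned_bp + ct.total_assigned_bp
    return sum(bin_max.values()) / denom if denom else 0.0


def _partitions_identical(cells: dict[tuple[str, str], int]) -> bool:
    rows: dict[str, int] = {}
    cols: dict[str, int] = {}
    for (x, y) in cells:
        rows[x] = rows.get(x, 0) + 1
        cols[y] = cols.get(y, 0) + 1
    return all(v == 1 for v in rows.values()) and all(
        v == 1 for v in cols.values()
    )


def adjusted_rand_index(
    ct: ContingencyTable, currency: Literal["bp", "seq"] = "bp"
) -> float:
    """Adjusted Rand index over the assigned portion of the data.

    Chance-corrected agreement between the predicted partition (bins)
    and the true partition (genomes) of the assigned items, where an
    item is a base pair (``currency="bp"``) or a sequence
    (``currency="seq"``).  Choose-2 sums are computed in exact integer
    arithmetic; the final ratio is an exact rational converted to float.

    When the chance-correction denominator is zero (fewer than two
    assigned items, or both partitions lump everything together) the
    index is 1.0 if the two partitions are identical and 0.0 otherwise.
    """
    cells = ct.cells_bp if currency == "bp" else ct.cells_seq
    row_tot: dict[str, int] = {}
    col_tot: dict[str, int] = {}
    for (x, y), v in cells.items():
        row_tot[x] = row_tot.get(x, 0) + v
        col_tot[y] = col_tot.get(y, 0) + v
    m = sum(row_tot.values())
    sum_cells = sum(math.comb(v, 2) for v in cells.values())
    sum_rows = sum(math.comb(v, 2) for v in row_tot.values())
    sum_cols = sum(math.comb(v, 2) for v in col_tot.values())
    pairs = math.comb(m, 2)
    if pairs == 0:
        degenerate = True
    else:
        expected = Fraction(sum_rows * sum_cols, pairs)
        numerator = sum_cells - expected
        denominator = Fraction(sum_rows + sum_cols, 2) - expected
        degenerate = denominator == 0
    if degenerate:
        value = 1.0 if _partitions_identical(cells) else 0.0
        logger.info(
            "ARI (%s) denominator degenerate; reporting %.1f", currency, value
        )
        return value
    return float(numerator / denominator)


def percentage_assigned(
    ct: ContingencyTable, currency: Literal["bp", "seq"] = "bp"
) -> float:
    """Fraction of the gold-standard data placed in any bin."""
    if currency == "bp":
        total = ct.total_assigned_bp + ct.unassigned_bp
        return ct.total_assigned_bp / total if total else 0.0
    return ct.total_assigned_seq / ct.total_seq if ct.total_seq else 0.0


def genome_recovery_counts(
    bins: Sequence[BinMetrics],
    contamination_bounds: Sequence[float] = DEFAULT_CONTAMINATION_BOUNDS,
    completeness_bounds: Sequence[float] = DEFAULT_COMPLETENESS_BOUNDS,
) -> dict[tuple[float, float], int]:
    """Genomes recovered below/above contamination/completeness bounds.

    A genome counts at cell (c_bound, r_bound) if at least one bin
    mapped to it has contamination strictly below c_bound *and*
    completeness strictly above r_bound; each genome counts once per
    cell no matter how many of its bins qualify.
    """
    for bound in (*contamination_bounds, *completeness_bounds):
        if not 0 < bound < 1:
            raise ValueError(f"recovery bound {bound} outside (0, 1)")
    counts: dict[tuple[float, float], int] = {}
    for c_bound in contamination_bounds:
        for r_bound in completeness_bounds:
            recovered = {
                b.mapped_genome
                for b in bins
                if b.contamination < c_bound and b.completeness > r_bound
            }
            counts[(c_bound, r_bound)] = len(recovered)
    return counts


def rank_binnings(
    summaries: Sequence[AssessmentSummary],
    criterion: str = RANK_SUM,
) -> list[AssessmentSummary]:
    """Order binnings best-first by the chosen criterion.

    ``purity`` ranks by the truncated average purity at the configured
    α, ``completeness`` by the genome-averaged completeness, and
    ``purity_plus_completeness`` by their sum.  Ties break by label.
    """
    if not summaries:
        raise ValueError("rank_binnings requires at least one summary")
    keys = {
        RANK_PURITY: lambda s: s.truncated_avg_purity,
        RANK_COMPLETENESS: lambda s: s.avg_completeness,
        RANK_SUM: lambda s: s.truncated_avg_purity + s.avg_completeness,
    }
    if criterion not in keys:
        raise ValueError(f"unknown ranking criterion {criterion!r}")
    score = keys[criterion]
    return sorted(summaries, key=lambda s: (-score(s), s.label))


def evaluate_all(
    gold: GoldStandard,
    binning: Binning,
    *,
    alpha: float = DEFAULT_ALPHA,
    mapping_criterion: str = MAJORITY_OVERLAP,
    contamination_bounds: Sequence[float] = DEFAULT_CONTAMINATION_BOUNDS,
    completeness_bounds: Sequence[float] = DEFAULT_COMPLETENESS_BOUNDS,
) -> AssessmentSummary:
    """Run the full assessment of one binning against one gold standard.

    Deterministic: identical inputs give bit-identical summaries.

    A binning with no evaluable sequences has undefined purity; by
    convention every fraction is reported as zero with the
    ``empty_binning`` flag set (and n_r equal to the genome count, all
    genomes being unmapped).
    """
    evaluable = sum(1 for s in binning.assignment if s in gold.assignment)
    if evaluable == 0:
        logger.warning("binning %r is empty: all metrics zero", binning.label)
        zero_recovery = {
            (c, r): 0
            for c in contamination_bounds
            for r in completeness_bounds
        }
        return AssessmentSummary(
            label=binning.label,
            avg_purity=0.0,
            avg_contamination=0.0,
            truncated_avg_purity=0.0,
            alpha=alpha,
            avg_completeness=0.0,
            avg_purity_bp=0.0,
            avg_completeness_bp=0.0,
            accuracy=0.0,
            ari_bp=0.0,
            ari_seq=0.0,
            pct_assigned_bp=0.0,
            recovery_counts=zero_recovery,
            n_bins=0,
            n_bins_after_truncation=0,
            n_genomes=len(gold.genome_sizes),
            n_r=len(gold.genome_sizes),
            std_error_purity=0.0,
            std_error_completeness=0.0,
            dropped_sequences=len(binning.assignment),
            empty_binning=True,
        )
    ct = build_contingency(gold, binning)
    mapping = make_mapping(ct, mapping_criterion, gold)
    bins = per_bin_metrics(ct, mapping)
    p_bar, c_bar, p_alpha, n_p, n_p_alpha, se_p = average_purity(bins, alpha)
    r_bar, n_r, se_r = average_completeness(bins, mapping)
    p_bp, r_bp = per_bp_purity_completeness(ct)
    return AssessmentSummary(
        label=binning.label,
        avg_purity=p_bar,
        avg_contamination=c_bar,
        truncated_avg_purity=p_alpha,
        alpha=alpha,
        avg_completeness=r_bar,
        avg_purity_bp=p_bp,
        avg_completeness_bp=r_bp,
        accuracy=accuracy(ct),
        ari_bp=adjusted_rand_index(ct, "bp"),
        ari_seq=adjusted_rand_index(ct, "seq"),
        pct_assigned_bp=percentage_assigned(ct, "bp"),
        recovery_counts=genome_recovery_counts(
            bins, contamination_bounds, completeness_bounds
        ),
        n_bins=n_p,
        n_bins_after_truncation=n_p_alpha,
        n_genomes=len(ct.genome_sizes),
        n_r=n_r,
        std_error_purity=se_p,
        std_error_completeness=se_r,
        dropped_sequences=ct.dropped_sequences,
    )
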