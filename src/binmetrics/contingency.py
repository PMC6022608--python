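"""Bin x genome contingency structure and the bin-to-genome mapping.

Every metric is derived from the overlap matrix m_{x,y}: the number of
base pairs (or sequences) of genome y placed in predicted bin x.  A
bin-to-genome mapping assigns each bin the single genome it is judged
to represent, under one of two criteria:

* ``majority_overlap`` (g): the genome contributing the most base
  pairs to the bin — the genome that best represents the bin.
* ``genome_fraction`` (g'): the genome whose largest *fraction* of its
  own base pairs sits in the bin — the bin that best represents the
  genome.  If several genomes are fully contained (fraction 1.0), the
  largest genome wins.

The mapping implies per-bin true positives (bin ∩ mapped genome), false
positives (the rest of the bin) and false negatives (the rest of the
mapped genome), all in base pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

from .model import Binning, GoldStandard

logger = logging.getLogger(__name__)

MAJORITY_OVERLAP = "majority_overlap"
GENOME_FRACTION = "genome_fraction"


@dataclass
class ContingencyTable:
    """Overlaps between predicted bins and gold-standard genomes.

    ``cells_bp[(x, y)]`` is m_{x,y} in base pairs; ``cells_seq`` counts
    sequences.  ``unassigned_bp`` (U) tallies gold-standard base pairs
    placed in no bin of the evaluated binning.
    """

    cells_bp: dict[tuple[str, str], int]
    cells_seq: dict[tuple[str, str], int]
    bin_totals_bp: dict[str, int]
    genome_totals_assigned_bp: dict[str, int]
    genome_sizes: dict[str, int]
    total_assigned_bp: int
    unassigned_bp: int
    unassigned_per_genome_bp: dict[str, int]
    total_assigned_seq: int
    total_seq: int
    dropped_sequences: int = 0

    @property
    def bins(self) -> list[str]:
        return sorted(self.bin_totals_bp)

    @property
    def genomes(self) -> list[str]:
        return sorted(self.genome_sizes)

    @property
    def total_bp(self) -> int:
        return self.total_assigned_bp + self.unassigned_bp


@dataclass
class BinGenomeMapping:
    """A bin-to-genome mapping with per-bin TP/FP/FN in base pairs.

    ``unmapped_genomes`` (Z) is the set of gold genomes that no bin maps
    to; they contribute completeness zero to genome-averaged metrics.
    """

    mapped_genome: dict[str, str]
    tp_bp: dict[str, int]
    fp_bp: dict[str, int]
    fn_bp: dict[str, int]
    unmapped_genomes: set[str]
    criterion: str


def build_contingency(gold: GoldStandard, binning: Binning) -> ContingencyTable:
    """Cross-tabulate a predicted binning against the gold standard.

    Sequences in the binning that are absent from the gold standard are
    excluded from evaluation (they are outside the universe the metrics
    are defined on), with a counted warning.  Bins left empty by the
    drop are removed.
    """
    dropped = sum(1 for s in binning.assignment if s not in gold.assignment)
    if dropped:
        logger.warning(
            "binning %r: %d sequence(s) absent from the gold standard "
            "were excluded from evaluation",
            binning.label,
            dropped,
        )
    evaluable = {
        s: b for s, b in binning.assignment.items() if s in gold.assignment
    }
    if not evaluable:
        raise ValueError(
            f"binning {binning.label!r}: no evaluable sequences (no overlap "
            f"with gold-standard ids)"
        )

    cells_bp: dict[tuple[str, str], int] = {}
    cells_seq: dict[tuple[str, str], int] = {}
    bin_totals: dict[str, int] = {}
    genome_assigned: dict[str, int] = {g: 0 for g in gold.genome_sizes}
    for seq_id, bin_id in evaluable.items():
        genome = gold.assignment[seq_id]
        length = gold.seq_lengths[seq_id]
        key = (bin_id, genome)
        cells_bp[key] = cells_bp.get(key, 0) + length
        cells_seq[key] = cells_seq.get(key, 0) + 1
        bin_totals[bin_id] = bin_totals.get(bin_id, 0) + length
        genome_assigned[genome] += length

    total_assigned = sum(bin_totals.values())
    unassigned_per_genome = {
        g: gold.genome_sizes[g] - genome_assigned[g] for g in gold.genome_sizes
    }
    return ContingencyTable(
        cells_bp=cells_bp,
        cells_seq=cells_seq,
        bin_totals_bp=bin_totals,
        genome_totals_assigned_bp=genome_assigned,
        genome_sizes=dict(gold.genome_sizes),
        total_assigned_bp=total_assigned,
        unassigned_bp=gold.total_bp - total_assigned,
        unassigned_per_genome_bp=unassigned_per_genome,
        total_assigned_seq=len(evaluable),
        total_seq=len(gold.assignment),
        dropped_sequences=dropped,
    )


def _finish_mapping(
    ct: ContingencyTable, mapped: dict[str, str], criterion: str
) -> BinGenomeMapping:
    tp = {x: ct.cells_bp[(x, y)] for x, y in mapped.items()}
    fp = {x: ct.bin_totals_bp[x] - tp[x] for x in mapped}
    fn = {x: ct.genome_sizes[y] - tp[x] for x, y in mapped.items()}
    unmapped = set(ct.genome_sizes) - set(mapped.values())
    return BinGenomeMapping(
        mapped_genome=mapped,
        tp_bp=tp,
        fp_bp=fp,
        fn_bp=fn,
        unmapped_genomes=unmapped,
        criterion=criterion,
    )


def map_bins_majority(ct: ContingencyTable) -> BinGenomeMapping:
    """Map each bin to its most abundant genome in base pairs (g).

    Ties (equal overlap) go to the larger genome, then the
    lexicographically smaller genome id, so the result is deterministic.
    """
    mapped: dict[str, str] = {}
    for x in ct.bin_totals_bp:
        candidates = [
            (y, bp) for (bx, y), bp in ct.cells_bp.items() if bx == x
        ]
        # maximize overlap; break ties toward the larger genome, then id
        mapped[x] = min(
            candidates,
            key=lambda c: (-c[1], -ct.genome_sizes[c[0]], c[0]),
        )[0]
    return _finish_mapping(ct, mapped, MAJORITY_OVERLAP)


def map_bins_fraction(
    ct: ContingencyTable, gold: GoldStandard | None = None
) -> BinGenomeMapping:
    """Map each bin to the genome with the largest contained fraction (g').

    The score for genome y in bin x is m_{x,y} / |y|.  When several
    genomes are completely contained in the bin (fraction 1.0) — or more
    generally tie — the largest genome is mapped, then the smaller id.
    """
    sizes = gold.genome_sizes if gold is not None else ct.genome_sizes
    mapped: dict[str, str] = {}
    for x in ct.bin_totals_bp:
        candidates = [
            (y, bp) for (bx, y), bp in ct.cells_bp.items() if bx == x
        ]
        # exact rational comparison: fraction desc, genome size desc, id asc
        mapped[x] = min(
            candidates,
            key=lambda c: (-Fraction(c[1], sizes[c[0]]), -sizes[c[0]], c[0]),
        )[0]
    return _finish_mapping(ct, mapped, GENOME_FRACTION)


def make_mapping(
    ct: ContingencyTable,
    criterion: str = MAJORITY_OVERLAP,
    gold: GoldStandard | None = None,
) -> BinGenomeMapping:
    """Dispatch to the requested mapping criterion."""
    if criterion == MAJORITY_OVERLAP:
        return map_bins_majority(ct)
    if criterion == GENOME_FRACTION:
        return map_bins_fraction(ct, gold)
    raise ValueError(f"unknown mapping criterion {criterion!r}")
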