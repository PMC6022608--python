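"""Synthetic gold standards and controllably degraded binnings.

Real benchmark gold standards come from simulated metagenomes with
known genome membership; here we generate miniature stand-ins so every
metric is testable without external data.  A gold standard is a set of
genomes of varying sizes, each composed of contigs; a degraded binning
starts from the perfect one-bin-per-genome solution and applies the
canonical binning error modes in a fixed order:

1. *merges* — fuse the bins of genome pairs (underbinning: several
   genomes end up in one bin);
2. *splits* — cut bins in two (overbinning: one genome spread over
   several bins);
3. *misassignments* — move assigned sequences to a wrong bin;
4. *unassignments* — drop sequences from the binning entirely.

All randomness flows from one seeded :class:`numpy.random.Generator`
per call, so identical specs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Binning, GoldStandard


@dataclass
class DegradationSpec:
    """Knobs controlling how far a binning departs from perfect.

    ``unassign_rate`` and ``misassign_rate`` are per-sequence Bernoulli
    probabilities; ``merge_pairs`` and ``split_count`` are whole-bin
    edit counts.  ``seed`` fully determines the output.
    """

    unassign_rate: float = 0.0
    misassign_rate: float = 0.0
    merge_pairs: int = 0
    split_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("unassign_rate", "misassign_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.merge_pairs < 0 or self.split_count < 0:
            raise ValueError("merge_pairs and split_count must be >= 0")


@dataclass
class PerturbationRecord:
    """Realized edit counts of one :func:`perturb_binning` call."""

    merged_pairs: list[tuple[str, str]] = field(default_factory=list)
    split_bins: list[str] = field(default_factory=list)
    misassigned: int = 0
    unassigned: int = 0


def generate_gold_standard(
    n_genomes: int,
    contigs_per_genome: tuple[int, int] = (5, 20),
    length_range_bp: tuple[int, int] = (1_000, 100_000),
    seed: int = 0,
) -> GoldStandard:
    """Generate a random gold standard with stable, sortable ids.

    Genome ids are ``G001``..; contig ids ``G001_c0001``..  Contig
    counts and lengths are drawn uniformly from the given inclusive
    ranges, so genome sizes vary across genomes.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    lo_c, hi_c = contigs_per_genome
    lo_l, hi_l = length_range_bp
    if not (1 <= lo_c <= hi_c) or not (1 <= lo_l <= hi_l):
        raise ValueError("contig-count and length ranges must be positive and ordered")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    lengths: dict[str, int] = {}
    for gi in range(1, n_genomes + 1):
        genome = f"G{gi:03d}"
        n_contigs = int(rng.integers(lo_c, hi_c + 1))
        for ci in range(1, n_contigs + 1):
            contig = f"{genome}_c{ci:04d}"
            assignment[contig] = genome
            lengths[contig] = int(rng.integers(lo_l, hi_l + 1))
    return GoldStandard(assignment=assignment, seq_lengths=lengths)


def perfect_binning(gold: GoldStandard, label: str = "perfect") -> Binning:
    """The one-bin-per-genome binning with every sequence assigned."""
    return Binning(
        label=label,
        assignment={s: f"bin_{g}" for s, g in gold.assignment.items()},
    )


def perturb_binning(
    gold: GoldStandard,
    spec: DegradationSpec,
    label: str = "perturbed",
) -> tuple[Binning, PerturbationRecord]:
    """Degrade the perfect binning according to ``spec``.

    Edits are applied in the fixed order merge -> split -> misassign ->
    unassign under one seeded random stream, so expected-metric
    reasoning stays tractable.  Returns the binning and a record of the
    edits actually realized.
    """
    rng = np.random.default_rng(spec.seed)
    assignment = dict(perfect_binning(gold, label).assignment)
    record = PerturbationRecord()

    bins = sorted(set(assignment.values()))
    n_mergeable = len(bins) // 2
    if spec.merge_pairs > n_mergeable:
        raise ValueError(
            f"merge_pairs={spec.merge_pairs} needs {2 * spec.merge_pairs} "
            f"bins, only {len(bins)} exist"
        )
    if spec.merge_pairs:
        chosen = rng.choice(len(bins), size=2 * spec.merge_pairs, replace=False)
        for k in range(spec.merge_pairs):
            keep, absorb = bins[chosen[2 * k]], bins[chosen[2 * k + 1]]
            for s, b in assignment.items():
                if b == absorb:
                    assignment[s] = keep
            record.merged_pairs.append((keep, absorb))

    bins = sorted(set(assignment.values()))
    if spec.split_count:
        if spec.split_count > len(bins):
            raise ValueError(
                f"split_count={spec.split_count} exceeds bin count {len(bins)}"
            )
        to_split = [
            bins[i]
            for i in rng.choice(len(bins), size=spec.split_count, replace=False)
        ]
        for b in to_split:
            members = sorted(s for s, bb in assignment.items() if bb == b)
            if len(members) < 2:
                continue
            half = rng.permutation(len(members))[: len(members) // 2]
            for idx in half:
                assignment[members[idx]] = f"{b}_split"
            record.split_bins.append(b)

    if spec.misassign_rate > 0:
        bins = sorted(set(assignment.values()))
        if len(bins) > 1:
            seqs = sorted(assignment)
            move = rng.random(len(seqs)) < spec.misassign_rate
            for s, m in zip(seqs, move):
                if not m:
                    continue
                current = assignment[s]
                others = [b for b in bins if b != current]
                assignment[s] = others[int(rng.integers(len(others)))]
                record.misassigned += 1

    if spec.unassign_rate > 0:
        seqs = sorted(assignment)
        drop = rng.random(len(seqs)) < spec.unassign_rate
        for s, d in zip(seqs, drop):
            if d:
                del assignment[s]
                record.unassigned += 1

    if not assignment:
        raise ValueError("degradation emptied the binning entirely")
    return Binning(label=label, assignment=assignment), record


def fixture_f1() -> tuple[GoldStandard, Binning]:
    """The canonical worked example used throughout the test suite.

    Three genomes — A (contigs a1: 60 bp, a2: 40 bp), B (b1: 50 bp,
    b2: 50 bp), C (c1: 30 bp) — and a two-bin prediction: bin X holds
    {a1, a2, b1}, bin Y holds {b2}, and c1 is left unassigned.  Every
    metric value for this instance is hand-computable.
    """
    gold = GoldStandard(
        assignment={"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"},
        seq_lengths={"a1": 60, "a2": 40, "b1": 50, "b2": 50, "c1": 30},
    )
    binning = Binning(
        label="F1",
        assignment={"a1": "X", "a2": "X", "b1": "X", "b2": "Y"},
    )
    return gold, binning


def write_fixture_files(
    gold: GoldStandard, binning: Binning, directory
) -> tuple[str, str]:
    """Emit a (gold standard, binning) pair as Bioboxes files.

    The gold standard carries lengths in a ``_LENGTH`` column so no
    FASTA input is needed.  Returns the two paths.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gold_path = directory / "gold_standard.tsv"
    with open(gold_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("@Version:0.9.0\n@SampleID:gold\n")
        fh.write("@@SEQUENCEID\tBINID\t_LENGTH\n")
        for seq in sorted(gold.assignment):
            fh.write(
                f"{seq}\t{gold.assignment[seq]}\t{gold.seq_lengths[seq]}\n"
            )
    from .formats import write_bioboxes_binning

    query_path = directory / f"{binning.label}.binning.tsv"
    write_bioboxes_binning(binning, query_path, sample_id=binning.label)
    return str(gold_path), str(query_path)
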