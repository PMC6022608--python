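"""Core data containers shared across the package.

The evaluation problem is defined over two partitions of a set of
sequences (contigs or reads): the *gold standard* assigns each sequence
to the genome it truly originates from, and a *binning* is a predicted
grouping of (a subset of) those sequences into genome bins.  Every
metric downstream is computed from these two maps plus per-sequence
lengths in base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


class DuplicateAssignmentError(FormatError):
    """A sequence appears more than once with conflicting assignments."""


class ConfigurationError(ValueError):
    """Raised when inputs are inconsistent or insufficient for a run."""


@dataclass
class GoldStandard:
    """The true sequence-to-genome partition with sequence lengths.

    Parameters
    ----------
    assignment
        Map from sequence id to the genome it belongs to.
    seq_lengths
        Map from sequence id to its length in base pairs.  Every
        assigned sequence must have a positive length.
    """

    assignment: dict[str, str]
    seq_lengths: dict[str, int]
    genome_sizes: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        missing = [s for s in self.assignment if s not in self.seq_lengths]
        if missing:
            shown = ", ".join(sorted(missing)[:10])
            raise ConfigurationError(
                f"{len(missing)} assigned sequence(s) lack a length "
                f"(first offenders: {shown})"
            )
        bad = [s for s, L in self.seq_lengths.items() if L < 1]
        if bad:
            raise ConfigurationError(
                f"non-positive length for sequence(s): {sorted(bad)[:10]}"
            )
        sizes: dict[str, int] = {}
        for seq, genome in self.assignment.items():
            sizes[genome] = sizes.get(genome, 0) + self.seq_lengths[seq]
        self.genome_sizes = sizes

    @property
    def genomes(self) -> set[str]:
        return set(self.genome_sizes)

    @property
    def total_bp(self) -> int:
        return sum(self.genome_sizes.values())

    def sequences_of(self, genome: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == genome]


@dataclass
class Binning:
    """A predicted sequence-to-bin partition.

    Each sequence sits in at most one bin; duplicate assignments are
    rejected at parse time.  ``metadata`` carries any extra Bioboxes
    columns (e.g. TAXID) keyed by sequence id, untouched by metrics.
    """

    label: str
    assignment: dict[str, str]
    metadata: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for b in self.assignment.values():
            if not b or any(ch.isspace() for ch in b):
                raise FormatError(f"invalid bin id {b!r}: must be a non-empty token")

    @property
    def bins(self) -> set[str]:
        return set(self.assignment.values())

    def __len__(self) -> int:
        return len(self.assignment)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Binning):
            return NotImplemented
        return self.label == other.label and self.assignment == other.assignment
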