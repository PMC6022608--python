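"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from binmetrics import Binning, GoldStandard, fixture_f1


@pytest.fixture
def f1():
    """The canonical hand-computable worked instance."""
    return fixture_f1()


@pytest.fixture
def f1_gold(f1):
    return f1[0]


@pytest.fixture
def f1_binning(f1):
    return f1[1]


def random_instance(
    rng: np.random.Generator,
    max_seqs: int = 30,
    max_genomes: int = 5,
    max_bins: int = 5,
    max_len: int = 10,
    unassign_prob: float = 0.3,
) -> tuple[GoldStandard, Binning]:
    """Small random (gold standard, binning) pair for oracle tests.

    Sequence lengths are uniform small integers so that base-pair
    metrics can be brute-forced by expanding sequences into items.
    """
    n_seqs = int(rng.integers(2, max_seqs + 1))
    n_genomes = int(rng.integers(1, max_genomes + 1))
    n_bins = int(rng.integers(1, max_bins + 1))
    assignment = {}
    lengths = {}
    bins = {}
    for i in range(n_seqs):
        sid = f"s{i:03d}"
        assignment[sid] = f"g{int(rng.integers(n_genomes))}"
        lengths[sid] = int(rng.integers(1, max_len + 1))
        if rng.random() > unassign_prob:
            bins[sid] = f"b{int(rng.integers(n_bins))}"
    gold = GoldStandard(assignment=assignment, seq_lengths=lengths)
    if not bins:  # ensure at least one assigned sequence
        sid = sorted(assignment)[0]
        bins[sid] = "b0"
    return gold, Binning(label="rand", assignment=bins)


def brute_force_ari(labels_x: np.ndarray, labels_y: np.ndarray) -> float:
    """Pair-counting adjusted Rand index, enumerating all item pairs.

    Counts, over every pair of items, co-membership agreement between
    the two labelings and applies the pair-count form
    ARI = 2(ad - bc) / ((a+b)(b+d) + (a+c)(c+d)).  Independent of the
    contingency-table route used by the implementation.
    """
    n = len(labels_x)
    assert n == len(labels_y)
    same_x = labels_x[:, None] == labels_x[None, :]
    same_y = labels_y[:, None] == labels_y[None, :]
    iu = np.triu_indices(n, k=1)
    sx, sy = same_x[iu], same_y[iu]
    a = int(np.sum(sx & sy))
    b = int(np.sum(sx & ~sy))
    c = int(np.sum(~sx & sy))
    d = int(np.sum(~sx & ~sy))
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        return 1.0 if b == 0 and c == 0 else 0.0
    return 2.0 * (a * d - b * c) / denom


def expand_items(
    gold: GoldStandard, binning: Binning, currency: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-item (bin, genome) labels of the assigned portion.

    For the base-pair currency every sequence is expanded into
    length_bp items, each carrying its sequence's labels.
    """
    xs, ys = [], []
    for sid in sorted(binning.assignment):
        if sid not in gold.assignment:
            continue
        reps = gold.seq_lengths[sid] if currency == "bp" else 1
        xs += [binning.assignment[sid]] * reps
        ys += [gold.assignment[sid]] * reps
    return np.asarray(xs), np.asarray(ys)
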