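"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's bitwise/lookup code paths:
contingency tables come from explicit per-sample Python loops and the
information measures from dictionary-of-probabilities arithmetic with
``math.log2``.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from epii.genotype_core import GenotypeMatrix, Phenotype, pack


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_pair_table(values: np.ndarray, i: int, j: int, labels: np.ndarray) -> np.ndarray:
    """Per-sample tally of the 4 x 4 x 2 pair contingency table."""
    counts = np.zeros((4, 4, 2), np.int64)
    for s in range(values.shape[0]):
        counts[values[s, i], values[s, j], labels[s]] += 1
    return counts


def brute_single_table(values: np.ndarray, i: int, labels: np.ndarray) -> np.ndarray:
    counts = np.zeros((4, 2), np.int64)
    for s in range(values.shape[0]):
        counts[values[s, i], labels[s]] += 1
    return counts


def brute_entropy(counts) -> float:
    """-sum p log2 p over the flattened table, 0 log 0 = 0."""
    flat = [float(c) for c in np.asarray(counts).ravel()]
    total = sum(flat)
    return -sum((c / total) * math.log2(c / total) for c in flat if c > 0)


def _marg(counts: np.ndarray, keep: tuple[int, ...]) -> np.ndarray:
    drop = tuple(ax for ax in range(counts.ndim) if ax not in keep)
    return counts.sum(axis=drop)


def brute_mi(counts) -> float:
    """I(X;C) from a 2-axis table via H(X) + H(C) - H(X, C)."""
    c = np.asarray(counts, float)
    return brute_entropy(c.sum(1)) + brute_entropy(c.sum(0)) - brute_entropy(c)


def brute_cmi(counts) -> float:
    """I(Y;X|Z) from a (Y, X, Z) table via the four-entropy identity."""
    c = np.asarray(counts, float)
    return (
        brute_entropy(_marg(c, (0, 2)))
        + brute_entropy(_marg(c, (1, 2)))
        - brute_entropy(c)
        - brute_entropy(_marg(c, (2,)))
    )


def brute_ii(counts) -> float:
    """I(X1;X2;C) from a (X1, X2, C) table via the seven-entropy identity."""
    c = np.asarray(counts, float)
    return (
        brute_entropy(_marg(c, (0, 1)))
        + brute_entropy(_marg(c, (0, 2)))
        + brute_entropy(_marg(c, (1, 2)))
        - brute_entropy(_marg(c, (0,)))
        - brute_entropy(_marg(c, (1,)))
        - brute_entropy(_marg(c, (2,)))
        - brute_entropy(c)
    )


# ---------------------------------------------------------------------------
# dataset builders
# ---------------------------------------------------------------------------

def make_dataset(values, labels) -> tuple[GenotypeMatrix, Phenotype]:
    values = np.asarray(values, np.uint8)
    n, p = values.shape
    gm = GenotypeMatrix(
        values=values,
        snp_ids=[f"snp{k + 1}" for k in range(p)],
        sample_ids=[f"s{k + 1}" for k in range(n)],
    )
    return gm, Phenotype(np.asarray(labels, np.uint8))


def random_dataset(rng, n: int, p: int, with_missing: bool = True):
    hi = 4 if with_missing else 3
    values = rng.integers(0, hi, (n, p)).astype(np.uint8)
    labels = rng.integers(0, 2, n).astype(np.uint8)
    if labels.min() == labels.max():  # both classes for scan paths
        labels[0] = 1 - labels[0]
    return make_dataset(values, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture
def xor_dataset():
    """3 SNPs, 4 samples: SNP1 ^ SNP2 == label, SNP3 constant."""
    rows = []
    labels = []
    for x1, x2 in itertools.product((0, 1), repeat=2):
        rows.append([x1, x2, 0])
        labels.append(x1 ^ x2)
    return make_dataset(rows, labels)


@pytest.fixture
def xor_packed(xor_dataset):
    gm, pheno = xor_dataset
    return pack(gm), pheno
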