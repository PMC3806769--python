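"""Permutation null of the maximum scan statistic and family-wise inference.

Phenotype labels are permuted uniformly (genotypes untouched, preserving LD
among SNPs) and the maximum statistic over the whole scan is recorded per
permutation.  Permutation ``b`` draws from an independent counter-derived
RNG substream ``(seed, b)``, so the null is reproducible and independent of
execution order or scan partitioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import episcan
from ._bitops import pack_bits
from .genotype_core import PackedGenotypeMatrix, Phenotype

__all__ = [
    "PermutationNull",
    "Threshold",
    "permutation_null",
    "select_threshold",
    "familywise_pvalue",
    "write_null",
    "read_null",
]


@dataclass
class PermutationNull:
    """B per-permutation maxima of a scan statistic under label shuffling."""

    kind: str  # "ii" or "mi"
    B: int
    maxima: np.ndarray  # length B, bits
    seed: int

    def __post_init__(self) -> None:
        self.maxima = np.asarray(self.maxima, dtype=np.float64)
        if self.maxima.shape != (self.B,):
            raise ValueError(
                f"expected {self.B} maxima, got shape {self.maxima.shape}"
            )

    @property
    def gamma_max(self) -> float:
        return float(self.maxima.max())


@dataclass
class Threshold:
    """Scan threshold derived from a permutation null."""

    gamma: float
    rule: str  # "strictly-above-max" or "multiplier"
    multiplier: float = 1.0


def _permuted_case_masks(labels: np.ndarray, B: int, seed: int) -> np.ndarray:
    """Packed case masks for B label permutations, substream (seed, b)."""
    n = labels.size
    masks = np.empty((B, (n + 63) // 64), np.uint64)
    for b in range(1, B + 1):
        rng = np.random.default_rng((seed, b))
        permuted = labels[rng.permutation(n)]
        masks[b - 1] = pack_bits(permuted == 1)
    return masks


def permutation_null(
    packed: PackedGenotypeMatrix,
    pheno: Phenotype,
    kind: str = "ii",
    B: int = 1000,
    seed: int = 0,
) -> PermutationNull:
    """Distribution of the max scan statistic under B label permutations.

    Each permutation preserves the case/control class counts (the label
    multiset is conserved); identical seeds give identical maxima vectors.
    """
    if B < 1:
        raise ValueError(f"number of permutations must be >= 1, got {B}")
    if kind not in ("ii", "mi"):
        raise ValueError(f"unknown statistic kind {kind!r} (expected 'ii' or 'mi')")
    if pheno.n_samples != packed.n_samples:
        raise ValueError(
            f"phenotype has {pheno.n_samples} labels for {packed.n_samples} samples"
        )
    if pheno.n_cases == 0 or pheno.n_controls == 0:
        raise ValueError("phenotype must contain both cases and controls")
    masks = _permuted_case_masks(pheno.labels, B, seed)
    maxima = episcan._max_multi(packed, masks, kind)
    return PermutationNull(kind=kind, B=B, maxima=maxima, seed=seed)


def select_threshold(
    null: PermutationNull, rule: str = "strictly-above-max", C: float = 1.0
) -> Threshold:
    """Derive the scan threshold gamma from a permutation null.

    ``strictly-above-max``: gamma equals the largest permutation maximum;
    hits must exceed it strictly, so any hit has family-wise p < 1/(B+1)...
    more precisely p-hat = 1/(B+1) under the add-one estimator.

    ``multiplier``: gamma = C * gamma_max (C < 1 is anti-conservative and
    triggers a warning).
    """
    if rule == "strictly-above-max":
        return Threshold(gamma=null.gamma_max, rule=rule, multiplier=1.0)
    if rule == "multiplier":
        if C < 1.0:
            warnings.warn(
                f"threshold multiplier C={C} < 1 is anti-conservative",
                stacklevel=2,
            )
        return Threshold(gamma=C * null.gamma_max, rule=rule, multiplier=C)
    raise ValueError(
        f"unknown threshold rule {rule!r} (expected 'strictly-above-max' or 'multiplier')"
    )


def familywise_pvalue(observed: float, null: PermutationNull) -> float:
    """Add-one family-wise p-value: (1 + #{maxima >= observed}) / (B + 1)."""
    r = int((null.maxima >= observed).sum())
    return (1 + r) / (null.B + 1)


def write_null(path, null: PermutationNull) -> None:
    """Write a permutation null as text: header lines then one max per line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kind\t{null.kind}\n# B\t{null.B}\n# seed\t{null.seed}\n")
        for v in null.maxima:
            fh.write(f"{float(v)!r}\n")


def read_null(path) -> PermutationNull:
    """Read a permutation null written by :func:`write_null`."""
    meta: dict[str, str] = {}
    maxima: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("\t")
                meta[key] = val
            else:
                maxima.append(float(line))
    try:
        return PermutationNull(
            kind=meta["kind"],
            B=int(meta["B"]),
            maxima=np.array(maxima),
            seed=int(meta["seed"]),
        )
    except KeyError as e:
        raise ValueError(f"{path}: missing header field {e.args[0]!r}") from None
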