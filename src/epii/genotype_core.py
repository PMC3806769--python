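"""Genotype data model, 2-bit packed encoding, contingency counting and I/O.

Genotypes are categorical with four states: 0, 1 and 2 count copies of the
minor allele and 3 marks a missing call.  Each SNP is stored as two bit
planes (high bit, low bit) across samples, so a genotype ``g`` at sample
``s`` is recovered as ``2 * high[s] + low[s]``.  Contingency tables are
computed by combining bit planes with bitwise AND and population counts,
which is exactly equivalent to a per-sample tally.

Missing genotypes are kept as a fourth category throughout; no samples are
dropped, so every count table over ``n`` samples sums to ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _bitops
from ._bitops import pack_bits, popcount, unpack_bits

MISSING = 3

#: tokens accepted as a missing genotype in the simple-tsv dialect
MISSING_TOKENS = frozenset({"NA", "-9", "3"})


class DatasetFormatError(ValueError):
    """Raised when an input file cannot be parsed in the declared dialect."""


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen = set()
        for x in ids:
            if x in seen:
                raise ValueError(f"duplicate {what} {x!r}")
            seen.add(x)


@dataclass
class GenotypeMatrix:
    """Dense ``n_samples x n_snps`` matrix of 2-bit genotype codes.

    Attributes
    ----------
    values
        uint8 array; every cell is one of ``{0, 1, 2, 3}``.
    snp_ids, sample_ids
        Unique identifiers matching the matrix dimensions.
    """

    values: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError(f"genotype matrix must be 2-D, got shape {values.shape}")
        if not np.issubdtype(values.dtype, np.integer):
            raise ValueError(f"genotype codes must be integers, got dtype {values.dtype}")
        bad = (values < 0) | (values > 3)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {int(values[r, c])} at sample row {r}, "
                f"SNP column {c} (expected 0, 1, 2 or 3)"
            )
        self.values = values.astype(np.uint8, copy=False)
        self.snp_ids = list(self.snp_ids)
        self.sample_ids = list(self.sample_ids)
        if len(self.snp_ids) != values.shape[1]:
            raise ValueError(
                f"{len(self.snp_ids)} SNP ids for {values.shape[1]} matrix columns"
            )
        if len(self.sample_ids) != values.shape[0]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {values.shape[0]} matrix rows"
            )
        _check_unique(self.snp_ids, "SNP id")
        _check_unique(self.sample_ids, "sample id")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


@dataclass
class Phenotype:
    """Binary case/control labels: 0 = control, 1 = case."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 1:
            raise ValueError("phenotype labels must be 1-D")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"phenotype labels must be integers, got {labels.dtype}")
        if labels.size and not np.isin(labels, (0, 1)).all():
            bad = labels[~np.isin(labels, (0, 1))][0]
            raise ValueError(f"phenotype labels must be 0 or 1, got {int(bad)}")
        self.labels = labels.astype(np.uint8, copy=False)

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return self.labels.size - self.n_cases

    def case_mask(self) -> np.ndarray:
        """Case indicator packed into uint64 words (padding bits zero)."""
        return pack_bits(self.labels == 1)


@dataclass
class PackedGenotypeMatrix:
    """Bit-plane representation of a :class:`GenotypeMatrix`.

    ``high[k]`` and ``low[k]`` are length-``n_samples`` bit vectors (packed
    into uint64 words) holding the high and low bit of SNP ``k``'s genotype
    for every sample.  Padding bits beyond ``n_samples`` are zero and are
    masked out of every population count.
    """

    high: np.ndarray  # (n_snps, n_words) uint64
    low: np.ndarray  # (n_snps, n_words) uint64
    n_samples: int
    snp_ids: list[str]
    sample_ids: list[str]
    _gmasks: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_snps(self) -> int:
        return self.high.shape[0]

    @property
    def n_words(self) -> int:
        return self.high.shape[1]

    def pad_mask(self) -> np.ndarray:
        return _bitops.pad_mask(self.n_samples)

    def genotype_masks(self) -> np.ndarray:
        """Per-SNP indicator bit vectors for each genotype state.

        Returns a ``(n_snps, 4, n_words)`` uint64 array where entry
        ``[k, g]`` has bit ``s`` set iff sample ``s`` carries genotype ``g``
        at SNP ``k``.  Padding bits are zero in all four planes.  The result
        is cached.
        """
        if self._gmasks is None:
            pm = self.pad_mask()
            hi, lo = self.high, self.low
            nhi, nlo = ~hi, ~lo
            self._gmasks = np.stack(
                [nhi & nlo & pm, nhi & lo, hi & nlo, hi & lo], axis=1
            )
        return self._gmasks

    def unpack(self) -> GenotypeMatrix:
        return unpack(self)


def pack(genotypes: GenotypeMatrix) -> PackedGenotypeMatrix:
    """Pack a genotype matrix into per-SNP bit planes.

    Round-trips exactly: ``unpack(pack(gm)).values == gm.values``.
    """
    v = genotypes.values.T  # (n_snps, n_samples)
    high = pack_bits((v >> 1) & 1)
    low = pack_bits(v & 1)
    return PackedGenotypeMatrix(
        high=high,
        low=low,
        n_samples=genotypes.n_samples,
        snp_ids=list(genotypes.snp_ids),
        sample_ids=list(genotypes.sample_ids),
    )


def unpack(packed: PackedGenotypeMatrix) -> GenotypeMatrix:
    """Inverse of :func:`pack`."""
    hi = unpack_bits(packed.high, packed.n_samples)
    lo = unpack_bits(packed.low, packed.n_samples)
    values = (2 * hi + lo).T.astype(np.uint8)
    return GenotypeMatrix(
        values=values,
        snp_ids=list(packed.snp_ids),
        sample_ids=list(packed.sample_ids),
    )


def _check_snp_index(packed: PackedGenotypeMatrix, i: int) -> None:
    if not 0 <= i < packed.n_snps:
        raise IndexError(f"SNP index {i} out of range for {packed.n_snps} SNPs")


def _check_pheno(packed: PackedGenotypeMatrix, pheno: Phenotype) -> None:
    if pheno.n_samples != packed.n_samples:
        raise ValueError(
            f"phenotype has {pheno.n_samples} labels for {packed.n_samples} samples"
        )


def pair_contingency(
    packed: PackedGenotypeMatrix, i: int, j: int, pheno: Phenotype
) -> np.ndarray:
    """4 x 4 x 2 count table (genotype at SNP i, genotype at SNP j, phenotype).

    Computed with bitwise AND of the genotype indicator planes and the
    phenotype mask followed by population counts; identical to the naive
    per-sample tally.  The 32 cells sum to ``n_samples``.
    """
    if i == j:
        raise ValueError(f"pair_contingency requires two distinct SNPs, got i == j == {i}")
    _check_snp_index(packed, i)
    _check_snp_index(packed, j)
    _check_pheno(packed, pheno)
    gmasks = packed.genotype_masks()
    case = pheno.case_mask()
    ctrl = ~case & packed.pad_mask()
    ab = gmasks[i][:, None, :] & gmasks[j][None, :, :]  # (4, 4, W)
    counts = np.empty((4, 4, 2), np.int64)
    counts[:, :, 0] = popcount(ab & ctrl).sum(-1, dtype=np.int64)
    counts[:, :, 1] = popcount(ab & case).sum(-1, dtype=np.int64)
    return counts


def single_contingency(
    packed: PackedGenotypeMatrix, i: int, pheno: Phenotype
) -> np.ndarray:
    """4 x 2 count table (genotype at SNP i, phenotype)."""
    _check_snp_index(packed, i)
    _check_pheno(packed, pheno)
    gmask = packed.genotype_masks()[i]  # (4, W)
    case = pheno.case_mask()
    ctrl = ~case & packed.pad_mask()
    counts = np.empty((4, 2), np.int64)
    counts[:, 0] = popcount(gmask & ctrl).sum(-1, dtype=np.int64)
    counts[:, 1] = popcount(gmask & case).sum(-1, dtype=np.int64)
    return counts


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def read_dataset(path, fmt: str = "simple-tsv") -> tuple[GenotypeMatrix, Phenotype]:
    """Read a case-control genotype dataset.

    ``simple-tsv``: tab-separated, header row; first column sample id, last
    column phenotype in {0, 1}, middle columns genotype codes with missing
    tokens "NA", "-9" or "3".

    ``plink-raw``: whitespace-separated PLINK additive recode (``--recode A``)
    text; phenotype 1/2 is mapped to 0/1 and "NA" genotypes to code 3.
    """
    if fmt == "simple-tsv":
        return _read_simple_tsv(path)
    if fmt == "plink-raw":
        return _read_plink_raw(path)
    raise ValueError(f"unknown dataset format {fmt!r} (expected 'simple-tsv' or 'plink-raw')")


def _parse_genotype_token(tok: str, path, lineno: int, col: str) -> int:
    if tok in ("0", "1", "2"):
        return int(tok)
    if tok in MISSING_TOKENS:
        return MISSING
    raise DatasetFormatError(
        f"{path}:{lineno}: unknown genotype token {tok!r} in column {col!r}"
    )


def _read_simple_tsv(path) -> tuple[GenotypeMatrix, Phenotype]:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise DatasetFormatError(f"{path}:1: empty file")
    header = lines[0].split("\t")
    if len(header) < 3:
        raise DatasetFormatError(
            f"{path}:1: header needs at least sample id, one SNP and a phenotype column"
        )
    if header[-1].lower() not in ("phenotype", "pheno", "label", "class"):
        raise DatasetFormatError(
            f"{path}:1: last header column must be the phenotype, got {header[-1]!r}"
        )
    snp_ids = header[1:-1]
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    labels: list[int] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise DatasetFormatError(
                f"{path}:{lineno}: ragged row with {len(fields)} fields, "
                f"expected {len(header)}"
            )
        sample_ids.append(fields[0])
        rows.append(
            [
                _parse_genotype_token(tok, path, lineno, snp)
                for tok, snp in zip(fields[1:-1], snp_ids)
            ]
        )
        ptok = fields[-1]
        if ptok not in ("0", "1"):
            raise DatasetFormatError(
                f"{path}:{lineno}: phenotype must be 0 or 1, got {ptok!r}"
            )
        labels.append(int(ptok))
    if not rows:
        raise DatasetFormatError(f"{path}: no sample rows found")
    gm = GenotypeMatrix(
        values=np.array(rows, np.uint8), snp_ids=snp_ids, sample_ids=sample_ids
    )
    return gm, Phenotype(np.array(labels, np.uint8))


_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def _read_plink_raw(path) -> tuple[GenotypeMatrix, Phenotype]:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise DatasetFormatError(f"{path}:1: empty file")
    header = lines[0].split()
    if len(header) < 7 or tuple(header[:6]) != _PLINK_META:
        raise DatasetFormatError(
            f"{path}:1: expected PLINK .raw header starting with "
            f"{' '.join(_PLINK_META)}"
        )
    # column names look like "rs123_A"; strip the counted-allele suffix
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in header[6:]]
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    labels: list[int] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != len(header):
            raise DatasetFormatError(
                f"{path}:{lineno}: ragged row with {len(fields)} fields, "
                f"expected {len(header)}"
            )
        sample_ids.append(f"{fields[0]}_{fields[1]}")
        ptok = fields[5]
        if ptok == "1":
            labels.append(0)
        elif ptok == "2":
            labels.append(1)
        else:
            raise DatasetFormatError(
                f"{path}:{lineno}: PLINK phenotype must be 1 (control) or 2 (case), "
                f"got {ptok!r}"
            )
        row = []
        for tok, snp in zip(fields[6:], snp_ids):
            if tok == "NA":
                row.append(MISSING)
            elif tok in ("0", "1", "2"):
                row.append(int(tok))
            else:
                raise DatasetFormatError(
                    f"{path}:{lineno}: unknown genotype token {tok!r} in column {snp!r}"
                )
        rows.append(row)
    if not rows:
        raise DatasetFormatError(f"{path}: no sample rows found")
    gm = GenotypeMatrix(
        values=np.array(rows, np.uint8), snp_ids=snp_ids, sample_ids=sample_ids
    )
    return gm, Phenotype(np.array(labels, np.uint8))


def write_dataset(path, genotypes: GenotypeMatrix, pheno: Phenotype) -> None:
    """Write a dataset in the simple-tsv dialect (missing cells as "NA")."""
    if pheno.n_samples != genotypes.n_samples:
        raise ValueError("phenotype length does not match genotype matrix")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\t" + "\t".join(genotypes.snp_ids) + "\tphenotype\n")
        for s, sid in enumerate(genotypes.sample_ids):
            cells = [
                "NA" if g == MISSING else str(int(g)) for g in genotypes.values[s]
            ]
            fh.write(sid + "\t" + "\t".join(cells) + f"\t{int(pheno.labels[s])}\n")
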