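"""Exhaustive pairwise interaction-information scan and single-SNP MI scan.

The scan enumerates all C(p, 2) unordered SNP pairs in lexicographic order,
builds each pair's 4 x 4 x 2 contingency table with bitwise AND/popcount over
the packed genotype planes, and evaluates interaction information from
integer counts through a precomputed ``k * log2(k)`` table.  Everything is
deterministic: rescanning the same input reproduces values bit for bit.

Reported SNP positions are 1-based; in-memory indices are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._bitops import popcount
from .genotype_core import PackedGenotypeMatrix, Phenotype
from .infotheory import InfoValue

__all__ = [
    "InteractionHit",
    "SingleHit",
    "ScanResult",
    "scan_pairs",
    "scan_singles",
    "max_statistic",
    "pair_values",
    "single_values",
    "export_gene_graph",
    "write_hits_tsv",
    "read_hits_tsv",
    "write_edge_list",
]

# ---------------------------------------------------------------------------
# integer-count statistics
# ---------------------------------------------------------------------------

_XLOGX_CACHE: dict[int, np.ndarray] = {}


def _xlogx_table(n: int) -> np.ndarray:
    """Lookup table T[k] = k * log2(k) for k = 0..n (T[0] = 0)."""
    t = _XLOGX_CACHE.get(n)
    if t is None:
        k = np.arange(1, n + 1, dtype=np.float64)
        t = np.zeros(n + 1)
        t[1:] = k * np.log2(k)
        _XLOGX_CACHE[n] = t
    return t


def _ii_from_class_counts(case, ctrl, n: int, T: np.ndarray) -> np.ndarray:
    """Interaction information for stacked pair tables.

    ``case`` and ``ctrl`` hold integer counts of shape ``(..., G, G)`` over
    (genotype_i, genotype_j) for each phenotype class; ``n`` is the total
    sample count of every table.
    """
    c12 = case + ctrl
    s3 = T[case].sum((-1, -2)) + T[ctrl].sum((-1, -2))
    s12 = T[c12].sum((-1, -2))
    a1 = case.sum(-1)
    b1 = ctrl.sum(-1)
    s1c = T[a1].sum(-1) + T[b1].sum(-1)
    a2 = case.sum(-2)
    b2 = ctrl.sum(-2)
    s2c = T[a2].sum(-1) + T[b2].sum(-1)
    s1 = T[a1 + b1].sum(-1)
    s2 = T[a2 + b2].sum(-1)
    ncase = a1.sum(-1)
    sc = T[ncase] + T[n - ncase]
    return (s1 + s2 + sc - s12 - s1c - s2c + s3) / n - math.log2(n)


def _mi_from_class_counts(case, ctrl, n: int, T: np.ndarray) -> np.ndarray:
    """Mutual information for stacked single-SNP tables of shape (..., G)."""
    sx = T[case + ctrl].sum(-1)
    sxc = T[case].sum(-1) + T[ctrl].sum(-1)
    ncase = case.sum(-1)
    sc = T[ncase] + T[n - ncase]
    v = math.log2(n) - (sx + sc - sxc) / n
    return np.maximum(v, 0.0)


# ---------------------------------------------------------------------------
# blocked pair enumeration
# ---------------------------------------------------------------------------

def _pair_index_chunks(p: int, chunk: int):
    """Yield (ii, jj) index arrays covering all i < j pairs lexicographically."""
    buf_i: list[np.ndarray] = []
    buf_j: list[np.ndarray] = []
    size = 0
    for i in range(p - 1):
        m = p - i - 1
        buf_i.append(np.full(m, i, dtype=np.intp))
        buf_j.append(np.arange(i + 1, p, dtype=np.intp))
        size += m
        if size >= chunk:
            yield np.concatenate(buf_i), np.concatenate(buf_j)
            buf_i, buf_j, size = [], [], 0
    if size:
        yield np.concatenate(buf_i), np.concatenate(buf_j)


def _iter_pair_blocks(gmasks: np.ndarray, class_masks: np.ndarray, *, word_budget: int = 4_000_000):
    """Iterate pair blocks yielding (ii, jj, tot, case).

    ``class_masks`` has shape (K, W); ``case`` comes back as integer counts
    of shape (m, K, 4, 4) and ``tot`` as (m, 4, 4) (class-independent).
    The word budget bounds the size of intermediate popcount buffers.
    """
    p, _, w = gmasks.shape
    K = class_masks.shape[0]
    chunk = max(16, word_budget // max(1, K * 16 * w))
    kchunk = max(1, word_budget // max(1, chunk * 16 * w))
    for ii, jj in _pair_index_chunks(p, chunk):
        ab = gmasks[ii][:, :, None, :] & gmasks[jj][:, None, :, :]  # (m,4,4,W)
        tot = popcount(ab).sum(-1, dtype=np.int64)
        m = ii.size
        case = np.empty((m, K, 4, 4), np.int64)
        for k0 in range(0, K, kchunk):
            sel = class_masks[k0 : k0 + kchunk]
            case[:, k0 : k0 + kchunk] = (
                popcount(ab[:, None] & sel[None, :, None, None, :])
                .sum(-1, dtype=np.int64)
            )
        yield ii, jj, tot, case


def _single_class_counts(gmasks: np.ndarray, class_masks: np.ndarray):
    """Return (tot (p,4), case (p,K,4)) genotype counts per SNP and class."""
    tot = popcount(gmasks).sum(-1, dtype=np.int64)
    case = popcount(gmasks[:, None] & class_masks[None, :, None, :]).sum(
        -1, dtype=np.int64
    )
    return tot, case


def _prepare(packed: PackedGenotypeMatrix, pheno: Phenotype, min_snps: int = 1):
    if pheno.n_samples != packed.n_samples:
        raise ValueError(
            f"phenotype has {pheno.n_samples} labels for {packed.n_samples} samples"
        )
    if packed.n_snps < min_snps:
        raise ValueError(f"scan requires at least {min_snps} SNPs, got {packed.n_snps}")
    if pheno.n_cases == 0 or pheno.n_controls == 0:
        raise ValueError("phenotype must contain both cases and controls")
    return packed.genotype_masks(), pheno.case_mask()


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------

@dataclass
class InteractionHit:
    """A SNP pair whose interaction information exceeded the threshold."""

    snp_i: str
    snp_j: str
    pos_i: int  # 1-based
    pos_j: int  # 1-based
    value: float  # bits
    pvalue: float | None = None

    @property
    def pair(self) -> tuple[int, int]:
        """Canonical (pos_i, pos_j) with pos_i < pos_j, 1-based."""
        return (self.pos_i, self.pos_j)


@dataclass
class SingleHit:
    """A single SNP whose mutual information exceeded the threshold."""

    snp: str
    pos: int  # 1-based
    value: float  # bits
    pvalue: float | None = None


@dataclass
class ScanResult:
    """Outcome of an exhaustive scan.

    ``hits`` contains exactly the items with value strictly above ``gamma``,
    sorted by descending value (ties by position).  ``maximum`` is the global
    arg-max regardless of the threshold, with lexicographic tie-breaking.
    """

    kind: str  # "ii" or "mi"
    gamma: float
    hits: list = field(default_factory=list)
    maximum: InteractionHit | SingleHit | None = None
    n_snps: int = 0
    n_evaluated: int = 0

    @property
    def max_value(self) -> float:
        return self.maximum.value if self.maximum is not None else math.nan


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def pair_values(packed: PackedGenotypeMatrix, pheno: Phenotype):
    """Interaction information for every SNP pair.

    Returns ``(ii, jj, values)`` with 0-based index arrays in lexicographic
    order and one value per pair.  Mostly useful for plots and diagnostics;
    prefer :func:`scan_pairs` for thresholded reporting.
    """
    gmasks, case_mask = _prepare(packed, pheno, min_snps=2)
    n = packed.n_samples
    T = _xlogx_table(n)
    out_i, out_j, out_v = [], [], []
    for ii, jj, tot, case in _iter_pair_blocks(gmasks, case_mask[None]):
        vals = _ii_from_class_counts(case[:, 0], tot - case[:, 0], n, T)
        out_i.append(ii)
        out_j.append(jj)
        out_v.append(vals)
    return np.concatenate(out_i), np.concatenate(out_j), np.concatenate(out_v)


def single_values(packed: PackedGenotypeMatrix, pheno: Phenotype) -> np.ndarray:
    """Mutual information with the phenotype for every SNP (length p)."""
    gmasks, case_mask = _prepare(packed, pheno)
    n = packed.n_samples
    T = _xlogx_table(n)
    tot, case = _single_class_counts(gmasks, case_mask[None])
    return _mi_from_class_counts(case[:, 0], tot - case[:, 0], n, T)


def scan_pairs(
    packed: PackedGenotypeMatrix, pheno: Phenotype, gamma: float
) -> ScanResult:
    """Exhaustive pairwise interaction-information scan.

    Evaluates all C(p, 2) unordered pairs and reports exactly those with
    interaction information strictly greater than ``gamma``.
    """
    gmasks, case_mask = _prepare(packed, pheno, min_snps=2)
    n = packed.n_samples
    p = packed.n_snps
    T = _xlogx_table(n)
    best_val = -math.inf
    best_pair: tuple[int, int] | None = None
    hit_i: list[np.ndarray] = []
    hit_j: list[np.ndarray] = []
    hit_v: list[np.ndarray] = []
    n_eval = 0
    for ii, jj, tot, case in _iter_pair_blocks(gmasks, case_mask[None]):
        vals = _ii_from_class_counts(case[:, 0], tot - case[:, 0], n, T)
        n_eval += vals.size
        k = int(np.argmax(vals))
        if vals[k] > best_val:  # strict: earlier (lexicographic) pair wins ties
            best_val = float(vals[k])
            best_pair = (int(ii[k]), int(jj[k]))
        sel = vals > gamma
        if sel.any():
            hit_i.append(ii[sel])
            hit_j.append(jj[sel])
            hit_v.append(vals[sel])
    hits = []
    if hit_v:
        hi = np.concatenate(hit_i)
        hj = np.concatenate(hit_j)
        hv = np.concatenate(hit_v)
        order = np.lexsort((hj, hi, -hv))
        hits = [
            InteractionHit(
                snp_i=packed.snp_ids[int(i)],
                snp_j=packed.snp_ids[int(j)],
                pos_i=int(i) + 1,
                pos_j=int(j) + 1,
                value=float(v),
            )
            for i, j, v in zip(hi[order], hj[order], hv[order])
        ]
    maximum = None
    if best_pair is not None:
        maximum = InteractionHit(
            snp_i=packed.snp_ids[best_pair[0]],
            snp_j=packed.snp_ids[best_pair[1]],
            pos_i=best_pair[0] + 1,
            pos_j=best_pair[1] + 1,
            value=best_val,
        )
    return ScanResult(
        kind="ii", gamma=gamma, hits=hits, maximum=maximum, n_snps=p, n_evaluated=n_eval
    )


def scan_singles(
    packed: PackedGenotypeMatrix, pheno: Phenotype, gamma: float
) -> ScanResult:
    """Single-SNP mutual-information scan (thresholded like :func:`scan_pairs`)."""
    vals = single_values(packed, pheno)
    best = int(np.argmax(vals))
    order = np.lexsort((np.arange(vals.size), -vals))
    hits = [
        SingleHit(snp=packed.snp_ids[int(k)], pos=int(k) + 1, value=float(vals[k]))
        for k in order
        if vals[k] > gamma
    ]
    maximum = SingleHit(
        snp=packed.snp_ids[best], pos=best + 1, value=float(vals[best])
    )
    return ScanResult(
        kind="mi",
        gamma=gamma,
        hits=hits,
        maximum=maximum,
        n_snps=packed.n_snps,
        n_evaluated=int(vals.size),
    )


def max_statistic(
    packed: PackedGenotypeMatrix, pheno: Phenotype, kind: str = "ii"
):
    """Maximum scan statistic without storing per-pair values.

    Returns ``((pos_i, pos_j), value)`` for ``kind="ii"`` or
    ``(pos, value)`` for ``kind="mi"``; positions are 1-based and ties go to
    the lexicographically smallest pair / smallest position.
    """
    if kind == "ii":
        res = scan_pairs(packed, pheno, gamma=math.inf)
        return (res.maximum.pos_i, res.maximum.pos_j), res.maximum.value
    if kind == "mi":
        res = scan_singles(packed, pheno, gamma=math.inf)
        return res.maximum.pos, res.maximum.value
    raise ValueError(f"unknown statistic kind {kind!r} (expected 'ii' or 'mi')")


def _max_multi(
    packed: PackedGenotypeMatrix, class_masks: np.ndarray, kind: str
) -> np.ndarray:
    """Maximum scan statistic for each of K phenotype masks at once.

    Fast path for permutation nulls: the genotype-pair AND planes are built
    once per block and reused across all masks.  Returns a length-K vector.
    """
    gmasks = packed.genotype_masks()
    n = packed.n_samples
    T = _xlogx_table(n)
    K = class_masks.shape[0]
    maxima = np.full(K, -math.inf)
    if kind == "ii":
        for _, _, tot, case in _iter_pair_blocks(gmasks, class_masks):
            vals = _ii_from_class_counts(case, tot[:, None] - case, n, T)  # (m, K)
            np.maximum(maxima, vals.max(0), out=maxima)
    elif kind == "mi":
        tot, case = _single_class_counts(gmasks, class_masks)
        vals = _mi_from_class_counts(case, tot[:, None] - case, n, T)  # (p, K)
        np.maximum(maxima, vals.max(0), out=maxima)
    else:
        raise ValueError(f"unknown statistic kind {kind!r} (expected 'ii' or 'mi')")
    return maxima


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

_HITS_HEADER = "snp_i\tsnp_j\tposition_i\tposition_j\tii_bits\tpvalue"


def write_hits_tsv(path, result: ScanResult) -> None:
    """Write scan hits as TSV (pair scans: 6 columns; single scans: 4)."""
    with open(path, "w", encoding="utf-8") as fh:
        if result.kind == "ii":
            fh.write(_HITS_HEADER + "\n")
            for h in result.hits:
                pv = "NA" if h.pvalue is None else repr(h.pvalue)
                fh.write(
                    f"{h.snp_i}\t{h.snp_j}\t{h.pos_i}\t{h.pos_j}\t{h.value!r}\t{pv}\n"
                )
        else:
            fh.write("snp\tposition\tmi_bits\tpvalue\n")
            for h in result.hits:
                pv = "NA" if h.pvalue is None else repr(h.pvalue)
                fh.write(f"{h.snp}\t{h.pos}\t{h.value!r}\t{pv}\n")


def read_hits_tsv(path) -> list[InteractionHit]:
    """Read a pair-hit TSV written by :func:`write_hits_tsv`."""
    hits: list[InteractionHit] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != _HITS_HEADER:
            raise ValueError(f"{path}: not a pair-hit TSV (header {header!r})")
        for line in fh:
            if not line.strip():
                continue
            si, sj, pi, pj, v, pv = line.rstrip("\n").split("\t")
            hits.append(
                InteractionHit(
                    snp_i=si,
                    snp_j=sj,
                    pos_i=int(pi),
                    pos_j=int(pj),
                    value=float(v),
                    pvalue=None if pv == "NA" else float(pv),
                )
            )
    return hits


def export_gene_graph(
    hits: list[InteractionHit], snp_to_gene: dict[str, str] | None = None
) -> nx.Graph:
    """Build the gene-gene interaction graph from pair hits.

    One node per gene (falling back to the SNP id when unmapped), one edge
    per hit; repeated gene pairs accumulate in the edge ``weight``.  A hit
    whose SNPs map to the same gene becomes a self-loop.
    """
    snp_to_gene = snp_to_gene or {}
    g = nx.Graph()
    for h in hits:
        a = snp_to_gene.get(h.snp_i, h.snp_i)
        b = snp_to_gene.get(h.snp_j, h.snp_j)
        if g.has_edge(a, b):
            g[a][b]["weight"] += 1
        else:
            g.add_edge(a, b, weight=1)
    return g


def write_edge_list(path, graph: nx.Graph) -> None:
    """Write the graph as a weighted edge-list TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('weight', 1)}\n")
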