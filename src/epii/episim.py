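"""Penetrance-table simulator for case-control data with planted epistasis.

A two-locus model is a 3x3 penetrance table ``f[i, j] = P(disease | g_a=i,
g_b=j)`` with genotype codes counting minor alleles, plus per-locus minor
allele frequencies.  Genotype priors are Hardy-Weinberg and loci are
independent, so prevalence and heritability follow by direct summation over
the nine cells.

The zero-marginal constructor builds tables whose per-locus marginal
penetrances are all equal to the prevalence, so the disease loci carry no
single-SNP signal and all association lives in the pair.  It parametrizes
the table as ``f = K + e`` with ``e`` in the exact null space of the
weighted marginal constraints, scales ``e`` to hit the target heritability,
and falls back to an enumerated optimal direction when a seeded random
direction leaves the [0, 1] box.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from .genotype_core import GenotypeMatrix, Phenotype

__all__ = [
    "PenetranceModel",
    "HybridModel",
    "TruthRecord",
    "SimulatedDataset",
    "hwe_probs",
    "prevalence",
    "heritability",
    "marginal_penetrance",
    "build_zero_marginal_model",
    "xor_model",
    "load_model_csv",
    "save_model_csv",
    "simulate_pure",
    "simulate_hybrid",
    "DEFAULT_HYBRID_POSITIONS",
]

#: 1-based positions of the five planted pairs in hybrid datasets
DEFAULT_HYBRID_POSITIONS = ((1, 100), (201, 300), (401, 500), (601, 700), (801, 900))


def _check_maf(maf: float) -> float:
    maf = float(maf)
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"minor allele frequency must be in (0, 0.5], got {maf}")
    return maf


def _genotype_probs(maf: float) -> np.ndarray:
    """HWE genotype probabilities indexed by minor-allele count 0, 1, 2."""
    q = _check_maf(maf)
    p = 1.0 - q
    return np.array([p * p, 2.0 * p * q, q * q])


def hwe_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities (q^2, 2pq, p^2).

    Ordered by minor-allele count 2, 1, 0 with ``q = maf``; always sums to 1.
    """
    return _genotype_probs(maf)[::-1]


@dataclass
class PenetranceModel:
    """3x3 penetrance table with per-locus minor allele frequencies.

    ``f[i, j]`` is the disease probability for ``i`` minor alleles at locus A
    and ``j`` at locus B.
    """

    f: np.ndarray
    maf_a: float
    maf_b: float

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=np.float64)
        if f.shape != (3, 3):
            raise ValueError(f"penetrance table must be 3x3, got shape {f.shape}")
        if (f < 0).any() or (f > 1).any():
            raise ValueError("penetrance entries must lie in [0, 1]")
        self.f = f
        self.maf_a = _check_maf(self.maf_a)
        self.maf_b = _check_maf(self.maf_b)

    def genotype_probs(self, locus: str) -> np.ndarray:
        """HWE probabilities indexed by minor-allele count 0, 1, 2."""
        if locus == "a":
            return _genotype_probs(self.maf_a)
        if locus == "b":
            return _genotype_probs(self.maf_b)
        raise ValueError(f"locus must be 'a' or 'b', got {locus!r}")

    def prevalence(self) -> float:
        return prevalence(self)

    def heritability(self) -> float:
        return heritability(self)

    def table_hash(self) -> str:
        h = hashlib.sha1()
        h.update(np.round(self.f, 12).tobytes())
        h.update(repr((round(self.maf_a, 12), round(self.maf_b, 12))).encode())
        return h.hexdigest()[:12]


def prevalence(model: PenetranceModel) -> float:
    """Population disease prevalence K under HWE-independent loci."""
    pa = model.genotype_probs("a")
    pb = model.genotype_probs("b")
    return float(pa @ model.f @ pb)


def heritability(model: PenetranceModel) -> float:
    """Variance-explained heritability of a binary penetrance model.

    h2 = sum_ij P(i) P(j) (f[i,j] - K)^2 / (K (1 - K)).  Undefined when the
    prevalence is degenerate (K = 0 or 1).
    """
    pa = model.genotype_probs("a")
    pb = model.genotype_probs("b")
    k = float(pa @ model.f @ pb)
    if k <= 0.0 or k >= 1.0:
        raise ValueError(f"heritability undefined for prevalence K={k}")
    w = np.outer(pa, pb)
    return float((w * (model.f - k) ** 2).sum() / (k * (1.0 - k)))


def marginal_penetrance(model: PenetranceModel, locus: str) -> np.ndarray:
    """Per-genotype marginal penetrance at one locus (3 values).

    For locus "a": ``m[i] = sum_j P(g_b=j) f[i, j]``.  A zero-marginal model
    has all three values equal to the prevalence at both loci.
    """
    if locus == "a":
        return model.f @ model.genotype_probs("b")
    if locus == "b":
        return model.f.T @ model.genotype_probs("a")
    raise ValueError(f"locus must be 'a' or 'b', got {locus!r}")


# ---------------------------------------------------------------------------
# zero-marginal model construction
# ---------------------------------------------------------------------------

def _balance_null_basis(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Orthonormal basis (9 x 4) of marginal-balanced 3x3 perturbations.

    A perturbation ``e`` is balanced when every weighted row sum
    ``sum_j pb[j] e[i, j]`` and column sum ``sum_i pa[i] e[i, j]`` vanishes,
    which keeps both marginal penetrances flat when added to a constant table.
    """
    a = np.zeros((6, 9))
    for i in range(3):
        a[i, 3 * i : 3 * i + 3] = pb
    for j in range(3):
        a[3 + j, j::3] = pa
    basis = null_space(a)
    if basis.shape[1] != 4:  # pragma: no cover - degenerate maf cannot occur
        raise RuntimeError("unexpected null-space dimension")
    return basis


def _weighted_norm(e: np.ndarray, w: np.ndarray) -> float:
    return float(np.sqrt((w * e * e).sum()))


def _feasible(k: float, e: np.ndarray, slack: float = 0.0) -> bool:
    f = k + e
    return bool((f >= -slack).all() and (f <= 1.0 + slack).all())


def _best_direction(pa: np.ndarray, pb: np.ndarray, k: float) -> np.ndarray:
    """Balanced perturbation maximizing weighted variance within the box.

    Maximizes ``sum_ij pa[i] pb[j] e[i,j]^2`` over the 4-dimensional balanced
    subspace intersected with ``-K <= e <= 1-K``.  The objective is convex,
    so the optimum sits at a polytope vertex; vertices are enumerated as
    solutions of four active bound constraints.
    """
    basis = _balance_null_basis(pa, pb)  # (9, 4)
    w = np.outer(pa, pb).ravel()
    lo, hi = -k, 1.0 - k
    best_val = -1.0
    best_e: np.ndarray | None = None
    cells = range(9)
    for combo in itertools.combinations(cells, 4):
        m = basis[list(combo)]  # (4, 4)
        if abs(np.linalg.det(m)) < 1e-12:
            continue
        for signs in itertools.product((lo, hi), repeat=4):
            x = np.linalg.solve(m, np.asarray(signs))
            e = basis @ x
            if (e < lo - 1e-9).any() or (e > hi + 1e-9).any():
                continue
            val = float(w @ (e * e))
            if val > best_val:
                best_val = val
                best_e = np.clip(e, lo, hi)
    if best_e is None:  # pragma: no cover - polytope always has vertices
        raise RuntimeError("vertex enumeration failed")
    return best_e.reshape(3, 3)


def max_heritability(maf: float, prevalence: float = 0.5) -> float:
    """Largest target heritability reachable by a zero-marginal model."""
    pa = pb = _genotype_probs(maf)
    k = float(prevalence)
    e = _best_direction(pa, pb, k)
    w = np.outer(pa, pb)
    return float((w * e * e).sum() / (k * (1.0 - k)))


def _build_at_prevalence(
    maf: float,
    target_h2: float,
    k: float,
    rng: np.random.Generator,
    max_tries: int,
) -> PenetranceModel | None:
    """Try to build a zero-marginal model at a fixed prevalence K.

    Random seeded directions in the balanced subspace come first; when the
    [0, 1] box rejects all of them, the enumerated best direction (blended
    toward the first random one for seed variety) is used.  Returns ``None``
    when the target heritability is unreachable at this K.
    """
    pa = pb = _genotype_probs(maf)
    w = np.outer(pa, pb)
    basis = _balance_null_basis(pa, pb)
    s = float(np.sqrt(target_h2 * k * (1.0 - k)))

    def finish(e: np.ndarray) -> PenetranceModel:
        return PenetranceModel(f=np.clip(k + e, 0.0, 1.0), maf_a=maf, maf_b=maf)

    first_delta: np.ndarray | None = None
    for _ in range(max_tries):
        delta = (basis @ rng.standard_normal(4)).reshape(3, 3)
        nrm = _weighted_norm(delta, w)
        if nrm < 1e-12:
            continue
        delta /= nrm
        if first_delta is None:
            first_delta = delta
        if _feasible(k, s * delta):
            return finish(s * delta)

    e_star = _best_direction(pa, pb, k)
    star_norm = _weighted_norm(e_star, w)
    if s > star_norm + 1e-12:
        return None
    d_star = e_star / star_norm
    for t in (0.5, 0.25, 0.1, 0.05, 0.0):
        delta = (1.0 - t) * d_star + t * first_delta
        nrm = _weighted_norm(delta, w)
        if nrm < 1e-12:
            continue
        delta /= nrm
        if _feasible(k, s * delta):
            return finish(s * delta)
    return finish(s * d_star)  # t = 0 is feasible by construction


def build_zero_marginal_model(
    maf: float,
    target_h2: float,
    seed=0,
    prevalence: float | None = None,
    max_tries: int = 200,
) -> PenetranceModel:
    """Construct a penetrance model with no marginal effects at either locus.

    The returned model satisfies ``max |marginal - K| < 1e-8`` at both loci
    and ``|heritability - target_h2| < 1e-6``; identical seeds give identical
    tables.  With ``prevalence=None`` the prevalence defaults to 0.5 but is
    searched outward over a grid when the [0, 1] bound on penetrance makes
    the target unreachable there (high heritability at low MAF needs an
    asymmetric prevalence).  An explicit ``prevalence`` is honored strictly;
    ``ValueError`` is raised when no feasible table exists.
    """
    maf = _check_maf(maf)
    if not 0.0 < target_h2 < 1.0:
        raise ValueError(f"target heritability must be in (0, 1), got {target_h2}")
    rng = np.random.default_rng(seed)
    if prevalence is not None:
        k = float(prevalence)
        if not 0.0 < k < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {k}")
        model = _build_at_prevalence(maf, target_h2, k, rng, max_tries)
        if model is None:
            raise ValueError(
                f"target heritability {target_h2} is infeasible for maf={maf} "
                f"at prevalence {k} (max achievable ~ "
                f"{max_heritability(maf, k):.4f})"
            )
        return model
    # grid outward from 0.5; first feasible K wins
    ks = [0.5]
    for step in range(1, 9):
        ks += [0.5 + 0.05 * step, 0.5 - 0.05 * step]
    best_reachable = 0.0
    for i, k in enumerate(ks):
        model = _build_at_prevalence(
            maf, target_h2, k, rng, max_tries if i == 0 else max(20, max_tries // 4)
        )
        if model is not None:
            return model
        best_reachable = max(best_reachable, max_heritability(maf, k))
    raise ValueError(
        f"target heritability {target_h2} is infeasible for maf={maf} at any "
        f"prevalence on the search grid (max achievable ~ {best_reachable:.4f})"
    )


def xor_model(maf: float, target_h2: float, prevalence: float = 0.5) -> PenetranceModel:
    """Canonical checkerboard zero-marginal model (XOR-type pattern).

    Deterministic rank-one construction: heterozygotes at an odd number of
    loci pull penetrance one way, the rest the other, scaled to the target
    heritability.  Raises ``ValueError`` when the scale leaves [0, 1].
    """
    maf = _check_maf(maf)
    k = float(prevalence)
    pa = _genotype_probs(maf)
    beta = pa[1] / (pa[0] + pa[2])
    u = np.array([-beta, 1.0, -beta])
    delta = np.outer(u, u)
    w = np.outer(pa, pa)
    delta /= _weighted_norm(delta, w)
    s = float(np.sqrt(target_h2 * k * (1.0 - k)))
    if not _feasible(k, s * delta):
        raise ValueError(
            f"XOR-type model infeasible for maf={maf}, h2={target_h2}, "
            f"prevalence={k}; use build_zero_marginal_model"
        )
    return PenetranceModel(f=k + s * delta, maf_a=maf, maf_b=maf)


def load_model_csv(path, maf_a: float, maf_b: float | None = None) -> PenetranceModel:
    """Load a 3x3 penetrance table from CSV (three comma-separated rows)."""
    f = np.loadtxt(path, delimiter=",", dtype=np.float64)
    return PenetranceModel(f=f, maf_a=maf_a, maf_b=maf_b if maf_b is not None else maf_a)


def save_model_csv(path, model: PenetranceModel) -> None:
    np.savetxt(path, model.f, delimiter=",", fmt="%.17g")


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class HybridModel:
    """Five pure epistatic models planted as five independent pairs."""

    models: list[PenetranceModel]
    positions: tuple[tuple[int, int], ...] = DEFAULT_HYBRID_POSITIONS

    def __post_init__(self) -> None:
        self.models = list(self.models)
        if len(self.models) != 5:
            raise ValueError(f"hybrid model needs exactly 5 models, got {len(self.models)}")
        self.positions = tuple(tuple(p) for p in self.positions)
        if len(self.positions) != 5:
            raise ValueError("hybrid model needs exactly 5 pair positions")
        flat = [p for pair in self.positions for p in pair]
        if len(set(flat)) != len(flat):
            raise ValueError(f"hybrid pair positions clash: {self.positions}")

    @classmethod
    def uniform(
        cls,
        maf: float,
        target_h2: float,
        seed: int = 0,
        positions: tuple[tuple[int, int], ...] = DEFAULT_HYBRID_POSITIONS,
    ) -> "HybridModel":
        """Five zero-marginal models sharing one heritability and MAF."""
        models = [
            build_zero_marginal_model(maf, target_h2, seed=(seed, m))
            for m in range(5)
        ]
        return cls(models=models, positions=positions)


@dataclass
class TruthRecord:
    """Planted ground truth of a simulated dataset."""

    pairs: tuple[tuple[int, int], ...]  # 1-based positions, each (a, b) a < b
    model_hashes: tuple[str, ...]
    seed: object

    def to_json(self) -> str:
        return json.dumps(
            {
                "pairs": [list(p) for p in self.pairs],
                "model_hashes": list(self.model_hashes),
                "seed": repr(self.seed),
            },
            indent=2,
        )


@dataclass
class SimulatedDataset:
    """Genotypes + phenotype + planted truth."""

    genotypes: GenotypeMatrix
    phenotype: Phenotype
    truth: TruthRecord


def _conditional_joint(model: PenetranceModel, case: bool) -> np.ndarray:
    """Exact P(g_a, g_b | phenotype class), a 3x3 probability table."""
    joint = np.outer(model.genotype_probs("a"), model.genotype_probs("b"))
    mass = joint * (model.f if case else (1.0 - model.f))
    total = mass.sum()
    if total <= 0.0:
        cls = "cases" if case else "controls"
        raise ValueError(f"penetrance table assigns zero probability to {cls}")
    return mass / total


def _draw_pair_genotypes(
    model: PenetranceModel, n_cases: int, n_controls: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Disease-locus genotype columns (g_a, g_b) for cases then controls."""
    ga = np.empty(n_cases + n_controls, np.uint8)
    gb = np.empty(n_cases + n_controls, np.uint8)
    for sl, case, count in (
        (slice(0, n_cases), True, n_cases),
        (slice(n_cases, None), False, n_controls),
    ):
        if count == 0:
            continue
        p = _conditional_joint(model, case).ravel()
        idx = rng.choice(9, size=count, p=p)
        ga[sl], gb[sl] = np.divmod(idx, 3)
    return ga, gb


def _noise_matrix(
    n: int, n_snps: int, noise_maf_range: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Label-independent HWE genotypes with per-SNP MAF ~ Uniform(range)."""
    lo, hi = noise_maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"noise MAF range must satisfy 0 < lo <= hi <= 0.5, got {noise_maf_range}")
    mafs = rng.uniform(lo, hi, size=n_snps)
    p0 = (1.0 - mafs) ** 2
    p1 = 2.0 * mafs * (1.0 - mafs)
    u = rng.random((n, n_snps))
    return ((u > p0).astype(np.uint8) + (u > p0 + p1)).astype(np.uint8)


def _finalize(
    values: np.ndarray,
    labels: np.ndarray,
    pairs: tuple[tuple[int, int], ...],
    models: list[PenetranceModel],
    seed,
    missing_rate: float,
    rng: np.random.Generator,
) -> SimulatedDataset:
    if missing_rate > 0.0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = 3
    n, p = values.shape
    gm = GenotypeMatrix(
        values=values,
        snp_ids=[f"snp{k + 1}" for k in range(p)],
        sample_ids=[f"s{k + 1}" for k in range(n)],
    )
    truth = TruthRecord(
        pairs=tuple(tuple(sorted(pr)) for pr in pairs),
        model_hashes=tuple(m.table_hash() for m in models),
        seed=seed,
    )
    return SimulatedDataset(genotypes=gm, phenotype=Phenotype(labels), truth=truth)


def simulate_pure(
    model: PenetranceModel,
    n_cases: int = 200,
    n_controls: int = 200,
    n_snps: int = 1000,
    positions: tuple[int, int] = (1, 10),
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
    seed=0,
    missing_rate: float = 0.0,
) -> SimulatedDataset:
    """Case-control dataset with one planted interacting pair.

    Disease-locus genotype pairs are drawn from the exact conditional
    distributions P(g_a, g_b | case) and P(g_a, g_b | control) (no rejection
    sampling); every other SNP is HWE noise independent of the label.
    ``positions`` are 1-based.  Class counts match the request exactly:
    cases come first, then controls.
    """
    a, b = positions
    if a == b:
        raise ValueError(f"disease-locus positions must be distinct, got {positions}")
    for pos in (a, b):
        if not 1 <= pos <= n_snps:
            raise ValueError(f"position {pos} out of range 1..{n_snps}")
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    labels = np.concatenate(
        [np.ones(n_cases, np.uint8), np.zeros(n_controls, np.uint8)]
    )
    values = _noise_matrix(n, n_snps, noise_maf_range, rng)
    ga, gb = _draw_pair_genotypes(model, n_cases, n_controls, rng)
    values[:, a - 1] = ga
    values[:, b - 1] = gb
    return _finalize(values, labels, ((a, b),), [model], seed, missing_rate, rng)


def simulate_hybrid(
    hybrid: HybridModel,
    n_cases: int = 200,
    n_controls: int = 200,
    n_snps: int = 1000,
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
    seed=0,
    missing_rate: float = 0.0,
) -> SimulatedDataset:
    """Dataset with five planted pairs simulated independently per sample.

    Each pair's genotypes are drawn from its own model conditional on the
    same per-sample label, so pairs are mutually independent given the
    phenotype.  Requires ``n_snps`` large enough for the pair positions
    (>= 900 for the default layout).
    """
    max_pos = max(p for pair in hybrid.positions for p in pair)
    if n_snps < max_pos:
        raise ValueError(
            f"n_snps={n_snps} too small for pair positions up to {max_pos}"
        )
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    labels = np.concatenate(
        [np.ones(n_cases, np.uint8), np.zeros(n_controls, np.uint8)]
    )
    values = _noise_matrix(n, n_snps, noise_maf_range, rng)
    for model, (a, b) in zip(hybrid.models, hybrid.positions):
        ga, gb = _draw_pair_genotypes(model, n_cases, n_controls, rng)
        values[:, a - 1] = ga
        values[:, b - 1] = gb
    return _finalize(
        values, labels, hybrid.positions, hybrid.models, seed, missing_rate, rng
    )
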