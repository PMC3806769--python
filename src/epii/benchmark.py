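"""Power / false-positive benchmark over simulated epistasis datasets.

Each replicate simulates a fresh dataset, derives its own threshold from a
fresh permutation null (gamma = C * max of B permutation maxima), runs the
chosen detection method and scores hits against the planted truth.

Detection is strict by default: a planted pair counts as detected only when
exactly that unordered pair is reported; any reported pair that is not a
planted pair is a false positive, even if it shares one SNP with the truth.
A lenient "overlap" column (pair sharing at least one planted SNP) is also
reported, since the original power definition is ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from . import cmim_baseline, episcan, episim, permtest
from .episim import SimulatedDataset
from .genotype_core import pack

__all__ = [
    "BenchmarkConfig",
    "ReplicateResult",
    "BenchmarkReport",
    "score_hits",
    "evaluate_replicate",
    "run_benchmark",
]


@dataclass
class BenchmarkConfig:
    """Configuration of one benchmark run.

    ``kind`` selects the generator: "pure" (one planted pair), "hybrid"
    (five planted pairs at the standard positions) or "null" (no planted
    pair; label independent of every SNP).  ``method`` is one of "ii", "mi"
    or "cmim".  Thresholds are re-derived per replicate from that
    replicate's own B permutations, scaled by C.
    """

    kind: str = "hybrid"
    maf: float = 0.4
    h2: float = 0.4
    n_cases: int = 200
    n_controls: int = 200
    n_snps: int = 1000
    replicates: int = 10
    method: str = "ii"
    B: int = 10
    C: float = 1.0
    seed: int = 0
    positions: tuple[int, int] = (1, 10)  # pure generator only
    noise_maf_range: tuple[float, float] = (0.05, 0.5)
    cmim_k: int | None = None  # default: 2 * number of planted pairs

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.kind not in ("pure", "hybrid", "null"):
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.method not in ("ii", "mi", "cmim"):
            raise ValueError(f"unknown method {self.method!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        d = dict(d)
        if "positions" in d:
            d["positions"] = tuple(d["positions"])
        if "noise_maf_range" in d:
            d["noise_maf_range"] = tuple(d["noise_maf_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ReplicateResult:
    """Per-replicate scoring detail."""

    index: int
    data_seed: int
    perm_seed: int
    gamma: float
    n_hits: int
    detected: tuple[tuple[int, int], ...]
    lenient_detected: tuple[tuple[int, int], ...]
    false_positives: int


@dataclass
class BenchmarkReport:
    """Aggregated benchmark outcome."""

    config: BenchmarkConfig
    rows: list[ReplicateResult]
    per_pair_power: float
    per_dataset_power: float
    lenient_per_pair_power: float
    false_positive_total: int

    @property
    def mean_false_positives(self) -> float:
        return self.false_positive_total / len(self.rows)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                "# per_pair_power\t{:.6g}\n# per_dataset_power\t{:.6g}\n"
                "# lenient_per_pair_power\t{:.6g}\n# false_positive_total\t{}\n".format(
                    self.per_pair_power,
                    self.per_dataset_power,
                    self.lenient_per_pair_power,
                    self.false_positive_total,
                )
            )
            fh.write(
                "replicate\tdata_seed\tperm_seed\tgamma\tn_hits\t"
                "n_detected\tn_lenient_detected\tfalse_positives\n"
            )
            for r in self.rows:
                fh.write(
                    f"{r.index}\t{r.data_seed}\t{r.perm_seed}\t{r.gamma!r}\t"
                    f"{r.n_hits}\t{len(r.detected)}\t{len(r.lenient_detected)}\t"
                    f"{r.false_positives}\n"
                )


def score_hits(
    truth_pairs, hit_pairs
) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...], int]:
    """Score reported pairs against planted pairs (all 1-based positions).

    Returns ``(detected, lenient_detected, false_positives)`` where a pair is
    detected iff it is reported exactly, leniently detected iff some reported
    pair shares at least one of its SNPs, and every non-planted reported pair
    is one false positive.
    """
    truth = {tuple(sorted(p)) for p in truth_pairs}
    hits = {tuple(sorted(p)) for p in hit_pairs}
    detected = tuple(sorted(truth & hits))
    fp = len(hits - truth)
    truth_snps = {p: set(p) for p in truth}
    hit_snps = set()
    for h in hits:
        hit_snps.update(h)
    lenient = tuple(sorted(p for p, s in truth_snps.items() if s & hit_snps))
    return detected, lenient, fp


def _run_method(
    dataset: SimulatedDataset, config: BenchmarkConfig, perm_seed: int
) -> tuple[float, list[tuple[int, int]], int]:
    """Run one detection method; returns (gamma, reported pairs, n_hits).

    For "mi" the reported "pairs" are the planted pairs whose two SNPs both
    exceed the single-SNP threshold, plus one false-positive pseudo-pair per
    hit SNP outside the truth.  For "cmim" the top ``2 * n_pairs`` picks play
    the role of hit SNPs (no permutation threshold involved).
    """
    packed = pack(dataset.genotypes)
    pheno = dataset.phenotype
    truth = [tuple(sorted(p)) for p in dataset.truth.pairs]
    truth_snps = {s for p in truth for s in p}

    if config.method == "ii":
        null = permtest.permutation_null(packed, pheno, "ii", config.B, perm_seed)
        gamma = config.C * null.gamma_max
        res = episcan.scan_pairs(packed, pheno, gamma)
        return gamma, [h.pair for h in res.hits], len(res.hits)

    if config.method == "mi":
        null = permtest.permutation_null(packed, pheno, "mi", config.B, perm_seed)
        gamma = config.C * null.gamma_max
        res = episcan.scan_singles(packed, pheno, gamma)
        hit_pos = {h.pos for h in res.hits}
    else:  # cmim
        k = config.cmim_k or max(2, 2 * len(truth))
        sel = cmim_baseline.cmim_select_fast(packed, pheno, k)
        hit_pos = {f + 1 for f in sel.features}
        gamma = math.nan
    pairs = [p for p in truth if p[0] in hit_pos and p[1] in hit_pos]
    # each hit SNP outside the planted loci counts as one false positive
    pairs += [(pos, pos) for pos in sorted(hit_pos - truth_snps)]
    return gamma, pairs, len(hit_pos)


def evaluate_replicate(
    dataset: SimulatedDataset,
    config: BenchmarkConfig,
    perm_seed: int = 0,
    hit_pairs=None,
) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...], int]:
    """Score one dataset; runs the configured method unless hits are given.

    Returns ``(detected, lenient_detected, false_positives)``.
    """
    if dataset.truth is None or dataset.truth.pairs is None:
        raise ValueError("dataset has no truth record to score against")
    if hit_pairs is None:
        _, hit_pairs, _ = _run_method(dataset, config, perm_seed)
    return score_hits(dataset.truth.pairs, hit_pairs)


def _make_dataset(config: BenchmarkConfig, model, data_seed: int) -> SimulatedDataset:
    if config.kind == "hybrid":
        return episim.simulate_hybrid(
            model,
            n_cases=config.n_cases,
            n_controls=config.n_controls,
            n_snps=config.n_snps,
            noise_maf_range=config.noise_maf_range,
            seed=data_seed,
        )
    if config.kind == "pure":
        return episim.simulate_pure(
            model,
            n_cases=config.n_cases,
            n_controls=config.n_controls,
            n_snps=config.n_snps,
            positions=config.positions,
            noise_maf_range=config.noise_maf_range,
            seed=data_seed,
        )
    # null generator: all SNPs are label-independent noise
    rng = np.random.default_rng(data_seed)
    n = config.n_cases + config.n_controls
    labels = np.concatenate(
        [np.ones(config.n_cases, np.uint8), np.zeros(config.n_controls, np.uint8)]
    )
    values = episim._noise_matrix(n, config.n_snps, config.noise_maf_range, rng)
    return episim._finalize(values, labels, (), [], data_seed, 0.0, rng)


def run_benchmark(config: BenchmarkConfig) -> BenchmarkReport:
    """Run the full benchmark; deterministic given ``config.seed``."""
    master = np.random.default_rng(config.seed)
    model_seed = int(master.integers(2**63))
    data_seeds = master.integers(2**63, size=config.replicates)
    perm_seeds = master.integers(2**63, size=config.replicates)

    model = None
    if config.kind == "hybrid":
        model = episim.HybridModel.uniform(config.maf, config.h2, seed=model_seed)
    elif config.kind == "pure":
        model = episim.build_zero_marginal_model(config.maf, config.h2, seed=model_seed)

    rows: list[ReplicateResult] = []
    n_pairs_per_dataset = 0
    for r in range(config.replicates):
        try:
            dataset = _make_dataset(config, model, int(data_seeds[r]))
            gamma, hit_pairs, n_hits = _run_method(
                dataset, config, int(perm_seeds[r])
            )
        except Exception as e:
            raise RuntimeError(f"benchmark replicate {r} failed: {e}") from e
        detected, lenient, fp = score_hits(dataset.truth.pairs, hit_pairs)
        n_pairs_per_dataset = len(dataset.truth.pairs)
        rows.append(
            ReplicateResult(
                index=r,
                data_seed=int(data_seeds[r]),
                perm_seed=int(perm_seeds[r]),
                gamma=gamma,
                n_hits=n_hits,
                detected=detected,
                lenient_detected=lenient,
                false_positives=fp,
            )
        )

    total_truth = config.replicates * n_pairs_per_dataset
    per_pair = (
        sum(len(r.detected) for r in rows) / total_truth if total_truth else math.nan
    )
    lenient_pp = (
        sum(len(r.lenient_detected) for r in rows) / total_truth
        if total_truth
        else math.nan
    )
    per_dataset = (
        sum(len(r.detected) == n_pairs_per_dataset for r in rows) / config.replicates
        if total_truth
        else math.nan
    )
    return BenchmarkReport(
        config=config,
        rows=rows,
        per_pair_power=per_pair,
        per_dataset_power=per_dataset,
        lenient_per_pair_power=lenient_pp,
        false_positive_total=sum(r.false_positives for r in rows),
    )
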