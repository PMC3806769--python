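# epii

Exhaustive interaction-information scans for pairwise epistasis in
case-control genotype data, with permutation-based family-wise thresholds, a
single-SNP mutual-information scan, a CMIM greedy-selection baseline, and a
penetrance-model simulator for planting zero-marginal epistatic pairs.

Genotypes (0/1/2 minor-allele copies, 3 = missing) are bit-packed two bits
per call; all contingency tables come from bitwise AND + popcount over the
packed planes, so the exhaustive scan over all C(p, 2) pairs is fast and
fully deterministic.

## Modules

| module | contents |
| --- | --- |
| `epii.genotype_core` | genotype matrix, 2-bit packing, popcount contingency tables, simple-tsv / PLINK `.raw` I/O |
| `epii.infotheory` | plug-in entropy, MI, conditional MI, interaction information (bits) |
| `epii.episcan` | pairwise interaction-information scan, single-SNP MI scan, hit reporting, gene-graph export |
| `epii.permtest` | permutation null of the max statistic, threshold selection, family-wise p-values |
| `epii.episim` | penetrance models, zero-marginal model constructor, pure/hybrid dataset simulation |
| `epii.cmim_baseline` | standard and fast (lazy) CMIM feature selection |
| `epii.benchmark` | power / false-positive benchmark harness over simulated replicates |

## Command line

```sh
# simulate a 200/200/1000 dataset with five planted zero-marginal pairs
epii simulate --hybrid 5 --maf 0.4 --h2 0.2 --seed 7 \
    --out data.tsv --truth truth.json

# permutation null of the max interaction-information statistic
epii permute --input data.tsv --B 1000 --seed 17 --stat ii --out null.txt

# exhaustive pair scan thresholded strictly above the permutation maximum
epii scan --input data.tsv --gamma-from-null null.txt --out hits.tsv

# single-SNP mutual-information scan with a fixed threshold (bits)
epii scan-single --input data.tsv --gamma 0.02 --out singles.tsv

# CMIM baseline (fast lazy variant)
epii cmim --input data.tsv -k 10 --fast --out features.tsv

# gene-gene interaction graph from a hit list
epii graph --hits hits.tsv --annot snp2gene.tsv --out edges.tsv

# power / false-positive benchmark from a YAML config
epii benchmark --config bench.yaml --out report.tsv
```

A benchmark config looks like:

```yaml
kind: hybrid          # pure | hybrid | null
maf: 0.4
h2: 0.4
n_cases: 200
n_controls: 200
n_snps: 1000
replicates: 10
method: ii            # ii | mi | cmim
B: 10                 # permutations per replicate for the threshold
C: 1.0                # threshold multiplier on the permutation maximum
seed: 7
```

## Python API sketch

```python
import numpy as np
from epii import episim, episcan, permtest
from epii.genotype_core import pack

model = episim.build_zero_marginal_model(maf=0.4, target_h2=0.4, seed=1)
ds = episim.simulate_pure(model, n_snps=1000, positions=(1, 10), seed=2)

packed = pack(ds.genotypes)
null = permtest.permutation_null(packed, ds.phenotype, kind="ii", B=1000, seed=3)
gamma = permtest.select_threshold(null, "strictly-above-max").gamma
result = episcan.scan_pairs(packed, ds.phenotype, gamma)
for hit in result.hits:
    print(hit.pos_i, hit.pos_j, hit.value, permtest.familywise_pvalue(hit.value, null))
```

## Conventions

- Logarithms are base 2; every statistic is in bits.
- Reported SNP positions are 1-based; Python API indices are 0-based.
- Missing genotypes are a fourth category in every count table; no samples
  are dropped.
- Hits require a value strictly greater than the threshold gamma.
- All randomness flows through explicit integer seeds; identical seeds give
  byte-identical scans, nulls, datasets and benchmark reports.
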