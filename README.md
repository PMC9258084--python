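# bsaseq

Forward simulation and statistical benchmarking of **BSA-Seq** — bulk
segregant analysis with high-throughput sequencing — for QTL mapping in
F2 populations.

BSA-Seq crosses two inbred parents, phenotypes a segregating F2
population, pools the DNA of the individuals in the two phenotypic
tails, sequences both pools, and scans for markers where the pools'
allele frequencies diverge: loci linked to a QTL are enriched for one
parental allele in the high pool and the other in the low pool. Which
scan statistic to use, and how its localization accuracy depends on the
recombination rate of the species, is an open practical question —
especially for low-recombination crops where a single QTL shifts allele
frequencies across much of a chromosome.

`bsaseq` answers it by simulation. It provides:

* a fast forward simulator of F2 gametes under the Haldane model
  (Poisson crossover counts with mean lambda, the chromosome map length
  in Morgans; uniform crossover placement), a single-QTL additive
  phenotype, phenotypic-tail bulks, and binomial or real-depth-driven
  sequencing noise;
* the nine scan statistics in common use — per-SNP **delta-SNP index**
  (`dsnp`), **G statistic** (`g`), **Euclidean distance** (`edm`),
  **LOD** (`lod`), and smoothed **t-delta-SNP** (`tdsnp`), **AFDexp**
  (block-regression), **G'** (`gprime`), **ED100^4** (`ed100_4`),
  **SmLOD** (`smlod`);
* peak calling, localization-error benchmarking across replicates, and
  simulation-based null significance thresholds (mean of per-replicate
  95% quantiles under no QTL effect);
* a CLI: `bsaseq simulate | scan | benchmark | null-thresholds | demo`.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Simulate a pearl-millet-like chromosome (lambda = 0.90, 10,000 markers
over 100 Mbp, 500 F2s, 10% bulks, depth 100) with a QTL of effect
k = 1 at the chromosome midpoint, then scan it:

```python
import numpy as np
from bsaseq import SimulationConfig, scan_once, call_peak

config = SimulationConfig(lambda_morgans=0.90, k=1.0, qtl_locus=5000)
scan = scan_once(config, np.random.default_rng(1))
for name in ("dsnp", "tdsnp", "g", "gprime", "ed100_4"):
    peak = call_peak(scan.tracks[name])
    print(f"{name:8s} peak at {peak.position_bp / 1e6:6.2f} Mb "
          f"(error {abs(peak.position_bp - 50.01e6) / 1e3:6.0f} kb)")
```

```
dsnp     peak at  50.14 Mb (error    130 kb)
tdsnp    peak at  50.52 Mb (error    510 kb)
g        peak at  47.58 Mb (error   2430 kb)
gprime   peak at  50.58 Mb (error    570 kb)
ed100_4  peak at  51.10 Mb (error   1090 kb)
```

All five statistics put the peak near the true QTL at 50.01 Mb, but the
raw G statistic lands on a noise excursion 2.4 Mb away while every
smoothed track stays within ~1 Mb; in other realizations the raw
delta-SNP is the one that wanders (here it happens to land close).
Single scans vary a lot — which is exactly why the benchmark averages
hundreds of replicates with random QTL positions. A full accuracy table
(mean error in kb per statistic, here 20 replicates):

```bash
bsaseq benchmark --n-replicates 20 --lambdas 0.9,1.3,2.15 \
    --qtl-locus random --out bench.tsv
```

Localization error falls as recombination rises, smoothing always
helps, and the windowed Euclidean-distance statistic `ed100_4` is the
most accurate overall, with mean errors below ~1 Mb even at
lambda = 0.90.

Null significance thresholds for the same design:

```bash
bsaseq null-thresholds --lambda-morgans 0.9 --n-sims 1000 --out thr.json
```

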