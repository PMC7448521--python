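# protscan

Gene-level rare-variant association tests that scan **flexibly shaped
windows of variants defined by proximity in protein 3D space**, plus
detection of the non-overlapping signal regions driving an association.

## The problem

Set-based tests (burden, SKAT) aggregate the rare variants of a gene to
gain power, but they aggregate along the chromosome. Trait-associated
missense variants often cluster instead in the folded protein — residues
far apart in sequence can form one functional surface. `protscan` tests
windows of variants that are close in 3D, so a tight spatial cluster of
causal variants is tested on its own rather than diluted in a whole-gene
set. It is aimed at sequencing studies (candidate-gene or exome-wide) where
per-variant score statistics and variant-to-structure coordinates are
available.

## The method

For the `m` variants of a gene with 3D coordinates `C_1..C_m`, join every
pair with Euclidean distance `d_ij <= w` and take connected components as
windows. Sweeping `w` over the sorted pairwise distances yields a nested
(laminar) family of at most `2m - 1` windows — the nodes of the
single-linkage merge tree. One extra window collects unmapped variants and
a global window spans the gene.

Each window `W` is tested from variant-level score summary statistics
`U` (scores) and `V` (their covariance):

* **mean (burden) test** `Q_W = (S'U_W)^2 / (S'V_W S)` with
  Madsen–Browning weights `S_j = 1/sqrt(MAF_j (1 - MAF_j))`; chi-square(1)
  null;
* **variance (SKAT-type) test** `Q_W = U_W' Omega U_W` with
  `Omega = diag(w_j^2)`, `w_j = Beta(MAF_j; 1, 25)` density; the null is
  the mixture `sum_k lambda_k chi2_1` with `lambda_k` the eigenvalues of
  `V_W^{1/2} Omega V_W^{1/2}`, evaluated by characteristic-function
  inversion (Davies-type).

Windows with fewer than 10 cumulative minor alleles are not tested.
Window p-values are combined into a gene-level p-value with the **Cauchy
combination** `Q = mean_j tan((1/2 - p_j) pi)`,
`p = 1/2 - arctan(Q)/pi` (fast, dependence-robust; genome-wide mode), or
with the **minimum-p scan statistic** whose null is built by Monte Carlo
(`U* ~ MVN(0, V)`; candidate-gene mode). Signal regions are windows below
the Monte-Carlo per-window threshold, selected greedily so that reported
regions are disjoint. A 1D comparator (`Scan1DModel`) runs the identical
pipeline over fixed-size chromosomal windows (`L/2 ... L/20`, skip `L/40`).

## Worked example

```python
import numpy as np
from protscan import ProteinScanModel
from protscan.simulate import SimConfig, simulate_gene

# synthetic gene: 1000 subjects, ~10% causal variants clustered in space
ds = simulate_gene(SimConfig(n=1000, seed=3, causal_fraction=0.1,
                             rho=0.1, effect_c=0.3), null=False)
model = ProteinScanModel.from_individual_data(ds.data, ds.spatial, ds.variants)

res = model.fit(test="mean", combine_method="minp", B=2000, seed=1)
print(res.summary())
report = res.detect_signals(alpha=0.05)
print("signal regions:", report.member_sets())
print("true causal   :", sorted(ds.causal_idx))
```

Output (abridged):

```
Scan test results
==============================================
gene:             gene
model:            ProteinScanModel
test:             mean
combination:      minp
windows tested:   88
gene p-value:     0.0004998
MC replicates:    2000

top windows (by p):
    provenance  size  mac            p                  members
STRUCTURE(SIM)     6 1105 1.514326e-14    v3,v5,v22,v30,v49,v51
...
signal regions: [frozenset({48, 2, 50, 4, 21, 29})]
true causal   : [2, 4, 21, 29, 48, 50]
```

The gene-level Monte-Carlo p-value is the smallest reportable at
`B = 2000` (resolution `1/(B+1)`), the best window is the six-variant
spatial cluster, and the single detected signal region is exactly the
planted causal set — the six causal variants are scattered along the
chromosome but tightly clustered in 3D, which is precisely the situation
the spatial windows exploit.

The same model can be fitted from summary statistics alone
(`ProteinScanModel(variants, stats, spatial)`), and a `protscan` command
line (`gene`, `signal`, `windows`, `simulate`) wraps the library for shell
use — see `protscan --help`.

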