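# covnet — two-group structural covariance network comparison

`covnet` analyzes the **structural covariance connectome**: a brain graph
whose edges reflect how strongly regional gray-matter volumes co-vary
across subjects, interpreted as coordinated development between regions.
Given a subjects × regions volume table with a two-level group label (for
example a patient cohort and matched controls), the package

1. builds a group-level **association matrix** `R` of Pearson correlations
   `r_ij` between regional volumes across that group's subjects;
2. binarizes `R` across a grid of **network densities** `D` by keeping
   exactly the `E = round(D·N(N−1)/2)` largest signed correlations, so both
   groups are always compared at equal edge counts;
3. computes global graph metrics — clustering coefficient `C_p`
   (segregation), characteristic path length `L_p` (integration), and
   small-worldness `σ = (C/C_rand)/(L/L_rand)` — and nodal degree and
   betweenness centrality, benchmarking the global measures against
   **Hirschberger–Qi–Steuer (HQS)** random covariance matrices matched to
   the moments of the observed matrix;
4. tests group differences with a **label-permutation framework**: in each
   permutation both association matrices are rebuilt, re-thresholded and
   re-measured; curves of metric vs. density are compared via their area
   under the curve (functional density analysis), with positional
   two-tailed p-values and Benjamini–Hochberg FDR correction;
5. classifies **hubs** (degree ≥ mean + 1 s.d. of network degree) per group
   and reports common and group-unique hub sets.

It is aimed at researchers running morphometry-based connectomics who have
already extracted regional volumes (e.g. 92 AAL regions from VBM) and want
a tested, reproducible implementation of the group-comparison statistics.
A first-class synthetic-data generator (planted modular covariance with
group effects) makes every stage testable without imaging data.

## Worked example

```python
from covnet import SyntheticConfig, generate_volume_table
from covnet.model import StructuralCovarianceModel

# two groups (34 + 28 subjects) of 92 regions; group A has stronger
# within-module covariance than group B
table = generate_volume_table(SyntheticConfig(seed=7))
model = StructuralCovarianceModel(table)
results = model.fit(n_perm=500, seed=7)
print(results.summary())
```

```
Structural covariance network comparison
========================================================================
Groups:        A = A (n=34), B = B (n=28)
Regions:       92
Density grid:  0.20:0.02:0.50  (D_min of full connectivity = 0.20)
Permutations:  500   HQS nulls: 20 observed / 5 per permutation

Global measures (functional density / AUC statistics)
------------------------------------------------------------------------
          metric  auc_diff      p      q direction
      clustering    0.0320 0.0020 0.0100       A>B
     path_length    0.0148 0.0240 0.0399       A>B
 norm_clustering    0.0240 0.2295 0.2869       A>B
norm_path_length    0.0107 0.0120 0.0299       A>B
 small_worldness    0.0145 0.4571 0.4571       A>B

Nodal measures with q < 0.05 (0 of 184 tests)
------------------------------------------------------------------------
(none)

Hubs (degree >= mean + 1 s.d., at D_min)
------------------------------------------------------------------------
A: 15 hubs; B: 14 hubs; common 2, unique-A 13, unique-B 12
unique to A: R001, R002, R003, R005, R006, R008, R009, R011, R033, ...
unique to B: R020, R026, R032, R048, R050, R054, R057, R067, R069, ...
```

Reading the output: `D_min` is the smallest grid density at which both
groups' graphs are fully connected — the analysis grid starts there.  Each
global row compares the two groups' metric-vs-density curves through the
difference of their areas under the curve (`auc_diff`, group A minus
group B); `p` is the positional two-tailed permutation p-value and `q` its
FDR-corrected version within the family of global measures.  Here the
planted effect (within-module correlation 0.65 in group A vs 0.55 in
group B) surfaces as significantly higher clustering in group A
(q = 0.01): the stronger within-module covariance makes A the more
segregated network.  The HQS-normalized clustering is not individually
significant at this sample size — the normalization absorbs part of the
raw effect into the null ensemble's variability.  Hub counts and the
unique-hub lists summarize where each group concentrates its
highest-degree nodes; with no hub planting the two sets differ only by
sampling noise.

The same pipeline runs from the shell:

```bash
covnet simulate --preset paper-shape --seed 7 -o volumes.csv
covnet validate volumes.csv
covnet run volumes.csv -o results/ --n-perm 500 --seed 7
```

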