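# assocpat

Predictability of association patterns from focal-follow scan samples.

Many group-living animals (the motivating system is a large, cohesive
multi-male multi-female primate group observed in dense forest) are never
all in view of one another: at any moment an individual is surrounded by a
*subgroup* — the set of group members in visual contact. Who makes up that
subgroup matters for social decision-making, because bystanders shape
interactions. `assocpat` asks, from scan-sample data, how predictable those
association patterns are on two levels:

- **Subgroup level.** Treat each scan's exact composition as one
  categorical outcome and compare its Shannon entropy H_obs with the mean
  entropy H_exp under a *constrained permutation null* that preserves
  per-scan party size, the focal's identity, individual occurrence
  frequencies, and runs of identical consecutive scans. The **entropy
  ratio** H_obs/H_exp equals 1 when composition is as random as the
  sampling structure allows; unlike KL divergence or Jensen–Shannon
  distance, it is robust to group size and data density (the package
  includes the simulation experiment demonstrating this).
- **Dyad level.** For every pair, the simple ratio index
  SRI = P_AB/(P_A + P_B + P_AB), its permutation expectation, the pairwise
  affinity value PAV = SRI_obs − SRI_exp ∈ [−1, 1], a permutation
  significance flag (observed SRI strictly above more than (1−α)·B of B
  permuted values), and a scan-bootstrap SD for precision. Dyad-year rows
  then feed binomial (significant-associate flag) and gaussian (PAV)
  regressions on kinship, rank difference (from Elo ratings of feeding
  supplants, ordinally standardized to [0, 1]), sex, age and
  reproductive-state combinations — with all-subsets AICc multimodel
  inference under marginality, Akaike weights, 95% best-model confidence
  sets, summed predictor weights, and dyad-flip resampling to neutralize
  the arbitrary orientation of unordered dyads.

A seeded synthetic generator emulates the sampling structure (focal-follow
blocks, autocorrelation, right-skewed subgroup sizes, gregariousness
heterogeneity, injectable dyadic assortativity) and exports its ground
truth, so every statistic is covered by calibration and recovery tests.

## Worked example

```python
from assocpat import (SyntheticConfig, AffinityEffects, generate_scan_dataset,
                      build_ensemble, entropy_report)
from assocpat.dyadic_association import dyad_table
from assocpat.null_model import bootstrap_scans

cfg = SyntheticConfig(n_individuals=30, n_scans=2000,
                      affinity_effects=AffinityEffects(kin=1.0, rank_similarity=1.0),
                      seed=42)
ds, truth = generate_scan_dataset(cfg)
ens = build_ensemble(ds, B=1000, seed=1)
rep = entropy_report(ds, ens)
print(f"H_obs = {rep.H_obs:.2f} bits, H_exp = {rep.H_exp:.2f} bits, "
      f"ratio = {rep.ratio:.4f}, unique = {100*rep.unique_frac:.0f}%")

table = dyad_table(ds, ens, boot=bootstrap_scans(ds, R=1000, seed=2))
print(f"significant associates: {table['significant'].mean():.1%} of dyads")
print(f"max bootstrap SD of SRI: {table['sri_sd_boot'].max():.4f}")
```

prints

```
H_obs = 10.77 bits, H_exp = 10.78 bits, ratio = 0.9992, unique = 91%
significant associates: 10.1% of dyads
max bootstrap SD of SRI: 0.0150
```

Read: subgroup composition is statistically indistinguishable from the
constrained null (ratio ≈ 1; 91% of the 2000 compositions occur once) —
yet a tenth of dyads associate significantly more than expected, because
kin and rank-similarity affinities were injected. Splitting the flag by the
generator's ground truth makes the contrast explicit: 74% of kin dyads are
significant associates versus 3% of non-kin. High subgroup-level entropy
and strong dyad-level predictability coexist; entropy alone understates
what an individual can predict about its social surroundings. The
bootstrap SDs (≤ 0.015) show 2000 scans estimate the indices precisely.

The same analysis runs from the shell: `assocpat simulate | permute |
entropy | associate | assort | run | report` (see `assocpat --help`); `run`
executes the whole pipeline from a YAML config and writes entropy reports,
dyad tables, the multimodel summary and a markdown report.

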