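# paleopop

Demographic reconstruction of gene variants archived in dated sediment
cores.

Lake and river sediments accumulate in dated layers, and the DNA they
preserve records how microbial gene pools changed through time.  For a
marker under changing selection — the classic example is *merA*, the
mercuric-reductase gene whose only known job is detoxifying mercury —
the effective population size Ne(t) of the gene's variant pool, read off
time-calibrated genealogies of variants from dated horizons, acts as a
proxy for the history of the selective pressure itself.  `paleopop`
implements the full inference chain from dated variants to a dated
demographic breakpoint, together with a synthetic-study generator so
every stage can be validated by parameter recovery:

1. **Synthetic studies** (`study`, `coalescent`, `seqevolve`,
   `trajectories`): multi-site sediment-core studies with known truth.
   Genealogies follow the heterochronous (serially sampled) coalescent —
   k active lineages merge at rate k(k−1)/2Ne(t), with tips entering at
   their horizon's deposition date — under constant, exponential,
   piecewise or sigmoidal Ne(t); sequences evolve under GTR+Γ with an
   uncorrelated lognormal relaxed clock; kit and cross-sample
   contaminant variants can be injected.
2. **Variant filters** (`filters`): exact-match dereplication, removal
   of variants present in the sequenced negative control, removal of
   variants found in more than one sample of a site (cross-contamination),
   alignment occupancy filtering (<10% occupied columns), and a cap of
   50 maximally phylodiverse variants per sample (Ward clustering of
   patristic distances, group medoids).
3. **Skyline inference** (`skyline`): coalescent-interval bookkeeping,
   the classic skyline N̂ = k(k−1)w/2, the exact piecewise-constant
   coalescent log-likelihood, and a grouped Bayesian skyline sampled by
   Metropolis–Hastings (default m = 25 groups), summarised to median and
   95% HPD trajectories on a calendar grid.
4. **Trait association** (`association`): the Association Index
   AI = Σᵢ (1−fᵢ)/2^(nᵢ−1) over internal nodes, with a BaTS-style
   tip-label permutation test of phylogeny–deposition-date clustering
   across a posterior tree sample.
5. **Trend and breakpoint** (`trend`, `pipeline`): a multi-site table of
   median log₁₀ Ne vs date, random-forest regressions (date + site,
   ten stratified 80/20 splits, held-out pseudo-R² = 1 − SSE/SST),
   partial dependence on date, an omission sensitivity analysis, and
   single-breakpoint segmented regression (iterative linearisation with
   a delta-method 99% CI for the breakpoint ψ), cross-checked by an
   exhaustive profile-search oracle.
6. **Support** (`io`, `agedepth`, `cli`): FASTA/Newick/NEXUS/TSV/YAML
   I/O with run manifests, age–depth dating (linear interpolation inside
   the anchored range, quadratic extrapolation down to 1750 CE), and
   site-table arithmetic.

## Worked example

Simulate the reference four-site study — six horizons per core at
50-year spacing (topmost 2010 CE), ten variants per horizon, and a
shared ten-fold sigmoidal Ne increase centred on 1784 CE — then run the
whole chain and date the change:

```python
from paleopop import recover_breakpoint

rec = recover_breakpoint(seed=1)
print(f"psi = {rec.fit.psi:.1f} CE (99% CI {rec.fit.ci[0]:.1f}-{rec.fit.ci[1]:.1f})")
print(f"adj R2 = {rec.fit.adj_r2:.2f}, RF pseudo-R2 = {rec.rf_scores.mean():.2f}")
```

```
psi = 1797.9 CE (99% CI 1793.3-1802.5)
adj R2 = 0.92, RF pseudo-R2 = 0.84
```

The dated breakpoint lands near the simulated onset: the two-segment
model places ψ just after the logistic midpoint (1784 CE) because the
reconstructed trajectory plateaus after the rise — see
`docs/methods.md` for the quantitative account of that offset.  The RF
pseudo-R² is the mean held-out score of the ten stratified splits, and
the CI half-width (~5 yr) mirrors the precision one obtains on clean
synthetic data.

The same chain is scriptable from the shell:

```bash
paleopop simulate-study --seed 1 --out study/
paleopop filter --counts study/counts.tsv --samples study/samples.tsv \
    --steps control,cross --out filtered/
paleopop run-all --seed 1 --out run/
```

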