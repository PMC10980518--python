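# Methods

## Problem and model

When a plant experiences two stresses simultaneously — here salinity (ST)
and waterlogging (WL), combined as SWL — the transcriptome and metabolome
of the combined treatment are not a superposition of the single-stress
responses. For a feature significant in all three stress-vs-control
contrasts, the relationship between its combined-stress log2 fold change
`f_SWL` and its single-stress log2FCs `f_ST`, `f_WL` is summarised by one
of seven pattern modes. Writing `S = f_ST + f_WL` for the additive
expectation and `σ` for a tolerance band on the log2FC scale, the
classifier applies a fixed-precedence decision tree:

1. **antagonistic** — both single-stress responses have the opposite sign
   to the combined response;
2. **unilateral** — exactly one single-stress response has the opposite
   sign;
3. all three responses in the same direction:
   a. **neutral** — `|f_ST − f_SWL| ≤ σ` and `|f_WL − f_SWL| ≤ σ`: the
      combined response matches both single responses;
   b. **dominant** — exactly one of the two differences is within `σ`:
      one stress sets the combined response;
   c. both differences exceed `σ`:
      i.   **synergistic** — `|f_SWL| − |S| > σ`: the combined response
           exceeds the additive expectation;
      ii.  **additive** — `||f_SWL| − |S|| ≤ σ`: the combined response
           matches the additive expectation;
      iii. **minor** — `|f_SWL| < max(|f_ST|, |f_WL|) − σ`: the combined
           response falls below at least one single-stress magnitude;
      iv.  **non-assigned** — the *sub-additive gap*: short of additivity
           by more than `σ` yet not below the single-stress magnitudes.

A triple with a zero component cannot have passed the magnitude screens
and is routed to non-assigned (`rule_path = "zero-sign"`) rather than
erroring, keeping the classifier total. The tree is symmetric in the two
single stresses and invariant to flipping the sign of the whole triple;
these are tested as properties, and the whole map is checked against an
independently coded brute-force region oracle on a dense grid.

### Interpretive choices

The source material describes the band comparisons in "±Sd" notation with
Sd fixed at 0.50; we implement every such comparison as an
absolute-difference band of width `σ` on the log2FC scale (a two-value
sample standard deviation would only rescale the threshold by √2).
"Synergistic" always denotes amplification, so the synergy test is
one-sided (`|f_SWL| > |S| + σ`); a shortfall beyond `σ` that does not meet
the minor rule is reported as non-assigned rather than forced into a mode.
The precedence order (direction → neutral → dominant → synergy/additivity
→ minor → non-assigned) is fixed because several regions overlap
geometrically; every assignment records the branch taken in `rule_path`.

## Screening and intersection

Transcripts pass at BH-adjusted FDR ≤ 0.05 and |log2FC| ≥ 1 (the
magnitude gate is configurable since upstream pipelines vary); metabolites
pass at VIP ≥ 1 with fold change ≥ 2 or ≤ 0.5, FC derived from the stored
log2FC as `2**log2fc` so one table schema serves both omics layers.
Benjamini–Hochberg adjustment is delegated to
`statsmodels.stats.multitest.multipletests`. The three regulated sets are
partitioned into the seven disjoint Venn regions; only the triple
intersection is eligible for mode classification. `estimate_sigma`
computes the sample standard deviation of the SWL-unique log2FCs as a
data-driven check on the tolerance; the classifier default remains
σ = 0.50 in all headline analyses.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `sigma` | 0.50 | log2FC | tolerance band of every mode comparison |
| `fdr_max` | 0.05 | probability | DEG significance ceiling |
| `min_abs_log2fc` | 1.0 | log2FC | DEG magnitude floor |
| `fc_up` / `fc_down` | 2.0 / 0.5 | fold change | DM magnitude gates |
| `vip_min` | 1.0 | — | DM OPLS-DA importance floor |
| `margin` | 0.30 | log2FC | simulator clearance from decision boundaries |
| `noise_sd` | 0.0 | log2FC | simulator Gaussian perturbation |
| `effect_range` | [1.2, 4.0] | log2FC | simulator magnitude range |

## Synthetic data

The simulator emulates post-quantification differential tables, not reads
or spectra. Common responders are drawn by rejection sampling: magnitudes
uniform on `effect_range`, signs set by the target mode (combined-stress
direction ±1 equiprobable), accepted only when the noiseless triple sits
inside the target mode's region with clearance ≥ `margin` from every
decision boundary at the spec's σ. The margin guarantees that noiseless
planted labels classify back exactly, which is tested across ≥ 20 seeds;
Gaussian noise added after acceptance erodes recovery smoothly, and mean
recovery is verified to be non-increasing in `noise_sd`. The region
predicates are written as closed-form membership tests independent of the
classifier's control flow, so the generator doubles as an oracle of the
mode geometry. The non-assigned (sub-additive gap) region is plantable
like any mode.

Unique responders are significant in exactly one contrast (sub-threshold
|log2FC| < 0.5 elsewhere); null features are sub-threshold everywhere.
FDR and VIP are decorative draws consistent with the gates
(significant: FDR ~ U(0, 0.04], VIP ~ U(1.1, 3)), not modelled test
statistics — the pipeline begins downstream of differential testing. The
default unique-responder counts (ST 27, WL 41, SWL 140) reproduce, at
desk scale, the strong excess of combined-stress responders over either
single stress seen in real combined-stress transcriptomes. What passing
tests show is therefore that the screening, intersection, classification
and summary logic is correct on data with the assumed structure; they say
nothing about count-level noise, normalisation or differential-testing
error in real data.

## Summaries

* Mode frequencies are reported with an explicit denominator (assigned
  features, optionally including non-assigned); printed-style percentages
  use half-up rounding, raw values are also emitted.
* The mode × log2FC contingency analysis bins features by `f_SWL` into
  half-open intervals (default edges −∞, −2, −1, 0, 1, 2, +∞), computes
  expected counts under independence and standard (unadjusted) Pearson
  residuals `(O − E)/√E`. Cells with `E = 0` carry residual 0 and are
  excluded from χ²; degrees of freedom count only non-empty rows and
  columns, so a degenerate table reports χ² = 0, dof = 0.
* Silhouette scores use Euclidean distance via
  `sklearn.metrics.silhouette_samples`; singleton groups score 0 by
  convention and all scores lie in [−1, 1]. The hierarchical clustering
  (Euclidean, Ward) that typically precedes a silhouette plot is left to
  standard library calls; only the silhouette statistic itself is part of
  this package's contract.
* `pct_increase` and `subset_frequency` (ω) are exact arithmetic with
  half-up presentation rounding.

## Numerical choices and degenerate inputs

All band comparisons use closed inequalities (`≤ σ`), so grid points on a
boundary resolve deterministically by the precedence order. Duplicate
feature identifiers are an error everywhere (silent aggregation would
corrupt Venn membership); rows with non-finite log2FC are dropped with a
warning on read. Empty inputs yield empty outputs (header-only tables,
zero-count frequency tables flagged with `total = 0`). Rejection sampling
aborts with an explicit error after a bounded number of attempts when the
requested margin is infeasible for the effect range.

## Problem sizes

The bundled analysis runs 70 planted common features (10 per mode),
208 unique responders, 100 nulls at noise 0.1; the recovery benchmarks
use 10 features per mode over 20 seeds (noiseless) and 30 per mode over
20 replicates per noise level (0.1/0.3/0.6); the classifier–oracle grid
has 41³ = 68 921 points. These sizes make every statistic stable at a few
seconds of runtime while exercising all code paths.

## Known limitations

* Significance is consumed, not computed: no count modelling, dispersion
  estimation or OPLS-DA fitting.
* Features significant in only one or two contrasts are reported in their
  Venn regions but never mode-classified.
* σ is a single global constant per run, not per-feature.
* The simulator's uniform-magnitude effect model is deliberately simple;
  it is a correctness harness, not a generative model of real
  transcriptomes.
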