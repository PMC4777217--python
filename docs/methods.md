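# Methods

`toxprofiler` implements the analysis chain used to turn quantitative
high-throughput screening (qHTS) concentration–response data into
mechanism-oriented compound clusters and cluster-based predictions of
in vivo toxicity. This note documents the models, the defaults and the
numerical choices, and what the synthetic benchmark does and does not
show.

## qHTS concentration–response processing

**Normalization.** Raw well signals are scaled against in-plate controls:
`% activity = 100 · (V_compound − V_DMSO) / (V_pos − V_DMSO)`, where the
control values are per-plate medians. In antagonist mode the scale is
shifted by −100 so DMSO maps to −100 % and the positive control to 0 %
(activity reads as signal loss). Normalization is affine-invariant in the
raw signal by construction. Equal control medians are a hard error.

**Plate-pattern correction.** Positional background is estimated from the
compound-free (DMSO-only) plates bracketing the compound plate stack; the
per-well background subtracted from each compound plate is the mean of the
first and last control plate. This is the simplest estimator consistent
with bracketing control plates; no within-stack interpolation is
attempted.

**Hill fit.** Each titration (≥ 4 points) is fitted by bounded
least-squares to the four-parameter Hill equation in log10 concentration,
`y = b + (E − b) / (1 + 10^((log AC50 − log c) · h))` with baseline `b`,
efficacy `E` (% activity, signed), slope `h ∈ [0.2, 10]` and AC50
constrained to one decade beyond the tested range. Six optimizer starts
spread the initial log AC50 across the tested range; the best-r² fit wins,
and ties within 1e−9 in r² resolve to the smaller |efficacy|
(conservative). Constant response vectors are returned unconverged with
efficacy 0 and treated downstream as inactive.

**Curve classes and ranks.** Classes follow the standard qHTS heuristics:
1.x = complete curve (the fitted response at the top tested concentration
reaches ≥ 90 % of the fitted span), 2.x = incomplete; x.1 = high efficacy
(|E| ≥ 2 × threshold), x.2 = low; 3 = single-point activity at the highest
concentration only; 4 = inactive. Activity for classes 1–2 requires
|E| ≥ threshold (default 30 % activity) and r² ≥ 0.5; class 3 is exempt
from the r² gate. Rank magnitudes are 8/6/5/3/1/0 for classes
1.1/2.1/1.2/2.2/3/4 with +1 (capped at 9) when AC50 < 1 µM, signed by
response direction, so more potent and efficacious compounds with
higher-quality curves always rank higher. The thresholds, the r² gate and
the potency bonus are all configurable; the defaults are this package's
codification and should be calibrated against reference compounds before
use on new assays.

**Reproducibility.** For triplicate runs a replicate is *active* when
|rank| ≥ 3 (configurable), *inactive* at rank 0, *marginal* otherwise.
Calls: mismatch when activity conflicts (active together with inactive,
or actives of opposite sign); active match with ≥ 2 same-sign actives and
no inactive; inactive match when all three are inactive; otherwise
inconclusive. The assay score is `2·%active match + %inactive match −
%inconclusive − 2·%mismatch` (grade A > 90, B 80–90), and replicate AC50
spread is summarized as `10^SD(log10 AC50)` with the sample (n−1)
standard deviation.

## SOM clustering

Activity profiles (curve-rank vectors) and binary structure fingerprints
are clustered on rectangular self-organizing maps under Euclidean
distance. Training is the classic sequential algorithm: the sampled
profile updates its best-matching unit (BMU) and the grid neighbourhood
under a Gaussian kernel truncated at the current radius. The learning
rate decays linearly from α₀ = 0.05 to 0 over the whole budget; the
radius decays linearly from its initial value (default 20, capped at the
grid diameter — a 20-unit radius is degenerate on a small grid) to 1 over
the first half of the budget and holds at 1 thereafter, so the second
half is BMU-only fine-tuning. This rough/fine split is what makes the map
converge to an exact vector quantization when the data contain at most
one distinct point per unit. The default budget is 14 phases of
10·n_samples steps. The codebook is initialized deterministically along
the first two principal axes (covariance eigenvectors with canonical
sign), so a fixed seed fixes the whole training trajectory. A full-batch
mode (samples canonically ordered by id) is provided when sample-order
invariance is required.

Compounds are labelled by their BMU as `k<row>.<col>` (1-based,
row-major; distance ties break to the lowest unit). Consensus clusters
intersect the activity and structure partitions — compounds co-cluster
only if they share both labels — so the consensus partition refines both
inputs; singleton consensus clusters are retained but flagged. Default
grid shapes are free parameters; reported cluster counts refer to
non-empty units.

## Annotation enrichment

Each cluster is tested for enrichment of each annotation term present in
it with a one-sided Fisher's exact test (exact hypergeometric tails, no
χ² approximation), directed by the observed deviation: over-represented
terms get the upper tail, depleted terms the lower. The universe is the
annotated compounds only. Raw p-values are reported by default (the
conventional thresholds 0.05/0.01/0.001 are left to the caller);
Benjamini–Hochberg q-values are optional. Clusters are labelled by the
enriched term with the smallest p (ties: larger in-cluster count, then
lexicographic term id); clusters with no annotated member are labelled
`unannotated`.

## Cluster-score toxicity models

For one endpoint, compounds with calls are split uniformly at random into
halves (sizes differ by ≤ 1, no stratification). Per cluster with
training members, a 2×2 table (in/out of cluster × toxic/non-toxic over
the training half) yields a one-sided Fisher P; the cluster's toxicity
score is −log10 P when the cluster's toxic fraction exceeds the training
fraction, +log10 P (negative) when it is deficient, and 0 on an exact
tie. P is floored at 1e−300. Test compounds inherit their cluster's
score; clusters with no training members score 0 under the default
`neutral` policy (an `abstain` mode drops them instead). Predictions are
ranked against the true calls with a tie-aware AUC-ROC — the rank
statistic (concordant pairs + half ties)/(n⁺·n⁻), identical to the
cutoff-sweep trapezoidal area with "toxic" meaning score > cutoff. The
cycle repeats (default 100 splits) with split seeds derived from the
master seed and a hash of the endpoint name, so editing the endpoint set
never perturbs other endpoints' splits. Single-class test halves are
dropped; an endpoint whose splits all degenerate is flagged unmodelable.
Per-assay predictivity uses |curve rank| directly as the score (direction
is deliberately ignored), flagging assays with AUC > 0.7.

## Endpoint calling

Dose-type endpoints (LD50-like): toxic strictly below 300 mg/kg.
Other numeric endpoints: the most-toxic 35 % are toxic, by the
nearest-rank percentile with boundary ties called toxic; the toxic
direction is per-endpoint metadata (default lower = worse). Replicates
are aggregated by median before calling; composites take a strict
majority over the available component calls (exactly half → non-toxic).
Endpoints are retained for modelling only with ≥ 50 toxic and ≥ 50
non-toxic calls. Replicate concordance (all replicate calls agree,
computed against the same thresholds as the primary calls) requires ≥ 20
replicated compounds, below which it is flagged undefined; a qHTS-style
score variant (2·%both-toxic + %both-non-toxic − 2·%discordant) is also
reported.

## Synthetic benchmark

The generator plants exactly the structure the analysis assumes: latent
mechanism classes with prototype rank profiles (entries on the curve-rank
scale), prototype fingerprints, 1–2 dominant annotation terms per class,
and class-conditional toxicity probabilities. `signal_strength` s ∈ [0,1]
interpolates between noise and prototypes: a profile is
`round(s·prototype + ε)` with ε Gaussian of SD 5·(1−s) clipped to
[−9, 9] (an integer-valued truncated discretized Gaussian, so synthetic
profiles live on the real rank scale); fingerprint bits flip with
probability 0.5·(1−s); an annotated compound (coverage 60 % by default)
carries a dominant term of its class with probability s, otherwise a
random term. The multiplicative attenuation of the prototype (rather
than pure additive noise) is what makes s = 0 genuinely class-free on a
bounded integer scale while s = 1 gives identical class members. Seeding
is splittable (per-compound spawn keys), so extending the library never
perturbs earlier compounds.

Dose endpoints draw log10 doses from N(1.9, 0.35) for latent-toxic
compounds (clipped below 300) and N(3.1, 0.35) otherwise (clipped above
300): the distribution straddles the 300 mg/kg rule while latent calls
survive thresholding exactly. Score endpoints draw N(∓1, 1). A replicate
copies the first value unless the latent call flips (probability
`replicate_noise`), so zero replicate noise gives concordance exactly 1
for every endpoint type.

What passing these tests shows — and does not. The synthetic plates have
Gaussian read noise, no positional artefacts beyond what the pattern
correction models, and no assay-specific interference
(autofluorescence, luciferase inhibition); the fingerprints have no real
chemistry; class structure is cleanly separable at high signal. Recovery
of planted classes, calibrated null AUCs and the ordering
combined ≥ single-source therefore validate the machinery, not the
biological claims; performance on real screening data depends on assay
quality and cluster granularity in ways the generator does not emulate.

## Problem sizes and evaluation choices

The packaged acceptance checks run at desk scale, chosen once: null
calibration on a 500-compound, 2-class library (8×8 activity and 10×10
structure grids, 100 splits); planted-signal recovery on 400-compound
libraries across 10 seeds (30 splits each, class toxic probabilities
0.9/0.1 — the theoretical AUC ceiling under perfect recovery and equal
class sizes is 0.90); Hill-fit recovery over 1,000 simulated titrations
at 5 % noise; the Fisher and AUC primitives against brute-force oracles
(1,000 random instances each). The demo pipeline (500 compounds, 8
assays, 4 endpoints, 25 splits) completes in well under five minutes on
one CPU.

## Known limitations

- Curve-class boundaries (the 90 % span completeness rule, the 0.5 r²
  gate, the 30 % efficacy threshold) are heuristics; borderline curves
  are sensitive to them.
- The sequential SOM depends on the seeded sample schedule; only batch
  mode is order-invariant.
- The percentile rule ties the toxic fraction of score-type endpoints to
  35 % by construction, so prevalence is not a free parameter for them.
- Cluster-score models share information only through cluster identity;
  compounds in training-free clusters are uninformative (scored 0 or
  abstained).
- The enrichment universe excludes unannotated compounds; with sparse
  annotation, small clusters can reach nominal significance easily and
  the optional FDR correction is advisable.
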