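# Methods

## Statistical model and procedure

### Paired differential expression

For feature *g* with per-patient log2 differences d_i = tumor_i − control_i
(complete pairs only), the statistic is t = d̄ / (s_d/√n), df = n − 1,
two-sided p. The signed fold change is FC = 2^d̄ for d̄ ≥ 0 and −2^−d̄
otherwise, so |FC| ≥ 1 always and down-regulation is negative — the
convention under which a −2.766 log2 shift prints as ≈ −6.80. Multiplicity
is handled by Benjamini–Hochberg step-up (adjusted_(i) = min_{j≥i}
p_(j)·m/j, clipped to 1), the microarray-DE default. The DE call
requires |FC| ≥ 1.5 **and** FDR ≤ 0.05. Differences with numerically zero
spread (s_d ≤ 10⁻¹²·max(1, max|d|)) and nonzero mean are reported as p = 0
with a `degenerate` flag rather than silently.

### Correlation networks

Pearson r over pairwise-complete observations (minimum 5), significance by
the exact small-sample t transform t = r√(n−2)/√(1−r²), df = n − 2 (not the
Fisher z approximation; the cohorts of interest have n ≈ 14). |r| = 1 maps
to p = 0. An edge is retained iff |r| ≥ r_cut and p ≤ α; defaults r_cut =
0.8, α = 0.05, with 0.6 as the broad-screen preset. Edge p values are
deliberately *not* corrected for multiplicity by default — the filtering
rule operates on raw p — but a BH mode exists. Pairs are keyed by
lexicographically sorted symbols so that set algebra across conditions is
well defined, and the full unfiltered pair table is exposed for inspection.

### Edge partition

Pairs present post-filter in both networks with equal sign are *common*
(coherently correlated); present in both with opposite signs: *sign-flip*;
otherwise exclusive to the network containing them. Sign-flip is a distinct
fourth category rather than being folded into common or both exclusives:
the coherence rule excludes such pairs from common, and dropping them would
hide exactly the rewiring of interest. The four sets are pairwise disjoint
and cover the union; partitioning (A,B) mirrors (B,A) with the exclusive
sets swapped.

### Symbol resolution and clock-controller tagging

Alias tables use the miRBase `aliases.txt` dialect (accession, tab,
semicolon-separated aliases). Matching is on exact alias tokens after
lowercasing and `hsa-` prefix normalization; the canonical name is the
*last* alias of the unique matching row. A symbol matching no row, or
several rows (typically ambiguous between −5p and −3p products), is kept
with its original name and logged — unresolvable is an outcome, not an
error. A pair is a *clock-controller* iff at least one member has a
validated clock-gene target; the bundled map covers the six recurrently
deregulated clock-targeting miRNAs (let-7e-5p, miR-125b-5p, miR-140-3p,
miR-99b-5p, miR-19b-3p, miR-139-5p) against a configurable 16-gene clock
universe.

### Topology

All seven indices are computed from scratch on the unweighted, undirected
graph (correlation magnitude is an edge attribute, never a path weight).
Because these networks fragment into small clusters, path-based metrics are
computed within each connected component and normalized by the component
order n_c (Cytoscape NetworkAnalyzer convention): betweenness by Brandes
accumulation scaled by 2/((n_c−1)(n_c−2)) (0 when n_c < 3); closeness =
(n_c−1)/Σd; ASPL = Σd/(n_c−1); radiality = (Δ_c+1−ASPL)/Δ_c with Δ_c the
component diameter. Degree centrality alone uses the full graph order
(degree/(n−1)). Conventions for degenerate cases: singletons report
closeness 0, ASPL 0, radiality 1; two-node components report radiality 1;
both carry a `degenerate_component` flag. A generic "centrality" request is
interpreted as degree centrality; all seven columns are always emitted so
no interpretation is lost.

### Candidate ranking

Eligibility: clock-targeting ∧ DE direction ≠ ns. Score = w₁·|log2FC| +
w₂·lost_edge_fraction + w₃·|Δ degree centrality|, where lost_edge_fraction
is the node's control-exclusive edge count over its control degree (0 when
the control degree is 0). The formula is this package's own explicit
rendering of a qualitative "expression level + topology" selection; the
default weights (1,1,1) are arbitrary and the ranking is invariant to
positive rescaling of the weight vector. Ties break by |log2FC|, then
symbol, making the order a strict total order.

### Validation statistics

* **2^−ΔΔCt**: ΔCt = mean(target Ct) − mean(reference Ct). Two sign
  conventions are exposed: `reciprocal` (ΔΔCt = ΔCt_calibrator − ΔCt_target)
  and `livak` (the standard reverse); they are exact reciprocals, and neither
  is asserted to be "the" right per-patient readout. A Ct-ratio helper
  (reference Ct / target Ct) covers the alternative plotted readout.
* **Median split**: low = values ≤ median (ties conservatively assigned to
  low), high = the rest; association by Pearson's chi-squared without
  continuity correction (a Yates flag exists), df = (r−1)(c−1); expected
  counts < 5 raise a warning flag rather than an error.
* **MSI**: ≥4 unstable Bethesda markers → MSI-H, 0 → MSS; counts 1–3 →
  MSI-L. Only 0, 2 and ≥4 are stated anchors; 1 and 3 are monotone
  interpolations and the call carries a `rule_interpolated` flag.

## Synthetic cohort: what it emulates and what it does not

The generator emits two log2 matrices (control, tumor) over the same
features and patients, centered at 8.0 (RMA-style microarray intensities).

* **Correlation modules**: member i = √|ρ|·F + √(1−|ρ|)·ε_i with standard
  normal F, ε — unit variance and *exact* pairwise population correlation
  ρ. Negative ρ uses loadings +√|ρ| / −√|ρ| and is restricted to two-member
  modules (equicorrelation below −1/(k−1) is not a valid covariance).
  Tumor and control carry independent module lists, so exclusive and
  sign-flip edges are planted directly.
* **Background features** are N(8, noise_sd²), default noise_sd = 0.3 log2
  units — a free parameter chosen as a plausible array noise scale, not an
  empirical claim; module members' noise is the √(1−|ρ|) idiosyncratic term,
  which keeps planted correlations unattenuated.
* **DE shifts** are added to tumor columns; **coupling** generates an mRNA
  as ρ·z_m + √(1−ρ²)·ε from the exactly standardized miRNA signal, per
  condition, giving exact population correlation ρ.
* **Determinism**: one PRNG stream per logical block (control modules,
  tumor modules, background per condition, coupling per condition), spawned
  from the master seed, with one child stream per module — adding a module
  leaves every other block's draws bit-identical.

Not emulated: probe-level effects, count-based (RNA-seq) noise, batch
effects, inter-patient correlation between the two tissues beyond the DE
shift, and any dependence between modules. A green recovery test therefore
establishes that the pipeline detects the planted Gaussian structure at the
stated thresholds — not that real microarray cohorts behave this way.

The default stated world (`study_like_config`) is a 14-pair, 300-miRNA
cohort with a ρ = 0.95 control-only module around hsa-miR-139-5p (so the
candidate loses 100% of its control edges), a persisting ρ = 0.9 module, a
sign-flipping pair, a tumor-exclusive anti-correlated pair, shifts of
−2.76595 (≈ −6.8 FC), −2.0, +1.2 log2 plus an equally shifted non-clock
decoy, and a ρ = −0.32 hsa-miR-139-5p→TIMELESS coupling.

## Numerical choices

* Missing values: empty cells parse as missing; features missing in >20% of
  samples are dropped with a warning; the rest is handled pairwise-complete
  (correlation) / complete-pairs (paired t). Quantile normalization requires
  a complete matrix and raises otherwise.
* Input scale: a matrix whose maximum is ≥ 30 is assumed linear and
  log2(x+1)-transformed with a warning.
* Quantile normalization: reference = across-sample mean of sorted columns;
  ties receive the mean reference value over their rank positions; the
  operation is idempotent to < 1e−12.
* Zero-variance paired differences are detected with a relative 1e−12
  tolerance (exact equality is meaningless in floating point).
* All artifacts are written without timestamps, with sorted keys and full
  float repr, so identical configs produce byte-identical runs (verified by
  SHA-256 in the manifest).

## Known limitations

* The candidate score weights have no empirical calibration; the ranking is
  a transparent heuristic, not a fitted model.
* Cross-dataset node flags are computed by symbol presence in the optional
  second dataset only; no intensity rescaling across platforms is attempted.
* The pipeline treats any row whose symbol is in the clock-gene universe as
  an mRNA row (excluded from the miRNA–miRNA network); mixed-content
  matrices with other mRNAs are not segregated automatically.
* Edge significance at n = 14 with thousands of pairs admits false
  positives at the raw-p filter by design (≈ 6×10⁻⁴ of null pairs pass
  |r| ≥ 0.8 ∧ p ≤ 0.05); interpretation of exclusive-set counts must keep
  that base rate in mind, which is why the unfiltered pair table and the BH
  mode are provided.
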