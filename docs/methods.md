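# Methods

This note documents the models and procedures qlckit implements, the
parameters that matter, the numerical conventions, and what the synthetic
benchmarks do and do not establish about real proteomes.

## X-rich low-complexity region detection

A region is reported for target residue X (default glutamine) when three
criteria hold simultaneously:

1. **minimum fraction** — at least `min_fraction` (default 0.25) of the
   span's residues are X;
2. **maximum interruption** — no run of more than `max_gap` (default 17)
   consecutive non-X residues separates two X residues inside the span;
3. **minimum length** — the span covers at least `min_length` (default 15)
   residues.

Spans always begin and end on the target residue. Allowing boundaries on
non-target residues would make the fraction criterion ill-posed (any
qualifying span could be padded with arbitrary flanking residues until the
fraction dipped below threshold), and the interruption criterion is stated
between pairs of target residues, which only constrains target-bounded
spans.

The gap comparison is **inclusive**: a run of exactly `max_gap` non-target
residues is permitted. The interruption threshold has been described both
inclusively and exclusively in the literature this parameterization comes
from; we fix the inclusive reading (under which 17 is the value selected by
the parameter sweep) and expose `max_gap` so the strict reading is
`max_gap=16`.

*Algorithm.* Target positions are split into chains wherever consecutive
targets are more than `max_gap` apart; no qualifying span can bridge such a
break. Within a chain, every target-bounded sub-span meeting the fraction
and length criteria is enumerated (O(m²) in the number of targets m, which
is small for real proteins), spans contained in a longer qualifying span are
discarded, and remaining overlaps are resolved greedily: repeatedly keep
the longest surviving candidate (ties toward the smaller start coordinate)
and drop everything overlapping it. The rule is deterministic and is
verified in the test suite against exhaustive substring enumeration on
thousands of random sequences. Published QLC censuses do not specify their
overlap handling; region-for-region comparisons against external region
lists should bear this choice in mind.

Ambiguity codes (X, B, Z, U, O) never match a target residue, count toward
span length, and are excluded from composition tables — a conservative
treatment given that such codes are rare in curated proteomes.

*Parameter sweep.* `sweep_max_gap` re-runs detection over a range of
`max_gap` values and reports two argmaxes — the gap maximizing the region
count and the gap maximizing total residue coverage — separately, with ties
broken toward the smaller gap. Reporting both makes a disagreement between
the two optima visible rather than hidden behind a single number.

*Ranking.* `rank_regions` sorts descending by histidine count, length, or
target count, with competition ranking for ties (tied regions share the
better rank) and deterministic tie order by protein id and start.

## Wootton–Federhen complexity and LCD segmentation

Window complexity is the entropy form of compositional complexity,

    C = − Σ_i (n_i / L) · log₂₀ (n_i / L)

over the residue categories present in a window of length L. The base-20
normalization maps C into [0, 1] (0 for homopolymers), which is what makes
a threshold of 0.6 meaningful; the multinomial form differs negligibly at
window 15 and is not implemented. Each full window's value is assigned to
its **central residue** (window must be odd); the first and last
(window−1)/2 residues inherit the nearest assigned value. The assignment
convention is not standardized anywhere we know of; the central-residue
choice keeps the profile symmetric under sequence reversal, which the tests
assert.

Segmentation: residues with complexity **strictly below** 0.6 are low
complexity (the boundary value counts as high; `strict=False` flips this),
runs of low residues separated by at most `gap_close=3` high residues are
merged, and merged runs of at least `min_length=30` residues are reported.
Proteins shorter than the window are skipped with a warning rather than
scored. Ambiguity codes form their own entropy categories, which can only
lower a window's claimed complexity.

## Enrichment and region-set comparison

`enrichment_log2` computes log2(fg/bg) per residue. The default mode
removes the target residue from **both** the region subsequences and the
proteome before computing fractions, leaving 19 categories: without this,
every non-target residue would appear depleted simply because the target
occupies ≥25% of the foreground. The 20-category mode
(`exclude_target=False`) is provided because published enrichment figures
are not always explicit about the denominator convention. Zero-count
categories carry a flag and a NaN ratio, never ±infinity.

`compare_region_sets` returns 100 · (f_A / f_B − 1), the percent excess of
a residue in region set A over region set B. By default, positions of B
covered by any region of A are removed from B's tally first, so that B
means "all *other* regions" when A-type regions are a subset of B-type
regions (as QLCs typically are of LCDs).

## Conservation scoring

Per column, the pseudocount-smoothed distribution p of non-gap standard
residues is compared with a background distribution q via the base-2
Jensen–Shannon divergence, and multiplied by (1 − gap fraction). The
default background is the marginal amino-acid frequency vector of the
BLOSUM62 substitution data, normalized to sum to 1; the substitution matrix
itself is not otherwise used. Defaults follow the cited JSD-conservation
method's defaults: pseudocount 1e−7, window 3, window weight 0.5. The
window average of column i uses the mean of the up to `window` raw scores
on each side **excluding column i**, truncated at the alignment ends.
Ambiguity codes are treated as uninformative, like gaps. Columns with gap
fraction above 0.99 are flagged and score 0. No sequence weighting is
applied; with tens of orthologs of moderate redundancy the effect on
column ranks is small, but strongly biased alignments should be
de-duplicated upstream.

A fully conserved column against the uniform background (no pseudocount)
scores H((δ+u)/2) − H(u)/2 = 0.854997; the tests pin this closed-form value
to 1e−4.

## Ensemble descriptors

R_g is geometric (unit weights) by default, on alpha-carbons when reading
multi-model PDB files; mass weighting is available by passing per-site
weights. The all-pairs identity R_g² = (1/2N²) ΣΣ |r_i − r_j|² serves as an
independent oracle in the tests.

ν^app is estimated from **internal-distance scaling**: for each sequence
separation s ≥ `min_separation`, the RMS inter-site distance over all site
pairs at that separation and all conformers; then an ordinary least-squares
fit of log RMS against log s. The slope is ν^app. The default
`min_separation=10` skips short separations dominated by local stiffness.
Alternative estimators (e.g. R_g versus chain length across constructs)
measure related but not identical exponents; reported ν^app values are
comparable only within one estimator. The estimator's dynamic range is
validated by its two analytic anchors: a rigid rod (r_ij = d·|i−j|) must
give ν = 1, r² = 1 exactly, and a freely jointed chain must give ν = 0.5
within sampling error — brackets that straddle the ~0.48–0.55 range typical
of disordered proteins near the theta point.

## Synthetic data: what it emulates and what it does not

`generate_proteome` plants tracts with **exact** residue counts: a tract of
length L carries round(0.4·L) targets (first and last position always a
target; internal non-target runs ≤ `max_gap`) and round(his_density·L)
histidines, inside background flanks drawn from the 19 non-target residues.
Exact counts make recovery and composition assertions sharp rather than
statistical. Two gap modes exist: `random` scatters the interruptions
(realistic spacing heterogeneity); `exact` places interruptions of exactly
`max_gap` between target blocks too short to qualify alone, the
construction under which the sweep optimum provably sits at the planted gap
value — with random gaps, a smaller allowance can *fragment* tracts into
several qualifying pieces and raise the region count, so the region-count
argmax is only meaningful under the `exact` construction.

Defaults (tract length 40–80, target fraction 0.4, max gap 10, flanks
30–80, His densities 0.12 vs 0.08 for the Q-rich vs generic plants in the
benchmark conditions) were chosen to resemble the composition of real
yeast QLCs while keeping every plant unambiguously detectable.

What passing these benchmarks shows: the detector, segmenter, comparator
and scorers implement their definitions correctly, with exact boundary
behavior. What it does not show: performance on real proteomes, where
region boundaries are not planted, target-free flanks are not guaranteed,
compositional drift is continuous, and the detector's overlap-resolution
rule can differ from that of other published censuses. The six
reference-proteome checks in the acceptance tests cover that gap when the
reference FASTA files are supplied.

The freely jointed chain is used as the ν = 0.5 reference because its
closed forms (⟨r²(s)⟩ = s·b², ⟨R_g²⟩ → N·b²/6) make the acceptance bands
analytic; excluded-volume (self-avoiding) chains are out of scope. The
generators emulate coordinate ensembles only — they carry no energetics,
so they validate the descriptors, not any conformational prediction.

## Numerical conventions and problem sizes

- Internal coordinates 0-based half-open; all files 1-based inclusive.
- Duplicate FASTA ids are a hard error (downstream truth tables key on id);
  a terminal `*` is stripped with a warning, an internal `*` is an error.
- Region TSV fractions are written at 6 decimal places and restored exactly
  from integer counts on read-back.
- The detector-vs-enumeration equivalence runs on 1000 random sequences of
  length ≤ 60 over {Q, A, H}; the ideal-chain benchmarks use 100 sites ×
  2000 conformers; the planted-recovery benchmark uses 50 tracts among 60
  proteins. These sizes give sub-percent sampling error on every asserted
  quantity while keeping the full suite fast.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); reruns are byte-identical.
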