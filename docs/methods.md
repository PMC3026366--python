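# Methods

## Problem setting and assumptions

`tlgrn` infers a directed gene regulatory network from a single
genes × time-points expression matrix.  Three assumptions are built in:

1. **Equally spaced time points.**  All lag arithmetic counts sampling
   intervals; a lag of τ means "τ sampling steps later".  Unevenly spaced
   series are out of scope (a single integer lag per gene pair would not be
   well defined).  Time points are 1-based throughout.
2. **Boolean expression states.**  Every metric operates on ON/OFF (1/0)
   states.  Continuous input is quantized per gene (see below).  Two-level
   quantization loses amplitude information by design; the package does not
   implement finer quantization.
3. **Regulation acts with a positive delay.**  A regulator influences its
   target at least one sampling step later; contemporaneous dependence is
   never scored (the unit-lag mode uses τ = 1, never τ = 0, and the
   proposed lag construction yields τ ≥ 1 whenever it is defined).

## Preprocessing

Missing values are imputed first: an interior gap takes the mean of its two
temporal neighbours (runs of gaps fill left-to-right, each gap using the
already-filled value to its left and the next observed value to its right);
a missing first/last point copies the nearest observed value.  A fully
missing gene row is an error.

Quantization is rank-based per gene: sort the m values ascending, discard
exactly one minimum and one maximum as outliers (one cell each, even under
ties), threshold at the median of the remaining m − 2 values, and map every
original value — including the two trimmed extremes — to 1 iff strictly
above the threshold.  Strict comparison makes ties at the threshold go to
OFF, so a constant gene deterministically becomes all-0 (with a logged
warning).  The rule is invariant under any strictly monotone transform of a
gene's values, so normalization choices upstream do not change the binary
matrix.  At least 4 time points are required so trimming leaves ≥ 2 values.

## Lags

For a binary sequence, the *initial up-regulation time* U is the first
OFF→ON switch; a gene already ON at t = 1 is taken to up-regulate at t = 1
(there is no observable switch, and excluding such genes would discard
regulators active from the start — these pairs can be recognized by U = 1).
The lag from A to B is τ(A→B) = C_B(U_A) − U_A, where C_B(t₀) is B's first
state change strictly after t₀ (any flip, in either direction).  When A
never turns ON or B never changes afterwards the lag is *undefined* (a
value, not an error); `lag_matrix` then substitutes a configurable default
(τ = 1, the legacy unit-delay assumption) and sets a per-pair fallback
flag.  Lags that would leave fewer than `min_overlap` overlapping time
points are likewise replaced by the default and flagged.

The classic lag I_B − I_A (difference of initial change times) is provided
as `zou_lag` for comparison only; it is negative for one direction of every
asynchronous pair, which is exactly the deficiency the non-negative
construction removes.

## Information metrics

Entropy, joint entropy (2- and 3-variable), MI and CMI are plug-in
(maximum-likelihood) estimates from empirical symbol frequencies, in bits,
with 0·log 0 ≡ 0 and **no pseudocounts** (pseudocounts appear only inside
the code-length estimators, where they are part of the code definition).
The time-lagged variants trim before counting: for lag τ the regulator and
any conditioning gene keep positions 1…m−τ, the target keeps τ+1…m.  TLMI
at τ = 0 equals MI exactly; TLMI is not symmetric for τ > 0.

Numerical conventions: MI/CMI values in [−10⁻¹², 0) — floating-point noise
from the four-entropy formulas — are clamped to 0; anything more negative
raises an internal-consistency error rather than being silently absorbed.
`min_overlap` (default 4 time points) bounds how much trimming any lagged
metric may apply: with fewer than 4 points a binary MI estimate is
essentially noise.

## Network scoring and model selection

The score matrix has entry (i, j) = TLMI(row_i → row_j) at τ(i→j) (unit
mode: τ ≡ 1); the diagonal is excluded — a gene's MI with itself is its
entropy and would trivially pass any threshold, so self-loops are never
considered and are also rejected on network input.

Both selection schemes sweep **every distinct score** as a threshold
(edge i→j kept iff score ≥ θ), plus a +∞ sentinel for the empty network,
so every realizable candidate including the densest and the empty one is
priced.  Candidates are nested along the sweep, so each gene has at most n
distinct parent sets across all n² thresholds; per-gene code lengths are
cached on that structure, which is what makes 20-gene sweeps interactive.
Ties in total length break toward the larger threshold (the sparser
network).

Per gene j with parent set S and per-parent lags τ(i→j), coding uses the
common overlap window t ∈ [max τ + 1, m]; parent i is read at t − τ(i→j).
Parentless genes use the default lag's window so all candidates for a gene
price a comparable stretch of data.

- **Network MDL**: total = λ·model + data.  Model length per gene with
  k ≥ 1 parents is k·log₂ n (parent identities) + 2ᵏ·`cpt_entry_bits`
  (table memory, default 8 bits/entry); parentless genes are free, so the
  empty network has model length 0.  Data length is the batch add-½
  (Laplace) conditional code.  λ defaults to 0.2 for synthetic data; 0.1
  is the published choice for biological runs.  These formulas are this
  package's concrete instantiation of "memory usage + network entropy";
  absolute bit counts are implementation-specific and only the induced
  ranking of candidates matters.
- **PMDL**: total = Krichevsky–Trofimov sequential code length only — each
  target symbol is predicted from the counts seen so far in its
  parent-state context, (c + ½)/(total + 1), in time order.  This is a true
  predictive code and needs no model-length term, removing the arbitrary λ.
  After selection, CMI pruning removes every edge i→j whose TLCMI given
  some other current regulator k of j (at lag τ(i→j), k trimmed on the
  regulator side) falls below `theta_cmi` (default 0.1 bits).  Removal is
  simultaneous after the full scan, so the result is scan-order
  independent; a `--condition-all` flag conditions on every third gene
  instead of co-parents only, for sensitivity analysis.  Note that
  simultaneous removal deletes *both* edges of a mutually redundant
  co-parent pair (e.g. duplicated regulator rows) — a real identifiability
  limit of the data, not an implementation artifact.

A `max_parents` cap is available; without it, a warning is logged when any
conditional-probability table would exceed 2¹⁶ entries, since table memory
grows as 2ᵏ.

## Evaluation

Edges are matched directed (an `--undirected` flag relaxes this).
Conventions for degenerate denominators, both logged: precision = 1 when no
edges were inferred (nothing asserted falsely), recall = 1 when the true
network is empty.  These keep data-size sweeps total; the ratio R/P is
undefined (None/NA) when precision is 0.

`saturation_sweep` reruns inference on growing prefixes (default 15, 20, …)
of one series — 13 runs for a 75-point series — and scores each;
`mi_curve_study` reports mean gene entropy, mean pairwise conditional
entropy and mean pairwise MI per prefix length.

## Synthetic data generator

`random_network` draws, per gene, an in-degree ~ Binomial(max_in_degree,
edge_density) (defaults 3, 0.5), parents uniformly without replacement
excluding the gene itself, a uniform random truth table over the parents,
and (optionally) per-edge integer delays in [1, edge_delay_max], so data
with true multi-step lags can be generated.  `simulate_series` starts from
a uniform random state and updates synchronously; each updated symbol is
flipped independently with probability `noise` (default 0.05), and the
flipped state feeds the next update (process noise), so for noise > 0 the
dynamics form an ergodic Markov chain.  All outputs are bit-reproducible
from (seed, parameters).

`expression_series` adds a continuous microarray-like readout: expression =
OFF level + (ON − OFF)·state + Gaussian observation noise (default sd 0.4
of the dynamic range, mid-range for microarray readout variability).
Quantizing this readout with the package's own trimmed-median rule
reproduces the key statistical shape of real median-binarized expression
data: the full-series median split drives every gene's binary marginal
toward a balanced 50/50 — so empirical entropy rises toward 1 bit as more
time points are used — while the small-sample bias of plug-in MI inflates
short-prefix MI estimates, so mean pairwise MI falls as data grow.  This
is the mechanism behind the MI-saturation study, and it only emerges
through the continuous-readout + median-quantization path; raw Boolean
states (skewed attractor occupancy) do not show it.

Two degeneracies of noiseless Boolean dynamics matter for parameter-recovery
studies: collapse to a fixed point (constant rows, no signal) and
synchronization into a shared attractor cycle (duplicated rows, regulators
informationally interchangeable).  `informative_dataset` therefore draws
instances from the seeded stream until at least half the gene rows show
sustained variation (row entropy ≥ 0.5 bits) and the dynamic rows are
pairwise distinct up to complementation with at least 4 distinct patterns,
and uses the first such instance.  This is an identifiability precondition:
on data failing it, no method can attribute the regulation.

**What the generator does not emulate:** continuous kinetics (no ODE/SDE
integration), transcription/degradation time scales, module structure
derived from a real interactome, replicate structure, or distribution tails
of array intensities.  Passing tests on this generator demonstrate the
inference machinery's correctness and its qualitative behaviour (lag
recovery, indirect-edge pruning, MI saturation, data-size response), not
quantitative accuracy on any particular biological data set — in
particular, published saturation points of specific generator instances
elsewhere are not reproduced here.

## Problem sizes and defaults used in the shipped studies

- Identity suite: 1,000 random pairs/triples, lengths 4–50.
- Sweep-selection cross-checks: 50 instances, n ≤ 4, m ≤ 12, against a
  naive enumeration of every distinct-threshold candidate.
- Pruning study: A→C→B chain, m = 40, 50 seeds, unit lags (the chain's
  direct edges genuinely have τ = 1; the composite A→B dependence is then
  fully explained by C one step back).
- Saturation study: 5 genes, 100 time points, flip noise 0.05, readout
  noise 0.4, 20 seeds, prefixes 15 vs 100; sweep harness: 20 genes,
  75 points, prefixes 15…75 step 5 (13 runs).
- Recovery study: 10 genes, 60 points, noiseless, unit delays, time-lagged
  PMDL versus complete-graph precision and empty-graph recall.

These sizes keep the full test suite and the reproduction script in the
seconds-to-a-minute range on a laptop while leaving each effect clearly
resolved.

## Known limitations

- Plug-in MI on few points is biased; thresholds tuned on one m do not
  transfer to another.
- The MDL model-length constants (8 bits/CPT entry, λ) are conventions;
  compare totals only within one configuration.
- CMI pruning conditions on one gene at a time; higher-order redundancy
  (an edge explained only by two genes jointly) is not detected.
- The proposed lag uses only the first up-regulation event; genes with
  multiple regulatory episodes get the lag of the first one.
- No network visualization, no AUROC/AUPR, no multi-level quantization.
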