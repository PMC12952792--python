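# Methods

## The model

Direct RNA sequencing drives an RNA strand 3'→5' through a nanopore; the
measured ionic current depends on the 5-mer residing in the pore. The motor
protein does not translocate the strand strictly monotonically: it can
transiently pull it back or push it forward by a fraction of a nucleotide
("jiggling"), so during one 5-mer's residence individual current samples
intermittently match the previous or next 5-mer's baseline. squigseg models
a read's current trace as a hierarchical hidden Markov model:

* **Outer chain.** Two states, base (B) and transition (T), emit blocks of
  samples. A read's transcript region is an alternating sequence
  B, T, B, …, B that tiles the signal. The outer chain contributes
  per-sample transition probabilities
  π_{g₁} ∏ᵢ T_{gᵢ₋₁ gᵢ}; self-transition probabilities near 1
  (0.99 for B) act as the change-point penalty.
* **Inner chain (base blocks).** Four states — `prev`, `curr`, `next`,
  `noise` — with Gaussian emissions N(μ_prev/curr/next, σ_inner) sharing
  one std and a uniform density over a wide current interval for `noise`.
  The block emission probability is the forward-algorithm marginal over all
  hidden paths, computed in log space (numba kernels; an exhaustive 4ⁿ path
  sum verifies it in the tests).
* **Transition blocks.** An ordinary least-squares line; the block log
  likelihood is the Gaussian residual likelihood at a fixed residual scale.
  A line with |slope| below a floor is inadmissible as a transition, as are
  blocks shorter than 3 or longer than 10 samples.

During segmentation no reference is available yet, so μ_curr is the 10%
trimmed mean of the candidate block and μ_prev/μ_next are trimmed means of
the 12 samples flanking it; at the signal edges the corresponding state is
disabled (its chain column zeroed and renormalized).

### Segmentation search

Candidate boundaries come from a smoothed, excursion-robust derivative: the
absolute difference of two adjacent 16-sample window *medians* (a plain
mean would be inflated by isolated excursion samples), thresholded at 0.75
times the statistic's noise floor. The floor is estimated from the MAD of
the signal's first differences, not from the score's own distribution — on
these signals genuine steps cover a large fraction of positions and would
inflate a self-referential threshold. Each above-threshold run seeds its
peak neighbourhood and the whole run (the statistic plateaus over a ramp).
An exact dynamic program over the candidate lattice then maximizes the
joint objective (block emissions + outer-chain terms) under the alternation
constraint; ties prefer fewer blocks. For speed, base blocks spanning more
than 150 samples are only considered between adjacent candidates, which
keeps the degenerate constant-signal case (single spanning block) exact.

Base-block mean and std are computed from the samples the inner HMM
attributes to `curr` (posterior ≥ 0.5). Masking the excursion and noise
samples is what removes the structured jiggling noise from downstream
event statistics; with 5% excursions per side, unmasked event means are
biased toward neighbour baselines by up to ~1 pA, enough to corrupt k-mer
table re-estimation.

### Alignment

Block means μ₁…μ_m are aligned to the reference 5-mer list s₁…s_n (pore
order, 3'→5') by a dynamic program whose four moves per cell are diagonal
match, k-mer skip (deletion), mean skip (insertion) and a vertical *stay*
that matches an additional mean to the same k-mer — the many-to-one
behaviour that merges sub-state blocks. Match scores are log Gaussian
densities from the k-mer table (the larger of the unmodified/modified
component densities when a modified state exists); indels score as a fixed
uniform log density over the table's level span ± 3 max σ. Boundary
conditions are M(0,0)=0, M(i,0)=i·g, M(0,j)=j·g; traceback starts at
(m, n) with tie order stay > match > del > ins. The *partial* variant
restricts moves to match/stay, anchors the path at s₁ and takes the best
cell of the last row, aligning all means to a prefix of the k-mer list
(used when the read covers only the 3' end of the reference). Blocks
aligned to one k-mer merge into an *event*; event mean/std pool the
member-block moments (combined-moments identity over the masked samples),
dwell is the masked sample count, and coordinates are reported at the
k-mer's 5'-most reference position with sample indices in whole-read
coordinates.

### Modification calling

Event means pooled per 5-mer across reads and sites are fit with a
two-component Gaussian mixture by EM in which the unmodified component's
mean is pinned to the pore-model baseline at every M-step. Initialization
is deterministic given a seed: component 2 starts at the mean of the
points beyond one sample-std on the heavier side, weights (0.7, 0.3), with
three seeded jitter restarts keeping the best likelihood. A 5-mer becomes
callable when the fitted components separate by more than 5 pA and the
modified weight is ≥ 5%; σ_mod is clamped into [0.5, 10] pA and σ's never
collapse below 0.05 pA. Per read, the hard state compares the two
component densities (larger density wins) while the reported probability
is the ω-weighted posterior ω_mod φ_mod / (ω_un φ_un + ω_mod φ_mod); a
site's modification rate is the fraction of covering reads called
modified (default coverage floor 20). Re-estimation iterates
align → assemble → refit until the mean absolute change of component means
falls below 5·10⁻³ pA (at most 5 rounds by default).

## The simulator

`squigseg.simulate` generates reads under exactly this generative story:
a poly(A) segment (all-A baseline) followed by alternating base blocks and
linear transition ramps traversing the reference 3'→5'. Within a base
block each sample is drawn i.i.d. from the current 5-mer's Gaussian with
probability 1−p_prev−p_next−p_noise, from the previous/next 5-mer's
baseline with probability p_prev/p_next, or uniformly from a wide noise
interval; a run-length excursion variant is available behind a flag.
Modified DRACH centres (drawn per read at `mod_rate`) emit from
(μ_mod, σ_mod). Defaults and what they emulate:

| parameter | default | why |
|---|---|---|
| `dwell_mean` | 35 samples | RNA002 translocates ~70 nt/s at 3012 Hz (~43 samples/nt); 35 keeps reads compact |
| `trans_len_range` | (3, 8) | transition state holds ~6 samples per event |
| `p_prev`, `p_next`, `p_noise` | 0.05, 0.05, 0.01 | excursion/noise rates consistent with observed jiggling |
| `polya_len` | 1000 | long tails make the standardization anchor precise (std error ~2%) |
| `gain_sd`, `offset_sd` | 0.02, 1.5 pA | pore-to-pore variability, undone by standardization |
| `n_blocks_per_kmer_max` | 1 | one base block per 5-mer; the sub-state mode (>1, with a 3 pA sub-state baseline spread) exists but makes same-level boundaries unidentifiable by construction |
| `mod_rate` | 0 | modification studies set it explicitly |

`synthetic_table` draws per-5-mer levels i.i.d. Uniform(78, 132) pA and
stds Uniform(1.8, 2.6) pA, the approximate span of the RNA002 pore model.

**What the simulator does not emulate:** adapter sequences, within-read
current drift, dwell-time autocorrelation, correlated baselines of
overlapping k-mers, basecalling/mapping errors, and modifications other
than a single two-state shift at DRACH centres. Tests passing on this
generator therefore demonstrate correctness of the algorithms under the
model's own assumptions, not performance on real flow-cell data.

## Numerical choices and edge cases

* All HMM computations in log space; −inf propagates for zero-density
  configurations instead of raising.
* σ_inner defaults to a per-read robust noise estimate
  (MAD of first differences / √2, clipped to [0.8, 5] pA); a fixed value
  under-fits low-noise signals and over-segments them.
* Population (ddof 0) conventions for all stds, matching the pooled
  combined-moments identity exactly.
* Segmentation tie-break: fewer blocks at equal objective; alignment
  traceback order stay > match > del > ins — both make outputs
  deterministic.
* Signals shorter than `min_base_len` return a single flagged block;
  constant signals return one base block spanning the input.
* Reads without a usable poly(A) interval raise an explicit
  "unstandardizable" error; a heuristic fallback detector (longest
  low-rolling-std run ≥ 200 samples) is provided and clearly marked as
  such.
* 5-mers hit only by deletion steps yield no event row.
* Event-sample access: library paths keep the masked member samples on the
  event object; the CLI `benchmark` subcommand, which only has the
  eventalign TSV and the signal files, re-slices contiguous sample ranges
  and therefore re-includes intra-event transition samples — use the
  library path for exact numbers.

## Evaluation protocol (desk scale)

`squigseg.benchmarks` fixes the simulation studies the test suite and
`scripts/acceptance.py` run: 50 reads over five random 30-nt references
for boundary recovery (±5 samples); 20-seed mixture recovery at
n = 1000 + 1000, Δ = 8 pA, σ = 2 pA; single-site m6A calling at coverage
200, true rate 0.3, Δ = 8 pA; table re-estimation from a 2 pA-perturbed
start at 120 reads; and a 12-read paired comparison against an equal-width
splitter (trim 3 for the splitter, which keeps its boundary samples). The
problem sizes are chosen so the full protocol runs in a few minutes on one
CPU while leaving each estimate's sampling error well inside the margins
the tests assert.

## Known limitations

* Boundaries between adjacent 5-mers whose baselines differ by ≲2 pA are
  unidentifiable in principle; with the RNA002-like level spread this caps
  boundary recovery around 94–96%.
* The DP is exact only over the proposed candidate lattice (plus the
  base-block span cap); a boundary the proposal misses cannot be recovered.
* Only the central position of a 5-mer carries a modification state; a
  5-mer influenced by modifications at several positions would need
  2⁵ = 32 states and is out of scope.
* The partial-alignment variant anchors at the first pore-order k-mer; it
  does not search for an arbitrary alignment window.
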