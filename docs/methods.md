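# Methods

## Resolution model

The theory module treats read-pair deletion calling as a geometric
placement problem. Read pairs fall uniformly and independently on a genome
of length `G`; reads have fixed length `r` and the two mates of a pair are
separated by a fixed inner distance `d` (the gap between the mates'
alignments, not the outer fragment length — the same convention the
simulator and the caller use). With `N` pairs the per-base probability that
no pair's upstream read begins at a given position is
`q = (1 − 1/G)^N`, approximated by `exp(−c/2r)` where `c = 2rN/G` is the
depth of coverage; the exact finite-genome form is used when `G` and `N`
are supplied instead of `c`.

A breakpoint `b` (upstream end of a homozygous deletion) is *detected* when
at least one discordant upstream read ends within `d` bases of it
(`P_b = 1 − q^(d+1)`). Conditional on detection, the distance from `b` to
the closest discordant read end follows `Pr(A_j) = (1−q) qʲ`, giving

    E[Δb | b, c] = (1−q)/(1−q^(d+1)) · S(q, d),

and the distance to the closest read end of any kind follows
`Pr(A′_j) = (1−q²) q^(2j) − q^(d+1) (1−q) qʲ`, giving

    E[Δ′b | b, c] = [(1−q²) S(q², d) − q^(d+1)(1−q) S(q, d)] / (1−q^(d+1)),

with `S(q, d) = Σ_{j≤d} j qʲ`. Substituting `q²` for `q` is exactly
doubling the coverage, which yields the identity
`E[Δ′b|b,c] = (1+q^(d+1)) E[Δb|b,2c] − q^(d+1) E[Δb|b,c]`; the test suite
verifies it to < 1e−9 relative over a 48-point grid, together with the
limits (all three expectations → `d/2` as `c → 0`; `E[Δ′b] → E[Δb|b,2c]`
at deep coverage).

The Monte-Carlo oracle simulates the same generative model directly:
independently at each offset `0..d` upstream of `b` it places a
discordant-pair read end with probability `1−q` and a concordant read end
with probability `1−q`, conditions on detection, and records the two
minima. Concordant placement is truncated at offset `d` because,
conditional on detection, `Δ′b ≤ Δb ≤ d`, so farther positions cannot
matter; this makes the oracle exact without unbounded loops. It is run
chunked (≤ 2²⁴ draws per block) so memory stays flat at 10⁵ trials.

### Numerical choices

* `S(q, d)`'s closed form divides by `(1−q)²` and cancels catastrophically
  as `q → 1`; when `(d+1)(1−q) < 0.1` the series is summed directly from
  `log q` (O(d), exact to machine precision). All powers of `q` are
  computed from `log q` (`−c/2r`, or `N·log1p(−1/G)`) via `exp`/`expm1`,
  so `1 − q^(d+1)` is stable arbitrarily close to `q = 1`.
* `q = 1` (zero coverage) and `q = 0` are handled by their analytic limits
  (`d/2` and `0`) instead of floating division.
* All expectations are conditional on detection (division by `P_b`).

## Trimming algorithm

Input: a deletion call's per-base coverage vector `c[1..L]` (ordered from
the end being processed), a coverage threshold `k ≥ 1` and a joint-coverage
fraction `f ∈ (0, 1]`.

1. Trim the maximal initial run with `c[x] > k` unconditionally.
2. Repeatedly consume a maximal run with `c[x] ≤ k` followed by a maximal
   run with `c[x] > k`. If the high run is empty, stop. Otherwise commit
   the extension iff the cumulative mean coverage of everything consumed so
   far exceeds `k·f`; on failure, stop and revert to the last commit.
3. Return the committed prefix length.

Comparisons are strict (`> k`, `> k·f`): a base at exactly `k` is low
coverage, which makes the procedure harmless on calls whose interior never
exceeds `k` — in particular on truly deleted regions with scattered 1×
noise when `k ≥ 2`. An extension must end on a high run; otherwise a long
trailing low-coverage stretch could be trimmed purely by dilution, which
would contradict the method's purpose. The cumulative mean (no reset after
a commit) is the default reading of the "joint coverage"; a
`joint_reset=True` variant that restarts the running sum after every commit
is provided for comparison, with no claim that either matches any external
implementation bit-for-bit. The streaming implementation is verified
against a brute-force largest-qualifying-prefix enumeration on 10⁴ random
vectors.

Both call ends are trimmed independently on the same vector (the
downstream trim is the upstream trim of the reversed vector); when the two
trims meet or cross, the call is removed. `pad` widens a call on both
sides before trimming, for window-resolution callers whose breakpoints may
already lie inside the deletion; with `pad = 0` the trimmed call is always
a subset of the original.

Defaults `k = 2`, `f = 0.5`. `k` should scale with depth (it separates
real coverage from erroneous alignments: raise it on deep or dirty data);
`f` controls how aggressively fragmented high-coverage evidence separated
by gaps is absorbed — smaller is more aggressive, `f = 1` effectively
requires the joint region to look like normal coverage.

## Simulator

The generator emulates a homozygous-deletion resequencing experiment:

* uniform random A/C/G/T reference (default 10 Mb, one contig);
* 50 deletions with log-uniform lengths in [100, 10000] bp, plus an equal
  number of insertions whose lengths are a permutation of the deletion
  lengths (the two SV classes are symmetric by construction); SVs are
  placed non-overlapping with at least `2(d̄ + r)` = 600 bp separation, so
  deletion calls are unambiguously one-to-one — placement distributes the
  slack multinomially instead of rejection-sampling, so it is exact and
  deterministic;
* per-base substitutions at rate 1e−4 (each hit base becomes a different
  base);
* `round(cL/2r)` read pairs with uniform upstream starts and inner
  distances `round(Normal(200, 50))` truncated at 0;
* an idealized unique mapper: a read maps iff its sample interval is one
  contiguous reference stretch; reads in novel insertions or crossing an
  SV junction are unmapped and the whole pair is dropped, which has the
  same effect as removing pairs with a zero-MAPQ mate. Retained reads get
  MAPQ 60. Pairs flanking a deletion keep both mates with the inner
  distance enlarged by the deleted length; pairs flanking an insertion
  shrink, and if the insertion exceeds the pair span the mates swap
  reference order and the pair is flagged improperly oriented.

Every stage draws from a named substream of one top-level seed
(`numpy` `SeedSequence.spawn`), so runs are byte-reproducible and stages
can be re-run in isolation.

What the generator does **not** emulate: repeats and mapping ambiguity
(every retained read is uniquely placed; MAPQ is binary), indel/sequencing
errors beyond substitutions, soft-clipped or split alignment of
junction-crossing reads, GC or positional coverage bias, and
heterozygosity. Substitutions therefore never perturb placements — they
matter only in exported FASTQ. Consequently, passing tests show the
method's behaviour under clean unique mapping with abrupt coverage edges,
not its robustness to repeat-induced mis-alignment, which on real data is
the main source of coverage inside deletions.

One structural consequence deserves emphasis, because the test suite
measures it. Since junction-crossing reads are dropped, coverage decays to
zero over the last read length before each true breakpoint (only reads
ending before the junction remain, their ends arriving at density `c/2r`
to `c/r` per base). The built-in RP caller emits the *intersection* of its
supporting pairs' inner intervals, so its boundary already sits at the
closest discordant read end. Between that boundary and the breakpoint the
expected coverage is below `k = 2` almost everywhere, so the trimmer —
which by design only removes bases with ≥ `k+1`-fold evidence — leaves
such calls essentially unchanged (the end-to-end comparison in the
acceptance script computes the before/after medians). Its measurable
benefits in this pipeline are (a) removing false-positive clusters, which
lie in fully covered sequence and are erased entirely, and (b) correcting
calls that overshoot into covered flanks by more than the coverage-taper
width — window-resolution or padded calls, as in the worked example. The
theory module's `E[Δ′b|b,c]` is the bound any coverage-guided refinement
could reach; reaching it would require single-read sensitivity (`k = 0`),
which would no longer be robust to erroneous alignments.

## Caller and evaluation

The caller estimates the insert model from properly oriented pairs with
one pass of outlier exclusion (distances > μ₀ + 5σ₀ dropped before
re-estimating, so deletion-spanning pairs do not inflate σ), classifies a
pair as deletion-discordant when its inner distance exceeds μ + 3σ,
clusters mutually overlapping discordant inner intervals by single
linkage, and reports `[max(up_end), min(down_start))` for clusters of ≥ 2
pairs. It is deliberately minimal; its false-positive rate grows with
genome size (insert-size tail pairs cluster by chance at a rate ∝ N²/G),
which the evaluation quantifies rather than hides.

A call is *correct* iff it overlaps exactly one true deletion and that
deletion overlaps exactly one call (≥ 1 shared base, half-open
arithmetic). Upstream difference = `truth.start − call.start`; downstream
difference = `call.end − truth.end`; positive means the called end lies
outside the true deletion. Recall = correct/truths, precision =
correct/calls (0 when a denominator is 0). Quartiles are numpy's linear
interpolation. The before/after comparison pairs records by matched
truth, counting truths whose call was removed or degraded as lost, and
reports the fraction driven from non-negative to negative (over-trimmed).

## Problem sizes used in the tests

Unit and property tests run on vectors ≤ 200 bases and genomes of 1–2 Mb;
the end-to-end checks use the standard 10 Mb / 50-deletion configuration
at coverages 5 and 10, and the Monte-Carlo grid uses 10⁵ trials per point.
These sizes keep the full suite under a minute while leaving every rate
estimate with comfortable statistical margin (binomial/Poisson 3σ bands
are stated next to each threshold in the tests).

## Known limitations

* Homozygous deletions only: a heterozygous deletion halves coverage
  instead of zeroing it, and the trimmer as specified would remove such
  calls outright at usual `k`.
* No split-read reasoning: bp-exact breakpoints from clipped reads are a
  different signature class and out of scope.
* The caller is a stand-in for exercising the pipeline, not a competitive
  SV caller.
* Coordinates are single-contig-per-track; whole-genome coverage uses one
  dense array per contig (40 MB per 10 Mb contig at int32), which is fine
  at the simulated scales but would need chunking for mammalian-scale
  contigs.
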