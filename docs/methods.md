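# Methods

`dnacodec` stores binary data in DNA under sequence constraints by
concatenating two codes: an inner joint source/channel code that maps bits
onto constraint-adhering bases via arithmetic coding run in reverse, and an
outer rateless fountain code that tolerates the loss of whole strands.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic evaluation does and does not show.

## Constrained sequence space

A codebook is a set *C* of DNA words of uniform length *n* satisfying the
user's constraints: GC fraction bounded in consecutive, non-overlapping
windows of `gc_interval` nt anchored at position 0 (trailing partial windows
exempt), homopolymer runs capped at `hp_max`, and forbidden motifs screened
case-insensitively on the forward strand (reverse complements opt-in).
The capacity cost is

    redundancy (bits/base) = 2 − log₂|C| / n,

zero for the unconstrained codebook and 2 in the degenerate single-word
limit.  `generate_codebook` enumerates the 4ⁿ space exhaustively (guarded at
n ≤ 16, vectorized in chunks), so it is an option for word lengths up to
~12; larger codebooks can be supplied as FASTA.

Constraints can also break *between* words, so the codebook travels with a
concatenation scheme: forbidden suffix→prefix pairs.  A junction run of
`hp_max`+1 identical bases split a+b across the boundary yields the pair
(xᵃ → xᵇ) for every split with b ≤ n; splits needing a longer next-word
prefix are caught one junction later, because keys are matched against the
rolling suffix of the whole emitted stream (this is also why keys may be
longer than a codeword — with 1-mer words a homopolymer cap is expressible
only as AAA→A-style rules).  Motif rules come from every boundary-spanning
split of each motif, which is why motifs longer than one codeword are
rejected.  GC content is *not* re-checked across junctions: when
`gc_interval` divides n (as in the evaluation codebook, n = 10 with 10 nt
windows) every complete window lies inside one word and nothing is lost;
for other geometries `validate_sequence` is the oracle that would surface
drift.

## Transition model

The model is a finite state transition diagram whose states are (position
in the current word, word prefix so far, rolling suffix of the emitted
stream).  P(base | state) is the empirical frequency of codewords extending
the prefix with that base — counts, not smoothed probabilities — with
codewords excluded when the junction context forbids their prefix.  States
are realized lazily; prefix counts are two binary searches on the sorted
integer codes of the codebook, so the 654k-word evaluation codebook needs
no materialized diagram.  The retained context width is the longest scheme
key (which, for generated schemes, equals max(hp_max, longest motif − 1)).
Because prefix frequencies telescope, the probability of any full word at
an unconstrained junction is exactly 1/|C|: the per-base information sums
to log₂|C|, consistent with the redundancy formula.

## Inner code: arithmetic modulation with CRC markers

The encoder is an arithmetic *decoder*: the framed payload bitstream is
treated as the code value of a compressed DNA string and expanded against
the model, one base per subinterval selection, in fixed A, C, G, T order.
The integer engine uses a 32-bit interval with standard E1/E2
renormalization and E3 straddle (pending-bit) handling; subinterval
boundaries are computed from integer codeword counts, so encoder and
decoder partition identically.  An exact rational engine over arbitrary
alphabets (`arith_interval`) serves as an independent oracle; the property
suite checks that the integer coder's emitted bit string always lies inside
the exact final interval.

Framing inserts an 8-bit CRC (polynomial 0x07, init 0x00, no reflection —
the plain SMBus variant; only the width is semantically load-bearing) after
every `s` payload bytes, the trailing partial block getting the final CRC;
when the payload length is an exact multiple of `s` the last window CRC
doubles as the final CRC.

Termination: modulation runs a shadow arithmetic encoder in lockstep and
stops as soon as the shadow has resolved every payload bit — the minimal
flush.  The decoder's padding bits after the payload are an alternating
0101… tail rather than zeros: an all-zero tail makes the implied code value
dyadic, and a dyadic value can sit exactly on a renormalization boundary so
that the final straddle never resolves (observed as an unbounded pending
count).  The alternating tail is never dyadic, so every bit resolves after
finitely many bases.  Optional padding to a target length is a
deterministic most-probable-base walk (ties in A<C<G<T order); the
demodulator knows the payload byte count and discards it.

## Sequential decoding

The error-tolerant decoder is a generalized stack algorithm over
arithmetic-demodulation states.  Each expansion produces up to nine
children: four base hypotheses scored against the current channel symbol
(match or substitution), four deletion hypotheses (base emitted, no symbol
consumed), and one insertion hypothesis (symbol skipped) allowed when the
following symbol is itself a model-plausible continuation.  The metric is
the Fano metric of an approximating binary symmetric channel with
transition probability p_t,

    match:    log₂(2(1−p_t)) − R + log₂ P(base | state)
    mismatch: log₂(2·p_t)    − R + log₂ P(base | state)

with deletion and insertion branches reusing the mismatch shape with their
own event probabilities (insertions carry no prior, as no base is emitted).
The model prior enters in the log domain to keep the metric additive.

**Bias choice.** The bias R is not the realized information rate: because
the prior term contributes −H(model) per base in expectation, a
conventional rate-valued bias gives the correct path a strongly negative
drift, turning the search breadth-first — and, worse, letting deletion
branches free-run and mine CRC-8 collisions into self-consistent but wrong
payloads.  The default is therefore

    R = log₂(2(1−p_t)) − H(model) − drift_margin,

with `drift_margin` = 0.25 bits/base, making the correct path's expected
increment exactly +0.25 while typical wrong continuations sink by several
bits.  R remains user-overridable.

CRC windows are verified the moment the bytes that complete them resolve;
failing children are pruned before creation.  Termination additionally
requires the candidate to have consumed all but `tail_slack` (default 8) of
the channel output — a CRC-consistent path that ignores most of the strand
is spurious.  When two paths under the same passed-CRC anchor fail the next
window, the whole stacked subtree can be penalized (`penalty` bits); with
the equivalent-state merge below the penalty is off by default, as
measurements showed it mostly displaced the truth-containing subtree.

**Equivalent-state merging.** Deletion/insertion hypotheses commute with
base hypotheses, so distinct branch orderings reach identical decoder
states (same coding interval, pending bits, resolved bytes, model state,
channel position).  With `merge_equivalent` (default, requires the penalty
off) only the best-metric copy of a state is kept, collapsing the
factorially many indel orderings; this roughly halved the search on
substitution channels and tripled throughput on mixed channels.

A numba-compiled fast path implements the identical search on a
struct-of-arrays node pool with lazy dual heaps (best-first pop with FIFO
tie-breaking, worst-first eviction at stack bound M); the pure-Python
reference implementation remains the semantic definition and the test
suite checks the two agree.

**Residual wrong decodes.** When a strand is genuinely too damaged, the
search can settle on a path that passes all 8-bit windows by collision
(~2–6% of failures at the stressed operating points).  Inner CRCs alone are
therefore not packet integrity; the outer code's optional per-packet
checksum (16-bit default, 32-bit available) plus a seed-range sanity check
discards such packets as erasures, and the file-wide CRC-32 with
over-complete re-elimination is the last line of defense.

**Payload whitening.**  Packet wires begin with small sequential seeds, and
low-entropy bytes make the arithmetic modulator walk the low end of every
interval — all strands shared a visibly repetitive prefix.  The pipeline
therefore XORs each wire with a fixed PCG64 keystream before framing (and
again after decoding; the operation is self-inverse and pinned), restoring
the uniform-bit assumption behind the flat base composition of
arithmetic-modulated strands.  Neither code sees the difference.

## Outer code: seeded fountain

Files are split into fixed-size chunks behind an optional header chunk
([u16 padding][u32 file CRC-32][NUL-terminated UTF-8 filename]); the header
must fit one chunk.  Each packet is the XOR of a seed-determined subset:
the seed initializes a pinned 32-bit generator (numpy PCG64), a degree is
drawn from the robust soliton distribution (c = 0.1, δ = 0.05; chosen so
that 1.3k packets over k = 20 chunks reach rank k in ≥95% of trials — the
textbook c = 0.03 manages only 75% under Gaussian elimination at small k),
and that many distinct chunk indices are drawn without replacement.  The
encoder verifies the emitted seed set spans all chunks over GF(2) and
appends extra seeds when it does not, so a clean channel always decodes.

Decoding sorts packets by inner-decoder final metric and performs online
GF(2) elimination in that order: a packet becomes a pivot only if it is
independent of the better packets already used — the metric-ordered
analogue of partial pivoting, which automatically excludes the worst
packets whenever the better ones already have full rank.  Any rank-k subset
reconstructs; a file-checksum mismatch triggers fallback reordering
(greedy single exclusions, then seeded random subsets within a budget).

The pipeline decodes strands progressively: every strand is first tried at
a small iteration cap, reconstruction is attempted as soon as enough
packets accumulate, and only while packets are still missing are leftover
strands escalated toward the full budget.  Easy channels therefore never
pay the worst-case search cost; the per-strand results are unchanged.

## Channel model and evaluation scale

The simulator applies i.i.d. per-base events in a fixed draw order:
insertion of a uniform base before the position, then deletion, then
substitution to a uniformly chosen different base — deterministic given a
seed.  Mixed-mode sweeps scale the high-mutagenesis rates (substitution
0.0238, deletion 0.0082, insertion 0.0039) by a common multiplier so their
sum matches the target aggregate BER, counted per original base.

The stressed-channel evaluation uses a 1 KiB random payload (scaled down
from multi-KiB originals), a codebook of all 10-mers with GC 40–60% per
10 nt window and homopolymers ≤ 3 (|C| = 653,896, redundancy 0.068
bits/base), CRC step s = 1, 8-byte chunks with a 16-bit packet checksum
(14-byte packet wires, ~117 nt strands), stack bound 30,000 with budget
escalation 30k → 80k → 150k expansions, and fountain overhead ε = 0.5
(substitutions, ~0.07 per-base) or ε = 0.8 with p_t = 0.12 (mixed, 0.065
aggregate).  Ten end-to-end trials per operating point; the problem sizes
keep a full evaluation within minutes on one core.

What this shows — and does not.  The synthetic channel is i.i.d. and
sequence-independent: no coverage skew, no sequence-dependent synthesis
error hotspots, no strand-level dropout model beyond whole-packet erasure,
and no read redundancy (each strand is seen exactly once, which is far
harsher than sequencing practice).  Passing these trials demonstrates the
coding machinery — constraint adherence, indel resynchronization, erasure
recovery — not wet-lab performance.

## Known limitations

- Generated schemes cannot express junction rules whose necessary next-word
  prefix exceeds one codeword (motifs longer than n are rejected for this
  reason).
- The stack decoder's wrong-payload residual makes the inner code unsafe
  without an outer integrity layer; this is inherent to short sync markers.
- Fountain decoding is Gaussian elimination only; belief propagation is an
  optimization, not implemented.
- Strand orientation is taken as given; an opt-in flag retries failed
  strands in the reverse-complement orientation, but no automatic
  orientation detection is attempted.
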