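# Methods notes

This note documents the models behind `drtkit`'s generators and
measurements, the defaults and why they were chosen, the numerical
decisions, and what the synthetic-data tests do and do not demonstrate
about real data.

## Read simulation model

`synthetic_data.simulate_product_read_set` draws each read independently:

* with probability `product_fraction` (default 0.8) the read is an RT
  **product**: a poly(dA) core of geometric length (support ≥ 1, mean
  `mu_core` = 30 nt), extended with probability `p_tail` = 0.3 by a
  3′ poly-C tail of geometric length (mean `mu_tail` = 8 nt) — the
  signature of template-independent terminal-transferase addition;
* otherwise it is a **contaminant**: a fixed-length
  (`read_length_cap` = 150 nt) substring of the supplied reference drawn
  uniformly, emulating fixed-cycle sequencing of carryover DNA. A
  fixed read length was chosen over reusing the product length law
  because real contaminant fragments are sequenced at full cycle count;
  a short geometric law would also make a large fraction of contaminant
  reads shorter than the triage k-mer size and undermine the
  mapped/unmapped ground truth the simulator is supposed to provide.

Noise is applied after assembly — per-base substitution to a uniformly
chosen different base at `sub_error_rate` = 0.01, then N-masking at
`n_rate` = 0.001 — so the truth table (label, core length, tail length)
describes the pre-noise read. The geometric law is a deliberate
single-parameter, memoryless convention: nothing about the product length
distribution is assumed beyond its mean, and both laws are configurable.
Reads are emitted as FASTQ with uniform quality `I`; qualities are carried
through trimming but never consulted.

Per-read random streams are spawned from one integer seed
(`numpy.random.SeedSequence.spawn`), so output is byte-identical across
runs and insensitive to consumption order.

**What this does not model:** indels, quality-dependent errors, adapter
read-through, PCR duplicates with divergent errors, or any real
library-preparation length profile. Passing tests show the pipeline's
operations are correct under the stated statistical structure, not that an
arbitrary real library will behave identically.

## Poly-C tail trimming

The trimmed window is the longest 3′-terminal window that (a) is at least
`min_tail` = 5 nt long, (b) begins and ends with C, and (c) contains at
most `max_mismatch` = 1 non-C base. The C-delimited rule means the
mismatch budget absorbs sequencing noise *inside* the tail but the trim
never removes a template boundary base (e.g. the final A of a short
core). A read that is entirely tail is dropped and counted. The operation
is provably idempotent: maximality of the window forces the retained read
to end in non-C. Trimming parameters are echoed into every report because
no canonical values exist for this artifact. A 5′ mode covers
reverse-complemented libraries.

Profiles (spectrum, positional composition, N-CPM) are computed on
post-trim reads by default, matching the workflow order composition →
trim → re-profile; the stages are independently callable if a different
order is wanted.

## Homopolymer spectrum semantics

Counting is read-level: a read contributes at most once per
(base, threshold) cell, so each cell is "percent of reads containing ≥ 1
qualifying run" and rows are non-increasing in the threshold by
construction. Run-level counting (runs per 100 reads) is available behind
a flag for diagnostics. N breaks runs and never forms one. CPM uses the
read count as denominator (ambiguous bases per million reads), not the
base count.

## k-mer triage surrogate

The internal classifier is a stand-in for an external aligner at desk
scale, not a reproduction of one: an index of all k-mers (k = 15, both
strands) per reference, with a read called mapped at ≥ 2 hits. k = 15 in
a 50-nt read tolerates one substitution while keeping the chance-match
probability of a random 15-mer against a 5-kb reference negligible
(≈ 10⁴ · 10⁴/4¹⁵ per read-pair well below 1%). Raising `min_hits` can
only move reads from mapped to unmapped (monotonicity is tested). Reads
matching several references are assigned to the first in configuration
order and counted once. For real data, the SAM route
(`seqio.parse_sam_unmapped`) consumes any aligner's output; secondary and
supplementary records are excluded so each read appears exactly once.

## Motif-input preparation

"Clustered by sequence identity" is implemented as exact full-length
identity (consistent with retaining "identical copies"); near-identity
clustering is explicitly out of scope. Clustering operates on post-trim
reads, since tails would otherwise split clusters. The poly(A) filter
default (≥ 10-nt A-run) is a configurable convention — only
"poly(A)-containing" is specified by the workflow — and under exact
identity the filter and the clustering commute (tested both ways).
Representatives with ≥ 10 copies are exported as
`cluster{rank}_n{count}` FASTA records; the recommended external MEME
call (ZOOPS model, width 35–40) is logged, never executed.

## Assembly inter-unit angle

A unit's **axis** is the first principal direction of its representative
atoms (Cα for amino acids, P for nucleotides), directed so that
axis · (last − first residue) > 0; with a known helix span (e.g. an α10
helix read off a deposited model) the fit can be restricted to that range
(`axis_mode="helix"`). The default whole-unit PCA mode exists because
helix boundaries are generally not printed; on head-to-head dimer units
the two modes give closely aligned directions.

The **assembly plane** is the least-variance direction of the pooled
coordinates — the "top view" in which the angle is defined. Angles are
measured between directed axes *after projection onto this plane*:
unprojected 3D angles between tilted axes would not be symmetry-forced to
120° even in an exactly C3 assembly. Directed (not folded) angles keep
the obtuse 120° hexamer geometry distinct from 60°. Adjacency is the
cyclic angular order of unit centroids about the normal. Classification
windows [75°, 105°) / [105°, 135°] put ±15° margins around the canonical
90° (tetramer) and 120° (hexamer) packings.

Numerical guards: ≥ 5 points and nonzero variance for an axis fit;
plane rejected as undefined when the smallest singular value is within
10% of the middle one (near-isotropic cloud); projection rejected when an
axis is within 10⁻⁶ of the plane normal.

**A subtlety worth recording:** the principal axis of a *finite discrete*
helix is intrinsically tilted away from its geometric axis (≈ 2° at
rise 1.5 Å, radius 2.3 Å, 20 residues) because the linear coordinate
correlates with the spiral phase. The helix generator therefore centres
phases on the midpoint, which confines the tilt to a fixed plane of the
helix frame; `simulate_planar_assembly` builds every unit from one
template (default 90°/residue twist, i.e. whole turns over 20 residues)
oriented so that the tilt stays inside the assembly plane and is
identical for all units — it cancels exactly in inter-unit angle
differences, which is why synthetic assemblies round-trip to < 10⁻⁶°
while a lone helix axis is only accurate to a couple of degrees.
Axis-recovery tests for single helices accordingly use radius 0 or
rotation-equivariance rather than absolute direction.

## ncRNA conservation

Upstream extraction uses 0-based half-open feature coordinates: `+`
strand → `[start−L, start)`, `−` strand → reverse complement of
`[end, end+L)`, truncated with a warning at contig edges. The default
L = 300 nt covers a ~190-nt ncRNA with margin; the anchor (CDS start vs
annotated gene start) is the caller's choice and is logged.

Reference-gap stripping removes exactly the alignment columns where the
chosen reference row has a gap, so output columns index the ungapped
reference 1:1 (idempotent; column count equals the ungapped reference
length). Column profiles exclude gaps from the frequency denominator and
report the gap fraction separately, the standard sequence-logo
convention; no small-sample IC correction is applied by default since the
profile here feeds tract detection rather than logo display. Internal
alphabet is DNA throughout; `rna=True` maps T→U at output only.

The family generator mutates a reference i.i.d. per position at
`sub_rate`, never touching masked positions, and can insert reference-gap
columns with a known true column map — which is exactly what the
gap-stripping oracle test consumes. At the test conditions (100
homologs, 30% substitution) an unmasked column reaches 95% consensus with
probability ≈ 10⁻¹⁰, so recovering exactly one 4-column tract is a sharp
check, not a lenient one.

## Problem sizes and determinism

The reference simulation used across the test suite and the acceptance
script is 10,000 reads — large enough that binomial 3σ bands are a few
tenths of a percent, small enough to run in seconds. Geometry and
conservation checks use 2–3 units × 20 residues and 100 × 188-nt
families. Every stochastic step takes an explicit seed; the orchestrated
pipeline is byte-deterministic given (config, seed), which is asserted by
test.

## Known limitations

* The k-mer classifier is not an aligner: no gapped alignment, no mapping
  quality, no clipping; boundary decisions near k will differ from any
  real aligner's.
* Exact-identity clustering treats a single sequencing error as a new
  cluster; the ≥ 10-copy filter therefore underestimates product
  diversity at high error rates.
* The angle measurement assumes an approximately planar assembly; for
  strongly non-planar oligomers the projected angle depends on the
  plane estimate, and the isotropy guard will reject clouds with no
  preferred plane rather than guess.
* Conservation profiling assumes an externally produced alignment;
  alignment errors propagate into column statistics unexamined.
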