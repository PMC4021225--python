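# Methods

## Problem and model

`psmatch` interprets tandem mass spectra (MS/MS) by peptide-spectrum matching
(PSM): each experimental spectrum is searched against a peptide database
digested in silico from a protein FASTA, the best-scoring candidate peptide is
reported, and the confidence of that top score is summarised as a z-value
against the candidate-score population. The package additionally provides two
parallel execution regimes — multicore (shared-memory workers on one machine)
and distributed (a head node dispatching chunks to isolated worker processes)
— whose results are contractually identical, field for field, to serial
execution. Speed is an engineering property here; correctness is defined as
serial identity, and that is what the test suite asserts.

## Peptide database and the 2-D index

Proteins are digested with the tryptic rule (cleave C-terminal to K or R
unless the next residue is P), emitting every peptide spanning at most
`max_missed` internal cleavage sites (default 2), filtered to length 6–50 and
neutral mass 500–5000 Da. These digestion defaults are standard practice for
tryptic searches and are all configuration-exposed. Identical sequences across
proteins are merged into one entry carrying the union of parent accessions;
a peptide's internal cleavage-site count is a function of its own sequence, so
merging never creates ambiguity in the recorded missed-cleavage count.

Masses are monoisotopic: the residue table is the standard IUPAC monoisotopic
table (via pyteomics), water is 18.010565 Da and the proton 1.007276 Da. An
optional fixed-modification table (residue → constant offset) is applied at
mass-computation time; it is empty by default.

The index is two-dimensional: peptides are bucketed by the integer part
(floor) of their neutral mass, and each bucket is sorted ascending by mass
with ties broken lexicographically by sequence, which makes index construction
and every downstream query fully deterministic. Candidate retrieval for a
precursor neutral mass Mm with tolerance t returns **all** peptides in the
closed window [Mm − t, Mm + t]: only buckets with keys in
[floor(Mm − t), floor(Mm + t)] are visited and the two edge buckets are
trimmed by binary search. The closed interval is the inclusive reading of a
"between Mm − t and Mm + t" window and is directly testable against a linear
scan; the tolerance is in Daltons only (a ppm mode would change the bucket
arithmetic and is out of scope). Exhaustive retrieval, rather than a
first-match probe, is required because every candidate must be scored for the
significance computation to be meaningful.

## Fragment ions and scoring

Eight singly-charged fragment-ion types are generated per candidate: the b
and y backbone series and their neutral-loss satellites b−H2O, b−NH3, b−CO
(the a ion), y−H2O, y−NH3, y−NH (the z ion). For a peptide of length L each
series has L−1 ions, so a full theoretical spectrum holds 8 × (L − 1) ions.
Two offset modes exist: `exact` subtracts the monoisotopic loss masses
(H2O 18.010565, NH3 17.026549, CO 27.994915, NH 15.010899 Da) and is the
chemically correct default; `nominal` subtracts the integer offsets
18/17/28 (b side) and 18/17/15 (y side), reproducing the conventional
integer-offset table bit-exactly. Coincident theoretical m/z values are kept
and counted separately. Only 1+ fragments are generated; multiply-charged
fragment series for high-charge precursors are a known limitation.

The similarity score compares m/z values: a theoretical ion is matched when
at least one experimental peak lies within ± `fragment_tol_da` (default
0.5 Da) of it, located by binary search over the m/z-sorted peak list; one
experimental peak may serve several theoretical ions. The default score is
the matched-ion count (a shared-peak count); an intensity mode instead sums,
per matched ion, the largest matching peak's intensity. The precursor window
defaults to t = 3.0 Da. Both score modes satisfy two monotonicity properties
asserted in the suite: adding experimental peaks never lowers the score, and
enlarging the fragment tolerance never lowers the matched-ion count.

The significance of a spectrum's top score is its z-value against the
candidate-score population: z = (max − mean) / population standard deviation,
defined as 0 for a single candidate or a zero-variance group. This is an
explicit, monotone, unitless choice for ranking confidence — simple enough to
verify by arithmetic, and deliberately not an E-value or FDR estimate (no
decoy machinery is included).

Ties for the best candidate are broken once, in one place: higher score, then
higher matched-ion count, then lexicographically smaller sequence. Every
execution path (serial, multicore merge, distributed merge) reuses this rule,
which is what makes serial/parallel identity provable rather than
approximate. A consequence worth knowing: isobaric peptides with identical
theoretical spectra (e.g. I/L substitutions) resolve deterministically to the
lexicographically smaller sequence.

## Parallel execution

**Multicore** (`mc_search`) partitions, for each spectrum, the candidate list
into `worker_count` contiguous slices scored concurrently — the similarity-
scoring step dominates the per-spectrum cost, so that is what is sliced — and
merges slice results in slice order before applying the shared tie-break. A
spectrum-level granularity is also provided for throughput. The partition
always has `worker_count` slices so the merge is identical everywhere; the
actual thread concurrency is capped at the machine's logical processor count
with a warning. Results are therefore identical to serial for every worker
count on any machine.

**Distributed** (`split_spectra` + `run_head_node`) splits the input into
contiguous, order-preserving chunks whose sizes differ by at most one
(ceil-first allocation) and dispatches each to an isolated worker subprocess
that loads its own copy of the index from a FASTA or an index TSV dump —
no shared mutable state, message passing via serialized chunk/report files.
The head node tracks each chunk through created → queued → running →
(finished | failed), retries a failed chunk once (the failure policy is a
package choice), and aborts the run with a partial-report dump when a chunk
exhausts its retries. Worker results are serialized with shortest-exact
(repr) floats so the merged report is byte-identical to a serial run. A
`fail_injection` hook lets tests force a chunk to fail a given number of
attempts, exercising the retry/abort state machine deterministically.

**Timing model.** Per candidate peptide, the scoring cost over n ion types is
t_k = Σᵢ (t_1i + t_2i) (searching + scoring per ion type) and a candidate
group of N peptides costs t_total = Σ_k t_k. Per distributed worker j,
t_j = t_1j + t_2j + t_3j (searching, scoring, communication) and the
predicted run total is t'_total = t_o + max_j t_j where t_o is the task
initialisation time. Workers record these components with a monotonic clock
and the run summary reports the prediction; wall-clock values are recorded,
never asserted against thresholds, because they are hardware measurements,
not contracts.

## File formats

Spectra use the Mascot generic format (MGF): BEGIN IONS / END IONS blocks
with TITLE, PEPMASS (first token = precursor m/z, the community convention),
CHARGE such as `2+`, and `mz intensity` peak lines. Blocks missing PEPMASS or
CHARGE are skipped with a warning (charge is never guessed); unsorted peak
lists are re-sorted with a warning. The precursor neutral mass is
Mm = z·(m/z) − z·proton. The writer emits floats in shortest exact (repr)
form: this makes write → read an identity and equal inputs byte-equal files,
which the round-trip and parallel-identity tests rely on; fixed 5-decimal
formatting is used instead in the human-facing TSV report. The peptide index
can be dumped to, and losslessly reloaded from, a TSV
(bucket_key, mass, sequence, missed_cleavages, parents).

## Synthetic data

The generator produces random proteins over the 20 canonical residues with
K/R sampled at 2.5× weight so tryptic sites occur at realistic density, and
one spectrum per sampled database peptide: a precursor charge drawn from
1+/2+/3+ with probabilities 0.2/0.5/0.3, an exact precursor m/z, every peak
of all 8 ion series (optionally perturbed by Gaussian m/z error), plus a
configurable number of uniform-random noise peaks, all at unit intensity.
Generation is a pure function of (parameters, seed).

What this emulates — and what it does not: the fixtures give ideal
fragmentation with complete ion series, no isotope envelopes, no chimeric
spectra and no realistic intensity structure. Passing the self-identification
test (100% top-1 recovery on noiseless spectra) therefore demonstrates the
correctness of retrieval, scoring and ranking machinery, not identification
sensitivity on real instrument data.

## Problem sizes

The shared test benchmark digests 165 random proteins of length 250–350 into
≈20,000 indexed peptides and searches 200 noiseless spectra; end-to-end and
CLI tests use a smaller 20-protein fixture. The acceptance script rebuilds a
120-protein / 100-spectrum benchmark from its `--seed` and recomputes every
reported quantity from scratch.

## Known limitations

- Tryptic, fully-specific digestion only; no variable modifications; no
  decoy/FDR machinery.
- 1+ fragment ions only; one declared charge per MGF block.
- Dalton tolerances only (no ppm).
- The distributed engine models cluster nodes as local subprocesses with
  file-based message passing; there is no network transport, scheduler
  integration, or checkpointing beyond the single retry.
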