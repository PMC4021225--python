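# psmatch

Peptide-spectrum matching (PSM) for tandem mass spectrometry, built around a
2-dimensional integer-mass peptide index and parallel execution regimes whose
results are provably identical to serial search.

Interpreting MS/MS spectra means searching each experimental spectrum against
a protein sequence database: digest the proteins in silico, retrieve the
candidate peptides whose neutral mass lies within a tolerance window of the
precursor mass, score every candidate's theoretical fragment spectrum against
the observed peaks, and report the best match with a measure of how much it
stands out. In real-time workflows — where identifications must keep up with
spectrum acquisition — the scoring step dominates the cost, so `psmatch` also
provides a multicore engine (concurrent workers slicing each spectrum's
candidate list) and a distributed engine (a head node dispatching spectrum
chunks to isolated worker processes and merging their reports). Parallelism
is never allowed to change the answer: every regime is tested byte-identical
to serial execution. The audience is proteomics tool builders and anyone who
needs a transparent, fully testable reference search engine.

## The method

* **2-D index.** Peptides are bucketed by ⌊mass⌋; each bucket is sorted by
  mass. Retrieval of all candidates with mass in the closed window
  [Mm − t, Mm + t] visits only buckets ⌊Mm − t⌋ … ⌊Mm + t⌋ and binary-searches
  the two edge buckets, instead of binary searching one large array.
* **8 ion types.** For each candidate of length L, the theoretical spectrum
  holds 8 × (L − 1) singly-charged ions: b, b−H2O, b−NH3, b−CO (a), y,
  y−H2O, y−NH3, y−NH (z), with exact monoisotopic losses or nominal integer
  offsets (18/17/28 and 18/17/15).
* **Score and significance.** A theoretical ion is matched when an
  experimental peak lies within ±0.5 Da (configurable); the score is the
  matched-ion count (or a matched-intensity sum). The top score's
  significance is its z-value against the candidate group:
  z = (max − mean) / population sd.
* **Timing model.** Per worker j, t_j = t_1j + t_2j + t_3j (searching,
  scoring, communication); a distributed run's predicted total is
  t'_total = t_o + max_j t_j, with t_o the task initialisation time.

See `docs/methods.md` for the full model, defaults and limitations.

## Worked example

Generate a small synthetic dataset with known ground truth, then search it:

```sh
$ psmatch simulate --out-dir demo --proteins 10 --n-spectra 5 --seed 42
wrote 10 proteins, 5 spectra (0 noise peaks, mass error sd 0.0) to demo

$ psmatch search --fasta demo/proteome.fasta --spectra demo/spectra.mgf --out demo/report.tsv
INFO psmatch: read 10 proteins -> 1083 indexed peptides; 5 spectra to search
INFO psmatch: searched 5 spectra, 5 matched; report at demo/report.tsv

$ cat demo/report.tsv
spectrum_id	peptide	neutral_mass	candidate_count	best_score	significance	parents
synthetic_00000	AYDAGCK	726.30068	4	48.00000	1.72698	SYN00002
synthetic_00001	KFGLWRFTK	1181.67095	5	64.00000	1.99213	SYN00006
synthetic_00002	LYLYKSCNSWSAKCDR	1935.89714	5	120.00000	1.99566	SYN00002
synthetic_00003	NLCKTAKWCR	1221.61107	5	72.00000	1.99685	SYN00006
synthetic_00004	RDWGANK	845.41440	4	48.00000	1.68134	SYN00000
```

Each row is one spectrum: the identified peptide, its neutral monoisotopic
mass, how many candidates N fell in the ±3 Da precursor window, the best
similarity score (here the matched-ion count — e.g. AYDAGCK has length 7, so
a perfect match scores 8 × 6 = 48), the z-value of that score within its
candidate group, and the parent protein accession. All five spectra recover
their ground-truth peptide (compare `demo/ground_truth.tsv`) with the
complete ion set matched, as expected for noiseless synthetic spectra.

Parallel modes reproduce the same report byte for byte:

```sh
psmatch search ... --mode mc --workers 4
psmatch search ... --mode dc --nodes 2 --chunks 3
```

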