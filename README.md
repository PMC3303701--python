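# tmcoffee

Consistency-based multiple sequence alignment of alpha-helical membrane
proteins with homology extension.

Each input sequence is extended into a profile of its close database
homologs (BLAST-style search, hits kept at 50–90% identity and >70%
coverage), every profile pair is aligned with a bi-phasic-gap pair-HMM, and
residue pairs whose posterior alignment probability exceeds 0.99 become
weighted constraints in a T-Coffee-style library. Triplet extension relays
support through third sequences, and a progressive aligner (UPGMA guide
tree, gap-penalty-free DP over extended weights) produces the final MSA.
Scoring utilities compute core-region SP/TC against annotated references,
and a simulator generates membrane-protein families with column-exact
ground truth so the whole pipeline runs offline.

## Layout

| module | role |
| --- | --- |
| `tmcoffee.formats` | FASTA/Clustal/core-XML/tabular-hit/library I/O, core data types |
| `tmcoffee.extension` | search backends (built-in Smith–Waterman, blast+, precomputed), hit filtering, profile building |
| `tmcoffee.pairhmm` | profile-adapted 5-state pair-HMM, forward–backward posteriors, constraint extraction |
| `tmcoffee.consistency` | constraint library, triplet extension (lazy and eager) |
| `tmcoffee.align` | guide tree, progressive alignment, refinement, end-to-end pipeline |
| `tmcoffee.evaluate` | core-region SP/TC, score reports, exact paired signed-rank test |
| `tmcoffee.simulate` | synthetic families, topology model, mini homolog database |
| `tmcoffee.cli` | `tmcoffee` command-line entry point |

## CLI

```sh
# simulate two families plus a shared mini database
tmcoffee simulate --families 2 --members 5 --seed 3 -o sim/

# keyword-subset a database
tmcoffee makedb --keyword transmembrane sim/minidb.fasta tm.fasta

# align with homology extension against a FASTA database
tmcoffee align --db sim/minidb.fasta --out out.fasta sim/fam0/seqs.fasta

# baseline without extension
tmcoffee align --no-extension --out plain.fasta sim/fam0/seqs.fasta

# score against the annotated reference
tmcoffee score --test out.fasta --ref sim/fam0/truth.fasta \
    --core sim/fam0/core.xml --report scores.tsv

# paired significance test between two score tables
tmcoffee compare scoresA.tsv scoresB.tsv

# e-value threshold sweep
tmcoffee sweep --db sim/minidb.fasta --ref sim/fam0/truth.fasta \
    --core sim/fam0/core.xml --thresholds 1e-10,1e-2,NONE sim/fam0/seqs.fasta
```

The `--db` handle may be a FASTA file (built-in local aligner), a directory
of `<query id>.tsv` precomputed tabular hits, or — programmatically — a
`BlastBackend` wrapping an external `blastp`. E-values from the built-in
backend are raw-score surrogates, not BLAST statistics.

Exit codes: 0 success, 1 usage error, 2 data/configuration error.

## File formats

- **Tabular hits**: TSV with columns `qseqid sseqid pident length qstart
  qend sstart send evalue qlen qseq sseq` (1-based inclusive coordinates;
  `qseq`/`sseq` are the gapped aligned segments, `qlen` the full query
  length used for coverage).
- **Core annotation XML**: `<family columns="N"><sequence id="...">
  <block start="..." end="..."/></sequence></family>` with 1-based
  inclusive alignment-column blocks.
- **Library**: T-Coffee-style text — header of `id length` lines, then
  per-pair blocks `#i j` of 1-based `posA posB weight` lines.
- **HMM parameters**: JSON (see `src/tmcoffee/data/probcons_params.json`);
  override with `--hmm-params FILE`.

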