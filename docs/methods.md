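# Methods

## Problem and model

`contigbin` operates downstream of metagenome assembly and database
search. Its inputs are assembled contigs (FASTA), tabular
similarity-search hits (the 12-column BLAST outfmt-6 dialect, optionally
extended with `nident` and `staxid`), an NCBI-style taxonomy
(`nodes.dmp`/`names.dmp`), and an accession→taxid map. Its outputs are
per-community taxonomic profiles, marker and gene catalogs, assembly
statistics, and two-community comparisons.

### Hit selection

Hits are retained when their E-value is **strictly** below the cutoff:
1e-10 for global (nt/nr-style) databases, 1e-5 for rRNA databases. The
database class is declared per input file because the tabular format
does not carry it. Within each contig's group, hits are ordered by
descending bitscore, breaking ties by ascending E-value and then by
subject accession; the last tie-break is a pure determinism convention.
Accessions resolve against the taxid map exactly first, then with the
trailing `.N` version stripped, because reference dumps differ in
versioning. Unresolvable hits are flagged and counted, never silently
dropped; assignment skips them, falling through to the next bitscore
stratum if an entire stratum is unresolved.

### Assignment

* **UBH** — the contig takes the taxon of its unique top-bitscore
  resolved hit; exact bitscore ties fall back to the LCA of the tied
  taxa (a tie between equally good references carries no signal below
  their common ancestor).
* **LCA** — candidates are all resolved hits with bitscore ≥
  (1 − `lca_top_percent`/100) × best resolved bitscore; the contig takes
  their LCA. The default window of 10% follows common practice for
  LCA-based contig classifiers. With a 0% window and a unique best hit,
  LCA reduces to UBH.

### Abundance weighting

A contig's weight is its identity count: `nident` when the hit table
carries it, otherwise `round(pident × length / 100)` (half-up). When an
assignment rests on several hits (ties or an LCA window), the weight is
the **maximum** identity count among the contributing hits — one weight
per contig, never a sum across hits, so each contig is counted exactly
once. Summing across a contig's hits would let deeply redundant
reference sets inflate a taxon, which is why the per-contig
representative weight was chosen; the alternative reading (summing all
retained hits) is deliberately not offered as a default.

At a reporting rank (family by default), each assigned contig
contributes its weight to its ancestor at that rank. Contigs assigned
only above the rank accumulate in `unassigned_weight`, which is
reported alongside but excluded from the proportion denominator — the
proportions describe the rank-resolved fraction of the community. The
"major taxa" list is the shortest descending-proportion prefix whose
sum reaches `cumulative_frac` (default 0.90); ties in proportion break
by ascending taxid for determinism.

### Assembly statistics

Contigs shorter than `min_contig_len` (default 100 nt, the assembler
floor) are excluded **inclusively** (≥ 100 kept): an assembler with a
stated minimum contig size of 100 emits contigs of exactly 100 nt, so
the inclusive reading is the only self-consistent one. N50 is the
largest length L such that contigs of length ≥ L contain at least half
the retained bases.

### Markers and genes

rRNA marker contigs take their taxonomy from the best hit after
skipping subjects whose scientific name contains an exclusion term
(defaults: "uncultured", "unidentified", "environmental sample",
"metagenome" — the canonical uninformative-name vocabulary; the list is
configurable because no standard fixes it). Chimera flags are consumed
from a two-column file produced by external tools (Uchime-style
output); chimera detection itself is out of scope.

Functional genes resolve through `gene2accession`/`gene_info`-dialect
maps (column indices configurable) and an editable catalog TSV shipping
the perchlorate-pathway targets (*pcrA–D*, *cld*) and nitrate
reductases (*narG*, *narH*, *napA*). The shipped catalog's member
accessions are synthetic placeholders (`SYN*`) so the bundled fixtures
resolve offline; production use supplies real accessions. Gene–taxon
tables count annotated contigs per class (rows) and annotation source
(columns; independent tallies per source, since per-source totals need
not deduplicate), with an `Undefined` row absorbing contigs whose
assignment does not resolve at the grouping rank and a totals row that
always equals the column sums.

### Alignment identity

`global_percent_identity` is a Needleman–Wunsch global alignment with
linear gap penalties (nucleotide defaults +1/−1/−2; protein mode uses a
named substitution matrix, BLOSUM62 with gap −8 by default). Percent
identity is identical columns over alignment columns of the optimal
alignment selected by a fixed traceback preference (diagonal, then up,
then left), which makes the figure deterministic even when several
optimal alignments exist with different identity counts. No claim is
made that these parameters reproduce identity figures computed by other
programs with unstated parameters.

## Synthetic communities

The generator emulates a two-community enrichment contrast: community A
dominated by one family (40%), community B with that family depleted to
5% and its mass redistributed — the signature of a nitrate-amended
culture losing its dominant family. Defaults (one decision, stated
here, not revisited):

| parameter | default | why |
|---|---|---|
| families × genera | 8 × 3, 1 species/genus | enough taxa for family-level structure at desk scale |
| contigs per community | 5,000 | resolves family proportions to a few % |
| length model | log-normal, median 230 nt, σ 0.55, truncated [100, 3500] | matches the scale of short-read metagenome assemblies (mean ≈ 230 nt, N50 ≈ 260 nt, floor 100 nt) |
| on-target identity | N(97, 1.5)% | near-reference enrichment genomes |
| identity decay | 3 points per rank step | off-target hits distinguishably worse |
| off-target rate | 0.3 | a third of contigs see a relative |
| bitscore | 30 + 0.18·n_ident + N(0, 2) | affine in identities; keeps the weakest on-target hit (100 nt) under E = 1e-10 and the longest contigs clear of float underflow |
| E-value | L_q · 2^(−bitscore) | any strictly monotone map suffices for threshold logic; this form is a convenience, not biophysics |

Off-target hits always receive a strictly lower bitscore than the
on-target hit, so UBH recovers the true source leaf by construction and
profile recovery error is dominated by multinomial sampling of the
community — which is what the convergence checks measure (L1 error
versus intended proportions shrinking over 200 → 1,000 → 5,000
contigs). All draws come from one seeded generator consumed contig by
contig, making runs at different sizes prefix-coupled under a common
seed. What the generator does **not** emulate: sequencing error,
chimeras, coverage-dependent assembly artifacts, conserved-region
cross-mapping, database incompleteness. Passing the synthetic
benchmarks therefore validates the bookkeeping and the statistics, not
robustness to real-data pathologies.

## Numerical and degenerate-input choices

* Proportions sum to 1 within 1e-9 by construction (integer weights /
  integer total); cumulative selection uses a 1e-12 slack against float
  accumulation.
* An empty profile yields an empty selection; a pipeline run whose
  threshold removes every hit still writes complete (empty) outputs and
  a consistent manifest.
* `contig_stats` on an empty retained set is an error (there is no N50
  of nothing); unknown taxids in taxonomy queries are errors rather
  than silent roots; merged/deleted-taxid history files are not
  consumed — the contract is strict.
* Rank strings compare exactly after lowercase/trim; no rank-synonym
  table.

## Limitations

* Weights use one representative hit per contig; coverage (read depth)
  is not modeled, so profiles are assembly-weighted, not
  read-weighted.
* The LCA window refers to the best *resolved* bitscore; if the single
  best hit is unresolvable the window is anchored one stratum down.
* Protein-vs-nucleotide frame bookkeeping is the search tool's job;
  hit tables are consumed as given regardless of the search program.
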