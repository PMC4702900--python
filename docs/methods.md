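# Methods

## The identification cascade

`lncseeker` classifies assembled transcript models (Cufflinks-style GTF or
BED12) into lncRNAs, TUCPs (transcripts of uncertain coding potential) and
coding-like transcripts by four sequential filters:

1. **Structure.** Only multi-exonic transcripts whose spliced length
   strictly exceeds `min_length_nt` (default 200 nt) continue. The exon
   minimum is 2.
2. **Known annotation, strand-specific.** A transcript is removed when any
   of its exons overlaps, or lies within `flank_nt` (default 50 nt,
   *inclusive*: a gap of exactly 50 nt removes) of, a same-strand coding or
   pseudogene exon. It is also removed when its exonic overlap covers at
   least `precursor_cover_frac` (default 80 %) of a same-strand small-RNA
   gene (miRNA precursor, miRNA, tRNA, rRNA, snRNA, snoRNA); coverage is
   measured over the small-RNA gene, and intronic span does not count.
   Opposite-strand features never remove, so antisense lncRNAs of coding
   genes are deliberately retained. Distances are genomic and
   strand-agnostic; only eligibility is strand-specific.
3. **Coding potential.** The longest ATG-to-stop ORF is found over the
   three forward frames (assemblies are stranded; no reverse-strand ORFs).
   An ORF may run off the 3' end without a stop; `nt_length` includes the
   stop codon so a stop-terminated full-length ORF reaches coverage 1.0,
   while `aa_length` excludes it. Ties on amino-acid length break by
   smaller 5' offset, then smaller frame. The decision table, with every
   threshold strict (`<`) exactly as stated and the TUCP coverage interval
   closed at both ends:
   - **coding-like** iff CDS score >= 800 or ORF coverage > 0.90;
   - otherwise **lncRNA** iff ORF < 100 aa and coverage < 0.30;
   - otherwise **TUCP**. This routes the corner case (ORF >= 100 aa,
     coverage < 30 %, score < 800), which the published rules leave
     unassigned, to TUCP — the conservative choice, keeping a long-ORF
     transcript out of the confident lncRNA set without discarding it.
4. **Protein similarity and domains.** Transcripts with any UniRef90
   BLASTX hit at E < 1e-30 are removed (strict `<`: a hit at exactly
   1e-30 is kept). The rest are translated in all three forward frames and
   removed when a single Pfam hit shows *both* full-sequence E < 1e-5 and
   best-domain E < 1e-5; the conjunction is per hit, never across hits,
   and PfamA/PfamB hits are treated identically. The library operates on
   parsed BLAST outfmt-6 and HMMER3 domtblout tables so all tests run
   without external tools or databases; command templates for running the
   tools can be stored in `PipelineConfig`.

### The CDS score surrogate

txCdsPredict is an opaque binary whose algorithm is not published in a
reimplementable form. `score_cds` is therefore a documented surrogate on
the same 0–1000 scale: `min(1000, 6·aa_length + 50·[has stop] +
50·[A/G at −3 of the start])`, and 0 for no ORF. It is deterministic and
monotone non-decreasing in ORF length, and the calibration keeps the 800
cutoff meaningful: an ORF under 100 aa cannot exceed 700, while a
stop-terminated ORF of ~125 aa or more with start context crosses 800.
Externally computed scores (a two-column TSV) override the surrogate per
transcript via `load_cds_scores` / `--cds-scores`.

## Locus model and naming

Surviving lncRNA transcripts are clustered into gene loci as connected
components of the same-strand exonic-overlap graph (>= 1 nt of exon
overlap, transitively closed) — the standard Cufflinks-style locus notion,
consistent with the strand-specific filter philosophy. Gene numbers are
assigned genome-wide, 1-based, by leftmost genomic position; transcript
numbers are positional within a gene by (start, end, input id), not
expression-ranked, for determinism. Names render as
`<species>-lncRNA<gene>-<transcript>` (e.g. `hsa-lncRNA10932-8`, the 8th
transcript of gene lncRNA10932 in human) and parse back exactly.

## Conservation

Each lncRNA is searched against the lncRNA sets of other species with
BLASTN (`-task blastn -word_size 6 -evalue 1e-5 -strand plus`; the search
is an external adapter, the library consumes its tabular output). Per
query and target species the hit with the lowest E-value is the ortholog
call; ties (not addressed by the one-way best-hit convention) break by
higher bit score, then lexicographic subject id, for determinism. No
minimum alignment length is imposed beyond the E-value cutoff.
`lineage_label` reduces per-species presence to the smallest named clade
containing the query species and every ortholog-bearing species, returning
the clade name, or `species-specific` when there are no orthologs.

## Function prediction (guilt by association)

Expression is FPKM (`count · 10^9 / (length · total fragments)`). Pearson
r is computed between each lncRNA and each protein-coding gene; the
two-sided p-value comes from `t = r·sqrt((n−2)/(1−r²))` on n−2 degrees of
freedom (the t reference is our choice; no method is canonical here).
Benjamini–Hochberg is applied over the *full family* of lnc × coding
pairs, and edges are kept at q < 0.05 and |r| >= 0.7 — conventional
defaults, both configurable, with a `--positive-only` switch since signed
vs positive-only co-expression is a genuinely open choice. Constant rows
are skipped with a warning rather than producing undefined correlations.

The partner set feeds a hypergeometric upper-tail test per GO term,
`P(X >= k)` with population N = the GO-annotated genes present in the
expression matrix (conditioning on testable genes, not the genome), K the
annotated genes with the term, n the partner-set size and k the partners
with the term. Both Bonferroni (`min(1, p·m)`) and BH corrections are
reported over the per-term family; rows sort by p with term-id
tie-breaks.

Small-RNA expression uses only the containment counting rule: a read
counts for a gene iff its interval is fully inside the annotated gene
region on the same strand; a read inside several genes counts once per
containing gene. Differential-expression normalisation is out of scope.

## The synthetic bundle

`fixtures.generate_fixture` builds, from one master seed (one independent
RNG stream per component, so adding a component never perturbs the
others): a 200 kb single-chromosome genome; planted transcripts — 8
lncRNAs (~520 nt, 40-aa ORF), 4 TUCPs (600 nt, 90-aa ORF, coverage
~0.46), 8 coding-like (900 nt, 280-aa ORF, coverage ~0.94), 3 antisense
lncRNAs over opposite-strand coding exons, and one deliberate failure per
cascade stage; decoy annotation features in separate slots; BLASTX/Pfam
hit tables; per-species BLASTN tables planting primate-conserved,
vertebrate-conserved and species-specific patterns; a 12-sample FPKM
matrix in which 8 partner genes track the target lncRNA's profile
(2 % relative noise) over 30 independent background genes; and a GO table
where the planted term annotates 7 of 8 partners against a ~10 %
background frequency.

ORFs are planted by explicit codon construction, not rejection sampling:
all background transcript sequence is drawn from the {C,G,T} alphabet, in
which neither ATG nor any stop codon (all contain A) can occur in any
frame, so the single planted ATG…stop span is provably the longest ORF;
the base after a planted stop is pinned to C so the stop's A cannot seed
a spurious start across the junction. Feature slots are separated by
300–500 nt, beyond the 50-nt flank, so no planted transcript can
accidentally trip the annotation filter.

What the bundle does **not** emulate: realistic exon/intron length
distributions, sequencing noise or read-level data, assembly artifacts,
overlapping gene dense regions, biased nucleotide composition, or the
scale of a real transcriptome. Passing the planted-recovery tests shows
the cascade implements its decision rules exactly; it does not measure
performance on real assemblies, which depends on assembly quality and
annotation completeness.

## Numerical choices and edge cases

- Coordinates are 0-based half-open internally; GTF converts at the
  boundary; exons are stored in genomic order with orientation applied
  only at sequence extraction.
- Pearson/hypergeometric come from scipy, BH/Bonferroni from statsmodels;
  test oracles are independent hand enumerations.
- Undefined ratios (classifier metrics with an empty denominator,
  correlations of constant vectors) are explicit flags/None, never NaN.
- Duplicate transcript ids in BED12 are an error, never merged; GTF exon
  lines sharing an id are grouped, and conflicts surface as chrom/strand
  validation errors.
- Problem sizes in the test suite (for example 1000-feature oracle scenes,
  10 000 random ORF sequences, draw enumeration for populations up to 12)
  are chosen so that brute-force oracles stay exact while the whole suite
  runs in seconds.

## Known limitations

- The surrogate CDS score is calibrated to the 800 cutoff but is not
  txCdsPredict; on real data, supply genuine scores for faithful results.
- One-way best hit is not orthology: no reciprocality or synteny.
- The function predictor is association, not mechanism; enrichment
  inherits every bias of the supplied GO annotation.
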