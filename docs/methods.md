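# Methods

`retrointron` analyzes intron gain in retrogenes: gene copies created by
reverse transcription of a processed mRNA and genomic reinsertion, which
are born intronless and occasionally re-acquire introns. This note
documents the models, parameters and numerical choices behind each stage,
what the synthetic benchmark does and does not show, and the known
limitations.

## Retrocopy scanning

Candidates are protein/CDS-to-genome alignments, either ingested from a
tabular (tBLASTn-like) file or produced by the built-in seeded aligner
(exact 14-mer seeds on both strands, positional clustering with a 400 bp
split gap, affine local polish with match +1, mismatch −2, gap open −5,
extend −1). The filter cascade retains a candidate iff, in order:

1. e-value ≤ 1e-10 (only when an e-value column is supplied; the package
   never computes e-values itself);
2. identity ≥ 40 %;
3. query coverage ≥ 70 %;
4. RNA-duplication evidence: more than three parental introns absent, or
   1–3 introns absent together with Ks < 2 to the parent or a downstream
   poly(A) tract (≥ 12 A within 30 bp of the aligned 3′ end, transcript
   sense; truncated windows are evaluated on the bases available);
5. repeat overlap of the span < 50 %;
6. no flanking similarity to the parental flanks (≥ 70 % identity over
   ≥ 50 % of a 2 kb flank — a DNA-duplication signature);
7. no candidate sub-region aligning to a parental intron (≥ 80 % identity
   over ≥ 50 bp — the second DNA-duplication signature).

The first failing step is recorded as the discard reason, which makes the
cascade auditable and keeps threshold relaxation monotone (relaxing any
single threshold can only grow the retained set).

An intron is "absent" when the flanking exons align contiguously in the
candidate. Because affine gap placement at an exon junction is ambiguous
by a few bases, the test probes a ±5 bp window across the junction and
calls the intron absent when the mapped window spans fewer than 10 extra
target bases. The tolerance is configurable; 10 bp absorbs alignment slop
without swallowing real introns (the shortest plausible spliceable intron
is ~60–70 bp).

## Gained-intron detection and transcript support

Annotated introns of transcripts overlapping a retained span are reported
per transcript (multi-transcript loci are not collapsed), labelled ORF or
UTR from the CDS annotation, with a flag recording whether the intron lies
inside the aligned span (a short terminal exon can leave an inserted
intron just outside it). A transcript alignment (BED12) supports an
intron iff one of its block junctions matches both intron boundaries
exactly — no slop, since junction evidence is only meaningful at
single-base resolution — and the transcript maps uniquely: its best locus
must beat the runner-up by ≥ 2 identity points (BED scores are read as
10× percent identity).

## Mechanism classification

The retrogene's annotated transcript span (poly(A) tail excluded) is
aligned to the parent mRNA with a true global affine alignment (same
scores as above), orientation chosen by the higher-scoring strand. End
gaps are penalized deliberately: both sequences are trimmed to
homologous spans, and a free-end-gap alignment would rather drop a short
terminal exon than pay for the internal gap an inserted intron creates,
hiding exactly the signal being classified.

Mechanisms are resolved in precedence order:

1. **reverse_orientation** — the best alignment orientation is opposite
   to the annotated transcription strand;
2. **insertion** — ≥ 80 % of the intron falls in a parent-side gap (no
   parental counterpart);
3. **intronization** — ≥ 80 % of the intron aligns to parental exonic
   sequence.

Anything else is reported `unclassified` rather than forced into a class.
The 80 % overlap thresholds absorb local alignment wobble at gap edges
while keeping the classes mutually exclusive in practice.

Intronizations are sub-classified by comparing the donor/acceptor
dinucleotides with their parental counterparts through the alignment:
`substitution` if at least one base differs, `cryptic` if both are
identical (the site pre-existed silently in the parent), `unresolvable`
if a boundary falls in a gap. For opposite-orientation loci the parental
counterparts are reported as the reverse complement of the parental sense
sequence. Boundary pairs are labelled canonical (GT-AG) or noncanonical
with the observed pair.

### Frameshift accounting

For an ORF intronization, the net coding-length change is

    Δ = intron_length − Σ(retro-side insertions) + Σ(retro-side deletions)

over indels within 100 bp of the intron in the alignment; the event is
non-frameshift iff Δ ≡ 0 (mod 3). The 100 bp window generalizes the
documented compensating-indel cases (indels 1, 2 and 100 bp from their
introns) and is configurable. UTR introns are classed `utr` with no Δ.
Accounting is translation-invariant: only offsets from the intron enter.

## Splice-signal scoring

Four signals are scored per intron, in the retrogene context ("after"
retroposition) and over the corresponding parental region ("before"):

- **5′SS**: log₂-odds of a 9-position weight matrix (−3 exonic … +6
  intronic) against a uniform background;
- **3′SS**: 24-position matrix (−20 intronic … +3 exonic);
- **BS**: maximum of a 7-mer branch-site matrix over −45…−15 from the
  acceptor (window truncated for introns < 60 bp);
- **PPT**: weighted pyrimidine content (T = 1.0, C = 0.75) plus
  longest-run fraction over −5…−45.

Raw scores are converted to percentiles against a reference distribution
of constitutive introns via the empirical CDF (fraction strictly below,
ties counted half), and before/after comparison operates on the sum of
the four percentiles (difference < 1e-9 is "unchanged"). Percentiles are
monotone in raw scores and invariant under any strictly monotone
transform applied to both query and reference.

The shipped matrices are editable TSVs with consensus-shaped frequencies
(MAG|GTRAGT donor, pyrimidine-rich NCAG|G acceptor, nyURAYn branch); they
approximate the published splice-signal models behind percentile-scoring
services, whose exact calibration sets are not redistributable. The
packaged reference distribution is built from the synthetic fixture's
constitutive introns; a user-supplied reference table is accepted for
real data, and percentile values from an external scorer can be compared
directly at the sum level.

## Ka/Ks (NG86)

Synonymous/nonsynonymous site counts per codon enumerate the nine
single-base mutations under the standard genetic code, excluding
mutations to stop codons from numerator and denominator; differences per
codon pair average the k! substitution orderings, excluding pathways
through stops (if every pathway hits a stop — possible for a handful of
2–3-step pairs — the average is taken over all pathways so the pair still
contributes). Proportions are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4 (saturation). Gapped,
ambiguous or stop-containing codon columns are dropped pairwise.

Significance of Ka ≠ Ks uses a normal approximation on the difference of
corrected rates with binomial variances propagated through the
correction (delta method). This is a deliberate simplification: a
likelihood-ratio test in a full codon-model framework is out of scope,
and the normal approximation is the standard companion to NG86 counting.
Intronic-vs-exonic contrasts across genes use the two-sided Wilcoxon
rank-sum test (exact null for tie-free combined n ≤ 20).

## Gene age

A gene's origin is the MRCA of the focal species and every species with
an ortholog present. Presence in a more distal species can only move the
origin rootward (monotonicity). Genes violating Dollo parsimony are still
dated at the MRCA but flagged `patchy`. `primate_specific` means all
present species lie inside the configured primate clade. Branches are
reported as labels (tip sets and rank along the focal root path), not
absolute ages; attaching times would require a divergence-time table
the package does not bundle. "Out-of-X" is parent on chromosome X with
the retrocopy elsewhere; the movement notation `a < -b` is parsed as
retro-chromosome ← parent-chromosome.

## Statistics and report

The two-sample proportion test defaults to chi-square with continuity
correction; Fisher's exact is always co-reported and flagged preferred
when any expected cell is below 5 (the flavor behind published
"proportion test" p-values is rarely stated, so both are shown and
neither is asserted against a printed figure). Report fractions
(intronization share, canonical-boundary count, ORF split, non-frameshift
share) recompute exactly from the emitted count columns.

## Synthetic data

The generator emulates the regime the pipeline targets, with defaults
fixed as the study conditions: 20 multi-exon parents (5–8 exons of
90–210 bp, introns 70–250 bp with GT-AG boundaries, embedded branch
motif and polypyrimidine tract, CDS free of internal stops), 30
retrocopies (spliced CDS + 30 bp poly(A), either strand), 12 injected
intron-gain events drawn uniformly over the four event modes
(substitution/cryptic intronization, insertion, reverse orientation), 3
DNA-duplication decoys (parents copied with introns), 3 % substitutions
and 5×10⁻⁴ indels/site (lengths 1–30 bp). Event injection precedes
divergence so boundary dinucleotides can be protected — otherwise cryptic
events would drift into apparent substitutions and truth labels would be
wrong; divergence indels are kept 120 bp away from injected introns so
frameshift truth stays constructible. Half of the substitution-mode
events carry a compensating indel making Δ ≡ 0 (mod 3), mirroring the
documented non-frameshift cases; inserted introns are multiples of 3 by
construction. Insertion sites are spaced 2.5–4 kb apart — wider than the
2 kb flank window of the flanking-similarity filter — because real
insertion sites are effectively isolated, and packing them closer makes
that filter (correctly, per its definition) fire on neighbors.

What passing the round trip shows: the scan, filters, intron detection
and mechanism classifier are mutually consistent and robust to 3 %
substitution divergence and sparse short indels. What it does not show:
performance on real genomes with repeat landscapes, segmental
duplications, paralogous gene families, fragmented or wrong annotations,
or divergence far beyond 5 % — the decoys model only the simplest
DNA-duplication confounder, and simulated introns are more stereotyped
than real ones.

Problem sizes were chosen so a full round trip (simulation + scan +
classification) completes in well under a minute and the entire suite in
a few minutes: genomes of ~250 kb, 1000-codon rate benchmarks, 61×61
codon enumeration.

## Known limitations

- The built-in seeded aligner is a convenience for self-contained runs
  and modest genome sizes; for genome-scale scans, feed an external
  alignment table.
- Splice-signal matrices are consensus approximations; absolute raw
  scores are not comparable across scorers (percentiles against a shared
  reference are).
- Ks-based evidence is computed from frame-consistent aligned codons of
  the discovery alignment; heavily gapped candidates may have undefined
  Ks and then rely on poly(A) evidence.
- The Ka = Ks test is approximate; at very low divergence the variance is
  dominated by few events and p-values should be read qualitatively.
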