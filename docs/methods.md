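# Methods

## Experimental design being modeled

Two yeast cultures — wild type and a knockout of the NatB catalytic
subunit — are grown on ¹⁴N and ¹⁵N media, mixed 1:1, digested with
trypsin or Lys-N, and quantified from MS1 isotope-pair intensities. A
biological replicate swaps the isotope labels, so any label-specific
bias flips sign between replicates while genuine knockout effects do
not. The pipeline consumes per-replicate peptide tables (sequence,
accession, modifications, identification score, two channel
intensities) and a protein FASTA; everything upstream of those tables
(search engine, FDR control, peak integration) is out of scope and
treated as given.

## Ratio model

Per replicate, each peptide's ratio is `r = log2(I_KO / I_WT)` with the
knockout channel chosen from the replicate's label orientation;
replicate ratios are averaged unweighted (weighting by intensity is a
possible refinement the original analysis does not specify). A row with
a missing or zero channel is an identification without a ratio — kept
for cataloguing termini, excluded from quantification. Missing is
deliberately distinct from zero throughout the I/O layer.

**Replicate agreement.** For peptides quantified in both replicates the
difference `d = r1 − r2` is, under the no-bias null, pure measurement
noise. The 95% band is `|d| ≤ 1.96·σ̂` with `σ̂ = 1.4826·MAD(d)` by
default: real ratio scatter is heavy-tailed (mis-assigned isotope
envelopes, chimeric spectra), and a plain SD would inflate the band
exactly when outliers are present. `method="sd"` restores the plain
estimator; at least 20 complete pairs are required, below which the
band is refused rather than fitted badly. Pairs outside the band are
flagged inconsistent and excluded from protein-level aggregation;
proteins left with only inconsistent peptides are dropped.

**Thresholds.** Identification scores: ≥ 30 for unmodified and
acetylated peptides, ≥ 25 for phosphopeptides (both boundaries
inclusive and configurable). Regulation: 3-fold, i.e. |mean r| ≥ log2 3
with inclusive boundaries, so a peptide exactly at the cut is called.

## N-terminal classification

Digestion follows the standard rules — trypsin cleaves C-terminal to
K/R (suppressed before proline; the suppression is configurable since
some search engines ignore it), Lys-N cleaves N-terminal to K — with at
most one missed cleavage by default. Semi-specific digestion adds every
proper prefix/suffix of a fully-specific peptide; it is what exposes
internal, non-annotated termini.

Events are classed by position: 1 (annotated initiator), 2
(post-Met-cleavage) or internal (≥ 3). Nat classes describe the
annotated terminus: NatB = retained Met + D/E/N penultimate at position
1, NatC-type = retained Met + I/L/W/F, NatA-type = S/A/T/V/G at
position 2. An internal event is classed `other` here even when its
local sequence matches a motif; substrate calling separately re-checks
the MD/ME/MN consensus at the event position, which is how internal
alternative-start substrates are admitted. (The enzyme literature also
lists Gln for NatB; the quantitative evidence this package models
supports D/E/N only, and that is the implemented consensus.)

Initiator-Met cleavage is modeled with the canonical
Met-aminopeptidase rule: cleavage permitted iff the penultimate residue
is one of the seven small residues A/C/G/P/S/T/V. Theoretical
observability of a terminus requires at least one fully-specific
N-terminal peptide (either protease, ≤ 1 missed cleavage, with and
without Met cleavage where permitted) of length 5–45 aa — the practical
MS detection window.

**Ambiguity.** `map_peptide` reports every placement of a peptide;
substrate calling relies on the recorded start (one placement per
event), matching how a curated substrate table lists a single start per
peptide.

## Substrate calling

`call = consensus AND mean ratio ≤ −log2(fold) AND replicate support`.
Consensus events missing the ratio cut are retained as a
`consensus-only` tier so a full descriptive report can be produced (the
published table includes such rows, e.g. ratios around −0.2); the
headline substrate count uses only the threshold tier. Whether
"verified in the replicate" means both replicates individually pass the
cut or only their mean is ambiguous; the implemented rule is: mean
passes, both replicates quantified (`require_both_replicates=True`,
relaxable). Report order: mean ratio ascending, ties by accession.

## Enrichment statistics

Foreground/background category percentages; effect size fg%/bg%;
significance from Pearson's chi-square (1 df, no Yates correction —
optional flag) on the 2×2 membership table; Bonferroni correction over
the tested categories (conservative, appropriate when one candidate
kinase is singled out; Benjamini–Hochberg available). Kinase analysis:
foreground = elevated sites, background = unchanged sites, disjoint by
construction. Localization analysis: background = **all** detected
proteins including the elevated ones — this matches the published
normalization and makes the degenerate elevated-set-equals-detected-set
case come out flat at ratio 1. Categories with an expected cell below 5
are flagged `low_count`; categories absent from the background are
omitted (an undefined ratio, not infinity). Items with no annotation
drop out of both margins.

## Conservation scoring

Per species: percent of all its ortholog sequences, pooled across
groups with in-paralogs counted individually, starting with MD/ME/MN
(a per-group-then-average alternative is available). Per protein:
percent of represented species with at least one motif-bearing member —
in-paralogs collapse, because the question is whether the species
conserves the motif at all. The top-k ranking uses the per-protein
score, ties broken lexicographically, and re-runs the species profile
on the subset. Ortholog sequences are used exactly as given (no
predicted Met cleavage before motif matching).

## Synthetic generator

The generator states a world mirroring the study's scale: 4000
proteins, 16% with NatB-consensus starts, 60 planted substrates whose
acetylated N-terminal peptide carries a −5 log2 effect while their
protein-level effect stays N(0, 0.3) (substrate abundance is largely
unaffected by loss of acetylation — the effect is on the acetylated
species); per-replicate ratio noise SD 0.5 (per-channel log2 noise
0.5/√2); 2000 phospho-sites of which 23% get +2.5 and 3.5% get −2.5,
with elevated sites over-sampled from configured kinases (default: one
kinase at multiplier 5) and localizations (bud 3×, cytoplasm 0.5×); 59
ortholog groups over 52 species, baseline per-sequence motif
probability 0.25, 5 groups planted fully conserved. Protein abundances
are log-normal (wide dynamic range) and a peptide is identified in a
replicate only if its stronger channel exceeds an intensity floor, so
singleton-replicate peptides and occasional total dropout occur.

Where no value was stated by the modeled study the defaults are one-off
realism choices: abundance log10 mean 5/SD 0.7 with peptide-level SD
0.4 and floor 10³ (≈ 1% dropout per peptide), identification scores
drawn above the filter thresholds (the tables emulate post-search
confident identifications; the score filter is exercised by unit tests
with explicit low-scoring rows), 1–10 detected tryptic peptides per
protein, ortholog presence probability 0.8 per species.

**What a green recovery test does and does not establish.** The
generator reproduces the statistical structure the analysis assumes —
label-swap antisymmetry, log-normal noise, planted effects, nuisance
dropout — but not real-data pathologies: no incomplete ¹⁵N
incorporation, no co-eluting envelope interference, no score-correlated
intensity bias, and far milder quantification dropout than real
acetyl-peptide enrichment (where a quarter of identified termini can
lack usable ratios). Recovery at ≥ 95% sensitivity/precision therefore
validates the calling logic and thresholds, not instrument-level
robustness. The few planted substrates missed at default settings are
proteins whose N-terminal peptide falls outside the 5–45 aa window or
below the abundance floor — the same observability limits the real
experiment has.

Determinism: every generator draws from its own child stream of the
config seed, so outputs are bit-identical for a fixed seed and
independent of call order.

## Numerical conventions

Protein coordinates are 1-based inclusive; position 1 is the annotated
initiator Met. Ratios are log2 throughout. Band and fold boundaries are
inclusive. Percentages are reported on 0–100. Chi-square on a table
with an empty margin returns (0, p = 1) flagged `low_count` rather than
NaN. Frequency matrices normalize per position over observed residues.

## Known limitations

- The quantitative tables are consumed as given: no FDR re-estimation,
  no isotope-envelope correction, no incorporation-rate modeling.
- Kinase predictions and localization annotations are inputs; their
  quality bounds the enrichment analysis.
- Protein-level aggregation uses unmodified peptides only and weights
  peptides equally.
- The chi-square p-values for very small categories are approximate;
  the `low_count` flag marks where an exact test would be preferable.
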