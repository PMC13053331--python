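# Methods

`cytoreport` generates and, above all, *evaluates* narrative interpretive
reports for combined quantitative lymphocyte profiling / B-cell subset
phenotyping (QLP/BSP) flow-cytometry panels. This note documents the models
and procedures it implements, the defaults that matter, and what the
synthetic test surface does and does not establish about real clinical data.

## Panel model and qualitative descriptors

A panel carries 34 reportable results: absolute counts (cells/mcL) and
relative percentages for six whole-blood populations (CD3, CD4, CD8, CD19,
CD20, NK) and eleven PBMC-based B-cell subsets (naive, transitional, total /
non-switched / switched / IgM-only memory, CD21+, CD21low, plasmablasts,
total IgM+, and a PBMC-side CD19+). Each numeric value x with reference
interval [L, U] maps to a descriptor (direction, degree):

- direction: decreased if x < L, increased if x > U, otherwise normal.
  Boundary values are normal — an abnormality is a value strictly outside
  the interval.
- degree: from the relative excursion d = (L − x)/L below or d = (x − U)/U
  above; mild for d < 0.25, moderate for 0.25 ≤ d < 0.5, significant for
  d ≥ 0.5. Institutions do not publish numeric definitions of these
  qualitative grades, so the cutpoints are package defaults, configurable
  per schema and per analyte. The relative (scale-free) form is used so the
  same cutpoints work for counts and percentages. A range with L = 0
  (plasmablasts) cannot be undershot by a non-negative value, so the
  decreased branch never divides by zero.

The bundled reference ranges are plausible adult values chosen once for the
synthetic test surface; they carry no clinical authority and are meant to be
replaced via `load_schema` wherever real institutional ranges exist.
Age-banded ranges are supported but the bundled schema is age-invariant.
Missing results must be explicitly flagged (`None`) and are excluded from
every downstream denominator.

## Synthetic cohorts

`generate_panel` draws, per analyte, an abnormality indicator, a side
(below/above), and a degree stratum, then samples the value uniformly inside
the excursion interval that maps back to that stratum — generator and
classifier are exact inverses by construction (a 1e-3 relative margin keeps
sampled excursions strictly inside their stratum so float round-trip cannot
cross a cutpoint). Significant excursions are capped at d = 2·t_significant
(and at d = 1 below, where the value floor is zero). Count/percent twins
co-deviate with probability equal to the pairing correlation, copying
direction and degree stratum.

The bundled `table1_profile` emulates a referral cohort: per-analyte
abnormality probability 0.22, a panel-level mixture (87 % of panels at full
probability, 13 % essentially normal at 3 % of it), below-fraction 0.6,
degree mix 0.55/0.30/0.15, pairing correlation 0.4. These reproduce, by a
back-of-envelope calculation, a cohort in which roughly 87 % of panels have
at least one abnormality and abnormal panels carry a median of about seven
abnormal findings. They are generator parameters, not measured quantities.

What the generator deliberately does *not* model: correlation between
different cell families (beyond twin pairing), age structure, longitudinal
repeat testing, disease labels, and physiological bounds (a significantly
increased percentage may exceed 100 %). Passing tests therefore demonstrate
the correctness of the evaluation machinery under controlled conditions,
not the performance of any generator on clinical data.

## Reference renderer and corruption oracle

`render_report` is a deterministic "reference author": QLP and BSP sections
comment every abnormality in their group (or state that populations are
within reference ranges), a PBMC section appears exactly when the PBMC
predicate fires, and the interpretation section is rendered from a rule
table over the panel (below). Two styles are bundled:

- `harmonized` — one preferred surface form per cell type, one sentence
  frame, count/percent twins with identical direction and degree always
  merged into a compound "absolute count and percentage" comment;
- `heterogeneous` — up to three synonym surfaces per cell type, two sentence
  frames (subject-first and quantifier-first), probabilistic compound
  merging (0.5), clause merging of adjacent comments (0.35), and shuffled
  comment order, emulating a multi-author corpus in which equivalent
  concepts are phrased differently.

All surface choices derive from a CRC32 hash of (style, specimen id), so
rendering is reproducible without global state. Merged clauses always use
the subject-first frame so each mention's cue scope stays local; the
quantifier-first frame is restricted to single-mention sentences.

`corrupt_report` plants errors at independent per-comment rates: omissions,
direction flips, degree shifts (mild→moderate→significant→moderate),
quantifier swaps (both→count), and hallucinated statements about in-range
analytes. Every edit is logged with the edited comment's position, its
before state, and its after state; replaying the log in statement space
(`apply_corruption_log`) predicts every evaluation tally of the corrupted
report exactly, which is the package's central self-check: the text route
(render → extract → evaluate) and the statement route must agree edit for
edit.

## Statement extraction

The default extractor is rule-based and deterministic. Cell-type mentions
are found longest-match-first against a many-to-one alias dictionary after
normalization (case-fold, hyphens→spaces, `+` stripped, accents removed);
unknown terms return an explicit no-match sentinel, never a guess. Each
mention's cue scope runs from the mention to the next mention (the whole
sentence, mention excluded, when it is the only one — surface forms like
"CD21-low" would otherwise self-assert a direction). Direction comes from a
closed lexicon (decreased/reduced/low/…, increased/elevated/…), with
negation ("not decreased", "no abnormality in …") and within-reference
phrasing mapping to normal; a direction without a magnitude adverb yields
degree = unspecified, which counts as a comment but is excluded from
degree-accuracy denominators. "Counts and percentages" resolves to
quantifier = both. An LLM-backed extractor can replace the rules behind the
same statement type; the bundled dictionary covers the default schema's
families plus common synonyms and is fully user-replaceable.

## Evaluation metrics

The statement↔abnormality join key is (canonical cell family, quantifier);
a `both` statement matches either twin. Under the lab-value standard the
reference set is every out-of-range analyte; under the reference-report
standard it is the reference report's own abnormality statements. Metrics:

- comment rate = matched reference abnormalities / reference abnormalities;
- direction and degree accuracy over commented abnormalities only (degree
  only where both claim and reference specify a magnitude);
- quantifier accuracy per commented family: the claimed framing (count,
  percent, or both) must equal the reference framing;
- unsupported statements (false positives) are claimed units with no
  reference abnormality; omissions (false negatives) the reverse.

Zero-denominator metrics return an explicit `None` sentinel and are
excluded from aggregation, never interpolated. When several statements
claim the same unit, the claim kept is the lexicographically smallest
(direction, degree) — a deterministic rule independent of sentence order,
needed so the text route and the statement-space route of the corruption
check cannot disagree on duplicates.

The PBMC check is a direct logical comparison: by default a PBMC comment is
expected iff the CD19+ or CD20+ absolute count is out of range; the
predicate is a configurable disjunction of per-analyte conditions. Error
rates are reported as 100·errors/statements to one decimal. The
prevalence/comment-rate correlation is Pearson on raw per-cell-type
abnormality counts (configurable to Spearman), excluding undefined cells.
Method comparison uses the signed-rank test for paired tables (zsplit zero
handling, so identical samples sit at the null center n(n+1)/4 rather than
erroring), the rank-sum test for unpaired ones, a Friedman omnibus when
more than two methods are paired, and Benjamini-Hochberg adjustment of the
pairwise p-values.

## Sentence labeling

Sentences are split abbreviation-safely on terminal punctuation and labeled
by majority vote of the k = 5 nearest reference sentences under cosine
similarity (k is configurable; no abstention threshold is applied). The
default embedding is a deterministic lexical hashing vectorizer (token
counts CRC32-hashed into 256 dimensions, L2-normalized) so the whole stack
runs offline and reproducibly; an API-based semantic embedder satisfies the
same `embed` contract. Ties break by summed similarity, then by section
order QLP < PBMC < BSP < INTERP; neighbor selection resolves equal
similarities by reference index, making labeling invariant to reference
order. Because the renderer's sections use disjoint vocabulary, mislabeling
between QLP and BSP comments is harmless downstream (extraction pools both),
and the pipeline's metric path is robust to the lexical embedder's
limitations; with free-text clinical reports a semantic embedder is the
appropriate backend.

## Retrieval baseline

Corpus panels are standardized per analyte (corpus mean/SD; a zero-SD
feature falls back to scale 1 with a warning; missing values impute to the
corpus mean and are flagged) and matched by cosine similarity.
`whole_report` returns the nearest neighbor's report verbatim. For
`per_section` assembly the section *layout* follows the overall nearest
neighbor, and each present section's text comes from the nearest neighbor
having that section; taking layout from the per-section candidates instead
would attach a PBMC section to every assembled report whenever any corpus
report has one, and would break the self-retrieval identity (an exact
corpus match must reproduce its own report). Ties resolve to the earliest
corpus index. Corpora are desk-scale; no approximate nearest-neighbor
structures are used.

## Interpretation checklist

Eighteen binary attributes (compartment abnormalities, lymphopenias,
subset-specific findings, a diagnostic consideration, recommendations,
caveats, and a normal-study statement) are detected by keyword/regex rules
with clause-local negation scope: an attribute is absent when its cue is
preceded by a negation token within the same clause. The same detectors are
applied to generated and reference texts — one code path. Each attribute
also carries a panel-side rule (a small and/or expression over descriptors)
used by the reference renderer, so detector correctness is testable by
exact recovery. Agreement is summarized per attribute as accuracy,
sensitivity, and specificity over a corpus, with zero-denominator cells
undefined; these satisfy accuracy = (sen·P + spe·N)/(P + N) wherever both
are defined. The bundled list is a drafted, user-editable stand-in for an
institution's own criteria; an LLM-judge adapter can replace the rule
detectors behind the same interface.

## Pipeline and reproducibility

`run_pipeline` generates a training and an evaluation cohort, renders
reference reports, produces two comparison methods (the corruption operator
as a controlled-error stand-in generator, and the retrieval baseline
indexed on the training cohort), labels sentences with a reference set
built from the training reports, extracts, evaluates under both standards,
runs the PBMC check and method comparisons, and writes tidy metrics plus a
manifest (package/library versions, seeds, SHA-256 config hash). All
randomness derives from the single config seed; the same config reproduces
byte-identical metric tables. Default sizes (300 train / 200 eval) keep a
full run under half a minute on one CPU; the test suite uses 200-panel
oracle-identity cohorts, a 40-panel × 21-spec corruption grid, and a
500-panel retrieval corpus with 100 queries — sizes chosen as the package's
own working scale for desk-top verification.

## Known limitations

- The bundled ranges, degree cutpoints, alias dictionary, and attribute
  checklist are placeholders for unpublished institutional artifacts; every
  one is a config file.
- The lexical embedder captures token overlap, not meaning; it is adequate
  for template-rendered text only.
- The rule extractor handles the renderer's grammar plus common paraphrase
  patterns, not arbitrary clinical prose.
- The corruption operator plants independent per-comment errors; real
  generator errors are correlated and context-dependent, so corruption
  rates should be read as a dial for exercising the metrics, not as a model
  of any specific LLM's failure modes.
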