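# Methods

This note documents the models, conventions and numerical choices behind
`myh9rd`, in the order the pipeline applies them.

## Variant notation and truncation arithmetic

The parser covers the notation subset that MYH9-RD reporting actually uses:
coding substitutions, deletions and duplications with explicit bases, and
protein-level missense, nonsense, frameshift (`fs*N`) and in-frame
deletion/duplication descriptions. It is not a general HGVS implementation
(no intronic, UTR or complex delins forms); protein-level notation is
authoritative for consequence typing, and duplications are tallied as
in-frame insertions. Coordinates are 1-based and inclusive at both ends.

Truncation arithmetic is defined so the printed arithmetic of the reference
cohort is exact:

* bare nonsense at residue *r* → product of *r* − 1 residues, stop at *r*;
* substitution-then-stop `p.(X r Y*)` → the substituted residue is retained,
  product of *r* residues, stop at *r* + 1 (hence `p.(Gln890Arg*)` gives an
  890-residue product with 1,070 of 1,960 residues removed);
* frameshift `fs*N` at *r* → *r* − 1 native residues plus *N* − 1 altered
  ones (product *r* + *N* − 2), stop at *r* + *N* − 1;
* a frameshift with unknown offset (`fs*?`) has no defined termination and
  is handled conservatively (no PVS1/PM4 decision is made from it).

Every truncating rule is cross-checked in the tests against an independent
string-level oracle that builds a mock 1,960-mer and applies the edit.

## Domain architecture

Exons map to domains as: 2–19 head (HD), 20 neck, 21–40 coiled-coil tail
(TD), 41 nonhelical tail (NHTD). The NHTD is anchored as the final 34
residues (start 1927), which the architecture validates. Published sources
give no residue coordinates for the HD/neck/TD boundaries, so the
residue-level fallback (HD ≤ 833, TD ≤ 1926) is a package convention used
only when a variant arrives without an exon; when an exon is provided it
wins (an exon-41 frameshift at residue 1924 is attributed NHTD, matching
how such variants are reported).

PM1 hotspots are configurable named intervals. The defaults are the two
regions that carry PM1 in the reference cohort: the last-50-residue
truncation window (1911–1960) and the exon-2 head cluster (93–96). The
SH3/motor-domain interface (residues 26–60) is carried descriptively and is
never used as evidence.

Conservation of a residue is the fraction of alignment rows matching the
reference at that column; gaps count in the depth but never as matches, and
residues index the ungapped reference. "Highly conserved" defaults to
≥ 0.9.

## Rarity and exclusion

PM2 eligibility requires max(known allele frequencies) ≤ 1e-4 **and** zero
carriers among internal controls. Absence from every database is
distinguished from an observed frequency of zero (an `unobserved` flag) but
both satisfy PM2. No published numeric cutoff exists for this disorder; the
1e-4 default is chosen so that a variant observed at 1:10,000 in one
database remains PM2-eligible, consistent with the reference cohort's
adjudications, and `rare_af_max` (1e-3) separates merely-rare from common.
Both are configuration, and PM2 eligibility is monotone in the threshold.

The four cohort exclusion criteria evaluate review flags (non-BPD carrier
counts, phenotype compatibility, alternate-gene diagnosis, unaffected-
relative carriage). A missing flag makes the criterion "not applicable" —
it is logged and never excludes. Phenotype compatibility is a supplied
boolean, not computed from HPO terms.

## Evidence assignment

Codes derive deterministically from the variant, patient, pedigree and
registry:

* **PVS1 / #PM4** — a truncation terminating at or before residue 1910
  receives PVS1 (loss of function is an accepted mechanism for this gene);
  one terminating inside the last 50 residues receives `#PM4`, a moderate
  code recording the PVS1 substitution. In-frame length changes receive
  plain PM4.
* **PM2** from the rarity assessment; **PM1** from hotspot intersection
  (the variant's own residue footprint, not the downstream region a
  truncation abolishes); **PM5** when the registry holds a different
  pathogenic change at the same residue.
* **PS2 / PM6** from confirmed / assumed de novo status.
* **PP1** from cosegregation, escalating with informative meioses:
  ≥ 2 supporting, ≥ 4 moderate, ≥ 7 strong. The tiers are a package
  convention (documented, configurable in code), not a published rule.
* **PP3** is strictly conjunctive: highly conserved nucleotide, highly
  conserved amino acid, predicted protein effect, GVGD class C65, and
  deleterious calls in SIFT **and** MutationTaster **and** PolyPhen. Any
  missing line withholds the code (logged); any disagreeing line denies it.
* **PP4** (phenotype specificity), **PS3** (functional evidence) and
  **PS4** (case prevalence, optionally at supporting strength) are review
  inputs, not computed — the underlying case/control counts and assay data
  are not part of the package's inputs.
* **A** (≥ 1 main syndromic feature beyond macrothrombocytes: inclusion
  bodies, hearing impairment, nephropathy, liver-enzyme elevation) and
  **B** (family history) are descriptive context.

Missing annotations never grant evidence: all tri-state inputs default to
"unknown", and unknown behaves like "not demonstrated".

## Combining and classification

Combining applies the Richards-2015 rule table to the counts of effective
levels (modulated strengths replace defaults; descriptive codes are
excluded). One clause was added beyond the published list: two or more
very-strong codes classify as pathogenic. The published table anticipates
at most one PVS1, and without this closure an escalation from strong to
very strong could lower a classification, breaking monotonicity; the
tests enforce both the literal table (via an independently transcribed
enumeration, exhaustive over all evidence multisets of size ≤ 8) and the
monotonicity property (10⁴ randomized additions/escalations). Benign-side
codes combine analogously (stand-alone or ≥ 2 strong → benign; 1 strong +
1 supporting or ≥ 2 supporting → likely benign) and a conflict between
sides resolves to VUS. Classification depends only on the multiset of
effective levels.

### Conservative-novel policy

Expert panels are reluctant to call a never-before-seen variant (likely)
pathogenic on predicted impact alone. The engine reproduces this as a
named, toggleable policy: a **novel** variant whose strict class is LP or P
is capped at VUS unless some independent corroboration backs it — PS3
functional data, a PM5 same-residue pathogenic precedent, a PM1 hotspot
location, or any strong-level code. Predicted impact alone, even PVS1,
does not lift the cap: the archetypal case is a novel stop gain with
PVS1+PM2+PP4 that the panel still reports as VUS because no functional
confirmation was possible. Every override is recorded in the audit trail
with the policy name. The exemption list is the package's reading of which
corroborations panels accept; it reproduces all twelve novel-variant
classifications in the reference cohort.

### Exception ledger

Three reference-cohort rows disagree with strict combining even after the
policy, and the published report does not explain them: Lys74Glu (strict
VUS from PS4_supporting+PM2+PP4+PP3, printed likely pathogenic), Arg1933*
(strict LP from PS4+PM2+PM1+PP4, printed pathogenic) and Met1934Trpfs*14
(strict pathogenic from PS4+#PM4+PM2+PM1+PP4, printed likely pathogenic).
These are recorded verbatim in a fixed exception ledger
(`myh9rd.fixture.EXCEPTION_LEDGER`); the concordance test asserts that the
engine's mismatches equal the ledger exactly, in both directions, so any
drift — a new mismatch or a silently "fixed" one — fails loudly. A related
open point is that Arg1933* terminates within the last 50 residues yet its
printed evidence lists no PM4; the fixture stores the row as printed, while
`assign_evidence` on the raw variant would emit `#PM4`.

### Contribution to phenotype

"Full" requires macrothrombocytes together with either thrombocytopenia
(count < 150×10⁹/L) or a corroboration outside the hematologic core —
hearing impairment, nephropathy, liver-enzyme elevation, or family history.
Inclusion bodies alone do not complete the picture: a patient with
macrothrombocytes, inclusions and a normal platelet count is "uncertain"
(this is the configuration of the one "uncertain" patient in the reference
cohort, whereas a normal-count patient with an affected family is "full").
Absent phenotype data always yields "uncertain" with a warning.

## Cohort summaries

Severity splits at ≤ 50×10⁹ platelets/L (severe/moderate) versus > 50
(mild); the published wording ("below … or above 50") does not cover
equality, and the ≤ convention is the package's choice, configurable.
Thrombocytopenia is strictly < 150. Patients with missing counts are
excluded from stratification and logged. A patient carrying two variants is
counted once, attributed to the variant with the higher final class, ties
broken toward the higher residue (which prefers tail-domain positions); the
attribution is logged. Spectrum counts deduplicate on the
(coding, protein) notation pair and are invariant under row order and
duplication. Every proportion is emitted with its numerator and
denominator; percentages render to one decimal.

Diagnostic yield counts patients enrolled as "unclassified platelet
disorder" or "suspected, unconfirmed" whose best carried variant ends
likely pathogenic or pathogenic — i.e. patients for whom sequencing
produced a new molecular diagnosis.

## Packaged reference cohort

`myh9rd/data/` ships a transcription of a published 50-patient, 28-variant
MYH9-RD cohort: notation, exons, domains, CADD scores, allele-frequency
strings (also parsed to numbers), evidence codes with their printed
modulations, classifications, contribution labels, enrollment statuses and
family structure, plus a registry of the previously reported variants.
SHA-256 checksums guard the files; the loader refuses silent edits.

Two transcription conventions deserve note. First, exon numbers are printed
for only some variants; the remainder were assigned from the gene's
standard exon numbering, and the resulting distinct-exon count equals the
published total (11), with the per-row domain column reproduced exactly.
Second, enrollment statuses follow the published group totals
(19 unclassified / 11 suspected / 20 known-unconfirmed) and the published
yield breakdown; where a row-level diagnosis blurb conflicts with those
totals, the totals win. Per-patient platelet counts, audiometry and
bleeding scores are published only in supplementary material and are
therefore absent from the fixture; cohort-level percentage claims that
depend on them (median count, the 39 %/61 % severity split, the 22 %
hearing-impairment rate) are **not** asserted against the fixture — they
are exercised on synthetic cohorts, where the planted truth is known.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
defaults mirroring the reference cohort:

| parameter | default | basis |
|---|---|---|
| families | 44, sizes 1–4 (P = .88/.08/.03/.01) | 50 patients in 44 pedigrees |
| domain mix HD/TD/NHTD | .34/.54/.12 | 17/27/6 carriers per domain |
| consequence mix | .75/.107/.071/.036/.036 | 21/3/2/1/1 of 28 variants |
| platelet lognormal (μ, σ) | HD (3.69, .5); TD (4.09, .5); NHTD (3.56, .6) | medians ≈ 40/60/35 ×10⁹/L, overall median ≈ 50 and the head-domain-more-severe gradient |
| penetrance (hearing) | HD .24 / TD .18 / NHTD .30 | 11/50 overall, domain split |
| penetrance (nephropathy) | HD .12 / TD .02 / NHTD .02 | 3/50, head-biased |
| penetrance (liver) | HD .05 / TD .03 / NHTD .05 | 2/50 |
| inclusion bodies | 1.0 everywhere | invariably present on immunofluorescence |
| enrollment mix | .38/.22/.40 | 19/11/20 |
| pathogenic fraction | 16/28 | classified LP/P share of the spectrum |
| exclusion plant rate | 24/74 | candidate filtering in the source cohort |
| allele frequencies | 80 % absent, else 10^U(−6,−4) | rare-disease spectrum |

One variant segregates per family; annotations (conservation, predictors,
GVGD, functional data, prevalence) are planted consistently with the true
class, with a configurable inconsistency-injection rate (default 0) for
stress-testing the conservative tri-state logic. Exclusion reasons are
planted per family at the configured rate and emitted as review contexts,
so exclusion recovery is exact bookkeeping. Pedigrees are nuclear; the
cosegregation count per family is (affected members − 1). The protein
alignment (depth 10) is generated with every mutated column fully
conserved and ~30 % of other columns variable.

The generator does **not** emulate sequencing error, genotype calling,
referral-network ascertainment, age-dependent penetrance, phenocopies, or
more than one variant per family. Passing recovery tests therefore show
that the pipeline's bookkeeping and estimators are correct under the
assumed structure — not that the structure captures every property of real
cohorts.

The seed fully determines the output (byte-identical files on re-runs).
Recovery checks run at 2,000 patients (2,000 single-member families), a
size chosen so that three binomial standard errors on the smallest domain
stratum are tight enough to be informative while the whole suite stays in
seconds.

## Known limitations

* PS3/PS4/PP4 are inputs; the package cannot re-derive panel judgments
  from raw assay or prevalence data.
* The HD/TD residue boundaries used without exon information are
  conventions, not measured coordinates.
* Benign-side evidence is implemented but no benign codes are assigned
  automatically (`assign_evidence` covers the pathogenic side only).
* The minimal VCF reader requires notation strings in INFO
  (`HGVSC`/`HGVSP`/`EXON`); it does not annotate raw alleles against a
  transcript.
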