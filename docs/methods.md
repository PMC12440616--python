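# Methods

This note documents the models and procedures implemented in `cnidapep`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Cleavage-site model

Prohormone convertases cleave precursor proteins at basic residues; the
carboxypeptidase then trims the basic residues, and a glycine left at the
new C-terminus is converted into an amide by PAM. The scanner models this
as follows, on the signal-trimmed region of each protein (coordinates
1-based, inclusive, everywhere):

* A **site** is a maximal run of K/R residues for which at least one
  length-2 window over the run — optionally extended left by an immediately
  preceding G — matches a configured motif. The default motif set is
  `KK, RK, KR, RR, GK, GR`. Consequences: any dibasic pair is a site; an
  isolated K or R is a site only when a G immediately precedes it
  (`GK`/`GR`); an isolated K/R with a non-G predecessor is *not* a site
  (monobasic cleavage without the glycine context is outside the model).
* The whole run is consumed, plus the preceding G when present; that G sets
  `amide_donor`, and the peptide ending at the site inherits
  `amidated=True`. Maximal-run consumption resolves overlapping motifs
  (`GKR`, `KKR`, `KRRR`…) deterministically into a single site and avoids
  double-counting.
* `X` (unknown residue) never matches K, R or G, nor any family pattern.

**Peptides** are the maximal non-empty segments strictly between consumed
regions, plus the segment after the signal and the tail after the last
site. A peptide *counts toward the precursor pass criterion* iff its length
is within `[min_len, window]` (defaults 3 and 20 — `window` reads the
"cleavage sites within a 20-residue range yielding a peptide" rule as a
maximum mature-peptide length, the interpretation consistent with typical
neuropeptide sizes; the alternative inter-site-distance reading is
reachable by adjusting `window`), its C-terminal boundary is a site (or the
protein terminus, allowed when the segment matches a family signature), and
— only when `require_n_motif=True` — it starts with Q (pyroglutamate), has
P at position 2, or abuts a site on its N side. The N-terminal motifs
default to *bonus* evidence rather than requirements because known
non-amidated LW peptides satisfy XP while other reported peptides would
fail a strict conjunctive rule; both readings are exposed.

**Families** are assigned by the first matching row of an ordered table of
C-terminal patterns (wildcard X) plus a required amidation state:
RFamide (`RF`, amidated), GLWamide (`XLW`, amidated — the G-[LIV]-W
signature simplified to its last two informative positions), PRXamide
(`PRX`, amidated), LW peptide (`LW`, non-amidated), KVamide (`KV`,
amidated), FRamide (`FR`, amidated).

**Scoring.** No canonical scoring function exists for this step, so the
score is this package's own, with config-exposed weights:
`score = 1.0·n_passing + 2.0·n_repeat_groups + 0.5·n_modified`, where a
repeat group is ≥2 passing peptides sharing C-terminal dipeptide and
amidation state (repeated peptide copies are a hallmark of neuropeptide
precursors) and modified means amidated, pyroglutamate or Pro-2. The
*pass* criterion is independent of the weights: at least one passing
peptide.

## Secretome prefilter

A record is kept iff it has a signal peptide, at most `max_tm_regions`
(default 0) transmembrane segments outside the signal region, and no
domain hit. TM segments ending within `1..signal_end` are discounted
because several TM callers report the signal peptide itself as a membrane
segment; counting it would systematically discard true secreted
precursors. Evidence rows whose id is not in the FASTA warn and are
ignored (users commonly subset FASTAs).

The fallback signal heuristic — used only when a record has no
signal-caller row and `missing_evidence_policy="heuristic"` — is
deliberately crude: a signal is called iff the first 30 residues contain a
run of ≥8 residues from {A,I,L,F,V,M,W,C}; the cleavage position is the
first small residue (A,G,S,C,T) within 10 positions after the run, else
run end + 5 (clamped). It is a testing device, not a replacement for a
real predictor; the synthetic generator plants signals this heuristic
recognizes by construction, which keeps the closed-loop tests
self-contained. How proteins without unambiguous caller output are handled
is exposed as the `drop | keep | heuristic` policy switch.

## Homology and expression filters

The homology rule follows the published thresholds with strict
inequalities: the top hit (smallest e-value; ties broken by higher
bitscore, then lexicographic subject id — invented for determinism)
removes a candidate iff identity >30% and e-value <0.05 and its
description contains no allow-listed keyword (`neuropeptide`,
`preprohormone`, `prohormone`, `precursor`, `uncharacterized`,
`hypothetical`). The keyword list encodes the inclusion of
neuropeptide-precursor and uncharacterized hits and is configurable, since
the original selection involved manual curation no algorithm reproduces.

"Neuronally expressed" has no published threshold; the filter uses a
two-part rule over gene-by-cluster mean summaries (the summary level is
itself an assumption — per-cell input is out of scope): detection
(best neuronal cluster mean > `min_neuronal_expression`, default 0) and
neuronal share (best neuronal mean / best overall mean ≥
`min_neuronal_share`, default 0.5). The share term tolerates genes that
are broadly but genuinely neuronally expressed while rejecting genes
dominated by gland or epithelial populations. All-zero profiles fail the
detection test before any ratio is formed.

## Similarity clustering

All unordered pairs are scored by exact local alignment (BLOSUM62; gap of
length L costs `11 + (L−1)·1`, the Bio.Align convention) and converted to
e-values with the ungapped Karlin–Altschul formula `E = K·m·n·exp(−λS)`
with K = 0.041, λ = 0.267 — the standard ungapped BLOSUM62 constants,
knowingly applied to gapped scores as a documented approximation. Pairs
with `E ≤ e_cutoff` (default 1e−4; non-canonical, since no published
cutoff exists for this step) become edges; clusters are connected
components, labelled `cluster_0, cluster_1, …` by decreasing size then
smallest member id, singletons labelled `singleton` — invariant under
input order.

The 2D layout initializes positions uniformly in the unit square from a
seeded generator and runs a fixed number of damped force iterations:
per-edge attraction `attraction·w·(Δ)` with `w = min(1, −log10 E / 10)`,
per-pair repulsion `repulsion·Δ/d²` with `d` floored at `min_dist`,
velocity update `v ← damping·(v + step·F)` with `step = 0.01` for
stability. Only two properties are contractual: bit-reproducibility for a
fixed seed, and separation of disconnected clusters; specific coordinates
are not meaningful.

## Synthetic benchmark

`make_precursor` assembles: signal (Met, a basic residue, a 10-residue
hydrophobic h-region, a small-residue c-region) + spacer + a separator
cleavage site + `n_copies × (core [+ donor G] + site)` + trailing spacer.
Every planted core is therefore delimited by cleavage sites on both ends,
so the manifest's coordinates are exactly what a correct scanner must
recover. Spacers and core prefixes are drawn from residues that can form
no site, no donor, no hydrophobic run and no family tail
(`A,D,E,N,S,T,P,Q,H,Y`); spacers default to 1–2 residues, below `min_len`,
so they never count as peptides. Cores are validated against boundary
ambiguity (no internal dibasic pair, no G-basic digram, no leading K/R, a
trailing K/R or G only under amidation); a `GK`/`GR` site motif requires
`amidated=True` because without its glycine the single basic residue is
not a site.

Decoys: *random* (length 60–200, K/R frequency ≈1% each, no signal),
*tm* (planted signal + a 21-residue hydrophobic segment with a matching
TM-caller row, so the prefilter drop reason is `tm`), *domainlike*
(planted signal + a domain-scanner row). Expression: neuronal genes draw
`2 + Poisson(3)` (mean 5, detection guaranteed) in 1–2 neuronal clusters
over a Poisson(0.1) background; non-neuronal genes mirror this with
`3 + Poisson(2)`, which pins their neuronal share below the 0.5 default;
ubiquitous genes draw Poisson(3) everywhere. The shifted draws are a
deliberate departure from plain Poisson noise so that class membership,
not sampling noise, decides filter outcomes at the default thresholds.
Alignment hits give precursors either no hit or an allow-keyword hit, and
decoys mostly strong non-neuropeptide hits.

The standard benchmark is 200 precursors (family templates cycled, 1–5
copies each, all neuronal) + 600 decoys (200 per kind). With 10%
adversarial precursors, two-thirds carry an embedded *monobasic* K/R —
recoverable, and a direct probe that the scanner does not over-cleave —
and one-third an embedded *dibasic* pair that genuinely splits the planted
peptide (flagged `expected_recoverable=False`); the expected
unrecoverable fraction is ≈3.3% of planted peptides, so expected boundary
recall ≈0.967, with seed-to-seed variance from the random copy counts.

**What passing shows — and does not.** Perfect precision/recall on the
clean benchmark shows the stages compose correctly against unambiguous
planted truth. Real proteomes differ in every hard way: signal peptides
need a real predictor, monobasic cleavage exists in vivo, spacers can look
like peptides, homology descriptions are messier than a keyword list, and
expression atlases carry batch structure none of which is simulated.
The benchmark validates the machinery, not the biology.

## Problem sizes and numerical choices

The test and acceptance suites use: 10,000 random sequences (length
30–500) for the scanner-vs-oracle and reconstruction suites; the
200+600-record benchmark for end-to-end recovery (the benchmark pipeline
runs skip the clustering stage, whose contracts are measured separately on
the planted two-family set of 10+10 sequences at ~60%+ within-family
identity); 40 randomized homology configs and 20 share thresholds for the
monotonicity sweeps. The independent oracles are a brute-force motif
enumerator (scanner) and a quadratic Gotoh dynamic program (alignment
scores). All randomness flows from explicit seeds; layout determinism is
asserted bitwise.

## Known limitations

* The signal heuristic has no statistical basis; use real caller tables
  for real data.
* Monobasic cleavage (K/R without G) and atypical convertase contexts are
  not modelled.
* Karlin–Altschul constants are ungapped approximations; e-values are
  comparable within a run, not calibrated against any database search.
* The family table is small and C-terminus-only; it labels, it does not
  discover families.
* The scoring weights are heuristics for ranking; only the ≥1-peptide pass
  criterion carries over from published practice.
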