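# cnidapep

**In silico discovery of neuropeptide precursors from predicted proteomes.**

Cnidarian nervous systems run largely on peptides. Neuropeptides are cut out
of secreted precursor proteins (preprohormones) by prohormone convertases at
basic cleavage sites, and many are stabilized by C-terminal amidation (a
glycine preceding the site is converted into an amide) or an N-terminal
pyroglutamate. Classical mining screens only for known motifs plus the
amidation glycine — which misses lineage-specific peptides that lack it,
such as non-amidated LW-peptides. `cnidapep` implements a relaxed,
expression-aware discovery pipeline for researchers mining predicted
proteomes (e.g. of *Hydra*, *Clytia* or *Nematostella*) for new precursor
candidates:

1. **Secretome prefilter** — keep proteins with a signal peptide, no
   transmembrane segment outside the signal, and no known functional
   domain. Evidence comes from external caller tables (signal, TM, domain);
   a built-in hydrophobic-run heuristic stands in when caller output is
   absent.
2. **Cleavage-site scan** — locate dibasic sites (KK, RK, KR, RR) and
   glycine-extended monobasic sites (GK, GR); a maximal K/R run plus an
   immediately preceding amide-donor G is consumed as one site. Segments
   between sites become candidate mature peptides, annotated with
   amidation, pyroglutamate (leading Q) and the Pro-at-position-2 motif,
   and assigned to C-terminal families (RFamide, GLWamide, PRXamide,
   non-amidated LW, KVamide, FRamide). A precursor passes if it yields at
   least one peptide of length 3–20.
3. **Homology filter** — remove candidates whose top database hit
   (>30% identity, e-value <0.05) identifies them as a known
   non-neuropeptide protein; hits described as neuropeptide precursors or
   uncharacterized proteins do not disqualify.
4. **Expression filter** — keep candidates detected in neuronal clusters of
   a gene-by-cluster single-cell summary, with a configurable neuronal-share
   threshold.
5. **Similarity clustering** — all-vs-all Smith–Waterman (BLOSUM62, affine
   gaps), Karlin–Altschul e-values `E = K·m·n·e^(−λS)`, connected-component
   clusters at an e-value cutoff, and a seeded, deterministic
   force-directed 2D layout.

A synthetic-proteome generator (`cnidapep.simulate`) plants precursors with
known peptide coordinates alongside random/transmembrane/domain decoys and
emits every input format the pipeline consumes plus a ground-truth
manifest, so the whole pipeline is testable end to end without downloads.

## Worked example

The package ships synthetic stand-in precursors reproducing the published
architectures of four characterized *Hydra* genes (see
`cnidapep/synthetic_examples.py`; only the LWa1 mature peptide EPEPPETGLW
is a real reported sequence). Scanning the LW-peptide precursor A stand-in:

```python
from cnidapep.synthetic_examples import SYNTHETIC_LW_PRECURSOR_A, scan_example

res = scan_example(SYNTHETIC_LW_PRECURSOR_A)
print("signal_end:", res.signal_end)
for p in res.peptides:
    print(p.start, p.end, p.mature, p.amidated, p.xp, p.family, p.counts_toward_pass)
print(res.score.score, res.score.passes)
```

prints

```
signal_end: 11
12 12 A False False unassigned False
15 24 EPEPPETGLW False True LW_peptide True
27 34 QPETNSLW False True LW_peptide True
37 44 DPNAHTLW False True LW_peptide True
47 48 SD False False unassigned False
6.5 True
```

The heuristic places the signal-peptidase cleavage after residue 11; three
LW-family peptides are cut out between dibasic KR sites, every one
non-amidated (there is no glycine before any basic run — the hallmark of
this precursor class), and each carries the Pro-at-position-2 protection
motif. The precursor scores 6.5 (three passing peptides + one repeat group
of shared C-termini + three modified peptides at weight 0.5) and passes the
≥1-peptide criterion.

The same stages are available from the shell:

```bash
cnidapep simulate --out-dir sim --n-precursors 200 --n-decoys 600 --seed 1
cnidapep pipeline config.yaml     # prefilter -> scan -> homology -> expression -> cluster
cnidapep scan proteome.fasta --out peptides.tsv
cnidapep cluster candidates.fasta --out-dir clust --seed 1
```

`pipeline` writes per-stage reasons tables, a candidate table with
per-stage pass flags, the mature-peptide table/FASTA, cluster labels with
2D layout coordinates, and a JSON run summary of stage survivor counts.

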