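"""Synthetic secreted proteomes with ground truth, for end-to-end testing.

The generator emulates the architecture of neuropeptide precursors: an
N-terminal signal peptide, then alternating spacer and peptide-core
segments, every segment delimited by a prohormone-convertase cleavage site
(a dibasic K/R pair, preceded by a glycine amide donor when the upstream
peptide is amidated). Alongside the precursors it emits decoy proteins
(random composition, transmembrane, domain-bearing), matching annotator
evidence tables, an alignment-hit table and a gene-by-cluster expression
matrix — everything the pipeline consumes — plus a truth manifest recording
every planted peptide's coordinates and flags.

Peptide cores are built so planted boundaries are unambiguous under the
scanner's rules: no adjacent K/R pairs, no K/R after a G, no K/R at the
core start, a terminal K/R only when amidated, a terminal G only when the
donor glycine follows. Adversarial cores relax this deliberately (an
embedded monobasic K/R, which a correct scanner must NOT cleave, or an
embedded dibasic pair, which genuinely splits the planted peptide) and are
flagged ``expected_recoverable=False`` when the split is real.

All generation is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SpecError
from .io import ALIGNMENT_COLUMNS, EvidenceTable, PrecursorRecord, write_fasta
from .scanner import DEFAULT_FAMILIES, MaturePeptide, assign_family

#: Residues used for spacers and core prefixes: no K/R (no spurious sites),
#: no G (no spurious amide donors), no strongly hydrophobic residues (no
#: spurious signal-peptide calls), no L/W (no spurious LW-family tails).
SAFE_RESIDUES = "ADENSTPQHY"

HYDROPHOBIC_POOL = "LIVFA"

#: (core tail, amidated) per family template; prefixes are sampled from
#: SAFE_RESIDUES. The tails carry the C-terminal family signatures.
FAMILY_TEMPLATES = {
    "RFamide": ("RF", True),
    "GLWamide": ("GLW", True),
    "PRXamide": ("PRG", True),
    "LW_peptide": ("LW", False),
    "KVamide": ("KV", True),
    "FRamide": ("FR", True),
    "unassigned": ("", None),  # amidation chosen at sampling time
}

DIBASIC_MOTIFS = ("KK", "RK", "KR", "RR")
ALL_MOTIFS = DIBASIC_MOTIFS + ("GK", "GR")

TRUTH_FORMAT_VERSION = "cnidapep-truth v1"


@dataclass
class PrecursorSpec:
    """Recipe for one synthetic precursor.

    ``peptide_core`` is repeated ``n_copies`` times; ``amidated`` plants a
    glycine amide donor before each cleavage site. A motif of GK or GR
    implies the glycine is the donor, so it requires ``amidated=True``.
    """

    peptide_core: str
    n_copies: int = 1
    amidated: bool = False
    cleavage_motif: str = "KR"
    spacer_len_range: tuple[int, int] = (1, 2)
    signal: bool = True
    max_core_len: int = 20
    #: adversarial cores break the core invariants on purpose; validation is skipped
    adversarial: bool = False

    def __post_init__(self):
        if not self.adversarial:
            validate_core(self.peptide_core, self.amidated, self.max_core_len)
        if self.n_copies < 1:
            raise SpecError("n_copies must be >= 1")
        if self.cleavage_motif not in ALL_MOTIFS:
            raise SpecError(f"unknown cleavage motif {self.cleavage_motif!r}")
        if self.cleavage_motif in ("GK", "GR") and not self.amidated:
            raise SpecError(
                "GK/GR motifs require amidated=True: without the glycine the "
                "single basic residue is not a cleavage site"
            )
        lo, hi = self.spacer_len_range
        if not 0 <= lo <= hi:
            raise SpecError("spacer_len_range must be 0 <= lo <= hi")


def validate_core(core: str, amidated: bool, max_len: int = 20) -> None:
    """Reject cores whose planted boundaries would be ambiguous."""
    if not core:
        raise SpecError("empty peptide core")
    if len(core) > max_len:
        raise SpecError(f"core longer than {max_len} residues")
    if core[0] in "KR":
        raise SpecError("core must not start with K/R (would extend the previous site's run)")
    for a, b in zip(core, core[1:]):
        if a in "KR" and b in "KR":
            raise SpecError("core contains an internal dibasic pair")
        if a == "G" and b in "KR":
            raise SpecError("core contains an internal G-basic site")
    if core[-1] in "KR" and not amidated:
        raise SpecError("terminal K/R in a non-amidated core would merge with the site")
    if core[-1] == "G" and not amidated:
        raise SpecError("terminal G in a non-amidated core would read as an amide donor")


@dataclass
class TruthPeptide:
    """One planted mature peptide: coordinates, flags and family label."""

    parent_id: str
    start: int
    end: int
    mature: str
    amidated: bool
    family: str
    expected_recoverable: bool = True


@dataclass
class TruthProtein:
    id: str
    klass: str  # precursor | decoy_random | decoy_tm | decoy_domainlike
    expression_class: str  # neuronal | non_neuronal | ubiquitous
    has_signal: bool
    signal_end: int
    peptides: list[TruthPeptide] = field(default_factory=list)


@dataclass
class TruthManifest:
    """Ground truth for one generated benchmark."""

    proteins: dict[str, TruthProtein] = field(default_factory=dict)

    def add(self, protein: TruthProtein) -> None:
        self.proteins[protein.id] = protein

    @property
    def precursor_ids(self) -> set[str]:
        return {p.id for p in self.proteins.values() if p.klass == "precursor"}

    def all_peptides(self) -> list[TruthPeptide]:
        return [pep for p in self.proteins.values() for pep in p.peptides]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.proteins.values():
            rows.append(
                {
                    "row_type": "protein", "id": p.id, "class": p.klass,
                    "expression_class": p.expression_class,
                    "has_signal": int(p.has_signal), "signal_end": p.signal_end,
                    "parent_id": "", "start": "", "end": "", "mature": "",
                    "amidated": "", "family": "", "expected_recoverable": "",
                }
            )
            for pep in p.peptides:
                rows.append(
                    {
                        "row_type": "peptide", "id": "", "class": "",
                        "expression_class": "", "has_signal": "", "signal_end": "",
                        "parent_id": pep.parent_id, "start": pep.start,
                        "end": pep.end, "mature": pep.mature,
                        "amidated": int(pep.amidated), "family": pep.family,
                        "expected_recoverable": int(pep.expected_recoverable),
                    }
                )
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {TRUTH_FORMAT_VERSION}\n")
            fh.write("# coordinates: 1-based, inclusive\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TruthManifest":
        with open(path) as fh:
            first = fh.readline().strip()
            if first != f"# {TRUTH_FORMAT_VERSION}":
                raise SpecError(f"unexpected truth-manifest header {first!r}")
        df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
        manifest = cls()
        for _, row in df.iterrows():
            if row["row_type"] == "protein":
                manifest.add(
                    TruthProtein(
                        id=str(row["id"]), klass=str(row["class"]),
                        expression_class=str(row["expression_class"]),
                        has_signal=bool(int(row["has_signal"])),
                        signal_end=int(row["signal_end"]),
                    )
                )
            else:
                manifest.proteins[str(row["parent_id"])].peptides.append(
                    TruthPeptide(
                        parent_id=str(row["parent_id"]), start=int(row["start"]),
                        end=int(row["end"]), mature=str(row["mature"]),
                        amidated=bool(int(row["amidated"])), family=str(row["family"]),
                        expected_recoverable=bool(int(row["expected_recoverable"])),
                    )
                )
        return manifest


def _sample(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n)) if n else ""


def make_signal(rng: np.random.Generator) -> str:
    """A signal peptide the prefilter's hydrophobic-run heuristic recognizes.

    Met start, a basic residue (the classic n-region charge), a 10-residue
    hydrophobic h-region, then a small-residue c-region the heuristic takes
    as the cleavage position.
    """
    return "MK" + _sample(rng, HYDROPHOBIC_POOL, 10) + "SA"


#: signal_end the heuristic assigns to make_signal output: the S at
#: position 13 is the first small residue after the hydrophobic run.
SIGNAL_END = 13


def _site_residues(motif: str, amidated: bool) -> str:
    if motif in ("GK", "GR"):
        return motif  # the G is the donor
    return ("G" if amidated else "") + motif


def _family_of(core: str, amidated: bool) -> str:
    probe = MaturePeptide(
        parent_id="", start=1, end=len(core), raw=core,
        amidated=amidated, pyroglu=core.startswith("Q"),
        xp=len(core) >= 2 and core[1] == "P",
    )
    return assign_family(probe, DEFAULT_FAMILIES)


def make_precursor(
    spec: PrecursorSpec, rng: np.random.Generator, record_id: str = "syn_precursor"
) -> tuple[PrecursorRecord, TruthProtein]:
    """Assemble one synthetic precursor and its truth entries.

    Layout: signal, spacer, then for each copy a separator cleavage site
    followed by the core (with donor G and site residues appended), and a
    trailing spacer. Every core is therefore delimited by cleavage sites on
    both ends, so its planted coordinates are exactly what the scanner
    should recover.
    """
    lo, hi = spec.spacer_len_range
    spacer = lambda: _sample(rng, SAFE_RESIDUES, int(rng.integers(lo, hi + 1)))

    parts: list[str] = []
    if spec.signal:
        parts.append(make_signal(rng))
    parts.append(spacer())
    parts.append("KR")  # separator site before the first core
    truth_peps: list[TruthPeptide] = []
    pos = sum(len(p) for p in parts)  # 1-based position of last residue so far
    for _ in range(spec.n_copies):
        start = pos + 1
        end = pos + len(spec.peptide_core)
        truth_peps.append(
            TruthPeptide(
                parent_id=record_id, start=start, end=end,
                mature=spec.peptide_core, amidated=spec.amidated,
                family=_family_of(spec.peptide_core, spec.amidated),
            )
        )
        site = _site_residues(spec.cleavage_motif, spec.amidated)
        parts.append(spec.peptide_core + site)
        pos = end + len(site)
    parts.append(spacer())

    residues = "".join(parts)
    record = PrecursorRecord(id=record_id, description=record_id, residues=residues)
    protein = TruthProtein(
        id=record_id, klass="precursor", expression_class="neuronal",
        has_signal=spec.signal, signal_end=SIGNAL_END if spec.signal else 0,
        peptides=truth_peps,
    )
    return record, protein


#: Background residue frequencies for random decoys: K and R suppressed
#: below 2% so accidental cleavage architecture is rare.
def _decoy_alphabet() -> tuple[list[str], np.ndarray]:
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    probs = np.full(20, 1.0, dtype=float)
    probs[letters.index("K")] = 0.2
    probs[letters.index("R")] = 0.2
    return letters, probs / probs.sum()


def make_decoys(
    kind: str,
    n: int,
    rng: np.random.Generator,
    id_prefix: str = "decoy",
) -> tuple[list[PrecursorRecord], list[TruthProtein], pd.DataFrame]:
    """Generate decoy proteins of one kind plus their evidence rows.

    ``random`` decoys are plain background composition with no signal.
    ``tm`` and ``domainlike`` decoys carry a planted signal peptide (so the
    prefilter reaches the transmembrane / domain check) plus a matching
    evidence row: a 21-residue hydrophobic segment reported by the TM
    caller, or a domain-scanner hit.
    """
    if kind not in ("random", "tm", "domainlike"):
        raise SpecError(f"unknown decoy kind {kind!r}")
    letters, probs = _decoy_alphabet()
    records, truths, evidence_rows = [], [], []
    for k in range(n):
        rec_id = f"{id_prefix}_{kind}_{k:04d}"
        body_len = int(rng.integers(60, 201))
        body = "".join(rng.choice(letters, size=body_len, p=probs))
        if kind == "random":
            residues = body
            has_signal, signal_end = False, 0
        else:
            signal = make_signal(rng)
            if kind == "tm":
                tm_start = len(signal) + int(rng.integers(20, 40))
                body = (
                    body[: tm_start - len(signal)]
                    + _sample(rng, "LIVFA", 21)
                    + body[tm_start - len(signal):]
                )
                evidence_rows.append(
                    {"id": rec_id, "region_type": "TMhelix",
                     "start": tm_start + 1, "end": tm_start + 21}
                )
            else:
                evidence_rows.append(
                    {"id": rec_id, "accession": f"PF{10000 + k:05d}"}
                )
            residues = signal + body
            has_signal, signal_end = True, SIGNAL_END
        records.append(PrecursorRecord(id=rec_id, description=rec_id, residues=residues))
        truths.append(
            TruthProtein(
                id=rec_id, klass=f"decoy_{kind}",
                expression_class="non_neuronal" if k % 2 == 0 else "ubiquitous",
                has_signal=has_signal, signal_end=signal_end,
            )
        )
    columns = (
        ["id", "region_type", "start", "end"] if kind == "tm" else ["id", "accession"]
    )
    evidence = pd.DataFrame(evidence_rows, columns=columns if kind != "random" else ["id"])
    return records, truths, evidence


DEFAULT_NEURONAL_CLUSTERS = ("N1", "N2", "N3", "N4")
DEFAULT_NON_NEURONAL_CLUSTERS = ("EC1", "EC2", "GL1", "GL2")


def make_expression(
    genes: Sequence[str],
    truth: TruthManifest,
    rng: np.random.Generator,
    neuronal_clusters: Sequence[str] = DEFAULT_NEURONAL_CLUSTERS,
    non_neuronal_clusters: Sequence[str] = DEFAULT_NON_NEURONAL_CLUSTERS,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Gene-by-cluster mean-expression matrix matching each gene's truth class.

    Neuronal genes: mean 5 (drawn 2 + Poisson(3), so detection is
    guaranteed) in one or two neuronal clusters, Poisson(0.1) background
    elsewhere. Non-neuronal genes: mirrored, with mean 5 (3 + Poisson(2))
    in non-neuronal clusters. Ubiquitous genes: Poisson(3) everywhere.
    """
    clusters = list(neuronal_clusters) + list(non_neuronal_clusters)
    n_neu = len(neuronal_clusters)
    matrix = np.zeros((len(genes), len(clusters)))
    for g, gene in enumerate(genes):
        cls = truth.proteins[gene].expression_class
        row = rng.poisson(0.1, size=len(clusters)).astype(float)
        if cls == "neuronal":
            chosen = rng.choice(n_neu, size=int(rng.integers(1, 3)), replace=False)
            for c in chosen:
                row[c] = 2.0 + rng.poisson(3)
        elif cls == "non_neuronal":
            chosen = rng.choice(len(non_neuronal_clusters), size=int(rng.integers(1, 3)), replace=False)
            for c in chosen:
                row[n_neu + c] = 3.0 + rng.poisson(2)
        elif cls == "ubiquitous":
            row = rng.poisson(3, size=len(clusters)).astype(float)
        else:
            raise SpecError(f"unknown expression class {cls!r}")
        matrix[g] = row
    frame = pd.DataFrame(matrix, index=list(genes), columns=clusters)
    frame.index.name = "gene"
    annotation = {c: "neuronal" for c in neuronal_clusters}
    annotation.update({c: "non_neuronal" for c in non_neuronal_clusters})
    return frame, annotation


_NON_NP_DESCRIPTIONS = (
    "trypsin inhibitor", "actin cytoskeletal protein", "collagen alpha chain",
    "serine protease", "ribosomal protein L7", "heat shock protein 70",
)
_ALLOWED_DESCRIPTIONS = (
    "FMRFamide neuropeptide precursor", "uncharacterized protein",
    "hypothetical protein", "prohormone-4-like",
)


def make_hit_table(truth: TruthManifest, rng: np.random.Generator) -> EvidenceTable:
    """Alignment hits consistent with the truth classes.

    Precursors get no hit (60%) or a strong hit whose description carries
    an allow-listed keyword; decoys get strong hits against ordinary
    non-neuropeptide proteins (70%) or no hit.
    """
    rows = []
    for protein in truth.proteins.values():
        is_precursor = protein.klass == "precursor"
        u = rng.random()
        if is_precursor and u < 0.6:
            continue
        if not is_precursor and u < 0.3:
            continue
        desc_pool = _ALLOWED_DESCRIPTIONS if is_precursor else _NON_NP_DESCRIPTIONS
        desc = desc_pool[int(rng.integers(len(desc_pool)))]
        identity = float(rng.uniform(40, 85))
        evalue = float(10.0 ** -rng.uniform(10, 50))
        rows.append(
            {
                "query": protein.id, "subject": f"UR90_{int(rng.integers(1_000_000)):07d}",
                "pct_identity": round(identity, 1), "length": 80,
                "mismatches": 10, "gapopens": 1, "qstart": 1, "qend": 80,
                "sstart": 1, "send": 80, "e_value": evalue,
                "bitscore": round(200 - 2 * np.log(evalue + 1e-300), 1),
                "description": desc,
            }
        )
    table = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS + ["description"])
    return EvidenceTable("alignment_hits", table, set(table["query"]))


def _sample_core(rng: np.random.Generator, family: str, max_len: int = 16) -> tuple[str, bool]:
    tail, amidated = FAMILY_TEMPLATES[family]
    if amidated is None:
        amidated = bool(rng.integers(2))
    prefix_len = int(rng.integers(3, max(4, max_len - len(tail) - 1)))
    return _sample(rng, SAFE_RESIDUES, prefix_len) + tail, amidated


def _make_adversarial(core: str, dibasic: bool, rng: np.random.Generator) -> str:
    """Embed a monobasic K/R (no split expected) or a dibasic pair (splits)."""
    insert = ("K" if rng.integers(2) else "R") * (2 if dibasic else 1)
    m = max(1, min(len(core) - 1, len(core) // 2))
    # pad with safe residues so the insertion cannot touch a G or K/R neighbour
    return core[:m] + "T" + insert + "T" + core[m:]


def make_benchmark(
    n_precursors: int = 200,
    n_decoys: int = 600,
    adversarial_frac: float = 0.0,
    seed: int = 0,
) -> "Benchmark":
    """The standard planted-architecture benchmark.

    ``n_precursors`` synthetic precursors (families cycled through the
    template table, 1-5 peptide copies each, all neuronally expressed) plus
    ``n_decoys`` decoys split evenly between random, transmembrane and
    domain-bearing kinds. ``adversarial_frac`` of the precursors get
    adversarial cores; one third of those carry a genuine internal dibasic
    pair and are flagged unrecoverable in the manifest.
    """
    rng = np.random.default_rng(seed)
    families = list(FAMILY_TEMPLATES)
    records: list[PrecursorRecord] = []
    truth = TruthManifest()

    n_adversarial = int(round(adversarial_frac * n_precursors))
    for k in range(n_precursors):
        family = families[k % len(families)]
        core, amidated = _sample_core(rng, family)
        adversarial = k < n_adversarial
        dibasic_adv = adversarial and (k % 3 == 0)
        if adversarial:
            core = _make_adversarial(core, dibasic_adv, rng)
        motif = (
            ALL_MOTIFS[int(rng.integers(len(ALL_MOTIFS)))]
            if amidated
            else DIBASIC_MOTIFS[int(rng.integers(len(DIBASIC_MOTIFS)))]
        )
        spec = PrecursorSpec(
            peptide_core=core,
            n_copies=int(rng.integers(1, 6)),
            amidated=amidated,
            cleavage_motif=motif,
            spacer_len_range=(1, 2),
            signal=True,
            adversarial=adversarial,
        )
        record, protein = make_precursor(spec, rng, record_id=f"syn_prec_{k:04d}")
        if dibasic_adv:
            for pep in protein.peptides:
                pep.expected_recoverable = False
        records.append(record)
        truth.add(protein)

    per_kind = n_decoys // 3
    evidence_tables: list[EvidenceTable] = []
    for kind in ("random", "tm", "domainlike"):
        n_kind = per_kind if kind != "domainlike" else n_decoys - 2 * per_kind
        recs, truths, ev = make_decoys(kind, n_kind, rng, id_prefix="syn")
        records.extend(recs)
        for t in truths:
            truth.add(t)
        if kind == "tm":
            evidence_tables.append(
                EvidenceTable("tm_caller", ev.rename(columns={"region_type": "region"})
                              [["id", "start", "end"]], set(ev["id"]))
            )
        elif kind == "domainlike":
            evidence_tables.append(
                EvidenceTable("domain_scanner", ev, set(ev["id"]))
            )

    hit_table = make_hit_table(truth, rng)
    expression, cluster_annotation = make_expression(
        [r.id for r in records], truth, rng
    )
    return Benchmark(
        records=records,
        truth=truth,
        evidence_tables=evidence_tables,
        hit_table=hit_table,
        expression=expression,
        cluster_annotation=cluster_annotation,
        seed=seed,
    )


def make_two_family_set(
    n_per_family: int = 10,
    length: int = 60,
    mutation_rate: float = 0.3,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Two planted sequence families for clustering tests.

    Each family descends from its own random master sequence; members carry
    independent point mutations at ``mutation_rate`` of positions, so
    within-family identity is about 1 - mutation_rate (>= 60% at the
    default) while between-family identity is at the ~5-10% random
    background. Returns (sequences by id, true family label by id).
    """
    rng = np.random.default_rng(seed)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    sequences: dict[str, str] = {}
    labels: dict[str, str] = {}
    for fam in ("famA", "famB"):
        master = rng.choice(letters, size=length)
        for k in range(n_per_family):
            member = master.copy()
            for pos in np.nonzero(rng.random(length) < mutation_rate)[0]:
                member[pos] = letters[int(rng.integers(20))]
            name = f"{fam}_{k:02d}"
            sequences[name] = "".join(member)
            labels[name] = fam
    return sequences, labels


def evaluate_recovery(
    truth: TruthManifest,
    identified_ids: Sequence[str],
    peptide_frame: Optional[pd.DataFrame] = None,
) -> dict[str, float]:
    """Score a pipeline run against the manifest.

    ``precursor_precision`` / ``precursor_recall`` compare the identified id
    set with the planted precursors. ``peptide_boundary_recall`` (when a
    peptide table with parent_id/start/end columns is given) is the
    fraction of all planted peptides whose exact 1-based coordinates appear
    among the scanner's extracted peptides.
    """
    identified = set(identified_ids)
    planted = truth.precursor_ids
    tp = len(identified & planted)
    out = {
        "precursor_precision": tp / len(identified) if identified else float("nan"),
        "precursor_recall": tp / len(planted) if planted else float("nan"),
    }
    if peptide_frame is not None:
        found = {
            (str(r.parent_id), int(r.start), int(r.end))
            for r in peptide_frame.itertuples()
        }
        planted_peps = truth.all_peptides()
        hits = sum(
            1 for p in planted_peps if (p.parent_id, p.start, p.end) in found
        )
        out["peptide_boundary_recall"] = (
            hits / len(planted_peps) if planted_peps else float("nan")
        )
    return out


@dataclass
class Benchmark:
    """A generated benchmark: inputs for every pipeline stage plus truth."""

    records: list[PrecursorRecord]
    truth: TruthManifest
    evidence_tables: list[EvidenceTable]
    hit_table: EvidenceTable
    expression: pd.DataFrame
    cluster_annotation: dict[str, str]
    seed: int

    def write(self, out_dir) -> dict[str, Path]:
        """Emit every input file the CLI pipeline consumes, plus the truth."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "proteome.fasta",
            "tm": out / "tm_evidence.tsv",
            "domain": out / "domain_evidence.tsv",
            "hits": out / "alignment_hits.tsv",
            "expression": out / "expression_matrix.tsv",
            "clusters": out / "cluster_annotation.tsv",
            "truth": out / "truth.tsv",
        }
        write_fasta(self.records, paths["fasta"])
        for table in self.evidence_tables:
            if table.source == "tm_caller":
                with open(paths["tm"], "w") as fh:
                    for row in table.table.itertuples():
                        fh.write(f"{row.id}\tTMhelix\t{row.start}\t{row.end}\n")
            elif table.source == "domain_scanner":
                table.table.to_csv(paths["domain"], sep="\t", index=False, header=False)
        hits = self.hit_table.table
        hits.to_csv(paths["hits"], sep="\t", index=False, header=False)
        with open(paths["expression"], "w") as fh:
            self.expression.to_csv(fh, sep="\t")
        with open(paths["clusters"], "w") as fh:
            for name, cls in self.cluster_annotation.items():
                fh.write(f"{name}\t{cls}\n")
        self.truth.write(paths["truth"])
        return paths
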