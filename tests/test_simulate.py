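"""Closed-loop tests: what the generator plants, the pipeline stages find."""

import numpy as np
import pytest

import cnidapep as cp
from cnidapep.errors import SpecError
from cnidapep.expression import ExpressionConfig, filter_by_expression
from cnidapep.prefilter import PrefilterConfig, apply_prefilter
from cnidapep.scanner import scan_record
from cnidapep.simulate import (
    Benchmark,
    PrecursorSpec,
    TruthManifest,
    make_benchmark,
    make_decoys,
    make_expression,
    make_precursor,
    make_two_family_set,
    validate_core,
)
from conftest import NEURONAL, profiles_from_benchmark


def _scan_generated(record, truth_protein):
    record.evidence = cp.Evidence(
        has_signal=truth_protein.has_signal, signal_end=truth_protein.signal_end
    )
    return scan_record(record)


class TestMakePrecursor:
    def test_repeated_amidated_cores_recovered(self, rng):
        spec = PrecursorSpec(peptide_core="QFRF", n_copies=3, amidated=True)
        record, truth = make_precursor(spec, rng)
        result = _scan_generated(record, truth)
        matches = [p for p in result.peptides if p.mature == "QFRF"]
        assert len(matches) == 3
        assert all(p.amidated and p.pyroglu and p.counts_toward_pass for p in matches)
        # planted coordinates agree exactly
        assert {(p.start, p.end) for p in matches} == {
            (t.start, t.end) for t in truth.peptides
        }

    def test_non_amidated_lw_cores_recovered(self, rng):
        spec = PrecursorSpec(peptide_core="EPEPPETGLW", n_copies=2, amidated=False)
        record, truth = make_precursor(spec, rng)
        result = _scan_generated(record, truth)
        matches = [p for p in result.peptides if p.mature == "EPEPPETGLW"]
        assert len(matches) == 2
        assert all(not p.amidated and p.family == "LW_peptide" for p in matches)

    def test_no_donor_anywhere_means_no_amidated_peptides(self, rng):
        spec = PrecursorSpec(peptide_core="DPNAHTLW", n_copies=4, amidated=False)
        record, truth = make_precursor(spec, rng)
        result = _scan_generated(record, truth)
        assert all(not p.amidated for p in result.peptides)

    def test_signalless_precursor_dropped_by_prefilter(self, rng):
        spec = PrecursorSpec(peptide_core="QFRF", amidated=True, signal=False)
        record, truth = make_precursor(spec, rng)
        assert truth.has_signal is False
        kept, report = apply_prefilter([record], [], PrefilterConfig())
        assert kept == []
        assert report.loc[0, "reason"] == "no_signal"

    def test_gk_motif_without_amidation_rejected(self):
        with pytest.raises(SpecError):
            PrecursorSpec(peptide_core="ADEN", amidated=False, cleavage_motif="GK")

    @pytest.mark.parametrize(
        "core",
        ["", "KADE", "ADKKDE", "ADGKDE", "ADENR", "ADENG", "A" * 30],
    )
    def test_ambiguous_cores_rejected(self, core):
        with pytest.raises(SpecError):
            validate_core(core, amidated=False)

    def test_terminal_basic_allowed_when_amidated(self):
        validate_core("ANFR", amidated=True)  # donor G separates it from the site

    def test_generation_deterministic(self):
        spec = PrecursorSpec(peptide_core="QFRF", n_copies=2, amidated=True)
        r1, _ = make_precursor(spec, np.random.default_rng(3))
        r2, _ = make_precursor(spec, np.random.default_rng(3))
        assert r1.residues == r2.residues


class TestMakeDecoys:
    def test_tm_decoys_dropped_with_tm_reason(self, rng):
        records, truths, ev = make_decoys("tm", 30, rng)
        import pandas as pd

        table = cp.EvidenceTable(
            "tm_caller", ev[["id", "start", "end"]], set(ev["id"])
        )
        kept, report = apply_prefilter(records, [table], PrefilterConfig())
        assert kept == []
        assert (report["reason"] == "tm").all()

    def test_domainlike_decoys_dropped_with_domain_reason(self, rng):
        records, truths, ev = make_decoys("domainlike", 30, rng)
        table = cp.EvidenceTable("domain_scanner", ev, set(ev["id"]))
        kept, report = apply_prefilter(records, [table], PrefilterConfig())
        assert kept == []
        assert (report["reason"] == "domain").all()

    def test_kr_free_random_decoy_has_no_sites(self, rng):
        # force a K/R-free sequence by stripping; zero sites expected
        records, _, _ = make_decoys("random", 5, rng)
        for record in records:
            stripped = record.residues.replace("K", "A").replace("R", "A")
            assert cp.find_cleavage_sites(stripped) == []

    def test_random_decoys_suppress_basic_residues(self, rng):
        records, _, _ = make_decoys("random", 50, rng)
        pooled = "".join(r.residues for r in records)
        freq = (pooled.count("K") + pooled.count("R")) / len(pooled)
        assert freq < 0.04


class TestMakeExpression:
    def _profiles(self, classes, seed=0):
        truth = TruthManifest()
        genes = []
        for k, cls in enumerate(classes):
            gid = f"g{k}"
            genes.append(gid)
            truth.add(
                cp.TruthProtein(
                    id=gid, klass="precursor", expression_class=cls,
                    has_signal=True, signal_end=13,
                )
            )
        matrix, annotation = make_expression(genes, truth, np.random.default_rng(seed))
        neuronal = {c for c, v in annotation.items() if v == "neuronal"}
        profiles = [
            cp.ExpressionProfile(str(g), {c: float(v) for c, v in row.items()}, set(neuronal))
            for g, row in matrix.iterrows()
        ]
        return genes, profiles

    def test_neuronal_genes_pass_defaults(self):
        genes, profiles = self._profiles(["neuronal"] * 20)
        kept, _ = filter_by_expression(genes, profiles, ExpressionConfig())
        assert kept == genes

    def test_non_neuronal_genes_fail_with_reason(self):
        genes, profiles = self._profiles(["non_neuronal"] * 20)
        kept, report = filter_by_expression(genes, profiles, ExpressionConfig())
        assert kept == []
        assert set(report["reason"]) <= {"not_neuronal", "low_share"}

    def test_ubiquitous_gene_kept_at_default_share(self):
        genes, profiles = self._profiles(["ubiquitous"] * 10, seed=2)
        kept, report = filter_by_expression(genes, profiles, ExpressionConfig())
        # broad expression: neuronal share is ~1 within noise for most genes
        assert len(kept) >= 8


class TestBenchmark:
    def test_deterministic_given_seed(self):
        b1 = make_benchmark(n_precursors=10, n_decoys=9, seed=5)
        b2 = make_benchmark(n_precursors=10, n_decoys=9, seed=5)
        assert [r.residues for r in b1.records] == [r.residues for r in b2.records]
        assert b1.expression.equals(b2.expression)
        assert b1.hit_table.table.equals(b2.hit_table.table)

    def test_truth_manifest_roundtrip(self, tmp_path, small_benchmark):
        path = tmp_path / "truth.tsv"
        small_benchmark.truth.write(path)
        again = TruthManifest.read(path)
        assert again.precursor_ids == small_benchmark.truth.precursor_ids
        original = {
            (p.parent_id, p.start, p.end, p.mature, p.amidated, p.family)
            for p in small_benchmark.truth.all_peptides()
        }
        restored = {
            (p.parent_id, p.start, p.end, p.mature, p.amidated, p.family)
            for p in again.all_peptides()
        }
        assert restored == original

    def test_manifest_coordinates_match_fasta(self, small_benchmark):
        by_id = {r.id: r for r in small_benchmark.records}
        for pep in small_benchmark.truth.all_peptides():
            residues = by_id[pep.parent_id].residues
            assert residues[pep.start - 1:pep.end] == pep.mature

    def test_two_family_set_identity_structure(self):
        seqs, labels = make_two_family_set(n_per_family=6, length=60, seed=8)

        def identity(a, b):
            return sum(x == y for x, y in zip(a, b)) / len(a)

        ids = list(seqs)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                pid = identity(seqs[a], seqs[b])
                if labels[a] == labels[b]:
                    assert pid >= 0.4  # ~(1-mu)^2 + background for sibling pairs
                else:
                    assert pid < 0.25
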