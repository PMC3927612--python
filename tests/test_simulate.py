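"""Tests of the multidomain-evolution simulator."""

import io
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from Bio import SeqIO

from paranet import simulate as sim
from tests.conftest import rich_config


def test_rates_zero_yields_unrelated_single_domain_proteins():
    cfg = sim.EvolutionConfig(n_ancestral_families=3, n_species=1, seed=5)
    result = sim.generate_proteome(cfg)
    assert len(result.proteins) == 3
    assert all(len(p.architecture) == 1 for p in result.proteins)
    assert all(l.relation == sim.UNRELATED for l in result.labels)
    assert result.log == []


def test_zero_families_or_species_rejected():
    with pytest.raises(sim.ConfigurationError):
        sim.generate_proteome(sim.EvolutionConfig(n_ancestral_families=0))
    with pytest.raises(sim.ConfigurationError):
        sim.generate_proteome(sim.EvolutionConfig(n_species=0))


def test_internal_shuffle_preset_architectures_and_labels(confusion_result):
    arch = {p.protein_id: [f for f, _ in p.architecture] for p in confusion_result.proteins}
    assert arch["A1*"] == ["a", "s", "s", "s", "s", "b"]
    assert arch["A2*"] == ["a", "b"]
    assert arch["X2*"] == ["x", "s", "s", "s", "s", "z"]
    labels = {
        frozenset((l.protein_id_a, l.protein_id_b)): l.relation
        for l in confusion_result.labels
    }
    assert labels[frozenset(("A1*", "A2*"))] == sim.PARALOG
    assert labels[frozenset(("X1*", "X2*"))] == sim.PARALOG
    assert labels[frozenset(("A1*", "X2*"))] == sim.EPAKTOLOG
    assert labels[frozenset(("A2*", "X2*"))] == sim.UNRELATED


def test_terminal_shuffle_preset_puts_shared_domains_terminally():
    result = sim.generate_proteome(sim.shuffle_terminal_config(2))
    arch = {p.protein_id: [f for f, _ in p.architecture] for p in result.proteins}
    assert arch["A1*"] == ["s", "s", "s", "s", "a", "b"]
    assert arch["X2*"] == ["x", "z", "s", "s", "s", "s"]


def test_same_seed_reproduces_byte_identical_output():
    cfg = rich_config(seed=11)
    r1 = sim.generate_proteome(cfg)
    r2 = sim.generate_proteome(cfg)
    assert [p.sequence for p in r1.proteins] == [p.sequence for p in r2.proteins]
    assert r1.log == r2.log
    assert r1.labels == r2.labels
    r3 = sim.generate_proteome(rich_config(seed=12))
    assert [p.sequence for p in r3.proteins] != [p.sequence for p in r1.proteins]


@pytest.mark.parametrize("seed", [3, 4, 5])
def test_replaying_event_log_reproduces_proteome(seed):
    cfg = rich_config(seed=seed)
    result = sim.generate_proteome(cfg)
    assert result.log  # the rates are high enough to produce events
    replayed = sim.replay_log(cfg, result.log)
    assert len(replayed) == len(result.proteins)
    for a, b in zip(replayed, result.proteins):
        assert a.protein_id == b.protein_id
        assert a.architecture == b.architecture
        assert a.sequence == b.sequence


def test_log_round_trips_through_json(confusion_result):
    text = sim.log_to_json(confusion_result.log)
    assert sim.log_from_json(text) == confusion_result.log


def test_every_logged_event_kind_is_configured(rich_result):
    kinds = {e.kind for e in rich_result.log}
    assert kinds <= set(sim.EVENT_KINDS)


def test_labels_symmetric_and_mutually_exclusive(rich_result):
    proteins = rich_result.proteins
    seen = Counter()
    for i, a in enumerate(proteins):
        for b in proteins[i + 1 :]:
            rel_ab = sim.pair_relation(a, b)
            rel_ba = sim.pair_relation(b, a)
            assert rel_ab == rel_ba
            seen[frozenset((a.protein_id, b.protein_id))] += 1
    assert all(v == 1 for v in seen.values())
    n = len(proteins)
    assert len(rich_result.labels) == n * (n - 1) // 2


def test_orthologs_share_lineage_across_species(rich_result):
    by_id = {p.protein_id: p for p in rich_result.proteins}
    for label in rich_result.labels:
        a, b = by_id[label.protein_id_a], by_id[label.protein_id_b]
        if label.relation == sim.ORTHOLOG:
            assert a.lineage_id == b.lineage_id
            assert a.species_id != b.species_id
        if label.relation == sim.EPAKTOLOG:
            assert a.root_gene_id != b.root_gene_id
            shared = set(a.shuffled_families) & set(b.shuffled_families)
            assert shared


# -- sequence emission -------------------------------------------------


def _flat_config(linker: int) -> sim.EvolutionConfig:
    return sim.EvolutionConfig(
        family_plan=(("a", 50, False), ("b", 50, False)),
        ancestral_architectures=(("a", "b"),),
        substitution_rate=0.0,
        linker_length_aa=linker,
        seed=0,
    )


def test_fasta_length_is_domains_plus_linker():
    result = sim.generate_proteome(_flat_config(linker=10))
    records = list(SeqIO.parse(io.StringIO(sim.emit_sequences(result.proteins)), "fasta"))
    assert len(records) == 1
    assert len(records[0].seq) == 110


def test_fasta_length_without_linker():
    result = sim.generate_proteome(_flat_config(linker=0))
    records = list(SeqIO.parse(io.StringIO(sim.emit_sequences(result.proteins)), "fasta"))
    assert len(records[0].seq) == 100


def test_fasta_round_trip_ids_and_lengths(rich_result):
    text = sim.emit_sequences(rich_result.proteins)
    records = {r.id: len(r.seq) for r in SeqIO.parse(io.StringIO(text), "fasta")}
    assert records == {
        p.protein_id: len(p.sequence) for p in rich_result.proteins
    }


# -- annotations -------------------------------------------------------


def test_undiverged_instance_gets_tiny_evalue():
    result = sim.generate_proteome(_flat_config(linker=10))
    ann = sim.emit_domain_annotations(result.proteins, result.families)
    assert (ann["evalue"] <= 1e-10).all()


def test_annotation_rows_ordered_and_non_overlapping():
    result = sim.generate_proteome(_flat_config(linker=10))
    ann = sim.emit_domain_annotations(result.proteins, result.families)
    assert len(ann) == 2
    assert ann.iloc[0]["start"] == 1 and ann.iloc[0]["end"] == 50
    assert ann.iloc[1]["start"] == 61 and ann.iloc[1]["end"] == 110
    assert ann.iloc[0]["end"] < ann.iloc[1]["start"]


def test_identity_below_detection_floor_is_omitted():
    model = sim.EvalueModel(detection_floor_pct=35.0)
    assert model(30.0) is None
    assert model(35.0) is not None
    assert model(90.0) < model(60.0)  # monotone decreasing in identity


def test_heavily_diverged_instances_can_fail_the_homology_cutoff():
    model = sim.EvalueModel()
    weak = model(40.0)
    assert weak is not None and weak > 1e-5


# -- pairwise scorer ---------------------------------------------------


def test_identical_proteins_give_maximal_score(confusion_hits):
    for query, group in confusion_hits.groupby("qseqid"):
        top = group.sort_values("bitscore", ascending=False).iloc[0]
        assert top["sseqid"] == query


def test_disjoint_family_sets_produce_no_row(confusion_hits):
    pair = confusion_hits[
        (confusion_hits["qseqid"] == "A2*") & (confusion_hits["sseqid"] == "X2*")
    ]
    assert pair.empty


def test_scores_symmetric(rich_hits):
    merged = rich_hits.merge(
        rich_hits,
        left_on=["qseqid", "sseqid"],
        right_on=["sseqid", "qseqid"],
        suffixes=("", "_rev"),
    )
    assert len(merged) == len(rich_hits)
    assert (merged["bitscore"] == merged["bitscore_rev"]).all()


def test_tandem_arrays_inflate_epaktolog_scores():
    """More tandem copies of the shared mobile domain -> higher pair score."""
    scores = []
    for n_tandem in range(4):  # 1..4 shared s copies
        result = sim.generate_proteome(sim.shuffle_internal_config(9, n_tandem=n_tandem))
        hits = sim.score_all_pairs(result.proteins)
        row = hits[(hits["qseqid"] == "A1*") & (hits["sseqid"] == "X2*")]
        scores.append(float(row["bitscore"].iloc[0]))
    assert scores == sorted(scores)
    assert all(b > a for a, b in zip(scores, scores[1:]))


def test_scorer_requires_two_proteins(confusion_result):
    with pytest.raises(ValueError):
        sim.score_all_pairs(confusion_result.proteins[:1])
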