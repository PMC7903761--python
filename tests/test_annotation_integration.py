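"""Annotation clustering, anchor selection, and variant sequences."""

from __future__ import annotations

import itertools
import random

import pytest

from metaptgx import digest_classify as dc
from metaptgx.annotation_integration import (
    AnnotationCluster,
    cluster_gene_models,
    format_entry_id,
    integrate,
    load_annotation_source,
    parse_entry_id,
    select_anchor,
    variant_sequence,
)
from metaptgx.genome_orf import GenomeError, Replicon, reverse_complement

from conftest import make_cluster_models, random_protein


def toy_genome_with_genes():
    """A small genome with three hand-placed genes (two +, one -)."""
    #           0         1         2         3
    #           0123456789012345678901234567890123456789
    g1 = "ATGAAACGTTAA"  # + strand @ 10, protein MKR
    g2 = "ATGGATGACTGCTAA"  # + strand, protein MDDC
    g3 = "ATGTGTCATTAA"  # on - strand, protein MCH
    spacer = "TTATTATTAT"
    seq = spacer + g1 + spacer + g2 + spacer + reverse_complement(g3) + spacer
    rep = Replicon("chr1", "spX", seq)
    feats = [
        ("chr1", 10, 10 + len(g1), "+", "g1", "MKR"),
        ("chr1", 10 + len(g1) + 10, 10 + len(g1) + 10 + len(g2), "+", "g2", "MDDC"),
        (
            "chr1",
            10 + len(g1) + 10 + len(g2) + 10,
            10 + len(g1) + 10 + len(g2) + 10 + len(g3),
            "-",
            "g3",
            "MCH",
        ),
    ]
    return rep, feats


def write_gff(path, feats, pseudo_ids=(), include_stop=True):
    lines = ["##gff-version 3"]
    for rep, start, stop_end, strand, locus, _prot in feats:
        s, end = start, stop_end
        if not include_stop:  # the stop codon sits at the 3' end of the CDS
            if strand == "+":
                end -= 3
            else:
                s += 3
        attrs = f"ID={locus};locus_tag={locus}"
        if locus in pseudo_ids:
            attrs += ";pseudo=true"
        lines.append(
            "\t".join(
                [rep, "test", "CDS", str(s + 1), str(end), ".", strand, "0", attrs]
            )
        )
    path.write_text("\n".join(lines) + "\n")


class TestLoadAnnotationSource:
    def test_toy_genes_translate_correctly(self, tmp_path):
        rep, feats = toy_genome_with_genes()
        gff = tmp_path / "a.gff3"
        write_gff(gff, feats)
        models = load_annotation_source(gff, [rep], "refseq")
        assert {m.locus_id: m.protein for m in models} == {
            "g1": "MKR",
            "g2": "MDDC",
            "g3": "MCH",
        }

    def test_pseudogene_excluded_and_counted(self, tmp_path):
        rep, feats = toy_genome_with_genes()
        gff = tmp_path / "a.gff3"
        write_gff(gff, feats, pseudo_ids={"g2"})
        counters = {}
        models = load_annotation_source(gff, [rep], "refseq", counters=counters)
        assert {m.locus_id for m in models} == {"g1", "g3"}
        assert counters["pseudo_skipped"] == 1

    def test_stop_codon_appended_when_dialect_excludes_it(self, tmp_path):
        rep, feats = toy_genome_with_genes()
        gff = tmp_path / "a.gff3"
        write_gff(gff, feats, include_stop=False)
        models = load_annotation_source(gff, [rep], "refseq", cds_includes_stop=False)
        by_id = {m.locus_id: m for m in models}
        for _rep, start, stop_end, strand, locus, prot in feats:
            assert by_id[locus].start == start
            assert by_id[locus].stop_end == stop_end
            assert by_id[locus].protein == prot

    def test_unknown_replicon_rejected(self, tmp_path):
        rep, feats = toy_genome_with_genes()
        gff = tmp_path / "a.gff3"
        feats = [("chrZ", *f[1:]) for f in feats]
        write_gff(gff, feats)
        with pytest.raises(GenomeError, match="unknown replicon"):
            load_annotation_source(gff, [rep], "refseq")


class TestClustering:
    def test_shared_stop_one_cluster(self):
        rng = random.Random(0)
        models = make_cluster_models(rng, 30, n_extensions=2)
        clusters = cluster_gene_models(models)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 3

    def test_opposite_strands_distinct_clusters(self):
        rng = random.Random(0)
        a = make_cluster_models(rng, 30, strand="+", stop_end=600, tag="a")
        b = make_cluster_models(rng, 30, strand="-", stop_end=600, tag="b")
        assert len(cluster_gene_models(a + b)) == 2

    def test_groupby_oracle_on_random_models(self):
        rng = random.Random(4)
        models = []
        for i in range(50):
            models.extend(
                make_cluster_models(
                    rng,
                    rng.randint(20, 60),
                    n_extensions=rng.randint(0, 2),
                    strand=rng.choice("+-"),
                    stop_end=300 * (i % 17 + 1),
                    tag=f"t{i}",
                )
            )
        clusters = cluster_gene_models(models)
        oracle = {m.cluster_key for m in models}
        assert len(clusters) == len(oracle)
        assert sum(len(c.members) for c in clusters) == len(models)


class TestAnchorSelection:
    def test_hierarchy_semantics(self):
        rng = random.Random(1)
        models = make_cluster_models(
            rng, 40, n_extensions=1, source="prodigal", variant_source="insilico"
        )
        (cluster,) = cluster_gene_models(models)
        select_anchor(cluster, ["refseq", "prodigal", "insilico"])
        assert cluster.anchor.source == "prodigal"

    def test_same_source_tie_breaks_to_longest(self):
        rng = random.Random(2)
        models = make_cluster_models(
            rng, 60, n_extensions=1, source="insilico", variant_source="insilico"
        )
        (cluster,) = cluster_gene_models(models)
        select_anchor(cluster, ["insilico"])
        assert len(cluster.anchor.protein) == max(len(m.protein) for m in cluster.members)

    def test_anchor_invariant_under_member_order(self):
        rng = random.Random(3)
        models = make_cluster_models(
            rng, 40, n_extensions=2, n_reductions=1, source="refseq"
        )
        anchors = set()
        order = list(models)
        for i in range(100):
            random.Random(i).shuffle(order)
            (cluster,) = cluster_gene_models(order)
            select_anchor(cluster, ["refseq", "prodigal"])
            anchors.add(cluster.anchor.locus_id)
        assert len(anchors) == 1

    def test_identical_start_becomes_provenance_not_variant(self):
        rng = random.Random(5)
        models = make_cluster_models(rng, 30, source="refseq")
        dup = make_cluster_models(rng, 30, source="prodigal", tag="d")[0]
        dup.protein = models[0].protein
        dup.start, dup.stop_end = models[0].start, models[0].stop_end
        (cluster,) = cluster_gene_models(models + [dup])
        select_anchor(cluster, ["refseq", "prodigal"])
        assert cluster.variants == []
        assert len(cluster.anchor_provenance) == 1


def distinguishing_prefix_oracle(anchor: str, variant: str, protease: str, mc: int) -> str:
    """Shortest variant prefix ending at a cleavage boundary (or the full
    proteoform) whose digest contains every peptide that distinguishes the
    variant from the anchor at <= mc missed cleavages."""
    def peps(p: str) -> set:
        return {x for x, _s, _m in dc.digest(p, protease, mc, min_len=1, max_len=10**6)}

    distinguishing = peps(variant) - peps(anchor)
    cuts = dc.cleavage_positions(variant, protease) + [len(variant)]
    for c in cuts:
        prefix = variant[:c]
        if distinguishing <= peps(prefix):
            return prefix
    return variant


def build_cluster(anchor: str, variant: str) -> tuple[AnnotationCluster, object]:
    models = []
    stop_end = 3 * (len(variant) + 1) + 30
    for prot, src, locus in ((anchor, "refseq", "a"), (variant, "prodigal", "v")):
        span = 3 * (len(prot) + 1)
        from metaptgx.annotation_integration import GeneModel

        models.append(
            GeneModel(
                source=src,
                locus_id=locus,
                replicon="chr",
                strand="+",
                start=stop_end - span,
                stop_end=stop_end,
                protein=prot,
            )
        )
    (cluster,) = cluster_gene_models(models)
    select_anchor(cluster, ["refseq", "prodigal"])
    return cluster, models[1]


class TestVariantSequence:
    def test_extension_stops_at_first_boundary_after_divergence(self):
        anchor = "MKAAARDDDKWWW"
        variant = "MSTR" + anchor
        cluster, vm = build_cluster(anchor, variant)
        expected0 = distinguishing_prefix_oracle(anchor, variant, "trypsin", 0)
        assert variant_sequence(cluster, vm, "trypsin", 0) == expected0 == "MSTR"
        expected1 = distinguishing_prefix_oracle(anchor, variant, "trypsin", 1)
        assert variant_sequence(cluster, vm, "trypsin", 1) == expected1 == "MSTRMK"

    def test_no_cleavage_site_returns_full_proteoform(self):
        # 36-aa variant without any Asp: no Asp-N site at all
        anchor = "MAAAAAGGGGGCCCCCHHHHH"
        variant = "MSSSSSGGGGGAAAAA" + anchor[1:]
        assert "D" not in variant
        cluster, vm = build_cluster(anchor, variant)
        assert variant_sequence(cluster, vm, "aspn", 1) == variant

    def test_reduction_prefix_covers_new_nterm(self):
        anchor = "MKAAARDDDKWWWKLLL"
        variant = "M" + anchor[6:]  # starts inside the anchor
        cluster, vm = build_cluster(anchor, variant)
        seq = variant_sequence(cluster, vm, "trypsin", 0)
        assert variant.startswith(seq)
        # the reduction's distinguishing N-terminal peptide is in the prefix
        oracle = distinguishing_prefix_oracle(anchor, variant, "trypsin", 0)
        assert seq == oracle

    @pytest.mark.parametrize("protease", ["trypsin", "aspn"])
    def test_oracle_equivalence_random_variants(self, protease):
        rng = random.Random(17)
        for mc in (0, 1, 2):
            for _ in range(30):
                anchor = "M" + random_protein(rng, rng.randint(15, 60))
                if rng.random() < 0.5:
                    variant = "M" + random_protein(rng, rng.randint(2, 12)) + anchor
                else:
                    cut = rng.randint(2, len(anchor) - 8)
                    variant = "M" + anchor[cut:]
                cluster, vm = build_cluster(anchor, variant)
                got = variant_sequence(cluster, vm, protease, mc)
                assert got == distinguishing_prefix_oracle(anchor, variant, protease, mc)


class TestIntegrate:
    def test_anchor_only_cluster_single_entry(self):
        rng = random.Random(8)
        clusters = cluster_gene_models(make_cluster_models(rng, 40))
        entries = integrate(clusters, ["refseq", "prodigal"], "trypsin")
        assert len(entries) == 1
        assert entries[0].role == "anchor"

    def test_two_extensions_give_three_entries(self):
        rng = random.Random(9)
        clusters = cluster_gene_models(make_cluster_models(rng, 40, n_extensions=2))
        entries = integrate(clusters, ["refseq", "prodigal"], "trypsin")
        assert len(entries) == 3
        assert sorted(e.role for e in entries) == ["anchor", "extension", "extension"]

    def test_idempotence_on_anchor_entries(self):
        rng = random.Random(10)
        models = []
        for i in range(10):
            models.extend(
                make_cluster_models(
                    rng, rng.randint(20, 50), n_extensions=1, stop_end=400 * (i + 1), tag=f"i{i}"
                )
            )
        clusters = cluster_gene_models(models)
        entries = integrate(clusters, ["refseq", "prodigal"], "trypsin")
        anchors = [e for e in entries if e.role == "anchor"]
        from metaptgx.annotation_integration import GeneModel

        remodel = [
            GeneModel(
                source="refseq",
                locus_id=e.entry_id,
                replicon=e.cluster_key[0],
                strand=e.cluster_key[1],
                start=(e.cluster_key[2] + 1) - 3 * (len(e.sequence) + 1),
                stop_end=e.cluster_key[2] + 1,
                protein=e.sequence,
            )
            for e in anchors
        ]
        entries2 = integrate(
            cluster_gene_models(remodel), ["refseq"], "trypsin"
        )
        assert sorted(e.sequence for e in entries2) == sorted(
            e.sequence for e in anchors
        )

    def test_partition_invariant(self):
        rng = random.Random(12)
        models = []
        for i in range(20):
            models.extend(
                make_cluster_models(
                    rng,
                    rng.randint(20, 50),
                    n_extensions=rng.randint(0, 2),
                    n_reductions=rng.randint(0, 1),
                    stop_end=500 * (i + 1),
                    tag=f"p{i}",
                )
            )
        clusters = cluster_gene_models(models)
        assert sum(len(c.members) for c in clusters) == len(models)


class TestHeaderCodec:
    @pytest.mark.parametrize(
        "species,key,source,role,vstart",
        [
            ("sp1", ("chr1", "+", 1234), "refseq", "anchor", None),
            ("sp2", ("plasmid_2", "-", 7), "insilico", "extension", 99),
        ],
    )
    def test_round_trip(self, species, key, source, role, vstart):
        eid = format_entry_id(species, key, source, role, vstart)
        meta = parse_entry_id(eid)
        assert meta["species"] == species
        assert meta["cluster_key"] == key
        assert meta["source"] == source
        assert meta["role"] == role
        assert meta["variant_start"] == vstart
        assert not meta["is_decoy"]
        decoy = parse_entry_id("DECOY_" + eid)
        assert decoy["is_decoy"]
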