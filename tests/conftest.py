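"""Shared fixtures: a small synthetic two-species community, its
protease-specific search databases, and peptide indexes."""

from __future__ import annotations

import random

import pytest

from metaptgx import db_builder as dbb
from metaptgx import digest_classify as dc
from metaptgx import synthetic_fixtures as sf
from metaptgx.annotation_integration import GeneModel


@pytest.fixture(scope="session")
def community(tmp_path_factory):
    out = tmp_path_factory.mktemp("community")
    return sf.generate_community(
        n_species=2,
        n_genes=20,
        n_hidden_sorfs=3,
        n_start_variants=2,
        seed=1,
        out_dir=out,
    )


@pytest.fixture(scope="session")
def community_dbs(community, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("dbs")
    dbs = {}
    for protease in ("trypsin", "aspn"):
        species_dbs = [
            sf.build_truth_db(st, protease, tmp) for st in community.species
        ]
        dbs[protease] = dbb.add_decoys(dbb.concatenate_dbs(species_dbs))
    return dbs


@pytest.fixture(scope="session")
def community_indexes(community_dbs):
    return {p: dc.build_peptide_index(db) for p, db in community_dbs.items()}


def random_protein(rng: random.Random, n: int, alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def make_cluster_models(
    rng: random.Random,
    anchor_len: int,
    n_extensions: int = 0,
    n_reductions: int = 0,
    replicon: str = "chr",
    strand: str = "+",
    stop_end: int | None = None,
    source: str = "refseq",
    variant_source: str = "prodigal",
    tag: str = "c",
) -> list[GeneModel]:
    """Construct one annotation cluster's gene models in memory.

    Extensions prepend M + random residues to the anchor protein;
    reductions start at an internal residue (initiator read as Met).
    Coordinates are synthesized to be frame-consistent with a shared stop.
    """
    anchor_protein = "M" + random_protein(rng, anchor_len - 1)
    if stop_end is None:
        stop_end = 3 * (anchor_len + 1) + 300
    models = []

    def interval(protein: str):
        span = 3 * (len(protein) + 1)
        if strand == "+":
            return stop_end - span, stop_end  # shared stop at high side
        return stop_end, stop_end + span  # minus strand: stop at low side

    def add(protein: str, src: str, locus: str):
        start, end = interval(protein)
        models.append(
            GeneModel(
                source=src,
                locus_id=locus,
                replicon=replicon,
                strand=strand,
                start=start,
                stop_end=end,
                protein=protein,
            )
        )

    add(anchor_protein, source, f"{tag}_anchor")
    for i in range(n_extensions):
        ext = "M" + random_protein(rng, rng.randint(3, 10))
        add(ext + anchor_protein, variant_source, f"{tag}_ext{i}")
    for i in range(n_reductions):
        cut = rng.randint(2, max(2, anchor_len - 10))
        add("M" + anchor_protein[cut + 1 :], variant_source, f"{tag}_red{i}")
    return models
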