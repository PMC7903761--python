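"""Assembly of per-species and concatenated multi-species search databases.

A species database is the composed pipeline: load ranked annotation sources
(generating the in silico six-frame source on the fly when requested),
collapse into stop-codon clusters, select anchors, and emit the minimally
redundant entry list for one protease.  Species databases are concatenated
into one community database; reverse or shuffled decoys are appended for
target-decoy FDR estimation.  Composition statistics and theoretical
class-1a identifiability are computed on the result.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from . import annotation_integration as ai
from . import digest_classify as dc
from . import genome_orf as go

DECOY_PREFIX = "DECOY_"
SPROTEIN_MAX_LEN = 100


@dataclass
class SearchDb:
    """A protease-specific protein search database."""

    entries: list[ai.DbEntry]
    protease: str
    species: set[str] = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    @property
    def has_decoys(self) -> bool:
        return any(e.is_decoy for e in self.entries)

    @property
    def targets(self) -> list[ai.DbEntry]:
        return [e for e in self.entries if not e.is_decoy]

    def entry(self, entry_id: str) -> ai.DbEntry:
        return self._by_id()[entry_id]

    def _by_id(self) -> dict[str, ai.DbEntry]:
        if not hasattr(self, "_id_cache") or len(self._id_cache) != len(self.entries):
            self._id_cache = {e.entry_id: e for e in self.entries}
        return self._id_cache


def build_species_db(
    genomes: list[go.Replicon],
    sources: list[tuple[str, str]],
    hierarchy: list[str],
    protease: str,
    min_len: int = go.DEFAULT_MIN_LEN,
    extra_cleavage_sites: int = 1,
    emit_reductions: bool = True,
    keep_pseudo: bool = False,
    cds_includes_stop: bool = True,
    counters: dict | None = None,
) -> SearchDb:
    """Build one species' database from its genome and annotation sources.

    ``sources`` is a list of (source_name, gff_path).  The in silico
    six-frame source is generated from the genome whenever ``"insilico"``
    appears in the hierarchy.  Output is deterministic for fixed inputs:
    clusters are emitted in genomic order regardless of source file order.
    """
    if not sources and "insilico" not in hierarchy:
        raise ValueError("at least one annotation source is required")
    species = genomes[0].species
    models: list[ai.GeneModel] = []
    for name, path in sources:
        models.extend(
            ai.load_annotation_source(
                path,
                genomes,
                name,
                cds_includes_stop=cds_includes_stop,
                keep_pseudo=keep_pseudo,
                counters=counters,
            )
        )
    if "insilico" in hierarchy:
        for rep in genomes:
            models.extend(
                ai.orfs_as_gene_models(go.six_frame_orfs(rep, min_len=min_len))
            )
    clusters = ai.cluster_gene_models(models)
    for cl in clusters:
        ai.select_anchor(cl, hierarchy)
    entries = ai.integrate(
        clusters,
        hierarchy,
        protease,
        extra_cleavage_sites=extra_cleavage_sites,
        species=species,
        emit_reductions=emit_reductions,
    )
    return SearchDb(
        entries=entries,
        protease=protease,
        species={species},
        provenance={
            "hierarchy": list(hierarchy),
            "min_len": min_len,
            "extra_cleavage_sites": extra_cleavage_sites,
            "reference_source": hierarchy[0],
        },
    )


def concatenate_dbs(dbs: list[SearchDb]) -> SearchDb:
    """Concatenate species databases into one community database."""
    if not dbs:
        raise ValueError("nothing to concatenate")
    protease = dbs[0].protease
    species: set[str] = set()
    entries: list[ai.DbEntry] = []
    for db in dbs:
        if db.protease != protease:
            raise ValueError(
                f"protease mismatch: {db.protease!r} vs {protease!r}"
            )
        if db.species & species:
            raise ValueError(f"species collision: {sorted(db.species & species)}")
        species |= db.species
        entries.extend(db.entries)
    provenance = dict(dbs[0].provenance)
    provenance["concatenated"] = sorted(species)
    return SearchDb(entries=entries, protease=protease, species=species, provenance=provenance)


def add_decoys(db: SearchDb, mode: str = "reverse", seed: int = 0) -> SearchDb:
    """Append one decoy per target entry (DECOY_-prefixed, same length)."""
    if db.has_decoys:
        raise ValueError("database already contains decoys")
    rng = random.Random(seed)
    decoys: list[ai.DbEntry] = []
    for e in db.entries:
        if mode == "reverse":
            seq = e.sequence[::-1]
        elif mode == "shuffle-seeded":
            chars = list(e.sequence)
            rng.shuffle(chars)
            seq = "".join(chars)
        else:
            raise ValueError(f"unknown decoy mode {mode!r}")
        decoys.append(
            ai.DbEntry(
                entry_id=DECOY_PREFIX + e.entry_id,
                species=e.species,
                cluster_key=e.cluster_key,
                source=e.source,
                role=e.role,
                sequence=seq,
                full_length=e.full_length,
                is_decoy=True,
                variant_start=e.variant_start,
            )
        )
    return SearchDb(
        entries=db.entries + decoys,
        protease=db.protease,
        species=set(db.species),
        provenance=dict(db.provenance, decoy_mode=mode),
    )


# ---------------------------------------------------------------------------
# FASTA + metadata I/O
# ---------------------------------------------------------------------------

def write_db_fasta(db: SearchDb, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for e in db.entries:
            fh.write(f">{e.entry_id} full_length={e.full_length}\n")
            for i in range(0, len(e.sequence), width):
                fh.write(e.sequence[i : i + width] + "\n")


def read_db_fasta(path, protease: str = "trypsin") -> SearchDb:
    entries: list[ai.DbEntry] = []
    species: set[str] = set()
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate entry id {rec.id!r}")
        seen.add(rec.id)
        meta = ai.parse_entry_id(rec.id)
        full_length = len(rec.seq)
        for token in rec.description.split():
            if token.startswith("full_length="):
                full_length = int(token.split("=", 1)[1])
        entries.append(
            ai.DbEntry(
                entry_id=rec.id,
                species=meta["species"],
                cluster_key=meta["cluster_key"],
                source=meta["source"],
                role=meta["role"],
                sequence=str(rec.seq),
                full_length=full_length,
                is_decoy=meta["is_decoy"],
                variant_start=meta["variant_start"],
            )
        )
        if not meta["is_decoy"]:
            species.add(meta["species"])
    return SearchDb(entries=entries, protease=protease, species=species)


def write_db_metadata(db: SearchDb, path) -> None:
    rows = [
        {
            "entry_id": e.entry_id,
            "species": e.species,
            "source": e.source,
            "role": e.role,
            "replicon": e.cluster_key[0],
            "strand": e.cluster_key[1],
            "stop_key": e.cluster_key[2],
            "full_length": e.full_length,
            "provenance": ";".join(e.provenance),
        }
        for e in db.entries
        if not e.is_decoy
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Composition statistics
# ---------------------------------------------------------------------------

def db_stats(
    db: SearchDb,
    sprotein_max_len: int = SPROTEIN_MAX_LEN,
    reference_source: str | None = None,
) -> pd.DataFrame:
    """Composition summary per species plus a Combined row.

    A cluster counts as a small-protein (sProtein) cluster iff its anchor's
    full proteoform is <= ``sprotein_max_len`` residues.  Per-source
    "additional" rows count clusters anchored by that source (no
    higher-ranked member exists); "extensions to reference sProteins"
    counts extension variant entries of reference-anchored sProtein
    clusters.
    """
    if reference_source is None:
        reference_source = db.provenance.get("reference_source", "refseq")
    hierarchy = db.provenance.get("hierarchy")
    anchors: dict[tuple, ai.DbEntry] = {}
    extensions: dict[tuple, int] = {}
    for e in db.targets:
        if e.role == ai.ROLE_ANCHOR:
            anchors[(e.species, *e.cluster_key)] = e
        elif e.role == ai.ROLE_EXTENSION:
            extensions[(e.species, *e.cluster_key)] = (
                extensions.get((e.species, *e.cluster_key), 0) + 1
            )
    sources = hierarchy or sorted({e.source for e in anchors.values()})
    non_ref_sources = [s for s in sources if s != reference_source]
    rows = []
    for sp in sorted(db.species):
        sp_anchors = {k: e for k, e in anchors.items() if e.species == sp}
        ref = [e for e in sp_anchors.values() if e.source == reference_source]
        ref_sp = [e for e in ref if e.full_length <= sprotein_max_len]
        ref_sp_keys = {
            (e.species, *e.cluster_key) for e in ref_sp
        }
        row = {
            "species": sp,
            "reference_proteins": len(ref),
            "reference_sproteins": len(ref_sp),
            "extensions_to_reference_sproteins": sum(
                n for k, n in extensions.items() if k in ref_sp_keys
            ),
        }
        for src in non_ref_sources:
            row[f"additional_{src}_sproteins"] = sum(
                1
                for e in sp_anchors.values()
                if e.source == src and e.full_length <= sprotein_max_len
            )
        row["total_clusters"] = len(sp_anchors)
        row["total_sprotein_clusters"] = sum(
            1 for e in sp_anchors.values() if e.full_length <= sprotein_max_len
        )
        rows.append(row)
    frame = pd.DataFrame(rows)
    combined = frame.drop(columns="species").sum()
    combined["species"] = "Combined"
    frame = pd.concat([frame, combined.to_frame().T], ignore_index=True)
    num_cols = [c for c in frame.columns if c != "species"]
    frame[num_cols] = frame[num_cols].astype(int)
    return frame[["species"] + num_cols]


@dataclass
class IdentifiabilityResult:
    fraction: float
    per_species: dict[str, float]
    unidentifiable: list[str]


def identifiability(
    db: SearchDb,
    protease: str | None = None,
    missed_cleavages: int = 2,
    min_len: int = dc.DEFAULT_MIN_PEP_LEN,
    max_len: int = dc.DEFAULT_MAX_PEP_LEN,
    il_equivalent: bool = True,
) -> IdentifiabilityResult:
    """Fraction of target entries with at least one class-1a peptide.

    This is the theoretical MS-identifiability of the database: an entry
    with no peptide unique to it can never be identified unambiguously,
    whatever is measured.
    """
    index = dc.build_peptide_index(
        db,
        protease or db.protease,
        missed_cleavages=missed_cleavages,
        il_equivalent=il_equivalent,
        min_len=min_len,
        max_len=max_len,
    )
    has_unique: dict[str, bool] = {e.entry_id: False for e in db.targets}
    for _pep, ents in index.peptide_to_entries.items():
        if len(ents) == 1:
            has_unique[next(iter(ents))] = True
    per_species_tot: dict[str, int] = {}
    per_species_uni: dict[str, int] = {}
    unidentifiable = []
    for e in db.targets:
        per_species_tot[e.species] = per_species_tot.get(e.species, 0) + 1
        if has_unique[e.entry_id]:
            per_species_uni[e.species] = per_species_uni.get(e.species, 0) + 1
        else:
            unidentifiable.append(e.entry_id)
    total = len(db.targets)
    return IdentifiabilityResult(
        fraction=(total - len(unidentifiable)) / total if total else 0.0,
        per_species={
            sp: per_species_uni.get(sp, 0) / n for sp, n in per_species_tot.items()
        },
        unidentifiable=sorted(unidentifiable),
    )
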