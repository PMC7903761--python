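"""Hierarchical integration of ranked annotation sources.

Gene models from every source (reference annotation, ab initio predictors,
in silico ORFs) are collapsed into *annotation clusters*: groups sharing a
stop codon but differing in start site.  The member from the highest-ranked
source becomes the cluster *anchor* and contributes its full protein
sequence to the search database.  Every other start site is a proteoform
*variant* (extension if it starts 5' of the anchor, reduction if 3') and
contributes only its N-terminal sequence up to a proteolytic cleavage
boundary — enough to cover every peptide that distinguishes it from the
anchor, while keeping the database minimally redundant.  Because the
boundary depends on the enzyme, databases are protease-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils

from .digest_classify import cleavage_positions
from .genome_orf import GenomeError, Orf, Replicon, translate_cds

logger = logging.getLogger("metaptgx")

ROLE_ANCHOR = "anchor"
ROLE_EXTENSION = "extension"
ROLE_REDUCTION = "reduction"


@dataclass
class GeneModel:
    """One CDS interval from one annotation source, stop codon included."""

    source: str
    locus_id: str
    replicon: str
    strand: str
    start: int
    stop_end: int
    protein: str
    pseudo: bool = False
    product: str = ""

    @property
    def stop_key(self) -> int:
        return self.stop_end - 1 if self.strand == "+" else self.start

    @property
    def cluster_key(self) -> tuple:
        return (self.replicon, self.strand, self.stop_key)


@dataclass
class AnnotationCluster:
    """All gene models sharing one stop codon; anchor + start-site variants."""

    key: tuple
    members: list[GeneModel] = field(default_factory=list)
    anchor: GeneModel | None = None
    variants: list[tuple[str, GeneModel]] = field(default_factory=list)
    anchor_provenance: list[GeneModel] = field(default_factory=list)


@dataclass
class DbEntry:
    """One FASTA record of the search database."""

    entry_id: str
    species: str
    cluster_key: tuple
    source: str
    role: str
    sequence: str
    full_length: int
    is_decoy: bool = False
    variant_start: int | None = None
    provenance: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA header codec: {species}|{replicon}|{strand}{stop_key}|{source}|{role}
# optionally followed by |{variant_start}; parsed back bit-exactly.
# ---------------------------------------------------------------------------

def format_entry_id(
    species: str,
    cluster_key: tuple,
    source: str,
    role: str,
    variant_start: int | None = None,
) -> str:
    replicon, strand, stop_key = cluster_key
    parts = [species, replicon, f"{strand}{stop_key}", source, role]
    if variant_start is not None:
        parts.append(str(variant_start))
    return "|".join(parts)


def parse_entry_id(entry_id: str) -> dict:
    decoy = entry_id.startswith("DECOY_")
    body = entry_id[6:] if decoy else entry_id
    parts = body.split("|")
    if len(parts) not in (5, 6):
        raise ValueError(f"malformed entry id {entry_id!r}")
    species, replicon, locus, source, role = parts[:5]
    strand, stop_key = locus[0], int(locus[1:])
    return {
        "species": species,
        "cluster_key": (replicon, strand, stop_key),
        "source": source,
        "role": role,
        "variant_start": int(parts[5]) if len(parts) == 6 else None,
        "is_decoy": decoy,
    }


# ---------------------------------------------------------------------------
# Loading annotation sources
# ---------------------------------------------------------------------------

def _is_pseudo(feature) -> bool:
    attrs = feature.attributes
    if "pseudo" in attrs and str(attrs["pseudo"][0]).lower() in ("true", "1", "yes"):
        return True
    if "gene_biotype" in attrs and attrs["gene_biotype"][0] == "pseudogene":
        return True
    return False


def load_annotation_source(
    gff,
    genomes,
    source_name: str,
    cds_includes_stop: bool = True,
    keep_pseudo: bool = False,
    counters: dict | None = None,
) -> list[GeneModel]:
    """Load CDS features of a GFF3 file as gene models of one source.

    Coordinates are normalized to include the stop codon (3 bases appended
    on the 3' side when the annotation dialect excludes it, with the stop
    codon verified).  Pseudogene-flagged features are dropped unless
    ``keep_pseudo``, in which case the proteoform up to the first internal
    stop is kept.  Features whose translation fails are skipped and counted.
    """
    if counters is None:
        counters = {}
    counters.setdefault("pseudo_skipped", 0)
    counters.setdefault("translation_mismatch", 0)
    counters.setdefault("loaded", 0)
    reps = {r.id: r for r in genomes}
    db = gffutils.create_db(
        str(gff),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.seqid not in reps:
            raise GenomeError(f"CDS {feat.id!r} references unknown replicon {feat.seqid!r}")
        rep = reps[feat.seqid]
        start, stop_end = feat.start - 1, feat.end  # to 0-based half-open
        strand = feat.strand
        if strand not in "+-":
            counters["translation_mismatch"] += 1
            continue
        if not cds_includes_stop:
            if strand == "+":
                stop_end += 3
            else:
                start -= 3
        if start < 0 or stop_end > len(rep):
            raise GenomeError(
                f"CDS {feat.id!r} out of range [{start},{stop_end}) on {rep.id}"
            )
        pseudo = _is_pseudo(feat)
        if pseudo and not keep_pseudo:
            counters["pseudo_skipped"] += 1
            continue
        dna = rep.sequence[start:stop_end]
        if strand == "-":
            from .genome_orf import reverse_complement

            dna = reverse_complement(dna)
        try:
            protein = translate_cds(dna, allow_internal_stop=pseudo)
        except GenomeError as exc:
            counters["translation_mismatch"] += 1
            logger.warning("skipping %s (%s): %s", feat.id, source_name, exc)
            continue
        if not protein:
            counters["translation_mismatch"] += 1
            continue
        attrs = feat.attributes
        locus = (
            attrs.get("locus_tag", attrs.get("ID", [feat.id or "feature"]))[0]
        )
        models.append(
            GeneModel(
                source=source_name,
                locus_id=locus,
                replicon=rep.id,
                strand=strand,
                start=start,
                stop_end=stop_end,
                protein=protein,
                pseudo=pseudo,
                product=attrs.get("product", [""])[0],
            )
        )
        counters["loaded"] += 1
    return models


def orfs_as_gene_models(orfs: list[Orf], source: str = "insilico") -> list[GeneModel]:
    """Adapt in silico ORFs to gene models of the 'insilico' source."""
    return [
        GeneModel(
            source=source,
            locus_id=f"{source}_{o.replicon}_{o.strand}{o.stop_key}",
            replicon=o.replicon,
            strand=o.strand,
            start=o.start,
            stop_end=o.stop_end,
            protein=o.protein,
        )
        for o in orfs
    ]


# ---------------------------------------------------------------------------
# Clustering and anchor selection
# ---------------------------------------------------------------------------

def cluster_gene_models(models: list[GeneModel]) -> list[AnnotationCluster]:
    """Partition gene models into stop-codon annotation clusters."""
    clusters: dict[tuple, AnnotationCluster] = {}
    for m in models:
        if (m.stop_end - m.start) % 3:
            raise GenomeError(
                f"gene model {m.locus_id!r}: interval not divisible by 3"
            )
        cl = clusters.setdefault(m.cluster_key, AnnotationCluster(key=m.cluster_key))
        ref = cl.members[0] if cl.members else None
        if ref is not None:
            same_stop = (
                m.stop_end == ref.stop_end if m.strand == "+" else m.start == ref.start
            )
            if not same_stop:
                raise GenomeError(
                    f"incompatible frames in cluster {m.cluster_key}: "
                    f"{m.locus_id} vs {ref.locus_id}"
                )
        cl.members.append(m)
    return [clusters[k] for k in sorted(clusters)]


def _five_prime_rank(m: GeneModel) -> int:
    # smaller = more 5' (longer proteoform side)
    return m.start if m.strand == "+" else -m.stop_end


def select_anchor(
    cluster: AnnotationCluster, hierarchy: list[str]
) -> AnnotationCluster:
    """Pick the cluster anchor from the highest-ranked source.

    Ties within one source break by longest proteoform, then 5'-most start,
    then locus id.  Members sharing the anchor's start become provenance
    notes on the anchor; the rest are labeled extension or reduction.
    """
    if not cluster.members:
        raise ValueError("empty annotation cluster")
    rank = {s: i for i, s in enumerate(hierarchy)}
    missing = {m.source for m in cluster.members} - set(rank)
    if missing:
        raise ValueError(f"hierarchy does not cover sources {sorted(missing)}")
    anchor = min(
        cluster.members,
        key=lambda m: (
            rank[m.source],
            -len(m.protein),
            _five_prime_rank(m),
            m.locus_id,
        ),
    )
    cluster.anchor = anchor
    cluster.variants = []
    cluster.anchor_provenance = []
    for m in cluster.members:
        if m is anchor:
            continue
        if m.start == anchor.start and m.stop_end == anchor.stop_end:
            cluster.anchor_provenance.append(m)
            continue
        role = (
            ROLE_EXTENSION if len(m.protein) > len(anchor.protein) else ROLE_REDUCTION
        )
        cluster.variants.append((role, m))
    return cluster


# ---------------------------------------------------------------------------
# Variant sequences and integration
# ---------------------------------------------------------------------------

def variant_sequence(
    cluster: AnnotationCluster,
    variant: GeneModel,
    protease: str,
    extra_cleavage_sites: int = 1,
) -> str:
    """N-terminal sequence representing a start-site variant.

    The emitted sequence runs from the variant's own initiator through the
    (1 + ``extra_cleavage_sites``)-th cleavage boundary at or 3' of the
    divergence point — the 3'-most of the anchor and variant starts, in the
    variant's protein coordinates.  This prefix contains every peptide (at
    up to ``extra_cleavage_sites`` missed cleavages) that distinguishes the
    variant proteoform from the anchor.  If the proteoform has too few
    boundaries the full proteoform is returned (e.g. a small protein with no
    Asp-N site is representable only in full).
    """
    if cluster.anchor is None:
        raise ValueError("cluster anchor not selected")
    if variant is cluster.anchor or variant not in cluster.members:
        raise ValueError("variant must be a non-anchor cluster member")
    v = variant.protein
    divergence = max(len(v) - len(cluster.anchor.protein), 0)
    cuts = [c for c in cleavage_positions(v, protease) if c >= divergence]
    if extra_cleavage_sites < len(cuts):
        return v[: cuts[extra_cleavage_sites]]
    return v


def integrate(
    clusters: list[AnnotationCluster],
    hierarchy: list[str],
    protease: str,
    extra_cleavage_sites: int = 1,
    species: str = "sp",
    emit_reductions: bool = True,
) -> list[DbEntry]:
    """Emit the minimally redundant entry list for a set of clusters.

    One full-length anchor entry per cluster plus one entry per distinct
    variant sequence; variants whose emitted sequence duplicates another
    entry of the same cluster are merged with provenance union.
    """
    entries: list[DbEntry] = []
    for cluster in clusters:
        if cluster.anchor is None:
            select_anchor(cluster, hierarchy)
        anchor = cluster.anchor
        anchor_entry = DbEntry(
            entry_id=format_entry_id(
                species, cluster.key, anchor.source, ROLE_ANCHOR
            ),
            species=species,
            cluster_key=cluster.key,
            source=anchor.source,
            role=ROLE_ANCHOR,
            sequence=anchor.protein,
            full_length=len(anchor.protein),
            provenance=[f"{anchor.source}:{anchor.locus_id}"]
            + [f"{m.source}:{m.locus_id}" for m in cluster.anchor_provenance],
        )
        entries.append(anchor_entry)
        by_sequence: dict[str, DbEntry] = {anchor_entry.sequence: anchor_entry}
        for role, variant in sorted(
            cluster.variants, key=lambda rv: (_five_prime_rank(rv[1]), rv[1].locus_id)
        ):
            if role == ROLE_REDUCTION and not emit_reductions:
                continue
            seq = variant_sequence(cluster, variant, protease, extra_cleavage_sites)
            tag = f"{variant.source}:{variant.locus_id}"
            if seq in by_sequence:
                by_sequence[seq].provenance.append(tag)
                continue
            v_start = variant.start if variant.strand == "+" else variant.stop_end
            entry = DbEntry(
                entry_id=format_entry_id(
                    species, cluster.key, variant.source, role, v_start
                ),
                species=species,
                cluster_key=cluster.key,
                source=variant.source,
                role=role,
                sequence=seq,
                full_length=len(variant.protein),
                variant_start=v_start,
                provenance=[tag],
            )
            by_sequence[seq] = entry
            entries.append(entry)
    return entries
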