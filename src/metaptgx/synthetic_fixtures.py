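"""Synthetic multi-species communities with known ground truth.

Every downstream module is exercised on communities generated here: genomes
with planted genes, hidden small ORFs (present in the genome and an ab
initio predictor's GFF but absent from the reference annotation), and
planted start-site variant pairs; simulated engine PSM tables with planted
per-entry spectral counts; and simulated query/reference spectrum pairs.
The generator also ships digitized copies of two published worked-example
tables for an eight-species gut community (SIHUMIx): a database-composition
summary and a 31-candidate novel small-protein evidence table (transcribed
from the publication, since extracted table text is typographically
ambiguous; every digitized row was re-checked against the printed row and
column totals).

Intergenic background sequence is drawn from a stop-codon-rich codon pool
(stops on both strands in the aligned frame), which keeps the number of
spurious in silico ORFs small enough for desk-scale tests; real intergenic
DNA is less stop-dense, so six-frame ORF counts on real genomes are far
larger than on these fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import db_builder as dbb
from . import digest_classify as dc
from . import psm_filter as pf
from . import validate_characterize as vc
from .genome_orf import Replicon, reverse_complement, translate_cds

_STOP_CODONS = ("TAA", "TAG", "TGA")
# stop codons plus their reverse complements: stop-dense on both strands
_BACKGROUND_CODONS = ("TAA", "TAG", "TGA", "TTA", "CTA", "TCA")
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)


@dataclass
class PlantedGene:
    locus_id: str
    replicon: str
    strand: str
    start: int  # inner (reference) interval, stop codon included
    stop_end: int
    protein: str  # inner proteoform
    in_reference: bool
    variant_ext_codons: int = 0  # predictor start-site extension, in codons
    variant_protein: str = ""

    @property
    def stop_key(self) -> int:
        return self.stop_end - 1 if self.strand == "+" else self.start


@dataclass
class SpeciesTruth:
    species: str
    replicon: Replicon
    genes: list[PlantedGene]
    hidden_sorfs: list[PlantedGene]
    paths: dict = field(default_factory=dict)

    @property
    def expected_clusters(self) -> int:
        return len(self.genes) + len(self.hidden_sorfs)

    @property
    def expected_stats(self) -> dict:
        ref_sp = [g for g in self.genes if len(g.protein) <= dbb.SPROTEIN_MAX_LEN]
        return {
            "reference_proteins": len(self.genes),
            "reference_sproteins": len(ref_sp),
            "extensions_to_reference_sproteins": sum(
                1 for g in ref_sp if g.variant_ext_codons
            ),
            "additional_predictor_sproteins": sum(
                1
                for s in self.hidden_sorfs
                if len(s.protein) <= dbb.SPROTEIN_MAX_LEN
            ),
            "total_clusters": self.expected_clusters,
            "total_sprotein_clusters": len(ref_sp) + len(self.hidden_sorfs),
        }


@dataclass
class CommunityTruth:
    species: list[SpeciesTruth]

    def by_name(self, name: str) -> SpeciesTruth:
        return next(s for s in self.species if s.species == name)


def _random_gene(rng, n_aa: int) -> str:
    """Sense-strand CDS: ATG + random non-stop codons + random stop."""
    body = "".join(rng.choice(_NON_STOP_CODONS) for _ in range(n_aa - 1))
    return "ATG" + body + rng.choice(_STOP_CODONS)


def _background(rng, n: int) -> str:
    out = "".join(
        rng.choice(_BACKGROUND_CODONS) for _ in range(n // 3 + 1)
    )
    return out[:n]


def generate_community(
    n_species: int = 2,
    genome_length: int = 12000,
    n_genes: int = 20,
    n_hidden_sorfs: int = 3,
    n_start_variants: int = 2,
    gene_len_range: tuple[int, int] = (40, 150),
    sorf_len_range: tuple[int, int] = (18, 100),
    seed: int = 0,
    out_dir=None,
) -> CommunityTruth:
    """Generate genomes + reference/predictor GFF3 sources with known truth.

    Per species: ``n_genes`` reference genes (lengths in aa drawn from
    ``gene_len_range``), the first ``n_start_variants`` of which get an
    upstream in-frame start in the predictor source (an extension variant),
    and ``n_hidden_sorfs`` small ORFs present only in the predictor source.
    Placement is sequential with stop-rich spacers; generation fails if the
    requested genes do not fit in ``genome_length``.  Deterministic for a
    fixed seed.  With ``out_dir`` set, FASTA and GFF3 files are written and
    their paths recorded in each species' truth.
    """
    import random as _random

    rng = _random.Random(seed)
    species_list: list[SpeciesTruth] = []
    for si in range(n_species):
        sp = f"sp{si + 1}"
        rep_id = f"{sp}_chr"
        parts: list[str] = []
        pos = 0
        genes: list[PlantedGene] = []
        hidden: list[PlantedGene] = []

        def place(block: str, spacer_range=(30, 60)) -> int:
            nonlocal pos
            spacer = _background(rng, rng.randint(*spacer_range))
            parts.append(spacer)
            pos += len(spacer)
            at = pos
            parts.append(block)
            pos += len(block)
            return at

        for gi in range(n_genes):
            n_aa = rng.randint(*gene_len_range)
            n_ext = rng.randint(4, 12) if gi < n_start_variants else 0
            inner = _random_gene(rng, n_aa)
            ext = (
                "ATG" + "".join(rng.choice(_NON_STOP_CODONS) for _ in range(n_ext - 1))
                if n_ext
                else ""
            )
            block_sense = ext + inner
            strand = rng.choice("+-")
            block = block_sense if strand == "+" else reverse_complement(block_sense)
            at = place(block)
            L = len(block_sense)
            if strand == "+":
                start, stop_end = at + 3 * n_ext, at + L
            else:
                start, stop_end = at, at + L - 3 * n_ext
            protein = translate_cds(inner)
            variant_protein = translate_cds(ext + inner) if n_ext else ""
            genes.append(
                PlantedGene(
                    locus_id=f"{sp}_g{gi + 1:03d}",
                    replicon=rep_id,
                    strand=strand,
                    start=start,
                    stop_end=stop_end,
                    protein=protein,
                    in_reference=True,
                    variant_ext_codons=n_ext,
                    variant_protein=variant_protein,
                )
            )
        for hi in range(n_hidden_sorfs):
            n_aa = rng.randint(*sorf_len_range)
            inner = _random_gene(rng, n_aa)
            strand = rng.choice("+-")
            block = inner if strand == "+" else reverse_complement(inner)
            at = place(block)
            hidden.append(
                PlantedGene(
                    locus_id=f"{sp}_sorf{hi + 1:03d}",
                    replicon=rep_id,
                    strand=strand,
                    start=at,
                    stop_end=at + len(inner),
                    protein=translate_cds(inner),
                    in_reference=False,
                )
            )
        if pos > genome_length:
            raise ValueError(
                f"cannot pack {n_genes} genes + {n_hidden_sorfs} sORFs "
                f"into {genome_length} bp (need {pos})"
            )
        parts.append(_background(rng, genome_length - pos))
        genome = "".join(parts)
        replicon = Replicon(id=rep_id, species=sp, sequence=genome)
        st = SpeciesTruth(species=sp, replicon=replicon, genes=genes, hidden_sorfs=hidden)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            fasta = out / f"{sp}.fasta"
            from .genome_orf import write_genome_fasta

            write_genome_fasta([replicon], fasta)
            ref_gff = out / f"{sp}_reference.gff3"
            pred_gff = out / f"{sp}_predictor.gff3"
            write_truth_gff(st, ref_gff, source="reference")
            write_truth_gff(st, pred_gff, source="predictor")
            st.paths = {
                "genome": str(fasta),
                "reference": str(ref_gff),
                "predictor": str(pred_gff),
            }
        species_list.append(st)
    return CommunityTruth(species=species_list)


def _gff_line(rep, src, start, stop_end, strand, attrs) -> str:
    return "\t".join(
        [rep, src, "CDS", str(start + 1), str(stop_end), ".", strand, "0", attrs]
    )


def write_truth_gff(st: SpeciesTruth, path, source: str) -> None:
    """Write the reference or predictor view of a species' planted truth."""
    lines = ["##gff-version 3"]
    for g in st.genes:
        if source == "reference":
            start, stop_end = g.start, g.stop_end
        else:  # predictor reports the extended start where one was planted
            ext = 3 * g.variant_ext_codons
            if g.strand == "+":
                start, stop_end = g.start - ext, g.stop_end
            else:
                start, stop_end = g.start, g.stop_end + ext
        lines.append(
            _gff_line(
                g.replicon,
                source,
                start,
                stop_end,
                g.strand,
                f"ID={source}_{g.locus_id};locus_tag={source}_{g.locus_id}",
            )
        )
    if source != "reference":
        for s in st.hidden_sorfs:
            lines.append(
                _gff_line(
                    s.replicon,
                    source,
                    s.start,
                    s.stop_end,
                    s.strand,
                    f"ID={source}_{s.locus_id};locus_tag={source}_{s.locus_id}",
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def build_truth_db(
    st: SpeciesTruth,
    protease: str,
    tmp_dir,
    hierarchy=("reference", "predictor"),
    **kwargs,
):
    """Convenience: build one species' database from its truth files."""
    if not st.paths:
        tmp = Path(tmp_dir)
        tmp.mkdir(parents=True, exist_ok=True)
        ref = tmp / f"{st.species}_reference.gff3"
        pred = tmp / f"{st.species}_predictor.gff3"
        write_truth_gff(st, ref, "reference")
        write_truth_gff(st, pred, "predictor")
        st.paths = {"reference": str(ref), "predictor": str(pred)}
    sources = [(s, st.paths[s]) for s in hierarchy if s in st.paths]
    return dbb.build_species_db(
        [st.replicon], sources, list(hierarchy), protease, **kwargs
    )


# ---------------------------------------------------------------------------
# PSM simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPsms:
    records: dict[tuple[str, str], list]  # (engine, protease) -> PsmRecords
    paths: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def all_records(self) -> list:
        out = []
        for recs in self.records.values():
            out.extend(recs)
        return out


def _qualifying_peptides(entry, protease, index) -> list[str]:
    peps = sorted(
        {
            pep
            for pep, _s, _m in dc.digest(
                entry.sequence,
                protease,
                index.missed_cleavages,
                index.min_len,
                index.max_len,
            )
            if dc.classify_peptide(pep, index) in ("1a", "3a")
        }
    )
    return peps


def simulate_psms(
    dbs: dict[str, "dbb.SearchDb"],
    psm_plan: dict[str, dict[tuple[str, str], int]],
    decoy_rate: float = 0.0,
    score_gap: float = 5.0,
    seed: int = 0,
    out_dir=None,
    indexes: dict[str, dc.PeptideIndex] | None = None,
) -> SimulatedPsms:
    """Generate engine-style PSM tables realizing a per-entry spectral plan.

    ``psm_plan`` maps entry_id -> {(protease, engine): PSM count}.  Planned
    PSMs draw unambiguous (class 1a/3a) peptides of the entry in the
    protease-specific database, cycling deterministically; an entry with no
    qualifying peptide at a requested protease raises (mirroring real small
    proteins that yield no detectable peptide for one enzyme).  Target
    scores are Normal(score_gap, 1); decoy PSMs (``decoy_rate`` per target
    PSM) draw decoy-entry peptides with Normal(0, 1) scores.
    """
    rng = np.random.default_rng(seed)
    indexes = indexes or {
        prot: dc.build_peptide_index(db) for prot, db in dbs.items()
    }
    records: dict[tuple[str, str], list] = {}
    spectrum_no = 0
    for entry_id in sorted(psm_plan):
        plan = psm_plan[entry_id]
        for (protease, engine), count in sorted(plan.items()):
            db = dbs[protease]
            index = indexes[protease]
            entry = db.entry(entry_id)
            peps = _qualifying_peptides(entry, protease, index)
            if not peps:
                raise ValueError(
                    f"entry {entry_id!r} has no unambiguous peptide under "
                    f"{protease}"
                )
            bucket = records.setdefault((engine, protease), [])
            for k in range(count):
                pep = peps[k % len(peps)]
                spectrum_no += 1
                bucket.append(
                    pf.PsmRecord(
                        spectrum_id=f"sp{spectrum_no:06d}",
                        peptide=pep,
                        charge=2,
                        engine=engine,
                        protease=protease,
                        score=float(rng.normal(score_gap, 1.0)),
                        entry_ids=tuple(sorted(index.entries_for(pep))),
                    )
                )
    if decoy_rate > 0:
        for (engine, protease), bucket in sorted(records.items()):
            db = dbs[protease]
            decoy_entries = [e for e in db.entries if e.is_decoy]
            if not decoy_entries:
                raise ValueError(f"{protease} database has no decoys")
            n_decoys = int(round(decoy_rate * len(bucket)))
            for _ in range(n_decoys):
                de = decoy_entries[int(rng.integers(len(decoy_entries)))]
                dpeps = dc.digest(de.sequence, protease, 1)
                if not dpeps:
                    continue
                pep = dpeps[int(rng.integers(len(dpeps)))][0]
                spectrum_no += 1
                bucket.append(
                    pf.PsmRecord(
                        spectrum_id=f"sp{spectrum_no:06d}",
                        peptide=pep,
                        charge=2,
                        engine=engine,
                        protease=protease,
                        score=float(rng.normal(0.0, 1.0)),
                        is_decoy=True,
                        entry_ids=(de.entry_id,),
                    )
                )
    sim = SimulatedPsms(records=records)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (engine, protease), bucket in sorted(records.items()):
            path = out / f"psms_{engine}_{protease}.tsv"
            pf.write_psm_table(bucket, path)
            sim.paths[(engine, protease)] = str(path)
    return sim


def expected_novel_passing(
    dbs: dict[str, "dbb.SearchDb"],
    psm_plan: dict[str, dict[tuple[str, str], int]],
    source_thresholds: dict[str, int] | None = None,
    sprotein_max_len: int = dbb.SPROTEIN_MAX_LEN,
) -> set[str]:
    """Analytic expectation: planned entries that must pass the filter.

    Mirrors the candidate definition (identified, <= sprotein_max_len aa,
    cluster without a reference member) and the source-dependent threshold
    on the protease/engine-summed PSM count, computed from the plan alone.
    """
    thresholds = dict(pf.DEFAULT_SOURCE_THRESHOLDS)
    if source_thresholds:
        thresholds.update(source_thresholds)
    passing: set[str] = set()
    any_db = next(iter(dbs.values()))
    reference = any_db.provenance.get("reference_source", "reference")
    for entry_id, plan in psm_plan.items():
        total = sum(plan.values())
        db = dbs[next(iter(plan))[0]]
        entry = db.entry(entry_id)
        if entry.full_length > sprotein_max_len:
            continue
        cluster_sources = {
            e.source
            for e in db.targets
            if e.species == entry.species and e.cluster_key == entry.cluster_key
        }
        for e in db.targets:
            if e.species == entry.species and e.cluster_key == entry.cluster_key:
                for prov in e.provenance:
                    cluster_sources.add(prov.split(":", 1)[0])
        if reference in cluster_sources:
            continue
        anchor_source = next(
            e.source
            for e in db.targets
            if e.species == entry.species
            and e.cluster_key == entry.cluster_key
            and e.role == "anchor"
        )
        if total >= thresholds[anchor_source]:
            passing.add(entry_id)
    return passing


# ---------------------------------------------------------------------------
# Spectrum simulation
# ---------------------------------------------------------------------------

def simulate_spectrum(
    peptide: str,
    noise_peaks: int = 0,
    intensity_jitter: float = 0.0,
    mz_jitter: float = 0.0,
    seed: int = 0,
) -> tuple[vc.Spectrum, vc.Spectrum]:
    """(query, reference) spectrum pair for one peptide.

    The reference is the clean predicted fragment spectrum; the query gets
    bounded m/z jitter (<= 0.01 Th so true pairs stay inside the product
    tolerance), multiplicative intensity jitter, and uniform noise peaks
    placed away from true fragments.
    """
    if mz_jitter > 0.01:
        raise ValueError("mz_jitter must be <= 0.01 Th")
    rng = np.random.default_rng(seed)
    reference = vc.predict_fragments(peptide)
    mz = reference.mz + rng.uniform(-mz_jitter, mz_jitter, reference.mz.size)
    intensity = reference.intensity * (
        1.0 + intensity_jitter * rng.uniform(-1, 1, reference.intensity.size)
    )
    noise_mz: list[float] = []
    lo, hi = reference.mz.min() + 5, reference.mz.max() + 50
    while len(noise_mz) < noise_peaks:
        cand = float(rng.uniform(lo, hi))
        if np.abs(reference.mz - cand).min() > 0.1:
            noise_mz.append(cand)
    query = vc.Spectrum(
        precursor_mz=reference.precursor_mz,
        charge=reference.charge,
        mz=np.concatenate([mz, noise_mz]),
        intensity=np.concatenate(
            [intensity, np.full(len(noise_mz), float(intensity.mean()))]
        ),
    )
    return query, reference


# ---------------------------------------------------------------------------
# Digitized published worked-example tables
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("metaptgx").joinpath("data", name)


def load_db_composition_table() -> pd.DataFrame:
    """Digitized composition summary of the published eight-species DB."""
    with resources.as_file(_data_path("published_db_composition.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_paper_tables() -> tuple[pd.Series, pd.DataFrame]:
    """(combined composition row, 31-candidate evidence table)."""
    comp = load_db_composition_table()
    combined = comp[comp["species"] == "Combined"].iloc[0]
    with resources.as_file(_data_path("published_novel_sproteins.tsv")) as p:
        table3 = pd.read_csv(p, sep="\t")
    return combined, table3
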