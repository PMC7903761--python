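"""Genome I/O and in silico ORF discovery.

The in silico annotation source is a modified six-frame translation: on each
strand and frame, every in-frame stop codon defines at most one maximal open
reading frame, started at the 5'-most qualifying start codon (ATG plus the
alternative bacterial initiators CTG, TTG and GTG).  Internal-start
proteoforms can optionally be enumerated for sensitivity studies; by default
they are left to the annotation-cluster machinery, which keeps the resulting
search database minimally redundant.

Coordinates are 0-based, half-open, on the forward strand throughout:
``start`` is the leftmost base of the ORF interval and ``stop_end`` one past
the rightmost base, with the strand recorded separately.  GFF3 I/O converts
to and from 1-based inclusive coordinates at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger("metaptgx")

VALID_ALPHABET = frozenset("ACGTN")
DEFAULT_START_CODONS = frozenset({"ATG", "CTG", "TTG", "GTG"})
DEFAULT_MIN_LEN = 18
BACTERIAL_TABLE = 11


class GenomeError(ValueError):
    """Raised for malformed genome input (alphabet, duplicates, parsing)."""


@dataclass
class Replicon:
    """A named DNA sequence (chromosome or plasmid) of one species."""

    id: str
    species: str
    sequence: str
    circular: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeError(f"replicon {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence) if c not in VALID_ALPHABET
            )
            raise GenomeError(
                f"replicon {self.id!r}: invalid character {self.sequence[pos]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Orf:
    """One open reading frame, stop codon included in the interval."""

    replicon: str
    strand: str
    start: int
    stop_end: int
    start_codon: str
    protein: str

    @property
    def stop_key(self) -> int:
        """Forward-strand coordinate of the stop codon's 3'-most base.

        For a minus-strand ORF the stop codon sits at the low-coordinate end
        of the interval, so the key is ``start``; on the plus strand it is
        ``stop_end - 1``.  This key is what annotation clustering groups on.
        """
        return self.stop_end - 1 if self.strand == "+" else self.start


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _codon_maps(genetic_code: int):
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    return dict(table.forward_table), frozenset(table.stop_codons)


def translate_cds(
    dna: str,
    genetic_code: int = BACTERIAL_TABLE,
    initiator_as_met: bool = True,
    allow_internal_stop: bool = False,
) -> str:
    """Translate a CDS nucleotide string to protein.

    The trailing stop codon is stripped if present.  An internal stop raises
    unless ``allow_internal_stop`` is set, in which case translation ends at
    the first internal stop (used for expressed-pseudogene proteoforms).
    The initiator codon is translated as Met regardless of identity when
    ``initiator_as_met`` (alternative initiators CTG/TTG/GTG are read by
    initiator tRNA-fMet in bacteria).
    """
    dna = dna.upper()
    if len(dna) % 3:
        raise GenomeError(f"CDS length {len(dna)} not divisible by 3")
    fwd, stops = _codon_maps(genetic_code)
    aas: list[str] = []
    n_codons = len(dna) // 3
    for i in range(n_codons):
        codon = dna[3 * i : 3 * i + 3]
        if "N" in codon:
            raise GenomeError(f"ambiguous codon {codon!r} at codon index {i}")
        if codon in stops:
            if i == n_codons - 1:
                break
            if allow_internal_stop:
                break
            raise GenomeError(f"internal stop codon {codon!r} at codon index {i}")
        aas.append(fwd[codon])
    if initiator_as_met and aas:
        aas[0] = "M"
    return "".join(aas)


def read_genome_fasta(
    path,
    species: str | None = None,
    species_map: dict[str, str] | None = None,
    circular: bool = False,
) -> list[Replicon]:
    """Read replicons from FASTA.

    The species tag is taken from ``species`` (applies to every record), from
    ``species_map`` (record id -> species), or from a ``species|replicon``
    header convention; otherwise it defaults to the record id.
    """
    replicons: list[Replicon] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        sp = species
        if sp is None and species_map is not None:
            sp = species_map.get(rid)
        if sp is None and "|" in rid:
            sp, rid = rid.split("|", 1)
        if sp is None:
            sp = rid
        if rid in seen:
            raise GenomeError(f"duplicate replicon id {rid!r} in {path}")
        seen.add(rid)
        replicons.append(
            Replicon(
                id=rid,
                species=sp,
                sequence=str(rec.seq),
                circular=circular,
                description=rec.description,
            )
        )
    if not replicons:
        raise GenomeError(f"no FASTA records found in {path}")
    return replicons


def write_genome_fasta(replicons, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rep in replicons:
            fh.write(f">{rep.id} species={rep.species}\n")
            for i in range(0, len(rep.sequence), width):
                fh.write(rep.sequence[i : i + width] + "\n")


def _scan_frame(
    seq: str,
    frame: int,
    start_codons: frozenset,
    stops: frozenset,
    min_len: int,
    emit_internal_starts: bool,
):
    """Yield (start_codon_idx, stop_codon_idx, start_codon) per qualifying ORF.

    Codon indices are relative to the frame-shifted sequence.  Codons
    containing N are neither starts nor stops and taint any ORF covering
    them.  ``min_len`` bounds the protein length = stop_idx - start_idx.
    """
    n_codons = (len(seq) - frame) // 3
    region_starts: list[tuple[int, str]] = []
    for i in range(n_codons):
        codon = seq[frame + 3 * i : frame + 3 * i + 3]
        if "N" in codon:
            # an N codon invalidates every ORF that would span it
            region_starts = []
            continue
        if codon in stops:
            for s, c in region_starts:
                if i - s >= min_len:
                    yield (s, i, c)
                    if not emit_internal_starts:
                        break
            region_starts = []
            continue
        if codon in start_codons:
            region_starts.append((i, codon))
    # trailing region without a stop codon yields nothing: an ORF requires
    # its stop to be present on the (linear) replicon


def six_frame_orfs(
    replicon: Replicon,
    min_len: int = DEFAULT_MIN_LEN,
    start_codons=DEFAULT_START_CODONS,
    genetic_code: int = BACTERIAL_TABLE,
    wrap_origin: bool = False,
    emit_internal_starts: bool = False,
) -> list[Orf]:
    """Find ORFs in all six frames of a replicon.

    By default one maximal ORF per (strand, in-frame stop codon) is
    returned: the 5'-most qualifying start with no intervening in-frame
    stop.  With ``emit_internal_starts`` every qualifying internal start is
    enumerated as well.  ORFs whose span contains an N are skipped (and
    counted in the log).  Origin-spanning ORFs of circular replicons are
    found only when ``wrap_origin`` is set, by scanning a doubled sequence
    and deduplicating on (strand, stop key).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    start_codons = frozenset(s.upper() for s in start_codons)
    fwd_table, stops = _codon_maps(genetic_code)

    def collect(seq: str, L: int, modulo: int | None) -> list[Orf]:
        found: list[Orf] = []
        rc = reverse_complement(seq)
        for strand, s in (("+", seq), ("-", rc)):
            for frame in range(3):
                for s_idx, t_idx, s_codon in _scan_frame(
                    s, frame, start_codons, stops, min_len, emit_internal_starts
                ):
                    lo = frame + 3 * s_idx
                    hi = frame + 3 * t_idx + 3  # one past stop codon
                    codons = s[lo:hi]
                    if strand == "-":
                        lo, hi = len(s) - hi, len(s) - lo
                    protein = translate_cds(
                        codons, genetic_code, initiator_as_met=True
                    )
                    if modulo is not None:
                        if hi <= modulo:
                            continue  # non-wrapping copy, found in first pass
                        if hi - lo > modulo:
                            continue  # longer than the replicon itself
                        lo %= modulo
                    found.append(
                        Orf(
                            replicon=replicon.id,
                            strand=strand,
                            start=lo,
                            stop_end=hi,
                            start_codon=s_codon,
                            protein=protein,
                        )
                    )
        return found

    orfs = collect(replicon.sequence, len(replicon), None)
    if wrap_origin and replicon.circular:
        seen = {(o.strand, o.stop_key) for o in orfs}
        for o in collect(replicon.sequence * 2, len(replicon), len(replicon)):
            key = (o.strand, o.stop_key % len(replicon))
            if key not in seen:
                seen.add(key)
                orfs.append(o)
    orfs.sort(key=lambda o: (o.start, o.stop_end, o.strand))
    return orfs


def orfs_to_gff3(orfs, path, source: str = "insilico") -> None:
    """Write ORFs as GFF3 CDS features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, o in enumerate(orfs):
            attrs = (
                f"ID={source}_{o.replicon}_{i:06d};"
                f"start_codon={o.start_codon}"
            )
            fh.write(
                "\t".join(
                    [
                        o.replicon,
                        source,
                        "CDS",
                        str(o.start + 1),
                        str(o.stop_end),
                        ".",
                        o.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )
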