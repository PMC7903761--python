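"""In silico proteolysis and peptide ambiguity classification.

Digestion is fully specific ("Full"): every peptide starts and ends at an
enzymatic cleavage boundary or a protein terminus.  Trypsin cleaves
C-terminal of K/R (cleavage before proline suppressed by default); Asp-N
cleaves N-terminal of D.

Peptides are classified by how they map onto a search database:

* ``1a`` — unique to exactly one database entry (unambiguous),
* ``2a`` — shared by several entries of one annotation cluster
  (e.g. an anchor and its start-site variant),
* ``3a`` — shared by entries from different clusters that carry one
  identical protein sequence (mainly duplicated genes),
* ``3b`` — shared by distinct proteins of different genes (ambiguous).

Isoleucine and leucine are isobaric and indistinguishable by standard
MS/MS, so peptide keys collapse I and L to the joint symbol J by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PROTEASES = ("trypsin", "aspn")
DEFAULT_MIN_PEP_LEN = 6
DEFAULT_MAX_PEP_LEN = 50
_IL_TABLE = str.maketrans("IL", "JJ")


def cleavage_positions(
    protein: str,
    protease: str,
    proline_rule: bool = True,
    aspn_residues: str = "D",
) -> list[int]:
    """Internal cleavage boundaries of a protein, as cut positions.

    A cut position ``c`` means cleavage between residues ``c-1`` and ``c``;
    the protein termini (0 and len) are not included.
    """
    protein = protein.upper()
    cuts: list[int] = []
    if protease == "trypsin":
        for i, aa in enumerate(protein[:-1]):
            if aa in "KR":
                if proline_rule and protein[i + 1] == "P":
                    continue
                cuts.append(i + 1)
    elif protease == "aspn":
        for i in range(1, len(protein)):
            if protein[i] in aspn_residues:
                cuts.append(i)
    else:
        raise ValueError(f"unknown protease {protease!r}")
    return cuts


def digest(
    protein: str,
    protease: str,
    missed_cleavages: int = 2,
    min_len: int = DEFAULT_MIN_PEP_LEN,
    max_len: int = DEFAULT_MAX_PEP_LEN,
    proline_rule: bool = True,
) -> list[tuple[str, int, int]]:
    """Fully specific digestion; returns (peptide, start offset, missed count)."""
    protein = protein.upper()
    bounds = [0] + cleavage_positions(protein, protease, proline_rule) + [len(protein)]
    out: list[tuple[str, int, int]] = []
    for i in range(len(bounds) - 1):
        for missed in range(missed_cleavages + 1):
            j = i + 1 + missed
            if j >= len(bounds):
                break
            pep = protein[bounds[i] : bounds[j]]
            if min_len <= len(pep) <= max_len:
                out.append((pep, bounds[i], missed))
    return out


def peptide_key(sequence: str, il_equivalent: bool = True) -> str:
    sequence = sequence.upper()
    return sequence.translate(_IL_TABLE) if il_equivalent else sequence


@dataclass
class PeptideIndex:
    """Maps peptide keys to the database entries they derive from."""

    protease: str
    missed_cleavages: int
    il_equivalent: bool
    min_len: int
    max_len: int
    peptide_to_entries: dict[str, set[str]] = field(default_factory=dict)
    entry_cluster: dict[str, tuple] = field(default_factory=dict)
    entry_group: dict[str, int] = field(default_factory=dict)

    def key(self, peptide: str) -> str:
        return peptide_key(peptide, self.il_equivalent)

    def entries_for(self, peptide: str) -> frozenset:
        return frozenset(self.peptide_to_entries.get(self.key(peptide), ()))


def build_peptide_index(
    db,
    protease: str | None = None,
    missed_cleavages: int = 2,
    il_equivalent: bool = True,
    min_len: int = DEFAULT_MIN_PEP_LEN,
    max_len: int = DEFAULT_MAX_PEP_LEN,
) -> PeptideIndex:
    """Digest every target entry of a search DB into a peptide index.

    Decoy entries are excluded.  Sequence-identity groups (entries with a
    byte-identical sequence, from different gene models) are precomputed to
    support the 3a class.
    """
    if protease is None:
        protease = db.protease
    index = PeptideIndex(protease, missed_cleavages, il_equivalent, min_len, max_len)
    groups: dict[str, int] = {}
    for entry in db.entries:
        if entry.is_decoy:
            continue
        gid = groups.setdefault(entry.sequence, len(groups))
        index.entry_group[entry.entry_id] = gid
        index.entry_cluster[entry.entry_id] = entry.cluster_key
        for pep, _start, _missed in digest(
            entry.sequence, protease, missed_cleavages, min_len, max_len
        ):
            index.peptide_to_entries.setdefault(
                peptide_key(pep, il_equivalent), set()
            ).add(entry.entry_id)
    return index


def classify_peptide(peptide: str, index: PeptideIndex) -> str:
    """Classify a peptide as 1a / 2a / 3a / 3b / unmapped against an index.

    Within-cluster multiplicity is 2a even when the shared sequences are
    identical; the identity-group (3a) test applies only across clusters.
    """
    entries = index.entries_for(peptide)
    if not entries:
        return "unmapped"
    if len(entries) == 1:
        return "1a"
    clusters = {index.entry_cluster[e] for e in entries}
    if len(clusters) == 1:
        return "2a"
    groups = {index.entry_group[e] for e in entries}
    if len(groups) == 1:
        return "3a"
    return "3b"
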