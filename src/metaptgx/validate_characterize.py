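"""Spectral validation scoring and candidate characterization.

Candidate small proteins are validated by comparing the experimental MS/MS
spectrum of an identifying peptide with the spectrum of the corresponding
synthetic peptide.  Similarity is scored on the 0-999 match-factor scale of
spectral library searching: a square-root-intensity normalized dot product
over greedily m/z-paired peaks (+-0.02 Th product tolerance), with the
*reverse* match computed after discarding query peaks absent from the
reference.  A candidate is validated when any peptide reaches match >= 500
and reverse match >= 700.

Characterization covers the ProtParam-style physicochemical descriptors
(isoelectric point by bisection of the Henderson-Hasselbalch net charge,
Kyte-Doolittle GRAVY, aliphatic index) and the abundance normalizations
NSAF (proteomics) and TPM (transcriptomics) with multi-mapping resolution
for duplicated genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pyteomics import mass as pt_mass
from pyteomics import mgf as pt_mgf

PROTON = 1.007276466812
WATER = 18.010564684
CARBAMIDOMETHYL = 57.02146
DEFAULT_FIXED_MODS = {"C": CARBAMIDOMETHYL}

# Kyte-Doolittle hydropathy indices
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Bjellqvist pKa set as used by ProtParam: residue-specific N-terminal pKa,
# acidic C-terminal corrections, and side-chain pKa values.
BJELLQVIST = {
    "nterm": {"default": 7.5, "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
              "T": 6.82, "V": 7.44, "E": 7.7},
    "cterm": {"default": 3.55, "D": 4.55, "E": 4.75},
    "positive": {"K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
}

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


def _check_standard(protein: str) -> str:
    protein = protein.upper()
    if not protein:
        raise ValueError("empty sequence")
    bad = set(protein) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)}")
    return protein


@dataclass
class Spectrum:
    """A centroided peak list with precursor information."""

    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size == 0:
            raise ValueError("spectrum has no peaks")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if not (np.isfinite(self.intensity).all() and (self.intensity >= 0).all()):
            raise ValueError("intensities must be finite and non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]


@dataclass
class MatchResult:
    match: int
    reverse_match: int
    n_matched_peaks: int
    precursor_ok: bool


def peptide_mass(peptide: str, fixed_mods=DEFAULT_FIXED_MODS) -> float:
    peptide = _check_standard(peptide)
    m = sum(pt_mass.std_aa_mass[aa] for aa in peptide) + WATER
    for aa, delta in (fixed_mods or {}).items():
        m += peptide.count(aa) * delta
    return m


def predict_fragments(
    peptide: str,
    charge: int = 2,
    fixed_mods=DEFAULT_FIXED_MODS,
) -> Spectrum:
    """Singly charged b- and y-ion spectrum from monoisotopic masses.

    ``charge`` is the precursor charge; product ions are 1+ with unit
    intensities (a geometry-only reference for match-factor scoring).
    """
    peptide = _check_standard(peptide)
    fixed_mods = fixed_mods or {}

    def res(aa: str) -> float:
        return pt_mass.std_aa_mass[aa] + fixed_mods.get(aa, 0.0)

    n = len(peptide)
    mzs = []
    prefix = 0.0
    for i in range(n - 1):
        prefix += res(peptide[i])
        mzs.append(prefix + PROTON)  # b-ion
    suffix = 0.0
    for i in range(n - 1, 0, -1):
        suffix += res(peptide[i])
        mzs.append(suffix + WATER + PROTON)  # y-ion
    total = peptide_mass(peptide, fixed_mods)
    return Spectrum(
        precursor_mz=(total + charge * PROTON) / charge,
        charge=charge,
        mz=np.array(sorted(mzs)),
        intensity=np.ones(len(mzs)),
    )


def _greedy_pairs(query: Spectrum, reference: Spectrum, tol: float):
    """Pair peaks by nearest m/z within tolerance, each peak used once.

    Candidate pairs are ranked by |delta m/z|, ties broken by higher
    intensity product.
    """
    cands = []
    j0 = 0
    for i, qm in enumerate(query.mz):
        j0 = np.searchsorted(reference.mz, qm - tol)
        j = j0
        while j < reference.mz.size and reference.mz[j] <= qm + tol:
            cands.append(
                (
                    abs(qm - reference.mz[j]),
                    -(query.intensity[i] * reference.intensity[j]),
                    i,
                    j,
                )
            )
            j += 1
    cands.sort()
    used_q: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _d, _p, i, j in cands:
        if i in used_q or j in used_r:
            continue
        used_q.add(i)
        used_r.add(j)
        pairs.append((i, j))
    return pairs


def _similarity(q_int, r_int, pairs) -> float:
    sq = sum(np.sqrt(q_int[i] * r_int[j]) for i, j in pairs)
    denom = q_int.sum() * r_int.sum()
    return float(sq * sq / denom) if denom > 0 else 0.0


def match_factors(
    query: Spectrum,
    reference: Spectrum,
    precursor_tol: float = 0.01,
    product_tol: float = 0.02,
) -> MatchResult:
    """0-999 match and reverse-match factors between two spectra.

    match = round(999 * (sum sqrt(Iq*Ir))^2 / (sum Iq * sum Ir)) over the
    greedy peak pairing; the reverse match drops unpaired query peaks
    first, so reverse >= match always.  The precursor agreement is
    reported but does not gate the score.
    """
    pairs = _greedy_pairs(query, reference, product_tol)
    sim = _similarity(query.intensity, reference.intensity, pairs)
    matched_q = sorted(i for i, _j in pairs)
    if matched_q:
        q_sub = query.intensity[matched_q]
        remap = {i: k for k, i in enumerate(matched_q)}
        sim_rev = _similarity(
            q_sub, reference.intensity, [(remap[i], j) for i, j in pairs]
        )
    else:
        sim_rev = 0.0
    return MatchResult(
        match=int(round(999 * sim)),
        reverse_match=int(round(999 * sim_rev)),
        n_matched_peaks=len(pairs),
        precursor_ok=abs(query.precursor_mz - reference.precursor_mz)
        <= precursor_tol,
    )


def validate_candidate(
    matches: list[MatchResult],
    match_min: int = 500,
    rmatch_min: int = 700,
) -> str:
    """'validated' | 'rejected' | 'not_testable' for one candidate.

    Validated iff any tested peptide reaches both thresholds; rejected iff
    every tested peptide fails; not testable when no spectra could be
    acquired (e.g. the synthetic peptide did not ionize).
    """
    if not matches:
        return "not_testable"
    for m in matches:
        if m.match >= match_min and m.reverse_match >= rmatch_min:
            return "validated"
    return "rejected"


# ---------------------------------------------------------------------------
# MGF-style peak list I/O
# ---------------------------------------------------------------------------

def read_mgf(path) -> dict[str, Spectrum]:
    spectra: dict[str, Spectrum] = {}
    with pt_mgf.MGF(str(path)) as reader:
        for i, sp in enumerate(reader):
            params = sp["params"]
            charge = int(params.get("charge", [2])[0])
            title = str(params.get("title", f"spectrum_{i}"))
            spectra[title] = Spectrum(
                precursor_mz=float(params["pepmass"][0]),
                charge=charge,
                mz=sp["m/z array"],
                intensity=sp["intensity array"],
            )
    return spectra


def write_mgf(spectra: dict[str, Spectrum], path) -> None:
    entries = [
        {
            "m/z array": sp.mz,
            "intensity array": sp.intensity,
            "params": {
                "title": title,
                "pepmass": sp.precursor_mz,
                "charge": sp.charge,
            },
        }
        for title, sp in spectra.items()
    ]
    pt_mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Physicochemical descriptors
# ---------------------------------------------------------------------------

def gravy(protein: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle index per residue."""
    protein = _check_standard(protein)
    return sum(KYTE_DOOLITTLE[aa] for aa in protein) / len(protein)


def net_charge(protein: str, ph: float, pka_set=BJELLQVIST) -> float:
    """Henderson-Hasselbalch net charge of a protein at a given pH."""
    protein = _check_standard(protein)
    nterm = pka_set["nterm"].get(protein[0], pka_set["nterm"]["default"])
    cterm = pka_set["cterm"].get(protein[-1], pka_set["cterm"]["default"])
    pos = 1.0 / (1.0 + 10 ** (ph - nterm))
    neg = 1.0 / (1.0 + 10 ** (cterm - ph))
    for aa, pka in pka_set["positive"].items():
        pos += protein.count(aa) / (1.0 + 10 ** (ph - pka))
    for aa, pka in pka_set["negative"].items():
        neg += protein.count(aa) / (1.0 + 10 ** (pka - ph))
    return pos - neg


def isoelectric_point(
    protein: str, pka_set=BJELLQVIST, tol: float = 0.001
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if net_charge(protein, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def aliphatic_index(protein: str) -> float:
    """AI = X(Ala) + 2.9 X(Val) + 3.9 (X(Ile) + X(Leu)), X in mole percent."""
    protein = _check_standard(protein)
    n = len(protein)
    x = {aa: 100.0 * protein.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


# ---------------------------------------------------------------------------
# Abundance normalizations
# ---------------------------------------------------------------------------

def nsaf(psm_counts, lengths) -> dict[str, float]:
    """Normalized spectral abundance factor; values sum to 1."""
    keys = list(psm_counts)
    if any(lengths[k] <= 0 for k in keys):
        raise ValueError("lengths must be positive")
    saf = {k: psm_counts[k] / lengths[k] for k in keys}
    total = sum(saf.values())
    if total == 0:
        raise ValueError("all PSM counts are zero")
    return {k: v / total for k, v in saf.items()}


def tpm(read_counts, gene_lengths) -> dict[str, float]:
    """Transcripts per million; values sum to 1e6."""
    keys = list(read_counts)
    if any(gene_lengths[k] <= 0 for k in keys):
        raise ValueError("gene lengths must be positive")
    rate = {k: read_counts[k] / gene_lengths[k] for k in keys}
    total = sum(rate.values())
    if total == 0:
        raise ValueError("all read counts are zero")
    return {k: 1e6 * v / total for k, v in rate.items()}


def resolve_multimap(unique_counts, multimapped_total: float, n_copies: int | None = None):
    """Distribute multi-mapping reads evenly over duplicated gene copies."""
    if n_copies is None:
        n_copies = len(unique_counts)
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    if multimapped_total < 0 or any(u < 0 for u in unique_counts):
        raise ValueError("counts must be non-negative")
    share = multimapped_total / n_copies
    return [u + share for u in unique_counts]
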