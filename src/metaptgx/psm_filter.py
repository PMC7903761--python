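"""PSM ingestion, identification rules, and novel small-protein calling.

Search engines are consumed, never run: their exported PSM tables are
normalized into records, q-values are estimated from target-decoy
competition when the engine did not provide them, and proteins are called
identified under engine-specific gates (a unique 1a/3a peptide, protein
q <= 0.01, plus a summed-score or PSM-count gate).  Novel small-protein
candidates are then identified entries of <= 100 aa whose annotation
cluster has no reference-source member, filtered by an annotation-source-
dependent PSM threshold: predictions from weaker evidence sources must be
supported by more spectra (reference 2, ab initio predictors 3, bare in
silico ORFs 4 PSMs by default, summed over proteases and engines).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

from . import digest_classify as dc
from .db_builder import DECOY_PREFIX, SearchDb, SPROTEIN_MAX_LEN

DEFAULT_SOURCE_THRESHOLDS = {
    "reference": 2,
    "refseq": 2,
    "prodigal": 3,
    "chemgenome": 3,
    "predictor": 3,
    "insilico": 4,
}
PROTEIN_Q_MAX = 0.01
_FLANK_RE = re.compile(r"^(?:([A-Z\-]|\[.\])\.)?([A-Za-z]+)(?:\.([A-Z\-]|\[.\]))?$")

DIALECTS = {
    "generic": {
        "spectrum": "spectrum_id",
        "peptide": "peptide",
        "charge": "charge",
        "score": "score",
        "proteins": "proteins",
        "qvalue": "qvalue",
    },
    "pd": {
        "spectrum": "First Scan",
        "peptide": "Annotated Sequence",
        "charge": "Charge",
        "score": "XCorr",
        "proteins": "Protein Accessions",
        "qvalue": "Percolator q-Value",
    },
    "msgf": {
        "spectrum": "SpecID",
        "peptide": "Peptide",
        "charge": "Charge",
        "score": "MSGFScore",
        "proteins": "Protein",
        "qvalue": "QValue",
    },
}


@dataclass
class PsmRecord:
    spectrum_id: str
    peptide: str
    charge: int
    engine: str
    protease: str
    score: float
    qvalue: float | None = None
    is_decoy: bool = False
    entry_ids: tuple[str, ...] = ()
    flanks: tuple[str | None, str | None] = (None, None)


def strip_flanks(peptide: str) -> tuple[str, tuple[str | None, str | None]]:
    """Normalize 'K.AAAR.D'-style notation to the bare peptide + flanks."""
    m = _FLANK_RE.match(peptide.strip())
    if not m:
        raise ValueError(f"unparseable peptide field {peptide!r}")
    return m.group(2).upper(), (m.group(1), m.group(3))


def load_psm_table(
    path,
    dialect: str | dict = "generic",
    engine: str = "other",
    protease: str = "trypsin",
    sep: str = "\t",
) -> list[PsmRecord]:
    """Read one engine x protease PSM export into normalized records."""
    cols = DIALECTS[dialect] if isinstance(dialect, str) else dialect
    frame = pd.read_csv(path, sep=sep)
    if frame.empty:
        raise ValueError(f"empty PSM table: {path}")
    missing = [
        cols[k] for k in ("spectrum", "peptide", "score") if cols[k] not in frame
    ]
    if missing:
        raise ValueError(f"PSM table {path} lacks mandatory columns {missing}")
    records: list[PsmRecord] = []
    for _, row in frame.iterrows():
        peptide, flanks = strip_flanks(str(row[cols["peptide"]]))
        raw = row.get(cols["proteins"], "")
        ids = tuple(
            p for p in str(raw).replace(",", ";").split(";") if p and p != "nan"
        )
        qv = row.get(cols.get("qvalue", ""), None)
        records.append(
            PsmRecord(
                spectrum_id=str(row[cols["spectrum"]]),
                peptide=peptide,
                charge=int(row.get(cols.get("charge", ""), 2) or 2),
                engine=engine,
                protease=protease,
                score=float(row[cols["score"]]),
                qvalue=None if qv is None or (isinstance(qv, float) and math.isnan(qv)) else float(qv),
                is_decoy=bool(ids) and all(i.startswith(DECOY_PREFIX) for i in ids),
                entry_ids=ids,
                flanks=flanks,
            )
        )
    return records


def write_psm_table(records: list[PsmRecord], path, sep: str = "\t") -> None:
    rows = [
        {
            "spectrum_id": r.spectrum_id,
            "peptide": r.peptide,
            "charge": r.charge,
            "score": r.score,
            "proteins": ";".join(r.entry_ids),
            "qvalue": "" if r.qvalue is None else r.qvalue,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Target-decoy FDR
# ---------------------------------------------------------------------------

def _qvalues(scored: list[tuple[float, bool]]) -> list[float]:
    """q-values for (score, is_decoy) items, higher score = better.

    q at score s = min over thresholds accepting s of #decoys/#targets at
    that threshold, capped at 1; monotone non-increasing in score.
    """
    thresholds = sorted({s for s, _d in scored}, reverse=True)
    nt = nd = 0
    groups: dict[float, float] = {}
    by_score: dict[float, list[int]] = {}
    for i, (s, _d) in enumerate(scored):
        by_score.setdefault(s, []).append(i)
    for t in thresholds:  # tied scores are counted together at one threshold
        for i in by_score[t]:
            if scored[i][1]:
                nd += 1
            else:
                nt += 1
        groups[t] = min(nd / max(nt, 1), 1.0)
    qs = [0.0] * len(scored)
    running = 1.0
    for t in reversed(thresholds):
        running = min(running, groups[t])
        for i in by_score[t]:
            qs[i] = running
    return qs


def target_decoy_fdr(
    records: list[PsmRecord],
    level: str = "psm",
    score_direction: str = "higher_better",
):
    """Estimate q-values by target-decoy competition.

    At PSM level every record is annotated in place and the list returned.
    At protein level each entry's score is its best PSM score; a mapping
    entry_id -> q-value is returned (decoy entries included).
    """
    if not any(r.is_decoy for r in records):
        raise ValueError(
            "no decoy PSMs present: search against a decoy-containing database "
            "or supply engine q-values"
        )
    sign = 1.0 if score_direction == "higher_better" else -1.0
    if level == "psm":
        qs = _qvalues([(sign * r.score, r.is_decoy) for r in records])
        for r, q in zip(records, qs):
            r.qvalue = q
        return records
    if level == "protein":
        best: dict[str, float] = {}
        decoy: dict[str, bool] = {}
        for r in records:
            for eid in r.entry_ids:
                s = sign * r.score
                if eid not in best or s > best[eid]:
                    best[eid] = s
                decoy[eid] = eid.startswith(DECOY_PREFIX)
        eids = sorted(best)
        qs = _qvalues([(best[e], decoy[e]) for e in eids])
        return dict(zip(eids, qs))
    raise ValueError(f"unknown level {level!r}")


# ---------------------------------------------------------------------------
# Identification and novelty filtering
# ---------------------------------------------------------------------------

@dataclass
class Evidence:
    """Per-entry identification evidence across proteases and engines."""

    entry_id: str
    peptides: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    psms: dict[tuple[str, str], int] = field(default_factory=dict)
    classes: set[str] = field(default_factory=set)
    protein_q: float | None = None

    @property
    def total_psms(self) -> int:
        return sum(self.psms.values())

    def psms_by_protease(self, protease: str) -> int:
        return sum(n for (p, _e), n in self.psms.items() if p == protease)

    def peptides_by_protease(self, protease: str) -> set[str]:
        out: set[str] = set()
        for (p, _e), peps in self.peptides.items():
            if p == protease:
                out |= peps
        return out


def identify_proteins(
    records: list[PsmRecord],
    db: SearchDb,
    indexes: dict[str, dc.PeptideIndex],
    protein_q_max: float = PROTEIN_Q_MAX,
    engine_rules: dict[str, dict] | None = None,
) -> dict[str, Evidence]:
    """Apply the identification rules per engine and merge the evidence.

    An entry is identified iff, for at least one engine run: (a) >= 1
    peptide of class 1a or 3a maps to it, (b) its protein-level q-value is
    <= ``protein_q_max`` (estimated per engine from decoy competition, or
    taken from engine-provided q-values), and (c) the engine gate holds —
    sequest: summed score >= 2; msgf and others: >= 2 PSMs.
    """
    engine_rules = engine_rules or {
        "sequest": {"min_summed_score": 2.0},
        "msgf": {"min_psms": 2},
        "other": {"min_psms": 2},
    }
    evidence: dict[str, Evidence] = {}
    identified: set[str] = set()
    by_engine: dict[str, list[PsmRecord]] = {}
    for r in records:
        by_engine.setdefault(r.engine, []).append(r)
    for engine, recs in by_engine.items():
        has_decoys = any(r.is_decoy for r in recs)
        if has_decoys:
            protein_q = target_decoy_fdr(recs, level="protein")
        else:
            protein_q = {}
            for r in recs:  # fall back to best engine-provided q per entry
                if r.qvalue is None:
                    raise ValueError(
                        f"engine {engine!r}: no decoys and no q-values supplied"
                    )
                for eid in r.entry_ids:
                    q = protein_q.get(eid)
                    protein_q[eid] = r.qvalue if q is None else min(q, r.qvalue)
        per_entry_unique: dict[str, list[PsmRecord]] = {}
        for r in recs:
            if r.is_decoy:
                continue
            index = indexes.get(r.protease)
            if index is None:
                raise ValueError(f"no peptide index for protease {r.protease!r}")
            cls = dc.classify_peptide(r.peptide, index)
            if cls not in ("1a", "3a"):
                continue
            for eid in index.entries_for(r.peptide):
                per_entry_unique.setdefault(eid, []).append(r)
                ev = evidence.setdefault(eid, Evidence(entry_id=eid))
                key = (r.protease, engine)
                ev.peptides.setdefault(key, set()).add(
                    index.key(r.peptide)
                )
                ev.psms[key] = ev.psms.get(key, 0) + 1
                ev.classes.add(cls)
        rule = engine_rules.get(engine, engine_rules["other"])
        for eid, unique_recs in per_entry_unique.items():
            q = protein_q.get(eid)
            if q is None or q > protein_q_max:
                continue
            ev = evidence[eid]
            if ev.protein_q is None or q < ev.protein_q:
                ev.protein_q = q
            if "min_summed_score" in rule:
                if sum(r.score for r in unique_recs) < rule["min_summed_score"]:
                    continue
            if "min_psms" in rule and len(unique_recs) < rule["min_psms"]:
                continue
            identified.add(eid)
    return {eid: evidence[eid] for eid in sorted(identified)}


@dataclass
class CandidateReport:
    """Per-candidate row of the novel small-protein report."""

    entry_id: str
    species: str
    source: str
    full_length: int
    sequence: str
    trypsin_peptides: int = 0
    trypsin_psms: int = 0
    aspn_peptides: int = 0
    aspn_psms: int = 0
    total_psms: int = 0
    classes: tuple[str, ...] = ()
    novel: bool = False
    passed: bool = False
    threshold: int = 0
    validation_status: str = "not_testable"
    known: bool = False
    characterization: dict = field(default_factory=dict)


def call_novel_sproteins(
    identified: dict[str, Evidence],
    db: SearchDb,
    source_thresholds: dict[str, int] | None = None,
    sprotein_max_len: int = SPROTEIN_MAX_LEN,
    per_protease: bool = False,
) -> list[CandidateReport]:
    """Filter identified entries down to novel small-protein candidates.

    Novelty is defined at the cluster level: the candidate's annotation
    cluster must have no reference-source member, which automatically
    excludes proteolytic maturation products of annotated proteins (their
    peptides map to reference-anchored entries).  The PSM threshold of the
    candidate's anchor source is applied to the 1a/3a PSM count summed over
    proteases and engines (or per protease with ``per_protease``).
    """
    thresholds = dict(DEFAULT_SOURCE_THRESHOLDS)
    if source_thresholds:
        thresholds.update(source_thresholds)
    reference = db.provenance.get("reference_source", "refseq")
    cluster_sources: dict[tuple, set[str]] = {}
    cluster_anchor_source: dict[tuple, str] = {}
    for e in db.targets:
        key = (e.species, *e.cluster_key)
        srcs = cluster_sources.setdefault(key, set())
        srcs.add(e.source)
        for prov in e.provenance:
            srcs.add(prov.split(":", 1)[0])
        if e.role == "anchor":
            cluster_anchor_source[key] = e.source
    report: list[CandidateReport] = []
    for eid, ev in identified.items():
        entry = db.entry(eid)
        key = (entry.species, *entry.cluster_key)
        novel = reference not in cluster_sources.get(key, set())
        anchor_source = cluster_anchor_source.get(key, entry.source)
        if anchor_source not in thresholds:
            raise KeyError(
                f"no PSM threshold configured for source {anchor_source!r}"
            )
        thr = thresholds[anchor_source]
        if per_protease:
            passed = any(
                ev.psms_by_protease(p) >= thr for p in ("trypsin", "aspn")
            )
        else:
            passed = ev.total_psms >= thr
        row = CandidateReport(
            entry_id=eid,
            species=entry.species,
            source=anchor_source,
            full_length=entry.full_length,
            sequence=entry.sequence,
            trypsin_peptides=len(ev.peptides_by_protease("trypsin")),
            trypsin_psms=ev.psms_by_protease("trypsin"),
            aspn_peptides=len(ev.peptides_by_protease("aspn")),
            aspn_psms=ev.psms_by_protease("aspn"),
            total_psms=ev.total_psms,
            classes=tuple(sorted(ev.classes)),
            novel=novel,
            passed=passed,
            threshold=thr,
        )
        if entry.full_length <= sprotein_max_len:
            report.append(row)
    return report


def novel_passing(report: list[CandidateReport]) -> list[CandidateReport]:
    return [r for r in report if r.novel and r.passed]


def report_summary(report) -> dict:
    """Protease-level summary of a candidate report.

    Accepts a list of CandidateReport rows or a DataFrame with
    ``trypsin_psms`` / ``aspn_psms`` columns (e.g. the digitized published
    evidence table).  Overlap% = 100 * |both proteases| / |Asp-N|, rounded;
    reported as None when no Asp-N identifications exist.
    """
    if isinstance(report, pd.DataFrame):
        tp = report["trypsin_psms"].to_numpy()
        ap = report["aspn_psms"].to_numpy()
        species = report.get("species")
    else:
        tp = [r.trypsin_psms for r in report]
        ap = [r.aspn_psms for r in report]
        species = [r.species for r in report]
    trypsin = sum(1 for t in tp if t > 0)
    aspn = sum(1 for a in ap if a > 0)
    both = sum(1 for t, a in zip(tp, ap) if t > 0 and a > 0)
    per_species: dict[str, int] = {}
    if species is not None:
        for sp in species:
            per_species[sp] = per_species.get(sp, 0) + 1
    return {
        "n_candidates": len(tp),
        "trypsin": trypsin,
        "aspn": aspn,
        "trypsin_exclusive": trypsin - both,
        "aspn_exclusive": aspn - both,
        "both": both,
        "overlap_pct": round(100 * both / aspn) if aspn else None,
        "per_species": per_species,
    }


def known_protein_screen(
    report: list[CandidateReport],
    known_sequences,
    il_equivalent: bool = False,
) -> list[CandidateReport]:
    """Flag candidates whose full sequence exactly matches a known protein.

    ``known_sequences`` is an iterable of protein strings or a FASTA path.
    Matched candidates are flagged, not deleted (exact screen only;
    homology searching is out of scope).
    """
    if isinstance(known_sequences, (str, bytes)) or hasattr(known_sequences, "read"):
        from Bio import SeqIO

        known_sequences = [str(r.seq) for r in SeqIO.parse(str(known_sequences), "fasta")]
    known = {dc.peptide_key(s, il_equivalent) for s in known_sequences}
    for row in report:
        row.known = dc.peptide_key(row.sequence, il_equivalent) in known
    return report
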