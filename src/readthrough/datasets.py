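"""Candidate ingestion, inclusion/exclusion filters, and segment-set assembly.

A readthrough candidate is a protein whose stop codon is sometimes decoded,
appending a C-terminal extension that starts at the recoded stop (represented
as the unknown residue X) and runs to the next in-frame stop.  This module
validates candidate tables against a proteome, applies the read-support,
AUG-reinitiation and readthrough-rate filters, and assembles the named
segment datasets used for all downstream comparisons:

==========  ==========================================================
NonTRC      proteome minus candidate-gene products
TRC         candidate proteins without their extensions
TRC_C       candidate C-termini of extension-equivalent length
TRC_C30     candidate C-terminal 30-residue segments
TRC_E       the extensions themselves
RAND_C      C-termini of length-matched random non-candidate proteins
==========  ==========================================================

Suffix ``_L`` marks sets filtered for extensions of >= 25 residues, ``_BR``
marks candidates that are evolutionarily conserved or show a readthrough rate
of at least 1.2% of their CDS translation rate.

All spans are 0-based half-open on the *extended* protein: CDS occupies
``[0, L)``, the X residue sits at ``L``, and the extension (which includes X
and counts it toward its length) occupies ``[L, L+E)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import read_fasta

logger = logging.getLogger(__name__)

MAX_PROTEIN_LENGTH = 10_000
SEGMENT_SET_NAMES = ("NonTRC", "TRC", "TRC_C", "TRC_C30", "TRC_E", "RAND_C")
EVIDENCE_VALUES = ("conserved", "ribo_profiling", "both")


@dataclass
class Proteome:
    """A reference proteome; proteins longer than 10,000 residues are
    excluded at load (window-based predictors cannot handle them)."""

    records: List[Tuple[str, str]]
    species: str = ""
    n_excluded_too_long: int = 0

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate protein ids in proteome")
        if any(not seq for _, seq in self.records):
            raise ValueError("empty sequence in proteome")
        self._index = {pid: seq for pid, seq in self.records}

    @classmethod
    def from_fasta(cls, path, species: str = "") -> "Proteome":
        records = read_fasta(path)
        kept = [(pid, seq) for pid, seq in records
                if len(seq) <= MAX_PROTEIN_LENGTH]
        return cls(records=kept, species=species,
                   n_excluded_too_long=len(records) - len(kept))

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, pid: str) -> bool:
        return pid in self._index

    def sequence(self, pid: str) -> str:
        return self._index[pid]


@dataclass
class TRCandidate:
    """One readthrough gene: CDS protein plus its X-initial extension."""

    id: str
    cds_protein: str
    extension: str
    extension_nt: Optional[str] = None
    evidence: str = "ribo_profiling"
    readthrough_rate: Optional[float] = None
    reads_rep1: Optional[int] = None
    reads_rep2: Optional[int] = None

    def __post_init__(self) -> None:
        if self.extension.count("X") != 1 or not self.extension.startswith("X"):
            raise ValueError(
                f"{self.id}: extension must contain exactly one X, at its "
                "start (double-readthrough regions are not supported)")
        if self.evidence not in EVIDENCE_VALUES:
            raise ValueError(f"{self.id}: unknown evidence {self.evidence!r}")
        if self.extension_nt is not None:
            if len(self.extension_nt) % 3 != 0:
                raise ValueError(f"{self.id}: extension_nt length not a "
                                 "multiple of 3")
            if len(self.extension_nt) != 3 * len(self.extension):
                raise ValueError(f"{self.id}: extension_nt codon count does "
                                 "not equal extension length")

    @property
    def extended(self) -> str:
        return self.cds_protein + self.extension

    @property
    def cds_length(self) -> int:
        return len(self.cds_protein)

    @property
    def extension_length(self) -> int:
        return len(self.extension)


@dataclass
class Segment:
    protein_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("segment span does not match sequence length")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentSet:
    name: str
    segments: List[Segment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def total_residues(self) -> int:
        return sum(s.length for s in self.segments)

    def sequences(self) -> List[str]:
        return [s.sequence for s in self.segments]


@dataclass
class FilterReport:
    stage: str
    n_input: int
    n_kept: int
    exclusions: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_input != self.n_kept + len(self.exclusions):
            raise ValueError("filter report does not balance")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exclusions, columns=["id", "reason"])


def load_candidates(path) -> List[TRCandidate]:
    """Load a candidate TSV into TRCandidate records.

    Expected columns: id, cds_protein, extension, and optionally
    extension_nt, evidence, readthrough_rate, reads_rep1, reads_rep2.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    out = []
    for row in frame.itertuples(index=False):
        def opt(name, cast):
            val = getattr(row, name, None)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                return None
            return cast(val)
        out.append(TRCandidate(
            id=str(row.id),
            cds_protein=str(row.cds_protein),
            extension=str(row.extension),
            extension_nt=opt("extension_nt", str),
            evidence=getattr(row, "evidence", "ribo_profiling"),
            readthrough_rate=opt("readthrough_rate", float),
            reads_rep1=opt("reads_rep1", int),
            reads_rep2=opt("reads_rep2", int),
        ))
    return out


def candidates_to_frame(candidates: Sequence[TRCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.id, c.cds_protein, c.extension, c.extension_nt, c.evidence,
          c.readthrough_rate, c.reads_rep1, c.reads_rep2)
         for c in candidates],
        columns=["id", "cds_protein", "extension", "extension_nt", "evidence",
                 "readthrough_rate", "reads_rep1", "reads_rep2"])


def _replace(candidate: TRCandidate, **kwargs) -> TRCandidate:
    data = dict(id=candidate.id, cds_protein=candidate.cds_protein,
                extension=candidate.extension,
                extension_nt=candidate.extension_nt,
                evidence=candidate.evidence,
                readthrough_rate=candidate.readthrough_rate,
                reads_rep1=candidate.reads_rep1,
                reads_rep2=candidate.reads_rep2)
    data.update(kwargs)
    return TRCandidate(**data)


def validate_candidates(candidates: Sequence[TRCandidate], proteome: Proteome,
                        ) -> Tuple[List[TRCandidate], FilterReport]:
    """Resolve candidate ids against the proteome.

    A candidate whose id is present is kept unchanged.  One whose id is
    missing is rescued if its CDS sequence is a perfect, equal-length match
    to exactly one proteome entry (it is remapped to that id); otherwise it
    is excluded with a reason.
    """
    ids = [c.id for c in candidates]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate candidate ids: {', '.join(dupes)}")
    seq_index: Dict[str, str] = {}
    for pid, seq in proteome.records:
        seq_index.setdefault(seq, pid)
    kept: List[TRCandidate] = []
    excl: List[Tuple[str, str]] = []
    for cand in candidates:
        if cand.id in proteome:
            kept.append(cand)
        elif cand.cds_protein and cand.cds_protein in seq_index:
            new_id = seq_index[cand.cds_protein]
            logger.info("candidate %s remapped to proteome entry %s by "
                        "exact sequence match", cand.id, new_id)
            kept.append(_replace(cand, id=new_id))
        elif cand.cds_protein:
            excl.append((cand.id, "no_sequence_match"))
        else:
            excl.append((cand.id, "id_not_found"))
    report = FilterReport("validate", len(candidates), len(kept), excl)
    return kept, report


def apply_read_filters(candidates: Sequence[TRCandidate], min_reads: int = 5,
                       ) -> Tuple[List[TRCandidate], FilterReport]:
    """Keep candidates with >= min_reads extension reads in *both* replicates.

    Candidates without read counts (e.g. conserved-evidence cases) pass
    through untouched.
    """
    kept, excl = [], []
    for cand in candidates:
        if cand.reads_rep1 is None or cand.reads_rep2 is None:
            kept.append(cand)
            continue
        if cand.reads_rep1 < 0 or cand.reads_rep2 < 0:
            raise ValueError(f"{cand.id}: negative read count")
        if cand.reads_rep1 >= min_reads and cand.reads_rep2 >= min_reads:
            kept.append(cand)
        else:
            excl.append((cand.id, "low_reads"))
    return kept, FilterReport("reads", len(candidates), len(kept), excl)


def apply_aug_filter(candidates: Sequence[TRCandidate],
                     ) -> Tuple[List[TRCandidate], FilterReport]:
    """Exclude candidates with an ATG in the first three in-frame extension
    codons (possible reinitiation site rather than true readthrough).

    Candidates without nucleotide sequence pass through with a warning.
    """
    kept, excl = [], []
    for cand in candidates:
        if cand.extension_nt is None:
            logger.warning("candidate %s has no extension nucleotide "
                           "sequence; AUG filter not applied", cand.id)
            kept.append(cand)
            continue
        nt = cand.extension_nt.upper().replace("U", "T")
        codons = [nt[i:i + 3] for i in range(0, min(9, len(nt)), 3)]
        if "ATG" in codons:
            excl.append((cand.id, "aug_reinitiation"))
        else:
            kept.append(cand)
    return kept, FilterReport("aug", len(candidates), len(kept), excl)


def sample_length_matched(target_lengths: Sequence[int],
                          donors: Sequence[Tuple[str, int]],
                          rng: np.random.Generator,
                          tolerance: float = 0.05,
                          max_tolerance: float = 0.10,
                          labels: Optional[Sequence[str]] = None,
                          ) -> List[str]:
    """Draw one donor per target, length within +/-tolerance, without
    replacement.

    If no donor falls within the tolerance it is widened in 1-percentage-
    point steps up to ``max_tolerance``; exhaustion raises, naming the
    target.  Shared by RAND_C assembly and the enrichment background.
    """
    labels = list(labels) if labels is not None else [str(i) for i in
                                                      range(len(target_lengths))]
    available = list(donors)
    chosen: List[str] = []
    for label, target in zip(labels, target_lengths):
        tol = tolerance
        pick = None
        while pick is None and tol <= max_tolerance + 1e-12:
            eligible = [i for i, (_, ln) in enumerate(available)
                        if abs(ln - target) <= tol * target]
            if eligible:
                pick = eligible[int(rng.integers(len(eligible)))]
            else:
                tol += 0.01
        if pick is None:
            raise ValueError(f"no length-matched donor within +/-"
                             f"{max_tolerance:.0%} for {label} "
                             f"(length {target})")
        chosen.append(available.pop(pick)[0])
    return chosen


def build_segment_sets(proteome: Proteome, candidates: Sequence[TRCandidate],
                       rng: np.random.Generator, tolerance: float = 0.05,
                       max_tolerance: float = 0.10,
                       ) -> Dict[str, SegmentSet]:
    """Assemble the six named segment datasets (spans on extended proteins).

    TRC_C/TRC_C30/TRC_E/RAND_C are index-aligned across candidates so that
    filtered variants keep matched partners together.  RAND_C donors are
    non-candidate proteins within the length tolerance of the *extended*
    candidate length, sampled without replacement; each donor contributes its
    C-terminus of extension-equivalent length.
    """
    cand_ids = {c.id for c in candidates}
    non_trc = SegmentSet("NonTRC", [
        Segment(pid, 0, len(seq), seq)
        for pid, seq in proteome.records if pid not in cand_ids])
    trc = SegmentSet("TRC", [
        Segment(c.id, 0, c.cds_length, c.cds_protein) for c in candidates])
    trc_c, trc_c30, trc_e = SegmentSet("TRC_C"), SegmentSet("TRC_C30"), SegmentSet("TRC_E")
    for c in candidates:
        L, E = c.cds_length, c.extension_length
        k = min(E, L)  # extensions longer than their protein truncate to it
        trc_c.segments.append(Segment(c.id, L - k, L, c.cds_protein[L - k:]))
        k30 = min(30, L)
        trc_c30.segments.append(Segment(c.id, L - k30, L, c.cds_protein[L - k30:]))
        trc_e.segments.append(Segment(c.id, L, L + E, c.extension))
    donors = [(pid, len(seq)) for pid, seq in proteome.records
              if pid not in cand_ids]
    donor_ids = sample_length_matched(
        [c.cds_length + c.extension_length for c in candidates], donors, rng,
        tolerance=tolerance, max_tolerance=max_tolerance,
        labels=[c.id for c in candidates])
    rand_c = SegmentSet("RAND_C")
    for c, did in zip(candidates, donor_ids):
        dseq = proteome.sequence(did)
        k = min(c.extension_length, len(dseq))
        rand_c.segments.append(
            Segment(did, len(dseq) - k, len(dseq), dseq[len(dseq) - k:]))
    return {s.name: s for s in (non_trc, trc, trc_c, trc_c30, trc_e, rand_c)}


def filter_long(sets: Dict[str, SegmentSet], min_len: int = 25,
                ) -> Dict[str, SegmentSet]:
    """Keep candidates with extensions of at least ``min_len`` residues.

    Filters TRC_E together with its index-matched partner sets; returned
    sets carry the ``_L`` suffix.
    """
    if "TRC_E" not in sets:
        raise ValueError("TRC_E set required for length filtering")
    keep = [i for i, seg in enumerate(sets["TRC_E"].segments)
            if seg.length >= min_len]
    out: Dict[str, SegmentSet] = {}
    for name in ("TRC_E", "TRC_C", "TRC_C30", "RAND_C"):
        if name in sets:
            out[name + "_L"] = SegmentSet(
                name + "_L", [sets[name].segments[i] for i in keep])
    return out


def filter_biologically_relevant(candidates: Sequence[TRCandidate],
                                 min_rate: float = 1.2,
                                 ) -> Tuple[List[TRCandidate], FilterReport]:
    """Keep evolutionarily conserved candidates unconditionally, plus
    profiling-evidence candidates with readthrough rate >= min_rate percent.
    """
    kept, excl = [], []
    for cand in candidates:
        if cand.evidence in ("conserved", "both"):
            kept.append(cand)
        elif cand.readthrough_rate is None:
            raise ValueError(f"{cand.id}: profiling-evidence candidate "
                             "without a readthrough rate")
        elif cand.readthrough_rate >= min_rate:
            kept.append(cand)
        else:
            excl.append((cand.id, "low_rate"))
    return kept, FilterReport("biologically_relevant", len(candidates),
                              len(kept), excl)
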