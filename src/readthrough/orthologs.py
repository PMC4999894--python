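"""Pairwise alignment of orthologous readthrough candidates.

CDS regions align well between orthologs, but the extensions (which start at
the ambiguous X residue) usually do not fit the same alignment — so CDSs and
extensions are aligned *separately* and their percent identities reported
side by side.  Shared extension motifs are then assessed under the
chance-occurrence probability filters (1e-3 and 1e-4).

Alignment is global Needleman-Wunsch with affine gaps (Gotoh), BLOSUM62
substitution scores, and X rescored to 0 against every residue.  The
traceback tie-break is fixed: match/mismatch wins over a gap placed in the
first sequence, which wins over a gap placed in the second — making every
alignment deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from .datasets import TRCandidate
from .motifscan import MotifHit

NEG_INF = float("-inf")
_BLOSUM62: Dict[Tuple[str, str], float] = {}


def blosum62_with_x() -> Dict[Tuple[str, str], float]:
    """BLOSUM62 scores with X scoring 0 against everything (incl. itself)."""
    if not _BLOSUM62:
        mat = substitution_matrices.load("BLOSUM62")
        for a in mat.alphabet:
            for b in mat.alphabet:
                _BLOSUM62[(a, b)] = float(mat[a, b])
        for a in list(mat.alphabet) + ["X"]:
            _BLOSUM62[("X", a)] = 0.0
            _BLOSUM62[(a, "X")] = 0.0
    return _BLOSUM62


@dataclass
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    @property
    def identity(self) -> float:
        """Identical columns / alignment length, in percent."""
        same = sum(1 for x, y in zip(self.aligned_a, self.aligned_b)
                   if x == y and x != "-")
        return 100.0 * same / self.length

    def column_of_a(self) -> List[int]:
        """Alignment column index of each residue of sequence a."""
        return [i for i, c in enumerate(self.aligned_a) if c != "-"]

    def column_of_b(self) -> List[int]:
        return [i for i, c in enumerate(self.aligned_b) if c != "-"]


def global_align(a: str, b: str,
                 matrix: Optional[Dict[Tuple[str, str], float]] = None,
                 gap_open: float = 10.0, gap_extend: float = 0.5) -> Alignment:
    """Optimal global alignment with affine gaps (a gap of length k costs
    ``gap_open + (k-1) * gap_extend``).

    Deterministic tie-break: diagonal (match/mismatch) is preferred over a
    gap in ``a``, which is preferred over a gap in ``b``.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    sub = matrix if matrix is not None else blosum62_with_x()
    n, m = len(a), len(b)
    # state 0 = diagonal, 1 = gap in a (consumes b), 2 = gap in b (consumes a)
    M = np.full((n + 1, m + 1), NEG_INF)
    GA = np.full((n + 1, m + 1), NEG_INF)  # '-' in a
    GB = np.full((n + 1, m + 1), NEG_INF)  # '-' in b
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        GA[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        GB[i, 0] = -gap_open - (i - 1) * gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub[(ai, b[j - 1])]
            M[i, j] = max(M[i - 1, j - 1], GA[i - 1, j - 1],
                          GB[i - 1, j - 1]) + s
            GA[i, j] = max(M[i, j - 1] - gap_open,
                           GA[i, j - 1] - gap_extend,
                           GB[i, j - 1] - gap_open)
            GB[i, j] = max(M[i - 1, j] - gap_open,
                           GB[i - 1, j] - gap_extend,
                           GA[i - 1, j] - gap_open)
    # traceback; candidate order (M, GA, GB) encodes the tie-break
    i, j = n, m
    tol = 1e-9
    score = max(M[n, m], GA[n, m], GB[n, m])
    for state in (0, 1, 2):
        if abs((M[n, m], GA[n, m], GB[n, m])[state] - score) <= tol:
            break
    out_a: List[str] = []
    out_b: List[str] = []
    while i > 0 or j > 0:
        if state == 0:
            target = M[i, j] - sub[(a[i - 1], b[j - 1])]
            cands = (M[i - 1, j - 1], GA[i - 1, j - 1], GB[i - 1, j - 1])
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            target = GA[i, j]
            cands = (M[i, j - 1] - gap_open, GA[i, j - 1] - gap_extend,
                     GB[i, j - 1] - gap_open)
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        else:
            target = GB[i, j]
            cands = (M[i - 1, j] - gap_open, GA[i - 1, j] - gap_open,
                     GB[i - 1, j] - gap_extend)
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        if i == 0 and j == 0:
            break
        for cand_state in (0, 1, 2):
            if cands[cand_state] > NEG_INF and abs(cands[cand_state] - target) <= tol:
                state = cand_state
                break
        else:  # pragma: no cover - would indicate a DP bookkeeping bug
            raise RuntimeError("traceback failed")
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                     float(score))


@dataclass
class SharedMotifReport:
    shared_1e3: List[str] = field(default_factory=list)
    shared_1e4: List[str] = field(default_factory=list)
    require_overlap: bool = False


@dataclass
class OrthologPair:
    id_a: str
    id_b: str
    cds_alignment: Alignment
    extension_alignment: Alignment
    shared_motifs: Optional[SharedMotifReport] = None

    @property
    def cds_identity(self) -> float:
        return self.cds_alignment.identity

    @property
    def extension_identity(self) -> float:
        return self.extension_alignment.identity


def align_pair(cand_a: TRCandidate, cand_b: TRCandidate,
               gap_open: float = 10.0, gap_extend: float = 0.5,
               ) -> OrthologPair:
    """Align CDS regions and extensions (from the X onward) separately."""
    if not cand_a.extension or not cand_b.extension:
        raise ValueError("both candidates must carry extensions")
    cds_aln = global_align(cand_a.cds_protein, cand_b.cds_protein,
                           gap_open=gap_open, gap_extend=gap_extend)
    ext_aln = global_align(cand_a.extension, cand_b.extension,
                           gap_open=gap_open, gap_extend=gap_extend)
    return OrthologPair(cand_a.id, cand_b.id, cds_aln, ext_aln)


def shared_motifs(pair: OrthologPair,
                  hits_a: Sequence[MotifHit], hits_b: Sequence[MotifHit],
                  p_max: float = 1e-3, require_overlap: bool = False,
                  ext_offset_a: int = 0, ext_offset_b: int = 0,
                  ) -> SharedMotifReport:
    """Motif types present in both partners' extensions below ``p_max``.

    By default co-occurrence of the motif type is enough; with
    ``require_overlap`` the two hit spans must additionally share at least
    one column of the extension alignment (hit spans are taken in extension
    coordinates after subtracting the offsets).  The report always lists the
    shared types at both 1e-3 and 1e-4 probability cuts.
    """
    def shared_at(cut: float) -> List[str]:
        a_by_id: Dict[str, List[MotifHit]] = {}
        for h in hits_a:
            if h.probability < cut:
                a_by_id.setdefault(h.elm_id, []).append(h)
        b_by_id: Dict[str, List[MotifHit]] = {}
        for h in hits_b:
            if h.probability < cut:
                b_by_id.setdefault(h.elm_id, []).append(h)
        common = sorted(set(a_by_id) & set(b_by_id))
        if not require_overlap:
            return common
        col_a = pair.extension_alignment.column_of_a()
        col_b = pair.extension_alignment.column_of_b()
        kept = []
        for elm_id in common:
            found = False
            for ha in a_by_id[elm_id]:
                ca = {col_a[p] for p in range(ha.span[0] - ext_offset_a,
                                              ha.span[1] - ext_offset_a)
                      if 0 <= p < len(col_a)}
                for hb in b_by_id[elm_id]:
                    cb = {col_b[p] for p in range(hb.span[0] - ext_offset_b,
                                                  hb.span[1] - ext_offset_b)
                          if 0 <= p < len(col_b)}
                    if ca & cb:
                        found = True
                        break
                if found:
                    break
            if found:
                kept.append(elm_id)
        return kept

    report = SharedMotifReport(shared_1e3=shared_at(min(p_max, 1e-3)),
                               shared_1e4=shared_at(1e-4),
                               require_overlap=require_overlap)
    if p_max not in (1e-3, 1e-4):
        report.shared_1e3 = shared_at(p_max)
    return report
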