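"""Per-residue structural annotation of full-length (extended) proteins.

Five tracks are produced for every protein: intrinsic-disorder score,
low-complexity flag, three-state secondary structure, disordered-binding-site
score, and Pfam-entity occupancy (taken from annotation input, never
predicted).  Window-based scorers see the residue in its natural sequence
context, so segments of interest are always *excised* from full-protein tracks
rather than re-predicted in isolation — windows deliberately cross the
CDS/extension junction.

The disorder, secondary-structure and binding scorers are simplified,
propensity-table stand-ins (tables in :mod:`readthrough.config`); real
predictor output can replace any track via :func:`import_scores`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AMINO_ACIDS, PredictorConfig

SCORE_TRACKS = ("disorder", "binding")
ALL_TRACKS = ("disorder", "low_complexity", "ss_class", "binding", "pfam")


@dataclass
class ResidueAnnotation:
    """Per-residue tracks for one protein (or an excised segment of one)."""

    protein_id: str
    sequence: str
    disorder: np.ndarray
    low_complexity: np.ndarray
    ss_class: np.ndarray
    binding: np.ndarray
    pfam: np.ndarray
    span: Optional[Tuple[int, int]] = None  # set on excised views

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name in ("disorder", "low_complexity", "ss_class", "binding", "pfam"):
            track = getattr(self, name)
            if len(track) != n:
                raise ValueError(f"track {name!r} has length {len(track)} != {n}")
        for name in SCORE_TRACKS:
            track = getattr(self, name)
            if track.size and (track.min() < 0.0 or track.max() > 1.0):
                raise ValueError(f"track {name!r} has scores outside [0, 1]")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def x_mask(self) -> np.ndarray:
        return np.frombuffer(self.sequence.encode(), dtype="S1") == b"X"


def _propensity_values(sequence: str, table: Dict[str, float]) -> np.ndarray:
    """Map residues to propensities; X gets the table mean, anything else errors."""
    mean = float(np.mean(list(table.values())))
    try:
        return np.array([mean if c == "X" else table[c] for c in sequence])
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in sequence") from exc


def _windowed_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean with truncated (not padded) terminal windows."""
    n = values.size
    left = (window - 1) // 2
    right = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def disorder_track(sequence: str, config: Optional[PredictorConfig] = None) -> np.ndarray:
    """Disorder score per residue: logistic of the windowed mean propensity.

    ``score_i = logistic(gain * (mean propensity in window at i - center))``.
    Deterministic; a length-1 sequence degenerates to its single residue.
    """
    config = config or PredictorConfig()
    if not sequence:
        raise ValueError("empty sequence")
    vals = _propensity_values(sequence, config.disorder_propensity)
    means = _windowed_mean(vals, config.disorder_window)
    return _logistic(config.disorder_logistic_gain *
                     (means - config.disorder_logistic_center))


def window_entropies(sequence: str, window: int) -> np.ndarray:
    """Shannon entropy K2 (bits) of the residue composition of each window.

    Windows are ``sequence[i:i+window]``; a sequence shorter than ``window``
    is evaluated as a single window of its own length.  X residues occupy
    positions but are excluded from the composition (the entropy denominator
    is the count of non-X residues in the window).
    """
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    w = min(window, n)
    # integer-encode, X -> -1
    alpha = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    codes = np.array([alpha.get(c, -1) for c in sequence], dtype=np.int64)
    n_win = n - w + 1
    out = np.empty(n_win)
    counts = np.zeros(20, dtype=np.int64)
    for j in codes[:w]:
        if j >= 0:
            counts[j] += 1
    for i in range(n_win):
        k = counts.sum()
        if k == 0:
            out[i] = 0.0
        else:
            c = counts[counts > 0]
            p = c / k
            out[i] = float(-(p * np.log2(p)).sum())
        if i + 1 < n_win:
            old, new = codes[i], codes[i + w]
            if old >= 0:
                counts[old] -= 1
            if new >= 0:
                counts[new] += 1
    return out


def seg_lowcomplexity(sequence: str, config: Optional[PredictorConfig] = None) -> np.ndarray:
    """Boolean low-complexity track via two-threshold windowed entropy.

    Windows whose composition entropy K2 is at or below the trigger threshold
    seed a region; the region extends across contiguous windows at or below
    the extension threshold; every residue covered by a retained window is
    flagged.  This is a trigger/extend dialect without the original SEG
    program's minimal-probability subsequence refinement.
    """
    config = config or PredictorConfig()
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    w = min(config.seg_window, n)
    k2 = window_entropies(sequence, w)
    trig = k2 <= config.seg_trigger
    ext = k2 <= config.seg_extend
    mask = np.zeros(n, dtype=bool)
    i = 0
    n_win = len(k2)
    while i < n_win:
        if not ext[i]:
            i += 1
            continue
        j = i
        while j < n_win and ext[j]:
            j += 1
        if trig[i:j].any():  # run is retained only if it contains a trigger
            mask[i:j - 1 + w] = True
        i = j
    return mask


def ss_track(sequence: str, config: Optional[PredictorConfig] = None) -> np.ndarray:
    """Three-state secondary structure per residue (H, E or C).

    Class is the argmax of windowed mean helix/strand propensities when that
    mean exceeds 1.0, otherwise coil; exact ties above threshold go to H.
    """
    config = config or PredictorConfig()
    if not sequence:
        raise ValueError("empty sequence")
    h = _windowed_mean(_propensity_values(sequence, config.ss_helix_propensity),
                       config.ss_window)
    e = _windowed_mean(_propensity_values(sequence, config.ss_strand_propensity),
                       config.ss_window)
    out = np.full(len(sequence), "C", dtype="<U1")
    helix = (h > config.ss_threshold) & (h >= e)
    strand = (e > config.ss_threshold) & (e > h)
    out[strand] = "E"
    out[helix] = "H"
    return out


def binding_track(sequence: str, disorder: np.ndarray,
                  config: Optional[PredictorConfig] = None) -> np.ndarray:
    """Disordered-binding-site score: interaction propensity gated by disorder.

    ``binding_i = gate_i * logistic(gain_b * (windowed interaction propensity
    - center_b))`` with ``gate_i = 1`` iff ``disorder_i >= theta_elm_disorder``
    — a region must look disordered in isolation to qualify as a fold-on-
    binding site.
    """
    config = config or PredictorConfig()
    if len(disorder) != len(sequence):
        raise ValueError("disorder track length does not match sequence")
    vals = _propensity_values(sequence, config.binding_interaction_propensity)
    means = _windowed_mean(vals, config.binding_window)
    raw = _logistic(config.binding_logistic_gain *
                    (means - config.binding_logistic_center))
    gate = np.asarray(disorder) >= config.theta_elm_disorder
    return np.where(gate, raw, 0.0)


def binding_sites(binding: np.ndarray, theta: float = 0.5) -> List[Tuple[int, int]]:
    """Maximal runs with binding score >= theta, as 0-based half-open spans."""
    mask = np.asarray(binding) >= theta
    spans: List[Tuple[int, int]] = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            spans.append((i, j))
            i = j
        else:
            i += 1
    return spans


def _pfam_mask(length: int, spans: Iterable[Tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for start, end in spans:
        if start < 0 or end > length or start >= end:
            raise ValueError(f"pfam span ({start}, {end}) outside protein "
                             f"of length {length}")
        mask[start:end] = True
    return mask


def annotate(protein_id: str, sequence: str,
             pfam_spans: Iterable[Tuple[int, int]] = (),
             config: Optional[PredictorConfig] = None) -> ResidueAnnotation:
    """Run all tracks once on the full extended sequence (CDS + X + extension).

    Pfam-entity spans come from annotation input (all entity types accepted);
    overlapping spans are unioned.
    """
    config = config or PredictorConfig()
    dis = disorder_track(sequence, config)
    return ResidueAnnotation(
        protein_id=protein_id,
        sequence=sequence,
        disorder=dis,
        low_complexity=seg_lowcomplexity(sequence, config),
        ss_class=ss_track(sequence, config),
        binding=binding_track(sequence, dis, config),
        pfam=_pfam_mask(len(sequence), pfam_spans),
    )


def excise(annotation: ResidueAnnotation, span: Tuple[int, int]) -> ResidueAnnotation:
    """Return the stored per-residue values over ``span`` — never re-predicted.

    Idempotent: excising the full span returns identical tracks.
    """
    start, end = span
    if start < 0 or end > annotation.length or start >= end:
        raise ValueError(f"span ({start}, {end}) outside annotation of "
                         f"length {annotation.length}")
    base = annotation.span[0] if annotation.span else 0
    return ResidueAnnotation(
        protein_id=annotation.protein_id,
        sequence=annotation.sequence[start:end],
        disorder=annotation.disorder[start:end].copy(),
        low_complexity=annotation.low_complexity[start:end].copy(),
        ss_class=annotation.ss_class[start:end].copy(),
        binding=annotation.binding[start:end].copy(),
        pfam=annotation.pfam[start:end].copy(),
        span=(base + start, base + end),
    )


def import_scores(path, track: str) -> Dict[str, np.ndarray]:
    """Load a per-residue score TSV (protein id, 0-based position, value).

    Positions must be contiguous from 0 for every protein; score tracks
    (disorder, binding) must lie in [0, 1].  Returns protein id -> values.
    """
    if track not in ALL_TRACKS:
        raise ValueError(f"unknown track {track!r}; expected one of {ALL_TRACKS}")
    frame = pd.read_csv(path, sep="\t", comment="#")
    out: Dict[str, np.ndarray] = {}
    for pid, grp in frame.groupby(frame.columns[0], sort=False):
        pos = grp.iloc[:, 1].to_numpy()
        if len(pos) != len(set(pos)):
            raise ValueError(f"duplicate positions for protein {pid!r}")
        order = np.argsort(pos)
        pos = pos[order]
        if pos[0] != 0 or not np.array_equal(pos, np.arange(len(pos))):
            raise ValueError(f"positions for protein {pid!r} are not "
                             "contiguous from 0")
        vals = grp.iloc[:, 2].to_numpy()[order]
        if track in SCORE_TRACKS:
            vals = vals.astype(float)
            if vals.min() < 0.0 or vals.max() > 1.0:
                raise ValueError(f"{track} values for {pid!r} outside [0, 1]")
        elif track in ("low_complexity", "pfam"):
            vals = vals.astype(bool)
        out[str(pid)] = vals
    return out


def overlay_track(annotation: ResidueAnnotation, track: str,
                  values: np.ndarray) -> ResidueAnnotation:
    """Replace one built-in track with imported values; other tracks untouched."""
    if len(values) != annotation.length:
        raise ValueError("imported track length does not match protein")
    kwargs = dict(
        protein_id=annotation.protein_id, sequence=annotation.sequence,
        disorder=annotation.disorder, low_complexity=annotation.low_complexity,
        ss_class=annotation.ss_class, binding=annotation.binding,
        pfam=annotation.pfam, span=annotation.span,
    )
    kwargs[track] = np.asarray(values)
    return ResidueAnnotation(**kwargs)


def export_scores(path, annotations: Sequence[ResidueAnnotation], track: str) -> None:
    """Write one track of several proteins as a per-residue TSV."""
    rows = []
    for ann in annotations:
        vals = getattr(ann, track)
        for i, v in enumerate(vals):
            rows.append((ann.protein_id, i, v))
    pd.DataFrame(rows, columns=["protein_id", "position", "value"]).to_csv(
        path, sep="\t", index=False)
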