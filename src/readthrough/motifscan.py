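"""Scanning proteins with ELM-style linear-motif patterns.

Patterns are regular expressions over residue classes, each with a chance-
occurrence probability and a set of species tags.  Hits are counted at every
distinct start position (overlapping matches of the same pattern are separate
hits, and multiple patterns matching the same span are distinct hits), then
classified by extension membership and by overlap with predicted disorder and
disordered binding sites.

The stop-codon residue X is tRNA-dependent and therefore matches any residue
class in a pattern position (universal wildcard).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .config import PredictorConfig
from .predictors import ResidueAnnotation, binding_sites


@dataclass(frozen=True)
class MotifPattern:
    elm_id: str
    pattern: str
    probability: float
    taxa: frozenset
    exemplar: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.probability <= 1.0:
            raise ValueError(f"{self.elm_id}: probability must be in (0, 1]")

    def compiled(self) -> "re.Pattern[str]":
        return _compile_with_x(self.pattern, self.elm_id)


@dataclass
class MotifHit:
    elm_id: str
    protein_id: str
    span: Tuple[int, int]
    probability: float
    in_extension: bool = False
    overlaps_disorder: bool = False
    overlaps_binding: bool = False

    def __post_init__(self) -> None:
        if self.span[0] >= self.span[1]:
            raise ValueError("hit span must be non-empty")


def rewrite_pattern_for_x(pattern: str) -> str:
    """Rewrite a residue-class regex so X matches any residue position.

    Literal residue letters become two-letter classes (``P`` -> ``[PX]``) and
    X is appended inside non-negated character classes.  Anchors, groups,
    quantifiers and escapes pass through untouched.
    """
    out: List[str] = []
    i, n = 0, len(pattern)
    while i < n:
        c = pattern[i]
        if c == "\\" and i + 1 < n:
            out.append(pattern[i:i + 2])
            i += 2
        elif c == "[":
            j = i + 1
            negated = j < n and pattern[j] == "^"
            if negated:
                j += 1
            if j < n and pattern[j] == "]":  # literal ] first in class
                j += 1
            while j < n and pattern[j] != "]":
                j += 2 if pattern[j] == "\\" else 1
            if j >= n:
                raise ValueError(f"unterminated character class in {pattern!r}")
            body = pattern[i + 1:j]
            if not negated and "X" not in body:
                out.append(f"[{body}X]")
            else:
                out.append(f"[{body}]")
            i = j + 1
        elif c.isalpha() and c.isupper():
            out.append(f"[{c}X]" if c != "X" else c)
            i += 1
        else:
            out.append(c)
            i += 1
    return "".join(out)


def _compile_with_x(pattern: str, elm_id: str) -> "re.Pattern[str]":
    try:
        return re.compile(rewrite_pattern_for_x(pattern))
    except (re.error, ValueError) as exc:
        raise ValueError(
            f"pattern for {elm_id!r} does not compile: {exc}") from exc


def load_patterns(path, species: Optional[str] = None) -> List[MotifPattern]:
    """Load a pattern TSV (elm_id, pattern, probability, taxa[, exemplar]).

    ``taxa`` is a comma-separated list of species tags; only patterns whose
    taxa include ``species`` are returned (all patterns when species is None).
    Patterns that do not compile raise with the offending elm_id named.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    patterns: List[MotifPattern] = []
    for row in frame.itertuples(index=False):
        taxa = frozenset(t.strip() for t in str(row.taxa).split(","))
        if species is not None and species not in taxa:
            continue
        exemplar = getattr(row, "exemplar", None)
        if exemplar is not None and pd.isna(exemplar):
            exemplar = None
        pat = MotifPattern(elm_id=str(row.elm_id), pattern=str(row.pattern),
                           probability=float(row.probability), taxa=taxa,
                           exemplar=exemplar)
        pat.compiled()  # fail fast, naming the elm_id
        patterns.append(pat)
    return patterns


def scan(protein_id: str, sequence: str,
         patterns: Sequence[MotifPattern]) -> List[MotifHit]:
    """Report every match of every pattern, one hit per distinct start."""
    hits: List[MotifHit] = []
    for pat in patterns:
        rx = pat.compiled()
        for start in range(len(sequence)):
            m = rx.match(sequence, start)
            if m is not None and m.end() > start:
                hits.append(MotifHit(elm_id=pat.elm_id, protein_id=protein_id,
                                     span=(start, m.end()),
                                     probability=pat.probability))
    return hits


def classify(hits: Iterable[MotifHit], annotation: ResidueAnnotation,
             extension_span: Optional[Tuple[int, int]],
             config: Optional[PredictorConfig] = None) -> List[MotifHit]:
    """Set the extension / disorder / binding overlap flags on each hit.

    A single residue of overlap suffices in all three cases: an incomplete
    motif completed by even one extension residue counts as an extension
    motif, and disorder overlap uses the reduced threshold (default 0.4)
    rather than the 0.5 used for disordered-fraction profiles.
    """
    config = config or PredictorConfig()
    sites = binding_sites(annotation.binding, config.theta_binding)
    out: List[MotifHit] = []
    for hit in hits:
        s, e = hit.span
        if s < 0 or e > annotation.length:
            raise ValueError(f"hit span {hit.span} outside annotation of "
                             f"length {annotation.length}")
        in_ext = (extension_span is not None
                  and s < extension_span[1] and e > extension_span[0])
        dis = bool((annotation.disorder[s:e] >= config.theta_elm_disorder).any())
        bind = any(s < be and e > bs for bs, be in sites)
        out.append(MotifHit(elm_id=hit.elm_id, protein_id=hit.protein_id,
                            span=hit.span, probability=hit.probability,
                            in_extension=in_ext, overlaps_disorder=dis,
                            overlaps_binding=bind))
    return out


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (so 6.25 -> 6.3), unlike banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def elm_density(n_motifs: int, n_residues: int) -> Tuple[float, float]:
    """Motifs per 100 residues: (rounded to 1 decimal, raw value)."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    raw = 100.0 * n_motifs / n_residues
    return round_half_away(raw, 1), raw


def low_probability_filter(hits: Iterable[MotifHit],
                           p_max: float = 1e-3) -> List[MotifHit]:
    """Keep hits with chance-occurrence probability strictly below p_max."""
    return [h for h in hits if h.probability < p_max]


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.protein_id, h.elm_id, h.span[0], h.span[1], h.probability,
          h.in_extension, h.overlaps_disorder, h.overlaps_binding)
         for h in hits],
        columns=["protein_id", "elm_id", "start", "end", "probability",
                 "in_extension", "overlaps_disorder", "overlaps_binding"])
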