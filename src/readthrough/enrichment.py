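"""GO-term enrichment against a length-matched sampled background.

Readthrough preferentially affects proteins of biased length, so a naive
whole-proteome background would confound term enrichment with protein
length.  Instead, one non-candidate protein of similar (+/-5%) *unextended*
length is sampled per candidate, and enrichment is computed by the upper-tail
hypergeometric test over the two-list universe (study plus sampled
background), with Benjamini-Hochberg adjustment across terms.  Term sets are
flat: no ontology-graph propagation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datasets import Proteome, sample_length_matched


@dataclass
class EnrichmentResult:
    term_id: str
    study_count: int       # k
    study_size: int        # n
    background_count: int  # K, annotated in the whole universe
    background_size: int   # N, universe size
    fold: float            # (k/n) / (K/N)
    p_raw: float
    p_adjusted: float


def length_matched_background(candidate_ids: Sequence[str],
                              proteome: Proteome,
                              rng: np.random.Generator,
                              tolerance: float = 0.05,
                              max_tolerance: float = 0.10) -> List[str]:
    """One non-candidate donor per candidate, matched on unextended length.

    Donors are sampled without replacement; tolerance widens in 1-point
    steps up to ``max_tolerance`` before erroring.  Deterministic for a
    fixed generator state.
    """
    cand = set(candidate_ids)
    donors = [(pid, len(seq)) for pid, seq in proteome.records
              if pid not in cand]
    targets = [len(proteome.sequence(pid)) for pid in candidate_ids]
    return sample_length_matched(targets, donors, rng, tolerance=tolerance,
                                 max_tolerance=max_tolerance,
                                 labels=list(candidate_ids))


def hypergeom_enrichment(study_ids: Sequence[str],
                         background_ids: Sequence[str],
                         go_map: Dict[str, Sequence[str]],
                         universe: str = "union",
                         proteome: Optional[Proteome] = None,
                         ) -> List[EnrichmentResult]:
    """Per-term upper-tail hypergeometric enrichment of the study set.

    With ``universe='union'`` (default, mirroring a two-list analysis) the
    population is study ∪ background; ``universe='proteome'`` uses the whole
    proteome instead.  p = P(X >= k) for k annotated study ids out of n,
    drawn from N population ids of which K are annotated.  Results carry
    BH-adjusted p-values and are sorted by them.
    """
    study = list(dict.fromkeys(study_ids))
    background = list(dict.fromkeys(background_ids))
    if not study or not background:
        raise ValueError("study and background must both be non-empty")
    if universe == "union":
        population = list(dict.fromkeys(study + background))
    elif universe == "proteome":
        if proteome is None:
            raise ValueError("universe='proteome' requires a proteome")
        population = [pid for pid, _ in proteome.records]
    else:
        raise ValueError(f"unknown universe {universe!r}")
    big_n = len(population)
    n = len(study)
    terms = sorted({t for pid in population for t in go_map.get(pid, ())})
    results = []
    study_set = set(study)
    for term in terms:
        annotated = {pid for pid in population if term in go_map.get(pid, ())}
        big_k = len(annotated)
        k = len(annotated & study_set)
        if k == 0:
            p = 1.0
            fold = 0.0
        else:
            p = float(hypergeom.sf(k - 1, big_n, big_k, n))
            fold = (k / n) / (big_k / big_n)
        results.append(EnrichmentResult(term, k, n, big_k, big_n, fold, p, p))
    if results:
        _, adj, _, _ = multipletests([r.p_raw for r in results],
                                     method="fdr_bh")
        for r, q in zip(results, adj):
            r.p_adjusted = float(q)
    return sorted(results, key=lambda r: (r.p_adjusted, r.p_raw, r.term_id))


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.term_id, r.study_count, r.study_size, r.background_count,
          r.background_size, r.fold, r.p_raw, r.p_adjusted)
         for r in results],
        columns=["term_id", "study_count", "study_size", "population_count",
                 "population_size", "fold", "p_raw", "p_adjusted"])
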