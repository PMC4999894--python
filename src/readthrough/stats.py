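"""Segment- and residue-level statistics for structural profiles.

Segment-based contrasts (distributions of per-segment residue fractions) use
the Mann-Whitney U test for two groups, or Kruskal-Wallis with Dunn's
post-hoc for three or more.  Residue-based contrasts pool all residues of a
segment set and test observed positive counts against an expectation derived
from a reference set's positive fraction, with Yates' continuity-corrected
chi-square.  Bonferroni correction is applied per comparison family; a
D'Agostino-Pearson omnibus test documents why the nonparametric route is
taken.

X residues (the recoded stop) count in every denominator but are never
counted positive for disorder, secondary structure or binding, and are
excluded from amino-acid composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .config import AMINO_ACIDS, PredictorConfig
from .predictors import ResidueAnnotation

PROPERTIES = ("disordered", "low_complexity", "secondary_structure",
              "pfam", "binding_site")


@dataclass
class StructuralProfile:
    """Residue fractions of one segment, with inclusive thresholds."""

    segment_key: str
    length: int
    disordered: float
    low_complexity: float
    secondary_structure: float
    pfam: float
    binding_site: float


@dataclass
class ComparisonResult:
    property: str
    groups: Tuple[str, ...]
    test: str
    statistic: float
    p_raw: float
    p_adjusted: Optional[float] = None
    alpha_corrected: float = 0.05
    n_comparisons: int = 1

    @property
    def significant(self) -> bool:
        p = self.p_raw if self.p_adjusted is None else self.p_adjusted
        return p < self.alpha_corrected


def profile(annotation: ResidueAnnotation,
            config: Optional[PredictorConfig] = None) -> StructuralProfile:
    """Structural profile of an excised segment annotation.

    Fractions use the full segment length (X included) as denominator;
    disorder uses score >= 0.5, binding uses score >= theta_binding, and X
    positions never count positive.
    """
    config = config or PredictorConfig()
    n = annotation.length
    if n == 0:
        raise ValueError("zero-length segment")
    not_x = ~annotation.x_mask
    key = annotation.protein_id
    if annotation.span is not None:
        key = f"{key}:{annotation.span[0]}-{annotation.span[1]}"
    return StructuralProfile(
        segment_key=key,
        length=n,
        disordered=float(((annotation.disorder >= config.theta_disorder) & not_x).sum()) / n,
        low_complexity=float((annotation.low_complexity & not_x).sum()) / n,
        secondary_structure=float((np.isin(annotation.ss_class, ("H", "E")) & not_x).sum()) / n,
        pfam=float((annotation.pfam & not_x).sum()) / n,
        binding_site=float(((annotation.binding >= config.theta_binding) & not_x).sum()) / n,
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for sample a (ties contribute 1/2)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:a.size].sum()
    return float(r1 - a.size * (a.size + 1) / 2.0)


def _exact_mw_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of group labelings.

    p = P(|U - n1*n2/2| >= |U_obs - n1*n2/2|) over all C(n1+n2, n1) ways of
    labeling the pooled values, which handles ties exactly.
    """
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    mu = n1 * n2 / 2.0
    obs_dev = abs(_u_statistic(a, b) - mu)
    offset = n1 * (n1 + 1) / 2.0
    total = 0
    extreme = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= obs_dev - 1e-12:
            extreme += 1
    return extreme / total


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 alpha: float = 0.05, method: str = "auto",
                 property: str = "", groups: Tuple[str, str] = ("a", "b"),
                 ) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    ``method='auto'`` uses full enumeration when both samples have at most 8
    values (exact even under ties) and the tie-corrected normal approximation
    otherwise; 'exact' and 'asymptotic' force a route.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(a, b)
    if method == "exact" or (method == "auto" and a.size <= 8 and b.size <= 8):
        p = _exact_mw_p(a, b)
    else:
        # tie-corrected normal approximation without continuity correction,
        # mirroring the deviation-based definition of the exact test
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic", use_continuity=False)
        p = float(min(p, 1.0))
    return ComparisonResult(property=property, groups=groups,
                            test="mann_whitney", statistic=u, p_raw=p,
                            alpha_corrected=alpha)


def kruskal_dunn(groups: Sequence[Sequence[float]], alpha: float = 0.05,
                 names: Optional[Sequence[str]] = None,
                 property: str = "") -> List[ComparisonResult]:
    """Kruskal-Wallis across >= 3 groups; Dunn's post-hoc when significant.

    Dunn's pairwise z uses pooled mean ranks with tie correction; each raw
    post-hoc p is multiplied by the number of pairwise comparisons (capped at
    1), per the Bonferroni-type adjustment convention.  The omnibus result is
    returned first, followed by one result per pair (when run).
    """
    if len(groups) < 3:
        raise ValueError("kruskal_dunn needs >= 3 groups; "
                         "use mann_whitney for two")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    names = list(names) if names is not None else [f"g{i}" for i in range(len(arrays))]
    if np.ptp(np.concatenate(arrays)) == 0.0:
        h, p_kw = 0.0, 1.0  # all pooled values identical; scipy would raise
    else:
        h, p_kw = sps.kruskal(*arrays)
    results = [ComparisonResult(property=property, groups=tuple(names),
                                test="kruskal_wallis", statistic=float(h),
                                p_raw=float(p_kw), alpha_corrected=alpha)]
    if p_kw >= alpha:
        return results
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_ranks = []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    pairs = list(combinations(range(len(arrays)), 2))
    m = len(pairs)
    for i, j in pairs:
        se = math.sqrt(var_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        results.append(ComparisonResult(
            property=property, groups=(names[i], names[j]), test="dunn",
            statistic=float(z), p_raw=float(p_raw),
            p_adjusted=float(min(1.0, p_raw * m)),
            alpha_corrected=alpha, n_comparisons=m))
    return results


def yates_chi2_residues(obs_positive: int, n_segment: int, ref_fraction: float,
                        alpha: float = 0.05, property: str = "",
                        groups: Tuple[str, str] = ("segment", "reference"),
                        ) -> ComparisonResult:
    """Two-category goodness-of-fit chi-square with Yates correction.

    Observed = positively assigned segment residues; expected = reference
    positive fraction times the segment residue count.
    chi2 = sum over {positive, negative} of (|O - E| - 0.5)^2 / E, df = 1.
    """
    if n_segment < 1:
        raise ValueError("n_segment must be >= 1")
    if not 0.0 < ref_fraction < 1.0:
        raise ValueError("ref_fraction must lie strictly between 0 and 1")
    e_pos = ref_fraction * n_segment
    e_neg = (1.0 - ref_fraction) * n_segment
    o_pos = float(obs_positive)
    o_neg = n_segment - o_pos
    chi2 = ((abs(o_pos - e_pos) - 0.5) ** 2 / e_pos
            + (abs(o_neg - e_neg) - 0.5) ** 2 / e_neg)
    p = float(sps.chi2.sf(chi2, df=1))
    return ComparisonResult(property=property, groups=groups,
                            test="yates_chi2", statistic=float(chi2),
                            p_raw=p, alpha_corrected=alpha)


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Corrected per-test significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def dagostino_pearson(sample: Sequence[float], alpha: float = 0.05,
                      property: str = "") -> ComparisonResult:
    """D'Agostino & Pearson K^2 omnibus normality test (skewness + kurtosis).

    Used to document the nonparametric-test justification; requires n >= 20.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 20:
        raise ValueError("dagostino_pearson requires n >= 20")
    if np.ptp(x) == 0.0:
        raise ValueError("sample has zero variance")
    k2, p = sps.normaltest(x)
    return ComparisonResult(property=property, groups=("sample",),
                            test="dagostino_pearson", statistic=float(k2),
                            p_raw=float(p), alpha_corrected=alpha)


def aa_composition(sequences: Iterable[str],
                   pseudocount: float = 0.0) -> Dict[str, float]:
    """Amino-acid frequencies over the 20 residues; X is excluded entirely."""
    counts = {aa: pseudocount for aa in AMINO_ACIDS}
    total = 20 * pseudocount
    for seq in sequences:
        for c in seq:
            if c in counts:
                counts[c] += 1
                total += 1
    if total == 0:
        raise ValueError("no countable residues")
    return {aa: counts[aa] / total for aa in AMINO_ACIDS}


def aa_composition_log2(segment_seqs: Iterable[str], reference_seqs: Iterable[str],
                        pseudocount: float = 0.0) -> Dict[str, float]:
    """Per-residue-type log2(freq_set / freq_reference).

    A pseudocount (added to every residue count in both sets) guards against
    absent residues; without one, a zero reference frequency is an error.
    """
    f_set = aa_composition(segment_seqs, pseudocount)
    f_ref = aa_composition(reference_seqs, pseudocount)
    out: Dict[str, float] = {}
    for aa in AMINO_ACIDS:
        if f_ref[aa] == 0.0:
            raise ValueError(f"reference frequency for {aa} is zero; "
                             "supply a pseudocount")
        out[aa] = float("-inf") if f_set[aa] == 0.0 else math.log2(f_set[aa] / f_ref[aa])
    return out
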