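"""Self-contained synthetic proteomes and readthrough-candidate bundles.

Everything downstream of this module is testable without any database
download: the generator emulates a proteome with log-normally distributed
protein lengths, a configurable number of readthrough candidates whose
extensions are drawn from a composition-biased residue distribution, planted
linear-motif instances, a planted GO enrichment, and ortholog pairs with
conserved CDS but independently drawn extensions.

Two composition regimes mirror the biology being emulated: ``fly_like``
extensions are enriched in the disorder-promoting residues P, Q, R, H and S;
``yeast_like`` extensions are enriched in the hydrophobic residues Y, L, I, F
and C and depleted in A, G, D, E and Q.  ``disorder_shift`` additionally
tilts the extension composition so that the *expected* disordered-residue
fraction of extensions exceeds that of background segments by the requested
amount — the tilt weight is solved analytically from the disorder predictor's
own window statistics (see ``expected_disorder_fraction``).

Every random draw flows from a single :class:`numpy.random.Generator`, so a
fixed seed yields a byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy import stats as sps
from scipy.optimize import brentq

from .config import AMINO_ACIDS, PredictorConfig
from .datasets import TRCandidate, candidates_to_frame
from .io import write_fasta, write_table
from .motifscan import MotifPattern

FLY_BOOST = set("PQRHS")
YEAST_BOOST = set("YLIFC")
YEAST_DEPLETE = set("AGDEQ")

#: Built-in miniature motif set used by generated bundles.  Probabilities
#: straddle the 1e-3 chance-occurrence cut; each exemplar matches its own
#: pattern.  The ``$``-anchored entry mimics a C-terminal targeting signal.
DEFAULT_PATTERNS: List[Tuple[str, str, float, str, str]] = [
    ("SYN_LIG_PXP",   "P.P",              2.0e-3, "fly,yeast", "PAP"),
    ("SYN_TRG_CTERM", "[SAC][KR][LM]$",   5.0e-4, "fly,yeast", "SKL"),
    ("SYN_DOC_SQ",    "[ST]Q.{2}[LIV]",   8.0e-4, "fly,yeast", "SQAAL"),
    ("SYN_MOD_KK",    "[KR][KR].L",       1.5e-3, "fly",       "KKAL"),
    ("SYN_LIG_WF",    "W..F",             9.0e-5, "yeast",     "WAAF"),
    ("SYN_LIG_YY",    "Y.Y[AG]",          6.0e-4, "yeast",     "YAYA"),
]

_STOP_CODON = "TGA"
_CODONS: Dict[str, List[str]] = {}


def _codon_table() -> Dict[str, List[str]]:
    if not _CODONS:
        from Bio.Data import CodonTable
        table = CodonTable.unambiguous_dna_by_id[1]
        for codon, aa in table.forward_table.items():
            _CODONS.setdefault(aa, []).append(codon)
        for aa in _CODONS:
            _CODONS[aa].sort()
    return _CODONS


@dataclass
class SynthConfig:
    """Parameters of one synthetic bundle; defaults are the study conditions.

    Protein lengths are log-normal with median ~350 residues; extension
    lengths log-normal with median ~20 residues (both medians match the
    scale of real fly/yeast readthrough data).  Readthrough rates are
    log-uniform over [0.1%, 10%], spanning the 1.2% biological-relevance cut
    from both sides; extension read counts are negative binomial.
    """

    seed: int = 0
    n_proteins: int = 300
    n_candidates: int = 60
    length_log_mean: float = 5.86   # ln-scale; median exp(5.86) ~ 350 res
    length_log_sd: float = 0.55
    ext_length_log_mean: float = 3.0  # median ~ 20 res, incl. the X
    ext_length_log_sd: float = 0.8
    regime: str = "neutral"
    composition_bias: Optional[Dict[str, float]] = None
    bias_factor: float = 2.0        # default boost/depletion used by regimes
    disorder_shift: float = 0.0
    motif_plant_rate: float = 0.0   # expected planted motifs / 100 ext residues
    go_terms: int = 20
    go_background_rate: float = 0.1
    go_enrichment_fold: float = 1.0
    ortholog_pairs: int = 0
    cds_identity: float = 0.7
    background_freqs: Optional[Dict[str, float]] = None  # default uniform 1/20
    read_nb_mean: float = 30.0
    read_nb_size: float = 5.0       # NB shape; variance = m + m^2/size
    rate_range: Tuple[float, float] = (0.1, 10.0)  # percent, log-uniform
    evidence_probs: Tuple[float, float, float] = (0.3, 0.6, 0.1)
    species: str = "fly"

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_candidates", "go_terms",
                     "ortholog_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_candidates > self.n_proteins:
            raise ValueError("n_candidates cannot exceed n_proteins")
        if self.regime not in ("fly_like", "yeast_like", "neutral"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "neutral":
            if self.disorder_shift != 0.0:
                raise ValueError("neutral regime requires disorder_shift = 0")
            if self.composition_bias:
                raise ValueError("neutral regime requires identity "
                                 "composition_bias")
        if self.composition_bias is not None and any(
                w <= 0 for w in self.composition_bias.values()):
            raise ValueError("composition weights must be > 0")
        if self.go_enrichment_fold < 1.0:
            raise ValueError("go_enrichment_fold must be >= 1")
        if self.ortholog_pairs > self.n_candidates:
            raise ValueError("ortholog_pairs cannot exceed n_candidates")
        if not 0.0 < self.cds_identity <= 1.0:
            raise ValueError("cds_identity must lie in (0, 1]")


def background_composition(config: SynthConfig) -> np.ndarray:
    """Background residue probabilities in AMINO_ACIDS order (default 1/20)."""
    if config.background_freqs is None:
        return np.full(20, 1.0 / 20.0)
    v = np.array([config.background_freqs.get(aa, 0.0) for aa in AMINO_ACIDS])
    if (v <= 0).any():
        raise ValueError("background frequencies must cover all 20 residues")
    return v / v.sum()


def regime_bias(config: SynthConfig) -> Dict[str, float]:
    """Multiplicative weight per residue implied by the regime (or explicit
    composition_bias when given)."""
    if config.composition_bias is not None:
        return {aa: config.composition_bias.get(aa, 1.0) for aa in AMINO_ACIDS}
    bias = {aa: 1.0 for aa in AMINO_ACIDS}
    if config.regime == "fly_like":
        for aa in FLY_BOOST:
            bias[aa] = config.bias_factor
    elif config.regime == "yeast_like":
        for aa in YEAST_BOOST:
            bias[aa] = config.bias_factor
        for aa in YEAST_DEPLETE:
            bias[aa] = 1.0 / config.bias_factor
    return bias


def expected_disorder_fraction(composition: np.ndarray,
                               pcfg: PredictorConfig) -> float:
    """Expected disordered-residue fraction of a long iid sequence.

    The disorder score thresholds the windowed mean propensity M at the
    logistic center c (score >= 0.5 iff M >= c).  For iid residues M is
    approximately Normal(mu, sigma^2 / w), so the expected fraction is
    Phi((mu - c) * sqrt(w) / sigma).
    """
    vals = np.array([pcfg.disorder_propensity[aa] for aa in AMINO_ACIDS])
    mu = float(composition @ vals)
    var = float(composition @ vals ** 2) - mu ** 2
    if var <= 0:
        return 1.0 if mu >= pcfg.disorder_logistic_center else 0.0
    z = (mu - pcfg.disorder_logistic_center) * np.sqrt(pcfg.disorder_window) / np.sqrt(var)
    return float(sps.norm.cdf(z))


def _tilted(base: np.ndarray, t: float, pcfg: PredictorConfig) -> np.ndarray:
    vals = np.array([pcfg.disorder_propensity[aa] for aa in AMINO_ACIDS])
    w = base * np.exp(t * vals)
    return w / w.sum()


def extension_composition(config: SynthConfig,
                          pcfg: Optional[PredictorConfig] = None) -> np.ndarray:
    """Residue probabilities for extension sampling.

    Background frequencies are reweighted by the regime bias, then — when
    ``disorder_shift`` is non-zero — exponentially tilted along the disorder
    propensity axis so the expected disordered fraction of extensions exceeds
    the background's by exactly the shift (solved with brentq).
    """
    pcfg = pcfg or PredictorConfig()
    bg = background_composition(config)
    bias = regime_bias(config)
    comp = bg * np.array([bias[aa] for aa in AMINO_ACIDS])
    comp = comp / comp.sum()
    if config.disorder_shift == 0.0:
        return comp
    target = expected_disorder_fraction(bg, pcfg) + config.disorder_shift
    if not 0.0 < target < 1.0:
        raise ValueError(f"disorder_shift {config.disorder_shift} puts the "
                         "target disordered fraction outside (0, 1)")

    def gap(t: float) -> float:
        return expected_disorder_fraction(_tilted(comp, t, pcfg), pcfg) - target

    lo, hi = -1.0, 1.0
    while gap(lo) > 0 and lo > -50:
        lo *= 2
    while gap(hi) < 0 and hi < 50:
        hi *= 2
    t = brentq(gap, lo, hi, xtol=1e-10)
    return _tilted(comp, t, pcfg)


def _sample_peptide(composition: np.ndarray, length: int,
                    rng: np.random.Generator) -> str:
    idx = rng.choice(20, size=length, p=composition)
    return "".join(AMINO_ACIDS[i] for i in idx)


def sample_extension(regime: str, length: int, rng: np.random.Generator,
                     config: Optional[SynthConfig] = None,
                     pcfg: Optional[PredictorConfig] = None) -> str:
    """Sample an extension peptide (without the leading X) of given length."""
    if length < 1:
        raise ValueError("extension length must be >= 1")
    if config is None or config.regime != regime:
        base = asdict(config) if config is not None else {}
        base.update(regime=regime, composition_bias=None)
        if regime == "neutral":
            base["disorder_shift"] = 0.0
        if "rate_range" in base:
            base["rate_range"] = tuple(base["rate_range"])
            base["evidence_probs"] = tuple(base["evidence_probs"])
        config = SynthConfig(**base)
    comp = extension_composition(config, pcfg)
    return _sample_peptide(comp, length, rng)


def default_patterns(species: Optional[str] = None) -> List[MotifPattern]:
    pats = []
    for elm_id, pattern, prob, taxa, exemplar in DEFAULT_PATTERNS:
        taxa_set = frozenset(taxa.split(","))
        if species is not None and species not in taxa_set:
            continue
        pats.append(MotifPattern(elm_id, pattern, prob, taxa_set, exemplar))
    return pats


def plant_motifs(extensions: Dict[str, str],
                 patterns: Sequence[MotifPattern],
                 rate: float, rng: np.random.Generator,
                 ) -> Tuple[Dict[str, str], List[Tuple[str, str, int, int]]]:
    """Substitute pattern exemplars into extensions at a Poisson rate.

    ``rate`` is the expected number of planted motifs per 100 extension
    residues.  Plant positions are uniform; plants never overlap each other
    (overlap would corrupt the recorded spans); an exemplar longer than its
    extension is skipped, never truncated.  Patterns anchored to the
    C-terminus are planted flush with the end.  Returns the modified
    extensions and a ledger of (extension id, elm_id, start, end) spans in
    extension coordinates (X at position 0).
    """
    for pat in patterns:
        if pat.exemplar is None or pat.compiled().fullmatch(pat.exemplar) is None:
            raise ValueError(f"pattern {pat.elm_id} lacks a self-matching "
                             "exemplar")
    out = dict(extensions)
    ledger: List[Tuple[str, str, int, int]] = []
    if rate <= 0:
        return out, ledger
    ids = sorted(out)
    for ext_id in ids:
        ext = out[ext_id]
        lo = 1 if ext.startswith("X") else 0  # never overwrite the stop X
        n_plant = rng.poisson(rate * len(ext) / 100.0)
        occupied: List[Tuple[int, int]] = []
        chars = list(ext)
        for _ in range(n_plant):
            pat = patterns[int(rng.integers(len(patterns)))]
            ex = pat.exemplar
            if len(ex) > len(ext) - lo:
                continue
            anchored = pat.pattern.endswith("$")
            placed = False
            for _attempt in range(20):
                if anchored:
                    start = len(ext) - len(ex)
                else:
                    start = int(rng.integers(lo, len(ext) - len(ex) + 1))
                end = start + len(ex)
                if all(end <= s or start >= e for s, e in occupied):
                    chars[start:end] = list(ex)
                    occupied.append((start, end))
                    ledger.append((ext_id, pat.elm_id, start, end))
                    placed = True
                    break
                if anchored:
                    break  # only one possible position
            if not placed:
                continue
        out[ext_id] = "".join(chars)
    return out, ledger


def plant_go(candidate_ids: Sequence[str], all_ids: Sequence[str],
             n_terms: int, fold: float, rng: np.random.Generator,
             background_rate: float = 0.1,
             ) -> Tuple[Dict[str, List[str]], Optional[str]]:
    """Assign GO terms; the first ("marked") term is enriched in candidates.

    The marked term annotates non-candidates with probability
    ``background_rate`` and candidates with ``fold`` times that (capped at
    1); the remaining terms annotate every protein uniformly at the
    background rate.  Returns (protein id -> term list, marked term id).
    """
    if fold < 1.0:
        raise ValueError("fold must be >= 1")
    if n_terms < 1:
        return {pid: [] for pid in all_ids}, None
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    marked = terms[0]
    cand = set(candidate_ids)
    go_map: Dict[str, List[str]] = {}
    for pid in all_ids:
        assigned = []
        p_marked = min(1.0, fold * background_rate) if pid in cand else background_rate
        if rng.random() < p_marked:
            assigned.append(marked)
        for term in terms[1:]:
            if rng.random() < background_rate:
                assigned.append(term)
        go_map[pid] = assigned
    return go_map, marked


@dataclass
class SynthBundle:
    """One generated dataset plus the ground truth needed to test recovery."""

    config: SynthConfig
    proteome_records: List[Tuple[str, str]]
    candidates: List[TRCandidate]
    patterns: List[MotifPattern]
    go_map: Dict[str, List[str]]
    marked_term: Optional[str]
    ortholog_rows: List[Dict[str, str]]
    motif_ledger: List[Tuple[str, str, int, int]]
    true_background: Dict[str, float]
    true_extension_composition: Dict[str, float]

    def write(self, outdir) -> None:
        """Write the bundle as plain-text files (FASTA + headered TSVs)."""
        import os
        os.makedirs(outdir, exist_ok=True)
        join = lambda *p: os.path.join(str(outdir), *p)
        write_fasta(join("proteome.fasta"), self.proteome_records)
        write_table(join("candidates.tsv"),
                    candidates_to_frame(self.candidates))
        import pandas as pd
        write_table(join("patterns.tsv"), pd.DataFrame(
            [(p.elm_id, p.pattern, p.probability, ",".join(sorted(p.taxa)),
              p.exemplar) for p in self.patterns],
            columns=["elm_id", "pattern", "probability", "taxa", "exemplar"]))
        write_table(join("go_map.tsv"), pd.DataFrame(
            [(pid, term) for pid in sorted(self.go_map)
             for term in self.go_map[pid]],
            columns=["protein_id", "term_id"]))
        write_table(join("orthologs.tsv"), pd.DataFrame(
            self.ortholog_rows,
            columns=["id_a", "id_b", "cds_b", "extension_b"]))
        write_table(join("motif_ledger.tsv"), pd.DataFrame(
            self.motif_ledger,
            columns=["extension_id", "elm_id", "start", "end"]),
            coord_note=True)
        ledger = {
            "marked_term": self.marked_term,
            "true_background": self.true_background,
            "true_extension_composition": self.true_extension_composition,
            "read_model": {"distribution": "negative_binomial",
                           "mean": self.config.read_nb_mean,
                           "size": self.config.read_nb_size},
            "rate_model": {"distribution": "log_uniform",
                           "range_percent": list(self.config.rate_range)},
        }
        cfg = asdict(self.config)
        cfg["rate_range"] = list(cfg["rate_range"])
        cfg["evidence_probs"] = list(cfg["evidence_probs"])
        with open(join("config.yaml"), "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)
        with open(join("ground_truth.yaml"), "w") as fh:
            yaml.safe_dump(ledger, fh, sort_keys=False)


def generate_bundle(config: SynthConfig,
                    pcfg: Optional[PredictorConfig] = None) -> SynthBundle:
    """Generate a complete synthetic bundle; deterministic for a fixed seed."""
    pcfg = pcfg or PredictorConfig()
    rng = np.random.default_rng(config.seed)
    bg = background_composition(config)
    ext_comp = extension_composition(config, pcfg)

    # proteome
    width = max(4, len(str(config.n_proteins)))
    lengths = np.clip(np.round(rng.lognormal(
        config.length_log_mean, config.length_log_sd,
        config.n_proteins)).astype(int), 30, 10_000)
    records = [(f"P{i + 1:0{width}d}", _sample_peptide(bg, int(n), rng))
               for i, n in enumerate(lengths)]

    # candidates are drawn from the central length range so that every
    # extended candidate has length-matched non-candidate controls; a real
    # proteome outnumbers its candidates ~50:1, which makes matching easy
    # there but not in a desk-scale proteome with heavy log-normal tails
    if config.n_candidates and config.n_candidates < config.n_proteins:
        lo_q, hi_q = np.quantile(lengths, [0.05, 0.90])
        central = [i for i in range(config.n_proteins)
                   if lo_q <= lengths[i] <= hi_q]
        if len(central) < config.n_candidates:
            central = list(range(config.n_proteins))
        cand_idx = sorted(central[:config.n_candidates])
    else:
        cand_idx = list(range(config.n_candidates))
    ext_lengths = np.clip(np.round(rng.lognormal(
        config.ext_length_log_mean, config.ext_length_log_sd,
        config.n_candidates)).astype(int), 4, 2000)
    # extension coordinates: X occupies position 0, peptide follows
    raw_exts = {records[i][0]:
                "X" + _sample_peptide(ext_comp, int(ext_lengths[k]) - 1, rng)
                for k, i in enumerate(cand_idx)}

    patterns = default_patterns(config.species) or default_patterns()
    extensions, ledger = plant_motifs(raw_exts, patterns,
                                      config.motif_plant_rate, rng)

    codons = _codon_table()
    ev_labels = ("conserved", "ribo_profiling", "both")
    candidates: List[TRCandidate] = []
    for i in cand_idx:
        pid = records[i][0]
        ext = extensions[pid]
        nt = _STOP_CODON + "".join(
            codons[aa][int(rng.integers(len(codons[aa])))] for aa in ext[1:])
        evidence = ev_labels[int(rng.choice(3, p=config.evidence_probs))]
        if evidence == "conserved":
            rate, r1, r2 = None, None, None
        else:
            lo, hi = config.rate_range
            rate = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            p_nb = config.read_nb_size / (config.read_nb_size + config.read_nb_mean)
            r1 = int(rng.negative_binomial(config.read_nb_size, p_nb))
            r2 = int(rng.negative_binomial(config.read_nb_size, p_nb))
        candidates.append(TRCandidate(
            id=pid, cds_protein=records[i][1], extension=ext,
            extension_nt=nt, evidence=evidence, readthrough_rate=rate,
            reads_rep1=r1, reads_rep2=r2))

    go_map, marked = plant_go([c.id for c in candidates],
                              [pid for pid, _ in records], config.go_terms,
                              config.go_enrichment_fold, rng,
                              config.go_background_rate)

    # ortholog pairs: partner CDS diverged by substitution only, partner
    # extension drawn independently from the same composition
    ortholog_rows: List[Dict[str, str]] = []
    aa_arr = np.array(list(AMINO_ACIDS))
    for i in range(config.ortholog_pairs):
        cand = candidates[i]
        cds = np.array(list(cand.cds_protein))
        mutate = rng.random(cds.size) < (1.0 - config.cds_identity)
        for j in np.where(mutate)[0]:
            choices = aa_arr[aa_arr != cds[j]]
            cds[j] = choices[int(rng.integers(choices.size))]
        ext_b = "X" + _sample_peptide(
            ext_comp, max(3, int(rng.integers(4, 40))), rng)
        ortholog_rows.append({"id_a": cand.id, "id_b": f"{cand.id}_orth",
                              "cds_b": "".join(cds), "extension_b": ext_b})

    return SynthBundle(
        config=config,
        proteome_records=records,
        candidates=candidates,
        patterns=patterns,
        go_map=go_map,
        marked_term=marked,
        ortholog_rows=ortholog_rows,
        motif_ledger=ledger,
        true_background={aa: float(v) for aa, v in zip(AMINO_ACIDS, bg)},
        true_extension_composition={aa: float(v) for aa, v in
                                    zip(AMINO_ACIDS, ext_comp)},
    )
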