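"""End-to-end orchestration: filters, annotation, scanning, statistics,
enrichment and ortholog comparison, with a manifest for reproducibility.

``run`` executes the full analysis on file inputs (which the synthetic
bundle writer produces in exactly the right shape) and writes headered TSV
tables plus a YAML manifest recording the seed, thresholds and counts of
every stage.  Every random choice (length-matched donor sampling) flows from
the single configured seed, so a rerun reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import PredictorConfig
from .datasets import (Proteome, TRCandidate, SegmentSet, FilterReport,
                       load_candidates, validate_candidates,
                       apply_read_filters, apply_aug_filter,
                       build_segment_sets, filter_long,
                       filter_biologically_relevant)
from .enrichment import (length_matched_background, hypergeom_enrichment,
                         results_to_frame)
from .io import read_table, write_table
from .motifscan import (MotifHit, load_patterns, scan, classify, elm_density,
                        low_probability_filter, hits_to_frame,
                        round_half_away)
from .orthologs import align_pair, shared_motifs
from .predictors import ResidueAnnotation, annotate, excise, binding_sites
from .stats import (profile, mann_whitney, kruskal_dunn, yates_chi2_residues,
                    bonferroni_threshold, dagostino_pearson,
                    aa_composition_log2, ComparisonResult, PROPERTIES)

logger = logging.getLogger(__name__)

SEGMENT_PROPERTIES = ("disordered", "low_complexity", "secondary_structure",
                      "binding_site")


@dataclass
class RunConfig:
    """Inputs, thresholds and bookkeeping for one pipeline run."""

    species: str = "fly"
    proteome_path: str = "proteome.fasta"
    candidates_path: str = "candidates.tsv"
    patterns_path: str = "patterns.tsv"
    go_map_path: Optional[str] = "go_map.tsv"
    orthologs_path: Optional[str] = None
    pfam_path: Optional[str] = None  # TSV: protein_id, start, end

    theta_disorder: float = 0.5
    theta_elm_disorder: float = 0.4
    min_extension_length: int = 25
    min_rate: float = 1.2       # percent of CDS translation rate
    min_reads: int = 5
    length_tolerance: float = 0.05
    p_max: float = 1e-3
    alpha: float = 0.05
    bonferroni_m_segment: int = 4
    bonferroni_m_residue: int = 8

    seed: int = 0
    outdir: str = "readthrough_out"
    resume: bool = False
    predictor: PredictorConfig = field(default_factory=PredictorConfig)

    def __post_init__(self) -> None:
        # keep the predictor thresholds in lock-step with the run thresholds
        self.predictor.theta_disorder = self.theta_disorder
        self.predictor.theta_elm_disorder = self.theta_elm_disorder


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def annotate_proteins(proteome: Proteome, candidates: Sequence[TRCandidate],
                      config: PredictorConfig,
                      pfam_spans: Optional[Dict[str, List[Tuple[int, int]]]] = None,
                      needed_ids: Optional[set] = None,
                      ) -> Dict[str, ResidueAnnotation]:
    """Annotate full-length proteins once each; candidates are annotated in
    their *extended* form so windows cross the CDS/extension junction."""
    pfam_spans = pfam_spans or {}
    cand_ids = {c.id for c in candidates}
    out: Dict[str, ResidueAnnotation] = {}
    for cand in candidates:
        out[cand.id] = annotate(cand.id, cand.extended,
                                pfam_spans.get(cand.id, ()), config)
    for pid, seq in proteome.records:
        if pid in cand_ids:
            continue
        if needed_ids is not None and pid not in needed_ids:
            continue
        out[pid] = annotate(pid, seq, pfam_spans.get(pid, ()), config)
    return out


def excise_set(segment_set: SegmentSet,
               annotations: Dict[str, ResidueAnnotation],
               ) -> List[ResidueAnnotation]:
    return [excise(annotations[seg.protein_id], (seg.start, seg.end))
            for seg in segment_set.segments]


def set_profiles(segment_set: SegmentSet,
                 annotations: Dict[str, ResidueAnnotation],
                 config: PredictorConfig) -> pd.DataFrame:
    rows = []
    for ann in excise_set(segment_set, annotations):
        p = profile(ann, config)
        rows.append((p.segment_key, p.length, p.disordered, p.low_complexity,
                     p.secondary_structure, p.pfam, p.binding_site))
    return pd.DataFrame(rows, columns=["segment", "length"] + list(PROPERTIES))


def set_residue_counts(segment_set: SegmentSet,
                       annotations: Dict[str, ResidueAnnotation],
                       config: PredictorConfig) -> Dict[str, Tuple[int, int]]:
    """Pooled (positive, total) residue counts per property for one set.

    X residues count in the total but never as positive.
    """
    pos = {p: 0 for p in SEGMENT_PROPERTIES}
    total = 0
    for ann in excise_set(segment_set, annotations):
        not_x = ~ann.x_mask
        total += ann.length
        pos["disordered"] += int(((ann.disorder >= config.theta_disorder) & not_x).sum())
        pos["low_complexity"] += int((ann.low_complexity & not_x).sum())
        pos["secondary_structure"] += int((np.isin(ann.ss_class, ("H", "E")) & not_x).sum())
        pos["binding_site"] += int(((ann.binding >= config.theta_binding) & not_x).sum())
    return {p: (pos[p], total) for p in SEGMENT_PROPERTIES}


def segment_contrasts(profiles: Dict[str, pd.DataFrame], alpha: float,
                      m: int, label: str,
                      sets: Tuple[str, str, str] = ("TRC_E", "RAND_C", "TRC_C"),
                      ) -> List[ComparisonResult]:
    """Kruskal-Wallis + Dunn's across the extension and its two references,
    one family per property, Bonferroni-corrected threshold alpha / m."""
    threshold = bonferroni_threshold(alpha, m)
    results: List[ComparisonResult] = []
    for prop in SEGMENT_PROPERTIES:
        groups = [profiles[name][prop].to_numpy() for name in sets]
        res = kruskal_dunn(groups, alpha=alpha, names=list(sets),
                           property=f"{label}:{prop}")
        for r in res:
            r.alpha_corrected = threshold
        results.extend(res)
    return results


def residue_contrasts(counts: Dict[str, Dict[str, Tuple[int, int]]],
                      alpha: float, m: int, label: str,
                      study: str = "TRC_E",
                      references: Tuple[str, ...] = ("RAND_C", "TRC_C"),
                      ) -> List[ComparisonResult]:
    """Yates chi-square of pooled study residues against each reference's
    positive fraction, per property."""
    threshold = bonferroni_threshold(alpha, m)
    results = []
    for prop in SEGMENT_PROPERTIES:
        obs, n_seg = counts[study][prop]
        for ref in references:
            ref_pos, ref_total = counts[ref][prop]
            if ref_pos == 0 or ref_pos == ref_total:
                logger.warning("%s: reference %s has a degenerate %s "
                               "fraction; chi-square skipped", label, ref, prop)
                continue
            res = yates_chi2_residues(obs, n_seg, ref_pos / ref_total,
                                      alpha=alpha,
                                      property=f"{label}:{prop}",
                                      groups=(study, ref))
            res.alpha_corrected = threshold
            results.append(res)
    return results


def scan_and_classify(candidates: Sequence[TRCandidate],
                      annotations: Dict[str, ResidueAnnotation],
                      patterns, config: PredictorConfig,
                      ) -> Dict[str, List[MotifHit]]:
    """Scan each extended candidate and classify hits against its annotation."""
    out: Dict[str, List[MotifHit]] = {}
    for cand in candidates:
        ann = annotations[cand.id]
        ext_span = (cand.cds_length, cand.cds_length + cand.extension_length)
        hits = scan(cand.id, cand.extended, patterns)
        out[cand.id] = classify(hits, ann, ext_span, config)
    return out


def segment_hit_counts(segment_set: SegmentSet,
                       annotations: Dict[str, ResidueAnnotation],
                       patterns, config: PredictorConfig,
                       ) -> Tuple[int, int, int]:
    """(total, with-disorder, with-binding) motif hits overlapping a set's
    segments, scanning each donor protein full-length."""
    total = with_dis = with_bind = 0
    for seg in segment_set.segments:
        ann = annotations[seg.protein_id]
        hits = scan(seg.protein_id, ann.sequence, patterns)
        hits = classify(hits, ann, (seg.start, seg.end), config)
        for h in hits:
            if h.in_extension:  # here: overlapping the segment span
                total += 1
                if h.overlaps_disorder:
                    with_dis += 1
                    if h.overlaps_binding:
                        with_bind += 1
    return total, with_dis, with_bind


def summarize_table1(candidates: Sequence[TRCandidate],
                     annotations: Dict[str, ResidueAnnotation],
                     hits_by_id: Dict[str, List[MotifHit]],
                     config: PredictorConfig, p_max: float = 1e-3,
                     ) -> pd.DataFrame:
    """Per-candidate structural/interaction metrics of the extension.

    Percentages are over the extension length including the X residue,
    rounded half-away-from-zero to one decimal; the density column is
    potential (disorder-overlapping) motifs per 100 extension residues.
    """
    rows = []
    for cand in candidates:
        ann = annotations[cand.id]
        L, E = cand.cds_length, cand.extension_length
        ext_ann = excise(ann, (L, L + E))
        p = profile(ext_ann, config)
        ext_hits = [h for h in hits_by_id.get(cand.id, []) if h.in_extension]
        n_dis = sum(1 for h in ext_hits if h.overlaps_disorder)
        n_bind = sum(1 for h in ext_hits
                     if h.overlaps_disorder and h.overlaps_binding)
        density, _ = elm_density(n_dis, E)
        n_sites = len(binding_sites(ext_ann.binding, config.theta_binding))
        low_p = sorted({h.elm_id for h in low_probability_filter(ext_hits, p_max)})
        rows.append((
            cand.id, L, E,
            round_half_away(100 * p.disordered, 1),
            round_half_away(100 * p.low_complexity, 1),
            round_half_away(100 * p.secondary_structure, 1),
            round_half_away(100 * p.binding_site, 1),
            n_sites, density, len(ext_hits), n_dis, n_bind,
            ",".join(low_p)))
    return pd.DataFrame(rows, columns=[
        "id", "cds_length", "extension_length", "disorder_pct",
        "low_complexity_pct", "secondary_structure_pct", "binding_site_pct",
        "binding_sites", "elm_density_per_100", "elms_total",
        "elms_with_disorder", "elms_with_binding", "low_probability_elms"])


def _comparisons_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.property, "|".join(r.groups), r.test, r.statistic, r.p_raw,
          r.p_adjusted, r.alpha_corrected, r.n_comparisons, r.significant)
         for r in results],
        columns=["property", "groups", "test", "statistic", "p_raw",
                 "p_adjusted", "alpha_corrected", "n_comparisons",
                 "significant"])


def run(config: RunConfig) -> Dict[str, pd.DataFrame]:
    """Execute the full analysis; returns the output tables and writes them
    (plus a manifest) to ``config.outdir``."""
    outdir = str(config.outdir)
    manifest_path = os.path.join(outdir, "manifest.yaml")
    if os.path.exists(manifest_path) and not config.resume:
        raise FileExistsError(
            f"output directory {outdir!r} already holds a run manifest; "
            "pass resume=True (or --resume) to overwrite")
    os.makedirs(outdir, exist_ok=True)
    pcfg = config.predictor
    rng = np.random.default_rng(config.seed)

    # --- load & filter -----------------------------------------------------
    proteome = Proteome.from_fasta(config.proteome_path, config.species)
    raw_candidates = load_candidates(config.candidates_path)
    candidates, rep_validate = validate_candidates(raw_candidates, proteome)
    candidates, rep_reads = apply_read_filters(candidates, config.min_reads)
    candidates, rep_aug = apply_aug_filter(candidates)
    reports = [rep_validate, rep_reads, rep_aug]

    pfam_spans: Dict[str, List[Tuple[int, int]]] = {}
    if config.pfam_path:
        pf = read_table(config.pfam_path)
        for row in pf.itertuples(index=False):
            pfam_spans.setdefault(str(row.protein_id), []).append(
                (int(row.start), int(row.end)))

    # --- segment sets & annotation ----------------------------------------
    sets = build_segment_sets(proteome, candidates, rng,
                              tolerance=config.length_tolerance)
    sets.update(filter_long(sets, config.min_extension_length))
    br_candidates, rep_br = filter_biologically_relevant(
        candidates, config.min_rate)
    reports.append(rep_br)
    annotations = annotate_proteins(proteome, candidates, pcfg, pfam_spans)

    profiles = {name: set_profiles(s, annotations, pcfg)
                for name, s in sets.items()}
    counts = {name: set_residue_counts(s, annotations, pcfg)
              for name, s in sets.items()}

    # --- statistics --------------------------------------------------------
    comparisons: List[ComparisonResult] = []
    ext_dis = profiles["TRC_E"]["disordered"]
    if len(ext_dis) >= 20 and ext_dis.nunique() > 1:
        comparisons.append(dagostino_pearson(ext_dis, config.alpha,
                                             property="TRC_E:disordered"))
    # candidate vs non-candidate protein length
    non_len = profiles["NonTRC"]["length"].to_numpy()
    trc_len = profiles["TRC"]["length"].to_numpy()
    if non_len.size and trc_len.size:
        comparisons.append(mann_whitney(
            trc_len, non_len, alpha=config.alpha, property="protein_length",
            groups=("TRC", "NonTRC")))
    comparisons += segment_contrasts(profiles, config.alpha,
                                     config.bonferroni_m_segment, "segments")
    comparisons += residue_contrasts(counts, config.alpha,
                                     config.bonferroni_m_residue, "residues")
    if len(sets["TRC_E_L"]) >= 2:
        comparisons += segment_contrasts(
            profiles, config.alpha, config.bonferroni_m_segment, "segments_L",
            sets=("TRC_E_L", "RAND_C_L", "TRC_C_L"))
    # biologically relevant rerun: restrict index-matched sets to BR candidates
    br_ids = {c.id for c in br_candidates}
    br_keep = [i for i, c in enumerate(candidates) if c.id in br_ids]
    if len(br_keep) >= 2:
        br_profiles = {}
        for name in ("TRC_E", "RAND_C", "TRC_C"):
            br_profiles[name + "_BR"] = profiles[name].iloc[br_keep]
        comparisons += segment_contrasts(
            br_profiles, config.alpha, config.bonferroni_m_segment,
            "segments_BR", sets=("TRC_E_BR", "RAND_C_BR", "TRC_C_BR"))

    composition = aa_composition_log2(
        sets["TRC_E"].sequences(), sets["NonTRC"].sequences(),
        pseudocount=0.5)

    # --- motifs ------------------------------------------------------------
    patterns = load_patterns(config.patterns_path, config.species)
    hits_by_id = scan_and_classify(candidates, annotations, patterns, pcfg)
    ext_hits = [h for hits in hits_by_id.values() for h in hits
                if h.in_extension]
    n_ext_residues = sets["TRC_E"].total_residues
    density_rows = []
    n_dis = sum(1 for h in ext_hits if h.overlaps_disorder)
    n_bind = sum(1 for h in ext_hits
                 if h.overlaps_disorder and h.overlaps_binding)
    if n_ext_residues:
        d, raw = elm_density(n_dis, n_ext_residues)
        density_rows.append(("TRC_E", len(ext_hits), n_dis, n_bind,
                             n_ext_residues, d, raw))
    for name in ("RAND_C", "TRC_C"):
        tot, wd, wb = segment_hit_counts(sets[name], annotations, patterns,
                                         pcfg)
        n_res = sets[name].total_residues
        if n_res:
            d, raw = elm_density(wd, n_res)
            density_rows.append((name, tot, wd, wb, n_res, d, raw))
    densities = pd.DataFrame(density_rows, columns=[
        "set", "elms_total", "elms_with_disorder", "elms_with_binding",
        "residues", "density_per_100", "density_raw"])

    table1 = summarize_table1(candidates, annotations, hits_by_id, pcfg,
                              config.p_max)

    # --- enrichment --------------------------------------------------------
    enrichment_frame = pd.DataFrame()
    if config.go_map_path:
        go = read_table(config.go_map_path)
        go_map: Dict[str, List[str]] = {}
        for row in go.itertuples(index=False):
            go_map.setdefault(str(row.protein_id), []).append(str(row.term_id))
        cand_ids = [c.id for c in candidates if c.id in proteome]
        if cand_ids:
            background = length_matched_background(
                cand_ids, proteome, rng, tolerance=config.length_tolerance)
            enrichment_frame = results_to_frame(
                hypergeom_enrichment(cand_ids, background, go_map))

    # --- orthologs ---------------------------------------------------------
    ortholog_frame = pd.DataFrame()
    if config.orthologs_path:
        orth = read_table(config.orthologs_path)
        cand_index = {c.id: c for c in candidates}
        rows = []
        for row in orth.itertuples(index=False):
            if str(row.id_a) not in cand_index:
                continue
            cand_a = cand_index[str(row.id_a)]
            cand_b = TRCandidate(id=str(row.id_b), cds_protein=str(row.cds_b),
                                 extension=str(row.extension_b),
                                 evidence="conserved")
            pair = align_pair(cand_a, cand_b)
            ann_b = annotate(cand_b.id, cand_b.extended, (), pcfg)
            hits_b = classify(
                scan(cand_b.id, cand_b.extended, patterns), ann_b,
                (cand_b.cds_length, len(cand_b.extended)), pcfg)
            ha = [h for h in hits_by_id[cand_a.id] if h.in_extension]
            hb = [h for h in hits_b if h.in_extension]
            rep = shared_motifs(pair, ha, hb, p_max=config.p_max,
                                ext_offset_a=cand_a.cds_length,
                                ext_offset_b=cand_b.cds_length)
            rows.append((pair.id_a, pair.id_b,
                         round_half_away(pair.cds_identity, 1),
                         round_half_away(pair.extension_identity, 1),
                         ",".join(rep.shared_1e3), ",".join(rep.shared_1e4)))
        ortholog_frame = pd.DataFrame(rows, columns=[
            "id_a", "id_b", "cds_identity_pct", "extension_identity_pct",
            "shared_motifs_p_lt_1e3", "shared_motifs_p_lt_1e4"])

    # --- write outputs -----------------------------------------------------
    tables: Dict[str, pd.DataFrame] = {
        "comparisons": _comparisons_frame(comparisons),
        "densities": densities,
        "table1": table1,
        "enrichment": enrichment_frame,
        "orthologs": ortholog_frame,
        "composition": pd.DataFrame(
            sorted(composition.items()), columns=["residue", "log2_ratio"]),
        "filter_reports": pd.concat(
            [r.to_frame().assign(stage=r.stage) for r in reports],
            ignore_index=True),
        "hits": hits_to_frame([h for hits in hits_by_id.values()
                               for h in hits]),
    }
    for name, frame in profiles.items():
        tables[f"profiles_{name}"] = frame
    for name, frame in tables.items():
        write_table(os.path.join(outdir, f"{name}.tsv"), frame,
                    coord_note=name == "hits")

    manifest = {
        "package_version": __version__,
        "species": config.species,
        "seed": config.seed,
        "thresholds": {
            "theta_disorder": config.theta_disorder,
            "theta_elm_disorder": config.theta_elm_disorder,
            "min_extension_length": config.min_extension_length,
            "min_rate_percent": config.min_rate,
            "min_reads": config.min_reads,
            "length_tolerance": config.length_tolerance,
            "p_max": config.p_max,
            "alpha": config.alpha,
            "bonferroni_m_segment": config.bonferroni_m_segment,
            "bonferroni_m_residue": config.bonferroni_m_residue,
        },
        "inputs": {name: {"path": str(path), "sha256": _sha256(str(path))}
                   for name, path in (
                       ("proteome", config.proteome_path),
                       ("candidates", config.candidates_path),
                       ("patterns", config.patterns_path),
                       ("go_map", config.go_map_path),
                       ("orthologs", config.orthologs_path))
                   if path and os.path.exists(str(path))},
        "counts": {
            "proteome": len(proteome),
            "proteome_excluded_too_long": proteome.n_excluded_too_long,
            "candidates_input": rep_validate.n_input,
            "candidates_final": len(candidates),
            "candidates_biologically_relevant": len(br_candidates),
            "extension_residues": int(n_ext_residues),
            "extension_elms": len(ext_hits),
            "extension_elms_with_disorder": int(n_dis),
            **{f"set_{name}": len(s) for name, s in sets.items()},
        },
    }
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return tables
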