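"""End-to-end orchestration: simulate/load -> detect -> validate/classify ->
merge -> cluster -> consensus/tree/superfamilies -> screens.

Every stage draws randomness from its own named substream of the single
pipeline seed, so two runs with identical inputs and seed produce
byte-identical bundles, and changing e.g. the number of bootstrap replicates
does not perturb merge tie-breaks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import io as bio
from ._rng import substream
from .cluster import FamilyPartition, all_vs_all_similarity, build_edges, mcl_cluster
from .constants import POL_DOMAINS
from .detect import Contig, LTRParams, filter_genome, run_detectors
from .domains import (ClassProfileLibrary, build_class_profiles,
                      translation_pieces, validate_and_classify)
from .merge import merge_detector_sets, resolve_nested, resolve_overlaps_within
from .phylo import (build_supermatrix, build_tree, cut_superfamilies,
                    family_consensuses, similarity_matrix)
from .screens import TaxonomyMap, ht_screen, spearman, summarize_abundance
from .simulate import SimulationSpec, generate_genome, generate_reference_panels


@dataclass
class PipelineConfig:
    """All stage thresholds, at the workflow's standard defaults."""

    min_contig: int = 10_000
    min_genome: int = 1_500_000
    ltr_dist: tuple[int, int] = (2000, 15000)
    ltr_len: tuple[int, int] = (200, 1200)
    orf_min: int = 300
    domain_keep_e: float = 0.01
    class_build_e: float = 1e-4
    classify_e: float = 1e-20
    match_min_span: int = 500
    score_cap: int = 200
    inflation: float = 4.0
    pre_inflation: float = 3.0
    min_cluster: int = 1
    consensus_min_frac: float = 1 / 3
    consensus_min_count: int = 2
    flag_similarity: float = 70.0
    flag_x: int = 5
    ht_identity: float = 0.80
    ht_frac: float = 0.20
    ht_min_span: int = 300
    merge_tolerance: int = 20
    element_len: tuple[int, int] = (2000, 15000)
    n_bootstrap: int = 100
    cluster_mode: str = "global"
    focal_class: str = "BEL/Pao"
    seed: int = 0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["ltr_dist"] = list(self.ltr_dist)
        d["ltr_len"] = list(self.ltr_len)
        d["element_len"] = list(self.element_len)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        for key in ("ltr_dist", "ltr_len", "element_len"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: list = field(default_factory=list)
    candidates_a: list = field(default_factory=list)
    candidates_b: list = field(default_factory=list)
    elements: list = field(default_factory=list)
    merge_report: dict = field(default_factory=dict)
    partition: FamilyPartition | None = None
    consensuses: dict = field(default_factory=dict)
    supermatrix: object = None
    tree: object = None
    superfamilies: object = None
    similarity: object = None
    ht_pairs: list = field(default_factory=list)
    abundance: object = None
    class_fractions: object = None
    genome_sizes: dict = field(default_factory=dict)
    excluded_genomes: list = field(default_factory=list)
    log: list = field(default_factory=list)

    def family_of(self, element_id: str) -> str:
        return self.partition.family_of(element_id)


def _log(result: PipelineResult, stage: str, **kv) -> None:
    result.log.append({"stage": stage, **kv})


def extract_domain_sequences(seq_nt: str, library: ClassProfileLibrary,
                             class_label: str, keep_e: float = 0.01) -> dict[str, str]:
    """Best-matching amino-acid window per pol domain of one element.

    Profiles of the element's assigned class are preferred; the pooled
    generic profiles serve for unclassified elements.  A domain is reported
    only when its best hit clears ``keep_e``.
    """
    if class_label in library.by_class:
        profiles = [p for p in library.class_profiles(class_label)
                    if p.domain_name in POL_DOMAINS]
    else:
        profiles = [p for p in library.generic_profiles if p.domain_name in POL_DOMAINS]
    pieces = translation_pieces(seq_nt, 60)
    out: dict[str, str] = {}
    best_e: dict[str, float] = {}
    for prof in profiles:
        hits = [(piece, h) for piece in pieces
                for h in scan_element_piece(prof, piece)]
        if not hits:
            continue
        piece, h = max(hits, key=lambda ph: ph[1][0])
        score, (s, e) = h
        n_eff = sum(max(1, len(p) - prof.length + 1) for p in pieces)
        ev = prof.e_value(score, n_eff)
        d = prof.domain_name
        if ev < keep_e and ev < best_e.get(d, np.inf):
            best_e[d] = ev
            out[d] = piece[s:e].replace("X", "")
    return out


def scan_element_piece(profile, piece: str):
    """Best window of one translated piece: [(score, (start, end))]."""
    from .domains import _encode_aa, _window_scores
    enc = _encode_aa(piece)
    scores = _window_scores(profile, enc)
    if scores.size == 0:
        return []
    b = int(np.argmax(scores))
    if enc.size >= profile.length:
        iv = (b, b + profile.length)
    else:
        iv = (0, enc.size)
    return [(float(scores[b]), iv)]


def run_pipeline(spec: SimulationSpec, config: PipelineConfig | None = None,
                 outdir: str | None = None,
                 panels: dict | None = None) -> PipelineResult:
    """Run the full analysis on a simulation spec and return the bundle."""
    config = config or PipelineConfig()
    result = PipelineResult(config=config)
    seed = config.seed

    # --- simulate -----------------------------------------------------------
    sim = generate_genome(spec)
    result.truth = sim.truth
    for w in sim.warnings:
        _log(result, "simulate", warning=w)
    _log(result, "simulate", n_truth=len(sim.truth),
         n_species=len(sim.genomes))

    panels = panels or generate_reference_panels(
        spec.templates, substream(seed, "panels"))
    library = build_class_profiles(panels, build_e=config.class_build_e,
                                   seed=substream(seed, "profiles"))
    _log(result, "profiles",
         n_profiles=sum(len(v) for v in library.by_class.values()))

    taxonomy = TaxonomyMap({g.species_id: {"genus": g.genus, "phylum": g.phylum,
                                           "subkingdom": g.subkingdom}
                            for g in spec.genomes})

    # --- detect / validate / classify / merge per species -------------------
    params_a = LTRParams(min_ltr=config.ltr_len[0], max_ltr=config.ltr_len[1],
                         min_dist=config.ltr_dist[0], max_dist=config.ltr_dist[1],
                         min_ltr_identity=0.75, seed_kmer=16)
    params_b = LTRParams(min_ltr=config.ltr_len[0], max_ltr=config.ltr_len[1],
                         min_dist=config.ltr_dist[0], max_dist=config.ltr_dist[1],
                         min_ltr_identity=0.85, seed_kmer=20)
    all_elements = []
    merge_report_total: dict[str, int] = {}
    for g in spec.genomes:
        sp = g.species_id
        contigs = [Contig(cid, sp, s) for cid, s in sim.genomes[sp]]
        retained, excluded = filter_genome(contigs, config.min_contig, config.min_genome)
        result.genome_sizes[sp] = sum(len(c) for c in retained)
        if excluded:
            result.excluded_genomes.append(sp)
            _log(result, "filter", species=sp, excluded=True)
            continue
        set_a, set_b = run_detectors(retained, params_a, params_b)
        result.candidates_a.extend(set_a)
        result.candidates_b.extend(set_b)

        kept_sets = []
        for tag, cset in (("A", set_a), ("B", set_b)):
            kept = []
            for cand in cset:
                ok, ce = validate_and_classify(cand.seq, library, config.orf_min,
                                               config.domain_keep_e,
                                               config.classify_e, cand.candidate_id)
                if not ok:
                    continue
                cand.class_label = ce.class_label
                cand.class_vote = ce.class_vote
                kept.append(cand)
            kept = resolve_nested(kept)
            kept = resolve_overlaps_within(kept, substream(seed, f"overlap:{sp}:{tag}"))
            kept_sets.append(kept)
        merged, report = merge_detector_sets(
            kept_sets[0], kept_sets[1], substream(seed, f"merge:{sp}"),
            config.merge_tolerance, config.element_len)
        for k, v in report.items():
            merge_report_total[k] = merge_report_total.get(k, 0) + v
        _log(result, "merge", species=sp, n_a=len(kept_sets[0]),
             n_b=len(kept_sets[1]), n_merged=len(merged), report=report)
        all_elements.extend(merged)
    result.elements = all_elements
    result.merge_report = merge_report_total

    if not all_elements:
        _log(result, "pipeline", note="no elements; downstream stages skipped")
        if outdir:
            write_bundle(result, outdir)
        return result

    # --- families -----------------------------------------------------------
    pairs = [(e.element_id, e.seq) for e in all_elements]
    matches = all_vs_all_similarity(pairs, min_span=config.match_min_span)
    edges = build_edges(matches)
    if config.cluster_mode == "global":
        partition = mcl_cluster([p[0] for p in pairs], edges,
                                inflation=config.inflation,
                                pre_inflation=config.pre_inflation)
    else:
        from .cluster import cluster_families
        partition = cluster_families(all_elements, "per_species",
                                     config.inflation, config.pre_inflation,
                                     config.match_min_span)
    result.partition = partition
    _log(result, "cluster", n_edges=len(edges), n_families=len(partition.families),
         converged=partition.converged)

    # --- consensus / tree / superfamilies (focal class families) ------------
    by_el = {e.element_id: e for e in all_elements}
    fam_class: dict[str, str] = {}
    for fid, members in partition.families.items():
        # strict assignments first; fall back to the softer class vote so a
        # family of diverged members (none reaching the 1e-20 rule) still
        # gets a family-level class for the downstream phylogeny
        votes = [by_el[m].class_label for m in members
                 if by_el[m].class_label != "unclassified"]
        if not votes:
            votes = [by_el[m].class_vote for m in members
                     if by_el[m].class_vote is not None]
        fam_class[fid] = max(set(votes), key=votes.count) if votes else "unclassified"
    focal_fams = [f for f, c in fam_class.items() if c == config.focal_class]

    domain_seqs: dict[str, dict[str, list[str]]] = {}
    for fid in focal_fams:
        domain_seqs[fid] = {d: [] for d in POL_DOMAINS}
        for m in partition.families[fid]:
            e = by_el[m]
            profile_class = (e.class_label if e.class_label in library.by_class
                             else (e.class_vote or "generic"))
            doms = extract_domain_sequences(e.seq, library, profile_class,
                                            config.domain_keep_e)
            for d, s in doms.items():
                if d in domain_seqs[fid]:
                    domain_seqs[fid][d].append(s)
    consensuses = family_consensuses(
        domain_seqs, seed=substream(seed, "consensus"),
        min_frac=config.consensus_min_frac, min_count=config.consensus_min_count,
        flag_similarity=config.flag_similarity, flag_x=config.flag_x)
    result.consensuses = consensuses
    eligible = [f for f, c in consensuses.items() if c.has_all_pol_domains()]
    _log(result, "consensus", n_focal_families=len(focal_fams),
         n_with_all_domains=len(eligible))

    if len(eligible) >= 3:
        sm = build_supermatrix(consensuses, spec.templates.outgroup_domains)
        tree = build_tree(sm, config.n_bootstrap, substream(seed, "bootstrap"))
        sf = cut_superfamilies(tree)
        result.supermatrix, result.tree, result.superfamilies = sm, tree, sf
        result.similarity = similarity_matrix(sm, sf)
        _log(result, "phylo", n_rows=len(sm.row_ids),
             n_superfamilies=len(sf.labels))
    else:
        _log(result, "phylo", skipped=True, n_eligible=len(eligible))

    # --- screens ------------------------------------------------------------
    result.ht_pairs = ht_screen(all_elements, taxonomy, config.ht_identity,
                                config.ht_frac, config.ht_min_span)
    per_species, per_class, warns = summarize_abundance(all_elements, result.genome_sizes)
    result.abundance, result.class_fractions = per_species, per_class
    for w in warns:
        _log(result, "abundance", warning=w)
    if len(per_species) >= 3 and per_species["count"].nunique() > 1 \
            and per_species["density_per_mbp"].nunique() > 1:
        rho, p = spearman(per_species["count"], per_species["density_per_mbp"])
        _log(result, "abundance", spearman_rho=rho, spearman_p=p)
    _log(result, "screens", n_ht_pairs=len(result.ht_pairs),
         n_cross_phylum=sum(1 for h in result.ht_pairs if h.rank == "cross_phylum"))

    if outdir:
        write_bundle(result, outdir)
    return result


def write_bundle(result: PipelineResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        fh.write(result.config.to_yaml())
    bio.write_truth_tsv(result.truth, os.path.join(outdir, "truth.tsv"))
    bio.write_truth_gff3(result.truth, os.path.join(outdir, "truth.gff3"))
    bio.write_candidates_tsv(result.candidates_a, os.path.join(outdir, "candidates_A.tsv"))
    bio.write_candidates_tsv(result.candidates_b, os.path.join(outdir, "candidates_B.tsv"))
    bio.write_elements_tsv(result.elements, os.path.join(outdir, "elements.tsv"))
    bio.write_elements_gff3(result.elements, os.path.join(outdir, "elements.gff3"))
    if result.partition is not None:
        bio.write_partition_tsv(result.partition, os.path.join(outdir, "families.tsv"))
    if result.consensuses:
        recs = []
        for fid in sorted(result.consensuses):
            fc = result.consensuses[fid]
            for d in sorted(fc.consensus):
                recs.append((f"{fid}_{d}", fc.consensus[d]))
        bio.write_fasta(recs, os.path.join(outdir, "consensus.faa"))
    if result.supermatrix is not None:
        bio.write_fasta(list(zip(result.supermatrix.row_ids, result.supermatrix.rows)),
                        os.path.join(outdir, "supermatrix.faa"))
    if result.tree is not None:
        with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
            fh.write(result.tree.newick() + "\n")
    if result.similarity is not None:
        result.similarity.to_csv(os.path.join(outdir, "superfamily_similarity.tsv"), sep="\t")
    with open(os.path.join(outdir, "ht_pairs.tsv"), "w") as fh:
        fh.write("id_a\tid_b\tspecies_a\tspecies_b\trank\tidentity\tspan\n")
        for h in result.ht_pairs:
            fh.write(f"{h.id_a}\t{h.id_b}\t{h.species_a}\t{h.species_b}\t"
                     f"{h.rank}\t{h.identity:.4f}\t{h.span}\n")
    if result.abundance is not None:
        result.abundance.to_csv(os.path.join(outdir, "abundance.tsv"), sep="\t", index=False)
    if result.class_fractions is not None:
        result.class_fractions.to_csv(os.path.join(outdir, "class_fractions.tsv"),
                                      sep="\t", index=False)
    with open(os.path.join(outdir, "log.jsonl"), "w") as fh:
        for entry in result.log:
            fh.write(json.dumps(entry, default=str) + "\n")


def bundle_digest(outdir: str, names: tuple[str, ...] = (
        "elements.tsv", "families.tsv", "truth.tsv")) -> str:
    """SHA-256 over the bundle's main TSVs (determinism check)."""
    h = hashlib.sha256()
    for name in names:
        path = os.path.join(outdir, name)
        if os.path.exists(path):
            with open(path, "rb") as fh:
                h.update(fh.read())
    return h.hexdigest()
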