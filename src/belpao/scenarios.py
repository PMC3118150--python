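"""Prebuilt study scenarios: seeded simulation specs exercising each stage.

These define the package's reference study conditions — genome sizes, copy
numbers and divergences under which detection, classification, clustering,
phylogeny and the horizontal-transfer screen are evaluated against planted
truth.  All randomness derives from the scenario seed.
"""

from __future__ import annotations

from .pipeline import PipelineConfig
from .simulate import (GenomeSpec, HTEvent, InsertionSpec, SimulationSpec,
                       make_template_set)


def small_genome_config(seed: int, min_genome: int = 100_000) -> PipelineConfig:
    """Config for scenarios with deliberately tiny toy genomes: only the
    assembly-size gate is lowered (and recorded in the bundle); every
    analysis threshold keeps its standard default."""
    return PipelineConfig(seed=seed, min_genome=min_genome)


def recovery_scenario(seed: int = 1) -> SimulationSpec:
    """Three same-genus species (~1.5 Mbp each, so every genome clears the
    1.5 Mbp assembly-size gate), 50 full-length elements per species at 5%
    nucleotide divergence, spread over 9 BEL/Pao families in 3 superfamilies.
    The reference conditions for detection recall/precision, family recovery
    and superfamily recovery."""
    templates = make_template_set(seed)
    bp_families = [t.family_id for t in templates.templates
                   if t.class_label == "BEL/Pao"]
    genomes = [GenomeSpec(f"sp{i + 1}", "GenusA", "PhylumI", [760_000, 760_000])
               for i in range(3)]
    copies = [6, 6, 6, 6, 6, 5, 5, 5, 5]  # 50 per species over 9 families
    insertions = [
        InsertionSpec(g.species_id, fam, n, substitution_rate=0.05,
                      indel_rate=0.002, fragment_fraction=0.0,
                      nesting_probability=0.0)
        for g in genomes for fam, n in zip(bp_families, copies)
    ]
    return SimulationSpec(genomes=genomes, templates=templates,
                          insertions=insertions, seed=seed)


def class_scenario(seed: int = 1) -> SimulationSpec:
    """One species with zero-divergence copies of all four LTR classes —
    the conditions for scoring class assignment accuracy."""
    templates = make_template_set(seed)
    genomes = [GenomeSpec("spC", "GenusC", "PhylumI", [760_000, 760_000])]
    insertions = [
        InsertionSpec("spC", t.family_id, 3, substitution_rate=0.0, indel_rate=0.0)
        for t in templates.templates
    ]
    return SimulationSpec(genomes=genomes, templates=templates,
                          insertions=insertions, seed=seed + 101)


def ht_scenario(seed: int = 1) -> SimulationSpec:
    """Four species in two phyla with one planted cross-phylum transfer at
    95% identity and a 70%-identity decoy that must stay below threshold."""
    templates = make_template_set(seed)
    bp = [t.family_id for t in templates.templates if t.class_label == "BEL/Pao"]
    genomes = [
        GenomeSpec("htA1", "GenusA", "PhylumI", [160_000]),
        GenomeSpec("htA2", "GenusA", "PhylumI", [160_000]),
        GenomeSpec("htB1", "GenusB", "PhylumI", [160_000]),
        GenomeSpec("htC1", "GenusC", "PhylumII", [160_000]),
    ]
    insertions = []
    for g, fams in (("htA1", bp[0:3]), ("htA2", bp[0:3]),
                    ("htB1", bp[3:6]), ("htC1", bp[6:9])):
        insertions += [InsertionSpec(g, f, 2, substitution_rate=0.05,
                                     indel_rate=0.002) for f in fams]
    ht_events = [
        HTEvent(bp[0], donor_species="htA1", recipient_species="htC1",
                identity_target=0.95),
        HTEvent(bp[1], donor_species="htA1", recipient_species="htB1",
                identity_target=0.70),
    ]
    return SimulationSpec(genomes=genomes, templates=templates,
                          insertions=insertions, ht_events=ht_events,
                          seed=seed + 202)


def demo_scenario(seed: int = 1) -> SimulationSpec:
    """Small full-featured demonstration: 3 species, all four classes,
    fragments and nested insertions included."""
    templates = make_template_set(seed, belpao_superfamilies=3,
                                  belpao_families_per_sf=2)
    genomes = [GenomeSpec(f"demo{i + 1}", "GenusD", "PhylumI", [250_000])
               for i in range(3)]
    insertions = []
    for g in genomes:
        for t in templates.templates:
            n = 4 if t.class_label == "BEL/Pao" else 2
            insertions.append(InsertionSpec(
                g.species_id, t.family_id, n, substitution_rate=0.05,
                indel_rate=0.002, fragment_fraction=0.15,
                nesting_probability=0.1))
    return SimulationSpec(genomes=genomes, templates=templates,
                          insertions=insertions, seed=seed + 303)
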