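"""Synthetic genomes with planted LTR retrotransposons of known provenance.

The generator emulates the structure of real LTR retrotransposons: a full
element is an internal protein-coding region flanked by two long terminal
repeats that are identical at insertion time, 4.2-10 kb in total with LTRs of
0.2-1.2 kb.  The internal region carries gag, protease, reverse transcriptase
and integrase domains, with the pol domains in their natural order (protease,
then RT, then integrase) inside a single stop-free reading frame.

Element amino-acid sequences are organised hierarchically so every downstream
stage has recoverable signal: a shared ancestral sequence per domain; class
ancestors for Ty1/Copia, Ty3/Gypsy, BEL/Pao and DIRS (Copia and Gypsy descend
from a common non-BEL ancestor, which makes them a usable outgroup pair for
tree rooting); superfamily ancestors inside the focal BEL/Pao class; family
ancestors inside each superfamily; and finally per-copy nucleotide divergence
applied when a copy is planted into a genome.  Planted copies may be
fragmented, nested inside earlier copies, or reverse-complemented, and every
planted interval is recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import as_generator, substream
from .constants import (AMINO_ACIDS, CLASSES, CODONS_FOR_AA, DOMAINS,
                        NUCLEOTIDES, revcomp)

_NT = np.frombuffer(NUCLEOTIDES.encode(), dtype=np.uint8)
_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


class SimulationError(ValueError):
    pass


class PanelDivergenceError(SimulationError):
    """Raised when the requested panel divergence cannot honour the margin."""


# ---------------------------------------------------------------------------
# sequence-level helpers
# ---------------------------------------------------------------------------

def random_nt(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_NT, size=length, p=p).tobytes().decode()


def random_aa(rng: np.random.Generator, length: int) -> str:
    """Random protein sequence at the codon-background composition."""
    from .constants import AA_BACKGROUND
    return rng.choice(_AA, size=length, p=AA_BACKGROUND).tobytes().decode()


def mutate_aa(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each residue with probability ``rate``; replacements are
    drawn from the codon-background composition (excluding the original
    residue), so composition stays stationary under repeated mutation."""
    from .constants import AA_BACKGROUND
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.array([AMINO_ACIDS.index(chr(c)) for c in arr])
    mask = rng.random(arr.size) < rate
    for i in np.nonzero(mask)[0]:
        p = AA_BACKGROUND.copy()
        p[idx[i]] = 0.0
        idx[i] = rng.choice(20, p=p / p.sum())
    return _AA[idx].tobytes().decode()


def back_translate(aa: str, rng: np.random.Generator) -> str:
    """Back-translate with a uniformly random synonymous codon per site."""
    return "".join(CODONS_FOR_AA[a][rng.integers(len(CODONS_FOR_AA[a]))] for a in aa)


def mutate_sequence(seq: str, substitution_rate: float, indel_rate: float, seed) -> tuple[str, float]:
    """Mutate a nucleotide sequence.

    Substitutions are drawn per site with probability ``substitution_rate``,
    uniformly over the three alternative bases.  Indel events occur per site
    with probability ``indel_rate``; each event is an insertion or deletion
    with equal probability and geometric length (mean 2 bp).  Returns the
    mutated sequence and the realized divergence, defined as
    (substituted sites + indel events) / original length.
    """
    if not (0 <= substitution_rate <= 1) or not (0 <= indel_rate < 1):
        raise SimulationError("mutation rates must lie in [0, 1)")
    rng = as_generator(seed)
    n = len(seq)
    if n == 0:
        return "", 0.0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.zeros(n, dtype=np.int8)
    for i, b in enumerate(NUCLEOTIDES):
        code[arr == ord(b)] = i
    sub_mask = rng.random(n) < substitution_rate
    n_sub = int(sub_mask.sum())
    if n_sub:
        code[sub_mask] = (code[sub_mask] + rng.integers(1, 4, size=n_sub)) % 4
        arr = _NT[code]
    else:
        arr = _NT[code]
    out = arr.tobytes().decode()

    indel_pos = np.nonzero(rng.random(n) < indel_rate)[0]
    n_indel = int(indel_pos.size)
    if n_indel:
        pieces: list[str] = []
        cursor = 0
        skip_until = 0
        for p in indel_pos:
            p = int(p)
            if p < skip_until:
                continue
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # insertion before p
                pieces.append(out[cursor:p])
                pieces.append(random_nt(rng, length))
                cursor = p
            else:  # deletion of [p, p+length)
                pieces.append(out[cursor:p])
                cursor = min(n, p + length)
                skip_until = cursor
        pieces.append(out[cursor:])
        out = "".join(pieces)
    return out, (n_sub + n_indel) / n


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

#: default amino-acid lengths per domain (all multiples of one residue; the
#: nucleotide spans are 3x these, each >= 300 bp as required downstream).
DOMAIN_AA_LENGTHS = {
    "gag": 140,
    "protease": 110,
    "reverse_transcriptase": 180,
    "integrase": 130,
}


@dataclass
class ElementTemplate:
    """Ancestral sequence of one element family."""

    template_id: str
    class_label: str
    family_id: str
    ltr_seq: str
    internal_seq: str
    domain_spans: dict[str, tuple[int, int]]
    superfamily_id: str | None = None
    domain_aa: dict[str, str] = field(default_factory=dict)

    @property
    def element_seq(self) -> str:
        return self.ltr_seq + self.internal_seq + self.ltr_seq

    @property
    def length(self) -> int:
        return 2 * len(self.ltr_seq) + len(self.internal_seq)

    def validate(self) -> None:
        if not 200 <= len(self.ltr_seq) <= 1200:
            raise SimulationError(f"{self.template_id}: LTR length {len(self.ltr_seq)} outside [200, 1200]")
        if not 4200 <= self.length <= 10000:
            raise SimulationError(f"{self.template_id}: element length {self.length} outside [4200, 10000]")
        spans = sorted(self.domain_spans.items(), key=lambda kv: kv[1][0])
        prev_end = 0
        for name, (s, e) in spans:
            if s < prev_end:
                raise SimulationError(f"{self.template_id}: domain {name} overlaps previous domain")
            if (e - s) % 3 or (e - s) < 300:
                raise SimulationError(f"{self.template_id}: domain {name} span invalid")
            prev_end = e
        pol = [self.domain_spans[d][0] for d in ("protease", "reverse_transcriptase", "integrase")]
        if sorted(pol) != pol:
            raise SimulationError(f"{self.template_id}: pol domains out of order")


@dataclass
class TemplateSet:
    templates: list[ElementTemplate]
    class_ancestors: dict[str, dict[str, str]]
    superfamily_of: dict[str, str]
    outgroup_domains: dict[str, dict[str, str]]

    def by_id(self, template_id: str) -> ElementTemplate:
        for t in self.templates:
            if t.template_id == template_id:
                return t
        raise KeyError(template_id)

    def by_class(self, class_label: str) -> list[ElementTemplate]:
        return [t for t in self.templates if t.class_label == class_label]


_CLASS_ABBREV = {"Ty1/Copia": "CO", "Ty3/Gypsy": "GY", "BEL/Pao": "BP", "DIRS": "DI"}


def _build_template(rng, class_label, family_id, superfamily_id, domain_aa,
                    ltr_len_range=(250, 900), element_len_range=(4800, 8000)) -> ElementTemplate:
    coding_aa = "".join(domain_aa[d] for d in DOMAINS)
    coding_nt = back_translate(coding_aa, rng)
    ltr_len = int(rng.integers(*ltr_len_range))
    lo = max(element_len_range[0], 2 * ltr_len + len(coding_nt) + 120, 4200)
    hi = min(element_len_range[1], 10000)
    if lo > hi:
        raise SimulationError("element length range infeasible for requested domains")
    total = int(rng.integers(lo, hi + 1))
    filler = total - 2 * ltr_len - len(coding_nt)
    f5 = int(rng.integers(60, max(61, filler - 60)))
    f3 = filler - f5
    internal = random_nt(rng, f5) + coding_nt + random_nt(rng, f3)
    spans: dict[str, tuple[int, int]] = {}
    pos = f5
    for d in DOMAINS:
        spans[d] = (pos, pos + 3 * len(domain_aa[d]))
        pos += 3 * len(domain_aa[d])
    tpl = ElementTemplate(
        template_id=family_id,
        class_label=class_label,
        family_id=family_id,
        ltr_seq=random_nt(rng, ltr_len),
        internal_seq=internal,
        domain_spans=spans,
        superfamily_id=superfamily_id,
        domain_aa=dict(domain_aa),
    )
    tpl.validate()
    return tpl


def make_template_set(
    seed,
    belpao_superfamilies: int = 3,
    belpao_families_per_sf: int = 3,
    other_classes: tuple[str, ...] = ("Ty1/Copia", "Ty3/Gypsy", "DIRS"),
    families_per_other_class: int = 2,
    sf_divergence: float = 0.30,
    family_divergence: float = 0.15,
    other_sf_divergence: float = 0.10,
    domain_aa_lengths: dict[str, int] | None = None,
) -> TemplateSet:
    """Generate the hierarchical family templates for all requested classes.

    Divergences are per-site amino-acid substitution probabilities applied at
    each level of the hierarchy (class ancestor -> superfamily ancestor ->
    family ancestor).  Defaults give within-superfamily consensus similarity
    well above between-superfamily similarity, and within-class similarity
    well above between-class similarity.
    """
    rng = as_generator(seed)
    lengths = dict(domain_aa_lengths or DOMAIN_AA_LENGTHS)

    root = {d: random_aa(rng, lengths[d]) for d in DOMAINS}
    out_anc = {d: mutate_aa(root[d], 0.28, rng) for d in DOMAINS}
    class_anc = {
        "BEL/Pao": {d: mutate_aa(root[d], 0.28, rng) for d in DOMAINS},
        "Ty1/Copia": {d: mutate_aa(out_anc[d], 0.18, rng) for d in DOMAINS},
        "Ty3/Gypsy": {d: mutate_aa(out_anc[d], 0.18, rng) for d in DOMAINS},
        "DIRS": {d: mutate_aa(root[d], 0.45, rng) for d in DOMAINS},
    }

    templates: list[ElementTemplate] = []
    sf_of: dict[str, str] = {}
    for s in range(belpao_superfamilies):
        sf_id = f"BP-{s + 1}"
        sf_anc = {d: mutate_aa(class_anc["BEL/Pao"][d], sf_divergence, rng) for d in DOMAINS}
        for f in range(belpao_families_per_sf):
            fam_id = f"{sf_id}-{f + 1}"
            fam_aa = {d: mutate_aa(sf_anc[d], family_divergence, rng) for d in DOMAINS}
            templates.append(_build_template(rng, "BEL/Pao", fam_id, sf_id, fam_aa))
            sf_of[fam_id] = sf_id
    for cls in other_classes:
        if cls not in class_anc:
            raise SimulationError(f"unknown class {cls!r}")
        abbrev = _CLASS_ABBREV[cls]
        sf_id = f"{abbrev}-1"
        sf_anc = {d: mutate_aa(class_anc[cls][d], other_sf_divergence, rng) for d in DOMAINS}
        for f in range(families_per_other_class):
            fam_id = f"{sf_id}-{f + 1}"
            fam_aa = {d: mutate_aa(sf_anc[d], family_divergence, rng) for d in DOMAINS}
            templates.append(_build_template(rng, cls, fam_id, sf_id, fam_aa))
            sf_of[fam_id] = sf_id

    outgroups = {
        "Copia_outgroup": dict(class_anc["Ty1/Copia"]),
        "Gypsy_outgroup": dict(class_anc["Ty3/Gypsy"]),
    }
    return TemplateSet(templates, class_anc, sf_of, outgroups)


# ---------------------------------------------------------------------------
# simulation spec and genome generation
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    species_id: str
    genus: str
    phylum: str
    contig_lengths: list[int]
    gc_fraction: float = 0.42
    subkingdom: str = "eumetazoa"

    def validate(self) -> None:
        if any(length < 10000 for length in self.contig_lengths):
            raise SimulationError(f"{self.species_id}: contigs must be >= 10 kb")
        if not 0 < self.gc_fraction < 1:
            raise SimulationError(f"{self.species_id}: gc_fraction outside (0, 1)")


@dataclass
class InsertionSpec:
    species_id: str
    family_id: str
    copy_number: int
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    fragment_fraction: float = 0.0
    nesting_probability: float = 0.0
    revcomp_probability: float = 0.25

    def validate(self) -> None:
        if self.copy_number < 0:
            raise SimulationError("copy_number must be >= 0")
        for name in ("substitution_rate", "indel_rate"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        for name in ("fragment_fraction", "nesting_probability", "revcomp_probability"):
            if not 0 <= getattr(self, name) <= 1:
                raise SimulationError(f"{name} outside [0, 1]")


@dataclass
class HTEvent:
    template_id: str
    donor_species: str
    recipient_species: str
    identity_target: float = 0.95


@dataclass
class SimulationSpec:
    genomes: list[GenomeSpec]
    templates: TemplateSet
    insertions: list[InsertionSpec]
    ht_events: list[HTEvent] = field(default_factory=list)
    seed: int = 0
    #: minimum background gap between sibling (non-nested) insertions
    min_gap: int = 300

    def validate(self) -> None:
        for g in self.genomes:
            g.validate()
        for ins in self.insertions:
            ins.validate()
            self.templates.by_id(ins.family_id)


@dataclass
class TruthRecord:
    species_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    family_id: str
    class_label: str
    divergence_realized: float
    nesting_depth: int = 0
    is_fragment: bool = False


@dataclass
class SimulationResult:
    genomes: dict[str, list[tuple[str, str]]]
    truth: list[TruthRecord]
    warnings: list[str]

    def contigs_for(self, species_id: str) -> list[tuple[str, str]]:
        return self.genomes[species_id]


class _Contig:
    """Top-level copies replace a background window (the contig keeps its
    specified length); nested copies are true insertions that expand their
    host and shift downstream coordinates."""

    def __init__(self, contig_id: str, seq: str):
        self.contig_id = contig_id
        self.seq = seq
        self.records: list[TruthRecord] = []

    def place(self, pos: int, payload: str, record: TruthRecord) -> None:
        length = len(payload)
        self.seq = self.seq[:pos] + payload + self.seq[pos + length:]
        record.start = pos
        record.end = pos + length
        self.records.append(record)

    def insert(self, pos: int, payload: str, record: TruthRecord) -> None:
        """Insert ``payload`` at ``pos``, shifting/extending existing records."""
        length = len(payload)
        self.seq = self.seq[:pos] + payload + self.seq[pos:]
        for r in self.records:
            if r.start >= pos:
                r.start += length
                r.end += length
            elif r.start < pos < r.end:
                r.end += length
        record.start = pos
        record.end = pos + length
        self.records.append(record)

    def free_position(self, rng, length: int, min_gap: int, tries: int = 60) -> int | None:
        """A start such that [pos, pos+length) plus flanking min_gap margins
        is pure background; None when the contig is too short or crowded."""
        if length + 2 * min_gap > len(self.seq):
            return None
        occupied = [(r.start, r.end) for r in self.records]
        for _ in range(tries):
            pos = int(rng.integers(min_gap, len(self.seq) - length - min_gap + 1))
            if all(pos + length <= s - min_gap or pos >= e + min_gap
                   for s, e in occupied):
                return pos
        return None


def _make_fragment(rng, seq: str) -> tuple[str, int]:
    """Cut a contiguous sub-interval that is missing at least the start of the
    5' LTR, so the fragment never contains two complete LTR copies."""
    n = len(seq)
    a = int(rng.integers(max(1, n // 20), max(2, n // 3)))
    min_len = min(1500, n - a - 1)
    b = int(rng.integers(a + max(1, min_len), n + 1))
    return seq[a:b], a


def generate_genome(spec: SimulationSpec) -> SimulationResult:
    """Build every genome in ``spec`` and the ground truth of planted copies.

    Deterministic given ``spec.seed``.  Insertions that cannot be placed
    (contig too short, no free position) are skipped with a warning and never
    produce out-of-bounds records.
    """
    spec.validate()
    genomes: dict[str, list[tuple[str, str]]] = {}
    truth: list[TruthRecord] = []
    warnings: list[str] = []

    contig_map: dict[str, list[_Contig]] = {}
    for g in spec.genomes:
        rng = substream(spec.seed, f"background:{g.species_id}")
        contigs = [
            _Contig(f"{g.species_id}_ctg{i + 1}", random_nt(rng, length, g.gc_fraction))
            for i, length in enumerate(g.contig_lengths)
        ]
        contig_map[g.species_id] = contigs

    for ins in spec.insertions:
        if ins.species_id not in contig_map:
            raise SimulationError(f"unknown species {ins.species_id!r} in insertions")
        tpl = spec.templates.by_id(ins.family_id)
        rng = substream(spec.seed, f"insert:{ins.species_id}:{ins.family_id}")
        contigs = contig_map[ins.species_id]
        for c in range(ins.copy_number):
            mutated, div = mutate_sequence(
                tpl.element_seq, ins.substitution_rate, ins.indel_rate,
                substream(spec.seed, f"copy:{ins.species_id}:{ins.family_id}:{c}"),
            )
            is_fragment = bool(rng.random() < ins.fragment_fraction)
            if is_fragment:
                mutated, _ = _make_fragment(rng, mutated)
            strand = "-" if rng.random() < ins.revcomp_probability else "+"
            payload = revcomp(mutated) if strand == "-" else mutated

            record = TruthRecord(
                species_id=ins.species_id, contig_id="", start=0, end=0, strand=strand,
                family_id=ins.family_id, class_label=tpl.class_label,
                divergence_realized=div, nesting_depth=0, is_fragment=is_fragment,
            )
            placed = False
            nest_hosts = [
                (ctg, r) for ctg in contigs for r in ctg.records
                if not r.is_fragment and r.nesting_depth < 2
                and r.end - r.start > len(payload) // 4 + 2 * len(tpl.ltr_seq) + 200
            ]
            if not is_fragment and nest_hosts and rng.random() < ins.nesting_probability:
                ctg, host = nest_hosts[int(rng.integers(len(nest_hosts)))]
                margin = len(tpl.ltr_seq) + 50
                lo, hi = host.start + margin, host.end - margin
                if lo < hi:
                    pos = int(rng.integers(lo, hi))
                    record.nesting_depth = host.nesting_depth + 1
                    record.contig_id = ctg.contig_id
                    ctg.insert(pos, payload, record)
                    placed = True
            if not placed:
                order = rng.permutation(len(contigs))
                for ci in order:
                    ctg = contigs[int(ci)]
                    if len(ctg.seq) < len(payload):
                        continue
                    pos = ctg.free_position(rng, len(payload), spec.min_gap)
                    if pos is not None:
                        record.contig_id = ctg.contig_id
                        ctg.place(pos, payload, record)
                        placed = True
                        break
            if not placed:
                warnings.append(
                    f"could not place copy {c} of {ins.family_id} in {ins.species_id}; skipped"
                )

    for ev in spec.ht_events:
        tpl = spec.templates.by_id(ev.template_id)
        rng = substream(spec.seed, f"ht:{ev.template_id}:{ev.recipient_species}")
        mutated, div = mutate_sequence(tpl.element_seq, 1.0 - ev.identity_target, 0.0, rng)
        contigs = contig_map[ev.recipient_species]
        for ctg in contigs:
            pos = ctg.free_position(rng, len(mutated), spec.min_gap)
            if pos is not None:
                record = TruthRecord(
                    species_id=ev.recipient_species, contig_id=ctg.contig_id,
                    start=0, end=0, strand="+", family_id=tpl.family_id,
                    class_label=tpl.class_label, divergence_realized=div,
                )
                ctg.place(pos, mutated, record)
                break
        else:
            warnings.append(f"could not place HT copy of {ev.template_id} in {ev.recipient_species}")

    for g in spec.genomes:
        contigs = contig_map[g.species_id]
        genomes[g.species_id] = [(c.contig_id, c.seq) for c in contigs]
        for c in contigs:
            for r in c.records:
                if not (0 <= r.start < r.end <= len(c.seq)):
                    raise SimulationError(f"internal error: out-of-bounds record {r}")
            truth.extend(sorted(c.records, key=lambda r: (r.start, r.end)))

    return SimulationResult(genomes=genomes, truth=truth, warnings=warnings)


# ---------------------------------------------------------------------------
# reference panels
# ---------------------------------------------------------------------------

def _ungapped_identity(a: str, b: str) -> float:
    return float(np.mean(np.frombuffer(a.encode(), np.uint8) == np.frombuffer(b.encode(), np.uint8)))


def generate_reference_panels(
    templates: TemplateSet,
    seed,
    n_min: int = 8,
    members_per_family: int = 2,
    panel_divergence: float = 0.03,
    margin: float = 0.20,
) -> dict[str, dict[str, list[tuple[str, str]]]]:
    """Per-class, per-domain panels of "canonical" amino-acid sequences.

    Panels stand in for curated repeat-library entries: each family ancestor
    contributes ``members_per_family`` lightly diverged members, padded with
    extra mutants until every class has at least ``n_min`` members per domain.
    Raises :class:`PanelDivergenceError` if mean within-class identity does not
    exceed mean between-class identity by ``margin`` (for >= 2 classes).
    """
    rng = as_generator(seed)
    classes = sorted({t.class_label for t in templates.templates}, key=CLASSES.index)
    if not classes:
        raise SimulationError("no templates")
    panels: dict[str, dict[str, list[tuple[str, str]]]] = {}
    for cls in classes:
        fams = templates.by_class(cls)
        panels[cls] = {d: [] for d in DOMAINS}
        for d in DOMAINS:
            for t in fams:
                for m in range(members_per_family):
                    seq = mutate_aa(t.domain_aa[d], panel_divergence, rng)
                    panels[cls][d].append((f"{cls}|{t.family_id}|{d}|{m + 1}", seq))
            pad = 0
            while len(panels[cls][d]) < n_min:
                t = fams[pad % len(fams)]
                seq = mutate_aa(t.domain_aa[d], panel_divergence, rng)
                pad += 1
                panels[cls][d].append((f"{cls}|{t.family_id}|{d}|pad{pad}", seq))

    if len(classes) >= 2:
        within, between = [], []
        for d in DOMAINS:
            for ci, ca in enumerate(classes):
                seqs_a = [s for _, s in panels[ca][d]]
                for i in range(len(seqs_a)):
                    for j in range(i + 1, len(seqs_a)):
                        within.append(_ungapped_identity(seqs_a[i], seqs_a[j]))
                for cb in classes[ci + 1:]:
                    for sa in seqs_a:
                        for sb in (s for _, s in panels[cb][d]):
                            between.append(_ungapped_identity(sa, sb))
        gap = float(np.mean(within) - np.mean(between))
        if gap < margin:
            raise PanelDivergenceError(
                f"within-class minus between-class identity {gap:.3f} below margin {margin:.3f}"
            )
    return panels
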