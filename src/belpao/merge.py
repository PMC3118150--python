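"""Resolution of nested/overlapping candidates and merging of detector sets.

The decision rules mirror the curation logic used when combining two de novo
LTR detectors: innermost element wins inside nested chains; overlaps within
one detector's output are resolved by a seeded random choice; when both
detectors report the same locus (endpoints within 20 bp) the second detector
(the one trusted for boundary accuracy) wins; otherwise-overlapping pairs are
decided by the 2,000-15,000 bp full-length gate, randomly when both qualify,
and dropped when neither does.  The final element set is overlap-free and
every retained element lies within the length gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import LTRCandidate


@dataclass
class MergedElement:
    element_id: str
    contig_id: str
    start: int
    end: int
    source_detector: str  # "A", "B" or "both"
    class_label: str = "unclassified"
    class_vote: str | None = None
    species_id: str = ""
    seq: str = ""
    provenance: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def locus(self) -> tuple[str, int, int]:
        return (self.contig_id, self.start, self.end)


def _contains(outer: tuple[int, int], inner: tuple[int, int], tol: int,
              min_len_diff: int) -> bool:
    return (outer[0] - tol <= inner[0] and inner[1] <= outer[1] + tol
            and (outer[1] - outer[0]) - (inner[1] - inner[0]) >= min_len_diff)


def resolve_nested(candidates: list[LTRCandidate], tol: int = 30,
                   min_len_diff: int = 200) -> list[LTRCandidate]:
    """Keep only innermost elements of nested chains (per contig).

    A candidate is a host (and removed) when another, shorter candidate lies
    inside its interval.  Detector boundaries jitter by a few bases, so
    containment is judged with a small tolerance.
    """
    out = []
    for x in candidates:
        is_host = any(
            y is not x and _contains((x.start, x.end), (y.start, y.end), tol, min_len_diff)
            for y in candidates if y.contig_id == x.contig_id
        )
        if not is_host:
            out.append(x)
    return out


def resolve_overlaps_within(candidates: list[LTRCandidate], rng: np.random.Generator) -> list[LTRCandidate]:
    """Repeatedly drop a uniformly random member of the first overlapping pair
    until the set is overlap-free.  Deterministic given the generator state."""
    kept = sorted(candidates, key=lambda c: (c.contig_id, c.start, c.end))
    while True:
        clash = None
        for i in range(len(kept) - 1):
            a, b = kept[i], kept[i + 1]
            if a.contig_id == b.contig_id and b.start < a.end:
                clash = (i, i + 1)
                break
        if clash is None:
            return kept
        drop = clash[int(rng.integers(2))]
        kept.pop(drop)


def _overlap(a, b) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_detector_sets(set_a: list, set_b: list, rng: np.random.Generator,
                        tolerance: int = 20,
                        length_range: tuple[int, int] = (2000, 15000)) -> tuple[list[MergedElement], dict]:
    """Merge two per-contig overlap-free candidate sets into the final
    element set (detector B plays the higher-precision role).

    Returns the merged, locus-sorted elements and a report of how often each
    rule fired.
    """
    lo, hi = length_range
    report = {"unique": 0, "same_position": 0, "length_gate": 0,
              "random_choice": 0, "eliminated": 0, "out_of_range": 0}
    chosen: list[tuple[object, str]] = []

    by_contig: dict[str, tuple[list, list]] = {}
    for c in set_a:
        by_contig.setdefault(c.contig_id, ([], []))[0].append(c)
    for c in set_b:
        by_contig.setdefault(c.contig_id, ([], []))[1].append(c)

    for contig_id in sorted(by_contig):
        ca, cb = by_contig[contig_id]
        ca = sorted(ca, key=lambda c: (c.start, c.end))
        cb = sorted(cb, key=lambda c: (c.start, c.end))
        used_b: set[int] = set()
        for a in ca:
            overlaps = [(j, _overlap(a, b)) for j, b in enumerate(cb)
                        if j not in used_b and _overlap(a, b) > 0]
            if not overlaps:
                report["unique"] += 1
                chosen.append((a, "A-unique"))
                continue
            j = max(overlaps, key=lambda jo: jo[1])[0]
            b = cb[j]
            used_b.add(j)
            if abs(a.start - b.start) <= tolerance and abs(a.end - b.end) <= tolerance:
                report["same_position"] += 1
                chosen.append((b, "both-within-20bp:B"))
                continue
            a_ok = lo <= (a.end - a.start) <= hi
            b_ok = lo <= (b.end - b.start) <= hi
            if a_ok and b_ok:
                report["random_choice"] += 1
                pick, tag = ((a, "overlap-random:A") if rng.integers(2) == 0
                             else (b, "overlap-random:B"))
                chosen.append((pick, tag))
            elif a_ok or b_ok:
                report["length_gate"] += 1
                chosen.append((a, "length-gate:A") if a_ok else (b, "length-gate:B"))
            else:
                report["eliminated"] += 1
        for j, b in enumerate(cb):
            if j not in used_b:
                report["unique"] += 1
                chosen.append((b, "B-unique"))

    out: list[MergedElement] = []
    for cand, tag in chosen:
        length = cand.end - cand.start
        if not lo <= length <= hi:
            report["out_of_range"] += 1
            continue
        if tag.startswith(("both", "overlap", "length")):
            source = "both"
        else:
            source = getattr(cand, "detector_tag", None) or getattr(cand, "source_detector", "A")
        out.append(MergedElement(
            element_id="", contig_id=cand.contig_id, start=cand.start, end=cand.end,
            source_detector=source, class_label=getattr(cand, "class_label", "unclassified"),
            class_vote=getattr(cand, "class_vote", None),
            species_id=getattr(cand, "species_id", ""), seq=getattr(cand, "seq", ""),
            provenance=tag,
        ))
    out.sort(key=lambda e: (e.contig_id, e.start, e.end))
    for i, e in enumerate(out):
        e.element_id = f"{e.species_id or 'el'}_{i + 1}"
    return out, report
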