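"""Clustering of genes and assembled transcripts into transcript units.

A transcript unit is the union of all same-strand, same-scaffold models
whose spans overlap, taken to transitive closure — the locus-level atom that
the antisense search pairs against predicted genes. Overlap means shared
bases (>= 1 bp); abutting intervals do not merge. Clustering works on
transcript spans, not exon chains: an intron-only overlap still marks one
locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .genome_io import (
    SOURCE_GENE,
    GenomicInterval,
    TranscriptModel,
    write_bed6,
)


@dataclass
class TranscriptUnit:
    """A connected component of overlapping same-strand models."""

    id: str
    scaffold: str
    strand: str
    span: GenomicInterval
    members: list[str]
    contains_gene: bool

    @property
    def length(self) -> int:
        return self.span.length


def build_transcript_units(models: Sequence[TranscriptModel]) -> list[TranscriptUnit]:
    """Partition ``models`` into transcript units.

    Two models land in the same unit iff they are connected by a chain of
    same-scaffold, same-strand span overlaps. Unit ids are assigned in
    (scaffold, start, strand) order, so the result is independent of input
    order.
    """
    groups: dict[tuple[str, str], list[TranscriptModel]] = {}
    for m in models:
        groups.setdefault((m.scaffold, m.strand), []).append(m)

    clusters: list[list[TranscriptModel]] = []
    for (scaffold, strand), members in groups.items():
        members = sorted(members, key=lambda m: (m.interval.start, m.interval.end, m.id))
        current: list[TranscriptModel] = []
        current_end = -1
        for m in members:
            if current and m.interval.start < current_end:
                current.append(m)
                current_end = max(current_end, m.interval.end)
            else:
                if current:
                    clusters.append(current)
                current = [m]
                current_end = m.interval.end
        if current:
            clusters.append(current)

    clusters.sort(key=lambda c: (c[0].scaffold, min(m.interval.start for m in c), c[0].strand))
    width = max(4, len(str(len(clusters))))
    units = []
    for i, cluster in enumerate(clusters, 1):
        start = min(m.interval.start for m in cluster)
        end = max(m.interval.end for m in cluster)
        first = cluster[0]
        units.append(
            TranscriptUnit(
                id=f"TU{i:0{width}d}",
                scaffold=first.scaffold,
                strand=first.strand,
                span=GenomicInterval(first.scaffold, start, end, first.strand),
                members=sorted(m.id for m in cluster),
                contains_gene=any(m.source == SOURCE_GENE for m in cluster),
            )
        )
    return units


def write_units_bed(units: Iterable[TranscriptUnit], path: str | Path) -> None:
    """Export units as BED6 (name = unit id, score = member count)."""
    write_bed6(
        (
            (u.scaffold, u.span.start, u.span.end, u.id, len(u.members), u.strand)
            for u in units
        ),
        path,
    )
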