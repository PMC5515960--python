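"""Candidate cis-NAT detection and SAT-pair configuration typing.

A cis-NAT candidate is a transcript unit on the strand opposite a predicted
gene at the same locus, admitted when the span overlap reaches at least 10%
of the length of either partner (the "any" rule; a stricter "both" rule is
available). Each admitted sense/antisense pair is classified into one of the
four canonical configurations: divergent (head-to-head, 5'-5'), convergent
(tail-to-tail, 3'-3'), S_contains_N (NAT embedded in the sense transcript)
or N_contains_S (NAT spanning the sense transcript).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome_io import GenomicInterval, Span, TranscriptModel
from .unitize import TranscriptUnit

#: the four SAT-pair configurations
DIVERGENT = "divergent"
CONVERGENT = "convergent"
S_CONTAINS_N = "S_contains_N"
N_CONTAINS_S = "N_contains_S"
CONFIGURATIONS = (DIVERGENT, CONVERGENT, S_CONTAINS_N, N_CONTAINS_S)


@dataclass
class CisPair:
    """One sense-transcript / antisense-unit pairing with its evidence."""

    st_id: str
    nat_id: str
    scaffold: str
    st_interval: GenomicInterval
    nat_interval: GenomicInterval
    overlap: Span
    config: str
    frac_of_st: float
    frac_of_nat: float


def classify_cis_pair(st: GenomicInterval, nat: GenomicInterval) -> str:
    """Classify an overlapping opposite-strand pair into its configuration.

    Containment is checked first; otherwise the overlapped end of the sense
    transcript decides: overlap covering the ST's 5' end means divergent
    (head-to-head), its 3' end convergent (tail-to-tail). For identical
    spans (mutual containment) N_contains_S is returned.
    """
    if st.strand == nat.strand:
        raise ValueError("classify_cis_pair requires opposite strands")
    if not st.overlaps(nat):
        raise ValueError("classify_cis_pair requires overlapping intervals")
    if nat.contains(st):
        return N_CONTAINS_S
    if st.contains(nat):
        return S_CONTAINS_N
    # partial overlap: exactly one end of the ST is covered
    overlaps_left = nat.start <= st.start
    five_prime_left = st.strand == "+"
    if overlaps_left == five_prime_left:
        return DIVERGENT
    return CONVERGENT


def find_cis_candidates(
    units: Sequence[TranscriptUnit],
    genes: Sequence[TranscriptModel],
    min_frac: float = 0.10,
    overlap_rule: str = "any",
) -> list[CisPair]:
    """All admissible (gene, opposite-strand unit) pairs.

    Candidate antisense units are those without a predicted-gene member.
    A pair is admitted when the span overlap length reaches ``min_frac``
    of the length of at least one partner (``overlap_rule='any'``) or of
    both (``'both'``). Output is sorted by (scaffold, ST start, NAT start).
    """
    if not (0 < min_frac <= 1):
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    if overlap_rule not in ("any", "both"):
        raise ValueError(f"overlap_rule must be 'any' or 'both', got {overlap_rule!r}")

    trees: dict[tuple[str, str], IntervalTree] = {}
    for unit in units:
        if unit.contains_gene:
            continue
        trees.setdefault((unit.scaffold, unit.strand), IntervalTree()).addi(
            unit.span.start, unit.span.end, unit
        )

    pairs: list[CisPair] = []
    for gene in genes:
        opposite = "-" if gene.strand == "+" else "+"
        tree = trees.get((gene.scaffold, opposite))
        if tree is None:
            continue
        for hit in tree.overlap(gene.interval.start, gene.interval.end):
            unit: TranscriptUnit = hit.data
            span = gene.interval.overlap_span(unit.span)
            assert span is not None
            frac_st = span.length / gene.interval.length
            frac_nat = span.length / unit.span.length
            ok_st = frac_st >= min_frac
            ok_nat = frac_nat >= min_frac
            admitted = (ok_st or ok_nat) if overlap_rule == "any" else (ok_st and ok_nat)
            if not admitted:
                continue
            pairs.append(
                CisPair(
                    st_id=gene.id,
                    nat_id=unit.id,
                    scaffold=gene.scaffold,
                    st_interval=gene.interval,
                    nat_interval=unit.span,
                    overlap=span,
                    config=classify_cis_pair(gene.interval, unit.span),
                    frac_of_st=frac_st,
                    frac_of_nat=frac_nat,
                )
            )
    pairs.sort(key=lambda p: (p.scaffold, p.st_interval.start, p.nat_interval.start, p.nat_id))
    return pairs


def overlap_ratio_profile(pairs: Iterable[CisPair]) -> pd.DataFrame:
    """Per-pair overlap lengths and fractional coverages (one row per pair)."""
    rows = [
        {
            "st_id": p.st_id,
            "nat_id": p.nat_id,
            "overlap_len": p.overlap.length,
            "frac_of_st": p.frac_of_st,
            "frac_of_nat": p.frac_of_nat,
            "config": p.config,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=["st_id", "nat_id", "overlap_len",
                                       "frac_of_st", "frac_of_nat", "config"])


def write_cis_catalog(pairs: Iterable[CisPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "st_id\tnat_id\tscaffold\tst_start\tst_end\tst_strand\t"
            "nat_start\tnat_end\tnat_strand\toverlap_len\t"
            "frac_of_st\tfrac_of_nat\tconfig\n"
        )
        for p in pairs:
            fh.write(
                f"{p.st_id}\t{p.nat_id}\t{p.scaffold}\t"
                f"{p.st_interval.start}\t{p.st_interval.end}\t{p.st_interval.strand}\t"
                f"{p.nat_interval.start}\t{p.nat_interval.end}\t{p.nat_interval.strand}\t"
                f"{p.overlap.length}\t{p.frac_of_st:.4f}\t{p.frac_of_nat:.4f}\t{p.config}\n"
            )


#: RGB colors for the BED12 track, one per configuration
_CONFIG_COLORS = {
    DIVERGENT: "27,158,119",
    CONVERGENT: "217,95,2",
    S_CONTAINS_N: "117,112,179",
    N_CONTAINS_S: "231,41,138",
}


def write_cis_bed12(pairs: Iterable[CisPair], path: str | Path) -> None:
    """BED12 track of antisense partners colored by configuration."""
    with open(path, "w") as fh:
        for p in pairs:
            iv = p.nat_interval
            fh.write(
                f"{p.scaffold}\t{iv.start}\t{iv.end}\t{p.nat_id}|{p.config}\t0\t"
                f"{iv.strand}\t{iv.start}\t{iv.end}\t{_CONFIG_COLORS[p.config]}\t"
                f"1\t{iv.length},\t0,\n"
            )
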