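"""Remote (trans) antisense pair detection.

A trans-NAT is transcribed from a locus remote from its sense transcript and
is only partially complementary to it. Detection runs in three chained
steps on spliced sequences:

1. **Complementarity search** — gap-free runs where a window of one sequence
   equals the reverse complement of a window of the other, found by exact
   12-mer seeding on the reverse-complemented partner and extension across
   isolated mismatches down to a configurable identity floor. A pair whose
   longest run exceeds 100 nt is a "100-nt pair".
2. **Coverage** — the run must exceed 50% of the length of at least one of
   the two sequences ("high-coverage").
3. **Duplex annealing** — a local hybridization alignment (match +1,
   mismatch -1, gap open -2, gap extend -0.5) around the run must coincide
   with it, and every interior bubble (maximal run of unpaired columns) must
   be no longer than 10% of the annealed region's length.

N never base-pairs and always counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .genome_io import Span, TranscriptModel, extract_sequence, reverse_complement
from .unitize import build_transcript_units

DEFAULT_SEED_LEN = 12
DEFAULT_IDENTITY_FLOOR = 0.8


@dataclass
class ComplementaryRegion:
    """A gap-free complementary run between two sequences.

    Spans are 0-based half-open offsets within each spliced sequence, read
    5'->3' of that sequence; both have the same length (gap-free core).
    """

    a_id: str
    b_id: str
    a_span: Span
    b_span: Span
    length: int
    identity: float


@dataclass
class DuplexResult:
    """Outcome of annealing two sequences around a seed region."""

    annealed_span_a: Span
    annealed_span_b: Span
    region_len: int          # annealed block length in alignment columns
    bubbles: list[int]       # interior unpaired-run lengths, in columns
    coincides: bool
    passes: bool


@dataclass
class TransPair:
    """A sense transcript paired with a remote antisense transcript."""

    st_id: str
    nat_id: str
    region: ComplementaryRegion
    duplex: DuplexResult
    coverage_st: float
    coverage_nat: float
    high_coverage: bool


@dataclass
class TransSearchConfig:
    min_complement_nt: int = 100       # run must be strictly longer than this
    coverage_frac: float = 0.50        # run must exceed this fraction of a sequence
    coverage_rule: str = "any"         # 'any' or 'both' sequences
    bubble_max_frac: float = 0.10
    seed_len: int = DEFAULT_SEED_LEN
    identity_floor: float = DEFAULT_IDENTITY_FLOOR
    min_distance: int = 0              # extra genomic gap required beyond non-overlap


# ---------------------------------------------------------------------------
# complementarity search
# ---------------------------------------------------------------------------

def _runs(bools: Sequence[bool]) -> list[tuple[bool, int, int]]:
    """Run-length encode a boolean sequence as (value, start, end) triples."""
    out: list[tuple[bool, int, int]] = []
    start = 0
    for i in range(1, len(bools) + 1):
        if i == len(bools) or bools[i] != bools[start]:
            out.append((bools[start], start, i))
            start = i
    return out


def _extend_core(
    runs: list[tuple[bool, int, int]], core_idx: int, identity_floor: float
) -> tuple[int, int, int]:
    """Grow a core match-run across isolated mismatches.

    Returns (start, end, matches) of the extended region. A mismatch run is
    crossed only if it is a single column flanked by matches and the overall
    identity stays at or above the floor. Extension is greedy, right first.
    """
    _, start, end = runs[core_idx]
    matches = end - start
    lo_idx = hi_idx = core_idx

    def try_step(idx: int, direction: int, start: int, end: int, matches: int):
        gap_idx = idx + direction
        nxt_idx = idx + 2 * direction
        if not (0 <= gap_idx < len(runs) and 0 <= nxt_idx < len(runs)):
            return None
        gap_val, g0, g1 = runs[gap_idx]
        nxt_val, n0, n1 = runs[nxt_idx]
        if gap_val or g1 - g0 != 1 or not nxt_val:
            return None
        new_start = min(start, n0)
        new_end = max(end, n1)
        new_matches = matches + (n1 - n0)
        if new_matches / (new_end - new_start) < identity_floor:
            return None
        return new_start, new_end, new_matches, nxt_idx

    moved = True
    while moved:
        moved = False
        step = try_step(hi_idx, +1, start, end, matches)
        if step:
            start, end, matches, hi_idx = step
            moved = True
        step = try_step(lo_idx, -1, start, end, matches)
        if step:
            start, end, matches, lo_idx = step
            moved = True
    return start, end, matches


def find_complementary_regions(
    a: str,
    b: str,
    min_len: int = 100,
    a_id: str = "a",
    b_id: str = "b",
    seed_len: int = DEFAULT_SEED_LEN,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> list[ComplementaryRegion]:
    """Maximal gap-free complementary runs of length >= ``min_len``.

    Runs are found where a window of ``a`` equals the reverse complement of
    a window of ``b``: exact seed cores of ``seed_len`` are located by
    k-mer indexing and extended across isolated single mismatches while the
    region identity stays >= ``identity_floor``. Output is ordered by
    (a offset, b offset).
    """
    if min_len < seed_len:
        raise ValueError(f"min_len must be >= seed size {seed_len}, got {min_len}")
    if not a or not b:
        return []
    a = a.upper()
    rcb = reverse_complement(b.upper())
    if len(a) < seed_len or len(rcb) < seed_len:
        return []

    index: dict[str, list[int]] = {}
    for i in range(len(a) - seed_len + 1):
        kmer = a[i : i + seed_len]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    diagonals: set[int] = set()
    for j in range(len(rcb) - seed_len + 1):
        kmer = rcb[j : j + seed_len]
        if "N" in kmer:
            continue
        for i in index.get(kmer, ()):
            diagonals.add(i - j)

    regions: dict[tuple[int, int], tuple[int, int, int]] = {}  # (d, start) -> (start,end,matches)
    for d in sorted(diagonals):
        j0 = max(0, -d)
        j1 = min(len(rcb), len(a) - d)
        if j1 - j0 < seed_len:
            continue
        match = [
            a[j + d] == rcb[j] and a[j + d] != "N" for j in range(j0, j1)
        ]
        runs = _runs(match)
        spans_on_diag: set[tuple[int, int, int]] = set()
        for idx, (val, s, e) in enumerate(runs):
            if val and e - s >= seed_len:
                spans_on_diag.add(_extend_core(runs, idx, identity_floor))
        for s, e, matches in spans_on_diag:
            if e - s >= min_len:
                regions[(d, j0 + s)] = (j0 + s, j0 + e, matches)

    out = []
    for (d, _), (s, e, matches) in regions.items():
        length = e - s
        out.append(
            ComplementaryRegion(
                a_id=a_id,
                b_id=b_id,
                a_span=Span(d + s, d + e),
                b_span=Span(len(b) - e, len(b) - s),
                length=length,
                identity=matches / length,
            )
        )
    out.sort(key=lambda r: (r.a_span.start, r.b_span.start))
    return out


# ---------------------------------------------------------------------------
# duplex annealing
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    return aligner


def _absorb_short_helices(columns: list[str], min_helix: int) -> list[str]:
    """Reclassify interior paired runs shorter than ``min_helix`` as unpaired.

    A lone base pair (or a 2-bp stack) inside a large unpaired stretch
    cannot nucleate a stable helix, so it belongs to the surrounding
    bubble. Applied repeatedly until stable; terminal runs are kept, as
    they delimit the annealed block.
    """
    cols = list(columns)
    changed = True
    while changed:
        changed = False
        runs = _runs([c == "M" for c in cols])
        for val, s, e in runs:
            if val and e - s < min_helix and s > 0 and e < len(cols):
                if cols[s - 1] != "M" and cols[e] != "M":
                    for i in range(s, e):
                        cols[i] = "X"
                    changed = True
    return cols


def anneal_duplex(
    a: str,
    b: str,
    seed: ComplementaryRegion,
    bubble_max_frac: float = 0.10,
    neighborhood: int = 100,
    min_helix: int = 3,
) -> DuplexResult:
    """Anneal ``a`` against ``b`` around a seed complementary region.

    The seed's neighborhood of ``a`` is locally aligned against the reverse
    complement of the corresponding neighborhood of ``b``. The annealed
    region is the maximal-scoring aligned block; bubbles are the maximal
    interior runs of unpaired columns (mismatches or gaps), after paired
    runs shorter than ``min_helix`` inside unpaired stretches are absorbed
    into them (an isolated pair cannot hold a helix open). The duplex
    passes when the annealed region shares at least one base with the seed
    on both sequences and no bubble exceeds ``bubble_max_frac`` of the
    annealed region's column length.
    """
    a = a.upper()
    b = b.upper()
    a_off = max(0, seed.a_span.start - neighborhood)
    a_sub = a[a_off : min(len(a), seed.a_span.end + neighborhood)]
    b_off = max(0, seed.b_span.start - neighborhood)
    b_sub = b[b_off : min(len(b), seed.b_span.end + neighborhood)]
    rcb = reverse_complement(b_sub)

    alignment = next(iter(_make_aligner().align(a_sub, rcb)), None)
    if alignment is None or alignment.score <= 0:
        return DuplexResult(Span(0, 0), Span(0, 0), 0, [], False, False)

    a_blocks, r_blocks = alignment.aligned
    columns: list[str] = []       # 'M' match, 'X' mismatch, 'G' gap
    consume: list[tuple[int, int]] = []  # (a, rcb) positions consumed per column
    prev_a_end = prev_r_end = None
    for (a0, a1), (r0, r1) in zip(a_blocks, r_blocks):
        if prev_a_end is not None:
            for _ in range(a0 - prev_a_end):
                columns.append("G")
                consume.append((1, 0))
            for _ in range(r0 - prev_r_end):
                columns.append("G")
                consume.append((0, 1))
        for ai, ri in zip(range(a0, a1), range(r0, r1)):
            paired = a_sub[ai] == rcb[ri] and a_sub[ai] != "N"
            columns.append("M" if paired else "X")
            consume.append((1, 1))
        prev_a_end, prev_r_end = a1, r1

    columns = _absorb_short_helices(columns, min_helix)

    # annealed block = maximal-scoring contiguous stretch of columns
    # (+1 paired, -1 unpaired); weak spurious extension into flanking
    # sequence is trimmed away here
    best = (0, 0, 0)  # (score, start, end)
    score, start = 0, 0
    for i, col in enumerate(columns):
        score += 1 if col == "M" else -1
        if score <= 0:
            score, start = 0, i + 1
        elif score > best[0]:
            best = (score, start, i + 1)
    c0, c1 = best[1], best[2]
    if c1 <= c0:
        return DuplexResult(Span(0, 0), Span(0, 0), 0, [], False, False)
    block = columns[c0:c1]
    region_len = len(block)
    bubbles: list[int] = []
    run = 0
    for col in block:
        if col == "M":
            if run:
                bubbles.append(run)
            run = 0
        else:
            run += 1

    a0_full = int(a_blocks[0][0])
    r0_full = int(r_blocks[0][0])
    a_start = a_off + a0_full + sum(c[0] for c in consume[:c0])
    a_end = a_start + sum(c[0] for c in consume[c0:c1])
    r_start = r0_full + sum(c[1] for c in consume[:c0])
    r_end = r_start + sum(c[1] for c in consume[c0:c1])
    b_start = b_off + len(b_sub) - r_end
    b_end = b_off + len(b_sub) - r_start
    span_a = Span(a_start, a_end)
    span_b = Span(b_start, b_end)

    coincides = (
        min(a_end, seed.a_span.end) > max(a_start, seed.a_span.start)
        and min(b_end, seed.b_span.end) > max(b_start, seed.b_span.start)
    )
    passes = coincides and all(bub <= bubble_max_frac * region_len for bub in bubbles)
    return DuplexResult(span_a, span_b, region_len, bubbles, coincides, passes)


# ---------------------------------------------------------------------------
# candidate search
# ---------------------------------------------------------------------------

def find_trans_candidates(
    genes: Sequence[TranscriptModel],
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, object],
    config: TransSearchConfig | None = None,
) -> list[TransPair]:
    """Remote sense/antisense pairs passing all three trans criteria.

    A (gene, transcript) pair is considered only when the two come from
    different transcript units with zero genomic span overlap ("located
    remotely"). It is reported when it holds a complementary run strictly
    longer than ``min_complement_nt``, the run is high-coverage, and the
    duplex anneals cleanly under the bubble rule. Regions are tried longest
    first and the first passing one is reported.
    """
    cfg = config or TransSearchConfig()
    units = build_transcript_units(list(genes) + list(transcripts))
    unit_of: dict[str, str] = {}
    for u in units:
        for member in u.members:
            unit_of[member] = u.id

    gene_seqs = {g.id: extract_sequence(g, genome) for g in genes}
    tx_seqs = {t.id: extract_sequence(t, genome) for t in transcripts}

    pairs: list[TransPair] = []
    for gene in genes:
        gseq = gene_seqs[gene.id]
        for tx in transcripts:
            if unit_of[gene.id] == unit_of[tx.id]:
                continue
            if gene.scaffold == tx.scaffold:
                gap = max(
                    tx.interval.start - gene.interval.end,
                    gene.interval.start - tx.interval.end,
                )
                if gap < cfg.min_distance or gene.interval.overlaps(tx.interval):
                    continue
            tseq = tx_seqs[tx.id]
            regions = find_complementary_regions(
                gseq,
                tseq,
                min_len=max(cfg.min_complement_nt, cfg.seed_len),
                a_id=gene.id,
                b_id=tx.id,
                seed_len=cfg.seed_len,
                identity_floor=cfg.identity_floor,
            )
            for region in sorted(regions, key=lambda r: (-r.length, r.a_span.start)):
                if region.length <= cfg.min_complement_nt:
                    continue
                cov_st = region.length / len(gseq)
                cov_nat = region.length / len(tseq)
                above = (cov_st > cfg.coverage_frac, cov_nat > cfg.coverage_frac)
                high = any(above) if cfg.coverage_rule == "any" else all(above)
                if not high:
                    continue
                duplex = anneal_duplex(gseq, tseq, region, cfg.bubble_max_frac)
                if duplex.passes:
                    pairs.append(
                        TransPair(
                            st_id=gene.id,
                            nat_id=tx.id,
                            region=region,
                            duplex=duplex,
                            coverage_st=cov_st,
                            coverage_nat=cov_nat,
                            high_coverage=True,
                        )
                    )
                    break
    pairs.sort(key=lambda p: (p.st_id, p.nat_id))
    return pairs


def write_trans_catalog(pairs: Iterable[TransPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "st_id\tnat_id\ta_start\ta_end\tb_start\tb_end\tregion_len\t"
            "identity\tcoverage_st\tcoverage_nat\tn_bubbles\tmax_bubble_frac\tpasses\n"
        )
        for p in pairs:
            max_frac = (
                max(p.duplex.bubbles) / p.duplex.region_len if p.duplex.bubbles else 0.0
            )
            fh.write(
                f"{p.st_id}\t{p.nat_id}\t{p.region.a_span.start}\t{p.region.a_span.end}\t"
                f"{p.region.b_span.start}\t{p.region.b_span.end}\t{p.region.length}\t"
                f"{p.region.identity:.4f}\t{p.coverage_st:.4f}\t{p.coverage_nat:.4f}\t"
                f"{len(p.duplex.bubbles)}\t{max_frac:.4f}\t{p.duplex.passes}\n"
            )
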