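"""Seeded generator of desk-scale fixtures with planted ground truth.

Emits exactly the formats the pipeline reads — genome FASTA, gene GFF3,
transcript GTF, a three-stage expression TSV, evidence TSVs and an
annotation map — together with a truth table describing what was planted:

* sense/antisense pairs in all four cis configurations, plus multiplex
  motifs producing 1:n, n:1 and n:n mapping relationships;
* remote reverse-complement segments forming trans pairs, including
  duplexes with small (passing) and large (failing) bubbles;
* one decoy class per filter criterion, each violating exactly one rule by
  a stated margin (sub-threshold overlap, short length, long ORF, protein
  hit, positive coding score, housekeeping/small-RNA hit, short or
  low-coverage complements);
* stage-specific presence patterns and positively/negatively correlated
  sense/antisense expression profiles;
* one deliberately over-represented functional category.

The same seed produces a byte-identical bundle. Planted parameters are
recomputable from the emitted files, which is what the recovery tests
check. Random sequence is uniform ACGT at a configurable GC content;
planted antisense transcripts are single-exon so spliced and genomic span
sequences coincide, while some genes and sense transcripts carry introns.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import (
    SOURCE_ASSEMBLED,
    SOURCE_GENE,
    GenomicInterval,
    TranscriptModel,
    reverse_complement,
    write_evidence_table,
    write_fasta,
    write_gff3_genes,
    write_gtf_transcripts,
)

STAGES = ("M", "P", "FB")
ENRICHED_TERM = "GO:TEST001"

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class SyntheticConfig:
    """Counts and sizes of the planted classes (the study conditions)."""

    n_per_config: int = 3            # cis pairs planted per configuration
    n_background_genes: int = 10     # genes without antisense partners
    include_decoys: bool = True
    include_motifs: bool = True      # 1:n, n:1, n:n relationship motifs
    include_trans: bool = True
    n_scaffolds: int = 6
    scaffold_len: int = 30000
    gap: int = 400                   # spacing between planted loci
    gc: float = 0.5
    rpkm_present: tuple[float, float] = (5.0, 25.0)
    rpkm_absent: tuple[float, float] = (0.05, 0.8)


@dataclass
class PlantedCis:
    st_id: str
    nat_id: str
    config: str
    frac_of_st: float
    frac_of_nat: float
    relation: str = "1:1"


@dataclass
class PlantedCisDecoy:
    st_id: str
    nat_id: str
    reason: str  # subthreshold|length|orf|nr|cpc|housekeeping|smallrna


@dataclass
class PlantedTrans:
    st_id: str
    nat_id: str
    region_len: int      # longest clean complementary run, exact by construction
    coverage_nat: float
    bubble_len: int
    expect_pass: bool
    reason: str = ""     # why a decoy fails: short|coverage|bubble


@dataclass
class SyntheticTruth:
    planted_cis: list[PlantedCis] = field(default_factory=list)
    cis_decoys: list[PlantedCisDecoy] = field(default_factory=list)
    planted_trans: list[PlantedTrans] = field(default_factory=list)
    coding_labels: dict[str, str] = field(default_factory=dict)
    planted_correlations: list[tuple[str, str, int]] = field(default_factory=list)
    stage_patterns: dict[str, list[str]] = field(default_factory=dict)
    enriched_terms: list[str] = field(default_factory=list)

    @property
    def final_cis_nat_ids(self) -> set[str]:
        return {p.nat_id for p in self.planted_cis}

    @property
    def final_trans_nat_ids(self) -> set[str]:
        return {p.nat_id for p in self.planted_trans if p.expect_pass}


@dataclass
class FixtureBundle:
    outdir: Path
    genome: dict[str, str]
    genes: list[TranscriptModel]
    transcripts: list[TranscriptModel]
    truth: SyntheticTruth
    paths: dict[str, Path]


class _Builder:
    def __init__(self, cfg: SyntheticConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.names = [f"scaffold_{i + 1}" for i in range(cfg.n_scaffolds)]
        self.seqs: dict[str, list[str]] = {}
        for name in self.names:
            p = [(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2]
            draws = rng.choice(4, size=cfg.scaffold_len, p=p)
            self.seqs[name] = [_BASES[i] for i in draws]
        self.cursors = {name: 200 for name in self.names}
        self.genes: list[TranscriptModel] = []
        self.transcripts: list[TranscriptModel] = []
        self._gene_no = 10000
        self._at_no = 10000
        self._tc_no = 10000

    # -- placement ---------------------------------------------------------

    def place(self, width: int, avoid: str | None = None) -> tuple[str, int]:
        for name in self.names:
            if name == avoid:
                continue
            if self.cursors[name] + width + self.cfg.gap <= self.cfg.scaffold_len - 200:
                start = self.cursors[name]
                self.cursors[name] = start + width + self.cfg.gap
                return name, start
        raise RuntimeError(
            f"genome too small to place a {width}-nt locus: raise scaffold_len "
            f"(now {self.cfg.scaffold_len}) or n_scaffolds (now {self.cfg.n_scaffolds})"
        )

    # -- feature registration ---------------------------------------------

    def add_gene(self, scaffold: str, start: int, length: int, strand: str,
                 n_exons: int = 1) -> TranscriptModel:
        self._gene_no += 1
        gid = f"GL{self._gene_no}"
        exons = self._exon_chain(scaffold, start, length, strand, n_exons)
        model = TranscriptModel(
            gid, GenomicInterval(scaffold, start, start + length, strand),
            exons, source=SOURCE_GENE,
        )
        self.genes.append(model)
        return model

    def add_nat(self, scaffold: str, start: int, length: int, strand: str) -> TranscriptModel:
        self._at_no += 1
        tid = f"AT{self._at_no}"
        iv = GenomicInterval(scaffold, start, start + length, strand)
        model = TranscriptModel(tid, iv, [iv], source=SOURCE_ASSEMBLED)
        self.transcripts.append(model)
        return model

    def add_sense_copy(self, gene: TranscriptModel) -> TranscriptModel:
        self._tc_no += 1
        tid = f"TC{self._tc_no}"
        model = TranscriptModel(
            tid, gene.interval, list(gene.exons), source=SOURCE_ASSEMBLED
        )
        self.transcripts.append(model)
        return model

    def _exon_chain(self, scaffold: str, start: int, length: int, strand: str,
                    n_exons: int) -> list[GenomicInterval]:
        if n_exons <= 1 or length < 300:
            return [GenomicInterval(scaffold, start, start + length, strand)]
        # carve introns of ~60 nt at deterministic fractions of the span
        intron = 60
        usable = length - intron * (n_exons - 1)
        cuts = sorted(
            int(usable * f) for f in np.linspace(0.3, 0.7, n_exons - 1)
        )
        exons = []
        pos = start
        prev = 0
        for i, cut in enumerate(cuts + [usable]):
            exon_len = cut - prev
            exons.append(GenomicInterval(scaffold, pos, pos + exon_len, strand))
            pos += exon_len + intron
            prev = cut
        return exons

    # -- sequence access / patching ---------------------------------------

    def spliced(self, model: TranscriptModel) -> str:
        parts = [
            "".join(self.seqs[model.scaffold][e.start:e.end]) for e in model.exons
        ]
        seq = "".join(parts)
        return reverse_complement(seq) if model.strand == "-" else seq

    def write_transcript_seq(self, model: TranscriptModel, seq: str) -> None:
        """Overwrite the genome under a single-exon model with ``seq``
        (given 5'->3' on the model's strand)."""
        assert len(model.exons) == 1 and len(seq) == model.interval.length
        genomic = reverse_complement(seq) if model.strand == "-" else seq
        self.seqs[model.scaffold][model.interval.start : model.interval.end] = list(genomic)

    def set_base(self, scaffold: str, pos: int, base: str) -> None:
        self.seqs[scaffold][pos] = base

    def random_bases(self, n: int, exclude_stops_in_frame: bool = False) -> str:
        if exclude_stops_in_frame:
            # random codons avoiding TAA/TAG/TGA
            codons = []
            stops = {"TAA", "TAG", "TGA"}
            while len(codons) < n // 3:
                c = "".join(_BASES[i] for i in self.rng.integers(0, 4, 3))
                if c not in stops:
                    codons.append(c)
            return "".join(codons)
        return "".join(_BASES[i] for i in self.rng.integers(0, 4, n))

    def mismatching_base(self, must_differ_from: str) -> str:
        choices = [b for b in _BASES if b != must_differ_from]
        return choices[int(self.rng.integers(0, len(choices)))]


# ---------------------------------------------------------------------------
# ORF handling
# ---------------------------------------------------------------------------

def _longest_orf_coords(seq: str) -> tuple[int, int] | None:
    """(aa_length, nt offset of the start codon) of the longest complete ORF."""
    best: tuple[int, int] | None = None
    stops = {"TAA", "TAG", "TGA"}
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in stops:
                if start is not None:
                    aa = (pos - start) // 3
                    if best is None or aa > best[0]:
                        best = (aa, start)
                    start = None
            elif codon == "ATG" and start is None:
                start = pos
    return best


def _disrupt_long_orfs(builder: _Builder, model: TranscriptModel, max_aa: int = 100) -> None:
    """Insert in-frame stops until the transcript has no ORF above ``max_aa``.

    Only used on planted non-coding antisense transcripts (single exon), so
    the genome under them can be patched freely.
    """
    while True:
        seq = builder.spliced(model)
        hit = _longest_orf_coords(seq)
        if hit is None or hit[0] <= max_aa:
            return
        aa, start_nt = hit
        mid_codon = start_nt + 3 * (aa // 2)
        seq = seq[:mid_codon] + "TAA" + seq[mid_codon + 3 :]
        builder.write_transcript_seq(model, seq)


# ---------------------------------------------------------------------------
# planting helpers
# ---------------------------------------------------------------------------

def _partial_overlap_coords(
    gene_start: int, gene_len: int, nat_len: int, ov: int, at_right_end: bool
) -> int:
    """Start coordinate of an antisense span overlapping one gene end."""
    if at_right_end:
        return gene_start + gene_len - ov
    return gene_start + ov - nat_len


def _plant_config_pair(
    b: _Builder, truth: SyntheticTruth, config: str
) -> tuple[TranscriptModel, TranscriptModel]:
    rng = b.rng
    strand = "+" if rng.random() < 0.5 else "-"
    anti = "-" if strand == "+" else "+"
    if config == "S_contains_N":
        nat_len = int(rng.integers(250, 550))
        gene_len = nat_len + int(rng.integers(250, 600))
    elif config == "N_contains_S":
        gene_len = int(rng.integers(350, 700))
        nat_len = gene_len + int(rng.integers(150, 400))
    else:
        gene_len = int(rng.integers(900, 1500))
        nat_len = int(rng.integers(260, 650))
    margin = 700
    scaffold, slot = b.place(margin + max(gene_len, nat_len) + margin)
    gene_start = slot + margin
    n_exons = int(rng.integers(1, 4))
    gene = b.add_gene(scaffold, gene_start, gene_len, strand, n_exons=n_exons)

    if config == "S_contains_N":
        nat_start = gene_start + int(rng.integers(40, gene_len - nat_len - 40))
        ov = nat_len
    elif config == "N_contains_S":
        nat_start = gene_start - int(rng.integers(30, nat_len - gene_len - 30))
        ov = gene_len
    else:
        ov = int(nat_len * rng.uniform(0.3, 0.7))
        ov = min(ov, gene_len - 50)
        # convergent overlaps the gene's 3' end; on '+' that is the right end
        right = (config == "convergent") == (strand == "+")
        nat_start = _partial_overlap_coords(gene_start, gene_len, nat_len, ov, right)
    nat = b.add_nat(scaffold, nat_start, nat_len, anti)
    truth.planted_cis.append(
        PlantedCis(gene.id, nat.id, config, ov / gene_len, ov / nat_len)
    )
    truth.coding_labels[nat.id] = "noncoding"
    return gene, nat


def _plant_motifs(b: _Builder, truth: SyntheticTruth) -> None:
    # 1:n — one gene with antisense partners at both ends
    scaffold, slot = b.place(2700)
    gs = slot + 500
    gene = b.add_gene(scaffold, gs, 1200, "+")
    nat_a = b.add_nat(scaffold, gs - 250, 400, "-")        # divergent, ov 150
    nat_b = b.add_nat(scaffold, gs + 1050, 400, "-")       # convergent, ov 150
    truth.planted_cis.append(
        PlantedCis(gene.id, nat_a.id, "divergent", 150 / 1200, 150 / 400, "1:n"))
    truth.planted_cis.append(
        PlantedCis(gene.id, nat_b.id, "convergent", 150 / 1200, 150 / 400, "1:n"))
    for nat in (nat_a, nat_b):
        truth.coding_labels[nat.id] = "noncoding"

    # n:1 — one antisense transcript bridging two genes
    scaffold, slot = b.place(2600)
    s = slot + 300
    g1 = b.add_gene(scaffold, s, 800, "+")
    g2 = b.add_gene(scaffold, s + 1100, 800, "+")
    nat = b.add_nat(scaffold, s + 700, 550, "-")           # ov 100 with g1, 150 with g2
    truth.planted_cis.append(
        PlantedCis(g1.id, nat.id, "convergent", 100 / 800, 100 / 550, "n:1"))
    truth.planted_cis.append(
        PlantedCis(g2.id, nat.id, "divergent", 150 / 800, 150 / 550, "n:1"))
    truth.coding_labels[nat.id] = "noncoding"

    # n:n — a chain of three genes and two bridging antisense transcripts
    scaffold, slot = b.place(4200)
    s = slot + 300
    g1 = b.add_gene(scaffold, s, 800, "+")
    g2 = b.add_gene(scaffold, s + 1300, 800, "+")
    g3 = b.add_gene(scaffold, s + 2600, 800, "+")
    n1 = b.add_nat(scaffold, s + 700, 700, "-")            # g1 right (100), g2 left (100)
    n2 = b.add_nat(scaffold, s + 2000, 700, "-")           # g2 right (100), g3 left (100)
    truth.planted_cis.append(
        PlantedCis(g1.id, n1.id, "convergent", 100 / 800, 100 / 700, "n:1"))
    truth.planted_cis.append(
        PlantedCis(g2.id, n1.id, "divergent", 100 / 800, 100 / 700, "n:n"))
    truth.planted_cis.append(
        PlantedCis(g2.id, n2.id, "convergent", 100 / 800, 100 / 700, "n:n"))
    truth.planted_cis.append(
        PlantedCis(g3.id, n2.id, "divergent", 100 / 800, 100 / 700, "n:1"))
    for nat in (n1, n2):
        truth.coding_labels[nat.id] = "noncoding"


def _plant_cis_decoys(
    b: _Builder, truth: SyntheticTruth, evidence: dict[str, dict[str, float]]
) -> None:
    # sub-threshold overlap: 5% of both partners, must fail admission
    scaffold, slot = b.place(2800)
    gs = slot + 300
    gene = b.add_gene(scaffold, gs, 1000, "+")
    nat = b.add_nat(scaffold, gs + 950, 1000, "-")         # ov 50 = 5% of each
    truth.cis_decoys.append(PlantedCisDecoy(gene.id, nat.id, "subthreshold"))
    truth.coding_labels[nat.id] = "noncoding"

    # short transcript: admitted (fully contained) but below the 200-nt rule
    scaffold, slot = b.place(1800)
    gs = slot + 300
    gene = b.add_gene(scaffold, gs, 900, "+")
    nat = b.add_nat(scaffold, gs + 300, 150, "-")
    truth.cis_decoys.append(PlantedCisDecoy(gene.id, nat.id, "length"))
    truth.coding_labels[nat.id] = "noncoding"

    # ORF-bearing transcript: 150-aa ORF on its own strand
    scaffold, slot = b.place(2200)
    gs = slot + 300
    gene = b.add_gene(scaffold, gs, 1100, "+")
    nat = b.add_nat(scaffold, gs + 200, 520, "-")
    orf = "ATG" + b.random_bases(450, exclude_stops_in_frame=True) + "TAA"
    nat_seq = b.random_bases(30) + orf + b.random_bases(520 - 30 - len(orf))
    b.write_transcript_seq(nat, nat_seq)
    truth.cis_decoys.append(PlantedCisDecoy(gene.id, nat.id, "orf"))
    truth.coding_labels[nat.id] = "coding"

    # evidence-flagged transcripts: each fails exactly one database step
    flagged = [
        ("nr", "nr", 1e-5),
        ("cpc", "cpc", 1.8),
        ("housekeeping", "housekeeping", 1e-12),
        ("smallrna", "smallrna", 1e-15),
    ]
    for reason, table, value in flagged:
        scaffold, slot = b.place(2300)
        gs = slot + 300
        gene = b.add_gene(scaffold, gs, 1000, "+")
        nat = b.add_nat(scaffold, gs + 800, 420, "-")      # convergent, ov 200
        evidence[table][nat.id] = value
        truth.cis_decoys.append(PlantedCisDecoy(gene.id, nat.id, reason))
        truth.coding_labels[nat.id] = "coding" if reason in ("nr", "cpc") else "noncoding"


def _embed_complement(
    b: _Builder,
    gene: TranscriptModel,
    nat: TranscriptModel,
    gene_off: int,
    seg_len: int,
    nat_off: int,
    insertion: tuple[int, int] | None = None,
) -> None:
    """Write rc(gene[gene_off:gene_off+seg_len]) into the transcript at
    ``nat_off`` and fence both outer ends with forced mismatches so the
    clean run length cannot creep outward by chance.

    ``insertion`` = (gene-segment offset k, length): extra random bases
    inserted into the transcript between the complements of segment
    positions k-1 and k, forming an interior bubble of that length when the
    duplex anneals.
    """
    gseq = b.spliced(gene)
    segment = gseq[gene_off : gene_off + seg_len]
    block = reverse_complement(segment)
    if insertion is not None:
        k, ins_len = insertion
        pos = seg_len - k  # rc reverses the segment, so gene offset k maps here
        block = block[:pos] + b.random_bases(ins_len) + block[pos:]
    nat_seq = b.spliced(nat)
    chars = list(nat_seq[:nat_off] + block + nat_seq[nat_off + len(block) :])
    # fences: two forced mismatch columns beyond each end of the block
    for t in (0, 1):
        gpos = gene_off + seg_len + t          # beyond the segment's right end
        npos = nat_off - 1 - t
        if 0 <= gpos < len(gseq) and 0 <= npos < len(chars):
            chars[npos] = b.mismatching_base(_COMPLEMENT[gseq[gpos]])
        gpos = gene_off - 1 - t                # beyond the left end
        npos = nat_off + len(block) + t
        if 0 <= gpos < len(gseq) and 0 <= npos < len(chars):
            chars[npos] = b.mismatching_base(_COMPLEMENT[gseq[gpos]])
    b.write_transcript_seq(nat, "".join(chars))


def _plant_trans(b: _Builder, truth: SyntheticTruth) -> None:
    designs = [
        # (gene_len, seg_len, nat_len, gene_off, nat_off, insertion, expect, reason)
        (400, 200, 300, 100, 50, None, True, ""),
        (500, 260, 305, 120, 25, None, True, ""),
        # 12-nt interior bubble: 12/192 ~ 6.2% of the annealed block, passes
        (210, 180, 240, 15, 20, (110, 12), True, ""),
        # near-miss: 90-nt complement, below the ">100 nt" rule
        (400, 90, 300, 150, 100, None, False, "short"),
        # near-miss: 120-nt run is only 20%/12% of the partners
        (1000, 120, 600, 300, 200, None, False, "coverage"),
        # near-miss: 30-nt bubble, 30/210 ~ 14.3% > 10%
        (210, 180, 240, 15, 20, (110, 30), False, "bubble"),
    ]
    for gene_len, seg_len, nat_len, gene_off, nat_off, insertion, expect, reason in designs:
        g_scaffold, g_slot = b.place(gene_len + 200)
        gene = b.add_gene(g_scaffold, g_slot + 100, gene_len, "+")
        n_scaffold, n_slot = b.place(nat_len + 200, avoid=g_scaffold)
        strand = "+" if b.rng.random() < 0.5 else "-"
        nat = b.add_nat(n_scaffold, n_slot + 100, nat_len, strand)
        _embed_complement(b, gene, nat, gene_off, seg_len, nat_off, insertion)
        if insertion:
            k, ins_len = insertion
            clean_run = max(k, seg_len - k)
            bubble = ins_len
        else:
            clean_run, bubble = seg_len, 0
        truth.planted_trans.append(
            PlantedTrans(
                gene.id, nat.id, clean_run, clean_run / nat_len, bubble, expect, reason
            )
        )
        truth.coding_labels[nat.id] = "noncoding"


# ---------------------------------------------------------------------------
# expression / annotation
# ---------------------------------------------------------------------------

def _expression_profiles(
    b: _Builder, truth: SyntheticTruth, cfg: SyntheticConfig
) -> dict[str, np.ndarray]:
    rng = b.rng
    lo, hi = cfg.rpkm_present
    alo, ahi = cfg.rpkm_absent

    def present() -> float:
        return float(rng.uniform(lo, hi))

    def absent() -> float:
        return float(rng.uniform(alo, ahi))

    profiles: dict[str, np.ndarray] = {}
    for model in b.genes + b.transcripts:
        profiles[model.id] = np.array([present() for _ in STAGES])

    # stage-specific presence for a few final cis NATs (not used for the
    # correlation plantings below)
    cis_nats = [p.nat_id for p in truth.planted_cis]
    patterns = [("M",), ("M",), ("P",), ("FB",), ("FB",), ("M", "P")]
    specific = cis_nats[: len(patterns)]
    for nat_id, on_stages in zip(specific, patterns):
        profiles[nat_id] = np.array(
            [present() if s in on_stages else absent() for s in STAGES]
        )
        truth.stage_patterns[nat_id] = list(on_stages)
    for model in b.genes + b.transcripts:
        if model.id not in truth.stage_patterns:
            truth.stage_patterns[model.id] = list(STAGES)

    # planted correlation signs on pairs whose NAT stays present in all stages
    up = np.array([2.5, 8.0, 22.0])
    down = up[::-1].copy()
    free_pairs = [p for p in truth.planted_cis if p.nat_id not in specific]
    signs = [+1, +1, +1, +1, -1, -1, -1]
    for pair, sign in zip(free_pairs, signs):
        jitter = lambda: 1.0 + rng.normal(0.0, 0.04, 3)  # noqa: E731
        st_shape = up if sign > 0 else up        # ST always rises
        nat_shape = up if sign > 0 else down
        profiles[pair.st_id] = np.clip(st_shape * rng.uniform(1.0, 3.0) * jitter(), 2.1, None)
        profiles[pair.nat_id] = np.clip(nat_shape * rng.uniform(1.0, 3.0) * jitter(), 2.1, None)
        truth.planted_correlations.append((pair.st_id, pair.nat_id, sign))
    return profiles


def _annotation_map(
    b: _Builder, truth: SyntheticTruth
) -> list[tuple[str, str, str]]:
    rng = b.rng
    gene_ids = [g.id for g in b.genes]
    st_ids = sorted({p.st_id for p in truth.planted_cis})
    rows: list[tuple[str, str, str]] = []

    n_take = min(10, len(st_ids))
    chosen = list(st_ids[:n_take])
    non_st = [g for g in gene_ids if g not in st_ids]
    chosen += [non_st[i] for i in map(int, rng.choice(len(non_st), 2, replace=False))]
    for g in sorted(chosen):
        rows.append((g, ENRICHED_TERM, "planted enriched category"))
    truth.enriched_terms = [ENRICHED_TERM]

    for t in range(1, 7):
        term = f"GO:BG{t:04d}"
        size = int(rng.integers(8, 15))
        size = min(size, len(gene_ids))
        members = [gene_ids[i] for i in map(int, rng.choice(len(gene_ids), size, replace=False))]
        for g in sorted(members):
            rows.append((g, term, f"background category {t}"))
    return rows


# ---------------------------------------------------------------------------
# entry point
# ---------------------------------------------------------------------------

def generate_fixture(
    outdir: str | Path,
    seed: int = 0,
    config: SyntheticConfig | None = None,
    preset: str | None = None,
) -> FixtureBundle:
    """Generate a complete fixture bundle under ``outdir``.

    ``preset='smoke'`` shrinks the planted counts for quick runs;
    ``preset='full'`` (default) uses the standard study conditions. The
    same (config, seed) always yields byte-identical files.
    """
    if preset == "smoke":
        config = config or SyntheticConfig(
            n_per_config=1, n_background_genes=4, n_scaffolds=4
        )
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    b = _Builder(cfg, rng)
    truth = SyntheticTruth()
    evidence: dict[str, dict[str, float]] = {
        "nr": {}, "cpc": {}, "housekeeping": {}, "smallrna": {}
    }

    for cfg_name in ("divergent", "convergent", "S_contains_N", "N_contains_S"):
        for _ in range(cfg.n_per_config):
            _plant_config_pair(b, truth, cfg_name)
    if cfg.include_motifs:
        _plant_motifs(b, truth)
    if cfg.include_decoys:
        _plant_cis_decoys(b, truth, evidence)
    if cfg.include_trans:
        _plant_trans(b, truth)
    for i in range(cfg.n_background_genes):
        length = int(rng.integers(800, 1600))
        scaffold, slot = b.place(length + 200)
        strand = "+" if rng.random() < 0.5 else "-"
        b.add_gene(scaffold, slot + 100, length, strand, n_exons=int(rng.integers(1, 3)))

    # sense transcripts for every third gene (they merge into the gene's unit)
    for gene in b.genes[::3]:
        b.add_sense_copy(gene)

    # benign evidence entries on passing NATs: hits that stay above cutoffs
    passing = [p.nat_id for p in truth.planted_cis]
    if passing:
        evidence["nr"][passing[0]] = 0.5
        evidence["cpc"][passing[0]] = -1.2
        if len(passing) > 1:
            evidence["nr"][passing[1]] = 0.01
            evidence["cpc"][passing[1]] = -0.4
            evidence["housekeeping"][passing[1]] = 1e-6

    # planted non-coding antisense transcripts must clear the ORF rule
    orf_decoys = {d.nat_id for d in truth.cis_decoys if d.reason == "orf"}
    trans_ids = {p.nat_id for p in truth.planted_trans}
    for model in b.transcripts:
        if model.id.startswith("AT") and model.id not in orf_decoys and model.id not in trans_ids:
            _disrupt_long_orfs(b, model)

    profiles = _expression_profiles(b, truth, cfg)
    annotation_rows = _annotation_map(b, truth)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = {name: "".join(chars) for name, chars in b.seqs.items()}
    paths = {
        "genome": outdir / "genome.fasta",
        "genes": outdir / "genes.gff3",
        "transcripts": outdir / "transcripts.gtf",
        "expression": outdir / "expression.tsv",
        "annotation": outdir / "annotation.tsv",
        "evidence_dir": outdir / "evidence",
        "truth": outdir / "truth.json",
    }
    write_fasta(genome, paths["genome"])
    genes_sorted = sorted(b.genes, key=lambda m: (m.scaffold, m.interval.start, m.id))
    tx_sorted = sorted(b.transcripts, key=lambda m: (m.scaffold, m.interval.start, m.id))
    write_gff3_genes(genes_sorted, paths["genes"])
    write_gtf_transcripts(tx_sorted, paths["transcripts"])

    with open(paths["expression"], "w") as fh:
        fh.write("transcript_id\t" + "\t".join(STAGES) + "\n")
        for model in genes_sorted + tx_sorted:
            vals = "\t".join(f"{v:.4f}" for v in profiles[model.id])
            fh.write(f"{model.id}\t{vals}\n")

    paths["evidence_dir"].mkdir(exist_ok=True)
    names = {"nr": "evalue", "cpc": "score", "housekeeping": "evalue", "smallrna": "evalue"}
    for key, table in evidence.items():
        write_evidence_table(
            dict(sorted(table.items())), paths["evidence_dir"] / f"{key}.tsv", names[key]
        )

    with open(paths["annotation"], "w") as fh:
        fh.write("gene_id\tterm_id\tterm_name\n")
        for gene_id, term, name in annotation_rows:
            fh.write(f"{gene_id}\t{term}\t{name}\n")

    with open(paths["truth"], "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")

    return FixtureBundle(
        outdir=outdir,
        genome=genome,
        genes=genes_sorted,
        transcripts=tx_sorted,
        truth=truth,
        paths=paths,
    )


def load_truth(path: str | Path) -> SyntheticTruth:
    with open(path) as fh:
        raw = json.load(fh)
    return SyntheticTruth(
        planted_cis=[PlantedCis(**d) for d in raw["planted_cis"]],
        cis_decoys=[PlantedCisDecoy(**d) for d in raw["cis_decoys"]],
        planted_trans=[PlantedTrans(**d) for d in raw["planted_trans"]],
        coding_labels=raw["coding_labels"],
        planted_correlations=[tuple(t) for t in raw["planted_correlations"]],
        stage_patterns=raw["stage_patterns"],
        enriched_terms=raw["enriched_terms"],
    )
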