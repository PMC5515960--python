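"""End-to-end orchestration: units -> cis/trans candidates -> non-coding
filters -> SAT characterization -> enrichment, with report generation.

Everything downstream of the input files is deterministic: identical inputs
and config produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cis_nat, enrichment, noncoding_filter, sat_expression, trans_nat, unitize
from .genome_io import (
    ExpressionMatrix,
    extract_sequence,
    read_annotation_map,
    read_evidence_dir,
    read_expression,
    read_gff3_genes,
    read_gtf_transcripts,
    load_genome,
    reverse_complement,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with its default."""

    cis_overlap_frac: float = 0.10
    overlap_rule: str = "any"
    trans_min_complement_nt: int = 100
    trans_coverage_frac: float = 0.50
    coverage_rule: str = "any"
    bubble_max_frac: float = 0.10
    min_length_nt: int = 200
    max_orf_aa: int = 100
    nr_evalue_cutoff: float = 1e-3
    cpc_keep_below: float = 0.0
    ncrna_evalue_cutoff: float = 1e-10
    rpkm_cutoff: float = 2.0
    min_mapped_for_report: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cis_overlap_frac", "trans_coverage_frac", "bubble_max_frac"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("trans_min_complement_nt", "min_length_nt", "max_orf_aa",
                     "nr_evalue_cutoff", "ncrna_evalue_cutoff", "rpkm_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class PipelineResult:
    config: PipelineConfig
    units: list[unitize.TranscriptUnit]
    cis_pairs: list[cis_nat.CisPair]              # admitted candidates
    trans_pairs: list[trans_nat.TransPair]
    records: list[noncoding_filter.NatRecord]
    final_cis_pairs: list[cis_nat.CisPair]        # both partners survived filtering
    final_trans_pairs: list[trans_nat.TransPair]
    relationships: list[sat_expression.SatRelationship]
    venn: dict[str, int]
    correlations: pd.DataFrame
    enrichment_results: list[enrichment.EnrichmentResult]
    unit_members: dict[str, list[str]]
    summary: dict

    @property
    def final_cis_nat_ids(self) -> set[str]:
        return {p.nat_id for p in self.final_cis_pairs}

    @property
    def final_trans_nat_ids(self) -> set[str]:
        return {p.nat_id for p in self.final_trans_pairs}


def _unit_span_sequence(unit: unitize.TranscriptUnit, genome) -> str:
    seq = str(genome[unit.scaffold][unit.span.start : unit.span.end]).upper()
    return reverse_complement(seq) if unit.strand == "-" else seq


def _length_histogram(lengths_by_kind: dict[str, list[int]], bin_nt: int = 100) -> pd.DataFrame:
    """Counts in 100-nt bins starting at 201 (201-300, 301-400, ...)."""
    rows = []
    all_lengths = [l for ls in lengths_by_kind.values() for l in ls]
    if all_lengths:
        top = max(max(all_lengths), 201)
        edges_hi = ((top - 201) // bin_nt + 1) * bin_nt + 200
        for lo in range(201, edges_hi, bin_nt):
            hi = lo + bin_nt - 1
            row = {"bin": f"{lo}-{hi}"}
            for kind, lengths in lengths_by_kind.items():
                row[kind] = sum(1 for l in lengths if lo <= l <= hi)
            rows.append(row)
    return pd.DataFrame(rows, columns=["bin"] + sorted(lengths_by_kind))


def run_pipeline(
    config: PipelineConfig,
    genome_path: str | Path,
    genes_gff: str | Path,
    transcripts_gtf: str | Path,
    expression_tsv: str | Path | None = None,
    evidence_dir: str | Path | None = None,
    annotation_tsv: str | Path | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full discovery-and-characterization pipeline.

    Writes the TSV/BED catalogs and a JSON summary under ``outdir`` when
    given; always returns the in-memory result.
    """
    genome = load_genome(genome_path)
    genes = read_gff3_genes(genes_gff)
    transcripts = read_gtf_transcripts(transcripts_gtf)
    logger.info("loaded %d genes, %d transcripts", len(genes), len(transcripts))

    units = unitize.build_transcript_units(genes + transcripts)
    unit_members = {u.id: u.members for u in units}
    logger.info("built %d transcript units", len(units))

    pairs = cis_nat.find_cis_candidates(
        units, genes, min_frac=config.cis_overlap_frac, overlap_rule=config.overlap_rule
    )
    logger.info("admitted %d candidate cis pairs", len(pairs))

    trans_cfg = trans_nat.TransSearchConfig(
        min_complement_nt=config.trans_min_complement_nt,
        coverage_frac=config.trans_coverage_frac,
        coverage_rule=config.coverage_rule,
        bubble_max_frac=config.bubble_max_frac,
    )
    tpairs = trans_nat.find_trans_candidates(genes, transcripts, genome, trans_cfg)
    logger.info("found %d candidate trans pairs", len(tpairs))

    # candidates for the five-step cascade
    unit_by_id = {u.id: u for u in units}
    tx_by_id = {t.id: t for t in transcripts}
    candidates: list[tuple[str, str, str]] = []
    evidence_ids: dict[str, list[str]] = {}
    seen: set[str] = set()
    for p in pairs:
        if p.nat_id in seen:
            continue
        seen.add(p.nat_id)
        unit = unit_by_id[p.nat_id]
        candidates.append((p.nat_id, "cis", _unit_span_sequence(unit, genome)))
        evidence_ids[p.nat_id] = list(unit.members)
    for p in tpairs:
        if p.nat_id in seen:
            continue
        seen.add(p.nat_id)
        tx = tx_by_id[p.nat_id]
        candidates.append((p.nat_id, "trans", extract_sequence(tx, genome)))
        evidence_ids[p.nat_id] = [p.nat_id]

    evidence = read_evidence_dir(evidence_dir)
    filter_cfg = noncoding_filter.FilterConfig(
        min_length_nt=config.min_length_nt,
        max_orf_aa=config.max_orf_aa,
        nr_evalue_cutoff=config.nr_evalue_cutoff,
        cpc_keep_below=config.cpc_keep_below,
        ncrna_evalue_cutoff=config.ncrna_evalue_cutoff,
    )
    records = noncoding_filter.apply_filters(
        candidates, evidence, filter_cfg, evidence_ids=evidence_ids
    )
    final_ids = {r.id for r in records if r.final}
    final_cis_pairs = [p for p in pairs if p.nat_id in final_ids]
    final_trans_pairs = [p for p in tpairs if p.nat_id in final_ids]
    logger.info(
        "%d cis and %d trans NATs pass all filters",
        len({p.nat_id for p in final_cis_pairs}),
        len({p.nat_id for p in final_trans_pairs}),
    )

    relationships = sat_expression.relationship_type(final_cis_pairs)

    venn: dict[str, int] = {}
    correlations = pd.DataFrame(
        columns=["st_id", "nat_id", "r", "N", "t", "p", "note"]
    )
    if expression_tsv is not None:
        expr = read_expression(expression_tsv)
        expr = _with_unit_rows(expr, unit_members, final_ids)
        nat_ids = sorted(
            {p.nat_id for p in final_cis_pairs} | {p.nat_id for p in final_trans_pairs}
        )
        venn = sat_expression.venn_partition(expr, nat_ids, cutoff=config.rpkm_cutoff)
        correlations = sat_expression.correlate_pairs(
            expr, [(p.st_id, p.nat_id) for p in final_cis_pairs]
        )

    enrichment_results: list[enrichment.EnrichmentResult] = []
    if annotation_tsv is not None:
        annotation = read_annotation_map(annotation_tsv)
        st_ids = sorted({p.st_id for p in final_cis_pairs})
        if st_ids:
            enrichment_results = enrichment.enrich(
                st_ids, annotation, total_genes=len(genes),
                min_mapped=config.min_mapped_for_report,
            )

    rec_by_id = {r.id: r for r in records}
    lengths_by_kind = {
        "cis": sorted(
            rec_by_id[i].length_nt for i in {p.nat_id for p in final_cis_pairs}
        ),
        "trans": sorted(
            rec_by_id[i].length_nt for i in {p.nat_id for p in final_trans_pairs}
        ),
    }
    config_hist = {c: 0 for c in cis_nat.CONFIGURATIONS}
    for p in final_cis_pairs:
        config_hist[p.config] += 1
    relation_counts = {rel: 0 for rel in sat_expression.RELATIONS}
    for r in relationships:
        relation_counts[r.relation] += 1

    summary = {
        "n_genes": len(genes),
        "n_transcripts": len(transcripts),
        "n_units": len(units),
        "n_cis_candidate_pairs": len(pairs),
        "n_trans_candidate_pairs": len(tpairs),
        "n_final_cis_nats": len({p.nat_id for p in final_cis_pairs}),
        "n_final_trans_nats": len({p.nat_id for p in final_trans_pairs}),
        "n_final_cis_pairs": len(final_cis_pairs),
        "configuration_counts": config_hist,
        "relationship_counts": relation_counts,
        "venn": venn,
        "n_enriched_terms_reported": len(enrichment_results),
    }

    result = PipelineResult(
        config=config,
        units=units,
        cis_pairs=pairs,
        trans_pairs=tpairs,
        records=records,
        final_cis_pairs=final_cis_pairs,
        final_trans_pairs=final_trans_pairs,
        relationships=relationships,
        venn=venn,
        correlations=correlations,
        enrichment_results=enrichment_results,
        unit_members=unit_members,
        summary=summary,
    )
    if outdir is not None:
        _write_reports(result, lengths_by_kind, Path(outdir))
    return result


def _with_unit_rows(
    expr: ExpressionMatrix, unit_members: dict[str, list[str]], unit_ids: set[str]
) -> ExpressionMatrix:
    """Append per-unit expression rows, aggregating members by maximum.

    A unit is "present" in a stage when any member transcript is, which the
    element-wise max encodes; most antisense units are single-member, where
    this is the identity.
    """
    rows = {}
    for uid in sorted(unit_ids & set(unit_members)):
        members = [m for m in unit_members[uid] if m in expr]
        if members:
            rows[uid] = expr.values.loc[members].max(axis=0)
    if not rows:
        return expr
    extra = pd.DataFrame(rows).T
    extra.columns = expr.values.columns
    return ExpressionMatrix(pd.concat([expr.values, extra]), unit=expr.unit)


def _write_reports(
    result: PipelineResult, lengths_by_kind: dict[str, list[int]], outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    unitize.write_units_bed(result.units, outdir / "units.bed")
    cis_nat.write_cis_catalog(result.cis_pairs, outdir / "cis_candidates.tsv")
    cis_nat.write_cis_catalog(result.final_cis_pairs, outdir / "cis_catalog.tsv")
    cis_nat.write_cis_bed12(result.final_cis_pairs, outdir / "cis_nats.bed12")
    trans_nat.write_trans_catalog(result.final_trans_pairs, outdir / "trans_catalog.tsv")
    noncoding_filter.write_trail_report(result.records, outdir / "filter_trails.tsv")
    noncoding_filter.filter_funnel_counts(result.records).to_csv(
        outdir / "filter_funnel.tsv", sep="\t", index=False
    )
    _length_histogram(lengths_by_kind).to_csv(
        outdir / "length_histogram.tsv", sep="\t", index=False
    )
    with open(outdir / "relationships.tsv", "w") as fh:
        fh.write("st_id\tnat_id\trelation\n")
        for r in result.relationships:
            fh.write(f"{r.st_id}\t{r.nat_id}\t{r.relation}\n")
    with open(outdir / "venn.tsv", "w") as fh:
        fh.write("region\tcount\n")
        for region, count in result.venn.items():
            fh.write(f"{region}\t{count}\n")
    result.correlations.to_csv(
        outdir / "correlations.tsv", sep="\t", index=False, float_format="%.6g"
    )
    enrichment.write_enrichment_table(
        result.enrichment_results, outdir / "enrichment.tsv"
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(outdir / "run_config.json", "w") as fh:
        fh.write(result.config.to_json() + "\n")
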