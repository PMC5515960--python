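"""The five-step non-coding filter cascade.

Candidate antisense transcripts become NATs only after passing, in order:

1. length: spliced length strictly greater than 200 nt;
2. ORF: longest ATG-initiated, stop-terminated open reading frame on the
   transcript's own strand at most 100 amino acids;
3. no protein-database (nr) hit at e-value <= 1e-3;
4. coding-potential (CPC) score strictly below 0;
5. no housekeeping-ncRNA or small-RNA hit at e-value <= 1e-10.

Evaluation stops at the first failure, so each record carries a trail of
exactly the steps that were evaluated. Steps 3-5 consume evidence tables
standing in for external searches; a missing table is a vacuous pass with a
warning (or a hard error in strict mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .genome_io import EvidenceTables

logger = logging.getLogger(__name__)

FILTER_STEPS = ("length", "orf", "nr", "cpc", "ncrna")


@dataclass
class FilterConfig:
    min_length_nt: int = 200          # keep iff length > this
    max_orf_aa: int = 100             # keep iff longest ORF <= this
    nr_evalue_cutoff: float = 1e-3    # hit at e <= cutoff disqualifies
    cpc_keep_below: float = 0.0       # keep iff score < this
    ncrna_evalue_cutoff: float = 1e-10
    strict: bool = False              # missing evidence table -> hard error

    def __post_init__(self) -> None:
        for name in ("min_length_nt", "max_orf_aa", "nr_evalue_cutoff", "ncrna_evalue_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class NatRecord:
    """A candidate antisense transcript with its filter trail."""

    id: str
    kind: str                         # 'cis' or 'trans'
    length_nt: int
    max_orf_aa: int | None            # None when the cascade stopped before the ORF scan
    filter_trail: list[tuple[str, bool, str]]
    final: bool


def max_orf_length(seq: str) -> int:
    """Longest ATG-initiated, stop-terminated ORF, in amino acids.

    Scans the three forward reading frames of the given strand (the
    sequence is taken 5'->3'); the stop codon is excluded from the count.
    Returns 0 when no complete ORF exists. Codons containing N translate to
    X: they count as residues and are never treated as stops.
    """
    seq = seq.upper()
    best = 0
    for frame in range(3):
        sub = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
        if len(sub) < 3:
            continue
        protein = str(Seq(sub).translate())
        # every '*'-terminated chunk: longest ORF starts at its first M
        chunks = protein.split("*")
        for chunk in chunks[:-1]:
            m = chunk.find("M")
            if m >= 0:
                best = max(best, len(chunk) - m)
    return best


def _no_hit(
    table: dict[str, float] | None,
    ids: Sequence[str],
    cutoff: float,
    name: str,
    strict: bool,
) -> tuple[bool, str]:
    """True when none of ``ids`` has a recorded e-value <= cutoff."""
    if table is None:
        if strict:
            raise ValueError(f"evidence table {name!r} missing in strict mode")
        logger.warning("evidence table %r missing; step passes vacuously", name)
        return True, f"no {name} table"
    hits = [table[i] for i in ids if i in table]
    if not hits:
        return True, "no hit"
    e = min(hits)
    if e <= cutoff:
        return False, f"hit with e={e:g} <= {cutoff:g}"
    return True, f"best hit e={e:g} > {cutoff:g}"


def apply_filters(
    candidates: Sequence[tuple[str, str, str]],
    evidence: EvidenceTables,
    config: FilterConfig | None = None,
    evidence_ids: dict[str, Sequence[str]] | None = None,
) -> list[NatRecord]:
    """Run the cascade over ``(id, kind, sequence)`` candidates.

    ``evidence_ids`` optionally maps a candidate id to the transcript ids
    under which external searches were recorded (e.g. the member transcripts
    of an antisense unit); the worst evidence over those ids is used. A pure
    function of its inputs: identical inputs give identical trails.
    """
    cfg = config or FilterConfig()
    records: list[NatRecord] = []
    for cid, kind, seq in candidates:
        ids = list(evidence_ids.get(cid, [cid])) if evidence_ids else [cid]
        if cid not in ids:
            ids.append(cid)
        trail: list[tuple[str, bool, str]] = []
        orf_aa: int | None = None
        length = len(seq)

        passed = length > cfg.min_length_nt
        trail.append(("length", passed, f"{length} nt"))
        if passed:
            orf_aa = max_orf_length(seq)
            passed = orf_aa <= cfg.max_orf_aa
            trail.append(("orf", passed, f"{orf_aa} aa"))
        if passed:
            passed, why = _no_hit(
                evidence.nr_best_evalue, ids, cfg.nr_evalue_cutoff, "nr", cfg.strict
            )
            trail.append(("nr", passed, why))
        if passed:
            if evidence.cpc_score is None:
                if cfg.strict:
                    raise ValueError("evidence table 'cpc' missing in strict mode")
                logger.warning("CPC table missing; step passes vacuously")
                passed, why = True, "no cpc table"
            else:
                scores = [evidence.cpc_score[i] for i in ids if i in evidence.cpc_score]
                if not scores:
                    logger.warning("no CPC score for %s; step passes with warning", cid)
                    passed, why = True, "score absent"
                else:
                    score = max(scores)
                    passed = score < cfg.cpc_keep_below
                    why = f"score={score:g}"
            trail.append(("cpc", passed, why))
        if passed:
            ok_hk, why_hk = _no_hit(
                evidence.housekeeping_best_evalue, ids, cfg.ncrna_evalue_cutoff,
                "housekeeping", cfg.strict,
            )
            ok_sm, why_sm = _no_hit(
                evidence.smallrna_best_evalue, ids, cfg.ncrna_evalue_cutoff,
                "smallrna", cfg.strict,
            )
            passed = ok_hk and ok_sm
            trail.append(("ncrna", passed, f"housekeeping: {why_hk}; smallrna: {why_sm}"))

        records.append(
            NatRecord(
                id=cid,
                kind=kind,
                length_nt=length,
                max_orf_aa=orf_aa,
                filter_trail=trail,
                final=passed and len(trail) == len(FILTER_STEPS),
            )
        )
    return records


def filter_funnel_counts(records: Sequence[NatRecord]) -> pd.DataFrame:
    """Cumulative retained/discarded counts per step, per kind and combined.

    Mirrors the per-step parenthetical counts of a filtering flow chart:
    ``retained`` after step k is the number of candidates that survived
    steps 1..k.
    """
    kinds = sorted({r.kind for r in records}) + ["all"]
    rows = []
    for kind in kinds:
        subset = [r for r in records if kind == "all" or r.kind == kind]
        surviving = len(subset)
        for step_idx, step in enumerate(FILTER_STEPS):
            failed_here = sum(
                1
                for r in subset
                if len(r.filter_trail) == step_idx + 1 and not r.filter_trail[-1][1]
            )
            surviving -= failed_here
            rows.append(
                {"kind": kind, "step": step, "retained": surviving, "discarded": failed_here}
            )
    return pd.DataFrame(rows, columns=["kind", "step", "retained", "discarded"])


def write_trail_report(records: Iterable[NatRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        header = "\t".join(["id", "kind", "length_nt", "max_orf_aa"]
                           + [f"pass_{s}" for s in FILTER_STEPS] + ["final"])
        fh.write(header + "\n")
        for r in records:
            flags = {step: "" for step in FILTER_STEPS}
            for step, ok, _ in r.filter_trail:
                flags[step] = str(ok)
            orf = "" if r.max_orf_aa is None else str(r.max_orf_aa)
            fh.write(
                "\t".join(
                    [r.id, r.kind, str(r.length_nt), orf]
                    + [flags[s] for s in FILTER_STEPS]
                    + [str(r.final)]
                )
                + "\n"
            )
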