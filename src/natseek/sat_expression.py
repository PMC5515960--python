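"""SAT-pair relationships, stage presence, and sense/antisense expression
correlation.

Covers the downstream characterization of sense/antisense (SAT) pairs:
mapping multiplicity (1:1, 1:n, n:1, n:n), RPKM computation, presence calls
and three-stage Venn partitioning at an RPKM cutoff of 2, profile
normalization for plotting, and Pearson correlation between sense and
antisense expression profiles with its significance from

    t = r / sqrt((1 - r^2) / (N - 2))

looked up one-sided (directional) on Student's t with N-2 degrees of
freedom.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cis_nat import CisPair
from .genome_io import ExpressionMatrix

RELATIONS = ("1:1", "1:n", "n:1", "n:n")


@dataclass
class SatRelationship:
    st_id: str
    nat_id: str
    relation: str


@dataclass
class StagePresence:
    transcript_id: str
    present: dict[str, bool]
    region: str | None  # exclusive Venn region label, None if absent everywhere


@dataclass
class CorrelationResult:
    st_id: str
    nat_id: str
    r: float
    N: int
    t: float
    p: float


def rpkm(read_count: float, transcript_len_nt: int, library_size: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if transcript_len_nt <= 0:
        raise ValueError("transcript length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return 1e9 * read_count / (library_size * transcript_len_nt)


def relationship_type(cis_pairs: Sequence[CisPair]) -> list[SatRelationship]:
    """Label each pair by the degrees of its endpoints in the ST-NAT graph.

    n:n iff the sense transcript maps to >= 2 antisense partners AND the
    antisense partner maps to >= 2 sense transcripts; 1:n when only the
    sense side is multiple; n:1 when only the antisense side; else 1:1.
    """
    st_degree: dict[str, int] = {}
    nat_degree: dict[str, int] = {}
    for p in cis_pairs:
        st_degree[p.st_id] = st_degree.get(p.st_id, 0) + 1
        nat_degree[p.nat_id] = nat_degree.get(p.nat_id, 0) + 1
    out = []
    for p in cis_pairs:
        st_multi = st_degree[p.st_id] >= 2
        nat_multi = nat_degree[p.nat_id] >= 2
        if st_multi and nat_multi:
            relation = "n:n"
        elif st_multi:
            relation = "1:n"
        elif nat_multi:
            relation = "n:1"
        else:
            relation = "1:1"
        out.append(SatRelationship(p.st_id, p.nat_id, relation))
    return out


def _venn_regions(stages: Sequence[str]) -> list[tuple[str, frozenset[str]]]:
    regions = []
    for k in (1, 2, 3):
        for combo in itertools.combinations(stages, k):
            regions.append(("&".join(combo), frozenset(combo)))
    return regions


def stage_presence(
    expr: ExpressionMatrix, transcript_id: str, cutoff: float = 2.0
) -> StagePresence:
    """Presence calls (abundance >= cutoff, inclusive) for one transcript."""
    profile = expr.profile(transcript_id)
    present = {stage: bool(profile[stage] >= cutoff) for stage in expr.stages}
    on = frozenset(s for s, ok in present.items() if ok)
    region = "&".join(s for s in expr.stages if s in on) if on else None
    return StagePresence(transcript_id, present, region)


def venn_partition(
    expr: ExpressionMatrix, ids: Iterable[str], cutoff: float = 2.0
) -> dict[str, int]:
    """Exclusive-region counts over exactly three stages.

    Returns the 7 region counts plus ``total`` (present in >= 1 stage).
    Transcripts below the cutoff in every stage are excluded from the
    total. The cutoff is inclusive: abundance == cutoff counts as present.
    """
    stages = expr.stages
    if len(stages) != 3:
        raise ValueError(f"venn_partition requires exactly 3 stages, got {len(stages)}")
    counts = {name: 0 for name, _ in _venn_regions(stages)}
    total = 0
    for tid in ids:
        sp = stage_presence(expr, tid, cutoff)
        if sp.region is not None:
            counts[sp.region] += 1
            total += 1
    counts["total"] = total
    return counts


def normalize_profile(
    values: Sequence[float], mode: str = "mean", log: bool = True
) -> np.ndarray:
    """Relative per-stage expression levels.

    With ``log`` the values are first transformed as log2(x + 1); the
    profile is then divided by its mean (``mode='mean'``) or its maximum
    (``mode='max'``). An all-zero profile has no scale and is an error.
    """
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    if not (x > 0).any():
        raise ValueError("all-zero profile cannot be normalized")
    if mode not in ("mean", "max"):
        raise ValueError(f"mode must be 'mean' or 'max', got {mode!r}")
    if log:
        x = np.log2(x + 1.0)
    denom = x.mean() if mode == "mean" else x.max()
    return x / denom


def pearson_with_significance(
    x: Sequence[float], y: Sequence[float], two_tailed: bool = False
) -> CorrelationResult:
    """Pearson r between two profiles with its t-based significance.

    t = r / sqrt((1 - r^2)/(N - 2)); the p-value is the directional
    (one-tailed, in the direction of the observed r) Student-t tail with
    N - 2 degrees of freedom, or twice that with ``two_tailed``. Perfect
    correlation reports t = +/-inf and p = 0. Zero variance in either
    profile leaves r undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("profiles must have equal length")
    if n < 3:
        raise ValueError("need at least 3 points for a significance test")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance profile: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) >= 1.0 - 1e-12:
        t = math.copysign(math.inf, r)
        p = 0.0
    else:
        t = r / math.sqrt((1.0 - r * r) / df)
        p = float(stats.t.sf(abs(t), df))
    if two_tailed:
        p = min(1.0, 2.0 * p)
    return CorrelationResult(st_id="", nat_id="", r=r, N=n, t=t, p=p)


def correlate_pairs(
    expr: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    two_tailed: bool = False,
) -> pd.DataFrame:
    """Correlation table for (st_id, nat_id) pairs found in the matrix.

    Pairs with a zero-variance profile are reported with NaN statistics
    rather than dropped, so the caller can see them flagged.
    """
    rows = []
    for st_id, nat_id in pairs:
        if st_id not in expr or nat_id not in expr:
            continue
        x = expr.profile(st_id).to_numpy()
        y = expr.profile(nat_id).to_numpy()
        try:
            res = pearson_with_significance(x, y, two_tailed=two_tailed)
            rows.append(
                {"st_id": st_id, "nat_id": nat_id, "r": res.r, "N": res.N,
                 "t": res.t, "p": res.p, "note": ""}
            )
        except ValueError as err:
            rows.append(
                {"st_id": st_id, "nat_id": nat_id, "r": np.nan, "N": len(x),
                 "t": np.nan, "p": np.nan, "note": str(err)}
            )
    return pd.DataFrame(rows, columns=["st_id", "nat_id", "r", "N", "t", "p", "note"])
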