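"""Per-site, per-strain A-to-I editing-level quantification and filtering.

The editing level at a site is the fraction of reads carrying G at an A
position on the sense strand (inosine reads as guanosine).  This module turns
replicate read-count tables into a filtered sites x strains editing matrix,
summarizes inter-strain variability, and applies the read-level filter
cascade used to call editing sites from nascent-RNA pileups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

MIN_COVERAGE = 50  # reads required to report an editing level
MAX_REPLICATE_DIFF = 0.20  # replicate levels differing by more than this are dropped
MIN_STRAINS = 35  # strains with a measurement required to keep a site


@dataclass(frozen=True)
class EditingSite:
    """Identity of an editing site (1-based position of the edited A)."""

    chrom: str
    pos: int
    strand: str
    gene_id: str
    site_id: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("site position must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError("site strand must be '+' or '-'")


@dataclass
class EditingMatrix:
    """Editing levels (fractions in [0, 1], NaN = missing) for sites x strains."""

    sites: List[EditingSite]
    strains: List[str]
    level: np.ndarray  # shape (n_sites, n_strains), float with NaN

    def __post_init__(self) -> None:
        self.level = np.asarray(self.level, dtype=float)
        if self.level.shape != (len(self.sites), len(self.strains)):
            raise ValueError("level matrix shape does not match sites x strains")
        with np.errstate(invalid="ignore"):
            bad = (self.level < 0) | (self.level > 1)
        if np.any(bad):
            raise ValueError("editing levels must lie in [0, 1] or be missing")

    @property
    def n_measured(self) -> np.ndarray:
        return np.sum(~np.isnan(self.level), axis=1)

    @property
    def site_ids(self) -> List[str]:
        return [s.site_id for s in self.sites]

    def site_index(self, site_id: str) -> int:
        return self.site_ids.index(site_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.level, index=self.site_ids, columns=self.strains)


class ReadObservation(NamedTuple):
    base: str  # observed base on the sense strand
    base_quality: int
    mapping_quality: int
    position_in_read: int  # 1-based


@dataclass
class PileupRecord:
    """Per-site pileup with read-level observations and context annotations."""

    chrom: str
    pos: int
    strand: Optional[str]
    reads: List[ReadObservation]
    homopolymer: bool = False
    simple_repeat: bool = False
    splice_junction_distance: int = 10_000
    bidirectional: bool = False


def compute_editing_level(
    g_count: int, total: int, min_coverage: int = MIN_COVERAGE
) -> float:
    """Editing level = G reads / total reads; missing (NaN) below coverage.

    Raises on inconsistent counts (more G reads than reads).
    """
    if g_count < 0 or total < 0 or g_count > total:
        raise ValueError(f"invalid counts g={g_count} total={total}")
    if total < min_coverage:
        return math.nan
    return g_count / total


def filter_replicates(
    rep1: float,
    rep2: float,
    coverage1: float = 1.0,
    coverage2: float = 1.0,
    max_diff: float = MAX_REPLICATE_DIFF,
) -> float:
    """Combine two replicate editing levels, or drop them when discordant.

    Returns the coverage-weighted mean when both are present and they differ
    by at most ``max_diff`` (strictly greater differences are excluded);
    missing (NaN) otherwise.  Symmetric in its arguments.
    """
    if math.isnan(rep1) or math.isnan(rep2):
        return math.nan
    if abs(rep1 - rep2) > max_diff:
        return math.nan
    w = coverage1 + coverage2
    if w <= 0:
        return math.nan
    return (rep1 * coverage1 + rep2 * coverage2) / w


def build_editing_matrix(
    counts: pd.DataFrame,
    sites: Optional[Sequence[EditingSite]] = None,
    min_strains: int = MIN_STRAINS,
    min_coverage: int = MIN_COVERAGE,
    max_replicate_diff: float = MAX_REPLICATE_DIFF,
) -> EditingMatrix:
    """Build the filtered editing matrix from a replicate counts table.

    ``counts`` columns: site_id, strain, replicate, g_count, total_count.
    Per strain and site, replicate levels are computed with the coverage
    rule, discordant replicates (difference > ``max_replicate_diff``) are
    dropped, concordant ones are combined by coverage-weighted mean, and
    sites measured in fewer than ``min_strains`` strains are removed.
    """
    required = {"site_id", "strain", "replicate", "g_count", "total_count"}
    missing_cols = required - set(counts.columns)
    if missing_cols:
        raise ValueError(f"counts table missing columns: {sorted(missing_cols)}")
    if counts.duplicated(["site_id", "strain", "replicate"]).any():
        raise ValueError("duplicate (site, strain, replicate) keys in counts table")

    site_map: Dict[str, EditingSite] = {}
    if sites is not None:
        site_map = {s.site_id: s for s in sites}

    if counts.empty:
        return EditingMatrix([], [], np.empty((0, 0)))

    site_ids = list(pd.unique(counts["site_id"]))
    strains = list(pd.unique(counts["strain"]))
    s_idx = {s: i for i, s in enumerate(site_ids)}
    t_idx = {s: i for i, s in enumerate(strains)}

    level = np.full((len(site_ids), len(strains)), np.nan)
    for (site_id, strain), grp in counts.groupby(["site_id", "strain"], sort=False):
        levels = []
        covs = []
        for _, row in grp.iterrows():
            levels.append(
                compute_editing_level(
                    int(row["g_count"]), int(row["total_count"]), min_coverage
                )
            )
            covs.append(float(row["total_count"]))
        if any(math.isnan(v) for v in levels):
            continue
        if max(levels) - min(levels) > max_replicate_diff:
            continue
        w = sum(covs)
        level[s_idx[site_id], t_idx[strain]] = (
            sum(v * c for v, c in zip(levels, covs)) / w if w > 0 else math.nan
        )

    keep = np.sum(~np.isnan(level), axis=1) >= min_strains
    kept_ids = [sid for sid, k in zip(site_ids, keep) if k]
    site_objs = [
        site_map.get(sid, EditingSite("unknown", 1, "+", "unknown", sid))
        for sid in kept_ids
    ]
    return EditingMatrix(site_objs, strains, level[keep])


def pairwise_strain_difference(
    matrix: EditingMatrix, threshold: float = 0.10
) -> pd.DataFrame:
    """Fraction of co-measured sites differing by >= ``threshold`` per strain pair.

    Symmetric; NaN for pairs with no co-measured site.  The diagonal is 0
    where a strain has any measurement.
    """
    L = matrix.level
    n = len(matrix.strains)
    out = np.full((n, n), np.nan)
    for a in range(n):
        for b in range(a, n):
            both = ~np.isnan(L[:, a]) & ~np.isnan(L[:, b])
            if not both.any():
                continue
            frac = np.mean(np.abs(L[both, a] - L[both, b]) >= threshold)
            out[a, b] = out[b, a] = frac
    return pd.DataFrame(out, index=matrix.strains, columns=matrix.strains)


def site_variability(matrix: EditingMatrix) -> pd.DataFrame:
    """Per-site variability: sample variance and a binomial-scaled variant.

    The binomial-scaled score divides the sample variance by ``p*(1-p)``
    where ``p`` is the site's mean level (missing when ``p`` is 0 or 1).
    Both are reported because the ranking metric is ambiguous in the source
    material for this analysis style; either column can be used for ranking.
    """
    rows = []
    for i, site in enumerate(matrix.sites):
        vals = matrix.level[i][~np.isnan(matrix.level[i])]
        if len(vals) < 2:
            rows.append((site.site_id, math.nan, math.nan, len(vals)))
            continue
        var = float(np.var(vals, ddof=1))
        p = float(np.mean(vals))
        scaled = var / (p * (1 - p)) if 0 < p < 1 else math.nan
        rows.append((site.site_id, var, scaled, len(vals)))
    return pd.DataFrame(
        rows, columns=["site_id", "sample_variance", "binomial_scaled", "n_measured"]
    ).set_index("site_id")


# Reason codes for pileup-based site discovery.
REASON_NO_STRAND = "no strand"
REASON_MIN_READS = "min reads"
REASON_MIN_FREQ = "min frequency"
REASON_HOMOPOLYMER = "homopolymer"
REASON_SIMPLE_REPEAT = "simple repeat"
REASON_SPLICE = "splice junction"
REASON_BIDIRECTIONAL = "bidirectional transcription"
REASON_ADAR_NULL = "present in ADAR-null"


def discover_sites_from_pileup(
    site: PileupRecord,
    adar_null: Optional[PileupRecord] = None,
    min_reads: int = 2,
    min_frequency: float = 0.03,
    min_quality: int = 20,
    max_read_start: int = 6,
    splice_distance: int = 4,
) -> Tuple[bool, List[str]]:
    """Accept or reject a candidate A-to-G editing site from a pileup.

    A read observation counts only if both base and mapping quality are at
    least ``min_quality``; a supporting (G) observation additionally must not
    lie within the first ``max_read_start`` bases of its read.  Acceptance
    requires >= ``min_reads`` supporting reads, variant frequency >=
    ``min_frequency``, no homopolymer / simple-repeat / splice-proximal /
    bidirectional-transcription context, and zero altered reads in the
    ADAR-null pileup when one is supplied.  Returns (accepted, reasons).
    """
    reasons: List[str] = []
    if site.strand not in ("+", "-"):
        return False, [REASON_NO_STRAND]

    usable = [
        r
        for r in site.reads
        if r.base_quality >= min_quality and r.mapping_quality >= min_quality
    ]
    supporting = [
        r for r in usable if r.base == "G" and r.position_in_read > max_read_start
    ]
    if len(supporting) < min_reads:
        reasons.append(REASON_MIN_READS)
    total = len(usable)
    freq = len(supporting) / total if total else 0.0
    if freq < min_frequency:
        reasons.append(REASON_MIN_FREQ)
    if site.homopolymer:
        reasons.append(REASON_HOMOPOLYMER)
    if site.simple_repeat:
        reasons.append(REASON_SIMPLE_REPEAT)
    if site.splice_junction_distance <= splice_distance:
        reasons.append(REASON_SPLICE)
    if site.bidirectional:
        reasons.append(REASON_BIDIRECTIONAL)
    if adar_null is not None and any(r.base == "G" for r in adar_null.reads):
        reasons.append(REASON_ADAR_NULL)
    return (not reasons), reasons
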