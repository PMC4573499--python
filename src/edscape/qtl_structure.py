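"""Structural interpretation of edQTLs relative to the edited dsRNA duplex.

Variants associated with editing changes are classified as lying within the
edited duplex (in the ECS or the edit-side strand) or distal to it.  For
within-duplex variants the two alleles' duplex constructs are folded and
compared: base-pairing status of the variant on the higher-editing allele's
structure, allelic free-energy difference (delta-G = G(high) - G(low); a
negative value means the higher-editing allele is more stable), and signed
position along the stem relative to the editing site.  Control variants are
selected with linkage-disequilibrium filtering (r^2 <= 0.05 against every
edQTL).  For distal edQTLs, secondary dsRNA stems near the variant are
discovered by folding its neighbourhood.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .edqtl_mapping import EdQTL, GenotypeMatrix, effect_size
from .ecs_prediction import EcsPrediction, MAX_BULGE, MIN_STEM_PAIRS, PROXIMAL_WINDOW
from .structure_engine import (
    RnaStructure,
    Stem,
    enumerate_stems,
    fold_mfe,
    fold_duplex,
)
from .synthetic_data import revcomp

LD_R2_MAX = 0.05  # inclusive: r^2 <= 0.05 passes the linkage filter
EFFECT_SIZE_GATE = 0.025

WITHIN_DUPLEX = "within_duplex"
DISTAL = "distal"
UNRESOLVED = "unresolved"


@dataclass
class StructuralComparison:
    variant_id: str
    site_id: str
    location_class: str
    is_base_paired: Optional[bool]
    delta_g: float  # G(higher-editing allele) - G(lower-editing allele)
    signed_position: Optional[int]
    allele_high: str
    allele_low: str
    effect_size: float
    passes_effect_gate: bool


@dataclass
class SecondaryStem:
    variant_id: str
    stem: Stem
    left_interval: Tuple[int, int]  # genomic, 0-based half-open
    right_interval: Tuple[int, int]
    n_pairs: int
    max_bulge: int
    distance_to_editing_site: Optional[int]


def classify_variant_location(
    variant_pos: int, prediction: Optional[EcsPrediction]
) -> str:
    """Within-duplex / distal classification of a variant (1-based position).

    A variant is within the duplex when it falls in the stem's edit-side or
    ECS interval of the site's accepted ECS prediction; sites without a
    prediction are ``unresolved`` and excluded from structural analyses.
    """
    if prediction is None or not prediction.accepted:
        return UNRESOLVED
    p0 = variant_pos - 1
    for iv in (prediction.edit_interval, prediction.ecs_interval):
        if iv is not None and iv[0] <= p0 < iv[1]:
            return WITHIN_DUPLEX
    return DISTAL


def ld_r2(a: np.ndarray, b: np.ndarray, min_n: int = 8) -> float:
    """Squared Pearson correlation of haploid-coded calls (NaN if degenerate)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    both = ~np.isnan(a) & ~np.isnan(b)
    if both.sum() < min_n:
        return float("nan")
    av, bv = a[both], b[both]
    if np.std(av) == 0 or np.std(bv) == 0:
        return float("nan")
    r = float(np.corrcoef(av, bv)[0, 1])
    return r * r


def select_control_variants(
    genotypes: GenotypeMatrix,
    edqtls: Sequence[EdQTL],
    predictions: Dict[str, EcsPrediction],
    mode: str = "duplex",
    r2_max: float = LD_R2_MAX,
    seed: int = 0,
    n_sample: Optional[int] = None,
) -> List[str]:
    """Control variants not associated with editing and not linked to edQTLs.

    ``duplex`` mode: variants inside predicted duplexes that are not edQTLs
    and have max r^2 <= ``r2_max`` (inclusive) against every edQTL.
    ``distal-matched`` mode: variants in the same genes as distal edQTLs,
    outside the primary duplex, same LD filter, randomly subsampled to
    ``n_sample`` with the given seed.
    """
    edqtl_ids = {e.variant_id for e in edqtls}
    edqtl_calls = [genotypes.row(v) for v in edqtl_ids]
    duplex_ivs = [
        iv
        for p in predictions.values()
        if p is not None and p.accepted
        for iv in (p.edit_interval, p.ecs_interval)
        if iv is not None
    ]

    def in_duplex(pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in duplex_ivs)

    def unlinked(call: np.ndarray) -> bool:
        for g in edqtl_calls:
            r2 = ld_r2(call, g)
            if not math.isnan(r2) and r2 > r2_max:
                return False
        return True

    vt = genotypes.variants
    if mode == "duplex":
        candidate_idx = [
            i
            for i in range(len(vt))
            if vt["variant_id"].iloc[i] not in edqtl_ids and in_duplex(vt["pos"].iloc[i] - 1)
        ]
    elif mode == "distal-matched":
        site_class = {
            e.variant_id: classify_variant_location(
                int(vt.set_index("variant_id").loc[e.variant_id, "pos"]),
                predictions.get(e.site_id),
            )
            for e in edqtls
        }
        distal_genes = {
            vt.set_index("variant_id").loc[e.variant_id, "gene_id"]
            for e in edqtls
            if site_class.get(e.variant_id) == DISTAL
        }
        candidate_idx = [
            i
            for i in range(len(vt))
            if vt["gene_id"].iloc[i] in distal_genes
            and vt["variant_id"].iloc[i] not in edqtl_ids
            and not in_duplex(vt["pos"].iloc[i] - 1)
        ]
    else:
        raise ValueError(f"unknown control mode {mode!r}")

    selected = [
        vt["variant_id"].iloc[i] for i in candidate_idx if unlinked(genotypes.calls[i])
    ]
    if not selected:
        warnings.warn(f"no control variants survive filtering in mode {mode!r}")
    if mode == "distal-matched" and n_sample is not None and len(selected) > n_sample:
        rng = np.random.default_rng(seed)
        selected = [selected[i] for i in sorted(rng.choice(len(selected), n_sample, replace=False))]
    return selected


def _segment(sequence: str, iv: Tuple[int, int], strand: str) -> str:
    seg = sequence[iv[0] : iv[1]]
    return revcomp(seg) if strand == "-" else seg


def _allele_construct(
    sequence: str,
    prediction: EcsPrediction,
    variant_pos0: int,
    allele: str,
) -> Tuple[str, str, Optional[int], str]:
    """Edit-side and ECS segments with the allele substituted.

    Returns (edit_seq, ecs_seq, variant index in the folded construct,
    segment name).  The construct is ``edit + linker + ecs`` with segment
    sequences in sense-strand orientation.
    """
    strand = prediction.site.strand
    seq = sequence
    base = allele if strand == "+" else revcomp(allele)
    in_edit = prediction.edit_interval[0] <= variant_pos0 < prediction.edit_interval[1]
    in_ecs = prediction.ecs_interval[0] <= variant_pos0 < prediction.ecs_interval[1]
    if in_edit or in_ecs:
        seq = seq[:variant_pos0] + base + seq[variant_pos0 + 1 :]
    edit_seq = _segment(seq, prediction.edit_interval, strand)
    ecs_seq = _segment(seq, prediction.ecs_interval, strand)

    def local_index(iv: Tuple[int, int]) -> int:
        if strand == "+":
            return variant_pos0 - iv[0]
        return iv[1] - 1 - variant_pos0

    idx: Optional[int] = None
    segment = "outside"
    if in_edit:
        idx = local_index(prediction.edit_interval)
        segment = "edit"
    elif in_ecs:
        idx = len(edit_seq) + 100 + local_index(prediction.ecs_interval)
        segment = "ecs"
    return edit_seq, ecs_seq, idx, segment


def compare_alleles(
    variant_id: str,
    genotypes: GenotypeMatrix,
    prediction: EcsPrediction,
    sequence: str,
    raw_levels: np.ndarray,
    effect_gate: float = EFFECT_SIZE_GATE,
) -> StructuralComparison:
    """Fold the two alleles' duplex constructs and compare their structures.

    The higher-editing allele is the one whose homozygote class has the
    higher mean raw editing level (ties broken toward the reference allele,
    with a warning).  ``delta_g = G(high) - G(low)``; base-pairing status of
    the variant is read from the higher-editing allele's structure.
    """
    vt = genotypes.variants.set_index("variant_id")
    row = vt.loc[variant_id]
    pos0 = int(row["pos"]) - 1
    g = genotypes.row(variant_id)
    both = ~np.isnan(raw_levels) & ~np.isnan(g)
    mean_ref = float(np.mean(raw_levels[both & (g == 0)])) if np.any(both & (g == 0)) else math.nan
    mean_alt = float(np.mean(raw_levels[both & (g == 1)])) if np.any(both & (g == 1)) else math.nan
    if math.isnan(mean_ref) or math.isnan(mean_alt):
        raise ValueError(f"variant {variant_id}: a homozygote class is empty")
    if mean_alt > mean_ref:
        allele_high, allele_low = str(row["alt"]), str(row["ref"])
    else:
        if mean_alt == mean_ref:
            warnings.warn(f"variant {variant_id}: tied class means; reference taken as higher")
        allele_high, allele_low = str(row["ref"]), str(row["alt"])

    energies = {}
    structures = {}
    var_idx: Optional[int] = None
    for allele in (allele_high, allele_low):
        edit_seq, ecs_seq, idx, segment = _allele_construct(
            sequence, prediction, pos0, allele
        )
        structure = fold_duplex(edit_seq, ecs_seq)
        energies[allele] = structure.energy
        structures[allele] = structure
        if idx is not None:
            assert not (len(edit_seq) <= idx < len(edit_seq) + 100), "variant mapped into linker"
            var_idx = idx
    delta_g = energies[allele_high] - energies[allele_low]
    is_paired = (
        bool(structures[allele_high].pairs[var_idx] >= 0) if var_idx is not None else None
    )
    eff = effect_size(raw_levels, g)
    return StructuralComparison(
        variant_id=variant_id,
        site_id=prediction.site.site_id,
        location_class=classify_variant_location(pos0 + 1, prediction),
        is_base_paired=is_paired,
        delta_g=float(delta_g),
        signed_position=signed_position(pos0 + 1, prediction),
        allele_high=allele_high,
        allele_low=allele_low,
        effect_size=eff,
        passes_effect_gate=bool(eff >= effect_gate),
    )


def signed_position(variant_pos: int, prediction: EcsPrediction) -> Optional[int]:
    """Base-pair distance along the stem from the editing site to the variant.

    The editing site is position 0; edit-side positions transcriptionally
    downstream of the site are positive, upstream negative; an ECS position
    inherits the sign of its paired edit-side position.  Unpaired (bulge)
    positions take the nearest stem pair.  Returns None for variants outside
    the duplex.
    """
    if prediction.stem is None or not prediction.pairs_genomic:
        return None
    p0 = variant_pos - 1
    site0 = prediction.site.pos - 1
    strand = prediction.site.strand
    pairs = sorted(
        prediction.pairs_genomic, key=lambda ij: ij[0], reverse=(strand == "-")
    )
    edit_pos = [ij[0] for ij in pairs]
    ecs_pos = [ij[1] for ij in pairs]
    site_idx = int(np.argmin([abs(e - site0) for e in edit_pos]))
    in_edit = prediction.edit_interval[0] <= p0 < prediction.edit_interval[1]
    in_ecs = prediction.ecs_interval[0] <= p0 < prediction.ecs_interval[1]
    if in_edit:
        var_idx = int(np.argmin([abs(e - p0) for e in edit_pos]))
    elif in_ecs:
        var_idx = int(np.argmin([abs(e - p0) for e in ecs_pos]))
    else:
        return None
    return var_idx - site_idx


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Two-sided Fisher exact test by hypergeometric enumeration.

    Returns (odds ratio, p).  The p-value sums, over all tables with the
    observed margins, the probabilities no larger than the observed one.
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    if min(r1, c1, n - r1, n - c1) < 0 or n == 0 or r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return float("nan"), float("nan")
    rv = stats.hypergeom(n, c1, r1)
    k_lo = max(0, r1 + c1 - n)
    k_hi = min(r1, c1)
    p_obs = rv.pmf(a)
    ks = np.arange(k_lo, k_hi + 1)
    pmf = rv.pmf(ks)
    p = float(np.sum(pmf[pmf <= p_obs * (1 + 1e-7)]))
    odds = math.inf if b * c == 0 and a * d > 0 else (
        float("nan") if b * c == 0 else (a * d) / (b * c)
    )
    return odds, min(1.0, p)


def pairing_enrichment_test(
    qtl_paired: Sequence[bool], control_paired: Sequence[bool]
) -> Tuple[float, float]:
    """Fisher exact test for base-pairing enrichment of edQTLs vs controls."""
    q = np.asarray(qtl_paired, dtype=bool)
    c = np.asarray(control_paired, dtype=bool)
    table = [
        [int(q.sum()), int((~q).sum())],
        [int(c.sum()), int((~c).sum())],
    ]
    return fisher_exact_2x2(table)


def mannwhitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "less", exact_max_n: int = 10
) -> Tuple[float, float]:
    """One-sided Mann-Whitney U test (x tends smaller when ``alternative='less'``).

    Exact permutation enumeration over rank assignments when both samples
    have at most ``exact_max_n`` observations (ties handled by midranks);
    otherwise the normal approximation with tie correction and continuity
    correction.  Returns (U, p) where U counts pairs with x > y (plus half
    the ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    if alternative == "greater":
        u, p = mannwhitney_u(np.negative(x), np.negative(y), "less", exact_max_n)
        n1, n2 = len(x), len(y)
        return n1 * n2 - u, p
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0  # pairs with x > y (+ half ties)
    if len(set(pooled)) == 1:
        return u1, 1.0
    if n1 <= exact_max_n and n2 <= exact_max_n:
        count = 0
        total = 0
        obs = r1
        for comb in itertools.combinations(range(n1 + n2), n1):
            total += 1
            if ranks[list(comb)].sum() <= obs + 1e-9:
                count += 1
        return u1, count / total
    mu = n1 * n2 / 2.0
    _, t_counts = np.unique(pooled, return_counts=True)
    nn = n1 + n2
    tie_term = float(np.sum(t_counts**3 - t_counts)) / (nn * (nn - 1))
    sigma2 = n1 * n2 / 12.0 * ((nn + 1) - tie_term)
    if sigma2 <= 0:
        return u1, 1.0
    z = (u1 - mu + 0.5) / math.sqrt(sigma2)
    return u1, float(stats.norm.cdf(z))


def delta_g_test(
    qtl_delta_gs: Sequence[float], control_delta_gs: Sequence[float]
) -> Tuple[float, float]:
    """One-sided Mann-Whitney: edQTL delta-Gs more negative than controls."""
    return mannwhitney_u(qtl_delta_gs, control_delta_gs, alternative="less")


def find_distal_stems(
    variant_id: str,
    variant_pos: int,
    sequence: str,
    site_pos: Optional[int] = None,
    window: int = PROXIMAL_WINDOW,
    min_pairs: int = MIN_STEM_PAIRS,
    max_bulge: int = MAX_BULGE,
    exclude_intervals: Sequence[Tuple[int, int]] = (),
) -> List[SecondaryStem]:
    """Secondary dsRNA stems around a distal variant.

    Folds +/- ``window`` nt around the variant and returns all maximal
    bulge-bounded stems meeting the cutoffs that contain the variant
    position, skipping stems overlapping ``exclude_intervals`` (the primary
    edited duplex).  Distances are from the stem to the associated editing
    site when ``site_pos`` is given.
    """
    p0 = variant_pos - 1
    lo = max(0, p0 - window)
    hi = min(len(sequence), p0 + window + 1)
    structure = fold_mfe(sequence[lo:hi])
    anchor = p0 - lo
    out: List[SecondaryStem] = []
    for stem in enumerate_stems(structure, min_pairs=min_pairs, max_bulge=max_bulge):
        if stem.side_of(anchor) is None:
            continue
        left = (lo + stem.left[0], lo + stem.left[1])
        right = (lo + stem.right[0], lo + stem.right[1])
        overlap = any(
            s < iv[1] and iv[0] < e for s, e in (left, right) for iv in exclude_intervals
        )
        if overlap:
            continue
        dist = None
        if site_pos is not None:
            s0 = site_pos - 1
            dist = int(
                min(
                    min(abs(s0 - left[0]), abs(s0 - (left[1] - 1))),
                    min(abs(s0 - right[0]), abs(s0 - (right[1] - 1))),
                )
            )
            if left[0] <= s0 < left[1] or right[0] <= s0 < right[1]:
                dist = 0
        out.append(
            SecondaryStem(
                variant_id=variant_id,
                stem=stem,
                left_interval=left,
                right_interval=right,
                n_pairs=stem.n_pairs,
                max_bulge=stem.max_bulge,
                distance_to_editing_site=dist,
            )
        )
    return out


def editing_site_window_frequency(
    variants: pd.DataFrame,
    sites: Sequence,
    window_sizes: Sequence[int] = (200, 500, 1_000, 2_000, 4_000),
) -> pd.DataFrame:
    """Editing-site counts in centered windows around each variant.

    ``variants`` needs columns variant_id, chrom, pos.  A site counts toward
    window ``w`` when ``|site.pos - variant.pos| <= w/2`` on the same
    chromosome; counts are monotone non-decreasing in window size.
    """
    site_by_chrom: Dict[str, np.ndarray] = {}
    for s in sites:
        site_by_chrom.setdefault(s.chrom, []).append(s.pos)
    site_by_chrom = {k: np.asarray(sorted(v)) for k, v in site_by_chrom.items()}
    rows = []
    for _, v in variants.iterrows():
        pos = site_by_chrom.get(v["chrom"], np.array([]))
        row = {"variant_id": v["variant_id"]}
        for w in window_sizes:
            row[f"w{w}"] = int(np.sum(np.abs(pos - v["pos"]) <= w / 2)) if len(pos) else 0
        rows.append(row)
    return pd.DataFrame(rows)
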