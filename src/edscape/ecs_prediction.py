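"""Prediction of editing complementary sequences (ECSs).

ADAR editing sites sit in one strand of a duplex whose other strand -- the
editing complementary sequence -- may be proximal (within a couple hundred
bases) or distal, often intronic.  Two approaches are implemented:

* **Approach 1 (proximal)**: fold the sense-strand region within 200 nt of
  the editing site and extract the stem containing the site; the ECS is the
  complementary strand of that stem.  A prediction is accepted when the stem
  has at least 20 pairs and a maximum bulge of 8 nt.
* **Approach 2 (distal, intronic)**: smooth a per-base conservation track
  with a 51-nt sliding window, take conserved candidate regions (smoothed
  score >= 0.90, length >= 20, within 2,500 nt of the site), join the
  site-flanking region (+/- 60 nt) to each buffered candidate (+/- 30 nt)
  with a 100-adenosine non-pairing linker, fold, and accept stems that pair
  the editing site region with the candidate segment under the same cutoffs.

An enrichment score -- the density of known editing sites inside predicted
ECSs relative to flanking regions of the same length -- quantifies
prediction accuracy, since ECSs, as the second strand of an edited duplex,
tend themselves to be edited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .editing_quant import EditingSite
from .structure_engine import (
    RnaStructure,
    Stem,
    extract_stem_at,
    fold_mfe,
)
from .synthetic_data import revcomp

PROXIMAL_WINDOW = 200
MIN_STEM_PAIRS = 20
MAX_BULGE = 8
CONS_SMOOTH_WINDOW = 51
CONS_MIN_SCORE = 0.90
CONS_MIN_LENGTH = 20
CONS_MAX_DISTANCE = 2_500
DISTAL_BUFFER = 30
DISTAL_SITE_FLANK = 60
DISTAL_LINKER = 100


@dataclass
class EcsPrediction:
    """A predicted ECS for one editing site.

    Genomic intervals are 0-based half-open on the site's chromosome; the
    ``structure`` is the folded window (sense-strand orientation) with
    ``site_index`` the editing site's position in it.
    """

    site: EditingSite
    approach: str  # "proximal" or "distal"
    stem: Optional[Stem]
    ecs_interval: Optional[Tuple[int, int]]
    edit_interval: Optional[Tuple[int, int]]
    distance: Optional[int]
    accepted: bool
    structure: Optional[RnaStructure] = None
    site_index: Optional[int] = None
    reject_reason: Optional[str] = None
    # per stem pair: (edit-side genomic position, ECS genomic position), 0-based
    pairs_genomic: List[Tuple[int, int]] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pairs_genomic is None:
            self.pairs_genomic = []

    @property
    def n_pairs(self) -> int:
        return self.stem.n_pairs if self.stem else 0

    @property
    def max_bulge(self) -> int:
        return self.stem.max_bulge if self.stem else 0


@dataclass
class ConservedRegion:
    """A conserved candidate ECS region (0-based half-open, track coords)."""

    start: int
    end: int
    smoothed_score: float
    distance_to_site: int


def _sense_window(
    sequence: str, site_pos0: int, strand: str, window: int
) -> Tuple[str, int, int]:
    """Extract the sense-strand folding window around a site.

    Returns (window sequence, anchor index in window, genomic window start).
    For minus-strand sites the window is reverse-complemented so the editing
    site is an A on the folded strand.
    """
    lo = max(0, site_pos0 - window)
    hi = min(len(sequence), site_pos0 + window + 1)
    win = sequence[lo:hi]
    if strand == "-":
        win = revcomp(win)
        anchor = hi - 1 - site_pos0
    else:
        anchor = site_pos0 - lo
    return win, anchor, lo


def _window_to_genomic(idx: int, win_len: int, win_start: int, strand: str) -> int:
    if strand == "-":
        return win_start + (win_len - 1 - idx)
    return win_start + idx


def _interval_to_genomic(
    start: int, end: int, win_len: int, win_start: int, strand: str
) -> Tuple[int, int]:
    a = _window_to_genomic(start, win_len, win_start, strand)
    b = _window_to_genomic(end - 1, win_len, win_start, strand)
    lo, hi = min(a, b), max(a, b)
    return lo, hi + 1


def _site_distance(stem: Stem, structure: RnaStructure, anchor: int) -> int:
    """Distance from the editing site to its paired (or nearest-pair) base."""
    if structure.pairs[anchor] >= 0:
        return abs(int(structure.pairs[anchor]) - anchor)
    # site unpaired within the stem: use the closest stem pair
    best = min(stem.pairs, key=lambda ij: min(abs(ij[0] - anchor), abs(ij[1] - anchor)))
    partner = best[1] if abs(best[0] - anchor) <= abs(best[1] - anchor) else best[0]
    return abs(partner - anchor)


def predict_proximal_ecs(
    site: EditingSite,
    sequence: str,
    window: int = PROXIMAL_WINDOW,
    min_pairs: int = MIN_STEM_PAIRS,
    max_bulge: int = MAX_BULGE,
) -> Optional[EcsPrediction]:
    """Approach 1: fold +/- ``window`` nt around the site, extract its stem.

    ``sequence`` is the site's chromosome/contig (the window is truncated at
    its ends).  Returns ``None`` when the site is unpaired with no enclosing
    pair in the window; otherwise a prediction whose ``accepted`` flag
    applies the stem-length and bulge cutoffs.
    """
    pos0 = site.pos - 1
    if not 0 <= pos0 < len(sequence):
        raise IndexError(f"site {site.site_id} outside sequence bounds")
    win, anchor, win_start = _sense_window(sequence, pos0, site.strand, window)
    structure = fold_mfe(win)
    stem = extract_stem_at(structure, anchor, min_pairs=1, max_bulge=max_bulge)
    if stem is None:
        return None
    side = stem.side_of(anchor)
    if side is None:
        # anchor sits in the hairpin loop between the two strands
        side = "left" if abs(anchor - stem.left[1]) <= abs(anchor - stem.right[0]) else "right"
    edit_iv, ecs_iv = (stem.left, stem.right) if side == "left" else (stem.right, stem.left)
    n = len(win)
    pairs_genomic = []
    for i, j in stem.pairs:
        e, c = (i, j) if side == "left" else (j, i)
        pairs_genomic.append(
            (
                _window_to_genomic(e, n, win_start, site.strand),
                _window_to_genomic(c, n, win_start, site.strand),
            )
        )
    prediction = EcsPrediction(
        site=site,
        approach="proximal",
        stem=stem,
        ecs_interval=_interval_to_genomic(*ecs_iv, n, win_start, site.strand),
        edit_interval=_interval_to_genomic(*edit_iv, n, win_start, site.strand),
        distance=_site_distance(stem, structure, anchor),
        accepted=stem.n_pairs >= min_pairs and stem.max_bulge <= max_bulge,
        structure=structure,
        site_index=anchor,
        reject_reason=None if stem.n_pairs >= min_pairs else "stem shorter than cutoff",
        pairs_genomic=pairs_genomic,
    )
    return prediction


def smooth_conservation(track: np.ndarray, window: int = CONS_SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average of a per-base conservation track.

    The window must be odd; positions near the track ends use the truncated
    window.  Output stays within [0, 1] for inputs in [0, 1].
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    track = np.asarray(track, dtype=float)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(track)])
    n = len(track)
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def candidate_conserved_regions(
    smoothed: np.ndarray,
    site_index: int,
    max_dist: int = CONS_MAX_DISTANCE,
    min_len: int = CONS_MIN_LENGTH,
    min_score: float = CONS_MIN_SCORE,
    introns: Optional[Sequence[Tuple[int, int]]] = None,
) -> List[ConservedRegion]:
    """Maximal qualifying runs of smoothed conservation near the site.

    A run qualifies when every base has smoothed score >= ``min_score``, it
    is at least ``min_len`` long, and its closest base lies within
    ``max_dist`` of the site.  When intron intervals are given, runs must lie
    entirely within one.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    qual = smoothed >= min_score
    regions: List[ConservedRegion] = []
    i = 0
    n = len(qual)
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i
        while j < n and qual[j]:
            j += 1
        if j - i >= min_len:
            if site_index < i:
                dist = i - site_index
            elif site_index >= j:
                dist = site_index - (j - 1)
            else:
                dist = 0
            ok = dist <= max_dist
            if ok and introns is not None:
                ok = any(s <= i and j <= e for s, e in introns)
            if ok:
                regions.append(
                    ConservedRegion(i, j, float(np.min(smoothed[i:j])), dist)
                )
        i = j
    return regions


def predict_distal_ecs(
    site: EditingSite,
    candidates: Sequence[ConservedRegion],
    sequence: str,
    buffer: int = DISTAL_BUFFER,
    site_flank: int = DISTAL_SITE_FLANK,
    linker: int = DISTAL_LINKER,
    min_pairs: int = MIN_STEM_PAIRS,
    max_bulge: int = MAX_BULGE,
) -> List[EcsPrediction]:
    """Approach 2: fold the site flank against each buffered candidate region.

    Assembles ``[site +/- site_flank] + linker adenosines (pairing
    forbidden) + [candidate +/- buffer]`` in sense-strand orientation, folds,
    and anchors stem extraction on the editing site.  Only stems whose
    partner strand lies in the candidate segment are accepted.  Returns one
    prediction per candidate (unaccepted ones carry a reject reason),
    ranked with accepted longest stems first.
    """
    pos0 = site.pos - 1
    out: List[EcsPrediction] = []
    for cand in candidates:
        s_lo = max(0, pos0 - site_flank)
        s_hi = min(len(sequence), pos0 + site_flank + 1)
        c_lo = max(0, cand.start - buffer)
        c_hi = min(len(sequence), cand.end + buffer)
        if s_lo < c_hi and c_lo < s_hi:
            warnings.warn(
                f"candidate region overlaps the site flank for {site.site_id}; "
                "falling back to the proximal approach"
            )
            prox = predict_proximal_ecs(
                site, sequence, min_pairs=min_pairs, max_bulge=max_bulge
            )
            if prox is not None:
                out.append(prox)
            continue
        site_seg = sequence[s_lo:s_hi]
        cand_seg = sequence[c_lo:c_hi]
        if site.strand == "-":
            # sense-strand orientation for both segments
            site_seg, cand_seg = revcomp(site_seg), revcomp(cand_seg)
        assembled = site_seg + "A" * linker + cand_seg
        mask = np.zeros(len(assembled), dtype=bool)
        mask[len(site_seg) : len(site_seg) + linker] = True
        anchor = (pos0 - s_lo) if site.strand == "+" else (s_hi - 1 - pos0)
        structure = fold_mfe(assembled, constraint_mask=mask)
        stem = extract_stem_at(structure, anchor, min_pairs=1, max_bulge=max_bulge)
        if stem is None:
            continue
        cand_offset = len(site_seg) + linker
        side = stem.side_of(anchor) or "left"
        edit_iv, ecs_iv = (
            (stem.left, stem.right) if side == "left" else (stem.right, stem.left)
        )
        in_candidate = ecs_iv[0] >= cand_offset
        # map assembled coordinates to genomic
        def to_genomic(iv: Tuple[int, int], segment: str) -> Tuple[int, int]:
            if segment == "site":
                if site.strand == "+":
                    return (s_lo + iv[0], s_lo + iv[1])
                return (s_lo + (len(site_seg) - iv[1]), s_lo + (len(site_seg) - iv[0]))
            a, b = iv[0] - cand_offset, iv[1] - cand_offset
            if site.strand == "+":
                return (c_lo + a, c_lo + b)
            return (c_lo + (len(cand_seg) - b), c_lo + (len(cand_seg) - a))

        def pos_genomic(idx: int) -> int:
            if idx < len(site_seg):
                if site.strand == "+":
                    return s_lo + idx
                return s_hi - 1 - idx
            k = idx - cand_offset
            if site.strand == "+":
                return c_lo + k
            return c_hi - 1 - k

        pairs_genomic = []
        for i, j in stem.pairs:
            e, c = (i, j) if side == "left" else (j, i)
            pairs_genomic.append((pos_genomic(e), pos_genomic(c)))

        accepted = (
            in_candidate and stem.n_pairs >= min_pairs and stem.max_bulge <= max_bulge
        )
        reason = None
        if not in_candidate:
            reason = "stem pairs within the site flank, not the candidate"
        elif stem.n_pairs < min_pairs:
            reason = "stem shorter than cutoff"
        out.append(
            EcsPrediction(
                site=site,
                approach="distal",
                stem=stem,
                ecs_interval=to_genomic(ecs_iv, "candidate" if in_candidate else "site"),
                edit_interval=to_genomic(edit_iv, "site"),
                distance=(
                    cand.distance_to_site if in_candidate else None
                ),
                accepted=accepted,
                structure=structure,
                site_index=anchor,
                reject_reason=reason,
                pairs_genomic=pairs_genomic,
            )
        )
    out.sort(key=lambda p: (not p.accepted, -p.n_pairs))
    return out


def _merge_intervals(ivs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def enrichment_score(
    predictions: Sequence[EcsPrediction],
    all_sites: Sequence[EditingSite],
    contig_lengths: Optional[Dict[str, int]] = None,
    exclude_anchor_sites: bool = True,
) -> Tuple[float, pd.DataFrame]:
    """Editing-site density in predicted ECSs relative to equal-length flanks.

    For each accepted ECS interval (merged per chromosome), two flanking
    regions of the ECS's own length are placed immediately up- and
    downstream (truncated at contig ends, with the score computed as a
    density ratio so truncation renormalizes lengths).  The aggregate score
    is ``(sites in ECSs) / (sites in flanks / 2)`` in the untruncated case; a
    uniform site distribution gives ~1.  The anchoring editing sites of the
    predictions themselves are excluded from the tallies by default (the
    flag is recorded in the per-region table).  Returns (score, table);
    the score is NaN when the flanks contain no sites.
    """
    anchors = {(p.site.chrom, p.site.pos - 1) for p in predictions} if exclude_anchor_sites else set()
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for p in predictions:
        if p.accepted and p.ecs_interval is not None:
            by_chrom.setdefault(p.site.chrom, []).append(p.ecs_interval)
    site_pos: Dict[str, np.ndarray] = {}
    for chrom in by_chrom:
        site_pos[chrom] = np.array(
            sorted(
                s.pos - 1
                for s in all_sites
                if s.chrom == chrom and (chrom, s.pos - 1) not in anchors
            )
        )

    rows = []
    ecs_count = ecs_len = flank_count = flank_len = 0
    for chrom, ivs in by_chrom.items():
        pos = site_pos[chrom]
        climit = contig_lengths.get(chrom) if contig_lengths else None
        for s, e in _merge_intervals(ivs):
            length = e - s
            n_ecs = int(np.sum((pos >= s) & (pos < e))) if len(pos) else 0
            f1 = (max(0, s - length), s)
            f2 = (e, min(climit, e + length) if climit is not None else e + length)
            n_fl = 0
            for fs, fe in (f1, f2):
                if len(pos):
                    n_fl += int(np.sum((pos >= fs) & (pos < fe)))
            ecs_count += n_ecs
            ecs_len += length
            flank_count += n_fl
            flank_len += (f1[1] - f1[0]) + (f2[1] - f2[0])
            rows.append(
                {
                    "chrom": chrom,
                    "ecs_start": s,
                    "ecs_end": e,
                    "n_sites_ecs": n_ecs,
                    "n_sites_flank": n_fl,
                    "flank_length": (f1[1] - f1[0]) + (f2[1] - f2[0]),
                    "anchor_excluded": exclude_anchor_sites,
                }
            )
    table = pd.DataFrame(rows)
    if flank_count == 0 or flank_len == 0 or ecs_len == 0:
        return float("nan"), table
    score = (ecs_count / ecs_len) / (flank_count / flank_len)
    return float(score), table


def substrate_properties(
    predictions: Sequence[EcsPrediction], flank: int = 10
) -> Dict[str, object]:
    """Distributions characterizing accepted editing substrates.

    Returns site-to-ECS distances, stem lengths, edit-side max bulges, and
    the fraction of substrates base-paired at each position within
    ``+/- flank`` nt of the editing site (position 0 = the site).
    """
    acc = [p for p in predictions if p.accepted and p.structure is not None]
    if not acc:
        raise ValueError("no accepted predictions")
    distances = [p.distance for p in acc if p.distance is not None]
    stem_lengths = [p.n_pairs for p in acc]
    edit_bulges = []
    for p in acc:
        side = p.stem.side_of(p.site_index)
        edit_bulges.append(
            p.stem.max_bulge_left if side in (None, "left") else p.stem.max_bulge_right
        )
    offsets = np.arange(-flank, flank + 1)
    paired = np.zeros(len(offsets))
    counts = np.zeros(len(offsets))
    for p in acc:
        for k, off in enumerate(offsets):
            idx = p.site_index + off
            if 0 <= idx < p.structure.n:
                counts[k] += 1
                if p.structure.pairs[idx] >= 0:
                    paired[k] += 1
    with np.errstate(invalid="ignore"):
        fraction = np.where(counts > 0, paired / np.maximum(counts, 1), np.nan)
    return {
        "distances": distances,
        "stem_lengths": stem_lengths,
        "edit_side_max_bulges": edit_bulges,
        "pairing_offsets": offsets,
        "pairing_fraction": fraction,
    }
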