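"""Synthetic strain panels, editing loci and read counts with planted truth.

The generator emulates the statistical structure of a targeted-resequencing
editing survey of a panel of fully inbred fly strains: haploid-coded biallelic
genotypes, per-site editing levels in [0, 1] with planted additive genotype
effects (half-difference convention: the two homozygote class means differ by
twice the planted effect), binomial read sampling around a mean coverage in
two replicates, and RNA loci containing planted hairpin duplexes whose
disruption by a variant alters editing.  Every quantity downstream stages
estimate has a recorded ground truth, and all generation is a pure function
of (config, seed).

Planted duplex loci are designed so that the minimum-free-energy fold
recovers exactly the planted stem: the two arms are perfect complements
(with specified bulges), flanking sequence is random with a rejection step
against off-target 12-nt self-complementarity, and short non-pairing spacer
tracts (all-C outside the arms, A/C-only loop) prevent chance flank pairs
from accreting onto the planted stem across a small bulge.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .editing_quant import EditingMatrix, EditingSite
from .edqtl_mapping import GenotypeMatrix
from .structure_engine import bases_pair

DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
GENE_SPACING = 10_000  # genomic offset between synthetic loci on the same chromosome
CHROM = "chrS"
SPACER = 9  # length of the all-C non-pairing tracts around planted arms


def revcomp(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic panel.

    Defaults mirror the emulated survey: 131 inbred strains in 2 replicates,
    biallelic cis variants, planted effects in editing-level units
    (half-difference convention; negative values mean the alternate,
    duplex-disrupting allele lowers editing).
    """

    n_strains: int = 131
    n_sites: int = 20
    n_variants_per_gene: int = 10
    maf_range: Tuple[float, float] = (0.1, 0.5)
    baseline_editing_range: Tuple[float, float] = (0.2, 0.8)
    effect_sizes: Tuple[float, ...] = (-0.2, -0.1, -0.05, 0.0)
    noise_sd: float = 0.05
    coverage_mean: float = 100.0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_strains < 8:
            raise ValueError("n_strains must be >= 8")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        blo, bhi = self.baseline_editing_range
        if not (0 <= blo <= bhi <= 1):
            raise ValueError("baseline_editing_range must lie within [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class DuplexSpec:
    """Specification of a planted editing duplex.

    ``bulges`` is a list of ``(pair_index, size, side)`` tuples: ``size``
    unpaired nucleotides inserted between stem pairs ``pair_index`` and
    ``pair_index + 1`` (pairs numbered 5'->3' along the edit-side arm) on
    side ``"edit"`` or ``"ecs"``.  ``ecs_offset`` is the distance in
    nucleotides from the editing site to the first ECS base.
    """

    stem_length: int
    bulges: Tuple[Tuple[int, int, str], ...] = ()
    ecs_offset: int = 40
    intronic: bool = False

    def __post_init__(self) -> None:
        if self.stem_length < 5:
            raise ValueError("stem length must be >= 5")
        if self.ecs_offset < 0:
            raise ValueError("ecs offset must be >= 0")
        for k, size, side in self.bulges:
            if not (0 <= k < self.stem_length - 1) or size < 1 or side not in ("edit", "ecs"):
                raise ValueError(f"invalid bulge spec ({k}, {size}, {side})")

    @property
    def site_index_in_arm(self) -> int:
        return self.stem_length // 2


@dataclass
class LocusTruth:
    """Ground-truth intervals for a planted locus (0-based, locus-local)."""

    site_index: int
    edit_interval: Tuple[int, int]
    ecs_interval: Tuple[int, int]
    pairs: List[Tuple[int, int]]
    spec: DuplexSpec


@dataclass
class Locus:
    gene_id: str
    chrom: str
    offset: int  # 0-based genomic start of the locus sequence
    sequence: str
    strand: str
    truth: Optional[LocusTruth] = None


@dataclass
class PlantedTruth:
    """Ground truth joining planted effects, duplexes and disrupting variants."""

    qtl_assignments: Dict[str, Tuple[str, float]]  # variant_id -> (site_id, effect)
    duplex_specs: Dict[str, DuplexSpec]  # site_id -> spec
    disrupting_variants: Set[str]
    sites: List[EditingSite] = field(default_factory=list)

    def validate(self) -> None:
        for v in self.disrupting_variants:
            if v not in self.qtl_assignments:
                raise ValueError(f"disrupting variant {v} has no planted effect")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    truth: PlantedTruth
    sites: List[EditingSite]
    loci: Dict[str, Locus]
    levels: EditingMatrix
    counts: pd.DataFrame


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _draw_calls(rng: np.random.Generator, n_strains: int, maf_range: Tuple[float, float]) -> np.ndarray:
    """Haploid calls with realized minor-allele frequency inside maf_range.

    The minor-allele count is drawn uniformly from the integer counts
    compatible with the range and assigned to a random strain subset, so the
    realized frequency always satisfies the configured bounds.
    """
    lo, hi = maf_range
    k_lo = max(1, math.ceil(lo * n_strains - 1e-9))
    k_hi = min(n_strains // 2, math.floor(hi * n_strains + 1e-9))
    if k_hi < k_lo:
        raise ValueError("maf_range admits no valid minor-allele count")
    k = int(rng.integers(k_lo, k_hi + 1))
    calls = np.zeros(n_strains)
    calls[rng.choice(n_strains, size=k, replace=False)] = 1.0
    return calls


def generate_genotypes(
    config: SimulationConfig,
    variant_table: Optional[pd.DataFrame] = None,
) -> GenotypeMatrix:
    """Generate a haploid-coded genotype matrix for the configured panel.

    Without a ``variant_table``, variants are laid out as
    ``n_sites * n_variants_per_gene`` biallelic SNVs, one gene per site,
    at arbitrary positions on the synthetic chromosome.
    """
    rng = np.random.default_rng([config.seed, 11])
    if variant_table is None:
        rows = []
        for g in range(config.n_sites):
            offset = g * GENE_SPACING
            pos = np.sort(
                rng.choice(np.arange(1, GENE_SPACING - 1), size=config.n_variants_per_gene, replace=False)
            )
            for v, p in enumerate(pos):
                ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
                rows.append(
                    {
                        "variant_id": f"g{g:03d}_v{v:02d}",
                        "chrom": CHROM,
                        "pos": int(offset + p),
                        "gene_id": f"g{g:03d}",
                        "ref": ref,
                        "alt": alt,
                    }
                )
        variant_table = pd.DataFrame(rows)
    strains = [f"S{i:03d}" for i in range(config.n_strains)]
    calls = np.vstack(
        [_draw_calls(rng, config.n_strains, config.maf_range) for _ in range(len(variant_table))]
    )
    return GenotypeMatrix(variant_table, strains, calls)


# ---------------------------------------------------------------------------
# duplex loci
# ---------------------------------------------------------------------------


def _choose_nonpairing(rng: np.random.Generator, opposite: Sequence[str]) -> str:
    for cand in "CAGT":
        if not any(bases_pair(cand, o) for o in opposite):
            return cand
    return "C"


def _build_arms(
    spec: DuplexSpec, rng: np.random.Generator
) -> Tuple[List[Tuple[str, Optional[int]]], List[Tuple[str, Optional[int]]]]:
    """Edit-side and ECS arm sequences as (base, pair_index or None) lists."""
    arm = [str(rng.choice(list("ACGT"))) for _ in range(spec.stem_length)]
    arm[spec.site_index_in_arm] = "A"
    ecs = [revcomp(b) for b in arm][::-1]  # ecs[k] pairs arm[stem_length-1-k]
    edit_seq: List[Tuple[str, Optional[int]]] = [(b, k) for k, b in enumerate(arm)]
    ecs_seq: List[Tuple[str, Optional[int]]] = [
        (b, spec.stem_length - 1 - k) for k, b in enumerate(ecs)
    ]
    # insert bulges (work 3' -> 5' in pair index so insertion points stay valid)
    for k, size, side in sorted(spec.bulges, key=lambda b: -b[0]):
        if side == "edit":
            at = next(i for i, (_, p) in enumerate(edit_seq) if p == k) + 1
            opp = [ecs_seq[i][0] for i, (_, p) in enumerate(ecs_seq) if p in (k, k + 1)]
            ins = _choose_nonpairing(rng, opp)
            for _ in range(size):
                edit_seq.insert(at, (ins, None))
        else:
            at = next(i for i, (_, p) in enumerate(ecs_seq) if p == k)
            opp = [edit_seq[i][0] for i, (_, p) in enumerate(edit_seq) if p in (k, k + 1)]
            ins = _choose_nonpairing(rng, opp)
            for _ in range(size):
                ecs_seq.insert(at, (ins, None))
    return edit_seq, ecs_seq


def _kmer_selfcomp(seq: str, arm_spans: List[Tuple[int, int]], k: int = 12) -> bool:
    """True if any k-mer reverse-complements another with either outside the arms."""

    def in_arms(i: int) -> bool:
        return any(s <= i and i + k <= e for s, e in arm_spans)

    positions: Dict[str, List[int]] = {}
    for i in range(len(seq) - k + 1):
        positions.setdefault(seq[i : i + k], []).append(i)
    for kmer, locs in positions.items():
        rc = revcomp(kmer)
        if rc not in positions:
            continue
        for i in locs:
            for j in positions[rc]:
                if j < i + k:  # overlapping windows are tiny self-hairpins, not duplexes
                    continue
                if not (in_arms(i) and in_arms(j)):
                    return True
    return False


def generate_duplex_locus(
    spec: DuplexSpec, seed: int, flank: int = 120
) -> Tuple[str, LocusTruth]:
    """Generate a locus whose MFE fold contains the planted hairpin.

    Layout: flank | C-spacer | edit arm | A/C loop | ECS arm | C-spacer |
    flank.  The editing site is the central base of the edit arm (always an
    A); ``spec.ecs_offset`` is the site-to-ECS distance, which fixes the loop
    length (must leave room for a >= 3 nt hairpin loop).
    """
    rng = np.random.default_rng([seed, 23])
    loop_len = spec.ecs_offset - (spec.stem_length - spec.site_index_in_arm)
    if loop_len < 3:
        raise ValueError(
            f"ecs_offset {spec.ecs_offset} too small to accommodate the hairpin loop"
        )
    edit_seq, ecs_seq = _build_arms(spec, rng)

    if loop_len <= 2 * SPACER:
        loop = "C" * loop_len
    else:
        mid = "".join(rng.choice(["A", "C"], size=loop_len - 2 * SPACER))
        loop = "C" * SPACER + mid + "C" * SPACER

    for _ in range(60):
        left = "".join(rng.choice(list("ACGT"), size=flank))
        right = "".join(rng.choice(list("ACGT"), size=flank))
        pre = left + "C" * SPACER
        edit_start = len(pre)
        edit_bases = "".join(b for b, _ in edit_seq)
        ecs_start = edit_start + len(edit_bases) + len(loop)
        ecs_bases = "".join(b for b, _ in ecs_seq)
        seq = pre + edit_bases + loop + ecs_bases + "C" * SPACER + right
        arm_spans = [
            (edit_start, edit_start + len(edit_bases)),
            (ecs_start, ecs_start + len(ecs_bases)),
        ]
        if not _kmer_selfcomp(seq, arm_spans):
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not generate low-self-complementarity flanks")

    edit_pos = {p: edit_start + i for i, (_, p) in enumerate(edit_seq) if p is not None}
    ecs_pos = {p: ecs_start + i for i, (_, p) in enumerate(ecs_seq) if p is not None}
    pairs = [(edit_pos[k], ecs_pos[k]) for k in range(spec.stem_length)]
    truth = LocusTruth(
        site_index=edit_pos[spec.site_index_in_arm],
        edit_interval=(edit_start, edit_start + len(edit_bases)),
        ecs_interval=(ecs_start, ecs_start + len(ecs_bases)),
        pairs=pairs,
        spec=spec,
    )
    return seq, truth


def generate_distal_locus(
    spec: DuplexSpec,
    distance: int,
    seed: int,
    flank: int = 80,
) -> Tuple[str, LocusTruth, np.ndarray]:
    """Generate a locus with a distal (intronic-style) ECS and conservation track.

    The ECS arm is placed ``distance`` nucleotides downstream of the editing
    site (beyond the proximal folding window when ``distance > 200``), and a
    per-base conservation track is returned that is high (1.0) over the ECS
    plus a margin and low elsewhere, so the ECS region survives 51-nt
    smoothing at the 0.90 threshold.
    """
    rng = np.random.default_rng([seed, 31])
    edit_seq, ecs_seq = _build_arms(spec, rng)
    edit_bases = "".join(b for b, _ in edit_seq)
    ecs_bases = "".join(b for b, _ in ecs_seq)
    site_in_arm = next(i for i, (_, p) in enumerate(edit_seq) if p == spec.site_index_in_arm)
    gap_len = distance - (len(edit_bases) - site_in_arm) - SPACER * 2
    if gap_len < 10:
        raise ValueError("distance too small for a distal layout")

    for _ in range(60):
        left = "".join(rng.choice(list("ACGT"), size=flank))
        right = "".join(rng.choice(list("ACGT"), size=flank))
        gap = "".join(rng.choice(["A", "C"], size=gap_len))  # non-self-pairing spacer
        pre = left + "C" * SPACER
        edit_start = len(pre)
        ecs_start = edit_start + len(edit_bases) + SPACER + gap_len + SPACER
        seq = (
            pre
            + edit_bases
            + "C" * SPACER
            + gap
            + "C" * SPACER
            + ecs_bases
            + "C" * SPACER
            + right
        )
        arm_spans = [
            (edit_start, edit_start + len(edit_bases)),
            (ecs_start, ecs_start + len(ecs_bases)),
        ]
        if not _kmer_selfcomp(seq, arm_spans):
            break
    else:  # pragma: no cover
        raise RuntimeError("could not generate low-self-complementarity flanks")

    edit_pos = {p: edit_start + i for i, (_, p) in enumerate(edit_seq) if p is not None}
    ecs_pos = {p: ecs_start + i for i, (_, p) in enumerate(ecs_seq) if p is not None}
    truth = LocusTruth(
        site_index=edit_pos[spec.site_index_in_arm],
        edit_interval=(edit_start, edit_start + len(edit_bases)),
        ecs_interval=(ecs_start, ecs_start + len(ecs_bases)),
        pairs=[(edit_pos[k], ecs_pos[k]) for k in range(spec.stem_length)],
        spec=spec,
    )
    cons = rng.uniform(0.0, 0.4, size=len(seq))
    margin = 25
    lo = max(0, ecs_start - margin)
    hi = min(len(seq), ecs_start + len(ecs_bases) + margin)
    cons[lo:hi] = 1.0
    return seq, truth, cons


# ---------------------------------------------------------------------------
# editing levels and read counts
# ---------------------------------------------------------------------------


def generate_editing_levels(
    genotypes: GenotypeMatrix,
    truth: PlantedTruth,
    config: SimulationConfig,
) -> EditingMatrix:
    """Additive-with-Gaussian-noise editing levels, clamped to [0, 1].

    ``level(strain, site) = clamp(baseline_site + 2 * effect * g + N(0, sd))``
    so the two homozygote class means differ by twice the planted effect and
    the half-difference estimator recovers it.
    """
    truth.validate()
    rng = np.random.default_rng([config.seed, 47])
    sites = truth.sites
    n_sites, n_strains = len(sites), len(genotypes.strains)
    lo, hi = config.baseline_editing_range
    baselines = rng.uniform(lo, hi, size=n_sites)
    level = np.tile(baselines[:, None], (1, n_strains))
    by_site: Dict[str, List[Tuple[str, float]]] = {}
    for var_id, (site_id, eff) in truth.qtl_assignments.items():
        by_site.setdefault(site_id, []).append((var_id, eff))
    for i, site in enumerate(sites):
        for var_id, eff in by_site.get(site.site_id, []):
            g = np.nan_to_num(genotypes.row(var_id), nan=0.0)
            level[i] += 2.0 * eff * g
    if config.noise_sd > 0:
        level += rng.normal(0.0, config.noise_sd, size=level.shape)
    return EditingMatrix(sites, list(genotypes.strains), np.clip(level, 0.0, 1.0))


def generate_read_counts(
    levels: EditingMatrix, config: SimulationConfig
) -> pd.DataFrame:
    """Per-replicate (G count, total count) sampling around the mean coverage.

    Total counts are Poisson around ``coverage_mean``; G counts are binomial
    in the true level, independently per replicate.
    """
    rng = np.random.default_rng([config.seed, 53])
    rows = []
    for i, site in enumerate(levels.sites):
        for j, strain in enumerate(levels.strains):
            p = levels.level[i, j]
            if math.isnan(p):
                continue
            for rep in range(1, config.n_replicates + 1):
                total = int(rng.poisson(config.coverage_mean))
                g = int(rng.binomial(total, p)) if total > 0 else 0
                rows.append((site.site_id, strain, rep, g, total))
    return pd.DataFrame(
        rows, columns=["site_id", "strain", "replicate", "g_count", "total_count"]
    )


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


def _disrupting_alt(sequence: str, pos: int, partner_base: str, rng: np.random.Generator) -> str:
    """An alternate allele at ``pos`` that cannot pair with the partner base."""
    ref = sequence[pos]
    options = [b for b in "ACGT" if b != ref and not bases_pair(b, partner_base)]
    return str(rng.choice(options)) if options else ("C" if ref != "C" else "A")


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic study: loci, genotypes, levels, counts.

    One gene/locus per editing site.  Sites with a nonzero planted effect get
    a duplex-disrupting variant inside the planted stem (the alternate allele
    breaks one base pair); remaining variants are placed in the flanks.
    Effects cycle through ``config.effect_sizes`` across sites.
    """
    rng = np.random.default_rng([config.seed, 3])
    sites: List[EditingSite] = []
    loci: Dict[str, Locus] = {}
    variant_rows = []
    qtl_assignments: Dict[str, Tuple[str, float]] = {}
    duplex_specs: Dict[str, DuplexSpec] = {}
    disrupting: Set[str] = set()

    for g in range(config.n_sites):
        gene_id = f"g{g:03d}"
        offset = g * GENE_SPACING
        stem_length = int(rng.integers(22, 33))
        bulges: Tuple[Tuple[int, int, str], ...] = ()
        if rng.random() < 0.5:
            # keep >= 6 pairs on each side so both helix segments fold stably
            k = int(rng.integers(6, stem_length - 7))
            if k == stem_length // 2:
                k += 1
            bulges = ((k, int(rng.integers(1, 4)), str(rng.choice(["edit", "ecs"]))),)
        loop_len = int(rng.integers(8, 21))
        spec = DuplexSpec(
            stem_length=stem_length,
            bulges=bulges,
            ecs_offset=loop_len + stem_length - stem_length // 2,
        )
        seq, truth_loc = generate_duplex_locus(spec, seed=int(rng.integers(2**31)))
        site_id = f"s{g:03d}"
        site = EditingSite(CHROM, offset + truth_loc.site_index + 1, "+", gene_id, site_id)
        sites.append(site)
        loci[gene_id] = Locus(gene_id, CHROM, offset, seq, "+", truth_loc)
        duplex_specs[site_id] = spec

        effect = config.effect_sizes[g % len(config.effect_sizes)]
        n_flank = config.n_variants_per_gene
        v = 0
        if effect != 0.0:
            # disrupting variant inside the planted stem, away from the site
            # interior pairs only: terminal pairs are structurally marginal
            # and their fold boundary can shift by a base
            pair_choices = [
                (i, j)
                for (i, j) in truth_loc.pairs[2:-2]
                if abs(i - truth_loc.site_index) >= 2
            ]
            pi, pj = pair_choices[int(rng.integers(len(pair_choices)))]
            on_ecs = bool(rng.random() < 0.4)
            vpos_local, partner_local = (pj, pi) if on_ecs else (pi, pj)
            var_id = f"{gene_id}_v{v:02d}"
            variant_rows.append(
                {
                    "variant_id": var_id,
                    "chrom": CHROM,
                    "pos": offset + vpos_local + 1,
                    "gene_id": gene_id,
                    "ref": seq[vpos_local],
                    "alt": _disrupting_alt(seq, vpos_local, seq[partner_local], rng),
                }
            )
            qtl_assignments[var_id] = (site_id, effect)
            disrupting.add(var_id)
            v += 1
            n_flank -= 1
        # one neutral within-duplex variant (a structural control: no effect)
        span_lo = truth_loc.edit_interval[0] - 10
        span_hi = truth_loc.ecs_interval[1] + 10
        if n_flank >= 2:
            used = {truth_loc.site_index} | {
                int(r["pos"]) - offset - 1 for r in variant_rows if r["gene_id"] == gene_id
            }
            duplex_positions = [
                p
                for iv in (truth_loc.edit_interval, truth_loc.ecs_interval)
                for p in range(iv[0] + 2, iv[1] - 2)
                if p not in used
            ]
            p = duplex_positions[int(rng.integers(len(duplex_positions)))]
            ref = seq[p]
            variant_rows.append(
                {
                    "variant_id": f"{gene_id}_v{v:02d}",
                    "chrom": CHROM,
                    "pos": offset + p + 1,
                    "gene_id": gene_id,
                    "ref": ref,
                    "alt": str(rng.choice([b for b in "ACGT" if b != ref])),
                }
            )
            v += 1
            n_flank -= 1
        # flank variants (outside the duplex span)
        flank_positions = [p for p in range(len(seq)) if not span_lo <= p < span_hi]
        chosen = rng.choice(len(flank_positions), size=n_flank, replace=False)
        for c in sorted(chosen):
            p = flank_positions[int(c)]
            ref = seq[p]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            variant_rows.append(
                {
                    "variant_id": f"{gene_id}_v{v:02d}",
                    "chrom": CHROM,
                    "pos": offset + p + 1,
                    "gene_id": gene_id,
                    "ref": ref,
                    "alt": alt,
                }
            )
            v += 1

    genotypes = generate_genotypes(config, pd.DataFrame(variant_rows))
    truth = PlantedTruth(qtl_assignments, duplex_specs, disrupting, sites)
    levels = generate_editing_levels(genotypes, truth, config)
    counts = generate_read_counts(levels, config)
    return SyntheticDataset(config, genotypes, truth, sites, loci, levels, counts)


def chromosome_sequence(loci: Dict[str, Locus]) -> str:
    """Assemble the synthetic chromosome (loci at their offsets, N-filled gaps)."""
    end = max(l.offset + len(l.sequence) for l in loci.values())
    buf = ["N"] * end
    for loc in loci.values():
        buf[loc.offset : loc.offset + len(loc.sequence)] = loc.sequence
    return "".join(buf)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Dict[str, Path]:
    """Write the dataset as VCF / FASTA / BED / TSV / truth JSON.

    Files round-trip through the package readers with value equality.
    """
    from . import io as eio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "fasta": outdir / "genome.fasta",
        "bed": outdir / "sites.bed",
        "counts": outdir / "counts.tsv",
        "levels": outdir / "levels.tsv",
        "genes": outdir / "genes.tsv",
        "truth": outdir / "truth.json",
    }
    eio.write_vcf(dataset.genotypes, paths["vcf"])
    eio.write_fasta({CHROM: chromosome_sequence(dataset.loci)}, paths["fasta"])
    eio.write_sites_bed(dataset.sites, paths["bed"])
    eio.write_counts_tsv(dataset.counts, paths["counts"])
    eio.write_editing_matrix(dataset.levels, paths["levels"])
    eio.write_genes_tsv(
        pd.DataFrame(
            [
                {
                    "gene_id": l.gene_id,
                    "chrom": l.chrom,
                    "start": l.offset,
                    "end": l.offset + len(l.sequence),
                    "strand": l.strand,
                }
                for l in dataset.loci.values()
            ]
        ),
        paths["genes"],
    )
    truth_json = {
        "qtl_assignments": {
            v: {"site_id": s, "effect": e}
            for v, (s, e) in dataset.truth.qtl_assignments.items()
        },
        "disrupting_variants": sorted(dataset.truth.disrupting_variants),
        "duplexes": {
            l.gene_id: {
                "site_pos": l.offset + l.truth.site_index + 1,
                "edit_interval": [l.offset + l.truth.edit_interval[0], l.offset + l.truth.edit_interval[1]],
                "ecs_interval": [l.offset + l.truth.ecs_interval[0], l.offset + l.truth.ecs_interval[1]],
                "stem_length": l.truth.spec.stem_length,
            }
            for l in dataset.loci.values()
            if l.truth is not None
        },
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=1, sort_keys=True) + "\n")
    return paths
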