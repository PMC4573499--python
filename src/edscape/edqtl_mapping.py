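"""Editing-QTL mapping: linear-model scans, permutation calibration, FDR.

For each editing site, levels across inbred strains are rank-transformed to
standard-normal quantiles and regressed (no covariates) on the haploid-coded
genotype of every variant in the same gene.  The minimum nominal p-value over
the site's variants is calibrated by permuting strain labels, giving an
empirical p-value per site; Storey q-values control the FDR across sites.
Sites with a primary edQTL are residualized on it and rescanned for secondary
edQTLs.  Effect sizes are half the difference in mean raw editing level
between the two homozygote classes.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .editing_quant import EditingMatrix

N_PERMUTATIONS = 10_000
MIN_MINOR_STRAINS = 4  # minor allele must be present in >= this many measured strains
MIN_COMPLETE_OBS = 8
GENOME_WIDE_THRESHOLD = 1e-8  # Bonferroni-style genome-wide flag
FDR_LEVELS = (0.05, 0.10)


@dataclass
class GenotypeMatrix:
    """Biallelic variants x strains, haploid-coded (0/1, NaN = missing)."""

    variants: pd.DataFrame  # columns: variant_id, chrom, pos, gene_id, ref, alt
    strains: List[str]
    calls: np.ndarray  # shape (n_variants, n_strains)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.variants), len(self.strains)):
            raise ValueError("calls shape does not match variants x strains")
        vals = self.calls[~np.isnan(self.calls)]
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("calls must be haploid-coded 0/1 or missing")
        self.variants = self.variants.reset_index(drop=True)
        self._vidx = {v: i for i, v in enumerate(self.variants["variant_id"])}

    def variant_index(self, variant_id: str) -> int:
        return self._vidx[variant_id]

    def row(self, variant_id: str) -> np.ndarray:
        return self.calls[self.variant_index(variant_id)]

    def gene_variant_indices(self, gene_id: str) -> np.ndarray:
        return np.flatnonzero((self.variants["gene_id"] == gene_id).to_numpy())


@dataclass
class AssociationResult:
    site_id: str
    variant_id: str
    beta: float
    p: float
    n: int
    genome_wide: bool = False


@dataclass
class EdQTL:
    site_id: str
    variant_id: str
    p_min: float
    p_empirical: float
    q: float
    rank: str  # "primary" or "secondary"
    effect_size: float
    distance_to_site: Optional[int] = None
    beta: float = float("nan")


def normalize_editing_levels(values: np.ndarray) -> Optional[np.ndarray]:
    """Rank-based inverse-normal transform of a per-site level vector.

    Non-missing values are ranked (ties get the average rank) and mapped to
    standard-normal quantiles Phi^-1((rank - 0.5) / n); missing entries stay
    missing.  Returns None (with a warning) for fewer than two values or zero
    variance, in which case the site is skipped.
    """
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values)
    v = values[mask]
    if len(v) < 2 or np.nanstd(v) == 0:
        warnings.warn("site skipped: fewer than 2 values or zero variance")
        return None
    ranks = stats.rankdata(v, method="average")
    out = np.full_like(values, np.nan)
    out[mask] = stats.norm.ppf((ranks - 0.5) / len(v))
    return out


def _ols_slope_p(g: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Closed-form simple-regression slope and two-sided t-test p-value."""
    n = len(g)
    gm = g - g.mean()
    ym = y - y.mean()
    sgg = float(gm @ gm)
    sgy = float(gm @ ym)
    syy = float(ym @ ym)
    beta = sgy / sgg
    df = n - 2
    resid = syy - sgy * sgy / sgg
    if resid <= 0:
        return beta, 0.0
    se = np.sqrt(resid / df / sgg)
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, float(p)


def testable_variant_indices(
    genotypes: GenotypeMatrix,
    y: np.ndarray,
    candidate_idx: np.ndarray,
    min_minor: int = MIN_MINOR_STRAINS,
    min_n: int = MIN_COMPLETE_OBS,
) -> np.ndarray:
    """Variants testable against a phenotype vector.

    Requires >= ``min_n`` strains with both genotype and level, nonzero
    genotype variance, and the minor allele present in >= ``min_minor`` of
    the strains with a level measurement.
    """
    keep = []
    for vi in candidate_idx:
        g = genotypes.calls[vi]
        both = ~np.isnan(g) & ~np.isnan(y)
        n = int(both.sum())
        if n < min_n:
            continue
        gv = g[both]
        n1 = int(gv.sum())
        minor = min(n1, n - n1)
        if minor < min_minor:
            continue
        keep.append(vi)
    return np.array(keep, dtype=int)


def cis_association_scan(
    site_id: str,
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    gene_id: Optional[str] = None,
    scope: str = "gene",
    min_minor: int = MIN_MINOR_STRAINS,
    min_n: int = MIN_COMPLETE_OBS,
    genome_threshold: float = GENOME_WIDE_THRESHOLD,
) -> List[AssociationResult]:
    """Scan variants for association with a (normalized) level vector.

    ``scope='gene'`` restricts to variants annotated to ``gene_id``;
    ``scope='genome'`` tests every variant and flags p below the
    Bonferroni-style genome-wide threshold.
    """
    if scope == "gene":
        if gene_id is None:
            raise ValueError("gene scope requires gene_id")
        candidates = genotypes.gene_variant_indices(gene_id)
    elif scope == "genome":
        candidates = np.arange(len(genotypes.variants))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    idx = testable_variant_indices(genotypes, y, candidates, min_minor, min_n)
    results = []
    for vi in idx:
        g = genotypes.calls[vi]
        both = ~np.isnan(g) & ~np.isnan(y)
        beta, p = _ols_slope_p(g[both], y[both])
        results.append(
            AssociationResult(
                site_id=site_id,
                variant_id=genotypes.variants["variant_id"].iloc[vi],
                beta=beta,
                p=p,
                n=int(both.sum()),
                genome_wide=(scope == "genome" and p < genome_threshold),
            )
        )
    return results


def site_permutation_seed(global_seed: int, site_id: str) -> int:
    """Stable per-site permutation seed derived from (global seed, site id)."""
    return (int(global_seed) * 2_654_435_761 + zlib.crc32(site_id.encode())) % (2**31)


def _min_p_for_y(G: np.ndarray, y: np.ndarray) -> float:
    """Minimum nominal p over variant rows of G (no missing values)."""
    n = len(y)
    ym = y - y.mean()
    Gm = G - G.mean(axis=1, keepdims=True)
    denom = np.sqrt((Gm**2).sum(axis=1) * float(ym @ ym))
    r = (Gm @ ym) / denom
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t2 = r**2 * df / (1.0 - r**2)
    tmax = np.sqrt(np.max(t2))
    return float(2.0 * stats.t.sf(tmax, df))


def permutation_empirical_p(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    variant_idx: np.ndarray,
    n_perm: int = N_PERMUTATIONS,
    seed: int = 0,
) -> Tuple[float, float]:
    """Empirical p for the site's best variant by strain-label permutation.

    Returns ``(p_min, p_empirical)`` with the add-one estimator
    ``(1 + #{null min-p <= p_min}) / (1 + n_perm)``; ties count as <=
    (conservative).  The variant set is fixed across permutations.
    """
    if len(variant_idx) == 0:
        raise ValueError("site has no testable variants")
    rng = np.random.default_rng(seed)
    G = genotypes.calls[variant_idx]
    mask = ~np.isnan(y)
    yv = y[mask]
    Gv = G[:, mask]
    if not np.isnan(Gv).any():
        p_min = _min_p_for_y(Gv, yv)
        count = 0
        for _ in range(n_perm):
            yp = yv[rng.permutation(len(yv))]
            if _min_p_for_y(Gv, yp) <= p_min:
                count += 1
    else:
        # missing genotypes: per-variant complete-case scan, permuting labels
        def min_p(yy: np.ndarray) -> float:
            best = 1.0
            for row in Gv:
                both = ~np.isnan(row)
                if both.sum() < MIN_COMPLETE_OBS or np.nanstd(row[both]) == 0:
                    continue
                _, p = _ols_slope_p(row[both], yy[both])
                best = min(best, p)
            return best

        p_min = min_p(yv)
        count = 0
        for _ in range(n_perm):
            yp = yv[rng.permutation(len(yv))]
            if min_p(yp) <= p_min:
                count += 1
    return p_min, (1 + count) / (1 + n_perm)


def qvalue_fdr(
    p_values: Sequence[float], pi0: Optional[float] = None, lambda_: float = 0.5
) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single lambda.

    ``pi0 = #{p > lambda} / ((1 - lambda) m)`` clipped to ``[1/m, 1]``;
    forcing ``pi0=1`` reproduces Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = np.sum(p > lambda_) / ((1 - lambda_) * m)
        pi0 = min(1.0, max(1.0 / m, pi0))
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pi0 * m * p[i] / rank)
        q[i] = val
        prev = val
    return q


def effect_size(raw_levels: np.ndarray, genotype: np.ndarray) -> float:
    """Half the difference in mean raw editing level between homozygote classes."""
    raw_levels = np.asarray(raw_levels, dtype=float)
    genotype = np.asarray(genotype, dtype=float)
    both = ~np.isnan(raw_levels) & ~np.isnan(genotype)
    g0 = raw_levels[both & (genotype == 0)]
    g1 = raw_levels[both & (genotype == 1)]
    if len(g0) == 0 or len(g1) == 0:
        return float("nan")
    return abs(float(np.mean(g1)) - float(np.mean(g0))) / 2.0


def regress_out(y: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Residuals of y on g (with intercept); exactly orthogonal to g.

    Missing entries in either vector propagate to the residuals.
    """
    both = ~np.isnan(y) & ~np.isnan(g)
    yv, gv = y[both], g[both]
    gm = gv - gv.mean()
    beta = float(gm @ (yv - yv.mean())) / float(gm @ gm)
    out = np.full_like(y, np.nan)
    out[both] = (yv - yv.mean()) - beta * gm
    return out


def signed_distance(site_pos: int, site_strand: str, variant_pos: int) -> int:
    """Genomic distance in transcription orientation (downstream positive)."""
    d = variant_pos - site_pos
    return d if site_strand == "+" else -d


@dataclass
class MappingResult:
    edqtls: List[EdQTL]
    per_site: pd.DataFrame  # site_id, rank, p_min, p_empirical, q, variant_id

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site_id": e.site_id,
                    "variant_id": e.variant_id,
                    "rank": e.rank,
                    "beta": e.beta,
                    "p_min": e.p_min,
                    "p_empirical": e.p_empirical,
                    "q": e.q,
                    "effect_size": e.effect_size,
                    "distance_to_site": e.distance_to_site,
                }
                for e in self.edqtls
            ]
        )


def _scan_stage(
    matrix: EditingMatrix,
    genotypes: GenotypeMatrix,
    phenotypes: Dict[str, np.ndarray],
    n_perm: int,
    seed: int,
    stage: str,
    exclude: Optional[Dict[str, set]] = None,
) -> pd.DataFrame:
    """One scan+permutation pass over sites; returns per-site best-variant table."""
    rows = []
    for site in matrix.sites:
        y = phenotypes.get(site.site_id)
        if y is None:
            continue
        candidates = genotypes.gene_variant_indices(site.gene_id)
        if exclude and site.site_id in exclude:
            drop = exclude[site.site_id]
            candidates = np.array(
                [
                    vi
                    for vi in candidates
                    if genotypes.variants["variant_id"].iloc[vi] not in drop
                ],
                dtype=int,
            )
        idx = testable_variant_indices(genotypes, y, candidates)
        if len(idx) == 0:
            continue
        results = cis_association_scan(site.site_id, y, genotypes, site.gene_id)
        if exclude and site.site_id in exclude:
            results = [r for r in results if r.variant_id not in exclude[site.site_id]]
        if not results:
            continue
        best = min(results, key=lambda r: r.p)
        p_min, p_emp = permutation_empirical_p(
            y,
            genotypes,
            idx,
            n_perm=n_perm,
            seed=site_permutation_seed(seed, stage + ":" + site.site_id),
        )
        rows.append(
            {
                "site_id": site.site_id,
                "variant_id": best.variant_id,
                "beta": best.beta,
                "p_min": p_min,
                "p_empirical": p_emp,
            }
        )
    return pd.DataFrame(rows)


def map_edqtls(
    matrix: EditingMatrix,
    genotypes: GenotypeMatrix,
    n_perm: int = N_PERMUTATIONS,
    seed: int = 0,
    fdr: float = 0.10,
) -> MappingResult:
    """Full two-stage edQTL mapping over an editing matrix.

    Primary pass: per site, normalize levels, scan same-gene variants,
    permutation-calibrate the best variant, q-values across sites, call
    primaries at ``q < fdr``.  Secondary pass: residualize each primary
    site's levels on its primary genotype, exclude the primary variant and
    perfect proxies (r^2 = 1), and repeat.
    """
    phenotypes: Dict[str, np.ndarray] = {}
    for i, site in enumerate(matrix.sites):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            yn = normalize_editing_levels(matrix.level[i])
        if yn is not None:
            phenotypes[site.site_id] = yn

    primary_tbl = _scan_stage(matrix, genotypes, phenotypes, n_perm, seed, "primary")
    edqtls: List[EdQTL] = []
    if primary_tbl.empty:
        return MappingResult([], primary_tbl)
    primary_tbl["q"] = qvalue_fdr(primary_tbl["p_empirical"].to_numpy())
    primary_tbl["rank"] = "primary"

    primaries: Dict[str, str] = {}
    for _, row in primary_tbl.iterrows():
        site = matrix.sites[matrix.site_index(row["site_id"])]
        g = genotypes.row(row["variant_id"])
        vpos = int(
            genotypes.variants.set_index("variant_id").loc[row["variant_id"], "pos"]
        )
        eff = effect_size(matrix.level[matrix.site_index(row["site_id"])], g)
        if row["q"] < fdr:
            primaries[row["site_id"]] = row["variant_id"]
            edqtls.append(
                EdQTL(
                    site_id=row["site_id"],
                    variant_id=row["variant_id"],
                    p_min=row["p_min"],
                    p_empirical=row["p_empirical"],
                    q=row["q"],
                    rank="primary",
                    effect_size=eff,
                    distance_to_site=signed_distance(site.pos, site.strand, vpos),
                    beta=row["beta"],
                )
            )

    # secondary pass on sites with a primary
    residuals: Dict[str, np.ndarray] = {}
    exclude: Dict[str, set] = {}
    for site_id, var_id in primaries.items():
        y = phenotypes[site_id]
        g = genotypes.row(var_id)
        both = ~np.isnan(y) & ~np.isnan(g)
        if np.nanstd(g[both]) == 0:
            continue
        residuals[site_id] = regress_out(y, g)
        # exclude the primary variant and perfect proxies (r^2 = 1)
        drop = {var_id}
        site = matrix.sites[matrix.site_index(site_id)]
        for vi in genotypes.gene_variant_indices(site.gene_id):
            other = genotypes.calls[vi]
            ok = ~np.isnan(g) & ~np.isnan(other)
            if ok.sum() >= 2 and np.std(other[ok]) > 0 and np.std(g[ok]) > 0:
                r = np.corrcoef(g[ok], other[ok])[0, 1]
                if r * r >= 1.0 - 1e-12:
                    drop.add(genotypes.variants["variant_id"].iloc[vi])
        exclude[site_id] = drop

    sec_sites = [s for s in matrix.sites if s.site_id in residuals]
    sec_matrix = EditingMatrix(
        sec_sites,
        matrix.strains,
        np.array([matrix.level[matrix.site_index(s.site_id)] for s in sec_sites])
        if sec_sites
        else np.empty((0, len(matrix.strains))),
    )
    sec_tbl = _scan_stage(
        sec_matrix, genotypes, residuals, n_perm, seed, "secondary", exclude
    )
    if not sec_tbl.empty:
        sec_tbl["q"] = qvalue_fdr(sec_tbl["p_empirical"].to_numpy())
        sec_tbl["rank"] = "secondary"
        for _, row in sec_tbl.iterrows():
            if row["q"] >= fdr:
                continue
            site = matrix.sites[matrix.site_index(row["site_id"])]
            g = genotypes.row(row["variant_id"])
            vpos = int(
                genotypes.variants.set_index("variant_id").loc[row["variant_id"], "pos"]
            )
            eff = effect_size(matrix.level[matrix.site_index(row["site_id"])], g)
            edqtls.append(
                EdQTL(
                    site_id=row["site_id"],
                    variant_id=row["variant_id"],
                    p_min=row["p_min"],
                    p_empirical=row["p_empirical"],
                    q=row["q"],
                    rank="secondary",
                    effect_size=eff,
                    distance_to_site=signed_distance(site.pos, site.strand, vpos),
                    beta=row["beta"],
                )
            )
    per_site = pd.concat(
        [primary_tbl, sec_tbl] if not sec_tbl.empty else [primary_tbl],
        ignore_index=True,
    )
    return MappingResult(edqtls, per_site)


DISTANCE_BINS = ((0, 1_000, "<1kb"), (1_000, 10_000, "1-10kb"), (10_000, 50_000, "10-50kb"))


def shared_site_association(
    edqtls: Sequence[EdQTL],
    matrix: EditingMatrix,
    genotypes: GenotypeMatrix,
) -> pd.DataFrame:
    """Associations of each edQTL with every other same-gene editing site.

    Rows carry the nominal p and a distance stratum (<1 kb, 1-10 kb,
    10-50 kb) measured from the edQTL's original site to the other site.
    """
    site_by_id = {s.site_id: s for s in matrix.sites}
    rows = []
    for e in edqtls:
        origin = site_by_id[e.site_id]
        g = genotypes.row(e.variant_id)
        for j, other in enumerate(matrix.sites):
            if other.site_id == e.site_id or other.gene_id != origin.gene_id:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                y = normalize_editing_levels(matrix.level[j])
            if y is None:
                continue
            both = ~np.isnan(y) & ~np.isnan(g)
            if both.sum() < MIN_COMPLETE_OBS or np.std(g[both]) == 0:
                continue
            beta, p = _ols_slope_p(g[both], y[both])
            dist = abs(other.pos - origin.pos)
            label = None
            for lo, hi, name in DISTANCE_BINS:
                if lo <= dist < hi:
                    label = name
                    break
            rows.append(
                {
                    "variant_id": e.variant_id,
                    "origin_site": e.site_id,
                    "other_site": other.site_id,
                    "beta": beta,
                    "p": p,
                    "distance": dist,
                    "distance_bin": label,
                }
            )
    return pd.DataFrame(rows)
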