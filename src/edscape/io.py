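"""Readers and writers for the external formats the pipeline consumes.

Conventions: BED stays 0-based half-open; every other human-facing table
uses 1-based positions.  TSV outputs carry a single ``#`` header line with
the stage name, a configuration hash and the seed, so identical runs are
byte-identical; readers skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .editing_quant import EditingMatrix, EditingSite
from .edqtl_mapping import GenotypeMatrix


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.start}..{self.end}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf_genotypes(
    path: str | Path, genes: Optional[pd.DataFrame] = None
) -> Tuple[GenotypeMatrix, Dict[str, int]]:
    """Read biallelic SNV genotypes from a VCF, haploid-coding inbred calls.

    0/0 -> 0, 1/1 -> 1, heterozygous or missing -> NaN; multi-allelic and
    indel records are skipped (counts returned).  ``genes`` (gene_id, chrom,
    start, end) assigns each variant a gene by interval containment.
    Returns (matrix, skip counters).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # 0 HOM_REF, 1 HET, 2 HOM_ALT, 3 UNKNOWN
    strains = list(vcf.samples)
    rows = []
    calls = []
    skipped = {"multiallelic": 0, "indel": 0}
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped["indel"] += 1
            continue
        gt = rec.gt_types  # 0 HOM_REF, 1 HET, 2 HOM_ALT, 3 UNKNOWN
        coded = np.where(gt == 0, 0.0, np.where(gt == 2, 1.0, np.nan))
        rows.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}_{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "gene_id": "",
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        calls.append(coded)
    vcf.close()
    table = pd.DataFrame(rows)
    if genes is not None and not table.empty:
        table["gene_id"] = assign_genes_to_positions(
            table["chrom"], table["pos"] - 1, genes
        )
    matrix = GenotypeMatrix(
        table, strains, np.vstack(calls) if calls else np.empty((0, len(strains)))
    )
    return matrix, skipped


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write haploid-coded genotypes as a VCF v4.2 with GT calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(genotypes.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.strains)
            + "\n"
        )
        for i, row in genotypes.variants.iterrows():
            gts = []
            for v in genotypes.calls[i]:
                if np.isnan(v):
                    gts.append("./.")
                else:
                    gts.append("0/0" if v == 0 else "1/1")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA / BED / TSV
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_sites_bed(path: str | Path) -> List[EditingSite]:
    """Read editing sites from BED6 (single-base intervals, strand required)."""
    sites = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: BED6 requires 6 columns (strand missing?)")
            chrom, start, end, name, _score, strand = f[:6]
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            if end - start != 1:
                raise ValueError(f"{path}:{ln}: editing sites are single bases")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{ln}: invalid strand {strand!r}")
            sites.append(EditingSite(chrom, start + 1, strand, "unknown", name))
    return sites


def write_sites_bed(sites: Sequence[EditingSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.site_id}\t0\t{s.strand}\n")


def assign_genes_to_positions(
    chroms: Sequence[str], pos0: Sequence[int], genes: pd.DataFrame
) -> List[str]:
    """Gene id per position by interval containment ('' when none)."""
    out = []
    for c, p in zip(chroms, pos0):
        hit = genes[(genes["chrom"] == c) & (genes["start"] <= p) & (p < genes["end"])]
        out.append(hit["gene_id"].iloc[0] if len(hit) else "")
    return out


def assign_genes_to_sites(
    sites: Sequence[EditingSite], genes: pd.DataFrame
) -> List[EditingSite]:
    ids = assign_genes_to_positions(
        [s.chrom for s in sites], [s.pos - 1 for s in sites], genes
    )
    return [
        EditingSite(s.chrom, s.pos, s.strand, g or "unknown", s.site_id)
        for s, g in zip(sites, ids)
    ]


def read_genes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"genes table needs columns {sorted(required)}")
    if (df["start"] >= df["end"]).any():
        raise ValueError("gene interval with start >= end")
    return df


def write_genes_tsv(genes: pd.DataFrame, path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        genes.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"site_id", "strain", "replicate", "g_count", "total_count"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        counts.to_csv(fh, sep="\t", index=False)


def write_editing_matrix(
    matrix: EditingMatrix, path: str | Path, header: str = ""
) -> None:
    meta = pd.DataFrame(
        {
            "site_id": [s.site_id for s in matrix.sites],
            "chrom": [s.chrom for s in matrix.sites],
            "pos": [s.pos for s in matrix.sites],
            "strand": [s.strand for s in matrix.sites],
            "gene_id": [s.gene_id for s in matrix.sites],
        }
    )
    levels = pd.DataFrame(
        np.round(matrix.level, 6), columns=matrix.strains
    )
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        pd.concat([meta, levels], axis=1).to_csv(fh, sep="\t", index=False)


def read_editing_matrix(path: str | Path) -> EditingMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    meta_cols = ["site_id", "chrom", "pos", "strand", "gene_id"]
    strains = [c for c in df.columns if c not in meta_cols]
    sites = [
        EditingSite(r["chrom"], int(r["pos"]), r["strand"], r["gene_id"], r["site_id"])
        for _, r in df.iterrows()
    ]
    return EditingMatrix(sites, strains, df[strains].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# conservation tracks
# ---------------------------------------------------------------------------


def read_conservation(
    path: str | Path, contig_lengths: Dict[str, int]
) -> Dict[str, np.ndarray]:
    """Read a bedGraph (4-column) or fixed-step wiggle conservation track.

    Returns a dense per-base array per chromosome (unscored positions 0).
    """
    tracks = {c: np.zeros(n) for c, n in contig_lengths.items()}
    with open(path) as fh:
        first = True
        mode = "bedgraph"
        chrom, pos, step = None, 0, 1
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                mode = "wig"
                kv = dict(tok.split("=") for tok in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                continue
            if mode == "wig":
                if chrom in tracks and 0 <= pos < len(tracks[chrom]):
                    tracks[chrom][pos] = float(line)
                pos += step
            else:
                c, s, e, v = line.split("\t")[:4]
                if c in tracks:
                    tracks[c][int(s) : int(e)] = float(v)
            first = False
    return tracks


def write_bedgraph(tracks: Dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, arr in tracks.items():
            start = 0
            for i in range(1, len(arr) + 1):
                if i == len(arr) or arr[i] != arr[start]:
                    if arr[start] != 0:
                        fh.write(f"{chrom}\t{start}\t{i}\t{arr[start]:g}\n")
                    start = i


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All stage parameters and input paths for an end-to-end run."""

    # inputs
    counts: str = ""
    sites_bed: str = ""
    genes: str = ""
    vcf: str = ""
    fasta: str = ""
    conservation: str = ""  # optional; required for the distal ECS approach
    outdir: str = "edscape_out"
    # quantification
    min_coverage: int = 50
    min_strains: int = 35
    max_replicate_diff: float = 0.20
    # mapping
    n_perm: int = 10_000
    fdr: float = 0.10
    fdr_levels: Tuple[float, float] = (0.05, 0.10)
    min_minor_strains: int = 4
    # structure / ECS
    window: int = 200
    min_stem_pairs: int = 20
    max_bulge: int = 8
    cons_window: int = 51
    cons_min_score: float = 0.90
    cons_min_length: int = 20
    cons_max_distance: int = 2_500
    distal_buffer: int = 30
    distal_site_flank: int = 60
    linker: int = 100
    effect_size_gate: float = 0.025
    ld_r2_max: float = 0.05
    seed: int = 0

    _PATH_FIELDS = ("counts", "sites_bed", "genes", "vcf", "fasta", "conservation", "outdir")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so identical
        analyses of the same data hash equal wherever they are run)."""
        params = {k: v for k, v in asdict(self).items() if k not in self._PATH_FIELDS}
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def header(self, stage: str) -> str:
        return f"# edscape {stage} config_hash={self.config_hash()} seed={self.seed}\n"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fdr_levels" in data:
            data["fdr_levels"] = tuple(data["fdr_levels"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["fdr_levels"] = list(data["fdr_levels"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
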