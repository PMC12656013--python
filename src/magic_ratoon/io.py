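"""Readers and writers for the pipeline's on-disk formats.

VCF 4.2 (GT and DP per sample; QD, MQ, FS site INFO), GFF3 gene models with
CDS features, and the tab-separated phenotype table with columns
``line_id, season, replicate, batch, TN, PL, SPP, GY``.

Reading goes through :mod:`cyvcf2` and :mod:`gffutils`; writing emits plain
text so synthetic bundles stay diff-able and round-trip losslessly through
the readers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENO_COLUMNS = ["line_id", "season", "replicate", "batch", "TN", "PL", "SPP", "GY"]

_VCF_HEADER_LINES = [
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant Confidence/Quality by Depth">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS Mapping Quality">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled p-value using Fisher\'s exact test to detect strand bias">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Approximate read depth">',
]


@dataclass
class VariantTable:
    """In-memory biallelic variant matrix as read from a VCF.

    Attributes
    ----------
    samples : list of str
    sites : DataFrame with columns chrom, pos, ref, alt, qd, mq, fs
        INFO fields absent from the file are NaN.
    gt : int8 array, shape (n_sites, n_samples, 2)
        Allele indexes; ``-1`` marks a missing call.
    dp : float array, shape (n_sites, n_samples)
        Per-genotype depth, NaN when the FORMAT lacks DP.
    """

    samples: list[str]
    sites: pd.DataFrame
    gt: np.ndarray
    dp: np.ndarray = field(repr=False, default=None)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage (n_sites, n_samples) with NaN for missing calls."""
        d = self.gt.sum(axis=2).astype(float)
        d[(self.gt < 0).any(axis=2)] = np.nan
        return d

    def het_mask(self) -> np.ndarray:
        """Boolean (n_sites, n_samples): called and heterozygous."""
        called = (self.gt >= 0).all(axis=2)
        return called & (self.gt[:, :, 0] != self.gt[:, :, 1])

    def site_keys(self) -> list[tuple]:
        return list(
            zip(self.sites["chrom"], self.sites["pos"], self.sites["ref"], self.sites["alt"])
        )


def read_vcf(path: str | os.PathLike) -> VariantTable:
    """Load a (possibly bgzipped) VCF into a :class:`VariantTable`.

    Multi-allelic records are split into per-ALT pseudo-sites: alleles other
    than the focal ALT are recoded as REF so every pseudo-site is biallelic,
    matching the downstream biallelic association tests.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, gts, dps = [], [], []
    for v in vcf:
        geno = np.asarray(
            [g[:2] for g in (v.genotypes or [])], dtype=np.int8
        ).reshape(len(samples), 2)
        try:
            dp = np.asarray(v.format("DP"), dtype=float).reshape(-1)[: len(samples)]
        except (TypeError, KeyError):
            dp = np.full(len(samples), np.nan)
        if dp.shape != (len(samples),):
            dp = np.full(len(samples), np.nan)
        dp = np.where(dp < 0, np.nan, dp)
        info = {k.lower(): v.INFO.get(k) for k in ("QD", "MQ", "FS")}
        for ai, alt in enumerate(v.ALT, start=1):
            g = geno.copy()
            g[(g > 0) & (g != ai)] = 0  # other ALTs folded into REF
            g[g == ai] = 1
            rows.append((v.CHROM, v.POS, v.REF, alt, info["qd"], info["mq"], info["fs"]))
            gts.append(g)
            dps.append(dp)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qd", "mq", "fs"])
    sites[["qd", "mq", "fs"]] = sites[["qd", "mq", "fs"]].astype(float)
    n = len(rows)
    gt = np.asarray(gts, dtype=np.int8).reshape(n, len(samples), 2)
    dparr = np.asarray(dps, dtype=float).reshape(n, len(samples))
    return VariantTable(samples=samples, sites=sites, gt=gt, dp=dparr)


def write_vcf(
    path: str | os.PathLike,
    sites: pd.DataFrame,
    gt: np.ndarray,
    samples: list[str],
    dp: np.ndarray | None = None,
    contigs: list[tuple[str, int]] | None = None,
) -> str:
    """Write a VCF 4.2 text file.

    Parameters mirror :class:`VariantTable`; ``sites`` needs columns
    chrom/pos/ref/alt and optionally qd/mq/fs (NaN values are omitted from
    INFO).
    """
    path = str(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=magic-ratoon\n")
        if contigs:
            for name, length in contigs:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if samples:
            cols += "\tFORMAT\t" + "\t".join(samples)
        fh.write(cols + "\n")
        has_info = {k: k in sites.columns for k in ("qd", "mq", "fs")}
        for i, row in enumerate(sites.itertuples(index=False)):
            info_parts = []
            for key, tag in (("qd", "QD"), ("mq", "MQ"), ("fs", "FS")):
                if has_info[key]:
                    val = getattr(row, key)
                    if val is not None and np.isfinite(val):
                        info_parts.append(f"{tag}={val:.2f}")
            info = ";".join(info_parts) if info_parts else "."
            if not samples:
                fh.write(
                    f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\n"
                )
                continue
            cells = []
            for j in range(len(samples)):
                a1, a2 = int(gt[i, j, 0]), int(gt[i, j, 1])
                g = "./." if a1 < 0 or a2 < 0 else f"{min(a1, a2)}/{max(a1, a2)}"
                if dp is not None and np.isfinite(dp[i, j]):
                    g += f":{int(dp[i, j])}"
                else:
                    g += ":."
                cells.append(g)
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )
    return path


def write_gff3(path: str | os.PathLike, genes) -> str:
    """Write gene/mRNA/CDS features (1-based inclusive) for a list of
    :class:`~magic_ratoon.haplotypes.GeneModel`."""
    path = str(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start = min(s for s, _ in g.cds_intervals)
            end = max(e for _, e in g.cds_intervals)
            fh.write(
                f"{g.chrom}\tmagic_ratoon\tgene\t{start}\t{end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tmagic_ratoon\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.cds_intervals, start=1):
                fh.write(
                    f"{g.chrom}\tmagic_ratoon\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{k};Parent={mrna}\n"
                )
    return path


def read_gff3(path: str | os.PathLike):
    """Parse gene models (gene features with CDS descendants) from a GFF3."""
    import gffutils

    from .haplotypes import GeneModel

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        cds = sorted(
            (c.start, c.end) for c in db.children(g, featuretype="CDS")
        )
        if not cds:
            continue
        tss = min(s for s, _ in cds) if g.strand != "-" else max(e for _, e in cds)
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand if g.strand in "+-" else "+",
                cds_intervals=cds,
                tss=tss,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.cds_intervals[0][0]))
    return genes


def write_phenotypes(path: str | os.PathLike, frame: pd.DataFrame) -> str:
    missing = [c for c in PHENO_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    frame[PHENO_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")
    return str(path)


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENO_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    return frame
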