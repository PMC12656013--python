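"""QTL calling and results tables.

Significant markers from the SNP scan and the gene scan are clustered per
chromosome by single-linkage within a merge window (default 500 kb, a
reporting convention — the clustering rule is not part of the association
model).  SNP and gene clusters whose peaks lie within the window are
reported as one QTL carrying both peaks; names follow the
``q<TRAIT><chrom>[.index]`` convention with sub-indexes assigned in
genomic order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class QTLRecord:
    name: str
    trait: str
    season: str                       # MC / RC / RA
    chrom: str
    snp_pos: int | None = None
    snp_p: float | None = None
    snp_pve: float | None = None
    gene_id: str | None = None
    gene_pos: int | None = None
    gene_p: float | None = None
    gene_pve: float | None = None
    nearby_gene: str | None = None
    nearby_distance_bp: int | None = None
    members: dict = field(default_factory=dict, repr=False)

    @property
    def peak_pos(self) -> int:
        if self.gene_pos is not None and (self.snp_p is None or (self.gene_p or 1) < (self.snp_p or 1)):
            return self.gene_pos
        return self.snp_pos if self.snp_pos is not None else self.gene_pos


def _clusters(positions: np.ndarray, window: int) -> list[np.ndarray]:
    """Single-linkage clusters of sorted genomic positions."""
    if len(positions) == 0:
        return []
    order = np.argsort(positions)
    groups = [[order[0]]]
    for idx in order[1:]:
        if positions[idx] - positions[groups[-1][-1]] <= window:
            groups[-1].append(idx)
        else:
            groups.append([idx])
    return [np.asarray(g) for g in groups]


def _chrom_number(chrom: str) -> str:
    m = re.search(r"(\d+)", str(chrom))
    return str(int(m.group(1))) if m else str(chrom)


def call_qtls(
    snp_records: pd.DataFrame | None,
    gene_records: pd.DataFrame | None,
    thresholds: dict,
    merge_window_bp: int = 500_000,
    trait: str = "trait",
    season: str = "MC",
) -> list[QTLRecord]:
    """Cluster one trait-season's significant markers into QTLs.

    ``thresholds`` maps 'snp' and 'gene' to their significance cutoffs.
    Gene records need a ``pos`` column (peak-gene position).  Returns
    unnamed records (``name`` filled by :func:`name_qtls`, which needs every
    season of a trait to assign sub-indexes in genomic order).
    """
    snp_records = snp_records if snp_records is not None else pd.DataFrame(columns=["chrom", "pos", "p", "pve"])
    gene_records = gene_records if gene_records is not None else pd.DataFrame(columns=["gene_id", "chrom", "pos", "p", "pve"])
    sig_snp = snp_records[snp_records["p"] < thresholds.get("snp", 0)].copy()
    sig_gene = gene_records[gene_records["p"] < thresholds.get("gene", 0)].copy()
    out: list[QTLRecord] = []
    for chrom in sorted(set(sig_snp.get("chrom", pd.Series(dtype=object))) | set(sig_gene.get("chrom", pd.Series(dtype=object)))):
        s = sig_snp[sig_snp["chrom"] == chrom].reset_index(drop=True)
        g = sig_gene[sig_gene["chrom"] == chrom].reset_index(drop=True)
        s_clusters = _clusters(s["pos"].to_numpy(float), merge_window_bp)
        g_clusters = _clusters(g["pos"].to_numpy(float), merge_window_bp)
        s_peaks = []
        for idx in s_clusters:
            block = s.iloc[idx]
            s_peaks.append(block.loc[block["p"].idxmin()])
        g_peaks = []
        for idx in g_clusters:
            block = g.iloc[idx]
            g_peaks.append(block.loc[block["p"].idxmin()])
        used_g = set()
        for sp in s_peaks:
            rec = QTLRecord(
                name="",
                trait=trait,
                season=season,
                chrom=str(chrom),
                snp_pos=int(sp["pos"]),
                snp_p=float(sp["p"]),
                snp_pve=float(sp.get("pve", np.nan)),
            )
            for gi, gp in enumerate(g_peaks):
                if gi in used_g:
                    continue
                if abs(int(gp["pos"]) - int(sp["pos"])) <= merge_window_bp:
                    rec.gene_id = str(gp["gene_id"])
                    rec.gene_pos = int(gp["pos"])
                    rec.gene_p = float(gp["p"])
                    rec.gene_pve = float(gp.get("pve", np.nan))
                    used_g.add(gi)
                    break
            out.append(rec)
        for gi, gp in enumerate(g_peaks):
            if gi in used_g:
                continue
            out.append(
                QTLRecord(
                    name="",
                    trait=trait,
                    season=season,
                    chrom=str(chrom),
                    gene_id=str(gp["gene_id"]),
                    gene_pos=int(gp["pos"]),
                    gene_p=float(gp["p"]),
                    gene_pve=float(gp.get("pve", np.nan)),
                )
            )
    return out


def name_qtls(qtls: list[QTLRecord]) -> list[QTLRecord]:
    """Assign q<TRAIT><chrom>[.i] names; sub-indexes in ascending genomic
    order within each trait-chromosome (across seasons)."""
    by_key: dict[tuple, list[QTLRecord]] = {}
    for q in qtls:
        by_key.setdefault((q.trait, q.chrom), []).append(q)
    for (trait, chrom), group in by_key.items():
        group.sort(key=lambda q: q.peak_pos)
        for i, q in enumerate(group, start=1):
            base = f"q{trait}{_chrom_number(chrom)}"
            q.name = base if len(group) == 1 else f"{base}.{i}"
    return qtls


def nearest_annotation(qtl: QTLRecord, landmarks: pd.DataFrame) -> QTLRecord:
    """Annotate a QTL with the nearest landmark gene from a BED frame
    (columns chrom, start, end, name; 0-based half-open).

    The signed distance runs from the peak (gene peak preferred, else SNP
    peak) to the interval: 0 inside, negative upstream of the interval
    start, positive past the end.  An empty BED leaves the record
    unannotated.
    """
    if landmarks is None or len(landmarks) == 0:
        return qtl
    pos = qtl.gene_pos if qtl.gene_pos is not None else qtl.snp_pos
    sub = landmarks[landmarks["chrom"].astype(str) == qtl.chrom]
    if len(sub) == 0:
        return qtl
    best, best_d = None, None
    for row in sub.itertuples(index=False):
        start1 = int(row.start) + 1  # BED -> 1-based inclusive
        end1 = int(row.end)
        if start1 <= pos <= end1:
            d = 0
        elif pos < start1:
            d = pos - start1  # negative: peak upstream of landmark
        else:
            d = pos - end1
        if best_d is None or abs(d) < abs(best_d):
            best, best_d = row, d
    qtl.nearby_gene = str(getattr(best, "name", ""))
    qtl.nearby_distance_bp = int(best_d)
    return qtl


def read_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    bed = bed.iloc[:, :4]
    bed.columns = ["chrom", "start", "end", "name"][: bed.shape[1]]
    if "name" not in bed.columns:
        bed["name"] = [f"feature{i}" for i in range(len(bed))]
    return bed


def qtl_table(qtls: list[QTLRecord]) -> pd.DataFrame:
    """Results-table view: trait, crop, QTL, SNP peak, gene peak, nearby gene."""
    rows = []
    for q in qtls:
        near = ""
        if q.nearby_gene:
            near = f"{abs(q.nearby_distance_bp) / 1000:.1f} kb to {q.nearby_gene}"
            if q.nearby_distance_bp == 0:
                near = f"within {q.nearby_gene}"
        rows.append(
            {
                "trait": q.trait,
                "crop": q.season,
                "qtl": q.name,
                "snp_pos": q.snp_pos,
                "snp_p": q.snp_p,
                "snp_pve": q.snp_pve,
                "peak_gene": q.gene_id,
                "gene_pos": q.gene_pos,
                "gene_p": q.gene_p,
                "gene_pve": q.gene_pve,
                "nearby_gene": near,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trait", "crop", "qtl", "snp_pos", "snp_p", "snp_pve",
            "peak_gene", "gene_pos", "gene_p", "gene_pve", "nearby_gene",
        ],
    )
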