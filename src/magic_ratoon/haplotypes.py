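"""Gene-haplotype construction for gene-based association testing.

A gene's marker is the multi-allelic haplotype class formed by concatenating
a line's alleles at every retained SNP/indel inside the gene's coding
intervals.  Inbred lines are near-homozygous, so no phasing is attempted:
homozygous calls are concatenated directly and lines heterozygous (or
missing) at any coding site are set aside per policy.  Classes are labelled
``Hap1..HapK`` in descending frequency; classes smaller than
``min_class_size`` are pooled into a ``RARE`` bucket that is reported but
excluded from testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = "MISSING"
RARE = "RARE"


@dataclass
class GeneModel:
    """An annotated gene: 1-based inclusive CDS intervals on one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    tss: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ivals = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
        self.cds_intervals = ivals

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]


@dataclass
class GeneHaplotypeSet:
    """Haplotype alleles of one gene and the line-to-class assignment."""

    gene_id: str
    variant_sites: list[tuple]          # ordered (chrom, pos, ref, alt) keys
    haplotypes: dict[str, tuple]        # label -> allele vector (Hap1.. frequency-ordered)
    assignment: pd.Series               # line_id -> label (HapK / RARE / MISSING)
    class_counts: dict[str, int]
    parents: dict[str, list[str]] = field(default_factory=dict)
    untestable: bool = False

    @property
    def n_classes(self) -> int:
        """Number of testable (non-RARE, non-MISSING) classes."""
        return len(self.haplotypes)

    def testable_labels(self) -> list[str]:
        return [l for l in self.class_counts if l not in (RARE, MISSING)]


@dataclass
class HaplotypeDesign:
    """(K-1) dummy columns vs the reference class, plus the line mask used."""

    gene_id: str
    columns: list[str]
    matrix: np.ndarray          # (n_included, K-1)
    mask: np.ndarray            # bool over the original line order
    reference: str
    testable: bool


def extract_coding_variants(gene: GeneModel, sites) -> list[tuple]:
    """Site keys whose POS falls inside any CDS interval, in genomic order.

    ``sites`` is an iterable of (chrom, pos, ref, alt) keys; indel membership
    is judged by the record POS alone (VCF left-alignment convention).
    """
    out = [
        key
        for key in sites
        if key[0] == gene.chrom and gene.contains(int(key[1]))
    ]
    out.sort(key=lambda k: int(k[1]))
    return out


def build_haplotypes(
    gene: GeneModel,
    genotypes: pd.DataFrame,
    min_class_size: int = 10,
    het_policy: str = "missing",
    founder_genotypes: pd.DataFrame | None = None,
) -> GeneHaplotypeSet:
    """Group lines into haplotype classes at one gene.

    Parameters
    ----------
    genotypes : DataFrame, lines x coding sites
        Alt-allele dosage (0/1/2, NaN missing) at the gene's coding sites in
        genomic order (columns are site keys).
    min_class_size : int
        Classes with fewer lines are pooled into ``RARE``.
    het_policy : {"missing", "allele"}
        ``missing`` (default) drops lines heterozygous at any coding site;
        ``allele`` keeps heterozygous calls as a distinct allele symbol.
    founder_genotypes : optional DataFrame, founders x same sites
        When given, each class records the founders whose homozygous vector
        matches it (the "Parents" column of the effect tables).
    """
    if het_policy not in ("missing", "allele"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    lines = list(genotypes.index)
    n_sites = genotypes.shape[1]
    if n_sites == 0:
        assign = pd.Series("Hap1", index=lines)
        return GeneHaplotypeSet(
            gene_id=gene.gene_id,
            variant_sites=[],
            haplotypes={"Hap1": ()},
            assignment=assign,
            class_counts={"Hap1": len(lines)},
        )

    g = genotypes.to_numpy(dtype=float)
    miss = ~np.isfinite(g)
    het = g == 1
    if het_policy == "missing":
        dropped = miss.any(axis=1) | het.any(axis=1)
        vec = np.where(g == 2, 1, 0).astype(np.int16)
    else:
        dropped = miss.any(axis=1)
        vec = np.where(g == 2, 1, np.where(g == 1, 2, 0)).astype(np.int16)

    labels = pd.Series(MISSING, index=lines, dtype=object)
    groups: dict[tuple, list[int]] = {}
    for i in np.flatnonzero(~dropped):
        groups.setdefault(tuple(vec[i]), []).append(i)

    if not groups:
        log.warning("%s: no informative lines, gene untestable", gene.gene_id)
        return GeneHaplotypeSet(
            gene_id=gene.gene_id,
            variant_sites=list(genotypes.columns),
            haplotypes={},
            assignment=labels,
            class_counts={MISSING: len(lines)},
            untestable=True,
        )

    # frequency-descending, lexicographic tiebreak -> deterministic labels
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    haplotypes: dict[str, tuple] = {}
    counts: dict[str, int] = {}
    k = 0
    rare_total = 0
    for veckey, idx in ordered:
        if len(idx) >= min_class_size:
            k += 1
            lab = f"Hap{k}"
            haplotypes[lab] = veckey
            counts[lab] = len(idx)
            labels.iloc[idx] = lab
        else:
            rare_total += len(idx)
            labels.iloc[idx] = RARE
    if rare_total:
        counts[RARE] = rare_total
    n_missing = int((labels == MISSING).sum())
    if n_missing:
        counts[MISSING] = n_missing

    parents: dict[str, list[str]] = {}
    if founder_genotypes is not None and haplotypes:
        fvec = np.where(founder_genotypes.to_numpy(dtype=float) == 2, 1, 0).astype(np.int16)
        for lab, hv in haplotypes.items():
            parents[lab] = [
                str(f)
                for f, row in zip(founder_genotypes.index, fvec)
                if tuple(row) == hv
            ]

    return GeneHaplotypeSet(
        gene_id=gene.gene_id,
        variant_sites=list(genotypes.columns),
        haplotypes=haplotypes,
        assignment=labels,
        class_counts=counts,
        parents=parents,
        untestable=len(haplotypes) == 0,
    )


def encode_design(
    hap_set: GeneHaplotypeSet, reference_class: str | None = None
) -> HaplotypeDesign:
    """Dummy-code a haplotype set as (K-1) indicators vs the reference class.

    RARE and MISSING lines are excluded via the returned mask.  With fewer
    than two testable classes the design is flagged untestable rather than
    raising.
    """
    labs = list(hap_set.haplotypes)
    if reference_class is None:
        reference_class = labs[0] if labs else ""
    elif reference_class not in labs:
        raise ValueError(f"reference class {reference_class!r} not among {labs}")
    others = [l for l in labs if l != reference_class]
    assign = hap_set.assignment
    mask = assign.isin(labs).to_numpy()
    if len(labs) < 2:
        return HaplotypeDesign(
            gene_id=hap_set.gene_id,
            columns=[],
            matrix=np.zeros((int(mask.sum()), 0)),
            mask=mask,
            reference=reference_class,
            testable=False,
        )
    sub = assign[mask]
    X = np.column_stack([(sub == l).to_numpy(float) for l in others])
    return HaplotypeDesign(
        gene_id=hap_set.gene_id,
        columns=others,
        matrix=X,
        mask=mask,
        reference=reference_class,
        testable=True,
    )


def genotypes_for_gene(gene: GeneModel, variants, dosage: np.ndarray, sample_ids) -> pd.DataFrame:
    """Slice a dosage matrix (sites x samples) down to one gene's coding sites.

    ``variants`` is the full ordered site-key list matching the dosage rows.
    Returns a lines-x-sites DataFrame suitable for :func:`build_haplotypes`.
    """
    keys = extract_coding_variants(gene, variants)
    index = {k: i for i, k in enumerate(variants)}
    rows = [index[k] for k in keys]
    sub = dosage[rows].T if rows else np.zeros((len(sample_ids), 0))
    return pd.DataFrame(sub, index=list(sample_ids), columns=keys)


def haplotype_table(hap_sets) -> pd.DataFrame:
    """Long-format summary (gene, K, class, count, parents) over many genes."""
    rows = []
    for hs in hap_sets:
        for lab, cnt in hs.class_counts.items():
            rows.append(
                {
                    "gene_id": hs.gene_id,
                    "n_classes": hs.n_classes,
                    "class": lab,
                    "count": cnt,
                    "parents": "/".join(hs.parents.get(lab, [])),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "n_classes", "class", "count", "parents"])
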