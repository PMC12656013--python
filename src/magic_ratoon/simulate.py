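"""Synthetic eight-founder MAGIC population generator.

Emulates the study design the analysis assumes: eight inbred founders
combined through a funnel (four two-way crosses, two four-way crosses, 144
eight-way F1 families), four F2 plants per family advanced by single-seed
descent, and a random subset of the resulting F7 lines phenotyped for
tiller number (TN), panicle length (PL, cm), spikelets per panicle (SPP)
and grain yield per plant (GY, g) over a main crop (MC) and a ratoon crop
(RC), in two field replicates and three staggered sowing batches.

Meiosis uses the Haldane model: crossover counts are Poisson with mean
(genetic length in cM)/100 per gamete per chromosome, positions uniform in
physical coordinates (uniform cM/bp), no interference.  Variant sites are
placed in small physical clusters so that synthetic gene models are
genetically tight, which keeps within-gene recombinants rare — the property
the gene-haplotype founder-mosaic oracle relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .haplotypes import GeneModel

FOUNDERS = ("DA5", "Pra", "ZS97", "MH63", "YJSM", "IR34", "GC2", "Cypress")
SEASONS = ("MC", "RC")
TRAITS = ("TN", "PL", "SPP", "GY")
_BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# founder panel
# ---------------------------------------------------------------------------


@dataclass
class Chromosome:
    name: str
    length_bp: int
    length_cm: float


@dataclass
class FounderPanel:
    """Eight homozygous founder genomes over a shared set of variant sites."""

    founder_ids: tuple[str, ...]
    chromosomes: list[Chromosome]
    positions: dict[str, np.ndarray]          # chrom -> sorted 1-based positions
    ref: dict[str, list[str]]
    alt: dict[str, list[str]]
    founder_alleles: dict[str, np.ndarray]    # chrom -> (8, n_sites) 0/1

    def __post_init__(self):
        if len(self.founder_ids) != 8:
            raise ValueError("a MAGIC panel needs exactly 8 founders")
        for c in self.chromosomes:
            pos = self.positions[c.name]
            if len(pos) and not np.all(np.diff(pos) > 0):
                raise ValueError(f"{c.name}: positions not strictly increasing")
            fa = self.founder_alleles[c.name]
            if len(pos) and not np.all((fa.min(axis=0) == 0) & (fa.max(axis=0) >= 1)):
                raise ValueError(f"{c.name}: monomorphic site among founders")

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def n_sites(self) -> int:
        return sum(len(self.positions[c]) for c in self.chrom_names)

    def site_keys(self) -> list[tuple]:
        keys = []
        for c in self.chrom_names:
            keys.extend(
                zip(
                    [c] * len(self.positions[c]),
                    (int(p) for p in self.positions[c]),
                    self.ref[c],
                    self.alt[c],
                )
            )
        return keys

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.site_keys(), columns=["chrom", "pos", "ref", "alt"])

    def site_index(self, chrom: str, pos: int) -> int:
        """Index of a site within its chromosome; raises if absent."""
        arr = self.positions[chrom]
        i = int(np.searchsorted(arr, pos))
        if i >= len(arr) or arr[i] != pos:
            raise ValueError(f"no panel site at {chrom}:{pos}")
        return i

    def founder_dosage(self) -> pd.DataFrame:
        """Founders x all-sites alt dosage (0/2, founders are homozygous)."""
        mats = [2 * self.founder_alleles[c] for c in self.chrom_names]
        return pd.DataFrame(
            np.hstack(mats), index=list(self.founder_ids), columns=self.site_keys()
        )


def build_founder_panel(
    n_chr: int = 12,
    sites_per_chr: int = 2000,
    indel_fraction: float = 0.1,
    seed: int = 0,
    chrom_length_bp: int = 30_000_000,
    chrom_length_cm: float = 150.0,
    cluster_size: int = 4,
    cluster_span_bp: int = 2000,
) -> FounderPanel:
    """Draw a synthetic founder panel.

    Sites are grouped in clusters of ``cluster_size`` within
    ``cluster_span_bp`` (gene-like loci) spread evenly along each
    chromosome.  Every site is polymorphic among the 8 founders with the
    minor allele carried by 1-4 founders, so founder allele frequencies span
    1/8..4/8.
    """
    if n_chr < 1 or sites_per_chr < 1:
        raise ValueError("n_chr and sites_per_chr must be positive")
    if not 0 <= indel_fraction <= 1:
        raise ValueError("indel_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms, positions, refs, alts, alleles = [], {}, {}, {}, {}
    for ci in range(n_chr):
        name = f"chr{ci + 1:02d}"
        chroms.append(Chromosome(name, chrom_length_bp, chrom_length_cm))
        n_clusters = math.ceil(sites_per_chr / cluster_size)
        margin = min(10_000, chrom_length_bp // 20)
        span_avail = chrom_length_bp - 2 * margin
        spacing = span_avail / n_clusters
        pos = []
        remaining = sites_per_chr
        for k in range(n_clusters):
            m = min(cluster_size, remaining)
            remaining -= m
            window = max(int(min(cluster_span_bp, spacing * 0.5)), m + 1)
            jitter_room = max(int(spacing) - window - 1, 1)
            origin = int(margin + k * spacing) + int(rng.integers(0, jitter_room))
            offs = np.sort(rng.choice(window, size=m, replace=False))
            pos.extend(int(origin + o) for o in offs)
        pos = np.asarray(sorted(set(pos)), dtype=np.int64)
        while len(pos) < sites_per_chr:  # collision backfill, rare
            extra = int(rng.integers(margin, chrom_length_bp - margin))
            if extra not in pos:
                pos = np.sort(np.append(pos, extra))
        m = len(pos)
        ref, alt = [], []
        is_indel = rng.random(m) < indel_fraction
        for i in range(m):
            b = _BASES[rng.integers(4)]
            if is_indel[i]:
                ins = "".join(_BASES[j] for j in rng.integers(0, 4, size=rng.integers(1, 7)))
                if rng.random() < 0.5:
                    ref.append(b), alt.append(b + ins)
                else:
                    ref.append(b + ins), alt.append(b)
            else:
                ref.append(b)
                alt.append(_BASES[(rng.integers(1, 4) + _BASES.index(b)) % 4])
        fa = np.zeros((8, m), dtype=np.int8)
        minor_counts = rng.integers(1, 5, size=m)
        for i in range(m):
            carriers = rng.choice(8, size=minor_counts[i], replace=False)
            fa[carriers, i] = 1
        positions[name], refs[name], alts[name], alleles[name] = pos, ref, alt, fa
    return FounderPanel(
        founder_ids=FOUNDERS,
        chromosomes=chroms,
        positions=positions,
        ref=refs,
        alt=alts,
        founder_alleles=alleles,
    )


# ---------------------------------------------------------------------------
# funnel pedigree and meiosis
# ---------------------------------------------------------------------------


@dataclass
class FunnelPedigree:
    """The crossing scheme: 2-way -> 4-way -> 8-way, then SSD from F2."""

    two_way_crosses: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("DA5", "Pra"),
            ("ZS97", "MH63"),
            ("YJSM", "IR34"),
            ("GC2", "Cypress"),
        ]
    )
    four_way_crosses: list[tuple[int, int]] = field(default_factory=lambda: [(0, 1), (2, 3)])
    n_eight_way_families: int = 144
    f2_plants_per_family: int = 4
    ssd_generations: int = 5
    n_selected_lines: int = 302

    def __post_init__(self):
        seen = [f for pair in self.two_way_crosses for f in pair]
        if len(seen) != len(set(seen)):
            raise ValueError("each founder may appear in exactly one two-way cross")
        used = [i for pair in self.four_way_crosses for i in pair]
        if sorted(used) != list(range(len(self.two_way_crosses))):
            raise ValueError("each two-way family must enter exactly one four-way cross")
        if self.ssd_generations < 1:
            raise ValueError("ssd_generations must be >= 1")
        for fld in ("n_eight_way_families", "f2_plants_per_family", "n_selected_lines"):
            if getattr(self, fld) < 1:
                raise ValueError(f"{fld} must be positive")

    @property
    def n_candidate_lines(self) -> int:
        return self.n_eight_way_families * self.f2_plants_per_family


# A homolog is a list of (start_bp, end_bp, founder_index) half-open segments
# tiling [1, L+1); a plant is, per chromosome, a pair of homologs.


def _merge(segs):
    out = [segs[0]]
    for s in segs[1:]:
        if s[2] == out[-1][2] and s[0] == out[-1][1]:
            out[-1] = (out[-1][0], s[1], s[2])
        else:
            out.append(s)
    return out


def _clip(hom, a, b):
    return [
        (max(s, a), min(e, b), f) for s, e, f in hom if e > a and s < b
    ]


def _gamete(h1, h2, length_bp, length_cm, rng):
    """One meiotic product under the Haldane model (no interference)."""
    n_x = rng.poisson(length_cm / 100.0)
    active = int(rng.integers(2))
    homs = (h1, h2)
    if n_x == 0:
        return list(homs[active])
    cuts = np.sort(rng.uniform(1.0, length_bp + 1.0, size=n_x))
    bounds = [1.0, *cuts.tolist(), float(length_bp) + 1.0]
    segs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b > a:
            segs.extend(_clip(homs[active], a, b))
        active ^= 1
    return _merge(segs)


def _meiosis(plant, chroms, rng):
    return [
        _gamete(h1, h2, c.length_bp, c.length_cm, rng)
        for (h1, h2), c in zip(plant, chroms)
    ]


@dataclass
class MagicLine:
    """One inbred MAGIC line: founder mosaic per homolog plus its genotype."""

    line_id: str
    mosaic: dict[str, tuple[list, list]]
    alleles: dict[str, np.ndarray]  # chrom -> (2, n_sites) allele index

    def dosage(self, chrom_names) -> np.ndarray:
        return np.concatenate([self.alleles[c].sum(axis=0) for c in chrom_names])

    def het_fraction(self, chrom_names) -> float:
        diff = np.concatenate(
            [self.alleles[c][0] != self.alleles[c][1] for c in chrom_names]
        )
        return float(diff.mean()) if diff.size else 0.0

    def founder_at(self, chrom: str, pos: int) -> tuple[int, int]:
        return tuple(_founder_at(h, np.asarray([pos]))[0] for h in self.mosaic[chrom])


def _founder_at(hom, positions):
    ends = np.asarray([e for _, e, _ in hom])
    founders = np.asarray([f for _, _, f in hom])
    idx = np.searchsorted(ends, positions, side="right")
    return founders[np.minimum(idx, len(ends) - 1)]


def simulate_funnel(
    panel: FounderPanel,
    pedigree: FunnelPedigree | None = None,
    map_function: str = "haldane",
    seed: int = 0,
) -> list[MagicLine]:
    """Run the funnel and SSD, returning the selected F lines.

    Only the Haldane map function is implemented (Poisson crossover counts,
    uniform positions); the argument exists so the model choice is explicit
    at call sites.
    """
    if map_function != "haldane":
        raise ValueError("only the 'haldane' map function is implemented")
    pedigree = pedigree or FunnelPedigree()
    fidx = {f: i for i, f in enumerate(panel.founder_ids)}
    for a, b in pedigree.two_way_crosses:
        if a not in fidx or b not in fidx:
            raise ValueError(f"pedigree founder {a}/{b} not in panel")
    if pedigree.n_selected_lines > pedigree.n_candidate_lines:
        raise ValueError(
            f"cannot select {pedigree.n_selected_lines} from "
            f"{pedigree.n_candidate_lines} candidate lines"
        )
    rng = np.random.default_rng(seed)
    chroms = panel.chromosomes

    def whole(f, c):
        return [(1.0, float(c.length_bp) + 1.0, fidx[f])]

    two_way = [
        [(whole(a, c), whole(b, c)) for c in chroms]
        for a, b in pedigree.two_way_crosses
    ]

    def four_way_plant(cross):
        i, j = pedigree.four_way_crosses[cross]
        g1 = _meiosis(two_way[i], chroms, rng)
        g2 = _meiosis(two_way[j], chroms, rng)
        return list(zip(g1, g2))

    candidates = []
    for fam in range(pedigree.n_eight_way_families):
        p1 = four_way_plant(0)
        p2 = four_way_plant(1)
        f1 = list(zip(_meiosis(p1, chroms, rng), _meiosis(p2, chroms, rng)))
        for _ in range(pedigree.f2_plants_per_family):
            plant = list(zip(_meiosis(f1, chroms, rng), _meiosis(f1, chroms, rng)))
            for _ in range(pedigree.ssd_generations):
                plant = list(zip(_meiosis(plant, chroms, rng), _meiosis(plant, chroms, rng)))
            candidates.append(plant)

    chosen = np.sort(
        rng.choice(len(candidates), size=pedigree.n_selected_lines, replace=False)
    )
    lines = []
    for li, ci in enumerate(chosen):
        plant = candidates[ci]
        mosaic, alleles = {}, {}
        for (h1, h2), c in zip(plant, chroms):
            pos = panel.positions[c.name]
            f1 = _founder_at(h1, pos)
            f2 = _founder_at(h2, pos)
            fa = panel.founder_alleles[c.name]
            cols = np.arange(len(pos))
            alleles[c.name] = np.vstack([fa[f1, cols], fa[f2, cols]]).astype(np.int8)
            mosaic[c.name] = (h1, h2)
        lines.append(MagicLine(line_id=f"L{li + 1:04d}", mosaic=mosaic, alleles=alleles))
    return lines


def dosage_matrix(panel: FounderPanel, lines) -> pd.DataFrame:
    """Lines x sites alt-dosage matrix (columns are panel site keys)."""
    mat = np.vstack([ln.dosage(panel.chrom_names) for ln in lines])
    return pd.DataFrame(mat, index=[ln.line_id for ln in lines], columns=panel.site_keys())


def founder_shares(panel: FounderPanel, lines) -> np.ndarray:
    """Genome-wide founder-origin share per founder (bp-weighted), sums to 1."""
    share = np.zeros(8)
    for ln in lines:
        for c in panel.chrom_names:
            for hom in ln.mosaic[c]:
                for s, e, f in hom:
                    share[f] += e - s
    return share / share.sum()


def expected_f2_het(panel: FounderPanel, pedigree: FunnelPedigree) -> float:
    """Analytic mean F2 heterozygosity over panel sites.

    At a locus an 8-way F1 carries one founder from each four-way side; an
    F2 plant is heterozygous iff its two gametes pick different homologs
    (probability 1/2) and those founders' alleles differ.  Averaging the
    allele-difference probability over the two disjoint founder quartets
    gives the per-site expectation.
    """
    sideA = [f for i in pedigree.four_way_crosses[0] for f in pedigree.two_way_crosses[i]]
    sideB = [f for i in pedigree.four_way_crosses[1] for f in pedigree.two_way_crosses[i]]
    fidx = {f: i for i, f in enumerate(panel.founder_ids)}
    ia = [fidx[f] for f in sideA]
    ib = [fidx[f] for f in sideB]
    tot, m = 0.0, 0
    for c in panel.chrom_names:
        fa = panel.founder_alleles[c]
        pa = fa[ia].mean(axis=0)
        pb = fa[ib].mean(axis=0)
        tot += float(np.sum(pa * (1 - pb) + pb * (1 - pa)))
        m += fa.shape[1]
    return 0.5 * tot / m


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def make_gene_models(
    panel: FounderPanel, coding_fraction: float = 0.8, seed: int = 0, max_gap_bp: int = 5000
) -> list[GeneModel]:
    """Synthetic gene models over the panel's site clusters.

    Consecutive sites closer than ``max_gap_bp`` form one locus; a
    ``coding_fraction`` of loci become genes whose CDS intervals cover the
    locus sites (split into two CDS intervals when the locus has >= 4 sites,
    exercising multi-exon extraction).
    """
    if not 0 <= coding_fraction <= 1:
        raise ValueError("coding_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = []
    for c in panel.chrom_names:
        pos = panel.positions[c]
        if not len(pos):
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
        clusters = np.split(np.arange(len(pos)), breaks + 1)
        for k, idx in enumerate(clusters):
            if rng.random() >= coding_fraction:
                continue
            p = pos[idx]
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = int(p[0]) - 10, int(p[-1]) + 10
            if len(p) >= 4:
                mid = int((p[len(p) // 2 - 1] + p[len(p) // 2]) // 2)
                cds = [(start, mid), (mid + 2, end)]
            else:
                cds = [(start, end)]
            genes.append(
                GeneModel(
                    gene_id=f"{c}g{k + 1:04d}",
                    chrom=c,
                    strand=strand,
                    cds_intervals=cds,
                    tss=start if strand == "+" else end,
                )
            )
    return genes


# ---------------------------------------------------------------------------
# trait architecture and phenotypes
# ---------------------------------------------------------------------------


@dataclass
class PlantedQTL:
    """A causal locus with a founder allelic series.

    ``effects`` has one entry per founder (panel order); a line's genetic
    value is the mean of its two homolog founders' effects, standardized
    across lines and scaled so the locus explains ``pve`` of the line-mean
    phenotypic variance.
    """

    chrom: str
    pos: int
    effects: tuple[float, ...]
    pve: float

    def __post_init__(self):
        if not 0 < self.pve < 1:
            raise ValueError("target PVE must lie in (0, 1)")
        if len(self.effects) != 8:
            raise ValueError("effects must list one value per founder")

    @classmethod
    def from_site(cls, panel: "FounderPanel", chrom: str, pos: int, pve: float,
                  sign: float = 1.0) -> "PlantedQTL":
        """A biallelic QTL whose effects follow the founders' alleles at the
        site, so the site's own SNP dosage carries the full signal."""
        i = panel.site_index(chrom, pos)
        alleles = panel.founder_alleles[chrom][:, i]
        return cls(chrom=chrom, pos=pos, effects=tuple(sign * float(a) for a in alleles), pve=pve)


@dataclass
class TraitSpec:
    """Variance bookkeeping for one trait, on the standardized line-mean scale.

    Components are fractions of the line-mean phenotypic variance (which is
    1 by construction): planted QTLs (per season), a cross-season shared
    polygenic term, a sowing-batch term (shared across seasons), a per-line
    residual ``residual_var`` (replicate noise has variance
    ``residual_var * n_replicates`` per record), and a season-specific
    polygenic remainder that absorbs whatever the other components leave.
    Setting ``specific`` explicitly fixes the season-specific variance
    instead (the line-mean variance then needn't be 1).
    """

    mean: dict[str, float]
    sd: dict[str, float]
    qtls: dict[str, list[PlantedQTL]] = field(default_factory=lambda: {"MC": [], "RC": []})
    shared_var: float = 0.3
    batch_var: float = 0.02
    residual_var: float = 0.12
    specific: float | None = None

    def qtl_var(self, season: str) -> float:
        return sum(q.pve for q in self.qtls.get(season, []))

    def specific_var(self, season: str) -> float:
        if self.specific is not None:
            if self.specific < 0:
                raise ValueError("specific variance must be >= 0")
            return self.specific
        v = 1.0 - self.qtl_var(season) - self.shared_var - self.batch_var - self.residual_var
        if v < -1e-9:
            raise ValueError(f"variance components exceed 1 for season {season}")
        return max(v, 0.0)

    def expected_cross_season_r(self) -> float:
        """Analytic line-mean cross-season correlation under the generator.

        Shared polygenic and batch components are common to both seasons;
        QTLs present in both seasons at the same site contribute
        sign(concordance) * sqrt(pve_MC * pve_RC).
        """
        cov = self.shared_var + self.batch_var
        for q1 in self.qtls.get("MC", []):
            for q2 in self.qtls.get("RC", []):
                if (q1.chrom, q1.pos) == (q2.chrom, q2.pos):
                    e1, e2 = np.asarray(q1.effects, float), np.asarray(q2.effects, float)
                    c1, c2 = e1 - e1.mean(), e2 - e2.mean()
                    denom = np.linalg.norm(c1) * np.linalg.norm(c2)
                    rho = float(c1 @ c2 / denom) if denom > 0 else 0.0
                    cov += rho * math.sqrt(q1.pve * q2.pve)
        return cov


@dataclass
class TraitArchitecture:
    """Per-trait specs plus how grain yield is composed.

    ``gy_mode="composed"`` builds GY from the standardized TN/SPP/PL
    line-season values with weights ``gy_weights[season]`` (TN, SPP, PL)
    plus independent noise; ``"direct"`` simulates GY from its own spec like
    any other trait.
    """

    traits: dict[str, TraitSpec]
    gy_mode: str = "composed"
    gy_weights: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"MC": (0.45, 0.28, 0.10), "RC": (0.55, 0.31, 0.16)}
    )
    n_background_sites: int = 200

    def __post_init__(self):
        if self.gy_mode not in ("composed", "direct"):
            raise ValueError("gy_mode must be 'composed' or 'direct'")

    @classmethod
    def default(cls, panel: FounderPanel) -> "TraitArchitecture":
        """Study-condition defaults with QTL allelic series and PVEs in the
        5-24% range, anchored to actual panel sites."""

        def site_at(chrom_i: int, frac: float) -> tuple[str, int]:
            c = panel.chrom_names[min(chrom_i, len(panel.chrom_names) - 1)]
            pos = panel.positions[c]
            return c, int(pos[min(int(frac * len(pos)), len(pos) - 1)])

        c1, p1 = site_at(0, 0.85)      # PL/TN locus, emulates the chr1 region
        c4a, p4a = site_at(3, 0.08)    # ratoon TN locus
        c4b, p4b = site_at(3, 0.94)    # main-crop TN/SPP locus
        series_3 = (0, 0, 0, 1, 1, 1, 2, 2)  # 3-class allelic series, gene-detectable
        traits = {
            "TN": TraitSpec(
                mean={"MC": 12.6, "RC": 16.4},
                sd={"MC": 3.0, "RC": 6.5},
                qtls={
                    "MC": [
                        PlantedQTL.from_site(panel, c1, p1, 0.06),
                        PlantedQTL(c4b, p4b, series_3, 0.10),
                    ],
                    "RC": [
                        # same locus, opposing seasonal effect
                        PlantedQTL.from_site(panel, c1, p1, 0.06, sign=-1.0),
                        PlantedQTL(c4a, p4a, series_3, 0.12),
                    ],
                },
                shared_var=0.25,
                batch_var=0.02,
                residual_var=0.12,
            ),
            "PL": TraitSpec(
                mean={"MC": 27.1, "RC": 18.4},
                sd={"MC": 3.1, "RC": 2.5},
                qtls={
                    "MC": [PlantedQTL.from_site(panel, c1, p1, 0.20)],
                    "RC": [PlantedQTL.from_site(panel, c1, p1, 0.11)],
                },
                shared_var=0.50,
                batch_var=0.02,
                residual_var=0.10,
            ),
            "SPP": TraitSpec(
                mean={"MC": 213.2, "RC": 59.3},
                sd={"MC": 65.0, "RC": 18.0},
                qtls={"MC": [PlantedQTL.from_site(panel, c4b, p4b, 0.11)], "RC": []},
                shared_var=0.34,
                batch_var=0.02,
                residual_var=0.15,
            ),
            "GY": TraitSpec(
                mean={"MC": 25.8, "RC": 11.0},
                sd={"MC": 10.5, "RC": 6.3},
                qtls={"MC": [], "RC": []},
                shared_var=0.10,
                batch_var=0.02,
                residual_var=0.20,
            ),
        }
        return cls(traits=traits)


@dataclass
class PhenotypeBook:
    """Per-replicate phenotype records plus derived helpers."""

    frame: pd.DataFrame

    def __post_init__(self):
        need = {"line_id", "season", "replicate", "batch", *TRAITS}
        missing = need - set(self.frame.columns)
        if missing:
            raise ValueError(f"phenotype frame lacks columns {sorted(missing)}")

    def line_means(self, season: str | None = None) -> pd.DataFrame:
        """Mean over replicates per line (x season unless one is fixed)."""
        df = self.frame
        if season is not None:
            df = df[df["season"] == season]
            return df.groupby("line_id", sort=True)[list(TRAITS)].mean()
        return df.groupby(["line_id", "season"], sort=True)[list(TRAITS)].mean()

    def batches(self) -> pd.Series:
        return self.frame.groupby("line_id", sort=True)["batch"].first()

    def ratooning_ability(self) -> pd.Series:
        """Per-line RA = ratoon-crop TN / main-crop TN (line means); NaN
        when a line lacks a season or has non-positive main-crop TN."""
        mc = self.line_means("MC")["TN"]
        rc = self.line_means("RC")["TN"]
        both = mc.index.intersection(rc.index)
        ra = rc.loc[both] / mc.loc[both].where(mc.loc[both] > 0)
        ra.name = "RA"
        return ra


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_phenotypes(
    panel: FounderPanel,
    lines,
    architecture: TraitArchitecture | None = None,
    n_replicates: int = 2,
    seed: int = 0,
) -> PhenotypeBook:
    """Draw two-season, replicated phenotypes for the given lines.

    Each line-season genetic value is the sum of standardized planted-QTL
    class values (scaled to their target PVE), a kinship-structured shared
    polygenic term, a season-specific polygenic term, and a batch offset;
    replicate records add independent noise.  All components are
    empirically standardized across lines so realized variance fractions
    track their targets tightly at moderate n.
    """
    architecture = architecture or TraitArchitecture.default(panel)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(lines)
    line_ids = [ln.line_id for ln in lines]

    # sowing batches: thirds of a random permutation, fixed per line
    perm = rng.permutation(n)
    batch = np.empty(n, dtype=int)
    for b in range(3):
        batch[perm[b * n // 3 : (b + 1) * n // 3 if b < 2 else n]] = b + 1
    batch_levels = _standardize(np.array([-1.0, 0.0, 1.0]))
    batch_z = _standardize(batch_levels[batch - 1])

    # background-site polygenic machinery (kinship-structured)
    dos = dosage_matrix(panel, lines).to_numpy(dtype=float)
    n_bg = min(architecture.n_background_sites, dos.shape[1])
    bg_idx = rng.choice(dos.shape[1], size=n_bg, replace=False)
    bg = dos[:, bg_idx]

    def polygenic(orth_basis=()) -> np.ndarray:
        """Kinship-structured standardized draw, orthogonalized in-sample
        against the trait's other components so planted variance fractions
        are realized exactly (population structure otherwise correlates
        nominally independent draws)."""
        w = rng.normal(size=n_bg)
        u = bg @ w
        for b in orth_basis:
            bb = float(b @ b)
            if bb > 0:
                u = u - (float(u @ b) / bb) * b
        if u.std() < 1e-10 * (abs(u).max() + 1.0) or u.std() == 0:
            u = rng.normal(size=n)  # basis exhausted the genotype span
            for b in orth_basis:
                bb = float(b @ b)
                if bb > 0:
                    u = u - (float(u @ b) / bb) * b
        return _standardize(u)

    def qtl_value(q: PlantedQTL) -> np.ndarray:
        i = panel.site_index(q.chrom, q.pos)  # raises if absent from panel
        eff = np.asarray(q.effects, dtype=float)
        vals = np.empty(n)
        for li, ln in enumerate(lines):
            f1, f2 = ln.founder_at(q.chrom, q.pos)
            vals[li] = 0.5 * (eff[f1] + eff[f2])
        return _standardize(vals)

    z: dict[tuple[str, str], np.ndarray] = {}  # (trait, season) -> line-level value
    traits_order = [t for t in TRAITS if t != "GY" or architecture.gy_mode == "direct"]
    for trait in traits_order:
        spec = architecture.traits[trait]
        qvals = {}
        for season in SEASONS:
            for q in spec.qtls.get(season, []):
                key = (q.chrom, q.pos, q.effects)
                if key not in qvals:
                    qvals[key] = qtl_value(q)
        basis = [batch_z, *qvals.values()]
        u_shared = polygenic(basis)
        basis.append(u_shared)
        for season in SEASONS:
            u_spec = polygenic(basis)
            basis.append(u_spec)
            g = math.sqrt(spec.shared_var) * u_shared
            g = g + math.sqrt(spec.specific_var(season)) * u_spec
            g = g + math.sqrt(spec.batch_var) * batch_z
            for q in spec.qtls.get(season, []):
                g = g + math.sqrt(q.pve) * qvals[(q.chrom, q.pos, q.effects)]
            z[(trait, season)] = g

    if architecture.gy_mode == "composed":
        spec = architecture.traits["GY"]
        for season in SEASONS:
            w = architecture.gy_weights[season]
            comp = sum(
                wi * z[(t, season)] for wi, t in zip(w, ("TN", "SPP", "PL"))
            )
            target_gen = 1.0 - spec.residual_var
            slack = target_gen - float(np.var(comp))
            if slack > 0:
                comp = comp + math.sqrt(slack) * _standardize(rng.normal(size=n))
            z[("GY", season)] = comp

    records = []
    for season in SEASONS:
        for trait in TRAITS:
            spec = architecture.traits[trait]
            noise_sd = math.sqrt(spec.residual_var * n_replicates)
            base = spec.mean[season] + spec.sd[season] * z[(trait, season)]
            for rep in range(1, n_replicates + 1):
                eps = rng.normal(scale=noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
                y = base + spec.sd[season] * eps
                # positivity guard for count/length scales; inactive on
                # centered (mean <= 0) test architectures
                if spec.mean[season] > 0:
                    floor = 0.0 if trait == "GY" else 0.01 * spec.mean[season]
                else:
                    floor = -np.inf
                records.append(
                    pd.DataFrame(
                        {
                            "line_id": line_ids,
                            "season": season,
                            "replicate": rep,
                            "batch": batch,
                            "trait": trait,
                            "value": np.maximum(y, floor),
                        }
                    )
                )
    long = pd.concat(records, ignore_index=True)
    wide = (
        long.pivot_table(
            index=["line_id", "season", "replicate", "batch"],
            columns="trait",
            values="value",
        )
        .reset_index()
        .rename_axis(columns=None)
    )
    wide = wide[["line_id", "season", "replicate", "batch", *TRAITS]]
    return PhenotypeBook(frame=wide.sort_values(["season", "line_id", "replicate"]).reset_index(drop=True))


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------


def write_synthetic_bundle(
    panel: FounderPanel,
    lines,
    genes,
    phenotypes: PhenotypeBook,
    out_dir,
    fail_fraction: float = 0.0,
    depth_mean: float = 6.0,
    seed: int = 0,
) -> dict[str, str]:
    """Emit VCF + GFF3 + phenotype TSV (+ a site-truth table) to ``out_dir``.

    A ``fail_fraction`` of sites gets one QC criterion (QD, MQ, FS or mean
    depth) drawn in its failing range; all other sites draw passing values.
    The truth table records what was injected so QC output can be verified
    exactly.
    """
    import os

    from . import io as mio

    if not 0 <= fail_fraction <= 1:
        raise ValueError("fail_fraction must lie in [0, 1]")
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    sites = panel.site_frame()
    m = len(sites)
    n = len(lines)

    qd = rng.uniform(10, 35, size=m)
    mq = rng.uniform(45, 60, size=m)
    fs = rng.uniform(0, 20, size=m)
    dp_lam = np.full(m, depth_mean)
    fail_mode = np.asarray(["pass"] * m, dtype=object)
    fail = rng.random(m) < fail_fraction
    modes = ("qd", "mq", "fs", "depth")
    for i in np.flatnonzero(fail):
        mode = modes[rng.integers(4)]
        fail_mode[i] = mode
        if mode == "qd":
            qd[i] = rng.uniform(0.05, 0.9)
        elif mode == "mq":
            mq[i] = rng.uniform(10, 38)
        elif mode == "fs":
            fs[i] = rng.uniform(85, 200)
        else:
            dp_lam[i] = 0.8 if rng.random() < 0.5 else 25.0
    sites["qd"], sites["mq"], sites["fs"] = qd, mq, fs

    if n:
        gt = np.stack(
            [np.concatenate([ln.alleles[c] for c in panel.chrom_names], axis=1).T for ln in lines],
            axis=1,
        )  # (m, n, 2)
    else:
        gt = np.zeros((m, 0, 2), dtype=np.int8)
    # Poisson depths: lambda 0.8 / 25 put the site mean outside the open (2, 15) band
    dp = rng.poisson(dp_lam[:, None], size=(m, n)).astype(float) if n else np.zeros((m, 0))

    contigs = [(c.name, c.length_bp) for c in panel.chromosomes]
    paths = {
        "vcf": mio.write_vcf(
            os.path.join(out_dir, "variants.vcf"),
            sites,
            gt,
            [ln.line_id for ln in lines],
            dp=dp,
            contigs=contigs,
        ),
        "gff3": mio.write_gff3(os.path.join(out_dir, "genes.gff3"), genes),
        "phenotypes": mio.write_phenotypes(
            os.path.join(out_dir, "phenotypes.tsv"), phenotypes.frame
        ),
    }
    truth = sites.copy()
    truth["fail_mode"] = fail_mode
    truth["mean_depth"] = dp.mean(axis=1) if n else np.nan
    truth_path = os.path.join(out_dir, "sites_truth.tsv")
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.4f")
    paths["sites_truth"] = truth_path
    return paths
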