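"""End-to-end orchestration: simulate -> qc -> haplotype -> gwas -> stats -> report.

Each stage writes its outputs under the run directory and is skipped on
re-run when they already exist, so deleting a downstream output regenerates
only that stage.  A manifest records the seed, package version and SHA-256
of every artifact; with a fixed seed the manifest hashes are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, io as mio
from . import haplotypes as hap
from . import lmm, qc, report as rep, simulate as sim
from . import traits as tr

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "haplotype", "gwas", "stats", "report")
GWAS_TRAITS = ("TN", "PL", "SPP", "GY", "RA")


@dataclass
class SimulationConfig:
    n_chr: int = 12
    sites_per_chr: int = 2000
    indel_fraction: float = 0.1
    n_eight_way_families: int = 144
    f2_plants_per_family: int = 4
    ssd_generations: int = 5
    n_selected_lines: int = 302
    n_replicates: int = 2
    fail_fraction: float = 0.05
    coding_fraction: float = 0.8


@dataclass
class RunConfig:
    out_dir: str = "magic_run"
    seed: int = 1
    vcf: str | None = None            # real-data mode when set
    gff: str | None = None
    pheno: str | None = None
    landmarks_bed: str | None = None
    traits: tuple = GWAS_TRAITS
    alpha: float = 0.05
    meff_window: int = 200
    merge_window_bp: int = 500_000
    min_class_size: int = 10
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "qc_thresholds" in kwargs:
            kwargs["qc_thresholds"] = qc.QCThresholds(**kwargs["qc_thresholds"])
        if "simulation" in kwargs:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        if "traits" in kwargs:
            kwargs["traits"] = tuple(kwargs["traits"])
        cfg = cls(**kwargs)
        if cfg.vcf is not None:
            for p in (cfg.vcf, cfg.gff, cfg.pheno):
                if p is None or not os.path.exists(p):
                    raise FileNotFoundError(f"real-data mode path missing: {p}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _exists(*paths) -> bool:
    return all(os.path.exists(p) for p in paths)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Run every stage; returns the manifest dictionary."""
    os.makedirs(config.out_dir, exist_ok=True)
    artifacts: dict[str, str] = {}
    state: dict = {"config": config}
    for stage in STAGES:
        fn = globals()[f"_stage_{stage}"]
        t0 = time.time()
        try:
            produced = fn(config, state, force)
        except Exception as exc:  # noqa: BLE001 - stage name context matters
            marker = os.path.join(config.out_dir, f"FAILED_{stage}")
            with open(marker, "w") as fh:
                fh.write(str(exc))
            raise PipelineError(stage, exc) from exc
        artifacts.update(produced)
        log.info("stage %-9s done in %.2fs (%d artifacts)", stage, time.time() - t0, len(produced))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(config.to_dict()),
        "artifacts": {k: _sha256(v) for k, v in sorted(artifacts.items())},
        "paths": artifacts,
    }
    path = os.path.join(config.out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, state: dict, force: bool) -> dict:
    if config.vcf is not None:  # real-data mode
        state["paths"] = {"vcf": config.vcf, "gff3": config.gff, "phenotypes": config.pheno}
        return {}
    out = os.path.join(config.out_dir, "sim")
    paths = {
        "vcf": os.path.join(out, "variants.vcf"),
        "gff3": os.path.join(out, "genes.gff3"),
        "phenotypes": os.path.join(out, "phenotypes.tsv"),
        "sites_truth": os.path.join(out, "sites_truth.tsv"),
    }
    if force or not _exists(*paths.values()):
        s = config.simulation
        panel = sim.build_founder_panel(
            n_chr=s.n_chr, sites_per_chr=s.sites_per_chr,
            indel_fraction=s.indel_fraction, seed=config.seed,
        )
        pedigree = sim.FunnelPedigree(
            n_eight_way_families=s.n_eight_way_families,
            f2_plants_per_family=s.f2_plants_per_family,
            ssd_generations=s.ssd_generations,
            n_selected_lines=s.n_selected_lines,
        )
        lines = sim.simulate_funnel(panel, pedigree, seed=config.seed + 1)
        genes = sim.make_gene_models(panel, coding_fraction=s.coding_fraction, seed=config.seed + 2)
        arch = sim.TraitArchitecture.default(panel)
        pheno = sim.simulate_phenotypes(panel, lines, arch, n_replicates=s.n_replicates, seed=config.seed + 3)
        paths = sim.write_synthetic_bundle(
            panel, lines, genes, pheno, out,
            fail_fraction=s.fail_fraction, seed=config.seed + 4,
        )
    state["paths"] = paths
    return {f"sim/{os.path.basename(v)}": v for v in paths.values()}


def _stage_qc(config: RunConfig, state: dict, force: bool) -> dict:
    out = os.path.join(config.out_dir, "qc")
    os.makedirs(out, exist_ok=True)
    report_path = os.path.join(out, "qc_report.tsv")
    summary_path = os.path.join(out, "qc_summary.tsv")
    vcf_path = os.path.join(out, "retained.vcf")
    variants = mio.read_vcf(state["paths"]["vcf"])
    if force or not _exists(report_path, summary_path, vcf_path):
        filtered, report = qc.apply_qc(variants, config.qc_thresholds)
        report.to_csv(report_path, sep="\t", index=False, float_format="%.6g")
        qc.qc_summary(report).to_csv(summary_path, sep="\t", index=False)
        mio.write_vcf(vcf_path, filtered.sites, filtered.gt, filtered.samples, dp=filtered.dp)
        state["variants"] = filtered
    else:
        state["variants"] = mio.read_vcf(vcf_path)
    return {"qc/qc_report.tsv": report_path, "qc/qc_summary.tsv": summary_path, "qc/retained.vcf": vcf_path}


def _stage_haplotype(config: RunConfig, state: dict, force: bool) -> dict:
    out = os.path.join(config.out_dir, "haplotype")
    os.makedirs(out, exist_ok=True)
    table_path = os.path.join(out, "haplotypes.tsv")
    assign_path = os.path.join(out, "assignments.tsv")
    variants: mio.VariantTable = state["variants"]
    genes = mio.read_gff3(state["paths"]["gff3"])
    dosage = variants.dosage()
    keys = variants.site_keys()
    hap_sets = []
    for gene in genes:
        geno = hap.genotypes_for_gene(gene, keys, dosage, variants.samples)
        hap_sets.append(hap.build_haplotypes(gene, geno, min_class_size=config.min_class_size))
    state["genes"] = genes
    state["hap_sets"] = hap_sets
    if force or not _exists(table_path, assign_path):
        hap.haplotype_table(hap_sets).to_csv(table_path, sep="\t", index=False)
        assign = pd.DataFrame({hs.gene_id: hs.assignment for hs in hap_sets})
        assign.index.name = "line_id"
        assign.to_csv(assign_path, sep="\t")
    return {"haplotype/haplotypes.tsv": table_path, "haplotype/assignments.tsv": assign_path}


def _phenotype_vectors(config: RunConfig, state: dict) -> sim.PhenotypeBook:
    book = sim.PhenotypeBook(frame=mio.read_phenotypes(state["paths"]["phenotypes"]))
    state["pheno"] = book
    return book


def _stage_gwas(config: RunConfig, state: dict, force: bool) -> dict:
    out = os.path.join(config.out_dir, "gwas")
    os.makedirs(out, exist_ok=True)
    variants: mio.VariantTable = state["variants"]
    book = _phenotype_vectors(config, state)
    samples = variants.samples
    dosage = variants.dosage()  # sites x lines
    G = pd.DataFrame(dosage.T, index=samples, columns=variants.site_keys())
    kin = lmm.kinship(G)
    state["kinship"] = kin

    batches = book.batches().reindex(samples)
    W = pd.get_dummies(batches, prefix="batch", drop_first=True).to_numpy(float)

    meff_snp = lmm.effective_tests(dosage, chrom=variants.sites["chrom"], scope="snp",
                                   alpha=config.alpha, window=config.meff_window)
    codes = _gene_codes(state["hap_sets"], samples)
    gene_chrom = [g.chrom for g in state["genes"]]
    meff_gene = lmm.effective_tests(codes, chrom=gene_chrom, scope="gene",
                                    alpha=config.alpha, window=config.meff_window)
    thresholds = {
        "snp": {"scope": "snp", "meff": meff_snp.meff, "alpha": config.alpha,
                "threshold": meff_snp.threshold, "n_tests": meff_snp.n_tests},
        "gene": {"scope": "gene", "meff": meff_gene.meff, "alpha": config.alpha,
                 "threshold": meff_gene.threshold, "n_tests": meff_gene.n_tests},
    }
    thr_path = os.path.join(out, "thresholds.json")
    with open(thr_path, "w") as fh:
        json.dump(thresholds, fh, indent=1, sort_keys=True)
    state["thresholds"] = {"snp": meff_snp.threshold, "gene": meff_gene.threshold}

    gene_meta = pd.DataFrame(
        {"gene_id": [g.gene_id for g in state["genes"]],
         "chrom": [g.chrom for g in state["genes"]],
         "pos": [g.tss for g in state["genes"]]}
    )
    designs = [hap.encode_design(hs) for hs in state["hap_sets"]]
    artifacts = {"gwas/thresholds.json": thr_path}
    state["scans"] = {}
    for trait in config.traits:
        for season in _seasons_for(trait):
            y = _trait_vector(book, trait, season).reindex(samples)
            ok = y.notna().to_numpy()
            if not ok.all():
                raise ValueError(f"{trait}/{season}: phenotype missing for some genotyped lines")
            fit = lmm.LinearMixedModel(y.to_numpy(float), kin, W).fit()
            snp_df = fit.scan_snps(dosage, sites=variants.sites)
            gene_df = fit.scan_genes(designs, gene_meta=gene_meta)
            tag = f"{trait}_{season}" if season else trait
            p_snp = os.path.join(out, f"snp_{tag}.tsv")
            p_gene = os.path.join(out, f"gene_{tag}.tsv")
            if force or not _exists(p_snp, p_gene):
                snp_df.to_csv(p_snp, sep="\t", index=False, float_format="%.6g")
                gene_df.to_csv(p_gene, sep="\t", index=False, float_format="%.6g")
            artifacts[f"gwas/snp_{tag}.tsv"] = p_snp
            artifacts[f"gwas/gene_{tag}.tsv"] = p_gene
            state["scans"][(trait, season)] = (snp_df, gene_df)
    return artifacts


def _seasons_for(trait: str):
    return (None,) if trait == "RA" else sim.SEASONS


def _trait_vector(book: sim.PhenotypeBook, trait: str, season: str | None) -> pd.Series:
    if trait == "RA":
        return book.ratooning_ability()
    return book.line_means(season)[trait]


def _gene_codes(hap_sets, samples) -> np.ndarray:
    """Numeric per-line haplotype codes (genes x lines) for Meff estimation."""
    rows = []
    for hs in hap_sets:
        labs = {l: i for i, l in enumerate(hs.haplotypes)}
        a = hs.assignment.reindex(samples)
        rows.append(a.map(lambda l: labs.get(l, np.nan)).to_numpy(float))
    return np.asarray(rows)


def _stage_stats(config: RunConfig, state: dict, force: bool) -> dict:
    out = os.path.join(config.out_dir, "stats")
    os.makedirs(out, exist_ok=True)
    book: sim.PhenotypeBook = state["pheno"]
    corr_rows, anova_rows, herit_rows, reg_rows = [], [], [], []
    for trait in sim.TRAITS:
        r, p = tr.cross_season_correlation(book, trait)
        corr_rows.append({"trait": trait, "r": r, "p": p})
        part = tr.anova_partition(book, trait)
        anova_rows.append({"trait": trait, **{k: round(v, 3) for k, v in part.percent.items()}})
        h = tr.heritability(part)
        herit_rows.append({"trait": trait, "h2": round(h.h2, 4), "vg": h.vg, "v_gxe": h.v_gxe, "ve": h.ve})
    for season in sim.SEASONS:
        model = tr.yield_component_regression(book, season)
        for k in ("TN", "SPP", "PL"):
            reg_rows.append({"season": season, "component": k,
                             "beta": model.beta[k], "p": model.pvalues[k]})
    paths = {
        "stats/correlations.tsv": os.path.join(out, "correlations.tsv"),
        "stats/anova.tsv": os.path.join(out, "anova.tsv"),
        "stats/heritability.tsv": os.path.join(out, "heritability.tsv"),
        "stats/yield_regression.tsv": os.path.join(out, "yield_regression.tsv"),
    }
    pd.DataFrame(corr_rows).to_csv(paths["stats/correlations.tsv"], sep="\t", index=False, float_format="%.4g")
    pd.DataFrame(anova_rows).to_csv(paths["stats/anova.tsv"], sep="\t", index=False)
    pd.DataFrame(herit_rows).to_csv(paths["stats/heritability.tsv"], sep="\t", index=False, float_format="%.4g")
    pd.DataFrame(reg_rows).to_csv(paths["stats/yield_regression.tsv"], sep="\t", index=False, float_format="%.4g")
    return paths


def _stage_report(config: RunConfig, state: dict, force: bool) -> dict:
    out = os.path.join(config.out_dir, "report")
    os.makedirs(out, exist_ok=True)
    landmarks = rep.read_bed(config.landmarks_bed) if config.landmarks_bed else None
    qtls = []
    for (trait, season), (snp_df, gene_df) in state["scans"].items():
        recs = rep.call_qtls(
            snp_df, gene_df, state["thresholds"],
            merge_window_bp=config.merge_window_bp,
            trait=trait, season=season or "RA",
        )
        qtls.extend(recs)
    rep.name_qtls(qtls)
    if landmarks is not None:
        for q in qtls:
            rep.nearest_annotation(q, landmarks)
    table = rep.qtl_table(qtls)
    path = os.path.join(out, "qtls.tsv")
    table.to_csv(path, sep="\t", index=False, float_format="%.4g")
    state["qtls"] = qtls
    return {"report/qtls.tsv": path}
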