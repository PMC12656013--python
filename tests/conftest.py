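"""Shared fixtures: small simulated populations reused across the suite.

Session-scoped so the funnel simulation runs once; sizes are desk-scale but
keep the multi-chromosome, clustered-site structure of the full design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import magic_ratoon as mr
import magic_ratoon.simulate as sim


@pytest.fixture(scope="session")
def panel_small() -> mr.FounderPanel:
    return mr.build_founder_panel(n_chr=2, sites_per_chr=120, indel_fraction=0.1, seed=11)


@pytest.fixture(scope="session")
def pedigree_small() -> mr.FunnelPedigree:
    return mr.FunnelPedigree(
        n_eight_way_families=40, f2_plants_per_family=2,
        ssd_generations=6, n_selected_lines=80,
    )


@pytest.fixture(scope="session")
def lines_small(panel_small, pedigree_small):
    return mr.simulate_funnel(panel_small, pedigree_small, seed=12)


@pytest.fixture(scope="session")
def genes_small(panel_small):
    return mr.make_gene_models(panel_small, coding_fraction=0.9, seed=13)


@pytest.fixture(scope="session")
def book_small(panel_small, lines_small):
    return mr.simulate_phenotypes(panel_small, lines_small, seed=14)


@pytest.fixture(scope="session")
def bundle_small(tmp_path_factory, panel_small, lines_small, genes_small, book_small):
    out = tmp_path_factory.mktemp("bundle")
    paths = mr.write_synthetic_bundle(
        panel_small, lines_small, genes_small, book_small, out,
        fail_fraction=0.3, seed=15,
    )
    return paths


@pytest.fixture(scope="session")
def variants_small(bundle_small):
    from magic_ratoon.io import read_vcf

    return read_vcf(bundle_small["vcf"])


# --- a study-scale population (302 lines) for power / calibration checks ---


@pytest.fixture(scope="session")
def panel_302() -> mr.FounderPanel:
    return mr.build_founder_panel(n_chr=3, sites_per_chr=400, indel_fraction=0.1, seed=21)


@pytest.fixture(scope="session")
def lines_302(panel_302):
    ped = mr.FunnelPedigree()  # 144 families x 4 F2 plants, 5 SSD, 302 selected
    return mr.simulate_funnel(panel_302, ped, seed=22)


@pytest.fixture(scope="session")
def dosage_302(panel_302, lines_302) -> pd.DataFrame:
    return sim.dosage_matrix(panel_302, lines_302)


@pytest.fixture(scope="session")
def kinship_302(dosage_302):
    import magic_ratoon.lmm as lmm

    return lmm.kinship(dosage_302)


def qtl_architecture(panel, trait="PL", pve=0.20, chrom_i=0, frac=0.5):
    """Single aligned QTL on an otherwise polygenic trait (test helper)."""
    c = panel.chrom_names[chrom_i]
    pos = int(panel.positions[c][int(frac * len(panel.positions[c]))])
    spec = sim.TraitSpec(
        mean={"MC": 27.1, "RC": 18.4},
        sd={"MC": 3.1, "RC": 2.5},
        qtls={"MC": [sim.PlantedQTL.from_site(panel, c, pos, pve)], "RC": []},
        shared_var=0.30,
        batch_var=0.02,
        residual_var=0.10,
    )
    arch = mr.TraitArchitecture.default(panel)
    arch.traits[trait] = spec
    return arch, (c, pos)
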