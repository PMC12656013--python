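"""Descriptive and inferential trait statistics.

Ratooning ability, cross-season correlations, standardized yield-component
regression, two-way genotype x season ANOVA with a percent variance
partition, broad-sense heritability h2 = Vg / Vp, Duncan's multiple range
test, and haplotype-effect tables with letter groupings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SEASONS, TRAITS, PhenotypeBook

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ratooning ability and correlations
# ---------------------------------------------------------------------------


def ratooning_ability(tn_main, tn_ratoon):
    """RA = ratoon-crop tiller number / main-crop tiller number.

    Undefined (NaN, with a warning) when the main-crop TN is not positive.
    Accepts scalars or arrays; scale-invariant by construction.
    """
    main = np.asarray(tn_main, dtype=float)
    rat = np.asarray(tn_ratoon, dtype=float)
    bad = main <= 0
    if np.any(bad):
        warnings.warn("RA undefined where main-crop TN <= 0; returning NaN", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ra = np.where(bad, np.nan, rat / main)
    return float(ra) if ra.ndim == 0 else ra


def cross_season_correlation(phenotypes: PhenotypeBook, trait: str) -> tuple[float, float]:
    """Pearson r (and two-sided t-based p) between the main- and
    ratoon-crop line means of one trait."""
    mc = phenotypes.line_means("MC")[trait]
    rc = phenotypes.line_means("RC")[trait]
    both = mc.index.intersection(rc.index)
    if len(both) < 3:
        raise ValueError("need at least 3 lines phenotyped in both seasons")
    x, y = mc.loc[both], rc.loc[both]
    if x.std() == 0 or y.std() == 0:
        warnings.warn(f"{trait}: zero variance in one season; correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# yield-component regression
# ---------------------------------------------------------------------------


@dataclass
class YieldComponentModel:
    season: str
    beta: dict[str, float]       # standardized coefficients of GY on TN, SPP, PL
    pvalues: dict[str, float]
    n: int
    r_squared: float

    def summary(self) -> str:
        rows = "\n".join(
            f"  {k:>4}: beta = {self.beta[k]: .3f}  p = {self.pvalues[k]:.3g}"
            for k in ("TN", "SPP", "PL")
        )
        return (
            f"Standardized OLS of GY on yield components ({self.season}, n={self.n}, "
            f"R2={self.r_squared:.3f})\n{rows}"
        )


def yield_component_regression(phenotypes: PhenotypeBook, season: str) -> YieldComponentModel:
    """OLS of standardized GY on standardized TN, SPP and PL (line means)."""
    import statsmodels.api as sm

    means = phenotypes.line_means(season).dropna()
    if len(means) < 10:
        raise ValueError("need at least 10 complete lines")
    Z = (means - means.mean()) / means.std(ddof=1)
    X = sm.add_constant(Z[["TN", "SPP", "PL"]])
    cond = np.linalg.cond(X.to_numpy())
    if cond > 1e6:
        warnings.warn(f"collinear predictors (condition number {cond:.2g})")
    fit = sm.OLS(Z["GY"], X).fit()
    return YieldComponentModel(
        season=season,
        beta={k: float(fit.params[k]) for k in ("TN", "SPP", "PL")},
        pvalues={k: float(fit.pvalues[k]) for k in ("TN", "SPP", "PL")},
        n=len(means),
        r_squared=float(fit.rsquared),
    )


# ---------------------------------------------------------------------------
# ANOVA partition and heritability
# ---------------------------------------------------------------------------


@dataclass
class AnovaPartition:
    """Percent of total sum of squares per term of the two-way line x season
    ANOVA (sequential / type-I on per-replicate records)."""

    trait: str
    percent: dict[str, float]            # genotype / environment / gxe / residual
    table: pd.DataFrame = field(repr=False, default=None)
    n_replicates: int = 2
    n_seasons: int = 2
    degraded: bool = False               # single replicate: G x E folded into residual

    def __post_init__(self):
        total = sum(self.percent.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"percent components sum to {total}, not 100")


def anova_partition(phenotypes: PhenotypeBook, trait: str) -> AnovaPartition:
    """Sequential two-way ANOVA of per-replicate records on line, season and
    their interaction; returns percent of total SS per term."""
    df = phenotypes.frame[["line_id", "season", "replicate", trait]].dropna()
    counts = df.groupby(["line_id", "season"])[trait].count()
    n_rep = int(counts.min())
    y = df[trait].to_numpy(float)
    # sequential SS via explicit projections: factors are balanced here and
    # this stays fast for hundreds of line levels
    line_codes, _ = pd.factorize(df["line_id"])
    seas_codes, _ = pd.factorize(df["season"])
    sst = float(np.sum((y - y.mean()) ** 2))

    def group_ss(codes):
        means = pd.Series(y).groupby(codes).transform("mean").to_numpy()
        return float(np.sum((means - y.mean()) ** 2))

    ss_line = group_ss(line_codes)
    ss_line_seas = group_ss(np.char.add(line_codes.astype(str), np.char.add("_", seas_codes.astype(str))))
    ss_seas_only = group_ss(seas_codes)
    # sequential order: line, then season, then interaction
    ss_season = ss_seas_only  # orthogonal to line in a balanced crossed design
    ss_inter = ss_line_seas - ss_line - ss_season
    ss_resid = sst - ss_line_seas
    a = len(np.unique(line_codes))
    s = len(np.unique(seas_codes))
    degraded = n_rep < 2
    if degraded:
        log.warning("%s: single replicate; interaction confounded with residual", trait)
        ss_resid = sst - ss_line - ss_season
        ss_inter = 0.0
        table = pd.DataFrame(
            {
                "term": ["genotype", "environment", "residual"],
                "df": [a - 1, s - 1, (a - 1) * (s - 1)],
                "ss": [ss_line, ss_season, ss_resid],
            }
        )
        percent = {
            "genotype": 100 * ss_line / sst,
            "environment": 100 * ss_season / sst,
            "gxe": 0.0,
            "residual": 100 * ss_resid / sst,
        }
    else:
        table = pd.DataFrame(
            {
                "term": ["genotype", "environment", "gxe", "residual"],
                "df": [a - 1, s - 1, (a - 1) * (s - 1), a * s * (n_rep - 1)],
                "ss": [ss_line, ss_season, ss_inter, ss_resid],
            }
        )
        percent = {
            "genotype": 100 * ss_line / sst,
            "environment": 100 * ss_season / sst,
            "gxe": 100 * ss_inter / sst,
            "residual": 100 * ss_resid / sst,
        }
    table["ms"] = table["ss"] / table["df"].clip(lower=1)
    table["percent"] = 100 * table["ss"] / sst
    # guard against tiny negative sequential interaction SS from imbalance
    lo = min(percent.values())
    if lo < 0:
        if lo < -1e-6:
            warnings.warn(f"{trait}: negative sequential SS component ({lo:.2g}) clipped")
        percent = {k: max(v, 0.0) for k, v in percent.items()}
        scale = 100.0 / sum(percent.values())
        percent = {k: v * scale for k, v in percent.items()}
    return AnovaPartition(
        trait=trait,
        percent=percent,
        table=table,
        n_replicates=n_rep,
        n_seasons=s,
        degraded=degraded,
    )


@dataclass
class Heritability:
    trait: str
    h2: float
    vg: float
    v_gxe: float
    ve: float
    basis: str = "anova mean squares"

    @property
    def vp(self) -> float:
        return self.vg + self.v_gxe + self.ve


def heritability(partition: AnovaPartition) -> Heritability:
    """Broad-sense h2 = Vg / Vp with variance components from the ANOVA
    mean squares (Vp = Vg + V_GxE + Ve); negative estimates floor at 0."""
    tab = partition.table.set_index("term")
    r, s = partition.n_replicates, partition.n_seasons
    ms_g = float(tab.loc["genotype", "ms"])
    ms_ge = float(tab.loc["gxe", "ms"]) if "gxe" in tab.index else float(tab.loc["residual", "ms"])
    ms_e = float(tab.loc["residual", "ms"])
    ve = ms_e
    v_gxe = max((ms_ge - ms_e) / max(r, 1), 0.0)
    vg = max((ms_g - ms_ge) / max(r * s, 1), 0.0)
    vp = vg + v_gxe + ve
    if vp <= 0:
        raise ValueError("phenotypic variance is zero; h2 undefined")
    return Heritability(trait=partition.trait, h2=vg / vp, vg=vg, v_gxe=v_gxe, ve=ve)


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------


def _duncan_lsr(alpha: float, p: int, df: int, mse: float, n_h: float) -> float:
    """Least significant range for a span of p ordered means, with Duncan's
    protection level alpha_p = 1 - (1 - alpha)^(p-1)."""
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    q = stats.studentized_range.ppf(1.0 - alpha_p, p, df)
    return float(q * np.sqrt(mse / n_h))


def duncan_groups(values_by_class: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Duncan's multiple range test with letter display.

    Classes are ordered by descending mean; a span of p ordered means is
    declared different when its range exceeds the least significant range
    q(alpha_p, p, df) * sqrt(MSE / n_h) with alpha_p = 1 - (1-alpha)^(p-1)
    and n_h the harmonic mean of the class sizes (Kramer adjustment for
    unbalanced data).  Spans inside a non-significant span are protected
    (declared non-significant).  Letters are emitted in mean order, 'a' for
    the highest mean; any two classes sharing a letter are not
    significantly different.

    Returns a frame with columns class, mean, sd, n, letters.
    """
    labs = list(values_by_class)
    arrays = {k: np.asarray(values_by_class[k], float) for k in labs}
    arrays = {k: v[np.isfinite(v)] for k, v in arrays.items()}
    k = len(labs)
    if k < 1:
        raise ValueError("need at least one class")
    means = {l: float(a.mean()) for l, a in arrays.items()}
    sds = {l: float(a.std(ddof=1)) if len(a) > 1 else 0.0 for l, a in arrays.items()}
    ns = {l: len(a) for l, a in arrays.items()}
    order = sorted(labs, key=lambda l: -means[l])
    N = sum(ns.values())
    df_err = N - k
    if df_err <= 0 or k == 1:
        letters = {l: "a" for l in labs}
        if df_err <= 0:
            log.warning("zero error degrees of freedom; no test performed")
    else:
        sse = sum(float(np.sum((arrays[l] - means[l]) ** 2)) for l in labs)
        mse = sse / df_err
        n_h = k / sum(1.0 / max(ns[l], 1) for l in labs)
        m = np.asarray([means[l] for l in order])
        nonsig = np.zeros((k, k), dtype=bool)  # span i..j not significant
        for i in range(k):
            nonsig[i, i] = True
        # largest spans first: a span below its LSR protects every sub-span
        for span in range(k, 1, -1):
            lsr = _duncan_lsr(alpha, span, df_err, mse, n_h)
            for i in range(0, k - span + 1):
                j = i + span - 1
                if nonsig[i, j]:
                    continue  # already protected by an outer span
                if m[i] - m[j] < lsr:
                    for a in range(i, j + 1):
                        for b in range(a, j + 1):
                            nonsig[a, b] = True
        letters = _letter_display(order, nonsig)
    out = pd.DataFrame(
        {
            "class": order,
            "mean": [means[l] for l in order],
            "sd": [sds[l] for l in order],
            "n": [ns[l] for l in order],
            "letters": [letters[l] for l in order],
        }
    )
    return out


def _letter_display(order: list, nonsig: np.ndarray) -> dict:
    """Assign letters from maximal non-significant spans of ordered means."""
    k = len(order)
    spans = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        spans.append((i, j))
    # keep maximal spans only
    maximal = [
        (i, j)
        for (i, j) in spans
        if not any((a <= i and j <= b) and (a, b) != (i, j) for (a, b) in spans)
    ]
    maximal.sort()
    letters = {l: "" for l in order}
    for li, (i, j) in enumerate(maximal):
        ch = chr(ord("a") + (li % 26))
        for t in range(i, j + 1):
            letters[order[t]] += ch
    return letters


# ---------------------------------------------------------------------------
# haplotype effect tables
# ---------------------------------------------------------------------------


def class_differences(means_by_class: dict, reference: str) -> dict:
    """Each class mean minus the reference class mean (the narrative
    "increased by" convention of the effect tables)."""
    if reference not in means_by_class:
        raise ValueError(f"reference class {reference!r} absent")
    ref = means_by_class[reference]
    return {k: v - ref for k, v in means_by_class.items() if k != reference}


@dataclass
class HaplotypeEffectTable:
    gene_id: str
    reference: str
    table: pd.DataFrame  # rows trait x season x class: mean, sd, n, letters, diff_vs_ref

    def formatted(self) -> pd.DataFrame:
        """Wide view: one row per trait_season, 'mean +/- sd letters' cells."""
        t = self.table.copy()
        t["cell"] = [
            f"{m:.1f} ± {s:.1f} {l}" for m, s, l in zip(t["mean"], t["sd"], t["letters"])
        ]
        return t.pivot(index="row", columns="class", values="cell")


def haplotype_effect_table(
    gene_id: str,
    hap_set,
    phenotypes: PhenotypeBook,
    traits=TRAITS,
    alpha: float = 0.05,
    reference: str | None = None,
    min_class_size: int = 2,
) -> HaplotypeEffectTable:
    """Per trait x season (plus RA): class mean +/- SD, n, Duncan letters and
    the difference to the reference class.

    The reference defaults to the class carrying the most founders (when
    founder membership is known), else the most frequent class.  Classes
    below ``min_class_size`` are excluded from the letter test but still
    reported.
    """
    labs = list(hap_set.haplotypes)
    if not labs:
        raise ValueError(f"{gene_id}: no testable haplotype classes")
    if reference is None:
        if hap_set.parents:
            reference = max(labs, key=lambda l: (len(hap_set.parents.get(l, [])), -labs.index(l)))
        else:
            reference = labs[0]
    assign = hap_set.assignment
    rows = []
    blocks: list[tuple[str, pd.Series]] = []
    for trait in traits:
        for season in SEASONS:
            blocks.append((f"{trait}_{season}", phenotypes.line_means(season)[trait]))
    blocks.append(("RA", phenotypes.ratooning_ability()))
    for row_name, series in blocks:
        values = {
            l: series.reindex(assign.index[assign == l]).dropna().to_numpy()
            for l in labs
        }
        testable = {l: v for l, v in values.items() if len(v) >= min_class_size}
        if len(testable) >= 2:
            letters = duncan_groups(testable, alpha=alpha).set_index("class")["letters"]
        else:
            letters = pd.Series("", index=labs)
        means = {l: float(v.mean()) if len(v) else np.nan for l, v in values.items()}
        diffs = class_differences(means, reference)
        for l in labs:
            v = values[l]
            rows.append(
                {
                    "row": row_name,
                    "class": l,
                    "mean": means[l],
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                    "n": len(v),
                    "letters": letters.get(l, ""),
                    "diff_vs_ref": diffs.get(l, 0.0),
                    "parents": "/".join(hap_set.parents.get(l, [])),
                }
            )
    return HaplotypeEffectTable(gene_id=gene_id, reference=reference, table=pd.DataFrame(rows))
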