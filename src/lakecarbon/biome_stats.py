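"""Biome-level emission:burial statistics and regional upscaling.

Compares boreal against subarctic-arctic lakes on their annual carbon
emission:burial ratios (one-way ANOVA on log-transformed ratios),
regresses emission on burial within each biome, tests slope homogeneity
across biomes with an ANCOVA interaction term (optional lake-area and DOC
covariates), and upscales mean areal emission to a regional flux in
Tg C yr-1.

Ratios are always computed per lake before any aggregation — the mean of
ratios, never the ratio of means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

BIOMES = ("boreal", "subarctic_arctic")


@dataclass
class ComparisonResult:
    """Outcome of one biome comparison test."""

    test: str
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    group_means: dict
    group_sds: dict
    transform: str


def _validate_biomes(df: pd.DataFrame) -> None:
    bad = set(df["biome"].unique()) - set(BIOMES)
    if bad:
        raise ValueError(f"unknown biome labels: {sorted(bad)}")


def emission_burial_ratio(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-lake emission:burial ratios and per-biome mean +/- SD (raw scale).

    Only paired records (both emission and burial present) are used;
    zero-burial records are excluded with a flag column rather than
    producing infinite ratios.

    Returns ``(per_lake, summary)`` where ``per_lake`` adds a ``ratio``
    column and ``summary`` has one row per biome with mean, sd, n.
    """
    _validate_biomes(records)
    df = records.copy()
    paired = df["emission_gc_m2_yr"].notna() & df["burial_gc_m2_yr"].notna()
    df = df[paired].copy()
    df["excluded_zero_burial"] = df["burial_gc_m2_yr"] <= 0
    usable = df[~df["excluded_zero_burial"]].copy()
    usable["ratio"] = usable["emission_gc_m2_yr"] / usable["burial_gc_m2_yr"]
    summary = (
        usable.groupby("biome")["ratio"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    return usable, summary


def compare_ratios_anova(records: pd.DataFrame, transform: str = "log") -> ComparisonResult:
    """One-way two-group ANOVA on per-lake emission:burial ratios.

    Ratios are log-transformed by default (their distribution is strongly
    right-skewed); reported group means and SDs stay on the raw scale.
    F has (1, n-2) degrees of freedom and equals the squared pooled
    two-sample t statistic.
    """
    per_lake, summary = emission_burial_ratio(records)
    groups = {b: g["ratio"].to_numpy() for b, g in per_lake.groupby("biome")}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 ratio records in each biome")
    if transform == "log":
        vals = [np.log(groups[b]) for b in sorted(groups)]
    elif transform == "none":
        vals = [groups[b] for b in sorted(groups)]
    else:
        raise ValueError(f"unknown transform {transform!r}")
    f, p = stats.f_oneway(*vals)
    n = sum(len(v) for v in vals)
    return ComparisonResult(
        test="emission:burial ratio ANOVA",
        f_statistic=float(f),
        df_num=1,
        df_den=n - 2,
        p_value=float(p),
        group_means=dict(zip(summary["biome"], summary["mean"])),
        group_sds=dict(zip(summary["biome"], summary["sd"])),
        transform=transform,
    )


def regress_emission_on_burial(records: pd.DataFrame, biome: str) -> dict:
    """Within-biome OLS of annual emission on burial (both g C m-2 yr-1).

    Returns slope, intercept, their SEs, R-squared and the slope p value.
    """
    per_lake, _ = emission_burial_ratio(records)
    sub = per_lake[per_lake["biome"] == biome]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 paired records in biome {biome!r}")
    x = sub["burial_gc_m2_yr"].to_numpy()
    y = sub["emission_gc_m2_yr"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: burial has zero variance")
    res = stats.linregress(x, y)
    return {
        "biome": biome,
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "slope_se": float(res.stderr),
        "intercept_se": float(res.intercept_stderr),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n": int(len(sub)),
    }


def compare_slopes_ancova(
    records: pd.DataFrame,
    covariates: tuple[str, ...] = (),
) -> ComparisonResult:
    """Test homogeneity of the emission~burial slope across biomes (ANCOVA).

    Fits ``emission ~ burial * biome`` (plus optional log lake area and
    DOC covariates) and F-tests the burial x biome interaction.
    """
    per_lake, _ = emission_burial_ratio(records)
    counts = per_lake.groupby("biome").size()
    if len(counts) < 2 or (counts < 3).any():
        raise ValueError("both biomes need >= 3 paired records")
    df = per_lake.rename(
        columns={"emission_gc_m2_yr": "emission", "burial_gc_m2_yr": "burial"}
    ).copy()
    formula = "emission ~ burial * biome"
    for cov in covariates:
        if cov == "area":
            df["log_area"] = np.log(df["area_m2"])
            formula += " + log_area"
        elif cov == "doc":
            formula += " + doc_mg_l"
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    model = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    anova = sm.stats.anova_lm(model, typ=2)
    inter = anova.loc["burial:biome"]
    slopes = {
        b: float(stats.linregress(g["burial"], g["emission"]).slope)
        for b, g in df.groupby("biome")
    }
    return ComparisonResult(
        test="emission~burial slope homogeneity (ANCOVA interaction)",
        f_statistic=float(inter["F"]),
        df_num=int(inter["df"]),
        df_den=int(model.df_resid),
        p_value=float(inter["PR(>F)"]),
        group_means=slopes,
        group_sds={},
        transform="none",
    )


def compare_emissions_anova(records: pd.DataFrame, variable: str = "emission_gc_m2_yr",
                            transform: str = "log") -> ComparisonResult:
    """One-way ANOVA comparing a per-lake quantity (emission or burial) across biomes.

    Accepts unpaired records: any record with the variable present enters.
    """
    _validate_biomes(records)
    df = records[records[variable].notna() & (records[variable] > 0)]
    groups = {b: g[variable].to_numpy() for b, g in df.groupby("biome")}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 records per biome")
    vals = [np.log(groups[b]) if transform == "log" else groups[b] for b in sorted(groups)]
    f, p = stats.f_oneway(*vals)
    n = sum(len(v) for v in vals)
    return ComparisonResult(
        test=f"{variable} ANOVA",
        f_statistic=float(f),
        df_num=1,
        df_den=n - 2,
        p_value=float(p),
        group_means={b: float(v.mean()) for b, v in groups.items()},
        group_sds={b: float(v.std(ddof=1)) for b, v in groups.items()},
        transform=transform,
    )


def upscale_emission(
    mean_gc_m2_yr: float,
    sd_gc_m2_yr: float,
    lake_area_m2: float,
    n: int | None = None,
    uncertainty: str = "sd",
) -> dict:
    """Regional lake C flux, Tg C yr-1, from a mean areal emission.

    ``flux = mean x area x 1e-12``.  The uncertainty convention is SD
    propagation (``sd x area``), matching how the biome means are
    reported; ``"se"`` divides by sqrt(n) first.
    """
    if lake_area_m2 < 0:
        raise ValueError("lake area must be >= 0")
    if mean_gc_m2_yr < 0:
        raise ValueError("mean emission must be >= 0")
    spread = sd_gc_m2_yr
    if uncertainty == "se":
        if not n:
            raise ValueError("n required for SE-based uncertainty")
        spread = sd_gc_m2_yr / np.sqrt(n)
    elif uncertainty != "sd":
        raise ValueError(f"unknown uncertainty convention {uncertainty!r}")
    return {
        "flux_tg_c_yr": mean_gc_m2_yr * lake_area_m2 * 1e-12,
        "uncertainty_tg_c_yr": spread * lake_area_m2 * 1e-12,
        "convention": uncertainty,
    }


def plot_emission_burial(records: pd.DataFrame, path) -> None:
    """Scatter of paired emission vs burial per biome with OLS lines, plus an
    inset-style box plot of the per-lake emission:burial ratios."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    per_lake, _ = emission_burial_ratio(records)
    fig, (ax, bx) = plt.subplots(1, 2, figsize=(9, 4), width_ratios=[2, 1])
    markers = {"boreal": ("o", "tab:green"), "subarctic_arctic": ("s", "tab:blue")}
    for biome, g in per_lake.groupby("biome"):
        m, c = markers.get(biome, ("x", "gray"))
        ax.scatter(g["burial_gc_m2_yr"], g["emission_gc_m2_yr"], marker=m,
                   facecolors="none", edgecolors=c, label=biome)
        if len(g) >= 3 and np.ptp(g["burial_gc_m2_yr"]) > 0:
            reg = regress_emission_on_burial(records, biome)
            xs = np.linspace(g["burial_gc_m2_yr"].min(), g["burial_gc_m2_yr"].max(), 50)
            ax.plot(xs, reg["intercept"] + reg["slope"] * xs, color=c, lw=1)
    ax.set_xlabel("C burial (g C m$^{-2}$ yr$^{-1}$)")
    ax.set_ylabel("C emission (g C m$^{-2}$ yr$^{-1}$)")
    ax.legend(frameon=False, fontsize=8)
    groups = [g["ratio"].to_numpy() for _, g in per_lake.groupby("biome")]
    bx.boxplot(groups, tick_labels=list(per_lake.groupby("biome").groups), whis=(5, 95))
    bx.set_ylabel("emission : burial")
    bx.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def read_biome_table(path) -> pd.DataFrame:
    """Read a biome table CSV, dropping duplicate lakes (newest record wins)."""
    df = pd.read_csv(path)
    _validate_biomes(df)
    return df.drop_duplicates(subset="lake_id", keep="last").reset_index(drop=True)
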