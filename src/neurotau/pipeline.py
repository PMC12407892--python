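"""End-to-end composition of the analysis stages.

The pipeline runs in the order the analyses build on each other: per-unit
timescale estimation (binning -> autocorrelation -> mixture fit -> BIC
selection -> QC), power-law tail fits per group with the maximum group
cutoff used for pooled data, and selective-versus-non-selective timescale
comparisons (two-sided Wilcoxon rank-sum with Benjamini-Hochberg
correction across groups at FDR 0.01).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from statsmodels.stats.multitest import multipletests

from .acf import DegenerateSeriesError, compute_autocorrelogram
from .mixture import ExpMixtureModel, NoConvergedFitError
from .spikes import DEFAULT_BIN_WIDTH, bin_spikes
from .tails import PowerLawModel, cutoff_percentile, fit_pooled

__all__ = [
    "fit_unit_timescale",
    "fit_population_timescales",
    "tail_report",
    "selective_timescale_comparison",
    "full_pipeline",
]

FDR_ALPHA = 0.01


def fit_unit_timescale(train, bin_width: float = DEFAULT_BIN_WIDTH,
                       max_lag: float = 5.0, max_components: int = 4,
                       n_starts: int = 10, seed: int = 0):
    """Selected mixture fit for one unit; returns (results, reason).

    ``results`` is None when the unit is excluded (degenerate counts or no
    converged fit), with ``reason`` naming why.
    """
    counts = bin_spikes(train, bin_width)
    try:
        ac = compute_autocorrelogram(counts, max_lag=max_lag)
    except DegenerateSeriesError:
        return None, "degenerate: constant count series"
    except ValueError as err:
        return None, f"invalid: {err}"
    model = ExpMixtureModel(ac, n_starts=n_starts, seed=seed)
    try:
        fit = model.fit_select(max_components=max_components)
    except NoConvergedFitError:
        return None, "no converged fit"
    return fit, None


def fit_population_timescales(trains, bin_width: float = DEFAULT_BIN_WIDTH,
                              max_lag: float = 5.0, max_components: int = 4,
                              n_starts: int = 10, seed: int = 0,
                              ) -> pd.DataFrame:
    """Per-unit timescale table for a collection of spike trains."""
    rows = []
    for k, train in enumerate(trains):
        fit, reason = fit_unit_timescale(
            train, bin_width=bin_width, max_lag=max_lag,
            max_components=max_components, n_starts=n_starts,
            seed=seed + k)
        if fit is None:
            rows.append({"unit_id": train.unit_id, "M": 0,
                         "tau_eff": np.nan, "r2": np.nan,
                         "qc_pass": False, "excluded": reason})
        else:
            rows.append({"unit_id": train.unit_id, "M": fit.M,
                         "tau_eff": fit.tau_eff, "r2": fit.r_squared,
                         "qc_pass": fit.qc_pass, "excluded": None,
                         "taus": fit.taus.tolist(),
                         "coeffs": fit.coeffs.tolist()})
    return pd.DataFrame(rows)


def tail_report(samples, n_boot: int = 200, seed=None,
                decimation: int = 1) -> dict:
    """Power-law tail fit with bootstrap GOF, LLRs and cutoff percentile."""
    model = PowerLawModel(samples, decimation=decimation)
    fit = model.fit()
    p_boot = model.bootstrap_gof(fit, n_boot=n_boot, seed=seed)
    llrs = model.compare_distributions(fit)
    return {
        "gamma": fit.gamma, "theta": fit.theta, "n_tail": fit.n_tail,
        "ks": fit.ks, "ci_gamma": list(fit.ci_gamma), "p_boot": p_boot,
        "cutoff_percentile": cutoff_percentile(samples, fit.theta),
        "llr": [{"alternative": r.alternative, "r0": r.r0,
                 "r_norm": r.r_norm, "p_value": r.p_value,
                 "significant": r.significant} for r in llrs],
    }


def selective_timescale_comparison(tau_eff, selective, groups=None,
                                   fdr_alpha: float = FDR_ALPHA) -> pd.DataFrame:
    """Selective vs non-selective timescales per group (Wilcoxon + BH).

    Two-sided Wilcoxon rank-sum of tau_eff between selective and
    non-selective units within each group, Benjamini-Hochberg corrected
    across groups at the given FDR.
    """
    tau_eff = np.asarray(tau_eff, dtype=float)
    selective = np.asarray(selective, dtype=bool)
    groups = (np.zeros(tau_eff.size, dtype=int) if groups is None
              else np.asarray(groups))
    rows = []
    for grp in pd.unique(groups):
        idx = groups == grp
        sel = tau_eff[idx & selective]
        non = tau_eff[idx & ~selective]
        if sel.size == 0 or non.size == 0:
            rows.append({"group": grp, "n_selective": sel.size,
                         "n_nonselective": non.size, "statistic": np.nan,
                         "p_value": np.nan})
            continue
        stat, p = ranksums(sel, non)
        rows.append({"group": grp, "n_selective": sel.size,
                     "n_nonselective": non.size,
                     "median_selective": float(np.median(sel)),
                     "median_nonselective": float(np.median(non)),
                     "statistic": float(stat), "p_value": float(p)})
    df = pd.DataFrame(rows)
    ok = df["p_value"].notna()
    df["significant"] = False
    if ok.any():
        rej, p_adj, _, _ = multipletests(df.loc[ok, "p_value"],
                                         alpha=fdr_alpha, method="fdr_bh")
        df.loc[ok, "p_adjusted"] = p_adj
        df.loc[ok, "significant"] = rej
    return df


def full_pipeline(trains_by_group: dict, n_boot: int = 200, seed: int = 0,
                  selectivity_by_unit: pd.DataFrame | None = None,
                  decimation: int = 1, **fit_kwargs) -> dict:
    """Timescale estimation, tail fits and comparisons for grouped units.

    ``trains_by_group`` maps a group name (e.g. brain structure) to its
    spike trains. Pooled tail fits across groups use the maximum group
    cutoff. ``selectivity_by_unit`` (columns unit_id, variable, selective)
    triggers the selective-vs-non-selective comparison per variable.
    """
    if not trains_by_group or all(len(v) == 0
                                  for v in trains_by_group.values()):
        raise ValueError("no input spike trains")
    report = {"groups": {}, "pooled": None}
    samples_by_group = {}
    frames = []
    for gi, (name, trains) in enumerate(trains_by_group.items()):
        df = fit_population_timescales(trains, seed=seed + 1000 * gi,
                                       **fit_kwargs)
        df["group"] = name
        frames.append(df)
        good = df.loc[df["qc_pass"], "tau_eff"].dropna().to_numpy()
        entry = {
            "n_units": len(df),
            "n_qc_pass": int(df["qc_pass"].sum()),
            "median_tau": float(np.median(good)) if good.size else np.nan,
            "iqr_tau": ([float(np.percentile(good, 25)),
                         float(np.percentile(good, 75))]
                        if good.size else None),
        }
        if good.size >= 30:
            entry["tail"] = tail_report(good, n_boot=n_boot,
                                        seed=seed + 7 * gi,
                                        decimation=decimation)
            samples_by_group[name] = good
        report["groups"][name] = entry
    table = pd.concat(frames, ignore_index=True)
    if len(samples_by_group) >= 1:
        groups = list(samples_by_group.values())
        pooled_fit = fit_pooled(groups, decimation=decimation)
        pooled_samples = np.concatenate(groups)
        report["pooled"] = {
            "gamma": pooled_fit.gamma, "theta": pooled_fit.theta,
            "n_tail": pooled_fit.n_tail, "ks": pooled_fit.ks,
            "cutoff_percentile": cutoff_percentile(pooled_samples,
                                                   pooled_fit.theta),
        }
    if selectivity_by_unit is not None:
        merged = table.merge(selectivity_by_unit, on="unit_id")
        comparisons = {}
        for variable, sub in merged.groupby("variable"):
            ok = sub["qc_pass"] & sub["tau_eff"].notna()
            comp = selective_timescale_comparison(
                sub.loc[ok, "tau_eff"], sub.loc[ok, "selective"],
                groups=sub.loc[ok, "group"])
            comparisons[variable] = comp.to_dict(orient="records")
        report["selectivity_comparisons"] = comparisons
    report["per_unit"] = table.drop(columns=["taus", "coeffs"],
                                    errors="ignore").to_dict(orient="records")
    return report
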