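"""End-to-end workflow: simulate/load -> phenotype -> survival models -> report.

Runs the full analysis: z-score the feature matrix, feature-level consensus
clustering with CDF-based k selection, first-PC signatures, tumor-level
consensus phenotyping with a SigClust check, a patient-characteristics
association block, then per endpoint (PFS, OS) the univariable screen, Cox
models with and without phenotype, nested likelihood-ratio tests, Uno
c-statistics with bootstrap CIs, and the median-prognostic-score
dichotomization.  One seed controls the whole run and reruns with the same
config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association_tests as at
from . import phenotyping as ph
from . import survival_models as sm
from .synthetic_cohort import CohortConfig, encode_covariates, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_analysis", "make_report", "report_from_tsv"]

_ENDPOINTS = {
    "PFS": ("time_to_progression", "progression"),
    "OS": ("time_to_death", "death"),
}
SCREEN_CANDIDATES = ("age", "smoking_status", "ecog", "line_of_therapy")
ALWAYS_KEEP = ("n_mutations",)


@dataclass
class RunConfig:
    """One fully-specified analysis run (simulated or from input files)."""

    features_path: str | None = None
    clinical_path: str | None = None
    simulate: CohortConfig | None = None
    endpoints: tuple[str, ...] = ("PFS", "OS")
    feature_k_range: tuple[int, int] = (2, 40)     # inclusive bounds
    phenotype_k_range: tuple[int, int] = (2, 5)
    n_resamples: int = 500
    subsample_frac: float = 0.8
    cdf_cutoff: float = 0.10
    tumor_distance: str = "euclidean"
    screen_threshold: float = 0.2
    sigclust_n_sim: int = 1000
    n_boot: int = 1000
    seed: int = 0
    outdir: str | None = None
    make_plots: bool = False  # consensus CDFs + KM curves, needs matplotlib

    def __post_init__(self) -> None:
        has_files = self.features_path is not None and self.clinical_path is not None
        if has_files == (self.simulate is not None):
            raise ValueError("provide exactly one of (features+clinical paths) or a simulation config")
        unknown = set(self.endpoints) - set(_ENDPOINTS)
        if unknown:
            raise ValueError(f"unknown endpoints: {sorted(unknown)}")


def _load_inputs(config: RunConfig):
    if config.simulate is not None:
        cohort = generate_cohort(config.simulate)
        return cohort.features, cohort.clinical
    features = pd.read_csv(config.features_path, index_col=0)
    clinical = pd.read_csv(config.clinical_path, index_col=0)
    if not features.index.equals(clinical.index):
        missing = features.index.symmetric_difference(clinical.index)
        raise ValueError(f"feature and clinical tables disagree on patient ids: {list(missing)[:5]}")
    return features, clinical


def _model_block(
    data: pd.DataFrame,
    covariates: list[str],
    time_col: str,
    event_col: str,
    tau: float,
    n_boot: int,
    seed: int,
) -> dict:
    fit = sm.cox_fit(data, covariates, time_col, event_col)
    lrt_stat, lrt_df, lrt_p = sm.lrt_nested(fit, None)
    c, lo, hi = sm.bootstrap_c_ci(
        data, covariates, time_col, event_col, tau=tau, n_boot=n_boot, seed=seed
    )
    return {
        "covariates": covariates,
        "rows": fit.summary().to_dict(orient="records"),
        "loglik": fit.loglik,
        "loglik_null": fit.loglik_null,
        "lrt_vs_null": {"statistic": lrt_stat, "df": lrt_df, "p": lrt_p},
        "c_statistic": {"c": c, "ci_low": lo, "ci_high": hi, "tau": tau,
                        "ci_method": f"bootstrap percentile, {n_boot} resamples"},
        "_fit": fit,
    }


def _endpoint_analysis(design: pd.DataFrame, endpoint: str, config: RunConfig) -> dict:
    time_col, event_col = _ENDPOINTS[endpoint]
    data = design
    if data[event_col].sum() < 1:
        raise sm.NoEventsError(f"{endpoint}: no observed events")
    tau = float(data.loc[data[event_col] == 1, time_col].max())

    out: dict = {"endpoint": endpoint, "tau_days": tau}

    # univariable block: each candidate plus phenotype on its own
    screen = sm.univariable_screen(
        data,
        list(SCREEN_CANDIDATES),
        time_col,
        event_col,
        threshold=config.screen_threshold,
        always_keep=ALWAYS_KEEP,
    )
    uni_rows = []
    for name in list(SCREEN_CANDIDATES) + list(ALWAYS_KEEP) + ["phenotype"]:
        try:
            f = sm.cox_fit(data, [name], time_col, event_col)
        except (sm.NoEventsError, sm.SingularInformationError, sm.ConvergenceError) as exc:
            warnings.warn(f"{endpoint}: univariable fit failed for {name!r}: {exc}")
            continue
        uni_rows.extend(f.summary().to_dict(orient="records"))
    out["univariable"] = uni_rows
    out["screen"] = {"retained": screen["retained"], "p_values": screen["p_values"]}

    reduced_covs = sorted(set(screen["retained"]) | set(ALWAYS_KEEP))
    full_covs = reduced_covs + ["phenotype"]

    phen_only = _model_block(data, ["phenotype"], time_col, event_col, tau, config.n_boot, config.seed + 11)
    reduced = _model_block(data, reduced_covs, time_col, event_col, tau, config.n_boot, config.seed + 13)
    full = _model_block(data, full_covs, time_col, event_col, tau, config.n_boot, config.seed + 17)
    stat, df, p = sm.lrt_nested(full.pop("_fit"), reduced["_fit"])
    full["lrt_vs_without_phenotype"] = {"statistic": stat, "df": df, "p": p}

    # K-M by phenotype, with NR-aware medians, and the median-score split
    km_medians = {}
    for g in (0, 1):
        sel = data["phenotype"] == g
        curve = sm.km_estimate(data.loc[sel, time_col], data.loc[sel, event_col])
        km_medians[f"phenotype_{g + 1}"] = curve.median
    lr_stat, lr_p = sm.logrank_test(data[time_col], data[event_col], data["phenotype"])
    full_fit = sm.cox_fit(data, full_covs, time_col, event_col)
    dich = sm.prognostic_dichotomize(full_fit, data, time_col, event_col)

    reduced.pop("_fit")
    phen_only.pop("_fit")
    out["models"] = {
        "phenotype_only": phen_only,
        "without_phenotype": reduced,
        "with_phenotype": full,
    }
    out["km_by_phenotype"] = {
        "median_days": km_medians,
        "logrank_statistic": lr_stat,
        "logrank_p": lr_p,
    }
    out["median_score_split"] = {
        "median_score": dich["median_score"],
        "logrank_statistic": dich["logrank_statistic"],
        "logrank_p": dich["logrank_p"],
    }
    return out


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and return the JSON-serializable report."""
    run_warnings: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        features, clinical = _load_inputs(config)

        z = ph.zscore_features(features)
        feat_dist = ph.correlation_distance(z)
        k_lo, k_hi = config.feature_k_range
        k_hi = min(k_hi, z.values.shape[1] - 1)
        feat_consensus = ph.consensus_cluster(
            feat_dist.to_numpy(),
            range(k_lo, k_hi + 1),
            n_resamples=config.n_resamples,
            subsample_frac=config.subsample_frac,
            seed=config.seed,
        )
        k_feat = ph.select_k_by_cdf(feat_consensus, cutoff=config.cdf_cutoff)
        feat_labels = ph.hierarchical_cut(1.0 - feat_consensus.consensus[k_feat], k_feat)
        feat_labels = pd.Series(feat_labels, index=z.values.columns)
        signatures = ph.derive_signatures(z, feat_labels)

        pk_lo, pk_hi = config.phenotype_k_range
        assignment = ph.assign_phenotypes(
            signatures,
            k_range=range(pk_lo, min(pk_hi, len(signatures.values) - 1) + 1),
            n_resamples=config.n_resamples,
            subsample_frac=config.subsample_frac,
            seed=config.seed + 1,
            tumor_distance=config.tumor_distance,
            cdf_cutoff=config.cdf_cutoff,
        )
        if assignment.n_phenotypes == 2:
            assignment.sigclust_p = ph.sigclust_test(
                signatures.values.to_numpy(),
                assignment.labels.to_numpy(),
                n_sim=config.sigclust_n_sim,
                seed=config.seed + 2,
            )

        association = at.association_report(clinical, assignment.labels.to_numpy())

        design = encode_covariates(clinical, assignment.labels.to_numpy())
        for col in ("time_to_progression", "progression", "time_to_death", "death"):
            if col in clinical.columns:
                design[col] = clinical[col].astype(float)

        endpoints = {}
        for endpoint in config.endpoints:
            time_col, event_col = _ENDPOINTS[endpoint]
            if time_col not in design.columns:
                raise ValueError(f"clinical table lacks {time_col!r} for endpoint {endpoint}")
            try:
                endpoints[endpoint] = _endpoint_analysis(design, endpoint, config)
            except sm.NoEventsError as exc:
                raise sm.NoEventsError(f"stage survival[{endpoint}]: {exc}") from exc
        run_warnings = sorted({str(w.message) for w in caught})

    report = {
        "config": _config_dict(config),
        "phenotyping": {
            "n_tumors": int(len(z.values)),
            "n_features_retained": int(z.values.shape[1]),
            "dropped_features": z.dropped,
            "selected_feature_k": int(k_feat),
            "feature_cdf_areas": {str(k): feat_consensus.areas[k] for k in feat_consensus.ks},
            "selected_phenotype_k": int(assignment.n_phenotypes),
            "phenotype_cdf_areas": {
                str(k): assignment.consensus.areas[k] for k in assignment.consensus.ks
            },
            "phenotype_sizes": assignment.labels.value_counts().sort_index().to_dict(),
            "sigclust_p": assignment.sigclust_p,
        },
        "association": association,
        "endpoints": endpoints,
        "warnings": run_warnings,
    }
    for msg in run_warnings:
        logger.warning("run_analysis: %s", msg)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        signatures.values.to_csv(outdir / "signatures.csv")
        assignment.labels.to_frame().to_csv(outdir / "phenotypes.csv")
        pd.DataFrame(
            feat_consensus.consensus[k_feat], index=z.values.columns, columns=z.values.columns
        ).to_csv(outdir / "feature_consensus.csv")
        make_report(report, "json", outdir)
        if config.make_plots:
            _save_plots(outdir, feat_consensus, design, config)
    return report


def _save_plots(outdir: Path, feat_consensus, design: pd.DataFrame, config: RunConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for k in feat_consensus.ks:
        ax1.plot(feat_consensus.cdf_grid, feat_consensus.cdfs[k], lw=0.8)
    ax1.set(xlabel="consensus value", ylabel="CDF", title="feature-level consensus CDFs")
    ax2.plot(feat_consensus.ks, [feat_consensus.areas[k] for k in feat_consensus.ks], "o-")
    ax2.axvline(feat_consensus.selected_k, ls="--", color="red")
    ax2.set(xlabel="k", ylabel="area under CDF", title="CDF delta-area k selection")
    fig.tight_layout()
    fig.savefig(outdir / "consensus_cdf.png", dpi=120)
    plt.close(fig)

    for endpoint in config.endpoints:
        time_col, event_col = _ENDPOINTS[endpoint]
        if time_col not in design.columns:
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        for g, label in ((0.0, "phenotype 1"), (1.0, "phenotype 2")):
            sel = design["phenotype"] == g
            if sel.sum() == 0:
                continue
            curve = sm.km_estimate(design.loc[sel, time_col], design.loc[sel, event_col])
            ax.step(curve.times, curve.survival, where="post", label=label)
        ax.set(xlabel="days", ylabel="survival", title=f"{endpoint} by radiomic phenotype",
               ylim=(0, 1.02))
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / f"km_{endpoint.lower()}.png", dpi=120)
        plt.close(fig)


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    if d.get("simulate") is not None:
        d["simulate"] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d["simulate"].items()}
    return d


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _render_nr(value):
    return "NR" if value is None else value


def _flatten(obj, prefix="") -> list[tuple[str, object]]:
    items: list[tuple[str, object]] = []
    if isinstance(obj, dict) and obj:
        for k, v in obj.items():
            items.extend(_flatten(v, f"{prefix}{k}."))
    elif isinstance(obj, (list, tuple)) and obj:
        for i, v in enumerate(obj):
            items.extend(_flatten(v, f"{prefix}{i}."))
    else:  # scalars and empty containers are leaves
        items.append((prefix[:-1], obj))
    return items


def _unflatten(pairs) -> object:
    root: dict = {}
    for key, value in pairs:
        parts = key.split(".")
        node = root
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value

    def listify(node):
        if isinstance(node, dict):
            node = {k: listify(v) for k, v in node.items()}
            keys = list(node.keys())
            # only contiguous 0..n-1 keys denote a list (digit keys like the
            # per-k CDF areas stay a dict)
            if keys and sorted(keys) == [str(i) for i in sorted(range(len(keys)))] and set(keys) == {
                str(i) for i in range(len(keys))
            }:
                return [node[str(i)] for i in range(len(keys))]
        return node

    return listify(root)


def make_report(report: dict, fmt: str, outdir) -> Path:
    """Serialize the analysis report deterministically.

    ``json`` writes the full nested report; ``tsv`` writes flat
    dotted-key/value lines with full-precision floats (round-trippable via
    :func:`report_from_tsv`); ``markdown`` renders the model tables with
    undefined survival medians shown as "NR" (not reached).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path = outdir / "report.json"
        path.write_text(json.dumps(report, indent=2, default=_json_default) + "\n")
        return path
    if fmt == "tsv":
        path = outdir / "report.tsv"
        lines = ["key\tvalue"]
        for key, value in _flatten(report):
            if isinstance(value, float):
                rendered = repr(value)
            else:
                rendered = json.dumps(value, default=_json_default)
            lines.append(f"{key}\t{rendered}")
        path.write_text("\n".join(lines) + "\n")
        return path
    if fmt == "markdown":
        path = outdir / "report.md"
        path.write_text(_render_markdown(report))
        return path
    raise ValueError(f"unknown report format {fmt!r}")


def report_from_tsv(path) -> dict:
    """Rebuild the nested report from a tsv serialization (full precision)."""
    pairs = []
    lines = Path(path).read_text().splitlines()[1:]
    for line in lines:
        key, _, raw = line.partition("\t")
        try:
            value = json.loads(raw)
        except json.JSONDecodeError:
            value = float(raw)
        pairs.append((key, value))
    return _unflatten(pairs)


def _fmt_p(p: float) -> str:
    return "< 0.005" if p < 0.005 else f"{p:.2g}"


def _render_markdown(report: dict) -> str:
    lines = ["# Radiomic phenotype analysis report", ""]
    phen = report.get("phenotyping", {})
    lines += [
        f"- derived feature clusters (k): {phen.get('selected_feature_k')}",
        f"- phenotypes: {phen.get('selected_phenotype_k')} "
        f"(sizes {phen.get('phenotype_sizes')}, SigClust p = {phen.get('sigclust_p')})",
        "",
        "## Phenotype-covariate associations",
        "",
        "| Covariate | Test | p |",
        "| --- | --- | --- |",
    ]
    for row in report.get("association", []):
        lines.append(f"| {row['covariate']} | {row['test']} | {_fmt_p(row['p'])} |")
    for name, ep in report.get("endpoints", {}).items():
        lines += ["", f"## {name}", "", "| Model | Covariate | HR (95% CI) | p |", "| --- | --- | --- | --- |"]
        for model_name, block in ep.get("models", {}).items():
            for row in block["rows"]:
                hr = f"{row['hr']:.2f} ({row['hr_ci_low']:.2f}, {row['hr_ci_high']:.2f})"
                lines.append(f"| {model_name} | {row['covariate']} | {hr} | {_fmt_p(row['p'])} |")
        lines += ["", "| Model | c-statistic (95% CI) | LRT p vs null | LRT p vs without phenotype |", "| --- | --- | --- | --- |"]
        for model_name, block in ep.get("models", {}).items():
            c = block["c_statistic"]
            cs = f"{c['c']:.2f} ({c['ci_low']:.2f}-{c['ci_high']:.2f})"
            p_null = _fmt_p(block["lrt_vs_null"]["p"])
            p_nested = (
                _fmt_p(block["lrt_vs_without_phenotype"]["p"])
                if "lrt_vs_without_phenotype" in block
                else ""
            )
            lines.append(f"| {model_name} | {cs} | {p_null} | {p_nested} |")
        med = ep.get("km_by_phenotype", {}).get("median_days", {})
        med_txt = ", ".join(f"{k}: {_render_nr(v)}" for k, v in med.items())
        lines += ["", f"Median survival (days) by phenotype: {med_txt}",
                  f"Median-prognostic-score split log-rank p: {_fmt_p(ep['median_score_split']['logrank_p'])}"]
    return "\n".join(lines) + "\n"
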