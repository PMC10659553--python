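"""End-to-end orchestration: cohort simulation → metric extraction →
group statistics → summary tables, figures and provenance."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import cvr as _cvr
from .synth import CohortData, CohortSpec, gen_cohort

__all__ = ["RunConfig", "extract_cvr_metrics", "cohort_summary",
           "run_pipeline", "render_report", "significance_stars"]

log = logging.getLogger("vasoreact")


class RunConfig(BaseModel):
    """Full pipeline configuration; every field has a default equal to the
    package's documented stage defaults.  Unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "cvr", "vessels", "density", "stats")
    out_dir: str | None = None
    # CVR extraction
    smooth_window_s: float = 30.0
    recovery_k: float = 1.0
    recovery_dwell_s: float = 60.0
    # density / morphology / doppler stage parameters (documented defaults)
    fill_factor_window: int = 60
    density_sigma: float = 3.0
    frangi_small_scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    frangi_large_scales: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0)
    doppler_lambda0_mm: float = 0.00131
    doppler_n: float = 1.38
    doppler_t_s: float = 0.000167
    doppler_theta_rad: float = 0.0
    cohort: CohortSpec = Field(default_factory=CohortSpec)

    def with_seed(self, seed: int) -> "RunConfig":
        cfg = self.model_copy(deep=True)
        cfg.seed = seed
        cfg.cohort.seed = seed
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()).hexdigest()[:16]


def extract_cvr_metrics(cohort: CohortData, smooth_window_s: float = 30.0,
                        k: float = 1.0, dwell_s: float = 60.0) -> pd.DataFrame:
    """Run the CVR metric extraction on every animal's class-mean trace."""
    rows = []
    cvr_animals = cohort.animals[cohort.animals["cohort"] == "cvr"]
    for _, a in cvr_animals.iterrows():
        aid = a["animal_id"]
        for cls in cohort.traces[aid]:
            trace = cohort.traces[aid][cls].mean(axis=0)
            m = _cvr.cvr_metrics(cohort.time_s, trace, cohort.t_inject_s,
                                 cohort.baseline_window_s, k=k,
                                 dwell_s=dwell_s,
                                 smooth_window_s=smooth_window_s)
            for metric, val in (("peak", m.peak_response_pct),
                                ("ir", m.integrated_reactivity),
                                ("rt", m.recovery_time_min)):
                rows.append({"animal_id": aid, "group": a["group"],
                             "sex": a["sex"], "roi_class": cls,
                             "metric": metric, "value": val,
                             "recovered": m.recovered})
    return pd.DataFrame(rows)


def _group_stats(values: pd.DataFrame) -> list[dict]:
    """Per (roi_class, metric): group mean ± SEM and the WT-vs-AD t-test."""
    out = []
    for (cls, metric), sub in values.groupby(["roi_class", "metric"]):
        wt = sub[sub["group"] == "WT"]["value"].to_numpy()
        ad = sub[sub["group"] == "AD"]["value"].to_numpy()
        t = df = p = np.nan
        if wt.size >= 2 and ad.size >= 2:
            t, df, p = _cvr.group_ttest(wt, ad)
        for g, v in (("WT", wt), ("AD", ad)):
            sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
            out.append({"roi_class": cls, "metric": metric, "group": g,
                        "mean": float(v.mean()), "sem": sem, "n": int(v.size),
                        "t": t, "df": df, "p": p})
    return out


def cohort_summary(cohort: CohortData, metrics: pd.DataFrame | None = None,
                   smooth_window_s: float = 30.0, k: float = 1.0,
                   dwell_s: float = 60.0) -> pd.DataFrame:
    """Long-format summary table (group, roi_class/order, metric, mean,
    SEM, n, p) across the CVR, vessel and density arms."""
    rows: list[dict] = []
    if cohort.traces:
        if metrics is None:
            metrics = extract_cvr_metrics(cohort, smooth_window_s, k, dwell_s)
        rows += _group_stats(metrics)
    if cohort.vessels is not None and len(cohort.vessels):
        per_animal = (cohort.vessels
                      .groupby(["animal_id", "group", "sex", "order"],
                               as_index=False)
                      .agg(cbfv=("cbfv_mm_s", "mean"),
                           diameter=("phi_um", "mean")))
        long = per_animal.melt(id_vars=["animal_id", "group", "sex", "order"],
                               value_vars=["cbfv", "diameter"],
                               var_name="metric", value_name="value")
        long = long.rename(columns={"order": "roi_class"})
        rows += _group_stats(long)
    if cohort.density is not None and len(cohort.density):
        per_animal = (cohort.density
                      .groupby(["animal_id", "group", "sex", "metric"],
                               as_index=False)["value"].mean())
        per_animal["roi_class"] = "capillary"
        rows += _group_stats(per_animal)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Simulate a cohort under ``config`` and reduce it to the summary
    table; deterministic given config (the cohort seed follows the root
    seed).  If ``out_dir`` is set, writes the table, per-animal metrics
    and a provenance record."""
    cfg = config.with_seed(config.seed)
    cohort = gen_cohort(cfg.cohort)
    metrics = None
    if cohort.traces:
        metrics = extract_cvr_metrics(cohort, cfg.smooth_window_s,
                                      cfg.recovery_k, cfg.recovery_dwell_s)
    table = cohort_summary(cohort, metrics, cfg.smooth_window_s,
                           cfg.recovery_k, cfg.recovery_dwell_s)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "summary.csv", index=False)
        if metrics is not None:
            metrics.to_csv(out / "cvr_metrics.csv", index=False)
        cohort.truth.to_csv(out / "ground_truth.csv", index=False)
        import importlib.metadata as im

        try:
            ver = im.version("vasoreact")
        except im.PackageNotFoundError:
            ver = "unknown"
        prov = {"config": json.loads(cfg.model_dump_json()),
                "config_hash": cfg.config_hash(), "package_version": ver,
                "numpy_version": np.__version__}
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))
        log.info("pipeline artifacts written to %s", out)
    return table


def significance_stars(p: float) -> str:
    """Annotation convention: *p<0.05, **p<0.01, ***p<0.001, else NS."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


_PANELS = {
    "peak": ("Peak response", "%"),
    "ir": ("Integrated reactivity", "%·min"),
    "rt": ("Recovery time", "min"),
    "cbfv": ("CBFv", "mm/s"),
    "diameter": ("Vessel diameter", "μm"),
    "ff_max": ("Max density", "a.u."),
    "ff_mean": ("Mean density", "a.u."),
}


def render_report(table: pd.DataFrame, out_dir: str | Path) -> Path:
    """Bar charts (mean ± SEM, significance stars) and a markdown summary."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if table is None or not len(table):
        raise ValueError("summary table is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# Cohort summary", "",
             "| metric | class | WT (mean±SEM) | AD (mean±SEM) | p | |",
             "|---|---|---|---|---|---|"]
    for metric in table["metric"].unique():
        sub = table[table["metric"] == metric]
        classes = sub["roi_class"].unique()
        fig, ax = plt.subplots(figsize=(1.6 * max(len(classes), 2) + 1, 3))
        width = 0.35
        xs = np.arange(len(classes))
        for off, (g, color) in enumerate((("WT", "0.6"), ("AD", "tab:red"))):
            rows = [sub[(sub["roi_class"] == c) & (sub["group"] == g)]
                    for c in classes]
            means = [float(r["mean"].iloc[0]) if len(r) else np.nan for r in rows]
            sems = [float(r["sem"].iloc[0]) if len(r) else 0.0 for r in rows]
            ax.bar(xs + (off - 0.5) * width, means, width, yerr=sems,
                   capsize=3, label=g, color=color)
        for xi, c in enumerate(classes):
            r = sub[(sub["roi_class"] == c)]
            if not len(r):
                log.warning("panel %s/%s empty; omitted", metric, c)
                continue
            p = float(r["p"].iloc[0])
            star = significance_stars(p)
            top = (r["mean"].abs() + r["sem"]).max()
            ax.text(xi, top * 1.05 * np.sign(r["mean"].iloc[0] or 1), star,
                    ha="center")
            wt = r[r["group"] == "WT"].iloc[0]
            ad = r[r["group"] == "AD"].iloc[0]
            lines.append(f"| {metric} | {c} | {wt['mean']:.3f}±{wt['sem']:.3f}"
                         f" | {ad['mean']:.3f}±{ad['sem']:.3f}"
                         f" | {p:.4g} | {star} |")
        title, unit = _PANELS.get(metric, (metric, ""))
        ax.set_xticks(xs, classes)
        ax.set_ylabel(f"{title} ({unit})")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out / f"panel_{metric}.png", dpi=120)
        plt.close(fig)
    (out / "summary.md").write_text("\n".join(lines) + "\n")
    return out / "summary.md"
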