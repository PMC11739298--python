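"""End-to-end orchestration: simulate or ingest a cohort, preprocess,
quantify, test, and emit a results bundle mirroring the study's analysis
structure (baseline behavior, hourly delta gain, NREMS proportions,
burden, ELISA, correlations).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocessing, spectral, stats, synthetic, tissue
from .core import ParameterError
from .preprocessing import FilterDesign

__all__ = ["RunConfig", "ResultsBundle", "PipelineError", "run_pipeline",
           "make_report", "analyze_cohort"]


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one end-to-end run; every field is echoed into the
    provenance record. Unknown keys in a config file are rejected."""

    cohort: str = "early"
    seed: int = 0
    recording_hours: float = 24.0
    fs_native: float = 198.7
    delta_gain_effect_pp: float = 8.0
    effect_decay_h: float = 2.0
    clipping_rate_per_h: float = 1.0
    spike_rate_per_h: float = 4.0
    n_per_cell: int | None = None       # override the example design sizes
    delta_band: tuple = (0.5, 4.0)
    summary_hours: tuple = (9, 10)
    summary_mode: str = "mean"
    min_epochs_per_hour: int = 15
    clip_threshold_frac: float = 0.999
    clip_min_run: int = 2
    fermi_edge_frac: float = 0.01
    iqr_mult: float = 8.0
    max_run: int = 7
    hp_trans: tuple = (0.25, 0.5)
    lp_trans: tuple = (30.0, 33.0)
    atten_db: float = 40.0
    t_variant: str = "student"
    fdr_q: float = 0.05
    include_masks: bool = True
    mask_um: float = 1500.0
    mask_um_per_pixel: float = 2.0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(open(path)) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("delta_band", "summary_hours", "hp_trans", "lp_trans"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def sim_params(self) -> synthetic.SimParams:
        return synthetic.SimParams(
            fs_native=self.fs_native, recording_hours=self.recording_hours,
            delta_gain_effect_pp=self.delta_gain_effect_pp,
            effect_decay_h=self.effect_decay_h,
            clipping_rate_per_h=self.clipping_rate_per_h,
            spike_rate_per_h=self.spike_rate_per_h, seed=self.seed)

    def filter_design(self) -> FilterDesign:
        return FilterDesign(self.hp_trans, self.lp_trans, self.atten_db)


@dataclass
class ResultsBundle:
    """All tables and statistics of one run, with provenance."""

    tables: dict = field(default_factory=dict)       # name -> DataFrame
    stats: dict = field(default_factory=dict)        # analysis name -> dict
    provenance: dict = field(default_factory=dict)
    log: list = field(default_factory=list)
    out_dir: str | None = None

    def note(self, msg: str) -> None:
        self.log.append(msg)


def _asdict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def analyze_cohort(bundle: synthetic.CohortBundle, config: RunConfig,
                   out: ResultsBundle) -> None:
    """Run the full analysis battery over an in-memory cohort bundle."""
    meta = bundle.metadata.set_index("subject_id")
    design = config.filter_design()

    # --- per-subject EEG pipeline: clean -> spectra -> hourly delta -> gain
    gain_rows, summary_rows = [], []
    for sid, days in bundle.recordings.items():
        hourly = {}
        hyps = {}
        for day in ("baseline", "treatment"):
            rec, hyp, _gt = days[day]
            clean, hyp_clean, _mask = preprocessing.preprocess(
                rec, hyp, clip_threshold_frac=config.clip_threshold_frac,
                clip_min_run=config.clip_min_run,
                fermi_edge_frac=config.fermi_edge_frac,
                iqr_mult=config.iqr_mult, max_run=config.max_run, design=design)
            spec = spectral.epoch_spectra(clean, hyp_clean)
            hourly[day] = spectral.hourly_state_band_power(
                spec, hyp_clean, state="NREM", band=config.delta_band,
                min_epochs=config.min_epochs_per_hour)
            hyps[day] = hyp_clean
        gain = spectral.delta_gain(hourly["treatment"], hourly["baseline"],
                                   summary_hours=config.summary_hours,
                                   summary_mode=config.summary_mode,
                                   subject_id=sid)
        for _, r in gain.per_hour.iterrows():
            gain_rows.append({"subject_id": sid, "zt_hour": int(r["zt_hour"]),
                              "gain_pp": r["gain_pp"]})
        b_pct, t_pct, d_pp = spectral.nrem_time_metrics(hyps["baseline"],
                                                        hyps["treatment"])
        summary_rows.append({
            "subject_id": sid, "genotype": meta.loc[sid, "genotype"],
            "treatment": meta.loc[sid, "treatment"],
            "gain_summary_pp": gain.summary, "nrem_pct_baseline": b_pct,
            "nrem_pct_treatment": t_pct, "delta_nrem_pp": d_pp})
    if gain_rows:
        out.tables["delta_gain"] = pd.DataFrame(gain_rows)
        out.tables["subject_summary"] = pd.DataFrame(summary_rows)

    # --- hourly SO-vs-placebo t-test series with FDR, per genotype
    if gain_rows:
        gains = out.tables["delta_gain"].pivot(index="subject_id",
                                               columns="zt_hour",
                                               values="gain_pp")
        hourly_tests = {}
        for gen in meta["genotype"].unique():
            so = gains.loc[[s for s in gains.index
                            if meta.loc[s, "genotype"] == gen
                            and meta.loc[s, "treatment"] == "SO"]]
            pl = gains.loc[[s for s in gains.index
                            if meta.loc[s, "genotype"] == gen
                            and meta.loc[s, "treatment"] == "placebo"]]
            if len(so) >= 2 and len(pl) >= 2:
                tbl = stats.hourly_gain_tests_fdr(so, pl, q=config.fdr_q,
                                                  variant=config.t_variant)
                tbl.insert(0, "genotype", gen)
                hourly_tests[gen] = tbl
        if hourly_tests:
            out.tables["hourly_delta_gain"] = pd.concat(hourly_tests.values(),
                                                        ignore_index=True)

    # --- NREMS proportion change: two-way ANOVA genotype x treatment
    if gain_rows:
        df = out.tables["subject_summary"].rename(columns={"delta_nrem_pp": "value"})
        try:
            out.stats["anova_nrem"] = _asdict(stats.two_way_anova(df))
        except ValueError as exc:
            out.note(f"anova_nrem skipped: {exc}")

    # --- baseline T-maze: Tg vs WT independent t
    tm = bundle.tmaze.merge(bundle.metadata, on="subject_id")
    bl = tm[tm["phase"] == "baseline"]
    tg = bl[bl["genotype"] == "Tg2576"]["percent_correct"].to_numpy()
    wt = bl[bl["genotype"] == "WT"]["percent_correct"].to_numpy()
    if tg.size >= 2 and wt.size >= 2:
        out.stats["baseline_tmaze"] = _asdict(
            stats.independent_t(wt, tg, variant="auto"))
    # paired baseline -> post within Tg, per treatment
    for trt in ("placebo", "SO"):
        sub = tm[(tm["genotype"] == "Tg2576") & (tm["treatment"] == trt)]
        piv = sub.pivot(index="subject_id", columns="phase",
                        values="percent_correct").dropna()
        if len(piv) >= 2:
            out.stats[f"tmaze_paired_{trt}"] = _asdict(
                stats.paired_t(piv["baseline"], piv["post"]))

    # --- plaque burden: fractionator per subject/region, two-way ANOVA
    if bundle.masks:
        rows = []
        for (sid, region), (mask, roi, upp, _true) in bundle.masks.items():
            cfg = tissue.FractionatorConfig(
                frame_um=tissue.REGION_FRAME_UM.get(region, 150.0))
            est = tissue.area_fraction_fractionator(mask, roi, upp, cfg,
                                                    seed=config.seed)
            rows.append({"subject_id": sid, "region": region,
                         "burden": est.burden,
                         "plaque_area_um2": est.plaque_area_um2,
                         "roi_area_um2": est.roi_area_um2})
        burden = pd.DataFrame(rows).merge(bundle.metadata, on="subject_id")
        out.tables["burden"] = burden
        for region in burden["region"].unique():
            df = burden[burden["region"] == region].rename(columns={"burden": "value"})
            try:
                out.stats[f"anova_burden_{region}"] = _asdict(stats.two_way_anova(df))
            except ValueError as exc:
                out.note(f"anova_burden_{region} skipped: {exc}")

    # --- ELISA: normalize, group comparisons, 42/40 ratios
    if len(bundle.elisa):
        norm, ratios = tissue.elisa_normalize(bundle.elisa)
        norm = norm.merge(bundle.metadata, on="subject_id")
        ratios = ratios.merge(bundle.metadata, on="subject_id")
        out.tables["elisa"] = norm
        out.tables["elisa_ratios"] = ratios
        comp = {}
        for (analyte, fraction), grp in norm.groupby(["analyte", "fraction"]):
            so = grp[grp["treatment"] == "SO"]["pg_per_mg"].to_numpy()
            pl = grp[grp["treatment"] == "placebo"]["pg_per_mg"].to_numpy()
            if so.size >= 2 and pl.size >= 2:
                comp[f"{fraction}_{analyte}"] = _asdict(
                    stats.independent_t(so, pl, variant="student"))
        for fraction, grp in ratios.groupby("fraction"):
            so = grp[grp["treatment"] == "SO"]["ratio_42_40"].dropna().to_numpy()
            pl = grp[grp["treatment"] == "placebo"]["ratio_42_40"].dropna().to_numpy()
            if so.size >= 2 and pl.size >= 2:
                comp[f"{fraction}_ratio_42_40"] = _asdict(
                    stats.independent_t(so, pl, variant="student"))
        out.stats["elisa"] = comp

    # --- correlations: gain vs cognition (biserial), gain vs burden (Pearson)
    corr = {}
    if "subject_summary" in out.tables:
        summ = out.tables["subject_summary"].set_index("subject_id")
        post = tm[(tm["phase"] == "post") & (tm["genotype"] == "Tg2576")]
        merged = post.join(summ["gain_summary_pp"], on="subject_id").dropna(
            subset=["gain_summary_pp"])
        if len(merged) >= 3:
            success = merged["percent_correct"] > 50.0
            if 0 < success.sum() < len(success):
                corr["gain_vs_cognition"] = _asdict(stats.biserial_corr(
                    merged["gain_summary_pp"].to_numpy(), success.to_numpy()))
        if "burden" in out.tables:
            b = out.tables["burden"]
            hip = b[(b["region"] == "hippocampus")
                    & (b["genotype"] == "Tg2576")].set_index("subject_id")
            joined = hip.join(summ["gain_summary_pp"]).dropna(
                subset=["gain_summary_pp", "burden"])
            if len(joined) >= 3:
                try:
                    corr["gain_vs_hippocampal_burden"] = _asdict(stats.pearson_corr(
                        joined["gain_summary_pp"], joined["burden"]))
                except ValueError as exc:
                    out.note(f"gain/burden correlation skipped: {exc}")
    if corr:
        out.stats["correlations"] = corr


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Simulate a cohort and run every analysis stage over it.

    Any stage failure raises :class:`PipelineError` labelled with the
    stage; if an output directory is configured, partial outputs are
    retained next to a ``FAILED`` marker.
    """
    out = ResultsBundle(provenance={"config": dataclasses.asdict(config)},
                        out_dir=config.out_dir)
    try:
        design = synthetic.example_design(config.cohort)
        if config.n_per_cell is not None:
            design = (design.groupby(["genotype", "treatment"], group_keys=False)
                      .head(config.n_per_cell).reset_index(drop=True))
        out.note(f"simulate: {len(design)} subjects, "
                 f"{config.recording_hours} h recordings")
        bundle = synthetic.simulate_cohort(design, config.sim_params(),
                                           seed=config.seed,
                                           include_masks=config.include_masks,
                                           mask_um=config.mask_um,
                                           mask_um_per_pixel=config.mask_um_per_pixel)
        out.tables["metadata"] = bundle.metadata
        out.tables["tmaze"] = bundle.tmaze
    except Exception as exc:
        _fail(out, "synthetic_data", exc)
    try:
        analyze_cohort(bundle, config, out)
        out.note("analysis complete")
    except Exception as exc:
        _fail(out, "analysis", exc)
    if config.out_dir:
        write_bundle(out, config.out_dir)
    return out


def _fail(out: ResultsBundle, stage: str, exc: Exception):
    out.note(f"FAILED at stage {stage}: {exc}")
    if out.out_dir:
        write_bundle(out, out.out_dir)
        Path(out.out_dir, "FAILED").write_text(f"{stage}: {exc}\n")
    raise PipelineError(stage, exc) from exc


def write_bundle(out: ResultsBundle, out_dir) -> None:
    from .io import write_json

    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    for name, df in out.tables.items():
        df.to_csv(d / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.10g")
    write_json(out.stats, d / "stats.json")
    write_json(out.provenance, d / "provenance.json")
    (d / "run.log").write_text("\n".join(out.log) + "\n")


def make_report(bundle: ResultsBundle, path) -> str:
    """Render a human-readable markdown summary with figures.

    Sections mirror the study's Results structure; missing tables produce
    a notice instead of a section.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    figdir = path.parent / "figures"
    figdir.mkdir(exist_ok=True)
    lines = ["# Slow-wave activity intervention analysis", ""]

    def _stat_lines(name, title):
        lines.append(f"## {title}")
        if name not in bundle.stats:
            lines.append("_Not available in this run._")
            lines.append("")
            return
        lines.append("```")
        lines.append(yaml.safe_dump(bundle.stats[name], sort_keys=False).strip())
        lines.append("```")
        lines.append("")

    # 1. NREMS time and delta gain
    lines.append("## NREMS proportion and delta activity gain")
    if "subject_summary" in bundle.tables:
        s = bundle.tables["subject_summary"]
        lines.append(s.groupby(["genotype", "treatment"])["delta_nrem_pp"]
                     .agg(["mean", "sem", "count"]).round(3).to_markdown())
        lines.append("")
    if "delta_gain" in bundle.tables and "subject_summary" in bundle.tables:
        g = bundle.tables["delta_gain"].merge(
            bundle.tables["subject_summary"][["subject_id", "genotype", "treatment"]],
            on="subject_id")
        fig, ax = plt.subplots(figsize=(7, 4))
        for (gen, trt), grp in g.groupby(["genotype", "treatment"]):
            m = grp.groupby("zt_hour")["gain_pp"].mean()
            ax.plot(m.index, m.values, marker="o", label=f"{gen}/{trt}")
        for zt in (1, 9):
            ax.axvline(zt, color="green", ls="--", lw=1)
            ax.annotate("admin", (zt, ax.get_ylim()[1]), color="green",
                        fontsize=8, ha="center")
        ax.set_xlabel("ZT hour")
        ax.set_ylabel("delta gain (p.p.)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(figdir / "delta_gain.png", dpi=110)
        plt.close(fig)
        lines.append("![hourly delta gain](figures/delta_gain.png)")
        lines.append("")
    else:
        lines.append("_No EEG tables in this run._")
        lines.append("")
    _stat_lines("anova_nrem", "Two-way ANOVA on ΔNREM")

    # 2. cognition
    _stat_lines("baseline_tmaze", "Baseline T-maze (WT vs Tg2576)")
    for trt in ("SO", "placebo"):
        _stat_lines(f"tmaze_paired_{trt}", f"T-maze change under {trt}")

    # 3. correlations
    _stat_lines("correlations", "Delta-gain correlations")
    if ("subject_summary" in bundle.tables and "burden" in bundle.tables
            and "correlations" in bundle.stats
            and "gain_vs_hippocampal_burden" in bundle.stats["correlations"]):
        s = bundle.tables["subject_summary"].set_index("subject_id")
        b = bundle.tables["burden"]
        hip = b[(b["region"] == "hippocampus")
                & (b["genotype"] == "Tg2576")].set_index("subject_id")
        joined = hip.join(s["gain_summary_pp"]).dropna(
            subset=["gain_summary_pp", "burden"])
        corr = bundle.stats["correlations"]["gain_vs_hippocampal_burden"]
        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.scatter(joined["gain_summary_pp"], joined["burden"], color="tab:red")
        ax.annotate(f"r = {corr['r']:.3f}, p = {corr['p']:.3f}",
                    xy=(0.05, 0.92), xycoords="axes fraction")
        ax.set_xlabel("delta gain, hours 9-10 (p.p.)")
        ax.set_ylabel("hippocampal burden (fraction)")
        fig.tight_layout()
        fig.savefig(figdir / "gain_vs_burden.png", dpi=110)
        plt.close(fig)
        lines.append("![gain vs burden](figures/gain_vs_burden.png)")
        lines.append("")

    # 4/5. burden
    lines.append("## Plaque burden")
    if "burden" in bundle.tables:
        b = bundle.tables["burden"]
        lines.append(b.groupby(["region", "genotype", "treatment"])["burden"]
                     .agg(["mean", "sem", "count"]).round(4).to_markdown())
        lines.append("")
        fig, ax = plt.subplots(figsize=(6, 4))
        summary = b.groupby(["region", "genotype", "treatment"])["burden"].mean()
        summary.plot.bar(ax=ax)
        ax.set_ylabel("area fraction")
        fig.tight_layout()
        fig.savefig(figdir / "burden.png", dpi=110)
        plt.close(fig)
        lines.append("![burden](figures/burden.png)")
        lines.append("")
        for region in b["region"].unique():
            _stat_lines(f"anova_burden_{region}", f"Two-way ANOVA, {region} burden")
    else:
        lines.append("_No plaque masks in this run._")
        lines.append("")

    # 6. ELISA
    _stat_lines("elisa", "ELISA group comparisons (pg/mg and Aβ-42/Aβ-40)")

    text = "\n".join(lines)
    path.write_text(text)
    return text
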