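"""End-to-end pipeline: simulate (or load) -> aggregate -> fit -> report.

Every stage writes plain CSV/JSON so any of them can be re-run from its
on-disk inputs or replaced with external data.  A manifest records the
configuration hash, all derived seeds and library versions; runs with
the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from .task_design import generate_schedule
from .cohort import (CohortConfig, GroupParams, DEFAULT_GROUPS,
                     generate_cohort, simulate_cohort_trials, cohort_to_frame)
from .preprocessing import aggregate
from .psychometrics import fit_psychometric, fit_vs_covariate
from .preference_stats import (classify_cohort, preference_table,
                               chi2_independence, split_plot_model,
                               backtransform_means)

log = logging.getLogger("ccaf")


@dataclass(frozen=True)
class RunConfig:
    """Settings for one pipeline run; round-trips through YAML/JSON."""

    seed: int = 0
    n_per_level: int = 32
    n_per_group: int = 30
    n_boot: int = 1000
    ci_level: float = 0.95
    audit_threshold: int = 7
    preference_chi2_correction: str = "none"
    audit_chi2_correction: str = "yates"
    level_coding: str = "categorical"
    logit_method: str = "adjusted"
    trials_csv: str | None = None       # when set, skip simulation
    group_params: dict = field(
        default_factory=lambda: {
            g: dataclasses.asdict(p) for g, p in DEFAULT_GROUPS.items()})
    audit_drinks_corr: float = 0.74
    lapse: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def cohort_config(self, seed: int) -> CohortConfig:
        groups = {g: GroupParams(**p) for g, p in self.group_params.items()}
        return CohortConfig(n_per_group=self.n_per_group, groups=groups,
                            audit_drinks_corr=self.audit_drinks_corr,
                            lapse=self.lapse, seed=seed)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _child_seeds(seed: int, n: int) -> list[int]:
    # independent derived seeds, kept below 2**31 for portability
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


def run_pipeline(config: RunConfig, outdir, plots: bool = False) -> dict:
    """Execute every stage; returns the result bundle and writes artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(
        ["schedule", "cohort", "trials", "boot_group", "boot_subject",
         "boot_audit"],
        _child_seeds(config.seed, 6)))

    stage = "schedule"
    try:
        schedule = generate_schedule(config.n_per_level, seeds["schedule"])
        schedule.to_csv(outdir / "schedule.csv")

        stage = "simulate"
        if config.trials_csv:
            trials = pd.read_csv(config.trials_csv)
        else:
            profiles = generate_cohort(config.cohort_config(seeds["cohort"]))
            cohort_to_frame(profiles).to_csv(outdir / "cohort.csv", index=False)
            trials = simulate_cohort_trials(profiles, schedule, seeds["trials"])
        trials.to_csv(outdir / "trials.csv", index=False)

        stage = "aggregate"
        summary = aggregate(trials, logit_method=config.logit_method)
        summary.to_csv(outdir / "summary.csv", index=False)

        stage = "fit"
        group_fits = {}
        for i, grp in enumerate(sorted(summary["group"].dropna().unique())):
            res = fit_psychometric(summary[summary["group"] == grp])
            boot = res.parametric_bootstrap(
                n_boot=config.n_boot, level=config.ci_level,
                seed=seeds["boot_group"] + i)
            group_fits[grp] = {**res.to_dict(),
                               "alpha_ci": list(boot.alpha_ci),
                               "beta_ci": list(boot.beta_ci),
                               "n_boot": boot.n_boot}
        subject_fits = {}
        subject_cis = {}
        for i, sid in enumerate(sorted(summary["subject_id"].unique())):
            res = fit_psychometric(summary, subject_id=sid)
            try:
                boot = res.parametric_bootstrap(
                    n_boot=config.n_boot, level=config.ci_level,
                    seed=seeds["boot_subject"] + i)
            except RuntimeError as exc:
                # unstable individual fit: record it, exclude from classification
                log.warning("subject %s bootstrap failed: %s", sid, exc)
                subject_fits[sid] = {**res.to_dict(), "error": str(exc)}
                continue
            subject_cis[sid] = boot.alpha_ci
            subject_fits[sid] = {**res.to_dict(),
                                 "alpha_ci": list(boot.alpha_ci),
                                 "beta_ci": list(boot.beta_ci)}
        with open(outdir / "fits.json", "w") as fh:
            json.dump({"group": group_fits, "subject": subject_fits}, fh,
                      indent=2)

        stage = "classify"
        classification = classify_cohort(subject_cis)
        classification.to_csv(outdir / "classification.csv", index=False)
        groups = summary.groupby("subject_id")["group"].first()
        pref_tab = preference_table(classification, groups)
        # unobserved categories carry no information for the frequency test
        occupied = pref_tab.loc[:, pref_tab.sum(axis=0) > 0]
        pref_chi2 = None
        if occupied.shape[1] >= 2 and (occupied.sum(axis=1) > 0).all():
            pref_chi2 = chi2_independence(
                occupied.to_numpy(),
                correction=config.preference_chi2_correction)

        stage = "contingency"
        audits = summary.groupby("subject_id")[["group", "audit"]].first()
        audit_tab = pd.crosstab(
            audits["group"], audits["audit"] >= config.audit_threshold)
        audit_chi2 = None
        if audit_tab.shape == (2, 2) and (audit_tab.to_numpy().sum(0) > 0).all():
            audit_chi2 = chi2_independence(
                audit_tab.to_numpy(), correction=config.audit_chi2_correction)
        contingency = {
            "preference": {
                "table": pref_tab.to_dict(),
                "chi2": None if pref_chi2 is None else pref_chi2.chi2,
                "df": None if pref_chi2 is None else pref_chi2.df,
                "p": None if pref_chi2 is None else pref_chi2.p,
                "correction": config.preference_chi2_correction,
            },
            "audit_threshold": None if audit_chi2 is None else {
                "threshold": config.audit_threshold,
                "table": audit_tab.to_numpy().tolist(),
                "chi2": audit_chi2.chi2, "df": audit_chi2.df,
                "p": audit_chi2.p, "correction": audit_chi2.correction,
            },
        }
        with open(outdir / "contingency.json", "w") as fh:
            json.dump(contingency, fh, indent=2)

        stage = "split_plot"
        anova_group = split_plot_model(summary, between=("group", "sex"),
                                       level_coding=config.level_coding)
        anova_audit = split_plot_model(summary, between=("group", "sex"),
                                       covariates=("audit",),
                                       level_coding="linear",
                                       factor_interactions=False)
        anova_group.anova.to_json(outdir / "anova_group.json", orient="records",
                                  indent=2)
        anova_audit.anova.to_json(outdir / "anova_audit.json", orient="records",
                                  indent=2)

        stage = "backtransform"
        means = {by: backtransform_means(summary, by, ci_level=config.ci_level)
                 for by in ("relative_point_level", "group", "sex")}

        stage = "covariate_fits"
        audit_fits = {}
        for lev in (-2, 0, 2):
            try:
                res, boot = fit_vs_covariate(
                    summary, lev, n_boot=config.n_boot,
                    ci_level=config.ci_level, seed=seeds["boot_audit"] + lev)
                audit_fits[lev] = {"slope": res.beta,
                                   "slope_ci": list(boot.beta_ci)}
            except (ValueError, RuntimeError) as exc:
                audit_fits[lev] = {"error": str(exc)}

        stage = "report"
        report = _render_report(config, group_fits, pref_tab, contingency,
                                anova_group, means, audit_fits)
        (outdir / "report.md").write_text(report)
        if plots:
            from .plotting import plot_group_curves
            fits = {g: fit_psychometric(summary[summary["group"] == g])
                    for g in group_fits}
            fig = plot_group_curves(summary, fits)
            fig.savefig(outdir / "choice_curves.png", dpi=150)

        manifest = {
            "config": config.to_dict(),
            "config_hash": config.hash(),
            "seeds": seeds,
            "versions": {"python": sys.version.split()[0],
                         "numpy": np.__version__, "pandas": pd.__version__},
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception:
        log.error("pipeline failed in stage %r", stage)
        raise

    return {
        "schedule": schedule, "trials": trials, "summary": summary,
        "group_fits": group_fits, "subject_fits": subject_fits,
        "classification": classification, "contingency": contingency,
        "anova_group": anova_group, "anova_audit": anova_audit,
        "means": means, "audit_fits": audit_fits, "manifest": manifest,
    }


def _render_report(config, group_fits, pref_tab, contingency, anova_group,
                   means, audit_fits) -> str:
    out = ["# CCAF analysis report", ""]
    out += ["## Group psychometric fits", "",
            "| group | PSE | 95% CI | slope | 95% CI |",
            "|---|---|---|---|---|"]
    for g, f in sorted(group_fits.items()):
        out.append(
            f"| {g} | {f['alpha']:.2f} | [{f['alpha_ci'][0]:.2f}, "
            f"{f['alpha_ci'][1]:.2f}] | {f['beta']:.2f} | "
            f"[{f['beta_ci'][0]:.2f}, {f['beta_ci'][1]:.2f}] |")
    out += ["", "## Preference classification", "", pref_tab.to_markdown(), ""]
    pref = contingency["preference"]
    if pref["chi2"] is not None:
        out += [f"chi2({pref['df']}) = {pref['chi2']:.2f}, "
                f"p = {pref['p']:.4g}", ""]
    else:
        out += ["(frequency test skipped: fewer than two occupied categories)",
                ""]
    if contingency["audit_threshold"]:
        a = contingency["audit_threshold"]
        out += [f"AUDIT >= {a['threshold']}: chi2({a['df']}) = "
                f"{a['chi2']:.2f}, p = {a['p']:.4g} "
                f"({a['correction']} correction)", ""]
    out += ["## Split-plot ANOVA (group model)", "```",
            anova_group.summary(), "```", ""]
    out += ["## Mean percentage alcohol choice", ""]
    for by, tab in means.items():
        out += [f"### by {by}", "", tab.to_markdown(index=False), ""]
    out += ["## Choice vs AUDIT (per level)", "",
            "| level | slope (logit/AUDIT point) | 95% CI |", "|---|---|---|"]
    for lev, f in sorted(audit_fits.items()):
        if "slope" in f:
            out.append(f"| {lev} | {f['slope']:.3f} | "
                       f"[{f['slope_ci'][0]:.3f}, {f['slope_ci'][1]:.3f}] |")
        else:
            out.append(f"| {lev} | (not fitted: {f['error']}) | |")
    out.append("")
    return "\n".join(out)
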