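"""End-to-end study orchestration from a config file.

Runs the full design: instrument selection → harmonization → univariable
MR (forward and, optionally, reverse) → sensitivity diagnostics →
replication + meta-analysis → MVMR and mediation per mediator → LD-score
genetic correlation, with an instrument audit trail and a deterministic,
re-runnable report.  One seed in the config governs every stochastic stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import (InsufficientInstrumentsError, bh_fdr, estimate_all,
                         estimates_table, ivw_estimate)
from .instruments import (apply_exclusion_list, filter_by_f, instrument_table,
                          ld_clump, load_ld, select_significant, steiger_filter)
from .io import SummaryStatSet, harmonize_multi, harmonize_pair, read_sumstats
from .ldsc import ldsc_rg
from .meta import forest_data, meta_analyze
from .mvmr import mediation_effects, mediation_table, mvmr_from_harmonized
from .sensitivity import cochran_q, leave_one_out, mr_presso, power_binary, single_snp_table
from .synthetic import read_ld_scores

FLOAT_FMT = "%.17g"


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Paths and thresholds for one full analysis run."""

    exposure: str
    outcome: str
    mediators: dict = field(default_factory=dict)      # name -> path
    replications: dict = field(default_factory=dict)   # name -> path
    ld: str | None = None                              # r² matrix / triplets
    ld_scores: str | None = None                       # per-SNP LD scores
    exclusion_list: str | None = None
    direction: str = "both"                            # forward | reverse | both
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    f_min: float = 10.0
    alpha: float = 0.05
    seed: int = 42
    n_boot: int = 1000
    presso_nsim: int = 5000
    outlier_alpha: float = 0.05
    steiger: bool = True
    fdr_family: str = "primary-per-analysis"

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse", "both"):
            raise ConfigError(f"invalid direction {self.direction!r}")
        if not (0 < self.p_threshold <= 1):
            raise ConfigError("p_threshold must be in (0, 1]")
        if not (0 <= self.clump_r2 <= 1):
            raise ConfigError("clump_r2 must be in [0, 1]")
        if self.f_min < 0 or self.clump_kb <= 0:
            raise ConfigError("thresholds out of range")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        for key in ("exposure", "outcome"):
            p = getattr(cfg, key)
            if not Path(p).exists():
                raise ConfigError(f"{key} path does not exist: {p}")
        for group in (cfg.mediators, cfg.replications):
            for name, p in group.items():
                if not Path(p).exists():
                    raise ConfigError(f"path for {name} does not exist: {p}")
        return cfg

    def hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """All result tables of one run plus provenance."""

    tables: dict = field(default_factory=dict)         # name -> DataFrame
    summary: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)
    failures: dict = field(default_factory=dict)       # direction -> reason
    provenance: dict = field(default_factory=dict)


def _select_instruments(sset: SummaryStatSet, cfg: AnalysisConfig, log: list[str],
                        label: str):
    """Criteria (significance → clump → F) with per-step counts."""
    counts = {"input": len(sset)}
    sig = select_significant(sset, cfg.p_threshold)
    counts["significant"] = len(sig)
    log.append(f"[{label}] genome-wide significant (p<{cfg.p_threshold:g}): {len(sig)}")
    if cfg.exclusion_list:
        sig = apply_exclusion_list(sig, cfg.exclusion_list)
        counts["after_exclusion"] = len(sig)
        log.append(f"[{label}] after confounder exclusion list: {len(sig)}")
    if cfg.ld and len(sig):
        ld = load_ld(cfg.ld, ids=list(sig.df["variant_id"]))
        clumped = ld_clump(sig, ld, r2_max=cfg.clump_r2, window_kb=cfg.clump_kb,
                           missing="independent")
    else:
        clumped = sig
    counts["clumped"] = len(clumped)
    log.append(f"[{label}] after LD clumping (r2<{cfg.clump_r2:g}, "
               f"{cfg.clump_kb:g} kb): {len(clumped)}")
    strong = filter_by_f(clumped, cfg.f_min)
    counts["strong"] = len(strong)
    log.append(f"[{label}] F > {cfg.f_min:g}: {len(strong)}")
    return strong, counts


def _analyze_pair(exposure: SummaryStatSet, outcome: SummaryStatSet,
                  cfg: AnalysisConfig, log: list[str], label: str):
    """One exposure→outcome analysis: selection, harmonization, estimates,
    sensitivity.  Returns a dict of tables or raises on zero instruments."""
    instruments, counts = _select_instruments(exposure, cfg, log, label)
    if len(instruments) == 0:
        raise InsufficientInstrumentsError(f"no instruments for {label}")
    h = harmonize_pair(instruments, outcome)
    counts["harmonized"] = len(h)
    log.append(f"[{label}] harmonized against outcome: {len(h)} "
               f"(actions: {h.action_counts})")
    steiger_rec = None
    if cfg.steiger:
        h, steiger_rec = steiger_filter(h)
        counts["steiger"] = len(h)
        log.append(f"[{label}] after Steiger filtering: {len(h)}")
    if len(h) == 0:
        raise InsufficientInstrumentsError(f"no instruments for {label} after filters")

    ests = estimate_all(h, n_boot=cfg.n_boot, seed=cfg.seed)
    est_df = estimates_table(ests)
    est_df.insert(0, "analysis", label)

    inst_df = instrument_table(instruments)
    r2_sum = float(inst_df["r2"].sum())
    f_min_v, f_max_v = float(inst_df["f_stat"].min()), float(inst_df["f_stat"].max())
    log.append(f"[{label}] F range [{f_min_v:.1f}, {f_max_v:.1f}], summed R2 "
               f"{100 * r2_sum:.2f}%")

    tables = {
        "estimates": est_df,
        "instruments": inst_df,
        "audit_counts": pd.DataFrame([{"analysis": label, **counts}]),
        "harmonization_audit": h.audit.assign(analysis=label),
    }
    if steiger_rec is not None:
        tables["steiger"] = steiger_rec.assign(analysis=label)

    k = len(h)
    sens_rows = []
    ivw = next((e for e in ests if e.method in ("ivw", "wald")), ests[0])
    if k >= 2:
        het = cochran_q(h, beta_ivw=ivw.beta)
        sens_rows.append({"analysis": label, "diagnostic": "cochran_q",
                          "value": het.q, "df": het.df, "pval": het.pval})
    egger = next((e for e in ests if e.method == "egger"), None)
    if egger is not None:
        sens_rows.append({"analysis": label, "diagnostic": "egger_intercept",
                          "value": egger.egger_intercept, "df": np.nan,
                          "pval": egger.egger_intercept_p})
    if k >= 4:
        presso = mr_presso(h, n_sim=cfg.presso_nsim, seed=cfg.seed,
                           outlier_alpha=cfg.outlier_alpha)
        sens_rows.append({"analysis": label, "diagnostic": "presso_global",
                          "value": presso.rss_obs, "df": np.nan,
                          "pval": presso.global_p})
        tables["presso_outliers"] = pd.DataFrame(
            {"analysis": label, "variant_id": presso.outlier_ids}
        )
        if presso.corrected_estimate is not None:
            corr = presso.corrected_estimate.as_row()
            corr["method"] = "ivw_outlier_corrected"
            corr_df = pd.DataFrame([corr])
            corr_df.insert(0, "analysis", label)
            tables["estimates"] = pd.concat([est_df, corr_df], ignore_index=True)
    if k >= 3:
        tables["leave_one_out"] = leave_one_out(h).assign(analysis=label)
    tables["single_snp"] = single_snp_table(h).assign(analysis=label)
    tables["sensitivity"] = pd.DataFrame(sens_rows)

    n_case = outcome.df["n_case"].median() if outcome.df["n_case"].notna().any() else np.nan
    n = outcome.sample_size
    if np.isfinite(n_case) and n > 0:
        cf = float(n_case) / n
        pw = power_binary(n, cf, min(r2_sum, 0.999), ivw.or_, cfg.alpha)
        tables["power"] = pd.DataFrame([{
            "analysis": label, "n": n, "case_fraction": cf, "r2_sum": r2_sum,
            "or": ivw.or_, "ncp": pw.ncp, "power": pw.power,
        }])
    return tables, h, instruments, ivw


def _merge(dst: dict, src: dict) -> None:
    for name, df in src.items():
        dst[name] = pd.concat([dst[name], df], ignore_index=True) if name in dst else df


def run_pipeline(config: AnalysisConfig) -> StudyReport:
    """Execute every stage of the study design for one config."""
    log: list[str] = [f"tsmr {__version__} | config {config.hash()} | seed {config.seed}"]
    report = StudyReport(provenance={
        "version": __version__, "config_hash": config.hash(), "seed": config.seed,
        "config": asdict(config),
    })
    exposure = read_sumstats(config.exposure, trait="exposure")
    outcome = read_sumstats(config.outcome, trait="outcome")

    directions = {"forward": (exposure, outcome)}
    if config.direction in ("reverse", "both"):
        directions["reverse"] = (outcome, exposure)
    if config.direction == "reverse":
        directions.pop("forward")

    primary_pvals: list[tuple[str, float]] = []
    forward_ivw = None
    forward_h = None
    forward_instruments = None
    all_tables: dict = {}

    for direction, (exp_s, out_s) in directions.items():
        try:
            tables, h, instruments, ivw = _analyze_pair(exp_s, out_s, config, log,
                                                        direction)
        except InsufficientInstrumentsError as exc:
            report.failures[direction] = str(exc)
            log.append(f"[{direction}] FAILED: {exc}")
            continue
        _merge(all_tables, tables)
        primary_pvals.append((direction, ivw.pval))
        if direction == "forward":
            forward_ivw, forward_h, forward_instruments = ivw, h, instruments

    # replication + meta-analysis on the forward direction
    meta_inputs = []
    if forward_ivw is not None:
        meta_inputs.append(("discovery", forward_ivw.beta, forward_ivw.se))
        for name, path in config.replications.items():
            rep_outcome = read_sumstats(path, trait=name)
            try:
                tables, _, _, rep_ivw = _analyze_pair(exposure, rep_outcome, config,
                                                      log, f"replication_{name}")
            except InsufficientInstrumentsError as exc:
                report.failures[f"replication_{name}"] = str(exc)
                log.append(f"[replication_{name}] FAILED: {exc}")
                continue
            _merge(all_tables, tables)
            primary_pvals.append((f"replication_{name}", rep_ivw.pval))
            meta_inputs.append((name, rep_ivw.beta, rep_ivw.se))
    if len(meta_inputs) >= 2:
        study_df = pd.DataFrame(meta_inputs, columns=["study", "beta", "se"])
        for model in ("fixed", "random"):
            res = meta_analyze(study_df[["beta", "se"]].to_numpy(), model=model)
            row = {"model": model, **{k: getattr(res, k) for k in (
                "pooled_beta", "se", "ci_low", "ci_high", "pval", "pooled_or",
                "or_ci_low", "or_ci_high", "tau2", "q_between", "i2", "n_studies")}}
            _merge(all_tables, {"meta": pd.DataFrame([row])})
            if model == "random":
                _merge(all_tables, {"forest": forest_data(study_df, res)})
        log.append(f"[meta] pooled {len(meta_inputs)} studies")

    # MVMR + mediation, forward direction only
    if forward_ivw is not None and config.mediators:
        med_rows = []
        for name, path in config.mediators.items():
            mediator = read_sumstats(path, trait=name)
            med_instruments, _ = _select_instruments(mediator, config, log,
                                                     f"mediator_{name}")
            union_ids = sorted(set(forward_instruments.df["variant_id"])
                               | set(med_instruments.df["variant_id"]))
            primary_sub = SummaryStatSet(
                df=exposure.df[exposure.df["variant_id"].isin(union_ids)]
                .reset_index(drop=True),
                trait="exposure",
            )
            hm = harmonize_multi(primary_sub, {name: mediator}, outcome)
            if len(hm) < 3:
                report.failures[f"mvmr_{name}"] = "too few joint instruments"
                continue
            mv = mvmr_from_harmonized(hm, [name])
            mv_df = mv.as_frame()
            mv_df.insert(0, "model", f"adjusted_for_{name}")
            _merge(all_tables, {"mvmr": mv_df})
            # exposure -> mediator (total-effect instruments)
            h_xm = harmonize_pair(forward_instruments, mediator)
            if config.steiger:
                h_xm, _ = steiger_filter(h_xm)
            if len(h_xm) < 2:
                report.failures[f"mediation_{name}"] = "too few exposure->mediator instruments"
                continue
            est_xm = ivw_estimate(h_xm)
            med = mediation_effects(forward_ivw, est_xm,
                                    mv.beta[name], mv.se[name], mediator=name)
            med_rows.append(med)
            prop = "NA" if med.proportion is None else f"{med.proportion:.2f}%"
            log.append(f"[mediation_{name}] indirect {med.indirect:.4f} ({prop} of total)")
        if med_rows:
            _merge(all_tables, {"mediation": mediation_table(med_rows)})

    # LD-score genetic correlation between exposure and outcome
    if config.ld_scores:
        scores = read_ld_scores(config.ld_scores)
        zx = exposure.df[["variant_id", "beta", "se", "n"]].copy()
        zy = outcome.df[["variant_id", "beta", "se", "n"]].copy()
        joined = scores.merge(zx, on="variant_id").merge(
            zy, on="variant_id", suffixes=("_x", "_y"))
        if len(joined) >= 50:
            z1 = (joined["beta_x"] / joined["se_x"]).to_numpy()
            z2 = (joined["beta_y"] / joined["se_y"]).to_numpy()
            n_blocks = min(200, max(2, len(joined) // 25))
            res = ldsc_rg(z1, z2, joined["ldscore"].to_numpy(),
                          exposure.sample_size, outcome.sample_size,
                          m=len(joined), n_blocks=n_blocks)
            _merge(all_tables, {"ldsc": pd.DataFrame([{
                "h2_exposure": res.h2_1, "h2_outcome": res.h2_2,
                "intercept_exposure": res.intercept_1,
                "intercept_outcome": res.intercept_2,
                "gencov": res.gencov, "rg": res.rg, "se_rg": res.se_rg,
                "pval_rg": res.pval_rg, "n_snps": len(joined),
                "n_blocks": res.n_blocks,
            }])})
            log.append(f"[ldsc] rg {res.rg:.4f} (se {res.se_rg:.4f})")
        else:
            report.failures["ldsc"] = "fewer than 50 SNPs with LD scores"

    # FDR over the declared family: primary p-value of each analysis
    if primary_pvals:
        fam = pd.DataFrame(primary_pvals, columns=["analysis", "pval"])
        fam["fdr"] = bh_fdr(fam["pval"].to_numpy())
        _merge(all_tables, {"fdr_family": fam})
        if "estimates" in all_tables:
            est = all_tables["estimates"]
            fdr_map = dict(zip(fam["analysis"], fam["fdr"]))
            mask = est["method"].isin(["ivw", "wald"])
            est.loc[mask, "fdr"] = est.loc[mask, "analysis"].map(fdr_map)

    report.tables = all_tables
    report.log = log
    report.summary = {
        "analyses": [a for a, _ in primary_pvals],
        "failures": report.failures,
        "fdr_family": config.fdr_family,
    }
    if not primary_pvals:
        report.summary["status"] = "no instruments in any direction"
    return report


def render_report(report: StudyReport, out_dir) -> list[str]:
    """Write all tables, the run log and a machine-readable summary.

    Numbers are written at full precision; output is byte-stable for a
    fixed config and seed.  Returns the file inventory (also written to
    ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    for name in sorted(report.tables):
        fname = f"{name}.tsv"
        report.tables[name].to_csv(out / fname, sep="\t", index=False,
                                   float_format=FLOAT_FMT)
        files.append(fname)
    (out / "run.log").write_text("\n".join(report.log) + "\n")
    files.append("run.log")
    summary = {"provenance": report.provenance, **report.summary}
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True,
                                                 default=str) + "\n")
    files.append("summary.json")
    (out / "manifest.json").write_text(json.dumps(sorted(files + ["manifest.json"]),
                                                  indent=1) + "\n")
    files.append("manifest.json")
    return sorted(files)
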