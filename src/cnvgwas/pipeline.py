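"""End-to-end orchestration of the CNV-GWAS stages.

The pipeline runs: simulate (optional) -> encode -> prefilter -> four-model
GWAS -> stepwise conditional analysis -> thresholds (effective tests) ->
region definition and merging -> statistical validation (tiers) ->
replication -> BMI confounding -> burden analyses -> report. Every stage
writes a TSV artifact plus a log line into the run directory; a stage
failure aborts with the stage name, leaving earlier artifacts in place.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .association import (
    MODELS,
    encode_genotypes,
    prefilter,
    run_burden_gwas,
    run_gwas,
    stepwise_conditional,
)
from .burden import burden_association, compute_burden, gwas_signal_corrected_burden
from .matrix import encode_probe_matrix, probe_frequencies, prune_probes
from .multiplicity import effective_tests, thresholds
from .phenotypes import select_covariates, select_covariates_linear
from .regions import Cnvr, define_cnvr, label_models, merge_cnvrs
from .simulate import (
    CovariateSpec,
    EffectSpec,
    GenomeModel,
    demo_genome,
    simulate_calls,
    simulate_phenotypes,
    simulate_replication_cohort,
)
from .validation import (
    assign_tier,
    bmi_confounding,
    coxph_fit,
    replicate,
    replication_enrichment_grid,
    residual_regression,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "encode", "gwas", "condition", "regions", "validate",
    "replicate", "bmi", "burden", "report",
)


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with the study defaults."""

    seed: int = 1
    n_samples: int = 20_000
    n_replication: int = 10_000
    diseases: dict = field(default_factory=lambda: {"disease_1": 0.05, "disease_2": 0.08})
    qs_cut: float = 0.5
    freq_cut: float = 1e-4
    fisher_cut: float = 1e-3
    min_cases: int = 2
    r2_prune: float = 0.9999
    prune_window: int = 500
    prune_step: int = 250
    r2_tag: float = 0.5
    tag_window_bp: int = 3_000_000
    tier_alpha: float = 1e-4
    neff_variance_fraction: float = 0.995
    alpha: float = 0.05
    models: tuple = MODELS
    replication_attenuation: float = 1.0
    replication_probe_keep: float = 1.0
    n_pcs: int = 4
    genome: GenomeModel | None = None
    effects: list = field(default_factory=list)
    covariate_spec: CovariateSpec | None = None

    def __post_init__(self):
        if self.covariate_spec is None:
            self.covariate_spec = CovariateSpec(n_pcs=self.n_pcs)


def demo_config(seed: int = 1, n_samples: int = 20_000) -> RunConfig:
    """Bundled demo: 3 loci, 2 diseases, mirror and deletion-only effects."""
    genome = demo_genome(n_loci=3)
    effects = [
        EffectSpec("disease_1", "locus_1", "mirror", log_odds=1.5, hazard_ratio=2.5),
        EffectSpec("disease_2", "locus_2", "delonly", log_odds=2.0, hazard_ratio=2.5),
    ]
    return RunConfig(
        seed=seed,
        n_samples=n_samples,
        n_replication=max(n_samples // 2, 1000),
        genome=genome,
        effects=effects,
    )


def load_config(path) -> RunConfig:
    """Read a run configuration from YAML (demo genome if none given)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    effects = [EffectSpec(**e) for e in raw.pop("effects", [])]
    genome_raw = raw.pop("genome", None)
    if genome_raw is not None:
        from .simulate import BreakpointCategory, CnvLocus

        loci = tuple(
            CnvLocus(
                locus_id=l["locus_id"], chrom=str(l["chrom"]),
                start=l["start"], end=l["end"],
                dup_freq=l.get("dup_freq", 0.0), del_freq=l.get("del_freq", 0.0),
                categories=tuple(
                    BreakpointCategory(c["start"], c["end"], c.get("weight", 1.0))
                    for c in l.get("categories", [])
                ),
                qs_noise=l.get("qs_noise", 0.2),
            )
            for l in genome_raw.get("loci", [])
        )
        genome = GenomeModel(
            chromosomes={str(k): v for k, v in genome_raw["chromosomes"].items()},
            probes={
                str(k): np.asarray(v) for k, v in genome_raw.get("probes", {}).items()
            },
            loci=loci,
        )
    else:
        genome = demo_genome()
    return RunConfig(genome=genome, effects=effects, **raw)


class PipelineRun:
    """Stateful executor; stages populate attributes and write artifacts."""

    def __init__(self, config: RunConfig, outdir):
        self.cfg = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.log_path = self.outdir / "pipeline.log"
        self._stage = None

    # -- infrastructure ----------------------------------------------------
    def _log(self, msg: str):
        logger.info("[%s] %s", self._stage, msg)
        with self.log_path.open("a") as fh:
            fh.write(f"[{self._stage}] {msg}\n")

    def _run_stage(self, name, fn):
        self._stage = name
        try:
            fn()
        except Exception as exc:
            self._log(f"FAILED: {exc}")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    def run(self, through: str = "report"):
        if through not in STAGES:
            raise ValueError(f"unknown stage {through!r}")
        fns = {
            "simulate": self.stage_simulate, "encode": self.stage_encode,
            "gwas": self.stage_gwas, "condition": self.stage_condition,
            "regions": self.stage_regions, "validate": self.stage_validate,
            "replicate": self.stage_replicate, "bmi": self.stage_bmi,
            "burden": self.stage_burden, "report": self.stage_report,
        }
        for name in STAGES:
            self._run_stage(name, fns[name])
            if name == through:
                break
        return self.outdir

    # -- stages ------------------------------------------------------------
    def stage_simulate(self):
        cfg = self.cfg
        self.calls = simulate_calls(cfg.genome, cfg.n_samples, cfg.seed)
        self.probes = cfg.genome.probe_table()
        self.pheno = simulate_phenotypes(
            self.calls, cfg.genome, cfg.effects, cfg.covariate_spec,
            cfg.n_samples, cfg.seed, diseases=cfg.diseases,
        )
        cio.write_calls(self.calls, self.outdir / "calls.tsv")
        cio.write_probes(self.probes, self.outdir / "probes.tsv")
        cio.write_phenotypes(self.pheno, self.outdir / "phenotypes.tsv")
        truth = [dataclasses.asdict(e) for e in cfg.effects]
        (self.outdir / "truth.yaml").write_text(yaml.safe_dump(truth))
        self._log(f"{len(self.calls)} calls, {cfg.n_samples} samples")

    def stage_encode(self):
        cfg = self.cfg
        self.samples = self.pheno["sample_id"].to_numpy()
        m = encode_probe_matrix(
            self.calls, self.probes, qs_cut=cfg.qs_cut, sample_ids=self.samples
        )
        freqs = probe_frequencies(m, freq_cut=cfg.freq_cut)
        kept_ids = prune_probes(
            m.subset_probes(freqs["retained"].to_numpy()),
            r2_max=cfg.r2_prune, window=cfg.prune_window, step=cfg.prune_step,
        )
        self.matrix_full = m
        self.matrix = m.subset_probes(kept_ids)
        if self.matrix.n_probes:
            self.freqs = probe_frequencies(self.matrix, freq_cut=cfg.freq_cut)
        else:  # e.g. an empty call table: nothing survives the filters
            self.freqs = self.matrix.probes.assign(
                dup_freq=[], del_freq=[], cnv_freq=[], retained=[]
            )
        freqs.to_csv(self.outdir / "probe_frequencies.tsv", sep="\t", index=False)
        self.matrix.probes.to_csv(
            self.outdir / "probes_retained.tsv", sep="\t", index=False
        )
        n_eff = effective_tests(
            self.matrix, variance_fraction=cfg.neff_variance_fraction
        )
        self.thresholds = thresholds(
            max(n_eff, 1), len(cfg.diseases) + 1, alpha=cfg.alpha
        )
        (self.outdir / "thresholds.json").write_text(
            json.dumps(
                {
                    "n_eff": self.thresholds.n_eff,
                    "n_traits": self.thresholds.n_traits,
                    "gw_p": self.thresholds.gw_p,
                    "xw_p": self.thresholds.xw_p,
                }
            )
        )
        self._log(
            f"{m.n_probes} probes encoded, {self.matrix.n_probes} retained, "
            f"n_eff={self.thresholds.n_eff}, gw_p={self.thresholds.gw_p:.3g}"
        )

    def _status_vector(self, disease: str) -> np.ndarray:
        s = self.pheno[f"{disease}_status"].map(
            {"case": 1.0, "control": 0.0}
        )
        return s.to_numpy(dtype=float)

    def _covariate_frame(self) -> pd.DataFrame:
        cols = ["age", "sex", "array"] + [
            c for c in self.pheno.columns if c.startswith("pc")
        ]
        return self.pheno[cols]

    def stage_gwas(self):
        cfg = self.cfg
        all_cov = self._covariate_frame()
        self.selected_covariates: dict[str, list[str]] = {}
        self.prefilters: dict[str, pd.DataFrame] = {}
        self.sumstats: dict[tuple[str, str], pd.DataFrame] = {}
        records = []
        outcomes = list(cfg.diseases) + ["disease_burden"]
        for disease in outcomes:
            if disease == "disease_burden":
                yburden = self.pheno["disease_burden"].to_numpy(dtype=float)
                status = (yburden > np.median(yburden)).astype(float)
                sel = select_covariates_linear(self.pheno["disease_burden"], all_cov)
            else:
                status = self._status_vector(disease)
                sel = select_covariates(
                    self.pheno[f"{disease}_status"], all_cov
                )
            self.selected_covariates[disease] = sel
            cov = all_cov[sel]
            pf_status = (
                status if disease != "disease_burden"
                else (yburden > np.median(yburden)).astype(float)
            )
            pf = prefilter(
                self.matrix, self.freqs, pf_status,
                fisher_cut=cfg.fisher_cut, min_cases=cfg.min_cases,
            )
            self.prefilters[disease] = pf
            for model in cfg.models:
                mask = pf[f"pass_{model}"].to_numpy()
                if disease == "disease_burden":
                    res = run_burden_gwas(
                        self.matrix, yburden, cov, model, probe_mask=mask
                    )
                else:
                    res = run_gwas(
                        self.matrix, status, cov, model, probe_mask=mask,
                        min_cases=cfg.min_cases,
                    )
                res.insert(0, "disease", disease)
                self.sumstats[(disease, model)] = res
                records.append(res)
        records = [r for r in records if len(r)]
        self.sumstats_all = (
            pd.concat(records, ignore_index=True)
            if records
            else pd.DataFrame(columns=["disease", "model", "probe_id", "p"])
        )
        self.sumstats_all.to_csv(self.outdir / "sumstats.tsv", sep="\t", index=False)
        self._log(f"{len(self.sumstats_all)} probe-model-disease regressions")

    def stage_condition(self):
        cfg = self.cfg
        gw_p = self.thresholds.gw_p
        cov_all = self._covariate_frame()
        leads = []
        for (disease, model), res in self.sumstats.items():
            sig = res.loc[res["p"].notna() & (res["p"] <= gw_p)]
            if sig.empty:
                continue
            cov = cov_all[self.selected_covariates[disease]]
            mask = self.prefilters[disease][f"pass_{model}"].to_numpy()
            if disease == "disease_burden":
                found = stepwise_conditional(
                    self.matrix, None, cov, model, gw_p, probe_mask=mask,
                    burden_phenotype=self.pheno["disease_burden"].to_numpy(float),
                )
            else:
                found = stepwise_conditional(
                    self.matrix, self._status_vector(disease), cov, model, gw_p,
                    probe_mask=mask,
                )
            if not found.empty:
                found.insert(0, "disease", disease)
                leads.append(found)
        self.leads = (
            pd.concat(leads, ignore_index=True)
            if leads
            else pd.DataFrame(
                columns=["disease", "model", "probe_id", "chrom", "pos", "beta",
                         "se", "p", "round"]
            )
        )
        self.leads.to_csv(self.outdir / "leads.tsv", sep="\t", index=False)
        self._log(f"{len(self.leads)} independent lead signals")

    def stage_regions(self):
        cfg = self.cfg
        intervals = []
        for _, lead in self.leads.iterrows():
            chrom, start, end = define_cnvr(
                self.matrix, lead["probe_id"], lead["model"],
                r2_min=cfg.r2_tag, window_bp=cfg.tag_window_bp,
            )
            intervals.append(
                {
                    "chrom": chrom, "start": start, "end": end,
                    "disease": lead["disease"], "model": lead["model"],
                    "probe_id": lead["probe_id"], "pos": lead["pos"],
                    "beta": lead["beta"], "se": lead["se"], "p": lead["p"],
                }
            )
        # per-disease merge: overlapping model-level signals of one disease
        # form one association with possibly several significant models
        self.signals = []
        for disease in {iv["disease"] for iv in intervals}:
            merged = merge_cnvrs([iv for iv in intervals if iv["disease"] == disease])
            for assoc in merged:
                best_model, main_model = label_models(
                    [{"model": s["model"], "p": s["p"]} for s in assoc.signals]
                )
                best_sig = min(assoc.signals, key=lambda s: s["p"])
                self.signals.append(
                    {
                        "signal_id": f"{disease}@{assoc.chrom}:{assoc.start}",
                        "disease": disease,
                        "chrom": assoc.chrom,
                        "cnvr_start": assoc.start, "cnvr_end": assoc.end,
                        "best_model": best_model, "main_model": main_model,
                        "models": ",".join(sorted({s["model"] for s in assoc.signals})),
                        "probe_id": best_sig["probe_id"], "pos": best_sig["pos"],
                        "model": best_model, "beta": best_sig["beta"],
                        "se": best_sig["se"], "p": best_sig["p"],
                    }
                )
        self.signals = pd.DataFrame(self.signals)
        # cross-disease merge into unique, non-overlapping regions
        self.cnvrs = merge_cnvrs(
            self.signals.rename(
                columns={"cnvr_start": "start", "cnvr_end": "end"}
            ).to_dict("records")
        ) if len(self.signals) else []
        self.signals.to_csv(self.outdir / "signals.tsv", sep="\t", index=False)
        cio.write_cnvr_table(self.cnvrs, self.outdir / "cnvrs.tsv")
        self._log(f"{len(self.signals)} signals in {len(self.cnvrs)} unique regions")

    def stage_validate(self):
        cfg = self.cfg
        cov_all = self._covariate_frame()
        rows = []
        for _, sig in self.signals.iterrows():
            disease = sig["disease"]
            i = self.matrix.probe_index(sig["probe_id"])
            g = self.matrix.row(i)
            encodings = {}
            for model in sig["models"].split(","):
                dose, valid = encode_genotypes(g, model)
                encodings[model] = np.where(valid, dose, np.nan)
            if disease == "disease_burden":
                rows.append(
                    {
                        "signal_id": sig["signal_id"], "fisher_p": np.nan,
                        "residual_p": np.nan, "coxph_p": np.nan,
                        "hazard_ratio": np.nan,
                        "tier": assign_tier(np.nan, np.nan, np.nan, True,
                                            cfg.tier_alpha),
                    }
                )
                continue
            cov = cov_all[self.selected_covariates[disease]]
            status = self._status_vector(disease)
            pf = self.prefilters[disease]
            fisher_p = float(
                pf.loc[pf["probe_id"] == sig["probe_id"], "fisher_p"].iloc[0]
            )
            res = residual_regression(status, cov, encodings)
            cox = coxph_fit(
                self.pheno[f"{disease}_age_last_healthy"].to_numpy(float),
                status, cov, encodings,
            )
            rows.append(
                {
                    "signal_id": sig["signal_id"], "fisher_p": fisher_p,
                    "residual_p": res["p"], "coxph_p": cox["p"],
                    "hazard_ratio": cox["hr"],
                    "tier": assign_tier(fisher_p, res["p"], cox["p"], False,
                                        cfg.tier_alpha),
                }
            )
        self.tiers = pd.DataFrame(
            rows, columns=["signal_id", "fisher_p", "residual_p", "coxph_p",
                           "hazard_ratio", "tier"]
        )
        self.tiers.to_csv(self.outdir / "tiers.tsv", sep="\t", index=False)
        # push tiers onto merged regions (best = lowest tier among members)
        tier_by_signal = dict(zip(self.tiers["signal_id"], self.tiers["tier"]))
        for r in self.cnvrs:
            member = [tier_by_signal.get(s.get("signal_id")) for s in r.signals]
            member = [t for t in member if t is not None]
            r.tier = min(member) if member else None
        cio.write_cnvr_table(self.cnvrs, self.outdir / "cnvrs.tsv")
        self._log(f"tiers assigned for {len(self.tiers)} signals")

    def stage_replicate(self):
        cfg = self.cfg
        if self.signals.empty:
            self.replication = pd.DataFrame(
                columns=["signal_id", "replication_probe", "p_old", "concordant",
                         "p_new", "evaluable", "strictly_replicated"]
            )
            self.replication.to_csv(
                self.outdir / "replication.tsv", sep="\t", index=False
            )
            self._log("no signals to replicate")
            return
        rep = simulate_replication_cohort(
            cfg.genome, cfg.effects, cfg.n_replication,
            cfg.replication_attenuation, cfg.seed + 1,
            covariate_spec=cfg.covariate_spec, diseases=cfg.diseases,
            probe_keep_fraction=cfg.replication_probe_keep,
        )
        samples = rep.phenotypes["sample_id"].to_numpy()
        m_rep = encode_probe_matrix(
            rep.calls, rep.probes, qs_cut=cfg.qs_cut, sample_ids=samples
        )
        cov_all = rep.phenotypes[
            ["age", "sex", "array"]
            + [c for c in rep.phenotypes.columns if c.startswith("pc")]
        ]
        results = []
        for disease in self.signals["disease"].unique():
            sub = self.signals.loc[self.signals["disease"] == disease]
            in_region = np.zeros(m_rep.n_probes, dtype=bool)
            for _, sig in sub.iterrows():
                in_region |= (
                    (m_rep.probes["chrom"] == str(sig["chrom"]))
                    & (m_rep.probes["pos"] >= sig["cnvr_start"])
                    & (m_rep.probes["pos"] <= sig["cnvr_end"])
                ).to_numpy()
            for model in sub["best_model"].unique():
                if disease == "disease_burden":
                    res = run_burden_gwas(
                        m_rep,
                        rep.phenotypes["disease_burden"].to_numpy(float),
                        cov_all, model, probe_mask=in_region,
                    )
                else:
                    status = rep.phenotypes[f"{disease}_status"].map(
                        {"case": 1.0, "control": 0.0}
                    ).to_numpy(dtype=float)
                    res = run_gwas(
                        m_rep, status, cov_all, model, probe_mask=in_region
                    )
                res["disease"], res["model"] = disease, model
                results.append(res)
        rep_results = pd.concat(results, ignore_index=True)
        rep_results.to_csv(
            self.outdir / "replication_sumstats.tsv", sep="\t", index=False
        )
        records = []
        for disease in self.signals["disease"].unique():
            sub = self.signals.loc[self.signals["disease"] == disease]
            for model in sub["best_model"].unique():
                pool = rep_results.loc[
                    (rep_results["disease"] == disease)
                    & (rep_results["model"] == model)
                ]
                recs = replicate(
                    sub.loc[sub["best_model"] == model], pool,
                    strict_alpha=cfg.alpha,
                )
                records.extend(recs)
        n_eval = sum(r.evaluable for r in records)
        if n_eval:
            cut = cfg.alpha / n_eval
            for r in records:
                r.strictly_replicated = bool(r.evaluable and r.p_new <= cut)
        self.replication = pd.DataFrame([dataclasses.asdict(r) for r in records])
        self.replication.to_csv(self.outdir / "replication.tsv", sep="\t", index=False)
        p_new = self.replication.loc[self.replication["evaluable"], "p_new"]
        if len(p_new):
            grid = replication_enrichment_grid(p_new.to_numpy())
            grid.to_csv(self.outdir / "replication_enrichment.tsv", sep="\t",
                        index=False)
        self._log(f"{n_eval} evaluable signals replicated against "
                  f"{cfg.n_replication} samples")

    def stage_bmi(self):
        cfg = self.cfg
        disease_signals = (
            self.signals.loc[self.signals["disease"] != "disease_burden"]
            if len(self.signals) else self.signals
        )
        if disease_signals.empty:
            self.bmi_results = pd.DataFrame(
                columns=["signal_id", "evaluable", "eligible", "likely_bmi_driven"]
            )
            self.bmi_results.to_csv(self.outdir / "bmi.tsv", sep="\t", index=False)
            self._log("no disease signals for BMI analysis")
            return
        cov_all = self._covariate_frame()
        status_by = {
            d: self._status_vector(d) for d in disease_signals["disease"].unique()
        }
        cov_by = {
            d: cov_all[self.selected_covariates[d]]
            for d in disease_signals["disease"].unique()
        }
        resid_cov = cov_all.assign(age2=cov_all["age"] ** 2)
        results = bmi_confounding(
            disease_signals.assign(model=disease_signals["best_model"]),
            self.matrix, status_by, cov_by,
            self.pheno["bmi"].to_numpy(float), resid_cov,
            gw_p=self.thresholds.gw_p,
            n_traits=self.thresholds.n_traits,
            alpha=cfg.alpha,
        )
        self.bmi_results = pd.DataFrame([dataclasses.asdict(r) for r in results])
        self.bmi_results.to_csv(self.outdir / "bmi.tsv", sep="\t", index=False)
        self._log(
            f"{int(self.bmi_results['eligible'].sum())} eligible signals, "
            f"{int(self.bmi_results['likely_bmi_driven'].sum())} likely BMI-driven"
        )

    def stage_burden(self):
        cfg = self.cfg
        burden = compute_burden(
            self.calls, self.pheno["sample_id"], qs_cut=cfg.qs_cut
        )
        burden.to_csv(self.outdir / "burden.tsv", sep="\t")
        cov_all = self._covariate_frame()
        rows = []
        n_traits = self.thresholds.n_traits
        for disease in list(cfg.diseases) + ["disease_burden"]:
            cov = cov_all[self.selected_covariates.get(disease, [])]
            if disease == "disease_burden":
                outcome = self.pheno["disease_burden"].to_numpy(float)
                binary = False
            else:
                outcome = self._status_vector(disease)
                binary = True
            for t in ("cnv", "dup", "del"):
                try:
                    res = burden_association(
                        burden[f"{t}_mb"].to_numpy(), outcome, cov, binary=binary
                    )
                except ValueError as exc:
                    self._log(f"burden {t}_mb vs {disease}: {exc}")
                    continue
                res.update(disease=disease, metric=f"{t}_mb",
                           significant=res["p"] <= cfg.alpha / n_traits)
                rows.append(res)
        self.burden_assoc = pd.DataFrame(rows)
        self.burden_assoc.to_csv(
            self.outdir / "burden_associations.tsv", sep="\t", index=False
        )
        # GWAS-signal-corrected burdens
        if len(self.signals):
            cnvr_table = self.signals.rename(
                columns={"cnvr_start": "start", "cnvr_end": "end"}
            )[["disease", "chrom", "start", "end", "models"]]
            corrected = gwas_signal_corrected_burden(
                self.calls, cnvr_table, self.pheno["sample_id"], qs_cut=cfg.qs_cut
            )
            crows = []
            for disease, tab in corrected.items():
                if disease == "disease_burden":
                    outcome, binary = self.pheno["disease_burden"].to_numpy(float), False
                elif disease in cfg.diseases:
                    outcome, binary = self._status_vector(disease), True
                else:
                    continue
                cov = cov_all[self.selected_covariates.get(disease, [])]
                for t in ("cnv", "dup", "del"):
                    try:
                        res = burden_association(
                            tab[f"{t}_mb"].to_numpy(), outcome, cov, binary=binary
                        )
                    except ValueError as exc:
                        self._log(f"corrected burden {t}_mb vs {disease}: {exc}")
                        continue
                    res.update(disease=disease, metric=f"{t}_mb_corrected",
                               significant=res["p"] <= cfg.alpha / n_traits)
                    crows.append(res)
            if crows:
                pd.DataFrame(crows).to_csv(
                    self.outdir / "burden_corrected_associations.tsv",
                    sep="\t", index=False,
                )
        self._log(f"{len(rows)} burden associations")

    def stage_report(self):
        rep = self.signals.copy() if len(self.signals) else pd.DataFrame(
            columns=["signal_id"]
        )
        for frame, cols in (
            (self.tiers, ["tier", "fisher_p", "residual_p", "coxph_p",
                          "hazard_ratio"]),
            (self.replication, ["p_new", "strictly_replicated", "evaluable"]),
            (self.bmi_results, ["eligible", "likely_bmi_driven"]),
        ):
            if len(frame) and "signal_id" in frame.columns:
                rep = rep.merge(
                    frame[["signal_id"] + [c for c in cols if c in frame.columns]],
                    on="signal_id", how="left",
                )
        self.report = rep
        rep.to_csv(self.outdir / "report.tsv", sep="\t", index=False)
        summary = {
            "n_signals": int(len(self.signals)),
            "n_cnvrs": int(len(self.cnvrs)),
            "n_eff": self.thresholds.n_eff,
            "gw_p": self.thresholds.gw_p,
            "xw_p": self.thresholds.xw_p,
        }
        (self.outdir / "report_summary.json").write_text(json.dumps(summary, indent=2))
        self._log(f"report written: {summary}")


def run_pipeline(config: RunConfig, outdir, through: str = "report") -> Path:
    """Execute the pipeline and return the run directory."""
    return PipelineRun(config, outdir).run(through=through)
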