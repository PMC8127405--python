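"""End-to-end orchestration: harmonize -> TWAS -> impute -> score ->
evaluate, driven by one YAML config, with a manifest recording inputs,
seeds and stage status. Re-runs skip completed stages unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import __version__
from .evaluate import CvScheme, ScorePredictor, evaluation_report
from .formats import (GenotypePanel, GwasSumstats, SnpWeightSet,
                      find_weight_dirs, harmonize, read_sumstats)
from .impute import impute_and_standardize, write_expression
from .prs import PrsSpec, clump_variants, compute_prs
from .scoring import GERS_THRESHOLDS, ScoreMatrix, stratified_gers
from .twas import attach_pp4, run_twas

log = logging.getLogger("gers")

STAGES = ("harmonize", "twas", "impute", "score", "evaluate")


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, msg: str):
        super().__init__(f"[{stage}:{code}] {msg}")
        self.stage, self.code = stage, code


@dataclass
class RunConfig:
    sumstats: str
    weights: str                  # root dir containing panel directories
    ref: str                      # PLINK prefix
    target: str                   # PLINK prefix
    pheno: str
    out: str
    hm3: str | None = None
    pp4: str | None = None
    trait_type: str = "continuous"
    gers_thresholds: tuple = GERS_THRESHOLDS
    strat_modes: tuple = ("all",)
    outer_k: int = 5
    inner_k: int = 10
    seed: int = 0
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.pop("schema_version", None)
        cfg = cls(**raw)
        for name in ("sumstats", "ref", "target", "pheno"):
            probe = getattr(cfg, name)
            if name in ("ref", "target"):
                probe = probe + ".bed"
            if not os.path.exists(probe):
                raise FileNotFoundError(f"config path {name}={probe} missing")
        return cfg


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class PipelineRun:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        os.makedirs(cfg.out, exist_ok=True)
        self.manifest_path = os.path.join(cfg.out, "manifest.json")
        if os.path.exists(self.manifest_path):
            with open(self.manifest_path) as fh:
                self.manifest = json.load(fh)
        else:
            self.manifest = {"version": __version__, "seed": cfg.seed,
                             "stages": {}, "inputs": {}}

    def _save(self):
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)

    def _done(self, stage: str) -> bool:
        return self.manifest["stages"].get(stage, {}).get("status") == "done"

    def _mark(self, stage: str, t0: float, **extra):
        self.manifest["stages"][stage] = {
            "status": "done", "seconds": round(time.time() - t0, 3), **extra}
        self._save()

    def path(self, name: str) -> str:
        return os.path.join(self.cfg.out, name)

    # -- stages ------------------------------------------------------------
    def run(self, force: bool = False) -> dict:
        cfg = self.cfg
        self.manifest["inputs"] = {
            "sumstats": _checksum(cfg.sumstats),
            "ref.bed": _checksum(cfg.ref + ".bed"),
            "target.bed": _checksum(cfg.target + ".bed"),
        }
        statuses = {}
        for stage in STAGES:
            if self._done(stage) and not force:
                log.info("stage %s: skipped (complete)", stage)
                statuses[stage] = "skipped"
                continue
            t0 = time.time()
            try:
                getattr(self, "_stage_" + stage)()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(stage, type(exc).__name__, str(exc)) from exc
            self._mark(stage, t0)
            statuses[stage] = "done"
            log.info("stage %s: done in %.1fs", stage, time.time() - t0)
        self.manifest["statuses_last_run"] = statuses
        self._save()
        return {"stages": statuses, "manifest": self.manifest_path}

    def _load_harmonized(self):
        ref = GenotypePanel.from_plink(self.path("harm.ref"))
        target = GenotypePanel.from_plink(self.path("harm.target"))
        ss = GwasSumstats(
            pd.read_csv(self.path("harm.sumstats.tsv"), sep="\t",
                        dtype={"SNP": str, "A1": str, "A2": str}),
            self.cfg.trait_type)
        sets = [SnpWeightSet.from_directory(d)
                for d in find_weight_dirs(self.path("harm.weights"))]
        return ss, sets, ref, target

    def _stage_harmonize(self):
        cfg = self.cfg
        ss = read_sumstats(cfg.sumstats, trait_type=cfg.trait_type)
        sets = [SnpWeightSet.from_directory(d)
                for d in find_weight_dirs(cfg.weights)]
        if not sets:
            raise StageError("harmonize", "no_weights",
                             f"no panel directories under {cfg.weights}")
        ref = GenotypePanel.from_plink(cfg.ref)
        target = GenotypePanel.from_plink(cfg.target)
        hm3 = None
        if cfg.hm3:
            hm3 = set(pd.read_csv(cfg.hm3, header=None)[0].astype(str))
        harm = harmonize(ss, sets, ref, target, hapmap3_ids=hm3)
        harm.ref.to_plink(self.path("harm.ref"))
        harm.target.to_plink(self.path("harm.target"))
        harm.sumstats.table.to_csv(self.path("harm.sumstats.tsv"), sep="\t",
                                   index=False)
        for ws in harm.weight_sets:
            ws.to_directory(os.path.join(self.path("harm.weights"),
                                         ws.panel_id))
        with open(self.path("harmonize.report.json"), "w") as fh:
            json.dump(harm.report, fh, indent=1, default=str)

    def _stage_twas(self):
        ss, sets, ref, _ = self._load_harmonized()
        tabs = [run_twas(ss, ws, ref) for ws in sets]
        twas = pd.concat(tabs, ignore_index=True)
        if self.cfg.pp4:
            pp4 = pd.read_csv(self.cfg.pp4, sep="\t",
                              dtype={"panel_id": str, "feature_id": str})
            twas = attach_pp4(twas, pp4)
        twas.to_csv(self.path("twas.tsv"), sep="\t", index=False)

    def _stage_impute(self):
        _, sets, ref, target = self._load_harmonized()
        for ws in sets:
            expr_t, expr_r = impute_and_standardize(target, ref, ws)
            write_expression(expr_t, self.path(f"expr.{ws.panel_id}.target.tsv"))
            write_expression(expr_r, self.path(f"expr.{ws.panel_id}.ref.tsv"))

    def _stage_score(self):
        cfg = self.cfg
        ss, sets, ref, target = self._load_harmonized()
        twas = pd.read_csv(self.path("twas.tsv"), sep="\t",
                           dtype={"panel_id": str, "feature_id": str,
                                  "gene_id": str, "chrom": str})
        combined: ScoreMatrix | None = None
        for ws in sets:
            expr_t, expr_r = impute_and_standardize(target, ref, ws)
            assoc = twas[twas["panel_id"] == ws.panel_id].reset_index(drop=True)
            for mode in cfg.strat_modes:
                sm = stratified_gers(expr_t, expr_r, assoc,
                                     thresholds=cfg.gers_thresholds, mode=mode)
                if sm.values.shape[1] == 0:
                    continue
                combined = sm if combined is None else combined.hstack(sm)
        if combined is None:
            raise StageError("score", "empty", "no GeRS columns produced")
        # PRS baseline
        spec = PrsSpec()
        retained = clump_variants(ss, ref, spec)
        prs = compute_prs(target, ss, retained, spec.thresholds, ref=ref)
        combined = combined.hstack(prs)
        combined.write(self.path("scores"))

    def _stage_evaluate(self):
        cfg = self.cfg
        scores = ScoreMatrix.read(self.path("scores"))
        pheno = pd.read_csv(cfg.pheno, sep="\t",
                            dtype={"FID": str, "IID": str})
        scheme = CvScheme(cfg.outer_k, cfg.inner_k, cfg.seed)
        gers_cols = [c for c in scores.values.columns if ".gers" in c]
        prs_cols = [c for c in scores.values.columns if c.startswith("prs")]
        results = []
        for name, cols in [("GeRS", gers_cols), ("PRS", prs_cols),
                           ("GeRS+PRS", gers_cols + prs_cols)]:
            if not cols:
                continue
            model = ScorePredictor.from_score_matrix(
                scores, pheno, cfg.trait_type, columns=cols, name=name)
            results.append(model.fit(scheme))
        comparisons = []
        names = [r.name for r in results]
        if "GeRS" in names and "PRS" in names:
            comparisons.append(("GeRS", "PRS"))
        if "GeRS+PRS" in names and "PRS" in names:
            comparisons.append(("GeRS+PRS", "PRS"))
        report = evaluation_report(results, comparisons)
        report["seed"] = cfg.seed
        with open(self.path("evaluation.json"), "w") as fh:
            json.dump(report, fh, indent=1, default=float)
        pd.DataFrame(report["models"]).to_csv(self.path("evaluation.tsv"),
                                              sep="\t", index=False)


def run_pipeline(cfg: RunConfig, force: bool = False) -> dict:
    """Execute all stages; returns {"stages": status map, "manifest": path}."""
    return PipelineRun(cfg).run(force=force)
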