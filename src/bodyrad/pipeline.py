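"""End-to-end orchestration: simulate → segment → extract → transform →
select → pool signatures → score → evaluate.

Each stage persists its outputs (CSV/JSON/NIfTI) under the run directory and
later stages read only those artifacts, so stages can be re-run separately.
A manifest with the config hash, package version, and per-artifact SHA-256
checksums makes reruns verifiable: the same config and seed reproduce
bit-identical artifacts.  Wall-clock timings go to a separate file so the
manifest itself stays deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bodycomp import composition_table
from .evaluate import harrell_c, km_estimate, logrank, stratify_risk, train_cutpoints
from .phantom import CohortConfig, generate_cohort, read_cohort, write_cohort
from .preprocessing import YeoJohnsonScaler, split_cohort
from .radiomics import default_registry, extract_features
from .selection import SelectionConfig, StabilityFeatureSelector, make_bootstrap_plan
from .signature import SignatureCoxModel, combine_scores, compute_score
from .signature import BODYCOMP_FEATURES, CLINICAL_FEATURES

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ["simulate", "split", "bodycomp", "radiomics", "transform",
          "select", "signature", "evaluate"]


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    bin_width: float = 25.0
    split_fraction: float = 0.8
    registry_classes: tuple = ("firstorder", "shape2D", "glszm")
    transform_clinical: bool = True
    resample_mode: str = "fixed-bootstrap"
    eval_bootstrap: int = 1000
    out_dir: str = "bodyrad_run"

    def validate(self):
        self.cohort.validate()
        self.selection.validate()
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.eval_bootstrap < 2:
            raise ValueError("eval_bootstrap must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        sel = SelectionConfig(**raw.pop("selection", {}))
        if "registry_classes" in raw:
            raw["registry_classes"] = tuple(raw["registry_classes"])
        cfg = cls(cohort=cohort, selection=sel, **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["registry_classes"] = list(self.registry_classes)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where the run lands, not what it computes
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _registry(cfg: RunConfig) -> dict:
    full = default_registry()
    return {k: v for k, v in full.items() if k in cfg.registry_classes}


# ---------------------------------------------------------------------------
# stages; each reads persisted inputs and writes artifacts under `out`

def stage_simulate(cfg: RunConfig, out: Path):
    patients, slices = generate_cohort(cfg.cohort, with_images=True)
    write_cohort(patients, slices, out)
    return ["cohort.csv"] + [f"images/{p.id}_{k}.nii"
                             for p in patients for k in ("hu", "labels")]


def stage_split(cfg: RunConfig, out: Path):
    df = pd.read_csv(out / "cohort.csv")
    plan = split_cohort(df["id"], strata=df["site"],
                        fraction=cfg.split_fraction, seed=cfg.cohort.seed + 1)
    plan.to_json(out / "split.json")
    return ["split.json"]


def stage_bodycomp(cfg: RunConfig, out: Path):
    patients, slices = read_cohort(out)
    with open(out / "split.json") as fh:
        train_ids = json.load(fh)["train_ids"]
    df = composition_table(patients, slices, train_ids=train_ids)
    df.to_csv(out / "bodycomp.csv", index=False)
    return ["bodycomp.csv"]


def stage_radiomics(cfg: RunConfig, out: Path):
    patients, slices = read_cohort(out)
    registry = _registry(cfg)
    rows = []
    for p, s in zip(patients, slices):
        fv = extract_features(s, registry=registry, bin_width=cfg.bin_width)
        fv["id"] = p.id
        rows.append(fv)
    df = pd.DataFrame(rows).set_index("id").reset_index()
    df.to_csv(out / "features.csv", index=False)
    sidecar = {"registry": {k: list(v) for k, v in registry.items()},
               "bin_width": cfg.bin_width, "grid_spacing_mm": 2.0}
    with open(out / "features_meta.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return ["features.csv", "features_meta.json"]


def _load_model_frame(out: Path):
    cohort = pd.read_csv(out / "cohort.csv").set_index("id")
    bc = pd.read_csv(out / "bodycomp.csv").set_index("id")
    rad = pd.read_csv(out / "features.csv").set_index("id")
    cohort["sex_male"] = (cohort["sex"] == "male").astype(float)
    return cohort, bc, rad


def stage_transform(cfg: RunConfig, out: Path):
    cohort, bc, rad = _load_model_frame(out)
    with open(out / "split.json") as fh:
        train_ids = json.load(fh)["train_ids"]
    cont = pd.concat(
        [bc[["smra", "smi", "vati", "sati"]], rad], axis=1)
    if cfg.transform_clinical:
        cont = pd.concat([cohort[["age", "bmi"]], cont], axis=1)
    scaler = YeoJohnsonScaler().fit(cont.loc[train_ids])
    transformed = scaler.transform(cont)
    if not cfg.transform_clinical:
        transformed = pd.concat([cohort[["age", "bmi"]], transformed], axis=1)
    transformed = pd.concat(
        [transformed, cohort[["sex_male"]],
         cohort[["asa_ge3"]].astype(float)], axis=1)
    transformed.reset_index().to_csv(out / "transformed.csv", index=False)
    scaler.to_json(out / "transform.json")
    return ["transformed.csv", "transform.json"]


def _training_outcome(out: Path):
    cohort = pd.read_csv(out / "cohort.csv").set_index("id")
    with open(out / "split.json") as fh:
        plan = json.load(fh)
    X = pd.read_csv(out / "transformed.csv").set_index("id")
    tr = plan["train_ids"]
    t = cohort.loc[tr, "time_months"].to_numpy()
    e = cohort.loc[tr, "event"].to_numpy().astype(bool)
    return cohort, plan, X, tr, t, e


def stage_select(cfg: RunConfig, out: Path):
    cohort, plan, X, tr, t, e = _training_outcome(out)
    rad_cols = [c for c in X.columns if "_original_" in c]
    bplan = make_bootstrap_plan(len(tr), cfg.selection.B, cfg.cohort.seed + 2)
    sel = StabilityFeatureSelector(
        B=cfg.selection.B, pool_cutoff=cfg.selection.pool_cutoff,
        corr_threshold=cfg.selection.corr_threshold,
        cv_folds=cfg.selection.cv_folds, random_state=cfg.cohort.seed + 2,
        plan=bplan, cv_rule=cfg.selection.cv_rule,
    ).fit(X.loc[tr, rad_cols], (t, e))
    sel.pool_frame().to_csv(out / "feature_pool.csv", index=False)
    with open(out / "candidates.json", "w") as fh:
        json.dump({"candidates": sel.candidates_, "status": sel.status_,
                   "n_skipped": sel.n_skipped_}, fh, indent=1)
    return ["feature_pool.csv", "candidates.json"]


def stage_signature(cfg: RunConfig, out: Path):
    cohort, plan, X, tr, t, e = _training_outcome(out)
    with open(out / "candidates.json") as fh:
        candidates = json.load(fh)["candidates"]
    bplan = make_bootstrap_plan(len(tr), cfg.selection.B, cfg.cohort.seed + 2)
    Xtr = X.loc[tr]
    artifacts = []
    scores = {}
    for name, cands in (("C", [c for c in CLINICAL_FEATURES if c in X.columns]),
                        ("B", [c for c in BODYCOMP_FEATURES if c in X.columns]),
                        ("R", candidates)):
        model = SignatureCoxModel(
            candidates=cands, B=cfg.selection.B,
            random_state=cfg.cohort.seed + 2, plan=bplan,
            resample_mode=cfg.resample_mode, name=name,
        ).fit(Xtr, (t, e))
        model.pool_frame().to_csv(out / f"signature_pool_{name}.csv",
                                  index=False)
        model.score_.to_json(out / f"score_{name}.json")
        artifacts += [f"signature_pool_{name}.csv", f"score_{name}.json"]
        scores[name] = model.score_
    # per-patient component scores on all patients
    lp = pd.DataFrame({f"{n}_score": compute_score(s, X)
                       for n, s in scores.items()}, index=X.index)
    # combined scores: Cox refit on component linear predictors
    combos = {"CR": ["C_score", "R_score"], "CB": ["C_score", "B_score"],
              "CBR": ["C_score", "B_score", "R_score"]}
    for cname, comps in combos.items():
        # drop degenerate components (e.g. an empty signature's constant lp)
        usable = [c for c in comps if lp.loc[tr, c].std() > 0]
        if len(usable) < 2:
            logger.warning("combined score %s skipped: fewer than two "
                           "informative components", cname)
            continue
        try:
            fs = combine_scores(lp.loc[tr, usable], t, e, cname)
            lp[f"{cname}_score"] = compute_score(fs, lp)
            fs.to_json(out / f"score_{cname}.json")
            artifacts.append(f"score_{cname}.json")
        except Exception as exc:  # degenerate component fits
            logger.warning("combined score %s skipped: %s", cname, exc)
    lp.reset_index().to_csv(out / "scores.csv", index=False)
    artifacts.append("scores.csv")
    return artifacts


def stage_evaluate(cfg: RunConfig, out: Path):
    cohort = pd.read_csv(out / "cohort.csv").set_index("id")
    with open(out / "split.json") as fh:
        plan = json.load(fh)
    lp = pd.read_csv(out / "scores.csv").set_index("id")
    results = {}
    artifacts = []
    for col in lp.columns:
        name = col.replace("_score", "")
        results[name] = {}
        for split, ids in (("train", plan["train_ids"]),
                           ("holdout", plan["holdout_ids"])):
            s = lp.loc[ids, col].to_numpy()
            t = cohort.loc[ids, "time_months"].to_numpy()
            e = cohort.loc[ids, "event"].to_numpy().astype(bool)
            entry = {}
            try:
                cres = harrell_c(s, t, e, n_bootstrap=cfg.eval_bootstrap,
                                 seed=cfg.cohort.seed + 3)
                entry.update(c=cres.c, ci_low=cres.ci_low, ci_high=cres.ci_high,
                             p_c_vs_half=cres.p,
                             n_comparable_pairs=cres.n_comparable_pairs)
            except ValueError as exc:
                entry["c_error"] = str(exc)
            cuts = train_cutpoints(lp.loc[plan["train_ids"], col].to_numpy())
            strata = stratify_risk(s, cuts)
            entry["strata_counts"] = {k: int(v) for k, v in
                                      zip(*np.unique(strata, return_counts=True))}
            try:
                chi2, dof, p = logrank(t, e, strata)
                entry.update(logrank_chi2=chi2, logrank_df=dof, logrank_p=p)
            except ValueError as exc:
                entry["logrank_error"] = str(exc)
            for label in np.unique(strata):
                km = km_estimate(t[strata == label], e[strata == label])
                fn = f"km_{name}_{split}_{label}.csv"
                km.to_csv(out / fn, index=False)
                artifacts.append(fn)
            entry["n"] = len(ids)
            results[name][split] = entry
    with open(out / "evaluation.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
    artifacts.append("evaluation.json")
    return artifacts


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "split": stage_split,
    "bodycomp": stage_bodycomp,
    "radiomics": stage_radiomics,
    "transform": stage_transform,
    "select": stage_select,
    "signature": stage_signature,
    "evaluate": stage_evaluate,
}


def run_stage(name: str, cfg: RunConfig, out_dir) -> list:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("stage=%s seed=%s config=%s", name, cfg.cohort.seed,
                cfg.config_hash())
    return _STAGE_FUNCS[name](cfg, out)


def run_pipeline(cfg: RunConfig, out_dir=None) -> dict:
    """Run all stages in order; returns the manifest (also written to disk)."""
    cfg.validate()
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": cfg.config_hash(), "version": __version__,
                "stages": {}}
    timings = {}
    for name in STAGES:
        t0 = _time.perf_counter()
        try:
            artifacts = run_stage(name, cfg, out)
        except Exception:
            logger.exception("stage %s failed; partial artifacts kept in %s",
                             name, out)
            raise
        timings[name] = _time.perf_counter() - t0
        manifest["stages"][name] = {a: _sha256(out / a) for a in sorted(artifacts)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(out / "timings.json", "w") as fh:
        json.dump(timings, fh, indent=1, sort_keys=True)
    with open(out / "config.yaml", "w") as fh:
        plain = json.loads(json.dumps(cfg.to_dict(), default=float))
        yaml.safe_dump(plain, fh, sort_keys=True)
    return manifest
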