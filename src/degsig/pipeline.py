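"""End-to-end orchestration: simulate -> deg -> enrich -> associate -> survive.

Every stage communicates through documented file formats (TSV/GMT/JSON)
so any stage can be rerun from files.  All outputs carry a provenance
header (package version, seed, config hash) and are byte-reproducible
for a fixed config: per-stage seeds are derived from the single config
seed salted with the stage name.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._utils import DegsigError, derive_seed, logger
from .association import classify_signatures, correlation_profile
from .enrichment import DEFAULT_ALPHA, ssgsea_matrix
from .io import (ClinicalTable, ExpressionMatrix, GeneSetCollection, align_samples,
                 read_clinical, read_expression, read_gmt, write_clinical,
                 write_expression, write_gmt)
from .sam import SamParams, build_deg_sets
from .simulate import (GroupEffects, SignatureSpec, SimulationConfig, SurvivalParams,
                       simulate_cohort, write_truth)
from .stratify import mean_sem_split
from .survival import combined_survival, survival_by_stratification


@dataclass
class PipelineConfig:
    out_dir: str = "out"
    expression_path: str | None = None
    clinical_path: str | None = None
    hallmark_gmt: str | None = None
    anchors: list[str] = field(default_factory=lambda: ["JAG1"])
    sam: SamParams = field(default_factory=SamParams)
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    simulate: dict | None = None  # SimulationConfig fields; enables the simulate stage
    combined_pairs: list[tuple[str, str]] = field(default_factory=list)  # (anchor, signature)
    stages: list[str] = field(default_factory=lambda: ["simulate", "deg", "enrich", "associate", "survive"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "sam" in raw and isinstance(raw["sam"], dict):
            raw["sam"] = SamParams(**raw["sam"])
        if "combined_pairs" in raw:
            raw["combined_pairs"] = [tuple(p) for p in raw["combined_pairs"]]
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # output location is not part of the analysis
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]

    def validate_paths(self) -> None:
        if "simulate" in self.stages and self.simulate is None and self.expression_path is None:
            raise DegsigError("config enables the simulate stage but gives no simulate block")
        for name, p in (("expression_path", self.expression_path),
                        ("clinical_path", self.clinical_path),
                        ("hallmark_gmt", self.hallmark_gmt)):
            if p is not None and not Path(p).exists():
                raise DegsigError(f"config {name} does not exist: {p}")


def _simulation_config(raw: dict, seed: int) -> SimulationConfig:
    raw = dict(raw)
    sigs = tuple(SignatureSpec(**s) for s in raw.pop("signatures", []))
    surv = SurvivalParams(**raw.pop("survival", {}))
    effects = GroupEffects(**raw.pop("group_effects", {}))
    raw.pop("seed", None)
    if "anchors" in raw:
        raw["anchors"] = tuple(raw["anchors"])
    return SimulationConfig(signatures=sigs, survival=surv, group_effects=effects, seed=seed, **raw)


def _header(config: PipelineConfig) -> str:
    return (f"# degsig v{__version__}\n# seed: {config.seed}\n"
            f"# config: {config.config_hash()}\n")


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, index_label: str) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g", mode="a")


def run_all(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    config.validate_paths()
    out = Path(config.out_dir)
    for sub in ("deg", "enrichment", "association", "survival"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    # --- inputs (simulated or from files)
    if "simulate" in config.stages and config.simulate is not None:
        sim_cfg = _simulation_config(config.simulate, derive_seed(config.seed, "simulate"))
        cohort = simulate_cohort(sim_cfg)
        expr, clin = cohort.expression, cohort.clinical
        hallmarks = cohort.true_signatures
        write_expression(expr, out / "expression.tsv")
        write_clinical(clin, out / "clinical.tsv")
        write_gmt(hallmarks, out / "signatures.gmt")
        write_truth(cohort, out / "truth.json")
    else:
        if config.expression_path is None:
            raise DegsigError("no expression input: give expression_path or a simulate block")
        fmt = "gct" if str(config.expression_path).endswith(".gct") else "tsv"
        expr = read_expression(config.expression_path, format=fmt)
        clin = read_clinical(config.clinical_path) if config.clinical_path else None
        if config.hallmark_gmt is None:
            raise DegsigError("no hallmark GMT given")
        hallmarks = read_gmt(config.hallmark_gmt)
    if clin is not None:
        expr, clin = align_samples(expr, clin)

    # --- deg
    deg_sets: GeneSetCollection | None = None
    if "deg" in config.stages:
        sam_params = SamParams(**{**asdict(config.sam), "seed": derive_seed(config.seed, "deg")})
        deg_sets, deg_results = build_deg_sets(expr, None, list(config.anchors), sam_params)
        for anchor, res in deg_results.items():
            _write_tsv(res.table, out / "deg" / f"{anchor}_sam.tsv", config, "gene_id")
        write_gmt(deg_sets, out / "deg" / "deg_sets.gmt")

    # --- enrich: ssGSEA of hallmark sets and DEG sets
    enr = enr_deg = None
    if "enrich" in config.stages:
        enr = ssgsea_matrix(expr, hallmarks, alpha=config.alpha)
        _write_tsv(enr.es, out / "enrichment" / "hallmark_es.tsv", config, "set")
        _write_tsv(enr.z, out / "enrichment" / "hallmark_z.tsv", config, "set")
        if deg_sets is not None and len(deg_sets):
            enr_deg = ssgsea_matrix(expr, deg_sets, alpha=config.alpha)
            _write_tsv(enr_deg.es, out / "enrichment" / "deg_es.tsv", config, "set")
            _write_tsv(enr_deg.z, out / "enrichment" / "deg_z.tsv", config, "set")

    # --- associate: predictors = anchor expression (+ DEG z rows)
    if "associate" in config.stages and enr is not None:
        predictors = expr.data.loc[[a for a in config.anchors if a in expr.data.index]]
        if enr_deg is not None:
            predictors = pd.concat([predictors, enr_deg.z])
        profile = correlation_profile(predictors, enr, dataset_tag="cohort")
        _write_tsv(profile.matrix, out / "association" / "correlation_profile.tsv", config, "signature")
        cls = classify_signatures([profile])
        cls_df = pd.DataFrame({
            "sum_r": cls.sum_r,
            "class": ["positive" if s in cls.positive else "negative" if s in cls.negative else "unassigned"
                      for s in cls.sum_r.index],
        })
        _write_tsv(cls_df, out / "association" / "signature_classes.tsv", config, "signature")

    # --- survive
    if "survive" in config.stages and clin is not None:
        results = []
        km_frames = []
        strata = {}
        for anchor in config.anchors:
            if anchor not in expr.data.index:
                continue
            strata[anchor] = mean_sem_split(expr.row(anchor))
        if enr is not None:
            for name in enr.set_names:
                strata[f"z:{name}"] = mean_sem_split(enr.z.loc[name])
        for label, strat in strata.items():
            try:
                km_hi, km_lo, lr = survival_by_stratification(strat, clin)
            except DegsigError as exc:
                logger.warning("survival for %s skipped: %s", label, exc)
                continue
            results.append((label, km_hi.times.size + km_lo.times.size,
                            int(lr.observed.sum()), lr.chi2, lr.df, lr.p))
            for km in (km_hi, km_lo):
                f = km.to_frame()
                f.insert(0, "group", f"{label}:{km.label}")
                km_frames.append(f)
        for anchor, sig in config.combined_pairs:
            if anchor not in strata or f"z:{sig}" not in strata:
                logger.warning("combined pair (%s, %s) unavailable; skipped", anchor, sig)
                continue
            try:
                curves, overall, pairwise = combined_survival(strata[anchor], strata[f"z:{sig}"], clin)
            except DegsigError as exc:
                logger.warning("combined survival (%s, %s) skipped: %s", anchor, sig, exc)
                continue
            results.append((f"{anchor}x{sig}", sum(c.times.size for c in curves.values()),
                            int(overall.observed.sum()), overall.chi2, overall.df, overall.p))
            for (g1, g2), lr in pairwise.items():
                results.append((f"{anchor}x{sig}:{g1}-vs-{g2}", 0, int(lr.observed.sum()),
                                lr.chi2, lr.df, lr.p))
        res_df = pd.DataFrame(results, columns=["stratifier", "n_times", "events", "chi2", "df", "p"]
                              ).set_index("stratifier")
        _write_tsv(res_df, out / "survival" / "logrank.tsv", config, "stratifier")
        if km_frames:
            km_all = pd.concat(km_frames, ignore_index=True).set_index("group")
            _write_tsv(km_all, out / "survival" / "km_curves.tsv", config, "group")

    logger.info("pipeline complete: %s", out)
    return out
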