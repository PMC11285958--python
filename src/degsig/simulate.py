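"""Synthetic expression cohorts with planted ground truth.

The generator produces the statistical structure the analysis assumes so
every downstream stage has a recovery test:

* per sample, a standard-normal latent activity per anchor gene; the
  anchor's expression row is that activity plus small observation noise;
* co-expression modules whose genes load on the anchor activity with a
  loading solved so the gene-activity Pearson correlation equals the
  target rho: ``beta = rho * sigma / sqrt(1 - rho^2)``;
* latent signature activities with a chosen correlation sign to the
  first anchor's activity (``h = sign * gamma * a + noise``), whose
  member genes load on them;
* pure-noise background genes (an honest null for SAM's FDR);
* exponential survival with hazard log-linear in the first anchor's
  activity and one designated signature activity, censored by an
  independent exponential whose rate is solved for the target fraction;
* optional tumor/normal, ordinal-stage and paired pre/post additive
  effects on the anchor rows.

Values are on an arbitrary log scale; no count-level noise, library-size
or batch structure is simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._utils import DegsigError, logger
from .io import ClinicalTable, ExpressionMatrix, GeneSet, GeneSetCollection


@dataclass(frozen=True)
class SignatureSpec:
    name: str
    size: int
    sign: int  # +1 or -1: planted correlation sign to the anchor activity
    strength: float = 0.5  # gamma

    def __post_init__(self) -> None:
        if self.size < 2:
            raise DegsigError(f"signature {self.name!r}: size must be >= 2")
        if self.sign not in (1, -1):
            raise DegsigError(f"signature {self.name!r}: sign must be +1 or -1")
        if self.strength < 0:
            raise DegsigError(f"signature {self.name!r}: strength must be >= 0")


@dataclass(frozen=True)
class SurvivalParams:
    baseline_hazard: float = 0.05
    coef_anchor: float = 0.7  # theta1, on the first anchor's latent activity
    coef_signature: float = 0.7  # theta2, on the designated signature activity
    censoring_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise DegsigError("baseline_hazard must be > 0")
        if not (0 <= self.censoring_fraction < 1):
            raise DegsigError("censoring_fraction must be in [0, 1)")


@dataclass(frozen=True)
class GroupEffects:
    tumor_normal_shift: float | None = None
    stage_slope: float | None = None
    paired_treatment_effect: float | None = None


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 300
    n_background_genes: int = 1000
    anchors: tuple[str, ...] = ("JAG1",)
    module_size: int | dict[str, int] = 100
    target_rho: float | dict[str, float] = 0.5
    signatures: tuple[SignatureSpec, ...] = ()
    noise_sd: float = 1.0
    anchor_noise_sd: float = 0.05
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    survival_signature: str | None = None  # default: first signature
    group_effects: GroupEffects = field(default_factory=GroupEffects)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise DegsigError("n_samples must be >= 10")
        for anchor in self.anchors:
            if _per_anchor(self.module_size, anchor) < 2:
                raise DegsigError(f"module_size for {anchor!r} must be >= 2")
            rho = _per_anchor(self.target_rho, anchor)
            if not (-1 < rho < 1):
                raise DegsigError(f"target_rho {rho} for {anchor!r} infeasible; must lie in (-1, 1)")
        if self.noise_sd <= 0:
            raise DegsigError("noise_sd must be > 0")
        names = list(self.anchors) + [s.name for s in self.signatures]
        if len(names) != len(set(names)):
            raise DegsigError("anchor and signature names must be unique")
        if self.survival_signature is not None and self.survival_signature not in {
            s.name for s in self.signatures
        }:
            raise DegsigError(f"unknown survival_signature {self.survival_signature!r}")


@dataclass
class GroundTruth:
    module_members: dict[str, list[str]]
    signature_members: dict[str, list[str]]
    signature_signs: dict[str, int]
    activities: pd.DataFrame  # (anchors + signatures) x samples latent activities
    hazard: SurvivalParams
    survival_signature: str | None
    module_loading: dict[str, float]


@dataclass
class SimulatedCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    true_signatures: GeneSetCollection
    truth: GroundTruth
    config: SimulationConfig


def _per_anchor(value, anchor: str):
    """A scalar applies to every anchor; a dict is looked up per anchor."""
    if isinstance(value, dict):
        if anchor not in value:
            raise DegsigError(f"no value for anchor {anchor!r}")
        return value[anchor]
    return value


def module_loading(rho: float, noise_sd: float) -> float:
    """Loading beta with corr(beta*a + noise, a) == rho for unit-variance a."""
    return rho * noise_sd / np.sqrt(1.0 - rho**2)


def _censoring_rate_for(lam: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_s c/(c+lambda_s) == target."""

    def frac(c: float) -> float:
        return float(np.mean(c / (c + lam))) - target

    lo, hi = 1e-12 * lam.min(), 1e12 * lam.max()
    return float(brentq(frac, lo, hi, maxiter=200))


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort; the same config (incl. seed) is bit-reproducible."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    sigma = config.noise_sd

    rows: dict[str, np.ndarray] = {}
    activities: dict[str, np.ndarray] = {}

    # anchors and their co-expression modules
    module_members: dict[str, list[str]] = {}
    loadings: dict[str, float] = {}
    for anchor in config.anchors:
        size = _per_anchor(config.module_size, anchor)
        beta = module_loading(_per_anchor(config.target_rho, anchor), sigma)
        loadings[anchor] = float(beta)
        a = rng.standard_normal(n)
        activities[anchor] = a
        rows[anchor] = a + config.anchor_noise_sd * rng.standard_normal(n)
        members = [f"{anchor}_M{j:03d}" for j in range(size)]
        module_members[anchor] = members
        noise = rng.standard_normal((size, n))
        for g, eps in zip(members, noise):
            rows[g] = beta * a + sigma * eps

    # signatures, driven by the first anchor's activity
    a0 = activities[config.anchors[0]]
    signature_members: dict[str, list[str]] = {}
    signature_signs: dict[str, int] = {}
    for spec in config.signatures:
        h = spec.sign * spec.strength * a0 + rng.standard_normal(n)
        activities[spec.name] = h
        members = [f"{spec.name}_G{j:03d}" for j in range(spec.size)]
        signature_members[spec.name] = members
        signature_signs[spec.name] = spec.sign
        noise = rng.standard_normal((spec.size, n))
        for g, eps in zip(members, noise):
            rows[g] = h + sigma * eps

    # pure-noise background
    for j in range(config.n_background_genes):
        rows[f"BG{j:05d}"] = sigma * rng.standard_normal(n)

    # survival: exponential, hazard log-linear in a0 and the designated signature
    surv = config.survival
    sig_name = config.survival_signature or (config.signatures[0].name if config.signatures else None)
    h_term = activities[sig_name] * surv.coef_signature if sig_name else 0.0
    lam = surv.baseline_hazard * np.exp(surv.coef_anchor * a0 + h_term)
    event_time = rng.exponential(1.0 / lam)
    if surv.censoring_fraction > 0:
        c_rate = _censoring_rate_for(lam, surv.censoring_fraction)
        censor_time = rng.exponential(1.0 / c_rate, size=n)
        os_time = np.minimum(event_time, censor_time)
        os_event = (event_time <= censor_time).astype(int)
    else:
        os_time = event_time
        os_event = np.ones(n, dtype=int)

    clin = pd.DataFrame({"os_time": os_time, "os_event": os_event}, index=pd.Index(sample_ids, name="sample_id"))

    # optional clinical group structure with additive shifts on anchor rows
    ge = config.group_effects
    if ge.tumor_normal_shift is not None:
        tumor = np.zeros(n, dtype=bool)
        tumor[: (n + 1) // 2] = True
        clin["tissue_class"] = np.where(tumor, "tumor", "normal")
        for anchor in config.anchors:
            rows[anchor] = rows[anchor] + ge.tumor_normal_shift * tumor
    if ge.stage_slope is not None:
        stage = rng.integers(1, 5, size=n)
        clin["stage"] = stage
        for anchor in config.anchors:
            rows[anchor] = rows[anchor] + ge.stage_slope * (stage - 2.5)
    if ge.paired_treatment_effect is not None:
        patient = np.array([f"P{i // 2:04d}" for i in range(n)])
        timepoint = np.array(["pre", "post"] * ((n + 1) // 2))[:n]
        if n % 2 == 1:
            timepoint[-1] = "pre"
        clin["timepoint"] = timepoint
        clin["patient_id"] = patient
        post = timepoint == "post"
        for anchor in config.anchors:
            rows[anchor] = rows[anchor] + ge.paired_treatment_effect * post

    expr = ExpressionMatrix(pd.DataFrame(rows, index=sample_ids).T)
    true_sets = GeneSetCollection(
        [GeneSet(name=name, description=f"planted signature (sign {signature_signs[name]:+d})",
                 members=frozenset(members))
         for name, members in signature_members.items()]
    )
    truth = GroundTruth(
        module_members=module_members,
        signature_members=signature_members,
        signature_signs=signature_signs,
        activities=pd.DataFrame(activities, index=sample_ids).T,
        hazard=surv,
        survival_signature=sig_name,
        module_loading=loadings,
    )
    logger.info("simulated cohort: %d genes x %d samples, %d anchors, %d signatures",
                expr.shape[0], n, len(config.anchors), len(config.signatures))
    return SimulatedCohort(
        expression=expr, clinical=ClinicalTable(clin), true_signatures=true_sets,
        truth=truth, config=config,
    )


def censoring_rate(cohort: SimulatedCohort) -> float:
    """Observed fraction of censored samples (os_event == 0)."""
    events = cohort.clinical.data["os_event"].to_numpy()
    return float((events == 0).mean())


def write_truth(cohort: SimulatedCohort, path: str | Path) -> None:
    """JSON sidecar with planted module membership, signs and hazard model."""
    truth = cohort.truth
    payload = {
        "module_members": truth.module_members,
        "signature_members": truth.signature_members,
        "signature_signs": truth.signature_signs,
        "survival_signature": truth.survival_signature,
        "hazard": {
            "baseline_hazard": truth.hazard.baseline_hazard,
            "coef_anchor": truth.hazard.coef_anchor,
            "coef_signature": truth.hazard.coef_signature,
            "censoring_fraction": truth.hazard.censoring_fraction,
        },
        "module_loading": truth.module_loading,
        "seed": cohort.config.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
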