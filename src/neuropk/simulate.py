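"""Synthetic rat-study generator.

Emulates the study design end to end: 11 male rats around 306 g, 150
mg/kg IV over 2 minutes once daily for 4 days, 9 plasma samples per
animal (5 within the first 24 h), 2 CSF samples within the first 24 h
and 6 in total with later samples staggered across animals,
intracisternal catheter failures that wipe an animal's CSF record, and
the occasional 100-fold plasma outlier. Noise follows the assay error
polynomial SD(Y) = C0 + C1*Y per matrix; values below the assay LLOQ
are flagged but kept.

True per-animal parameters and noise-free concentrations are stored in
separate ``TruthRecord`` objects so recovery tests can compare against
ground truth without the truth ever entering the fitting path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import reference
from .likelihood import ErrorModel, default_error_model
from .models import (
    CSF,
    PLASMA,
    TWO_MINUTE_INFUSION_H,
    DoseEvent,
    Observation,
    PKParams,
    SubjectRecord,
    get_structure,
    predict_concentrations,
    standard_regimen,
)

__all__ = [
    "StudyDesign",
    "TruthRecord",
    "default_design",
    "rich_design",
    "sample_population",
    "simulate_subject",
    "simulate_study",
    "inject_artifacts",
]


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design and noise/artifact settings of a synthetic study.

    Times are hours after the first dose. ``stagger_offsets_h`` cycles
    across animals and shifts every post-day-1 sample, emulating the
    staggered schedule of the original protocol.
    """

    n_animals: int = 11
    weight_mean_g: float = 306.0
    weight_sd_g: float = 25.0
    dose_mg_per_kg: float = 150.0
    n_days: int = 4
    dose_interval_h: float = 24.0
    infusion_h: float = TWO_MINUTE_INFUSION_H
    plasma_times_h: tuple[float, ...] = (0.2, 0.5, 1.0, 2.0, 4.0, 24.2, 48.2, 72.2, 76.0)
    csf_times_h: tuple[float, ...] = (1.0, 2.0, 24.5, 26.0, 48.5, 72.5)
    stagger_offsets_h: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5)
    csf_failure_prob: float = 4.0 / 11.0
    outlier_prob: float = 1.0 / 11.0
    noise_scale: float = 1.0
    lloq: dict = field(default_factory=lambda: dict(reference.LLOQ))
    structure: str = "four_compartment_lag"

    def __post_init__(self) -> None:
        horizon = self.n_days * self.dose_interval_h + self.dose_interval_h
        for t in self.plasma_times_h + self.csf_times_h:
            if not 0 <= t <= horizon:
                raise ValueError(f"sample time {t} outside the study horizon")
        for p in (self.csf_failure_prob, self.outlier_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0,1]")

    def doses_for(self, weight_g: float) -> list[DoseEvent]:
        return standard_regimen(
            weight_g=weight_g,
            dose_mg_per_kg=self.dose_mg_per_kg,
            n_days=self.n_days,
            interval_h=self.dose_interval_h,
            infusion_h=self.infusion_h,
        )


def default_design(**overrides) -> StudyDesign:
    """The 11-animal published design."""
    return StudyDesign(**overrides)


def rich_design(n_animals: int = 25, **overrides) -> StudyDesign:
    """A dense single-dose design (12 plasma + 8 CSF samples in 24 h).

    Used for parameter-recovery and end-to-end checks, where sampling
    density rather than the sparse clinical-style schedule is wanted.
    Plasma sampling starts right after the 2-minute infusion ends: the
    central-peripheral distribution half-life is under a minute, so the
    early draws are what anchor the central volume and the
    intercompartmental rates. Sampling stops while concentrations are
    still well above the assay quantitation limit - draws taken after
    the profile has decayed into the assay noise floor carry no signal
    and only bias the washout. No catheter failures and no outliers.
    """
    kw = dict(
        n_animals=n_animals,
        n_days=1,
        plasma_times_h=(0.05, 0.1, 0.2, 0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0),
        csf_times_h=(0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0),
        stagger_offsets_h=(0.0,),
        csf_failure_prob=0.0,
        outlier_prob=0.0,
    )
    kw.update(overrides)
    return StudyDesign(**kw)


@dataclass
class TruthRecord:
    """Ground truth for one simulated animal (never used in fitting)."""

    subject_id: str
    params: PKParams
    weight_g: float
    truth: list[tuple[float, str, float]]  # (time, channel, noise-free conc)

    def channel_values(self, output: str) -> np.ndarray:
        return np.array([v for _, ch, v in self.truth if ch == output])


def _lognormal_from_median_cv(median: float, cv_pct: float):
    """(mu, sigma) of a log-normal with the given median and CV%."""
    cv = cv_pct / 100.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return math.log(median), sigma


def sample_population(
    medians: PKParams,
    cv_percents: dict[str, float],
    n: int,
    seed: int,
    structure: str = "four_compartment_lag",
) -> list[PKParams]:
    """Log-normal per-parameter draws with given medians and CV%.

    A log-normal with median m and coefficient of variation c has
    mu = ln m and sigma^2 = ln(1 + c^2); parameters are drawn
    independently.
    """
    structure = get_structure(structure)
    rng = np.random.default_rng(seed)
    draws = {}
    for name in structure.active_params:
        m = medians.get(name)
        if m is None or m <= 0:
            raise ValueError(f"positive median required for {name!r}")
        cv = cv_percents.get(name, 0.0)
        if cv < 0:
            raise ValueError(f"negative CV% for {name!r}")
        mu, sigma = _lognormal_from_median_cv(m, cv)
        draws[name] = np.exp(rng.normal(mu, sigma, size=n)) if sigma > 0 else np.full(n, m)
    return [
        PKParams(**{name: float(draws[name][i]) for name in structure.active_params})
        for i in range(n)
    ]


def _add_noise(truth: np.ndarray, sd0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise truncated at zero: resample once, then clamp."""
    obs = truth + rng.normal(0.0, 1.0, size=truth.shape) * sd0
    neg = obs < 0
    if np.any(neg):
        obs[neg] = truth[neg] + rng.normal(0.0, 1.0, size=int(neg.sum())) * sd0[neg]
        np.clip(obs, 0.0, None, out=obs)
    return obs


def simulate_subject(
    params: PKParams,
    design: StudyDesign,
    weight_g: float,
    seed: int,
    subject_id: str = "R1",
    stagger_h: float = 0.0,
    error_model: ErrorModel | None = None,
) -> tuple[SubjectRecord, TruthRecord]:
    """One animal: weight-based regimen, scheduled samples, assay noise.

    The noise SD uses the channel's error polynomial evaluated at the
    noise-free concentration, scaled by ``design.noise_scale``; values
    below the LLOQ are flagged (``extra['below_lloq']``) but reported.
    """
    rng = np.random.default_rng(seed)
    error_model = error_model or default_error_model()
    doses = design.doses_for(weight_g)
    observations: list[Observation] = []
    truth_rows: list[tuple[float, str, float]] = []
    for output, times in ((PLASMA, design.plasma_times_h), (CSF, design.csf_times_h)):
        t = np.array(
            [ti if ti <= design.dose_interval_h else ti + stagger_h for ti in times]
        )
        clean = predict_concentrations(params, design.structure, doses, t, output)
        sd0 = error_model.polynomial(output).sd(clean) * design.noise_scale
        noisy = _add_noise(clean.copy(), sd0, rng) if design.noise_scale > 0 else clean
        lloq = design.lloq.get(output)
        for ti, yv, cv in zip(t, noisy, clean):
            extra = {}
            if lloq is not None and yv < lloq:
                extra["below_lloq"] = "1"
            observations.append(
                Observation(time=float(ti), value=float(yv), output=output, extra=extra)
            )
            truth_rows.append((float(ti), output, float(cv)))
    subject = SubjectRecord(
        id=subject_id, weight=weight_g, doses=doses, observations=observations
    )
    truth = TruthRecord(
        subject_id=subject_id, params=params, weight_g=weight_g, truth=truth_rows
    )
    return subject, truth


def inject_artifacts(
    dataset: Sequence[SubjectRecord],
    csf_failure_prob: float,
    outlier_prob: float,
    seed: int,
) -> list[SubjectRecord]:
    """Catheter failures (drop all CSF rows) and 100-fold plasma outliers.

    Outlier rows keep ``excluded=False``: spotting and excluding them is
    downstream quality control, as in the original analysis.
    """
    for p in (csf_failure_prob, outlier_prob):
        if not 0 <= p <= 1:
            raise ValueError(f"probability {p} outside [0,1]")
    rng = np.random.default_rng(seed)
    out = []
    for sub in dataset:
        obs = list(sub.observations)
        if rng.random() < csf_failure_prob:
            obs = [o for o in obs if o.output != CSF]
        if outlier_prob > 0 and rng.random() < outlier_prob:
            plasma_idx = [i for i, o in enumerate(obs) if o.output == PLASMA]
            if plasma_idx:
                i = int(rng.choice(plasma_idx))
                o = obs[i]
                obs[i] = Observation(
                    time=o.time,
                    value=o.value * 100.0,
                    output=o.output,
                    excluded=False,
                    extra=dict(o.extra),
                )
        out.append(
            SubjectRecord(
                id=sub.id, weight=sub.weight, doses=list(sub.doses), observations=obs
            )
        )
    return out


def simulate_study(
    design: StudyDesign | None = None,
    medians: PKParams | None = None,
    cv_percents: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[SubjectRecord], list[TruthRecord]]:
    """A complete synthetic study: population draws, sampling, artifacts."""
    design = design or default_design()
    medians = medians or reference.REFERENCE_MEDIANS
    cv_percents = cv_percents if cv_percents is not None else dict(reference.REFERENCE_CV_PCT)
    rng = np.random.default_rng(seed)
    params = sample_population(
        medians,
        cv_percents,
        design.n_animals,
        seed=int(rng.integers(2**31)),
        structure=design.structure,
    )
    weights = rng.normal(design.weight_mean_g, design.weight_sd_g, design.n_animals)
    weights = np.clip(weights, 50.0, None)
    subjects, truths = [], []
    for i in range(design.n_animals):
        stagger = design.stagger_offsets_h[i % len(design.stagger_offsets_h)]
        sub, tr = simulate_subject(
            params[i],
            design,
            float(weights[i]),
            seed=int(rng.integers(2**31)),
            subject_id=f"R{i + 1}",
            stagger_h=stagger,
        )
        subjects.append(sub)
        truths.append(tr)
    subjects = inject_artifacts(
        subjects,
        design.csf_failure_prob,
        design.outlier_prob,
        seed=int(rng.integers(2**31)),
    )
    return subjects, truths
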