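"""Synthetic longitudinal MS cohort generator with known ground truth.

The forward model mirrors the structure the analysis pipeline assumes:

* Each patient has a latent *untreated* CombiWISE trajectory, linear in
  age, with an intercept at the first visit (``baseline_cw``) and a true
  untreated slope.  The slope couples to the patient's adjusted
  CombiWISE/age, COMRIS-CTD and therapy delay (plus shifted-gamma noise
  allowing a minority of improving patients).
* Treatment epochs carry the same age-dependent efficacy lines the
  adjustment calculus uses.  Past treatment lowers the measured baseline
  multiplicatively (``measured = untreated * (1 - Eff(0, t0))``); during
  follow-up each treated segment attenuates the slope
  (``observed = true * (1 - Eff)`` while worsening, ``true / (1 - Eff)``
  while improving), i.e. the generator is the exact inverse of the
  adjustment equations.
* Visit-level CombiWISE adds independent Gaussian measurement noise, and
  exacerbation visits receive a transient bump so the exclusion rule is
  exercised end-to-end.
* Each emitted CombiWISE value is decomposed into an internally consistent
  (EDSS, SNRS, T25FW, 9HPT) quadruple: EDSS is drawn on its legal grid
  from a target correlated with the composite, SNRS follows its own
  anti-correlated integer scale, and the two timed tests are solved so the
  composite formula reproduces the emitted value to machine precision.

Marginal distributions default to the real cohort's summary moments (age
48.6 +/- 11.6 y, onset 37.1 +/- 11.4 y, baseline CombiWISE 30.4 +/- 17.5,
COMRIS-CTD 12.8 +/- 6.3, ~50% female, ~88% white, ~60% smokers) and the
mean follow-up of 4.49 y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .cohort import PatientRecord, TreatmentEpoch, Visit, write_cohort
from .scales import COMBIWISE_COEFFICIENTS
from .therapy import EfficacyModel, cumulative_efficacy, epoch_efficacy

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "generate_files", "scale_experiment"]


@dataclass(frozen=True)
class SeverityCoupling:
    """True-slope model: linear in severity and MRI burden, plus a step
    effect of delayed therapy start (untreated compartmentalized
    inflammation saturates, so the delay acts as a threshold rather than a
    linear dose)."""

    slope_mean: float = 1.0  # CombiWISE units/year
    cw_per_age: float = 1.0  # per SD of untreated baseline CW / age
    cw_saturation_sd: float = 1.25  # severity effect saturates beyond ~1.25 SD
    # (progression rates plateau at high disability)
    comris: float = 0.4  # per SD of COMRIS-CTD
    therapy_delay: float = 0.35  # shift when therapy started late or never
    delay_threshold_years: float = 6.0
    noise_shape: float = 2.0  # gamma shape of the slope noise
    noise_scale: float = 0.35  # gamma scale; noise = gamma - shape*scale (mean 0)


@dataclass(frozen=True)
class TreatmentPolicy:
    """Probabilities and shapes of past and follow-up treatment exposure."""

    p_past_treatment: float = 0.5
    severity_logit_scale: float = 1.0  # confounding by indication: sicker
    # patients are more likely to have been treated (logit shift per SD of
    # untreated baseline CW/age)
    p_high_past: float = 0.5  # class of a past epoch
    delay_scale_years: float = 3.0  # exponential mean of onset-to-therapy delay
    delay_cap_years: float = 15.0  # cap; also assigned to never-treated for coupling
    p_future: tuple[float, float, float, float] = (0.45, 0.2, 0.2, 0.15)
    # probabilities of none / low-only / high-only / both during follow-up
    p_short_epoch: float = 0.15  # chance of an extra < 6-month epoch


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 201
    seed: int = 1
    onset_age_mean: float = 37.1
    onset_age_sd: float = 11.4
    onset_age_min: float = 8.0
    first_visit_age_mean: float = 48.6
    first_visit_age_sd: float = 11.6
    first_visit_age_range: tuple[float, float] = (23.0, 70.0)
    baseline_cw_mean: float = 30.4
    baseline_cw_sd: float = 17.5
    comris_mean: float = 12.8
    comris_sd: float = 6.3
    comris_cw_corr: float = 0.35
    followup_span_mean: float = 4.49
    followup_span_sd: float = 2.90
    followup_span_range: tuple[float, float] = (1.0, 12.0)
    visits_per_year: float = 1.5
    measurement_noise_sd: float = 2.0  # CombiWISE units per visit
    exacerbation_rate: float = 0.05  # per-visit probability
    exacerbation_bump: float = 8.0  # transient CombiWISE increase
    p_female: float = 0.498
    p_white: float = 0.876
    p_smoker: float = 0.602
    family_history_probs: tuple[float, ...] = (0.672, 0.139, 0.050, 0.080, 0.059)
    # none / mild / moderate / strong / unknown
    coupling: SeverityCoupling = field(default_factory=SeverityCoupling)
    policy: TreatmentPolicy = field(default_factory=TreatmentPolicy)
    efficacy: EfficacyModel = field(default_factory=EfficacyModel)


@dataclass
class GroundTruth:
    """Latent quantities the pipeline is supposed to recover."""

    per_patient: pd.DataFrame  # true slope, untreated baseline, efficacies, delay
    latent_visits: pd.DataFrame  # latent and emitted CombiWISE per visit
    coupling: SeverityCoupling


def _calibrated_truncnorm_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Pre-truncation (mu, sigma) whose [lo, hi]-truncation has the target moments.

    Truncation shrinks the spread, so drawing from N(mean, sd) and clipping
    would systematically under-disperse the cohort; inverting the truncated
    moments keeps the emitted marginals on their published targets.
    """

    def residual(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = sps.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.fsolve(residual, [mean, math.log(sd)], full_output=False)
    return float(sol[0]), float(math.exp(sol[1]))


def _draw_calibrated(rng, mean, sd, lo, hi, size) -> np.ndarray:
    mu, sigma = _calibrated_truncnorm_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return sps.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def _truncated_normal(rng, mean, sd, lo=-math.inf, hi=math.inf, size=1) -> np.ndarray:
    out = np.empty(size, dtype=float)
    for i in range(size):
        for _ in range(1000):
            x = rng.normal(mean, sd)
            if lo <= x <= hi:
                out[i] = x
                break
        else:
            out[i] = min(max(mean, lo), hi)
    return out


_EDSS_CHOICES = np.array([0.0] + [x / 2.0 for x in range(2, 21)])
_LOG2_T_RANGE = (1.0, math.log2(179.5))  # T25FW in [2, 179.5] s
_LOG2_H_RANGE = (3.0, math.log2(299.5))  # 9HPT in [8, 299.5] s


def _decompose_combiwise(target: float, rng) -> tuple[float, int, float, float]:
    """Solve (EDSS, SNRS, T25FW, 9HPT) so the composite equals ``target``.

    EDSS is snapped to its legal grid near target/10, SNRS follows its own
    anti-correlated integer scale, and the two timed tests absorb the
    remainder exactly.  ``target`` must lie in [0.5, 99].
    """
    c = COMBIWISE_COEFFICIENTS
    lo = c["log2_t25fw"] * _LOG2_T_RANGE[0] + c["log2_ndh_9hpt"] * _LOG2_H_RANGE[0]
    hi = c["log2_t25fw"] * _LOG2_T_RANGE[1] + c["log2_ndh_9hpt"] * _LOG2_H_RANGE[1]
    for attempt in range(60):
        jitter = 0.8 if attempt < 30 else 0.0
        edss_raw = target / 10.0 + rng.normal(0.0, jitter)
        edss = float(_EDSS_CHOICES[np.argmin(np.abs(_EDSS_CHOICES - edss_raw))])
        snrs_raw = 100.0 - 0.95 * target + rng.normal(0.0, 4.0 * jitter + 0.01)
        snrs = int(min(max(round(snrs_raw), 0), 100))
        remainder = target - c["intercept"] - c["edss"] * edss - c["snrs"] * snrs
        if lo <= remainder <= hi:
            a_min = max(
                _LOG2_T_RANGE[0],
                (remainder - c["log2_ndh_9hpt"] * _LOG2_H_RANGE[1]) / c["log2_t25fw"],
            )
            a_max = min(
                _LOG2_T_RANGE[1],
                (remainder - c["log2_ndh_9hpt"] * _LOG2_H_RANGE[0]) / c["log2_t25fw"],
            )
            a = rng.uniform(a_min, a_max)
            b = (remainder - c["log2_t25fw"] * a) / c["log2_ndh_9hpt"]
            return edss, snrs, 2.0**a, 2.0**b
        # deterministic rescue: push SNRS toward the feasible band
        snrs_fix = (target - c["intercept"] - c["edss"] * edss - 0.5 * (lo + hi)) / c["snrs"]
        snrs = int(min(max(round(snrs_fix), 0), 100))
        remainder = target - c["intercept"] - c["edss"] * edss - c["snrs"] * snrs
        if lo <= remainder <= hi:
            a = 0.5 * (
                max(
                    _LOG2_T_RANGE[0],
                    (remainder - c["log2_ndh_9hpt"] * _LOG2_H_RANGE[1]) / c["log2_t25fw"],
                )
                + min(
                    _LOG2_T_RANGE[1],
                    (remainder - c["log2_ndh_9hpt"] * _LOG2_H_RANGE[0]) / c["log2_t25fw"],
                )
            )
            b = (remainder - c["log2_t25fw"] * a) / c["log2_ndh_9hpt"]
            return edss, snrs, 2.0**a, 2.0**b
    raise RuntimeError(f"no consistent component decomposition for CombiWISE={target}")


def _draw_past_epochs(
    rng, policy, onset_age, first_age, p_treat=None
) -> tuple[list[TreatmentEpoch], float]:
    """Treatment history before the first visit; returns (epochs, delay).

    Treated patients start a DMT ``delay`` years after onset and, apart from
    short switching gaps (and possibly one abandoned < 6-month trial first),
    stay on therapy up to the visit — exposure heterogeneity then comes
    from onset age, delay and drug class.
    """
    room = first_age - onset_age
    if p_treat is None:
        p_treat = policy.p_past_treatment
    if rng.random() >= p_treat or room < 1.0:
        return [], math.nan
    delay = float(
        min(max(rng.exponential(policy.delay_scale_years), 0.25), max(room - 0.5, 0.25))
    )
    epochs = []
    t = onset_age + delay
    if rng.random() < policy.p_short_epoch and first_age - t > 1.5:
        d = float(rng.uniform(0.1, 0.45))  # an abandoned first DMT
        epochs.append(
            TreatmentEpoch(t, t + d, "high" if rng.random() < policy.p_high_past else "low")
        )
        t += d + float(rng.uniform(0.2, 0.6))
    n_main = int(rng.integers(1, 3))
    for k in range(n_main):
        if first_age - t < 0.3:
            break
        if k == n_main - 1:
            end = first_age - float(rng.uniform(0.0, 0.3))
        else:
            end = min(t + float(rng.uniform(1.0, 6.0)), first_age - 0.5)
        if end - t < 0.2:
            break
        cls = "high" if rng.random() < policy.p_high_past else "low"
        epochs.append(TreatmentEpoch(t, end, cls))
        t = end + float(rng.uniform(0.3, 1.0))
    return epochs, delay


def _draw_future_epochs(rng, policy, first_age, last_age) -> list[TreatmentEpoch]:
    """Treatment epochs during longitudinal follow-up."""
    kind = rng.choice(4, p=policy.p_future)
    span = last_age - first_age
    if kind == 0 or span < 0.5:
        return []
    classes = {1: ["low"], 2: ["high"], 3: ["low", "high"]}[int(kind)]
    rng.shuffle(classes)
    epochs = []
    t = first_age + float(rng.uniform(0.0, span / 4.0))
    for cls in classes:
        duration = float(rng.uniform(max(span / 4.0, 0.5), span))
        end = min(t + duration, last_age)
        if end - t < 0.2:
            break
        epochs.append(TreatmentEpoch(t, end, cls))
        t = end + float(rng.uniform(0.3, 1.0))
        if t >= last_age - 0.2:
            break
    return epochs


def _latent_trajectory(ages, baseline_measured, true_slope, epochs, efficacy):
    """Latent observed CombiWISE at each visit age, under treatment attenuation."""
    first = ages[0]
    boundaries = sorted(
        {first, ages[-1]}
        | {e.start_age for e in epochs if first < e.start_age < ages[-1]}
        | {e.end_age for e in epochs if first < e.end_age < ages[-1]}
    )
    # cumulative latent value at each boundary
    values = [baseline_measured]
    for a, b in zip(boundaries, boundaries[1:]):
        mid = 0.5 * (a + b)
        eff = 0.0
        for e in epochs:
            if e.start_age - 1e-12 <= mid <= e.end_age + 1e-12:
                eff = epoch_efficacy(TreatmentEpoch(max(e.start_age, first), min(e.end_age, ages[-1]), e.efficacy_class), efficacy)
                break
        seg_slope = true_slope * (1.0 - eff) if true_slope > 0 else true_slope / (1.0 - eff)
        values.append(values[-1] + seg_slope * (b - a))
    return np.interp(ages, boundaries, values)


def generate(config: GeneratorConfig | None = None) -> tuple[list[PatientRecord], GroundTruth]:
    """Draw a synthetic cohort; returns the patients and their ground truth."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    cp = cfg.coupling
    pol = cfg.policy

    n = cfg.n_patients
    first_age = _draw_calibrated(
        rng, cfg.first_visit_age_mean, cfg.first_visit_age_sd, *cfg.first_visit_age_range, size=n
    )
    onset = np.array(
        [
            _truncated_normal(
                rng, cfg.onset_age_mean, cfg.onset_age_sd, cfg.onset_age_min, a - 0.1
            )[0]
            for a in first_age
        ]
    )
    cw0_true = _draw_calibrated(rng, cfg.baseline_cw_mean, cfg.baseline_cw_sd, 1.0, 99.0, size=n)
    z_cw = (cw0_true - cw0_true.mean()) / cw0_true.std()
    mu_c, sig_c = _calibrated_truncnorm_params(cfg.comris_mean, cfg.comris_sd, 0.0, math.inf)
    rho = cfg.comris_cw_corr
    z_comris = rho * z_cw + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    comris = mu_c + sig_c * z_comris
    for i in range(n):  # resample the independent part until nonnegative
        while comris[i] < 0:
            z_comris[i] = rho * z_cw[i] + math.sqrt(1 - rho**2) * rng.standard_normal()
            comris[i] = mu_c + sig_c * z_comris[i]

    span = _truncated_normal(
        rng, cfg.followup_span_mean, cfg.followup_span_sd, *cfg.followup_span_range, size=n
    )

    patients: list[PatientRecord] = []
    truth_rows = []
    latent_rows = []
    cw_per_age = cw0_true / first_age
    z1 = (cw_per_age - cw_per_age.mean()) / cw_per_age.std()
    # confounding by indication: treatment probability rises with severity
    from scipy.special import expit, logit

    base = min(max(pol.p_past_treatment, 1e-6), 1 - 1e-6)
    p_treat = expit(logit(base) + pol.severity_logit_scale * z1)
    # pre-draw treatment histories so delay can enter the slope coupling
    past_epochs_all, delays = [], np.empty(n)
    for i in range(n):
        eps, delay = _draw_past_epochs(rng, pol, onset[i], first_age[i], p_treat[i])
        past_epochs_all.append(eps)
        delays[i] = pol.delay_cap_years if math.isnan(delay) else min(delay, pol.delay_cap_years)

    z2 = (comris - comris.mean()) / comris.std()
    late_start = (delays > cp.delay_threshold_years).astype(float)
    noise = rng.gamma(cp.noise_shape, cp.noise_scale, size=n) - cp.noise_shape * cp.noise_scale
    sat = np.tanh(z1 / cp.cw_saturation_sd) * cp.cw_saturation_sd
    true_slope = (
        cp.slope_mean
        + cp.cw_per_age * sat
        + cp.comris * z2
        + cp.therapy_delay * (late_start - late_start.mean())
        + noise
    )

    for i in range(n):
        pid = f"SYN{i:04d}"
        last_age = first_age[i] + span[i]
        future = _draw_future_epochs(rng, pol, first_age[i], last_age)
        epochs = past_epochs_all[i] + future
        # past treatment attenuates the measured baseline multiplicatively
        eff_past = cumulative_efficacy(past_epochs_all[i], 0.0, first_age[i], cfg.efficacy).value
        cw0_measured = cw0_true[i] * (1.0 - eff_past)

        n_visits = int(max(3, round(span[i] * cfg.visits_per_year)))
        ages = first_age[i] + np.linspace(0.0, span[i], n_visits)
        if n_visits > 2:
            jitter = rng.uniform(-0.08, 0.08, size=n_visits - 2)
            ages[1:-1] = np.sort(ages[1:-1] + jitter)
        latent = _latent_trajectory(ages, cw0_measured, true_slope[i], future, cfg.efficacy)
        eff_followup = cumulative_efficacy(future, ages[0], ages[-1], cfg.efficacy).value

        visits = []
        prev_age = 0.0
        for j, age in enumerate(ages):
            if age - prev_age < 0.02:
                age = prev_age + 0.02
            prev_age = age
            noise_j = rng.normal(0.0, cfg.measurement_noise_sd)
            exac = int(rng.random() < cfg.exacerbation_rate) if j > 0 else 0
            target = latent[j] + noise_j + (cfg.exacerbation_bump if exac else 0.0)
            target = float(min(max(target, 0.5), 99.0))
            edss, snrs, t25fw, hpt = _decompose_combiwise(target, rng)
            visits.append(
                Visit(
                    visit_age=float(age),
                    edss=edss,
                    snrs=snrs,
                    t25fw_seconds=t25fw,
                    t25fw_fail=0,
                    ndh_9hpt_seconds=hpt,
                    ndh_9hpt_fail=0,
                    exacerbation=exac,
                    comris_ctd=float(comris[i]),
                )
            )
            latent_rows.append(
                {
                    "patient_id": pid,
                    "visit_age": float(age),
                    "latent_cw": float(latent[j]),
                    "emitted_cw": target,
                    "exacerbation": exac,
                }
            )
        fh = rng.choice(5, p=cfg.family_history_probs)
        p = PatientRecord(
            patient_id=pid,
            sex="female" if rng.random() < cfg.p_female else "male",
            race="white" if rng.random() < cfg.p_white else "other",
            smoking="yes" if rng.random() < cfg.p_smoker else "no_or_unknown",
            family_history=None if fh == 4 else int(fh),
            onset_age=float(onset[i]),
            visits=visits,
            treatments=sorted(epochs, key=lambda e: e.start_age),
        )
        p.validate()
        patients.append(p)
        truth_rows.append(
            {
                "patient_id": pid,
                "true_slope": float(true_slope[i]),
                "baseline_cw_untreated": float(cw0_true[i]),
                "baseline_cw_measured_latent": float(cw0_measured),
                "eff_past": float(eff_past),
                "eff_followup": float(eff_followup),
                "therapy_delay": float(delays[i]),
                "comris_ctd": float(comris[i]),
                "first_visit_age": float(first_age[i]),
                "followup_span": float(span[i]),
            }
        )
    truth = GroundTruth(
        per_patient=pd.DataFrame(truth_rows).set_index("patient_id"),
        latent_visits=pd.DataFrame(latent_rows),
        coupling=cp,
    )
    return patients, truth


def generate_files(config: GeneratorConfig, out_dir) -> dict[str, Path]:
    """Generate a cohort and write its CSV files; ground truth goes to a sibling.

    The ground-truth files never feed the pipeline's inputs; they exist for
    validation against the latent state only.
    """
    patients, truth = generate(config)
    paths = write_cohort(patients, out_dir)
    gt_dir = Path(out_dir).parent / (Path(out_dir).name + "_ground_truth")
    gt_dir.mkdir(parents=True, exist_ok=True)
    truth.per_patient.to_csv(gt_dir / "ground_truth.csv")
    truth.latent_visits.to_csv(gt_dir / "latent_visits.csv", index=False)
    paths["ground_truth"] = gt_dir / "ground_truth.csv"
    return paths


# ---------------------------------------------------------------------------
# pipeline-level simulation experiment

EXPERIMENT_GBM = {
    "shrinkage": 0.02,
    "tree_grid": (500, 1000, 2000),
    "cv_folds": 5,
}

INFLUENCE_THRESHOLD = 4.0  # percent relative influence kept in the reduced model


def scale_experiment(
    config: GeneratorConfig | None = None,
    n_replicates: int = 20,
    seed: int = 1,
    gbm_hyperparameters: dict | None = None,
) -> pd.DataFrame:
    """Held-out correlation of each severity scale with adjusted slopes.

    For each replicate: generate a cohort, compute MSSS, ARMSS, measured
    CombiWISE/age, therapy-adjusted CombiWISE/age and MS-DSS at the first
    visit, fit therapy-adjusted CombiWISE slopes, split 2:1 stratified, and
    record each scale's Pearson correlation with the adjusted slopes in the
    validation arm (the model is trained on the training arm only).
    Returns one row per replicate.
    """
    from scipy import stats

    from .model import evaluate as model_evaluate
    from .model import features_frame, reduce_and_retrain, train
    from .partition import PartitionSpec, stratified_split
    from .scales import build_reference, compute_rank_severity
    from .trajectories import adjust_trajectory, eligible, fit_slope

    cfg = config or GeneratorConfig()
    hp = dict(EXPERIMENT_GBM)
    if gbm_hyperparameters:
        hp.update(gbm_hyperparameters)
    rows = []
    for rep in range(n_replicates):
        rep_seed = seed + rep
        cohort, _ = generate(
            GeneratorConfig(**{**cfg.__dict__, "seed": cfg.seed + rep})
        )
        cohort = [p for p in cohort if eligible(p)]
        feats = features_frame(cohort, cfg.efficacy)
        targets = pd.Series(
            {
                p.patient_id: adjust_trajectory(
                    fit_slope(p, "CombiWISE"), p, cfg.efficacy
                ).adjusted_slope
                for p in cohort
            }
        )
        ref_dd = build_reference(cohort, "disease_duration")
        ref_age = build_reference(cohort, "age")
        msss, armss, meas_cw_age = {}, {}, {}
        for p in cohort:
            first = p.visits[0]
            msss[p.patient_id] = compute_rank_severity(
                first.edss, first.visit_age - p.onset_age, ref_dd
            )
            armss[p.patient_id] = compute_rank_severity(first.edss, first.visit_age, ref_age)
            meas_cw_age[p.patient_id] = feats.loc[p.patient_id, "measured_cw"] / feats.loc[
                p.patient_id, "age"
            ]
        strata = pd.DataFrame(
            {
                "race": [p.race for p in cohort],
                "sex": [p.sex for p in cohort],
                "adj_cw_per_age": feats["adj_cw_per_age"].to_numpy(),
                "first_visit_age": feats["age"].to_numpy(),
            },
            index=[p.patient_id for p in cohort],
        )
        train_ids, val_ids = stratified_split(strata, PartitionSpec(seed=rep_seed))
        full = train(feats.loc[train_ids], targets.loc[train_ids], hp, seed=rep_seed)
        model = reduce_and_retrain(
            full, feats.loc[train_ids], targets.loc[train_ids], INFLUENCE_THRESHOLD
        )
        y_val = targets.loc[val_ids].to_numpy(dtype=float)

        def corr(values: dict) -> float:
            v = np.array([values[i] for i in val_ids], dtype=float)
            return float(stats.pearsonr(v, y_val)[0])

        rows.append(
            {
                "replicate": rep,
                "seed": cfg.seed + rep,
                "msss": corr(msss),
                "armss": corr(armss),
                "measured_cw_per_age": corr(meas_cw_age),
                "adjusted_cw_per_age": corr(dict(feats["adj_cw_per_age"])),
                "msdss": model_evaluate(model, feats.loc[val_ids], y_val).r,
                "n_features_reduced": len(model.feature_names),
                "n_validation": len(val_ids),
            }
        )
    return pd.DataFrame(rows)
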