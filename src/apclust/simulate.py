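"""Synthetic surgical cohorts with known feature -> prolonged-stay effects.

The generator emulates the structure of a non-cardiac surgery registry with
non-invasive (cuff) arterial-pressure monitoring:

* seven surgery classes with class-specific intervention-duration
  distributions, mixed in roughly the proportions seen in large
  mixed-surgery registries;
* per-patient latent mean arterial pressure following a mean-reverting
  (Ornstein--Uhlenbeck) diffusion around an individual set-point, sampled at
  a jittered cuff cadence (default one reading per ~3 minutes); pulse
  pressure follows its own slower mean-reverting process, and
  DAP = MAP - PP/3, SAP = DAP + PP, so SAP > MAP > DAP at every clean sample;
* measurement artifacts (large spurious offsets) and missing gaps injected
  after the physiology, with their positions recorded for test assertions;
* length of stay drawn from negative-binomial count mixtures: a latent
  prolonged-stay indicator is first drawn from a logistic model whose linear
  predictor is the sum of *planted* standardized arterial-pressure features
  times user-chosen log-odds coefficients, then LOS is placed below or above
  a class-specific cut so that the downstream subgroup-median labelling
  recovers the latent indicator with high probability.

Everything random flows from a single integer seed; identical
(config, seed) pairs give identical cohorts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

SURGERY_CLASSES = (
    "digestive", "thoracic", "gynecological", "neurosurgical",
    "ENT", "urological", "vascular",
)

# class mix from a large mixed non-cardiac registry (normalised)
_DEFAULT_CLASS_PROBS = np.array([0.208, 0.137, 0.136, 0.215, 0.107, 0.153, 0.045])
_DEFAULT_CLASS_PROBS = tuple(_DEFAULT_CLASS_PROBS / _DEFAULT_CLASS_PROBS.sum())

# lognormal (median_minutes, sigma_log) per class
_DEFAULT_DURATION_DIST = (
    (120.0, 0.45), (150.0, 0.40), (90.0, 0.45), (140.0, 0.50),
    (70.0, 0.50), (100.0, 0.45), (110.0, 0.45),
)

# class-specific LOS cut (days): the value the subgroup median lands on
_DEFAULT_LOS_CUTS = (3, 4, 2, 4, 2, 3, 5)

#: planted effects used by the recovery experiments: three features in
#: distinct correlation blocks, each the strongest single summary of its
#: latent axis (diastolic floor, pulse-pressure spread, pulse-pressure peak)
#: so that per-block recovery is well-posed despite the SAP/DAP channels
#: being deterministic mixtures of the MAP and PP processes
RECOVERY_EFFECTS = {"MinDAP": -0.60, "DropPP": 0.55, "MaxPP": 0.45}


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic cohort generator (units in field comments)."""

    n_patients: int = 500
    seed: int = 0
    class_probs: tuple = _DEFAULT_CLASS_PROBS
    duration_dist: tuple = _DEFAULT_DURATION_DIST      # (median min, log-sd) per class
    sampling_interval_s: float = 180.0                 # mean cuff cadence
    sampling_jitter: float = 0.25                      # +- fraction of the cadence
    baseline_map_dist: tuple = (84.0, 8.0)             # mmHg mean, SD of MAP set-point
    ou_theta: float = 0.10                             # 1/min mean reversion of MAP
    ou_sigma: float = 4.0                              # mmHg/sqrt(min) MAP volatility
    pp_baseline_dist: tuple = (48.0, 11.0)             # mmHg mean, SD of PP set-point
    pp_theta: float = 0.05                             # 1/min mean reversion of PP
    pp_sigma: float = 3.0                              # mmHg/sqrt(min) PP volatility
    artifact_rate: float = 2.0                         # expected artifacts per trace
    artifact_magnitude: float = 55.0                   # mmHg offset scale
    gap_rate: float = 0.3                              # expected gaps per trace
    gap_length_dist: tuple = (4.0, 0.6)                # lognormal (median min, log-sd)
    effect_coefs: dict = field(default_factory=dict)   # feature name -> log-odds per SD
    base_plos_rate: float = 0.34                       # marginal prolonged-stay fraction
    death_rate: float = 0.01
    los_dispersion: float = 2.0                        # NB size r (smaller = more overdispersed)
    los_cuts: tuple = _DEFAULT_LOS_CUTS                # per-class cut (days)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        probs = np.asarray(self.class_probs, dtype=float)
        if len(probs) != 7 or (probs < 0).any():
            raise ValueError("class_probs must be 7 non-negative weights")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        for name in ("artifact_rate", "gap_rate", "ou_theta", "ou_sigma",
                     "pp_theta", "pp_sigma", "los_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("base_plos_rate", "death_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.sampling_interval_s:
            raise ValueError("sampling_interval_s must be positive")


@dataclass
class SimCohort:
    """A generated cohort: patient table, raw traces and the planted truth."""

    patients: pd.DataFrame      # id, age, sex, surgery_class, duration_min, los_days, died
    traces: pd.DataFrame        # patient_id, t_seconds, signal, value_mmHg (long format)
    truth: dict                 # planted coefficients, z-scores, latent labels, artifact log


_CUMTIME_RE = re.compile(r"^CumTime(MAP|SAP|DAP|PP)(>|<)(\d+(?:\.\d+)?)$")
_SUMMARY_RE = re.compile(r"^(Min|Max|Mean|Median|Std|Var|Drop)(MAP|SAP|DAP|PP)$")


def _planted_feature(name: str, channels: dict[str, np.ndarray]) -> float:
    """Evaluate a named arterial-pressure feature on clean samples."""
    m = _SUMMARY_RE.match(name)
    if m:
        stat, sig = m.groups()
        x = channels[sig]
        if stat == "Min":
            return float(np.min(x))
        if stat == "Max":
            return float(np.max(x))
        if stat == "Mean":
            return float(np.mean(x))
        if stat == "Median":
            return float(np.median(x))
        if stat == "Std":
            return float(np.std(x, ddof=1))
        if stat == "Var":
            return float(np.std(x, ddof=1) / np.mean(x))
        if stat == "Drop":
            return float(np.max(x) - np.min(x))
    m = _CUMTIME_RE.match(name)
    if m:
        sig, side, thr = m.group(1), m.group(2), float(m.group(3))
        x = channels[sig]
        frac = np.mean(x > thr) if side == ">" else np.mean(x < thr)
        return float(frac)
    raise KeyError(f"unknown planted feature name: {name!r}")


def _simulate_ou(rng: np.random.Generator, t_min: np.ndarray, mu: float,
                 theta: float, sigma: float, x0: float | None = None) -> np.ndarray:
    """Exact discretisation of a mean-reverting diffusion at given times."""
    n = len(t_min)
    x = np.empty(n)
    stat_sd = sigma / np.sqrt(2.0 * theta) if theta > 0 else sigma
    x[0] = mu + (x0 - mu if x0 is not None else rng.normal(0.0, stat_sd))
    for i in range(1, n):
        dt = t_min[i] - t_min[i - 1]
        if theta > 0:
            a = np.exp(-theta * dt)
            sd = sigma * np.sqrt((1.0 - a * a) / (2.0 * theta))
        else:
            a, sd = 1.0, sigma * np.sqrt(dt)
        x[i] = mu + (x[i - 1] - mu) * a + rng.normal(0.0, sd)
    return x


def inject_gaps(traces: pd.DataFrame, rate: float, length_dist: tuple,
                rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop whole measurement windows to mimic monitoring interruptions."""
    if rate < 0:
        raise ValueError("gap rate must be non-negative")
    med, sd = length_dist
    drops = []
    log = []
    for pid, grp in traces.groupby("patient_id", sort=True):
        n_gaps = rng.poisson(rate)
        if n_gaps == 0:
            continue
        t = grp["t_seconds"].to_numpy()
        t0, t1 = t.min(), t.max()
        for _ in range(n_gaps):
            length_s = float(np.exp(np.log(med) + sd * rng.normal()) * 60.0)
            start = float(rng.uniform(t0, max(t0, t1 - length_s)))
            mask = (grp["t_seconds"] >= start) & (grp["t_seconds"] < start + length_s)
            drops.extend(grp.index[mask].tolist())
            log.append({"patient_id": int(pid), "start_s": start, "length_s": length_s})
    out = traces.drop(index=set(drops)).reset_index(drop=True)
    return out, pd.DataFrame(log, columns=["patient_id", "start_s", "length_s"])


def inject_artifacts(traces: pd.DataFrame, rate: float, magnitude: float,
                     seed: int | np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Displace random measurements by +- magnitude-scale offsets.

    Returns the corrupted table and a log of the positions and offsets so
    tests can assert that downstream artifact removal recovers them.
    """
    if rate < 0:
        raise ValueError("artifact rate must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = traces.copy()
    log = []
    for pid, grp in out.groupby("patient_id", sort=True):
        n_art = rng.poisson(rate)
        if n_art == 0 or len(grp) == 0:
            continue
        rows = rng.choice(grp.index.to_numpy(), size=min(n_art, len(grp)), replace=False)
        for r in rows:
            offset = float(rng.choice([-1.0, 1.0]) * magnitude * rng.uniform(0.9, 1.5))
            out.loc[r, "value_mmHg"] = out.loc[r, "value_mmHg"] + offset
            log.append({
                "patient_id": int(pid),
                "t_seconds": int(out.loc[r, "t_seconds"]),
                "signal": out.loc[r, "signal"],
                "offset_mmHg": offset,
            })
    return out, pd.DataFrame(log, columns=["patient_id", "t_seconds", "signal", "offset_mmHg"])


def generate_cohort(config: SimConfig) -> SimCohort:
    """Generate a full synthetic cohort (patients, traces, truth ledger)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    cols_p = ["id", "age", "sex", "surgery_class", "duration_min", "los_days", "died"]
    cols_t = ["patient_id", "t_seconds", "signal", "value_mmHg"]
    if n == 0:
        return SimCohort(
            patients=pd.DataFrame(columns=cols_p),
            traces=pd.DataFrame(columns=cols_t),
            truth={"effect_coefs": dict(config.effect_coefs), "z": pd.DataFrame(),
                   "p_plos": np.array([]), "latent_plos": np.array([]),
                   "artifacts": pd.DataFrame(), "gaps": pd.DataFrame()},
        )

    cls_idx = rng.choice(7, size=n, p=np.asarray(config.class_probs, dtype=float))
    med_dur = np.array([config.duration_dist[c][0] for c in cls_idx])
    sd_dur = np.array([config.duration_dist[c][1] for c in cls_idx])
    duration = np.exp(np.log(med_dur) + sd_dur * rng.normal(size=n))
    duration = np.maximum(duration, 21.0)  # eligibility floor is 20 min

    age = np.clip(rng.normal(55.0, 17.5, size=n), 18.0, 95.0)
    sex = np.where(rng.random(n) < 0.553, "male", "female")

    map_mu = rng.normal(*config.baseline_map_dist, size=n)
    pp_mu = np.maximum(rng.normal(*config.pp_baseline_dist, size=n), 15.0)

    records = []
    channels_per_patient: list[dict[str, np.ndarray]] = []
    for i in range(n):
        # jittered cuff cadence, integer seconds
        t, times = 0.0, [0.0]
        while True:
            step = config.sampling_interval_s * (
                1.0 + config.sampling_jitter * rng.uniform(-1.0, 1.0))
            t += step
            if t > duration[i] * 60.0:
                break
            times.append(t)
        t_s = np.unique(np.round(times).astype(int))
        t_min = t_s / 60.0
        map_v = _simulate_ou(rng, t_min, map_mu[i], config.ou_theta, config.ou_sigma)
        pp_v = _simulate_ou(rng, t_min, pp_mu[i], config.pp_theta, config.pp_sigma)
        pp_v = np.maximum(pp_v, 10.0)
        dap_v = map_v - pp_v / 3.0
        sap_v = dap_v + pp_v
        channels_per_patient.append({"MAP": map_v, "SAP": sap_v, "DAP": dap_v, "PP": pp_v})
        for sig, v in (("SAP", sap_v), ("DAP", dap_v), ("MAP", map_v)):
            for ts, val in zip(t_s, v):
                records.append((i, int(ts), sig, float(val)))

    traces = pd.DataFrame(records, columns=cols_t)

    # planted features -> standardized z-scores -> logistic latent label
    coefs = dict(config.effect_coefs)
    if coefs:
        feat = {name: np.array([_planted_feature(name, ch) for ch in channels_per_patient])
                for name in coefs}
        z = pd.DataFrame({name: (v - v.mean()) / v.std(ddof=1) if v.std(ddof=1) > 0
                          else np.zeros(n) for name, v in feat.items()})
        eta = sum(coefs[name] * z[name].to_numpy() for name in coefs)
    else:
        z = pd.DataFrame(index=range(n))
        eta = np.zeros(n)

    if config.base_plos_rate in (0.0, 1.0):
        p = np.full(n, config.base_plos_rate)
    elif np.allclose(eta, 0.0):
        p = np.full(n, config.base_plos_rate)
    else:
        alpha = brentq(lambda a: expit(a + eta).mean() - config.base_plos_rate, -20, 20)
        p = expit(alpha + eta)
    latent = rng.random(n) < p

    # LOS: negative-binomial mixtures below/above the class cut
    r = max(config.los_dispersion, 1e-6)
    cuts = np.array([config.los_cuts[c] for c in cls_idx])
    los = np.empty(n, dtype=int)
    for i in range(n):
        cut = cuts[i]
        if latent[i]:
            mu1 = 3.0
            k = rng.negative_binomial(r, r / (r + mu1))
            los[i] = cut + 1 + k
        else:
            # mass concentrated at the cut so the subgroup median lands there
            mu0 = 1.2 * max(cut - 1, 1)
            k = rng.negative_binomial(r, r / (r + mu0))
            los[i] = 1 + min(k, cut - 1) if cut > 1 else 1
    died = rng.random(n) < config.death_rate

    patients = pd.DataFrame({
        "id": np.arange(n), "age": age, "sex": sex,
        "surgery_class": [SURGERY_CLASSES[c] for c in cls_idx],
        "duration_min": duration, "los_days": los, "died": died,
    })

    # corruption injected last so the truth above reflects clean physiology
    traces, gap_log = inject_gaps(traces, config.gap_rate, config.gap_length_dist, rng)
    traces, artifact_log = inject_artifacts(traces, config.artifact_rate,
                                            config.artifact_magnitude, rng)

    truth = {
        "effect_coefs": coefs,
        "z": z,
        "p_plos": p,
        "latent_plos": latent,
        "artifacts": artifact_log,
        "gaps": gap_log,
        "class_index": cls_idx,
    }
    return SimCohort(patients=patients, traces=traces, truth=truth)


def population_asmd(z: np.ndarray, p: np.ndarray) -> float:
    """Population aSMD of a standardized feature under known event probabilities.

    Integrates the planted logistic model over the empirical feature draws:
    group moments are probability-weighted means/SDs with weights p (event
    group) and 1-p (non-event group).
    """
    z = np.asarray(z, dtype=float)
    p = np.asarray(p, dtype=float)
    w1, w0 = p / p.sum(), (1 - p) / (1 - p).sum()
    m1, m0 = np.sum(w1 * z), np.sum(w0 * z)
    var1 = np.sum(w1 * (z - m1) ** 2)
    return float(abs(m1 - m0) / np.sqrt(var1))
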