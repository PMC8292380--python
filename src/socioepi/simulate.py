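"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a long-term field study of a social
carnivore: a maternal pedigree with kinship-correlated methylation, repeated
fecal glucocorticoid metabolite (fGCM) measurements with individual random
intercepts, global %CCGG methylation clustered by maternal ID, focal-animal
maternal-care observations, and co-occurrence sessions from which association
networks are built over the communal-den (CD) and den-independent (DI)
developmental windows.

Every dataset ships a ground-truth ledger (planted effect sizes, random-effect
draws, the true differentially-methylated-site set) so downstream estimators
can be benchmarked with recovery tests.  All randomness flows from a single
seed through named ``SeedSequence`` sub-streams, so output is reproducible and
stable under unrelated config edits.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior
from .methylation import MethylationCounts

__all__ = [
    "TrueEffects",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_pedigree",
    "simulate_behavior",
    "simulate_fgcm",
    "simulate_methylation",
    "simulate_dataset",
    "simulate_z_scores",
    "simulate_mediation_chain",
]

_DAYS_PER_MONTH = 30.44


@dataclass
class TrueEffects:
    """Planted generative effects (the ground truth the pipeline estimates).

    Slopes are per 1-SD of the (realized) exposure.  Defaults follow the
    directions and magnitudes the study design anticipates: social
    connectedness after den independence lowers log fGCMs, closer maternal
    proximity raises global %CCGG methylation, maternal care itself has no
    direct fGCM effect.
    """

    beta_care_on_logfgcm: float = 0.0
    beta_network_on_logfgcm: float = -0.12
    beta_care_on_ccgg: float = 1.36
    sigma_id: float = 0.35          # individual random-intercept SD, log fGCM
    sigma_mom: float = 1.0          # maternal random-intercept SD, %CCGG
    sigma_resid_fgcm: float = 0.50  # residual SD, log fGCM
    sigma_resid_ccgg: float = 2.0   # residual SD, %CCGG
    tau_kinship: float = 0.5        # logit-scale kinship variance, methylation
    frac_true_dms: float = 0.025    # proportion of CpGs with a planted effect
    beta_dms: float = 1.0           # logit-scale effect magnitude at true sites
    z_bias: float = 0.0             # planted test-statistic bias
    z_inflation: float = 1.0        # planted test-statistic inflation (> 0)

    def validate(self) -> None:
        for name in ("sigma_id", "sigma_mom", "sigma_resid_fgcm",
                     "sigma_resid_ccgg", "tau_kinship"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.frac_true_dms <= 1.0:
            raise ValueError("frac_true_dms must lie in [0, 1]")
        if self.z_inflation <= 0:
            raise ValueError("z_inflation must be > 0")


@dataclass
class SimulationConfig:
    n_mothers: int = 40
    offspring_per_mother: int = 2
    n_sessions: int = 500
    session_length_min: int = 30
    n_cpg: int = 2000
    mean_coverage: float = 30.0
    seed: int = 0
    effects: TrueEffects = field(default_factory=TrueEffects)
    n_fas_per_pair: int = 15          # mean FAS sessions per mother-cub pair
    ccgg_mean: float = 75.0           # population %CCGG level
    fgcm_log_mean: float = 4.0        # population mean log fGCM (ng/g)
    care_disturbance_effect: float = -0.4  # human disturbance lowers care (logit)
    care_rate_override: float | None = None  # force per-minute close-proximity rate
    covariate_effects_scale: float = 1.0     # scales fGCM covariate terms

    def validate(self) -> None:
        for name in ("n_mothers", "offspring_per_mother", "n_sessions",
                     "session_length_min", "n_cpg"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mean_coverage < 10:
            raise ValueError("mean_coverage must be >= 10")
        self.effects.validate()

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic sub-stream of the master seed."""
        h = int.from_bytes(stream.encode(), "little") % (2**32)
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed,
                                                            spawn_key=(h,)))


# --------------------------------------------------------------------------
# pedigree and kinship


def simulate_pedigree(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Maternal pedigree (founder mothers, their cubs) and the additive
    relationship matrix over all individuals.

    Fathers are unobserved and assumed unrelated, so the additive
    relationship is 1 on the diagonal, 0.5 between mother and offspring, and
    0.25 between maternal sibs.
    """
    config.validate()
    rng = config.rng("pedigree")
    rows = []
    base = dt.date(2005, 1, 1)
    for m in range(config.n_mothers):
        mid = f"M{m:03d}"
        rows.append({"individual_id": mid, "mother_id": None, "sex": "F",
                     "birth_date": base + dt.timedelta(days=int(rng.integers(0, 1500)))})
        for k in range(config.offspring_per_mother):
            cid = f"C{m:03d}_{k}"
            bdate = dt.date(2011, 1, 1) + dt.timedelta(days=int(rng.integers(0, 1200)))
            rows.append({"individual_id": cid, "mother_id": mid,
                         "sex": "F" if rng.random() < 0.5 else "M",
                         "birth_date": bdate})
    ped = pd.DataFrame(rows)
    kin = kinship_from_pedigree(ped)
    return ped, kin


def kinship_from_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Additive relationship matrix by the tabular method (sires unknown)."""
    ids = pedigree["individual_id"].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in pedigree")
    pos = {i: k for k, i in enumerate(ids)}
    mothers = pedigree["mother_id"].tolist()
    for i, m in zip(ids, mothers):
        if m is not None and not (isinstance(m, float) and np.isnan(m)):
            if m not in pos:
                raise ValueError(f"mother {m!r} of {i!r} not in pedigree")
            if pos[m] >= pos[i]:
                raise ValueError("pedigree must list mothers before their offspring")
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        m = mothers[i]
        has_mom = m is not None and not (isinstance(m, float) and np.isnan(m))
        if has_mom:
            mi = pos[m]
            A[i, :i] = 0.5 * A[mi, :i]
            A[:i, i] = A[i, :i]
        A[i, i] = 1.0  # sire unknown and unrelated: no inbreeding term
    return pd.DataFrame(A, index=ids, columns=ids)


# --------------------------------------------------------------------------
# behavior: covariates, FAS records, co-occurrence sessions


_DISTURBANCE_LEVELS = np.array(["low", "medium", "high"])


def simulate_behavior(
    pedigree: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate FAS care records, co-occurrence sessions, and covariates.

    Returns ``(fas_records, sessions, covariates)``.  Care minutes respect
    nursing <= close proximity and grooming <= close proximity (both occur
    within 1 m of the mother).  Sessions span every cub's CD and DI windows.
    """
    if pedigree.empty:
        raise ValueError("pedigree is empty")
    config.validate()
    rng = config.rng("behavior")
    cubs = pedigree[pedigree["mother_id"].notna()].reset_index(drop=True)
    mothers = pedigree[pedigree["mother_id"].isna()]

    # --- covariates ---------------------------------------------------
    rank_by_mother = {m: r for m, r in zip(
        mothers["individual_id"],
        np.linspace(1, -1, len(mothers)),  # standardized rank, high to low
    )}
    cov_rows = []
    for _, cub in cubs.iterrows():
        dist = _DISTURBANCE_LEVELS[rng.integers(0, 3)]
        cd_len_months = float(np.clip(rng.normal(6.98, 1.74), 2.0, 12.0))
        cov_rows.append({
            "individual_id": cub["individual_id"],
            "mother_id": cub["mother_id"],
            "sex": cub["sex"],
            "birth_date": cub["birth_date"],
            "maternal_rank": rank_by_mother[cub["mother_id"]],
            "litter_size": int(rng.integers(1, 3)),
            "parity": int(rng.integers(1, 6)),
            "clan_size": int(rng.integers(35, 61)),
            "human_disturbance": dist,
            "prey_abundance": "high" if rng.random() < 0.5 else "low",
            "cd_length_months": cd_len_months,
            "age_at_darting_months": float(rng.uniform(11, 27)),
        })
    covariates = pd.DataFrame(cov_rows)

    # --- latent care and sociability propensities ---------------------
    dist_eff = {"low": 0.0, "medium": 0.5 * config.care_disturbance_effect,
                "high": config.care_disturbance_effect}
    care_logit = (
        -0.6
        + 0.3 * covariates["maternal_rank"].to_numpy()
        + covariates["human_disturbance"].map(dist_eff).to_numpy()
        + rng.normal(0, 0.5, len(covariates))
    )
    if config.care_rate_override is not None:
        p_close = np.full(len(covariates), float(config.care_rate_override))
    else:
        p_close = _sigmoid(care_logit)
    greg = rng.normal(0, 0.7, len(covariates)) + 0.2 * covariates["maternal_rank"].to_numpy()
    covariates["care_propensity"] = care_logit
    covariates["gregariousness"] = greg

    # --- FAS records ---------------------------------------------------
    fas_rows = []
    for i, cub in covariates.iterrows():
        n_fas = 1 + rng.poisson(config.n_fas_per_pair - 1)
        for s in range(n_fas):
            age_m = float(rng.uniform(0.5, 14.0))
            date = _add_months(cub["birth_date"], age_m)
            minutes = int(rng.integers(3, config.session_length_min + 1))
            close = int(rng.binomial(minutes, p_close[i]))
            nursing = int(rng.binomial(close, 0.45)) if close else 0
            grooming = int(rng.binomial(close, 0.25)) if close else 0
            fas_rows.append({
                "session_id": f"FAS{i:03d}_{s:03d}",
                "mother_id": cub["mother_id"],
                "cub_id": cub["individual_id"],
                "date": date,
                "minutes_together": minutes,
                "minutes_close": close,
                "minutes_nursing": nursing,
                "minutes_grooming": grooming,
                "cub_age_months": age_m,
                "mother_lactating": bool(age_m < 13.0),
            })
    fas_records = pd.DataFrame(fas_rows)

    # --- co-occurrence sessions ----------------------------------------
    all_ids = pedigree["individual_id"].tolist()
    cub_ids = covariates["individual_id"].tolist()
    p_attend_cub = _sigmoid(-0.2 + greg)
    start = min(covariates["birth_date"])
    span_days = (max(covariates["birth_date"]) - start).days + int(30 * _DAYS_PER_MONTH)
    sess_rows = []
    for s in range(config.n_sessions):
        date = start + dt.timedelta(days=int(rng.integers(0, span_days)))
        present = [m for m in mothers["individual_id"] if rng.random() < 0.5]
        for i, cid in enumerate(cub_ids):
            age_m = (date - covariates.loc[i, "birth_date"]).days / _DAYS_PER_MONTH
            if 0 < age_m < 2.05 * covariates.loc[i, "cd_length_months"]:
                if rng.random() < p_attend_cub[i]:
                    present.append(cid)
        sess_rows.append({
            "session_id": f"S{s:04d}",
            "date": date,
            "ampm": "am" if rng.random() < 0.5 else "pm",
            "present_ids": ";".join(present),
        })
    sessions = pd.DataFrame(sess_rows)
    return fas_records, sessions, covariates


# --------------------------------------------------------------------------
# outcomes


_REPRO_STATES = np.array(["nulliparous", "pregnant", "lactating", "other"])


def simulate_fgcm(
    individuals: pd.DataFrame,
    effects: TrueEffects,
    config: SimulationConfig,
    care_z: np.ndarray | None = None,
    network_z: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Repeated fGCM samples (ng/g) per individual.

    log(fGCM) = intercept + covariate terms + planted exposure effects +
    individual random intercept (SD ``sigma_id``) + residual.  Repeats per
    animal range 1-18.  Returns the sample table and the per-individual true
    random intercepts (ground truth for BLUP recovery).
    """
    if individuals.empty:
        raise ValueError("no individuals to sample")
    rng = config.rng("fgcm")
    n = len(individuals)
    care_z = np.zeros(n) if care_z is None else np.asarray(care_z, float)
    network_z = np.zeros(n) if network_z is None else np.asarray(network_z, float)
    u_id = rng.normal(0.0, effects.sigma_id, n)
    sex_eff = np.where(individuals["sex"].to_numpy() == "M", -0.05, 0.0)
    rows = []
    for i in range(n):
        n_samp = int(1 + min(rng.poisson(4), 17))  # repeats in 1..18
        ind = individuals.iloc[i]
        for s in range(n_samp):
            age = float(rng.uniform(13, 60))
            state = _REPRO_STATES[rng.integers(0, 4)] if ind["sex"] == "F" else "other"
            ampm = "am" if rng.random() < 0.5 else "pm"
            mu = (
                config.fgcm_log_mean
                + config.covariate_effects_scale * (
                    sex_eff[i]
                    + 0.002 * (age - 30.0)
                    + (0.08 if state == "pregnant" else 0.0)
                    + (0.05 if ampm == "am" else 0.0)
                )
                + effects.beta_care_on_logfgcm * care_z[i]
                + effects.beta_network_on_logfgcm * network_z[i]
                + u_id[i]
            )
            log_val = mu + rng.normal(0.0, effects.sigma_resid_fgcm)
            rows.append({
                "individual_id": ind["individual_id"],
                "fgcm_ng_g": float(np.exp(log_val)),
                "age_months": age,
                "repro_state": state,
                "ampm": ampm,
            })
    samples = pd.DataFrame(rows)
    truth = pd.Series(u_id, index=individuals["individual_id"].to_numpy(), name="u_id")
    return samples, truth


def simulate_methylation(
    individuals: pd.DataFrame,
    kinship: pd.DataFrame,
    effects: TrueEffects,
    config: SimulationConfig,
    exposure: np.ndarray | None = None,
    care_z: np.ndarray | None = None,
) -> tuple[MethylationCounts, pd.DataFrame, dict]:
    """Per-CpG counts with kinship-correlated site effects, plus %CCGG.

    For each CpG j and individual i,
    logit(p_ij) = a_j + x_i * b_j + c_age * age_i + u_ij with
    u_.j ~ MVN(0, tau_kinship * K); methylated ~ Binomial(total, p);
    total ~ 1 + Poisson(mean_coverage - 1).  A fraction ``frac_true_dms`` of
    sites receive a nonzero b_j of magnitude ``beta_dms`` and random sign.

    %CCGG = linear model with maternal random intercept (SD ``sigma_mom``)
    and a planted care slope ``beta_care_on_ccgg``.

    Returns (counts, ccgg table, ground-truth dict).
    """
    n = len(individuals)
    ids = individuals["individual_id"].tolist()
    if kinship.shape != (n, n) or list(kinship.index) != ids:
        raise ValueError("kinship dimension/order must match individuals")
    rng = config.rng("methylation")
    m = config.n_cpg
    x = np.zeros(n) if exposure is None else np.asarray(exposure, float)
    care_z = np.zeros(n) if care_z is None else np.asarray(care_z, float)
    age = individuals["age_at_darting_months"].to_numpy(dtype=float)

    a = rng.normal(0.0, 1.0, m)                       # site intercepts
    n_true = int(round(effects.frac_true_dms * m))
    true_idx = rng.choice(m, size=n_true, replace=False)
    b = np.zeros(m)
    if n_true:
        b[true_idx] = effects.beta_dms * rng.choice([-1.0, 1.0], n_true)

    if effects.tau_kinship > 0:
        K = kinship.to_numpy()
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        u = np.sqrt(effects.tau_kinship) * (rng.standard_normal((m, n)) @ L.T)
    else:
        u = np.zeros((m, n))
    c_age = 0.005
    logit_p = a[:, None] + np.outer(b, x) + c_age * (age - age.mean())[None, :] + u
    p = _sigmoid(logit_p)
    total = 1 + rng.poisson(config.mean_coverage - 1.0, size=(m, n))
    meth = rng.binomial(total, p)

    positions = np.sort(rng.choice(10_000_000, size=m, replace=False))
    sites = pd.DataFrame({
        "chrom": [f"scaffold_{1 + i % 40}" for i in range(m)],
        "start": positions,
        "end": positions + 1,
    })
    counts = MethylationCounts(sites, ids, meth, total)

    mom_labels = individuals["mother_id"].to_numpy()
    mom_ids = pd.unique(mom_labels)
    mom_u = dict(zip(mom_ids, rng.normal(0.0, effects.sigma_mom, len(mom_ids))))
    ccgg = (
        config.ccgg_mean
        + effects.beta_care_on_ccgg * care_z
        + np.array([mom_u[mv] for mv in mom_labels])
        + rng.normal(0.0, effects.sigma_resid_ccgg, n)
    )
    ccgg_table = pd.DataFrame({
        "individual_id": ids,
        "mother_id": mom_labels,
        "pct_ccgg": np.clip(ccgg, 0.0, 100.0),
    })
    truth = {
        "true_dms_sites": counts.site_ids().iloc[np.sort(true_idx)].tolist(),
        "true_dms_index": np.sort(true_idx).tolist(),
        "beta_site": b.tolist(),
        "exposure": x.tolist(),
        "mom_intercepts": {k: float(v) for k, v in mom_u.items()},
    }
    return counts, ccgg_table, truth


def simulate_z_scores(n: int, effects: TrueEffects, rng: np.random.Generator,
                      frac_signal: float = 0.0, signal_mean: float = 3.0) -> np.ndarray:
    """Test statistics with planted bias/inflation (and optional signal),
    for exercising the empirical-null correction machinery directly."""
    n_sig = int(round(frac_signal * n))
    z = effects.z_bias + effects.z_inflation * rng.standard_normal(n)
    if n_sig:
        idx = rng.choice(n, n_sig, replace=False)
        z[idx] = signal_mean + rng.standard_normal(n_sig)
    return z


def simulate_mediation_chain(
    n_individuals: int,
    rng: np.random.Generator,
    a: float = 1.0,
    b: float = 0.5,
    direct: float = 0.0,
    reps: int = 3,
    noise_m: float = 0.5,
    noise_y: float = 0.4,
    sigma_id: float = 0.3,
) -> pd.DataFrame:
    """Small X -> M -> Y chain with repeated Y per individual, for testing
    the three-step mediation procedure under planted regimes."""
    x = rng.standard_normal(n_individuals)
    m_ = a * x + noise_m * rng.standard_normal(n_individuals)
    u = sigma_id * rng.standard_normal(n_individuals)
    rows = []
    for i in range(n_individuals):
        for r in range(reps):
            y = direct * x[i] + b * m_[i] + u[i] + noise_y * rng.standard_normal()
            rows.append({"individual_id": f"I{i:03d}", "mother_id": f"G{i // 2:03d}",
                         "exposure": x[i], "mediator": m_[i], "outcome": y,
                         "age_months": 24.0})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# full study bundle


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    pedigree: pd.DataFrame
    kinship: pd.DataFrame           # over all individuals
    covariates: pd.DataFrame        # per cub, with realized exposures added
    fas_records: pd.DataFrame
    sessions: pd.DataFrame
    care: pd.DataFrame              # realized care proportions per cub
    network_metrics: pd.DataFrame   # realized CD/DI metrics per cub
    fgcm: pd.DataFrame
    ccgg: pd.DataFrame
    counts: MethylationCounts
    ground_truth: dict

    def cub_kinship(self) -> pd.DataFrame:
        ids = self.counts.individuals
        return self.kinship.loc[ids, ids]

    def write(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        ped = self.pedigree.copy()
        ped["mother_id"] = ped["mother_id"].fillna("")
        ped[["individual_id", "mother_id", "sex"]].to_csv(
            d / "pedigree.tsv", sep="\t", index=False)
        self.kinship.to_csv(d / "kinship.tsv", sep="\t")
        self.covariates.to_csv(d / "covariates.csv", index=False)
        self.fas_records.to_csv(d / "fas_records.csv", index=False)
        self.sessions.to_csv(d / "sessions.csv", index=False)
        self.care.to_csv(d / "care.csv", index=False)
        self.network_metrics.to_csv(d / "network_metrics.csv", index=False)
        self.fgcm.to_csv(d / "fgcm.csv", index=False)
        self.ccgg.to_csv(d / "ccgg.csv", index=False)
        self.counts.to_bismark_dir(d / "bismark")
        self.counts.to_wide(d / "methylation_wide.tsv")
        with open(d / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)


def simulate_dataset(config: SimulationConfig) -> SimulatedStudy:
    """End-to-end study generation.

    The planted fGCM/%CCGG effects act on the *realized*, standardized
    exposures (care proportions and DI network degree computed from the
    generated observation records with the same machinery the analysis
    uses), so recovery tests have an exact generative target.
    """
    config.validate()
    pedigree, kinship = simulate_pedigree(config)
    fas, sessions, covariates = simulate_behavior(pedigree, config)

    care = behavior.maternal_care_proportions(fas)
    windows = {}
    for _, row in covariates.iterrows():
        cd_end = _add_months(row["birth_date"], row["cd_length_months"])
        windows[row["individual_id"]] = behavior.define_windows(
            row["individual_id"], row["birth_date"], cd_end)
    netm = behavior.window_metrics_table(sessions, windows)

    merged = covariates.merge(care.rename(columns={"cub_id": "individual_id"}),
                              on="individual_id", how="left")
    di = netm[netm["window"] == "DI"].set_index("individual_id")
    merged["di_degree"] = merged["individual_id"].map(di["degree"]).astype(float)
    care_z = _safe_z(merged["prop_close_proximity"].to_numpy(dtype=float))
    network_z = _safe_z(merged["di_degree"].to_numpy(dtype=float))
    merged["care_z"] = care_z
    merged["network_z"] = network_z

    fgcm, u_id = simulate_fgcm(merged, config.effects, config,
                               care_z=care_z, network_z=network_z)
    # true per-individual stress propensity (what the fGCM BLUPs estimate)
    stress = (config.effects.beta_care_on_logfgcm * care_z
              + config.effects.beta_network_on_logfgcm * network_z
              + u_id.to_numpy())
    stress_z = _safe_z(stress) if np.std(stress) > 0 else stress
    cub_ids = merged["individual_id"].tolist()
    cub_kin = kinship.loc[cub_ids, cub_ids]
    counts, ccgg, meth_truth = simulate_methylation(
        merged, cub_kin, config.effects, config, exposure=stress_z, care_z=care_z)

    ground_truth = {
        "effects": asdict(config.effects),
        "u_id": {k: float(v) for k, v in u_id.items()},
        "care_z": dict(zip(cub_ids, map(float, care_z))),
        "network_z": dict(zip(cub_ids, map(float, network_z))),
        "stress_z": dict(zip(cub_ids, map(float, stress_z))),
        **meth_truth,
    }
    return SimulatedStudy(
        config=config, pedigree=pedigree, kinship=kinship, covariates=merged,
        fas_records=fas, sessions=sessions, care=care, network_metrics=netm,
        fgcm=fgcm, ccgg=ccgg, counts=counts, ground_truth=ground_truth,
    )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _safe_z(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x = np.where(np.isnan(x), np.nanmean(x), x)
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _add_months(date: dt.date, months: float) -> dt.date:
    return date + dt.timedelta(days=int(round(months * _DAYS_PER_MONTH)))
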