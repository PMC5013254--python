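"""Synthetic longitudinal-trial generator with known ground truth.

Emulates the record structure a retrospective drug-response analysis
consumes — monthly medication logs with categorical compliance codes
and missingness, annual medication-class records, dated phenotype
measurements, baseline covariates, and an additive genotype dosage
matrix — together with a :class:`TruthRecord` holding every latent
quantity the pipeline estimates.

The generator's central feature is a configurable confounding pathway
mirroring the statin/LDL scenario: a causal SNP raises the
pre-treatment phenotype (``gamma_g``), a higher pre-treatment phenotype
makes baseline prescription of a confounder co-medication more likely
(logistic slope ``link_lambda``, calibrated to a marginal on-at-baseline
probability), and the co-medication's trajectory score shifts the
response (``effect`` per score level).  With a zero direct SNP effect
(``beta_direct = 0``) an unadjusted SNP regression is biased while a
score-adjusted one is not, which is exactly the contrast the
paired-model bootstrap comparison is designed to expose.

All randomness flows through one seeded generator with per-component
substreams, so edits to one component's parameters leave the others'
draws unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genetics import GenotypeMatrix
from .trial_data import TrialDataset

_SUBSTREAMS = ("genotypes", "phenotype", "primary", "conmeds", "compliance", "baselines")


@dataclass(frozen=True)
class ConmedParams:
    """Latent trajectory process for one concomitant medication."""

    prob_on_at_baseline: float = 0.3
    start_hazard_per_day: float = 2e-4
    stop_hazard_per_day: float = 3e-4
    link_lambda: float = 0.0  # logistic slope of baseline use on standardized pre-phenotype
    annual_only: bool = False  # recorded only in annual logs (binary scoring)
    effect: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)  # per score 1..4


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 2000
    visit_interval_days: int = 30
    trial_length_days: int = 1460
    primary_medication: str = "primary_med"
    phenotype: str = "hba1c_pct"
    # primary-medication start-time distribution
    prob_primary_never: float = 0.30
    prob_primary_at_baseline: float = 0.25
    prob_primary_insufficient: float = 0.02
    prob_primary_stop_restart: float = 0.05
    # window geometry used by the truth scorer
    window_min_days: int = 90
    window_max_days: int = 270
    pre_lookback_days: int = 30
    persistence_grace_days: int = 30
    # compliance process: probs of codes 1,2,3,4 given a record, then missingness
    compliance_probs: tuple[float, float, float, float] = (0.92, 0.04, 0.01, 0.03)
    prob_compliance_missing: float = 0.10
    # phenotype model
    baseline_mean: float = 8.3
    baseline_sd: float = 1.0
    gamma_g: float = 0.5  # causal-SNP effect on pre-treatment phenotype
    primary_effect: float = -1.2
    beta_direct: float = 0.0  # direct SNP effect on response
    noise_sd: float = 1.0
    # genotypes
    n_snps: int = 50
    causal_snp: str = "snp_causal"
    causal_freq: float = 0.30
    # records bookkeeping
    prob_missing_phenotype: float = 0.10
    prob_inconsistent: float = 0.001
    prob_genetic_consent: float = 0.83
    prob_insulin: float = 0.30
    conmeds: dict[str, ConmedParams] = field(
        default_factory=lambda: {
            "statin": ConmedParams(
                prob_on_at_baseline=0.60,
                start_hazard_per_day=2e-4,
                stop_hazard_per_day=2e-4,
                link_lambda=3.0,
                effect=(-0.3, -0.45, -1.2, -1.5),
            ),
            "ace_inhibitor": ConmedParams(prob_on_at_baseline=0.45),
            "sulfonylurea": ConmedParams(prob_on_at_baseline=0.30, stop_hazard_per_day=5e-4),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.prob_primary_never, self.prob_primary_at_baseline,
            self.prob_primary_insufficient, self.prob_primary_stop_restart,
            self.prob_compliance_missing, self.prob_missing_phenotype,
            self.prob_inconsistent, self.prob_genetic_consent, self.prob_insulin,
        ]
        for name, p in zip(
            ["prob_primary_never", "prob_primary_at_baseline", "prob_primary_insufficient",
             "prob_primary_stop_restart", "prob_compliance_missing", "prob_missing_phenotype",
             "prob_inconsistent", "prob_genetic_consent", "prob_insulin"], probs
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"invalid config: {name} must lie in [0, 1]")
        if abs(sum(self.compliance_probs) - 1) > 1e-9:
            raise ValueError("invalid config: compliance_probs must sum to 1")
        if self.noise_sd <= 0 or self.baseline_sd <= 0:
            raise ValueError("invalid config: noise_sd and baseline_sd must be positive")
        for med, cp in self.conmeds.items():
            if not 0 <= cp.prob_on_at_baseline <= 1:
                raise ValueError(f"invalid config: conmed {med} prob_on_at_baseline")
            if cp.start_hazard_per_day < 0 or cp.stop_hazard_per_day < 0:
                raise ValueError(f"invalid config: conmed {med} hazards must be >= 0")
        if not 0 < self.causal_freq < 1:
            raise ValueError("invalid config: causal_freq must lie in (0, 1)")


def noiseless_compliance_config(**overrides) -> SimulationConfig:
    """Study conditions with fully observed, fully compliant records.

    Used to check that the production scorer reproduces the generator's
    latent trajectory scores exactly (compliance is then deterministic,
    so scores are a pure function of start/stop timing).
    """
    base = dict(
        compliance_probs=(1.0, 0.0, 0.0, 0.0),
        prob_compliance_missing=0.0,
        prob_inconsistent=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def confounding_config(**overrides) -> SimulationConfig:
    """Study conditions for the confounding demonstration.

    Every subject starts the primary medication in-trial with clean
    compliance and phenotypes, so the analysis cohort is essentially the
    full sample; the genotype→pre-phenotype→prescription pathway is
    active and the direct SNP effect is zero.
    """
    base = dict(
        prob_primary_never=0.0,
        prob_primary_at_baseline=0.0,
        prob_primary_insufficient=0.0,
        prob_primary_stop_restart=0.0,
        prob_missing_phenotype=0.0,
        prob_inconsistent=0.0,
        prob_genetic_consent=1.0,
        compliance_probs=(1.0, 0.0, 0.0, 0.0),
        prob_compliance_missing=0.0,
        beta_direct=0.0,
        gamma_g=0.8,
        noise_sd=0.8,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class TruthRecord:
    """Everything the generator knows that the pipeline estimates."""

    config: SimulationConfig
    subjects: pd.DataFrame  # per-subject latent quantities incl. truth scores
    snps: pd.DataFrame  # snp, freq, causal, beta_direct

    def truth_windows(self) -> dict[str, int]:
        """Window start day per subject that started the primary in-trial."""
        sub = self.subjects
        ok = sub["primary_category"].eq("starter")
        return dict(zip(sub.loc[ok, "subject_id"], sub.loc[ok, "window_start"].astype(int)))


def _calibrate_logistic_intercept(z: np.ndarray, lam: float, target: float) -> float:
    """Intercept alpha with mean sigmoid(alpha + lam*z) = target (bisection)."""
    if target <= 0:
        return -np.inf
    if target >= 1:
        return np.inf
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(mid + lam * z)))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _snap_up(day: float, interval: int) -> int:
    return int(np.ceil(day / interval) * interval)


def _draw_exponential_day(rng: np.random.Generator, hazard: float) -> float:
    if hazard <= 0:
        return np.inf
    return float(rng.exponential(1.0 / hazard))


def _truth_score(
    record_days: np.ndarray,
    codes: np.ndarray,
    start: int,
    cfg: SimulationConfig,
) -> int:
    """Independent trajectory scorer on the generator's own records.

    Deliberately re-derives the Table-style score from raw (day, code)
    pairs without touching the production scoring code path.
    """
    end = start + cfg.window_max_days
    if record_days.size == 0:
        return 0
    on_at_start = bool((record_days <= start).any())
    in_win = (record_days >= start) & (record_days <= end)
    persisted = False
    if in_win.any():
        reaches = record_days[in_win].max() >= end - cfg.persistence_grace_days
        win_codes = codes[in_win].astype(float)
        # NOCB then trailing LOCF, written independently
        filled = win_codes.copy()
        nxt = np.nan
        for i in range(len(filled) - 1, -1, -1):
            if np.isnan(filled[i]):
                filled[i] = nxt
            else:
                nxt = filled[i]
        prev = np.nan
        for i in range(len(filled)):
            if np.isnan(filled[i]):
                filled[i] = prev
            else:
                prev = filled[i]
        obs = filled[~np.isnan(filled)]
        if obs.size:
            frac_full = np.isin(obs, (1, 4)).mean()
            compliant = frac_full >= 0.8 and not (obs == 3).any()
        else:
            compliant = False
        persisted = bool(reaches and compliant)
    if on_at_start:
        return 4 if persisted else 1
    return 3 if persisted else 2


def simulate_trial(
    config: SimulationConfig | None = None,
) -> tuple[TrialDataset, GenotypeMatrix, TruthRecord]:
    """Generate one synthetic trial; deterministic given ``config.seed``."""
    cfg = config or SimulationConfig()
    root = np.random.default_rng(cfg.seed)
    streams = dict(zip(_SUBSTREAMS, root.spawn(len(_SUBSTREAMS))))
    n = cfg.n_subjects
    iv = cfg.visit_interval_days
    visits = np.arange(0, cfg.trial_length_days + 1, iv)
    subject_ids = [f"S{i:05d}" for i in range(1, n + 1)]

    # --- genotypes -----------------------------------------------------
    g_rng = streams["genotypes"]
    snp_ids = [cfg.causal_snp] + [f"snp{i:04d}" for i in range(1, cfg.n_snps)]
    freqs = np.concatenate([[cfg.causal_freq], g_rng.uniform(0.05, 0.5, cfg.n_snps - 1)])
    G = g_rng.binomial(2, freqs, size=(n, cfg.n_snps)).astype(float)
    spacing = 5_000_000 // max(cfg.n_snps, 1)
    snp_info = pd.DataFrame(
        {"snp": snp_ids, "chrom": "19", "pos": 42_912_079 + spacing * np.arange(cfg.n_snps)}
    )
    genotypes = GenotypeMatrix(
        pd.DataFrame(G, index=pd.Index(subject_ids, name="subject_id"), columns=snp_ids),
        snp_info,
    )
    g_causal = G[:, 0]

    # --- pre-treatment phenotype --------------------------------------
    ph_rng = streams["phenotype"]
    pre_pheno = (
        cfg.baseline_mean
        + cfg.gamma_g * (g_causal - 2 * cfg.causal_freq)
        + ph_rng.normal(0, cfg.baseline_sd, n)
    )
    z_pre = (pre_pheno - pre_pheno.mean()) / pre_pheno.std(ddof=0)

    # --- primary-medication trajectories ------------------------------
    pr_rng = streams["primary"]
    u = pr_rng.random(n)
    category = np.where(
        u < cfg.prob_primary_never,
        "never",
        np.where(u < cfg.prob_primary_never + cfg.prob_primary_at_baseline, "baseline", "starter"),
    )
    latest_start = cfg.trial_length_days - cfg.window_max_days - iv
    start_choices = visits[(visits >= iv) & (visits <= latest_start)]
    primary_start = np.full(n, -1, dtype=int)
    primary_start[category == "baseline"] = 0
    primary_start[category == "starter"] = pr_rng.choice(
        start_choices, size=int((category == "starter").sum())
    )
    insufficient = (category == "starter") & (pr_rng.random(n) < cfg.prob_primary_insufficient)
    stop_restart = (
        (category == "starter") & ~insufficient
        & (pr_rng.random(n) < cfg.prob_primary_stop_restart)
    )
    primary_end = np.where(category == "never", -1, cfg.trial_length_days)
    short_end = primary_start + pr_rng.integers(0, max(cfg.window_min_days - iv, 1), n)
    primary_end = np.where(insufficient, short_end, primary_end)
    gap_start = primary_start + iv * pr_rng.integers(1, cfg.window_max_days // iv - 1, n)
    gap_len = iv * pr_rng.integers(1, 3, n)

    # --- conmed trajectories -------------------------------------------
    cm_rng = streams["conmeds"]
    conmed_start: dict[str, np.ndarray] = {}
    conmed_stop: dict[str, np.ndarray] = {}
    for med, cp in cfg.conmeds.items():
        alpha = _calibrate_logistic_intercept(z_pre, cp.link_lambda, cp.prob_on_at_baseline)
        with np.errstate(over="ignore"):
            p_base = 1.0 / (1.0 + np.exp(-(alpha + cp.link_lambda * z_pre)))
        on_base = cm_rng.random(n) < p_base
        starts = np.full(n, np.inf)
        starts[on_base] = -iv  # on from before randomization
        if cp.start_hazard_per_day > 0:
            later = cm_rng.exponential(1.0 / cp.start_hazard_per_day, n)
            starts = np.where(
                ~on_base & (later <= cfg.trial_length_days),
                np.ceil(later / iv) * iv,
                starts,
            )
        durations = (
            cm_rng.exponential(1.0 / cp.stop_hazard_per_day, n)
            if cp.stop_hazard_per_day > 0
            else np.full(n, np.inf)
        )
        stops = np.where(np.isfinite(starts), np.maximum(starts, 0) + durations, -np.inf)
        stops = np.where(np.isfinite(stops), np.floor(stops / iv) * iv, stops)
        conmed_start[med] = starts
        conmed_stop[med] = stops

    # --- monthly logs and compliance -----------------------------------
    co_rng = streams["compliance"]
    window_start = np.where(primary_start >= 0, primary_start, 0)

    def _on_matrix(starts: np.ndarray, stops: np.ndarray) -> np.ndarray:
        return (visits[None, :] >= np.maximum(starts, 0)[:, None]) & (
            visits[None, :] <= stops[:, None]
        )

    def _codes_for(on: np.ndarray) -> np.ndarray:
        codes = co_rng.choice([1.0, 2.0, 3.0, 4.0], size=on.shape, p=cfg.compliance_probs)
        miss = co_rng.random(on.shape) < cfg.prob_compliance_missing
        codes[miss] = np.nan
        codes[~on] = np.nan
        return codes

    med_on: dict[str, np.ndarray] = {}
    med_codes: dict[str, np.ndarray] = {}

    prim_on = _on_matrix(primary_start.astype(float), primary_end.astype(float))
    prim_on[category == "never"] = False
    in_gap = (visits[None, :] >= gap_start[:, None]) & (
        visits[None, :] < (gap_start + gap_len)[:, None]
    )
    prim_on[stop_restart] &= ~in_gap[stop_restart]
    med_on[cfg.primary_medication] = prim_on
    med_codes[cfg.primary_medication] = _codes_for(prim_on)

    for med, cp in cfg.conmeds.items():
        if cp.annual_only:
            continue
        on = _on_matrix(conmed_start[med], conmed_stop[med])
        med_on[med] = on
        med_codes[med] = _codes_for(on)

    # inconsistent-records fault injection: annual says on, monthly logs absent
    inconsistent = streams["baselines"].random(n) < cfg.prob_inconsistent
    med_on[cfg.primary_medication][inconsistent] = False

    # insulin: continuous dose, on from baseline for a subset
    on_insulin = co_rng.random(n) < cfg.prob_insulin
    insulin_base = np.clip(co_rng.normal(30, 10, n), 1, None)
    insulin_dose = insulin_base[:, None] + co_rng.normal(0, 2, (n, len(visits)))
    insulin_dose = np.clip(insulin_dose, 0, None)

    # --- truth scores and response -------------------------------------
    score_cols: dict[str, np.ndarray] = {}
    for med, cp in cfg.conmeds.items():
        on = _on_matrix(conmed_start[med], conmed_stop[med])
        codes = med_codes.get(med)
        scores = np.zeros(n, dtype=int)
        for i in range(n):
            days = visits[on[i]]
            c = codes[i][on[i]] if codes is not None else np.ones(on[i].sum())
            scores[i] = _truth_score(days, c, int(window_start[i]), cfg) if days.size else 0
        score_cols[med] = scores

    resp_rng = streams["phenotype"].spawn(1)[0]
    response = cfg.primary_effect + cfg.beta_direct * g_causal + resp_rng.normal(0, cfg.noise_sd, n)
    for med, cp in cfg.conmeds.items():
        s = score_cols[med]
        eff = np.array([0.0, *cp.effect])
        response += eff[s]

    # --- phenotype observations ----------------------------------------
    obs_rng = streams["phenotype"].spawn(2)[1]
    pheno_rows = []
    pre_day = np.where(
        primary_start > 0,
        primary_start - obs_rng.integers(0, cfg.pre_lookback_days + 1, n),
        0,
    )
    post_day = window_start + obs_rng.integers(cfg.window_min_days, cfg.window_max_days + 1, n)
    miss_u = obs_rng.random(n)
    drop_pre = miss_u < cfg.prob_missing_phenotype / 2
    drop_post = (miss_u >= cfg.prob_missing_phenotype / 2) & (miss_u < cfg.prob_missing_phenotype)
    for i, sid in enumerate(subject_ids):
        if not drop_pre[i]:
            pheno_rows.append((sid, int(max(pre_day[i], 0)), cfg.phenotype, float(pre_pheno[i])))
        if category[i] == "starter" and not drop_post[i]:
            pheno_rows.append(
                (sid, int(post_day[i]), cfg.phenotype, float(pre_pheno[i] + response[i]))
            )
    phenotypes = pd.DataFrame(pheno_rows, columns=["subject_id", "day", "phenotype", "value"])

    # --- long-format medication logs ------------------------------------
    log_frames = []
    for med, on in med_on.items():
        si, vi = np.where(on)
        log_frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.array(subject_ids)[si],
                    "day": visits[vi],
                    "medication": med,
                    "compliance": med_codes[med][si, vi],
                    "insulin_units_per_day": np.nan,
                }
            )
        )
    ins_on = np.zeros((n, len(visits)), dtype=bool)
    ins_on[on_insulin] = True
    si, vi = np.where(ins_on)
    if len(si):
        log_frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.array(subject_ids)[si],
                    "day": visits[vi],
                    "medication": "insulin",
                    "compliance": np.nan,
                    "insulin_units_per_day": insulin_dose[si, vi],
                }
            )
        )
    med_logs = pd.concat(log_frames, ignore_index=True)
    med_logs["compliance"] = med_logs["compliance"].astype("Float64")

    # --- annual logs -----------------------------------------------------
    annual_days = np.arange(0, cfg.trial_length_days + 1, 365)
    ann_rows = []
    all_meds = {cfg.primary_medication: (primary_start.astype(float), primary_end.astype(float))}
    for med in cfg.conmeds:
        all_meds[med] = (conmed_start[med], conmed_stop[med])
    for med, (starts, stops) in all_meds.items():
        never = (
            (category == "never")
            if med == cfg.primary_medication
            else ~np.isfinite(starts)
        )
        for d in annual_days:
            if med == cfg.primary_medication:
                on_d = (~never) & (starts <= d) & (d <= stops)
                on_d |= inconsistent & (d == 0)  # fault: annual-only evidence
            else:
                on_d = np.isfinite(starts) & (starts <= d) & (d <= stops)
            for i in np.where(on_d | (d == 0))[0]:
                ann_rows.append((subject_ids[i], int(d), med, bool(on_d[i])))
    annual_logs = pd.DataFrame(
        ann_rows, columns=["subject_id", "day", "medication_class", "on_flag"]
    )

    # --- baselines -------------------------------------------------------
    b_rng = streams["baselines"]
    baselines = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": b_rng.normal(62.8, 6.5, n).round(1),
            "years_diabetic": np.clip(b_rng.normal(10.8, 7.0, n), 0, None).round(1),
            "bmi": np.clip(b_rng.normal(32.0, 5.0, n), 18, 45).round(1),
            "female": (b_rng.random(n) < 0.39).astype(int),
            "intensive_glycemia": (b_rng.random(n) < 0.5).astype(int),
            "genetic_consent": (b_rng.random(n) < cfg.prob_genetic_consent).astype(int),
        }
    )

    class_map = {cfg.primary_medication: cfg.primary_medication}
    class_map.update({m: m for m in cfg.conmeds})
    class_map["insulin"] = "insulin"

    ds = TrialDataset(
        med_logs=med_logs,
        annual_logs=annual_logs,
        phenotypes=phenotypes,
        baselines=baselines,
        medication_class_map=class_map,
    )

    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "g_causal": g_causal,
            "pre_phenotype": pre_pheno,
            "primary_category": category,
            "primary_start": primary_start,
            "window_start": window_start,
            "response": response,
            "inconsistent": inconsistent,
            "on_insulin": on_insulin,
        }
    )
    for med in cfg.conmeds:
        subjects[f"score_{med}"] = score_cols[med]
    snps = pd.DataFrame(
        {
            "snp": snp_ids,
            "freq": freqs,
            "causal": [s == cfg.causal_snp for s in snp_ids],
            "beta_direct": [cfg.beta_direct if s == cfg.causal_snp else 0.0 for s in snp_ids],
        }
    )
    truth = TruthRecord(config=cfg, subjects=subjects, snps=snps)
    return ds, genotypes, truth


def truth_scores(truth: TruthRecord) -> pd.DataFrame:
    """Per-subject expected conmed scores from the latent trajectories."""
    sub = truth.subjects
    cols = {c.removeprefix("score_"): sub[c] for c in sub.columns if c.startswith("score_")}
    out = pd.DataFrame(cols)
    out.index = pd.Index(sub["subject_id"], name="subject_id")
    return out


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["conmeds"] = {m: asdict(cp) for m, cp in cfg.conmeds.items()}
    return d
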