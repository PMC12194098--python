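"""Synthetic divergent-thinking rating study generator.

Emulates the data structure every downstream stage assumes: each
participant carries a latent originality trait and a fluency propensity
(bivariate normal, correlation ``rho_orig_fluency``); per task they
produce a negative-binomially distributed number of responses whose
qualities scatter around the trait; ordinal 1..K ratings then arise from
rater-specific graded-response processes, both per response (individual
scoring, default 3 raters) and per participant-task ideational pool
(snapshot scoring, default 5 raters).  The pool-level latent is the mean
of the top ``pool_top_m`` response qualities, reflecting that holistic
raters weigh a pool's best ideas.

Defaults reproduce a study-scale design: 201 participants x 3 tasks,
mean 7.88 responses per participant-task (about 4750 responses in
expectation) and the packaged rater presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .irt import RaterParams, category_probs
from .presets import INDIVIDUAL_RATERS, SNAPSHOT_RATERS
from .rating_data import RatingTable, write_long_csv


@dataclass
class GeneratorConfig:
    """Study-condition knobs of the synthetic generator.

    ``fluency_mean`` is the marginal mean number of responses per
    participant-task; ``fluency_dispersion`` the negative-binomial size
    (smaller = more overdispersed); ``fluency_kappa`` scales how strongly
    the fluency propensity factor shifts individual means;
    ``sigma_response`` the within-person response-quality SD on the trait
    scale; ``rho_orig_fluency`` the originality-fluency confound the
    latent models downstream must recover.
    """

    n_participants: int = 201
    n_tasks: int = 3
    K: int = 5
    individual_raters: tuple = INDIVIDUAL_RATERS
    snapshot_raters: tuple = SNAPSHOT_RATERS
    fluency_mean: float = 4752 / 603  # ~7.88 responses per participant-task
    fluency_dispersion: float = 8.0
    fluency_kappa: float = 0.5
    rho_orig_fluency: float = 0.3
    sigma_response: float = 1.0
    pool_top_m: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1 or self.n_tasks < 1 or self.K < 2:
            raise ValueError("need n_participants >= 1, n_tasks >= 1, K >= 2")
        if abs(self.rho_orig_fluency) > 1:
            raise ValueError("|rho_orig_fluency| must be <= 1")
        if not self.individual_raters or not self.snapshot_raters:
            raise ValueError("rater rosters must be non-empty")


@dataclass
class SyntheticStudy:
    """Generated tables plus the simulation ground truth."""

    individual_table: RatingTable
    snapshot_table: RatingTable
    true_theta: pd.Series          # per participant: latent originality
    true_fluency_factor: pd.Series  # per participant: fluency propensity
    true_quality: pd.Series        # per response unit: standardized quality
    true_pool_latent: pd.Series    # per pool unit: standardized pool latent
    config: GeneratorConfig

    def ground_truth_frame(self) -> pd.DataFrame:
        """Long frame of all latent quantities, for the simulate CLI."""
        parts = [
            pd.DataFrame({"kind": "theta", "id": self.true_theta.index,
                          "value": self.true_theta.to_numpy()}),
            pd.DataFrame({"kind": "fluency_factor", "id": self.true_fluency_factor.index,
                          "value": self.true_fluency_factor.to_numpy()}),
            pd.DataFrame({"kind": "quality", "id": self.true_quality.index,
                          "value": self.true_quality.to_numpy()}),
            pd.DataFrame({"kind": "pool_latent", "id": self.true_pool_latent.index,
                          "value": self.true_pool_latent.to_numpy()}),
        ]
        return pd.concat(parts, ignore_index=True)


def sample_grm_rating(params: RaterParams, theta, rng) -> np.ndarray:
    """Draw a 1..K category per trait value from the rater's GRM process."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    probs = category_probs(params, theta)
    cum = np.cumsum(probs, axis=-1)
    u = rng.random(theta.shape)
    cats = 1 + (u[..., None] > cum).sum(axis=-1)
    return np.minimum(cats, probs.shape[-1])


def _rate_units(raters, latent, unit_ids, meta, rng) -> pd.DataFrame:
    frames = []
    for params in raters:
        ratings = sample_grm_rating(params, latent, rng)
        frames.append(pd.DataFrame({
            "participant_id": meta["participant_id"], "task_id": meta["task_id"],
            "unit_id": unit_ids, "rater_id": params.rater_id, "rating": ratings}))
    return pd.concat(frames, ignore_index=True)


def generate_study(config: GeneratorConfig) -> SyntheticStudy:
    """Generate one fully reproducible synthetic study from its seed."""
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_person = np.random.default_rng(streams[0])
    rng_fluency = np.random.default_rng(streams[1])
    rng_quality = np.random.default_rng(streams[2])
    rng_ind = np.random.default_rng(streams[3])
    rng_snap = np.random.default_rng(streams[4])

    n, T = config.n_participants, config.n_tasks
    pids = [f"P{i+1:04d}" for i in range(n)]
    tasks = [f"T{t+1}" for t in range(T)]

    rho = config.rho_orig_fluency
    cov = np.array([[1.0, rho], [rho, 1.0]])
    theta, flu = rng_person.multivariate_normal([0.0, 0.0], cov, size=n).T

    # per participant-task response counts: NB with log-normal person effect,
    # kappa^2/2 correction keeps the marginal mean at fluency_mean
    kappa = config.fluency_kappa
    mu = config.fluency_mean * np.exp(kappa * flu - kappa ** 2 / 2.0)
    r = config.fluency_dispersion
    counts = np.empty((n, T), dtype=int)
    for t in range(T):
        draws = rng_fluency.negative_binomial(r, r / (r + mu), size=n)
        counts[:, t] = np.maximum(draws, 1)

    sigma = config.sigma_response
    scale = np.sqrt(1.0 + sigma ** 2)

    unit_ids, upart, utask, quality = [], [], [], []
    pool_ids, ppart, ptask, pool_raw = [], [], [], []
    for i, pid in enumerate(pids):
        for t, tid in enumerate(tasks):
            m = counts[i, t]
            q = (theta[i] + rng_quality.normal(0.0, sigma, size=m)) / scale
            for idx in range(m):
                unit_ids.append(f"{pid}_{tid}_{idx+1:03d}")
            upart += [pid] * m
            utask += [tid] * m
            quality.append(q)
            top = np.sort(q)[::-1][: config.pool_top_m]
            pool_ids.append(f"{pid}_{tid}")
            ppart.append(pid)
            ptask.append(tid)
            pool_raw.append(top.mean())
    quality = np.concatenate(quality)
    pool_raw = np.asarray(pool_raw)
    pool_latent = (pool_raw - pool_raw.mean()) / pool_raw.std()

    ind_meta = pd.DataFrame({"participant_id": upart, "task_id": utask})
    ind_records = _rate_units(config.individual_raters, quality, unit_ids, ind_meta, rng_ind)
    snap_meta = pd.DataFrame({"participant_id": ppart, "task_id": ptask})
    snap_records = _rate_units(config.snapshot_raters, pool_latent, pool_ids, snap_meta,
                               rng_snap)

    individual = RatingTable(ind_records, K=config.K, level="response",
                             raters=[p.rater_id for p in config.individual_raters])
    snapshot = RatingTable(snap_records, K=config.K, level="pool",
                           raters=[p.rater_id for p in config.snapshot_raters])
    return SyntheticStudy(
        individual_table=individual,
        snapshot_table=snapshot,
        true_theta=pd.Series(theta, index=pd.Index(pids, name="participant_id")),
        true_fluency_factor=pd.Series(flu, index=pd.Index(pids, name="participant_id")),
        true_quality=pd.Series(quality, index=pd.Index(unit_ids, name="unit_id")),
        true_pool_latent=pd.Series(pool_latent, index=pd.Index(pool_ids, name="unit_id")),
        config=config,
    )


def write_study(study: SyntheticStudy, individual_path, snapshot_path,
                truth_path=None) -> None:
    """Write the generated tables (and optionally the ground truth) as CSV."""
    write_long_csv(study.individual_table, individual_path)
    write_long_csv(study.snapshot_table, snapshot_path)
    if truth_path is not None:
        study.ground_truth_frame().to_csv(truth_path, index=False)
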