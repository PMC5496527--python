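"""Open-distance model: day-varying availability thinning a shared superpopulation.

Aerial surveys flown over several days never resample the same transect, but
if each day's transects representatively cover the study area, day-to-day
variation in encounter rate reflects variation in availability p_a — the
probability a bear present in the area can be seen at all (not hidden by
cover or behavior). Treating availability as temporary emigration, each
candidate group i (data augmentation as in the CDS model) carries:

    z_i ~ Bernoulli(ψ)          superpopulation membership
    a_i ~ Bernoulli(φ_{t(i)})   availability on its survey date t(i)
    y_i ~ Bernoulli(z_i · a_i · exp(−x_i²/(2σ²)))

with a hierarchical availability distribution φ_t ~ Beta(α, β) whose
between-day variation is what informs mean availability. Observed groups
keep their transect's date; augmented slots are assigned dates in proportion
to per-date effort, fixed before sampling, so each date's candidate pool
represents the study area.

The estimand is the superpopulation N_super — all bears exposed to sampling
at any point over the survey. Any residual incomplete detection at the apex
is absorbed into φ (it is not separable from availability here), and
permanent presence in the study area (p_p = 1) is assumed.

Scaling: Σ z_i s_i counts superpopulation bears across the T per-date
covered samples, so density divides by T × (mean per-date covered area) and
N_super multiplies by the study area.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import SurveyDataset, covered_area
from .cds import McmcConfig, PosteriorSamples, PriorFamily, PriorSpec

__all__ = ["OpenSurveyDataset", "run_open_mcmc", "mean_availability"]

_ALPHA_BETA_CAP = 50.0  # truncation of the Beta hyperparameters' Gamma(1, 0.1) priors


@dataclass(frozen=True)
class OpenSurveyDataset:
    """A survey whose transects span T ≥ 2 dates, each assumed representative."""

    survey: SurveyDataset

    def __post_init__(self) -> None:
        if self.n_dates < 2:
            raise ValueError(
                f"open model needs ≥ 2 survey dates, got {self.n_dates}: "
                "availability is inestimable from a single day"
            )

    @property
    def dates(self) -> list:
        return self.survey.dates()

    @property
    def n_dates(self) -> int:
        return len(self.survey.dates())

    def effort_by_date(self) -> np.ndarray:
        """Summed transect length (km) per date, in date order."""
        order = {d: k for k, d in enumerate(self.dates)}
        eff = np.zeros(self.n_dates)
        for t in self.survey.transects:
            eff[order[t.date]] += t.length_km
        if np.any(eff <= 0):
            raise ValueError("every survey date must have positive effort")
        return eff

    def detection_dates(self) -> np.ndarray:
        """Date index (into ``dates``) of each detection's transect."""
        order = {d: k for k, d in enumerate(self.dates)}
        t_date = {t.id: order[t.date] for t in self.survey.transects}
        return np.array([t_date[d.transect_id] for d in self.survey.detections], dtype=int)


def _allocate_latent_dates(effort: np.ndarray, n_lat: int) -> np.ndarray:
    """Deterministic largest-remainder allocation of latent slots ∝ per-date effort."""
    quota = effort / effort.sum() * n_lat
    counts = np.floor(quota).astype(int)
    short = n_lat - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts))
        counts[order[:short]] += 1
    return np.repeat(np.arange(effort.size), counts)


def _beta_hyper_logpost(alpha: float, beta: float, phi: np.ndarray) -> float:
    if alpha <= 0 or beta <= 0 or alpha + beta > _ALPHA_BETA_CAP:
        return -math.inf
    ll = float(stats.beta.logpdf(phi, alpha, beta).sum())
    # Gamma(shape 1, rate 0.1) priors on each hyperparameter
    ll += -0.1 * alpha - 0.1 * beta
    return ll


def _run_chain_open(
    x_obs: np.ndarray,
    e_obs: np.ndarray,
    d_obs: np.ndarray,
    w: float,
    T: int,
    m_t: np.ndarray,
    d_lat: np.ndarray,
    n_iter: int,
    burnin: int,
    thin: int,
    sigma_prior: PriorSpec,
    seed: int,
    fix_phi: float | None,
) -> tuple[dict[str, np.ndarray], float]:
    rng = np.random.default_rng(seed)
    n = x_obs.size
    n_lat = d_lat.size
    M = n + n_lat

    sigma = float(np.clip(sigma_prior.sample(rng), w / 20.0, 2.0 * w))
    psi = rng.uniform(0.2, 0.8)
    lam = float(e_obs.mean()) + 0.1 if n else 1.0
    phi = np.full(T, fix_phi) if fix_phi is not None else rng.uniform(0.4, 0.9, size=T)
    alpha, beta = 5.0, 3.0
    x_lat = rng.uniform(0.0, w, size=n_lat)
    z_lat = rng.random(n_lat) < 0.5
    a_lat = rng.random(n_lat) < 0.7
    e_lat = rng.poisson(lam, size=n_lat)

    obs_a_by_date = np.bincount(d_obs, minlength=T).astype(float)

    step_sigma = 0.2
    step_hyper = 0.3
    acc_sig_win = acc_sig_post = 0
    acc_hyp_win = 0
    n_post = 0

    n_keep = (n_iter - burnin) // thin
    out = {
        "sigma": np.empty(n_keep), "psi": np.empty(n_keep), "lambda": np.empty(n_keep),
        "N_cov": np.empty(n_keep), "phi": np.empty((n_keep, T)),
    }
    x_obs_sq = x_obs ** 2
    sum_e_obs = float(e_obs.sum())
    k = 0
    for it in range(n_iter):
        inv2s2 = 1.0 / (2.0 * sigma * sigma)

        # ridge-swap move: ψ and the φ_t are weakly identified (the data
        # constrain mainly their product), and single-site Gibbs mixes slowly
        # along that ridge. Propose ψ' = κψ, φ' = φ/κ with (z, a)
        # marginalized out; the conditional (z, a) refresh below completes
        # the partially collapsed joint update.
        if fix_phi is None:
            kappa = math.exp(0.2 * rng.normal())
            psi_p = kappa * psi
            phi_p = phi / kappa
            if 0.0 < psi_p < 1.0 and np.all(phi_p < 1.0):
                p_lat0 = np.exp(-(x_lat ** 2) * inv2s2)
                lp_c = float(np.log1p(-psi * phi[d_lat] * p_lat0).sum())
                lp_p = float(np.log1p(-psi_p * phi_p[d_lat] * p_lat0).sum())
                if n:
                    lp_c += n * math.log(psi) + float(np.log(phi[d_obs]).sum())
                    lp_p += n * math.log(psi_p) + float(np.log(phi_p[d_obs]).sum())
                lp_c += float(stats.beta.logpdf(phi, alpha, beta).sum())
                lp_p += float(stats.beta.logpdf(phi_p, alpha, beta).sum())
                if math.log(rng.random()) < lp_p - lp_c + (1 - T) * math.log(kappa):
                    psi, phi = psi_p, phi_p

        phi_d = phi[d_lat]
        p_lat = np.exp(-(x_lat ** 2) * inv2s2)

        # joint (z, a) update for latent slots: 4-cell categorical given y = 0
        w00 = (1.0 - psi) * (1.0 - phi_d)
        w01 = (1.0 - psi) * phi_d
        w10 = psi * (1.0 - phi_d)
        w11 = psi * phi_d * (1.0 - p_lat)
        tot = w00 + w01 + w10 + w11
        u = rng.random(n_lat) * tot
        c1 = w00
        c2 = w00 + w01
        c3 = c2 + w10
        z_lat = u >= c2
        a_lat = ((u >= c1) & (u < c2)) | (u >= c3)

        # latent distances: prior proposal; likelihood ratio only where z·a = 1
        za = z_lat & a_lat
        x_prop = rng.uniform(0.0, w, size=n_lat)
        p_prop = np.exp(-(x_prop ** 2) * inv2s2)
        ratio = np.where(za, (1.0 - p_prop) / np.maximum(1.0 - p_lat, 1e-300), 1.0)
        x_lat = np.where(rng.random(n_lat) < ratio, x_prop, x_lat)

        e_lat = rng.poisson(lam, size=n_lat)

        n_in = n + int(z_lat.sum())
        psi = rng.beta(1.0 + n_in, 1.0 + M - n_in)
        lam = rng.gamma(1.0 + sum_e_obs + e_lat.sum(), 1.0 / (1.0 + M))

        if fix_phi is None:
            a_by_date = obs_a_by_date + np.bincount(d_lat, weights=a_lat.astype(float), minlength=T)
            phi = rng.beta(alpha + a_by_date, beta + m_t - a_by_date)
            phi = np.clip(phi, 1e-9, 1.0 - 1e-9)

            # Beta hyperparameters: joint log-scale random walk
            la, lb = math.log(alpha), math.log(beta)
            la_p = la + step_hyper * rng.normal()
            lb_p = lb + step_hyper * rng.normal()
            a_p, b_p = math.exp(la_p), math.exp(lb_p)
            lp_cur = _beta_hyper_logpost(alpha, beta, phi) + la + lb
            lp_prop = _beta_hyper_logpost(a_p, b_p, phi) + la_p + lb_p
            if math.log(rng.random()) < lp_prop - lp_cur:
                alpha, beta = a_p, b_p
                acc_hyp_win += 1

        # σ: log-scale random-walk Metropolis
        sigma_prop = sigma * math.exp(step_sigma * rng.normal())
        lp_cur = sigma_prior.logpdf(sigma) + math.log(sigma)
        lp_prop = sigma_prior.logpdf(sigma_prop) + math.log(sigma_prop)
        if math.isfinite(lp_prop):
            inv2s2_p = 1.0 / (2.0 * sigma_prop * sigma_prop)
            x_in = x_lat[za]
            if n:
                lp_cur += float(-(x_obs_sq * inv2s2).sum())
                lp_prop += float(-(x_obs_sq * inv2s2_p).sum())
            if x_in.size:
                x_in_sq = x_in ** 2
                lp_cur += float(np.log1p(-np.exp(-x_in_sq * inv2s2)).sum())
                lp_prop += float(np.log1p(-np.exp(-x_in_sq * inv2s2_p)).sum())
            if math.log(rng.random()) < lp_prop - lp_cur:
                sigma = sigma_prop
                acc_sig_win += 1
                if it >= burnin:
                    acc_sig_post += 1
        if it >= burnin:
            n_post += 1

        if it < burnin and (it + 1) % 50 == 0:
            step_sigma *= math.exp(acc_sig_win / 50.0 - 0.375)
            step_sigma = float(np.clip(step_sigma, 1e-3, 2.0))
            acc_sig_win = 0
            if fix_phi is None:
                step_hyper *= math.exp(acc_hyp_win / 50.0 - 0.3)
                step_hyper = float(np.clip(step_hyper, 1e-3, 2.0))
                acc_hyp_win = 0

        if it >= burnin and (it - burnin) % thin == 0 and k < n_keep:
            out["sigma"][k] = sigma
            out["psi"][k] = psi
            out["lambda"][k] = lam
            out["N_cov"][k] = (1.0 + e_obs).sum() + (1.0 + e_lat[z_lat]).sum()
            out["phi"][k] = phi
            k += 1

    return out, acc_sig_post / max(n_post, 1)


def run_open_mcmc(
    dataset: OpenSurveyDataset,
    config: McmcConfig | dict | None = None,
    sigma_prior: PriorSpec | None = None,
    fix_phi: float | None = None,
) -> PosteriorSamples:
    """Fit the temporary-emigration open-distance model.

    Returns posterior draws of σ, ψ, λ, per-date availability φ_t, mean
    availability ``p_a_mean`` = (1/T)Σφ_t, and the superpopulation size
    ``N_super`` (also aliased as ``N_bears`` so the CDS summary helpers
    apply). ``fix_phi`` pins every φ_t (e.g. at 1.0 to recover the closed
    CDS model — used for validation).
    """
    if config is None:
        config = McmcConfig()
    elif isinstance(config, dict):
        config = McmcConfig.from_dict(config)
    survey = dataset.survey
    w = survey.strip_width_m
    if sigma_prior is None:
        sigma_prior = PriorSpec(PriorFamily.UNIFORM, (1.0, 2.0 * w))

    x_obs = survey.distances()
    e_obs = survey.group_sizes().astype(float) - 1.0
    d_obs = dataset.detection_dates()
    n = x_obs.size
    M = config.M if config.M is not None else max(5 * n, n + 200)
    if M <= n:
        raise ValueError(f"augmentation size M={M} must exceed n={n}")

    T = dataset.n_dates
    effort = dataset.effort_by_date()
    d_lat = _allocate_latent_dates(effort, M - n)
    m_t = (np.bincount(d_obs, minlength=T) + np.bincount(d_lat, minlength=T)).astype(float)

    # superpopulation scaling: T per-date samples of mean covered area each
    mean_covered = covered_area(survey) / T
    scale = survey.study_area_km2 / (T * mean_covered)

    draws: dict[str, list[np.ndarray]] = {
        "sigma": [], "psi": [], "lambda": [], "N_super": [], "phi": [], "p_a_mean": [],
    }
    acc_rates = []
    for chain in range(config.chains):
        chain_seed = (config.seed + chain) % (2 ** 31)
        out, acc = _run_chain_open(
            x_obs, e_obs, d_obs, w, T, m_t, d_lat,
            config.iters, config.burnin, config.thin, sigma_prior, chain_seed, fix_phi,
        )
        draws["sigma"].append(out["sigma"])
        draws["psi"].append(out["psi"])
        draws["lambda"].append(out["lambda"])
        draws["N_super"].append(out["N_cov"] * scale)
        draws["phi"].append(out["phi"])
        draws["p_a_mean"].append(out["phi"].mean(axis=1))
        acc_rates.append(acc)
        if acc < 0.01:
            warnings.warn(f"chain {chain}: σ acceptance rate {acc:.3f} < 1%", stacklevel=2)

    stacked = {key: np.stack(v) for key, v in draws.items()}
    stacked["N_bears"] = stacked["N_super"]
    return PosteriorSamples(
        draws=stacked, burnin=config.burnin, thin=config.thin, seed=config.seed, M=M,
        acceptance={"sigma": float(np.mean(acc_rates))},
    )


def mean_availability(posterior: PosteriorSamples) -> dict:
    """Posterior summary of mean availability p̄_a = (1/T)Σφ_t.

    Returns mean, median and the central 95% credible interval.
    """
    draws = posterior.flat("p_a_mean")
    lo, hi = (float(v) for v in np.percentile(draws, [2.5, 97.5]))
    return {
        "mean": float(draws.mean()),
        "median": float(np.median(draws)),
        "lo": lo,
        "hi": hi,
    }
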