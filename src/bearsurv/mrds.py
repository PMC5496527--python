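"""Double-observer mark–recapture distance sampling (MRDS) with point independence.

The estimator combines two likelihood factors that share no parameters:

* a two-piece normal distance shape g(x) fitted to the pooled perpendicular
  distances (``detfun.fit_twopiece_ml``), with g(apex) = 1, and
* an intercept-only double-observer mark–recapture model at the apex, fitted
  to the capture-history tallies conditional on detection by at least one
  observer.

Point independence means observer detections are assumed independent only at
the apex, where the absolute joint detection probability
p· = 1 − (1 − p₁)(1 − p₂) anchors the full detection function
p(x) = p· · g(x). Abundance is Horvitz–Thompson over individual bears, and
uncertainty comes from a nonparametric bootstrap over transects (the
independent design unit).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import (
    AbundanceEstimate,
    History,
    Method,
    SurveyDataset,
    covered_area,
)
from .detfun import TwoPieceNormalCurve, fit_twopiece_ml

__all__ = [
    "CaptureTally",
    "MrdsFit",
    "tally_histories",
    "fit_mr_intercept",
    "fit_mrds",
    "estimate_abundance_ht",
    "bootstrap_mrds",
]

G_FLOOR = 1e-6  # detections with fitted g(x) below this are excluded from HT


@dataclass(frozen=True)
class CaptureTally:
    """Counts of double-observer capture histories: pilot-only, observer-only, both."""

    n10: int
    n01: int
    n11: int

    def __post_init__(self) -> None:
        if min(self.n10, self.n01, self.n11) < 0:
            raise ValueError("tallies must be ≥ 0")

    @property
    def total(self) -> int:
        return self.n10 + self.n01 + self.n11


@dataclass(frozen=True)
class MrdsFit:
    """Joint MRDS fit: distance shape plus apex detection probabilities."""

    curve: TwoPieceNormalCurve
    p1: float
    p2: float
    p_dot: float
    loglik: float
    w: float

    def full_detection(self, x):
        """p(x) = p̂· · g(x): absolute detection probability at distance x."""
        return self.p_dot * self.curve.evaluate(x)


def tally_histories(dataset: SurveyDataset) -> CaptureTally:
    """Count capture histories; every detection must carry one."""
    missing = [k for k, d in enumerate(dataset.detections) if d.history is None]
    if missing:
        raise ValueError(f"detections without capture history at rows {missing}")
    hist = [d.history for d in dataset.detections]
    return CaptureTally(
        n10=sum(h is History.PILOT_ONLY for h in hist),
        n01=sum(h is History.OBSERVER_ONLY for h in hist),
        n11=sum(h is History.BOTH for h in hist),
    )


def fit_mr_intercept(tally: CaptureTally) -> tuple[float, float, float]:
    """Conditional multinomial MLEs of the apex detection probabilities.

    Conditioning on detection by at least one observer, the duplicate fraction
    among observer-2 detections estimates p₁ and vice versa:
    p̂₁ = n11/(n01+n11), p̂₂ = n11/(n10+n11), p̂· = 1 − (1−p̂₁)(1−p̂₂).
    """
    if tally.n11 == 0:
        raise ValueError("no duplicate detections (n11 = 0): apex probabilities are inestimable")
    p1 = tally.n11 / (tally.n01 + tally.n11)
    p2 = tally.n11 / (tally.n10 + tally.n11)
    p_dot = 1.0 - (1.0 - p1) * (1.0 - p2)
    return p1, p2, p_dot


def _mr_loglik(tally: CaptureTally, p1: float, p2: float) -> float:
    """Conditional multinomial log-likelihood of the history tallies."""
    p_dot = 1.0 - (1.0 - p1) * (1.0 - p2)
    pr10 = p1 * (1.0 - p2) / p_dot
    pr01 = (1.0 - p1) * p2 / p_dot
    pr11 = p1 * p2 / p_dot
    ll = 0.0
    for n, pr in ((tally.n10, pr10), (tally.n01, pr01), (tally.n11, pr11)):
        if n > 0:
            if pr <= 0:
                return -np.inf
            ll += n * np.log(pr)
    return ll


def fit_mrds(dataset: SurveyDataset, c_max: float | None = None) -> MrdsFit:
    """Joint MRDS fit on a survey with capture histories.

    Under the intercept-only MR model, the distance-shape factor and the
    capture-history factor share no parameters, so the joint MLE is the pair
    of separate MLEs and the joint log-likelihood is their sum.
    """
    if dataset.n_detections < 10:
        raise ValueError(f"need ≥ 10 detections, got {dataset.n_detections}")
    shape_fit = fit_twopiece_ml(dataset.distances(), dataset.strip_width_m, c_max=c_max)
    tally = tally_histories(dataset)
    p1, p2, p_dot = fit_mr_intercept(tally)
    loglik = shape_fit.loglik + _mr_loglik(tally, p1, p2)
    return MrdsFit(curve=shape_fit.curve, p1=p1, p2=p2, p_dot=p_dot,
                   loglik=float(loglik), w=dataset.strip_width_m)


def estimate_abundance_ht(fit: MrdsFit, dataset: SurveyDataset) -> AbundanceEstimate:
    """Horvitz–Thompson abundance over individual bears (point estimate only).

    N̂_cov = Σᵢ sᵢ / (p̂· g(xᵢ)) over detections in the covered strips, then
    scaled by study_area / covered_area. Detections with g(x) below a small
    floor are excluded (a far-tail observation under a tight σ̂₂ would
    otherwise dominate the sum).
    """
    x = dataset.distances()
    s = dataset.group_sizes().astype(float)
    g = np.asarray(fit.curve.evaluate(x), dtype=float).reshape(-1)
    keep = g >= G_FLOOR
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} detection(s) with fitted g(x) < {G_FLOOR:g} from the HT sum",
            stacklevel=2,
        )
    n_cov = float(np.sum(s[keep] / (fit.p_dot * g[keep])))
    area = covered_area(dataset)
    n_hat = n_cov / area * dataset.study_area_km2
    return AbundanceEstimate(n_hat=n_hat, lo=n_hat, hi=n_hat, cv=0.0,
                             method=Method.MRDS_BC,
                             extras={"N_cov": n_cov, "n_dropped_g_floor": n_dropped})


def _resample_transects(dataset: SurveyDataset, rng: np.random.Generator) -> SurveyDataset:
    """Resample transects with replacement; detections travel with their transect."""
    by_transect: dict[str, list] = {t.id: [] for t in dataset.transects}
    for d in dataset.detections:
        by_transect[d.transect_id].append(d)
    idx = rng.integers(0, len(dataset.transects), size=len(dataset.transects))
    new_transects = []
    new_detections = []
    for rep, i in enumerate(idx):
        t = dataset.transects[i]
        new_id = f"{t.id}~{rep}"  # keep ids unique across repeated draws
        new_transects.append(type(t)(id=new_id, date=t.date, length_km=t.length_km))
        for d in by_transect[t.id]:
            new_detections.append(type(d)(transect_id=new_id, distance_m=d.distance_m,
                                          group_size=d.group_size, history=d.history))
    return SurveyDataset(
        transects=tuple(new_transects),
        detections=tuple(new_detections),
        truncation_w_m=dataset.truncation_w_m,
        study_area_km2=dataset.study_area_km2,
        left_trunc_c_m=dataset.left_trunc_c_m,
    )


def bootstrap_mrds(
    dataset: SurveyDataset,
    B: int = 500,
    seed: int = 0,
    c_max: float | None = None,
    max_redraw_factor: int = 5,
) -> AbundanceEstimate:
    """Nonparametric transect bootstrap of the MRDS abundance estimator.

    Each replicate resamples transects with replacement, refits the full MRDS
    model, and recomputes the HT abundance. Replicates with inestimable MR
    (no duplicate detections) or too few detections are redrawn; more than 20%
    redraws triggers a warning. The replicate refits start the shape optimizer
    from the point-estimate fit (plus two perturbed starts) for speed.

    Returns the point estimate from the full data with a percentile 95%
    interval and CV = bootstrap SD / point estimate.
    """
    if B < 100:
        raise ValueError(f"B must be ≥ 100, got {B}")
    point_fit = fit_mrds(dataset, c_max=c_max)
    point = estimate_abundance_ht(point_fit, dataset)

    c0, s1, s2 = point_fit.curve.apex_c, point_fit.curve.sigma_left, point_fit.curve.sigma_right
    w = dataset.strip_width_m
    starts = np.array([
        [c0, s1, s2],
        [min(c0 * 1.5 + 0.02 * w, w / 2 if c_max is None else c_max), s1 * 1.5, s2 * 0.7],
        [c0 * 0.5, s1 * 0.7, s2 * 1.5],
    ])

    rng = np.random.default_rng(seed)
    draws = np.empty(B)
    n_redraws = 0
    b = 0
    max_attempts = max_redraw_factor * B
    attempts = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # g-floor warnings inside replicates
        while b < B:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(f"bootstrap exceeded {max_attempts} attempts; data too sparse")
            rep = _resample_transects(dataset, rng)
            try:
                shape_fit = fit_twopiece_ml(rep.distances(), w, c_max=c_max, starts=starts)
                p1, p2, p_dot = fit_mr_intercept(tally_histories(rep))
            except (ValueError, RuntimeError):
                n_redraws += 1
                continue
            fit = MrdsFit(curve=shape_fit.curve, p1=p1, p2=p2, p_dot=p_dot,
                          loglik=np.nan, w=w)
            draws[b] = estimate_abundance_ht(fit, rep).n_hat
            b += 1
    if n_redraws > 0.2 * B:
        warnings.warn(f"{n_redraws} bootstrap replicates redrawn (> 20% of B={B})", stacklevel=2)

    lo, hi = np.percentile(draws, [2.5, 97.5])
    sd = float(np.std(draws, ddof=1))
    n_hat = point.n_hat
    return AbundanceEstimate(
        n_hat=n_hat, lo=float(min(lo, n_hat)), hi=float(max(hi, n_hat)),
        cv=sd / n_hat if n_hat > 0 else 0.0,
        method=Method.MRDS_BC,
        extras={
            "c": point_fit.curve.apex_c, "sigma1": point_fit.curve.sigma_left,
            "sigma2": point_fit.curve.sigma_right, "p1": point_fit.p1,
            "p2": point_fit.p2, "p_dot": point_fit.p_dot,
            "B": B, "seed": seed, "n_redraws": n_redraws,
        },
    )
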