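"""Composite-likelihood fitting, AIC model selection, parametric bootstrap.

The observed data are pairwise folded 2D SFS; monomorphic cells and
singletons are masked and ignored throughout (the SNP filters remove
singletons, and polymorphic RAD loci give no reliable estimate of the
monomorphic fraction). The composite log10-likelihood treats unmasked
cells as independent multinomial draws:

    log10 CL = sum over pairs, unmasked cells of m_cell * log10(p_cell)

where p are the model's expected cell probabilities, renormalised over
unmasked cells. The ceiling of this quantity (Gibbs' inequality) is
reached when p equals the observed relative frequencies, giving the
MaxObsLhood goodness-of-fit reference; the Obs/Est log-likelihood ratio
is reported as a diagnostic. Models with the same observed spectra are
compared by AIC = 2k - 2 ln(10) * MaxEstLhood, a difference of at least
10 being treated as decisive; parameter uncertainty comes from refitting
simulated pseudoreplicate spectra.

The optimiser is an ECM-style loop: each cycle re-estimates the expected
SFS by coalescent simulation under a cycle-fixed random seed (common
random numbers, so within-cycle comparisons are not dominated by Monte
Carlo noise) and proposes coordinate-wise steps on transformed (log10
where applicable) parameters, accepting only non-decreasing moves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import DemographicModel, validate_event_order
from .engine import expected_pair_sfs
from .sfs import Folded2DSFS

__all__ = [
    "FitResult",
    "SelectionRule",
    "BootstrapResult",
    "composite_log10_likelihood",
    "max_observed_log10_likelihood",
    "fit_model",
    "compare_models",
    "parametric_bootstrap",
]

LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# likelihoods


def _check_matched(obs: list[Folded2DSFS], exp: list[Folded2DSFS]) -> None:
    if len(obs) != len(exp):
        raise ValueError("observed and expected SFS lists differ in length")
    for o, e in zip(obs, exp):
        if o.pair != e.pair:
            raise ValueError(f"pair mismatch: {o.pair} vs {e.pair}")
        if o.counts.shape != e.counts.shape:
            raise ValueError(f"shape mismatch for pair {o.pair}")
        if not np.array_equal(o.mask, e.mask):
            raise ValueError(f"mask mismatch for pair {o.pair}")


def composite_log10_likelihood(obs: list[Folded2DSFS], exp: list[Folded2DSFS]) -> float:
    """Sum of m_cell * log10(p_cell) over unmasked cells of every pair.

    Expected probabilities are renormalised over unmasked cells; a zero
    probability in any unmasked cell is a hard error (the simulation
    floor guarantees positivity).
    """
    _check_matched(obs, exp)
    total = 0.0
    for o, e in zip(obs, exp):
        keep = ~o.mask
        m = o.counts[keep]
        p = e.counts[keep].astype(float)
        if np.any(p <= 0.0):
            raise ValueError(
                f"unmasked zero expected probability in pair {o.pair}; "
                "probability floor violated"
            )
        p = p / p.sum()
        total += float(np.sum(m * np.log10(p)))
    return total


def max_observed_log10_likelihood(obs: list[Folded2DSFS]) -> float:
    """Likelihood ceiling: the composite likelihood if the expected SFS
    matched the observed relative frequencies exactly (Gibbs bound)."""
    if not obs:
        raise ValueError("need at least one observed SFS")
    total = 0.0
    for o in obs:
        m = o.counts[~o.mask]
        M = m.sum()
        if M <= 0:
            continue
        nz = m > 0
        total += float(np.sum(m[nz] * np.log10(m[nz] / M)))
    return total


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    model_name: str
    submodel: str
    n_demes: int
    param_names: list[str]
    best_params: dict
    max_est_lhood: float  # log10 composite likelihood at the optimum
    max_obs_lhood: float  # log10 likelihood ceiling
    k: int
    replicate: int  # index of the best replicate run
    traces: list = field(default_factory=list)  # per replicate, lik per cycle

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * LN10 * self.max_est_lhood

    @property
    def obs_est_ratio(self) -> float:
        """MaxObsLhood / MaxEstLhood on the log10 scale (<= 1, near 1 = good fit)."""
        return self.max_obs_lhood / self.max_est_lhood

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model_name,
                "submodel": self.submodel,
                "n_demes": self.n_demes,
                "best_params": self.best_params,
                "MaxEstLhood": self.max_est_lhood,
                "MaxObsLhood": self.max_obs_lhood,
                "k": self.k,
                "AIC": self.aic,
                "replicate": self.replicate,
            },
            indent=1,
        )


@dataclass(frozen=True)
class SelectionRule:
    delta_aic_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.delta_aic_threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class BootstrapResult:
    param_names: list[str]
    mean: np.ndarray
    low: np.ndarray  # 2.5th percentile
    high: np.ndarray  # 97.5th percentile
    n_pseudoreplicates: int
    estimates: np.ndarray  # (n_pseudo, P) best estimate per pseudoreplicate

    def __post_init__(self) -> None:
        if np.any(self.low > self.high):
            raise ValueError("percentile interval has low > high")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "ci_low": self.low, "ci_high": self.high},
            index=self.param_names,
        )


# ---------------------------------------------------------------------------
# optimisation


def _transform(model: DemographicModel):
    """Bounds and forward/backward maps to the optimiser's space
    (log10 for log-scale parameters)."""
    lows, highs, logs = [], [], []
    for p in model.params:
        if p.scale == "log":
            lows.append(np.log10(p.low))
            highs.append(np.log10(p.high))
            logs.append(True)
        else:
            lows.append(p.low)
            highs.append(p.high)
            logs.append(False)
    lows, highs = np.array(lows), np.array(highs)
    logs = np.array(logs)

    def to_natural(z):
        v = z.copy()
        v[logs] = 10.0 ** v[logs]
        return v

    return lows, highs, to_natural


def _draw_start(model, lows, highs, to_natural, rng, max_tries=1000):
    for _ in range(max_tries):
        z = rng.uniform(lows, highs)
        if not validate_event_order(model, to_natural(z)):
            return z
    return None


def fit_model(
    model: DemographicModel,
    obs: list[Folded2DSFS],
    n_sims: int = 100_000,
    n_cycles: int = 60,
    n_replicates: int = 100,
    seed: int = 0,
    floor_factor: float = 10.0,
    step_frac: float = 0.25,
) -> FitResult:
    """Maximise the composite likelihood over the model's free parameters.

    Runs ``n_replicates`` independent searches from random start points
    (uniform on the range, log-uniform for log-scale parameters), each
    with ``n_cycles`` coordinate-wise improvement cycles re-estimating
    the expected SFS with ``n_sims`` coalescent simulations per
    evaluation. Returns the best replicate's result; all replicate
    likelihood traces are retained. Parameter vectors violating the event
    order are rejected during both start sampling and proposals.
    """
    if not obs:
        raise ValueError("no observed spectra given")
    exp_pairs = [
        (a, b)
        for i, a in enumerate(model.deme_names)
        for b in model.deme_names[i + 1 :]
    ]
    obs_pairs = [o.pair for o in obs]
    if obs_pairs != exp_pairs:
        raise ValueError(f"observed pairs {obs_pairs} do not match model pairs {exp_pairs}")

    rng = np.random.default_rng(seed)
    lows, highs, to_natural = _transform(model)
    P = len(model.params)
    max_obs = max_observed_log10_likelihood(obs)

    def evaluate(z, cycle_seed):
        v = to_natural(z)
        if validate_event_order(model, v):
            return -np.inf
        exp = expected_pair_sfs(model, v, n_sims=n_sims, seed=cycle_seed, floor_factor=floor_factor)
        return composite_log10_likelihood(obs, exp)

    best: tuple[float, np.ndarray, int] | None = None
    traces: list[list[float]] = []
    n_failed = 0
    for rep in range(n_replicates):
        z = _draw_start(model, lows, highs, to_natural, rng)
        if z is None:
            n_failed += 1
            traces.append([])
            continue
        steps = np.full(P, step_frac) * (highs - lows)
        trace: list[float] = []
        cur = -np.inf
        if n_cycles == 0:  # degenerate run: score the start point
            cur = evaluate(z, int(rng.integers(2**31)))
            trace.append(cur)
        for cyc in range(n_cycles):
            cseed = int(rng.integers(2**31))
            cur = evaluate(z, cseed)  # common random numbers within the cycle
            for p in range(P):
                improved = False
                for sign in (+1.0, -1.0):
                    zc = z.copy()
                    zc[p] = np.clip(z[p] + sign * steps[p], lows[p], highs[p])
                    if zc[p] == z[p]:
                        continue
                    lc = evaluate(zc, cseed)
                    if lc > cur:
                        z, cur = zc, lc
                        improved = True
                        break
                if not improved:
                    steps[p] *= 0.5
            trace.append(cur)
        traces.append(trace)
        if np.isfinite(cur) and (best is None or cur > best[0]):
            best = (cur, z.copy(), rep)

    if best is None:
        raise RuntimeError(
            f"all {n_replicates} replicates failed event-order validation"
        )
    lik, z, rep = best
    v = to_natural(z)
    return FitResult(
        model_name=model.name,
        submodel=model.submodel,
        n_demes=model.n_demes,
        param_names=model.param_names(),
        best_params={n: float(x) for n, x in zip(model.param_names(), v)},
        max_est_lhood=float(lik),
        max_obs_lhood=float(max_obs),
        k=model.k,
        replicate=rep,
        traces=traces,
    )


# ---------------------------------------------------------------------------
# model comparison


def compare_models(fits: list[FitResult], rule: SelectionRule = SelectionRule()) -> pd.DataFrame:
    """Rank fits of the same observed spectra by AIC.

    3-deme and 4-deme fits must never be mixed: their observed data
    differ, so their likelihoods are not comparable. The best model is
    flagged significant when the runner-up's delta-AIC reaches the
    threshold.
    """
    if not fits:
        raise ValueError("no fits to compare")
    n_demes = {f.n_demes for f in fits}
    if len(n_demes) > 1:
        raise ValueError(
            f"cannot compare fits across deme counts {sorted(n_demes)}: "
            "their observed spectra differ"
        )
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    order = np.argsort(aics, kind="stable")
    significant = bool(len(fits) > 1 and np.sort(delta)[1] >= rule.delta_aic_threshold)
    rows = []
    for i in order:
        f = fits[i]
        label = f.model_name + (f"({f.submodel})" if f.submodel else "")
        rows.append(
            {
                "model": label,
                "k": f.k,
                "MaxEstLhood": f.max_est_lhood,
                "MaxObsLhood": f.max_obs_lhood,
                "obs_est_ratio": f.obs_est_ratio,
                "AIC": f.aic,
                "delta_AIC": delta[i],
                "best": bool(i == order[0]),
                "best_is_significant": significant if i == order[0] else False,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parametric bootstrap


def parametric_bootstrap(
    model: DemographicModel,
    best_params,
    n_snps_per_pair,
    n_pseudo: int = 100,
    n_reps: int = 100,
    n_sims: int = 100_000,
    n_cycles: int = 60,
    seed: int = 0,
    floor_factor: float = 10.0,
) -> BootstrapResult:
    """95% percentile confidence intervals by parametric bootstrap.

    Simulates ``n_pseudo`` pseudoreplicate spectra under ``best_params``
    with the observed per-pair SNP totals, refits each with ``n_reps``
    replicate searches, and summarises the per-pseudoreplicate best
    estimates by their mean and [2.5%, 97.5%] percentiles.
    """
    from .synthetic import pseudoreplicate_sfs

    rng = np.random.default_rng(seed)
    names = model.param_names()
    estimates = np.zeros((n_pseudo, len(names)))
    for b in range(n_pseudo):
        ps = int(rng.integers(2**31))
        pseudo = pseudoreplicate_sfs(model, best_params, n_snps_per_pair, seed=ps, n_sims=n_sims)
        fit = fit_model(
            model, pseudo, n_sims=n_sims, n_cycles=n_cycles, n_replicates=n_reps,
            seed=int(rng.integers(2**31)), floor_factor=floor_factor,
        )
        estimates[b] = [fit.best_params[n] for n in names]
    return BootstrapResult(
        param_names=names,
        mean=estimates.mean(axis=0),
        low=np.percentile(estimates, 2.5, axis=0),
        high=np.percentile(estimates, 97.5, axis=0),
        n_pseudoreplicates=n_pseudo,
        estimates=estimates,
    )
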