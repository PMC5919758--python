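"""Estimators for the experimental readouts of stochastic tuning.

* Jeffreys-prior credible intervals for Poisson colony/cell counts.
* Kernel-density overlap between fluorescence distributions and the
  exponential decay fit giving a population mixing time.
* Recovery time of epigenetically tuned populations: linear interpolation
  of colony-formation rates across days against a 1-in-10,000 threshold.
* Blanked (autofluorescence-subtracted, size-normalized) median log2 fold
  change with bootstrap confidence intervals.
* A two-level Student-t hierarchical model for qPCR delta-Ct values
  (technical run scatter around sample means, biological scatter of sample
  means around condition means), sampled with emcee.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "FluorescenceSnapshot",
    "JeffreysPosterior",
    "MixingFit",
    "RecoveryResult",
    "FoldChangeResult",
    "DctFit",
    "poisson_jeffreys_posterior",
    "density_overlap",
    "mixing_time_fit",
    "recovery_time",
    "blanked_fold_change",
    "fit_hierarchical_dct",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class FluorescenceSnapshot:
    """Per-cell fluorescence values at one timepoint.

    ``fsc`` (forward scatter, a cell-size proxy) is required for the
    size-normalized fold-change analysis and optional otherwise.
    """

    values: np.ndarray
    fsc: np.ndarray | None = None
    time: float = 0.0  # minutes since t = 0
    population: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fluorescence values must be finite")
        if self.fsc is not None:
            self.fsc = np.asarray(self.fsc, dtype=float)
            if self.fsc.shape != self.values.shape:
                raise ValueError("fsc must have the same length as values")


@dataclass(frozen=True)
class JeffreysPosterior:
    """Gamma posterior for a Poisson rate under the Jeffreys prior."""

    shape: float
    rate: float
    interval: tuple[float, float]  # central 95% credible interval

    @property
    def mean(self) -> float:
        return self.shape / self.rate


@dataclass(frozen=True)
class MixingFit:
    """Exponential mixing-time fit f(t) = a * exp(-t/tau)."""

    a: float
    tau: float  # minutes
    half_life: float  # tau * ln 2
    residual_norm: float
    degenerate: bool = False


@dataclass(frozen=True)
class RecoveryResult:
    """Day at which colonies-per-plated-cell crosses the threshold."""

    days: float | None
    censored: bool
    daily_rates: pd.DataFrame = field(compare=False, default=None)


@dataclass(frozen=True)
class FoldChangeResult:
    log2_fold_change: float
    ci: tuple[float, float]
    median_a: float
    median_b: float
    n_boot: int


@dataclass
class DctFit:
    """Posterior summaries of the hierarchical delta-Ct model."""

    class_summary: pd.DataFrame  # mu_c median + 95% CrI per class
    sample_summary: pd.DataFrame
    diagnostics: dict
    chain: np.ndarray  # flattened posterior samples (n_samples, n_params)
    param_names: list[str]


# ---------------------------------------------------------------------------
# Poisson counts


def poisson_jeffreys_posterior(counts, interval: float = 0.95) -> JeffreysPosterior:
    """Posterior for a Poisson rate given counts on a common scale.

    With the Jeffreys prior the posterior is Gamma(0.5 + sum(counts), n)
    where n is the number of observations.  Counts observed at different
    dilutions must be rescaled to a common effective denominator first.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one count observation")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    shape = 0.5 + counts.sum()
    rate = float(counts.size)
    lo = (1 - interval) / 2
    dist = stats.gamma(a=shape, scale=1.0 / rate)
    return JeffreysPosterior(
        shape=float(shape), rate=rate, interval=(float(dist.ppf(lo)), float(dist.ppf(1 - lo)))
    )


# ---------------------------------------------------------------------------
# KDE overlap and mixing time


def _values(sample) -> np.ndarray:
    if isinstance(sample, FluorescenceSnapshot):
        return sample.values
    return np.asarray(sample, dtype=float)


def density_overlap(a, b, bw_method="scott", grid_size: int = 1024) -> float:
    """Overlap coefficient of two samples' kernel density estimates.

    Integrates min(f_a, f_b) over a shared grid spanning both samples
    (padded by three bandwidths).  Symmetric, bounded in [0, 1].
    """
    xa, xb = _values(a), _values(b)
    for name, x in (("a", xa), ("b", xb)):
        if len(np.unique(x)) < 2:
            raise ValueError(f"sample {name} has fewer than 2 distinct values; density undefined")
    ka = stats.gaussian_kde(xa, bw_method=bw_method)
    kb = stats.gaussian_kde(xb, bw_method=bw_method)
    ha = math.sqrt(float(ka.covariance[0, 0]))
    hb = math.sqrt(float(kb.covariance[0, 0]))
    lo = min(xa.min() - 3 * ha, xb.min() - 3 * hb)
    hi = max(xa.max() + 3 * ha, xb.max() + 3 * hb)
    grid = np.linspace(lo, hi, grid_size)
    overlap = np.trapezoid(np.minimum(ka(grid), kb(grid)), grid)
    return float(min(overlap, 1.0))


def mixing_time_fit(
    times, overlaps, degenerate_rel: float = 0.02
) -> MixingFit:
    """Fit the mixing timescale from an overlap-vs-time series.

    The overlap series x_t is transformed to f(t) = (max(x) - x_t) / x_{t=0}
    and fitted with a * exp(-t / tau) by nonlinear least squares (initialized
    from a log-linear fit).  ``half_life`` is tau * ln 2.  The fit is flagged
    degenerate — no mixing signal — when the maximum overlap is attained at
    t = 0 or the total rise in overlap is below ``degenerate_rel`` of x_0.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(overlaps, dtype=float)
    if t.shape != x.shape or t.ndim != 1:
        raise ValueError("times and overlaps must be 1-D arrays of equal length")
    if len(t) < 3:
        raise ValueError("need at least 3 timepoints to fit a mixing time")
    order = np.argsort(t)
    t, x = t[order], x[order]
    if t[0] != 0:
        raise ValueError("series must include t = 0 (the sorting timepoint)")
    x0 = x[0]
    if x0 <= 0:
        raise ValueError("overlap at t = 0 must be positive")
    if int(np.argmax(x)) == 0 or (x.max() - x0) / x0 < degenerate_rel:
        return MixingFit(a=0.0, tau=math.inf, half_life=math.inf, residual_norm=0.0,
                         degenerate=True)
    f = (x.max() - x) / x0

    pos = f > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(f[pos]), 1)
        tau0 = -1.0 / slope if slope < 0 else t.max()
        a0 = math.exp(intercept)
    else:
        tau0, a0 = t.max() / 2, max(f.max(), 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            t,
            f,
            p0=(a0, max(tau0, 1e-6)),
            bounds=([0, 1e-9], [np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"mixing-time fit did not converge (init a={a0:.4g}, tau={tau0:.4g}): {exc}"
        ) from exc
    a_fit, tau = float(popt[0]), float(popt[1])
    resid = float(np.linalg.norm(f - a_fit * np.exp(-t / tau)))
    return MixingFit(a=a_fit, tau=tau, half_life=tau * math.log(2), residual_norm=resid)


# ---------------------------------------------------------------------------
# recovery time


def recovery_time(
    counts: pd.DataFrame,
    threshold: float = 1e-4,
    cells_at_unit_dilution: float = 1e5,
) -> RecoveryResult:
    """Day at which colonies-per-plated-cell first crosses ``threshold``.

    ``counts`` has columns day, dilution, count and optionally a boolean
    ``haze`` column marking spots too dense to count.  A haze spot whose
    next 10-fold more dilute spot shows zero colonies is assigned a count of
    1; other haze spots are excluded as uncountable.  Per-day rates pool the
    countable spots (sum of counts over sum of plated cells, with
    ``cells_at_unit_dilution`` cells plated at dilution 1) and the crossing
    day is linearly interpolated between bracketing observations.
    """
    df = counts.copy()
    required = {"day", "dilution", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    if "haze" not in df.columns:
        df["haze"] = False
    if np.any(df["dilution"] <= 0):
        raise ValueError("dilutions must be positive")

    rows = []
    for day, grp in df.groupby("day"):
        grp = grp.sort_values("dilution")  # most concentrated first
        counts_eff = grp["count"].to_numpy(dtype=float)
        haze = grp["haze"].to_numpy(dtype=bool)
        dil = grp["dilution"].to_numpy(dtype=float)
        usable = ~haze
        for i in np.nonzero(haze)[0]:
            # next 10-fold more dilute spot with zero colonies -> count 1
            more_dilute = np.nonzero(dil > dil[i])[0]
            if len(more_dilute) and counts_eff[more_dilute[0]] == 0 and not haze[more_dilute[0]]:
                counts_eff[i] = 1.0
                usable[i] = True
        if not usable.any():
            continue
        cells = cells_at_unit_dilution / dil[usable]
        rate = counts_eff[usable].sum() / cells.sum()
        rows.append({"day": day, "rate": rate})
    daily = pd.DataFrame(rows).sort_values("day").reset_index(drop=True)
    if len(daily) == 0:
        raise ValueError("no countable observations")
    if np.any(np.diff(daily["rate"]) < 0):
        warnings.warn("colony-formation rate is not monotone non-decreasing in time")

    above = daily["rate"] >= threshold
    if not above.any():
        return RecoveryResult(days=None, censored=True, daily_rates=daily)
    i = int(np.argmax(above.to_numpy()))
    if i == 0:
        return RecoveryResult(days=float(daily["day"][0]), censored=False, daily_rates=daily)
    d0, d1 = daily["day"][i - 1], daily["day"][i]
    r0, r1 = daily["rate"][i - 1], daily["rate"][i]
    frac = (threshold - r0) / (r1 - r0)
    return RecoveryResult(
        days=float(d0 + frac * (d1 - d0)), censored=False, daily_rates=daily
    )


# ---------------------------------------------------------------------------
# blanked fold change


def _blank(snap: FluorescenceSnapshot, blank: FluorescenceSnapshot) -> np.ndarray:
    """Size-normalize by FSC^1.5 and subtract expected autofluorescence.

    The autofluorescence map is a lowess fit (default span) of the blank
    population's normalized signal against FSC, evaluated at each cell's FSC
    by interpolation.
    """
    if snap.fsc is None or blank.fsc is None:
        raise ValueError("fsc is required in condition and blank snapshots")
    y = snap.values / snap.fsc**1.5
    yb = blank.values / blank.fsc**1.5
    fit = lowess(yb, blank.fsc, return_sorted=True)
    auto = np.interp(snap.fsc, fit[:, 0], fit[:, 1])
    return y - auto


def blanked_fold_change(
    cond_a: FluorescenceSnapshot,
    cond_b: FluorescenceSnapshot,
    blank_a: FluorescenceSnapshot,
    blank_b: FluorescenceSnapshot,
    n_boot: int = 200,
    seed: int | None = None,
) -> FoldChangeResult:
    """Median log2 fold change of blanked fluorescence, b relative to a.

    Confidence interval from ``n_boot`` bootstrap resamples of cells in each
    condition (percentile 95% interval).
    """
    ba = _blank(cond_a, blank_a)
    bb = _blank(cond_b, blank_b)
    med_a, med_b = float(np.median(ba)), float(np.median(bb))
    for name, m in (("a", med_a), ("b", med_b)):
        if m <= 0:
            raise ValueError(
                f"median blanked fluorescence in condition {name} is {m:.4g} <= 0; "
                "log2 fold change undefined"
            )
    fc = math.log2(med_b / med_a)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = np.median(rng.choice(ba, size=len(ba), replace=True))
        rb = np.median(rng.choice(bb, size=len(bb), replace=True))
        boots[i] = np.log2(rb / ra) if ra > 0 and rb > 0 else np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return FoldChangeResult(
        log2_fold_change=fc, ci=(float(lo), float(hi)),
        median_a=med_a, median_b=med_b, n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# hierarchical delta-Ct model


def _t_logpdf(z, df):
    """Standard Student-t log density (vectorized; avoids scipy call overhead
    inside the sampler's inner loop)."""
    from scipy.special import gammaln

    return (
        gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * math.log(math.pi) - 0.5 * np.log(df)
        - (df + 1.0) / 2.0 * np.log1p(z * z / df)
    )


def _dct_log_prob(theta, dct, sample_idx, class_of_sample, n_classes, n_samples):
    """Log posterior of the two-level t model.

    theta = [mu_c (n_classes), log sigma_c (n_classes), mu_s (n_samples),
             log sigma_rep, log nu_rep, log nu_bio].
    Flat priors on locations, half-flat on sigmas (via the log-Jacobian so
    the prior is flat on the sigma scale), weak exponential priors pulling
    the degrees of freedom toward moderate values.
    """
    mu_c = theta[:n_classes]
    log_sig_c = theta[n_classes : 2 * n_classes]
    mu_s = theta[2 * n_classes : 2 * n_classes + n_samples]
    log_sig_rep, log_nu_rep, log_nu_bio = theta[-3:]
    if np.any(np.abs(theta) > 50):
        return -np.inf
    sig_c = np.exp(log_sig_c)
    sig_rep = np.exp(log_sig_rep)
    nu_rep = 1.0 + np.exp(log_nu_rep)
    nu_bio = 1.0 + np.exp(log_nu_bio)
    # observation level
    lp = np.sum(_t_logpdf((dct - mu_s[sample_idx]) / sig_rep, nu_rep)) - len(
        dct
    ) * np.log(sig_rep)
    # sample level
    lp += np.sum(
        _t_logpdf((mu_s - mu_c[class_of_sample]) / sig_c[class_of_sample], nu_bio)
        - np.log(sig_c[class_of_sample])
    )
    # priors: flat on sigma (=> add log_sigma Jacobian), weak on dofs
    lp += log_sig_rep + np.sum(log_sig_c)
    lp += -nu_rep / 30.0 - nu_bio / 30.0
    if not np.isfinite(lp):
        return -np.inf
    return lp


def fit_hierarchical_dct(
    obs: pd.DataFrame,
    n_walkers: int = 32,
    n_steps: int = 2000,
    burn: int = 500,
    seed: int | None = None,
    min_acceptance: float = 0.05,
) -> DctFit:
    """Fit the hierarchical delta-Ct model by ensemble MCMC.

    ``obs`` has columns class, sample, day (unused beyond bookkeeping) and
    dct, each dct being the per-sample-per-day median across technical
    replicates.  Observations scatter (Student-t, scale sigma_rep) around
    sample means mu_s, which scatter (Student-t, scale sigma_c per class)
    around class means mu_c — the quantity of interest.  Returns posterior
    medians and central 95% credible intervals; raises on sampler
    non-convergence (mean acceptance below ``min_acceptance``).
    """
    required = {"class", "sample", "dct"}
    if not required.issubset(obs.columns):
        raise ValueError(f"observations must have columns {sorted(required)}")
    df = obs.copy()
    if not np.all(np.isfinite(df["dct"])):
        raise ValueError("dct values must be finite")
    # canonical row order: the posterior is exchangeable, and sorting makes
    # the sampler bit-reproducible under input permutations
    df = df.sort_values(["class", "sample", "dct"], kind="mergesort").reset_index(drop=True)
    classes = sorted(df["class"].unique())
    samples = sorted(df["sample"].unique())
    class_idx = {c: i for i, c in enumerate(classes)}
    sample_idx_map = {s: i for i, s in enumerate(samples)}
    dct = df["dct"].to_numpy(dtype=float)
    sample_idx = df["sample"].map(sample_idx_map).to_numpy()
    class_of_sample = np.array(
        [class_idx[df.loc[df["sample"] == s, "class"].iloc[0]] for s in samples]
    )
    n_classes, n_samples = len(classes), len(samples)
    ndim = 2 * n_classes + n_samples + 3

    # moment-based initialization
    samp_means = df.groupby("sample")["dct"].mean().reindex(samples).to_numpy()
    cls_means = np.array(
        [samp_means[class_of_sample == i].mean() for i in range(n_classes)]
    )
    resid_sd = max(float(df.groupby("sample")["dct"].std().mean()), 0.05)
    if not np.isfinite(resid_sd):
        resid_sd = 0.05
    cls_sd = np.array(
        [
            max(np.std(samp_means[class_of_sample == i]), 0.05)
            if (class_of_sample == i).sum() > 1
            else resid_sd
            for i in range(n_classes)
        ]
    )
    center = np.concatenate(
        [cls_means, np.log(cls_sd), samp_means, [np.log(resid_sd), np.log(10.0), np.log(10.0)]]
    )
    rng = np.random.default_rng(seed)
    p0 = center + 0.05 * rng.standard_normal((n_walkers, ndim))

    sampler = emcee.EnsembleSampler(
        n_walkers,
        ndim,
        _dct_log_prob,
        args=(dct, sample_idx, class_of_sample, n_classes, n_samples),
    )
    sampler.random_state = np.random.RandomState(
        rng.integers(0, 2**31 - 1)
    ).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    acc = float(np.mean(sampler.acceptance_fraction))
    if acc < min_acceptance:
        raise RuntimeError(
            f"delta-Ct sampler failed to mix: mean acceptance {acc:.3f} < {min_acceptance}"
        )
    chain = sampler.get_chain(discard=burn, flat=True)

    names = (
        [f"mu_c[{c}]" for c in classes]
        + [f"log_sigma_c[{c}]" for c in classes]
        + [f"mu_s[{s}]" for s in samples]
        + ["log_sigma_rep", "log_nu_rep", "log_nu_bio"]
    )
    q = np.percentile(chain, [2.5, 50, 97.5], axis=0)
    class_summary = pd.DataFrame(
        {
            "class": classes,
            "mu_c_median": q[1, :n_classes],
            "mu_c_lo": q[0, :n_classes],
            "mu_c_hi": q[2, :n_classes],
            "sigma_c_median": np.exp(q[1, n_classes : 2 * n_classes]),
        }
    )
    sample_summary = pd.DataFrame(
        {
            "sample": samples,
            "class": [classes[i] for i in class_of_sample],
            "mu_s_median": q[1, 2 * n_classes : 2 * n_classes + n_samples],
            "mu_s_lo": q[0, 2 * n_classes : 2 * n_classes + n_samples],
            "mu_s_hi": q[2, 2 * n_classes : 2 * n_classes + n_samples],
        }
    )
    diagnostics = {"mean_acceptance": acc, "n_walkers": n_walkers, "n_steps": n_steps,
                   "burn": burn, "ndim": ndim}
    return DctFit(
        class_summary=class_summary,
        sample_summary=sample_summary,
        diagnostics=diagnostics,
        chain=chain,
        param_names=names,
    )
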