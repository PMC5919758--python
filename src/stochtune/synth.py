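"""Synthetic data with known ground truth for the estimator suite.

Each generator emulates the structure of one experimental readout —
expression-sorted populations relaxing back together, colony counts in a
dilution series, two-level qPCR delta-Ct tables — with the true parameter
recoverable by the paired estimator.  None of them attempt to model
instrument optics or amplification chemistry; they exist so every analysis
path can be exercised end-to-end with a known answer.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .stats import FluorescenceSnapshot

__all__ = [
    "gen_mixing_series",
    "gen_colony_counts",
    "gen_dct",
    "gen_two_pop",
]


def gen_mixing_series(
    tau_true: float,
    timepoints,
    noise_sd: float = 0.0,
    n_cells: int = 20_000,
    delta0: float = 0.8,
    log_mean: float = 6.0,
    log_sd: float = 0.7,
    seed: int | None = None,
) -> dict[str, list[FluorescenceSnapshot]]:
    """Sorted sub-populations relaxing toward the full distribution.

    Cells carry lognormal fluorescence.  At t = 0 the ``top20`` and
    ``bottom20`` populations sit ``delta0`` apart (in log units, split
    symmetrically about the mock mean) and the separation decays as
    exp(-t / tau_true) — a mean-reverting log-scale relaxation whose only
    tunable feature is the timescale.  ``noise_sd`` applies multiplicative
    lognormal noise to the separation at each timepoint.  ``tau_true`` may
    be ``inf`` (no mixing: separation constant).

    Returns a dict of population label -> list of snapshots (one per
    timepoint), deterministic under fixed seed.
    """
    if not (tau_true > 0):
        raise ValueError("tau_true must be positive (may be inf)")
    rng = np.random.default_rng(seed)
    out: dict[str, list[FluorescenceSnapshot]] = {"top20": [], "bottom20": [], "mock": []}
    for t in sorted(float(t) for t in timepoints):
        decay = 1.0 if math.isinf(tau_true) else math.exp(-t / tau_true)
        sep = delta0 * decay
        if noise_sd > 0:
            sep *= math.exp(noise_sd * rng.standard_normal())
        for pop, shift in (("top20", +sep / 2), ("bottom20", -sep / 2), ("mock", 0.0)):
            logv = rng.normal(log_mean + shift, log_sd, n_cells)
            out[pop].append(
                FluorescenceSnapshot(values=np.exp(logv), time=t, population=pop)
            )
    return out


def gen_colony_counts(
    rate_per_cell: float,
    dilutions=(1.0, 10.0, 100.0, 1000.0),
    days=(2, 4, 6, 8),
    growth_day: float = 0,
    seed: int | None = None,
    cells_at_unit_dilution: float = 1e5,
    haze_above: float = 500.0,
) -> pd.DataFrame:
    """Dilution-spotting colony counts with Poisson noise.

    Counts are Poisson(rate_per_cell * cells plated) for days at or after
    ``growth_day`` and zero before.  Spots whose expected count exceeds
    ``haze_above`` are marked as uncountable haze (count reported 0,
    haze=True), emulating confluent growth at the concentrated end of the
    series.
    """
    if not 0 <= rate_per_cell <= 1:
        raise ValueError("rate_per_cell must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for day in days:
        for dil in dilutions:
            cells = cells_at_unit_dilution / dil
            expected = rate_per_cell * cells if day >= growth_day else 0.0
            if expected > haze_above:
                rows.append({"day": day, "dilution": dil, "count": 0, "haze": True})
            else:
                rows.append(
                    {
                        "day": day,
                        "dilution": dil,
                        "count": int(rng.poisson(expected)),
                        "haze": False,
                    }
                )
    return pd.DataFrame(rows)


def gen_dct(
    class_means,
    sigma_c: float,
    sigma_rep: float,
    n_samples: int = 4,
    n_days: int = 3,
    nu_bio: float = 10.0,
    nu_rep: float = 10.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-level delta-Ct table: sample means drawn t(class mean, sigma_c),
    observations drawn t(sample mean, sigma_rep), one row per sample x day."""
    if sigma_c <= 0 or sigma_rep <= 0:
        raise ValueError("sigmas must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    if np.ndim(class_means) == 0:
        class_means = [float(class_means)]
    for ci, mu_c in enumerate(class_means):
        label = f"class{ci}"
        for si in range(n_samples):
            mu_s = mu_c + sigma_c * rng.standard_t(nu_bio)
            sample = f"{label}_s{si}"
            for day in range(n_days):
                dct = mu_s + sigma_rep * rng.standard_t(nu_rep)
                rows.append(
                    {"class": label, "sample": sample, "day": day, "dct": float(dct)}
                )
    return pd.DataFrame(rows)


def gen_two_pop(
    median_shift: float = 4.0,
    n_cells: int = 4000,
    autofluor: float = 50.0,
    signal_a: float = 200.0,
    fsc_mean: float = 1e5,
    fsc_cv: float = 0.25,
    noise_cv: float = 0.3,
    seed: int | None = None,
) -> tuple[FluorescenceSnapshot, FluorescenceSnapshot, FluorescenceSnapshot, FluorescenceSnapshot]:
    """Two conditions with a known median fold change, plus matched blanks.

    Fluorescence scales with FSC^1.5 (the size dependence the analysis
    removes) plus an FSC-dependent autofluorescence shared with the
    nonfluorescent blanks.  Returns (cond_a, cond_b, blank_a, blank_b) with
    the true blanked median log2 fold change equal to log2(median_shift).
    """
    rng = np.random.default_rng(seed)

    def make(signal: float, population: str) -> FluorescenceSnapshot:
        fsc = rng.lognormal(np.log(fsc_mean), fsc_cv, n_cells)
        size_factor = (fsc / fsc_mean) ** 1.5
        per_cell = signal * rng.lognormal(-(noise_cv**2) / 2, noise_cv, n_cells)
        auto = autofluor * (0.5 + 0.5 * fsc / fsc_mean)
        values = (per_cell + auto) * size_factor
        return FluorescenceSnapshot(values=values, fsc=fsc, population=population)

    cond_a = make(signal_a, "cond_a")
    cond_b = make(signal_a * median_shift, "cond_b")
    blank_a = make(0.0, "blank_a")
    blank_b = make(0.0, "blank_b")
    return cond_a, cond_b, blank_a, blank_b
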