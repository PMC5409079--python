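"""Bland-Altman agreement between two prediction methods.

Used here to ask whether monospecies and multispecies calibrations are
interchangeable: differences d_i = a_i - b_i are summarised by their mean
d and standard deviation sd, with limits of agreement d ± 1.96 sd. Under
approximate normality 95% of paired differences should fall inside the
limits. Confidence intervals use the classical small-sample formulas:
sd/sqrt(n) for the mean difference and sd*sqrt(3/n) for each limit, with
t quantiles by default (z behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import SampleSizeError

Z_95 = 1.96


@dataclass
class AgreementResult:
    n: int
    d: float                      # mean difference (% DM)
    sd_diff: float                # SD of differences, n-1 denominator
    loa_lower: float
    loa_upper: float
    ci_d: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    outside_ids: list


def bland_altman(a, b, sample_ids=None, use_t: bool = True) -> AgreementResult:
    """Limits-of-agreement analysis of paired measurements a and b.

    Differences are taken as ``a - b`` (here: monospecies minus
    multispecies prediction). ``sample_ids`` labels the points reported as
    outside the limits; indices are used when omitted.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("a and b must have equal length")
    n = a.size
    if n < 3:
        raise SampleSizeError("Bland-Altman needs at least 3 pairs")
    if sample_ids is None:
        sample_ids = list(range(n))
    diffs = a - b
    d = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lower = d - Z_95 * sd
    upper = d + Z_95 * sd

    q = float(stats.t.ppf(0.975, n - 1)) if use_t else Z_95
    half_d = q * sd / np.sqrt(n)
    half_loa = q * sd * np.sqrt(3.0 / n)
    outside = [sid for sid, diff in zip(sample_ids, diffs)
               if diff < lower or diff > upper]
    return AgreementResult(
        n=n,
        d=d,
        sd_diff=sd,
        loa_lower=lower,
        loa_upper=upper,
        ci_d=(d - half_d, d + half_d),
        ci_loa_lower=(lower - half_loa, lower + half_loa),
        ci_loa_upper=(upper - half_loa, upper + half_loa),
        outside_ids=outside,
    )


def agreement_plot(result: AgreementResult, a, b, species=None, ax=None):
    """Difference-vs-mean scatter with limits of agreement and their CIs.

    Points outside the limits are ring-marked; when species labels are
    given, points are coloured by species.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    means = (a + b) / 2.0
    diffs = a - b
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))

    if species is not None:
        species = np.asarray(species)
        for sp in sorted(set(species)):
            m = species == sp
            ax.scatter(means[m], diffs[m], s=25, label=str(sp), alpha=0.8)
        ax.legend(fontsize=8)
    else:
        ax.scatter(means, diffs, s=25, alpha=0.8)

    outside_mask = (diffs < result.loa_lower) | (diffs > result.loa_upper)
    if outside_mask.any():
        ax.scatter(means[outside_mask], diffs[outside_mask], s=90,
                   facecolors="none", edgecolors="red", linewidths=1.2)

    ax.axhline(result.d, color="darkblue", linestyle=":", label="mean difference")
    for y in (result.loa_lower, result.loa_upper):
        ax.axhline(y, color="black", linestyle="--", linewidth=1)
    xlim = ax.get_xlim()
    for ci in (result.ci_d, result.ci_loa_lower, result.ci_loa_upper):
        ax.fill_between(xlim, ci[0], ci[1], color="grey", alpha=0.25)
    ax.set_xlim(xlim)
    ax.set_xlabel("Mean of methods (% DM)")
    ax.set_ylabel("Difference between methods (% DM)")
    return ax
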