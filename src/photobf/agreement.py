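"""Method-agreement statistics for paired body-fat estimates.

Implements the three analyses used to compare a candidate %BF estimator
with the DXA criterion:

* **Meng-Rosenthal-Rubin Z** for two dependent correlations sharing one
  variable (is the photographic model's correlation with DXA higher than
  the BMI-plus-covariates model's?), via Fisher's z transform.
* **Lin's concordance correlation coefficient**, which penalizes both
  decorrelation and location/scale shift (population moments, per Lin's
  original definition).
* **Bland-Altman** absolute and relative difference analysis with 95%
  limits of agreement mean +- 1.96 SD (sample SD, n-1 denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError


def _as_finite(name: str, v) -> np.ndarray:
    a = np.asarray(v, dtype=float).ravel()
    if not np.isfinite(a).all():
        raise ValidationError(f"{name} contains non-finite values")
    return a


def meng_test(x, y1, y2) -> tuple[float, float]:
    """Compare corr(x, y1) with corr(x, y2) for paired data (Meng et al.).

    Returns (Z, two-sided p). With r1 = cor(x, y1), r2 = cor(x, y2),
    r12 = cor(y1, y2), z_i = atanh(r_i):

        Z = (z1 - z2) * sqrt((n - 3) / (2 (1 - r12) h)),
        h = (1 - f rbar2) / (1 - rbar2),
        f = min(1, (1 - r12) / (2 (1 - rbar2))),  rbar2 = (r1^2 + r2^2) / 2.

    Antisymmetric in (y1, y2); Z = 0 when the two correlations are equal.
    """
    x, y1, y2 = _as_finite("x", x), _as_finite("y1", y1), _as_finite("y2", y2)
    n = len(x)
    if not (len(y1) == len(y2) == n):
        raise ValidationError("x, y1, y2 must have equal length")
    if n <= 3:
        raise ValidationError("Meng's test requires n >= 4")
    r1 = float(np.corrcoef(x, y1)[0, 1])
    r2 = float(np.corrcoef(x, y2)[0, 1])
    r12 = float(np.corrcoef(y1, y2)[0, 1])
    if abs(r1) >= 1.0 - 1e-12 or abs(r2) >= 1.0 - 1e-12:
        raise ValidationError(
            "a correlation is exactly +-1; Fisher's z is infinite (handle exact fits separately)"
        )
    if abs(r1 - r2) < 1e-12:
        return 0.0, 1.0  # equal correlations: no difference to test
    if r12 >= 1.0:
        raise ValidationError("predictors are perfectly correlated yet r1 != r2")
    rbar2 = (r1**2 + r2**2) / 2.0
    f = min(1.0, (1.0 - r12) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (math.atanh(r1) - math.atanh(r2)) * math.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return z, float(p)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    ccc = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2), with
    1/n moments. Equals 1 iff y = x; bounded by |pearson r|.
    """
    x, y = _as_finite("x", x), _as_finite("y", y)
    if len(x) != len(y) or len(x) < 2:
        raise ValidationError("lin_ccc requires paired vectors of length >= 2")
    vx, vy = np.var(x), np.var(y)
    if vx == 0 and vy == 0:
        raise ValidationError("both inputs are constant; concordance undefined")
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    return float(2.0 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2))


@dataclass(frozen=True)
class BlandAltman:
    mode: str  # "absolute" or "relative"
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    diffs: np.ndarray
    means: np.ndarray  # pairwise means (the BA plot abscissa)

    @property
    def within_limits_frac(self) -> float:
        inside = (self.diffs >= self.loa_low) & (self.diffs <= self.loa_high)
        return float(inside.mean())


def bland_altman(x, y, mode: str = "absolute") -> BlandAltman:
    """Bland-Altman difference analysis of estimator y against criterion x.

    absolute: d_i = y_i - x_i; relative: d_i = (y_i - x_i) / ((y_i + x_i)/2).
    Limits of agreement are mean +- 1.96 * sample SD.
    """
    x, y = _as_finite("x", x), _as_finite("y", y)
    if len(x) != len(y):
        raise ValidationError("paired vectors required")
    means = (x + y) / 2.0
    if mode == "absolute":
        diffs = y - x
    elif mode == "relative":
        if np.any(means == 0):
            raise ValidationError("relative differences undefined where the pairwise mean is 0")
        diffs = (y - x) / means
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    return BlandAltman(
        mode=mode,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        diffs=diffs,
        means=means,
    )


@dataclass(frozen=True)
class MethodComparison:
    """Full agreement report between the photographic and baseline models."""

    r_dp: float  # criterion vs photographic estimate
    r_db: float  # criterion vs no-photo (BMI + covariates) estimate
    r_pb: float  # between the two estimates
    z_meng: float
    p_two_sided: float
    ccc: dict[str, float]
    bland_altman_absolute: BlandAltman
    bland_altman_relative: BlandAltman


def compare_methods(bf_dxa, bf_photo, bf_nophoto) -> MethodComparison:
    """Compute the standard report: correlations, Meng Z, CCC, Bland-Altman."""
    x = _as_finite("bf_dxa", bf_dxa)
    yp = _as_finite("bf_photo", bf_photo)
    yb = _as_finite("bf_nophoto", bf_nophoto)
    z, p = meng_test(x, yp, yb)
    return MethodComparison(
        r_dp=float(np.corrcoef(x, yp)[0, 1]),
        r_db=float(np.corrcoef(x, yb)[0, 1]),
        r_pb=float(np.corrcoef(yp, yb)[0, 1]),
        z_meng=z,
        p_two_sided=p,
        ccc={"photo": lin_ccc(x, yp), "nophoto": lin_ccc(x, yb)},
        bland_altman_absolute=bland_altman(x, yp, "absolute"),
        bland_altman_relative=bland_altman(x, yp, "relative"),
    )


def comparison_table(cmpr: MethodComparison) -> str:
    """Plain-text table of correlations and concordance per model."""
    lines = [
        f"{'model':<28}{'r vs DXA':>10}{'Lin CCC':>10}",
        f"{'no-photo (BMI+covariates)':<28}{cmpr.r_db:>10.3f}{cmpr.ccc['nophoto']:>10.3f}",
        f"{'photographic':<28}{cmpr.r_dp:>10.3f}{cmpr.ccc['photo']:>10.3f}",
        f"Meng Z = {cmpr.z_meng:.2f}, two-sided p = {cmpr.p_two_sided:.2g}",
        (
            f"Bland-Altman (absolute): mean {cmpr.bland_altman_absolute.mean_diff:.2f}, "
            f"LoA [{cmpr.bland_altman_absolute.loa_low:.2f}, "
            f"{cmpr.bland_altman_absolute.loa_high:.2f}]"
        ),
    ]
    return "\n".join(lines)


def plot_agreement(cmpr: MethodComparison, bf_dxa, bf_photo, path: str) -> None:
    """Scatter + Bland-Altman panels (criterion vs photographic estimate)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(bf_dxa, dtype=float)
    y = np.asarray(bf_photo, dtype=float)
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    axes[0].scatter(x, y, s=12)
    lim = [min(x.min(), y.min()), max(x.max(), y.max())]
    axes[0].plot(lim, lim, "k--", lw=1)
    axes[0].set(xlabel="%BF criterion (DXA)", ylabel="%BF photographic", title=f"r = {cmpr.r_dp:.2f}")
    for ax, ba, title in (
        (axes[1], cmpr.bland_altman_absolute, "absolute difference"),
        (axes[2], cmpr.bland_altman_relative, "relative difference"),
    ):
        ax.scatter(ba.means, ba.diffs, s=12)
        for yline in (ba.mean_diff, ba.loa_low, ba.loa_high):
            ax.axhline(yline, color="k", ls="--", lw=1)
        ax.set(xlabel="pairwise mean", ylabel="difference", title=title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
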