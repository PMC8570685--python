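"""Method-agreement statistics: Bland–Altman and Pearson correlation.

Used to validate automated scores against manual scores across videos.
Bland–Altman reports the bias (mean of automatic − manual differences)
with 95% limits of agreement at bias ± 1.96 × SD of the differences; the
SD uses the n−1 (sample) denominator, the standard convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = ["AgreementReport", "bland_altman", "pearson", "agreement_report",
           "plot_bland_altman", "plot_scatter_fit"]


@dataclass(frozen=True)
class AgreementReport:
    bias: float
    loa_low: float
    loa_high: float
    pearson_r: float
    r_squared: float
    p_value: float
    n: int

    def to_json_dict(self) -> dict:
        return {
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
        }


def _pair(auto, manual) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(auto, dtype=np.float64)
    m = np.asarray(manual, dtype=np.float64)
    if a.shape != m.shape or a.ndim != 1:
        raise ValueError("auto and manual must be 1-d vectors of equal length")
    return a, m


def bland_altman(auto, manual) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high) of the differences auto − manual."""
    a, m = _pair(auto, manual)
    if a.size < 2:
        raise ValueError("need at least 2 paired values")
    d = a - m
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def pearson(auto, manual) -> tuple[float, float, float]:
    """(r, r², two-sided p) product-moment correlation; p from the
    t transform with n − 2 degrees of freedom."""
    a, m = _pair(auto, manual)
    if a.size < 3:
        raise ValueError("need at least 3 paired values")
    if a.std() == 0 or m.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(a, m)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def agreement_report(auto, manual) -> AgreementReport:
    a, m = _pair(auto, manual)
    bias, lo, hi = bland_altman(a, m)
    r, r2, p = pearson(a, m)
    return AgreementReport(
        bias=bias, loa_low=lo, loa_high=hi,
        pearson_r=r, r_squared=r2, p_value=p, n=int(a.size),
    )


def _agg_plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_bland_altman(auto, manual, path: str | Path, label: str = "value") -> None:
    """Bland–Altman plot: differences against means, with the bias (dotted
    black) and 95% limits of agreement (dotted magenta)."""
    plt = _agg_plt()
    a, m = _pair(auto, manual)
    bias, lo, hi = bland_altman(a, m)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter((a + m) / 2, a - m, s=18, color="tab:blue")
    ax.axhline(0, color="black")
    ax.axhline(bias, color="black", linestyle=":")
    for y in (lo, hi):
        ax.axhline(y, color="magenta", linestyle=":")
    ax.set_xlabel(f"mean of methods ({label})")
    ax.set_ylabel("automatic − manual")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scatter_fit(auto, manual, path: str | Path, label: str = "value") -> None:
    """Scatter of automatic vs manual values with a least-squares line."""
    plt = _agg_plt()
    a, m = _pair(auto, manual)
    slope, intercept = np.polyfit(m, a, 1)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(m, a, s=18, color="tab:blue")
    xs = np.linspace(m.min(), m.max(), 50)
    ax.plot(xs, slope * xs + intercept, color="black")
    ax.set_xlabel(f"manual ({label})")
    ax.set_ylabel(f"automatic ({label})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
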