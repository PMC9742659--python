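"""Voxel-wise image-quality metrics and the strategy-comparison statistics.

Metrics against the reference ASC image: mean error (ME), mean absolute
error (MAE), relative and absolute relative error in percent (RE%, ARE%),
peak signal-to-noise ratio (PSNR, dB) and the structural similarity index
(SSIM).  RE/ARE divide by the reference voxel value, so every metric is
evaluated on an explicit mask — by default, reference > 0.01 normalized
units (the body region); the same mask is applied to all metrics for
consistency.  PSNR uses Peak = max of the masked reference by default
(``peak='reference'``) or the fixed normalized ceiling 5 (``peak=5.0``).

Strategies are compared per metric by a two-sided Mann-Whitney (Wilcoxon
rank-sum) test with Benjamini-Hochberg adjustment across the family of
pairwise comparisons; significance is declared at q < 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.metrics import structural_similarity
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EvalMask",
    "MetricsReport",
    "StatTestResult",
    "voxel_metrics",
    "ssim",
    "joint_histogram_r2",
    "compare_strategies",
    "summarize_reports",
]

METRIC_NAMES = ("ME", "MAE", "RE_pct", "ARE_pct", "PSNR_dB", "SSIM")


@dataclass(frozen=True)
class EvalMask:
    """Evaluation mask: ``reference > tau`` (default) or the whole image."""

    rule: str = "reference>tau"
    tau: float = 0.01

    def build(self, ref: np.ndarray) -> np.ndarray:
        if self.rule == "whole":
            mask = np.ones_like(ref, dtype=bool)
        elif self.rule == "reference>tau":
            mask = np.asarray(ref) > self.tau
        else:
            raise ValueError(f"unknown mask rule {self.rule!r}")
        if not mask.any():
            raise ValueError("evaluation mask is empty")
        return mask


@dataclass
class MetricsReport:
    study_id: str
    strategy: str
    ME: float
    MAE: float
    RE_pct: float
    ARE_pct: float
    PSNR_dB: float
    SSIM: float
    vxl: int
    peak: float

    def __post_init__(self):
        # Jensen-type inequalities hold for any sample
        assert self.MAE >= abs(self.ME) - 1e-12
        assert self.ARE_pct >= abs(self.RE_pct) - 1e-9


@dataclass
class StatTestResult:
    metric: str
    strategy_a: str
    strategy_b: str
    p_value: float
    q_value: float
    significant: bool


def voxel_metrics(
    pred: np.ndarray,
    ref: np.ndarray,
    mask: EvalMask | np.ndarray = EvalMask(),
    study_id: str = "",
    strategy: str = "",
    peak="reference",
    data_range: float = 5.0,
) -> MetricsReport:
    """All voxel-wise metrics of one predicted image against its reference.

    Means run over masked voxels only.  If the masked prediction equals the
    reference exactly, PSNR is reported as +inf.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must be conformable")
    m = mask if isinstance(mask, np.ndarray) else mask.build(ref)
    if m.shape != ref.shape:
        raise ValueError("mask grid must match the image grid")
    if not m.any():
        raise ValueError("evaluation mask is empty")
    p, r = pred[m], ref[m]
    if (r <= 0).any():
        raise ValueError("reference must be positive on the mask for RE/ARE")
    diff = p - r
    me = float(diff.mean())
    mae = float(np.abs(diff).mean())
    re = float((diff / r).mean() * 100.0)
    are = float(np.abs(diff / r).mean() * 100.0)
    mse_val = float((diff * diff).mean())
    pk = float(r.max()) if peak == "reference" else float(peak)
    psnr = np.inf if mse_val == 0 else float(10.0 * np.log10(pk * pk / mse_val))
    # SSIM needs room for its 11-px window; report NaN on tiny fixtures
    s = ssim(pred, ref, data_range=data_range) if min(pred.shape) >= 11 else float("nan")
    return MetricsReport(
        study_id=study_id,
        strategy=strategy,
        ME=me,
        MAE=mae,
        RE_pct=re,
        ARE_pct=are,
        PSNR_dB=psnr,
        SSIM=s,
        vxl=int(m.sum()),
        peak=pk,
    )


def ssim(pred: np.ndarray, ref: np.ndarray, data_range: float = 5.0) -> float:
    """Mean local SSIM, Gaussian window of 11 px (sigma 1.5), K1/K2 = 0.01/0.03.

    ``data_range`` is the dynamic range L of the stabilizing constants
    C1 = (K1 L)^2, C2 = (K2 L)^2; 5 for normalized PET images.  A pair of
    identical constant images scores 1 by the stabilized formula.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must be conformable")
    return float(
        structural_similarity(
            ref,
            pred,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=data_range,
            K1=0.01,
            K2=0.03,
        )
    )


def joint_histogram_r2(
    pred_studies,
    ref_studies,
    mask: EvalMask = EvalMask(),
    bins: int = 128,
    value_range: tuple = (0.0, 5.0),
):
    """Pooled voxel-wise correlation across studies.

    Returns ``(hist2d, r_squared, slope)``: a ``bins x bins`` joint histogram
    over ``value_range`` squared (reference on the first axis) and the
    coefficient of determination of the ordinary least-squares fit of
    predicted on reference voxel values.
    """
    ps, rs = [], []
    for pred, ref in zip(pred_studies, ref_studies):
        m = mask.build(np.asarray(ref))
        ps.append(np.asarray(pred, dtype=float)[m])
        rs.append(np.asarray(ref, dtype=float)[m])
    p = np.concatenate(ps)
    r = np.concatenate(rs)
    if p.size < 2:
        raise ValueError("need at least 2 pooled masked voxels")
    if np.var(r) == 0:
        raise ValueError("reference has zero variance; R^2 undefined")
    hist, _, _ = np.histogram2d(r, p, bins=bins, range=[value_range, value_range])
    fit = stats.linregress(r, p)
    return hist, float(fit.rvalue**2), float(fit.slope)


def reports_to_frame(reports) -> pd.DataFrame:
    return pd.DataFrame([vars(rep) for rep in reports])


def compare_strategies(
    reports,
    metrics=METRIC_NAMES,
    alpha: float = 0.05,
    grouping: str = "overall",
):
    """Pairwise two-sided Mann-Whitney tests with BH adjustment.

    ``reports`` is an iterable of MetricsReport (or an equivalent DataFrame).
    The BH step-up correction runs across the whole family of
    (strategy pair x metric) comparisons within the grouping; a comparison is
    significant iff q < alpha.  Ties are handled by midranks (the test then
    uses the normal approximation with tie correction).  Results are
    invariant to the ordering of studies.
    """
    df = reports if isinstance(reports, pd.DataFrame) else reports_to_frame(reports)
    strategies = sorted(df["strategy"].unique())
    rows = []
    for metric in metrics:
        for a, b in itertools.combinations(strategies, 2):
            xa = df.loc[df["strategy"] == a, metric].to_numpy(dtype=float)
            xb = df.loc[df["strategy"] == b, metric].to_numpy(dtype=float)
            if len(xa) < 3 or len(xb) < 3:
                raise ValueError("need >= 3 studies per group")
            xa = xa[np.isfinite(xa)]
            xb = xb[np.isfinite(xb)]
            p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
            rows.append((metric, a, b, p))
    pvals = [r[3] for r in rows]
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return [
        StatTestResult(metric=m, strategy_a=a, strategy_b=b, p_value=p,
                       q_value=float(q), significant=bool(q < alpha))
        for (m, a, b, p), q in zip(rows, qvals)
    ]


def summarize_reports(reports) -> pd.DataFrame:
    """Per-strategy mean, SD and normal-theory 95% CI of each metric."""
    df = reports if isinstance(reports, pd.DataFrame) else reports_to_frame(reports)
    rows = []
    for strategy, grp in df.groupby("strategy"):
        for metric in METRIC_NAMES:
            x = grp[metric].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            mean = x.mean()
            sd = x.std(ddof=1) if len(x) > 1 else 0.0
            half = 1.959963984540054 * sd / np.sqrt(len(x)) if len(x) > 1 else 0.0
            rows.append(
                dict(strategy=strategy, metric=metric, mean=mean, sd=sd,
                     ci_low=mean - half, ci_high=mean + half, n=len(x))
            )
    return pd.DataFrame(rows)
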