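"""Method agreement: normalization factors, bias/accuracy, Bland-Altman.

The small-VOI method is compared against the whole-kidney-parenchyma
(WKP) reference.  The normalization factor

    NF = mean over kidneys x spheres of D_SV / D_WKP

acts as an apparent recovery coefficient for the SV method; dividing an
SV dose by NF gives the normalized dose D_SVN.  Agreement is then
summarised on the percentage-difference scale

    PD = 100 (D_SVN - D_WKP) / D_WKP

whose mean is the *bias* and whose sample standard deviation is what
the clinical literature calls the *accuracy* of the method.  Bland-
Altman limits of agreement are bias +/- 1.96 SD on the same scale.

``MethodComparison`` packages this as a statsmodels-style model: build
it from paired doses, ``fit()`` returns an :class:`AgreementResults`
with a ``summary()`` table and a Bland-Altman plot method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalization_factor",
    "apply_nf",
    "percent_difference",
    "bias_accuracy",
    "bland_altman",
    "pearson_r",
    "MethodComparison",
    "AgreementResults",
]


def normalization_factor(d_sv, d_wkp=None) -> float:
    """Mean single-SV dose ratio, the apparent RC of the SV method.

    Either pass per-sphere doses and matching reference doses, or a
    single array of precomputed ratios.  With 18 patients (36 kidneys)
    and 5 spheres per kidney this is the mean of 180 ratio terms.
    """
    d_sv = np.asarray(d_sv, dtype=float)
    if d_sv.size == 0:
        raise ValueError("normalization factor needs at least one dose ratio")
    if d_wkp is None:
        ratios = d_sv
    else:
        d_wkp = np.asarray(d_wkp, dtype=float)
        if d_wkp.shape != d_sv.shape:
            raise ValueError("d_sv and d_wkp must have equal shapes")
        if np.any(d_wkp <= 0):
            raise ValueError("all reference doses must be positive")
        ratios = d_sv / d_wkp
    return float(ratios.mean())


def apply_nf(d_sv, nf: float):
    """Normalized SV dose: D_SVN = D_SV / NF."""
    if nf <= 0:
        raise ValueError(f"normalization factor must be positive, got {nf}")
    out = np.asarray(d_sv, dtype=float) / nf
    return float(out) if out.ndim == 0 else out


def percent_difference(d_svn, d_wkp):
    """PD = 100 (D_SVN - D_WKP) / D_WKP, the Bland-Altman difference axis."""
    d_svn = np.asarray(d_svn, dtype=float)
    d_wkp = np.asarray(d_wkp, dtype=float)
    if np.any(d_wkp <= 0):
        raise ValueError("reference doses must be positive")
    out = 100.0 * (d_svn - d_wkp) / d_wkp
    return float(out) if out.ndim == 0 else out


def bias_accuracy(pds) -> tuple[float, float]:
    """Mean (bias) and sample SD (accuracy) of percentage differences."""
    arr = np.asarray(pds, dtype=float)
    if arr.size < 2:
        raise ValueError("bias/accuracy need at least 2 values")
    return float(arr.mean()), float(arr.std(ddof=1))


def pearson_r(x, y) -> float:
    """Product-moment correlation between two dose series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("Pearson r needs at least 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson r undefined for zero variance")
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(d_svn, d_wkp) -> dict[str, float]:
    """Bias and 95% limits of agreement on the PD scale.

    Differences are normalized to the reference (WKP) dose, so the
    returned quantities are percentages; LoA = bias +/- 1.96 SD exactly.
    """
    d_svn = np.asarray(d_svn, dtype=float)
    d_wkp = np.asarray(d_wkp, dtype=float)
    if d_svn.size < 3 or d_wkp.size != d_svn.size:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    pds = percent_difference(d_svn, d_wkp)
    bias = float(np.mean(pds))
    sd = float(np.std(pds, ddof=1))
    return {
        "bias_percent": bias,
        "sd_percent": sd,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
    }


class MethodComparison:
    """Paired-dose comparison of an SV method against the WKP reference.

    Parameters
    ----------
    d_sv, d_wkp : array-like
        Paired doses (Gy), one pair per kidney, for the SV estimate
        being evaluated and the reference.
    single_sv_ratios : array-like, optional
        Per-sphere single-SV dose ratios used to estimate the
        normalization factor.  When omitted, NF is estimated from the
        evaluated pairs themselves (in-sample).
    kidney_ids : sequence of str, optional
    """

    def __init__(self, d_sv, d_wkp, single_sv_ratios=None, kidney_ids=None):
        self.d_sv = np.asarray(d_sv, dtype=float)
        self.d_wkp = np.asarray(d_wkp, dtype=float)
        if self.d_sv.shape != self.d_wkp.shape or self.d_sv.ndim != 1:
            raise ValueError("d_sv and d_wkp must be 1-D arrays of equal length")
        if np.any(self.d_wkp <= 0):
            raise ValueError("reference doses must be positive")
        self.single_sv_ratios = (
            None if single_sv_ratios is None
            else np.asarray(single_sv_ratios, dtype=float)
        )
        self.kidney_ids = list(kidney_ids) if kidney_ids is not None else None

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, sv_col: str = "d_sv", wkp_col: str = "d_wkp",
        id_col: str | None = "kidney_id", single_sv_ratios=None,
    ) -> "MethodComparison":
        ids = df[id_col].tolist() if id_col and id_col in df.columns else None
        return cls(df[sv_col].to_numpy(), df[wkp_col].to_numpy(),
                   single_sv_ratios=single_sv_ratios, kidney_ids=ids)

    def fit(self, normalize: bool = True) -> "AgreementResults":
        """Estimate NF, apply it, and summarise agreement.

        With ``normalize=False`` the raw (uncorrected) SV doses are
        compared instead and NF is reported but not applied.
        """
        ratios = (
            self.single_sv_ratios
            if self.single_sv_ratios is not None
            else self.d_sv / self.d_wkp
        )
        nf = normalization_factor(ratios)
        d_eval = apply_nf(self.d_sv, nf) if normalize else self.d_sv.copy()
        ba = bland_altman(d_eval, self.d_wkp)
        return AgreementResults(
            nf=nf,
            normalized=normalize,
            bias_percent=ba["bias_percent"],
            accuracy_percent=ba["sd_percent"],
            pearson_r=pearson_r(self.d_sv, self.d_wkp),
            loa_low=ba["loa_low"],
            loa_high=ba["loa_high"],
            n=len(self.d_sv),
            d_svn=d_eval,
            d_wkp=self.d_wkp.copy(),
        )


@dataclass
class AgreementResults:
    """Agreement summary of an SV method against the WKP reference."""

    nf: float
    normalized: bool
    bias_percent: float
    accuracy_percent: float
    pearson_r: float
    loa_low: float
    loa_high: float
    n: int
    d_svn: np.ndarray = field(repr=False)
    d_wkp: np.ndarray = field(repr=False)

    @property
    def pd_values(self) -> np.ndarray:
        return percent_difference(self.d_svn, self.d_wkp)

    def summary(self) -> str:
        label = "normalized (D_SV / NF)" if self.normalized else "raw D_SV"
        return "\n".join(
            [
                "SV vs WKP method agreement",
                f"  kidneys          : {self.n}",
                f"  evaluated dose   : {label}",
                f"  NF (apparent RC) : {self.nf:.4f}",
                f"  bias             : {self.bias_percent:+.2f} %",
                f"  accuracy (SD PD) : {self.accuracy_percent:.2f} %",
                f"  Pearson r        : {self.pearson_r:.3f}",
                f"  95% LoA          : [{self.loa_low:+.2f}, {self.loa_high:+.2f}] %",
            ]
        )

    def plot_bland_altman(self, ax=None):
        """Bland-Altman plot: PD against the reference dose."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pds = self.pd_values
        ax.scatter(self.d_wkp, pds, s=18, alpha=0.8)
        ax.axhline(self.bias_percent, color="red", label="bias")
        for y in (self.loa_low, self.loa_high):
            ax.axhline(y, color="red", linestyle="--")
        ax.set_xlabel("WKP absorbed dose (Gy)")
        ax.set_ylabel("PD (%)")
        ax.legend(loc="best")
        return ax
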