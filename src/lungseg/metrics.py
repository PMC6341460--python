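"""Filter-quality and segmentation-quality metrics.

Filter quality, comparing a noisy image I0 with its filtered version If:

* SSI (speckle suppression index) — the ratio of coefficients of
  variation, (sigma_f / mu_f) * (mu_0 / sigma_0). Values below 1 mean the
  filter suppressed speckle; an identity filter scores exactly 1.
* SMPI (speckle and mean preservation index) — Q * (sigma_f / sigma_0)
  with Q = 1 + |mu_0 - mu_f| / mu_0. Lower is better; the Q factor
  penalizes filters that buy smoothness by shifting the mean intensity.

Segmentation quality compares a predicted tumor mask against a manual
reference pixelwise: TPR (sensitivity), TNR (specificity), FPR, FNR, all
as percentages, with the identities TPR + FNR = 100 and TNR + FPR = 100.
Accuracy is reported both as the balanced mean (TPR + TNR)/2 and as raw
pixel accuracy 100*(TP + TN)/total, which differ when the tumor occupies
a small fraction of the slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._validation import check_image, check_mask

__all__ = [
    "FilterQualityReport",
    "ConfusionReport",
    "ssi",
    "smpi",
    "confusion_rates",
    "filter_quality",
]


@dataclass
class FilterQualityReport:
    ssi: float
    smpi: float


@dataclass
class ConfusionReport:
    """Pixelwise confusion counts and derived rates (percent).

    Rates are NaN when undefined (reference mask with no positives or
    no negatives), never silently zero.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    tpr: float
    tnr: float
    fpr: float
    fnr: float
    accuracy: float
    pixel_accuracy: float

    @classmethod
    def from_counts(cls, tp: int, tn: int, fp: int, fn: int) -> "ConfusionReport":
        pos = tp + fn
        neg = tn + fp
        total = pos + neg
        if total == 0:
            raise ValueError("empty masks")
        tpr = 100.0 * tp / pos if pos else float("nan")
        tnr = 100.0 * tn / neg if neg else float("nan")
        return cls(
            tp=tp,
            tn=tn,
            fp=fp,
            fn=fn,
            tpr=tpr,
            tnr=tnr,
            fpr=100.0 - tnr,
            fnr=100.0 - tpr,
            accuracy=(tpr + tnr) / 2.0,
            pixel_accuracy=100.0 * (tp + tn) / total,
        )

    @classmethod
    def from_rates(cls, tpr: float, tnr: float) -> "ConfusionReport":
        """Derive the rate family from printed TPR/TNR percentages alone.

        Counts and pixel accuracy are unavailable and set to -1/NaN;
        useful for re-deriving accuracy and miss rates from tabulated
        sensitivity/specificity.
        """
        return cls(
            tp=-1,
            tn=-1,
            fp=-1,
            fn=-1,
            tpr=tpr,
            tnr=tnr,
            fpr=100.0 - tnr,
            fnr=100.0 - tpr,
            accuracy=(tpr + tnr) / 2.0,
            pixel_accuracy=float("nan"),
        )


def _moments(img: np.ndarray) -> tuple[float, float]:
    return float(img.mean()), float(img.std())


def ssi(noisy, filtered) -> float:
    """Speckle suppression index: (sigma_f/mu_f) * (mu_0/sigma_0); < 1 is suppression."""
    noisy = check_image(noisy, name="noisy")
    filtered = check_image(filtered, name="filtered")
    if noisy.shape != filtered.shape:
        raise ValueError("noisy and filtered images must share a shape")
    mu0, sd0 = _moments(noisy)
    muf, sdf = _moments(filtered)
    if mu0 == 0.0 or sd0 == 0.0:
        raise ValueError("SSI undefined: noisy image has zero mean or zero std")
    if muf == 0.0:
        return 0.0 if sdf == 0.0 else float("inf")
    return (sdf / muf) * (mu0 / sd0)


def smpi(noisy, filtered) -> float:
    """Speckle and mean preservation index: (1 + |mu_0-mu_f|/mu_0) * sigma_f/sigma_0."""
    noisy = check_image(noisy, name="noisy")
    filtered = check_image(filtered, name="filtered")
    if noisy.shape != filtered.shape:
        raise ValueError("noisy and filtered images must share a shape")
    mu0, sd0 = _moments(noisy)
    muf, sdf = _moments(filtered)
    if mu0 == 0.0 or sd0 == 0.0:
        raise ValueError("SMPI undefined: noisy image has zero mean or zero std")
    q = 1.0 + abs(mu0 - muf) / mu0
    return q * (sdf / sd0)


def filter_quality(noisy, filtered) -> FilterQualityReport:
    """Both filter metrics at once."""
    return FilterQualityReport(ssi=ssi(noisy, filtered), smpi=smpi(noisy, filtered))


def confusion_rates(pred, truth) -> ConfusionReport:
    """Pixelwise confusion rates of a predicted mask against a reference."""
    pred = check_mask(pred, name="pred")
    truth = check_mask(truth, name="truth")
    if pred.shape != truth.shape:
        raise ValueError("pred and truth masks must share a shape")
    p = pred.astype(bool)
    t = truth.astype(bool)
    tp = int(np.sum(p & t))
    tn = int(np.sum(~p & ~t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    return ConfusionReport.from_counts(tp, tn, fp, fn)
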