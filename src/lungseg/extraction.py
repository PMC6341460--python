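"""Turn a k-cluster label map into a single binary tumor mask.

Tumors are hyperdense on CT, so the default rule keeps the cluster with
the brightest center, then drops connected components smaller than
``min_area`` (8-connectivity) — speckle residue survives clustering as
scattered bright islands — and can optionally keep only the largest
component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._validation import check_mask

__all__ = ["ExtractionConfig", "TumorExtractor", "extract_tumor"]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connected neighborhood


@dataclass
class ExtractionConfig:
    """Tumor-mask extraction settings.

    rule: 'brightest_cluster' (default) or 'cluster_index' with
    ``target_index``; ``min_area`` in pixels; ``keep`` either
    'all_components' or 'largest_component'.
    """

    rule: str = "brightest_cluster"
    target_index: int | None = None
    min_area: int = 30
    keep: str = "all_components"

    def __post_init__(self):
        if self.rule not in ("brightest_cluster", "cluster_index"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.keep not in ("all_components", "largest_component"):
            raise ValueError(f"unknown keep mode {self.keep!r}")
        if self.min_area < 0:
            raise ValueError("min_area must be nonnegative")
        if self.rule == "cluster_index" and self.target_index is None:
            raise ValueError("rule 'cluster_index' requires target_index")


class TumorExtractor:
    """Deterministic label-map -> binary-mask post-processor.

    Not an optimizable estimator; exposed as a class so the extraction
    rule travels with the pipeline configuration.
    """

    def __init__(self, config: ExtractionConfig | None = None):
        self.config = config or ExtractionConfig()

    def extract(self, labels: np.ndarray, centers: np.ndarray) -> np.ndarray:
        cfg = self.config
        labels = np.asarray(labels)
        centers = np.asarray(centers, dtype=np.float64)
        if cfg.rule == "cluster_index":
            target = int(cfg.target_index)
            if not 0 <= target < centers.size:
                raise ValueError(
                    f"target_index {target} out of range for k={centers.size}"
                )
        else:
            target = int(np.argmax(centers))
        mask = (labels == target).astype(np.uint8)
        if mask.sum() == 0:
            warnings.warn(
                "selected tumor cluster is empty; returning all-zero mask",
                stacklevel=2,
            )
            return mask
        comp, n = ndimage.label(mask, structure=_STRUCT8)
        if n == 0:
            return mask
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
        keep_ids = np.flatnonzero(sizes >= cfg.min_area) + 1
        if cfg.keep == "largest_component" and keep_ids.size > 0:
            keep_ids = np.array([1 + int(np.argmax(sizes))])
            if sizes[keep_ids[0] - 1] < cfg.min_area:
                keep_ids = np.array([], dtype=int)
        out = np.isin(comp, keep_ids).astype(np.uint8)
        if out.sum() == 0:
            warnings.warn(
                "all tumor components removed by size filtering", stacklevel=2
            )
        return out


def extract_tumor(
    labels: np.ndarray,
    centers: np.ndarray,
    config: ExtractionConfig | None = None,
) -> np.ndarray:
    """Extract the tumor mask from a label map and its cluster centers."""
    return TumorExtractor(config).extract(labels, centers)
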