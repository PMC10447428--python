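"""Fixed-length per-subject descriptors from per-vertex curvature fields.

Vertex counts vary from subject to subject (mesh resolution follows ROI
size), so raw per-vertex features are not directly comparable across
subjects. The resolution here is distributional: an area-weighted histogram
(or empirical quantile vector) of the per-vertex scalar, over a value range
frozen from the training cohort so that test subjects are binned identically.

Feature types mirror the three Gauss-map descriptors: the shape operator
(encoded through its eigenvalue pair kappa1, kappa2, two concatenated
halves), the Gaussian curvature K, and the mean curvature H.

Feature-level fusion concatenates the per-region descriptors (hippocampus
first, amygdala second); region-level fusion happens upstream on the masks
and needs nothing here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curvature import CurvatureField

FEATURE_TYPES = ("shape_operator", "gaussian_curvature", "mean_curvature")
ENCODINGS = ("histogram", "quantile")


class EmptyFieldError(ValueError):
    """Curvature field has no valid vertices."""


class PairingError(ValueError):
    """Feature vectors to be fused belong to different subjects."""


@dataclass
class FeatureVector:
    """Fixed-length descriptor for one subject, feature type and region."""

    subject_id: str
    region_tag: str
    feature_type: str
    encoding: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def feature_samples(f: CurvatureField, feature_type: str):
    """Per-vertex scalar channel(s) and area weights for one feature type.

    Returns a list of (values, weights) pairs: one pair for the scalar
    descriptors, two (kappa1 then kappa2) for the shape operator.
    """
    if feature_type not in FEATURE_TYPES:
        raise ValueError(f"unknown feature type {feature_type!r}")
    m = f.valid
    if not m.any():
        raise EmptyFieldError("no valid vertices in curvature field")
    w = f.vertex_area[m]
    if feature_type == "shape_operator":
        return [(f.kappa1[m], w), (f.kappa2[m], w)]
    if feature_type == "gaussian_curvature":
        return [(f.K[m], w)]
    return [(f.H[m], w)]


def fit_value_range(fields: list[CurvatureField], feature_type: str,
                    lo_pct: float = 1.0, hi_pct: float = 99.0):
    """Pooled [lo_pct, hi_pct] percentile range per channel over a cohort.

    The winsorizing range is a training-cohort statistic, frozen into the
    model and re-applied unchanged to test subjects (no leakage of test
    distributions into binning).
    """
    n_chan = 2 if feature_type == "shape_operator" else 1
    ranges = []
    for ch in range(n_chan):
        pooled = np.concatenate([feature_samples(f, feature_type)[ch][0]
                                 for f in fields])
        lo, hi = np.percentile(pooled, [lo_pct, hi_pct])
        if hi <= lo:  # degenerate (constant) channel
            hi = lo + 1e-9
        ranges.append((float(lo), float(hi)))
    return ranges


def build_descriptor(f: CurvatureField, feature_type: str,
                     encoding: str = "histogram", length: int = 64,
                     value_range=None, subject_id: str = "",
                     region_tag: str = "") -> FeatureVector:
    """Encode a curvature field as a fixed-length vector.

    histogram : area-weighted, normalised to sum 1, over ``value_range``
        (values clipped into range, i.e. winsorized at the range edges);
        falls back to the field's own 1-99 percentile span when no range is
        given.
    quantile : empirical quantiles at ``length`` evenly spaced probabilities
        in [0, 1] (linear interpolation); keeps physical units, offered for
        ablation.

    The shape-operator feature concatenates a kappa1 half and a kappa2 half,
    so its total length is ``2 * length``.
    """
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding {encoding!r}")
    if length < 2:
        raise ValueError("descriptor length must be >= 2")
    channels = feature_samples(f, feature_type)
    if value_range is None:
        value_range = [tuple(np.percentile(v, [1, 99])) for v, _ in channels]
    parts = []
    for (vals, w), (lo, hi) in zip(channels, value_range):
        if encoding == "histogram":
            clipped = np.clip(vals, lo, hi)
            hist, _ = np.histogram(clipped, bins=length, range=(lo, hi),
                                   weights=w)
            parts.append(hist / hist.sum())
        else:
            qs = np.quantile(vals, np.linspace(0, 1, length))
            parts.append(qs)
    return FeatureVector(subject_id=subject_id, region_tag=region_tag,
                         feature_type=feature_type, encoding=encoding,
                         values=np.concatenate(parts))


def fuse_features(a: FeatureVector, b: FeatureVector) -> FeatureVector:
    """Concatenate two per-region descriptors (a before b) for one subject.

    Convention: hippocampus first, amygdala second. The result carries
    region_tag ``feature_fusion``.
    """
    if a.subject_id != b.subject_id:
        raise PairingError(
            f"cannot fuse descriptors of {a.subject_id!r} and {b.subject_id!r}")
    if a.feature_type != b.feature_type or a.encoding != b.encoding:
        raise PairingError("fused descriptors must share feature type and "
                           "encoding")
    return FeatureVector(subject_id=a.subject_id, region_tag="feature_fusion",
                         feature_type=a.feature_type, encoding=a.encoding,
                         values=np.concatenate([a.values, b.values]))
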