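"""Assemble per-scan feature vectors into a labeled tabular dataset.

One row per sample; columns are ``source_id``, ``label`` and the named
features (prefixed by family: shape_, firstorder_, glcm_, glszm_, glrlm_,
ngtdm_, gldm_, dglm_). Samples whose extraction fails are dropped with a
logged warning rather than poisoning the table; assembled tables contain no
missing or non-finite values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .augmentation import AugmentedSample
from .dglm import dglm_averaged_features
from .firstorder import firstorder_features
from .shape_features import shape_features
from .texture_matrices import texture_features
from .volume_io import ROIMask, VolumeImage, discretize

__all__ = ["ExtractionConfig", "FeatureTable", "extract_all", "build_table"]

logger = logging.getLogger(__name__)

META_COLUMNS = ("source_id", "label")


@dataclass
class ExtractionConfig:
    """Feature-extraction knobs; defaults follow the package conventions
    (32 gray levels, distance 1, Chebyshev radius 1, 26-connectivity)."""

    bin_count: int = 32
    delta: int = 1
    ngtdm_radius: int = 1
    gldm_radius: int = 1
    gldm_gamma: int = 0
    connectivity: int = 26
    mode_2d: bool = False
    shape: bool = True
    dglm: bool = True
    dglm_delta: int = 1
    dglm_strict: bool = False
    dglm_angles: tuple[int, ...] = (0, 45, 90, 135)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["dglm_angles"] = list(self.dglm_angles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractionConfig":
        d = dict(d)
        if "dglm_angles" in d:
            d["dglm_angles"] = tuple(d["dglm_angles"])
        return cls(**d)


@dataclass
class FeatureTable:
    """Wrapper around the canonical pandas representation."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in META_COLUMNS:
            if col not in self.df.columns:
                raise ValueError(f"feature table missing column {col!r}")
        feats = self.df[self.feature_names]
        if not np.isfinite(feats.to_numpy(dtype=float)).all():
            raise ValueError("feature table contains non-finite values")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLUMNS]

    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=int)

    @property
    def groups(self) -> np.ndarray:
        return self.df["source_id"].to_numpy(dtype=object)

    def select(self, feature_names: Sequence[str]) -> "FeatureTable":
        cols = list(META_COLUMNS) + [f for f in feature_names]
        return FeatureTable(df=self.df[cols].copy())

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureTable":
        return cls(df=pd.read_csv(path))


def extract_all(
    vol: VolumeImage, mask: ROIMask, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """One flat feature map for a volume/mask pair; deterministic."""
    config = config or ExtractionConfig()
    dvol = discretize(vol, mask, bin_count=config.bin_count)
    feats: dict[str, float] = {}
    if config.shape:
        feats.update(shape_features(mask, vol.spacing))
    feats.update(firstorder_features(vol, mask, dvol))
    feats.update(
        texture_features(
            dvol,
            delta=config.delta,
            ngtdm_radius=config.ngtdm_radius,
            gldm_radius=config.gldm_radius,
            gldm_gamma=config.gldm_gamma,
            connectivity=config.connectivity,
            mode_2d=config.mode_2d,
        )
    )
    if config.dglm:
        feats.update(
            dglm_averaged_features(
                dvol,
                delta=config.dglm_delta,
                strict=config.dglm_strict,
                angles=config.dglm_angles,
            )
        )
    bad = [k for k, v in feats.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values: {bad}")
    return feats


def build_table(
    samples: Sequence[AugmentedSample], config: ExtractionConfig | None = None
) -> FeatureTable:
    """Extract features for every sample; failed samples are dropped."""
    if len(samples) == 0:
        raise ValueError("no samples to extract")
    rows = []
    for k, sample in enumerate(samples):
        try:
            feats = extract_all(sample.volume, sample.mask, config)
        except Exception as exc:  # noqa: BLE001 - isolate per-sample failures
            logger.warning("extraction failed for sample %s (#%d): %s", sample.source_id, k, exc)
            continue
        row = {"source_id": sample.source_id, "label": int(sample.label)}
        row.update(feats)
        rows.append(row)
    if not rows:
        raise ValueError("extraction failed for every sample")
    return FeatureTable(df=pd.DataFrame(rows))
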