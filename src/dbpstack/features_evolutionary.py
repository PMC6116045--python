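"""Evolutionary-information features from PSSM profiles.

Two encoders operate on a z-score-normalized PSSM:

* **Local segment descriptor** (``local_dpp``): the profile is split into
  ``n`` row segments; each segment contributes the 20 per-residue-type
  column means (local composition of evolutionary scores) and, for each
  lag ``xi = 1..lambda``, the average squared difference between scores
  ``xi`` positions apart (sequence-order information). Dimension:
  ``20 * (1 + lambda) * n``.

* **Wavelet descriptor** (``pssm_dwt``): each of the 20 normalized columns
  is treated as a 1-D signal and decomposed with a 4-level discrete wavelet
  transform. Per level, the approximation and detail bands each contribute
  their max, min, mean and (population) standard deviation, plus the first
  5 detail coefficients: 13 values per level, 52 per column, 1040 total.

Normalization z-scores each residue-type column over the L positions with
the population standard deviation; zero-spread columns become all-zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt

from .io_formats import PSSM_ALPHABET, FeatureBlock, PssmProfile

logger = logging.getLogger(__name__)

BAND_STATS = ("max", "min", "mean", "std")


@dataclass(frozen=True, eq=False)
class NormalizedPssm:
    """Column-wise z-scored PSSM (L x 20)."""

    values: np.ndarray
    source_id: str
    column_order: tuple[str, ...] = PSSM_ALPHABET

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SegmentSpec:
    """Segment count ``n`` and correlation depth ``lam`` (lambda)."""

    n: int = 2
    lam: int = 2

    def __post_init__(self) -> None:
        if self.n < 1 or self.lam < 1:
            raise ValueError("segment count n and depth lambda must be >= 1")


@dataclass(frozen=True)
class DwtConfig:
    """Wavelet decomposition settings.

    With the defaults (4 Haar levels, 4 statistics per band, 5 leading
    detail coefficients) each residue-type column yields
    ``levels * (2 * 4 + leading_detail_count) = 52`` features.
    """

    levels: int = 4
    wavelet_name: str = "haar"
    leading_detail_count: int = 5
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.leading_detail_count < 0:
            raise ValueError("leading_detail_count must be >= 0")

    @property
    def features_per_column(self) -> int:
        return self.levels * (2 * len(BAND_STATS) + self.leading_detail_count)


def normalize_pssm(profile: PssmProfile) -> NormalizedPssm:
    """Z-score each residue-type column over positions (population std).

    Columns with zero spread are set to all-zero. Profiles with fewer than
    two rows have no defined spread and are rejected.
    """
    scores = profile.scores
    if scores.shape[0] < 2:
        raise ValueError(
            f"profile {profile.record_id!r}: need >= 2 rows to normalize"
        )
    mean = scores.mean(axis=0)
    std = scores.std(axis=0)  # population convention
    out = np.zeros_like(scores)
    nonzero = std > 0
    out[:, nonzero] = (scores[:, nonzero] - mean[nonzero]) / std[nonzero]
    return NormalizedPssm(
        values=out, source_id=profile.record_id, column_order=profile.column_order
    )


def segment_bounds(length: int, n: int) -> list[tuple[int, int]]:
    """Half-open row ranges tiling ``[0, length)`` into ``n`` segments.

    The first ``n - 1`` segments have length ``floor(length / n)``; the last
    takes the remainder.
    """
    if n < 1:
        raise ValueError("segment count must be >= 1")
    width = length // n
    if width == 0:
        raise ValueError(f"cannot split length {length} into {n} segments")
    bounds = [(k * width, (k + 1) * width) for k in range(n - 1)]
    bounds.append(((n - 1) * width, length))
    return bounds


def local_dpp(npssm: NormalizedPssm, spec: SegmentSpec = SegmentSpec()) -> FeatureBlock:
    """Segment-wise local evolutionary descriptor, dimension 20(1+lam)n.

    Layout is segment-major: for each segment, the 20 column means, then
    for each residue type the ``lam`` lag terms
    ``phi_j^xi = mean_i (p'_{i,j} - p'_{i+xi,j})^2`` with divisor
    ``length(segment) - xi``.
    """
    values = npssm.values
    bounds = segment_bounds(values.shape[0], spec.n)
    min_len = min(end - start for start, end in bounds)
    if spec.lam >= min_len:
        raise ValueError(
            f"lambda={spec.lam} must be smaller than the shortest segment "
            f"length {min_len} (n={spec.n}, L={values.shape[0]})"
        )
    feats: list[float] = []
    labels: list[str] = []
    for k, (start, end) in enumerate(bounds, start=1):
        seg = values[start:end]
        feats.extend(seg.mean(axis=0))
        labels.extend(f"seg{k}.part1.{res}" for res in npssm.column_order)
        for j, res in enumerate(npssm.column_order):
            col = seg[:, j]
            for xi in range(1, spec.lam + 1):
                diff = col[:-xi] - col[xi:]
                feats.append(float(np.mean(diff * diff)))
                labels.append(f"seg{k}.part2.{res}.xi{xi}")
    return FeatureBlock("local_dpp", np.array(feats), tuple(labels))


def dwt_decompose(signal, cfg: DwtConfig = DwtConfig()):
    """Iterated single-level DWT of ``signal``.

    Returns a list of ``(approx, detail)`` coefficient arrays, one pair per
    level; level ``i + 1`` decomposes level ``i``'s approximation band. If
    the running approximation band shrinks below two samples the recursion
    stops early and fewer than ``cfg.levels`` pairs are returned.
    """
    approx = np.asarray(signal, dtype=float)
    bands: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(cfg.levels):
        if approx.size < 2:
            break
        approx, detail = pywt.dwt(approx, cfg.wavelet_name, mode=cfg.mode)
        bands.append((approx, detail))
    return bands


def dwt_column_features(signal, cfg: DwtConfig = DwtConfig()):
    """Per-column wavelet features: per level, band statistics for the
    approximation and detail bands plus the leading detail coefficients
    (zero-padded). Missing levels (signal too short) contribute zeros.

    Returns ``(values, labels)`` with ``cfg.features_per_column`` entries.
    """
    bands = dwt_decompose(signal, cfg)
    if len(bands) < cfg.levels:
        logger.warning(
            "signal of length %d supports only %d of %d DWT levels; "
            "missing levels contribute zero features",
            np.asarray(signal).size,
            len(bands),
            cfg.levels,
        )
    values: list[float] = []
    labels: list[str] = []
    for level in range(1, cfg.levels + 1):
        if level <= len(bands):
            approx, detail = bands[level - 1]
            for band_name, band in (("approx", approx), ("detail", detail)):
                values.extend(
                    (band.max(), band.min(), band.mean(), band.std())
                )
                labels.extend(
                    f"lvl{level}.{band_name}.{stat}" for stat in BAND_STATS
                )
            lead = list(detail[: cfg.leading_detail_count])
            lead += [0.0] * (cfg.leading_detail_count - len(lead))
        else:
            values.extend([0.0] * (2 * len(BAND_STATS)))
            labels.extend(
                f"lvl{level}.{band_name}.{stat}"
                for band_name in ("approx", "detail")
                for stat in BAND_STATS
            )
            lead = [0.0] * cfg.leading_detail_count
        values.extend(lead)
        labels.extend(
            f"lvl{level}.detail.c{i + 1}" for i in range(cfg.leading_detail_count)
        )
    return np.array(values), labels


def pssm_dwt(npssm: NormalizedPssm, cfg: DwtConfig = DwtConfig()) -> FeatureBlock:
    """Wavelet descriptor over all 20 residue-type columns (default 1040-D)."""
    all_values: list[np.ndarray] = []
    all_labels: list[str] = []
    for j, res in enumerate(npssm.column_order):
        values, labels = dwt_column_features(npssm.values[:, j], cfg)
        all_values.append(values)
        all_labels.extend(f"{res}.{lab}" for lab in labels)
    return FeatureBlock("pssm_dwt", np.concatenate(all_values), tuple(all_labels))
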