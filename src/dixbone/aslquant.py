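"""pCASL perfusion quantification.

Pairwise control-label subtraction, time averaging, conversion of the
perfusion-weighted signal to cerebral blood flow with the standard
single-compartment (general kinetic) model, and temporal SNR of the
perfusion-weighted series.

Model
-----
For labeling duration tau (s), post-label delay PLD (s), labeling
efficiency alpha, arterial blood T1 ``T1b`` (s) and blood-brain partition
coefficient lambda (ml/g):

    CBF [ml/100g/min] = 6000 * lambda * dM * exp(PLD / T1b)
                        / (2 * alpha * T1b * M0 * (1 - exp(-tau / T1b)))

which is linear in dM / M0; the generator in :mod:`dixbone.phantom` uses
the exact inverse, so quantification round-trips the phantom's perfusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import Image3D, require_same_grid
from .phantom import ASLSeries

__all__ = [
    "PerfusionWeighted",
    "subtract_pairs",
    "quantify_cbf",
    "delta_m_from_cbf",
    "tsnr",
]


@dataclass
class PerfusionWeighted:
    """Time-averaged control-minus-label difference image."""

    delta_m: Image3D
    n_pairs_used: int

    def __post_init__(self):
        if self.n_pairs_used < 1:
            raise ValueError("n_pairs_used must be >= 1")
        if not np.all(np.isfinite(self.delta_m.data)):
            raise ValueError("delta_m must be finite")


def _pair_differences(series: ASLSeries) -> np.ndarray:
    """(n_pairs, nx, ny, nz) stack of control - label differences.

    Differences are formed pair by pair (no full control/label copies) so
    a whole-head 64-pair series fits comfortably in memory.
    """
    frames = series.volumes
    if len(frames) % 2 != 0:
        raise ValueError("odd frame count: control/label pairing broken")
    n_pairs = len(frames) // 2
    dtype = np.result_type(frames[0].data.dtype, np.float32)
    diffs = np.empty((n_pairs,) + frames[0].shape, dtype=dtype)
    for p in range(n_pairs):
        np.subtract(frames[2 * p].data, frames[2 * p + 1].data, out=diffs[p])
    return diffs


def subtract_pairs(series: ASLSeries) -> PerfusionWeighted:
    """Pairwise subtraction and time averaging: dM = mean(control - label)."""
    diffs = _pair_differences(series)
    return PerfusionWeighted(
        delta_m=series.volumes[0].with_data(diffs.mean(axis=0, dtype=np.float64)),
        n_pairs_used=diffs.shape[0],
    )


def _kinetic_factor(label_duration, post_label_delay, labeling_efficiency,
                    blood_t1, partition_coefficient):
    """dM/M0 per unit CBF (ml/100 g/min): the bracketed model terms."""
    for name, v in (("label_duration", label_duration),
                    ("post_label_delay", post_label_delay),
                    ("labeling_efficiency", labeling_efficiency),
                    ("blood_t1", blood_t1),
                    ("partition_coefficient", partition_coefficient)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    return (
        2.0 * labeling_efficiency * blood_t1
        * (1.0 - np.exp(-label_duration / blood_t1))
        * np.exp(-post_label_delay / blood_t1)
        / (6000.0 * partition_coefficient)
    )


def delta_m_from_cbf(cbf, m0, **constants) -> np.ndarray:
    """Forward model: perfusion-weighted signal from CBF (the generator's
    side of the round trip)."""
    return np.asarray(cbf) * np.asarray(m0) * _kinetic_factor(**constants)


def quantify_cbf(pw: PerfusionWeighted, m0: Image3D,
                 params: ASLSeries | dict, mask: Image3D | None = None) -> Image3D:
    """Invert the single-compartment model to a CBF map in ml/100 g/min.

    Voxels where M0 <= 0 are set to 0 outside ``mask`` and rejected inside
    it (a nonpositive baseline within brain means the model is invalid).
    """
    consts = params.constants() if isinstance(params, ASLSeries) else dict(params)
    require_same_grid(pw.delta_m, m0)
    m0d = m0.data
    if mask is not None:
        require_same_grid(m0, mask)
        inside = mask.data > 0
        if np.any(m0d[inside] <= 0):
            raise ValueError("nonpositive M0 inside the brain mask")
    factor = _kinetic_factor(**consts)
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf = pw.delta_m.data / (m0d * factor)
    cbf = np.where(m0d > 0, cbf, 0.0)
    if mask is not None:
        cbf = np.where(mask.data > 0, cbf, 0.0)
    return pw.delta_m.with_data(cbf)


def tsnr(series: ASLSeries, mask: Image3D) -> float:
    """Temporal SNR of the perfusion-weighted (pair-difference) series.

    Mean over mask voxels of the temporal mean, divided by the mean over
    mask voxels of the temporal standard deviation.
    """
    diffs = _pair_differences(series)
    if diffs.shape[0] < 2:
        raise ValueError("tSNR needs at least 2 perfusion-weighted samples")
    m = mask.data > 0
    if not m.any():
        raise ValueError("empty mask")
    temporal_mean = diffs.mean(axis=0, dtype=np.float64)[m].mean()
    temporal_sd = diffs.std(axis=0, ddof=1).astype(np.float64)[m].mean()
    if temporal_sd == 0:
        raise ValueError("degenerate noiseless series: zero temporal SD")
    return float(temporal_mean / temporal_sd)
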