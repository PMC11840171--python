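"""Resting-state denoising: aCompCor, confound regression, band-pass, despike.

The chain applied to each preprocessed 4D scan:

1. extract the first five principal-component time series from the eroded
   WM and CSF masks (aCompCor);
2. regress out, in a single voxel-wise model, those 10 components, the 6
   motion parameters and their 6 backward-difference derivatives, an
   intercept and a linear trend;
3. band-pass the residuals (default 0.008-0.1 Hz) with a zero-phase filter;
4. squash residual spikes beyond ``despike_k`` median absolute deviations
   toward a running median;
5. restore each voxel's original mean.

A final linear-detrend projection after despiking guarantees the output
carries no residual linear trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

DEFAULT_BAND = (0.008, 0.1)
DEFAULT_DESPIKE_K = 4.0
DESPIKE_MEDIAN_WINDOW = 11


@dataclass
class ConfoundMatrix:
    """Labelled T×p nuisance regressors (22 columns under defaults)."""

    values: np.ndarray
    columns: list[str]
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("confound values/column labels mismatch")


@dataclass
class DenoisedScan:
    """A denoised 4D scan with its affine, TR and validity mask."""

    data: np.ndarray
    affine: np.ndarray
    tr: float
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("scan must be 4D")


def acompcor(scan: np.ndarray, tissue_mask: np.ndarray, n_components: int = 5,
             erode: bool = True) -> np.ndarray:
    """Principal-component nuisance time series from a tissue mask.

    The mask is eroded by one voxel (6-connectivity) to guard against
    partial-volume contamination at tissue borders; the voxel×time matrix
    is demeaned per voxel and decomposed by SVD. Returns a T×n matrix of
    unit-variance component series ordered by explained variance.
    """
    scan = np.asarray(scan, dtype=float)
    mask = np.asarray(tissue_mask).astype(bool)
    if erode:
        eroded = ndimage.binary_erosion(mask)
        if not eroded.any():
            raise ValueError(
                "one-voxel erosion emptied the tissue mask; pass erode=False "
                "for very small masks")
        mask = eroded
    if not mask.any():
        raise ValueError("empty tissue mask")
    X = scan[mask]                       # voxels × T
    X = X - X.mean(axis=1, keepdims=True)
    # right singular vectors are the component time series
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if n_components > rank:
        raise ValueError(
            f"requested {n_components} components but masked data has rank "
            f"{rank}")
    comps = vt[:n_components].T          # T × n
    sd = comps.std(axis=0, ddof=0)
    return comps / sd


def backward_differences(x: np.ndarray) -> np.ndarray:
    """First-order backward differences with the first row set to 0."""
    d = np.zeros_like(np.asarray(x, dtype=float))
    d[1:] = np.diff(np.asarray(x, dtype=float), axis=0)
    return d


def build_confounds(motion: np.ndarray | pd.DataFrame,
                    acompcor_wm: np.ndarray, acompcor_csf: np.ndarray,
                    tr: float) -> ConfoundMatrix:
    """Assemble the 22-column confound matrix.

    5 WM + 5 CSF aCompCor components, 6 motion parameters and their 6
    backward-difference derivatives.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must be T×6")
    wm = np.asarray(acompcor_wm, dtype=float)
    csf = np.asarray(acompcor_csf, dtype=float)
    T = motion.shape[0]
    if wm.shape[0] != T or csf.shape[0] != T:
        raise ValueError("confound row counts differ")
    deriv = backward_differences(motion)
    values = np.column_stack([wm, csf, motion, deriv])
    columns = ([f"acompcor_wm_{i}" for i in range(wm.shape[1])]
               + [f"acompcor_csf_{i}" for i in range(csf.shape[1])]
               + [f"motion_{i}" for i in range(6)]
               + [f"motion_deriv_{i}" for i in range(6)])
    return ConfoundMatrix(values=values, columns=columns, tr=tr)


def regress_confounds(data: np.ndarray, confounds: np.ndarray,
                      add_trend: bool = True) -> np.ndarray:
    """Residualize time series (T×V) against confounds + intercept (+ trend).

    All regressors enter one simultaneous least-squares model, so no
    confound variance is reintroduced by later steps.
    """
    T = data.shape[0]
    cols = [np.ones(T)]
    if add_trend:
        cols.append(np.linspace(-1.0, 1.0, T))
    if confounds is not None and confounds.size:
        cols.append(np.asarray(confounds, dtype=float))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, data, rcond=None)
    return data - X @ beta


def bandpass_filter(data: np.ndarray, tr: float,
                    band: tuple[float, float] = DEFAULT_BAND,
                    design: str = "fft", order: int = 4) -> np.ndarray:
    """Zero-phase band-pass along axis 0 of a T×V array.

    ``design='fft'`` (default) zeroes all DFT bins outside [low, high]:
    exactly unit gain in band, zero out of band, no phase distortion.
    ``design='butter'`` applies a forward-backward Butterworth instead.
    """
    low, high = band
    fs = 1.0 / tr
    nyq = fs / 2.0
    if not (0.0 < low < high):
        raise ValueError("band must satisfy 0 < low < high")
    if high >= nyq:
        raise ValueError(f"band high {high} Hz ≥ Nyquist {nyq:.4f} Hz")
    data = np.asarray(data, dtype=float)
    if design == "fft":
        T = data.shape[0]
        freqs = np.fft.rfftfreq(T, d=tr)
        keep = (freqs >= low) & (freqs <= high)
        spec = np.fft.rfft(data, axis=0)
        spec[~keep] = 0.0
        return np.fft.irfft(spec, n=T, axis=0)
    if design == "butter":
        sos = signal.butter(order, [low, high], btype="band", fs=fs,
                            output="sos")
        return signal.sosfiltfilt(sos, data, axis=0)
    raise ValueError(f"unknown filter design '{design}'")


def despike(data: np.ndarray, k: float = DEFAULT_DESPIKE_K,
            window: int = DESPIKE_MEDIAN_WINDOW) -> np.ndarray:
    """Squash excursions beyond k·MAD toward the running median.

    Samples within k·MAD of the running median pass unchanged; samples
    beyond it are mapped through a hyperbolic tangent so that
    |sample − median| ≤ k·MAD everywhere afterwards.
    """
    data = np.asarray(data, dtype=float)
    squeeze = data.ndim == 1
    if squeeze:
        data = data[:, None]
    run_med = signal.medfilt(data, kernel_size=(window, 1))
    resid = data - run_med
    mad = np.median(np.abs(resid), axis=0, keepdims=True) * 1.4826
    mad = np.where(mad > 0, mad, np.inf)   # flat series: nothing to squash
    scale = k * mad
    z = resid / scale
    finite_scale = np.where(np.isfinite(scale), scale, 1.0)
    out = run_med + np.where(np.abs(z) > 1.0,
                             finite_scale * np.tanh(z), resid)
    return out[:, 0] if squeeze else out


def denoise_pipeline(scan: np.ndarray, affine: np.ndarray,
                     confounds: ConfoundMatrix,
                     band: tuple[float, float] = DEFAULT_BAND,
                     despike_k: float = DEFAULT_DESPIKE_K,
                     filter_design: str = "fft",
                     valid_mask: np.ndarray | None = None) -> DenoisedScan:
    """Run the full denoising chain on a 4D scan.

    Confound regression (simultaneous with intercept and linear trend),
    zero-phase band-pass, despiking, a final trend projection, and mean
    restoration, applied to every voxel in ``valid_mask`` (default: voxels
    with nonzero temporal variance).
    """
    scan = np.asarray(scan, dtype=float)
    if scan.ndim != 4:
        raise ValueError("scan must be 4D")
    T = scan.shape[3]
    if confounds.values.shape[0] != T:
        raise ValueError("confound rows do not match scan timepoints")
    if valid_mask is None:
        valid_mask = np.var(scan, axis=3) > 0
    valid_mask = np.asarray(valid_mask).astype(bool)

    Y = scan[valid_mask].T                       # T × V
    means = Y.mean(axis=0, keepdims=True)
    resid = regress_confounds(Y, confounds.values, add_trend=True)
    filtered = bandpass_filter(resid, confounds.tr, band=band,
                               design=filter_design)
    squashed = despike(filtered, k=despike_k)
    # guarantee a trend-free output: despiking/filtering can leave a tiny slope
    trend = np.linspace(-1.0, 1.0, T)[:, None]
    trend /= np.linalg.norm(trend)
    cleaned = squashed - squashed.mean(axis=0, keepdims=True)
    cleaned -= trend @ (trend.T @ cleaned)
    cleaned += means

    out = np.zeros_like(scan)
    out[valid_mask] = cleaned.T
    return DenoisedScan(data=out, affine=np.asarray(affine, dtype=float),
                        tr=confounds.tr, valid_mask=valid_mask)
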