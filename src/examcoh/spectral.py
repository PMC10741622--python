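"""Kaiser-windowed FFT spectral estimators on 1-second epochs.

Power spectral density and magnitude-squared coherence are estimated by
averaging over the retained (artifact-free) 1-s epochs of a task
segment — a Welch-style scheme with non-overlapping segments.  With
256-sample epochs at 256 Hz the frequency resolution is exactly 1 Hz,
so band aggregation is a plain mean over integer-frequency bins.

The magnitude-squared coherence between channels x and y is

    gamma2_xy(f) = |sum_k X_k(f) conj(Y_k(f))|^2
                   / (sum_k |X_k(f)|^2 * sum_k |Y_k(f)|^2)

with the sums over the K retained epochs.  For independent signals the
estimator has the well-known positive bias E[gamma2] ~= 1/K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import kaiser

from .montage import CHANNELS, pair_name
from .preprocess import EpochSet

#: Kaiser shape parameter: beta = 8 gives ~ -58 dB sidelobes, suppressing
#: spectral leakage between bands at 1 Hz resolution.
DEFAULT_KAISER_BETA = 8.0


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band, inclusive on both edges, in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi <= 45:
            raise ValueError(
                f"band {self.name}: need 0 < lo < hi <= 45 (hardware passband), "
                f"got [{self.lo}, {self.hi}]")

    def bins(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean selector of frequency bins with lo <= f <= hi."""
        return (freqs >= self.lo - 1e-9) & (freqs <= self.hi + 1e-9)


#: Conventional clinical bands.  Gamma is ">30 Hz", i.e. the first 1-Hz
#: bin above the beta band, capped at the headset's 45 Hz passband edge.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1, 3),
    BandDefinition("theta", 4, 7),
    BandDefinition("alpha", 8, 12),
    BandDefinition("beta", 13, 30),
    BandDefinition("gamma", 31, 45),
)

#: Delta is computed but left out of default group reports.
DEFAULT_REPORT_BANDS: tuple[str, ...] = ("theta", "alpha", "beta", "gamma")


def band_by_name(name: str,
                 bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}")


def _windowed_spectra(epochs: EpochSet, kaiser_beta: float):
    """rFFT of demeaned, Kaiser-windowed retained epochs.

    Returns ``(freqs, X, U)`` with X of shape (n_retained, n_channels,
    n_freqs) and U = sum(w^2) the window power normalization.
    """
    x = epochs.retained()
    if x.shape[0] == 0:
        raise ValueError(
            f"no retained epochs for participant "
            f"{epochs.participant or '<unknown>'}, task {epochs.task or '<unknown>'}")
    n = x.shape[2]
    w = kaiser(n, kaiser_beta).astype(x.dtype)
    x = x - x.mean(axis=2, keepdims=True)
    X = np.fft.rfft(x * w, axis=2)
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.sampling_rate)
    return freqs, X, float(np.sum(w ** 2))


def _psd_from_spectra(X: np.ndarray, U: float, fs: float,
                      n_samples: int) -> np.ndarray:
    p = (np.abs(X) ** 2).mean(axis=0).astype(np.float64) * (2.0 / (fs * U))
    p[:, 0] /= 2.0
    if n_samples % 2 == 0:
        p[:, -1] /= 2.0  # Nyquist bin is not duplicated
    return p


def psd_epochs(epochs: EpochSet,
               kaiser_beta: float = DEFAULT_KAISER_BETA
               ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD per channel, averaged over retained epochs.

    Returns ``(freqs, psd)`` with psd in µV²/Hz of shape
    (n_channels, n_freqs); for 1-s epochs at 256 Hz the frequency axis is
    0..128 Hz at 1 Hz spacing.  The estimate is window-power corrected so
    that the integral of the PSD equals the (windowed) signal variance
    (Parseval).
    """
    freqs, X, U = _windowed_spectra(epochs, kaiser_beta)
    return freqs, _psd_from_spectra(X, U, epochs.sampling_rate,
                                    epochs.epochs.shape[2])


def band_power(psd: np.ndarray, freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Mean PSD over the band's bins, one value per channel."""
    sel = band.bins(freqs)
    if not sel.any():
        raise ValueError(f"band {band.name} [{band.lo}, {band.hi}] Hz has no "
                         "bins on the frequency axis")
    return psd[..., sel].mean(axis=-1)


def coherence_matrix(epochs: EpochSet,
                     kaiser_beta: float = DEFAULT_KAISER_BETA
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Full magnitude-squared coherence, shape (n_ch, n_ch, n_freqs).

    Requires at least two retained epochs (a single segment gives
    identically 1).  The matrix is symmetric with unit diagonal and all
    values in [0, 1].
    """
    if epochs.n_retained < 2:
        raise ValueError("coherence needs >=2 retained epochs "
                         f"(got {epochs.n_retained})")
    freqs, X, _ = _windowed_spectra(epochs, kaiser_beta)
    return freqs, _coherence_from_spectra(X)


def _coherence_from_spectra(X: np.ndarray) -> np.ndarray:
    # Cross-spectral matrix summed over epochs: S[i, j, f] = sum_k X_ki conj(X_kj)
    Xf = np.moveaxis(X, 2, 0)                       # (n_freq, n_ep, n_ch)
    S = np.swapaxes(Xf, 1, 2) @ np.conj(Xf)         # (n_freq, n_ch, n_ch)
    S = np.moveaxis(S, 0, 2).astype(np.complex128)  # (n_ch, n_ch, n_freq)
    auto = np.real(np.einsum("iif->if", S))
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(S) ** 2 / denom
    coh[~np.isfinite(coh)] = 0.0
    return np.clip(coh, 0.0, 1.0)


def coherence_pairs(epochs: EpochSet,
                    kaiser_beta: float = DEFAULT_KAISER_BETA,
                    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS):
    """Band-averaged coherence for all 91 channel pairs.

    Returns a pandas DataFrame indexed by canonical pair name
    (e.g. ``"FC5-FC6"``) with one column per band; every value is the
    unweighted mean of in-band coherence bins and lies in [0, 1].
    """
    import pandas as pd

    labels = CHANNELS if epochs.epochs.shape[1] == len(CHANNELS) else None
    if labels is None:
        raise ValueError("coherence_pairs expects the 14-channel montage "
                         f"(got {epochs.epochs.shape[1]} channels)")
    freqs, coh = coherence_matrix(epochs, kaiser_beta)
    iu = np.triu_indices(len(labels), k=1)
    names = [pair_name(labels[i], labels[j]) for i, j in zip(*iu)]
    data = {}
    for band in bands:
        sel = band.bins(freqs)
        if not sel.any():
            raise ValueError(f"band {band.name} has no bins")
        band_coh = coh[:, :, sel].mean(axis=2)
        data[band.name] = band_coh[iu]
    return pd.DataFrame(data, index=pd.Index(names, name="pair"))
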