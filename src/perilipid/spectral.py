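"""Triglyceride spectral model for chemical-shift-encoded imaging at 3 T.

The fat signal is modelled as a sum of nine spectral peaks whose relative
amplitudes follow from proton bookkeeping on a triglyceride with mean chain
length ``CL``, ``ndb`` double bonds per molecule and ``nmidb``
methylene-interrupted (diallylic) double bonds per molecule.  Peak positions
are the standard in vivo assignments (ppm, water at 4.70 ppm), converted to
frequency offsets with 1 ppm = 127.74 Hz at 3 T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriglycerideSpectrum",
    "fat_peak_amplitudes",
    "fat_modulation",
    "signal_model",
    "PEAK_PPM",
    "WATER_PPM",
    "HZ_PER_PPM_3T",
    "NMIDB_COEFF",
]

#: Chemical shifts of the nine triglyceride peaks (ppm).
PEAK_PPM = np.array([0.90, 1.30, 1.60, 2.02, 2.24, 2.75, 4.20, 5.19, 5.29])
PEAK_NAMES = (
    "methyl",
    "methylene",
    "beta-carboxyl",
    "alpha-olefinic",
    "alpha-carboxyl",
    "diallylic",
    "glycerol-CH2",
    "glycerol-CH",
    "olefinic",
)
WATER_PPM = 4.70
HZ_PER_PPM_3T = 127.74

#: Empirical triglyceride relation nmidb = 0.093 * ndb**2 used when nmidb is
#: not fitted as a free parameter.
NMIDB_COEFF = 0.093

# indices into PEAK_PPM for the composition-sensitive peaks
_IDX_METHYLENE = 1
_IDX_ALPHA_OLEFINIC = 3
_IDX_DIALLYLIC = 5
_IDX_OLEFINIC = 8


def fat_peak_amplitudes(cl: float, ndb, nmidb) -> np.ndarray:
    """Normalised amplitudes of the nine fat peaks.

    Proton counts per triglyceride molecule:

    ========  ====================  =======================
    ppm       assignment            protons
    ========  ====================  =======================
    0.90      methyl                9
    1.30      methylene             6(CL-4) - 8 ndb + 2 nmidb
    1.60      beta-carboxyl CH2     6
    2.02      alpha-olefinic CH2    4 (ndb - nmidb)
    2.24      alpha-carboxyl CH2    6
    2.75      diallylic CH2         2 nmidb
    4.20      glycerol CH2          4
    5.19      glycerol CH           1
    5.29      olefinic CH=CH        2 ndb
    ========  ====================  =======================

    Amplitudes are the proton counts divided by their total
    (6 CL + 2 - 2 ndb), so they sum to one.

    Parameters
    ----------
    cl : float
        Mean fatty-acid chain length (carbons per chain); must exceed 2.
    ndb, nmidb : float or ndarray
        Double bonds and methylene-interrupted double bonds per molecule.
        Broadcast against each other; the peak axis is appended last.

    Returns
    -------
    ndarray of shape ``broadcast(ndb, nmidb).shape + (9,)``
    """
    if cl <= 2:
        raise ValueError(f"chain length must exceed 2, got {cl}")
    ndb = np.asarray(ndb, dtype=float)
    nmidb = np.asarray(nmidb, dtype=float)
    if np.any(ndb < 0):
        raise ValueError("ndb must be non-negative")
    if np.any(nmidb < 0):
        raise ValueError("nmidb must be non-negative")
    ndb, nmidb = np.broadcast_arrays(ndb, nmidb)
    shape = ndb.shape
    protons = np.empty(shape + (9,), dtype=float)
    protons[..., 0] = 9.0
    protons[..., _IDX_METHYLENE] = 6.0 * (cl - 4.0) - 8.0 * ndb + 2.0 * nmidb
    protons[..., 2] = 6.0
    protons[..., _IDX_ALPHA_OLEFINIC] = 4.0 * (ndb - nmidb)
    protons[..., 4] = 6.0
    protons[..., _IDX_DIALLYLIC] = 2.0 * nmidb
    protons[..., 6] = 4.0
    protons[..., 7] = 1.0
    protons[..., _IDX_OLEFINIC] = 2.0 * ndb
    for idx, name in ((_IDX_METHYLENE, PEAK_NAMES[_IDX_METHYLENE]),
                      (_IDX_ALPHA_OLEFINIC, PEAK_NAMES[_IDX_ALPHA_OLEFINIC])):
        if np.any(protons[..., idx] < 0):
            raise ValueError(
                f"(CL={cl}, ndb, nmidb) yields a negative amplitude at the "
                f"{name} peak"
            )
    total = 6.0 * cl + 2.0 - 2.0 * ndb
    return protons / total[..., None]


@dataclass(frozen=True)
class TriglycerideSpectrum:
    """Fat spectral model: peak offsets plus the amplitude rule.

    Attributes
    ----------
    cl : mean chain length, fixed (weakly identifiable at 16 echoes).
    hz_per_ppm : field-strength scaling; 127.74 Hz/ppm at 3 T.
    peak_ppm : peak positions in ppm.
    water_ppm : water reference (amplitude convention: water offset 0 Hz).
    """

    cl: float = 17.5
    hz_per_ppm: float = HZ_PER_PPM_3T
    peak_ppm: np.ndarray = field(default_factory=lambda: PEAK_PPM.copy())
    water_ppm: float = WATER_PPM

    @property
    def peak_offsets_hz(self) -> np.ndarray:
        """Fat peak frequency offsets relative to water (Hz)."""
        return (np.asarray(self.peak_ppm) - self.water_ppm) * self.hz_per_ppm

    def amplitudes(self, ndb, nmidb) -> np.ndarray:
        return fat_peak_amplitudes(self.cl, ndb, nmidb)


def fat_modulation(spectrum: TriglycerideSpectrum, echo_times_ms, ndb, nmidb):
    """Complex fat modulation c(TE) = sum_m alpha_m exp(i 2 pi f_m TE).

    ``echo_times_ms`` has shape (n_echoes,); ``ndb``/``nmidb`` broadcast.
    Returns an array of shape ``broadcast(ndb, nmidb).shape + (n_echoes,)``.
    """
    te_s = np.asarray(echo_times_ms, dtype=float) * 1e-3
    alpha = spectrum.amplitudes(ndb, nmidb)  # (..., 9)
    phases = np.exp(2j * np.pi * np.outer(te_s, spectrum.peak_offsets_hz))  # (E, 9)
    return alpha @ phases.T  # (..., E)


def signal_model(w, f, ndb, nmidb, psi_hz, r2star, echo_times_ms,
                 spectrum: TriglycerideSpectrum):
    """Forward CSE signal for one voxel (or broadcast stack of voxels).

    s(TE) = [W + F c(TE)] exp(i 2 pi psi TE) exp(-R2* TE)

    with TE in seconds internally (inputs in ms), psi in Hz, R2* in 1/s.
    """
    te_s = np.asarray(echo_times_ms, dtype=float) * 1e-3
    c = fat_modulation(spectrum, echo_times_ms, ndb, nmidb)
    w = np.asarray(w, dtype=float)[..., None]
    f = np.asarray(f, dtype=float)[..., None]
    psi = np.asarray(psi_hz, dtype=float)[..., None]
    r2s = np.asarray(r2star, dtype=float)[..., None]
    return (w + f * c) * np.exp((2j * np.pi * psi - r2s) * te_s)
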