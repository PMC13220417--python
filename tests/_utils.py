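"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np

from lfpcoupling.pac import extract_band, surrogate_threshold
from lfpcoupling.spectral import BandSpec

#: narrow theta band around the generator's 8 Hz rhythm
THETA_CELL = BandSpec("theta_cell", 7.5, 8.5)
#: 20 Hz-wide amplitude band around the generator's 75 Hz gamma carrier
GAMMA_CELL = BandSpec("gamma_cell", 65.0, 85.0)


def cell_phase_amp(x: np.ndarray, fs: float,
                   phase_band: BandSpec = THETA_CELL,
                   amp_band: BandSpec = GAMMA_CELL):
    """Interior phase/amplitude series for one comodulogram cell."""
    p = extract_band(x, phase_band, fs)
    a = extract_band(x, amp_band, fs)
    edge = max(p.n_edge, a.n_edge)
    return p.phase[edge:-edge], a.amplitude[edge:-edge]


def cell_mi(x: np.ndarray, fs: float, surrogate_seed: int | None = None):
    """MI (or surrogate-tested MI result) at the theta x gamma carrier cell."""
    ph, am = cell_phase_amp(x, fs)
    if surrogate_seed is None:
        from lfpcoupling.pac import modulation_index

        return modulation_index(ph, am).mi
    return surrogate_threshold(ph, am, seed=surrogate_seed, fs=fs)


def write_edf(path, data: np.ndarray, fs: float, labels: list[str]) -> None:
    """Minimal EDF writer (synthetic fixtures only): 16-bit, 1 s records."""
    ns, n = data.shape
    spr = int(fs)
    nrec = n // spr
    pmin, pmax = -1000.0, 1000.0
    dmin, dmax = -32768, 32767
    pad = lambda vals, w: b"".join(str(v).encode()[:w].ljust(w) for v in vals)
    hdr = b"0".ljust(8)
    hdr += b"synthetic patient".ljust(80)
    hdr += b"synthetic recording".ljust(80)
    hdr += b"01.01.20" + b"00.00.00"
    hdr += str(256 * (ns + 1)).encode().ljust(8)
    hdr += b"".ljust(44)
    hdr += str(nrec).encode().ljust(8)
    hdr += b"1".ljust(8)
    hdr += str(ns).encode().ljust(4)
    hdr += pad(labels, 16)
    hdr += pad([""] * ns, 80)
    hdr += pad(["uV"] * ns, 8)
    hdr += pad(["%g" % pmin] * ns, 8) + pad(["%g" % pmax] * ns, 8)
    hdr += pad([dmin] * ns, 8) + pad([dmax] * ns, 8)
    hdr += pad([""] * ns, 80)
    hdr += pad([spr] * ns, 8)
    hdr += pad([""] * ns, 32)
    scale = (dmax - dmin) / (pmax - pmin)
    dig = np.clip((data - pmin) * scale + dmin, dmin, dmax).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(nrec):
            for ch in range(ns):
                fh.write(dig[ch, r * spr:(r + 1) * spr].tobytes())
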