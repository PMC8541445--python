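"""Electrode montage and frequency-band definitions shared across the pipeline.

The montage is the 16-channel 10-20 subset used by the P300 brain-computer
interface the recordings come from (central / centro-parietal / parieto-
occipital coverage).  Band limits follow the classical clinical convention
(Delta 0.5-3 Hz, Theta 4-8 Hz, Alpha 9-13 Hz, Beta 14-30 Hz); because the
spectral grid is sampled every 0.75 Hz, bands are made exhaustive over the
grid as half-open intervals with edges midway between the printed limits, so
no grid frequency is left unassigned.
"""

from __future__ import annotations

CHANNELS: tuple[str, ...] = (
    "FZ", "CZ", "PZ", "OZ",
    "C1", "C2", "C3", "C4", "C5", "C6",
    "CP3", "CP4", "P3", "P4", "PO7", "PO8",
)

#: band -> (low, high) in Hz. Low edge inclusive, high edge exclusive except
#: for Beta, whose 30 Hz upper limit is inclusive. Frequencies above 30 Hz
#: are decomposed but assigned to no band.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 3.5),
    "theta": (3.5, 8.5),
    "alpha": (8.5, 13.5),
    "beta": (13.5, 30.0),
}

BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta")

#: carrier frequencies used by the synthetic generator, placed well inside
#: each band's bin range
BAND_CARRIER_HZ: dict[str, float] = {
    "delta": 1.5,
    "theta": 6.0,
    "alpha": 10.0,
    "beta": 20.0,
}

_EPS = 1e-9


def band_of(freq_hz: float) -> str | None:
    """Return the band a grid frequency belongs to, or None if unassigned."""
    for name, (lo, hi) in BANDS.items():
        if name == "beta":
            if lo - _EPS <= freq_hz <= hi + _EPS:
                return name
        elif lo - _EPS <= freq_hz < hi - _EPS:
            return name
    return None


def check_montage(labels) -> None:
    """Raise if *labels* contains duplicates."""
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate channel labels in montage")
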