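"""Canonical EEG frequency-band edges shared by the generator and the feature stage.

The classical attention/engagement indices used throughout this package
(beta/alpha, beta/theta, beta/(alpha+theta)) are defined on these bands.
"""

#: Band edges in Hz, inclusive lower edge, exclusive upper edge.
BAND_EDGES_HZ: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

BAND_ORDER: tuple[str, ...] = ("theta", "alpha", "beta")
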