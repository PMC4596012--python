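"""Physical constants and the canonical channel roster.

Internal canonical units used everywhere in the package:
mV, ms, mM, S/cm2, uF/cm2, um (geometry), pA (injected current),
cm/s (permeability).  Conversions from the printed parameter-table units
happen once, in :mod:`cahomeo.biophysics`.
"""

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)
TEMPERATURE = 308.15  # K (35 C)

#: Canonical ordering of the 12 conductances. Every 12-vector in the
#: package (conductances, mRNAs, time constants) follows this order.
CHANNEL_NAMES = (
    "Leak", "NaF", "KDR", "KA", "KM", "HCN",
    "CaT", "CaR", "CaN", "CaL", "SK", "BK",
)

#: Indices into the canonical roster.
CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNEL_NAMES)}

CALCIUM_CHANNELS = ("CaT", "CaR", "CaN", "CaL")


def thermal_voltage(temperature: float = TEMPERATURE) -> float:
    """RT/F in mV."""
    return 1e3 * GAS_CONSTANT * temperature / FARADAY
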