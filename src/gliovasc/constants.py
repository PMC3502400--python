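"""Physical constants (CODATA 2018) and fixed model temperature."""

R_GAS = 8.314462618  # J mol^-1 K^-1
FARADAY = 96485.33212  # C mol^-1
BODY_TEMP = 310.15  # K (37 degC); the model is isothermal


def rt_over_f(temperature: float = BODY_TEMP) -> float:
    """R*T/F in millivolts."""
    return 1000.0 * R_GAS * temperature / FARADAY
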