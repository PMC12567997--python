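"""Closed-form timing and power calculators for the ring's analog front end.

LED duty-cycling dominates the power budget: the LED only needs to be ON
long enough to cover the ADC sampling window (T_SAMP) plus the TIA settling
time (T_TIASU ≥ 8·R_F·C_F), the LED/PD setup delays and a damping margin.
At a 100 Hz per-LED firing rate a 70 μs ON time gives a 0.7% duty cycle.
The TIA compensation capacitor C_F trades stability against bandwidth; the
module-current summary converts a battery capacity into expected lifetime.

All calculators are pure closed-form arithmetic (SI units unless a name
says otherwise) so they evaluate exactly and instantly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

__all__ = [
    "TimingBudget",
    "TIAConfig",
    "CurrentBudget",
    "duty_cycle",
    "led_on_budget",
    "tia_settling_min",
    "tia_comp_cap",
    "effective_bandwidth",
    "current_budget",
]

log = logging.getLogger(__name__)


def duty_cycle(led_on_us: float, fire_rate_hz: float) -> float:
    """LED duty cycle (fraction): ON time [μs] × firing rate [Hz]."""
    if led_on_us < 0 or fire_rate_hz < 0:
        raise ValueError("inputs must be non-negative")
    return led_on_us * 1e-6 * fire_rate_hz


def led_on_budget(
    t_samp_us: float, t_tiasu_us: float, t_ledsu_pdsu_us: float, margin_us: float
) -> float:
    """LED ON time [μs]: ADC sampling + TIA settling + LED/PD setup + margin."""
    parts = (t_samp_us, t_tiasu_us, t_ledsu_pdsu_us, margin_us)
    if any(p < 0 for p in parts):
        raise ValueError("time components must be non-negative")
    return float(sum(parts))


def tia_settling_min(r_f: float, c_f: float, multiple: float = 8.0) -> float:
    """Minimum TIA settling time [s] = multiple × R_F·C_F (multiple=1 gives τ)."""
    if r_f <= 0 or c_f <= 0 or multiple <= 0:
        raise ValueError("inputs must be positive")
    return multiple * r_f * c_f


def tia_comp_cap(c_i: float, r_f: float, ugb: float, mode: str = "stability") -> float:
    """TIA compensation capacitance [F] from input capacitance, R_F and UGB.

    mode='stability' (default): C_F = sqrt(C_i / (2π·R_F·UGB)), the
    dimensionally consistent pole-matching form that lands in the pF range
    for typical photodiode front ends.  mode='literal': C_F =
    C_i / (2π·R_F·UGB), the formula exactly as printed in the design
    reference — dimensionally inconsistent (yields ~1e-24 F) and kept only
    for fidelity; selecting it logs a note.
    """
    if c_i <= 0 or r_f <= 0 or ugb <= 0:
        raise ValueError("inputs must be positive")
    if mode == "literal":
        log.info(
            "tia_comp_cap literal mode: formula as printed is dimensionally "
            "inconsistent; value will not be a physical capacitance"
        )
        return c_i / (2.0 * math.pi * r_f * ugb)
    if mode == "stability":
        return math.sqrt(c_i / (2.0 * math.pi * r_f * ugb))
    raise ValueError("mode must be 'literal' or 'stability'")


def effective_bandwidth(f_rc_hz: float, f_sp_adc_hz: float, t_samp_s: float) -> float:
    """Effective signal-chain bandwidth [Hz] = f_RC × f_SP(ADC) × T_SAMP."""
    if f_rc_hz < 0 or f_sp_adc_hz < 0 or t_samp_s < 0:
        raise ValueError("inputs must be non-negative")
    return f_rc_hz * f_sp_adc_hz * t_samp_s


@dataclass(frozen=True)
class TimingBudget:
    """Resolved acquisition timing for one LED channel.

    Times in μs, frequencies in Hz.  ``f_sp_sys`` is the per-LED system
    sampling rate (100 Hz class), ``f_sp_adc`` the much faster ADC rate used
    within each ON window.
    """

    t_samp_us: float = 30.0
    t_tiasu_us: float = 20.0
    t_ledsu_pdsu_us: float = 10.0
    margin_us: float = 10.0
    f_sp_sys_hz: float = 100.0
    f_sp_adc_hz: float = 2500.0
    f_rc_hz: float = 100.0

    @property
    def led_on_us(self) -> float:
        return led_on_budget(
            self.t_samp_us, self.t_tiasu_us, self.t_ledsu_pdsu_us, self.margin_us
        )

    @property
    def duty_cycle(self) -> float:
        return duty_cycle(self.led_on_us, self.f_sp_sys_hz)

    @property
    def f_sig_eff_hz(self) -> float:
        return effective_bandwidth(self.f_rc_hz, self.f_sp_adc_hz, self.t_samp_us * 1e-6)


@dataclass(frozen=True)
class TIAConfig:
    """Transimpedance front-end values (SI units)."""

    r_f: float = 1e6
    c_f: float = 2.5e-12
    c_i: float = 20e-12
    ugb: float = 1e6

    @property
    def time_constant(self) -> float:
        return self.r_f * self.c_f

    @property
    def settling_min(self) -> float:
        return tia_settling_min(self.r_f, self.c_f, 8.0)

    def comp_cap(self, mode: str = "stability") -> float:
        return tia_comp_cap(self.c_i, self.r_f, self.ugb, mode=mode)


@dataclass(frozen=True)
class CurrentBudget:
    """Module current sum [μA] and battery lifetime [h]."""

    modules: dict
    battery_mah: float

    @property
    def total_ua(self) -> float:
        return float(sum(self.modules.values()))

    @property
    def lifetime_h(self) -> float:
        return self.battery_mah / (self.total_ua / 1000.0)


def current_budget(modules: dict, battery_mah: float) -> CurrentBudget:
    """Sum named module currents [μA] and derive battery life [h]."""
    if any(v < 0 for v in modules.values()):
        raise ValueError("module currents must be non-negative")
    if battery_mah <= 0:
        raise ValueError("battery capacity must be positive")
    if not modules or sum(modules.values()) == 0:
        raise ValueError("at least one non-zero module current is required")
    return CurrentBudget(modules=dict(modules), battery_mah=battery_mah)
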