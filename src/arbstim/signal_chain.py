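"""Behavioral model of the analog drive chain.

One channel's analog path is: a 12-bit DAC acting as a zero-order hold, a
first-order RC reconstruction filter (-3 dB near 33 kHz), a subtracting
amplifier that maps the unipolar DAC range onto a symmetric bipolar one, a
unity-gain isolation stage, a modified Howland voltage-to-current converter
(nominal transconductance 1 mA/V) with hard compliance clipping at the
supply rails, and an analog multiplexer that shorts source and electrode
whenever the trigger line is deasserted.

The model is behavioral, not SPICE-level: op-amps are ideal, the isolation
amplifier is unity gain with zero delay, and the Howland stage is an ideal
transconductor below compliance.  Within the design band (DC to 30 kHz at a
60 kHz sampling rate) these idealizations hold to within the tolerances the
bench characterization of such a chain supports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.signal import lfilter, lfilter_zi

from .protocol import sample_to_dac_code

DAC_LEVELS = 4096


@dataclass(frozen=True)
class AnalogChainParams:
    """Component values of the analog chain.

    Defaults are the built device's values: a 2.2 kOhm / 2.2 nF reconstruction
    filter (cutoff ~33 kHz), a 1 kOhm subtractor resistor, a Howland stage
    with R1 = 300 kOhm, R2 = 1 kOhm and 3 pF compensation, and +-15 V supply.
    The transconductance is set by the Howland R2: g_m = 1/R2 = 1 mA/V.
    ``c_h`` is retained for documentation; the compensation pole is not
    dynamically modeled.
    """

    v_ref: float = 3.3        # DAC full-scale voltage [V]
    r1_f: float = 2200.0      # reconstruction-filter resistance [ohm]
    c_f: float = 2.2e-9       # reconstruction-filter capacitance [F]
    r2_f: float = 1000.0      # subtractor resistance [ohm]
    r1_h: float = 300_000.0   # Howland R1 [ohm]
    r2_h: float = 1000.0      # Howland R2 (sets transconductance) [ohm]
    c_h: float = 3e-12        # Howland compensation capacitance [F]
    v_s: float = 15.0         # compliance/supply voltage magnitude [V]

    def __post_init__(self) -> None:
        for name in ("v_ref", "r1_f", "c_f", "r2_f", "r1_h", "r2_h", "c_h", "v_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def g_m(self) -> float:
        """Nominal transconductance of the Howland stage [A/V]."""
        return 1.0 / self.r2_h

    @property
    def tau(self) -> float:
        """Reconstruction-filter time constant R1*C [s]."""
        return self.r1_f * self.c_f

    @property
    def f_cutoff(self) -> float:
        """-3 dB frequency of the reconstruction filter [Hz]."""
        return 1.0 / (2.0 * np.pi * self.tau)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalogChainParams":
        """Load component values from a YAML mapping of field names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass(frozen=True)
class LoadModel:
    """Electrode-tissue load: pure resistance or a series RC.

    A series RC is the simplest lumped approximation of an electrode's
    access resistance plus interfacial capacitance; full constant-phase
    electrode models are out of scope.
    """

    r_load: float
    c_load: float | None = None

    def __post_init__(self) -> None:
        if self.r_load <= 0:
            raise ValueError("r_load must be positive")
        if self.c_load is not None and self.c_load <= 0:
            raise ValueError("c_load must be positive when given")

    @property
    def kind(self) -> str:
        return "resistive" if self.c_load is None else "series-RC"


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled time series (voltage in volts or current in amps)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def to_csv(self, path: str | Path) -> None:
        """Write the trace as two-column CSV (time, value)."""
        np.savetxt(path, np.column_stack([self.times, self.values]),
                   delimiter=",", fmt="%.9g")


def dac_output(codes: Sequence[int], fs: float, v_ref: float = 3.3,
               oversample: int = 32) -> Trace:
    """Zero-order-hold DAC output for a sequence of unipolar 12-bit codes.

    Each code is held at ``v_ref * code / 4096`` volts for one sampling
    period, rendered on a grid ``oversample`` times denser than ``fs``.
    """
    codes = np.asarray(codes, dtype=float)
    if codes.size == 0:
        return Trace(np.empty(0), np.empty(0))
    if codes.min() < 0 or codes.max() > DAC_LEVELS - 1:
        raise ValueError("DAC codes must lie in 0..4095")
    if oversample < 8:
        raise ValueError("oversample must be >= 8 for a usable staircase")
    values = np.repeat(v_ref * codes / DAC_LEVELS, oversample)
    times = np.arange(values.size) / (fs * oversample)
    return Trace(times, values)


def reconstruction_filter(trace: Trace, params: AnalogChainParams) -> Trace:
    """First-order RC low-pass, DC gain 1, time constant ``r1_f * c_f``.

    Discretized exactly for piecewise-constant input (matched exponential
    step response): y[n] = a*y[n-1] + (1-a)*x[n] with a = exp(-dt/tau).
    The filter state starts settled at the first input value, so a constant
    input passes through unchanged.
    """
    if len(trace.values) == 0:
        return trace
    a = np.exp(-trace.dt / params.tau)
    b, den = [1.0 - a], [1.0, -a]
    zi = lfilter_zi(b, den) * trace.values[0]
    y, _ = lfilter(b, den, trace.values, zi=zi)
    return Trace(trace.times, y)


def recenter(trace: Trace, params: AnalogChainParams) -> Trace:
    """Subtractor stage: affine map V -> 2V - v_ref.

    Sends the unipolar DAC range [0, v_ref] onto the symmetric
    [-v_ref, +v_ref], so the DAC midscale corresponds to 0 V.
    """
    return Trace(trace.times, 2.0 * trace.values - params.v_ref)


def frequency_response(f: float | np.ndarray,
                       params: AnalogChainParams) -> complex | np.ndarray:
    """Analytic complex gain of the reconstruction filter: 1/(1 + j*2*pi*f*tau)."""
    return 1.0 / (1.0 + 1j * 2.0 * np.pi * np.asarray(f) * params.tau)


def _ideal_load_voltage(current: np.ndarray, load: LoadModel, dt: float) -> np.ndarray:
    """Load voltage developed by a given current, before compliance limits."""
    v = current * load.r_load
    if load.c_load is not None:
        # series capacitor integrates the delivered charge
        charge = np.concatenate([[0.0], np.cumsum(
            0.5 * (current[1:] + current[:-1]) * dt)])
        v = v + charge / load.c_load
    return v


def howland_drive(v_in: Trace, load: LoadModel,
                  params: AnalogChainParams) -> tuple[Trace, Trace]:
    """Voltage-to-current conversion with hard compliance clipping.

    Below compliance the stage is an ideal transconductor,
    ``I = g_m * V_in``.  Wherever the load voltage the ideal current would
    develop exceeds the supply magnitude ``v_s``, the output saturates: the
    load voltage pins at ``+-v_s`` and the delivered current scales down by
    ``v_s / |V_ideal|`` at that instant.

    Returns ``(current_trace, load_voltage_trace)``.
    """
    i_ideal = params.g_m * v_in.values
    v_ideal = _ideal_load_voltage(i_ideal, load, v_in.dt)
    over = np.abs(v_ideal) > params.v_s
    i_out = i_ideal.copy()
    v_out = v_ideal.copy()
    if np.any(over):
        scale = params.v_s / np.abs(v_ideal[over])
        v_out[over] = np.sign(v_ideal[over]) * params.v_s
        i_out[over] = i_ideal[over] * scale
    return Trace(v_in.times, i_out), Trace(v_in.times, v_out)


def mux_gate(current: Trace, trigger: np.ndarray) -> Trace:
    """Analog-multiplexer shorting: current passes only while the trigger is on.

    With the trigger deasserted both the source and the electrode are
    shorted, so the delivered current is exactly zero there.
    """
    trigger = np.asarray(trigger, dtype=bool)
    if trigger.shape != current.values.shape:
        raise ValueError("trigger trace must align with the current trace")
    return Trace(current.times, np.where(trigger, current.values, 0.0))


def simulate_chain(samples: Sequence[int], fs: float, load: LoadModel,
                   params: AnalogChainParams | None = None,
                   oversample: int = 32,
                   trigger: np.ndarray | None = None) -> tuple[Trace, Trace]:
    """Run signed samples through the full analog chain.

    Composition: offset-binary DAC codes -> zero-order hold -> RC
    reconstruction filter -> recentering subtractor -> unity-gain isolation ->
    Howland transconductor with compliance clipping -> trigger-gated mux.
    By default the trigger is asserted for the whole playback window.

    Returns ``(delivered_current, load_voltage)``.
    """
    if params is None:
        params = AnalogChainParams()
    codes = [sample_to_dac_code(int(s)) for s in samples]
    staircase = dac_output(codes, fs, v_ref=params.v_ref, oversample=oversample)
    filtered = reconstruction_filter(staircase, params)
    centered = recenter(filtered, params)
    # isolation amplifier: unity gain, zero delay
    current, v_load = howland_drive(centered, load, params)
    if trigger is None:
        trigger = np.ones(len(current.values), dtype=bool)
    gated = mux_gate(current, trigger)
    v_load = Trace(v_load.times, np.where(np.asarray(trigger, bool),
                                          v_load.values, 0.0))
    return gated, v_load
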