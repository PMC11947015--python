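"""Stimulus design: generation, quantization, validation and CSV I/O.

Waveforms are designed as normalized floating-point signals in [-1, 1] and
then quantized to the device's signed 12-bit sample range [-2048, 2047].
The stimulus file dialect is one integer per line, no header.

Charge balance matters because net charge left at the electrode drives
irreversible electrochemistry; :func:`check_charge_balance` reports the net
charge of a stimulus relative to the total charge it moves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import chirp as _scipy_chirp

from .emulator import CAPACITY, FREQ_TABLE
from .errors import (
    AliasingError,
    CapacityError,
    CsvFormatError,
    NormalizationError,
    ResolutionError,
    SampleRangeError,
)
from .protocol import SAMPLE_MAX, SAMPLE_MIN

log = logging.getLogger(__name__)

#: Positive full scale used for symmetric quantization.
QUANT_FULL_SCALE = 2047

DEVICE_RATES = tuple(FREQ_TABLE.values())


@dataclass(frozen=True)
class Waveform:
    """Continuous-valued stimulus: normalized amplitudes on a uniform grid."""

    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.size and np.max(np.abs(self.values)) > 1.0 + 1e-12:
            raise NormalizationError("waveform values must lie in [-1, 1]")

    @property
    def duration(self) -> float:
        return self.values.size / self.fs


@dataclass(frozen=True)
class StimulusBuffer:
    """Quantized stimulus: signed 12-bit integers ready for upload."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.int64)
        object.__setattr__(self, "samples", arr)
        if arr.size > CAPACITY:
            raise CapacityError(
                f"stimulus has {arr.size} samples; capacity is {CAPACITY}"
            )
        if arr.size and (arr.min() < SAMPLE_MIN or arr.max() > SAMPLE_MAX):
            raise SampleRangeError(
                f"samples must lie in [{SAMPLE_MIN}, {SAMPLE_MAX}]"
            )

    def __len__(self) -> int:
        return int(self.samples.size)


# ----------------------------------------------------------------------
# generators


def _check_nyquist(f: float, fs: float, what: str) -> None:
    nyq = fs / 2.0
    if f > nyq:
        raise AliasingError(f"{what} {f} Hz exceeds the Nyquist limit {nyq} Hz")
    if f == nyq:
        log.warning("%s %s Hz sits exactly at Nyquist; amplitude is "
                    "phase-dependent", what, f)


def gen_biphasic(amplitude: float, phase_s: float, interphase_s: float,
                 fs: float) -> Waveform:
    """Charge-balanced rectangular biphasic pulse, cathodic phase first.

    Two symmetric phases of ``phase_s`` seconds separated by an interphase
    gap; sub-sample durations round to the nearest whole sample (a phase must
    span at least one sample).  The sample sum is exactly zero.
    """
    if not 0 < abs(amplitude) <= 1.0:
        raise NormalizationError("amplitude must be in (0, 1]")
    n_phase_exact = phase_s * fs
    if n_phase_exact < 1.0:
        raise ResolutionError(
            f"phase {phase_s * 1e6:.3g} us spans {n_phase_exact:.3g} samples "
            f"at fs={fs:.0f} Hz; at least one sample is required"
        )
    n_phase = round(n_phase_exact)
    n_gap_exact = interphase_s * fs
    n_gap = round(n_gap_exact)
    if abs(n_gap - n_gap_exact) > 1e-9:
        log.warning("interphase gap %.3g us rounds to %d sample(s) at "
                    "fs=%.0f Hz", interphase_s * 1e6, n_gap, fs)
    values = np.concatenate([
        np.full(n_phase, -amplitude),
        np.zeros(n_gap),
        np.full(n_phase, +amplitude),
    ])
    return Waveform(fs, values)


def gen_chirp(f0: float, f1: float, duration_s: float, fs: float) -> Waveform:
    """Unit-amplitude linear frequency sweep from ``f0`` to ``f1``.

    Starts at zero phase (sin); the instantaneous frequency is ``f0`` at
    t = 0 and ``f1`` at t = ``duration_s``.
    """
    _check_nyquist(f1, fs, "chirp end frequency")
    _check_nyquist(f0, fs, "chirp start frequency")
    n = round(duration_s * fs)
    t = np.arange(n) / fs
    values = _scipy_chirp(t, f0=f0, t1=duration_s, f1=f1,
                          method="linear", phi=-90)
    return Waveform(fs, values)


def gen_am_sine(carrier_hz: float, env_hz: float, env_peak: float,
                env_offset: float, duration_s: float, fs: float) -> Waveform:
    """Sinusoidal carrier with a rectified-triangular amplitude envelope.

    The envelope is ``env_offset + env_peak * tri(t)`` where ``tri`` is a
    unit-peak triangle at ``env_hz`` starting at its trough, so the envelope
    spans ``[env_offset, env_offset + env_peak]``.
    """
    _check_nyquist(carrier_hz, fs, "carrier frequency")
    if env_offset + env_peak > 1.0 + 1e-12:
        raise NormalizationError(
            f"envelope peak {env_offset + env_peak} exceeds full scale 1.0"
        )
    n = round(duration_s * fs)
    t = np.arange(n) / fs
    frac = (env_hz * t) % 1.0
    tri = 1.0 - np.abs(1.0 - 2.0 * frac)  # 0 -> 1 -> 0 per period
    envelope = env_offset + env_peak * tri
    return Waveform(fs, envelope * np.sin(2.0 * np.pi * carrier_hz * t))


def gen_sine(f_hz: float, vpp_fraction: float, duration_s: float,
             fs: float) -> Waveform:
    """Sinusoid whose peak-to-peak spans ``vpp_fraction`` of full scale."""
    _check_nyquist(f_hz, fs, "sine frequency")
    if not 0 <= vpp_fraction <= 2.0:
        raise NormalizationError("vpp_fraction must be in [0, 2]")
    n = round(duration_s * fs)
    t = np.arange(n) / fs
    return Waveform(fs, (vpp_fraction / 2.0) * np.sin(2.0 * np.pi * f_hz * t))


# ----------------------------------------------------------------------
# quantization


def quantize(w: Waveform) -> StimulusBuffer:
    """Map normalized values to signed 12-bit samples: round(value * 2047).

    Quantization is symmetric (+-2047) so that negating a waveform negates
    its buffer exactly; -2048 remains representable in input files.
    """
    if w.values.size > CAPACITY:
        raise CapacityError(
            f"waveform has {w.values.size} samples; capacity is {CAPACITY}"
        )
    samples = np.clip(np.rint(w.values * QUANT_FULL_SCALE),
                      SAMPLE_MIN, SAMPLE_MAX).astype(np.int64)
    return StimulusBuffer(samples, w.fs)


def dequantize(buf: StimulusBuffer) -> Waveform:
    """Samples back to normalized amplitudes (divide by 2047, clip at -1)."""
    return Waveform(buf.fs, np.clip(buf.samples / QUANT_FULL_SCALE, -1.0, 1.0))


def offset_compensate(w: Waveform, measured_dc: float) -> Waveform:
    """Subtract a measured DC offset from the design, re-clamping to [-1, 1].

    Components downstream of the DAC can introduce small DC levels; rather
    than AC-coupling (which would reshape low-frequency stimuli), the offset
    is removed at sample-generation time.
    """
    if not abs(measured_dc) < 1.0:
        raise NormalizationError("measured_dc must satisfy |dc| < 1")
    return Waveform(w.fs, np.clip(w.values - measured_dc, -1.0, 1.0))


# ----------------------------------------------------------------------
# charge balance


@dataclass(frozen=True)
class ChargeBalanceReport:
    """Net-versus-total charge accounting for a stimulus buffer.

    ``net`` and ``total`` are in sample-seconds (sample units integrated over
    time); ``net_coulombs`` is filled in when chain parameters are supplied,
    using the chain's volts-per-sample-unit and transconductance.
    """

    net: float
    total: float
    passed: bool
    tolerance_fraction: float
    net_coulombs: float | None = None

    @property
    def imbalance(self) -> float:
        """|net| / total; 0 for a perfectly balanced stimulus."""
        return abs(self.net) / self.total if self.total else 0.0


def check_charge_balance(buf: StimulusBuffer, tolerance_fraction: float = 1e-3,
                         params=None) -> ChargeBalanceReport:
    """Check that a stimulus leaves (almost) no net charge at the electrode.

    Passes iff ``|sum(samples)| <= tolerance_fraction * sum(|samples|)``.
    With ``params`` (an ``AnalogChainParams``) the net charge is also
    expressed in coulombs via the chain gain: one sample unit corresponds to
    ``v_ref / 2048`` volts at the converter input, hence
    ``g_m * v_ref / 2048`` amps at the electrode.
    """
    if len(buf) == 0:
        raise ValueError("cannot assess charge balance of an empty stimulus")
    net_sum = float(buf.samples.sum())
    total_sum = float(np.abs(buf.samples).sum())
    net = net_sum / buf.fs
    total = total_sum / buf.fs
    passed = abs(net_sum) <= tolerance_fraction * total_sum
    net_c = None
    if params is not None:
        amps_per_unit = params.g_m * params.v_ref / 2048.0
        net_c = net * amps_per_unit
    return ChargeBalanceReport(net, total, passed, tolerance_fraction, net_c)


# ----------------------------------------------------------------------
# CSV I/O


def csv_write(buf: StimulusBuffer, path: str | Path) -> None:
    """Write a stimulus file: one integer sample per line, no header."""
    with open(path, "w") as fh:
        for s in buf.samples:
            fh.write(f"{int(s)}\n")


def csv_read(path: str | Path, fs: float = 60_000) -> StimulusBuffer:
    """Read a stimulus file, validating every line.

    Each line must hold a single integer in [-2048, 2047]; anything else is
    reported with its 1-based line number.  An empty file is an error.
    """
    samples: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text:
                raise CsvFormatError(f"{path}: line {lineno}: empty line")
            try:
                value = int(text)
            except ValueError:
                raise CsvFormatError(
                    f"{path}: line {lineno}: {text!r} is not an integer"
                ) from None
            if not SAMPLE_MIN <= value <= SAMPLE_MAX:
                raise CsvFormatError(
                    f"{path}: line {lineno}: {value} outside "
                    f"[{SAMPLE_MIN}, {SAMPLE_MAX}]"
                )
            samples.append(value)
    if not samples:
        raise CsvFormatError(f"{path}: file contains no samples")
    return StimulusBuffer(np.array(samples, dtype=np.int64), fs)
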