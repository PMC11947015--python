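"""Analytic design-requirement checks, recomputed from first principles.

These small closed-form functions reproduce the numbers that size the
instrument: reconstruction-filter cutoff, per-channel memory, minimum
sampling rate for a given pulse phase, usable bandwidth, serial-link
throughput, memory capacity and the compliance-voltage bound.
"""

from __future__ import annotations

from .emulator import CAPACITY
from .protocol import UART_BAUD, UART_BITS_PER_BYTE

import math


def rc_cutoff_hz(r_ohm: float = 2200.0, c_farad: float = 2.2e-9) -> float:
    """-3 dB frequency of a first-order RC low-pass: 1 / (2*pi*R*C).

    With the chain's 2.2 kOhm / 2.2 nF this is ~32.9 kHz, i.e. 33 kHz to the
    nearest kilohertz — just above the Nyquist band of the top sampling rate.
    """
    return 1.0 / (2.0 * math.pi * r_ohm * c_farad)


def min_memory_bytes_per_channel(duration_s: float = 0.5, fs: float = 60_000,
                                 bits_per_sample: int = 12) -> float:
    """Memory needed to hold a stimulus: duration * rate * sample width.

    Storing 0.5 s at 60 kHz with 12-bit samples takes 45 000 bytes (45 KB)
    per channel.
    """
    return duration_s * fs * bits_per_sample / 8.0


def min_sampling_rate_hz(phase_s: float = 50e-6) -> float:
    """Minimum rate to reconstruct a rectangular phase: two samples per phase.

    A 50 us phase needs one sample every 25 us, i.e. 40 kHz.
    """
    return 2.0 / phase_s


def reconstruction_bandwidth_hz(fs: float = 60_000) -> float:
    """Nyquist bandwidth of arbitrary waveforms at sampling rate ``fs``."""
    return fs / 2.0


def uart_throughput_bytes_per_s(baud: int = UART_BAUD,
                                bits_per_byte: int = UART_BITS_PER_BYTE) -> float:
    """Payload throughput of the serial link: baud / bits-per-framed-byte.

    1 Mbaud with 8N1 framing moves 100 000 bytes per second.
    """
    return baud / bits_per_byte


def channel_capacity_samples(n_rams: int = 2, words_per_ram: int = 2**14) -> int:
    """Samples one channel can store: two 16 k-word RAM banks = 32 768."""
    return n_rams * words_per_ram


def channel_capacity_bytes(bits_per_sample: int = 12) -> float:
    """Usable bytes of stimulus storage per channel (12 of each 16 bits)."""
    return channel_capacity_samples() * bits_per_sample / 8.0


def max_stimulus_seconds(fs: float = 60_000) -> float:
    """Longest stimulus the memory holds at rate ``fs`` (0.546 s at 60 kHz)."""
    return channel_capacity_samples() / fs


def min_compliance_voltage(i_peak_amp: float = 1e-3,
                           z_load_ohm: float = 15_000.0) -> float:
    """Supply magnitude needed to drive ``i_peak`` through ``z_load``.

    Driving 1 mA through a 15 kOhm electrode requires at least +-15 V.
    """
    return i_peak_amp * z_load_ohm


def upload_seconds(n_samples: int = CAPACITY, baud: int = UART_BAUD) -> float:
    """Modeled line time to upload one channel's stimulus.

    Each sample travels as one 16-bit command word = 2 framed bytes; a full
    32 768-sample channel takes ~0.66 s at 1 Mbaud, under the one-second
    usability budget.
    """
    return n_samples * 2 * UART_BITS_PER_BYTE / baud


def summary() -> dict[str, float]:
    """All requirement numbers at their design-point arguments."""
    return {
        "rc_cutoff_khz": rc_cutoff_hz() / 1e3,
        "min_memory_kbytes_per_channel": min_memory_bytes_per_channel() / 1e3,
        "min_sampling_rate_khz": min_sampling_rate_hz() / 1e3,
        "bandwidth_khz": reconstruction_bandwidth_hz() / 1e3,
        "uart_throughput_kbytes_per_s": uart_throughput_bytes_per_s() / 1e3,
        "channel_capacity_samples": float(channel_capacity_samples()),
        "max_stimulus_seconds": max_stimulus_seconds(),
        "min_compliance_voltage": min_compliance_voltage(),
        "max_upload_seconds_per_channel": upload_seconds(),
    }
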