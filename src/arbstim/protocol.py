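"""Bit-exact codec for the stimulator's 16-bit command words.

Every host<->device transaction is one 16-bit word: the command code in the
4 most significant bits, a 12-bit payload in the rest.  Words travel over the
UART as two bytes, least significant byte first.  Stimulus samples are signed
12-bit integers carried in the payload as two's complement.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Iterator

from .errors import PayloadRangeError, SampleRangeError, TransportError

#: Serial framing used for throughput accounting: 1 start + 8 data + 1 stop.
UART_BAUD = 1_000_000
UART_BITS_PER_BYTE = 10

SAMPLE_MIN = -2048
SAMPLE_MAX = 2047
PAYLOAD_MASK = 0x0FFF


class CommandCode(enum.IntEnum):
    """The 16 command codes understood by the playback state machine."""

    ISDATA0 = 0x0      # store one sample for channel 0 at its write pointer
    ISDATA1 = 0x1      # store one sample for channel 1 at its write pointer
    SET_SIZE_LO = 0x2  # 12 LSB of the stimulus length in samples
    SET_SIZE_HI = 0x3  # 12 MSB of the stimulus length in samples
    SET_FREQ = 0x4     # sampling-frequency index (0/1/2 -> 30/50/60 kHz)
    SET_LOOPED = 0x5   # 0 = play once, 1 = repeat continuously
    START = 0x6        # begin (or resume) playback
    PAUSE = 0x7        # pause playback, keeping the read pointer
    REWIND = 0x8       # read pointer back to sample 0
    WR_REWIND = 0x9    # both write pointers back to sample 0
    UNDEFINED = 0xA    # reserved; accepted and ignored
    DBG_ECHO = 0xB     # device echoes the full received word
    DBG_READ = 0xC     # read one context value selected by the payload
    DBG_DUMP0 = 0xD    # stream back the stored channel-0 stimulus
    DBG_DUMP1 = 0xE    # stream back the stored channel-1 stimulus
    NOP = 0xF          # do nothing


class ReadSelector(enum.IntEnum):
    """DBG_READ payload values and the context field each one selects."""

    SIZE_LO = 0x0
    SIZE_HI = 0x1
    FREQ = 0x2
    CYCLE_COUNT = 0x3
    RUNNING = 0x4
    LOOPED = 0x5
    RD_PTR_LO = 0x6
    RD_PTR_HI = 0x7
    WR_PTR0_LO = 0x8
    WR_PTR0_HI = 0x9
    WR_PTR1_LO = 0xA
    WR_PTR1_HI = 0xB


@dataclass(frozen=True)
class CommandWord:
    """A decoded 16-bit command: 4-bit code plus 12-bit unsigned payload."""

    code: CommandCode
    data: int

    def __post_init__(self) -> None:
        if not 0 <= int(self.code) <= 0xF:
            raise PayloadRangeError(f"command code {self.code!r} not in 0x0..0xF")
        if not 0 <= self.data <= PAYLOAD_MASK:
            raise PayloadRangeError(
                f"payload {self.data} outside the unsigned 12-bit range 0..4095"
            )

    @property
    def word(self) -> int:
        """The full 16-bit value: code * 2**12 + data."""
        return (int(self.code) << 12) | self.data


def encode_command(code: CommandCode | int, data: int = 0) -> tuple[int, int]:
    """Encode a command as its two wire bytes ``(low, high)``.

    The low byte is transmitted first.
    """
    if not 0 <= int(code) <= 0xF:
        raise PayloadRangeError(f"command code {code!r} not in 0x0..0xF")
    word = CommandWord(CommandCode(code), data).word
    return word & 0xFF, word >> 8


def decode_bytes(low: int, high: int) -> CommandWord:
    """Inverse of :func:`encode_command`; every 16-bit word decodes."""
    if not (0 <= low <= 0xFF and 0 <= high <= 0xFF):
        raise PayloadRangeError(f"bytes ({low}, {high}) outside 0..255")
    word = (high << 8) | low
    return CommandWord(CommandCode(word >> 12), word & PAYLOAD_MASK)


def encode_sample(value: int) -> int:
    """Map a signed sample in [-2048, 2047] to its 12-bit two's-complement field."""
    value = int(value)
    if not SAMPLE_MIN <= value <= SAMPLE_MAX:
        raise SampleRangeError(
            f"sample {value} outside the signed 12-bit range "
            f"[{SAMPLE_MIN}, {SAMPLE_MAX}]"
        )
    return value & PAYLOAD_MASK


def decode_sample(field: int) -> int:
    """Inverse of :func:`encode_sample`."""
    if not 0 <= field <= PAYLOAD_MASK:
        raise PayloadRangeError(f"sample field {field} outside 0..4095")
    return field - 4096 if field >= 2048 else field


def sample_to_dac_code(value: int) -> int:
    """Signed sample -> unipolar DAC code (offset binary, midscale = 0).

    The analog subtractor after the DAC re-centers midscale to 0 V, so the
    device maps sample ``s`` to DAC code ``s + 2048``.
    """
    if not SAMPLE_MIN <= value <= SAMPLE_MAX:
        raise SampleRangeError(f"sample {value} outside [{SAMPLE_MIN}, {SAMPLE_MAX}]")
    return value + 2048


def words_to_bytes(words: Iterable[int]) -> bytes:
    """Serialize 16-bit words low-byte-first for the UART link."""
    out = bytearray()
    for w in words:
        out.append(w & 0xFF)
        out.append((w >> 8) & 0xFF)
    return bytes(out)


def bytes_to_words(data: bytes) -> Iterator[int]:
    """Deserialize a low-byte-first byte stream into 16-bit words."""
    if len(data) % 2:
        raise TransportError(f"odd byte count {len(data)} cannot form 16-bit words")
    for i in range(0, len(data), 2):
        yield data[i] | (data[i + 1] << 8)
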