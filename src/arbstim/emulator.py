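"""Sample-accurate emulator of the two-channel playback state machine.

The real device is an FPGA that stores up to 32 k 12-bit samples per channel
in single-port RAM, interprets 16-bit commands arriving over a UART, and
streams the stored stimulus to one DAC per channel at a configurable sampling
rate.  This module reproduces that behavior at the level a host program can
observe: command side effects, debug readback, the DAC transaction stream and
its timing.  It is sample-accurate, not clock-edge-accurate: UART bit timing,
SPI edges and the FPGA clock are not modeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import CapacityError, ConfigurationError
from .protocol import (
    PAYLOAD_MASK,
    CommandCode,
    CommandWord,
    ReadSelector,
    decode_bytes,
    words_to_bytes,
)

log = logging.getLogger(__name__)

#: Samples per channel: two 16384-word single-port RAM banks.
CAPACITY = 2 * 2**14

#: Sampling-frequency index -> samples per second.
FREQ_TABLE = {0: 30_000, 1: 50_000, 2: 60_000}


def sampling_rate(freq_index: int) -> int:
    """Samples per second for a frequency index (0, 1, 2 -> 30, 50, 60 kHz)."""
    try:
        return FREQ_TABLE[freq_index]
    except KeyError:
        raise ConfigurationError(
            f"unknown frequency index {freq_index}; valid indices are 0, 1, 2"
        ) from None


@dataclass(frozen=True)
class DacTransaction:
    """One 16-bit DAC write: a single 12-bit sample for one channel.

    ``time`` is seconds since playback (re)started from sample 0; consecutive
    transactions on a channel are spaced by exactly one sampling period.
    """

    channel: int
    sample_index: int
    word: int
    time: float


@dataclass
class DeviceState:
    """Full device context: memories, configuration registers and pointers."""

    mem0: list[int] = field(default_factory=lambda: [0] * CAPACITY)
    mem1: list[int] = field(default_factory=lambda: [0] * CAPACITY)
    size_lo: int = 0
    size_hi: int = 0
    freq_index: int = 0
    looped: bool = False
    running: bool = False
    cycle_count: int = 0
    rd_ptr: int = 0
    wr_ptr0: int = 0
    wr_ptr1: int = 0

    @property
    def size(self) -> int:
        """Configured stimulus length in samples (24-bit, from two halves)."""
        return (self.size_hi << 12) | self.size_lo

    @property
    def effective_size(self) -> int:
        """Playback length: the configured size clamped at memory capacity."""
        return min(self.size, CAPACITY)


class DeviceEmulator:
    """Software twin of the stimulator FPGA, driven one command at a time.

    Commands mutate :attr:`state` and may produce response words; playback is
    advanced explicitly with :meth:`advance`, which emits the DAC transaction
    stream both channels would see.  A virtual trigger-out line
    (:attr:`trigger_out`) is asserted while playback is running and gates the
    analog output multiplexer downstream.
    """

    def __init__(self) -> None:
        self.state = DeviceState()
        self._play_count = 0  # transactions emitted since sample 0
        self._rx = bytearray()  # half-received command byte, if any

    # ------------------------------------------------------------------
    # command interpretation

    def apply_command(self, cmd: CommandWord) -> list[int]:
        """Apply one decoded command; return the device's response words."""
        s = self.state
        code, data = cmd.code, cmd.data
        if code == CommandCode.ISDATA0:
            self._store(s.mem0, "wr_ptr0", 0, data)
        elif code == CommandCode.ISDATA1:
            self._store(s.mem1, "wr_ptr1", 1, data)
        elif code == CommandCode.SET_SIZE_LO:
            s.size_lo = data
        elif code == CommandCode.SET_SIZE_HI:
            s.size_hi = data
        elif code == CommandCode.SET_FREQ:
            s.freq_index = data
        elif code == CommandCode.SET_LOOPED:
            s.looped = bool(data & 1)
        elif code == CommandCode.START:
            if s.size == 0:
                log.warning("START ignored: stimulus size is 0")
            else:
                if s.size > CAPACITY:
                    log.warning(
                        "configured size %d exceeds capacity %d; playback "
                        "clamps at capacity", s.size, CAPACITY,
                    )
                s.running = True
        elif code == CommandCode.PAUSE:
            s.running = False  # rd_ptr preserved; next START resumes
        elif code == CommandCode.REWIND:
            s.rd_ptr = 0
            self._play_count = 0
        elif code == CommandCode.WR_REWIND:
            s.wr_ptr0 = 0
            s.wr_ptr1 = 0
        elif code == CommandCode.DBG_ECHO:
            return [cmd.word]
        elif code == CommandCode.DBG_READ:
            return [self._read_context(data)]
        elif code == CommandCode.DBG_DUMP0:
            return self._dump(s.mem0, "wr_ptr0")
        elif code == CommandCode.DBG_DUMP1:
            return self._dump(s.mem1, "wr_ptr1")
        # NOP and UNDEFINED: no effect, no response
        return []

    def _store(self, mem: list[int], ptr_attr: str, channel: int, data: int) -> None:
        ptr = getattr(self.state, ptr_attr)
        if ptr >= CAPACITY:
            raise CapacityError(
                f"channel {channel} memory full: cannot store sample "
                f"{ptr + 1} of a {CAPACITY}-sample memory"
            )
        mem[ptr] = data & PAYLOAD_MASK
        setattr(self.state, ptr_attr, ptr + 1)

    def _read_context(self, selector: int) -> int:
        """DBG_READ: the selected 12-bit context value, MSBs zero.

        An out-of-range selector reads as 0.
        """
        s = self.state
        table = {
            ReadSelector.SIZE_LO: s.size_lo,
            ReadSelector.SIZE_HI: s.size_hi,
            ReadSelector.FREQ: s.freq_index,
            ReadSelector.CYCLE_COUNT: s.cycle_count & PAYLOAD_MASK,
            ReadSelector.RUNNING: int(s.running),
            ReadSelector.LOOPED: int(s.looped),
            ReadSelector.RD_PTR_LO: s.rd_ptr & PAYLOAD_MASK,
            ReadSelector.RD_PTR_HI: s.rd_ptr >> 12,
            ReadSelector.WR_PTR0_LO: s.wr_ptr0 & PAYLOAD_MASK,
            ReadSelector.WR_PTR0_HI: s.wr_ptr0 >> 12,
            ReadSelector.WR_PTR1_LO: s.wr_ptr1 & PAYLOAD_MASK,
            ReadSelector.WR_PTR1_HI: s.wr_ptr1 >> 12,
        }
        try:
            return table[ReadSelector(selector)]
        except ValueError:
            return 0

    def _dump(self, mem: list[int], ptr_attr: str) -> list[int]:
        """DBG_DUMP: stop playback, return the stored stimulus, rewind."""
        s = self.state
        s.running = False
        out = list(mem[: s.effective_size])
        s.rd_ptr = 0
        self._play_count = 0
        setattr(self.state, ptr_attr, 0)
        return out

    # ------------------------------------------------------------------
    # playback

    def advance(self, n_samples: int) -> list[DacTransaction]:
        """Advance playback by up to ``n_samples`` sampling periods.

        While running, each period emits one DAC transaction per channel from
        the shared read pointer.  At the end of the stimulus a looped session
        wraps to sample 0; a one-shot session stops with the read pointer
        parked at ``size``.  Advancing while paused emits nothing.
        """
        s = self.state
        txs: list[DacTransaction] = []
        if not s.running:
            return txs
        fs = sampling_rate(s.freq_index)
        eff = s.effective_size
        if eff == 0:
            s.running = False
            return txs
        emitted = 0
        while emitted < n_samples and s.running:
            if s.rd_ptr >= eff:
                if s.looped:
                    s.rd_ptr = 0
                else:
                    s.running = False
                    break
            idx = s.rd_ptr
            t = self._play_count / fs
            txs.append(DacTransaction(0, idx, s.mem0[idx], t))
            txs.append(DacTransaction(1, idx, s.mem1[idx], t))
            s.rd_ptr += 1
            self._play_count += 1
            s.cycle_count = self._play_count & PAYLOAD_MASK
            emitted += 1
            if s.rd_ptr >= eff:
                if s.looped:
                    s.rd_ptr = 0
                else:
                    s.running = False
        return txs

    @property
    def trigger_out(self) -> bool:
        """Virtual trigger line: asserted while playback runs."""
        return self.state.running

    def external_trigger(self) -> None:
        """A trigger-in edge behaves like receiving a START command."""
        self.apply_command(CommandWord(CommandCode.START, 0))

    # ------------------------------------------------------------------
    # byte-level interface (what the UART deserializer does)

    def feed_bytes(self, data: bytes) -> bytes:
        """Feed raw link bytes; return the serialized response bytes.

        Bytes pair up low-first into 16-bit words; a trailing odd byte is
        held until its partner arrives.
        """
        self._rx.extend(data)
        responses: list[int] = []
        while len(self._rx) >= 2:
            low, high = self._rx[0], self._rx[1]
            del self._rx[:2]
            responses.extend(self.apply_command(decode_bytes(low, high)))
        return words_to_bytes(responses)
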