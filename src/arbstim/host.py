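"""Host-side stimulation controller.

Mirrors the control flow a user script follows against the device: sanitize
the two channel stimuli, probe the link with an echo, rewind, configure size,
frequency and looping, read every configuration register back, upload both
stimuli sample by sample, verify them with full memory dumps, and only then
allow START.  The controller talks through the transport abstraction, so the
same code drives the in-process emulator or real hardware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

from .emulator import CAPACITY
from .errors import (
    CapacityError,
    ConfigurationError,
    LengthMismatchError,
    SampleRangeError,
    TransportError,
    UploadError,
)
from .protocol import (
    SAMPLE_MAX,
    SAMPLE_MIN,
    UART_BAUD,
    UART_BITS_PER_BYTE,
    CommandCode,
    ReadSelector,
    bytes_to_words,
    encode_command,
    encode_sample,
)
from .transport import Transport
from .waveforms import StimulusBuffer

log = logging.getLogger(__name__)

#: Fixed probe payload for the DBG_ECHO link check.
ECHO_PROBE = 0x5A5

FREQ_CHOICES = {30: 0, 50: 1, 60: 2}


@dataclass(frozen=True)
class SessionConfig:
    """User-facing session parameters.

    ``freq`` is in the user-facing kilohertz unit (30/50/60) and maps to the
    device frequency index 0/1/2.  Defaults: 60, not looped.
    """

    path0: str
    path1: str
    freq: int = 60
    looped: bool = False

    def __post_init__(self) -> None:
        if self.freq not in FREQ_CHOICES:
            raise ConfigurationError(
                f"--freq must be one of {sorted(FREQ_CHOICES)}, got {self.freq}"
            )

    @property
    def freq_index(self) -> int:
        return FREQ_CHOICES[self.freq]


@dataclass
class VerificationReport:
    """Outcome of the three verification gates and any mismatches found.

    ``mismatches`` entries are ``(what, sent, received)`` where ``what`` is a
    configuration field name or ``"chN[i]"`` for a stimulus sample.
    """

    echo_ok: bool = False
    readback_ok: bool = False
    dump_ok: bool = False
    mismatches: list[tuple[str, int, int]] = field(default_factory=list)
    upload_seconds: dict[int, float] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return (self.echo_ok and self.readback_ok and self.dump_ok
                and not self.mismatches)


def sanitize(stim0: StimulusBuffer, stim1: StimulusBuffer) -> tuple[StimulusBuffer, StimulusBuffer]:
    """Validate the channel pair before any byte is sent.

    Every sample must be a signed 12-bit integer, both stimuli must have the
    same length (they share one read pointer), and the length must fit the
    per-channel memory.
    """
    for ch, stim in ((0, stim0), (1, stim1)):
        if len(stim) == 0:
            raise SampleRangeError(f"channel {ch}: stimulus is empty")
        lo, hi = int(stim.samples.min()), int(stim.samples.max())
        if lo < SAMPLE_MIN or hi > SAMPLE_MAX:
            raise SampleRangeError(
                f"channel {ch}: sample outside [{SAMPLE_MIN}, {SAMPLE_MAX}] "
                f"(min {lo}, max {hi})"
            )
    if len(stim0) != len(stim1):
        raise LengthMismatchError(
            f"stimuli lengths differ: channel 0 has {len(stim0)}, "
            f"channel 1 has {len(stim1)}"
        )
    if len(stim0) > CAPACITY:
        raise CapacityError(
            f"stimulus length {len(stim0)} exceeds capacity {CAPACITY}"
        )
    return stim0, stim1


class HostController:
    """Drives one stimulation session over a transport.

    START is refused until all three verification gates (echo, configuration
    readback, upload dump) have passed.
    """

    def __init__(self, transport: Transport) -> None:
        self.transport = transport
        self.report = VerificationReport()
        self._size = 0

    # -- low-level helpers ------------------------------------------------

    def _send(self, code: CommandCode, data: int = 0) -> None:
        low, high = encode_command(code, data)
        self.transport.write(bytes([low, high]))

    def _recv_words(self, n: int) -> list[int]:
        return list(bytes_to_words(self.transport.read(2 * n)))

    def _query(self, code: CommandCode, data: int = 0) -> int:
        self._send(code, data)
        return self._recv_words(1)[0]

    def read_context(self, selector: ReadSelector) -> int:
        """DBG_READ one context value from the device."""
        return self._query(CommandCode.DBG_READ, int(selector))

    # -- session stages ---------------------------------------------------

    def configure(self, session: SessionConfig, size: int) -> VerificationReport:
        """Echo probe, rewind, configure, and verify every register readback."""
        echoed = self._query(CommandCode.DBG_ECHO, ECHO_PROBE)
        expected_echo = (int(CommandCode.DBG_ECHO) << 12) | ECHO_PROBE
        self.report.echo_ok = echoed == expected_echo
        if not self.report.echo_ok:
            self.report.mismatches.append(("echo", expected_echo, echoed))
            raise TransportError(
                f"echo probe failed: sent {expected_echo:#06x}, "
                f"received {echoed:#06x}"
            )
        self._send(CommandCode.REWIND)
        self._send(CommandCode.WR_REWIND)
        size_lo, size_hi = size & 0xFFF, size >> 12
        self._send(CommandCode.SET_SIZE_LO, size_lo)
        self._send(CommandCode.SET_SIZE_HI, size_hi)
        self._send(CommandCode.SET_FREQ, session.freq_index)
        self._send(CommandCode.SET_LOOPED, int(session.looped))
        expected = {
            ReadSelector.SIZE_LO: size_lo,
            ReadSelector.SIZE_HI: size_hi,
            ReadSelector.FREQ: session.freq_index,
            ReadSelector.LOOPED: int(session.looped),
        }
        ok = True
        for selector, want in expected.items():
            got = self.read_context(selector)
            log.debug("readback %s: expected %d, got %d", selector.name, want, got)
            if got != want:
                ok = False
                self.report.mismatches.append((selector.name, want, got))
        self.report.readback_ok = ok
        if not ok:
            bad = ", ".join(m[0] for m in self.report.mismatches)
            raise ConfigurationError(f"configuration readback mismatch: {bad}")
        self._size = size
        return self.report

    def upload_and_verify(self, stim0: StimulusBuffer,
                          stim1: StimulusBuffer) -> VerificationReport:
        """Send both stimuli sample by sample, then verify via full dumps."""
        plan = (
            (0, CommandCode.ISDATA0, CommandCode.DBG_DUMP0, stim0),
            (1, CommandCode.ISDATA1, CommandCode.DBG_DUMP1, stim1),
        )
        ok = True
        for ch, isdata, dump, stim in plan:
            fields = [encode_sample(int(s)) for s in stim.samples]
            sent0 = self.transport.bytes_sent
            for f in fields:
                self._send(isdata, f)
            self.report.upload_seconds[ch] = (
                (self.transport.bytes_sent - sent0)
                * UART_BITS_PER_BYTE / UART_BAUD
            )
            self._send(dump)
            received = self._recv_words(len(fields))
            for i, (want, got) in enumerate(zip(fields, received)):
                if want != got:
                    ok = False
                    self.report.mismatches.append((f"ch{ch}[{i}]", want, got))
        self.report.dump_ok = ok
        if not ok:
            first = self.report.mismatches[0]
            raise UploadError(
                f"upload verification failed; first divergence at {first[0]}: "
                f"sent {first[1]}, read {first[2]}"
            )
        return self.report

    # -- playback control --------------------------------------------------

    def start(self) -> None:
        """Issue START; refused until every verification gate has passed."""
        if not self.report.passed:
            raise ConfigurationError(
                "refusing START: verification gates not all passed "
                f"(echo={self.report.echo_ok}, readback={self.report.readback_ok}, "
                f"dump={self.report.dump_ok})"
            )
        self._send(CommandCode.START)

    def is_running(self) -> bool:
        return bool(self.read_context(ReadSelector.RUNNING))

    def pause_if_running(self) -> bool:
        """Send PAUSE only if the device reports RUNNING=1; return whether sent."""
        if self.is_running():
            self._send(CommandCode.PAUSE)
            return True
        return False

    # -- full scripted session ---------------------------------------------

    def run_session(self, session: SessionConfig, stim0: StimulusBuffer,
                    stim1: StimulusBuffer,
                    prompt: Callable[[str], None] | None = None) -> int:
        """Run the complete control flow; return 0 on success.

        ``prompt`` is called before START, before PAUSE and before exit so an
        interactive front end can wait for the user; tests inject a no-op.
        Failures return a nonzero status identifying the stage.
        """
        if prompt is None:
            prompt = lambda _msg: None  # noqa: E731 - unattended default
        stages = {"sanitize": 1, "configure": 2, "upload": 3, "playback": 4}
        stage = "sanitize"
        try:
            sanitize(stim0, stim1)
            stage = "configure"
            self.configure(session, len(stim0))
            stage = "upload"
            self.upload_and_verify(stim0, stim1)
            stage = "playback"
            prompt("Press any key to START stimulation")
            self.start()
            prompt("Press any key to PAUSE stimulation")
            self.pause_if_running()
            prompt("Press any key to exit")
        except Exception as exc:
            log.error("session failed during %s: %s", stage, exc)
            return stages[stage]
        return 0
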