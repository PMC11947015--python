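"""Byte transports linking the host controller to a device.

Two implementations share one contract: an in-process loopback wrapping the
emulator (deterministic, used by the test suite and the default CLI mode) and
a serial port at 1 Mbaud 8N1 for real hardware.  Both count bytes so the host
can model line occupancy (10 bit-times per byte at 1 Mbaud).
"""

from __future__ import annotations

from abc import ABC, abstractmethod

from .emulator import DeviceEmulator
from .errors import TransportError
from .protocol import UART_BAUD, UART_BITS_PER_BYTE


class Transport(ABC):
    """Byte pipe with send/receive accounting."""

    def __init__(self) -> None:
        self.bytes_sent = 0
        self.bytes_received = 0

    @abstractmethod
    def write(self, data: bytes) -> None:
        """Send bytes to the device."""

    @abstractmethod
    def read(self, n: int) -> bytes:
        """Receive exactly ``n`` bytes or raise :class:`TransportError`."""

    def modeled_seconds(self, n_bytes: int) -> float:
        """Line time for ``n_bytes`` at 1 Mbaud with 8N1 framing."""
        return n_bytes * UART_BITS_PER_BYTE / UART_BAUD

    def close(self) -> None:  # pragma: no cover - trivial default
        pass


class LoopbackTransport(Transport):
    """Deterministic in-process link to a :class:`DeviceEmulator`.

    Writes are interpreted immediately; any response bytes queue up for
    subsequent reads.
    """

    def __init__(self, emulator: DeviceEmulator | None = None) -> None:
        super().__init__()
        self.emulator = emulator if emulator is not None else DeviceEmulator()
        self._rx = bytearray()

    def write(self, data: bytes) -> None:
        self.bytes_sent += len(data)
        self._rx.extend(self.emulator.feed_bytes(data))

    def read(self, n: int) -> bytes:
        if len(self._rx) < n:
            raise TransportError(
                f"requested {n} bytes but only {len(self._rx)} available"
            )
        out = bytes(self._rx[:n])
        del self._rx[:n]
        self.bytes_received += n
        return out


class SerialTransport(Transport):
    """Real serial link at 1 Mbaud, 8 data bits, no parity, 1 stop bit.

    Requires the optional ``pyserial`` package; it is imported lazily so the
    rest of the toolkit works without it.
    """

    def __init__(self, port: str, timeout: float = 2.0) -> None:
        super().__init__()
        try:
            import serial
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise TransportError(
                "pyserial is required for hardware sessions; "
                "install it or use the emulator loopback"
            ) from exc
        self._ser = serial.Serial(  # pragma: no cover - needs hardware
            port,
            baudrate=UART_BAUD,
            bytesize=8,
            parity="N",
            stopbits=1,
            timeout=timeout,
        )

    def write(self, data: bytes) -> None:  # pragma: no cover - needs hardware
        self.bytes_sent += len(data)
        self._ser.write(data)

    def read(self, n: int) -> bytes:  # pragma: no cover - needs hardware
        data = self._ser.read(n)
        self.bytes_received += len(data)
        if len(data) < n:
            raise TransportError(f"serial read timed out after {len(data)}/{n} bytes")
        return data

    def close(self) -> None:  # pragma: no cover - needs hardware
        self._ser.close()
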