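import numpy as np
import pytest

from arbstim import CommandCode, CommandWord, DeviceEmulator
from arbstim.protocol import encode_sample


def send(emu: DeviceEmulator, code: CommandCode, data: int = 0) -> list[int]:
    """Apply one command to the emulator, returning its response words."""
    return emu.apply_command(CommandWord(code, data))


def upload(emu: DeviceEmulator, channel: int, samples) -> None:
    """Configure the stimulus size and store samples on one channel."""
    n = len(samples)
    send(emu, CommandCode.SET_SIZE_LO, n & 0xFFF)
    send(emu, CommandCode.SET_SIZE_HI, n >> 12)
    isdata = CommandCode.ISDATA0 if channel == 0 else CommandCode.ISDATA1
    for s in samples:
        send(emu, isdata, encode_sample(int(s)))


@pytest.fixture
def emu() -> DeviceEmulator:
    return DeviceEmulator()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
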