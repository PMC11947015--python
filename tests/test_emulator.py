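"""Playback state-machine behavior: storage, readback, timing, looping.

The first block mirrors the device's own simulation test plan, one test per
behavior: data storage with pointer checks, size/frequency/loop readback,
one-shot and looped playback, pause/resume, both rewinds, and echo.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arbstim import CAPACITY, CommandCode, DeviceEmulator, sampling_rate
from arbstim.errors import CapacityError, ConfigurationError
from arbstim.protocol import ReadSelector, decode_sample, encode_sample
from conftest import send, upload


def read(emu, selector):
    return send(emu, CommandCode.DBG_READ, int(selector))[0]


# ----------------------------------------------------------------------
# device-style verification tests, one per behavior


@pytest.mark.parametrize("channel", [0, 1])
def test_store_data_increments_write_pointer_and_dumps_back(emu, channel):
    """ISDATA: each stored sample advances the channel's write pointer and a
    dump returns the identical sequence."""
    samples = [0, 2047, -2048, -1, 123]
    wr_lo = ReadSelector.WR_PTR0_LO if channel == 0 else ReadSelector.WR_PTR1_LO
    send(emu, CommandCode.SET_SIZE_LO, len(samples))
    isdata = CommandCode.ISDATA0 if channel == 0 else CommandCode.ISDATA1
    for i, s in enumerate(samples):
        send(emu, isdata, encode_sample(s))
        assert read(emu, wr_lo) == i + 1
    dump = CommandCode.DBG_DUMP0 if channel == 0 else CommandCode.DBG_DUMP1
    words = send(emu, dump)
    assert [decode_sample(w) for w in words] == samples
    assert read(emu, wr_lo) == 0  # dump rewinds the write pointer


def test_set_size_lo_readback(emu):
    send(emu, CommandCode.SET_SIZE_LO, 5)
    assert read(emu, ReadSelector.SIZE_LO) == 5


def test_set_size_hi_readback(emu):
    send(emu, CommandCode.SET_SIZE_HI, 0x7)
    assert read(emu, ReadSelector.SIZE_HI) == 0x7
    assert emu.state.size == 0x7 << 12


def test_set_freq_readback(emu):
    send(emu, CommandCode.SET_FREQ, 1)
    assert read(emu, ReadSelector.FREQ) == 1


def test_set_looped_readback(emu):
    send(emu, CommandCode.SET_LOOPED, 1)
    assert read(emu, ReadSelector.LOOPED) == 1
    send(emu, CommandCode.SET_LOOPED, 0)
    assert read(emu, ReadSelector.LOOPED) == 0


def test_start_plays_stored_stimuli_on_both_channels(emu):
    """One-shot playback emits exactly `size` transactions per channel, each
    carrying the stored sample for its index."""
    s0 = [10, -10, 500, -500]
    s1 = [1, 2, 3, 4]
    upload(emu, 0, s0)
    upload(emu, 1, s1)
    send(emu, CommandCode.START)
    txs = emu.advance(10)
    ch0 = [t for t in txs if t.channel == 0]
    ch1 = [t for t in txs if t.channel == 1]
    assert [decode_sample(t.word) for t in ch0] == s0
    assert [decode_sample(t.word) for t in ch1] == s1
    assert [t.sample_index for t in ch0] == [0, 1, 2, 3]
    assert emu.state.running is False
    assert emu.state.rd_ptr == 4  # parked at size until REWIND


def test_looped_playback_repeats_the_stimulus(emu):
    upload(emu, 0, [5, 6, 7, 8])
    send(emu, CommandCode.SET_FREQ, 2)
    send(emu, CommandCode.SET_LOOPED, 1)
    send(emu, CommandCode.START)
    txs = [t for t in emu.advance(10) if t.channel == 0]
    assert [t.sample_index for t in txs] == [0, 1, 2, 3, 0, 1, 2, 3, 0, 1]
    assert emu.state.running is True


def test_pause_preserves_pointer_and_resume_completes_playback(emu):
    """PAUSE mid-stimulus, read the pointer, resume: the concatenated output
    equals an uninterrupted run."""
    samples = [3, 1, 4, 1]
    upload(emu, 0, samples)
    send(emu, CommandCode.START)
    first = [t for t in emu.advance(2) if t.channel == 0]
    send(emu, CommandCode.PAUSE)
    assert read(emu, ReadSelector.RD_PTR_LO) == 2
    assert emu.advance(5) == []  # paused: nothing plays
    send(emu, CommandCode.START)
    rest = [t for t in emu.advance(10) if t.channel == 0]
    played = [decode_sample(t.word) for t in first + rest]
    assert played == samples


def test_rewind_resets_pointer_and_replay_matches_first_run(emu):
    upload(emu, 0, [9, 8, 7])
    send(emu, CommandCode.START)
    run1 = [t.word for t in emu.advance(5) if t.channel == 0]
    assert read(emu, ReadSelector.RD_PTR_LO) == 3
    send(emu, CommandCode.PAUSE)
    send(emu, CommandCode.REWIND)
    assert read(emu, ReadSelector.RD_PTR_LO) == 0
    send(emu, CommandCode.START)
    run2 = [t.word for t in emu.advance(5) if t.channel == 0]
    assert run2 == run1


def test_write_rewind_enables_bit_identical_rewrite(emu):
    upload(emu, 0, [1, 2, 3])
    assert read(emu, ReadSelector.WR_PTR0_LO) == 3
    send(emu, CommandCode.WR_REWIND)
    assert read(emu, ReadSelector.WR_PTR0_LO) == 0
    for s in (7, 8, 9):
        send(emu, CommandCode.ISDATA0, encode_sample(s))
    words = send(emu, CommandCode.DBG_DUMP0)
    assert [decode_sample(w) for w in words] == [7, 8, 9]


def test_echo_returns_the_received_word(emu):
    assert send(emu, CommandCode.DBG_ECHO, 0xABC) == [0xBABC]


# ----------------------------------------------------------------------
# further state-machine semantics


def test_sampling_rate_table():
    assert [sampling_rate(i) for i in (0, 1, 2)] == [30_000, 50_000, 60_000]
    with pytest.raises(ConfigurationError):
        sampling_rate(3)


def test_size_lo_then_read_after_three_stores(emu):
    send(emu, CommandCode.SET_SIZE_LO, 5)
    assert read(emu, ReadSelector.SIZE_LO) == 5
    for _ in range(3):
        send(emu, CommandCode.ISDATA0, 7)
    assert read(emu, ReadSelector.WR_PTR0_LO) == 3


def test_undefined_read_selector_returns_zero(emu):
    send(emu, CommandCode.SET_SIZE_LO, 99)
    assert send(emu, CommandCode.DBG_READ, 0xC) == [0]
    assert send(emu, CommandCode.DBG_READ, 0xFFF) == [0]


def test_nop_and_undefined_change_nothing(emu):
    upload(emu, 0, [1, 2])
    before = (emu.state.size, emu.state.wr_ptr0, emu.state.rd_ptr,
              emu.state.running, list(emu.state.mem0[:4]))
    assert send(emu, CommandCode.NOP, 0x123) == []
    assert send(emu, CommandCode.UNDEFINED, 0x456) == []
    after = (emu.state.size, emu.state.wr_ptr0, emu.state.rd_ptr,
              emu.state.running, list(emu.state.mem0[:4]))
    assert after == before


def test_store_beyond_capacity_raises(emu):
    emu.state.wr_ptr0 = CAPACITY
    with pytest.raises(CapacityError):
        send(emu, CommandCode.ISDATA0, 1)


def test_start_with_zero_size_is_a_noop(emu):
    send(emu, CommandCode.START)
    assert emu.state.running is False
    assert emu.advance(10) == []


def test_size_beyond_capacity_clamps_playback(emu, caplog):
    """The device accepts an oversized SIZE (the host rejects it); playback
    clamps at memory capacity with a warning."""
    send(emu, CommandCode.SET_SIZE_LO, (CAPACITY + 1) & 0xFFF)
    send(emu, CommandCode.SET_SIZE_HI, (CAPACITY + 1) >> 12)
    with caplog.at_level("WARNING"):
        send(emu, CommandCode.START)
    assert "capacity" in caplog.text
    txs = [t for t in emu.advance(CAPACITY + 10) if t.channel == 0]
    assert len(txs) == CAPACITY


def test_transaction_timing_matches_sampling_period(emu):
    for idx in (0, 1, 2):
        e = DeviceEmulator()
        upload(e, 0, [1, 2, 3, 4, 5])
        send(e, CommandCode.SET_FREQ, idx)
        send(e, CommandCode.START)
        times = [t.time for t in e.advance(5) if t.channel == 0]
        diffs = np.diff(times)
        assert np.allclose(diffs, 1.0 / sampling_rate(idx), rtol=0, atol=1e-15)


def test_trigger_out_follows_running_and_external_trigger_starts(emu):
    upload(emu, 0, [1, 2])
    assert emu.trigger_out is False
    emu.external_trigger()
    assert emu.trigger_out is True
    emu.advance(2)
    assert emu.trigger_out is False


def test_byte_interface_handles_split_words(emu):
    """Bytes may arrive one at a time; a half word is held for its partner."""
    assert emu.feed_bytes(b"\xbc") == b""
    out = emu.feed_bytes(b"\xba")  # completes DBG_ECHO 0xABC
    assert out == b"\xbc\xba"


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(st.integers(-2048, 2047), min_size=1, max_size=200))
def test_memory_roundtrip_property(samples):
    """Any stimulus uploads and dumps back bit-identically."""
    emu = DeviceEmulator()
    upload(emu, 1, samples)
    words = send(emu, CommandCode.DBG_DUMP1)
    assert [decode_sample(w) for w in words] == samples


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    st.lists(st.integers(-2048, 2047), min_size=1, max_size=12),
    st.lists(st.integers(0, 5), min_size=1, max_size=10),
)
def test_pause_resume_equivalence_property(samples, chunks):
    """Any interleaving of PAUSE/START that plays out yields the same
    concatenated transaction stream as an uninterrupted run."""
    emu = DeviceEmulator()
    upload(emu, 0, samples)
    send(emu, CommandCode.START)
    played = []
    for n in chunks:
        played += [t for t in emu.advance(n) if t.channel == 0]
        send(emu, CommandCode.PAUSE)
        send(emu, CommandCode.START)
    played += [t for t in emu.advance(len(samples)) if t.channel == 0]
    assert [decode_sample(t.word) for t in played] == samples
    assert [t.sample_index for t in played] == list(range(len(samples)))


def test_dump_stops_ongoing_stimulation(emu):
    upload(emu, 0, [1, 2, 3, 4])
    send(emu, CommandCode.START)
    emu.advance(2)
    send(emu, CommandCode.DBG_DUMP0)
    assert emu.state.running is False
    assert emu.state.rd_ptr == 0
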