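# arbstim

A software twin of a two-channel arbitrary-current-waveform neurostimulator
of the kind used in preclinical neural-engineering research (retinal
prostheses, kilohertz electrical stimulation, temporal-interference
paradigms). The real instrument is an FPGA that stores up to 32 768 signed
12-bit samples per channel, plays them out through a DAC at 30/50/60 kHz,
and drives the electrodes through an analog chain ending in a Howland
current source. This package reproduces that system end to end in Python,
for anyone who needs to design stimuli for such a device, rehearse a
stimulation session without hardware, or reason about what current actually
reaches an electrode of a given impedance.

It provides five pieces:

- **`arbstim.protocol`** — bit-exact codec for the 16-bit command words
  (4-bit command code, 12-bit payload, low byte first on the wire) and the
  two's-complement sample encoding.
- **`arbstim.emulator`** — a sample-accurate emulator of the device's
  command interpreter and playback state machine: sample memories, size /
  frequency / loop registers, read and write pointers, debug readback and
  dump, pause/resume semantics, and the timed DAC transaction stream.
- **`arbstim.signal_chain`** — a behavioral model of one channel's analog
  path. The DAC is a zero-order hold with full scale `V_ref = 3.3 V`; the
  reconstruction filter is a first-order RC with
  `f_c = 1/(2·pi·R·C) = 1/(2·pi·2.2 kΩ·2.2 nF) ≈ 33 kHz`; a subtractor maps
  `[0, V_ref]` onto `[-V_ref, +V_ref]`; the Howland stage is an ideal
  transconductor `I_out = g_m·V_in` with `g_m = 1/R2 = 1 mA/V`, hard-clipped
  when the load voltage would exceed the ±15 V supply; an analog multiplexer
  shorts source and electrode whenever the trigger line is deasserted.
- **`arbstim.waveforms`** — stimulus design: charge-balanced biphasic
  pulses, sines, linear chirps, amplitude-modulated carriers; quantization
  to `round(2047·x)`; a charge-balance report; the one-integer-per-line CSV
  stimulus dialect.
- **`arbstim.host`** — the host-side controller: sanitize both channel
  files, probe the link with an echo, configure and read back every
  register, upload sample by sample, verify by full memory dump, and only
  then permit START. It runs over a transport abstraction, so the same code
  drives the in-process emulator or real hardware on a 1 Mbaud serial port.

## Worked example

Generate the classic preclinical pulse — 500 µs cathodic and anodic phases
with a 10 µs interphase gap at 60 kHz — then run a complete verified
session against the emulator:

```text
$ arbstim generate biphasic ch0.csv ch1.csv
wrote 61 samples per channel to ch0.csv and ch1.csv

$ arbstim stimulate ch0.csv ch1.csv --freq 60 --yes
verification passed: True
channel 0: 61 samples uploaded (1.22 ms modeled line time)
channel 1: 61 samples uploaded (1.22 ms modeled line time)
emulator played 61 samples per channel at 60000 Hz (1.02 ms)
```

The 61 samples are 30 per phase plus a one-sample gap (10 µs rounds up to
one 16.7 µs sampling period); "verification passed" means the echo,
register-readback and memory-dump gates all matched, and the modeled line
time is the byte count times 10 µs per byte at 1 Mbaud 8N1.

Now push that full-scale pulse into a 10 kΩ electrode:

```text
$ arbstim simulate ch0.csv --load-r 10000
delivered current: 3.0000 mA peak-to-peak
load voltage peak: 15.000 V (compliance clipping!)
```

A full-scale sample asks for 3.3 mA, which would need 33 V across 10 kΩ —
far beyond the ±15 V supply — so the source saturates and delivers only
±1.5 mA (3.0 mA peak-to-peak). This is exactly the saturation a
high-impedance microelectrode produces on the bench; at `--load-r 1000` the
same stimulus passes through unclipped.

The analytic design numbers are available as `arbstim budget`
(reconstruction-filter cutoff, memory sizing, minimum sampling rate,
bandwidth, UART throughput, capacity, compliance bound).

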