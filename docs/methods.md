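# Methods

## What is modeled

The package is a software twin of a two-channel arbitrary-waveform current
stimulator: an FPGA-based digital core that stores and plays stimuli, and a
per-channel analog chain that turns DAC codes into electrode current. The
twin has three layers of fidelity:

1. **Bit-exact**: the command protocol. Every 16-bit word (4-bit code,
   12-bit payload), its low-byte-first serialization, and the
   two's-complement sample encoding are reproduced exactly, and the codec
   round trip is verified exhaustively over all 65 536 words.
2. **Sample-accurate**: the playback state machine. Command side effects,
   register readback, pointer arithmetic, pause/resume, looping and dump
   semantics match the device at the granularity of one stimulus sample.
   The emulator is *not* clock-edge-accurate: UART bit timing, SPI edges
   and FPGA clock cycles are below its abstraction floor. The internal
   cycle counter that spaces samples in hardware is surfaced as a
   12-bit free-running sample counter in the debug readback.
3. **Behavioral**: the analog chain. Ideal op-amps, unity-gain zero-delay
   isolation, an ideal transconductor with hard clipping. This is the
   right level for stimulus design questions (what current reaches the
   electrode, when does the source saturate) and deliberately below the
   level of SPICE (no slewing, noise, or supply ripple).

## Digital core

Each channel owns 32 768 sample slots (two 16 384-word single-port RAM
banks); samples are 12-bit payloads stored in 16-bit words. One shared read
pointer drives both channels, which is why the host refuses channel files
of unequal length. The stimulus length register is 24 bits, set as two
12-bit halves; the device itself accepts an oversized length (the check
lives host-side, as in the real control script) and the emulator clamps
playback at capacity with a warning.

Sampling-rate indices 0/1/2 map to 30/50/60 kHz. The device's own register
documentation prints these choices in MHz; the kilohertz reading is the one
consistent with the stated ~60 kHz sampling requirement and the
user-facing `--freq 60` flag, and is what this package implements.

Semantics chosen where the hardware description is silent:

- **DBG_READ response format**: the 12-bit context value in the LSBs with
  the four MSBs zero (the echo command, by contrast, returns the command
  code in its MSBs). An out-of-range selector reads as 0.
- **DBG_DUMP**: returns `size` words, each a stored 12-bit payload
  zero-extended to 16 bits; it stops any ongoing playback and rewinds the
  read pointer and the dumped channel's write pointer.
- **START with size 0** is a no-op that leaves the machine idle.
- **ISDATA while running** is accepted and writes at the write pointer —
  matching what the hardware would do rather than what a careful host
  should do.
- **Trigger**: a virtual trigger-out line is asserted exactly while
  playback runs and gates the analog multiplexer; an external trigger-in
  event is modeled as equivalent to receiving START.

Transaction timestamps are `k / f_s` for the k-th sample emitted since the
read pointer last left zero; pausing does not reset the counter, so a
resumed run concatenates seamlessly (a property the test suite checks over
arbitrary pause/resume interleavings).

## Analog chain

Stage by stage, for DAC code `c` (sample `s + 2048`):

| stage | model | parameters (defaults) |
|---|---|---|
| DAC | zero-order hold, `V = V_ref·c/4096` | `V_ref = 3.3 V` |
| reconstruction filter | 1st-order RC, DC gain 1 | `R = 2.2 kΩ`, `C = 2.2 nF`, `f_c ≈ 32.9 kHz` |
| subtractor | `V → 2V − V_ref` | maps `[0, V_ref]` to `±V_ref` |
| isolation | unity gain, zero delay | — |
| Howland stage | `I = g_m·V`, clip at `±V_s` | `g_m = 1/R2 = 1 mA/V`, `V_s = 15 V` |
| mux | `I → 0` when trigger off | — |

Numerical choices:

- The staircase is rendered on a grid `oversample` × the sampling rate
  (default 32, minimum 8). The filter uses the exact discretization for
  piecewise-constant input, `y[n] = a·y[n−1] + (1−a)·x[n]` with
  `a = exp(−dt/τ)`, initialized settled at the first input value; this
  makes the −3 dB point testable against the closed form
  `1/(1 + j2πfτ)` to 1% without transient contamination.
- The subtractor gain of exactly 2 is a design choice consistent with the
  stated symmetric ±3.3 V output range; the hardware schematic value is
  not published.
- Compliance clipping is instantaneous and exact at ±15 V (no op-amp
  headroom margin): where the ideal load voltage `I·Z` exceeds `V_s`, the
  load voltage pins at `±V_s` and the current scales by `V_s/|V_ideal|`.
  Clipping is idempotent and never engages when the peak demand is within
  compliance.
- Loads are pure resistances or a series RC (access resistance plus
  interfacial capacitance, integrated by trapezoidal accumulation of
  delivered charge). Constant-phase-element electrode models are out of
  scope.
- The Howland compensation capacitor (3 pF) and the op-amp's finite output
  impedance are carried in the parameter set for documentation but not
  dynamically modeled: within the design band (DC–30 kHz) the measured
  response of such a stage is flat, and the bench-observed roll-off to
  ~0.75 mA/V at 30 kHz is a hardware artifact this model intentionally
  does not fit.

## Stimulus toolkit

Waveforms are designed in normalized units (`|x| ≤ 1`, where 1 maps to
+3.3 V at the converter input and hence 3.3 mA into the load) and
quantized symmetrically, `round(2047·x)`, so that negating a waveform
negates its buffer exactly and sign-symmetric stimuli are exactly charge
balanced; −2048 remains legal in input files. Sub-sample durations (e.g. a
10 µs interphase gap at 60 kHz) round to the nearest whole sample with a
warning. Chirps start at zero phase; the rectified-triangle AM envelope
starts at its trough.

The charge-balance report compares `|Σs|` against `tolerance · Σ|s|`; with
chain parameters supplied it also converts to coulombs via
`g_m·V_ref/2048` amps per sample unit. This is a design-hygiene check, not
an electrochemical safety model: material-specific charge-injection
windows are out of scope.

## Host controller and transports

The controller enforces the session order: sanitize → echo probe → rewind
both pointers → set size/frequency/loop → read every register back →
upload one ISDATA per sample → verify by full dump → START only after all
three gates pass (this gate order is asserted by tests over a recording
transport). PAUSE is sent only if a RUNNING readback returns 1. Prompts
are injectable callbacks so unattended runs and tests need no terminal.
Defaults when flags are omitted: 60 kHz, not looped.

Line-time accounting assumes 8N1 framing at 1 Mbaud (10 bit-times per
byte, 100 kB/s): a full 32 768-sample channel uploads in 0.655 s, within
the one-second usability budget. The serial transport imports pyserial
lazily; everything else, including the whole test suite, runs against the
deterministic in-process loopback.

## What the tests do and do not show

All test inputs are generated by the waveform toolkit or written inline;
there are no recorded hardware traces. Passing therefore demonstrates
internal consistency (protocol round trips, state-machine invariants,
agreement of the time-domain chain with its analytic frequency response,
conservation and determinism of playback) and agreement with the published
operating points of the modeled instrument class (1 mA/V transconductance,
2.2 V pp → 2.2 mA pp into 1 kΩ, saturation beyond ±15 V). It does not
demonstrate anything about a physical device's noise, distortion,
high-frequency roll-off, or electrode electrochemistry.

Problem sizes: chain simulations use 10–20 ms of signal at 60 kHz with
32× oversampling; the filter oracle uses a 2 ms window at 64×; the codec
test is exhaustive over all 65 536 words; property tests run a few dozen
derandomized examples each. The suite completes in a few seconds.
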