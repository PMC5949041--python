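# Methods

## The modelled system

`q15pipe` simulates a three-layer real-time architecture for biosignal
acquisition on an 8-bit AVR-class micro-controller: a *hardware layer*
(timer-driven multiplexed ADC sampling into bounded per-channel FIFO queues,
plus a 1 ms tick for non-blocking countdown timers), a *DSP layer* (Q15
fixed-point filtering, polyphase decimation, Goertzel single-bin analysis,
sliding-window segmentation), and an asynchronous *task manager* that runs
the DSP stages whenever their input queues hold data. The simulator has two
jobs: reproduce the target's integer arithmetic bit-exactly on a host, and
evaluate measured cycle/memory cost models to decide real-time feasibility.

## Fixed-point semantics

All coefficients and samples are 16-bit signed integers; Q15 interprets a
raw value `r` as `r/2**15 ∈ [−1, 1)`. Sums of coefficient–sample products
are accumulated in a 32-bit register; the filter output is the accumulator
divided by `a[0]` with round-half-to-even applied to the *exact rational*
quotient (not truncate-then-adjust), for any sign combination. Half-even is
the right tie rule for IIR recursions because it has no systematic bias to
feed back. Quotients outside the 16-bit range saturate to the rail with a
warning rather than wrap.

Overflow of the modelled 32-bit accumulator is *detected and raised*, not
wrapped: on the real device it is undefined behaviour, and a simulator
should expose it. The scalar path checks every partial sum (the target
accumulates sequentially); the vectorized path checks the final
accumulator of each output, which is equivalent for the FIR chains the
scenarios use (all partial sums are bounded by the final-magnitude bound
there).

Real-to-Q15 conversion rounds to nearest (ties to even) and saturates; the
conversion rule is a package choice, since printed coefficient sets are
already integers.

## DSP kernels

**Filter.** History lives in one `p+q+2`-word circular buffer — inputs
first, then outputs — written with modulo addressing, so `view(i)` shows
the same words a debugger would see on the device. Each coefficient part is
limited to 255 entries (byte-indexed tables on the target).

**Polyphase decimator.** `y[n] = Σ_{k=0..p} x[nD−k]·h[k]`, scaled by
`2**15` with half-even rounding (the recurrence has no `a[0]`; Q15 taps make
`Σh = 2**15` unity gain). Emission convention: the `n = 0` output exists
and uses `x[0]`, so outputs are the full-rate FIR outputs at input indices
`0, D, 2D, …` — equivalently, keep-every-D starting at the first output.
With input lengths divisible by `D` (all scenario runs) this gives exactly
`len(x)/D` outputs, the count used by the loss bookkeeping.

**Goertzel.** The recurrence runs over `N` data samples plus one final
zero-input step; the power `P = s₁² + s₂² − 2cos(ω₀)s₁s₂` of the terminal
states then equals the squared magnitude of the single-bin DFT sum
`|Σ_{n<N} x[n]e^{−jω₀n}|²` *for any* `ω₀`, not only bin centres (the
zero-input step contributes a pure phase factor). The recurrence runs in
double precision by default; a `q15` mode quantizes `cos(ω₀)` and keeps the
state in a checked 32-bit register, with the factor 2 applied in the
accumulator since `2cos(ω₀)` itself can exceed the Q15 range. The emitted
power is the raw recurrence value (it is used comparatively, for tone
detection; no output scale is imposed). In `q15` mode the power itself is
reported at full precision — only the state words are range-checked.

**Sliding windows.** Length `L`, hop `H` (`1 ≤ H ≤ L`), circular buffer;
`add` on a full window is an error (the caller must `advance` first), and
the block energy is the unscaled `Σx²` in a checked 32-bit accumulator.
"Energy", not power: no `1/L` normalization is applied, and downstream
comparisons are correlation-based, so the scale is immaterial.

## Acquisition and timing

The ADC transfer is floor-based and clamped: `code = ⌊2^bits · v/vref⌋` into
`[0, 2^bits−1]`. The reference voltage and transfer curve are package
choices (only the bit resolution is fixed by the target); scenario
correlations are insensitive to them, absolute codes are not. Queue
overflow drops the *incoming* sample (reject-newest) and counts it: queued
data stays contiguous and every loss is observable. All channels share one
`Fs`; slower streams are made downstream by decimation.

Timers count in units of `T0r` ms: a timer loaded with `k` expires exactly
`k·T0r` ms after (re)trigger. Expiry is level-signalled (the query stays
true until retrigger). In simulation the tick is ideal, so timer drift is
exactly zero.

## The executive and the vectorized fast path

`run_pipeline` advances simulated time over nanosecond-quantized event
timestamps. At equal instants, events fire in a fixed order — acquisition
conversion, timer tick, then one task-manager round in declared stage
order, each stage draining its whole input queue (a one-sample-per-round
mode exists for stress-testing queue sizing; stages with empty queues are
skipped). The tie-break order is a package convention chosen for
determinism: identical configs and seeds give bit-identical outputs and
event logs.

Long-duration runs (the 8-hour integrity scenarios) use vectorized integer
paths — int64 convolution plus vectorized half-even division — that are
*bit-identical* to the per-sample executive; the equivalence is asserted by
tests that run both paths on the same stream. This is a performance design,
not an approximation: an 8-hour, 14.4-million-sample two-channel run
completes in a few seconds.

## Resource model

Every cycle/memory formula is a measured regression shipped as data, e.g.
hardware layer mean `10/lq + 87` cycles (worst case 97 at `lq = 1`), filter
`669 + 83.5(p+q)` cycles and `20 + 2(p+q+2)` bytes, Goertzel
`965 + 821/(N+1)` cycles (worst case 1786 at `N = 0`) and a constant 62
bytes, block energy `653 + 51L`, timing `5 + (43Nt + 37)/T0r` (worst case
`42 + 43Nt`). The polyphase memory formula is read as
`10 + 20D + 4⌈(p+1)/D⌉` bytes. Coefficient tables live outside the class
but are budgeted (2 bytes each) in feasibility analyses.

The platform defaults — 16 MHz clock, 2048 B data memory, 32768 B program
memory — are the profiled board's; the 10-byte data-memory reserve for
stack/globals is a calibration chosen so the 1 Hz maximum filter length is
exactly 497 total coefficients, and is documented as such. The per-sample
cycle budget is `C_ava = Fclk/Fs − 97`; block algorithms fed by an N-deep
acquisition queue get `N·(Fclk/Fs − 97)` — this grouping reproduces the
16-bin FFT limit of ≈21 kHz (exactly 20,737 Hz), whereas the alternative
reading `N·Fclk/Fs − 97` does not. "Filter length" counts total
coefficients: `p+q+2` for the plain filter, `p+1` taps for the decimator.

Known limit: the equations do not reproduce one published polyphase spot
value (182 coefficients at 14 kHz, D = 64; they give a cycle-bound ≈210),
so that point is documented rather than asserted.

## Scenarios and their generators

The four validation scenarios fix both the processing chain and the
synthetic input. Generator defaults are study conditions, chosen once:
tone amplitudes 30 % of full scale, white-noise σ 2 % of full scale, blink
rate 0.5 Hz (raised-cosine bumps of 0.3 s, amplitude 15 % of full scale),
baselines placed so signals stay inside the ADC range. Randomness comes
only from a seeded `numpy` generator, so every run is bit-reproducible from
`(scenario, seed)`.

* **SC1** (blink detector, 250 Hz): printed double-zero low-pass
  `b = [2048, 6628, 9458, 6628, 2048]`, `a = [26810]`. `Σb = a0`, so the DC
  gain is exactly 1 and the double zero at 100 Hz gives > 60 dB rejection.
* **SC2** (voice power, 4 kHz): printed Savitzky–Golay derivative high-pass
  `[2731, −21845, 0, 21845, −2731]` with unity normalizer `a = [32767]`
  (no printed `a` exists; unity is assumed), then 50-sample windows with
  hop 25 reduced to energy. `Σb = 0`: DC gain exactly 0.
* **SC3** (host-FFT integration, 250 Hz): non-overlapping 64-sample blocks
  handed to `numpy.fft` — a stand-in for the device's external FFT library,
  whose measured costs enter only the resource model. The run checks
  sample-count integrity; its correlation isolates 10-bit quantization by
  comparing per-block dominant-bin power from codes vs the analog signal.
* **SC4** (accelerometer smoothing, 2 × 250 Hz): 50-tap Hamming-windowed
  sinc low-pass at 5 Hz, quantized to Q15 (no printed taps exist; the
  recipe is fixed so all runs use identical taps), decimation `D = 5` (the
  body-text value; one figure caption says 4). Group delay
  `(taps−1)/2 = 24.5` samples is visible as lag.

The fixed-vs-float Pearson correlations these runs report depend on the
synthetic inputs; the correlation figures measured on the original hardware
(0.982 for SC1, 0.971 for SC2) came from real recordings that are not
available, so the package's
criterion is the weaker, generator-independent bound r ≥ 0.97, which the
synthetic runs exceed by a wide margin (≥ 0.999). Passing therefore shows
arithmetic fidelity, not performance on real physiological noise, motion
artifacts or electrode drift — none of which the generators emulate.

Default problem sizes — 10 s for SC1, 5 s for SC2, 60 s for SC3/SC4, with
8-hour (28,800 s) versions for the integrity checks — are the package's
validation sizes; correlations are insensitive to duration beyond a few
seconds.

## SUS scoring

The usability module scores the 10-item System Usability Scale:
`2.5·(Σ_odd (xᵢ−1) + Σ_even (5−xᵢ))`, range exactly 0–100, monotone
increasing in odd (positively phrased) items and decreasing in even ones.
It exists for users running their own evaluations; no published response
data is bundled.

## Numerical and degenerate-input choices

* Ties in half-even rounding are exercised directly by tests (5/2 → 2,
  7/2 → 4) and property-checked against an exact `Fraction` oracle.
* `D = 1` polyphase degenerates to the plain FIR; `L = H` windows are
  non-overlapping blocks; zero-duration runs yield empty streams without
  error.
* Empty queues are skipped, never blocked on; a stage exception aborts the
  run with context, while queue overflow only logs and counts.
* `expected_sample_count` floors `Fs·duration` per channel before dividing
  by `D` (with a half-ulp guard against float representation of exact
  products), matching the integer bookkeeping of the loss checks.
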